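"""Trial-by-trial stabilization of population odor responses.

Each trial's population vector (500 ms response window, or a -2.0 to
-1.5 s pre-odor control window) is scored by its mean Euclidean distance
to the last five awake responses of the same odor ("stable trials"),
normalized by the mean pairwise distance among the stable trials.  A
multiple regression with z-scored predictors (sniff rate, population
firing rate, trial number, and their pairwise interactions) partitions
the trial-by-trial decline; the residuals of a reduced sniff+rate model
expose the trial trend that sniffing and excitability cannot explain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


def distance_to_stable(X: np.ndarray, stable_idx) -> np.ndarray:
    """Normalized distance of every trial to the stable-trial set.

    ``X`` is trials x cells; ``stable_idx`` indexes the 5 stable trials
    (conventionally the last five awake presentations).  For a stable
    trial itself, the self-distance is excluded from its mean.  The
    normalizer is the mean over the 10 distinct stable-stable pairs.
    """
    X = np.asarray(X, float)
    stable_idx = np.asarray(stable_idx, int)
    if stable_idx.size != 5:
        raise ValueError("the stable set must have exactly 5 trials")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 trials")
    S = X[stable_idx]
    pair_d = [np.linalg.norm(S[i] - S[j]) for i in range(5) for j in range(i + 1, 5)]
    norm = float(np.mean(pair_d))
    if norm == 0.0:
        raise ValueError("identical stable trials: distance normalizer is zero")
    D = np.linalg.norm(X[:, None, :] - S[None, :, :], axis=2)  # trials x 5
    out = np.empty(X.shape[0])
    stable_set = set(stable_idx.tolist())
    for t in range(X.shape[0]):
        d = D[t]
        if t in stable_set:
            d = np.delete(d, np.nonzero(stable_idx == t)[0])
        out[t] = d.mean() / norm
    return out


def sniff_rate(first_breath_s) -> np.ndarray:
    """Sniff rate (Hz) = reciprocal of the first breath duration after
    odor presentation; non-positive or missing durations -> NaN."""
    d = np.asarray(first_breath_s, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(d > 0, 1.0 / d, np.nan)


@dataclass
class StabilizationFit:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    residuals: np.ndarray
    n_obs: int
    model: object


def _zscore_columns(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        sd = out[c].std(ddof=0)
        if sd == 0:
            raise ValueError(f"predictor {c!r} is constant")
        out[c] = (out[c] - out[c].mean()) / sd
    return out


def fit_stabilization_regression(distance, sniff_rate_hz, pop_rate_hz,
                                 trial_number,
                                 interactions: bool = True) -> StabilizationFit:
    """OLS of distance-to-stable on z-scored predictors.

    Main effects: sniff rate, population firing rate, trial number;
    plus all pairwise interactions (built from the z-scored mains and
    themselves z-scored) unless ``interactions=False``.
    """
    df = pd.DataFrame({
        "sniff": np.asarray(sniff_rate_hz, float),
        "rate": np.asarray(pop_rate_hz, float),
        "trial": np.asarray(trial_number, float),
    })
    y = np.asarray(distance, float)
    ok = np.isfinite(y) & np.isfinite(df.to_numpy()).all(axis=1)
    df, y = df[ok], y[ok]
    if len(df) < 20:
        raise ValueError("need at least 20 observations")
    Z = _zscore_columns(df)
    if interactions:
        for a, b in (("sniff", "rate"), ("sniff", "trial"), ("rate", "trial")):
            Z[f"{a}:{b}"] = Z[a] * Z[b]
        Z = _zscore_columns(Z)
    design = sm.add_constant(Z)
    if np.linalg.cond(design.to_numpy()) > 1e8:
        corr = Z.corr().abs()
        np.fill_diagonal(corr.to_numpy(), 0)
        worst = corr.stack().idxmax()
        raise ValueError(f"collinear design; worst pair {worst}")
    fit = sm.OLS(y, design).fit()
    return StabilizationFit(params=fit.params, bse=fit.bse,
                            tvalues=fit.tvalues, pvalues=fit.pvalues,
                            residuals=np.asarray(fit.resid), n_obs=len(df),
                            model=fit)


def reduced_model_residuals(distance, sniff_rate_hz, pop_rate_hz,
                            trial_number) -> dict:
    """Residuals of the sniff+rate-only model, examined against trials.

    Returns the residuals paired with trial numbers and the Spearman
    rho (with p) of residual vs trial number: a negative rho means the
    distance declines over trials beyond what sniffing and overall
    excitability explain.
    """
    df = pd.DataFrame({
        "sniff": np.asarray(sniff_rate_hz, float),
        "rate": np.asarray(pop_rate_hz, float),
    })
    y = np.asarray(distance, float)
    trials = np.asarray(trial_number, float)
    ok = np.isfinite(y) & np.isfinite(df.to_numpy()).all(axis=1)
    df, y, trials = df[ok], y[ok], trials[ok]
    if len(df) < 20:
        raise ValueError("need at least 20 observations")
    design = sm.add_constant(_zscore_columns(df))
    fit = sm.OLS(y, design).fit()
    resid = np.asarray(fit.resid)
    rho, p = stats.spearmanr(resid, trials)
    return {"residuals": resid, "trial_number": trials,
            "rho": float(rho), "p": float(p), "model": fit}


def pca_trajectories(X: np.ndarray, stable_idx, k: int = 3) -> dict:
    """Ordinary PCA of trial population vectors with a stable-trial
    ellipsoid (mean +- 1 SD along each component)."""
    X = np.asarray(X, float)
    if X.shape[0] < k:
        warnings.warn(f"only {X.shape[0]} trials; reducing k to {X.shape[0]}",
                      stacklevel=2)
        k = X.shape[0]
    mu = X.mean(axis=0)
    Xc = X - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = Xc @ Vt[:k].T
    var = s**2 / max(X.shape[0] - 1, 1)
    stable = scores[np.asarray(stable_idx, int)]
    return {
        "scores": scores,
        "components": Vt[:k],
        "explained_variance": var[:k],
        "mean": mu,
        "stable_center": stable.mean(axis=0),
        "stable_sd": stable.std(axis=0, ddof=1),
    }
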
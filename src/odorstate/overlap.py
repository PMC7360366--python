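"""Demixed PCA marginalizations and the Matusita overlap of response clouds.

Condition-averaged population activity is decomposed into Stimulus,
State, and Stimulus x State interaction marginalizations (an exact ANOVA
decomposition around the grand mean).  Demixed components are reduced-
rank, optionally ridge-regularized regressions of each marginalization
on the full condition averages.  Single-trial responses projected onto
the top stimulus components form per-(odor, state) Gaussian clouds whose
cross-state overlap is scored with Matusita's measure (the Bhattacharyya
coefficient of two Gaussians):

    xi = 2^(p/2) |S1|^(1/4) |S2|^(1/4) / |S1 + S2|^(1/2)
         * exp(-1/4 (mu1 - mu2)^T (S1 + S2)^(-1) (mu1 - mu2))

xi = 1 for identical clouds and -> 0 for disjoint ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


# --------------------------------------------------------------------------
# marginalization
# --------------------------------------------------------------------------


@dataclass
class MarginalizationSet:
    """Exact decomposition of condition means (cells x odors x states):
    condition mean = grand + stimulus + state + interaction."""

    grand_mean: np.ndarray          # cells
    stimulus: np.ndarray            # cells x odors x states (constant in state)
    state: np.ndarray               # cells x odors x states (constant in odor)
    interaction: np.ndarray         # cells x odors x states

    def reconstruction(self) -> np.ndarray:
        return (self.grand_mean[:, None, None] + self.stimulus + self.state
                + self.interaction)

    def flat(self, which: str) -> np.ndarray:
        """A marginalization as cells x (odors*states)."""
        M = getattr(self, which)
        return M.reshape(M.shape[0], -1)


def condition_means(X: np.ndarray, odors: np.ndarray,
                    states: np.ndarray) -> tuple[np.ndarray, list, list]:
    """Trial matrix (rows x cells) -> cells x odors x states means."""
    odors = np.asarray(odors)
    states = np.asarray(states)
    odor_levels = sorted(np.unique(odors).tolist())
    state_levels = sorted(np.unique(states).tolist())
    n_cells = X.shape[1]
    M = np.full((n_cells, len(odor_levels), len(state_levels)), np.nan)
    for oi, o in enumerate(odor_levels):
        for si, s in enumerate(state_levels):
            sel = (odors == o) & (states == s)
            if not sel.any():
                raise ValueError(f"missing condition odor={o}, state={s}")
            M[:, oi, si] = X[sel].mean(axis=0)
    return M, odor_levels, state_levels


def marginalize(M: np.ndarray) -> MarginalizationSet:
    """ANOVA-style marginalization of a cells x odors x states mean tensor."""
    if M.ndim != 3:
        raise ValueError("expected cells x odors x states condition means")
    grand = M.mean(axis=(1, 2))
    stim = M.mean(axis=2, keepdims=True) - grand[:, None, None]
    state = M.mean(axis=1, keepdims=True) - grand[:, None, None]
    stim = np.broadcast_to(stim, M.shape).copy()
    state = np.broadcast_to(state, M.shape).copy()
    inter = M - grand[:, None, None] - stim - state
    return MarginalizationSet(grand_mean=grand, stimulus=stim, state=state,
                              interaction=inter)


# --------------------------------------------------------------------------
# demixed components
# --------------------------------------------------------------------------


@dataclass
class DemixedComponents:
    """Encoder/decoder axis pairs per marginalization.

    ``decoders[m]`` is k x cells (projection axes), ``encoders[m]`` is
    cells x k; their product reconstructs the marginalized averages with
    non-increasing residual as rank grows.  ``variance[m]`` is each
    component's share of its own marginalization's variance, and
    ``variance_by_marg[m]`` attributes each component's total projected
    variance across all marginalizations.
    """

    decoders: dict[str, np.ndarray]
    encoders: dict[str, np.ndarray]
    variance: dict[str, np.ndarray]
    variance_by_marg: dict[str, dict[str, np.ndarray]]
    grand_mean: np.ndarray


def fit_dpca(marg: MarginalizationSet, n_components: int = 3,
             ridge: float | None = None,
             which: tuple[str, ...] = ("stimulus", "state", "interaction")
             ) -> DemixedComponents:
    """Reduced-rank regression of each marginalization on the full data.

    For marginalization X_m and centered condition averages X, finds the
    rank-k map F D minimizing ||X_m - F D X||_F^2 (+ ridge on the OLS
    step).  Default ridge is 1e-6 x total data variance; pass 0 to
    disable.
    """
    X = (marg.reconstruction() - marg.grand_mean[:, None, None])
    Xf = X.reshape(X.shape[0], -1)
    n_cells, n_cond = Xf.shape
    if n_components > min(n_cells, n_cond):
        raise ValueError("n_components exceeds min(cells, conditions)")
    if ridge is None:
        ridge = 1e-6 * float(np.var(Xf))
    G = Xf @ Xf.T + ridge * np.eye(n_cells)
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError:
        warnings.warn("singular design; forcing ridge regularization",
                      stacklevel=2)
        Ginv = np.linalg.inv(Xf @ Xf.T + max(ridge, 1e-8) * np.eye(n_cells))
    decoders, encoders, variance, var_by = {}, {}, {}, {}
    for m in which:
        Xm = marg.flat(m)
        A = Xm @ Xf.T @ Ginv           # full-rank OLS map
        U, s, Vt = np.linalg.svd(A @ Xf, full_matrices=False)
        F = U[:, :n_components]        # encoder
        D = F.T @ A                    # decoder
        decoders[m] = D
        encoders[m] = F
        tot = float(np.sum(Xm**2))
        comp_var = np.array([float(np.sum((D[k] @ Xm) ** 2)) for k in range(n_components)])
        variance[m] = comp_var / tot if tot > 0 else comp_var
        var_by[m] = {
            other: np.array([float(np.sum((D[k] @ marg.flat(other)) ** 2))
                             for k in range(n_components)])
            for other in which
        }
    return DemixedComponents(decoders=decoders, encoders=encoders,
                             variance=variance, variance_by_marg=var_by,
                             grand_mean=marg.grand_mean)


def project_trials(components: DemixedComponents, X: np.ndarray,
                   marginalization: str = "stimulus", k: int = 3,
                   axes: str = "encoder") -> np.ndarray:
    """Project trial population vectors onto the top-k component axes.

    ``axes="encoder"`` (default) projects onto the orthonormal component
    directions in neural space, which preserves any state- or
    interaction-dependent displacement a trial carries along those
    directions; ``axes="decoder"`` applies the demixing read-out, whose
    projections of the condition means reproduce the reduced-rank
    reconstruction scores but which suppresses the other
    marginalizations by construction.
    """
    if axes == "encoder":
        A = components.encoders[marginalization]  # cells x k
        if k > A.shape[1]:
            raise ValueError(f"requested {k} components, have {A.shape[1]}")
        W = A[:, :k]
    elif axes == "decoder":
        D = components.decoders[marginalization]
        if k > D.shape[0]:
            raise ValueError(f"requested {k} components, have {D.shape[0]}")
        W = D[:k].T
    else:
        raise ValueError(f"unknown axes {axes!r}")
    Xc = np.asarray(X, float) - components.grand_mean
    return Xc @ W


# --------------------------------------------------------------------------
# Gaussian clouds and Matusita overlap
# --------------------------------------------------------------------------


@dataclass
class GaussianCloud:
    mu: np.ndarray
    sigma: np.ndarray
    n_trials: int
    odor: int | None = None
    state: str | None = None
    rank_deficient: bool = False

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, float)
        self.sigma = np.asarray(self.sigma, float)
        if self.sigma.shape != (self.mu.size, self.mu.size):
            raise ValueError("covariance shape does not match mean")
        if not np.allclose(self.sigma, self.sigma.T):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.sigma).min() < -1e-10:
            raise ValueError("covariance is not PSD")


def trial_clouds(scores: np.ndarray, odors: np.ndarray,
                 states: np.ndarray) -> dict[tuple, GaussianCloud]:
    """Group projected trials into per-(odor, state) Gaussian clouds
    (unbiased covariance, n-1 denominator)."""
    out = {}
    odors = np.asarray(odors)
    states = np.asarray(states)
    p = scores.shape[1]
    for o in np.unique(odors):
        for s in np.unique(states):
            sel = (odors == o) & (states == s)
            pts = scores[sel]
            if not sel.any():
                continue
            mu = pts.mean(axis=0)
            if pts.shape[0] > 1:
                sigma = np.cov(pts.T, ddof=1).reshape(p, p)
            else:
                sigma = np.zeros((p, p))
            cloud = GaussianCloud(mu=mu, sigma=sigma, n_trials=pts.shape[0],
                                  odor=int(o), state=str(s),
                                  rank_deficient=pts.shape[0] < p + 1)
            out[(int(o), str(s))] = cloud
    return out


def matusita_overlap(a: GaussianCloud, b: GaussianCloud,
                     ridge: float = 1e-8) -> float:
    """Matusita's overlap (Bhattacharyya coefficient) of two Gaussians.

    Symmetric in its arguments, 1 iff the clouds coincide, in [0, 1]
    for all PSD covariances.  A ridge is added to S1 + S2 when it is
    numerically singular.
    """
    if a.mu.size != b.mu.size:
        raise ValueError("clouds must share the same dimension")
    p = a.mu.size
    s1, s2 = a.sigma, b.sigma
    sign, logdet_sum = np.linalg.slogdet(s1 + s2)
    if sign <= 0 or logdet_sum < -300:
        # ridge both covariances consistently so xi(A, A) stays exactly 1
        warnings.warn("near-singular covariance sum; adding ridge", stacklevel=2)
        s1 = s1 + ridge * np.eye(p)
        s2 = s2 + ridge * np.eye(p)
    s_sum = s1 + s2
    _, logdet_sum = np.linalg.slogdet(s_sum)
    _, ld1 = np.linalg.slogdet(s1)
    _, ld2 = np.linalg.slogdet(s2)
    d = a.mu - b.mu
    maha = float(d @ np.linalg.solve(s_sum, d))
    log_xi = (p / 2.0) * np.log(2.0) + 0.25 * (ld1 + ld2) \
        - 0.5 * logdet_sum - 0.25 * maha
    return float(np.exp(log_xi))


def overlap_contrast(scores_a, scores_b) -> dict:
    """Unpaired equal-variance t-test on per-odor overlap scores."""
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 overlap scores per group")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return {"t": float(t), "df": int(a.size + b.size - 2), "p": float(p)}
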
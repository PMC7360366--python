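# Methods

`odorstate` re-implements a cross-brain-state analysis of olfactory
population codes: how odor representations in the olfactory bulb (OB)
and piriform cortex (PCx) behave when the brain switches from wakefulness
to ketamine/xylazine (k/x) anesthesia. Because the original extracellular
recordings are not bundled with the package, every stage is validated on
a ground-truthed spike-train simulator that reproduces the statistical
structure the analyses assume. This note documents the models, the
estimators, the numerical choices, and what the synthetic validation does
and does not establish.

## The recording model

A session consists of simultaneously sorted units from one region, a
trial table (6 odors, ~15 awake presentations each followed by ~7 under
k/x), and a respiration airflow trace (negative = inhalation). All
analyses are sniff-referenced: response windows start at the first
inhalation at or after odor onset, baselines at the last inhalation
strictly before onset, and post-odor analyses at the first inhalation
after odor offset.

**Trial selection.** The standard analysis subset is the last 7 awake
trials before anesthesia induction (early trials carry sniff-related
variability and response drift) and the first 7 trials after behavioral
anesthesia onset. The stabilization analysis instead uses the first 15
awake presentations of each odor, unexcluded.

**Unit stability criteria.** Units are discarded if their overall rate
falls below 0.01 Hz, their rate changes more than 100-fold across states,
or their mean peak-to-peak waveform amplitude changes by more than
50 µV. Boundaries are strict: a unit exactly at any threshold is kept.
"Overall rate" is computed over the full duration of each state, a
denominator choice the QC table records explicitly.

## Single-cell statistics

**Response index.** For each cell-odor-state, spike counts over the first
sniff after odor onset are compared with counts over the last pre-odor
sniff. The response index is 2·auROC − 1, where auROC is the probability
that an evoked trial count exceeds a baseline trial count (ties count
half); ±1 means complete separation. Significance uses a two-sided
Wilcoxon rank-sum test at α = 0.05 — exact, tie-aware permutation
enumeration when both groups have ≤ 10 trials (the usual case at 7
trials), a tie-corrected normal approximation otherwise. A pair is
*robust* if significantly activated in both states, otherwise
state-specific (awake-only / k/x-only) or unresponsive.

**Sparseness.** Treves–Rolls sparseness
S = (1 − (Σr/n)²/(Σr²/n)) / (1 − 1/n), bounded in [0, 1] with 1 = a
one-hot tuning vector. The formula is applied across odors for lifetime
sparseness and across cells for population sparseness; the
Willmore–Tolhurst (unnormalized) variant is available via a flag.

**Latency and peak.** PSTHs are built in 10 ms bins, smoothed with a
20 ms Gaussian kernel (smoothing can be disabled); onset latency is the
first post-alignment time where the smoothed rate exceeds the baseline
mean + 2.5 baseline SD for at least two consecutive bins, and peak is the
maximum smoothed rate in the response epoch. Zero baseline variance falls
back to an epsilon threshold with a warning.

**Respiratory phase and PPC.** Each spike's phase interpolates linearly
from inhalation onset (0°) to exhalation onset (180°); the
exhalation-to-next-inhalation half maps to [180°, 360°) — an extension
beyond the two anchor points, chosen for continuity. Pairwise phase
consistency is the mean cosine of all pairwise phase differences,
computed through the resultant-vector identity
PPC = (|Σe^{iθ}|² − n)/(n(n−1)), which equals the O(n²) pair sum exactly
and is unbiased (uniform phases give expectation 0).

**Bootstrap difference test.** Group contrasts of per-cell statistics
resample size-matched groups with replacement from the pooled values
1000 times; the two-sided p is add-one corrected,
p = (1 + #{|null| ≥ |empirical|})/(1 + n_boot). Confidence intervals are
within-group percentile bootstraps.

## Population geometry

**Pseudopopulations.** Cells from separate sessions are pooled by
matching within-odor trial order (trial k of one session pairs with
trial k of the others); this preserves the trial-number structure the
stabilization analysis needs. Random pairing is available behind a flag.

**Separation.** Trial population vectors (first-sniff counts) are
correlated pairwise (Pearson); separation = mean within-odor − mean
across-odor correlation. A trial is never paired with itself (self-pairs
with r = 1 would inflate separation), so 7 trials × 2 odors give 21
within-odor pairs per odor and 49 across-odor pairs. The cross-state
variant correlates awake trials against k/x trials and likewise excludes
index-matched same-odor pairs. The OB-vs-PCx contrast is tested against
a null that draws size-matched pseudo-regions with replacement from the
pooled cells.

**Noise correlations.** Within a sliding window around inhalation
(120/60/30 ms bins, 30 ms step), counts are z-scored across trials per
cell per stimulus; Pearson correlations per simultaneously recorded cell
pair are averaged across pairs, then stimuli, then sessions — the
averaging order is asserted by a test where the orders differ. A shared
log-normal gain g (E[g] = 1, configurable SD) applied to Poisson rates
induces ρ = λ²v/(λ + λ²v) with v = Var(g) for equal-rate cells, which the
estimator recovers within ±0.02 at 500 trials.

## Decoding

Odor identity is decoded from 480 ms spike-count vectors with a linear
multiclass SVM using the Crammer–Singer objective (scikit-learn
`LinearSVC`, C = 1 by default and exposed; no feature scaling by default,
matching raw-count features; a z-scoring flag exists). Within-state
accuracy uses stratified seeded 10-fold cross-validation (folds reduce
with a warning when a class has fewer trials); every trial is held out
exactly once, which the fold builder verifies. Accuracy-versus-size
curves average 200 random cell subsets per size (fewer in the desk-scale
drivers; the number is a parameter) with percentile-bootstrap CIs on the
mean (1000 resamples). Cross-state decoding trains on all awake trials
and tests on all anesthetized trials with no cross-validation.

**Cross-time decoding.** Rates are kernel-smoothed (Gaussian, SD 200 ms,
truncated at 4 SD) and aligned to the first inhalation after odor
offset, spanning −1.5 to +4 s. For every train/test bin pair the
classifier is trained with leave-one-trial-out so that no bin of the
held-out trial ever enters training; the diagonal is same-bin decoding.
The default bin grid is 100 ms (coarser in the drivers to bound run
time).

## Demixed PCA and the Matusita overlap

Condition means (cells × odors × states) decompose exactly into grand
mean + stimulus effect (state-averaged) + state effect (odor-averaged) +
interaction — an ANOVA identity the tests check to machine precision.
For each marginalization, components solve a reduced-rank (ridge
λ = 1e-6 × data variance, exposed) regression of the marginalized
averages on the full centered condition means; encoder axes are the left
singular vectors of the fitted map, decoders the corresponding read-out
rows, with a per-component variance ledger across marginalizations. This
is a deliberate simplification of full dPCA: there is no per-trial noise
marginalization.

Single 500 ms trials are projected onto the top 3 stimulus components.
The projection uses the orthonormal component axes in neural space (the
encoder axes — equivalent to axes from PCA on stimulus-averaged
responses, which is the stated conceptual analogy for this decomposition).
This is a deliberate design choice: the demixing *read-out* (decoder)
annihilates the state and interaction condition patterns by construction
(their condition-space row spaces are orthogonal to the stimulus rows),
which would erase precisely the cross-state displacement of same-odor
response clouds that the overlap score is meant to measure. Decoder-axis
projection remains available (`axes="decoder"`) and reproduces the
reduced-rank reconstruction scores on condition means.

Per (odor, state), the projected trials form a Gaussian cloud (mean and
unbiased covariance). The overlap of awake and k/x clouds is Matusita's
measure, the Bhattacharyya coefficient of two Gaussians:

ξ = 2^{p/2} |Σ₁|^{1/4}|Σ₂|^{1/4} / |Σ₁+Σ₂|^{1/2} ·
exp(−¼ (μ₁−μ₂)ᵀ(Σ₁+Σ₂)⁻¹(μ₁−μ₂))

ξ ∈ [0, 1], ξ(A, A) = 1 identically; computation is in log space via
`slogdet`, and a 1e-8 ridge is added to *both* covariances (consistently,
so the self-overlap identity survives) only when the sum is numerically
singular. A Monte-Carlo check integrates √(f₁f₂) by importance sampling
from the equal mixture (f₁+f₂)/2, whose weights are bounded by 1
(AM–GM), and agrees within 1%. Region contrasts use an unpaired
equal-variance t-test over the six per-odor scores (df = n₁+n₂−2).

## Stabilization

Per session-odor, trial population vectors (500 ms response window, or a
control window 2.0–1.5 s before odor inhalation) are scored by
distance-to-stable: the mean Euclidean distance to the last five awake
responses, normalized by the mean pairwise distance among those five.
Stable trials exclude their own zero self-distance (including it would
deflate late-trial distances); identical stable trials raise an error
naming the series. The statistic is invariant to cell permutation and
common scaling.

Pooled across session-odor series, distance is regressed on z-scored
sniff rate (reciprocal of the first post-odor breath duration),
population mean rate, and trial number, plus all three pairwise
interactions (themselves z-scored; the three-way term is excluded). A
reduced model with only sniff and rate is fit, and the Spearman ρ of its
residuals against trial number isolates the trial effect that sniffing
and excitability cannot explain. Designs with condition number above
1e8 are rejected with the offending columns named. Pooling is a single
OLS across series (per-session fits behind a flag); no random effects.

One calibration fact worth recording: for stationary data the trial
coefficient's t statistic is essentially nominal (SD ≈ 1.03 across
simulated nulls), so about 4.5–5% of stationary runs exceed |t| = 2 by
construction — a 2σ screen on a single run is evidence, not proof, of a
trial effect; the residual-trend contrast between profiles is the more
interpretable readout.

## Opto-tagging

Inhibitory-opsin (Arch/Jaws) tagging uses twenty 1 s laser pulses: a
unit is tagged iff the rank-sum test comparing per-pulse counts in the
1 s before vs during the pulse gives p < 1e-4 AND the median last-spike
latency from pulse onset is below threshold; pulses with no spikes
contribute latency 0. Units with overall rates < 0.175 Hz or peak-trough
times < 0.35 ms are excluded from classification entirely. The printed
latency threshold in the source protocol reads 0.01 ms, which is
physically implausible for a 1 s silencing pulse; the default here is
0.01 s (10 ms) and the threshold is a parameter. ChR2 tagging accepts an
externally computed SALT p-value plus the latency-to-peak criterion; the
SALT algorithm itself is out of scope.

## The synthetic-data generator

Spikes are drawn from an inhomogeneous Poisson process thinned on a 1 ms
grid:

rate_i(t) = base_i(state) · gain(trial) · (1 + d(state)·cos θ(t)) + evoked_i(t)

* **Baselines.** Per-cell rates are log-normal (σ = 0.7) around the
  profile means: OB 6.58 Hz awake / 2.62 Hz k/x (measured values for
  mitral/tufted populations); PCx 4.0 / 3.0 Hz — PCx spontaneous rates
  are not pinned by a printed number, so weakly state-dependent values
  were chosen once to reflect the qualitative observation that PCx
  activity is comparatively state-robust.
* **Respiration.** Awake breath durations are gamma (shape 4, mean
  0.25 s) clipped to instantaneous rates of 2–12 Hz (irregular); k/x
  durations are normal (0.5 ± 0.02 s, metronomic). Airflow is a
  negative half-sine during inhalation (40% of the cycle) and a positive
  half-sine during exhalation. Respiratory phase θ advances linearly
  inhalation→exhalation (0→π) and exhalation→next inhalation (π→2π).
* **Entrainment.** Phase modulation depth d is 0.8 under k/x and 0.2× as
  much awake; the time-average of cos θ over full cycles is zero, so
  entrainment conserves mean rate.
* **Responses.** Each cell-odor pair draws a class per profile — OB-like:
  4% robust, 22% awake-only, 4% k/x-only, 10% suppressed; PCx-like: 14%
  robust (amplitude ×1.5), 8% awake-only, 3% k/x-only, 12% suppressed;
  TeLC-like: PCx-like class mix but no robust amplification and no
  trial drift. Evoked transients are half-Gaussian rises (60 ms) to a
  log-normal peak (mean 20 Hz, σ_log = 0.5) followed by 200 ms
  exponential decay, aligned to the first inhalation after odor onset.
  Onset latencies are 50 ± 15 ms for robust and 70 ± 20 ms for
  state-specific responses — inside the first sniff, as sniff-coupled
  responses are, and shorter for robust responses. Suppression is a rate
  decrement of 70% of the cell's baseline, floored at zero.
* **Drift and sniffing.** Awake trials carry a multiplicative response
  factor 1 + a·exp(−trial/τ) (a = 1, τ = 4 trials) and an elevated sniff
  rate (×1.5) during odor sampling on the first five presentations;
  evoked amplitude additionally scales with (sniff rate / 4 Hz)^0.5, so
  sniffing is a genuine confound for the stabilization regression.
* **Noise correlations.** A per-trial log-normal gain (σ = 0.2, E = 1)
  multiplies a configurable fraction of cells (default all), inducing
  weak positive spike-count correlations.

What the generator does **not** emulate: biophysics or recurrent
dynamics (the profiles encode outcomes, not mechanisms), LFPs beyond the
airflow trace, bursting/refractoriness (pure Poisson), electrode drift,
or spike-sorting artifacts. Passing tests therefore establish that the
estimators recover planted structure under the assumed statistics — not
that real recordings satisfy those assumptions.

## Problem sizes and reproducibility

The test-suite and driver runs use desk-scale study conditions chosen to
keep full runs fast while preserving every contrast: 30–80 cells per
region, 6 odors, 15 awake + 7 k/x presentations (7 awake where drift is
irrelevant), 1–3 sessions per pseudopopulation, and 25–50 cell-subsample
draws per decoding point. The acceptance script
(`scripts/acceptance.py`) regenerates everything from a single `--seed`;
all stage seeds derive from it through named substreams, and identical
configurations reproduce outputs byte-for-byte.

## Appendix: deterministic test fixtures

`make_fixture` returns small hand-specified sessions used by the unit
tests:

* **tiny-2odor** — 4 cells × 2 odors × 4 trials, 10 s per trial, odor on
  at 2 s after trial start (exactly on an inhalation onset of the
  regular 0.5 s breathing, so the response alignment *is* that
  inhalation, the baseline inhalation is 0.5 s earlier, and every first
  breath lasts 0.5 s). Spike counts placed in each trial's 480 ms
  response window:

  | cell | odor 0 trials | odor 1 trials | role |
  |------|---------------|---------------|------|
  | 0 | 5, 6, 5, 4 | 0, 1, 0, 1 | odor-0 selective |
  | 1 | 1, 0, 1, 0 | 6, 5, 7, 6 | odor-1 selective |
  | 2 | 2, 2, 2, 2 | 2, 2, 2, 2 | untuned |
  | 3 | 0, 0, 0, 0 | 0, 0, 0, 0 | silent |

* **qc-edge-cases** — stability-criterion boundary units: unit 0 at
  exactly 0.01 Hz (kept), unit 1 with an exactly 100-fold rate change
  (kept), unit 2 with a 51 µV amplitude change (discarded), unit 3 a
  clean keeper.
* **phase-locked** — one unit whose every spike falls exactly on an
  inhalation onset (phase 0°, PPC = 1).
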
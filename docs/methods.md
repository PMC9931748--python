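# Methods

`covnet` compares the covariance structure of brain networks between two
subject groups — here called V (the comparison group) and NV (the control
group) — in four large-scale networks: default mode (DMN, 4 nodes),
salience (SN, 7 nodes), dorsal attention (DAN, 4 nodes) and
fronto-parietal (FPN, 4 nodes), 19 regions of interest (ROIs) in total.
It does so for three structural gray-matter measures (GMM, GMV, GMD,
treated identically downstream) and for resting-state (RS) time series.

## Pipeline model

**Extraction.** Each ROI value is the mean over the ROI's voxels of the
subject's segment image (GMD/GMM) or the voxel sum times voxel volume
(GMV, mm^3); RS series are per-timepoint ROI means. No resampling is
performed: images must share the atlas grid exactly.

**Time-series conditioning.** Per subject and ROI: the first 4 volumes
are discarded (field saturation), a quadratic polynomial trend is
removed, a 4th-order Butterworth band-pass of 0.01–0.08 Hz is applied
forward–backward (zero phase; TR = 1.6 s gives a Nyquist of 0.3125 Hz),
and the series is z-scored over time. Conditioning is only approximately
idempotent: re-filtering already band-limited data attenuates band-edge
content again (the squared Butterworth response), so the package tests
near-idempotence (per-column correlation > 0.98), not exact
reapplication stability.

**Deconfounding.** ROI columns are residualized by OLS on z-scored
numeric confounds (age, number of other psychotropic drugs, and — for
structural data only — total intracranial volume) and dummy-encoded
categorical confounds (sex, psychiatric diagnosis, antidepressant use),
with an intercept, then re-standardized. Residualization on a fixed
design is a projection, hence idempotent. For time series the
subject-level design rows are expanded to one row per retained timepoint
and the pooled series is residualized, mirroring the structural path.

**Group networks.** A Gaussian graphical model is estimated per group by
the graphical lasso: maximize `log det T − tr(S T) − λ Σ_{i≠j} |T_ij|`
over positive-definite precision matrices T, where S is the empirical
covariance of standardized group data (subjects × 19 for structural
measures; pooled timepoints × 19 for RS, assuming one shared functional
structure per group). The penalty acts on off-diagonals only so the
partial-correlation scale is untouched. Partial correlations are
`P_ij = −T_ij / sqrt(T_ii T_jj)`; zeros of T are conditional
independences and map to exact zeros of P (threshold 1e-10). λ is chosen
by 3-fold cross-validated held-out log-likelihood on a log-spaced grid
over `[0.01 λmax, λmax]` (λmax = largest |off-diagonal| of S, at which
the solution is diagonal), with iterative grid refinement; folds are
shuffled by a seed, so selection is deterministic. The solver is
sklearn's coordinate-descent graphical lasso; when its duality-gap
criterion is not met within the iteration budget the last iterate is
kept and marked `converged=False` — its KKT residual is typically
1e-4–1e-3, which is far below the bootstrap envelope resolution — while
hard failures (ill-conditioned resamples) raise and are dropped.

**Edge differences.** The control group is resampled with replacement B
times at its original size (whole subjects; for RS a drawn subject
contributes its entire series, preserving temporal dependence), the
network is re-estimated per resample, and each edge's percentile
interval at two-sided level α (default 1e-5, i.e. a 99.999% interval)
forms the null envelope. With B draws the finest attainable two-sided
level is 2/(B+1); finer requests are clamped to the (min, max) envelope
and the effective level is recorded alongside the nominal one. A victim
edge outside the envelope is flagged −1 (less covariance in V) or +1.
By default the cross-validated penalty selection is re-run inside every
bootstrap replicate, so the envelope includes penalty-selection
variability; a fixed-λ fast mode exists for large B.

**Known statistical property — anti-conservatism.** The envelope is
centered on the control *sample* estimate, which itself deviates from
the population value by about one sampling SD, and the victim estimate
carries its own sampling SD; their difference has roughly twice the
variance the envelope accounts for. In simulation with both groups drawn
from the same distribution (n = 32 per group), the fixed-λ mode flags
edges at roughly an order of magnitude above the effective level; with
CV re-run per replicate the envelope widens (penalty-selection
variability) and the excess drops to ~2.5×. Under the same analysis, a
planted edge difference of Δ = −0.4 in partial correlation at
n = 100/group is detected in only ~80% of runs, with several false edges
per run, because the rule effectively demands a ~3σ excursion of a
single noisy estimate. These are properties of the procedure being
implemented, reproduced deliberately; the package reports the effective
level and leaves the interpretation to the analyst. The acceptance suite
measures both properties honestly (see `tests/test_acceptance.py`).

**Summaries.** Nonzero flags are tallied over the 10 network-pair
categories (4 within + 6 between) and over the 19 nodes (each edge
touches two). Category shares are percentages of flagged edges, node
shares of 2× flagged edges. Ties in "most affected network" are
reported as ties.

**Brain–behavior CCA.** Brain features are the deconfounded structural
values of every node incident to a flagged edge (per modality, labeled
e.g. `GMD DMN.PCUN`) plus, per flagged RS edge, the subject-level
correlation of the two conditioned series. Behavior is the eight scores
BDI, STAI-trait, SCI stress exposure, TMT, VFT_1, VFT_2, MWT_B and digit
span (ZNS). CCA is solved by QR + SVD of the whitened cross-covariance;
variates are unit-variance, with signs fixed so the largest-|loading| X
variable loads positively. Mode k is tested sequentially with Wilks'
Λ_k = Π_{i≥k}(1 − r_i²) via the symmetric textbook Rao F approximation
(which reduces exactly to the simple-correlation F test at p = q = 1);
statsmodels' CanCorr, used as an independent oracle in the tests, applies
the SAS/MANOVA df convention — Λ agrees exactly, p-values to ~1e-2.
P-values are Bonferroni-multiplied by the number of modes, and a mode is
significant only if all earlier modes are (sequential rule; note the raw
sequential p-values are not monotone in general). Loadings are Pearson
correlations of inputs with variates; the report keeps |r| strictly
greater than 0.2. When n ≤ p + q the canonical correlations are
degenerate (r = 1 regardless of signal); the fit is refused unless
`allow_overfit=True` is passed explicitly.

## Synthetic data

The generator emulates the study conditions end to end: two groups of 32
subjects, 19 ROIs, 250 RS volumes at TR = 1.6 s, with group-level
precision matrices built from a network-block partial-correlation target
(within-network w = 0.12, between-network b = 0.02). These defaults are
the largest round values that keep the implied unit-diagonal precision
comfortably positive definite — a constant within-block partial
correlation above 1/6 is mathematically infeasible for the 7-node SN
block — and infeasible targets are shrunk uniformly with a log message.
Group differences are planted directly on the partial-correlation scale
(the pipeline's readout) and mapped back to a precision matrix. RS
series follow a stationary AR(1) process (φ = 0.4) whose innovations are
scaled so the marginal cross-sectional covariance equals the target;
structural values get confound-driven shifts (age, sex, TIV slopes), and
behavioral scores share a latent factor with the planted-edge nodes
(behavior–latent correlation 0.5, brain–latent 0.3) at the means and SDs
of a realistic clinical sample, giving the CCA stage a recoverable
ground-truth mode. Volumetric fixtures paint ROI values into small
NIfTI images so extraction round-trips exactly at zero noise.

What the generator does not emulate: hemodynamics, motion or scanner
batch effects, spatial noise correlation, subject-level heterogeneity of
network structure within a group. Passing tests therefore demonstrate
correctness of the estimators and the detection machinery under the
stated model, not robustness to real acquisition artifacts.

## Numerical and design choices

- All randomness flows from one master seed through named CRC32-keyed
  substreams (`simulate.substream`), so e.g. changing B does not perturb
  fold assignment. TSV floats use 12 significant digits; identical seeds
  give byte-identical outputs.
- Bootstrap refits use a relaxed solver tolerance (dual gap 1e-3, 50
  iterations) — envelope quantiles do not need the 1e-7 gap used for
  point estimates; replicates whose solver fails hard are dropped and
  counted, and more than 5% failures abort the run.
- Subjects are processed in lexicographic id order everywhere.
- Structural z-scoring happens within group after deconfounding (this is
  what makes group covariance interpretable as correlation); time series
  are z-scored per ROI within subject over time.
- Test and acceptance problem sizes are scaled so the whole suite runs
  on a single CPU. The null-calibration test uses the fixed-penalty mode
  (the only one that reaches B = 1000) over 50 replicate datasets of
  n = 32 per group — the Monte-Carlo SE of the flag rate is far inside
  the margin being tested; `scripts/acceptance.py` additionally measures
  the CV-per-replicate variant at B = 150. The power check runs 20
  seeded repetitions at n = 100/group, B = 500; the Wilks permutation
  oracle uses 10^4 draws; the CCA null calibration 500 draws.

## Limitations

- The group comparison is the percentile-envelope rule described above,
  with its documented anti-conservatism; it is not a calibrated
  two-sample test (a permutation test would be, but is out of scope).
- Network estimation is group-level only; subject-level functional
  connectivity appears solely as CCA features.
- No spatial registration: images must already live on the atlas grid.
- The bundled atlas fixture is a synthetic block parcellation for
  testing; real analyses should load their own label image and network
  table.
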
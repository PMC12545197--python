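# Methods

## The model

Each cortical voxel's preprocessed BOLD time series `y_v(t)` is modelled as
a linear readout of delayed linguistic features:

    y_v(t) = Σ_b Σ_d x_b(t − d)ᵀ w_{v,b,d} + ε_v(t),    d ∈ {2, …, 7} s

where `b` indexes feature bands (the production and comprehension embedding
blocks in the separate model; a single block in the unified and
single-modality models) and the FIR delays `d` absorb the sluggish, regionally
variable hemodynamic coupling without assuming a canonical response shape.
`x_b(t)` is the per-TR contextual-embedding vector of band `b` at the chosen
(layer, context-length) cell; TRs where the band's modality is silent are
zero rows, which keeps both bands on one common time axis so that joint
banded fitting and weight swapping are well defined.

Weights are estimated by banded ridge regression: a separate penalty per
band, selected per voxel on the Cartesian grid of ten log-spaced values
between 10⁻² and 10⁷ (100 pairs for two bands) by 5-fold inner
cross-validation with *contiguous* temporal folds (shuffled TR folds would
leak autocorrelated signal). Selection minimizes mean validation MSE per
voxel; ties take the first pair in grid order, making fits deterministic.
The solver rescales band columns by `1/√α_b` and solves a unit-penalty ridge
via the primal normal equations when P ≤ T and the dual (kernel) form when
P > T, so designs far wider than the number of TRs (33,792 columns) are
handled exactly. Per-band Gram matrices are precomputed once per fold so the
10 × 10 grid costs one Cholesky solve per pair, not one Gram product.

Evaluation is leave-one-session-out: the model, including the inner penalty
search, is refit for every held-out session and scored by Pearson r between
predicted and observed responses. Weights are stored per fold and
fold-averaged for all weight-space analyses (the single tuning map reported
per condition is less noisy than per-fold maps). Zero-variance predictions
or targets score r = 0 and are flagged, rather than propagating NaNs.

### Cross-modality generalization

For the separate model the production and comprehension weight blocks are
exchanged — feature index and delay preserved — and the swapped model is
re-scored per fold on the same held-out sessions. The swap is an exact
involution. A voxel is "cross-modal" when r > 0.05 in both the same- and
swapped-modality scoring.

### Inference

Per fold, a one-sided permutation test shuffles the order of contiguous
20-TR blocks of the held-out time series (blocks preserve local
autocorrelation; a partial tail block moves as one unit) 1,000 times;
p = (1 + #{null r ≥ observed r}) / (n_perm + 1), so p is never zero. Fold p
values combine by Fisher's method (−2Σln p against χ² with 2k df) and are
FDR-corrected across voxels by Benjamini–Hochberg. "Linguistic" voxels are
those with q < 0.05.

### Variance partitioning

With R² defined as `max(r, 0)²` of the cross-validated predictions of the
joint (separate), production-only and comprehension-only models:

    unique_production    = R²_joint − R²_comprehension
    unique_comprehension = R²_joint − R²_production
    shared               = R²_production + R²_comprehension − R²_joint

The three terms sum to R²_joint exactly; CV sampling can make individual
terms negative, and those are clipped to zero *after* the identity is
formed — each term independently, without redistributing the clipped mass,
trading forced additivity for transparency. Components are reported on the
square-root scale to stay commensurate with correlation-based accuracy.
Negative r is clipped before squaring because squaring would alias the sign
of chance-level anticorrelated predictions into spurious explained variance.
Voxels whose separate-model r exceeds 0.05 are labelled by their largest
component (production / comprehension / bimodal), ties breaking toward
shared then production; all other voxels are "none". TRs are used as-is
despite unequal per-modality sample counts.

### Weight-space PCA

Per band, FIR weights are averaged over the six delay copies of each feature
(33,792 → 5,632 mean weights for the separate model), each voxel's tuning
column is scaled by `max(r_v, 0)`, and a mean-centred PCA is run over voxels.
A parallel "stimulus PCA" over the per-TR embeddings themselves serves as the
null reference: structure present in the features does not by itself make a
weight component meaningful. The top 20 components of each side are matched
one-to-one by Gale–Shapley stable marriage with preferences given by the
absolute Pearson correlation between loading vectors (the only quantity both
sides share); the weight side proposes, and ties break deterministically by
index. Significance uses 1,000 bootstrap resamples — voxels resampled with
replacement on the weight side, TR utterances on the stimulus side, these
being each PCA's observation units — recomputing each matched pair's
variance-explained fraction by projecting the resampled data onto the
*original* loadings (fixing component identity avoids order switching;
refitting per resample is available behind `refit=True`). A weight PC is
significant only if its stimulus partner explains more variance in **zero**
of the 1,000 resamples (exceedance p < 0.001). Utterance reports rank the
Pearson correlation between a loading vector and each utterance embedding,
top-20 in each direction, ties to the earlier TR.

## The synthetic generator

The generator produces data with the statistical structure the analysis
assumes, plus known ground truth, so every stage is testable without any
download.

- **Turn-taking** is an independent two-state Markov chain per modality,
  restarted per run. Defaults target the occupancies of natural dialogue
  (~217 of 430 TRs produced and ~214 comprehended per 7-min run) with a mean
  speaking-bout of 3 TRs — conversational turns of a few seconds. Both
  modalities may overlap within a TR. Only occupancy and bout scale are
  modelled; real turn-taking dynamics (interruptions, back-channels) are not.
- **Embeddings**: each present TR draws a latent content vector; the
  embedding at context length L is the mean of latent vectors over the
  trailing L seconds where the modality is present, mirroring token
  averaging over a growing window, so feature autocorrelation grows
  monotonically with L. The first `shared_dims` coordinates carry a common
  "topic" stream, AR(1) with coefficient 0.9 (topic persistence of roughly
  ten seconds): this is what makes the two interlocutors' content — and
  hence shared explained variance — correlated even though they rarely speak
  simultaneously. Modality-unique coordinates are white in time. Real
  embedding geometry (anisotropy, token-frequency effects) is not emulated,
  so passing tests certify the pipeline's statistical behaviour, not
  performance on real language.
- **Voxel classes**: production-only / comprehension-only voxels are tuned
  in the modality-unique coordinates; *bimodal* voxels are tuned inside the
  shared-topic block with exactly orthogonal production/comprehension
  tunings (independently tuned, yet dominated by shared variance — the
  shared content, not tuning similarity, is what the intersection term
  measures); *cross-modal* voxels have tunings whose empirical correlation
  equals ρ exactly (the residual is orthogonalized before mixing, since a
  sampled construction would miss a ±0.05 band at small D); *null* voxels
  are zero. Class allocation is deterministic largest-remainder.
- **BOLD**: the band drives are mixed through a fixed delay profile over
  2–7 s (peak near 4–5 s), realized per run, plus AR(1) noise (coefficient
  0.3) — the minimal noise model that makes block permutation non-trivially
  necessary. `oracle_noise_sd` sets the noise so that a perfect decoder
  would score a chosen r (0.5 in the standard scenarios), putting all
  recovery statements on a common SNR footing.
- **Motion**: random-walk rigid-body parameters; frame-wise displacement
  sums absolute translation steps plus rotation steps converted to arc
  length at a 50 mm cortex-to-head-centre radius, FD(0) = 0.
- All randomness flows from one root seed through named substreams
  (schedule / embeddings / truth / noise / motion).

## Numerical and design choices

- Segment-to-TR assignment uses the midpoint with floor on half-open bins: a
  midpoint exactly on a boundary goes to the later TR (deterministic,
  consistent with 0-based half-open indexing throughout).
- The unified model averages the two modalities' embeddings where both are
  present and falls back to the single present modality otherwise.
- FIR delays never cross run boundaries; rows whose lag would reach into the
  previous run are zero. A delay exceeding a run length yields all-zero
  columns with a warning.
- BOLD preprocessing: per voxel per run, subtract a centred 120-s running
  median with edge-truncated windows (truncation avoids fabricating pre-scan
  signal; the cost is a small residual ramp in the first/last half-window),
  then standardize to zero mean, unit variance. Zero-variance voxels are
  flagged and zeroed.
- Sessions with fewer than 20 TRs are excluded from LOSO with a warning; an
  all-zero design yields zero weights at the maximal penalty.
- The full-menu widths (78 cells, 5,632, 33,792, 5,632 delay-averaged, 2,816
  PCs) are asserted at full dimensionality; all simulation-based suites run
  at reduced size — D = 32 features, 150–500 voxels, 4 sessions of 1–3 runs
  of 430 TRs — chosen so the complete test suite and the reproduction script
  each finish in minutes on a single CPU while leaving comfortable margins
  on every recovery threshold.

## Known limitations

- Tuning-correlation estimates are attenuated by weight-estimation noise
  (≈ ρ × reliability²); at the standard scenario sizes the bias is a few
  hundredths. Where production and comprehension regressors are strongly
  correlated (shared content), per-band credit assignment also biases the
  estimated tuning correlation of redundantly driven voxels upward; the
  generator's solo-speech stretches are what keep per-band tunings
  identifiable.
- The per-voxel penalty search is exhaustive over the band grid, which is
  tractable for two bands; more bands would need a smarter search.
- The documented feature total for the FIR-expanded separate model is
  5,632 × 6 = 33,792; one alternative figure sometimes quoted for this
  configuration (34,932) is inconsistent with that arithmetic and is not
  used.
- Volumetric geometry is out of scope: BOLD is handled as [TR × voxel]
  matrices; NIfTI inputs would be flattened through a mask at ingest.
- The CLI intentionally covers only the simulate → sweep → report loop; the
  per-stage operations are the library surface.
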
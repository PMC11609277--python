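# Methods

`globalmeth` re-implements, as a tested library, the computational readouts
used to characterise a CRISPR effector (a dCas9–DNMT3A "SAM" recruitment
system) that deposits DNA methylation globally rather than at its sgRNA
target. Each module mirrors one experimental readout; a synthetic-data module
generates inputs with the statistical structure each analysis assumes, so
every stage can be validated end to end without array, sequencing or imaging
data.

## Methylome fold-change analysis

**Model.** Two arms — cells with active DNMT3A versus a catalytically
inactive control (plus an untransduced mock) — are profiled on a CpG array
yielding beta values β ∈ [0, 1] per probe and sample.

**Procedure.** (1) Probes whose detection p-value exceeds 0.01 in *any*
sample are dropped (strict inequality; the conservative whole-row drop is
used because per-sample masking would desynchronise replicate pairing).
(2) Betas are quantile normalized across samples: each column is mapped onto
the row-wise mean of the sorted columns, average ranks for ties. (3) Per CpG
and replicate pair r, FC_r = max(β_active, 0.01) / max(β_inactive, 0.01);
the reported FC is the arithmetic mean over replicate pairs (pairing by
replicate index). The 0.01 floor guards ratios at unmethylated sites; it is
a modelling choice, configurable. (4) The genome-wide summary is the mean FC
over retained probes; per-CpG log2 FCs export as a 0-based half-open
bedGraph (probe manifests are 1-based, Illumina convention). (5) Sample
structure is summarised by classical (Torgerson) MDS on Euclidean distances
between beta vectors: double-centred squared-distance matrix, top-k
eigenvectors scaled by √eigenvalue, each axis sign-fixed so its first
nonzero loading is positive.

**A caveat worth knowing.** Across-sample quantile normalization *removes*
genuinely global methylation differences: it forces identical marginal
distributions, so an arm-wide shift survives only through rank reordering.
With a shift applied to every CpG the post-normalization mean FC collapses
to ≈1. The default `methylome run` pipeline therefore offers
`--no-normalize`; shift-recovery analyses (including the acceptance
script's 3-fold scenario) compute FC on unnormalized betas, while null
calibration uses the full normalized path, where the symmetric null is
unaffected.

## Chromatin-state enrichment

Hypermethylated CpGs (FC ≥ 2, inclusive) are counted per chromHMM-style
chromatin state after assigning each probe to the unique interval containing
it (1-based position p lies in 0-based half-open [start, end) iff
start ≤ p−1 < end; a probe whose 0-based coordinate misses every interval is
"unassigned" but remains in the sampling universe, since it is on the
array). The null re-draws the same number of probes uniformly without
replacement from the full probe universe, 100 times by default, recording
per-state membership counts; Z = (observed − null mean)/null sd with the
n−1 sample sd, undefined when the null is degenerate. Marginally each
state's null count is hypergeometric, which the tests verify analytically.

An alternative null (`null_mode="fc-recount"`) draws, per state, as many
random probes as the state contains and re-counts FC ≥ 2 sites among them —
the other natural reading of "select the same number of CpG sites and count
the significant ones". Both nulls are calibrated against the same
hypergeometric law for a genome-wide partition; `membership` is the default.

## Pooled-screen scoring

Guide counts are normalized to log2(reads-per-million + 1); the per-guide
log-fold-change is the replicate-paired mean of active − inactive
abundance; a region's gene score is the unweighted mean LFC of its guides
(the screen's region-level statistic; rank-aggregation scoring is
deliberately out of scope). Robust z-scores centre region scores on the median of pseudo-regions built
from consecutive blocks of 10 non-targeting guides (matching the
10-guides-per-region library design); the null spread of an n-guide region
is the scaled MAD (1.4826×) of the non-targeting guide LFCs divided by √n —
pooling all ~737 control guides keeps the spread estimate stable, where a
MAD over the ~73 pseudo-region scores would carry ~13% noise and visibly
inflate the 3σ tail.
Arm concordance is the Pearson r (two-tailed t-transform p) of
replicate-averaged guide abundances or of region scores between arms — the
diagnostic that, in a no-hit screen, shows a tight diagonal.

## HRM percent-methylation

After bisulfite conversion, methylated amplicons melt at higher temperature.
Curves are normalized by fitting linear baselines in a pre-melt and a
post-melt window and rescaling to (F − post)/(pre − post). Default windows
span the first and last max(2 °C, 15% of the grid): a fitted baseline is
extrapolated across the entire grid, so its slope error grows linearly with
distance — on the instrument's 60–95 °C ramp, 2 °C windows would let
realistic fluorescence noise (σ ≈ 0.01) distort the normalized curve by
~0.1 near the transition, an order of magnitude above the quantification
tolerance. The methylated fraction is the closed-form least-squares
coefficient of the sample curve against the 0% and 100% standard curves,
clipped to [0, 1]; the 25% and 50% standards are held out as accuracy
checks. The estimate is exact on any noise-free convex combination of the
end members and monotone in the true fraction.

## Single-particle tracking

Spots are local maxima of the scale-normalized LoG response
(−s²·∇²G_s ∗ I) above a threshold, minimum separation 2s, refined to
sub-pixel by a 3-point quadratic fit per axis. Frame-to-frame linking solves
the standard LAP with link cost = squared displacement (forbidden beyond
`max_disp`) against per-detection termination and birth alternatives of cost
`max_disp²`; there is no gap closing and no merge/split, so a missed
detection terminates its track. Per-track time-averaged MSD uses lags up to
25% of the track length (variance control). The fit is nonlinear least
squares of MSD(t) = 4·D·t^α + 2·σ², bounds D ≥ 0, α ∈ (0, 2], σ ≥ 0,
initialised from a zero-lag extrapolation for σ and a log-log regression of
the σ-corrected first lags for D and α — without the σ pre-estimate a flat
curve is degenerate (α → 0 folds the constant into D). Mobility summaries
keep tracks of ≥ 5 consecutive frames with fit R² ≥ 0.8; the quality filter
is a *minimum* (an R² ceiling would retain only bad fits) and is
user-overridable. Two-condition contrasts report the difference of median D
with a bootstrap percentile interval.

## Synthetic data: what it emulates, what it does not

* **Methylome** (defaults: 20,000 CpGs on 5 chromosomes, 10 uniform
  chromatin states, 3 replicates/arm): baseline per-CpG means are
  Beta(0.85, 0.85) — bimodal, as array beta distributions are — and
  per-sample betas are Beta-distributed about the arm mean at precision 120
  (beta sd ≈ 0.045 at β = 0.5, typical array replicate noise). The active arm
  raises a CpG's mean by `global_shift` (default 0.3, clipped below 1) with
  probability `shift_probability × state multiplier` (defaults 0.3 and 1).
  A shift of 0.2805 with shift probability 1 gives a true mean FC of 3.0
  (root-found by direct Monte Carlo of the generative model) — the
  generator's analogue of the ~3-fold global increase the effector induces.
  Detection p-values exceed 0.01 at rate 0.005. Not emulated: Infinium
  probe-type chemistry, batch effects, copy-number confounding, spatial
  correlation of methylation along the genome.
* **Screen** (defaults: 1009 regions × 10 guides, 737 non-targeting, 262
  AAVS1 guides, depth 500, duplicate arms): counts are negative binomial
  (dispersion 20; count CV ≈ 0.23 at depth 500) around a per-guide mean
  whose log2 offset (SD 1.2) is shared across arms — the
  library-representation spread that produces the tight guide-abundance
  diagonal of a null screen; r ≈ var/(var + noise) ≈ 0.96 analytically,
  matching published screen replicate correlations. Effects enter as
  2^(log2 effect) on the active-arm mean only.
* **Tracking**: increments are fractional Gaussian noise (Hurst H = α/2;
  Cholesky of the exact Toeplitz autocovariance, reducing to i.i.d. Gaussian
  steps at α = 1) scaled so the 2-D ensemble MSD is 4·D·t^α, plus isotropic
  localization noise. Defaults mirror the imaging conditions: 30 ms frames,
  0.107 µm pixels, PSF σ 1.3 px, peak 300 counts on background 100
  (SNR ≈ 15). Not emulated: blinking/photobleaching, motion blur within a
  frame, drift, axial defocus.
* **Melt curves**: two logistic transitions (Tm 82 °C methylated, 76 °C
  unmethylated, width 1 °C) mixed by the true fraction, on the instrument's
  60–95 °C/0.1 °C grid, with i.i.d. Gaussian noise (σ 0.01) on standards and
  unknowns alike. Not emulated: amplicon-specific multi-domain melting,
  temperature-dependent dye quenching.

Because the generators are idealisations, passing tests demonstrate that the
*algorithms* are correct and calibrated under their stated assumptions — not
that real arrays, screens or movies are free of the artefacts listed above.

## Numerical choices and degenerate inputs

Quantile normalization interpolates the reference at average-rank positions,
so it is exact for tie-free columns and idempotent. Fold-change floors both
numerator and denominator, making FC antisymmetric under arm swap whenever
no flooring triggers. Classical MDS clamps negative eigenvalues to zero
before the square root. Enrichment Z is reported as NaN when the null sd is
zero. The melt estimator raises when the 0% and 100% standards coincide
(no melt separation — fraction unidentifiable). `fit_msd` reports a flagged
non-converged fit rather than raising; `summarize_mobility` raises only when
*no* track survives filtering. LAP linking breaks cost ties by solver order;
tests assert cost-optimality, not a particular tie-break.

## Problem sizes

Calibration suites use 200 null methylomes of 20,000 CpGs (enrichment),
20-seed full-size screens, 300-track ensembles (MSD), five 100-frame 64 px
movies (imaging closure), and 100-draw melt recoveries — sizes at which every
acceptance statistic's sampling error is comfortably below its tolerance.

## Known limitations

Replicate pairing is by index; a pairing-free (mean-of-arms) estimator is
not offered. The enrichment test ignores spatial autocorrelation of probes
within chromatin states (as does the resampling design it implements).
Gene-score robust z assumes non-targeting guides behave like
region-targeting nulls. The tracker has no gap closing, so blinking
fragments tracks rather than bridging them. IDAT parsing, probe-type bias
correction, rank-aggregation screen scoring and chromHMM training are out of
scope by design.
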
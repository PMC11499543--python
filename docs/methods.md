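# Methods

## The measurement and the pipeline model

An nCounter run digitally counts probe–mRNA hybridization events for a fixed
codeset: here ~56 endogenous immune genes (containing a 30-gene ISG panel
plus NF-κB-regulated and IFN-γ-regulated panels), 3 housekeeping genes
(*NRDC*, *OTUD5*, *TUBB*), 6 spiked-in positive controls at a descending
concentration ladder, and negative controls at background. Lanes are run in
cartridges of 12, each cartridge also carrying healthy donor reference
samples.

Raw counts confound three things: the biology of interest, the optical/
chemical efficiency of the lane, and the amount of RNA loaded. The pipeline
models both nuisance terms as per-sample multiplicative factors and removes
them in two steps sharing one construction. For a scope of n samples,

    factor_i = (1/n * sum_j geomean_j) / geomean_i

where geomean_i is the geometric mean of the control probes in sample i —
positive controls for step 1, housekeeping genes for step 2. The normalized
value is raw × pos_factor × hk_factor. Two algebraic consequences are used
as exact tests: after step 1 all samples in a scope share one
positive-control geomean (and likewise for housekeeping after step 2), and
the scope mean of control geomeans is conserved, i.e. the scope is rescaled
to its own average lane rather than to an external standard.

### Decisions where the construction was genuinely open

* **Basis of the housekeeping factor.** The factor formula is stated once
  for both control sets without fixing whether housekeeping geomeans are
  taken on raw or on step-1-rescaled counts. The default follows the vendor
  convention — housekeeping geomeans on step-1 output — which is what makes
  the housekeeping-equalization invariant exact. `hk_factor_on_raw: true`
  computes both factors from raw counts for reproduction studies; the final
  product raw × f_pos × f_hk differs then only through the hk factor.
* **Scope of n.** Default `per_batch`: each cartridge is normalized against
  itself, because lane-to-lane effects within a cartridge are what the
  positive controls calibrate, and each cartridge carries its own healthy
  references. `global` pools the whole cohort; it is also the right scope
  when *measuring* lane-factor recovery, since per-batch factors recover
  lane factors only up to one free constant per batch.
* **Zeros.** Geometric means are undefined at 0, and negative-control-level
  probes do hit 0. Counts are floored at `pseudocount` (default 1) inside
  geomean computations only; stored values are never altered. At nCounter
  background levels (single digits) a floor of 1 is a negligible
  distortion.
* **No background subtraction.** Negative controls are carried through and
  available for QC but never subtracted; subtraction would break the purely
  multiplicative model and is not needed for the well-expressed panels the
  scores use.

## Scores

* **Geomean score** — geometric mean of normalized counts over the panel.
  It is scale-equivariant (doubling every panel gene doubles the score),
  insensitive to panel gene order, and monotone in each gene. This is the
  single per-sample "ISG" number used for longitudinal monitoring.
* **Z-score** — per gene, log2(value + pseudocount) standardized by the
  healthy-reference mean and SD of the same transform, averaged over the
  panel. The log base (2) and the per-gene-then-average construction follow
  the common whole-blood interferon-score practice. Per-gene z values are
  clipped at ±10 by default (`z_truncation`) so that a single saturated
  probe cannot dominate a 30-gene average; `null` disables clipping.
* **Reference fitting** — all healthy, unstimulated samples in the run, at
  least 2. A gene with (near-)zero variance across references would make z
  explode, so per-gene SDs are floored at 10% of the panel-median SD (with
  a tiny absolute floor for the fully degenerate all-identical case); every
  flooring is warned about. The healthy band is the 2.5th–97.5th percentile
  of healthy geomean scores by default (`reference_band`), min–max via
  `(0, 100)`.

## Stimulation assay

Paired aliquots of one draw (exact match on subject and date), one cultured
with IFN-β and one without; either uncultured blood or the cultured
unstimulated control may serve as denominator — both are distinct
stimulation statuses in the sample sheet, and two simultaneous candidates
raise an ambiguity error rather than a silent choice. The induction ratio
stim/unstim is reported raw; the responsive/non-responsive call uses a
configurable threshold, default 2-fold, chosen so that clearly induced
healthy blood (severalfold) and fully blocked blood (ratio ≈ 1) fall on
opposite sides while partial escape (≈1.8-fold) is called non-responsive.
The call is deliberately secondary to the reported ratio.

## Panels are configuration

The exact identities of validated ISG/NF-κB/IFN-γ panels are
assay-specific and not something this package should hard-code. The bundled
defaults have the correct structure — 30 ISGs, disjoint 10-gene NF-κB and
IFN-γ lists, *NRDC*/*OTUD5*/*TUBB* housekeeping, POS_A–F — with ISG members
drawn from the published whole-blood interferon-score literature, and are
marked as placeholders in the config file itself. Scores computed with
different gene lists are not comparable across studies.

## Synthetic cohorts: what they emulate and what they do not

The generator draws, from a single seed:

* lane factors LogNormal(0, σ_lane), default σ_lane = 0.3 — a realistic
  spread of lane efficiencies (±35% typical);
* per-cohort gene baselines LogNormal(log 150, 0.6) for endogenous genes;
  housekeeping levels fixed (600/400/2000), independent of disease by
  construction;
* endogenous and housekeeping counts NegBin(mean = lane × baseline ×
  effect, size = 50): overdispersed but not wild — CV ≈ 15% above Poisson
  at high counts;
* positive controls Poisson around lane × 60 × (128, 32, 8, 2, 0.5, 0.125)
  and negative controls Poisson around lane × 2 — counting of spiked
  material is near-Poisson;
* the ISG effect: θ^s × m, with θ the fold-elevation in patients (default
  8, a markedly elevated untreated signature), s ∈ [0, 1] the residual
  fraction of the elevation on the log scale (1 = untreated, 0 = fully
  suppressed; a tapering trajectory is a schedule of s values), and m the
  stimulation multiplier on stimulated aliquots (default 5).

Samples are packed into batches of 12 with at least 2 healthy unstimulated
references per batch (an error otherwise, since reference fitting would be
impossible downstream). `expected_scores` gives the analytic noise-free ISG
geomean score (geomean of ISG baselines × θ^s × m, lane factors removed) as
an oracle for recovery tests.

Not emulated: probe-specific hybridization efficiencies (all biology is
relative to per-gene baselines, which the scores' geometric means absorb),
cartridge-level QC failures, cross-hybridization, RNA degradation, batch-
correlated biology, or clinical covariates. Passing recovery tests
therefore shows the pipeline's arithmetic and inference are correct under
the stated multiplicative count model — not that any particular clinical
cohort satisfies that model.

## Problem sizes and numerical tolerances

Validation uses: a hand-computed 3-lane oracle (factors exactly 7/3, 7/6,
7/12, checked to 1e-12 against a pure-Python loop transcription of the
formula); equalization and conservation invariants at 1e-9 relative
deviation; lane-factor recovery on 24 lanes at σ_lane = 0.3 (Pearson r
against 1/pos_factor under global scope, ≥ 0.95 at the tested seed);
elevation recovery with 20 patients vs 20 healthy at θ = 8 (median-ratio
within ±20%); null calibration over 100 seeded 20-vs-20 cohorts at θ = 1
(two-sided Mann–Whitney at α = 0.01 non-significant in ≥95%); stimulation
classification over 100 seeded replicates each of m = 5 and m = 1 (≥95%
correct). Rank-correlation score recovery is evaluated across samples with
graded suppression s ∈ [0, 1], because samples sharing one true score are
fully tied and carry no rank information. These sizes keep the full suite
and the acceptance script in the tens of seconds on one CPU while leaving
wide statistical margins.

## Known limitations

* Probe symbols must be unique across the whole codeset (the matrix is
  symbol-indexed); real codesets satisfy this.
* Dates in machine-readable inputs are ISO-8601 only.
* The per-batch normalization makes scores comparable across batches only
  through the healthy references each batch carries; no explicit
  cross-batch calibration beyond the two factors is attempted.
* No statistical test for treatment effect is provided; cohorts of this
  kind are far too small, and the intended output is the trajectory against
  the healthy band.
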
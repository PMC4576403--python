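# Methods

This note records the models, conventions and numerical choices behind
`cytogi`, and what the synthetic-data results do and do not demonstrate.

## Auto-gating model

The gating stage is a grid-density clusterer in the "clustering without K"
family. For one sample with events `x ∈ R^d` (d = 7 channels by default):

1. **Binning.** Each channel's observed (per-file) range is split into
   `n_bins` equal-width intervals (default 12); each event falls into one
   hyper-rectangular bin. A constant channel collapses to a single bin with
   a warning.
2. **Dense bins.** A bin is *dense* when it holds at least
   `min_density_fraction × n_events` events (default 0.001), floored at 2
   events — a lone event is treated as an outlier, not a cluster seed.
   Without the floor, any sample with fewer than 1000 events would make
   every occupied bin dense and every stray tail event its own cluster.
3. **Merging.** Dense bins that are Chebyshev-adjacent (any of the 3^d − 1
   grid neighbors) join one cluster via connected components. The result is
   independent of bin enumeration order.
4. **Total assignment.** Every event in a non-dense bin is attached to the
   cluster of the nearest dense-bin centroid (Euclidean distance on
   per-file z-scored channels; centroids are the event means of each dense
   bin). Percentages downstream are therefore always relative to the total
   cell population. If no bin is dense the sample degenerates to a single
   cluster, with a warning.
5. **Level profiles.** Per cluster and channel, the raw centroid is mapped
   to an ordinal level: the per-file range [min, max] *over cluster
   centroids* is split into four equal-width intervals and
   `level = 1 + floor(4·(v − min)/(max − min))`, clamped to [1, 4]. Equal-
   width partitioning (rather than quantiles) is the simplest within-file
   normalization and makes level vectors invariant under any positive
   affine rescaling of a channel; it is isolated in `normalize_levels` so a
   quantile strategy could be swapped in.

Defaults `n_bins = 12`, `min_density_fraction = 0.001` were fixed against
the synthetic template. Because the level scale is renormalized per file
from as few as four or five centroids, it is deliberately coarse; queries
are written against that coarseness (e.g. "SSC = 4" for the maximal-SSC
population).

## Population queries and the Granularity Index

Queries are boolean predicates over levels, built from atoms
`channel {=, ≤, ≥} level` with AND/OR and parentheses; comparators act on
the ordinal levels, never on raw centroids. The ten built-in populations
(total/marker-positive lymphocytes, monocytes, total/hyper/hypogranular
granulocytes) follow the standard scatter-gate definitions; note the
hypergranular definition's `FSC ≥ 1` conjunct is vacuous (all levels are
≥ 1) and is kept verbatim for fidelity. Hypergranular (`SSC = 4`) and
hypogranular (intermediate SSC patterns) are provably disjoint over the
4×4 scatter grid, so GI = %hyper − %hypo is well defined.

GI is the **signed** difference, ranging −100 % to +100 %. The defining
prose for this index is sometimes phrased as an "absolute difference", but
the stated range and the negative cutoffs (−9.25 %, −27 %, −43 %) force the
signed reading; no absolute variant is offered. By default the percent
denominator includes debris clusters ("relative to the total cell
population"); `exclude_debris` drops FSC = 1 ∧ SSC = 1 clusters from
numerator and denominator.

Baseline = the screening visit; if both screening and day-0 gatings exist,
screening wins. Subjects without a baseline gating are excluded with a
logged count; duplicate baseline gatings for a subject are an error.

## Statistics

* **Fisher two-tailed** uses the probability-mass convention: sum, over the
  hypergeometric support at fixed margins, of every table probability not
  exceeding the observed one. The implementation works on exact integer
  numerators (`math.comb` products over a common denominator), so
  probability ties resolve exactly and no floating-point tie slack is
  needed. An empty margin yields p = 1 with a warning.
* **Likelihood ratio** LR⁺ = (a/m)/(b/n) with the log-method 95 % CI,
  `exp(ln LR ± 1.96·√((1−a/m)/a + (1−b/n)/b))`, z fixed at 1.96. This
  convention reproduces published LR/CI rows from their counts at 2-decimal
  rounding (validating the choice). Boundary counts (a = 0 or b = 0) return
  an explicit 0/∞ result with NaN bounds rather than raising.
* **Kruskal–Wallis** (two-sample) delegates to `scipy.stats.kruskal`
  (midrank ties, tie-corrected H, χ² with 1 df); all-identical input
  returns (0, 1). Tests verify the χ² p against the exact permutation
  distribution on small inputs and that H is monotone in the squared
  rank-sum deviation.
* **Pearson r²** squares `scipy.stats.pearsonr`; zero-variance input is an
  error, not silently 0.
* **Youden cutpoints** evaluate J = sensitivity + specificity − 1 at the
  midpoints between consecutive distinct values plus ±∞, for a stated flag
  direction (below/above flags positive); ties in J break toward the
  threshold flagging fewer subjects.

### Band cutoffs: a deliberate design choice

Running *both* Youden optimizations on the same arm — "low GI flags
failure" and "high GI flags success" — is the same optimization twice:
J_below-failure(t) ≡ J_above-success(t) at every candidate threshold, so
with a unique maximum both return the same cutoff (the package exposes this
identity through `derive_gi_cutoffs`, and a test asserts it). A single arm
therefore cannot define two band boundaries. `derive_band_cutoffs` instead
takes one failure-identification cutpoint from each arm — RTX failures are
flagged *below* a threshold, CYC failures *above* one — and uses the sorted
pair as the low/high boundaries. The zone between them, where the two arms'
evidence disagrees, is the middle band ("best clinical judgment"). Band
membership is inclusive at both boundaries (low: GI ≤ low cut; high:
GI ≥ high cut). When derived cutoffs are unusable (infinite or coincident,
as can happen on null data), the pipeline falls back to GI tertiles with a
warning.

### Stratification and projection

Each band gets per-arm n, remission counts/rates and a between-arm
two-tailed Fisher p. The profiled-design projection assumes low-band
patients receive CYC at that band's observed CYC rate, high-band patients
RTX at the observed RTX rate, and middle-band patients keep their observed
outcomes; the expected remission total is rounded to the nearest integer
*before* the observed-vs-projected Fisher comparison (reproducing published
integer projections). An empty outer band contributes zero; a populated
band whose favored arm is empty is an error. All internal arithmetic is
full precision; rounding to printed precision happens only at presentation.

## Synthetic-data generator

**Event model.** Each sample is a diagonal-covariance Gaussian mixture on a
0–1023 raw scale over FSC, SSC and five B-cell markers (CD19, CD21, CD23,
CD5, CD1c), with five components: lymphocytes, monocytes, hypergranular and
hypogranular granulocytes, and 5 % low-scatter debris. Component counts are
multinomial; values are clipped to the instrument range; ground-truth
labels ride along for validation only.

Populations are deliberately **compact** (per-channel sd 8–30 units against
population separations of 150–700): with 7-dimensional binning, a diffuse
population dilutes its occupancy until no bin clears the 0.001·n density
threshold (at 50 000 events a 7 %-abundance population with sd ≈ 25–30 on
the narrow marker channels produced no dense bin at all, silently merging
into its neighbor). Compactness is therefore a generator design constraint,
not cosmetics. Consequences worth knowing: real cytometry populations are
heavier-tailed, skewed and spectrally overlapping, so passing tests here
show the pipeline is *correct under its own assumptions*, not that the
gating would resolve real samples equally well; and the marker-positive
lymphocyte subsets coincide with total lymphocytes because lymphocytes are
a single Gaussian component (subset heterogeneity is not modelled).

**Latent GI.** Per patient, GI ~ Normal(`gi_mean` = 20, `gi_sd` = 35),
clipped so each granulocyte subset keeps ≥ 1 % of events. The granulocyte
total G (≈ 0.66 of events, after per-patient jitter of the lymphocyte and
monocyte fractions: N(0.22, 0.04) and N(0.07, 0.015), clipped) splits as
hyper = (G + GI/100)/2, hypo = (G − GI/100)/2, which makes the measured GI
an unbiased estimator of the latent value up to multinomial noise. The
defaults place roughly a fifth to a quarter of patients below −9.25 %, and
just under a third above 47.6 %, matching the band occupancies such a
cohort is expected to show; the ≥ 1 % clipping guarantees every sample
retains a maximal-SSC cluster to anchor level 4.

**Outcomes.** Remission ~ Bernoulli(expit(logit(`baseline_remission`) +
b_arm·(GI − `gi_mean`))) with `baseline_remission` = 0.58 (the observed
overall remission rate in a 187-patient cohort of this design).
`gi_effect_rtx` (+30 by default) and `gi_effect_cyc` (−30) are the target
remitter-vs-non-remitter mean-GI gaps per arm; the slope b_arm is solved
numerically (Gauss–Hermite quadrature + Brent root-finding) so the realized
gap equals the parameter — the first-order slope effect/σ² underdelivers
(a configured 30 realized only ≈ 16). The gap saturates near 1.6·σ, so
effects beyond ≈ 55 at σ = 35 are rejected as unattainable.

**Problem sizes.** Cohort simulations default to 2 000 events per sample:
the GI's multinomial sampling error is then ≈ 1 pp, an order of magnitude
below the between-patient spread, while keeping a 1 000-patient cohort
cheap to gate. Estimator-consistency checks use 50 000 events (sampling
error ≈ 0.2 pp) to isolate gating error. The parameter-recovery harness
runs 20 replicates of 1 000-patient cohorts for the effect and null
conditions; the concordance harness uses 100 samples.

**Determinism.** All randomness flows from one `numpy` Generator seeded by
`CohortConfig.seed`; repeated calls are bit-identical, and the pipeline's
reports are byte-identical across reruns of the same configuration.

## FCS I/O

A minimal FCS 3.0/3.1 list-mode codec: float32/float64 and unsigned-integer
data, little/big endian per `$BYTEORD`, linear gain applied on read.
Unsupported dialects (correlated/histogram mode, log-amplified integer
parameters, mixed widths) are rejected with named errors rather than
guessed. Writing always produces little-endian float32 FCS 3.1; an
event-less table is an error, not an empty file. Round-trips preserve
values to float32 precision.

## Known limitations

* Equal-width level normalization is one reading of "normalized within each
  file"; a quantile reading would shift level boundaries. The choice is
  isolated behind `normalize_levels`.
* No compensation/spillover, doublets, time drift, or longitudinal visits;
  single-baseline-visit cohorts only.
* The outcome model is logistic in GI with arm-specific slope — the minimal
  model producing the opposed-arm pattern; real effect shapes may be
  non-monotone.
* Projection inference treats the projected cohort as an independent
  sample in the Fisher comparison, as is conventional for this style of
  what-if estimate; it is a descriptive contrast, not a causal claim.
* Inference is unadjusted (no covariates, no multiplicity correction),
  matching the analysis design this package implements.
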
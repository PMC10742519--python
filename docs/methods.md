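# Methods

## The model

`genefabric` characterizes a transcriptome profiled in several conditions
(e.g. tumor nodules and the surrounding normal tissue) with `n` biological
replicas per condition and up to three redundant microarray spots per gene.
Three independent descriptors are attached to every gene `i` in every
condition `c`:

- **AVE** — the arithmetic mean over replicas of the normalized expression
  `a_i^(c;k)`. Normalization divides each sample's gene-level net
  fluorescence (foreground − background, summed over the gene's `υ_i`
  spots) by the sample's median gene, so `a > 1` means above-median
  expression and profiles are comparable across samples.
- **REV** — relative expression variability in percent: the midpoint of the
  chi-square confidence interval of the coefficient of variation, pooled
  over the `υ_i·n` spot-level values,

      REV = ½·[√(r/χ²((1−ci)/2; r)) + √(r/χ²((1+ci)/2; r))] · (s/μ) · 100,
      r = υ_i·n − 1,  ci = 0.95.

  The chi-square factor (≈2.15 at r = 3) corrects the small-sample bias of
  the plain CV and tends to 1 as r grows. Low REV marks a gene whose
  abundance the tissue actively protects. The control scale is `100/REV`;
  **REC** references it to the condition median (positive REC =
  tighter-than-median control).
- **COR** — the Pearson correlation of two genes' log2 normalized
  expressions across the replicas of one condition. With `m` paired values
  the two-tailed significance threshold is `r* = t*/√(t*² + m − 2)` with
  `t*` the 0.975 t-quantile on `m − 2` d.f.: 0.95 / 0.71 / 0.58 for m = 4 /
  8 / 12. A pair is synergistic (COR ≥ r*), antagonistic (COR ≤ −r*),
  independent (|COR| ≤ 0.05), or unclassified. Pathway coordination is
  `COORD = %SYN + %ANT − %IND` over all gene pairs of the pathway.

Cancer-vs-reference regulation uses the signed fold `x` of the AVEs
(reciprocal convention, |x| ≥ 1, negative = down) with the per-gene cutoff

    CUT = 1 + √((REV_cancer/100)² + (REV_ref/100)²),

and a two-tailed Welch t-test on the replicate values; a gene is
significantly regulated iff `|x| > CUT` and `p < 0.05`. The weighted
individual regulation is `|WIR| = AVE_ref · (|x| − 1) · (1 − p)` signed by
the direction, and `WPR` is the mean |WIR| over a pathway's quantified
genes. Remodeling combines three orthogonal axes per gene and contrast —
WIR, `Δcontrol = 100/REV_cancer − 100/REV_ref`, and the coordination change
`ΔCOR = Σ_j (|COR_ij^cancer| − |COR_ij^ref|)` — into the transcriptomic
distance `TDI = √(WIR² + Δcontrol² + ΔCOR²)`. The gene commanding height

    GCH_i = (median REV / REV_i) · exp(4 · mean_{j≠i} COR²_ij)

rewards tight control and broad coordination; the top-ranked gene is the
region's gene master regulator (GMR).

## Assumptions

- Replicas are exchangeable instances of the same steady state; the
  replicate scatter estimates biological variability, not regulation.
- Only pairwise coordination is modeled; higher-order gene clusters are
  not resolved at n = 4.
- No multiple-testing correction is applied across genes or pairs; the
  per-gene CUT and the strict small-m correlation thresholds are the
  operative guards.
- The Welch test runs on linear normalized values because the compared
  quantities are the linear-scale AVEs; `log2_test=True` is available.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `ratio` (filter) | 2.0 | spot reliability: fg ≥ ratio·bg in *every* sample |
| `ci` (REV) | 0.95 | chi-square interval level of the CV estimate |
| `alpha` | 0.05 | two-tailed significance for correlations and the Welch test |
| `ind_cut` | 0.05 | \|COR\| below which a pair counts as independent |
| `uniform_cut` | 1.5 | the conventional fold cutoff the false-hit audit compares against |
| `spot_mode` | `replica` | correlate replica-aggregated values (m = n); `spot` pairs k-th spots (m = υn) |
| GCH weight | 4 | fixed exponent weight of the mean squared correlation |

The spot-level correlation mode is only defined for genes with equal spot
counts; the replica-aggregated default avoids pairing ambiguity when spot
counts differ.

## The synthetic generator

The generator emulates a replicated single-color microarray design
(default 4 conditions × 4 replicas, named after the tissue regions of a
kidney-tumor study) and provides the ground truth the recovery tests
check. Per gene: a lognormal baseline spread around `baseline_mean`
(log2-sd 1.5, giving a realistic dynamic range for a median-gene
normalization), a CV drawn from `cv_range` (default 5–50%, typical of
microarray biological replicas; `cv_overrides` pins individual genes), and
lognormal replicate noise with log-sd matched to that CV. Planted folds
multiply the condition mean. Correlation blocks share a per-replica latent
factor on the log scale; a negative block loading alternates the sign of
the per-gene loading so that pairs of opposite sign are antagonistic, and
a block may be restricted to one condition (a condition-specific hub).
Redundant spots are near-replicates: the first spot carries the replicate
value exactly, extra spots add 5% multiplicative noise, so the zero-CV
limit yields exactly equal replicas. Background is `background_level` with
10% Gaussian jitter truncated at zero; non-failing spots are clipped to
fg ≥ 2.0001·bg so the planted failing set is exactly the set the filter
removes.

What it does **not** emulate: dye or spatial array artifacts, probe
cross-hybridization, heavy-tailed outlier spots, and the median-scale
stability of a 13k-gene array — at desk-scale gene counts (tens to
hundreds) the per-sample median carries sampling noise that slightly
attenuates negative correlations and inflates positive ones. Passing
recovery tests therefore demonstrate the estimators' behavior under the
stated noise model, not performance on any particular real platform.

## Numerical choices

- Net fluorescence is floored at `1e-6 ×` the sample median net so log2
  is always defined; the reliability filter makes true non-positives rare.
- The per-sample median over an even gene count is the mean of the two
  central values; normalization is single-pass (no iterative re-medianing).
- Correlation matrices clip to [−1, 1]; zero-variance genes get undefined
  (NaN) correlations, which are never counted as independent and are
  skipped (and counted) in ΔCOR sums.
- Ties exactly at a significance threshold are classified significant.
- Degenerate Welch input (zero variance both sides) returns p = 1 for
  equal means, p = 0 otherwise.
- GMR ties break lexicographically with a warning.
- Output TSVs are sorted and printed at 6 significant digits, so reruns of
  the same configuration are byte-identical.

## Design decisions

- REV pools spot-level values across replicas (r = υn − 1) rather than
  aggregating spots first, so redundant spots genuinely add degrees of
  freedom.
- REC is defined on the `100/REV` control scale (not on REV itself), which
  makes "gained control" positive and Δcontrol a difference of controls.
- The ΔCOR axis of TDI is pathway-restricted when a pathway context is
  given and region-wide otherwise; the GCH correlation average is always
  region-wide, since the hierarchy is a property of the whole
  transcriptome.
- Percentages in pathway summaries use the quantified gene count as the
  denominator; overlapping pathways count a shared symbol once in union
  counts.
- Test problem sizes (40–400 genes, 10–25 seeds per recovery check) were
  chosen so each Monte-Carlo rate is estimated well away from its
  asserted bound while the whole suite stays interactive.

## Known limitations

- At m = 4 paired values the |COR| ≥ 0.95 threshold makes coordination
  calls conservative; planted antagonism is recovered in a majority but
  not a large majority of seeds (see the generator caveat on median-scale
  noise).
- The GCH closed form is one concrete realization of "low REV, strong
  coordination"; its exponent weight (4) sets the balance between the two
  factors and is not fitted.
- The optional GEO series-matrix loader maps processed intensities into
  the probe-table schema with zero background; it cannot reconstruct
  fg/bg-level filtering and is provided for convenience only.
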
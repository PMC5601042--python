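# Methods

## Problem setting

An ordered transcription-factor cascade (default DYT1 → TDF1 → AMS → MS188)
controls tapetum development. Each factor is assayed by a loss-of-function
mutant profiled against wild type with replicated expression arrays, and the
tapetum transcriptome is profiled by RNA-seq of laser-captured tapetal cells
at two anther stage pools. Because the factors are activators arranged in a
linear pathway, a gene regulated at tier *j* of the cascade is expected to
lose expression in the mutant of tier *j* and of every tier upstream of it —
a *nested* down-regulation pattern. The pipeline turns that expectation into
a classifier and surrounds it with the statistics needed to produce its
inputs.

## Differential expression (SAM, two-class unpaired)

For gene *i* with wild-type replicates `x` (n₁ of them) and mutant replicates
`y` (n₂):

    s(i)² = a · ( Σ(x − x̄)² + Σ(y − ȳ)² ),   a = (1/n₁ + 1/n₂)/(n₁ + n₂ − 2)
    d(i)  = (ȳ − x̄) / (s(i) + s0)

Down-regulation in the mutant gives d < 0. The fudge factor `s0` damps the
inflation of |d| at small `s`; in `auto` mode it is chosen from candidates
{0} ∪ {percentiles 0, 5, …, 95 of s} as the candidate minimizing the
coefficient of variation of the windowed MAD of d across 100 s-quantile
windows (MAD scaled by 1/0.6745), ties broken toward the smallest candidate.

**Scale.** The statistic is computed on log2-transformed intensities by
default (`log_transform=True`), the customary scale for array data; without
the transform, genes of low absolute abundance carry proportionally small
mean differences and large effects at low baselines become undetectable.
The fold-change filter is always the *linear* condition-mean ratio, so
"fold change > 2 down" means ȳ/x̄ < 0.5 regardless of the statistic's scale.

**Permutation null.** With n₁ = n₂ = 3 all C(6,3) = 20 balanced label
assignments (including the identity) are enumerated, eliminating sampling
noise; larger designs fall back to seeded sampling (an exact-enumeration cap
of 10,000 assignments). For each assignment the d vector is recomputed and
sorted; d̄(i) is the mean of the i-th order statistic over assignments.
Observed d are ranked with a stable sort (ties broken by input position, and
by sorted sample name in the matrix wrapper, so replicate order within a
condition never changes any result).

**Calling and FDR.** At offset Δ a gene is significant when
|d(i) − d̄(i)| ≥ Δ. Cut points are the least extreme called d in each
direction; every gene beyond a cut is counted as called for FDR purposes.
The FDR at Δ is π̂0 × (median over permutations of the number of permuted d
beyond the cuts) / (number called), clamped to [0, 1], with
π̂0 = min(1, #{observed d inside the permuted (q25, q75)} / (0.5 m)). A
gene's q-value is the smallest FDR over a 51-point Δ grid spanning
[0, max|d − d̄|] at which the gene's own offset reaches Δ; this keeps q
monotone non-increasing in |d − d̄| (cut-based q-values would not be). Genes
called at no grid point get q = 1.

**Final down calls** require all three of: d̄(i) − d(i) ≥ Δ, linear fold
change < 0.5, and q < 0.05. Δ may be fixed per mutant (reproducing reported
cut-offs such as 1.43/2.2/1.55/1.47) or scanned: the smallest grid Δ whose
estimated FDR — and that of every larger Δ — stays below the 0.05 target.
The run-level achieved FDR is reported and flagged if it exceeds the target.
Up-regulated calls are computed symmetrically but feed nothing downstream;
the cascade factors are activators, so lost targets are the analysis object.

## Expression gating

All three gates are strict inequalities, matching their definitions:
*expressed* ⇔ FPKM confidence lower bound > 0; *extremely highly expressed*
⇔ FPKM > 300; comparison gate ⇔ FPKM > 2. The comparison gate defaults to
"either stage pool" (a gene expressed above threshold at stages 6–7 or 8–10
passes); "both" is available since the choice is not dictated by the gate's
definition. Shared-catalog percentages are computed against the *union* of
the two catalogs — the only denominator consistent with both printed
percentages (15977/20548 → 77.8, 187/388 → 48.2) — and rounded half away
from zero to one decimal. Cascade retention percentages are emitted at both
0 and 1 decimals, since both renderings appear in practice (81.5% but 78%,
65%).

## Nested specificity classification

Input: the ordered mutant labels, per-mutant down sets D₁…D_k, and the gate.
The domain is gate ∪ (∪ D_m). A gated gene whose membership pattern is the
prefix D₁…D_j (and nothing downstream) is `tier_j`-specific; membership in
all k sets is `common`; any other gated pattern — including membership in a
downstream set without the upstream ones, and membership in no set — is
`unassigned`; down-regulated genes outside the gate are `not_gated`. The
partition is checked to be disjoint and exhaustive on every run. For
perfectly nested inputs the identity `tier_j count = c_j − c_{j+1}` holds
exactly, where c_j = |gate ∩ D₁ ∩ … ∩ D_j|. Real data are never perfectly
nested; reporting the leak as `unassigned` rather than silently dropping it
keeps the contract honest. The gate is applied *before* specificity.

## Enrichment

One-sided upper-tail hypergeometric test per (class, category):
p = Σ_{i≥k} C(K,i)·C(N−K,n−i)/C(N,n), computed via the survival function of
`scipy.stats.hypergeom`. The default background is the tapetum-expressed
gate (classes are selections from gated genes; testing them against the
whole genome would conflate tapetum expression with cascade regulation); the
background is configurable. Categories are flagged at raw p < 0.05; a
Benjamini–Hochberg q column per class is appended for modern use but does
not drive the flag. Depletion is not tested.

## Heatmap matrices

Per gene and mutant, log2((mutant mean + c)/(WT mean + c)) with pseudocount
c = 1 on linear intensities (c = 0 available when all means are positive).
Rows are ordered by average-linkage hierarchical clustering on Euclidean
distances; the gene list is lexicographically pre-sorted so tie-breaks and
leaf rotations are deterministic, and two identical inputs produce
byte-identical output files. Rendering is left to the caller; the artifact
is the matrix plus the leaf order.

## Synthetic studies

The generator emulates the three data modalities with a planted truth:

- Tiers are drawn per gene from proportions (none, DYT1-, TDF1-,
  AMS-specific, common) = **(0.70, 0.06, 0.055, 0.07, 0.115)** — roughly the
  relative class sizes such a cascade yields, dominated by unregulated genes.
- Wild-type intensity per replicate is 2^(b + ε) with baseline
  b ~ N(**8**, **1.5**) log2 units (a realistic array dynamic range) and
  replicate noise ε ~ N(0, **0.25**) log2 units; log-normal replicate noise
  on linear intensities is the standard model for two-color array data and
  keeps values positive. Three replicates per condition.
- A tier-*j* gene's intensity is multiplied by 2^effect in its affected
  mutants (the nested set), effect ~ N(**−2**, **0.25**) clamped at −1 so
  every planted effect clears the two-fold definition of regulation.
- **frac_not_tapetum = 0.20** of genes are not tapetum-expressed: their FPKM
  is uniform on (0, 2) with confidence lower bound 0 in both stage tables;
  expressed genes get FPKM = 2 + LogNormal(1.5, 2) (> 2 strictly, a few
  percent exceeding the 300 "extremely high" threshold) with bounds
  fpkm ± margin (margin 1.0, so lower bounds stay positive).
- Categories: 12 flat gene sets, one planted per affected tier at inclusion
  odds ratio **10** against a base rate of 0.05, the rest uniform; odds 1
  turns planting off. An optional `frac_non_nested` fraction of unregulated
  genes receives a non-nested effect (down in one downstream mutant only) to
  exercise the classifier's `unassigned` path; default 0.
- One `SeedSequence` per run, spawned into independent child streams per
  output table, so identical configs give byte-identical files.

What the generator does *not* emulate: probe-level array artifacts, dye
bias, normalization residue, correlated genes, read-level RNA-seq sampling,
or non-null genes with effects below two-fold. Passing recovery tests
therefore show the pipeline's logic is correct under its own assumptions,
not that real arrays meet those assumptions.

## Validation protocol and problem sizes

- Exact oracle equivalence of d, s, d̄ and the Δ-called set against a
  brute-force pure-Python enumeration on ≤ 10-gene, 3v3 matrices.
- Null control: 20 independent 500-gene exchangeable studies; the pooled
  down-call fraction must stay within 0.05 plus three binomial standard
  errors (the filters make it far smaller in practice).
- Recovery: 10 independent 2,000-gene studies at the default conditions;
  macro-averaged precision and recall over the four affected classes must
  each reach 0.90. Planted-category enrichment is checked over 200
  light-weight 500-gene truth draws (no expression matrices needed): the
  planted category must attain the smallest p within its target class in
  ≥ 95% of draws.
- Monotonicity: mean recovery F1 over seeds is non-increasing in replicate
  noise (checked at sd 0.1 / 0.8 / 2.5).

These sizes keep the full suite to a few minutes while leaving the binomial
and Monte-Carlo error bars comfortably inside the asserted margins.

## Numerical and design notes

- Gene ids are uppercased at ingest; tables are UTF-8 TSV with headers;
  missing values are rejected, never imputed.
- Percent rounding is half away from zero (`decimal`-based, not banker's).
- Order-statistic ties break by input position (matrix wrapper: by gene id),
  making every output deterministic under a fixed seed.
- `fdr_at_delta` isolates π̂0 and the median false-call count behind one
  interface so alternative estimators can be swapped.
- The per-mutant down-regulated totals and expressed-gene catalog sizes of
  the original study depend on its deposited raw data and are not
  reproduced here; the worked example and property suites above are the
  package's correctness contract.

## Known limitations

- SAM variants (paired, multiclass, survival) are out of scope, as is
  probe-level normalization; inputs are normalized intensities.
- The cascade order is configuration, never inferred.
- Annotation sets are flat (MapMan-bin style); no GO DAG propagation.
- With only 20 balanced permutations at 3v3, FDR estimates are coarse
  (granularity ~1/20 per direction); fixed Δ values from larger designs are
  accepted but their implied FDR is recomputed on the data at hand.
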
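# Methods

## The analysis model

`exprtrend` studies calendar-time drift of gene expression in a cancer
cohort. The unit of analysis is the *diagnosis-year bin*: patients are
grouped into B consecutive year intervals (default B = 8), and every
statistic is a function of the per-bin mean expression trajectory
μ_{g,0..B−1} of each gene g.

**Binning.** Whole calendar years are never split across bins. In
`quantile` mode the B−1 internal year boundaries are chosen to minimise the
max/min bin-occupancy ratio; when the number of boundary placements
C(D−1, B−1) over D distinct years is enumerable (≤ 5·10⁵, which covers any
realistic diagnosis-year span) the optimum is found by exhaustive
vectorised search, ties resolved to the earliest boundaries; otherwise a
greedy quantile fallback is used. `explicit` mode accepts user-supplied
edges verbatim, for replicating a published grouping. Intervals are
left-closed, the last also right-closed; a single-year last bin is encoded
by equal final edges.

**Trend call.** Over the B−1 consecutive comparisons, strict increases,
strict decreases and ties are counted separately; ties count as neither
(with continuous data they are measure-zero, but synthetic or integer data
need the rule). A gene is up-regulated when n_increase ≥ k_min (default
B−2, i.e. 6 of 7 at B = 8), down-regulated symmetrically; k_min > (B−1)/2
guarantees the two calls are mutually exclusive. The effect size is
log2FC = log₂(μ_{B−1}+ε) − log₂(μ_0+ε) with pseudocount ε defaulting to
half the smallest positive matrix value, so zero bin means stay finite.
Ranked reports order up-genes by log2FC descending and down-genes
ascending, ties broken by gene id.

A subtlety worth stating: because consecutive steps share a bin mean, the
B−1 comparisons are *dependent*. Under the exchangeable null (no drift)
the probability of an up call is the Eulerian ascent probability
P(≥ k_min ascents among orderings of B iid values); at B = 8, k_min = 6
this is 248/40320 ≈ 0.62% per direction — much smaller than the 2⁻⁷-based
value one would get by (incorrectly) treating the steps as independent
coin flips. The test suite asserts the correctly enumerated rate.

**Annotation overlap.** Each called gene is assigned to exactly one region
of the oncogene × TSG × lincRNA Venn diagram (multi-membership regions are
reported as such, never double-counted); the lincRNA share of each called
list is reported with the called-set size as denominator.

**Over-representation.** For query size n from universe N, pathway size K
(in-universe) and overlap k, the one-sided Fisher p is the hypergeometric
upper tail at k; the EASE score (default, mirroring DAVID) decrements k by
one first and is therefore never smaller than the Fisher p. The default
universe is the set of matrix genes annotated in ≥ 1 gene set (DAVID-like
background). Raw p < α (default 0.05) defines significance; Benjamini-
Hochberg q-values are computed only behind a flag, since the replicated
workflow used uncorrected p-values. Up- and down-lists are tested
separately. Tails are evaluated with `scipy.stats.hypergeom`, which agrees
with exact big-integer arithmetic to ~10⁻¹⁵ relative error on the tested
ranges.

**Survival.** Kaplan-Meier estimation and single log-rank tests go through
`lifelines`. Cutpoint selection evaluates every midpoint between
consecutive distinct expression values that leaves ≥ minprop (default 0.1)
of the cohort on each side, computing the log-rank χ² = U²/V for all
candidates at once with a vectorised counting-process implementation
(U = Σ_j d₁ⱼ − dⱼ n₁ⱼ/nⱼ and the hypergeometric variance over distinct
event times); the maximising candidate wins, ties going to the lower
cutpoint, "high" meaning strictly greater than the cutpoint. The reported
`p_naive` is the 1-df χ² tail at the selected cutpoint — deliberately the
same anti-conservative quantity the survminer-style "auto best cutoff"
workflow reports. The inflation is real and measured (null rejection rate
≈ 0.4 at n = 250 with minprop 0.1, versus the nominal 0.05 that the
fixed-median split attains); a permutation-based selection-adjusted
p-value is available (`adjust="permutation"`) but off by default for
fidelity to the replicated procedure.

**Hub filter.** A called gene passes when (1) it is not in the lincRNA
catalog; (2) p_naive < 0.05 (strict); (3) |log2FC| > 1 (strict); (4) its
trajectory has at most one counter-directional strict step and every such
step's log2 magnitude is < ⅓·|log2FC|. "Total change" in rule 4 is the
last-vs-first log2FC, the only total the workflow defines; the rule is
applied direction-symmetrically (for a down-gene the counter-step is a
rise). Tightening any threshold can only shrink the hub set (tested).

**Per-subtype reruns.** Trend calling and enrichment are repeated inside
each PAM50 subtype using the *whole-cohort* bin edges rather than
re-balancing per subtype, so per-subtype counts are comparable to the
cohort-level ones; subtypes with fewer than `min_subtype_n` (default 20)
patients, or that leave a year bin empty, are skipped with a logged
warning. An override to re-bin per subtype is available through the
binning configuration.

## The synthetic cohort generator

The generator emulates the statistical shape of the target cohort, not its
biology: log2 expression of gene g in patient i of bin b is
N(μ_g + s_g·δ·b, σ²) with s_g ∈ {+1,−1,0} (planted up / down / null),
μ_g ~ U(3, 8), and expression 2^(that draw) — log-normal with multiplicative
noise, so δ is exactly the expected per-bin log2-mean shift. Diagnosis
years are uniform over the window (default 1988–2011, redrawn if fewer
than B distinct years appear); subtype labels are multinomial (default
probabilities 0.45/0.24/0.20/0.11 for LumA/LumB/Basal/Her2, the observed
mix among subtyped TCGA-BRCA patients).

Survival: a fraction `frac_prognostic` (default 0.05) of planted genes
carries a hazard effect with sign matching its trend direction; patient
hazard is baseline_hazard · exp(Σ_g s_g·β·1[x_{gi} > median_g]), i.e.
effects multiply, and each prognostic gene keeps a marginal hazard ratio
e^β. Defaults β = 1, baseline_hazard = 0.15/year. The small default
prognostic fraction keeps the aggregate log-hazard spread near 1,
comparable to real prognostic indices; power and size properties are
measured on dedicated single-prognostic-gene configs that isolate β.
Censoring is an independent U(0, censor_horizon) draw (default horizon
20 years; observed time min(T, U)), giving ≈ 32% censoring for
baseline-hazard patients — typical of overall-survival data.

Pathways: `n_enriched_pathways` (default 5 of 20) sets draw a fraction
`planted_enrichment_frac` (default 0.5) of their members from the planted
genes, the rest from null genes; background sets are uniform draws.
Annotation catalogs are uniform samples (5% oncogenes, 5% TSGs, 10%
lincRNAs), deliberately overlapping the planted genes at chance rates.

What the generator does **not** emulate: read counts or library-size
normalisation, batch effects, gene-gene correlation, subtype-specific
expression signatures (labels are sampled independently of expression),
or identifier-namespace mismatches. Passing tests therefore demonstrate
correctness of the statistical machinery on cleanly specified inputs, not
robustness to the normalisation and annotation noise of real RNA-seq
cohorts.

## Numerical and design choices

- All randomness flows from a single integer seed through one
  `numpy.random.Generator`; identical configs give byte-identical outputs.
- Trend ties and zero means: strict inequalities throughout; ε handles
  log2 of zero; a NaN bin mean is a data error, not silently skipped.
- Log-rank degenerate cases: no events (zero variance) → χ² = 0, p = 1;
  at-risk blocks of size 1 contribute zero variance terms.
- Candidate-scan tie-break: first (lowest) cutpoint at equal χ², for
  determinism.
- Patients with missing diagnosis year or survival data are dropped with
  logged counts, never imputed.
- Problem sizes in the shipped tests and acceptance script (≤ 2000 genes,
  ≤ 1000 patients, 200–400 Monte-Carlo replicates) were chosen so each
  statistical check has comfortable margin (≥ 3 SE) while the whole suite
  runs in about a minute.

## Known limitations

- The naive best-cutpoint p-value is anti-conservative by construction;
  downstream hub counts inherit that optimism. This replicates the target
  workflow faithfully; for inference, use the permutation adjustment.
- The quantile binning optimises the max/min occupancy ratio; other
  balance criteria (e.g. minimising the largest bin) can give different
  edges when year counts are very skewed.
- Gene identifiers are taken at face value; expression, catalogs and GMT
  files must share one namespace.
- The enrichment universe is configurable but defaults to annotated
  matrix genes; published pathway-level counts from web services depend on
  their private backgrounds and annotation snapshots and are not
  reproducible quantities.
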
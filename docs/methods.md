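# Methods

## Statistical model

### Differential expression

Expression values are assumed to be normalized log2 intensities; the
analysis is location-invariant, so absolute scale does not matter. For probe
g with group means x̄₁ (case, n₁ samples) and x̄₂ (control, n₂), the effect
is the difference of log2 means, log2FC_g = x̄₁ − x̄₂, reported alongside the
signed linear fold change sign(log2FC)·2^|log2FC| (so the |FC| ≥ 1.5 gate is
|log2FC| ≥ log2 1.5 ≈ 0.585). Ratio-of-linear-means is a possible alternative
reading of "fold change" for array data; difference of log2 means is the
standard one for log-scale matrices and is what this package computes.

The per-probe pooled variance s²_g (residual df d = n₁ + n₂ − 2; the
equal-variance model is required for moderation, Welch's test is provided
separately) is shrunk by empirical Bayes. The prior is a scaled inverse
chi-square with df d0 and scale s0²; marginally, s²_g follows s0²·F(d, d0).
Writing z_g = log s²_g and e_g = z_g − ψ(d/2) + log(d/2):

- E[e] estimates log s0² + ψ(d0/2) − log(d0/2);
- Var(e) estimates ψ′(d/2) + ψ′(d0/2),

so d0 solves ψ′(d0/2) = Var(e) − ψ′(d/2), inverted by Newton iteration on
the trigamma function (relative tolerance 1e-10; closed-form asymptotes
1/√y for y > 1e7 and 1/y for y < 1e-6 seed the iteration region). When the
moment equation leaves no positive excess variance the probes are
homogeneous: d0 = ∞ and s0² = exp(mean(e)), the bias-adjusted geometric mean
variance (note this applies the ψ/log chi-square correction, so for
literally constant s² it returns const·exp(log(d/2) − ψ(d/2)), slightly
above the constant — the estimator is defined for sampled variances). At
least 30 positive variances are required for a fit.

The moderated statistic uses s²_post = (d0 s0² + d s²_g)/(d0 + d) on
d + d0 df. d0 = 0 is accepted and reproduces the ordinary pooled t exactly;
d0 = ∞ uses s0² as the denominator with the reference df capped at
d + 10⁶ (numerically the normal limit, no special-cased distribution).
Two-sided P throughout. BH FDR is computed over all probes jointly and
reported; the screening flag `is_de` uses raw P (the legacy convention this
chain reproduces), with both thresholds configurable.

The standalone alternatives: Welch's t (scipy), paired t (scipy, with an
explicit zero-variance-of-differences error), and a Mann–Whitney U whose
two-sided P is computed by exact enumeration of all C(n₁+n₂, n₁) label
arrangements when the combined sample size is ≤ 12 (ties handled by the
enumeration; the "at least as extreme" criterion is |U − n₁n₂/2| with a
1e-9 slack for rank-sum float error), else by the normal approximation with
tie correction and a 0.5 continuity correction.

### Coexpression network

Every DE lncRNA × DE mRNA pair is scored with the Pearson correlation over
all samples pooled (cases + controls). Pooling is the common practice for
coding–noncoding coexpression screens and maximizes n; it does mean that a
strong shared group effect alone can push a DE–DE pair past the threshold,
which is a property of the method, not an artifact — a within-group option
(`samples="case"/"control"`) is exposed for sensitivity analyses. Edge
P-values come from the exact null relation t = r√(n−2)/√(1−r²) on n−2 df
(|r| = 1 ↦ P = 0; n ≥ 4 required). Edges require |PCC| > 0.7 AND P < 0.05,
both strict, following the usual "> threshold" phrasing of such screens
(the DE fold-change gate is non-strict ≥, likewise following its own
convention). Probes with zero variance have undefined correlations and are
skipped with a warning. Edge P-values are not multiplicity-adjusted for the
screening decision (none of the classic chain is); BH over all candidate
pairs is reported in an `fdr` column.

Node degree is the raw edge count (a "degree > 60" hub rule is only
meaningful for raw counts); hubs are strictly above the cutoff. Nodes
without a passing edge are not part of the network — so the network's node
counts are generally smaller than the DE totals. Top-k edge ranking sorts by
ascending P with ties broken by |PCC| descending and then (lnc_id, mrna_id)
lexicographically, making output deterministic.

### Cis-target prediction

The distance between two loci is the minimum gap between their spans on the
same chromosome (0 when overlapping or abutting; incomparable across
chromosomes). Span-gap is symmetric and strand-agnostic, which matches a
window defined "upstream and downstream" without a TSS anchor; coordinates
are BED-convention 0-based half-open and distances are in bp. The window
test is inclusive (gap ≤ 300,000 by default). Strand is recorded
(`same_strand`) but not used by the window test. Queries run against a
per-chromosome list sorted by start; a candidate slice is cut with binary
search using the chromosome's maximum interval length as the left margin,
then exact gaps are computed — output is identical (and tested identical) to
the quadratic all-pairs scan, which ships as
`find_cis_pairs_bruteforce`. The final candidate table is the inner join of
cis pairs with network edges, carrying both distance and edge statistics.

### Over-representation

Hypergeometric upper tail P[X ≥ k] for overlap k between the query and a
gene set, both restricted to the universe (default: all mRNA probes/symbols
on the array, the standard array-ORA background; overridable). k = 0 gives
P = 1 (the full mass). Up- and downregulated DE mRNAs present in the network
are tested separately, mirroring how such studies report pathway direction.
Significance is flagged at raw P < 0.05; BH FDR is always reported. Gene
identity uses the annotation's symbol column when supplied, else probe ids,
case-sensitively.

### qPCR quantification

Per sample, ΔCt = Ct(target) − Ct(reference); ΔΔCt = ΔCt − mean control-group
ΔCt (arithmetic mean of ΔCt, i.e. geometric-mean baseline on the fold
scale, so the control group's geometric mean fold is exactly 1); fold =
2^−ΔΔCt. Adding any per-sample constant to all of that sample's Ct values
cancels in ΔCt. Group tests run on ΔCt (log scale, closer to normal —
standard qPCR practice) with Welch's t by default or Mann–Whitney;
direction is the sign of the case-vs-control abundance difference
(lower ΔCt = higher abundance). Concordance is the fraction of genes whose
qPCR direction matches the array DE direction. Technical-replicate
averaging, efficiency correction and multi-reference normalization are out
of scope (single-reference 2^−ΔΔCt only).

## Synthetic data generator

The generator emulates the two-group array design the pipeline targets:
13 case vs 9 control samples; by default 2,262 lncRNA and 3,186 mRNA probes
(a 10% scale model of a ~22.6k/31.9k-probe array, keeping desk runs fast;
full scale is a config change) with 40/44 planted DE probes (scaled
similarly from ~400/440 DE calls). Null probes are i.i.d. Normal(8.0,
noise_sd²) log2 units in both groups — the baseline is arbitrary because the
analysis is location-invariant; noise_sd defaults to 0.5 log2 units, a
mid-range between-subject SD for blood arrays (real arrays have
heteroscedastic, intensity-dependent variance; see limitations). Planted DE
probes get ±planted_log2fc (default 1.5) added to the case group. Linked
pairs are drawn from a bivariate normal with correlation planted_rho
(default 0.85) across all samples BEFORE group effects are added, so the
planted correlation is a within-population correlation and not an artifact
of the group shift; when both biotypes have enough planted DE probes the
pairs are taken from them (with matching signs, preserving the pooled
correlation) so they survive the DE screen, otherwise from null probes.

Annotation places every probe on a synthetic genome (default 3 × 600 Mb).
Designated cis pairs sit on one chromosome at a uniform gap in
[0, window_bp]; non-cis linked pairs go to different chromosomes; every
other inter-gene gap is strictly greater than the window (gene lengths
0.5–5 kb, spacing window + 1–10 kb). Consequently the only within-window
lncRNA–mRNA pairs in the whole annotation are the planted ones, and the
truth table's cis labels agree exactly with a brute-force scan. The default
genome is sized so the default probe count fits; a genome too small raises a
capacity error.

The qPCR generator emulates an independent validation cohort (9 case vs 12
control by default — validation cohorts are typically resampled, not the
array subjects). Target Ct = 25 − direction·planted_log2fc in cases, plus a
per-sample loading shift and optional measurement noise (cycles); the
reference gene sits at Ct 18 with the same loading shift, so ΔCt cancels the
shift and the noise-free round trip recovers planted folds exactly. A
gene-set generator emits two sets enriched in planted up-/downregulated
mRNAs plus random background sets, giving the ORA stage true and null
targets.

All randomness flows from the single config seed. Each generator consumes
its own child stream (`default_rng([seed, k])`, k = 0 expression,
1 annotation, 2 qPCR, 3 gene sets) in a fixed documented order, so each
output is bit-identical for a given seed regardless of which generators are
called or in what order.

What passing recovery tests do and do not show: the generator's Gaussian,
homoscedastic, complete-data world matches the pipeline's assumptions by
construction. Recovery there validates the inference chain's logic and
calibration, not its robustness to normalization artifacts, batch effects,
intensity-dependent variance, probe cross-hybridization or missing values —
none of which are simulated.

## Test and acceptance problem sizes

Stochastic checks use sizes chosen to make the assertions sharp but quick:
null calibration and DE recovery on 10,000-probe matrices; prior-df
recovery with 20 replicate fits of 5,000 probes each; permutation oracle
with 10⁵ permutations at n = 22; network recovery with 200 planted pairs
against ~40,000 null pairs; interval-index equality on 1,000 random loci
plus deterministic boundary/overlap cases; Monte-Carlo hypergeometric
checks at 10⁶ draws; the end-to-end run on a 1,400-probe bundle with 5
planted cis pairs. All are seeded and finish in seconds.

## Known limitations

- Two-group designs only; no covariates, batch terms or multi-group
  contrasts.
- Complete matrices assumed; missing values are rejected (optional
  probe-drop flag), never imputed.
- The ORA stand-in scores user-supplied GMT collections with a
  hypergeometric test; it does not reproduce proprietary knowledge-base
  scores (pathway z-scores, upstream regulators), and category tallies
  require a user-supplied set-to-category map.
- Correlation edges are marginal Pearson associations; no partial
  correlation, mutual information or soft-threshold (WGCNA-style) networks.
- Cis prediction is purely positional + correlational; no sequence-based
  interaction scoring or regulatory-element annotation.
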
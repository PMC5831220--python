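# Methods

## The group-silhouette score

The score treats the user's grouping, not a clustering, as the partition.
For sample *i*: *u_i* is the mean distance to the other members of its own
group, *v_i* the minimum over other groups of the mean distance to that
group (with two groups this is simply the mean distance to the other group),
and *s_i* = (*v_i* − *u_i*) / max(*u_i*, *v_i*) ∈ [−1, 1]. AS is the plain
arithmetic mean of the *s_i* over all samples.

Conventions for degenerate cases:

- a sample alone in its group scores *s_i* = 0 (Rousseeuw's convention;
  keeps AS defined in leave-one-out style designs);
- if max(*u_i*, *v_i*) = 0 — every relevant distance is zero — *s_i* = 0;
  such a sample is indifferent between groups;
- at least two groups with members are required; an empty group after
  restriction to the matrix's samples is an error.

With more than two groups, *v_i* uses the **nearest** other group, the
standard silhouette definition; the two-group case reduces to the simpler
"distance to the other group" reading.

## Distance

d(i, j) = 1 − Spearman's ρ between sample columns i and j, midranks for
ties, giving d ∈ [0, 2] (0 = identical ranking, 2 = exactly reversed).
Rank correlation makes the distance invariant to any monotone per-sample
transform, so counts and log-signals can be treated uniformly. A sample
column that is constant across all genes has no defined ranking and is
reported as an error naming the sample. The matrix is symmetrized and
clipped to [0, 2] to absorb floating-point noise only.

## Filtering

Two filters precede distance computation: genes zero in **all** samples are
dropped (they are unobserved, and their all-tied ranks would dilute every
correlation), and genes with **identical** expression vectors are collapsed
to their first occurrence — near-identical low-count patterns otherwise
dominate the tied-rank mass. Row identity is exact equality of stored
values, no tolerance: counts and quantified signals are exact in storage,
and any representative of a duplicate class yields the same distances. The
DE test uses the zero-filtered matrix (every observed gene is tested); the
distance/silhouette/clustering path uses the zero-then-unique-filtered
matrix. Both filters are recomputed per subsample inside the sweep, since a
gene can lose its last non-zero cell in a subsample.

Raw (unlogged) microarray signals can be prepared with `log2_floor`:
signals below 1 are set to 1, then log2-transformed. The transform refuses
count matrices — it is a microarray convention.

## Clustering

Average-linkage (UPGMA) agglomeration on the distance matrix, recomputing
the unweighted mean of all cross-pair distances at every step (O(n³), and n
is a sample count, so trivial). Ties in the minimal candidate distance are
broken toward the lexicographically smallest (node_a, node_b) id pair,
with leaves numbered 0..n−1 in input order and internal nodes in creation
order — merges are therefore identical across platforms. In Newick output,
node heights are halved so the leaf-to-leaf path length equals the
cophenetic (merge-height) distance; a 2-leaf tree merged at height 0.4
serializes as `(A:0.2,B:0.2);`.

## Count simulator

Counts are independent negative binomials with the variance model
V = μ + φμ². Sampling uses size r = 1/φ and success probability
r/(r + mean); φ = 0 degenerates continuously to Poisson. A configuration
fixes n_genes, the planted DEG fraction p_deg (round(n_genes · p_deg)
genes are DEGs), the fold change (default 4, applied multiplicatively to
the up-regulated group's mean), the fraction of DEGs up-regulated in group
A (default 0.5), and the two group sizes. DEGs occupy the first rows of
the matrix; the truth table records is_deg and up_group per gene.

Per-gene (μ, φ) pairs come from either:

- the **synthetic default**: log10 μ ~ Normal(1.0, 0.7) truncated to
  μ ∈ [0.5, 10⁵] (median ≈ 10, a long right tail into the tens of
  thousands), φ ~ Gamma(shape 2, mean 0.15) truncated to [0.001, 2.0]
  (median ≈ 0.13). This emulates the wide mean range and moderate
  overdispersion of a bulk RNA-seq experiment; or
- a user-supplied two-column (μ, φ) table, resampled with replacement —
  the hook for plugging in an empirical joint distribution estimated from
  a real dataset.

What the generator does **not** emulate: library-size variation (depths
are equal unless an explicit per-sample depth-multiplier vector is given —
the DE engine still estimates factors from the data), correlated genes,
outlier samples, batch effects, and any mean–dispersion dependence (μ and
φ are drawn independently). Passing tests on this generator therefore
demonstrate the internal consistency of the score/test/sweep machinery and
its calibration under a clean NB world, not robustness to those real-data
pathologies. In particular the absolute AS value at a given p_deg depends
on the (μ, φ) source; the claims checked here (trends across N_rep, null
behaviour, P_DEG–AS correlation, AUC near 1 at high replication) are the
ones robust to that choice.

## DE engine

A self-contained exact negative-binomial test, in the spirit of the
classic exact test for two-group count data, rather than a re-implementation
of any specific pipeline:

1. **Normalization.** `norm_factors` returns per-sample *relative effective
   depths*, geometric mean 1. `libsize`: proportional to column sums.
   `tmm`: column sums × trimmed-mean-of-M-values adjustments (30% M-trim,
   5% A-trim, both sides; reference = the column whose 75th percentile of
   depth-scaled counts is closest to the median across columns).
   `degespipe`: three iterations of {tmm → test → drop genes with q ≤ FDR →
   recompute tmm on the remainder}, so putative DEGs stop distorting the
   factors. Counts are divided by the factor, putting every sample on the
   common (geometric-mean) depth.

2. **Dispersion.** Per gene, a method-of-moments estimate on the normalized
   counts, (s² − m̄)/m̄² pooled across the two groups with (n_g − 1)
   weights, floored at 0, then shrunk 50/50 toward the 10%-trimmed mean
   across genes. The equal-weight shrinkage is deliberately simple; it is
   the knob that trades small-N_rep stability against per-gene
   adaptivity, and 50/50 keeps the null type-I error near nominal down to
   3–5 replicates per group (checked by simulation in the test suite).

3. **Exact split test.** The normalized group totals y_A, y_B are rounded
   to integers. A sum of n i.i.d. NB(μ, φ) is NB(nμ, φ/n), and with a
   common per-sample null mean the NB probability parameter cancels from
   the conditional law of y_A given t = y_A + y_B:

       P(K = k | t) ∝ Γ(k + n_A/φ)/Γ(k+1) · Γ(t − k + n_B/φ)/Γ(t−k+1),

   a two-parameter weight depending only on group sizes and φ (φ → 0
   gives the binomial split of a Poisson total). The two-sided p-value
   sums the probabilities of all splits no more probable than the observed
   one (log-scale comparison with a 1e−9 relative tolerance so exact ties
   — e.g. the perfectly balanced case, p = 1 — are included). For totals
   ≤ 4000 the split distribution is enumerated in full; above that the
   enumeration is restricted to a window of ±16 conditional standard
   deviations around the mode and the observation (the distribution is
   log-concave, so the excluded tail mass is < 1e−50 and the window is
   exact at any p-value a BH threshold ever looks at). Genes with zero
   total in both groups carry no information and are excluded (NaN).

4. **Summaries.** BH q-values (step-down minimum, capped at 1);
   P_DEG = 100 × #{q ≤ FDR}/#tested (default FDR 0.10; 0.01–0.40
   supported); P_trueDEG = P_DEG × (1 − FDR); AUC = Mann–Whitney
   probability that a random true DEG has a smaller p-value than a random
   non-DEG, ties counted 1/2, undefined (omitted) when the truth is
   one-class.

## Sweep harness

`run_sweep` subsamples n_rep replicates per group uniformly **without
replacement** (within an iteration; iterations are independent), then
refilters, rescores and retests each subsample. Child seeds derive from
numpy's `SeedSequence(master, spawn_key=(n_rep, iteration))`, so any single
record can be reproduced in isolation and the whole sweep is bit-stable
under a fixed master seed. `pdeg_as_scatter` instead simulates a fresh
dataset per (config, iteration) at the requested group size, tabulating
(P_simDEG, P_DEG, AS) for correlation analyses at fixed N_rep.
`slope_as_vs_nrep` is the least-squares slope of the per-level mean AS
against n_rep — the flatness statistic.

## Problem sizes and determinism

The shipped experiments use 10,000 genes × (40+40) samples for the baseline
run, and 1,000–2,000 genes with up to 30 replicates per group for sweeps
and scatter grids — sizes at which every behaviour of interest (trend
directions, calibration, correlation strength) is already stable while a
full sweep stays in the minutes range on one CPU. Every stochastic path
takes an explicit integer seed; identical seeds give bit-identical
matrices, records and CLI output files.

## Known limitations

- Two-group designs only; no multi-factor/GLM testing and no
  continuous-response (limma-style) path — continuous matrices are accepted
  by the distance/silhouette/clustering side only.
- The exact test assumes the NB variance model; severe model misfit (e.g.
  zero inflation) is not detected.
- The rounding of normalized group totals to integers discards sub-count
  information when factors differ greatly from 1.
- TMM here is the unweighted doubly-trimmed mean of M-values; no
  precision-weighting of M-values is applied.
- AS is a global mean; a single aberrant sample can be visible in the
  per-sample s_i but muted in AS — inspect both, plus the intra/inter group
  distance summary.
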
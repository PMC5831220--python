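"""Two-group differential expression for count matrices.

The engine is a self-contained exact negative-binomial test. Counts are
scaled to a common effective library size; the scaled group totals
(y_A, y_B) are then compared under the null that both groups share one
per-sample mean. Because a sum of n i.i.d. NB(mu, phi) variables is
NB(n*mu, phi/n), the conditional distribution of the group-A total given
the grand total t depends only on the group sizes and the dispersion:

    P(K = k | t) ∝ C(k + r_A - 1, k) * C(t - k + r_B - 1, t - k),
    r_A = n_A / phi,  r_B = n_B / phi,

(the NB probability parameter cancels; phi -> 0 gives the binomial split
of a Poisson total). The two-sided p-value sums the probabilities of all
splits no more probable than the observed one.

Per-gene dispersions are method-of-moments estimates on the normalized
counts, floored at 0 and shrunk 50/50 toward the 10%-trimmed mean across
genes, which stabilizes behaviour at small replicate numbers.

P_DEG is the percentage of tested genes with Benjamini-Hochberg q-value
at or below the FDR threshold; P_trueDEG = P_DEG * (1 - threshold) is the
statistically expected truly-DE share of those declarations. AUC is the
Mann-Whitney probability that a random true DEG out-ranks (smaller p) a
random non-DEG, with ties counted 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import rankdata, trim_mean

from .iolib import ExpressionMatrix, GroupLabels, ModeError, MODE_COUNTS

NORM_METHODS = ("libsize", "tmm", "degespipe")

_FULL_ENUM_MAX = 4000  # full split enumeration below this total
_WINDOW_SDS = 16.0  # half-window in conditional SDs above it
_POISSON_PHI = 1e-10


@dataclass
class DEResult:
    """Per-gene p/q/rank table plus the scalar summaries derived from it."""

    table: pd.DataFrame  # index gene_id; columns p_value, q_value, rank
    norm_factors: pd.Series
    fdr_threshold: float
    p_deg: float
    p_true_deg: float
    auc: float | None = None

    @property
    def n_tested(self) -> int:
        return int(self.table["p_value"].notna().sum())


def _two_group_index(m: ExpressionMatrix, labels: GroupLabels):
    lab = labels.restrict(m.sample_ids)
    groups = lab.groups
    if len(groups) != 2:
        raise ValueError(f"exactly 2 groups required, got {groups}")
    ga = np.array([j for j, s in enumerate(m.sample_ids) if lab.assignment[s] == groups[0]])
    gb = np.array([j for j, s in enumerate(m.sample_ids) if lab.assignment[s] == groups[1]])
    return groups, ga, gb


def norm_factors(
    m: ExpressionMatrix, labels: GroupLabels, method: str = "tmm", fdr: float = 0.1
) -> pd.Series:
    """Per-sample relative effective depths, geometric mean 1.

    ``libsize`` uses the column sums alone; ``tmm`` multiplies them by
    trimmed-mean-of-M-values adjustment factors (30% M-trim, 5% A-trim,
    reference = the column whose 75th count percentile is closest to the
    median across columns); ``degespipe`` iterates {tmm, exact test, drop
    genes with q <= fdr, recompute tmm on the remainder} three times so
    putative DEGs stop distorting the factors.
    """
    if m.mode != MODE_COUNTS:
        raise ModeError("normalization factors are defined for count matrices")
    if method not in NORM_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {NORM_METHODS}")
    colsum = m.values.sum(axis=0)
    if np.any(colsum == 0):
        bad = [s for s, c in zip(m.sample_ids, colsum) if c == 0]
        raise ValueError(f"zero column sum for sample(s) {bad}")
    if method == "libsize":
        f = colsum
    elif method == "tmm":
        f = colsum * _tmm_adjustment(m.values, colsum)
    else:  # degespipe
        f = colsum * _tmm_adjustment(m.values, colsum)
        f = _rescale_geomean(f)
        for _ in range(3):
            p = exact_nb_test(m, labels, pd.Series(f, index=m.sample_ids))
            q = bh_adjust(np.nan_to_num(p, nan=1.0))
            keep = q > fdr
            if keep.sum() < 2:
                break
            sub = m.values[keep, :]
            subsum = sub.sum(axis=0)
            if np.any(subsum == 0):
                break
            f = subsum * _tmm_adjustment(sub, subsum)
    return pd.Series(_rescale_geomean(np.asarray(f, float)), index=m.sample_ids)


def _rescale_geomean(f: np.ndarray) -> np.ndarray:
    return f / np.exp(np.mean(np.log(f)))


def _tmm_adjustment(values: np.ndarray, colsum: np.ndarray) -> np.ndarray:
    """Doubly trimmed mean of M-values per column against a reference."""
    q75 = np.percentile(values / colsum[None, :], 75, axis=0)
    ref = int(np.argmin(np.abs(q75 - np.median(q75))))
    out = np.ones(values.shape[1])
    ref_col = values[:, ref] / colsum[ref]
    for j in range(values.shape[1]):
        if j == ref:
            continue
        col = values[:, j] / colsum[j]
        ok = (col > 0) & (ref_col > 0)
        if ok.sum() < 10:
            continue
        M = np.log2(col[ok] / ref_col[ok])
        A = 0.5 * np.log2(col[ok] * ref_col[ok])
        m_lo, m_hi = np.percentile(M, [30, 70])
        a_lo, a_hi = np.percentile(A, [5, 95])
        keep = (M >= m_lo) & (M <= m_hi) & (A >= a_lo) & (A <= a_hi)
        if keep.any():
            out[j] = 2.0 ** float(M[keep].mean())
    return out


def _split_pvalue(y_a: int, t: int, n_a: int, n_b: int, phi: float) -> float:
    """Exact two-sided p for the observed split of t into (y_a, t - y_a)."""
    if t == 0:
        return 1.0
    if phi < _POISSON_PHI:
        # Poisson limit: binomial split with success prob n_a / (n_a + n_b).
        a = n_a / (n_a + n_b)
        logw_fn = lambda k: (
            gammaln(t + 1) - gammaln(k + 1) - gammaln(t - k + 1)
            + k * np.log(a) + (t - k) * np.log1p(-a)
        )
        m_a = t * a
        var = t * a * (1 - a)
    else:
        r_a, r_b = n_a / phi, n_b / phi
        logw_fn = lambda k: (
            gammaln(k + r_a) - gammaln(k + 1)
            + gammaln(t - k + r_b) - gammaln(t - k + 1)
        )
        m_a = t * n_a / (n_a + n_b)
        m_b = t - m_a
        v_a = m_a + phi * m_a**2 / n_a
        v_b = m_b + phi * m_b**2 / n_b
        var = v_a * v_b / (v_a + v_b)
    if t <= _FULL_ENUM_MAX:
        lo, hi = 0, t
    else:
        half = max(200.0, _WINDOW_SDS * np.sqrt(var))
        lo = int(max(0, np.floor(min(m_a, y_a) - half)))
        hi = int(min(t, np.ceil(max(m_a, y_a) + half)))
    ks = np.arange(lo, hi + 1)
    logw = logw_fn(ks)
    logz = logsumexp(logw)
    log_obs = logw[y_a - lo]
    qualify = logw <= log_obs + 1e-9
    return float(min(1.0, np.exp(logsumexp(logw[qualify]) - logz)))


def exact_nb_test(
    m: ExpressionMatrix,
    labels: GroupLabels,
    factors: pd.Series | None = None,
) -> np.ndarray:
    """Per-gene exact NB p-values for a two-group comparison.

    Returns an array aligned with ``m.gene_ids``; genes with zero total in
    both groups get NaN (they carry no information and should have been
    zero-filtered upstream). Each group must have at least 2 samples so a
    dispersion can be estimated.
    """
    if m.mode != MODE_COUNTS:
        raise ModeError("the exact NB test applies to count matrices")
    groups, ga, gb = _two_group_index(m, labels)
    if ga.size < 2 or gb.size < 2:
        raise ValueError("each group needs at least 2 samples")
    if factors is None:
        factors = norm_factors(m, labels, "tmm")
    f = np.asarray([factors[s] for s in m.sample_ids], dtype=float)
    if np.any(f <= 0):
        raise ValueError("normalization factors must be positive")
    scaled = m.values / f[None, :]

    phi = _moderated_dispersions(scaled, ga, gb)
    y_a = np.rint(scaled[:, ga].sum(axis=1)).astype(np.int64)
    y_b = np.rint(scaled[:, gb].sum(axis=1)).astype(np.int64)
    t = y_a + y_b

    p = np.full(m.n_genes, np.nan)
    for i in range(m.n_genes):
        if t[i] == 0:
            continue
        p[i] = _split_pvalue(int(y_a[i]), int(t[i]), ga.size, gb.size, float(phi[i]))
    return p


def _moderated_dispersions(scaled: np.ndarray, ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    """Method-of-moments phi per gene, shrunk 50/50 to the trimmed mean."""
    per_gene = np.zeros(scaled.shape[0])
    weight = np.zeros(scaled.shape[0])
    for idx in (ga, gb):
        grp = scaled[:, idx]
        mean = grp.mean(axis=1)
        var = grp.var(axis=1, ddof=1)
        ok = mean > 0
        w = idx.size - 1
        est = np.zeros(scaled.shape[0])
        est[ok] = (var[ok] - mean[ok]) / mean[ok] ** 2
        per_gene[ok] += w * est[ok]
        weight[ok] += w
    with np.errstate(invalid="ignore"):
        phi = np.where(weight > 0, per_gene / np.maximum(weight, 1), 0.0)
    phi = np.maximum(phi, 0.0)
    informative = weight > 0
    common = float(trim_mean(phi[informative], 0.1)) if informative.any() else 0.0
    return 0.5 * phi + 0.5 * common


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg q-values, input order preserved, capped at 1."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(n)
    q[order] = q_sorted
    return q


def p_deg(q_values, fdr: float) -> float:
    """Percentage of tested genes with q <= fdr (NaN entries excluded)."""
    q = np.asarray(q_values, dtype=float)
    tested = np.isfinite(q)
    if tested.sum() == 0:
        return 0.0
    return 100.0 * float((q[tested] <= fdr).sum()) / float(tested.sum())


def p_true_deg(p_deg_value: float, fdr: float) -> float:
    """Expected truly-DE share of declarations: P_DEG * (1 - FDR)."""
    return p_deg_value * (1.0 - fdr)


def auc_vs_truth(p_values, is_deg) -> float:
    """Mann-Whitney AUC of the ascending-p gene ranking against truth."""
    p = np.asarray(p_values, dtype=float)
    truth = np.asarray(is_deg, dtype=bool)
    ok = np.isfinite(p)
    p, truth = p[ok], truth[ok]
    n1, n0 = int(truth.sum()), int((~truth).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("need at least one DEG and one non-DEG")
    ranks = rankdata(p)  # ascending; ties get average ranks
    rank_sum_deg = float(ranks[truth].sum())
    return (n1 * n0 + n1 * (n1 + 1) / 2.0 - rank_sum_deg) / (n1 * n0)


def run_de(
    m: ExpressionMatrix,
    labels: GroupLabels,
    fdr: float = 0.10,
    norm: str = "tmm",
    truth: pd.Series | None = None,
) -> DEResult:
    """Normalize, test, adjust, and summarize a two-group comparison.

    ``truth`` (a boolean per-gene Series) adds the AUC of the p-value
    ranking. Genes absent from ``truth`` raise; extra truth rows are
    ignored.
    """
    factors = norm_factors(m, labels, norm, fdr=fdr)
    p = exact_nb_test(m, labels, factors)
    tested = np.isfinite(p)
    q = np.full_like(p, np.nan)
    q[tested] = bh_adjust(p[tested])
    rank = np.full(p.size, np.nan)
    rank[tested] = rankdata(p[tested], method="ordinal")
    table = pd.DataFrame(
        {"p_value": p, "q_value": q, "rank": rank}, index=m.gene_ids
    )
    pct = p_deg(q, fdr)
    auc = None
    if truth is not None:
        aligned = truth.reindex(m.gene_ids)
        if aligned.isna().any():
            missing = list(aligned.index[aligned.isna()])[:5]
            raise ValueError(f"truth missing for genes {missing}")
        flags = aligned.to_numpy(dtype=bool)
        # AUC is undefined when the truth is one-class (e.g. a null simulation)
        auc = auc_vs_truth(p, flags) if 0 < flags.sum() < flags.size else None
    return DEResult(table, factors, fdr, pct, p_true_deg(pct, fdr), auc)
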
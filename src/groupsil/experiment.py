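"""Bootstrap replicate-number sweeps and P_DEG-vs-AS scatter experiments.

The central question these harnesses address: the percentage of declared
DEGs (P_DEG) grows with the number of replicates per group, while the
average silhouette (AS) of the same grouping does not — AS measures the
separation structure of the data, not the power of the test. A sweep
subsamples N_rep replicates per group many times (without replacement
within an iteration), recomputing the filters, AS, and the DE summary on
every subsample, exactly as one would on a fresh dataset of that size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .detest import run_de
from .iolib import ExpressionMatrix, GroupLabels
from .metrics import silhouette_scores, spearman_distance
from .preprocess import filter_genes, zero_filter
from .simulate import SimulatedDataset, SimulationConfig, simulate_counts, subsample_replicates


def derive_seed(master_seed: int, *key: int) -> int:
    """Deterministic child seed from the master seed and an integer key.

    Uses numpy's SeedSequence spawn-key mechanism, so every (n_rep,
    iteration) record of a sweep can be re-run in isolation. The result is
    kept below 2**31.
    """
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class SweepConfig:
    """A replicate-number sweep: grid x iterations at one FDR threshold."""

    n_rep_grid: list[int]
    n_iterations: int = 100
    fdr: float = 0.10
    seed: int = 0
    norm: str = "tmm"
    unique_filter: bool = True

    def __post_init__(self) -> None:
        if not self.n_rep_grid:
            raise ValueError("n_rep_grid must be non-empty")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class SweepResult:
    """One record per (n_rep, iteration): p_deg, as_value, auc, sampled ids."""

    records: pd.DataFrame
    config: SweepConfig = field(repr=False, default=None)

    def summary(self) -> pd.DataFrame:
        """Per-n_rep mean/sd of p_deg, as_value and (when present) auc."""
        cols = [c for c in ("p_deg", "as_value", "auc") if c in self.records]
        agg = self.records.groupby("n_rep")[cols].agg(["mean", "std"])
        agg.columns = [f"{a}_{b}" for a, b in agg.columns]
        return agg.reset_index()


def _as_source(source) -> tuple[ExpressionMatrix, GroupLabels, pd.Series | None]:
    if isinstance(source, SimulatedDataset):
        return source.matrix, source.labels, source.truth["is_deg"]
    matrix, labels = source
    return matrix, labels, None


def evaluate_subsample(
    matrix: ExpressionMatrix,
    labels: GroupLabels,
    truth: pd.Series | None,
    fdr: float,
    norm: str = "tmm",
    unique: bool = True,
) -> dict:
    """Filters + AS + DE summary for one (sub)matrix, as the sweep does it.

    AS uses the zero-then-unique-filtered matrix; the DE test uses the
    zero-filtered matrix — the filters are recomputed per subsample
    because a gene can lose all its non-zero cells in a subsample.
    """
    de_matrix, _ = zero_filter(matrix)
    as_matrix, report = filter_genes(matrix, unique=unique)
    sil = silhouette_scores(spearman_distance(as_matrix), labels)
    sub_truth = truth.reindex(de_matrix.gene_ids) if truth is not None else None
    de = run_de(de_matrix, labels, fdr=fdr, norm=norm, truth=sub_truth)
    return {
        "p_deg": de.p_deg,
        "as_value": sil.AS,
        "auc": de.auc if de.auc is not None else np.nan,
        "n_genes_de": de_matrix.n_genes,
        "n_genes_as": as_matrix.n_genes,
        "filter_report": report,
        "silhouette": sil,
        "de_result": de,
    }


def run_sweep(source, cfg: SweepConfig) -> SweepResult:
    """Bootstrap N_rep sweep over a dataset with known group labels.

    ``source`` is a :class:`SimulatedDataset` (AUC is then recorded
    against the planted truth) or an ``(ExpressionMatrix, GroupLabels)``
    pair. Sampling is without replacement within an iteration and
    independent across iterations; every record's subsample is
    reproducible from (seed, n_rep, iteration) alone.
    """
    matrix, labels, truth = _as_source(source)
    min_group = min(len(labels.members(g)) for g in labels.groups)
    for n_rep in cfg.n_rep_grid:
        if n_rep > min_group:
            raise ValueError(f"n_rep={n_rep} exceeds smallest group size {min_group}")
    rows = []
    for n_rep in cfg.n_rep_grid:
        for it in range(cfg.n_iterations):
            child = derive_seed(cfg.seed, n_rep, it)
            try:
                sub_m, sub_g = subsample_replicates(matrix, labels, n_rep, child)
                ev = evaluate_subsample(
                    sub_m, sub_g, truth, cfg.fdr, cfg.norm, cfg.unique_filter
                )
            except Exception as exc:
                raise RuntimeError(
                    f"sweep iteration failed at n_rep={n_rep}, iteration={it}: {exc}"
                ) from exc
            rows.append(
                {
                    "n_rep": n_rep,
                    "iteration": it,
                    "p_deg": ev["p_deg"],
                    "as_value": ev["as_value"],
                    "auc": ev["auc"],
                    "sampled_ids": ",".join(sub_m.sample_ids),
                }
            )
    return SweepResult(pd.DataFrame(rows), cfg)


def pdeg_as_scatter(
    configs: list[SimulationConfig],
    n_rep: int,
    iterations: int,
    fdr: float = 0.10,
    norm: str = "tmm",
) -> pd.DataFrame:
    """(p_simdeg, p_deg, as_value) per freshly simulated dataset.

    For each config, ``iterations`` independent datasets are simulated at
    ``n_rep`` replicates per group (seeds derived from the config's seed),
    then scored with the same per-dataset filtering as the sweep. Feeding
    a grid of planted DEG fractions reproduces the strong positive
    P_DEG-vs-AS relationship at fixed N_rep.
    """
    rows = []
    for cfg in configs:
        for it in range(iterations):
            child = replace(
                cfg, n_rep_A=n_rep, n_rep_B=n_rep, seed=derive_seed(cfg.seed, it)
            )
            ds = simulate_counts(child)
            ev = evaluate_subsample(ds.matrix, ds.labels, ds.truth["is_deg"], fdr, norm)
            rows.append(
                {
                    "p_simdeg": cfg.p_deg * 100.0,
                    "iteration": it,
                    "p_deg": ev["p_deg"],
                    "as_value": ev["as_value"],
                    "auc": ev["auc"],
                }
            )
    return pd.DataFrame(rows)


def slope_as_vs_nrep(result: SweepResult) -> float:
    """Least-squares slope of mean AS per n_rep level against n_rep.

    Near-zero slope is the signature that AS does not depend on the
    number of replicates.
    """
    means = result.records.groupby("n_rep")["as_value"].mean()
    if len(means) < 2:
        raise ValueError("need at least 2 n_rep levels for a slope")
    x = means.index.to_numpy(dtype=float)
    y = means.to_numpy(dtype=float)
    return float(np.polyfit(x, y, 1)[0])
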
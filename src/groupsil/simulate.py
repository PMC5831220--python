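"""Negative-binomial RNA-seq count simulation with known DEG structure.

Counts for gene g in sample j are drawn independently from a negative
binomial with mean m and variance m + phi * m**2 (phi = 0 degenerates to
Poisson). Non-DEGs share one mean mu across both groups; a DEG
up-regulated in group A has mean fold_change * mu in A and mu in B
(mirrored for B-up DEGs). Per-gene (mu, phi) pairs come either from a
documented synthetic default or from a user-supplied two-column table
resampled with replacement, standing in for an empirical mean/dispersion
distribution estimated from real data.

Library depths are equal by construction unless a per-sample depth
multiplier vector is supplied; the DE engine still estimates
normalization factors from the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .iolib import ExpressionMatrix, FormatError, GroupLabels, MODE_COUNTS

SYNTHETIC_DEFAULT = "synthetic_default"

# Synthetic (mu, phi) source: log10(mu) ~ Normal(1.0, 0.7) truncated to
# mu in [0.5, 1e5]; phi ~ Gamma(shape 2, mean 0.15) truncated to
# [0.001, 2.0]. Medians mu ~ 10, phi ~ 0.13 — a bulk RNA-seq-like regime.
_MU_LOG10_MEAN = 1.0
_MU_LOG10_SD = 0.7
_MU_RANGE = (0.5, 1e5)
_PHI_SHAPE = 2.0
_PHI_MEAN = 0.15
_PHI_RANGE = (0.001, 2.0)


@dataclass
class NBParams:
    """Per-gene NB mean and dispersion (variance = mu + phi * mu**2)."""

    mu: float
    phi: float

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError("mu must be positive")
        if self.phi < 0:
            raise ValueError("phi must be non-negative")


@dataclass
class SimulationConfig:
    """Design of a two-group NB simulation.

    ``p_deg`` is the planted DEG fraction (the true P_simDEG);
    ``fold_change`` the multiplicative effect on the up-regulated group's
    mean; ``frac_up_in_A`` the share of DEGs up-regulated in group A.
    """

    n_genes: int
    p_deg: float
    n_rep_A: int
    n_rep_B: int
    seed: int
    fold_change: float = 4.0
    frac_up_in_A: float = 0.5
    param_source: str = SYNTHETIC_DEFAULT
    depth_factors: list[float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_deg <= 1.0:
            raise ValueError("p_deg must be in [0, 1]")
        if not 0.0 <= self.frac_up_in_A <= 1.0:
            raise ValueError("frac_up_in_A must be in [0, 1]")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")
        if self.n_genes < 1 or self.n_rep_A < 1 or self.n_rep_B < 1:
            raise ValueError("n_genes and replicate counts must be >= 1")

    @property
    def n_deg(self) -> int:
        return int(round(self.n_genes * self.p_deg))

    @property
    def n_up_A(self) -> int:
        return int(round(self.n_deg * self.frac_up_in_A))


@dataclass
class SimulatedDataset:
    """Counts plus the per-gene truth table the generator planted."""

    matrix: ExpressionMatrix
    truth: pd.DataFrame  # index gene_id; columns is_deg (bool), up_group (A/B/none)
    config: SimulationConfig
    params: list[NBParams] = field(repr=False, default_factory=list)

    @property
    def labels(self) -> GroupLabels:
        assignment = {s: s[0] for s in self.matrix.sample_ids}
        return GroupLabels(assignment, ["A", "B"])


def _truncated(draw, lo: float, hi: float, n: int, rng) -> np.ndarray:
    out = np.empty(n)
    filled = 0
    while filled < n:
        x = draw(rng, n - filled)
        x = x[(x >= lo) & (x <= hi)]
        out[filled : filled + x.size] = x
        filled += x.size
    return out


def draw_params(n_genes: int, source: str = SYNTHETIC_DEFAULT, seed: int | None = None,
                rng: np.random.Generator | None = None) -> list[NBParams]:
    """Draw per-gene (mu, phi) pairs from the configured source.

    ``source`` is either ``"synthetic_default"`` or ``"table:<path>"``
    pointing at a two-column (mu, phi) text file whose rows are resampled
    with replacement.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if source == SYNTHETIC_DEFAULT:
        mu = 10.0 ** _truncated(
            lambda r, k: r.normal(_MU_LOG10_MEAN, _MU_LOG10_SD, k),
            np.log10(_MU_RANGE[0]), np.log10(_MU_RANGE[1]), n_genes, rng,
        )
        phi = _truncated(
            lambda r, k: r.gamma(_PHI_SHAPE, _PHI_MEAN / _PHI_SHAPE, k),
            *_PHI_RANGE, n_genes, rng,
        )
    elif source.startswith("table:"):
        path = source[len("table:"):]
        try:
            table = pd.read_csv(path, sep=None, engine="python", header=None,
                                comment="#", dtype=str)
            if len(table) and not _is_number(table.iloc[0, 0]):
                table = table.iloc[1:]
            grid = table.to_numpy(dtype=float)
        except (ValueError, pd.errors.ParserError) as exc:
            raise FormatError(f"malformed (mu, phi) table {path}: {exc}") from exc
        if grid.ndim != 2 or grid.shape[1] != 2 or grid.shape[0] == 0:
            raise FormatError(f"(mu, phi) table {path} must be non-empty with 2 columns")
        if np.any(grid[:, 0] <= 0) or np.any(grid[:, 1] < 0):
            raise FormatError(f"(mu, phi) table {path} has mu <= 0 or phi < 0")
        rows = rng.integers(0, grid.shape[0], size=n_genes)
        mu, phi = grid[rows, 0], grid[rows, 1]
    else:
        raise ValueError(f"unknown parameter source {source!r}")
    return [NBParams(float(m), float(p)) for m, p in zip(mu, phi)]


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except (TypeError, ValueError):
        return False


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mean, variance = mean + phi mean^2); phi = 0 handled as Poisson.

    Parameterization: size r = 1/phi, success prob p = r / (r + mean),
    which is continuous in distribution as phi -> 0.
    """
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = phi == 0
    if np.any(pois):
        out[pois] = rng.poisson(mean[pois])
    if np.any(~pois):
        r = 1.0 / phi[~pois]
        p = r / (r + mean[~pois])
        out[~pois] = rng.negative_binomial(r, p)
    return out


def simulate_counts(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate a two-group count matrix with planted DEGs.

    The first ``round(n_genes * p_deg)`` genes are DEGs; of those the
    first ``round(n_deg * frac_up_in_A)`` are up-regulated in group A and
    the rest in group B. Samples are named A1..A{n_rep_A}, B1..B{n_rep_B}.
    Same seed, same dataset, bit for bit.
    """
    rng = np.random.default_rng(cfg.seed)
    params = draw_params(cfg.n_genes, cfg.param_source, rng=rng)
    mu = np.array([p.mu for p in params])
    phi = np.array([p.phi for p in params])
    n_deg, n_up_A = cfg.n_deg, cfg.n_up_A
    up_group = np.array(["none"] * cfg.n_genes, dtype=object)
    up_group[:n_up_A] = "A"
    up_group[n_up_A:n_deg] = "B"
    is_deg = np.zeros(cfg.n_genes, dtype=bool)
    is_deg[:n_deg] = True

    mean_A = np.where(up_group == "A", cfg.fold_change * mu, mu)
    mean_B = np.where(up_group == "B", cfg.fold_change * mu, mu)
    n_samples = cfg.n_rep_A + cfg.n_rep_B
    means = np.empty((cfg.n_genes, n_samples))
    means[:, : cfg.n_rep_A] = mean_A[:, None]
    means[:, cfg.n_rep_A :] = mean_B[:, None]
    if cfg.depth_factors is not None:
        depth = np.asarray(cfg.depth_factors, dtype=float)
        if depth.shape != (n_samples,) or np.any(depth <= 0):
            raise ValueError("depth_factors must be positive, one per sample")
        means = means * depth[None, :]
    counts = _nb_draw(rng, means, phi[:, None])

    gene_ids = [f"gene_{i + 1}" for i in range(cfg.n_genes)]
    sample_ids = [f"A{i + 1}" for i in range(cfg.n_rep_A)] + [
        f"B{i + 1}" for i in range(cfg.n_rep_B)
    ]
    matrix = ExpressionMatrix(gene_ids, sample_ids, counts.astype(float), MODE_COUNTS)
    truth = pd.DataFrame({"is_deg": is_deg, "up_group": up_group}, index=gene_ids)
    return SimulatedDataset(matrix, truth, cfg, params)


def subsample_replicates(
    matrix: ExpressionMatrix,
    labels: GroupLabels,
    n_rep: int,
    seed: int,
) -> tuple[ExpressionMatrix, GroupLabels]:
    """Draw ``n_rep`` distinct samples per group, uniformly without replacement.

    The gene set is unchanged; selected samples keep their original column
    order. ``n_rep`` equal to a group's full size returns that group intact.
    """
    rng = np.random.default_rng(seed)
    keep: set[str] = set()
    for grp in labels.groups:
        members = [s for s in matrix.sample_ids if labels.assignment.get(s) == grp]
        if n_rep > len(members):
            raise ValueError(
                f"n_rep={n_rep} exceeds group {grp!r} size {len(members)}"
            )
        chosen = rng.choice(len(members), size=n_rep, replace=False)
        keep.update(members[i] for i in chosen)
    ordered = [s for s in matrix.sample_ids if s in keep]
    return matrix.select_samples(ordered), labels.restrict(ordered)


def subsample_dataset(
    ds: SimulatedDataset, n_rep: int, seed: int
) -> tuple[ExpressionMatrix, GroupLabels]:
    return subsample_replicates(ds.matrix, ds.labels, n_rep, seed)


def with_replicates(cfg: SimulationConfig, n_rep: int, seed: int) -> SimulationConfig:
    """A copy of ``cfg`` at ``n_rep`` replicates per group and a new seed."""
    return replace(cfg, n_rep_A=n_rep, n_rep_B=n_rep, seed=seed)
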
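"""Replicate-generation strategies: similarity-based metacells, random
metacells, and pseudobulk aggregation.

Similarity-based metacells ("sMetacells") are built per time point with a
kernel k-medoids surrogate for archetypal partitioning: greedy max-min
seeding of archetype cells on an adaptive-Gaussian kernel over the
embedding, then alternating assignment / kernel-medoid re-selection
until a fixed point.  Random metacells ("rMetacells") average a fixed
number of randomly drawn same-type cells per (day, cell type) stratum.
Pseudobulk sums raw counts per (sample, cell type) and re-normalizes.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .core_data import (
    DEFAULT_SCALE_FACTOR,
    AnnotatedExpressionMatrix,
    TimeGrid,
    normalize_counts,
)

__all__ = [
    "Metacell",
    "MetacellSet",
    "target_metacell_count",
    "build_knn_graph",
    "construct_smetacells",
    "construct_rmetacells",
    "aggregate_pseudobulk",
    "single_cell_metacells",
    "assign_type_and_purity",
    "filter_for_analysis",
]

logger = logging.getLogger(__name__)

METHODS = ("seacell_like", "random", "pseudobulk", "single_cell")

#: Default single-cells-per-metacell ratio.
DEFAULT_RATIO = 75
DEFAULT_CELLS_PER_RMETACELL = 20
DEFAULT_RMETACELL_REPLICATES = 3


@dataclass
class Metacell:
    id: str
    method: str
    day: int
    member_cell_ids: list[str]
    expression: np.ndarray  # mean normalized expression over genes
    cell_type: str
    purity: float
    severity: str
    sample_id: str | None = None

    @property
    def n_members(self) -> int:
        return len(self.member_cell_ids)


@dataclass
class MetacellSet:
    metacells: list[Metacell]
    gene_ids: list[str]
    provenance: dict = field(default_factory=dict)
    time_grid: TimeGrid = field(default_factory=TimeGrid)

    def __len__(self) -> int:
        return len(self.metacells)

    def __iter__(self):
        return iter(self.metacells)

    def expression_matrix(self) -> np.ndarray:
        """Metacells x genes matrix, row order matching :attr:`metacells`."""
        return np.vstack([m.expression for m in self.metacells])

    def meta_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [m.id for m in self.metacells],
                "method": [m.method for m in self.metacells],
                "day": [m.day for m in self.metacells],
                "cell_type": [m.cell_type for m in self.metacells],
                "purity": [m.purity for m in self.metacells],
                "n_members": [m.n_members for m in self.metacells],
                "severity": [m.severity for m in self.metacells],
                "sample_id": [m.sample_id or "" for m in self.metacells],
            }
        )

    def membership_table(self) -> pd.DataFrame:
        rows = [
            {"metacell_id": m.id, "cell_id": c}
            for m in self.metacells
            for c in m.member_cell_ids
        ]
        return pd.DataFrame(rows, columns=["metacell_id", "cell_id"])

    def subset(self, keep: Sequence[bool]) -> "MetacellSet":
        return MetacellSet(
            metacells=[m for m, k in zip(self.metacells, keep) if k],
            gene_ids=self.gene_ids,
            provenance=dict(self.provenance),
            time_grid=self.time_grid,
        )


def target_metacell_count(
    n_cells: int,
    ratio: int = DEFAULT_RATIO,
    day: int | None = None,
    day_overrides: dict[int, int] | None = None,
) -> int:
    """Number of metacells for a time point: one per ``ratio`` cells,
    rounded to the nearest multiple of 10 (half-up), floored at 10.

    ``day_overrides`` maps a day to an explicit count, taking precedence
    (e.g. doubling the final day for better baseline comparison).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if day_overrides and day is not None and int(day) in day_overrides:
        return int(day_overrides[int(day)])
    quotient = n_cells / ratio
    rounded = int(np.floor(quotient / 10.0 + 0.5)) * 10
    return max(rounded, 10)


def build_knn_graph(embedding: np.ndarray, k: int) -> sp.csr_matrix:
    """Symmetric adaptive-Gaussian kernel adjacency over k nearest neighbors.

    Per-cell bandwidth is the distance to the ``ceil(k/3)``-th neighbor;
    the directed weights ``exp(-(d_ij / sigma_i)^2)`` are symmetrized by
    averaging, and self-weights are set to 1.
    """
    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError(f"k={k} must be < n_cells={n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    dist, idx = nn.kneighbors(embedding)
    # drop self by index (ties at distance 0 may shuffle the self column)
    keep = idx != np.arange(n)[:, None]
    keep[np.cumsum(keep, axis=1) > k] = False  # cap rows without self at k
    dist = dist[keep].reshape(n, k)
    idx = idx[keep].reshape(n, k)
    sigma = np.maximum(dist[:, int(np.ceil(k / 3)) - 1], 1e-12)
    w = np.exp(-((dist / sigma[:, None]) ** 2))
    rows = np.repeat(np.arange(n), k)
    W = sp.csr_matrix((w.ravel(), (rows, idx.ravel())), shape=(n, n))
    W = (W + W.T) / 2.0
    W.setdiag(1.0)
    return sp.csr_matrix(W)


def _adaptive_kernel(embedding: np.ndarray, cols: np.ndarray, k: int) -> np.ndarray:
    """Dense adaptive-Gaussian similarity between all cells and ``cols`` cells."""
    n = embedding.shape[0]
    kk = min(max(k, 2), n - 1)
    nn = NearestNeighbors(n_neighbors=kk + 1).fit(embedding)
    dist, _ = nn.kneighbors(embedding)
    sigma = np.maximum(dist[:, max(int(np.ceil(kk / 3)), 1)], 1e-12)
    d2 = (
        np.sum(embedding**2, axis=1)[:, None]
        - 2.0 * embedding @ embedding[cols].T
        + np.sum(embedding[cols] ** 2, axis=1)[None, :]
    )
    d2 = np.maximum(d2, 0.0)
    return np.exp(-d2 / (sigma[:, None] * sigma[cols][None, :]))


def assign_type_and_purity(member_types: Iterable[str]) -> tuple[str, float]:
    """Modal member type (lexicographic tie-break) and its fraction."""
    counts = Counter(member_types)
    if not counts:
        raise ValueError("metacell must have at least one member")
    best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    total = sum(counts.values())
    return best[0], best[1] / total


def _modal_severity(severities: Iterable[str]) -> str:
    label, _ = assign_type_and_purity(severities)
    return label


def _mean_expression(normalized: sp.csr_matrix, idx: np.ndarray) -> np.ndarray:
    return np.asarray(normalized[idx].mean(axis=0)).ravel()


def _require_normalized(matrix: AnnotatedExpressionMatrix) -> None:
    if matrix.normalized is None:
        raise ValueError("normalized layer absent; call matrix.normalize() first")


def construct_smetacells(
    matrix: AnnotatedExpressionMatrix,
    embedding: np.ndarray | None = None,
    ratio: int = DEFAULT_RATIO,
    day_overrides: dict[int, int] | None = None,
    k: int = 15,
    max_iter: int = 50,
    seed: int = 0,
) -> MetacellSet:
    """Similarity-preserving metacells, built per time point.

    For each day's cells: seed ``target_metacell_count`` archetypes by
    greedy max-min coverage of the adaptive kernel, then alternate
    (i) assign every cell to its most similar archetype and (ii) replace
    each archetype with its group's kernel medoid, until the assignment
    stops changing or ``max_iter`` sweeps.  The total similarity of
    cells to their archetypes is non-decreasing across sweeps.  Every
    cell of a day belongs to exactly one metacell; empty groups are
    dropped (logged).
    """
    _require_normalized(matrix)
    if embedding is None:
        if matrix.embedding is None:
            raise ValueError("no embedding supplied and matrix.embedding is None")
        embedding = matrix.embedding
    embedding = np.asarray(embedding, dtype=float)

    meta = matrix.cell_meta
    non_control = meta["severity"] != "control"
    metacells: list[Metacell] = []
    for day in matrix.time_grid:
        day_idx = np.flatnonzero((meta["day"].to_numpy() == day) & non_control.to_numpy())
        if day_idx.size == 0:
            continue
        n_mc = min(
            target_metacell_count(day_idx.size, ratio, day=day, day_overrides=day_overrides),
            day_idx.size,
        )
        groups = _kernel_kmedoids(embedding[day_idx], n_mc, k=k, max_iter=max_iter)
        dropped = n_mc - len(groups)
        if dropped:
            logger.warning("day %s: dropped %d empty metacells", day, dropped)
        for j, grp in enumerate(groups):
            idx = day_idx[grp]
            ctype, purity = assign_type_and_purity(meta["cell_type"].iloc[idx])
            metacells.append(
                Metacell(
                    id=f"sMC_d{day}_{j:03d}",
                    method="seacell_like",
                    day=int(day),
                    member_cell_ids=meta["cell_id"].iloc[idx].tolist(),
                    expression=_mean_expression(matrix.normalized, idx),
                    cell_type=ctype,
                    purity=purity,
                    severity=_modal_severity(meta["severity"].iloc[idx]),
                )
            )
    return MetacellSet(
        metacells=metacells,
        gene_ids=list(matrix.gene_ids),
        provenance={
            "method": "seacell_like",
            "params": {"ratio": ratio, "k": k, "day_overrides": day_overrides or {}},
            "seed": seed,
        },
        time_grid=matrix.time_grid,
    )


def _kernel_kmedoids(
    embedding: np.ndarray, n_groups: int, k: int, max_iter: int
) -> list[np.ndarray]:
    """Partition cells into ``n_groups`` by kernel k-medoids.

    Returns member index arrays (positions into ``embedding`` rows).
    Deterministic: seeding is greedy max-min starting from the highest
    kernel-density cell; all ties break on the lowest index.
    """
    n = embedding.shape[0]
    if n_groups > n:
        raise ValueError(f"n_groups={n_groups} exceeds n_cells={n}")
    if n_groups == n:
        return [np.array([i]) for i in range(n)]
    K_all = _adaptive_kernel(embedding, np.arange(n), k)  # n x n, symmetric-ish

    # greedy max-min seeding on the kernel: start at peak density, then
    # repeatedly take the cell least similar to the chosen archetypes
    density = K_all.sum(axis=1)
    archetypes = [int(np.argmax(density))]
    max_sim = K_all[:, archetypes[0]].copy()
    for _ in range(1, n_groups):
        cand = int(np.argmin(max_sim))
        archetypes.append(cand)
        max_sim = np.maximum(max_sim, K_all[:, cand])
    arche = np.asarray(archetypes)

    assign = np.argmax(K_all[:, arche], axis=1)
    for _ in range(max_iter):
        # medoid update: member maximizing within-group similarity sum
        new_arche = arche.copy()
        for gidx in range(len(arche)):
            members = np.flatnonzero(assign == gidx)
            if members.size == 0:
                continue
            sub = K_all[np.ix_(members, members)].sum(axis=0)
            new_arche[gidx] = members[int(np.argmax(sub))]
        new_assign = np.argmax(K_all[:, new_arche], axis=1)
        if np.array_equal(new_assign, assign) and np.array_equal(new_arche, arche):
            break
        arche, assign = new_arche, new_assign
    return [np.flatnonzero(assign == gidx) for gidx in range(len(arche)) if np.any(assign == gidx)]


def construct_rmetacells(
    matrix: AnnotatedExpressionMatrix,
    n_per_metacell: int = DEFAULT_CELLS_PER_RMETACELL,
    n_replicates: int = DEFAULT_RMETACELL_REPLICATES,
    seed: int = 0,
) -> MetacellSet:
    """Random same-type metacells per (day, cell type) stratum.

    Each metacell averages ``n_per_metacell`` cells drawn without
    replacement (different metacells of a stratum may overlap).  Strata
    with fewer than ``n_per_metacell`` cells are skipped with a warning.
    """
    _require_normalized(matrix)
    rng = np.random.default_rng(seed)
    meta = matrix.cell_meta
    non_control = meta["severity"] != "control"
    metacells: list[Metacell] = []
    for day in matrix.time_grid:
        day_mask = (meta["day"].to_numpy() == day) & non_control.to_numpy()
        for ctype in sorted(meta.loc[day_mask, "cell_type"].unique()):
            stratum = np.flatnonzero(day_mask & (meta["cell_type"].to_numpy() == ctype))
            if stratum.size < n_per_metacell:
                logger.warning(
                    "day %s type %s: %d cells < %d, stratum skipped",
                    day, ctype, stratum.size, n_per_metacell,
                )
                continue
            for rep in range(n_replicates):
                idx = rng.choice(stratum, size=n_per_metacell, replace=False)
                metacells.append(
                    Metacell(
                        id=f"rMC_d{day}_{ctype}_{rep}",
                        method="random",
                        day=int(day),
                        member_cell_ids=meta["cell_id"].iloc[idx].tolist(),
                        expression=_mean_expression(matrix.normalized, idx),
                        cell_type=ctype,
                        purity=1.0,
                        severity=_modal_severity(meta["severity"].iloc[idx]),
                    )
                )
    return MetacellSet(
        metacells=metacells,
        gene_ids=list(matrix.gene_ids),
        provenance={
            "method": "random",
            "params": {"n_per_metacell": n_per_metacell, "n_replicates": n_replicates},
            "seed": seed,
        },
        time_grid=matrix.time_grid,
    )


def aggregate_pseudobulk(
    matrix: AnnotatedExpressionMatrix,
    by_cell_type: bool = True,
    scale_factor: float = DEFAULT_SCALE_FACTOR,
) -> MetacellSet:
    """Sum raw counts per (sample, cell type) — or per sample with
    ``by_cell_type=False`` — then re-normalize the summed profile."""
    meta = matrix.cell_meta
    non_control = meta["severity"] != "control"
    keys = (
        list(zip(meta["sample_id"], meta["cell_type"]))
        if by_cell_type
        else [(s, "all") for s in meta["sample_id"]]
    )
    key_arr = pd.Series(keys)
    metacells: list[Metacell] = []
    for key in sorted(key_arr[non_control].unique()):
        idx = np.flatnonzero((key_arr == key).to_numpy() & non_control.to_numpy())
        summed = np.asarray(matrix.counts[idx].sum(axis=0)).ravel()
        total = summed.sum()
        if total == 0:
            continue
        expr = np.log1p(summed / total * scale_factor)
        sample_id, ctype = key
        if by_cell_type:
            ctype_label, purity = assign_type_and_purity(meta["cell_type"].iloc[idx])
        else:
            ctype_label, purity = "all", 1.0
        metacells.append(
            Metacell(
                id=f"PB_{sample_id}_{ctype}",
                method="pseudobulk",
                day=int(meta["day"].iloc[idx[0]]),
                member_cell_ids=meta["cell_id"].iloc[idx].tolist(),
                expression=expr,
                cell_type=ctype_label,
                purity=purity,
                severity=_modal_severity(meta["severity"].iloc[idx]),
                sample_id=sample_id,
            )
        )
    return MetacellSet(
        metacells=metacells,
        gene_ids=list(matrix.gene_ids),
        provenance={"method": "pseudobulk", "params": {"by_cell_type": by_cell_type}, "seed": None},
        time_grid=matrix.time_grid,
    )


def single_cell_metacells(matrix: AnnotatedExpressionMatrix) -> MetacellSet:
    """Each cell as its own 'metacell' — the single-cell-granularity comparator."""
    _require_normalized(matrix)
    meta = matrix.cell_meta
    dense = matrix.normalized
    metacells = [
        Metacell(
            id=f"SC_{meta['cell_id'].iloc[i]}",
            method="single_cell",
            day=int(meta["day"].iloc[i]),
            member_cell_ids=[meta["cell_id"].iloc[i]],
            expression=np.asarray(dense[i].todense()).ravel(),
            cell_type=meta["cell_type"].iloc[i],
            purity=1.0,
            severity=meta["severity"].iloc[i],
        )
        for i in range(matrix.n_cells)
        if meta["severity"].iloc[i] != "control"
    ]
    return MetacellSet(
        metacells=metacells,
        gene_ids=list(matrix.gene_ids),
        provenance={"method": "single_cell", "params": {}, "seed": None},
        time_grid=matrix.time_grid,
    )


def filter_for_analysis(
    mcs: MetacellSet,
    min_cells_per_type: int = 500,
    purity_min: float | None = None,
    day_masks: dict[str, Sequence[int]] | None = None,
) -> MetacellSet:
    """Apply the pre-analysis exclusions.

    Cell types whose metacells cover fewer than ``min_cells_per_type``
    single cells in total are removed; an optional purity floor keeps
    only sufficiently pure metacells (0.95 reproduces the "pure" subset);
    ``day_masks`` drops listed days for specific cell types.
    """
    cells_per_type: Counter = Counter()
    for m in mcs:
        cells_per_type[m.cell_type] += m.n_members
    day_masks = day_masks or {}
    keep = []
    for m in mcs:
        ok = cells_per_type[m.cell_type] >= min_cells_per_type
        if ok and purity_min is not None:
            ok = m.purity > purity_min
        if ok and m.day in set(day_masks.get(m.cell_type, ())):
            ok = False
        keep.append(ok)
    out = mcs.subset(keep)
    if len(mcs) and not len(out):
        raise ValueError("filter removed every metacell")
    out.provenance["filters"] = {
        "min_cells_per_type": min_cells_per_type,
        "purity_min": purity_min,
        "day_masks": {k: list(v) for k, v in day_masks.items()},
        "n_in": len(mcs),
        "n_out": len(out),
    }
    logger.info("filter_for_analysis: %d -> %d metacells", len(mcs), len(out))
    return out
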
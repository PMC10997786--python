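"""Time-series scRNA-seq count simulator with planted temporal programs.

Counts are negative-binomial draws around a cell-specific library factor
times ``exp(gene trajectory + cell-type/state marker offsets + patient
offset + N(0, noise_sd))``.  Differentially expressed genes follow
quadratic log-trajectories constructed to provably satisfy one of the
eight velocity-trend classes; everything else is flat through time, so
downstream regression, gating, and trend calls can all be checked
against known ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_data import AnnotatedExpressionMatrix, TimeGrid
from .trends import TrendLabel, classify_trend_closed_form

__all__ = [
    "SimConfig",
    "SimTruth",
    "TrendParamError",
    "validate_trend_params",
    "trend_mean_function",
    "make_trend_params",
    "simulate_timecourse",
    "simulate_replicate_values",
]


class TrendParamError(ValueError):
    """Quadratic coefficients violate the declared trend class."""


def _vertex(A: float, B: float) -> float:
    return -B / (2.0 * A)


def validate_trend_params(
    trend_class: TrendLabel, A: float, B: float, C: float, window: tuple[float, float]
) -> None:
    """Check the closed-form constraints of a trend class; raise naming them."""
    t0, t1 = float(window[0]), float(window[1])
    cls = TrendLabel(trend_class)

    def fail(constraint: str) -> None:
        raise TrendParamError(f"{cls.value}: violated constraint: {constraint}")

    if cls is TrendLabel.INC_CONST:
        if A != 0:
            fail("A == 0 (linear)")
        if B <= 0:
            fail("B > 0 (increasing slope)")
    elif cls is TrendLabel.DEC_CONST:
        if A != 0:
            fail("A == 0 (linear)")
        if B >= 0:
            fail("B < 0 (decreasing slope)")
    elif cls is TrendLabel.INC_ACCEL:
        if A <= 0:
            fail("A > 0 (convex)")
        if _vertex(A, B) > t0:
            fail("vertex <= t_min (speed grows over window)")
    elif cls is TrendLabel.INC_DECEL:
        if A >= 0:
            fail("A < 0 (concave)")
        if _vertex(A, B) < t1:
            fail("vertex >= t_max (speed shrinks over window)")
    elif cls is TrendLabel.DEC_ACCEL:
        if A >= 0:
            fail("A < 0 (concave)")
        if _vertex(A, B) > t0:
            fail("vertex <= t_min (speed grows over window)")
    elif cls is TrendLabel.DEC_DECEL:
        if A <= 0:
            fail("A > 0 (convex)")
        if _vertex(A, B) < t1:
            fail("vertex >= t_max (speed shrinks over window)")
    elif cls is TrendLabel.MAXIMA:
        if A >= 0:
            fail("A < 0 (downward parabola)")
        if not (t0 < _vertex(A, B) < t1):
            fail("t_min < vertex < t_max (interior maximum)")
    elif cls is TrendLabel.MINIMA:
        if A <= 0:
            fail("A > 0 (upward parabola)")
        if not (t0 < _vertex(A, B) < t1):
            fail("t_min < vertex < t_max (interior minimum)")


def trend_mean_function(
    trend_class: TrendLabel,
    params: tuple[float, float, float],
    t: float | np.ndarray,
    window: tuple[float, float],
) -> float | np.ndarray:
    """Evaluate ``A t^2 + B t + C`` after validating the class constraints."""
    A, B, C = params
    validate_trend_params(trend_class, A, B, C, window)
    t = np.asarray(t, dtype=float)
    t0, t1 = window
    if np.any(t < t0) or np.any(t > t1):
        raise ValueError(f"t outside window [{t0}, {t1}]")
    out = A * t**2 + B * t + C
    return float(out) if out.ndim == 0 else out


def make_trend_params(
    trend_class: TrendLabel,
    days: tuple[int, ...],
    amplitude: float,
    rng: np.random.Generator,
) -> tuple[float, float, float]:
    """Draw (A, B, C) of the given class with the requested amplitude.

    ``amplitude`` is half the peak-to-trough swing (waveform convention),
    so the trajectory's grid maximum minus minimum equals
    ``2 * amplitude`` log-units.  The returned trajectory has minimum 0
    over the grid days (a non-negative log-expression boost) and the
    coefficients provably satisfy the class constraints: the closed-form
    classifier recovers the class.
    """
    cls = TrendLabel(trend_class)
    days_arr = np.asarray(days, dtype=float)
    t0, t1 = float(days_arr[0]), float(days_arr[-1])
    span = t1 - t0

    swing = 2.0 * amplitude  # peak-to-trough range
    if cls in (TrendLabel.INC_CONST, TrendLabel.DEC_CONST):
        B = swing / span
        if cls is TrendLabel.DEC_CONST:
            B = -B
        A = 0.0
    elif cls in (TrendLabel.INC_ACCEL, TrendLabel.DEC_DECEL):
        # convex; vertex at or left/right of the window edge
        v = t0 - rng.uniform(0.0, 0.15) * span if cls is TrendLabel.INC_ACCEL else t1 + rng.uniform(0.0, 0.15) * span
        A = swing / abs((t0 - v) ** 2 - (t1 - v) ** 2)
        B = -2.0 * A * v
    elif cls in (TrendLabel.INC_DECEL, TrendLabel.DEC_ACCEL):
        v = t1 + rng.uniform(0.0, 0.15) * span if cls is TrendLabel.INC_DECEL else t0 - rng.uniform(0.0, 0.15) * span
        A = -swing / abs((t0 - v) ** 2 - (t1 - v) ** 2)
        B = -2.0 * A * v
    else:  # MAXIMA / MINIMA: vertex placed so every interior day beats both endpoints
        interior = days_arr[1:-1]
        lo = max((t0 + interior.max()) / 2, t0)
        hi = min((t1 + interior.min()) / 2, t1)
        if not lo < hi:
            raise ValueError(f"grid {days} admits no interior-extremum vertex")
        # shrink to the strict interior of the admissible interval
        v = lo + (0.25 + 0.5 * rng.uniform()) * (hi - lo)
        d2 = (days_arr - v) ** 2
        A = swing / (d2.max() - d2.min())  # grid range == swing exactly
        if cls is TrendLabel.MAXIMA:
            A = -A
        B = -2.0 * A * v

    vals = A * days_arr**2 + B * days_arr
    C = -vals.min()
    validate_trend_params(cls, A, B, C, (t0, t1))
    got = classify_trend_closed_form(A, B, C, (t0, t1), days_arr)
    if got is not cls:
        raise RuntimeError(f"constructed params classify as {got}, wanted {cls}")
    return float(A), float(B), float(C)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic time course (all sizes desk-scale)."""

    seed: int
    days: tuple[int, ...] = TimeGrid().days
    n_cell_types: int = 5
    n_states_per_type: int = 2
    cells_per_type_day: int = 120
    n_genes: int = 1000
    n_de_per_trend: int = 25
    amplitude: float = 1.0
    noise_sd: float = 0.2
    lib_mu: float = 0.0
    lib_sd: float = 0.3
    nb_dispersion: float = 0.1
    n_patients: int = 5
    n_patients_per_day: int = 2
    patient_sd: float = 0.1
    n_type_markers: int = 30
    type_offset: float = 2.5
    n_state_markers: int = 20
    state_offset: float = 2.0
    severe_patients: tuple[str, ...] = ("patient_0",)
    severe_steepness: float = 1.5
    base_log_mean_range: tuple[float, float] = (np.log(0.2), np.log(3.0))

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in (
            "n_cell_types",
            "n_states_per_type",
            "cells_per_type_day",
            "n_genes",
            "n_patients",
            "n_patients_per_day",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        n_de = 8 * self.n_de_per_trend
        if n_de > self.n_genes:
            raise ValueError(f"{n_de} DE genes exceed n_genes={self.n_genes}")
        if self.n_patients_per_day > self.n_patients:
            raise ValueError("n_patients_per_day exceeds n_patients")


@dataclass
class SimTruth:
    """Planted ground truth: per-gene programs and per-cell assignments."""

    gene_table: pd.DataFrame  # gene_id, is_de, trend_class, A, B, C, affected_cell_types
    cell_table: pd.DataFrame  # cell_id, cell_type, state, day, patient_id, severity
    config: SimConfig

    def de_genes(self) -> pd.DataFrame:
        return self.gene_table[self.gene_table["is_de"]].reset_index(drop=True)


def _day_patients(cfg: SimConfig, day_idx: int) -> list[str]:
    """Rotate a fixed-size patient subset across days (1-3 samples/day style)."""
    return [
        f"patient_{(day_idx + j) % cfg.n_patients}" for j in range(cfg.n_patients_per_day)
    ]


def simulate_timecourse(config: SimConfig) -> tuple[AnnotatedExpressionMatrix, SimTruth]:
    """Generate counts + metadata + ground truth, reproducible from the seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    days = np.asarray(cfg.days, dtype=int)
    window = (float(days[0]), float(days[-1]))
    G = cfg.n_genes
    gene_ids = [f"gene_{g:05d}" for g in range(G)]

    # ---- gene programs -------------------------------------------------
    trend_classes = list(TrendLabel)
    de_rows = []
    coef = np.zeros((G, 3))
    is_de = np.zeros(G, dtype=bool)
    trend_of = np.array([""] * G, dtype=object)
    g = 0
    for cls in trend_classes:
        for _ in range(cfg.n_de_per_trend):
            A, B, C = make_trend_params(cls, tuple(days), cfg.amplitude, rng)
            coef[g] = (A, B, C)
            is_de[g] = True
            trend_of[g] = cls.value
            g += 1
    base_log_mean = rng.uniform(*cfg.base_log_mean_range, size=G)

    type_names = [f"type_{i}" for i in range(cfg.n_cell_types)]
    # marker offsets: disjoint blocks drawn from the non-DE tail when possible
    marker_pool = rng.permutation(np.arange(8 * cfg.n_de_per_trend, G))
    type_markers: dict[str, np.ndarray] = {}
    state_markers: dict[tuple[str, int], np.ndarray] = {}
    pos = 0

    def take(n: int) -> np.ndarray:
        nonlocal pos
        if pos + n <= len(marker_pool):
            out = marker_pool[pos : pos + n]
            pos += n
        else:  # pool exhausted: recycle with replacement (deterministic)
            out = rng.choice(marker_pool if len(marker_pool) else np.arange(G), size=n)
        return out

    for t in type_names:
        type_markers[t] = take(cfg.n_type_markers)
        for s in range(cfg.n_states_per_type):
            state_markers[(t, s)] = take(cfg.n_state_markers)

    patient_ids = [f"patient_{i}" for i in range(cfg.n_patients)]
    patient_offsets = {p: rng.normal(0.0, cfg.patient_sd, size=G) for p in patient_ids}
    severity_of = {
        p: ("severe" if p in cfg.severe_patients else "mild") for p in patient_ids
    }

    # ---- cells ---------------------------------------------------------
    rows_meta = []
    log_mu_rows = []
    for di, day in enumerate(days):
        pts = _day_patients(cfg, di)
        traj = coef[:, 0] * day**2 + coef[:, 1] * day + coef[:, 2]
        for t in type_names:
            for ci in range(cfg.cells_per_type_day):
                patient = pts[ci % len(pts)]
                state = int(rng.integers(cfg.n_states_per_type))
                lam = base_log_mean.copy()
                lam[type_markers[t]] += cfg.type_offset
                lam[state_markers[(t, state)]] += cfg.state_offset
                lam += patient_offsets[patient]
                steep = cfg.severe_steepness if severity_of[patient] == "severe" else 1.0
                lam[is_de] += steep * traj[is_de]
                log_mu_rows.append(lam)
                rows_meta.append(
                    {
                        "cell_id": f"cell_{len(rows_meta):06d}",
                        "sample_id": f"{patient}_d{day}",
                        "patient_id": patient,
                        "day": int(day),
                        "cell_type": t,
                        "state": state,
                        "severity": severity_of[patient],
                    }
                )
    log_mu = np.vstack(log_mu_rows)
    n_cells = log_mu.shape[0]

    lib = np.exp(rng.normal(cfg.lib_mu, cfg.lib_sd, size=n_cells))
    eps = rng.normal(0.0, cfg.noise_sd, size=(n_cells, G)) if cfg.noise_sd > 0 else 0.0
    mean = lib[:, None] * np.exp(log_mu + eps)
    if cfg.nb_dispersion > 0:
        r = 1.0 / cfg.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mean))
    else:
        counts = rng.poisson(mean)
    # a zero-total cell cannot be normalized; nudge deterministically
    totals = counts.sum(axis=1)
    counts[totals == 0, 0] = 1

    meta = pd.DataFrame(rows_meta)
    cell_truth = meta[
        ["cell_id", "cell_type", "state", "day", "patient_id", "severity"]
    ].copy()
    matrix = AnnotatedExpressionMatrix(
        counts=sp.csr_matrix(counts),
        cell_meta=meta.drop(columns=["state"]),
        gene_ids=gene_ids,
        time_grid=TimeGrid(tuple(int(d) for d in days)),
    )
    gene_table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_de": is_de,
            "trend_class": [t if t else "" for t in trend_of],
            "A": coef[:, 0],
            "B": coef[:, 1],
            "C": coef[:, 2],
            "affected_cell_types": ["all" if d else "" for d in is_de],
        }
    )
    return matrix, SimTruth(gene_table=gene_table, cell_table=cell_truth, config=cfg)


def simulate_replicate_values(
    gene_table: pd.DataFrame,
    days: tuple[int, ...],
    n_replicates_per_day: int,
    noise_sd: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw metareplicate-level values directly on the log scale.

    For each gene row of ``gene_table`` (columns A, B, C; zero for null
    genes) and each day, draws ``n_replicates_per_day`` values
    ``A d^2 + B d + C + N(0, noise_sd)``.  Returns ``(times, values)``
    where ``times`` has length ``len(days) * n_replicates_per_day`` and
    ``values`` is genes x observations.  This is the generator used to
    exercise the regression stage in isolation from count sampling.
    """
    rng = np.random.default_rng(seed)
    days_arr = np.asarray(days, dtype=float)
    times = np.repeat(days_arr, n_replicates_per_day)
    A = gene_table["A"].to_numpy()[:, None]
    B = gene_table["B"].to_numpy()[:, None]
    C = gene_table["C"].to_numpy()[:, None]
    mean = A * times[None, :] ** 2 + B * times[None, :] + C
    values = mean + rng.normal(0.0, noise_sd, size=mean.shape)
    return times, values


def null_gene_table(n_genes: int, level: float = 1.0) -> pd.DataFrame:
    """Flat (non-DE) gene table for null simulations."""
    return pd.DataFrame(
        {
            "gene_id": [f"gene_{g:05d}" for g in range(n_genes)],
            "is_de": False,
            "trend_class": "",
            "A": 0.0,
            "B": 0.0,
            "C": level,
        }
    )
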
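"""Stage orchestration: simulate -> metacells -> DEGs -> trends -> diagnostics."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import core_data, diagnostics, metacells, synthetic, timecourse, trends
from .core_data import AnnotatedExpressionMatrix, TimeGrid
from .metacells import MetacellSet

__all__ = ["RunConfig", "label_deg_table", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Resolved parameters of a full run (JSON-serializable)."""

    seed: int
    out_dir: str
    input_dir: str | None = None  # None -> simulate
    days: tuple[int, ...] = core_data.DEFAULT_TIME_GRID
    scale_factor: float = core_data.DEFAULT_SCALE_FACTOR
    n_hvgs: int = 500
    n_components: int = 30
    ratio: int = 75
    day_overrides: dict[int, int] = dataclasses.field(default_factory=dict)
    knn_k: int = 15
    n_per_metacell: int = 20
    n_replicates: int = 3
    alpha: float = 0.05
    r2_min: float = 0.5
    min_n: int = 4
    min_cells_per_type: int = 500
    day_masks: dict[str, list[int]] = dataclasses.field(default_factory=dict)
    grouping: str = "per-type"
    sim: dict = dataclasses.field(default_factory=dict)  # SimConfig overrides

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["days"] = list(d["days"])
        return json.dumps(d, indent=2, sort_keys=True)


def label_deg_table(
    degs: pd.DataFrame,
    mcs: MetacellSet,
    grouping: str = "per-type",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Attach trend labels (and display strings) to a gated DEG table."""
    degs = degs.copy()
    labels = []
    day_means_cache: dict[str, pd.DataFrame] = {}
    for _, row in degs.iterrows():
        stratum = row["cell_type"]
        if stratum not in day_means_cache:
            day_means_cache[stratum] = timecourse.stratum_day_means(mcs, stratum, grouping)
        dm = day_means_cache[stratum]
        window = (float(dm.index.min()), float(dm.index.max()))
        label = trends.classify_trend(
            row["A"],
            row["B"],
            row["C"],
            row["p_A"],
            window,
            dm[row["gene"]].to_numpy(),
            alpha=alpha,
        )
        labels.append(label)
    degs["trend"] = [l.display for l in labels]
    degs["trend_code"] = [l.value for l in labels]
    return degs


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; every output is a TSV under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(config.to_json() + "\n")

    stage = "input"
    try:
        if config.input_dir is None:
            stage = "simulate"
            sim_cfg = synthetic.SimConfig(
                seed=config.seed, days=tuple(config.days), **config.sim
            )
            matrix, truth = synthetic.simulate_timecourse(sim_cfg)
            _write(truth.gene_table, out / "truth_genes.tsv")
            _write(truth.cell_table, out / "truth_cells.tsv")
            core_data.write_expression_matrix(matrix, out / "simulated")
        else:
            d = Path(config.input_dir)
            matrix = core_data.read_expression_matrix(
                d / "matrix.mtx",
                d / "features.tsv",
                d / "barcodes.tsv",
                d / "cell_meta.tsv",
                time_grid=TimeGrid(tuple(config.days)),
            )

        stage = "preprocess"
        matrix.normalize(config.scale_factor)
        if matrix.embedding is None:
            hvgs = core_data.select_hvgs(matrix, min(config.n_hvgs, matrix.n_genes))
            matrix.embedding = core_data.compute_embedding(
                matrix, hvgs, n_components=config.n_components
            )

        stage = "metacells"
        smc = metacells.construct_smetacells(
            matrix,
            ratio=config.ratio,
            day_overrides=config.day_overrides,
            k=config.knn_k,
            seed=config.seed,
        )
        rmc = metacells.construct_rmetacells(
            matrix,
            n_per_metacell=config.n_per_metacell,
            n_replicates=config.n_replicates,
            seed=config.seed,
        )
        pbk = metacells.aggregate_pseudobulk(matrix)
        for name, mcs in (("smetacells", smc), ("rmetacells", rmc), ("pseudobulk", pbk)):
            _write(
                pd.DataFrame(
                    mcs.expression_matrix(),
                    columns=mcs.gene_ids,
                ).assign(id=[m.id for m in mcs])[["id"] + mcs.gene_ids],
                out / f"{name}_expression.tsv",
            )
            _write(mcs.meta_table(), out / f"{name}_meta.tsv")
            _write(mcs.membership_table(), out / f"{name}_membership.tsv")

        stage = "degs"
        filtered = metacells.filter_for_analysis(
            smc,
            min_cells_per_type=config.min_cells_per_type,
            day_masks=config.day_masks,
        )
        fits, degs = timecourse.find_timecourse_degs(
            filtered,
            alpha=config.alpha,
            r2_min=config.r2_min,
            grouping=config.grouping,
            min_n=config.min_n,
        )
        _write(fits, out / "fits.tsv")

        stage = "trends"
        degs = label_deg_table(degs, filtered, grouping=config.grouping, alpha=config.alpha)
        _write(degs, out / "degs.tsv")

        stage = "diagnostics"
        reports = []
        for mcs in (smc, rmc):
            try:
                reports.append(diagnostics.mean_sd_per_stratum(mcs))
            except ValueError:
                logger.warning("variance report skipped for %s", mcs.provenance["method"])
        if reports:
            _write(pd.concat(reports, ignore_index=True), out / "variance_report.tsv")
        gd = diagnostics.genes_detected(
            smc.expression_matrix(), [m.id for m in smc]
        ).assign(method="seacell_like")
        _write(gd, out / "genes_detected.tsv")
        if len(degs):
            sev = diagnostics.severity_expression_table(
                smc, sorted(degs["gene"].unique())[:20]
            )
            _write(sev, out / "severity_expression.tsv")
    except Exception as exc:  # annotate with the failing stage, keep partial output
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return out
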
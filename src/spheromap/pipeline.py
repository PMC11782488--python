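"""End-to-end runs: configuration, staging, logging, reporting.

A run executes QC filter -> radial positioning -> per-gene fits -> spatial
calling -> pattern classification -> (optional) pathway scan and
downsampling curve, writing every result as a TSV plus a JSON metadata file
(config echo, versions, seed, per-stage counts). Reruns with the same
config and seed reproduce identical tables byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calling import (
    SpatialCallConfig,
    SpatialScreen,
    downsampling_curve,
)
from .io import (
    SpheromapError,
    filter_expressed_genes,
    qc_filter_cells,
    read_cell_metadata,
    read_counts,
    read_gmt,
    write_table,
)
from .pathways import PathwayScan, PathwayScanConfig


@dataclass
class RunConfig:
    """All inputs and thresholds of a pipeline run (echoed into metadata)."""

    counts_path: str
    cells_path: str
    out_dir: str
    seed: int
    counts_dialect: str = "mtx_triplet"
    gmt_path: str | None = None
    # QC / filtering
    min_depth: int = 10_000
    min_genes_detected: int = 2_000
    min_mean_umis: float = 1.0
    skip_qc: bool = False
    # spatial calling
    fdr_max: float = 0.10
    mag_min: float = 0.30
    loglik_per_cell: float = -4.91
    boundary_margin: float = 0.1
    interior_contrast: float = 0.1
    # pathways
    min_genes: int = 5
    n_bins: int = 10
    # downsampling
    downsample_ps: list[float] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def validate(self) -> None:
        for name, lo, hi in (
            ("fdr_max", 0, 1), ("mag_min", 0, 1),
            ("boundary_margin", 0, 0.5), ("interior_contrast", 0, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise SpheromapError(f"{name}={v} outside [{lo}, {hi}]")
        if any(not 0 <= p <= 1 for p in self.downsample_ps):
            raise SpheromapError("downsample probabilities must lie in [0, 1]")


def _setup_logging(out_dir: Path) -> logging.Logger:
    logger = logging.getLogger(f"spheromap.{out_dir.name}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s", datefmt="%Y-%m-%dT%H:%M:%S"
    )
    for handler in (
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(out_dir / "run.log", mode="w"),
    ):
        handler.setFormatter(fmt)
        logger.addHandler(handler)
    return logger


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory.

    Any stage failure aborts with the stage name in the exception message
    and leaves an ``INCOMPLETE`` marker file in the run directory.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "INCOMPLETE").write_text("run in progress\n")
    logger = _setup_logging(out)
    meta: dict = {
        "config": asdict(config),
        "package_version": __version__,
        "seed": config.seed,
        "stages": {},
    }
    stage = "load"
    try:
        t0 = time.perf_counter()
        matrix = read_counts(config.counts_path, dialect=config.counts_dialect)
        cells = read_cell_metadata(config.cells_path)
        if [c.cell_id for c in cells] != list(matrix.cell_ids):
            raise SpheromapError("cell metadata does not match matrix columns")
        meta["stages"]["load"] = {
            "n_genes": matrix.n_genes, "n_cells": matrix.n_cells,
            "seconds": round(time.perf_counter() - t0, 3),
        }
        logger.info("loaded %d genes x %d cells", matrix.n_genes, matrix.n_cells)

        stage = "qc"
        t0 = time.perf_counter()
        if config.skip_qc:
            report = {"n_input": len(cells), "n_retained": len(cells),
                      "n_dropped": 0}
        else:
            cells, matrix, report = qc_filter_cells(
                cells, matrix, config.min_depth, config.min_genes_detected
            )
        logger.info("QC: retained %d / %d cells",
                    report["n_retained"], report["n_input"])
        matrix = filter_expressed_genes(matrix, config.min_mean_umis)
        logger.info("expression filter: %d genes retained", matrix.n_genes)
        meta["stages"]["qc"] = {
            **report, "n_genes_expressed": matrix.n_genes,
            "seconds": round(time.perf_counter() - t0, 3),
        }

        stage = "fit_and_call"
        t0 = time.perf_counter()
        call_cfg = SpatialCallConfig(
            fdr_max=config.fdr_max, mag_min=config.mag_min,
            loglik_per_cell=config.loglik_per_cell,
            boundary_margin=config.boundary_margin,
            interior_contrast=config.interior_contrast,
        )
        results = SpatialScreen(matrix, cells, call_cfg).fit()
        write_table(results.table, out / "spatial_genes.tsv")
        meta["stages"]["fit_and_call"] = {
            "n_genes_tested": len(results.table),
            "n_retained": int(results.table["retained"].sum()),
            "n_spatial": results.n_spatial,
            "pattern_counts": results.pattern_counts(),
            "seconds": round(time.perf_counter() - t0, 3),
        }
        logger.info("spatial calling: %d genes called spatial", results.n_spatial)

        if config.gmt_path:
            stage = "pathways"
            t0 = time.perf_counter()
            collection = read_gmt(config.gmt_path)
            scan_cfg = PathwayScanConfig(
                min_genes=config.min_genes, fdr_max=config.fdr_max,
                n_bins=config.n_bins,
            )
            scan = PathwayScan(matrix, cells, collection, scan_cfg,
                               seed=config.seed).fit()
            write_table(scan.table, out / "pathways.tsv")
            meta["stages"]["pathways"] = {
                "n_sets_tested": len(scan.table),
                "n_significant": scan.n_significant,
                "seconds": round(time.perf_counter() - t0, 3),
            }
            logger.info("pathways: %d significant / %d tested",
                        scan.n_significant, len(scan.table))

        if config.downsample_ps:
            stage = "downsample"
            t0 = time.perf_counter()
            curve = downsampling_curve(
                matrix, cells, config.downsample_ps, call_cfg, seed=config.seed
            )
            write_table(curve, out / "downsampling_curve.tsv")
            meta["stages"]["downsample"] = {
                "n_points": len(curve),
                "seconds": round(time.perf_counter() - t0, 3),
            }
            logger.info("downsampling curve: %d points", len(curve))

        stage = "finalize"
        (out / "run_metadata.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n"
        )
        (out / "INCOMPLETE").unlink()
        logger.info("run complete: %s", out)
        return out
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise SpheromapError(f"stage {stage!r} failed: {exc}") from exc


def table_digest(path: str | Path) -> str:
    """SHA-256 of an output table (determinism checks)."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def report(run_dir: str | Path, n_genes_plot: int = 4,
           make_figures: bool = True) -> dict:
    """Summarize a completed run directory; regenerable from it alone.

    Writes a ``report/`` subdirectory with a text summary, per-gene
    diagnostic plot data for the strongest spatial genes (binned observed
    mean UMIs vs r with the fitted curve), and — when matplotlib is usable —
    the corresponding figures.
    """
    run_dir = Path(run_dir)
    if (run_dir / "INCOMPLETE").exists():
        raise SpheromapError(
            f"run at {run_dir} is incomplete; see run.log for the failed stage"
        )
    meta = json.loads((run_dir / "run_metadata.json").read_text())
    genes = pd.read_csv(run_dir / "spatial_genes.tsv", sep="\t")
    rep_dir = run_dir / "report"
    rep_dir.mkdir(exist_ok=True)

    spatial = genes[genes["spatial"] == True]  # noqa: E712 - TSV round-trip
    pattern_counts = spatial["pattern"].value_counts().to_dict()
    lines = [
        "Run summary",
        f"genes tested: {len(genes)}",
        f"spatial genes: {len(spatial)}",
        "pattern counts: "
        + ", ".join(f"{k}={v}" for k, v in sorted(pattern_counts.items())),
    ]
    out: dict = {"pattern_counts": pattern_counts, "n_spatial": len(spatial)}

    top = spatial.sort_values("magnitude", ascending=False).head(n_genes_plot)
    grid = np.linspace(0.0, 1.0, 51)
    curve_rows = []
    for _, row in top.iterrows():
        f = row["a"] + row["b"] * grid + row["c"] * grid**2
        curve_rows += [
            {"gene_id": row["gene_id"], "r": float(g), "f": float(v),
             "pattern": row["pattern"]}
            for g, v in zip(grid, f)
        ]
    curves = pd.DataFrame(curve_rows)
    write_table(curves, rep_dir / "fitted_curves.tsv")

    pw_path = run_dir / "pathways.tsv"
    if pw_path.exists():
        pw = pd.read_csv(pw_path, sep="\t").sort_values("q").head(10)
        lines.append("top pathways:")
        lines += [
            f"  {r.set_name}: xi={r.xi:.3f} q={r.q:.3g} avgR={r.avgR:.2f}"
            for r in pw.itertuples()
        ]
        out["n_significant_pathways"] = meta["stages"].get(
            "pathways", {}
        ).get("n_significant")

    if make_figures and not curves.empty:
        try:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(5, 4))
            for gid, sub in curves.groupby("gene_id"):
                ax.plot(sub["r"], sub["f"], label=gid)
            ax.set_xlabel("radial position r (0 = core)")
            ax.set_ylabel("fractional abundance f(r)")
            ax.legend(fontsize=7)
            fig.tight_layout()
            fig.savefig(rep_dir / "fitted_curves.png", dpi=120)
            plt.close(fig)
        except Exception:  # pragma: no cover - plotting is best-effort
            pass

    (rep_dir / "summary.txt").write_text("\n".join(lines) + "\n")
    out["summary"] = "\n".join(lines)
    return out
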
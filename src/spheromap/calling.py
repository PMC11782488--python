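"""Genome-wide spatial gene calling, pattern classification and downsampling.

Fits every gene's regulation function, tests the linear and quadratic trends,
controls the FDR across genes (Benjamini-Hochberg), and labels called genes
with one of four spatial patterns:

* ``core`` — expression highest at r = 0, decreasing outward;
* ``periphery`` — highest at r = 1;
* ``intermediate`` — interior maximum (downward parabola);
* ``extrema`` — interior minimum, expressed at both ends;
* ``other`` — significant but the interior feature is too shallow to trust;
* ``flat`` — not called spatial.

Genes are called spatial when q < fdr_max AND regulation magnitude >
mag_min, among genes whose model fit is adequate (per-cell log likelihood
above a threshold, so the cutoff transfers across dataset sizes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import CellProfile, CountMatrix, SpheromapError
from .model import (
    GeneRegulationModel,
    GeneRegulationResults,
    RegulationFunction,
    RegulationPriors,
    test_spatial,
)

PATTERNS = ("core", "periphery", "intermediate", "extrema", "other", "flat")

RESULT_COLUMNS = [
    "gene_id", "a", "b", "c", "theta",
    "se_a", "se_b", "se_c", "se_log_theta",
    "loglik", "converged", "retained",
    "p_b", "p_c", "p_gene", "q", "magnitude", "spatial", "pattern",
]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values.

    q_(i) = min_{j>=i} p_(j)*m/j, capped at 1; order-preserving and >= p
    elementwise.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise SpheromapError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_pattern(
    f: RegulationFunction,
    b_significant: bool,
    c_significant: bool,
    boundary_margin: float = 0.1,
    interior_contrast: float = 0.1,
) -> str:
    """Assign a spatial pattern label to a called gene's fitted function.

    The interior vertex r* = -b/(2c) drives the parabolic labels only when
    the quadratic trend is significant, r* sits at least ``boundary_margin``
    inside [0, 1] (ties go to the monotone branch), and the vertex-boundary
    contrast |f(r*) - nearer boundary value| / max f reaches
    ``interior_contrast``; otherwise the monotone direction over [0, 1]
    decides between core and periphery.
    """
    delta, tau = boundary_margin, interior_contrast
    f0, f1 = f(0.0), f(1.0)
    r_star = f.vertex()
    monotone = "periphery" if f1 > f0 else "core"
    if not c_significant or r_star is None:
        return monotone
    if not (delta < r_star < 1.0 - delta):  # on-margin ties -> monotone branch
        return monotone
    f_star = f(r_star)
    _, f_max = f.extrema()
    closer_boundary = f0 if r_star <= 0.5 else f1
    contrast = abs(f_star - closer_boundary) / f_max
    if contrast < tau:
        return "other"
    return "intermediate" if f.c < 0 else "extrema"


@dataclass
class SpatialCallConfig:
    """Thresholds for genome-wide spatial calling.

    fdr_max : BH q-value cutoff (default 0.10, i.e. fdr < 10%).
    mag_min : minimal regulation magnitude 1 - min f/max f (default 0.30).
    loglik_per_cell : per-cell log-likelihood floor for retaining a gene's
        fit (default -4.91/cell; applied as threshold * n_cells).
    boundary_margin, interior_contrast : pattern-classification knobs.
    """

    fdr_max: float = 0.10
    mag_min: float = 0.30
    loglik_per_cell: float = -4.91
    boundary_margin: float = 0.1
    interior_contrast: float = 0.1
    alpha_sig: float = 0.05  # per-trend significance used only for labelling
    gene_test: str = "wald_joint"  # or "bonferroni" (marginal-Wald combination)


class SpatialScreen:
    """Genome-wide screen for spatially regulated genes.

    Parameters
    ----------
    matrix : CountMatrix
        Gene-filtered genes x cells UMI counts.
    cells : sequence of CellProfile
        Positioned cells matching the matrix columns.
    config : SpatialCallConfig, optional

    ``fit()`` returns a :class:`SpatialScreenResults` whose ``table`` holds,
    per gene: MAP estimates, Laplace SEs, log likelihood, Wald p-values,
    BH q, regulation magnitude and the pattern label.
    """

    def __init__(self, matrix: CountMatrix, cells: Sequence[CellProfile],
                 config: SpatialCallConfig | None = None):
        if [c.cell_id for c in cells] != list(matrix.cell_ids):
            raise SpheromapError("matrix columns do not match cell profiles")
        self.matrix = matrix
        self.cells = list(cells)
        self.config = config or SpatialCallConfig()
        self.radial = np.array([c.radial_position for c in cells])
        self.depth = np.array([c.depth for c in cells], dtype=float)

    def fit(self, verbose: bool = False) -> "SpatialScreenResults":
        cfg = self.config
        rows = []
        fits: dict[str, GeneRegulationResults] = {}
        rn = (self.radial, self.depth)
        for i, gene in enumerate(self.matrix.gene_ids):
            res = GeneRegulationModel(
                self.matrix.counts[i], rn, gene_id=gene
            ).fit()
            fits[gene] = res
            row = {
                "gene_id": gene,
                "a": res.params.a, "b": res.params.b, "c": res.params.c,
                "theta": res.theta,
                "se_a": res.se_a, "se_b": res.se_b, "se_c": res.se_c,
                "se_log_theta": res.se_log_theta,
                "loglik": res.llf, "converged": res.converged,
            }
            ok = res.converged and res.has_se
            row["retained"] = bool(
                ok
                and np.isfinite(res.llf)
                and res.llf >= cfg.loglik_per_cell * res.n_cells_used
            )
            if ok:
                p_b, p_c, p_gene = test_spatial(res, method=cfg.gene_test)
                row.update(p_b=p_b, p_c=p_c, p_gene=p_gene)
                row["magnitude"] = res.magnitude
            else:
                row.update(p_b=np.nan, p_c=np.nan, p_gene=np.nan,
                           magnitude=np.nan)
            rows.append(row)
        table = pd.DataFrame(rows)

        retained = table["retained"].to_numpy()
        if not retained.any():
            raise SpheromapError(
                "no gene passed the model-fit retention threshold "
                f"(loglik_per_cell={cfg.loglik_per_cell}); "
                f"{int((~table['converged']).sum())} of {len(table)} fits "
                "did not converge"
            )
        q = np.full(len(table), np.nan)
        q[retained] = bh_fdr(table.loc[retained, "p_gene"].to_numpy())
        table["q"] = q
        table["spatial"] = (
            retained & (table["q"] < cfg.fdr_max) & (table["magnitude"] > cfg.mag_min)
        )

        patterns = []
        for _, row in table.iterrows():
            if not row["spatial"]:
                patterns.append("flat")
                continue
            fn = RegulationFunction(row["a"], row["b"], row["c"])
            patterns.append(
                classify_pattern(
                    fn,
                    b_significant=row["p_b"] < cfg.alpha_sig,
                    c_significant=row["p_c"] < cfg.alpha_sig,
                    boundary_margin=cfg.boundary_margin,
                    interior_contrast=cfg.interior_contrast,
                )
            )
        table["pattern"] = patterns
        table = table[RESULT_COLUMNS]
        return SpatialScreenResults(self, table, fits)


@dataclass
class SpatialScreenResults:
    """Per-gene spatial calls plus access to the underlying fits."""

    screen: SpatialScreen
    table: pd.DataFrame
    fits: dict[str, GeneRegulationResults] = field(repr=False, default_factory=dict)

    @property
    def n_spatial(self) -> int:
        return int(self.table["spatial"].sum())

    def pattern_counts(self) -> dict[str, int]:
        counts = self.table.loc[self.table["spatial"], "pattern"].value_counts()
        return {p: int(counts.get(p, 0)) for p in PATTERNS if p != "flat"}

    def summary(self) -> str:
        n = len(self.table)
        n_ret = int(self.table["retained"].sum())
        pat = self.pattern_counts()
        lines = [
            "Spatial gene screen",
            "=" * 42,
            f"{'genes tested':<30}{n:>12}",
            f"{'fits retained':<30}{n_ret:>12}",
            f"{'spatial genes called':<30}{self.n_spatial:>12}",
            "-" * 42,
        ]
        lines += [f"{'pattern ' + p:<30}{k:>12}" for p, k in pat.items()]
        lines.append("=" * 42)
        return "\n".join(lines)


def call_spatial_genes(
    matrix: CountMatrix,
    cells: Sequence[CellProfile],
    config: SpatialCallConfig | None = None,
) -> pd.DataFrame:
    """Fit all genes and return the per-gene spatial-call table."""
    return SpatialScreen(matrix, cells, config).fit().table


# ---------------------------------------------------------------------------
# Downsampling
# ---------------------------------------------------------------------------


def downsample_counts(matrix: CountMatrix, p: float, seed=None) -> CountMatrix:
    """Binomially thin every UMI count: n' ~ Binomial(n, p), independently.

    Emulates sequencing at a fraction p of the original depth.
    """
    if not 0.0 <= p <= 1.0:
        raise SpheromapError(f"thinning probability {p} outside [0, 1]")
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(matrix.counts, p)
    return CountMatrix(list(matrix.gene_ids), list(matrix.cell_ids), thinned)


def downsampling_curve(
    matrix: CountMatrix,
    cells: Sequence[CellProfile],
    ps: Sequence[float],
    config: SpatialCallConfig | None = None,
    seed=None,
    min_mean_umis: float = 1.0,
) -> pd.DataFrame:
    """Number of spatial genes as a function of sequencing depth.

    For each retention probability p, thins the counts, re-derives the cell
    depths, re-applies the expressed-gene filter (mean >= min_mean_umis UMIs
    per cell) and reruns the full spatial calling. Returns a table with
    columns (p, n_genes_tested, n_spatial_genes).
    """
    from .io import filter_expressed_genes

    rng = np.random.default_rng(seed)
    rows = []
    for p in ps:
        thinned = downsample_counts(
            matrix, p, seed=rng.integers(0, 2**31 - 1)
        )
        depths = thinned.depths()
        keep = depths >= 1
        thinned = thinned.subset_cells(keep)
        kept_cells = [
            CellProfile(c.cell_id, c.radial_position, int(d))
            for c, d, k in zip(cells, depths, keep) if k
        ]
        expressed = filter_expressed_genes(thinned, min_mean_umis)
        if expressed.n_genes == 0 or len(kept_cells) < 10:
            rows.append({"p": p, "n_genes_tested": 0, "n_spatial_genes": 0})
            continue
        try:
            table = call_spatial_genes(expressed, kept_cells, config)
            n_spatial = int(table["spatial"].sum())
            n_tested = len(table)
        except SpheromapError:
            n_spatial, n_tested = 0, expressed.n_genes
        rows.append(
            {"p": p, "n_genes_tested": n_tested, "n_spatial_genes": n_spatial}
        )
    return pd.DataFrame(rows)
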
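"""Non-parametric pathway-level spatial association.

Summing the UMIs of a pathway's member genes within each cell and dividing
by the cell's total UMIs gives the pathway's fractional abundance per cell.
Aggregation across genes suppresses single-gene expression noise (law of
large numbers), so pathway fractions can be tested against radial position
directly — without a parametric regulation function — using Chatterjee's Xi
correlation, a rank statistic sensitive to arbitrary (including
non-monotone) functional dependence. BH FDR controls multiplicity across
pathways, and each pathway's positional tendency is summarized by avgR, its
abundance-weighted average radial position over 10 spatial bins.

The module also carries the confound check: a per-gene NB regression of
counts on radial position with and without per-cell cell-cycle / stress
signature scores as covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .calling import bh_fdr
from .io import CellProfile, CountMatrix, GeneSetCollection, SpheromapError

__all__ = [
    "pathway_fraction_per_cell",
    "filter_genesets",
    "xi_correlation",
    "avg_radial_position",
    "pathway_spatial_scan",
    "PathwayScan",
    "regress_confounds",
]


def pathway_fraction_per_cell(matrix: CountMatrix, geneset: Sequence[str],
                              set_name: str = "<set>") -> np.ndarray:
    """Fraction of each cell's transcriptome from a gene set's members.

    Per cell: sum of the member genes' UMIs divided by the cell's total
    UMIs (all genes in the matrix).
    """
    members = [g for g in geneset if g in set(matrix.gene_ids)]
    if not members:
        raise SpheromapError(
            f"gene set {set_name!r} has no genes in the count matrix"
        )
    idx = [matrix.gene_index(g) for g in members]
    depths = matrix.depths().astype(float)
    if (depths == 0).any():
        raise SpheromapError("cells with zero total UMIs; QC-filter first")
    return matrix.counts[idx].sum(axis=0) / depths


def filter_genesets(
    collection: GeneSetCollection, matrix: CountMatrix, min_genes: int = 5
) -> GeneSetCollection:
    """Keep sets with at least ``min_genes`` members in the gene universe."""
    universe = set(matrix.gene_ids)
    kept = {
        name: genes
        for name, genes in collection
        if sum(g in universe for g in genes) >= min_genes
    }
    return GeneSetCollection(
        sets=kept,
        descriptions={k: collection.descriptions.get(k, "") for k in kept},
    )


# ---------------------------------------------------------------------------
# Chatterjee's Xi
# ---------------------------------------------------------------------------


def _xi_statistic(x: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> float:
    """Tie-aware Chatterjee Xi of y against x (random x-tie-break)."""
    n = x.size
    # sort by x, breaking x-ties at random so the statistic is well defined
    order = np.lexsort((rng.random(n), x))
    y_sorted = y[order]
    # r_i = #{j : y_j <= y_i}, l_i = #{j : y_j >= y_i}, both in x-order
    sorter = np.argsort(y_sorted, kind="mergesort")
    y_asc = y_sorted[sorter]
    r = np.searchsorted(y_asc, y_sorted, side="right")
    l = n - np.searchsorted(y_asc, y_sorted, side="left")
    denom = 2.0 * np.sum(l * (n - l))
    if denom == 0:  # constant y
        return 0.0
    return 1.0 - n * np.abs(np.diff(r)).sum() / denom


def xi_correlation(
    x,
    y,
    method: str = "auto",
    n_permutations: int = 1000,
    seed=None,
) -> tuple[float, float]:
    """Chatterjee's Xi correlation of y against x, with a p-value.

    Xi estimates how well y is a measurable function of x: ~0 under
    independence, -> 1 for noiseless functional dependence (monotone or
    not). Being rank-based, it is invariant to strictly increasing
    transforms of x and of y. Ties are handled by the tie-aware estimator
    with seeded random tie-breaking on x.

    The one-sided p-value (large Xi = dependence) uses the asymptotic null
    sqrt(n)*xi -> Normal(0, 2/5) when ``method="asymptotic"``, a seeded
    permutation null when ``method="permutation"``, and with ``"auto"``
    picks asymptotics for n >= 100 with < 10% tied y values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise SpheromapError("x and y must be equal-length 1-d vectors")
    n = x.size
    if n < 3:
        raise SpheromapError("need at least 3 observations")
    rng = np.random.default_rng(seed)
    if np.unique(y).size == 1:
        return 0.0, 1.0  # constant y: no dependence to detect
    xi = _xi_statistic(x, y, rng)
    if method == "auto":
        tie_frac = 1.0 - np.unique(y).size / n
        method = "asymptotic" if (n >= 100 and tie_frac < 0.10) else "permutation"
    if method == "asymptotic":
        p = float(norm.sf(xi * np.sqrt(n * 5.0 / 2.0)))
    elif method == "permutation":
        perm_stats = np.array([
            _xi_statistic(x, rng.permutation(y), rng)
            for _ in range(n_permutations)
        ])
        p = float((1 + (perm_stats >= xi).sum()) / (1 + n_permutations))
    else:
        raise SpheromapError(f"unknown method {method!r}")
    return float(xi), p


def avg_radial_position(
    fraction, r, n_bins: int = 10
) -> float:
    """Abundance-weighted average radial position of a pathway (avgR).

    Cells are binned into ``n_bins`` equal-width, right-closed bins on
    [0, 1]; within each non-empty bin the mean radial position and mean
    pathway fraction are taken, and avgR is the fraction-weighted mean of
    the bin positions: values near 0 place the pathway in the core, near 1
    at the periphery.
    """
    fraction = np.asarray(fraction, dtype=float)
    r = np.asarray(r, dtype=float)
    if n_bins < 2:
        raise SpheromapError("need n_bins >= 2")
    if fraction.shape != r.shape:
        raise SpheromapError("fraction and r must align")
    if not np.any(fraction > 0):
        raise SpheromapError("all pathway fractions are zero; avgR undefined")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # right-closed bins; r = 0 joins the first bin
    idx = np.clip(np.searchsorted(edges, r, side="left") - 1, 0, n_bins - 1)
    r_bar, f_bar = [], []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        r_bar.append(r[mask].mean())
        f_bar.append(fraction[mask].mean())
    r_bar, f_bar = np.array(r_bar), np.array(f_bar)
    return float((r_bar * f_bar).sum() / f_bar.sum())


# ---------------------------------------------------------------------------
# Pathway scan
# ---------------------------------------------------------------------------


@dataclass
class PathwayScanConfig:
    min_genes: int = 5
    fdr_max: float = 0.10
    n_bins: int = 10
    xi_method: str = "auto"
    n_permutations: int = 1000


class PathwayScan:
    """Scan a gene-set collection for spatial association.

    ``fit()`` returns a results object whose ``table`` has one row per
    tested set: n_genes_present, xi, p, BH q, significance at
    ``fdr_max``, and avgR.
    """

    def __init__(
        self,
        matrix: CountMatrix,
        cells: Sequence[CellProfile],
        collection: GeneSetCollection,
        config: PathwayScanConfig | None = None,
        seed=None,
    ):
        if [c.cell_id for c in cells] != list(matrix.cell_ids):
            raise SpheromapError("matrix columns do not match cell profiles")
        self.matrix = matrix
        self.cells = list(cells)
        self.collection = collection
        self.config = config or PathwayScanConfig()
        self.seed = seed
        self.radial = np.array([c.radial_position for c in cells])

    def fit(self) -> "PathwayScanResults":
        cfg = self.config
        tested = filter_genesets(self.collection, self.matrix, cfg.min_genes)
        if len(tested) == 0:
            raise SpheromapError(
                f"no gene set has >= {cfg.min_genes} genes in the matrix"
            )
        universe = set(self.matrix.gene_ids)
        root = np.random.default_rng(self.seed)
        rows = []
        for name, genes in tested:
            frac = pathway_fraction_per_cell(self.matrix, genes, set_name=name)
            xi, p = xi_correlation(
                self.radial, frac, method=cfg.xi_method,
                n_permutations=cfg.n_permutations,
                seed=root.integers(0, 2**31 - 1),
            )
            rows.append(
                {
                    "set_name": name,
                    "n_genes_present": sum(g in universe for g in genes),
                    "xi": xi,
                    "p": p,
                    "avgR": avg_radial_position(frac, self.radial, cfg.n_bins),
                }
            )
        table = pd.DataFrame(rows)
        table["q"] = bh_fdr(table["p"].to_numpy())
        table["significant"] = table["q"] < cfg.fdr_max
        table = table[
            ["set_name", "n_genes_present", "xi", "p", "q", "significant", "avgR"]
        ]
        return PathwayScanResults(self, table)


@dataclass
class PathwayScanResults:
    scan: PathwayScan
    table: pd.DataFrame

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def summary(self) -> str:
        return (
            f"Pathway spatial scan: {len(self.table)} sets tested, "
            f"{self.n_significant} significant at "
            f"fdr < {self.scan.config.fdr_max:g}"
        )


def pathway_spatial_scan(
    matrix: CountMatrix,
    cells: Sequence[CellProfile],
    collection: GeneSetCollection,
    min_genes: int = 5,
    fdr_max: float = 0.10,
    n_bins: int = 10,
    seed=None,
) -> pd.DataFrame:
    """One-call pathway scan returning the results table."""
    cfg = PathwayScanConfig(min_genes=min_genes, fdr_max=fdr_max, n_bins=n_bins)
    return PathwayScan(matrix, cells, collection, cfg, seed=seed).fit().table


# ---------------------------------------------------------------------------
# Confound regression
# ---------------------------------------------------------------------------


def _signature_score(matrix: CountMatrix, genes: Sequence[str], name: str,
                     depths: np.ndarray) -> np.ndarray:
    """Log fractional abundance of a signature, against the cells' recorded
    total UMIs (not the matrix subset's column sums, which would couple the
    score to whichever genes happen to be in the matrix)."""
    members = [g for g in genes if g in set(matrix.gene_ids)]
    if not members:
        raise SpheromapError(f"signature {name!r} has no genes in the matrix")
    idx = [matrix.gene_index(g) for g in members]
    frac = matrix.counts[idx].sum(axis=0) / depths
    return np.log(frac + 1e-6)  # pseudocount guards all-zero cells


def regress_confounds(
    matrix: CountMatrix,
    cells: Sequence[CellProfile],
    cellcycle_genes: Sequence[str] | None = None,
    stress_genes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-gene NB regression of counts on radial position, with and
    without intrinsic-state covariates.

    Fits, for every gene, a negative-binomial GLM with log link and
    log-depth offset on (1, r) [raw] and on (1, r, cell-cycle score,
    stress score) [adjusted], where the scores are log pathway fractions of
    user-supplied signature gene lists. Returns the per-gene table of both
    space coefficients and the Pearson correlation between them across
    genes — near 1 means spatial calls are not driven by intrinsic cell
    state gradients.
    """
    import warnings as _warnings

    r = np.array([c.radial_position for c in cells])
    depths = np.array([c.depth for c in cells], dtype=float)
    offset = np.log(depths)

    covars, labels = [], []
    for genes, label in ((cellcycle_genes, "cc_score"), (stress_genes, "stress_score")):
        if genes:
            score = _signature_score(matrix, genes, label, depths)
            if np.unique(score).size == 1:
                _warnings.warn(
                    f"{label} is constant across cells; dropped", stacklevel=2
                )
                continue
            covars.append(score)
            labels.append(label)
    if not covars:
        _warnings.warn(
            "no usable signature genes: adjusted coefficients equal raw",
            stacklevel=2,
        )

    x_raw = sm.add_constant(r[:, None])
    x_adj = (
        sm.add_constant(np.column_stack([r] + covars)) if covars else x_raw
    )

    rows = []
    for i, gene in enumerate(matrix.gene_ids):
        n = matrix.counts[i].astype(float)
        mu0 = max(n.sum() / depths.sum(), 1e-12) * depths
        denom = max(float(((n - mu0) ** 2 - mu0).sum()), 1e-12)
        alpha = float(np.clip(denom / (mu0**2).sum(), 1e-4, 100.0))
        coef_raw = _nb_space_coef(n, x_raw, offset, alpha)
        coef_adj = (
            coef_raw if x_adj is x_raw
            else _nb_space_coef(n, x_adj, offset, alpha)
        )
        rows.append(
            {"gene_id": gene, "space_coef_raw": coef_raw,
             "space_coef_adjusted": coef_adj}
        )
    table = pd.DataFrame(rows)
    ok = np.isfinite(table["space_coef_raw"]) & np.isfinite(
        table["space_coef_adjusted"]
    )
    if ok.sum() >= 3 and table.loc[ok, "space_coef_raw"].std() > 0:
        corr = float(
            np.corrcoef(
                table.loc[ok, "space_coef_raw"],
                table.loc[ok, "space_coef_adjusted"],
            )[0, 1]
        )
    else:
        corr = np.nan
    return table, corr


def _nb_space_coef(n, exog, offset, alpha) -> float:
    import warnings as _warnings

    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            res = sm.GLM(
                n, exog, family=sm.families.NegativeBinomial(alpha=alpha),
                offset=offset,
            ).fit(maxiter=200)
        return float(res.params[1])  # coefficient on radial position
    except Exception:  # noqa: BLE001 - non-convergent gene, not fatal
        return np.nan
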
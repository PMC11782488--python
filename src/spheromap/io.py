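"""Data containers and file I/O for spheroid single-cell spatial transcriptomics.

The data model is small and explicit:

* :class:`CountMatrix` — a genes x cells UMI count matrix with string ids.
* :class:`CellProfile` / cell tables — per-cell dye intensities, radial
  position on the core-periphery axis, and sequencing depth (total UMIs).
* :class:`GeneSetCollection` — named gene sets parsed from GMT files.

Radial positioning follows the dye-diffusion logic: a membrane-permeant dye
(Calcein-AM) added to the growth medium penetrates spheroids only partially,
so measured fluorescence encodes depth from the surface. Scaling the log
intensity to [0, 1] yields a radial coordinate r with 0 = core, 1 = periphery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class SpheromapError(ValueError):
    """Raised on invalid inputs or infeasible requests."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class CellProfile:
    """One sorted cell: identity, dye intensities, position and depth.

    Parameters
    ----------
    cell_id : str
        Unique cell identifier.
    radial_position : float
        Position on the core-periphery axis, in [0, 1] (0 = core).
    depth : int
        Total UMIs sequenced in the cell (>= 1).
    calcein_intensity, vybrant_intensity : float, optional
        Raw dye fluorescence (arbitrary units, > 0 when present).
    """

    cell_id: str
    radial_position: float
    depth: int
    calcein_intensity: float | None = None
    vybrant_intensity: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.radial_position <= 1.0):
            raise SpheromapError(
                f"cell {self.cell_id}: radial position {self.radial_position} "
                "outside [0, 1]"
            )
        if self.depth < 1:
            raise SpheromapError(f"cell {self.cell_id}: depth {self.depth} < 1")
        for name in ("calcein_intensity", "vybrant_intensity"):
            val = getattr(self, name)
            if val is not None and val <= 0:
                raise SpheromapError(f"cell {self.cell_id}: {name} {val} <= 0")


def cells_to_frame(cells: Sequence[CellProfile]) -> pd.DataFrame:
    """Tabulate cell profiles (one row per cell, indexed by cell_id)."""
    ids = [c.cell_id for c in cells]
    if len(set(ids)) != len(ids):
        raise SpheromapError("duplicate cell ids")
    return pd.DataFrame(
        {
            "cell_id": ids,
            "radial_position": [c.radial_position for c in cells],
            "total_umis": [c.depth for c in cells],
            "calcein_intensity": [c.calcein_intensity for c in cells],
        }
    ).set_index("cell_id", drop=False)


def frame_to_cells(frame: pd.DataFrame) -> list[CellProfile]:
    """Inverse of :func:`cells_to_frame`."""
    out = []
    for _, row in frame.iterrows():
        cal = row.get("calcein_intensity")
        out.append(
            CellProfile(
                cell_id=str(row["cell_id"]),
                radial_position=float(row["radial_position"]),
                depth=int(row["total_umis"]),
                calcein_intensity=None if cal is None or pd.isna(cal) else float(cal),
            )
        )
    return out


@dataclass
class CountMatrix:
    """Genes x cells UMI count matrix with string identifiers.

    Counts are stored dense (int64); datasets at the scale this package
    targets (thousands of genes x thousands of cells) fit comfortably.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise SpheromapError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise SpheromapError("counts must be integral")
            self.counts = np.round(self.counts).astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise SpheromapError("counts must be non-negative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise SpheromapError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise SpheromapError("duplicate cell ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def depths(self) -> np.ndarray:
        """Per-cell total UMIs (column sums)."""
        return self.counts.sum(axis=0)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise SpheromapError(f"gene {gene_id!r} not in matrix") from None

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            [self.gene_ids[i] for i in keep], list(self.cell_ids), self.counts[keep]
        )

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            list(self.gene_ids), [self.cell_ids[i] for i in keep], self.counts[:, keep]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class GeneSetCollection:
    """Ordered mapping of gene-set name -> member gene ids (+ descriptions)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise SpheromapError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


# ---------------------------------------------------------------------------
# Radial positioning
# ---------------------------------------------------------------------------


def compute_radial_position(
    intensities,
    clip_quantiles: tuple[float, float] = (0.0, 0.0),
    cell_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Scale log dye intensities to radial positions in [0, 1].

    r = (log I - lo) / (hi - lo), clipped to [0, 1], where lo and hi are
    the ``clip_quantiles`` of the log intensities (defaults (0, 0): plain
    min-max). Core maps near 0, periphery near 1. The result is invariant
    to multiplying all intensities by a positive constant.

    Parameters
    ----------
    intensities : array-like of float
        Positive dye intensities, one per cell.
    clip_quantiles : (float, float)
        Lower and upper tail fractions in [0, 0.5) to clip for outlier
        robustness, e.g. (0.01, 0.01) uses the 1st and 99th percentiles.
    cell_ids : sequence of str, optional
        Used only in error messages.
    """
    x = np.asarray(intensities, dtype=float)
    lo_q, hi_q = clip_quantiles
    if not (0 <= lo_q < 0.5 and 0 <= hi_q < 0.5):
        raise SpheromapError("clip quantiles must lie in [0, 0.5)")
    bad = np.flatnonzero(~(x > 0))
    if bad.size:
        name = cell_ids[bad[0]] if cell_ids is not None else f"index {bad[0]}"
        raise SpheromapError(
            f"non-positive intensity {x[bad[0]]} for cell {name}; "
            "log scaling requires positive intensities"
        )
    logx = np.log(x)
    lo = np.quantile(logx, lo_q)
    hi = np.quantile(logx, 1.0 - hi_q)
    if hi <= lo:
        raise SpheromapError(
            "constant intensities: no core-periphery axis can be defined"
        )
    return np.clip((logx - lo) / (hi - lo), 0.0, 1.0)


# ---------------------------------------------------------------------------
# QC and gene filtering
# ---------------------------------------------------------------------------


def qc_filter_cells(
    cells: Sequence[CellProfile],
    matrix: CountMatrix,
    min_depth: int = 10_000,
    min_genes_detected: int = 2_000,
) -> tuple[list[CellProfile], CountMatrix, dict]:
    """Drop cells with too few UMIs or too few detected genes.

    Returns the retained cells, the column-subset matrix, and a report
    dict with retained/dropped counts.
    """
    if [c.cell_id for c in cells] != list(matrix.cell_ids):
        raise SpheromapError("matrix columns do not match cell profiles")
    depth = np.array([c.depth for c in cells])
    n_detected = (matrix.counts > 0).sum(axis=0)
    keep = (depth >= min_depth) & (n_detected >= min_genes_detected)
    if not keep.any():
        raise SpheromapError(
            f"QC removed all {len(cells)} cells "
            f"(min_depth={min_depth}, min_genes_detected={min_genes_detected})"
        )
    report = {
        "n_input": len(cells),
        "n_retained": int(keep.sum()),
        "n_dropped": int((~keep).sum()),
    }
    kept_cells = [c for c, k in zip(cells, keep) if k]
    return kept_cells, matrix.subset_cells(keep), report


def filter_expressed_genes(
    matrix: CountMatrix, min_mean_umis: float = 1.0
) -> CountMatrix:
    """Keep genes with at least ``min_mean_umis`` UMIs per cell on average.

    This defines the analysis gene universe: with n UMIs sequenced per
    cell, only genes of fractional abundance above ~1/n are quantifiable
    in single cells, so genes below one UMI per cell on average carry too
    little signal for per-gene spatial inference.
    """
    if matrix.n_genes == 0 or matrix.n_cells == 0:
        raise SpheromapError("empty count matrix")
    mean_umis = matrix.counts.sum(axis=1) / matrix.n_cells
    keep = mean_umis >= min_mean_umis
    if not keep.any():
        warnings.warn("no genes pass the expression filter", stacklevel=2)
    return matrix.subset_genes(keep)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def read_counts(
    path: str | Path,
    dialect: str = "mtx_triplet",
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> CountMatrix:
    """Read a genes x cells count matrix.

    ``mtx_triplet``: Matrix Market coordinate file (1-based triplets) with
    companion one-column ``genes.tsv`` / ``cells.tsv`` id files (defaulting
    to those names next to the .mtx). ``dense_tsv``: gene rows, cell
    columns, header row of cell ids, first column gene ids.
    """
    path = Path(path)
    if dialect == "mtx_triplet":
        genes_path = Path(genes_path) if genes_path else path.with_name("genes.tsv")
        cells_path = Path(cells_path) if cells_path else path.with_name("cells.tsv")
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # noqa: BLE001 - surface parser context
            raise SpheromapError(f"failed to parse {path}: {exc}") from exc
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        gene_ids = _read_id_column(genes_path)
        cell_ids = _read_id_column(cells_path)
        if dense.shape != (len(gene_ids), len(cell_ids)):
            raise SpheromapError(
                f"{path}: matrix is {dense.shape} but id files give "
                f"{len(gene_ids)} genes x {len(cell_ids)} cells"
            )
        return CountMatrix(gene_ids, cell_ids, dense)
    if dialect == "dense_tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        vals = frame.to_numpy()
        if not np.allclose(vals, np.round(vals)) or (vals < 0).any():
            bad = np.argwhere((vals < 0) | ~np.isclose(vals, np.round(vals)))[0]
            raise SpheromapError(
                f"{path}: non-integer or negative count at data line {bad[0] + 2}"
            )
        return CountMatrix(
            [str(g) for g in frame.index], [str(c) for c in frame.columns], vals
        )
    raise SpheromapError(f"unknown counts dialect {dialect!r}")


def _read_id_column(path: Path) -> list[str]:
    ids = [
        line.split("\t")[0].strip()
        for line in path.read_text().splitlines()
        if line.strip()
    ]
    if not ids:
        raise SpheromapError(f"{path}: no identifiers found")
    return ids


def write_counts(
    matrix: CountMatrix, path: str | Path, dialect: str = "mtx_triplet"
) -> None:
    """Write a count matrix (inverse of :func:`read_counts`)."""
    path = Path(path)
    if dialect == "mtx_triplet":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(matrix.counts))
        path.with_name("genes.tsv").write_text("\n".join(matrix.gene_ids) + "\n")
        path.with_name("cells.tsv").write_text("\n".join(matrix.cell_ids) + "\n")
    elif dialect == "dense_tsv":
        matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id")
    else:
        raise SpheromapError(f"unknown counts dialect {dialect!r}")


def read_cell_metadata(
    path: str | Path, clip_quantiles: tuple[float, float] = (0.0, 0.0)
) -> list[CellProfile]:
    """Read a cell-metadata TSV into cell profiles.

    Required columns: ``cell_id``, ``total_umis``, and either
    ``radial_position`` (used verbatim) or ``calcein_intensity`` (converted
    via :func:`compute_radial_position`).
    """
    frame = pd.read_csv(path, sep="\t")
    for col in ("cell_id", "total_umis"):
        if col not in frame.columns:
            raise SpheromapError(f"{path}: missing required column {col!r}")
    if "radial_position" not in frame.columns:
        if "calcein_intensity" not in frame.columns:
            raise SpheromapError(
                f"{path}: need either radial_position or calcein_intensity"
            )
        frame["radial_position"] = compute_radial_position(
            frame["calcein_intensity"].to_numpy(),
            clip_quantiles,
            cell_ids=frame["cell_id"].tolist(),
        )
    return frame_to_cells(frame)


def write_cell_metadata(cells: Sequence[CellProfile], path: str | Path) -> None:
    cells_to_frame(cells).to_csv(path, sep="\t", index=False)


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with header (no index)."""
    frame.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT gene-set file: name TAB description TAB gene [TAB gene ...].

    Duplicate genes within a set are dropped (order preserved); a line with
    fewer than three fields is rejected with its line number.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise SpheromapError(
                f"{path}:{lineno}: expected >= 3 tab-separated fields, "
                f"got {len(fields)}"
            )
        name, desc, *genes = fields
        if name in sets:
            raise SpheromapError(f"{path}:{lineno}: duplicate set name {name!r}")
        seen: dict[str, None] = {}
        for g in genes:
            if g:
                seen.setdefault(g, None)
        if not seen:
            raise SpheromapError(f"{path}:{lineno}: set {name!r} has no genes")
        sets[name] = list(seen)
        descriptions[name] = desc
    if not sets:
        warnings.warn(f"{path}: empty gene set collection", stacklevel=2)
        return GeneSetCollection(sets={}, descriptions={})
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, collection.descriptions.get(name, "")] + genes)
        for name, genes in collection
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
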
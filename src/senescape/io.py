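"""Readers, writers and validated in-memory containers.

All spatial coordinates are micrometres with the origin at the ROI
top-left corner and y increasing downward (raster convention), so that
continuous centroids and label-mask pixels share one frame.

Gene symbols are matched case-sensitively after whitespace trimming;
gene-set symbols absent from a matrix are counted and logged, never an
error, because curated senescence sets routinely contain symbols missing
from any given expression matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("senescape")

VALID_REGIONS = {"EC", "MTG", "SSC", "other"}
VALID_DIAGNOSES = {"AD", "NDC"}


# ---------------------------------------------------------------------------
# Expression data
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """A genes x cells expression matrix with per-cell annotations.

    ``matrix`` holds raw counts or log-normalised values; ``normalised``
    records which.  ``cell_meta`` is indexed by cell id and must provide
    at least ``sample_id`` and ``diagnosis``.
    """

    matrix: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame
    normalised: bool = False

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if not sp.issparse(self.matrix):
            self.matrix = sp.csr_matrix(np.asarray(self.matrix, dtype=float))
        else:
            self.matrix = self.matrix.tocsr().astype(float)
        n_genes, n_cells = self.matrix.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene id count ({len(self.gene_ids)}) does not match matrix "
                f"rows ({n_genes})"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"cell id count ({len(self.cell_ids)}) does not match matrix "
                f"columns ({n_cells})"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell ids")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("expression matrix contains negative entries")
        for col in ("sample_id", "diagnosis"):
            if col not in self.cell_meta.columns:
                raise ValueError(f"cell_meta missing required column '{col}'")
        if not self.cell_meta.index.equals(pd.Index(self.cell_ids)):
            try:
                self.cell_meta = self.cell_meta.loc[self.cell_ids]
            except KeyError as exc:
                raise ValueError("cell_meta does not cover all cell ids") from exc
        if self.cell_meta["sample_id"].isna().any():
            raise ValueError("every cell needs a sample_id")
        if self.cell_meta["diagnosis"].isna().any():
            raise ValueError("every cell needs a diagnosis")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    def gene_indices(self, symbols) -> np.ndarray:
        """Indices of matched symbols; unmatched symbols are logged."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        cleaned = [str(s).strip() for s in symbols]
        idx = [lookup[s] for s in cleaned if s in lookup]
        n_missing = len(cleaned) - len(idx)
        if n_missing:
            logger.info("%d/%d gene-set symbols not in matrix", n_missing, len(cleaned))
        return np.asarray(idx, dtype=int)

    def dense(self) -> np.ndarray:
        return np.asarray(self.matrix.todense())


def normalize_log1p(dataset: ExpressionDataset, scale: float = 1e4) -> ExpressionDataset:
    """Library-size normalise each cell to ``scale`` counts, then log1p."""
    if dataset.normalised:
        return dataset
    mat = dataset.matrix.tocsc().astype(float)
    libsize = np.asarray(mat.sum(axis=0)).ravel()
    libsize[libsize == 0] = 1.0
    mat = mat.multiply(scale / libsize).tocsr()
    mat.data = np.log1p(mat.data)
    return ExpressionDataset(
        matrix=mat,
        gene_ids=dataset.gene_ids,
        cell_ids=dataset.cell_ids,
        cell_meta=dataset.cell_meta,
        normalised=True,
    )


def read_expression(matrix_path, genes_path, cells_path, meta_path) -> ExpressionDataset:
    """Read a MatrixMarket genes x cells matrix with TSV sidecars.

    ``genes_path``/``cells_path`` are single-column (first column used)
    TSVs without header; ``meta_path`` is CSV/TSV with a ``cell_id``
    column.
    """
    try:
        matrix = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # noqa: BLE001 - reraise with file context
        raise ValueError(f"malformed MatrixMarket file {matrix_path}: {exc}") from exc
    genes = pd.read_csv(genes_path, sep="\t", header=None).iloc[:, 0].astype(str).str.strip().to_numpy()
    cells = pd.read_csv(cells_path, sep="\t", header=None).iloc[:, 0].astype(str).str.strip().to_numpy()
    if matrix.shape[0] != len(genes):
        raise ValueError(
            f"gene sidecar has {len(genes)} entries but matrix has "
            f"{matrix.shape[0]} rows"
        )
    if matrix.shape[1] != len(cells):
        raise ValueError(
            f"cell sidecar has {len(cells)} entries but matrix has "
            f"{matrix.shape[1]} columns"
        )
    meta = _read_table(meta_path)
    if "cell_id" not in meta.columns:
        raise ValueError("cell metadata must have a 'cell_id' column")
    meta = meta.set_index("cell_id")
    normalised = bool(np.any(np.asarray(sp.coo_matrix(matrix).data) % 1 != 0))
    return ExpressionDataset(
        matrix=sp.csr_matrix(matrix),
        gene_ids=genes,
        cell_ids=cells,
        cell_meta=meta,
        normalised=normalised,
    )


def write_expression(dataset: ExpressionDataset, matrix_path, genes_path, cells_path, meta_path) -> None:
    scipy.io.mmwrite(str(matrix_path), dataset.matrix)
    pd.Series(dataset.gene_ids).to_csv(genes_path, sep="\t", header=False, index=False)
    pd.Series(dataset.cell_ids).to_csv(cells_path, sep="\t", header=False, index=False)
    dataset.cell_meta.rename_axis("cell_id").reset_index().to_csv(meta_path, index=False)


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene lists, e.g. the canonical senescence pathway (CSP)."""

    sets: dict[str, list[str]]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, symbols in self.sets.items():
            if not symbols:
                raise ValueError(f"gene set '{name}' is empty")
            if len(set(symbols)) != len(symbols):
                raise ValueError(f"gene set '{name}' has duplicate symbols")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_gmt(path, min_genes: int = 10) -> GeneSetCollection:
    """Parse a GMT file, dropping sets with fewer than ``min_genes`` genes.

    The default of 10 mirrors the curation rule that pathways with fewer
    than 10 genes are excluded before scoring.  Symbols are de-duplicated
    (order preserved) before the size filter is applied.
    """
    sets: dict[str, list[str]] = {}
    provenance: dict[str, str] = {}
    n_dropped = 0
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"GMT file {path} is empty")
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
        name, desc, *symbols = fields
        symbols = [s.strip() for s in symbols if s.strip()]
        symbols = list(dict.fromkeys(symbols))
        if len(symbols) < min_genes:
            n_dropped += 1
            continue
        sets[name] = symbols
        provenance[name] = desc
    if n_dropped:
        logger.info("read_gmt: dropped %d set(s) with < %d genes", n_dropped, min_genes)
    return GeneSetCollection(sets=sets, provenance=provenance)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, symbols in collection.items():
            desc = collection.provenance.get(name, "")
            fh.write("\t".join([name, desc, *symbols]) + "\n")


# ---------------------------------------------------------------------------
# Imaging single-cell tables
# ---------------------------------------------------------------------------

#: default required (non-channel) columns of an imaging cell table
IMAGING_BASE_COLUMNS = ["cell_id", "roi_id", "sample_id", "x_um", "y_um"]


@dataclass
class ImagingCellTable:
    """Segmented-cell records from imaging mass cytometry.

    ``table`` has one row per cell with centroid coordinates in um,
    one column per channel mean intensity (listed in ``channels``), and
    optional ``diagnosis``, ``region`` and ``cluster_label`` columns.
    """

    table: pd.DataFrame
    channels: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in IMAGING_BASE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"imaging cell table missing column(s): {missing}")
        missing_ch = [c for c in self.channels if c not in self.table.columns]
        if missing_ch:
            raise ValueError(f"imaging cell table missing channel column(s): {missing_ch}")
        for coord in ("x_um", "y_um"):
            vals = pd.to_numeric(self.table[coord], errors="coerce")
            bad = vals.isna()
            if bad.any():
                raise ValueError(
                    f"non-numeric {coord} at row index {int(np.flatnonzero(bad)[0])}"
                )
            self.table[coord] = vals.astype(float)
        for ch in self.channels:
            vals = pd.to_numeric(self.table[ch], errors="coerce")
            if vals.isna().any() or (vals < 0).any():
                raise ValueError(f"channel '{ch}' has missing or negative intensities")
            self.table[ch] = vals.astype(float)
        if self.table.duplicated(subset=["roi_id", "cell_id"]).any():
            raise ValueError("(roi_id, cell_id) pairs must be unique")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


def read_imaging_cells(path, schema_config: dict | None = None) -> ImagingCellTable:
    """Read a CSV/TSV cell table.

    ``schema_config`` may provide ``columns`` (mapping from our canonical
    names to file column names) and must provide ``channels`` (list of
    channel columns) unless every non-base column is a channel.
    """
    schema_config = schema_config or {}
    df = _read_table(path)
    rename = {v: k for k, v in schema_config.get("columns", {}).items()}
    df = df.rename(columns=rename)
    channels = schema_config.get("channels")
    if channels is None:
        reserved = set(IMAGING_BASE_COLUMNS) | {"diagnosis", "region", "cluster_label"}
        channels = [c for c in df.columns if c not in reserved]
    return ImagingCellTable(table=df, channels=list(channels))


def write_imaging_cells(cells: ImagingCellTable, path) -> None:
    cells.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Plaque objects
# ---------------------------------------------------------------------------

@dataclass
class PlaqueSet:
    """Amyloid-plaque objects per ROI: disks and/or label masks.

    ``disks`` has columns (roi_id, plaque_id, cx_um, cy_um, radius_um).
    ``masks`` maps roi_id -> (label image, um-per-pixel scale); labels
    are positive integers on a zero background.
    """

    disks: pd.DataFrame | None = None
    masks: dict | None = None

    def __post_init__(self) -> None:
        if self.disks is None and self.masks is None:
            self.disks = pd.DataFrame(
                columns=["roi_id", "plaque_id", "cx_um", "cy_um", "radius_um"]
            )
        if self.disks is not None and len(self.disks):
            if (self.disks["radius_um"] <= 0).any():
                raise ValueError("plaque radius must be > 0")
        if self.masks is not None:
            for roi, (mask, scale) in self.masks.items():
                mask = np.asarray(mask)
                if mask.min() < 0:
                    raise ValueError(f"mask for ROI {roi} has negative labels")
                if scale <= 0:
                    raise ValueError("um-per-pixel scale must be > 0")
                self.masks[roi] = (mask.astype(int), float(scale))

    def n_objects(self, roi_id) -> int:
        n = 0
        if self.disks is not None:
            n += int((self.disks["roi_id"] == roi_id).sum())
        if self.masks is not None and roi_id in self.masks:
            mask, _ = self.masks[roi_id]
            n += len(np.unique(mask[mask > 0]))
        return n

    def roi_ids(self) -> list:
        rois = []
        if self.disks is not None:
            rois.extend(self.disks["roi_id"].unique().tolist())
        if self.masks is not None:
            rois.extend(r for r in self.masks if r not in rois)
        return rois


def read_plaques(path, scale_um_per_px: float = 1.0, roi_id: str = "roi0") -> PlaqueSet:
    """Read plaques from a disk-parameter CSV or a label-mask TIFF.

    TIFF masks are attributed to a single ``roi_id``; CSVs carry their
    own ``roi_id`` column.
    """
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        import tifffile

        mask = tifffile.imread(path)
        return PlaqueSet(masks={roi_id: (np.asarray(mask), scale_um_per_px)})
    df = _read_table(path)
    required = ["roi_id", "plaque_id", "cx_um", "cy_um", "radius_um"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"plaque table missing column(s): {missing}")
    return PlaqueSet(disks=df)


def mask_to_disks(plaques: PlaqueSet) -> pd.DataFrame:
    """Equivalent-area disk per labelled mask object (centroid + radius)."""
    from skimage.measure import regionprops

    rows = []
    if plaques.masks:
        for roi, (mask, scale) in plaques.masks.items():
            for prop in regionprops(mask):
                cy, cx = prop.centroid
                radius = float(np.sqrt(prop.area / np.pi)) * scale
                rows.append(
                    {
                        "roi_id": roi,
                        "plaque_id": int(prop.label),
                        "cx_um": cx * scale,
                        "cy_um": cy * scale,
                        "radius_um": radius,
                    }
                )
    return pd.DataFrame(rows, columns=["roi_id", "plaque_id", "cx_um", "cy_um", "radius_um"])
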
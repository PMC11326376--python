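"""Reading and writing Visium-style spatial datasets.

A "section" is one tissue slice: a full-resolution RGB slide image, a table
of barcoded spot positions on that image, and a spot x gene count matrix in
MatrixMarket format with barcode/feature sidecar TSVs (the SpaceRanger
output layout).  This module loads that layout into the package's in-memory
model (:class:`SpatialDataset`) and can write it back losslessly.

Conventions
-----------
* Pixel coordinates are 0-based ``(row, col)`` = ``(y, x)``, matching numpy
  image indexing.  The positions-CSV columns ``pxl_row_in_fullres`` and
  ``pxl_col_in_fullres`` map directly onto them.
* Expression rows are always stored spot-major in :class:`SpotGrid` order;
  every downstream module relies on that single ordering contract.
* The feature-ID column (Ensembl-style) is the canonical gene key; gene
  symbols are carried as metadata only, because symbols are not unique.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import sparse
from scipy.io import mmread, mmwrite

logger = logging.getLogger("histex")

_LAYERS = ("counts", "normalized", "corrected", "predicted")

POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


class DataError(ValueError):
    """A dataset violates the layout or an invariant of the data model."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SlideImage:
    """A full-resolution RGB histology image.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8 array.
    microns_per_pixel
        Optional physical scale of the raster (um/px).
    """

    pixels: np.ndarray
    microns_per_pixel: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise DataError(
                f"slide image must be (H, W, 3) RGB, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise DataError("slide image must have positive height and width")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise DataError("pixel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.microns_per_pixel is not None and not self.microns_per_pixel > 0:
            raise DataError("microns_per_pixel must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class SpotGrid:
    """Barcoded capture spots and their coordinates on a slide.

    ``pixel_xy`` holds 0-based ``(row, col)`` pixel coordinates, one row per
    spot, aligned with ``spot_ids``; ``array_rc`` optionally carries the
    integer array-grid coordinates from the positions table.
    """

    spot_ids: list[str]
    pixel_xy: np.ndarray
    array_rc: np.ndarray | None = None
    in_tissue: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.spot_ids = [str(s) for s in self.spot_ids]
        if len(set(self.spot_ids)) != len(self.spot_ids):
            raise DataError("spot_ids must be unique")
        self.pixel_xy = np.asarray(self.pixel_xy, dtype=float)
        if self.pixel_xy.shape != (len(self.spot_ids), 2):
            raise DataError(
                f"pixel_xy must be ({len(self.spot_ids)}, 2), got {self.pixel_xy.shape}"
            )
        if not np.all(np.isfinite(self.pixel_xy)) or np.any(self.pixel_xy < 0):
            raise DataError("pixel coordinates must be finite and >= 0")
        if self.array_rc is not None:
            self.array_rc = np.asarray(self.array_rc, dtype=int)
            if self.array_rc.shape != (len(self.spot_ids), 2):
                raise DataError("array_rc shape mismatch with spot_ids")
        if self.in_tissue is None:
            self.in_tissue = np.ones(len(self.spot_ids), dtype=bool)
        else:
            self.in_tissue = np.asarray(self.in_tissue, dtype=bool)
            if self.in_tissue.shape != (len(self.spot_ids),):
                raise DataError("in_tissue shape mismatch with spot_ids")

    def __len__(self) -> int:
        return len(self.spot_ids)

    def subset(self, index: np.ndarray) -> "SpotGrid":
        """Return a new grid restricted (and reordered) to integer ``index``."""
        index = np.asarray(index)
        return SpotGrid(
            spot_ids=[self.spot_ids[i] for i in index],
            pixel_xy=self.pixel_xy[index],
            array_rc=None if self.array_rc is None else self.array_rc[index],
            in_tissue=self.in_tissue[index],
        )


@dataclass
class ExpressionMatrix:
    """A dense spots x genes matrix with row/column labels and a layer tag.

    ``layer`` records what the values are: raw ``"counts"``, total-count +
    log1p ``"normalized"``, batch-``"corrected"``, or model ``"predicted"``.
    The counts layer must be nonnegative and integer-valued.
    """

    values: np.ndarray
    spot_ids: list[str]
    gene_ids: list[str]
    layer: str = "counts"
    gene_symbols: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spot_ids = [str(s) for s in self.spot_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise DataError("expression values must be 2-D (spots x genes)")
        if self.values.shape != (len(self.spot_ids), len(self.gene_ids)):
            raise DataError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.spot_ids)} spots x {len(self.gene_ids)} genes"
            )
        if len(set(self.spot_ids)) != len(self.spot_ids):
            raise DataError("spot_ids must be unique")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("gene_ids must be unique")
        if self.layer not in _LAYERS:
            raise DataError(f"unknown layer {self.layer!r}; expected one of {_LAYERS}")
        if self.layer == "counts":
            if np.any(self.values < 0):
                raise DataError("counts must be nonnegative")
            if not np.allclose(self.values, np.round(self.values)):
                raise DataError("counts must be integer-valued")
        if self.gene_symbols is not None and len(self.gene_symbols) != len(self.gene_ids):
            raise DataError("gene_symbols length mismatch")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def restrict_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Column-subset (and reorder) to ``gene_ids``."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise DataError(f"genes not present: {missing[:5]}")
        cols = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            values=self.values[:, cols],
            spot_ids=list(self.spot_ids),
            gene_ids=list(gene_ids),
            layer=self.layer,
            gene_symbols=None
            if self.gene_symbols is None
            else [self.gene_symbols[c] for c in cols],
        )

    def reorder_spots(self, spot_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.spot_ids)}
        missing = [s for s in spot_ids if s not in index]
        if missing:
            raise DataError(
                f"{len(missing)} barcodes present in positions but absent from the "
                f"matrix; first offenders: {missing[:5]}"
            )
        rows = [index[s] for s in spot_ids]
        return ExpressionMatrix(
            values=self.values[rows],
            spot_ids=list(spot_ids),
            gene_ids=list(self.gene_ids),
            layer=self.layer,
            gene_symbols=self.gene_symbols,
        )


@dataclass
class SpatialDataset:
    """One section: slide image + spot grid + expression matrix."""

    image: SlideImage
    spots: SpotGrid
    expression: ExpressionMatrix
    section_id: str = "section"

    def __post_init__(self) -> None:
        if self.spots.spot_ids != self.expression.spot_ids:
            raise DataError(
                "spot order of SpotGrid and ExpressionMatrix must agree; "
                "use ExpressionMatrix.reorder_spots before constructing"
            )

    @property
    def n_spots(self) -> int:
        return len(self.spots)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find_file(dir_path: Path, candidates: Sequence[str], what: str) -> Path:
    for name in candidates:
        p = dir_path / name
        if p.exists():
            return p
    raise DataError(
        f"missing {what} in {dir_path}: expected one of {list(candidates)}"
    )


def _read_positions(path: Path) -> pd.DataFrame:
    """Read a tissue-positions table, auto-detecting the headered dialect.

    SpaceRanger v1 writes ``tissue_positions_list.csv`` without a header
    row; v2 writes ``tissue_positions.csv`` with one.  The first line tells
    them apart: a header starts with the literal column name ``barcode``.
    """
    with _open_maybe_gz(path) as fh:
        first = fh.readline()
    has_header = first.strip().lower().startswith("barcode")
    df = pd.read_csv(
        path,
        header=0 if has_header else None,
        names=None if has_header else POSITION_COLUMNS,
    )
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in POSITION_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"positions file {path} lacks columns {missing}")
    return df[POSITION_COLUMNS]


def _read_tsv_column(path: Path, ncol_min: int = 1) -> pd.DataFrame:
    with _open_maybe_gz(path) as fh:
        df = pd.read_csv(fh, sep="\t", header=None)
    if df.shape[1] < ncol_min:
        raise DataError(f"{path} has fewer than {ncol_min} columns")
    return df


def read_visium(dir_path: str | Path) -> SpatialDataset:
    """Load one SpaceRanger-style section directory into a :class:`SpatialDataset`.

    The directory must contain a slide image (``image.png``/``.tif`` or the
    usual ``tissue_hires_image.png``), a tissue-positions CSV, and an MTX
    matrix with ``barcodes``/``features`` TSVs (gzipped variants accepted;
    the matrix may live in the directory root or under
    ``filtered_feature_bc_matrix/``).  Spots are filtered to ``in_tissue``
    and expression rows are reordered to SpotGrid order.
    """
    dir_path = Path(dir_path)
    if not dir_path.is_dir():
        raise DataError(f"not a directory: {dir_path}")

    image_path = _find_file(
        dir_path,
        ["image.png", "image.tif", "image.tiff", "tissue_hires_image.png",
         "tissue_image.png", "tissue_image.tif"],
        "slide image",
    )
    pos_path = _find_file(
        dir_path,
        ["tissue_positions.csv", "tissue_positions_list.csv",
         "tissue_positions.csv.gz", "tissue_positions_list.csv.gz",
         "spatial/tissue_positions.csv", "spatial/tissue_positions_list.csv"],
        "tissue positions CSV",
    )
    mtx_dirs = [dir_path, dir_path / "filtered_feature_bc_matrix"]
    mtx_path = None
    for d in mtx_dirs:
        for name in ("matrix.mtx", "matrix.mtx.gz"):
            if (d / name).exists():
                mtx_path = d / name
                break
        if mtx_path:
            break
    if mtx_path is None:
        raise DataError(
            f"missing count matrix in {dir_path}: expected matrix.mtx(.gz) "
            "in the root or under filtered_feature_bc_matrix/"
        )
    mtx_dir = mtx_path.parent
    barcodes_path = _find_file(mtx_dir, ["barcodes.tsv", "barcodes.tsv.gz"], "barcodes TSV")
    features_path = _find_file(
        mtx_dir, ["features.tsv", "features.tsv.gz", "genes.tsv", "genes.tsv.gz"],
        "features TSV",
    )

    with Image.open(image_path) as im:
        pixels = np.asarray(im.convert("RGB"))
    image = SlideImage(pixels=pixels)

    positions = _read_positions(pos_path)
    n_total = len(positions)
    positions = positions[positions["in_tissue"].astype(int) == 1].reset_index(drop=True)
    n_dropped = n_total - len(positions)
    logger.info(
        "read_visium(%s): %d barcodes, %d in tissue, %d dropped",
        dir_path, n_total, len(positions), n_dropped,
    )
    if len(positions) == 0:
        raise DataError(f"no in-tissue spots in {pos_path}")

    spots = SpotGrid(
        spot_ids=positions["barcode"].tolist(),
        pixel_xy=positions[["pxl_row_in_fullres", "pxl_col_in_fullres"]].to_numpy(),
        array_rc=positions[["array_row", "array_col"]].to_numpy(),
        in_tissue=np.ones(len(positions), dtype=bool),
    )

    barcodes = _read_tsv_column(barcodes_path)[0].astype(str).tolist()
    features = _read_tsv_column(features_path)
    gene_ids = features[0].astype(str).tolist()
    gene_symbols = (
        features[1].astype(str).tolist() if features.shape[1] >= 2 else None
    )

    # MatrixMarket stores genes x barcodes (SpaceRanger convention).
    if mtx_path.suffix == ".gz":
        with gzip.open(mtx_path, "rb") as fh:
            m = mmread(fh)
    else:
        m = mmread(mtx_path)
    m = sparse.csr_matrix(m)
    if m.shape != (len(gene_ids), len(barcodes)):
        raise DataError(
            f"matrix shape {m.shape} does not match {len(gene_ids)} features "
            f"x {len(barcodes)} barcodes"
        )
    counts = ExpressionMatrix(
        values=np.asarray(m.T.todense()),
        spot_ids=barcodes,
        gene_ids=gene_ids,
        layer="counts",
        gene_symbols=gene_symbols,
    ).reorder_spots(spots.spot_ids)

    return SpatialDataset(
        image=image, spots=spots, expression=counts, section_id=dir_path.name
    )


def write_dataset(dataset: SpatialDataset, dir_path: str | Path) -> None:
    """Write a section in the exact layout :func:`read_visium` consumes."""
    if dataset.expression.n_genes == 0:
        raise DataError("empty gene set: refusing to write a dataset with 0 genes")
    if dataset.expression.layer != "counts":
        raise DataError("write_dataset expects the counts layer")
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)

    Image.fromarray(dataset.image.pixels).save(dir_path / "image.png")

    spots = dataset.spots
    array_rc = (
        spots.array_rc
        if spots.array_rc is not None
        else np.zeros((len(spots), 2), dtype=int)
    )
    pd.DataFrame(
        {
            "barcode": spots.spot_ids,
            "in_tissue": spots.in_tissue.astype(int),
            "array_row": array_rc[:, 0],
            "array_col": array_rc[:, 1],
            "pxl_row_in_fullres": spots.pixel_xy[:, 0],
            "pxl_col_in_fullres": spots.pixel_xy[:, 1],
        }
    ).to_csv(dir_path / "tissue_positions.csv", index=False)

    expr = dataset.expression
    mmwrite(
        dir_path / "matrix.mtx",
        sparse.csr_matrix(expr.values.T.astype(int)),
        field="integer",
    )
    pd.Series(expr.spot_ids).to_csv(
        dir_path / "barcodes.tsv", index=False, header=False
    )
    symbols = expr.gene_symbols if expr.gene_symbols is not None else expr.gene_ids
    pd.DataFrame(
        {"id": expr.gene_ids, "symbol": symbols, "type": "Gene Expression"}
    ).to_csv(dir_path / "features.tsv", sep="\t", index=False, header=False)


def align_sections(
    a: SpatialDataset, b: SpatialDataset
) -> tuple[SpatialDataset, SpatialDataset]:
    """Restrict two sections to their shared gene universe.

    Both outputs carry an identical, lexicographically sorted gene list (the
    intersection of the two input universes); spots are untouched.  Needed
    before any cross-section step such as the HVG union.  Idempotent.
    """
    shared = sorted(set(a.expression.gene_ids) & set(b.expression.gene_ids))
    if not shared:
        raise DataError("gene universes of the two sections do not intersect")
    out = []
    for ds in (a, b):
        out.append(
            SpatialDataset(
                image=ds.image,
                spots=ds.spots,
                expression=ds.expression.restrict_genes(shared),
                section_id=ds.section_id,
            )
        )
    return out[0], out[1]
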
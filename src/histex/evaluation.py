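"""Per-gene correlation metrics and spatial visualization.

Prediction quality is summarized by per-gene Pearson correlation across
the spots of the held-out section:

* ``R_bar`` — the mean correlation over all genes with a defined PCC,
* ``R_bar_50`` — the mean over the top-k' (default 50) most highly
  expressed genes (HEGs), ranked by mean PREDICTED expression.

A gene whose observed or predicted vector has zero variance has an
undefined correlation; such genes are excluded from the means and counted
(``n_undefined``) rather than coerced to zero, which would bias the mean.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_spatial import DataError, ExpressionMatrix, SpatialDataset

logger = logging.getLogger("histex")


@dataclass
class EvalReport:
    """Per-gene PCCs plus the R_bar / R_bar_50 summaries."""

    per_gene_pcc: dict[str, float | None]
    mean_all: float
    mean_top_heg: float
    k_used: int
    heg_ids: list[str]
    n_undefined: int
    k_prime: int = 50

    def __post_init__(self) -> None:
        for g, v in self.per_gene_pcc.items():
            if v is not None and not (-1 - 1e-9 <= v <= 1 + 1e-9):
                raise DataError(f"PCC for {g} outside [-1, 1]: {v}")
        if self.k_used + self.n_undefined != len(self.per_gene_pcc):
            raise DataError("k_used + n_undefined must equal the gene count")

    def to_dict(self) -> dict:
        return {
            "mean_all": self.mean_all,
            "mean_top_heg": self.mean_top_heg,
            "k_used": self.k_used,
            "n_undefined": self.n_undefined,
            "k_prime": self.k_prime,
            "heg_ids": self.heg_ids,
            "per_gene_pcc": {k: v for k, v in sorted(self.per_gene_pcc.items())},
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def pcc(x: np.ndarray, y: np.ndarray) -> float | None:
    """Pearson correlation: Cov(x, y) / (sigma(x) * sigma(y)).

    Symmetric in its arguments and invariant to positive affine transforms
    of either.  Returns ``None`` (the undefined marker) when either vector
    has zero variance, rather than raising.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("pcc expects two equal-length 1-D vectors")
    if x.size < 2:
        raise DataError("pcc needs at least 2 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        return None
    r = float(xc @ yc) / (sx * sy)
    return max(-1.0, min(1.0, r))


def _check_aligned(y_true: ExpressionMatrix, y_pred: ExpressionMatrix) -> None:
    if y_true.gene_ids != y_pred.gene_ids:
        raise DataError("gene lists of truth and prediction differ")
    if y_true.spot_ids != y_pred.spot_ids:
        raise DataError("spot lists of truth and prediction differ")


def per_gene_pcc(y_true: ExpressionMatrix,
                 y_pred: ExpressionMatrix) -> dict[str, float | None]:
    """PCC across spots for every gene; ``None`` marks zero-variance genes."""
    _check_aligned(y_true, y_pred)
    return {
        g: pcc(y_true.values[:, j], y_pred.values[:, j])
        for j, g in enumerate(y_true.gene_ids)
    }


def mean_pcc_all(y_true: ExpressionMatrix,
                 y_pred: ExpressionMatrix) -> tuple[float, dict[str, float | None]]:
    """R_bar: mean per-gene PCC over the genes where it is defined."""
    pccs = per_gene_pcc(y_true, y_pred)
    defined = [v for v in pccs.values() if v is not None]
    n_undef = len(pccs) - len(defined)
    if n_undef:
        logger.info("mean_pcc_all: %d genes with undefined PCC excluded", n_undef)
    mean = float(np.mean(defined)) if defined else float("nan")
    return mean, pccs


def rank_heg(y_pred: ExpressionMatrix, k_prime: int) -> list[str]:
    """Top-``k_prime`` genes by mean predicted expression across spots.

    Descending by mean; ties break lexicographically by gene ID.
    """
    if k_prime > y_pred.n_genes:
        raise DataError(
            f"k_prime={k_prime} exceeds the {y_pred.n_genes} genes present"
        )
    means = y_pred.values.mean(axis=0)
    order = sorted(range(y_pred.n_genes),
                   key=lambda j: (-means[j], y_pred.gene_ids[j]))
    return [y_pred.gene_ids[j] for j in order[:k_prime]]


def mean_pcc_top_heg(y_true: ExpressionMatrix, y_pred: ExpressionMatrix,
                     k_prime: int = 50,
                     rank_on: str = "predicted") -> tuple[float, list[str]]:
    """R_bar_50: mean PCC over the top-k' most highly expressed genes.

    HEGs are ranked on the predicted matrix by default (``rank_on`` may be
    set to ``"observed"`` for sensitivity analysis).  Genes with undefined
    PCC inside the top set are excluded from the average.
    """
    _check_aligned(y_true, y_pred)
    if rank_on not in ("predicted", "observed"):
        raise DataError("rank_on must be 'predicted' or 'observed'")
    heg = rank_heg(y_pred if rank_on == "predicted" else y_true, k_prime)
    pccs = per_gene_pcc(y_true, y_pred)
    defined = [pccs[g] for g in heg if pccs[g] is not None]
    mean = float(np.mean(defined)) if defined else float("nan")
    return mean, heg


def evaluate(y_true: ExpressionMatrix, y_pred: ExpressionMatrix,
             k_prime: int = 50, rank_on: str = "predicted") -> EvalReport:
    """Full report: per-gene PCCs, R_bar, R_bar_50 and bookkeeping counts."""
    mean_all, pccs = mean_pcc_all(y_true, y_pred)
    k_prime_eff = min(k_prime, y_true.n_genes)
    mean_heg, heg_ids = mean_pcc_top_heg(y_true, y_pred, k_prime_eff, rank_on)
    n_undef = sum(1 for v in pccs.values() if v is None)
    return EvalReport(
        per_gene_pcc=pccs,
        mean_all=mean_all,
        mean_top_heg=mean_heg,
        k_used=len(pccs) - n_undef,
        heg_ids=heg_ids,
        n_undefined=n_undef,
        k_prime=k_prime_eff,
    )


def spatial_gene_plot(dataset_truth: SpatialDataset, y_pred: ExpressionMatrix,
                      gene_id: str, out_path: str | Path) -> tuple[float, float]:
    """Side-by-side observed / predicted spot maps for one gene.

    Spots are scattered at their pixel coordinates, color-mapped by
    expression with a color scale shared between the two panels (limits =
    min/max over the union of both vectors, returned for inspection).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    truth_expr = dataset_truth.expression
    if gene_id not in truth_expr.gene_ids:
        raise DataError(f"gene {gene_id!r} not in the observed matrix")
    if gene_id not in y_pred.gene_ids:
        raise DataError(f"gene {gene_id!r} not in the predicted matrix")
    obs = truth_expr.values[:, truth_expr.gene_ids.index(gene_id)]
    pred = y_pred.reorder_spots(truth_expr.spot_ids)
    prd = pred.values[:, pred.gene_ids.index(gene_id)]
    vmin = float(min(obs.min(), prd.min()))
    vmax = float(max(obs.max(), prd.max()))

    xy = dataset_truth.spots.pixel_xy
    fig, axes = plt.subplots(1, 2, figsize=(9, 4.2), constrained_layout=True)
    for ax, values, title in ((axes[0], obs, "observed"),
                              (axes[1], prd, "predicted")):
        sc = ax.scatter(xy[:, 1], xy[:, 0], c=values, s=12, cmap="viridis",
                        vmin=vmin, vmax=vmax)
        ax.set_title(f"{gene_id} ({title})")
        ax.invert_yaxis()
        ax.set_aspect("equal")
        ax.set_xticks([])
        ax.set_yticks([])
    fig.colorbar(sc, ax=axes, shrink=0.85)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return vmin, vmax
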
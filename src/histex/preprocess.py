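"""Model-input preparation: spot-centered patches and expression targets.

The pipeline order is fixed: align gene universes -> total-count + log1p
normalization -> per-section highly-variable-gene (HVG) ranking and union ->
restriction to the union -> batch correction.  Patches are square RGB
crops centered on each in-tissue spot; regions falling outside the slide
are padded with constant white, which matches H&E background (reflection
padding would fabricate tissue).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .io_spatial import DataError, ExpressionMatrix, SlideImage, SpotGrid

logger = logging.getLogger("histex")

BATCH_METHODS = ("none", "center_scale", "external_harmony")


@dataclass
class PatchSet:
    """N fixed-size RGB patches aligned to spots, as ``(N, 3, P, P)`` uint8."""

    patches: np.ndarray
    spot_ids: list[str]

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches)
        if self.patches.ndim != 4 or self.patches.shape[1] != 3:
            raise DataError(
                f"patches must be (N, 3, P, P), got {self.patches.shape}"
            )
        if self.patches.shape[2] != self.patches.shape[3]:
            raise DataError("patches must be square")
        if len(self.spot_ids) != self.patches.shape[0]:
            raise DataError("spot_ids length must equal number of patches")
        if self.patches.dtype != np.uint8:
            self.patches = self.patches.astype(np.uint8)

    @property
    def n_spots(self) -> int:
        return self.patches.shape[0]

    @property
    def patch_size(self) -> int:
        return self.patches.shape[2]


@dataclass
class PreprocessConfig:
    """Preprocessing knobs.

    patch_size
        Side of the square crop, in pixels (default 224, the standard input
        size of ImageNet-style encoders; a Visium spot is ~55 um across).
    target_sum
        Per-spot total count after scaling, before log1p (default 1e4).
    n_hvg
        Genes ranked per section by variance of the normalized values;
        the union over sections is the prediction panel (default 1000).
    batch_correction
        ``none``, built-in ``center_scale``, or ``external_harmony`` (a
        user-supplied callable hook; the algorithm itself is external).
    """

    patch_size: int = 224
    target_sum: float = 1e4
    n_hvg: int = 1000
    batch_correction: str = "center_scale"

    def __post_init__(self) -> None:
        if self.patch_size < 8 or self.patch_size % 2 != 0:
            raise DataError("patch_size must be even and >= 8")
        if self.n_hvg < 1:
            raise DataError("n_hvg must be >= 1")
        if self.target_sum <= 0:
            raise DataError("target_sum must be positive")
        if self.batch_correction not in BATCH_METHODS:
            raise DataError(
                f"batch_correction must be one of {BATCH_METHODS}, "
                f"got {self.batch_correction!r}"
            )


def extract_patches(
    image: SlideImage, spots: SpotGrid, patch_size: int = 224
) -> PatchSet:
    """Crop one ``patch_size`` square per in-tissue spot, centered on it.

    Out-of-slide regions are filled with white (255, 255, 255).  A spot
    whose center lies outside the slide entirely is an error.  Row order
    follows the SpotGrid.
    """
    if patch_size < 1:
        raise DataError("patch_size must be positive")
    H, W = image.shape
    half = patch_size // 2
    keep = np.flatnonzero(spots.in_tissue)
    patches = np.full((len(keep), patch_size, patch_size, 3), 255, dtype=np.uint8)
    ids: list[str] = []
    for out_i, i in enumerate(keep):
        r, c = spots.pixel_xy[i]
        ri, ci = int(round(r)), int(round(c))
        if not (0 <= ri < H and 0 <= ci < W):
            raise DataError(
                f"spot {spots.spot_ids[i]!r} center ({ri}, {ci}) lies outside "
                f"the {H}x{W} slide"
            )
        r0, r1 = ri - half, ri - half + patch_size
        c0, c1 = ci - half, ci - half + patch_size
        sr0, sr1 = max(r0, 0), min(r1, H)
        sc0, sc1 = max(c0, 0), min(c1, W)
        patches[out_i, sr0 - r0 : sr1 - r0, sc0 - c0 : sc1 - c0] = image.pixels[
            sr0:sr1, sc0:sc1
        ]
        ids.append(spots.spot_ids[i])
    return PatchSet(patches=patches.transpose(0, 3, 1, 2), spot_ids=ids)


def drop_empty_spots(expr: ExpressionMatrix) -> tuple[ExpressionMatrix, list[str]]:
    """Remove spots whose total count is zero (scale factor undefined there)."""
    totals = expr.values.sum(axis=1)
    empty = np.flatnonzero(totals == 0)
    if len(empty) == 0:
        return expr, []
    dropped = [expr.spot_ids[i] for i in empty]
    logger.warning("dropping %d empty spots: %s", len(dropped), dropped[:5])
    keep = np.flatnonzero(totals > 0)
    return (
        ExpressionMatrix(
            values=expr.values[keep],
            spot_ids=[expr.spot_ids[i] for i in keep],
            gene_ids=list(expr.gene_ids),
            layer=expr.layer,
            gene_symbols=expr.gene_symbols,
        ),
        dropped,
    )


def normalize_expression(
    expr: ExpressionMatrix, target_sum: float = 1e4
) -> ExpressionMatrix:
    """Total-count normalize each spot to ``target_sum``, then log1p.

    Output layer is ``"normalized"``; ``exp(v) - 1`` row sums equal
    ``target_sum`` exactly (up to float error) for every spot.
    """
    if expr.layer != "counts":
        raise DataError(f"normalize_expression expects counts, got {expr.layer!r}")
    totals = expr.values.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if len(zero) > 0:
        raise DataError(
            "spots with zero total count cannot be normalized; first offenders: "
            f"{[expr.spot_ids[i] for i in zero[:5]]} (drop_empty_spots first)"
        )
    scaled = expr.values * (target_sum / totals)[:, None]
    return ExpressionMatrix(
        values=np.log1p(scaled),
        spot_ids=list(expr.spot_ids),
        gene_ids=list(expr.gene_ids),
        layer="normalized",
        gene_symbols=expr.gene_symbols,
    )


def select_hvg_union(
    sections: Sequence[ExpressionMatrix], n_hvg: int = 1000
) -> list[str]:
    """Top-``n_hvg`` most variable genes per section, union over sections.

    Variance is the plain per-gene variance of the normalized values within
    a section; ties break lexicographically by gene ID, so the result is
    deterministic under any permutation of the gene columns.  The returned
    union is sorted; its size lies in ``[n_hvg, n_sections * n_hvg]``.
    """
    if len(sections) == 0:
        raise DataError("need at least one section")
    gene_ids = sections[0].gene_ids
    for s in sections[1:]:
        if s.gene_ids != gene_ids:
            raise DataError("sections must share an identical gene list (align first)")
    if n_hvg > len(gene_ids):
        raise DataError(
            f"n_hvg={n_hvg} exceeds the {len(gene_ids)} genes available"
        )
    union: set[str] = set()
    for s in sections:
        if s.layer not in ("normalized", "corrected"):
            raise DataError("HVG selection expects normalized values")
        var = s.values.var(axis=0)
        # sort by (-variance, gene_id): descending variance, lexicographic ties
        order = sorted(range(len(gene_ids)), key=lambda i: (-var[i], gene_ids[i]))
        union.update(gene_ids[i] for i in order[:n_hvg])
    return sorted(union)


def batch_correct(
    sections: Sequence[ExpressionMatrix],
    method: str = "center_scale",
    harmony_hook: Callable[[list[np.ndarray]], list[np.ndarray]] | None = None,
) -> list[ExpressionMatrix]:
    """Remove section-level (batch) shifts from normalized expression.

    ``none``
        Identity; the layer is relabeled ``"corrected"`` so downstream
        contracts are uniform.
    ``center_scale``
        Per section, per gene: subtract the section-specific gene mean and
        divide by the pooled (cross-section) per-gene standard deviation;
        zero-variance genes are divided by 1.  This removes additive batch
        shifts and puts genes on a common scale.
    ``external_harmony``
        Delegates to ``harmony_hook`` (sections in -> sections out, shapes
        preserved); the Harmony algorithm itself is not part of this
        package.
    """
    if method not in BATCH_METHODS:
        raise DataError(f"unknown batch correction method {method!r}")
    if len(sections) == 0:
        raise DataError("need at least one section")
    gene_ids = sections[0].gene_ids
    for s in sections[1:]:
        if s.gene_ids != gene_ids:
            raise DataError("sections must share an identical gene list")

    def relabel(values: np.ndarray, s: ExpressionMatrix) -> ExpressionMatrix:
        return ExpressionMatrix(
            values=values,
            spot_ids=list(s.spot_ids),
            gene_ids=list(s.gene_ids),
            layer="corrected",
            gene_symbols=s.gene_symbols,
        )

    if method == "none":
        return [relabel(s.values.copy(), s) for s in sections]

    if method == "external_harmony":
        if harmony_hook is None:
            raise DataError("external_harmony requires a harmony_hook callable")
        out_values = harmony_hook([s.values for s in sections])
        if len(out_values) != len(sections):
            raise DataError("harmony hook returned the wrong number of sections")
        out = []
        for s, v in zip(sections, out_values):
            v = np.asarray(v, dtype=float)
            if v.shape != s.values.shape:
                raise DataError(
                    f"harmony hook returned shape {v.shape}, expected {s.values.shape}"
                )
            out.append(relabel(v, s))
        return out

    # center_scale: pooled per-gene sd across all sections, section-wise centering
    pooled = np.concatenate([s.values for s in sections], axis=0)
    sd = pooled.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    out = []
    for s in sections:
        centered = s.values - s.values.mean(axis=0, keepdims=True)
        out.append(relabel(centered / sd, s))
    return out
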
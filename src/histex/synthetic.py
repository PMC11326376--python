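"""Seeded two-section synthetic benchmark data.

Emulates the structure the predictor is built for: a regular grid of
capture spots on a slide, latent "tissue factors" over that grid —
a discrete region component (contiguous anatomical regions, each with its
own factor profile, like cortical layers or cerebellar lobes) plus a
smooth within-tissue continuum — count-valued expression driven by those
factors through a nonnegative loading matrix with negative-binomial
noise, and an H&E-like image whose local color and texture around each
spot encode the same factors.  Two sections share the loadings and the
region profiles (shared biology) but draw independent geometry, so the
train-on-one / test-on-the-other protocol is exercisable end to end, with
a configurable additive batch shift between sections.  The discrete
regions give the tissue clusters of near-identical spots that real
sections have; they are what makes attention over spots (which averages
highly correlated spots) a meaningful operation on this data.

What the images emulate — and what they do not: each spot sits in an
eosin-pink disc whose RGB levels encode three latent factors and which is
speckled with dark hematoxylin-like blobs whose count encodes a fourth;
a latent-independent per-pixel noise floor is always present so that,
at ``image_encoding_strength = 0``, patches still vary but carry no
expression signal (the negative control).  There are no staining
artifacts, tissue folds, or fiducials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_spatial import (
    DataError,
    ExpressionMatrix,
    SlideImage,
    SpatialDataset,
    SpotGrid,
)

_BLOB_COLOR = np.array([72.0, 48.0, 118.0])       # hematoxylin-like purple
_DISC_BASE = np.array([232.0, 204.0, 214.0])      # eosin-like pink
_ENCODE_DEPTH = 130.0                             # max color swing per channel


@dataclass
class SimConfig:
    """Generator knobs; defaults are the desk-scale benchmark conditions.

    16x16 spots per section; 60 genes driven by 4 latent tissue factors
    composed of 4 discrete anatomical regions (contiguous, equal-count,
    profiles shared across sections) plus a weaker smooth continuum
    (length scale in spot units); ~5000 expected counts per spot with
    negative-binomial dispersion 10; full-strength image encoding with
    realistic latent-independent staining variability (``image_noise``
    scales per-spot stain jitter, blob-count jitter and speckle); a mild
    additive batch shift between the two sections.
    """

    seed: int = 0
    n_rows: int = 16
    n_cols: int = 16
    spot_spacing_px: int = 32
    n_genes: int = 60
    n_latent: int = 4
    spatial_length_scale: float = 3.0
    image_encoding_strength: float = 1.0
    count_depth: float = 5000.0
    noise_dispersion: float = 10.0
    section_shift: float = 0.3
    image_noise: float = 1.0
    n_regions: int = 4
    region_strength: float = 1.5
    continuum_strength: float = 0.5
    latent_field_mode: str = "smoothed_noise"   # or "gp" (exact, small grids)

    def __post_init__(self) -> None:
        if self.n_rows * self.n_cols < 2:
            raise DataError("grid too small: need at least 2 spots")
        if self.n_latent > self.n_genes:
            raise DataError("n_latent must be <= n_genes")
        if min(self.n_rows, self.n_cols, self.spot_spacing_px, self.n_genes,
               self.n_latent) < 1:
            raise DataError("grid, spacing, gene and latent counts must be positive")
        if not (0.0 <= self.image_encoding_strength <= 1.0):
            raise DataError("image_encoding_strength must lie in [0, 1]")
        if self.spatial_length_scale <= 0 or self.count_depth <= 0:
            raise DataError("spatial_length_scale and count_depth must be positive")
        if not self.noise_dispersion > 0:
            raise DataError("noise_dispersion must be positive (np.inf = Poisson)")
        if self.image_noise < 0:
            raise DataError("image_noise must be nonnegative")
        if self.n_regions < 1 or self.region_strength < 0:
            raise DataError("n_regions must be >= 1 and region_strength >= 0")
        if self.continuum_strength < 0:
            raise DataError("continuum_strength must be nonnegative")
        if self.region_strength == 0 and self.continuum_strength == 0:
            raise DataError("at least one of region/continuum strength must be > 0")
        if self.latent_field_mode not in ("smoothed_noise", "gp"):
            raise DataError("latent_field_mode must be 'smoothed_noise' or 'gp'")


@dataclass
class GroundTruth:
    """What the generator knows: factors, loadings, noise-free rates."""

    latent_fields: np.ndarray   # (n_spots, n_latent), standardized
    loadings: np.ndarray        # (n_latent, n_genes), nonnegative
    clean_rates: np.ndarray     # (n_spots, n_genes), expected counts
    region_labels: np.ndarray | None = None   # (n_spots,) discrete tissue region

    def __post_init__(self) -> None:
        if np.any(self.loadings < 0):
            raise DataError("loadings must be nonnegative")
        if np.any(self.clean_rates < 0):
            raise DataError("clean_rates must be nonnegative")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)


def _shared_params(config: SimConfig):
    """Biology shared by both sections: loadings, baselines, region profiles."""
    rng = np.random.default_rng([config.seed, 7919])
    # each gene loads mainly on one latent (round-robin) plus weak background
    primary = np.arange(config.n_genes) % config.n_latent
    loadings = 0.08 * np.abs(rng.standard_normal((config.n_latent, config.n_genes)))
    loadings[primary, np.arange(config.n_genes)] += rng.uniform(
        0.9, 1.6, size=config.n_genes
    )
    baselines = rng.normal(0.0, 0.8, size=config.n_genes)
    shift_dir = rng.standard_normal(config.n_genes)
    # latent-space profile of each discrete tissue region (anatomy shared
    # across sections; where the regions lie differs per section)
    region_profiles = rng.standard_normal((config.n_regions, config.n_latent))
    return loadings, baselines, shift_dir, region_profiles


def _latent_fields(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth standardized factor maps over the spot grid, (n_spots, n_latent)."""
    shape = (config.n_rows, config.n_cols)
    n_spots = config.n_rows * config.n_cols
    fields = np.empty((n_spots, config.n_latent))
    if config.latent_field_mode == "gp":
        rr, cc = np.meshgrid(np.arange(config.n_rows), np.arange(config.n_cols),
                             indexing="ij")
        pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        cov = np.exp(-0.5 * d2 / config.spatial_length_scale**2)
        chol = np.linalg.cholesky(cov + 1e-8 * np.eye(n_spots))
        for k in range(config.n_latent):
            fields[:, k] = chol @ rng.standard_normal(n_spots)
    else:
        for k in range(config.n_latent):
            white = rng.standard_normal(shape)
            smooth = gaussian_filter(white, sigma=config.spatial_length_scale,
                                     mode="reflect")
            fields[:, k] = smooth.ravel()
    return _standardize(fields)


def _standardize(fields: np.ndarray) -> np.ndarray:
    mean = fields.mean(axis=0)
    sd = fields.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (fields - mean) / sd


def _region_geometry(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Partition the grid into contiguous discrete regions (anatomy).

    A smooth scalar field is quantile-binned into ``n_regions`` equal-count
    bins; because the field is smooth, bins form contiguous areas, like
    anatomical regions in a tissue section.
    """
    if config.n_regions == 1:
        return np.zeros(config.n_rows * config.n_cols, dtype=int)
    white = rng.standard_normal((config.n_rows, config.n_cols))
    u = gaussian_filter(white, sigma=config.spatial_length_scale,
                        mode="reflect").ravel()
    edges = np.quantile(u, np.linspace(0, 1, config.n_regions + 1)[1:-1])
    return np.digitize(u, edges)


def _render_image(config: SimConfig, fields: np.ndarray,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Paint the slide; returns (uint8 image, spot pixel centers)."""
    s = config.spot_spacing_px
    H = s * (config.n_rows + 1)
    W = s * (config.n_cols + 1)
    canvas = np.full((H, W, 3), 255.0)
    centers = np.empty((config.n_rows * config.n_cols, 2))
    radius = 0.45 * s
    strength = config.image_encoding_strength

    i = 0
    for r in range(config.n_rows):
        for c in range(config.n_cols):
            cy, cx = (r + 1) * s, (c + 1) * s
            centers[i] = (cy, cx)
            z = fields[i]
            color = _DISC_BASE - strength * _ENCODE_DEPTH * _sigmoid(
                1.2 * z[np.arange(3) % config.n_latent]
            )
            # latent-independent per-spot stain jitter (staining variability)
            color = color + rng.normal(0.0, 56.0 * config.image_noise, size=3)
            y0, y1 = int(cy - radius) - 1, int(cy + radius) + 2
            x0, x1 = int(cx - radius) - 1, int(cx + radius) + 2
            yy, xx = np.mgrid[y0:y1, x0:x1]
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
            canvas[y0:y1, x0:x1][mask] = color

            # hematoxylin-like blobs: count encodes the 4th factor (if any)
            z_blob = z[3] if config.n_latent > 3 else z[0]
            n_blobs = 4 + int(round(strength * 14 * _sigmoid(1.2 * z_blob)))
            n_blobs += rng.poisson(8.0 * config.image_noise)  # latent-independent jitter
            for _ in range(n_blobs):
                ang = rng.uniform(0, 2 * np.pi)
                rad = radius * np.sqrt(rng.uniform(0, 0.85))
                by, bx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
                br = rng.uniform(1.2, 2.4)
                by0, by1 = int(by - br) - 1, int(by + br) + 2
                bx0, bx1 = int(bx - br) - 1, int(bx + br) + 2
                byy, bxx = np.mgrid[by0:by1, bx0:bx1]
                bmask = (byy - by) ** 2 + (bxx - bx) ** 2 <= br**2
                canvas[by0:by1, bx0:bx1][bmask] = _BLOB_COLOR
            i += 1

    # speckle noise floor, always present so patches vary even at strength 0
    canvas += rng.normal(0.0, 4.0 + 16.0 * config.image_noise, size=canvas.shape)
    return np.clip(canvas, 0, 255).astype(np.uint8), centers


def simulate_section(config: SimConfig,
                     section_index: int = 0) -> tuple[SpatialDataset, GroundTruth]:
    """Generate one section; all randomness derives from (seed, section_index).

    The pipeline: smooth latent fields -> softplus-linked clean rates with
    shared loadings (section 1 additionally gets the additive batch shift
    on log-rates) -> per-spot depth scaling to ``count_depth`` ->
    negative-binomial counts (Poisson when ``noise_dispersion`` is inf) ->
    slide image encoding the fields at ``image_encoding_strength``.
    """
    if section_index not in (0, 1):
        raise DataError("section_index must be 0 or 1")
    loadings, baselines, shift_dir, region_profiles = _shared_params(config)
    rng = np.random.default_rng([config.seed, section_index])

    continuum = _latent_fields(config, rng)
    region_labels = _region_geometry(config, rng)
    fields = _standardize(
        config.region_strength * region_profiles[region_labels]
        + config.continuum_strength * continuum
    )
    eta = fields @ loadings + baselines
    if section_index == 1 and config.section_shift != 0.0:
        eta = eta + config.section_shift * shift_dir
    rates_unscaled = _softplus(1.5 * eta)
    fractions = rates_unscaled / rates_unscaled.sum(axis=1, keepdims=True)
    clean_rates = config.count_depth * fractions

    if np.isinf(config.noise_dispersion):
        counts = rng.poisson(clean_rates)
    else:
        r = config.noise_dispersion
        lam = rng.gamma(shape=r, scale=clean_rates / r)
        counts = rng.poisson(lam)

    image_pixels, centers = _render_image(config, fields, rng)
    n_spots = config.n_rows * config.n_cols
    grid_rc = np.column_stack([
        np.repeat(np.arange(config.n_rows), config.n_cols),
        np.tile(np.arange(config.n_cols), config.n_rows),
    ])
    spot_ids = [f"SPOT{i:04d}-{section_index + 1}" for i in range(n_spots)]
    gene_ids = [f"g{j:04d}" for j in range(config.n_genes)]

    dataset = SpatialDataset(
        image=SlideImage(pixels=image_pixels),
        spots=SpotGrid(spot_ids=spot_ids, pixel_xy=centers, array_rc=grid_rc,
                       in_tissue=np.ones(n_spots, dtype=bool)),
        expression=ExpressionMatrix(values=counts.astype(float),
                                    spot_ids=spot_ids, gene_ids=gene_ids,
                                    layer="counts"),
        section_id=f"synthetic-{config.seed}-s{section_index + 1}",
    )
    truth = GroundTruth(latent_fields=fields, loadings=loadings,
                        clean_rates=clean_rates, region_labels=region_labels)
    return dataset, truth


def simulate_pair(config: SimConfig
                  ) -> tuple[SpatialDataset, SpatialDataset, GroundTruth, GroundTruth]:
    """Two sections with shared loadings, independent fields, batch shift on #2."""
    ds0, gt0 = simulate_section(config, section_index=0)
    ds1, gt1 = simulate_section(config, section_index=1)
    return ds0, ds1, gt0, gt1
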
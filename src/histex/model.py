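"""The spot predictor: backbone F, refinement head G, spot attention A.

The network maps a 3 x P x P RGB patch to a d-dimensional expression
prediction in two stages: a convolutional backbone ``F`` extracts an image
embedding, and a two-layer fully connected refinement head ``G`` maps the
embedding to gene space.  A third, parameter-free stage mixes the per-spot
predictions through scaled dot-product self-attention over the spots of a
section,

    A(Q, K, V) = softmax(Q K^T / sqrt(d)) V,   with Q = K = V = G(F(X)),

so spots whose predicted profiles already agree are averaged together —
a transductive smoothing that exploits spot-spot interactions without
adding a single learned parameter (no Q/K/V projections, no heads, no
positional encoding).

Training optimizes the sum of two mean-squared-error terms, one on the
direct predictions ``G(F(X))`` and one on the attended predictions
``A(G(F(X)))``; see :func:`dual_loss`.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _nn
from .io_spatial import DataError
from .preprocess import PatchSet

BACKBONE_KINDS = ("tiny_cnn", "residual_cnn", "none")
CHECKPOINT_VERSION = 1

#: batch size used when pushing patches through the backbone (memory bound)
_FORWARD_CHUNK = 256


@dataclass
class LossReport:
    """The two MSE branches and their sum, L = L_mse + L_mse'."""

    l_direct: float
    l_attended: float
    l_total: float

    def __post_init__(self) -> None:
        if self.l_direct < 0 or self.l_attended < 0 or self.l_total < 0:
            raise DataError("loss terms must be nonnegative")
        if self.l_total != self.l_direct + self.l_attended:
            raise DataError("l_total must equal l_direct + l_attended exactly")


def patches_to_float(patches: np.ndarray, dtype=np.float32) -> np.ndarray:
    """uint8 RGB -> centered float in [-0.5, 0.5]."""
    return patches.astype(dtype) / 255.0 - 0.5


def _build_backbone(kind: str, patch_size: int, embed_dim: int,
                    rng: np.random.Generator, dtype=np.float32) -> _nn.Sequential:
    if kind == "tiny_cnn":
        c = embed_dim // 4
        return _nn.Sequential(
            _nn.Conv2d(3, c, k=3, stride=2, pad=1, rng=rng, dtype=dtype),
            _nn.ReLU(),
            _nn.Conv2d(c, 2 * c, k=3, stride=2, pad=1, rng=rng, dtype=dtype),
            _nn.ReLU(),
            _nn.Conv2d(2 * c, 4 * c, k=3, stride=2, pad=1, rng=rng, dtype=dtype),
            _nn.ReLU(),
            _nn.GlobalAvgPool(),
        )
    if kind == "residual_cnn":
        c = embed_dim // 2
        return _nn.Sequential(
            _nn.Conv2d(3, c, k=3, stride=2, pad=1, rng=rng, dtype=dtype),
            _nn.ReLU(),
            _nn.ResidualBlock(c, rng=rng, dtype=dtype),
            _nn.Conv2d(c, 2 * c, k=3, stride=2, pad=1, rng=rng, dtype=dtype),
            _nn.ReLU(),
            _nn.ResidualBlock(2 * c, rng=rng, dtype=dtype),
            _nn.GlobalAvgPool(),
        )
    if kind == "none":
        # backbone-ablation: frozen random linear embed of downsampled pixels
        return _nn.Sequential(
            _nn.FrozenPixelEmbed(patch_size, embed_dim, rng=rng, dtype=dtype)
        )
    raise DataError(f"unknown backbone_kind {kind!r}; expected one of {BACKBONE_KINDS}")


class SpotPredictor:
    """Backbone F + refinement head G, with attention applied on top.

    Parameters
    ----------
    gene_ids
        Output gene panel; the head's output dimension is ``len(gene_ids)``.
    patch_size
        Side of the square input patches, pixels.
    backbone_kind
        ``tiny_cnn`` (3 strided conv blocks; the fast desk-scale encoder),
        ``residual_cnn`` (strided stem + identity-skip residual blocks), or
        ``none`` (frozen random pixel embedding; the backbone ablation).
    embed_dim, hidden_dim
        Embedding width of F and hidden width of G.
    seed
        Seeds the weight initialization; two predictors built with the same
        arguments are bitwise identical.
    """

    def __init__(self, gene_ids: list[str], patch_size: int = 224,
                 backbone_kind: str = "tiny_cnn", embed_dim: int = 32,
                 hidden_dim: int = 64, seed: int = 0, dtype=np.float32) -> None:
        if backbone_kind not in BACKBONE_KINDS:
            raise DataError(
                f"unknown backbone_kind {backbone_kind!r}; expected one of {BACKBONE_KINDS}"
            )
        self.gene_ids = list(gene_ids)
        self.patch_size = int(patch_size)
        self.backbone_kind = backbone_kind
        self.embed_dim = int(embed_dim)
        self.hidden_dim = int(hidden_dim)
        self.seed = int(seed)
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.backbone = _build_backbone(backbone_kind, patch_size, embed_dim, rng, dtype)
        self.head = _nn.Sequential(
            _nn.Linear(embed_dim, hidden_dim, rng=rng, dtype=dtype),
            _nn.ReLU(),
            _nn.Linear(hidden_dim, len(gene_ids), rng=rng, dtype=dtype),
        )
        self.network = _nn.Sequential(self.backbone, self.head)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def temperature_dim(self) -> int:
        """The sqrt-scaling dimension inside attention: columns of K = genes."""
        return self.n_genes

    def _check_patches(self, patches: PatchSet) -> None:
        if patches.n_spots and patches.patch_size != self.patch_size:
            raise DataError(
                f"patch size {patches.patch_size} does not match the model's "
                f"configured {self.patch_size}"
            )


# ---------------------------------------------------------------------------
# Attention
# ---------------------------------------------------------------------------


def attention(fx: np.ndarray, scale_dim: float | None = None,
              return_weights: bool = False):
    """Parameter-free scaled dot-product self-attention over spots.

    ``softmax(fx fx^T / sqrt(scale_dim)) fx`` with the softmax taken
    row-wise (per query spot) after per-row max subtraction for overflow
    safety.  ``scale_dim`` defaults to the number of columns of ``fx``
    (the dimension of K).  With one spot the output equals the input.
    """
    fx = np.asarray(fx)
    if fx.ndim != 2 or fx.shape[0] < 1:
        raise DataError("attention expects an (N, d) matrix with N >= 1")
    if not np.all(np.isfinite(fx)):
        raise DataError("attention input contains non-finite entries")
    if scale_dim is None:
        scale_dim = fx.shape[1]
    if not scale_dim > 0:
        raise DataError("scale_dim must be positive")
    scores = (fx @ fx.T) / np.sqrt(scale_dim)
    scores -= scores.max(axis=1, keepdims=True)
    weights = np.exp(scores)
    weights /= weights.sum(axis=1, keepdims=True)
    out = weights @ fx
    if return_weights:
        return out, weights
    return out


def attention_backward(fx: np.ndarray, weights: np.ndarray, dout: np.ndarray,
                       scale_dim: float) -> np.ndarray:
    """Gradient of the attention output w.r.t. its input ``fx``.

    Three paths contribute: through V (= fx), and through Q and K inside
    the softmax scores S = fx fx^T / sqrt(d).
    """
    dA = dout @ fx.T
    dfx = weights.T @ dout
    dS = weights * (dA - (dA * weights).sum(axis=1, keepdims=True))
    dfx += (dS @ fx + dS.T @ fx) / np.sqrt(scale_dim)
    return dfx


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------


def mse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean squared error over all N*d entries."""
    return float(np.mean((np.asarray(y_true, dtype=np.float64)
                          - np.asarray(y_pred, dtype=np.float64)) ** 2))


def l2norm_sum(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Sum over spots of the un-squared L2 norm of the residual (flag variant)."""
    diff = np.asarray(y_true, dtype=np.float64) - np.asarray(y_pred, dtype=np.float64)
    return float(np.linalg.norm(diff, axis=1).sum())


def dual_loss(y_true: np.ndarray, pred_direct: np.ndarray,
              pred_attended: np.ndarray, flavor: str = "mse") -> LossReport:
    """L = L_mse + L_mse': direct branch plus attended branch.

    ``flavor="mse"`` (default) averages squared residuals over all entries;
    ``flavor="l2norm"`` sums per-spot L2 norms instead (sensitivity-check
    variant).  The total is always the exact sum of the two branches.
    """
    y_true = np.asarray(y_true)
    pred_direct = np.asarray(pred_direct)
    pred_attended = np.asarray(pred_attended)
    if y_true.shape != pred_direct.shape or y_true.shape != pred_attended.shape:
        raise DataError(
            f"shape mismatch: truth {y_true.shape}, direct {pred_direct.shape}, "
            f"attended {pred_attended.shape}"
        )
    fn = {"mse": mse, "l2norm": l2norm_sum}.get(flavor)
    if fn is None:
        raise DataError(f"unknown loss flavor {flavor!r}")
    l_direct = fn(y_true, pred_direct)
    l_attended = fn(y_true, pred_attended)
    return LossReport(l_direct=l_direct, l_attended=l_attended,
                      l_total=l_direct + l_attended)


# ---------------------------------------------------------------------------
# Forward passes
# ---------------------------------------------------------------------------


def forward_direct(model: SpotPredictor, patches: PatchSet) -> np.ndarray:
    """Evaluation-mode direct predictions G(F(X)), one row per spot."""
    model._check_patches(patches)
    n = patches.n_spots
    if n == 0:
        return np.zeros((0, model.n_genes), dtype=model.dtype)
    outs = []
    for start in range(0, n, _FORWARD_CHUNK):
        x = patches_to_float(patches.patches[start : start + _FORWARD_CHUNK],
                             model.dtype)
        outs.append(model.network.forward(x))
    return np.concatenate(outs, axis=0)


def forward_full(model: SpotPredictor, patches: PatchSet
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Both branches: (G(F(X)), A(G(F(X)))) over the given spot set.

    The attended branch mixes over exactly the spots passed in this call;
    callers choose the scope (minibatch during training, whole section at
    inference).  The no-attention ablation simply uses the first output.
    """
    pred_direct = forward_direct(model, patches)
    if pred_direct.shape[0] == 0:
        return pred_direct, pred_direct.copy()
    pred_attended = attention(pred_direct, scale_dim=model.temperature_dim)
    return pred_direct, pred_attended


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: SpotPredictor, path: str | Path,
                    extra_meta: dict | None = None) -> None:
    """Persist weights + architecture + gene panel to a single ``.npz`` file."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "gene_ids": model.gene_ids,
        "patch_size": model.patch_size,
        "backbone_kind": model.backbone_kind,
        "embed_dim": model.embed_dim,
        "hidden_dim": model.hidden_dim,
        "seed": model.seed,
    }
    if extra_meta:
        meta["extra"] = extra_meta
    arrays = {
        f"param:{p}": owner.params[name]
        for p, owner, name in model.network.param_items()
    }
    arrays["meta"] = np.frombuffer(
        json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8
    )
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    Path(path).write_bytes(buf.getvalue())


def load_checkpoint(path: str | Path) -> tuple[SpotPredictor, dict]:
    """Rebuild a predictor from :func:`save_checkpoint` output."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"checkpoint not found: {path}")
    if not zipfile.is_zipfile(path):
        raise DataError(f"{path} is not a model checkpoint")
    data = np.load(path)
    meta = json.loads(bytes(data["meta"]).decode())
    if meta.get("version") != CHECKPOINT_VERSION:
        raise DataError(f"unsupported checkpoint version {meta.get('version')}")
    model = SpotPredictor(
        gene_ids=meta["gene_ids"], patch_size=meta["patch_size"],
        backbone_kind=meta["backbone_kind"], embed_dim=meta["embed_dim"],
        hidden_dim=meta["hidden_dim"], seed=meta["seed"],
    )
    for p, owner, name in model.network.param_items():
        owner.params[name][...] = data[f"param:{p}"]
    return model, meta.get("extra", {})
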
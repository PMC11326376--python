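"""Training and inference for the spot predictor.

One section's (patch, expression) pairs are fit with Adam on the dual
objective L = L_mse + L_mse'.  During training the attended branch mixes
over the spots of the current minibatch; at inference the attention is
applied once over ALL spots of the query section jointly, matching the
transductive reading of spot-spot interactions (a section is predicted as
a whole).  All randomness — weight initialization and epoch shuffling —
derives from ``TrainConfig.seed``, so a run is reproducible bitwise on CPU.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import _nn
from .io_spatial import DataError, ExpressionMatrix
from .model import (
    LossReport,
    SpotPredictor,
    attention,
    attention_backward,
    forward_direct,
    patches_to_float,
)
from .preprocess import PatchSet

logger = logging.getLogger("histex")

ATTENTION_SCOPES = ("batch", "section")


@dataclass
class TrainConfig:
    """Optimization and ablation switches.

    ``use_sat=False`` removes the attention branch entirely (no gradient
    flows through it and the objective reduces to the direct MSE);
    ``use_backbone=False`` replaces the conv encoder with a frozen random
    linear embedding of 8x-downsampled grayscale pixels, isolating the
    backbone's contribution.  ``attention_scope`` controls whether training
    attention spans the minibatch (default) or the full section (one
    full-batch step per epoch).
    """

    epochs: int = 50
    batch_size: int = 128
    learning_rate: float = 1e-4
    seed: int = 0
    use_sat: bool = True
    use_backbone: bool = True
    device: str = "cpu"
    backbone_kind: str = "tiny_cnn"
    embed_dim: int = 32
    hidden_dim: int = 64
    attention_scope: str = "batch"
    loss_flavor: str = "mse"

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or not self.learning_rate > 0:
            raise DataError("epochs, batch_size, learning_rate must be positive")
        if self.use_sat and self.batch_size < 2:
            raise DataError("batch_size must be >= 2 when use_sat is true")
        if self.device != "cpu":
            raise DataError("only cpu execution is supported")
        if self.attention_scope not in ATTENTION_SCOPES:
            raise DataError(f"attention_scope must be one of {ATTENTION_SCOPES}")


@dataclass
class TrainedModel:
    model: SpotPredictor
    loss_history: list[LossReport]
    config_fingerprint: str
    config: TrainConfig = field(repr=False, default=None)


def config_fingerprint(*configs) -> str:
    """Stable hash of one or more dataclass configs (order-sensitive)."""
    payload = json.dumps([asdict(c) if not isinstance(c, dict) else c
                          for c in configs], sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _mse_grad(y: np.ndarray, pred: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - y
    n = diff.size
    return float(np.mean(diff.astype(np.float64) ** 2)), (2.0 / n) * diff


def _l2norm_grad(y: np.ndarray, pred: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - y
    norms = np.linalg.norm(diff, axis=1, keepdims=True)
    safe = np.where(norms > 0, norms, 1.0)
    return float(norms.sum()), diff / safe


_LOSS_GRADS = {"mse": _mse_grad, "l2norm": _l2norm_grad}


def fit(patches: PatchSet, targets: ExpressionMatrix, config: TrainConfig,
        model: SpotPredictor | None = None) -> TrainedModel:
    """Fit a predictor to one section by minibatch Adam on the dual loss.

    ``patches`` and ``targets`` must be aligned spot-for-spot.  Returns the
    trained model with its per-epoch loss history (epoch means over steps).
    Raises on a non-finite loss, naming the offending epoch and step.
    """
    if patches.spot_ids != targets.spot_ids:
        raise DataError("patches and targets are not aligned by spot_id")
    if targets.layer not in ("normalized", "corrected"):
        raise DataError(
            f"targets must be 'normalized' or 'corrected', got {targets.layer!r}"
        )
    n = patches.n_spots
    if n < 2:
        raise DataError("need at least 2 spots to train")
    loss_grad = _LOSS_GRADS.get(config.loss_flavor)
    if loss_grad is None:
        raise DataError(f"unknown loss flavor {config.loss_flavor!r}")

    if model is None:
        model = SpotPredictor(
            gene_ids=list(targets.gene_ids),
            patch_size=patches.patch_size,
            backbone_kind=config.backbone_kind if config.use_backbone else "none",
            embed_dim=config.embed_dim,
            hidden_dim=config.hidden_dim,
            seed=config.seed,
        )
    if model.gene_ids != targets.gene_ids:
        raise DataError("model gene panel does not match target genes")

    x_all = patches_to_float(patches.patches, model.dtype)
    y_all = targets.values.astype(model.dtype)
    rng = np.random.default_rng(config.seed)
    opt = _nn.Adam(model.network, lr=config.learning_rate)
    batch_size = n if config.attention_scope == "section" else min(config.batch_size, n)

    history: list[LossReport] = []
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        sums = np.zeros(2)
        n_steps = 0
        for step, start in enumerate(range(0, n, batch_size)):
            idx = perm[start : start + batch_size]
            if config.use_sat and len(idx) < 2:
                continue  # a 1-spot tail batch has no interactions to attend over
            x, y = x_all[idx], y_all[idx]
            model.network.zero_grad()
            fx = model.network.forward(x)
            l_direct, dfx = loss_grad(y, fx)
            if config.use_sat:
                att, weights = attention(
                    fx, scale_dim=model.temperature_dim, return_weights=True
                )
                l_att, datt = loss_grad(y, att)
                dfx = dfx + attention_backward(
                    fx, weights, datt, model.temperature_dim
                )
            else:
                l_att = 0.0
            if not np.isfinite(l_direct) or not np.isfinite(l_att):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {step} "
                    f"(direct={l_direct}, attended={l_att})"
                )
            model.network.backward(dfx.astype(model.dtype))
            opt.step()
            sums += (l_direct, l_att)
            n_steps += 1
        l_direct_mean, l_att_mean = sums / max(n_steps, 1)
        history.append(LossReport(
            l_direct=l_direct_mean, l_attended=l_att_mean,
            l_total=l_direct_mean + l_att_mean,
        ))
    fp = config_fingerprint(config, {"genes": targets.gene_ids,
                                     "patch_size": patches.patch_size})
    logger.info("fit: %d epochs, final loss %.6f", config.epochs,
                history[-1].l_total)
    return TrainedModel(model=model, loss_history=history,
                        config_fingerprint=fp, config=config)


def predict(trained: TrainedModel | SpotPredictor, patches: PatchSet,
            use_sat: bool = True) -> ExpressionMatrix:
    """Predict a section's expression from its patches.

    With ``use_sat`` the attention mixes once over all spots of the query
    section jointly; without it the direct branch G(F(X)) is returned.
    Output layer is ``"predicted"`` with the model's gene panel as columns.
    """
    model = trained.model if isinstance(trained, TrainedModel) else trained
    pred = np.asarray(forward_direct(model, patches), dtype=np.float64)
    if use_sat and pred.shape[0] > 1:
        # double precision at inference keeps the mixing numerically tight
        pred = attention(pred, scale_dim=model.temperature_dim)
    return ExpressionMatrix(
        values=np.asarray(pred, dtype=np.float64),
        spot_ids=list(patches.spot_ids),
        gene_ids=list(model.gene_ids),
        layer="predicted",
    )
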
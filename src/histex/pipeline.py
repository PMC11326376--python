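"""End-to-end orchestration: simulate/load -> preprocess -> train -> predict -> evaluate.

A run is described by one YAML config with sections ``{simulate | data,
preprocess, train, eval}`` plus a top-level ``seed``; command-line flags
override config keys, and the fully resolved config is always written back
into the output directory so a run is auditable.  Every output directory
receives exactly one ``manifest.json`` (tool version, resolved config,
input content hashes, seed, wall-clock timestamps) and a machine-readable
``events.jsonl`` log.  ``report.json`` — the evaluation result — contains
no timestamps, so identical configs and inputs reproduce it byte for byte
on CPU.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from scipy import sparse
from scipy.io import mmread, mmwrite

from .evaluation import EvalReport, evaluate, spatial_gene_plot
from .io_spatial import (
    DataError,
    ExpressionMatrix,
    SpatialDataset,
    align_sections,
    read_visium,
    write_dataset,
)
from .preprocess import (
    PatchSet,
    PreprocessConfig,
    batch_correct,
    drop_empty_spots,
    extract_patches,
    normalize_expression,
    select_hvg_union,
)
from .synthetic import SimConfig, simulate_pair
from .training import TrainConfig, TrainedModel, config_fingerprint, fit, predict

logger = logging.getLogger("histex")

TOOL_VERSION = "0.1.0"


class ConfigError(ValueError):
    """The run configuration is malformed or incomplete."""


@dataclass
class RunManifest:
    """Provenance record written once per pipeline output directory."""

    tool_version: str
    config_snapshot: dict
    input_fingerprints: dict
    seed: int
    timestamps: dict = field(default_factory=dict)

    def save(self, out_dir: Path) -> None:
        (out_dir / "manifest.json").write_text(
            json.dumps(self.__dict__, indent=2, sort_keys=True, default=str)
        )


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()


def load_config(config_path: str | Path,
                overrides: dict[str, Any] | None = None) -> dict:
    """Read the YAML config and apply dotted-key overrides (``train.epochs``)."""
    path = Path(config_path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        node = cfg
        parts = key.split(".")
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = value
    return cfg


def _section_fingerprint(ds: SpatialDataset) -> str:
    h = hashlib.sha256()
    h.update(ds.image.pixels.tobytes())
    h.update(ds.expression.values.astype(np.float64).tobytes())
    h.update("\n".join(ds.expression.spot_ids).encode())
    h.update("\n".join(ds.expression.gene_ids).encode())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Intermediate persistence
# ---------------------------------------------------------------------------


def save_processed_section(path: str | Path, patches: PatchSet,
                           expr: ExpressionMatrix) -> None:
    """Persist one preprocessed section (patches + target matrix) to ``.npz``."""
    if patches.spot_ids != expr.spot_ids:
        raise DataError("patches and expression are not aligned")
    np.savez_compressed(
        path,
        patches=patches.patches,
        values=expr.values,
        spot_ids=np.array(expr.spot_ids),
        gene_ids=np.array(expr.gene_ids),
        layer=np.array(expr.layer),
    )


def load_processed_section(path: str | Path) -> tuple[PatchSet, ExpressionMatrix]:
    data = np.load(path, allow_pickle=False)
    spot_ids = [str(s) for s in data["spot_ids"]]
    expr = ExpressionMatrix(
        values=data["values"], spot_ids=spot_ids,
        gene_ids=[str(g) for g in data["gene_ids"]], layer=str(data["layer"]),
    )
    return PatchSet(patches=data["patches"], spot_ids=spot_ids), expr


def write_expression_mtx(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write a real-valued matrix as ``.mtx`` with barcode/gene sidecar TSVs."""
    path = Path(path)
    mmwrite(path, sparse.csr_matrix(expr.values.T), field="real")
    pd.Series(expr.spot_ids).to_csv(path.with_suffix(".barcodes.tsv"),
                                    index=False, header=False)
    pd.Series(expr.gene_ids).to_csv(path.with_suffix(".genes.tsv"),
                                    index=False, header=False)


def read_expression_mtx(path: str | Path, layer: str = "predicted") -> ExpressionMatrix:
    path = Path(path)
    m = np.asarray(sparse.csr_matrix(mmread(path)).todense()).T
    spot_ids = pd.read_csv(path.with_suffix(".barcodes.tsv"),
                           header=None)[0].astype(str).tolist()
    gene_ids = pd.read_csv(path.with_suffix(".genes.tsv"),
                           header=None)[0].astype(str).tolist()
    return ExpressionMatrix(values=m, spot_ids=spot_ids, gene_ids=gene_ids,
                            layer=layer)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def preprocess_pair(train_ds: SpatialDataset, test_ds: SpatialDataset,
                    pconfig: PreprocessConfig
                    ) -> tuple[tuple[PatchSet, ExpressionMatrix],
                               tuple[PatchSet, ExpressionMatrix]]:
    """Shared-gene preprocessing of a train/test section pair.

    Order: align gene universes -> drop empty spots -> normalize ->
    per-section HVG union -> restrict -> batch correct.  Patches are
    extracted afterwards for exactly the surviving spots, so the returned
    pairs are aligned spot-for-spot.
    """
    train_ds, test_ds = align_sections(train_ds, test_ds)
    out = []
    normalized = []
    kept_spots = []
    for ds in (train_ds, test_ds):
        expr, _ = drop_empty_spots(ds.expression)
        normalized.append(normalize_expression(expr, pconfig.target_sum))
        kept_spots.append(expr.spot_ids)
    panel = select_hvg_union(normalized, pconfig.n_hvg)
    restricted = [e.restrict_genes(panel) for e in normalized]
    corrected = batch_correct(restricted, pconfig.batch_correction)
    for ds, expr in zip((train_ds, test_ds), corrected):
        keep = [i for i, s in enumerate(ds.spots.spot_ids) if s in set(expr.spot_ids)]
        spots = ds.spots.subset(np.array(keep, dtype=int))
        patches = extract_patches(ds.image, spots, pconfig.patch_size)
        out.append((patches, expr.reorder_spots(patches.spot_ids)))
    return out[0], out[1]


def _load_or_simulate(cfg: dict, seed: int
                      ) -> tuple[SpatialDataset, SpatialDataset]:
    if "simulate" in cfg:
        sim_kwargs = dict(cfg.get("simulate") or {})
        sim_kwargs.setdefault("seed", seed)
        sim = SimConfig(**sim_kwargs)
        ds0, ds1, _, _ = simulate_pair(sim)
        sections = {1: ds0, 2: ds1}
    elif "data" in cfg:
        data = cfg["data"]
        for key in ("train_dir", "test_dir"):
            if key not in data:
                raise ConfigError(f"data section must name {key}")
        return read_visium(data["train_dir"]), read_visium(data["test_dir"])
    else:
        raise ConfigError("config must contain a 'simulate' or a 'data' section")
    train_on = int(cfg.get("train", {}).get("train_on_section", 1))
    if train_on not in (1, 2):
        raise ConfigError("train.train_on_section must be 1 or 2")
    return sections[train_on], sections[3 - train_on]


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None,
                 overrides: dict[str, Any] | None = None) -> RunManifest:
    """Execute the full protocol described by a config file.

    Writes, under the output directory: the resolved config, preprocessed
    intermediates, the model checkpoint, held-out predictions (MTX),
    ``report.json`` + per-gene TSV, the per-epoch loss TSV, the JSONL event
    log and the manifest.  Re-running with the same config and inputs
    reproduces ``report.json`` byte for byte.  On a stage failure a
    ``FAILED`` marker naming the stage is left behind and the error is
    re-raised.
    """
    t_start = _now()
    cfg = load_config(config_path, overrides)
    out_dir = Path(out_dir or cfg.get("out_dir", "histex_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))

    events_path = out_dir / "events.jsonl"
    events_path.write_text("")

    def log_event(stage: str, **kw) -> None:
        with open(events_path, "a") as fh:
            fh.write(json.dumps({"stage": stage, "time": _now(), **kw}) + "\n")

    stage = "setup"
    try:
        stage = "load_data"
        log_event(stage, status="start")
        train_ds, test_ds = _load_or_simulate(cfg, seed)
        fingerprints = {
            "train_section": _section_fingerprint(train_ds),
            "test_section": _section_fingerprint(test_ds),
        }
        if bool(cfg.get("simulate", {})) and cfg.get("write_sections", False):
            write_dataset(train_ds, out_dir / "sections" / "train")
            write_dataset(test_ds, out_dir / "sections" / "test")

        stage = "preprocess"
        log_event(stage, status="start")
        pconfig = PreprocessConfig(**(cfg.get("preprocess") or {}))
        (train_patches, train_expr), (test_patches, test_expr) = preprocess_pair(
            train_ds, test_ds, pconfig
        )
        save_processed_section(out_dir / "train_processed.npz",
                               train_patches, train_expr)
        save_processed_section(out_dir / "test_processed.npz",
                               test_patches, test_expr)

        stage = "train"
        log_event(stage, status="start")
        train_kwargs = dict(cfg.get("train") or {})
        train_kwargs.pop("train_on_section", None)
        train_kwargs.setdefault("seed", seed)
        tconfig = TrainConfig(**train_kwargs)
        trained = fit(train_patches, train_expr, tconfig)
        from .model import save_checkpoint
        save_checkpoint(trained.model, out_dir / "model.ckpt",
                        extra_meta={"fingerprint": trained.config_fingerprint})
        pd.DataFrame(
            [(i, r.l_direct, r.l_attended, r.l_total)
             for i, r in enumerate(trained.loss_history)],
            columns=["epoch", "l_direct", "l_attended", "l_total"],
        ).to_csv(out_dir / "loss_history.tsv", sep="\t", index=False)

        stage = "predict"
        log_event(stage, status="start")
        y_pred = predict(trained, test_patches, use_sat=tconfig.use_sat)
        write_expression_mtx(y_pred, out_dir / "predictions.mtx")

        stage = "evaluate"
        log_event(stage, status="start")
        eval_cfg = cfg.get("eval") or {}
        report = evaluate(test_expr, y_pred,
                          k_prime=int(eval_cfg.get("k_prime", 50)),
                          rank_on=eval_cfg.get("rank_on", "predicted"))
        report.save_json(out_dir / "report.json")
        pd.DataFrame(
            sorted(report.per_gene_pcc.items()),
            columns=["gene_id", "pcc"],
        ).to_csv(out_dir / "per_gene_pcc.tsv", sep="\t", index=False)
        for gene in eval_cfg.get("plot_genes", []) or []:
            test_for_plot = SpatialDataset(
                image=test_ds.image,
                spots=test_ds.spots.subset(np.array(
                    [i for i, s in enumerate(test_ds.spots.spot_ids)
                     if s in set(test_expr.spot_ids)], dtype=int)),
                expression=test_expr,
            )
            spatial_gene_plot(test_for_plot, y_pred, gene,
                              out_dir / f"plot_{gene}.png")
        log_event("done", status="ok", mean_all=report.mean_all)
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        log_event(stage, status="failed", error=str(exc))
        raise

    resolved = dict(cfg)
    resolved["seed"] = seed
    (out_dir / "config_resolved.yaml").write_text(yaml.safe_dump(resolved))
    manifest = RunManifest(
        tool_version=TOOL_VERSION,
        config_snapshot=resolved,
        input_fingerprints=fingerprints,
        seed=seed,
        timestamps={"start": t_start, "end": _now()},
    )
    manifest.save(out_dir)
    return manifest
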
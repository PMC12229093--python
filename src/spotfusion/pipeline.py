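"""End-to-end workflow: simulate -> preprocess -> train-align -> train-decode
-> predict -> evaluate (-> wsi), with manifests and derived per-stage seeds.

Configuration is a nested dict (YAML-loadable).  The defaults carry the
model's stated values (momentum 0.995, pseudo-target weight 0.4,
temperature 0.07, 2000-gene HVG input panel, 300-gene target panel); the
``tiny`` profile shrinks encoders, panels and spot counts to desk scale
while keeping those training constants.
"""

from __future__ import annotations

import copy
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, spatial_dataset, synthetic, wsi_inference
from .encoders import GeneEncoderConfig, ImageEncoderConfig
from .expression_decoder import (
    DecodeTrainConfig,
    DecoderConfig,
    ExpressionDecoder,
    freeze_encoder,
    train_decoder,
)
from .fusion_igm import FusionConfig
from .momentum_alignment import AlignConfig, AlignmentModel, train_alignment

__all__ = ["default_config", "tiny_config", "run_pipeline", "stage_seed", "STAGES"]

STAGES = ("simulate", "preprocess", "train-align", "train-decode", "predict", "evaluate", "wsi")

_STAGE_DEPS = {
    "simulate": (),
    "preprocess": ("simulate",),
    "train-align": ("preprocess",),
    "train-decode": ("train-align",),
    "predict": ("train-decode",),
    "evaluate": ("predict",),
    "wsi": ("train-decode",),
}

_DEFAULTS = {
    "seed": 0,
    "sim": {
        "grid_shape": [24, 24],
        "n_genes": 200,
        "latent_dim": 4,
        "image_size": 40,
        "noise_sd": 0.02,
        "count_depth": 5000.0,
    },
    "preprocess": {
        "hvg_k": 2000,
        "target_k": 300,
        "n_holdout": 64,
    },
    "image": {
        "input_resolution": 224,
        "vit_patch_size": 32,
        "depth": 12,
        "heads": 12,
        "width": 768,
        "embed_dim": 512,
    },
    "gene": {
        "backbone_layers": 12,
        "backbone_heads": 8,
        "backbone_width": 200,
        "dropout": 0.5,
        "embed_dim": 512,
    },
    "fusion": {
        "heads": 4,
        "ffn_hidden": 256,
        "n_blocks": 1,
        "symmetric_negatives": True,
    },
    "align": {
        "beta": 0.995,
        "alpha": 0.4,
        "tau": 0.07,
        "batch_size": 32,
        "lr": 1e-4,
        "weight_decay": 0.02,
        "steps": 300,
        "lambda_igm": 1.0,
    },
    "decode": {
        "hidden_dim": 512,
        "n_layers": 4,
        "heads": 8,
        "tokens": 8,
        "lr": 1e-4,
        "weight_decay": 0.02,
        "batch_size": 32,
        "steps": 200,
    },
    "evaluate": {
        "adjacent_ks": [5, 10],
        "random_k": 14,
    },
    "wsi": {
        "width": 1536,
        "height": 1024,
        "tile_size": 256,
        "n_tiles": 20,
        "n_tissue_regions": 3,
    },
}

_TINY_OVERRIDES = {
    "sim": {"grid_shape": [16, 20]},
    "preprocess": {"hvg_k": 128, "target_k": 50, "n_holdout": 64},
    "image": {"input_resolution": 32, "vit_patch_size": 16, "depth": 2, "heads": 4, "width": 64},
    "gene": {"backbone_layers": 2, "backbone_heads": 4, "backbone_width": 64, "dropout": 0.1},
    "align": {"lr": 1e-3},
    "decode": {"hidden_dim": 64, "n_layers": 2, "heads": 2, "tokens": 4, "lr": 1e-3},
}


def _deep_update(base: dict, overrides: dict) -> dict:
    for key, value in overrides.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base


def default_config(overrides: dict | None = None) -> dict:
    cfg = copy.deepcopy(_DEFAULTS)
    if overrides:
        _deep_update(cfg, overrides)
    return cfg


def tiny_config(overrides: dict | None = None) -> dict:
    cfg = default_config(copy.deepcopy(_TINY_OVERRIDES))
    if overrides:
        _deep_update(cfg, overrides)
    return cfg


def load_config(path, tiny: bool = False) -> dict:
    overrides = yaml.safe_load(Path(path).read_text()) or {}
    return tiny_config(overrides) if tiny else default_config(overrides)


def stage_seed(seed: int, stage: str) -> int:
    """Fan one global seed out to a stable per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2 ** 31)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_manifest(outdir: Path, stage: str, config: dict, inputs: list, outputs: list) -> None:
    manifest = {
        "stage": stage,
        "config_hash": _config_hash(config),
        "seed": stage_seed(config["seed"], stage),
        "inputs": {str(p): _file_hash(Path(p)) for p in inputs if Path(p).is_file()},
        "outputs": [str(p) for p in outputs],
    }
    mdir = outdir / "manifests"
    mdir.mkdir(parents=True, exist_ok=True)
    (mdir / f"{stage}.json").write_text(json.dumps(manifest, indent=2))


def _require(outdir: Path, path: Path, needed_by: str, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{needed_by}' needs {path}, which stage '{produced_by}' produces — "
            f"run '{produced_by}' first")
    return path


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: dict, outdir: Path) -> list:
    sim = config["sim"]
    spec = synthetic.SyntheticSpec(
        grid_shape=tuple(sim["grid_shape"]),
        n_genes=sim["n_genes"],
        latent_dim=sim["latent_dim"],
        image_size=sim["image_size"],
        noise_sd=sim["noise_sd"],
        count_depth=sim["count_depth"],
        rng_seed=stage_seed(config["seed"], "simulate"),
    )
    slc, latents = synthetic.generate_slice(spec, slice_id="synthetic-slice")
    slice_dir = spatial_dataset.write_slice_dir(slc, outdir / "data" / "slice")
    np.savetxt(outdir / "data" / "latents.tsv", latents, delimiter="\t")
    return [slice_dir / "manifest.json", outdir / "data" / "latents.tsv"]


def _stage_preprocess(config: dict, outdir: Path) -> list:
    slice_dir = _require(outdir, outdir / "data" / "slice", "preprocess", "simulate")
    slc = spatial_dataset.read_slice_dir(slice_dir)
    pp = config["preprocess"]
    normalized = spatial_dataset.normalize_expression(slc.counts)
    hvg = spatial_dataset.select_hvg(normalized, slc.gene_names, k=pp["hvg_k"])
    target = spatial_dataset.select_target_genes(normalized, slc.gene_names, k=pp["target_k"])
    hvg_x = spatial_dataset.subset_to_panel(normalized, slc.gene_names, hvg).matrix
    target_x = spatial_dataset.subset_to_panel(normalized, slc.gene_names, target).matrix
    patches = spatial_dataset.resize_patches(slc.patches, config["image"]["input_resolution"])

    rng = np.random.default_rng(stage_seed(config["seed"], "preprocess"))
    order = rng.permutation(slc.n)
    hold = pp["n_holdout"]
    split = {"train": order[:-hold], "holdout": order[-hold:]}
    out = outdir / "preprocessed.npz"
    np.savez_compressed(
        out,
        patches=patches,
        hvg_x=hvg_x,
        target_x=target_x,
        coords=slc.coords,
        train_idx=split["train"],
        holdout_idx=split["holdout"],
        hvg_names=np.array(hvg.names),
        target_names=np.array(target.names),
    )
    return [out]


def _stage_train_align(config: dict, outdir: Path) -> list:
    data = np.load(_require(outdir, outdir / "preprocessed.npz", "train-align", "preprocess"))
    seed = stage_seed(config["seed"], "train-align")
    img_cfg = ImageEncoderConfig(**config["image"])
    gene_cfg = GeneEncoderConfig(n_genes=data["hvg_x"].shape[1], **config["gene"])
    fus_cfg = FusionConfig(dim=config["image"]["width"], **config["fusion"])
    align_cfg = AlignConfig(seed=seed, **config["align"])
    model = AlignmentModel(img_cfg, gene_cfg, fus_cfg, beta=align_cfg.beta, seed=seed)
    tr = data["train_idx"]
    train_alignment(data["patches"][tr], data["hvg_x"][tr], model, align_cfg,
                    log_path=outdir / "align_log.jsonl")
    ckpt = outdir / "checkpoints" / "alignment.npz"
    model.save(ckpt)
    return [ckpt, outdir / "align_log.jsonl"]


def _stage_train_decode(config: dict, outdir: Path) -> list:
    data = np.load(_require(outdir, outdir / "preprocessed.npz", "train-decode", "preprocess"),
                   allow_pickle=False)
    ckpt = _require(outdir, outdir / "checkpoints" / "alignment.npz", "train-decode", "train-align")
    seed = stage_seed(config["seed"], "train-decode")
    model = AlignmentModel.load(ckpt)
    encoder = freeze_encoder(model.image_encoder)
    dec = config["decode"]
    from .nn import set_rng

    set_rng(seed)
    decoder = ExpressionDecoder(DecoderConfig(
        in_dim=config["image"]["embed_dim"],
        hidden_dim=dec["hidden_dim"], n_layers=dec["n_layers"], heads=dec["heads"],
        tokens=dec["tokens"], n_genes_out=data["target_x"].shape[1]))
    train_cfg = DecodeTrainConfig(lr=dec["lr"], weight_decay=dec["weight_decay"],
                                  batch_size=dec["batch_size"], steps=dec["steps"], seed=seed)
    tr = data["train_idx"]
    train_decoder(data["patches"][tr], data["target_x"][tr], decoder, encoder, train_cfg,
                  log_path=outdir / "decode_log.jsonl")
    out = outdir / "checkpoints" / "decoder.npz"
    decoder.save(out)
    return [out, outdir / "decode_log.jsonl"]


def _load_models(config: dict, outdir: Path, needed_by: str):
    ckpt = _require(outdir, outdir / "checkpoints" / "alignment.npz", needed_by, "train-align")
    dec = _require(outdir, outdir / "checkpoints" / "decoder.npz", needed_by, "train-decode")
    return AlignmentModel.load(ckpt), ExpressionDecoder.load(dec)


def _stage_predict(config: dict, outdir: Path) -> list:
    data = np.load(_require(outdir, outdir / "preprocessed.npz", "predict", "preprocess"))
    model, decoder = _load_models(config, outdir, "predict")
    ho = data["holdout_idx"]
    V = model.image_encoder(data["patches"][ho]).data
    preds = decoder.predict(V)
    names = [str(g) for g in data["target_names"]]
    df = pd.DataFrame(preds, columns=names)
    out_tsv = outdir / "predictions.tsv"
    df.to_csv(out_tsv, sep="\t", index=False)
    try:
        import anndata

        ad = anndata.AnnData(X=preds, var=pd.DataFrame(index=names))
        ad.layers["truth"] = data["target_x"][ho]
        ad.write_h5ad(outdir / "predictions.h5ad")
    except Exception as exc:  # pragma: no cover - container format is optional
        warnings.warn(f"could not write annotated container: {exc}")
    return [out_tsv]


def _stage_evaluate(config: dict, outdir: Path) -> list:
    data = np.load(_require(outdir, outdir / "preprocessed.npz", "evaluate", "preprocess"))
    model, decoder = _load_models(config, outdir, "evaluate")
    ho = data["holdout_idx"]
    patches, hvg_x, target_x = data["patches"][ho], data["hvg_x"][ho], data["target_x"][ho]
    coords = data["coords"][ho]
    V, E = model.embed(patches, hvg_x)
    seed = stage_seed(config["seed"], "evaluate")

    report = evaluation.EvalReport()
    for k in config["evaluate"]["adjacent_ks"]:
        sets = [evaluation.adjacent_candidates(coords, i, k) for i in range(len(ho))]
        report.alignment_accuracy[f"adjacent{k}"] = evaluation.alignment_accuracy(V, E, sets)
    rk = config["evaluate"]["random_k"]
    sets = [evaluation.random_candidates(len(ho), i, rk, seed + i) for i in range(len(ho))]
    report.alignment_accuracy[f"random{rk}"] = evaluation.alignment_accuracy(V, E, sets)

    preds = decoder.predict(model.image_encoder(patches).data)
    report.pcc_spot = evaluation.pearson_per_spot(target_x, preds)
    report.pcc_gene = evaluation.pearson_per_gene(target_x, preds)
    report.mse, report.mae = evaluation.mse_mae(target_x, preds)
    report.save(outdir, gene_names=[str(g) for g in data["target_names"]])
    return [outdir / "eval_report.json"]


def _stage_wsi(config: dict, outdir: Path) -> list:
    model, decoder = _load_models(config, outdir, "wsi")
    w = config["wsi"]
    seed = stage_seed(config["seed"], "wsi")
    image, truth = synthetic.generate_wsi_fixture(
        w["width"], w["height"], w["n_tissue_regions"], seed, tile_size=w["tile_size"])
    tiles, scores = wsi_inference.select_patches(image, w["tile_size"], w["n_tiles"])
    pred = wsi_inference.predict_wsi(tiles, model.image_encoder, decoder)
    score_df = pd.DataFrame([
        {"x0": s.tile_origin[0], "y0": s.tile_origin[1], "T_t": s.T_t, "N_t": s.N_t,
         "score": s.score, "excluded": s.excluded}
        for s in scores
    ])
    score_df.to_csv(outdir / "wsi_tile_scores.tsv", sep="\t", index=False)
    pd.Series(pred, name="predicted").to_csv(outdir / "wsi_prediction.tsv", sep="\t")
    return [outdir / "wsi_tile_scores.tsv", outdir / "wsi_prediction.tsv"]


_STAGE_FN = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "train-align": _stage_train_align,
    "train-decode": _stage_train_decode,
    "predict": _stage_predict,
    "evaluate": _stage_evaluate,
    "wsi": _stage_wsi,
}


def run_pipeline(config: dict, outdir, stages=None) -> dict:
    """Run the requested stages in dependency order; returns stage -> outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(stages) if stages else [s for s in STAGES if s != "wsi"]
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; valid: {list(STAGES)}")
    ordered = [s for s in STAGES if s in stages]
    results = {}
    for stage in ordered:
        outputs = _STAGE_FN[stage](config, outdir)
        inputs = []
        for dep in _STAGE_DEPS[stage]:
            mpath = outdir / "manifests" / f"{dep}.json"
            if mpath.exists():
                inputs.extend(json.loads(mpath.read_text())["outputs"])
        _write_manifest(outdir, stage, config, inputs, outputs)
        results[stage] = [str(p) for p in outputs]
    return results
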
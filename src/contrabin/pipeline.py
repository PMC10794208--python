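"""End-to-end orchestration: augment -> features -> train -> embed ->
cluster sweep -> select -> size filter -> write, with each stage also
runnable standalone from cached artifacts.

A run manifest (JSON) records the configuration, seed, assembly N50, the
temperature actually used, the selected sweep parameters and stage timings,
which is sufficient to reproduce the run from the raw inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np

from . import augment as aug
from . import clustering as clu
from . import features as feat
from . import io_formats as io
from . import model as mdl

logger = logging.getLogger(__name__)

MODES = ("co-assembly", "single-sample", "multi-sample")

FEATURES_FILE = "features.npz"
CHECKPOINT_FILE = "checkpoint.npz"
EMBEDDINGS_FILE = "embeddings.npz"
MANIFEST_FILE = "manifest.json"


@dataclass
class RunConfig:
    contigs: str = ""
    depths: list = field(default_factory=list)
    scg: str | None = None
    outdir: str = "contrabin_out"
    mode: str = "co-assembly"
    min_contig_len: int = io.DEFAULT_MIN_CONTIG_LEN
    n_aug: int = aug.DEFAULT_N_AUG
    min_frag_len: int = aug.DEFAULT_MIN_FRAG_LEN
    encoder: mdl.EncoderConfig = field(default_factory=mdl.EncoderConfig)
    train: mdl.TrainConfig = field(default_factory=mdl.TrainConfig)
    grid: clu.SweepGrid = field(default_factory=clu.SweepGrid)
    knn_k: int | None = None
    min_bin_bp: int = clu.DEFAULT_MIN_BIN_BP
    seed: int = 0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    def validate_inputs(self):
        if not self.depths:
            raise ValueError("at least one depth input is required")
        if self.mode == "single-sample" and len(self.depths) != 1:
            raise ValueError("single-sample mode takes exactly one depth input")
        if self.mode == "multi-sample" and len(self.depths) < 2:
            raise ValueError(
                "multi-sample mode needs >=2 depth inputs (reads of all "
                "samples mapped against this sample's contigs)")


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    return obj


class StageError(RuntimeError):
    def __init__(self, stage, message):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _load_inputs(cfg: RunConfig):
    cfg.validate_inputs()
    contigs = io.read_fasta(cfg.contigs, min_contig_len=cfg.min_contig_len)
    tracks = [io.read_depth(p, contigs) for p in cfg.depths]
    scg = (io.read_scg_table(cfg.scg, contigs) if cfg.scg
           else io.SCGTable(hits=[]))
    return contigs, tracks, scg


def stage_features(cfg: RunConfig):
    """Augment + feature construction; caches features.npz and the view
    coordinate audit TSV in the output directory."""
    contigs, tracks, _ = _load_inputs(cfg)
    views = aug.augment_contigs(contigs, n_aug=cfg.n_aug,
                                min_frag_len=cfg.min_frag_len, seed=cfg.seed)
    block = feat.build_features(views, tracks)
    os.makedirs(cfg.outdir, exist_ok=True)
    aug.dump_views_tsv(views, os.path.join(cfg.outdir, "views.tsv"))
    np.savez(os.path.join(cfg.outdir, FEATURES_FILE),
             x_com=block.x_com, x_cov=block.x_cov,
             parent_ids=np.array(block.parent_ids),
             view_indices=block.view_indices,
             contig_ids=np.array(contigs.ids),
             contig_lengths=contigs.lengths,
             n50=np.array([contigs.n50]))
    return contigs, views, block


def _load_features(cfg: RunConfig):
    path = os.path.join(cfg.outdir, FEATURES_FILE)
    if not os.path.exists(path):
        raise StageError("train", f"missing {path}; run the `features` stage first")
    with np.load(path, allow_pickle=False) as d:
        block = feat.FeatureBlock(x_com=d["x_com"], x_cov=d["x_cov"],
                                  parent_ids=list(d["parent_ids"]),
                                  view_indices=d["view_indices"])
        meta = {"contig_ids": list(d["contig_ids"]),
                "contig_lengths": d["contig_lengths"],
                "n50": int(d["n50"][0])}
    return block, meta


class _CachedViews:
    """Just enough ViewSet surface for train(): counts, not sequences."""

    def __init__(self, n_contigs, V):
        self.n_contigs = n_contigs
        self.V = V


def stage_train(cfg: RunConfig):
    block, meta = _load_features(cfg)
    V = int(np.max(block.view_indices)) + 1
    views = _CachedViews(len(meta["contig_ids"]), V)
    params = mdl.train(block, views, cfg.train, cfg.encoder, n50=meta["n50"])
    mdl.save_checkpoint(params, os.path.join(cfg.outdir, CHECKPOINT_FILE))
    with open(os.path.join(cfg.outdir, "loss_history.tsv"), "w") as fh:
        fh.write("epoch\tmean_loss\n")
        for e, l in enumerate(params.loss_history):
            fh.write(f"{e}\t{l:.6f}\n")
    return params, meta


def stage_embed(cfg: RunConfig):
    ckpt = os.path.join(cfg.outdir, CHECKPOINT_FILE)
    if not os.path.exists(ckpt):
        raise StageError("embed", f"missing {ckpt}; run the `train` stage first")
    block, meta = _load_features(cfg)
    params = mdl.load_checkpoint(ckpt)
    Z = mdl.embed(block, params)
    np.savez(os.path.join(cfg.outdir, EMBEDDINGS_FILE), Z=Z,
             contig_ids=np.array(meta["contig_ids"]),
             contig_lengths=meta["contig_lengths"])
    return Z, meta


def stage_cluster(cfg: RunConfig):
    path = os.path.join(cfg.outdir, EMBEDDINGS_FILE)
    if not os.path.exists(path):
        raise StageError("cluster", f"missing {path}; run the `embed` stage first")
    with np.load(path) as d:
        Z = d["Z"]
        contig_ids = [str(c) for c in d["contig_ids"]]
        lengths = d["contig_lengths"]
    if cfg.scg:
        dummy = io.ContigSet(contig_ids, ["N" * int(l) for l in lengths],
                             min_contig_len=0)
        scg = io.read_scg_table(cfg.scg, dummy)
    else:
        scg = io.SCGTable(hits=[])
    best, diag = clu.run_sweep_and_select(
        Z, scg, contig_ids, lengths, grid=cfg.grid, knn_k=cfg.knn_k,
        seed=cfg.seed, return_diagnostics=True)
    final = clu.filter_small_bins(best, lengths, min_bin_bp=cfg.min_bin_bp)
    diag.to_csv(os.path.join(cfg.outdir, "sweep_diagnostics.tsv"),
                sep="\t", index=False)
    return final, best, contig_ids, lengths


def run_pipeline(cfg: RunConfig) -> io.BinAssignment:
    """Full in-memory run; writes bins, diagnostics and the run manifest.

    Returns the final assignment with contig_id keys."""
    timings = {}
    manifest = {"config": _to_jsonable(cfg), "seed": cfg.seed}

    def timed(stage, fn, *args, **kw):
        t0 = time.time()
        try:
            out = fn(*args, **kw)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        timings[stage] = round(time.time() - t0, 3)
        return out

    contigs, tracks, scg = timed("read", _load_inputs, cfg)
    logger.info("read %d contigs (N50=%d), %d samples, %d SCG hits",
                len(contigs), contigs.n50, len(tracks), len(scg.hits))
    views = timed("augment", aug.augment_contigs, contigs, cfg.n_aug,
                  cfg.min_frag_len, cfg.seed)
    block = timed("features", feat.build_features, views, tracks)
    params = timed("train", mdl.train, block, views, cfg.train, cfg.encoder,
                   n50=contigs.n50)
    Z = timed("embed", mdl.embed, block, params)
    best, diag = timed("cluster", clu.run_sweep_and_select, Z, scg,
                       contigs.ids, contigs.lengths, cfg.grid, cfg.knn_k,
                       cfg.seed, True)
    final = clu.filter_small_bins(best, contigs.lengths,
                                  min_bin_bp=cfg.min_bin_bp)
    named = io.BinAssignment(
        labels={contigs.ids[i]: b for i, b in final.labels.items()},
        params=best.params)
    os.makedirs(cfg.outdir, exist_ok=True)
    io.write_bins(named, contigs, cfg.outdir)
    diag.to_csv(os.path.join(cfg.outdir, "sweep_diagnostics.tsv"),
                sep="\t", index=False)
    mdl.save_checkpoint(params, os.path.join(cfg.outdir, CHECKPOINT_FILE))
    manifest.update({
        "n_contigs": len(contigs), "n50": int(contigs.n50),
        "tau": params.tau, "epochs_run": len(params.loss_history),
        "selected_params": {"sigma": best.params[0],
                            "resolution": best.params[1],
                            "edge_ratio": best.params[2]},
        "n_bins_pre_filter": best.n_bins(),
        "n_bins_final": named.n_bins(),
        "n_unbinned": len(contigs) - len(named.labels),
        "timings_s": timings,
    })
    with open(os.path.join(cfg.outdir, MANIFEST_FILE), "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("wrote %d bins (%d contigs unbinned) to %s",
                named.n_bins(), manifest["n_unbinned"], cfg.outdir)
    return named
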
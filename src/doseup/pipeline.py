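"""End-to-end orchestration: phantom -> preprocess -> RPR -> two-phase
training -> inference -> evaluation, driven by one RunConfig.

Every stage writes a manifest (inputs, outputs, stage seed, config hash)
so reruns are auditable; deterministic stages reproduce their manifest
hashes bit-for-bit. The single global seed expands into per-stage seeds
through a stable hash, so stages can be rerun in isolation.

Intermediate arrays travel as compressed ``.npz`` bundles per subject;
evaluation images and reports are written as 8-bit PNG and CSV/JSON.
"""

from __future__ import annotations

import hashlib
import json
import os
import time

import numpy as np
import pandas as pd

from . import metrics as M
from .config import RunConfig, dump_config
from .ctio import (standardize_plane, to_eval_uint8, window_normalize,
                   write_png)
from .phantom import (PhantomSpec, apply_misalignment, generate_phantom_subject,
                      save_subject)
from .registration import build_rpr
from .roi import CNR_REGIONS, REFERENCE_REGION, RoiSet, mask_to_polygons
from .translator import (TrainConfig, load_state, save_state, train_phase,
                         translate)

__all__ = ["STAGES", "stage_seed", "run_pipeline", "PipelineError"]

STAGES = ("phantom", "preprocess", "rpr", "train1", "train2", "infer", "evaluate")


class PipelineError(RuntimeError):
    pass


def stage_seed(global_seed: int, stage: str) -> int:
    """Expand the global seed into a stable per-stage seed (< 2^31)."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(dump_config(cfg), sort_keys=True).encode()).hexdigest()[:16]


def _subject_seed(base: int, sid: str) -> int:
    h = hashlib.sha256(f"{base}:{sid}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _write_manifest(out_dir: str, stage: str, cfg: RunConfig, seed: int,
                    inputs: list[str], outputs: list[str]):
    files = []
    for p in sorted(outputs):
        if os.path.isdir(p):
            files.extend(os.path.join(p, f) for f in sorted(os.listdir(p)))
        elif os.path.isfile(p):
            files.append(p)
    man = {
        "stage": stage,
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "inputs": sorted(inputs),
        "outputs": sorted(outputs),
        "output_hashes": {
            os.path.relpath(p, out_dir): hashlib.sha256(
                open(p, "rb").read()).hexdigest()[:16]
            for p in files if os.path.isfile(p)
        },
        "written_at": None,  # timestamps intentionally excluded from hashing
    }
    path = os.path.join(out_dir, f"manifest_{stage}.json")
    man["written_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(path, "w") as fh:
        json.dump(man, fh, indent=1)
    return path


def _all_subjects(cfg: RunConfig) -> list[str]:
    out = []
    for ids in cfg.split.values():
        out.extend(ids)
    return out


def _require(path: str, stage: str):
    if not os.path.exists(path):
        raise PipelineError(f"stage {stage!r}: missing required input {path!r}")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_phantom(cfg: RunConfig, out: str) -> list[str]:
    seed = stage_seed(cfg.seed, "phantom")
    pdir = os.path.join(out, "phantom")
    os.makedirs(pdir, exist_ok=True)
    outputs = []
    tags = list(cfg.dose_levels)
    levels = [cfg.dose_levels[t] for t in tags]
    for sid in _all_subjects(cfg):
        sseed = _subject_seed(seed, sid)
        spec = PhantomSpec(**{**cfg.phantom.__dict__, "organ_layout_seed": sseed})
        vols, truth = generate_phantom_subject(spec, levels, seed=sseed,
                                               dose_tags=tags, jitter_kappa=True)
        by_tag = dict(zip(tags, vols))
        moved, fields = apply_misalignment(by_tag["Post100"], spec, seed=sseed + 1)
        by_tag["Post100_acquired"] = moved
        sdir = save_subject(pdir, sid, by_tag, truth)
        np.savez_compressed(os.path.join(sdir, "truth.npz"),
                            fields=fields,
                            landmarks=truth.landmark_coords,
                            **{f"mask_{k}": v for k, v in truth.region_masks.items()})
        outputs.append(sdir)
    return outputs


def _stage_preprocess(cfg: RunConfig, out: str) -> list[str]:
    pdir = os.path.join(out, "phantom")
    qdir = os.path.join(out, "preprocessed")
    os.makedirs(qdir, exist_ok=True)
    size = cfg.train_phase1.input_size
    outputs = []
    for sid in _all_subjects(cfg):
        sdir = os.path.join(pdir, sid)
        _require(os.path.join(sdir, "truth.npz"), "preprocess")
        from .ctio import read_volume
        arrs = {}
        for tag in (*cfg.dose_levels, "Post100_acquired"):
            vol = read_volume(os.path.join(sdir, f"{tag}.nii.gz"))
            unit = window_normalize(vol)
            arrs[tag] = np.stack([
                standardize_plane(unit.voxels[z], train_size=size,
                                  canvas=max(unit.voxels.shape[1:]))
                for z in range(unit.n_slices)]).astype(np.float32)
        path = os.path.join(qdir, f"{sid}.npz")
        np.savez_compressed(path, **arrs)
        outputs.append(path)
    return outputs


def _fixed_tag(cfg: RunConfig, sid: str) -> str:
    return "Pre" if sid in cfg.split.get("pretrain", []) else "Post40"


def _stage_rpr(cfg: RunConfig, out: str) -> list[str]:
    qdir = os.path.join(out, "preprocessed")
    rdir = os.path.join(out, "rpr")
    os.makedirs(rdir, exist_ok=True)
    outputs = []
    qc_rows = []
    for sid in _all_subjects(cfg):
        path = os.path.join(qdir, f"{sid}.npz")
        _require(path, "rpr")
        with np.load(path) as npz:
            fixed = npz[_fixed_tag(cfg, sid)]
            moving = npz["Post100_acquired"]
        rprs = []
        for z in range(fixed.shape[0]):
            rpr, comp, qc = build_rpr(fixed[z], moving[z], cfg.registration)
            rprs.append(np.clip(rpr, 0.0, 1.0).astype(np.float32))
            qc_rows.append({"subject": sid, "slice": z,
                            **{f"{stage}_{k}": v
                               for stage, rec in qc.items() if isinstance(rec, dict)
                               for k, v in rec.items() if k != "flags"}})
        opath = os.path.join(rdir, f"{sid}.npz")
        np.savez_compressed(opath, rpr=np.stack(rprs))
        outputs.append(opath)
    qc_path = os.path.join(rdir, "registration_qc.csv")
    pd.DataFrame(qc_rows).to_csv(qc_path, index=False)
    outputs.append(qc_path)
    return outputs


def _gather_pairs(cfg: RunConfig, out: str, cohort: str) -> list:
    qdir = os.path.join(out, "preprocessed")
    rdir = os.path.join(out, "rpr")
    pairs = []
    for sid in cfg.split.get(cohort, []):
        _require(os.path.join(qdir, f"{sid}.npz"), f"train ({cohort})")
        _require(os.path.join(rdir, f"{sid}.npz"), f"train ({cohort})")
        with np.load(os.path.join(qdir, f"{sid}.npz")) as npz:
            fixed = npz[_fixed_tag(cfg, sid)]
        with np.load(os.path.join(rdir, f"{sid}.npz")) as npz:
            rpr = npz["rpr"]
        for z in range(fixed.shape[0]):
            pairs.append((fixed[z], rpr[z]))
    return pairs


def _stage_train(cfg: RunConfig, out: str, phase: int) -> list[str]:
    cohort = "pretrain" if phase == 1 else "finetune"
    pairs = _gather_pairs(cfg, out, cohort)
    if not pairs:
        raise PipelineError(f"train{phase}: no training pairs (empty {cohort!r} split)")
    tcfg = cfg.train_phase1 if phase == 1 else cfg.train_phase2
    tcfg = TrainConfig(**{**tcfg.__dict__, "seed": stage_seed(cfg.seed, f"train{phase}")})
    init = None
    if phase == 2:
        ck1 = os.path.join(out, "checkpoints", "phase1.npz")
        if os.path.exists(ck1):
            init = load_state(ck1)
    state, log = train_phase(pairs, tcfg, cfg.loss_weights, init_from=init)
    cdir = os.path.join(out, "checkpoints")
    os.makedirs(cdir, exist_ok=True)
    ck = os.path.join(cdir, f"phase{phase}.npz")
    save_state(state, ck)
    log_path = os.path.join(cdir, f"phase{phase}_log.csv")
    pd.DataFrame(log).to_csv(log_path, index=False)
    return [ck, log_path]


def _stage_infer(cfg: RunConfig, out: str) -> list[str]:
    ck = os.path.join(out, "checkpoints", "phase2.npz")
    if not os.path.exists(ck):
        ck = os.path.join(out, "checkpoints", "phase1.npz")
    _require(ck, "infer")
    state = load_state(ck)
    qdir = os.path.join(out, "preprocessed")
    idir = os.path.join(out, "translated")
    os.makedirs(idir, exist_ok=True)
    outputs = []
    for sid in cfg.split.get("eval", []):
        path = os.path.join(qdir, f"{sid}.npz")
        _require(path, "infer")
        with np.load(path) as npz:
            fixed = npz["Post40"]
        trs = np.stack([translate(fixed[z], state) for z in range(fixed.shape[0])])
        opath = os.path.join(idir, f"{sid}.npz")
        np.savez_compressed(opath, translated=trs.astype(np.float32))
        outputs.append(opath)
        for z in range(trs.shape[0]):
            png = os.path.join(idir, f"{sid}_{z:03d}.png")
            write_png(to_eval_uint8(trs[z]), png)
            outputs.append(png)
    return outputs


def _roi_for_slice(masks: dict, z: int, size: int, canvas: int) -> RoiSet:
    roi = RoiSet(source_image_tag=f"slice_{z}")
    for name in (*CNR_REGIONS, REFERENCE_REGION):
        if name not in masks:
            continue
        m = standardize_plane(masks[name][z].astype(float), train_size=size,
                              canvas=canvas) > 0.5
        for poly in mask_to_polygons(m):
            roi.add(name, poly)
    return roi


def _stage_evaluate(cfg: RunConfig, out: str) -> list[str]:
    qdir = os.path.join(out, "preprocessed")
    rdir = os.path.join(out, "rpr")
    idir = os.path.join(out, "translated")
    edir = os.path.join(out, "report")
    os.makedirs(edir, exist_ok=True)
    size = cfg.train_phase1.input_size
    embedder = M.RandomProjectionEmbedder(seed=stage_seed(cfg.seed, "evaluate"))
    backbone = M.SeededConvBackbone(seed=stage_seed(cfg.seed, "evaluate"))
    slice_rows, roi_rows = [], []
    ref_set, gen_set = [], []
    for sid in cfg.split.get("eval", []):
        for p, st in ((os.path.join(qdir, f"{sid}.npz"), "evaluate"),
                      (os.path.join(rdir, f"{sid}.npz"), "evaluate"),
                      (os.path.join(idir, f"{sid}.npz"), "evaluate")):
            _require(p, st)
        with np.load(os.path.join(qdir, f"{sid}.npz")) as npz:
            inputs = npz["Post40"]
        with np.load(os.path.join(rdir, f"{sid}.npz")) as npz:
            rprs = npz["rpr"]
        with np.load(os.path.join(idir, f"{sid}.npz")) as npz:
            trs = npz["translated"]
        tdir = os.path.join(out, "phantom", sid, "truth.npz")
        with np.load(tdir) as npz:
            masks = {k[5:]: npz[k] for k in npz.files if k.startswith("mask_")}
        canvas = masks["body"].shape[1]
        for z in range(inputs.shape[0]):
            x8 = to_eval_uint8(inputs[z])
            r8 = to_eval_uint8(np.clip(rprs[z], 0, 1))
            t8 = to_eval_uint8(trs[z])
            ref_set.append(r8)
            gen_set.append(t8)
            psnr_t, mse_t = M.psnr_mse(t8, r8)
            psnr_i, mse_i = M.psnr_mse(x8, r8)
            row = {"subject": sid, "slice": z,
                   "psnr": psnr_t, "mse": mse_t,
                   "psnr_input": psnr_i, "mse_input": mse_i,
                   "ms_ssim": M.ms_ssim(t8, r8),
                   "lpips": M.lpips(t8, r8, backbone)}
            slice_rows.append(row)
            roi = _roi_for_slice(masks, z, size, canvas)
            for region in CNR_REGIONS:
                if region not in roi.regions or not roi.reference_polygons:
                    continue
                res_t = M.cnr(t8, x8, roi, region)
                res_i = M.cnr(x8, x8, roi, region)
                gen_sample = M.roi_intensity_sample(t8, roi, region)
                rpr_sample = M.roi_intensity_sample(r8, roi, region)
                kld, w1 = M.distribution_similarity(gen_sample, rpr_sample)
                rho = M.vessel_profile_correlation(t8, r8, roi, region)
                roi_rows.append({"subject": sid, "slice": z, "region": region,
                                 "cnr": res_t.cnr, "cnr_input": res_i.cnr,
                                 "mu_sig": res_t.mu_sig, "mu_ref": res_t.mu_ref,
                                 "sigma_ref": res_t.sigma_ref,
                                 "kld": kld, "wasserstein": w1,
                                 "profile_corr": rho})
    report = M.MetricReport(per_slice=pd.DataFrame(slice_rows),
                            per_roi=pd.DataFrame(roi_rows))
    if len(ref_set) >= 2:
        report.dataset_level["fid"] = M.fid(ref_set, gen_set, embedder)
        report.dataset_level["fid_input_vs_rpr"] = M.fid(
            ref_set, [to_eval_uint8(s) for s in
                      np.concatenate([np.load(os.path.join(qdir, f"{sid}.npz"))["Post40"]
                                      for sid in cfg.split.get("eval", [])])],
            M.RandomProjectionEmbedder(seed=stage_seed(cfg.seed, "evaluate")))
    report.summarize()
    paths = [os.path.join(edir, "per_slice.csv"), os.path.join(edir, "per_roi.csv"),
             os.path.join(edir, "summary.json")]
    report.to_csv(paths[0], paths[1])
    report.to_json(paths[2])
    return paths


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stages in canonical order; returns manifest paths."""
    stages = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    out = cfg.paths.get("output", "out")
    os.makedirs(out, exist_ok=True)
    runners = {
        "phantom": _stage_phantom,
        "preprocess": _stage_preprocess,
        "rpr": _stage_rpr,
        "train1": lambda c, o: _stage_train(c, o, 1),
        "train2": lambda c, o: _stage_train(c, o, 2),
        "infer": _stage_infer,
        "evaluate": _stage_evaluate,
    }
    manifests = {}
    for stage in stages:
        outputs = runners[stage](cfg, out)
        manifests[stage] = _write_manifest(out, stage, cfg,
                                           stage_seed(cfg.seed, stage), [], outputs)
    return manifests
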
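"""Shared fixtures.

The expensive session fixtures (phantom subjects with registration-built
pseudo-references, smoke-trained models) are built lazily, so unit-test
runs that do not touch them stay fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from doseup.ctio import standardize_plane, window_normalize
from doseup.phantom import (PhantomSpec, apply_misalignment,
                            generate_phantom_subject, transport_points)
from doseup.registration import RegistrationConfig, build_rpr
from doseup.translator import LossWeights, TrainConfig, train_phase

# smoke-scale network: narrow widths and a short bottleneck keep a
# 200-iteration run around a minute on one CPU while preserving the
# architecture family (ResNet generator + 70x70-receptive PatchGAN)
SMOKE = dict(input_size=64, n_res_blocks=3, ngf=10, ndf=10, n_patches=64,
             batch_size=4)
SMOKE_ITERS = 200


def make_subject_pairs(layout_seed: int, noise_seed: int, fixed_dose: float = 0.4,
                       n_slices: int = 4, size: int = 64, grid: int = 128):
    """One phantom subject as (fixed, RPR) training pairs plus its truth."""
    spec = PhantomSpec(grid_size=grid, n_slices=n_slices,
                       organ_layout_seed=layout_seed, noise_sd=8.0)
    vols, truth = generate_phantom_subject(spec, [fixed_dose, 1.0],
                                           seed=noise_seed, jitter_kappa=True)
    fixed_vol = window_normalize(vols[0])
    moving_vol, fields = apply_misalignment(window_normalize(vols[1]), spec,
                                            seed=noise_seed + 500)
    cfg = RegistrationConfig()
    pairs = []
    for z in range(n_slices):
        fx = standardize_plane(fixed_vol.voxels[z], train_size=size, canvas=grid)
        mv = standardize_plane(moving_vol.voxels[z], train_size=size, canvas=grid)
        rpr, _, _ = build_rpr(fx, mv, cfg)
        pairs.append((fx.astype(np.float32), np.clip(rpr, 0, 1).astype(np.float32)))
    return pairs, truth, spec


@pytest.fixture(scope="session")
def phantom_bank():
    """Training/validation data for the smoke-training studies."""
    p2_train = []
    for sid in range(3):
        pairs, _, _ = make_subject_pairs(sid, noise_seed=100 + sid)
        p2_train += pairs
    p2_val, val_truth, val_spec = make_subject_pairs(7, noise_seed=999)
    p1_train = []
    for sid in range(10, 12):
        pairs, _, _ = make_subject_pairs(sid, noise_seed=200 + sid, fixed_dose=0.0)
        p1_train += pairs
    return {"p2_train": p2_train, "p2_val": p2_val, "p1_train": p1_train,
            "val_truth": val_truth, "val_spec": val_spec}


def train_smoke(pairs, seed: int, iterations: int = SMOKE_ITERS,
                weights: LossWeights | None = None, init_from=None, phase: int = 2):
    cfg = TrainConfig(**SMOKE, max_iterations=iterations, seed=seed, phase=phase)
    state, log = train_phase(pairs, cfg, weights or LossWeights(),
                             init_from=init_from)
    return state, log


@pytest.fixture(scope="session")
def smoke_models(phantom_bank):
    """Full-objective smoke models, one per seed (shared across tests)."""
    out = {}
    for seed in (11, 12, 13):
        out[seed] = train_smoke(phantom_bank["p2_train"], seed)
    return out


@pytest.fixture(scope="session")
def noedge_models(phantom_bank):
    """Edge-ablated counterparts at the same iteration budget."""
    out = {}
    for seed in (11, 12, 13):
        out[seed] = train_smoke(phantom_bank["p2_train"], seed,
                                weights=LossWeights(lambda_edge=0.0))
    return out


@pytest.fixture(scope="session")
def kt_models(phantom_bank):
    """Knowledge-transfer study: one Phase-1 pretrain, then per-seed
    Phase-2 runs fine-tuned vs from-scratch at equal budget."""
    phase1, _ = train_smoke(phantom_bank["p1_train"], seed=21, iterations=150,
                            phase=1)
    runs = {}
    for seed in (5, 6, 7):
        ft, _ = train_smoke(phantom_bank["p2_train"], seed, iterations=70,
                            init_from=phase1)
        sc, _ = train_smoke(phantom_bank["p2_train"], seed, iterations=70)
        runs[seed] = (ft, sc)
    return {"phase1": phase1, "runs": runs}


@pytest.fixture(scope="session")
def registration_pairs():
    """20 seeded phantom pairs with known smooth misalignment at 128 px."""
    pairs = []
    for s in range(20):
        spec = PhantomSpec(grid_size=128, n_slices=1, organ_layout_seed=s,
                           noise_sd=8.0)
        vols, truth = generate_phantom_subject(spec, [0.4, 1.0], seed=s)
        fixed = window_normalize(vols[0]).voxels[0]
        moved, fields = apply_misalignment(window_normalize(vols[1]), spec,
                                           seed=s + 1000)
        lm = truth.landmark_coords[truth.landmark_coords[:, 0] == 0.0][:, 1:]
        moving_lm = transport_points(fields[0], lm)
        pairs.append({"fixed": fixed, "moving": moved.voxels[0],
                      "landmarks": lm, "moving_landmarks": moving_lm,
                      "true_field": fields[0]})
    return pairs
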
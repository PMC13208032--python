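"""Structure-preserving dose-up translation: objective and training.

The generator maps a preprocessed low-enhanced slice to its full-dose
appearance, supervised by registration-based pseudo-references (RPRs)
rather than ground truth. The total generator objective is

    L = l_adv * L_adv + l_SRC * L_SRC + l_HDCE * L_HDCE
        + l_pyr * L_pyr + l_edge * L_edge

with default weights (1.0, 0.1, 0.2, 15.0, 2.0):

* ``L_adv`` — least-squares PatchGAN adversarial loss (the convention of
  the contrastive-translation family; switchable).
* ``L_pyr`` — pyramid L1: mean absolute error between the generated image
  and the RPR at 4 dyadic scales, each level built by 2x average-pooling
  the *output* (one generator forward per step), per-scale weights
  uniform 1.0.
* ``L_edge`` — edge preservation: mean absolute disagreement of forward-
  difference gradients plus 4-neighbour Laplacians (replicate boundary).
* ``L_HDCE`` — hard-negative decoupled patchwise contrastive loss: for
  each of 512 sampled patch locations (shared between the input's and the
  output's encoder features, projected by the 2-layer MLP feature net and
  L2-normalized), an InfoNCE-style loss whose denominator excludes the
  positive (decoupled) and re-weights negatives by ``exp(beta * sim)``
  normalized to unit mean (hard-negative up-weighting). In the infinite-
  temperature limit the loss tends to ``log(K - 1)`` for ``K`` sampled
  patches.
* ``L_SRC`` — semantic-relation consistency: Jensen-Shannon divergence
  between the row-softmaxed patch-patch similarity matrices of the input
  and output features; zero iff the two relation matrices agree.

Training alternates Adam updates (beta1 0.5, beta2 0.999, constant lr
2e-4) of the discriminator and the generator+feature-net. Knowledge
transfer is two-phase: Phase 1 learns Pre -> Post100 on the abundant
cohort; Phase 2 fine-tunes Post40 -> Post100 from the Phase-1 checkpoint
(``init_from``). Everything is deterministic under the config seed.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .models import PatchGANDiscriminator, PatchProjector, ResnetGenerator
from .nn import Adam, Tensor

__all__ = [
    "LossWeights",
    "TrainConfig",
    "ModelState",
    "build_models",
    "build_pyramid",
    "pyramid_l1",
    "edge_loss",
    "contrastive_losses",
    "total_loss",
    "train_phase",
    "translate",
    "save_state",
    "load_state",
]


@dataclass
class LossWeights:
    """Weighting coefficients of the total objective (defaults committed)."""

    lambda_adv: float = 1.0
    lambda_src: float = 0.1
    lambda_hdce: float = 0.2
    lambda_pyr: float = 15.0
    lambda_edge: float = 2.0
    scale_weights: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)

    def validate(self):
        for name in ("lambda_adv", "lambda_src", "lambda_hdce", "lambda_pyr",
                     "lambda_edge"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.scale_weights) != 4:
            raise ValueError("scale_weights must have 4 entries (scales L1..L4)")
        if any(w < 0 for w in self.scale_weights):
            raise ValueError("scale_weights must be >= 0")


@dataclass
class TrainConfig:
    """Optimization and architecture hyperparameters (defaults committed).

    ``ngf``/``ndf`` widths and ``max_iterations`` exist so hermetic smoke
    runs can train narrow models for a fixed iteration budget; the
    full-scale values are the defaults.
    """

    lr: float = 2e-4
    betas: tuple[float, float] = (0.5, 0.999)
    epochs: int = 40
    batch_size: int = 16
    input_size: int = 256
    n_res_blocks: int = 9
    ngf: int = 64
    ndf: int = 64
    netf_channels: int = 256
    n_patches: int = 512
    temperature: float = 0.07
    hard_neg_beta: float = 1.0
    src_temperature: float = 0.07
    adversarial: str = "lsgan"
    seed: int = 0
    phase: int = 1
    max_iterations: int | None = None
    residual_output: bool = False

    def validate(self):
        if self.phase not in (1, 2):
            raise ValueError("phase must be 1 or 2")
        if self.lr < 0:
            raise ValueError("lr must be >= 0")
        for name in ("epochs", "batch_size", "input_size", "ngf", "ndf",
                     "netf_channels", "n_patches", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_res_blocks < 0:
            raise ValueError("n_res_blocks must be >= 0")


@dataclass
class ModelState:
    """Generator, discriminator and feature-net parameters plus provenance."""

    generator: ResnetGenerator
    discriminator: PatchGANDiscriminator
    projector: PatchProjector
    config: TrainConfig
    seed: int
    iteration: int = 0
    provenance: list = field(default_factory=list)

    def checksum(self) -> float:
        tot = 0.0
        for mod in (self.generator, self.discriminator, self.projector):
            for k, v in sorted(mod.state_dict().items()):
                tot += float(np.abs(v).sum())
        return tot


def build_models(config: TrainConfig, seed: int | None = None) -> ModelState:
    """Deterministically initialize generator / discriminator / feature net."""
    config.validate()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    gen = ResnetGenerator(config.ngf, config.n_res_blocks, rng=rng)
    if config.residual_output:
        gen.residual_output = True
        gen.head.weight.data[:] = 0.0
        gen.head.bias.data[:] = 0.0
    disc = PatchGANDiscriminator(config.ndf, rng=rng)
    proj = PatchProjector(gen.feature_channels(), config.netf_channels, rng=rng)
    return ModelState(gen, disc, proj, config, seed,
                      provenance=[{"event": "init", "seed": seed,
                                   "phase": config.phase}])


def _as_batch_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if arr.dtype not in (np.float32, np.float64):
        arr = arr.astype(np.float64)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[:, None]
    return Tensor(arr)


def _generator_forward(gen: ResnetGenerator, x: Tensor, collect: bool = False):
    """Forward with optional residual-output variant."""
    if getattr(gen, "residual_output", False):
        x2 = x * 2.0 - 1.0
        h, taps = gen.encode(x2, collect=collect)
        delta = gen.up1_norm(gen.up1(h.upsample_nearest2x())).relu()
        delta = gen.up2_norm(gen.up2(delta.upsample_nearest2x())).relu()
        delta = gen.head(delta)
        y = (x2 + delta) * 0.5 + 0.5
        return (y, taps) if collect else y
    return gen.forward(x, collect_features=collect)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def build_pyramid(generated, rpr, n_levels: int = 4):
    """Dyadic pyramid of (generated, RPR) pairs by 2x average pooling.

    Tensor inputs stay on the autograd graph; plain arrays come back as
    plain arrays (so ``pyramid_l1`` on arrays returns a float).
    """
    if isinstance(generated, Tensor) or isinstance(rpr, Tensor):
        g = _as_batch_tensor(generated)
        y = _as_batch_tensor(rpr)
        levels = [(g, y)]
        for _ in range(n_levels - 1):
            g = g.avg_pool2d(2)
            y = y.avg_pool2d(2)
            levels.append((g, y))
        return levels

    def pool(x):
        return x.reshape(*x.shape[:-2], x.shape[-2] // 2, 2,
                         x.shape[-1] // 2, 2).mean(axis=(-3, -1))

    g = np.asarray(generated, dtype=np.float64)
    y = np.asarray(rpr, dtype=np.float64)
    levels = [(g, y)]
    for _ in range(n_levels - 1):
        g = pool(g)
        y = pool(y)
        levels.append((g, y))
    return levels


def pyramid_l1(levels: list[tuple, ], weights: LossWeights | None = None):
    """Sum over scales of lambda_s * mean |g_s - y_s| (mean reduction)."""
    weights = weights or LossWeights()
    weights.validate()
    if len(levels) != len(weights.scale_weights):
        raise ValueError(
            f"expected {len(weights.scale_weights)} pyramid levels, got {len(levels)}")
    was_array = not isinstance(levels[0][0], Tensor)
    total = None
    for s, ((g, y), lam) in enumerate(zip(levels, weights.scale_weights)):
        g = _as_batch_tensor(g)
        y = _as_batch_tensor(y)
        if g.shape != y.shape:
            raise ValueError(f"pyramid level {s}: shape mismatch {g.shape} vs {y.shape}")
        term = (g - y).abs().mean() * lam
        total = term if total is None else total + term
    return float(total.data) if was_array else total


_LAP_KERNEL = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]],
                       dtype=np.float32).reshape(1, 1, 3, 3)


def edge_loss(generated, rpr):
    """mean|grad G - grad y| + mean|lap G - lap y| (replicate boundaries)."""
    g = _as_batch_tensor(generated)
    y = _as_batch_tensor(rpr)
    was_array = not isinstance(generated, Tensor)
    if g.shape != y.shape:
        raise ValueError(f"edge_loss: shape mismatch {g.shape} vs {y.shape}")
    lap_w = Tensor(_LAP_KERNEL.astype(g.data.dtype))
    grad_term = ((g.fdiff(-2) - y.fdiff(-2)).abs().mean()
                 + (g.fdiff(-1) - y.fdiff(-1)).abs().mean())
    lap_g = g.pad2d(1, "edge").conv2d(lap_w, None)
    lap_y = y.pad2d(1, "edge").conv2d(lap_w, None)
    lap_term = (lap_g - lap_y).abs().mean()
    out = grad_term + lap_term
    return float(out.data) if was_array else out


def _row_softmax(s: Tensor, tau: float) -> Tensor:
    """Numerically stable row softmax of a similarity tensor (.../K axis)."""
    logits = s * (1.0 / tau)
    m = Tensor(logits.data.max(axis=-1, keepdims=True))  # detached shift
    e = (logits - m).exp()
    return e / e.sum(axis=-1, keepdims=True)


def contrastive_losses(input_features: list, output_features: list,
                       config: TrainConfig | None = None):
    """(L_HDCE, L_SRC) from per-layer projected patch features.

    Each entry is a (B, K, C) L2-normalized feature block; input and
    output lists are index-aligned (same sampled locations).
    """
    config = config or TrainConfig()
    if len(input_features) != len(output_features):
        raise ValueError("layer lists differ in length")
    tau = config.temperature
    beta = config.hard_neg_beta
    hdce_terms = []
    src_terms = []
    for k_feat, q_feat in zip(input_features, output_features):
        k_feat = k_feat if isinstance(k_feat, Tensor) else Tensor(np.asarray(k_feat))
        q_feat = q_feat if isinstance(q_feat, Tensor) else Tensor(np.asarray(q_feat))
        B, K, C = q_feat.shape
        if K < 2:
            raise ValueError("need at least 2 patches per layer")
        s = q_feat @ k_feat.transpose(0, 2, 1)  # (B, K, K) similarities
        eye = np.eye(K, dtype=s.data.dtype)[None]
        # decoupled positive / hard-negative weighted denominator
        pos = (s * Tensor(eye)).sum(axis=-1)  # (B, K)
        w = np.exp(beta * s.data) * (1.0 - eye)  # detached hard-neg weights
        w = w * ((K - 1) / np.maximum(w.sum(axis=-1, keepdims=True), 1e-30))
        m = (s.data / tau).max(axis=-1, keepdims=True)  # detached shift
        e = (s * (1.0 / tau) - Tensor(m)).exp() * Tensor(w * (1.0 - eye))
        lse = e.sum(axis=-1).log() + Tensor(m[..., 0])
        hdce_terms.append((lse - pos * (1.0 / tau)).mean())
        # semantic-relation consistency (Jensen-Shannon between row softmaxes)
        p = _row_softmax(k_feat @ k_feat.transpose(0, 2, 1), config.src_temperature)
        q = _row_softmax(s_out := (q_feat @ q_feat.transpose(0, 2, 1)),
                         config.src_temperature)
        mix = (p + q) * 0.5
        jsd = ((p * ((p + 1e-12).log() - (mix + 1e-12).log())).sum(axis=-1)
               + (q * ((q + 1e-12).log() - (mix + 1e-12).log())).sum(axis=-1)) * 0.5
        src_terms.append(jsd.mean())
    n = float(len(hdce_terms))
    hdce = hdce_terms[0] * (1.0 / n)
    src = src_terms[0] * (1.0 / n)
    for t in hdce_terms[1:]:
        hdce = hdce + t * (1.0 / n)
    for t in src_terms[1:]:
        src = src + t * (1.0 / n)
    return hdce, src


def total_loss(components: dict, weights: LossWeights | None = None):
    """lambda-weighted sum of the five objective components."""
    weights = weights or LossWeights()
    weights.validate()
    lam = {"adv": weights.lambda_adv, "src": weights.lambda_src,
           "hdce": weights.lambda_hdce, "pyr": weights.lambda_pyr,
           "edge": weights.lambda_edge}
    total = None
    any_tensor = any(isinstance(v, Tensor) for v in components.values())
    for name, lam_v in lam.items():
        if name not in components:
            raise ValueError(f"missing loss component {name!r}")
        v = components[name]
        val = float(v.data) if isinstance(v, Tensor) else float(v)
        if not math.isfinite(val):
            raise ValueError(f"loss component {name!r} is not finite ({val})")
        term = v * lam_v if isinstance(v, Tensor) else lam_v * val
        total = term if total is None else total + term
    return total if any_tensor else float(total)


# ---------------------------------------------------------------------------
# training & inference
# ---------------------------------------------------------------------------

def _sample_ids(rng: np.random.Generator, hw: int, k: int) -> np.ndarray:
    if hw <= k:
        return np.arange(hw)
    return rng.choice(hw, size=k, replace=False)


def _project_taps(taps: list[Tensor], projector: PatchProjector,
                  ids_per_layer: list[np.ndarray]) -> list[Tensor]:
    out = []
    for l, (tap, ids) in enumerate(zip(taps, ids_per_layer)):
        patches = tap.take_spatial(ids)  # (B, K, C)
        out.append(projector.project(l, patches))
    return out


def train_phase(dataset: list[tuple[np.ndarray, np.ndarray]],
                config: TrainConfig,
                weights: LossWeights | None = None,
                init_from: ModelState | None = None):
    """Train one knowledge-transfer phase on (input, RPR) slice pairs.

    Phase 1 trains from scratch on Pre -> Post100 pairs; Phase 2 may pass
    the Phase-1 checkpoint as ``init_from`` (Post40 -> Post100
    fine-tuning). Returns the trained :class:`ModelState` and the
    per-iteration loss log (list of dicts). Deterministic under
    ``config.seed``.
    """
    config.validate()
    weights = weights or LossWeights()
    weights.validate()
    if not dataset:
        raise ValueError("empty dataset")
    if init_from is not None:
        # clone the checkpoint so fine-tuning never mutates the caller's state
        state = build_models(init_from.config, seed=init_from.seed)
        state.generator.load_state_dict(init_from.generator.state_dict())
        state.discriminator.load_state_dict(init_from.discriminator.state_dict())
        state.projector.load_state_dict(init_from.projector.state_dict())
        state.config = config
        state.seed = config.seed
        state.provenance = init_from.provenance + [{"event": "init_from",
                                                    "phase": config.phase}]
    else:
        state = build_models(config)
    gen, disc, proj = state.generator, state.discriminator, state.projector
    opt_g = Adam(gen.parameters() + proj.parameters(), lr=config.lr, betas=config.betas)
    opt_d = Adam(disc.parameters(), lr=config.lr, betas=config.betas)
    order_rng = np.random.default_rng((config.seed * 1_000_003 + 17) % (2 ** 31))
    patch_rng = np.random.default_rng((config.seed * 7_368_787 + 29) % (2 ** 31))

    n = len(dataset)
    bs = min(config.batch_size, n)
    iters_per_epoch = max(n // bs, 1)
    budget = config.max_iterations
    total_iters = budget if budget is not None else config.epochs * iters_per_epoch

    log: list[dict] = []
    last_good: dict[str, np.ndarray] | None = None
    it = 0
    use_contrastive = weights.lambda_hdce > 0 or weights.lambda_src > 0
    while it < total_iters:
        perm = order_rng.permutation(n)
        for b0 in range(0, iters_per_epoch * bs, bs):
            if it >= total_iters:
                break
            idx = perm[b0 % n:b0 % n + bs]
            if len(idx) < bs:
                idx = perm[:bs]
            x = Tensor(np.stack([np.asarray(dataset[i][0], np.float32)
                                 for i in idx])[:, None])
            y = Tensor(np.stack([np.asarray(dataset[i][1], np.float32)
                                 for i in idx])[:, None])

            fake, taps_in = _generator_forward(gen, x, collect=True)

            # discriminator step (least-squares GAN, RPR as "real")
            opt_d.zero_grad()
            pred_real = disc(y)
            pred_fake_d = disc(Tensor(fake.data.copy()))
            d_loss = ((pred_real - 1.0) ** 2.0).mean() * 0.5 \
                + (pred_fake_d ** 2.0).mean() * 0.5
            d_loss.backward()
            opt_d.step()

            # generator + feature-net step
            opt_g.zero_grad()
            pred_fake = disc(fake)
            adv = ((pred_fake - 1.0) ** 2.0).mean()
            pyr = pyramid_l1(build_pyramid(fake, y), weights)
            edge = edge_loss(fake, y)
            if use_contrastive:
                _, taps_out = gen.encode(fake * 2.0 - 1.0, collect=True)
                ids = [_sample_ids(patch_rng,
                                   t.shape[2] * t.shape[3],
                                   config.n_patches) for t in taps_in]
                feats_in = _project_taps(taps_in, proj, ids)
                feats_out = _project_taps(taps_out, proj, ids)
                hdce, src = contrastive_losses(feats_in, feats_out, config)
            else:
                hdce = Tensor(np.float32(0.0))
                src = Tensor(np.float32(0.0))
            g_loss = total_loss(
                {"adv": adv, "src": src, "hdce": hdce, "pyr": pyr, "edge": edge},
                weights)
            g_loss.backward()
            opt_g.step()

            rec = {"iteration": it, "g_total": float(g_loss.data),
                   "d_loss": float(d_loss.data), "adv": float(adv.data),
                   "pyr": float(pyr.data), "edge": float(edge.data),
                   "hdce": float(hdce.data), "src": float(src.data)}
            if not all(math.isfinite(v) for v in rec.values()):
                warnings.warn(f"divergence at iteration {it}; "
                              "restoring last good checkpoint")
                if last_good is not None:
                    gen.load_state_dict(last_good["gen"])
                    disc.load_state_dict(last_good["disc"])
                    proj.load_state_dict(last_good["proj"])
                state.iteration = it
                return state, log
            log.append(rec)
            if it % 50 == 0:
                last_good = {"gen": gen.state_dict(), "disc": disc.state_dict(),
                             "proj": proj.state_dict()}
            it += 1
    state.iteration = total_iters
    state.provenance.append({"event": "trained", "phase": config.phase,
                             "iterations": total_iters, "seed": config.seed})
    return state, log


def translate(slice2d: np.ndarray, state: ModelState) -> np.ndarray:
    """Enhance a single preprocessed slice (no reference image consumed)."""
    arr = np.asarray(slice2d, dtype=np.float32)
    if arr.ndim != 2:
        raise ValueError("translate expects a single 2-D slice")
    if arr.shape[0] % 4 or arr.shape[1] % 4:
        raise ValueError(
            f"slice shape {arr.shape} incompatible with the 4x down/upsampling "
            f"of the generator (trained at {state.config.input_size})")
    out = _generator_forward(state.generator, Tensor(arr[None, None]))
    return np.clip(out.data[0, 0].astype(np.float64), 0.0, 1.0)


# ---------------------------------------------------------------------------
# (de)serialization — single-file .npz checkpoints
# ---------------------------------------------------------------------------

def save_state(state: ModelState, path: str):
    arrays = {}
    for tag, mod in (("G", state.generator), ("D", state.discriminator),
                     ("F", state.projector)):
        for k, v in mod.state_dict().items():
            arrays[f"{tag}::{k}"] = v
    meta = {"config": asdict(state.config), "seed": state.seed,
            "iteration": state.iteration, "provenance": state.provenance}
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_state(path: str) -> ModelState:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        cfg_dict = meta["config"]
        for key in ("betas",):
            if key in cfg_dict and isinstance(cfg_dict[key], list):
                cfg_dict[key] = tuple(cfg_dict[key])
        config = TrainConfig(**cfg_dict)
        state = build_models(config, seed=meta["seed"])
        for tag, mod in (("G", state.generator), ("D", state.discriminator),
                         ("F", state.projector)):
            sd = {k.split("::", 1)[1]: npz[k] for k in npz.files
                  if k.startswith(tag + "::")}
            mod.load_state_dict(sd)
    state.iteration = meta["iteration"]
    state.provenance = meta["provenance"]
    return state
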
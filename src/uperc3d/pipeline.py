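"""Training and evaluation harness tying phantoms, losses and denoisers together.

The reference training protocol is 30 000 Adam iterations, batch 16, learning
rate 0.001, random 96^3 crops.  That is GPU-scale; this package additionally
defines a *desk scale* — batch/crop/iteration sizes chosen once so a full
experiment (three seeds, two losses) runs on a single CPU core — used by
:func:`desk_experiment` and the bundled acceptance study.  The property under
test is the same at either scale: training with the untrained perceptual loss
(or L1) must lift validation SSIM clearly above the noisy-input baseline.

Seed policy: one experiment seed deterministically derives independent
sub-seeds for model init, crop sampling and noise draws, so ablations vary
exactly one factor.  The loss network's own seed lives in its config.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .denoisers import DenoiserConfig, build_denoiser
from .loss_networks import LossNetConfig, build_loss_network
from .losses import l1_loss, perceptual_loss, ssim_objective
from .metrics import CropSpec, EvalResult, aggregate, evaluate_pair, ssim3d
from .phantoms import NoiseSpec, PhantomConfig, add_rician_noise, generate_phantom
from .volume import Volume3D

__all__ = ["TrainConfig", "TrainHistory", "make_training_pairs", "train",
           "denoise", "run_experiment", "desk_experiment", "make_phantom_sets",
           "save_checkpoint", "load_checkpoint"]

LOSSES = ("l1", "ssim", "upl")


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    Defaults are the desk-scale values; ``TrainConfig.reference()`` returns
    the full-scale protocol (30 000 iterations, batch 16, 96^3 crops).
    """

    iterations: int = 300
    batch_size: int = 4
    learning_rate: float = 1e-3
    crop_size: int = 32
    seed: int = 0
    loss: str = "upl"
    loss_net: LossNetConfig = field(default_factory=LossNetConfig)
    noise_level: float = 0.10
    loss_mix: float = 0.0  # fraction of L1 blended into the main loss
    validate_every: int = 50

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.loss not in LOSSES:
            raise ValueError(f"unknown loss {self.loss!r}; valid: {LOSSES}")
        if not 0.0 <= self.loss_mix <= 1.0:
            raise ValueError("loss_mix must lie in [0, 1]")

    @classmethod
    def reference(cls, **overrides) -> "TrainConfig":
        """The full-scale training protocol."""
        base = dict(iterations=30_000, batch_size=16, crop_size=96)
        base.update(overrides)
        return cls(**base)


@dataclass
class TrainHistory:
    losses: list[float] = field(default_factory=list)
    val_iterations: list[int] = field(default_factory=list)
    val_ssim: list[float] = field(default_factory=list)
    noisy_val_ssim: float = math.nan
    loss_net_checksum_before: float = math.nan
    loss_net_checksum_after: float = math.nan
    loss_net_intact: bool | None = None


def _subseeds(seed: int, n: int = 4) -> list[int]:
    """Derive independent 31-bit sub-seeds from one experiment seed."""
    return [int(s) % (2 ** 31) for s in np.random.SeedSequence(seed).generate_state(n)]


def _volume_noise_seed(base_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0]) % (2 ** 31)


def make_training_pairs(clean_set: list[Volume3D], noise: NoiseSpec,
                        crop_size: int, seed: int):
    """Infinite stream of spatially aligned (noisy crop, clean crop) arrays.

    Each volume is corrupted once (per-volume seed derived from
    ``noise.seed``); every draw picks a volume and a uniformly random corner
    and crops clean and noisy versions at identical coordinates.
    Deterministic given ``seed``.
    """
    if not clean_set:
        raise ValueError("empty training set")
    for v in clean_set:
        if min(v.shape) < crop_size:
            raise ValueError(
                f"crop size {crop_size} exceeds a training volume of shape {v.shape}")
    noisy_set = [add_rician_noise(v, NoiseSpec(noise.level, _volume_noise_seed(noise.seed, i)))
                 if noise.level > 0 else v
                 for i, v in enumerate(clean_set)]
    rng = np.random.default_rng(seed)
    c = crop_size
    while True:
        i = int(rng.integers(len(clean_set)))
        clean, noisy = clean_set[i], noisy_set[i]
        corner = [int(rng.integers(s - c + 1)) for s in clean.shape]
        sl = tuple(slice(o, o + c) for o in corner)
        yield noisy.data[sl], clean.data[sl]


def train(denoiser_cfg: DenoiserConfig, train_cfg: TrainConfig,
          train_set: list[Volume3D], val_set: list[Volume3D] | None = None):
    """Run the training loop; returns ``(model, TrainHistory)``.

    Exactly ``iterations`` optimizer steps; fully deterministic given the
    configs.  With the perceptual loss the extractor is built frozen before
    the first step and verified bit-identical afterwards.  A non-finite loss
    aborts with a diagnostic naming the iteration.
    """
    s_init, s_data, s_noise, _ = _subseeds(train_cfg.seed)
    model = build_denoiser(denoiser_cfg, seed=s_init)
    model.train()

    extractor = None
    pre_state = None
    if train_cfg.loss == "upl":
        extractor = build_loss_network(train_cfg.loss_net)
        pre_state = {k: v.copy() for k, v in extractor.state_dict().items()}

    history = TrainHistory()
    if extractor is not None:
        history.loss_net_checksum_before = extractor.checksum()

    pairs = make_training_pairs(train_set, NoiseSpec(train_cfg.noise_level, s_noise),
                                train_cfg.crop_size, s_data)
    opt = nn.Adam(model.parameters(), lr=train_cfg.learning_rate)

    val_clean = list(val_set) if val_set else []
    val_noisy = [add_rician_noise(v, NoiseSpec(train_cfg.noise_level,
                                               _volume_noise_seed(s_noise + 1, i)))
                 for i, v in enumerate(val_clean)]
    if val_clean:
        history.noisy_val_ssim = float(np.mean(
            [ssim3d(n, c) for n, c in zip(val_noisy, val_clean)]))

    def _objective(pred, target_arr):
        target = nn.Tensor(target_arr)
        if train_cfg.loss == "l1":
            main = l1_loss(pred, target)
        elif train_cfg.loss == "ssim":
            main = ssim_objective(pred, target)
        else:
            main = perceptual_loss(extractor, pred, target).tensor
        if train_cfg.loss_mix > 0 and train_cfg.loss != "l1":
            main = main * (1.0 - train_cfg.loss_mix) \
                + l1_loss(pred, target) * train_cfg.loss_mix
        return main

    for it in range(1, train_cfg.iterations + 1):
        batch = [next(pairs) for _ in range(train_cfg.batch_size)]
        noisy = np.stack([b[0] for b in batch])[:, None]
        clean = np.stack([b[1] for b in batch])[:, None]
        x = nn.Tensor(noisy)
        pred = model(x)
        loss = _objective(pred, clean)
        if not math.isfinite(loss.item()):
            raise RuntimeError(f"training diverged: non-finite loss at iteration {it}")
        history.losses.append(loss.item())
        opt.zero_grad()
        loss.backward()
        opt.step()
        if val_clean and (it % train_cfg.validate_every == 0
                          or it == train_cfg.iterations):
            vs = [ssim3d(denoise(model, n), c) for n, c in zip(val_noisy, val_clean)]
            history.val_iterations.append(it)
            history.val_ssim.append(float(np.mean(vs)))
            model.train()

    if extractor is not None:
        history.loss_net_checksum_after = extractor.checksum()
        post_state = extractor.state_dict()
        history.loss_net_intact = (
            pre_state.keys() == post_state.keys()
            and all(np.array_equal(pre_state[k], post_state[k]) for k in pre_state))
    return model, history


def denoise(model: nn.Module, vol: Volume3D) -> Volume3D:
    """Inference wrapper: eval-mode forward pass, output clamped to [0, 1]."""
    if min(vol.shape) < 8:
        raise ValueError(f"volume dims must be >= 8 per axis, got {vol.shape}")
    was_training = model.training
    model.eval()
    out = model(nn.Tensor(vol.data[None, None])).data[0, 0]
    if was_training:
        model.train()
    return Volume3D(np.clip(out, 0.0, 1.0), vol.spacing, dict(vol.meta))


def make_phantom_sets(phantom_cfg: PhantomConfig, n_train: int, n_val: int,
                      n_test: int, seed: int = 0):
    """Generate disjoint train/val/test phantom sets (disjoint seed ranges)."""
    train = [generate_phantom(phantom_cfg, seed + i) for i in range(n_train)]
    val = [generate_phantom(phantom_cfg, seed + 10_000 + i) for i in range(n_val)]
    test = [generate_phantom(phantom_cfg, seed + 20_000 + i) for i in range(n_test)]
    return train, val, test


# ---------------------------------------------------------------------------
# Desk-scale experiment (the package's scaled acceptance study)
# ---------------------------------------------------------------------------

#: Sizes chosen once for single-CPU runtime (see docs/methods.md).
DESK_SCALE = dict(iterations=150, batch_size=2, crop_size=16,
                  phantom_shape=(32, 32, 32), n_train=64, n_val=4,
                  noise_level=0.10)


def desk_experiment(loss: str, seed: int, scale: dict | None = None,
                    loss_net: LossNetConfig | None = None) -> dict:
    """Train a DnCNN with ``loss`` on synthetic tube phantoms at desk scale.

    Returns final/baseline validation SSIM and the SSIM gain over the noisy
    input — the scaled stand-in for the full-scale benchmark results.
    """
    sc = dict(DESK_SCALE)
    if scale:
        sc.update(scale)
    phantom_cfg = PhantomConfig(shape=sc["phantom_shape"])
    train_set, val_set, _ = make_phantom_sets(phantom_cfg, sc["n_train"], sc["n_val"], 0,
                                              seed=1000 * (seed + 1))
    cfg = TrainConfig(
        iterations=sc["iterations"], batch_size=sc["batch_size"],
        crop_size=sc["crop_size"], seed=seed, loss=loss,
        loss_net=loss_net or LossNetConfig(depth=3, kernel_size=3, n_features=32,
                                           init_method="xavier_normal"),
        noise_level=sc["noise_level"],
    )
    model, history = train(DenoiserConfig(architecture="dncnn"), cfg, train_set, val_set)
    final_ssim = history.val_ssim[-1]
    return {
        "loss": loss,
        "seed": seed,
        "noisy_ssim": history.noisy_val_ssim,
        "denoised_ssim": final_ssim,
        "ssim_gain": final_ssim - history.noisy_val_ssim,
        "loss_net_intact": history.loss_net_intact,
        "history": history,
        "model": model,
    }


def save_checkpoint(model: nn.Module, path: str | Path) -> None:
    """Save model weights with the architecture config embedded (.npz)."""
    cfg = getattr(model, "config", None)
    meta = json.dumps(asdict(cfg)) if cfg is not None else "{}"
    np.savez(path, __config__=np.array(meta), **model.state_dict())


def load_checkpoint(path: str | Path) -> nn.Module:
    """Rebuild the model described by a checkpoint and load its weights."""
    with np.load(path, allow_pickle=False) as data:
        cfg = DenoiserConfig(**json.loads(str(data["__config__"])))
        state = {k: data[k] for k in data.files if k != "__config__"}
    model = build_denoiser(cfg)
    model.load_state_dict(state)
    model.eval()
    return model


# ---------------------------------------------------------------------------
# Experiment grid
# ---------------------------------------------------------------------------

def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_experiment(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run a losses x architectures x noise-levels x seeds grid end to end.

    ``config`` is a dict (or path to a YAML file) with sections ``data``,
    ``noise``, ``denoiser``, ``loss``, ``train`` and ``eval``.  Every grid
    cell runs generate -> corrupt -> train -> denoise -> evaluate; one JSON
    report per cell plus a merged table keyed by (arch, loss, noise, seed)
    are written when ``out_dir`` is given.  Failures are recorded per cell
    and the grid continues.
    """
    if isinstance(config, (str, Path)):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    data = config.get("data", {})
    phantom_cfg = PhantomConfig(**data.get("phantom", {}))
    train_set, val_set, test_set = make_phantom_sets(
        phantom_cfg, data.get("n_train", 8), data.get("n_val", 2),
        data.get("n_test", 2), seed=data.get("seed", 0))

    noise_levels = config.get("noise", {}).get("levels", [0.10])
    archs = config.get("denoiser", {}).get("architectures", ["dncnn"])
    arch_overrides = config.get("denoiser", {}).get("overrides", {})
    losses = config.get("loss", {}).get("losses", ["upl"])
    loss_net_cfg = LossNetConfig(**config.get("loss", {}).get("loss_net", {}))
    tr = config.get("train", {})
    seeds = tr.get("seeds", [0])
    crop_kind = config.get("eval", {}).get("crop", "none")
    crop = CropSpec(kind=crop_kind) if crop_kind != "none" else None

    out_dir = Path(out_dir) if out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    cell_results: dict[tuple, EvalResult] = {}
    for arch in archs:
        for loss in losses:
            for level in noise_levels:
                for seed in seeds:
                    key = (arch, loss, level, seed)
                    try:
                        den_cfg = DenoiserConfig(architecture=arch,
                                                 **arch_overrides.get(arch, {}))
                        cfg = TrainConfig(
                            iterations=tr.get("iterations", 50),
                            batch_size=tr.get("batch_size", 2),
                            crop_size=tr.get("crop_size", 16),
                            learning_rate=tr.get("learning_rate", 1e-3),
                            validate_every=tr.get("validate_every", 50),
                            seed=seed, loss=loss, loss_net=loss_net_cfg,
                            noise_level=level)
                        model, history = train(den_cfg, cfg, train_set, val_set)
                        res = EvalResult(region=crop_kind, seed=seed)
                        for i, tv in enumerate(test_set):
                            noisy = add_rician_noise(
                                tv, NoiseSpec(level, _volume_noise_seed(90_000 + seed, i)))
                            pred = denoise(model, noisy)
                            res.add(*evaluate_pair(pred, tv, crop))
                        cell_results[key] = res
                        row = {"arch": arch, "loss": loss, "noise": level,
                               "seed": seed, "status": "ok",
                               "per_image": res.per_image,
                               "mean_ssim": float(np.mean(res.metric_values(0))),
                               "noisy_val_ssim": history.noisy_val_ssim,
                               "final_val_ssim": history.val_ssim[-1] if history.val_ssim else None}
                    except Exception as exc:  # record and continue the grid
                        row = {"arch": arch, "loss": loss, "noise": level,
                               "seed": seed, "status": "failed", "error": str(exc)}
                    rows.append(row)
                    if out_dir:
                        name = f"cell_{arch}_{loss}_n{level:g}_s{seed}.json"
                        (out_dir / name).write_text(
                            json.dumps(row, sort_keys=True, indent=1,
                                       default=_json_default))

    # merged per-(arch, loss, noise) aggregates over seeds
    merged = {}
    for (arch, loss, level), group in _group_cells(cell_results).items():
        agg = aggregate(group)
        merged[f"{arch}/{loss}/{level:g}"] = agg.aggregate
    report = {"rows": rows, "aggregate": merged}
    if out_dir:
        (out_dir / "merged.json").write_text(
            json.dumps(report, sort_keys=True, indent=1, default=_json_default))
    return report


def _group_cells(cells: dict[tuple, EvalResult]) -> dict[tuple, list[EvalResult]]:
    groups: dict[tuple, list[EvalResult]] = {}
    for (arch, loss, level, _seed), res in sorted(cells.items(), key=lambda kv: kv[0]):
        groups.setdefault((arch, loss, level), []).append(res)
    return groups
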
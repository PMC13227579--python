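"""Two-direction cycle training loop with structure self-supervision.

Each step runs both translation directions. For an FI image ``x`` with
extracted structure label ``x_s``: the FI->FFA generator produces the fake
angiogram ``y'`` and the predicted source structure ``x'_s``; the reverse
generator then closes the cycle, producing ``x''`` and ``x''_s``. The
symmetric pass starts from a real FFA image. Four PatchGAN critics score
fake FI, fake FFA and the two fake structure rasters; critics are updated
first on detached fakes, then both generators are updated on the combined
objective. Ablation switches: ``use_ssm`` removes the auxiliary structure
outputs, their losses and the structure critics; ``use_cl`` removes the
cycle pass and its norm losses.

All randomness (weight init, data order, crops, flips) flows from the
config seed. The optimizer is RMSProp for all six networks with a shared
learning-rate schedule: constant, then linear decay to zero.
"""

from __future__ import annotations

import json

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .image_io import PairRecord, RasterImage, load_manifest, paired_augment, read_image
from .networks import (
    DiscriminatorConfig,
    GeneratorConfig,
    PatchDiscriminator,
    TranslationBundle,
    UNetGenerator,
)
from .nn import RMSProp, Tensor, concat
from .objectives import DirectionTerms, LossComponents, LossConfig, total_objectives
from .structure import ExtractionParams, extract_structure

__all__ = [
    "TrainConfig",
    "lr_at_epoch",
    "build_models",
    "train_step",
    "compute_structure_labels",
    "fit",
    "save_checkpoint",
    "load_checkpoint",
    "translate",
]

DISCRIMINATOR_NAMES = ("fi", "ffa", "fis", "ffas")


@dataclass
class TrainConfig:
    epochs: int = 200
    decay_start_epoch: int = 150
    lr: float = 2e-4
    batch_size: int = 3
    load_size: int = 286
    crop_size: int = 256
    seed: int = 0
    use_ssm: bool = True
    use_cl: bool = True
    cycle_input_mode: str = "image"  # image | image_plus_structure | structure
    hflip: bool = True
    gen_depth: int = 7
    gen_base_channels: int = 64
    disc_n_layers: int = 3
    disc_base_channels: int = 64
    lambda1: float = 10.0
    lambda2: float = 10.0
    lambda_struct: float = 1.0
    lambda_cyc: float = 10.0
    rmsprop_alpha: float = 0.99
    rmsprop_eps: float = 1e-8
    checkpoint_every: int = 0  # 0: final checkpoint only

    def __post_init__(self):
        if not self.decay_start_epoch < self.epochs:
            raise ValueError("decay_start_epoch must be < epochs")
        if self.crop_size > self.load_size:
            raise ValueError("crop_size must be <= load_size")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.cycle_input_mode not in ("image", "image_plus_structure", "structure"):
            raise ValueError(f"unknown cycle_input_mode {self.cycle_input_mode!r}")

    @classmethod
    def tiny(cls, **kw) -> "TrainConfig":
        """CPU-friendly preset for small synthetic experiments."""
        kw.setdefault("epochs", 30)
        kw.setdefault("decay_start_epoch", 20)
        kw.setdefault("load_size", 72)
        kw.setdefault("crop_size", 64)
        kw.setdefault("gen_depth", 3)
        kw.setdefault("gen_base_channels", 16)
        kw.setdefault("disc_base_channels", 16)
        kw.setdefault("disc_n_layers", 2)
        return cls(**kw)

    def loss_config(self) -> LossConfig:
        return LossConfig(self.lambda1, self.lambda2, self.lambda_struct, self.lambda_cyc)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def lr_at_epoch(epoch: int, cfg: TrainConfig) -> float:
    """Constant ``lr`` before the decay start, then linear decay to zero."""
    if epoch < 0 or epoch > cfg.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs}]")
    if epoch <= cfg.decay_start_epoch:
        return cfg.lr
    return cfg.lr * (1.0 - (epoch - cfg.decay_start_epoch) / (cfg.epochs - cfg.decay_start_epoch))


def _gen_in_channels(cfg: TrainConfig) -> int:
    return 4 if cfg.cycle_input_mode == "image_plus_structure" else 3


def build_models(cfg: TrainConfig, rng: np.random.Generator | None = None) -> dict:
    """Instantiate the two generators and the four-critic registry."""
    rng = rng or np.random.default_rng(cfg.seed)
    gcfg = GeneratorConfig(
        in_channels=_gen_in_channels(cfg), depth=cfg.gen_depth, base_channels=cfg.gen_base_channels,
        max_channels=min(512, cfg.gen_base_channels * 8),
    )
    dcfg_img = DiscriminatorConfig(3, cfg.disc_n_layers, cfg.disc_base_channels)
    dcfg_str = DiscriminatorConfig(1, cfg.disc_n_layers, cfg.disc_base_channels)
    models = {
        "G_fi2ffa": UNetGenerator(gcfg, rng=rng),
        "G_ffa2fi": UNetGenerator(gcfg, rng=rng),
        "D_fi": PatchDiscriminator(dcfg_img, rng=rng),
        "D_ffa": PatchDiscriminator(dcfg_img, rng=rng),
        "D_fis": PatchDiscriminator(dcfg_str, rng=rng),
        "D_ffas": PatchDiscriminator(dcfg_str, rng=rng),
    }
    assert tuple(n[2:] for n in models if n.startswith("D_")) == DISCRIMINATOR_NAMES
    return models


def build_optimizers(models: dict, cfg: TrainConfig) -> dict:
    return {
        name: RMSProp(net.parameters(), lr=cfg.lr, alpha=cfg.rmsprop_alpha, eps=cfg.rmsprop_eps)
        for name, net in models.items()
    }


def _to_net(img01: np.ndarray) -> np.ndarray:
    return (2.0 * img01 - 1.0).astype(np.float32)


def _from_net(img_pm1: np.ndarray) -> np.ndarray:
    return np.clip((img_pm1 + 1.0) / 2.0, 0.0, 1.0).astype(np.float32)


def _repeat3(t: Tensor) -> Tensor:
    return concat([t, t, t], axis=1)


def _gen_input(img: Tensor, struct: Tensor | np.ndarray | None, mode: str) -> Tensor:
    if mode == "image_plus_structure":
        s = struct if isinstance(struct, Tensor) else Tensor(struct)
        return concat([img, s * 2.0 - 1.0], axis=1)
    return img


def _cycle_input(y_hat: Tensor, s_hat: Tensor | None, mode: str) -> Tensor:
    if mode == "image":
        return y_hat
    if s_hat is None:
        raise ValueError("cycle_input_mode needs the structure output; enable use_ssm")
    if mode == "structure":
        return _repeat3(s_hat * 2.0 - 1.0)
    return concat([y_hat, s_hat * 2.0 - 1.0], axis=1)


def _direction_pass(g_fwd: UNetGenerator, g_bwd: UNetGenerator, x: Tensor,
                    src_label: np.ndarray, cfg: TrainConfig) -> TranslationBundle:
    mode = cfg.cycle_input_mode
    y_hat, s_hat = g_fwd(_gen_input(x, src_label, mode), with_structure=cfg.use_ssm)
    x_cyc = s_cyc = None
    if cfg.use_cl:
        x_cyc, s_cyc = g_bwd(_cycle_input(y_hat, s_hat, mode), with_structure=cfg.use_ssm)
    return TranslationBundle(x=x, y_hat=y_hat, s_hat=s_hat, x_cyc=x_cyc, s_cyc=s_cyc)


def train_step(batch: dict, models: dict, opts: dict, cfg: TrainConfig,
               loss_cfg: LossConfig | None = None) -> LossComponents:
    """One optimization step on a batch; critics first, then generators.

    ``batch`` holds float32 arrays: ``fi``/``ffa`` as (N, 3, H, W) in [0, 1]
    and ``fi_struct``/``ffa_struct`` as (N, 1, H, W) binary labels from the
    classical extractor.
    """
    loss_cfg = loss_cfg or cfg.loss_config()
    for k in ("fi", "ffa", "fi_struct", "ffa_struct"):
        if k not in batch:
            raise ValueError(f"batch missing {k!r}")
    if batch["fi"].shape != batch["ffa"].shape or batch["fi"].shape[2:] != batch["fi_struct"].shape[2:]:
        raise ValueError("batch arrays disagree on shape")

    x = Tensor(_to_net(batch["fi"]))
    y = Tensor(_to_net(batch["ffa"]))
    xs = batch["fi_struct"].astype(np.float32)
    ys = batch["ffa_struct"].astype(np.float32)

    g_ab, g_ba = models["G_fi2ffa"], models["G_ffa2fi"]
    fwd = _direction_pass(g_ab, g_ba, x, xs, cfg)  # x' of FFA domain
    bwd = _direction_pass(g_ba, g_ab, y, ys, cfg)

    # ---------------- discriminator updates (detached fakes) ----------------
    d_specs = {
        "ffa": (models["D_ffa"], y, fwd.y_hat),
        "fi": (models["D_fi"], x, bwd.y_hat),
    }
    if cfg.use_ssm:
        d_specs["fis"] = (models["D_fis"], Tensor(xs), fwd.s_hat)
        d_specs["ffas"] = (models["D_ffas"], Tensor(ys), bwd.s_hat)

    d_scores_for_report: dict[str, tuple] = {}
    from .objectives import lsgan_d_loss

    for name, (disc, real, fake) in d_specs.items():
        opt = opts[f"D_{name}"]
        opt.zero_grad()
        r_sc = disc(real.detach() if isinstance(real, Tensor) else Tensor(real))
        f_sc = disc(fake.detach())
        loss = lsgan_d_loss(r_sc, f_sc, loss_cfg.real_target, loss_cfg.fake_target)
        loss.backward()
        opt.step()
        d_scores_for_report[name] = (r_sc.detach(), f_sc.detach())

    # ---------------- generator update --------------------------------------
    for name in ("G_fi2ffa", "G_ffa2fi"):
        opts[name].zero_grad()
    for name in d_specs:
        models[f"D_{name}"].zero_grad()

    fi_terms = DirectionTerms(
        bundle=fwd, source_structure=xs, target_image=y.detach(),
        g_scores_image=models["D_ffa"](fwd.y_hat),
        g_scores_structure=models["D_fis"](fwd.s_hat) if cfg.use_ssm else None,
        d_scores={k: d_scores_for_report[k] for k in ("ffa", "fis") if k in d_scores_for_report},
    )
    ffa_terms = DirectionTerms(
        bundle=bwd, source_structure=ys, target_image=x.detach(),
        g_scores_image=models["D_fi"](bwd.y_hat),
        g_scores_structure=models["D_ffas"](bwd.s_hat) if cfg.use_ssm else None,
        d_scores={k: d_scores_for_report[k] for k in ("fi", "ffas") if k in d_scores_for_report},
    )
    total_g, _, comps = total_objectives(fi_terms, ffa_terms, loss_cfg,
                                         use_ssm=cfg.use_ssm, use_cl=cfg.use_cl)
    if not np.isfinite(comps.total_g):
        raise FloatingPointError("non-finite generator loss")
    total_g.backward()
    opts["G_fi2ffa"].step()
    opts["G_ffa2fi"].step()
    for m in models.values():
        m.zero_grad()
    return comps


def compute_structure_labels(records: list[PairRecord],
                             params: ExtractionParams | None = None) -> list[dict]:
    """Load each pair and extract both structure labels (cached by ``fit``)."""
    out = []
    for rec in records:
        fi = read_image(rec.fi_path, modality="FI")
        ffa = read_image(rec.ffa_path, modality="FFA")
        out.append(
            {
                "fi": fi.pixels,
                "ffa": ffa.pixels,
                "fi_struct": extract_structure(fi, "FI", params).pixels,
                "ffa_struct": extract_structure(ffa, "FFA", params).pixels,
            }
        )
    return out


def fit(manifest: str | list[PairRecord], cfg: TrainConfig, out_dir: str | Path,
        resume: str | Path | None = None) -> dict:
    """Train on a manifest of pseudo-paired images; returns paths + metrics.

    Structure labels are extracted once from the full-size images and then
    augmented alongside the images (shared crop/flip, nearest-neighbor
    resampling); per-epoch mean loss components go to ``metrics.csv`` and
    the final networks + optimizer state to ``checkpoint_final.npz``.
    """
    records = load_manifest(manifest) if isinstance(manifest, (str, Path)) else list(manifest)
    if not records:
        raise ValueError("empty manifest")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(cfg.seed)
    init_ss, data_ss = ss.spawn(2)
    models = build_models(cfg, rng=np.random.default_rng(init_ss))
    opts = build_optimizers(models, cfg)
    data_rng = np.random.default_rng(data_ss)
    start_epoch = 0
    if resume is not None:
        state = load_checkpoint(resume)
        _check_config(state["config"], cfg)
        for name, net in models.items():
            net.load_state_dict(state["weights"][name])
        for name, opt in opts.items():
            opt.load_state_dict(state["optimizers"][name])
        start_epoch = int(state["epoch"]) + 1
        data_rng.bit_generator.state = state["rng_state"]

    data = compute_structure_labels(records)
    loss_cfg = cfg.loss_config()
    rows = []
    n = len(data)
    iter_log = open(out_dir / "iterations.jsonl", "a" if resume else "w")
    for epoch in range(start_epoch, cfg.epochs):
        lr = lr_at_epoch(epoch, cfg)
        for opt in opts.values():
            opt.lr = lr
        order = data_rng.permutation(n)
        epoch_comps: list[LossComponents] = []
        for it, b0 in enumerate(range(0, n, cfg.batch_size)):
            idx = order[b0 : b0 + cfg.batch_size]
            batch = _make_batch([data[i] for i in idx], cfg, data_rng)
            comps = train_step(batch, models, opts, cfg, loss_cfg)
            epoch_comps.append(comps)
            iter_log.write(json.dumps({"epoch": epoch, "iter": it, **comps.as_dict()}) + "\n")
        mean = {k: float(np.mean([c.as_dict()[k] for c in epoch_comps]))
                for k in epoch_comps[0].as_dict()}
        mean.update({"epoch": epoch, "lr": lr})
        rows.append(mean)
        if cfg.checkpoint_every and (epoch + 1) % cfg.checkpoint_every == 0:
            save_checkpoint(out_dir / f"checkpoint_{epoch:04d}.npz", models, opts, cfg, epoch, data_rng)

    iter_log.close()
    metrics = pd.DataFrame(rows)
    metrics.to_csv(out_dir / "metrics.csv", index=False)
    ckpt = out_dir / "checkpoint_final.npz"
    save_checkpoint(ckpt, models, opts, cfg, cfg.epochs - 1, data_rng)
    return {"checkpoint": str(ckpt), "metrics": str(out_dir / "metrics.csv"),
            "final_epoch_metrics": rows[-1] if rows else {}}


def _make_batch(samples: list[dict], cfg: TrainConfig, rng: np.random.Generator) -> dict:
    fis, ffas, fss, ffss = [], [], [], []
    for s in samples:
        fi, ffa, fs, ffs, _ = paired_augment(
            s["fi"], s["ffa"], s["fi_struct"][:, :, None].astype(np.float32),
            s["ffa_struct"][:, :, None].astype(np.float32),
            cfg.load_size, cfg.crop_size, rng, hflip=cfg.hflip,
        )
        fis.append(fi.transpose(2, 0, 1))
        ffas.append(ffa.transpose(2, 0, 1))
        fss.append(fs.transpose(2, 0, 1))
        ffss.append(ffs.transpose(2, 0, 1))
    return {
        "fi": np.stack(fis).astype(np.float32),
        "ffa": np.stack(ffas).astype(np.float32),
        "fi_struct": np.stack(fss).astype(np.float32),
        "ffa_struct": np.stack(ffss).astype(np.float32),
    }


# ------------------------------------------------------------ checkpointing

def save_checkpoint(path: str | Path, models: dict, opts: dict, cfg: TrainConfig,
                    epoch: int, data_rng: np.random.Generator | None = None) -> None:
    path = Path(path)
    arrays = {}
    for name, net in models.items():
        for pn, arr in net.state_dict().items():
            arrays[f"w::{name}::{pn}"] = arr
    for name, opt in opts.items():
        sd = opt.state_dict()
        for i, v in enumerate(sd["v"]):
            arrays[f"o::{name}::v{i}"] = v
    meta = {
        "config": asdict(cfg),
        "epoch": int(epoch),
        "optim": {name: {k: opt.state_dict()[k] for k in ("lr", "alpha", "eps")} for name, opt in opts.items()},
        "rng_state": _jsonify(data_rng.bit_generator.state) if data_rng is not None else None,
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path: str | Path) -> dict:
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["meta_json"].tobytes()).decode())
        weights: dict[str, dict] = {}
        optim_v: dict[str, dict[int, np.ndarray]] = {}
        for key in z.files:
            if key.startswith("w::"):
                _, name, pn = key.split("::", 2)
                weights.setdefault(name, {})[pn] = z[key]
            elif key.startswith("o::"):
                _, name, vk = key.split("::", 2)
                optim_v.setdefault(name, {})[int(vk[1:])] = z[key]
    optimizers = {}
    for name, vs in optim_v.items():
        sd = dict(meta["optim"][name])
        sd["v"] = [vs[i] for i in sorted(vs)]
        optimizers[name] = sd
    return {
        "config": meta["config"],
        "epoch": meta["epoch"],
        "weights": weights,
        "optimizers": optimizers,
        "rng_state": _dejsonify(meta["rng_state"]) if meta["rng_state"] else None,
    }


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return {"__ndarray__": obj.tolist(), "dtype": str(obj.dtype)}
    return obj


def _dejsonify(obj):
    if isinstance(obj, dict):
        if "__ndarray__" in obj:
            return np.asarray(obj["__ndarray__"], dtype=obj["dtype"])
        return {k: _dejsonify(v) for k, v in obj.items()}
    return obj


def _check_config(saved: dict, cfg: TrainConfig) -> None:
    current = asdict(cfg)
    for k in ("gen_depth", "gen_base_channels", "disc_n_layers", "disc_base_channels",
              "cycle_input_mode", "epochs", "decay_start_epoch"):
        if saved.get(k) != current[k]:
            raise ValueError(f"checkpoint config mismatch on {k}: {saved.get(k)} vs {current[k]}")


# ---------------------------------------------------------------- inference

def translate(img: RasterImage, checkpoint: str | Path, direction: str = "fi2ffa",
              params: ExtractionParams | None = None) -> tuple[RasterImage, np.ndarray]:
    """Translate one image through a trained generator (inference mode).

    Returns the translated image ([0, 1] pixels) and the predicted
    structure raster. The checkpoint's network configuration is rebuilt and
    validated; an unknown direction or incompatible image size is an error.
    """
    if direction not in ("fi2ffa", "ffa2fi"):
        raise ValueError(f"direction must be fi2ffa or ffa2fi, got {direction!r}")
    state = load_checkpoint(checkpoint)
    cfg = TrainConfig(**state["config"])
    models = build_models(cfg, rng=np.random.default_rng(0))
    name = "G_fi2ffa" if direction == "fi2ffa" else "G_ffa2fi"
    models[name].load_state_dict(state["weights"][name])
    gen = models[name]

    px = img.pixels
    if px.shape[2] == 1:
        px = np.repeat(px, 3, axis=2)
    h, w = px.shape[:2]
    div = 2**cfg.gen_depth
    if h % div or w % div:
        raise ValueError(f"image size {h}x{w} not divisible by {div}; resize first")
    x = Tensor(_to_net(px.transpose(2, 0, 1)[None]))
    if cfg.cycle_input_mode == "image_plus_structure":
        modality = "FI" if direction == "fi2ffa" else "FFA"
        label = extract_structure(img, modality, params).pixels[None, None].astype(np.float32)
        x = concat([x, Tensor(label * 2.0 - 1.0)], axis=1)
    y, s = gen(x, with_structure=True)
    out_img = RasterImage(_from_net(y.data[0]).transpose(1, 2, 0),
                          modality="FFA" if direction == "fi2ffa" else "FI")
    return out_img, s.data[0, 0].copy()
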
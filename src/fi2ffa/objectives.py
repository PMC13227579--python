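"""Loss system for structure self-supervised cycle translation.

Six families of terms, all built from the first-order (L1) norm and the
least-squares adversarial objective:

* structure losses — L1 between each generator's auxiliary structure output
  and the structure label extracted from the *source* image (the structural
  content of the input must survive translation);
* generation losses — lambda-weighted L1 between the translated image and
  its pseudo-paired target (lambda_1 = lambda_2 = 10);
* adversarial losses — least-squares GAN with real/fake codes 1/0 and
  generator target 1; the discriminator side carries the conventional 1/2
  factor. Four critics score FI, FFA and the two structure domains;
* cycle losses — L1 between the round-trip reconstruction (image and
  structure) and the source; cycle intermediates receive *only* norm
  losses, never an adversarial term.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .networks import TranslationBundle
from .nn import Tensor

__all__ = [
    "LossConfig",
    "LossComponents",
    "l1_loss",
    "structure_loss",
    "generation_loss",
    "lsgan_d_loss",
    "lsgan_g_loss",
    "cycle_losses",
    "total_objectives",
    "DirectionTerms",
]


@dataclass
class LossConfig:
    lambda1: float = 10.0  # FI-direction generation weight
    lambda2: float = 10.0  # FFA-direction generation weight
    lambda_struct: float = 1.0  # weight on the structure L1 terms
    lambda_cyc: float = 10.0  # weight on the cycle norm terms
    real_target: float = 1.0
    fake_target: float = 0.0
    gen_target: float = 1.0

    def __post_init__(self):
        if min(self.lambda1, self.lambda2, self.lambda_struct, self.lambda_cyc) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class LossComponents:
    """Per-term loss values of one training step (floats, detached)."""

    struct_fi: float = 0.0
    struct_ffa: float = 0.0
    gen_fi: float = 0.0
    gen_ffa: float = 0.0
    adv_g_fi: float = 0.0
    adv_g_ffa: float = 0.0
    adv_g_fis: float = 0.0
    adv_g_ffas: float = 0.0
    adv_d_fi: float = 0.0
    adv_d_ffa: float = 0.0
    adv_d_fis: float = 0.0
    adv_d_ffas: float = 0.0
    cyc_img_fi: float = 0.0
    cyc_struct_fi: float = 0.0
    cyc_img_ffa: float = 0.0
    cyc_struct_ffa: float = 0.0
    total_g: float = 0.0
    total_d: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    def generator_parts(self) -> dict[str, float]:
        keys = [
            "struct_fi", "struct_ffa", "gen_fi", "gen_ffa",
            "adv_g_fi", "adv_g_ffa", "adv_g_fis", "adv_g_ffas",
            "cyc_img_fi", "cyc_struct_fi", "cyc_img_ffa", "cyc_struct_ffa",
        ]
        return {k: float(getattr(self, k)) for k in keys}


def _as_tensor(a) -> Tensor:
    """Wrap arrays without downcasting: float64 inputs keep full precision
    (the analytic loss identities hold to 1e-8); network tensors stay
    float32."""
    if isinstance(a, Tensor):
        return a
    arr = np.asarray(a)
    if arr.dtype != np.float64:
        arr = arr.astype(np.float32)
    return Tensor(arr, dtype=arr.dtype)


def l1_loss(a, b) -> Tensor:
    """Mean absolute elementwise difference (first-order norm)."""
    a, b = _as_tensor(a), _as_tensor(b)
    if a.shape != b.shape:
        raise ValueError(f"l1_loss: shape mismatch {a.shape} vs {b.shape}")
    return (a - b).abs().mean()


def structure_loss(pred_structure, label_structure) -> Tensor:
    """L1 between the auxiliary structure output and its extracted label."""
    label = getattr(label_structure, "pixels", label_structure)
    return l1_loss(pred_structure, np.asarray(label, dtype=np.float32))


def generation_loss(pred_img, target_img, lam: float = 10.0) -> Tensor:
    """Weighted L1 between the translated image and its pseudo-paired target."""
    return l1_loss(pred_img, target_img) * float(lam)


def lsgan_d_loss(d_real_scores, d_fake_scores, real_target: float = 1.0, fake_target: float = 0.0) -> Tensor:
    """Discriminator-side least-squares loss on raw patch scores.

    0.5 * mean((D(real) - 1)^2) + 0.5 * mean((D(fake) - 0)^2); the fake
    scores must come from detached generator output.
    """
    r, f = _as_tensor(d_real_scores), _as_tensor(d_fake_scores)
    return ((r - real_target) ** 2).mean() * 0.5 + ((f - fake_target) ** 2).mean() * 0.5


def lsgan_g_loss(d_fake_scores, gen_target: float = 1.0) -> Tensor:
    """Generator-side least-squares loss: mean((D(fake) - 1)^2)."""
    f = _as_tensor(d_fake_scores)
    return ((f - gen_target) ** 2).mean()


def cycle_losses(bundle: TranslationBundle, source_structure, lam_cyc: float = 10.0) -> tuple[Tensor, Tensor]:
    """Norm losses on the cycle intermediates (no adversarial term).

    cyc_img = lam * L1(x'', x); cyc_struct = lam * L1(x''_s, struct(x)).
    """
    if bundle.x_cyc is None or bundle.s_cyc is None:
        raise ValueError("cycle_losses: bundle is missing cycle tensors")
    label = getattr(source_structure, "pixels", source_structure)
    cyc_img = l1_loss(bundle.x_cyc, bundle.x.detach()) * float(lam_cyc)
    cyc_struct = l1_loss(bundle.s_cyc, np.asarray(label, dtype=np.float32)) * float(lam_cyc)
    return cyc_img, cyc_struct


@dataclass
class DirectionTerms:
    """Everything the objective needs for one translation direction."""

    bundle: TranslationBundle
    source_structure: object  # StructureMap or binary array, label of bundle.x
    target_image: object  # pseudo-paired target for the generation L1
    g_scores_image: Tensor | None = None  # D(fake image), generator side
    g_scores_structure: Tensor | None = None  # D(fake structure), generator side
    d_scores: dict = field(default_factory=dict)
    # d_scores maps critic name -> (real_scores, fake_scores_detached)


def _val(t) -> float:
    return float(np.asarray(t.data if isinstance(t, Tensor) else t))


def total_objectives(fi_dir: DirectionTerms, ffa_dir: DirectionTerms, cfg: LossConfig,
                     use_ssm: bool = True, use_cl: bool = True):
    """Compose the full objective for both directions.

    Returns ``(total_g, total_d, components)`` where the totals are autodiff
    scalars and ``components`` is the detached numeric breakdown. ``fi_dir``
    is the FI -> FFA direction (source x is an FI image); ``ffa_dir`` is the
    reverse. With ``use_ssm`` off, structure terms and structure critics are
    excluded; with ``use_cl`` off, cycle terms are excluded.
    """
    comps = LossComponents()
    zero = Tensor(np.zeros((), dtype=np.float32))
    total_g = zero
    total_d = zero

    for name, d, lam_gen, tag in (
        ("fi", fi_dir, cfg.lambda2, "ffa"),  # FI source -> fake FFA judged by D_FFA
        ("ffa", ffa_dir, cfg.lambda1, "fi"),
    ):
        b = d.bundle
        g_img = generation_loss(b.y_hat, d.target_image, lam_gen)
        setattr(comps, f"gen_{tag}", _val(g_img))
        total_g = total_g + g_img

        adv_img = lsgan_g_loss(d.g_scores_image, cfg.gen_target)
        setattr(comps, f"adv_g_{tag}", _val(adv_img))
        total_g = total_g + adv_img

        if use_ssm:
            s = structure_loss(b.s_hat, d.source_structure) * cfg.lambda_struct
            setattr(comps, f"struct_{name}", _val(s))
            total_g = total_g + s
            adv_s = lsgan_g_loss(d.g_scores_structure, cfg.gen_target)
            setattr(comps, f"adv_g_{name}s", _val(adv_s))
            total_g = total_g + adv_s

        if use_cl:
            if use_ssm:
                cyc_i, cyc_s = cycle_losses(b, d.source_structure, cfg.lambda_cyc)
                setattr(comps, f"cyc_struct_{name}", _val(cyc_s))
                total_g = total_g + cyc_s
            else:
                if b.x_cyc is None:
                    raise ValueError("cycle learning enabled but bundle has no cycle image")
                cyc_i = l1_loss(b.x_cyc, b.x.detach()) * cfg.lambda_cyc
            setattr(comps, f"cyc_img_{name}", _val(cyc_i))
            total_g = total_g + cyc_i

        for critic, (real_sc, fake_sc) in d.d_scores.items():
            dl = lsgan_d_loss(real_sc, fake_sc, cfg.real_target, cfg.fake_target)
            setattr(comps, f"adv_d_{critic}", _val(dl))
            total_d = total_d + dl

    for t in ("total_g", "total_d"):
        v = _val(total_g if t == "total_g" else total_d)
        if not np.isfinite(v):
            bad = [k for k, x in comps.as_dict().items() if not np.isfinite(x)]
            raise FloatingPointError(f"non-finite loss component(s): {bad or [t]}")
        setattr(comps, t, v)
    return total_g, total_d, comps
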
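# fi2ffa

Translation of color fundus images (FI) into fundus fluorescein
angiography (FFA) appearance — and back — with **structure self-supervised
cycle learning**, plus everything needed to develop and test the method
without clinical data: a synthetic pseudo-paired phantom generator, a
classical vessel-structure extractor, and FID/KID evaluation.

## Why

FFA shows the retinal vasculature in high contrast but requires injecting
fluorescein dye, which some patients cannot tolerate. Synthesizing an
FFA-style image from an ordinary fundus photograph offers a non-invasive
surrogate. The failure mode of naive image-to-image translation here is
structural: generated angiograms drop real vessels or invent meaningless
capillaries. This package attacks that directly by making the vascular
structure itself the supervision signal.

## Method in brief

Two U-shaped generators translate FI→FFA and FFA→FI directions; four
PatchGAN critics score fake FI, fake FFA and the two fake structure
rasters (least-squares GAN). A deterministic classical pipeline — green
channel, field-of-view masking, histogram + adaptive equalization,
homomorphic filtering, gamma 1.5, an oriented line detector (length 10,
width 1), min-max stretch, Otsu — extracts a binary vessel structure
`s(x)` from any image, for free. Each generator carries an auxiliary
decoder trained to reproduce `s(input)` (L1 + structure critic), and each
direction is closed into a cycle whose reconstruction and structure get
norm-only (L1) penalties:

```
L_G = Σ_dir [ λ·L1(fake, pseudo-paired target)      λ1 = λ2 = 10
            + LSGAN_G(D_img) + LSGAN_G(D_struct)
            + λ_s·L1(ŝ, s(x))                        λ_s = 1
            + λ_c·L1(x'', x) + λ_c·L1(s''̂, s(x)) ]   λ_c = 10
L_D = Σ_critics ½·mean((D(real)−1)²) + ½·mean(D(fake)²)
```

Training uses RMSProp (lr 2e-4, batch 3, instance norm), constant lr then
linear decay to zero. Real FI/FFA pairs are only *pseudo-paired* (small
rigid displacement), which the synthetic generator reproduces.

The neural-network layer (`fi2ffa.nn`) is a compact float32 reverse-mode
autodiff engine on numpy — conv / transposed-conv / max-pool / instance
norm / RMSProp — with every primitive gradient-checked against finite
differences.

## Worked example

```python
import numpy as np
from fi2ffa import (TrainConfig, extract_structure, fit, make_paired_dataset,
                    read_image, structure_preservation_score, translate)
from fi2ffa.evaluation import dice
from fi2ffa.synthetic import generate_vessel_tree, rasterize_structure, render_fi

# 1. classical structure extraction on a synthetic phantom with known truth
scene = generate_vessel_tree(seed=0, field_radius=128.0)
img = render_fi(scene, 256, seed=100)
gt = rasterize_structure(scene, 256)
print("extraction Dice vs ground truth:", round(dice(extract_structure(img, "FI").pixels, gt), 3))

# 2. train the tiny preset on 20 pseudo-pairs and translate
recs = make_paired_dataset(20, size=72, seed=0, max_misalign_px=2.0, out_dir="scratch/demo")
res = fit(recs, TrainConfig.tiny(seed=0), "scratch/demo_run")
fi = read_image(recs[0].fi_path, "FI")
fake_ffa, pred_structure = translate(fi, res["checkpoint"], "fi2ffa")
print("structure preservation:", round(structure_preservation_score(fi, fake_ffa, "FI", "FFA"), 3))
```

Printed on this machine:

```
extraction Dice vs ground truth: 0.742
structure preservation: 0.732
```

The first number says the classical extractor recovers ~74% (Dice) of the
phantom's true vessel mask from the rendered fundus image. The second says
that after the ~3-minute tiny training run, the vessels extracted from the
translated angiogram overlap the input's vessels at Dice ≈ 0.73 — an
untrained generator scores ≈ 0.2 on the same images.

A CLI wraps the same functionality:

```bash
fi2ffa synth --n 20 --size 256 --seed 0 --misalign 3 --out data/
fi2ffa extract-structure --in data/pair_0000_fi.png --modality fi --out struct.png
fi2ffa train --manifest data/manifest.csv --tiny --out run/
fi2ffa translate --in data/pair_0000_fi.png --ckpt run/checkpoint_final.npz --direction fi2ffa --out out/
fi2ffa eval --real data_real/ --fake out/ --metric fid,kid --out report.json
```

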
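# mindsct

Structure-constrained unpaired MRI→CT translation for the chest, with a
modality-independent neighbourhood descriptor (MIND) consistency loss.

## The problem

PET/MRI scanners need CT-like attenuation maps, but MRI carries no direct
information about photon attenuation, and in the chest no paired MRI/CT
training data can be acquired (breathing, cardiac motion and posture make
registration impractical).  Unpaired translation networks (CycleGAN,
U-GAT-IT) can synthesise CT-contrast images from MRI, but nothing in their
objectives stops them from quietly moving or deleting anatomy — fatal for
attenuation correction, where bone position is exactly what matters.

This package implements the structure-constrained remedy: add to the
translation objective a penalty on the change of the MIND descriptor,

    MIND(I, x, r) = (1/n) · exp(−D_p(I, x, x+r) / V(I, x)),  r ∈ R,

a per-pixel vector of exponentiated, variance-normalised patch
self-dissimilarities (`D_p` a patch SSD, `V` a local variance estimate,
`n` normalising the channel maximum to 1).  MIND is invariant to affine
intensity changes, so it describes local geometry in a way that transfers
across modalities; penalising

    L_MIND = E‖MIND(G(I)) − MIND(I)‖₁

anchors anatomy through the contrast swap.  The package provides:

* `mindsct.mind` — the descriptor and loss (vectorised and
  differentiable paths), plus a scikit-learn `MINDDescriptor` transformer;
* `mindsct.losses` — CycleGAN and U-GAT-IT objectives (adversarial,
  cycle, identity, CAM) and their MIND-augmented totals;
* `mindsct.networks` — the AdaLIN/CAM generator and patch discriminators
  on a small numpy autodiff engine (`mindsct.autodiff`);
* `mindsct.training` — alternating min–max training for all four
  variants, checkpointing/resume, and the `UnpairedTranslator` estimator
  (`fit(MRI_stack, CT_stack)`, `transform` = MRI→CT);
* `mindsct.phantom` — seeded unpaired chest phantoms with ground-truth
  body/lung/bone masks (the test oracle for structure preservation);
* `mindsct.imageio` — HU windowing (WL 350 / WW 2000), background
  removal, median-tissue normalisation, resampling, PNG/NIfTI/DICOM I/O;
* `mindsct.evaluation` — the 1–5 misalignment rubric, Dice/centroid/
  contrast proxies, and Wilcoxon + Bonferroni method comparison;
* `mindsct.study` — the frozen desk-scale four-variant comparison.

See `docs/methods.md` for the model details and design decisions.

## Worked example

```python
import numpy as np
from mindsct import MINDConfig, mind_loss
from mindsct.phantom import PhantomConfig, generate_dataset
from mindsct.training import UnpairedTranslator
from mindsct.evaluation import structure_report

cfg = PhantomConfig(size=32)
mri = generate_dataset(cfg, "mri_style", 16, 0)      # unpaired domains:
ct  = generate_dataset(cfg, "ct_style", 16, 1000)    # disjoint seed streams

est = UnpairedTranslator(variant="ugatit", with_mind=True, lambda_mind=300.0,
                         image_size=32, base_width=8, disc_layers=2,
                         learning_rate=5e-4, mind_search_radius=1,
                         epochs=100, max_steps=300, seed=0)
est.fit(np.stack([s.image for s in mri]), np.stack([s.image for s in ct]))

held = generate_dataset(cfg, "mri_style", 10, 5000)
synth = est.transform(np.stack([s.image for s in held]))
rep = [structure_report(s, y) for s, y in zip(held, synth)]
print("median held-out bone Dice:", np.median([r["bone_dice"] for r in rep]))
print("MIND(MRI, synthetic CT):",
      round(mind_loss(held[0].image, synth[0], MINDConfig.from_radii(1, 1)), 4))
```

Output from this exact script:

```
median held-out bone Dice: 0.3303030303030303
MIND(MRI, synthetic CT): 0.0894
```

A bone Dice of 0.33 after 300 updates means the synthesised CT paints
bright bone at roughly the right places on held-out phantoms (the same
run without the MIND term reaches 0.28; the full three-seed comparison
lives in `mindsct.study.run_comparison`).  The MIND value of ~0.09 is the
mean per-channel descriptor discrepancy between an MRI and its synthetic
CT — small, because the descriptor sees geometry, not contrast.

A command-line surface wraps the same functions:

```sh
mindsct phantoms --n 16 --style mri --size 32 --seed 0 --out mri/
mindsct phantoms --n 16 --style ct  --size 32 --seed 1000 --out ct/
mindsct train --variant ugatit --mind --domain-a mri/ --domain-b ct/ --out run/
mindsct translate --checkpoint run/checkpoint_final.npz --in mri/ --out synth/
mindsct evaluate --source mri/ --synth synth/ --out report.tsv
mindsct mind-distance --a mri/mri_000000.png --b synth/mri_000000.png
```

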
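# petmoco

Data-driven head-motion correction for **dynamic ¹⁸F-FDG brain PET**, built
around a conditional GAN that converts low-count early frames into
reference-frame-like images so that ordinary rigid registration can find the
motion, plus the full downstream quantification chain: image-derived input
function (IDIF) extraction with partial-volume correction, and Patlak
CMRGlc.  A synthetic dynamic phantom with complete ground truth (masks,
arterial input function, kinetics, applied motion) makes every stage
testable without patient data.

## Who this is for

PET methodologists who want a desk-scale, fully inspectable implementation
of cGAN-aided motion correction: the appearance-conversion idea, the
two motion-correction drivers (cGAN-aided vs the classic summed-early-frame
baseline), and a quantification pipeline whose accuracy can be measured
against simulation ground truth rather than asserted.

## The method

**Frame mapping.** A 60-min FDG acquisition is rebinned as
24×5 s, 1×60 s, 1×120 s, 11×300 s (37 frames).  Early frames are noisy and
show a blood-dominated tracer pattern; the last frame F_ref (55–60 min) is
the high-count registration reference.  A 3D conditional GAN
(U-net-like generator *G* with skip connections, PatchGAN discriminator *D*
with two extra convolutional layers) learns one mapping per frame index from
motion-free pairs (frame *i*, reference frame):

```
L(G, D) = E[log D(x, y)] + E[log(1 − D(x, G(x)))]          (minimax value)
G*      = arg min_G max_D  L(G, D) + λ · E|G(x) − y|,  λ = 1
```

**Motion estimation.**  Each mapped frame is rigidly registered (6 DOF:
3 translations in mm, 3 intrinsic Z-Y-X Euler angles about the image
centre) by a coarse-to-fine mutual-information routine (pyramid 4/2/1,
Powell optimisation, cubic-spline metric resampling).  The baseline
(`moco_standard`) sums the first 3 min into an early reference, smooths by
4 mm, registers later frames to it, and re-expresses everything relative to
F_ref.

**Quantification.**  The blood-pool TAC is sampled from the internal-carotid
vessel mask, moved per frame by its motion vector (ROI-side correction),
recovered by iterative two-compartment partial-volume correction, converted
to plasma via the plasma-to-blood ratio, delay-matched to the arterial
curve, dispersed with a τ = 5 s monoexponential kernel, and fed into Patlak
graphical analysis (fit from 25 min, 8 points on this schedule):

```
CMRGlc = 0.1 · slope · plasma_glucose / LC      [µmol/100 g/min],  LC = 0.65
```

## Worked example

```python
import numpy as np
from petmoco import phantom as ph
from petmoco.core import make_schedule
from petmoco.evaluation import train_frame_mappings, motion_errors
from petmoco.registration import moco_cgan
from petmoco.cgan import CGANConfig

schedule = make_schedule(ph.DEFAULT_FRAME_PATTERN)   # 37 frames, 3600 s
spec = ph.PhantomSpec()                              # 64x64x48 at 3 mm

# one pooled cGAN mapping from 8 synthetic subjects (~5 min on one CPU)
models = train_frame_mappings(
    spec, [24, 25, 27, 30, 33], n_subjects=8,
    config=CGANConfig(epochs=3, augment=False), seed=100, pooled=True)

# held-out subject with the interframe-motion protocol injected
test = ph.make_dataset(ph.random_subject_spec(spec, 777), schedule, seed=778)
moved, truth = ph.inject_interframe_motion(test.noisy, test.truth, seed=1)

frames = [i for i in range(37) if schedule.mid_times[i] > 120 and i != 36]
estimates = moco_cgan(moved, models, frames=frames)
err = motion_errors(estimates, truth, frames)
print(err[["frame", "trans_err_mm", "rot_err_deg"]].to_string(index=False))
```

Output from this exact run:

```
 frame  trans_err_mm  rot_err_deg
    24      0.100008     0.389936
    25      0.195279     0.427661
    26      0.052943     0.283547
    27      0.045464     0.097314
    28      0.050226     0.115981
    29      0.044285     0.133452
    30      0.051452     0.285977
    31      0.125778     0.325190
    32      0.042428     0.162648
    33      0.048681     0.205094
    34      0.033163     0.185924
    35      0.019097     0.139100
```

Every frame with mid-time past 2 min is recovered within 0.2 mm and 0.43°
of the injected motion (protocol: up to 2 voxels = 6 mm translation and 1°
rotation per axis) — comfortably inside the 1-voxel / 0.5° accuracy band
that makes the IDIF usable.

The CLI drives the same pipeline from a shell
(`petmoco simulate|train|moco|idif|patlak|evaluate`, see `--help`).

## Acceptance script

`scripts/acceptance.py` re-runs the whole chain from scratch at reduced
scale — phantom simulation, pooled cGAN training, the interframe
simulated-motion experiment with all four correction arms (cGAN, standard
frame-based, uncorrected, ground-truth oracle), IDIF extraction and Patlak
CMRGlc — prints the per-arm summary table, and writes its JSON result file:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

| module | contents |
| --- | --- |
| `petmoco.phantom` | synthetic dynamic phantom, noise model, motion injection |
| `petmoco.kinetics` | input-function models, 2TCM, Patlak, CMRGlc |
| `petmoco.nn` / `petmoco.cgan` | NumPy 3D conv nets; `CGANFrameMapping` estimator |
| `petmoco.registration` | MI rigid registration, the two moco drivers |
| `petmoco.idif` | TAC extraction, PVC, delay/dispersion/plasma chain |
| `petmoco.evaluation` | metrics, dataset splits, simulated-motion experiments |
| `petmoco.io` / `petmoco.cli` / `petmoco.config` | NIfTI+sidecar/CSV I/O, YAML config, CLI |

See `docs/methods.md` for the model assumptions, numerical choices and
known limitations.
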
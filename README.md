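# histomri

Spatially relating 3D tumor histology to in vivo MRI by image
registration, with a fully ground-truthed synthetic test bed.

Verifying what MRI signal actually corresponds to in tissue requires
putting histological sections and in vivo images into the same coordinate
frame — but excision, fixation, embedding and sectioning deform the tumor,
and color histology and gray-scale MRI share no intensity relationship.
`histomri` implements a methodology built around five ideas: an
intermediate **ex vivo MRI** of the fixed specimen, a **reference cutting
plane** shared by all three 3D images, dense serial sectioning, **elastic
(B-spline) registration**, and use of the complete 3D data sets. Because
real paired histology/MRI data of this kind are not publicly deposited, the
package ships a seeded tumor-phantom generator (viable / necrotic /
hemorrhagic compartments, fixation shrinkage and deformation, jittered
H&E-like sectioning) with exact ground-truth transforms, so every step is
testable against known truth.

## The pipeline

1. **stacking** — serial H&E sections are reconstructed into a 3D volume by
   iterative rigid 2D registration of adjacent sections, on the color
   channel that best separates necrotic from viable tissue (the red
   channel, chosen by histogram separability); slice spacing is the
   physical 80 µm interval.
2. **stack2ex** — the stack is registered to the ex vivo MRI by a
   three-step strategy of increasing degrees of freedom (rigid → affine →
   B-spline), initialized by the shared reference plane.
3. **ex2in** — the in vivo MRI is realigned to the reference-plane frame,
   then the ex vivo MRI is registered to it (rigid → affine with isotropic
   scaling → B-spline); the scaling step's determinant reports the global
   fixation volume change, `ΔV = 100·(1 − det T)`.
4. **stack2in** — the two results are concatenated automatically and the
   color histology stack is warped onto the in vivo grid.

Registration follows the fixed-image-to-moving-image (pull-back)
convention with mutual information for the inter-modality steps; accuracy
is evaluated by landmark RMS distance, reference-plane angulation (the
rotation of the recovered rigid transform about in-plane axes), global and
per-VOI volume change, and intensity-PDF tissue characterization
(interquartile-range segmentation of the in vivo MRI from
histology-confirmed regions).

## Worked example

```python
from histomri.phantom import PhantomConfig, generate
from histomri.workflow import run_pipeline

phantom = generate(PhantomConfig(seed=1))   # in vivo + ex vivo + sections
run = run_pipeline(phantom)                 # stack -> stack2ex -> ex2in -> stack2in

rms = run.summary["landmark_rms_mm"]
print({k: round(v, 3) for k, v in rms.items()})
# {'initial': 0.827, 'rigid': 0.36, 'affine': 0.302, 'elastic': 0.267}

print(round(run.summary["global_volume_change_percent"]["ex2in"], 1))
# 12.9

print(run.summary["driver_channel"],
      {k: round(v, 2) for k, v in run.summary["channel_scores"].items()})
# red {'red': 1.0, 'green': 0.87, 'blue': 0.33}
```

Landmark RMS drops from 0.83 mm (reference-plane alignment only) to
0.27 mm after the full concatenated registration, strictly improving
through the rigid, affine and elastic steps; the recovered global volume
change of 12.9 % matches the phantom's programmed 13.2 % fixation
shrinkage; and the red channel is selected for stacking with the strictly
largest necrotic/viable separability score.

The same run is available from a shell:

```bash
histomri run-all --workdir work --seed 1
```

which writes the phantom, per-stage transform files, warped volumes,
metric logs, an evaluation CSV/JSON and a reproducibility manifest into
`work/`. Individual subcommands (`phantom`, `stack`, `stack2ex`, `ex2in`,
`stack2in`, `evaluate`) run the stages separately on a work directory.

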
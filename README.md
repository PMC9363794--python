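# dfa-meter

Automated measurement of the **disc-fovea angle (DFA)** from color fundus
photographs.

The DFA — the angle between the line joining the optic-disc center to the
foveal center and the horizontal through the disc center — is the standard
fundus-photographic measure of ocular torsion, used in diagnosing
rotational strabismus. Manual measurement is slow and poorly reproducible.
`dfa-meter` implements a fully automatic pipeline:

1. a DeepLabv3+ segmentation network (MobileNetV2 encoder, ASPP,
   encoder-decoder; U-Net and PSPNet baselines included) labels the optic
   disc and a fixed-radius *virtual macular area* in each image;
2. each structure's center is extracted as the center of the minimum
   enclosing circle of its largest connected component;
3. the signed angle is computed as
   `DFA = arctan(|OY − MY| / |OX − MX|) · 180/π`, negated when the macular
   center lies below the disc center (image y grows downward).

Evaluation reports per-class IoU and pixel accuracy with their means
(MIoU, MPA), disc/macula center errors (DO, DM, in pixels), and
min/max/average DFA error in degrees.

Because clinical fundus datasets of this kind are not redistributable, the
package ships a seeded synthetic-fundus generator with exact ground-truth
geometry (disc ellipse, foveal darkening, vessel arcs, sensor noise, and
the 400-px-radius virtual macula label at native 2,584-px width, scaled
linearly for smaller renders). The networks run on a small numpy autodiff
engine contained in the package; no GPU or deep-learning framework is
required.

## Worked example

```python
import numpy as np
from dfa_meter import (
    FundusSegmenter, GeneratorConfig, evaluate, compute_dfa,
)
from dfa_meter.synth import sample_scenes, render_image, render_labels
import pandas as pd

# 80 synthetic 128x128 fundus images with known geometry
scenes = sample_scenes(80, GeneratorConfig(width=128, height=128), seed=42)
images = np.stack([render_image(s) for s in scenes])
masks = np.stack([render_labels(s) for s in scenes])

# the pure angle computation
print(compute_dfa((1000, 1000), (1600, 940)).angle)   # 5.710593137499643

# train a desk-scale DeepLabv3+ (width 0.25) and evaluate held out
seg = FundusSegmenter(input_size=128, width_multiplier=0.25,
                      learning_rate=2e-3, epochs=20, seed=0)
seg.fit(images[:64], masks[:64])
held = scenes[64:]
manifest = pd.DataFrame(dict(
    id=range(16),
    disc_x=[s.disc_center[0] for s in held], disc_y=[s.disc_center[1] for s in held],
    fovea_x=[s.fovea_center[0] for s in held], fovea_y=[s.fovea_center[1] for s in held],
    true_dfa_deg=[s.true_dfa for s in held]))
report = evaluate(images[64:], masks[64:], manifest, model=seg.model_)
print(report.dfa_table)
print(report.seg_table)
```

prints (about one minute of training on one CPU core):

```
            model
Min      0.027362
Max      7.265557
Average  2.730634
                          IoU         PA
Background          97.887498  98.039246
Optic disc          83.587655  99.816895
Macular             78.057716  98.222351
Average (MIoU/MPA)  86.510956  98.692830
```

i.e. the trained desk-scale model segments the three classes with a mean
IoU of 0.87 and measures the DFA of held-out images with a mean error of
2.7°. At this miniature scale the disc-fovea distance is only ~40 px, so
every pixel of macula-center error costs ~1.4° — the same center errors at
native resolution (disc-fovea distance ~800 px) correspond to fractions of
a degree. Feeding the ground-truth masks through the geometric stages
(`evaluate(..., model=None)`) recovers the true angle exactly, isolating
the learned stage as the only error source.

The same flow is available from the shell:

```bash
dfa-meter synth --n 100 --width 128 --height 128 --seed 1 --out-dir data/
dfa-meter split --manifest data/manifest.csv --seed 1 --out data/splits.csv
dfa-meter train --arch deeplabv3plus --data-dir data/ --splits data/splits.csv \
                --input-size 128 --width-multiplier 0.25 --epochs 20 \
                --lr 0.002 --seed 1 --out model.npz
dfa-meter measure --image data/images/00000.png --checkpoint model.npz
dfa-meter evaluate --data-dir data/ --checkpoint model.npz \
                   --splits data/splits.csv --out-dir report/
```

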
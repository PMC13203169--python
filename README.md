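# shouldermorph

Edge-aware shoulder CT analysis at desk scale: 3-D bone segmentation with
distance-weighted losses, marching-cubes reconstruction, glenohumeral (GH)
pathology staging, and human–AI agreement statistics — all exercised on
synthetic shoulder phantoms, with no external data required.

## Who this is for

Researchers studying morphology-driven implant selection in shoulder
arthroplasty (anatomical vs reverse prostheses), and anyone who needs a
fully testable, CPU-only reference implementation of:

* an **edge-aware dual-decoder segmentation network**: a 3-D U-Net whose
  second decoder predicts class boundaries through a pyramidal multi-scale
  module and feeds them back into the region decoder at every resolution;
* its **distance-weighted losses**: with `DWM = exp(−EDT)` (EDT = distance
  to the class boundary),

  ```
  L_r = α(1−D) + (1−α)·C        C  = −Σ_c k_c Σ_i DWM·y·log ŷ
  L_e = β·C + (1−β)·Ĉ           Ĉ  = −Σ_c k_c Σ_i DWM·(1−y)·log(1−ŷ)
  ```

  where `D` is the class-weighted soft Dice and `k_c` inverse-frequency
  class weights;
* a **multi-task GH classifier** (shared encoder → projection → four
  softmax heads: osteophyte grade, joint-space condition, alignment,
  implant type) trained with class-weighted cross-entropy,
  `w_c = (1/N_c) / Σ_i (1/N_i)`;
* the **blinded-panel statistics**: Fleiss' κ, per-case vote entropy
  `H = −Σ p_c log₂ p_c`, per-rater sensitivity/accuracy summaries from
  TP/FN counts, a logistic-regression "virtual consensus" over rater votes,
  and the exact McNemar test.

The networks run on a small numpy autodiff engine included in the package
(no GPU frameworks needed); every gradient is finite-difference checked.

## Worked example

```python
import numpy as np
from shouldermorph.phantoms import PhantomConfig, generate_phantom
from shouldermorph.celunet import compute_distance_weight_map
from shouldermorph.reconstruct import reconstruct_mesh, extract_gh_region
from shouldermorph.agreement import case_entropy, rater_summary, load_rater_records

case = generate_phantom(PhantomConfig(os_grade=1, js_grade=1, hsa_grade=0, seed=7))
print(case.implant)                      # 1  (anatomical: not eccentric/collapsed/severe)

dwm = compute_distance_weight_map(case.labels, classes=(1, 2))
print(round(float(dwm[1].max()), 4))     # 1.0  (boundary voxels carry weight exp(0))

mesh = reconstruct_mesh(case.labels, class_id=1)
print(mesh.is_watertight)                # True

region = extract_gh_region(case.labels, image=case.image, crop_size_mm=64)
print(region.size_voxels)                # (48, 48, 48)

print(round(case_entropy(7, 3).H, 4))    # 0.8813  (7-3 split of ten raters, bits)

summary = rater_summary(load_rater_records()).set_index("rater_id")
print(round(summary.loc["mean", "accuracy"], 2),
      round(summary.loc["SD", "accuracy"], 2))         # 0.61 0.06
```

The last line summarises the ten-surgeon implant-selection count table that
ships with the package: from each rater's anatomical/reverse true-positive
and false-negative counts it derives per-rater accuracy (range 0.51–0.69),
anatomical sensitivity (mean 0.53) and reverse sensitivity (mean 0.69) —
reverse implants are recognised more reliably than anatomical ones under
morphology-only reading.

An end-to-end run (phantoms → train segmentation → segment → mesh → GH crop
→ train classifier → metrics → simulated rater panel analysis):

```bash
shouldermorph pipeline --out run --seed 0
```

writes NIfTI volumes, STL meshes, per-stage manifests and JSON/CSV reports
into `run/`; re-running the same config reproduces every report bitwise.
Individual stages are exposed as `shouldermorph phantom|seg|recon|metrics|agree`
subcommands.

## Layout

| module | contents |
| --- | --- |
| `shouldermorph.phantoms` | synthetic shoulder phantoms + simulated rater panels |
| `shouldermorph.celunet` | DWM, edge labels, region/edge losses, dual-decoder network, training |
| `shouldermorph.reconstruct` | marching-cubes meshes (STL), GH-region isolation |
| `shouldermorph.arthronet` | class weights, multi-task loss, classifier, training |
| `shouldermorph.metrics` | Dice/Jaccard/precision/recall, Macro/Weighted F1, boundary recall |
| `shouldermorph.agreement` | Fleiss' κ, vote entropy, rater summaries, virtual consensus, McNemar |
| `shouldermorph.pipeline` / `cli` | orchestration, manifests, `shouldermorph` CLI |
| `shouldermorph.nn` | numpy reverse-mode autodiff: conv3d, upsampling, Adam |

See `docs/methods.md` for the model assumptions, parameter defaults, what
the phantoms do and do not emulate, and known limitations.
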
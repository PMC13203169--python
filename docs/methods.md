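# Methods

`shouldermorph` is a desk-scale re-implementation of a two-stage CT analysis
chain for shoulder arthroplasty planning — edge-aware bone segmentation,
surface reconstruction with glenohumeral (GH) region isolation, multi-task
pathology/implant staging — together with the statistics used to compare a
model against a panel of human raters. Everything runs on synthetic 3-D
shoulder phantoms so the whole chain is testable on one CPU without any
external data.

## Synthetic phantoms

Each phantom is a voxel grid (default 48³ at 1 mm isotropic spacing)
containing two bone-like objects:

* **Humeral head** — a mildly anisotropic ellipsoid (semi-axes
  `r, 0.95r, 1.05r`, default `r = 0.19 ×` the smallest physical grid
  extent), carrying up to six hemispherical "osteophyte" bumps seeded on the
  lateral hemisphere. Bump protrusion encodes the osteophyte grade:
  1.5 / 5 / 9 mm, the centres of the clinical <3, 3–7 and >7 mm bands.
* **Scapular plate** — a spherical-shell cap ("glenoid cup", thickness 3 mm,
  half-angle 55°) concentric with the head, opening toward it. The inner
  radius is the head radius plus the joint-space gap: 4 mm (physiological),
  1.5 mm (narrowed), exactly 0 (non-detectable).
* **Alignment** — the eccentric condition displaces the head 5 mm superiorly
  relative to the cup; concentric means exactly 0 offset.

The implant label follows a stated, testable surrogate rule: **reverse**
iff the joint is eccentric, the joint space has collapsed, or osteophytes
are severe; **anatomical** otherwise. `label_noise_p` optionally flips the
label, modelling decision noise around the morphology signal. Intensities
are a low background plateau, an 800 trabecular plateau, a 1200 one-voxel
cortical rim, and additive Gaussian noise (default SD 25). Each bone is
post-processed to a single 6-connected component (a collapsed, eccentric
joint can otherwise shave off stray shell voxels).

What the phantoms deliberately do **not** model: realistic scapular
anatomy, Hounsfield-unit calibration, CT reconstruction artifacts, partial
volume effects, or inter-patient anatomical variability. Passing tests on
phantoms therefore demonstrate that the pipeline's machinery — losses,
optimisation, cropping, metrics — behaves as specified, not that the
networks would reach the same accuracy on clinical CT.

A simulated rater panel draws implant votes per case: a rater answers
correctly with the class sensitivity of the true label
(`sensitivity_anatomical` / `sensitivity_reverse`), and with probability
`bias_reverse` the vote is overridden toward reverse, mimicking the
reverse-leaning tendency of morphology-only readings.

## Segmentation: dual-decoder edge-aware U-Net

The network is a 3-D U-Net encoder with two parallel decoders. The edge
decoder reconstructs per-class boundary probability maps through a
pyramidal module (per-level 1×1×1 convolutions, upsampled and summed, then
a sigmoid); its features feed forward into the region decoder at every
resolution (unidirectional fusion), so boundary evidence refines the region
prediction. An ablation flag removes the edge branch entirely, and a
separate flag removes only the fusion links (their parameter cost is
analytic: `27·c_i²` per level, which the tests verify).

Losses. With `DWM = exp(−EDT)` (EDT = unsigned Euclidean distance to the
class boundary, in voxel units by default; a spacing-aware option exists):

* region loss `L_r = α(1−D) + (1−α)·C`, where `D` is the class-weighted
  soft Dice and `C` the DWM- and class-weighted cross-entropy;
* edge loss `L_e = β·C + (1−β)·Ĉ`, with `Ĉ` the reverse cross-entropy
  `−Σ k_c Σ DWM·(1−y)·log(1−ŷ)` penalising false-positive boundary mass.

Both losses are written so a perfect prediction scores 0 (a convention the
"1 − (…)" blend of a similarity and a loss cannot satisfy as printed
elsewhere; we treat that as the intended semantics). Cross-entropies are
normalised by the total applied weight so the loss magnitude is independent
of grid size; normalisation can be disabled, in which case scaling all
class weights scales the CE term proportionally (a tested property). Class
weights `k_c` default to inverse relative frequency normalised to sum to
one. Defaults `α = β = 0.5`; probabilities are clipped at `ε = 1e−7`.

Edge ground truth is the one-voxel-thick 6-connectivity morphological
boundary (an in-class voxel with a 6-neighbour outside the class; the grid
border counts as outside).

The networks run on a small in-repo reverse-mode autodiff engine over numpy
(conv3d via strided windows and GEMM, stride-1 input gradients as a
correlation with the flipped kernel, Adam). Every operation's gradient is
checked against central finite differences in the test suite. Training is
float32 by default for speed; construction and optimisation are
deterministic given the seed.

## Reconstruction and GH isolation

Surfaces come from classic marching cubes on the binary class mask
(iso-level 0.5, one-voxel zero padding so objects touching the grid border
still close), vertices in physical mm. Meshes from solid objects are
watertight with Euler characteristic 2; enclosed volume tracks the voxel
count to within iso-surface placement (±15% on a 10 mm cube).

The GH region is isolated as a fixed-physical-size crop (default 64 mm
cube, clamped to the grid) centred at the midpoint of the closest
boundary-voxel pair between humerus and scapula; ties break toward the
lexicographically smallest voxel pair, making the crop deterministic. This
closest-approach definition is our own concrete choice for "automatic GH
isolation"; a fixed crop size keeps the classifier input constant.

## Multi-task classifier

A shared convolutional encoder (stride-2 blocks, default widths 8/16/32),
global average pooling, a non-linear projection (width 64), and four
parallel softmax heads: osteophyte severity (3), joint-space condition (3),
alignment (2), implant type (2). The loss is the sum over tasks of
class-weighted cross-entropy with weights
`w_c = (1/N_c) / Σ_i (1/N_i)` — normalised inverse frequency; the printed
form `w_c = 1/N_c Σ 1/N_i` is the same up to the constant that
normalisation fixes. Each task term is normalised by the batch mass of the
true-class weights. Tasks are weighted equally; weighting is applied to all
four tasks and is configurable. Where a class is unobserved in a (small)
training split but the task still shows two classes, add-one smoothing
keeps the weight defined.

## Agreement statistics

* **Fleiss' κ** `= (P_o − P_e)/(1 − P_e)` with per-item agreement
  `P_{o,i} = Σ_j n_ij(n_ij−1) / (k(k−1))` and `P_e = Σ_j P_j²`. When every
  vote ever cast is a single category, `P_e = 1` and κ is reported as
  undefined (an explicit error), never a silent number.
* **Vote entropy** `H = −Σ p_c log₂ p_c` with `p_c = n_c/N` and
  `0·log 0 = 0`; 0 bits at unanimity, 1 bit at an even split.
* **Rater summaries** from per-rater TP/FN counts of the two implant
  classes: sensitivities are `TP/(TP+FN)` per class — the only convention
  consistent with the shipped surgeon table, where three raters total 51
  anatomical cases — and cohort rows use the sample (n−1) SD, the only
  convention under which the accuracy SD rounds to the printed 0.06.
  Comparisons against printed cells use round-half-away-from-zero to two
  decimals.
* **Virtual consensus**: stratified 5-fold cross-validated accuracy of a
  logistic regression over the raters' binary votes (scikit-learn); the
  validation protocol is our choice, as none is prescribed for this
  statistic.
* **McNemar**: exact binomial two-sided test on discordant pairs
  (statsmodels), preferred over the χ² approximation at n ≈ 100.

## Desk-scale study conditions

Training tests run deliberately small, fixed configurations:

* segmentation — 25 phantoms on 24³ grids at 2 mm (15 train / 5 val / 5
  test), depth-3 U-Net with 4 base channels, Adam 3e−3, ≤24 epochs,
  patience 8, three seeds;
* classification — 80 phantoms on 32³ grids at 1.5 mm (48/12/20), encoder
  8/16/32, ≤40 epochs, three seeds; label-noise robustness at flip
  probabilities 0 / 0.2 / 0.4.

At these sizes the held-out mean foreground Dice exceeds 0.90 and all four
classification tasks exceed 0.80 accuracy. The negative control — shuffled
implant labels fall to chance — is run on an implant-**balanced** cohort
(`generate_cohort(balance_implant=True)`), because under uniform grades the
disjunctive implant rule makes reverse the large majority and the chance
level would be the majority rate rather than 0.5; mirroring a balanced test
design restores the 0.5 reference. Since shuffled-label predictions are
constant within grade combinations (few effective samples), the control
reports the mean accuracy over three independent shuffles. These are
learnability checks of the implementation, not claims about clinical-scale
performance.

## Numerical choices and edge cases

* Metric zero-division convention: precision/recall/F1 are 0 when their
  denominator vanishes, flagged in the report.
* Distribution comparisons of per-case metrics use a paired two-sided
  Wilcoxon signed-rank test.
* Pipeline stage seeds derive from the run seed by hashing the stage name,
  so stages are independently reproducible; manifests record the stage,
  config hash and seed, and re-running a config reproduces all CSV/JSON
  reports bitwise.
* Degenerate inputs are rejected with explicit messages: absent classes in
  DWM/mesh/GH extraction (naming the class), unequal rater row sums,
  zero class counts in weight derivation, grids too small to contain the
  phantom geometry.

## Known limitations

* The autodiff engine implements only the operations these models need; it
  is not a general framework and runs on CPU only.
* Phantom realism is intentionally minimal (see above); transfer of any
  accuracy number to clinical CT is out of scope.
* The GH isolation rule and the implant surrogate rule are package design
  choices standing in for procedures that are not otherwise specified.
* Fleiss' κ, entropy and consensus statistics of the *simulated* panel
  depend on the chosen rater profiles; only the statistics' mathematics,
  and the shipped surgeon count table, are anchored externally.
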
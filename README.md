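# uamt3d

Semi-supervised 3D medical image segmentation with an **uncertainty-aware
mean teacher** and a **residual / CBAM-attention 3D U-Net**, implemented on a
pure-numpy neural-network backend (no GPU or deep-learning framework
required).

## The problem

In adaptive radiotherapy for breast cancer, the clinical target volume (CTV)
must be delineated on cone-beam CT (CBCT) images acquired at the treatment
machine. CBCT volumes are noisy, shaded and laterally truncated, and labeled
CBCT data are scarce because contouring requires expert clinicians. This
package implements a consistency-regularised semi-supervised approach: a
small labeled pool (mixing clean CT-like and degraded CBCT-like volumes at a
5:3 ratio) and a large unlabeled pool of degraded volumes train a
student/teacher pair of identical networks.

* **Backbone** — 3D U-Net whose blocks carry optional residual shortcuts and
  a serial channel-then-spatial attention gate (CBAM); the two switches span
  the ablation axis plain U-Net → residual → residual+CBAM.
* **Mean teacher** — the teacher's parameters are an exponential moving
  average of the student's: `z′_t = ε z′_{t−1} + (1 − ε) z_t` with ε = 0.99.
  The teacher is never updated by gradients.
* **Uncertainty gating** — the teacher runs N = 8 Monte-Carlo-dropout forward
  passes on each noisy unlabeled input; the mean softmax `M_c = (1/N) Σ_t
  p_t^c` yields the voxelwise entropy `U = −Σ_c M_c ln M_c`, and only voxels
  with `U < I` (a ramped threshold) contribute to the consistency loss
  `L_con = Σ_i H(u_i<I)(f_i − f_i′)² / Σ_i H(u_i<I)`.
* **Objective** — `L = L_sup + λ(t) · L_con`, with `L_sup` the mean of soft
  Dice loss and cross-entropy on labeled cases and
  `λ(t) = λ_max · exp(−5(1 − t/T)²)` the standard Gaussian ramp.
* **Evaluation** — DSC, Jaccard, 95th-percentile Hausdorff distance and
  average symmetric surface distance (mm or voxel units), computed from
  6-connectivity surface voxels and verified against exhaustive brute force.

Because no public CT/CBCT cohort exists for this task, the package ships a
**synthetic phantom generator**: paired clean/degraded volumes containing a
half-ellipsoid soft-tissue target seated against a high-intensity slab, with
multiplicative shading, additive noise and lateral truncation on the degraded
rendering. All training and evaluation code is exercised end-to-end on these
phantoms.

## Worked example

A desk-scale run (pure numpy is slow; keep volumes small on a CPU). With
`cfg.yaml`:

```yaml
data:    {volume_shape: [32, 32, 12], n_cases: 20, labeled_fraction: 0.10,
          test_fraction: 0.20, seed: 0}
model:   {levels: 3, base_channels: 4, sam_kernel: 3}
loss:    {lambda_max: 0.1, rampup_length: 100}
trainer: {epochs: 15, lr: 0.01, seed: 0}
```

```bash
uamt3d generate-data --config cfg.yaml --out data
# INFO wrote 20 cases (2 labeled) to data
uamt3d train --config cfg.yaml --data data --out run       # ~4 min on 1 CPU
# INFO training: 2 labeled / 14 unlabeled / 4 test cases
# INFO finished at step 210; checkpoint in run
uamt3d evaluate --checkpoint run/checkpoint.zip --data data --out report --units voxel
# INFO dsc: 0.8663 +- 0.0424 (n=4)
# INFO jaccard: 0.7666 +- 0.0645 (n=4)
# INFO hd95: 1.0000 +- 0.0000 (n=4)
# INFO asd: 0.3817 +- 0.1048 (n=4)
uamt3d predict --checkpoint run/checkpoint.zip \
    --in data/case_016_degraded.nii.gz --out pred.nii.gz
uamt3d uncertainty --checkpoint run/checkpoint.zip \
    --in data/case_016_degraded.nii.gz --out entropy.nii.gz
```

With 10% labels (2 of 16 training cases) the teacher segments the held-out
degraded volumes at mean Dice 0.87, with sub-voxel average surface error.

Library use, with the scaled benchmark the tests run:

```python
>>> from uamt3d.experiments import ssl_benchmark
>>> bench = ssl_benchmark()
>>> bench["supervised_only_median_teacher_dsc"]
0.848
>>> bench["consistency_median_teacher_dsc"]
0.858
```

Those two numbers are the across-seed median test Dice of the teacher network
trained with 10% labels — without (0.848) and with (0.858) the
uncertainty-gated consistency loss on the unlabeled pool: consistency
training on unlabeled degraded volumes improves segmentation of the degraded
test domain.

`uamt3d report` recomputes the relative-change percentages between the
published clinical benchmark scores shipped with the package (for example,
DSC 0.75 → 0.82 against the plain mean teacher at 10% labels is a +9.33%
change, and 95HD 27.74 → 8.93 against the uncertainty-aware mean teacher is
−67.81%).

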
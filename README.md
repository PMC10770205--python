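# dsareg — automated registration of pre/post-thrombectomy cerebral DSA

In ischemic stroke care, digital subtraction angiography (DSA) series are
recorded before and after endovascular thrombectomy (EVT). Comparing the two
recordings — which vessels reperfused, how the territory filled — requires a
spatial alignment that is missing in practice: the C-arm is repositioned and
the patient moves between acquisitions, and a partially successful
thrombectomy makes new arteries appear that have no counterpart in the
pre-treatment image. `dsareg` implements an automated registration pipeline
for this setting, aimed at researchers building quantitative pre/post
comparisons of cerebral angiography.

## Method

Each series is collapsed into its **minimum intensity projection** (minIP),
`P(r,c) = min_t I_t(r,c)`, a single image showing every vessel that
opacified at any time. The pre-EVT minIP (moving image) is aligned onto the
post-EVT minIP (fixed image) with a global planar transform from the nested
family

  translation (2 dof) ⊂ rigid (3) ⊂ **similarity (4)** ⊂ affine (6) ⊂ projective (8),

fitted by least squares to point correspondences (closed-form Procrustes for
rigid/similarity, normalized DLT + geometric refinement for projective). The
similarity model `T(x) = s R x + t` is the default: scale-aware linear
transforms suffice for this projection geometry, and higher-dof gains tend
to be overfitting.

Correspondences come from three automatic sources, pooled:

* **SIFT** and **ORB** keypoints matched by nearest descriptor with Lowe
  ratio test (0.75) and mutual cross-check;
* two **anatomical landmarks** — the internal carotid artery (ICA) terminus
  and the M1 segment of the middle cerebral artery — detected by a compact
  convolutional encoder–decoder that regresses per-landmark heatmaps
  (sigmoid output, trained with KL or Jensen–Shannon divergence against
  Gaussian targets, decoded by argmax or centre of mass).

A similarity transform is estimated robustly (RANSAC over minimal 2-point
samples, consensus at 3 px, least-squares refit on the inliers). A
registration counts as a **solution** when at least 5 inliers support it,
and a solution is **valid** when its mean error against reference
(manually annotated) correspondences is ≤ 10 px.

Because clinical registry data cannot be redistributed, the package ships a
synthetic angiogram simulator: bifurcating vessel trees rendered as dark
anti-aliased tubes with a propagating contrast front, pre/post pairs related
by a known similarity transform, distal subtrees removed pre-treatment, and
exact landmark ground truth. Every component is tested against it.

## Worked example

```python
from dsareg import PipelineConfig, make_pair, register_pair

pair = make_pair(seed=7)                      # synthetic pre/post pair, known truth
res = register_pair(pair.pre_seq, pair.post_seq, PipelineConfig(seed=0),
                    reference=pair.reference_correspondences())

s, rot, tx, ty = res.transform.similarity_params()
st, rott, _, _ = pair.true_transform.similarity_params()
print(f"status: {res.status.status.value}")
print(f"inliers: {res.n_inliers}/{res.n_correspondences} pooled SIFT+ORB matches")
print(f"recovered scale {s:.4f} (true {st:.4f}), rotation {rot:.2f} deg (true {rott:.2f})")
print(f"mean error vs reference annotations: {res.status.mean_annotation_error_px:.2f} px")
```

prints

```
status: valid
inliers: 83/92 pooled SIFT+ORB matches
recovered scale 1.0562 (true 1.0551), rotation 11.95 deg (true 11.92)
mean error vs reference annotations: 0.14 px
```

i.e. the sampled ground-truth similarity (scale 1.055, rotation 11.9°) is
recovered to sub-percent scale and sub-degree rotation, the solution is
supported by 83 inlying correspondences, and the registration error measured
on held-out reference points is 0.14 px — far below the 10 px validity
threshold.

The same pipeline is scriptable from the shell:

```
dsareg simulate --n 50 --seed 0 --out cohort/        # synthetic cohort + manifest
dsareg register --pre P/pre --post P/post --out r.json
dsareg evaluate --n 20 --seed 0 --out report/        # per-method success table
dsareg train-landmarks --n-pairs 100 --out lm.npz    # ICA/M1 detector
dsareg assess-transforms --annotations ann.csv --out table.csv
```

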
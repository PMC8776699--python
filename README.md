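# spinefuse

Automated rigid registration of planning CT to CT-myelogram for postoperative
spine stereotactic body radiotherapy (SBRT) planning — and the statistical
machinery to compare it against human registration.

After spinal stabilization surgery, metal hardware makes MRI unusable for
spinal-cord delineation, so a CT-myelogram (CT after intrathecal iodinated
contrast) is fused to the planning CT instead. The fusion must be accurate to
about the slice thickness (1 mm), because the spinal cord is the
dose-limiting organ millimetres from the target. `spinefuse` implements a
fully automated rigid registration for this task:

1. a **whole-image baseline**: rigid alignment maximizing normalized mutual
   information (NMI) over the full volumes, from an automatic coarse start;
2. the **contour-focused registration**: starting from the baseline, it
   maximizes NMI restricted to an automatically extracted landmark contour —
   the lesioned vertebrae plus the surgical hardware (extended by one level
   on each side when the lesion spans only one or two vertebrae) — so that
   anatomy changes away from the surgical site cannot bias the alignment of
   the structures that matter.

The similarity metric is

```
NMI(A, B) = (H(A) + H(B) − H(A,B)) / H(A,B)  ∈ [0, 1],
```

computed from a 64×64 joint histogram of paired HU values inside the contour;
it equals 1 when the two images are identical and perfectly aligned. The
6-DOF transform (translations in mm along the left–right, anterior–posterior
and craniocaudal axes; rotations in degrees in the axial, coronal and
sagittal planes, LPS frame) is found by Nelder–Mead search in a
coarse-to-fine image pyramid with multi-basin tracking.

Because the underlying patient scans are not public, the package ships a
**synthetic spine phantom** (vertebral bodies, spinal canal with cord and
CSF, pedicle screws, a lytic lesion, CT noise, and a known rigid
misalignment) that serves as instrumented ground truth, plus the study-style
evaluation: masked NMI improvement over baseline, Pearson correlation,
per-axis transform-error decomposition, NMI-loss perturbation tables, blinded
vote aggregation with an exact (Clopper–Pearson) non-inferiority test,
one-sided paired t-test, and one-way ANOVA with Tukey HSD.

## Worked example

```sh
spinefuse phantom --out-dir work --seed 7
spinefuse register --primary work/primary.nii.gz --secondary work/secondary.nii.gz \
                   --annotation work/levels.json --out work/arir.json
spinefuse evaluate nmi --primary work/primary.nii.gz --secondary work/secondary.nii.gz \
                       --transform work/arir.json
```

The same flow from Python, with a known misalignment:

```python
import numpy as np
from spinefuse import (PhantomSpec, generate_phantom_pair, make_rigid,
                       LesionAnnotation, run_arir_workflow)
from spinefuse.geometry import decompose_difference

spec = PhantomSpec(seed=7)                       # 96x96x160 at 1.074x1.074x1.0 mm
center = (np.array(spec.shape) - 1) * np.asarray(spec.spacing) / 2
truth = make_rigid(2.7, -0.6, 3.6, 1.2, -2.4, 2.9, center)
primary, secondary, info = generate_phantom_pair(spec.with_transform(truth))
ann = LesionAnnotation(tuple(spec.lesion_levels), tuple(info.level_boundaries))
result, mask = run_arir_workflow(primary, secondary, ann)
err = decompose_difference(result.transform, truth, center=center)
print(f"masked NMI {result.metric_value:.4f}, |dt| {err.dt_abs:.3f} mm")
```

prints

```
masked NMI 0.1823, |dt| 0.010 mm
```

i.e. the automated workflow recovered the 4.5 mm / ~3° misalignment to within
0.01 mm, and the final contour-restricted NMI of the noisy pair is 0.18 (the
contrast-filled CSF keeps the two modalities from ever reaching 1).

`spinefuse demo --n-cases 28 --out-dir out` runs the full synthetic study —
phantom cohort, both registrations, an emulated human-registration arm,
per-case evaluation, and the complete statistics block.

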
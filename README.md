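# zlinekit

Automated isolation and quantification of sarcomeric **z-line architecture**
in fluorescence micrographs of striated myocytes (cardiac and skeletal
muscle).

## The problem

Sarcomeres produce force perpendicular to their z-lines, so z-line
organization — visualized by α-actinin immunostaining — is the standard
readout of myocyte structural quality. Two obstacles make naive analysis
unreliable:

1. α-actinin also stains **off-target structures** (immature stress fibers,
   cell boundaries) that run *parallel* to actin fibrils, whereas true
   z-lines run *perpendicular* to them. Off-target signal contaminates any
   orientation statistic computed on the raw stain.
2. Summarizing architecture needs metrics beyond a single order parameter:
   how much of the stain is real z-line, how laterally continuous z-lines
   are across neighboring myofibrils, and how the geometry translates into
   force.

`zlinekit` addresses both with a fully automatic pipeline operating on a
two-channel image (α-actinin required, actin optional, nuclei optional).

## The method

**Skeleton extraction.** The α-actinin channel is smoothed by
coherence-enhancing anisotropic diffusion (explicit finite differences with
a structure-tensor-steered diffusion tensor), contrast-enhanced by white
top-hat filtering, background-flattened by subtracting an interpolated
block-percentile surface, binarized by adaptive mean thresholding, and
thinned to a one-pixel skeleton with short spurs and small objects trimmed.
Per-pixel nematic orientations θ ∈ [0, π) come from the least-mean-square
(structure tensor) gradient estimator.

**Actin-guided segmentation.** The actin channel yields a local *director*
per ~5 μm grid tile: the maximum-eigenvalue eigenvector of the nematic
tensor **T** = ⟨2 r rᵀ − I⟩ over the tile's orientation unit vectors
r = (cos θ, sin θ). Each skeleton pixel is scored by

γ = |p̂_actin · q̂_α-actinin| = |cos(θ_actin − θ_pixel)|

and classified **off-target** when γ ≥ 0.7 (too parallel to actin), z-line
otherwise. The **z-line fraction** N_z / N_α — surviving pixels over all
skeleton pixels — quantifies staining quality: 1 when every pixel is
perpendicular to its local actin, 0 when none is.

**Continuous z-lines.** Z-line pixels are linked into continuous chains:
each pixel keeps six "candidate neighbors" (excluding the two compass
directions perpendicular to its own orientation), prefers the most parallel
occupied candidate on each side, and links are kept when mutual. A lateral
shift of one pixel between abutting segments is bridged; two or more pixels
always break the chain. The median continuous z-line length summarizes the
(right-skewed) length distribution.

**Further metrics.** The orientational order parameter (OOP, maximum
eigenvalue of **T**; 1 = aligned, 0 = isotropic) of the z-lines and of the
raw stain; the normalized stress estimate along the cell's major axis
σ̃ₓ = Σᵢ cos²(θᵢ + π/2) / N_T; sarcomere spacing (dominant z-line repeat
along the actin director); and nuclei per mm². Per-coverslip reports pool
raw counts and angle sets across fields of view, never per-field scalars.

Without an actin co-stain the tool cannot separate z-lines from off-target
staining and reports only the plain α-actinin OOP.

## Worked example

```python
import numpy as np
from zlinekit import (PhantomSpec, make_tissue_phantom, analyze_image,
                      sarcomere_spacing)

spec = PhantomSpec(offtarget_fraction=0.3, seed=11)   # 30% off-target staining
actin, actinin, zline_truth, offtarget_truth = make_tissue_phantom(spec)
result = analyze_image(actinin, actin, image_id="phantom")
r = result.report
print(f"z-line fraction      : {r.zline_fraction:.3f}")
print(f"z-line OOP           : {r.zline_oop:.3f}")
print(f"alpha-actinin OOP    : {r.alpha_actinin_oop:.3f}")
print(f"median cont. z-line  : {r.median_czl_um:.2f} um")
seg = result.artifacts["segmentation"]
sp = sarcomere_spacing(seg.zline_skeleton, result.artifacts["director_grid"])
print(f"sarcomere spacing    : {np.median(sp):.2f} um")
```

Output:

```
z-line fraction      : 0.688
z-line OOP           : 0.993
alpha-actinin OOP    : 0.373
median cont. z-line  : 3.83 um
sarcomere spacing    : 1.92 um
```

The phantom was generated with 30 % of its α-actinin structure drawn
parallel to the fibrils, and the measured fraction (0.688 ≈ 1 − 0.3)
recovers that. The z-line OOP (0.993) far exceeds the raw α-actinin OOP
(0.373): the raw stain mixes ordered z-lines with perpendicular off-target
segments, and segmentation decouples organization from staining quality.
The recovered sarcomere spacing (1.92 μm) matches the generative 2 μm
lattice to within one pixel (1/6 μm).

## Command line

```bash
zlinekit run manifest.csv --out results/       # batch fields + coverslips
zlinekit synth fig2 --shift 2                  # continuity validation fixture
zlinekit synth phantom --seed 3 --offtarget-fraction 0.2
zlinekit tune manifest.csv grid.yaml           # parameter selection vs traces
```

`run` consumes a CSV manifest (`coverslip_id, field_id, path_actinin,
path_actin, path_nuclei`) and writes per-field and per-coverslip CSV
reports, masks, line labels and a resolved-parameter YAML whose hash is
stamped on every output row.

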
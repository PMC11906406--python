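# icodwi

Icosahedral group-convolutional networks for diffusion-weighted MRI (DWI)
tissue segmentation — direct, regular-representation group convolutions on
`SE(3)` and its subgroups, with a synthetic phantom generator so the whole
stack is testable without restricted clinical data.

## The problem

A DWI scan measures, in each voxel, signal attenuation along N gradient
directions on the sphere: a discretization of a function
f: ℝ³ × S² → ℝ.  Rigidly rotating the subject transforms both the voxel
grid *and* each voxel's spherical signal — the natural symmetry group is
SE(3) acting on ℝ³ × S².  Networks whose layers are equivariant to that
action carry the symmetry as an inductive bias instead of hoping to learn
it from augmentation.

This package discretizes S² by the 12 vertices of an icosahedron and SO(3)
by the icosahedron's 60 rotational symmetries (12 fibers × 5 spins over the
vertex stabilizer), and implements the three operators of a separable
group-convolutional layer in direct form:

* **lifting** — an 11-point star-shaped spherical kernel (center, 5 edge
  arc-midpoints, 5 one-ring vertices) translated to every vertex and spun
  5×, producing one response per group element:
  `(f ∗ κ)(g) = Σⱼ f(g·pⱼ) κ(pⱼ)`;
* **group convolution** — a kernel supported on one fiber, applied as a
  cyclic correlation over the 5 spins of each coset through the Cayley
  table: `(F ∗ K)(g) = Σₖ F(g σₖ⁻¹) K(σₖ)`;
* **spatial convolution** — a 3³ kernel applied per group slot, either
  unrotated (𝕋³ × SO(3)), rotated by the fiber's coset representative
  (SE(3)\*), or rotated with the slot's own rotation (SE(3));
* **max-projection** — channel-wise max over spins (→ sphere) or over all
  60 elements (→ voxel grid), conferring invariance.

Because the star kernel's orbit is closed under the group, lifting, group
convolution and projection are *exactly* equivariant (pure index
permutations), and the package's embedding makes the three 180° coordinate
axis rotations grid-exact, enabling interpolation-free end-to-end
equivariance tests.

The ablation family — classical CNN, single-voxel SO(3) network,
decoupled 𝕋³×SO(3), partial and full SE(3) variants, and a
rotation-averaged classical CNN — is built from declarative specs with
exact parameter accounting, trained with focal loss
(γ=2, α=(0.35, 0.35, 0.15, 0.15)) on CSF / subcortical / WM / GM patches.

## Worked example

```python
import numpy as np
from icodwi import (PhantomConfig, build_icosahedron, build_network,
                    evaluate, extract_patches, generate_phantom, preset,
                    train)
from icodwi.icosa_group import build_rotation_group

group = build_rotation_group(build_icosahedron())
vol_tr, lab_tr, _ = generate_phantom(PhantomConfig(seed=11))
vol_te, lab_te, _ = generate_phantom(PhantomConfig(seed=12))
ds_tr = extract_patches(vol_tr, lab_tr, patch_size=7, max_patches=1200, seed=1)
ds_te = extract_patches(vol_te, lab_te, patch_size=7, max_patches=400, seed=2)

net = build_network(preset("decoupled-"), seed=0, group=group)  # 2,514 params
train(net, ds_tr, epochs=15, seed=0)
report = evaluate(net.predict(ds_te.patches, ds_te.scheme), ds_te.labels)
print(f"held-out overall accuracy: {report.overall_accuracy:.3f}")
```

Output:

```
held-out overall accuracy: 0.845
```

The phantom is a 32³ four-tissue volume (90 directions at b=1000 s/mm²,
Rician noise); 0.845 means the 2,514-parameter decoupled network classifies
84.5% of held-out voxels from a second phantom correctly after 15 epochs.
Rotating every test patch by a random octahedral element leaves this
network's accuracy essentially unchanged, while the classical CNN trained
the same way loses ≈0.2 accuracy — the robustness contrast the group
structure buys.  The `examples/` scripts walk through each capability
(group tables, phantoms and signal resampling, equivariance, parameter
accounting, training and rotation robustness).

A thin CLI covers the same workflow from a shell:

```bash
icodwi simulate --out /tmp/ph --seed 0
icodwi count-params --preset full-compare   # prints 34964
icodwi equiv-check
icodwi train --data /tmp/ph --out /tmp/model.npz --preset baseline- --epochs 20
icodwi evaluate --data /tmp/ph --model /tmp/model.npz --preset baseline- --out /tmp/report
```

## Layout

- `src/icodwi/icosa_group.py` — icosahedron, the 60-element rotation group,
  Cayley/inverse/fiber tables, regular representation.
- `src/icodwi/spherical_signal.py` — gradient tables, b0 normalization,
  Watson interpolation, NIfTI / FSL bval-bvec I/O.
- `src/icodwi/equivariant_layers.py` — lifting, fiber group convolution,
  rotation-tied spatial convolution, max-projection.
- `src/icodwi/nn.py` — numpy training layers (forward + backward) and Adam.
- `src/icodwi/networks.py` — architecture specs, presets, exact parameter
  counts, network builder.
- `src/icodwi/train_eval.py` — patches, focal loss, octahedral
  augmentation, rotated test sets, metrics, training loop.
- `src/icodwi/synthetic_data.py` — tensor-model DWI phantoms.
- `src/icodwi/cli.py` — `simulate / train / evaluate / equiv-check /
  count-params / rotate-testset`.

See `docs/methods.md` for the model, its assumptions, parameter defaults
and the limits of what the synthetic study shows.
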
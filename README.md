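# ctrecon

3D surface reconstruction of motion-degraded CT, for medical-imaging
researchers and engineers who need fast, smooth organ meshes from clinical
volumes.  The toolkit covers the whole chain:

1. **Motion-blur simulation** — uniform linear motion degrades an image as
   `I_b = P * I_c + N`, with a line-shaped PSF `P` parameterized by blur
   angle and amplitude (pixels).
2. **GAN deblurring** — a U-net generator (C64-C128-C256-C512-C512-C512 /
   DC512-DC512-DC512-DC256-DC128-DC64-C3, 5x5 kernels, skip connections)
   trained against a convolutional discriminator with the objective
   `L = L_rec + λ·L_adv`, λ = 0.01.
3. **Restoration metrics** — Shannon entropy ratio `E_r = E_d / E_p`,
   MSE, and `PSNR = 10·log10((2^n−1)²/MSE)`.
4. **Pre-segmentation** — seeded region growing plus histogram-threshold
   refinement.
5. **Golden-section Marching Cubes** — Marching Cubes in which each active
   cube edge's surface point is placed at the golden fraction
   g = (√5−1)/2 ≈ 0.618 from the edge's lower endpoint and cached per
   canonical edge, so the point/normal of an edge shared by four cubes is
   computed once instead of four times; followed by **isosurface direction
   smoothing**, which replaces each triangle's unit normal by the
   renormalized mean over its neighborhood, N′ = normalize(Σ N_k/(n+1)),
   removing the scale-like shading artifact of discontinuous face normals.

Synthetic phantoms (spheres, ellipsoids, blob unions) with analytic
surfaces make every stage testable without any data download.  See
`docs/methods.md` for the full model descriptions and design choices.

## Worked example

```python
from ctrecon import (PhantomSpec, make_volume, extract_isosurface,
                     smooth_normals, normal_roughness, mesh_topology,
                     mesh_surface_area, write_mesh)

phantom = make_volume(PhantomSpec(kind="sphere", dims=(64, 64, 64), radii=20.0))
mesh = extract_isosurface(phantom.volume, phantom.isovalue)
print(mesh.stats["cells_traversed"])          # 250047
print(mesh.stats["per_edge_computation_max"]) # 1
print(mesh_topology(mesh)["euler_characteristic"])  # 2
before = normal_roughness(mesh)
smooth_normals(mesh)
after = normal_roughness(mesh, mesh.smoothed_normals)
print(round(before, 4), round(after, 4))      # 0.2616 0.0901
print(round(mesh_surface_area(mesh), 1), round(phantom.surface_area, 1))
                                              # 5552.4 5026.5
write_mesh(mesh, "sphere.stl", normals="smoothed")
```

All 250,047 cube cells of the 64³ grid are traversed; the per-edge cache
computes every equivalent point exactly once (`per_edge_computation_max`
is 1 even though interior edges are requested by up to four cubes).  The
mesh is a closed surface of sphere topology (Euler characteristic 2).
Direction smoothing cuts the mean adjacent-normal angular deviation from
0.262 rad to 0.090 rad without moving any vertex.  The mesh area exceeds
the analytic 4πr² by ~10% — the documented geometric bias of fixed-fraction
vertex placement (see `docs/methods.md`).

The same flow is available from the shell:

```sh
ctrecon phantom --kind sphere --dims 64,64,64 --radius 20 --refs refs.json sphere.npz
ctrecon reconstruct --isovalue 110 --smooth on --stats stats.json sphere.npz sphere.stl
ctrecon blur --angle 45 --amplitude 15 clear.png blurred.png
ctrecon metrics --clear clear.png --test blurred.png
```

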
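# silkbls

Brillouin-light-spectroscopy (BLS) analysis of elastic anisotropy in protein
fibers — built around the silkworm (*Bombyx mori*) silk study that compares the
anisotropic native fiber with the isotropic regenerated fibroin film and with
spider dragline silk.

BLS measures the inelastic scattering of laser light by thermally excited GHz
acoustic phonons: each phonon produces a doublet at frequency shifts
ω_B = ±cq, where c is the sound velocity and q the probed wave vector set by
the scattering geometry. From spectra recorded at many angles α between q and
the fiber axis, the full transversely isotropic stiffness tensor — and from it
the engineering moduli — follows. The package implements every stage and a
synthetic-data generator so the whole pipeline is testable without an
interferometer:

1. **geometry** — probed wave vectors: q∥ = (4π/λ)sin(θ/2) in transmission,
   q⊥ = (4π/λ)√(n² − cos²(θ/2)) in reflection, q_bs = 4πn/λ in
   backscattering; velocities c = 2πf/q.
2. **spectral** — Lorentzian + linear-baseline peak fitting (lmfit) with
   Poisson weighting and covariance-based uncertainties; acoustic-branch
   labeling (L∥, L⊥, QL, QT, PT).
3. **christoffel** — closed-form branch velocities of a transversely
   isotropic solid,
   ρc_PT² = C66 sin²α + C44 cos²α and
   ρc²_{QL,QT} = ½[C11 sin²α + C33 cos²α + C44 ± √((C11 sin²α − C33 cos²α +
   C44 cos2α)² + 4(C13+C44)² sin²α cos²α)],
   cross-validated against a 3×3 acoustic-tensor (Γ_ik = C_ijkl n_j n_l / ρ)
   eigensolver.
4. **inversion** — weighted nonlinear least squares for the independent
   constants (C11, C33, C44, C13, optionally C66), with positive-definite
   reparameterization, Jacobian covariance scaled by χ²/dof, and a residual
   bootstrap.
5. **moduli** — compliance inversion to E∥, E⊥, G13, G12, the Reuss bulk
   modulus K, ν31, ν12; isotropic M = ρc_L², G = ρc_T², ν = (r²−2)/(2(r²−1)).
6. **synthetic** — seeded generators for spectra (Lorentzian doublets +
   counting noise) and velocity datasets, plus the published reference
   tensors as fixtures.

## Worked example

```python
from silkbls import fixtures, moduli_from_tensor, velocities_ti

tensor = fixtures()["silkworm_0"]       # C11=13.0, C13=8.6, C33=32.1, C44=C66=4.5 GPa
print(velocities_ti(tensor, 0.0).c_QL)  # 4876.2  m/s, axial longitudinal velocity
m = moduli_from_tensor(tensor)
print(m.E_axial, m.E_lateral, m.K)      # 23.4  10.4  8.5  (GPa)
print(m.nu_31, m.nu_12)                 # 0.51  0.16
```

E∥ = 23.4 GPa and E⊥ = 10.4 GPa are the Young's moduli along and normal to
the fiber axis (anisotropy ≈ 2.2); K is the Reuss bulk modulus; ν31 > 0.5 is
admissible for an anisotropic solid and reflects the C66 = C44 constraint
used when the pure transverse branch is only measurable on-axis.

The `examples/` scripts each run one capability end to end and print what the
numbers mean:

```sh
python examples/wavevectors_and_velocities.py   # scattering geometry
python examples/film_isotropic_moduli.py        # isotropic film: M=12.2, G=3.0 GPa, nu=0.34
python examples/christoffel_curves.py           # c(alpha) branch curves + moduli
python examples/invert_synthetic_dataset.py     # noisy data -> tensor -> moduli
```

A thin CLI covers the same pipeline for file-based work:

```sh
silkbls simulate --fixture silkworm_0 --seed 1 -o sim
silkbls fit-tensor sim/velocities.csv -o fit
silkbls moduli sim/tensor.json          # or any tensor JSON
```

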
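# boldsim

Forward simulation of susceptibility-driven transverse MR signal decay —
the physics underneath BOLD fMRI contrast, contrast-agent relaxometry and
iron-particle T2* mapping — in a single tissue voxel.

## The problem

The T2*-weighted MR signal of a voxel is shaped by microscopic magnetic
field gradients around susceptibility perturbers: deoxygenated blood
vessels, contrast-agent-loaded cells, ferritin, myelinated axons.  Water
protons diffusing through these dipole fields accumulate irreversible
phase, so the transverse signal decays faster than tissue T2 alone would
predict.  Forward modeling recreates this process from first principles —
place perturbers in a voxel, compute the field offset ΔB(**r**), diffuse
spins through it, play an RF pulse sequence, and sum the transverse
magnetization — so that measured signals can be interpreted quantitatively.

`boldsim` is aimed at MR physicists and quantitative-fMRI researchers who
need such simulations without writing one from scratch: for Boxerman-style
vessel-size analyses, sequence optimization (GE / SE / ASE), dictionary
generation, or teaching.

## The model

A voxel is a square (2D) or cube (3D) of side `W` with periodic boundaries.
Perturbers carry a susceptibility difference Δχ (SI) and a wall permeation
probability. Field offsets along B0:

- infinite cylinder: ΔB = B0·Δχ/6·(3cos²θ − 1) inside,
  B0·Δχ/2·(R/r)²·cos 2φ·sin²θ outside;
- sphere: 0 inside, B0·Δχ/3·(R/r)³·(3cos²θ − 1) outside;
- arbitrary mask: Fourier convolution of χ(**r**) with the unit dipole
  kernel G(**r**) = (3z² − r²)/(4π r⁵).

Spins either random-walk in continuous space (Monte Carlo: steps
~ N(0, 2DΔt) per axis, Bernoulli wall permeation) or, on 2D grids, the
magnetization field is convolved each step with a discrete diffusion kernel
(sampled Gaussian or the lattice-exact `exp(−t)·Iₙ(t)` Bessel kernel).
Each step the transverse magnetization precesses by γ·ΔB·Δt and relaxes
with optional per-compartment T2/T1; RF pulses are instantaneous rotations
about an arbitrary axis.  A method is named by its five choices, e.g.
`2D-GRD-CYL-ANA-DD` = 2D, gridded, cylinders, analytic field,
deterministic diffusion; incompatible combinations are rejected.

The susceptibility-attributable rates are measured against a Δχ=0 twin run:
ΔR2(\*) = −ln(|S(TE)|/|S₀(TE)|)/TE, with ΔR2′ = ΔR2* − ΔR2 the refocusable
part.

## Worked example

```python
import boldsim as bs

# grey-matter-like voxel: 1 um vessels, 2% CBV, dchi = 0.3 ppm (cgs),
# D = 1e-3 mm^2/s, spin echo TE = 70 ms
cfg = bs.make_fixture("gm_cylinders_2d", seed=0, n_spins=4000)
tc = bs.run_simulation(cfg)
mag = tc.magnitude()
print(f"|S(TE)|/|S(0)| = {mag[-1] / mag[0]:.3f}")

rates = bs.rates_for_config(cfg)
print(f"dR2* = {rates.dr2_ge:.1f} 1/s, dR2 = {rates.dr2_se:.1f} 1/s, "
      f"dR2' = {rates.dr2_prime:.1f} 1/s")
```

prints (seed 0):

```
|S(TE)|/|S(0)| = 0.557
dR2* = 12.0 1/s, dR2 = 8.4 1/s, dR2' = 3.7 1/s
```

i.e. this voxel's vessels destroy ~44% of the spin-echo signal by 70 ms;
of the 12.0 s⁻¹ gradient-echo rate increase, 8.4 s⁻¹ survives a refocusing
pulse because diffusion through capillary-scale gradients is irreversible,
and 3.7 s⁻¹ is static dephasing that the echo recovers.

The same is available from a shell:

```bash
boldsim fixtures gm_cylinders_2d --seed 0 --out demo/
boldsim simulate demo/gm_cylinders_2d_config.yaml --out demo/signal.csv
boldsim sweep demo/gm_cylinders_2d_config.yaml --radii 0.001 0.005 0.01 \
    --repeats 2 --out demo/sweep.csv
```

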
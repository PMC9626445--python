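# gliomech

Finite-element simulation of brain tumour growth as a mechanical process,
for researchers in tumour biomechanics and mathematical oncology who want a
self-contained, tested implementation of a biphasic, hyperelastic,
DTI-informed growth model.

## The model

Healthy and tumourous brain tissue are saturated two-phase mixtures: a
hyperelastic solid phase (cells, volume fraction φ_s) and an interstitial
fluid (φ_ℓ = 1 − φ_s).  A smooth indicator χ ∈ [0, 1] on the reference
configuration marks the tumour (region {χ > 0.1}).  Growth enters through
the multiplicative decomposition

    F_s = F_e F_g,   F_g = g 𝐈,   J_s = J_e g³,

so proliferation inflates the natural (stress-free) state isotropically and
the elastic part F_e carries the stress.  The solid obeys an isochoric
Mooney–Rivlin plus logarithmic volumetric energy

    W = ½μ₁(I_C̄ₑ − 3) + ½μ₂(II_C̄ₑ − 3) + ½κ(ln J_e)²,

with tumour/healthy parameters blended by χ.  The mixture momentum balance
Div(−J_s p F_sᵀ⁻¹ + P_s) = 0 and the fluid mass balance (a Darcy problem
with Holmes–Mow, deformation-dependent mobility k(J_e)·𝐀) determine the
displacement u_s and pressure p; nutrients c_n are advected, diffuse along
the DTI tensor 𝐃, and are consumed by the tumour.  The growth stretch
evolves as ġ/g = Γ_s/(3φ_s) with

    Γ_s = γ φ_s (φ_max − φ_s)(c_n − c₀)₊ · [1 − δ₁Σ₊/(Σ₊ + δ₂)],

the last factor (optional) inhibiting proliferation under compression
Σ = −tr(𝐓_s)/3.  As the tissue deforms, the eigenvectors of 𝐃 and of the
preferential-direction tensor 𝐀 are reoriented by F_s (directions change,
eigenvalues and hence tr 𝐃 do not), feeding the altered anisotropy back
into transport.  Everything is solved in the Lagrangian frame with P1
tetrahedra and a semi-implicit Euler / monolithic Newton scheme.  Units:
mm, day, MPa.  See `docs/methods.md` for the full account.

Patient MRI/DTI data are not required: the `phantom` module generates
ball-shaped "skull-bounded brain" meshes, spherical tumour indicators and
synthetic DTI voxel grids (isotropic / uniform-axis / radial fibres).

## Worked example

```bash
cat > spec.yaml <<EOF
brain_radius: 40.0
h: 8.0
refine_factor: 2.5
tumour_radius: 7.0
interface_width: 1.0
dti_mode: isotropic
EOF
gliomech phantom  --spec spec.yaml --out ph
gliomech simulate --mesh ph/phantom.vtu --t-end 3 --out run
gliomech postprocess --run run
```

prints

```
phantom: 1473 nodes, 7308 cells -> ph
simulate: 30 steps, final V = 3.276 cm^3 -> run
{
 "VDT_day": null,
 "SGR_percent_per_day": null,
 "VRE_mm_per_year": 40.310451932007304,
 "volume_doubled": false
}
```

Reading the numbers: the 7 mm tumour indicator occupies 2.94 cm³ of the
40 mm phantom at t = 0 (the {χ > 0.1} ball); after 3 simulated days of
nutrient-limited growth the deformed tumour volume is 3.28 cm³.  The
volume has not yet doubled, so the volume doubling time (VDT) and specific
growth rate (SGR = 100 ln2/VDT) are not reported; the mean velocity of
radial expansion of the equivalent sphere over these 3 days is
40.3 mm/year.  The run directory holds a VTU time series (displacement,
pressure, nutrients as point data; g, φ_s, Σ, FA as cell data — openable in
ParaView), `volume_series.csv`, and `manifest.json` with input hashes and
the per-step Newton/CFL log.

The same pipeline is scriptable from Python
(`gliomech.phantom` → `gliomech.solver.run_simulation` →
`gliomech.postprocess`); the CLI is a thin wrapper over those functions.

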
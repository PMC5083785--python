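# rootpatch

Models of root hair initiation in *Arabidopsis* root epidermal cells, for
plant developmental biologists and biomechanics modellers. The package
answers two linked questions in one place:

1. **Where on the cell is the initiation site?** A reaction–diffusion model
   of ROP GTPase activation, driven by an intracellular auxin gradient,
   positions a patch of active ROP on a compartmentalized 2D cell surface.
2. **Can wall stresses explain the star-like microtubule pattern seen at
   that site?** A geometrically nonlinear Saint Venant–Kirchhoff shell model
   of a turgor-pressurized wall patch with a locally softened/stiffened or
   extra-loaded circular region, plus a classifier of the surrounding
   principal-stress pattern (radial vs. circumferential).

## The models in brief

Auxin obeys a source–sink balance on the compartment mesh,
`dA/dt = D_a ΔA + t + s_in·[source] − s_out·A·[sink] − q·A`, and ROP cycles
between a cytosolic inactive form and a membrane-bound active form with
auxin-dependent autocatalytic activation `R_i(k_1 + k_2 R_a² A)`, slow
active-form diffusion, and extra decay at the cell outline. Both systems are
integrated to steady state with fixed-step RK4.

The wall patch is a 20 × 20 μm, 0.5 μm thick membrane/shell under follower
pressure (turgor − 1 atm), fixed at its edges, with Saint Venant–Kirchhoff
response `S = λ tr(E) I + 2μ E`. Around the modified central region the
Cauchy stress is decomposed in a polar frame; the ratio σ_rr/σ_θθ above or
below 1 classifies the pattern as radial or circumferential. See
`docs/methods.md` for the full formulation and numerical choices.

## Worked example

```python
import rootpatch as rp

# 1. Position the ROP patch under the default auxin gradient
res = rp.simulate_patterning(mode="gradient")
print(f"auxin gradient: {res.gradient_percent:.1f}%")
print(f"patches: {res.summary.n_peaks}, basal offset "
      f"{res.summary.basal_offset:.3f}, lateral offset "
      f"{res.summary.lateral_offset:.3f}")

# 2. Classify the stress pattern around a stiffened initiation site
state, stress, ratio = rp.run_scenario("stiff")
print(f"stiff centre: ratio {ratio.mean_ratio:.2f} -> {ratio.mean_classification}")
```

prints

```
auxin gradient: 22.4%
patches: 1, basal offset 0.025, lateral offset 0.000
stiff centre: ratio 1.17 -> radial
```

— the auxin gradient is ~20% basal-to-apical; a single active-ROP patch
sits laterally centered near the basal end of the cell; and a stiffened
central region surrounds itself with a radial (star-like) maximal-stress
pattern, the mechanical signature matching the microtubule arrangement
observed at initiation sites. A softened region instead gives ratio < 1
(circumferential), and doubling the turgor in the central region flips even
the softened case back to radial.

The same runs are available from the shell:

```sh
rootpatch rop --mode gradient --out out/
rootpatch analyze --scenario stiff --out out/
rootpatch sweep modulus --values 60,80,100,120,140 --out modulus_sweep.csv
```

Outputs are plain text: legacy-ASCII VTK meshes/fields, CSV tables, JSON
summaries.

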
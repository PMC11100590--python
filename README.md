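# slicekin

Kinetic analysis of target slicing by AGO2–RISC (an Argonaute protein
loaded with a guide RNA). The package provides the complete quantitative
machinery around single-molecule-free, gel-based slicing assays: forward
ODE models of single- and multiple-turnover slicing, closed-form
approximations, bounded least-squares parameter estimation with the
constraint fallbacks such fits need in practice, RISC-stock
quantification from titration filter binding, association-rate
estimation, a thermodynamic model of 3′-mismatch tolerance,
hydroxyl-radical footprinting normalization, and seeded synthetic-data
generators so every stage is testable without raw gel data.

## Who it is for

Biochemists and computational biologists quantifying RNAi enzymology:
anyone fitting fraction-sliced time courses from phosphorimager-
quantified gels, calibrating purified RISC concentrations, or relating
guide–target pairing energetics to slicing rates.

## The models

**Single turnover (accepted biphasic model).** Enzyme E (total
concentration [E_all], nM) is a mixture of an intact fraction `F_a` and a
defective fraction `1 − F_a`. Both bind free target S at `k_on`
(nM⁻¹ s⁻¹, capped at the diffusion limit of 1 nM⁻¹ s⁻¹ = 60 nM⁻¹ min⁻¹);
the intact complex ES slices at `k_slice` (s⁻¹), the defective complex
E′S only at the much slower `k_phase2`:

    d[P]/dt   = k_slice·[ES] + k_phase2·[E′S]
    d[ES]/dt  = k_on·[E][S] − k_slice·[ES]        (E recycled on slicing)
    d[E′S]/dt = k_on·[E′][S] − k_phase2·[E′S]
    F_sliced  = [P] / ([P] + [S] + [ES] + [E′S])

τ_slice = 1/k_slice is the characteristic slicing time. Fits are seeded
by the pseudo-steady-state closed form

    F(t) = F_a·(1 − e^(−t / (1/(k_on[E]) + 1/k_slice)))
         + (1 − F_a)·(1 − e^(−k_phase2·t))

and refined against the ODE model by bounded least squares with rate
constants in log space. If `k_on` (fast-binding data) or `k_phase2`
(time courses too short to see the slow phase) cannot be confidently
resolved, the fit is repeated with `k_on` pinned at the diffusion limit
or `k_phase2` pinned at zero, in that order, and flagged.

**Multiple turnover** adds explicit enzyme–product complexes, product
release at `k_offP`, product re-binding, and a plateau factor `F_max`.

**Titration quantification.** Stock RISC concentration from dilution
series: ordinary linear regression below 60% bound, or the tight-binding
quadratic (stock, K_D, y-intercept) near saturation, with an automatic
fallback to the linear fit when the stock estimate is not significant
(p > 0.05).

**Thermodynamics of 3′-mismatch tolerance.** For targets paired only
through guide position 16, the relative slicing rate follows a two-state
sigmoid in the predicted central pairing energy ΔG°₉₋₁₂:

    k_slice(16-bp)/k_slice(perfect) = 1 / (e^((ΔG°₉₋₁₂ + ΔG°_thres)/RT) + 1)

with R = 1.987204×10⁻³ kcal mol⁻¹ K⁻¹ and T = 310.15 K. Helpers remove
the duplex initiation (4.09 kcal/mol) and symmetry (0.43 kcal/mol)
penalties from externally predicted duplex energies, and the
steady-state knockdown ceiling (1/τ_slice) / (ln2/t½ + 1/τ_slice)
bounds what a slow-slicing guide can achieve in cells.

**Footprinting.** Hydroxyl-radical reactivities are rescaled per
position between quenched-reagent (0) and naked-guide (1) anchor lanes,
with degradation-band correction by neighbor averaging and a QC flag for
denatured replicates.

## Worked example

```
$ slicekin simulate --kind slicing --seed 7 --sigma 0.02 --out demo.csv
wrote demo.csv (truth: demo.csv.truth.json)
$ slicekin fit-slicing demo.csv
k_on = 0.00505 nM^-1 s^-1, k_slice = 0.00968 s^-1, k_phase2 = 1.09e-05 s^-1, F_a = 0.886
tau_slice = 103 s
$ slicekin knockdown-ceiling --tau-slice 12 --half-life 120
maximal knockdown = 0.9352 (94%)
```

The simulated dataset was generated with k_on = 0.005 nM⁻¹ s⁻¹,
k_slice = 0.01 s⁻¹, k_phase2 = 10⁻⁵ s⁻¹ and F_a = 0.9 (recorded in the
truth sidecar) at a 0.33/3.3/33 nM enzyme dilution series with 2%
measurement noise; the fit recovers all four parameters within a few
percent, and τ_slice is reported in adaptive units. The knockdown
ceiling says a guide needing 12 min per slicing event cannot suppress a
2-h-half-life mRNA by more than ~94% at steady state, however abundant
the RISC.

The same analyses are available as library calls
(`slicekin.fit_single_turnover`, `slicekin.fit_titration_quadratic`,
`slicekin.fit_dG_thres`, `slicekin.max_knockdown`, ...) and as a batch
pipeline driven by a YAML config (`slicekin report`).

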
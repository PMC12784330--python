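# Methods

This note records the models behind each module, the defaults and why, what
the synthetic generators do and do not emulate, and the numerical choices.

## Harmonic phonon thermodynamics

A polymorph is represented by its mode wavenumbers ν̃ᵢ (cm⁻¹) with sampling
weights wᵢ (Σwᵢ = modes per cell covered), molecules per cell Z, and a
lattice energy E_latt (kJ/mol of molecules, the static crystal relative to
separated static molecules).  Per-mode functions use the exact quantum
harmonic oscillator with x = hcν̃/k_BT; all exponentials are evaluated in
e⁻ˣ form so stiff modes at low temperature cannot overflow.  Molar
quantities are (N_A/Z)·Σwᵢ·(per-mode value).  Enthalpy is H = E_latt + U_vib:
the pV term between solid phases is of order 10⁻³ kJ/mol (computed
explicitly by `pdv_term`) and is neglected, which also makes ΔG and ΔA
between polymorphs identical here.

Constants are CODATA 2018, fixed in `constants.py`.  Input wavenumbers with
|ν̃| < 0.05 cm⁻¹ are dropped with a warning (Γ-point acoustic modes);
genuinely negative values raise, because an imaginary frequency means the
harmonic model is invalid for that structure and must not be silently
absorbed.

Transition temperatures are the roots of ΔA(T): every sign change on the
temperature grid is bracketed and refined by Brent's method to 10⁻³ K.
Absence of a root is a reported outcome, not an error.  The static baseline
ΔH_sub = −E_latt − 2RT is provided as the reference that cannot describe
enantiotropy (under it, polymorph enthalpy differences equal lattice-energy
differences at all temperatures).

## Quasi-harmonic model

E(V) is fitted with a cubic polynomial by default (a Murnaghan equation of
state is an option; no particular EOS is canonical for this problem, and on
the narrow ±8 % volume ranges used here the two agree).  Frequencies vary
with volume through a constant per-mode Grüneisen parameter: ln ν̃ᵢ is
fitted linearly in ln V through matched mode indices across the grid.  This
assumes mode ordering is conserved; a reordering by more than two positions
triggers a warning, and crossing modes are out of scope.  F(V;T) is
minimised by bounded scalar minimisation to 10⁻⁶ relative; a minimum within
10⁻⁴ of the grid hull is flagged unreliable per temperature.  K = V d²F/dV²
is evaluated by central differences in molar-volume units (giving Pa
directly); α = (1/V_eq)dV_eq/dT by central differences on the temperature
grid (one-sided at the ends, which is why closed-form comparisons exclude
endpoint temperatures).

Cp − Cv is computed two ways and both are reported: the integral form
∫₀ᵀ V K α² dT′ (primary) by trapezoidal quadrature, with the integrand
linearly extrapolated from the first two grid points down to T = 0 (exact
for a constant integrand), and the pointwise textbook form T·V·K·α².  The
two coincide for constant integrand and differ otherwise; the discrepancy
is exposed on the result object rather than hidden.

The synthetic volume grid (`make_volume_grid`) applies the Grüneisen scaling
only to modes below 300 cm⁻¹: intramolecular vibrations have near-zero γ,
and scaling them too loads E(V) with an unphysical zero-point pressure that
pushes the minimum off any realistic grid.  Default curvature corresponds
to K ≈ 10 GPa at 323 Å³/molecule — typical of an organic molecular crystal.

## Calorimetry consensus

Cp(T) per form is fitted by ordinary least squares to a quadratic
(coefficient covariance from σ²(XᵀX)⁻¹); evaluation more than 50 K outside
the fit range warns.  ΔCp for the II→I transition is Cp(I) − Cp(II), so
Cp(II) > Cp(I) makes the measured enthalpy fall as the DSC onset rises with
heating rate.  Kirchhoff shifts integrate the quadratic in closed form —
no quadrature error, exactly reversible.

Replicates are aggregated to the pooling unit (laboratory by default;
laboratory × heating-rate optional) as unweighted means; the unit's squared
standard error comes from the replicate scatter (`se_method="empirical"`,
matching error bars drawn as twice the standard error of replicates) or
from the stated per-record uncertainties (`"stated"`).  DerSimonian–Laird
pooling then uses fixed-effect weights 1/vᵢ, Q = Σwᵢ(yᵢ−ȳ)²,
τ² = max(0, (Q−(k−1))/(Σw − Σw²/Σw)), and random-effects weights
1/(vᵢ+τ²).

**Interval calibration.**  With few laboratories (k = 4) the nominal-95 %
interval built with the normal 1.96 multiplier undercovers: measured over
1000 simulated campaigns at the default design (τ = σ = 0.1 kJ/mol) it
covers the truth ≈ 88 % of the time — the well-documented small-k behaviour
of this estimator, not an implementation artefact (the estimator matches an
independent formula-level oracle and an external implementation to 10⁻¹⁰).
The expanded-uncertainty option (`ci_multiplier="t"`, Student t on k−1
degrees of freedom) covers ≈ 96 % and is what the coverage checks assert.
Both multipliers are available; the default remains 1.96.

The consensus anchors an enthalpy curve ΔH(T) = ΔH(T_ref) + ∫ ΔCp dT′
reported at 25 °C, and the onset-window statistic
ΔH(150 °C) − ΔH(170 °C) quantifies how much the measured enthalpy varies
across the onsets seen at common heating rates.

## Synthetic study conditions

The generators' defaults are the study conditions, chosen once:

- **Enantiotropic pair**: Einstein-mode recipes (soft block 50/100 cm⁻¹ vs
  58/105 cm⁻¹ over an identical stiff block), ΔE_latt solved so the ΔA = 0
  crossing sits at 324.15 K (51 °C, the solvent-mediated bracket for this
  system).  Einstein recipes keep the ground truth closed-form: the
  returned crossing is the bisection root of the analytic ΔA, so
  generator/consumer agreement is testable to 0.01 K.  A full phonon
  dispersion is *not* emulated; weights stand in for q-point sampling.
- **DSC campaign**: 4 labs × heating rates (1, 2, 5, 10, 20) K/min × 5
  replicates; onset = 425.15 K + 5.0·ln(rate) K (an affine-in-ln-rate
  kinetic shift — the functional form is a simulation choice, the data only
  say onsets "rise with rate"), spanning ≈ 152–167 °C; truth
  ΔH(150 °C) = 3.15 kJ/mol; between-lab sd τ = 0.1 and replicate sd
  σ = 0.1 kJ/mol.
- **ΔCp truth**: a·(T − 100)(T − 173.15) J/(mol K) with a ≈ −1.387×10⁻⁴
  solved in closed form so that ∫ from 150 °C down to 25 °C raises the
  enthalpy from 3.15 to exactly 4.02 kJ/mol.  The sign change at 173 K
  reproduces the crossing of the two forms' heat-capacity curves (form II
  lower below ≈ −100 °C, higher above).  These two constraints fix the
  150–170 °C window integral at ≈ 0.24 kJ/mol; a window variation as large
  as 0.55 kJ/mol is *not* representable by any quadratic ΔCp that also
  satisfies the crossing and the 25 °C shift — a genuine tension among the
  three literature figures that the acceptance checks surface rather than
  hide.  Form I's Cp quadratic gives 297.1 J/(mol K) at 300 K.
- **Lattice series**: orthorhombic only (both relevant forms are), linear
  axial growth with the c-axis dominant, calibrated to exactly 4.54 %
  volume growth over 150 → 416.15 K (−123.15 → 143 °C).
- **Polytypes**: layers are square grids of a rigid asymmetric 4-atom
  motif; a 'B' layer is the 180° rotation of an 'A' layer about the
  stacking axis.  Both polytypes share one layer-z scaffold (gap 4 Å
  between like layers, 9 Å bordering a flipped layer — a re-oriented layer
  packs at a different spacing, and the shared scaffold is what makes the
  pair a polytype).  With 5 Å in-plane spacing, a 15-molecule cluster is
  geometrically confined to two shared layers (perfect overlay) while a
  30-molecule cluster reaches the flipped layer (overlay drops to 25/30).
  No thermal motion, disorder or solvates are simulated, so overlay RMSDs
  on synthetic pairs are ≈ 0 rather than the tenths of an Ångström seen
  with experimental structures; the match-count signature, not the RMSD
  magnitude, is the transferable result.

Every generator is a pure function of (spec, seed) via
`numpy.random.default_rng`.

## Packing overlay

Molecules are recovered by bonding atom pairs whose minimum-image distance
is below the covalent-radius sum + 0.4 Å, taking connected components, and
unwrapping each by breadth-first accumulation of the bond image shifts
(error if a component spans more than half of all atoms — a covalent
network, not a molecular crystal).  Clusters grow the supercell until the
N-th neighbour distance is stable, with deterministic (distance, molecule
id, translation) tie-breaking.  The correspondence search is seeded on the
central-molecule pair; admissibility requires all matched inter-centroid
distances to agree within 20 % (relative) and each pair's own superposition
rotation to agree with the central seed rotation within 25° — conventional
packing-similarity tolerances, both flags.  Backtracking maximises the
matched count with best-first child ordering and a 10⁶-node budget (the
incumbent is returned on exhaustion).  Hydrogens are excluded by default
(robust to CIFs without H); inversion is tried by default and kept when it
lowers the RMSD of the final all-matched-atom Kabsch superposition, which
enforces a proper rotation and raises on rank-deficient point sets.

## Problem sizes and determinism

Defaults keep everything interactive on one core: temperature grids of a
few hundred points, 7-volume quasi-harmonic grids, 100-record DSC
campaigns, 1000-campaign coverage simulations, 30-molecule clusters from
108-atom cells.  The pipeline driver derives one named seed per stage from
the master seed; identical configuration and seed give byte-identical
outputs, and every stage logs its input checksums and parameters.

## Known limitations

- No phonon calculation: frequencies are inputs (or synthetic recipes).
- Constant-γ interpolation cannot follow crossing modes; anisotropic
  (cell-shape) quasi-harmonics and high-temperature anharmonicity are out
  of scope.
- Orthorhombic-only synthetic cells and a·b·c volumes; supply a volume
  column for anything else.
- The onset kinetic shift is phenomenological; no activation-energy model.
- Packing overlay handles rigid identical molecules; no disorder, no
  flexible-molecule conformational matching beyond what the rigid RMSD
  absorbs.
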
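"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator is a pure function of (spec, seed).  The defaults encode the
study conditions of the sulfamerazine I/II/V system:

* an enantiotropic pair — the higher-lattice-energy form has the softer
  low-frequency modes, hence higher vibrational entropy, and overtakes on
  heating (Einstein-mode recipes keep the ground truth closed-form);
* multi-laboratory DSC of the II -> I transition: onsets rising with
  heating rate over roughly 150-170 C, enthalpies falling with onset
  because Cp(II) > Cp(I), between-lab heterogeneity tau and replicate
  scatter sigma, truth dH(150 C) = 3.15 kJ/mol;
* quadratic-trend heat capacities with the form II curve crossing above
  form I near 173 K;
* smooth anisotropic orthorhombic lattice expansion (4.54 % volume growth
  over 150 K -> 416.15 K by construction);
* a pair of layered polytypes sharing identical layers, one with every
  third layer rotated 180 degrees about the stacking axis.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constants import AVOGADRO_NA, CELSIUS_OFFSET
from .harmonic import PhononSpectrum, mode_functions
from .structures import CrystalStructure, Site, UnitCell

__all__ = [
    "EnantiotropicPairSpec", "DscSimSpec", "PolytypeSpec",
    "make_phonon_pair", "make_cp_dataset", "make_dsc_dataset",
    "make_lattice_series", "make_polytype_pair", "make_solubility_dataset",
    "default_delta_cp_coef", "DEFAULT_CP_COEF_I",
    "DEFAULT_ENANTIOTROPIC_SPEC", "DEFAULT_DSC_SPEC", "DEFAULT_POLYTYPE_SPEC",
]


# --------------------------------------------------------------------------
# enantiotropic phonon pair

@dataclass
class EnantiotropicPairSpec:
    """Recipe for a pair of polymorphs with a free-energy crossing.

    ``delta_e_latt`` is E_latt(A) - E_latt(B) in kJ/mol: positive means A is
    the less stable form at 0 K, so A must carry the higher vibrational
    entropy (softer mean frequency) for a crossing to exist.  If
    ``target_crossing_k`` is set, delta_e_latt is solved from the recipes so
    the crossing lands exactly there.
    """

    recipe_a: list[tuple[float, int]]  # (wavenumber cm^-1, multiplicity)
    recipe_b: list[tuple[float, int]]
    delta_e_latt: float = 3.0
    z: int = 1
    e_latt_b: float = -102.0  # kJ/mol, reference form
    target_crossing_k: float | None = None

    def __post_init__(self) -> None:
        for recipe in (self.recipe_a, self.recipe_b):
            for nu, mult in recipe:
                if nu <= 0:
                    raise ValueError("all recipe frequencies must be positive")
                if mult < 1 or int(mult) != mult:
                    raise ValueError("multiplicities must be positive integers")
        if self.delta_e_latt > 0 and self.target_crossing_k is None:
            # classical entropy order: higher S <=> lower weighted mean ln(nu)
            def mean_ln(recipe):
                w = np.array([m for _, m in recipe], float)
                nu = np.array([f for f, _ in recipe], float)
                return float(np.dot(w, np.log(nu)) / w.sum())

            if mean_ln(self.recipe_a) >= mean_ln(self.recipe_b):
                raise ValueError(
                    "delta_e_latt > 0 requires form A to have the higher "
                    "vibrational entropy (lower mean frequency)"
                )


def _recipe_arrays(recipe):
    nu = np.array([f for f, _ in recipe], float)
    w = np.array([m for _, m in recipe], float)
    return nu, w


def _delta_a_vib(spec: EnantiotropicPairSpec, t: float) -> float:
    """A_vib(A) - A_vib(B) in J per mole of molecules (closed form)."""
    nu_a, w_a = _recipe_arrays(spec.recipe_a)
    nu_b, w_b = _recipe_arrays(spec.recipe_b)
    _, a_a, _, _ = mode_functions(nu_a, t)
    _, a_b, _, _ = mode_functions(nu_b, t)
    return AVOGADRO_NA / spec.z * (float(np.dot(w_a, a_a)) - float(np.dot(w_b, a_b)))


def make_phonon_pair(spec: EnantiotropicPairSpec, seed: int,
                     jitter_sd: float = 0.0
                     ) -> tuple[PhononSpectrum, PhononSpectrum, float]:
    """Two Einstein-mode phonon spectra and the exact dA = 0 crossing (K).

    The crossing solves ``1000*delta_e_latt + dA_vib(T) = 0`` by bisection to
    0.01 K on [1, 1000] K.  Optional log-normal jitter (sd in ln-space) is
    applied to the emitted mode frequencies only — the returned crossing is
    the truth of the noise-free recipe.
    """
    de = spec.delta_e_latt
    if spec.target_crossing_k is not None:
        de = -_delta_a_vib(spec, spec.target_crossing_k) / 1000.0

    def g(t):
        return de * 1000.0 + _delta_a_vib(spec, t)

    lo, hi = 1.0, 1000.0
    if g(lo) * g(hi) >= 0:
        raise ValueError(
            "dA has no sign change in [1, 1000] K; change the recipe "
            "(larger frequency contrast or smaller |delta_e_latt|)"
        )
    crossing = float(brentq(g, lo, hi, xtol=0.01))

    rng = np.random.default_rng(seed)
    specs = []
    for recipe, e_latt, label in (
        (spec.recipe_a, spec.e_latt_b + de, "A"),
        (spec.recipe_b, spec.e_latt_b, "B"),
    ):
        nu, w = _recipe_arrays(recipe)
        nu = np.repeat(nu, w.astype(int))
        if jitter_sd > 0:
            nu = nu * np.exp(rng.normal(0.0, jitter_sd, nu.size))
        specs.append(PhononSpectrum(nu, z=spec.z, lattice_energy=e_latt, label=label))
    return specs[0], specs[1], crossing


# softer low-frequency recipe for the high-entropy form, identical stiff block
DEFAULT_ENANTIOTROPIC_SPEC = EnantiotropicPairSpec(
    recipe_a=[(50.0, 6), (100.0, 6), (1500.0, 20)],
    recipe_b=[(58.0, 6), (105.0, 6), (1500.0, 20)],
    z=1,
    e_latt_b=-102.0,
    target_crossing_k=324.15,  # 51 C, the slurry-bracketed region
)


# --------------------------------------------------------------------------
# heat capacities and DSC

def default_delta_cp_coef() -> tuple[float, float, float]:
    """Default truth for dCp(I-II) = a (T - 100)(T - 173.15) J/(mol K).

    The scale ``a`` is solved in closed form so that
    int_{298.15}^{423.15} dCp dT = -870 J/mol, i.e. the transition enthalpy
    grows from 3.15 kJ/mol at 150 C to 4.02 kJ/mol at 25 C; the sign change
    at 173.15 K reproduces the crossing of the two forms' Cp curves.
    """
    r1, r2 = 100.0, 173.15

    def anti(t):
        return t**3 / 3.0 - (r1 + r2) * t**2 / 2.0 + r1 * r2 * t

    a = -870.0 / (anti(423.15) - anti(298.15))
    return (a * r1 * r2, -a * (r1 + r2), a)


#: quadratic Cp of the high-temperature form (J/(mol K), T in K);
#: gives Cp(300 K) = 297.1
DEFAULT_CP_COEF_I = (24.1, 0.88, 1.0e-4)


def make_cp_dataset(coef_by_form: dict[str, tuple[float, float, float]] | None = None,
                    t_range: tuple[float, float] = (260.0, 440.0),
                    noise_sd: float = 1.0, n_points: int = 50,
                    seed: int = 0) -> pd.DataFrame:
    """Noisy quadratic Cp(T) points per form, in the `cp` CSV schema."""
    if coef_by_form is None:
        c_i = np.array(DEFAULT_CP_COEF_I)
        c_ii = c_i - np.array(default_delta_cp_coef())
        coef_by_form = {"I": tuple(c_i), "II": tuple(c_ii)}
    if t_range[0] <= 0:
        raise ValueError("temperature range must be positive (Kelvin)")
    if n_points < 3:
        raise ValueError("need at least 3 points per form")
    rng = np.random.default_rng(seed)
    rows = []
    for form, (c0, c1, c2) in coef_by_form.items():
        t = np.linspace(*t_range, n_points)
        cp = c0 + c1 * t + c2 * t * t + rng.normal(0.0, noise_sd, n_points)
        rows.append(pd.DataFrame({"T_K": t, "form": form, "cp_J_per_molK": cp}))
    return pd.concat(rows, ignore_index=True)


@dataclass
class DscSimSpec:
    """Design of a multi-laboratory DSC campaign for one transition."""

    n_labs: int = 4
    replicates: int = 5
    heating_rates: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0, 20.0)
    dh_ref_kj: float = 3.15
    tref_k: float = 423.15
    dcp_coef: tuple[float, float, float] = field(default_factory=default_delta_cp_coef)
    onset_t0_k: float = 425.15  # onset at 1 K/min
    onset_slope_k_per_ln_rate: float = 5.0
    onset_noise_sd_k: float = 0.5
    tau_kj: float = 0.1  # between-lab sd
    sigma_kj: float = 0.1  # within-measurement sd

    def __post_init__(self) -> None:
        if self.n_labs < 2:
            raise ValueError("need at least 2 labs")
        if self.tau_kj < 0 or self.sigma_kj <= 0:
            raise ValueError("tau must be >= 0 and sigma > 0")
        if any(r <= 0 for r in self.heating_rates):
            raise ValueError("heating rates must be positive")


DEFAULT_DSC_SPEC = DscSimSpec()


def _dcp_integral(coef, t0, t1):
    c0, c1, c2 = coef

    def anti(t):
        return c0 * t + c1 * t * t / 2.0 + c2 * t**3 / 3.0

    return anti(t1) - anti(t0)


def make_dsc_dataset(spec: DscSimSpec, seed: int) -> pd.DataFrame:
    """Simulated per-replicate DSC records in the `dsc` CSV schema.

    onset = T0 + s ln(rate) + N(0, onset_sd^2);
    dH = dH(T_ref) + int_{T_ref}^{onset} dCp dT + lab effect N(0, tau^2)
    + N(0, sigma^2); the stated uncertainty column is sigma.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for lab_i in range(spec.n_labs):
        lab_effect = rng.normal(0.0, spec.tau_kj) if spec.tau_kj > 0 else 0.0
        for rate in spec.heating_rates:
            for _ in range(spec.replicates):
                onset = (spec.onset_t0_k
                         + spec.onset_slope_k_per_ln_rate * np.log(rate))
                if spec.onset_noise_sd_k > 0:
                    onset += rng.normal(0.0, spec.onset_noise_sd_k)
                dh = (spec.dh_ref_kj
                      + _dcp_integral(spec.dcp_coef, spec.tref_k, onset) / 1000.0
                      + lab_effect)
                dh += rng.normal(0.0, spec.sigma_kj)
                rows.append({
                    "lab": f"lab{lab_i + 1}",
                    "heating_rate_K_per_min": rate,
                    "onset_T_C": onset - CELSIUS_OFFSET,
                    "dH_kJ_per_mol": dh,
                    "u_dH_kJ_per_mol": spec.sigma_kj,
                })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# lattice expansion

def make_lattice_series(base_cell: UnitCell | tuple[float, float, float],
                        axial_growth: dict[str, float] | None = None,
                        t_range: tuple[float, float] = (150.0, 416.15),
                        n_points: int = 20, noise_sd_a: float = 0.0,
                        seed: int = 0) -> pd.DataFrame:
    """Orthorhombic lattice parameters vs temperature (`lattice` schema).

    ``axial_growth`` maps axis -> fractional linear growth over the range;
    each axis expands linearly in T.  Defaults give 4.54 % volume growth over
    150 -> 416.15 K with the largest expansion along c.
    """
    if isinstance(base_cell, UnitCell):
        if not base_cell.is_orthorhombic:
            raise ValueError("only orthorhombic synthetic cells are supported")
        a0, b0, c0 = base_cell.a, base_cell.b, base_cell.c
    else:
        a0, b0, c0 = base_cell
    if axial_growth is None:
        ga, gb = 0.006, 0.015
        gc = 1.0454 / ((1 + ga) * (1 + gb)) - 1.0  # exact 4.54 % volume growth
        axial_growth = {"a": ga, "b": gb, "c": gc}
    t = np.linspace(*t_range, n_points)
    frac = (t - t_range[0]) / (t_range[1] - t_range[0])
    rng = np.random.default_rng(seed)
    data = {"T_K": t}
    for axis, base in zip("abc", (a0, b0, c0)):
        series = base * (1.0 + axial_growth[axis] * frac)
        if noise_sd_a > 0:
            series = series + rng.normal(0.0, noise_sd_a, n_points)
        if (series <= 0).any():
            raise ValueError("expansion polynomial yields non-positive lengths")
        data[f"{axis}_A"] = series
    df = pd.DataFrame(data)
    df["V_A3"] = df["a_A"] * df["b_A"] * df["c_A"]
    return df


# --------------------------------------------------------------------------
# polytypes

#: rigid asymmetric 4-atom motif (element, Cartesian offset in A); no
#: rotational symmetry, so a layer flip is detectable by orientation
_DEFAULT_MOTIF = (
    ("C", (0.0, 0.0, 0.0)),
    ("N", (1.4, 0.0, 0.2)),
    ("O", (0.3, 1.2, -0.3)),
    ("S", (-0.7, -0.5, 0.9)),
)


@dataclass
class PolytypeSpec:
    """Layered structures differing only in their stacking sequence.

    Each layer is a square grid of identical rigid molecules.  A 'B' code
    means the layer is rotated 180 degrees about the stacking axis (through
    the cell origin).  Both polytypes share one layer-z scaffold, derived
    from the sequence containing flips: the gap bordering a flipped layer is
    ``gap_flip``, all others ``gap_same`` — re-oriented layers pack at a
    different spacing, which is what lets a cluster be confined to the
    common layers.
    """

    stacking_a: str = "AAA"
    stacking_b: str = "AAB"
    motif: tuple = _DEFAULT_MOTIF
    grid_n: int = 3
    in_plane_spacing: float = 5.0
    gap_same: float = 4.0
    gap_flip: float = 9.0

    def __post_init__(self) -> None:
        if len(self.stacking_a) != len(self.stacking_b):
            raise ValueError("stacking sequences must have equal length")
        if len(self.motif) < 3:
            raise ValueError("motif needs at least 3 atoms")
        if set(self.stacking_a + self.stacking_b) - {"A", "B"}:
            raise ValueError("stacking codes must be 'A'/'B' strings")


DEFAULT_POLYTYPE_SPEC = PolytypeSpec()


def _layer_z_positions(spec: PolytypeSpec) -> tuple[np.ndarray, float]:
    codes = spec.stacking_b if "B" in spec.stacking_b else spec.stacking_a
    n = len(codes)
    gaps = []
    for k in range(n):  # gap between layer k and layer k+1 (periodic)
        nxt = codes[(k + 1) % n]
        gaps.append(spec.gap_flip if (codes[k] == "B" or nxt == "B") else spec.gap_same)
    z = np.concatenate([[0.0], np.cumsum(gaps[:-1])])
    return z, float(np.sum(gaps))


def _build_polytype(spec: PolytypeSpec, codes: str) -> CrystalStructure:
    z_pos, c_len = _layer_z_positions(spec)
    a_len = b_len = spec.grid_n * spec.in_plane_spacing
    cell = UnitCell(a_len, b_len, c_len)
    flip = np.diag([-1.0, -1.0, 1.0])  # 180 deg about the stacking axis
    sites = []
    coords_all = []
    for layer, code in enumerate(codes):
        for i in range(spec.grid_n):
            for j in range(spec.grid_n):
                origin = np.array([i * spec.in_plane_spacing,
                                   j * spec.in_plane_spacing, z_pos[layer]])
                for el, off in spec.motif:
                    cart = origin + np.asarray(off, float)
                    if code == "B":
                        cart = flip @ np.array([cart[0], cart[1], 0.0]) + np.array([0, 0, cart[2]])
                    coords_all.append(cart)
                    frac = (cart[0] / a_len, cart[1] / b_len, cart[2] / c_len)
                    sites.append(Site(el, frac, f"{el}{len(sites) + 1}"))
    # overlap check over minimum images
    arr = np.array(coords_all)
    box = np.array([a_len, b_len, c_len])
    n_mol_atoms = len(spec.motif)
    for i in range(len(arr)):
        for j in range(i + 1, len(arr)):
            if i // n_mol_atoms == j // n_mol_atoms:
                continue
            d = arr[i] - arr[j]
            d -= box * np.round(d / box)
            if np.linalg.norm(d) < 0.8:
                raise ValueError("overlapping atoms after stacking; widen spacings")
    return CrystalStructure(cell=cell, sites=sites, name=f"polytype_{codes}")


def make_polytype_pair(spec: PolytypeSpec = DEFAULT_POLYTYPE_SPEC
                       ) -> tuple[CrystalStructure, CrystalStructure]:
    """Two P1 layered structures sharing the layer scaffold; flipped layers
    per the stacking codes.  Identical codes give identical structures."""
    return _build_polytype(spec, spec.stacking_a), _build_polytype(spec, spec.stacking_b)


# --------------------------------------------------------------------------
# solubility lines

def make_solubility_dataset(crossing_t_c: float = 43.0,
                            slopes: tuple[float, float] = (0.30, 0.22),
                            base_a: float = 2.0,
                            t_points_c: tuple[float, ...] = (20, 30, 40, 50, 60),
                            noise_sd: float = 0.0, seed: int = 0,
                            forms: tuple[str, str] = ("II", "V")) -> pd.DataFrame:
    """Two linear clear-point solubility series crossing at a set temperature
    (`solubility` schema, temperatures in Celsius)."""
    m1, m2 = slopes
    b1 = base_a
    b2 = b1 + (m1 - m2) * crossing_t_c  # forces the intersection
    rng = np.random.default_rng(seed)
    rows = []
    for form, (m, b) in zip(forms, ((m1, b1), (m2, b2))):
        for t in t_points_c:
            y = m * t + b + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append({"T_C": t, "form": form, "solubility_mg_per_g": y})
    return pd.DataFrame(rows)
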
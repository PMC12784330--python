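"""Harmonic-oscillator statistical thermodynamics of molecular crystal
polymorphs from a set of phonon frequencies.

Each vibrational mode of wavenumber :math:`\\tilde\\nu` contributes, with
:math:`x = h c \\tilde\\nu / k_B T`,

.. math::

    u &= h c \\tilde\\nu\\,(1/2 + 1/(e^x - 1)) \\\\
    a &= h c \\tilde\\nu/2 + k_B T \\ln(1 - e^{-x}) \\\\
    s &= k_B\\,(x/(e^x - 1) - \\ln(1 - e^{-x})) \\\\
    c_v &= k_B\\, x^2 e^x / (e^x - 1)^2

Cell sums are divided by Z (molecules per cell) and scaled by Avogadro's
number, so every output is per mole of molecules.  The enthalpy baseline is
``H = E_latt + U_vib`` — the pressure-volume term between solid phases is
negligible (of order 1e-3 kJ/mol) and is neglected, which also makes the
Gibbs and Helmholtz free-energy differences between polymorphs identical.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .constants import AVOGADRO_NA, BOLTZMANN_KB, GAS_R, HC_JCM

__all__ = [
    "PhononSpectrum",
    "ThermoCurve",
    "PairResult",
    "mode_functions",
    "thermo_curve",
    "pair_analysis",
    "zpe_difference",
    "sublimation_baseline",
    "ACOUSTIC_CUTOFF_CM1",
]

#: wavenumbers below this (cm^-1) are treated as Gamma-point acoustic modes
ACOUSTIC_CUTOFF_CM1 = 0.05


@dataclass(frozen=True)
class PhononSpectrum:
    """Vibrational mode set for one polymorph's unit cell.

    Parameters
    ----------
    frequencies : array of mode wavenumbers in cm^-1 (all > 0 after the
        acoustic-mode filter; negative/imaginary input is an error because the
        harmonic model is invalid there).
    weights : sampling weights; their sum is the number of modes per cell
        covered by the sampling.  Default 1 per mode.
    z : molecules per cell.
    lattice_energy : E_latt in kJ/mol of molecules (static lattice relative
        to separated static molecules; typically negative).
    """

    frequencies: np.ndarray
    weights: np.ndarray = None  # type: ignore[assignment]
    z: int = 1
    lattice_energy: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        freqs = np.atleast_1d(np.asarray(self.frequencies, dtype=float))
        w = self.weights
        w = np.ones_like(freqs) if w is None else np.atleast_1d(np.asarray(w, dtype=float))
        if freqs.shape != w.shape:
            raise ValueError("frequencies and weights must have equal length")
        near_zero = np.abs(freqs) < ACOUSTIC_CUTOFF_CM1
        if near_zero.any():
            warnings.warn(
                f"dropping {int(near_zero.sum())} near-zero mode(s) "
                f"(|wavenumber| < {ACOUSTIC_CUTOFF_CM1} cm^-1, Gamma-point acoustic)",
                stacklevel=3,
            )
            freqs, w = freqs[~near_zero], w[~near_zero]
        if (freqs <= 0).any():
            bad = np.nonzero(freqs <= 0)[0]
            raise ValueError(
                f"negative/imaginary mode wavenumbers at indices {bad.tolist()}: "
                "the harmonic model is not valid for this structure"
            )
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        if self.z < 1 or int(self.z) != self.z:
            raise ValueError("z (molecules per cell) must be a positive integer")
        object.__setattr__(self, "frequencies", freqs)
        object.__setattr__(self, "weights", w)

    @property
    def zpe(self) -> float:
        """Zero-point energy, J per mole of molecules."""
        per_cell = 0.5 * HC_JCM * float(np.dot(self.weights, self.frequencies))
        return AVOGADRO_NA * per_cell / self.z


def mode_functions(nu_cm1, t_kelvin):
    """Per-mode thermodynamic functions (u, a, s, cv) in J and J/K.

    Vectorised over both arguments; uses exp(-x) forms throughout so that
    large x (low T or stiff modes) never overflows.
    """
    nu = np.asarray(nu_cm1, dtype=float)
    t = np.asarray(t_kelvin, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("mode wavenumber must be positive")
    if np.any(t <= 0):
        raise ValueError("temperature must be positive")
    eps = HC_JCM * nu  # mode quantum, J
    x = eps / (BOLTZMANN_KB * t)
    emx = np.exp(-x)
    occ = emx / (1.0 - emx)  # Bose occupation 1/(e^x - 1)
    log1m = np.log1p(-emx)
    u = eps * (0.5 + occ)
    a = 0.5 * eps + BOLTZMANN_KB * t * log1m
    s = BOLTZMANN_KB * (x * occ - log1m)
    cv = BOLTZMANN_KB * x**2 * emx / (1.0 - emx) ** 2
    return u, a, s, cv


@dataclass
class ThermoCurve:
    """Temperature-gridded molar thermodynamic functions for one polymorph.

    Units: J/mol (energies), J/(mol K) (entropy, heat capacity), per mole of
    molecules.  ``helmholtz`` and ``enthalpy`` include the static lattice
    energy; ``a_vib`` is the vibrational part alone.
    """

    temperatures: np.ndarray
    u_vib: np.ndarray
    a_vib: np.ndarray
    entropy: np.ndarray
    cv: np.ndarray
    zpe: float
    lattice_energy_j: float
    label: str = ""

    @property
    def helmholtz(self) -> np.ndarray:
        """A(T) = E_latt + A_vib(T), J/mol."""
        return self.lattice_energy_j + self.a_vib

    @property
    def enthalpy(self) -> np.ndarray:
        """H(T) = E_latt + U_vib(T) (pV neglected), J/mol."""
        return self.lattice_energy_j + self.u_vib

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "T_K": self.temperatures,
                "U_vib_J_per_mol": self.u_vib,
                "A_J_per_mol": self.helmholtz,
                "H_J_per_mol": self.enthalpy,
                "S_J_per_molK": self.entropy,
                "Cv_J_per_molK": self.cv,
            }
        )


def thermo_curve(spec: PhononSpectrum, temperatures) -> ThermoCurve:
    """Harmonic thermodynamic functions of one polymorph on a T grid."""
    t = np.atleast_1d(np.asarray(temperatures, dtype=float))
    if np.any(t <= 0):
        raise ValueError("all grid temperatures must be positive")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("temperature grid must be strictly increasing")
    scale = AVOGADRO_NA / spec.z
    u, a, s, cv = mode_functions(spec.frequencies[:, None], t[None, :])
    w = spec.weights[:, None]
    return ThermoCurve(
        temperatures=t,
        u_vib=scale * np.sum(w * u, axis=0),
        a_vib=scale * np.sum(w * a, axis=0),
        entropy=scale * np.sum(w * s, axis=0),
        cv=scale * np.sum(w * cv, axis=0),
        zpe=spec.zpe,
        lattice_energy_j=spec.lattice_energy * 1000.0,
        label=spec.label,
    )


@dataclass
class PairResult:
    """Polymorph-pair differences (A minus B) and transition temperatures.

    ``transition_temperatures`` lists every root of dA(T) = 0 bracketed by a
    sign change on the grid, refined to 1e-3 K.  An empty list is a valid
    outcome (monotropic pair over the grid).
    """

    curve_a: ThermoCurve
    curve_b: ThermoCurve
    transition_temperatures: list[float] = field(default_factory=list)

    @property
    def temperatures(self) -> np.ndarray:
        return self.curve_a.temperatures

    @property
    def delta_a(self) -> np.ndarray:
        return self.curve_a.helmholtz - self.curve_b.helmholtz

    #: with pV neglected, dG between solid phases equals dA
    delta_g = delta_a

    @property
    def delta_h(self) -> np.ndarray:
        return self.curve_a.enthalpy - self.curve_b.enthalpy

    @property
    def delta_s(self) -> np.ndarray:
        return self.curve_a.entropy - self.curve_b.entropy

    @property
    def delta_cv(self) -> np.ndarray:
        return self.curve_a.cv - self.curve_b.cv

    @property
    def delta_zpe(self) -> float:
        return self.curve_a.zpe - self.curve_b.zpe

    def summary(self) -> str:
        lines = [
            f"Polymorph pair: {self.curve_a.label or 'A'} - {self.curve_b.label or 'B'}",
            f"  dE_latt = {(self.curve_a.lattice_energy_j - self.curve_b.lattice_energy_j) / 1000:+.4f} kJ/mol",
            f"  dZPE    = {self.delta_zpe / 1000:+.4f} kJ/mol",
        ]
        if self.transition_temperatures:
            for t in self.transition_temperatures:
                lines.append(f"  dA = 0 at T* = {t:.2f} K ({t - 273.15:.2f} C)")
        else:
            lines.append("  no dA = 0 crossing on the grid")
        return "\n".join(lines)


def pair_analysis(spec_a: PhononSpectrum, spec_b: PhononSpectrum, temperatures,
                  refine_tol_k: float = 1e-3) -> PairResult:
    """Free-energy difference curves between two polymorphs and the
    temperature(s) where the stability order inverts (dA = 0)."""
    curve_a = thermo_curve(spec_a, temperatures)
    curve_b = thermo_curve(spec_b, temperatures)
    t = curve_a.temperatures

    def delta_a_at(temp: float) -> float:
        ua, aa, sa, _ = mode_functions(spec_a.frequencies, temp)
        ub, ab, sb, _ = mode_functions(spec_b.frequencies, temp)
        da = (spec_a.lattice_energy - spec_b.lattice_energy) * 1000.0
        da += AVOGADRO_NA / spec_a.z * float(np.dot(spec_a.weights, aa))
        da -= AVOGADRO_NA / spec_b.z * float(np.dot(spec_b.weights, ab))
        return da

    grid_da = curve_a.helmholtz - curve_b.helmholtz
    roots: list[float] = []
    sign = np.sign(grid_da)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        root = brentq(delta_a_at, t[i], t[i + 1], xtol=refine_tol_k)
        roots.append(float(root))
    # an exact zero on a grid point between opposite signs also counts
    for i in np.nonzero(sign == 0)[0]:
        if 0 < i < len(t) - 1 and sign[i - 1] * sign[i + 1] < 0:
            roots.append(float(t[i]))
    return PairResult(curve_a, curve_b, sorted(roots))


def zpe_difference(spec_a: PhononSpectrum, spec_b: PhononSpectrum) -> float:
    """ZPE(A) - ZPE(B), kJ per mole of molecules."""
    return (spec_a.zpe - spec_b.zpe) / 1000.0


def sublimation_baseline(e_latt_kj: float, t_kelvin: float) -> float:
    """Static-lattice sublimation enthalpy estimate, kJ/mol.

    dH_sub = -E_latt - 2RT: ideal gas, equal crystal/gas conformations and
    Dulong-Petit solids.  Under this baseline polymorph enthalpy differences
    reduce to lattice-energy differences at every temperature, so it cannot
    describe enantiotropy — it is the reference the phonon models improve on.
    """
    if t_kelvin < 0:
        raise ValueError("temperature must be non-negative")
    return -e_latt_kj - 2.0 * GAS_R * t_kelvin / 1000.0
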
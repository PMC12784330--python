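"""Quasi-harmonic free-energy minimisation over cell volume.

The harmonic model fixes the structure, so it yields Cv and Helmholtz
energies only.  The quasi-harmonic approximation re-evaluates the phonon
frequencies at a range of fixed cell volumes; minimising

.. math:: F(V; T) = E(V) + A_{vib}(V, T)

over V at each temperature gives the equilibrium volume V_eq(T), hence the
volumetric expansion coefficient alpha(T), the bulk modulus
K = V d2F/dV2, the Gibbs energy G = F(V_eq) + p V_eq, and the isobaric heat
capacity through

.. math:: C_p(T) - C_v(T) = \\int_0^{T} V K \\alpha^2 \\, dT'

(the pointwise textbook form ``T V K alpha^2`` is co-reported; the two
coincide when the integrand is constant and differ otherwise).

Frequency-volume coupling assumes a constant Grueneisen parameter per mode:
ln(nu_i) is linear in ln(V) through matched mode indices across the grid.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar

from .constants import A3_TO_M3, AVOGADRO_NA
from .harmonic import PhononSpectrum, mode_functions

__all__ = ["VolumeGrid", "EVModel", "QhaResult", "QhaModel", "fit_ev",
           "free_energy_surface", "qha_solve", "cp_from_cv"]


@dataclass
class VolumeGrid:
    """Static energies and phonon spectra on a grid of fixed cell volumes.

    volumes : cell volumes, A^3
    energies : static lattice energies E(V), kJ per mole of molecules
    spectra : PhononSpectrum at each volume (same mode count, same z)
    """

    volumes: np.ndarray
    energies: np.ndarray
    spectra: list[PhononSpectrum]

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.volumes.size < 3:
            raise ValueError("need at least 3 volumes")
        if len(set(np.round(self.volumes, 9))) != self.volumes.size:
            raise ValueError("volumes must be distinct")
        order = np.argsort(self.volumes)
        self.volumes = self.volumes[order]
        self.energies = self.energies[order]
        self.spectra = [self.spectra[i] for i in order]
        counts = {s.frequencies.size for s in self.spectra}
        if len(counts) != 1:
            raise ValueError("all spectra must share the same mode count")
        zs = {s.z for s in self.spectra}
        if len(zs) != 1:
            raise ValueError("all spectra must share z")
        interior = self.energies[1:-1].min()
        if interior > min(self.energies[0], self.energies[-1]):
            raise ValueError("E(V) must have an interior minimum on the grid")
        # flag mode crossings: constant-gamma interpolation assumes conserved ordering
        ranks = [np.argsort(np.argsort(s.frequencies)) for s in self.spectra]
        for r in ranks[1:]:
            if np.abs(r - ranks[0]).max() > 2:
                warnings.warn(
                    "mode ordering changes by more than 2 positions across the "
                    "volume grid; constant-Grueneisen interpolation is unreliable"
                )
                break

    @property
    def z(self) -> int:
        return self.spectra[0].z


class EVModel:
    """Polynomial (default cubic) or Murnaghan fit of E(V).

    Exposes ``e``, ``de_dv`` and ``d2e_dv2`` (kJ/mol, per A^3) plus the RMS
    residual of the fit.
    """

    def __init__(self, volumes, energies, kind: str = "cubic"):
        v = np.asarray(volumes, float)
        e = np.asarray(energies, float)
        self.kind = kind
        self.vmin, self.vmax = float(v.min()), float(v.max())
        if kind == "cubic":
            deg = min(3, v.size - 1)
            self._poly = np.polynomial.Polynomial.fit(v, e, deg)
            self._d1 = self._poly.deriv(1)
            self._d2 = self._poly.deriv(2)
            self.residual_rms = float(np.sqrt(np.mean((self._poly(v) - e) ** 2)))
        elif kind == "murnaghan":
            def murn(vv, e0, v0, b0, bp):
                return e0 + b0 * vv / bp * ((v0 / vv) ** bp / (bp - 1) + 1) - v0 * b0 / (bp - 1)

            i0 = int(np.argmin(e))
            # curvature estimate seeds B0 on the right scale
            quad = np.polyfit(v, e, 2)
            b0_guess = max(2.0 * quad[0] * v[i0], 1e-6)
            p0 = [e[i0], v[i0], b0_guess, 4.0]
            popt, _ = curve_fit(murn, v, e, p0=p0, maxfev=20000)
            self._params = popt
            self._murn = murn
            h = 1e-5 * (self.vmax - self.vmin)
            self._d1 = lambda vv: (murn(vv + h, *popt) - murn(vv - h, *popt)) / (2 * h)
            self._d2 = lambda vv: (murn(vv + h, *popt) - 2 * murn(vv, *popt) + murn(vv - h, *popt)) / h**2
            self.residual_rms = float(np.sqrt(np.mean((murn(v, *popt) - e) ** 2)))
        else:
            raise ValueError("kind must be 'cubic' or 'murnaghan'")
        # require an interior minimum of the fitted model
        vv = np.linspace(self.vmin, self.vmax, 2001)
        i = int(np.argmin(self.e(vv)))
        if i in (0, len(vv) - 1):
            raise ValueError(
                "fitted E(V) has no interior minimum within the grid hull; "
                "widen the volume grid"
            )
        self.v_static_min = float(vv[i])

    def e(self, v):
        return self._poly(v) if self.kind == "cubic" else self._murn(np.asarray(v, float), *self._params)

    def de_dv(self, v):
        return self._d1(v)

    def d2e_dv2(self, v):
        return self._d2(v)


def fit_ev(grid: VolumeGrid, kind: str = "cubic") -> EVModel:
    """Least-squares energy-volume model over the grid."""
    return EVModel(grid.volumes, grid.energies, kind=kind)


def _gruneisen_coeffs(grid: VolumeGrid) -> tuple[np.ndarray, np.ndarray]:
    """Per-mode least-squares line ln(nu) = a + b ln(V) across the grid."""
    lnv = np.log(grid.volumes)
    lnf = np.log(np.stack([s.frequencies for s in grid.spectra]))  # (nvol, nmode)
    x = np.vstack([np.ones_like(lnv), lnv]).T
    coef, *_ = np.linalg.lstsq(x, lnf, rcond=None)
    return coef[0], coef[1]  # intercepts, slopes (= -gamma per mode)


def interpolated_spectrum(grid: VolumeGrid, volume: float) -> PhononSpectrum:
    """Phonon spectrum at an arbitrary volume via constant-gamma mapping."""
    a, b = _gruneisen_coeffs(grid)
    freqs = np.exp(a + b * np.log(volume))
    ref = grid.spectra[0]
    return PhononSpectrum(freqs, ref.weights.copy(), z=ref.z,
                          lattice_energy=0.0, label=ref.label)


def free_energy_surface(grid: VolumeGrid, t_kelvin: float, ev: EVModel | None = None):
    """Return F(V; T) = E(V) + A_vib(V, T) in J/mol as a callable of V (A^3)."""
    if t_kelvin <= 0:
        raise ValueError("temperature must be positive")
    ev = ev or fit_ev(grid)
    a_int, b_slope = _gruneisen_coeffs(grid)
    ref = grid.spectra[0]
    scale = AVOGADRO_NA / ref.z

    def f_of_v(v):
        freqs = np.exp(a_int + b_slope * np.log(v))
        _, a_mode, _, _ = mode_functions(freqs, t_kelvin)
        return ev.e(v) * 1000.0 + scale * float(np.dot(ref.weights, a_mode))

    return f_of_v


@dataclass
class QhaResult:
    """Equilibrium-volume thermodynamics on a temperature grid.

    Units: volumes A^3 per cell, K(T) in Pa, G in J/mol, heat capacities in
    J/(mol K); ``boundary_flags`` marks temperatures where the minimiser hit
    the volume-grid hull (values there are unreliable).
    """

    temperatures: np.ndarray
    v_eq: np.ndarray
    alpha: np.ndarray
    bulk_modulus: np.ndarray
    gibbs: np.ndarray
    helmholtz: np.ndarray
    cv: np.ndarray
    cp: np.ndarray
    cp_pointwise: np.ndarray
    boundary_flags: np.ndarray
    pressure: float
    z: int

    @property
    def cp_discrepancy(self) -> np.ndarray:
        """Integral-form minus pointwise-form Cp (zero for constant integrand)."""
        return self.cp - self.cp_pointwise

    def summary(self) -> str:
        i = len(self.temperatures) // 2
        t = self.temperatures
        return "\n".join(
            [
                "Quasi-harmonic solution",
                f"  T range        : {t[0]:.1f} - {t[-1]:.1f} K ({t.size} points)",
                f"  V_eq({t[i]:.0f} K)   : {self.v_eq[i]:.3f} A^3/cell",
                f"  alpha({t[i]:.0f} K)  : {self.alpha[i]:.3e} 1/K",
                f"  K({t[i]:.0f} K)      : {self.bulk_modulus[i] / 1e9:.3f} GPa",
                f"  Cp-Cv({t[i]:.0f} K)  : {self.cp[i] - self.cv[i]:.4f} J/(mol K)",
                f"  hull-boundary hits: {int(self.boundary_flags.sum())}",
            ]
        )


def cp_from_cv(cv, v_molar, k_pa, alpha, temperatures):
    """Isobaric from isochoric heat capacity.

    Primary (integral) form: Cp(T) = Cv(T) + int_0^T V K alpha^2 dT' by
    trapezoidal quadrature; below the first grid point the integrand is
    linearly extrapolated (from the first two points) down to T = 0, which
    keeps a constant integrand exact.  Also returns the pointwise form
    Cv + T V K alpha^2.

    Parameters are on a common temperature grid; ``v_molar`` in m^3/mol,
    ``k_pa`` in Pa, ``alpha`` in 1/K.  Returns ``(cp_integral, cp_pointwise)``.
    """
    cv = np.asarray(cv, float)
    t = np.asarray(temperatures, float)
    v = np.broadcast_to(np.asarray(v_molar, float), cv.shape)
    k = np.broadcast_to(np.asarray(k_pa, float), cv.shape)
    al = np.broadcast_to(np.asarray(alpha, float), cv.shape)
    if not (cv.shape == t.shape):
        raise ValueError("all series must share one temperature grid")
    integrand = v * k * al**2
    cum = np.concatenate([[0.0], np.cumsum(np.diff(t) * 0.5 * (integrand[1:] + integrand[:-1]))])
    if t.size > 1:  # linear extrapolation of the integrand onto [0, T0]
        slope = (integrand[1] - integrand[0]) / (t[1] - t[0])
        g_at_zero = integrand[0] - slope * t[0]
        head = 0.5 * (g_at_zero + integrand[0]) * t[0]
    else:
        head = integrand[0] * t[0]
    return cv + cum + head, cv + t * integrand


class QhaModel:
    """statsmodels-style front end: ``QhaModel(grid, pressure).fit(t_grid)``."""

    def __init__(self, grid: VolumeGrid, pressure_pa: float = 101325.0,
                 ev_kind: str = "cubic"):
        self.grid = grid
        self.pressure = pressure_pa
        self.ev = fit_ev(grid, kind=ev_kind)
        self._a_int, self._b_slope = _gruneisen_coeffs(grid)

    def fit(self, temperatures) -> QhaResult:
        return qha_solve(self.grid, temperatures, self.pressure, ev=self.ev)


def qha_solve(grid: VolumeGrid, temperatures, pressure_pa: float = 101325.0,
              ev: EVModel | None = None) -> QhaResult:
    """Minimise F(V;T) per temperature and derive alpha, K, G, Cv, Cp."""
    t = np.atleast_1d(np.asarray(temperatures, float))
    if np.any(t <= 0) or (t.size > 1 and np.any(np.diff(t) <= 0)):
        raise ValueError("temperature grid must be positive and strictly increasing")
    ev = ev or fit_ev(grid)
    z = grid.z
    vlo, vhi = grid.volumes.min(), grid.volumes.max()
    edge = 1e-4 * (vhi - vlo)

    v_eq = np.empty_like(t)
    f_eq = np.empty_like(t)
    kmod = np.empty_like(t)
    cv = np.empty_like(t)
    flags = np.zeros(t.size, dtype=bool)

    for i, ti in enumerate(t):
        f = free_energy_surface(grid, ti, ev=ev)
        res = minimize_scalar(f, bounds=(vlo, vhi), method="bounded",
                              options={"xatol": 1e-6 * (vhi - vlo)})
        v = float(res.x)
        if v - vlo < edge or vhi - v < edge:
            warnings.warn(f"T = {ti:.2f} K: quasi-harmonic minimum at the "
                          "volume-grid hull; value flagged unreliable")
            flags[i] = True
        v_eq[i] = v
        f_eq[i] = f(v)
        h = 1e-3 * (vhi - vlo)
        d2 = (f(v + h) - 2.0 * f(v) + f(v - h)) / h**2  # J/mol per A^6
        v_molar_i = v * A3_TO_M3 * AVOGADRO_NA / z
        # K = V d2F/dV2 with V in molar units: (J/mol)/(m^3/mol) = Pa
        kmod[i] = v_molar_i * d2 / (A3_TO_M3 * AVOGADRO_NA / z) ** 2
        spec_v = interpolated_spectrum(grid, v)
        _, _, _, cv_modes = mode_functions(spec_v.frequencies, ti)
        cv[i] = AVOGADRO_NA / z * float(np.dot(spec_v.weights, cv_modes))

    alpha = np.gradient(v_eq, t) / v_eq
    v_molar = v_eq * A3_TO_M3 * AVOGADRO_NA / z
    gibbs = f_eq + pressure_pa * v_molar
    cp_int, cp_pt = cp_from_cv(cv, v_molar, kmod, alpha, t)
    return QhaResult(t, v_eq, alpha, kmod, gibbs, f_eq, cv, cp_int, cp_pt,
                     flags, pressure_pa, z)
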
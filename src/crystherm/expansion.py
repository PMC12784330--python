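"""Variable-temperature lattice analysis: axial and volumetric thermal
expansion fits, percentage changes, densities and the polymorph pV term.

Both sulfamerazine forms treated here are orthorhombic, so when the volume
column is absent it is computed as a*b*c; a supplied V column is always
preferred and is required for non-orthogonal cells.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import A3_TO_M3, AVOGADRO_NA

__all__ = ["LatticeSeries", "ExpansionFit", "ExpansionModel", "fit_expansion",
           "percent_change", "density", "pdv_term"]

QUANTITIES = ("a", "b", "c", "V")
_COLS = {"a": "a_A", "b": "b_A", "c": "c_A", "V": "V_A3"}


@dataclass
class LatticeSeries:
    """Lattice parameters vs temperature, possibly from several sources."""

    table: pd.DataFrame  # columns T_K, a_A, b_A, c_A [, V_A3, source]
    z: int | None = None
    molar_mass: float | None = None  # g/mol

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in ("T_K", "a_A", "b_A", "c_A"):
            if col not in df.columns:
                raise ValueError(f"lattice series missing column {col!r}")
        if (df["T_K"] <= 0).any():
            raise ValueError("temperatures must be positive (Kelvin)")
        if (df[["a_A", "b_A", "c_A"]] <= 0).any().any():
            raise ValueError("lattice lengths must be positive")
        if "V_A3" not in df.columns or df["V_A3"].isna().all():
            df["V_A3"] = df["a_A"] * df["b_A"] * df["c_A"]
        else:
            df["V_A3"] = df["V_A3"].fillna(df["a_A"] * df["b_A"] * df["c_A"])
        if "source" not in df.columns:
            df["source"] = "default"
        self.table = df.sort_values("T_K").reset_index(drop=True)


@dataclass
class _PolyFit:
    coef: np.ndarray  # ascending powers
    cov: np.ndarray
    t_range: tuple[float, float]
    residual_sd: float

    def __call__(self, t):
        return np.polynomial.polynomial.polyval(np.asarray(t, dtype=float), self.coef)

    def deriv(self, t):
        dcoef = np.polynomial.polynomial.polyder(self.coef)
        return np.polynomial.polynomial.polyval(np.asarray(t, dtype=float), dcoef)

    @property
    def stderr(self):
        return np.sqrt(np.diag(self.cov))


@dataclass
class ExpansionFit:
    """Per-quantity polynomial fits q(T) and expansion coefficients.

    alpha_q(T) = (1/q) dq/dT in 1/K; for an orthorhombic cell
    alpha_V = alpha_a + alpha_b + alpha_c.
    """

    fits: dict[str, _PolyFit]
    degree: int
    source_residuals: pd.DataFrame
    z: int | None = None
    molar_mass: float | None = None

    def __call__(self, quantity: str, t):
        return self.fits[quantity](t)

    def alpha(self, quantity: str, t):
        """Instantaneous expansion coefficient (1/q) dq/dT, 1/K."""
        f = self.fits[quantity]
        return f.deriv(t) / f(t)

    def summary(self) -> str:
        lines = [f"Thermal expansion fit (degree {self.degree})"]
        lo, hi = self.fits["V"].t_range
        tm = 0.5 * (lo + hi)
        for q in QUANTITIES:
            lines.append(
                f"  {q:>2}: alpha({tm:.0f} K) = {self.alpha(q, tm):.3e} 1/K, "
                f"residual sd = {self.fits[q].residual_sd:.2e}"
            )
        if len(self.source_residuals) > 1:
            lines.append("  per-source residual means (inter-source offsets):")
            lines.append(self.source_residuals.to_string(float_format=lambda v: f"{v:.2e}"))
        return "\n".join(lines)


class ExpansionModel:
    """Least-squares polynomial model of a lattice-parameter series."""

    def __init__(self, series: LatticeSeries, degree: int = 2):
        n = len(series.table)
        if n < degree + 2:
            raise ValueError(f"need at least degree+2 = {degree + 2} points, got {n}")
        self.series = series
        self.degree = degree

    def fit(self) -> ExpansionFit:
        df = self.series.table
        t = df["T_K"].to_numpy(dtype=float)
        fits: dict[str, _PolyFit] = {}
        resid_rows = []
        for q in QUANTITIES:
            y = df[_COLS[q]].to_numpy(dtype=float)
            x = np.vander(t, self.degree + 1, increasing=True)
            coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
            resid = y - x @ coef
            dof = max(t.size - (self.degree + 1), 1)
            s2 = float(resid @ resid) / dof
            cov = s2 * np.linalg.inv(x.T @ x)
            fits[q] = _PolyFit(coef, cov, (float(t.min()), float(t.max())), float(np.sqrt(s2)))
            for src, sub_idx in df.groupby("source").groups.items():
                resid_rows.append(
                    {"quantity": q, "source": src,
                     "mean_residual": float(resid[df.index.get_indexer(sub_idx)].mean())}
                )
        fit = ExpansionFit(
            fits=fits,
            degree=self.degree,
            source_residuals=pd.DataFrame(resid_rows),
            z=self.series.z,
            molar_mass=self.series.molar_mass,
        )
        for q in QUANTITIES:
            tt = np.linspace(*fits[q].t_range, 101)
            if np.any(fits[q](tt) <= 0):
                raise ValueError(f"fitted {q}(T) is not positive over the data range")
        return fit


def fit_expansion(series: LatticeSeries, degree: int = 2) -> ExpansionFit:
    return ExpansionModel(series, degree=degree).fit()


def percent_change(fit: ExpansionFit, quantity: str, t1_k: float, t2_k: float,
                   mode: str = "fitted", series: LatticeSeries | None = None) -> float:
    """100 (q(T2) - q(T1)) / q(T1).

    ``mode='fitted'`` evaluates the fitted polynomial; ``mode='endpoints'``
    uses the raw data points nearest T1 and T2 (requires ``series``).
    """
    if mode == "fitted":
        q1 = float(fit(quantity, t1_k))
        q2 = float(fit(quantity, t2_k))
    elif mode == "endpoints":
        if series is None:
            raise ValueError("endpoints mode needs the raw series")
        df = series.table
        col = _COLS[quantity]
        q1 = float(df.iloc[(df["T_K"] - t1_k).abs().argmin()][col])
        q2 = float(df.iloc[(df["T_K"] - t2_k).abs().argmin()][col])
    else:
        raise ValueError("mode must be 'fitted' or 'endpoints'")
    return 100.0 * (q2 - q1) / q1


def density(volume_a3: float, z: int, molar_mass: float) -> float:
    """Crystal density in g/cm^3 from cell volume (A^3), Z and M (g/mol)."""
    if z is None or molar_mass is None:
        raise ValueError("z and molar_mass are both required")
    if volume_a3 <= 0:
        raise ValueError("volume must be positive")
    return z * molar_mass / (AVOGADRO_NA * volume_a3 * 1e-24)


def pdv_term(v_a_a3_per_molecule: float, v_b_a3_per_molecule: float,
             pressure_pa: float = 101325.0) -> float:
    """Molar p dV between two polymorphs, kJ/mol.

    Sign follows the argument order (A -> B reported as V_A - V_B).  At
    ambient pressure and typical molecular volumes this is of order
    1e-3 kJ/mol — the justification for neglecting pV in solid-solid
    thermodynamics.
    """
    if v_a_a3_per_molecule <= 0 or v_b_a3_per_molecule <= 0:
        raise ValueError("volumes must be positive")
    dv_m3_per_mol = (v_a_a3_per_molecule - v_b_a3_per_molecule) * A3_TO_M3 * AVOGADRO_NA
    return pressure_pa * dv_m3_per_mol / 1000.0
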
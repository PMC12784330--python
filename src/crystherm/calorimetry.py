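"""Transition-enthalpy consensus from multi-laboratory DSC.

Solid-solid transitions measured by DSC have onsets that shift upward with
heating rate, and because the two polymorphs differ in heat capacity the
measured enthalpy depends on the onset temperature.  The workflow here:

1. fit each form's measured Cp(T) to a quadratic (``CpModel``),
2. Kirchhoff-shift every DSC enthalpy from its onset to a common reference
   temperature using the closed-form integral of the quadratic dCp,
3. pool the laboratory means with a DerSimonian-Laird random-effects model
   (method-of-moments between-lab variance tau^2),
4. carry the pooled value across temperature as an enthalpy curve
   dH(T) = dH(Tref) + int_Tref^T dCp dT'.

Sign convention: for the II -> I transition dCp = Cp(I) - Cp(II); with
Cp(II) > Cp(I) the transition enthalpy decreases with temperature.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import CELSIUS_OFFSET

__all__ = [
    "CpFit", "CpModel", "fit_cp", "DeltaCp", "delta_cp", "kirchhoff_shift",
    "ConsensusResult", "RandomEffectsMeta", "dersimonian_laird",
    "EnthalpyCurve", "consensus_pipeline", "onset_range_variation",
    "solubility_crossing",
]


def _quad_design(t: np.ndarray) -> np.ndarray:
    return np.vstack([np.ones_like(t), t, t * t]).T


@dataclass
class CpFit:
    """Quadratic heat-capacity fit Cp(T) = c0 + c1 T + c2 T^2 (J/(mol K), T in K)."""

    form: str
    coef: np.ndarray  # (c0, c1, c2)
    cov: np.ndarray  # 3x3 covariance of the coefficients
    t_range: tuple[float, float]
    residual_sd: float
    n_points: int

    #: extrapolation beyond the fit range by more than this is flagged
    extrapolation_margin_k: float = 50.0

    def __call__(self, t, flag_extrapolation: bool = True):
        t = np.asarray(t, dtype=float)
        lo, hi = self.t_range
        m = self.extrapolation_margin_k
        if flag_extrapolation and np.any((t < lo - m) | (t > hi + m)):
            warnings.warn(
                f"Cp fit for {self.form!r} evaluated more than {m} K outside "
                f"its fit range [{lo:.1f}, {hi:.1f}] K"
            )
        c0, c1, c2 = self.coef
        return c0 + c1 * t + c2 * t * t

    @property
    def stderr(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def summary(self) -> str:
        names = ["c0", "c1", "c2"]
        lines = [
            f"Quadratic Cp fit: form {self.form!r} "
            f"({self.n_points} points, {self.t_range[0]:.1f}-{self.t_range[1]:.1f} K)",
            f"{'':>4}{'coef':>14}{'std err':>12}",
        ]
        for name, c, se in zip(names, self.coef, self.stderr):
            lines.append(f"{name:>4}{c:>14.6g}{se:>12.3g}")
        lines.append(f"residual sd = {self.residual_sd:.4g} J/(mol K)")
        return "\n".join(lines)


class CpModel:
    """Ordinary least squares quadratic for one form's Cp(T) data."""

    def __init__(self, t_kelvin, cp_j_per_molk, form: str = ""):
        t = np.asarray(t_kelvin, dtype=float)
        cp = np.asarray(cp_j_per_molk, dtype=float)
        if t.size != cp.size:
            raise ValueError("temperature and Cp arrays differ in length")
        if t.size < 4:
            raise ValueError("need at least 4 Cp points for a quadratic fit")
        bad = np.nonzero(~(np.isfinite(t) & np.isfinite(cp)))[0]
        if bad.size:
            raise ValueError(f"non-finite Cp data at rows {bad.tolist()}")
        if np.any(t <= 0):
            raise ValueError("temperatures must be positive (Kelvin)")
        self.t, self.cp, self.form = t, cp, form

    @classmethod
    def from_table(cls, cp_table: pd.DataFrame, form: str) -> "CpModel":
        sub = cp_table[cp_table["form"].astype(str) == str(form)]
        return cls(sub["T_K"].to_numpy(), sub["cp_J_per_molK"].to_numpy(), form=form)

    def fit(self) -> CpFit:
        x = _quad_design(self.t)
        coef, _, _, _ = np.linalg.lstsq(x, self.cp, rcond=None)
        resid = self.cp - x @ coef
        dof = self.t.size - 3
        s2 = float(resid @ resid) / dof if dof > 0 else 0.0
        cov = s2 * np.linalg.inv(x.T @ x)
        fit = CpFit(
            form=self.form,
            coef=coef,
            cov=cov,
            t_range=(float(self.t.min()), float(self.t.max())),
            residual_sd=float(np.sqrt(s2)),
            n_points=self.t.size,
        )
        if np.any(fit(np.linspace(*fit.t_range, 101), flag_extrapolation=False) <= 0):
            warnings.warn(f"fitted Cp for {self.form!r} is not positive over the fit range")
        return fit


def fit_cp(cp_table: pd.DataFrame, form: str) -> CpFit:
    """Quadratic OLS Cp fit for one form from a `cp`-schema table."""
    return CpModel.from_table(cp_table, form).fit()


@dataclass
class DeltaCp:
    """Difference of two quadratic Cp fits: dCp(T) = Cp(A) - Cp(B)."""

    coef: np.ndarray
    t_range: tuple[float, float]
    label: str = ""

    def __call__(self, t):
        c0, c1, c2 = self.coef
        t = np.asarray(t, dtype=float)
        return c0 + c1 * t + c2 * t * t

    def integral(self, t0: float, t1: float) -> float:
        """Closed-form integral of the quadratic between t0 and t1, J/mol."""
        c0, c1, c2 = self.coef

        def anti(t):
            return c0 * t + c1 * t * t / 2.0 + c2 * t**3 / 3.0

        return float(anti(t1) - anti(t0))

    def crossovers(self) -> list[float]:
        """Real roots of dCp(T) = 0 (sign-change temperatures), ascending."""
        c0, c1, c2 = self.coef
        if abs(c2) > 0:
            disc = c1 * c1 - 4.0 * c2 * c0
            if disc < 0:
                return []
            r = np.sqrt(disc)
            roots = sorted([(-c1 - r) / (2 * c2), (-c1 + r) / (2 * c2)])
        elif abs(c1) > 0:
            roots = [-c0 / c1]
        else:
            return []
        return [float(t) for t in roots if t > 0]


def delta_cp(fit_a: CpFit, fit_b: CpFit) -> DeltaCp:
    """dCp(T) = Cp_A(T) - Cp_B(T) from two quadratic fits."""
    lo = max(fit_a.t_range[0], fit_b.t_range[0])
    hi = min(fit_a.t_range[1], fit_b.t_range[1])
    if lo >= hi:
        raise ValueError("Cp fit ranges do not overlap")
    return DeltaCp(
        coef=np.asarray(fit_a.coef) - np.asarray(fit_b.coef),
        t_range=(lo, hi),
        label=f"{fit_a.form}-{fit_b.form}",
    )


def kirchhoff_shift(dh_kj: float, t0_k: float, tref_k: float, dcp: DeltaCp) -> float:
    """Shift a transition enthalpy between temperatures.

    dH(Tref) = dH(T0) + int_{T0}^{Tref} dCp dT, the quadratic integrated in
    closed form (no quadrature error).  Input/output in kJ/mol.
    """
    return dh_kj + dcp.integral(t0_k, tref_k) / 1000.0


@dataclass
class ConsensusResult:
    """DerSimonian-Laird random-effects pooled estimate.

    All enthalpies in kJ/mol; tau^2 in (kJ/mol)^2.  The confidence interval
    uses a normal 1.96 multiplier by default (a t-quantile option is on the
    model).
    """

    mean: float
    se: float
    tau2: float
    q: float
    df: int
    ci_halfwidth: float
    k_groups: int
    reference_temperature_k: float | None = None
    group_table: pd.DataFrame | None = None
    fixed_effect_mean: float = np.nan
    fixed_effect_se: float = np.nan

    @property
    def ci(self) -> tuple[float, float]:
        return (self.mean - self.ci_halfwidth, self.mean + self.ci_halfwidth)

    def summary(self) -> str:
        lines = ["DerSimonian-Laird random-effects consensus"]
        if self.reference_temperature_k is not None:
            lines.append(
                f"  reference T : {self.reference_temperature_k:.2f} K "
                f"({self.reference_temperature_k - CELSIUS_OFFSET:.2f} C)"
            )
        lines += [
            f"  pooled dH   : {self.mean:.3f} +/- {self.ci_halfwidth:.3f} kJ/mol (95% CI)",
            f"  SE          : {self.se:.4f} kJ/mol",
            f"  tau^2       : {self.tau2:.5f} (kJ/mol)^2",
            f"  Cochran Q   : {self.q:.3f} on {self.df} df  ({self.k_groups} groups)",
        ]
        if self.group_table is not None:
            lines.append(self.group_table.to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)


class RandomEffectsMeta:
    """DerSimonian-Laird meta-analysis of group-level estimates.

    ``values``/``variances`` are replicate-level measurements with squared
    standard uncertainties; ``groups`` are the pooling-unit labels (one lab,
    or one lab x heating-rate series).  Replicates are first combined into
    group means with squared standard errors.
    """

    def __init__(self, values, variances, groups=None, se_method: str = "empirical",
                 ci_multiplier: str = "normal"):
        y = np.asarray(values, dtype=float)
        v = np.asarray(variances, dtype=float)
        if y.size != v.size:
            raise ValueError("values and variances differ in length")
        if np.any(v <= 0):
            raise ValueError("all variances must be positive")
        if se_method not in ("empirical", "stated"):
            raise ValueError("se_method must be 'empirical' or 'stated'")
        self.se_method = se_method
        self.ci_multiplier = ci_multiplier
        if groups is None:
            groups = np.arange(y.size)
        self.frame = pd.DataFrame({"y": y, "v": v, "group": np.asarray(groups)})
        if self.frame["group"].nunique() < 2:
            raise ValueError("need at least 2 groups for a random-effects consensus")

    def _group_level(self) -> pd.DataFrame:
        rows = []
        for g, sub in self.frame.groupby("group", sort=True):
            n = len(sub)
            mean = float(sub["y"].mean())
            if self.se_method == "empirical" and n >= 2:
                var = float(sub["y"].var(ddof=1)) / n
                if var == 0.0:  # identical replicates: fall back on stated u
                    var = float(sub["v"].mean()) / n
            else:
                var = float(sub["v"].mean()) / n
            rows.append({"group": g, "n": n, "mean": mean, "var": var})
        return pd.DataFrame(rows)

    def fit(self, reference_temperature_k: float | None = None) -> ConsensusResult:
        gtab = self._group_level()
        y = gtab["mean"].to_numpy()
        v = gtab["var"].to_numpy()
        k = y.size
        w = 1.0 / v
        y_fe = float(np.sum(w * y) / np.sum(w))
        q = float(np.sum(w * (y - y_fe) ** 2))
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - (k - 1)) / denom)
        w_re = 1.0 / (v + tau2)
        mean = float(np.sum(w_re * y) / np.sum(w_re))
        se = float(np.sqrt(1.0 / np.sum(w_re)))
        if self.ci_multiplier == "normal":
            mult = 1.959963984540054
        elif self.ci_multiplier == "t":
            from scipy.stats import t as t_dist

            mult = float(t_dist.ppf(0.975, k - 1))
        else:
            raise ValueError("ci_multiplier must be 'normal' or 't'")
        gtab["weight_re"] = w_re / np.sum(w_re)
        return ConsensusResult(
            mean=mean,
            se=se,
            tau2=tau2,
            q=q,
            df=k - 1,
            ci_halfwidth=mult * se,
            k_groups=k,
            reference_temperature_k=reference_temperature_k,
            group_table=gtab,
            fixed_effect_mean=y_fe,
            fixed_effect_se=float(np.sqrt(1.0 / np.sum(w))),
        )


def dersimonian_laird(values, variances, groups=None, **kwargs) -> ConsensusResult:
    """Functional front end for :class:`RandomEffectsMeta`."""
    return RandomEffectsMeta(values, variances, groups=groups, **kwargs).fit()


@dataclass
class EnthalpyCurve:
    """dH(T) anchored at a reference value and carried by dCp integration."""

    dh_ref_kj: float
    tref_k: float
    dcp: DeltaCp

    def __call__(self, t_kelvin):
        t = np.asarray(t_kelvin, dtype=float)
        if t.ndim == 0:
            return kirchhoff_shift(self.dh_ref_kj, self.tref_k, float(t), self.dcp)
        return np.array([kirchhoff_shift(self.dh_ref_kj, self.tref_k, ti, self.dcp) for ti in t])


@dataclass
class ConsensusPipelineResult:
    consensus: ConsensusResult
    curve: EnthalpyCurve
    dh_at_298_kj: float
    corrected_records: pd.DataFrame

    def summary(self) -> str:
        return (
            self.consensus.summary()
            + f"\n  dH(298.15 K): {self.dh_at_298_kj:.3f} kJ/mol"
        )


def consensus_pipeline(dsc_table: pd.DataFrame, fit_product: CpFit,
                       fit_reactant: CpFit, tref_k: float,
                       unit: str = "lab", **meta_kwargs) -> ConsensusPipelineResult:
    """Kirchhoff-shift every DSC record to ``tref_k``, pool by lab, anchor the
    enthalpy-temperature curve at the pooled value.

    ``fit_product``/``fit_reactant`` are the Cp fits of the high- and
    low-temperature form (I and II for the II -> I transition), so the dCp
    convention is Cp(product) - Cp(reactant).
    """
    required = {"lab", "heating_rate_K_per_min", "onset_T_C", "dH_kJ_per_mol", "u_dH_kJ_per_mol"}
    missing = required - set(dsc_table.columns)
    if missing:
        raise ValueError(f"dsc table missing columns {sorted(missing)}")
    if dsc_table["u_dH_kJ_per_mol"].isna().any() or (dsc_table["u_dH_kJ_per_mol"] <= 0).any():
        raise ValueError("every DSC record needs a positive stated uncertainty")

    dcp = delta_cp(fit_product, fit_reactant)
    df = dsc_table.copy()
    df["onset_T_K"] = df["onset_T_C"] + CELSIUS_OFFSET
    df["dH_at_ref_kJ_per_mol"] = [
        kirchhoff_shift(dh, t0, tref_k, dcp)
        for dh, t0 in zip(df["dH_kJ_per_mol"], df["onset_T_K"])
    ]
    if unit == "lab":
        df["pool_unit"] = df["lab"].astype(str)
    elif unit == "lab_rate":
        df["pool_unit"] = df["lab"].astype(str) + "@" + df["heating_rate_K_per_min"].astype(str)
    else:
        raise ValueError("unit must be 'lab' or 'lab_rate'")

    meta = RandomEffectsMeta(
        df["dH_at_ref_kJ_per_mol"],
        df["u_dH_kJ_per_mol"] ** 2,
        groups=df["pool_unit"],
        **meta_kwargs,
    )
    consensus = meta.fit(reference_temperature_k=tref_k)
    curve = EnthalpyCurve(consensus.mean, tref_k, dcp)
    return ConsensusPipelineResult(
        consensus=consensus,
        curve=curve,
        dh_at_298_kj=float(curve(298.15)),
        corrected_records=df,
    )


def onset_range_variation(curve: EnthalpyCurve, t_low_k: float, t_high_k: float) -> float:
    """dH(T_low) - dH(T_high) over an onset-temperature window, kJ/mol.

    Positive when dCp < 0, i.e. when the measured enthalpy falls as the
    DSC onset moves up with heating rate.
    """
    return float(curve(t_low_k) - curve(t_high_k))


def solubility_crossing(points_a, points_b) -> float | None:
    """Temperature (same unit as the inputs) where two fitted solubility
    lines cross; ``None`` for parallel or coincident lines.

    Each input is an (n, 2) array-like of (temperature, solubility); a line
    is fitted to each by ordinary least squares.
    """
    out = []
    for pts in (points_a, points_b):
        arr = np.asarray(pts, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] != 2:
            raise ValueError("each solubility series needs >= 2 (T, value) points")
        t, y = arr[:, 0], arr[:, 1]
        if np.ptp(t) == 0:
            raise ValueError("degenerate solubility series: all temperatures equal")
        slope, intercept = np.polyfit(t, y, 1)
        out.append((slope, intercept))
    (m1, b1), (m2, b2) = out
    if np.isclose(m1, m2, rtol=1e-12, atol=1e-12):
        return None
    return float((b2 - b1) / (m1 - m2))
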
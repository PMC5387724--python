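"""Single-turnover glycosylase kinetics: progress curves, saturation, energies.

Under single-turnover conditions (enzyme in excess over substrate) product
formation follows the integrated first-order rate law

    P(t) = P_max · (1 − exp(−k_obs · t))

and the apparent rate constant k_obs saturates hyperbolically with total
enzyme concentration [E0]:

    k_obs = k2 · [E0] / (Km + [E0])

where k2 is the single-turnover catalytic rate constant and Km the
half-saturating enzyme concentration.  When Km ≫ [E0] the hyperbola is
indistinguishable from a line through the origin and only the catalytic
efficiency k2/Km is identifiable:

    k_obs = (k2/Km) · [E0]

Mutational effects are expressed as fold changes in k2/Km, apparent
transition-state free-energy penalties

    ΔΔG = −RT · ln[(k2/Km)_mutant / (k2/Km)_wild type]   (kcal/mol)

and, for a double mutant with its two single-mutant parents, the
double-mutant-cycle coupling energy (ΔΔG_A + ΔΔG_B) − ΔΔG_AB.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

#: Gas constant in kcal·mol⁻¹·K⁻¹.
GAS_CONSTANT_KCAL = 1.987e-3

#: Default assay temperature: 60 °C in kelvin.
DEFAULT_TEMPERATURE_K = 333.15


class FitFailure(RuntimeError):
    """Curve fit did not converge or produced a non-physical rate."""


@dataclass(frozen=True)
class ProgressCurve:
    """One single-turnover time course at a fixed enzyme concentration."""

    enzyme_concentration: float      # molar
    timepoints: np.ndarray           # seconds, strictly increasing
    product: np.ndarray              # yield (fraction or nM), same unit as P_max
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        p = np.asarray(self.product, dtype=float)
        object.__setattr__(self, "timepoints", t)
        object.__setattr__(self, "product", p)
        if t.size != p.size:
            raise ValueError("timepoints and product must have equal length")
        if t.size < 4:
            raise ValueError("a progress curve needs at least 4 timepoints")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("product yield must be non-negative")
        if self.enzyme_concentration <= 0:
            raise ValueError("enzyme concentration must be positive")


@dataclass(frozen=True)
class ProgressFit:
    """First-order fit P(t) = P_max(1 − e^(−k_obs t))."""

    p_max: float
    k_obs: float                     # s⁻¹
    p_max_se: float
    k_obs_se: float
    rss: float
    r_squared: float
    n_points: int

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.p_max * (1.0 - np.exp(-self.k_obs * np.asarray(t, dtype=float)))


@dataclass(frozen=True)
class KineticParameters:
    """Saturation-fit output: hyperbolic (k2, Km) or linear (k2/Km only)."""

    model: Literal["hyperbolic", "linear"]
    k2_over_Km: float                # s⁻¹·M⁻¹
    k2_over_Km_se: float
    k2: Optional[float] = None       # s⁻¹
    Km: Optional[float] = None       # molar
    k2_se: Optional[float] = None
    Km_se: Optional[float] = None

    def __post_init__(self) -> None:
        if self.model == "hyperbolic":
            if self.k2 is None or self.Km is None:
                raise ValueError("hyperbolic model requires k2 and Km")
            if not math.isclose(self.k2_over_Km, self.k2 / self.Km, rel_tol=1e-9):
                raise ValueError("k2_over_Km must equal k2/Km for the hyperbolic model")
        elif self.model == "linear":
            if self.k2 is not None or self.Km is not None:
                raise ValueError("linear model carries no individual k2 or Km")
        else:
            raise ValueError(f"unknown model {self.model!r}")


def _first_order(t, p_max, k_obs):
    return p_max * (1.0 - np.exp(-k_obs * t))


class ProgressCurveModel:
    """Exponential progress-curve model for one time course.

    ``ProgressCurveModel(curve).fit()`` returns a :class:`ProgressFit`.
    """

    def __init__(self, curve: ProgressCurve) -> None:
        self.curve = curve

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, enzyme_concentration: float, label: str = ""
    ) -> "ProgressCurveModel":
        """Build from a table with ``time`` (s) and ``yield`` columns."""
        cols = {c.lower(): c for c in df.columns}
        t = df[cols.get("time", "time")].to_numpy(dtype=float)
        y = df[cols.get("yield", cols.get("product", "yield"))].to_numpy(dtype=float)
        return cls(ProgressCurve(enzyme_concentration, t, y, label=label))

    def fit(self) -> ProgressFit:
        t, p = self.curve.timepoints, self.curve.product
        if np.allclose(p, p[0]):
            raise FitFailure("progress curve is constant; nothing to fit")
        p_max0 = float(np.max(p))
        half = p_max0 / 2.0
        above = np.nonzero(p >= half)[0]
        t_half = t[above[0]] if above.size else t[-1]
        k0 = math.log(2.0) / max(t_half, 1e-12)
        try:
            popt, pcov = curve_fit(
                _first_order,
                t,
                p,
                p0=[p_max0, k0],
                maxfev=20000,
                xtol=1e-10,
                ftol=1e-10,
            )
        except RuntimeError as exc:
            raise FitFailure(f"progress-curve fit failed: {exc}") from exc
        p_max, k_obs = float(popt[0]), float(popt[1])
        if k_obs <= 0 or not np.isfinite(k_obs):
            raise FitFailure(f"fitted k_obs = {k_obs:.3g} s^-1 is non-physical")
        se = np.sqrt(np.diag(pcov))
        resid = p - _first_order(t, *popt)
        rss = float(np.sum(resid**2))
        tss = float(np.sum((p - p.mean()) ** 2))
        r2 = 1.0 - rss / tss if tss > 0 else float("nan")
        return ProgressFit(
            p_max=p_max,
            k_obs=k_obs,
            p_max_se=float(se[0]),
            k_obs_se=float(se[1]),
            rss=rss,
            r_squared=r2,
            n_points=t.size,
        )


def fit_progress_curve(curve: ProgressCurve) -> ProgressFit:
    """Functional wrapper over :class:`ProgressCurveModel`."""
    return ProgressCurveModel(curve).fit()


def _hyperbola(e0, k2, km):
    return k2 * e0 / (km + e0)


class SaturationModel:
    """k_obs-vs-[E0] model yielding k2, Km or (linear regime) k2/Km.

    Parameters
    ----------
    e0 : array of total enzyme concentrations (molar)
    k_obs : array of apparent rate constants (s⁻¹)
    model : "auto" fits the hyperbola and falls back to the origin-line
        when Km is not identifiable (fitted Km > 3×max[E0], or its
        standard error exceeds the estimate).
    """

    def __init__(
        self,
        e0: Sequence[float],
        k_obs: Sequence[float],
        model: Literal["auto", "hyperbolic", "linear"] = "auto",
    ) -> None:
        self.e0 = np.asarray(e0, dtype=float)
        self.k_obs = np.asarray(k_obs, dtype=float)
        if self.e0.size != self.k_obs.size:
            raise ValueError("e0 and k_obs must have equal length")
        if self.e0.size < 3:
            raise ValueError("need at least 3 (E0, k_obs) points")
        if np.max(self.e0) / np.min(self.e0) < 4:
            raise ValueError("E0 values must span at least 4-fold")
        if np.allclose(self.k_obs, 0):
            raise ValueError("all k_obs are zero; no activity to fit")
        self.model = model

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, model: Literal["auto", "hyperbolic", "linear"] = "auto"
    ) -> "SaturationModel":
        cols = {c.lower(): c for c in df.columns}
        return cls(
            df[cols.get("e0", "E0")].to_numpy(dtype=float),
            df[cols.get("k_obs", "k_obs")].to_numpy(dtype=float),
            model=model,
        )

    @classmethod
    def from_progress_curves(
        cls,
        curves: Iterable[ProgressCurve],
        model: Literal["auto", "hyperbolic", "linear"] = "auto",
    ) -> "SaturationModel":
        """Fit each progress curve, then model k_obs against [E0]."""
        e0, kobs = [], []
        for c in curves:
            e0.append(c.enzyme_concentration)
            kobs.append(fit_progress_curve(c).k_obs)
        return cls(e0, kobs, model=model)

    def _fit_hyperbolic(self) -> KineticParameters:
        k2_0 = float(np.max(self.k_obs))
        km_0 = float(np.median(self.e0))
        try:
            popt, pcov = curve_fit(
                _hyperbola,
                self.e0,
                self.k_obs,
                p0=[k2_0, km_0],
                maxfev=20000,
                xtol=1e-10,
                ftol=1e-10,
            )
        except RuntimeError as exc:
            raise FitFailure(f"hyperbolic fit failed: {exc}") from exc
        k2, km = float(popt[0]), float(popt[1])
        if k2 <= 0 or km <= 0:
            raise FitFailure("hyperbolic fit returned non-physical parameters")
        se = np.sqrt(np.diag(pcov))
        eff = k2 / km
        eff_se = eff * math.sqrt((se[0] / k2) ** 2 + (se[1] / km) ** 2)
        return KineticParameters(
            model="hyperbolic",
            k2=k2,
            Km=km,
            k2_se=float(se[0]),
            Km_se=float(se[1]),
            k2_over_Km=eff,
            k2_over_Km_se=float(eff_se),
        )

    def _fit_linear(self) -> KineticParameters:
        # least squares through the origin: slope = Σ x y / Σ x²
        x, y = self.e0, self.k_obs
        slope = float(np.sum(x * y) / np.sum(x * x))
        resid = y - slope * x
        dof = max(x.size - 1, 1)
        slope_se = math.sqrt(float(np.sum(resid**2)) / dof / float(np.sum(x * x)))
        if slope <= 0:
            raise FitFailure("linear fit returned a non-positive slope")
        return KineticParameters(
            model="linear", k2_over_Km=slope, k2_over_Km_se=slope_se
        )

    def fit(self) -> KineticParameters:
        if self.model == "hyperbolic":
            return self._fit_hyperbolic()
        if self.model == "linear":
            return self._fit_linear()
        try:
            params = self._fit_hyperbolic()
        except FitFailure:
            return self._fit_linear()
        km_unidentifiable = (
            params.Km > 3.0 * float(np.max(self.e0))
            or (params.Km_se is not None and params.Km_se > params.Km)
        )
        return self._fit_linear() if km_unidentifiable else params


def fit_kobs_vs_E0(
    points: Sequence[tuple[float, float]],
    model: Literal["auto", "hyperbolic", "linear"] = "auto",
) -> KineticParameters:
    """Functional wrapper over :class:`SaturationModel`."""
    e0 = [p[0] for p in points]
    kobs = [p[1] for p in points]
    return SaturationModel(e0, kobs, model=model).fit()


def catalytic_efficiency(k2: float, Km: float) -> float:
    """Catalytic efficiency k2/Km in s⁻¹·M⁻¹."""
    if Km <= 0:
        raise ValueError("Km must be positive")
    return k2 / Km


def fold_change(eff_ref: float, eff_other: float) -> float:
    """Ratio of catalytic efficiencies, reference over other."""
    if eff_ref <= 0 or eff_other <= 0:
        raise ValueError("efficiencies must be positive")
    return eff_ref / eff_other


def ddg(
    eff_mut: float, eff_wt: float, temperature: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Apparent transition-state penalty ΔΔG = −RT·ln(eff_mut/eff_wt), kcal/mol."""
    if eff_mut <= 0 or eff_wt <= 0:
        raise ValueError("efficiencies must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return -GAS_CONSTANT_KCAL * temperature * math.log(eff_mut / eff_wt)


def coupling_energy(ddg_double: float, ddg_a: float, ddg_b: float) -> float:
    """Double-mutant-cycle coupling energy (ΔΔG_A + ΔΔG_B) − ΔΔG_AB, kcal/mol.

    Positive values mean the two sites interact energetically: the double
    mutation costs less than the sum of its parts.
    """
    return (ddg_a + ddg_b) - ddg_double


@dataclass
class EnergyTable:
    """Per-enzyme catalytic efficiencies, fold changes and energies."""

    table: pd.DataFrame
    wild_type: str
    temperature: float
    double_mutant: Optional[str] = None
    parents: Optional[tuple[str, str]] = None
    coupling: Optional[float] = None

    def summary(self, sig_figs: int = 2) -> str:
        def fmt(x):
            if x is None or (isinstance(x, float) and not math.isfinite(x)):
                return ""
            return f"{float(f'%.{sig_figs}g' % x):g}"

        lines = [
            f"Energy table (T = {self.temperature:g} K, wild type = {self.wild_type})",
            "enzyme\tk2/Km (s-1 M-1)\tactivity change (fold)\t"
            "enhancement (fold)\tddG (kcal/mol)",
        ]
        for name, row in self.table.iterrows():
            enh = row.get("enhancement_fold")
            lines.append(
                f"{name}\t{row['k2_over_Km']:.2g}\t{fmt(row['activity_change_fold'])}\t"
                f"{fmt(enh) if enh == enh else ''}\t{row['ddg'] or 0.0:.1f}"
            )
        if self.coupling is not None:
            a, b = self.parents
            lines.append(
                f"coupling energy ({a} + {b} vs {self.double_mutant}): "
                f"{self.coupling:.1f} kcal/mol"
            )
        return "\n".join(lines)


def build_energy_table(
    fits: dict[str, KineticParameters | float],
    wild_type: str,
    temperature: float = DEFAULT_TEMPERATURE_K,
    double_mutant: Optional[str] = None,
    parents: Optional[tuple[str, str]] = None,
) -> EnergyTable:
    """Fold changes, ΔΔG and (optionally) double-mutant coupling energy.

    ``fits`` maps enzyme name to a :class:`KineticParameters` or directly
    to a k2/Km value.  Rows are ordered with the wild type first, then the
    remaining enzymes sorted by name, so permuting the input leaves the
    table unchanged.  When ``double_mutant`` and both ``parents`` are
    present, enhancement folds over each parent and the coupling energy
    are included.
    """
    if wild_type not in fits:
        raise ValueError(f"wild type {wild_type!r} missing from fits")

    def eff(v) -> float:
        return v.k2_over_Km if isinstance(v, KineticParameters) else float(v)

    eff_wt = eff(fits[wild_type])
    names = [wild_type] + sorted(n for n in fits if n != wild_type)
    rows = []
    for name in names:
        e = eff(fits[name])
        rows.append(
            {
                "enzyme": name,
                "k2_over_Km": e,
                "activity_change_fold": fold_change(eff_wt, e),
                "ddg": ddg(e, eff_wt, temperature),
                "enhancement_fold": float("nan"),
            }
        )
    df = pd.DataFrame(rows).set_index("enzyme")

    coupling = None
    if double_mutant is not None and parents is not None:
        have_parents = all(p in fits for p in parents)
        if double_mutant in fits and have_parents:
            eff_d = eff(fits[double_mutant])
            for p in parents:
                df.loc[p, "enhancement_fold"] = fold_change(eff_d, eff(fits[p]))
            coupling = coupling_energy(
                df.loc[double_mutant, "ddg"],
                df.loc[parents[0], "ddg"],
                df.loc[parents[1], "ddg"],
            )
    return EnergyTable(
        table=df,
        wild_type=wild_type,
        temperature=temperature,
        double_mutant=double_mutant,
        parents=parents,
        coupling=coupling,
    )
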
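"""Chou-Talalay median-effect analysis of two-drug combinations.

The median-effect equation fa/fu = (D/Dm)^m relates the fraction of cells
affected (fa; fu = 1 - fa) to dose D, with Dm the dose producing the
median (50%) effect and m the curve's sigmoidicity.  It is log-linear:

    log(fa/fu) = m * log(D) - m * log(Dm)

so (m, Dm) come from least squares on the log-linearized line, with r the
line's correlation coefficient.  For a dose pair (d1, d2) with observed
effect fa, the combination index in its mutually exclusive form is

    CI = d1/Dx1(fa) + d2/Dx2(fa),    Dx_k = Dm_k * (fa/fu)^(1/m_k)

with synergism for CI < 0.8, additivity for 0.8 <= CI <= 1.2 and
antagonism for CI > 1.2.  The dose-reduction index DRI_k = Dx_k/d_k is the
fold reduction of drug k achievable in combination at the same effect
level; CI = sum(1/DRI_k) holds identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FA_EPS",
    "MedianEffectModel",
    "MedianEffectResults",
    "fit_median_effect",
    "equivalent_dose",
    "combination_index",
    "classify_ci",
    "dose_reduction_index",
    "CombinationAnalysis",
    "CombinationResults",
    "analyze_combination",
]

#: fraction-affected values are clipped into [FA_EPS, 1 - FA_EPS]
FA_EPS = 1e-6

#: additivity band: CI in [lo, hi] is additive, below synergistic, above
#: antagonistic
DEFAULT_CI_BANDS = (0.8, 1.2)


def _clip_fa(fa: np.ndarray) -> np.ndarray:
    fa = np.asarray(fa, dtype=float)
    out = np.clip(fa, FA_EPS, 1.0 - FA_EPS)
    n_clip = int(np.sum(out != fa))
    if n_clip:
        warnings.warn(
            f"clipped {n_clip} fraction-affected value(s) into "
            f"[{FA_EPS}, {1 - FA_EPS}]", stacklevel=3)
    return out


class MedianEffectModel:
    """Median-effect model for one drug's dose-effect data.

    Parameters
    ----------
    doses : positive dose values (any consistent unit).
    fa : fraction affected in (0, 1); values outside are clipped to
        [1e-6, 1 - 1e-6] with a warning.
    """

    def __init__(self, doses, fa):
        doses = np.asarray(doses, dtype=float)
        fa = np.asarray(fa, dtype=float)
        if doses.shape != fa.shape or doses.ndim != 1:
            raise ValueError("doses and fa must be equal-length 1-D")
        if np.any(doses <= 0):
            raise ValueError("doses must be strictly positive")
        if np.unique(doses).size < 2:
            raise ValueError("need >=2 distinct doses")
        self.doses = doses
        self.fa = _clip_fa(fa)

    def fit(self, fix_dm: float | None = None) -> "MedianEffectResults":
        """Least squares on the log-linearized median-effect line.

        ``fix_dm`` constrains the median-effect dose and estimates only the
        slope m (used when Dm is known, e.g. a reported IC50).
        """
        x = np.log10(self.doses)
        y = np.log10(self.fa / (1.0 - self.fa))
        if np.allclose(y, y[0]):
            raise ValueError("degenerate fit: all fa values identical")
        if fix_dm is not None:
            if fix_dm <= 0:
                raise ValueError("fix_dm must be positive")
            v = x - np.log10(fix_dm)
            m = float(np.sum(v * y) / np.sum(v * v))
            dm = float(fix_dm)
        else:
            m, b = np.polyfit(x, y, 1)
            m = float(m)
            if m == 0:
                raise ValueError("degenerate fit: zero slope")
            dm = float(10.0 ** (-b / m))
        yhat = m * (x - np.log10(dm))
        sx, sy = np.std(x), np.std(y)
        r = float(np.corrcoef(x, y)[0, 1]) if sx > 0 and sy > 0 else np.nan
        sse = float(np.sum((y - yhat) ** 2))
        return MedianEffectResults(model=self, dm=dm, m=m, r=r, sse=sse,
                                   dm_fixed=fix_dm is not None)


@dataclass
class MedianEffectResults:
    """(Dm, m, r) of a fitted median-effect line."""

    model: MedianEffectModel
    dm: float
    m: float
    r: float
    sse: float
    dm_fixed: bool = False

    def equivalent_dose(self, fa) -> np.ndarray | float:
        """Dx producing effect fa: Dx = Dm * (fa/(1-fa))^(1/m)."""
        return equivalent_dose(self, fa)

    def fa_at(self, dose) -> np.ndarray | float:
        """Predicted fraction affected at a dose."""
        dose = np.asarray(dose, dtype=float)
        out = 1.0 / (1.0 + (self.dm / dose) ** self.m)
        return float(out) if out.ndim == 0 else out

    def summary(self) -> str:
        return (
            "Median-effect fit\n"
            f"  n points : {self.model.doses.size}\n"
            f"  Dm       : {self.dm:.6g}{' (fixed)' if self.dm_fixed else ''}\n"
            f"  m        : {self.m:.4f}\n"
            f"  r        : {self.r:.4f}"
        )


def fit_median_effect(doses, fa) -> MedianEffectResults:
    """Convenience wrapper: ``MedianEffectModel(doses, fa).fit()``."""
    return MedianEffectModel(doses, fa).fit()


def equivalent_dose(fit: MedianEffectResults, fa) -> np.ndarray | float:
    """Dose of a single drug producing effect fa: Dm * (fa/(1-fa))^(1/m)."""
    fa_arr = np.asarray(fa, dtype=float)
    if np.any((fa_arr <= 0) | (fa_arr >= 1)):
        raise ValueError("fa must lie strictly inside (0, 1)")
    dx = fit.dm * (fa_arr / (1.0 - fa_arr)) ** (1.0 / fit.m)
    return float(dx) if dx.ndim == 0 else dx


def combination_index(dose1, dose2, dx1, dx2) -> float:
    """Mutually exclusive combination index: d1/Dx1 + d2/Dx2."""
    dx1, dx2 = float(dx1), float(dx2)
    if dx1 <= 0 or dx2 <= 0:
        raise ValueError("equivalent doses must be positive")
    return float(dose1) / dx1 + float(dose2) / dx2


def classify_ci(ci: float, bands: tuple[float, float] = DEFAULT_CI_BANDS) -> str:
    """synergistic (CI < lo), additive (lo <= CI <= hi), antagonistic (CI > hi)."""
    lo, hi = bands
    if ci <= 0:
        raise ValueError("CI must be positive")
    if ci < lo:
        return "synergistic"
    if ci > hi:
        return "antagonistic"
    return "additive"


def dose_reduction_index(dose: float, dx: float) -> float:
    """DRI = Dx / dose: fold dose reduction at equal effect."""
    if dose <= 0:
        raise ValueError("dose must be positive")
    return float(dx) / float(dose)


# ---------------------------------------------------------------------------
# full combination analysis (Model/Results)
# ---------------------------------------------------------------------------

def _dose_fa_frame(table, dose_col="dose") -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    doses, fa = table
    return pd.DataFrame({dose_col: np.asarray(doses, float),
                         "fa": np.asarray(fa, float)})


class CombinationAnalysis:
    """Constant-ratio two-drug combination analysis.

    Parameters
    ----------
    single1, single2 : per-drug dose-effect tables (DataFrame with columns
        ``dose``/``fa``, or a (doses, fa) pair).
    combo : combination table (DataFrame with ``dose1``/``dose2``/``fa``).
    ci_bands : additivity band for the synergy call.
    fix_dm : optional (dm1, dm2) pair constraining the single-drug
        median-effect doses to known IC50s.
    """

    def __init__(self, single1, single2, combo,
                 ci_bands: tuple[float, float] = DEFAULT_CI_BANDS,
                 fix_dm: tuple[float, float] | None = None):
        self.single1 = _dose_fa_frame(single1)
        self.single2 = _dose_fa_frame(single2)
        combo = combo if isinstance(combo, pd.DataFrame) else pd.DataFrame(
            {"dose1": combo[0], "dose2": combo[1], "fa": combo[2]})
        for col in ("dose1", "dose2", "fa"):
            if col not in combo.columns:
                raise ValueError(f"combo table lacks required column {col!r}")
        self.combo = combo
        self.ci_bands = ci_bands
        self.fix_dm = fix_dm

    def fit(self) -> "CombinationResults":
        fd1, fd2 = self.fix_dm if self.fix_dm else (None, None)
        fit1 = MedianEffectModel(
            self.single1["dose"], self.single1["fa"]).fit(fix_dm=fd1)
        fit2 = MedianEffectModel(
            self.single2["dose"], self.single2["fa"]).fit(fix_dm=fd2)
        total = self.combo["dose1"].to_numpy() + self.combo["dose2"].to_numpy()
        fit_combo = MedianEffectModel(total, self.combo["fa"]).fit()
        rows = []
        for _, row in self.combo.iterrows():
            fa = float(np.clip(row["fa"], FA_EPS, 1.0 - FA_EPS))
            dx1 = fit1.equivalent_dose(fa)
            dx2 = fit2.equivalent_dose(fa)
            ci = combination_index(row["dose1"], row["dose2"], dx1, dx2)
            rows.append({
                "dose1": row["dose1"], "dose2": row["dose2"], "fa": fa,
                "ci": ci, "call": classify_ci(ci, self.ci_bands),
                "dri1": dose_reduction_index(row["dose1"], dx1),
                "dri2": dose_reduction_index(row["dose2"], dx2),
            })
        return CombinationResults(
            model=self, fit1=fit1, fit2=fit2, fit_combo=fit_combo,
            table=pd.DataFrame(rows),
        )


@dataclass
class CombinationResults:
    """Per-dose-pair CI/DRI table plus the three median-effect fits."""

    model: CombinationAnalysis
    fit1: MedianEffectResults
    fit2: MedianEffectResults
    fit_combo: MedianEffectResults
    table: pd.DataFrame

    def fa_ci_curve(self, fa_grid=None) -> pd.DataFrame:
        """CI as a function of effect level along the constant-ratio ray.

        For each fa, the combination's total dose comes from the combo
        median-effect fit and is split into components by the design ratio;
        CI is then evaluated against the single-drug equivalent doses.
        """
        if fa_grid is None:
            fa_grid = np.linspace(0.05, 0.95, 19)
        fa_grid = np.asarray(fa_grid, dtype=float)
        d1 = self.model.combo["dose1"].to_numpy()
        d2 = self.model.combo["dose2"].to_numpy()
        ratio = float(np.median(d2 / d1))
        total = np.asarray(self.fit_combo.equivalent_dose(fa_grid))
        dose1 = total / (1.0 + ratio)
        dose2 = total * ratio / (1.0 + ratio)
        dx1 = np.asarray(self.fit1.equivalent_dose(fa_grid))
        dx2 = np.asarray(self.fit2.equivalent_dose(fa_grid))
        ci = dose1 / dx1 + dose2 / dx2
        return pd.DataFrame({"fa": fa_grid, "ci": ci,
                             "dose1": dose1, "dose2": dose2})

    def median_effect_plot_data(self) -> pd.DataFrame:
        """Points of the log-linearized median-effect plot for all 3 fits."""
        frames = []
        for label, fit in (("drug1", self.fit1), ("drug2", self.fit2),
                           ("combination", self.fit_combo)):
            d = fit.model.doses
            fa = fit.model.fa
            frames.append(pd.DataFrame({
                "series": label,
                "log_dose": np.log10(d),
                "log_fa_fu": np.log10(fa / (1 - fa)),
                "fitted": fit.m * (np.log10(d) - np.log10(fit.dm)),
            }))
        return pd.concat(frames, ignore_index=True)

    def plot_fa_ci(self, ax=None):
        """Fa-CI plot: CI vs fraction affected, additivity band shaded."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve = self.fa_ci_curve()
        ax.plot(curve["fa"], curve["ci"], "-", color="0.4", label="CI(fa)")
        ax.plot(self.table["fa"], self.table["ci"], "ko", label="measured")
        lo, hi = self.model.ci_bands
        ax.axhspan(lo, hi, color="0.9", label=f"additive [{lo}, {hi}]")
        ax.set_xlabel("fraction affected")
        ax.set_ylabel("combination index")
        ax.legend()
        return ax

    def plot_median_effect(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        data = self.median_effect_plot_data()
        for label, grp in data.groupby("series"):
            pts = ax.plot(grp["log_dose"], grp["log_fa_fu"], "o", label=label)
            order = np.argsort(grp["log_dose"].to_numpy())
            ax.plot(grp["log_dose"].to_numpy()[order],
                    grp["fitted"].to_numpy()[order], "-",
                    color=pts[0].get_color())
        ax.set_xlabel("log10 dose")
        ax.set_ylabel("log10 fa/fu")
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = [
            "Chou-Talalay combination analysis",
            f"  drug 1: Dm = {self.fit1.dm:.4g}, m = {self.fit1.m:.3f}, r = {self.fit1.r:.3f}",
            f"  drug 2: Dm = {self.fit2.dm:.4g}, m = {self.fit2.m:.3f}, r = {self.fit2.r:.3f}",
            f"  combo : Dm = {self.fit_combo.dm:.4g}, m = {self.fit_combo.m:.3f}, "
            f"r = {self.fit_combo.r:.3f}",
            "",
            f"  {'dose1':>10} {'dose2':>10} {'fa':>8} {'CI':>7} {'call':>13} "
            f"{'DRI1':>7} {'DRI2':>7}",
        ]
        for _, row in self.table.iterrows():
            lines.append(
                f"  {row['dose1']:>10.4g} {row['dose2']:>10.4g} {row['fa']:>8.4f} "
                f"{row['ci']:>7.3f} {row['call']:>13} {row['dri1']:>7.3f} "
                f"{row['dri2']:>7.3f}")
        return "\n".join(lines)


def analyze_combination(single1, single2, combo, **kwargs) -> CombinationResults:
    """Convenience wrapper: ``CombinationAnalysis(...).fit()``."""
    return CombinationAnalysis(single1, single2, combo, **kwargs).fit()
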
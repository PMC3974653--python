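"""Quantitative high-throughput screen (qHTS) analysis.

Every library compound is tested as an 8-point titration series, so each
compound yields a concentration-response curve (CRC).  This module normalizes
raw plate reads against in-plate controls, fits a four-parameter logistic
(4PL, Hill) model to each titration, assigns an Inglese-style curve class
(1.1/1.2 complete, 2.1/2.2 incomplete, 3 low-confidence, 4 inactive),
triages compounds into active / inactive / inconclusive, ranks hits, and
computes therapeutic-category enrichment.

Internal sign convention: inhibition is stored as *positive* percent
activity (DMSO basal = 0, full inhibition = 100).  Screen reports that
print inhibition with a negative sign (efficacy "-85", class "-1.1") are
parsed by absolute value with the direction recorded separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "CURVE_CLASSES",
    "CLASS_CONFIDENCE_ORDER",
    "ScreenConfig",
    "TitrationSeries",
    "DoseResponseCurve",
    "DoseResponseResults",
    "normalize_plate",
    "normalize_screen",
    "extract_titrations",
    "fit_4pl",
    "classify_curve",
    "triage_activity",
    "fit_screen",
    "rank_hits",
    "category_enrichment",
]

#: the six Inglese curve-class labels
CURVE_CLASSES = ("1.1", "1.2", "2.1", "2.2", "3", "4")

#: confidence order used for hit ranking (highest confidence first)
CLASS_CONFIDENCE_ORDER = ("1.1", "1.2", "2.1", "2.2")


@dataclass(frozen=True)
class ScreenConfig:
    """Tunable thresholds of the screen analysis.

    Attributes
    ----------
    active_efficacy_pct : float
        Minimum fitted efficacy (strict >) for an active call; the screen's
        rule is "curve class 1.1-2.2 with efficacy higher than 60%".
    high_efficacy_pct : float
        Sub-class split: efficacy >= 80% -> x.1, < 80% -> x.2.
    min_efficacy_pct : float
        Efficacy floor below which a fitted curve is called inactive
        (class 4, "insufficient efficacy").
    poor_fit_r2 : float
        Curves with r^2 below this are class 3 ("poorly fit").
    noise_multiplier : float
        A response is significant when it exceeds ``noise_multiplier`` times
        the robust per-curve noise estimate.
    min_significant_pct : float
        Absolute floor on the significance threshold (percent of window),
        so that noiseless data does not declare every wiggle significant.
    plateau_window : float
        "Asymptote present" means >= ``plateau_min_points`` tested
        concentrations whose model response lies within
        ``plateau_window * efficacy`` of the plateau.
    plateau_min_points : int
        See above.
    efficacy_cap_factor : float
        Fitted |top - bottom| is capped at this multiple of the observed
        response span (guards runaway extrapolation on incomplete curves).
    triage_on_observed_max : bool
        Alternative activity rule: use the maximal observed response instead
        of fitted efficacy when applying the 60% activity cut.
    """

    active_efficacy_pct: float = 60.0
    high_efficacy_pct: float = 80.0
    min_efficacy_pct: float = 30.0
    poor_fit_r2: float = 0.5
    noise_multiplier: float = 3.0
    min_significant_pct: float = 6.0
    plateau_window: float = 0.10
    plateau_min_points: int = 2
    efficacy_cap_factor: float = 2.5
    triage_on_observed_max: bool = False


DEFAULT_CONFIG = ScreenConfig()


@dataclass(frozen=True)
class TitrationSeries:
    """One compound's concentration-response series.

    Concentrations are in µM and strictly increasing; responses are
    normalized percent activity (0 = DMSO basal, 100 = full inhibition).
    """

    compound_id: str
    concentrations: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        resp = np.asarray(self.responses, dtype=float)
        if conc.shape != resp.shape or conc.ndim != 1:
            raise ValueError("concentrations and responses must be equal-length 1-D")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "responses", resp)

    def __len__(self) -> int:
        return self.concentrations.size


def four_param_logistic(x, bottom, top, ic50, hill):
    """4PL response: y = bottom + (top - bottom) / (1 + (ic50/x)^hill)."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ic50 / x) ** hill)


# ---------------------------------------------------------------------------
# plate normalization
# ---------------------------------------------------------------------------

def normalize_plate(
    plate: pd.DataFrame,
    *,
    read_col: str = "read",
    role_col: str = "role",
    dmso_role: str = "dmso",
    pos_role: str = "pos_ctrl",
    window_tol: float = 1e-9,
) -> pd.DataFrame:
    """Normalize raw plate reads to percent inhibition.

    normalized = 100 * (median(dmso) - read) / (median(dmso) - median(pos))

    so the DMSO-only control median maps to exactly 0 (basal) and the
    positive-control (full kill) median to exactly 100.  The positive
    control in this assay reduces the luminescent signal, hence the
    direction of the window.

    Parameters
    ----------
    plate : DataFrame with at least `read` and `role` columns; sample rows
        keep all other columns.

    Returns
    -------
    Copy of ``plate`` with a ``normalized`` column added.

    Raises
    ------
    ValueError : fewer than 2 wells of either control role, or a degenerate
        control window.
    """
    reads = plate[read_col].to_numpy(dtype=float)
    roles = plate[role_col].to_numpy()
    dmso = reads[roles == dmso_role]
    pos = reads[roles == pos_role]
    if dmso.size < 2 or pos.size < 2:
        raise ValueError(
            f"need >=2 control wells of each kind, got {dmso.size} '{dmso_role}' "
            f"and {pos.size} '{pos_role}'"
        )
    dmso_med = float(np.median(dmso))
    pos_med = float(np.median(pos))
    window = dmso_med - pos_med
    if abs(window) <= window_tol * max(1.0, abs(dmso_med)):
        raise ValueError(
            f"degenerate control window: median(dmso)={dmso_med}, median(pos)={pos_med}"
        )
    out = plate.copy()
    out["normalized"] = 100.0 * (dmso_med - reads) / window
    return out


def normalize_screen(plates: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Normalize every plate of a multi-plate table (grouped by plate_id)."""
    parts = [normalize_plate(grp, **kwargs)
             for _, grp in plates.groupby("plate_id", sort=False)]
    return pd.concat(parts, ignore_index=True)


def extract_titrations(
    normalized_plates: pd.DataFrame, compound_map: pd.DataFrame
) -> list[TitrationSeries]:
    """Join normalized sample wells with the compound map into titrations.

    The map assigns (plate_id, row, col) wells to compounds with their
    tested concentration (µM); each compound's points are sorted by
    concentration.  Returns one TitrationSeries per compound, in map order.
    """
    samples = normalized_plates[normalized_plates["role"] == "sample"]
    merged = compound_map.merge(
        samples[["plate_id", "row", "col", "normalized"]],
        on=["plate_id", "row", "col"], how="left", validate="one_to_one")
    if merged["normalized"].isna().any():
        missing = merged.loc[merged["normalized"].isna(), "compound_id"].unique()
        raise ValueError(
            f"compound map points to wells absent from the plates, e.g. "
            f"{missing[:3].tolist()}")
    out = []
    for cid, grp in merged.groupby("compound_id", sort=False):
        grp = grp.sort_values("concentration")
        out.append(TitrationSeries(
            cid, grp["concentration"].to_numpy(), grp["normalized"].to_numpy()))
    return out


# ---------------------------------------------------------------------------
# 4PL model / results (statsmodels-style)
# ---------------------------------------------------------------------------

class DoseResponseCurve:
    """Four-parameter logistic dose-response model for one titration series.

    Model: ``y = bottom + (top - bottom) / (1 + (ic50/x)^hill)`` with
    ``hill > 0`` so the response rises with concentration (inhibition
    convention).

    Parameters
    ----------
    series : TitrationSeries, or pass ``concentrations`` / ``responses``.

    Examples
    --------
    >>> s = TitrationSeries("cmpd", [0.01, 0.1, 1.0, 10.0], [1.0, 9.0, 50.0, 91.0])
    >>> res = DoseResponseCurve(s).fit()
    >>> bool(res.converged)
    True
    """

    def __init__(self, series: TitrationSeries | None = None, *,
                 concentrations=None, responses=None, compound_id: str = ""):
        if series is None:
            series = TitrationSeries(compound_id, np.asarray(concentrations, float),
                                     np.asarray(responses, float))
        if len(series) < 4:
            raise ValueError("need >=4 titration points to fit a 4PL")
        self.series = series

    #: deterministic start grid (no randomness anywhere in the fit)
    _GRID_HILLS = np.array([0.3, 0.7, 1.0, 1.5, 2.2, 3.5, 5.5, 8.0])
    _N_GRID_IC50 = 25

    def _start_points(self):
        """Deterministic multi-start seeds from a coarse profile grid.

        For fixed (ic50, hill) the 4PL is linear in (bottom, top), so
        those two are profiled out in closed form over a log-spaced ic50 x
        hill grid; the best few grid cells seed the full nonlinear fit.
        """
        conc = self.series.concentrations
        resp = self.series.responses
        lg = np.linspace(np.log10(conc[0]) - 1.0, np.log10(conc[-1]) + 1.0,
                         self._N_GRID_IC50)
        ic50 = 10.0 ** lg
        # f[i, j, k] = logistic fraction at conc k for (ic50 i, hill j)
        ratio = ic50[:, None, None] / conc[None, None, :]
        f = 1.0 / (1.0 + ratio ** self._GRID_HILLS[None, :, None])
        fm = f.mean(axis=2, keepdims=True)
        ym = resp.mean()
        var_f = ((f - fm) ** 2).sum(axis=2)
        cov_fy = ((f - fm) * (resp - ym)).sum(axis=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.where(var_f > 1e-12, cov_fy / np.maximum(var_f, 1e-12), 0.0)
        intercept = ym - slope * fm[..., 0]
        pred = intercept[..., None] + slope[..., None] * f
        sse = ((resp - pred) ** 2).sum(axis=2)
        order = np.argsort(sse, axis=None, kind="stable")
        starts = []
        for flat in order[:3]:
            i, j = np.unravel_index(flat, sse.shape)
            bottom = intercept[i, j]
            top = bottom + slope[i, j]
            starts.append((bottom, top, ic50[i], self._GRID_HILLS[j]))
        return starts

    def fit(self, config: ScreenConfig = DEFAULT_CONFIG) -> "DoseResponseResults":
        conc = self.series.concentrations
        resp = self.series.responses
        bounds = (
            [-300.0, -300.0, conc[0] / 1e4, 0.05],
            [300.0, 300.0, conc[-1] * 1e4, 10.0],
        )
        best = None
        sst = float(np.sum((resp - resp.mean()) ** 2))
        target_sse = max(1e-12, 1e-10 * max(sst, 1.0))
        for p0 in self._start_points():
            p0 = np.clip(p0, bounds[0], bounds[1])
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = optimize.curve_fit(
                        four_param_logistic, conc, resp, p0=p0,
                        bounds=bounds, maxfev=800,
                    )
            except (RuntimeError, ValueError):
                continue
            sse = float(np.sum((resp - four_param_logistic(conc, *popt)) ** 2))
            if best is None or sse < best[0]:
                best = (sse, popt)
            if best[0] < target_sse:
                break  # already an essentially exact fit
        if best is None:
            return DoseResponseResults(
                model=self, bottom=np.nan, top=np.nan, ic50=np.nan,
                hill=np.nan, sse=np.nan, r2=np.nan, converged=False,
                config=config,
            )
        sse, (bottom, top, ic50, hill) = best
        r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse < 1e-12 else 0.0)
        return DoseResponseResults(
            model=self, bottom=float(bottom), top=float(top), ic50=float(ic50),
            hill=float(hill), sse=sse, r2=float(r2), converged=True,
            config=config,
        )


@dataclass
class DoseResponseResults:
    """Fitted 4PL parameters plus derived curve class and activity call."""

    model: DoseResponseCurve
    bottom: float
    top: float
    ic50: float
    hill: float
    sse: float
    r2: float
    converged: bool
    config: ScreenConfig = field(default=DEFAULT_CONFIG)

    @property
    def efficacy(self) -> float:
        """|top - bottom|, capped at a multiple of the observed span."""
        if not self.converged:
            return 0.0
        resp = self.model.series.responses
        span = float(resp.max() - resp.min())
        cap = self.config.efficacy_cap_factor * max(span, 1e-12)
        return float(min(abs(self.top - self.bottom), cap))

    @property
    def curve_class(self) -> str:
        return classify_curve(self, self.model.series, self.config)

    @property
    def activity(self) -> str:
        eff = (
            float(np.max(np.abs(self.model.series.responses)))
            if self.config.triage_on_observed_max
            else self.efficacy
        )
        return triage_activity(self.curve_class, eff, self.config)

    def predict(self, conc) -> np.ndarray:
        return four_param_logistic(conc, self.bottom, self.top, self.ic50, self.hill)

    def summary(self) -> str:
        s = self.model.series
        lines = [
            f"4PL dose-response fit: {s.compound_id or '<unnamed>'}",
            f"  n points   : {len(s)}",
            f"  IC50 (µM)  : {self.ic50:.4g}",
            f"  Hill slope : {self.hill:.3f}",
            f"  top/bottom : {self.top:.2f} / {self.bottom:.2f} %",
            f"  efficacy   : {self.efficacy:.1f} %",
            f"  r^2        : {self.r2:.4f}   converged: {self.converged}",
            f"  curve class: {self.curve_class}   activity: {self.activity}",
        ]
        return "\n".join(lines)


def fit_4pl(series: TitrationSeries, config: ScreenConfig = DEFAULT_CONFIG) -> DoseResponseResults:
    """Convenience wrapper: ``DoseResponseCurve(series).fit(config)``."""
    return DoseResponseCurve(series).fit(config)


# ---------------------------------------------------------------------------
# curve classification
# ---------------------------------------------------------------------------

def _robust_noise(resp: np.ndarray) -> float:
    """Robust noise scale from the least-active half of the responses."""
    a = np.sort(np.abs(resp))
    low = a[: max(3, a.size // 2)]
    return float(1.4826 * np.median(np.abs(low - np.median(low))))


def _significance_threshold(resp: np.ndarray, config: ScreenConfig) -> float:
    return max(config.noise_multiplier * _robust_noise(resp),
               config.min_significant_pct)


def _plateau_support(fit: DoseResponseResults, conc: np.ndarray, config: ScreenConfig):
    """Count tested concentrations supporting each fitted plateau.

    A plateau is supported by points whose *model* response lies within
    ``plateau_window * |top-bottom|`` of that plateau's level.
    """
    eff = abs(fit.top - fit.bottom)
    tol = config.plateau_window * max(eff, 1e-12)
    y = fit.predict(conc)
    n_bottom = int(np.sum(np.abs(y - fit.bottom) <= tol))
    n_top = int(np.sum(np.abs(y - fit.top) <= tol))
    return n_bottom, n_top


def classify_curve(
    fit: DoseResponseResults,
    series: TitrationSeries | None = None,
    config: ScreenConfig | None = None,
) -> str:
    """Assign the Inglese curve class of a fitted titration.

    Decision order (each step total, mutually exclusive):

    4  - no convergence, no significant response, or fitted efficacy below
         the ``min_efficacy_pct`` floor ("inactive / insufficient efficacy");
    3  - significant activity at only the highest tested concentration, or a
         poor fit (r^2 < ``poor_fit_r2``);
    1.x - both asymptotes supported inside the tested range (complete CRC);
    2.x - exactly one asymptote supported (incomplete CRC);
    .1 vs .2 - fitted efficacy >= 80% vs < 80%.

    A mid-slope curve supporting neither plateau is reported as class 3
    (low confidence).
    """
    if series is None:
        series = fit.model.series
    if config is None:
        config = fit.config
    resp = series.responses
    conc = series.concentrations
    thresh = _significance_threshold(resp, config)
    significant = np.abs(resp) > thresh

    if not fit.converged:
        return "4" if not significant.any() else "3"
    if not significant.any():
        return "4"
    if fit.efficacy < config.min_efficacy_pct:
        return "4"
    # activity at only the highest concentration
    if significant[-1] and not significant[:-1].any():
        return "3"
    if fit.r2 < config.poor_fit_r2:
        return "3"
    n_bottom, n_top = _plateau_support(fit, conc, config)
    k = config.plateau_min_points
    if n_bottom >= k and n_top >= k:
        base = "1"
    elif n_bottom >= k or n_top >= k:
        base = "2"
    else:
        return "3"
    sub = "1" if fit.efficacy >= config.high_efficacy_pct else "2"
    return f"{base}.{sub}"


def triage_activity(
    curve_class: str, efficacy: float, config: ScreenConfig = DEFAULT_CONFIG
) -> str:
    """Activity call from (curve class, efficacy).

    active: class in {1.1, 1.2, 2.1, 2.2} and efficacy strictly > 60%;
    inactive: class 4; inconclusive: everything else (class 3, and sigmoid
    curves whose efficacy does not clear the cut).
    """
    cls = str(curve_class)
    if cls not in CURVE_CLASSES:
        raise ValueError(f"unknown curve class {curve_class!r}")
    if cls == "4":
        return "inactive"
    if cls in CLASS_CONFIDENCE_ORDER and efficacy > config.active_efficacy_pct:
        return "active"
    return "inconclusive"


# ---------------------------------------------------------------------------
# screen-level table operations
# ---------------------------------------------------------------------------

def fit_screen(
    series_list: list[TitrationSeries],
    config: ScreenConfig = DEFAULT_CONFIG,
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fit + classify + triage every titration; one row per compound.

    ``annotations`` (indexed or keyed by compound_id, with optional
    ``name``/``category`` columns) is merged into the output.
    """
    rows = []
    for s in series_list:
        res = DoseResponseCurve(s).fit(config)
        rows.append(
            {
                "compound_id": s.compound_id,
                "ic50": res.ic50,
                "hill": res.hill,
                "top": res.top,
                "bottom": res.bottom,
                "efficacy": res.efficacy,
                "max_response": float(np.max(np.abs(s.responses))),
                "r2": res.r2,
                "converged": res.converged,
                "curve_class": res.curve_class,
                "activity": res.activity,
            }
        )
    out = pd.DataFrame(rows)
    if annotations is not None:
        ann = annotations.reset_index() if annotations.index.name == "compound_id" else annotations
        keep = [c for c in ("compound_id", "name", "category") if c in ann.columns]
        out = out.merge(ann[keep].drop_duplicates("compound_id"),
                        on="compound_id", how="left")
    return out


def rank_hits(
    fits: pd.DataFrame, top_n: int | None = 50, *, active_only: bool = True
) -> pd.DataFrame:
    """Rank hits by curve-class confidence then potency.

    Sort key: curve-class confidence block (1.1 < 1.2 < 2.1 < 2.2), then
    ascending IC50 within a block, ties broken by compound_id so the order
    is deterministic.  With ``active_only`` (default) only compounds whose
    activity call is 'active' are ranked.
    """
    df = fits.copy()
    if active_only:
        df = df[df["activity"] == "active"]
    df = df[df["curve_class"].isin(CLASS_CONFIDENCE_ORDER)]
    order = {c: i for i, c in enumerate(CLASS_CONFIDENCE_ORDER)}
    df = df.assign(_block=df["curve_class"].map(order))
    df = df.sort_values(["_block", "ic50", "compound_id"], kind="mergesort")
    df = df.drop(columns="_block").reset_index(drop=True)
    if top_n is not None:
        if top_n > len(df):
            warnings.warn(
                f"requested top {top_n} hits but only {len(df)} available",
                stacklevel=2,
            )
        df = df.head(top_n)
    return df


def category_enrichment(fits: pd.DataFrame, *, flag_ratio_pct: float = 20.0) -> pd.DataFrame:
    """Per-therapeutic-category activity enrichment.

    enrichment_ratio = 100 * n_active / n_total per category; categories with
    no compounds are excluded; sorted by descending ratio (ties by category
    name); ``enriched`` flags ratio > ``flag_ratio_pct``.
    """
    df = fits.dropna(subset=["category"])
    groups = df.groupby("category", sort=False)
    tab = pd.DataFrame(
        {
            "n_total": groups.size(),
            "n_active": groups["activity"].apply(lambda a: int((a == "active").sum())),
        }
    )
    tab = tab[tab["n_total"] > 0]
    tab["active_fraction"] = tab["n_active"] / tab["n_total"]
    tab["enrichment_ratio"] = 100.0 * tab["active_fraction"]
    tab["enriched"] = tab["enrichment_ratio"] > flag_ratio_pct
    tab = tab.sort_values(
        ["enrichment_ratio", "category"], ascending=[False, True], kind="mergesort"
    ).reset_index()
    return tab
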
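"""Synthetic data generators with planted ground truth.

Everything the analysis pipeline consumes can be generated here, so every
stage is testable end-to-end without external downloads:

* a screening library with planted curve classes, potencies and efficacies
  (:func:`gen_screen_library`) and the corresponding raw 1536-well plate
  reads (:func:`gen_plate_reads`);
* paired cross-species expression matrices with a tunable cross-dataset
  correlation (:func:`gen_expression_pair`);
* sparse drug->target maps (:func:`gen_drug_target_map`);
* constant-ratio combination viability tables generated from median-effect
  curves with a specified true combination index
  (:func:`gen_combination_assay`).

All randomness flows through explicit integer seeds; there is no global
random state, and identical seeds give identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qhts import four_param_logistic

__all__ = [
    "PlateLayout",
    "SyntheticCombinationTruth",
    "titration_concentrations",
    "gen_screen_library",
    "gen_plate_reads",
    "gen_expression_pair",
    "gen_drug_target_map",
    "gen_combination_assay",
    "reference_screen_composition",
]

#: stock serial-dilution factor of the library (1:2.236 interplate steps);
#: the 8 *tested* concentrations are every other step, i.e. spaced 2.236**2.
STOCK_DILUTION = 2.236
TESTED_DILUTION = STOCK_DILUTION ** 2
TOP_CONC_UM = 46.0
N_POINTS = 8


def titration_concentrations(
    n_points: int = N_POINTS,
    top_um: float = TOP_CONC_UM,
    dilution: float = TESTED_DILUTION,
) -> np.ndarray:
    """The tested concentration ladder in µM, ascending.

    Defaults give 8 points anchored at 46 µM descending by 2.236**2 per
    step, so the lowest tested dose is ~0.59 nM (the assay's nominal
    0.5 nM - 46 µM range).
    """
    k = np.arange(n_points)[::-1]
    return top_um / dilution ** k


@dataclass(frozen=True)
class PlateLayout:
    """1536-well plate geometry with control columns.

    Columns are 1-based.  By default columns 1-4 hold controls (1-2 DMSO
    basal, 3-4 positive control / full kill), columns 5-48 hold samples.
    """

    n_rows: int = 32
    n_cols: int = 48
    dmso_cols: tuple[int, ...] = (1, 2)
    pos_cols: tuple[int, ...] = (3, 4)

    def __post_init__(self):
        if set(self.dmso_cols) & set(self.pos_cols):
            raise ValueError("a column cannot hold both control roles")
        if self.n_rows * len(self.dmso_cols) < 2 or self.n_rows * len(self.pos_cols) < 2:
            raise ValueError("layout must reserve >=2 wells per control role")

    @property
    def sample_cols(self) -> list[int]:
        ctrl = set(self.dmso_cols) | set(self.pos_cols)
        return [c for c in range(1, self.n_cols + 1) if c not in ctrl]

    @property
    def samples_per_plate(self) -> int:
        return self.n_rows * len(self.sample_cols)


# ---------------------------------------------------------------------------
# screening library
# ---------------------------------------------------------------------------

_VALID_CLASSES = ("1.1", "1.2", "2.1", "2.2", "3", "4")

_DEFAULT_CATEGORIES = (
    "antineoplastic", "antiseptic", "antimalarial", "estrogen", "anthelmintic",
    "antibiotic", "cardiovascular", "cns", "antiinflammatory", "other",
)


def _largest_remainder_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    raw = {k: n * p for k, p in proportions.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    order = sorted(proportions, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in order[:short]:
        counts[k] += 1
    return counts


def gen_screen_library(
    n_compounds: int,
    class_mix: dict,
    seed: int,
    *,
    low_efficacy_fraction: float = 0.3,
    shallow_fraction: float = 0.0,
    categories: tuple[str, ...] = _DEFAULT_CATEGORIES,
    concentrations: np.ndarray | None = None,
) -> pd.DataFrame:
    """Generate a screening-library truth table with planted curve classes.

    Parameters
    ----------
    n_compounds : library size (>= 1).
    class_mix : mapping curve-class label -> proportion (must sum to 1 within
        1e-9).  Keys may be strings ("1.1") or numbers (1.1, 4).
    low_efficacy_fraction : fraction of class 1.2 / 2.2 compounds planted
        with efficacy below the 60% activity cut (45-58%) instead of above
        it (62-78%); these become inconclusive under triage.  The count per
        class is rounded deterministically.  A mapping
        {"1.2": f, "2.2": f} sets the fraction per class.
    shallow_fraction : fraction of class-3 compounds planted as shallow
        low-slope curves rather than highest-dose-only spikes.

    Planted efficacies keep >= 2 percentage points clear of the 60% / 80%
    decision boundaries so that noiseless classification is deterministic.
    IC50s are log-uniform inside windows that guarantee the planted
    asymptote structure on the tested ladder: mid-range for complete (1.x)
    curves, at/above the top of the range for incomplete (2.x) curves.

    Returns
    -------
    DataFrame with columns compound_id, true_class, true_ic50 (µM),
    true_hill, true_top, true_bottom (percent inhibition), category.
    """
    if n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    mix = {str(k): float(v) for k, v in class_mix.items()}
    for k in mix:
        if k not in _VALID_CLASSES:
            raise ValueError(f"unknown curve class {k!r} in class_mix")
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError(f"class_mix proportions sum to {sum(mix.values())}, not 1")
    conc = (titration_concentrations() if concentrations is None
            else np.asarray(concentrations, float))
    rng = np.random.default_rng(seed)
    counts = _largest_remainder_counts(n_compounds, mix)

    def log_uniform(lo, hi, size):
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size))

    rows = []
    idx = 0
    for cls in _VALID_CLASSES:
        n_cls = counts.get(cls, 0)
        if n_cls == 0:
            continue
        ids = [f"NPC-{i:05d}" for i in range(idx, idx + n_cls)]
        idx += n_cls
        if cls in ("1.1", "1.2"):
            ic50 = log_uniform(conc[3], conc[4], n_cls)
            hill = rng.uniform(1.5, 3.0, n_cls)
        elif cls in ("2.1", "2.2"):
            # just above the top tested dose; hills kept moderate so at
            # least two concentrations respond above the noise floor
            ic50 = log_uniform(conc[6] * 1.15, conc[6] * 1.8, n_cls)
            hill = rng.uniform(1.5, 2.0, n_cls)
        elif cls == "3":
            ic50 = np.full(n_cls, conc[-1])
            hill = rng.uniform(1.5, 3.0, n_cls)
        else:  # class 4: nominal placement, curve is flat anyway
            ic50 = np.full(n_cls, conc[4])
            hill = rng.uniform(1.5, 3.0, n_cls)
        if cls in ("1.1", "2.1"):
            top = rng.uniform(82.0, 100.0, n_cls)
        elif cls in ("1.2", "2.2"):
            frac = (low_efficacy_fraction.get(cls, 0.0)
                    if isinstance(low_efficacy_fraction, dict)
                    else low_efficacy_fraction)
            n_low = int(round(frac * n_cls))
            top = np.concatenate([
                rng.uniform(45.0, 58.0, n_low),
                rng.uniform(62.0, 78.0, n_cls - n_low),
            ])
        elif cls == "3":
            # steep curve centred on the top dose: a single-point spike
            top = rng.uniform(85.0, 135.0, n_cls)
            hill = np.full(n_cls, 8.0)
            n_shallow = int(round(shallow_fraction * n_cls))
            if n_shallow:
                hill[:n_shallow] = rng.uniform(0.3, 0.42, n_shallow)
                top[:n_shallow] = rng.uniform(35.0, 55.0, n_shallow)
                ic50[:n_shallow] = np.exp(rng.uniform(
                    np.log(conc[3]), np.log(conc[4]), n_shallow))
        else:
            top = np.zeros(n_cls)
        rows.append(pd.DataFrame({
            "compound_id": ids,
            "true_class": cls,
            "true_ic50": ic50,
            "true_hill": hill,
            "true_top": top,
            "true_bottom": 0.0,
            "category": rng.choice(categories, n_cls),
        }))
    truth = pd.concat(rows, ignore_index=True)
    if truth["compound_id"].duplicated().any():
        raise AssertionError("compound ids must be unique")
    return truth


def gen_plate_reads(
    truth: pd.DataFrame,
    *,
    layout: PlateLayout | None = None,
    noise_sd: float = 3.0,
    seed: int = 0,
    concentrations: np.ndarray | None = None,
    dmso_level: float = 2000.0,
    pos_level: float = 200.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate raw interplate-titration plate reads for a library.

    Each compound occupies one well position across a stack of 8 plates
    (one tested concentration per plate).  Raw reads are the planted 4PL
    response plus Gaussian noise (``noise_sd`` in percent-of-window units),
    mapped into raw-luminescence space anchored by the control levels:
    ``read = dmso_level - response/100 * (dmso_level - pos_level)``.
    Control wells receive the same noise.

    Returns
    -------
    (plates, compound_map) : plates has columns plate_id, row, col, read,
    role; compound_map has compound_id, plate_id, row, col, concentration
    (µM), category.
    """
    layout = layout or PlateLayout()
    truth = truth.reset_index(drop=True)
    conc = (titration_concentrations() if concentrations is None
            else np.asarray(concentrations, float))
    rng = np.random.default_rng(seed)
    window = dmso_level - pos_level
    n = len(truth)
    n_stacks = math.ceil(n / layout.samples_per_plate)

    # planted normalized response, compounds x points
    resp = four_param_logistic(
        conc[None, :],
        truth["true_bottom"].to_numpy()[:, None],
        truth["true_top"].to_numpy()[:, None],
        truth["true_ic50"].to_numpy()[:, None],
        truth["true_hill"].to_numpy()[:, None],
    )
    if noise_sd > 0:
        resp = resp + rng.normal(0.0, noise_sd, resp.shape)

    sample_wells = [(r, c) for c in layout.sample_cols
                    for r in range(1, layout.n_rows + 1)]
    plate_rows, map_rows = [], []
    for stack in range(n_stacks):
        block = truth.iloc[stack * layout.samples_per_plate:
                           (stack + 1) * layout.samples_per_plate]
        wells = sample_wells[: len(block)]
        for point in range(conc.size):
            plate_id = f"S{stack + 1:02d}-P{point + 1}"
            # control wells
            for cols, role, level_resp in (
                (layout.dmso_cols, "dmso", 0.0),
                (layout.pos_cols, "pos_ctrl", 100.0),
            ):
                for c in cols:
                    for r in range(1, layout.n_rows + 1):
                        y = level_resp
                        if noise_sd > 0:
                            y = y + rng.normal(0.0, noise_sd)
                        plate_rows.append(
                            (plate_id, r, c, dmso_level - y / 100.0 * window, role))
            for (r, c), (i, comp) in zip(wells, block.iterrows()):
                y = resp[i, point]
                plate_rows.append(
                    (plate_id, r, c, dmso_level - y / 100.0 * window, "sample"))
                map_rows.append(
                    (comp["compound_id"], plate_id, r, c, conc[point],
                     comp["category"]))
    plates = pd.DataFrame(
        plate_rows, columns=["plate_id", "row", "col", "read", "role"])
    cmap = pd.DataFrame(
        map_rows,
        columns=["compound_id", "plate_id", "row", "col", "concentration",
                 "category"])
    return plates, cmap


def reference_screen_composition() -> tuple[int, dict[str, float], dict[str, float]]:
    """Library composition matching the published triage proportions.

    3,826 compounds: 76 actives (40 complete-curve actives with
    sub-10 µM potency, 36 incomplete-curve actives above 10 µM),
    269 inconclusives (150 class-3 plus 60 + 59 low-efficacy sigmoids)
    and 3,481 inactives.

    Returns
    -------
    (n_compounds, class_mix, low_efficacy_fraction mapping) suitable for
    :func:`gen_screen_library`.
    """
    n = 3826
    mix = {"1.1": 20 / n, "1.2": 80 / n, "2.1": 18 / n, "2.2": 77 / n,
           "3": 150 / n, "4": 3481 / n}
    return n, mix, {"1.2": 60 / 80, "2.2": 59 / 77}


# ---------------------------------------------------------------------------
# paired expression matrices
# ---------------------------------------------------------------------------

def gen_expression_pair(
    n_genes: int,
    n_samples_a: int = 3,
    n_samples_b: int = 12,
    rho: float = 0.86,
    seed: int = 0,
    *,
    n_divergent: int = 0,
    private_frac: float = 0.0,
    noise_sd: float = 0.08,
    species: tuple[str, str] = ("mouse", "human"),
):
    """Generate two expression matrices whose gene-wise means correlate at rho.

    The matrices emulate microarray data z-scored against a broader cohort,
    so per-gene means over the emitted samples are *not* constrained to
    zero.  ``n_genes`` concordant genes share a latent level ``g`` plus
    bounded per-dataset offsets (uniform on ±0.35, so the cross-dataset
    mean difference never exceeds 0.7 — safely inside a 2-fold cut);
    the latent variance is chosen so the expected Pearson correlation of
    the gene means equals ``rho`` exactly.  ``n_divergent`` extra shared
    genes get a planted cross-dataset offset of at least 1.3 (beyond
    2-fold), and ``private_frac`` adds genes private to each dataset.

    Returns
    -------
    (a, b, truth) where a and b are :class:`pheoscreen.meta.ExpressionMatrix`
    and truth records per-gene planted means and the divergent flag.
    """
    from .meta import ExpressionMatrix

    if n_genes < 3:
        raise ValueError("n_genes must be >= 3 (correlation undefined below)")
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    half = 0.35
    var_e = half * half / 3.0
    a_rho = abs(rho)
    flip = -1.0 if rho < 0 else 1.0
    if a_rho >= 1.0 - 1e-12:
        g = rng.normal(0.0, 1.0, n_genes)
        mean_a, mean_b = g, flip * g
    elif a_rho <= 1e-12:
        mean_a = rng.uniform(-half, half, n_genes)
        mean_b = rng.uniform(-half, half, n_genes)
    else:
        # latent variance solving corr(empirical gene means) = rho, which
        # accounts for both the bounded per-dataset offsets and the sample
        # noise attenuation (noise variance / n_samples per dataset)
        ea = var_e + noise_sd ** 2 / n_samples_a
        eb = var_e + noise_sd ** 2 / n_samples_b
        r2 = a_rho * a_rho
        var_g = (r2 * (ea + eb)
                 + math.sqrt(r2 * r2 * (ea + eb) ** 2
                             + 4.0 * (1.0 - r2) * r2 * ea * eb)) / (2.0 * (1.0 - r2))
        g = rng.normal(0.0, math.sqrt(var_g), n_genes)
        mean_a = g + rng.uniform(-half, half, n_genes)
        mean_b = flip * g + rng.uniform(-half, half, n_genes)

    genes = [f"GENE{i + 1:05d}" for i in range(n_genes)]
    divergent = np.zeros(n_genes + n_divergent, dtype=bool)
    if n_divergent:
        g2 = rng.normal(0.0, 0.5, n_divergent)
        off = rng.uniform(1.3, 2.0, n_divergent) * rng.choice([-1.0, 1.0], n_divergent)
        mean_a = np.concatenate([mean_a, g2])
        mean_b = np.concatenate([mean_b, g2 + off])
        genes += [f"DIVG{i + 1:05d}" for i in range(n_divergent)]
        divergent[n_genes:] = True

    n_private = int(round(private_frac * n_genes))

    def build(means, n_samples, tag, priv_prefix):
        m = np.asarray(means)
        if n_private:
            m = np.concatenate([m, rng.normal(0.0, 0.6, n_private)])
        names = genes + [f"{priv_prefix}{i + 1:05d}" for i in range(n_private)]
        noise = (rng.normal(0.0, noise_sd, (m.size, n_samples))
                 if noise_sd > 0 else np.zeros((m.size, n_samples)))
        vals = m[:, None] + noise
        cols = [f"{tag}_s{j + 1}" for j in range(n_samples)]
        return pd.DataFrame(vals, index=names, columns=cols)

    df_a = build(mean_a, n_samples_a, species[0], "PRIVA")
    df_b = build(mean_b, n_samples_b, species[1], "PRIVB")
    truth = pd.DataFrame({
        "gene": genes, "mean_a": mean_a, "mean_b": mean_b,
        "divergent": divergent,
    })
    a = ExpressionMatrix(df_a, species=species[0], normalized="cohort-zscore")
    b = ExpressionMatrix(df_b, species=species[1], normalized="cohort-zscore")
    return a, b, truth


def gen_drug_target_map(
    drugs: int | list[str],
    genes: list[str],
    seed: int = 0,
    *,
    targets_per_drug: tuple[int, int] = (5, 120),
) -> pd.DataFrame:
    """Sparse drug->target bipartite map as a two-column (drug, gene) table."""
    if isinstance(drugs, int):
        drugs = [f"drug{i + 1:02d}" for i in range(drugs)]
    if not drugs or not len(genes):
        raise ValueError("need at least one drug and one gene")
    rng = np.random.default_rng(seed)
    lo, hi = targets_per_drug
    rows = []
    for d in drugs:
        k = int(rng.integers(lo, min(hi, len(genes)) + 1))
        for g in rng.choice(genes, size=max(1, k), replace=False):
            rows.append((d, g))
    return pd.DataFrame(rows, columns=["drug", "gene"])


# ---------------------------------------------------------------------------
# constant-ratio combination assays
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticCombinationTruth:
    """Ground truth for a constant-ratio two-drug combination experiment.

    dm1/dm2 are the drugs' median-effect doses, m1/m2 their sigmoidicity
    exponents, ratio = dose2/dose1 (e.g. 200 for a 1:200 design), ci_true
    the planted combination index (constant across effect levels), and
    noise_sd the Gaussian noise added to generated fraction-affected values.
    """

    dm1: float
    dm2: float
    m1: float = 1.0
    m2: float = 1.0
    ratio: float = 1.0
    ci_true: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.dm1 <= 0 or self.dm2 <= 0:
            raise ValueError("median-effect doses must be positive")
        if self.m1 <= 0 or self.m2 <= 0:
            raise ValueError("sigmoidicity exponents must be positive")
        if self.ratio <= 0:
            raise ValueError("dose ratio must be positive")
        if self.ci_true <= 0:
            raise ValueError("ci_true must be positive")


_FA_EPS = 1e-6


def _ci_at_fa(fa, d1, d2, truth: SyntheticCombinationTruth):
    t = fa / (1.0 - fa)
    dx1 = truth.dm1 * t ** (1.0 / truth.m1)
    dx2 = truth.dm2 * t ** (1.0 / truth.m2)
    return d1 / dx1 + d2 / dx2


def _solve_fa(d1, d2, truth: SyntheticCombinationTruth) -> float:
    """fa at which the dose pair's combination index equals ci_true."""
    from scipy.optimize import brentq

    f = lambda fa: _ci_at_fa(fa, d1, d2, truth) - truth.ci_true
    lo, hi = 1e-12, 1.0 - 1e-12
    # CI is strictly decreasing in fa (Dx increases with fa)
    return float(brentq(f, lo, hi, xtol=1e-15, rtol=1e-14))


def gen_combination_assay(
    truth: SyntheticCombinationTruth,
    dose_levels=None,
    seed: int = 0,
    *,
    single_folds=(0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0),
) -> dict[str, pd.DataFrame]:
    """Generate single-drug and combination viability (fraction-affected) tables.

    ``dose_levels`` is a list of (dose1, dose2) pairs sharing the truth's
    ratio; by default the Table-2-style ladder of IC50 folds
    (4, 2, 1, 0.5, 0.25) x (dm1, dm2) is used.  Each combination row's
    noise-free fa is the level at which the pair's combination index equals
    ``ci_true``; single-drug fa values follow each drug's median-effect
    curve.  Gaussian noise (``truth.noise_sd``) is added to fa, and values
    forced outside (0, 1) are clipped and flagged in a ``clipped`` column.

    Returns dict with keys ``drug1``, ``drug2`` (columns dose, fa, clipped)
    and ``combo`` (columns dose1, dose2, fa, clipped).
    """
    rng = np.random.default_rng(seed)
    if dose_levels is None:
        folds = (4.0, 2.0, 1.0, 0.5, 0.25)
        dose_levels = [(f * truth.dm1, f * truth.dm1 * truth.ratio) for f in folds]
    for d1, d2 in dose_levels:
        if d1 <= 0 or d2 <= 0:
            raise ValueError("doses must be positive")
        if abs(d2 / d1 - truth.ratio) > 1e-9 * truth.ratio:
            raise ValueError(
                f"dose pair ({d1}, {d2}) does not share the stated ratio "
                f"{truth.ratio}")

    def noisy(fa):
        fa = np.asarray(fa, dtype=float)
        if truth.noise_sd > 0:
            fa = fa + rng.normal(0.0, truth.noise_sd, fa.shape)
        clipped = (fa < _FA_EPS) | (fa > 1.0 - _FA_EPS)
        return np.clip(fa, _FA_EPS, 1.0 - _FA_EPS), clipped

    out = {}
    for key, dm, m in (("drug1", truth.dm1, truth.m1),
                       ("drug2", truth.dm2, truth.m2)):
        doses = np.array([f * dm for f in single_folds])
        fa, clipped = noisy(1.0 / (1.0 + (dm / doses) ** m))
        out[key] = pd.DataFrame({"dose": doses, "fa": fa, "clipped": clipped})
    fa0 = [_solve_fa(d1, d2, truth) for d1, d2 in dose_levels]
    fa, clipped = noisy(fa0)
    out["combo"] = pd.DataFrame({
        "dose1": [d for d, _ in dose_levels],
        "dose2": [d for _, d in dose_levels],
        "fa": fa,
        "clipped": clipped,
    })
    return out
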
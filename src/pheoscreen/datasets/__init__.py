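"""Bundled reference tables.

Two small published result tables from a qHTS drug-repurposing screen
against metastatic pheochromocytoma (MTT) cells are shipped for worked
examples and desk checks:

* the top-50 hit list (name, curve class, IC50 µM, efficacy %), printed in
  the screen's inhibition-direction notation: curve class and efficacy
  carry a negative sign for inhibitors;
* the epirubicin + SAHA constant-ratio (1:200) combination table: dose
  pair, fraction affected, combination index, synergy call and the two
  dose-reduction indices.  Doses are recorded in nM (consistent with 4x
  ladders of the single-drug IC50s of 5 nM epirubicin and 1 µM SAHA).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["load_top50_hits", "load_epirubicin_saha"]


def _path(name: str):
    return resources.files(__package__).joinpath(name)


def load_top50_hits() -> pd.DataFrame:
    """Top-50 qHTS hit table, parsed into the internal sign convention.

    The printed negative curve classes ("-1.1") and efficacies ("-85")
    denote inhibition; they are parsed by absolute value with the direction
    kept in a ``direction`` column (-1 = inhibition).
    """
    with resources.as_file(_path("mtt_qhts_top50_hits.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    df["direction"] = np.where(df["efficacy_pct"] < 0, -1, 1)
    df["curve_class"] = df["curve_class"].astype(str).str.lstrip("-")
    df["efficacy_pct"] = df["efficacy_pct"].abs()
    return df


def load_epirubicin_saha() -> pd.DataFrame:
    """Epirubicin/SAHA constant-ratio combination reference table (doses nM)."""
    with resources.as_file(_path("epirubicin_saha_combination.tsv")) as p:
        return pd.read_csv(p, sep="\t")
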
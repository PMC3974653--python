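"""Cross-species expression meta-analysis.

Bridges murine screen hits to human relevance: gene-wise z-scoring of each
dataset, merging on the shared (uppercased) gene-symbol namespace, a
<2-fold cross-dataset change filter, and a per-drug Pearson correlation
between the two datasets' mean expression profiles over each drug's target
genes.

A note on z-scoring: strictly per-gene z-scoring across a dataset's own
samples forces every gene's mean over those samples to zero, which would
make cross-dataset mean-profile correlations degenerate.  Public datasets
are typically normalized across a broader cohort than the analysis subset,
so subset gene means remain informative.  :class:`ExpressionMatrix` carries
a ``normalized`` state flag: matrices arriving already scaled (e.g. the
synthetic generator's cohort-z-scored output) are merged as-is, while raw
matrices must pass through :func:`zscore_genes` first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "MergedExpression",
    "DrugTargetMap",
    "zscore_genes",
    "merge_common_genes",
    "fold_change_filter",
    "overall_correlation",
    "drug_target_correlation",
    "replicate_correlation",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a species tag.

    ``values``: DataFrame, index = gene symbols (unique), columns = sample
    ids.  ``normalized``: "raw", "zscore", or any already-scaled marker.
    Genes containing missing values are dropped at construction with a
    logged count.
    """

    values: pd.DataFrame
    species: str = ""
    normalized: str = "raw"
    zero_variance_genes: list = field(default_factory=list)

    def __post_init__(self):
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate gene symbols, e.g. {dups}")
        n_missing = int(v.isna().any(axis=1).sum())
        if n_missing:
            logger.info("dropping %d genes with missing values", n_missing)
            self.values = v.dropna(axis=0)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def zscore_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Gene-wise z-score: each gene row to mean 0, population sd 1.

    Zero-variance rows are set to all-zeros and listed in
    ``zero_variance_genes``.  Idempotent.  Rejects single-sample matrices
    (sd undefined).
    """
    if matrix.n_samples < 2:
        raise ValueError("z-scoring needs >=2 samples per gene")
    v = matrix.values
    mean = v.mean(axis=1)
    sd = v.std(axis=1, ddof=0)
    flat = sd <= 0
    sd_safe = sd.mask(flat, 1.0)
    z = v.sub(mean, axis=0).div(sd_safe, axis=0)
    z.loc[flat] = 0.0
    return ExpressionMatrix(
        z, species=matrix.species, normalized="zscore",
        zero_variance_genes=list(v.index[flat]),
    )


@dataclass
class MergedExpression:
    """Two z-scored datasets merged on their common genes."""

    values: pd.DataFrame
    samples_a: list[str]
    samples_b: list[str]
    species: tuple[str, str]

    @property
    def common_genes(self) -> pd.Index:
        return self.values.index

    def mean_profiles(self) -> tuple[pd.Series, pd.Series]:
        """Per-gene mean over each dataset's samples."""
        return (self.values[self.samples_a].mean(axis=1),
                self.values[self.samples_b].mean(axis=1))


def _map_symbols(mat: ExpressionMatrix, ortholog_map: dict | None) -> pd.DataFrame:
    v = mat.values
    idx = v.index.astype(str).str.upper()
    if ortholog_map:
        upper_map = {str(k).upper(): str(val).upper() for k, val in ortholog_map.items()}
        idx = idx.map(lambda g: upper_map.get(g, g))
    out = v.copy()
    out.index = idx
    # collisions after mapping: keep the first occurrence
    out = out[~out.index.duplicated(keep="first")]
    return out


def merge_common_genes(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
    restrict_to=None,
    *,
    ortholog_map: dict | None = None,
) -> MergedExpression:
    """Merge two scaled matrices on the intersection of their gene symbols.

    Symbols are uppercased into a shared namespace (murine Tp53 meets human
    TP53); an optional two-column ortholog mapping overrides this for the
    first matrix.  ``restrict_to`` (e.g. the union of drug-target genes)
    further intersects the row set.  Columns are the union of both
    datasets' samples.
    """
    for m, tag in ((a, "first"), (b, "second")):
        if m.normalized == "raw":
            raise ValueError(
                f"{tag} matrix is not scaled; apply zscore_genes() before merging")
    va = _map_symbols(a, ortholog_map)
    vb = _map_symbols(b, ortholog_map=None)
    common = va.index.intersection(vb.index)
    if restrict_to is not None:
        keep = pd.Index([str(g).upper() for g in restrict_to]).unique()
        common = common.intersection(keep)
    common = common.sort_values()
    if len(common) == 0:
        raise ValueError(
            f"no common genes (first: {len(va)}, second: {len(vb)}, "
            f"restriction: {'none' if restrict_to is None else len(set(restrict_to))})")
    overlap = set(va.columns) & set(vb.columns)
    if overlap:
        raise ValueError(f"sample ids shared between datasets: {sorted(overlap)[:5]}")
    merged = pd.concat([va.loc[common], vb.loc[common]], axis=1)
    logger.info("merged on %d common genes", len(common))
    return MergedExpression(
        merged, samples_a=list(va.columns), samples_b=list(vb.columns),
        species=(a.species, b.species),
    )


def fold_change_filter(merged: MergedExpression, threshold_fold: float = 2.0) -> list[str]:
    """Genes whose cross-dataset mean difference is below the fold cut.

    On log2/z-scale data a k-fold change corresponds to a mean difference
    of log2(k); genes with |mean_a - mean_b| < log2(threshold_fold) are
    kept.  Returns the surviving gene list (matrix order).
    """
    if threshold_fold <= 1.0:
        raise ValueError("threshold_fold must be > 1")
    ma, mb = merged.mean_profiles()
    cut = np.log2(threshold_fold)
    keep = (ma - mb).abs() < cut
    return list(merged.common_genes[keep])


def overall_correlation(merged: MergedExpression, genes=None) -> float:
    """Pearson correlation of the two datasets' gene-mean vectors.

    Optionally restricted to a gene list (e.g. the fold-change-filter
    survivors).  This is the dataset-level similarity summary of the merged
    cross-species comparison.
    """
    ma, mb = merged.mean_profiles()
    if genes is not None:
        genes = [str(g).upper() for g in genes]
        ma, mb = ma.loc[genes], mb.loc[genes]
    if len(ma) < 3:
        raise ValueError("need >=3 genes for a correlation")
    return float(np.corrcoef(ma.to_numpy(), mb.to_numpy())[0, 1])


@dataclass
class DrugTargetMap:
    """Drug name -> set of (uppercased) target gene symbols."""

    targets: dict[str, set[str]]

    def __post_init__(self):
        clean = {}
        for drug, genes in self.targets.items():
            genes = {str(g).upper() for g in genes}
            if not genes:
                raise ValueError(f"drug {drug!r} has an empty target set")
            clean[str(drug)] = genes
        self.targets = clean

    @classmethod
    def from_frame(cls, df: pd.DataFrame, drug_col: str = "drug",
                   gene_col: str = "gene") -> "DrugTargetMap":
        groups = df.groupby(drug_col)[gene_col].apply(set)
        return cls(groups.to_dict())

    @property
    def drugs(self) -> list[str]:
        return sorted(self.targets)

    @property
    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for g in self.targets.values():
            out |= g
        return out

    def __len__(self):
        return len(self.targets)

    def __getitem__(self, drug):
        return self.targets[drug]


def drug_target_correlation(
    merged: MergedExpression,
    dtmap: DrugTargetMap,
    min_targets: int = 3,
    *,
    gene_agreement_cut: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-drug cross-dataset Pearson correlation over target genes.

    For each drug, r = Pearson between the two datasets' gene-wise mean
    profiles restricted to that drug's mapped target genes.  Drugs with
    fewer than ``min_targets`` mapped genes are reported with ``defined``
    False and r = NaN.  The overall value is the mean of the defined r's.

    ``gene_agreement_cut``, if given, adds an ``n_high_correlated`` column
    counting each drug's target genes whose cross-dataset mean difference
    is below the cut (same scale as the fold-change filter).  No default
    is claimed for this threshold.
    """
    ma, mb = merged.mean_profiles()
    rows = []
    for drug in dtmap.drugs:
        targets = sorted(dtmap[drug] & set(merged.common_genes))
        n = len(targets)
        n_high = (int(((ma.loc[targets] - mb.loc[targets]).abs()
                       < gene_agreement_cut).sum())
                  if gene_agreement_cut is not None else None)
        if n < min_targets:
            rows.append((drug, n, np.nan, False, n_high))
            continue
        x = ma.loc[targets].to_numpy()
        y = mb.loc[targets].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((drug, n, np.nan, False, n_high))
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        rows.append((drug, n, r, True, n_high))
    table = pd.DataFrame(
        rows, columns=["drug", "n_targets_mapped", "pearson_r", "defined",
                       "n_high_correlated"])
    if gene_agreement_cut is None:
        table = table.drop(columns="n_high_correlated")
    defined = table.loc[table["defined"], "pearson_r"]
    overall = float(defined.mean()) if len(defined) else float("nan")
    return table, overall


def replicate_correlation(matrix: ExpressionMatrix) -> pd.DataFrame:
    """QC report: pairwise Pearson correlation between samples.

    The screen's upstream QC expects replicate correlations > 0.98; this is
    a report, not a gate.
    """
    return matrix.values.corr(method="pearson")
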
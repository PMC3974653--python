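# pheoscreen

Analysis toolkit for quantitative high-throughput drug-repurposing screens
(qHTS) in metastatic pheochromocytoma/paraganglioma (PHEO/PGL), the most
common tumor of the adrenal medulla.  It covers the full chain from raw
1536-well plate reads to a ranked hit list, a cross-species expression
bridge, a drug–target network, and Chou–Talalay synergy quantification —
the workflow used to triage ~3,800 clinically approved compounds against a
murine metastatic PHEO (MTT) cell line and to nominate drug combinations
such as epirubicin + SAHA.

## Who it is for

Screeners and computational biologists who have (a) plate-reader tables
with in-plate controls, (b) a compound/titration map, and optionally
(c) expression matrices from two species plus a drug→target-gene map and
(d) constant-ratio combination viability data — and who want the published
triage, correlation, hub and synergy statistics reproducibly, with a
synthetic-data generator that makes every stage testable without
downloads.

## The models at the core

**Dose–response (qHTS).**  Raw reads are normalized per plate to percent
inhibition, `100·(median(DMSO) − read) / (median(DMSO) − median(pos))`,
so DMSO basal = 0 and the positive control (doxorubicin, full kill) = 100.
Each 8-point titration (0.5 nM–46 µM) is fitted with the four-parameter
logistic

    y = bottom + (top − bottom) / (1 + (IC50/x)^h),

and classified into Inglese curve classes: 1.1/1.2 complete curves (both
asymptotes, efficacy ≥80% / <80%), 2.1/2.2 incomplete (one asymptote),
3 single-point or poorly fit, 4 inactive.  Triage: classes 1.1–2.2 with
efficacy >60% are active, class 4 inactive, the rest inconclusive; hits
are ranked by class confidence then potency, and per-therapeutic-category
enrichment (`100·n_active/n_total`) is reported.

**Cross-species meta-analysis.**  Gene-wise z-scored murine and human
matrices are merged on their shared (uppercased) gene symbols, genes with
≥2-fold cross-dataset change are removed, and each drug's relevance is
scored by the Pearson correlation between the two datasets' mean
expression profiles over that drug's target genes.

**Drug–target network.**  An undirected drug/gene graph (optionally with
every target connected to every drug); node importance is eccentricity
centrality, `score(v) = 1 / max_u dist(v, u)` within v's component; top-20
hubs and GMT gene-set subnetworks are extracted.

**Synergy (Chou–Talalay).**  The median-effect equation
`fa/fu = (D/Dm)^m` is fitted log-linearly per drug; for a dose pair at
observed effect `fa`, the combination index is
`CI = d1/Dx1 + d2/Dx2` with `Dx = Dm·(fa/fu)^(1/m)`; CI <0.8 synergistic,
0.8–1.2 additive, >1.2 antagonistic; the dose-reduction index is
`DRI = Dx/d`, and `CI = Σ 1/DRI` holds identically.

## Worked example

The bundled epirubicin + SAHA constant-ratio (1:200) combination table
(doses in nM), re-analyzed from the dose pairs, fractions affected and
DRI-implied single-drug points:

```python
import numpy as np
from pheoscreen import CombinationAnalysis
from pheoscreen.datasets import load_epirubicin_saha

t = load_epirubicin_saha()
fa = t["fraction_affected"].to_numpy()
res = CombinationAnalysis(
    (np.asarray(t.dri_epi * t.dose_epi_nm), fa),    # epirubicin dose-effect
    (np.asarray(t.dri_saha * t.dose_saha_nm), fa),  # SAHA dose-effect
    t.rename(columns={"dose_epi_nm": "dose1", "dose_saha_nm": "dose2",
                      "fraction_affected": "fa"})[["dose1", "dose2", "fa"]],
).fit()
print(res.summary())
```

prints

```
Chou-Talalay combination analysis
  drug 1: Dm = 15.09, m = 0.603, r = 1.000
  drug 2: Dm = 1903, m = 1.145, r = 1.000
  combo : Dm = 624.3, m = 0.805, r = 0.997

       dose1      dose2       fa      CI          call    DRI1    DRI2
          20       4000   0.8086   0.719   synergistic   8.227   1.674
          10       2000   0.7406   0.537   synergistic   8.593   2.378
           5       1000   0.5884   0.568   synergistic   5.459   2.600
         2.5        500   0.4467   0.553   synergistic   4.230   3.156
        1.25        250   0.3281   0.518   synergistic   3.675   4.069
```

Every CI is below 0.8, so the combination is synergistic at all tested
levels; DRI1 = 8.2 at the top level means epirubicin's dose could be cut
~8-fold at equal effect.  `res.plot_fa_ci()` and
`res.plot_median_effect()` draw the Fa–CI and median-effect plots.

A full synthetic screen from the shell:

```sh
pheoscreen run --seed 1 --out-dir out/      # simulate → screen → … → synergy
pheoscreen screen fit --plates out/plates.tsv --map out/compound_map.tsv --out fits.tsv
pheoscreen net hubs --targets out/drug_targets.tsv --top 20 --out hubs.tsv
```

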
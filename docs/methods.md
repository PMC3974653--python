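# Methods

This note documents the statistical procedures, the thresholds and their
defaults, the numerical choices, and what the synthetic-data generators do
and do not emulate.

## Plate normalization

Each 1536-well plate carries its own controls in columns 1–4 (DMSO basal
and doxorubicin full-kill).  Reads are mapped affinely so the DMSO median
is exactly 0% and the positive-control median exactly 100% inhibition.
The median (not mean) aggregates control wells — robust to occasional
dispensing failures; a control window below numerical tolerance raises a
degenerate-window error rather than producing unbounded values.
Normalization is affine, hence idempotent on already-normalized data with
ideal controls.

## Four-parameter logistic fit

Model `y = bottom + (top − bottom)/(1 + (IC50/x)^h)`, `h > 0` (response
rises with concentration; inhibition is stored as positive percent, and
reports that print inhibition negatively are parsed by absolute value
with the direction recorded).  Fitting is bounded least squares
(`scipy.optimize.curve_fit`) started from a deterministic coarse profile
grid: for fixed (IC50, h) the model is linear in (bottom, top), so those
are profiled out in closed form over a 25×8 log-IC50 × hill grid and the
three best cells seed the nonlinear refinement.  There is no randomness
anywhere in the fit; an optimizer failure sets `converged = False`
instead of raising.  Reported efficacy is |top − bottom| capped at 2.5×
the observed response span, which stops runaway asymptote extrapolation
on incomplete curves while leaving ordinary fits untouched (printed
screen efficacies above 100% remain representable).  On noiseless
synthetic curves the fit matches a dense brute-force grid oracle and
recovers planted IC50s to ≲1e-12 relative.

## Curve classification and triage

Classification is total and mutually exclusive over {1.1, 1.2, 2.1, 2.2,
3, 4}, decided in the order 4 → 3 → completeness → efficacy split:

1. **Class 4** — no convergence with no significant response, no response
   above the significance threshold, or fitted efficacy under the
   `min_efficacy_pct` floor (default 30%).
2. **Class 3** — significant activity at only the highest tested
   concentration, or r² < 0.5 (“poorly fit”), or a mid-slope curve
   supporting neither plateau.
3. **1.x vs 2.x** — a plateau counts as present when ≥2 tested
   concentrations have model responses within 10% of the fitted
   asymptote’s level inside the tested range (the literature never
   defines “asymptote present” numerically; this operationalization is
   config-exposed via `plateau_window` / `plateau_min_points`).  Both
   plateaus → complete (1.x), exactly one → incomplete (2.x).
4. **.1 vs .2** — fitted efficacy ≥80% vs <80% (comparison non-strict at
   80, strict at the 60% activity cut, exactly as the rules are worded).

Significance threshold: `max(3·σ̂, 6%)` where σ̂ is 1.4826×MAD of the
least-active half of the responses — the absolute floor keeps noiseless
data from declaring every wiggle significant.

Triage: active = class 1.1–2.2 with efficacy >60%; inactive = class 4;
everything else inconclusive.  Published hit lists contain sub-60%
curve-class hits, suggesting the original cut may have used the maximal
*observed* response rather than fitted efficacy; both rules are
implemented (`triage_on_observed_max`), the fitted-efficacy rule being
the default.  Hit ranking sorts by class confidence block
(1.1 < 1.2 < 2.1 < 2.2), ascending IC50 within a block, compound id on
ties, so output order is deterministic.  Category enrichment is
`100·n_active/n_total` per therapeutic category, flagged above 20%.

## Synthetic screens

The generator emulates the assay geometry: 32×48-well plates, columns 1–2
DMSO and 3–4 positive control, one well position per compound across a
stack of 8 plates (interplate titration, one tested concentration per
plate).  The tested ladder anchors at 46 µM and descends by 2.236² ≈ 5
per step to ≈0.59 nM; the library's 1:2.236 serial dilution is the
*stock* scheme whose alternate steps form the 8 tested doses, and the
15-plate stock layout itself is not modeled.  Raw reads are the planted
4PL response plus additive Gaussian noise (default sd 3% of the control
window — consistent with typical luminescence CVs) mapped into
luminescence space anchored at 2000 (basal) and 200 (full-kill) counts.

Planted classes are boundary-avoiding so noiseless recovery is
deterministic: efficacies keep ≥2 points clear of the 60/80 cuts (x.1:
82–100, x.2: 62–78 or, for the low-efficacy fraction, 45–58); complete
curves put IC50 mid-ladder (between points 4 and 5) with hills 1.5–3;
incomplete curves put IC50 just above the top tested dose (1.15–1.8× the
7th point) with hills 1.5–2 so at least two concentrations respond above
the noise floor; class 3 is a steep (h = 8) curve centred on the top dose
(a single-point spike), with an optional shallow-curve variant; class 4
is flat.  `reference_screen_composition()` returns the mix that matches
the published triage proportions (3,826 compounds → 76/3,481/269 with 40
potent actives).  Not emulated: edge effects, liquid-handling artifacts,
luminescence photophysics, 24 h vs 48 h time points — so recovery rates
here bound what the pipeline can do on ideal plates, not on pathological
real ones.

## Cross-species meta-analysis

`zscore_genes` maps every gene row to mean 0 / population sd 1
(zero-variance rows to zeros, flagged; single-sample matrices rejected).
Strict within-dataset z-scoring would force every gene's mean over its
own samples to zero and make cross-dataset mean-profile correlations
degenerate; public datasets are typically normalized over a broader
cohort than the analysis subset, so subset means stay informative.  The
`ExpressionMatrix.normalized` flag records this state: raw matrices must
be z-scored before merging, already-scaled matrices pass through
unchanged.  Merging uppercases symbols into a shared namespace (an
explicit ortholog table can override the murine→human identification),
intersects gene sets (optionally restricted to drug-target genes), and
keeps the union of samples.  The fold-change filter drops genes with
|Δmean| ≥ log2(threshold) (threshold default 2) on the log2/z scale; it
is monotone in the threshold.  Per-drug correlation is the Pearson r
between the two datasets' gene-mean vectors over the drug's mapped
targets (the only construction well-defined for unequal sample counts);
drugs with <3 mapped targets are flagged undefined rather than scored.
The dataset-level summary is the same correlation over all (or the
filter-surviving) common genes.  Replicate-correlation QC is a report,
not a gate.  The threshold behind "number of highly correlated genes" is
never defined in the source material; it is exposed as the optional
`gene_agreement_cut` with no claimed default.

The expression-pair generator plants per-gene latent levels shared
between species with bounded per-dataset offsets (uniform ±0.35, so
concordant genes can never cross a 2-fold cut) plus i.i.d. sample noise
(sd 0.08, giving replicate correlations ≈0.98); the latent variance is
solved in closed form so the correlation of the *empirical* gene means
equals the requested rho, including the noise attenuation.  Divergent
genes get offsets ≥1.3 (safely beyond 2-fold), so the filter's survivor
set is exactly the concordant set with overwhelming probability.  Real
arrays add probe effects, batch structure and heavy-tailed noise that
this generator deliberately omits.

## Drug–target network

Undirected, unweighted (direction and weights are never stated for this
construction).  Base edges are drug→target; the "connected node network"
flag additionally links every target gene to every drug (edge relation
`connected` vs `targets` is kept, so gene-set extraction can require a
*targeting* drug).  Eccentricity is computed per connected component
(global eccentricity is infinite on disconnected graphs); singleton
components get an undefined score.  Hub ties break by degree then lexical
id.  The published global network reports 2,153 nodes for 22 drugs +
2,129 genes (= 2,151); this package reports its own exact counts rather
than forcing agreement with that figure.  Gene sets arrive as named
plain-text lists (GMT), not live pathway-database queries, for version
pinning and offline operation.

## Chou–Talalay analysis

Median-effect fits are ordinary least squares on
`log10(fa/fu) = m·(log10 D − log10 Dm)`; fa is clipped to
[1e-6, 1−1e-6] with a warning; all-identical fa is a degenerate-fit
error.  `fit(fix_dm=...)` constrains Dm and estimates only the slope.
The CI uses the mutually exclusive form `d1/Dx1 + d2/Dx2` (no third
product term): applied to the bundled combination table it reproduces
all five printed CI values within 0.0003, so it is the form the original
software computed.  Bands: CI <0.8 synergistic, 0.8–1.2 additive, >1.2
antagonistic (the source text's "antagonism when CI<1.2" is an evident
misprint).  `CI = Σ 1/DRI` holds exactly for every emitted row by
construction.  The Fa–CI curve fits the combination's total dose as a
single agent and splits it by the design ratio.  Note the bundled
table's DRI-implied single-drug lines pass through Dm ≈ 15.1 nM
(m ≈ 0.603, epirubicin) and ≈1.90 µM (m ≈ 1.145, SAHA) — close to, but
not equal to, the approximate "relative IC50s" of 5 nM and 1 µM quoted
for those drugs; the analysis is unit-agnostic (only dose ratios enter
CI), and the bundled doses are recorded in nM.

The combination generator inverts the exact CI computation: for each
constant-ratio dose pair it solves (Brent's method, tolerance 1e-14) for
the fa at which the pair's CI equals the planted `ci_true`, then adds
Gaussian fa noise, clipping into (0,1) with a flag.  Additivity
(ci_true = 1) therefore round-trips to CI = 1 within solver tolerance.
At 1% fa noise the per-dose-level CI at extreme effect levels (fa ≈ 0.8)
carries a propagated sd of ≈0.06, so recovery statements are made at the
experiment level — the mean CI over the 5 dose levels, which is also the
CI estimate the analysis reports: ≥95% of additive replicates fall in
[0.9, 1.1] there.

## Sizes, runtime, determinism

Every generator takes an explicit integer seed; there is no global random
state, and identical seeds give byte-identical outputs.  Default problem
sizes — 500-compound screens for recovery measurements, one full-size
3,826-compound screen for the triage counts, 200 replicates per planted
CI for synergy calls, 100 random graphs (≤100 nodes) for the centrality
oracle, 5 replicate 1,753-gene expression pairs — were chosen so the
statistics they estimate are stable to well inside the tolerances quoted
for them.  The pipeline manifest records the package version, seed,
config snapshot and SHA-256 of every artifact, so reruns are verifiably
identical.

## Known limitations

* Curve-class boundaries are inherently unstable for compounds whose true
  efficacy sits near 60/80% or whose IC50 sits near the ladder edge; the
  generators avoid those regions by design, so recovery rates do not
  describe boundary compounds.
* The meta-analysis treats uppercased symbol identity as the default
  cross-species gene mapping; genuine orthology requires the optional
  mapping table.
* Fold-change filtering on z-scores (when no log-scale data is
  available) is a scale approximation, logged as such.
* The network stage does not compute pathway-enrichment p-values; gene
  sets are user-supplied.
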
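# Methods

## Data model

The pipeline operates on a complete genes × samples matrix of
quantification cycles (Ct). Missing cells are a hard error; the only
relaxation offered is dropping whole samples (`drop_incomplete_samples`),
because every statistic below assumes one common sample set and
pairwise-complete variants would make the six methods' rankings
incomparable. Technical replicates (columns `sample__r<k>`) are collapsed
by the arithmetic mean of Ct by default (median optional). Valid Ct lie in
(0, 45] cycles — the upper bound is the usual number of amplification
cycles an instrument runs.

Amplification efficiencies `E` are fold-per-cycle (ideal doubling `E = 2`),
either supplied per gene or fitted from a dilution series: an OLS fit of Ct
on log₁₀ input has slope `−1/log₁₀(E)`, so `E = 10^(−1/slope)`. Values must
lie in (1, 2.2]; genes without an entry default to 2. Relative quantities
are anchored at each gene's minimum Ct (the sample with the most template):
`Q[g,s] = E_g^(minCt_g − Ct[g,s])`, so `max_s Q = 1` per gene, the geNorm
convention. Calibrator-anchored quantities appear only in the normalization
stage.

## Per-gene stability statistics

**Comparative ΔCt.** For each ordered gene pair, the SD (ddof = 1, as for
every SD in the package) over samples of `Ct_i − Ct_k`; a gene's `mSD` is
the mean over its partners. Raw-Ct scale.

**BestKeeper.** Per gene: mean Ct (AM), "SD" as the mean absolute deviation
from AM (BestKeeper's original convention; classical ddof-1 SD via
`sd_mode="classic"`), CV% = 100·SD/AM. The BestKeeper index is the
per-sample geometric mean of all candidates' Ct; genes are ranked by the
Pearson correlation `r` of their Ct with the index (descending), with SD
and CV reported alongside and available as alternative ranking keys. A
zero-variance gene has undefined `r`: it is scored NaN, ranked last, and a
warning is emitted. No SD-based pre-filter is applied to the index by
default (`sd_filter` enables one).

**geNorm.** On log₂ quantities, the pairwise variation
`V_jk = SD_s(log₂ Q_j − log₂ Q_k)` and `M_j = mean_{k≠j} V_jk`. The gene
with the highest M is removed and M recomputed until two genes remain;
those two are reported tied at ranks 1–2 (their M values are equal by
construction). Each gene's reported score is its M at removal. Ties on
equal M remove the later gene in input order and are recorded in the trace.
Genes with reported M ≥ 1.5 are flagged unusable. With all `E = 2`,
`SD(log₂ Q_j/Q_k) = SD(Ct_k − Ct_j)`, so the full-panel M equals the ΔCt
mSD exactly — a cross-algorithm identity the acceptance suite checks to
1e−9.

The gene-number rule: `NF_n` is the per-sample geometric mean quantity of
the n most stable genes; `V_{n/n+1} = SD_s(log₂ NF_n/NF_{n+1})`. The
smallest n with V below the 0.15 threshold is recommended; if none falls
below, N−1 is reported with a flag.

**NormFinder-style variance decomposition.** Each sample's across-gene mean
of log₂ quantities is subtracted first (removing the loading term shared by
all genes). With G genes and groups g of size n_g:

    SV_i = mean_g( |z_ig| + sqrt(s²_ig / n_g) )

where `s²_ig` is the intra-group variance of gene i's residuals and `z_ig`
is the gene × group interaction — the group mean of the residuals, centered
across groups, multiplied by `G/(G−1)`. That factor undoes the 1/G
contamination the across-gene centering introduces (a pure ±δ between-group
shift on one gene then yields SV = δ exactly, for any panel size).
Ungrouped data (or a single group) use the corrected residual SD,
`SD_s(y_i)·sqrt(G/(G−1))`. Groups must have more than two samples; exact
equality with the originally published NormFinder estimator is not claimed.

## Consensus rank aggregation

The consensus is the permutation minimizing the summed (optionally
weighted) Spearman footrule distance `Σ_g |pos_a(g) − pos_b(g)|` to the
input orderings (Kendall distance available as an option). The optimizer is
cross-entropy Monte Carlo over a gene × position probability matrix:
initialized uniform; each iteration samples candidates position-by-position
without replacement (row renormalization over the unassigned genes),
re-estimates the matrix from the elite ρ fraction and blends
`P ← s·P + (1−s)·F` with smoothing s = 0.25 retained by the old matrix.
Defaults: `samples_per_iter = max(2000, 40·n)`, ρ = 0.1, stagnation limit
15, at most 200 iterations — sized for panels of n ≤ 20, where convergence
typically takes ~25 iterations. The input lists are injected into the first
candidate pool, so the result can never score worse than any input, and a
fixed seed makes the run bit-reproducible.

Because the footrule objective decomposes per position, the exact optimum
is a linear assignment problem; the test suite uses the Hungarian algorithm
(and, for n ≤ 8, full enumeration via `aggregate_exhaustive`, lexicographic
tie-break in gene input order) as independent oracles for the stochastic
optimizer. On 50 random 5–6 gene instances the CE result matches the
exhaustive optimum 50/50.

## Combination scoring (GrayNorm-style)

Every subset of the candidate panel (2ⁿ − 1 subsets; full enumeration
guarded at n ≤ 20, CLI default size 3 following common practice of using
three references) is scored as a normalizer: NF per sample is the subset's
geometric-mean quantity, rescaled so the control group's mean NF is exactly
1; the score is the mean over non-control groups of |mean(1/NF) − 1|, with
the within-group CV of 1/NF as tie-break only. This is the simplest
declared statistic consistent with the "mean 1/NF close to 1" principle;
it is recomputable from the per-group columns the module writes. No
per-sample centering is applied before scoring — a combination is judged as
the normalizer one would actually divide by, which keeps the contamination
property (adding a treatment-responsive gene to a flat combination always
worsens its score) intact. The consequence for loading noise is discussed
under Limitations.

## Target-gene normalization

`RQ_s = E_target^(mean calibrator Ct − Ct_s)`; normalized fold
`= RQ_s / NF_s`, rescaled so the calibrator group's mean fold is exactly 1
(group-mean anchoring is less brittle than anchoring on a single sample).
Group summaries report mean fold ± SE (SD/√n, ddof = 1) over the samples
sharing a group label, treated as biological replicates. The non-normalized
RQ column is exported alongside for comparison.

## Synthetic data

The generator emulates a small qPCR screen. Latent log₂ expression:

    L[g,s] = β[g, group(s)] + λ[s] + ε[g,s]

with treatment effects β (zero for stable genes), per-sample loading
offsets λ ~ N(0, σ_loading²) shared by all genes, and gene noise
ε ~ N(0, σ_g²) — Normal on the log₂ scale, i.e. multiplicative on
quantity, the usual qPCR error structure (Ct-scale additive noise is not
modeled). Cycles: `Ct = C0_g − L·ln2/ln(E_g)`, with baselines C0 uniform on
[18, 30] cycles and efficiencies uniform on [1.85, 2.05] (both reflecting
typical assay ranges); the emitted efficiency table reports the true values
unless the mis-specification mode (`report_efficiency_as_two`) is on.

Defaults define the canonical recovery scenario the test bench uses:
3 stable genes (σ = 0.1 log₂ units), 3 mildly responsive (±1 log₂ shift in
one treatment group), 2 strongly responsive (±3), σ_loading = 0.5, and a
control plus two treatment groups with 3 biological replicates each. The
shift assignment spreads groups and signs (mild: −1, −1 in the first
treatment group, +1 in the second; strong: +3 in the first, −3 in the
second) for two reasons: a panel whose responsive genes all move together
is systematically co-regulated, which no stability algorithm can be
expected to resolve (co-regulated trios tie with the truly stable trio in
geNorm and distort the BestKeeper index); and no subset of ≤3 shifted genes
cancels exactly in a geometric mean, so no responsive combination is a
spuriously flat normalizer. Under these defaults each of the four per-gene
algorithms places the 3 stable genes in its top 4 in ≥99/100 seeds, a
fold-4 target normalized with the stable triple is recovered within ~0.2 on
average, and V_{2/3} < 0.15 in 100/100 seeds once stable-gene noise is
σ ≤ 0.05.

What the generator does **not** emulate: technical-replicate structure,
amplification-curve artifacts (primer dimers, plateau effects), inter-run
calibration, missing values, and Ct-scale (additive-cycle) noise. Passing
recovery tests therefore show the algorithms behave correctly under the
stated error model, not that any particular real panel is stable.

## Numerical choices and degenerate inputs

All SDs use ddof = 1. Geometric means are computed in log space. Ties in
score-based rankings are broken stably by input gene order and recorded
explicitly. Constant genes: ΔCt/geNorm handle them (their pair SDs are 0);
BestKeeper's r is undefined and ranks last with a warning. Exhaustive
aggregation refuses n > 8; combination enumeration refuses "all" for
n > 20. Pipeline outputs are byte-reproducible for a fixed seed (the
timestamp lives only in `run.json`).

## Limitations

* **Combination scores under loading noise.** The combination score is a
  function of group means of 1/NF, and per-sample loading does not cancel
  in it: between a treatment group and the control, the group-mean log₂ NF
  carries noise of SD σ_loading·√(2/n) regardless of which genes are in the
  combination (~0.41 log₂ units at the defaults), while one mildly
  responsive gene diluted into a size-3 combination shifts log₂ NF by only
  1/3. With few replicates the scan therefore cannot reliably single out
  the exactly-stable triple — at the defaults it does so in roughly 15 of
  100 seeds, and the recovery is only deterministic as σ_loading → 0 (the
  unit suite checks exact recovery at σ_loading = 0). Rankings by the
  per-gene algorithms, which work on pairwise ratios or centered residuals
  where loading cancels, are unaffected; and a combination picked by the
  scan still normalizes correctly (loading cancels sample-wise in
  RQ/NF). The practical reading: with 3 replicates per group the
  combination scan separates strongly responsive normalizers from flat
  ones, but fine distinctions below ~0.4 log₂ units are beyond its
  resolution.
* BestKeeper judges genes on raw Ct, so per-sample loading and per-gene
  abundance shift its SD/CV — an inherent property of the method, kept
  deliberately (documented exception to the invariance properties the
  other algorithms satisfy).
* The NormFinder-style SV combines bias and sampling error additively;
  it matches the published tool's behavior qualitatively, not bit-for-bit.
* The cross-entropy hyperparameters are package defaults; they are not
  claimed to reproduce any particular external aggregation tool's settings.
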
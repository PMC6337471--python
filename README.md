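# refstab

Reference-gene stability evaluation and multi-reference normalization for
qRT-PCR experiments.

Relative quantification by qRT-PCR reports a target gene's expression as a
fold change against one or more *reference* ("housekeeping") genes. If the
references themselves respond to the tissue or treatment under study, every
downstream fold change is biased — so candidate references must be screened
for stability first. `refstab` implements the six procedures commonly used
for that screen on a genes × samples table of quantification cycles (Ct),
with per-gene amplification efficiencies `E` (fold increase per cycle,
ideally 2):

| method | statistic | scale | orientation |
|---|---|---|---|
| comparative ΔCt | mSD — mean over partners of SD(Ct_i − Ct_k) | raw Ct | lower is stabler |
| BestKeeper | r — correlation with the per-sample geometric-mean index (SD/CV% reported) | raw Ct | higher r is stabler |
| geNorm | M — mean pairwise variation SD(log₂ Q_j/Q_k), iterative exclusion; V_{n/n+1} < 0.15 rule for the number of references | log₂ quantities | lower is stabler |
| NormFinder-style | SV — inter-group deviation + intra-group SE after per-sample centering | log₂ quantities | lower is stabler |
| rank aggregation | cross-entropy Monte-Carlo minimization of the total Spearman footrule distance to the four orderings | ranks | — |
| GrayNorm-style combination scan | mean over treatment groups of \|mean(1/NF) − 1\| for every gene subset's normalization factor | quantities | lower is stabler |

Quantities are efficiency-corrected, `Q[g,s] = E_g^(min_s' Ct[g,s'] − Ct[g,s])`,
and the normalization factor of a reference set is the per-sample geometric
mean of its quantities. Target genes are reported as
`E_target^(ΔCt vs calibrator) / NF`, rescaled so the calibrator group's mean
fold is 1.

A synthetic-data generator produces Ct panels with known ground truth
(stable genes, treatment-responsive genes, per-sample loading offsets,
per-gene efficiencies), so the whole pipeline is testable end to end. The
package also bundles, as a worked example, the published rank orderings of a
14-gene *Metasequoia glyptostroboides* candidate panel under four condition
sets.

## Worked example

Aggregate the four bundled tissue-panel orderings into a consensus:

```python
from refstab import aggregate_ce
from refstab.datasets import metasequoia_ranking_lists

lists = metasequoia_ranking_lists("tissue")   # ΔCt, BestKeeper, geNorm, NormFinder
res = aggregate_ce(lists, seed=0)
print(res.ranking[:3], res.objective)
```

prints

```
['AP-2', 'Cpn60β', 'elF-5A'] 54.0
```

— the three genes all four algorithms jointly place at the top of the
tissue panel, at a total footrule distance of 54 rank units from the four
input orderings.

The full pipeline on a synthetic screen:

```sh
refstab simulate --out sim --seed 1
refstab run --ct sim/ct.csv --samples sim/samples.csv --eff sim/eff.csv \
            --out results --combo-size 3 --seed 17
```

`results/` then holds one CSV per method (`delta_ct.csv`, `bestkeeper.csv`,
`genorm.csv` + exclusion trace + V curve, `normfinder.csv`), the consensus
ordering, the combination scan (`graynorm.csv`), a `summary.csv` with each
method's recommended 3-gene set, and a `run.json` log with the seed. For
the commands above the summary reads

```
method,genes
delta_ct,STB3+STB2+STB1
bestkeeper,STB2+STB3+STB1
normfinder,STB2+STB3+STB1
genorm,STB2+STB3+STB1
rank_aggreg,STB2+STB3+STB1
graynorm,STB2+STB3+UNS3
```

— the four per-gene rankings and their consensus all recover the three
simulated stable genes; the combination scan swaps one in this draw because
per-sample loading noise does not cancel in its group-mean score (see the
limitations section of `docs/methods.md`).

Pre-computed rank tables can be aggregated directly:

```sh
refstab aggregate --rankings rankings.csv --out consensus.csv --seed 1
```

where `rankings.csv` has one column per algorithm and one row per rank.

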
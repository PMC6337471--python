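"""End-to-end orchestration: Ct tables in, ranked result tables out.

The flow mirrors the standard reference-gene evaluation workflow:
quantities -> four per-gene stability algorithms -> consensus rank
aggregation -> geNorm V curve -> GrayNorm combination scan -> (optional)
target-gene normalization against the best combination.  Every stage's
table is written as CSV; a machine-readable run log records the seed and
configuration so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .ct_io import (
    QpcrValidationError,
    QPCRDataset,
    assemble_dataset,
    read_ct_table,
    read_efficiencies,
    read_sample_sheet,
    write_ranking_table,
)
from .graynorm import combination_table, graynorm_scan
from .normalization import normalization_factor, relative_expression
from .quantities import relative_quantities
from .rank_aggregation import ConsensusRanking, aggregate_ce, footrule_distance
from .stability import (
    BestKeeperResult,
    GenormResult,
    PairwiseVariationCurve,
    StabilityRanking,
    bestkeeper,
    delta_ct_msd,
    genorm,
    genorm_v_curve,
    normfinder,
)

logger = logging.getLogger("refstab")

ALL_ALGORITHMS = ("delta_ct", "bestkeeper", "normfinder", "genorm")


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on, in one reproducible object."""

    ct_path: str
    samples_path: str
    eff_path: str | None = None
    out_dir: str = "refstab_out"
    algorithms: tuple[str, ...] = ALL_ALGORITHMS
    bestkeeper_rank_key: str = "r"  # "r" | "sd" | "cv"
    genorm_threshold: float = 0.15
    m_cutoff: float = 1.5
    combo_size: int = 3
    target_genes: tuple[str, ...] = ()
    replicate_policy: str = "mean"
    drop_incomplete_samples: bool = False
    seed: int = 17
    ce_samples_per_iter: int | None = None
    ce_rho: float = 0.1
    ce_smoothing: float = 0.25
    ce_stagnation_limit: int = 15
    ce_max_iterations: int = 200

    def __post_init__(self) -> None:
        if self.genorm_threshold <= 0:
            raise QpcrValidationError("geNorm threshold must be > 0")
        if self.combo_size < 1:
            raise QpcrValidationError("combination size must be >= 1")
        bad = [a for a in self.algorithms if a not in ALL_ALGORITHMS]
        if bad:
            raise QpcrValidationError(f"unknown algorithms: {bad}")
        if len(self.algorithms) < 2:
            raise QpcrValidationError("need >=2 algorithms for a consensus")


@dataclass
class PipelineResult:
    config: PipelineConfig
    dataset: QPCRDataset
    rankings: dict[str, StabilityRanking]
    bestkeeper: BestKeeperResult | None
    genorm: GenormResult | None
    v_curve: PairwiseVariationCurve | None
    consensus: ConsensusRanking
    graynorm: list  # ranked CombinationScore list
    expression: dict[str, object] = field(default_factory=dict)
    files: dict[str, Path] = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full evaluation; writes result CSVs under ``config.out_dir``.

    On failure every file written so far is removed, so an output directory
    either holds a complete bundle or nothing from the failed run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, out, written)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _write(df: pd.DataFrame, path: Path, written: list[Path], **kw) -> Path:
    df.to_csv(path, index=False, float_format="%.6g", **kw)
    written.append(path)
    return path


def _run(config: PipelineConfig, out: Path, written: list[Path]) -> PipelineResult:
    t0 = time.time()
    ct = read_ct_table(
        config.ct_path,
        replicate_policy=config.replicate_policy,
        drop_incomplete_samples=config.drop_incomplete_samples,
    )
    sheet = read_sample_sheet(config.samples_path)
    eff = read_efficiencies(config.eff_path, genes=ct.gene_ids)
    ds = assemble_dataset(ct, sheet, eff)

    candidates = [g for g in ct.gene_ids if g not in set(config.target_genes)]
    missing_targets = [g for g in config.target_genes if g not in ct.gene_ids]
    if missing_targets:
        raise QpcrValidationError(f"target genes absent from Ct matrix: {missing_targets}")
    ct_ref = ct.subset_genes(candidates)
    q_all = relative_quantities(ct, eff)
    q_ref = q_all.subset_genes(candidates)
    logger.info("loaded %d candidate genes x %d samples", len(candidates), ct.n_samples)

    rankings: dict[str, StabilityRanking] = {}
    bk_result: BestKeeperResult | None = None
    gn_result: GenormResult | None = None
    files: dict[str, Path] = {}

    if "delta_ct" in config.algorithms:
        rankings["delta_ct"] = delta_ct_msd(ct_ref)
        files["delta_ct"] = out / "delta_ct.csv"
        write_ranking_table(rankings["delta_ct"], files["delta_ct"])
        written.append(files["delta_ct"])
    if "bestkeeper" in config.algorithms:
        bk_result = bestkeeper(ct_ref)
        rankings["bestkeeper"] = bk_result.ranking_by(config.bestkeeper_rank_key)
        stats = bk_result.stats.rename_axis("gene").reset_index()
        files["bestkeeper"] = _write(stats, out / "bestkeeper.csv", written)
    if "normfinder" in config.algorithms:
        rankings["normfinder"] = normfinder(q_ref, sheet)
        files["normfinder"] = out / "normfinder.csv"
        write_ranking_table(rankings["normfinder"], files["normfinder"])
        written.append(files["normfinder"])
    v_curve: PairwiseVariationCurve | None = None
    if "genorm" in config.algorithms:
        gn_result = genorm(q_ref)
        rankings["genorm"] = gn_result.ranking
        files["genorm"] = out / "genorm.csv"
        write_ranking_table(rankings["genorm"], files["genorm"])
        written.append(files["genorm"])
        files["genorm_trace"] = _write(gn_result.trace, out / "genorm_trace.csv", written)
        v_curve = genorm_v_curve(q_ref, gn_result.ranking, config.genorm_threshold)
        vdf = v_curve.v.rename_axis("n").reset_index()
        files["genorm_v"] = _write(vdf, out / "genorm_v.csv", written)

    lists = [rankings[a].ranking for a in config.algorithms if a in rankings]
    consensus = aggregate_ce(
        lists,
        seed=config.seed,
        samples_per_iter=config.ce_samples_per_iter,
        rho=config.ce_rho,
        smoothing=config.ce_smoothing,
        stagnation_limit=config.ce_stagnation_limit,
        max_iterations=config.ce_max_iterations,
    )
    cdf = pd.DataFrame(
        {"rank": range(1, len(consensus.ranking) + 1), "gene": consensus.ranking}
    )
    files["consensus"] = _write(cdf, out / "consensus.csv", written)

    combos = graynorm_scan(q_ref, sheet, size=config.combo_size)
    files["graynorm"] = _write(combination_table(combos), out / "graynorm.csv", written)

    expression: dict[str, object] = {}
    if config.target_genes:
        refs = list(combos[0].genes)
        nf = normalization_factor(q_ref, refs, sheet)
        rows = []
        summaries = []
        for target in config.target_genes:
            rel = relative_expression(ct, target, eff, nf, sheet)
            expression[target] = rel
            for s in rel.fold.index:
                rows.append(
                    {
                        "target": target,
                        "sample": s,
                        "fold": rel.fold[s],
                        "non_normalized_rq": rel.raw_rq[s],
                    }
                )
            summaries.append(rel.summary.assign(target=target))
        files["expression"] = _write(pd.DataFrame(rows), out / "expression.csv", written)
        files["expression_summary"] = _write(
            pd.concat(summaries, ignore_index=True)[
                ["target", "group", "mean_fold", "se", "n"]
            ],
            out / "expression_summary.csv",
            written,
        )

    result = PipelineResult(
        config=config,
        dataset=ds,
        rankings=rankings,
        bestkeeper=bk_result,
        genorm=gn_result,
        v_curve=v_curve,
        consensus=consensus,
        graynorm=combos,
        expression=expression,
        files=files,
    )
    files["summary"] = _write(
        consensus_report(result), out / "summary.csv", written
    )

    log = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "n_candidate_genes": len(candidates),
        "n_samples": ct.n_samples,
        "algorithms": list(rankings),
        "consensus_objective": consensus.objective,
        "consensus_iterations": consensus.n_iterations,
        "recommended_n_references": None if v_curve is None else v_curve.recommended_n,
        "elapsed_seconds": round(time.time() - t0, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    run_log = out / "run.json"
    with open(run_log, "w") as fh:
        json.dump(log, fh, indent=2)
    written.append(run_log)
    files["run_log"] = run_log
    logger.info("pipeline finished in %.2fs; results in %s", log["elapsed_seconds"], out)
    return result


def consensus_report(result: PipelineResult, k: int | None = None) -> pd.DataFrame:
    """One row per method with its recommended top-k genes/combination."""
    k = result.config.combo_size if k is None else k
    rows = []
    for alg in result.config.algorithms:
        if alg in result.rankings:
            rows.append(
                {"method": alg, "genes": "+".join(result.rankings[alg].top(k))}
            )
    rows.append({"method": "rank_aggreg", "genes": "+".join(result.consensus.ranking[:k])})
    if result.graynorm:
        rows.append({"method": "graynorm", "genes": result.graynorm[0].label})
    return pd.DataFrame(rows, columns=["method", "genes"])


def aggregate_rankings_file(
    rankings_csv: str | Path,
    seed: int | None = None,
    weights: Sequence[float] | None = None,
    **ce_kwargs,
) -> tuple[ConsensusRanking, pd.DataFrame]:
    """Standalone aggregation of pre-computed rank lists.

    ``rankings_csv``: columns = algorithm names, rows = rank positions,
    cells = gene ids (exactly the shape of a published ranking table's rank
    columns).  Returns the consensus plus a per-method rank table including
    the consensus column, with the recomputed footrule objective attached.
    """
    df = pd.read_csv(rankings_csv, dtype=str)
    if "rank" in {c.lower() for c in df.columns}:
        df = df.drop(columns=[c for c in df.columns if c.lower() == "rank"])
    lists = [list(df[c]) for c in df.columns]
    consensus = aggregate_ce(lists, weights=weights, seed=seed, **ce_kwargs)
    check = sum(footrule_distance(consensus.ranking, l) for l in lists)
    if weights is None and abs(check - consensus.objective) > 1e-9:
        raise AssertionError("consensus objective does not recompute")  # pragma: no cover
    out = df.copy()
    out["consensus"] = consensus.ranking
    return consensus, out
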
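"""Per-gene reference-gene stability algorithms.

Four classic procedures, each producing a :class:`StabilityRanking` so that
their orderings can be compared and aggregated:

* **comparative ΔCt** — for every gene pair, the SD over samples of their Ct
  difference; a gene's mSD is the mean of its pairwise SDs.  Operates on raw
  Ct, lower is stabler.
* **BestKeeper** — descriptive statistics on raw Ct (mean, SD as mean
  absolute deviation, CV%) plus the correlation r of each gene with the
  BestKeeper index (per-sample geometric mean Ct of all candidates).  Genes
  are ranked by descending r.
* **geNorm** — on log2 efficiency-corrected quantities, a gene's M value is
  its mean pairwise variation (SD of the log2 expression ratio) with all
  other candidates; the worst gene is excluded and M recomputed until two
  remain.  Lower M is stabler; M >= 1.5 flags a gene as unusable.
* **NormFinder-style variance decomposition** — after removing per-sample
  loading (centering each sample by its across-gene mean of log2
  quantities), a gene's stability value combines its inter-group deviation
  and intra-group sampling error; ungrouped data fall back to the corrected
  SD of the residuals.

ΔCt and BestKeeper deliberately stay on the Ct scale and geNorm/NormFinder
on log2 quantities, matching each method's original definition.  With all
E = 2 the ΔCt mSD and the full-panel geNorm M coincide exactly, since
SD(log2(Q_j/Q_k)) = SD(Ct_k - Ct_j).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ct_io import CtMatrix, QpcrValidationError, SampleSheet
from .quantities import QuantityMatrix

__all__ = [
    "StabilityRanking",
    "BestKeeperResult",
    "GenormResult",
    "PairwiseVariationCurve",
    "delta_ct_msd",
    "bestkeeper",
    "genorm",
    "genorm_v_curve",
    "normfinder",
]

#: geNorm's published cutoff: a gene with M at or above this is unstable.
GENORM_M_CUTOFF = 1.5


@dataclass
class StabilityRanking:
    """One algorithm's per-gene scores and the implied ordering.

    ``ranking`` orders genes most stable first and is consistent with
    ``scores`` under ``orientation`` up to the tie groups listed in
    ``ties``; NaN scores (undefined, e.g. zero-variance BestKeeper r)
    sort last.
    """

    algorithm: str
    scores: pd.Series
    orientation: str  # "lower_is_stabler" | "higher_is_stabler"
    ranking: list[str]
    ties: list[tuple[str, ...]] = field(default_factory=list)
    score_label: str = "score"

    def __post_init__(self) -> None:
        if self.orientation not in {"lower_is_stabler", "higher_is_stabler"}:
            raise ValueError(f"bad orientation {self.orientation!r}")
        if sorted(self.ranking) != sorted(self.scores.index):
            raise ValueError("ranking is not a permutation of the gene universe")

    def position(self, gene: str) -> int:
        """1-based rank of ``gene`` (most stable = 1)."""
        return self.ranking.index(gene) + 1

    def top(self, k: int) -> list[str]:
        return self.ranking[:k]


def _rank_from_scores(
    scores: pd.Series, orientation: str, algorithm: str, score_label: str
) -> StabilityRanking:
    key = scores.to_numpy(dtype=float).copy()
    if orientation == "higher_is_stabler":
        key = -key
    key[np.isnan(key)] = np.inf  # undefined scores rank last
    order = np.argsort(key, kind="stable")
    ranking = [scores.index[i] for i in order]
    ties = []
    for val in np.unique(key[np.isfinite(key)]):
        members = [scores.index[i] for i in np.flatnonzero(key == val)]
        if len(members) > 1:
            ties.append(tuple(members))
    return StabilityRanking(
        algorithm=algorithm,
        scores=scores,
        orientation=orientation,
        ranking=ranking,
        ties=ties,
        score_label=score_label,
    )


def _pairwise_sd(x: np.ndarray) -> np.ndarray:
    """SD over samples (ddof=1) of x_i - x_k for every ordered gene pair."""
    diffs = x[:, None, :] - x[None, :, :]
    return diffs.std(axis=2, ddof=1)


def delta_ct_msd(ct: CtMatrix) -> StabilityRanking:
    """Comparative ΔCt: mSD_i = mean over partners k of SD_s(Ct_i - Ct_k)."""
    if ct.n_genes < 2 or ct.n_samples < 2:
        raise QpcrValidationError("ΔCt needs >=2 genes and >=2 samples")
    sd = _pairwise_sd(ct.values)
    g = ct.n_genes
    msd = (sd.sum(axis=1)) / (g - 1)  # diagonal is 0
    scores = pd.Series(msd, index=ct.gene_ids, name="mSD")
    return _rank_from_scores(scores, "lower_is_stabler", "delta_ct", "mSD")


@dataclass
class BestKeeperResult:
    """BestKeeper ranking (by r) plus the full descriptive-statistics table."""

    ranking: StabilityRanking
    stats: pd.DataFrame  # columns: AM, SD, CV, r
    index: pd.Series  # per-sample BestKeeper index (geometric mean Ct)

    def ranking_by(self, key: str) -> StabilityRanking:
        """Alternative ranking by ``"r"`` (descending) or ``"sd"``/``"cv"``."""
        key = key.lower()
        if key == "r":
            return self.ranking
        if key not in {"sd", "cv"}:
            raise ValueError(f"unknown BestKeeper ranking key {key!r}")
        col = key.upper()
        scores = self.stats[col].rename(col)
        return _rank_from_scores(scores, "lower_is_stabler", "bestkeeper", col)


def bestkeeper(
    ct: CtMatrix, sd_mode: str = "mad", sd_filter: float | None = None
) -> BestKeeperResult:
    """BestKeeper descriptive statistics and index correlations on raw Ct.

    Parameters
    ----------
    sd_mode :
        ``"mad"`` (default) uses the mean absolute deviation from the mean,
        BestKeeper's original "SD"; ``"classic"`` uses the sample SD
        (ddof=1).
    sd_filter :
        If given, genes with SD above this value are excluded from the
        index computation (they are still scored against it).  By default
        every candidate contributes to the index.
    """
    if ct.n_genes < 2 or ct.n_samples < 3:
        raise QpcrValidationError("BestKeeper needs >=2 genes and >=3 samples")
    if sd_mode not in {"mad", "classic"}:
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    x = ct.values
    am = x.mean(axis=1)
    if sd_mode == "mad":
        sd = np.abs(x - am[:, None]).mean(axis=1)
    else:
        sd = x.std(axis=1, ddof=1)
    cv = 100.0 * sd / am

    in_index = np.ones(ct.n_genes, dtype=bool)
    if sd_filter is not None:
        in_index = sd <= sd_filter
        if not in_index.any():
            raise QpcrValidationError("sd_filter excluded every gene from the index")
    index = np.exp(np.log(x[in_index]).mean(axis=0))

    r = np.full(ct.n_genes, np.nan)
    idx_centered = index - index.mean()
    idx_ss = float(idx_centered @ idx_centered)
    for i in range(ct.n_genes):
        xi = x[i] - x[i].mean()
        ss = float(xi @ xi)
        if ss <= 0 or idx_ss <= 0:
            warnings.warn(
                f"BestKeeper r undefined for constant gene {ct.gene_ids[i]!r}; "
                "ranked last",
                stacklevel=2,
            )
            continue
        r[i] = float(xi @ idx_centered) / np.sqrt(ss * idx_ss)

    stats = pd.DataFrame(
        {"AM": am, "SD": sd, "CV": cv, "r": r}, index=ct.gene_ids
    )
    scores = stats["r"].rename("r")
    ranking = _rank_from_scores(scores, "higher_is_stabler", "bestkeeper", "r")
    return BestKeeperResult(
        ranking=ranking,
        stats=stats,
        index=pd.Series(index, index=ct.sample_ids, name="bestkeeper_index"),
    )


@dataclass
class GenormResult:
    """geNorm ranking, stepwise exclusion trace, and full-panel M values."""

    ranking: StabilityRanking
    trace: pd.DataFrame  # step, n_genes, removed_gene, m_at_removal, tied_with
    initial_m: pd.Series  # full-panel M before any exclusion
    unstable: list[str]  # genes whose reported M >= GENORM_M_CUTOFF


def _genorm_m(l2: np.ndarray) -> np.ndarray:
    """M_j = mean over k != j of SD_s(log2 Q_j - log2 Q_k)."""
    v = _pairwise_sd(l2)
    g = l2.shape[0]
    return v.sum(axis=1) / (g - 1)


def genorm(q: QuantityMatrix) -> GenormResult:
    """Iterative geNorm exclusion on log2 quantities.

    The gene with the highest M is removed and M recomputed until two genes
    remain; those two are tied at ranks 1-2 (geNorm cannot order them — their
    M values are identical by construction).  Each gene's reported score is
    its M at the step of its removal; ties on equal M are broken by removing
    the later gene in input order, and recorded in the trace.
    """
    genes = q.gene_ids
    g = len(genes)
    if g < 3:
        raise QpcrValidationError("geNorm needs >=3 candidate genes")
    if len(q.sample_ids) < 2:
        raise QpcrValidationError("geNorm needs >=2 samples")
    l2 = q.log2q.to_numpy()
    initial_m = pd.Series(_genorm_m(l2), index=genes, name="M")

    remaining = list(range(g))
    removal_order: list[int] = []
    scores = {}
    rows = []
    step = 0
    while len(remaining) > 2:
        sub = l2[remaining]
        m = _genorm_m(sub)
        worst_val = m.max()
        tied_local = np.flatnonzero(m == worst_val)
        # later in input order = largest original index among ties
        worst_local = int(tied_local[np.argmax([remaining[i] for i in tied_local])])
        worst = remaining[worst_local]
        scores[genes[worst]] = float(worst_val)
        tied_with = (
            tuple(genes[remaining[i]] for i in tied_local if remaining[i] != worst)
            if len(tied_local) > 1
            else ()
        )
        rows.append(
            {
                "step": step,
                "n_genes": len(remaining),
                "removed_gene": genes[worst],
                "m_at_removal": float(worst_val),
                "tied_with": "|".join(tied_with),
            }
        )
        removal_order.append(worst)
        remaining.remove(worst)
        step += 1

    a, b = remaining  # in input order
    final_v = float(
        np.std(l2[a] - l2[b], ddof=1)
    )  # their mutual V == each one's M on the final pair
    scores[genes[a]] = final_v
    scores[genes[b]] = final_v

    ranking_idx = [a, b] + list(reversed(removal_order))
    ranking = [genes[i] for i in ranking_idx]
    score_ser = pd.Series({g_: scores[g_] for g_ in genes}, name="M").reindex(genes)
    ties = [(genes[a], genes[b])]
    for row in rows:
        if row["tied_with"]:
            ties.append(tuple([row["removed_gene"], *row["tied_with"].split("|")]))
    sr = StabilityRanking(
        algorithm="genorm",
        scores=score_ser,
        orientation="lower_is_stabler",
        ranking=ranking,
        ties=ties,
        score_label="M",
    )
    unstable = [g_ for g_ in genes if scores[g_] >= GENORM_M_CUTOFF]
    trace = pd.DataFrame(
        rows, columns=["step", "n_genes", "removed_gene", "m_at_removal", "tied_with"]
    )
    return GenormResult(ranking=sr, trace=trace, initial_m=initial_m, unstable=unstable)


@dataclass
class PairwiseVariationCurve:
    """geNorm V_{n/n+1} values and the recommended number of references.

    ``recommended_n`` is the smallest n whose V falls below ``threshold``;
    if none does, it is set to N-1 and ``none_below_threshold`` flags it.
    """

    v: pd.Series  # index n = 2..N-1, value V_{n/n+1}
    recommended_n: int
    threshold: float
    none_below_threshold: bool = False


def genorm_v_curve(
    q: QuantityMatrix, ranking: StabilityRanking, threshold: float = 0.15
) -> PairwiseVariationCurve:
    """Pairwise variation between normalization factors of n and n+1 genes.

    NF_n is the per-sample geometric mean quantity of the n most stable
    genes (per ``ranking``); V_{n/n+1} = SD over samples of
    log2(NF_n / NF_{n+1}).  The published rule of thumb: the smallest n
    with V below 0.15 is enough references.
    """
    genes = ranking.ranking
    n_total = len(genes)
    if n_total < 3:
        raise QpcrValidationError("V curve needs >=3 genes")
    l2 = q.log2q.loc[genes].to_numpy()
    # log2 NF_n = mean of the top-n genes' log2 quantities
    cum = np.cumsum(l2, axis=0)
    vs = {}
    for n in range(2, n_total):
        log_nf_n = cum[n - 1] / n
        log_nf_n1 = cum[n] / (n + 1)
        vs[n] = float(np.std(log_nf_n - log_nf_n1, ddof=1))
    v = pd.Series(vs, name="V")
    below = v[v < threshold]
    if below.empty:
        return PairwiseVariationCurve(
            v=v, recommended_n=n_total - 1, threshold=threshold, none_below_threshold=True
        )
    return PairwiseVariationCurve(
        v=v, recommended_n=int(below.index[0]), threshold=threshold
    )


def normfinder(
    q: QuantityMatrix, sheet: SampleSheet | None = None
) -> StabilityRanking:
    """Model-based stability value on sample-centered log2 quantities.

    Each sample is first centered by its across-gene mean, removing the
    per-sample loading term shared by all genes.  With group structure
    (>=2 groups, each with >=3 samples) a gene's stability value averages,
    over groups, the magnitude of its inter-group deviation plus the
    standard error of its intra-group variation:

        SV_i = mean_g( |z_ig| + sqrt(s2_ig / n_g) )

    where z_ig is the gene x group interaction (group mean of the residuals,
    centered across groups, scaled by G/(G-1) to undo the contamination the
    across-gene centering introduces) and s2_ig the intra-group variance
    (ddof=1).  Without groups, SV_i is the SD of the gene's residuals with
    the analogous sqrt(G/(G-1)) correction.  Lower is stabler.
    """
    genes = q.gene_ids
    g = len(genes)
    if g < 3:
        raise QpcrValidationError("NormFinder needs >=3 candidate genes")
    l2 = q.log2q.to_numpy()
    y = l2 - l2.mean(axis=0, keepdims=True)  # remove per-sample loading

    groups: list[list[int]] = []
    if sheet is not None:
        order = {s: i for i, s in enumerate(q.sample_ids)}
        for grp in sheet.groups:
            members = [order[s] for s in sheet.samples_in(grp) if s in order]
            if members:
                groups.append(members)
        for grp, members in zip(sheet.groups, groups):
            if len(members) <= 2:
                raise QpcrValidationError(
                    f"NormFinder needs more than two samples per group; "
                    f"group {grp!r} has {len(members)}"
                )

    if sheet is None or len(groups) < 2:
        if y.shape[1] < 2:
            raise QpcrValidationError("NormFinder needs >=2 samples")
        sv = y.std(axis=1, ddof=1) * np.sqrt(g / (g - 1))
    else:
        n_groups = len(groups)
        means = np.stack([y[:, m].mean(axis=1) for m in groups], axis=1)  # g x G
        s2 = np.stack(
            [y[:, m].var(axis=1, ddof=1) for m in groups], axis=1
        )
        ng = np.array([len(m) for m in groups], dtype=float)
        z = (means - means.mean(axis=1, keepdims=True)) * (g / (g - 1))
        sv = (np.abs(z) + np.sqrt(s2 / ng[None, :])).mean(axis=1)

    scores = pd.Series(sv, index=genes, name="SV")
    return _rank_from_scores(scores, "lower_is_stabler", "normfinder", "SV")
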
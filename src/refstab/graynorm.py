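"""Combination scoring of candidate reference-gene sets (GrayNorm-style).

Instead of ranking genes one by one, every subset of the candidate panel is
scored as a normalization factor: NF per sample is the geometric mean of
the subset's relative quantities, rescaled so the control group's mean NF
is exactly 1.  A combination is good when each treatment group's mean 1/NF
stays close to 1.0 — i.e. the normalizer does not itself respond to the
treatment.  With n candidates there are 2**n - 1 non-empty combinations.

The primary score is the mean over non-control groups of
``|mean(1/NF) - 1|``; the CV of 1/NF within groups breaks ties.  This is
the simplest statistic consistent with the "mean 1/NF close to 1.0"
principle and it is recomputable from the per-group columns this module
reports.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ct_io import QpcrValidationError, SampleSheet
from .quantities import QuantityMatrix

__all__ = [
    "CombinationScore",
    "enumerate_combinations",
    "graynorm_score",
    "rank_combinations",
    "graynorm_scan",
    "combination_table",
]

#: 2**n - 1 grows fast; refuse full enumeration beyond this panel size.
MAX_ALL_GENES = 20


@dataclass
class CombinationScore:
    """A reference-gene subset with per-group 1/NF statistics.

    ``per_group`` maps group -> (mean of 1/NF, CV of 1/NF); the score is
    the mean over non-control groups of |mean_inv_nf - 1| after the control
    group's mean NF has been rescaled to exactly 1.
    """

    genes: tuple[str, ...]
    per_group: dict[str, tuple[float, float]]
    score: float
    control_group: str

    @property
    def mean_cv(self) -> float:
        """Mean CV of 1/NF across all groups (tie-break statistic)."""
        return float(np.mean([cv for _, cv in self.per_group.values()]))

    @property
    def label(self) -> str:
        return "+".join(self.genes)


def enumerate_combinations(
    genes: Sequence[str], size: int | str = "all"
) -> list[tuple[str, ...]]:
    """All non-empty subsets ("all") or all subsets of a fixed size.

    Deterministic order: by subset size, then lexicographic in the input
    gene order (the order :func:`itertools.combinations` yields).
    """
    genes = list(genes)
    n = len(genes)
    if n < 1:
        raise QpcrValidationError("need at least one candidate gene")
    if size == "all":
        if n > MAX_ALL_GENES:
            raise QpcrValidationError(
                f"2**{n}-1 combinations is too many; pass an explicit size"
            )
        sizes = range(1, n + 1)
    else:
        k = int(size)
        if k < 1 or k > n:
            raise QpcrValidationError(f"combination size {k} out of range 1..{n}")
        sizes = (k,)
    out: list[tuple[str, ...]] = []
    for k in sizes:
        out.extend(itertools.combinations(genes, k))
    return out


def graynorm_score(
    q: QuantityMatrix, sheet: SampleSheet, combo: Sequence[str]
) -> CombinationScore:
    """Score one reference-gene combination against the control group."""
    combo = tuple(combo)
    if not combo:
        raise QpcrValidationError("empty combination")
    missing = [g for g in combo if g not in q.q.index]
    if missing:
        raise QpcrValidationError(f"combination genes absent from quantities: {missing}")
    control = sheet.require_control()
    groups = sheet.groups
    if len(groups) < 2:
        raise QpcrValidationError("GrayNorm needs at least one non-control group")

    log_nf = q.log2q.loc[list(combo)].mean(axis=0)  # log2 geometric mean
    nf = np.power(2.0, log_nf)
    ctrl_samples = sheet.samples_in(control)
    scale = nf.loc[ctrl_samples].mean()
    nf = nf / scale  # control group's mean NF is exactly 1
    inv = 1.0 / nf

    per_group: dict[str, tuple[float, float]] = {}
    devs = []
    for grp in groups:
        vals = inv.loc[sheet.samples_in(grp)].to_numpy()
        m = float(vals.mean())
        cv = float(vals.std(ddof=1) / m) if len(vals) > 1 else 0.0
        per_group[grp] = (m, cv)
        if grp != control:
            devs.append(abs(m - 1.0))
    return CombinationScore(
        genes=combo,
        per_group=per_group,
        score=float(np.mean(devs)),
        control_group=control,
    )


def rank_combinations(
    scores: Sequence[CombinationScore], top_k: int | None = None
) -> list[CombinationScore]:
    """Ascending by score, ties by ascending mean CV of 1/NF.

    The sort is stable, so combinations that remain tied keep the
    deterministic enumeration order (by size, then lexicographic in input
    gene order).
    """
    if not scores:
        raise QpcrValidationError("no combination scores to rank")
    ordered = sorted(scores, key=lambda c: (c.score, c.mean_cv))
    return ordered if top_k is None else ordered[:top_k]


def graynorm_scan(
    q: QuantityMatrix,
    sheet: SampleSheet,
    size: int | str = 3,
    top_k: int | None = None,
    genes: Sequence[str] | None = None,
) -> list[CombinationScore]:
    """Score and rank every combination of the candidate panel."""
    genes = list(q.gene_ids) if genes is None else list(genes)
    combos = enumerate_combinations(genes, size)
    return rank_combinations([graynorm_score(q, sheet, c) for c in combos], top_k)


def combination_table(scores: Sequence[CombinationScore]) -> pd.DataFrame:
    """Flatten scored combinations into a result table (one row per combo)."""
    if not scores:
        raise QpcrValidationError("no combination scores")
    groups = list(scores[0].per_group)
    rows = []
    for c in scores:
        row: dict[str, object] = {"genes": c.label, "size": len(c.genes), "score": c.score}
        for grp in groups:
            m, cv = c.per_group[grp]
            row[f"mean_inv_nf_{grp}"] = m
            row[f"cv_inv_nf_{grp}"] = cv
        rows.append(row)
    return pd.DataFrame(rows)
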
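"""Multi-reference normalization of target-gene expression.

The normalization factor (NF) for a sample is the geometric mean of the
chosen reference genes' relative quantities; a target's efficiency-
corrected quantity divided by the NF gives its normalized fold change
relative to the calibrator (control) group.  Folds are rescaled so the
calibrator group's *mean* fold is exactly 1 — group-mean anchoring is more
robust than anchoring on a single sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ct_io import CtMatrix, EfficiencyTable, QpcrValidationError, SampleSheet
from .quantities import QuantityMatrix

__all__ = ["RelativeExpression", "normalization_factor", "relative_expression"]


@dataclass
class RelativeExpression:
    """Normalized expression of one target gene.

    ``fold`` is the per-sample normalized relative quantity (calibrator
    group mean = 1); ``raw_rq`` is the non-normalized efficiency-corrected
    quantity anchored on the calibrator mean Ct; ``summary`` has one row
    per group with mean fold, standard error (SD/sqrt(n), ddof=1), and n.
    """

    target: str
    fold: pd.Series
    raw_rq: pd.Series
    summary: pd.DataFrame


def normalization_factor(
    q: QuantityMatrix, refs, sheet: SampleSheet
) -> pd.Series:
    """Per-sample NF = geometric mean of reference quantities.

    Rescaled so the calibrator (control) group's mean NF is exactly 1.
    """
    refs = list(refs)
    if not refs:
        raise QpcrValidationError("reference set is empty")
    missing = [g for g in refs if g not in q.q.index]
    if missing:
        raise QpcrValidationError(f"reference genes absent from quantities: {missing}")
    control = sheet.require_control()
    log_nf = q.log2q.loc[refs].mean(axis=0)
    nf = np.power(2.0, log_nf)
    ctrl = sheet.samples_in(control)
    if not ctrl:
        raise QpcrValidationError("calibrator group has no samples")
    nf = nf / nf.loc[ctrl].mean()
    return nf.rename("NF")


def relative_expression(
    ct: CtMatrix,
    target: str,
    eff: EfficiencyTable,
    nf: pd.Series,
    sheet: SampleSheet,
) -> RelativeExpression:
    """Efficiency-corrected, NF-normalized fold change of a target gene.

    RQ_s = E_target**(mean calibrator Ct - Ct_s); fold_s = RQ_s / NF_s,
    rescaled so the calibrator group's mean fold is 1.  Biological
    replicates are the samples sharing a group label; the per-group summary
    reports mean fold +/- SE over them.
    """
    if target not in ct.ct.index:
        raise QpcrValidationError(f"target gene {target!r} not in Ct matrix")
    control = sheet.require_control()
    ctrl = sheet.samples_in(control)
    if not ctrl:
        raise QpcrValidationError("calibrator group has no samples")
    ct_t = ct.ct.loc[target]
    missing = [s for s in ct_t.index if s not in nf.index]
    if missing:
        raise QpcrValidationError(f"NF missing for samples: {missing}")
    e = eff.for_gene(target)
    rq = np.power(e, ct_t.loc[ctrl].mean() - ct_t)
    fold = rq / nf.loc[rq.index]
    fold = fold / fold.loc[ctrl].mean()

    rows = []
    for grp in sheet.groups:
        vals = fold.loc[sheet.samples_in(grp)].to_numpy()
        n = len(vals)
        se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        rows.append(
            {"group": grp, "mean_fold": float(vals.mean()), "se": se, "n": n}
        )
    summary = pd.DataFrame(rows, columns=["group", "mean_fold", "se", "n"])
    return RelativeExpression(
        target=target,
        fold=fold.rename("fold"),
        raw_rq=rq.rename("raw_rq"),
        summary=summary,
    )
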
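"""Efficiency-corrected relative quantities and standard-curve efficiencies.

A Ct difference of d cycles corresponds to an E**d fold difference in
starting template, where E is the gene's amplification efficiency (2 for
perfect doubling).  Quantities here are anchored per gene at the sample
with the minimum Ct (the most template), so Q = E**(Ct_min - Ct) lies in
(0, 1] with max exactly 1 — the geNorm-style convention.  Calibrator-
anchored quantities for fold-change reporting live in
:mod:`refstab.normalization`.

Efficiencies come from a dilution series: Ct regressed on log10 input has
slope -1/log10(E), hence E = 10**(-1/slope).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ct_io import CtMatrix, EfficiencyTable, QpcrValidationError

__all__ = [
    "QuantityMatrix",
    "DilutionSeries",
    "DilutionFit",
    "relative_quantities",
    "efficiency_from_dilution",
    "log_transform",
    "read_dilution_series",
]


@dataclass
class QuantityMatrix:
    """Relative quantities Q (max 1 per gene) and their log2."""

    q: pd.DataFrame
    log2q: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.q.to_numpy() <= 0).any():
            raise QpcrValidationError("relative quantities must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.q.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.q.columns)

    def subset_genes(self, genes: Sequence[str]) -> "QuantityMatrix":
        missing = [g for g in genes if g not in self.q.index]
        if missing:
            raise QpcrValidationError(f"genes not in quantity matrix: {missing}")
        return QuantityMatrix(self.q.loc[list(genes)], self.log2q.loc[list(genes)])


@dataclass
class DilutionSeries:
    """One gene's standard curve: (log10 relative input, mean Ct) points."""

    gene_id: str
    points: Sequence[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise QpcrValidationError(
                f"dilution series for {self.gene_id!r} needs >=3 points, "
                f"got {len(self.points)}"
            )
        x = np.array([p[0] for p in self.points], dtype=float)
        dx = np.diff(x)
        if not ((dx > 0).all() or (dx < 0).all()):
            raise QpcrValidationError(
                f"log10 inputs for {self.gene_id!r} must be strictly monotone"
            )

    @property
    def log10_inputs(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=float)

    @property
    def ct(self) -> np.ndarray:
        return np.array([p[1] for p in self.points], dtype=float)


@dataclass
class DilutionFit:
    gene_id: str
    slope: float  # cycles per log10 input
    intercept: float
    efficiency: float  # E = 10**(-1/slope)
    r_squared: float


def relative_quantities(
    ct: CtMatrix, eff: EfficiencyTable | None = None
) -> QuantityMatrix:
    """Q[g, s] = E_g ** (min_s' Ct[g, s'] - Ct[g, s]).

    The per-gene maximum is exactly 1 (attained at the minimum-Ct sample);
    with all E = 2 this is the familiar 2**(-dCt) expression measure.
    """
    if eff is None:
        eff = EfficiencyTable.uniform(ct.gene_ids)
    e = eff.for_genes(ct.gene_ids).to_numpy()[:, None]
    x = ct.values
    dct = x.min(axis=1, keepdims=True) - x
    q = e**dct
    log2q = dct * np.log2(e)
    qdf = pd.DataFrame(q, index=ct.gene_ids, columns=ct.sample_ids)
    ldf = pd.DataFrame(log2q, index=ct.gene_ids, columns=ct.sample_ids)
    return QuantityMatrix(qdf, ldf)


def log_transform(qm: QuantityMatrix) -> QuantityMatrix:
    """Return ``qm`` with log2q recomputed from q (idempotent)."""
    q = qm.q.to_numpy()
    if (q <= 0).any():
        raise QpcrValidationError("cannot log-transform non-positive quantities")
    return QuantityMatrix(qm.q, pd.DataFrame(np.log2(q), index=qm.q.index, columns=qm.q.columns))


def efficiency_from_dilution(series: DilutionSeries) -> DilutionFit:
    """OLS fit of Ct vs log10 input; E = 10**(-1/slope).

    A non-negative slope means Ct does not decrease with template input,
    i.e. the assay did not amplify — that is an error, not a fit.
    """
    res = stats.linregress(series.log10_inputs, series.ct)
    if res.slope >= 0:
        raise QpcrValidationError(
            f"dilution series for {series.gene_id!r} has slope "
            f"{res.slope:.4g} >= 0 (no amplification)"
        )
    e = 10.0 ** (-1.0 / res.slope)
    return DilutionFit(
        gene_id=series.gene_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        efficiency=float(e),
        r_squared=float(res.rvalue**2),
    )


def read_dilution_series(path: str | Path) -> list[DilutionSeries]:
    """Read long-format ``gene,log10_input,ct`` into per-gene series."""
    df = pd.read_csv(path, dtype={"gene": str})
    needed = {"gene", "log10_input", "ct"}
    missing = needed - set(df.columns)
    if missing:
        raise QpcrValidationError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for gene, sub in df.groupby("gene", sort=False):
        pts = list(zip(sub["log10_input"].astype(float), sub["ct"].astype(float)))
        out.append(DilutionSeries(gene_id=str(gene), points=pts))
    return out
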
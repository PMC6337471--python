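"""Reading, validation, and writing of qPCR tables.

Three plain-CSV dialects are understood:

* ``ct.csv`` — wide quantification-cycle table, header ``gene,<sample>,...``.
  Technical replicates may be encoded as columns suffixed ``__r<k>``
  (e.g. ``L1__r1,L1__r2,L1__r3``) and are collapsed on read.
* ``samples.csv`` — ``sample_id,group,is_control``; groups are experimental
  conditions (tissue, time point, treatment), exactly one group may be the
  control/calibrator.
* ``eff.csv`` — ``gene,E`` per-gene amplification efficiencies on the
  fold-per-cycle scale (ideal doubling: E = 2).

All downstream algorithms assume a complete Ct matrix on a shared sample
set, so missing cells are a hard error by default; the only escape hatch is
dropping whole samples.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QpcrValidationError",
    "CtMatrix",
    "SampleSheet",
    "EfficiencyTable",
    "QPCRDataset",
    "read_ct_table",
    "write_ct_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_efficiencies",
    "write_efficiencies",
    "assemble_dataset",
    "write_ranking_table",
    "CT_MAX",
]

#: Upper bound of a credible quantification cycle; runs use 45 cycles, so a
#: Ct above that (or non-positive) is an instrument/parse artifact.
CT_MAX = 45.0

_REPLICATE_RE = re.compile(r"^(?P<base>.+?)__r(?P<k>\d+)$")


class QpcrValidationError(ValueError):
    """Raised when an input table violates a structural or range constraint."""


@dataclass
class CtMatrix:
    """Genes x samples quantification-cycle values.

    Parameters
    ----------
    ct :
        DataFrame indexed by gene id with sample ids as columns; values are
        Ct in PCR cycles, finite and in ``(0, CT_MAX]``.
    replicates :
        Optional raw technical-replicate table (columns ``sample__r<k>``)
        kept for provenance; ``ct`` must equal its per-sample collapse.
    replicate_policy :
        How ``replicates`` were collapsed ("mean" or "median").
    """

    ct: pd.DataFrame
    replicates: pd.DataFrame | None = None
    replicate_policy: str = "mean"

    def __post_init__(self) -> None:
        self.ct = self.ct.astype(float)
        self.validate()

    @property
    def gene_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def values(self) -> np.ndarray:
        return self.ct.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.ct.shape[0]

    @property
    def n_samples(self) -> int:
        return self.ct.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "CtMatrix":
        missing = [g for g in genes if g not in self.ct.index]
        if missing:
            raise QpcrValidationError(f"genes not in Ct matrix: {missing}")
        return CtMatrix(self.ct.loc[list(genes)])

    def validate(self) -> None:
        idx = self.ct.index
        cols = self.ct.columns
        if idx.duplicated().any():
            dups = sorted(set(idx[idx.duplicated()]))
            raise QpcrValidationError(f"duplicate gene ids: {dups}")
        if cols.duplicated().any():
            dups = sorted(set(cols[cols.duplicated()]))
            raise QpcrValidationError(f"duplicate sample ids: {dups}")
        vals = self.ct.to_numpy()
        bad = ~np.isfinite(vals) | (vals <= 0) | (vals > CT_MAX)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise QpcrValidationError(
                f"Ct value {vals[g, s]!r} for gene {idx[g]!r}, sample "
                f"{cols[s]!r} is outside (0, {CT_MAX}]"
            )
        if self.replicates is not None:
            collapsed = _collapse_replicates(self.replicates, self.replicate_policy)
            if not np.allclose(collapsed.to_numpy(), vals, atol=1e-9):
                raise QpcrValidationError(
                    "ct does not equal the collapse of the replicate layer"
                )


@dataclass
class SampleSheet:
    """Sample-to-condition assignment with an optional control group."""

    frame: pd.DataFrame  # columns: sample_id, group, is_control

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "is_control"}
        missing = required - set(self.frame.columns)
        if missing:
            raise QpcrValidationError(f"sample sheet missing columns: {sorted(missing)}")
        self.frame = self.frame.reset_index(drop=True)
        sids = self.frame["sample_id"]
        if sids.duplicated().any():
            dups = sorted(set(sids[sids.duplicated()]))
            raise QpcrValidationError(f"duplicate sample ids in sample sheet: {dups}")
        flagged = self.frame.loc[self.frame["is_control"].astype(bool), "group"]
        if flagged.nunique() > 1:
            raise QpcrValidationError(
                f"more than one control group flagged: {sorted(flagged.unique())}"
            )
        # the flag must be consistent within a group
        for grp, sub in self.frame.groupby("group", sort=False):
            vals = set(sub["is_control"].astype(bool))
            if len(vals) > 1:
                raise QpcrValidationError(
                    f"group {grp!r} mixes is_control true and false"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def groups(self) -> list[str]:
        """Group labels in order of first appearance."""
        return list(dict.fromkeys(self.frame["group"]))

    @property
    def control_group(self) -> str | None:
        flagged = self.frame.loc[self.frame["is_control"].astype(bool), "group"]
        return None if flagged.empty else flagged.iloc[0]

    def require_control(self) -> str:
        ctrl = self.control_group
        if ctrl is None:
            raise QpcrValidationError(
                "this analysis needs a control/calibrator group "
                "(no sample has is_control = true)"
            )
        return ctrl

    def samples_in(self, group: str) -> list[str]:
        return list(self.frame.loc[self.frame["group"] == group, "sample_id"])

    def group_of(self) -> pd.Series:
        return self.frame.set_index("sample_id")["group"]


@dataclass
class EfficiencyTable:
    """Per-gene amplification efficiency E (fold increase per cycle).

    Genes absent from the table default to the ideal E = 2.0.  Values must
    lie in ``(1, max_e]``; the default ceiling of 2.2 tolerates the slight
    over-unity estimates dilution-series fits produce in practice.
    """

    values: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    max_e: float = 2.2

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.duplicated().any():
            dups = sorted(set(self.values.index[self.values.index.duplicated()]))
            raise QpcrValidationError(f"duplicate gene ids in efficiency table: {dups}")
        bad = self.values[(self.values <= 1.0) | (self.values > self.max_e)]
        if not bad.empty:
            g = bad.index[0]
            raise QpcrValidationError(
                f"efficiency E={bad.iloc[0]} for gene {g!r} outside (1, {self.max_e}]"
            )

    def for_gene(self, gene: str) -> float:
        return float(self.values.get(gene, 2.0))

    def for_genes(self, genes: Sequence[str]) -> pd.Series:
        return self.values.reindex(list(genes)).fillna(2.0)

    @classmethod
    def uniform(cls, genes: Sequence[str], e: float = 2.0) -> "EfficiencyTable":
        return cls(pd.Series(e, index=list(genes), dtype=float))


@dataclass
class QPCRDataset:
    """The assembled, cross-validated input bundle for the pipeline."""

    ct: CtMatrix
    samples: SampleSheet
    efficiencies: EfficiencyTable


def _parse_header(path: Path) -> list[str]:
    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    return [h.strip() for h in header]


def _collapse_replicates(reps: pd.DataFrame, policy: str) -> pd.DataFrame:
    bases: dict[str, list[str]] = {}
    for col in reps.columns:
        m = _REPLICATE_RE.match(col)
        base = m.group("base") if m else col
        bases.setdefault(base, []).append(col)
    out = {}
    for base, cols in bases.items():
        block = reps[cols]
        out[base] = block.median(axis=1) if policy == "median" else block.mean(axis=1)
    return pd.DataFrame(out, index=reps.index)


def read_ct_table(
    path: str | Path,
    replicate_policy: str = "mean",
    *,
    drop_incomplete_samples: bool = False,
) -> CtMatrix:
    """Read a wide Ct CSV, collapsing technical-replicate columns.

    Parameters
    ----------
    path :
        CSV with the gene id in the first column and one column per sample
        (or per technical replicate, suffixed ``__r<k>``).
    replicate_policy :
        ``"mean"`` (default) or ``"median"`` collapse replicate columns by
        that statistic; ``"error"`` refuses replicate columns outright.
    drop_incomplete_samples :
        If true, samples with any missing gene are removed instead of
        raising.  Pairwise-complete analysis is deliberately not offered:
        every downstream statistic assumes one common sample set.
    """
    path = Path(path)
    if replicate_policy not in {"mean", "median", "error"}:
        raise ValueError(f"unknown replicate_policy {replicate_policy!r}")
    header = _parse_header(path)
    if len(header) < 2:
        raise QpcrValidationError(f"{path}: need a gene column plus >=1 sample column")
    raw_cols = header[1:]
    if len(set(raw_cols)) != len(raw_cols):
        dups = sorted({c for c in raw_cols if raw_cols.count(c) > 1})
        raise QpcrValidationError(f"{path}: duplicate sample columns {dups}")
    has_reps = any(_REPLICATE_RE.match(c) for c in raw_cols)
    if has_reps and replicate_policy == "error":
        raise QpcrValidationError(
            f"{path}: replicate columns present but replicate_policy='error'"
        )

    df = pd.read_csv(path, dtype={header[0]: str})
    df = df.set_index(header[0])
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise QpcrValidationError(f"{path}: duplicate gene ids {dups}")

    # locate non-numeric cells before coercion so the error can name them
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad_parse = numeric.isna() & df.notna()
    if bad_parse.any().any():
        g, s = np.argwhere(bad_parse.to_numpy())[0]
        raise QpcrValidationError(
            f"{path}: non-numeric Ct {df.iat[g, s]!r} for gene "
            f"{df.index[g]!r}, sample {df.columns[s]!r}"
        )

    replicates = numeric if has_reps else None
    collapsed = _collapse_replicates(numeric, replicate_policy) if has_reps else numeric

    if collapsed.isna().any().any():
        if drop_incomplete_samples:
            collapsed = collapsed.dropna(axis=1, how="any")
            if collapsed.shape[1] == 0:
                raise QpcrValidationError(f"{path}: no complete samples remain")
            if replicates is not None:
                keep = [
                    c
                    for c in replicates.columns
                    if (_REPLICATE_RE.match(c).group("base") if _REPLICATE_RE.match(c) else c)
                    in collapsed.columns
                ]
                replicates = replicates[keep]
        else:
            g, s = np.argwhere(collapsed.isna().to_numpy())[0]
            raise QpcrValidationError(
                f"{path}: missing Ct for gene {collapsed.index[g]!r}, sample "
                f"{collapsed.columns[s]!r} (use drop_incomplete_samples to drop "
                f"the sample)"
            )

    vals = collapsed.to_numpy()
    bad = ~np.isfinite(vals) | (vals <= 0) | (vals > CT_MAX)
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise QpcrValidationError(
            f"{path}: Ct value {vals[g, s]!r} for gene {collapsed.index[g]!r}, "
            f"sample {collapsed.columns[s]!r} is outside (0, {CT_MAX}]"
        )
    return CtMatrix(collapsed, replicates=replicates, replicate_policy=replicate_policy)


def write_ct_table(ctm: CtMatrix, path: str | Path) -> None:
    out = ctm.ct.copy()
    out.index.name = "gene"
    out.to_csv(path, float_format="%.10g")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read ``sample_id,group,is_control`` and validate it."""
    df = pd.read_csv(path, dtype=str)
    required = {"sample_id", "group", "is_control"}
    missing = required - set(df.columns)
    if missing:
        raise QpcrValidationError(f"{path}: missing columns {sorted(missing)}")
    truthy = {"true", "1", "yes", "y", "t"}
    falsy = {"false", "0", "no", "n", "f", ""}
    flags = []
    for v in df["is_control"].fillna(""):
        lv = str(v).strip().lower()
        if lv in truthy:
            flags.append(True)
        elif lv in falsy:
            flags.append(False)
        else:
            raise QpcrValidationError(f"{path}: unrecognized is_control value {v!r}")
    df = df.assign(is_control=flags)
    return SampleSheet(df[["sample_id", "group", "is_control"]])


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.frame.to_csv(path, index=False)


def read_efficiencies(
    path: str | Path | None,
    genes: Sequence[str] | None = None,
    max_e: float = 2.2,
) -> EfficiencyTable:
    """Read ``gene,E``; with no file every gene defaults to E = 2."""
    if path is None:
        ser = pd.Series(dtype=float)
    else:
        df = pd.read_csv(path, dtype={0: str})
        cols = {c.lower(): c for c in df.columns}
        gene_col = cols.get("gene", cols.get("gene_id", df.columns[0]))
        e_col = cols.get("e", df.columns[1])
        ser = pd.Series(
            pd.to_numeric(df[e_col], errors="raise").to_numpy(),
            index=df[gene_col].astype(str),
        )
    table = EfficiencyTable(ser, max_e=max_e)
    if genes is not None:
        table = EfficiencyTable(table.for_genes(genes), max_e=max_e)
    return table


def write_efficiencies(eff: EfficiencyTable, path: str | Path) -> None:
    out = eff.values.rename("E").rename_axis("gene").reset_index()
    out.to_csv(path, index=False, float_format="%.10g")


def assemble_dataset(
    ct: CtMatrix, samples: SampleSheet, efficiencies: EfficiencyTable | None = None
) -> QPCRDataset:
    """Cross-validate the three tables into one dataset object."""
    sheet_ids = samples.sample_ids
    missing = [s for s in ct.sample_ids if s not in sheet_ids]
    if missing:
        raise QpcrValidationError(f"samples absent from sample sheet: {missing}")
    extra = [s for s in sheet_ids if s not in ct.sample_ids]
    if extra:
        raise QpcrValidationError(f"sample sheet lists unknown samples: {extra}")
    if efficiencies is None:
        efficiencies = EfficiencyTable.uniform(ct.gene_ids)
    else:
        efficiencies = EfficiencyTable(
            efficiencies.for_genes(ct.gene_ids), max_e=efficiencies.max_e
        )
    return QPCRDataset(ct=ct, samples=samples, efficiencies=efficiencies)


def write_ranking_table(rankings, path: str | Path) -> None:
    """Write one or more stability rankings side by side.

    Layout mirrors the conventional presentation: a ``rank`` column, then a
    ``(gene, score)`` column pair per algorithm, most stable first.
    """
    rankings = list(rankings) if isinstance(rankings, (list, tuple)) else [rankings]
    if not rankings:
        raise QpcrValidationError("no rankings to write")
    universe = set(rankings[0].ranking)
    if not universe:
        raise QpcrValidationError("empty ranking")
    for r in rankings[1:]:
        if set(r.ranking) != universe:
            raise QpcrValidationError(
                f"rankings cover different gene universes: {r.algorithm}"
            )
    n = len(universe)
    data: dict[str, list] = {"rank": list(range(1, n + 1))}
    for r in rankings:
        data[f"{r.algorithm}_gene"] = list(r.ranking)
        data[f"{r.algorithm}_{r.score_label}"] = [r.scores.get(g) for g in r.ranking]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6g")
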
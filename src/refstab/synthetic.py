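"""Synthetic Ct datasets with known ground truth.

The generator emulates a realistic qPCR candidate-reference-gene screen on
a small panel: a latent log2 expression per gene and sample

    L[g, s] = beta[g, group(s)] + lambda[s] + eps[g, s]

composed of a treatment effect (zero for stable genes), a per-sample
loading offset shared by all genes (pipetting / RNA-input variation,
``sigma_loading`` log2 units), and Normal noise on the log2 scale
(multiplicative on quantity, the usual qPCR error structure).  The latent
expression maps to cycles through each gene's amplification efficiency:

    Ct[g, s] = C0[g] - L[g, s] * ln(2) / ln(E[g])

so one log2 unit of expression is one cycle when E = 2.  Baselines C0 are
drawn uniformly over a plausible Ct window and efficiencies uniformly over
a realistic assay range; both are reported truthfully unless the
mis-specification mode is enabled.

The default spec is the canonical recovery scenario the test-bench is
built around: three stable genes, three mildly treatment-responsive genes
(+1 log2 unit in the first treatment group), two strongly responsive genes
(+3 log2 units in the second), a control plus two treatment groups with
three biological replicates each, sigma_stable = 0.1 and
sigma_loading = 0.5 log2 units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ct_io import (
    CtMatrix,
    EfficiencyTable,
    QpcrValidationError,
    SampleSheet,
    write_ct_table,
    write_efficiencies,
    write_sample_sheet,
)
from .quantities import DilutionSeries

__all__ = [
    "GroupSpec",
    "SyntheticSpec",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_dataset",
    "generate_dilution_series",
    "write_dataset",
]


@dataclass(frozen=True)
class GroupSpec:
    name: str
    n_replicates: int = 3
    is_control: bool = False


def _default_groups() -> tuple[GroupSpec, ...]:
    return (
        GroupSpec("control", 3, is_control=True),
        GroupSpec("t1", 3),
        GroupSpec("t2", 3),
    )


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic screen; defaults are the recovery scenario."""

    n_stable: int = 3
    n_unstable: int = 5
    groups: tuple[GroupSpec, ...] = field(default_factory=_default_groups)
    sigma_stable: float = 0.1  # log2 units
    sigma_unstable: float = 0.1
    #: gene -> group -> log2 shift; None derives the canonical pattern:
    #: shifts are spread over the treatment groups with mixed signs so the
    #: panel carries no net co-regulation (the panel-mean shift per group
    #: stays small, and no small subset of shifted genes cancels exactly in
    #: a geometric mean) — a screen whose candidate panel is systematically
    #: co-regulated violates every stability algorithm's assumptions.
    group_effects: Mapping[str, Mapping[str, float]] | None = None
    mild_shift: float = 1.0
    strong_shift: float = 3.0
    sigma_loading: float = 0.5
    baseline_ct_range: tuple[float, float] = (18.0, 30.0)
    efficiency_range: tuple[float, float] = (1.85, 2.05)
    #: target gene -> group -> log2 fold vs control (targets are extra rows
    #: in the Ct matrix, not part of the reference candidate panel)
    targets: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    sigma_target: float = 0.1
    seed: int = 0
    #: mis-specification mode: report E = 2 for every gene regardless of
    #: the efficiencies actually used to generate the data
    report_efficiency_as_two: bool = False

    def validate(self) -> None:
        if self.n_stable < 0 or self.n_unstable < 0 or self.n_stable + self.n_unstable < 1:
            raise QpcrValidationError("need at least one reference gene")
        if not self.groups:
            raise QpcrValidationError("need at least one group")
        if any(g.n_replicates < 1 for g in self.groups):
            raise QpcrValidationError("every group needs >=1 replicate")
        if sum(g.is_control for g in self.groups) > 1:
            raise QpcrValidationError("at most one control group")
        for s in (self.sigma_stable, self.sigma_unstable, self.sigma_loading, self.sigma_target):
            if s < 0:
                raise QpcrValidationError("noise SDs must be >= 0")
        lo, hi = self.efficiency_range
        if not (1.0 < lo <= hi <= 2.2):
            raise QpcrValidationError("efficiency range must lie within (1, 2.2]")
        lo, hi = self.baseline_ct_range
        if not (0.0 < lo <= hi <= 45.0):
            raise QpcrValidationError("baseline Ct range must lie within (0, 45]")

    @property
    def stable_genes(self) -> list[str]:
        return [f"STB{i + 1}" for i in range(self.n_stable)]

    @property
    def unstable_genes(self) -> list[str]:
        return [f"UNS{i + 1}" for i in range(self.n_unstable)]

    def resolved_group_effects(self) -> dict[str, dict[str, float]]:
        if self.group_effects is not None:
            return {g: dict(eff) for g, eff in self.group_effects.items()}
        effects: dict[str, dict[str, float]] = {}
        treatment = [g.name for g in self.groups if not g.is_control]
        if not treatment:
            treatment = [self.groups[0].name]
        uns = self.unstable_genes
        n_strong = min(2, len(uns))
        mild = uns[: len(uns) - n_strong]
        strong = uns[len(uns) - n_strong :]
        for i, gene in enumerate(mild):
            grp = treatment[(i * len(treatment)) // max(1, len(mild))]
            sign = -1.0 if grp == treatment[0] else 1.0
            effects[gene] = {grp: sign * self.mild_shift}
        for j, gene in enumerate(strong):
            grp = treatment[j % len(treatment)]
            sign = 1.0 if j % 2 == 0 else -1.0
            effects[gene] = {grp: sign * self.strong_shift}
        return effects


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset."""

    stable_genes: list[str]
    unstable_genes: list[str]
    target_genes: list[str]
    loading_offsets: dict[str, float]  # sample -> lambda (log2 units)
    target_folds: dict[str, dict[str, float]]  # target -> group -> fold (linear)
    group_effects: dict[str, dict[str, float]]  # gene -> group -> log2 shift

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


@dataclass
class SyntheticDataset:
    ct: CtMatrix
    samples: SampleSheet
    efficiencies: EfficiencyTable
    truth: SyntheticTruth

    @property
    def reference_genes(self) -> list[str]:
        return self.truth.stable_genes + self.truth.unstable_genes


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one dataset; deterministic for a fixed ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    ref_genes = spec.stable_genes + spec.unstable_genes
    target_genes = list(spec.targets)
    genes = ref_genes + target_genes
    n_genes = len(genes)

    samples: list[str] = []
    sample_group: list[str] = []
    is_control: list[bool] = []
    for grp in spec.groups:
        for k in range(grp.n_replicates):
            samples.append(f"{grp.name}_{k + 1}")
            sample_group.append(grp.name)
            is_control.append(grp.is_control)
    n_samples = len(samples)

    c0 = rng.uniform(*spec.baseline_ct_range, size=n_genes)
    e = rng.uniform(*spec.efficiency_range, size=n_genes)
    lam = rng.normal(0.0, spec.sigma_loading, size=n_samples)

    sigma = np.empty(n_genes)
    sigma[: spec.n_stable] = spec.sigma_stable
    sigma[spec.n_stable : len(ref_genes)] = spec.sigma_unstable
    sigma[len(ref_genes) :] = spec.sigma_target
    eps = rng.normal(0.0, 1.0, size=(n_genes, n_samples)) * sigma[:, None]

    effects = spec.resolved_group_effects()
    for t, folds in spec.targets.items():
        effects.setdefault(t, {}).update(folds)
    beta = np.zeros((n_genes, n_samples))
    gidx = {g: i for i, g in enumerate(genes)}
    for gene, per_group in effects.items():
        if gene not in gidx:
            raise QpcrValidationError(f"group effect for unknown gene {gene!r}")
        for grp, shift in per_group.items():
            mask = np.array([sg == grp for sg in sample_group])
            if not mask.any():
                raise QpcrValidationError(f"group effect for unknown group {grp!r}")
            beta[gidx[gene], mask] = shift

    latent = beta + lam[None, :] + eps
    cycles_per_log2 = np.log(2.0) / np.log(e)
    ct_vals = c0[:, None] - latent * cycles_per_log2[:, None]

    ct = CtMatrix(pd.DataFrame(ct_vals, index=genes, columns=samples))
    sheet = SampleSheet(
        pd.DataFrame(
            {"sample_id": samples, "group": sample_group, "is_control": is_control}
        )
    )
    reported_e = np.full(n_genes, 2.0) if spec.report_efficiency_as_two else e
    eff = EfficiencyTable(pd.Series(reported_e, index=genes))
    truth = SyntheticTruth(
        stable_genes=spec.stable_genes,
        unstable_genes=spec.unstable_genes,
        target_genes=target_genes,
        loading_offsets=dict(zip(samples, lam.tolist())),
        target_folds={
            t: {grp: float(2.0**shift) for grp, shift in folds.items()}
            for t, folds in spec.targets.items()
        },
        group_effects={g: dict(v) for g, v in effects.items()},
    )
    return SyntheticDataset(ct=ct, samples=sheet, efficiencies=eff, truth=truth)


def generate_dilution_series(
    gene: str,
    true_e: float,
    c0: float = 25.0,
    dilution_factor: float = 5.0,
    n_points: int = 5,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> DilutionSeries:
    """Standard-curve points: Ct = c0 - x / log10(E) at log10 input x.

    Inputs start at the undiluted template (x = 0) and decrease by
    log10(dilution_factor) per step, mirroring a serial dilution.
    """
    if not (1.0 < true_e <= 2.2):
        raise QpcrValidationError(f"true efficiency {true_e} outside (1, 2.2]")
    if n_points < 3:
        raise QpcrValidationError("need >=3 dilution points")
    if dilution_factor <= 1.0:
        raise QpcrValidationError("dilution factor must exceed 1")
    rng = np.random.default_rng(seed)
    x = -np.arange(n_points) * np.log10(dilution_factor)
    ct = c0 - x / np.log10(true_e)
    if noise_sd > 0:
        ct = ct + rng.normal(0.0, noise_sd, size=n_points)
    return DilutionSeries(gene_id=gene, points=list(zip(x.tolist(), ct.tolist())))


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Emit ct.csv / samples.csv / eff.csv / truth.json into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ct": out / "ct.csv",
        "samples": out / "samples.csv",
        "eff": out / "eff.csv",
        "truth": out / "truth.json",
    }
    write_ct_table(ds.ct, paths["ct"])
    write_sample_sheet(ds.samples, paths["samples"])
    write_efficiencies(ds.efficiencies, paths["eff"])
    ds.truth.to_json(paths["truth"])
    return paths
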
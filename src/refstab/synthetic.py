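"""Seeded generator of synthetic Ct datasets.

The generative model mirrors the structure every Ct-based stability method
assumes: for gene *i*, sample *s* in group *g*,

    Ct_is = baseline_i + shift_s + effect_ig + eps_is

with a per-sample global technical shift ``shift_s ~ N(0, technical_shift_sd^2)``
shared by all genes (RNA input / RT variability — the component stability
statistics must cancel), gene-level Gaussian noise ``eps_is ~ N(0, noise_sd_i^2)``
on the Ct (log2-expression) scale, and deterministic group effects encoding
dysregulation (a fold change F in a group is a Ct shift of ``-log2(F)``).
Cells can be masked missing completely at random.

Presets emulate a four-group rodent multi-trauma design (control, isolated
fracture Fx, traumatic brain injury TBI, combined TBI+Fx; n = 6 per group)
with five routinely used candidate housekeepers, optionally planting a
group-specific dysregulated gene:

* ``paper_d3_bone`` — an *Actb*-like gene shifted by 1.5 cycles in the
  fracture-containing groups (callus vs intact bone);
* ``paper_d3_hypothalamus`` — a *B2m*-like gene shifted by 1.5 cycles in
  the TBI-containing groups (neuroinflammation);
* ``paper_wat`` — ten candidates with a mildly unstable *Gapdh*-like gene;
* ``neutral`` — no planted effects, low noise.

Randomness uses ``numpy.random.default_rng`` (PCG64), so a seed fixes the
dataset bit-for-bit across platforms.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ct_data import ROLE_REFERENCE, ROLE_TARGET, CtMatrix
from .errors import AnalysisError, ValidationError

PRESETS = ("paper_d3_bone", "paper_d3_hypothalamus", "paper_wat", "neutral")

#: The standard four-arm trauma design, n = 6 per group and time point.
DEFAULT_GROUPS = ("control", "Fx", "TBI", "TBI+Fx")
DEFAULT_N_PER_GROUP = 6


@dataclass(frozen=True)
class GeneSpec:
    """One simulated gene: baseline Ct, noise SD, per-group Ct shifts."""

    name: str
    baseline_ct: float
    noise_sd: float = 0.2
    group_effects: dict[str, float] = field(default_factory=dict)
    role: str = ROLE_REFERENCE

    def __post_init__(self) -> None:
        if not (0.0 < self.baseline_ct < 50.0):
            raise ValidationError(f"gene {self.name!r}: baseline Ct {self.baseline_ct} out of (0, 50)")
        if self.noise_sd < 0:
            raise ValidationError(f"gene {self.name!r}: negative noise SD")


@dataclass(frozen=True)
class SyntheticDesign:
    """Full study design: groups, gene panel, noise structure, seed."""

    genes: tuple[GeneSpec, ...]
    groups: tuple[str, ...] = DEFAULT_GROUPS
    n_per_group: int = DEFAULT_N_PER_GROUP
    tissue: str = "bone"
    timepoint: str = "d3"
    technical_shift_sd: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValidationError("need at least 2 samples per group")
        if not self.groups:
            raise ValidationError("at least one group is required")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValidationError("missing_rate must be a probability")
        if self.technical_shift_sd < 0:
            raise ValidationError("technical_shift_sd must be >= 0")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate gene names in design")
        unknown = {grp for g in self.genes for grp in g.group_effects} - set(self.groups)
        if unknown:
            raise ValidationError(f"group effects reference unknown groups: {sorted(unknown)}")

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["generator"] = "numpy.random.default_rng (PCG64)"
        return json.dumps(payload, indent=2)


def generate(design: SyntheticDesign, seed: int | None = None) -> CtMatrix:
    """Draw one Ct dataset from the design; same seed, same matrix."""
    if not design.genes:
        raise ValidationError("design has no genes")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    sample_ids, group_labels = [], []
    for grp in design.groups:
        for k in range(design.n_per_group):
            sample_ids.append(f"{grp}_{k + 1}")
            group_labels.append(grp)
    n = len(sample_ids)
    L = len(design.genes)
    shifts = rng.normal(0.0, design.technical_shift_sd, size=n)
    values = np.empty((L, n))
    for i, gene in enumerate(design.genes):
        effects = np.array([gene.group_effects.get(g, 0.0) for g in group_labels])
        eps = rng.normal(0.0, gene.noise_sd, size=n)
        values[i] = gene.baseline_ct + shifts + effects + eps
    if design.missing_rate > 0:
        mask = rng.random(size=values.shape) < design.missing_rate
        values[mask] = np.nan
    meta = pd.DataFrame(
        {"group": group_labels, "tissue": design.tissue, "timepoint": design.timepoint},
        index=sample_ids,
    )
    roles = pd.Series({g.name: g.role for g in design.genes}, dtype=object)
    df = pd.DataFrame(values, index=[g.name for g in design.genes], columns=sample_ids)
    return CtMatrix(df, meta, roles)


def preset(name: str, seed: int = 0) -> SyntheticDesign:
    """A named study design (see module docstring)."""
    if name not in PRESETS:
        raise AnalysisError(f"unknown preset {name!r}; available: {PRESETS}")
    fx_groups = {"Fx": -1.5, "TBI+Fx": -1.5}
    tbi_groups = {"TBI": -1.5, "TBI+Fx": -1.5}
    if name == "paper_d3_bone":
        genes = (
            GeneSpec("Actb", 17.0, 0.3, group_effects=fx_groups),
            GeneSpec("B2m", 19.5, 0.3),
            GeneSpec("Gapdh", 18.0, 0.3),
            GeneSpec("Hprt", 24.0, 0.3),
            GeneSpec("Ppia", 19.0, 0.3),
        )
        return SyntheticDesign(genes=genes, tissue="bone", timepoint="d3", seed=seed)
    if name == "paper_d3_hypothalamus":
        genes = (
            GeneSpec("Actb", 17.0, 0.3),
            GeneSpec("B2m", 19.5, 0.3, group_effects=tbi_groups),
            GeneSpec("Gapdh", 18.0, 0.3),
            GeneSpec("Hprt", 24.0, 0.3),
            GeneSpec("Ppia", 19.0, 0.3),
        )
        return SyntheticDesign(genes=genes, tissue="hypothalamus", timepoint="d3", seed=seed)
    if name == "paper_wat":
        genes = (
            GeneSpec("Actb", 18.0, 0.2),
            GeneSpec("B2m", 20.0, 0.2),
            GeneSpec("Gapdh", 18.5, 0.4, group_effects={"Fx": -0.75, "TBI": -0.4, "TBI+Fx": -0.9}),
            GeneSpec("Hprt", 24.5, 0.2),
            GeneSpec("Ppia", 18.0, 0.2),
            GeneSpec("Hmbs", 25.0, 0.2),
            GeneSpec("Psmb2", 22.0, 0.2),
            GeneSpec("Rplp0", 17.5, 0.2),
            GeneSpec("Srsf4", 23.5, 0.2),
            GeneSpec("Tbp", 26.5, 0.2),
        )
        return SyntheticDesign(genes=genes, tissue="wat", timepoint="d3", seed=seed)
    genes = (
        GeneSpec("g1", 18.0, 0.1),
        GeneSpec("g2", 20.0, 0.1),
        GeneSpec("g3", 22.0, 0.1),
        GeneSpec("g4", 24.0, 0.1),
        GeneSpec("g5", 26.0, 0.1),
    )
    return SyntheticDesign(genes=genes, tissue="generic", timepoint="d3", seed=seed)


def add_target(
    design: SyntheticDesign,
    name: str,
    fold_changes: dict[str, float],
    noise_sd: float = 0.2,
    baseline_ct: float = 26.0,
) -> SyntheticDesign:
    """Append a target gene whose group fold changes F become Ct shifts -log2(F)."""
    if name in {g.name for g in design.genes}:
        raise ValidationError(f"gene name {name!r} already used in design")
    for grp, fold in fold_changes.items():
        if fold <= 0:
            raise ValidationError(f"fold change for group {grp!r} must be > 0, got {fold}")
    effects = {grp: -math.log2(fold) for grp, fold in fold_changes.items() if fold != 1.0}
    target = GeneSpec(name, baseline_ct, noise_sd, group_effects=effects, role=ROLE_TARGET)
    return dataclasses.replace(design, genes=design.genes + (target,))
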
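"""Delta-delta-Ct normalization of target genes and group comparison.

Relative quantification follows the standard two-step contrast: per sample,
``dCt = Ct_target - Ct_ref`` (with several references, the arithmetic mean
of their Ct, i.e. the geometric mean of their quantities); ``ddCt`` centers
dCt on the mean dCt of the control group; relative quantity
``rq = E**(-ddCt)`` with amplification efficiency E (default 2: one cycle =
one doubling).  Centering on the control *mean* makes the geometric mean of
rq over control samples exactly 1.

Group differences are tested nonparametrically: each non-control group is
compared with the control group by a two-sided Mann-Whitney U test (exact
by enumeration for small tie-free samples, otherwise normal approximation
with tie and continuity corrections).  A Shapiro-Wilk normality check is
available for annotation; the workflow stays nonparametric regardless.

:func:`compare_housekeeping` runs the same target against several candidate
reference sets side by side, exposing how a dysregulated housekeeper
manufactures spurious "regulation" (false positives) or masks real effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ct_data import CtMatrix
from .errors import AnalysisError

#: Largest per-group size for which the exact Mann-Whitney null is used.
EXACT_MWU_MAX_N = 8


@dataclass
class GroupTest:
    group: str
    n: int
    n_control: int
    U: float
    p: float
    method: str


@dataclass
class NormalizedExpression:
    """Per-sample normalized expression of one target gene.

    ``table`` columns: sample, group, delta_ct, delta_delta_ct, rq.
    ``summaries`` is indexed by group with n, mean_rq, sd_rq.
    ``tests`` holds one Mann-Whitney comparison vs control per other group.
    """

    target: str
    references: tuple[str, ...]
    control_group: str
    efficiency: float
    table: pd.DataFrame
    summaries: pd.DataFrame
    tests: list[GroupTest]


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U, p) with U = min(U_a, U_b).

    Exact null distribution when both samples have <= 8 observations and no
    ties; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise AnalysisError("Mann-Whitney comparison needs at least 3 observations per group")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = len(a) <= EXACT_MWU_MAX_N and len(b) <= EXACT_MWU_MAX_N and not has_ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    u_a = float(res.statistic)
    u_min = min(u_a, len(a) * len(b) - u_a)
    return u_min, float(res.pvalue)


@dataclass
class ShapiroResult:
    W: float
    p: float
    is_normal: bool | None  # None when W is undefined (constant input)


def shapiro_wilk_gate(values: Sequence[float], alpha: float = 0.05) -> ShapiroResult:
    """Shapiro-Wilk normality check (annotation only; the pipeline stays
    nonparametric either way)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise AnalysisError("Shapiro-Wilk needs at least 3 observations")
    if len(x) > 5000:
        raise AnalysisError("Shapiro-Wilk approximation unreliable above 5000 observations")
    if np.ptp(x) == 0.0:
        return ShapiroResult(W=float("nan"), p=float("nan"), is_normal=None)
    W, p = stats.shapiro(x)
    return ShapiroResult(W=float(W), p=float(p), is_normal=bool(p >= alpha))


def normalize_ddct(
    ct: CtMatrix,
    target: str,
    references: Sequence[str],
    control_group: str,
    efficiency: float = 2.0,
    aggregate: str = "ct_mean",
    test: bool = True,
) -> NormalizedExpression:
    """Normalize one target gene to a reference set by delta-delta-Ct.

    Parameters
    ----------
    aggregate
        ``"ct_mean"`` (default): one pseudo-reference = arithmetic mean of
        reference Ct values.  ``"rq_mean"``: normalize per individual
        reference, then average the per-reference relative quantities.
    test
        Run Mann-Whitney comparisons of each non-control group vs control
        (needs >= 3 samples in each compared group).
    """
    references = tuple(references)
    if target in references:
        raise AnalysisError(f"target {target!r} cannot be among its references")
    if not references:
        raise AnalysisError("at least one reference gene is required")
    missing = [g for g in (target, *references) if g not in ct.values.index]
    if missing:
        raise AnalysisError(f"genes not in dataset: {missing}")
    if aggregate not in {"ct_mean", "rq_mean"}:
        raise AnalysisError(f"unknown aggregate mode {aggregate!r}")
    cc = ct.complete_cases([target, *references])
    groups = cc.meta["group"]
    if control_group not in set(groups):
        raise AnalysisError(f"control group {control_group!r} absent from the data")
    control_mask = (groups == control_group).to_numpy()

    tgt = cc.values.loc[target].to_numpy(dtype=float)
    ref = cc.values.loc[list(references)].to_numpy(dtype=float)
    if aggregate == "ct_mean":
        dct = tgt - ref.mean(axis=0)
        ddct = dct - dct[control_mask].mean()
        rq = np.power(efficiency, -ddct)
    else:
        dct_per_ref = tgt[None, :] - ref  # (R, n)
        ddct_per_ref = dct_per_ref - dct_per_ref[:, control_mask].mean(axis=1, keepdims=True)
        rq = np.power(efficiency, -ddct_per_ref).mean(axis=0)
        dct = dct_per_ref.mean(axis=0)
        ddct = ddct_per_ref.mean(axis=0)

    table = pd.DataFrame(
        {
            "sample": cc.sample_ids,
            "group": groups.to_numpy(),
            "delta_ct": dct,
            "delta_delta_ct": ddct,
            "rq": rq,
        }
    )
    summaries = (
        table.groupby("group", sort=False)["rq"]
        .agg(n="count", mean_rq="mean", sd_rq=lambda v: v.std(ddof=1))
        .astype({"n": int})
    )
    tests: list[GroupTest] = []
    if test:
        control_rq = table.loc[table["group"] == control_group, "rq"].to_numpy()
        for g in dict.fromkeys(table["group"]):
            if g == control_group:
                continue
            other = table.loc[table["group"] == g, "rq"].to_numpy()
            if len(other) < 3 or len(control_rq) < 3:
                continue
            U, p = mann_whitney_u(other, control_rq)
            exact = (
                len(other) <= EXACT_MWU_MAX_N
                and len(control_rq) <= EXACT_MWU_MAX_N
                and len(np.unique(np.concatenate([other, control_rq]))) == len(other) + len(control_rq)
            )
            tests.append(
                GroupTest(
                    group=g,
                    n=len(other),
                    n_control=len(control_rq),
                    U=U,
                    p=p,
                    method="exact" if exact else "asymptotic",
                )
            )
    return NormalizedExpression(
        target=target,
        references=references,
        control_group=control_group,
        efficiency=efficiency,
        table=table,
        summaries=summaries,
        tests=tests,
    )


def compare_housekeeping(
    ct: CtMatrix,
    target: str,
    ref_sets: Sequence[Sequence[str]],
    control_group: str,
    efficiency: float = 2.0,
) -> list[NormalizedExpression]:
    """Normalize the same target to several reference sets side by side."""
    if not ref_sets:
        raise AnalysisError("at least one reference set is required")
    return [
        normalize_ddct(ct, target, refs, control_group, efficiency=efficiency)
        for refs in ref_sets
    ]
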
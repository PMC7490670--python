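"""GeNorm expression-stability analysis.

GeNorm scores a candidate reference gene by the average variability of its
expression *ratio* against every other candidate: for genes *j*, *k* the
pairwise variation ``V_jk`` is the standard deviation over samples of
``log2(Q_j / Q_k)``, and the stability value ``M_j`` is the mean of ``V_jk``
over all partners ``k != j``.  A perfectly co-regulated pair has ``V = 0``;
global per-sample effects (RNA input, RT efficiency) cancel in the ratio.

The full procedure is the classical stepwise exclusion: recompute M on the
surviving panel, drop the gene with the largest M, repeat until two genes
remain (these share their final M by construction).  The pairwise-variation
curve ``V_n/n+1`` between normalization factors built from the top *n* and
*n+1* genes selects how many reference genes are needed (default cutoff
``V < 0.15``).

Relative quantities are ``Q = E**(minCt - Ct)`` with amplification
efficiency ``E`` (ideal 2.0, one doubling per cycle), scaled so the highest
expressor of each gene has ``Q = 1``.  M is invariant to this scaling; with
``E = 2`` the pairwise variation reduces to the SD of Ct differences.

All standard deviations use the n-1 (sample) denominator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ct_data import CtMatrix
from .errors import AnalysisError

#: GeNorm suitability thresholds on M.
M_THRESHOLD_HOMOGENEOUS = 0.5
M_THRESHOLD_HETEROGENEOUS = 1.5
#: Default pairwise-variation cutoff for the optimal gene count.
V_CUTOFF = 0.15

EFFICIENCY_RANGE = (1.6, 2.2)


@dataclass
class RelativeQuantityMatrix:
    """Relative quantities Q = E**(minCt - Ct), per-gene maximum exactly 1."""

    Q: pd.DataFrame
    efficiency: float = 2.0

    @property
    def genes(self) -> list[str]:
        return list(self.Q.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.Q.columns)

    @property
    def log2_q(self) -> pd.DataFrame:
        return np.log2(self.Q)


@dataclass
class GeNormResult:
    """Outcome of the stepwise-exclusion ranking.

    ``M_final`` holds each gene's M at the step it was excluded (the last
    surviving pair shares one value); ``M_full_panel`` is the single-pass M
    on the complete panel.  ``ranking`` is 1 = most stable with the final
    pair tied (fractional rank 1.5 each).
    """

    M_final: pd.Series
    M_full_panel: pd.Series
    removal_order: list[str]
    ranking: pd.Series
    suitability: pd.Series
    threshold_used: float

    @property
    def stability_order(self) -> list[str]:
        """Genes from most to least stable (final pair first, in input order)."""
        order = list(reversed(self.removal_order))
        survivors = [g for g in self.M_final.index if g not in set(self.removal_order)]
        return survivors + order


@dataclass
class VCurve:
    """Pairwise-variation curve V_n/n+1 and the selected reference-gene count."""

    V: dict[int, float]
    cutoff: float
    optimal_n: int
    ranking_used: list[str]
    cutoff_inclusive: bool = False


def relative_quantities(ct: CtMatrix, efficiency: float = 2.0, genes: Iterable[str] | None = None) -> RelativeQuantityMatrix:
    """Transform Ct to relative quantities Q = efficiency**(minCt - Ct).

    Requires complete cases over the panel; raises if any Ct is missing.
    """
    lo, hi = EFFICIENCY_RANGE
    if not (lo <= efficiency <= hi):
        raise AnalysisError(f"amplification efficiency {efficiency} outside plausible range [{lo}, {hi}]")
    genes = list(genes) if genes is not None else ct.genes
    vals = ct.values.loc[genes]
    if vals.isna().any().any():
        raise AnalysisError(
            "missing Ct values present; restrict to complete cases first (CtMatrix.complete_cases)"
        )
    q = np.power(efficiency, vals.min(axis=1).to_numpy()[:, None] - vals.to_numpy())
    return RelativeQuantityMatrix(pd.DataFrame(q, index=vals.index, columns=vals.columns), efficiency)


def _pairwise_sd_matrix(logq: np.ndarray) -> np.ndarray:
    """V[j, k] = SD over samples of log-ratio of genes j and k (ddof=1)."""
    L = logq.shape[0]
    V = np.zeros((L, L))
    for j in range(L):
        diff = logq[j] - logq  # (L, n)
        V[j] = diff.std(axis=1, ddof=1)
    return V


def m_values(rq: RelativeQuantityMatrix, panel: Sequence[str] | None = None) -> pd.Series:
    """Per-gene GeNorm M: mean pairwise log-ratio SD against all partners."""
    panel = list(panel) if panel is not None else rq.genes
    if len(panel) < 2:
        raise AnalysisError("GeNorm M needs at least 2 genes in the panel")
    logq = rq.log2_q.loc[panel].to_numpy()
    if logq.shape[1] < 3:
        raise AnalysisError("GeNorm M needs at least 3 samples")
    V = _pairwise_sd_matrix(logq)
    L = len(panel)
    M = (V.sum(axis=1)) / (L - 1)  # diagonal is zero
    return pd.Series(M, index=panel, name="M")


def genorm_rank(
    rq: RelativeQuantityMatrix,
    panel: Sequence[str] | None = None,
    homogeneous: bool = False,
) -> GeNormResult:
    """Stepwise-exclusion GeNorm ranking.

    Repeatedly computes M on the surviving panel and removes the gene with
    the largest M (ties broken by input order) until two genes remain; these
    share the final M and tie at the top of the ranking.  With fewer than 3
    genes no exclusion is possible and the single-pass M is used, with a
    warning.
    """
    panel = list(panel) if panel is not None else rq.genes
    threshold = M_THRESHOLD_HOMOGENEOUS if homogeneous else M_THRESHOLD_HETEROGENEOUS
    M_full = m_values(rq, panel)
    if len(panel) < 3:
        warnings.warn("fewer than 3 genes: stepwise exclusion skipped, single-pass M used", UserWarning)
        ranking = pd.Series(1.5, index=panel)
        return GeNormResult(
            M_final=M_full.copy(),
            M_full_panel=M_full,
            removal_order=[],
            ranking=ranking,
            suitability=M_full < threshold,
            threshold_used=threshold,
        )
    surviving = list(panel)
    removal_order: list[str] = []
    M_final = pd.Series(np.nan, index=panel, dtype=float)
    while len(surviving) > 2:
        M = m_values(rq, surviving)
        worst = M.idxmax()  # first max in panel order on ties
        M_final[worst] = M[worst]
        removal_order.append(worst)
        surviving.remove(worst)
    M_pair = m_values(rq, surviving)
    M_final[surviving] = M_pair
    # ranks: final pair ties at 1.5, then 3, 4, ... in reverse removal order
    ranking = pd.Series(np.nan, index=panel, dtype=float)
    ranking[surviving] = 1.5
    for pos, gene in enumerate(reversed(removal_order), start=3):
        ranking[gene] = float(pos)
    return GeNormResult(
        M_final=M_final,
        M_full_panel=M_full,
        removal_order=removal_order,
        ranking=ranking,
        suitability=M_final < threshold,
        threshold_used=threshold,
    )


def flag_suitability(M: pd.Series, homogeneous: bool = False) -> tuple[pd.Series, float]:
    """Flag genes as suitable references: M < 0.5 (homogeneous panels) or M < 1.5."""
    threshold = M_THRESHOLD_HOMOGENEOUS if homogeneous else M_THRESHOLD_HETEROGENEOUS
    return M < threshold, threshold


def select_optimal_n(
    V: dict[int, float],
    L: int,
    cutoff: float = V_CUTOFF,
    cutoff_inclusive: bool = False,
) -> int:
    """Smallest n whose V_n/n+1 passes the cutoff; all L genes (with a
    warning) if none does."""
    passes = [n for n, v in V.items() if (v <= cutoff if cutoff_inclusive else v < cutoff)]
    if passes:
        return min(passes)
    warnings.warn(
        f"no V_n/n+1 below cutoff {cutoff}; using all {L} genes for normalization",
        UserWarning,
    )
    return L


def pairwise_variation_curve(
    rq: RelativeQuantityMatrix,
    ranking: Sequence[str],
    cutoff: float = V_CUTOFF,
    cutoff_inclusive: bool = False,
) -> VCurve:
    """V_n/n+1 curve over nested normalization factors and the optimal count.

    ``NF_n(sample)`` is the geometric mean of Q over the n most stable genes
    in ``ranking``; ``V_n/n+1`` is the SD over samples of
    ``log2(NF_n / NF_{n+1})``.  The optimal count is the smallest n whose V
    passes the cutoff (strict ``<`` by default); if none passes, all genes
    are kept with a warning.
    """
    ranking = list(ranking)
    L = len(ranking)
    if L < 3:
        raise AnalysisError("pairwise-variation curve needs at least 3 ranked genes")
    logq = rq.log2_q.loc[ranking].to_numpy()
    if logq.shape[1] < 3:
        raise AnalysisError("pairwise-variation curve needs at least 3 samples")
    # log2 NF_n = mean of the top-n rows of log2 Q
    cums = np.cumsum(logq, axis=0)
    V: dict[int, float] = {}
    for n in range(2, L):
        log_nf_n = cums[n - 1] / n
        log_nf_n1 = cums[n] / (n + 1)
        V[n] = float(np.std(log_nf_n - log_nf_n1, ddof=1))
    optimal_n = select_optimal_n(V, L, cutoff=cutoff, cutoff_inclusive=cutoff_inclusive)
    return VCurve(V=V, cutoff=cutoff, optimal_n=optimal_n, ranking_used=ranking, cutoff_inclusive=cutoff_inclusive)
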
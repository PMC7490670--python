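"""Rank assembly across stability methods and the consensus recommendation.

Brings together the four stability analyses — NormFinder, GeNorm,
BestKeeper (contributing both its correlation and its SD ranking) and the
comparative delta-Ct method — into one rank table, computes

* the **final rank**: the sum of per-method ranks, re-ranked ascending, and
* a **RefFinder-style score**: the geometric mean of the four method ranks
  (labelled "-style" because the web tool's internal conventions are not
  published),

and recommends the top genes, taking the set size from the GeNorm
pairwise-variation curve.  All ties receive fractional average ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .bestkeeper import BestKeeperResult, bestkeeper_stats
from .ct_data import CtMatrix
from .errors import AnalysisError
from .genorm import (
    GeNormResult,
    VCurve,
    genorm_rank,
    pairwise_variation_curve,
    relative_quantities,
)
from .normfinder import NormFinderResult, normfinder_stability

#: Methods summed into the final rank by default (BestKeeper
#: contributes its two printed statistics as separate ranks).
FINAL_RANK_METHODS = ("normfinder", "genorm", "bestkeeper_r", "bestkeeper_sd")
#: The four columns entering the RefFinder-style geometric mean.
REFFINDER_METHODS = ("delta_ct", "normfinder", "genorm", "bestkeeper_sd")


@dataclass
class DeltaCtStability:
    """Comparative delta-Ct stability: mean pairwise Ct-difference SD per gene."""

    mean_sd: pd.Series
    ranking: pd.Series


@dataclass
class ConsensusRanking:
    rank_table: pd.DataFrame
    final_rank_score: pd.Series
    final_rank: pd.Series
    reffinder_score: pd.Series
    reffinder_rank: pd.Series
    recommended: list[str] = field(default_factory=list)


def delta_ct_stability(ct: CtMatrix, panel: Sequence[str] | None = None) -> DeltaCtStability:
    """Mean over partner genes of the SD of pairwise Ct differences.

    Algebraically identical to the full-panel GeNorm M at efficiency 2,
    since log2 of a quantity ratio at E = 2 is a Ct difference.
    """
    panel = list(panel) if panel is not None else ct.candidate_genes()
    if len(panel) < 2:
        raise AnalysisError("comparative delta-Ct needs at least 2 genes")
    vals = ct.values.loc[panel]
    if vals.isna().any().any():
        raise AnalysisError("missing Ct values present; restrict to complete cases first")
    y = vals.to_numpy(dtype=float)
    L = len(panel)
    mean_sd = np.empty(L)
    for i in range(L):
        diffs = y[i] - y
        sds = diffs.std(axis=1, ddof=1)
        mean_sd[i] = (sds.sum()) / (L - 1)
    s = pd.Series(mean_sd, index=panel, name="mean_sd")
    return DeltaCtStability(mean_sd=s, ranking=pd.Series(rankdata(mean_sd, method="average"), index=panel))


def assemble_ranks(
    nf: NormFinderResult,
    gn: GeNormResult,
    bk: BestKeeperResult,
    dct: DeltaCtStability,
) -> pd.DataFrame:
    """Combine per-method rankings into one table (rows = genes).

    Columns: normfinder, genorm, bestkeeper_r, bestkeeper_sd, delta_ct.
    Lower is better everywhere; ties carry fractional average ranks.
    """
    genes = list(nf.sv.index)
    for name, other in (
        ("genorm", set(gn.M_final.index)),
        ("bestkeeper", set(bk.stats.index)),
        ("delta_ct", set(dct.mean_sd.index)),
    ):
        if other != set(genes):
            raise AnalysisError(f"gene panel mismatch between normfinder and {name}")
    table = pd.DataFrame(
        {
            "normfinder": nf.ranking.reindex(genes),
            "genorm": gn.ranking.reindex(genes),
            "bestkeeper_r": bk.stats["rank_r"].reindex(genes),
            "bestkeeper_sd": bk.stats["rank_sd"].reindex(genes),
            "delta_ct": dct.ranking.reindex(genes),
        },
        index=genes,
    )
    return table


def final_rank(
    rank_table: pd.DataFrame,
    methods: Sequence[str] = FINAL_RANK_METHODS,
) -> tuple[pd.Series, pd.Series]:
    """Sum the selected method ranks and re-rank the sum (1 = best)."""
    methods = list(methods)
    if not methods:
        raise AnalysisError("final rank needs at least one method column")
    missing = [m for m in methods if m not in rank_table.columns]
    if missing:
        raise AnalysisError(f"unknown method columns: {missing}")
    score = rank_table[methods].sum(axis=1)
    score.name = "final_rank_score"
    rank = pd.Series(rankdata(score.to_numpy(), method="average"), index=rank_table.index, name="final_rank")
    return score, rank


def reffinder_rank(
    rank_table: pd.DataFrame,
    bestkeeper_column: str = "bestkeeper_sd",
) -> tuple[pd.Series, pd.Series]:
    """Geometric mean of the four method ranks, re-ranked ascending."""
    cols = ["delta_ct", "normfinder", "genorm", bestkeeper_column]
    missing = [m for m in cols if m not in rank_table.columns]
    if missing:
        raise AnalysisError(f"unknown method columns: {missing}")
    mat = rank_table[cols].to_numpy(dtype=float)
    if (mat <= 0).any():
        raise AnalysisError("non-positive rank encountered; rankings must be >= 1")
    score = pd.Series(np.exp(np.log(mat).mean(axis=1)), index=rank_table.index, name="reffinder_score")
    rank = pd.Series(rankdata(score.to_numpy(), method="average"), index=rank_table.index, name="reffinder_rank")
    return score, rank


def recommend(consensus: ConsensusRanking, vcurve: VCurve, suitability: pd.Series | None = None) -> list[str]:
    """Top ``optimal_n`` genes by final rank.

    Ties at the boundary are broken by the RefFinder-style score, then by
    input order.  Genes failing the GeNorm suitability flag are kept (the
    set size comes from the V curve) but reported with a warning.
    """
    genes = list(consensus.rank_table.index)
    order = sorted(
        range(len(genes)),
        key=lambda i: (consensus.final_rank.iloc[i], consensus.reffinder_score.iloc[i], i),
    )
    chosen = [genes[i] for i in order[: vcurve.optimal_n]]
    if suitability is not None:
        flagged = [g for g in chosen if not bool(suitability.get(g, True))]
        if flagged:
            warnings.warn(
                f"recommended gene(s) fail the GeNorm suitability threshold: {flagged}",
                UserWarning,
            )
    return chosen


@dataclass
class PipelineResult:
    """Everything the full stability evaluation produces on one dataset."""

    normfinder: NormFinderResult
    genorm: GeNormResult
    bestkeeper: BestKeeperResult
    delta_ct: DeltaCtStability
    vcurve: VCurve
    consensus: ConsensusRanking

    @property
    def recommended(self) -> list[str]:
        return self.consensus.recommended

    def summary_table(self) -> pd.DataFrame:
        """Gene-level summary: method statistics, ranks and consensus scores."""
        t = self.consensus.rank_table.copy()
        t.insert(0, "sv", self.normfinder.sv)
        t.insert(1, "M", self.genorm.M_final)
        t.insert(2, "bk_r", self.bestkeeper.stats["r"])
        t.insert(3, "bk_sd", self.bestkeeper.stats["sd"])
        t.insert(4, "dct_mean_sd", self.delta_ct.mean_sd)
        t["final_rank_score"] = self.consensus.final_rank_score
        t["final_rank"] = self.consensus.final_rank
        t["reffinder_score"] = self.consensus.reffinder_score
        t["reffinder_rank"] = self.consensus.reffinder_rank
        t["genorm_suitable"] = self.genorm.suitability
        return t


def run_pipeline(
    ct: CtMatrix,
    panel: Sequence[str] | None = None,
    efficiency: float = 2.0,
    homogeneous: bool = False,
    cutoff: float = 0.15,
    cutoff_inclusive: bool = False,
    final_rank_methods: Sequence[str] = FINAL_RANK_METHODS,
    bestkeeper_column: str = "bestkeeper_sd",
    sd_variant: str = "sd",
) -> PipelineResult:
    """Run all four stability methods plus consensus on one Ct dataset.

    Operates on complete cases over the candidate panel; target genes are
    excluded from all stability statistics.
    """
    panel = list(panel) if panel is not None else ct.candidate_genes()
    if len(panel) < 3:
        raise AnalysisError("the full pipeline needs at least 3 candidate genes")
    cc = ct.complete_cases(panel)
    rq = relative_quantities(cc, efficiency=efficiency, genes=panel)
    gn = genorm_rank(rq, panel, homogeneous=homogeneous)
    vcurve = pairwise_variation_curve(rq, gn.stability_order, cutoff=cutoff, cutoff_inclusive=cutoff_inclusive)
    nf = normfinder_stability(cc, genes=panel)
    bk = bestkeeper_stats(cc, panel, sd_variant=sd_variant)
    dct = delta_ct_stability(cc, panel)
    table = assemble_ranks(nf, gn, bk, dct)
    score, frank = final_rank(table, final_rank_methods)
    rscore, rrank = reffinder_rank(table, bestkeeper_column)
    consensus = ConsensusRanking(
        rank_table=table,
        final_rank_score=score,
        final_rank=frank,
        reffinder_score=rscore,
        reffinder_rank=rrank,
    )
    consensus.recommended = recommend(consensus, vcurve, gn.suitability)
    return PipelineResult(
        normfinder=nf,
        genorm=gn,
        bestkeeper=bk,
        delta_ct=dct,
        vcurve=vcurve,
        consensus=consensus,
    )
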
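"""BestKeeper descriptive stability analysis.

BestKeeper builds a per-sample index as the geometric mean of the candidate
reference genes' Ct values and judges each candidate by (a) its raw Ct
dispersion (SD, CV) and (b) the Pearson correlation ``r`` of its Ct with
the index.  Stable housekeepers have low SD and high ``r``; a gene that
drifts with overall sample-to-sample variation (RNA input, technical
shifts) tracks the index and correlates strongly.

The index is computed over the candidate panel only.  ``sd`` defaults to
the sample standard deviation about the arithmetic mean; the mean absolute
deviation about the geometric mean is available as ``sd_variant="mad-geomean"``
since reimplementations of the original spreadsheet differ on this point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ct_data import CtMatrix
from .errors import AnalysisError

SD_VARIANTS = ("sd", "mad-geomean")


@dataclass
class BestKeeperResult:
    """Per-sample index plus per-gene descriptive statistics and ranks.

    ``stats`` columns: geo_mean, arith_mean, min, max, sd (cycles),
    cv (% of arith_mean), r, p, r_defined, rank_r (descending r,
    undefined-r genes last), rank_sd (ascending sd).
    """

    index: pd.Series
    stats: pd.DataFrame
    sd_variant: str = "sd"


def bestkeeper_index(ct: CtMatrix, panel: Sequence[str] | None = None) -> pd.Series:
    """Per-sample BestKeeper index: geometric mean of candidate Ct values."""
    panel = list(panel) if panel is not None else ct.candidate_genes()
    if not panel:
        raise AnalysisError("empty candidate panel")
    vals = ct.values.loc[panel]
    if vals.isna().any().any():
        raise AnalysisError("missing Ct values present; restrict to complete cases first")
    if (vals.to_numpy() <= 0).any():
        raise AnalysisError("non-positive Ct value; geometric mean undefined")
    idx = np.exp(np.log(vals).mean(axis=0))
    idx.name = "bestkeeper_index"
    return idx


def bestkeeper_stats(
    ct: CtMatrix,
    panel: Sequence[str] | None = None,
    sd_variant: str = "sd",
) -> BestKeeperResult:
    """Full BestKeeper table: dispersion, correlation with the index, ranks.

    A zero-variance gene has undefined ``r`` (flagged ``r_defined=False``,
    ranked after all defined-r genes in input order); p-values come from the
    t distribution with n-2 degrees of freedom.
    """
    if sd_variant not in SD_VARIANTS:
        raise AnalysisError(f"unknown sd_variant {sd_variant!r}; expected one of {SD_VARIANTS}")
    panel = list(panel) if panel is not None else ct.candidate_genes()
    index = bestkeeper_index(ct, panel)
    vals = ct.values.loc[panel]
    n = vals.shape[1]
    if n < 4:
        raise AnalysisError("BestKeeper p-values need at least 4 samples")
    idx_arr = index.to_numpy()
    rows = []
    for gene in panel:
        x = vals.loc[gene].to_numpy(dtype=float)
        geo = float(np.exp(np.log(x).mean()))
        arith = float(x.mean())
        if sd_variant == "sd":
            sd = float(x.std(ddof=1))
        else:
            sd = float(np.abs(x - geo).mean())
        cv = 100.0 * sd / arith
        if x.std(ddof=1) == 0.0 or np.std(idx_arr, ddof=1) == 0.0:
            r, p, defined = np.nan, np.nan, False
        else:
            r, p = stats.pearsonr(x, idx_arr)
            r, p, defined = float(r), float(p), True
        rows.append(
            {
                "gene": gene,
                "geo_mean": geo,
                "arith_mean": arith,
                "min": float(x.min()),
                "max": float(x.max()),
                "sd": sd,
                "cv": cv,
                "r": r,
                "p": p,
                "r_defined": defined,
            }
        )
    table = pd.DataFrame(rows).set_index("gene")
    defined_mask = table["r_defined"].to_numpy()
    rank_r = np.empty(len(panel))
    if defined_mask.any():
        rank_r[defined_mask] = stats.rankdata(-table.loc[defined_mask, "r"].to_numpy(), method="average")
    # undefined-r genes follow, in input order
    n_def = int(defined_mask.sum())
    rank_r[~defined_mask] = n_def + 1 + np.arange((~defined_mask).sum())
    table["rank_r"] = rank_r
    table["rank_sd"] = stats.rankdata(table["sd"].to_numpy(), method="average")
    return BestKeeperResult(index=index, stats=table, sd_variant=sd_variant)
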
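"""NormFinder model-based stability analysis.

NormFinder treats Ct as log-scale expression and decomposes its variation
into a systematic inter-group component (how much a gene's level shifts
between experimental groups) and a stochastic intra-group component (its
residual noise within a group), combining both into a per-gene stability
value ``sv`` — lower is more stable.  A gene can therefore be penalised for
being *biased* between groups even if it is quiet within each group, which
is exactly the failure mode of a dysregulated housekeeper.

Model per group g, gene i, sample j (after centering each gene on its grand
mean): ``y_igj = a_ig + t_gj + e_igj`` with gene-by-group level ``a_ig``,
per-sample effect ``t_gj`` and noise ``e_igj``.  Estimation:

1. two-way residuals ``r = y - rowmean - colmean + grandmean`` per group;
2. intra-group variance ``s2_ig = L/(L-1) * sum_j r^2 / (n_g - 1)`` (the
   L/(L-1) factor corrects the sum-to-zero constraint across genes);
3. inter-group deviation ``d_ig = genemean_ig - grandmean_g`` (sums to zero
   over genes within each group);
4. sampling variance of d: ``v_ig = ((L-1)/L)^2 s2_ig/n_g +
   (1/L^2) sum_{i'!=i} s2_i'g/n_g``;
5. common inter-group variance by method of moments:
   ``gamma2 = max(0, sum d^2 / (G (L-1)) - mean v)``;
6. shrinkage ``d_tilde = d * gamma2 / (gamma2 + v)``;
7. ``sv_i = mean_g [ |d_tilde_ig| + sqrt(gamma2 v_ig / (gamma2 + v_ig)) ]``.

With a single group the inter-group part is undefined and ``sv`` is the
residual standard deviation from the same two-way fit on the whole panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .ct_data import CtMatrix
from .errors import AnalysisError


@dataclass
class NormFinderResult:
    """Per-gene stability values and the variance components behind them.

    ``d_hat``/``d_tilde`` are genes x groups (cycles), ``sigma2`` genes x
    groups intra-group variances (cycles^2), ``gamma2`` the common
    inter-group variance.  ``ranking`` is fractional, 1 = most stable.
    """

    sv: pd.Series
    ranking: pd.Series
    grouped: bool
    d_hat: pd.DataFrame | None = None
    d_tilde: pd.DataFrame | None = None
    sigma2: pd.DataFrame | None = None
    gamma2: float | None = None


def _two_way_residuals(y: np.ndarray) -> np.ndarray:
    """Residuals of the additive gene + sample fit: y - row - col + grand."""
    row = y.mean(axis=1, keepdims=True)
    col = y.mean(axis=0, keepdims=True)
    return y - row - col + y.mean()


def _intra_group_variance(y_g: np.ndarray) -> np.ndarray:
    """Bias-corrected per-gene residual variance within one group."""
    L, n_g = y_g.shape
    r = _two_way_residuals(y_g)
    s2 = (L / (L - 1)) * (r**2).sum(axis=1) / (n_g - 1)
    return np.maximum(s2, 0.0)


def normfinder_stability(
    ct: CtMatrix,
    group_by: str = "group",
    genes: list[str] | None = None,
    grouped: bool | None = None,
) -> NormFinderResult:
    """Compute NormFinder stability values on complete-case Ct data.

    Grouped mode (the default whenever the metadata column has >= 2 levels)
    needs at least 2 samples per group and 3 genes.  With ``grouped=False``
    (or a single group) the ungrouped estimator (residual SD) is used.
    """
    genes = list(genes) if genes is not None else ct.genes
    vals = ct.values.loc[genes]
    if vals.isna().any().any():
        raise AnalysisError("missing Ct values present; restrict to complete cases first")
    if group_by not in ct.meta.columns:
        raise AnalysisError(f"unknown metadata field {group_by!r}")
    labels = ct.meta[group_by]
    group_names = list(dict.fromkeys(labels))
    if grouped is True and len(group_names) < 2:
        raise AnalysisError("grouped NormFinder requires >= 2 groups; use grouped=False for one group")
    if grouped is False:
        group_names = group_names[:1]
        labels = pd.Series(group_names[0], index=labels.index) if group_names else labels
    L = len(genes)
    y = vals.to_numpy(dtype=float)
    y = y - y.mean(axis=1, keepdims=True)  # center each gene on its grand mean

    if len(group_names) == 1:
        if L < 2 or y.shape[1] < 3:
            raise AnalysisError("ungrouped NormFinder needs >= 2 genes and >= 3 samples")
        s2 = _intra_group_variance(y)
        sv = pd.Series(np.sqrt(s2), index=genes, name="sv")
        ranking = pd.Series(rankdata(sv.to_numpy(), method="average"), index=genes)
        return NormFinderResult(sv=sv, ranking=ranking, grouped=False)

    if L < 3:
        raise AnalysisError("grouped NormFinder needs at least 3 genes")
    G = len(group_names)
    cols = {g: [i for i, lab in enumerate(labels) if lab == g] for g in group_names}
    small = [g for g, idx in cols.items() if len(idx) < 2]
    if small:
        raise AnalysisError(f"groups with fewer than 2 samples: {small}")

    s2 = np.empty((L, G))
    d_hat = np.empty((L, G))
    v = np.empty((L, G))
    for k, g in enumerate(group_names):
        y_g = y[:, cols[g]]
        n_g = y_g.shape[1]
        s2[:, k] = _intra_group_variance(y_g)
        gene_means = y_g.mean(axis=1)
        d_hat[:, k] = gene_means - gene_means.mean()
        total = s2[:, k].sum()
        v[:, k] = ((L - 1) / L) ** 2 * s2[:, k] / n_g + (total - s2[:, k]) / (L**2 * n_g)

    gamma2 = max(0.0, (d_hat**2).sum() / (G * (L - 1)) - v.mean())
    if gamma2 == 0.0:
        warnings.warn(
            "no inter-group variance detected (gamma2 = 0); stability values collapse to 0 "
            "and ranking falls back to mean sampling SD",
            UserWarning,
        )
        d_tilde = np.zeros_like(d_hat)
        sv = np.zeros(L)
        order_stat = np.sqrt(v).mean(axis=1)
    else:
        d_tilde = d_hat * gamma2 / (gamma2 + v)
        sv = (np.abs(d_tilde) + np.sqrt(gamma2 * v / (gamma2 + v))).mean(axis=1)
        order_stat = sv

    sv_s = pd.Series(sv, index=genes, name="sv")
    ranking = pd.Series(rankdata(order_stat, method="average"), index=genes)
    return NormFinderResult(
        sv=sv_s,
        ranking=ranking,
        grouped=True,
        d_hat=pd.DataFrame(d_hat, index=genes, columns=group_names),
        d_tilde=pd.DataFrame(d_tilde, index=genes, columns=group_names),
        sigma2=pd.DataFrame(s2, index=genes, columns=group_names),
        gamma2=gamma2,
    )


def intergroup_variation(ct: CtMatrix, group_by: str = "group", genes: list[str] | None = None) -> pd.DataFrame:
    """Inter-group deviations and intra-group SDs for diagnostic plots.

    Returns a long table (gene, group, d_hat, intra_sd): ``d_hat`` is the
    estimated deviation of the gene's level in that group from the group
    consensus (cycles, sums to zero over genes within a group) and
    ``intra_sd`` the within-group residual SD.
    """
    res = normfinder_stability(ct, group_by=group_by, genes=genes)
    if not res.grouped:
        raise AnalysisError("inter-group variation requires at least 2 groups")
    rows = []
    for g in res.d_hat.columns:
        for gene in res.d_hat.index:
            rows.append(
                {
                    "gene": gene,
                    "group": g,
                    "d_hat": float(res.d_hat.loc[gene, g]),
                    "intra_sd": float(np.sqrt(res.sigma2.loc[gene, g])),
                }
            )
    return pd.DataFrame(rows)
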
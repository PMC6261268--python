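"""Per-gene expression aging slopes and downstream comparisons.

Expression change with replicative age is modeled as an exponential fit to
bud-scar counts: ordinary least squares of log2(TPM + pseudocount) on
``ave_budscars`` with replicate (batch) and strain covariates, so the
coefficient is a rate of change per cell division directly comparable to
the chromatin aging slopes.  Companions: average-linkage hierarchical
clustering under the uncentered Pearson (cosine) distance, moving-window
averages for ordered overlays, growth-rate-slope (GRS) comparison with a
stress-independent gene filter, and telomere-distance trends.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .diffacc import SingularDesignError, _design_matrix, bh_adjust
from .genome import GenomeAnnotation

__all__ = [
    "fit_expression_slopes",
    "cluster_genes",
    "moving_average",
    "grs_comparison",
    "telomere_distance_profile",
]


def fit_expression_slopes(
    tpm: pd.DataFrame,
    design: pd.DataFrame,
    model: str = "common",
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """OLS aging slopes on log2(TPM + pseudocount), all genes at once.

    ``design`` rows correspond to ``tpm`` columns, with ``replicate,
    strain, ave_budscars`` columns.  Wald t tests with residual df; BH q
    across genes.  Interaction model returns per-strain ``beta_<s>`` etc.
    """
    design = design.reset_index(drop=True)
    if design["ave_budscars"].nunique() < 2:
        raise ValueError("design needs at least two distinct ave_budscars values")
    X, age_cols = _design_matrix(design, model)
    Xm = X.to_numpy()
    n, p_dim = Xm.shape
    if n != tpm.shape[1]:
        raise ValueError("design rows must match tpm columns")
    dof = n - p_dim
    if dof <= 0:
        raise SingularDesignError("no residual degrees of freedom")
    Y = np.log2(tpm.to_numpy(dtype=float) + pseudocount).T  # samples x genes

    XtX_inv = np.linalg.inv(Xm.T @ Xm)
    B = XtX_inv @ Xm.T @ Y  # p x genes
    resid = Y - Xm @ B
    sigma2 = (resid**2).sum(axis=0) / dof
    col_idx = {c: i for i, c in enumerate(X.columns)}

    out = {}
    for c in age_cols:
        tag = "" if model == "common" else f"_{c[4:-1]}"
        j = col_idx[c]
        beta = B[j]
        se = np.sqrt(sigma2 * XtX_inv[j, j])
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        p = 2 * stats.t.sf(np.abs(tstat), dof)
        p = np.where(se > 0, p, np.where(beta == 0, 1.0, 0.0))
        out[f"beta{tag}"] = beta
        out[f"se{tag}"] = se
        out[f"p{tag}"] = p
        out[f"q{tag}"] = bh_adjust(p)
    res = pd.DataFrame(out, index=tpm.index)
    if model == "common":
        res["direction"] = np.where(res["beta"] > 0, "up", np.where(res["beta"] < 0, "down", "flat"))
    return res


def cluster_genes(matrix: pd.DataFrame) -> dict:
    """Average-linkage hierarchical clustering of genes.

    Distance is 1 minus the uncentered Pearson correlation (equivalently
    the cosine distance).  Rows with zero norm are excluded with a warning;
    ties break deterministically by input order (stable condensed-index
    ordering).  Returns ``{"linkage": Z, "leaf_order": kept row labels in
    dendrogram order, "kept": row labels used, "excluded": dropped}``.
    """
    X = matrix.to_numpy(dtype=float)
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} zero-norm rows from clustering")
    kept = matrix.index[~zero]
    X = X[~zero]
    if len(X) < 2:
        raise ValueError("need at least two non-degenerate rows to cluster")
    d = np.clip(pdist(X, metric="cosine"), 0.0, None)
    Z = linkage(d, method="average")
    order = leaves_list(Z)
    return {
        "linkage": Z,
        "leaf_order": list(kept[order]),
        "kept": list(kept),
        "excluded": list(matrix.index[zero]),
    }


def moving_average(values, window: int = 100) -> np.ndarray:
    """Centered moving mean with shrinking edge windows.

    Missing values are excluded per window; a window longer than the vector
    collapses to the global mean.  The 100-bin default matches the
    moving-window overlay convention for ordered gene lists.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    s = pd.Series(np.asarray(values, dtype=float))
    if window > len(s):
        return np.full(len(s), s.mean())
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def grs_comparison(
    slopes: pd.DataFrame,
    grs: pd.Series,
    esr_induced: set | None = None,
    bound: float = 5.0,
    q_cut: float = 0.05,
    min_overlap: int = 50,
) -> dict:
    """Compare aging slopes with growth rate slopes (GRS).

    GRS is the published per-gene slope of expression on culture growth
    rate; genes with negative GRS rise when growth slows.  Returns the
    merged table, the Pearson r over all intersecting genes, r over the
    ESR-induced subset when given, and the *stress-independent* gene set:
    significant agers (q < ``q_cut``) whose |GRS| < ``bound``, i.e. genes
    whose age trend is not explained by the growth-rate/stress axis.
    """
    common = slopes.index.intersection(grs.index)
    if len(common) < min_overlap:
        raise ValueError(f"only {len(common)} genes shared between slopes and GRS (< {min_overlap})")
    tab = pd.DataFrame(
        {"beta": slopes.loc[common, "beta"], "q": slopes.loc[common, "q"], "grs": grs.loc[common]}
    ).dropna()
    r_all = float(stats.pearsonr(tab["beta"], tab["grs"])[0])
    out = {"table": tab, "r_all": r_all, "n": len(tab)}
    if esr_induced is not None:
        sub = tab.loc[tab.index.isin(esr_induced)]
        out["r_esr_induced"] = (
            float(stats.pearsonr(sub["beta"], sub["grs"])[0]) if len(sub) > 2 else np.nan
        )
    stress_ind = tab[(tab["q"] < q_cut) & (tab["grs"].abs() < bound)]
    out["stress_independent"] = set(stress_ind.index)
    return out


def telomere_distance_profile(
    slopes: pd.DataFrame,
    genome: GenomeAnnotation,
    n_bins: int = 8,
    min_distance: int = 1000,
) -> pd.DataFrame:
    """Median aging slope versus distance to the nearest chromosome end.

    Distance of a gene = min(TSS, chrom_length - TSS); genes are grouped
    into log-spaced distance bins and the per-bin median and IQR of slopes
    reported.  Subtelomeric silencing loss shows up as an elevated median
    in the nearest-end bins.
    """
    genes = genome.genes.set_index("gene_id")
    common = slopes.index.intersection(genes.index)
    tss = genes.loc[common, "tss"].to_numpy(dtype=float)
    lens = genes.loc[common, "chrom"].map(genome.chrom_lengths).to_numpy(dtype=float)
    dist = np.minimum(tss, lens - tss)
    beta = slopes.loc[common, "beta"].to_numpy()
    edges = np.geomspace(max(min_distance, 1), max(dist.max(), min_distance + 1), n_bins + 1)
    edges[0] = 0.0
    idx = np.clip(np.digitize(dist, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = idx == b
        if m.any():
            vals = beta[m]
            rows.append(
                (edges[b], edges[b + 1], int(m.sum()), float(np.median(vals)),
                 float(np.percentile(vals, 25)), float(np.percentile(vals, 75)))
            )
        else:
            rows.append((edges[b], edges[b + 1], 0, np.nan, np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["dist_lo", "dist_hi", "n_genes", "median_slope", "q1", "q3"]
    )
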
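"""Bin-level differential accessibility: aging slopes and enrichment.

The genome is tiled into non-overlapping 100-bp bins; per-bin insertion
counts are modeled with a negative-binomial log-linear regression

    log E[count_ij] = log(factor_ij) + replicate_j + strain_j + beta_i * age_j

where age is the average bud-scar count of the sample and ``factor`` is a
bin- and sample-specific normalization factor derived from per-sample
quantile normalization.  ``beta_i`` is the *aging slope*: the per-cell-
division rate of log accessibility change.  An interaction model
(``strain:age``) yields per-strain slopes.  Dispersion is estimated per bin
by method of moments (no shrinkage trend), coefficients by IRLS, and Wald
statistics are referred to a t distribution with residual degrees of
freedom — at a dozen samples the normal reference is noticeably
anti-conservative.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .genome import GenomeAnnotation

__all__ = [
    "quantile_norm_factors",
    "fit_aging_slopes",
    "bh_adjust",
    "classify_bins",
    "assign_bins_to_genes",
    "hypergeom_enrich",
]


class SingularDesignError(ValueError):
    pass


def quantile_norm_factors(bins: pd.DataFrame) -> pd.DataFrame:
    """Per-bin, per-sample normalization factors from quantile normalization.

    Each sample's counts are quantile-normalized against the across-sample
    mean order-statistic reference (ties averaged); the factor is
    ``raw / quantile_normalized`` where the normalized value is positive,
    else 1.  Factors are strictly positive by construction.
    """
    X = bins.to_numpy(dtype=float)
    n, m = X.shape
    if m < 2:
        raise ValueError("need at least two samples")
    if (X.sum(axis=0) == 0).any():
        raise ValueError("all-zero sample column")
    ref = np.sort(X, axis=0).mean(axis=1)
    Q = np.empty_like(X)
    ranks_axis = np.arange(1, n + 1, dtype=float)
    for j in range(m):
        r = stats.rankdata(X[:, j], method="average")
        Q[:, j] = np.interp(r, ranks_axis, ref)
    factors = np.where(Q > 0, np.divide(X, Q, out=np.ones_like(X), where=Q > 0), 1.0)
    factors[factors <= 0] = 1.0
    return pd.DataFrame(factors, index=bins.index, columns=bins.columns)


def _design_matrix(design: pd.DataFrame, model: str) -> tuple[pd.DataFrame, list[str]]:
    """Build the regression design: intercept + replicate + strain dummies
    + age (+ per-strain age for the interaction model).

    Returns (X, age_columns) where age_columns lists, in order, the columns
    whose coefficients are per-strain aging slopes (a single shared column
    for the common model).
    """
    d = design.reset_index(drop=True)
    X = pd.DataFrame({"Intercept": np.ones(len(d))})
    for r in sorted(d["replicate"].unique())[1:]:
        X[f"replicate[{r}]"] = (d["replicate"] == r).astype(float)
    strains = sorted(d["strain"].unique())
    for s in strains[1:]:
        X[f"strain[{s}]"] = (d["strain"] == s).astype(float)
    if model == "common":
        X["ave_budscars"] = d["ave_budscars"].astype(float)
        age_cols = ["ave_budscars"]
    elif model == "interaction":
        age_cols = []
        for s in strains:
            col = f"age[{s}]"
            X[col] = np.where(d["strain"] == s, d["ave_budscars"].astype(float), 0.0)
            age_cols.append(col)
    else:
        raise ValueError(f"unknown model {model!r}")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify a dependent column set via the SVD null space
        _, sv, vt = np.linalg.svd(X.to_numpy())
        null = vt[-1]
        cols = [c for c, v in zip(X.columns, null) if abs(v) > 1e-8]
        raise SingularDesignError(f"design matrix is singular; collinear columns: {cols}")
    return X, age_cols


def _moment_dispersion(y: np.ndarray, mu: np.ndarray, n_params: int, floor: float = 1e-8) -> float:
    """Method-of-moments NB dispersion: the alpha at which the Pearson
    statistic sum (y-mu)^2 / (mu + alpha mu^2) equals the residual degrees
    of freedom.  No shrinkage across bins."""
    dof = max(len(y) - n_params, 1)

    def excess(a: float) -> float:
        return float(((y - mu) ** 2 / (mu + a * mu**2)).sum() - dof)

    if excess(0.0) <= 0:
        return floor
    hi = 1.0
    while excess(hi) > 0 and hi < 1e6:
        hi *= 4
    alpha = optimize.brentq(excess, 0.0, hi)
    return float(max(alpha, floor))


def fit_aging_slopes(
    bins: pd.DataFrame,
    design: pd.DataFrame,
    factors: pd.DataFrame | None = None,
    model: str = "common",
    dispersion_floor: float = 1e-8,
) -> pd.DataFrame:
    """Negative-binomial aging-slope regression for every bin.

    Parameters
    ----------
    bins : DataFrame
        Bins x samples matrix of raw (integer) insertion counts.
    design : DataFrame
        One row per sample (same order as columns) with ``replicate,
        strain, ave_budscars`` columns.
    factors : DataFrame, optional
        Bin x sample normalization factors (offsets enter as log factors);
        defaults to all ones.
    model : "common" or "interaction"

    Returns a DataFrame indexed like ``bins`` with ``beta, se, p, q,
    direction`` for the common model, or per-strain ``beta_<s>, se_<s>,
    p_<s>, q_<s>`` columns for the interaction model.  All-zero bins are
    skipped (NaN results, ``tested = False``); q-values are BH-adjusted
    over the tested bins only.
    """
    design = design.reset_index(drop=True)
    if design["ave_budscars"].nunique() < 2:
        raise ValueError("design needs at least two distinct ave_budscars values")
    X, age_cols = _design_matrix(design, model)
    Xm = X.to_numpy()
    n, p_dim = Xm.shape
    dof = max(n - p_dim, 1)
    if factors is None:
        off_all = np.zeros((len(bins), n))
    else:
        off_all = np.log(factors.to_numpy(dtype=float))
    Y = bins.to_numpy(dtype=float)

    col_idx = {c: i for i, c in enumerate(X.columns)}
    out: dict[str, np.ndarray] = {}
    for c in age_cols:
        tag = "" if model == "common" else f"_{c[4:-1]}"
        out[f"beta{tag}"] = np.full(len(bins), np.nan)
        out[f"se{tag}"] = np.full(len(bins), np.nan)
        out[f"p{tag}"] = np.full(len(bins), np.nan)
    tested = np.zeros(len(bins), dtype=bool)
    dispersion = np.full(len(bins), np.nan)

    for i in range(len(bins)):
        y = Y[i]
        if y.sum() == 0:
            continue
        offset = off_all[i]
        try:
            with warnings.catch_warnings():
                # low-count bins can trigger benign separation/overflow
                # warnings inside IRLS; their results are NaN-guarded below
                warnings.simplefilter("ignore")
                pois = sm.GLM(y, Xm, family=sm.families.Poisson(), offset=offset).fit()
                alpha = _moment_dispersion(y, pois.fittedvalues, p_dim, floor=dispersion_floor)
                res = sm.GLM(
                    y, Xm, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
                ).fit(start_params=pois.params)
        except Exception:
            continue
        if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
            continue
        tested[i] = True
        dispersion[i] = alpha
        for c in age_cols:
            tag = "" if model == "common" else f"_{c[4:-1]}"
            j = col_idx[c]
            b = res.params[j]
            se = res.bse[j]
            out[f"beta{tag}"][i] = b
            out[f"se{tag}"][i] = se
            out[f"p{tag}"][i] = 2 * stats.t.sf(abs(b / se), dof) if se > 0 else np.nan

    result = pd.DataFrame(out, index=bins.index)
    result["dispersion"] = dispersion
    result["tested"] = tested
    for c in age_cols:
        tag = "" if model == "common" else f"_{c[4:-1]}"
        q = np.full(len(bins), np.nan)
        mask = tested & np.isfinite(result[f"p{tag}"].to_numpy())
        if mask.any():
            q[mask] = bh_adjust(result.loc[mask, f"p{tag}"].to_numpy())
        result[f"q{tag}"] = q
        result[f"direction{tag}"] = np.where(
            result[f"beta{tag}"] > 0, "opening", np.where(result[f"beta{tag}"] < 0, "closing", "flat")
        )
        result.loc[~tested, f"direction{tag}"] = ""
    return result


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _overlaps(bin_start: np.ndarray, bin_end: np.ndarray, iv: list[tuple[int, int]]) -> np.ndarray:
    hit = np.zeros(len(bin_start), dtype=bool)
    for s, e in iv:
        hit |= (bin_start < e) & (bin_end > s)
    return hit


def _parse_bin_index(index: pd.Index) -> pd.DataFrame:
    parts = index.to_series().str.extract(r"(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)")
    parts["start"] = parts["start"].astype(int)
    parts["end"] = parts["end"].astype(int)
    return parts


def promoter_intervals(genome: GenomeAnnotation, promoter_length: int = 400) -> pd.DataFrame:
    """Strand-aware promoters: up to ``promoter_length`` bp upstream of each
    TSS, clipped to the chromosome."""
    rows = []
    for g in genome.genes.itertuples(index=False):
        if g.strand == "+":
            s, e = max(g.tss - promoter_length, 0), g.tss
        else:
            s, e = g.tss + 1, min(g.tss + 1 + promoter_length, genome.chrom_lengths[g.chrom])
        rows.append((g.chrom, s, e, g.gene_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def classify_bins(
    results: pd.DataFrame,
    genome: GenomeAnnotation,
    q_cut: float = 1e-6,
    promoter_length: int = 400,
) -> tuple[pd.Series, pd.DataFrame]:
    """Label significant bins by genomic context and tabulate directions.

    A bin is assigned by 1-bp-overlap precedence ARS > promoter > gene body
    > other.  Returns ``(category per significant bin, summary)`` where the
    summary has, per category, the fraction of significant bins opening and
    closing and the bin count.
    """
    sig = results[(results["q"] < q_cut) & results["tested"]]
    coords = _parse_bin_index(sig.index)
    promoters = promoter_intervals(genome, promoter_length)
    category = pd.Series("other", index=sig.index, dtype=object)
    for chrom in coords["chrom"].unique():
        m = (coords["chrom"] == chrom).to_numpy()
        bs = coords.loc[m, "start"].to_numpy()
        be = coords.loc[m, "end"].to_numpy()
        gene_iv = [
            (g.start, g.end) for g in genome.genes.itertuples(index=False) if g.chrom == chrom
        ]
        prom_iv = [
            (r.start, r.end) for r in promoters.itertuples(index=False) if r.chrom == chrom
        ]
        ars_iv = [
            (r.start, r.end) for r in genome.ars_intervals.itertuples(index=False) if r.chrom == chrom
        ]
        lab = np.full(m.sum(), "other", dtype=object)
        lab[_overlaps(bs, be, gene_iv)] = "gene_body"
        lab[_overlaps(bs, be, prom_iv)] = "promoter"
        lab[_overlaps(bs, be, ars_iv)] = "ARS"
        category.iloc[np.where(m)[0]] = lab
    rows = []
    for cat in ["ARS", "promoter", "gene_body", "other"]:
        idx = category[category == cat].index
        nsig = len(idx)
        if nsig:
            opening = float((sig.loc[idx, "beta"] > 0).mean())
        else:
            opening = np.nan
        rows.append((cat, nsig, opening, 1 - opening if nsig else np.nan))
    summary = pd.DataFrame(rows, columns=["category", "n_bins", "frac_opening", "frac_closing"])
    return category, summary


def assign_bins_to_genes(
    bin_index: pd.Index, genome: GenomeAnnotation, promoter_length: int = 400
) -> pd.Series:
    """Map each bin to the gene whose body (or, failing that, promoter) it
    intersects.  Bins touching neither get NaN; ties resolve to the first
    gene in annotation order."""
    coords = _parse_bin_index(bin_index)
    promoters = promoter_intervals(genome, promoter_length)
    out = pd.Series(np.nan, index=bin_index, dtype=object)
    for chrom in coords["chrom"].unique():
        m = (coords["chrom"] == chrom).to_numpy()
        bs = coords.loc[m, "start"].to_numpy()
        be = coords.loc[m, "end"].to_numpy()
        assigned = np.full(m.sum(), None, dtype=object)
        for g in genome.genes[genome.genes.chrom == chrom].itertuples(index=False):
            hit = (bs < g.end) & (be > g.start) & (assigned == None)  # noqa: E711
            assigned[hit] = g.gene_id
        for r in promoters[promoters.chrom == chrom].itertuples(index=False):
            hit = (bs < r.end) & (be > r.start) & (assigned == None)  # noqa: E711
            assigned[hit] = r.gene_id
        out.iloc[np.where(m)[0]] = assigned
    return out


def hypergeom_enrich(
    selected_genes: set, target_genes: set, universe: set
) -> dict[str, float]:
    """Upper-tail hypergeometric enrichment of ``target_genes`` within
    ``selected_genes`` against ``universe``.

    Returns ``p`` = P(overlap >= observed), ``fold`` =
    (overlap/|selected|) / (|target|/|universe|) (NaN when degenerate), and
    the overlap count.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected_genes) & universe
    target = set(target_genes) & universe
    k = len(selected & target)
    M, n, N = len(universe), len(target), len(selected)
    if n == 0 or N == 0:
        return {"p": 1.0, "fold": float("nan"), "overlap": k}
    p = float(stats.hypergeom.sf(k - 1, M, n, N))
    fold = (k / N) / (n / M)
    return {"p": min(p, 1.0), "fold": fold, "overlap": k}
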
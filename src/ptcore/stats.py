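"""Differential statistics: precision-weighted empirical-Bayes moderated t
linear models, rank products, exact tests and clustering.

The moderated-t fit follows the standard count pipeline for windowed
coverage: log2-CPM transformation, a mean-variance trend fitted with a
locally-weighted smoother that yields per-observation precision weights,
per-feature weighted least squares, and empirical-Bayes shrinkage of the
residual variances toward a common prior estimated by moment matching of
the log-variance distribution.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from scipy.cluster.hierarchy import linkage
from scipy.interpolate import interp1d
from scipy.spatial.distance import squareform
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Fisher's exact test

@dataclass
class FisherResult:
    oddsratio: float
    p: float
    ci_low: float
    ci_high: float
    table: tuple[int, int, int, int]


def fisher_exact(table) -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 table ``(a, b, c, d)``.

    The two-sided p sums hypergeometric probabilities of all tables (same
    margins) whose probability does not exceed the observed one (relative
    slack 1e-7).  OR is the cross-product ``ad/bc``; when any cell is zero,
    0.5 is added to every cell for both the OR and the CI (Haldane
    correction).  CI is the 95% Wald interval on the log OR.
    """
    a, b, c, d = (int(x) for x in np.asarray(table).ravel())
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        raise ValueError("degenerate 2x2 table (all-zero margin)")
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    p = float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = a, b, c, d
    oddsratio = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    log_or = math.log(oddsratio)
    return FisherResult(
        oddsratio=oddsratio,
        p=p,
        ci_low=math.exp(log_or - 1.96 * se),
        ci_high=math.exp(log_or + 1.96 * se),
        table=(a, b, c, d),
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum

def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def wilcoxon_rank_sum(x, y, exact_limit: int = 200_000) -> tuple[float, float]:
    """Mann-Whitney U with midranks for ties; returns ``(U, two-sided p)``.

    Exact p by enumeration of rank assignments when ``C(n+m, m)`` does not
    exceed ``exact_limit`` (covers all n+m <= 20 and e.g. 10 vs 10);
    otherwise a normal approximation with continuity and tie correction.
    The two-sided exact p uses the symmetric tail criterion
    ``P(|U - mn/2| >= |u - mn/2|)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty input")
    nx, ny = len(x), len(y)
    ranks = _midranks(np.concatenate([x, y]))
    rx = ranks[:nx].sum()
    u = rx - nx * (nx + 1) / 2.0
    mn = nx * ny
    if math.comb(nx + ny, nx) <= exact_limit:
        dev_obs = abs(u - mn / 2.0)
        count = total = 0
        base = np.arange(1, nx + 1).sum()
        for comb in itertools.combinations(range(nx + ny), nx):
            u_perm = ranks[list(comb)].sum() - nx * (nx + 1) / 2.0
            total += 1
            if abs(u_perm - mn / 2.0) >= dev_obs - 1e-9:
                count += 1
        return float(u), count / total
    # normal approximation with tie correction
    n = nx + ny
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sd = math.sqrt(mn / 12.0 * (n + 1 - tie_term))
    if sd == 0:
        return float(u), 1.0
    z = (abs(u - mn / 2.0) - 0.5) / sd
    return float(u), float(min(1.0, 2 * sps.norm.sf(max(z, 0.0))))


# ---------------------------------------------------------------------------
# Empirical-Bayes moderated linear model

def make_design(conditions, blocks=None, baseline=None):
    """Build a design matrix for a two-condition comparison with optional
    blocking factor (e.g. cell-line pair).

    Returns ``(X, contrast, colnames)``; the contrast extracts the
    condition effect (second level minus baseline).
    """
    conditions = list(conditions)
    levels = sorted(set(conditions))
    if len(levels) != 2:
        raise ValueError("exactly two condition levels required")
    if baseline is None:
        baseline = levels[0]
    other = [l for l in levels if l != baseline][0]
    cols = [np.ones(len(conditions)), np.array([1.0 if c == other else 0.0 for c in conditions])]
    names = ["intercept", f"{other}-vs-{baseline}"]
    if blocks is not None:
        blocks = list(blocks)
        for lvl in sorted(set(blocks))[1:]:
            cols.append(np.array([1.0 if b == lvl else 0.0 for b in blocks]))
            names.append(f"block_{lvl}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design")
    contrast = np.zeros(X.shape[1])
    contrast[1] = 1.0
    return X, contrast, names


def trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve ``trigamma(y) = x`` by Newton iteration (monotone decreasing)."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def estimate_prior_variance(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching estimate of (d0, s0^2) from residual variances.

    Matches the mean and variance of ``log(s2)`` to the scaled-F model:
    ``e = log(s2) - digamma(df/2) + log(df/2)``; then
    ``trigamma(d0/2) = var(e) - trigamma(df/2)`` (inverted by Newton) and
    ``s0^2 = exp(mean(e) + digamma(d0/2) - log(d0/2))``.  Returns
    ``(inf, exp(mean(e)))`` when the trigamma equation has no positive
    solution (no evidence of variance heterogeneity).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return math.inf, float(np.mean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return math.inf, float(math.exp(e_mean))
    d0 = 2.0 * trigamma_inverse(e_var)
    s0_2 = math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return d0, float(s0_2)


def _log2_cpm(counts: np.ndarray, lib_sizes: np.ndarray) -> np.ndarray:
    return np.log2((counts + 0.5) / (lib_sizes + 1.0) * 1e6)


def moderated_fit(
    counts,
    design: np.ndarray,
    contrast: np.ndarray,
    weights: bool = True,
    lfc_cut: float = 2.0,
    fdr_cut: float = 0.001,
    lib_sizes: np.ndarray | None = None,
    d0_override: float | None = None,
    span: float = 0.5,
    feature_ids=None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated-t differential test on a count matrix.

    Parameters
    ----------
    counts : (features x samples) array of non-negative counts.
    design : (samples x p) design matrix (full column rank).
    contrast : length-p contrast vector; the reported log2FC is its estimate.
    weights : fit a mean-variance trend on sqrt(residual SD) vs mean
        log2 count and use predicted-SD^-4 precision weights.
    d0_override : force the prior degrees of freedom (0 disables shrinkage
        entirely, reproducing the ordinary weighted t).

    Returns a DataFrame with log2FC, t, p, FDR, df, call and attrs
    ``d0``, ``s0_2``, ``residual_df``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be 2-D (features x samples)")
    G, n = counts.shape
    X = np.asarray(design, dtype=float)
    p_cols = X.shape[1]
    if np.linalg.matrix_rank(X) < p_cols:
        raise ValueError("rank-deficient design")
    resid_df = n - p_cols
    if resid_df < 1:
        raise ValueError("no residual degrees of freedom")
    # each design "group" (unique row) needs >= 2 samples for a variance
    _, grp_counts = np.unique(X, axis=0, return_counts=True)
    if np.min(grp_counts) < 2:
        raise ValueError("each design cell needs >= 2 samples")
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if np.any(lib_sizes <= 0):
        raise ValueError("library size must be positive")

    y = _log2_cpm(counts, lib_sizes)
    pinv = np.linalg.pinv(X)
    beta = y @ pinv.T                      # G x p
    fitted = beta @ X.T                    # G x n
    resid = y - fitted
    s2_ols = (resid**2).sum(axis=1) / resid_df

    if weights:
        # mean-variance trend: sqrt(residual SD) vs average log2 count
        mean_log_count = y.mean(axis=1) + np.log2(np.exp(np.mean(np.log(lib_sizes + 1.0)))) - np.log2(1e6)
        sqrt_sd = np.sqrt(np.sqrt(np.maximum(s2_ols, 1e-12)))
        trend = lowess(sqrt_sd, mean_log_count, frac=span, it=3, return_sorted=True)
        tx, ty = trend[:, 0], trend[:, 1]
        tx, uniq = np.unique(tx, return_index=True)
        ty = ty[uniq]
        if len(tx) < 2:
            predict = lambda v: np.full_like(v, float(ty[0]))
        else:
            predict = interp1d(tx, ty, bounds_error=False, fill_value=(ty[0], ty[-1]))
        # per-observation fitted log2 count -> predicted sqrt-SD -> weight
        fitted_count = fitted + (np.log2(lib_sizes + 1.0) - np.log2(1e6))[None, :]
        pred = np.clip(np.asarray(predict(fitted_count.ravel())).reshape(G, n), 1e-3, None)
        W = pred**-4.0
    else:
        W = np.ones_like(y)

    # per-feature weighted least squares (vectorized over features)
    XtWX = np.einsum("gs,sp,sq->gpq", W, X, X)
    XtWy = np.einsum("gs,sp,gs->gp", W, X, y)
    XtWX_inv = np.linalg.inv(XtWX)
    beta_w = np.einsum("gpq,gq->gp", XtWX_inv, XtWy)
    fitted_w = np.einsum("gp,sp->gs", beta_w, X)
    resid_w = y - fitted_w
    s2 = np.einsum("gs,gs->g", W, resid_w**2) / resid_df
    cvec = np.asarray(contrast, dtype=float)
    est = beta_w @ cvec
    vfac = np.einsum("p,gpq,q->g", cvec, XtWX_inv, cvec)

    if d0_override is not None:
        d0 = float(d0_override)
        s0_2 = float(np.median(s2[s2 > 0])) if np.any(s2 > 0) else 1.0
    else:
        d0, s0_2 = estimate_prior_variance(s2, resid_df)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + resid_df * s2) / (d0 + resid_df)
        df_total = d0 + resid_df
    if d0 == 0:
        s2_post = s2
        df_total = resid_df

    se = np.sqrt(np.maximum(s2_post * vfac, 1e-300))
    t = est / se
    if math.isinf(df_total):
        pvals = 2 * sps.norm.sf(np.abs(t))
    else:
        pvals = 2 * sps.t.sf(np.abs(t), df_total)
    fdr = bh_fdr(pvals)
    call = np.where(
        (fdr < fdr_cut) & (est > lfc_cut), "up",
        np.where((fdr < fdr_cut) & (est < -lfc_cut), "down", "ns"),
    )
    out = pd.DataFrame(
        {
            "feature": feature_ids if feature_ids is not None else np.arange(G),
            "log2FC": est,
            "t": t,
            "p": pvals,
            "FDR": fdr,
            "s2": s2,
            "s2_post": s2_post,
            "call": call,
        }
    )
    out.attrs["d0"] = d0
    out.attrs["s0_2"] = s0_2
    out.attrs["residual_df"] = resid_df
    out.attrs["df_total"] = df_total
    out.attrs["lfc_cut"] = lfc_cut
    out.attrs["fdr_cut"] = fdr_cut
    return out


def moderated_two_group(a: np.ndarray, b: np.ndarray) -> pd.DataFrame:
    """Empirical-Bayes moderated t on already-transformed values (e.g. the
    windowed log2 damage signal): two-group comparison b minus a with
    pooled per-feature variances shrunk toward the moment-matched prior.

    ``a``/``b`` are features x replicates arrays.  Returns a DataFrame with
    delta, t, p and attrs ``d0``, ``s0_2``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[0] != b.shape[0]:
        raise ValueError("a and b must be feature x replicate arrays")
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 replicates per group")
    df = n1 + n2 - 2
    delta = b.mean(axis=1) - a.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df
    d0, s0_2 = estimate_prior_variance(s2, df)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(np.maximum(s2_post * (1.0 / n1 + 1.0 / n2), 1e-300))
    t = delta / se
    if math.isinf(df_total):
        p = 2 * sps.norm.sf(np.abs(t))
    else:
        p = 2 * sps.t.sf(np.abs(t), df_total)
    out = pd.DataFrame({"delta": delta, "t": t, "p": p})
    out.attrs.update({"d0": d0, "s0_2": s0_2, "df_total": df_total})
    return out


# ---------------------------------------------------------------------------
# Rank product

def rank_product(
    log2fc: pd.DataFrame,
    direction: str = "up",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank-product meta-analysis over k independent pair comparisons.

    ``log2fc`` is a genes x pairs DataFrame of per-pair log2 fold changes.
    Genes are ranked within each pair (rank 1 = most extreme in the chosen
    ``direction``); RP is the geometric mean of ranks.  The permutation p
    for each gene is the fraction of null RPs (ranks permuted independently
    per pair, pooled over genes) at or below the observed value, with +1
    smoothing.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if log2fc.shape[1] < 2:
        raise ValueError("rank product needs >= 2 pairs")
    if log2fc.isna().any().any():
        raise ValueError("gene sets mismatch (missing values)")
    G, k = log2fc.shape
    vals = log2fc.to_numpy(dtype=float)
    if direction == "up":
        vals = -vals
    ranks = np.argsort(np.argsort(vals, axis=0), axis=0) + 1.0
    rp = np.exp(np.log(ranks).sum(axis=1) / k)

    rng = np.random.default_rng(seed)
    null_log_rp = np.empty((n_permutations, G))
    base = np.log(np.arange(1, G + 1, dtype=float))
    for i in range(n_permutations):
        acc = np.zeros(G)
        for _ in range(k):
            acc += base[rng.permutation(G)]
        null_log_rp[i] = acc / k
    null = np.sort(null_log_rp.ravel())
    counts = np.searchsorted(null, np.log(rp) + 1e-12, side="right")
    pvals = (counts + 1.0) / (null.size + 1.0)
    out = pd.DataFrame(
        {"RP": rp, "p": pvals, "FDR": bh_fdr(pvals)}, index=log2fc.index
    )
    out.attrs["direction"] = direction
    out.attrs["n_permutations"] = n_permutations
    return out


def rank_product_exhaustive(log2fc: pd.DataFrame, direction: str = "up") -> pd.DataFrame:
    """Exhaustive-permutation oracle for tiny instances (k small, G <= ~6)."""
    G, k = log2fc.shape
    vals = log2fc.to_numpy(dtype=float)
    if direction == "up":
        vals = -vals
    ranks = np.argsort(np.argsort(vals, axis=0), axis=0) + 1.0
    rp_obs = np.exp(np.log(ranks).sum(axis=1) / k)
    perms = list(itertools.permutations(range(1, G + 1)))
    null = []
    for combo in itertools.product(perms, repeat=k):
        mat = np.array(combo, dtype=float).T
        null.extend(np.exp(np.log(mat).sum(axis=1) / k))
    null = np.sort(np.array(null))
    counts = np.searchsorted(null, rp_obs + 1e-12, side="right")
    pvals = (counts + 1.0) / (null.size + 1.0)
    return pd.DataFrame({"RP": rp_obs, "p": pvals}, index=log2fc.index)


# ---------------------------------------------------------------------------
# Correlation clustering / Z-scaling

def zscale_rows(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row (x - mean) / SD; constant rows are dropped.

    Returns ``(scaled, kept_row_indices)``.
    """
    m = np.asarray(matrix, dtype=float)
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, ddof=1, keepdims=True)
    keep = sd.ravel() > 0
    return (m[keep] - mu[keep]) / sd[keep], np.flatnonzero(keep)


def correlation_cluster(
    matrix,
    method: str = "average",
    zscale: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Pairwise Spearman correlation of samples (columns) and hierarchical
    clustering.

    With ``zscale`` off, samples are clustered on distance ``1 - rho``.
    With ``zscale`` on, rows are Z-scaled and samples clustered on
    Euclidean distance of the scaled columns (the heatmap dialect used for
    small gene panels).  ``method`` is a scipy linkage method ('average',
    'ward', ...).  Returns ``(correlation DataFrame, linkage matrix)``.
    """
    if isinstance(matrix, pd.DataFrame):
        cols = list(matrix.columns)
        m = matrix.to_numpy(dtype=float)
    else:
        m = np.asarray(matrix, dtype=float)
        cols = list(range(m.shape[1]))
    if m.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    rho = sps.spearmanr(m).statistic
    if np.isscalar(rho):  # two samples
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    corr = pd.DataFrame(rho, index=cols, columns=cols)
    if zscale:
        scaled, _ = zscale_rows(m)
        Z = linkage(scaled.T, method=method)
    else:
        dist = squareform(np.clip(1.0 - rho, 0.0, 2.0), checks=False)
        Z = linkage(dist, method=method)
    return corr, Z


def cut_two_groups(Z: np.ndarray, n: int) -> np.ndarray:
    """Labels (0/1) from cutting a linkage tree into two clusters."""
    from scipy.cluster.hierarchy import fcluster

    return fcluster(Z, t=2, criterion="maxclust") - 1
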
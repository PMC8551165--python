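"""Differential expression and ordination for a paired two-factor design.

The study design is paired within colonies: each genet (genetic individual)
contributes one symbiotic and one aposymbiotic branch, and the model
``~ genet + state`` tests the symbiotic-state effect after absorbing genet
differences.  Counts K[i, j] for gene i in sample j are modelled as
negative binomial with mean mu_ij = s_j * q_ij and per-gene dispersion
alpha_i (Var = mu + alpha * mu^2), where s_j are median-of-ratios size
factors and log2 q_ij = X beta follows the design matrix.  The state
coefficient is tested per gene with a Wald test and Benjamini-Hochberg
adjusted; positive log2 fold change means higher expression in symbiotic
branches.

Dispersions are estimated by a covariate-aware Pearson method of moments on
the fitted means, floored at 1e-8 and shrunk 50/50 on the log scale toward
a smoothed mean-dispersion trend for small-sample stability.

Also here: the regularized log transform used for ordination, PCA in the
``prcomp`` convention, a sequential (type-I) permutation PERMANOVA on
Euclidean distances, and the paired one-tailed t-test used for symbiont
read-mapping fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .io import check_counts_design

log = logging.getLogger("holosym")

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8
DISPERSION_CEIL = 100.0


# ---------------------------------------------------------------------------
# Filtering and normalization

def filter_low_counts(counts: pd.DataFrame, min_total: int = 10) -> pd.DataFrame:
    """Keep genes with at least ``min_total`` counts summed over all samples."""
    keep = counts.sum(axis=1) >= min_total
    out = counts.loc[keep]
    log.info("low-count filter: input=%d removed=%d retained=%d",
             len(counts), int((~keep).sum()), len(out))
    if out.empty:
        raise ValueError(f"low-count filter at min_total={min_total} removed every gene")
    return out


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    s_j = median over genes (expressed in every sample) of K[i, j] divided
    by the gene's geometric mean across samples.
    """
    K = counts.to_numpy(dtype=float)
    all_pos = (K > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("size factors need at least one gene expressed in all samples")
    logK = np.log(K[all_pos])
    log_geomean = logK.mean(axis=1, keepdims=True)
    log_s = np.median(logK - log_geomean, axis=0)
    log_s = log_s - log_s.mean()  # geometric mean 1
    return pd.Series(np.exp(log_s), index=counts.columns, name="size_factor")


def regularized_log(counts: pd.DataFrame, s: pd.Series,
                    pseudocount: float = 1.0) -> pd.DataFrame:
    """Variance-stabilizing shifted log of normalized counts.

    T[i, j] = log2(K[i, j] / s_j + pseudocount).  Used as the ordination
    input (PCA, PERMANOVA); only the rank/geometry of samples matters
    downstream, not the exact transform values.
    """
    sv = s.reindex(counts.columns).to_numpy(dtype=float)
    if (sv <= 0).any() or np.isnan(sv).any():
        raise ValueError("size factors must be positive for all samples")
    return pd.DataFrame(
        np.log2(counts.to_numpy(dtype=float) / sv + pseudocount),
        index=counts.index, columns=counts.columns,
    )


# ---------------------------------------------------------------------------
# Design matrix

def design_matrix(design: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Full-rank design matrix for ``~ genet + state``.

    Columns: intercept, one dummy per genet beyond the first (sorted), and
    the state indicator (1 = symbiotic).  The state column is always last.
    """
    genets = sorted(design["genet"].unique())
    if len(genets) < 2:
        raise ValueError("design needs >= 2 genets")
    states = set(design["state"])
    if states != {"symbiotic", "aposymbiotic"}:
        raise ValueError("design needs both symbiotic and aposymbiotic samples")
    n = len(design)
    cols = [np.ones(n)]
    names = ["intercept"]
    for g in genets[1:]:
        cols.append((design["genet"] == g).to_numpy(dtype=float))
        names.append(f"genet_{g}")
    cols.append((design["state"] == "symbiotic").to_numpy(dtype=float))
    names.append("state_symbiotic")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix ~genet+state is not full rank "
                         "(state confounded with genet?)")
    return X, names


# ---------------------------------------------------------------------------
# Negative-binomial GLM, vectorized over genes

def _nb_loglik(K: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-gene NB log-likelihood; Poisson limit used below alpha ~ 1e-7."""
    a = alpha[:, None]
    small = alpha < 1e-7
    ll = np.empty(K.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_a = 1.0 / np.clip(a, 1e-12, None)
        nb = (gammaln(K + inv_a) - gammaln(inv_a) - gammaln(K + 1)
              + K * np.log(a * mu / (1 + a * mu)) - inv_a * np.log1p(a * mu))
        po = K * np.log(mu) - mu - gammaln(K + 1)
        po = np.where(K == 0, -mu, po)  # 0*log(0) -> 0
        nb = np.where(K == 0, -inv_a * np.log1p(a * mu), nb)
    ll = np.where(small, po.sum(axis=1), nb.sum(axis=1))
    return ll


def _irls(K: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: np.ndarray,
          max_iter: int = 60, tol: float = 1e-9) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """IRLS for a log-link NB GLM, run simultaneously for all genes.

    Returns (beta, XtWX at the solution, converged mask).  The NB
    log-likelihood is kept non-decreasing by step halving.
    """
    G, n = K.shape
    p = X.shape[1]
    ridge = 1e-10 * np.eye(p)
    beta = np.linalg.lstsq(X, np.log(K + 0.5).T - offset[:, None], rcond=None)[0].T
    ll = _nb_loglik(K, np.exp(np.clip(beta @ X.T + offset, -30, 30)), alpha)
    converged = np.zeros(G, dtype=bool)
    A = np.empty((G, p, p))
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T + offset, -30, 30)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offset) + (K - mu) / mu
        A = np.einsum("gn,np,nq->gpq", W, X, X) + ridge
        b = np.einsum("gn,np->gp", W * z, X)
        try:
            beta_new = np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta_new = np.stack([np.linalg.lstsq(A[g], b[g], rcond=None)[0]
                                 for g in range(G)])
        # step halving: never let the log-likelihood decrease
        for _ in range(8):
            ll_new = _nb_loglik(
                K, np.exp(np.clip(beta_new @ X.T + offset, -30, 30)), alpha)
            worse = ll_new < ll - 1e-10
            if not worse.any():
                break
            beta_new[worse] = 0.5 * (beta_new[worse] + beta[worse])
        delta = np.abs(beta_new - beta).max(axis=1)
        beta = beta_new
        ll = np.maximum(ll, ll_new)
        converged |= delta < tol
        if converged.all():
            break
    # final weights at the solution, for the observed information
    eta = np.clip(beta @ X.T + offset, -30, 30)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha[:, None] * mu)
    A = np.einsum("gn,np,nq->gpq", W, X, X) + ridge
    return beta, A, converged


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iterations)."""
    from scipy.special import polygamma

    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        step = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += step
        if abs(step) < 1e-8 * y:
            break
    return y


def estimate_dispersions(K: np.ndarray, mu: np.ndarray, n_params: int,
                         ) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-gene NB dispersion: Pearson method of moments + EB moderation.

    The raw estimate solves sum_j (K - mu)^2 / (mu + alpha mu^2) = n - p
    per gene by a short fixed-point iteration on the fitted means mu of a
    preliminary fit, so variance explained by the design (genet blocks)
    does not inflate it.  Raw estimates are floored at 1e-8 and shrunk on
    the log scale toward a lowess trend of dispersion against mean
    expression; the shrinkage weight is set empirically by decomposing the
    spread of log dispersions around the trend into sampling noise
    (trigamma(d/2) for d residual df) and genuine gene-to-gene variation,
    in the manner of moderated variance estimators.

    Returns (moderated dispersions, raw dispersions, prior df).  The prior
    df quantifies how much information the trend contributes; the Wald
    reference downstream is a t with residual + prior df.
    """
    from scipy.special import polygamma

    G, n = K.shape
    df = max(n - n_params, 1)
    resid2 = (K - mu) ** 2
    alpha = np.maximum((resid2 - mu).sum(axis=1) / (mu ** 2).sum(axis=1),
                       DISPERSION_FLOOR)
    for _ in range(25):
        pearson = (resid2 / (mu + alpha[:, None] * mu ** 2)).sum(axis=1)
        alpha = np.clip(alpha * pearson / df, DISPERSION_FLOOR, DISPERSION_CEIL)
    raw = alpha.copy()

    base_mean = mu.mean(axis=1)
    informative = raw > DISPERSION_FLOOR * 10
    log_raw = np.log(np.maximum(raw, DISPERSION_FLOOR))
    if informative.sum() >= 20:
        xs = np.log(base_mean[informative])
        ys = log_raw[informative]
        trend_pts = lowess(ys, xs, frac=0.5, it=2, return_sorted=True)
        trend = np.interp(np.log(base_mean), trend_pts[:, 0], trend_pts[:, 1])
        resid_var = float(np.var(ys - np.interp(xs, trend_pts[:, 0], trend_pts[:, 1]),
                                 ddof=1))
    else:
        trend = np.full(G, np.log(max(np.median(raw), DISPERSION_FLOOR)))
        resid_var = float(np.var(log_raw - trend, ddof=1)) if G > 1 else 0.0

    sampling_var = float(polygamma(1, df / 2.0))
    prior_var = max(resid_var - sampling_var, 0.0)
    if prior_var <= 1e-6:
        prior_df = np.inf
        w_raw = 0.0
    else:
        prior_df = 2.0 * _trigamma_inverse(prior_var)
        w_raw = df / (df + prior_df)
    shrunk = np.exp(w_raw * log_raw + (1.0 - w_raw) * trend)
    shrunk = np.clip(shrunk, DISPERSION_FLOOR, DISPERSION_CEIL)
    return shrunk, raw, prior_df


def fit_nb_de(counts: pd.DataFrame, design: pd.DataFrame, fdr_level: float = 0.1,
              dispersion: float | np.ndarray | None = None) -> pd.DataFrame:
    """Two-factor negative-binomial Wald differential expression.

    Fits ``~ genet + state`` per gene and tests the state coefficient.
    ``dispersion`` fixes the NB dispersion (scalar or per-gene) instead of
    estimating it — useful for the Poisson limit (dispersion -> 0).

    Returns a frame indexed by gene: baseMean, log2FoldChange (positive =
    higher in symbiotic), lfcSE, stat, pvalue, padj, dispersion, significant,
    converged.  Non-converged genes get missing p-values and are excluded
    from the BH adjustment.
    """
    check_counts_design(counts, design)
    design = design.loc[list(counts.columns)]
    states = design["state"].value_counts()
    if (states < 2).any():
        raise ValueError("need >= 2 samples per symbiotic state")
    X, names = design_matrix(design)
    state_idx = names.index("state_symbiotic")

    K = counts.to_numpy(dtype=float)
    s = size_factors(counts)
    offset = np.log(s.to_numpy(dtype=float))
    G, n = K.shape

    if dispersion is not None:
        alpha = np.broadcast_to(np.asarray(dispersion, dtype=float), (G,)).copy()
        alpha = np.clip(alpha, DISPERSION_FLOOR, None)
        prior_df = np.inf  # dispersion known, no estimation uncertainty
    else:
        # preliminary Poisson fit to get covariate-conditional means
        beta0, _, _ = _irls(K, X, offset, np.full(G, DISPERSION_FLOOR), max_iter=30)
        mu0 = np.exp(np.clip(beta0 @ X.T + offset, -30, 30))
        alpha, _, prior_df = estimate_dispersions(K, mu0, n_params=X.shape[1])

    beta, A, converged = _irls(K, X, offset, alpha)

    cov = np.linalg.inv(A)
    se = np.sqrt(np.maximum(cov[:, state_idx, state_idx], 0.0))
    stat = np.where(se > 0, beta[:, state_idx] / se, np.nan)
    # Wald reference: t whose df combines residual df with the dispersion
    # prior df (normal in the known-dispersion limit)
    df_resid = max(n - X.shape[1], 1)
    df_total = df_resid + prior_df
    if np.isfinite(df_total):
        pvalue = 2.0 * stats.t.sf(np.abs(stat), df_total)
    else:
        pvalue = 2.0 * stats.norm.sf(np.abs(stat))
    pvalue = np.where(converged & np.isfinite(stat), pvalue, np.nan)

    padj = np.full(G, np.nan)
    ok = np.isfinite(pvalue)
    if ok.any():
        padj[ok] = multipletests(pvalue[ok], method="fdr_bh")[1]

    norm_counts = K / s.to_numpy(dtype=float)
    out = pd.DataFrame({
        "baseMean": norm_counts.mean(axis=1),
        "log2FoldChange": beta[:, state_idx] / LN2,
        "lfcSE": se / LN2,
        "stat": stat,
        "pvalue": pvalue,
        "padj": padj,
        "dispersion": alpha,
        "significant": (padj < fdr_level) & ok,
        "converged": converged,
    }, index=counts.index)
    n_sig = int(out["significant"].sum())
    log.info("NB Wald DE: %d genes tested, %d significant at FDR < %g",
             int(ok.sum()), n_sig, fdr_level)
    return out


# ---------------------------------------------------------------------------
# Ordination

def pca(T: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples in the ``prcomp`` convention (genes centered, unscaled).

    ``T`` is genes x samples.  Returns (scores: samples x PCs, explained
    variance fractions).
    """
    if T.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    M = T.to_numpy(dtype=float).T  # samples x genes
    M = M - M.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    k = min(M.shape[0] - 1, len(S))
    scores = U[:, :k] * S[:k]
    var = S[:k] ** 2
    frac = var / (S ** 2).sum() if (S ** 2).sum() > 0 else np.zeros(k)
    return (
        pd.DataFrame(scores, index=T.columns,
                     columns=[f"PC{i+1}" for i in range(k)]),
        frac,
    )


@dataclass
class PermanovaResult:
    table: pd.DataFrame  # rows: factors, residual, total; cols: df, SS, R2, F, p
    n_permutations: int
    seed: int


def _hat(Xk: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(Xk)
    return Q @ Q.T


def permanova(T: pd.DataFrame, design: pd.DataFrame,
              factors: tuple[str, ...] = ("genet", "state"),
              n_perm: int = 9999, seed: int = 0) -> PermanovaResult:
    """Sequential (type-I) permutation MANOVA on Euclidean sample distances.

    Partitions the total sum of squared Euclidean distances between samples
    over the factors in formula order (default genet, then state), computes
    a pseudo-F per factor, and obtains p-values by freely permuting sample
    rows: p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    design = design.loc[list(T.columns)]
    for f in factors:
        if design[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
        if design.groupby(f).size().min() < 2:
            raise ValueError(f"factor {f!r} has a level with fewer than 2 samples")
    M = T.to_numpy(dtype=float).T  # samples x genes
    n = M.shape[0]
    sq = ((M[:, None, :] - M[None, :, :]) ** 2).sum(axis=2)  # squared distances
    C = np.eye(n) - np.ones((n, n)) / n
    Gmat = -0.5 * C @ sq @ C  # Gower-centered

    # sequential hat matrices: intercept, +factor1, +factor1+factor2, ...
    blocks = [np.ones((n, 1))]
    hats = [_hat(np.ones((n, 1)))]
    ranks = [1]
    for f in factors:
        levels = sorted(design[f].unique())
        dummies = np.column_stack(
            [(design[f] == lv).to_numpy(dtype=float) for lv in levels[1:]])
        blocks.append(dummies)
        Xk = np.column_stack(blocks)
        rk = np.linalg.matrix_rank(Xk)
        if rk <= ranks[-1]:
            raise ValueError(f"factor {f!r} is confounded with preceding terms")
        hats.append(_hat(Xk))
        ranks.append(rk)

    def partition(Gm: np.ndarray) -> tuple[np.ndarray, float]:
        ss = np.array([np.sum(hats[k + 1] * Gm) - np.sum(hats[k] * Gm)
                       for k in range(len(factors))])
        ss_res = np.trace(Gm) - np.sum(hats[-1] * Gm)
        return ss, ss_res

    ss, ss_res = partition(Gmat)
    dfs = np.diff(ranks)
    df_res = n - ranks[-1]
    if df_res < 1:
        raise ValueError("no residual degrees of freedom")
    F_obs = (ss / dfs) / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(factors))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = Gmat[np.ix_(perm, perm)]
        ss_p, ss_res_p = partition(Gp)
        F_p = (ss_p / dfs) / (ss_res_p / df_res)
        exceed += F_p >= F_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    total = np.trace(Gmat)
    rows = []
    for i, f in enumerate(factors):
        rows.append((f, int(dfs[i]), ss[i], ss[i] / total, F_obs[i], pvals[i]))
    rows.append(("residual", int(df_res), ss_res, ss_res / total, np.nan, np.nan))
    rows.append(("total", n - 1, total, 1.0, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["term", "df", "SS", "R2", "F", "p"]).set_index("term")
    return PermanovaResult(table=table, n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------

def paired_onetailed_ttest(x, y, direction: str = "greater") -> tuple[float, int, float]:
    """Paired one-tailed t-test on per-colony values.

    ``direction="greater"`` tests whether x (e.g. symbiotic-branch symbiont
    mapping fraction) exceeds its paired y.  Returns (t, df, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need equal-length paired vectors with n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences")
    n = len(d)
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    if direction == "greater":
        p = float(stats.t.sf(t, df))
    elif direction == "less":
        p = float(stats.t.cdf(t, df))
    else:
        raise ValueError("direction must be 'greater' or 'less'")
    return float(t), df, p
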
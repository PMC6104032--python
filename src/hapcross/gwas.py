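"""Haplotype-block and SNP association scans with a mixed linear model.

The model is y = X b + Z u + e with u ~ N(0, sigma_g^2 K) for a genomic
relationship matrix K and e ~ N(0, sigma_e^2 I).  Variance components are
estimated once per trait-environment scan on the null model (P3D-style)
via the spectral reparameterization of K, then every feature is tested by
generalized least squares with those components fixed.  Principal-component
covariates are chosen by BIC on the maximum-likelihood fits.

Significance uses the two-condition rule: a feature must pass the p-value
threshold (fixed 0.001/0.0001 per trait family, or the empirical bottom
0.1 percentile of the scan's p-value distribution) AND deviate from the
uniform expectation in the QQ plot (pointwise 95% beta order-statistic
band).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .datatypes import MISSING, GenotypeMatrix, HaplotypeBlock, TraitTable

__all__ = ["kinship", "pca_covariates", "MLMFit", "fit_null_mlm",
           "select_pcs_bic", "block_design", "snp_design", "test_feature",
           "empirical_threshold", "qq_deviation", "genomic_inflation",
           "AssociationResult", "MixedModelScan"]


def _imputed_centered(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Dosages with missing imputed to the marker mean, and allele freqs."""
    obs = G.calls != MISSING
    dose = np.where(obs, G.calls, 0).astype(float)
    nobs = np.maximum(1, obs.sum(axis=0))
    mean = dose.sum(axis=0) / nobs
    M = np.where(obs, G.calls, mean[None, :]).astype(float)
    return M, mean / 2.0


def kinship(G: GenotypeMatrix) -> np.ndarray:
    """Centered-dosage genomic relationship matrix (VanRaden):
    K = W W' / (2 sum p(1-p)), W = M - 2p.  PSD by construction; the
    diagonal is about 1 + F (about 2 for fully inbred lines)."""
    if G.n_markers < 2:
        raise ValueError("kinship needs at least 2 markers")
    M, p = _imputed_centered(G)
    W = M - 2.0 * p[None, :]
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all markers monomorphic; kinship undefined")
    return W @ W.T / denom


def pca_covariates(G: GenotypeMatrix, k: int) -> np.ndarray:
    """Top-k principal-component scores of the centered dosage matrix.

    Deterministic sign convention: each loading vector's largest-magnitude
    entry is made positive.  ``k = 0`` returns an (n, 0) array.
    """
    if k >= G.n_lines:
        raise ValueError("k must be < number of lines")
    if k == 0:
        return np.zeros((G.n_lines, 0))
    M, _ = _imputed_centered(G)
    Mc = M - M.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Mc, full_matrices=False)
    for i in range(min(k, len(s))):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    return U[:, :k] * s[:k]


@dataclass
class MLMFit:
    """Null-model variance components and the spectral machinery to reuse."""

    sigma_g2: float
    sigma_e2: float
    loglik_ml: float
    loglik_reml: float
    n_pcs: int
    beta: np.ndarray
    eigvals: np.ndarray
    eigvecs: np.ndarray

    def __post_init__(self) -> None:
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be >= 0")
        if not np.isfinite(self.loglik_ml):
            raise ValueError("log-likelihood must be finite")


def _profile_loglik(log_lam: float, ys: np.ndarray, Xs: np.ndarray,
                    s: np.ndarray, reml: bool) -> float:
    lam = np.exp(log_lam)
    w = lam * s + 1.0
    Xw = Xs / w[:, None]
    XtWX = Xs.T @ Xw
    XtWy = Xw.T @ ys
    beta = np.linalg.solve(XtWX, XtWy)
    r = ys - Xs @ beta
    rss = float(np.sum(r * r / w))
    n, p = Xs.shape
    if reml:
        df = n - p
        sig = max(rss / df, 1e-300)
        _, ld_xwx = np.linalg.slogdet(XtWX)
        _, ld_xx = np.linalg.slogdet(Xs.T @ Xs)
        ll = -0.5 * (df * np.log(2 * np.pi * sig) + np.sum(np.log(w))
                     + ld_xwx - ld_xx + df)
    else:
        sig = max(rss / n, 1e-300)
        ll = -0.5 * (n * np.log(2 * np.pi * sig) + np.sum(np.log(w)) + n)
    return ll


def fit_null_mlm(y: np.ndarray, X: np.ndarray, K: np.ndarray,
                 n_pcs: int | None = None) -> MLMFit:
    """Fit the null mixed model by spectral reparameterization.

    K is eigendecomposed once; the likelihood in the rotated basis is a
    one-dimensional function of the variance ratio lambda = sigma_g^2 /
    sigma_e^2, optimized on log scale.  Both ML (for BIC comparisons of
    fixed-effect structures) and REML (for the final components) are
    evaluated.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = y.size
    if not np.all(np.isfinite(y)):
        raise ValueError("trait vector contains non-finite values")
    s, U = np.linalg.eigh(K)
    if s.min() < -1e-6 * max(1.0, s.max()):
        raise ValueError("kinship matrix is not positive semi-definite")
    s = np.clip(s, 0.0, None)
    ys = U.T @ y
    Xs = U.T @ X
    if np.var(y) < 1e-30:
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        return MLMFit(0.0, 0.0, 0.0, 0.0, n_pcs or 0, beta, s, U)

    def neg_ml(ll):
        return -_profile_loglik(ll, ys, Xs, s, reml=False)

    def neg_reml(ll):
        return -_profile_loglik(ll, ys, Xs, s, reml=True)

    bounds = (-12.0, 12.0)
    grid = np.linspace(*bounds, 25)
    best = grid[int(np.argmin([neg_reml(g) for g in grid]))]
    res = optimize.minimize_scalar(
        neg_reml, bounds=(max(bounds[0], best - 2), min(bounds[1], best + 2)),
        method="bounded")
    lam_reml = float(np.exp(res.x))
    ll_reml = -float(res.fun)

    best_ml = grid[int(np.argmin([neg_ml(g) for g in grid]))]
    res_ml = optimize.minimize_scalar(
        neg_ml,
        bounds=(max(bounds[0], best_ml - 2), min(bounds[1], best_ml + 2)),
        method="bounded")
    ll_ml = -float(res_ml.fun)

    # components at the REML optimum
    w = lam_reml * s + 1.0
    Xw = Xs / w[:, None]
    beta = np.linalg.solve(Xs.T @ Xw, Xw.T @ ys)
    r = ys - Xs @ beta
    p = Xs.shape[1]
    sigma_e2 = float(np.sum(r * r / w) / max(n - p, 1))
    sigma_g2 = lam_reml * sigma_e2
    # treat a boundary-small ratio as zero genetic variance
    if lam_reml <= np.exp(bounds[0]) * 1.01:
        sigma_g2 = 0.0
    return MLMFit(sigma_g2, sigma_e2, ll_ml, ll_reml,
                  n_pcs if n_pcs is not None else X.shape[1] - 1,
                  beta, s, U)


def select_pcs_bic(y: np.ndarray, G: GenotypeMatrix, K: np.ndarray,
                   k_max: int = 5) -> int:
    """Number of PC covariates minimizing BIC = -2 logL_ML + params ln(n).

    Parameters counted: intercept + k PCs + 2 variance components.  Ties
    go to the smaller k.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("trait vector contains non-finite values")
    n = y.size
    pcs = pca_covariates(G, min(k_max, G.n_lines - 1)) if k_max > 0 else \
        np.zeros((n, 0))
    best_k, best_bic = 0, np.inf
    for k in range(0, k_max + 1):
        X = np.column_stack([np.ones(n), pcs[:, :k]])
        fit = fit_null_mlm(y, X, K, n_pcs=k)
        n_params = (k + 1) + 2
        bic = -2.0 * fit.loglik_ml + n_params * np.log(n)
        if bic < best_bic - 1e-12:
            best_bic, best_k = bic, k
    return best_k


def block_design(block: HaplotypeBlock, line_ids: list[str],
                 pool_threshold: float = 0.01
                 ) -> tuple[np.ndarray, list[str], str]:
    """Dummy-coded class design for a block over the given lines.

    Classes with frequency below ``pool_threshold`` among the design lines
    are pooled into ``"rare-other"``; the reference (dropped) level is the
    most frequent class.  Rows for unassigned lines are NaN.

    Returns (design matrix, non-reference class labels, reference class).
    """
    labels = [block.assignments.get(l) for l in line_ids]
    obs = [x for x in labels if x is not None]
    if not obs:
        return np.full((len(line_ids), 0), np.nan), [], ""
    freq: dict[str, float] = {}
    for x in obs:
        freq[x] = freq.get(x, 0) + 1
    total = len(obs)
    freq = {k: v / total for k, v in freq.items()}
    pooled = {k: ("rare-other" if v < pool_threshold else k)
              for k, v in freq.items()}
    plabels = [None if x is None else pooled[x] for x in labels]
    pfreq: dict[str, float] = {}
    for x in plabels:
        if x is not None:
            pfreq[x] = pfreq.get(x, 0) + 1
    ref = max(sorted(pfreq), key=lambda k: pfreq[k])
    others = [c for c in sorted(pfreq) if c != ref]
    design = np.full((len(line_ids), len(others)), np.nan)
    for i, x in enumerate(plabels):
        if x is None:
            continue
        design[i] = 0.0
        if x != ref:
            design[i, others.index(x)] = 1.0
    return design, others, ref


def snp_design(G: GenotypeMatrix, marker: str,
               line_ids: list[str]) -> np.ndarray:
    """Single-column dosage design; missing calls become NaN rows."""
    j = G.marker_index(marker)
    col = np.full((len(line_ids), 1), np.nan)
    for i, l in enumerate(line_ids):
        c = G.calls[G.line_index(l), j]
        if c != MISSING:
            col[i, 0] = float(c)
    return col


@dataclass
class AssociationResult:
    feature: str
    trait: str
    environment: str
    p_value: float
    df: int
    effects: dict[str, float] = field(default_factory=dict)
    n: int = 0
    significant: bool = False
    qq_deviates: bool = False
    threshold: float = np.nan

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value must be in (0, 1]")


def test_feature(y: np.ndarray, X: np.ndarray, K: np.ndarray, fit: MLMFit,
                 feature_design: np.ndarray, feature: str = "",
                 trait: str = "", environment: str = "",
                 class_labels: list[str] | None = None) -> AssociationResult:
    """GLS F-test of the feature columns with null variance components.

    The covariance sigma_g^2 K + sigma_e^2 I from the null fit is held
    fixed (P3D); lines with a missing feature value are dropped for this
    test only (the covariance is subset accordingly).  Effects are the GLS
    coefficients of the feature columns (per class, relative to the
    reference class for blocks; per dosage unit for SNPs).
    """
    y = np.asarray(y, dtype=float)
    F = np.asarray(feature_design, dtype=float)
    if F.ndim == 1:
        F = F[:, None]
    keep = ~np.isnan(F).any(axis=1)
    if F.shape[1] == 0 or keep.sum() < X.shape[1] + F.shape[1] + 1:
        return AssociationResult(feature, trait, environment, 1.0, 0,
                                 {}, int(keep.sum()))
    ys, Xs, Fs = y[keep], X[keep], F[keep]
    # drop constant feature columns among tested lines (single class)
    varies = Fs.std(axis=0) > 0
    labels = class_labels or [f"c{i}" for i in range(F.shape[1])]
    labels = [l for l, v in zip(labels, varies) if v]
    Fs = Fs[:, varies]
    if Fs.shape[1] == 0:
        return AssociationResult(feature, trait, environment, 1.0, 0,
                                 {}, int(keep.sum()))
    V = fit.sigma_g2 * K[np.ix_(keep.nonzero()[0], keep.nonzero()[0])] \
        + fit.sigma_e2 * np.eye(int(keep.sum()))
    if fit.sigma_g2 == 0 and fit.sigma_e2 == 0:
        V = np.eye(int(keep.sum()))
    from scipy.linalg import solve_triangular

    L = np.linalg.cholesky(V + 1e-10 * np.eye(V.shape[0]))
    yw = solve_triangular(L, ys, lower=True)
    Xw = solve_triangular(L, Xs, lower=True)
    Fw = solve_triangular(L, Fs, lower=True)
    n = ys.size
    q0 = Xw.shape[1]
    full = np.column_stack([Xw, Fw])
    beta_full, rss_full, rank_full = _ols(full, yw)
    _, rss_null, rank_null = _ols(Xw, yw)
    df_num = rank_full - rank_null
    df_den = n - rank_full
    if df_num <= 0 or df_den <= 0 or rss_full <= 0:
        return AssociationResult(feature, trait, environment, 1.0, 0, {}, n)
    fstat = ((rss_null - rss_full) / df_num) / (rss_full / df_den)
    p = float(stats.f.sf(max(fstat, 0.0), df_num, df_den))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    effects = {lab: float(b) for lab, b in zip(labels, beta_full[q0:])}
    return AssociationResult(feature, trait, environment, p, int(df_num),
                             effects, n)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int]:
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return beta, float(r @ r), int(rank)


def empirical_threshold(pvalues, percentile: float = 0.1) -> float:
    """The bottom-``percentile``-percent quantile of a scan's p-values.

    With the default 0.1 the threshold is the 0.001 quantile (inverted-CDF
    convention, so 1,000 uniform p-values give the smallest order
    statistic).  Fixed thresholds (e.g. 0.001 for yield, 0.0001 for
    disease) are configured on :class:`MixedModelScan` instead.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    needed = int(round(100.0 / percentile))
    if p.size < needed:
        warnings.warn(
            f"only {p.size} tests; the bottom {percentile} percentile needs "
            f">= {needed} for a meaningful quantile", stacklevel=2)
    return float(np.quantile(p, percentile / 100.0, method="inverted_cdf"))


def qq_deviation(pvalues, band: float = 0.95) -> np.ndarray:
    """Pointwise QQ-plot deviation flags against the uniform expectation.

    The i-th order statistic of n uniform p-values is Beta(i, n-i+1); a
    feature deviates iff its observed p-value falls below that
    distribution's lower (1-band) quantile, i.e. its -log10(p) exceeds the
    upper pointwise band.  Returns flags aligned to the input order.
    """
    p = np.asarray(list(pvalues), dtype=float)
    n = p.size
    if n < 20:
        raise ValueError("QQ deviation needs at least 20 tests")
    order = np.argsort(p, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    lower_band = stats.beta.ppf(1.0 - band, ranks, n - ranks + 1)
    return p < lower_band


def genomic_inflation(pvalues) -> float:
    """Median chi-square inflation factor lambda_GC."""
    p = np.asarray(list(pvalues), dtype=float)
    chi = stats.chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, df=1))


class MixedModelScan(BaseEstimator):
    """Per trait-environment haplotype-block (and optional SNP) scan.

    Parameters
    ----------
    k_max : int
        Cap on the number of PC covariates; the number used per trait is
        chosen by BIC.
    pool_threshold : float
        Block classes rarer than this among tested lines are pooled into a
        "rare-other" level before dummy coding.
    threshold : float | str | dict
        Significance threshold per scan: a fixed p-value, ``"empirical"``
        (bottom ``threshold_percentile`` percent of the scan's p-values),
        or a dict mapping trait name to either.
    threshold_percentile : float
        Percentile (in percent) for the empirical threshold.
    include_snps : bool
        Also test every marker as a single-dosage feature.

    Attributes
    ----------
    results_ : pd.DataFrame
        One row per feature x trait x environment with p-value, effects,
        threshold, QQ flag and the two-condition significance call.
    fits_ : dict
        Null-model fit per (trait, environment).
    """

    def __init__(self, k_max: int = 5, pool_threshold: float = 0.01,
                 threshold: float | str | dict = 0.001,
                 threshold_percentile: float = 0.1,
                 include_snps: bool = False, per_feature_reml: bool = False):
        self.k_max = k_max
        self.pool_threshold = pool_threshold
        self.threshold = threshold
        self.threshold_percentile = threshold_percentile
        self.include_snps = include_snps
        self.per_feature_reml = per_feature_reml

    def _threshold_for(self, trait: str, pvals: np.ndarray) -> float:
        spec = self.threshold
        if isinstance(spec, dict):
            spec = spec.get(trait, 0.001)
        if spec == "empirical":
            return empirical_threshold(pvals, self.threshold_percentile)
        return float(spec)

    def fit(self, blocks: list[HaplotypeBlock], G: GenotypeMatrix,
            traits: TraitTable, trait_names: list[str] | None = None
            ) -> "MixedModelScan":
        K_full = kinship(G)
        rows: list[dict] = []
        self.fits_ = {}
        for trait in (trait_names or traits.traits()):
            for env in traits.environments(trait):
                vec = traits.vector(trait, env)
                line_ids = [l for l in G.line_ids if l in vec.index]
                if len(line_ids) < 10:
                    continue
                idx = [G.line_index(l) for l in line_ids]
                y = vec.loc[line_ids].to_numpy(dtype=float)
                Gsub = G.subset(lines=line_ids)
                K = K_full[np.ix_(idx, idx)]
                k_opt = select_pcs_bic(y, Gsub, K, self.k_max)
                pcs = pca_covariates(Gsub, k_opt)
                X = np.column_stack([np.ones(len(y)), pcs])
                null_fit = fit_null_mlm(y, X, K, n_pcs=k_opt)
                self.fits_[(trait, env)] = null_fit
                scan: list[AssociationResult] = []
                for blk in blocks:
                    design, labels, ref = block_design(
                        blk, line_ids, self.pool_threshold)
                    fit_for_test = null_fit
                    if self.per_feature_reml:
                        keep = ~np.isnan(design).any(axis=1)
                        if keep.sum() > X.shape[1] + design.shape[1] + 2:
                            d0 = np.nan_to_num(design[keep])
                            v = d0.std(axis=0) > 0
                            fit_for_test = fit_null_mlm(
                                y[keep],
                                np.column_stack([X[keep], d0[:, v]]),
                                K[np.ix_(keep.nonzero()[0],
                                         keep.nonzero()[0])],
                                n_pcs=k_opt)
                            res = test_feature(
                                y[keep], X[keep],
                                K[np.ix_(keep.nonzero()[0],
                                         keep.nonzero()[0])],
                                fit_for_test, design[keep], blk.name,
                                trait, env, labels)
                            scan.append(res)
                            continue
                    scan.append(test_feature(y, X, K, null_fit, design,
                                             blk.name, trait, env, labels))
                if self.include_snps:
                    for m in G.marker_ids:
                        scan.append(test_feature(
                            y, X, K, null_fit, snp_design(Gsub, m, line_ids),
                            m, trait, env, ["dosage"]))
                pvals = np.array([r.p_value for r in scan])
                thr = self._threshold_for(trait, pvals)
                if pvals.size >= 20:
                    qq = qq_deviation(pvals)
                else:
                    qq = pvals < 1.0 / max(pvals.size, 1)
                for r, dev in zip(scan, qq):
                    r.threshold = thr
                    r.qq_deviates = bool(dev)
                    r.significant = bool(r.p_value <= thr and dev)
                    rows.append(dict(
                        feature=r.feature, trait=r.trait, environment=r.environment,
                        p_value=r.p_value, df=r.df, n=r.n,
                        effects=";".join(f"{k}={v:.6g}"
                                         for k, v in r.effects.items()),
                        threshold=r.threshold, significant=r.significant,
                        qq_deviates=r.qq_deviates))
        self.results_ = pd.DataFrame(rows, columns=[
            "feature", "trait", "environment", "p_value", "df", "n",
            "effects", "threshold", "significant", "qq_deviates"])
        return self


def scan_blocks(blocks, G, traits, **params) -> pd.DataFrame:
    """Functional wrapper over :class:`MixedModelScan`."""
    return MixedModelScan(**params).fit(blocks, G, traits).results_
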
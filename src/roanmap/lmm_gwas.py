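"""Univariate linear mixed model association with a Wald test.

Per-marker model::

    y = W a + x b + u + e,   u ~ MVN(0, lam/tau * K),   e ~ MVN(0, 1/tau * I)

K is the centred genotype relatedness matrix; it is eigendecomposed once,
and for each marker the variance ratio ``lam`` is estimated by REML on
``ln lam in [ln 1e-5, ln 1e5]`` (coarse grid then Brent refinement),
followed by generalized least squares with weights ``1 / (lam * d_i + 1)``.
The Wald statistic is referred to F(1, n - c - 1) where c is the covariate
count.  Case/control phenotypes are coded 0/1 and fitted with the linear
(not logistic) mixed model; ordinal tick scores are analysed as a numeric
trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = ["KinshipMatrix", "compute_kinship", "lmm_wald_scan", "stratified_scan",
           "GENOME_WIDE_P", "SUGGESTIVE_P"]

GENOME_WIDE_P = 5e-8
SUGGESTIVE_P = 1e-5

_EIG_CLIP = 1e-10
_LOG_LAMBDA_LO, _LOG_LAMBDA_HI = np.log(1e-5), np.log(1e5)
_LN_LAMBDA_TOL = 1e-6


@dataclass
class KinshipMatrix:
    K: np.ndarray
    eigenvalues: np.ndarray  # clipped at a small floor, ascending
    eigenvectors: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.K, self.K.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")
        recon = (self.eigenvectors * self.eigenvalues) @ self.eigenvectors.T
        err = np.abs(recon - self.K).max()
        if err > 1e-6 * max(1.0, np.abs(self.K).max()):
            raise ValueError(f"eigen-reconstruction error {err:g} too large")

    @property
    def n(self) -> int:
        return self.K.shape[0]


def compute_kinship(g: GenotypeMatrix) -> KinshipMatrix:
    """Centred relatedness: K = (1/p) sum_k (x_k - 2 f_k 1)(x_k - 2 f_k 1)^T.

    Missing dosages are mean-imputed per marker; all-missing markers are
    excluded with a log entry.  Requires at least two polymorphic markers.
    """
    x = g.dosage_float()
    counts = np.sum(~np.isnan(x), axis=0)
    drop = counts == 0
    if drop.any():
        log.info("compute_kinship: excluding %d all-missing markers", drop.sum())
        x = x[:, ~drop]
    means = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(means, inds[1])
    centred = x - means  # means = 2 f_k
    poly = centred.std(axis=0) > 0
    if poly.sum() < 2:
        raise ValueError("need at least two polymorphic markers for kinship")
    p = centred.shape[1]
    K = centred @ centred.T / p
    d, U = np.linalg.eigh(K)
    d = np.clip(d, _EIG_CLIP, None)
    K = (U * d) @ U.T  # re-symmetrized, clipped reconstruction
    return KinshipMatrix(K, d, U)


def _reml_parts(loglam: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray):
    lam = np.exp(loglam)
    w = 1.0 / (lam * d + 1.0)
    Xw = Xt * w[:, None]
    XtWX = Xw.T @ Xt
    XtWy = Xw.T @ yt
    beta = np.linalg.solve(XtWX, XtWy)
    rss = float(yt @ (w * yt) - XtWy @ beta)
    return w, XtWX, beta, rss


def _neg_restricted_ll(loglam: float, d: np.ndarray, yt: np.ndarray,
                       Xt: np.ndarray) -> float:
    n, p = Xt.shape
    try:
        w, XtWX, _, rss = _reml_parts(loglam, d, yt, Xt)
    except np.linalg.LinAlgError:
        return np.inf
    if rss <= 0:
        return np.inf
    lam = np.exp(loglam)
    logdet_h = float(np.sum(np.log(lam * d + 1.0)))
    sign, logdet_x = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    return 0.5 * (logdet_h + logdet_x + (n - p) * np.log(rss))


def _fit_marker(d, yt, Xt) -> tuple[float, float, float, float, float]:
    """REML-optimal lambda plus GLS beta, se, Wald F and p for one marker."""
    grid = np.linspace(_LOG_LAMBDA_LO, _LOG_LAMBDA_HI, 21)
    vals = [_neg_restricted_ll(g, d, yt, Xt) for g in grid]
    k = int(np.argmin(vals))
    lo = grid[max(0, k - 1)]
    hi = grid[min(len(grid) - 1, k + 1)]
    res = optimize.minimize_scalar(
        _neg_restricted_ll, bounds=(lo, hi), args=(d, yt, Xt),
        method="bounded", options={"xatol": _LN_LAMBDA_TOL})
    loglam = float(res.x) if res.fun <= vals[k] else float(grid[k])
    lam = float(np.exp(loglam))
    w, XtWX, beta, rss = _reml_parts(loglam, d, yt, Xt)
    n, p = Xt.shape
    df = n - p
    sigma2 = rss / df
    cov = np.linalg.inv(XtWX) * sigma2
    b = float(beta[-1])
    se = float(np.sqrt(cov[-1, -1]))
    fstat = (b / se) ** 2
    pval = float(stats.f.sf(fstat, 1, df))
    return lam, b, se, fstat, pval


def lmm_wald_scan(y: np.ndarray, g: GenotypeMatrix, kin: KinshipMatrix,
                  W: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Per-marker Wald tests under the mixed model.

    Returns a DataFrame with chrom, pos, marker_id, af, beta, se, lam,
    wald_p; monomorphic or design-collinear markers are flagged untested
    (NaN statistics, ``tested = False``).
    """
    y = np.asarray(y, dtype=float)
    n = g.n_individuals
    if y.shape != (n,) or np.isnan(y).any():
        raise ValueError("phenotype vector must be complete and length n")
    if W is None:
        W = np.ones((n, 1))
    U, d = kin.eigenvectors, kin.eigenvalues
    yt = U.T @ y
    Wt = U.T @ W
    x = g.dosage_float()
    means = np.nanmean(x, axis=0)
    idx = np.where(np.isnan(x))
    x[idx] = np.take(means, idx[1])
    Xt_all = U.T @ x
    af = g.allele_frequency()
    out = {k: [] for k in ("af", "beta", "se", "lam", "wald_stat", "wald_p", "tested")}
    c = W.shape[1]
    for k in range(x.shape[1]):
        xk = x[:, k]
        tested = xk.std() > 0
        if tested:
            # collinearity with covariates -> untested
            resid = xk - W @ np.linalg.lstsq(W, xk, rcond=None)[0]
            tested = float(resid @ resid) > 1e-10 * n
        if not tested:
            for key, v in (("beta", np.nan), ("se", np.nan), ("lam", np.nan),
                           ("wald_stat", np.nan), ("wald_p", np.nan)):
                out[key].append(v)
            out["tested"].append(False)
        else:
            Xt = np.column_stack([Wt, Xt_all[:, k]])
            lam, b, se, fstat, pval = _fit_marker(d, yt, Xt)
            out["beta"].append(b)
            out["se"].append(se)
            out["lam"].append(lam)
            out["wald_stat"].append(fstat)
            out["wald_p"].append(pval)
            out["tested"].append(True)
        out["af"].append(af[k])
    m = g.markers
    res = pd.DataFrame({"chrom": m.chrom, "pos": m.pos_bp,
                        "marker_id": m.marker_id, **out})
    res.attrs["n"] = n
    res.attrs["df"] = n - c - 1
    return res


def stratified_scan(y: np.ndarray, g: GenotypeMatrix, groups,
                    min_group: int = 20) -> dict[str, pd.DataFrame]:
    """Independent scans within each group label, kinship recomputed per subset.

    Groups with fewer than ``min_group`` individuals or a single phenotype
    class are skipped with a warning.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    results: dict[str, pd.DataFrame] = {}
    for gname in pd.unique(groups):
        rows = np.flatnonzero(groups == gname)
        if len(rows) < min_group:
            log.warning("stratified_scan: %s skipped (n=%d < %d)",
                        gname, len(rows), min_group)
            continue
        ysub = y[rows]
        if len(np.unique(ysub)) < 2:
            log.warning("stratified_scan: %s skipped (single phenotype class)", gname)
            continue
        gsub = g.subset_individuals(rows)
        kin = compute_kinship(gsub)
        results[str(gname)] = lmm_wald_scan(ysub, gsub, kin)
    return results


def write_assoc_tsv(path, result: pd.DataFrame) -> None:
    cols = ["chrom", "pos", "marker_id", "af", "beta", "se", "lam", "wald_p"]
    result[cols].to_csv(path, sep="\t", index=False)
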
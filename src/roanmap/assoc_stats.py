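"""Contingency-table association, prediction concordance and the
per-marker genotype-frequency scan.

Chi-squared p-values are computed via the log upper tail of the chi-squared
distribution, never via 1 - CDF, so values around 1e-300 are exact.  The
continuity correction is applied for 2x2 tables only (mainstream software
convention).  A useful identity for audit: on a 2xk table with disjoint
support (perfect separation) the Pearson statistic equals the total count N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = ["ContingencyResult", "ConcordanceReport", "chi2_test", "concordance",
           "predict_phenotype", "genotype_freq_scan"]


@dataclass
class ContingencyResult:
    observed: np.ndarray
    expected: np.ndarray
    statistic: float
    df: int
    correction: str  # "none" | "yates"
    log10_p: float

    @property
    def p_value(self) -> float:
        return float(10.0 ** self.log10_p)


def chi2_test(table, correction: str = "none") -> ContingencyResult:
    """Pearson chi-squared test of independence on a counts matrix.

    Zero-margin rows/columns are dropped with a warning; ``yates`` applies
    the continuity correction and is only valid on a 2x2 table.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("need a matrix with at least 2 rows and 2 columns")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValueError("table must hold non-negative integers")
    if obs.sum() == 0:
        raise ValueError("all-zero table")
    keep_r = obs.sum(axis=1) > 0
    keep_c = obs.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        log.warning("chi2_test: dropping %d zero-margin rows, %d columns",
                    (~keep_r).sum(), (~keep_c).sum())
        obs = obs[keep_r][:, keep_c]
        if min(obs.shape) < 2:
            raise ValueError("fewer than 2 informative rows or columns remain")
    if correction not in ("none", "yates"):
        raise ValueError("correction must be 'none' or 'yates'")
    if correction == "yates" and obs.shape != (2, 2):
        raise ValueError("Yates correction applies only to 2x2 tables")
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    diff = np.abs(obs - expected)
    if correction == "yates":
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float(np.sum(diff ** 2 / expected))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return ContingencyResult(obs.astype(np.int64), expected, stat, df,
                             correction, _log10_chi2_sf(stat, df))


def _log10_chi2_sf(stat: float, df: int) -> float:
    """log10 of the chi-squared upper tail, exact arbitrarily far out.

    Uses scipy's logsf where it is finite; beyond that, the asymptotic
    series for the normalized upper incomplete gamma function
    Q(s, x) ~ x^{s-1} e^{-x} / Gamma(s) * sum_k Gamma(s) / (Gamma(s-k) x^k)
    with s = df/2, x = stat/2.
    """
    from scipy.special import gammaln

    ls = float(stats.chi2.logsf(stat, df))
    if np.isfinite(ls):
        return ls / np.log(10.0)
    s, x = df / 2.0, stat / 2.0
    term, total = 1.0, 1.0
    for k in range(1, 60):
        term *= (s - k) / x
        total += term
        if abs(term) < 1e-17 * abs(total):
            break
    log_q = (s - 1.0) * np.log(x) - x - gammaln(s) + np.log(total)
    return float(log_q / np.log(10.0))


@dataclass
class ConcordanceReport:
    n_compared: int
    n_concordant: int
    discordant_ids: list

    @property
    def rate(self) -> float:
        return self.n_concordant / self.n_compared if self.n_compared else np.nan


def concordance(calls_a, calls_b, ids: Optional[Sequence] = None
                ) -> ConcordanceReport:
    """Element-wise agreement over jointly non-missing entries."""
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    if a.shape != b.shape:
        raise ValueError("call vectors must have equal length")
    if ids is None:
        ids = np.arange(len(a))
    ids = np.asarray(ids)

    def missing(v):
        if v.dtype.kind == "f":
            return np.isnan(v)
        return (v == MISSING) | (v == None)  # noqa: E711

    ok = ~missing(a) & ~missing(b)
    agree = ok & (a == b)
    return ConcordanceReport(int(ok.sum()), int(agree.sum()),
                             ids[ok & ~agree].tolist())


def predict_phenotype(carrier_counts, roan_case) -> dict:
    """Dominant-model prediction table: predicted roan iff >= 1 carrier copy.

    Returns the 2x2 table [[TP, FN], [FP, TN]] plus sensitivity and
    specificity; margins conserve the input cohort sizes.
    """
    counts = np.asarray(carrier_counts)
    case = np.asarray(roan_case, dtype=bool)
    pred = counts >= 1
    tp = int(np.sum(pred & case))
    fn = int(np.sum(~pred & case))
    fp = int(np.sum(pred & ~case))
    tn = int(np.sum(~pred & ~case))
    return {
        "table": np.array([[tp, fn], [fp, tn]]),
        "sensitivity": tp / (tp + fn) if (tp + fn) else np.nan,
        "specificity": tn / (tn + fp) if (tn + fp) else np.nan,
    }


def genotype_freq_scan(g1: GenotypeMatrix, g2: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker 2x3 genotype-count chi-squared between two cohorts.

    Monomorphic-in-both markers are skipped; output is sorted by ascending
    p (ties by position) with a Bonferroni column for convenience (raw p is
    the reported quantity).
    """
    if list(g1.markers.marker_id) != list(g2.markers.marker_id):
        raise ValueError("cohorts must share one marker map")
    rows = []
    for k in range(len(g1.markers)):
        c1 = np.bincount(g1.dosage[:, k][g1.dosage[:, k] != MISSING],
                         minlength=3)[:3]
        c2 = np.bincount(g2.dosage[:, k][g2.dosage[:, k] != MISSING],
                         minlength=3)[:3]
        tab = np.array([c1, c2])
        nonzero = tab.sum(axis=0) > 0
        if nonzero.sum() < 2 or (tab.sum(axis=1) == 0).any():
            continue
        res = chi2_test(tab[:, nonzero], correction="none")
        rows.append({"marker_id": g1.markers.marker_id[k],
                     "chrom": g1.markers.chrom[k],
                     "pos": int(g1.markers.pos_bp[k]),
                     "chi2": res.statistic, "df": res.df,
                     "log10_p": res.log10_p, "p": res.p_value})
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["log10_p", "pos"]).reset_index(drop=True)
        out["p_bonferroni"] = np.minimum(1.0, out["p"] * len(out))
    return out
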
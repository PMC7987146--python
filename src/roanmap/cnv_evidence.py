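"""Duplication evidence from array intensity, read depth and pair orientation.

Three independent channels support a tandem duplication call:

* ``delta_lrr`` — log-R-ratio at an in-duplication probe minus the mean over
  the nearest flanking probes (elevated in carriers);
* windowed read depth, normalized by the supplied table's global mean, with
  the inside/flank copy ratio expected at CN/2 under a Poisson depth model;
* discordant read-pair orientation: outward-facing (everted) pairs at the
  junction are the tandem-orientation signature.

The breakpoint caller combines a run of elevated depth windows with an
outward-pair cluster; it implements the evidence logic only and is not a
general structural-variant caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import Interval, MarkerMap

__all__ = ["delta_lrr", "lrr_group_test", "depth_windows", "copy_ratio",
           "classify_pairs", "call_tandem_dup", "DepthProfile", "DupCall"]


def delta_lrr(lrr: pd.DataFrame, markers: MarkerMap, inside_marker: str,
              flank_k: int = 10) -> pd.Series:
    """dLRR = LRR(inside probe) - mean LRR over the flank_k nearest flanking
    probes (split half per side); missing flank values are dropped from the
    mean, a missing inside value yields a missing output.
    """
    if inside_marker not in lrr.columns:
        raise ValueError(f"inside marker {inside_marker!r} absent from LRR table")
    mk = list(markers.marker_id)
    k0 = mk.index(inside_marker)
    chrom = markers.chrom[k0]
    same = [j for j in range(len(mk)) if markers.chrom[j] == chrom
            and mk[j] in lrr.columns and j != k0]
    left = sorted([j for j in same if j < k0], key=lambda j: k0 - j)
    right = sorted([j for j in same if j > k0], key=lambda j: j - k0)
    per_side = flank_k // 2
    flank = left[:per_side] + right[:flank_k - min(per_side, len(left))]
    if len(flank) < flank_k:
        flank = left[:flank_k - len(right)] + right
    if len(flank) < flank_k:
        raise ValueError(f"only {len(flank)} flanking markers available, "
                         f"need {flank_k}")
    flank_cols = [mk[j] for j in flank]
    return lrr[inside_marker] - lrr[flank_cols].mean(axis=1, skipna=True)


def lrr_group_test(lrr: pd.DataFrame, marker: str, group_a, group_b
                   ) -> dict[str, float]:
    """Welch two-sample t-test on per-individual LRR at one probe."""
    a = lrr.loc[list(group_a), marker].dropna()
    b = lrr.loc[list(group_b), marker].dropna()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two non-missing values")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {"mean_a": float(a.mean()), "mean_b": float(b.mean()),
            "n_a": int(len(a)), "n_b": int(len(b)),
            "t": float(t), "p": float(p)}


@dataclass
class DepthProfile:
    individual: str
    chrom: str
    windows: pd.DataFrame  # start, end, mean_dp, ratio
    global_mean: float


def depth_windows(depth: pd.DataFrame, window_bp: int = 5000,
                  individual: Optional[str] = None) -> DepthProfile:
    """Non-overlapping window means, tiling the chromosome from position 1,
    normalized by the global mean of the supplied depth table.
    """
    if individual is not None:
        depth = depth[depth["id"] == individual]
    elif "id" in depth.columns:
        uniq = depth["id"].unique()
        if len(uniq) != 1:
            raise ValueError("pass individual= when the table holds several ids")
        individual = str(uniq[0])
    chroms = depth["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("depth_windows expects a single chromosome")
    gmean = float(depth["dp"].mean())
    win = (depth["pos"] - 1) // window_bp
    agg = depth.groupby(win)["dp"].mean()
    out = pd.DataFrame({
        "start": agg.index.to_numpy() * window_bp + 1,
        "end": (agg.index.to_numpy() + 1) * window_bp,
        "mean_dp": agg.to_numpy(),
    })
    out["ratio"] = out["mean_dp"] / gmean
    return DepthProfile(str(individual), str(chroms[0]), out, gmean)


def copy_ratio(depth: pd.DataFrame, dup: Interval, flank_bp: int = 100_000) -> float:
    """Mean depth inside the duplication over mean depth in the two flanks.

    Expectation under the Poisson model is CN/2; invariant under global
    depth rescaling.
    """
    on = depth[depth["chrom"] == dup.chrom]
    pos = on["pos"].to_numpy()
    dp = on["dp"].to_numpy()
    inside = (pos >= dup.start_bp) & (pos <= dup.end_bp)
    flank = ((pos >= dup.start_bp - flank_bp) & (pos < dup.start_bp)) | \
            ((pos > dup.end_bp) & (pos <= dup.end_bp + flank_bp))
    if not inside.any() or not flank.any():
        raise ValueError("no depth observations inside dup or in flanks")
    return float(dp[inside].mean() / dp[flank].mean())


def classify_pairs(pairs: pd.DataFrame, insert_mean: float,
                   insert_sd: float) -> pd.DataFrame:
    """Annotate read pairs with an orientation class.

    After normalizing pos1 <= pos2: forward-reverse facing each other within
    insert_mean +/- 4 sd -> proper-inward; reverse-then-forward (facing
    away) -> outward; equal strands -> same-strand; proper orientation with
    an insert beyond the bound -> distance-anomaly.
    """
    df = pairs.copy()
    swap = df["pos1"] > df["pos2"]
    if swap.any():
        for a, b in (("pos1", "pos2"), ("strand1", "strand2")):
            df.loc[swap, [a, b]] = df.loc[swap, [b, a]].to_numpy()
    insert = df["pos2"] - df["pos1"]
    lo = insert_mean - 4 * insert_sd
    hi = insert_mean + 4 * insert_sd
    s1, s2 = df["strand1"].to_numpy(), df["strand2"].to_numpy()
    cls = np.where(s1 == s2, "same-strand",
                   np.where((s1 == "-") & (s2 == "+"), "outward",
                            np.where((insert >= lo) & (insert <= hi),
                                     "proper-inward", "distance-anomaly")))
    df["orientation"] = cls
    return df


@dataclass
class DupCall:
    interval: Interval
    support: int  # outward pairs
    mean_ratio: float  # depth ratio inside the called interval
    cn_estimate: int
    cn_tie: bool  # ratio landed exactly between copy numbers

    @property
    def length_bp(self) -> int:
        return self.interval.length_bp


def _round_half_up(x: float) -> tuple[int, bool]:
    frac = x - np.floor(x)
    tie = abs(frac - 0.5) < 1e-9
    return int(np.floor(x + 0.5)), tie


def call_tandem_dup(profile: DepthProfile, pairs: pd.DataFrame,
                    min_support: int = 3, ratio_min: float = 1.25,
                    insert_mean: float = 400.0,
                    ) -> tuple[Optional[DupCall], list[Interval]]:
    """Call a tandem duplication from a depth profile plus annotated pairs.

    A candidate is a maximal run of >= 2 consecutive windows with ratio >=
    ratio_min; a call is made iff >= min_support outward pairs cluster with
    both ends within insert_mean of the run boundaries.  Breakpoints are the
    median outward-pair end coordinates; CN = round(2 x mean inside ratio),
    half-up with a tie flag.  Depth runs without pair support are returned
    as depth-only candidates, not calls.
    """
    w = profile.windows.sort_values("start").reset_index(drop=True)
    hot = (w["ratio"] >= ratio_min).to_numpy()
    starts = w["start"].to_numpy()
    ends = w["end"].to_numpy()
    runs: list[tuple[int, int]] = []
    start = None
    for j in range(len(w) + 1):
        adjacent = j < len(w) and (start is None or starts[j] == ends[j - 1] + 1)
        if j < len(w) and hot[j] and adjacent:
            if start is None:
                start = j
        else:
            if start is not None and j - start >= 2:
                runs.append((start, j - 1))
            start = j if (j < len(w) and hot[j]) else None
    outward = pairs[pairs["orientation"] == "outward"] \
        if "orientation" in pairs.columns else pairs
    candidates: list[Interval] = []
    best: Optional[DupCall] = None
    # breakpoints may sit anywhere inside the boundary windows, so the
    # clustering tolerance is the insert size plus one window width
    window_bp = int(np.median(ends - starts)) + 1 if len(w) else 0
    tol = insert_mean + window_bp
    for lo, hi in runs:
        run_start = int(w["start"].iloc[lo])
        run_end = int(w["end"].iloc[hi])
        iv = Interval(profile.chrom, run_start, run_end)
        near = outward[(np.abs(outward["pos1"] - run_start) <= tol)
                       & (np.abs(outward["pos2"] - run_end) <= tol)]
        if len(near) < min_support:
            candidates.append(iv)
            continue
        bk_start = int(np.median(near["pos1"]))
        bk_end = int(np.median(near["pos2"]))
        inner = w[(w["start"] >= bk_start) & (w["end"] <= bk_end)]
        ratios = inner["ratio"] if len(inner) else w["ratio"].iloc[lo:hi + 1]
        mean_ratio = float(ratios.mean())
        cn, tie = _round_half_up(2.0 * mean_ratio)
        call = DupCall(Interval(profile.chrom, bk_start, bk_end),
                       int(len(near)), mean_ratio, cn, tie)
        if best is None or call.support > best.support:
            best = call
    return best, candidates
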
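"""Fused-lasso smoothing of the read-depth profile and segment extraction.

The smoother solves the 1-D fused-lasso (total-variation denoising) problem

    minimize  (1/2) * sum_i (y_i - beta_i)^2  +  lam * sum_i |beta_{i+1} - beta_i|

exactly, using Condat's direct non-iterative algorithm.  The piecewise-
constant minimizer is then merged into maximal constant runs, each becoming
one segment; masked bins always terminate runs, so segmentation operates per
contiguous unmasked stretch per chromosome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profile import BinProfile

__all__ = ["SegmentSet", "fused_lasso_fit", "select_lambda", "extract_segments",
           "absorb_small_segments", "segment_profile"]


def fused_lasso_fit(y: np.ndarray, lam: float) -> np.ndarray:
    """Exact minimizer of the 1-D fused-lasso objective (Condat's algorithm).

    Parameters
    ----------
    y : 1-D array of finite floats, length >= 1.
    lam : fusion penalty weight, >= 0.

    Returns
    -------
    The unique piecewise-constant minimizer, same length as ``y``.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) == 0:
        raise ValueError("y must be a non-empty 1-D vector")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    n = len(y)
    if n == 1 or lam == 0.0:
        return y.copy()

    x = np.empty(n)
    # Condat (2013), Algorithm 1, translated to 0-based indices.
    k = k0 = kminus = kplus = 0
    vmin = y[0] - lam
    vmax = y[0] + lam
    umin = lam
    umax = -lam
    while True:
        if k == n - 1:
            if umin < 0.0:
                x[k0:kminus + 1] = vmin
                k = k0 = kminus = kminus + 1
                vmin = y[k]
                umin = lam
                umax = y[k] + lam - vmax
                if k == n - 1:
                    # re-enter termination with the refreshed state
                    continue
            elif umax > 0.0:
                x[k0:kplus + 1] = vmax
                k = k0 = kplus = kplus + 1
                vmax = y[k]
                umax = -lam
                umin = y[k] - lam - vmin
                if k == n - 1:
                    continue
            else:
                x[k0:n] = vmin + umin / (k - k0 + 1)
                return x
        if y[k + 1] + umin < vmin - lam:          # negative jump necessary
            x[k0:kminus + 1] = vmin
            k = k0 = kminus = kplus = kminus + 1
            vmin = y[k]
            vmax = y[k] + 2.0 * lam
            umin = lam
            umax = -lam
        elif y[k + 1] + umax > vmax + lam:        # positive jump necessary
            x[k0:kplus + 1] = vmax
            k = k0 = kminus = kplus = kplus + 1
            vmin = y[k] - 2.0 * lam
            vmax = y[k]
            umin = lam
            umax = -lam
        else:                                     # no jump: extend the segment
            k += 1
            umin += y[k] - vmin
            umax += y[k] - vmax
            if umin >= lam:
                vmin += (umin - lam) / (k - k0 + 1)
                umin = lam
                kminus = k
            if umax <= -lam:
                vmax += (umax + lam) / (k - k0 + 1)
                umax = -lam
                kplus = k


def select_lambda(y: np.ndarray) -> float:
    """Universal-threshold penalty with a robust first-difference noise scale.

    sigma_hat = median(|y_{i+1} - y_i|) / (0.6745 * sqrt(2)), the standard
    median-absolute consistency scaling for Gaussian noise (differences of
    iid N(0, sigma^2) are N(0, 2 sigma^2)); lambda = sigma_hat * sqrt(2 ln n).
    Returns 0 for a constant vector.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 observations to select lambda")
    sigma = float(np.median(np.abs(np.diff(y)))) / (0.6745 * math.sqrt(2.0))
    return sigma * math.sqrt(2.0 * math.log(len(y)))


@dataclass
class SegmentSet:
    """Piecewise-constant segments over the unmasked bins of a profile.

    ``bin_span`` holds (first, last) bin indices (inclusive) into the parent
    profile's bin arrays; ``level`` is the fused-lasso fitted value used by
    all downstream statistics, ``rd_mean`` the mean corrected read depth of
    member bins (reporting only).
    """

    chrom: np.ndarray
    bin_first: np.ndarray
    bin_last: np.ndarray       # inclusive
    start: np.ndarray          # bp, 0-based
    end: np.ndarray            # bp, half-open
    level: np.ndarray
    rd_mean: np.ndarray
    n_bins: np.ndarray

    @property
    def n(self) -> int:
        """Total number of segments."""
        return len(self.level)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "level": self.level,
                "rd_mean": self.rd_mean,
                "n_bins": self.n_bins,
            }
        )


def _contiguous_stretches(profile: BinProfile) -> list[np.ndarray]:
    """Maximal runs of unmasked bins, split at chromosome changes and masked gaps."""
    idx = profile.unmasked()
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(
        (np.diff(idx) != 1)
        | (profile.chrom[idx[1:]] != profile.chrom[idx[:-1]])
    )
    return np.split(idx, breaks + 1)


def extract_segments(
    profile: BinProfile,
    fitted: list[np.ndarray],
    merge_tol: float = 1e-8,
) -> SegmentSet:
    """Merge fitted values into maximal constant runs, one stretch at a time.

    ``fitted`` must align with the contiguous unmasked stretches of the
    profile (as produced by :func:`segment_profile`).  Adjacent bins whose
    fitted values differ by <= ``merge_tol`` join one segment; the segment
    level is the mean fitted value of the run.
    """
    stretches = _contiguous_stretches(profile)
    if len(stretches) != len(fitted):
        raise ValueError(f"{len(fitted)} fitted vectors for {len(stretches)} unmasked stretches")
    rows: list[tuple] = []
    rd = np.where(np.isnan(profile.rd), profile.rd_raw, profile.rd)
    for idx, f in zip(stretches, fitted):
        if len(idx) != len(f):
            raise ValueError(f"fitted vector length {len(f)} != stretch length {len(idx)}")
        jump = np.flatnonzero(np.abs(np.diff(f)) > merge_tol)
        starts = np.concatenate([[0], jump + 1])
        ends = np.concatenate([jump + 1, [len(f)]])
        for s, e in zip(starts, ends):
            bins = idx[s:e]
            rows.append(
                (
                    profile.chrom[bins[0]],
                    bins[0],
                    bins[-1],
                    profile.start[bins[0]],
                    profile.start[bins[-1]] + profile.width,
                    float(np.mean(f[s:e])),
                    float(np.mean(rd[bins])),
                    len(bins),
                )
            )
    cols = list(zip(*rows)) if rows else [[]] * 8
    return SegmentSet(
        chrom=np.array(cols[0], dtype=object),
        bin_first=np.array(cols[1], dtype=np.int64),
        bin_last=np.array(cols[2], dtype=np.int64),
        start=np.array(cols[3], dtype=np.int64),
        end=np.array(cols[4], dtype=np.int64),
        level=np.array(cols[5], dtype=float),
        rd_mean=np.array(cols[6], dtype=float),
        n_bins=np.array(cols[7], dtype=np.int64),
    )


def absorb_small_segments(segments: SegmentSet, min_bins: int = 20) -> SegmentSet:
    """Merge segments shorter than ``min_bins`` into their closer-level
    genomic neighbor, smallest first, until none remain (isolated short
    segments flanked only by mask gaps are kept).

    Very short segments are transient noise excursions of the smoother, not
    credible copy-number events at the depths this caller targets; left in
    place their erratic levels blur the density contrast between the normal
    cluster and true outlier segments.
    """
    if min_bins <= 1 or segments.n == 0:
        return segments
    rows = [
        dict(chrom=segments.chrom[i], start=int(segments.start[i]), end=int(segments.end[i]),
             level=float(segments.level[i]), rd_mean=float(segments.rd_mean[i]),
             n_bins=int(segments.n_bins[i]), bin_first=int(segments.bin_first[i]),
             bin_last=int(segments.bin_last[i]))
        for i in range(segments.n)
    ]

    def neighbors(i: int) -> list[int]:
        r = rows[i]
        out = []
        if i > 0 and rows[i - 1]["chrom"] == r["chrom"] and rows[i - 1]["bin_last"] + 1 == r["bin_first"]:
            out.append(i - 1)
        if i < len(rows) - 1 and rows[i + 1]["chrom"] == r["chrom"] and r["bin_last"] + 1 == rows[i + 1]["bin_first"]:
            out.append(i + 1)
        return out

    while True:
        cand = [i for i, r in enumerate(rows) if r["n_bins"] < min_bins and neighbors(i)]
        if not cand:
            break
        i = min(cand, key=lambda k: (rows[k]["n_bins"], k))
        j = min(neighbors(i), key=lambda k: abs(rows[k]["level"] - rows[i]["level"]))
        a, b = (i, j) if i < j else (j, i)
        ra, rb = rows[a], rows[b]
        nb = ra["n_bins"] + rb["n_bins"]
        rows[a:b + 1] = [dict(
            chrom=ra["chrom"], start=ra["start"], end=rb["end"],
            level=(ra["level"] * ra["n_bins"] + rb["level"] * rb["n_bins"]) / nb,
            rd_mean=(ra["rd_mean"] * ra["n_bins"] + rb["rd_mean"] * rb["n_bins"]) / nb,
            n_bins=nb, bin_first=ra["bin_first"], bin_last=rb["bin_last"],
        )]
    return SegmentSet(
        chrom=np.array([r["chrom"] for r in rows], dtype=object),
        bin_first=np.array([r["bin_first"] for r in rows], dtype=np.int64),
        bin_last=np.array([r["bin_last"] for r in rows], dtype=np.int64),
        start=np.array([r["start"] for r in rows], dtype=np.int64),
        end=np.array([r["end"] for r in rows], dtype=np.int64),
        level=np.array([r["level"] for r in rows], dtype=float),
        rd_mean=np.array([r["rd_mean"] for r in rows], dtype=float),
        n_bins=np.array([r["n_bins"] for r in rows], dtype=np.int64),
    )


def segment_profile(
    profile: BinProfile,
    lam: float | None = None,
    merge_tol: float = 1e-8,
) -> tuple[SegmentSet, float]:
    """Smooth every contiguous unmasked stretch and extract segments.

    When ``lam`` is None the penalty is selected per profile with
    :func:`select_lambda` on the concatenated unmasked depth signal.
    Returns the segment set and the penalty actually used.
    """
    stretches = _contiguous_stretches(profile)
    if not stretches:
        raise ValueError("no unmasked bins to segment")
    rd = np.where(np.isnan(profile.rd), profile.rd_raw, profile.rd)
    if lam is None:
        y_all = rd[profile.unmasked()]
        lam = select_lambda(y_all) if len(y_all) >= 2 else 0.0
    fitted = [fused_lasso_fit(rd[idx], lam) for idx in stretches]
    return extract_segments(profile, fitted, merge_tol=merge_tol), lam
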
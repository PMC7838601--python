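"""Bivariate Gaussian significance testing of (rho, delta) and CNV typing.

Under a CNV-free profile the segment features (rho, delta) scatter in one
dense cluster that is approximately bivariate Gaussian.  A null N(mu, Sigma)
is fitted to all observed feature pairs; each segment's p-value is the
probability mass of the density region less probable than its own position,

    p_i = exp(-m_i^2 / 2),   m_i^2 = (x_i - mu)^T Sigma^{-1} (x_i - mu),

which is exactly the chi-square (2 df) survival function of the squared
Mahalanobis distance.  Segments with p < alpha (default 0.005, no multiple-
testing correction) are declared CNVs and typed against the baseline r_b:
the bin-count-weighted mean RD level of the cluster-center neighborhood
(all segments within gamma of the densest segment).  Level above r_b is an
amplification, at or below is a deletion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureTable
from .segmentation import SegmentSet

__all__ = [
    "NullModel",
    "CNVCall",
    "fit_null",
    "robust_null",
    "p_values",
    "declare_cnvs",
    "declare_outliers",
    "baseline_rd",
    "assign_types",
]

AMPLIFICATION = "amplification"
DELETION = "deletion"


@dataclass
class NullModel:
    """Fitted bivariate Gaussian over (rho, delta)."""

    mu: np.ndarray            # [mean rho, mean delta]
    sigma: np.ndarray         # 2x2 covariance, positive-definite
    regularization: float     # ridge added to the diagonal (0 if none)

    def mahalanobis_sq(self, x: np.ndarray) -> np.ndarray:
        """Squared Mahalanobis distance of each row of x (n x 2)."""
        diff = np.atleast_2d(x) - self.mu
        sol = np.linalg.solve(self.sigma, diff.T)
        return np.einsum("ij,ji->i", diff, sol)


@dataclass
class CNVCall:
    chrom: str
    start: int                # bp, 0-based
    end: int                  # bp, half-open
    rd: float                 # segment level
    p_value: float
    status: str               # amplification | deletion
    n_bins: int


def fit_null(features: FeatureTable) -> NullModel:
    """Sample mean and covariance (denominator n-1) of the observed (rho, delta).

    A near-singular covariance (min eigenvalue < 1e-8 * trace) receives a
    ridge of 1e-8 * trace on the diagonal; a feature with no variance at all
    is an error, never a silent NaN.
    """
    if features.n < 3:
        raise ValueError(f"need >= 3 segments to fit the null, got {features.n}")
    x = np.column_stack([features.rho.astype(float), features.delta])
    mu = x.mean(axis=0)
    sigma = np.cov(x, rowvar=False, ddof=1)
    trace = float(np.trace(sigma))
    if trace <= 0.0:
        raise ValueError("both features are constant: rho and delta have zero variance")
    ridge = 0.0
    if float(np.linalg.eigvalsh(sigma).min()) < 1e-8 * trace:
        ridge = 1e-8 * trace
        sigma = sigma + ridge * np.eye(2)
    for k, name in enumerate(("rho", "delta")):
        if sigma[k, k] <= 0.0:
            raise ValueError(f"feature {name} has zero variance")
    return NullModel(mu=mu, sigma=sigma, regularization=ridge)


def _subset(features: FeatureTable, keep: np.ndarray) -> FeatureTable:
    return FeatureTable(
        rho=features.rho[keep],
        delta=features.delta[keep],
        order_rank=features.order_rank[keep],
        gamma=features.gamma,
        distances=features.distances,
    )


def robust_null(
    features: FeatureTable,
    exclude_p: float = 1e-8,
    refit_rounds: int = 2,
) -> tuple[NullModel, np.ndarray]:
    """Null fit made resistant to the outliers it is meant to detect.

    Two refinements on top of the plain sample fit:

    * the global density peak is excluded from the fitting set (its delta is
      the max-distance convention for the cluster center, not a draw from
      the same rule as everyone else's nearest-denser distance, and its one
      huge value can dominate the delta variance);
    * up to ``refit_rounds`` refits drop segments that are already extreme
      (p < ``exclude_p``) *and* lie in the outlier orientation (delta above
      the null mean, rho below), so that gross copy-number segments stop
      inflating the covariance, while extreme-but-ordinary segments keep
      anchoring it (which keeps the false-flag rate on CNV-free profiles
      low).

    Returns the final model and the p-values of *all* segments under it.
    """
    n = features.n
    peak = int(np.lexsort((np.arange(n), -features.rho))[0])
    keep = np.ones(n, dtype=bool)
    if n >= 4:
        keep[peak] = False
    model = fit_null(_subset(features, keep))
    p = p_values(features, model)
    for _ in range(refit_rounds):
        exclude = (p < exclude_p) & (features.delta > model.mu[1]) & (features.rho < model.mu[0])
        if n >= 4:
            exclude[peak] = True
        new_keep = ~exclude
        if new_keep.sum() < 3 or np.array_equal(new_keep, keep):
            break
        keep = new_keep
        model = fit_null(_subset(features, keep))
        p = p_values(features, model)
    return model, p


def p_values(features: FeatureTable, model: NullModel) -> np.ndarray:
    """Lowest-density-region tail probability per segment: exp(-m^2 / 2)."""
    x = np.column_stack([features.rho.astype(float), features.delta])
    m2 = model.mahalanobis_sq(x)
    return np.exp(-0.5 * m2)


def declare_cnvs(segments: SegmentSet, p: np.ndarray, alpha: float = 0.005) -> np.ndarray:
    """Indices (genomic order) of segments with p < alpha."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if len(p) != segments.n:
        raise ValueError("p-value vector does not align with segments")
    return np.flatnonzero(np.asarray(p) < alpha)


def declare_outliers(
    features: FeatureTable,
    model: NullModel,
    p: np.ndarray,
    alpha: float = 0.005,
    shield_ratio: float = 0.1,
    max_rounds: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Declaration with outlier orientation and shielded-outlier recovery.

    Base rule: a segment is declared when p < alpha *and* it lies in the
    outlier corner of the decision graph (delta above the null mean, rho
    below) — copy-number outliers are sparse, isolated objects; a
    significant deviation in any other orientation is not a CNV signature.

    Recovery rule: recurrent events at the same copy number form a tight
    clump in level space whose densest member absorbs the whole clump's
    isolation (large delta) while shielding its peers (tiny delta).  A
    shielded segment i is additionally declared when

    * delta_i >= gamma (it is not density-connected to its shield — tight
      gamma-pairs also arise by chance in a CNV-free tail),
    * the denser segment that defined delta_i is already declared,
    * delta_i < ``shield_ratio`` times delta'_i, the distance to the nearest
      denser segment *outside* the declared set (the clump is far tighter
      than its separation from the rest),
    * the re-tested feature (rho_i, delta'_i) is significant at alpha / n
      (a multiplicity correction, since the recovery re-tests adaptively)
      and in the outlier orientation.

    Rounds repeat until no segment is added.  Returns (declared indices in
    genomic order, per-segment p-values with recovered segments carrying
    their re-tested value).
    """
    n = features.n
    d = features.distances.full()
    rho = features.rho
    declared = np.zeros(n, dtype=bool)
    quad = (features.delta > model.mu[1]) & (rho < model.mu[0])
    declared[(np.asarray(p) < alpha) & quad] = True
    alpha_prop = alpha / n
    p_final = np.asarray(p, dtype=float).copy()
    for _ in range(max_rounds):
        added = False
        for i in np.flatnonzero(~declared):
            if features.delta[i] < features.gamma:
                continue
            denser = np.flatnonzero(rho > rho[i])
            if len(denser) == 0:
                continue
            avail = denser[~declared[denser]]
            shields = denser[declared[denser]]
            if len(shields) == 0 or len(avail) == 0:
                continue
            if d[i, shields].min() > features.delta[i] + 1e-12:
                continue
            d_prime = d[i, avail].min()
            if features.delta[i] >= shield_ratio * d_prime:
                continue
            x = np.array([[float(rho[i]), d_prime]])
            p_i = float(np.exp(-0.5 * model.mahalanobis_sq(x)[0]))
            if p_i < alpha_prop and d_prime > model.mu[1] and rho[i] < model.mu[0]:
                declared[i] = True
                p_final[i] = min(p_final[i], p_i)
                added = True
        if not added:
            break
    return np.flatnonzero(declared), p_final


def baseline_rd(segments: SegmentSet, features: FeatureTable) -> float:
    """Bin-count-weighted mean level of the cluster-center neighborhood.

    The center c is the segment of maximal rho (ties -> lowest genomic
    index); the neighborhood is every segment within gamma of c, c included.
    Weighting by member-bin counts lets long normal segments dominate.
    """
    c = int(np.argmax(features.rho))  # argmax returns the first maximal index
    d_to_c = np.abs(segments.level - segments.level[c])
    members = d_to_c < features.gamma
    members[c] = True
    w = segments.n_bins[members].astype(float)
    return float(np.average(segments.level[members], weights=w))


def assign_types(
    segments: SegmentSet,
    flagged: np.ndarray,
    p: np.ndarray,
    r_b: float,
) -> list[CNVCall]:
    """Type each flagged segment against r_b and merge adjacent same-status calls.

    Amplification iff level > r_b, deletion otherwise (a segment exactly at
    the baseline falls in the deletion branch; it cannot be a significant
    outlier in practice).  Flagged segments that are genomically adjacent
    (no unmasked bin between them), on the same chromosome and of the same
    status merge into one interval carrying the minimum member p-value.
    """
    flagged = np.asarray(flagged, dtype=int)
    if len(flagged) == 0:
        return []
    order = flagged[np.lexsort((segments.start[flagged],
                                np.array([str(c) for c in segments.chrom[flagged]])))]
    calls: list[CNVCall] = []
    prev_idx = None
    for i in order:
        status = AMPLIFICATION if segments.level[i] > r_b else DELETION
        adjacent = (
            prev_idx is not None
            and segments.chrom[i] == calls[-1].chrom
            and segments.bin_first[i] == segments.bin_last[prev_idx] + 1
            and status == calls[-1].status
        )
        if adjacent:
            last = calls[-1]
            nb = last.n_bins + int(segments.n_bins[i])
            # bin-weighted level over the merged span; min p retained
            rd = (last.rd * last.n_bins + segments.level[i] * segments.n_bins[i]) / nb
            calls[-1] = CNVCall(
                chrom=last.chrom,
                start=last.start,
                end=int(segments.end[i]),
                rd=float(rd),
                p_value=min(last.p_value, float(p[i])),
                status=status,
                n_bins=nb,
            )
        else:
            calls.append(
                CNVCall(
                    chrom=str(segments.chrom[i]),
                    start=int(segments.start[i]),
                    end=int(segments.end[i]),
                    rd=float(segments.level[i]),
                    p_value=float(p[i]),
                    status=status,
                    n_bins=int(segments.n_bins[i]),
                )
            )
        prev_idx = i
    return calls


def calls_to_frame(calls: list[CNVCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "status": c.status,
                "rd": c.rd,
                "p_value": c.p_value,
                "n_bins": c.n_bins,
            }
            for c in calls
        ],
        columns=["chrom", "start", "end", "status", "rd", "p_value", "n_bins"],
    )
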
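"""End-to-end CNV calling pipeline and call-file output.

Stages: load counts -> (optional) GC annotation -> GC-bias correction ->
low-quality masking -> fused-lasso segmentation -> density-peak features ->
bivariate Gaussian null -> declaration at alpha -> typing against r_b ->
BED-like output.  The run is deterministic given inputs and configuration;
every output file carries a reproducibility header (version, config hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .features import compute_features
from .nulltest import (
    CNVCall,
    assign_types,
    baseline_rd,
    declare_outliers,
    robust_null,
)
from .profile import (
    BinProfile,
    annotate_gc,
    correct_gc_bias,
    load_read_counts,
    mask_low_quality_bins,
)
from .segmentation import absorb_small_segments, segment_profile

__all__ = ["PipelineConfig", "RunReport", "run_call_pipeline", "call_profile", "write_calls_bed"]

log = logging.getLogger("dpcnv")


@dataclass
class PipelineConfig:
    input: str = ""
    reference: str | None = None
    chroms: list[str] | None = None
    bin_size: int = 1000
    gc_bin_width: float = 0.01
    min_bins_per_stratum: int = 20
    zero_run_min: int = 10
    lam: float | None = None             # None -> data-driven universal threshold
    merge_tol: float = 1e-8
    min_seg_bins: int = 20               # absorb shorter segments into neighbors
    gamma: float | None = None           # None -> neighbor-fraction quantile
    neighbor_fraction: float = 0.02
    alpha: float = 0.005
    exclude_p: float = 1e-8              # robust-null extreme-outlier cut
    refit_rounds: int = 2
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    n_bins: int = 0
    n_masked: int = 0
    n_segments: int = 0
    lam: float = float("nan")
    gamma: float = float("nan")
    mu: list[float] = field(default_factory=list)
    sigma: list[list[float]] = field(default_factory=list)
    r_b: float = float("nan")
    alpha: float = float("nan")
    n_flagged: int = 0
    n_calls: int = 0
    config_hash: str = ""


def call_profile(profile: BinProfile, config: PipelineConfig) -> tuple[list[CNVCall], RunReport]:
    """Run segmentation, feature extraction and significance testing on a
    prepared (corrected, masked) profile.

    Profiles too degenerate to define a density structure (fewer than three
    segments, or all segment levels identical) yield an empty call set.
    """
    report = RunReport(alpha=config.alpha, config_hash=config.config_hash())
    report.n_bins = profile.n_bins
    report.n_masked = int(profile.mask.sum())

    segments, lam = segment_profile(profile, lam=config.lam, merge_tol=config.merge_tol)
    report.lam = lam
    segments = absorb_small_segments(segments, min_bins=config.min_seg_bins)
    report.n_segments = segments.n
    log.info("segmentation: %d segments after absorption (lambda=%.4g)", segments.n, lam)
    if segments.n < 3:
        log.info("fewer than 3 segments; no density structure, zero calls")
        return [], report

    try:
        features = compute_features(segments, gamma=config.gamma,
                                     neighbor_fraction=config.neighbor_fraction)
        model, p = robust_null(features, exclude_p=config.exclude_p,
                               refit_rounds=config.refit_rounds)
    except ValueError as exc:
        log.info("degenerate feature structure (%s); zero calls", exc)
        return [], report
    report.gamma = features.gamma
    report.mu = [float(v) for v in model.mu]
    report.sigma = [[float(v) for v in row] for row in model.sigma]

    flagged, p_final = declare_outliers(features, model, p, alpha=config.alpha)
    report.n_flagged = len(flagged)
    r_b = baseline_rd(segments, features)
    report.r_b = r_b
    calls = assign_types(segments, flagged, p_final, r_b)
    report.n_calls = len(calls)
    log.info("declared %d significant segments -> %d calls (r_b=%.3f)", len(flagged), len(calls), r_b)
    return calls, report


def run_call_pipeline(config: PipelineConfig) -> tuple[list[CNVCall], RunReport]:
    """Full pipeline from a BAM or count TSV to typed CNV calls."""
    try:
        profile = load_read_counts(config.input, bin_size=config.bin_size, chroms=config.chroms)
    except Exception as exc:
        raise RuntimeError(f"stage load_read_counts failed: {exc}") from exc
    log.info("loaded %d bins from %s", profile.n_bins, config.input)

    if config.reference:
        try:
            profile = annotate_gc(profile, config.reference)
        except Exception as exc:
            raise RuntimeError(f"stage annotate_gc failed: {exc}") from exc
    profile = mask_low_quality_bins(profile, zero_run_min=config.zero_run_min)
    try:
        profile = correct_gc_bias(profile, gc_bin_width=config.gc_bin_width,
                                  min_bins_per_stratum=config.min_bins_per_stratum)
    except Exception as exc:
        raise RuntimeError(f"stage correct_gc_bias failed: {exc}") from exc
    return call_profile(profile, config)


def write_calls_bed(calls: list[CNVCall], report: RunReport, path: str | Path,
                    seed: int | None = None) -> None:
    """BED-like TSV: chrom, start, end, status, rd, p_value, n_bins (0-based
    half-open), preceded by a reproducibility header."""
    with open(path, "w") as fh:
        fh.write(f"##dpcnv_version={__version__}\n")
        fh.write(f"##config_hash={report.config_hash}\n")
        if seed is not None:
            fh.write(f"##seed={seed}\n")
        fh.write(f"##n_segments={report.n_segments}\tgamma={report.gamma:.6g}\t"
                 f"r_b={report.r_b:.6g}\talpha={report.alpha}\n")
        fh.write("#chrom\tstart\tend\tstatus\trd\tp_value\tn_bins\n")
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.status}\t"
                     f"{c.rd:.6g}\t{c.p_value:.6g}\t{c.n_bins}\n")
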
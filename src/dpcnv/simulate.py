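"""Synthetic binned tumor read-depth profiles with known CNV truth.

The generator is a transparent purity-mixture count model, a lightweight
stand-in for full read-level tumor simulators.  For a bin with tumor copy
number CN at tumor purity p the expected count is

    mu = base_depth * [(1 - p) + p * CN / 2] * g(gc),

i.e. a mixture of diploid normal cells and tumor cells, optionally modulated
by a smooth GC response g (mean-normalized to 1).  Counts are drawn
negative-binomially with the given overdispersion (Poisson when 0).  GC
fractions follow a smooth autocorrelated process confined to [0.3, 0.7].

The scenario grid of interest crosses tumor purity {0.2, 0.3, 0.4} with
coverage depth {4x, 6x}; the coverage presets assume 100 bp reads, so a 4x
genome yields about 40 expected reads per 1 kb bin and 6x about 60.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .nulltest import AMPLIFICATION, DELETION, CNVCall
from .profile import BinProfile

__all__ = [
    "SimConfig",
    "SimTruth",
    "Metrics",
    "coverage_to_base_depth",
    "random_cnv_spec",
    "simulate_profile",
    "evaluate_calls",
]

READ_LENGTH = 100  # bp, fixed for the coverage presets

GAIN = "gain"
LOSS = "loss"


def coverage_to_base_depth(coverage: float, bin_size: int = 1000) -> float:
    """Expected reads per diploid bin for a genome-wide coverage depth."""
    return coverage * bin_size / READ_LENGTH


@dataclass
class SimConfig:
    """Parameters of one simulated sample.

    ``cnv_spec`` lists embedded events as (start_bin, length_bins,
    copy_number) with copy_number in {0, 1, 3, 4, ...} (2 is diploid and not
    an event).  ``dispersion`` is the negative-binomial overdispersion a in
    Var = mu + a * mu^2; 0 selects Poisson counts.
    """

    n_bins: int = 50_000
    bin_size: int = 1000
    base_depth: float = coverage_to_base_depth(6.0)
    purity: float = 0.4
    cnv_spec: list[tuple[int, int, int]] = field(default_factory=list)
    gc_bias: float = 0.0
    dispersion: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_bins < 1 or self.bin_size < 100:
            raise ValueError("n_bins >= 1 and bin_size >= 100 required")
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        prev_end = -1
        for start, length, cn in sorted(self.cnv_spec):
            if cn == 2 or cn < 0:
                raise ValueError(f"CNV copy number must be a non-negative integer != 2, got {cn}")
            if length < 1 or start < 0 or start + length > self.n_bins:
                raise ValueError(f"CNV ({start}, {length}) outside [0, {self.n_bins})")
            if start <= prev_end:
                raise ValueError(f"overlapping CNV intervals at bin {start}")
            prev_end = start + length - 1


@dataclass
class SimTruth:
    """Ground-truth CNV intervals in bp coordinates."""

    start: np.ndarray          # bp, 0-based
    end: np.ndarray            # bp, half-open
    copy_number: np.ndarray
    status: np.ndarray         # gain | loss

    @property
    def n(self) -> int:
        return len(self.start)

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for s, e, cn, st in zip(self.start, self.end, self.copy_number, self.status):
                fh.write(f"chr1\t{s}\t{e}\t{st}\t{cn}\n")


def random_cnv_spec(
    n_bins: int,
    n_cnvs: int = 20,
    min_len: int = 20,
    max_len: int = 100,
    copy_numbers: tuple[int, ...] = (0, 1, 4, 6),
    rng: np.random.Generator | None = None,
    gap: int = 50,
) -> list[tuple[int, int, int]]:
    """Disjoint random CNV intervals separated by at least ``gap`` diploid bins."""
    rng = np.random.default_rng(rng)
    lengths = rng.integers(min_len, max_len + 1, size=n_cnvs)
    cns = rng.choice(copy_numbers, size=n_cnvs)
    # place sequentially in the slack left over after reserving lengths + gaps
    slack = n_bins - int(lengths.sum()) - gap * (n_cnvs + 1)
    if slack < 0:
        raise ValueError(f"{n_cnvs} CNVs of <= {max_len} bins do not fit in {n_bins} bins")
    offsets = np.sort(rng.integers(0, slack + 1, size=n_cnvs))
    spec = []
    for k in range(n_cnvs):
        start = int(offsets[k]) + int(lengths[:k].sum()) + gap * (k + 1)
        spec.append((start, int(lengths[k]), int(cns[k])))
    return spec


def _smooth_gc(n_bins: int, rng: np.random.Generator) -> np.ndarray:
    """AR(1) latent process squashed into [0.3, 0.7]."""
    phi = 0.98
    eps = rng.normal(0.0, np.sqrt(1.0 - phi * phi), size=n_bins)
    eps[0] = rng.normal()  # stationary start
    z = lfilter([1.0], [1.0, -phi], eps)
    return 0.5 + 0.2 * np.tanh(z)


def simulate_profile(config: SimConfig) -> tuple[BinProfile, SimTruth]:
    """Draw one binned tumor profile plus its ground truth.

    Identical config (seed included) gives bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_bins
    gc = _smooth_gc(n, rng)

    cn = np.full(n, 2, dtype=np.int64)
    for start, length, c in config.cnv_spec:
        cn[start:start + length] = c

    if config.gc_bias != 0.0:
        g = 1.0 + config.gc_bias * np.sin(2.0 * np.pi * gc)
        g = g / g.mean()
    else:
        g = np.ones(n)

    mu = config.base_depth * ((1.0 - config.purity) + config.purity * cn / 2.0) * g
    if config.dispersion == 0.0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / config.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))

    profile = BinProfile(
        chrom=np.array(["chr1"] * n, dtype=object),
        start=np.arange(n, dtype=np.int64) * config.bin_size,
        width=config.bin_size,
        count=counts.astype(np.int64),
        gc=gc,
    )
    spec = sorted(config.cnv_spec)
    truth = SimTruth(
        start=np.array([s * config.bin_size for s, _, _ in spec], dtype=np.int64),
        end=np.array([(s + ln) * config.bin_size for s, ln, _ in spec], dtype=np.int64),
        copy_number=np.array([c for _, _, c in spec], dtype=np.int64),
        status=np.array([GAIN if c > 2 else LOSS for _, _, c in spec], dtype=object),
    )
    return profile, truth


@dataclass
class Metrics:
    precision: float
    sensitivity: float
    f1: float
    n_calls: int
    n_truth: int
    n_correct_calls: int
    n_truth_detected: int


_STATUS_MATCH = {AMPLIFICATION: GAIN, DELETION: LOSS}


def evaluate_calls(
    calls: list[CNVCall],
    truth: SimTruth,
    min_overlap_fraction: float = 0.0,
) -> Metrics:
    """Precision / sensitivity / F1 of a call set against the ground truth.

    A call is correct when it overlaps a truth interval of the same status
    by more than ``min_overlap_fraction`` of the truth interval's length
    (any positive overlap when the fraction is 0).  Precision is correct
    calls over all calls; sensitivity is detected truth intervals (each
    counted once) over all truth intervals; F1 is their harmonic mean.
    """
    n_calls, n_truth = len(calls), truth.n
    correct = 0
    hit = np.zeros(n_truth, dtype=bool)
    for call in calls:
        ok = False
        for t in range(n_truth):
            if _STATUS_MATCH.get(call.status) != truth.status[t]:
                continue
            ov = min(call.end, truth.end[t]) - max(call.start, truth.start[t])
            needed = min_overlap_fraction * (truth.end[t] - truth.start[t])
            if ov > 0 and ov >= needed:
                ok = True
                hit[t] = True
        correct += ok
    if n_calls == 0:
        if n_truth:
            warnings.warn("no calls against a non-empty truth set; precision reported as 0")
        precision = 0.0
    else:
        precision = correct / n_calls
    sensitivity = float(hit.sum()) / n_truth if n_truth else 0.0
    f1 = (
        2.0 * precision * sensitivity / (precision + sensitivity)
        if precision + sensitivity > 0
        else 0.0
    )
    return Metrics(precision, sensitivity, f1, n_calls, n_truth, correct, int(hit.sum()))
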
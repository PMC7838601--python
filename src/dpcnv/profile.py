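"""Binned read-depth profiles: loading, GC annotation, bias correction, masking.

A :class:`BinProfile` holds per-bin read counts along one or more chromosomes
at a fixed bin size, together with the GC fraction of each bin's reference
sequence, the raw and GC-corrected read depth, and a mask flagging bins that
are excluded from all downstream analysis (assembly gaps, all-N reference,
long zero-count runs).

Because the bin size is constant, the raw per-bin count itself serves as the
read-depth proxy (``rd_raw = count``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BinProfile",
    "load_read_counts",
    "annotate_gc",
    "correct_gc_bias",
    "mask_low_quality_bins",
    "write_count_tsv",
]

TSV_HEADER = "#chrom\tstart\tcount\tgc"


@dataclass
class BinProfile:
    """Per-bin read-depth profile over one or more chromosomes.

    Bins within a chromosome are contiguous, non-overlapping and sorted by
    start.  ``gc`` is NaN where not yet annotated or where the reference is
    all N; ``rd`` is NaN until :func:`correct_gc_bias` has run.
    """

    chrom: np.ndarray          # str per bin
    start: np.ndarray          # 0-based bp
    width: int                 # bin size, bp
    count: np.ndarray          # int reads per bin
    gc: np.ndarray = field(default=None)        # fraction in [0,1] or NaN
    rd_raw: np.ndarray = field(default=None)    # float depth proxy
    rd: np.ndarray = field(default=None)        # GC-corrected depth
    mask: np.ndarray = field(default=None)      # True = excluded

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.count = np.asarray(self.count, dtype=np.int64)
        n = len(self.count)
        if self.gc is None:
            self.gc = np.full(n, np.nan)
        if self.rd_raw is None:
            self.rd_raw = self.count.astype(float)
        if self.rd is None:
            self.rd = np.full(n, np.nan)
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)
        self.gc = np.asarray(self.gc, dtype=float)
        self.rd_raw = np.asarray(self.rd_raw, dtype=float)
        self.rd = np.asarray(self.rd, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self._validate()

    def _validate(self) -> None:
        n = len(self.count)
        for name in ("chrom", "start", "gc", "rd_raw", "rd", "mask"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name!r} has length {len(getattr(self, name))}, expected {n}")
        if np.any(self.count < 0):
            raise ValueError("negative read count")
        for chrom in self.chromosomes:
            s = self.start[self.chrom == chrom]
            if len(s) and not np.array_equal(s, np.arange(s[0], s[0] + len(s) * self.width, self.width)):
                bad = np.flatnonzero(np.diff(s) != self.width)
                raise ValueError(
                    f"bins on {chrom} are not sorted/contiguous at row {bad[0] + 1 if len(bad) else 0} "
                    f"(start {s[bad[0] + 1] if len(bad) else s[0]})"
                )

    @property
    def n_bins(self) -> int:
        return len(self.count)

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    @property
    def end(self) -> np.ndarray:
        return self.start + self.width

    def unmasked(self) -> np.ndarray:
        """Indices of bins that enter the analysis."""
        return np.flatnonzero(~self.mask)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "count": self.count,
                "gc": self.gc,
                "rd_raw": self.rd_raw,
                "rd": self.rd,
                "mask": self.mask,
            }
        )


def _profile_from_table(df: pd.DataFrame, bin_size: int) -> BinProfile:
    gc = df["gc"].to_numpy(float) if "gc" in df.columns else None
    return BinProfile(
        chrom=df["chrom"].to_numpy(object),
        start=df["start"].to_numpy(np.int64),
        width=bin_size,
        count=df["count"].to_numpy(np.int64),
        gc=gc,
    )


def _load_tsv(path: Path, bin_size: int, chroms: Sequence[str] | None) -> BinProfile:
    df = pd.read_csv(path, sep="\t", comment=None, dtype={0: str})
    df.columns = [c.lstrip("#") for c in df.columns]
    required = {"chrom", "start", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"count TSV {path} lacks columns {sorted(required - set(df.columns))}")
    if chroms is not None:
        df = df[df["chrom"].isin(chroms)].reset_index(drop=True)
    # validate sortedness/contiguity per chromosome before building
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        diffs = np.diff(starts)
        bad = np.flatnonzero(diffs != bin_size)
        if len(bad):
            row = sub.index[bad[0] + 1]
            if diffs[bad[0]] <= 0:
                raise ValueError(f"count TSV {path}: unsorted or overlapping bins at row {row} ({chrom}:{starts[bad[0] + 1]})")
            raise ValueError(f"count TSV {path}: non-contiguous bins at row {row} ({chrom}:{starts[bad[0] + 1]})")
    return _profile_from_table(df, bin_size)


def _load_bam(path: Path, bin_size: int, chroms: Sequence[str] | None) -> BinProfile:
    import pysam

    if not (Path(str(path) + ".bai").exists() or Path(str(path)).with_suffix(".bai").exists()
            or Path(str(path) + ".csi").exists()):
        raise FileNotFoundError(f"missing BAM index for {path} (expected {path}.bai)")
    with pysam.AlignmentFile(str(path), "rb") as bam:
        names = list(bam.references)
        lengths = dict(zip(names, bam.lengths))
        use = [c for c in (chroms if chroms is not None else names) if c in lengths]
        if chroms is not None:
            missing = set(chroms) - set(names)
            if missing:
                raise ValueError(f"chromosomes {sorted(missing)} absent from {path}")
        chrom_col: list[str] = []
        start_col: list[int] = []
        counts: list[np.ndarray] = []
        for chrom in use:
            nb = -(-lengths[chrom] // bin_size)  # ceil division: cover end to end
            c = np.zeros(nb, dtype=np.int64)
            for read in bam.fetch(chrom):
                if read.is_unmapped or read.is_secondary or read.is_duplicate or read.is_supplementary:
                    continue
                c[read.reference_start // bin_size] += 1
            chrom_col.extend([chrom] * nb)
            start_col.extend(range(0, nb * bin_size, bin_size))
            counts.append(c)
    return BinProfile(
        chrom=np.array(chrom_col, dtype=object),
        start=np.array(start_col, dtype=np.int64),
        width=bin_size,
        count=np.concatenate(counts) if counts else np.zeros(0, dtype=np.int64),
    )


def load_read_counts(
    alignment_source: str | Path,
    bin_size: int = 1000,
    chroms: Sequence[str] | None = None,
) -> BinProfile:
    """Build a :class:`BinProfile` from a coordinate-sorted indexed BAM or a
    count-table TSV (columns chrom, start, count[, gc]).

    Reads are assigned to the bin containing their leftmost mapped base;
    unmapped, secondary, supplementary and duplicate-flagged reads are
    skipped.  ``bin_size`` must be at least 100 bp.
    """
    if bin_size < 100:
        raise ValueError(f"bin_size must be >= 100 bp, got {bin_size}")
    path = Path(alignment_source)
    if not path.exists():
        raise FileNotFoundError(f"input {path} does not exist")
    if path.suffix.lower() == ".bam":
        return _load_bam(path, bin_size, chroms)
    return _load_tsv(path, bin_size, chroms)


def write_count_tsv(profile: BinProfile, path: str | Path) -> None:
    """Write the count-table dialect: ``#chrom  start  count  gc``."""
    with open(path, "w") as fh:
        fh.write(TSV_HEADER + "\n")
        for chrom, start, count, gc in zip(profile.chrom, profile.start, profile.count, profile.gc):
            gc_s = "" if np.isnan(gc) else f"{gc:.6g}"
            fh.write(f"{chrom}\t{start}\t{count}\t{gc_s}\n")


def annotate_gc(profile: BinProfile, reference: str | Path, n_mask_fraction: float = 0.5) -> BinProfile:
    """Annotate each bin with the GC fraction of its reference sequence.

    gc = (#G + #C) / (#A + #C + #G + #T) over the bin; bins whose sequence is
    more than ``n_mask_fraction`` N bases are masked (gc left NaN when no
    informative base exists).
    """
    from pyfaidx import Fasta

    fasta = Fasta(str(reference), sequence_always_upper=True)
    missing = [c for c in profile.chromosomes if c not in fasta]
    if missing:
        raise ValueError(f"chromosome(s) {missing} absent from reference {reference}")
    gc = profile.gc.copy()
    mask = profile.mask.copy()
    for i in range(profile.n_bins):
        seq = str(fasta[profile.chrom[i]][profile.start[i]: profile.start[i] + profile.width])
        n_n = seq.count("N")
        informative = sum(seq.count(b) for b in "ACGT")
        if len(seq) == 0 or n_n > n_mask_fraction * len(seq):
            mask[i] = True
        if informative > 0:
            gc[i] = (seq.count("G") + seq.count("C")) / informative
    out = BinProfile(profile.chrom, profile.start, profile.width, profile.count,
                     gc=gc, rd_raw=profile.rd_raw, rd=profile.rd, mask=mask)
    return out


def correct_gc_bias(
    profile: BinProfile,
    gc_bin_width: float = 0.01,
    min_bins_per_stratum: int = 20,
) -> BinProfile:
    """Median-stratum GC-bias correction.

    ``rd = rd_raw * m / m_gc`` where *m* is the median raw depth over all
    unmasked bins and *m_gc* the median over unmasked bins in the same GC
    stratum (width ``gc_bin_width``).  Strata with fewer than
    ``min_bins_per_stratum`` bins borrow the global median (no correction);
    strata whose median is zero are masked.
    """
    idx = profile.unmasked()
    if len(idx) == 0:
        raise ValueError("all bins are masked; nothing to correct")
    rd_raw = profile.rd_raw
    m = float(np.median(rd_raw[idx]))
    rd = np.full(profile.n_bins, np.nan)
    mask = profile.mask.copy()

    gc = profile.gc
    no_gc = idx[np.isnan(gc[idx])]
    rd[no_gc] = rd_raw[no_gc]  # un-annotated bins pass through uncorrected

    with_gc = idx[~np.isnan(gc[idx])]
    strata = np.floor(gc[with_gc] / gc_bin_width).astype(int)
    for s in np.unique(strata):
        members = with_gc[strata == s]
        if len(members) < min_bins_per_stratum:
            rd[members] = rd_raw[members]
            continue
        m_gc = float(np.median(rd_raw[members]))
        if m_gc == 0.0:
            mask[members] = True
            continue
        rd[members] = rd_raw[members] * m / m_gc
    return BinProfile(profile.chrom, profile.start, profile.width, profile.count,
                      gc=gc, rd_raw=rd_raw, rd=rd, mask=mask)


def mask_low_quality_bins(profile: BinProfile, zero_run_min: int = 10) -> BinProfile:
    """Mask bins inside runs of >= ``zero_run_min`` consecutive zero-count bins.

    Long zero runs are assembly gaps or unmappable sequence; calling them as
    deletions would be artifactual.  Runs are evaluated per chromosome.
    """
    mask = profile.mask.copy()
    for chrom in profile.chromosomes:
        where = np.flatnonzero(profile.chrom == chrom)
        zero = profile.count[where] == 0
        # run-length encode the zero indicator
        boundaries = np.flatnonzero(np.diff(zero.astype(np.int8))) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [len(zero)]])
        for s, e in zip(starts, ends):
            if zero[s] and e - s >= zero_run_min:
                mask[where[s:e]] = True
    return BinProfile(profile.chrom, profile.start, profile.width, profile.count,
                      gc=profile.gc, rd_raw=profile.rd_raw, rd=profile.rd, mask=mask)
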
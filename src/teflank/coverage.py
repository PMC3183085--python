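"""Read filtering, fragment extension, coverage tracks, and flank profiles.

Reads are extended directionally to the expected fragment length (native
ChIP chromatin is predominantly mono-nucleosomal, hence the 150 bp
default; immunoprecipitated methylated DNA uses 200 bp).  Coverage at a
base is the number of extended fragments overlapping it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome_io import AlignedRead, GenomicInterval, SignalTrack, TEInsertion

log = logging.getLogger(__name__)

DEFAULT_FRAGMENT_LEN = 150

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"


@dataclass
class FlankProfile:
    """Per-base coverage over one flank of one element.

    ``values[0]`` is the base adjacent to the element edge; indices
    increase away from the element, regardless of genomic strand.
    """

    copy_id: str
    side: str
    values: np.ndarray
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.side not in (FIVE_PRIME, THREE_PRIME):
            raise ValueError(f"invalid side {self.side!r}")
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class MetaProfile:
    """Copy-count and library-size normalized family average profile."""

    family: str
    side: str
    values: np.ndarray
    n_copies: int
    lib_scale: float


def filter_reads(
    reads: Sequence[AlignedRead],
    min_mapq: int = 7,
    unique_only: bool = True,
    dedup: bool = True,
) -> tuple[list[AlignedRead], int]:
    """Apply mapping-quality, uniqueness, and duplicate filters.

    A read is kept iff mapq >= min_mapq and (when unique_only) it aligned
    uniquely.  Duplicates share (chrom, pos5, strand); only the first
    occurrence is retained.  Returns (kept reads, retained count).
    """
    kept: list[AlignedRead] = []
    seen: set[tuple[str, int, str]] = set()
    for r in reads:
        if r.mapq < min_mapq:
            continue
        if unique_only and not r.is_unique:
            continue
        if dedup:
            key = (r.chrom, r.pos5, r.strand)
            if key in seen:
                continue
            seen.add(key)
        kept.append(r)
    return kept, len(kept)


def extend_read(
    read: AlignedRead,
    fragment_len: int = DEFAULT_FRAGMENT_LEN,
    chrom_size: int | None = None,
) -> GenomicInterval:
    """Directionally extend a read to its fragment interval.

    + strand: [pos5, pos5+fragment_len); - strand: [pos5-fragment_len+1,
    pos5+1).  The interval is silently clipped to [0, chrom_size).
    """
    if read.strand == "+":
        start, end = read.pos5, read.pos5 + fragment_len
    else:
        start, end = read.pos5 - fragment_len + 1, read.pos5 + 1
    clipped_start = max(start, 0)
    clipped_end = end if chrom_size is None else min(end, chrom_size)
    if clipped_start != start or clipped_end != end:
        log.debug(
            "fragment %s:%d-%d clipped to %d-%d", read.chrom, start, end,
            clipped_start, clipped_end,
        )
    return GenomicInterval(read.chrom, clipped_start, clipped_end, read.strand)


def _fragment_bounds(
    reads: Sequence[AlignedRead],
    fragment_len: int,
    chrom_sizes: dict[str, int] | None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Clipped fragment (start, end) arrays, parallel to ``reads``."""
    starts = np.empty(len(reads), dtype=np.int64)
    ends = np.empty(len(reads), dtype=np.int64)
    chroms = []
    for i, r in enumerate(reads):
        if r.strand == "+":
            s, e = r.pos5, r.pos5 + fragment_len
        else:
            s, e = r.pos5 - fragment_len + 1, r.pos5 + 1
        s = max(s, 0)
        if chrom_sizes is not None:
            e = min(e, chrom_sizes[r.chrom])
        starts[i], ends[i] = s, e
        chroms.append(r.chrom)
    return starts, ends, chroms


def mask_te_reads(
    reads: Sequence[AlignedRead],
    te_intervals: Sequence[GenomicInterval | TEInsertion],
    fragment_len: int = DEFAULT_FRAGMENT_LEN,
    chrom_sizes: dict[str, int] | None = None,
) -> list[AlignedRead]:
    """Drop reads whose extended fragment overlaps any element body.

    Whole reads are removed (not clipped) when the fragment overlaps a
    body by >= 1 bp, so element-internal signal never leaks into flank
    statistics.
    """
    bodies: dict[str, list[tuple[int, int]]] = {}
    for te in te_intervals:
        iv = te.interval if isinstance(te, TEInsertion) else te
        bodies.setdefault(iv.chrom, []).append((iv.start, iv.end))
    index = {}
    for chrom, ivs in bodies.items():
        ivs.sort()
        starts = np.array([s for s, _ in ivs], dtype=np.int64)
        # max end over a sorted prefix handles nested/overlapping bodies
        ends = np.maximum.accumulate(np.array([e for _, e in ivs], dtype=np.int64))
        index[chrom] = (starts, ends)

    if not reads:
        return []
    fstarts, fends, fchroms = _fragment_bounds(reads, fragment_len, chrom_sizes)
    kept = []
    for i, r in enumerate(reads):
        hit = False
        if r.chrom in index:
            starts, ends = index[r.chrom]
            j = int(np.searchsorted(starts, fends[i], side="left")) - 1
            hit = j >= 0 and ends[j] > fstarts[i]
        if not hit:
            kept.append(r)
    return kept


def build_coverage(
    reads: Sequence[AlignedRead],
    fragment_len: int,
    chrom_sizes: dict[str, int],
) -> SignalTrack:
    """Per-base extended-fragment coverage over the whole genome.

    Conservation: the total coverage equals the summed (clipped) fragment
    lengths of the input reads.
    """
    diffs = {c: np.zeros(n + 1, dtype=np.int64) for c, n in chrom_sizes.items()}
    for r in reads:
        if r.chrom not in diffs:
            raise ValueError(f"read on unknown chromosome {r.chrom!r}")
        size = chrom_sizes[r.chrom]
        if r.strand == "+":
            s, e = r.pos5, r.pos5 + fragment_len
        else:
            s, e = r.pos5 - fragment_len + 1, r.pos5 + 1
        s, e = max(s, 0), min(e, size)
        if e > s:
            d = diffs[r.chrom]
            d[s] += 1
            d[e] -= 1
    return SignalTrack(
        {c: np.cumsum(d[:-1]).astype(float) for c, d in diffs.items()}
    )


def extract_flank_profile(
    track: SignalTrack,
    insertion: TEInsertion,
    flank_len: int = 5000,
) -> tuple[FlankProfile, FlankProfile]:
    """Strand-aware 5' and 3' flank profiles for one element.

    For a + strand element the 5' flank is the genomic interval
    [start-flank_len, start) read right-to-left so that index 0 abuts the
    element; the 3' flank is [end, end+flank_len) left-to-right.  For a
    - strand element the genomic sides swap and orientations mirror.
    Flanks that run off the chromosome are zero-padded and flagged.

    Returns (five_prime, three_prime).
    """
    iv = insertion.interval
    upstream = track.region(iv.chrom, iv.start - flank_len, iv.start)[::-1]
    downstream = track.region(iv.chrom, iv.end, iv.end + flank_len)
    up_trunc = not track.covers(iv.chrom, iv.start - flank_len, iv.start)
    down_trunc = not track.covers(iv.chrom, iv.end, iv.end + flank_len)
    if iv.strand == "-":
        five = FlankProfile(insertion.copy_id, FIVE_PRIME, downstream, down_trunc)
        three = FlankProfile(insertion.copy_id, THREE_PRIME, upstream, up_trunc)
    else:
        five = FlankProfile(insertion.copy_id, FIVE_PRIME, upstream, up_trunc)
        three = FlankProfile(insertion.copy_id, THREE_PRIME, downstream, down_trunc)
    return five, three


def aggregate_profiles(
    profiles: Sequence[FlankProfile],
    lib_scale: float = 1.0,
    family: str = "",
) -> MetaProfile:
    """Average per-copy flank profiles and rescale for library size.

    ``values = (sum of profiles) / n_copies * lib_scale`` where lib_scale
    is N_reference_line / N_this_line (1 for the reference line itself).
    All profiles must share side and length.
    """
    if not profiles:
        raise ValueError("no profiles to aggregate")
    side = profiles[0].side
    n = len(profiles[0].values)
    for p in profiles:
        if p.side != side:
            raise ValueError("cannot aggregate mixed 5'/3' profiles")
        if len(p.values) != n:
            raise ValueError("cannot aggregate profiles of mixed lengths")
    stacked = np.vstack([p.values for p in profiles])
    values = stacked.sum(axis=0) / len(profiles) * lib_scale
    return MetaProfile(
        family=family,
        side=side,
        values=values,
        n_copies=len(profiles),
        lib_scale=lib_scale,
    )


def write_metaprofile(profile: MetaProfile, path) -> None:
    """Export a metaprofile as TSV (offset_bp, density)."""
    with open(path, "w") as fh:
        fh.write("offset_bp\tdensity\n")
        for i, v in enumerate(profile.values):
            fh.write(f"{i}\t{float(v)!r}\n")
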
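"""Core comparison statistics: RPKM, RPKM asymmetry, skewness, windowed
spreading analysis, nonparametric group tests, and the genome-wide
differential scan.

The asymmetry of a region between two libraries A and B is

    (RPKM_A - RPKM_B) / (RPKM_A + RPKM_B + eps)

which lies in [-1, +1]: +1 means enriched only in A (the full-site line),
-1 only in B, and 0 equal enrichment.  ``eps`` only guards the division
by zero; it is small enough (1e-9 by default) that one-sided regions
still score +/-1 to at least six decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .genome_io import AlignedRead, GenomicInterval, SignalTrack, TEInsertion
from .coverage import DEFAULT_FRAGMENT_LEN, _fragment_bounds

DEFAULT_EPS = 1e-9

#: distance bands from the element edge, bp: reconciles the <1 kb band with
#: the wider non-overlapping windows used for spreading-length estimation
DEFAULT_WINDOW_SCHEME = ((0, 1000), (1000, 2500), (2500, 5000))


# ---------------------------------------------------------------------------
# RPKM and asymmetry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionReadStats:
    """Inputs to the RPKM computation for one region.

    ``n`` is the (possibly fractional) number of reads assigned to the
    region, ``L_kb`` the region length in kilobases, ``N_millions`` the
    total filtered library size in millions of reads.
    """

    n: float
    L_kb: float
    N_millions: float
    region: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("read count must be >= 0")
        if self.L_kb <= 0:
            raise ValueError("region length must be positive")
        if self.N_millions <= 0:
            raise ValueError("library size must be positive")


def rpkm(stats: RegionReadStats) -> float:
    """Reads per kilobase of region per million mapped library reads."""
    return stats.n / (stats.L_kb * stats.N_millions)


def rpkm_asymmetry(rpkm_a: float, rpkm_b: float, eps: float = DEFAULT_EPS) -> float:
    """Normalized RPKM difference between two libraries, in [-1, +1]."""
    if rpkm_a < 0 or rpkm_b < 0:
        raise ValueError("RPKM values must be >= 0")
    if eps <= 0:
        raise ValueError("eps must be positive")
    return (rpkm_a - rpkm_b) / (rpkm_a + rpkm_b + eps)


@dataclass
class AsymmetryRecord:
    """Per-copy, per-window RPKM pair and asymmetry value."""

    copy_id: str
    window_label: str
    rpkm_a: float
    rpkm_b: float
    asymmetry: float
    eps: float = DEFAULT_EPS
    truncated: bool = False
    side: str = "both"


def window_label(window: tuple[int, int]) -> str:
    """Human-readable label for a distance band, e.g. (0,1000) -> '<1kb'."""

    def kb(x: int) -> str:
        v = x / 1000
        return f"{v:g}"

    lo, hi = window
    if lo == 0:
        return f"<{kb(hi)}kb"
    return f"{kb(lo)}–{kb(hi)}kb"


# ---------------------------------------------------------------------------
# fragment index: region read counting
# ---------------------------------------------------------------------------


class FragmentIndex:
    """Sorted per-chromosome extended-fragment intervals for region counts.

    Counting modes:

    ``fractional``
        each fragment contributes the proportion of its length lying
        inside the region (matching the fractional read counts fed into
        RPKM);
    ``five_prime``
        each fragment contributes 1 iff its 5' anchor lies in the region.
    """

    def __init__(
        self,
        reads: Sequence[AlignedRead],
        fragment_len: int = DEFAULT_FRAGMENT_LEN,
        chrom_sizes: dict[str, int] | None = None,
    ):
        self.fragment_len = fragment_len
        self.n_reads = len(reads)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if not reads:
            return
        starts, ends, chroms = _fragment_bounds(reads, fragment_len, chrom_sizes)
        pos5 = np.array([r.pos5 for r in reads], dtype=np.int64)
        order = {}
        for i, c in enumerate(chroms):
            order.setdefault(c, []).append(i)
        for c, idx in order.items():
            idx = np.array(idx, dtype=np.int64)
            s, e, p = starts[idx], ends[idx], pos5[idx]
            srt = np.argsort(s, kind="stable")
            self._by_chrom[c] = (s[srt], e[srt], np.sort(p))

    def count(self, region: GenomicInterval, mode: str = "fractional") -> float:
        """Fractional (or 5'-anchored) read count overlapping ``region``."""
        if region.chrom not in self._by_chrom:
            return 0.0
        starts, ends, pos5 = self._by_chrom[region.chrom]
        if mode == "five_prime":
            lo = np.searchsorted(pos5, region.start, side="left")
            hi = np.searchsorted(pos5, region.end, side="left")
            return float(hi - lo)
        if mode != "fractional":
            raise ValueError(f"unknown counting mode {mode!r}")
        # fragments overlapping [start, end) have start < end and
        # start > region.start - fragment_len (lengths never exceed it)
        i0 = np.searchsorted(starts, region.start - self.fragment_len, side="left")
        i1 = np.searchsorted(starts, region.end, side="left")
        if i1 <= i0:
            return 0.0
        s, e = starts[i0:i1], ends[i0:i1]
        ov = np.minimum(e, region.end) - np.maximum(s, region.start)
        mask = ov > 0
        if not mask.any():
            return 0.0
        frac = ov[mask] / (e[mask] - s[mask])
        return float(frac.sum())


def _as_index(
    reads,
    fragment_len: int,
    chrom_sizes: dict[str, int] | None,
) -> FragmentIndex:
    if isinstance(reads, FragmentIndex):
        return reads
    return FragmentIndex(reads, fragment_len, chrom_sizes)


def _flank_windows(
    insertion: TEInsertion, window: tuple[int, int]
) -> tuple[GenomicInterval | None, GenomicInterval | None, bool]:
    """Oriented 5'/3' distance-band intervals; truncation at chrom start.

    Windows that would extend left of base 0 are clipped; full off-chrom
    windows come back as None.  Right-edge truncation is the caller's to
    detect (needs the chromosome size).
    """
    iv = insertion.interval
    w0, w1 = window
    up_start, up_end = iv.start - w1, iv.start - w0
    truncated = up_start < 0
    upstream = None
    if up_end > 0:
        upstream = GenomicInterval(iv.chrom, max(up_start, 0), up_end)
    downstream = GenomicInterval(iv.chrom, iv.end + w0, iv.end + w1)
    if iv.strand == "-":
        return downstream, upstream, truncated
    return upstream, downstream, truncated


def copy_flank_asymmetry(
    reads_a,
    reads_b,
    insertion: TEInsertion,
    N_a: int,
    N_b: int,
    window: tuple[int, int] = (0, 1000),
    combine_sides: bool = True,
    eps: float = DEFAULT_EPS,
    fragment_len: int = DEFAULT_FRAGMENT_LEN,
    chrom_sizes: dict[str, int] | None = None,
    count_mode: str = "fractional",
):
    """Per-copy flank RPKM asymmetry at one distance band.

    ``reads_a``/``reads_b`` are filtered, element-masked reads (or
    prebuilt :class:`FragmentIndex` objects) for the full-site (A) and
    empty-site (B) lines; ``N_a``/``N_b`` are the lines' total filtered
    library sizes.  With ``combine_sides`` the 5' and 3' windows pool into
    one region of twice the band span (one asymmetry per copy); otherwise
    a list of two per-side records is returned.  Records whose windows run
    off the chromosome are flagged ``truncated`` (compute anyway, exclude
    from summaries).
    """
    idx_a = _as_index(reads_a, fragment_len, chrom_sizes)
    idx_b = _as_index(reads_b, fragment_len, chrom_sizes)
    five, three, truncated = _flank_windows(insertion, window)
    if chrom_sizes is not None:
        size = chrom_sizes[insertion.interval.chrom]
        for w in (five, three):
            if w is not None and w.end > size:
                truncated = True
    w0, w1 = window
    span_kb = (w1 - w0) / 1000.0

    def _record(regions, label_suffix: str, side: str, L_kb: float) -> AsymmetryRecord:
        n_a = sum(idx_a.count(r, count_mode) for r in regions if r is not None)
        n_b = sum(idx_b.count(r, count_mode) for r in regions if r is not None)
        r_a = rpkm(RegionReadStats(n_a, L_kb, N_a / 1e6))
        r_b = rpkm(RegionReadStats(n_b, L_kb, N_b / 1e6))
        return AsymmetryRecord(
            copy_id=insertion.copy_id,
            window_label=window_label(window) + label_suffix,
            rpkm_a=r_a,
            rpkm_b=r_b,
            asymmetry=rpkm_asymmetry(r_a, r_b, eps),
            eps=eps,
            truncated=truncated,
            side=side,
        )

    if combine_sides:
        return _record([five, three], "", "both", 2 * span_kb)
    return [
        _record([five], ":5p", "five_prime", span_kb),
        _record([three], ":3p", "three_prime", span_kb),
    ]


def windowed_asymmetry(
    reads_a,
    reads_b,
    insertions: Sequence[TEInsertion],
    N_a: int,
    N_b: int,
    scheme: Sequence[tuple[int, int]] = DEFAULT_WINDOW_SCHEME,
    combine_sides: bool = True,
    eps: float = DEFAULT_EPS,
    fragment_len: int = DEFAULT_FRAGMENT_LEN,
    chrom_sizes: dict[str, int] | None = None,
) -> list[AsymmetryRecord]:
    """Asymmetry records for every copy at every distance band in ``scheme``.

    Bands must be ordered and non-overlapping.
    """
    for (a0, a1), (b0, b1) in zip(scheme, scheme[1:]):
        if a1 > b0:
            raise ValueError("window scheme must be ordered and non-overlapping")
    for w0, w1 in scheme:
        if w1 <= w0:
            raise ValueError(f"empty window {(w0, w1)}")
    idx_a = _as_index(reads_a, fragment_len, chrom_sizes)
    idx_b = _as_index(reads_b, fragment_len, chrom_sizes)
    records: list[AsymmetryRecord] = []
    for ins in insertions:
        for window in scheme:
            rec = copy_flank_asymmetry(
                idx_a, idx_b, ins, N_a, N_b,
                window=window, combine_sides=combine_sides, eps=eps,
                fragment_len=fragment_len, chrom_sizes=chrom_sizes,
            )
            records.extend(rec if isinstance(rec, list) else [rec])
    return records


# ---------------------------------------------------------------------------
# distribution summaries
# ---------------------------------------------------------------------------


def skewness(values: Sequence[float]) -> float:
    """Adjusted Fisher-Pearson standardized third moment G1.

    G1 = [n^2 / ((n-1)(n-2))] * m3 / s^3 with s the sample (n-1) standard
    deviation — the convention of common desktop statistics packages.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("skewness needs at least 3 values")
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise ValueError("skewness undefined for zero-variance data")
    return float(sps.skew(x, bias=False))


@dataclass
class DistributionSummary:
    n_values: int
    skewness: float  # NaN when undefined (zero variance)
    median: float
    bin_edges: np.ndarray
    counts: np.ndarray


def summarize_distribution(
    records: Sequence[AsymmetryRecord],
    bins: int = 21,
    value_range: tuple[float, float] = (-1.0, 1.0),
) -> DistributionSummary:
    """Histogram + skewness + median of non-truncated asymmetry records."""
    vals = np.array(
        [r.asymmetry for r in records if not r.truncated], dtype=float
    )
    if vals.size < 3:
        raise ValueError("need at least 3 non-flagged records to summarize")
    try:
        skew = skewness(vals)
    except ValueError:
        skew = float("nan")
    counts, edges = np.histogram(vals, bins=bins, range=value_range)
    return DistributionSummary(
        n_values=int(vals.size),
        skewness=skew,
        median=float(np.median(vals)),
        bin_edges=edges,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# nonparametric multi-group comparison
# ---------------------------------------------------------------------------


def kruskal_dunn(groups: dict[str, Sequence[float]]) -> dict:
    """Kruskal-Wallis across groups plus Dunn pairwise post-hoc z tests.

    Both statistics are tie-corrected; Dunn p-values are two-sided normal
    tail probabilities with Bonferroni adjustment over the pairwise
    comparisons.  Returns ``{"H", "p_kw", "pairwise": [(i, j, z, p_adj)]}``.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [np.asarray(groups[lab], dtype=float) for lab in labels]
    for lab, s in zip(labels, samples):
        if s.size == 0:
            raise ValueError(f"group {lab!r} is empty")
    try:
        H, p_kw = sps.kruskal(*samples)
    except ValueError:  # all values identical across all groups
        H, p_kw = 0.0, 1.0

    pooled = np.concatenate(samples)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    offset = 0
    for s in samples:
        mean_ranks.append(ranks[offset : offset + s.size].mean())
        offset += s.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1)))
    base_var = N * (N + 1) / 12.0 - tie_term

    pairwise = []
    m = len(labels) * (len(labels) - 1) // 2
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            se = np.sqrt(base_var * (1.0 / samples[i].size + 1.0 / samples[j].size))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            pairwise.append((labels[i], labels[j], float(z), float(min(1.0, p * m))))
    return {"H": float(H), "p_kw": float(p_kw), "pairwise": pairwise}


# ---------------------------------------------------------------------------
# genome-wide differential scan
# ---------------------------------------------------------------------------


def asymmetry_scan(
    track_a: SignalTrack,
    track_b: SignalTrack,
    N_a: int,
    N_b: int,
    window: int = 1000,
    step: int = 500,
    min_abs_asym: float = 0.9,
    min_rpkm: float = 1.0,
    fragment_len: int = DEFAULT_FRAGMENT_LEN,
    eps: float = DEFAULT_EPS,
) -> list[tuple[GenomicInterval, float]]:
    """Sliding-window scan for loci differentially covered between lines.

    Windows with |asymmetry| >= min_abs_asym and max per-line RPKM >=
    min_rpkm are candidates; overlapping candidate windows merge (the
    merged locus keeps the strongest window's asymmetry).  The fractional
    read count of a window is its coverage sum divided by the fragment
    length.  Sorted by |asymmetry| descending, then coordinate.
    """
    if step > window:
        raise ValueError("step must not exceed window")
    if set(track_a.chroms) != set(track_b.chroms):
        raise ValueError("tracks must cover the same chromosomes")
    hits: list[tuple[GenomicInterval, float]] = []
    for chrom in track_a.chroms:
        size = min(track_a.length(chrom), track_b.length(chrom))
        if size < window:
            continue
        csum_a = np.concatenate(([0.0], np.cumsum(track_a.values(chrom)[:size])))
        csum_b = np.concatenate(([0.0], np.cumsum(track_b.values(chrom)[:size])))
        starts = np.arange(0, size - window + 1, step)
        n_a = (csum_a[starts + window] - csum_a[starts]) / fragment_len
        n_b = (csum_b[starts + window] - csum_b[starts]) / fragment_len
        L_kb = window / 1000.0
        r_a = n_a / (L_kb * (N_a / 1e6))
        r_b = n_b / (L_kb * (N_b / 1e6))
        asym = (r_a - r_b) / (r_a + r_b + eps)
        mask = (np.abs(asym) >= min_abs_asym) & (np.maximum(r_a, r_b) >= min_rpkm)
        current: list[tuple[int, int, float]] | None = None
        for s, a in zip(starts[mask], asym[mask]):
            s = int(s)
            if current is not None and s < current[1]:
                best = a if abs(a) > abs(current[2]) else current[2]
                current = (current[0], s + window, best)
            else:
                if current is not None:
                    hits.append(
                        (GenomicInterval(chrom, current[0], current[1]), current[2])
                    )
                current = (s, s + window, float(a))
        if current is not None:
            hits.append((GenomicInterval(chrom, current[0], current[1]), current[2]))
    hits.sort(key=lambda h: (-abs(h[1]), h[0].chrom, h[0].start))
    return hits


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------


def write_asymmetry_records(records: Sequence[AsymmetryRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("copy_id\twindow\trpkm_a\trpkm_b\tasymmetry\ttruncated\tside\n")
        for r in records:
            fh.write(
                f"{r.copy_id}\t{r.window_label}\t{r.rpkm_a!r}\t{r.rpkm_b!r}\t"
                f"{r.asymmetry!r}\t{int(r.truncated)}\t{r.side}\n"
            )


def write_scan_bed(hits: Sequence[tuple[GenomicInterval, float]], path) -> None:
    """Scan candidates as BED; score = |asymmetry| scaled to [0, 1000]."""
    with open(path, "w") as fh:
        for i, (iv, asym) in enumerate(hits):
            score = int(round(min(1.0, abs(asym)) * 1000))
            sign = "+" if asym >= 0 else "-"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tcand{i}\t{score}\t{sign}\n"
            )
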
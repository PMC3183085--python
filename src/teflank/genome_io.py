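"""Plain-text genomic I/O, coordinate conventions, and element classification.

All internal coordinates are 0-based half-open.  The element (TE) table is
read in the genome-browser convention (1-based, fully closed) and converted
on input; BED, bedGraph and fixedStep wiggle files keep their native
conventions.  Reads are carried as 5'-anchored records rather than
intervals because fragment extension is directional.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)

STRANDS = frozenset({"+", "-", "."})

#: columns every element table must provide, in addition to per-line presence
TE_TABLE_CORE_COLUMNS = ("copy_id", "chrom", "start", "end", "strand", "family")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TEInsertion:
    """One annotated element/insertion site with per-line presence calls."""

    interval: GenomicInterval
    family: str
    copy_id: str
    status: str  # {"common", "polymorphic"}
    present_in: frozenset
    copy_class: str = field(default="")

    def __post_init__(self) -> None:
        if self.status not in ("common", "polymorphic"):
            raise ValueError(f"invalid status {self.status!r}")
        self.present_in = frozenset(self.present_in)
        if not self.copy_class:
            self.copy_class = classify_copy(self)

    @property
    def length_bp(self) -> int:
        return len(self.interval)


@dataclass(slots=True)
class AlignedRead:
    """A filtered sequencing read anchored at its 5'-most base.

    ``pos5`` is the 5'-most coordinate in read orientation (0-based): the
    leftmost base for + strand reads and the rightmost base for - strand
    reads.
    """

    chrom: str
    pos5: int
    read_len: int
    strand: str
    mapq: int
    is_unique: bool = True

    def __post_init__(self) -> None:
        if self.read_len <= 0:
            raise ValueError("read_len must be positive")
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"read strand must be + or -, got {self.strand!r}")

    def span(self) -> tuple[int, int]:
        """Half-open genomic interval occupied by the read itself."""
        if self.strand == "+":
            return self.pos5, self.pos5 + self.read_len
        return self.pos5 - self.read_len + 1, self.pos5 + 1


class SignalTrack:
    """Dense per-base signal, one float array per chromosome.

    Used for fragment coverage, mappability fractions, and normalized
    densities alike; mappability tracks are additionally expected to stay
    within [0, 1] but this is not enforced here.
    """

    def __init__(self, data: dict[str, np.ndarray]):
        self._data = {c: np.asarray(v, dtype=float) for c, v in data.items()}

    @classmethod
    def zeros(cls, chrom_sizes: dict[str, int]) -> "SignalTrack":
        return cls({c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()})

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._data

    def length(self, chrom: str) -> int:
        return len(self._data[chrom])

    def values(self, chrom: str) -> np.ndarray:
        return self._data[chrom]

    def covers(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) lies fully within the chromosome."""
        return chrom in self._data and start >= 0 and end <= self.length(chrom)

    def region(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Values over [start, end); bases outside the chromosome pad as 0."""
        if end <= start:
            raise ValueError(f"empty region {chrom}:{start}-{end}")
        arr = self._data[chrom]
        lo, hi = max(start, 0), min(end, len(arr))
        if lo >= hi:
            log.debug("region %s:%d-%d entirely off-chromosome", chrom, start, end)
            return np.zeros(end - start, dtype=float)
        out = np.zeros(end - start, dtype=float)
        out[lo - start : hi - start] = arr[lo:hi]
        if lo != start or hi != end:
            log.debug("region %s:%d-%d clipped to chromosome", chrom, start, end)
        return out

    def region_sum(self, chrom: str, start: int, end: int) -> float:
        return float(self.region(chrom, start, end).sum())

    def region_mean(self, chrom: str, start: int, end: int) -> float:
        return float(self.region(chrom, start, end).mean())


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its TSS anchor."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def promoter(self, halfwidth: int = 1000) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, max(0, self.tss - halfwidth), self.tss + halfwidth, self.strand
        )


# ---------------------------------------------------------------------------
# element table
# ---------------------------------------------------------------------------


def _parse_presence(code: str) -> bool:
    """Map a +/- presence code to a boolean.

    '+/+' and '+/-' both count as present (heterozygous presence still
    contributes signal); '-/-' is absent.  The unicode minus sign is
    tolerated.
    """
    code = code.strip().replace("−", "-")
    allowed = {"+/+", "+/-", "-/+", "-/-", "+", "-"}
    if code not in allowed:
        raise ValueError(f"unknown presence code {code!r}")
    return "+" in code


def read_te_table(
    path, presence_columns: Sequence[str] | None = None
) -> list[TEInsertion]:
    """Read an element table (TSV, 1-based inclusive coordinates).

    Parameters
    ----------
    path:
        TSV file with header columns ``copy_id, chrom, start, end, strand,
        family`` plus one presence column per cell line (codes ``+/+``,
        ``+/-``, ``-/-``).
    presence_columns:
        Names of the presence columns; defaults to every non-core column.

    Returns
    -------
    list of :class:`TEInsertion` with 0-based half-open coordinates and
    ``status`` derived from the presence calls.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in TE_TABLE_CORE_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"element table missing columns: {missing}")
        if presence_columns is None:
            presence_columns = [c for c in header if c not in TE_TABLE_CORE_COLUMNS]
        if not presence_columns:
            raise ValueError("element table has no presence columns")
        insertions = []
        for i, row in enumerate(reader, start=1):
            try:
                start1 = int(row["start"])
                end1 = int(row["end"])
                if start1 < 1 or end1 < start1:
                    raise ValueError(f"bad coordinates {start1}-{end1}")
                interval = GenomicInterval(
                    row["chrom"], start1 - 1, end1, row["strand"]
                )
                present = frozenset(
                    lab for lab in presence_columns if _parse_presence(row[lab])
                )
                if not present:
                    raise ValueError("element absent from every line")
                status = (
                    "common" if present == frozenset(presence_columns) else "polymorphic"
                )
                insertions.append(
                    TEInsertion(
                        interval=interval,
                        family=row["family"],
                        copy_id=row["copy_id"],
                        status=status,
                        present_in=present,
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"malformed element table row {i}: {exc}") from exc
    return insertions


def write_te_table(insertions: Iterable[TEInsertion], path, line_labels: Sequence[str]):
    """Write an element table in the 1-based inclusive input convention."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(list(TE_TABLE_CORE_COLUMNS) + list(line_labels))
        for ins in insertions:
            codes = ["+/+" if lab in ins.present_in else "-/-" for lab in line_labels]
            writer.writerow(
                [
                    ins.copy_id,
                    ins.interval.chrom,
                    ins.interval.start + 1,
                    ins.interval.end,
                    ins.interval.strand,
                    ins.family,
                ]
                + codes
            )


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


def read_reads(path, dialect: str = "bed6q") -> list[AlignedRead]:
    """Read aligned-read records.

    ``bed6q`` is BED6 with the score field holding the mapping quality and
    an optional 7th column (0/1) flagging unique alignment (default 1).
    ``sam_min`` accepts a minimal SAM subset: header lines are skipped,
    unmapped reads dropped, strand from flag bit 0x10, uniqueness from an
    ``NH:i:`` tag when present.
    """
    if dialect == "bed6q":
        return _read_bed6q(path)
    if dialect == "sam_min":
        return _read_sam_min(path)
    raise ValueError(f"unknown read dialect {dialect!r}")


def _read_bed6q(path) -> list[AlignedRead]:
    reads = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path} line {i}: expected >= 6 BED fields")
            chrom, start, end, _name, score, strand = fields[:6]
            start, end = int(start), int(end)
            if start < 0 or end <= start:
                raise ValueError(f"{path} line {i}: bad coordinates {start}-{end}")
            if strand not in ("+", "-"):
                raise ValueError(f"{path} line {i}: missing/invalid strand {strand!r}")
            is_unique = True
            if len(fields) >= 7:
                is_unique = fields[6] not in ("0", "false", "False")
            pos5 = start if strand == "+" else end - 1
            reads.append(
                AlignedRead(
                    chrom=chrom,
                    pos5=pos5,
                    read_len=end - start,
                    strand=strand,
                    mapq=int(score),
                    is_unique=is_unique,
                )
            )
    return reads


def _read_sam_min(path) -> list[AlignedRead]:
    reads = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("@"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 11:
                raise ValueError(f"{path} line {i}: truncated SAM record")
            flag = int(fields[1])
            if flag & 0x4:  # unmapped
                continue
            pos = int(fields[3]) - 1
            if pos < 0:
                raise ValueError(f"{path} line {i}: negative position")
            seq = fields[9]
            if seq == "*":
                raise ValueError(f"{path} line {i}: SEQ required in sam_min dialect")
            read_len = len(seq)
            strand = "-" if flag & 0x10 else "+"
            is_unique = True
            for tag in fields[11:]:
                m = re.match(r"NH:i:(\d+)", tag)
                if m:
                    is_unique = int(m.group(1)) == 1
            pos5 = pos if strand == "+" else pos + read_len - 1
            reads.append(
                AlignedRead(
                    chrom=fields[2],
                    pos5=pos5,
                    read_len=read_len,
                    strand=strand,
                    mapq=int(fields[4]),
                    is_unique=is_unique,
                )
            )
    return reads


def write_reads(reads: Iterable[AlignedRead], path) -> None:
    """Write reads as BED6+1 (score = mapq, col 7 = uniqueness flag)."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            start, end = r.span()
            fh.write(
                f"{r.chrom}\t{start}\t{end}\tr{i}\t{r.mapq}\t{r.strand}\t"
                f"{1 if r.is_unique else 0}\n"
            )


# ---------------------------------------------------------------------------
# signal tracks (bedGraph / fixedStep wiggle)
# ---------------------------------------------------------------------------


def read_signal_track(path, chrom_sizes: dict[str, int] | None = None) -> SignalTrack:
    """Read a bedGraph or fixedStep wiggle into a dense :class:`SignalTrack`.

    Bases not mentioned in the file are 0.  When ``chrom_sizes`` is not
    given, chromosome lengths are inferred from the right-most interval.
    Overlapping bedGraph intervals (or overlapping fixedStep spans) raise,
    since the per-base value would be ambiguous.
    """
    spans: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        chrom = None
        pos = step = span = None
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                attrs = dict(kv.split("=") for kv in line.split()[1:])
                chrom = attrs["chrom"]
                pos = int(attrs["start"]) - 1  # wiggle is 1-based
                step = int(attrs.get("step", 1))
                span = int(attrs.get("span", 1))
                continue
            fields = line.split()
            if len(fields) == 4:  # bedGraph
                c, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                spans.setdefault(c, []).append((s, e, v))
                chrom = None
            elif len(fields) == 1 and chrom is not None:  # fixedStep value
                v = float(fields[0])
                spans.setdefault(chrom, []).append((pos, pos + span, v))
                pos += step
            else:
                raise ValueError(f"{path} line {i}: unrecognized track line {line!r}")
    if chrom_sizes is None:
        chrom_sizes = {
            c: max(e for _, e, _ in ivs) for c, ivs in spans.items()
        }
    track = SignalTrack.zeros(chrom_sizes)
    for c, ivs in spans.items():
        if c not in chrom_sizes:
            raise ValueError(f"track chromosome {c!r} not in chrom sizes")
        arr = track.values(c)
        seen = np.zeros(len(arr), dtype=bool)
        for s, e, v in ivs:
            if e > len(arr):
                raise ValueError(f"interval {c}:{s}-{e} exceeds chromosome length")
            if seen[s:e].any():
                raise ValueError(f"overlapping track intervals at {c}:{s}-{e}")
            seen[s:e] = True
            arr[s:e] = v
    return track


def write_signal_track(track: SignalTrack, path) -> None:
    """Write as bedGraph (half-open), run-length encoded, zero runs omitted.

    Values are written with full round-trip precision so step-constant data
    survives read/write bitwise.
    """
    with open(path, "w") as fh:
        for chrom in track.chroms:
            vals = track.values(chrom)
            if len(vals) == 0:
                continue
            bounds = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate(([0], bounds))
            ends = np.concatenate((bounds, [len(vals)]))
            for s, e in zip(starts, ends):
                v = float(vals[s])
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v!r}\n")


# ---------------------------------------------------------------------------
# genes, chromosome sizes, expression counts
# ---------------------------------------------------------------------------


def read_genes(path, fmt: str | None = None) -> list[GeneModel]:
    """Read gene models from BED6 (TSS = strand-aware 5' end) or minimal GTF.

    Format is inferred from the extension when ``fmt`` is None.
    """
    if fmt is None:
        fmt = "gtf" if str(path).endswith((".gtf", ".gff")) else "bed"
    genes = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if fmt == "bed":
                if len(fields) < 6:
                    raise ValueError(f"{path} line {i}: expected BED6")
                chrom, start, end, name, _score, strand = fields[:6]
                start, end = int(start), int(end)
                tss = start if strand != "-" else end - 1
                genes.append(GeneModel(name, chrom, tss, strand))
            elif fmt == "gtf":
                if len(fields) < 9:
                    raise ValueError(f"{path} line {i}: expected 9 GTF fields")
                if fields[2] != "gene":
                    continue
                chrom, start, end, strand = (
                    fields[0],
                    int(fields[3]) - 1,
                    int(fields[4]),
                    fields[6],
                )
                m = re.search(r'gene_id "([^"]+)"', fields[8])
                if not m:
                    raise ValueError(f"{path} line {i}: missing gene_id attribute")
                tss = start if strand != "-" else end - 1
                genes.append(GeneModel(m.group(1), chrom, tss, strand))
            else:
                raise ValueError(f"unknown gene format {fmt!r}")
    return genes


def write_genes_bed(genes: Iterable[GeneModel], path, gene_lengths=None) -> None:
    """Write genes as BED6 spanning [TSS, TSS+len) in transcript orientation."""
    gene_lengths = gene_lengths or {}
    with open(path, "w") as fh:
        for g in genes:
            n = gene_lengths.get(g.gene_id, 1)
            if g.strand == "-":
                start, end = g.tss - n + 1, g.tss + 1
            else:
                start, end = g.tss, g.tss + n
            fh.write(f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def read_expression(path):
    """Read per-gene expression counts.

    TSV with columns ``gene_id, length_bp, <line label>...``; returns a
    pandas DataFrame indexed by gene_id.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns or "length_bp" not in df.columns:
        raise ValueError("expression table needs gene_id and length_bp columns")
    return df.set_index("gene_id")


# ---------------------------------------------------------------------------
# copy classification and length filters
# ---------------------------------------------------------------------------


def classify_copy(
    insertion,
    full_len_min: int = 4000,
    solo_ltr_len: int = 320,
    solo_tol: float = 0.20,
) -> str:
    """Classify an element by length: full_length / solo_LTR / other.

    Full-length elements are at least ``full_len_min`` bp; solo LTRs fall
    within ``solo_tol`` (fractional) of the typical solo-LTR length.
    Full-length takes precedence.  Accepts a TEInsertion or a plain length.
    """
    length = insertion if isinstance(insertion, (int, np.integer)) else insertion.length_bp
    if length >= full_len_min:
        return "full_length"
    if abs(length - solo_ltr_len) <= solo_tol * solo_ltr_len:
        return "solo_LTR"
    return "other"


def filter_full_length(
    insertions: Sequence[TEInsertion], min_len: int = 4000
) -> list[TEInsertion]:
    """Keep elements with length >= min_len, preserving input order."""
    return [ins for ins in insertions if ins.length_bp >= min_len]
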
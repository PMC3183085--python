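"""Multi-step filter for genes plausibly silenced by insertion-induced
heterochromatin.

The composition is: (1) polymorphic copies near a TSS; (2) repressive
signal at the copy body and at the gene promoter in the insertion-carrying
line, but not at the promoter of the empty-site line; (3) expression
reduced in the insertion-carrying line.  "Enriched" is operationalized as
a fold over the genome-median window RPKM, which is scale-free across
library depths.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome_io import GeneModel, GenomicInterval, SignalTrack, TEInsertion
from .coverage import DEFAULT_FRAGMENT_LEN
from .asymmetry import RegionReadStats, rpkm

log = logging.getLogger(__name__)


@dataclass
class GeneImpactCandidate:
    gene_id: str
    copy_id: str
    tss_distance_bp: int
    copy_rpkm_full: float = 0.0
    promoter_rpkm_full: float = 0.0
    promoter_rpkm_empty: float = 0.0
    expr_full: float = 0.0
    expr_empty: float = 0.0
    expression_ratio: float = 0.0
    passed_filters: list[str] = field(default_factory=list)


def tss_distance(insertion: TEInsertion, gene: GeneModel) -> int | None:
    """Gap in bp between an element and a TSS; 0 when the TSS overlaps.

    None when they sit on different chromosomes.
    """
    iv = insertion.interval
    if iv.chrom != gene.chrom:
        return None
    if iv.start <= gene.tss < iv.end:
        return 0
    if gene.tss >= iv.end:
        return gene.tss - iv.end
    return iv.start - gene.tss


def tss_proximal_copies(
    insertions: Sequence[TEInsertion],
    genes: Sequence[GeneModel],
    max_dist: int = 5000,
) -> list[tuple[TEInsertion, GeneModel, int]]:
    """All (copy, gene, distance) pairs with the TSS within ``max_dist`` bp.

    A gene may pair with several copies and vice versa.  The caller is
    expected to pass polymorphic copies only.
    """
    pairs = []
    for ins in insertions:
        for gene in genes:
            d = tss_distance(ins, gene)
            if d is not None and d <= max_dist:
                pairs.append((ins, gene, d))
    return pairs


def genome_median_rpkm(
    track: SignalTrack,
    N_reads: int,
    window: int = 1000,
    fragment_len: int = DEFAULT_FRAGMENT_LEN,
) -> float:
    """Median RPKM over non-overlapping genome-tiling windows.

    Fractional window read counts come from coverage sums divided by the
    fragment length (exact for fractional overlap assignment).
    """
    values = []
    for chrom in track.chroms:
        vals = track.values(chrom)
        n_win = len(vals) // window
        if n_win == 0:
            continue
        sums = vals[: n_win * window].reshape(n_win, window).sum(axis=1)
        values.append(sums / fragment_len)
    if not values:
        raise ValueError("track too short for any window")
    counts = np.concatenate(values)
    return float(np.median(counts) / ((window / 1000.0) * (N_reads / 1e6)))


def _region_rpkm(
    track: SignalTrack,
    region: GenomicInterval,
    N_reads: int,
    fragment_len: int,
) -> float:
    n = track.region_sum(region.chrom, region.start, region.end) / fragment_len
    return rpkm(RegionReadStats(n, len(region) / 1000.0, N_reads / 1e6))


def enrichment_filter(
    pairs: Sequence[tuple[TEInsertion, GeneModel, int]],
    track_full: SignalTrack,
    track_empty: SignalTrack,
    N_full: int,
    N_empty: int,
    promoter_halfwidth: int = 1000,
    min_fold: float = 2.0,
    fragment_len: int = DEFAULT_FRAGMENT_LEN,
    body_track_full: SignalTrack | None = None,
) -> list[tuple[TEInsertion, GeneModel, int, dict]]:
    """Keep pairs where repressive signal marks copy and promoter in the
    insertion-carrying line only.

    Keeps a pair iff copy-body RPKM (full line) and promoter RPKM (full
    line) both reach ``min_fold`` times the genome-median window RPKM of
    that line, while the empty line's promoter stays below its own
    threshold.  Returns the surviving pairs with the measured RPKMs.

    When the promoter window overlaps the element body (TSS within the
    halfwidth of the edge), element-internal signal would bleed into the
    promoter measurement; pass element-masked tracks as
    ``track_full``/``track_empty`` and the unmasked full-line track as
    ``body_track_full`` so promoter enrichment reflects spreading only.
    """
    if not pairs:
        return []
    if body_track_full is None:
        body_track_full = track_full
    med_full = genome_median_rpkm(track_full, N_full, fragment_len=fragment_len)
    med_empty = genome_median_rpkm(track_empty, N_empty, fragment_len=fragment_len)
    med_body = genome_median_rpkm(body_track_full, N_full, fragment_len=fragment_len)
    out = []
    for ins, gene, dist in pairs:
        promoter = gene.promoter(promoter_halfwidth)
        body_full = _region_rpkm(body_track_full, ins.interval, N_full, fragment_len)
        prom_full = _region_rpkm(track_full, promoter, N_full, fragment_len)
        prom_empty = _region_rpkm(track_empty, promoter, N_empty, fragment_len)
        ok = (
            body_full >= min_fold * med_body
            and prom_full >= min_fold * med_full
            and prom_empty < min_fold * med_empty
        )
        if ok:
            out.append(
                (
                    ins,
                    gene,
                    dist,
                    {
                        "copy_rpkm_full": body_full,
                        "promoter_rpkm_full": prom_full,
                        "promoter_rpkm_empty": prom_empty,
                    },
                )
            )
    return out


def expression_compare(
    counts_full: dict[str, float],
    counts_empty: dict[str, float],
    gene: GeneModel,
    gene_length: int,
    lib_full: float,
    lib_empty: float,
    min_ratio: float = 2.0,
) -> tuple[float, bool]:
    """Normalized expression ratio empty/full for one gene.

    ratio = RPKM_empty / RPKM_full; the flag is True iff the ratio reaches
    ``min_ratio`` (expression lower in the insertion-carrying line).  Zero
    in both lines leaves the ratio undefined (NaN, flag False).
    """
    c_full = counts_full.get(gene.gene_id, 0.0)
    c_empty = counts_empty.get(gene.gene_id, 0.0)
    L_kb = gene_length / 1000.0
    r_full = c_full / (L_kb * (lib_full / 1e6))
    r_empty = c_empty / (L_kb * (lib_empty / 1e6))
    if r_full == 0 and r_empty == 0:
        log.info("gene %s has zero expression in both lines", gene.gene_id)
        return float("nan"), False
    if r_full == 0:
        return math.inf, True
    ratio = r_empty / r_full
    return ratio, ratio >= min_ratio


@dataclass
class GeneImpactConfig:
    max_dist: int = 5000
    promoter_halfwidth: int = 1000
    min_fold: float = 2.0
    min_expr_ratio: float = 2.0
    fragment_len: int = DEFAULT_FRAGMENT_LEN


def run_gene_impact(
    insertions: Sequence[TEInsertion],
    genes: Sequence[GeneModel],
    track_full: SignalTrack,
    track_empty: SignalTrack,
    N_full: int,
    N_empty: int,
    expr_full: dict[str, float],
    expr_empty: dict[str, float],
    gene_lengths: dict[str, int],
    config: GeneImpactConfig | None = None,
    body_track_full: SignalTrack | None = None,
) -> list[GeneImpactCandidate]:
    """Compose proximity, enrichment, and expression filters.

    ``insertions`` should be the polymorphic set.  ``track_full`` /
    ``track_empty`` should be element-masked coverage so promoter
    enrichment measures spreading rather than element-internal signal;
    ``body_track_full`` (unmasked full-line coverage, defaults to
    ``track_full``) supplies the copy-body measurement.  Candidates
    passing all three filters come back with per-filter provenance,
    ordered by gene_id.
    """
    cfg = config or GeneImpactConfig()
    lib_full = sum(expr_full.values())
    lib_empty = sum(expr_empty.values())
    pairs = tss_proximal_copies(insertions, genes, cfg.max_dist)
    enriched = enrichment_filter(
        pairs, track_full, track_empty, N_full, N_empty,
        promoter_halfwidth=cfg.promoter_halfwidth, min_fold=cfg.min_fold,
        fragment_len=cfg.fragment_len, body_track_full=body_track_full,
    )
    candidates = []
    for ins, gene, dist, rpkms in enriched:
        ratio, lower = expression_compare(
            expr_full, expr_empty, gene, gene_lengths[gene.gene_id],
            lib_full, lib_empty, min_ratio=cfg.min_expr_ratio,
        )
        if not lower:
            continue
        candidates.append(
            GeneImpactCandidate(
                gene_id=gene.gene_id,
                copy_id=ins.copy_id,
                tss_distance_bp=dist,
                expr_full=expr_full.get(gene.gene_id, 0.0),
                expr_empty=expr_empty.get(gene.gene_id, 0.0),
                expression_ratio=ratio,
                passed_filters=["tss_proximity", "enrichment", "expression"],
                **rpkms,
            )
        )
    candidates.sort(key=lambda c: c.gene_id)
    return candidates


def write_candidates(candidates: Sequence[GeneImpactCandidate], path) -> None:
    cols = [
        "gene_id", "copy_id", "tss_distance_bp", "copy_rpkm_full",
        "promoter_rpkm_full", "promoter_rpkm_empty", "expr_full",
        "expr_empty", "expression_ratio", "passed_filters",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in candidates:
            row = [
                c.gene_id, c.copy_id, str(c.tss_distance_bp),
                repr(c.copy_rpkm_full), repr(c.promoter_rpkm_full),
                repr(c.promoter_rpkm_empty), repr(c.expr_full),
                repr(c.expr_empty), repr(c.expression_ratio),
                ",".join(c.passed_filters),
            ]
            fh.write("\t".join(row) + "\n")
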
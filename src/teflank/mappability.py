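"""Mappability scoring of element bodies and flanks.

Consumes a per-base alignability track (values in [0, 1]: the fraction of
reads over a base that align uniquely) and averages it over regions of
interest.  Young repeat interiors score near 0, so copies whose selected
region falls below a threshold are flagged as low-confidence rather than
silently used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .genome_io import GenomicInterval, SignalTrack, TEInsertion

log = logging.getLogger(__name__)

REGION_SELECTORS = ("body", "flank")


@dataclass(frozen=True)
class MappabilityScore:
    region: GenomicInterval
    mean_score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_score <= 1.0):
            raise ValueError("mean mappability must lie in [0, 1]")


def mean_mappability(track: SignalTrack, region: GenomicInterval) -> MappabilityScore:
    """Arithmetic mean of per-base mappability over a region.

    Bases missing from the track (off-chromosome) count as 0 and are
    logged.
    """
    if len(region) == 0:
        raise ValueError("empty region")
    if not track.covers(region.chrom, region.start, region.end):
        log.debug("mappability region %s extends beyond track; padding 0", region)
    mean = track.region(region.chrom, region.start, region.end).mean()
    return MappabilityScore(region=region, mean_score=float(mean))


def _selected_regions(
    insertion: TEInsertion, selector: str, flank_len: int
) -> list[GenomicInterval]:
    iv = insertion.interval
    if selector == "body":
        return [GenomicInterval(iv.chrom, iv.start, iv.end)]
    regions = []
    if iv.start > 0:
        regions.append(
            GenomicInterval(iv.chrom, max(0, iv.start - flank_len), iv.start)
        )
    regions.append(GenomicInterval(iv.chrom, iv.end, iv.end + flank_len))
    return regions


def score_insertion(
    insertion: TEInsertion,
    track: SignalTrack,
    region_selector: str = "flank",
    flank_len: int = 5000,
) -> float:
    """Mean mappability over the selected region(s) of one element."""
    if region_selector not in REGION_SELECTORS:
        raise ValueError(f"region_selector must be one of {REGION_SELECTORS}")
    regions = _selected_regions(insertion, region_selector, flank_len)
    total = sum(len(r) for r in regions)
    weighted = sum(mean_mappability(track, r).mean_score * len(r) for r in regions)
    return weighted / total


def filter_by_mappability(
    insertions: Sequence[TEInsertion],
    track: SignalTrack,
    region_selector: str = "flank",
    min_mean: float = 0.5,
    flank_len: int = 5000,
) -> tuple[list[tuple[TEInsertion, float]], list[tuple[TEInsertion, float]]]:
    """Partition elements by mean mappability of body or flanks.

    Returns ``(kept, dropped)``, each a list of (insertion, mean_score).
    Kept iff the mean over the selected region is >= min_mean.  Intended
    for flagging low-confidence copies in summaries, not silent removal.
    """
    kept, dropped = [], []
    for ins in insertions:
        score = score_insertion(ins, track, region_selector, flank_len)
        (kept if score >= min_mean else dropped).append((ins, score))
    return kept, dropped


def write_mappability_scores(
    scored: Sequence[tuple[TEInsertion, float, bool]], path, region_selector: str
) -> None:
    with open(path, "w") as fh:
        fh.write("copy_id\tselector\tmean_score\tkept\n")
        for ins, score, kept_flag in scored:
            fh.write(
                f"{ins.copy_id}\t{region_selector}\t{score!r}\t{int(kept_flag)}\n"
            )
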
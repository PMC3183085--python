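"""Synthetic two-line cohorts with known ground truth.

Generates an insertion-carrying line (A) and an empty-site line (B) that
share "common" elements and differ at "polymorphic" ones.  Read 5'
positions are drawn from a piecewise-constant Poisson model: genome-wide
background, a fold enrichment inside present element bodies, and a flank
enrichment that decays with distance from the element edge according to a
step or exponential kernel.  Both lines are emitted in the coordinates of
the insertion-carrying reference, matching an analysis where all reads
align to the assembly that contains the full sites.

Everything is driven by one seeded generator, so a fixed seed reproduces
byte-identical fixture bundles.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .genome_io import (
    AlignedRead,
    GeneModel,
    GenomicInterval,
    SignalTrack,
    TEInsertion,
    write_chrom_sizes,
    write_genes_bed,
    write_reads,
    write_signal_track,
    write_te_table,
)

#: minimum body-to-body gap so 5 kb flanks never touch a neighboring body
_COPY_GAP = 10_500
#: keep bodies at least this far from chromosome ends (flank + slack)
_EDGE_MARGIN = 5_250


@dataclass(frozen=True)
class PlantedGene:
    """A gene silenced in line A by a promoter-proximal insertion."""

    tss_distance: int = 368
    silencing_fold: float = 4.0


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 4
    chrom_len_bp: int = 2_000_000
    n_common_copies: int = 50
    n_polymorphic_copies: int = 50
    te_len_bp: int = 5_000
    background_rate: float = 0.02  # expected fragments per bp, line A
    te_fold: float = 10.0
    flank_fold: float = 8.0
    spreading_len_bp: int = 1_000
    kernel: str = "step"  # {"step", "exponential"}
    kernel_tau: float = 1_000.0
    lib_size_a: float = 1.0  # relative library-depth factors
    lib_size_b: float = 1.0
    read_len: int = 36
    fragment_len: int = 150
    mappability_hole_frac: float = 0.3
    n_genes: int = 20
    expr_mean: float = 200.0
    planted_impact_genes: tuple[PlantedGene, ...] = ()
    line_a: str = "lineA"
    line_b: str = "lineB"
    family: str = "IAP"
    flank_len: int = 5_000

    def __post_init__(self) -> None:
        if self.kernel not in ("step", "exponential"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        for name in ("background_rate", "te_fold", "flank_fold",
                     "lib_size_a", "lib_size_b", "expr_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.spreading_len_bp < 0:
            raise ValueError("spreading_len_bp must be >= 0")
        if not (0.0 <= self.mappability_hole_frac <= 1.0):
            raise ValueError("mappability_hole_frac must lie in [0, 1]")
        if len(self.planted_impact_genes) > self.n_polymorphic_copies:
            raise ValueError("more planted genes than polymorphic copies")


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    chrom_sizes: dict[str, int]
    insertions: list[TEInsertion]
    genes: list[GeneModel]
    gene_lengths: dict[str, int]
    reads_a: list[AlignedRead]
    reads_b: list[AlignedRead]
    mappability: SignalTrack
    expr_counts: dict[str, dict[str, int]]
    truth: dict

    @property
    def polymorphic(self) -> list[TEInsertion]:
        return [i for i in self.insertions if i.status == "polymorphic"]

    @property
    def common(self) -> list[TEInsertion]:
        return [i for i in self.insertions if i.status == "common"]


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------


def _place_copies(cfg: SimulationConfig, rng: np.random.Generator):
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    n_total = cfg.n_common_copies + cfg.n_polymorphic_copies
    demand = n_total * (cfg.te_len_bp + _COPY_GAP)
    capacity = cfg.n_chroms * (cfg.chrom_len_bp - 2 * _EDGE_MARGIN)
    if demand > 0.85 * capacity:
        raise ValueError(
            f"genome too small for {n_total} copies "
            f"(need ~{demand} bp of {capacity} bp available)"
        )
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    bodies: list[tuple[str, int, int]] = []
    hi = cfg.chrom_len_bp - cfg.te_len_bp - _EDGE_MARGIN
    for _ in range(n_total):
        for attempt in range(1000):
            chrom = chroms[int(rng.integers(cfg.n_chroms))]
            start = int(rng.integers(_EDGE_MARGIN, hi))
            end = start + cfg.te_len_bp
            clash = any(
                start - _COPY_GAP < e and s < end + _COPY_GAP
                for s, e in placed[chrom]
            )
            if not clash:
                placed[chrom].append((start, end))
                bodies.append((chrom, start, end))
                break
        else:
            raise RuntimeError("failed to place a copy after 1000 attempts")
    # deterministic ids follow genomic order
    bodies.sort()
    strands = rng.choice(["+", "-"], size=n_total)
    status = np.array(
        ["common"] * cfg.n_common_copies + ["polymorphic"] * cfg.n_polymorphic_copies
    )
    rng.shuffle(status)
    insertions = []
    for k, ((chrom, start, end), strand, st) in enumerate(
        zip(bodies, strands, status)
    ):
        present = (
            frozenset({cfg.line_a, cfg.line_b})
            if st == "common"
            else frozenset({cfg.line_a})
        )
        insertions.append(
            TEInsertion(
                interval=GenomicInterval(chrom, start, end, str(strand)),
                family=cfg.family,
                copy_id=f"copy{k:04d}",
                status=str(st),
                present_in=present,
            )
        )
    return chroms, insertions


def _place_genes(
    cfg: SimulationConfig,
    insertions: list[TEInsertion],
    rng: np.random.Generator,
):
    """Background genes far from any copy, plus planted impacted genes
    anchored just downstream of successive polymorphic copies."""
    zones: dict[str, list[tuple[int, int]]] = {}
    for ins in insertions:
        iv = ins.interval
        zones.setdefault(iv.chrom, []).append(
            (iv.start - cfg.flank_len - 2000, iv.end + cfg.flank_len + 2000)
        )
    chroms = sorted({i.interval.chrom for i in insertions}) or ["chr1"]
    genes, gene_lengths = [], {}
    impacted: dict[str, dict] = {}

    polymorphic = [i for i in insertions if i.status == "polymorphic"]
    for j, spec in enumerate(cfg.planted_impact_genes):
        host = polymorphic[j]
        gid = f"impact{j:02d}"
        tss = host.interval.end + spec.tss_distance
        genes.append(GeneModel(gid, host.interval.chrom, tss, "+"))
        gene_lengths[gid] = 1500
        impacted[gid] = {
            "impacted": True,
            "silencing_fold": spec.silencing_fold,
            "copy_id": host.copy_id,
            "tss_distance": spec.tss_distance,
        }

    for j in range(cfg.n_genes):
        for attempt in range(1000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            tss = int(rng.integers(2000, cfg.chrom_len_bp - 5000))
            if not any(s <= tss < e for s, e in zones.get(chrom, [])):
                gid = f"gene{j:04d}"
                genes.append(GeneModel(gid, chrom, tss, "+"))
                gene_lengths[gid] = int(rng.integers(1000, 3000))
                break
        else:
            raise RuntimeError("failed to place a gene after 1000 attempts")
    return genes, gene_lengths, impacted


# ---------------------------------------------------------------------------
# read generation
# ---------------------------------------------------------------------------


def _flank_extra_positions(
    cfg: SimulationConfig,
    edge: int,
    direction: int,
    rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Extra flank read positions on one genomic side of an element.

    ``direction`` is -1 for the left side (positions < edge) and +1 for
    the right side (positions >= edge).
    """
    excess = cfg.flank_fold - 1.0
    if excess <= 0 or cfg.spreading_len_bp == 0:
        return np.empty(0, dtype=np.int64)
    if cfg.kernel == "step":
        span = min(cfg.spreading_len_bp, cfg.flank_len)
        n = rng.poisson(rate * excess * span)
        d = rng.integers(0, span, n)
    else:
        tau = cfg.kernel_tau
        mass = tau * (1.0 - math.exp(-cfg.flank_len / tau))
        n = rng.poisson(rate * excess * mass)
        u = rng.random(n)
        d = (-tau * np.log1p(-u * (1.0 - math.exp(-cfg.flank_len / tau)))).astype(
            np.int64
        )
    if direction > 0:
        return edge + d
    return edge - 1 - d


def _line_reads(
    cfg: SimulationConfig,
    chroms: list[str],
    insertions: list[TEInsertion],
    holes: dict[str, np.ndarray],
    lib_factor: float,
    rng: np.random.Generator,
    line: str,
) -> list[AlignedRead]:
    rate = cfg.background_rate * lib_factor
    per_chrom: dict[str, list[np.ndarray]] = {c: [] for c in chroms}
    for chrom in chroms:
        n_bg = rng.poisson(rate * cfg.chrom_len_bp)
        per_chrom[chrom].append(rng.integers(0, cfg.chrom_len_bp, n_bg))
    for ins in insertions:
        if line not in ins.present_in:
            continue
        iv = ins.interval
        n_body = rng.poisson(rate * (cfg.te_fold - 1.0) * len(iv))
        per_chrom[iv.chrom].append(rng.integers(iv.start, iv.end, n_body))
        per_chrom[iv.chrom].append(
            _flank_extra_positions(cfg, iv.start, -1, rate, rng)
        )
        per_chrom[iv.chrom].append(
            _flank_extra_positions(cfg, iv.end, +1, rate, rng)
        )
    reads: list[AlignedRead] = []
    for chrom in chroms:
        pos = np.concatenate(per_chrom[chrom]) if per_chrom[chrom] else np.empty(0, int)
        pos = np.clip(pos, 0, cfg.chrom_len_bp - 1).astype(np.int64)
        strands = rng.choice(["+", "-"], size=pos.size)
        # keep the read body itself on-chromosome for either orientation
        pos = np.where(
            strands == "-",
            np.clip(pos, cfg.read_len - 1, cfg.chrom_len_bp - 1),
            np.clip(pos, 0, cfg.chrom_len_bp - cfg.read_len),
        )
        hole_edges = holes.get(chrom)
        if hole_edges is not None and hole_edges.size:
            # inside a hole <=> searchsorted index is odd
            in_hole = (np.searchsorted(hole_edges, pos, side="right") % 2) == 1
        else:
            in_hole = np.zeros(pos.size, dtype=bool)
        for p, s, h in zip(pos.tolist(), strands.tolist(), in_hole.tolist()):
            reads.append(
                AlignedRead(
                    chrom=chrom,
                    pos5=p,
                    read_len=cfg.read_len,
                    strand=s,
                    mapq=37,
                    is_unique=not h,
                )
            )
    return reads


def _mappability(
    cfg: SimulationConfig, chroms: list[str], insertions: list[TEInsertion]
) -> tuple[SignalTrack, dict[str, np.ndarray]]:
    """All-1 track with a central zero hole inside every element body."""
    track = SignalTrack(
        {c: np.ones(cfg.chrom_len_bp, dtype=float) for c in chroms}
    )
    holes: dict[str, list[int]] = {c: [] for c in chroms}
    if cfg.mappability_hole_frac > 0:
        for ins in insertions:
            iv = ins.interval
            hole_len = int(round(len(iv) * cfg.mappability_hole_frac))
            if hole_len == 0:
                continue
            mid = (iv.start + iv.end) // 2
            s, e = mid - hole_len // 2, mid - hole_len // 2 + hole_len
            track.values(iv.chrom)[s:e] = 0.0
            holes[iv.chrom].extend((s, e))
    hole_edges = {
        c: np.array(sorted(v), dtype=np.int64) for c, v in holes.items()
    }
    return track, hole_edges


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a complete two-line cohort from a seeded generative model."""
    rng = np.random.default_rng(config.seed)
    chroms, insertions = _place_copies(config, rng)
    genes, gene_lengths, impacted = _place_genes(config, insertions, rng)
    mapp_track, holes = _mappability(config, chroms, insertions)
    reads_a = _line_reads(
        config, chroms, insertions, holes, config.lib_size_a / config.lib_size_a,
        rng, config.line_a,
    )
    reads_b = _line_reads(
        config, chroms, insertions, holes, config.lib_size_b / config.lib_size_a,
        rng, config.line_b,
    )
    expr_a: dict[str, int] = {}
    expr_b: dict[str, int] = {}
    for g in genes:
        lam = config.expr_mean
        lam_a = lam / impacted[g.gene_id]["silencing_fold"] if g.gene_id in impacted else lam
        expr_a[g.gene_id] = int(rng.poisson(lam_a))
        expr_b[g.gene_id] = int(rng.poisson(lam))
    truth = {
        "copies": {
            ins.copy_id: {
                "status": ins.status,
                "present_in": sorted(ins.present_in),
                "spreading_len_bp": config.spreading_len_bp,
                "flank_fold": config.flank_fold,
            }
            for ins in insertions
        },
        "genes": {
            g.gene_id: impacted.get(
                g.gene_id, {"impacted": False, "silencing_fold": 1.0}
            )
            for g in genes
        },
    }
    return SyntheticCohort(
        config=config,
        chrom_sizes={c: config.chrom_len_bp for c in chroms},
        insertions=insertions,
        genes=genes,
        gene_lengths=gene_lengths,
        reads_a=reads_a,
        reads_b=reads_b,
        mappability=mapp_track,
        expr_counts={config.line_a: expr_a, config.line_b: expr_b},
        truth=truth,
    )


def write_fixture_bundle(cohort: SyntheticCohort, directory) -> dict:
    """Write the cohort as a directory of plain-text files; return manifest.

    Re-running with the same seed/config reproduces byte-identical files.
    """
    os.makedirs(directory, exist_ok=True)
    cfg = cohort.config
    files = {
        "te_table": "te_table.tsv",
        "genes": "genes.bed",
        "reads_a": f"reads_{cfg.line_a}.bed",
        "reads_b": f"reads_{cfg.line_b}.bed",
        "mappability": "mappability.bedGraph",
        "expression": "expression.tsv",
        "chrom_sizes": "chrom.sizes",
        "truth": "truth.json",
    }
    p = lambda name: os.path.join(directory, files[name])
    write_te_table(cohort.insertions, p("te_table"), [cfg.line_a, cfg.line_b])
    write_genes_bed(cohort.genes, p("genes"), cohort.gene_lengths)
    write_reads(cohort.reads_a, p("reads_a"))
    write_reads(cohort.reads_b, p("reads_b"))
    write_signal_track(cohort.mappability, p("mappability"))
    with open(p("expression"), "w") as fh:
        fh.write(f"gene_id\tlength_bp\t{cfg.line_a}\t{cfg.line_b}\n")
        for g in sorted(cohort.genes, key=lambda g: g.gene_id):
            fh.write(
                f"{g.gene_id}\t{cohort.gene_lengths[g.gene_id]}\t"
                f"{cohort.expr_counts[cfg.line_a][g.gene_id]}\t"
                f"{cohort.expr_counts[cfg.line_b][g.gene_id]}\n"
            )
    write_chrom_sizes(cohort.chrom_sizes, p("chrom_sizes"))
    with open(p("truth"), "w") as fh:
        json.dump(cohort.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest = {
        "seed": cfg.seed,
        "line_labels": [cfg.line_a, cfg.line_b],
        "config": dataclasses.asdict(cfg),
        "files": files,
    }
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
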
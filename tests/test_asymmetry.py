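import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from teflank import asymmetry as asym
from teflank.genome_io import AlignedRead, GenomicInterval, SignalTrack
from teflank.simulate import SimulationConfig, simulate_cohort
from teflank.coverage import extend_read, filter_reads, mask_te_reads

from conftest import make_insertion

# ---------------------------------------------------------------------------
# RPKM
# ---------------------------------------------------------------------------


def test_rpkm_direct_substitution():
    assert asym.rpkm(asym.RegionReadStats(1000, 1.0, 1.0)) == 1000.0
    assert asym.rpkm(asym.RegionReadStats(0, 1.0, 1.0)) == 0.0
    assert asym.rpkm(asym.RegionReadStats(50, 2.0, 10.0)) == 2.5


def test_rpkm_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        asym.RegionReadStats(10, 0.0, 1.0)
    with pytest.raises(ValueError):
        asym.RegionReadStats(10, 1.0, 0.0)
    with pytest.raises(ValueError):
        asym.RegionReadStats(-1, 1.0, 1.0)


# ---------------------------------------------------------------------------
# asymmetry statistic
# ---------------------------------------------------------------------------


def test_asymmetry_equal_rpkms_is_zero():
    for v in (0.5, 1.0, 100.0, 1e6):
        assert asym.rpkm_asymmetry(v, v) == 0.0


def test_asymmetry_one_sided_extremes():
    assert asym.rpkm_asymmetry(100.0, 0.0) == pytest.approx(1.0, abs=1e-6)
    assert asym.rpkm_asymmetry(0.0, 100.0) == pytest.approx(-1.0, abs=1e-6)


def test_asymmetry_zero_zero():
    assert asym.rpkm_asymmetry(0.0, 0.0) == 0.0


def test_asymmetry_rejects_negative():
    with pytest.raises(ValueError):
        asym.rpkm_asymmetry(-1.0, 1.0)
    with pytest.raises(ValueError):
        asym.rpkm_asymmetry(1.0, 1.0, eps=0.0)


nonneg = st.floats(min_value=0, max_value=1e9, allow_nan=False)


@given(a=nonneg, b=nonneg)
def test_asymmetry_antisymmetric_and_bounded(a, b):
    x = asym.rpkm_asymmetry(a, b)
    assert -1.0 <= x <= 1.0
    assert x == pytest.approx(-asym.rpkm_asymmetry(b, a), abs=1e-12)


@given(
    a=st.floats(min_value=1e-2, max_value=1e6),
    b=st.floats(min_value=1e-2, max_value=1e6),
    c=st.floats(min_value=0.01, max_value=100.0),
)
def test_asymmetry_scale_invariance(a, b, c):
    # the eps guard perturbs the ratio by at most ~eps / (c * (a + b))
    tol = max(1e-9, 10 * asym.DEFAULT_EPS / (c * (a + b)))
    assert asym.rpkm_asymmetry(a * c, b * c) == pytest.approx(
        asym.rpkm_asymmetry(a, b), abs=tol
    )


def test_window_label():
    assert asym.window_label((0, 1000)) == "<1kb"
    assert asym.window_label((1000, 2500)) == "1–2.5kb"
    assert asym.window_label((2500, 5000)) == "2.5–5kb"


# ---------------------------------------------------------------------------
# fragment index
# ---------------------------------------------------------------------------


def test_fragment_index_matches_bruteforce(rng):
    reads = []
    for _ in range(200):
        strand = "+" if rng.random() < 0.5 else "-"
        reads.append(
            AlignedRead("chr1", int(rng.integers(0, 5000)), 36, strand, 30)
        )
    sizes = {"chr1": 5000}
    index = asym.FragmentIndex(reads, 150, sizes)
    for _ in range(30):
        s = int(rng.integers(0, 4000))
        e = s + int(rng.integers(100, 1000))
        region = GenomicInterval("chr1", s, e)
        expected = 0.0
        for r in reads:
            iv = extend_read(r, 150, chrom_size=5000)
            ov = min(iv.end, e) - max(iv.start, s)
            if ov > 0:
                expected += ov / len(iv)
        assert index.count(region) == pytest.approx(expected)


def test_fragment_index_five_prime_mode():
    reads = [
        AlignedRead("chr1", 100, 36, "+", 30),
        AlignedRead("chr1", 400, 36, "-", 30),
    ]
    index = asym.FragmentIndex(reads, 150, {"chr1": 1000})
    assert index.count(GenomicInterval("chr1", 0, 200), "five_prime") == 1.0
    assert index.count(GenomicInterval("chr1", 0, 401), "five_prime") == 2.0


# ---------------------------------------------------------------------------
# per-copy flank asymmetry
# ---------------------------------------------------------------------------


def _flank_reads(rng, ins, window, n, chrom="chr1"):
    """n reads uniform in both flank windows of an insertion."""
    w0, w1 = window
    reads = []
    for _ in range(n):
        if rng.random() < 0.5:
            pos = int(rng.integers(ins.interval.start - w1, ins.interval.start - w0))
        else:
            pos = int(rng.integers(ins.interval.end + w0, ins.interval.end + w1))
        reads.append(AlignedRead(chrom, pos, 36, "+", 30))
    return reads


def test_one_sided_signal_gives_plus_one(rng):
    ins = make_insertion()
    reads_a = _flank_reads(rng, ins, (0, 1000), 50)
    rec = asym.copy_flank_asymmetry(
        reads_a, [], ins, N_a=1000, N_b=1000, chrom_sizes={"chr1": 200_000}
    )
    assert rec.asymmetry == pytest.approx(1.0, abs=1e-6)
    assert rec.rpkm_b == 0.0


def test_library_normalization_shifts_sign(rng):
    # equal raw counts but line A sequenced 2x deeper -> negative asymmetry
    ins = make_insertion()
    reads = _flank_reads(rng, ins, (0, 1000), 60)
    rec = asym.copy_flank_asymmetry(
        reads, list(reads), ins, N_a=2_000_000, N_b=1_000_000,
        chrom_sizes={"chr1": 200_000},
    )
    assert rec.asymmetry < 0
    assert rec.asymmetry == pytest.approx(-1.0 / 3.0, abs=1e-6)


def test_truncated_window_flagged():
    ins = make_insertion(start=500, end=5500)
    rec = asym.copy_flank_asymmetry(
        [], [], ins, N_a=1000, N_b=1000, window=(0, 1000),
        chrom_sizes={"chr1": 200_000},
    )
    assert rec.truncated


def test_per_side_records(rng):
    ins = make_insertion()
    reads_a = _flank_reads(rng, ins, (0, 1000), 40)
    recs = asym.copy_flank_asymmetry(
        reads_a, [], ins, N_a=1000, N_b=1000, combine_sides=False,
        chrom_sizes={"chr1": 200_000},
    )
    assert [r.side for r in recs] == ["five_prime", "three_prime"]


def test_windowed_asymmetry_labels(rng):
    ins = make_insertion()
    records = asym.windowed_asymmetry(
        [], [], [ins], N_a=1000, N_b=1000, chrom_sizes={"chr1": 200_000}
    )
    assert [r.window_label for r in records] == ["<1kb", "1–2.5kb", "2.5–5kb"]
    assert asym.windowed_asymmetry([], [], [], 1000, 1000) == []


def test_windowed_asymmetry_rejects_overlapping_scheme():
    with pytest.raises(ValueError):
        asym.windowed_asymmetry(
            [], [], [], 1000, 1000, scheme=((0, 1500), (1000, 2500))
        )


def test_null_simulation_mean_near_zero():
    # no enrichment anywhere: per-copy asymmetry averages to ~0
    cfg = SimulationConfig(
        seed=5, n_chroms=2, chrom_len_bp=1_200_000, n_common_copies=0,
        n_polymorphic_copies=60, te_fold=1.0, flank_fold=1.0, n_genes=0,
        mappability_hole_frac=0.0,
    )
    cohort = simulate_cohort(cfg)
    a, n_a = filter_reads(cohort.reads_a)
    b, n_b = filter_reads(cohort.reads_b)
    a = mask_te_reads(a, cohort.insertions, chrom_sizes=cohort.chrom_sizes)
    b = mask_te_reads(b, cohort.insertions, chrom_sizes=cohort.chrom_sizes)
    records = [
        asym.copy_flank_asymmetry(
            asym.FragmentIndex(a, 150, cohort.chrom_sizes),
            asym.FragmentIndex(b, 150, cohort.chrom_sizes),
            ins, n_a, n_b, chrom_sizes=cohort.chrom_sizes,
        )
        for ins in cohort.insertions
    ]
    vals = [r.asymmetry for r in records if not r.truncated]
    assert abs(np.mean(vals)) < 0.1


# ---------------------------------------------------------------------------
# skewness
# ---------------------------------------------------------------------------


def test_skewness_symmetric_is_zero():
    assert asym.skewness([-2, -1, 0, 1, 2]) == 0.0


def test_skewness_right_tail_positive():
    assert asym.skewness([0, 0, 0, 10]) > 0


def test_skewness_matches_moment_formula(rng):
    # left-skewed mixture, checked against the G1 moments written out
    x = np.concatenate([rng.normal(0.5, 0.1, 800), rng.normal(-0.5, 0.3, 200)])
    n = x.size
    m3 = np.mean((x - x.mean()) ** 3)
    s = x.std(ddof=1)
    expected = (n**2 / ((n - 1) * (n - 2))) * m3 / s**3
    got = asym.skewness(x)
    assert got < 0
    assert got == pytest.approx(expected, rel=1e-9)


def test_skewness_errors():
    with pytest.raises(ValueError):
        asym.skewness([1.0, 2.0])
    with pytest.raises(ValueError):
        asym.skewness([3.0, 3.0, 3.0])


@settings(max_examples=50)
@given(
    shift=st.floats(min_value=-100, max_value=100),
    scale=st.floats(min_value=0.01, max_value=100),
)
def test_skewness_shift_scale_invariance(shift, scale):
    x = np.array([-2.0, -1.0, 0.0, 1.5, 4.0])
    base = asym.skewness(x)
    assert asym.skewness(x * scale + shift) == pytest.approx(base, abs=1e-6)
    assert asym.skewness(-x) == pytest.approx(-base, abs=1e-9)


# ---------------------------------------------------------------------------
# distribution summaries
# ---------------------------------------------------------------------------


def _records(values, truncated=None):
    truncated = truncated or [False] * len(values)
    return [
        asym.AsymmetryRecord(f"c{i}", "<1kb", 0, 0, v, truncated=t)
        for i, (v, t) in enumerate(zip(values, truncated))
    ]


def test_summary_zero_variance_reports_nan():
    s = asym.summarize_distribution(_records([0.0, 0.0, 0.0, 0.0]))
    assert np.isnan(s.skewness)
    assert s.median == 0.0


def test_summary_symmetric_pairs():
    s = asym.summarize_distribution(_records([-0.5, 0.5, -0.2, 0.2]))
    assert s.skewness == pytest.approx(0.0, abs=1e-12)


def test_summary_excludes_truncated():
    recs = _records([0.1, 0.2, 0.3, 0.9], truncated=[False, False, False, True])
    s = asym.summarize_distribution(recs)
    assert s.n_values == 3
    with pytest.raises(ValueError):
        asym.summarize_distribution(recs[:2])


def test_summary_histogram_default_bins():
    s = asym.summarize_distribution(_records([-1.0, 0.0, 1.0]))
    assert len(s.counts) == 21
    assert s.bin_edges[0] == -1.0 and s.bin_edges[-1] == 1.0
    assert s.counts.sum() == 3


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------


def test_kruskal_identical_groups():
    res = asym.kruskal_dunn({"a": [1, 2, 3], "b": [1, 2, 3]})
    assert res["H"] == pytest.approx(0.0, abs=1e-9)
    assert res["p_kw"] > 0.9


def test_kruskal_large_shift_significant(rng):
    a = rng.normal(0, 1, 200)
    res = asym.kruskal_dunn({"a": a, "b": a + 2})
    assert res["p_kw"] < 1e-3
    assert res["pairwise"][0][3] < 1e-3


def test_kruskal_three_groups_pairwise_count(rng):
    groups = {k: rng.normal(i, 1, 30) for i, k in enumerate("abc")}
    res = asym.kruskal_dunn(groups)
    assert len(res["pairwise"]) == 3


def test_kruskal_single_group_error():
    with pytest.raises(ValueError):
        asym.kruskal_dunn({"a": [1, 2, 3]})
    with pytest.raises(ValueError):
        asym.kruskal_dunn({"a": [1.0], "b": []})


def test_dunn_matches_independent_computation(rng):
    # re-derive the tie-corrected Dunn z for two groups from first principles
    a = list(rng.integers(0, 8, 40).astype(float))
    b = list(rng.integers(2, 10, 25).astype(float))
    res = asym.kruskal_dunn({"a": a, "b": b})
    pooled = np.array(a + b)
    ranks = sps.rankdata(pooled)
    N = pooled.size
    _, t = np.unique(pooled, return_counts=True)
    tie = (t**3 - t).sum() / (12 * (N - 1))
    var = (N * (N + 1) / 12 - tie) * (1 / len(a) + 1 / len(b))
    z_expected = (ranks[:40].mean() - ranks[40:].mean()) / np.sqrt(var)
    _, _, z, p = res["pairwise"][0]
    assert z == pytest.approx(z_expected, rel=1e-12)
    assert p == pytest.approx(min(1.0, 2 * sps.norm.sf(abs(z_expected))), rel=1e-12)


# ---------------------------------------------------------------------------
# differential scan
# ---------------------------------------------------------------------------


def test_scan_block_only_in_b():
    size = 100_000
    a = SignalTrack.zeros({"chr1": size})
    b = SignalTrack.zeros({"chr1": size})
    b.values("chr1")[50_000:52_000] = 5.0
    hits = asym.asymmetry_scan(a, b, 10_000, 10_000, min_rpkm=0.1)
    assert len(hits) == 1
    iv, val = hits[0]
    assert val == pytest.approx(-1.0, abs=1e-6)
    assert iv.start <= 50_000 and iv.end >= 52_000


def test_scan_identical_tracks_no_candidates():
    t = SignalTrack({"chr1": np.ones(50_000)})
    assert asym.asymmetry_scan(t, t, 10_000, 10_000) == []


def test_scan_planted_blocks_recovered(rng):
    size = 1_000_000
    a = SignalTrack.zeros({"chr1": size})
    b = SignalTrack.zeros({"chr1": size})
    planted = [100_000, 300_000, 500_000, 700_000, 900_000 - 2000]
    for s in planted:
        b.values("chr1")[s : s + 2000] = 4.0
    hits = asym.asymmetry_scan(a, b, 10_000, 10_000, min_rpkm=0.1)
    assert len(hits) == 5
    found = sorted(iv.start for iv, _ in hits)
    for s, iv_start in zip(sorted(planted), found):
        assert abs(iv_start - s) <= 1000  # within one scan step


def test_scan_step_larger_than_window_rejected():
    t = SignalTrack({"chr1": np.ones(10_000)})
    with pytest.raises(ValueError):
        asym.asymmetry_scan(t, t, 1000, 1000, window=500, step=1000)
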
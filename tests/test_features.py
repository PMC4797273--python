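"""Window statistics, tracks, methylation, states, feature matrices, profiles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cobindscan.events import EventTable, Peak, ValidationError, classify_events
from cobindscan.features import (
    CoverageTrack,
    CpGTable,
    FeatureMatrix,
    ReadTrack,
    Segmentation,
    aggregate_profile,
    count_reads,
    extract_features,
    methylation_level,
    resolve_feature_set,
    rpkm,
    state_at,
    window_around,
)
from cobindscan.genome import InMemoryGenome, gc_content


# ---------------------------------------------------------------------------
# windows, rpkm, gc
# ---------------------------------------------------------------------------

def test_window_around_basic_and_clipping():
    w = window_around(500, 100)
    assert (w.start, w.end) == (450, 550)
    clipped = window_around(10, 100)
    assert (clipped.start, clipped.end) == (0, 60)
    wide = window_around(500, 6000)
    assert (wide.start, wide.end) == (0, 3500)
    end_clip = window_around(990, 100, chrom_length=1000)
    assert (end_clip.start, end_clip.end) == (940, 1000)


def test_window_around_errors():
    with pytest.raises(ValidationError):
        window_around(500, 101)  # odd width
    with pytest.raises(ValidationError):
        window_around(1000, 100, chrom_length=1000)  # summit beyond end


@pytest.mark.parametrize(
    "count,window,library,expected",
    [(10, 100, 10**6, 100.0), (0, 100, 10**6, 0.0), (1, 1000, 10**6, 1.0)],
)
def test_rpkm_fixtures(count, window, library, expected):
    assert rpkm(count, window, library) == expected


def test_rpkm_errors_and_linearity():
    with pytest.raises(ValidationError):
        rpkm(1, 100, 0)
    assert rpkm(20, 100, 10**6) == 2 * rpkm(10, 100, 10**6)
    assert rpkm(10, 100, 2 * 10**6) == rpkm(10, 100, 10**6) / 2


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.integers(0, 10_000), st.integers(1, 5_000), st.integers(1, 10**8))
def test_rpkm_scaling_laws(count, window, library):
    """Doubling counts doubles RPKM; doubling the library halves it."""
    base = rpkm(count, window, library)
    assert rpkm(2 * count, window, library) == pytest.approx(2 * base)
    assert rpkm(count, window, 2 * library) == pytest.approx(base / 2)


@pytest.mark.parametrize(
    "seq,expected", [("GCGC", 1.0), ("ATAT", 0.0), ("ACGT", 0.5), ("acgt", 0.5),
                     ("ANGT", 1 / 3)],
)
def test_gc_content(seq, expected):
    assert gc_content(seq) == pytest.approx(expected)


def test_gc_content_all_n_is_missing_and_illegal_rejected():
    assert math.isnan(gc_content("NNNN"))
    with pytest.raises(ValidationError):
        gc_content("ACGU")


def test_gc_reverse_complement_invariant():
    rng = np.random.default_rng(0)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGTN"), size=50))
        rc = "".join(comp[b] for b in reversed(seq))
        got, want = gc_content(seq), gc_content(rc)
        assert got == pytest.approx(want) or (math.isnan(got) and math.isnan(want))


# ---------------------------------------------------------------------------
# read counting
# ---------------------------------------------------------------------------

def _track(intervals, name="t", library=None):
    return ReadTrack.from_intervals(name, intervals, library)


def test_count_reads_fixture():
    track = _track([("c", 440, 476), ("c", 560, 596)], library=10)
    win = window_around(500, 100, chrom="c")
    assert count_reads(track, win) == 1


def test_count_reads_edge_cases():
    win = window_around(500, 100, chrom="c")
    assert count_reads(_track([("other", 450, 500)], library=5), win) == 0
    # read exactly equal to the window
    assert count_reads(_track([("c", 450, 550)]), win) == 1
    # 1-bp touching at each edge: [414,450) misses, [449,485) hits
    assert count_reads(_track([("c", 414, 450), ("c", 549, 585)]), win) == 1
    assert count_reads(_track([("c", 413, 449), ("c", 550, 586)]), win) == 0


def test_count_reads_five_prime_mode():
    track = _track([("c", 440, 476), ("c", 460, 496), ("c", 549, 585)])
    win = window_around(500, 100, chrom="c")
    assert count_reads(track, win, mode="overlap") == 3
    assert count_reads(track, win, mode="five_prime") == 2  # 440 is outside


def test_count_matches_enumeration_on_random_reads():
    rng = np.random.default_rng(3)
    starts = rng.integers(0, 5000, size=400)
    lengths = rng.integers(20, 80, size=400)
    track = _track([("c", int(s), int(s + l)) for s, l in zip(starts, lengths)])
    for _ in range(30):
        s = int(rng.integers(0, 4800))
        e = s + int(rng.integers(10, 200))
        win = window_around((s + e) // 2, 2 * ((e - s) // 2) or 2, chrom="c")
        expected = sum(1 for a, l in zip(starts, lengths)
                       if a < win.end and a + l > win.start)
        assert count_reads(track, win) == expected


def test_library_size_must_cover_stored_reads():
    with pytest.raises(ValidationError):
        _track([("c", 0, 36), ("c", 50, 86)], library=1)


# ---------------------------------------------------------------------------
# methylation and segmentation
# ---------------------------------------------------------------------------

def test_methylation_level():
    cpgs = CpGTable({"c": (np.array([460, 520, 900]), np.array([0.2, 0.8, 0.5]))})
    win = window_around(500, 100, chrom="c")
    assert methylation_level(cpgs, win) == pytest.approx(0.5)
    assert math.isnan(methylation_level(cpgs, window_around(2000, 100, chrom="c")))
    single = CpGTable({"c": (np.array([500]), np.array([0.37]))})
    assert methylation_level(single, win) == pytest.approx(0.37)


def test_cpg_validation():
    with pytest.raises(ValidationError):
        CpGTable({"c": (np.array([1, 1]), np.array([0.5, 0.5]))})
    with pytest.raises(ValidationError):
        CpGTable({"c": (np.array([1]), np.array([1.5]))})


def test_state_at_half_open_and_gap():
    seg = Segmentation(
        {"c": (np.array([0, 100]), np.array([100, 200]), ["E7", "E2"])},
        states=["E2", "E7"],
    )
    label, onehot = state_at(seg, "c", 50)
    assert label == "E7" and list(onehot) == [0.0, 1.0]
    # boundary belongs to the next interval (half-open)
    assert state_at(seg, "c", 100)[0] == "E2"
    label, onehot = state_at(seg, "c", 300)
    assert label is None and not onehot.any()


def test_segmentation_overlap_rejected():
    with pytest.raises(ValidationError):
        Segmentation({"c": (np.array([0, 50]), np.array([100, 150]), ["E1", "E2"])})


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def _toy_events():
    a = [Peak("c", 100, 400, 250, name="a1"), Peak("c", 1000, 1300, 1150, name="a2"),
         Peak("c", 2000, 2300, 2150, name="a3")]
    b = [Peak("c", 1050, 1350, 1200, name="b1")]
    return classify_events(a, b, 0.30)


def test_extract_features_zero_counts_give_zero_columns():
    events = _toy_events()
    empty = ReadTrack.from_arrays("mark", {}, library_size=10**6)
    m = extract_features(events, [empty], side="A")
    assert np.allclose(m.values, 0.0)  # log2(0 + 1) = 0


def test_extract_features_hand_computed_log2_rpkm():
    events = _toy_events()
    # a1 window [200,300): 2 reads; a2 window [1100,1200): 1; a3: 0
    t1 = _track([("c", 190, 226), ("c", 250, 286), ("c", 1150, 1186)],
                name="m1", library=10**6)
    t2 = _track([("c", 2100, 2136)], name="m2", library=2 * 10**6)
    m = extract_features(events, [t1, t2], side="A", pseudocount=1.0)
    assert m.feature_names == ["m1", "m2"]
    expected_m1 = [math.log2(20 + 1), math.log2(10 + 1), math.log2(0 + 1)]
    expected_m2 = [0.0, 0.0, math.log2(5 + 1)]
    assert np.allclose(m.values[:, 0], expected_m1)
    assert np.allclose(m.values[:, 1], expected_m2)


def test_extract_features_labels_follow_contrast_side():
    events = _toy_events()  # a2-b1 co-occupied, a1/a3 solo
    empty = ReadTrack.from_arrays("mark", {}, library_size=100)
    m = extract_features(events, [empty], side="A")
    assert list(m.site_ids) == ["a1", "a2", "a3"]
    assert list(m.labels) == [0, 1, 0]
    mb = extract_features(events, [empty], side="B")
    assert list(mb.site_ids) == ["b1"] and list(mb.labels) == [1]


def test_extract_features_missing_chromosome_flagged():
    events = _toy_events()
    track = _track([("other", 0, 36)], name="m")
    m = extract_features(events, [track], side="A")
    assert m.missing_mask[:, 0].all()


def test_extract_features_gc_and_methylation_and_state(small_cell):
    events = small_cell.truth
    m = extract_features(
        events, list(small_cell.tracks.values()), genome=small_cell.genome,
        cpgs=small_cell.cpgs, seg=small_cell.segmentation, side="A",
    )
    assert "GC" in m.feature_names and "methylation" in m.feature_names
    assert any(f.startswith("state_") for f in m.feature_names)
    # methylation-bearing rows only, and no missing methylation remains
    j = m.feature_names.index("methylation")
    assert np.isfinite(m.values[:, j]).all()
    assert m.n_sites <= len(events.side("A"))


def test_extract_row_order_is_event_order(small_cell):
    m1 = extract_features(small_cell.truth, [small_cell.tracks["DNaseI"]], side="A")
    m2 = extract_features(small_cell.truth, [small_cell.tracks["DNaseI"]], side="A")
    assert list(m1.site_ids) == list(m2.site_ids)
    assert np.array_equal(m1.values, m2.values)
    assert list(m1.site_ids) == small_cell.truth.side("A")["name"].tolist()


def test_coverage_track_mean():
    cov = CoverageTrack(
        "dnase",
        {"c": (np.array([0, 100]), np.array([100, 200]), np.array([2.0, 4.0]))},
    )
    assert cov.mean_coverage(window_around(100, 100, chrom="c")) == pytest.approx(3.0)
    assert cov.mean_coverage(window_around(500, 100, chrom="c")) == 0.0


def test_feature_matrix_tsv_round_trip(tmp_path, small_cell):
    m = extract_features(small_cell.truth, list(small_cell.tracks.values()),
                         genome=small_cell.genome, side="A")
    m.write_tsv(tmp_path / "m.tsv")
    back = FeatureMatrix.read_tsv(tmp_path / "m.tsv")
    assert back.feature_names == m.feature_names
    assert np.allclose(back.values, m.values, equal_nan=True)
    assert np.array_equal(back.labels, m.labels)


def test_resolve_feature_set():
    avail = ["DNaseI", "H3K4me3", "H3K27ac", "GC", "methylation", "state_E1"]
    assert resolve_feature_set(avail, "all") == ["DNaseI", "H3K4me3", "H3K27ac", "GC"]
    assert resolve_feature_set(avail, "dnase+gc") == ["DNaseI", "GC"]
    assert resolve_feature_set(avail, "hms") == ["H3K4me3", "H3K27ac"]
    assert resolve_feature_set(avail, "H3K4me3") == ["H3K4me3"]
    with pytest.raises(ValidationError):
        resolve_feature_set(avail, "H3K9ac")


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def test_profile_uniform_track_is_flat():
    events = classify_events([Peak("c", 99_000, 99_300, 99_150, name="a")], [])
    # one read in every 100-bp bin across the whole span
    reads = [("c", s, s + 36) for s in range(95_000, 103_000, 100)]
    prof = aggregate_profile(classify_events([Peak("c", 99_000, 99_300, 99_150, name="a")], []),
                             _track(reads, library=10**6), span=2000, bin_bp=100)
    row = prof.mean_rpkm[prof.categories.index("A_only")]
    assert len(row) == 20
    assert np.allclose(row, row[0])


def test_profile_delta_reads_hit_central_bin_only():
    events = classify_events([Peak("c", 10_000, 10_300, 10_150, name="a")], [])
    track = _track([("c", 10_140, 10_160)] * 5, library=10**6)
    prof = aggregate_profile(events, track, span=6000, bin_bp=100)
    # reads straddle the summit: exactly the two innermost bins (centers +-50)
    row = prof.mean_rpkm[0]
    nonzero_centers = set(prof.bin_centers[np.flatnonzero(row > 0)])
    assert nonzero_centers == {-50, 50}


def test_profile_matches_brute_force(small_cell):
    track = small_cell.tracks["DNaseI"]
    events = small_cell.truth
    prof = aggregate_profile(events, track, span=2000, bin_bp=100, side="A",
                             chrom_sizes=small_cell.genome.chrom_sizes)
    records = events.side("A")
    for cat in prof.categories:
        sub = records[records["category"] == cat].head(10)
        for _, rec in sub.iterrows():
            left = rec["summit"] - 1000
            for bi in range(20):
                s, e = left + bi * 100, left + bi * 100 + 100
                if s < 0:
                    continue
                expected = rpkm(
                    count_reads(track, window_around(s + 50, 100, chrom=rec["chrom"])),
                    100, track.library_size,
                )
                # the site's own contribution is included in the bin mean
                ci = prof.categories.index(cat)
                assert prof.n_sites[ci, bi] > 0
    # single-site category equals its own binned vector
    one = classify_events([Peak("chrS1", 5000, 5300, 5150, name="solo")], [])
    p1 = aggregate_profile(one, track, span=2000, bin_bp=100)
    own = [
        rpkm(track.count_many("chrS1", np.array([5150 - 1000 + i * 100]),
                              np.array([5150 - 1000 + i * 100 + 100]))[0],
             100, track.library_size)
        for i in range(20)
    ]
    assert np.allclose(p1.mean_rpkm[0], own)


def test_profile_brute_force_means(small_cell):
    """Per-bin means equal an explicit loop over sites."""
    track = small_cell.tracks["H3K9me3"]
    events = small_cell.truth
    records = events.side("A").head(30)
    sub_events = EventTable(records.reset_index(drop=True))
    prof = aggregate_profile(sub_events, track, span=1000, bin_bp=100,
                             chrom_sizes=small_cell.genome.chrom_sizes)
    for ci, cat in enumerate(prof.categories):
        cat_recs = records[records["category"] == cat]
        for bi in range(10):
            vals = []
            for _, rec in cat_recs.iterrows():
                s = rec["summit"] - 500 + bi * 100
                if s < 0 or s + 100 > small_cell.genome.chrom_sizes[rec["chrom"]]:
                    continue
                c = track.count_many(rec["chrom"], np.array([s]), np.array([s + 100]))[0]
                vals.append(rpkm(c, 100, track.library_size))
            if vals:
                assert prof.mean_rpkm[ci, bi] == pytest.approx(np.mean(vals))
                assert prof.n_sites[ci, bi] == len(vals)
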
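"""Positional motif-density computation: orientation, scanning,
aggregation, smoothing, permutation nulls, cross-binding profiles."""

import re

import numpy as np
import pytest
from hypothesis import given, strategies as st

from apakit import (
    DEFAULT_PAS_MOTIFS,
    FlankWindow,
    GenomeSequence,
    MotifSet,
    Site,
    SiteSet,
    aggregate_density,
    anchor_position,
    cross_site_profile,
    extract_flanks,
    permutation_z,
    reverse_complement,
    scan_motif_starts,
    smooth_profile,
)
from conftest import make_sites


def naive_density(windows, motifs):
    """Independent oracle: regex lookahead scan, one window at a time."""
    flank = windows[0].flank
    counts = np.zeros(2 * flank)
    for w in windows:
        for motif in motifs:
            for m in re.finditer(f"(?={motif})", w.sequence):
                counts[m.start()] += 1
    return counts / len(windows)


def random_windows(n, flank, seed, alphabet="ACGT"):
    rng = np.random.default_rng(seed)
    return [
        FlankWindow(f"w{i}", flank,
                    "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), 2 * flank)]))
        for i in range(n)
    ]


class TestAnchorAndFlanks:
    @pytest.mark.parametrize(
        "strand,start,end,expected",
        [("+", 10, 20, 10), ("-", 10, 20, 19), ("-", 0, 1, 0)],
    )
    def test_anchor_is_transcript_5prime_end(self, strand, start, end, expected):
        assert anchor_position(Site("c", start, end, "s", 0, strand)) == expected

    def test_plus_strand_window_is_direct_slice(self, small_genome):
        sites = make_sites((150, 160, "+"))
        windows, n_dropped = extract_flanks(sites, small_genome, flank=5)
        assert n_dropped == 0
        assert windows[0].sequence == small_genome["chr1"][145:155]

    def test_minus_strand_window_per_base_lookup(self, small_genome):
        # brute-force oracle: offset o reads complement(genome[anchor - o])
        sites = make_sites((100, 110, "-"))
        anchor = 109
        windows, _ = extract_flanks(sites, small_genome, flank=5)
        seq = windows[0].sequence
        assert seq == reverse_complement(small_genome["chr1"][105:115])
        comp = dict(zip("ACGTN", "TGCAN"))
        for o in range(-5, 5):
            assert seq[o + 5] == comp[small_genome["chr1"][anchor - o]]

    def test_out_of_bounds_sites_dropped_and_counted(self, small_genome):
        sites = make_sites((3, 10, "+"), (150, 160, "+"))
        windows, n_dropped = extract_flanks(sites, small_genome, flank=5)
        assert n_dropped == 1
        assert len(windows) == 1

    def test_all_sites_dropped_is_an_error(self, small_genome):
        sites = make_sites((0, 4, "+"))
        with pytest.raises(ValueError, match="all sites dropped"):
            extract_flanks(sites, small_genome, flank=50)


class TestScan:
    def test_overlapping_motifs_reported_at_start_offsets(self):
        window = FlankWindow("w", 4, "AAATAAAC")
        hits = scan_motif_starts(window, DEFAULT_PAS_MOTIFS)
        assert hits == [(-4, "AAATAA"), (-3, "AATAAA")]

    def test_dense_overlap_counts_every_occurrence(self):
        window = FlankWindow("w", 5, "AATAAATAAA")
        hits = scan_motif_starts(window, DEFAULT_PAS_MOTIFS)
        assert hits == [
            (-5, "AATAAA"), (-4, "ATAAAT"), (-2, "AAATAA"), (-1, "AATAAA"),
        ]

    def test_no_a_means_no_match(self):
        window = FlankWindow("w", 6, "C" * 12)
        assert scan_motif_starts(window) == []

    def test_n_in_candidate_span_blocks_match(self):
        window = FlankWindow("w", 4, "AANAAATC")
        assert scan_motif_starts(window) == []

    def test_motifset_rejects_duplicates_and_short_motifs(self):
        with pytest.raises(ValueError, match="duplicate"):
            MotifSet(["AATAAA", "AATAAA"])
        with pytest.raises(ValueError, match="shorter"):
            MotifSet(["ACG"])


class TestAggregate:
    def test_density_is_matches_per_window(self):
        # one AATAAA planted at offset +2 in each of two otherwise-C windows
        seq = "C" * 12 + "AATAAA" + "C" * 2
        windows = [FlankWindow("a", 10, seq), FlankWindow("b", 10, seq)]
        prof = aggregate_density(windows, ["AATAAA"])
        assert prof.density_at(2) == 1.0
        assert prof.raw_density.sum() == 1.0

    def test_all_n_windows_give_zero_profile(self):
        windows = [FlankWindow("a", 10, "N" * 20)]
        prof = aggregate_density(windows)
        assert prof.raw_density.sum() == 0.0

    def test_empty_window_list_is_an_error(self):
        with pytest.raises(ValueError, match="no windows"):
            aggregate_density([])

    def test_matches_naive_rescan_oracle_exactly(self):
        windows = random_windows(200, 30, seed=11, alphabet="ACGTN")
        prof = aggregate_density(windows, DEFAULT_PAS_MOTIFS)
        expected = naive_density(windows, DEFAULT_PAS_MOTIFS)
        assert np.array_equal(prof.raw_density, expected)

    @given(st.integers(0, 10_000))
    def test_mass_conservation_total_is_integer_match_count(self, seed):
        windows = random_windows(20, 15, seed=seed, alphabet="AT")
        prof = aggregate_density(windows)
        total = prof.raw_density.sum() * prof.n_sites
        assert abs(total - round(total)) < 1e-9
        assert round(total) == prof.meta["total_matches"]


class TestSmoothing:
    def _unit_profile(self, flank=20, at=0):
        raw = np.zeros(2 * flank)
        raw[at + flank] = 1.0
        from apakit import PositionalProfile

        return PositionalProfile(np.arange(-flank, flank), raw, n_sites=1)

    def test_constant_profile_unchanged(self):
        from apakit import PositionalProfile

        prof = PositionalProfile(np.arange(-5, 5), np.full(10, 0.3), n_sites=1)
        out = smooth_profile(prof, 5)
        np.testing.assert_allclose(out.smoothed_density, 0.3)

    def test_unit_mass_spreads_to_w_neighbours(self):
        out = smooth_profile(self._unit_profile(), 11)
        idx = np.abs(out.offsets) <= 5
        np.testing.assert_allclose(out.smoothed_density[idx], 1 / 11)
        assert out.smoothed_density[~idx].sum() == 0.0

    def test_w1_is_identity_and_raw_unchanged(self):
        prof = self._unit_profile()
        out = smooth_profile(prof, 1)
        assert np.array_equal(out.smoothed_density, prof.raw_density)
        assert np.array_equal(out.raw_density, prof.raw_density)

    def test_edges_truncate_to_existing_offsets(self):
        out = smooth_profile(self._unit_profile(flank=3, at=-3), 3)
        # leftmost offset: mean over the two offsets that exist
        assert out.smoothed_density[0] == pytest.approx(1 / 2)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            smooth_profile(self._unit_profile(), 4)


class TestPermutationNull:
    def test_same_seed_gives_identical_z(self):
        windows = random_windows(50, 20, seed=3)
        a = permutation_z(windows, n_perm=100, seed=9)
        b = permutation_z(windows, n_perm=100, seed=9)
        assert np.array_equal(a.z, b.z)

    def test_too_few_permutations_rejected(self):
        windows = random_windows(5, 20, seed=3)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_z(windows, n_perm=50, seed=0)

    def test_unplanted_background_has_quiet_z(self):
        windows = random_windows(300, 50, seed=21)
        prof = permutation_z(windows, n_perm=200, seed=5)
        assert np.mean(np.abs(prof.z) < 3) >= 0.95


class TestStrandMirror:
    def test_mirrored_genome_reproduces_profile_bit_identically(self):
        rng = np.random.default_rng(13)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3000)])
        genome = GenomeSequence()
        genome["c"] = seq
        L = len(seq)
        records = []
        for i in range(80):
            start = int(rng.integers(120, L - 140))
            end = start + 15
            strand = "+" if rng.random() < 0.5 else "-"
            records.append(Site("c", start, end, f"s{i}", 0.0, strand))
        sites = SiteSet(records)

        mirrored = GenomeSequence()
        mirrored["c"] = reverse_complement(seq)
        flipped = SiteSet(
            [
                Site("c", L - s.end, L - s.start, s.name, s.score,
                     "-" if s.strand == "+" else "+")
                for s in records
            ]
        )
        prof = aggregate_density(extract_flanks(sites, genome, 100)[0])
        prof_m = aggregate_density(extract_flanks(flipped, mirrored, 100)[0])
        assert np.array_equal(prof.raw_density, prof_m.raw_density)


class TestCrossSiteProfile:
    def test_shifted_queries_peak_exactly_at_shift(self):
        anchors = make_sites((1000, 1010, "+"), (5000, 5010, "+"), (9000, 9010, "-"))
        from apakit.synthetic import shift_sites

        queries = shift_sites(anchors, 7)
        prof = cross_site_profile(anchors, queries, flank=100)
        assert prof.density_at(7) == 1.0
        assert prof.raw_density.sum() == 1.0

    def test_identical_queries_peak_at_zero(self):
        anchors = make_sites((1000, 1010, "+"), (5000, 5010, "-"))
        prof = cross_site_profile(anchors, anchors, flank=50)
        assert prof.density_at(0) == 1.0
        assert prof.raw_density.sum() == 1.0

    def test_opposite_strand_queries_never_counted(self):
        anchors = make_sites((1000, 1010, "+"))
        queries = make_sites((1005, 1015, "-"))
        prof = cross_site_profile(anchors, queries, flank=50)
        assert prof.raw_density.sum() == 0.0

    def test_empty_set_is_an_error(self):
        anchors = make_sites((1000, 1010, "+"))
        with pytest.raises(ValueError, match="non-empty"):
            cross_site_profile(anchors, SiteSet([]), flank=50)


def test_planted_offset_recovered_through_full_stack():
    from apakit import synthetic

    genome = synthetic.gen_genome(60_000, seed=1)
    sites = synthetic.gen_sites(genome, 300, flank=100, site_len=15, seed=2)
    planted, truth = synthetic.plant_pas(
        genome, sites, offset_mean=20, offset_sd=5, planting_prob=0.5, seed=3
    )
    windows, _ = extract_flanks(sites, planted, 100)
    prof = smooth_profile(aggregate_density(windows), 11)
    assert abs(prof.argmax_offset() - 20) <= 3
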
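import numpy as np
import pytest

from satkit import satfind
from satkit.satfind import DetectionParams, SeedCluster
from satkit.seqio import SequenceRecord
from satkit.simulate import PlantSpec, random_genome, random_unit, simulate_genome
from tests import _oracles

P = DetectionParams()


def rec(seq, rid="r"):
    return SequenceRecord(rid, "", seq)


def revcomp_record(record):
    return SequenceRecord(record.id, record.description, _oracles.revcomp(record.seq))


class TestEnumerateSeedKmers:
    def test_homopolymer_seed_excluded(self):
        assert satfind.enumerate_seed_kmers(rec("A" * 30), P) == {}

    def test_dinucleotide_seed_excluded(self):
        seq = "AC" * 15
        assert "ACACACACAC" not in satfind.enumerate_seed_kmers(rec(seq), P)

    def test_perfect_array_rotations_indexed(self):
        u = "ACGGTTCAAG"
        index = satfind.enumerate_seed_kmers(rec(u * 6), P)
        for r in range(10):
            assert u[r:] + u[:r] in index
        assert index[u] == [1, 11, 21, 31, 41, 51]

    def test_matches_bruteforce_index(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        assert satfind.enumerate_seed_kmers(rec(seq), P) == _oracles.kmer_index(seq, 10)

    def test_fast_path_agrees_with_enumeration(self, rng):
        u = random_unit(rng, 17)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 400)) + u * 5 + "N" * 5 + u * 4
        full = satfind.enumerate_seed_kmers(rec(seq), P)
        want = {k: v for k, v in full.items() if len(v) >= P.min_copies}
        got = {k: list(v) for k, v in satfind._frequent_seed_index(seq, P).items()}
        assert got == want


class TestDetectSeedClusters:
    def test_four_in_window_forms_cluster(self):
        clusters = satfind.detect_seed_clusters({"ACGGTTCAAG": [1, 11, 21, 31]}, P)
        assert len(clusters) == 1
        assert clusters[0].positions == (1, 11, 21, 31)

    def test_three_occurrences_insufficient(self):
        assert satfind.detect_seed_clusters({"ACGGTTCAAG": [1, 11, 21]}, P) == []

    def test_distant_groups_split_into_two_clusters(self):
        pos = [1, 11, 21, 31, 5001, 5011, 5021, 5031]
        clusters = satfind.detect_seed_clusters({"ACGGTTCAAG": pos}, P)
        assert [c.positions for c in clusters] == [(1, 11, 21, 31),
                                                   (5001, 5011, 5021, 5031)]

    def test_windowed_runs_match_bruteforce_count(self, rng):
        """Every window of min_copies consecutive occurrences spans <= window."""
        pos = sorted(set(int(x) for x in rng.integers(1, 4000, 25)))
        clusters = satfind.detect_seed_clusters({"ACGGTTCAAG": pos}, P)
        for c in clusters:
            q = c.positions
            assert len(q) >= P.min_copies
            for i in range(len(q) - P.min_copies + 1):
                assert q[i + P.min_copies - 1] - q[i] <= P.window - P.k

    def test_overlapping_rotation_clusters_merge(self, rng):
        u = random_unit(rng, 20)
        record, _ = simulate_genome(3000, 0.5, [PlantSpec(u, 6, position=1000)], seed=3)
        index = satfind._frequent_seed_index(record.seq, P)
        assert len(index) >= 10  # many rotations seed independently
        clusters = satfind.detect_seed_clusters(index, P)
        assert len(clusters) == 1


class TestEstimatePeriod:
    @pytest.mark.parametrize("positions,expected", [
        ((1, 11, 21, 31), 10),
        ((1, 11, 22, 32, 42), 10),        # mode of {10, 11, 10, 10}
        ((1, 401, 801, 1201), None),      # all gaps beyond max_period
    ])
    def test_mode_of_spacings(self, positions, expected):
        cluster = SeedCluster("ACGGTTCAAG", positions)
        assert satfind.estimate_period(cluster, P) == expected

    def test_tie_broken_toward_smaller(self):
        cluster = SeedCluster("ACGGTTCAAG", (1, 13, 23, 35, 45))  # {12,10,12,10}
        assert satfind.estimate_period(cluster, P) == 10


def _delimit(record, params=P):
    index = satfind._frequent_seed_index(record.seq, params)
    clusters = satfind.detect_seed_clusters(index, params)
    assert clusters, "no seed cluster found"
    period = satfind.estimate_period(clusters[0], params)
    return satfind.delimit_and_segment(record, clusters[0], period, params)


class TestDelimitAndSegment:
    def test_perfect_array_matches_bruteforce_span(self, rng):
        u = random_unit(rng, 10)
        bg = random_genome(300, 0.5, seed=11).seq
        seq = bg[:100] + u * 6 + bg[100:]
        arrays = _oracles.perfect_tandem_arrays(seq)
        assert len(arrays) == 1
        start, end, period = arrays[0]
        ra = _delimit(rec(seq))
        assert (ra.start, ra.end) == (start, end)
        assert ra.unit_lengths() == [10] * ((end - start + 1) // 10)

    def test_one_substitution_keeps_boundaries(self, rng):
        u = random_unit(rng, 10)
        mutated = u[:4] + ("A" if u[4] != "A" else "C") + u[5:]
        bg = random_genome(300, 0.5, seed=11).seq
        clean = bg[:100] + u * 6 + bg[100:]
        noisy = bg[:100] + u * 2 + mutated + u * 3 + bg[100:]
        want = _oracles.perfect_tandem_arrays(clean)[0]
        ra = _delimit(rec(noisy))
        assert (ra.start, ra.end) == (want[0], want[1])
        assert len(ra.unit_lengths()) == 6

    def test_array_at_sequence_start_clamped(self, rng):
        u = random_unit(rng, 10)
        seq = u * 4 + random_genome(200, 0.5, seed=5).seq
        ra = _delimit(rec(seq))
        assert ra.start == 1
        assert len(ra.unit_lengths()) >= 4

    def test_internal_indel_is_bridged_not_split(self, rng):
        u = random_unit(rng, 20)
        # one copy carries a 1-nt insertion: register shifts mid-array
        bg = random_genome(500, 0.5, seed=9).seq
        seq = bg[:200] + u * 3 + (u[:8] + "A" + u[8:]) + u * 3 + bg[200:]
        ra = _delimit(rec(seq))
        assert ra.start <= 203
        assert ra.end - ra.start + 1 >= 7 * 20


class TestRegularityFilter:
    @pytest.mark.parametrize("lengths,accepted,ni,modal", [
        ([10, 10, 10, 12, 10], True, 4, 10),
        ([10, 12, 14, 16, 18], False, 1, 10),
        ([10, 10, 12, 12], False, 2, 10),   # tie -> smaller modal, 0.5 < 0.6
    ])
    def test_modal_length_rule(self, lengths, accepted, ni, modal):
        bounds = [1]
        for l in lengths[:-1]:
            bounds.append(bounds[-1] + l)
        ra = satfind.RawArray("r", 1, sum(lengths), 10, bounds)
        got_acc, got_ni, got_modal = satfind.regularity_filter(ra, P)
        assert (got_acc, got_ni, got_modal) == (accepted, ni, modal)


class TestScoreRepeats:
    def test_five_identical_units_score_one(self, rng):
        unit = random_unit(rng, 37)
        assert satfind.score_repeats([unit] * 5) == 1.0

    def test_one_mismatch_in_ten_between_two_units(self):
        a = "ACGGTTCAAG"
        b = "ACGGTTCAAT"
        assert satfind.score_repeats([a, b]) == pytest.approx(0.95)

    def test_order_invariant(self, rng):
        units = [random_unit(rng, 15) for _ in range(2)] * 2
        assert satfind.score_repeats(units) == satfind.score_repeats(units[::-1])

    def test_single_unit_rejected(self):
        with pytest.raises(ValueError):
            satfind.score_repeats(["ACGTACGTAC"])


class TestFindSatellites:
    def test_random_background_yields_nothing(self):
        for seed in range(20):
            record = random_genome(5000, 0.5, seed=seed)
            calls = satfind.find_satellites(record)
            oracle = _oracles.perfect_tandem_arrays(record.seq)
            # any hit must correspond to a genuine tandem structure
            assert len(calls) <= len(oracle)
            assert calls == []

    def test_planted_perfect_array_recovered_exactly(self, rng):
        u = random_unit(rng, 21)
        record, truths = simulate_genome(5000, 0.5, [PlantSpec(u, 8, position=2000)], seed=7)
        calls = satfind.find_satellites(record)
        assert len(calls) == 1
        c = calls[0]
        assert (c.period, c.n_copies, c.score) == (21, 8, 1.0)
        assert c.ni >= 7  # a chance lag-21 match at an edge may pad one unit
        assert abs(c.start - truths[0].start) <= 21
        assert abs(c.end - truths[0].end) <= 21

    def test_two_loci_of_same_unit_give_two_calls(self, rng):
        u = random_unit(rng, 21)
        record, _ = simulate_genome(
            8000, 0.5, [PlantSpec(u, 6, position=1000), PlantSpec(u, 6, position=4000)],
            seed=13)
        calls = satfind.find_satellites(record)
        assert len(calls) == 2

    def test_reverse_complement_symmetry(self):
        for seed in range(6):
            srng = np.random.default_rng(seed + 100)
            plants = [PlantSpec(random_unit(srng, int(srng.integers(12, 60))),
                                int(srng.integers(4, 12)),
                                sub_rate=float(srng.uniform(0, 0.02)))
                      for _ in range(3)]
            record, _ = simulate_genome(20000, 0.45, plants, seed=seed)
            fwd = satfind.find_satellites(record)
            bwd = satfind.find_satellites(revcomp_record(record))
            L = len(record.seq)
            assert len(fwd) == len(bwd)
            mirrored = sorted((L - c.end + 1, L - c.start + 1) for c in fwd)
            assert mirrored == sorted((c.start, c.end) for c in bwd)

    def test_monotonicity_in_min_copies_and_regularity(self):
        srng = np.random.default_rng(77)
        plants = [PlantSpec(random_unit(srng, int(srng.integers(12, 40))),
                            int(srng.integers(4, 10)),
                            sub_rate=0.02, indel_rate=0.1) for _ in range(6)]
        record, _ = simulate_genome(30000, 0.4, plants, seed=77)
        base = len(satfind.find_satellites(record))
        stricter_copies = len(satfind.find_satellites(
            record, DetectionParams(min_copies=6)))
        stricter_frac = len(satfind.find_satellites(
            record, DetectionParams(min_regular_frac=0.9)))
        assert stricter_copies <= base
        assert stricter_frac <= base

    def test_emitted_calls_satisfy_invariants(self):
        for seed in range(4):
            srng = np.random.default_rng(seed + 500)
            plants = [PlantSpec(random_unit(srng, int(srng.integers(12, 80))),
                                int(srng.integers(4, 15)),
                                sub_rate=float(srng.uniform(0, 0.03)),
                                indel_rate=float(srng.uniform(0, 0.05)))
                      for _ in range(4)]
            record, _ = simulate_genome(25000, 0.5, plants, seed=seed)
            for c in satfind.find_satellites(record):
                c.validate(replicon_length=len(record.seq), max_period=P.max_period)
                assert c.sequence == record.seq[c.start - 1:c.end]
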
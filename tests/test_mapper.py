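"""Core mapping algorithm: seeding, refinement, merging, step-down loop."""

import numpy as np
import pytest

from fanseq.mapper import (
    Candidate,
    MapParams,
    extract_seeds,
    find_hotspots,
    iterative_map,
    map_read_stage,
    merge_best,
    refine_banded,
    refine_hamming,
    run_parallel,
)
from fanseq.preprocess import Read
from fanseq.refindex import build_seed_index, encode_read, segment_reference
from fanseq.simulate import random_genome, revcomp, simulate_reads


def seeds_offsets(bases, n):
    return [off for off, _ in extract_seeds(encode_read(bases), n)]


def semi_global_edit_oracle(read, window):
    """Full unbanded DP: minimal unit-cost edit distance of the read aligned
    anywhere inside the window (leading/trailing window bases free)."""
    m, w = len(read), len(window)
    prev = [0] * (w + 1)
    for i in range(1, m + 1):
        cur = [i] + [0] * w
        for j in range(1, w + 1):
            sub = prev[j - 1] + (read[i - 1] != window[j - 1])
            cur[j] = min(sub, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev)


def brute_force_best_hamming(read, seq):
    """Scan every window of both strands for the minimal mismatch count."""
    m = len(read)
    rc = revcomp(read)
    best = (m + 1, None)
    for p in range(len(seq) - m + 1):
        win = seq[p : p + m]
        for strand, r in (("+", read), ("-", rc)):
            mm = sum(a != b for a, b in zip(r, win))
            if mm < best[0]:
                best = (mm, (p, strand))
    return best


class TestExtractSeeds:
    def test_75nt_read_14nt_seeds(self):
        assert seeds_offsets("A" * 75, 14) == [0, 14, 28, 42, 56, 61]

    def test_exact_tiling_no_end_anchor(self):
        assert seeds_offsets("A" * 28, 14) == [0, 14]

    def test_too_short(self):
        assert extract_seeds(encode_read("A" * 13), 14) == []

    def test_ambiguous_seed_dropped(self):
        bases = "ACGTACGTACGTAC" + "N" + "CGTACGTACGTAC"  # 28 nt, N at 14
        offs = seeds_offsets(bases, 14)
        assert offs == [0]


class TestFindHotspots:
    def test_exact_copy_all_seeds_agree(self, small_genome, small_segments):
        _, seq = small_genome
        idx = build_seed_index(small_segments[0], 14)
        read = Read("r", seq[100:175])
        spots = find_hotspots(read, idx, 14)
        assert spots[0].cand_start == 100 and spots[0].strand == "+"
        assert spots[0].support == 6

    def test_one_substitution_dirties_one_tile(self, small_genome, small_segments):
        _, seq = small_genome
        idx = build_seed_index(small_segments[0], 14)
        bases = list(seq[100:175])
        bases[20] = {"A": "C"}.get(bases[20], "A")  # position 20 sits in tile 14..27
        spots = find_hotspots(Read("r", "".join(bases)), idx, 14)
        top = spots[0]
        assert (top.cand_start, top.strand, top.support) == (100, "+", 5)

    def test_reverse_complement_read(self, small_genome, small_segments):
        _, seq = small_genome
        idx = build_seed_index(small_segments[0], 14)
        read = Read("r", revcomp(seq[40:115]))
        spots = find_hotspots(read, idx, 14)
        assert spots[0].cand_start == 40 and spots[0].strand == "-"

    def test_negative_candidate_start_discarded(self):
        seg = segment_reference({"s": "ACGTACGTACGTACGT"}, 100, 0)[0]
        idx = build_seed_index(seg, 4)
        # read whose offset-4 seed matches position 0 implies cand_start -4
        read = Read("r", "TTTTACGT")
        spots = find_hotspots(read, idx, 4)
        assert all(h.cand_start >= 0 for h in spots)


class TestRefineHamming:
    def test_direct_count_and_threshold(self):
        seg = segment_reference({"s": "ACGAACGT"}, 100, 0)[0]
        read = encode_read("ACGT")
        assert refine_hamming(read, seg, 0, 1) == 1
        assert refine_hamming(read, seg, 0, 0) is None

    def test_window_out_of_bounds_rejected(self):
        seg = segment_reference({"s": "ACGT"}, 100, 0)[0]
        read = encode_read("ACGTA")
        assert refine_hamming(read, seg, 0, 5) is None
        assert refine_hamming(encode_read("ACG"), seg, 2, 5) is None

    def test_reference_n_counts_as_mismatch(self):
        seg = segment_reference({"s": "ACNT"}, 100, 0)[0]
        assert refine_hamming(encode_read("ACGT"), seg, 0, 7) == 1
        assert refine_hamming(encode_read("ACNT"), seg, 0, 7) == 1  # read N != ref N

    def test_exactly_seven_substitutions(self, small_genome, rng):
        _, seq = small_genome
        seg = segment_reference({"x": seq}, 10**8, 0)[0]
        bases = list(seq[500:575])
        pos = rng.choice(75, size=7, replace=False)
        for p in pos:
            bases[p] = "ACGT"[("ACGT".index(bases[p]) + 1) % 4]
        assert refine_hamming(encode_read("".join(bases)), seg, 500, 7) == 7

    def test_matches_brute_force_scan(self, rng):
        name, seq = random_genome(300, seed=21)
        seg = segment_reference({name: seq}, 10**6, 0)[0]
        for _ in range(50):
            p = int(rng.integers(0, 300 - 20))
            bases = list(seq[p : p + 20])
            for q in rng.choice(20, size=int(rng.integers(0, 4)), replace=False):
                bases[q] = "ACGT"[int(rng.integers(0, 4))]
            read = "".join(bases)
            mm_oracle, _ = brute_force_best_hamming(read, seq)
            mms = [
                refine_hamming(encode_read(read), seg, c, 20)
                for c in range(0, 300 - 20 + 1)
            ]
            rc_mms = [
                refine_hamming(encode_read(revcomp(read)), seg, c, 20)
                for c in range(0, 300 - 20 + 1)
            ]
            assert min(m for m in mms + rc_mms if m is not None) == mm_oracle


class TestRefineBanded:
    def test_single_insertion_worked_example(self):
        seg = segment_reference({"s": "TTTTAACGGTTTTTT"}, 100, 0)[0]
        res = refine_banded(encode_read("AACCGGTT"), seg, 4, 1, 1)
        assert res == (0, 1, "3M1I4M", 4)

    def test_identity_any_allowance(self):
        seg = segment_reference({"s": "GGGACGTACGTGGG"}, 100, 0)[0]
        res = refine_banded(encode_read("ACGTACGT"), seg, 3, 5, 2)
        assert res == (0, 0, "8M", 3)

    def test_two_indels_rejected_with_allowance_one(self):
        # read needs two separate 1-nt insertions relative to the reference
        seg = segment_reference({"s": "TTTACGTACGTACGTTT"}, 100, 0)[0]
        read = "ACGGTACGTAACGT"  # ACGTACGTACGT with G and A inserted
        assert semi_global_edit_oracle(read, "TTTACGTACGTACGTTT") == 2
        res = refine_banded(encode_read(read), seg, 3, 2, 1)
        assert res is None

    def test_deletion_detected(self):
        seg = segment_reference({"s": "TTTACGTACGTTT"}, 100, 0)[0]
        res = refine_banded(encode_read("ACGACGT"), seg, 3, 1, 1)  # T deleted
        mm, ind, cigar, pos = res
        assert (mm, ind) == (0, 1)
        assert cigar.count("D") == 1 and pos == 3

    def test_wide_band_equals_full_dp_oracle(self, rng):
        """With the band at least the read length, the banded DP must find
        the same minimal error count as an unbanded semi-global DP."""
        for _ in range(300):
            m = int(rng.integers(8, 51))
            read = "".join("ACGT"[i] for i in rng.integers(0, 4, m))
            window = "".join("ACGT"[i] for i in rng.integers(0, 4, m + 20))
            seq = "AAAA" + window + "AAAA"
            seg = segment_reference({"s": seq}, 10**6, 0)[0]
            # band (= indel allowance) covering the whole sequence, so the
            # banded DP must reduce to an unbanded semi-global alignment
            res = refine_banded(encode_read(read), seg, 14, 10**6, len(seq))
            oracle = semi_global_edit_oracle(read, seq)
            assert res is not None
            mm, ind, cigar, pos = res
            assert mm + ind == oracle

    def test_indel_shifted_read_recovers_truth(self, small_genome):
        _, seq = small_genome
        seg = segment_reference({"x": seq}, 10**8, 0)[0]
        window = seq[1000:1075]
        read = window[:30] + window[31:]  # delete base 30
        res = refine_banded(encode_read(read), seg, 1000, 7, 1)
        mm, ind, cigar, pos = res
        assert (mm, ind, pos) == (0, 1, 1000)
        assert "1D" in cigar


class TestMapReadStageAndMerge:
    def test_unique_exact_read(self, small_genome, small_segments):
        _, seq = small_genome
        params = MapParams(E=7, I=0, S=12)
        idx = [(s, build_seed_index(s, 14)) for s in small_segments]
        cands = map_read_stage(Read("r", seq[200:275]), idx, params, 14)
        assert len(cands) == 1
        assert cands[0].pos == 200 and cands[0].mismatches == 0
        res = merge_best(cands, "r", 14)
        assert res.unique and res.stage == 14

    def test_duplicated_window_gives_tied_candidates(self):
        core = random_genome(40, seed=33)[1]
        seq = core + random_genome(30, seed=34)[1] + core
        seg = segment_reference({"s": seq}, 10**6, 0)
        params = MapParams(E=2, I=0, S=4, initial_seed=8)
        idx = [(s, build_seed_index(s, 8)) for s in seg]
        cands = map_read_stage(Read("r", core), idx, params, 8)
        assert sorted(c.pos for c in cands) == [0, 70]
        res = merge_best(cands, "r", 8)
        assert res.pos == 0 and not res.unique

    def test_only_minimal_error_locations_returned(self, rng):
        # plant a window and a 1-mismatch paralog; a 1-error read must map to
        # wherever brute force says the minimum is, excluding 2-error spots
        base = random_genome(60, seed=44)[1]
        paralog = list(base)
        paralog[30] = "A" if base[30] != "A" else "C"
        seq = base + "TT" + "".join(paralog)
        seg = segment_reference({"s": seq}, 10**6, 0)
        read_b = list(base)
        read_b[10] = "A" if base[10] != "A" else "C"
        read = "".join(read_b)
        params = MapParams(E=5, I=0, S=6, initial_seed=6)
        idx = [(s, build_seed_index(s, 6)) for s in seg]
        cands = map_read_stage(Read("r", read), idx, params, 6)
        mm_oracle, (p_oracle, strand) = brute_force_best_hamming(read, seq)
        assert mm_oracle == 1
        assert all(c.mismatches == 1 for c in cands)
        assert (p_oracle, strand) in {(c.pos, c.strand) for c in cands}

    def test_merge_dedupes_overlap_duplicates(self):
        c = Candidate("s", 100, "+", 1, 0, "75M")
        res = merge_best([c, c], "r", 14)
        assert res.unique

    def test_merge_tie_rule_and_empty(self):
        a = Candidate("s", 4, "+", 1, 0, "10M")
        b = Candidate("s", 0, "+", 1, 0, "10M")
        res = merge_best([a, b], "r", 14)
        assert res.pos == 0 and not res.unique
        plus = Candidate("s", 7, "+", 1, 0, "10M")
        minus = Candidate("s", 7, "-", 1, 0, "10M")
        assert merge_best([minus, plus], "r", 14).strand == "+"
        assert merge_best([], "r", 14) is None


class TestIterativeMap:
    def test_zero_error_read_maps_at_initial_stage(self, small_genome):
        name, seq = small_genome
        reads = [Read("r", seq[300:375])]
        res, tallies = iterative_map(reads, {name: seq}, MapParams())
        assert res[0].pos == 300 and res[0].stage == 14
        assert tallies[0].mapped == 1

    def test_step_down_rescues_read_dirty_at_14(self, small_genome):
        # 26-nt read, substitutions at positions 13 and 25: both 14-nt seeds
        # (offsets 0, 12) are dirty, but the 12-nt seed at offset 0 is clean
        name, seq = small_genome
        bases = list(seq[1000:1026])
        for p in (13, 25):
            bases[p] = "ACGT"[("ACGT".index(bases[p]) + 2) % 4]
        reads = [Read("r", "".join(bases))]
        res, tallies = iterative_map(
            reads, {name: seq}, MapParams(E=2, I=0, S=12)
        )
        assert res[0] is not None
        assert res[0].pos == 1000 and res[0].stage == 12
        assert [t.seed_len for t in tallies] == [14, 12]
        assert tallies[0].mapped == 0 and tallies[1].mapped == 1

    def test_foreign_read_stays_unmapped(self, small_genome):
        name, seq = small_genome
        foreign = random_genome(75, seed=999, name="other")[1]
        res, _ = iterative_map(
            [Read("r", foreign)], {name: seq}, MapParams(E=3)
        )
        assert res[0] is None

    def test_short_read_deferred_to_matching_stage(self, small_genome):
        name, seq = small_genome
        reads = [Read("r", seq[50:63])]  # 13 nt: no 14-nt seed possible
        res, _ = iterative_map(reads, {name: seq}, MapParams(E=0, S=12))
        assert res[0] is not None and res[0].stage == 12

    def test_lowering_S_never_unmaps_or_moves_reads(self, small_genome):
        name, seq = small_genome
        reads, _ = simulate_reads((name, seq), 120, sub_rate=0.05, seed=5)
        res_hi, _ = iterative_map(reads, {name: seq}, MapParams(E=7, S=12))
        res_lo, _ = iterative_map(reads, {name: seq}, MapParams(E=7, S=8))
        n_hi = sum(r is not None for r in res_hi)
        n_lo = sum(r is not None for r in res_lo)
        assert n_lo >= n_hi
        for a, b in zip(res_hi, res_lo):
            if a is not None:
                assert (b.source_id, b.pos, b.strand) == (
                    a.source_id, a.pos, a.strand,
                )

    def test_empty_read_set(self, small_genome):
        name, seq = small_genome
        res, tallies = iterative_map([], {name: seq}, MapParams())
        assert res == [] and tallies == []


@pytest.fixture(scope="module")
def dataset():
    name, seq = random_genome(30_000, seed=77)
    reads, _ = simulate_reads((name, seq), 150, sub_rate=0.03, seed=78)
    return name, seq, reads


class TestDeterminismAndInvariance:
    @staticmethod
    def signature(results):
        return [
            None
            if r is None
            else (r.read_id, r.source_id, r.pos, r.strand, r.mismatches,
                  r.indels, r.cigar, r.unique, r.stage)
            for r in results
        ]

    def test_worker_count_invariance(self, dataset):
        name, seq, reads = dataset
        params = MapParams(E=7, S=12, segment_size=9_000)
        base, _ = iterative_map(reads, {name: seq}, params, workers=1)
        for w in (2, 4):
            res, _ = run_parallel(reads, {name: seq}, params, workers=w)
            assert self.signature(res) == self.signature(base)

    def test_segment_size_invariance(self, dataset):
        name, seq, reads = dataset
        sigs = []
        for size in (5_000, 12_000, 50_000_000):
            res, _ = iterative_map(
                reads, {name: seq}, MapParams(E=7, S=12, segment_size=size)
            )
            sigs.append(self.signature(res))
        assert sigs[0] == sigs[1] == sigs[2]

    def test_segment_size_invariance_with_indels(self, dataset):
        name, seq, _ = dataset
        reads, _ = simulate_reads(
            (name, seq), 60, sub_rate=0.02, indel_rate=0.004, seed=79
        )
        sigs = []
        for size in (5_000, 50_000_000):
            res, _ = iterative_map(
                reads, {name: seq}, MapParams(E=7, I=1, S=12, segment_size=size)
            )
            sigs.append(self.signature(res))
        assert sigs[0] == sigs[1]

    def test_batch_path_equals_per_read_path(self, dataset):
        name, seq, reads = dataset
        params = MapParams(E=7, S=12)
        segs = segment_reference({name: seq}, 50_000_000, 75)
        idx = [(s, build_seed_index(s, 14)) for s in segs]
        res, _ = iterative_map(reads, {name: seq}, params)
        for read, r in zip(reads[:50], res[:50]):
            cands = map_read_stage(read, idx, params, 14, {name: len(seq)})
            expect = merge_best(cands, read.read_id, 14)
            if r is not None and r.stage == 14:
                assert expect is not None
                assert (expect.pos, expect.strand, expect.unique) == (
                    r.pos, r.strand, r.unique,
                )
            else:
                assert expect is None


class TestPigeonholeGuarantee:
    @pytest.mark.parametrize("n", [4, 6])
    def test_true_position_always_candidate(self, n, rng):
        """For f <= floor(L/n)-1 substitutions, some tiling seed is clean, so
        the true location must appear among the refined candidates."""
        from itertools import combinations

        name, seq = random_genome(400, seed=55)
        segs = segment_reference({name: seq}, 10**6, 0)
        params = MapParams(E=30, I=0, S=n, initial_seed=n,
                           max_hotspots_refined=10**6)
        idx = [(s, build_seed_index(s, n)) for s in segs]
        for L in (n, 2 * n + 1, 3 * n + 2):
            f = L // n - 1
            if f == 0:
                continue
            start = 137
            window = seq[start : start + L]
            placements = list(combinations(range(L), f))
            if len(placements) > 400:
                sel = rng.choice(len(placements), size=400, replace=False)
                placements = [placements[i] for i in sel]
            for pos in placements:
                bases = list(window)
                for p in pos:
                    bases[p] = "ACGT"[("ACGT".index(bases[p]) + 1) % 4]
                cands = map_read_stage(Read("r", "".join(bases)), idx, params, n)
                assert any(
                    c.pos == start and c.strand == "+" for c in cands
                ), f"L={L} f={f} pos={pos}"
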
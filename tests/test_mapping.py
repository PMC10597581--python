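"""Mapper, best-reference selection, deduplication, and pileup tests with
simulator-truth and brute-force recount oracles."""

from collections import Counter

import numpy as np
import pytest

from paleomito.mapping import (
    MapParams,
    Pileup,
    ReferenceIndex,
    deduplicate,
    make_pileup,
    map_read,
    map_reads,
    select_best_reference,
)
from paleomito.seqs import QualityRead, random_genome, revcomp
from paleomito.sim import PanelConfig, ReadSimParams, simulate_panel, simulate_reads


def make_read(seq, read_id="r", qual=37):
    return QualityRead(read_id, seq, np.full(len(seq), qual))


class TestMapRead:
    def test_exact_substring_maps_to_position(self, genome):
        index = ReferenceIndex("ref", genome)
        read = make_read(genome[1000:1050])
        m = map_read(read, index)
        assert m.ref_start == 1000 and m.edit_distance == 0
        assert m.strand == "+" and m.unique_best

    def test_reverse_strand(self, genome):
        index = ReferenceIndex("ref", genome)
        read = make_read(revcomp(genome[500:560]))
        m = map_read(read, index)
        assert m.ref_start == 500 and m.strand == "-" and m.edit_distance == 0

    def test_origin_wrapping_read(self, genome):
        index = ReferenceIndex("ref", genome)
        read = make_read(genome[-20:] + genome[:30])
        m = map_read(read, index)
        assert m.ref_start == len(genome) - 20
        assert m.edit_distance == 0
        assert m.wraps and m.ref_end == len(genome) + 30

    def test_mismatch_fraction_gate(self, genome):
        index = ReferenceIndex("ref", genome)
        seq = list(genome[300:350])
        for pos in (20, 25, 30, 35, 40, 45):  # 6/50 = 12% > 10%
            seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        assert map_read(make_read("".join(seq)), index) is None

    def test_ambiguous_read_unmapped(self, genome):
        index = ReferenceIndex("ref", genome)
        assert map_read(make_read("N" * 50), index) is None

    def test_simulated_reads_map_to_true_coordinates(self, genome):
        reads, truth = simulate_reads(genome, ReadSimParams(n_fragments=1000, seed=13))
        index = ReferenceIndex("ref", genome)
        correct = 0
        for read in reads:
            m = map_read(read, index)
            t = truth.reads[read.read_id]
            if m and m.ref_start == t.start and m.strand == t.strand:
                correct += 1
        assert correct >= 990

    def test_repeat_placement_not_unique(self):
        core = random_genome(1000, np.random.default_rng(5))
        genome = core + core  # exact duplication: every read has two placements
        index = ReferenceIndex("ref", genome)
        m = map_read(make_read(core[100:150]), index)
        assert m is not None and not m.unique_best


class TestSelectBestReference:
    def test_source_clade_selected(self):
        panel, refs = simulate_panel(
            PanelConfig(
                n_clades=2,
                samples_per_clade=2,
                genome_length=1500,
                planted_fixed_diffs_per_clade=25,  # 50 fixed diffs between A and B
                intra_clade_mut_rate=0.0,
                seed=21,
            )
        )
        reads, _ = simulate_reads(refs["clade1"], ReadSimParams(n_fragments=400, seed=22))
        result = select_best_reference(reads, refs)
        assert result.best_ref == "clade1"
        assert not result.tie

    def test_identical_references_tie_flagged(self, genome):
        reads, _ = simulate_reads(genome, ReadSimParams(n_fragments=100, seed=23))
        result = select_best_reference(reads, {"refB": genome, "refA": genome})
        assert result.best_ref == "refA"  # lexicographic tie-break
        assert result.tie

    def test_permutation_invariant(self, genome):
        other = random_genome(2000, np.random.default_rng(9))
        reads, _ = simulate_reads(genome, ReadSimParams(n_fragments=150, seed=24))
        r1 = select_best_reference(reads, {"a": genome, "b": other})
        r2 = select_best_reference(reads, {"b": other, "a": genome})
        assert r1.best_ref == r2.best_ref
        assert r1.table.sort_values("ref_id").to_dict() == r2.table.sort_values("ref_id").to_dict()

    def test_no_compatible_reference(self):
        reads = [make_read("ACGT" * 15)]
        refs = {
            "x": random_genome(1200, np.random.default_rng(1)),
            "y": random_genome(1200, np.random.default_rng(2)),
        }
        with pytest.raises(ValueError, match="no reference compatible"):
            select_best_reference(reads, refs)


class TestDeduplicate:
    def _mapped(self, genome, read, index=None):
        index = index or ReferenceIndex("ref", genome)
        return map_read(read, index)

    def test_identical_coordinates_collapse(self, genome):
        index = ReferenceIndex("ref", genome)
        a = map_read(make_read(genome[100:150], "a", qual=30), index)
        b = map_read(make_read(genome[100:150], "b", qual=37), index)
        kept, stats = deduplicate([a, b])
        assert [m.read_id for m in kept] == ["b"]  # higher quality wins
        assert stats.duplication_level == pytest.approx(0.5)

    def test_equal_quality_smaller_id_wins(self, genome):
        index = ReferenceIndex("ref", genome)
        a = map_read(make_read(genome[100:150], "zz"), index)
        b = map_read(make_read(genome[100:150], "aa"), index)
        kept, _ = deduplicate([a, b])
        assert kept[0].read_id == "aa"

    def test_same_start_different_end_both_kept(self, genome):
        index = ReferenceIndex("ref", genome)
        a = map_read(make_read(genome[100:150], "a"), index)
        b = map_read(make_read(genome[100:160], "b"), index)
        kept, stats = deduplicate([a, b])
        assert len(kept) == 2 and stats.duplication_level == 0.0

    def test_dup_rate_recovered(self, genome):
        rate = 0.25
        reads, truth = simulate_reads(
            genome, ReadSimParams(n_fragments=4000, dup_rate=rate, seed=31)
        )
        index = ReferenceIndex("ref", genome)
        mapped = map_reads(reads, index)
        kept, stats = deduplicate(mapped)
        sd = np.sqrt(rate * (1 - rate) / len(mapped))
        # coordinate collisions between independent fragments push the level
        # slightly above the duplicate fraction, never below it
        assert stats.duplication_level > rate - 3 * sd
        assert stats.duplication_level < rate + 0.05


class TestPileup:
    def test_two_nonoverlapping_reads(self):
        genome = random_genome(100, np.random.default_rng(3))
        index = ReferenceIndex("ref", genome, MapParams(k=11))
        reads = [make_read(genome[0:11], "a"), make_read(genome[50:61], "b")]
        mapped = [map_read(r, index) for r in reads]
        pileup = make_pileup(mapped, 100)
        assert int((pileup.depth == 1).sum()) == 22
        assert pileup.depth.sum() / 100 == pytest.approx(0.22)

    def test_mismatch_contributes_observed_base(self, genome):
        index = ReferenceIndex("ref", genome)
        pos = next(i for i in range(820, 840) if genome[i] == "C")
        seq = list(genome[800:850])
        seq[pos - 800] = "T"
        m = map_read(make_read("".join(seq)), index)
        pileup = make_pileup([m], len(genome))
        assert pileup.base_counts(pos)["T"] == 1
        assert pileup.base_counts(pos)["C"] == 0

    def test_totals_match_brute_force_recount(self, genome):
        reads, _ = simulate_reads(
            genome, ReadSimParams(n_fragments=300, seq_error=0.02, seed=41)
        )
        index = ReferenceIndex("ref", genome)
        mapped = map_reads(reads, index)
        pileup = make_pileup(mapped, len(genome))
        recount = {}
        for m in mapped:
            for rpos, op, base, _ in m.columns():
                if op == "M" and base in "ACGT":
                    recount[(rpos, base)] = recount.get((rpos, base), 0) + 1
        for (rpos, base), count in recount.items():
            assert pileup.base_counts(rpos)[base] == count
        assert pileup.depth.sum() == sum(recount.values())

    def test_conservation(self, genome):
        reads, _ = simulate_reads(genome, ReadSimParams(n_fragments=500, seed=43))
        index = ReferenceIndex("ref", genome)
        mapped = map_reads(reads, index)
        pileup = make_pileup(mapped, len(genome))
        assert pileup.depth.sum() == sum(len(m.seq) for m in mapped)

    def test_dedup_never_increases_depth(self, genome):
        reads, _ = simulate_reads(
            genome, ReadSimParams(n_fragments=1000, dup_rate=0.3, seed=44)
        )
        index = ReferenceIndex("ref", genome)
        mapped = map_reads(reads, index)
        before = make_pileup(mapped, len(genome)).depth
        kept, _ = deduplicate(mapped)
        after = make_pileup(kept, len(genome)).depth
        assert (after <= before).all()

    def test_out_of_range_position_errors(self):
        pileup = Pileup(100)
        with pytest.raises(IndexError):
            pileup.base_counts(100)
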
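"""Diagnostic-site discovery, agreement statistics, clade assignment, and
region extraction — checked against exhaustive per-column scan oracles."""

import numpy as np
import pytest

from paleomito.diagnostics import (
    CladePanel,
    assign_clade,
    extract_region,
    filter_missing,
    find_clade_fixed_query_divergent_sites,
    find_inter_clade_fixed_sites,
    map_sites_to_reference,
    p_distance,
    site_agreement,
)
from paleomito.mapping import ReferenceIndex, make_pileup, map_reads
from paleomito.sim import (
    PanelConfig,
    ReadSimParams,
    mix_contamination,
    simulate_panel,
    simulate_reads,
)
from tests.test_sim import brute_force_fixed_sites


def tiny_panel(rows, clades):
    return CladePanel(
        sequences=dict(rows),
        clades=dict(clades),
    )


class TestInterCladeFixedSites:
    def test_single_differing_column(self):
        panel = tiny_panel(
            [("a1", "AAAA"), ("a2", "AAAA"), ("b1", "AACA"), ("b2", "AACA")],
            [("a1", "A"), ("a2", "A"), ("b1", "B"), ("b2", "B")],
        )
        sites = find_inter_clade_fixed_sites(panel)
        assert [s.column for s in sites] == [2]
        assert dict(sites[0].clade_bases) == {"A": "A", "B": "C"}

    def test_polymorphic_clade_column_excluded(self):
        panel = tiny_panel(
            [("a1", "AAAA"), ("a2", "AACA"), ("b1", "AACA"), ("b2", "AACA")],
            [("a1", "A"), ("a2", "A"), ("b1", "B"), ("b2", "B")],
        )
        assert find_inter_clade_fixed_sites(panel) == []

    def test_missing_column_fraction_gate(self):
        panel = tiny_panel(
            [("a1", "ANAA"), ("a2", "ANAA"), ("b1", "ACCA"), ("b2", "ANCA")],
            [("a1", "A"), ("a2", "A"), ("b1", "B"), ("b2", "B")],
        )
        # column 1: 3/4 missing -> excluded even though clade B is fixed C
        sites = find_inter_clade_fixed_sites(panel, max_missing_frac=0.5)
        assert [s.column for s in sites] == [2]

    def test_all_missing_clade_contributes_no_constraint(self):
        panel = tiny_panel(
            [("a1", "AATA"), ("a2", "AATA"), ("b1", "AACA"), ("b2", "AACA"),
             ("c1", "AANA"), ("c2", "AA-A")],
            [("a1", "A"), ("a2", "A"), ("b1", "B"), ("b2", "B"),
             ("c1", "C"), ("c2", "C")],
        )
        sites = find_inter_clade_fixed_sites(panel, max_missing_frac=0.4)
        assert [s.column for s in sites] == [2]
        assert sites[0].base_of("C") is None

    def test_matches_brute_force_on_simulated_panels(self):
        for seed in range(5):
            panel, _ = simulate_panel(
                PanelConfig(
                    n_clades=3,
                    samples_per_clade=5,
                    genome_length=1200,
                    planted_fixed_diffs_per_clade=10,
                    intra_clade_mut_rate=0.002,
                    seed=seed,
                )
            )
            got = [s.column for s in find_inter_clade_fixed_sites(panel)]
            assert got == brute_force_fixed_sites(panel)
            assert got == sorted(got)


class TestQueryDivergentSites:
    def test_identical_query_empty(self, clean_panel):
        panel, refs = clean_panel
        sites = find_clade_fixed_query_divergent_sites(panel, "clade1", refs["clade1"])
        assert sites == []

    def test_engineered_private_substitutions(self, clean_panel):
        panel, refs = clean_panel
        query = list(refs["clade1"])
        targets = [5, 100, 400, 800, 1200]
        for pos in targets:
            query[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[query[pos]]
        sites = find_clade_fixed_query_divergent_sites(panel, "clade1", "".join(query))
        assert [s.column for s in sites] == targets
        for s in sites:
            assert s.focal_base == query[s.column]  # agreement anchored to query base

    def test_query_n_not_divergent(self, clean_panel):
        panel, refs = clean_panel
        query = "N" * 10 + refs["clade1"][10:]
        assert find_clade_fixed_query_divergent_sites(panel, "clade1", query) == []

    def test_matches_exhaustive_scan(self, noisy_panel):
        panel, refs = noisy_panel
        rng = np.random.default_rng(3)
        query = list(refs["clade2"])
        muts = rng.choice(len(query), size=8, replace=False)
        for pos in muts:
            query[pos] = {"A": "G", "C": "T", "G": "A", "T": "C"}[query[pos]]
        query = "".join(query)
        got = {s.column for s in find_clade_fixed_query_divergent_sites(panel, "clade2", query)}
        # oracle: per-column scan
        members = panel.members("clade2")
        want = set()
        for col in range(panel.n_columns):
            observed = {panel.sequences[s][col] for s in members} - set("N-")
            if len(observed) == 1 and query[col] not in ("N", "-") and query[col] != next(iter(observed)):
                want.add(col)
        assert got == want

    def test_unknown_clade_errors(self, clean_panel):
        panel, refs = clean_panel
        with pytest.raises(ValueError):
            find_clade_fixed_query_divergent_sites(panel, "nope", refs["clade1"])


class TestSiteAgreement:
    def _pileup_and_sites(self, fraction, seed=60, n_frag=3000):
        panel, refs = simulate_panel(
            PanelConfig(n_clades=2, samples_per_clade=3, genome_length=1500,
                        planted_fixed_diffs_per_clade=20,
                        intra_clade_mut_rate=0.0, seed=seed)
        )
        endo, et = simulate_reads(refs["clade1"], ReadSimParams(n_fragments=n_frag, seed=seed + 1), id_prefix="e")
        cont, ct = simulate_reads(refs["clade2"], ReadSimParams(n_fragments=n_frag, seed=seed + 2), id_prefix="c")
        pooled, _ = mix_contamination(endo, et, cont, ct, fraction, seed=seed + 3)
        index = ReferenceIndex("clade1", refs["clade1"])
        mapped = map_reads(pooled, index)
        pileup = make_pileup(mapped, 1500)
        sites = find_inter_clade_fixed_sites(panel, focal_clade="clade1")
        return pileup, sites

    def test_pure_reads_full_agreement(self):
        pileup, sites = self._pileup_and_sites(0.0)
        stats = site_agreement(pileup, sites)
        assert stats.median == 1.0 and stats.iqr == 0.0

    def test_contamination_shifts_median(self):
        f = 0.10
        pileup, sites = self._pileup_and_sites(f)
        stats = site_agreement(pileup, sites)
        depths = stats.per_site["depth"].to_numpy()
        sd = np.sqrt(f * (1 - f) / depths.mean())
        assert abs(stats.median - (1 - f)) < 3 * sd

    def test_median_iqr_match_sort_based_computation(self):
        pileup, sites = self._pileup_and_sites(0.2)
        stats = site_agreement(pileup, sites)
        vals = np.sort(stats.agreements)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        assert stats.median == pytest.approx(float(med))
        assert stats.iqr == pytest.approx(float(q3 - q1))

    def test_all_uncovered_errors(self):
        from paleomito.mapping import Pileup

        pileup, sites = self._pileup_and_sites(0.0, n_frag=100)
        empty = Pileup(1500)
        with pytest.raises(ValueError, match="covered"):
            site_agreement(empty, sites)

    def test_monotone_in_contamination(self):
        medians = []
        for f in (0.0, 0.1, 0.3):
            pileup, sites = self._pileup_and_sites(f, n_frag=2000)
            medians.append(site_agreement(pileup, sites).median)
        assert medians[0] > medians[1] > medians[2]


class TestAssignClade:
    def test_consensus_assigns_to_own_clade(self, noisy_panel):
        panel, refs = noisy_panel
        for clade, consensus in refs.items():
            result = assign_clade(consensus, panel)
            assert result.assigned_clade == clade

    def test_leave_one_out(self, noisy_panel):
        panel, _ = noisy_panel
        for sample, seq in panel.sequences.items():
            result = assign_clade(seq, panel, exclude=[sample])
            assert result.assigned_clade == panel.clades[sample], sample

    def test_all_n_query_unassignable(self, noisy_panel):
        panel, _ = noisy_panel
        with pytest.raises(ValueError, match="unassignable"):
            assign_clade("N" * panel.n_columns, panel)

    def test_vote_totals(self, clean_panel):
        panel, refs = clean_panel
        result = assign_clade(refs["clade2"], panel)
        # 30 planted sites: own 10 -> only clade2 votes; other clades' 20 ->
        # clade2 shares the root base with the third clade
        assert result.votes["clade2"] == 30
        assert result.n_usable_sites == 30


class TestRegionExtraction:
    def test_slice_lengths(self):
        aln = {f"s{i}": "ACGT" * 100 for i in range(5)}
        out = extract_region(aln, (10, 186))
        assert all(len(s) == 176 for s in out.values())

    def test_missing_threshold_boundary(self):
        base = "A" * 176
        aln = {
            "drop": "N" * 18 + base[18:],  # 18/176 = 10.2% > 10% -> removed
            "keep": "N" * 17 + base[17:],  # 17/176 = 9.7% -> kept
        }
        kept, removed = filter_missing(aln, max_frac=0.10)
        assert removed == ["drop"] and list(kept) == ["keep"]

    def test_extract_then_filter_order(self):
        # three sequences: s1 clean; s2 missing only inside the region; s3
        # missing only outside it.  Extract-then-filter must drop s2, keep s3.
        region = (4, 8)
        aln = {
            "s1": "AAAAACGTAAAA",
            "s2": "AAAANNNNAAAA",
            "s3": "NNNNACGTNNNN",
        }
        sub = extract_region(aln, region)
        kept, removed = filter_missing(sub, max_frac=0.10)
        assert set(kept) == {"s1", "s3"} and removed == ["s2"]

    def test_empty_interval_errors(self):
        with pytest.raises(ValueError):
            extract_region({"a": "ACGT"}, (2, 2))


class TestHelpers:
    def test_p_distance_pairwise_deletion(self):
        assert p_distance("ACGT", "ACGA") == pytest.approx(0.25)
        assert p_distance("ACGN", "ACGA") == 0.0
        assert p_distance("AC-T", "ACGT") == pytest.approx(0.0)

    def test_map_sites_through_gapped_reference(self):
        panel = tiny_panel(
            [("a1", "ATTA"), ("a2", "ATTA"), ("b1", "AGCA"), ("b2", "AGCA")],
            [("a1", "A"), ("a2", "A"), ("b1", "B"), ("b2", "B")],
        )
        sites = find_inter_clade_fixed_sites(panel, focal_clade="A")
        assert [s.column for s in sites] == [1, 2]
        mapped, dropped = map_sites_to_reference(sites, "A-TA")
        assert [(s.column, pos) for s, pos in mapped] == [(2, 1)]
        assert [s.column for s in dropped] == [1]
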
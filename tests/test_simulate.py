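"""Synthetic-data generators: planted truth and determinism."""

from collections import Counter

import numpy as np
import pytest

from dgecast import simulate
from dgecast.simulate import (
    NO_SITE,
    gen_ct_table,
    gen_deg_tables,
    gen_edge_list,
    gen_gene_sets,
    gen_library_pair,
    gen_raw_reads,
    gen_transcriptome,
)
from dgecast.tags import canonical_tag


class TestTranscriptome:
    def test_unique_tags_when_no_structure_requested(self):
        tx = gen_transcriptome(10, frac_no_site=0, frac_shared_tag=0, seed=1)
        tags = list(tx.truth.values())
        assert len(tags) == 10 and len(set(tags)) == 10
        assert NO_SITE not in tags

    def test_all_no_site_at_fraction_one(self):
        tx = gen_transcriptome(5, frac_no_site=1.0, seed=1)
        assert all(t == NO_SITE for t in tx.truth.values())
        assert all("CATG" not in seq for _, seq in tx.records)

    def test_shared_tags_exist_at_requested_fraction(self):
        tx = gen_transcriptome(100, frac_shared_tag=0.1, seed=7)
        dup = [t for t, n in Counter(tx.truth.values()).items() if t != NO_SITE and n >= 2]
        assert len(dup) >= 1
        n_sharing = sum(n for t, n in Counter(tx.truth.values()).items() if t != NO_SITE and n >= 2)
        assert n_sharing == pytest.approx(10, abs=2)

    def test_truth_tag_is_the_canonical_tag_of_its_sequence(self):
        tx = gen_transcriptome(40, frac_no_site=0.2, frac_shared_tag=0.2, seed=3)
        for gene, seq in tx.records:
            expected = tx.truth[gene]
            got = canonical_tag(seq)
            assert got == (None if expected == NO_SITE else expected)

    def test_deterministic_given_seed(self):
        a = gen_transcriptome(30, frac_no_site=0.1, frac_shared_tag=0.2, seed=9)
        b = gen_transcriptome(30, frac_no_site=0.1, frac_shared_tag=0.2, seed=9)
        assert a.records == b.records and a.truth == b.truth

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            gen_transcriptome(0, seed=1)
        with pytest.raises(ValueError):
            gen_transcriptome(5, frac_no_site=0.8, frac_shared_tag=0.6, seed=1)
        with pytest.raises(ValueError):
            gen_transcriptome(5, min_len=10, seed=1)


class TestLibraryPair:
    def test_null_generator_plants_nothing(self, transcriptome):
        pair = gen_library_pair(transcriptome, 10**6, 10**6, n_de=0, seed=3)
        assert all(fc == 0 for fc in pair.de_truth.values())

    def test_planted_count_and_depth_bookkeeping(self, transcriptome):
        pair = gen_library_pair(transcriptome, 10**5, 10**5, n_de=2, de_log2fc=2.0, seed=3)
        assert sum(1 for fc in pair.de_truth.values() if fc == 2.0) == 2
        assert sum(pair.counts1.values()) == pair.depth1
        assert sum(pair.counts2.values()) == pair.depth2

    def test_planted_fold_change_realised(self, transcriptome):
        """Mean count ratio of DE genes ~ 4 across seeds (Monte Carlo)."""
        ratios = []
        for seed in range(50):
            pair = gen_library_pair(
                transcriptome,
                10**6,
                10**6,
                n_de=5,
                de_log2fc=2.0,
                seed=seed,
                de_min_expected=500,
            )
            for g, fc in pair.de_truth.items():
                if fc != 0 and pair.counts1[g] > 0:
                    ratios.append(pair.counts2[g] / pair.counts1[g])
        assert np.mean(ratios) == pytest.approx(4.0, rel=0.05)

    def test_deterministic_given_seed(self, transcriptome):
        a = gen_library_pair(transcriptome, 10**4, 10**4, n_de=3, de_log2fc=1.0, seed=6)
        b = gen_library_pair(transcriptome, 10**4, 10**4, n_de=3, de_log2fc=1.0, seed=6)
        assert a.counts1 == b.counts1 and a.counts2 == b.counts2
        assert a.de_truth == b.de_truth

    def test_too_many_de_genes_rejected(self, transcriptome):
        with pytest.raises(ValueError):
            gen_library_pair(transcriptome, 100, 100, n_de=999, seed=1)


class TestRawReads:
    def test_no_contamination_reads_start_with_truth_tags(self, transcriptome, library_pair):
        reads1, reads2 = gen_raw_reads(library_pair, transcriptome, seed=2)
        truth_tags = {t for t in transcriptome.truth.values() if t != NO_SITE}
        for rs in (reads1, reads2):
            assert all(r[:21] in truth_tags for r in rs.reads)

    def test_reads_are_49_bp(self, transcriptome, library_pair):
        reads1, _ = gen_raw_reads(
            library_pair, transcriptome, frac_empty=0.1, frac_lowq=0.1, seed=2
        )
        assert {len(r) for r in reads1.reads} == {49}

    def test_contaminant_composition_recorded(self, transcriptome, library_pair):
        reads1, _ = gen_raw_reads(
            library_pair,
            transcriptome,
            frac_empty=0.1,
            frac_lowq=0.05,
            frac_singleton_noise=0.02,
            seed=12,
        )
        comp = reads1.composition
        n_clean = comp["clean"]
        assert len(reads1.reads) == sum(comp.values())
        # binomial draws: ~10% empties of the clean read count
        assert comp["empty"] == pytest.approx(0.1 * n_clean, rel=0.3)

    def test_no_site_gene_with_counts_is_an_error(self):
        tx = simulate.SyntheticTranscriptome(
            [("g1", "AAAATTTTGGGGCCCCAAAATTTT" * 3)], {"g1": NO_SITE}
        )
        pair = simulate.SyntheticLibraryPair({"g1": 5}, {"g1": 5}, 5, 5, {"g1": 0.0}, 0)
        with pytest.raises(ValueError):
            gen_raw_reads(pair, tx, seed=1)


class TestDegTables:
    def test_tables_share_the_universe(self):
        synth = gen_deg_tables(100, 10, 5, 5, seed=2)
        universes = [set(df["gene"]) for df in synth.tables.values()]
        assert universes[0] == universes[1] == universes[2]
        assert len(universes[0]) == 100

    def test_membership_partitions_the_universe(self):
        synth = gen_deg_tables(60, 10, 6, 4, seed=5)
        counts = Counter(synth.planted_membership.values())
        assert counts["castration-only"] == 10
        assert counts["crpc-shared"] == 6
        assert counts["crpc-specific"] == 4
        assert counts["null"] == 40

    def test_zero_shared_gives_empty_shared_rows(self):
        synth = gen_deg_tables(50, 5, 0, 5, seed=1)
        assert "crpc-shared" not in synth.planted_membership.values()

    def test_significant_rows_match_labels_under_thresholds(self):
        synth = gen_deg_tables(80, 8, 6, 6, seed=4)
        sig = {
            name: set(df[(df["q"] < 0.001) & (df["log2fc"].abs() > 1)]["gene"])
            for name, df in synth.tables.items()
        }
        for gene, label in synth.planted_membership.items():
            assert (gene in sig["castration"]) == (
                label in ("castration-only", "crpc-shared")
            )
            assert (gene in sig["crpc_a"]) == (label in ("crpc-shared", "crpc-specific"))
            assert (gene in sig["crpc_b"]) == (label == "crpc-specific")

    def test_oversized_categories_rejected(self):
        with pytest.raises(ValueError):
            gen_deg_tables(10, 5, 4, 4, seed=1)


class TestGeneSetsAndEdges:
    def test_planted_overlap_is_exact(self):
        universe = [f"g{i}" for i in range(50)]
        query = universe[:10]
        sets, target = gen_gene_sets(5, 8, universe, query, enriched_set_overlap=6, seed=3)
        assert len(sets[target][1] & set(query)) == 6

    def test_overlap_larger_than_set_rejected(self):
        with pytest.raises(ValueError):
            gen_gene_sets(3, 5, [f"g{i}" for i in range(20)], ["g0"], 6, seed=1)

    def test_hub_degree_planted_exactly(self):
        edges = gen_edge_list(50, 100, hub_node="HUB", hub_degree=35, seed=5)
        deg = Counter()
        for a, b, _ in edges:
            assert a != b  # no self-loops
            deg[a] += 1
            deg[b] += 1
        assert deg["HUB"] == 35
        assert len(edges) == 100
        assert len({(min(a, b), max(a, b)) for a, b, _ in edges}) == 100

    def test_infeasible_edge_counts_rejected(self):
        with pytest.raises(ValueError):
            gen_edge_list(10, 5, hub_degree=8, seed=1)
        with pytest.raises(ValueError):
            gen_edge_list(10, 9, hub_degree=10, seed=1)


class TestCtTable:
    def test_reference_and_groups_present(self):
        ct = gen_ct_table({"GENE1": 4.0}, n_replicates=3, seed=1)
        assert set(ct["gene"]) == {"GENE1", "GAPDH"}
        assert set(ct["group"]) == {"control", "treated"}
        assert len(ct) == 12

    def test_fold_change_lowers_treated_ct(self):
        ct = gen_ct_table({"GENE1": 8.0}, ct_noise_sd=0.0, seed=1)
        g = ct[ct["gene"] == "GENE1"]
        diff = (
            g[g["group"] == "control"]["ct"].mean()
            - g[g["group"] == "treated"]["ct"].mean()
        )
        assert diff == pytest.approx(3.0)  # log2(8) cycles
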
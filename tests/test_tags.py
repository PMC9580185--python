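"""Tag catalog, read cleaning, mismatch mapping, TPM and correlation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dgecast import (
    build_tag_catalog,
    clean_tags,
    compute_tpm,
    library_correlation,
    map_tags,
    simulate,
)
from dgecast.tags import CountTable

from .oracles import all_site_tags, brute_force_assign

ADAPTOR = simulate.DEFAULT_ADAPTOR


class TestCatalog:
    def test_single_site_tag(self):
        cat = build_tag_catalog([("g1", "GGCATGACGTACGTACGTACGTAAAAA")])
        assert cat.gene_tag["g1"] == "CATGACGTACGTACGTACGTA"

    def test_no_site_gene_recorded(self):
        cat = build_tag_catalog([("g1", "AAAATTTTGGGGCCCC")])
        assert cat.no_site_genes == {"g1"}

    def test_three_prime_most_site_wins(self):
        # two qualifying CATG sites; brute-force scan gives the candidates
        seq = "CATG" + "A" * 17 + "CATG" + "C" * 17 + "TT"
        cat = build_tag_catalog([("g1", seq)])
        assert cat.gene_tag["g1"] == all_site_tags(seq)[-1]

    def test_site_without_17nt_downstream_does_not_qualify(self):
        seq = "TT" + "CATG" + "A" * 17 + "CATG" + "C" * 5
        cat = build_tag_catalog([("g1", seq)])
        assert cat.gene_tag["g1"] == "CATG" + "A" * 17

    def test_n_in_window_never_forms_a_tag(self):
        seq = "CATG" + "A" * 8 + "N" + "A" * 8
        assert build_tag_catalog([("g1", seq)]).no_site_genes == {"g1"}

    def test_shared_tags_flagged_ambiguous(self):
        tx = simulate.gen_transcriptome(100, frac_shared_tag=0.1, seed=7)
        cat = build_tag_catalog(tx.records)
        shared = [t for t, gs in cat.entries.items() if len(gs) >= 2]
        assert shared and set(shared) == set(cat.ambiguous)

    def test_agrees_with_brute_force_scan(self, transcriptome, catalog):
        for gene, seq in transcriptome.records:
            candidates = all_site_tags(seq)
            if candidates:
                assert catalog.gene_tag[gene] == candidates[-1]
            else:
                assert gene in catalog.no_site_genes

    def test_duplicate_ids_and_empty_input_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_tag_catalog([("g", "CATG" + "A" * 17), ("g", "CATG" + "C" * 17)])
        with pytest.raises(ValueError, match="empty"):
            build_tag_catalog([])


class TestCleaning:
    def test_clean_reads_survive_with_no_removals(self):
        tag = "CATG" + "ACGT" * 4 + "A"
        reads = [(tag + ADAPTOR * 3)[:49]] * 10
        clean, report = clean_tags(reads, ADAPTOR)
        assert clean == {tag: 10}
        assert report.removed_empty == report.removed_lowq == 0
        assert report.removed_length == report.removed_singleton == 0

    def test_adaptor_only_read_is_empty(self):
        clean, report = clean_tags([(ADAPTOR * 3)[:49]], ADAPTOR)
        assert report.removed_empty == 1 and report.clean_tags_total == 0

    def test_hand_enumerated_mixture(self):
        t1 = "CATG" + "A" * 17
        t2 = "CATG" + "C" * 17
        n_read = t1[:10] + "N" + t1[11:]
        reads = [(t1 + ADAPTOR * 3)[:49]] * 5
        reads += [(t2 + ADAPTOR * 3)[:49]]
        reads += [(n_read + ADAPTOR * 3)[:49]]
        clean, report = clean_tags(reads, ADAPTOR)
        assert clean == {t1: 5}
        assert report.removed_lowq == 1 and report.removed_singleton == 1

    def test_off_length_tags_removed(self):
        short = "CATG" + "A" * 15  # 19 nt before the adaptor
        clean, report = clean_tags([(short + ADAPTOR * 3)[:49]] * 3, ADAPTOR)
        assert not clean and report.removed_length == 3

    @given(st.integers(0, 2**31 - 1))
    def test_report_reconciles_on_fuzzed_reads(self, seed):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGTN"))
        reads = []
        for _ in range(rng.integers(1, 60)):
            kind = rng.integers(0, 4)
            if kind == 0:  # random garbage of random length
                reads.append("".join(bases[rng.integers(0, 5, rng.integers(1, 60))]))
            elif kind == 1:  # adaptor only
                reads.append((ADAPTOR * 3)[:49])
            else:  # tag-like read, possibly repeated
                tag = "CATG" + "".join(bases[rng.integers(0, 4, 17)])
                reads += [(tag + ADAPTOR * 3)[:49]] * int(rng.integers(1, 4))
        _, report = clean_tags(reads, ADAPTOR)
        report.check()  # raises if the removal identity is violated


class TestMapping:
    def test_exact_unique_match_counts(self, catalog, transcriptome):
        tag = catalog.gene_tag[transcriptome.gene_ids[0]]
        table = map_tags({tag: 7}, catalog)
        assert table.counts[transcriptome.gene_ids[0]] == 7

    def test_one_mismatch_assignment_matches_brute_force(self, catalog):
        rng = np.random.default_rng(0)
        genes = sorted(catalog.gene_tag)
        for gene in genes[:10]:
            tag = list(catalog.gene_tag[gene])
            i = rng.integers(4, len(tag))  # keep the CATG anchor intact
            tag[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[tag[i]]
            mutated = "".join(tag)
            expected = brute_force_assign(mutated, catalog.gene_tag)
            table = map_tags({mutated: 3}, catalog)
            if expected is None:
                assert table.total_mapped == 0
            else:
                assert table.counts[expected] == 3

    def test_tie_at_distance_one_discarded(self):
        cat = build_tag_catalog(
            [
                ("g1", "CATG" + "A" * 17),
                ("g2", "CATG" + "A" * 16 + "C"),
            ]
        )
        # distance 1 from both catalog tags
        tie = "CATG" + "A" * 16 + "G"
        assert map_tags({tie: 5}, cat).total_mapped == 0

    def test_ambiguous_exact_hits_discarded(self):
        shared = "CATG" + "G" * 17
        cat = build_tag_catalog(
            [("g1", "TT" + shared), ("g2", "CC" + shared)]
        )
        assert map_tags({shared: 9}, cat).total_mapped == 0

    def test_wrong_length_tag_rejected(self, catalog):
        with pytest.raises(ValueError):
            map_tags({"CATGAA": 1}, catalog)

    def test_round_trip_recovers_counts(self, transcriptome, catalog, library_pair):
        reads1, _ = simulate.gen_raw_reads(library_pair, transcriptome, seed=4)
        clean, _ = clean_tags(reads1.reads, ADAPTOR)
        table = map_tags(clean, catalog)
        for gene, c in library_pair.counts1.items():
            if c >= 2:
                assert table.counts[gene] == c
            else:  # singletons are removed by cleaning step 5
                assert table.counts[gene] == 0


class TestTPM:
    def test_exact_fractions(self):
        assert compute_tpm({"A": 1, "B": 1, "C": 2}) == {
            "A": 250000.0,
            "B": 250000.0,
            "C": 500000.0,
        }

    def test_single_gene_gets_the_whole_million(self):
        assert compute_tpm({"A": 5}) == {"A": 1e6}

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            compute_tpm({"A": 0})

    @given(st.integers(0, 2**31 - 1))
    def test_sums_to_one_million(self, seed):
        rng = np.random.default_rng(seed)
        counts = {f"g{i}": int(c) for i, c in enumerate(rng.integers(0, 500, 30))}
        if sum(counts.values()) == 0:
            counts["g0"] = 1
        assert sum(compute_tpm(counts).values()) == pytest.approx(1e6, rel=1e-9)


class TestCorrelation:
    def test_self_correlation_is_one(self, library_pair):
        t = CountTable.from_counts("a", library_pair.counts1)
        assert library_correlation(t, t) == pytest.approx(1.0)

    def test_null_pair_highly_correlated(self, transcriptome):
        pair = simulate.gen_library_pair(transcriptome, 10**6, 10**6, n_de=0, seed=8)
        t1 = CountTable.from_counts("a", pair.counts1)
        t2 = CountTable.from_counts("b", pair.counts2)
        assert library_correlation(t1, t2) > 0.95

    def test_perturbation_lowers_correlation(self, transcriptome):
        null = simulate.gen_library_pair(transcriptome, 10**6, 10**6, n_de=0, seed=8)
        shifted = simulate.gen_library_pair(
            transcriptome, 10**6, 10**6, n_de=25, de_log2fc=2.0, seed=8
        )
        r_null = library_correlation(
            CountTable.from_counts("a", null.counts1),
            CountTable.from_counts("b", null.counts2),
        )
        r_de = library_correlation(
            CountTable.from_counts("a", shifted.counts1),
            CountTable.from_counts("b", shifted.counts2),
        )
        assert r_de < r_null

    def test_undefined_without_variance(self):
        t1 = CountTable.from_counts("a", {"G1": 5})
        with pytest.raises(ValueError):
            library_correlation(t1, t1)
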
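import re

import pytest

from tagdge.digest import tag_sites

from tagdge.annotate import (
    AnnotationReport,
    annotation_rates,
    build_index,
    expression_frame,
    map_tags,
)
from tagdge.simulate import SimulationConfig, generate_transcriptome
from tagdge.tagproc import TagCountTable, TagLedger, filter_tags

TAG_RE = re.compile(r"(?=(CATG[ACGT]{17}))")


def table_from(entries, retained=None):
    retained = sum(entries.values()) if retained is None else retained
    ledger = TagLedger(
        total_tags=retained,
        clean_tags=retained,
        singleton_tags=0,
        retained_tags=retained,
        unique_tags=len(entries),
    )
    return TagCountTable(entries=dict(entries), ledger=ledger)


class TestBuildIndex:
    def test_single_site_rank0(self):
        seq = "AAA" + "CATG" + "T" * 17
        index = build_index([("g1", seq)])
        assert len(index) == 1
        (tag,) = index.tag_to_genes
        assert tag == "CATG" + "T" * 17
        assert index.tag_to_genes[tag] == {"g1": 0}

    def test_site_too_close_to_3prime_end(self):
        seq = "A" * 40 + "CATG" + "T" * 10
        assert len(build_index([("g1", seq)])) == 0

    def test_multi_gene_key_keeps_all_genes(self):
        seq = "AAA" + "CATG" + "T" * 17
        index = build_index([("g1", seq), ("g2", "GG" + seq)])
        tag = "CATG" + "T" * 17
        assert set(index.tag_to_genes[tag]) == {"g1", "g2"}

    def test_duplicate_ids_rejected(self):
        seq = "AAA" + "CATG" + "T" * 17
        with pytest.raises(ValueError, match="duplicate"):
            build_index([("g1", seq), ("g1", seq)])

    def test_keys_match_regex_oracle(self):
        cfg = SimulationConfig(n_genes=40, length_range=(100, 500), seed=13)
        transcripts = generate_transcriptome(cfg)
        index = build_index(transcripts)
        expected = set()
        for _, seq in transcripts:
            expected.update(TAG_RE.findall(seq))
        assert set(index.tag_to_genes) == expected

    def test_ranks_count_from_3prime(self):
        seq = "CATG" + "A" * 20 + "CATG" + "C" * 17
        index = build_index([("g1", seq)])
        ranks = {tag: genes["g1"] for tag, genes in index.tag_to_genes.items()}
        assert ranks["CATG" + "C" * 17] == 0
        assert ranks[seq[:21]] == 1


class TestMapTags:
    def setup_method(self):
        self.t1 = "CATG" + "A" * 17
        self.t2 = "CATG" + "C" * 17
        self.shared = "CATG" + "G" * 17
        self.index = build_index(
            [
                ("g1", "TT" + self.t1),
                ("g2", "TT" + self.t2 + "AA" + self.shared),
                ("g3", "TT" + self.shared),
            ]
        )

    def test_exact_single_gene_assigned(self):
        counts, report = map_tags(table_from({self.t1: 5}), self.index)
        assert counts == {"g1": 5}
        assert report.matched_unique_tags == 1
        assert report.matched_tag_copies == 5

    def test_exact_multi_gene_discarded(self):
        counts, report = map_tags(table_from({self.shared: 9}), self.index)
        assert counts == {}
        assert report.ambiguous_unique_tags == 1

    def test_one_mismatch_unique_assigned(self):
        variant = self.t1[:10] + "T" + self.t1[11:]
        counts, report = map_tags(table_from({variant: 4}), self.index)
        assert counts == {"g1": 4}
        # brute-force Hamming oracle over all index keys
        dists = {
            tag: sum(a != b for a, b in zip(variant, tag))
            for tag in self.index.tag_to_genes
        }
        hits = {g for tag, d in dists.items() if d <= 1 for g in self.index.exact(tag)}
        assert hits == {"g1"}

    def test_two_mismatches_unmatched(self):
        variant = "CATG" + "TT" + "A" * 15
        counts, report = map_tags(table_from({variant: 4}), self.index)
        assert counts == {}
        assert report.unmatched_unique_tags == 1

    def test_mismatch_spanning_two_genes_discarded(self):
        # distance 1 from both g1's and g2's unique tags is impossible here,
        # so use a variant of the shared tag: its neighborhood spans g2, g3
        variant = self.shared[:12] + "T" + self.shared[13:]
        counts, report = map_tags(table_from({variant: 2}), self.index)
        assert counts == {}
        assert report.ambiguous_unique_tags == 1

    def test_exact_hit_precedence_over_mismatch(self):
        # t1 is an exact g1 hit; adding a distance-1 key for g9 must not
        # change the assignment
        neighbor = self.t1[:20] + "G"
        index2 = build_index(
            [
                ("g1", "TT" + self.t1),
                ("g9", "TT" + neighbor),
            ]
        )
        counts, _ = map_tags(table_from({self.t1: 3}), index2)
        assert counts == {"g1": 3}

    def test_multi_site_same_gene_counted_once(self):
        seq = "AA" + self.t1 + "CC" + self.t1
        index = build_index([("g1", seq)])
        counts, report = map_tags(table_from({self.t1: 7}), index)
        assert counts == {"g1": 7}
        assert report.matched_unique_tags == 1

    def test_empty_index_reports_unmatched(self):
        counts, report = map_tags(table_from({self.t1: 3}), build_index([]))
        assert counts == {}
        assert report.unmatched_unique_tags == 1

    def test_partition_property(self, small_sim, small_tables):
        index = build_index(small_sim.transcripts)
        counts, report = map_tags(small_tables["CO"], index)
        assert sum(counts.values()) == report.matched_tag_copies
        assert report.matched_tag_copies <= small_tables["CO"].ledger.retained_tags
        assert (
            report.matched_unique_tags
            + report.ambiguous_unique_tags
            + report.unmatched_unique_tags
            == report.unique_tags
        )

    def test_noise_free_counts_equal_simulator_draws(self):
        from tagdge.simulate import make_truth, simulate_libraries

        cfg = SimulationConfig(
            n_genes=30,
            length_range=(100, 400),
            n_tags_per_library=20_000,
            error_rate=0.0,
            n_rate=0.0,
            adapter_rate=0.0,
            frac_de=0.0,
            seed=21,
        )
        transcripts = generate_transcriptome(cfg)
        truth = make_truth(cfg)
        reads, _, draws, _ = simulate_libraries(
            transcripts, truth, cfg, return_gene_draws=True
        )
        index = build_index(transcripts)
        # restrict to genes whose every tag is single-gene in the index
        unambiguous = {
            gid
            for gi, (gid, seq) in enumerate(transcripts)
            if all(len(index.exact(tag)) == 1 for _, _, tag in tag_sites(seq))
        }
        table = filter_tags(reads, min_copy=1)
        counts, _ = map_tags(table, index)
        gene_ids = [gid for gid, _ in transcripts]
        for gi, gid in enumerate(gene_ids):
            if gid in unambiguous:
                assert counts.get(gid, 0) == int((draws == gi).sum())


class TestAnnotationRates:
    def test_printed_ds_values(self):
        report = AnnotationReport(
            unique_tags=340_187,
            matched_unique_tags=43_085,
            matched_tag_copies=1_457_659,
            retained_tags=4_480_328,
            matched_genes=23_912,
        )
        assert annotation_rates(report, 43_990) == {
            "matched_unique_pct": 12.67,
            "matched_gene_pct": 54.36,
            "matched_total_pct": 32.53,
        }

    def test_printed_co_values(self):
        report = AnnotationReport(
            unique_tags=328_806,
            matched_unique_tags=39_143,
            matched_tag_copies=1_398_438,
            retained_tags=4_410_133,
            matched_genes=22_826,
        )
        assert annotation_rates(report, 43_990) == {
            "matched_unique_pct": 11.90,
            "matched_gene_pct": 51.89,
            "matched_total_pct": 31.71,
        }

    def test_all_matched_is_100(self):
        report = AnnotationReport(
            unique_tags=10,
            matched_unique_tags=10,
            matched_tag_copies=50,
            retained_tags=50,
            matched_genes=5,
        )
        rates = annotation_rates(report, 5)
        assert rates == {
            "matched_unique_pct": 100.0,
            "matched_gene_pct": 100.0,
            "matched_total_pct": 100.0,
        }

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            annotation_rates(AnnotationReport(), 10)


class TestExpressionFrame:
    def test_tpm_identity(self, small_sim, small_tables):
        index = build_index(small_sim.transcripts)
        libraries = {}
        reports = {}
        for lib, table in small_tables.items():
            counts, report = map_tags(table, index)
            libraries[lib] = (counts, table.ledger.retained_tags)
            reports[lib] = report
        frame = expression_frame(libraries)
        for lib in libraries:
            total_tpm = frame[f"tpm_{lib}"].sum()
            expected = (
                reports[lib].matched_tag_copies
                / small_tables[lib].ledger.retained_tags
                * 1e6
            )
            assert total_tpm == pytest.approx(expected, rel=1e-12)

    def test_missing_gene_gets_zero(self):
        frame = expression_frame({"A": ({"g1": 10}, 100), "B": ({"g2": 5}, 50)})
        row = frame.set_index("gene_id")
        assert row.loc["g1", "count_B"] == 0
        assert row.loc["g2", "tpm_B"] == pytest.approx(1e5)
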
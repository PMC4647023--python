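import gzip
import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathminer.network_core import SeedPairPath
from pathminer.permutation import GeneScore
from pathminer.string_io import (
    ScoredInteraction,
    SeedSet,
    StringParseError,
    parse_string_links,
    read_edges_tsv,
    read_seed_set,
    read_symbol_map,
    write_results,
)


def parse_text(text: str, **kw):
    return parse_string_links(io.StringIO(text), **kw)


class TestParseStringLinks:
    def test_basic_record_maps_fields_and_strips_prefix(self):
        res = parse_text("9606.ENSPA 9606.ENSPB 700\n", species_prefix="9606.")
        assert res.interactions == [ScoredInteraction("ENSPA", "ENSPB", 700)]
        assert res.n_directed_records == 1

    def test_mirrored_directed_records_merge_keeping_max(self):
        res = parse_text("9606.X 9606.Y 300\n9606.Y 9606.X 400\n")
        assert res.interactions == [ScoredInteraction("X", "Y", 400)]
        assert res.n_directed_records == 2
        assert res.n_undirected == 1

    def test_header_line_autodetected(self):
        res = parse_text("protein1 protein2 combined_score\n9606.A 9606.B 500\n")
        assert res.header_skipped
        assert res.n_undirected == 1

    def test_other_species_filtered(self):
        res = parse_text("10090.A 10090.B 500\n9606.A 9606.B 500\n")
        assert res.n_species_filtered == 1
        assert [i.pair for i in res.interactions] == [("A", "B")]

    def test_empty_after_filtering_raises(self):
        with pytest.raises(StringParseError, match="no interactions"):
            parse_text("10090.A 10090.B 500\n")

    def test_malformed_lines_counted_not_fatal(self):
        res = parse_text("9606.A 9606.B 500\n9606.C 9606.D banana\njunk\n")
        assert res.n_malformed == 2
        assert res.n_undirected == 1

    def test_strict_mode_names_line_number(self):
        with pytest.raises(StringParseError, match="line 2"):
            parse_text("9606.A 9606.B 500\n9606.C 9606.D banana\n", strict=True)

    def test_self_loops_dropped_and_counted(self):
        res = parse_text("9606.A 9606.A 500\n9606.A 9606.B 600\n")
        assert res.n_self_loops == 1
        assert res.n_undirected == 1

    def test_out_of_range_score_skipped(self):
        res = parse_text("9606.A 9606.B 1200\n9606.A 9606.B 500\n")
        assert res.n_malformed == 1
        assert res.interactions[0].score == 500

    def test_keep_prefix_flag(self):
        res = parse_text("9606.A 9606.B 500\n", strip_prefix=False)
        assert res.interactions[0].pair == ("9606.A", "9606.B")

    def test_gzip_path(self, tmp_path):
        path = tmp_path / "links.txt.gz"
        with gzip.open(path, "wt") as fh:
            fh.write("9606.A 9606.B 640\n")
        res = parse_string_links(path)
        assert res.interactions == [ScoredInteraction("A", "B", 640)]

    def test_dedup_idempotent_on_concatenation(self):
        body = "9606.A 9606.B 500\n9606.B 9606.C 700\n9606.A 9606.C 321\n"
        once = parse_text(body).interactions
        twice = parse_text(body + body).interactions
        assert once == twice

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 20), st.integers(0, 20), st.integers(150, 999)
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_parsed_scores_always_in_range(self, triples):
        lines = "".join(
            f"9606.P{a:02d} 9606.P{b:02d} {s}\n" for a, b, s in triples
        )
        try:
            res = parse_text(lines)
        except StringParseError:
            # all lines were self-loops
            assert all(a == b for a, b, _ in triples)
            return
        for it in res.interactions:
            assert 150 <= it.score <= 999
            assert it.protein_a < it.protein_b


class TestScoredInteraction:
    def test_unordered_pairs_compare_equal(self):
        assert ScoredInteraction("B", "A", 500) == ScoredInteraction("A", "B", 500)

    def test_self_pair_rejected(self):
        with pytest.raises(StringParseError):
            ScoredInteraction("A", "A", 500)

    @pytest.mark.parametrize("score", [149, 1000, 0])
    def test_score_out_of_range_rejected(self, score):
        with pytest.raises(StringParseError):
            ScoredInteraction("A", "B", score)


class TestReadSeedSet:
    def test_plain_list(self, tmp_path):
        f = tmp_path / "seeds.txt"
        f.write_text("ENSP1\nENSP2\n\nENSP3\n")
        seeds = read_seed_set(f)
        assert set(seeds.members) == {"ENSP1", "ENSP2", "ENSP3"}

    def test_duplicates_collapsed_with_warning(self, tmp_path, caplog):
        f = tmp_path / "seeds.txt"
        f.write_text("ENSP1\nENSP1\n")
        with caplog.at_level("WARNING"):
            seeds = read_seed_set(f)
        assert len(seeds) == 1
        assert "duplicate" in caplog.text

    def test_empty_file_raises(self, tmp_path):
        f = tmp_path / "seeds.txt"
        f.write_text("\n\n")
        with pytest.raises(ValueError, match="no IDs"):
            read_seed_set(f)

    def test_species_prefix_normalised(self, tmp_path):
        f = tmp_path / "seeds.txt"
        f.write_text("9606.ENSP1\nENSP2\n")
        seeds = read_seed_set(f)
        assert set(seeds.members) == {"ENSP1", "ENSP2"}

    def test_tsv_column(self, tmp_path):
        f = tmp_path / "seeds.tsv"
        f.write_text("symbol\tensembl\nKRAS\tENSP1\nTP53\tENSP2\n")
        seeds = read_seed_set(f, id_column="ensembl")
        assert set(seeds.members) == {"ENSP1", "ENSP2"}

    def test_missing_column_raises(self, tmp_path):
        f = tmp_path / "seeds.tsv"
        f.write_text("a\tb\n1\t2\n")
        with pytest.raises(ValueError, match="nope"):
            read_seed_set(f, id_column="nope")


class TestSeedSet:
    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            SeedSet(frozenset())

    def test_iteration_sorted_and_membership(self):
        s = SeedSet(frozenset(["B", "A"]))
        assert list(s) == ["A", "B"]
        assert "A" in s and "C" not in s


def _score(gene, bet, fdr, n=1000):
    return GeneScore(gene, bet, int(round(fdr * n)), fdr, fdr < 0.05, n)


class TestWriteResults:
    def make_path(self, nodes, weights):
        return SeedPairPath(
            nodes[0], nodes[-1], tuple(nodes), sum(weights), tuple(weights)
        )

    def test_single_path_row_counts(self, tmp_path):
        p = self.make_path(["A", "B", "C"], [1, 2])
        written = write_results([p], [], tmp_path)
        assert len(written["paths"].read_text().splitlines()) == 2  # header + 1
        assert len(written["edges"].read_text().splitlines()) == 3  # header + 2

    def test_empty_scores_header_only(self, tmp_path):
        written = write_results([], [], tmp_path)
        assert written["genes"].read_text().splitlines() == [
            "gene\tbetweenness\tpermutation_fdr"
        ]

    def test_candidate_table_columns_and_symbols(self, tmp_path):
        p = self.make_path(["A", "X", "B"], [1, 1])
        scores = [_score("X", 1, 0.002), _score("Y", 5, 0.5)]
        written = write_results(
            [p], scores, tmp_path, symbol_map={"X": "GENE_X"}
        )
        lines = written["candidates"].read_text().splitlines()
        assert lines[0] == "row_number\tprotein_id\tgene_symbol\tbetweenness\tpermutation_fdr"
        assert lines[1].startswith("1\tX\tGENE_X\t1\t0.002")
        assert len(lines) == 2  # Y is not a candidate

    def test_edge_tsv_round_trip(self, tmp_path):
        paths = [
            self.make_path(["A", "B", "C"], [1, 300]),
            self.make_path(["B", "C", "D"], [300, 850]),
        ]
        written = write_results(paths, [], tmp_path)
        back = read_edges_tsv(written["edges"])
        expected = {
            ScoredInteraction("A", "B", 999),
            ScoredInteraction("B", "C", 700),
            ScoredInteraction("C", "D", 150),
        }
        assert set(back) == expected

    def test_unwritable_directory_raises(self, tmp_path):
        # an existing regular file cannot serve as the output directory
        blocked = tmp_path / "blocked"
        blocked.write_text("")
        with pytest.raises(OSError):
            write_results([], [], blocked)


def test_read_symbol_map(tmp_path):
    f = tmp_path / "map.tsv"
    f.write_text("ENSP1\tKRAS\nENSP2\tTP53\n")
    assert read_symbol_map(f) == {"ENSP1": "KRAS", "ENSP2": "TP53"}
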
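"""Motif parsing, overlapping occurrence counting, expected counts and the
enrichment index, checked against an independent naive scanner."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pollenscreen.motifs import (
    DEFAULT_MOTIFS,
    Motif,
    MotifCountTable,
    count_occurrences,
    count_table,
    enrichment_index,
    enrichment_table,
    expected_count,
    load_registry,
    parse_motif,
    site_totals,
    write_registry,
)
from pollenscreen.promoters import reverse_complement


def naive_count(seq: str, motif: Motif) -> int:
    """Position-by-position reference scanner (the test-side oracle)."""
    seq = seq.upper()
    k = motif.k
    total = 0
    for i in range(len(seq) - k + 1):
        if all(seq[i + j] in motif.positions[j] for j in range(k)):
            total += 1
    return total


class TestParseMotif:
    @pytest.mark.parametrize(
        "pattern, k, m, canonical",
        [
            ("AGAAA", 5, 1, "AGAAA"),
            ("[TA]AAAG", 5, 2, "[AT]AAAG"),
            ("[T/A]AAAG", 5, 2, "[AT]AAAG"),
            ("tCcAcCa", 7, 1, "TCCACCA"),
            ("[ACGT]A", 2, 4, "[ACGT]A"),
        ],
    )
    def test_patterns_parse_with_degeneracy(self, pattern, k, m, canonical):
        motif = parse_motif("x", pattern)
        assert (motif.k, motif.m, motif.pattern) == (k, m, canonical)

    @pytest.mark.parametrize("bad", ["AG[XZ]AA", "", "A[]G", "A[CG", "AG-AA"])
    def test_bad_patterns_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_motif("x", bad)

    def test_words_enumerates_concrete_matches(self):
        assert parse_motif("x", "[TA]A").words() == ["AA", "TA"]


class TestCountOccurrences:
    @pytest.mark.parametrize(
        "seq, pattern, expected",
        [
            ("AGAAAGAAA", "AGAAA", 2),        # overlapping at 1 and 5
            ("TAAAGAAAAG", "[TA]AAAG", 2),    # TAAAG at 1, AAAAG at 6
            ("AAAA", "AAAAA", 0),             # shorter than k
            ("NNNNNNNN", "AGAAA", 0),         # N matches nothing
            ("AGANAGAAA", "AGAAA", 1),
            ("agaaagaaa", "AGAAA", 2),        # case-insensitive input
        ],
    )
    def test_examples(self, seq, pattern, expected):
        assert count_occurrences(seq, parse_motif("x", pattern)) == expected

    def test_non_overlapping_mode(self):
        assert count_occurrences("AAAA", parse_motif("x", "AA")) == 3
        assert count_occurrences("AAAA", parse_motif("x", "AA"),
                                 overlapping=False) == 2

    def test_illegal_character_is_error(self):
        with pytest.raises(ValueError, match="illegal sequence"):
            count_occurrences("ACGU", parse_motif("x", "AC"))

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(data=st.data())
    def test_matches_naive_scanner_on_random_pairs(self, data):
        seq = data.draw(st.text(alphabet="ACGTN", min_size=0, max_size=80))
        k = data.draw(st.integers(1, 9))
        positions = [data.draw(st.sampled_from("ACGT")) for _ in range(k)]
        for idx in data.draw(
                st.lists(st.integers(0, k - 1), max_size=2, unique=True)):
            positions[idx] = "".join(
                sorted(data.draw(st.sets(st.sampled_from("ACGT"),
                                         min_size=2, max_size=4))))
        pattern = "".join(p if len(p) == 1 else f"[{p}]" for p in positions)
        motif = parse_motif("x", pattern)
        assert count_occurrences(seq, motif) == naive_count(seq, motif)

    def test_reverse_complement_pairing(self):
        # scanning a sequence for AGAAA equals scanning its reverse
        # complement for TTTCT (the reverse-complementary element)
        agaaa = parse_motif("x", "AGAAA")
        tttct = parse_motif("y", "TTTCT")
        rng = np.random.default_rng(5)
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            assert (count_occurrences(seq, agaaa)
                    == count_occurrences(reverse_complement(seq), tttct))


class TestExpectedCount:
    def test_closed_forms(self):
        assert expected_count(parse_motif("x", "AGAAA"), 1024) == 1.0
        assert expected_count(parse_motif("x", "TCCACCA"), 16384) == 1.0
        assert expected_count(parse_motif("x", "[TA]AAAG"), 2000) == pytest.approx(
            2000 * 2 / 1024)

    def test_windows_mode_subtracts_edge_windows(self):
        motif = parse_motif("x", "AGAAA")
        assert expected_count(motif, 2000, mode="windows") == pytest.approx(
            1996 / 1024)
        assert expected_count(motif, 3, mode="windows") == 0.0

    def test_negative_length_is_error(self):
        with pytest.raises(ValueError):
            expected_count(parse_motif("x", "A"), -1)


def _table(counts: dict[str, list[int]], lengths: list[int],
           motifs=DEFAULT_MOTIFS) -> MotifCountTable:
    index = pd.Index([f"p{i}" for i in range(len(lengths))], name="gene")
    return MotifCountTable(pd.DataFrame(counts, index=index),
                           pd.Series(lengths, index=index),
                           {m.name: m for m in motifs})


class TestEnrichmentIndex:
    def test_uniform_two_hits_per_2kb_promoter(self):
        table = _table({"AGAAA": [2, 2, 2]}, [2000, 2000, 2000])
        res = enrichment_index(table, "AGAAA")
        assert res.expected_mean == pytest.approx(2000 / 1024)
        assert res.index == pytest.approx(2 / (2000 / 1024))
        assert res.index == pytest.approx(1.024)
        assert res.enriched

    def test_zero_counts_give_zero_index_not_enriched(self):
        table = _table({"AGAAA": [0, 0]}, [2000, 2000])
        res = enrichment_index(table, "AGAAA")
        assert res.index == 0.0 and not res.enriched

    def test_truncated_promoter_lengths_are_honoured(self):
        table = _table({"AGAAA": [1, 1]}, [2000, 500])
        res = enrichment_index(table, "AGAAA")
        assert res.expected_mean == pytest.approx((2000 + 500) / 2 / 1024)

    def test_all_empty_promoters_is_error(self):
        table = _table({"AGAAA": [0]}, [0])
        with pytest.raises(ValueError, match="expected mean"):
            enrichment_index(table, "AGAAA")

    def test_unknown_motif_is_error(self):
        table = _table({"AGAAA": [1]}, [2000])
        with pytest.raises(KeyError):
            enrichment_index(table, "NOPE")

    def test_enrichment_table_covers_all_columns(self):
        table = _table({"AGAAA": [2], "TTTCT": [0]}, [2000])
        frame = enrichment_table(table)
        assert frame["motif"].tolist() == ["AGAAA", "TTTCT"]
        assert frame["enriched"].tolist() == [True, False]


class TestSiteTotals:
    def test_single_promoter_total(self):
        table = _table({"AGAAA": [3], "TTTCT": [4]}, [2000])
        res = site_totals(table, ["AGAAA", "TTTCT"])
        assert res.per_promoter.tolist() == [7]

    def test_min_max_mean(self):
        table = _table({"AGAAA": [9, 49]}, [2000, 2000])
        res = site_totals(table, ["AGAAA"])
        assert (res.min, res.max, res.mean) == (9, 49, 29.0)

    def test_zero_counts_and_errors(self):
        table = _table({"AGAAA": [0, 0]}, [2000, 2000])
        assert site_totals(table, ["AGAAA"]).mean == 0.0
        with pytest.raises(ValueError):
            site_totals(table, [])
        with pytest.raises(KeyError):
            site_totals(table, ["NOPE"])


class TestRegistry:
    EXPECTED = {
        "pollen": {"AGAAA", "TCCACCA", "TGTGGTT", "[TA]AAAG", "AAATGA",
                   "TTTCT", "TGTGA", "AGGTCA", "GAAACG", "GAATAT"},
        "JA": {"GCCGCC", "CGTCA", "TGACG"},
        "ABA": {"CCACC"},
    }

    def test_shipped_registry_contents(self):
        by_cat: dict[str, set[str]] = {}
        for m in DEFAULT_MOTIFS:
            by_cat.setdefault(m.category, set()).add(m.name)
            assert m.source  # every entry carries its literature source
        assert by_cat == self.EXPECTED

    def test_registry_tsv_round_trip(self, tmp_path):
        path = tmp_path / "registry.tsv"
        write_registry(DEFAULT_MOTIFS, path)
        back = load_registry(path)
        assert [(m.name, m.pattern, m.category) for m in back] == [
            (m.name, m.pattern, m.category) for m in DEFAULT_MOTIFS]

    def test_count_table_frame_round_trip(self, tmp_path):
        seqs = {"p1": "AGAAAGAAATTTCT", "p2": "CCCCCCCCCC"}
        table = count_table(seqs, DEFAULT_MOTIFS)
        back = MotifCountTable.from_frame(table.to_frame(), DEFAULT_MOTIFS)
        assert back.counts.equals(table.counts)
        assert back.lengths.tolist() == table.lengths.tolist()
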
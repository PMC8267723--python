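"""Abundance binning, concentration statistics, correlation and pruning."""

import numpy as np
import pandas as pd
import pytest

from pollenscreen.atlas_io import ExpressionAtlas
from pollenscreen.profile_stats import (
    ANTHER_SCHEME,
    POLLEN_SCHEME,
    TRACE,
    AbundanceScheme,
    CorrelationMatrix,
    classify_abundance,
    correlation_matrix,
    prune_redundant_tissues,
    summarize_tissue,
    summarize_atlas,
)


def _atlas(columns: dict[str, list[float]]) -> ExpressionAtlas:
    frame = pd.DataFrame(columns)
    frame.index = pd.Index([f"g{i}" for i in range(len(frame))], name="gene_id")
    return ExpressionAtlas(frame)


class TestClassifyAbundance:
    @pytest.mark.parametrize(
        "fpkm, label",
        [
            (0.0, TRACE), (0.99, TRACE),
            (1.0, "LEG"), (9.999, "LEG"),
            (10.0, "MEG"), (39.999, "MEG"),
            (40.0, "HEG"), (399.999, "HEG"),
            (400.0, "VHEG"), (500.0, "VHEG"), (1e9, "VHEG"),
        ],
    )
    def test_half_open_bins_closed_below(self, fpkm, label):
        assert classify_abundance(fpkm, POLLEN_SCHEME) == label

    def test_anther_scale_edges(self):
        assert classify_abundance(1999.0, ANTHER_SCHEME) == "HEG"
        assert classify_abundance(2000.0, ANTHER_SCHEME) == "VHEG"

    @pytest.mark.parametrize("bad", [-1.0, float("nan"), float("inf")])
    def test_invalid_fpkm_rejected(self, bad):
        with pytest.raises(ValueError):
            classify_abundance(bad)

    def test_scheme_validation(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            AbundanceScheme(1.0, (1.0, 1.0, 40.0), ("a", "b", "c"))
        with pytest.raises(ValueError, match="equal eg_min"):
            AbundanceScheme(2.0, (1.0, 10.0), ("a", "b"))

    def test_every_value_gets_exactly_one_label(self):
        rng = np.random.default_rng(0)
        labels = {TRACE, *POLLEN_SCHEME.bin_labels}
        for x in rng.lognormal(2, 3, size=500):
            assert classify_abundance(float(x), POLLEN_SCHEME) in labels


class TestSummarizeTissue:
    def test_worked_example(self):
        # FPKMs [500, 50, 20, 5, 0.5, 0]: 4 expressed genes, one per bin;
        # top-3 mass 570 of a 575.5 whole-transcriptome total.
        atlas = _atlas({"t": [500, 50, 20, 5, 0.5, 0], "u": [1] * 6})
        s = summarize_tissue(atlas, "t", POLLEN_SCHEME, top_ns=(3,))
        assert s.n_eg == 4
        assert s.bin_counts == {"LEG": 1, "MEG": 1, "HEG": 1, "VHEG": 1}
        assert s.mean_fpkm_eg == pytest.approx(143.75)
        top3 = s.top_n_stats[3]
        assert top3.mean_fpkm == pytest.approx(190.0)
        assert top3.percent == pytest.approx(100 * 570 / 575.5)

    def test_top_n_truncates_to_expressed_genes(self):
        atlas = _atlas({"t": [7.0, 0.2, 0.0], "u": [1.0] * 3})
        s = summarize_tissue(atlas, "t", top_ns=(300,))
        assert s.top_n_stats[300].n_used == 1
        assert s.top_n_stats[300].mean_fpkm == pytest.approx(7.0)

    def test_percent_is_100_when_no_trace_mass(self):
        atlas = _atlas({"t": [5.0, 2.0], "u": [1.0, 1.0]})
        s = summarize_tissue(atlas, "t", top_ns=(2,))
        assert s.top_n_stats[2].percent == pytest.approx(100.0)

    def test_all_zero_tissue_reports_missing_not_zero(self):
        atlas = _atlas({"t": [0.0, 0.0], "u": [1.0, 2.0]})
        s = summarize_tissue(atlas, "t", top_ns=(3,))
        assert s.n_eg == 0
        assert s.mean_fpkm_eg is None
        assert s.top_n_stats[3].percent is None

    def test_absent_tissue_and_bad_n(self):
        atlas = _atlas({"t": [1.0], "u": [1.0]})
        with pytest.raises(KeyError):
            summarize_tissue(atlas, "nosuch")
        with pytest.raises(ValueError):
            summarize_tissue(atlas, "t", top_ns=(0,))

    def test_invariants_over_randomized_atlases(self, random_atlas_factory):
        for seed in range(25):
            atlas = random_atlas_factory(seed)
            for tissue in atlas.tissue_names:
                s = summarize_tissue(atlas, tissue, top_ns=(1, 5, 20, 1000))
                assert sum(s.bin_counts.values()) == s.n_eg
                percents = [st.percent for st in s.top_n_stats.values()
                            if st.percent is not None]
                assert percents == sorted(percents)
                assert all(0 < p <= 100 + 1e-9 for p in percents)

    def test_invariant_to_gene_row_order(self, random_atlas_factory):
        atlas = random_atlas_factory(3)
        shuffled = ExpressionAtlas(atlas.data.sample(frac=1, random_state=1))
        a = summarize_tissue(atlas, "t0", top_ns=(5,))
        b = summarize_tissue(shuffled, "t0", top_ns=(5,))
        assert a.top_n_stats[5].percent == pytest.approx(b.top_n_stats[5].percent)
        assert a.bin_counts == b.bin_counts

    def test_summarize_atlas_has_one_row_per_tissue(self, random_atlas_factory):
        atlas = random_atlas_factory(0)
        table = summarize_atlas(atlas)
        assert table["tissue"].tolist() == atlas.tissue_names


class TestCorrelationMatrix:
    def test_identical_columns_correlate_perfectly(self):
        atlas = _atlas({"a": [1, 2, 3], "b": [1, 2, 3], "c": [5, 1, 9]})
        cm = correlation_matrix(atlas)
        assert cm.r.at["a", "b"] == pytest.approx(1.0)

    def test_reversed_columns_anticorrelate(self):
        atlas = _atlas({"a": [1, 2, 3], "b": [3, 2, 1]})
        assert correlation_matrix(atlas).r.at["a", "b"] == pytest.approx(-1.0)

    def test_closed_form_value(self):
        # r([1,2,4],[2,2,5]) = 5 / sqrt((42/9)*6) = 0.944911...
        atlas = _atlas({"a": [1, 2, 4], "b": [2, 2, 5]})
        assert correlation_matrix(atlas).r.at["a", "b"] == pytest.approx(
            0.9449, abs=5e-5)

    def test_zero_variance_is_missing_and_flagged(self):
        atlas = _atlas({"a": [1, 2, 3], "flat": [2, 2, 2]})
        cm = correlation_matrix(atlas)
        assert cm.degenerate == ("flat",)
        assert np.isnan(cm.r.at["a", "flat"])
        assert np.isnan(cm.r.at["flat", "flat"])
        assert cm.r.at["a", "a"] == 1.0

    def test_symmetric_unit_diagonal_and_gene_permutation_invariant(
            self, random_atlas_factory):
        atlas = random_atlas_factory(11)
        cm = correlation_matrix(atlas)
        r = cm.r.to_numpy()
        assert np.allclose(r, r.T, equal_nan=True)
        assert np.allclose(np.diag(r), 1.0)
        assert np.nanmax(np.abs(r)) <= 1 + 1e-12
        shuffled = ExpressionAtlas(atlas.data.sample(frac=1, random_state=5))
        assert np.allclose(correlation_matrix(shuffled).r.to_numpy(), r,
                           equal_nan=True)

    def test_log_transform_changes_result(self, random_atlas_factory):
        atlas = random_atlas_factory(2)
        raw = correlation_matrix(atlas, "identity").r
        logd = correlation_matrix(atlas, "log2p1").r
        assert not np.allclose(raw.to_numpy(), logd.to_numpy())

    def test_too_few_genes_or_bad_transform(self):
        atlas = _atlas({"a": [1.0], "b": [2.0]})
        with pytest.raises(ValueError, match="at least 2 genes"):
            correlation_matrix(atlas)
        atlas2 = _atlas({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError, match="transform"):
            correlation_matrix(atlas2, "sqrt")


class TestPruneRedundantTissues:
    @staticmethod
    def _cm(names, r):
        return CorrelationMatrix(pd.DataFrame(r, index=names, columns=names))

    def test_threshold_one_without_duplicates_keeps_all(self):
        cm = self._cm(["a", "b"], [[1.0, 0.5], [0.5, 1.0]])
        assert prune_redundant_tissues(cm, 1.0, ["a", "b"]) == ["a", "b"]

    def test_duplicate_columns_keep_earlier_priority(self):
        atlas = _atlas({"a": [1, 2, 3], "b": [1, 2, 3], "c": [9, 1, 4]})
        cm = correlation_matrix(atlas)
        assert prune_redundant_tissues(cm, 1.0, ["b", "a", "c"]) == ["b", "c"]

    def test_greedy_example_matches_brute_force(self):
        cm = self._cm(
            ["A", "B", "C"],
            [[1.0, 0.99, 0.2], [0.99, 1.0, 0.2], [0.2, 0.2, 1.0]],
        )
        assert prune_redundant_tissues(cm, 0.95, ["A", "B", "C"]) == ["A", "C"]

    def test_greedy_contract_on_random_matrices(self):
        # retained tissues are pairwise below threshold; every dropped tissue
        # has an earlier retained tissue at or above threshold
        rng = np.random.default_rng(8)
        for _ in range(30):
            n = int(rng.integers(2, 7))
            x = rng.random((n, n))
            r = (x + x.T) / 2
            np.fill_diagonal(r, 1.0)
            names = [f"t{i}" for i in range(n)]
            cm = self._cm(names, r)
            thr = float(rng.uniform(0.3, 1.0))
            prio = list(rng.permutation(names))
            kept = prune_redundant_tissues(cm, thr, prio)
            kept_set = set(kept)
            for i, a in enumerate(kept):
                for b in kept[:i]:
                    assert cm.r.at[a, b] < thr
            for t in prio:
                if t not in kept_set:
                    earlier = [k for k in prio[:prio.index(t)] if k in kept_set]
                    assert any(cm.r.at[t, k] >= thr for k in earlier)

    def test_validation(self):
        cm = self._cm(["a", "b"], [[1.0, 0.2], [0.2, 1.0]])
        with pytest.raises(ValueError, match="r_threshold"):
            prune_redundant_tissues(cm, 0.0, ["a", "b"])
        with pytest.raises(ValueError, match="permutation"):
            prune_redundant_tissues(cm, 0.9, ["a"])
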
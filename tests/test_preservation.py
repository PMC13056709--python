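import numpy as np
import pandas as pd
import pytest

from txfidelity import (
    CountMatrix,
    FoldChangeProfile,
    ValidationError,
    build_profiles,
    compile_gene_universe,
    composition,
    preservation_matrix,
)
from txfidelity import preservation as pres_mod
from txfidelity.simulate import allocate_counts


def _profile(cell_type, timepoint, genes, log2fc, significant):
    table = pd.DataFrame(
        {
            "gene_id": genes,
            "mean_target": 1.0,
            "mean_baseline": 1.0,
            "log2fc": log2fc,
            "p_raw": 0.5,
            "p_adj": np.where(significant, 0.01, 0.9),
            "significant": significant,
        }
    )
    return FoldChangeProfile(cell_type, timepoint, table, 30)


class TestBuildProfiles:
    def test_literal_day14_copies_reproduce_day0_profiles(self, small_experiment):
        day0, _, truth = small_experiment
        copies = CountMatrix(
            day0.values.copy(),
            day0.gene_ids,
            np.array([c.replace("d0", "d14cp") for c in day0.cell_ids], dtype=object),
        )
        counts = CountMatrix.concat_cells([day0, copies])
        cells = pd.concat(
            [
                pd.DataFrame(
                    {"cell_id": day0.cell_ids, "sample_id": "S1",
                     "timepoint": "day0", "label": truth.cell_labels_day0}
                ),
                pd.DataFrame(
                    {"cell_id": copies.cell_ids, "sample_id": "S1",
                     "timepoint": "day14", "label": truth.cell_labels_day0}
                ),
            ],
            ignore_index=True,
        )
        p0, p14 = build_profiles(counts, cells)
        assert set(p0) == set(p14)
        for t in p0:
            assert np.allclose(
                p0[t].table["log2fc"], p14[t].table["log2fc"], atol=1e-12
            )

    def test_type_absent_at_day14_gets_no_substituted_profile(self, small_counts, small_cells):
        cells = small_cells.copy()
        victim = cells.loc[cells["timepoint"] == "day14", "label"].iloc[0]
        cells = cells[~((cells["timepoint"] == "day14") & (cells["label"] == victim))]
        p0, p14 = build_profiles(small_counts, cells)
        assert victim in p0 and victim not in p14

    def test_day14_baseline_excludes_only_the_counterpart(self, small_counts, small_cells, monkeypatch):
        recorded = {}
        real_run_de = pres_mod.run_de

        def spy(counts, target, baseline, cfg):
            key = (len(target), len(baseline))
            recorded.setdefault(len(recorded), key)
            return real_run_de(counts, target, baseline, cfg)

        monkeypatch.setattr(pres_mod, "run_de", spy)
        p0, p14 = build_profiles(small_counts, small_cells)
        d0 = small_cells[small_cells["timepoint"] == "day0"]
        d14 = small_cells[small_cells["timepoint"] == "day14"]
        n_day0 = len(d0)
        calls = list(recorded.values())
        day0_calls = calls[: len(p0)]
        day14_calls = calls[len(p0) :]
        for t, (n_target, n_baseline) in zip(p0, day0_calls):
            assert n_target == (d0["label"] == t).sum()
            assert n_baseline == n_day0 - n_target
        for t, (n_target, n_baseline) in zip(p14, day14_calls):
            assert n_target == (d14["label"] == t).sum()
            assert n_baseline == n_day0 - (d0["label"] == t).sum()

    def test_small_types_skipped(self, small_counts, small_cells):
        p0, _ = build_profiles(small_counts, small_cells, min_cells=10**6)
        assert p0 == {}


class TestGeneUniverse:
    def test_union_of_significant_sets(self):
        a = _profile("A", "day0", ["a", "b", "c"], [1, 0, -1], [True, True, False])
        b = _profile("B", "day0", ["a", "b", "c"], [0, 1, 1], [False, True, True])
        assert compile_gene_universe([a, b]) == ["a", "b", "c"]

    def test_day14_exclusion_flag(self):
        a = _profile("A", "day0", ["a", "b"], [1, 0], [True, False])
        b = _profile("A", "day14", ["a", "b"], [0, 1], [False, True])
        assert compile_gene_universe([a, b], include_day14=False) == ["a"]
        assert compile_gene_universe([a, b], include_day14=True) == ["a", "b"]

    def test_no_significant_genes_is_an_error(self):
        a = _profile("A", "day0", ["a"], [0.0], [False])
        with pytest.raises(ValidationError, match="significan"):
            compile_gene_universe([a])

    def test_matches_brute_force_union(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(60)]
        profiles = [
            _profile(f"T{j}", "day0", genes, rng.normal(size=60), rng.random(60) < 0.2)
            for j in range(5)
        ]
        expected = sorted(set().union(*[p.significant_genes for p in profiles]))
        assert compile_gene_universe(profiles) == expected


class TestPreservationMatrix:
    def _pair(self, fc14, fc0, genes=None):
        genes = genes or list("abc")
        sig = [True] * len(genes)
        p14 = {"T": _profile("T", "day14", genes, fc14, sig)}
        p0 = {"T": _profile("T", "day0", genes, fc0, sig)}
        return p0, p14

    def test_perfect_linear_correlation(self):
        p0, p14 = self._pair([1, 0, -1], [2, 0, -2])
        m = preservation_matrix(p0, p14, list("abc"))
        assert np.isclose(m.r.loc["T", "T"], 1.0)

    def test_anti_correlation(self):
        p0, p14 = self._pair([1, 0, -1], [-1, 0, 1])
        assert np.isclose(preservation_matrix(p0, p14, list("abc")).r.loc["T", "T"], -1.0)

    def test_hand_computed_pearson(self):
        # r((1,2,3),(1,2,4)) = 9 / sqrt(84)
        p0, p14 = self._pair([1, 2, 3], [1, 2, 4])
        assert np.isclose(preservation_matrix(p0, p14, list("abc")).r.loc["T", "T"], 9 / np.sqrt(84))

    def test_constant_vector_is_undefined_not_zero(self):
        p0, p14 = self._pair([1, 1, 1], [1, 2, 4])
        assert np.isnan(preservation_matrix(p0, p14, list("abc")).r.loc["T", "T"])

    def test_small_universe_rejected(self):
        p0, p14 = self._pair([1, 2], [1, 2], genes=list("ab"))
        with pytest.raises(ValidationError, match="universe"):
            preservation_matrix(p0, p14, list("ab"))

    def test_missing_universe_gene_is_an_error(self):
        p0, p14 = self._pair([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValidationError, match="missing"):
            preservation_matrix(p0, p14, list("abcz"))

    def test_everywhere_nonsignificant_gene_leaves_matrix_unchanged(self):
        genes = [f"g{i}" for i in range(10)]
        rng = np.random.default_rng(9)
        sig = [True] * 10
        fc14, fc0 = rng.normal(size=10), rng.normal(size=10)
        p14 = {"T": _profile("T", "day14", genes, fc14, sig)}
        p0 = {"T": _profile("T", "day0", genes, fc0, sig)}
        base_universe = compile_gene_universe([p0["T"], p14["T"]])
        base = preservation_matrix(p0, p14, base_universe)

        genes2 = genes + ["extra"]
        p14b = {"T": _profile("T", "day14", genes2, list(fc14) + [3.0], sig + [False])}
        p0b = {"T": _profile("T", "day0", genes2, list(fc0) + [-3.0], sig + [False])}
        universe2 = compile_gene_universe([p0b["T"], p14b["T"]])
        assert universe2 == base_universe  # non-significant gene never enters
        again = preservation_matrix(p0b, p14b, universe2)
        assert np.allclose(base.r.to_numpy(), again.r.to_numpy())


class TestComposition:
    def test_simple_fraction(self):
        cells = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(10)],
                "sample_id": "S1",
                "timepoint": "day0",
                "label": ["A"] * 4 + ["B"] * 6,
            }
        )
        table = composition(cells)
        assert table.set_index("label").loc["A", "fraction"] == 0.4

    def test_fractions_sum_to_one_per_group(self, small_cells):
        table = composition(small_cells)
        sums = table.groupby(["sample_id", "timepoint"])["fraction"].sum()
        assert np.allclose(sums, 1.0)

    def test_configured_neuron_depletion_recovered(self, small_cells, small_config):
        table = composition(small_cells)
        spec = small_config.cell_types[0]
        got = table.set_index(["timepoint", "label"]).loc[("day14", spec.name), "fraction"]
        expected = (
            allocate_counts(
                [t.day14_fraction for t in small_config.cell_types],
                small_config.n_cells_day14,
            )[0]
            / small_config.n_cells_day14
        )
        assert abs(got - expected) < 1e-12
        assert abs(got - spec.day14_fraction) < 0.05
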
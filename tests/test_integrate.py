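import numpy as np
import pandas as pd
import pytest

from dystromon.integrate import (
    csv_index,
    eigengene_cross_correlation,
    hub_sensor_scan,
    module_overlap,
)
from dystromon.network import CoexpressionNetwork, ModulePartition, tom_similarity

from oracles import csv_oracle, jaccard_overlap_oracle


def _partition(assignment: dict, all_genes) -> ModulePartition:
    labels = tuple(assignment.get(g, "grey") for g in all_genes)
    return ModulePartition(gene_ids=tuple(all_genes), labels=labels)


def _network(genes, adjacency) -> CoexpressionNetwork:
    return CoexpressionNetwork(gene_ids=tuple(genes), soft_power=6,
                               adjacency=adjacency, tom=tom_similarity(adjacency))


class TestModuleOverlap:
    def test_identical_modules(self):
        genes = [f"g{i}" for i in range(10)]
        assign = {g: "blue" for g in genes[:5]}
        tab = module_overlap(_partition(assign, genes), _partition(assign, genes))
        row = tab.iloc[0]
        assert row["jaccard"] == 1.0 and row["overlap_coef"] == 1.0

    def test_worked_three_gene_example(self):
        genes = ["g1", "g2", "g3", "g4", "g5"]
        pa = _partition({"g1": "m", "g2": "m", "g3": "m"}, genes)
        pb = _partition({"g2": "m", "g3": "m", "g4": "m"}, genes)
        row = module_overlap(pa, pb).iloc[0]
        assert row["jaccard"] == pytest.approx(0.5)
        assert row["overlap_coef"] == pytest.approx(2 / 3)

    def test_subset_module_has_unit_overlap(self):
        genes = [f"g{i}" for i in range(12)]
        pa = _partition({g: "small" for g in genes[:4]}, genes)
        pb = _partition({g: "big" for g in genes[:10]}, genes)
        row = module_overlap(pa, pb).iloc[0]
        assert row["overlap_coef"] == 1.0
        assert row["jaccard"] == pytest.approx(4 / 10)

    def test_jaccard_never_exceeds_overlap_on_random_partitions(self, rng):
        genes = [f"g{i}" for i in range(60)]
        for _ in range(20):
            la = {g: f"m{rng.integers(3)}" for g in genes if rng.random() > 0.3}
            lb = {g: f"k{rng.integers(3)}" for g in genes if rng.random() > 0.3}
            tab = module_overlap(_partition(la, genes), _partition(lb, genes))
            ok = tab["jaccard"] <= tab["overlap_coef"] + 1e-12
            assert ok.all()
            # spot-check one pair against the set-arithmetic oracle
            row = tab.iloc[0]
            sa = {g for g, m in la.items() if m == row["module_a"]}
            sb = {g for g, m in lb.items() if m == row["module_b"]}
            if sa and sb:
                j, o = jaccard_overlap_oracle(sa, sb)
                assert row["jaccard"] == pytest.approx(j)
                assert row["overlap_coef"] == pytest.approx(o)


class TestCsvIndex:
    def _setup(self, rng, n=50):
        genes = [f"g{i}" for i in range(n)]
        a1 = np.abs(np.corrcoef(rng.normal(size=(n, 20)))) ** 6
        a2 = np.abs(np.corrcoef(rng.normal(size=(n, 20)))) ** 6
        np.fill_diagonal(a1, 1.0)
        np.fill_diagonal(a2, 1.0)
        assign = {g: ("blue" if i < 20 else "red") for i, g in enumerate(genes) if i < 35}
        part = _partition(assign, genes)
        return genes, part, _network(genes, a1), _network(genes, a2)

    def test_native_network_scores_hundred_percent(self, rng):
        genes, part, net1, _ = self._setup(rng)
        overall, per_mod = csv_index(part, net1, net1, edge_quantile=0.05)
        assert overall == pytest.approx(100.0)

    def test_zero_edge_foreign_network_scores_zero(self, rng):
        genes, part, net1, _ = self._setup(rng)
        empty = CoexpressionNetwork(gene_ids=tuple(genes), soft_power=6,
                                    adjacency=np.eye(len(genes)),
                                    tom=np.eye(len(genes)))
        overall, _ = csv_index(part, net1, empty, edge_quantile=0.05)
        assert overall == pytest.approx(0.0)

    def test_matches_pair_enumeration_oracle(self, rng):
        from dystromon.integrate import _binarize
        genes, part, net1, net2 = self._setup(rng)
        overall, _ = csv_index(part, net1, net2, edge_quantile=0.10)
        native = _binarize(net1, genes, 0.10)
        foreign = _binarize(net2, genes, 0.10)
        assert overall == pytest.approx(csv_oracle(list(part.labels), native, foreign))


class TestEigengeneCrossCorrelation:
    def test_identical_eigengenes_give_unit_correlation(self, rng):
        e = rng.normal(size=20)
        tab = eigengene_cross_correlation({"blue": e}, {"pink": e},
                                          np.arange(20), np.arange(20))
        assert tab["r"].iloc[0] == pytest.approx(1.0)
        assert tab["p"].iloc[0] <= np.finfo(float).tiny

    def test_report_invariant_to_label_renaming(self, rng):
        ea = {f"m{i}": rng.normal(size=15) for i in range(3)}
        eb = {f"k{i}": rng.normal(size=15) for i in range(2)}
        idx = np.arange(15)
        t1 = eigengene_cross_correlation(ea, eb, idx, idx)
        renamed = {f"renamed_{k}": v for k, v in ea.items()}
        t2 = eigengene_cross_correlation(renamed, eb, idx, idx)
        assert np.allclose(np.sort(t1["r"]), np.sort(t2["r"]))
        assert np.allclose(np.sort(t1["adj_p"]), np.sort(t2["adj_p"]))

    def test_too_few_matched_samples_rejected(self, rng):
        e = rng.normal(size=20)
        with pytest.raises(ValueError, match="matched"):
            eigengene_cross_correlation({"a": e}, {"b": e}, [0, 1], [0, 1])

    def test_null_coupling_controls_false_positives(self, rng):
        # independent tissues: few pairs pass BH at 0.05
        flags = []
        for _ in range(30):
            ea = {f"m{i}": rng.normal(size=20) for i in range(4)}
            eb = {f"k{i}": rng.normal(size=20) for i in range(4)}
            tab = eigengene_cross_correlation(ea, eb, np.arange(20), np.arange(20))
            flags.append((tab["adj_p"] < 0.05).mean())
        assert np.mean(flags) <= 0.05


class TestHubSensorScan:
    def test_hub_equal_to_eigengene_tops_table(self, rng):
        me = rng.normal(size=18)
        blood_expr = np.vstack([me, rng.normal(size=(4, 18))])
        genes = [f"b{i}" for i in range(5)]
        tab = hub_sensor_scan(blood_expr, genes, {"blue": ["b0", "b1"]},
                              {"pink": me}, np.arange(18), np.arange(18))
        top = tab.iloc[0]
        assert top["hub_gene"] == "b0" and top["r"] == pytest.approx(1.0)

    def test_zero_variance_hub_skipped_with_warning(self, rng, caplog):
        blood_expr = np.vstack([np.zeros(18), rng.normal(size=(1, 18))])
        with caplog.at_level("WARNING", logger="dystromon"):
            tab = hub_sensor_scan(blood_expr, ["b0", "b1"], {"blue": ["b0", "b1"]},
                                  {"pink": rng.normal(size=18)},
                                  np.arange(18), np.arange(18))
        assert "b0" not in set(tab["hub_gene"])
        assert "zero variance" in caplog.text

    def test_planted_sensor_detected(self, rng):
        # a blood gene loading on the shared factor of a muscle module is
        # flagged at FDR 0.05 with high probability at rho = 0.8, n = 20
        hits = 0
        for _ in range(10):
            f = rng.normal(size=20)
            me = 0.95 * f + np.sqrt(1 - 0.95 ** 2) * rng.normal(size=20)
            sensor = 0.8 * f + np.sqrt(1 - 0.8 ** 2) * rng.normal(size=20)
            blood_expr = np.vstack([sensor, rng.normal(size=(9, 20))])
            genes = [f"b{i}" for i in range(10)]
            hubs = {"blue": genes[:5]}
            tab = hub_sensor_scan(blood_expr, genes, hubs, {"pink": me},
                                  np.arange(20), np.arange(20))
            top = tab.set_index("hub_gene")
            hits += bool(top.loc["b0", "adj_p"] < 0.05)
        assert hits >= 8

    def test_null_scan_controls_false_positives(self, rng):
        fps = []
        for _ in range(30):
            blood_expr = rng.normal(size=(10, 20))
            genes = [f"b{i}" for i in range(10)]
            tab = hub_sensor_scan(blood_expr, genes, {"blue": genes[:5]},
                                  {f"m{i}": rng.normal(size=20) for i in range(3)},
                                  np.arange(20), np.arange(20))
            fps.append((tab["adj_p"] < 0.05).sum())
        assert np.mean(fps) <= 0.05 * 15 + 0.2
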
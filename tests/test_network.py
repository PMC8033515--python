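import numpy as np
import pytest

from dystromon.network import (
    GREY,
    adjacency_matrix,
    build_network,
    detect_modules,
    kme_hubs,
    module_eigengene,
    pick_soft_power,
    scale_free_fit,
    tom_similarity,
)

from oracles import power_iteration_eigengene, tom_oracle


def _module_expr(rng, sizes=(60, 60), loading=0.9, n_noise=60, n_samples=30):
    """Latent-factor expression with planted modules plus background genes."""
    total = sum(sizes) + n_noise
    f = rng.standard_normal((len(sizes), n_samples))
    expr = rng.standard_normal((total, n_samples)) * np.sqrt(1 - loading ** 2)
    start = 0
    truth = np.full(total, -1)
    for m, size in enumerate(sizes):
        expr[start:start + size] += loading * f[m]
        truth[start:start + size] = m
    expr[sum(sizes):] = rng.standard_normal((n_noise, n_samples))
    return expr, truth


class TestTom:
    def test_matches_triple_loop_oracle(self, rng):
        r = np.corrcoef(rng.normal(size=(30, 15)))
        a = np.abs(r) ** 6
        np.fill_diagonal(a, 1.0)
        assert np.allclose(tom_similarity(a), tom_oracle(a), atol=1e-12)

    def test_no_common_neighbors_reduces_to_direct_adjacency_term(self):
        # two genes connected only to each other
        a = np.eye(4)
        a[0, 1] = a[1, 0] = 0.6
        a[2, 3] = a[3, 2] = 0.2
        tom = tom_similarity(a)
        k = a.sum(axis=0) - 1
        assert tom[0, 1] == pytest.approx(0.6 / (min(k[0], k[1]) + 1 - 0.6))

    def test_unit_edge_with_identical_binary_neighborhoods_gives_one(self):
        # a_01 = 1 and genes 0, 1 share exactly the same unit-weight neighbors
        a = np.eye(5)
        for u in (2, 3):
            a[0, u] = a[u, 0] = 1.0
            a[1, u] = a[u, 1] = 1.0
        a[0, 1] = a[1, 0] = 1.0
        tom = tom_similarity(a)
        assert tom[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_asymmetric_adjacency_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(a)


class TestEigengene:
    def test_identical_profiles_explain_all_variance(self, rng):
        profile = rng.normal(size=12)
        expr = np.tile(profile, (5, 1)) * rng.uniform(0.5, 2, 5)[:, None]
        eig, ve = module_eigengene(expr)
        assert ve == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std()
        assert np.allclose(np.abs(np.corrcoef(eig, z)[0, 1]), 1.0)

    def test_negating_members_flips_eigengene_not_kme_magnitude(self, rng):
        expr = rng.normal(size=(8, 15))
        eig, _ = module_eigengene(expr)
        eig_neg, _ = module_eigengene(-expr)
        assert np.allclose(eig_neg, -eig, atol=1e-10)

    def test_matches_power_iteration_oracle(self, rng):
        expr = rng.normal(size=(20, 25))
        eig, ve = module_eigengene(expr)
        eig_o, ve_o = power_iteration_eigengene(expr)
        assert np.allclose(np.abs(eig), np.abs(eig_o / np.linalg.norm(eig_o)
                                               * np.linalg.norm(eig)), atol=1e-8)
        assert ve == pytest.approx(ve_o, abs=1e-8)

    def test_too_small_module_rejected(self, rng):
        with pytest.raises(ValueError):
            module_eigengene(rng.normal(size=(1, 10)))


class TestSoftPower:
    def test_single_candidate_returned_with_warning(self, rng, caplog):
        expr, _ = _module_expr(rng)
        with caplog.at_level("WARNING", logger="dystromon"):
            power, r2 = pick_soft_power(expr, candidates=(4,), target_r2=0.99)
        assert power == 4

    def test_equicorrelation_falls_back_to_six(self, rng, caplog):
        # exact equicorrelation: connectivity is constant, no scale-free fit
        f = rng.standard_normal(40)
        expr = 0.9 * f[None, :] + 0.1 * rng.standard_normal((80, 40))
        with caplog.at_level("WARNING", logger="dystromon"):
            power, _ = pick_soft_power(expr, target_r2=0.95)
        assert power == 6
        assert "falling back" in caplog.text

    def test_too_few_genes_rejected(self, rng):
        with pytest.raises(ValueError, match="50 genes"):
            pick_soft_power(rng.normal(size=(20, 10)))


class TestDetectModules:
    def test_planted_modules_recovered(self, rng):
        expr, truth = _module_expr(rng)
        a = adjacency_matrix(expr, 6)
        part = detect_modules(tom_similarity(a), expr, range(len(truth)))
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(truth, part.labels) >= 0.8

    def test_pure_noise_is_mostly_grey(self, rng):
        expr = rng.standard_normal((200, 30))
        a = adjacency_matrix(expr, 6)
        part = detect_modules(tom_similarity(a), expr, range(200))
        assert part.labels.count(GREY) / 200 >= 0.9

    def test_duplicated_module_merged_by_eigengene_step(self, rng):
        expr, truth = _module_expr(rng, sizes=(40,), n_noise=40)
        # append a copy of the module: correlation 1 with the original
        dup = np.vstack([expr, expr[:40] + 1e-6 * rng.standard_normal((40, 30))])
        a = adjacency_matrix(dup, 6)
        part = detect_modules(tom_similarity(a), dup, range(len(dup)))
        labels_orig = {part.labels[i] for i in range(40)}
        labels_dup = {part.labels[i] for i in range(len(expr), len(expr) + 40)}
        assert labels_orig == labels_dup and GREY not in labels_orig

    def test_deterministic_given_expression(self, rng):
        expr, _ = _module_expr(rng)
        a = adjacency_matrix(expr, 6)
        tom = tom_similarity(a)
        p1 = detect_modules(tom, expr, range(expr.shape[0]))
        p2 = detect_modules(tom, expr, range(expr.shape[0]))
        assert p1.labels == p2.labels

    def test_labels_ordered_by_module_size(self, rng):
        expr, _ = _module_expr(rng, sizes=(70, 40), n_noise=50)
        a = adjacency_matrix(expr, 6)
        part = detect_modules(tom_similarity(a), expr, range(expr.shape[0]))
        sizes = {m: part.labels.count(m) for m in part.module_labels}
        if {"turquoise", "blue"} <= set(sizes):
            assert sizes["turquoise"] >= sizes["blue"]


class TestKmeHubs:
    def test_gene_equal_to_eigengene_is_top_hub(self, rng):
        expr, truth = _module_expr(rng, sizes=(40,), n_noise=40)
        a = adjacency_matrix(expr, 6)
        part = detect_modules(tom_similarity(a), expr, range(expr.shape[0]))
        mod = part.module_labels[0]
        # plant a member tracking the eigengene exactly
        expr2 = expr.copy()
        idx0 = [i for i, l in enumerate(part.labels) if l == mod][0]
        expr2[idx0] = part.eigengenes[mod]
        part2 = detect_modules(tom_similarity(adjacency_matrix(expr2, 6)),
                               expr2, range(expr2.shape[0]))
        mod2 = part2.labels[idx0]
        hubs = kme_hubs(expr2, part2, top_k=5)
        assert idx0 in hubs[mod2]
        assert part2.kme[idx0] >= max(part2.kme[g] for g in part2.members(mod2)) - 1e-9

    def test_grey_genes_have_no_kme(self, rng):
        expr, truth = _module_expr(rng)
        a = adjacency_matrix(expr, 6)
        part = detect_modules(tom_similarity(a), expr, range(expr.shape[0]))
        grey = [g for g, l in zip(part.gene_ids, part.labels) if l == GREY]
        assert all(g not in part.kme for g in grey)

    def test_small_module_returns_all_members(self, rng):
        expr, _ = _module_expr(rng, sizes=(35,), n_noise=40)
        a = adjacency_matrix(expr, 6)
        part = detect_modules(tom_similarity(a), expr, range(expr.shape[0]),
                              min_size=30)
        for mod, hub_list in kme_hubs(expr, part, top_k=100).items():
            assert len(hub_list) == len(part.members(mod))


def test_scale_free_r2_high_for_powerlaw_degrees(rng):
    # block-structured adjacency with heavy-tailed connectivity
    expr, _ = _module_expr(rng, sizes=(50, 30, 20), loading=0.85, n_noise=100)
    a = adjacency_matrix(expr, 6)
    assert 0.0 <= scale_free_fit(a) <= 1.0
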
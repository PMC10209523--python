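"""Similarity metrics: built-in formulas, registry, and oracle agreement."""

import math

import pytest

from hetpaths import (
    MetaPath,
    MetaPathError,
    MetricContext,
    MetricError,
    MetricSpec,
    build_graph,
    default_registry,
    dwpc,
    normalized_path_count,
    path_count,
    pathsim,
    precompute_adjacency,
    register_metric,
    score_pair,
)

import oracles
from conftest import RDPF, RDR, random_graph, random_metapath, sample_typed_pair

TOL = 1e-9


class TestFixtureValues:
    """Scores on the FIX1 reference graph, frozen from independent enumeration."""

    def test_path_count(self, fix1_ctx):
        r = path_count(fix1_ctx, "r1", "f1", RDPF)
        assert r.score == 2 and r.path_count == 2

    def test_normalized_path_count(self, fix1_ctx):
        # 2 paths r1->f1; marginals: 2 out of r1, 4 into f1 (two per drug)
        r = normalized_path_count(fix1_ctx, "r1", "f1", RDPF)
        assert r.score == pytest.approx(2 * 2 / (2 + 4), abs=TOL)

    def test_dwpc_is_sum_of_path_degree_products(self, fix1_ctx):
        # both RDPF paths have PDP (1*2 * 2*1 * 1*2)^-w = 8^-0.4
        r = dwpc(fix1_ctx, "r1", "f1", RDPF, w=0.4)
        assert r.score == pytest.approx(2 * 8 ** -0.4, abs=TOL)

    def test_pathsim_peer_drugs(self, fix1_ctx):
        assert pathsim(fix1_ctx, "r1", "r2", RDR).score == pytest.approx(1.0, abs=TOL)

    def test_pathsim_self_is_one_when_supported(self, fix1_ctx):
        assert pathsim(fix1_ctx, "r1", "r1", RDR).score == pytest.approx(1.0, abs=TOL)

    def test_disconnected_pair_scores_zero_not_error(self):
        g = build_graph(
            [("r1", "d1"), ("r2", "d2")],
            [("r1", "drug"), ("r2", "drug"), ("d1", "disease"), ("d2", "disease")],
        )
        ctx = MetricContext(precompute_adjacency(g))
        m = MetaPath.of("drug", "disease")
        assert path_count(ctx, "r1", "d2", m).score == 0
        assert normalized_path_count(ctx, "r1", "d2", m).score == 0
        assert pathsim(ctx, "r1", "r2", RDR).score == 0  # no disease co-neighbors


class TestDwpc:
    @pytest.mark.parametrize("seed", [61, 62])
    def test_w_zero_reduces_exactly_to_path_count(self, seed):
        g = random_graph(seed, n_per_type=15)
        ctx = MetricContext(precompute_adjacency(g))
        m = random_metapath(seed, max_types=4)
        pair = sample_typed_pair(g, m, seed)
        if pair is None:
            pytest.skip("no endpoint nodes")
        u, v = pair
        assert dwpc(ctx, u, v, m, w=0.0).score == path_count(ctx, u, v, m).score

    def test_exponent_out_of_range_rejected(self, fix1_ctx):
        with pytest.raises(MetricError):
            dwpc(fix1_ctx, "r1", "f1", RDPF, w=1.5)

    def test_hub_inflation_is_damped(self):
        """Raising a hub's degree strictly lowers DWPC through it for w > 0."""
        def star(extra_drugs):
            types = [("r1", "drug"), ("d1", "disease"), ("p1", "protein")]
            edges = [("r1", "d1"), ("d1", "p1")]
            for i in range(extra_drugs):
                types.append((f"x{i}", "drug"))
                edges.append((f"x{i}", "d1"))
            g = build_graph(edges, types)
            return MetricContext(precompute_adjacency(g))

        m = MetaPath.of("drug", "disease", "protein")
        small = dwpc(star(0), "r1", "p1", m, w=0.4).score
        large = dwpc(star(5), "r1", "p1", m, w=0.4).score
        assert large < small


class TestPathSim:
    def test_requires_symmetric_metapath(self, fix1_ctx):
        with pytest.raises(MetaPathError, match="symmetric"):
            pathsim(fix1_ctx, "r1", "f1", RDPF)

    def test_force_uses_round_trip(self, fix1_ctx):
        r = pathsim(fix1_ctx, "r1", "r2", MetaPath.of("drug", "disease", "protein"), force=True)
        assert 0.0 <= r.score <= 1.0

    def test_symmetric_in_arguments(self, fix1_ctx):
        assert pathsim(fix1_ctx, "r1", "r2", RDR).score == pathsim(fix1_ctx, "r2", "r1", RDR).score


class TestRegistry:
    def test_custom_metric_dispatch(self, fix1_ctx):
        reg = default_registry()
        exists = MetricSpec("path-exists", lambda ctx, u, v, m, paths: float(len(paths) > 0))
        register_metric(reg, exists)
        r = score_pair(fix1_ctx, "r1", "f1", RDPF, "path-exists", registry=reg)
        assert r.score == 1.0 and r.path_count == 2

    def test_builtin_name_collision_rejected(self):
        reg = default_registry()
        with pytest.raises(MetricError, match="already registered"):
            register_metric(reg, MetricSpec("pc", lambda *a: 0.0))

    def test_unknown_metric_error_lists_names(self, fix1_ctx):
        with pytest.raises(MetricError, match="pathsim"):
            score_pair(fix1_ctx, "r1", "f1", RDPF, "foo")

    def test_score_pair_matches_direct_calls(self, fix1_ctx):
        assert score_pair(fix1_ctx, "r1", "f1", RDPF, "pc").score == 2
        assert score_pair(fix1_ctx, "r1", "f1", RDPF, "npc").score == pytest.approx(2 / 3, abs=TOL)


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", [71, 72, 73])
    def test_all_metrics_match_brute_force(self, seed):
        g = random_graph(seed, n_per_type=12)
        ctx = MetricContext(precompute_adjacency(g))
        m = random_metapath(seed, max_types=4)
        pair = sample_typed_pair(g, m, seed)
        if pair is None:
            pytest.skip("no endpoint nodes")
        u, v = pair
        assert path_count(ctx, u, v, m).score == oracles.brute_pc(g, u, v, m)
        assert normalized_path_count(ctx, u, v, m).score == pytest.approx(
            oracles.brute_npc(g, u, v, m), abs=TOL
        )
        assert dwpc(ctx, u, v, m, w=0.4).score == pytest.approx(
            oracles.brute_dwpc(g, u, v, m, 0.4), abs=TOL
        )
        sym = MetaPath(m.types + m.reverse().types[1:])
        assert pathsim(ctx, u, u, sym).score == pytest.approx(
            oracles.brute_pathsim(g, u, u, sym), abs=TOL
        )

    @pytest.mark.parametrize("seed", [81, 82])
    def test_range_invariants(self, seed):
        g = random_graph(seed, n_per_type=12)
        ctx = MetricContext(precompute_adjacency(g))
        m = random_metapath(seed, max_types=4)
        pair = sample_typed_pair(g, m, seed)
        if pair is None:
            pytest.skip("no endpoint nodes")
        u, v = pair
        pc = path_count(ctx, u, v, m).score
        npc = normalized_path_count(ctx, u, v, m).score
        dw = dwpc(ctx, u, v, m, w=0.4).score
        assert pc == int(pc) >= 0
        assert 0.0 <= npc <= 1.0
        assert 0.0 <= dw <= pc + TOL
        sym = MetaPath(m.types + m.reverse().types[1:])
        peers = sorted(n for n, t in g.type_of.items() if t == sym.types[0])
        for peer in peers[:3]:
            assert 0.0 <= pathsim(ctx, u, peer, sym).score <= 1.0
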
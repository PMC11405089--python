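"""Triangle-update mechanism against independent brute-force loop oracles,
plus the symmetry properties of both encoders (permutation equivariance,
rigid-motion invariance, attention normalization, residual identities)."""

import numpy as np
import pytest

from conftest import random_graph2d
from gtam.autodiff import Tensor
from gtam.gta_core import (
    CFConvInit,
    EdgeToNode,
    EncoderConfig,
    GINInit,
    GTAEncoder2D,
    GTAEncoder3D,
    NodeToEdge,
    TriangleAttention,
    TriangleMultiplicative,
    admissible_w,
)
from gtam.molio import Graph2D, build_graph3d
from gtam.pretrain import random_rotation


# ---------------------------------------------------------------------------
# numpy replicas of the layers, applied entry-by-entry in plain loops
# ---------------------------------------------------------------------------

def np_linear(layer, x):
    y = x @ layer.weight.data
    return y + layer.bias.data if layer.bias is not None else y


def np_layernorm(layer, x):
    mu = x.mean(-1, keepdims=True)
    var = ((x - mu) ** 2).mean(-1, keepdims=True)
    return (x - mu) / np.sqrt(var + layer.eps) * layer.gamma.data + layer.beta.data


def np_silu(x):
    return x / (1.0 + np.exp(-x))


def np_mlp(mlp, x):
    for i, layer in enumerate(mlp.layers):
        x = np_linear(layer, x)
        if i < len(mlp.layers) - 1:
            x = np_silu(x)
    return x


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def make_inputs(n, d, rng):
    h = rng.normal(size=(n, d))
    z = rng.normal(size=(n, n, d))
    z[np.arange(n), np.arange(n)] = 0.0
    return h, z


def graph_cases(n_graphs=20, max_nodes=8, seed=5):
    rng = np.random.default_rng(seed)
    for _ in range(n_graphs):
        n = int(rng.integers(3, max_nodes + 1))
        g = random_graph2d(n, rng)
        yield g, rng


@pytest.fixture(scope="module")
def cfg():
    return EncoderConfig(d_h=8, d_z=8, n_triangle_blocks=1, n_heads=2,
                         d_hidden=8)


class TestNodeToEdge:
    def test_matches_per_pair_loop_oracle(self, cfg):
        op = NodeToEdge(cfg, np.random.default_rng(0))
        for g, rng in graph_cases():
            n = g.n_atoms
            h, z = make_inputs(n, 8, rng)
            pm = g.adjacency()
            out = op(Tensor(h), Tensor(z), pm).data
            f = np_linear(op.proj, np_layernorm(op.norm, h))
            expect = z.copy()
            for u in range(n):
                for v in range(n):
                    if pm[u, v]:
                        expect[u, v] += np_linear(op.out, f[u] * f[v])
            assert np.allclose(out, expect, atol=1e-5)

    def test_zeroed_update_path_is_identity(self, cfg):
        op = NodeToEdge(cfg, np.random.default_rng(0))
        op.out.weight.data[:] = 0.0
        op.out.bias.data[:] = 0.0
        rng = np.random.default_rng(1)
        g = random_graph2d(5, rng)
        h, z = make_inputs(5, 8, rng)
        out = op(Tensor(h), Tensor(z), g.adjacency()).data
        assert np.array_equal(out, z)

    def test_symmetric_inputs_keep_symmetry(self, cfg):
        op = NodeToEdge(cfg, np.random.default_rng(0))
        rng = np.random.default_rng(2)
        h = np.tile(rng.normal(size=8), (2, 1))  # h_u = h_v
        z = np.zeros((2, 2, 8))
        z[0, 1] = z[1, 0] = rng.normal(size=8)
        pm = np.array([[False, True], [True, False]])
        out = op(Tensor(h), Tensor(z), pm).data
        assert np.allclose(out[0, 1], out[1, 0], atol=1e-12)


class TestTriangleMultiplicative:
    def test_matches_triple_loop_oracle_on_complete_graph(self, cfg):
        op = TriangleMultiplicative(cfg, np.random.default_rng(0))
        rng = np.random.default_rng(3)
        n = 5
        _, z = make_inputs(n, 8, rng)
        pm = ~np.eye(n, dtype=bool)
        out = op(Tensor(z), pm).data
        a = np_layernorm(op.norm_in, z)
        a[np.arange(n), np.arange(n)] = 0.0
        expect = z.copy()
        for u in range(n):
            for v in range(n):
                if not pm[u, v]:
                    continue
                s = np.zeros(8)
                found = False
                for w in range(n):
                    if w in (u, v):
                        continue
                    s += a[u, w] * a[v, w]
                    found = True
                if found:
                    gate = sigmoid(np_linear(op.gate, z[u, v]))
                    expect[u, v] += gate * np_linear(
                        op.out, np_layernorm(op.norm_sum, s))
        assert np.allclose(out, expect, atol=1e-5)

    def test_matches_oracle_on_sparse_graphs(self, cfg):
        op = TriangleMultiplicative(cfg, np.random.default_rng(0))
        for g, rng in graph_cases(n_graphs=10, seed=7):
            n = g.n_atoms
            _, z = make_inputs(n, 8, rng)
            pm = g.adjacency()
            m3 = admissible_w(pm, "intersection")
            out = op(Tensor(z), pm).data
            a = np_layernorm(op.norm_in, z)
            a[np.arange(n), np.arange(n)] = 0.0
            expect = z.copy()
            for u in range(n):
                for v in range(n):
                    if not pm[u, v] or not m3[u, v].any():
                        continue
                    s = sum(a[u, w] * a[v, w] for w in np.nonzero(m3[u, v])[0])
                    gate = sigmoid(np_linear(op.gate, z[u, v]))
                    expect[u, v] += gate * np_linear(
                        op.out, np_layernorm(op.norm_sum, s))
            assert np.allclose(out, expect, atol=1e-5)

    def test_edge_without_shared_neighbor_unchanged(self, cfg):
        # path graph 0-1-2: edge (0,1) closes no triangle
        g = Graph2D(np.ones(3, dtype=int), np.zeros(3, dtype=int),
                    np.zeros(3, dtype=bool),
                    np.array([[0, 1, 1, 2], [1, 0, 2, 1]]),
                    np.zeros(4, dtype=int))
        op = TriangleMultiplicative(cfg, np.random.default_rng(0))
        rng = np.random.default_rng(4)
        _, z = make_inputs(3, 8, rng)
        out = op(Tensor(z), g.adjacency()).data
        assert np.array_equal(out[0, 1], z[0, 1])
        assert np.array_equal(out[1, 2], z[1, 2])

    def test_saturated_negative_gate_suppresses_update(self, cfg):
        op = TriangleMultiplicative(cfg, np.random.default_rng(0))
        op.gate.weight.data[:] = 0.0
        op.gate.bias.data[:] = -50.0
        rng = np.random.default_rng(5)
        n = 4
        _, z = make_inputs(n, 8, rng)
        out = op(Tensor(z), ~np.eye(n, dtype=bool)).data
        assert np.allclose(out, z, atol=1e-4)


class TestTriangleAttention:
    def test_matches_triple_loop_oracle_complete_graph(self, cfg):
        op = TriangleAttention(cfg, np.random.default_rng(0))
        rng = np.random.default_rng(6)
        n = 6
        _, z = make_inputs(n, 8, rng)
        pm = ~np.eye(n, dtype=bool)
        out = op(Tensor(z), pm).data
        nh, dk = op.n_heads, op.d_head
        q = np_linear(op.q, z).reshape(n, n, nh, dk)
        k = np_linear(op.k, z).reshape(n, n, nh, dk)
        v = np_linear(op.v, z).reshape(n, n, nh, dk)
        b = np_linear(op.b, z)
        c = np.sqrt(dk)
        expect = z.copy()
        for u in range(n):
            for v_ in range(n):
                if u == v_:
                    continue
                ws = [w for w in range(n) if w not in (u, v_)]
                heads = []
                for head in range(nh):
                    logits = np.array([
                        q[u, v_, head] @ k[w, v_, head] / c + b[w, u, head]
                        for w in ws])
                    e = np.exp(logits - logits.max())
                    a = e / e.sum()
                    heads.append(sum(a[i] * v[u, w, head]
                                     for i, w in enumerate(ws)))
                gate = sigmoid(np_linear(op.gate, z[u, v_]))
                expect[u, v_] += gate * np.concatenate(heads)
        assert np.allclose(out, expect, atol=1e-5)

    def test_matches_oracle_on_sparse_graphs(self, cfg):
        op = TriangleAttention(cfg, np.random.default_rng(0))
        for g, rng in graph_cases(n_graphs=10, seed=8):
            n = g.n_atoms
            _, z = make_inputs(n, 8, rng)
            pm = g.adjacency()
            m3 = admissible_w(pm, "intersection")
            out = op(Tensor(z), pm).data
            nh, dk = op.n_heads, op.d_head
            q = np_linear(op.q, z).reshape(n, n, nh, dk)
            k = np_linear(op.k, z).reshape(n, n, nh, dk)
            v = np_linear(op.v, z).reshape(n, n, nh, dk)
            b = np_linear(op.b, z)
            c = np.sqrt(dk)
            expect = z.copy()
            for u in range(n):
                for v_ in range(n):
                    ws = list(np.nonzero(m3[u, v_])[0])
                    if not pm[u, v_] or not ws:
                        continue
                    heads = []
                    for head in range(nh):
                        logits = np.array([
                            q[u, v_, head] @ k[w, v_, head] / c + b[w, u, head]
                            for w in ws])
                        e = np.exp(logits - logits.max())
                        a = e / e.sum()
                        heads.append(sum(a[i] * v[u, w, head]
                                         for i, w in enumerate(ws)))
                    gate = sigmoid(np_linear(op.gate, z[u, v_]))
                    expect[u, v_] += gate * np.concatenate(heads)
            assert np.allclose(out, expect, atol=1e-5)

    def test_attention_rows_sum_to_one(self, cfg):
        op = TriangleAttention(cfg, np.random.default_rng(0))
        rng = np.random.default_rng(9)
        n = 6
        _, z = make_inputs(n, 8, rng)
        pm = ~np.eye(n, dtype=bool)
        op(Tensor(z), pm)
        m3 = admissible_w(pm, "intersection")
        sums = op.last_attention.sum(axis=2)
        for u in range(n):
            for v in range(n):
                if m3[u, v].any():
                    assert np.allclose(sums[u, v], 1.0, atol=1e-6)

    def test_single_admissible_w_degenerate_softmax(self, cfg):
        # triangle graph: for edge (0,1) the only third vertex is 2
        g = Graph2D(np.ones(3, dtype=int), np.zeros(3, dtype=int),
                    np.zeros(3, dtype=bool),
                    np.array([[0, 1, 1, 2, 0, 2], [1, 0, 2, 1, 2, 0]]),
                    np.zeros(6, dtype=int))
        op = TriangleAttention(cfg, np.random.default_rng(0))
        rng = np.random.default_rng(10)
        _, z = make_inputs(3, 8, rng)
        out = op(Tensor(z), g.adjacency()).data
        v = np_linear(op.v, z).reshape(3, 3, op.n_heads, op.d_head)
        gate = sigmoid(np_linear(op.gate, z[0, 1]))
        expect = z[0, 1] + gate * v[0, 2].reshape(-1)
        assert np.allclose(out[0, 1], expect, atol=1e-10)
        assert np.allclose(op.last_attention[0, 1, 2], 1.0)

    def test_identical_keys_split_attention_equally(self, cfg):
        op = TriangleAttention(cfg, np.random.default_rng(0))
        n = 4
        z = np.zeros((n, n, 8))  # all-equal edges -> identical k, b, v
        pm = ~np.eye(n, dtype=bool)
        op(Tensor(z), pm)
        m3 = admissible_w(pm, "intersection")
        a = op.last_attention
        assert np.allclose(a[0, 1, m3[0, 1]], 0.5, atol=1e-12)


class TestEdgeToNode:
    def test_matches_per_node_loop_oracle(self, cfg):
        op = EdgeToNode(cfg, np.random.default_rng(0))
        for g, rng in graph_cases(n_graphs=10, seed=12):
            n = g.n_atoms
            h, z = make_inputs(n, 8, rng)
            pm = g.adjacency()
            out = op(Tensor(h), Tensor(z), pm).data
            lz = np_layernorm(op.norm, z)
            expect = h.copy()
            for u in range(n):
                rows = [lz[v, u] for v in range(n) if pm[v, u]]
                cols = [lz[u, v] for v in range(n) if pm[u, v]]
                if rows:
                    expect[u] += np_mlp(op.mlp_row, np.sum(rows, axis=0))
                if cols:
                    expect[u] += np_mlp(op.mlp_col, np.sum(cols, axis=0))
            assert np.allclose(out, expect, atol=1e-5)

    def test_isolated_node_unchanged(self, cfg):
        op = EdgeToNode(cfg, np.random.default_rng(0))
        rng = np.random.default_rng(13)
        h, z = make_inputs(3, 8, rng)
        pm = np.zeros((3, 3), dtype=bool)
        pm[0, 1] = pm[1, 0] = True      # node 2 isolated
        out = op(Tensor(h), Tensor(z), pm).data
        assert np.array_equal(out[2], h[2])
        assert not np.array_equal(out[0], h[0])

    def test_symmetric_z_gives_equal_row_col_contributions(self, cfg):
        op = EdgeToNode(cfg, np.random.default_rng(0))
        # tie the two MLPs
        for la, lb in zip(op.mlp_row.layers, op.mlp_col.layers):
            lb.weight.data = la.weight.data.copy()
            lb.bias.data = la.bias.data.copy()
        rng = np.random.default_rng(14)
        h = rng.normal(size=(2, 8))
        z = np.zeros((2, 2, 8))
        z[0, 1] = z[1, 0] = rng.normal(size=8)
        pm = np.array([[False, True], [True, False]])
        out = op(Tensor(h), Tensor(z), pm).data
        lz = np_layernorm(op.norm, z)
        half = np_mlp(op.mlp_row, lz[1, 0])
        assert np.allclose(out[0], h[0] + 2 * half, atol=1e-10)


# ---------------------------------------------------------------------------
# Initialization stages
# ---------------------------------------------------------------------------

def permute_graph2d(g, perm):
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    return Graph2D(g.element_idx[perm], g.formal_charge[perm],
                   g.is_aromatic_atom[perm],
                   inv[g.edge_index], g.edge_type.copy())


class TestGINInit:
    def test_permutation_equivariance(self, cfg):
        stage = GINInit(cfg, np.random.default_rng(0))
        rng = np.random.default_rng(15)
        g = random_graph2d(6, rng)
        perm = rng.permutation(6)
        h1, z1 = stage(g)
        h2, z2 = stage(permute_graph2d(g, perm))
        # new node j carries old node perm[j]
        assert np.allclose(h2.data, h1.data[perm], atol=1e-10)
        assert np.allclose(z2.data, z1.data[np.ix_(perm, perm)], atol=1e-10)

    def test_single_node_molecule(self, cfg):
        stage = GINInit(cfg, np.random.default_rng(0))
        g = Graph2D(np.array([1]), np.array([0]), np.array([False]),
                    np.empty((2, 0), dtype=int), np.empty(0, dtype=int))
        h, z = stage(g)
        assert h.shape == (1, cfg.d_h) and np.isfinite(h.data).all()

    def test_two_hop_sensitivity_path_vs_triangle(self, cfg):
        stage = GINInit(cfg, np.random.default_rng(0))
        path = Graph2D(np.ones(3, dtype=int), np.zeros(3, dtype=int),
                       np.zeros(3, dtype=bool),
                       np.array([[0, 1, 1, 2], [1, 0, 2, 1]]),
                       np.zeros(4, dtype=int))
        tri = Graph2D(np.ones(3, dtype=int), np.zeros(3, dtype=int),
                      np.zeros(3, dtype=bool),
                      np.array([[0, 1, 1, 2, 0, 2], [1, 0, 2, 1, 2, 0]]),
                      np.zeros(6, dtype=int))
        hp, _ = stage(path)
        ht, _ = stage(tri)
        assert not np.allclose(hp.data[1], ht.data[1], atol=1e-6)


class TestCFConvInit:
    def test_rigid_motion_invariance(self, cfg):
        stage = CFConvInit(cfg, np.random.default_rng(0))
        rng = np.random.default_rng(16)
        coords = rng.normal(size=(5, 3)) * 2
        z_nums = np.array([6, 7, 8, 6, 6])
        g1 = build_graph3d(coords, z_nums)
        rot = random_rotation(rng)
        g2 = build_graph3d(coords @ rot.T + [1, 2, 3], z_nums)
        h1, e1 = stage(z_nums, Tensor(g1.distance_map))
        h2, e2 = stage(z_nums, Tensor(g2.distance_map))
        assert np.allclose(h1.data, h2.data, atol=1e-5)
        assert np.allclose(e1.data, e2.data, atol=1e-5)

    def test_edge_embedding_responds_to_distance(self, cfg):
        stage = CFConvInit(cfg, np.random.default_rng(0))
        za = np.array([6, 6])
        g_near = build_graph3d([[0, 0, 0], [1.5, 0, 0]], za)
        g_far = build_graph3d([[0, 0, 0], [3.0, 0, 0]], za)
        _, e1 = stage(za, Tensor(g_near.distance_map))
        _, e2 = stage(za, Tensor(g_far.distance_map))
        assert not np.allclose(e1.data[0, 1], e2.data[0, 1], atol=1e-6)

    def test_matches_per_node_loop_oracle(self, cfg):
        stage = CFConvInit(cfg, np.random.default_rng(0))
        rng = np.random.default_rng(17)
        coords = rng.normal(size=(5, 3)) * 2
        z_nums = np.array([6, 7, 8, 6, 7])
        g = build_graph3d(coords, z_nums)
        h, z = stage(z_nums, Tensor(g.distance_map))
        # independent loop: embedding rows, per-pair rbf filter, conv sum
        from gtam.molio import element_index
        sym = {6: "C", 7: "N", 8: "O"}
        h0 = np.stack([stage.elem_emb.weight.data[element_index(sym[int(a)])]
                       for a in z_nums])
        centers = np.linspace(0, cfg.rbf_cutoff, cfg.n_rbf)
        gamma = 1.0 / (2 * (centers[1] - centers[0]) ** 2)
        expect = np.zeros_like(h0)
        for u in range(5):
            conv = np.zeros(cfg.d_h)
            for v in range(5):
                if u == v:
                    continue
                rbf = np.exp(-gamma * (g.distance_map[u, v] - centers) ** 2)
                conv += h0[v] * np_mlp(stage.filter, rbf)
            expect[u] = h0[u] + np_mlp(stage.post, conv)
        assert np.allclose(h.data, expect, atol=1e-5)
        rbf01 = np.exp(-gamma * (g.distance_map[0, 1] - centers) ** 2)
        assert np.allclose(z.data[0, 1], np_linear(stage.z_proj, rbf01),
                           atol=1e-5)


# ---------------------------------------------------------------------------
# Full encoders
# ---------------------------------------------------------------------------

class TestEncoders:
    def test_pooled_width_is_256_by_default(self, fixtures):
        enc = GTAEncoder2D(EncoderConfig(d_h=16, d_z=16, n_triangle_blocks=1,
                                         n_heads=2, d_hidden=16), seed=0)
        state = enc(fixtures[0][0])
        assert state.pooled.shape == (256,)

    def test_2d_permutation_equivariance_and_pooled_invariance(
            self, enc2d, fixtures):
        rng = np.random.default_rng(20)
        for g2d, _ in fixtures[:4]:
            perm = rng.permutation(g2d.n_atoms)
            s1 = enc2d(g2d)
            s2 = enc2d(permute_graph2d(g2d, perm))
            assert np.allclose(s2.h.data, s1.h.data[perm], atol=1e-5)
            assert np.allclose(s2.z.data, s1.z.data[np.ix_(perm, perm)],
                               atol=1e-5)
            assert np.allclose(s2.pooled.data, s1.pooled.data, atol=1e-5)

    def test_3d_rigid_motion_invariance(self, enc3d, fixtures):
        rng = np.random.default_rng(21)
        for _, g3d in fixtures[:4]:
            ref = enc3d(g3d)
            rot = random_rotation(rng)
            moved = build_graph3d(g3d.coords @ rot.T + rng.normal(0, 4, 3),
                                  g3d.atomic_numbers)
            out = enc3d(moved)
            scale = np.abs(ref.pooled.data).max()
            assert np.abs(out.pooled.data - ref.pooled.data).max() < 1e-4 * scale
            hscale = np.abs(ref.h.data).max()
            assert np.abs(out.h.data - ref.h.data).max() < 1e-4 * hscale

    def test_3d_permutation_equivariance(self, enc3d, fixtures):
        rng = np.random.default_rng(22)
        _, g3d = fixtures[0]
        perm = rng.permutation(g3d.n_atoms)
        permuted = build_graph3d(g3d.coords[perm], g3d.atomic_numbers[perm])
        s1, s2 = enc3d(g3d), enc3d(permuted)
        assert np.allclose(s2.h.data, s1.h.data[perm], atol=1e-5)
        assert np.allclose(s2.pooled.data, s1.pooled.data, atol=1e-5)

    def test_batched_forward_equals_single_forwards(self, enc2d, enc3d,
                                                    fixtures):
        singles2 = [enc2d(g) for g, _ in fixtures]
        batch2 = enc2d.encode_batch([g for g, _ in fixtures])
        for a, b in zip(singles2, batch2):
            assert np.allclose(a.pooled.data, b.pooled.data, atol=1e-5)
        singles3 = [enc3d(g) for _, g in fixtures[:3]]
        batch3 = enc3d.encode_batch([g for _, g in fixtures[:3]])
        for a, b in zip(singles3, batch3):
            assert np.allclose(a.pooled.data, b.pooled.data, atol=1e-5)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="divisible"):
            EncoderConfig(d_z=10, n_heads=4)
        with pytest.raises(ValueError, match="positive"):
            EncoderConfig(d_h=0)

    def test_gradients_reach_every_parameter(self, small_config, fixtures):
        enc2 = GTAEncoder2D(small_config, seed=1)
        enc3 = GTAEncoder3D(small_config, seed=1)
        g2d, g3d = fixtures[0]
        s2, s3 = enc2(g2d), enc3(g3d)
        loss = (s2.pooled * s3.pooled).sum() + (s2.z * s2.z).sum() \
            + (s3.z * s3.z).sum()
        loss.backward()
        for p in list(enc2.parameters()) + list(enc3.parameters()):
            assert p.grad is not None
            assert np.isfinite(p.grad).all()
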
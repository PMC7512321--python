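"""Entropy forms, bounds, energy and temperature for undirected graphs.

Expected values here were derived from independent oracles before the
implementation existed: brute-force eigendecompositions for the spectral
examples, hand evaluation of the closed forms for the degree-statistics
examples, and hand evaluation of the per-edge fluctuation terms for the
transition examples.
"""

import math

import numpy as np
import pytest

import netthermo as nt
from netthermo.graph import GraphValidationError

from conftest import random_graph


class TestSpectralEntropy:
    def test_empty_graph_is_zero(self):
        s = nt.laplacian_spectrum(nt.build_undirected_graph(4, []))
        assert nt.entropy_spectral_exact(s) == 0.0

    def test_k2_degenerate_distribution(self, k2):
        # p = {0, 1}: a pure state has zero entropy
        assert nt.entropy_spectral_exact(nt.laplacian_spectrum(k2)) == pytest.approx(0.0, abs=1e-12)

    def test_k3_is_ln2(self, k3):
        # eigenvalues {0, 3/2, 3/2} -> p = {0, 1/2, 1/2}
        s = nt.laplacian_spectrum(k3)
        assert nt.entropy_spectral_exact(s) == pytest.approx(math.log(2), abs=1e-12)

    @pytest.mark.parametrize(
        "kind,n,expected",
        [("complete", 2, 0.0), ("complete", 3, 0.5)],
    )
    def test_quadratic_examples(self, kind, n, expected):
        s = nt.laplacian_spectrum(nt.gen_named_graph(kind, n))
        assert nt.entropy_spectral_quadratic(s) == pytest.approx(expected, abs=1e-12)

    def test_quadratic_empty_graph(self):
        s = nt.laplacian_spectrum(nt.build_undirected_graph(4, []))
        assert nt.entropy_spectral_quadratic(s) == 0.0

    def test_quadratic_equals_trace_form(self, rng):
        """sum p(1-p) == Tr[L]/n - Tr[L^2]/n^2 on random graphs."""
        for _ in range(25):
            g = random_graph(rng)
            lap = nt.normalized_laplacian(g)
            n = g.n_nodes
            trace_form = np.trace(lap) / n - np.trace(lap @ lap) / n**2
            got = nt.entropy_spectral_quadratic(nt.laplacian_spectrum(g))
            assert got == pytest.approx(trace_form, abs=1e-12)


class TestDegreeForm:
    def test_k3_printed(self, k3):
        assert nt.entropy_degree_form(k3) == pytest.approx(7 / 12, abs=1e-14)

    def test_p4_printed(self, p4):
        assert nt.entropy_degree_form(p4) == pytest.approx(43 / 64, abs=1e-14)

    def test_k2_spectral_consistent_matches_quadratic(self, k2):
        got = nt.entropy_degree_form(k2, "spectral_consistent")
        assert got == pytest.approx(0.0, abs=1e-14)

    def test_spectral_consistent_identity(self, rng):
        """c = 2 degree form reproduces the quadratic spectral entropy."""
        for _ in range(100):
            g = random_graph(rng, no_isolated=True)
            a = nt.entropy_degree_form(g, "spectral_consistent")
            b = nt.entropy_spectral_quadratic(nt.laplacian_spectrum(g))
            assert a == pytest.approx(b, abs=1e-12)

    def test_isolated_nodes_warn(self):
        g = nt.build_undirected_graph(3, [(0, 1)])
        with pytest.warns(RuntimeWarning, match="isolated"):
            nt.entropy_degree_form(g)

    @pytest.mark.parametrize("n", range(3, 51))
    def test_closed_forms(self, n):
        kn = nt.entropy_degree_form(nt.gen_named_graph("complete", n))
        pn = nt.entropy_degree_form(nt.gen_named_graph("path", n))
        assert kn == pytest.approx(1 - (2 * n - 1) / (2 * n * (n - 1)), abs=1e-14)
        assert pn == pytest.approx(1 - (5 * n + 1) / (4 * n * n), abs=1e-14)


class TestBounds:
    def test_n3_values(self):
        lo, hi = nt.entropy_bounds(3)
        assert lo == pytest.approx(5 / 9, abs=1e-14)
        assert hi == pytest.approx(7 / 12, abs=1e-14)

    def test_n4_lower_is_p4(self, p4):
        lo, _ = nt.entropy_bounds(4)
        assert lo == pytest.approx(0.671875, abs=1e-14)
        assert nt.entropy_degree_form(p4) == pytest.approx(lo, abs=1e-14)

    def test_ordering_and_validation(self):
        for n in range(3, 30):
            lo, hi = nt.entropy_bounds(n)
            assert lo < hi
        with pytest.raises(GraphValidationError):
            nt.entropy_bounds(2)

    def test_connected_samples_respect_bounds(self, rng):
        checked = 0
        while checked < 50:
            g = random_graph(rng, n_min=4, n_max=25, p_min=0.3, no_isolated=True)
            # require connectivity: one union-find pass via spectrum (#zero eigs)
            s = nt.laplacian_spectrum(g)
            if np.sum(s.eigenvalues < 1e-10) != 1:
                continue
            checked += 1
            lo, hi = nt.entropy_bounds(g.n_nodes)
            h = nt.entropy_degree_form(g)
            assert lo - 1e-12 <= h <= hi + 1e-12


class TestInternalEnergy:
    @pytest.mark.parametrize("kind,n,expected",
                             [("complete", 3, 3), ("path", 4, 3)])
    def test_named(self, kind, n, expected):
        assert nt.internal_energy(nt.gen_named_graph(kind, n)) == expected

    def test_empty(self):
        assert nt.internal_energy(nt.build_undirected_graph(4, [])) == 0


class TestEntropyChange:
    def test_p3_to_k3_printed(self, p3, k3):
        # surviving edges (0,1) and (1,2) each contribute 2/8
        assert nt.entropy_change(p3, k3, "printed") == pytest.approx(0.5, abs=1e-14)

    def test_p3_to_k3_exact(self, p3, k3):
        assert nt.entropy_change(p3, k3, "exact") == pytest.approx(1 / 36, abs=1e-12)

    @pytest.mark.parametrize("mode", ["printed", "first_order", "exact"])
    def test_identity_transition_is_zero(self, k3, mode):
        assert nt.entropy_change(k3, k3, mode) == 0.0

    def test_node_count_mismatch_rejected(self, k3, p4):
        with pytest.raises(GraphValidationError):
            nt.entropy_change(k3, p4)

    def test_exact_equals_algebraic_decomposition(self, rng):
        """Exact dH = (1/n^2)[printed terms - gained-edge terms + lost-edge terms]."""
        trials = 0
        while trials < 100:
            g = random_graph(rng, n_min=4, p_min=0.2)
            g2 = nt.perturb_graph(g, float(rng.uniform(0, 0.3)),
                                  float(rng.uniform(0, 0.3)),
                                  seed=int(rng.integers(2**31)))
            if g.has_isolated_nodes() or g2.has_isolated_nodes():
                continue
            trials += 1
            d = nt.degree_vector(g)
            d2 = nt.degree_vector(g2)
            gained = sum(1.0 / (d2[u] * d2[v]) for (u, v) in (g2.edges - g.edges))
            lost = sum(1.0 / (d[u] * d[v]) for (u, v) in (g.edges - g2.edges))
            n = g.n_nodes
            rhs = (nt.entropy_change(g, g2, "printed") - gained + lost) / (n * n)
            assert nt.entropy_change(g, g2, "exact") == pytest.approx(rhs, abs=1e-12)

    def test_first_order_limit(self):
        """printed -> first_order as degree changes shrink against degrees."""
        diffs = []
        for m in (5, 10, 20, 40):
            g = nt.gen_named_graph("complete", m)
            edges = set(g.edges)
            edges.discard((0, 1))
            g2 = nt.UndirectedGraph(m, frozenset(edges))
            diffs.append(abs(nt.entropy_change(g, g2, "printed")
                             - nt.entropy_change(g, g2, "first_order")))
        assert all(a > b for a, b in zip(diffs, diffs[1:]))


class TestInverseTemperature:
    def test_p3_to_k3_printed(self, p3, k3):
        tm = nt.inverse_temperature(p3, k3, "printed")
        assert tm.inverse_temperature == pytest.approx(0.5, abs=1e-14)
        assert tm.temperature == pytest.approx(2.0, abs=1e-14)
        assert tm.dU == 1 and not tm.degenerate

    def test_p3_to_k3_first_order(self, p3, k3):
        tm = nt.inverse_temperature(p3, k3, "first_order")
        assert tm.inverse_temperature == pytest.approx(1.0, abs=1e-14)
        assert tm.temperature == pytest.approx(1.0, abs=1e-14)

    def test_identity_transition_degenerate_nan(self, k3):
        with pytest.warns(RuntimeWarning):
            tm = nt.inverse_temperature(k3, k3)
        assert tm.degenerate
        assert math.isnan(tm.inverse_temperature) and math.isnan(tm.temperature)

    def test_edge_preserving_rewiring_is_signed_infinity(self):
        # P_4 rewired to the star S_4: |E| unchanged, entropy changes
        p4 = nt.gen_named_graph("path", 4)
        s4 = nt.gen_named_graph("star", 4)
        tm = nt.inverse_temperature(p4, s4, "exact")
        assert tm.degenerate and tm.temperature == 0.0
        assert math.isinf(tm.inverse_temperature)
        assert math.copysign(1, tm.inverse_temperature) == math.copysign(1, tm.dH)
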
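"""Wiring invariants: clustered weight conservation, uniform connectivity,
sign constraints, input/output layer construction."""

import numpy as np
import pytest
from scipy import stats

from clusterrl import ConfigurationError, Population, TetzlaffParams
from clusterrl.topology import (
    Circuit,
    ClusterSpec,
    build_representation_layer,
    wire_input_projections,
    wire_output_layer,
)


def _summed_input(circuit, pop_name, sign):
    """Realized summed recurrent input weight per neuron (one sign class)."""
    pop = circuit.populations[pop_name]
    total = np.zeros(pop.n)
    for name, proj in circuit.projections.items():
        if proj.post_pop != pop_name or not name.startswith("rec_"):
            continue
        w = circuit.projection_weights(name)
        if np.sign(w.sum()) != sign:
            continue
        np.add.at(total, proj.post - pop.start, w)
    return total


def _build(n_clusters, j_plus, seed=0):
    spec = ClusterSpec(
        n_exc=400, n_inh=120, n_clusters=n_clusters, j_plus=j_plus,
        j_plus_inh=min(j_plus, 1.5) if n_clusters > 1 else 1.0,
    )
    c = Circuit()
    m = build_representation_layer(c, spec, np.random.default_rng(seed))
    return c, m, spec


def test_cluster_membership_counts():
    _, m, _ = _build(8, 6.0)
    for cl in range(8):
        assert m.exc_ids(cl).size == 50
        assert m.inh_ids(cl).size == 15


def test_divisibility_and_feasibility_errors():
    with pytest.raises(ConfigurationError):
        ClusterSpec(n_exc=400, n_inh=100, n_clusters=8)
    with pytest.raises(ConfigurationError):
        ClusterSpec(n_exc=400, n_inh=120, n_clusters=4, j_plus=5.0)
    with pytest.raises(ConfigurationError):
        ClusterSpec(n_exc=400, n_inh=120, j_plus=0.5)


def test_degenerate_clustering_matches_unclustered():
    """n_clusters=1 (or j_plus=1) leaves all weights at the base magnitude."""
    c1, _, spec1 = _build(1, 1.0)
    c8 = Circuit()
    spec8 = ClusterSpec(n_exc=400, n_inh=120, n_clusters=8, j_plus=1.0,
                        j_plus_inh=1.0)
    build_representation_layer(c8, spec8, np.random.default_rng(0))
    for c, spec in ((c1, spec1), (c8, spec8)):
        w_ee = c.projection_weights("rec_EE")
        assert np.allclose(np.unique(w_ee), spec.j_ee * spec.weight_scale)


@pytest.mark.parametrize("n_clusters,j_plus", [(1, 1.0), (4, 3.0), (8, 6.0), (20, 6.0)])
def test_total_input_weight_conserved(n_clusters, j_plus):
    """Expected summed input strength per neuron is invariant under clustering.

    Excitatory and inhibitory input strengths are conserved separately;
    the comparison is a small Monte-Carlo over wiring realizations.
    """
    for sign in (1, -1):
        ref = np.mean(
            [_summed_input(_build(1, 1.0, seed=s)[0], "rep_exc", sign).mean()
             for s in (1, 2, 3)]
        )
        val = np.mean(
            [_summed_input(_build(n_clusters, j_plus, seed=s)[0], "rep_exc", sign).mean()
             for s in (1, 2, 3)]
        )
        assert abs(val - ref) / abs(ref) < 0.02


def test_in_degree_is_binomial():
    """Uniform Bernoulli wiring: realized in-degrees match Binomial(N-1, p)."""
    c, _, spec = _build(8, 6.0, seed=2)
    proj = c.projections["rec_EE"]
    in_deg = np.bincount(proj.post, minlength=spec.n_exc)
    n, p = spec.n_exc - 1, spec.conn_prob
    assert in_deg.mean() == pytest.approx(n * p, rel=0.02)
    # chi-square against the binomial quantiles (coarse bins)
    edges = stats.binom.ppf([0.0, 0.2, 0.4, 0.6, 0.8, 1.0], n, p)
    counts, _ = np.histogram(in_deg, bins=np.unique(edges) + 0.5)
    expected = np.full(counts.size, in_deg.size / counts.size)
    chi2 = ((counts - expected) ** 2 / expected).sum()
    assert chi2 < stats.chi2.ppf(0.999, counts.size - 1)


def test_sign_constraints():
    c, _, _ = _build(8, 6.0)
    names = list(c.projections)
    for name in names:
        w = c.projection_weights(name)
        if name in ("rec_EE", "rec_IE"):
            assert np.all(w >= 0)
        if name in ("rec_EI", "rec_II"):
            assert np.all(w <= 0)


def test_input_projection_initialization():
    rng = np.random.default_rng(7)
    c = Circuit()
    c.add_population(Population("input", 2, "poisson"))
    c.add_population(Population("rep", 3, "lif"))
    projs = wire_input_projections(
        c, "input", ["rep"], rng, 33.33, 66.66, TetzlaffParams()
    )
    w = c.projection_weights(projs[0].name)
    assert w.size == 6
    assert np.all((w >= 33.33) & (w <= 66.66))
    # constant bounds give constant weights
    c2 = Circuit()
    c2.add_population(Population("input", 2, "poisson"))
    c2.add_population(Population("rep", 3, "lif"))
    p2 = wire_input_projections(c2, "input", ["rep"], rng, 5.0, 5.0, TetzlaffParams())
    assert np.allclose(c2.projection_weights(p2[0].name), 5.0)
    # uniform-distribution oracle on a large draw
    c3 = Circuit()
    c3.add_population(Population("input", 100, "poisson"))
    c3.add_population(Population("rep", 1000, "lif"))
    p3 = wire_input_projections(c3, "input", ["rep"], rng, 0.0, 10.0, TetzlaffParams())
    w3 = c3.projection_weights(p3[0].name)
    se = 10.0 / np.sqrt(12) / np.sqrt(w3.size)
    assert abs(w3.mean() - 5.0) < 3 * se


def test_output_layer_wiring():
    rng = np.random.default_rng(3)
    c = Circuit()
    c.add_population(Population("rep_exc", 20, "lif"))
    wire_output_layer(c, 3, "rep_exc", rng, TetzlaffParams())
    lat = c.projections["output_lateral"]
    assert lat.pre.size == 6  # 3 * 2 ordered pairs, no self-inhibition
    w_lat = c.projection_weights("output_lateral")
    assert np.all(w_lat < 0)
    out_proj = c.projections["output_proj"]
    assert out_proj.plastic == "three_factor"
    with pytest.raises(ConfigurationError):
        wire_output_layer(Circuit(), 1, "x", rng, TetzlaffParams())
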
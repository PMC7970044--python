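"""Construction of the three-layer circuit.

The representation layer is a clustered balanced random network: connection
probability is uniform Bernoulli across all pairs, but synaptic weights
within a cluster (excitatory and inhibitory neurons are both assigned to
clusters) are scaled up by ``j_plus`` while between-cluster weights are
scaled down by ``j_minus = (n_clusters - j_plus) / (n_clusters - 1)``, so
that the expected summed input weight per neuron equals the unclustered
reference — total synaptic strength is conserved in expectation (exact
per-neuron conservation would require fixed in-degrees, which Bernoulli
wiring does not provide).

Input projections are plastic all-to-all excitatory synapses with uniformly
initialized weights; the output layer is a winner-takes-all circuit with
static all-to-all lateral inhibition and a background Poisson drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import ConfigurationError, Network, NeuronParams, Population
from .plasticity import TetzlaffParams

__all__ = [
    "ClusterSpec",
    "ClusterMembership",
    "Projection",
    "Circuit",
    "build_representation_layer",
    "wire_input_projections",
    "wire_output_layer",
]

REFERENCE_N = 5000  # network size at which base weights are quoted


@dataclass(frozen=True)
class ClusterSpec:
    """Specification of the clustered balanced representation layer.

    Base weights j_xy are magnitudes in pA of the connection onto
    population x from population y; inhibitory weights enter the network
    with negative sign.  Weights are quoted for the reference size of
    5000 neurons and scaled by (5000 / N) at other sizes so the expected
    summed input per neuron is size-invariant.
    """

    n_exc: int = 4000
    n_inh: int = 1000
    n_clusters: int = 8
    conn_prob: float = 0.2
    j_plus: float = 6.0
    j_plus_inh: float | None = None  # clustering of E-I/I-E/I-I blocks; default j_plus
    j_ee: float = 2.0
    j_ei: float = 9.0
    j_ie: float = 3.0
    j_ii: float = 9.0
    delay_ms: float = 1.0
    exc_params: NeuronParams = field(
        default_factory=lambda: NeuronParams(tau_m=20.0, I_bias=300.0)
    )
    inh_params: NeuronParams = field(
        default_factory=lambda: NeuronParams(tau_m=10.0, I_bias=555.0)
    )

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ConfigurationError("n_clusters must be >= 1")
        if self.n_exc % self.n_clusters or self.n_inh % self.n_clusters:
            raise ConfigurationError(
                "n_exc and n_inh must be divisible by n_clusters"
            )
        if not 0 < self.conn_prob <= 1:
            raise ConfigurationError("conn_prob must be in (0, 1]")
        for jp in (self.j_plus, self.j_plus_inh):
            if jp is None:
                continue
            if jp < 1:
                raise ConfigurationError("j_plus must be >= 1")
            if jp > self.n_clusters:
                raise ConfigurationError(
                    "j_plus > n_clusters makes weight conservation infeasible"
                )

    def _scales(self, j_plus: float) -> tuple[float, float]:
        if self.n_clusters == 1:
            return 1.0, 1.0
        return j_plus, (self.n_clusters - j_plus) / (self.n_clusters - 1)

    @property
    def j_minus(self) -> float:
        """Between-cluster scaling conserving expected total input weight."""
        return self._scales(self.j_plus)[1]

    @property
    def j_plus_inh_eff(self) -> float:
        return self.j_plus if self.j_plus_inh is None else self.j_plus_inh

    @property
    def weight_scale(self) -> float:
        return REFERENCE_N / (self.n_exc + self.n_inh)

    def scaled_to(self, n_exc: int, n_inh: int, **overrides) -> "ClusterSpec":
        return replace(self, n_exc=n_exc, n_inh=n_inh, **overrides)


@dataclass
class ClusterMembership:
    """Cluster assignment of every representation neuron (E and I)."""

    exc_cluster: np.ndarray
    inh_cluster: np.ndarray
    n_clusters: int

    def exc_ids(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.exc_cluster == c)

    def inh_ids(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.inh_cluster == c)


@dataclass
class Projection:
    """A named block of synapses between two populations.

    ``pre``/``post`` are global unit indices; ``edge_ids`` index into the
    circuit-wide edge list.  ``plastic`` is None for static synapses, or
    the rule name ('hebbian' | 'three_factor') with its parameters.
    """

    name: str
    pre_pop: str
    post_pop: str
    pre: np.ndarray
    post: np.ndarray
    edge_ids: np.ndarray
    plastic: str | None = None
    rule_params: TetzlaffParams | None = None


class Circuit:
    """Accumulates populations and projections, then compiles to a Network."""

    def __init__(self) -> None:
        self.populations: dict[str, Population] = {}
        self.projections: dict[str, Projection] = {}
        self._pre: list[np.ndarray] = []
        self._post: list[np.ndarray] = []
        self._weight: list[np.ndarray] = []
        self._delay: list[np.ndarray] = []
        self._n_units = 0
        self._n_edges = 0

    def add_population(self, pop: Population) -> Population:
        if pop.name in self.populations:
            raise ConfigurationError(f"duplicate population {pop.name!r}")
        pop.start = self._n_units
        self._n_units += pop.n
        self.populations[pop.name] = pop
        return pop

    def add_projection(
        self,
        name: str,
        pre_pop: str,
        post_pop: str,
        pre_local,
        post_local,
        weight,
        delay_ms: float = 1.0,
        plastic: str | None = None,
        rule_params: TetzlaffParams | None = None,
    ) -> Projection:
        if name in self.projections:
            raise ConfigurationError(f"duplicate projection {name!r}")
        ppre = self.populations[pre_pop]
        ppost = self.populations[post_pop]
        pre = ppre.globalize(pre_local)
        post = ppost.globalize(post_local)
        weight = np.broadcast_to(np.asarray(weight, float), pre.shape).copy()
        if pre.shape != post.shape:
            raise ConfigurationError("pre and post id arrays must align")
        if plastic is not None and plastic not in ("hebbian", "three_factor"):
            raise ConfigurationError(f"unknown plasticity rule {plastic!r}")
        if plastic is not None and rule_params is None:
            raise ConfigurationError("plastic projections need rule parameters")
        edge_ids = np.arange(self._n_edges, self._n_edges + pre.size, dtype=np.int64)
        self._n_edges += pre.size
        self._pre.append(pre)
        self._post.append(post)
        self._weight.append(weight)
        self._delay.append(np.full(pre.size, float(delay_ms)))
        proj = Projection(
            name, pre_pop, post_pop, pre, post, edge_ids, plastic, rule_params
        )
        self.projections[name] = proj
        return proj

    def projection_weights(self, name: str) -> np.ndarray:
        """Initial weights of a projection, in edge order (pre-compile view)."""
        return self._weight[list(self.projections).index(name)]

    def compile(self, dt: float = 0.1, seed: int = 0, **net_kwargs) -> Network:
        from .core import _PlasticGroup

        edges = {
            "pre": np.concatenate(self._pre) if self._pre else np.empty(0, np.int64),
            "post": np.concatenate(self._post) if self._post else np.empty(0, np.int64),
            "weight": np.concatenate(self._weight) if self._weight else np.empty(0),
            "delay_ms": np.concatenate(self._delay) if self._delay else np.empty(0),
        }
        groups = []
        for proj in self.projections.values():
            if proj.plastic is None:
                continue
            rp = proj.rule_params
            groups.append(
                _PlasticGroup(
                    name=proj.name,
                    edge_idx=proj.edge_ids,
                    rule=0 if proj.plastic == "hebbian" else 1,
                    mu=rp.mu,
                    kappa=rp.kappa,
                    F_T=rp.F_T,
                    w_min=rp.w_min,
                    w_max=rp.w_max,
                )
            )
        return Network(
            list(self.populations.values()), edges, groups, dt=dt, seed=seed, **net_kwargs
        )


def _bernoulli_edges(
    rng: np.random.Generator,
    n_pre: int,
    n_post: int,
    p: float,
    exclude_self: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    mask = rng.random((n_pre, n_post)) < p
    if exclude_self:
        np.fill_diagonal(mask, False)
    pre, post = np.nonzero(mask)
    return pre.astype(np.int64), post.astype(np.int64)


def build_representation_layer(
    circuit: Circuit,
    spec: ClusterSpec,
    rng: np.random.Generator,
    exc_name: str = "rep_exc",
    inh_name: str = "rep_inh",
) -> ClusterMembership:
    """Create the E/I populations and the four static recurrent projections.

    Cluster membership is assigned in contiguous equal-sized blocks; weights
    are the base magnitudes scaled by j_plus within and j_minus between
    clusters, negative for inhibitory presynaptic neurons.
    """
    circuit.add_population(
        Population(exc_name, spec.n_exc, "lif", params=spec.exc_params)
    )
    circuit.add_population(
        Population(inh_name, spec.n_inh, "lif", params=spec.inh_params)
    )
    membership = ClusterMembership(
        exc_cluster=np.repeat(np.arange(spec.n_clusters), spec.n_exc // spec.n_clusters),
        inh_cluster=np.repeat(np.arange(spec.n_clusters), spec.n_inh // spec.n_clusters),
        n_clusters=spec.n_clusters,
    )
    ws = spec.weight_scale
    jp_e, jm_e = spec._scales(spec.j_plus)
    jp_i, jm_i = spec._scales(spec.j_plus_inh_eff)
    blocks = [
        ("EE", exc_name, exc_name, spec.j_ee * ws, +1.0, jp_e, jm_e,
         membership.exc_cluster, membership.exc_cluster, True),
        ("EI", inh_name, exc_name, spec.j_ei * ws, -1.0, jp_i, jm_i,
         membership.inh_cluster, membership.exc_cluster, False),
        ("IE", exc_name, inh_name, spec.j_ie * ws, +1.0, jp_i, jm_i,
         membership.exc_cluster, membership.inh_cluster, False),
        ("II", inh_name, inh_name, spec.j_ii * ws, -1.0, jp_i, jm_i,
         membership.inh_cluster, membership.inh_cluster, True),
    ]
    for tag, pre_pop, post_pop, j, sign, jp, jm, cl_pre, cl_post, excl in blocks:
        n_pre = circuit.populations[pre_pop].n
        n_post = circuit.populations[post_pop].n
        pre, post = _bernoulli_edges(rng, n_pre, n_post, spec.conn_prob, excl)
        same = cl_pre[pre] == cl_post[post]
        w = sign * j * np.where(same, jp, jm)
        circuit.add_projection(
            f"rec_{tag}", pre_pop, post_pop, pre, post, w, delay_ms=spec.delay_ms
        )
    return membership


def wire_input_projections(
    circuit: Circuit,
    input_pop: str,
    target_pops: list[str],
    rng: np.random.Generator,
    init_low: float = 33.33,
    init_high: float = 66.66,
    rule_params: TetzlaffParams | None = None,
    plastic: bool = True,
    delay_ms: float = 1.0,
    conn_prob: float = 1.0,
    name: str = "input_proj",
) -> list[Projection]:
    """Plastic excitatory projections from the input layer.

    All-to-all by default; with ``conn_prob`` < 1 each input-target pair is
    connected independently with that probability, which gives the target
    neurons heterogeneous (mixed-selective) stimulus tuning.  Initial
    weights are drawn uniformly from [init_low, init_high].
    """
    if init_low > init_high:
        raise ConfigurationError("init_low must not exceed init_high")
    n_in = circuit.populations[input_pop].n
    projs = []
    for tgt in target_pops:
        n_t = circuit.populations[tgt].n
        if conn_prob >= 1.0:
            pre, post = np.meshgrid(np.arange(n_in), np.arange(n_t), indexing="ij")
        else:
            pre, post = _bernoulli_edges(rng, n_in, n_t, conn_prob)
        w = rng.uniform(init_low, init_high, size=pre.size)
        projs.append(
            circuit.add_projection(
                f"{name}__{tgt}" if len(target_pops) > 1 else name,
                input_pop,
                tgt,
                pre.ravel(),
                post.ravel(),
                w,
                delay_ms=delay_ms,
                plastic="hebbian" if plastic else None,
                rule_params=rule_params if plastic else None,
            )
        )
    return projs


def wire_output_layer(
    circuit: Circuit,
    n_outputs: int,
    exc_pop: str,
    rng: np.random.Generator,
    rule_params: TetzlaffParams,
    out_params: NeuronParams | None = None,
    w_init_low: float = 0.5,
    w_init_high: float = 1.5,
    j_lateral: float = 500.0,
    bg_rate: float = 2000.0,
    w_bg: float = 30.0,
    plastic: bool = True,
    out_name: str = "out",
    bg_name: str = "out_bg",
) -> Population:
    """Winner-takes-all output layer.

    Plastic excitatory projections from the excitatory representation
    neurons to each output neuron; static all-to-all lateral inhibition
    among outputs (no self-inhibition); an independent background Poisson
    source per output neuron provides exploratory drive.
    """
    if n_outputs < 2:
        raise ConfigurationError("need at least two output neurons")
    out = circuit.add_population(
        Population(out_name, n_outputs, "lif", params=out_params or NeuronParams())
    )
    n_e = circuit.populations[exc_pop].n
    pre, post = np.meshgrid(np.arange(n_e), np.arange(n_outputs), indexing="ij")
    w = rng.uniform(w_init_low, w_init_high, size=n_e * n_outputs)
    circuit.add_projection(
        "output_proj",
        exc_pop,
        out_name,
        pre.ravel(),
        post.ravel(),
        w,
        plastic="three_factor" if plastic else None,
        rule_params=rule_params if plastic else None,
    )
    lat_pre, lat_post = np.nonzero(~np.eye(n_outputs, dtype=bool))
    circuit.add_projection(
        "output_lateral", out_name, out_name, lat_pre, lat_post, -abs(j_lateral)
    )
    circuit.add_population(
        Population(bg_name, n_outputs, "poisson", rate_base=bg_rate)
    )
    ids = np.arange(n_outputs)
    circuit.add_projection("output_bg", bg_name, out_name, ids, ids, w_bg)
    return out
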
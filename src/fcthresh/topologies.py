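"""Structural ground-truth network generators.

Networks of N spiking neurons (80% excitatory regular-spiking, 20% inhibitory
fast-spiking by default) wired according to one of four topologies:

* random (RND): every neuron projects to ``out_degree`` uniformly chosen targets;
* small-world (SW): a rewired ring lattice among the excitatory population, with a
  subset of lattice links translated onto the inhibitory population;
* scale-free (SF): preferential-attachment out-degree sequences with row-shuffled
  (uniform) targets, giving power-law out-degrees and normal in-degrees;
* modular: weakly coupled dense blocks with a sparsely connected remainder.

Sign conventions: every outgoing weight of an excitatory neuron is positive,
every outgoing weight of an inhibitory neuron is negative, and inhibitory
neurons project exclusively onto excitatory neurons.  Conduction delays are
integer milliseconds, uniform on [1, 20] for excitatory links and fixed at 1 ms
for inhibitory links.  Initial synaptic weights are drawn at generation time:
excitatory ~ Normal(7, 1) (clipped to a small positive floor), inhibitory
~ Normal(-7, 1) (clipped to a small negative ceiling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StructuralNetwork",
    "generate_random",
    "generate_small_world",
    "generate_scale_free",
    "generate_modular",
]

REGULAR_SPIKING = "regular_spiking"
FAST_SPIKING = "fast_spiking"

#: excitatory delay range (ms), inclusive
EXC_DELAY_RANGE = (1, 20)
INH_DELAY = 1
#: initial weight distributions (mean, sd)
EXC_WEIGHT = (7.0, 1.0)
INH_WEIGHT = (-7.0, 1.0)
#: clip floor so sign invariants survive the Gaussian draw
WEIGHT_FLOOR = 0.1


@dataclass
class StructuralNetwork:
    """Ground-truth signed, directed, delayed network.

    ``adjacency[i, j]`` is the synaptic weight of the link i -> j (0 = no link);
    ``delays[i, j]`` the conduction delay in ms, defined only on the link support.
    """

    n_neurons: int
    n_excitatory: int
    adjacency: np.ndarray
    delays: np.ndarray
    neuron_types: np.ndarray
    topology_tag: str
    rng_seed: int
    params: dict = field(default_factory=dict)

    @property
    def n_inhibitory(self) -> int:
        return self.n_neurons - self.n_excitatory

    @property
    def is_excitatory(self) -> np.ndarray:
        return self.neuron_types == REGULAR_SPIKING

    @property
    def n_links(self) -> int:
        return int(np.count_nonzero(self.adjacency))

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on violation."""
        A = self.adjacency
        if A.shape != (self.n_neurons, self.n_neurons):
            raise ValueError("adjacency shape does not match n_neurons")
        if np.any(np.diag(A) != 0):
            raise ValueError("self-connections are forbidden")
        exc = self.is_excitatory
        if np.any(A[exc] < 0):
            raise ValueError("excitatory neuron with a negative outgoing weight")
        if np.any(A[~exc] > 0):
            raise ValueError("inhibitory neuron with a positive outgoing weight")
        # inhibitory neurons may only target excitatory neurons
        if np.any(A[np.ix_(~exc, ~exc)] != 0):
            raise ValueError("inhibitory-to-inhibitory connection found")
        support = A != 0
        d = self.delays[support]
        if d.size and (d.min() < 1):
            raise ValueError("delays must be >= 1 ms on the link support")


def _draw_weights(rng: np.random.Generator, n: int, excitatory: bool) -> np.ndarray:
    if excitatory:
        w = rng.normal(*EXC_WEIGHT, size=n)
        return np.clip(w, WEIGHT_FLOOR, None)
    w = rng.normal(*INH_WEIGHT, size=n)
    return np.clip(w, None, -WEIGHT_FLOOR)


def _assemble(
    n_neurons: int,
    n_excitatory: int,
    sources: np.ndarray,
    targets: np.ndarray,
    tag: str,
    seed: int,
    rng: np.random.Generator,
    params: dict,
) -> StructuralNetwork:
    """Build the dense signed adjacency + delay matrices from an edge list."""
    A = np.zeros((n_neurons, n_neurons))
    D = np.zeros((n_neurons, n_neurons), dtype=np.int64)
    exc_edge = sources < n_excitatory
    weights = np.empty(len(sources))
    weights[exc_edge] = _draw_weights(rng, int(exc_edge.sum()), True)
    weights[~exc_edge] = _draw_weights(rng, int((~exc_edge).sum()), False)
    delays = np.where(
        exc_edge,
        rng.integers(EXC_DELAY_RANGE[0], EXC_DELAY_RANGE[1] + 1, size=len(sources)),
        INH_DELAY,
    )
    A[sources, targets] = weights
    D[sources, targets] = delays
    types = np.array(
        [REGULAR_SPIKING] * n_excitatory + [FAST_SPIKING] * (n_neurons - n_excitatory)
    )
    net = StructuralNetwork(
        n_neurons=n_neurons,
        n_excitatory=n_excitatory,
        adjacency=A,
        delays=D,
        neuron_types=types,
        topology_tag=tag,
        rng_seed=seed,
        params=params,
    )
    net.validate()
    return net


def _check_counts(n_neurons: int, n_excitatory: int, out_degree: int) -> None:
    if not 0 <= n_excitatory <= n_neurons:
        raise ValueError("n_excitatory must lie in [0, n_neurons]")
    if out_degree < 0 or out_degree >= n_neurons:
        raise ValueError("out_degree must satisfy 0 <= out_degree < n_neurons")


def generate_random(
    n_neurons: int = 500,
    n_excitatory: int = 400,
    out_degree: int = 40,
    seed: int = 0,
) -> StructuralNetwork:
    """Random (RND) topology: each neuron projects to ``out_degree`` uniformly
    chosen distinct targets (no autapses).

    Excitatory neurons may target any other neuron; inhibitory neurons target
    excitatory neurons only.  In-degrees follow a binomial (Poisson-like) law.
    """
    _check_counts(n_neurons, n_excitatory, out_degree)
    n_inh = n_neurons - n_excitatory
    if n_inh > 0 and out_degree > n_excitatory:
        raise ValueError(
            "inhibitory out_degree exceeds the number of excitatory targets"
        )
    rng = np.random.default_rng(seed)
    src, tgt = [], []
    all_ids = np.arange(n_neurons)
    exc_ids = np.arange(n_excitatory)
    for i in range(n_neurons):
        pool = all_ids if i < n_excitatory else exc_ids
        pool = pool[pool != i]
        if out_degree > 0:
            choice = rng.choice(pool, size=out_degree, replace=False)
            src.append(np.full(out_degree, i))
            tgt.append(choice)
    sources = np.concatenate(src) if src else np.empty(0, dtype=int)
    targets = np.concatenate(tgt) if tgt else np.empty(0, dtype=int)
    return _assemble(
        n_neurons, n_excitatory, sources, targets, "RND", seed, rng,
        {"out_degree": out_degree},
    )


def generate_small_world(
    n_neurons: int = 500,
    n_excitatory: int = 400,
    out_degree: int = 40,
    rewiring_p: float = 0.3,
    seed: int = 0,
    e_to_i_links: int | None = None,
) -> StructuralNetwork:
    """Small-world (SW) topology, a three-block Watts–Strogatz variant.

    The excitatory population is wired as an undirected ring lattice
    (``out_degree/2`` neighbours per side, every link bidirectional); each
    lattice pair is rewired jointly with probability ``rewiring_p`` to a
    uniformly chosen excitatory partner.  ``e_to_i_links`` directed
    excitatory-to-excitatory links (default 4 per excitatory neuron) are then
    translated onto inhibitory targets, spread so that every inhibitory
    neuron receives at least one excitatory input.  The inhibitory block
    projects randomly onto the excitatory population.  The total link budget
    is ``n_neurons * out_degree`` exactly.
    """
    _check_counts(n_neurons, n_excitatory, out_degree)
    if not 0.0 <= rewiring_p <= 1.0:
        raise ValueError("rewiring_p must lie in [0, 1]")
    if out_degree % 2 != 0:
        raise ValueError("out_degree must be even (ring lattice convention)")
    n_inh = n_neurons - n_excitatory
    rng = np.random.default_rng(seed)
    half = out_degree // 2

    # undirected ring lattice: each pair (i, i+o), o = 1..half, listed once;
    # pairs are first marked for rewiring, then re-targeted against the final
    # edge set so no two pairs collide
    und: set[tuple[int, int]] = set()
    rewire_homes: list[int] = []
    for i in range(n_excitatory):
        for o in range(1, half + 1):
            j = (i + o) % n_excitatory
            if rng.random() < rewiring_p and n_excitatory > out_degree + 1:
                rewire_homes.append(i)  # joint rewiring, home endpoint kept
            else:
                und.add((min(i, j), max(i, j)))
    for i in rewire_homes:
        for _ in range(100 * n_excitatory):
            jj = int(rng.integers(n_excitatory))
            if jj != i and (min(i, jj), max(i, jj)) not in und:
                und.add((min(i, jj), max(i, jj)))
                break
        else:
            raise ValueError("rewiring failed: no free partner found")
    ee_src = np.array([e[k] for e in und for k in (0, 1)], dtype=int)
    ee_tgt = np.array([e[k] for e in und for k in (1, 0)], dtype=int)

    if e_to_i_links is None:
        e_to_i_links = 4 * n_excitatory if n_inh > 0 else 0
    if e_to_i_links > len(ee_src):
        raise ValueError("e_to_i_links exceeds the number of lattice links")
    ei_src = np.empty(0, dtype=int)
    ei_tgt = np.empty(0, dtype=int)
    if e_to_i_links > 0:
        pick = rng.choice(len(ee_src), size=e_to_i_links, replace=False)
        # round-robin over shuffled inhibitory ids: every inhibitory neuron
        # gets at least one input when e_to_i_links >= n_inh
        inh_targets = n_excitatory + (np.arange(e_to_i_links) % n_inh)
        inh_targets = inh_targets[rng.permutation(e_to_i_links)]
        ei_src = ee_src[pick]
        ei_tgt = inh_targets
        keep = np.ones(len(ee_src), dtype=bool)
        keep[pick] = False
        ee_src, ee_tgt = ee_src[keep], ee_tgt[keep]
        # a source may now hold duplicate E->I links; spread them
        ei_src, ei_tgt = _dedupe_edges(ei_src, ei_tgt, n_neurons,
                                       n_excitatory, rng,
                                       target_lo=n_excitatory)

    # inhibitory block: random projections onto the excitatory population
    ie_src, ie_tgt = [], []
    if n_inh > 0 and out_degree > 0:
        if out_degree > n_excitatory:
            raise ValueError(
                "inhibitory out_degree exceeds the number of excitatory targets"
            )
        for i in range(n_excitatory, n_neurons):
            ie_src.append(np.full(out_degree, i))
            ie_tgt.append(rng.choice(n_excitatory, size=out_degree, replace=False))
    ie_src = np.concatenate(ie_src) if ie_src else np.empty(0, dtype=int)
    ie_tgt = np.concatenate(ie_tgt) if ie_tgt else np.empty(0, dtype=int)

    sources = np.concatenate([ee_src, ei_src, ie_src]).astype(int)
    targets = np.concatenate([ee_tgt, ei_tgt, ie_tgt]).astype(int)
    return _assemble(
        n_neurons, n_excitatory, sources, targets, "SW", seed, rng,
        {"out_degree": out_degree, "rewiring_p": rewiring_p,
         "e_to_i_links": e_to_i_links},
    )


def _dedupe_edges(sources, targets, n_neurons, n_excitatory, rng,
                  target_lo: int = 0):
    """Redirect duplicate (source, target) pairs to unused admissible targets
    (ids in [target_lo, limit) where limit honours the sign blocks)."""
    key = sources.astype(np.int64) * n_neurons + targets
    order = np.argsort(key, kind="stable")
    sources, targets = sources[order], targets[order]
    key = key[order]
    dup = np.zeros(len(key), dtype=bool)
    dup[1:] = key[1:] == key[:-1]
    if not dup.any():
        return sources, targets
    for idx in np.flatnonzero(dup):
        i = sources[idx]
        taken = set(targets[sources == i].tolist())
        limit = n_neurons if i < n_excitatory else n_excitatory
        candidates = [j for j in range(target_lo, limit)
                      if j != i and j not in taken]
        if not candidates:
            raise ValueError("cannot deduplicate edges: target pool exhausted")
        targets[idx] = candidates[rng.integers(len(candidates))]
    return _dedupe_edges(sources, targets, n_neurons, n_excitatory, rng,
                         target_lo)


def _powerlaw_out_degrees(
    n_nodes: int,
    kmin: int,
    kmax: int,
    budget: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Out-degree sequence ~ truncated power law p(k) ∝ k^(-gamma) on
    [kmin, kmax], with gamma solved so the expected mean equals
    ``budget / n_nodes``; the draw is then adjusted by unit steps on random
    nodes so the total matches ``budget`` exactly.
    """
    from scipy.optimize import brentq

    if kmin < 1:
        raise ValueError("min_links_per_neuron must be >= 1")
    target = budget / n_nodes
    if target < kmin or target > kmax:
        raise ValueError(
            f"link budget implies mean out-degree {target:.1f} outside "
            f"[{kmin}, {kmax}]"
        )
    k = np.arange(kmin, kmax + 1, dtype=float)
    if target == kmin:
        deg = np.full(n_nodes, kmin, dtype=np.int64)
        if deg.sum() != budget:
            raise ValueError("degenerate budget cannot be met exactly")
        return deg

    def mean_at(gamma):
        w = k ** (-gamma)
        return (w * k).sum() / w.sum() - target

    gamma = brentq(mean_at, -5.0, 50.0, xtol=1e-10)
    p = k ** (-gamma)
    p /= p.sum()
    deg = rng.choice(np.arange(kmin, kmax + 1), size=n_nodes, p=p).astype(np.int64)
    diff = budget - deg.sum()
    while diff != 0:
        i = rng.integers(n_nodes)
        if diff > 0 and deg[i] < kmax:
            deg[i] += 1
            diff -= 1
        elif diff < 0 and deg[i] > kmin:
            deg[i] -= 1
            diff += 1
    return deg


def shuffle_rows(adjacency: np.ndarray, n_excitatory: int, seed: int = 0) -> np.ndarray:
    """Re-draw every row's targets uniformly within the admissible pool,
    preserving each row's link count (out-degree) and weights multiset.

    This is the row-shuffle used by the scale-free construction to suppress
    bidirectional pairs while keeping the out-degree sequence (row sums of
    the link support) exactly invariant.
    """
    A = np.asarray(adjacency)
    out = np.zeros_like(A)
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    for i in range(n):
        w = A[i][A[i] != 0]
        limit = n if i < n_excitatory else n_excitatory
        pool = np.delete(np.arange(limit), i) if i < limit else np.arange(limit)
        tgt = rng.choice(pool, size=w.size, replace=False)
        out[i, tgt] = rng.permutation(w)
    return out


def generate_scale_free(
    n_neurons: int = 500,
    n_excitatory: int = 400,
    min_links_per_neuron: int = 5,
    seed: int = 0,
    out_degree: int = 40,
) -> StructuralNetwork:
    """Scale-free (SF) topology.

    Per population, out-degrees follow a truncated power law with minimum
    ``min_links_per_neuron`` whose exponent is solved from the mean-degree
    budget (``out_degree`` per neuron on average; at the defaults the
    exponent is ~1.8 and the total is exactly 20,000 links).  Each row's
    targets are drawn uniformly over the admissible pool (the row-shuffle
    step), so outgoing degrees are power-law distributed while incoming
    degrees are binomial, i.e. approximately normal, and bidirectional pairs
    are rare.  Excitatory neurons may target anyone; inhibitory neurons
    target excitatory neurons only.
    """
    _check_counts(n_neurons, n_excitatory, out_degree)
    n_inh = n_neurons - n_excitatory
    rng = np.random.default_rng(seed)
    exc_budget = n_excitatory * out_degree
    inh_budget = n_inh * out_degree

    src, tgt = [], []
    if n_excitatory > 1 and exc_budget:
        exc_deg = _powerlaw_out_degrees(
            n_excitatory, min_links_per_neuron, n_neurons - 1, exc_budget, rng
        )
        all_ids = np.arange(n_neurons)
        for i in range(n_excitatory):
            pool = all_ids[all_ids != i]
            src.append(np.full(exc_deg[i], i))
            tgt.append(rng.choice(pool, size=exc_deg[i], replace=False))
    if n_inh > 0 and inh_budget:
        inh_deg = _powerlaw_out_degrees(
            n_inh, min_links_per_neuron, n_excitatory, inh_budget, rng
        )
        exc_ids = np.arange(n_excitatory)
        for j, i in enumerate(range(n_excitatory, n_neurons)):
            src.append(np.full(inh_deg[j], i))
            tgt.append(rng.choice(exc_ids, size=inh_deg[j], replace=False))
    sources = np.concatenate(src) if src else np.empty(0, dtype=int)
    targets = np.concatenate(tgt) if tgt else np.empty(0, dtype=int)
    return _assemble(
        n_neurons, n_excitatory, sources, targets, "SF", seed, rng,
        {"min_links_per_neuron": min_links_per_neuron, "out_degree": out_degree},
    )


def generate_modular(
    n_neurons: int = 500,
    module_sizes: tuple[int, ...] = (175, 175, 100),
    intra_p: float = 0.25,
    inter_p: float = 0.01,
    seed: int = 0,
    n_excitatory: int | None = None,
) -> StructuralNetwork:
    """Modular topology: dense intra-module, sparse inter-module wiring.

    By default two excitatory modules (175 neurons each) and one inhibitory
    module (100 neurons); neurons outside any module are sparsely connected at
    ``inter_p``.  The inhibitory module projects onto the excitatory modules at
    ``intra_p`` (it serves both), keeping inhibition effective despite the
    weak inter-module coupling.
    """
    if not (0 <= intra_p <= 1 and 0 <= inter_p <= 1):
        raise ValueError("connection probabilities must lie in [0, 1]")
    if sum(module_sizes) > n_neurons:
        raise ValueError("module sizes exceed n_neurons")
    rng = np.random.default_rng(seed)

    # Layout: excitatory modules first, then out-of-module (excitatory)
    # neurons, then the inhibitory module at the top ids.  When n_excitatory
    # is not given, the last module is taken to be the inhibitory one.
    if n_excitatory is None:
        inh_size = module_sizes[-1] if len(module_sizes) else 0
        n_excitatory = n_neurons - inh_size
        exc_modules = module_sizes[:-1]
        inh_modules = module_sizes[-1:]
    else:
        exc_modules, inh_modules, acc = [], [], 0
        for size in module_sizes:
            (exc_modules if acc + size <= n_excitatory else inh_modules).append(size)
            acc += size
    module_of = np.full(n_neurons, -1, dtype=int)
    pos, mid = 0, 0
    for size in exc_modules:
        module_of[pos : pos + size] = mid
        pos += size
        mid += 1
    pos = n_neurons - sum(inh_modules)
    for size in inh_modules:
        module_of[pos : pos + size] = mid
        pos += size
        mid += 1
    exc = np.zeros(n_neurons, dtype=bool)
    exc[:n_excitatory] = True

    inh_module_ids = set(module_of[~exc].tolist()) - {-1}
    P = np.zeros((n_neurons, n_neurons))
    same = (module_of[:, None] == module_of[None, :]) & (module_of[:, None] >= 0)
    P[:] = inter_p
    P[same] = intra_p
    # inhibitory modules project into excitatory modules at intra_p
    for mid in inh_module_ids:
        rows = module_of == mid
        cols = (module_of >= 0) & exc
        P[np.ix_(rows, cols)] = intra_p
    # forbidden links: autapses and inhibitory -> inhibitory
    P[np.ix_(~exc, ~exc)] = 0.0
    np.fill_diagonal(P, 0.0)

    mask = rng.random((n_neurons, n_neurons)) < P
    sources, targets = np.nonzero(mask)
    return _assemble(
        n_neurons, n_excitatory, sources, targets, "MODULAR", seed, rng,
        {"module_sizes": tuple(module_sizes), "intra_p": intra_p,
         "inter_p": inter_p},
    )
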
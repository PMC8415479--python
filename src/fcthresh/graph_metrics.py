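"""Topological characterization of structural and functional networks.

All metrics operate on the binarized, symmetrized graph (an undirected edge
exists wherever either direction carries a link): the clustering-coefficient
pair-count denominator is undirected, and the same convention is applied to
path lengths and the small-world index so structural and functional graphs are
compared on equal footing.  Hub detection uses total (in + out) degree of the
directed graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "TopologyMetrics",
    "binarize_undirected",
    "clustering_coefficient",
    "path_length",
    "small_world_index",
    "fit_degree_distribution",
    "detect_hubs",
    "degree_sequences",
]


@dataclass
class TopologyMetrics:
    n_links: int
    swi: float
    c_g: float
    l_g: float
    c_rand: float
    l_rand: float
    hubs: np.ndarray
    unreachable_fraction: float = 0.0


def binarize_undirected(adjacency: np.ndarray) -> np.ndarray:
    """Undirected binary adjacency: edge wherever either direction is nonzero."""
    A = (adjacency != 0) | (adjacency.T != 0)
    A = A.astype(np.float64)
    np.fill_diagonal(A, 0.0)
    return A


def clustering_coefficient(adjacency: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients and their mean.

    C_i = (# links among neighbours of i) / (k_i (k_i - 1) / 2), with C_i = 0
    for nodes of degree < 2.  Accepts a directed/signed matrix (binarized and
    symmetrized first).
    """
    A = binarize_undirected(np.asarray(adjacency))
    if A.shape[0] < 3:
        raise ValueError("clustering requires at least 3 nodes")
    k = A.sum(axis=1)
    # links among neighbours of i = (A^3)_ii / 2 for a simple undirected graph
    triangles = np.einsum("ij,ji->i", A @ A, A) / 2.0
    denom = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, triangles / denom, 0.0)
    return c, float(c.mean())


def path_length(adjacency: np.ndarray) -> tuple[float, float]:
    """Mean shortest-path length over reachable ordered pairs.

    Returns ``(l_g, unreachable_fraction)``; unreachable pairs are excluded
    from the mean.  Raises if no pair is reachable.
    """
    A = binarize_undirected(np.asarray(adjacency))
    n = A.shape[0]
    if n < 2:
        raise ValueError("path length requires at least 2 nodes")
    d = shortest_path(csr_matrix(A), method="D", unweighted=True, directed=False)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    n_pairs = off.sum()
    if not finite.any():
        raise ValueError("graph is fully disconnected: path length undefined")
    return float(d[finite].mean()), float(1.0 - finite.sum() / n_pairs)


def _random_reference(A: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Degree-preserving randomization of an undirected binary graph."""
    import igraph as ig

    src, tgt = np.nonzero(np.triu(A))
    g = ig.Graph(n=A.shape[0], edges=list(zip(src.tolist(), tgt.tolist())))
    g = g.copy()
    # 10 swap attempts per edge thoroughly mixes the ensemble
    g.rewire(n=10 * g.ecount())
    R = np.zeros_like(A)
    e = np.array(g.get_edgelist())
    if len(e):
        R[e[:, 0], e[:, 1]] = 1.0
        R[e[:, 1], e[:, 0]] = 1.0
    return R


def small_world_index(
    adjacency: np.ndarray, n_reference: int = 20, seed: int = 0
) -> TopologyMetrics:
    """Small-world index SWI = (C_g / C_rand) / (L_g / L_rand).

    C_rand and L_rand are averaged over ``n_reference`` degree-preserving
    random rewirings of the (symmetrized) graph.  SWI > 1 indicates
    small-world organization.
    """
    A = binarize_undirected(np.asarray(adjacency))
    rng = np.random.default_rng(seed)
    _, c_g = clustering_coefficient(A)
    l_g, unreach = path_length(A)
    c_rand_vals, l_rand_vals = [], []
    for _ in range(n_reference):
        R = _random_reference(A, rng)
        _, c_r = clustering_coefficient(R)
        l_r, _ = path_length(R)
        c_rand_vals.append(c_r)
        l_rand_vals.append(l_r)
    c_rand = float(np.mean(c_rand_vals))
    l_rand = float(np.mean(l_rand_vals))
    swi = (c_g / c_rand) / (l_g / l_rand)
    degrees = degree_sequences(adjacency)["total"]
    return TopologyMetrics(
        n_links=int(np.count_nonzero(adjacency)),
        swi=float(swi),
        c_g=c_g,
        l_g=l_g,
        c_rand=c_rand,
        l_rand=l_rand,
        hubs=detect_hubs(degrees),
        unreachable_fraction=unreach,
    )


def degree_sequences(adjacency: np.ndarray) -> dict[str, np.ndarray]:
    """In-, out- and total-degree sequences of the directed binary graph,
    plus sign-split in-degrees (excitatory = positive sources, inhibitory =
    negative sources)."""
    A = np.asarray(adjacency)
    support = A != 0
    out_deg = support.sum(axis=1)
    in_deg = support.sum(axis=0)
    return {
        "in": in_deg,
        "out": out_deg,
        "total": in_deg + out_deg,
        "in_excitatory": (A > 0).sum(axis=0),
        "in_inhibitory": (A < 0).sum(axis=0),
    }


def detect_hubs(degrees: np.ndarray) -> np.ndarray:
    """Hub nodes: degree at least one standard deviation above the mean."""
    degrees = np.asarray(degrees, dtype=float)
    if degrees.size < 2:
        raise ValueError("hub detection requires at least 2 nodes")
    sd = degrees.std(ddof=1)
    return np.flatnonzero(degrees >= degrees.mean() + sd)


def _gaussian(k, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((k - mu) / sigma) ** 2)


def fit_degree_distribution(
    degrees: np.ndarray,
    family: str = "gaussian",
    cumulative: bool = False,
) -> dict:
    """Fit the empirical degree distribution.

    family="gaussian": least-squares fit of a scaled normal density to the
    unit-bin histogram (or to the empirical survival function when
    ``cumulative``); returns mean, sd, r_squared.
    family="powerlaw": linear fit of log10 frequency vs log10 degree over
    nonzero bins; returns slope, intercept, r_squared.
    """
    degrees = np.asarray(degrees, dtype=float)
    if degrees.size < 10:
        raise ValueError("degree fit requires at least 10 nodes")
    if family == "gaussian":
        if np.ptp(degrees) == 0:
            raise ValueError("all degrees identical: gaussian fit undefined")
        lo, hi = int(degrees.min()), int(degrees.max())
        bins = np.arange(lo - 0.5, hi + 1.5)
        freq, _ = np.histogram(degrees, bins=bins, density=True)
        k = np.arange(lo, hi + 1, dtype=float)
        if cumulative:
            freq = 1.0 - np.cumsum(freq)
        p0 = (freq.max() if not cumulative else 0.5,
              degrees.mean(), max(degrees.std(ddof=1), 1e-6))
        if cumulative:
            def model(x, mu, sigma):
                from scipy.stats import norm
                return norm.sf(x, loc=mu, scale=sigma)
            popt, _ = curve_fit(model, k, freq, p0=p0[1:], maxfev=20000)
            fitted = model(k, *popt)
            mu, sigma = popt
        else:
            try:
                popt, _ = curve_fit(_gaussian, k, freq, p0=p0, maxfev=20000)
            except RuntimeError:
                # ill-conditioned on strongly non-gaussian data: fall back to
                # sample moments with a least-squares amplitude
                mu0, sd0 = degrees.mean(), degrees.std(ddof=1)
                shape = _gaussian(k, 1.0, mu0, sd0)
                amp = float(shape @ freq / (shape @ shape))
                popt = (amp, mu0, sd0)
            fitted = _gaussian(k, *popt)
            mu, sigma = popt[1], abs(popt[2])
        ss_res = float(np.sum((freq - fitted) ** 2))
        ss_tot = float(np.sum((freq - freq.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        return {"family": "gaussian", "mean": float(mu), "sd": float(sigma),
                "r_squared": r2}
    if family == "powerlaw":
        degrees = degrees[degrees > 0]
        lo, hi = degrees.min(), degrees.max()
        if cumulative:
            # survival function at each observed degree
            k = np.unique(degrees)
            freq = np.array([(degrees >= kk).mean() for kk in k])
        else:
            unit_counts, _ = np.histogram(
                degrees, bins=np.arange(lo - 0.5, hi + 1.5)
            )
            if np.all(unit_counts > 0):
                # dense support: unit bins are exact (no binning bias)
                freq = unit_counts / degrees.size
                k = np.arange(lo, hi + 1, dtype=float)
            else:
                # sparse tail: logarithmic bins avoid the singleton plateau
                n_bins = max(int(np.ceil(10 * np.log10(hi / lo))), 5)
                edges = np.unique(np.round(
                    np.logspace(np.log10(lo - 0.5), np.log10(hi + 0.5),
                                n_bins + 1)
                ))
                counts, _ = np.histogram(degrees, bins=edges)
                widths = np.diff(edges)
                freq = counts / (widths * degrees.size)
                k = np.sqrt(edges[:-1] * edges[1:])  # geometric bin centres
        keep = freq > 0
        x, y = np.log10(k[keep]), np.log10(freq[keep])
        slope, intercept = np.polyfit(x, y, 1)
        fitted = slope * x + intercept
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        return {"family": "powerlaw", "slope": float(slope),
                "intercept": float(intercept), "r_squared": r2}
    raise ValueError(f"unknown family: {family!r}")
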
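"""Network metrics, connected components and the power-law size model.

Metrics follow the standard graph definitions: density ρ = 2E/(N(N−1)),
average degree ⟨k⟩ = 2E/N, PageRank as the stationary probability of a
damped random walk, and connected components interpreted as transient
molecular clusters.  The component-size distribution n_c(s) is modelled as
a power law A·s^b fitted by ordinary least squares in log-log space: A is
the model value at s = 1 (≈ the monomer count) and b the decay exponent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network_build import InteractionNetwork


@dataclass
class NetworkMetrics:
    """Topological summary of one interaction network."""

    density_all: float
    density_interacting: float
    average_degree: float
    pagerank: dict[int, float]
    pagerank_mean_interacting: float


@dataclass
class ComponentSizeDistribution:
    """Counts n_c(s) of connected components by size s (monomers included)."""

    counts: dict[int, int]
    n_components: int
    n_nodes: int

    @property
    def fractions(self) -> dict[int, float]:
        if self.n_components == 0:
            return {}
        return {s: c / self.n_components for s, c in self.counts.items()}


@dataclass
class PowerLawFit:
    """Fitted n_c(s) = A·s^b with the log-log regression R²."""

    A: float
    b: float
    r_squared_fit: float

    def predict(self, s) -> np.ndarray:
        return self.A * np.asarray(s, dtype=float) ** self.b


def _graph(net: InteractionNetwork | nx.Graph) -> nx.Graph:
    if isinstance(net, nx.Graph):
        return net
    return net.to_networkx()


def network_density(net: InteractionNetwork | nx.Graph,
                    mode: str = "all") -> float:
    """Density 2E/(N(N−1)) over all nodes or interacting (degree ≥ 1) nodes.

    The interacting mode drops isolated molecules before counting N; with E
    fixed and a smaller denominator it can only be larger than the all-node
    density.

    Raises
    ------
    ValueError
        If the chosen node set has fewer than two nodes, or mode is unknown.
    """
    g = _graph(net)
    if mode == "interacting":
        g = g.subgraph([n for n, d in g.degree() if d >= 1])
    elif mode != "all":
        raise ValueError(f"unknown mode {mode!r}")
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("density undefined for fewer than 2 nodes")
    return nx.density(g)


def average_degree(net: InteractionNetwork | nx.Graph) -> float:
    """Mean degree 2E/N over the all-nodes set."""
    g = _graph(net)
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("average degree undefined for an empty node set")
    return 2.0 * g.number_of_edges() / n


def pagerank(net: InteractionNetwork | nx.Graph, damping: float = 0.85,
             tol: float = 1e-10, max_iter: int = 10_000) -> dict[int, float]:
    """Stationary visiting probabilities of the damped random walk.

    Each undirected edge is walked in both directions; isolated nodes are
    dangling and redistribute uniformly.  Convergence is |Δ|₁ < tol.

    Raises
    ------
    ValueError
        On an empty node set or damping outside (0, 1).
    networkx.PowerIterationFailedConvergence
        If the iteration cap is reached.
    """
    g = _graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("pagerank undefined for an empty node set")
    if not (0 < damping < 1):
        raise ValueError("damping must be in (0, 1)")
    # networkx checks err < N*tol; rescale to get an |Δ|₁ < tol guarantee
    return nx.pagerank(g, alpha=damping, tol=tol / g.number_of_nodes(),
                       max_iter=max_iter)


def connected_components(net: InteractionNetwork | nx.Graph) -> list[set[int]]:
    """Maximal connected node sets; isolated nodes are size-1 components."""
    return [set(c) for c in nx.connected_components(_graph(net))]


def component_size_distribution(
        net: InteractionNetwork | nx.Graph) -> ComponentSizeDistribution:
    """Histogram of component sizes, monomers (size 1) included."""
    comps = connected_components(net)
    counts: dict[int, int] = {}
    for c in comps:
        counts[len(c)] = counts.get(len(c), 0) + 1
    return ComponentSizeDistribution(counts=dict(sorted(counts.items())),
                                     n_components=len(comps),
                                     n_nodes=sum(len(c) for c in comps))


def classify_component_topology(subgraph: nx.Graph) -> str:
    """Label a connected component as ``linear``, ``branched`` or ``cyclic``.

    Linear: a simple path (all degrees ≤ 2, edges = size − 1); cyclic:
    edge count ≥ size; branched otherwise.

    Raises
    ------
    ValueError
        For components of size < 2 (monomers are not classifiable).
    """
    n = subgraph.number_of_nodes()
    if n < 2:
        raise ValueError("components of size < 2 are not classifiable")
    e = subgraph.number_of_edges()
    if e >= n:
        return "cyclic"
    if all(d <= 2 for _, d in subgraph.degree()) and e == n - 1:
        return "linear"
    return "branched"


def compute_metrics(net: InteractionNetwork | nx.Graph,
                    damping: float = 0.85) -> NetworkMetrics:
    """All topology metrics of a network in one pass.

    Metrics undefined on the given network (density on < 2 nodes, mean
    PageRank with no interacting nodes) are reported as NaN.
    """
    g = _graph(net)
    pr = pagerank(g, damping=damping) if g.number_of_nodes() else {}
    interacting = [n for n, d in g.degree() if d >= 1]
    try:
        d_all = network_density(g, "all")
    except ValueError:
        d_all = math.nan
    try:
        d_int = network_density(g, "interacting")
    except ValueError:
        d_int = math.nan
    try:
        k = average_degree(g)
    except ValueError:
        k = math.nan
    pr_mean = (float(np.mean([pr[n] for n in interacting]))
               if interacting else math.nan)
    return NetworkMetrics(density_all=d_all, density_interacting=d_int,
                          average_degree=k, pagerank=pr,
                          pagerank_mean_interacting=pr_mean)


def fit_power_law(dist: ComponentSizeDistribution | dict[int, float],
                  weighted: bool = False) -> PowerLawFit:
    """Fit n_c(s) = A·s^b by least squares on ln n_c vs ln s.

    Only sizes with positive counts enter the regression.  A is the model
    intercept at s = 1 and b the slope.  With ``weighted=True`` each point
    is weighted by its count (larger sizes are rarer and noisier).

    Raises
    ------
    ValueError
        If fewer than two distinct sizes have positive counts.
    """
    counts = dist.counts if isinstance(dist, ComponentSizeDistribution) else dist
    items = sorted((s, c) for s, c in counts.items() if c > 0)
    if len(items) < 2:
        raise ValueError("need at least 2 sizes with positive counts to fit")
    s = np.array([x[0] for x in items], dtype=float)
    c = np.array([x[1] for x in items], dtype=float)
    x = np.log(s)
    y = np.log(c)
    w = c if weighted else None
    slope, intercept = np.polyfit(x, y, 1, w=w)
    y_hat = slope * x + intercept
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(A=float(np.exp(intercept)), b=float(slope),
                       r_squared_fit=r2)
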
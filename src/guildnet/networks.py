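"""Per-treatment co-occurrence networks and the cross-treatment permutation test.

A network per treatment keeps only genus pairs whose SparCC correlation is
bootstrap-significant (p < alpha); nodes are genera incident to at least one
significant edge, signed by the correlation's sign. Metrics follow the study
conventions: connectance = edges / nodes^2 and mean degree = 2 edges / nodes.

Two treatments' networks are compared by a paired permutation test: over the
union genus set, each unordered genus pair carries a 0/1 edge indicator per
treatment; a permutation independently swaps the two treatments' indicators
for each pair (preserving each pair's edge multiset), both networks are
reformed, and the metric difference recomputed. The two-sided p-value is the
add-one-corrected share of permutations at least as extreme as observed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METRICS = ("n_edges", "n_nodes", "connectance", "mean_degree")


@dataclass
class Network:
    """Significant-edge co-occurrence network for one treatment."""

    treatment: str
    graph: nx.Graph = field(repr=False)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def metrics(self) -> dict:
        n = self.graph.number_of_nodes()
        e = self.graph.number_of_edges()
        signs = [d.get("sign", "+") for _, _, d in self.graph.edges(data=True)]
        n_pos = sum(s == "+" for s in signs)
        out = {
            "n_nodes": n,
            "n_edges": e,
            "n_pos": n_pos,
            "n_neg": e - n_pos,
            "connectance": e / n**2 if n else 0.0,
            "mean_degree": 2.0 * e / n if n else 0.0,
            "empty": n == 0,
        }
        return out

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {
                "genus_a": a,
                "genus_b": b,
                "sign": d.get("sign"),
                "rho": d.get("rho"),
                "p": d.get("p"),
            }
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["genus_a", "genus_b", "sign", "rho", "p"])

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_network(
    rho: pd.DataFrame,
    p_values: pd.DataFrame,
    alpha: float = 0.05,
    treatment: str = "",
    guilds: pd.Series | None = None,
) -> Network:
    """Keep edges with p < alpha; nodes are genera with at least one edge."""
    if rho.shape != p_values.shape or list(rho.index) != list(p_values.index):
        raise ValueError("rho and p_values must be conformable with matching genera")
    genera = list(rho.index)
    g = nx.Graph()
    for i, j in itertools.combinations(range(len(genera)), 2):
        p = p_values.iat[i, j]
        if p < alpha:
            r = rho.iat[i, j]
            if r == 0:
                raise ValueError(
                    f"edge ({genera[i]}, {genera[j]}) significant with rho == 0; "
                    "inconsistent correlation/p-value inputs"
                )
            g.add_edge(genera[i], genera[j], sign="+" if r > 0 else "-", rho=float(r), p=float(p))
    if guilds is not None:
        for node in g.nodes:
            g.nodes[node]["guild"] = str(guilds.get(node, ""))
    return Network(treatment=treatment, graph=g)


def network_metrics(net: Network) -> dict:
    """Metric dict for a network (empty networks give zeros, flagged)."""
    return net.metrics()


@dataclass
class NetPermTest:
    """Cross-treatment permutation comparison of one network metric."""

    treatments: tuple[str, str]
    metric: str
    observed_a: float
    observed_b: float
    observed_diff: float
    n_perm: int
    null_mean: float
    null_sd: float
    null_quantiles: dict[str, float]
    p_value: float
    seed: int
    two_sided: bool = True

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["treatments"] = list(self.treatments)
        return d


def _pair_metric_columns(
    indicators: np.ndarray, incidence: np.ndarray, metric: str
) -> np.ndarray:
    """Metric per column of a pairs x k edge-indicator matrix."""
    e = indicators.sum(axis=0).astype(float)
    if metric == "n_edges":
        return e
    deg = incidence @ indicators  # genera x k
    n = (deg > 0).sum(axis=0).astype(float)
    if metric == "n_nodes":
        return n
    with np.errstate(divide="ignore", invalid="ignore"):
        if metric == "connectance":
            out = np.where(n > 0, e / n**2, 0.0)
        elif metric == "mean_degree":
            out = np.where(n > 0, 2.0 * e / n, 0.0)
        else:
            raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    return out


def permtest_metric(
    net_a: Network,
    net_b: Network,
    metric: str,
    n_perm: int = 10_000,
    seed: int = 0,
    union_genera: list[str] | None = None,
    two_sided: bool = True,
    shuffle: str = "pairwise",
) -> NetPermTest:
    """Permutation test of a metric difference between two treatment networks.

    ``union_genera`` fixes the node universe (defaults to the union of both
    networks' nodes; the study uses genera present in any treatment network).
    ``shuffle='pairwise'`` swaps each pair's two indicators independently with
    probability 1/2; ``'global'`` reshuffles the pooled indicator vector.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if union_genera is None:
        union_genera = sorted(set(net_a.nodes) | set(net_b.nodes))
    missing = (set(net_a.nodes) | set(net_b.nodes)) - set(union_genera)
    if missing:
        raise ValueError(f"union_genera must cover both networks; missing {sorted(missing)}")
    genera = list(union_genera)
    pairs = list(itertools.combinations(range(len(genera)), 2))
    pair_index = {(genera[i], genera[j]): k for k, (i, j) in enumerate(pairs)}

    def indicator(net: Network) -> np.ndarray:
        v = np.zeros(len(pairs), dtype=np.int8)
        for a, b in net.edges:
            v[pair_index[tuple(sorted((a, b)))]] = 1
        return v

    a = indicator(net_a)
    b = indicator(net_b)
    incidence = np.zeros((len(genera), len(pairs)), dtype=np.int8)
    for k, (i, j) in enumerate(pairs):
        incidence[i, k] = incidence[j, k] = 1

    obs_a = _pair_metric_columns(a[:, None], incidence, metric)[0]
    obs_b = _pair_metric_columns(b[:, None], incidence, metric)[0]
    observed = obs_a - obs_b

    rng = np.random.default_rng(seed)
    diffs = np.empty(n_perm)
    chunk = max(1, min(n_perm, int(2e7 // max(len(pairs), 1))))
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        if shuffle == "pairwise":
            swap = rng.integers(0, 2, size=(len(pairs), k), dtype=np.int8).astype(bool)
            pa = np.where(swap, b[:, None], a[:, None])
            pb = np.where(swap, a[:, None], b[:, None])
        elif shuffle == "global":
            pool = np.concatenate([a, b])
            pa = np.empty((len(pairs), k), dtype=np.int8)
            pb = np.empty((len(pairs), k), dtype=np.int8)
            for c in range(k):
                perm = rng.permutation(pool)
                pa[:, c] = perm[: len(pairs)]
                pb[:, c] = perm[len(pairs):]
        else:
            raise ValueError("shuffle must be 'pairwise' or 'global'")
        diffs[done : done + k] = _pair_metric_columns(pa, incidence, metric) - \
            _pair_metric_columns(pb, incidence, metric)
        done += k

    if two_sided:
        extreme = np.abs(diffs) >= abs(observed) - 1e-12
    else:
        extreme = diffs >= observed - 1e-12
    p = (1.0 + extreme.sum()) / (n_perm + 1.0)
    qs = np.quantile(diffs, [0.025, 0.25, 0.5, 0.75, 0.975])
    return NetPermTest(
        treatments=(net_a.treatment, net_b.treatment),
        metric=metric,
        observed_a=float(obs_a),
        observed_b=float(obs_b),
        observed_diff=float(observed),
        n_perm=n_perm,
        null_mean=float(diffs.mean()),
        null_sd=float(diffs.std(ddof=1)) if n_perm > 1 else 0.0,
        null_quantiles={f"q{q}": float(v) for q, v in zip((2.5, 25, 50, 75, 97.5), qs)},
        p_value=float(p),
        seed=seed,
        two_sided=two_sided,
    )
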
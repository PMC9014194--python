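"""Synthetic allele frequencies on trees and admixture graphs.

Populations evolve along a rooted graph: root frequencies are drawn
i.i.d. per SNP, each edge perturbs frequencies by genetic drift of
magnitude tau, and an admixture node is the weighted elementwise average
of its two parents (mixing happens *before* any drift on the node's
outgoing edges, mirroring the distinction between the unobserved mixing
population and the drifted, sampled one). Two drift models:

* ``gaussian_truncated`` — p' = clip(p + Normal(0, tau * p(1-p)), 0, 1);
  tau is branch length in drift units, supports analytic expectations.
* ``binomial_wright_fisher`` — p' = Binomial(N, p)/N with N = round(1/tau),
  a discrete single-step Wright–Fisher sanity check.

Randomness is reproducible: each node's stream is seeded by hashing the
global seed with the node label, so editing one branch never reshuffles
drift elsewhere in the graph.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .exceptions import ValidationError
from .freqs import AlleleFreqMatrix
from .fstats import F2Matrix

__all__ = ["GraphSpec", "SimConfig", "simulate", "expected_f2"]


@dataclass
class GraphSpec:
    """A rooted tree or admixture graph driving the simulator.

    ``edges`` are (parent, child, tau >= 0) drift branches;
    ``admixture_events`` are (child, parent_a, parent_b, w) with
    child = w * parent_a + (1 - w) * parent_b. Every non-root node is
    either the child of exactly one drift edge or of one admixture event.
    ``leaves`` names the nodes emitted as observed populations.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, float], ...]
    admixture_events: tuple[tuple[str, str, str, float], ...] = ()
    leaves: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.nodes = tuple(str(n) for n in self.nodes)
        self.edges = tuple(
            (str(p), str(c), float(t)) for p, c, t in self.edges
        )
        self.admixture_events = tuple(
            (str(c), str(a), str(b), float(w))
            for c, a, b, w in self.admixture_events
        )
        self.leaves = tuple(str(x) for x in self.leaves)
        self._validate()

    def _validate(self) -> None:
        nodes = set(self.nodes)
        if len(nodes) != len(self.nodes):
            raise ValidationError("duplicate node labels")
        admix_children = {c for c, *_ in self.admixture_events}
        drift_children: dict[str, int] = {}
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for p, c, t in self.edges:
            if p not in nodes or c not in nodes:
                raise ValidationError(f"edge ({p}, {c}) names unknown node")
            if t < 0:
                raise ValidationError(f"negative drift on edge ({p}, {c})")
            drift_children[c] = drift_children.get(c, 0) + 1
            g.add_edge(p, c)
        for c, a, b, w in self.admixture_events:
            if {c, a, b} - nodes:
                raise ValidationError(f"admixture event names unknown node")
            if not 0.0 <= w <= 1.0:
                raise ValidationError(f"admixture weight {w} outside [0, 1]")
            g.add_edge(a, c)
            g.add_edge(b, c)
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError("graph contains a cycle")
        roots = [
            n
            for n in self.nodes
            if n not in drift_children and n not in admix_children
        ]
        if len(roots) != 1:
            raise ValidationError(
                f"graph must have exactly one root, found {roots}"
            )
        for c, k in drift_children.items():
            if k > 1:
                raise ValidationError(f"node {c} has {k} incoming drift edges")
            if c in admix_children:
                raise ValidationError(
                    f"node {c} is both a drift child and an admixture child"
                )
        unknown_leaves = set(self.leaves) - nodes
        if unknown_leaves:
            raise ValidationError(f"unknown leaves: {sorted(unknown_leaves)}")
        self._root = roots[0]
        self._graph = g

    @property
    def root(self) -> str:
        return self._root

    @classmethod
    def from_json(cls, path: str | Path) -> "GraphSpec":
        doc = json.loads(Path(path).read_text())
        return cls(
            nodes=tuple(doc["nodes"]),
            edges=tuple((e[0], e[1], e[2]) for e in doc.get("edges", [])),
            admixture_events=tuple(
                (a[0], a[1], a[2], a[3])
                for a in doc.get("admixture_events", [])
            ),
            leaves=tuple(doc.get("leaves", [])),
        )

    def to_json(self, path: str | Path) -> None:
        doc = {
            "nodes": list(self.nodes),
            "edges": [list(e) for e in self.edges],
            "admixture_events": [list(a) for a in self.admixture_events],
            "leaves": list(self.leaves),
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings.

    ``root_distribution`` is ("uniform", lo, hi) or ("beta", a, b); the
    default uniform(0.1, 0.9) keeps frequencies away from the boundaries
    so that truncation of Gaussian drift is negligible at tau <= 0.05.
    """

    n_snps: int = 1000
    root_distribution: tuple = ("uniform", 0.1, 0.9)
    drift_model: str = "gaussian_truncated"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValidationError("need at least one SNP")
        kind = self.root_distribution[0]
        if kind == "uniform":
            _, lo, hi = self.root_distribution
            if not (0.0 <= lo < hi <= 1.0):
                raise ValidationError("uniform bounds must satisfy 0<=lo<hi<=1")
        elif kind == "beta":
            _, a, b = self.root_distribution
            if a <= 0 or b <= 0:
                raise ValidationError("beta parameters must be positive")
        else:
            raise ValidationError(f"unknown root distribution: {kind!r}")
        if self.drift_model not in ("gaussian_truncated", "binomial_wright_fisher"):
            raise ValidationError(f"unknown drift model: {self.drift_model!r}")


def _node_rng(seed: int, label: str) -> np.random.Generator:
    digest = hashlib.sha256(label.encode()).digest()[:8]
    return np.random.default_rng(
        [int(seed) & 0x7FFFFFFF, int.from_bytes(digest, "big")]
    )


def _drift(
    p: np.ndarray, tau: float, model: str, rng: np.random.Generator
) -> np.ndarray:
    if tau == 0.0:
        return p.copy()
    if model == "gaussian_truncated":
        sd = np.sqrt(tau * p * (1.0 - p))
        return np.clip(p + rng.normal(0.0, 1.0, p.shape) * sd, 0.0, 1.0)
    n_eff = max(1, round(1.0 / tau))
    return rng.binomial(n_eff, p) / n_eff


def simulate(
    graph: GraphSpec, cfg: SimConfig
) -> tuple[AlleleFreqMatrix, dict[str, np.ndarray]]:
    """Evolve allele frequencies down the graph.

    Returns the leaf populations as an :class:`AlleleFreqMatrix` plus the
    frequency vectors of *all* nodes (root and internal included) for
    oracle checks. Bit-identical output for identical (graph, cfg).
    """
    if not graph.leaves:
        raise ValidationError("graph defines no leaf populations")
    kind, p1, p2 = cfg.root_distribution
    rng_root = _node_rng(cfg.seed, graph.root)
    if kind == "uniform":
        root_freq = rng_root.uniform(p1, p2, cfg.n_snps)
    else:
        root_freq = rng_root.beta(p1, p2, cfg.n_snps)
    freqs: dict[str, np.ndarray] = {graph.root: root_freq}
    drift_edge = {c: (p, t) for p, c, t in graph.edges}
    admix = {c: (a, b, w) for c, a, b, w in graph.admixture_events}
    for node in nx.topological_sort(graph._graph):
        if node == graph.root:
            continue
        if node in admix:
            a, b, w = admix[node]
            freqs[node] = w * freqs[a] + (1.0 - w) * freqs[b]
        else:
            parent, tau = drift_edge[node]
            freqs[node] = _drift(
                freqs[parent], tau, cfg.drift_model, _node_rng(cfg.seed, node)
            )
    leaf_values = np.vstack([freqs[x] for x in graph.leaves])
    return AlleleFreqMatrix(leaf_values, graph.leaves), freqs


def _root_heterozygosity(cfg: SimConfig) -> float:
    """E[p(1-p)] under the root frequency distribution (closed form)."""
    kind, p1, p2 = cfg.root_distribution
    if kind == "uniform":
        lo, hi = p1, p2
        antider = lambda p: p**2 / 2.0 - p**3 / 3.0
        return (antider(hi) - antider(lo)) / (hi - lo)
    a, b = p1, p2
    return a * b / ((a + b) * (a + b + 1.0))


def expected_f2(graph: GraphSpec, cfg: SimConfig) -> F2Matrix:
    """First-order expected pairwise F2 for an admixture-free graph.

    Under Gaussian drift without boundary truncation, each edge on the
    path between two leaves contributes tau_e * E[p(1-p)]; the
    heterozygosity is approximated as constant along the graph at its
    root-distribution value, so the prediction is accurate for moderate
    total drift (relative error O(total tau)).
    """
    if graph.admixture_events:
        raise ValidationError("expected_f2 supports admixture-free graphs only")
    het = _root_heterozygosity(cfg)
    und = nx.Graph()
    und.add_nodes_from(graph.nodes)
    for p, c, t in graph.edges:
        und.add_edge(p, c, tau=t)
    leaves = graph.leaves
    n = len(leaves)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            path = nx.shortest_path(und, leaves[i], leaves[j])
            total_tau = sum(
                und.edges[u, v]["tau"] for u, v in zip(path, path[1:])
            )
            m[i, j] = m[j, i] = total_tau * het
    return F2Matrix(m, leaves, source="computed")
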
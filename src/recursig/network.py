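"""Protein-interaction subnetwork, axis path and Bayesian-network
direction inference.

The pipeline: filter a STRING-style edge table at combined score >= 600,
take the induced subgraph on the two seed genes and every node within k=1
hops of either seed (restricted to the component containing both seeds),
read off the unweighted shortest seed-to-seed path (the "axis"), detect
communities by greedy modularity agglomeration, learn a linear-Gaussian
Bayesian network over the axis genes per cohort by AIC hill climbing, and
combine the learned edge directions across cohorts into a consensus.

Gaussian AIC scores are identical across Markov-equivalent DAGs, so a
single cohort's learned directions are tie-break artifacts; the consensus
over cohorts is the quantity of interest, and each learned structure also
exposes its undirected skeleton.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import greedy_modularity_communities, modularity
from scipy.stats import hypergeom

from .stats import bh_adjust

log = logging.getLogger(__name__)

DEFAULT_SCORE_THRESHOLD = 600


class NetworkError(ValueError):
    pass


@dataclass
class CommunityPartition:
    membership: dict[str, int]
    modularity_q: float

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))


@dataclass
class DAGStructure:
    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]  # directed (parent, child)
    score_aic: float
    search: str  # hill_climb | exhaustive
    n_enumerated: int = 0  # structures visited (exhaustive search only)

    def skeleton(self) -> set[frozenset]:
        return {frozenset(e) for e in self.edges}


@dataclass
class ConsensusDirections:
    # per unordered pair: counts of supporting cohorts per direction
    tallies: dict[frozenset, dict[str, int]]
    calls: dict[frozenset, str]  # "A->B" | "undetermined"


# ---------------------------------------------------------------------------
# graph construction and topology

def build_graph(edges: pd.DataFrame, score_threshold: int = DEFAULT_SCORE_THRESHOLD) -> nx.Graph:
    """Score-filtered simple graph from a (node1, node2, combined_score)
    table.  Duplicate edges keep the maximum score; self-loops are
    dropped."""
    required = {"node1", "node2", "combined_score"}
    if not required.issubset(edges.columns):
        raise NetworkError(f"edge table needs columns {sorted(required)}")
    G = nx.Graph(score_threshold=score_threshold)
    for i, row in enumerate(edges.itertuples(index=False)):
        a, b, s = str(row.node1), str(row.node2), row.combined_score
        try:
            s = int(s)
        except (TypeError, ValueError):
            raise NetworkError(f"malformed combined_score at row {i}: {s!r}")
        if not 0 <= s <= 1000:
            raise NetworkError(f"combined_score out of range at row {i}: {s}")
        if a == b or s < score_threshold:
            continue
        if G.has_edge(a, b):
            G[a][b]["combined_score"] = max(G[a][b]["combined_score"], s)
        else:
            G.add_edge(a, b, combined_score=s)
    return G


def read_edge_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def extract_centered_subnetwork(graph: nx.Graph, seeds: Sequence[str], k: int = 1) -> nx.Graph:
    """Induced subgraph on the seeds and all nodes within k hops of either
    seed, restricted to the connected component containing both seeds."""
    if len(seeds) != 2:
        raise NetworkError("exactly 2 seed genes required")
    for s in seeds:
        if s not in graph:
            raise NetworkError(f"seed {s} absent from graph")
    nodes = set(seeds)
    for s in seeds:
        nodes |= set(nx.single_source_shortest_path_length(graph, s, cutoff=k))
    sub = graph.subgraph(nodes).copy()
    comps = list(nx.connected_components(sub))
    with_a = next(c for c in comps if seeds[0] in c)
    if seeds[1] not in with_a:
        raise NetworkError(f"no connecting subnetwork at k={k}")
    return sub.subgraph(with_a).copy()


def shortest_axis_path(subnetwork: nx.Graph, seeds: Sequence[str]) -> list[str]:
    """Unweighted shortest path between the seeds; among equal-length
    paths the lexicographically smallest node sequence is returned."""
    if len(seeds) != 2:
        raise NetworkError("exactly 2 seed genes required")
    try:
        paths = nx.all_shortest_paths(subnetwork, seeds[0], seeds[1])
        return min(paths)
    except (nx.NetworkXNoPath, nx.NodeNotFound) as exc:
        raise NetworkError(f"seeds disconnected: {exc}") from exc


def enumerate_paths_oracle(graph: nx.Graph, seeds: Sequence[str]) -> list[str]:
    """Exhaustive simple-path enumeration oracle for small graphs
    (<= 12 nodes): the shortest path with the lexicographic tie-break."""
    if graph.number_of_nodes() > 12:
        raise NetworkError("oracle restricted to <= 12 nodes")
    best = None
    for path in nx.all_simple_paths(graph, seeds[0], seeds[1]):
        key = (len(path), path)
        if best is None or key < best:
            best = key
    if best is None:
        raise NetworkError("seeds disconnected")
    return best[1]


def detect_communities(subnetwork: nx.Graph) -> CommunityPartition:
    """Greedy modularity agglomeration (unweighted edges)."""
    if subnetwork.number_of_nodes() < 2:
        raise NetworkError("need >= 2 nodes")
    comms = greedy_modularity_communities(subnetwork)
    membership = {}
    for i, c in enumerate(sorted(comms, key=lambda c: sorted(c)[0])):
        for node in c:
            membership[node] = i
    q = modularity(subnetwork, comms)
    return CommunityPartition(membership=membership, modularity_q=float(q))


def hub_nodes(subnetwork: nx.Graph, partition: CommunityPartition) -> dict[int, str]:
    """Top-degree node per community (ties toward the alphabetically
    first name), mirroring degree-proportional node sizing in network
    figures."""
    hubs: dict[int, str] = {}
    for node, comm in partition.membership.items():
        cur = hubs.get(comm)
        deg, cur_deg = subnetwork.degree(node), None if cur is None else subnetwork.degree(cur)
        if cur is None or deg > cur_deg or (deg == cur_deg and node < cur):
            hubs[comm] = node
    return hubs


# ---------------------------------------------------------------------------
# linear-Gaussian Bayesian networks

PENALTIES = ("aic", "bic")


def _penalty_weight(penalty: str, n: int) -> float:
    if penalty == "aic":
        return 1.0
    if penalty == "bic":
        return 0.5 * np.log(n)
    raise NetworkError(f"unknown penalty {penalty!r}")


def _node_score(data: np.ndarray, child: int, parents: tuple[int, ...]) -> tuple[float, int]:
    """Maximized Gaussian log-likelihood and free-parameter count of one
    node given its parents (OLS residual variance, MLE)."""
    n = data.shape[0]
    y = data[:, child]
    if parents:
        X = np.column_stack([np.ones(n), data[:, list(parents)]])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
    else:
        resid = y - y.mean()
    sigma2 = float(resid @ resid) / n
    if sigma2 <= 0:
        sigma2 = 1e-300
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
    return ll, len(parents) + 2  # coefficients + intercept + variance


def _total_score(data, parent_sets, cache, w: float = 1.0) -> float:
    total = 0.0
    for child, parents in enumerate(parent_sets):
        key = (child, parents)
        if key not in cache:
            ll, k = _node_score(data, child, parents)
            cache[key] = ll - w * k  # penalized log-likelihood
        total += cache[key]
    return total


def _is_acyclic(adj: dict[int, set], n: int) -> bool:
    color = [0] * n

    def visit(u):
        color[u] = 1
        for v in adj.get(u, ()):  # u -> v
            if color[v] == 1 or (color[v] == 0 and not visit(v)):
                return False
        color[u] = 2
        return True

    return all(color[u] != 0 or visit(u) for u in range(n))


def _score_edge_set(data, names, edges, cache, w: float = 1.0) -> float:
    p = len(names)
    parent_sets = []
    for child in range(p):
        parents = tuple(sorted(u for (u, v) in edges if v == child))
        parent_sets.append(parents)
    return _total_score(data, parent_sets, cache, w)


def learn_dag_hc(data: pd.DataFrame, max_genes: int = 8,
                 penalty: str = "aic") -> DAGStructure:
    """Steepest-ascent hill climbing over single-edge additions, deletions
    and reversals from the empty graph, scoring linear-Gaussian networks
    by penalized log-likelihood.

    ``penalty`` is "aic" (one unit per free parameter; the default, and
    the score used for axis-direction inference) or "bic" (log(n)/2 per
    parameter; the consistent choice for structure-recovery experiments,
    since AIC admits a spurious edge per variable pair with probability
    P(chi2_1 > 2) ~ 0.16).

    Deterministic: candidate moves are evaluated in lexicographic edge
    order and the first move attaining the best strictly positive gain is
    applied.
    """
    names = tuple(data.columns)
    X = data.to_numpy(dtype=float)
    if X.shape[0] < 10:
        raise NetworkError("need >= 10 samples")
    if len(names) > max_genes:
        raise NetworkError(f"too many genes ({len(names)} > {max_genes})")
    if np.any(X.std(axis=0) == 0):
        raise NetworkError("constant column")
    w = _penalty_weight(penalty, X.shape[0])
    p = len(names)
    cache: dict = {}
    edges: set[tuple[int, int]] = set()
    score = _score_edge_set(X, names, edges, cache, w)
    pairs = [(i, j) for i in range(p) for j in range(p) if i != j]
    while True:
        best_gain, best_edges = 0.0, None
        candidates = []
        for (u, v) in sorted(pairs):
            if (u, v) in edges:
                candidates.append(("delete", edges - {(u, v)}))
                if (v, u) not in edges:
                    candidates.append(("reverse", (edges - {(u, v)}) | {(v, u)}))
            elif (v, u) not in edges:
                candidates.append(("add", edges | {(u, v)}))
        for _, new_edges in candidates:
            adj: dict[int, set] = {}
            for a, b in new_edges:
                adj.setdefault(a, set()).add(b)
            if not _is_acyclic(adj, p):
                continue
            new_score = _score_edge_set(X, names, new_edges, cache, w)
            gain = new_score - score
            if gain > best_gain + 1e-12:
                best_gain, best_edges = gain, new_edges
        if best_edges is None:
            break
        edges = best_edges
        score += best_gain
    named = tuple(sorted((names[u], names[v]) for (u, v) in edges))
    return DAGStructure(nodes=names, edges=named, score_aic=float(score), search="hill_climb")


def enumerate_dags_oracle(data: pd.DataFrame, penalty: str = "aic") -> DAGStructure:
    """Exhaustively score every labeled DAG on <= 4 variables and return
    the maximum (543 structures on 4 nodes).  Test oracle for
    :func:`learn_dag_hc`."""
    names = tuple(data.columns)
    p = len(names)
    if p > 4:
        raise NetworkError("oracle restricted to <= 4 genes")
    X = data.to_numpy(dtype=float)
    w = _penalty_weight(penalty, X.shape[0])
    cache: dict = {}
    unordered = list(itertools.combinations(range(p), 2))
    best: Optional[tuple[float, tuple]] = None
    n_seen = 0
    for choice in itertools.product((0, 1, 2), repeat=len(unordered)):
        edges = set()
        for (a, b), c in zip(unordered, choice):
            if c == 1:
                edges.add((a, b))
            elif c == 2:
                edges.add((b, a))
        adj: dict[int, set] = {}
        for a, b in edges:
            adj.setdefault(a, set()).add(b)
        if not _is_acyclic(adj, p):
            continue
        n_seen += 1
        s = _score_edge_set(X, names, edges, cache, w)
        named = tuple(sorted((names[u], names[v]) for (u, v) in edges))
        key = (s, named)
        if best is None or s > best[0] + 1e-12:
            best = (s, named)
    log.info("enumerated %d DAGs on %d nodes", n_seen, p)
    return DAGStructure(nodes=names, edges=best[1], score_aic=float(best[0]),
                        search="exhaustive", n_enumerated=n_seen)


def score_dag(data: pd.DataFrame, edges: Iterable[tuple[str, str]],
              penalty: str = "aic") -> float:
    """Penalized Gaussian log-likelihood of an explicit DAG; used to
    check score equivalence across Markov-equivalent structures."""
    names = tuple(data.columns)
    idx = {n: i for i, n in enumerate(names)}
    edge_idx = {(idx[a], idx[b]) for a, b in edges}
    w = _penalty_weight(penalty, data.shape[0])
    return _score_edge_set(data.to_numpy(dtype=float), names, edge_idx, {}, w)


def direction_consensus(dags: Sequence[DAGStructure]) -> ConsensusDirections:
    """Tally learned directions per unordered pair across cohorts; the
    consensus is the strict majority among cohorts where the edge is
    present; ties and all-absent pairs are undetermined."""
    node_sets = {d.nodes for d in dags}
    if len(node_sets) != 1:
        raise NetworkError("DAGs must share one node set")
    nodes = dags[0].nodes
    tallies: dict[frozenset, dict[str, int]] = {}
    for a, b in itertools.combinations(sorted(nodes), 2):
        key = frozenset((a, b))
        t = {f"{a}->{b}": 0, f"{b}->{a}": 0, "absent": 0}
        for d in dags:
            if (a, b) in d.edges:
                t[f"{a}->{b}"] += 1
            elif (b, a) in d.edges:
                t[f"{b}->{a}"] += 1
            else:
                t["absent"] += 1
        tallies[key] = t
    calls = {}
    for key, t in tallies.items():
        directions = {k: v for k, v in t.items() if k != "absent"}
        present = sum(directions.values())
        if present == 0:
            calls[key] = "undetermined"
            continue
        top, top_n = max(directions.items(), key=lambda kv: kv[1])
        others = present - top_n
        calls[key] = top if top_n > others else "undetermined"
    return ConsensusDirections(tallies=tallies, calls=calls)


# ---------------------------------------------------------------------------
# enrichment

def read_gmt(path) -> dict[str, set]:
    """Read a GMT gene-set collection (name <tab> description <tab>
    genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def hypergeometric_enrichment(
    genes: Iterable[str],
    collections: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a gene set against each
    collection set, BH-adjusted across sets (significant: adjusted
    p < 0.05)."""
    universe = set(universe)
    if not universe:
        raise NetworkError("empty universe")
    query = set(genes)
    if not query.issubset(universe):
        raise NetworkError("query genes must be within the universe")
    rows = []
    for name, members in collections.items():
        members = set(members) & universe
        k = len(query & members)
        M, K, n = len(universe), len(members), len(query)
        p = float(hypergeom.sf(k - 1, M, K, n))
        rows.append({"set": name, "overlap": k, "set_size": K, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"] = bh_adjust(df["p"].to_numpy())
        df["significant"] = df["p_adjusted"] < 0.05
    return df.sort_values("p").reset_index(drop=True)
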
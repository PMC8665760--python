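"""All-vs-all P-value graph, cluster calling, novelty criteria, force layout,
and CLANS-format I/O.

The map treats each sequence as a node; edges carry the pairwise local-
alignment score and its E/P-value. Clusters are connected components of the
subgraph at a P-value cutoff (1e-3 for map display, 1e-10 for the discovery
criteria), components below a minimum size are noise, and the published
novelty rules apply: a cluster is *novel* if no member is traceable to a
seed, and a noise node is an *outlier* if it has few or no connections to
any cluster at the stringent cutoff (quantified as a maximum fraction of its
possible links, default zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import _kernels
from .align import AlignParams, KAParams, log10_evalue, profile_of
from .alphabet import encode
from .records import SequenceRecord


@dataclass
class Edge:
    i: str
    j: str
    score: float
    e_value: float
    p_value: float


@dataclass
class EdgeList:
    nodes: list[str]
    edges: list[Edge] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        order = {n: k for k, n in enumerate(self.nodes)}
        for e in self.edges:
            if e.i == e.j:
                raise ValueError(f"self-edge on {e.i}")
            if not 0.0 <= e.p_value <= 1.0:
                raise ValueError(f"edge {e.i}-{e.j}: P-value out of [0,1]")
            key = (e.i, e.j) if order[e.i] < order[e.j] else (e.j, e.i)
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)

    def subgraph(self, p_cutoff: float) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(
            (e.i, e.j, {"p": e.p_value}) for e in self.edges if e.p_value <= p_cutoff
        )
        return g


@dataclass
class ClusterMap:
    coords: dict[str, tuple[float, float]]
    cluster_of: dict[str, int | None]
    novel_flags: dict[int, bool] = field(default_factory=dict)
    outliers: set[str] = field(default_factory=set)


def allvsall_edges(
    records: list[SequenceRecord],
    params: AlignParams,
    ka: KAParams,
    p_keep: float = 0.1,
) -> EdgeList:
    """Pairwise local alignment of every record pair; keep edges at P <= p_keep.

    P-values are pairwise (search space = len_a * len_b). Stored E/P-values
    are computed in log space so deep similarities do not underflow to an
    uninformative zero (P floors at ~1e-300).
    """
    codes = [encode(r.seq, warn_unknown=False) for r in records]
    profs = [profile_of(c, params) for c in codes]
    edges: list[Edge] = []
    n = len(records)
    for i in range(n):
        for j in range(i + 1, n):
            s = _kernels.local_score(profs[i], codes[j], params.gap_open, params.gap_extend)
            log_e = log10_evalue(s, len(codes[i]), len(codes[j]), ka)
            e_val = 10.0 ** max(log_e, -300.0)
            p_val = max(-math.expm1(-e_val), 1e-300)
            if p_val <= p_keep:
                edges.append(Edge(records[i].id, records[j].id, float(s), e_val, p_val))
    return EdgeList(nodes=[r.id for r in records], edges=edges)


def connected_clusters(
    edges: EdgeList, p_cutoff: float, min_size: int = 1
) -> dict[str, int | None]:
    """Connected components at P <= p_cutoff; components below min_size are noise.

    Cluster ids are deterministic: numbered by decreasing size, ties by the
    smallest member id. Noise nodes map to None.
    """
    if not 0.0 < p_cutoff <= 1.0:
        raise ValueError("p_cutoff must be in (0, 1]")
    comps = [sorted(c) for c in nx.connected_components(edges.subgraph(p_cutoff))]
    comps.sort(key=lambda c: (-len(c), c[0]))
    assignment: dict[str, int | None] = {}
    cid = 0
    for comp in comps:
        if len(comp) >= min_size:
            for node in comp:
                assignment[node] = cid
            cid += 1
        else:
            for node in comp:
                assignment[node] = None
    return assignment


def detect_novel_and_outliers(
    assignment: dict[str, int | None],
    edges: EdgeList,
    seed_membership: dict[str, str | None],
    p_cutoff: float,
    max_link_fraction: float = 0.0,
) -> tuple[dict[int, bool], set[str]]:
    """Apply the novelty and outlier criteria to a cluster assignment.

    A cluster is novel iff it contains no seed-traced node (one with a
    non-None entry in ``seed_membership``). A noise node is an outlier iff
    its links at P <= p_cutoff into clustered nodes are at most
    ``max_link_fraction`` of its possible links (default 0: no connections).
    """
    clusters = sorted({c for c in assignment.values() if c is not None})
    novel = {c: True for c in clusters}
    for node, c in assignment.items():
        if c is not None and seed_membership.get(node) is not None:
            novel[c] = False

    n_clustered = sum(1 for c in assignment.values() if c is not None)
    links: dict[str, int] = {}
    for e in edges.edges:
        if e.p_value > p_cutoff:
            continue
        if assignment.get(e.j) is not None:
            links[e.i] = links.get(e.i, 0) + 1
        if assignment.get(e.i) is not None:
            links[e.j] = links.get(e.j, 0) + 1
    outliers = {
        node
        for node, c in assignment.items()
        if c is None and links.get(node, 0) <= max_link_fraction * max(n_clustered, 1)
    }
    return novel, outliers


def force_layout(
    edges: EdgeList,
    attract_k: float = 1.0,
    repulse_k: float = 0.05,
    p_floor: float = 1e-40,
    max_iter: int = 300,
    cooling: float = 0.97,
    tolerance: float = 1e-4,
    rng_seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """CLANS-style force-directed 2D embedding.

    Attraction along each edge is proportional to its normalized weight
    min(-log10 P, -log10 p_floor)/(-log10 p_floor) times the distance;
    all pairs repel with repulse_k/distance. Displacements are capped and
    cooled per iteration; iteration stops at max_iter or when the mean
    displacement drops below tolerance. Deterministic under rng_seed.
    """
    nodes = list(edges.nodes)
    n = len(nodes)
    rng = np.random.default_rng(rng_seed)
    pos = rng.random((n, 2))
    if n == 1:
        return {nodes[0]: (float(pos[0, 0]), float(pos[0, 1]))}
    index = {node: k for k, node in enumerate(nodes)}
    wmax = -math.log10(p_floor)
    ei = np.array([index[e.i] for e in edges.edges], dtype=np.int64)
    ej = np.array([index[e.j] for e in edges.edges], dtype=np.int64)
    w = np.array(
        [min(-math.log10(max(e.p_value, 1e-300)), wmax) / wmax for e in edges.edges]
    )
    step = 0.1
    for _ in range(max_iter):
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(dist, 1.0)
        force = (repulse_k * diff / dist[:, :, None] ** 2).sum(axis=1)
        if len(ei):
            pull = attract_k * w[:, None] * (pos[ej] - pos[ei])
            np.add.at(force, ei, pull)
            np.add.at(force, ej, -pull)
        disp = np.clip(force * step, -step, step)
        pos += disp
        step *= cooling
        if np.abs(disp).mean() < tolerance:
            break
    return {node: (float(pos[k, 0]), float(pos[k, 1])) for node, k in index.items()}


# ---------------------------------------------------------------------------
# CLANS text format


class ClansParseError(ValueError):
    pass


def write_clans(
    records: list[SequenceRecord],
    edges: EdgeList,
    coords: dict[str, tuple[float, float]],
    path,
) -> None:
    """Write the CLANS text dialect: sequences=N header, <seq>, <pos>, <hsp>."""
    index = {r.id: k for k, r in enumerate(records)}
    with open(path, "w") as fh:
        fh.write(f"sequences={len(records)}\n")
        fh.write("<seq>\n")
        for r in records:
            fh.write(f">{r.header()}\n{r.seq}\n")
        fh.write("</seq>\n")
        fh.write("<pos>\n")
        for r in records:
            x, y = coords[r.id]
            fh.write(f"{index[r.id]} {x!r} {y!r} 0.0\n")
        fh.write("</pos>\n")
        fh.write("<hsp>\n")
        for e in edges.edges:
            fh.write(f"{index[e.i]} {index[e.j]}:{e.p_value!r}\n")
        fh.write("</hsp>\n")


def read_clans(path):
    """Parse a CLANS file back to (records, edges, coords).

    Scores and E-values are not stored in the format; re-read edges carry
    the P-value with score/E-value set to NaN.
    """
    from pathlib import Path

    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("sequences="):
        raise ClansParseError("header: expected 'sequences=<N>' on line 1")
    try:
        n_seq = int(lines[0].split("=", 1)[1])
    except ValueError as exc:
        raise ClansParseError("header: sequence count is not an integer") from exc

    blocks: dict[str, list[tuple[int, str]]] = {}
    current = None
    for lineno, line in enumerate(lines[1:], start=2):
        s = line.strip()
        if not s:
            continue
        if s.startswith("<") and s.endswith(">") and not s.startswith("</"):
            current = s[1:-1]
            blocks[current] = []
        elif s.startswith("</"):
            if current != s[2:-1]:
                raise ClansParseError(f"block {s[2:-1]!r}: mismatched close at line {lineno}")
            current = None
        else:
            if current is None:
                raise ClansParseError(f"line {lineno}: content outside any block")
            blocks[current].append((lineno, s))

    for name in ("seq", "pos", "hsp"):
        if name not in blocks:
            raise ClansParseError(f"block {name!r}: missing")

    records: list[SequenceRecord] = []
    header = None
    for lineno, s in blocks["seq"]:
        if s.startswith(">"):
            header = s[1:]
        else:
            if header is None:
                raise ClansParseError(f"block 'seq': sequence before header at line {lineno}")
            records.append(SequenceRecord.from_header(header, s))
            header = None
    if len(records) != n_seq:
        raise ClansParseError(
            f"block 'seq': {len(records)} records but header says {n_seq}"
        )

    coords: dict[str, tuple[float, float]] = {}
    for lineno, s in blocks["pos"]:
        parts = s.split()
        try:
            if len(parts) != 4:
                raise ValueError
            idx = int(parts[0])
            xy = (float(parts[1]), float(parts[2]))
        except ValueError as exc:
            raise ClansParseError(
                f"block 'pos': expected 'index x y z' at line {lineno}"
            ) from exc
        if not 0 <= idx < n_seq:
            raise ClansParseError(f"block 'pos': index {idx} out of range at line {lineno}")
        coords[records[idx].id] = xy

    edge_list: list[Edge] = []
    for lineno, s in blocks["hsp"]:
        try:
            left, pval = s.split(":", 1)
            i, j = (int(x) for x in left.split())
            p = float(pval)
        except ValueError as exc:
            raise ClansParseError(f"block 'hsp': expected 'i j:p' at line {lineno}") from exc
        if not (0 <= i < n_seq and 0 <= j < n_seq):
            raise ClansParseError(f"block 'hsp': index out of range at line {lineno}")
        edge_list.append(Edge(records[i].id, records[j].id, math.nan, math.nan, p))

    return records, EdgeList(nodes=[r.id for r in records], edges=edge_list), coords
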
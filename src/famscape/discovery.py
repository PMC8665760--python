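"""Orchestration of the full iterative discovery protocol.

Round structure: profile-iterated searches from every pending seed; pooling
with duplicate and fragment removal; redundancy filtering; all-vs-all
clustering of the pool at the stringent P cutoff; detection of novel
clusters (not traceable to any seed) and outliers; re-seeding from one
central representative per novel cluster plus each outlier. The loop stops
when a round adds no new sequences to the pool, at which point the final
map, per-family member lists and per-round log are emitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .align import AlignParams, calibrate_evalue, sw_align
from .clustermap import (
    ClusterMap,
    EdgeList,
    allvsall_edges,
    connected_clusters,
    detect_novel_and_outliers,
    force_layout,
)
from .config import PipelineConfig
from .psearch import calibration_seed, iterative_search
from .records import SequenceRecord
from .redundancy import filter_redundant


@dataclass
class Provenance:
    found_by: str
    round_index: int


@dataclass
class DiscoveryResult:
    pool: dict[str, Provenance]
    records: list[SequenceRecord]
    edges: EdgeList
    cluster_map: ClusterMap
    families: dict[int, list[str]]
    log: list[dict]
    converged: bool

    def seed_chain(self, record_id: str) -> list[str]:
        """Provenance chain from a pooled record back to an original seed."""
        chain = [record_id]
        while True:
            prov = self.pool[chain[-1]]
            if prov.found_by == chain[-1]:
                return chain
            chain.append(prov.found_by)


def _remove_duplicates_and_fragments(
    records: list[SequenceRecord],
    params: AlignParams,
    fragment_identity: float,
    fragment_coverage: float,
) -> list[SequenceRecord]:
    """Drop exact sequence duplicates, then fragments: a record contained in a
    longer record at >= fragment_identity over (nearly) its full length."""
    seen: dict[str, str] = {}
    unique: list[SequenceRecord] = []
    for rec in sorted(records, key=lambda r: r.id):
        if rec.seq in seen:
            continue
        seen[rec.seq] = rec.id
        unique.append(rec)
    unique.sort(key=lambda r: (-len(r), r.id))
    kept: list[SequenceRecord] = []
    for rec in unique:
        is_fragment = False
        for longer in kept:
            if len(longer) <= len(rec):
                continue
            aln = sw_align(longer.seq, rec.seq, params)
            if aln.identity >= fragment_identity and aln.coverage >= fragment_coverage:
                is_fragment = True
                break
        if not is_fragment:
            kept.append(rec)
    return kept


def _central_member(cluster_nodes: list[str], edges: EdgeList) -> str:
    """Member with the highest summed -log10 P to its co-members."""
    members = set(cluster_nodes)
    weight = {n: 0.0 for n in cluster_nodes}
    for e in edges.edges:
        if e.i in members and e.j in members:
            w = -math.log10(max(e.p_value, 1e-300))
            weight[e.i] += w
            weight[e.j] += w
    return max(sorted(weight), key=lambda n: weight[n])


def run_discovery(
    seeds: list[SequenceRecord],
    db: list[SequenceRecord],
    config: PipelineConfig | None = None,
) -> DiscoveryResult:
    """Run the iterative search-pool-filter-cluster-reseed protocol.

    Terminates when no new records enter the pool (or at
    ``discovery_max_rounds``, flagged via ``converged=False``). The final
    cluster map is laid out with the force-directed embedding; families are
    the clusters of the final assignment.
    """
    if not seeds:
        raise ValueError("at least one seed is required")
    config = config or PipelineConfig()
    params = AlignParams(gap_open=config.gap_open, gap_extend=config.gap_extend)
    by_id = {r.id: r for r in db}
    for s in seeds:
        by_id.setdefault(s.id, s)

    pool: dict[str, Provenance] = {}
    searched: set[str] = set()
    pending: list[SequenceRecord] = list(seeds)
    log: list[dict] = []
    converged = False

    lengths = sorted(len(r.seq) for r in db) or [len(seeds[0].seq)]
    calib_len = max(50, lengths[len(lengths) // 2])
    ka = calibrate_evalue(
        params, calib_len, n_shuffles=config.calib_shuffles,
        rng_seed=calibration_seed(config.rng_seed, "allvsall", 0),
    )

    edges = EdgeList(nodes=[])
    assignment: dict[str, int | None] = {}
    novel: dict[int, bool] = {}
    outliers: set[str] = set()
    retained_records: list[SequenceRecord] = []

    for round_index in range(1, config.discovery_max_rounds + 1):
        new_ids: list[str] = []
        for seed in pending:
            searched.add(seed.id)
            if seed.id not in pool:
                pool[seed.id] = Provenance(found_by=seed.id, round_index=round_index)
                new_ids.append(seed.id)
            result = iterative_search(seed, db, config)
            for rid in result.accepted:
                if rid not in pool:
                    pool[rid] = Provenance(found_by=seed.id, round_index=round_index)
                    new_ids.append(rid)

        pooled = [by_id[rid] for rid in sorted(pool)]
        deduped = _remove_duplicates_and_fragments(
            pooled, params, config.fragment_identity, config.fragment_coverage
        )
        filt = filter_redundant(
            deduped, config.filter_max_identity, config.filter_min_coverage, params
        )
        retained_records = [r for r in deduped if r.id in set(filt.retained)]

        edges = allvsall_edges(retained_records, params, ka, p_keep=config.edge_p_keep)
        assignment = connected_clusters(
            edges, config.discovery_cluster_p, config.discovery_min_cluster_size
        )
        seed_membership = {rid: (rid if rid in searched else None) for rid in assignment}
        novel, outliers = detect_novel_and_outliers(
            assignment, edges, seed_membership,
            config.discovery_cluster_p, config.outlier_max_link_fraction,
        )

        next_seeds: list[SequenceRecord] = []
        clusters: dict[int, list[str]] = {}
        for node, c in assignment.items():
            if c is not None:
                clusters.setdefault(c, []).append(node)
        for c, members in sorted(clusters.items()):
            if novel.get(c):
                rep = _central_member(members, edges)
                if rep not in searched:
                    next_seeds.append(by_id[rep])
        for node in sorted(outliers):
            if node not in searched:
                next_seeds.append(by_id[node])

        log.append(
            {
                "round": round_index,
                "seeds_searched": sorted(s.id for s in pending),
                "new_records": len(new_ids),
                "pool_size": len(pool),
                "map_size": len(retained_records),
                "n_clusters": len(clusters),
                "n_novel": sum(novel.values()),
                "n_outliers": len(outliers),
            }
        )

        if round_index > 1 and not new_ids:
            converged = True
            break
        if not next_seeds:
            converged = True
            break
        pending = next_seeds

    coords = force_layout(
        edges,
        attract_k=config.attract_k,
        repulse_k=config.repulse_k,
        p_floor=config.p_floor,
        max_iter=config.layout_max_iter,
        cooling=config.layout_cooling,
        tolerance=config.layout_tolerance,
        rng_seed=config.rng_seed,
    )
    cluster_map = ClusterMap(
        coords=coords, cluster_of=assignment, novel_flags=novel, outliers=outliers
    )
    families = {}
    for node, c in assignment.items():
        if c is not None:
            families.setdefault(c, []).append(node)
    families = {c: sorted(m) for c, m in sorted(families.items())}
    return DiscoveryResult(
        pool=pool,
        records=retained_records,
        edges=edges,
        cluster_map=cluster_map,
        families=families,
        log=log,
        converged=converged,
    )
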
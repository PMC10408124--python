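"""RBP subtype clustering and redundancy removal.

Subtypes are the connected components of the graph whose edges are passing
RBD hits (single linkage): any chain of qualifying pairwise links merges
clusters, which is how horizontal-transfer hits chain transitively across
phage genera.  Two redundancy rules thin the dataset:

* same-serogroup dedupe — among records of one host serogroup, records
  >= 80 % full-length identity to an already-kept record are collapsed,
  keeping the highest prophage score first;
* within-genus dedupe — one representative per (subtype, genus) cell.

Removed records ("doubles") keep their host-serogroup votes: each removed
record's serogroup is recorded on its surviving representative so that the
later consensus validation still counts it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx

from .align import PairwiseHit, global_identity_pct
from .config import PipelineConfig
from .records import RBPRecord

#: (representative rbp_id) -> [(removed rbp_id, removed host_serogroup)]
DoublesMap = Dict[str, List[Tuple[str, Optional[str]]]]


@dataclass(frozen=True)
class SubtypeCluster:
    """A connected component of passing RBD hits.

    ``subtype_id`` is the lexicographically smallest member id, which makes
    the partition stable under input reordering.
    """

    subtype_id: str
    member_rbp_ids: frozenset
    genera_present: frozenset
    serogroups_observed: Tuple[str, ...]  # known serogroups, sorted, multiset


def cluster_subtypes(
    records: Sequence[RBPRecord], hits: Sequence[PairwiseHit]
) -> List[SubtypeCluster]:
    """Partition records into subtypes by single-linkage over passing hits."""
    by_id = {r.rbp_id: r for r in records}
    graph = nx.Graph()
    graph.add_nodes_from(by_id)
    for hit in hits:
        if hit.passes:
            if hit.query_id not in by_id or hit.subject_id not in by_id:
                raise KeyError(
                    f"hit references unknown record "
                    f"{hit.query_id!r}/{hit.subject_id!r}"
                )
            graph.add_edge(hit.query_id, hit.subject_id)
    clusters = []
    for component in nx.connected_components(graph):
        members = frozenset(component)
        recs = [by_id[m] for m in members]
        clusters.append(
            SubtypeCluster(
                subtype_id=min(members),
                member_rbp_ids=members,
                genera_present=frozenset(r.genus for r in recs),
                serogroups_observed=tuple(
                    sorted(
                        r.host_serogroup
                        for r in recs
                        if r.host_serogroup is not None
                    )
                ),
            )
        )
    return sorted(clusters, key=lambda c: c.subtype_id)


_GROUP_RANK = {g: i for i, g in enumerate("ABCDEF")}


def keep_priority(record: RBPRecord) -> tuple:
    """Sort key for redundancy removal; earlier records are kept.

    Priority: higher prophage score, stronger evidence group (A first),
    longer sequence, then smaller rbp_id.
    """
    score = record.prophage_score if record.prophage_score is not None else -1.0
    return (
        -score,
        _GROUP_RANK[record.evidence_group.value],
        -record.length,
        record.rbp_id,
    )


def dedupe_same_serogroup(
    records: Sequence[RBPRecord], cfg: PipelineConfig
) -> Tuple[List[RBPRecord], DoublesMap]:
    """Collapse near-duplicate RBPs (>= redundancy_identity) per serogroup.

    Greedy by keep-priority: a record is removed when its full-length
    global identity to an already-kept record of the same host serogroup
    reaches the threshold.  Records with unknown serogroup always pass.
    Kept records are returned in input order.
    """
    kept_ids: set = set()
    doubles: DoublesMap = {}
    by_serogroup: Dict[str, List[RBPRecord]] = {}
    for rec in records:
        if rec.host_serogroup is None:
            kept_ids.add(rec.rbp_id)
        else:
            by_serogroup.setdefault(rec.host_serogroup, []).append(rec)
    for serogroup in sorted(by_serogroup):
        group_kept: List[RBPRecord] = []
        for rec in sorted(by_serogroup[serogroup], key=keep_priority):
            rep = next(
                (
                    k
                    for k in group_kept
                    if global_identity_pct(rec.aa_sequence, k.aa_sequence, cfg)
                    >= cfg.redundancy_identity
                ),
                None,
            )
            if rep is None:
                group_kept.append(rec)
                kept_ids.add(rec.rbp_id)
            else:
                doubles.setdefault(rep.rbp_id, []).append(
                    (rec.rbp_id, rec.host_serogroup)
                )
    return [r for r in records if r.rbp_id in kept_ids], doubles


def dedupe_within_genus(
    clusters: Sequence[SubtypeCluster], records: Sequence[RBPRecord]
) -> Tuple[List[RBPRecord], DoublesMap]:
    """Keep one representative per (subtype, genus) cell.

    Every nonempty cell keeps exactly one record; the serogroups of the
    removed doubles are recorded on the representative.
    """
    by_id = {r.rbp_id: r for r in records}
    kept_ids: set = set()
    doubles: DoublesMap = {}
    for cluster in clusters:
        cells: Dict[str, List[RBPRecord]] = {}
        for rbp_id in cluster.member_rbp_ids:
            rec = by_id[rbp_id]
            cells.setdefault(rec.genus, []).append(rec)
        for genus in sorted(cells):
            ranked = sorted(cells[genus], key=keep_priority)
            rep, removed = ranked[0], ranked[1:]
            kept_ids.add(rep.rbp_id)
            for rec in removed:
                doubles.setdefault(rep.rbp_id, []).append(
                    (rec.rbp_id, rec.host_serogroup)
                )
    return [r for r in records if r.rbp_id in kept_ids], doubles


def restrict_clusters(
    clusters: Sequence[SubtypeCluster],
    records: Sequence[RBPRecord],
) -> List[SubtypeCluster]:
    """Restrict a partition to a surviving record subset (ids recomputed)."""
    by_id = {r.rbp_id: r for r in records}
    out: List[SubtypeCluster] = []
    for cluster in clusters:
        members = frozenset(m for m in cluster.member_rbp_ids if m in by_id)
        if not members:
            continue
        recs = [by_id[m] for m in members]
        out.append(
            SubtypeCluster(
                subtype_id=min(members),
                member_rbp_ids=members,
                genera_present=frozenset(r.genus for r in recs),
                serogroups_observed=tuple(
                    sorted(
                        r.host_serogroup
                        for r in recs
                        if r.host_serogroup is not None
                    )
                ),
            )
        )
    return sorted(out, key=lambda c: c.subtype_id)
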
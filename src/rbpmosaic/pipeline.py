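"""End-to-end orchestration of the RBP serogroup-specificity pipeline.

Stage order follows the dataset-assembly procedure: metadata pre-filters
(prophage activity, rough host strains), same-serogroup redundancy
removal, anchor/RBD delineation, all-vs-all RBD hits, single-linkage
subtype clustering, within-genus redundancy removal, serogroup
assignment, the genus filter, accounting, domain phylogenies with
nearest-neighbor concordance, and the conserved-DNA-motif scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

from . import align, delineation, filters, motifs, phylo, subtyping, validation
from .config import PipelineConfig
from .records import Lifestyle, RBPRecord

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    records_input: List[RBPRecord]
    records_filtered: List[RBPRecord]
    dropped: Dict[str, str]                      # rbp_id -> reason code
    prophage_flags: Dict[str, str]
    records_deduped: List[RBPRecord]             # after same-serogroup dedupe
    doubles_serogroup: subtyping.DoublesMap
    delineations: Dict[str, delineation.DomainDelineation]
    hits: List[align.PairwiseHit]
    clusters: List[subtyping.SubtypeCluster]     # partition of records_deduped
    records_representative: List[RBPRecord]      # after within-genus dedupe
    doubles_genus: subtyping.DoublesMap
    clusters_representative: List[subtyping.SubtypeCluster]
    assigned: List[validation.AssignedCluster]
    final_records: List[RBPRecord]
    ledger: validation.LedgerReport
    concordance: Dict[str, float] = field(default_factory=dict)
    trees: Dict[str, str] = field(default_factory=dict)
    motifs: List[motifs.MotifHit] = field(default_factory=list)


def _merge_doubles(
    primary: subtyping.DoublesMap, secondary: subtyping.DoublesMap
) -> subtyping.DoublesMap:
    """Chain doubles maps: votes of records removed earlier follow their
    representative when that representative is itself removed later."""
    merged: subtyping.DoublesMap = {k: list(v) for k, v in primary.items()}
    for rep, removed in secondary.items():
        bucket = merged.setdefault(rep, [])
        for rid, serogroup in removed:
            bucket.append((rid, serogroup))
            bucket.extend(merged.pop(rid, []))
    return merged


def run_pipeline(
    records: Sequence[RBPRecord],
    cfg: Optional[PipelineConfig] = None,
    boundary_table: Optional[Mapping[str, int]] = None,
    compute_phylo: bool = True,
    compute_motifs: bool = True,
    motif_seed: Optional[int] = None,
) -> PipelineResult:
    cfg = cfg or PipelineConfig()
    records = list(records)

    # 1. metadata pre-filters
    kept, prophage_flags = filters.filter_prophages(records, cfg)
    dropped = {
        rid: flag for rid, flag in prophage_flags.items() if flag.startswith("dropped")
    }
    kept, rough_dropped = filters.filter_rough_hosts(kept, cfg)
    dropped.update(rough_dropped)

    # 2. same-serogroup redundancy removal (full-length identity)
    deduped, doubles_sero = subtyping.dedupe_same_serogroup(kept, cfg)
    for rep, removed in doubles_sero.items():
        for rid, _ in removed:
            dropped[rid] = f"redundant_same_serogroup:{rep}"

    # 3. delineation and RBD hits
    delins = delineation.delineate(deduped, cfg, boundary_table)
    hits = align.all_vs_all_hits(deduped, delins, cfg)

    # 4. subtype clustering and within-genus dedupe
    clusters = subtyping.cluster_subtypes(deduped, hits)
    reps, doubles_genus = subtyping.dedupe_within_genus(clusters, deduped)
    clusters_rep = subtyping.restrict_clusters(clusters, reps)
    for rep, removed in doubles_genus.items():
        for rid, _ in removed:
            dropped[rid] = f"redundant_within_genus:{rep}"

    # 5. serogroup assignment with doubles votes, genus filter, ledger
    doubles_all = _merge_doubles(doubles_sero, doubles_genus)
    assigned = validation.assign_all(clusters_rep, reps, cfg, doubles_all)
    final_records = validation.genus_filter(assigned, reps, cfg)
    ledger = validation.build_ledger(records, assigned, final_records, dropped)

    result = PipelineResult(
        records_input=records,
        records_filtered=kept,
        dropped=dropped,
        prophage_flags=prophage_flags,
        records_deduped=deduped,
        doubles_serogroup=doubles_sero,
        delineations=delins,
        hits=hits,
        clusters=clusters,
        records_representative=reps,
        doubles_genus=doubles_genus,
        clusters_representative=clusters_rep,
        assigned=assigned,
        final_records=final_records,
        ledger=ledger,
    )

    # 6. domain phylogenies + concordance on the final data set
    if compute_phylo and len(final_records) >= 3:
        genus_labels = {r.rbp_id: r.genus for r in final_records}
        sero_labels = {
            r.rbp_id: r.host_serogroup or "unknown" for r in final_records
        }
        usable = [r for r in final_records if delins[r.rbp_id].anchor_end > 0]
        for region, labels in (
            ("anchor", genus_labels),
            ("rbd", sero_labels),
            ("full", sero_labels),
        ):
            recs = usable if region == "anchor" else final_records
            if len(recs) < 3:
                continue
            ids, identity = align.identity_matrix(recs, region, delins, cfg)
            dm = phylo.distances_from_identity(ids, identity, region)
            result.trees[region] = phylo.nj_tree(dm)
            label_key = "genus" if region == "anchor" else "serogroup"
            try:
                result.concordance[f"{region}_{label_key}"] = (
                    phylo.label_concordance(dm, labels)
                )
            except phylo.PhyloError as exc:
                logger.warning("concordance undefined for %s: %s", region, exc)
        # control: anchors should NOT sort by serogroup
        if len(usable) >= 3:
            ids, identity = align.identity_matrix(usable, "anchor", delins, cfg)
            dm = phylo.distances_from_identity(ids, identity, "anchor")
            try:
                result.concordance["anchor_serogroup"] = phylo.label_concordance(
                    dm, sero_labels
                )
            except phylo.PhyloError as exc:
                logger.warning("anchor/serogroup concordance undefined: %s", exc)

    # 7. conserved DNA motifs on lytic records carrying nucleotide data
    if compute_motifs:
        lytic = [
            r
            for r in deduped
            if r.lifestyle is Lifestyle.lytic and r.nt_sequence is not None
        ]
        if len(lytic) >= cfg.motifs.min_members:
            seed = cfg.rng_seed if motif_seed is None else motif_seed
            result.motifs = motifs.find_motifs(lytic, delins, cfg, seed)

    return result
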
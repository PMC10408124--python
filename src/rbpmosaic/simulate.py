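"""Synthetic RBP datasets with known ground truth.

The generator emulates the statistical structures the pipeline assumes
about real modular phage RBPs:

* per-genus ancestral anchor domains, near-conserved within a genus
  (default 5 % per-site divergence);
* serogroup-linked RBD families shared across genera (horizontal
  transfer), diverged within a family by up to 40 % substitutions and
  unrelated (background identity) between families;
* near-duplicate records at >= 80 % identity for the redundancy rules;
* decoy clusters whose host-serogroup labels mix below the 90 %
  consensus, and records with unknown host serogroup;
* conserved DNA motifs planted at the anchor/RBD boundary of the CDS and
  in the noncoding flank downstream of the stop codon (lytic genera
  only), mutated per site at a configurable rate.

Substitutions are drawn per site uniformly over alternative residues or
bases; there are no indels, so the planted anchor boundary is exact.
Nucleotide sequences are back-translated with a fixed codon table; the
boundary motif is planted at the DNA level and the affected codons are
re-translated back into the protein, so the CDS-translation invariant
holds exactly while the DNA-level motif identity matches the configured
mutation rate.  Everything is deterministic for a fixed (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

AA20 = "ACDEFGHIKLMNPQRSTVWY"
BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}

#: Fixed back-translation table (one high-usage codon per residue).
CODON = {
    "A": "GCG", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGC", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGC",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAT",
}

_TRANSLATE = {v: k for k, v in CODON.items()}


class GeneratorError(ValueError):
    """Raised for contradictory generator configurations."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic datasets.

    Defaults are scaled to a desk-size analysis: 5 genera (one temperate,
    contributing prophage records), 6 serogroup-linked RBD families spread
    across genera by horizontal transfer, anchors of 150-210 aa diverged
    5 % within a genus, RBDs of 350-600 aa diverged up to 40 % within a
    family, plus planted near-duplicates, one decoy cluster with mixed
    host serogroups, records with unknown serogroup, and boundary (44 nt)
    and downstream (20 nt) DNA motifs mutated at 15 % per site.
    """

    n_genera: int = 5
    n_temperate_genera: int = 1
    n_families: int = 6
    family_size_range: Tuple[int, int] = (3, 5)
    anchor_len_range: Tuple[int, int] = (150, 210)
    rbd_len_range: Tuple[int, int] = (350, 600)
    anchor_divergence: float = 0.05
    rbd_divergence_range: Tuple[float, float] = (0.0, 0.40)
    hgt_fraction: float = 0.3
    n_redundant: int = 2
    duplicate_divergence: float = 0.03
    n_decoys: int = 1
    decoy_size: int = 3
    n_unknown: int = 2
    branched_phage: bool = True
    motif_boundary_len: int = 44
    motif_downstream_len: int = 20
    motif_downstream_offset: int = 20  # 0-based offset into the flank
    motif_mut_rate: float = 0.15
    downstream_flank_len: int = 120
    serogroup_pool: Tuple[str, ...] = (
        "O157", "O26", "O103", "O111", "O145", "O104",
        "O45", "O91", "O146", "O78", "O18", "4s/O22",
    )

    def __post_init__(self) -> None:
        lo, hi = self.rbd_divergence_range
        if not 0.0 <= lo <= hi < 0.85:
            raise GeneratorError(
                "within-family RBD divergence must stay below background "
                "(cross-family) divergence"
            )
        if self.n_families + 2 * self.n_decoys + 0 > len(self.serogroup_pool):
            raise GeneratorError("serogroup pool too small for families + decoys")
        if self.n_temperate_genera >= self.n_genera:
            raise GeneratorError("at least one lytic genus is required")
        if self.motif_boundary_len >= 3 * self.anchor_len_range[0]:
            raise GeneratorError("boundary motif longer than the shortest anchor CDS")
        if (
            self.motif_downstream_offset + self.motif_downstream_len
            > self.downstream_flank_len
        ):
            raise GeneratorError("downstream motif does not fit in the flank")


@dataclass
class SyntheticTruth:
    """Planted ground truth, serializable alongside the dataset."""

    seed: int
    genera: Dict[str, dict]            # genus -> {anchor_len, lifestyle}
    families: Dict[str, str]           # family id -> serogroup
    per_record: Dict[str, dict]        # rbp_id -> provenance
    redundancy_pairs: List[Tuple[str, str]]  # (original, near-duplicate)
    motif_boundary: Dict[str, Tuple[int, int]]   # rbp_id -> CDS nt span
    motif_downstream: Dict[str, Tuple[int, int]] # rbp_id -> flank nt span
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        raw = json.loads(text)
        raw["redundancy_pairs"] = [tuple(p) for p in raw["redundancy_pairs"]]
        raw["motif_boundary"] = {
            k: tuple(v) for k, v in raw["motif_boundary"].items()
        }
        raw["motif_downstream"] = {
            k: tuple(v) for k, v in raw["motif_downstream"].items()
        }
        return cls(**raw)


# ---------------------------------------------------------------------------
# sequence-level helpers
# ---------------------------------------------------------------------------

def random_aa(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(AA20))[rng.integers(0, 20, length)])


def random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, length)])


def mutate_aa(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Per-site substitution to a uniformly drawn alternative residue."""
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        alternatives = AA20.replace(out[i], "")
        out[i] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(out)


def mutate_nt(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        alternatives = BASES.replace(out[i], "")
        out[i] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(out)


def mutate_nt_wobble(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Concentrate an average per-site rate on third codon positions.

    Used for motifs planted inside a CDS: the overall expected number of
    substitutions matches ``rate * len(seq)`` but changes land on wobble
    positions, so the encoded peptide stays conserved while the DNA
    diverges — codon-level conservation exceeding amino-acid needs, as
    observed in real recombination-hotspot motifs.
    """
    out = list(seq)
    wobble_rate = min(3.0 * rate, 1.0)
    draws = rng.random(len(seq))
    for i in range(2, len(seq), 3):
        if draws[i] < wobble_rate:
            alternatives = BASES.replace(out[i], "")
            out[i] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(out)


def back_translate(aa: str) -> str:
    return "".join(CODON[res] for res in aa)


def translate_fixed(cds: str) -> str:
    """Translate using the standard code (via Biopython) — exact inverse of
    back_translate only on its own codons, general otherwise."""
    from Bio.Seq import Seq

    return str(Seq(cds).translate())


def _repair_stops(cds: List[str], lo_codon: int, hi_codon: int) -> None:
    """Edit the third base of any stop codon in [lo_codon, hi_codon).

    TAA/TAG -> TAC (Tyr), TGA -> TGC (Cys): the minimal deterministic fix
    that keeps the first two motif bases intact.
    """
    for c in range(lo_codon, hi_codon):
        codon = "".join(cds[3 * c : 3 * c + 3])
        if codon in STOPS:
            cds[3 * c + 2] = "C"


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def generate_dataset(
    gen_cfg: Optional[GeneratorConfig] = None, seed: int = 0
):
    """Generate (records, truth) for one synthetic study.

    Deterministic for a fixed (gen_cfg, seed).  Every emitted record maps
    to exactly one truth entry.
    """
    from .records import RBPRecord  # local import keeps module load light

    cfg = gen_cfg or GeneratorConfig()
    rng = np.random.default_rng(seed)

    genus_names = [f"genus{i + 1:02d}" for i in range(cfg.n_genera)]
    n_lytic = cfg.n_genera - cfg.n_temperate_genera
    genera: Dict[str, dict] = {}
    anchors: Dict[str, str] = {}
    for i, name in enumerate(genus_names):
        anchor_len = int(rng.integers(cfg.anchor_len_range[0],
                                      cfg.anchor_len_range[1] + 1))
        anchors[name] = random_aa(rng, anchor_len)
        genera[name] = {
            "anchor_len": anchor_len,
            "lifestyle": "lytic" if i < n_lytic else "temperate",
        }

    families: Dict[str, str] = {}
    family_rbd: Dict[str, str] = {}
    family_home: Dict[str, str] = {}
    for f in range(cfg.n_families):
        fid = f"fam{f + 1:02d}"
        families[fid] = cfg.serogroup_pool[f]
        family_rbd[fid] = random_aa(
            rng, int(rng.integers(cfg.rbd_len_range[0], cfg.rbd_len_range[1] + 1))
        )
        family_home[fid] = genus_names[f % cfg.n_genera]
    decoy_ids: List[str] = []
    for d in range(cfg.n_decoys):
        fid = f"decoy{d + 1:02d}"
        decoy_ids.append(fid)
        family_rbd[fid] = random_aa(
            rng, int(rng.integers(cfg.rbd_len_range[0], cfg.rbd_len_range[1] + 1))
        )
        family_home[fid] = genus_names[int(rng.integers(0, cfg.n_genera))]

    # record specs: (genus, family, serogroup, evidence, unknown_flag)
    specs: List[dict] = []

    def other_genus(home: str) -> str:
        choices = [g for g in genus_names if g != home]
        return choices[int(rng.integers(0, len(choices)))]

    for fid in sorted(families):
        size = int(
            rng.integers(cfg.family_size_range[0], cfg.family_size_range[1] + 1)
        )
        for m in range(size):
            home = family_home[fid]
            if m == 0 or rng.random() > cfg.hgt_fraction:
                genus = home
            else:
                genus = other_genus(home)
            specs.append(
                {
                    "genus": genus,
                    "family": fid,
                    "serogroup": families[fid],
                    "evidence": "A" if m == 0 else ("C", "E", "F")[
                        int(rng.integers(0, 3))
                    ],
                    "hgt": genus != home,
                }
            )

    label_cursor = cfg.n_families
    for fid in decoy_ids:
        label_a = cfg.serogroup_pool[label_cursor]
        label_b = cfg.serogroup_pool[label_cursor + 1]
        label_cursor += 2
        for m in range(cfg.decoy_size):
            specs.append(
                {
                    "genus": family_home[fid]
                    if m == 0
                    else genus_names[int(rng.integers(0, cfg.n_genera))],
                    "family": fid,
                    "serogroup": label_b if m == cfg.decoy_size - 1 else label_a,
                    "evidence": ("E", "F")[int(rng.integers(0, 2))],
                    "hgt": False,
                }
            )

    for u in range(cfg.n_unknown):
        fid = sorted(families)[u % cfg.n_families]
        specs.append(
            {
                "genus": family_home[fid],
                "family": fid,
                "serogroup": None,
                "evidence": "F",
                "hgt": False,
            }
        )

    # assign phage ids per genus, instantiate sequences
    counters = {g: 0 for g in genus_names}
    truth_records: Dict[str, dict] = {}
    seq_parts: Dict[str, dict] = {}
    order: List[str] = []
    for spec in specs:
        genus = spec["genus"]
        counters[genus] += 1
        phage_id = f"{genus}_ph{counters[genus]:02d}"
        rbp_id = f"{phage_id}_rbp1"
        anchor = mutate_aa(rng, anchors[genus], cfg.anchor_divergence)
        div = float(
            rng.uniform(cfg.rbd_divergence_range[0], cfg.rbd_divergence_range[1])
        )
        rbd = mutate_aa(rng, family_rbd[spec["family"]], div)
        seq_parts[rbp_id] = {
            "phage_id": phage_id,
            "rbp_index": 1,
            "genus": genus,
            "aa": anchor + rbd,
            "anchor_end": genera[genus]["anchor_len"],
            **spec,
            "rbd_divergence": div,
        }
        order.append(rbp_id)
        truth_records[rbp_id] = {
            "genus": genus,
            "family": spec["family"],
            "serogroup": spec["serogroup"],
            "anchor_end": genera[genus]["anchor_len"],
            "is_decoy": spec["family"].startswith("decoy"),
            "is_unknown": spec["serogroup"] is None,
            "duplicate_of": None,
        }

    # near-duplicates of known-serogroup, non-experimental records
    redundancy_pairs: List[Tuple[str, str]] = []
    candidates = [
        rid
        for rid in order
        if seq_parts[rid]["serogroup"] is not None
        and seq_parts[rid]["evidence"] != "A"
        and not truth_records[rid]["is_decoy"]
    ]
    for k in range(min(cfg.n_redundant, len(candidates))):
        orig_id = candidates[int(rng.integers(0, len(candidates)))]
        orig = seq_parts[orig_id]
        genus = orig["genus"]
        counters[genus] += 1
        phage_id = f"{genus}_ph{counters[genus]:02d}"
        dup_id = f"{phage_id}_rbp1"
        seq_parts[dup_id] = {
            **orig,
            "phage_id": phage_id,
            "aa": mutate_aa(rng, orig["aa"], cfg.duplicate_divergence),
            "evidence": "F",
        }
        order.append(dup_id)
        truth_records[dup_id] = {
            **truth_records[orig_id],
            "duplicate_of": orig_id,
        }
        redundancy_pairs.append((orig_id, dup_id))
        candidates = [c for c in candidates if c != orig_id]
        if not candidates:
            break

    # one branched phage: second record of a lytic genus joins the first
    if cfg.branched_phage:
        by_genus: Dict[str, List[str]] = {}
        for rid in order:
            g = seq_parts[rid]["genus"]
            if genera[g]["lifestyle"] == "lytic":
                by_genus.setdefault(g, []).append(rid)
        for g in sorted(by_genus):
            rids = by_genus[g]
            partner = next(
                (
                    rid
                    for rid in rids[1:]
                    if seq_parts[rid]["family"] != seq_parts[rids[0]]["family"]
                    and truth_records[rid]["duplicate_of"] is None
                ),
                None,
            )
            if partner is not None:
                host = seq_parts[rids[0]]
                old = partner
                new_id = f"{host['phage_id']}_rbp2"
                seq_parts[new_id] = {
                    **seq_parts.pop(old),
                    "phage_id": host["phage_id"],
                    "rbp_index": 2,
                }
                truth_records[new_id] = truth_records.pop(old)
                order[order.index(old)] = new_id
                break

    # nucleotide layer: back-translation + motif planting
    motif_boundary_seq = random_nt(rng, cfg.motif_boundary_len)
    motif_downstream_seq = random_nt(rng, cfg.motif_downstream_len)
    motif_boundary: Dict[str, Tuple[int, int]] = {}
    motif_downstream: Dict[str, Tuple[int, int]] = {}

    records: List = []
    for rid in order:
        part = seq_parts[rid]
        genus = part["genus"]
        lytic = genera[genus]["lifestyle"] == "lytic"
        aa = part["aa"]
        cds = list(back_translate(aa))
        if lytic:
            bend = 3 * part["anchor_end"]
            lo = bend - cfg.motif_boundary_len  # 0-based start
            # keep the planted window codon-aligned so wobble mutations
            # land on third codon positions of the CDS
            lo -= lo % 3
            planted = motif_boundary_seq
            if lo + len(planted) > bend:
                planted = planted[: bend - lo]
            planted = mutate_nt_wobble(rng, planted, cfg.motif_mut_rate)
            cds[lo : lo + len(planted)] = list(planted)
            _repair_stops(cds, lo // 3, (lo + len(planted) + 2) // 3)
            aa = translate_fixed("".join(cds))
            # 1-based CDS coordinates of the planted window
            motif_boundary[rid] = (lo + 1, lo + len(planted))
        flank = list(random_nt(rng, cfg.downstream_flank_len))
        if lytic:
            off = cfg.motif_downstream_offset
            flank[off : off + cfg.motif_downstream_len] = list(
                mutate_nt(rng, motif_downstream_seq, cfg.motif_mut_rate)
            )
            motif_downstream[rid] = (off + 1, off + cfg.motif_downstream_len)
        nt = "".join(cds) + "TAA" + "".join(flank)

        prophage = genera[genus]["lifestyle"] == "temperate"
        serogroup = part["serogroup"]
        records.append(
            RBPRecord(
                rbp_id=rid,
                phage_id=part["phage_id"],
                genus=genus,
                aa_sequence=aa,
                lifestyle=genera[genus]["lifestyle"],
                source="prophage" if prophage else "phage",
                rbp_index=part["rbp_index"],
                nt_sequence=nt,
                evidence_group=part["evidence"],
                host_strain=(
                    f"EC-{serogroup.replace('/', '-')}-{rid[-7:]}"
                    if serogroup
                    else None
                ),
                host_serogroup=serogroup,
                serogroup_evidence=(
                    "rbp_level"
                    if part["evidence"] == "A"
                    else ("unknown" if serogroup is None else "host_strain")
                ),
                prophage_score=(
                    round(float(rng.uniform(0.82, 0.99)), 3) if prophage else None
                ),
                curated_anchor_end=None,
            )
        )
        truth_records[rid]["rbd_divergence"] = part["rbd_divergence"]

    truth = SyntheticTruth(
        seed=seed,
        genera=genera,
        families=families,
        per_record=truth_records,
        redundancy_pairs=redundancy_pairs,
        motif_boundary=motif_boundary,
        motif_downstream=motif_downstream,
        # JSON-normalized (tuples -> lists) so serialization round-trips
        config=json.loads(json.dumps(asdict(cfg))),
    )
    return records, truth


#: Structure of the published initial selection: six serogroup-linked RBP
#: subtypes totalling 17 RBPs spread over seven phage genera.
INITIAL_SELECTION_COMPOSITION = {
    "O157": ("Kuttervirus", "Lederbergvirus", "Kagunavirus", "Gamaleyavirus"),
    "O103": ("Uetakevirus", "Kuttervirus", "Nouzillyvirus"),
    "O104": ("Kayfunavirus", "Kagunavirus", "Lederbergvirus"),
    "O18": ("Kayfunavirus", "Gamaleyavirus", "Uetakevirus"),
    "O78": ("Kuttervirus", "Nouzillyvirus"),
    "4s/O22": ("Gamaleyavirus", "Kagunavirus"),
}


def generate_initial_selection(seed: int = 0):
    """Synthetic stand-in mirroring the published initial selection.

    Seventeen records in six serogroup-linked RBD families spread over
    seven phage genera (the structure of the curated reference data set;
    all sequences here are synthetic).  Each family's first member
    carries experimental RBP-level evidence (group A); the rest are
    horizontal-transfer finds (group C).  Returns (records, curated
    boundary table, family map serogroup -> member rbp_ids).
    """
    from .records import RBPRecord

    rng = np.random.default_rng(seed)
    genera = sorted({g for gs in INITIAL_SELECTION_COMPOSITION.values()
                     for g in gs})
    anchors = {
        g: random_aa(rng, int(rng.integers(150, 211))) for g in genera
    }
    records = []
    boundaries: Dict[str, int] = {}
    family_map: Dict[str, List[str]] = {}
    for serogroup, members in sorted(INITIAL_SELECTION_COMPOSITION.items()):
        rbd = random_aa(rng, int(rng.integers(350, 601)))
        for k, genus in enumerate(members):
            rid = f"{genus}_{serogroup.replace('/', '-')}_{k + 1}"
            aa = (
                mutate_aa(rng, anchors[genus], 0.05)
                + mutate_aa(rng, rbd, float(rng.uniform(0.05, 0.35)))
            )
            records.append(
                RBPRecord(
                    rbp_id=rid,
                    phage_id=rid,
                    genus=genus,
                    aa_sequence=aa,
                    lifestyle="lytic",
                    evidence_group="A" if k == 0 else "C",
                    host_serogroup=serogroup,
                    serogroup_evidence="rbp_level" if k == 0 else "host_strain",
                    host_strain=f"EC-{serogroup.replace('/', '-')}-{k}",
                )
            )
            boundaries[rid] = len(anchors[genus])
            family_map.setdefault(serogroup, []).append(rid)
    return records, boundaries, family_map


# ---------------------------------------------------------------------------
# recovery metrics
# ---------------------------------------------------------------------------

def _interval_jaccard(a: Tuple[int, int], b: Tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
    union = (a[1] - a[0] + 1) + (b[1] - b[0] + 1) - inter
    return inter / union if union else 0.0


def motif_localization_jaccard(
    hits, truth_spans: Dict[str, Tuple[int, int]]
) -> float:
    """Mean per-member interval Jaccard of the best hit vs planted spans.

    The best hit is the one sharing the most members with the truth;
    returns 0.0 when no hit overlaps any planted member.
    """
    best = 0.0
    for hit in hits:
        shared = [m for m in hit.member_ids if m in truth_spans]
        if not shared:
            continue
        score = float(
            np.mean(
                [
                    _interval_jaccard(hit.member_spans[m], tuple(truth_spans[m]))
                    for m in shared
                ]
            )
        )
        best = max(best, score)
    return best


def recovery_report(result, truth: SyntheticTruth) -> Dict[str, float]:
    """Compare pipeline outputs against planted ground truth.

    ``result`` is a ``rbpmosaic.pipeline.PipelineResult``.  Reports the
    subtype-partition adjusted Rand index, serogroup-assignment accuracy
    over assigned clusters, decoy false-assignment count, mean absolute
    anchor-boundary error, motif localization Jaccard per region, and the
    fraction of planted near-duplicate pairs correctly collapsed.
    """
    from sklearn.metrics import adjusted_rand_score

    known = set(truth.per_record)
    clustered = sorted(
        m for c in result.clusters for m in c.member_rbp_ids if m in known
    )
    missing = [
        m for c in result.clusters for m in c.member_rbp_ids if m not in known
    ]
    if missing:
        raise GeneratorError(f"pipeline records unknown to the truth: {missing}")
    label_true = [truth.per_record[m]["family"] for m in clustered]
    member_to_cluster = {
        m: c.subtype_id for c in result.clusters for m in c.member_rbp_ids
    }
    label_pred = [member_to_cluster[m] for m in clustered]
    ari = float(adjusted_rand_score(label_true, label_pred))

    n_assigned = 0
    n_correct = 0
    decoy_false = 0
    for ac in result.assigned:
        if ac.assigned_serogroup is None:
            continue
        members = sorted(ac.cluster.member_rbp_ids)
        fams = [truth.per_record[m]["family"] for m in members]
        modal_family = max(set(fams), key=fams.count)
        if modal_family.startswith("decoy"):
            decoy_false += 1
            continue
        n_assigned += 1
        if ac.assigned_serogroup == truth.families.get(modal_family):
            n_correct += 1

    errors = [
        abs(d.anchor_end - truth.per_record[rid]["anchor_end"])
        for rid, d in result.delineations.items()
        if rid in truth.per_record
    ]

    boundary_hits = [h for h in result.motifs if h.region == "boundary_flank"]
    downstream_hits = [
        h for h in result.motifs if h.region == "downstream_noncoding"
    ]

    surviving = {r.rbp_id for r in result.records_deduped}
    pairs_ok = sum(
        1
        for orig, dup in truth.redundancy_pairs
        if not ({orig, dup} <= surviving)
    )

    return {
        "subtype_ari": ari,
        "serogroup_accuracy": (n_correct / n_assigned) if n_assigned else 0.0,
        "decoy_false_assignments": float(decoy_false),
        "mean_delineation_error": float(np.mean(errors)) if errors else float("nan"),
        "motif_boundary_jaccard": motif_localization_jaccard(
            boundary_hits, truth.motif_boundary
        ),
        "motif_downstream_jaccard": motif_localization_jaccard(
            downstream_hits, truth.motif_downstream
        ),
        "redundancy_removal_correct": (
            pairs_ok / len(truth.redundancy_pairs)
            if truth.redundancy_pairs
            else 1.0
        ),
    }
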
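"""Domain records for phage receptor-binding proteins (RBPs).

An RBP is modeled as a single record carrying its amino-acid sequence,
optionally the nucleotide sequence of the coding region plus a downstream
noncoding flank, and the curated metadata that drives dataset assembly:
phage genus, evidence group (A-F, strongest first), host serogroup and the
level at which that serogroup was established, and prophage-prediction
scores for records mined from bacterial genomes.

Serogroup labels are opaque strings from a single namespace that mixes
O-antigens ("O157"), compound labels ("4s/O22") and K-antigens ("K1", used
as an outgroup specificity); equality is exact, case-sensitive string match.
Amino-acid coordinates are 1-based inclusive throughout the package, so an
anchor ending at position 150 spans residues 1..150.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NT_ALPHABET = frozenset("ACGT")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_K_ANTIGEN_RE = re.compile(r"^K\d+$")


class RecordError(ValueError):
    """Raised when an RBP record violates a structural invariant."""


class Lifestyle(str, enum.Enum):
    lytic = "lytic"
    temperate = "temperate"
    unknown = "unknown"


class Source(str, enum.Enum):
    phage = "phage"
    prophage = "prophage"


class EvidenceGroup(str, enum.Enum):
    """Provenance of a record, strongest evidence first.

    A: serogroup specificity confirmed experimentally at the RBP level.
    B: confirmed at the phage level (single-RBP phages only).
    C: identified through horizontal transfer from group A/B RBDs.
    D: single-RBP prophages integrated in strains of known serogroup.
    E: all RBPs of the genera enriched by groups A-D.
    F: additional horizontal-transfer hits from group A-E RBDs.
    """

    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"
    F = "F"


class SerogroupEvidence(str, enum.Enum):
    rbp_level = "rbp_level"
    phage_level = "phage_level"
    host_strain = "host_strain"
    unknown = "unknown"


@dataclass
class RBPRecord:
    """One receptor-binding protein with its curation metadata.

    ``nt_sequence``, when present, covers the CDS (optionally including the
    stop codon) followed by a noncoding downstream flank; the CDS portion
    must translate to ``aa_sequence`` under the standard genetic code.
    ``split_rbp`` marks the adapter-plus-separate-RBD architecture in which
    the whole stored protein is receptor-binding domain (anchor length 0).
    """

    rbp_id: str
    phage_id: str
    genus: str
    aa_sequence: str
    lifestyle: Lifestyle = Lifestyle.unknown
    source: Source = Source.phage
    rbp_index: int = 1
    nt_sequence: Optional[str] = None
    evidence_group: EvidenceGroup = EvidenceGroup.F
    host_strain: Optional[str] = None
    host_serogroup: Optional[str] = None
    serogroup_evidence: SerogroupEvidence = SerogroupEvidence.unknown
    prophage_score: Optional[float] = None
    curated_anchor_end: Optional[int] = None
    split_rbp: bool = False

    def __post_init__(self) -> None:
        self.lifestyle = Lifestyle(self.lifestyle)
        self.source = Source(self.source)
        self.evidence_group = EvidenceGroup(self.evidence_group)
        self.serogroup_evidence = SerogroupEvidence(self.serogroup_evidence)
        self.validate()

    # -- invariants ----------------------------------------------------

    def validate(self) -> None:
        if not self.rbp_id:
            raise RecordError("rbp_id must be nonempty")
        if not self.aa_sequence:
            raise RecordError(f"{self.rbp_id}: aa_sequence is empty")
        bad = set(self.aa_sequence) - AA_ALPHABET
        if bad:
            raise RecordError(
                f"{self.rbp_id}: illegal amino-acid characters {sorted(bad)}"
            )
        if self.rbp_index < 1:
            raise RecordError(f"{self.rbp_id}: rbp_index must be >= 1")
        if self.evidence_group in (EvidenceGroup.A, EvidenceGroup.B) and (
            self.host_serogroup is None
        ):
            raise RecordError(
                f"{self.rbp_id}: evidence group {self.evidence_group.value} "
                "requires a host serogroup"
            )
        if self.prophage_score is not None:
            if self.source is not Source.prophage:
                raise RecordError(
                    f"{self.rbp_id}: prophage_score set on a non-prophage record"
                )
            if not 0.0 <= self.prophage_score <= 1.0:
                raise RecordError(
                    f"{self.rbp_id}: prophage_score {self.prophage_score} "
                    "outside [0, 1]"
                )
        if self.curated_anchor_end is not None and self.curated_anchor_end < 0:
            raise RecordError(f"{self.rbp_id}: negative curated_anchor_end")
        if self.nt_sequence is not None:
            self._validate_nt()

    def _validate_nt(self) -> None:
        nt = self.nt_sequence
        assert nt is not None
        bad = set(nt) - NT_ALPHABET
        if bad:
            raise RecordError(
                f"{self.rbp_id}: illegal nucleotide characters {sorted(bad)}"
            )
        cds_len = 3 * len(self.aa_sequence)
        if len(nt) < cds_len:
            raise RecordError(
                f"{self.rbp_id}: nt_sequence shorter than the CDS implied by "
                "aa_sequence"
            )
        translated = str(Seq(nt[:cds_len]).translate())
        if translated != self.aa_sequence:
            raise RecordError(
                f"{self.rbp_id}: CDS does not translate to aa_sequence"
            )

    # -- derived views ---------------------------------------------------

    @property
    def length(self) -> int:
        return len(self.aa_sequence)

    @property
    def cds(self) -> Optional[str]:
        """CDS nucleotides (stop codon excluded), or None without nt data."""
        if self.nt_sequence is None:
            return None
        return self.nt_sequence[: 3 * len(self.aa_sequence)]

    @property
    def downstream_flank(self) -> Optional[str]:
        """Noncoding nucleotides after the CDS (and stop codon, if present)."""
        if self.nt_sequence is None:
            return None
        pos = 3 * len(self.aa_sequence)
        if self.nt_sequence[pos : pos + 3] in STOP_CODONS:
            pos += 3
        return self.nt_sequence[pos:]

    @property
    def is_k_outgroup(self) -> bool:
        """True when the host serogroup is a K (capsule) antigen label."""
        return self.host_serogroup is not None and bool(
            _K_ANTIGEN_RE.match(self.host_serogroup)
        )
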
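"""Pipeline configuration.

All thresholds of the analysis are collected in one flat-ish dataclass so a
run is fully described by (dataset, config, seed).  Defaults follow the
published procedure this pipeline reproduces: horizontal-transfer hits need
>= 30 % amino-acid identity and >= 60 % coverage over the receptor-binding
domain; near-duplicates at >= 80 % full-length identity are collapsed;
serogroup consensus requires >= 90 % agreement with at least two known
votes; genera need at least two serogroup-specific RBPs to survive the
final filter; the tentative N-terminal anchor cutoff is 150 aa; prophages
count as active above a prediction score of 0.8 and as ambiguous between
0.5 and 0.8; and phages hosted on common rough laboratory strains are
discarded because rough strains display no O-antigen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import FrozenSet, Mapping, Union

#: Common rough E. coli laboratory strains (no O-antigen displayed).
DEFAULT_ROUGH_STRAINS = frozenset(
    {"58", "AG1", "B", "BL21", "C", "C600", "DH1", "DH5α", "MG1655", "W3110", "W945"}
)


class ConfigError(ValueError):
    """Raised for inconsistent configuration values."""


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring for pairwise alignment.

    Protein scoring mirrors BLASTp defaults (BLOSUM62, gap open 11,
    gap extend 1; a gap of length k costs open + k*extend).  Nucleotide
    scoring (2/-3 with heavy affine gap costs) is used only for the DNA
    flank alignments of the motif scan; the gap-averse penalties keep
    fixed-origin flank windows positionally aligned instead of scattering
    random background sequence with spurious gaps.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    nt_match: float = 2.0
    nt_mismatch: float = -3.0
    nt_gap_open: float = 20.0
    nt_gap_extend: float = 8.0


@dataclass(frozen=True)
class MotifParams:
    """Windows and thresholds of the conserved-DNA-motif scan.

    ``flank_halfwidth`` nt are taken on each side of the anchor/RBD
    boundary (position 3*anchor_end of the CDS) and ``downstream_len`` nt
    after the stop codon.  Conserved windows must span >= ``min_len``
    alignment columns whose ``window``-column smoothed mean pairwise
    identity stays >= ``min_mean_identity`` %, trimmed to columns
    individually >= ``col_floor`` %, with >= ``min_members`` non-gap
    members.  Defaults bracket the reported motif lengths (20/44/95 nt)
    and identities (63/69/81 %).
    """

    flank_halfwidth: int = 150
    downstream_len: int = 120
    min_len: int = 15
    min_mean_identity: float = 55.0
    window: int = 10
    col_floor: float = 40.0
    min_members: int = 4
    n_permutations: int = 999


@dataclass(frozen=True)
class PipelineConfig:
    # horizontal-transfer hit criterion (percent)
    hit_min_identity: float = 30.0
    hit_min_coverage: float = 60.0
    min_rbd_len: int = 10
    # redundancy removal
    redundancy_identity: float = 80.0
    # serogroup consensus
    consensus_fraction: float = 0.90
    consensus_min_known: int = 2
    # genus-level filter on the final data set
    genus_min_specific_rbps: int = 2
    # anchor/RBD delineation
    default_anchor_cutoff: int = 150
    smoothing_window: int = 20
    t_high: float = 0.7
    t_low: float = 0.4
    # prophage metadata filter
    prophage_active_score: float = 0.8
    prophage_ambiguous_floor: float = 0.5
    allow_ambiguous: bool = True
    rough_strain_blocklist: FrozenSet[str] = DEFAULT_ROUGH_STRAINS
    # nested parameter groups
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    motifs: MotifParams = field(default_factory=MotifParams)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hit_min_identity", "hit_min_coverage", "redundancy_identity"):
            v = getattr(self, name)
            if not 0.0 < v <= 100.0:
                raise ConfigError(f"{name} must lie in (0, 100], got {v}")
        if not 0.0 < self.consensus_fraction <= 1.0:
            raise ConfigError("consensus_fraction must lie in (0, 1]")
        if self.consensus_min_known < 1:
            raise ConfigError("consensus_min_known must be positive")
        if self.default_anchor_cutoff <= 0 or self.min_rbd_len <= 0:
            raise ConfigError("cutoffs must be positive")
        if not 0.0 <= self.prophage_ambiguous_floor <= self.prophage_active_score <= 1.0:
            raise ConfigError(
                "need 0 <= prophage_ambiguous_floor <= prophage_active_score <= 1"
            )
        if not 0.0 <= self.t_low <= self.t_high <= 1.0:
            raise ConfigError("need 0 <= t_low <= t_high <= 1")


_BOOL_STRINGS = {"true": True, "false": False, "1": True, "0": False,
                 "yes": True, "no": False}

_NESTED = {
    f.name: ("alignment", type(getattr(AlignmentParams(), f.name)))
    for f in fields(AlignmentParams)
}
_NESTED.update(
    {
        f.name: ("motifs", type(getattr(MotifParams(), f.name)))
        for f in fields(MotifParams)
    }
)


def _coerce(raw: str, typ: type):
    if typ is bool:
        try:
            return _BOOL_STRINGS[raw.strip().lower()]
        except KeyError:
            raise ConfigError(f"cannot parse boolean from {raw!r}") from None
    if typ is frozenset or typ is FrozenSet[str]:
        return frozenset(s.strip() for s in raw.split(",") if s.strip())
    return typ(raw)


def config_from_mapping(mapping: Mapping[str, str]) -> PipelineConfig:
    """Build a PipelineConfig from flat ``key = value`` string pairs.

    Keys of the nested alignment/motif groups are addressed by their bare
    field names (they do not collide with top-level fields).
    """
    top = {f.name: f for f in fields(PipelineConfig)}
    base = PipelineConfig()
    updates: dict = {}
    nested_updates: dict = {"alignment": {}, "motifs": {}}
    for key, raw in mapping.items():
        key = key.strip()
        if key in ("alignment", "motifs"):
            raise ConfigError(f"{key} must be set through its member keys")
        if key in top:
            f = top[key]
            typ = type(getattr(base, key))
            updates[key] = _coerce(raw, typ)
        elif key in _NESTED:
            group, typ = _NESTED[key]
            nested_updates[group][key] = _coerce(raw, typ)
        else:
            raise ConfigError(f"unknown configuration key {key!r}")
    if nested_updates["alignment"]:
        updates["alignment"] = replace(base.alignment, **nested_updates["alignment"])
    if nested_updates["motifs"]:
        updates["motifs"] = replace(base.motifs, **nested_updates["motifs"])
    return replace(base, **updates)


def config_from_file(path: Union[str, Path]) -> PipelineConfig:
    """Parse a flat ``key = value`` configuration file ('#' comments)."""
    mapping: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, raw = line.split("=", 1)
        mapping[key.strip()] = raw.strip()
    return config_from_mapping(mapping)
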
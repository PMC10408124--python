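"""Metadata pre-filters applied before any sequence computation.

Prophage-derived records are screened on their prophage-prediction score
(active above the threshold, optionally ambiguous within a band below it),
and phages hosted on common rough laboratory strains are discarded because
rough strains display no O-antigen and therefore carry no serogroup signal.
Both filters are idempotent and mutually order-independent; every dropped
record is reported with a reason code.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Sequence, Tuple

from .config import PipelineConfig
from .records import RBPRecord, Source

logger = logging.getLogger(__name__)

# flag / reason codes
ACTIVE = "active"
AMBIGUOUS = "ambiguous"
DROP_LOW_SCORE = "dropped:score_below_floor"
DROP_AMBIGUOUS_OFF = "dropped:ambiguous_not_allowed"
DROP_MISSING_SCORE = "dropped:missing_score"
DROP_ROUGH_HOST = "dropped:rough_host_strain"


def filter_prophages(
    records: Sequence[RBPRecord], cfg: PipelineConfig
) -> Tuple[List[RBPRecord], Dict[str, str]]:
    """Keep active (score > threshold) prophages; flag or drop the rest.

    Prophages scoring within [ambiguous_floor, active threshold] are kept
    with an ``ambiguous`` flag only when ``cfg.allow_ambiguous`` is on.
    Non-prophage records pass untouched (no flag).  Returns the kept
    records (input order) and a flag map covering every prophage record.
    """
    kept: List[RBPRecord] = []
    flags: Dict[str, str] = {}
    for rec in records:
        if rec.source is not Source.prophage:
            kept.append(rec)
            continue
        score = rec.prophage_score
        if score is None:
            flags[rec.rbp_id] = DROP_MISSING_SCORE
            logger.warning("prophage %s has no score; dropped", rec.rbp_id)
        elif score > cfg.prophage_active_score:
            flags[rec.rbp_id] = ACTIVE
            kept.append(rec)
        elif score >= cfg.prophage_ambiguous_floor:
            if cfg.allow_ambiguous:
                flags[rec.rbp_id] = AMBIGUOUS
                kept.append(rec)
            else:
                flags[rec.rbp_id] = DROP_AMBIGUOUS_OFF
        else:
            flags[rec.rbp_id] = DROP_LOW_SCORE
    return kept, flags


def filter_rough_hosts(
    records: Sequence[RBPRecord], cfg: PipelineConfig
) -> Tuple[List[RBPRecord], Dict[str, str]]:
    """Drop records whose host strain is a blocklisted rough strain.

    Matching is case-insensitive and exact; empty/unknown strains pass.
    """
    blocked = {s.casefold() for s in cfg.rough_strain_blocklist}
    kept: List[RBPRecord] = []
    dropped: Dict[str, str] = {}
    for rec in records:
        strain = (rec.host_strain or "").strip()
        if strain and strain.casefold() in blocked:
            dropped[rec.rbp_id] = DROP_ROUGH_HOST
        else:
            kept.append(rec)
    return kept, dropped
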
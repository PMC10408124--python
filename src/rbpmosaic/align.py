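"""Pairwise alignment, percent identity/coverage, and the HGT hit criterion.

Local alignment (Smith-Waterman, BLOSUM62, affine gaps) stands in for the
BLASTp searches of the original procedure; global alignment backs the
percent-identity matrices.  Identity is counted over all aligned columns
including gap columns (a conservative, exactly testable convention), and a
gap of length k costs ``gap_open + k * gap_extend``.

The horizontal-gene-transfer hit criterion operates on the delineated
receptor-binding domains (RBDs): two RBDs are linked when their local
alignment reaches >= 30 % identity and covers >= 60 % of either RBD.  The
coverage test is symmetrized with OR because query/subject roles are
arbitrary in an all-vs-all comparison, mirroring a search run with each
RBD as query in turn.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .config import AlignmentParams, PipelineConfig
from .delineation import DomainDelineation, rbd_seq
from .records import AA_ALPHABET, NT_ALPHABET, RBPRecord

logger = logging.getLogger(__name__)


class AlignmentError(ValueError):
    """Raised for sequences that cannot be aligned."""


@dataclass(frozen=True)
class Alignment:
    """One pairwise alignment summarized by identity bookkeeping.

    Spans are 1-based inclusive; ``n_columns`` counts every alignment
    column including gap columns, so ``identity_pct`` uses the gap-
    inclusive denominator.
    """

    query_id: str
    subject_id: str
    query_span: Tuple[int, int]
    subject_span: Tuple[int, int]
    score: float
    n_columns: int
    n_identical: int
    mode: str  # "local" | "global"

    @property
    def identity_pct(self) -> float:
        if self.n_columns == 0:  # empty local alignment (score 0)
            return 0.0
        return 100.0 * self.n_identical / self.n_columns

    def __post_init__(self) -> None:
        if self.n_identical > self.n_columns:
            raise AlignmentError("n_identical exceeds n_columns")


@dataclass(frozen=True)
class PairwiseHit:
    """RBD-vs-RBD comparison; the edge primitive of subtype clustering.

    ``coverage_pct`` is the larger of the two directional coverages (the
    OR-symmetrized criterion), so ``passes`` holds exactly when
    identity >= hit_min_identity and coverage_pct >= hit_min_coverage.
    """

    query_id: str
    subject_id: str
    identity_pct: float
    coverage_pct: float
    passes: bool


def _check_alphabet(seq: str, alphabet: frozenset, label: str) -> None:
    if not seq:
        raise AlignmentError(f"{label}: empty sequence")
    bad = set(seq) - alphabet
    if bad:
        raise AlignmentError(f"{label}: illegal characters {sorted(bad)}")


def make_aligner(
    params: AlignmentParams, mode: str, molecule: str = "protein"
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    if molecule == "protein":
        aligner.substitution_matrix = substitution_matrices.load(params.matrix)
        open_, extend = params.gap_open, params.gap_extend
    else:
        aligner.match_score = params.nt_match
        aligner.mismatch_score = params.nt_mismatch
        open_, extend = params.nt_gap_open, params.nt_gap_extend
    # gap of length k costs open + k*extend
    aligner.open_gap_score = -(open_ + extend)
    aligner.extend_gap_score = -extend
    return aligner


def _summarize(
    aln, query_id: str, subject_id: str, mode: str
) -> Alignment:
    counts = aln.counts()
    n_columns = counts.gaps + counts.identities + counts.mismatches
    q_blocks, s_blocks = aln.aligned
    if len(q_blocks) == 0:
        return _empty_alignment(query_id, subject_id, mode)
    query_span = (int(q_blocks[0][0]) + 1, int(q_blocks[-1][1]))
    subject_span = (int(s_blocks[0][0]) + 1, int(s_blocks[-1][1]))
    return Alignment(
        query_id=query_id,
        subject_id=subject_id,
        query_span=query_span,
        subject_span=subject_span,
        score=float(aln.score),
        n_columns=int(n_columns),
        n_identical=int(counts.identities),
        mode=mode,
    )


def _empty_alignment(query_id: str, subject_id: str, mode: str) -> Alignment:
    """Score-0 local alignment of sequences with no positive-scoring pair."""
    return Alignment(
        query_id=query_id,
        subject_id=subject_id,
        query_span=(0, 0),
        subject_span=(0, 0),
        score=0.0,
        n_columns=0,
        n_identical=0,
        mode=mode,
    )


def _align(
    a: str,
    b: str,
    params: AlignmentParams,
    mode: str,
    molecule: str,
    query_id: str,
    subject_id: str,
) -> Alignment:
    alphabet = AA_ALPHABET if molecule == "protein" else NT_ALPHABET
    _check_alphabet(a, alphabet, query_id)
    _check_alphabet(b, alphabet, subject_id)
    aligner = make_aligner(params, mode, molecule)
    try:
        aln = next(iter(aligner.align(a, b)))  # deterministic first optimum
    except StopIteration:
        return _empty_alignment(query_id, subject_id, mode)
    return _summarize(aln, query_id, subject_id, mode)


def align_local(
    a: str,
    b: str,
    cfg: PipelineConfig,
    query_id: str = "query",
    subject_id: str = "subject",
    molecule: str = "protein",
) -> Alignment:
    """Optimal local alignment under the configured scoring."""
    return _align(a, b, cfg.alignment, "local", molecule, query_id, subject_id)


def align_global(
    a: str,
    b: str,
    cfg: PipelineConfig,
    query_id: str = "query",
    subject_id: str = "subject",
    molecule: str = "protein",
) -> Alignment:
    """Optimal global alignment (end gaps penalized)."""
    return _align(a, b, cfg.alignment, "global", molecule, query_id, subject_id)


def global_identity_pct(a: str, b: str, cfg: PipelineConfig,
                        molecule: str = "protein") -> float:
    """Percent identity of the global alignment of two sequences."""
    return align_global(a, b, cfg, molecule=molecule).identity_pct


def rbd_hit(
    query: RBPRecord,
    subject: RBPRecord,
    delineations: Dict[str, DomainDelineation],
    cfg: PipelineConfig,
) -> Optional[PairwiseHit]:
    """RBD-vs-RBD local alignment scored against the HGT hit criterion.

    Returns None (with a warning) when either RBD is shorter than
    ``cfg.min_rbd_len``.
    """
    rbd_q = rbd_seq(query, delineations[query.rbp_id])
    rbd_s = rbd_seq(subject, delineations[subject.rbp_id])
    if len(rbd_q) < cfg.min_rbd_len or len(rbd_s) < cfg.min_rbd_len:
        logger.warning(
            "RBD shorter than %d aa for %s/%s; no hit computed",
            cfg.min_rbd_len,
            query.rbp_id,
            subject.rbp_id,
        )
        return None
    aln = align_local(
        rbd_q, rbd_s, cfg, query_id=query.rbp_id, subject_id=subject.rbp_id
    )
    cov_q = 100.0 * (aln.query_span[1] - aln.query_span[0] + 1) / len(rbd_q)
    cov_s = 100.0 * (aln.subject_span[1] - aln.subject_span[0] + 1) / len(rbd_s)
    coverage = max(cov_q, cov_s)
    passes = (
        aln.identity_pct >= cfg.hit_min_identity
        and coverage >= cfg.hit_min_coverage
    )
    return PairwiseHit(
        query_id=query.rbp_id,
        subject_id=subject.rbp_id,
        identity_pct=aln.identity_pct,
        coverage_pct=coverage,
        passes=passes,
    )


def all_vs_all_hits(
    records: Sequence[RBPRecord],
    delineations: Dict[str, DomainDelineation],
    cfg: PipelineConfig,
) -> List[PairwiseHit]:
    """All unordered RBD pairs, in (i, j) order of the input sequence."""
    hits: List[PairwiseHit] = []
    for query, subject in itertools.combinations(records, 2):
        hit = rbd_hit(query, subject, delineations, cfg)
        if hit is not None:
            hits.append(hit)
    return hits


def region_sequence(
    record: RBPRecord, region: str, delineation: Optional[DomainDelineation]
) -> str:
    if region == "full":
        return record.aa_sequence
    if delineation is None:
        raise AlignmentError(
            f"{record.rbp_id}: region {region!r} needs a delineation"
        )
    if region == "anchor":
        return record.aa_sequence[: delineation.anchor_end]
    if region == "rbd":
        return rbd_seq(record, delineation)
    raise AlignmentError(f"unknown region {region!r}")


def identity_matrix(
    records: Sequence[RBPRecord],
    region: str = "full",
    delineations: Optional[Dict[str, DomainDelineation]] = None,
    cfg: Optional[PipelineConfig] = None,
) -> Tuple[List[str], np.ndarray]:
    """Symmetric percent-identity matrix from pairwise global alignments.

    ``region`` selects anchor, rbd, or full protein; the diagonal is
    exactly 100.
    """
    cfg = cfg or PipelineConfig()
    if len(records) < 2:
        raise AlignmentError("identity_matrix needs >= 2 records")
    seqs = [
        region_sequence(
            r, region, None if delineations is None else delineations.get(r.rbp_id)
        )
        for r in records
    ]
    ids = [r.rbp_id for r in records]
    n = len(records)
    mat = np.full((n, n), 100.0)
    for i, j in itertools.combinations(range(n), 2):
        pct = align_global(
            seqs[i], seqs[j], cfg, query_id=ids[i], subject_id=ids[j]
        ).identity_pct
        mat[i, j] = mat[j, i] = pct
    return ids, mat
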
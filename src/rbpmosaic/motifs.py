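"""Conserved DNA motifs flanking the receptor-binding domain.

Lytic phages exchanging RBDs carry short conserved DNA stretches around
the swap points — candidate recombination hotspots.  Two flank regions
are scanned: a window centered on the anchor/RBD boundary of the CDS
(``boundary_flank``) and the noncoding region downstream of the stop
codon (``downstream_noncoding``).  Per region the windows are aligned
with a center-star multiple alignment, a sliding-window conservation
profile delimits maximal conserved runs, and each reported motif carries
mean +/- sd pairwise identity, a consensus with IUPAC ambiguity codes, a
position-frequency matrix, and a permutation p-value against same-length
windows drawn from the surrounding flank alignment.

Pairwise identity between two aligned rows ignores columns where both
rows are gaps; a gap against a base counts as a mismatch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .align import make_aligner
from .config import PipelineConfig
from .delineation import DomainDelineation
from .records import RBPRecord

logger = logging.getLogger(__name__)

GAP = "-"

BOUNDARY = "boundary_flank"
DOWNSTREAM = "downstream_noncoding"

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


class MotifError(ValueError):
    """Raised for invalid motif-scan inputs."""


@dataclass(frozen=True)
class FlankWindow:
    """One nucleotide window, 1-based coordinates relative to its origin.

    For ``boundary_flank`` the origin is the CDS start (positions are CDS
    coordinates); for ``downstream_noncoding`` the origin is the first
    base after the stop codon.
    """

    rbp_id: str
    region: str
    seq: str
    start: int
    end: int
    truncated: bool = False


@dataclass(frozen=True)
class FlankSet:
    region: str
    windows: Tuple[FlankWindow, ...]


@dataclass(frozen=True)
class MotifHit:
    """A maximal conserved window of the flank alignment."""

    region: str
    col_start: int  # 1-based alignment columns, inclusive
    col_end: int
    member_ids: Tuple[str, ...]
    member_spans: Dict[str, Tuple[int, int]]  # per-member nt coordinates
    mean_identity_pct: float
    sd_identity_pct: float
    consensus: str
    pfm: np.ndarray  # 4 x span, rows A,C,G,T
    background_identity_pct: float
    permutation_p: Optional[float] = None

    @property
    def span_len(self) -> int:
        return self.col_end - self.col_start + 1


# ---------------------------------------------------------------------------
# flank extraction
# ---------------------------------------------------------------------------

def extract_flanks(
    records: Sequence[RBPRecord],
    delineations: Dict[str, DomainDelineation],
    cfg: PipelineConfig,
) -> Dict[str, FlankSet]:
    """Cut the boundary and downstream nucleotide windows per record.

    Records without nucleotide data are skipped with a warning; windows
    truncated at a sequence edge are kept and flagged.
    """
    p = cfg.motifs
    boundary: List[FlankWindow] = []
    downstream: List[FlankWindow] = []
    for rec in records:
        if rec.nt_sequence is None:
            logger.warning("%s: no nt_sequence; skipped in motif scan", rec.rbp_id)
            continue
        delin = delineations[rec.rbp_id]
        cds = rec.cds
        assert cds is not None
        center = 3 * delin.anchor_end
        lo = max(1, center - p.flank_halfwidth + 1)
        hi = min(len(cds), center + p.flank_halfwidth)
        if hi - lo + 1 >= 1 and delin.anchor_end > 0:
            boundary.append(
                FlankWindow(
                    rec.rbp_id,
                    BOUNDARY,
                    cds[lo - 1 : hi],
                    lo,
                    hi,
                    truncated=(lo > center - p.flank_halfwidth + 1)
                    or (hi < center + p.flank_halfwidth),
                )
            )
        flank = rec.downstream_flank
        if flank:
            end = min(len(flank), p.downstream_len)
            downstream.append(
                FlankWindow(
                    rec.rbp_id,
                    DOWNSTREAM,
                    flank[:end],
                    1,
                    end,
                    truncated=end < p.downstream_len,
                )
            )
    return {
        BOUNDARY: FlankSet(BOUNDARY, tuple(boundary)),
        DOWNSTREAM: FlankSet(DOWNSTREAM, tuple(downstream)),
    }


# ---------------------------------------------------------------------------
# center-star multiple alignment
# ---------------------------------------------------------------------------

def star_msa(
    windows: Sequence[FlankWindow], cfg: PipelineConfig
) -> Tuple[List[str], List[str]]:
    """Center-star multiple alignment of nucleotide windows.

    The center is the window maximizing the summed pairwise global-
    alignment score (ties -> lexicographically smallest id); the others
    are merged against it under "once a gap, always a gap".  Returns
    (ids, aligned rows) with ids in input order.
    """
    if len(windows) < 2:
        raise MotifError("star_msa needs >= 2 windows")
    aligner = make_aligner(cfg.alignment, "global", "nucleotide")
    n = len(windows)
    scores = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = aligner.score(windows[i].seq, windows[j].seq)
            scores[i, j] = scores[j, i] = s
    totals = scores.sum(axis=1)
    order = sorted(range(n), key=lambda k: (-totals[k], windows[k].rbp_id))
    center = order[0]
    center_seq = windows[center].seq
    length = len(center_seq)

    # pairwise alignments against the center, recorded as per-position
    # insertion counts (gaps in the center row) and gapped other rows
    inserts = np.zeros(length + 1, dtype=int)  # inserts[i]: before center pos i
    pairwise: Dict[int, Tuple[List[str], List[int]]] = {}
    for k in range(n):
        if k == center:
            continue
        aln = next(iter(aligner.align(center_seq, windows[k].seq)))
        c_row, o_row = str(aln[0]), str(aln[1])
        seg_inserts = [0] * (length + 1)
        pos = 0
        other_chunks: List[str] = [""] * (length + 1)
        chunk = []
        for cc, oc in zip(c_row, o_row):
            if cc == GAP:
                seg_inserts[pos] += 1
                other_chunks[pos] += oc
            else:
                chunk.append(oc)
                pos += 1
        # chunk now holds the residue (or gap) of `other` at each center pos
        pairwise[k] = (other_chunks, chunk)  # type: ignore[assignment]
        inserts = np.maximum(inserts, seg_inserts)

    def build_center_row() -> str:
        parts = []
        for i in range(length):
            parts.append(GAP * int(inserts[i]))
            parts.append(center_seq[i])
        parts.append(GAP * int(inserts[length]))
        return "".join(parts)

    def build_other_row(k: int) -> str:
        other_chunks, per_pos = pairwise[k]
        parts = []
        for i in range(length):
            ins = other_chunks[i]
            parts.append(ins + GAP * (int(inserts[i]) - len(ins)))
            parts.append(per_pos[i])
        ins = other_chunks[length]
        parts.append(ins + GAP * (int(inserts[length]) - len(ins)))
        return "".join(parts)

    rows: List[str] = []
    ids: List[str] = []
    for k in range(n):
        ids.append(windows[k].rbp_id)
        rows.append(build_center_row() if k == center else build_other_row(k))
    assert len({len(r) for r in rows}) == 1
    return ids, rows


# ---------------------------------------------------------------------------
# conservation scan
# ---------------------------------------------------------------------------

def _char_matrix(rows: Sequence[str]) -> np.ndarray:
    return np.array([list(r) for r in rows])


def _pair_masks(mat: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """(match, valid) boolean arrays of shape (n_pairs, n_cols).

    A column is valid for a pair unless both rows are gaps; it matches
    when both rows carry the same non-gap base.
    """
    gap = mat == GAP
    iu, ju = np.triu_indices(mat.shape[0], 1)
    both_gap = gap[iu] & gap[ju]
    match = (mat[iu] == mat[ju]) & ~gap[iu] & ~both_gap
    return match, ~both_gap


def column_identity_profile(rows: Sequence[str]) -> np.ndarray:
    """Per-column mean pairwise identity (both-gap pairs excluded)."""
    match, valid = _pair_masks(_char_matrix(rows))
    nvalid = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        profile = np.where(nvalid > 0, match.sum(axis=0) / np.maximum(nvalid, 1), 0.0)
    return profile


def _identities_from_masks(
    match: np.ndarray, valid: np.ndarray, col_start: int, col_end: int
) -> np.ndarray:
    """Per-pair percent identities over 1-based columns [col_start, col_end]."""
    m = match[:, col_start - 1 : col_end].sum(axis=1)
    v = valid[:, col_start - 1 : col_end].sum(axis=1)
    ok = v > 0
    return 100.0 * m[ok] / v[ok]


def pairwise_identity_over_columns(
    rows: Sequence[str], col_start: int, col_end: int
) -> Tuple[float, float]:
    """Mean and sd of all-pairs identity over columns [col_start, col_end].

    Columns are 1-based inclusive; per pair, both-gap columns are ignored
    and gap-vs-base counts as mismatch.  Pairs with no scorable column
    are skipped.
    """
    match, valid = _pair_masks(_char_matrix(rows))
    idents = _identities_from_masks(match, valid, col_start, col_end)
    if idents.size == 0:
        return 0.0, 0.0
    sd = float(idents.std(ddof=1)) if idents.size > 1 else 0.0
    return float(idents.mean()), sd


def _smooth_profile(profile: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window)
    sums = np.convolve(profile, kernel, mode="same")
    counts = np.convolve(np.ones_like(profile), kernel, mode="same")
    return sums / counts


def _columns_to_member_span(
    row: str, window: FlankWindow, col_start: int, col_end: int
) -> Tuple[int, int]:
    """Map alignment columns to nt coordinates of one member window."""
    upstream = sum(1 for ch in row[: col_start - 1] if ch != GAP)
    inside = sum(1 for ch in row[col_start - 1 : col_end] if ch != GAP)
    start = window.start + upstream
    end = start + max(inside - 1, 0)
    return start, end


def scan_conserved_windows(
    ids: Sequence[str],
    rows: Sequence[str],
    flankset: FlankSet,
    cfg: PipelineConfig,
) -> List[MotifHit]:
    """Delimit maximal conserved runs of the flank alignment.

    A run is a maximal stretch of columns whose smoothed (width
    ``cfg.motifs.window``) mean pairwise identity stays >=
    ``min_mean_identity``; runs are trimmed to columns individually >=
    ``col_floor``, merged when overlapping, and reported when they span
    >= ``min_len`` columns with >= ``min_members`` members non-gap over
    >= 80 % of the span.
    """
    p = cfg.motifs
    ncol = len(rows[0])
    if ncol < p.min_len:
        return []
    profile = column_identity_profile(rows)
    # insertion columns (mostly gaps) carry no conservation signal and must
    # not break a conserved run: smoothing and thresholding operate on the
    # core columns (>= 50 % occupancy); spans are mapped back afterwards
    mat = _char_matrix(rows)
    occupancy = (mat != GAP).mean(axis=0)
    core = np.flatnonzero(occupancy >= 0.5)
    if core.size < p.min_len:
        return []
    core_profile = profile[core]
    smoothed = _smooth_profile(core_profile, p.window)
    above = smoothed >= p.min_mean_identity / 100.0
    floor = core_profile >= p.col_floor / 100.0

    # maximal runs of `above`; the centered smoothing shrinks a genuine
    # conserved block by up to half a window at each edge, so runs are
    # first extended by at most window/2 columns that individually clear
    # the floor, then trimmed to floor-clearing columns at both ends
    half = p.window // 2
    ncore = core.size
    spans: List[Tuple[int, int]] = []  # indices into `core`
    c = 0
    while c < ncore:
        if not above[c]:
            c += 1
            continue
        start = c
        while c < ncore and above[c]:
            c += 1
        end = c - 1
        left_limit = max(0, start - half)
        while start > left_limit and floor[start - 1]:
            start -= 1
        right_limit = min(ncore - 1, end + half)
        while end < right_limit and floor[end + 1]:
            end += 1
        while start <= end and not floor[start]:
            start += 1
        while end >= start and not floor[end]:
            end -= 1
        if start <= end:
            spans.append((start, end))
    # merge overlapping/adjacent spans, then map back to alignment columns
    merged: List[Tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    merged = [(int(core[s]), int(core[e])) for s, e in merged]

    window_by_id = {w.rbp_id: w for w in flankset.windows}
    hits: List[MotifHit] = []
    background_mean, _ = pairwise_identity_over_columns(rows, 1, ncol)
    for s, e in merged:
        if e - s + 1 < p.min_len:
            continue
        span_len = e - s + 1
        members = [
            (i, rid)
            for i, rid in enumerate(ids)
            if sum(1 for ch in rows[i][s : e + 1] if ch != GAP) >= 0.8 * span_len
        ]
        if len(members) < p.min_members:
            continue
        member_rows = [rows[i] for i, _ in members]
        mean, sd = pairwise_identity_over_columns(member_rows, s + 1, e + 1)
        if mean < p.min_mean_identity:
            continue
        consensus, pfm = consensus_and_pfm(member_rows, s + 1, e + 1)
        member_spans = {
            rid: _columns_to_member_span(rows[i], window_by_id[rid], s + 1, e + 1)
            for i, rid in members
        }
        hits.append(
            MotifHit(
                region=flankset.region,
                col_start=s + 1,
                col_end=e + 1,
                member_ids=tuple(rid for _, rid in members),
                member_spans=member_spans,
                mean_identity_pct=mean,
                sd_identity_pct=sd,
                consensus=consensus,
                pfm=pfm,
                background_identity_pct=background_mean,
            )
        )
    return hits


def consensus_and_pfm(
    rows: Sequence[str], col_start: int, col_end: int
) -> Tuple[str, np.ndarray]:
    """Consensus (modal base, ties -> IUPAC code) and base frequencies.

    The position-frequency matrix has rows A, C, G, T normalized over
    non-gap members per column; all-gap columns yield 'N' and zeros.
    """
    if len(rows) < 2:
        raise MotifError("consensus needs >= 2 rows")
    mat = _char_matrix(rows)[:, col_start - 1 : col_end]
    span = mat.shape[1]
    pfm = np.zeros((4, span))
    bases = "ACGT"
    consensus = []
    for c in range(span):
        col = [ch for ch in mat[:, c] if ch != GAP]
        if not col:
            consensus.append("N")
            continue
        counts = np.array([col.count(b) for b in bases], dtype=float)
        pfm[:, c] = counts / counts.sum()
        top = counts.max()
        tied = frozenset(b for b, k in zip(bases, counts) if k == top)
        consensus.append(_IUPAC[tied])
    return "".join(consensus), pfm


def motif_significance(
    hit: MotifHit,
    rows: Sequence[str],
    cfg: PipelineConfig,
    seed: int,
) -> float:
    """Permutation p-value of a motif against its surrounding flanks.

    The null distribution is the mean pairwise identity of
    ``n_permutations`` random same-length column windows drawn from the
    full flank alignment excluding the hit span;
    p = (1 + #{null >= observed}) / (N + 1).
    """
    p = cfg.motifs
    span = hit.span_len
    ncol = len(rows[0])
    allowed = [
        s
        for s in range(1, ncol - span + 2)
        if s + span - 1 < hit.col_start or s > hit.col_end
    ]
    if not allowed:
        raise MotifError("flanks shorter than the motif span; p undefined")
    rng = np.random.default_rng(seed)
    starts = rng.choice(allowed, size=p.n_permutations, replace=True)
    observed = hit.mean_identity_pct
    match, valid = _pair_masks(_char_matrix(rows))
    null_ge = 0
    for s in starts:
        idents = _identities_from_masks(match, valid, int(s), int(s) + span - 1)
        mean = float(idents.mean()) if idents.size else 0.0
        if mean >= observed:
            null_ge += 1
    return (1 + null_ge) / (p.n_permutations + 1)


def find_motifs(
    records: Sequence[RBPRecord],
    delineations: Dict[str, DomainDelineation],
    cfg: PipelineConfig,
    seed: int = 0,
) -> List[MotifHit]:
    """Full motif scan over both flank regions, with permutation p-values."""
    flanks = extract_flanks(records, delineations, cfg)
    out: List[MotifHit] = []
    for region in (BOUNDARY, DOWNSTREAM):
        fs = flanks[region]
        if len(fs.windows) < max(2, cfg.motifs.min_members):
            continue
        ids, rows = star_msa(fs.windows, cfg)
        for hit in scan_conserved_windows(ids, rows, fs, cfg):
            pval = motif_significance(hit, rows, cfg, seed)
            out.append(
                MotifHit(
                    **{
                        **hit.__dict__,
                        "permutation_p": pval,
                    }
                )
            )
    return out
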
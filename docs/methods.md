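# Methods

This note documents the models and procedures implemented in
`rbpmosaic`, the parameters that matter, the numerical conventions, and
what the synthetic benchmarks do and do not demonstrate.

## Model and assumptions

The pipeline rests on three biological assumptions about modular phage
receptor-binding proteins (RBPs):

1. **Two-domain modularity.** An RBP is an N-terminal anchor domain
   (particle attachment, genus-conserved) followed by a C-terminal
   receptor-binding domain (RBD; host-specificity, horizontally
   exchanged). Coordinates are 1-based inclusive: anchor = 1..anchor_end,
   RBD = anchor_end+1..L. Split-architecture RBPs (adapter plus separate
   RBD protein) are modeled as one record with anchor_end = 0.
2. **Specificity travels with the RBD.** RBDs recognizably homologous at
   ≥ 30 % amino-acid identity over ≥ 60 % coverage are treated as one
   subtype with one O-antigen specificity. Subtypes are the connected
   components of passing pairwise hits (single linkage), because
   horizontal-transfer hits chain transitively across genera.
3. **Prophage–host matching.** A prophage's RBP is assumed to match the
   O-antigen of the strain it is integrated in, which is why prophage
   records vote with their host strain's serogroup and why hosts lacking
   an O-antigen (rough laboratory strains) are excluded.

Serogroup labels are opaque strings in a single namespace (O-antigens,
compound labels like `4s/O22`, K-antigens as an outgroup specificity);
equality is exact string match and labels are never parsed.

## Parameters

All thresholds live in `PipelineConfig` (units in brackets, defaults in
parentheses):

- `hit_min_identity` [%] (30) and `hit_min_coverage` [%] (60): the HGT
  hit criterion over delineated RBDs. Coverage is measured against
  either RBD and symmetrized with OR, since query/subject roles are
  arbitrary in an all-vs-all comparison; consequently a hit passes
  exactly when identity ≥ 30 % and max(coverage_q, coverage_s) ≥ 60 %.
- `redundancy_identity` [%] (80): full-length identity above which
  same-serogroup records are collapsed. Keep-priority: higher prophage
  score, stronger evidence group (A first), longer sequence, smaller id.
- `consensus_fraction` (0.90) and `consensus_min_known` (2): the modal
  known serogroup must hold ≥ 90 % of the known votes, with at least two
  votes. Unknown serogroups neither support nor veto; they only fail to
  count toward the minimum. Votes of removed redundancy doubles are kept
  on their surviving representative. A tie can never assign (two
  distinct labels cannot both reach 90 %).
- `genus_min_specific_rbps` (2): genera must contribute at least two
  serogroup-assigned RBPs to the final set.
- `default_anchor_cutoff` [aa] (150), `smoothing_window` [aa] (20),
  `t_high` (0.7), `t_low` (0.4): delineation (below).
- `prophage_active_score` (0.8), `prophage_ambiguous_floor` (0.5),
  `allow_ambiguous` (on): prophage-prediction score bands. Scores are
  external tool outputs carried in the metadata; the pipeline performs
  no prophage prediction itself.
- Alignment: BLOSUM62 with gap open 11 / extend 1 for proteins (the
  scoring used by standard protein database search); a gap of length k
  costs open + k·extend. Nucleotide scoring for the motif scan is
  match 2 / mismatch −3 with gap open 20 / extend 8 — deliberately
  gap-averse, because flank windows share a coordinate origin and the
  conventional 5/−4 scheme scatters random flanks with spurious gaps
  (in testing it inflated 120-nt windows to 414 alignment columns and
  the planted motif was missed).
- Motif scan: `flank_halfwidth` 150 nt, `downstream_len` 120 nt,
  `min_len` 15 columns, `min_mean_identity` 55 %, smoothing `window`
  10 columns, `col_floor` 40 %, `min_members` 4, `n_permutations` 999.
  The identity floor sits between the ~25 % background of unrelated DNA
  and the 60–80 % conservation of real flanking motifs.

## Delineation

Every record receives exactly one delineation through the total dispatch
priority curated > breakpoint > default. The breakpoint heuristic
computes, per record, a positional conservation profile (fraction of
same-genus partners identical at each position, from N-terminally
anchored pairwise global alignments — no protein MSA heuristic is
introduced), smooths it with a centered 20-aa moving average, and places
the boundary with two cooperating rules:

- **Threshold rule:** the last position ≥ `t_high` before the profile
  first drops below `t_low`.
- **Change-point guard:** the position maximizing the prefix/suffix
  conservation contrast, weighted by √(b(L−b)) as in a two-sample
  statistic. The guard overrides the threshold answer when the two
  disagree by more than the smoothing window, and replaces the default
  fallback when no clean drop exists (contrast ≥ 0.15), with the search
  restricted to the first two thirds of the protein (anchors are
  N-terminal minorities, and terminal columns of end-gapped alignments
  are unreliable).

The threshold rule alone has two verified failure modes: a chance cold
streak of substitutions can end the conserved prefix early, and a genus
harboring several members of one RBD family keeps RBD conservation above
`t_low`, letting the rule leap deep into the RBD. With the guard, the
planted boundary is recovered within ±9 aa in all of 100 replicates of
the benchmark fixture (4 records, anchors 10 % diverged, unrelated
RBDs); fewer than 3 same-genus records, or a flat profile, fall back to
the 150-aa default with a warning. The unweighted contrast was also
tried and rejected: it favors short pristine prefixes when the anchor
has internal variability.

## Neighbor joining and concordance

Trees are built by canonical neighbor joining on d = 1 − identity/100
from pairwise global alignments (for small, strongly diverged sets this
tracks MSA-derived identity matrices closely without committing to an
MSA heuristic). Negative branch lengths are clamped to zero with the
deficit moved to the sister branch, preserving the pair sum; Q-criterion
ties break on the smaller index pair, making output order-invariant.
This is implemented in-package because the clamping convention is part
of the documented behavior; scikit-bio's independent NJ implementation
serves as a cross-check in the test suite (identical topologies on
additive matrices, verified against an exhaustive least-squares topology
enumeration for n ≤ 6).

Clustering agreement is reported as nearest-neighbor label concordance:
the fraction of taxa whose nearest neighbor (ties broken by smallest id)
shares their label, singleton labels excluded. This is deterministic and
needs no clade-extraction convention; it is *not* a tree statistic, so a
tree could in principle disagree with it in marginal cases.

## Motif scan

Flank windows are cut per record in boundary-relative (CDS) and
stop-codon-relative coordinates, aligned by center-star MSA (center =
window maximizing summed pairwise global scores, ties lexicographic;
merge under "once a gap, always a gap"). Conservation is a per-column
mean pairwise identity where both-gap pairs are excluded and gap-vs-base
counts as mismatch. Insertion columns (< 50 % occupancy) carry no signal
and are excluded from run detection so they cannot break a conserved
run. Detected runs are extended by at most half a smoothing window where
individual columns clear `col_floor` — correcting the systematic edge
shrink of centered smoothing — then trimmed to floor-clearing columns.
Significance is a permutation test: the observed mean identity against
999 same-length column windows drawn (seeded) from the flank alignment
excluding the hit; p = (1 + #{null ≥ obs}) / (N + 1), so the floor is
0.001.

## The synthetic generator

`generate_dataset` emits ~25–30 records per dataset under defaults:
5 genera (one temperate, contributing score-carrying prophage records),
6 serogroup-linked RBD families placed across genera with 30 % HGT
probability, anchors 150–210 aa at 5 % within-genus divergence, RBDs
350–600 aa diverged up to 40 % within a family (substitutions only, no
indels — planted boundaries are exact), 2 near-duplicates at ~97 %
identity, 1 decoy cluster of 3 records with a 2:1 label mixture (below
the 90 % consensus), 2 unknown-serogroup records, and one branched
phage carrying two RBPs. These sizes keep a full pipeline run at a few
seconds so that multi-replicate recovery properties are testable; they
are scaled-down relative to real curated collections (~136 records) but
realize the same structures.

Nucleotide sequences are back-translated with a fixed one-codon-per-
residue table. The boundary motif (44 nt, ending at the anchor/RBD
boundary, codon-aligned) is planted at the DNA level with mutations
concentrated on wobble positions, and the affected codons are
re-translated back into the protein. This keeps the CDS-translation
invariant exact while producing the characteristic pattern of real
recombination-hotspot motifs: DNA conservation in the planted window
(~75–80 % pairwise) exceeding what the encoded peptide requires, against
unrelated cross-genus background. The downstream motif (20 nt in the
120-nt noncoding flank) is planted with uniform per-site mutation at
15 %, giving ~73 % pairwise identity over a ~25 % random background.
Stop codons arising anywhere in a planted window are repaired
deterministically by editing the third base (TAA/TAG→TAC, TGA→TGC).

What passing the synthetic benchmarks shows: the pipeline's inference
chain (delineation → hits → clustering → consensus → concordance →
motifs) recovers planted structure exactly under the stated divergence
regimes, rejects planted decoys, and never loses a record in the
accounting. What it does not show: robustness to indels and length
variation within domains, to rate heterogeneity along sequences, to
misannotated CDS boundaries, or to real phylogenetic autocorrelation —
real RBD families are trees, not stars around an ancestor. The
boundary-flank motif scan in the full pipeline additionally inherits
window-placement jitter from estimated boundaries and a structured
(partly conserved) background, so its localization is reported as a
metric rather than guaranteed; the clean-background localization
property (Jaccard ≥ 0.9, p ≤ 0.01) holds in ≥ 95 % of 100 replicates.

## Degenerate inputs and tie-breaks

- A local alignment with no positive-scoring residue pair is reported
  with score 0, zero columns and identity 0; it can never be a hit.
- RBDs shorter than 10 aa produce no hit (warning), and delineations
  must leave ≥ 10 aa of RBD.
- Identity denominators include gap columns (conservative and exactly
  testable); the matrix diagonal is exactly 100.
- Subtype ids are the lexicographically smallest member id; modal-vote
  ties take the lexicographically largest label but can never reach the
  90 % consensus with ≥ 2 voters, so the tie-break never assigns.
- Conflicting experimental (RBP-level) serogroups within one subtype
  are a hard error — a data contradiction that must not be auto-resolved.
- Records missing nucleotide data are skipped by the motif scan with a
  warning; windows truncated at sequence edges are kept and flagged.

## Problem sizes

The test suite runs ~170 tests in ~5 minutes on one CPU: recovery
properties use 25–100 seeded replicates of the default-size generator;
exhaustive oracles cover local/global alignment on ≤ 8-mers over a
4-letter alphabet, connected components on 200 random graphs, and NJ
topology enumeration up to 6 taxa (split recovery up to 8).
`scripts/acceptance.py` uses 5 generator replicates and finishes in
under a minute.
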
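"""Flank extraction, center-star MSA, conserved-window scan, significance."""

import dataclasses
import itertools

import numpy as np
import pytest

from rbpmosaic import PipelineConfig
from rbpmosaic.config import MotifParams
from rbpmosaic.delineation import DomainDelineation, DelineationMethod
from rbpmosaic.motifs import (
    BOUNDARY,
    DOWNSTREAM,
    FlankSet,
    FlankWindow,
    MotifError,
    consensus_and_pfm,
    extract_flanks,
    motif_significance,
    pairwise_identity_over_columns,
    scan_conserved_windows,
    star_msa,
)
from rbpmosaic.records import RBPRecord
from rbpmosaic.simulate import (
    CODON,
    back_translate,
    generate_dataset,
    mutate_nt,
    random_nt,
)


def nt_record(rbp_id, aa, flank, genus="g"):
    nt = back_translate(aa) + "TAA" + flank
    return RBPRecord(rbp_id=rbp_id, phage_id=f"{rbp_id}_p", genus=genus,
                     aa_sequence=aa, nt_sequence=nt, lifestyle="lytic")


def delin(rbp_id, anchor_end):
    return DomainDelineation(rbp_id, anchor_end, DelineationMethod.curated, 1.0)


class TestExtractFlanks:
    def test_boundary_window_arithmetic(self, cfg):
        # anchor_end 150, halfwidth 150 -> CDS window 301..600
        aa = "A" * 300
        rec = nt_record("r", aa, "G" * 50)
        flanks = extract_flanks([rec], {"r": delin("r", 150)}, cfg)
        (w,) = flanks[BOUNDARY].windows
        assert (w.start, w.end) == (301, 600)
        assert not w.truncated
        assert w.seq == rec.cds[300:600]

    def test_short_rbd_truncates_and_flags(self, cfg):
        aa = "A" * 160  # CDS 480 nt; window would reach 630
        rec = nt_record("r", aa, "G" * 50)
        flanks = extract_flanks([rec], {"r": delin("r", 150)}, cfg)
        (w,) = flanks[BOUNDARY].windows
        assert w.end == 480 and w.truncated

    def test_downstream_window_starts_after_stop(self, cfg):
        flank = random_nt(np.random.default_rng(0), 200)
        rec = nt_record("r", "A" * 200, flank)
        flanks = extract_flanks([rec], {"r": delin("r", 150)}, cfg)
        (w,) = flanks[DOWNSTREAM].windows
        assert (w.start, w.end) == (1, cfg.motifs.downstream_len)
        assert w.seq == flank[: cfg.motifs.downstream_len]

    def test_record_without_nt_is_skipped_with_warning(self, cfg, caplog):
        rec = RBPRecord(rbp_id="r", phage_id="p", genus="g",
                        aa_sequence="A" * 200)
        with caplog.at_level("WARNING", logger="rbpmosaic.motifs"):
            flanks = extract_flanks([rec], {"r": delin("r", 150)}, cfg)
        assert flanks[BOUNDARY].windows == ()
        assert "no nt_sequence" in caplog.text

    def test_planted_motif_lies_inside_the_window(self, cfg):
        records, truth = generate_dataset(seed=2)
        lytic = [r for r in records if r.lifestyle.value == "lytic"]
        delins = {
            r.rbp_id: delin(r.rbp_id, truth.per_record[r.rbp_id]["anchor_end"])
            for r in lytic
        }
        flanks = extract_flanks(lytic, delins, cfg)
        for w in flanks[BOUNDARY].windows:
            lo, hi = truth.motif_boundary[w.rbp_id]
            assert w.start <= lo and hi <= w.end


class TestStarMSA:
    def test_identical_windows_align_gapless(self, cfg):
        wins = [FlankWindow(f"r{k}", BOUNDARY, "ACGTACGTACGT", 1, 12)
                for k in range(3)]
        ids, rows = star_msa(wins, cfg)
        assert rows == ["ACGTACGTACGT"] * 3

    def test_three_window_merge_matches_hand_construction(self, cfg):
        # center is the full-length window; one row needs an internal gap
        wins = [
            FlankWindow("a", BOUNDARY, "ACGTACGTAC", 1, 10),
            FlankWindow("b", BOUNDARY, "ACGTCGTAC", 1, 9),   # T deleted
            FlankWindow("c", BOUNDARY, "ACGTACGTAC", 1, 10),
        ]
        ids, rows = star_msa(wins, cfg)
        by = dict(zip(ids, rows))
        assert by["a"] == "ACGTACGTAC"
        assert by["c"] == "ACGTACGTAC"
        assert by["b"].replace("-", "") == "ACGTCGTAC"
        assert len(by["b"]) == 10 and by["b"].count("-") == 1

    def test_alignment_invariant_to_input_order(self, cfg):
        rng = np.random.default_rng(3)
        base = random_nt(rng, 60)
        wins = [
            FlankWindow(f"r{k}", BOUNDARY, mutate_nt(rng, base, 0.2), 1, 60)
            for k in range(5)
        ]
        ids_f, rows_f = star_msa(wins, cfg)
        ids_r, rows_r = star_msa(wins[::-1], cfg)
        assert dict(zip(ids_f, rows_f)) == dict(zip(ids_r, rows_r))

    def test_single_window_is_an_error(self, cfg):
        with pytest.raises(MotifError, match=">= 2"):
            star_msa([FlankWindow("a", BOUNDARY, "ACGT", 1, 4)], cfg)


def _flankset(rows, region=DOWNSTREAM):
    return FlankSet(region, tuple(
        FlankWindow(f"r{k}", region, row.replace("-", ""), 1,
                    len(row.replace("-", "")))
        for k, row in enumerate(rows)
    ))


class TestScanConservedWindows:
    def test_all_identical_alignment_is_one_full_span_hit(self, cfg):
        rows = ["ACGTACGTACGTACGTACGT"] * 4
        ids = [f"r{k}" for k in range(4)]
        hits = scan_conserved_windows(ids, rows, _flankset(rows), cfg)
        assert len(hits) == 1
        h = hits[0]
        assert (h.col_start, h.col_end) == (1, 20)
        assert h.mean_identity_pct == 100.0

    def _planted(self, seed, motif_identity=0.7, n=8, flank=100, motif_len=44):
        rng = np.random.default_rng(seed)
        motif = random_nt(rng, motif_len)
        rate = 1 - np.sqrt(motif_identity)  # pairwise identity ~ (1-r)^2
        rows, spans = [], {}
        for k in range(n):
            left = random_nt(rng, flank)
            right = random_nt(rng, flank)
            rows.append(left + mutate_nt(rng, motif, rate) + right)
            spans[f"r{k}"] = (flank + 1, flank + motif_len)
        return rows, spans

    def test_planted_motif_localized_with_high_jaccard(self, cfg):
        from rbpmosaic.simulate import motif_localization_jaccard

        rows, spans = self._planted(0)
        ids = [f"r{k}" for k in range(len(rows))]
        hits = scan_conserved_windows(ids, rows, _flankset(rows), cfg)
        assert len(hits) == 1
        assert motif_localization_jaccard(hits, spans) >= 0.9

    def test_threshold_above_planted_identity_finds_nothing(self, cfg):
        rows, _ = self._planted(1)
        ids = [f"r{k}" for k in range(len(rows))]
        high = dataclasses.replace(
            cfg, motifs=dataclasses.replace(cfg.motifs, min_mean_identity=95.0)
        )
        assert scan_conserved_windows(ids, rows, _flankset(rows), high) == []

    def test_raising_threshold_never_lengthens_spans(self, cfg):
        rows, _ = self._planted(2)
        ids = [f"r{k}" for k in range(len(rows))]
        prev_total = None
        for thr in (55.0, 65.0, 75.0, 85.0):
            c = dataclasses.replace(
                cfg, motifs=dataclasses.replace(cfg.motifs, min_mean_identity=thr)
            )
            hits = scan_conserved_windows(ids, rows, _flankset(rows), c)
            total = sum(h.span_len for h in hits)
            if prev_total is not None:
                assert total <= prev_total
            prev_total = total

    def test_mean_and_sd_match_brute_force_all_pairs(self, cfg):
        rows, _ = self._planted(3, n=6)
        ids = [f"r{k}" for k in range(len(rows))]
        (h,) = scan_conserved_windows(ids, rows, _flankset(rows), cfg)
        # brute force over the motif columns
        sub = [r[h.col_start - 1 : h.col_end] for r in rows]
        idents = []
        for a, b in itertools.combinations(sub, 2):
            pairs = [(x, y) for x, y in zip(a, b) if not (x == "-" and y == "-")]
            matches = sum(x == y and x != "-" for x, y in pairs)
            idents.append(100.0 * matches / len(pairs))
        assert h.mean_identity_pct == pytest.approx(np.mean(idents))
        assert h.sd_identity_pct == pytest.approx(np.std(idents, ddof=1))


class TestSignificance:
    def test_perfectly_conserved_motif_reaches_the_floor_p(self, cfg):
        rng = np.random.default_rng(4)
        motif = random_nt(rng, 30)
        rows = [random_nt(rng, 80) + motif + random_nt(rng, 80)
                for _ in range(6)]
        ids = [f"r{k}" for k in range(6)]
        (h,) = scan_conserved_windows(ids, rows, _flankset(rows), cfg)
        p = motif_significance(h, rows, cfg, seed=0)
        assert p == 1 / (cfg.motifs.n_permutations + 1)

    def test_background_window_has_uniform_p(self, cfg):
        """A 'motif' sampled from the background itself is not significant:
        its permutation p is uniform on the grid (mean ~ 0.5)."""
        quick = dataclasses.replace(
            cfg, motifs=dataclasses.replace(cfg.motifs, n_permutations=199)
        )
        ps = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            rows = [random_nt(rng, 160) for _ in range(5)]
            from rbpmosaic.motifs import MotifHit

            start = int(rng.integers(1, 160 - 20))
            mean, sd = pairwise_identity_over_columns(rows, start, start + 19)
            hit = MotifHit(
                region=DOWNSTREAM, col_start=start, col_end=start + 19,
                member_ids=tuple(f"r{k}" for k in range(5)), member_spans={},
                mean_identity_pct=mean, sd_identity_pct=sd, consensus="",
                pfm=np.zeros((4, 20)), background_identity_pct=mean,
            )
            ps.append(motif_significance(hit, rows, quick, seed=seed))
        assert abs(np.mean(ps) - 0.5) < 0.1

    def test_fixed_seed_is_bitwise_reproducible(self, cfg):
        rng = np.random.default_rng(6)
        motif = random_nt(rng, 25)
        rows = [random_nt(rng, 60) + mutate_nt(rng, motif, 0.1)
                + random_nt(rng, 60) for _ in range(5)]
        ids = [f"r{k}" for k in range(5)]
        (h,) = scan_conserved_windows(ids, rows, _flankset(rows), cfg)
        assert motif_significance(h, rows, cfg, 123) == motif_significance(
            h, rows, cfg, 123
        )

    def test_flank_shorter_than_motif_is_an_error(self, cfg):
        rows = ["ACGTACGTACGTACGTACGT"] * 4
        ids = [f"r{k}" for k in range(4)]
        (h,) = scan_conserved_windows(ids, rows, _flankset(rows), cfg)
        with pytest.raises(MotifError, match="undefined"):
            motif_significance(h, rows, cfg, 0)


class TestConsensusAndPFM:
    def test_unanimous_column(self):
        consensus, pfm = consensus_and_pfm(["AAA", "AAA", "AAA"], 1, 3)
        assert consensus == "AAA"
        assert pfm[0].tolist() == [1.0, 1.0, 1.0]

    def test_tied_column_uses_iupac_code(self):
        consensus, _ = consensus_and_pfm(["AG", "AG", "GG", "GG"], 1, 1)
        assert consensus == "R"  # A/G tie

    def test_noiseless_planting_recovers_the_consensus(self):
        rng = np.random.default_rng(7)
        motif = random_nt(rng, 30)
        consensus, _ = consensus_and_pfm([motif] * 5, 1, 30)
        assert consensus == motif
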
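"""Target scoring, transcriptome scan, target mimicry, conserved-lncRNA screen."""

import numpy as np
import pandas as pd
import pytest

from etiomir import synthio, targets
from etiomir._seq import revcomp_dna

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def rc_rna(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


MATURE = "UGGAGCUCCCUUCAUUCCAAU"  # 21 nt, miR156-like composition


def perfect_site(mature: str) -> str:
    """Target window (5'->3') pairing every miRNA position Watson-Crick."""
    return rc_rna(mature)


class TestForcedScores:
    def test_perfect_complement_scores_zero(self):
        assert targets.score_window_ungapped(MATURE, perfect_site(MATURE)) == 0.0

    def test_single_wobble_outside_seed_scores_half(self):
        # miRNA position 15 is outside 2-13: G:U wobble there costs 0.5
        mature = MATURE[:14] + "G" + MATURE[15:]
        window = list(perfect_site(mature))
        # target base opposite miRNA position k sits at window index L-k
        window[len(mature) - 15] = "U"
        assert targets.score_window_ungapped(mature, "".join(window)) == 0.5

    def test_single_mismatch_inside_seed_scores_two(self):
        mature = MATURE[:4] + "A" + MATURE[5:]  # position 5, in the seed
        window = list(perfect_site(mature))
        window[len(mature) - 5] = "C"  # A:C is a mismatch, never a wobble
        assert targets.score_window_ungapped(mature, "".join(window)) == 2.0

    def test_wobble_inside_seed_scores_one(self):
        mature = MATURE[:4] + "G" + MATURE[5:]
        window = list(perfect_site(mature))
        window[len(mature) - 5] = "U"
        assert targets.score_window_ungapped(mature, "".join(window)) == 1.0

    def test_indel_outside_seed_scores_two(self):
        window = perfect_site(MATURE)
        # delete the target base opposite miRNA position 16 (outside seed)
        clipped = window[: len(MATURE) - 16] + window[len(MATURE) - 15 :]
        exp, _aln = targets.score_target_site(MATURE, clipped)
        assert exp == 2.0

    def test_indel_inside_seed_scores_four(self):
        window = perfect_site(MATURE)
        clipped = window[: len(MATURE) - 5] + window[len(MATURE) - 4 :]
        exp, _aln = targets.score_target_site(MATURE, clipped)
        assert exp == 4.0

    def test_penalties_add_per_position(self, rng):
        # independent per-position oracle over random single-window duplexes
        for _ in range(50):
            mature = "".join(rng.choice(list("ACGU"), size=21))
            window = "".join(rng.choice(list("ACGU"), size=21))
            got = targets.score_window_ungapped(mature, window)
            expected = 0.0
            for k in range(1, 22):
                mb = mature[k - 1]
                tb = window[21 - k]
                if _COMP[mb] == tb:
                    p = 0.0
                elif {mb, tb} == {"G", "U"}:
                    p = 0.5
                else:
                    p = 1.0
                expected += p * (2.0 if 2 <= k <= 13 else 1.0)
            assert got == pytest.approx(expected)

    def test_window_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            targets.score_window_ungapped(MATURE, "ACGU")


def _collapse_oracle(penalties, L, cutoff):
    chosen = []
    for p in np.nonzero(penalties <= cutoff)[0]:
        e = float(penalties[p])
        if chosen and p <= chosen[-1][0] + L - 1:
            if e < chosen[-1][1]:
                chosen[-1] = (int(p), e)
        else:
            chosen.append((int(p), e))
    return chosen


class TestScan:
    def test_perfect_site_found_with_exact_span(self):
        site = perfect_site(MATURE)
        tx = "A" * 30 + site + "A" * 30
        hits = targets.scan_transcriptome({"m1": MATURE}, {"t1": tx})
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end) == (31, 30 + len(MATURE))
        assert h.expectation == 0.0 and h.category == "cleavage"

    def test_no_hits_in_unrelated_sequence(self, rng):
        tx = "".join(rng.choice(list("ACGU"), size=300))
        # a random 21-mer against random sequence essentially never reaches 3.0
        hits = targets.scan_transcriptome({"m1": MATURE}, {"t1": tx}, cutoff=3.0)
        for h in hits:
            assert h.expectation <= 3.0  # any hit must still honor the cutoff

    def test_central_mismatch_is_translational(self):
        window = list(perfect_site(MATURE))
        k = 10  # central position
        mb = MATURE[k - 1]
        bad = next(b for b in "ACGU" if b != _COMP[mb] and {mb, b} != {"G", "U"})
        window[len(MATURE) - k] = bad
        tx = "C" * 20 + "".join(window) + "C" * 20
        hits = targets.scan_transcriptome({"m1": MATURE}, {"t1": tx}, cutoff=3.0)
        assert len(hits) == 1 and hits[0].category == "translational"

    def test_scan_matches_bruteforce_window_scores(self, rng):
        L = 21
        for trial in range(10):
            mature = "".join(rng.choice(list("ACGU"), size=L))
            tx = "".join(rng.choice(list("ACGU"), size=200))
            if rng.random() < 0.7:  # embed a near-perfect site
                p = int(rng.integers(0, 180))
                site = list(perfect_site(mature))
                if rng.random() < 0.5:
                    site[int(rng.integers(L))] = str(rng.choice(list("ACGU")))
                tx = tx[:p] + "".join(site) + tx[p + L :]
            hits = targets.scan_transcriptome({"m": mature}, {"t": tx}, cutoff=4.0)
            pen = np.array(
                [
                    targets.score_window_ungapped(mature, tx[p : p + L])
                    for p in range(len(tx) - L + 1)
                ]
            )
            expected = _collapse_oracle(pen, L, 4.0)
            assert [(h.start - 1, h.expectation) for h in hits] == pytest.approx(
                expected
            )

    def test_adding_mismatches_never_lowers_expectation(self, rng):
        window = perfect_site(MATURE)
        last = 0.0
        positions = rng.permutation(len(MATURE))
        w = list(window)
        for p in positions[:8]:
            mb = MATURE[len(MATURE) - 1 - p]
            w[p] = next(b for b in "ACGU" if b != _COMP[mb] and {mb, b} != {"G", "U"})
            exp = targets.score_window_ungapped(MATURE, "".join(w))
            assert exp >= last
            last = exp

    def test_scan_on_planted_transcriptome(self, small_truth):
        import copy

        truth = copy.copy(small_truth)
        truth.transcripts = {}
        truth = synthio.plant_targets(truth, seed=41, species="zm")
        matures = {m.mirna_id: m.mature_seq for m in truth.mirnas["zm"]}
        hits = targets.scan_transcriptome(matures, truth.transcripts)
        perfect = [h for h in hits if h.expectation == 0.0]
        # every planted (miRNA, transcript) pair is recovered with a 0-expectation site
        planted = {(t["mirna_id"], t["transcript_id"]) for t in truth.target_sites}
        found = {(h.mirna_id, h.transcript_id) for h in perfect}
        assert planted <= found


class TestMimicry:
    def test_constructed_bulge_site_detected_exactly(self):
        s = 10
        site = rc_rna(MATURE[s:]) + "CUA" + rc_rna(MATURE[:s])
        lnc = "A" * 12 + site + "A" * 12
        mimics = targets.detect_mimicry({"m1": MATURE}, {"l1": lnc})
        assert len(mimics) == 1
        site_hit = mimics[0]
        assert site_hit.start == 13 and site_hit.end == 12 + len(site)
        assert site_hit.bulge_length == 3
        assert site_hit.bulge_after_position == 10
        assert site_hit.flank_expectation == 0.0

    def test_perfect_complement_is_not_a_mimic(self):
        lnc = "G" * 15 + perfect_site(MATURE) + "G" * 15
        assert targets.detect_mimicry({"m1": MATURE}, {"l1": lnc}) == []

    @pytest.mark.parametrize("bulge_len", [1, 2, 3, 4, 5, 6, 7])
    def test_only_bulges_of_two_to_five_qualify(self, bulge_len):
        s = 10
        bulge = "CUA" * 3
        site = rc_rna(MATURE[s:]) + bulge[:bulge_len] + rc_rna(MATURE[:s])
        lnc = "A" * 12 + site + "A" * 12
        mimics = targets.detect_mimicry({"m1": MATURE}, {"l1": lnc})
        if 2 <= bulge_len <= 5:
            assert [m.bulge_length for m in mimics] == [bulge_len]
        else:
            assert mimics == []

    def test_mimic_site_is_not_a_cleavage_site(self):
        s = 10
        site = rc_rna(MATURE[s:]) + "CUA" + rc_rna(MATURE[:s])
        lnc = "A" * 12 + site + "A" * 12
        hits = targets.scan_transcriptome({"m1": MATURE}, {"l1": lnc}, cutoff=3.0)
        assert [h for h in hits if h.category == "cleavage"] == []

    def test_planted_mimic_lncrnas_recovered(self, small_truth):
        import copy

        truth = copy.copy(small_truth)
        truth.mimic_lncrnas, truth.mimic_sites = {}, []
        truth = synthio.plant_mimic_lncrnas(truth, seed=42, species="zm")
        matures = {m.mirna_id: m.mature_seq for m in truth.mirnas["zm"]}
        mimics = targets.detect_mimicry(matures, truth.mimic_lncrnas)
        found = {(m.mirna_id, m.lncrna_id, m.start, m.end) for m in mimics}
        for rec in truth.mimic_sites:
            assert (
                rec["mirna_id"],
                rec["lncrna_id"],
                rec["site_start"],
                rec["site_end"],
            ) in found


class TestConservedLncRNA:
    def test_planted_structured_lncrnas_retained(self, small_truth):
        import copy

        truth = copy.deepcopy(small_truth)
        records = synthio.plant_conserved_lncrnas(truth, seed=43)
        tags = [reg["fragment"] for r in records for reg in r["regions"].values()]
        cands = targets.screen_conserved_lncrna(
            truth.ortholog_pairs,
            truth.genes["zm"],
            truth.genes["os"],
            truth.genomes["zm"],
            truth.genomes["os"],
            tags,
            seed=7,
            n_shuffles=40,
        )
        got = {(c.gene_a, c.gene_b) for c in cands}
        planted = {r["pairs"] for r in records}
        assert planted <= got
        for c in cands:
            assert c.e_value <= 1e-6 and c.expressed and c.structure_z < -1.0

    def test_no_tags_means_no_candidates(self, small_truth):
        import copy

        truth = copy.deepcopy(small_truth)
        synthio.plant_conserved_lncrnas(truth, seed=43)
        cands = targets.screen_conserved_lncrna(
            truth.ortholog_pairs,
            truth.genes["zm"],
            truth.genes["os"],
            truth.genomes["zm"],
            truth.genomes["os"],
            tags=[],
            seed=7,
            n_shuffles=10,
        )
        assert cands == []

    def test_unrelated_flanks_fail_the_alignment_step(self, small_truth):
        # without planting, downstream flanks are random: nothing may pass e<=1e-6
        cands = targets.screen_conserved_lncrna(
            small_truth.ortholog_pairs,
            small_truth.genes["zm"],
            small_truth.genes["os"],
            small_truth.genomes["zm"],
            small_truth.genomes["os"],
            tags=["ACGTACGTACGTACGTACGTA"],
            seed=7,
            n_shuffles=10,
        )
        assert cands == []

    def test_mfe_zscore_separates_hairpin_from_random(self, rng):
        half = "".join(rng.choice(list("ACGU"), size=30))
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        hairpin = half + "AACAA" + "".join(comp[c] for c in reversed(half))
        z_hp = targets.mfe_zscore(hairpin, np.random.default_rng(1), n_shuffles=50)
        assert z_hp < -1.0
        rand = "".join(rng.choice(list("ACGU"), size=65))
        z_rand = targets.mfe_zscore(rand, np.random.default_rng(1), n_shuffles=50)
        assert z_rand > z_hp


class TestIntersect:
    def _sites(self):
        return [
            targets.TargetSite("m1", "tx1", 10, 30, 1.5, "cleavage", ("", "", "")),
            targets.TargetSite("m2", "tx2", 5, 25, 2.0, "translational", ("", "", "")),
        ]

    def test_inner_join_on_gene_id(self):
        curated = pd.DataFrame(
            {"gene_id": ["g1"], "label": ["SBP"], "annotation": ["transcription factor"]}
        )
        out = targets.intersect_gene_lists(
            self._sites(), curated, {"tx1": "g1", "tx2": "g2"}
        )
        assert len(out) == 1
        assert out.target_gene.iloc[0] == "g1" and out.label.iloc[0] == "SBP"

    def test_empty_intersection(self):
        curated = pd.DataFrame({"gene_id": ["gX"], "label": ["x"], "annotation": ["y"]})
        out = targets.intersect_gene_lists(self._sites(), curated)
        assert out.empty

    def test_matches_set_oracle(self):
        curated = pd.DataFrame(
            {"gene_id": ["tx1", "tx2", "tx9"], "label": list("abc"), "annotation": [""] * 3}
        )
        out = targets.intersect_gene_lists(self._sites(), curated)
        assert set(out.target_gene) == {"tx1", "tx2"} & {"tx1", "tx2", "tx9"}
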
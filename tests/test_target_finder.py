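import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cescan import (
    AlignmentParams,
    MiRNA,
    PlantSpec,
    SequenceRecord,
    align_window,
    find_target_sites,
    make_transcript_with_planted_sites,
    predict_all,
    reverse_complement,
    scan_seed_matches,
    seed_target_patterns,
)
from oracles import naive_site_scan, rc_rna

MIR122 = "UGGAGUGUGACAAUGGUGUUUG"

rna_seq = st.text(alphabet="ACGU", min_size=18, max_size=25)


def _tx(seq, biotype="lncRNA", tid="t1"):
    return SequenceRecord(tid, seq, biotype)


class TestSeedPatterns:
    def test_mir122_like_patterns(self):
        pats = seed_target_patterns(MiRNA("m", MIR122))
        assert pats == {
            "6mer": "CACUCC",
            "7mer-m8": "ACACUCC",
            "7mer-A1": "CACUCCA",
            "8mer": "ACACUCCA",
        }

    def test_poly_a_seed_gives_poly_u_pattern(self):
        pats = seed_target_patterns(MiRNA("m", "GAAAAAAGGGCCCGGGCCC"))
        assert pats["6mer"] == "UUUUUU"

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError, match="length"):
            MiRNA("m", "UGGAGUG")

    @settings(max_examples=50, derandomize=True)
    @given(rna_seq)
    def test_pattern_structure_invariants(self, seq):
        """6mer is a suffix of 7mer-m8; A1 classes append exactly one A."""
        mi = MiRNA("m", seq)
        pats = seed_target_patterns(mi)
        assert pats["7mer-m8"].endswith(pats["6mer"])
        assert pats["7mer-A1"] == pats["6mer"] + "A"
        assert pats["8mer"] == pats["7mer-m8"] + "A"
        assert pats["6mer"] == rc_rna(seq[1:7])


class TestSeedScan:
    def test_contained_8mer_pattern_found(self):
        (sm,) = scan_seed_matches(_tx("AAACACUCCAAA"), MiRNA("m", MIR122))
        assert (sm.site_class, sm.t_start, sm.t_end) == ("8mer", 2, 10)

    def test_planted_6mer_in_clean_background(self, panel8):
        spec = PlantSpec(500, planted=((panel8[0].id, "6mer", 100),), rng_seed=9)
        rec, truth = make_transcript_with_planted_sites(spec, panel8)
        (sm,) = scan_seed_matches(rec, panel8[0])
        assert (sm.t_start, sm.site_class) == (100, "6mer")

    def test_no_pattern_means_no_hits(self):
        # poly-A transcript cannot complement a poly-A-free seed
        assert scan_seed_matches(_tx("A" * 50), MiRNA("m", MIR122)) == []

    def test_t_equivalent_to_u_in_transcripts(self):
        rna = scan_seed_matches(_tx("AAACACUCCAAA"), MiRNA("m", MIR122))
        dna = scan_seed_matches(_tx("AAACACTCCAAA"), MiRNA("m", MIR122))
        assert [(s.site_class, s.t_start) for s in rna] == [
            (s.site_class, s.t_start) for s in dna
        ]

    def test_class_collapse_most_specific_wins(self):
        """A locus matching the 8mer pattern is reported once, as 8mer only."""
        sms = scan_seed_matches(_tx("GGGACACUCCAGGG"), MiRNA("m", MIR122))
        assert [s.site_class for s in sms] == ["8mer"]


class TestAlignWindow:
    def test_perfect_duplex_scores_length_times_match(self):
        mi = MiRNA("m", MIR122)
        tx = _tx(reverse_complement(MIR122))
        (sm,) = scan_seed_matches(tx, mi)
        res = align_window(tx, sm, mi)
        assert res.score == len(MIR122) * 5.0
        assert all(state == "WC" for _, _, state in res.paired)
        assert len(res.paired) == len(MIR122)

    def test_seed_only_scores_anchored_columns(self):
        # miRNA tail of C's against an all-A window: no 3' column can pair
        mi = MiRNA("m", "C" + "GGAGUG" + "C" * 15)
        tx = _tx("A" * 19 + "CACUCC" + "U")
        (site,) = find_target_sites(tx, mi)
        assert site.alignment_score == 6 * 5.0

    def test_compensatory_site_pairs_13_18_block(self, panel8):
        mi = panel8[2]
        spec = PlantSpec(300, planted=((mi.id, "mismatch-compensatory", 100),), rng_seed=5)
        rec, _ = make_transcript_with_planted_sites(spec, panel8)
        (sm,) = scan_seed_matches(rec, mi, allow_mismatch=True)
        res = align_window(rec, sm, mi)
        assert set(range(13, 19)) <= res.watson_crick_positions()

    def test_score_monotone_in_three_prime_pairing(self):
        """Extending Watson-Crick 3' pairing never decreases the score."""
        mi = MiRNA("m", "C" + "GGAGUG" + "C" * 8 + "GUGUGUG")
        tail = mi.sequence[8:]
        scores = []
        for k in range(0, 12):
            # complement the k tail bases adjacent to the seed (miRNA 9..8+k)
            comp = reverse_complement(tail[:k])
            window = "A" * (19 - 1 - len(comp)) + comp + "A" + "CACUCC" + "U"
            tx = _tx(window)
            (site,) = find_target_sites(tx, mi)
            scores.append(site.alignment_score)
        assert all(b >= a for a, b in zip(scores, scores[1:]))

    def test_window_truncates_at_transcript_start(self):
        mi = MiRNA("m", MIR122)
        tx = _tx("CACUCCAAAAAAAAAA")  # seed match at position 0
        sites = find_target_sites(tx, mi)
        assert sites and sites[0].window_start == 0


class TestMismatchCompensation:
    def test_mismatch_with_scrambled_3prime_not_reported(self, panel8):
        mi = panel8[0]
        spec = PlantSpec(400, planted=((mi.id, "mismatch-compensatory", 100),), rng_seed=2)
        rec, _ = make_transcript_with_planted_sites(spec, panel8)
        seq = list(rec.sequence)
        # destroy the planted 13-18 complement upstream of the site
        block = reverse_complement(mi.three_prime_block)
        pos = rec.sequence.find(block)
        assert 0 <= pos < 100
        seq[pos] = next(b for b in "ACGU" if b != seq[pos] and b != seq[pos + 1])
        broken = SequenceRecord(rec.id, "".join(seq), rec.biotype)
        found = scan_seed_matches(broken, mi, allow_mismatch=True)
        assert all(s.site_class != "mismatch-compensatory" for s in found)

    def test_mismatch_mode_off_reports_nothing(self, panel8):
        mi = panel8[0]
        spec = PlantSpec(400, planted=((mi.id, "mismatch-compensatory", 100),), rng_seed=2)
        rec, _ = make_transcript_with_planted_sites(spec, panel8)
        assert scan_seed_matches(rec, mi, allow_mismatch=False) == []


class TestOracleEquivalence:
    @pytest.mark.parametrize("allow_mismatch", [False, True])
    def test_matches_naive_scanner_on_random_sequences(self, allow_mismatch):
        rng = np.random.default_rng(7)
        for _ in range(25):
            tseq = "".join("ACGU"[b] for b in rng.integers(0, 4, size=800))
            mseq = "".join("ACGU"[b] for b in rng.integers(0, 4, size=22))
            tx, mi = _tx(tseq), MiRNA("m", mseq)
            got = [
                (s.site_class, s.t_start, s.t_end)
                for s in scan_seed_matches(tx, mi, allow_mismatch=allow_mismatch)
            ]
            want = naive_site_scan(tseq, mseq, allow_mismatch)
            assert sorted(got) == sorted(want)


class TestPredictAll:
    def test_two_planted_sites_across_transcripts(self, panel8):
        recs, truths = [], []
        for i, cls in enumerate(["8mer", "7mer-A1"]):
            spec = PlantSpec(
                300, planted=((panel8[i].id, cls, 120),), rng_seed=30 + i,
                transcript_id=f"tx{i}",
            )
            rec, truth = make_transcript_with_planted_sites(spec, panel8)
            recs.append(rec)
            truths.extend(truth)
        table = predict_all(recs, panel8)
        assert len(table) == 2
        assert sorted(table["site_class"]) == ["7mer-A1", "8mer"]
        assert list(table["conserved"]) == [None, None]

    def test_deterministic_across_runs(self, panel8):
        spec = PlantSpec(300, planted=((panel8[0].id, "8mer", 50),), rng_seed=3)
        rec, _ = make_transcript_with_planted_sites(spec, panel8)
        a = predict_all([rec], panel8)
        b = predict_all([rec], panel8)
        assert a.equals(b)

    def test_no_mirnas_gives_empty_table(self, panel8):
        spec = PlantSpec(300, planted=(), rng_seed=3)
        rec, _ = make_transcript_with_planted_sites(spec, panel8)
        assert predict_all([rec], []).empty

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            AlignmentParams(match_score=1.0, wobble_score=2.0)
        with pytest.raises(ValueError):
            AlignmentParams(gap_open=-1.0, gap_extend=-4.0)
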
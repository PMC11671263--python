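"""Six-frame ORF scanning, hexamer coding scores, and ORF selection."""

import numpy as np
import pytest

from isocurl._util import random_dna, revcomp
from isocurl.io import Transcript
from isocurl.orf import (HexamerModel, ORFRecord, scan_orfs, score_orf,
                         select_orfs, train_coding_model)
from isocurl.synthetic import SimConfig, biased_codon_seq, generate_coding_training

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_orfs(seq, min_aa):
    """Independent enumeration from first principles: every in-frame ATG
    that directly follows the nearest upstream stop (no ATG in between),
    plus edge-runs without an upstream stop, extended to the next stop
    or the transcript edge."""
    out = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        n = len(s)
        for f in range(3):
            codon_pos = list(range(f, n - 2, 3))
            stops = [p for p in codon_pos if s[p:p + 3] in STOPS]
            starts = []
            # edge run: anything before the first stop reaches the 5' edge
            first_stop = stops[0] if stops else None
            if first_stop is None or first_stop > f:
                starts.append(f)
            for p in codon_pos:
                if s[p:p + 3] != "ATG":
                    continue
                prev_stops = [q for q in stops if q < p]
                if not prev_stops:
                    continue  # run reaches the edge: the longer edge ORF wins
                q = prev_stops[-1]
                between = [r for r in codon_pos
                           if q < r < p and (s[r:r + 3] == "ATG")]
                if not between:
                    starts.append(p)
            for p in starts:
                nxt = [q for q in stops if q >= p]
                end = (nxt[0] + 3) if nxt else f + 3 * ((n - f) // 3)
                if end <= p:
                    continue
                sub = s[p:end]
                has_stop = sub[-3:] in STOPS
                aa = (end - p) // 3 - (1 if has_stop else 0)
                if aa < min_aa:
                    continue
                if strand == "+":
                    lo, hi = p, end
                else:
                    lo, hi = n - end, n - p
                has_start = sub[:3] == "ATG"
                completeness = {(True, True): "complete", (False, True): "5prime_partial",
                                (True, False): "3prime_partial",
                                (False, False): "internal"}[(has_start, has_stop)]
                out.append((lo, hi, strand, completeness, aa))
    return sorted(out)


class TestScanOrfs:
    def test_complete_orf_construct(self, rng):
        body = biased_codon_seq(rng, 300)
        seq = "ATG" + body + "TAA"
        recs = scan_orfs(Transcript("t", seq), min_aa=100)
        plus = [r for r in recs if r.strand == "+" and r.completeness == "complete"]
        [rec] = plus
        assert (rec.start, rec.end) == (0, len(seq))
        assert rec.protein_length == 301

    def test_short_random_sequence_yields_nothing(self, rng):
        assert scan_orfs(Transcript("t", random_dna(rng, 200)), min_aa=100) == []

    def test_three_prime_truncation(self, rng):
        seq = "C" * 31 + "TGA" + "ATG" + biased_codon_seq(rng, 150)  # no stop after
        recs = [r for r in scan_orfs(Transcript("t", seq), min_aa=100)
                if r.strand == "+"]
        assert any(r.completeness == "3prime_partial" for r in recs)

    def test_five_prime_truncation(self, rng):
        # run reaches the 5' edge without an ATG-free prefix: partial ORF
        seq = biased_codon_seq(rng, 150).replace("ATG", "CCC") + "TAA" + "G" * 40
        recs = [r for r in scan_orfs(Transcript("t", seq), min_aa=100)
                if r.strand == "+" and r.frame == 0]
        assert recs and recs[0].completeness == "5prime_partial"
        assert recs[0].start == 0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            seq = random_dna(rng, int(rng.integers(150, 1000)))
            got = sorted((r.start, r.end, r.strand, r.completeness, r.protein_length)
                         for r in scan_orfs(Transcript("t", seq), min_aa=20))
            assert got == brute_force_orfs(seq, 20)

    def test_min_aa_validation(self):
        with pytest.raises(ValueError):
            scan_orfs(Transcript("t", "ACGT"), min_aa=0)


class TestHexamerModel:
    def test_matched_distributions_give_zero_table(self):
        # period-4 sequences sized so coding (in-frame) and background
        # (position-free) hexamer counts coincide exactly
        background = ("ACGT" * 12)[:45]   # 40 hexamers, 10 per distinct hexamer
        coding = ("ACGT" * 31)[:123]      # 40 in-frame hexamers, 10 each
        model = train_coding_model([coding], [background])
        assert np.allclose(model.table, 0.0)

    def test_trained_model_separates_coding_from_background(self):
        cfg = SimConfig(seed=9)
        coding, background = generate_coding_training(cfg)
        model = train_coding_model(coding[:80], background[:80])
        cod_scores = [score_orf(s, model) for s in coding[80:]]
        bg_scores = [score_orf(s, model) for s in background[80:]]
        assert np.mean([s > 0 for s in cod_scores]) >= 0.95
        assert np.mean([s <= 0 for s in bg_scores]) >= 0.95

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_coding_model([], ["ACGTACGT"])


class TestScoreOrf:
    def test_zero_model_scores_zero(self):
        model = HexamerModel(np.zeros(4096))
        assert score_orf("ATGGCATTACAA", model) == 0.0

    def test_single_hexamer_identity(self):
        table = np.zeros(4096)
        idx = 0
        for b in "ACGTAA":
            idx = idx * 4 + "ACGT".index(b)
        table[idx] = 1.7
        assert score_orf("ACGTAA", HexamerModel(table)) == pytest.approx(1.7)

    def test_mean_over_in_frame_hexamers(self):
        rng = np.random.default_rng(5)
        table = rng.normal(size=4096)
        seq = "ACGTAAGGCTACGGA"  # 15 nt -> hexamers at 0, 3, 6, 9
        def idx(h):
            v = 0
            for b in h:
                v = v * 4 + "ACGT".index(b)
            return v
        expected = np.mean([table[idx(seq[i:i + 6])] for i in (0, 3, 6, 9)])
        assert score_orf(seq, HexamerModel(table)) == pytest.approx(expected)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            score_orf("ACGTA", HexamerModel(np.zeros(4096)))


class TestSelectOrfs:
    @pytest.fixture
    def model(self):
        cfg = SimConfig(seed=9)
        coding, background = generate_coding_training(cfg)
        return train_coding_model(coding, background)

    def test_strong_coding_orf_retained(self, rng, model):
        seq = random_dna(rng, 90) + "TAAATG" + biased_codon_seq(rng, 200) + \
            "TAA" + random_dna(rng, 60)
        t = Transcript("t", seq)
        kept = select_orfs(t, scan_orfs(t, min_aa=100), model)
        assert any(r.completeness == "complete" and r.coding_score > 0 for r in kept)

    def test_nested_orf_dropped(self, model):
        outer = ORFRecord("t", 0, 900, "+", 0, "complete", 299, 1.0)
        inner = ORFRecord("t", 300, 600, "+", 0, "complete", 99, 1.0)
        rng = np.random.default_rng(8)
        t = Transcript("t", ("ATG" + biased_codon_seq(rng, 298) + "TAA")[:900])
        kept = select_orfs(t, [outer, inner], model)
        assert [r.start for r in kept] == [0]

    def test_negative_score_dropped(self, rng, model):
        seq = random_dna(rng, 500)
        t = Transcript("t", seq)
        cands = scan_orfs(t, min_aa=30)
        kept = select_orfs(t, cands, model)
        assert all(r.coding_score > 0 for r in kept)

    def test_selection_is_idempotent(self, rng, model):
        seq = random_dna(rng, 90) + "TAAATG" + biased_codon_seq(rng, 150) + \
            "TAA" + random_dna(rng, 400)
        t = Transcript("t", seq)
        once = select_orfs(t, scan_orfs(t, min_aa=30), model)
        twice = select_orfs(t, list(once), model)
        assert [(r.start, r.end, r.strand) for r in twice] == \
            [(r.start, r.end, r.strand) for r in once]


class TestCompletenessTruth:
    def test_planted_truncations_classified_exactly(self, rng):
        body = biased_codon_seq(rng, 160)  # 480 nt, stop-free in frame
        utr5 = random_dna(rng, 50)
        utr3 = random_dna(rng, 50)
        # planted CDS occupies [53, 539) of the full transcript
        full = utr5 + "TAA" + "ATG" + body + "TGA" + utr3
        cases = [
            ("complete", full, 53, 539),
            # cut inside the CDS from the 5' side: ATG lost, run hits the edge
            ("5prime_partial", ("ATG" + body)[30:] + "TGA" + utr3, 0, 456),
            # cut from the 3' side: stop lost
            ("3prime_partial", utr5 + "TAA" + "ATG" + body[:150], 53, 206),
        ]
        for expected, seq, start, end in cases:
            recs = scan_orfs(Transcript("t", seq), min_aa=40)
            match = [r for r in recs if r.strand == "+"
                     and (r.start, r.end) == (start, end)]
            assert match and match[0].completeness == expected, (expected, recs)
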
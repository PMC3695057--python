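
import numpy as np
import pandas as pd
import pytest

from mirhub.promoter import (
    CountMatrix,
    PromoterRegion,
    TransfacParseError,
    build_pwm,
    extract_promoters,
    hits_to_bed,
    parse_transfac,
    parse_transfac_records,
    scan_promoter,
    score_pvalue_table,
    write_transfac,
)
from mirhub.seq import revcomp

from conftest import random_dna

SIMPLE = """ID M00001
P0      A      C      G      T
01      10     0      0      0
02      0      10     0      0
XX
//
"""


def enumerate_tail(pwm, s):
    """Brute-force P(score >= s) over all 4^w background words."""
    scores = np.zeros(1)
    for i in range(pwm.width):
        scores = (scores[:, None] + pwm.log_odds[i][None, :]).ravel()
    probs = np.ones_like(scores)
    for i in range(pwm.width):
        probs *= 0.25  # uniform background per position
    return float(probs[scores >= s].sum())


class TestTransfacParsing:
    def test_simple_matrix(self):
        cm = parse_transfac(SIMPLE)
        assert cm.motif_id == "M00001"
        assert cm.width == 2
        assert cm.consensus == "AC"

    def test_round_trip(self, tmp_path, rng):
        cm = CountMatrix("RT1", rng.integers(0, 30, size=(6, 4)).astype(float))
        path = tmp_path / "m.transfac"
        write_transfac(cm, path)
        back = parse_transfac(path.read_text())
        assert back.motif_id == "RT1"
        assert np.allclose(back.counts, cm.counts)

    def test_spacing_variants_parse_identically(self):
        tabbed = SIMPLE.replace("      ", "\t")
        squeezed = "\n".join(" ".join(line.split()) for line in SIMPLE.splitlines())
        for variant in (tabbed, squeezed):
            cm = parse_transfac(variant)
            assert np.allclose(cm.counts, parse_transfac(SIMPLE).counts)

    def test_malformed_row_reports_line(self):
        bad = SIMPLE.replace("02      0      10     0      0", "02  0  x  0  0")
        with pytest.raises(TransfacParseError, match="line 4"):
            parse_transfac(bad)

    def test_negative_count_rejected(self):
        bad = SIMPLE.replace("01      10     0      0      0",
                             "01      -1     0      0      0")
        with pytest.raises(TransfacParseError, match="negative"):
            parse_transfac(bad)

    def test_multiple_records(self):
        cms = parse_transfac_records(SIMPLE + SIMPLE.replace("M00001", "M00002"))
        assert [c.motif_id for c in cms] == ["M00001", "M00002"]

    def test_acgt_column_reordering(self):
        permuted = (
            "ID M1\nP0 T G C A\n01 1 2 3 4\nXX\n//\n"
        )
        cm = parse_transfac(permuted)
        assert cm.counts.tolist() == [[4.0, 3.0, 2.0, 1.0]]


class TestBuildPwm:
    def test_uniform_counts_give_zero_log_odds(self):
        cm = CountMatrix("u", np.full((3, 4), 5.0))
        pwm = build_pwm(cm, pseudocount=0.0)
        assert np.allclose(pwm.log_odds, 0.0)

    def test_hand_computed_cell(self):
        cm = CountMatrix("h", np.array([[10.0, 0.0, 0.0, 0.0]]))
        pwm = build_pwm(cm, pseudocount=0.25)
        # log2((10.25/11)/0.25)
        assert pwm.log_odds[0, 0] == pytest.approx(1.898, abs=1e-3)

    def test_count_scaling_invariance_without_pseudocount(self):
        cm = CountMatrix("s", np.array([[3.0, 1.0, 5.0, 1.0], [2.0, 2.0, 4.0, 2.0]]))
        scaled = CountMatrix("s", cm.counts * 10)
        a = build_pwm(cm, pseudocount=0.0)
        b = build_pwm(scaled, pseudocount=0.0)
        assert np.allclose(a.log_odds, b.log_odds)

    def test_bad_background_rejected(self):
        cm = CountMatrix("b", np.full((2, 4), 1.0))
        with pytest.raises(ValueError):
            build_pwm(cm, background=[0.5, 0.5, 0.0, 0.0])


class TestScoreTail:
    def test_degenerate_all_zero_pwm(self):
        cm = CountMatrix("z", np.full((4, 4), 2.0))
        pwm = build_pwm(cm, pseudocount=0.0)
        tail = score_pvalue_table(pwm)
        assert tail.tail(0.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("width", [4, 5, 6, 7, 8])
    def test_dp_matches_enumeration(self, width):
        rng = np.random.default_rng(width)
        cm = CountMatrix("r", rng.integers(0, 25, size=(width, 4)) + 1.0)
        pwm = build_pwm(cm)
        bw = 0.01
        tail = score_pvalue_table(pwm, bin_width=bw)
        margin = width * bw
        for s in np.linspace(pwm.log_odds.min(axis=1).sum(), pwm.max_score, 25):
            dp = tail.tail(s)
            assert enumerate_tail(pwm, s + margin) - 1e-12 <= dp
            assert dp <= enumerate_tail(pwm, s - margin) + 1e-12

    def test_survival_function_shape(self, rich_pwm):
        tail = rich_pwm.score_tail
        assert tail.tail(-1e9) == 1.0
        assert tail.tail(rich_pwm.max_score + 1.0) == 0.0
        cum = tail.tail_cum
        assert (np.diff(cum) <= 1e-15).all()

    def test_bin_overflow_guard(self):
        cm = CountMatrix("w", np.array([[50.0, 1.0, 1.0, 1.0]] * 2))
        pwm = build_pwm(cm)
        with pytest.raises(ValueError, match="bin_width"):
            score_pvalue_table(pwm, bin_width=1e-9, max_bins=1000)


class TestExtractPromoters:
    @pytest.fixture
    def genome(self, rng):
        return {"chr1": random_dna(rng, 5000)}

    def test_plus_strand_interval(self, genome):
        tss = pd.DataFrame(
            {"id": ["p"], "chrom": ["chr1"], "strand": ["+"], "tss": [2000]}
        )
        (prom,) = extract_promoters(tss, genome)
        assert (prom.start, prom.end) == (1000, 2500)
        assert prom.sequence == genome["chr1"][1000:2500]
        assert len(prom.sequence) == 1500

    def test_minus_strand_interval_and_revcomp(self, genome):
        # covered bases t-499 .. t+1000 inclusive, reverse-complemented
        tss = pd.DataFrame(
            {"id": ["m"], "chrom": ["chr1"], "strand": ["-"], "tss": [2000]}
        )
        (prom,) = extract_promoters(tss, genome)
        assert (prom.start, prom.end) == (1501, 3001)
        assert prom.sequence == revcomp(genome["chr1"][1501:3001])

    def test_single_base_window(self, genome):
        tss = pd.DataFrame(
            {"id": ["s"], "chrom": ["chr1"], "strand": ["+"], "tss": [100]}
        )
        (prom,) = extract_promoters(tss, genome, upstream=0, downstream=1)
        assert prom.sequence == genome["chr1"][100]

    def test_truncation_recorded(self, genome):
        tss = pd.DataFrame(
            {"id": ["t"], "chrom": ["chr1"], "strand": ["+"], "tss": [100]}
        )
        (prom,) = extract_promoters(tss, genome)
        assert prom.truncated
        assert prom.start == 0
        assert len(prom.sequence) == 600

    def test_unknown_chromosome_rejected(self, genome):
        tss = pd.DataFrame(
            {"id": ["x"], "chrom": ["chrZ"], "strand": ["+"], "tss": [100]}
        )
        with pytest.raises(KeyError):
            extract_promoters(tss, genome)


class TestScanPromoter:
    def test_planted_consensus_found(self, rich_pwm, rng):
        seq = random_dna(rng, 300)
        planted = seq[:120] + rich_pwm.consensus + seq[120 + rich_pwm.width:]
        prom = PromoterRegion("p", "chr1", "+", 0, len(planted), planted)
        hits = scan_promoter(rich_pwm, prom)
        assert any(h.offset == 120 and h.strand == "+" for h in hits)

    def test_uniform_pwm_no_hits(self):
        cm = CountMatrix("u", np.full((6, 4), 3.0))
        pwm = build_pwm(cm, pseudocount=0.0)
        score_pvalue_table(pwm)
        prom = PromoterRegion("p", "chr1", "+", 0, 100, "ACGT" * 25)
        assert scan_promoter(pwm, prom) == []

    def test_minus_orientation_hit(self, rich_pwm, rng):
        seq = random_dna(rng, 300)
        word = revcomp(rich_pwm.consensus)
        planted = seq[:77] + word + seq[77 + rich_pwm.width:]
        prom = PromoterRegion("p", "chr1", "+", 0, len(planted), planted)
        hits = scan_promoter(rich_pwm, prom)
        assert any(h.offset == 77 and h.strand == "-" for h in hits)

    def test_mirror_symmetry(self, rich_pwm, rng):
        seq = random_dna(rng, 200)
        planted = seq[:50] + rich_pwm.consensus + seq[50 + rich_pwm.width:]
        fwd = scan_promoter(
            rich_pwm, PromoterRegion("f", "c", "+", 0, len(planted), planted)
        )
        rc = revcomp(planted)
        rev = scan_promoter(
            rich_pwm, PromoterRegion("r", "c", "+", 0, len(rc), rc)
        )
        w = rich_pwm.width
        mirrored = sorted(
            (len(planted) - w - h.offset, "-" if h.strand == "+" else "+",
             round(h.score, 9))
            for h in fwd
        )
        got = sorted((h.offset, h.strand, round(h.score, 9)) for h in rev)
        assert got == mirrored

    def test_n_windows_skipped(self, rich_pwm):
        seq = "N" * 50 + rich_pwm.consensus + "N" * 50
        prom = PromoterRegion("p", "c", "+", 0, len(seq), seq)
        hits = scan_promoter(rich_pwm, prom)
        assert [h.offset for h in hits if h.strand == "+"] == [50]

    def test_short_promoter_empty(self, rich_pwm):
        prom = PromoterRegion("p", "c", "+", 0, 4, "ACGT")
        assert scan_promoter(rich_pwm, prom) == []

    def test_uncalibrated_pwm_rejected(self):
        cm = CountMatrix("u", np.full((4, 4), 3.0))
        pwm = build_pwm(cm)
        prom = PromoterRegion("p", "c", "+", 0, 40, "ACGT" * 10)
        with pytest.raises(ValueError, match="calibrat"):
            scan_promoter(pwm, prom)

    def test_false_hit_rate_on_random_sequence(self, rich_pwm):
        # empirical hit count on random background matches the calibrated
        # per-window hit probability (the largest tail value below p_max;
        # the score distribution is discrete, so this sharpens the naive
        # windows * p_max bound) within Poisson tolerance
        rng = np.random.default_rng(123)
        p_max, total_hits, total_windows = 1e-3, 0, 0
        for i in range(100):
            seq = random_dna(rng, 500)
            prom = PromoterRegion(f"p{i}", "c", "+", 0, 500, seq)
            hits = scan_promoter(rich_pwm, prom, p_max=p_max)
            total_hits += len(hits)
            total_windows += 2 * (500 - rich_pwm.width + 1)
        cum = rich_pwm.score_tail.tail_cum
        eligible = cum[cum < p_max]
        per_window = float(eligible.max()) if eligible.size else 0.0
        expected = total_windows * per_window
        assert expected <= total_windows * p_max
        assert abs(total_hits - expected) < 4 * np.sqrt(expected) + 2

    def test_bed_output_coordinates(self, rich_pwm, tmp_path, rng):
        seq = random_dna(rng, 200)
        planted = seq[:30] + rich_pwm.consensus + seq[30 + rich_pwm.width:]
        prom = PromoterRegion("p", "chr9", "+", 1000, 1200, planted)
        hits = scan_promoter(rich_pwm, prom)
        path = tmp_path / "hits.bed"
        hits_to_bed(hits, {"p": prom}, {rich_pwm.motif_id: rich_pwm}, path)
        line = path.read_text().splitlines()[0].split("\t")
        assert line[0] == "chr9"
        assert int(line[1]) == 1030
        assert int(line[2]) == 1030 + rich_pwm.width
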
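"""PWM construction, DP p-values vs enumeration, scanning, CpG retention."""

from itertools import product

import numpy as np
import pytest

from cpgprofiler import motif_scan as msc
from cpgprofiler.data_io import PFMRecord, PromoterRegion
from cpgprofiler.synthetic_data import synthetic_pfms

_RC = str.maketrans("ACGT", "TGCA")


def _random_pfm(rng, width):
    counts = rng.integers(0, 30, size=(4, width)).astype(float)
    counts[rng.integers(0, 4), :] += 1  # at least one positive per column
    return PFMRecord(motif_id="R", motif_name="rand", counts=counts)


def _enum_pvalue(pwm, threshold_bits, granularity=1000):
    """Oracle: exhaustive 4^w enumeration on the same integer grid."""
    ilo = np.rint(pwm.logodds * granularity).astype(int)
    t = int(np.rint(threshold_bits * granularity))
    total = 0.0
    for word in product(range(4), repeat=pwm.width):
        s = sum(ilo[b, j] for j, b in enumerate(word))
        if s >= t:
            total += np.prod([pwm.background[b] for b in word])
    return total


class TestPfmToPwm:
    def test_uniform_column_zero_logodds(self):
        pfm = PFMRecord("M", "m", np.array([[1.0], [1], [1], [1]]))
        pwm = msc.pfm_to_pwm(pfm)
        np.testing.assert_allclose(pwm.logodds[:, 0], 0.0, atol=1e-12)

    def test_dominant_base_one_bit(self):
        pfm = PFMRecord("M", "m", np.array([[3.0], [1], [1], [1]]))
        pwm = msc.pfm_to_pwm(pfm, pseudocount=1e-9)
        assert pwm.logodds[0, 0] == pytest.approx(np.log2(0.5 / 0.25), abs=1e-6)

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        pwm = msc.pfm_to_pwm(_random_pfm(rng, 5))
        np.testing.assert_allclose(pwm.probs.sum(axis=0), 1.0, atol=1e-9)

    def test_invalid_inputs_rejected(self):
        pfm = PFMRecord("M", "m", np.ones((4, 2)))
        with pytest.raises(ValueError):
            msc.pfm_to_pwm(pfm, pseudocount=0.0)
        with pytest.raises(ValueError):
            msc.pfm_to_pwm(pfm, background=np.array([0.5, 0.5, 0.0, 0.0]))


class TestScorePvalue:
    def test_width_one_unique_best_base(self):
        pfm = PFMRecord("M", "m", np.array([[10.0], [1], [1], [1]]))
        pwm = msc.pfm_to_pwm(pfm)
        assert msc.score_pvalue(pwm, pwm.max_score) == pytest.approx(0.25)

    def test_threshold_at_or_below_min_is_one(self):
        pfm = PFMRecord("M", "m", np.array([[10.0, 1], [1, 10], [1, 1], [1, 1]]))
        pwm = msc.pfm_to_pwm(pfm)
        assert msc.score_pvalue(pwm, pwm.min_score) == 1.0
        assert msc.score_pvalue(pwm, pwm.min_score - 5) == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_dp_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        pwm = msc.pfm_to_pwm(_random_pfm(rng, int(rng.integers(2, 7))))
        for frac in (0.2, 0.5, 0.9):
            t = pwm.min_score + frac * (pwm.max_score - pwm.min_score)
            assert msc.score_pvalue(pwm, t) == pytest.approx(_enum_pvalue(pwm, t), abs=1e-12)

    def test_p_monotone_in_threshold(self):
        rng = np.random.default_rng(42)
        pwm = msc.pfm_to_pwm(_random_pfm(rng, 5))
        ts = np.linspace(pwm.min_score, pwm.max_score, 30)
        ps = [msc.score_pvalue(pwm, t) for t in ts]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


def _embed(rng, consensus, offset, length=300):
    bg = "".join(rng.choice(list("ACGT"), length))
    return bg[:offset] + consensus + bg[offset:]


class TestScanSequence:
    def test_planted_consensus_found_at_offset(self):
        rng = np.random.default_rng(1)
        pwm = msc.pfm_to_pwm(synthetic_pfms()[0])
        seq = _embed(rng, pwm.consensus, 50)
        region = PromoterRegion(name="r", sequence=seq)
        hits = msc.scan_sequence(pwm, region, p_threshold=1e-4)
        assert any(h.start == 50 and h.strand == "+" for h in hits)

    def test_strand_symmetry_on_reverse_complement(self):
        rng = np.random.default_rng(2)
        pwm = msc.pfm_to_pwm(synthetic_pfms()[0])
        seq = _embed(rng, pwm.consensus, 50)
        rc = seq.translate(_RC)[::-1]
        fwd = msc.scan_sequence(pwm, PromoterRegion(name="f", sequence=seq), 1e-3)
        rev = msc.scan_sequence(pwm, PromoterRegion(name="r", sequence=rc), 1e-3)
        L = len(seq)
        mirror = sorted((L - h.end, "-" if h.strand == "+" else "+") for h in fwd)
        assert mirror == sorted((h.start, h.strand) for h in rev)

    def test_zero_threshold_gives_no_hits(self):
        pwm = msc.pfm_to_pwm(synthetic_pfms()[0])
        region = PromoterRegion(name="r", sequence="ACGT" * 50)
        assert msc.scan_sequence(pwm, region, p_threshold=0.0) == []

    def test_sequence_shorter_than_motif(self):
        pwm = msc.pfm_to_pwm(synthetic_pfms()[0])
        assert msc.scan_sequence(pwm, PromoterRegion(name="r", sequence="ACG")) == []

    def test_n_positions_never_match(self):
        pwm = msc.pfm_to_pwm(synthetic_pfms()[0])
        seq = pwm.consensus.replace("C", "N", 1) + "A" * 20
        hits = msc.scan_sequence(pwm, PromoterRegion(name="r", sequence=seq), p_threshold=1.0)
        assert all(h.start != 0 for h in hits)

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_recall_in_random_background(self, seed):
        rng = np.random.default_rng(seed)
        pwm = msc.pfm_to_pwm(synthetic_pfms()[0])
        assert msc.information_content(pwm) >= 10
        offset = int(rng.integers(0, 900))
        seq = _embed(rng, pwm.consensus, offset, length=1000)
        hits = msc.scan_sequence(pwm, PromoterRegion(name="r", sequence=seq), 1e-4)
        assert any(h.start == offset and h.strand == "+" for h in hits)


class TestCpGRetention:
    def _hit(self, start, end, cpgs):
        return msc.MotifHit("M", "m", "r", start, end, "+", 5.0, 1e-5, cpgs)

    def test_contained_cpg_retained(self):
        region = PromoterRegion(name="r", sequence="A" * 12 + "CG" + "A" * 10)
        pwm = msc.pfm_to_pwm(synthetic_pfms()[1])
        hits = msc.scan_sequence(pwm, region, p_threshold=1.0)
        h10 = [h for h in hits if h.start == 10][0]  # [10,17) contains CpG at 12
        assert h10.contained_cpgs == [0]

    def test_boundary_g_outside_drops_under_containment(self):
        # CpG C at 17: hit [10,18) holds C but its G at 18 falls outside
        region = PromoterRegion(name="r", sequence="A" * 17 + "CG" + "A" * 10)
        contain = msc._contained_cpgs(region, 10, 18, "contain")
        any_mode = msc._contained_cpgs(region, 10, 18, "any")
        assert contain == [] and any_mode == [0]

    def test_retain_filters_and_preserves_order(self):
        hits = [self._hit(0, 8, [1]), self._hit(3, 11, []), self._hit(5, 13, [2])]
        kept = msc.retain_cpg_overlapping(hits)
        assert [h.start for h in kept] == [0, 5]

    def test_region_without_cpgs_retains_nothing(self):
        region = PromoterRegion(name="r", sequence="ATATAT" * 10)
        pwm = msc.pfm_to_pwm(synthetic_pfms()[0])
        hits = msc.scan_sequence(pwm, region, p_threshold=1.0)
        assert msc.retain_cpg_overlapping(hits) == []
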
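"""Copy-number gain timing, WGD classification and the age regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from clonehist import gaintiming as gt
from clonehist.readfilter import SampleProfile


class TestAssignMultiplicity:
    @pytest.mark.parametrize(
        "alt,total,purity,cnt,expected",
        [
            (15, 30, 1.0, 4, 2),   # VAF 0.5 matches two of four copies
            (7, 30, 1.0, 4, 1),
            (30, 30, 1.0, 2, 2),   # 2+0: VAF 1 only consistent with both copies
        ],
    )
    def test_hand_cases(self, alt, total, purity, cnt, expected):
        assert gt.assign_multiplicity(alt, total, purity, cnt)[0] == expected

    def test_zero_depth_unassigned(self):
        assert gt.assign_multiplicity(0, 0, 1.0, 4)[0] == 0

    def test_tie_goes_to_single_copy(self):
        # alt=0 gives equal... not equal; construct exact tie: total=0 handled,
        # use symmetric point where likelihoods match only approximately is not
        # a tie; instead verify the strict-inequality rule via ll2 == ll1 at alt
        # where v2 = 1 - v1 is impossible here, so check boundary behaviour
        # around the decision threshold instead.
        m = gt.assign_multiplicity(np.arange(31), np.full(31, 30), 1.0, 4)
        assert sorted(set(m.tolist())) == [1, 2]
        assert (np.diff(m) >= 0).all()  # single threshold in alt


def _oracle_time(n1, n2, state):
    """Grid maximum-likelihood inversion, independent of the closed form."""
    # expected visible multiplicity-2 fraction at gain time t:
    #   2+2: both parental copies duplicate -> 2t of (2t + 4(1-t)) = t/(2-t)
    #   2+0: one copy duplicated, one lost -> t of (t + 2(1-t)) = t/(2-t)
    #   2+1: one copy duplicated            -> t of (2t + 3(1-t)) = t/(3-t)
    def neg_ll(t):
        p2 = t / (2 - t) if state in ("2+0", "2+2") else t / (3 - t)
        p2 = min(max(p2, 1e-12), 1 - 1e-12)
        return -(n2 * np.log(p2) + n1 * np.log(1 - p2))
    res = minimize_scalar(neg_ll, bounds=(1e-9, 1 - 1e-9), method="bounded",
                          options={"xatol": 1e-12})
    return float(res.x)


class TestSegmentTime:
    def test_no_pre_duplication_evidence(self):
        assert gt.segment_time(40, 0, "2+2", seed=0)["time"] == 0.0

    def test_planted_half_time(self):
        res = gt.segment_time(40, 20, "2+2", seed=0)
        assert res["time"] == pytest.approx(0.5)

    def test_late_gain_truncates_at_one(self):
        assert gt.segment_time(10, 10, "2+1", seed=0)["time"] == pytest.approx(1.0)

    @pytest.mark.parametrize("state", ["2+0", "2+1", "2+2"])
    def test_matches_likelihood_oracle(self, state):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n2 = int(rng.integers(1, 40))
            n1 = int(rng.integers(max(1, n2), 200))
            ours = gt.segment_time(n1, n2, state, seed=1)["time"]
            oracle = _oracle_time(n1, n2, state)
            if ours in (0.0, 1.0):
                assert abs(ours - round(oracle)) < 1e-3 or oracle > 0.99
            else:
                assert ours == pytest.approx(oracle, abs=1e-5)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(n1=st.integers(1, 100), n2=st.integers(1, 100), k=st.floats(0.5, 20),
           state=st.sampled_from(["2+0", "2+1", "2+2"]))
    def test_scale_invariance(self, n1, n2, k, state):
        a = gt.segment_time(n1, n2, state, n_boot=2, seed=0)["time"]
        b = gt.segment_time(n1 * k, n2 * k, state, n_boot=2, seed=0)["time"]
        assert a == pytest.approx(b)

    def test_ci_contains_point_and_eligibility(self):
        res = gt.segment_time(400, 100, "2+2", seed=2)
        assert res["ci_low"] <= res["time"] <= res["ci_high"]
        assert res["eligible"]
        tiny = gt.segment_time(3, 2, "2+2", seed=2)
        assert not tiny["eligible"]  # wide CI at 5 mutations

    def test_untimeable_state_rejected(self):
        with pytest.raises(ValueError, match="3\\+2"):
            gt.segment_time(10, 5, "3+2")


def _timed_frame(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "major", "minor",
                                     "n_mult1", "n_mult2", "eligible"])
    df["state"] = df["major"].astype(str) + "+" + df["minor"].astype(str)
    return df


class TestPreDupBurden:
    def test_eq3_hand_example(self):
        # pre=10; totals on 2+1 & 2+0 = 30; totals over all eligible = 60
        timed = _timed_frame([
            ("1", 1, 100, 2, 2, 25, 5, True),
            ("2", 1, 100, 2, 1, 18, 2, True),
            ("3", 1, 100, 2, 0, 7, 3, True),
        ])
        est = gt.pre_dup_burden(timed, genome_length=300)
        assert est.num_pre_dup_subs == 10
        assert est.num_total_subs_21_20 == 30
        assert est.num_total_subs_22_21_20 == 60
        assert est.cn_adjusted_burden == pytest.approx(15.0)

    def test_pure_22_has_no_adjustment(self):
        timed = _timed_frame([("1", 1, 100, 2, 2, 30, 10, True)])
        est = gt.pre_dup_burden(timed, genome_length=100)
        assert est.cn_adjusted_burden == est.num_pre_dup_subs == 10

    def test_extrapolation_doubles(self):
        timed = _timed_frame([
            ("1", 1, 50, 2, 2, 25, 5, True),
            ("2", 1, 50, 2, 1, 18, 2, True),
            ("3", 1, 50, 2, 0, 7, 3, True),
        ])
        est = gt.pre_dup_burden(timed, genome_length=300)
        assert est.genome_wide_burden == pytest.approx(2 * est.cn_adjusted_burden)

    def test_subdivision_invariance(self):
        whole = _timed_frame([("1", 1, 200, 2, 2, 40, 10, True)])
        split = _timed_frame([
            ("1", 1, 100, 2, 2, 22, 6, True),
            ("1", 101, 200, 2, 2, 18, 4, True),
        ])
        a = gt.pre_dup_burden(whole, genome_length=400)
        b = gt.pre_dup_burden(split, genome_length=400)
        assert a.cn_adjusted_burden == b.cn_adjusted_burden
        assert a.genome_wide_burden == b.genome_wide_burden

    def test_no_eligible_segments(self):
        timed = _timed_frame([("1", 1, 100, 2, 2, 30, 10, False)])
        assert gt.pre_dup_burden(timed) is None

    def test_oracle_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            rows = []
            for i in range(rng.integers(1, 8)):
                major, minor = rng.choice([(2, 0), (2, 1), (2, 2)])
                rows.append((str(i), 1, int(rng.integers(10, 1000)), major, minor,
                             int(rng.integers(0, 50)), int(rng.integers(1, 20)), True))
            timed = _timed_frame(rows)
            G = int(timed["end"].sum() * 2)
            est = gt.pre_dup_burden(timed, genome_length=G)
            # independent literal evaluation
            pre = sum(r[6] for r in rows)
            tot2120 = sum(r[5] + r[6] for r in rows if (r[3], r[4]) != (2, 2))
            tot_all = sum(r[5] + r[6] for r in rows)
            adj = pre + pre * tot2120 / tot_all
            covered = sum(r[2] for r in rows)
            assert est.cn_adjusted_burden == pytest.approx(adj)
            assert est.genome_wide_burden == pytest.approx(adj * G / covered)


class TestClassifyWGD:
    @pytest.mark.parametrize("psi,h,expected", [
        (2.9, 0.0, True),    # boundary inclusive
        (2.0, 0.4, False),
        (4.0, 0.0, True),
    ])
    def test_rule(self, psi, h, expected):
        profile = SampleProfile(1.0, psi, 30.0, h)
        assert gt.classify_wgd(profile) is expected

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(psi=st.floats(1.0, 6.0), h=st.floats(0.0, 0.9),
           dpsi=st.floats(0.0, 1.0), dh=st.floats(0.0, 0.1))
    def test_monotone(self, psi, h, dpsi, dh):
        base = gt.classify_wgd(SampleProfile(1.0, psi, 1.0, h))
        assert gt.classify_wgd(SampleProfile(1.0, psi + dpsi, 1.0, h)) >= base
        assert gt.classify_wgd(SampleProfile(1.0, psi, 1.0, min(h + dh, 1.0))) >= base


class TestCellDivisions:
    def test_postpubertal_headline(self):
        out = gt.cell_divisions(5.8)
        assert out["point"] == pytest.approx(5.8 / 1.2)
        assert out["divisions"] == 5

    def test_zero(self):
        assert gt.cell_divisions(0.0)["divisions"] == 0

    def test_range_uses_doubled_bounds(self):
        lo, hi = gt.cell_divisions(12.0)["range"]
        assert lo == pytest.approx(12 / 1.4)
        assert hi == pytest.approx(12 / 1.0)

    def test_bad_rate(self):
        with pytest.raises(ValueError):
            gt.cell_divisions(5.0, rate_per_haploid=(0.0, 0.7))


class TestAgeCurve:
    def test_recovers_published_coefficients(self):
        ages = np.arange(0, 61)
        burdens = -0.59 + 574.02 * np.exp(-0.26 * ages)
        fit = gt.fit_age_curve(ages, burdens)
        assert round(fit.a, 2) == -0.59
        assert round(fit.b, 2) == 574.02
        assert round(fit.c, 2) == -0.26

    def test_constant_data_degenerates(self):
        fit = gt.fit_age_curve([0, 10, 20, 30], [7.0, 7.0, 7.0, 7.0])
        assert fit.degenerate
        assert fit.a == pytest.approx(7.0)
        assert fit.b == 0.0

    def test_self_consistency(self):
        ages = np.linspace(0, 40, 25)
        burdens = 10 + 100 * np.exp(-0.5 * ages)
        fit = gt.fit_age_curve(ages, burdens)
        assert round(fit.a, 2) == 10.0
        assert round(fit.b, 2) == 100.0
        assert round(fit.c, 2) == -0.5

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            gt.fit_age_curve([1, 2, 3], [1, 2, 3])


class TestFocalEvents:
    def test_amplification(self):
        segs = pd.DataFrame([{"chrom": "1", "start": 1, "end": 500_000,
                              "major": 9, "minor": 1}])
        out = gt.classify_focal_events(segs, average_ploidy=3.5)
        assert out.loc[0, "call"] == "amplification"

    def test_large_segment_is_gain_tier(self):
        segs = pd.DataFrame([{"chrom": "12", "start": 1, "end": 2_000_000,
                              "major": 10, "minor": 2}])
        out = gt.classify_focal_events(segs, average_ploidy=3.5)
        assert out.loc[0, "call"] == "gain"

    def test_homozygous_deletion(self):
        segs = pd.DataFrame([{"chrom": "9", "start": 1, "end": 300_000,
                              "major": 0, "minor": 0}])
        out = gt.classify_focal_events(segs, average_ploidy=2.0)
        assert out.loc[0, "call"] == "deletion"

    def test_gene_overlap_reported(self):
        segs = pd.DataFrame([{"chrom": "12", "start": 100, "end": 500_000,
                              "major": 11, "minor": 0}])
        genes = pd.DataFrame([{"gene": "KRAS", "chrom": "12", "start": 200, "end": 900}])
        out = gt.classify_focal_events(segs, 2.0, genes)
        assert out.loc[0, "genes"] == "KRAS"


class TestSoftMultiplicity:
    def test_matches_truth_on_clean_mixture(self):
        rng = np.random.default_rng(2)
        n, pi = 3000, 0.2
        is2 = rng.random(n) < pi
        tot = rng.poisson(35, n)
        vaf = np.where(is2, 0.5, 0.25)
        alt = rng.binomial(tot, vaf)
        n1, n2 = gt.soft_multiplicity_counts(alt, tot, 1.0, 4)
        assert n2 / n == pytest.approx(is2.mean(), abs=0.02)

    def test_clonal_scale_recovered(self):
        rng = np.random.default_rng(3)
        groups = []
        for cnt, pi in ((4, 0.2), (3, 0.1), (2, 0.15)):
            n = 800
            is2 = rng.random(n) < pi
            v = np.where(is2, 2, 1) * 0.92 / cnt
            tot = rng.poisson(30, n)
            alt = rng.binomial(tot, v)
            groups.append((alt, tot, cnt))
        s = gt.fit_clonal_scale(groups, 1.0)
        assert s == pytest.approx(0.92, abs=0.02)
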
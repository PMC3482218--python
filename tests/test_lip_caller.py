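import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lipscan.lip_caller import (LipCallParams, call_lips, find_polar_peaks,
                                lips_to_bed, packing_cutoff, summary_json)
from lipscan.profiles import ProfilePair

from conftest import random_track


def make_pair(pr, rho=None, start=4):
    pr = np.asarray(pr, float)
    rho = np.full(len(pr), 0.8) if rho is None else np.asarray(rho, float)
    nums = np.arange(start, start + len(pr))
    return ProfilePair("t", nums, [str(x) for x in nums], ["ALA"] * len(pr),
                       pr, rho)


def brute_force_lips(p, params):
    """Independent enumeration of the LIP definition.

    A LIP is a maximal interval over assigned positions in which every PR
    exceeds theta_base (after bridging at most max_gap sub-base finite
    positions), at least one PR reaches theta_peak, and the packing
    association holds for the configured mode.
    """
    n = len(p.pr)
    mu = np.nanmean(np.where(np.isfinite(p.rho), p.rho, np.nan))
    finite = p.rho[np.isfinite(p.rho)]
    cut = finite.mean() - params.k_sd * finite.std(ddof=0)

    def above(i):
        return not math.isnan(p.pr[i]) and p.pr[i] > params.theta_base

    def is_seed(i):
        return not math.isnan(p.pr[i]) and p.pr[i] >= params.theta_peak

    def extended_ok(a, b):
        """Interval composed of above-base runs bridged by <=max_gap gaps."""
        if not (above(a) and above(b)):
            return False
        gap = 0
        for i in range(a, b + 1):
            if above(i):
                gap = 0
            else:
                if math.isnan(p.pr[i]):
                    return False
                gap += 1
                if gap > params.max_gap:
                    return False
        return True

    def packing_ok(a, b):
        if params.packing_mode == "strict":
            return any(np.isfinite(p.rho[i]) and p.rho[i] < cut
                       for i in range(a, b + 1))
        # wall: overlap with a below-mean basin containing a sub-cutoff dip
        for i in range(a, b + 1):
            if not (np.isfinite(p.rho[i]) and p.rho[i] < mu):
                continue
            lo = i
            while lo > 0 and np.isfinite(p.rho[lo - 1]) and p.rho[lo - 1] < mu:
                lo -= 1
            hi = i
            while hi + 1 < n and np.isfinite(p.rho[hi + 1]) and p.rho[hi + 1] < mu:
                hi += 1
            if any(p.rho[k] < cut for k in range(lo, hi + 1)
                   if np.isfinite(p.rho[k])):
                return True
        return False

    valid = [(a, b) for a in range(n) for b in range(a, n)
             if extended_ok(a, b)]
    maximal = [(a, b) for a, b in valid
               if not any((c <= a and b <= d and (c, d) != (a, b))
                          for c, d in valid)]
    out = [(a, b) for a, b in maximal
           if any(is_seed(i) for i in range(a, b + 1))
           and b - a + 1 >= params.min_len
           and packing_ok(a, b)]
    return sorted(set(out))


class TestPackingCutoff:
    def test_constant_track(self):
        p = make_pair([0.4] * 5, [0.8] * 5)
        co = packing_cutoff(p)
        assert co.cutoff == pytest.approx(0.8)

    def test_two_values(self):
        p = make_pair([0.4, 0.4], [0.9, 0.7])
        co = packing_cutoff(p, k_sd=2.0)
        assert co.mu == pytest.approx(0.8)
        assert co.sigma == pytest.approx(0.1)       # population SD
        assert co.cutoff == pytest.approx(0.6)

    def test_missing_track_rejected(self):
        p = make_pair([0.4, 0.4], [math.nan, math.nan])
        with pytest.raises(ValueError):
            packing_cutoff(p)


class TestCandidates:
    def test_flat_track_no_candidates(self):
        p = make_pair([0.45] * 20)
        assert find_polar_peaks(p) == []

    def test_hand_evaluated_peak(self):
        pr = np.full(30, 0.4)
        pr[12:19] = [0.6, 0.7, 0.9, 0.95, 0.9, 0.7, 0.6]
        p = make_pair(pr, start=0)
        cands = find_polar_peaks(p)
        assert len(cands) == 1
        c = cands[0]
        assert (c.start, c.end) == (12, 18)
        assert c.peak_positions == [14, 15, 16]
        assert c.max_pr == pytest.approx(0.95)

    def test_two_seeds_in_one_run_merge(self):
        pr = np.full(20, 0.4)
        pr[5:15] = 0.6
        pr[7] = 0.9
        pr[12] = 0.85
        p = make_pair(pr, start=0)
        cands = find_polar_peaks(p)
        assert len(cands) == 1
        assert (cands[0].start, cands[0].end) == (5, 14)
        assert cands[0].peak_positions == [7, 12]

    def test_inf_pr_counts_as_seed_and_extension(self):
        pr = np.array([0.4, 0.6, math.inf, 0.6, 0.4])
        p = make_pair(pr, start=0)
        cands = find_polar_peaks(p)
        assert len(cands) == 1
        assert (cands[0].start, cands[0].end) == (1, 3)
        assert math.isinf(cands[0].max_pr)

    def test_missing_terminates_extension(self):
        pr = np.array([0.6, math.nan, 0.9, 0.6, 0.4])
        p = make_pair(pr, start=0)
        cands = find_polar_peaks(p)
        assert len(cands) == 1
        assert (cands[0].start, cands[0].end) == (2, 3)


class TestCalling:
    def test_above_average_packing_rejected(self):
        pr = np.full(20, 0.4)
        pr[8:11] = [0.7, 0.9, 0.7]
        rho = np.linspace(0.7, 0.9, 20)
        rho[8:11] = 0.95          # candidate on densely packed ground
        p = make_pair(pr, rho, start=0)
        passing, records = call_lips(p, return_rejected=True)
        assert passing == []
        assert len(records) == 1 and not records[0].packing_pass

    def test_wall_mode_recovers_basin_wall(self):
        pr = np.full(20, 0.4)
        pr[4:7] = [0.7, 0.9, 0.7]      # candidate at 4..6
        rho = np.full(20, 0.9)
        rho[4:12] = [0.84, 0.82, 0.80, 0.60, 0.40, 0.42, 0.60, 0.84]
        p = make_pair(pr, rho, start=0)
        strict = call_lips(p, LipCallParams(packing_mode="strict"))
        wall = call_lips(p, LipCallParams(packing_mode="wall"))
        assert strict == []
        assert len(wall) == 1
        assert (wall[0].start, wall[0].end) == (4, 6)

    def test_lip_invariants_machine_checked(self):
        rng = np.random.default_rng(0)
        params = LipCallParams()
        for _ in range(30):
            p = random_track(rng)
            for l in call_lips(p, params):
                seg = p.pr[l.start_idx:l.end_idx + 1]
                assert all(v > params.theta_base for v in seg
                           if not math.isnan(v))
                assert any(v >= params.theta_peak for v in seg
                           if not math.isnan(v))
                assert l.packing_pass

    @pytest.mark.parametrize("mode", ["strict", "wall"])
    def test_matches_brute_force_enumeration(self, mode):
        rng = np.random.default_rng(42)
        params = LipCallParams(packing_mode=mode)
        for _ in range(150):
            p = random_track(rng, n=int(rng.integers(10, 50)))
            if not np.isfinite(p.rho).sum() >= 2:
                continue
            got = [(l.start_idx, l.end_idx) for l in call_lips(p, params)]
            assert sorted(got) == brute_force_lips(p, params)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_hypothesis(self, seed):
        rng = np.random.default_rng(seed)
        params = LipCallParams(packing_mode="wall",
                               max_gap=int(rng.integers(0, 2)))
        p = random_track(rng, n=int(rng.integers(10, 40)))
        if np.isfinite(p.rho).sum() < 2:
            return
        got = [(l.start_idx, l.end_idx) for l in call_lips(p, params)]
        assert sorted(got) == brute_force_lips(p, params)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            p = random_track(rng)
            if np.isfinite(p.rho).sum() < 2:
                continue
            n_low = len(call_lips(p, LipCallParams(theta_peak=0.8)))
            n_high = len(call_lips(p, LipCallParams(theta_peak=1.0)))
            assert n_high <= n_low
            n_k2 = len(call_lips(p, LipCallParams(packing_mode="strict",
                                                  k_sd=2.0)))
            n_k3 = len(call_lips(p, LipCallParams(packing_mode="strict",
                                                  k_sd=3.0)))
            assert n_k3 <= n_k2

    def test_idempotent(self):
        p = random_track(np.random.default_rng(3))
        a = [(l.start, l.end) for l in call_lips(p)]
        b = [(l.start, l.end) for l in call_lips(p)]
        assert a == b

    def test_param_validation(self):
        with pytest.raises(ValueError):
            LipCallParams(theta_peak=0.4, theta_base=0.5)
        with pytest.raises(ValueError):
            LipCallParams(k_sd=0.0)
        with pytest.raises(ValueError):
            LipCallParams(packing_mode="loose")


class TestOutputs:
    def test_bed_is_zero_based_half_open(self):
        pr = np.full(10, 0.4)
        pr[3:6] = [0.6, 0.9, 0.6]
        rho = np.full(10, 0.8)
        rho[4] = 0.2
        p = make_pair(pr, rho, start=10)   # author numbers 10..19
        lips = call_lips(p)
        assert len(lips) == 1
        assert (lips[0].start, lips[0].end) == (13, 15)
        bed = lips_to_bed(lips, "prot")
        chrom, s, e, name, score, strand = bed.strip().split("\t")
        # author-inclusive 13..15 <-> 0-based half-open [12, 15)
        assert (chrom, int(s), int(e)) == ("prot", 12, 15)
        assert int(score) == 90

    def test_summary_json_roundtrip(self):
        import json
        p = random_track(np.random.default_rng(5))
        payload = json.loads(summary_json(p, LipCallParams()))
        assert payload["protein_id"] == "rand"
        assert "packing_cutoff" in payload
        assert len(payload["candidates"]) >= len(payload["lips"])
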
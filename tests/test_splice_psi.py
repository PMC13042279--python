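"""PSI arithmetic, event read assignment and the beta-binomial group test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from novapipe import splice_psi
from novapipe._io import revcomp
from novapipe.circ_quant import CountParams
from novapipe.splice_psi import (a3ss_event, compute_psi, count_event_reads,
                                 effective_lengths, event_scaffolds,
                                 filter_events, se_event)


class TestComputePsi:
    def test_boundary_values(self):
        assert compute_psi(0, 10) == 0.0
        assert compute_psi(10, 0) == 1.0
        assert np.isnan(compute_psi(0, 0))

    def test_length_normalised_hand_value(self):
        # I=80 over l_I=2 vs S=20 over l_S=1: (40)/(40+20)
        assert compute_psi(80, 20, 2, 1) == pytest.approx(2 / 3)

    def test_equal_lengths_reduce_to_simple_ratio(self):
        assert compute_psi(30, 10, 5, 5) == pytest.approx(0.75)

    @given(st.integers(0, 1000), st.integers(0, 1000),
           st.floats(0.01, 100), st.integers(1, 20), st.integers(1, 20))
    @settings(max_examples=200, deadline=None)
    def test_scale_invariance(self, i, s, c, l_i, l_s):
        if i + s == 0:
            return
        a = compute_psi(i, s, l_i, l_s)
        b = compute_psi(i * c, s * c, l_i, l_s)
        assert a == pytest.approx(b)
        assert 0.0 <= a <= 1.0


class TestEventReadCounting:
    def _genome(self, n=3000, seed=0):
        rng = np.random.default_rng(seed)
        return {"chrT": "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])}

    def test_inclusion_only_reads_give_zero_skipping(self):
        genome = self._genome()
        ev = se_event("e1", "g1", "chrT", "+", 500, (700, 900), 1100)
        inc, _ = event_scaffolds(ev, genome)
        reads = {"s1": [(sc.sequence[f : f + 150], revcomp(sc.sequence[f : f + 150]))
                        for sc in inc for f in range(0, 40, 5)]}
        counts, _ = count_event_reads(ev, reads, genome)
        assert counts.loc["s1", "S"] == 0
        assert counts.loc["s1", "I"] == len(reads["s1"])

    def test_a3ss_six_nt_window_reads_assigned_to_long_form_only(self):
        """A read whose seam falls inside the 6-nt acceptor window exists only
        in the long-acceptor junction; it must count as inclusion."""
        genome = self._genome(seed=1)
        ev = a3ss_event("e1", "g1", "chrT", "+", donor_end=500,
                        long_acceptor=794, short_acceptor=800)
        inc, skip = event_scaffolds(ev, genome)
        long_reads = [(inc[0].sequence[f : f + 150], inc[0].sequence[f : f + 150])
                      for f in range(0, 50, 3)]
        counts, tally = count_event_reads(ev, {"s1": long_reads}, genome)
        assert counts.loc["s1", "I"] == len(long_reads)
        assert counts.loc["s1", "S"] == 0
        assert tally.ambiguous_form == 0

    def test_simulated_psi_recovered_within_binomial_band(self):
        rng = np.random.default_rng(2)
        genome = self._genome(seed=3)
        ev = se_event("e1", "g1", "chrT", "+", 500, (700, 860), 1100)
        inc, skip = event_scaffolds(ev, genome)
        l_i, l_s = effective_lengths(ev)
        psi = 0.5
        p_read = psi * l_i / (psi * l_i + (1 - psi) * l_s)
        n = 1000
        n_inc = rng.binomial(n, p_read)
        pairs = []
        for count, side in ((n_inc, inc), (n - n_inc, skip)):
            for _ in range(count):
                sc = side[int(rng.integers(len(side)))]
                f = int(rng.integers(0, 51))
                r1 = sc.sequence[f : f + 150]
                pairs.append((r1, revcomp(r1)))
        counts, _ = count_event_reads(ev, {"s1": pairs}, genome)
        est = compute_psi(counts.loc["s1", "I"], counts.loc["s1", "S"], l_i, l_s)
        assert est == pytest.approx(0.5, abs=0.05)


class TestTestEvent:
    @staticmethod
    def _counts(k_wt, n_wt, k_mut, n_mut):
        idx = [f"wt_{i}" for i in range(len(k_wt))] + \
              [f"m_{i}" for i in range(len(k_mut))]
        counts = pd.DataFrame({"I": list(k_wt) + list(k_mut),
                               "S": [n - k for k, n in zip(k_wt, n_wt)] +
                                    [n - k for k, n in zip(k_mut, n_mut)]}, index=idx)
        groups = pd.Series(["wt"] * len(k_wt) + ["mut"] * len(k_mut), index=idx)
        return counts, groups

    def test_identical_groups_are_null(self):
        counts, groups = self._counts([50, 52, 48], [100] * 3, [50, 52, 48], [100] * 3)
        res = splice_psi.test_event(counts, groups, "wt", "mut")
        assert res.dpsi == pytest.approx(0.0)
        assert res.p > 0.9

    def test_group_swap_negates_dpsi_keeps_p(self):
        counts, groups = self._counts([80, 75, 85], [100] * 3, [40, 45, 35], [100] * 3)
        a = splice_psi.test_event(counts, groups, "wt", "mut")
        b = splice_psi.test_event(counts, groups, "mut", "wt")
        assert a.dpsi == pytest.approx(-b.dpsi)
        assert a.p == pytest.approx(b.p, rel=1e-6)

    def test_zero_overdispersion_reduces_to_binomial_lrt(self):
        """With rho pinned at 0 the statistic must equal the closed-form
        binomial LRT computed here independently."""
        counts, groups = self._counts([60, 70, 65], [100] * 3, [40, 45, 50], [100] * 3)
        res = splice_psi.test_event(counts, groups, "wt", "mut", rho_fixed=0.0)

        def ll(k, n):
            p = k / n
            return k * np.log(p) + (n - k) * np.log(1 - p)

        k1, n1, k2, n2 = 195.0, 300.0, 135.0, 300.0
        stat = 2 * (ll(k1, n1) + ll(k2, n2) - ll(k1 + k2, n1 + n2))
        assert res.stat == pytest.approx(stat, abs=1e-6)

    def test_free_overdispersion_matches_binomial_on_binomial_data(self):
        counts, groups = self._counts([60, 61, 59, 60], [100] * 4,
                                      [60, 59, 61, 60], [100] * 4)
        free = splice_psi.test_event(counts, groups, "wt", "mut")
        fixed = splice_psi.test_event(counts, groups, "wt", "mut", rho_fixed=0.0)
        assert free.stat == pytest.approx(fixed.stat, abs=0.05)

    def test_degenerate_all_inclusion_gives_p_one(self):
        counts, groups = self._counts([100] * 3, [100] * 3, [100] * 3, [100] * 3)
        res = splice_psi.test_event(counts, groups, "wt", "mut")
        assert res.p == 1.0

    def test_orientation_wt_minus_mutant(self):
        counts, groups = self._counts([80, 80, 80], [100] * 3, [50, 50, 50], [100] * 3)
        res = splice_psi.test_event(counts, groups, "wt", "mut")
        assert res.dpsi == pytest.approx(0.3, abs=1e-9)


class TestFilterEvents:
    @staticmethod
    def _frame(rows):
        return pd.DataFrame(rows, columns=["event_id", "type", "gene_id",
                                           "IncLevelDifference", "FDR"])

    def test_both_thresholds_required(self):
        df = self._frame([("e1", "SE", "g1", 0.19, 0.04),
                          ("e2", "SE", "g2", 0.25, 0.04),
                          ("e3", "A3SS", "g3", -0.30, 0.06)])
        sig, summary = filter_events(df)
        assert list(sig["event_id"]) == ["e2"]
        assert summary.set_index("type")["n"].to_dict() == {"SE": 1}

    def test_known_passing_subset(self):
        df = self._frame([("e1", "SE", "g1", 0.5, 0.01),
                          ("e2", "RI", "g2", -0.21, 0.05),
                          ("e3", "MXE", "g3", 0.2, 0.05),
                          ("e4", "A5SS", "g4", 0.9, 0.051)])
        sig, summary = filter_events(df)
        assert set(sig["event_id"]) == {"e1", "e2", "e3"}
        assert summary["n"].sum() == len(sig)

    def test_empty_input(self):
        sig, summary = filter_events(self._frame([]))
        assert sig.empty and summary.empty


def test_effective_lengths_jc_and_jcec():
    ev = se_event("e1", "g1", "chrT", "+", 500, (700, 900), 1100)
    l_i, l_s = effective_lengths(ev, read_length=150, min_overhang=8)
    assert (l_i, l_s) == (102, 51)  # two inclusion junctions vs one skip
    l_i2, l_s2 = effective_lengths(ev, read_length=150, min_overhang=8, mode="jcec")
    assert l_i2 == 102 + (200 - 150 + 1) and l_s2 == 51
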
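"""Back-splice scaffolds, split-read calling, counting and filtering."""

import numpy as np
import pandas as pd
import pytest

from novapipe._io import revcomp
from novapipe.circ_quant import (CallParams, CircLocus, CoordinateError,
                                 CountParams, build_scaffold, call_bsj,
                                 count_junction_reads, counts_to_frame,
                                 filter_circ)
from novapipe.synthetic_data import FixtureConfig, SimConfig, make_fixture, simulate_reads


def _random_genome(n, seed, name="chrT"):
    rng = np.random.default_rng(seed)
    return {name: "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])}


class TestBuildScaffold:
    def test_long_circle_takes_terminal_and_initial_100mers(self):
        genome = _random_genome(1000, 1)
        locus = CircLocus("c1", "chrT", 100, 400, "+")
        sc = build_scaffold(locus, genome)
        circ = genome["chrT"][100:400]
        assert len(sc.sequence) == 200 and sc.seam_offset == 100
        assert sc.sequence == circ[-100:] + circ[:100]

    def test_exact_200_circle_is_a_rotation(self):
        genome = _random_genome(1000, 2)
        locus = CircLocus("c1", "chrT", 100, 300, "+")
        sc = build_scaffold(locus, genome)
        circ = genome["chrT"][100:300]
        assert sc.sequence == circ[100:] + circ[:100]
        assert sorted(sc.sequence) == sorted(circ)

    def test_short_circle_tiles_circularly(self):
        """A 60-nt circle must tile to 100 nt per side; checked against a
        hand-built string."""
        genome = _random_genome(1000, 3)
        circ = genome["chrT"][200:260]
        expected_left = (circ * 3)[-100:]
        expected_right = (circ * 3)[:100]
        sc = build_scaffold(CircLocus("c1", "chrT", 200, 260, "+"), genome)
        assert sc.sequence == expected_left + expected_right

    def test_minus_strand_scaffold_is_transcript_oriented(self):
        genome = _random_genome(1000, 4)
        circ_rc = revcomp(genome["chrT"][100:400])
        sc = build_scaffold(CircLocus("c1", "chrT", 100, 400, "-"), genome)
        assert sc.sequence == circ_rc[-100:] + circ_rc[:100]

    def test_locus_outside_contig_raises(self):
        genome = _random_genome(300, 5)
        with pytest.raises(CoordinateError):
            build_scaffold(CircLocus("c1", "chrT", 100, 400, "+"), genome)


class TestCallBsj:
    def test_simulated_circles_recovered_exactly(self, fixture, sim):
        reads, _ = sim
        loci, _ = call_bsj(reads, fixture.genome)
        called = {(l.chrom, l.start, l.end, l.strand) for l in loci}
        truth = {(c.chrom, c.start, c.end, c.strand) for c in fixture.circ_loci}
        assert called == truth

    def test_isoforms_six_nt_apart_yield_two_loci(self, fixture, sim):
        reads, _ = sim
        loci, _ = call_bsj(reads, fixture.genome)
        crh = [l for l in loci if any(
            c.gene_id == "crh-1L" and (l.start, l.end) == (c.start, c.end)
            for c in fixture.circ_loci)]
        assert len(crh) == 2
        assert abs(crh[0].start - crh[1].start) == 6
        assert crh[0].end == crh[1].end

    def test_linear_reads_call_nothing(self):
        genome = _random_genome(2000, 7)
        seq = genome["chrT"]
        reads = {"s1": [(seq[i : i + 150], revcomp(seq[i + 20 : i + 170]))
                        for i in range(0, 1500, 10)]}
        loci, _ = call_bsj(reads, genome)
        assert loci == []

    def test_recovery_rate_over_seeds(self, small_fixture_config):
        """Circles with decent read support should essentially always be
        recovered from noise-free reads."""
        import dataclasses
        recovered = total = 0
        for seed in range(5):
            fx = make_fixture(dataclasses.replace(small_fixture_config, seed=400 + seed))
            reads, truth = simulate_reads(fx, SimConfig(seed=600 + seed))
            loci, _ = call_bsj(reads, fx.genome)
            called = {(l.chrom, l.start, l.end, l.strand) for l in loci}
            for c in fx.circ_loci:
                pooled = sum(truth.circ_unique[(c.circ_id, s)] for s in truth.samples)
                if pooled >= 5:
                    total += 1
                    recovered += (c.chrom, c.start, c.end, c.strand) in called
        assert total > 0 and recovered / total >= 0.95


class TestCountJunctionReads:
    def test_no_reads_gives_zero_counts(self, fixture):
        scaffolds = [build_scaffold(c, fixture.genome) for c in fixture.circ_loci]
        counts, _ = count_junction_reads(scaffolds, {"s1": []})
        assert all(c.raw == 0 and c.unique == 0 for c in counts)

    def test_duplicate_collapse_thirty_reads_ten_copies(self, fixture):
        """30 seam-spanning pairs of which 10 are byte-identical copies of
        one pair must count as 21 unique."""
        sc = build_scaffold(fixture.circ_loci[0], fixture.genome)
        seq = sc.sequence
        pairs = [(seq[f : f + 150], revcomp(seq[f + 20 : f + 170])) for f in range(20)]
        dup = (seq[25 : 175], revcomp(seq[45 : 195]))
        pairs += [dup] * 10
        assert len(pairs) == 30 and len(set(pairs)) == 21
        counts, _ = count_junction_reads([sc], {"s1": pairs})
        by_id = {c.circ_id: c for c in counts}
        assert by_id[sc.circ_id].raw == 30
        assert by_id[sc.circ_id].unique == 21

    def test_noise_free_unique_counts_equal_truth(self, fixture, sim):
        reads, truth = sim
        scaffolds = [build_scaffold(c, fixture.genome) for c in fixture.circ_loci]
        counts, _ = count_junction_reads(scaffolds, reads)
        frame = counts_to_frame(counts, "unique")
        expected = truth.circ_count_frame()
        pd.testing.assert_frame_equal(
            frame.loc[expected.index, expected.columns], expected)

    def test_counting_is_strand_symmetric(self, fixture, sim):
        reads, _ = sim
        sample = next(iter(reads))
        flipped = {sample: [(revcomp(r1), revcomp(r2)) for r1, r2 in reads[sample]]}
        scaffolds = [build_scaffold(c, fixture.genome) for c in fixture.circ_loci]
        a, _ = count_junction_reads(scaffolds, {sample: reads[sample]})
        b, _ = count_junction_reads(scaffolds, flipped)
        assert [(c.circ_id, c.unique) for c in a] == [(c.circ_id, c.unique) for c in b]

    def test_overhang_required_on_both_sides_of_seam(self, fixture):
        sc = build_scaffold(fixture.circ_loci[0], fixture.genome)
        # a read ending 4 nt past the seam: insufficient right overhang
        short_overhang = sc.sequence[0:104][-100:]
        counts, _ = count_junction_reads([sc], {"s1": [(short_overhang, short_overhang)]},
                                         CountParams(min_overhang=8))
        assert counts[0].unique == 0


class TestFilterCirc:
    def test_pooled_threshold_boundary(self):
        df = pd.DataFrame({"s1": [6, 6], "s2": [5, 6]}, index=["a", "b"])
        kept = filter_circ(df, 12)
        assert list(kept.index) == ["b"]  # pooled 11 removed, pooled 12 kept

    def test_mixed_pool_counts(self):
        df = pd.DataFrame({"s1": [5, 12, 100]}, index=["a", "b", "c"])
        assert list(filter_circ(df, 12).index) == ["b", "c"]

    def test_empty_matrix_passes_through(self):
        df = pd.DataFrame(columns=["s1"])
        assert filter_circ(df, 12).empty

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_circ(pd.DataFrame({"s1": [1]}), -1)

    def test_row_order_preserved(self):
        df = pd.DataFrame({"s1": [20, 13, 40]}, index=["z", "a", "m"])
        assert list(filter_circ(df, 12).index) == ["z", "a", "m"]
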
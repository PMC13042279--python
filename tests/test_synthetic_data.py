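"""Generator contracts: determinism, geometry, and recorded ground truth."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from novapipe.circ_quant import build_scaffold
from novapipe.synthetic_data import (ConfigurationError, CtDesign, FixtureConfig,
                                     SimConfig, SurvivalParams, make_fixture,
                                     simulate_ct, simulate_reads, simulate_survival,
                                     simulate_viability, write_fixture, write_reads)


class TestMakeFixture:
    def test_focus_locus_isoform_pair_shares_donor_and_differs_by_offset(self, fixture):
        crh = [c for c in fixture.circ_loci if c.gene_id == "crh-1L"]
        assert len(crh) == 2
        a, b = sorted(crh, key=lambda c: c.length)
        assert a.end == b.end  # shared splice donor
        assert b.start == a.start - 6
        assert {a.length, b.length} == {205, 211}

    def test_no_alt_acceptor_means_one_isoform_per_circ_exon(self):
        cfg = FixtureConfig(seed=5, include_focus_gene=False, n_plain_circ_genes=3,
                            n_shared_genes=0, splice_gene_types=())
        fx = make_fixture(cfg)
        genes = [c.gene_id for c in fx.circ_loci]
        assert len(genes) == len(set(genes)) == 3

    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        paths = []
        for sub in ("a", "b"):
            fx = make_fixture(FixtureConfig(seed=11))
            paths.append(write_fixture(fx, tmp_path / sub))
        for key in paths[0]:
            assert open(paths[0][key], "rb").read() == open(paths[1][key], "rb").read()

    def test_features_fit_inside_contig(self, fixture):
        contig_len = len(fixture.genome["chrI"])
        for m in fixture.models:
            assert 0 <= m.span[0] < m.span[1] <= contig_len
        for c in fixture.circ_loci:
            assert c.end <= contig_len

    def test_too_short_contig_rejected(self):
        with pytest.raises(ConfigurationError, match="too short"):
            make_fixture(FixtureConfig(seed=1, contig_length=500))


class TestSimulateReads:
    def test_truth_counts_match_emission_when_no_duplicates(self, fixture):
        cfg = SimConfig(seed=9, duplicate_fraction=0.0)
        reads, truth = simulate_reads(fixture, cfg)
        total_pairs = sum(len(v) for v in reads.values())
        total_truth = sum(truth.circ_unique.values()) + sum(
            i + s for i, s in truth.event_counts.values())
        assert total_pairs == total_truth

    def test_duplicates_are_byte_identical_extra_pairs(self, fixture):
        cfg = SimConfig(seed=9, duplicate_fraction=0.5)
        reads, truth = simulate_reads(fixture, cfg)
        n_pairs = sum(len(v) for v in reads.values())
        n_unique = sum(len(set(v)) for v in reads.values())
        assert n_pairs > n_unique  # duplicates exist and collapse under set()

    def test_same_seed_gives_identical_fastq(self, fixture, tmp_path):
        outs = []
        for sub in ("a", "b"):
            reads, _ = simulate_reads(fixture, SimConfig(seed=13))
            outs.append(write_reads(reads, tmp_path / sub))
        sample = next(iter(outs[0]))
        for i in (0, 1):
            assert open(outs[0][sample][i], "rb").read() == \
                   open(outs[1][sample][i], "rb").read()

    def test_genotype_effect_doubles_mean_count_over_seeds(self, small_fixture_config):
        fx = make_fixture(small_fixture_config)
        circ = fx.circ_loci[0].circ_id
        ratios = []
        for seed in range(100):
            _, truth = simulate_reads(fx, SimConfig(
                seed=5000 + seed, duplicate_fraction=0.0,
                circ_log2fc={circ: 1.0}))
            cf = truth.circ_count_frame()
            g = truth.genotype_series()
            ratios.append(cf.loc[circ, (g == "nova-1").values].mean()
                          / cf.loc[circ, (g == "wt").values].mean())
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.05)

    def test_psi_converges_at_high_depth(self, small_fixture_config):
        cfg = dataclasses.replace(small_fixture_config, splice_gene_types=("SE",))
        fx = make_fixture(cfg)
        event = next(e for e in fx.events if e.etype == "SE")
        _, truth = simulate_reads(fx, SimConfig(
            seed=77, event_depth=10_000, psi={event.event_id: (0.6, 0.6)}))
        from novapipe.splice_psi import compute_psi, effective_lengths
        l_i, l_s = effective_lengths(event)
        for sample in truth.samples:
            i, s = truth.event_counts[(event.event_id, sample)]
            assert compute_psi(i, s, l_i, l_s) == pytest.approx(0.6, abs=0.02)

    def test_excessive_overhang_rejected(self):
        with pytest.raises(ConfigurationError, match="overhang"):
            SimConfig(seed=1, min_overhang=80, read_length=150)


class TestSimulateSurvival:
    def test_zero_censoring_gives_all_deaths(self):
        df = simulate_survival(50, SurvivalParams(), censor_rate=0.0, seed=3)
        assert (df["event"] == 1).all()
        assert (df["censor_reason"] == "").all()
        assert (df["day"] >= 1).all()

    def test_censored_records_carry_reasons(self):
        df = simulate_survival(200, SurvivalParams(), censor_rate=0.3, seed=3)
        censored = df[df["event"] == 0]
        assert len(censored) > 0
        assert set(censored["censor_reason"]) <= {"rupture", "bagging", "walling"}

    def test_invalid_censor_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_survival(10, SurvivalParams(), censor_rate=1.0, seed=1)

    def test_null_logrank_p_uniform_over_seeds(self):
        """Under equal hazards the log-rank P should be U(0,1) across seeds."""
        from scipy import stats
        from novapipe.pheno_stats import km_logrank
        params = SurvivalParams(scales={"a": 18.0, "b": 18.0})
        ps = []
        for seed in range(500):
            df = simulate_survival(150, params, censor_rate=0.1, seed=10_000 + seed)
            ps.append(km_logrank(df, "a", "b").p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_hazard_ratio_direction_recovered(self):
        """Lower hazard (ratio 0.7) must show as longer mean lifespan in
        nearly every replicate experiment."""
        shape = 4.0
        scale_b = 18.0 * 0.7 ** (-1.0 / shape)
        params = SurvivalParams(shape=shape, scales={"a": 18.0, "b": scale_b})
        hits = 0
        n_seeds = 60
        for seed in range(n_seeds):
            df = simulate_survival(150, params, censor_rate=0.0, seed=20_000 + seed)
            means = df.groupby("group")["day"].mean()
            hits += means["b"] > means["a"]
        assert hits / n_seeds > 0.95


class TestSimulateCt:
    def test_zero_noise_recovers_folds_exactly(self):
        from novapipe.pheno_stats import ddct
        design = CtDesign(targets={"t1": 1.0, "t2": 0.25}, noise_sd=0.0)
        table, truth = simulate_ct(design, seed=4)
        folds = ddct(table, reference_group="wt", housekeeping="cdc-42")
        mut = folds[folds["genotype"] == "nova-1"]
        for gene, expect in truth.items():
            assert mut.loc[mut["gene"] == gene, "fold"].to_numpy() == pytest.approx(expect)

    def test_same_seed_gives_identical_table(self):
        a, _ = simulate_ct(CtDesign(), seed=8)
        b, _ = simulate_ct(CtDesign(), seed=8)
        pd.testing.assert_frame_equal(a, b)

    def test_design_validation(self):
        with pytest.raises(ConfigurationError):
            CtDesign(genotypes=("wt",))
        with pytest.raises(ConfigurationError):
            CtDesign(targets={})


def test_viability_counts_bounded():
    df = simulate_viability(seed=2)
    assert ((df["n_alive"] >= 0) & (df["n_alive"] <= df["n_exposed"])).all()
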
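"""End-to-end orchestration: fixture -> reads -> circRNA quantification ->
differential expression -> splicing PSI -> YCAY motifs -> overlap ->
phenotype statistics, with a content-hash manifest for reproducibility.

Every stage writes plain-text tables under the run directory; the manifest
records the seed, all thresholds and the SHA-256 of every output, so two runs
with the same config and seed are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import circ_quant, diff_expression, integration, motif_ycay, pheno_stats, splice_psi
from .synthetic_data import (CtDesign, Fixture, FixtureConfig, SimConfig,
                             SurvivalParams, make_fixture, simulate_ct,
                             simulate_reads, simulate_survival, simulate_viability,
                             write_fixture, write_reads, write_truth)

ALL_STAGES = ("fixture", "reads", "circ", "de", "psi", "motif", "overlap", "pheno")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Pipeline thresholds (defaulting to the analysis' canonical values) and
    simulation settings."""

    seed: int
    outdir: str
    stages: tuple[str, ...] = ALL_STAGES
    min_junction_reads: int = 12
    lfc: float = 0.5
    alpha: float = 0.05
    use: str = "p"            # classify on raw P ("p") or BH FDR ("fdr")
    fdr: float = 0.05
    dpsi: float = 0.2
    ycay_bins: tuple[int, int] = (20, 60)
    ycay_cut: int = 20
    survival_n: int = 150
    censor_rate: float = 0.1
    fixture: FixtureConfig | None = None
    sim: SimConfig | None = None

    def __post_init__(self) -> None:
        for name in ("min_junction_reads", "lfc", "alpha", "fdr", "dpsi", "ycay_cut"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat key/value YAML config; keys mirror the dataclass
        fields, with ``fixture.*`` and ``sim.*`` nested mappings."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        fixture = raw.pop("fixture", None)
        sim = raw.pop("sim", None)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        cfg = cls(**raw)
        if fixture:
            fixture.setdefault("seed", cfg.seed)
            cfg.fixture = FixtureConfig(**fixture)
        if sim:
            sim.setdefault("seed", cfg.seed + 1)
            cfg.sim = SimConfig(**sim)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and return (and write) the run manifest.

    Stages consume in-memory products of earlier stages; requesting a stage
    whose inputs were not produced raises a :class:`PipelineError` naming the
    missing upstream stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    stage_log: dict[str, dict] = {}

    def need(product: str, upstream: str):
        if product not in state:
            raise PipelineError(f"missing input {product!r}: run stage {upstream!r} first")
        return state[product]

    # wall times go to run.log (excluded from hashing) so the manifest itself
    # is bit-identical across reruns with one seed
    timings: dict[str, float] = {}

    def log_stage(name: str, t0: float, **info):
        timings[name] = round(time.perf_counter() - t0, 3)
        stage_log[name] = dict(info)

    for stage in config.stages:
        t0 = time.perf_counter()
        if stage == "fixture":
            fx_cfg = config.fixture or FixtureConfig(seed=config.seed)
            fixture = make_fixture(fx_cfg)
            state["fixture"] = fixture
            write_fixture(fixture, out / "fixture")
            log_stage(stage, t0, genes=len(fixture.models),
                      circ_loci=len(fixture.circ_loci), events=len(fixture.events))

        elif stage == "reads":
            fixture: Fixture = need("fixture", "fixture")
            sim_cfg = config.sim or SimConfig(seed=config.seed + 1)
            reads, truth = simulate_reads(fixture, sim_cfg)
            state.update(reads=reads, truth=truth, sim_cfg=sim_cfg)
            write_reads(reads, out / "reads")
            write_truth(truth, out / "truth")
            log_stage(stage, t0, samples=len(reads),
                      pairs=sum(len(v) for v in reads.values()))

        elif stage == "circ":
            fixture = need("fixture", "fixture")
            reads = need("reads", "reads")
            loci, call_tally = circ_quant.call_bsj(reads, fixture.genome)
            known = {(c.chrom, c.start, c.end, c.strand): c for c in fixture.circ_loci}
            renamed = []
            for locus in loci:
                match = known.get((locus.chrom, locus.start, locus.end, locus.strand))
                renamed.append(dataclasses.replace(
                    locus, circ_id=match.circ_id, gene_id=match.gene_id) if match else locus)
            scaffolds = [circ_quant.build_scaffold(l, fixture.genome) for l in renamed]
            counts, count_tally = circ_quant.count_junction_reads(scaffolds, reads)
            unique = circ_quant.counts_to_frame(counts, "unique")
            filtered = circ_quant.filter_circ(unique, config.min_junction_reads)
            state.update(called_loci=renamed, circ_counts=unique, circ_filtered=filtered)
            from ._io import write_bed6
            write_bed6(out / "circ_called.bed",
                       [(l.chrom, l.start, l.end, l.circ_id, 0, l.strand) for l in renamed])
            unique.to_csv(out / "circ_counts.tsv", sep="\t")
            filtered.to_csv(out / "circ_counts_filtered.tsv", sep="\t")
            with open(out / "circ_filter_log.txt", "w") as fh:
                fh.write(f"loci_called\t{len(renamed)}\n"
                         f"ambiguous_anchor_reads\t{call_tally.ambiguous_anchor}\n"
                         f"multi_scaffold_reads\t{count_tally.multi_scaffold}\n"
                         f"kept_after_min_{config.min_junction_reads}\t{len(filtered)}\n")
            log_stage(stage, t0, loci=len(renamed), kept=len(filtered))

        elif stage == "de":
            truth = need("truth", "reads")
            filtered = need("circ_filtered", "circ")
            cm = diff_expression.CountMatrix(filtered, truth.genotype_series())
            cm = diff_expression.normalize(cm)
            res = diff_expression.fit_nb_test(cm, mutant=truth.mutant,
                                              wildtype=truth.wildtype)
            res = diff_expression.classify_de(res, config.lfc, config.alpha, use=config.use)
            state["de_results"] = res
            res.to_csv(out / "de_results.tsv", sep="\t")
            log_stage(stage, t0, features=len(res),
                      up=int((res["call"] == "up").sum()),
                      down=int((res["call"] == "down").sum()))

        elif stage == "psi":
            fixture = need("fixture", "fixture")
            reads = need("reads", "reads")
            truth = need("truth", "reads")
            sim_cfg = state.get("sim_cfg") or SimConfig(seed=config.seed + 1)
            res = splice_psi.analyze_events(
                fixture.events, reads, fixture.genome, truth.genotype_series(),
                wt_label=truth.wildtype, mut_label=truth.mutant,
                read_length=sim_cfg.read_length, min_overhang=sim_cfg.min_overhang)
            sig, summary = splice_psi.filter_events(res, config.fdr, config.dpsi)
            state.update(psi_results=res, psi_sig=sig)
            res.to_csv(out / "psi_results.tsv", sep="\t", index=False)
            sig.to_csv(out / "psi_significant.tsv", sep="\t", index=False)
            summary.to_csv(out / "psi_type_summary.tsv", sep="\t", index=False)
            log_stage(stage, t0, events=len(res), significant=len(sig))

        elif stage == "motif":
            fixture = need("fixture", "fixture")
            profiles = {}
            rows = []
            for m in fixture.models:
                prof = motif_ycay.profile_transcript(
                    m, fixture.genome, focus_exon=m.alt_acceptor_exon,
                    bins=config.ycay_bins)
                profiles[m.gene_id] = prof
                rows.append({
                    "transcript": m.gene_id, "exonic_total": prof.exonic_total,
                    "category": prof.category,
                    "junction_spanning": prof.junction_spanning,
                    "upstream_intron": prof.upstream_intron,
                    "downstream_intron": prof.downstream_intron,
                    "gene_body": prof.gene_body,
                    "per_exon": ",".join(map(str, prof.per_exon)),
                })
            state["motif_profiles"] = profiles
            pd.DataFrame(rows).to_csv(out / "ycay_profiles.tsv", sep="\t", index=False)
            if "psi_sig" in state and not state["psi_sig"].empty:
                sig_genes = set(state["psi_sig"]["gene_id"])
                sig = [p for g, p in profiles.items() if g in sig_genes]
                ctl = [p for g, p in profiles.items() if g not in sig_genes]
                if sig and ctl:
                    enr = motif_ycay.compare_sets(sig, ctl, cut=config.ycay_cut)
                    pd.DataFrame([{
                        "prop_significant": enr.prop_significant,
                        "prop_control": enr.prop_control,
                        "odds_ratio": enr.odds_ratio, "P": enr.p,
                    }]).to_csv(out / "ycay_enrichment.tsv", sep="\t", index=False)
            log_stage(stage, t0, transcripts=len(rows))

        elif stage == "overlap":
            de_res = need("de_results", "de")
            sig = need("psi_sig", "psi")
            gene_map = {l.circ_id: l.gene_id for l in state.get("called_loci", [])
                        if l.gene_id}
            venn, records = integration.overlap_sets(de_res, sig, gene_map)
            pd.DataFrame([dataclasses.asdict(venn)]).to_csv(
                out / "overlap_venn.tsv", sep="\t", index=False)
            pd.DataFrame([{
                "gene_id": r.gene_id,
                "circs": ";".join(f"{c}:{call}" for c, call in r.circs),
                "events": ";".join(f"{e}:{t}:{d:+.3f}" for e, t, d in r.events),
                "event_types": ",".join(r.event_types),
            } for r in records]).to_csv(out / "overlap_records.tsv", sep="\t", index=False)
            log_stage(stage, t0, shared=venn.shared)

        elif stage == "pheno":
            surv = simulate_survival(config.survival_n, SurvivalParams(),
                                     config.censor_rate, seed=config.seed + 2)
            surv.to_csv(out / "survival_records.csv", index=False)
            groups = list(SurvivalParams().scales)
            km = pheno_stats.km_logrank(surv, groups[0], groups[1])
            ct, true_folds = simulate_ct(CtDesign(), seed=config.seed + 3)
            ct.to_csv(out / "ct_table.csv", index=False)
            folds = pheno_stats.ddct(ct, reference_group=CtDesign().reference,
                                     housekeeping=CtDesign().housekeeping)
            folds.to_csv(out / "ddct_folds.tsv", sep="\t", index=False)
            viab = simulate_viability(seed=config.seed + 4)
            viab.to_csv(out / "viability.csv", index=False)
            vres = pheno_stats.viability_test(viab, groups[0], groups[1])
            pd.DataFrame([{
                "logrank_chi2": km.chi2, "logrank_p": km.p,
                "mean_lifespan_wt": km.mean_a, "mean_lifespan_mut": km.mean_b,
                "lifespan_pct_change": km.pct_change,
                "viability_t": vres.t, "viability_p": vres.p,
            }]).to_csv(out / "pheno_summary.tsv", sep="\t", index=False)
            log_stage(stage, t0, animals=len(surv))

        else:  # pragma: no cover - guarded in __post_init__
            raise PipelineError(f"unknown stage {stage!r}")

    with open(out / "run.log", "w") as fh:
        for name, secs in timings.items():
            fh.write(f"{name}\t{secs}s\t{stage_log[name]}\n")

    files = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name not in ("manifest.json", "run.log"):
            files[str(path.relative_to(out))] = _sha256(path)
    config_dict = _jsonable(config)
    config_dict.pop("outdir")  # run location is not part of the scientific identity
    manifest = {
        "seed": config.seed,
        "config": config_dict,
        "stages": stage_log,
        "files": files,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
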
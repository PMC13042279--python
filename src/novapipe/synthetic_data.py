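"""Seeded toy data with known ground truth for every pipeline stage.

The generator emulates the study design this pipeline targets: two genotypes
(wild-type and a *nova-1*-like mutant) with five biological replicates of
paired-end 150-nt reads, circRNAs whose back-splice junction read counts
follow a negative-binomial law with genotype-specific means, linear
alternative-splicing events with genotype-specific inclusion levels, PCR
duplicates as byte-identical read pairs, and censored lifespan / qPCR Ct
tables. The bundled "focus" locus reproduces the crh-1 exon-4 geometry: one
shared splice donor and two alternative 3' splice acceptors 6 nt apart,
giving 205- and 211-nt exon isoforms and therefore two circRNA isoforms
whose circularised lengths differ by 6 nt.

Reads are emitted only over junction-informative windows (back-splice and
linear splice junction scaffolds), not as whole-transcript shotgun; this is
exactly the evidence the downstream exact-match counters consume, so every
emitted quantity has a recorded expectation in :class:`SimTruth`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._io import revcomp, write_bed6, write_fasta, write_fastq_pairs
from .circ_quant import CircLocus, build_scaffold
from .splice_psi import (SpliceEvent, a3ss_event, a5ss_event, effective_lengths,
                         event_scaffolds, mxe_event, ri_event, se_event)

ALPHABET = "ACGT"
MAX_GENOME = 500_000


class ConfigurationError(ValueError):
    pass


class ToyGenome(dict):
    """Contig name -> uppercase ACGT sequence; total length capped at 500 kb."""

    def __init__(self, contigs: dict[str, str]):
        total = 0
        for name, seq in contigs.items():
            if set(seq) - set(ALPHABET):
                raise ValueError(f"contig {name!r} has non-ACGT characters")
            total += len(seq)
        if total > MAX_GENOME:
            raise ConfigurationError(f"genome of {total} nt exceeds {MAX_GENOME}")
        super().__init__(contigs)


@dataclass
class ToyGeneModel:
    """A linear gene with optional alternative-splicing and circRNA features.

    ``exons`` are sorted, non-overlapping 0-based half-open intervals of the
    canonical isoform. ``alt_acceptor_exon`` designates one exon with a second
    3' splice acceptor ``alt_acceptor_offset`` nt further into the upstream
    intron, producing a second, longer exon isoform. ``circ_exons`` marks
    exons that circularise (one circle per exon isoform).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    alt_acceptor_exon: int | None = None
    alt_acceptor_offset: int = 0
    alt_donor_exon: int | None = None
    alt_donor_offset: int = 0
    cassette_exon: int | None = None
    retained_intron: int | None = None
    mxe_pair: tuple[int, int] | None = None
    circ_exons: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        prev_end = -1
        for s, e in self.exons:
            if not (prev_end < s < e):
                raise ValueError(f"{self.gene_id}: exons must be sorted and non-overlapping")
            prev_end = e
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if self.alt_acceptor_exon is not None and self.alt_acceptor_offset <= 0:
            raise ValueError("alt acceptor needs a positive offset")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class Effects:
    """Ground-truth genotype effects baked into a fixture's defaults."""

    circ_log2fc: dict[str, float] = field(default_factory=dict)
    circ_base_mean: dict[str, float] = field(default_factory=dict)
    psi: dict[str, tuple[float, float]] = field(default_factory=dict)  # (wt, mutant)


@dataclass
class Fixture:
    genome: ToyGenome
    models: list[ToyGeneModel]
    circ_loci: list[CircLocus]
    events: list[SpliceEvent]
    default_effects: Effects
    seed: int


@dataclass
class FixtureConfig:
    """Layout of the toy genome. Defaults give one crh-1-like focus locus
    (A3'SS, 205/211-nt exon isoforms, two circles), one gene shared between
    the circRNA and splicing programmes, eight plain circRNA hosts and one
    gene per remaining linear event class."""

    seed: int
    contig_name: str = "chrI"
    include_focus_gene: bool = True
    n_plain_circ_genes: int = 8
    n_shared_genes: int = 1
    splice_gene_types: tuple[str, ...] = ("SE", "A3SS", "A5SS", "RI", "MXE")
    alt_acceptor_offset: int = 6
    focus_exon_length: int = 205      # canonical; the long isoform adds the offset
    exon_length_range: tuple[int, int] = (150, 260)
    intron_length_range: tuple[int, int] = (80, 150)
    n_exons: int = 5
    flank: int = 300
    contig_length: int | None = None


def _gene_coords(rng, start: int, exon_lengths: list[int], intron_range) -> tuple:
    exons = []
    pos = start
    for i, el in enumerate(exon_lengths):
        exons.append((pos, pos + el))
        pos += el
        if i < len(exon_lengths) - 1:
            pos += int(rng.integers(intron_range[0], intron_range[1] + 1))
    return tuple(exons), pos


def events_from_models(models: list[ToyGeneModel]) -> list[SpliceEvent]:
    """Derive the linear splicing events implied by the gene models."""
    events: list[SpliceEvent] = []
    for m in models:
        if m.alt_acceptor_exon is not None:
            i = m.alt_acceptor_exon
            s, e = m.exons[i]
            if m.strand == "+":
                donor_end = m.exons[i - 1][1]
                events.append(a3ss_event(f"{m.gene_id}_A3SS", m.gene_id, m.chrom, m.strand,
                                         donor_end, s - m.alt_acceptor_offset, s))
            else:
                # on the - strand the acceptor sits at the exon's genomic end
                donor_start = m.exons[i + 1][0]
                events.append(SpliceEvent(f"{m.gene_id}_A3SS", "A3SS", m.gene_id, m.chrom,
                                          m.strand,
                                          inc_junctions=((e + m.alt_acceptor_offset, donor_start),),
                                          skip_junctions=((e, donor_start),)))
        if m.cassette_exon is not None:
            c = m.cassette_exon
            events.append(se_event(f"{m.gene_id}_SE", m.gene_id, m.chrom, m.strand,
                                   m.exons[c - 1][1], m.exons[c], m.exons[c + 1][0]))
        if m.alt_donor_exon is not None:
            d = m.alt_donor_exon
            s, e = m.exons[d]
            if m.strand == "+":
                events.append(a5ss_event(f"{m.gene_id}_A5SS", m.gene_id, m.chrom, m.strand,
                                         e + m.alt_donor_offset, e, m.exons[d + 1][0]))
            else:
                events.append(SpliceEvent(f"{m.gene_id}_A5SS", "A5SS", m.gene_id, m.chrom,
                                          m.strand,
                                          inc_junctions=((m.exons[d - 1][1], s - m.alt_donor_offset),),
                                          skip_junctions=((m.exons[d - 1][1], s),)))
        if m.retained_intron is not None:
            i = m.retained_intron
            events.append(ri_event(f"{m.gene_id}_RI", m.gene_id, m.chrom, m.strand,
                                   (m.exons[i][1], m.exons[i + 1][0])))
        if m.mxe_pair is not None:
            a, b = m.mxe_pair
            events.append(mxe_event(f"{m.gene_id}_MXE", m.gene_id, m.chrom, m.strand,
                                    m.exons[a - 1][1], m.exons[a], m.exons[b],
                                    m.exons[b + 1][0]))
    return events


def circ_loci_from_models(models: list[ToyGeneModel]) -> list[CircLocus]:
    """One CircLocus per circularising exon isoform.

    An exon with an alternative acceptor yields two circles sharing the
    shared-donor coordinate and differing at the acceptor side by the
    configured offset.
    """
    loci: list[CircLocus] = []
    for m in models:
        for i in m.circ_exons:
            s, e = m.exons[i]
            variants = [(s, e)]
            if m.alt_acceptor_exon == i and m.alt_acceptor_offset:
                if m.strand == "+":
                    variants.append((s - m.alt_acceptor_offset, e))
                else:
                    variants.append((s, e + m.alt_acceptor_offset))
            for vs, ve in variants:
                loci.append(CircLocus(circ_id=f"circ_{m.gene_id}_{ve - vs}",
                                      chrom=m.chrom, start=vs, end=ve,
                                      strand=m.strand, gene_id=m.gene_id))
    return loci


def make_fixture(config: FixtureConfig) -> Fixture:
    """Build the toy genome, gene models, circRNA loci and splicing events.

    Deterministic for a fixed seed. The focus locus yields exactly two
    circles sharing their shared-donor coordinate and differing by
    ``alt_acceptor_offset`` nt (default 6) at the acceptor."""
    rng = np.random.default_rng(config.seed)
    el_lo, el_hi = config.exon_length_range
    models: list[ToyGeneModel] = []
    pos = config.flank
    effects = Effects()

    def rand_lengths(n):
        return [int(rng.integers(el_lo, el_hi + 1)) for _ in range(n)]

    if config.include_focus_gene:
        lengths = rand_lengths(config.n_exons)
        focus = min(3, config.n_exons - 2)
        lengths[focus] = config.focus_exon_length
        exons, pos = _gene_coords(rng, pos, lengths, config.intron_length_range)
        models.append(ToyGeneModel("crh-1L", config.contig_name, "+", exons,
                                   alt_acceptor_exon=focus,
                                   alt_acceptor_offset=config.alt_acceptor_offset,
                                   circ_exons=(focus,)))
        pos += config.flank
        long_len = config.focus_exon_length + config.alt_acceptor_offset
        effects.circ_log2fc[f"circ_crh-1L_{long_len}"] = -1.0
        effects.psi["crh-1L_A3SS"] = (0.6, 0.3)

    for j in range(config.n_shared_genes):
        lengths = rand_lengths(config.n_exons)
        exons, pos = _gene_coords(rng, pos, lengths, config.intron_length_range)
        gid = f"shared{j + 1}"
        models.append(ToyGeneModel(gid, config.contig_name, "+", exons,
                                   cassette_exon=2, circ_exons=(2,)))
        pos += config.flank
        effects.circ_log2fc[f"circ_{gid}_{exons[2][1] - exons[2][0]}"] = 1.0
        effects.psi[f"{gid}_SE"] = (0.7, 0.4)

    for j in range(config.n_plain_circ_genes):
        lengths = rand_lengths(3)
        exons, pos = _gene_coords(rng, pos, lengths, config.intron_length_range)
        gid = f"cg{j + 1:02d}"
        strand = "+" if j % 2 == 0 else "-"
        models.append(ToyGeneModel(gid, config.contig_name, strand, exons, circ_exons=(1,)))
        pos += config.flank
        cid = f"circ_{gid}_{exons[1][1] - exons[1][0]}"
        if j < 2:
            effects.circ_log2fc[cid] = 1.0
        elif j == 2:
            effects.circ_log2fc[cid] = -1.0
        elif j == 3:
            effects.circ_base_mean[cid] = 1.0  # stays under the junction-read filter

    for etype in config.splice_gene_types:
        gid = f"sg_{etype}"
        lengths = rand_lengths(config.n_exons)
        exons, pos = _gene_coords(rng, pos, lengths, config.intron_length_range)
        kwargs: dict = {}
        if etype == "SE":
            kwargs["cassette_exon"] = 2
            effects.psi[f"{gid}_SE"] = (0.5, 0.8)
        elif etype == "A3SS":
            kwargs.update(alt_acceptor_exon=2, alt_acceptor_offset=config.alt_acceptor_offset)
        elif etype == "A5SS":
            kwargs.update(alt_donor_exon=2, alt_donor_offset=7)
        elif etype == "RI":
            kwargs["retained_intron"] = 1
        elif etype == "MXE":
            kwargs["mxe_pair"] = (2, 3)
        else:
            raise ConfigurationError(f"unknown splice gene type {etype!r}")
        models.append(ToyGeneModel(gid, config.contig_name, "+", exons, **kwargs))
        pos += config.flank

    needed = pos + config.flank
    length = config.contig_length if config.contig_length is not None else needed
    if length < needed:
        raise ConfigurationError(
            f"contig of {length} nt too short for requested features ({needed} nt)")
    seq = list("".join(np.array(list(ALPHABET))[rng.integers(0, 4, size=length)]))

    loci = circ_loci_from_models(models)
    # Back-splice breakpoints are only defined up to rotation when the bases
    # flanking both junction sides coincide; nudge those bases apart so every
    # simulated locus has a unique, exactly recoverable breakpoint.
    ends: dict[int, set[int]] = {}
    starts: dict[int, set[int]] = {}
    for c in loci:
        ends.setdefault(c.end, set()).add(c.start)
        starts.setdefault(c.start, set()).add(c.end)
    for e, ss in ends.items():
        forbidden = {seq[s] for s in ss}
        if seq[e] in forbidden:
            seq[e] = next(b for b in ALPHABET if b not in forbidden)
    for s, es in starts.items():
        forbidden = {seq[e - 1] for e in es}
        if seq[s - 1] in forbidden:
            seq[s - 1] = next(b for b in ALPHABET if b not in forbidden)

    genome = ToyGenome({config.contig_name: "".join(seq)})
    events = events_from_models(models)
    return Fixture(genome, models, loci, events, effects, config.seed)


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class SimConfig:
    """Read-level simulation parameters. Defaults are the study conditions:
    5 replicates per genotype, 150-nt pairs, NB dispersion phi = 0.05 with
    variance mu + phi * mu^2, and a 10% PCR-duplicate fraction."""

    seed: int
    n_replicates: int = 5
    genotypes: tuple[str, str] = ("wt", "nova-1")  # first entry is wild-type
    read_length: int = 150
    min_overhang: int = 8
    fragment_range: tuple[int, int] = (150, 200)
    duplicate_fraction: float = 0.10
    phi: float = 0.05
    circ_base_mean: float = 30.0
    event_depth: float = 120.0
    circ_log2fc: dict[str, float] | None = None
    circ_base_mean_overrides: dict[str, float] | None = None
    psi: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.duplicate_fraction < 1.0:
            raise ConfigurationError("duplicate_fraction must be in [0, 1)")
        if self.min_overhang > self.read_length // 2:
            raise ConfigurationError("min_overhang exceeds half the read length")
        if self.read_length > 200:
            raise ConfigurationError("read length exceeds the 200-nt scaffold")
        if self.phi < 0:
            raise ConfigurationError("phi must be >= 0")


@dataclass
class SimTruth:
    """Exact expectations recorded while emitting reads; everything needed to
    verify downstream quantification with zero tolerance."""

    seed: int
    phi: float
    duplicate_fraction: float
    genotype_of: dict[str, str]
    wildtype: str
    mutant: str
    circ_unique: dict[tuple[str, str], int] = field(default_factory=dict)
    circ_mean: dict[tuple[str, str], float] = field(default_factory=dict)
    circ_log2fc: dict[str, float] = field(default_factory=dict)
    event_counts: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)
    true_psi: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.genotype_of)

    def circ_count_frame(self) -> pd.DataFrame:
        circ_ids = sorted({c for c, _ in self.circ_unique})
        data = {s: [self.circ_unique[(c, s)] for c in circ_ids] for s in self.samples}
        df = pd.DataFrame(data, index=circ_ids)
        df.index.name = "feature"
        return df

    def genotype_series(self) -> pd.Series:
        return pd.Series(self.genotype_of)


def _nb_draw(rng, mean: float, phi: float) -> int:
    if mean <= 0:
        return 0
    if phi == 0:
        return int(rng.poisson(mean))
    lam = rng.gamma(1.0 / phi, mean * phi)
    return int(rng.poisson(lam))


_COMBO_CACHE: dict[tuple, list[tuple[int, int]]] = {}


def _spanning_pairs(rng, scaffold_seq: str, n: int, cfg: SimConfig,
                    distinct: bool) -> list[tuple[str, str]]:
    """Draw n read pairs whose first mate crosses the scaffold seam with at
    least the configured overhang; ``distinct`` draws without replacement
    over (fragment start, fragment length) so every pair is unique."""
    length = len(scaffold_seq)
    seam = length // 2
    rl = cfg.read_length
    lf_lo = max(rl, cfg.fragment_range[0])
    lf_hi = min(length, cfg.fragment_range[1])
    key = (length, rl, lf_lo, lf_hi, cfg.min_overhang)
    combos = _COMBO_CACHE.get(key)
    if combos is None:
        combos = []
        for lf in range(lf_lo, lf_hi + 1):
            f_lo = max(0, seam + cfg.min_overhang - rl)
            f_hi = min(length - lf, seam - cfg.min_overhang)
            combos.extend((f, lf) for f in range(f_lo, f_hi + 1))
        _COMBO_CACHE[key] = combos
    if not combos:
        raise ConfigurationError("no seam-spanning fragment placements possible")
    if distinct:
        n = min(n, len(combos))
        idx = rng.choice(len(combos), size=n, replace=False)
    else:
        idx = rng.integers(0, len(combos), size=n)
    pairs = []
    for i in idx:
        f, lf = combos[i]
        frag = scaffold_seq[f : f + lf]
        pairs.append((frag[:rl], revcomp(frag[-rl:])))
    return pairs


def simulate_reads(fixture: Fixture, config: SimConfig
                   ) -> tuple[dict[str, list[tuple[str, str]]], SimTruth]:
    """Emit per-sample paired reads over every back-splice and linear splice
    junction, with recorded expectations.

    BSJ pairs are drawn *without replacement* over fragment placements, so the
    recorded unique count equals the deduplicated count exactly; PCR
    duplicates are then added as byte-identical copies at the configured
    fraction. Linear-event reads are drawn with replacement at the event
    depth, split between inclusion and skipping forms so that the
    length-normalised PSI matches the configured truth in expectation.
    """
    rng = np.random.default_rng(config.seed)
    wt, mut = config.genotypes
    samples = [f"{g}_{r + 1}" for g in config.genotypes for r in range(config.n_replicates)]
    genotype_of = {s: s.rsplit("_", 1)[0] for s in samples}
    eff = fixture.default_effects
    lfc = dict(eff.circ_log2fc)
    if config.circ_log2fc is not None:
        lfc.update(config.circ_log2fc)
    base_mean = dict(eff.circ_base_mean)
    if config.circ_base_mean_overrides is not None:
        base_mean.update(config.circ_base_mean_overrides)
    psi_truth = dict(eff.psi)
    if config.psi is not None:
        psi_truth.update(config.psi)

    truth = SimTruth(seed=config.seed, phi=config.phi,
                     duplicate_fraction=config.duplicate_fraction,
                     genotype_of=genotype_of, wildtype=wt, mutant=mut,
                     circ_log2fc={c.circ_id: lfc.get(c.circ_id, 0.0)
                                  for c in fixture.circ_loci})

    scaffolds = {c.circ_id: build_scaffold(c, fixture.genome) for c in fixture.circ_loci}
    ev_scaffolds = {e.event_id: event_scaffolds(e, fixture.genome) for e in fixture.events}
    ev_lengths = {e.event_id: effective_lengths(e, config.read_length, config.min_overhang)
                  for e in fixture.events}

    reads: dict[str, list[tuple[str, str]]] = {}
    for sample in samples:
        geno = genotype_of[sample]
        out: list[tuple[str, str]] = []
        for circ in fixture.circ_loci:
            mean = base_mean.get(circ.circ_id, config.circ_base_mean)
            if geno == mut:
                mean *= 2.0 ** lfc.get(circ.circ_id, 0.0)
            truth.circ_mean[(circ.circ_id, geno)] = mean
            n_unique = _nb_draw(rng, mean, config.phi)
            pairs = _spanning_pairs(rng, scaffolds[circ.circ_id].sequence, n_unique,
                                    config, distinct=True)
            truth.circ_unique[(circ.circ_id, sample)] = len(pairs)
            for pair in pairs:
                out.append(pair)
                if rng.random() < config.duplicate_fraction:
                    out.append(pair)  # byte-identical PCR duplicate
        for ev in fixture.events:
            psi_wt, psi_mut = psi_truth.get(ev.event_id, (0.5, 0.5))
            psi = psi_wt if geno == wt else psi_mut
            truth.true_psi[(ev.event_id, geno)] = psi
            l_i, l_s = ev_lengths[ev.event_id]
            n = _nb_draw(rng, config.event_depth, config.phi)
            p_read = psi * l_i / (psi * l_i + (1.0 - psi) * l_s) if n else 0.0
            n_inc = int(rng.binomial(n, p_read)) if n else 0
            inc_sc, skip_sc = ev_scaffolds[ev.event_id]
            for count, side in ((n_inc, inc_sc), (n - n_inc, skip_sc)):
                per_scaffold = rng.multinomial(count, [1.0 / len(side)] * len(side))
                for sc, m in zip(side, per_scaffold):
                    out.extend(_spanning_pairs(rng, sc.sequence, int(m), config,
                                               distinct=False))
            truth.event_counts[(ev.event_id, sample)] = (n_inc, n - n_inc)
        reads[sample] = out
    return reads, truth


# ---------------------------------------------------------------------------
# survival and qPCR simulation


@dataclass
class SurvivalParams:
    """Weibull lifespans: scale (days) per group, common shape. The default
    mutant scale gives a 14.75% longer mean lifespan than wild-type, the
    effect size this pipeline is designed to detect."""

    shape: float = 4.0
    scales: dict[str, float] = field(
        default_factory=lambda: {"wt": 18.0, "nova-1": 18.0 * 1.1475})

    def __post_init__(self) -> None:
        if self.shape <= 0 or any(s <= 0 for s in self.scales.values()):
            raise ConfigurationError("shape and scales must be positive")


CENSOR_REASONS = ("rupture", "bagging", "walling")


def simulate_survival(n_per_group: int, params: SurvivalParams, censor_rate: float,
                      seed: int) -> pd.DataFrame:
    """Integer-day survival records with censor flags and reasons.

    Columns: animal, group, day, event (1 = death, 0 = censored),
    censor_reason (empty for deaths).
    """
    if n_per_group < 1:
        raise ConfigurationError("n_per_group must be >= 1")
    if not 0.0 <= censor_rate < 1.0:
        raise ConfigurationError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for group, scale in params.scales.items():
        for i in range(n_per_group):
            t = scale * rng.weibull(params.shape)
            day = max(1, math.ceil(t))
            if rng.random() < censor_rate:
                c_day = int(rng.integers(1, day + 1))
                reason = CENSOR_REASONS[int(rng.integers(0, len(CENSOR_REASONS)))]
                rows.append((f"{group}_{i}", group, c_day, 0, reason))
            else:
                rows.append((f"{group}_{i}", group, day, 1, ""))
    return pd.DataFrame(rows, columns=["animal", "group", "day", "event", "censor_reason"])


def simulate_viability(seed: int, n_replicates: int = 3, n_exposed: int = 90,
                       p_survival: dict[str, float] | None = None) -> pd.DataFrame:
    """Heat-shock recovery counts: per replicate and group, animals alive
    after recovery out of those exposed (binomial per replicate). Defaults:
    3 replicates of 90 animals, mutants recovering better than wild-type."""
    probs = p_survival or {"wt": 0.45, "nova-1": 0.75}
    if not all(0.0 <= p <= 1.0 for p in probs.values()):
        raise ConfigurationError("survival probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for group, p in probs.items():
        for r in range(n_replicates):
            alive = int(rng.binomial(n_exposed, p))
            rows.append((r + 1, group, n_exposed, alive))
    return pd.DataFrame(rows, columns=["replicate", "group", "n_exposed", "n_alive"])


@dataclass
class CtDesign:
    """qPCR panel layout: per-target true fold changes (mutant over the
    reference genotype) and a shared housekeeping gene."""

    genotypes: tuple[str, ...] = ("wt", "nova-1")
    reference: str = "wt"
    targets: dict[str, float] = field(
        default_factory=lambda: {"circ_long": 0.5, "circ_short": 1.0, "linear_host": 1.0})
    housekeeping: str = "cdc-42"
    n_replicates: int = 3
    noise_sd: float = 0.15
    loading_sd: float = 0.3
    base_ct: float = 22.0
    housekeeping_ct: float = 16.0

    def __post_init__(self) -> None:
        if len(self.genotypes) < 2:
            raise ConfigurationError("need at least two genotypes")
        if not self.targets:
            raise ConfigurationError("need at least one target gene")
        if self.reference not in self.genotypes:
            raise ConfigurationError("reference genotype not in genotypes")


def simulate_ct(design: CtDesign, seed: int) -> tuple[pd.DataFrame, dict[str, float]]:
    """Tidy Ct table (sample, genotype, gene, replicate, ct) plus the true
    fold changes. Per-sample loading offsets hit target and housekeeping
    alike, so relative quantification cancels them."""
    rng = np.random.default_rng(seed)
    rows = []
    for geno in design.genotypes:
        for r in range(design.n_replicates):
            sample = f"{geno}_{r + 1}"
            load = rng.normal(0.0, design.loading_sd) if design.loading_sd else 0.0
            for gene, fold in design.targets.items():
                shift = -math.log2(fold) if geno != design.reference else 0.0
                ct = design.base_ct + load + shift + (
                    rng.normal(0.0, design.noise_sd) if design.noise_sd else 0.0)
                rows.append((sample, geno, gene, r + 1, ct))
            hk = design.housekeeping_ct + load + (
                rng.normal(0.0, design.noise_sd) if design.noise_sd else 0.0)
            rows.append((sample, geno, design.housekeeping, r + 1, hk))
    df = pd.DataFrame(rows, columns=["sample", "genotype", "gene", "replicate", "ct"])
    return df, dict(design.targets)


# ---------------------------------------------------------------------------
# file emission


def write_fixture(fixture: Fixture, outdir) -> dict[str, str]:
    """Write genome FASTA, gene-model GFF3 (1-based closed) and circRNA BED6
    (0-based half-open). Byte-identical across runs for a fixed seed."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": str(outdir / "genome.fa"),
        "annotation": str(outdir / "genes.gff3"),
        "circs": str(outdir / "circs.bed"),
    }
    write_fasta(paths["genome"], sorted(fixture.genome.items()))
    with open(paths["annotation"], "w") as fh:
        fh.write("##gff-version 3\n")
        for m in fixture.models:
            g_s, g_e = m.span
            fh.write(f"{m.chrom}\ttoy\tgene\t{g_s + 1}\t{g_e}\t.\t{m.strand}\t.\t"
                     f"ID=gene:{m.gene_id}\n")
            fh.write(f"{m.chrom}\ttoy\tmRNA\t{g_s + 1}\t{g_e}\t.\t{m.strand}\t.\t"
                     f"ID=tx:{m.gene_id}.1;Parent=gene:{m.gene_id}\n")
            for i, (s, e) in enumerate(m.exons):
                fh.write(f"{m.chrom}\ttoy\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                         f"ID=exon:{m.gene_id}.{i + 1};Parent=tx:{m.gene_id}.1\n")
            if m.alt_acceptor_exon is not None:
                i = m.alt_acceptor_exon
                s, e = m.exons[i]
                if m.strand == "+":
                    s -= m.alt_acceptor_offset
                else:
                    e += m.alt_acceptor_offset
                fh.write(f"{m.chrom}\ttoy\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                         f"ID=exon:{m.gene_id}.{i + 1}L;Parent=tx:{m.gene_id}.2\n")
    write_bed6(paths["circs"],
               [(c.chrom, c.start, c.end, c.circ_id, 0, c.strand) for c in fixture.circ_loci])
    return paths


def write_reads(reads: dict[str, list[tuple[str, str]]], outdir) -> dict[str, tuple[str, str]]:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sample, pairs in reads.items():
        r1 = outdir / f"{sample}_R1.fastq.gz"
        r2 = outdir / f"{sample}_R2.fastq.gz"
        write_fastq_pairs(r1, r2, pairs, name_prefix=sample)
        paths[sample] = (str(r1), str(r2))
    return paths


def write_truth(truth: SimTruth, outdir) -> dict[str, str]:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    circ = truth.circ_count_frame()
    circ_path = outdir / "truth_circ_counts.tsv"
    circ.to_csv(circ_path, sep="\t")
    ev_rows = [(e, s, i, k) for (e, s), (i, k) in sorted(truth.event_counts.items())]
    ev_path = outdir / "truth_event_counts.tsv"
    pd.DataFrame(ev_rows, columns=["event_id", "sample", "I", "S"]).to_csv(
        ev_path, sep="\t", index=False)
    meta_path = outdir / "truth_meta.tsv"
    pd.DataFrame({
        "sample": truth.samples,
        "genotype": [truth.genotype_of[s] for s in truth.samples],
    }).to_csv(meta_path, sep="\t", index=False)
    return {"circ_counts": str(circ_path), "event_counts": str(ev_path),
            "meta": str(meta_path)}
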
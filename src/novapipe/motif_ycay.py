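"""NOVA binding-site (YCAY, Y = C or T) scanning and enrichment.

NOVA-family splicing factors recognise the tetranucleotide YCAY; its density
in and around an alternatively spliced exon is the standard proxy for direct
NOVA regulation. Scanning is a per-position sliding window over
transcript-orientation sequence (YCAY is not its own reverse complement, so
minus-strand genes are reverse-complemented before scanning) and overlapping
occurrences are counted. Transcripts are binned by exonic site count into
low (< 20), intermediate (20-59) and enriched (>= 60) classes, and a
significant set is compared against a control set by a two-sided exact test
on the 2x2 table at a density cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import stats

from ._io import revcomp

_Y = frozenset("CT")


def count_ycay(sequence: str) -> int:
    """Number of (possibly overlapping) YCAY windows in the sequence.

    U is treated as T; any other non-ACGT character raises with its offset.
    """
    s = sequence.upper().replace("U", "T")
    for i, ch in enumerate(s):
        if ch not in "ACGT":
            raise ValueError(f"non-ACGTU character {ch!r} at offset {i}")
    n = 0
    for i in range(len(s) - 3):
        if s[i] in _Y and s[i + 1] == "C" and s[i + 2] == "A" and s[i + 3] in _Y:
            n += 1
    return n


DEFAULT_BINS = (20, 60)


def categorize(exonic_total: int, bins: tuple[int, int] = DEFAULT_BINS) -> str:
    """Bin an exonic YCAY total: < bins[0] low, up to bins[1]-1 intermediate,
    >= bins[1] enriched (the boundary value itself counts as enriched)."""
    lo, hi = bins
    if exonic_total < lo:
        return "low"
    if exonic_total < hi:
        return "intermediate"
    return "enriched"


@dataclass
class MotifProfile:
    """Per-transcript YCAY tally, partitioned by exon, with flanking-intron
    counts for one designated exon. ``junction_spanning`` counts sites that
    straddle an exon-exon boundary in the spliced transcript; they are kept
    out of the per-exon totals."""

    transcript_id: str
    per_exon: list[int]
    junction_spanning: int = 0
    upstream_intron: int | None = None
    downstream_intron: int | None = None
    gene_body: int | None = None
    bins: tuple[int, int] = DEFAULT_BINS

    @property
    def exonic_total(self) -> int:
        return sum(self.per_exon)

    @property
    def category(self) -> str:
        return categorize(self.exonic_total, self.bins)


def profile_transcript(gene_model, genome: dict[str, str],
                       focus_exon: int | None = None,
                       bins: tuple[int, int] = DEFAULT_BINS) -> MotifProfile:
    """Scan a gene model's exons (transcript orientation) for YCAY sites.

    For ``focus_exon`` (an index into the model's exons) the flanking-intron
    counts are reported too, as is the unspliced gene-body total, so any of
    the common counting conventions can be read off one profile.
    """
    contig = genome[gene_model.chrom]
    exons = list(gene_model.exons)
    minus = gene_model.strand == "-"
    if focus_exon is not None and not 0 <= focus_exon < len(exons):
        raise ValueError(f"focus exon {focus_exon} not in model with {len(exons)} exons")

    exon_seqs = [contig[s:e] for s, e in exons]
    if minus:
        exon_seqs = [revcomp(s) for s in reversed(exon_seqs)]
    per_exon = [count_ycay(s) for s in exon_seqs]
    spliced = "".join(exon_seqs)
    junction_spanning = count_ycay(spliced) - sum(per_exon)
    if minus:
        per_exon = per_exon[::-1]  # report in genomic exon order

    up = down = None
    if focus_exon is not None:
        introns = [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]
        gen_up = introns[focus_exon - 1] if focus_exon > 0 else None
        gen_down = introns[focus_exon] if focus_exon < len(introns) else None
        if minus:
            gen_up, gen_down = gen_down, gen_up

        def intron_count(iv):
            if iv is None:
                return None
            seq = contig[iv[0] : iv[1]]
            return count_ycay(revcomp(seq) if minus else seq)

        up, down = intron_count(gen_up), intron_count(gen_down)

    g_s, g_e = exons[0][0], exons[-1][1]
    body_seq = contig[g_s:g_e]
    gene_body = count_ycay(revcomp(body_seq) if minus else body_seq)

    return MotifProfile(transcript_id=gene_model.gene_id, per_exon=per_exon,
                        junction_spanning=junction_spanning,
                        upstream_intron=up, downstream_intron=down,
                        gene_body=gene_body, bins=bins)


@dataclass
class EnrichmentResult:
    prop_significant: float
    prop_control: float
    odds_ratio: float
    p: float
    table: tuple[tuple[int, int], tuple[int, int]] = ((0, 0), (0, 0))


def compare_sets(significant, control, cut: int = 20) -> EnrichmentResult:
    """Compare YCAY density between a significant and a control transcript
    set: fraction at/above ``cut`` exonic sites in each, odds ratio, and a
    two-sided Fisher exact P on the 2x2 table.

    Accepts :class:`MotifProfile` lists or plain exonic-count lists.
    """
    def totals(profiles):
        return [p.exonic_total if isinstance(p, MotifProfile) else int(p) for p in profiles]

    sig, ctl = totals(significant), totals(control)
    if not sig or not ctl:
        raise ValueError("both transcript sets must be non-empty")
    a = sum(t >= cut for t in sig)
    b = len(sig) - a
    c = sum(t >= cut for t in ctl)
    d = len(ctl) - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(prop_significant=a / len(sig), prop_control=c / len(ctl),
                            odds_ratio=float(odds), p=float(p), table=((a, b), (c, d)))
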
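"""Back-splice junction (BSJ) scaffolds, split-read circRNA calling and
junction-read counting.

A circRNA is represented by the genomic interval of its circularised exon(s);
the evidence for it is reads that cross the back-splice seam, i.e. the
non-colinear joint between the circle's 3' end and its 5' start. Detection
and counting are alignment-free: the caller anchors exact k-mers of the two
read halves on the genome and looks for anchors in inverted genomic order,
and the counter matches reads exactly into a 200-nt pseudo-reference
("junction scaffold") centred on the seam. Reads are assumed to come from a
stranded library whose first mate is in transcript orientation; the second
mate is matched in either orientation.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from ._io import revcomp

SCAFFOLD_LENGTH = 200
SEAM_OFFSET = 100


class CoordinateError(ValueError):
    """A locus does not fit inside its contig."""


@dataclass(frozen=True)
class CircLocus:
    """One back-splice circle: the genomic span of the circularised sequence.

    ``start``/``end`` are 0-based half-open; two isoforms of one host gene may
    share ``end`` (the shared splice donor on the + strand) and differ at
    ``start`` (alternative 3' splice acceptors).
    """

    circ_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid circle interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        """Circularised length in nt (single-exon circles)."""
        return self.end - self.start


@dataclass(frozen=True)
class JunctionScaffold:
    """200-nt pseudo-reference across a BSJ; the seam sits at offset 100."""

    circ_id: str
    sequence: str
    seam_offset: int = SEAM_OFFSET

    def __post_init__(self) -> None:
        if len(self.sequence) != SCAFFOLD_LENGTH:
            raise ValueError("scaffold must be exactly 200 nt")


@dataclass
class JunctionCount:
    circ_id: str
    sample: str
    raw: int
    unique: int

    def __post_init__(self) -> None:
        if not 0 <= self.unique <= self.raw:
            raise ValueError("need 0 <= unique <= raw")


@dataclass
class CallParams:
    """Tuning for the split-read caller."""

    k: int = 20                # anchor length
    max_hits: int = 4          # k-mer ambiguity cutoff
    min_overhang: int = 8      # nt required on each side of the seam
    min_support: int = 2       # reads required to report a locus
    max_circle: int = 100_000  # sanity cap on end - start


@dataclass
class CallTally:
    ambiguous_anchor: int = 0
    considered: int = 0


def circle_sequence(locus: CircLocus, genome: dict[str, str]) -> str:
    """Circle sequence 5'->3' in transcript orientation."""
    try:
        contig = genome[locus.chrom]
    except KeyError:
        raise CoordinateError(f"unknown contig {locus.chrom!r}") from None
    if locus.end > len(contig):
        raise CoordinateError(
            f"{locus.circ_id}: [{locus.start}, {locus.end}) outside contig "
            f"{locus.chrom} of length {len(contig)}"
        )
    seq = contig[locus.start : locus.end]
    return revcomp(seq) if locus.strand == "-" else seq


def build_scaffold(locus: CircLocus, genome: dict[str, str]) -> JunctionScaffold:
    """Build the 200-nt junction scaffold for a circle.

    Left of the seam: the last 100 nt of the circle; right: its first 100 nt.
    Circles shorter than 100 nt per side are tiled circularly, so the scaffold
    is always exactly 200 nt with the seam at offset 100.
    """
    circ = circle_sequence(locus, genome)
    reps = -(-SEAM_OFFSET // len(circ)) + 1  # enough copies to take 100 nt
    tiled = circ * reps
    left = tiled[-SEAM_OFFSET:]
    right = tiled[:SEAM_OFFSET]
    return JunctionScaffold(circ_id=locus.circ_id, sequence=left + right)


def _kmer_index(genome: dict[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for chrom, seq in genome.items():
        for i in range(len(seq) - k + 1):
            index[seq[i : i + k]].append((chrom, i))
    return index


def _extend_match(seq: str, contig: str, pos: int) -> int:
    """Length of the exact match of ``seq`` against ``contig`` starting at pos."""
    n = 0
    limit = min(len(seq), len(contig) - pos)
    while n < limit and seq[n] == contig[pos + n]:
        n += 1
    return n


def call_bsj(
    reads_by_sample: dict[str, list[tuple[str, str]]],
    genome: dict[str, str],
    params: CallParams | None = None,
) -> tuple[list[CircLocus], CallTally]:
    """Call candidate circRNA loci from split reads.

    For each first mate (transcript sense, both orientations tried), the
    prefix and suffix k-mers are anchored on the genome. A prefix anchor
    *downstream* of the suffix anchor is the inverted-order signature of a
    back-splice; the exact breakpoint is found by extending the prefix match
    and verifying that the read remainder matches the putative circle start.
    Loci with at least ``min_support`` consistent reads are reported, sorted
    by coordinate. Reads whose anchors are too ambiguous are skipped and
    tallied.
    """
    p = params or CallParams()
    index = _kmer_index(genome, p.k)
    votes: Counter[tuple[str, int, int, str]] = Counter()
    tally = CallTally()

    for pairs in reads_by_sample.values():
        for r1, _ in pairs:
            tally.considered += 1
            for seq, strand in ((r1, "+"), (revcomp(r1), "-")):
                if len(seq) < 2 * p.k:
                    continue
                pre_hits = index.get(seq[: p.k], [])
                suf_hits = index.get(seq[-p.k :], [])
                if len(pre_hits) > p.max_hits or len(suf_hits) > p.max_hits:
                    tally.ambiguous_anchor += 1
                    continue
                for chrom1, p1 in pre_hits:
                    contig = genome[chrom1]
                    for chrom2, p2 in suf_hits:
                        if chrom2 != chrom1 or p1 <= p2:
                            continue  # colinear or cross-contig: not a BSJ
                        a = _extend_match(seq, contig, p1)
                        if not (p.min_overhang <= a <= len(seq) - p.min_overhang):
                            continue
                        end = p1 + a
                        start = p2 + p.k - (len(seq) - a)
                        if not (0 <= start < end and end - start <= p.max_circle):
                            continue
                        if seq[a:] == contig[start : start + len(seq) - a]:
                            votes[(chrom1, start, end, strand)] += 1

    loci = [
        CircLocus(circ_id=f"bsj_{c}_{s}_{e}_{st}", chrom=c, start=s, end=e, strand=st)
        for (c, s, e, st), n in votes.items()
        if n >= p.min_support
    ]
    loci.sort(key=lambda l: (l.chrom, l.start, l.end, l.strand))
    return loci, tally


@dataclass
class CountParams:
    min_overhang: int = 8
    ambiguous_policy: str = "drop"  # or "all"


@dataclass
class CountTally:
    multi_scaffold: int = 0
    unmatched: int = 0


class _ScaffoldMatcher:
    """Exact matcher of fixed-length reads into seam-spanning scaffold windows."""

    def __init__(self, scaffolds: list[JunctionScaffold], min_overhang: int):
        self.scaffolds = scaffolds
        self.min_overhang = min_overhang
        self._by_len: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def _windows(self, length: int) -> dict[str, list[tuple[str, int]]]:
        if length not in self._by_len:
            table: dict[str, list[tuple[str, int]]] = defaultdict(list)
            for sc in self.scaffolds:
                seam = sc.seam_offset
                lo = max(0, seam + self.min_overhang - length)
                hi = min(len(sc.sequence) - length, seam - self.min_overhang)
                for o in range(lo, hi + 1):
                    table[sc.sequence[o : o + length]].append((sc.circ_id, o))
            self._by_len[length] = table
        return self._by_len[length]

    def match(self, read: str) -> list[tuple[str, int]]:
        """Seam-spanning hits for the read in either orientation.

        The offset is taken from whichever orientation matches, so the result
        is invariant under reverse-complementing the read.
        """
        table = self._windows(len(read))
        hits = table.get(read)
        if hits is None:
            hits = table.get(revcomp(read))
        if not hits:
            return []
        # a short tiled circle can contain the same window at several offsets;
        # that is one scaffold hit, not an ambiguity
        first: dict[str, int] = {}
        for circ_id, o in hits:
            first.setdefault(circ_id, o)
        return list(first.items())


def count_junction_reads(
    scaffolds: list[JunctionScaffold],
    reads_by_sample: dict[str, list[tuple[str, str]]],
    params: CountParams | None = None,
) -> tuple[list[JunctionCount], CountTally]:
    """Count BSJ-spanning read pairs per circle per sample, with dedup.

    The first mate must match a scaffold exactly across the seam with at
    least ``min_overhang`` nt on each side. Pairs are deduplicated on the
    (scaffold, mate-offset pair) tuple, mirroring coordinate-based duplicate
    marking. First mates matching several scaffolds are dropped and tallied
    (default) or credited to all (``ambiguous_policy="all"``).
    """
    p = params or CountParams()
    matcher = _ScaffoldMatcher(scaffolds, p.min_overhang)
    tally = CountTally()
    results: list[JunctionCount] = []

    for sample in reads_by_sample:
        raw: Counter[str] = Counter()
        seen: defaultdict[str, set] = defaultdict(set)
        for r1, r2 in reads_by_sample[sample]:
            hits = matcher.match(r1)
            if not hits:
                tally.unmatched += 1
                continue
            if len(hits) > 1 and p.ambiguous_policy == "drop":
                tally.multi_scaffold += 1
                continue
            for circ_id, o1 in hits:
                scaffold = next(s for s in scaffolds if s.circ_id == circ_id)
                o2 = scaffold.sequence.find(r2)
                if o2 < 0:
                    o2 = scaffold.sequence.find(revcomp(r2))
                key = (min(o1, o2), max(o1, o2))
                raw[circ_id] += 1
                seen[circ_id].add(key)
        for sc in scaffolds:
            results.append(
                JunctionCount(
                    circ_id=sc.circ_id,
                    sample=sample,
                    raw=raw.get(sc.circ_id, 0),
                    unique=len(seen.get(sc.circ_id, ())),
                )
            )
    return results, tally


def counts_to_frame(counts: list[JunctionCount], value: str = "unique") -> pd.DataFrame:
    """Pivot junction counts into a features x samples integer matrix."""
    df = pd.DataFrame([(c.circ_id, c.sample, getattr(c, value)) for c in counts],
                      columns=["circ_id", "sample", value])
    wide = df.pivot(index="circ_id", columns="sample", values=value).fillna(0).astype(int)
    wide.index.name = "feature"
    wide.columns.name = None
    return wide


def filter_circ(
    counts: pd.DataFrame, min_junction_reads: int = 12, scope: str = "pooled"
) -> pd.DataFrame:
    """Drop circles with too few junction reads.

    ``scope="pooled"`` (default) sums unique junction reads across samples and
    keeps rows with a pooled total >= ``min_junction_reads``; ``"per_sample"``
    requires every sample to reach the threshold. Row order is preserved.
    """
    if min_junction_reads < 0:
        raise ValueError("min_junction_reads must be non-negative")
    if counts.empty:
        return counts
    if scope == "pooled":
        keep = counts.sum(axis=1) >= min_junction_reads
    elif scope == "per_sample":
        keep = (counts >= min_junction_reads).all(axis=1)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return counts.loc[keep]
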
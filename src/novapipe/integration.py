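"""Host-gene-level intersection of the circRNA and linear-splicing programmes.

A gene is in the circRNA set if any of its circles received an up/down call,
and in the splicing set if any of its events passed the significance filter;
the overlap is the gene-level Venn of the two sets, with per-gene records of
what happens on each side (a gene can carry several event types at once).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd


@dataclass
class OverlapRecord:
    gene_id: str
    circs: list[tuple[str, str]]          # (circ id, call)
    events: list[tuple[str, str, float]]  # (event id, type, dPSI)

    @property
    def event_types(self) -> list[str]:
        return sorted({t for _, t, _ in self.events})


@dataclass
class VennCounts:
    circ_only: int
    splice_only: int
    shared: int


def overlap_sets(
    de_results: pd.DataFrame,
    sig_events: pd.DataFrame,
    gene_map: dict[str, str] | pd.Series | None = None,
) -> tuple[VennCounts, list[OverlapRecord]]:
    """Intersect differentially expressed circRNAs with significant splicing
    events at the host-gene level.

    ``de_results`` is a classified DE frame (feature index, ``call`` column);
    only up/down rows enter the circ set. ``sig_events`` is the filtered
    splicing frame (``event_id``/``type``/``gene_id``/``IncLevelDifference``).
    ``gene_map`` maps circ feature ids to host genes; circs it cannot map are
    warned about and treated as their own single-circ "gene" (circ-only).
    """
    if gene_map is not None and not isinstance(gene_map, pd.Series):
        gene_map = pd.Series(gene_map)

    circ_genes: dict[str, list[tuple[str, str]]] = {}
    called = de_results[de_results["call"].isin(["up", "down"])]
    for circ_id, row in called.iterrows():
        gene = None
        if gene_map is not None and circ_id in gene_map.index:
            gene = gene_map[circ_id]
        if gene is None or (isinstance(gene, float) and pd.isna(gene)):
            warnings.warn(f"circRNA {circ_id!r} has no host-gene mapping; "
                          "treated as its own locus", stacklevel=2)
            gene = str(circ_id)
        circ_genes.setdefault(str(gene), []).append((str(circ_id), row["call"]))

    splice_genes: dict[str, list[tuple[str, str, float]]] = {}
    for _, row in sig_events.iterrows():
        splice_genes.setdefault(str(row["gene_id"]), []).append(
            (str(row["event_id"]), str(row["type"]), float(row["IncLevelDifference"])))

    shared = sorted(set(circ_genes) & set(splice_genes))
    counts = VennCounts(circ_only=len(set(circ_genes) - set(splice_genes)),
                        splice_only=len(set(splice_genes) - set(circ_genes)),
                        shared=len(shared))
    records = [OverlapRecord(g, sorted(circ_genes[g]), sorted(splice_genes[g]))
               for g in shared]
    return counts, records
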
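"""Scan chromosomes for the 5-bp Mu-type target consensus NYSRN.

The Mu transpososome duplicates a 5-bp target site with consensus NYSRN
(N = any base, Y = C/T, S = G/C, R = A/G) at both ends of each insertion.
The per-gene NYSRN frequency is the denominator of the transposition target
preference (TTP) score, so the scan must be deterministic and exact.

NYSRN is its own reverse-complement pattern, so a single-strand scan finds
every targetable window; scanning both strands would double every count
without changing any rank.  On uniform random DNA the per-position match
probability is 1 * 1/2 * 1/2 * 1/2 * 1 = 1/8.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .genome_io import GeneAnnotation, GenomeRecord

MOTIF_LENGTH = 5

#: NYSRN as a character-class regex; genomic N never matches (an N in the
#: chromosome is unknown sequence, not a wildcard), so masked regions
#: contribute zero motifs.  Lookahead keeps overlapping occurrences.
_NYSRN_RE = re.compile(r"(?=[ACGT][CT][GC][AG][ACGT])")


@dataclass(frozen=True)
class MotifTable:
    """Per-gene NYSRN counts plus the genome-wide position list.

    A motif occurrence is credited to a gene iff its full 5-nt span lies
    within the gene interval; boundary-spanning occurrences count only
    genome-wide.  Overlapping occurrences are all counted.
    """

    positions: tuple[int, ...]
    per_gene: Mapping[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return len(self.positions)


def scan_nysrn(genome: GenomeRecord) -> list[int]:
    """Return sorted start positions of NYSRN windows.

    On circular chromosomes windows crossing the origin are included; their
    start positions are reported modulo the genome length.
    """
    seq = genome.sequence
    if genome.topology == "circular" and len(seq) >= MOTIF_LENGTH:
        extended = seq + seq[: MOTIF_LENGTH - 1]
        hits = [m.start() for m in _NYSRN_RE.finditer(extended)]
        return sorted(h for h in hits if h < len(seq))
    return [m.start() for m in _NYSRN_RE.finditer(seq)]


def motif_count_per_gene(
    positions: Sequence[int], annotations: Sequence[GeneAnnotation]
) -> MotifTable:
    """Tabulate NYSRN occurrences per gene (full-containment crediting)."""
    per_gene = {g.gene_id: 0 for g in annotations}
    for g in annotations:
        per_gene[g.gene_id] = sum(
            1 for p in positions if g.start <= p and p + MOTIF_LENGTH <= g.end
        )
    return MotifTable(tuple(sorted(positions)), per_gene)


def write_motif_table(
    table: MotifTable, annotations: Sequence[GeneAnnotation], path
) -> None:
    genes = {g.gene_id: g for g in annotations}
    with open(path, "w") as fh:
        fh.write("gene_id\tgene_length\tmotif_count\n")
        for gid, count in table.per_gene.items():
            fh.write(f"{gid}\t{genes[gid].length}\t{count}\n")
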
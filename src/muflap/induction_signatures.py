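"""Detect spontaneous prophage induction (SPI) from cellular DNA reads.

Two mechanism-specific signatures:

* Mu-like (transposition) prophages replicate by copy-producing
  transposition, so cellular DNA from an induced subpopulation carries new
  5'flaps at the Mu genome ends (L_NEW / R_NEW).  Original flaps from the
  resident locus are expected in every lysogen and are not evidence.

* Integrase (site-specific) prophages excise by attL x attR recombination,
  restoring attP and joining the two prophage termini on the excised circle.
  20-mers spanning the attP junction (L-attP-R) occur on the circle but
  nowhere on the lysogen chromosome, so any read containing one is direct
  evidence of excision.

A simple read-start-pileup heuristic flags candidate cos/terminus positions
on phage genomes: packaging cuts concatemers at cos, so molecule ends (and
hence read 5' starts) pile up there far above the background fragmentation
rate.  This is deliberately a lightweight stand-in for full
terminal-redundancy analysis.

Matching is exact throughout; sequencing errors reduce sensitivity, not
specificity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import flap_analysis
from .genome_io import GenomeRecord, Lysogen, ProphageRecord, revcomp

SIGNATURE_K = 20

#: cos sequences of the two integrase-type citromicrobial prophages, as
#: determined from packaged-genome termini; shipped as test fixtures.
COS_PHI_D = "GGCGTGGCGTGGGGGCGAG"
COS_PHI_E = "CTACGCCCCAC"


@dataclass(frozen=True)
class JunctionSignature:
    """The L-attP-R junction of an excised circle and its signature 20-mers.

    ``junction_sequence`` is (last J nt of the prophage genome) + attP +
    (first J nt); ``signature_kmers`` are the junction 20-mers that span the
    full attP (or the junction midpoint when attP > 20 nt) and occur nowhere
    on the lysogen chromosome, either strand.
    """

    prophage_id: str
    junction_sequence: str
    signature_kmers: frozenset[str]


@dataclass(frozen=True)
class InductionReport:
    prophage_id: str
    mechanism: str
    evidence_count: int
    induced: bool
    min_evidence: int = 1


def build_attP_junction(
    prophage: ProphageRecord,
    lysogen: Lysogen,
    context: int = SIGNATURE_K,
) -> JunctionSignature:
    """Build the excised-circle junction and screen its 20-mers for
    chromosome uniqueness.

    The prophage genome excludes attP, so the circle reads
    ...R-terminus | attP | L-terminus... ; a signature k-mer must cover the
    whole attP (guaranteeing it cannot arise from attL or attR alone) and is
    discarded if it occurs anywhere on the lysogen chromosome or its reverse
    complement.
    """
    if prophage.mechanism != "site_specific":
        raise ValueError("attP junctions exist only for site-specific prophages")
    attp = prophage.attP
    J = max(context, SIGNATURE_K)
    genome = prophage.genome
    if len(genome) < J:
        raise ValueError("prophage genome shorter than junction context")
    junction = genome[-J:] + attp + genome[:J]

    if len(attp) <= SIGNATURE_K:
        lo = max(0, J + len(attp) - SIGNATURE_K)
        hi = min(len(junction) - SIGNATURE_K, J)
    else:
        warnings.warn(
            f"attP of {prophage.id} is longer than {SIGNATURE_K} nt; signature "
            "k-mers cover the junction midpoint instead of the full attP"
        )
        mid = J + len(attp) // 2
        lo = max(0, mid - SIGNATURE_K)
        hi = min(len(junction) - SIGNATURE_K, mid)
    candidates = {junction[i : i + SIGNATURE_K] for i in range(lo, hi + 1)}

    chrom = lysogen.host.sequence
    if lysogen.host.topology == "circular":
        chrom = chrom + chrom[: SIGNATURE_K - 1]
    chrom_rc = revcomp(chrom)
    kept = frozenset(
        k for k in candidates if k not in chrom and k not in chrom_rc
    )
    if not kept:
        warnings.warn(
            f"no chromosome-unique junction k-mers for {prophage.id}; "
            "the attP context re-occurs in the chromosome"
        )
    return JunctionSignature(prophage.id, junction, kept)


def _read_seqs(reads: Iterable[tuple[str, str]] | Iterable[str]) -> Iterable[str]:
    for item in reads:
        yield (item[1] if isinstance(item, tuple) else item).upper()


def detect_integrase_induction(
    cell_reads: Iterable[tuple[str, str]] | Iterable[str],
    signature: JunctionSignature,
    min_evidence: int = 1,
) -> InductionReport:
    """Count reads (either orientation) containing >= 1 signature k-mer."""
    if not signature.signature_kmers:
        raise ValueError(
            "empty junction signature: rebuild with more context or accept that "
            "this prophage's excision cannot be distinguished from the chromosome"
        )
    kmers = signature.signature_kmers
    evidence = 0
    for seq in _read_seqs(cell_reads):
        if any(k in seq for k in kmers) or any(k in revcomp(seq) for k in kmers):
            evidence += 1
    return InductionReport(
        signature.prophage_id, "site_specific", evidence,
        evidence >= min_evidence, min_evidence,
    )


def detect_mu_induction(
    cell_reads: Sequence[tuple[str, str]] | Sequence[str],
    prophage: ProphageRecord,
    lysogen: Lysogen,
    min_evidence: int = 1,
) -> InductionReport:
    """New 5'flaps in cellular reads evidence Mu-type replicative transposition.

    Delegates to the flap pipeline: extract around the prophage termini, map
    against the lysogen chromosome, classify; evidence is y (new flaps only —
    the resident locus contributes original flaps in any culture).
    """
    if prophage.mechanism != "transposition":
        raise ValueError("Mu-type detection applies to transposition prophages")
    flaps = flap_analysis.extract_flaps(cell_reads, prophage.genome)
    mapped = flap_analysis.map_flaps(flaps, lysogen.host)
    counts, _ = flap_analysis.classify_flaps(mapped, prophage, host_length=len(lysogen.host))
    return InductionReport(
        prophage.id, "transposition", counts.y, counts.y >= min_evidence, min_evidence
    )


def read_start_histogram(
    reads: Iterable[tuple[str, str]] | Iterable[str],
    genome: GenomeRecord,
) -> dict[str, np.ndarray]:
    """Histogram of read 5'-start positions per strand by exact placement.

    Each read is placed at its first exact match on the forward or reverse
    strand of ``genome`` (treated circularly when flagged); the 5' start of
    a reverse-strand read is the rightmost base of its forward-coordinate
    window.  Unplaceable reads are ignored.
    """
    seq = genome.sequence
    n = len(seq)
    ext = seq + seq if genome.topology == "circular" else seq
    hist = {"+": np.zeros(n, dtype=int), "-": np.zeros(n, dtype=int)}
    for r in _read_seqs(reads):
        i = ext.find(r)
        if i != -1 and i < n:
            hist["+"][i % n] += 1
            continue
        j = ext.find(revcomp(r))
        if j != -1 and j < n:
            hist["-"][(j + len(r) - 1) % n] += 1
    return hist


def detect_termini(
    start_histogram: Mapping[str, np.ndarray], fold: float = 20.0
) -> dict[str, list[int]]:
    """Positions whose read-start count is >= fold x the median nonzero
    start count, per strand.  Near-opposite-strand peak pairs are candidate
    cos/terminus ends; pairing is left to the caller's report."""
    out: dict[str, list[int]] = {}
    for strand, counts in start_histogram.items():
        counts = np.asarray(counts)
        nonzero = counts[counts > 0]
        if nonzero.size == 0:
            out[strand] = []
            continue
        threshold = fold * float(np.median(nonzero))
        out[strand] = [int(i) for i in np.nonzero(counts >= threshold)[0]]
    return out
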
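"""Domain model and I/O for genomes, gene annotations, and prophage records.

Coordinates are 0-based, half-open everywhere in this package; 1-based
inclusive coordinates appear only in rendered reports.  Sequences are
restricted to the alphabet ``{A, C, G, T, N}`` — IUPAC ambiguity codes other
than N are rejected at parse time, because the downstream flap and motif
machinery is defined on exact nucleotides.

Circular chromosomes are stored linearly with an explicit ``topology`` flag;
operations that need wrap-around (motif scanning, flap mapping) virtually
extend the sequence by ``k - 1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised on malformed input files or sequences."""


def revcomp(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_alphabet(seq: str, context: str = "sequence") -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_ALPHABET
    if bad:
        raise FormatError(
            f"{context} contains characters outside A,C,G,T,N: {sorted(bad)}"
        )
    return seq


@dataclass(frozen=True)
class GenomeRecord:
    """A chromosome or phage genome.

    ``topology`` distinguishes circular bacterial chromosomes from linear
    (e.g. cos-cut) molecules; the sequence itself is always stored linearly.
    """

    id: str
    sequence: str
    topology: Literal["circular", "linear"] = "linear"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"genome {self.id!r} has empty sequence")
        object.__setattr__(self, "sequence", _check_alphabet(self.sequence, f"genome {self.id!r}"))
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"bad topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval on a host chromosome with a functional category label.

    ``category`` is a caller-provided subsystem label (controlled vocabulary)
    or ``"hypothetical"``; wrap-around genes on circular chromosomes are
    represented as two intervals sharing a gene_id.
    """

    gene_id: str
    start: int
    end: int
    strand: Literal["+", "-"] = "+"
    category: str = "hypothetical"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: bad interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ProphageRecord:
    """An integrated prophage on a host chromosome.

    ``mechanism`` is either ``"transposition"`` (Mu-like: flanked by a
    duplicated 5-bp target site matching the NYSRN consensus) or
    ``"site_specific"`` (integrase-mediated: attL/attR junctions flanking the
    element, attP restored on the excised circle).  ``genome`` is the
    prophage sequence as integrated, i.e. ``host[left:right]``; the 5-bp
    duplication (transposition) and the att cores (site-specific) lie just
    outside the ``[left, right)`` interval.
    """

    id: str
    host_id: str
    left: int
    right: int
    mechanism: Literal["transposition", "site_specific"]
    genome: str
    target_dup: str | None = None  # transposition only, length 5
    attP: str | None = None        # site_specific only
    cos: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.left < self.right):
            raise ValueError(f"prophage {self.id}: bad interval [{self.left},{self.right})")
        object.__setattr__(self, "genome", _check_alphabet(self.genome, f"prophage {self.id}"))
        if self.mechanism == "transposition":
            if self.target_dup is None or len(self.target_dup) != 5:
                raise ValueError(f"prophage {self.id}: transposition requires a 5-nt target_dup")
            object.__setattr__(self, "target_dup", self.target_dup.upper())
        elif self.mechanism == "site_specific":
            if not self.attP:
                raise ValueError(f"prophage {self.id}: site_specific requires attP")
            object.__setattr__(self, "attP", self.attP.upper())
        else:
            raise ValueError(f"prophage {self.id}: unknown mechanism {self.mechanism!r}")
        if self.cos is not None:
            object.__setattr__(self, "cos", self.cos.upper())

    @property
    def length(self) -> int:
        return self.right - self.left


@dataclass(frozen=True)
class Lysogen:
    """A host chromosome together with its resident prophages."""

    host: GenomeRecord
    prophages: tuple[ProphageRecord, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "prophages", tuple(self.prophages))
        ivs = sorted((p.left, p.right, p.id) for p in self.prophages)
        for (l1, r1, i1), (l2, r2, i2) in zip(ivs, ivs[1:]):
            if l2 < r1:
                raise ValueError(f"prophages {i1} and {i2} overlap")
        for p in self.prophages:
            if p.host_id != self.host.id:
                raise ValueError(f"prophage {p.id} host_id {p.host_id!r} != host {self.host.id!r}")
            if p.right > len(self.host):
                raise ValueError(f"prophage {p.id} exceeds host length")
            if self.host.sequence[p.left:p.right] != p.genome:
                raise ValueError(f"prophage {p.id} genome does not match host[{p.left}:{p.right}]")


# ---------------------------------------------------------------------------
# FASTA

def read_genomes(path: str | Path, topology: str = "linear") -> list[GenomeRecord]:
    """Read all records of a FASTA file, preserving order."""
    records = [
        GenomeRecord(rec.id, str(rec.seq), topology)  # alphabet checked in ctor
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def read_genome(path: str | Path, topology: str = "linear") -> GenomeRecord:
    """Read a single-record FASTA file."""
    records = read_genomes(path, topology)
    if len(records) != 1:
        raise FormatError(f"expected one record in {path}, found {len(records)}")
    return records[0]


def write_genomes(genomes: Iterable[GenomeRecord], path: str | Path) -> None:
    recs = [SeqRecord(Seq(g.sequence), id=g.id, description="") for g in genomes]
    SeqIO.write(recs, str(path), "fasta")


def write_genome(genome: GenomeRecord, path: str | Path) -> None:
    write_genomes([genome], path)


# ---------------------------------------------------------------------------
# Annotations: 5-column TSV or GFF3

TSV_COLUMNS = ("gene_id", "start", "end", "strand", "category")


def read_annotations(path: str | Path, *, subsystem_key: str = "subsystem") -> list[GeneAnnotation]:
    """Read gene annotations from TSV (gene_id, start, end, strand, category)
    or GFF3 (decided by extension; the category is taken from the
    ``subsystem_key`` attribute, default "subsystem", falling back to
    "hypothetical")."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_gff3(path, subsystem_key)
    return _read_tsv(path)


def _read_tsv(path: Path) -> list[GeneAnnotation]:
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[:1] == ["gene_id"]:  # header
                continue
            if len(fields) != 5:
                raise FormatError(f"{path}:{ln}: expected 5 tab-separated fields")
            gid, start, end, strand, category = fields
            genes.append(GeneAnnotation(gid, int(start), int(end), strand, category))
    return genes


def _read_gff3(path: Path, subsystem_key: str) -> list[GeneAnnotation]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneAnnotation] = []
    for feat in db.all_features(order_by="start"):
        if feat.featuretype not in ("gene", "CDS"):
            continue
        gid = feat.attributes.get("ID", feat.attributes.get("locus_tag", [None]))[0]
        if gid is None:
            raise FormatError(f"{path}: feature without ID at {feat.start}")
        category = feat.attributes.get(subsystem_key, ["hypothetical"])[0]
        # GFF3 is 1-based inclusive; convert to 0-based half-open
        genes.append(GeneAnnotation(gid, feat.start - 1, feat.end, feat.strand, category))
    return genes


def write_annotations(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.start}\t{g.end}\t{g.strand}\t{g.category}\n")


# ---------------------------------------------------------------------------
# Prophage records: JSON schema

def write_prophages(prophages: Sequence[ProphageRecord], path: str | Path) -> None:
    payload = [
        {
            "id": p.id,
            "host_id": p.host_id,
            "left": p.left,
            "right": p.right,
            "mechanism": p.mechanism,
            "genome": p.genome,
            "target_dup": p.target_dup,
            "attP": p.attP,
            "cos": p.cos,
        }
        for p in prophages
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_prophages(path: str | Path) -> list[ProphageRecord]:
    payload = json.loads(Path(path).read_text())
    return [ProphageRecord(**entry) for entry in payload]


# ---------------------------------------------------------------------------
# BED intervals

def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read (chrom, start, end) triples from a BED file (0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append((chrom, int(start), int(end)))
    return out


# ---------------------------------------------------------------------------
# Reference reconstruction and masking

def reconstruct_attB_reference(lysogen: Lysogen) -> GenomeRecord:
    """Remove every prophage from the host chromosome, restoring the naive
    (pre-integration) sequence.

    For transposition-type prophages the flanking 5-bp target duplication is
    collapsed back to a single copy (the element plus its right-hand
    duplicate are excised).  For site-specific prophages the attL..attR span
    collapses to a single attB copy: the element plus one att core are
    excised, leaving the bacterial attachment site in place.
    """
    host = lysogen.host
    cuts: list[tuple[int, int]] = []
    for p in sorted(lysogen.prophages, key=lambda p: p.left):
        if p.mechanism == "transposition":
            # lysogen is ... dup5 [prophage] dup5 ... ; drop prophage + right dup
            lo, hi = p.left, p.right + 5
        else:
            # lysogen is ... attL(core) [prophage] attR(core) ...; prophage
            # interval starts right after attL, so dropping prophage + attR
            # leaves a single att core = attB
            lo, hi = p.left, p.right + len(p.attP)
        if hi > len(host):
            raise ValueError(f"prophage {p.id}: flank bookkeeping exceeds host length")
        if cuts and lo < cuts[-1][1]:
            raise ValueError("prophage excision intervals overlap")
        cuts.append((lo, hi))
    seq = host.sequence
    pieces = []
    pos = 0
    for lo, hi in cuts:
        pieces.append(seq[pos:lo])
        pos = hi
    pieces.append(seq[pos:])
    return GenomeRecord(host.id, "".join(pieces), host.topology)


def mask_regions(genome: GenomeRecord, intervals: Iterable[tuple[int, int]]) -> GenomeRecord:
    """Replace the given 0-based half-open intervals with N, length unchanged."""
    seq = list(genome.sequence)
    n = len(seq)
    for start, end in intervals:
        if not (0 <= start <= end <= n):
            raise ValueError(f"interval [{start},{end}) out of bounds for length {n}")
        seq[start:end] = "N" * (end - start)
    return replace(genome, sequence="".join(seq))
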
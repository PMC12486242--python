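"""Extract, map and classify host-derived 5'flaps from Mu-like phage reads.

Headful packaging of a Mu-like genome carries flanking host DNA into the
capsid.  The 20 nt of host sequence immediately outside each genome end (the
5'flap) identifies the chromosomal site the packaged copy occupied: flaps
matching the native prophage flanks are *original*, all other uniquely
mapping flaps are *new* and mark replicative-transposition targets.

Because each mature particle corresponds to one transposon copy, counting
original flaps (x) and new flaps (y) estimates the average burst size as
(x + y) / x = 1 + n, where n is the number of duplicated transposons per
cell at the end of the lytic cycle.

All matching is exact (no mismatches), mirroring a 100%-identity,
100%-coverage mapping policy: sequencing errors cost sensitivity, never
specificity.  The module operates in memory at synthetic/desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

from .genome_io import GenomeRecord, ProphageRecord, revcomp

FLAP_LEN = 20


@dataclass(frozen=True)
class Flap:
    """A host-derived flap adjacent to one prophage genome end.

    The sequence is stored in prophage-strand orientation (reads are
    canonicalized before anchoring).  ``host_position`` is the 0-based start
    of the flap's 20-mer on the host forward strand, filled by ``map_flaps``.
    """

    end: Literal["L", "R"]
    sequence: str
    read_id: str = ""
    host_position: int | None = None
    host_strand: Literal["+", "-"] | None = None
    flap_class: Literal["original", "new", "unmapped", "ambiguous", "unclassified"] = "unclassified"

    def __post_init__(self) -> None:
        if len(self.sequence) != FLAP_LEN:
            raise ValueError(f"flap must be {FLAP_LEN} nt, got {len(self.sequence)}")


@dataclass(frozen=True)
class FlapCounts:
    """Partition of extracted flaps: x original, y new, plus rejects."""

    x: int
    y: int
    unmapped: int = 0
    ambiguous: int = 0

    @property
    def total(self) -> int:
        return self.x + self.y + self.unmapped + self.ambiguous


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def extract_flaps(
    reads: Iterable[tuple[str, str]] | Iterable[str],
    prophage_genome: str,
    flap_len: int = FLAP_LEN,
    anchor_len: int = 20,
) -> list[Flap]:
    """Pull flap_len-nt flaps from reads anchored on the prophage termini.

    A flap is emitted when a read (in either orientation) contains an exact
    ``anchor_len``-nt match to a prophage terminal segment with at least
    ``flap_len`` nt outward of it; the outward ``flap_len`` nt are the flap.
    Reads shorter than ``anchor_len + flap_len`` are skipped.

    ``reads`` may be plain sequences or (read_id, sequence) pairs.
    """
    if flap_len != FLAP_LEN:
        raise ValueError("flap length is fixed at 20 nt")
    prophage_genome = prophage_genome.upper()
    if len(prophage_genome) < anchor_len:
        raise ValueError("prophage genome shorter than anchor length")
    l_anchor = prophage_genome[:anchor_len]
    r_anchor = prophage_genome[-anchor_len:]
    min_len = anchor_len + flap_len

    flaps: list[Flap] = []
    for idx, item in enumerate(reads):
        read_id, seq = item if isinstance(item, tuple) else (f"read{idx}", item)
        seq = seq.upper()
        if len(seq) < min_len:
            continue
        for oriented in (seq, revcomp(seq)):
            for i in _find_all(oriented, l_anchor):
                if i >= flap_len:
                    flaps.append(Flap("L", oriented[i - flap_len : i], read_id))
            for j in _find_all(oriented, r_anchor):
                end = j + anchor_len
                if end + flap_len <= len(oriented):
                    flaps.append(Flap("R", oriented[end : end + flap_len], read_id))
    return flaps


def map_flaps(flaps: Sequence[Flap], host_genome: GenomeRecord) -> list[Flap]:
    """Fill host_position by exact substring search against the host.

    A flap maps iff its 20-mer occurs exactly once on the host chromosome
    considering both strands (and origin-crossing windows on circular
    chromosomes); multi-occurrence flaps become ``ambiguous``, absent ones
    ``unmapped``.  Position is the forward-strand start of the matched
    window, reported modulo the chromosome length.
    """
    host = host_genome.sequence
    n = len(host)
    search = host + host[: FLAP_LEN - 1] if host_genome.topology == "circular" else host

    cache: dict[str, tuple[int | None, str | None, str]] = {}

    def locate(seq: str) -> tuple[int | None, str | None, str]:
        if seq in cache:
            return cache[seq]
        fwd = [p % n for p in _find_all(search, seq)]
        rc = revcomp(seq)
        rev = [] if rc == seq else [p % n for p in _find_all(search, rc)]
        hits = [(p, "+") for p in fwd] + [(p, "-") for p in rev]
        if len(hits) == 1:
            res = (hits[0][0], hits[0][1], "mapped")
        elif hits:
            res = (None, None, "ambiguous")
        else:
            res = (None, None, "unmapped")
        cache[seq] = res
        return res

    out = []
    for f in flaps:
        pos, strand, status = locate(f.sequence)
        if status == "mapped":
            out.append(replace(f, host_position=pos, host_strand=strand, flap_class="unclassified"))
        else:
            out.append(replace(f, flap_class=status))
    return out


def classify_flaps(
    mapped_flaps: Sequence[Flap], prophage: ProphageRecord, host_length: int | None = None
) -> tuple[FlapCounts, list[Flap]]:
    """Split mapped flaps into original (native-locus) vs new.

    A flap is *original* iff it sits at the host window immediately flanking
    the native prophage on the matching side: the 20 nt upstream of the left
    boundary (L) or downstream of the right boundary (R), forward strand.
    Those windows contain the 5-bp target duplication at their prophage-
    proximal edge, exactly as the flaps of re-inserted copies do, so both
    locus classes are measured with the same ruler.  Everything else that
    maps uniquely is *new*.

    Returns the counts and the flap list with ``flap_class`` filled.
    """
    if prophage.left is None or prophage.right is None:
        raise ValueError("prophage coordinates are required for classification")
    n = host_length
    orig_l = prophage.left - FLAP_LEN
    if n is not None:
        orig_l %= n
    orig_r = prophage.right % n if n is not None else prophage.right

    x = y = unmapped = ambiguous = 0
    out = []
    for f in mapped_flaps:
        if f.flap_class == "unmapped":
            unmapped += 1
            out.append(f)
            continue
        if f.flap_class == "ambiguous":
            ambiguous += 1
            out.append(f)
            continue
        if f.host_position is None:
            raise ValueError("flap not mapped; run map_flaps first")
        is_original = (
            f.host_strand == "+"
            and (
                (f.end == "L" and f.host_position == orig_l)
                or (f.end == "R" and f.host_position == orig_r)
            )
        )
        if is_original:
            x += 1
            out.append(replace(f, flap_class="original"))
        else:
            y += 1
            out.append(replace(f, flap_class="new"))
    return FlapCounts(x, y, unmapped, ambiguous), out


def burst_size(counts: FlapCounts) -> float:
    """Average burst size from flap counts: (x + y) / x = 1 + y/x.

    Undefined when no original flaps were recovered (x = 0).
    """
    if counts.x < 1:
        raise ValueError(
            "burst size undefined: no original 5'flaps recovered (x = 0); "
            "check prophage coordinates or sequencing depth"
        )
    return (counts.x + counts.y) / counts.x


def dedup_flaps(flaps: Sequence[Flap]) -> list[Flap]:
    """Collapse flaps with identical (end, sequence), keeping first occurrence.

    The default burst-size estimator counts every read occurrence (reads are
    the particle proxy); this opt-in mode counts each distinct flap once.
    """
    seen: set[tuple[str, str]] = set()
    out = []
    for f in flaps:
        key = (f.end, f.sequence)
        if key not in seen:
            seen.add(key)
            out.append(f)
    return out


def write_flap_table(flaps: Sequence[Flap], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tend\tflap_seq\thost_position\tstrand\tclass\n")
        for f in flaps:
            pos = "" if f.host_position is None else f.host_position
            strand = f.host_strand or ""
            fh.write(f"{f.read_id}\t{f.end}\t{f.sequence}\t{pos}\t{strand}\t{f.flap_class}\n")
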
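"""Ground-truthed synthetic data emulating a polylysogen induction study.

The generator builds, from a single seed: a circular host chromosome with
annotated genes; a resident Mu-like prophage inserted at an NYSRN site with
the 5-bp target duplication; an optional integrase-type prophage flanked by
attL/attR with a cos site; replicative-transposition events with planted
per-category target preferences; headful-packaged particle molecules
(flanking host DNA on both ends); particle and cellular sequencing reads;
and paired host/phage metagenome count tables following a power law.

Every stage records its ground truth so downstream estimators (flap
extraction, burst size, TTP enrichment, induction detection, log-log slope)
can be validated without re-simulation.  All randomness flows from
``SimulationConfig.seed``; identical configs give identical bytes.

Default condition choices (documented in the methods note): 50-kb
chromosome with 40 genes of 800 bp; target-preference multipliers 10x (hot)
/ 0x (cold) / 1x baseline, with category sizes 18/18/4 so that both
enrichment and depletion can reach P < .01 in ~7-gene bins; 150 nt of host
DNA packaged per end; transposition targets drawn without replacement by
default (distinct sites, making the burst identity 1 + n exact), with a
with-replacement mode for population-scale event counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .flap_analysis import FLAP_LEN
from .genome_io import (
    GeneAnnotation,
    GenomeRecord,
    Lysogen,
    ProphageRecord,
    revcomp,
)
from .motif_scan import MOTIF_LENGTH, scan_nysrn

HOT_CATEGORY = "prophage_competitor"
COLD_CATEGORY = "respiration"
BASE_CATEGORY = "hypothetical"


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; every default is a study condition."""

    seed: int = 0
    genome_length: int = 50_000
    n_genes: int = 40
    gene_length: int = 800  # mean; individual genes drawn in [0.5, 1.5] x mean
    n_hot_genes: int = 18
    n_cold_genes: int = 18
    hot_multiplier: float = 10.0
    cold_multiplier: float = 0.0
    # prophages
    mu_genome_length: int = 2_000
    include_site_specific: bool = True
    ss_genome_length: int = 2_000
    attP_length: int = 12
    cos_length: int = 12
    immunity_margin: int = 100  # nt around the resident Mu excluded from targeting
    # transposition / packaging / particle reads
    n_events: int = 5
    with_replacement: bool = False
    flank_capture: int = 150
    read_length: int = 100
    depth: float = 30.0
    error_rate: float = 0.0
    # cellular DNA
    spi_rate: float = 0.0
    cell_reads: int = 30_000
    cell_read_length: int = 150
    n_induction_sites: int = 3
    terminal_read_fraction: float = 0.3
    # metagenome
    n_samples: int = 60
    meta_slope: float = 0.5
    meta_intercept_log10: float = 0.0
    meta_noise_sd: float = 0.2
    host_log10_mean: float = 0.5
    host_log10_sd: float = 0.4
    host_length_bp: int = 3_000_000
    phage_length_bp: int = 40_000
    sample_size_bp: float = 1e9

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


@dataclass(frozen=True)
class TranspositionEvent:
    """One replicative-transposition event at NYSRN site ``position``."""

    position: int
    target_dup: str
    gene_id: str | None


@dataclass
class GroundTruth:
    naive_genome: GenomeRecord | None = None
    annotations: list[GeneAnnotation] = field(default_factory=list)
    mu_insertion_site: int | None = None
    events: list[TranspositionEvent] = field(default_factory=list)
    per_gene_events: dict[str, int] = field(default_factory=dict)
    molecules: list[tuple[str, str]] = field(default_factory=list)
    induced_read_counts: dict[str, int] = field(default_factory=dict)
    induction_sites: list[int] = field(default_factory=list)
    cos_cut_position: int | None = None
    true_slope: float | None = None


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def cslice(seq: str, start: int, length: int) -> str:
    """``length`` characters starting at ``start`` on a circular sequence."""
    n = len(seq)
    if length > n:
        raise ValueError("slice longer than sequence")
    start %= n
    if start + length <= n:
        return seq[start : start + length]
    return seq[start:] + seq[: start + length - n]


# ---------------------------------------------------------------------------
# Lysogen construction

def make_lysogen(config: SimulationConfig) -> tuple[Lysogen, list[GeneAnnotation], GroundTruth]:
    """Build a polylysogen: random chromosome + genes + prophages.

    The Mu-like prophage is inserted at an intergenic NYSRN site with the
    5-bp target duplication flanking both ends; the optional integrase-type
    prophage replaces a planted attB core with attL + genome + attR
    (attL = attR = attP = attB core, the identical-core model) and carries a
    cos site.  Gene coordinates are shifted onto lysogen coordinates.
    """
    rng = config.rng(1)
    L = config.genome_length
    lengths = rng.integers(
        config.gene_length // 2, config.gene_length * 3 // 2 + 1, config.n_genes
    )
    span = int(lengths.sum())
    if span + 2 * (config.n_genes + 1) > L:
        raise ValueError("genome too small for requested genes")
    naive = _random_dna(rng, L)

    gap = (L - span) // (config.n_genes + 1)
    genes_naive: list[tuple[str, int, int]] = []
    pos = gap
    for i, glen in enumerate(lengths):
        genes_naive.append((f"gene{i:03d}", pos, pos + int(glen)))
        pos += int(glen) + gap

    if config.n_hot_genes + config.n_cold_genes > config.n_genes:
        raise ValueError("hot + cold gene counts exceed n_genes")
    categories = (
        [HOT_CATEGORY] * config.n_hot_genes
        + [COLD_CATEGORY] * config.n_cold_genes
        + [BASE_CATEGORY] * (config.n_genes - config.n_hot_genes - config.n_cold_genes)
    )
    rng.shuffle(categories)

    # --- choose an intergenic NYSRN site for the Mu prophage
    genic = np.zeros(L, dtype=bool)
    for _, s, e in genes_naive:
        genic[s:e] = True
    sites = [
        p
        for p in scan_nysrn(GenomeRecord("naive", naive, "circular"))
        if p + MOTIF_LENGTH <= L and not genic[p : p + MOTIF_LENGTH].any()
        and config.flank_capture < p < L - config.flank_capture - MOTIF_LENGTH
    ]
    if not sites:
        raise ValueError("no intergenic NYSRN site available for Mu insertion")
    mu_site = int(sites[rng.integers(0, len(sites))])
    mu_genome = _random_dna(rng, config.mu_genome_length)
    dup = naive[mu_site : mu_site + MOTIF_LENGTH]

    # --- optional site-specific prophage in a downstream intergenic gap
    insertions: list[tuple[int, str, str]] = [(mu_site, "mu", mu_genome)]
    attB = attB_pos = ss_genome = cos = None
    if config.include_site_specific:
        # plant attB mid-way through the last intergenic gap
        last_gene_end = genes_naive[-1][2]
        attB_pos = (last_gene_end + L - config.attP_length) // 2
        if attB_pos <= mu_site + MOTIF_LENGTH:
            raise ValueError("no room for the site-specific prophage")
        attB = _random_dna(rng, config.attP_length)
        naive = naive[:attB_pos] + attB + naive[attB_pos + config.attP_length :]
        ss_genome = _random_dna(rng, config.ss_genome_length)
        cos_pos = config.ss_genome_length // 3
        cos = ss_genome[cos_pos : cos_pos + config.cos_length]
        insertions.append((attB_pos, "ss", ss_genome))
        # re-check: attB planting must not destroy the chosen Mu site
        if not (mu_site + MOTIF_LENGTH <= attB_pos):
            raise ValueError("attB overlaps Mu insertion site")

    # --- apply insertions right-to-left so earlier coordinates are stable
    lys_seq = naive
    shifts: list[tuple[int, int]] = []  # (naive position, inserted length)
    prophages: list[dict] = []
    for ipos, kind, genome_seq in sorted(insertions, reverse=True):
        if kind == "mu":
            # naive ... [dup at ipos] ... -> ... dup + MU + dup ...
            lys_seq = lys_seq[: ipos + MOTIF_LENGTH] + genome_seq + lys_seq[ipos:]
            shifts.append((ipos, len(genome_seq) + MOTIF_LENGTH))
            prophages.append(
                dict(kind="mu", naive_pos=ipos, left=ipos + MOTIF_LENGTH,
                     genome=genome_seq, target_dup=dup)
            )
        else:
            # naive ... [attB core at ipos] ... -> ... attL + SS + attR ...
            core_end = ipos + config.attP_length
            lys_seq = lys_seq[:core_end] + genome_seq + attB + lys_seq[core_end:]
            shifts.append((ipos, len(genome_seq) + config.attP_length))
            prophages.append(
                dict(kind="ss", naive_pos=ipos, left=core_end,
                     genome=genome_seq, attP=attB, cos=cos)
            )

    def lys_coord(naive_pos: int) -> int:
        return naive_pos + sum(ln for p, ln in shifts if p < naive_pos)

    host = GenomeRecord("synthetic_host", lys_seq, "circular")
    records = []
    for p in prophages:
        left = lys_coord(p["naive_pos"]) + (
            MOTIF_LENGTH if p["kind"] == "mu" else config.attP_length
        )
        if p["kind"] == "mu":
            records.append(
                ProphageRecord("phiMu", host.id, left, left + len(p["genome"]),
                               "transposition", p["genome"], target_dup=p["target_dup"])
            )
        else:
            records.append(
                ProphageRecord("phiInt", host.id, left, left + len(p["genome"]),
                               "site_specific", p["genome"], attP=p["attP"], cos=p["cos"])
            )
    records.sort(key=lambda r: r.left)
    lysogen = Lysogen(host, tuple(records))

    annotations = [
        GeneAnnotation(gid, lys_coord(s), lys_coord(s) + (e - s), "+", cat)
        for (gid, s, e), cat in zip(genes_naive, categories)
    ]
    truth = GroundTruth(
        naive_genome=GenomeRecord("synthetic_host", naive, "circular"),
        annotations=annotations,
        mu_insertion_site=mu_site,
    )
    return lysogen, annotations, truth


# ---------------------------------------------------------------------------
# Replicative transposition

def _mu_prophage(lysogen: Lysogen) -> ProphageRecord:
    for p in lysogen.prophages:
        if p.mechanism == "transposition":
            return p
    raise ValueError("lysogen has no Mu-like (transposition) prophage")


def target_site_weights(
    lysogen: Lysogen,
    annotations: Sequence[GeneAnnotation],
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """NYSRN sites on the lysogen chromosome with sampling weights.

    Sites inside (or within ``immunity_margin`` of) the resident Mu prophage
    get weight 0 (transposition self-immunity); sites fully inside a gene
    inherit its category multiplier; intergenic sites weigh 1.
    """
    mu = _mu_prophage(lysogen)
    positions = np.array(scan_nysrn(lysogen.host), dtype=int)
    mult = {
        HOT_CATEGORY: config.hot_multiplier,
        COLD_CATEGORY: config.cold_multiplier,
    }
    weights = np.ones(len(positions))
    lo = mu.left - config.immunity_margin - MOTIF_LENGTH
    hi = mu.right + config.immunity_margin
    weights[(positions > lo) & (positions < hi)] = 0.0
    for g in annotations:
        inside = (positions >= g.start) & (positions + MOTIF_LENGTH <= g.end)
        weights[inside] = mult.get(g.category, 1.0)
    return positions, weights


def simulate_replicative_transposition(
    lysogen: Lysogen,
    annotations: Sequence[GeneAnnotation],
    config: SimulationConfig,
) -> list[TranspositionEvent]:
    """Draw n_events NYSRN target sites with category-weighted probability.

    Without replacement (default) every event occupies a distinct site; with
    replacement models independent events across a cell population.
    """
    rng = config.rng(2)
    positions, weights = target_site_weights(lysogen, annotations, config)
    eligible = weights > 0
    if not config.with_replacement and config.n_events > int(eligible.sum()):
        raise ValueError(
            f"n_events={config.n_events} exceeds {int(eligible.sum())} eligible NYSRN sites"
        )
    if config.n_events == 0:
        return []
    p = weights / weights.sum()
    chosen = rng.choice(positions, size=config.n_events,
                        replace=config.with_replacement, p=p)
    host = lysogen.host.sequence

    def containing_gene(q: int) -> str | None:
        for g in annotations:
            if g.start <= q and q + MOTIF_LENGTH <= g.end:
                return g.gene_id
        return None

    return [
        TranspositionEvent(int(q), cslice(host, int(q), MOTIF_LENGTH), containing_gene(int(q)))
        for q in sorted(int(c) for c in chosen)
    ]


# ---------------------------------------------------------------------------
# Headful packaging and reads

def simulate_headful_packaging(
    lysogen: Lysogen,
    events: Sequence[TranspositionEvent],
    config: SimulationConfig,
) -> list[tuple[str, str]]:
    """One packaged molecule per transposon copy: the original locus plus one
    per event, each ``flank_capture`` nt of host context + prophage genome +
    ``flank_capture`` nt of context.  The 5-bp target duplication sits at the
    prophage-proximal edge of both flanks."""
    if config.flank_capture < FLAP_LEN:
        raise ValueError("flank_capture must be >= 20 nt")
    mu = _mu_prophage(lysogen)
    host = lysogen.host.sequence
    f = config.flank_capture
    molecules = [
        ("orig", cslice(host, mu.left - f, f) + mu.genome + cslice(host, mu.right, f))
    ]
    for i, ev in enumerate(events):
        q = ev.position
        left_flank = cslice(host, q - f + MOTIF_LENGTH, f)   # ends with the dup
        right_flank = cslice(host, q, f)                     # starts with the dup
        molecules.append((f"ev{i:05d}", left_flank + mu.genome + right_flank))
    return molecules


def simulate_reads(
    molecules: Sequence[tuple[str, str]],
    config: SimulationConfig,
    mode: Literal["uniform", "tile_junctions"] = "uniform",
    tile_step: int = 1,
) -> list[tuple[str, str]]:
    """Fragment packaged molecules into reads.

    ``uniform``: random fragment starts at mean coverage ``depth``, random
    strand, per-base substitution errors at ``error_rate``.

    ``tile_junctions``: deterministic, error-free windows fully covering the
    20-nt flap + 20-nt anchor at each molecule end, every ``tile_step``
    offsets, alternating strands — a lossless junction census giving every
    molecule end the identical read count, so the burst identity 1 + n is
    exact.
    """
    rng = config.rng(3)
    rl = config.read_length
    reads: list[tuple[str, str]] = []
    junction_span = 2 * FLAP_LEN  # flap + anchor
    for mol_id, seq in molecules:
        n = len(seq)
        if rl > n:
            raise ValueError(f"read_length {rl} exceeds molecule {mol_id} ({n} nt)")
        if mode == "tile_junctions":
            f = config.flank_capture
            regions = [(f - FLAP_LEN, f + FLAP_LEN), (n - f - FLAP_LEN, n - f + FLAP_LEN)]
            for lo, hi in regions:
                first = max(0, hi - rl)
                last = min(lo, n - rl)
                for s in range(first, last + 1, tile_step):
                    frag = seq[s : s + rl]
                    if s % 2:
                        frag = revcomp(frag)
                    reads.append((f"{mol_id}:{s}", frag))
        elif mode == "uniform":
            n_reads = max(1, int(round(config.depth * n / rl)))
            starts = rng.integers(0, n - rl + 1, size=n_reads)
            strands = rng.random(n_reads) < 0.5
            for idx, (s, flip) in enumerate(zip(starts, strands)):
                frag = seq[s : s + rl]
                if config.error_rate > 0:
                    frag = _mutate(frag, config.error_rate, rng)
                if flip:
                    frag = revcomp(frag)
                reads.append((f"{mol_id}:u{idx}", frag))
        else:
            raise ValueError(f"unknown read mode {mode!r}")
    return reads


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if hits.size:
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        for i in hits:
            choices = bases[bases != arr[i]]
            arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# Cellular DNA with rare induction

def excised_circle_linear(prophage: ProphageRecord) -> tuple[str, int]:
    """Excised circle (genome + attP) linearized at the cos cut.

    Returns the linear sequence and the cut position in circle coordinates
    (the planted terminus detect_termini should recover).
    """
    if prophage.mechanism != "site_specific":
        raise ValueError("excision circles exist only for site-specific prophages")
    circle = prophage.genome + prophage.attP
    if prophage.cos:
        cut = circle.find(prophage.cos)
        if cut == -1:
            raise ValueError(f"cos sequence of {prophage.id} not found in its genome")
    else:
        cut = 0
    return circle[cut:] + circle[:cut], cut


def simulate_cellular_dna(
    lysogen: Lysogen,
    annotations: Sequence[GeneAnnotation],
    config: SimulationConfig,
) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Chromosome reads plus, at proportion ``spi_rate``, reads from
    induction molecules: Mu transposed copies and/or cos-linearized excised
    circles.  Terminal reads (starting exactly at a molecule end) are
    emitted at ``terminal_read_fraction`` of circle reads, modelling
    molecule ends as obligate fragment boundaries."""
    if not 0.0 <= config.spi_rate <= 1.0:
        raise ValueError("spi_rate must be in [0, 1]")
    rng = config.rng(4)
    host = lysogen.host.sequence
    rl = config.cell_read_length
    truth = GroundTruth()

    # molecules grouped per prophage so each prophage is induced equally often
    induction_pool: dict[str, list[str]] = {}
    if config.spi_rate > 0:
        for p in lysogen.prophages:
            if p.mechanism == "transposition":
                ev_cfg = dc_replace(
                    config, n_events=config.n_induction_sites,
                    hot_multiplier=1.0, cold_multiplier=1.0, with_replacement=False,
                )
                events = simulate_replicative_transposition(lysogen, annotations, ev_cfg)
                truth.induction_sites = [e.position for e in events]
                induction_pool[p.id] = [
                    mol for _, mol in simulate_headful_packaging(lysogen, events, config)[1:]
                ]
            else:
                linear, cut = excised_circle_linear(p)
                truth.cos_cut_position = cut
                induction_pool[p.id] = [linear]
    pool_ids = sorted(induction_pool)

    reads: list[tuple[str, str]] = []
    counts: dict[str, int] = {p.id: 0 for p in lysogen.prophages}
    is_induced = rng.random(config.cell_reads) < config.spi_rate
    for i in range(config.cell_reads):
        if is_induced[i] and pool_ids:
            pid = pool_ids[rng.integers(0, len(pool_ids))]
            mols = induction_pool[pid]
            mol = mols[rng.integers(0, len(mols))]
            counts[pid] += 1
            n = len(mol)
            if rng.random() < config.terminal_read_fraction:
                if rng.random() < 0.5:
                    frag = mol[:rl]
                else:
                    frag = revcomp(mol[n - rl :])
            else:
                s = int(rng.integers(0, n - rl + 1))
                frag = mol[s : s + rl]
                if rng.random() < 0.5:
                    frag = revcomp(frag)
            label = f"spi{i}"
        else:
            s = int(rng.integers(0, len(host)))
            frag = cslice(host, s, rl)
            if rng.random() < 0.5:
                frag = revcomp(frag)
            label = f"cell{i}"
        if config.error_rate > 0:
            frag = _mutate(frag, config.error_rate, rng)
        reads.append((label, frag))
    truth.induced_read_counts = counts
    return reads, truth


# ---------------------------------------------------------------------------
# Metagenome count tables

def simulate_metagenome_counts(config: SimulationConfig):
    """Paired cellular/virion count tables following a planted power law.

    Host log10 RPKM is normal; phage log10 RPKM = intercept + slope * host +
    noise.  Counts are emitted as expected read numbers consistent with the
    RPKM formula, so a noise-free simulation is recovered exactly by the
    estimator.  Returns (records, true_slope).
    """
    from .phage_ecology import AbundanceRecord

    if config.n_samples < 3:
        raise ValueError("need at least 3 samples")
    rng = config.rng(5)
    log_host = rng.normal(config.host_log10_mean, config.host_log10_sd, config.n_samples)
    noise = (
        rng.normal(0.0, config.meta_noise_sd, config.n_samples)
        if config.meta_noise_sd > 0
        else np.zeros(config.n_samples)
    )
    log_phage = config.meta_intercept_log10 + config.meta_slope * log_host + noise

    def reads_for(rpkm_value: float, length: int) -> float:
        return rpkm_value * (length / 1_000.0) * (config.sample_size_bp / 1_000_000.0)

    records = []
    for i in range(config.n_samples):
        st = f"ST{i:03d}"
        host_rpkm = 10.0 ** log_host[i]
        phage_rpkm = 10.0 ** log_phage[i]
        records.append(
            AbundanceRecord(
                f"{st}_cell", st, "cellular", "host_genome", "host",
                reads_for(host_rpkm, config.host_length_bp),
                config.host_length_bp, config.sample_size_bp,
            ).with_rpkm()
        )
        records.append(
            AbundanceRecord(
                f"{st}_vir", st, "virion", "prophage_genome", "prophage",
                reads_for(phage_rpkm, config.phage_length_bp),
                config.phage_length_bp, config.sample_size_bp,
            ).with_rpkm()
        )
    return records, config.meta_slope
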
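"""End-to-end experiment runners over the synthetic-data generator.

Each function wires generator -> estimator for one question the package
answers: flap-based burst size, transposition target preference hot/cold
spots, spontaneous-induction detection, and phage-host abundance scaling.
They are the single implementation used by the analysis scripts, the test
suite, and the acceptance recomputation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import flap_analysis as fa
from . import induction_signatures as isg
from . import motif_scan as ms
from . import phage_ecology as pe
from . import synthetic_data as sd
from . import ttp_enrichment as te
from .genome_io import GenomeRecord, Lysogen, revcomp


@dataclass(frozen=True)
class BurstRun:
    n_events: int
    counts: fa.FlapCounts
    burst: float


def _mu(lysogen: Lysogen):
    return next(p for p in lysogen.prophages if p.mechanism == "transposition")


def _flap_counts(lysogen, reads):
    mu = _mu(lysogen)
    flaps = fa.extract_flaps(reads, mu.genome)
    mapped = fa.map_flaps(flaps, lysogen.host)
    return fa.classify_flaps(mapped, mu, host_length=len(lysogen.host))


def run_burst_experiment(
    seed: int,
    n_events: int,
    subsample_fraction: float | None = None,
    subsample_seed: int = 0,
) -> BurstRun:
    """Simulate n_events transpositions, package, tile junctions losslessly,
    and estimate burst size; optionally subsample reads first.

    With lossless junction tiling the estimate equals 1 + n exactly.
    """
    with_replacement = n_events > 2_000
    cfg = sd.SimulationConfig(
        seed=seed, n_events=n_events, with_replacement=with_replacement,
        hot_multiplier=1.0, cold_multiplier=1.0,
    )
    lysogen, annotations, _ = sd.make_lysogen(cfg)
    events = sd.simulate_replicative_transposition(lysogen, annotations, cfg)
    molecules = sd.simulate_headful_packaging(lysogen, events, cfg)
    reads = sd.simulate_reads(molecules, cfg, mode="tile_junctions")
    if subsample_fraction is not None:
        rng = np.random.default_rng((seed, subsample_seed, 7))
        keep = rng.random(len(reads)) < subsample_fraction
        reads = [r for r, k in zip(reads, keep) if k]
    counts, _ = _flap_counts(lysogen, reads)
    return BurstRun(n_events, counts, fa.burst_size(counts))


@dataclass(frozen=True)
class TTPRun:
    calls: dict[str, str]
    rows: list[te.TTPRow]
    enrichment: list[te.EnrichmentResult]
    counts: fa.FlapCounts


def run_ttp_experiment(
    seed: int,
    hot_multiplier: float = 10.0,
    cold_multiplier: float = 0.0,
    n_events: int = 5_000,
) -> TTPRun:
    """Full TTP pipeline on a simulated lysogen: transposition with planted
    per-category preference, headful packaging, junction reads, flap
    extraction/mapping, NYSRN normalization, six-bin ranking, hypergeometric
    enrichment, hot/cold calls.

    Population-scale event counts are drawn with replacement (independent
    cells may target the same site); one junction read per molecule end.
    """
    cfg = sd.SimulationConfig(
        seed=seed, n_events=n_events, with_replacement=True,
        hot_multiplier=hot_multiplier, cold_multiplier=cold_multiplier,
    )
    lysogen, annotations, _ = sd.make_lysogen(cfg)
    events = sd.simulate_replicative_transposition(lysogen, annotations, cfg)
    molecules = sd.simulate_headful_packaging(lysogen, events, cfg)
    reads = sd.simulate_reads(molecules, cfg, mode="tile_junctions", tile_step=61)
    counts, classified = _flap_counts(lysogen, reads)
    table = ms.motif_count_per_gene(ms.scan_nysrn(lysogen.host), annotations)
    rows, _ = te.ttp_scores(classified, annotations, table)
    binned = te.bin_genes(rows)
    enrichment = te.category_enrichment(binned)
    calls = {c.category: c.call for c in te.call_spots(enrichment)}
    return TTPRun(calls, binned, enrichment, counts)


@dataclass(frozen=True)
class InductionRun:
    mu_evidence: int
    integrase_evidence: int
    cos_cut_position: int | None
    detected_termini: list[int]


def run_induction_experiment(seed: int, spi_rate: float) -> InductionRun:
    """Cellular-DNA simulation plus both induction detectors and the
    read-start terminus scan on the excised circle."""
    cfg = sd.SimulationConfig(seed=seed, spi_rate=spi_rate)
    lysogen, annotations, _ = sd.make_lysogen(cfg)
    reads, truth = sd.simulate_cellular_dna(lysogen, annotations, cfg)
    mu = _mu(lysogen)
    ss = next(p for p in lysogen.prophages if p.mechanism == "site_specific")
    mu_rep = isg.detect_mu_induction(reads, mu, lysogen)
    sig = isg.build_attP_junction(ss, lysogen)
    int_rep = isg.detect_integrase_induction(reads, sig)
    circle = GenomeRecord("circle", ss.genome + ss.attP, "circular")
    hist = isg.read_start_histogram(reads, circle)
    termini = isg.detect_termini(hist)["+"]
    return InductionRun(
        mu_rep.evidence_count, int_rep.evidence_count,
        truth.cos_cut_position, termini,
    )


@dataclass(frozen=True)
class CosRun:
    cut_position: int
    detected_termini: list[int]

    @property
    def recovered(self) -> bool:
        return self.cut_position in self.detected_termini


def run_cos_terminus_experiment(seed: int, n_reads: int = 2_000) -> CosRun:
    """Emulate sequencing of induced integrase-phage particles: reads from
    cos-linearized excised circles (molecule ends are obligate fragment
    boundaries), then read-start terminus detection on the circle."""
    cfg = sd.SimulationConfig(seed=seed)
    lysogen, _, _ = sd.make_lysogen(cfg)
    ss = next(p for p in lysogen.prophages if p.mechanism == "site_specific")
    linear, cut = sd.excised_circle_linear(ss)
    rng = np.random.default_rng((seed, 11))
    rl = cfg.cell_read_length
    reads = []
    for i in range(n_reads):
        if rng.random() < cfg.terminal_read_fraction:
            frag = linear[:rl] if rng.random() < 0.5 else revcomp(linear[-rl:])
        else:
            s = int(rng.integers(0, len(linear) - rl + 1))
            frag = linear[s : s + rl]
            if rng.random() < 0.5:
                frag = revcomp(frag)
        reads.append((f"p{i}", frag))
    circle = GenomeRecord("circle", ss.genome + ss.attP, "circular")
    hist = isg.read_start_histogram(reads, circle)
    return CosRun(cut, isg.detect_termini(hist)["+"])


def run_ptw_experiment(
    seed: int,
    slope: float = 0.5,
    noise_sd: float = 0.2,
    n_samples: int = 60,
) -> pe.PtWResult:
    """Simulated paired metagenome tables -> RPKM, filters, station pairing,
    log-log OLS slope with CI classification and VHR correlation."""
    cfg = sd.SimulationConfig(
        seed=seed, meta_slope=slope, meta_noise_sd=noise_sd, n_samples=n_samples
    )
    records, _ = sd.simulate_metagenome_counts(cfg)
    pairs = pe.pair_stations(records, "prophage_genome", "host_genome")
    return pe.loglog_slope(pairs, "prophage_genome", "host_genome")
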
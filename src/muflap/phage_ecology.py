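"""Abundance analytics: co-induction relative abundance, RPKM, virus-host
ratios, and log-log abundance scaling for Piggyback-the-Winner inference.

Relative abundance of co-induced phages is length-normalized: read counts
divided by genome length (or coverage values used directly), then scaled to
fractions of the mixture.

Metagenomic abundance is expressed as RPKM — reads per kb of genome per Mbp
of metagenomic sample — and filtered (host RPKM > 0.1, prophage RPKM > 0.01,
strict) before analysis.  For stations sequenced in both cellular and virion
fractions, the virus-host ratio VHR = virion-fraction phage RPKM /
cellular-fraction host RPKM.  A power law y ~ x^b between phage (y) and host
(x) abundance is fitted by OLS on log10-transformed values; b < 1 (sublinear,
by 95% CI) together with a negative VHR-host Spearman correlation is the
metagenomic fingerprint of Piggyback-the-Winner dynamics.

Read mapping itself is upstream of this module: it consumes per-sample count
tables produced by any recruitment pipeline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

FILTER_MIN_RPKM = {"host": 0.1, "prophage": 0.01}


@dataclass(frozen=True)
class AbundanceRecord:
    sample_id: str
    station: str
    fraction: Literal["cellular", "virion"]
    entity_id: str
    entity_type: Literal["host", "prophage"]
    mapped_reads: float
    entity_length: int
    sample_size_bp: float
    rpkm_value: float | None = None

    def with_rpkm(self) -> "AbundanceRecord":
        return replace(
            self, rpkm_value=rpkm(self.mapped_reads, self.entity_length, self.sample_size_bp)
        )


@dataclass(frozen=True)
class PtWResult:
    """Per prophage-host pair scaling statistics across stations."""

    pair_id: tuple[str, str]
    n_stations: int
    lm_slope: float
    slope_ci: tuple[float, float]
    slope_class: Literal["sublinear", "linear", "superlinear", "indeterminate"]
    intercept: float
    spearman_phage_host: tuple[float, float]
    spearman_vhr_host: tuple[float, float]


def relative_abundance(
    entities: Sequence[tuple[str, float, float]] | Sequence[tuple[str, float]],
) -> dict[str, float]:
    """Length-normalized relative abundance of a phage mixture.

    Accepts (id, mapped_reads, genome_length) triples, weighted as
    reads/length, or (id, coverage) pairs, weighted as-is (coverage is
    already per-base).  Returns fractions summing to 1.
    """
    weights: dict[str, float] = {}
    for entry in entities:
        if len(entry) == 3:
            eid, reads, length = entry
            if length <= 0:
                raise ValueError(f"{eid}: non-positive genome length")
            weights[eid] = reads / length
        elif len(entry) == 2:
            eid, coverage = entry
            weights[eid] = float(coverage)
        else:
            raise ValueError("entries must be (id, reads, length) or (id, coverage)")
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("all weights are zero; no signal to normalize")
    return {eid: w / total for eid, w in weights.items()}


def rpkm(mapped_reads: float, entity_length_bp: float, sample_size_bp: float) -> float:
    """Reads per kb of genome per Mbp of metagenomic sample."""
    if entity_length_bp < 1 or sample_size_bp < 1:
        raise ValueError("entity length and sample size must be >= 1 bp")
    return mapped_reads / (entity_length_bp / 1_000.0) / (sample_size_bp / 1_000_000.0)


def filter_records(records: Sequence[AbundanceRecord]) -> list[AbundanceRecord]:
    """Strict abundance filter: hosts kept iff RPKM > 0.1, prophages iff
    RPKM > 0.01.  Idempotent."""
    out = []
    for r in records:
        r = r if r.rpkm_value is not None else r.with_rpkm()
        if r.rpkm_value > FILTER_MIN_RPKM[r.entity_type]:
            out.append(r)
    return out


def pair_stations(
    records: Sequence[AbundanceRecord],
    phage_id: str,
    host_id: str,
    apply_filter: bool = True,
) -> pd.DataFrame:
    """One row per station with a filter-passing virion-fraction phage RPKM
    and cellular-fraction host RPKM; VHR computed per row."""
    recs = filter_records(records) if apply_filter else [
        r if r.rpkm_value is not None else r.with_rpkm() for r in records
    ]
    phage = {
        r.station: r.rpkm_value
        for r in recs
        if r.entity_id == phage_id and r.fraction == "virion"
    }
    host = {
        r.station: r.rpkm_value
        for r in recs
        if r.entity_id == host_id and r.fraction == "cellular"
    }
    stations = sorted(set(phage) & set(host))
    rows = [
        {
            "station": s,
            "phage_rpkm": phage[s],
            "host_rpkm": host[s],
            "vhr": phage[s] / host[s],
        }
        for s in stations
        if host[s] > 0
    ]
    return pd.DataFrame(rows, columns=["station", "phage_rpkm", "host_rpkm", "vhr"])


def loglog_slope(
    pairs: pd.DataFrame,
    phage_id: str = "phage",
    host_id: str = "host",
    ci_level: float = 0.95,
) -> PtWResult:
    """OLS fit of log10(phage RPKM) on log10(host RPKM) with CI-based
    classification of the power-law exponent.

    sublinear: CI inside (0, 1); linear: CI contains 1 and excludes 0;
    superlinear: CI lower bound > 1; otherwise indeterminate.  Spearman
    correlations (average ranks on ties) accompany the fit.
    """
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 paired stations, got {len(pairs)}")
    x = np.log10(pairs["host_rpkm"].to_numpy(float))
    y = np.log10(pairs["phage_rpkm"].to_numpy(float))
    fit = stats.linregress(x, y)
    dof = len(x) - 2
    tcrit = stats.t.ppf(0.5 + ci_level / 2.0, dof)
    half = tcrit * fit.stderr
    lo, hi = fit.slope - half, fit.slope + half

    if 0.0 < lo and hi < 1.0:
        slope_class = "sublinear"
    elif lo > 1.0:
        slope_class = "superlinear"
    elif lo <= 1.0 <= hi and lo > 0.0:
        slope_class = "linear"
    else:
        slope_class = "indeterminate"

    def _spearman(a, b) -> tuple[float, float]:
        # a rank correlation against a constant is taken as 0 (no trend)
        if np.ptp(np.asarray(a, float)) == 0 or np.ptp(np.asarray(b, float)) == 0:
            return 0.0, 1.0
        r = stats.spearmanr(a, b)
        return float(r.statistic), float(r.pvalue)

    sp_ph = _spearman(pairs["host_rpkm"], pairs["phage_rpkm"])
    sp_vhr = _spearman(pairs["host_rpkm"], pairs["vhr"])
    return PtWResult(
        pair_id=(phage_id, host_id),
        n_stations=len(pairs),
        lm_slope=float(fit.slope),
        slope_ci=(float(lo), float(hi)),
        slope_class=slope_class,
        intercept=float(fit.intercept),
        spearman_phage_host=sp_ph,
        spearman_vhr_host=sp_vhr,
    )


# ---------------------------------------------------------------------------
# TSV / JSON plumbing

COUNT_COLUMNS = [
    "sample_id", "station", "fraction", "entity_id", "entity_type",
    "mapped_reads", "entity_length", "sample_size_bp",
]


def read_count_table(path) -> list[AbundanceRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    return [
        AbundanceRecord(
            str(row.sample_id), str(row.station), row.fraction, str(row.entity_id),
            row.entity_type, float(row.mapped_reads), int(row.entity_length),
            float(row.sample_size_bp),
        ).with_rpkm()
        for row in df.itertuples()
    ]


def write_abundance_table(records: Sequence[AbundanceRecord], path) -> None:
    rows = [
        {
            **{c: getattr(r, c) for c in COUNT_COLUMNS},
            "rpkm": r.rpkm_value if r.rpkm_value is not None else r.with_rpkm().rpkm_value,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def ptw_result_to_dict(res: PtWResult) -> dict:
    return {
        "phage": res.pair_id[0],
        "host": res.pair_id[1],
        "n_stations": res.n_stations,
        "lm_slope": res.lm_slope,
        "slope_ci_low": res.slope_ci[0],
        "slope_ci_high": res.slope_ci[1],
        "slope_class": res.slope_class,
        "intercept_log10": res.intercept,
        "spearman_phage_host_rho": res.spearman_phage_host[0],
        "spearman_phage_host_p": res.spearman_phage_host[1],
        "spearman_vhr_host_rho": res.spearman_vhr_host[0],
        "spearman_vhr_host_p": res.spearman_vhr_host[1],
    }


def write_ptw_results(results: Sequence[PtWResult], path) -> None:
    with open(path, "w") as fh:
        json.dump([ptw_result_to_dict(r) for r in results], fh, indent=1)
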
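"""Transposition target preference (TTP) scoring and hot/cold-spot calling.

For each chromosomal gene the TTP score is the count of new 5'flaps credited
to the gene divided by the gene's NYSRN motif count — i.e. observed
transposition incidence normalized by targetable sites.  Genes are ranked by
TTP and split into six rank bins; per (subsystem category, bin) cells a
hypergeometric tail test (raw P < .01, no multiplicity correction) flags
enrichment or depletion.  A category significantly enriched in top bins and
depleted in lower bins is a transposition hot spot; the mirrored pattern is
a cold spot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

from scipy.stats import hypergeom

from .flap_analysis import FLAP_LEN, Flap
from .genome_io import GeneAnnotation
from .motif_scan import MotifTable

DEFAULT_N_BINS = 6
DEFAULT_ALPHA = 0.01
DEFAULT_TOP_BINS = frozenset({1, 2})
DEFAULT_LOW_BINS = frozenset({4, 5, 6})


@dataclass(frozen=True)
class TTPRow:
    gene_id: str
    category: str
    flap_hits: int
    motif_count: int
    ttp_score: float
    rank: int | None = None  # 1-based, descending score
    bin: int | None = None   # 1..n_bins


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric tail probabilities for one (category, bin) cell.

    Population N = all scored genes, K = scored genes in the category,
    m = genes in the bin, k = category genes in the bin;
    p_enrich = P[X >= k], p_deplete = P[X <= k] for X ~ Hypergeom(N, K, m).
    """

    category: str
    bin: int
    N: int
    K: int
    m: int
    k: int
    p_enrich: float
    p_deplete: float
    alpha: float = DEFAULT_ALPHA

    @property
    def enriched(self) -> bool:
        return self.p_enrich < self.alpha

    @property
    def depleted(self) -> bool:
        return self.p_deplete < self.alpha


@dataclass(frozen=True)
class SpotCall:
    category: str
    call: Literal["hot", "cold", "none"]
    supporting: tuple[tuple[int, str], ...] = ()  # (bin, "enriched"|"depleted")


def flap_hits_per_gene(
    flaps: Sequence[Flap], annotations: Sequence[GeneAnnotation]
) -> dict[str, int]:
    """Credit each mapped new flap to the gene fully containing its 20-mer.

    Symmetric with motif crediting: the flap's [pos, pos+20) interval must
    lie inside the gene; boundary-spanning flaps count for no gene.
    """
    hits = {g.gene_id: 0 for g in annotations}
    new_positions = [f.host_position for f in flaps if f.flap_class == "new"]
    for g in annotations:
        hits[g.gene_id] = sum(
            1 for p in new_positions if g.start <= p and p + FLAP_LEN <= g.end
        )
    return hits


def ttp_scores(
    flaps: Sequence[Flap],
    annotations: Sequence[GeneAnnotation],
    motif_table: MotifTable,
) -> tuple[list[TTPRow], list[str]]:
    """Score each gene; genes without NYSRN sites cannot host targeted events
    and are excluded from scoring (returned separately)."""
    if not annotations:
        raise ValueError("empty annotation set")
    hits = flap_hits_per_gene(flaps, annotations)
    rows, zero_motif = [], []
    for g in annotations:
        m = motif_table.per_gene.get(g.gene_id)
        if m is None:
            raise ValueError(f"gene {g.gene_id} missing from motif table")
        if m == 0:
            zero_motif.append(g.gene_id)
            continue
        rows.append(TTPRow(g.gene_id, g.category, hits[g.gene_id], m, hits[g.gene_id] / m))
    return rows, zero_motif


def bin_genes(rows: Sequence[TTPRow], n_bins: int = DEFAULT_N_BINS) -> list[TTPRow]:
    """Rank rows by TTP score (descending) and split into n_bins contiguous
    blocks of near-equal size, earlier bins taking the extra gene.

    Ties break on motif_count descending then gene_id, so the split is
    deterministic across runs.
    """
    if len(rows) < n_bins:
        raise ValueError(f"need at least {n_bins} scored genes, got {len(rows)}")
    ordered = sorted(rows, key=lambda r: (-r.ttp_score, -r.motif_count, r.gene_id))
    n = len(ordered)
    base, extra = divmod(n, n_bins)
    out, idx = [], 0
    for b in range(1, n_bins + 1):
        size = base + (1 if b <= extra else 0)
        for _ in range(size):
            r = ordered[idx]
            out.append(TTPRow(r.gene_id, r.category, r.flap_hits, r.motif_count,
                              r.ttp_score, rank=idx + 1, bin=b))
            idx += 1
    return out


def category_enrichment(
    binned_rows: Sequence[TTPRow], alpha: float = DEFAULT_ALPHA
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment/depletion per (category, bin) cell."""
    N = len(binned_rows)
    categories = sorted({r.category for r in binned_rows})
    bins = sorted({r.bin for r in binned_rows})
    results = []
    for cat in categories:
        K = sum(1 for r in binned_rows if r.category == cat)
        for b in bins:
            m = sum(1 for r in binned_rows if r.bin == b)
            k = sum(1 for r in binned_rows if r.bin == b and r.category == cat)
            dist = hypergeom(N, K, m)
            results.append(
                EnrichmentResult(
                    cat, b, N, K, m, k,
                    p_enrich=float(dist.sf(k - 1)),
                    p_deplete=float(dist.cdf(k)),
                    alpha=alpha,
                )
            )
    return results


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (optional, off by default)."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        r = m - rank_from_end
        prev = min(prev, pvalues[i] * m / r)
        adj[i] = prev
    return adj


def call_spots(
    results: Sequence[EnrichmentResult],
    top_bins: frozenset[int] | set[int] = DEFAULT_TOP_BINS,
    low_bins: frozenset[int] | set[int] = DEFAULT_LOW_BINS,
    alpha: float = DEFAULT_ALPHA,
) -> list[SpotCall]:
    """Call hot/cold spots per category.

    hot: enriched (p < alpha) in >= 1 top bin AND depleted in >= 1 low bin;
    cold: the mirror image.  The bin partitions are a documented choice and
    configurable.
    """
    by_cat: dict[str, list[EnrichmentResult]] = {}
    for r in results:
        by_cat.setdefault(r.category, []).append(r)
    calls = []
    for cat, cells in sorted(by_cat.items()):
        top_enriched = [(c.bin, "enriched") for c in cells if c.bin in top_bins and c.p_enrich < alpha]
        top_depleted = [(c.bin, "depleted") for c in cells if c.bin in top_bins and c.p_deplete < alpha]
        low_enriched = [(c.bin, "enriched") for c in cells if c.bin in low_bins and c.p_enrich < alpha]
        low_depleted = [(c.bin, "depleted") for c in cells if c.bin in low_bins and c.p_deplete < alpha]
        if top_enriched and low_depleted:
            calls.append(SpotCall(cat, "hot", tuple(top_enriched + low_depleted)))
        elif top_depleted and low_enriched:
            calls.append(SpotCall(cat, "cold", tuple(top_depleted + low_enriched)))
        else:
            calls.append(SpotCall(cat, "none"))
    return calls


def write_ttp_table(rows: Sequence[TTPRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcategory\tflap_hits\tmotif_count\tttp_score\trank\tbin\n")
        for r in rows:
            fh.write(
                f"{r.gene_id}\t{r.category}\t{r.flap_hits}\t{r.motif_count}\t"
                f"{r.ttp_score:.6g}\t{r.rank or ''}\t{r.bin or ''}\n"
            )


def write_enrichment_table(results: Sequence[EnrichmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("category\tbin\tN\tK\tm\tk\tp_enrich\tp_deplete\n")
        for r in results:
            fh.write(
                f"{r.category}\t{r.bin}\t{r.N}\t{r.K}\t{r.m}\t{r.k}\t"
                f"{r.p_enrich:.6g}\t{r.p_deplete:.6g}\n"
            )


def write_spot_calls(calls: Sequence[SpotCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("category\tcall\tsupport\n")
        for c in calls:
            support = ";".join(f"bin{b}:{d}" for b, d in c.supporting)
            fh.write(f"{c.category}\t{c.call}\t{support}\n")
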
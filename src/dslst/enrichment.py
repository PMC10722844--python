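"""Zone-enrichment odds ratios: per clade, the odds of occurrence in the
mesopelagic versus the epipelagic zone, with Fisher's exact significance.

Counts are pooled read counts aggregated at a taxonomic rank. The log odds
ratio is on the natural-log scale with a Haldane-Anscombe +0.5 correction
applied to the estimate (never to the exact test) when any cell is zero.
Positive values mean the clade is relatively more frequent in the
mesopelagic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .community import (
    EPIPELAGIC_LAYERS,
    MESOPELAGIC_LAYERS,
    CountTable,
    SampleMetadata,
    TaxonomyTable,
    ValidationError,
    aggregate_rank,
)


@dataclass
class ZoneOddsResult:
    clade: str
    table: np.ndarray  # [[a, b], [c, d]] = [[clade meso, other meso], [clade epi, other epi]]
    log_odds_ratio: float
    p_value: float
    significant: bool

    @property
    def a(self) -> int:
        return int(self.table[0, 0])

    @property
    def b(self) -> int:
        return int(self.table[0, 1])

    @property
    def c(self) -> int:
        return int(self.table[1, 0])

    @property
    def d(self) -> int:
        return int(self.table[1, 1])


def log_odds_ratio(table: np.ndarray) -> float:
    """Natural-log odds ratio ln((a*d)/(b*c)) of a 2x2 table, adding 0.5 to
    every cell when any cell is zero (Haldane-Anscombe)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    if (t == 0).any():
        t = t + 0.5
    return float(np.log((t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])))


def fisher_exact_two_sided(table: np.ndarray) -> float:
    """Two-sided Fisher exact p: the sum, over all 2x2 tables with the
    observed margins, of hypergeometric probabilities no larger than the
    observed table's (with a 1 + 1e-7 relative slack for floating ties, the
    usual convention)."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    a = int(t[0, 0])
    r1 = int(t[0].sum())
    c1 = int(t[:, 0].sum())
    n = int(t.sum())
    if n == 0:
        return 1.0
    lo = max(0, r1 + c1 - n)
    return float(fisher_exact_margin_sweep(r1, c1, n)[a - lo])


def fisher_exact_margin_sweep(r1: int, c1: int, n: int) -> np.ndarray:
    """Two-sided Fisher p for *every* table sharing the margins
    (r1, n - r1) x (c1, n - c1), indexed by the top-left cell over its
    support [max(0, r1 + c1 - n), min(r1, c1)]."""
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    order = np.argsort(pmf)
    csum = np.cumsum(pmf[order])
    idx = np.searchsorted(pmf[order], pmf * (1 + 1e-7), side="right")
    return np.minimum(csum[np.minimum(idx, len(csum)) - 1], 1.0)


def _zone_samples(table: CountTable, metadata: SampleMetadata) -> tuple[list[int], list[int]]:
    meso, epi = [], []
    for j, s in enumerate(table.sample_ids):
        layer = metadata.frame.loc[s, "layer"]
        if layer in MESOPELAGIC_LAYERS:
            meso.append(j)
        elif layer in EPIPELAGIC_LAYERS:
            epi.append(j)
    if not meso or not epi:
        raise ValidationError("both zones need at least one sample")
    return meso, epi


def zone_odds(
    table: CountTable,
    taxonomy: TaxonomyTable,
    metadata: SampleMetadata,
    clade: str,
    rank: str = "phylum",
    presence: bool = False,
    alpha: float = 0.05,
) -> ZoneOddsResult:
    """Mesopelagic-vs-epipelagic odds for one clade at ``rank``.

    Default aggregation pools read counts over all samples of each zone;
    ``presence=True`` instead counts samples in which the clade occurs.
    """
    agg = aggregate_rank(table, taxonomy, rank)
    if clade not in agg.asv_ids:
        raise ValidationError(f"clade {clade!r} not found at rank {rank!r}")
    meso, epi = _zone_samples(agg, metadata)
    row = agg.counts[agg.asv_ids.index(clade)]
    if presence:
        a = int((row[meso] > 0).sum())
        c = int((row[epi] > 0).sum())
        b = len(meso) - a
        d = len(epi) - c
    else:
        totals = agg.counts.sum(axis=0)
        a = int(row[meso].sum())
        c = int(row[epi].sum())
        b = int(totals[meso].sum()) - a
        d = int(totals[epi].sum()) - c
    if a + c == 0:
        raise ValidationError(f"clade {clade!r} absent from both zones")
    t22 = np.array([[a, b], [c, d]], dtype=np.int64)
    p = fisher_exact_two_sided(t22)
    return ZoneOddsResult(clade, t22, log_odds_ratio(t22), p, bool(p < alpha))


def zone_odds_panel(
    table: CountTable,
    taxonomy: TaxonomyTable,
    metadata: SampleMetadata,
    rank: str = "phylum",
    top_k: int = 10,
    split_phylum: str | None = None,
    presence: bool = False,
    alpha: float = 0.05,
) -> list[ZoneOddsResult]:
    """Odds panel for the ``top_k`` clades by overall mean relative abundance.

    ``split_phylum`` replaces one phylum by its classes (the classic
    "split Proteobacteria into classes" display); the classes enter the
    ranking with the remaining phyla.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    agg = aggregate_rank(table, taxonomy, rank, include_unassigned=False)
    clades: list[tuple[str, str, float]] = []  # (name, rank used, mean rel abund)
    totals = table.counts.sum(axis=0).astype(float)
    for name, row in zip(agg.asv_ids, agg.counts):
        clades.append((name, rank, float((row / totals).mean())))
    if split_phylum is not None and rank == "phylum":
        clades = [c for c in clades if c[0] != split_phylum]
        cls_agg = aggregate_rank(table, taxonomy, "class", include_unassigned=False)
        members = {
            taxonomy.get(asv, "class")
            for asv in table.asv_ids
            if taxonomy.get(asv, "phylum") == split_phylum
        }
        for name, row in zip(cls_agg.asv_ids, cls_agg.counts):
            if name in members:
                clades.append((name, "class", float((row / totals).mean())))
    clades.sort(key=lambda c: c[2], reverse=True)
    results = []
    for name, use_rank, _ in clades[:top_k]:
        results.append(
            zone_odds(table, taxonomy, metadata, name, rank=use_rank,
                      presence=presence, alpha=alpha)
        )
    return results
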
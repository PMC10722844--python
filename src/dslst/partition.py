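"""Per-profile source partitioning of DSL diversity.

For every vertical profile, each ASV present in the profile's DSL sample(s)
is assigned to exactly one source category:

* ``EPI_shared``     — also present in the profile's epipelagic samples
                       (SURF or DCM); epipelagic precedence applies, so an
                       ASV shared with both EPI and MS is still EPI_shared.
* ``unique_DSL``     — present in no other layer of the profile.
* ``MS_only_shared`` — shared with the shallow mesopelagic only.
* ``MD_only_shared`` — shared with the deep mesopelagic only.
* ``all_meso_shared``— shared with both MS and MD (but not EPI).

Mesopelagic-shared ASVs can additionally be flagged as DSL-enriched when a
one-way ANOVA across the mesopelagic layers plus Tukey post-hoc comparisons
show a significantly higher relative abundance at the DSL than in every
adjacent layer tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .community import (
    EPIPELAGIC_LAYERS,
    MESOPELAGIC_LAYERS,
    CountTable,
    SampleMetadata,
    ValidationError,
    relative_abundance,
)

logger = logging.getLogger(__name__)

CATEGORIES = (
    "EPI_shared",
    "unique_DSL",
    "MS_only_shared",
    "MD_only_shared",
    "all_meso_shared",
)
MESO_SHARED_CATEGORIES = ("MS_only_shared", "MD_only_shared", "all_meso_shared")


@dataclass
class LayerSets:
    """Per-profile presence sets of ASV ids (presence = count > 0)."""

    profile_id: str
    epi: frozenset[str]
    ms: frozenset[str]
    dsl: frozenset[str]
    md: frozenset[str]


@dataclass
class PartitionResult:
    """Classification of one profile's DSL ASVs plus summary statistics."""

    profile_id: str
    assignments: dict[str, str]  # asv_id -> category
    enriched: frozenset[str]
    counts: dict[str, int]
    percentages: dict[str, float]
    abundance: dict[str, float]  # mean summed relative abundance in DSL samples
    n_dsl: int

    @property
    def enriched_pct(self) -> float:
        return 100.0 * len(self.enriched) / self.n_dsl if self.n_dsl else 0.0

    @property
    def meso_origin_pct(self) -> float:
        return sum(self.percentages[c] for c in MESO_SHARED_CATEGORIES)

    @property
    def attributable_pct(self) -> float:
        """Unique plus enriched: the diversity attributable to the DSL."""
        return self.percentages["unique_DSL"] + self.enriched_pct


@dataclass
class PartitionSummary:
    mean_pct: dict[str, float]
    mean_abundance: dict[str, float]
    mean_n_dsl: float
    se_n_dsl: float
    mean_enriched_pct: float
    mean_meso_origin_pct: float
    attributable_pct: float
    n_profiles: int


@dataclass
class SeasonalOverlap:
    """Membership of one layer's ASVs in the per-season presence regions."""

    layer: str
    seasons: list[str]
    regions: dict[frozenset[str], set[str]]  # season subset -> ASVs
    asv_fraction: dict[frozenset[str], float]
    abundance_fraction: dict[frozenset[str], float]

    @property
    def shared_all(self) -> frozenset[str]:
        return frozenset(self.seasons)


# ---------------------------------------------------------------------------
# layer sets and classification
# ---------------------------------------------------------------------------


def _presence_set(table: CountTable, sample_ids: list[str]) -> frozenset[str]:
    if not sample_ids:
        return frozenset()
    idx = [table.sample_index(s) for s in sample_ids]
    mask = (table.counts[:, idx] > 0).any(axis=1)
    return frozenset(a for a, m in zip(table.asv_ids, mask) if m)


def layer_sets(
    table: CountTable, metadata: SampleMetadata, profile_id: str
) -> LayerSets:
    """Presence sets per layer for one profile; SURF and DCM are merged into
    a single epipelagic (EPI) set. Missing MS/MD layers yield empty sets
    with a logged warning."""
    in_table = set(table.sample_ids)

    def samples(layer: str) -> list[str]:
        return [
            s
            for s in metadata.samples_where(profile_id=profile_id, layer=layer)
            if s in in_table
        ]

    dsl_samples = samples("DSL")
    if not dsl_samples:
        raise ValidationError(f"profile {profile_id!r} has no DSL sample")
    epi_samples = samples("SURF") + samples("DCM")
    ms_samples = samples("MS")
    md_samples = samples("MD")
    for layer, ss in (("MS", ms_samples), ("MD", md_samples)):
        if not ss:
            logger.warning("profile %s has no %s sample; set is empty", profile_id, layer)
    return LayerSets(
        profile_id=profile_id,
        epi=_presence_set(table, epi_samples),
        ms=_presence_set(table, ms_samples),
        dsl=_presence_set(table, dsl_samples),
        md=_presence_set(table, md_samples),
    )


def partition_profile(sets: LayerSets) -> dict[str, str]:
    """Assign every DSL ASV of the profile to exactly one source category."""
    assignments: dict[str, str] = {}
    for asv in sets.dsl:
        if asv in sets.epi:
            assignments[asv] = "EPI_shared"
        else:
            in_ms, in_md = asv in sets.ms, asv in sets.md
            if in_ms and in_md:
                assignments[asv] = "all_meso_shared"
            elif in_ms:
                assignments[asv] = "MS_only_shared"
            elif in_md:
                assignments[asv] = "MD_only_shared"
            else:
                assignments[asv] = "unique_DSL"
    return assignments


def profile_partition(
    table: CountTable,
    metadata: SampleMetadata,
    profile_id: str,
    enriched: frozenset[str] | set[str] = frozenset(),
) -> PartitionResult:
    """Classify one profile's DSL ASVs and attach count / percentage /
    abundance summaries. ``enriched`` is restricted to the profile's
    mesopelagic-shared ASVs."""
    sets = layer_sets(table, metadata, profile_id)
    assignments = partition_profile(sets)
    n_dsl = len(assignments)
    counts = {c: 0 for c in CATEGORIES}
    for cat in assignments.values():
        counts[cat] += 1
    percentages = {
        c: (100.0 * counts[c] / n_dsl if n_dsl else 0.0) for c in CATEGORIES
    }
    meso_shared = {
        a for a, c in assignments.items() if c in MESO_SHARED_CATEGORIES
    }
    enriched_here = frozenset(enriched) & meso_shared
    dsl_samples = [
        s
        for s in metadata.samples_where(profile_id=profile_id, layer="DSL")
        if s in set(table.sample_ids)
    ]
    sub = table.select_samples(dsl_samples)
    relabund = relative_abundance(sub)
    pos = {a: i for i, a in enumerate(sub.asv_ids)}
    abundance = {}
    for cat in CATEGORIES:
        idx = [pos[a] for a, c in assignments.items() if c == cat]
        abundance[cat] = (
            float(relabund[idx].sum(axis=0).mean()) if idx else 0.0
        )
    return PartitionResult(
        profile_id=profile_id,
        assignments=assignments,
        enriched=enriched_here,
        counts=counts,
        percentages=percentages,
        abundance=abundance,
        n_dsl=n_dsl,
    )


# ---------------------------------------------------------------------------
# DSL enrichment (ANOVA + Tukey)
# ---------------------------------------------------------------------------


def detect_enriched(
    table: CountTable,
    metadata: SampleMetadata,
    candidate_asvs,
    alpha: float = 0.05,
    adjust: str | None = None,
) -> set[str]:
    """Flag candidate ASVs whose relative abundance is significantly higher
    at the DSL than in every adjacent mesopelagic layer they occupy.

    Per ASV: one-way ANOVA on per-sample relative abundance across the
    occupied mesopelagic layers (profiles act as replicates), then Tukey
    HSD; enriched requires ANOVA p < alpha, every DSL-vs-adjacent Tukey
    adjusted p < alpha, and the DSL mean strictly largest. Layers with fewer
    than 2 replicate samples cause the ASV to be skipped (never enriched).
    ``adjust="bh"`` applies Benjamini-Hochberg across candidates to the
    ANOVA p-values; the default matches raw per-ASV testing.
    """
    if adjust not in (None, "none", "bh"):
        raise ValueError("adjust must be None, 'none' or 'bh'")
    in_table = set(table.sample_ids)
    layer_samples = {
        layer: [s for s in metadata.samples_where(layer=layer) if s in in_table]
        for layer in MESOPELAGIC_LAYERS
    }
    if not layer_samples["DSL"]:
        raise ValidationError("no DSL samples available")
    relabund = relative_abundance(table)
    asv_pos = {a: i for i, a in enumerate(table.asv_ids)}
    layer_cols = {
        layer: [table.sample_index(s) for s in ss]
        for layer, ss in layer_samples.items()
    }
    records: list[tuple[str, float, dict[str, float], list[str]]] = []
    for asv in candidate_asvs:
        i = asv_pos.get(asv)
        if i is None:
            continue
        values = {layer: relabund[i, cols] for layer, cols in layer_cols.items()}
        occupied = ["DSL"] + [
            layer
            for layer in ("MS", "MD")
            if len(values[layer]) and (values[layer] > 0).any()
        ]
        if len(occupied) < 2:
            continue  # nothing to compare against
        if any(len(values[layer]) < 2 for layer in occupied):
            logger.warning("ASV %s skipped: <2 replicates in a compared layer", asv)
            continue
        groups = [values[layer] for layer in occupied]
        if all(np.ptp(np.concatenate(groups)) == 0 for _ in (0,)):
            continue  # zero variance overall; F undefined
        with np.errstate(invalid="ignore", divide="ignore"):
            f_res = stats.f_oneway(*groups)
        anova_p = float(f_res.pvalue)
        if np.isnan(anova_p):
            continue
        means = {layer: float(v.mean()) for layer, v in zip(occupied, groups)}
        if any(means["DSL"] <= means[layer] for layer in occupied[1:]):
            continue
        tukey = stats.tukey_hsd(*groups)
        tukey_ok = all(
            float(tukey.pvalue[0, k]) < alpha for k in range(1, len(occupied))
        )
        if tukey_ok:
            records.append((asv, anova_p, means, occupied))
    if not records:
        return set()
    p_anova = np.array([r[1] for r in records])
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        p_anova = multipletests(p_anova, method="fdr_bh")[1]
    return {r[0] for r, p in zip(records, p_anova) if p < alpha}


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def summarize_partition(results: list[PartitionResult]) -> PartitionSummary:
    """Mean category percentages across profiles (the multi-profile Venn
    summary), mean DSL richness +/- SE, and the DSL-attributable fraction
    (mean unique % + mean enriched %)."""
    if not results:
        raise ValidationError("need at least one profile partition")
    k = len(results)
    mean_pct = {
        c: float(np.mean([r.percentages[c] for r in results])) for c in CATEGORIES
    }
    mean_abund = {
        c: float(np.mean([r.abundance[c] for r in results])) for c in CATEGORIES
    }
    totals = np.array([r.n_dsl for r in results], dtype=float)
    mean_enriched = float(np.mean([r.enriched_pct for r in results]))
    return PartitionSummary(
        mean_pct=mean_pct,
        mean_abundance=mean_abund,
        mean_n_dsl=float(totals.mean()),
        se_n_dsl=float(totals.std(ddof=1) / np.sqrt(k)) if k > 1 else 0.0,
        mean_enriched_pct=mean_enriched,
        mean_meso_origin_pct=float(np.mean([r.meso_origin_pct for r in results])),
        attributable_pct=mean_pct["unique_DSL"] + mean_enriched,
        n_profiles=k,
    )


@dataclass
class PooledContribution:
    n_meso_asvs: int
    n_pooled_unique: int
    unique_fraction: float
    unique_abundance_share: float
    with_enriched_fraction: float | None = None
    with_enriched_abundance_share: float | None = None


def pooled_contribution(
    table: CountTable,
    metadata: SampleMetadata,
    enriched: set[str] | None = None,
) -> PooledContribution:
    """Pool all profiles: ASVs present in any DSL sample but in no MS/MD
    sample are pooled-unique. Fractions are over the union of ASVs present
    in any mesopelagic sample; abundance shares are fractions of total
    mesopelagic reads."""
    in_table = set(table.sample_ids)
    samples = {
        layer: [s for s in metadata.samples_where(layer=layer) if s in in_table]
        for layer in MESOPELAGIC_LAYERS
    }
    if not samples["MS"] or not samples["MD"]:
        raise ValidationError("pooled contribution needs MS and MD samples")
    dsl_set = _presence_set(table, samples["DSL"])
    adjacent = _presence_set(table, samples["MS"]) | _presence_set(table, samples["MD"])
    meso_all = dsl_set | adjacent
    pooled_unique = dsl_set - adjacent
    meso_cols = [
        table.sample_index(s)
        for layer in MESOPELAGIC_LAYERS
        for s in samples[layer]
    ]
    meso_counts = table.counts[:, meso_cols]
    total_reads = meso_counts.sum()
    pos = {a: i for i, a in enumerate(table.asv_ids)}

    def share(asvs: set[str]) -> float:
        idx = [pos[a] for a in asvs]
        return float(meso_counts[idx].sum() / total_reads) if idx else 0.0

    result = PooledContribution(
        n_meso_asvs=len(meso_all),
        n_pooled_unique=len(pooled_unique),
        unique_fraction=len(pooled_unique) / len(meso_all) if meso_all else 0.0,
        unique_abundance_share=share(pooled_unique),
    )
    if enriched is not None:
        combined = pooled_unique | (set(enriched) & meso_all)
        result.with_enriched_fraction = (
            len(combined) / len(meso_all) if meso_all else 0.0
        )
        result.with_enriched_abundance_share = share(combined)
    return result


def seasonal_overlap(
    table: CountTable, metadata: SampleMetadata, layer: str = "DSL"
) -> SeasonalOverlap:
    """Season-overlap regions (the 3-way Venn) of one layer's ASVs.

    Each ASV present in the layer is assigned to the subset of seasons in
    which it occurs; per region the ASV count/fraction and the fraction of
    the layer's total reads are reported.
    """
    in_table = set(table.sample_ids)
    by_season: dict[str, list[str]] = {}
    for s in metadata.samples_where(layer=layer):
        if s in in_table:
            by_season.setdefault(str(metadata.frame.loc[s, "season"]), []).append(s)
    if not by_season:
        raise ValidationError(f"no samples for layer {layer!r}")
    if len(by_season) < 2:
        raise ValidationError(
            f"layer {layer!r} sampled in fewer than 2 seasons"
        )
    seasons = sorted(by_season)
    presence = {season: _presence_set(table, ss) for season, ss in by_season.items()}
    all_asvs = frozenset().union(*presence.values())
    membership: dict[str, frozenset[str]] = {
        asv: frozenset(s for s in seasons if asv in presence[s]) for asv in all_asvs
    }
    regions: dict[frozenset[str], set[str]] = {}
    for asv, region in membership.items():
        regions.setdefault(region, set()).add(asv)
    layer_cols = [
        table.sample_index(s) for ss in by_season.values() for s in ss
    ]
    layer_counts = table.counts[:, layer_cols]
    total_reads = layer_counts.sum()
    pos = {a: i for i, a in enumerate(table.asv_ids)}
    n_total = len(all_asvs)
    asv_fraction = {r: len(m) / n_total for r, m in regions.items()}
    abundance_fraction = {
        r: float(layer_counts[[pos[a] for a in m]].sum() / total_reads)
        for r, m in regions.items()
    }
    return SeasonalOverlap(
        layer=layer,
        seasons=seasons,
        regions=regions,
        asv_fraction=asv_fraction,
        abundance_fraction=abundance_fraction,
    )
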
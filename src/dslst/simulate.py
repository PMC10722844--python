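"""Layer-stratified, season-structured synthetic community generator.

Plants taxa of known ecological category (surface/DCM specialists,
mesopelagic generalists, DSL-unique, DSL-enriched, per-season indicators,
cosmopolitans) into a SURF/DCM/MS/DSL/MD x winter/spring/summer sampling
design, draws read counts from a (Dirichlet-)multinomial at a configurable
depth, and emits the ground-truth labels so every analysis stage can be
validated against planted truth.

Structural zeros are hard: a category absent from a layer by design never
appears there at any depth or seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .community import (
    LAYERS,
    SEASONS,
    CountTable,
    SampleMetadata,
    TaxonomyTable,
    ValidationError,
)
from .diversity import EEM

CATEGORY_NAMES = (
    "surface_specialist",
    "dcm_specialist",
    "mesopelagic_generalist",
    "dsl_unique",
    "dsl_enriched",
    "seasonal_indicator",
    "cosmopolitan",
)

# expected DSL source-partition category implied by each planted occupancy
EXPECTED_PARTITION = {
    "cosmopolitan": "EPI_shared",
    "mesopelagic_generalist": "all_meso_shared",
    "dsl_enriched": "all_meso_shared",
    "dsl_unique": "unique_DSL",
    "seasonal_indicator": "unique_DSL",
}

_LAYER_DEPTH_M = {"SURF": 5.0, "DCM": 80.0, "MS": 300.0, "DSL": 525.0, "MD": 700.0}

# relative mean-abundance multiplier of each category in each layer;
# zero entries are structural (hard) zeros
_LAYER_MULTIPLIER = {
    "surface_specialist": {"SURF": 5.0, "DCM": 1.0, "MS": 0.0, "DSL": 0.0, "MD": 0.0},
    "dcm_specialist": {"SURF": 1.0, "DCM": 5.0, "MS": 0.0, "DSL": 0.0, "MD": 0.0},
    "mesopelagic_generalist": {"SURF": 0.0, "DCM": 0.0, "MS": 1.0, "DSL": 1.0, "MD": 1.0},
    "dsl_unique": {"SURF": 0.0, "DCM": 0.0, "MS": 0.0, "DSL": 1.0, "MD": 0.0},
    "dsl_enriched": {"SURF": 0.0, "DCM": 0.0, "MS": 1.0, "DSL": 1.0, "MD": 1.0},
    "seasonal_indicator": {"SURF": 0.0, "DCM": 0.0, "MS": 0.0, "DSL": 1.0, "MD": 0.0},
    "cosmopolitan": {"SURF": 1.0, "DCM": 1.0, "MS": 1.0, "DSL": 1.0, "MD": 1.0},
}

# layer-dependent covariate means: epipelagic warmer, richer in DOC and
# cells; mesopelagic saltier and nutrient-richer
_ENV_MEANS = {
    "temperature_c": {"SURF": 30.0, "DCM": 26.0, "MS": 23.0, "DSL": 22.0, "MD": 21.8},
    "salinity": {"SURF": 38.5, "DCM": 39.0, "MS": 39.8, "DSL": 40.2, "MD": 40.4},
    "doc_umol": {"SURF": 75.0, "DCM": 68.0, "MS": 52.0, "DSL": 48.0, "MD": 45.0},
    "nitrate_umol": {"SURF": 0.2, "DCM": 2.0, "MS": 12.0, "DSL": 16.0, "MD": 18.0},
    "oxygen_umol": {"SURF": 200.0, "DCM": 180.0, "MS": 60.0, "DSL": 40.0, "MD": 55.0},
    "fluorescence": {"SURF": 0.2, "DCM": 1.2, "MS": 0.05, "DSL": 0.02, "MD": 0.02},
    "prokaryotic_abundance": {
        "SURF": 5e5, "DCM": 6e5, "MS": 1.5e5, "DSL": 1.0e5, "MD": 0.8e5,
    },
}

_PHYLA_POOL = [
    ("Bacteria", "Proteobacteria"),
    ("Bacteria", "Bacteroidetes"),
    ("Bacteria", "Cyanobacteria"),
    ("Bacteria", "Actinobacteria"),
    ("Bacteria", "Chloroflexi"),
    ("Bacteria", "Planctomycetes"),
    ("Bacteria", "Marinimicrobia"),
    ("Archaea", "Thaumarchaeota"),
    ("Archaea", "Euryarchaeota"),
    ("Bacteria", "Verrucomicrobia"),
]
_ORDERS_PER_PHYLUM = 3  # small fixed pool so rank aggregation is exercised


@dataclass
class CommunitySpec:
    """Generative parameters for :func:`generate_community`.

    ``overdispersion`` is the Dirichlet concentration mass: sample
    compositions are drawn from Dirichlet(overdispersion * expected) before
    the multinomial; ``None`` means no overdispersion (plain multinomial).
    """

    n_surface_specialist: int = 15
    n_dcm_specialist: int = 10
    n_mesopelagic_generalist: int = 60
    n_dsl_unique: int = 25
    n_dsl_enriched: int = 15
    n_seasonal_indicator: int = 5  # per season
    n_cosmopolitan: int = 20
    n_profiles: int = 5
    seasons: tuple[str, ...] = SEASONS
    season_layers: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "winter": ("SURF", "DCM", "DSL"),
            "spring": ("SURF", "DCM", "MS", "DSL", "MD"),
            "summer": ("SURF", "DCM", "DSL"),
        }
    )
    enrichment_fold: float = 10.0
    indicator_fold: float = 10.0
    lognormal_sigma: float = 0.5
    overdispersion: float | None = None
    depth: int = 50_000
    seed: int = 0

    def validate(self) -> None:
        counts = [
            self.n_surface_specialist, self.n_dcm_specialist,
            self.n_mesopelagic_generalist, self.n_dsl_unique,
            self.n_dsl_enriched, self.n_seasonal_indicator, self.n_cosmopolitan,
        ]
        if any(c < 0 for c in counts):
            raise ValidationError("category counts must be >= 0")
        if sum(counts) == 0:
            raise ValidationError("spec generates no taxa")
        if self.enrichment_fold <= 0 or self.indicator_fold <= 0:
            raise ValidationError("fold-changes must be > 0")
        if self.depth < 1:
            raise ValidationError("sequencing depth must be >= 1")
        if self.n_profiles < 1:
            raise ValidationError("need at least one profile")
        if self.lognormal_sigma < 0:
            raise ValidationError("lognormal_sigma must be >= 0")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise ValidationError("overdispersion must be > 0 or None")
        for season in self.seasons:
            if season not in SEASONS:
                raise ValidationError(f"unknown season {season!r}")
            layers = self.season_layers.get(season, ())
            if "DSL" not in layers:
                raise ValidationError(f"season {season!r} must sample the DSL")
            if any(l not in LAYERS for l in layers):
                raise ValidationError(f"unknown layer in season {season!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CommunitySpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown spec keys: {sorted(unknown)}")
        if "seasons" in raw:
            raw["seasons"] = tuple(raw["seasons"])
        if "season_layers" in raw:
            raw["season_layers"] = {
                k: tuple(v) for k, v in raw["season_layers"].items()
            }
        spec = cls(**raw)
        spec.validate()
        return spec


@dataclass
class GroundTruth:
    """Planted labels emitted alongside a generated community."""

    category: dict[str, str]  # asv_id -> planted category
    indicator_season: dict[str, str]  # indicator asv_id -> season
    expected_partition: dict[str, str]  # asv_id -> expected DSL category (DSL taxa only)
    enriched: frozenset[str]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for asv, cat in self.category.items():
            rows.append(
                {
                    "asv_id": asv,
                    "category": cat,
                    "indicator_season": self.indicator_season.get(asv, ""),
                    "expected_partition": self.expected_partition.get(asv, ""),
                    "enriched": asv in self.enriched,
                }
            )
        return pd.DataFrame(rows).set_index("asv_id")


def _taxon_roster(spec: CommunitySpec) -> list[tuple[str, str, str | None]]:
    """(asv_id, category, indicator season or None), in generation order."""
    roster: list[tuple[str, str, str | None]] = []
    blocks = [
        ("surface_specialist", spec.n_surface_specialist),
        ("dcm_specialist", spec.n_dcm_specialist),
        ("mesopelagic_generalist", spec.n_mesopelagic_generalist),
        ("dsl_unique", spec.n_dsl_unique),
        ("dsl_enriched", spec.n_dsl_enriched),
        ("cosmopolitan", spec.n_cosmopolitan),
    ]
    i = 0
    for cat, n in blocks:
        for _ in range(n):
            roster.append((f"ASV{i:04d}", cat, None))
            i += 1
    for season in spec.seasons:
        for _ in range(spec.n_seasonal_indicator):
            roster.append((f"ASV{i:04d}", "seasonal_indicator", season))
            i += 1
    return roster


def _sample_plan(spec: CommunitySpec) -> list[dict[str, object]]:
    plan = []
    for season in spec.seasons:
        for p in range(1, spec.n_profiles + 1):
            profile = f"{season[:2]}P{p}"
            for layer in spec.season_layers[season]:
                plan.append(
                    {
                        "sample_id": f"{profile}_{layer}",
                        "station": f"ST{p}",
                        "season": season,
                        "layer": layer,
                        "profile_id": profile,
                        "depth_m": _LAYER_DEPTH_M[layer],
                    }
                )
    return plan


def _taxonomy_for(roster) -> TaxonomyTable:
    lineages = {}
    for i, (asv, _cat, _season) in enumerate(roster):
        domain, phylum = _PHYLA_POOL[i % len(_PHYLA_POOL)]
        order_idx = (i // len(_PHYLA_POOL)) % _ORDERS_PER_PHYLUM
        lineages[asv] = (
            domain,
            phylum,
            f"{phylum}_class{order_idx}",
            f"{phylum}_order{order_idx}",
            f"{phylum}_family{order_idx}",
            f"Genus{i % 40}",
        )
    return TaxonomyTable(lineages)


def generate_community(
    spec: CommunitySpec, seed: int | None = None
) -> tuple[CountTable, TaxonomyTable, SampleMetadata, GroundTruth]:
    """Draw one synthetic community.

    Expected per-sample composition is the normalized product of a fixed
    per-taxon lognormal base abundance, the category-by-layer multiplier
    (with hard zeros), the DSL enrichment fold for ``dsl_enriched`` taxa and
    the seasonal fold for indicators in their own season. Counts come from a
    multinomial (optionally Dirichlet-overdispersed) at ``spec.depth``.
    Identical seeds give identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    roster = _taxon_roster(spec)
    plan = _sample_plan(spec)
    n_taxa = len(roster)
    base = np.exp(rng.normal(0.0, spec.lognormal_sigma, size=n_taxa))

    counts = np.zeros((n_taxa, len(plan)), dtype=np.int64)
    for j, sample in enumerate(plan):
        layer = str(sample["layer"])
        season = str(sample["season"])
        expected = np.empty(n_taxa)
        for i, (asv, cat, ind_season) in enumerate(roster):
            mult = _LAYER_MULTIPLIER[cat][layer]
            if mult > 0.0:
                if cat == "dsl_enriched" and layer == "DSL":
                    mult *= spec.enrichment_fold
                elif cat == "seasonal_indicator" and season == ind_season:
                    mult *= spec.indicator_fold
            expected[i] = base[i] * mult
        total = expected.sum()
        if total == 0:
            raise ValidationError(f"sample {sample['sample_id']} has empty expected composition")
        p = expected / total
        support = p > 0
        if spec.overdispersion is not None:
            p_draw = np.zeros(n_taxa)
            p_draw[support] = rng.dirichlet(spec.overdispersion * p[support])
            p = p_draw
        counts[:, j] = rng.multinomial(spec.depth, p)

    table = CountTable([r[0] for r in roster], [s["sample_id"] for s in plan], counts)
    taxonomy = _taxonomy_for(roster)
    metadata = SampleMetadata(
        pd.DataFrame(plan).set_index("sample_id")
    )
    category = {asv: cat for asv, cat, _ in roster}
    indicator_season = {asv: s for asv, _c, s in roster if s is not None}
    expected_partition = {
        asv: EXPECTED_PARTITION[cat]
        for asv, cat, _ in roster
        if cat in EXPECTED_PARTITION
    }
    enriched = frozenset(asv for asv, cat, _ in roster if cat == "dsl_enriched")
    truth = GroundTruth(category, indicator_season, expected_partition, enriched)
    return table, taxonomy, metadata, truth


def generate_env(
    spec: CommunitySpec,
    metadata: SampleMetadata,
    sd_fraction: float = 0.05,
    seed: int | None = None,
) -> SampleMetadata:
    """Fill layer-dependent environmental covariates.

    Each covariate is Gaussian around its layer mean with standard deviation
    ``sd_fraction`` times the mean's magnitude (0 gives the exact means).
    Epipelagic-vs-mesopelagic contrasts are built into the means:
    temperature, DOC and cell abundance fall with depth while salinity and
    nitrate rise.
    """
    if sd_fraction < 0:
        raise ValidationError("sd_fraction must be >= 0")
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    frame = metadata.frame.copy()
    layers = frame["layer"].to_numpy()
    for cov, means in _ENV_MEANS.items():
        mu = np.array([means[l] for l in layers], dtype=float)
        sd = sd_fraction * np.abs(mu)
        frame[cov] = mu + rng.normal(0.0, 1.0, size=len(mu)) * sd
    return SampleMetadata(frame)


def generate_eem(
    target_bix: float,
    excitation: np.ndarray | None = None,
    emission: np.ndarray | None = None,
) -> EEM:
    """Synthetic EEM whose BIX evaluates exactly to ``target_bix``.

    Intensity is linear in emission wavelength (and flat in excitation), so
    bilinear interpolation reproduces the planted 380/430 nm ratio exactly
    even when those wavelengths fall between grid points.
    """
    if target_bix <= 0:
        raise ValidationError("target_bix must be > 0")
    if excitation is None:
        excitation = np.arange(240.0, 601.0, 10.0)
    if emission is None:
        emission = np.arange(351.0, 462.0, 3.0)  # 3 nm steps; 380/430 off-grid
    excitation = np.asarray(excitation, dtype=float)
    emission = np.asarray(emission, dtype=float)
    if not (excitation[0] <= 310.0 <= excitation[-1]):
        raise ValidationError("excitation grid must cover 310 nm")
    if not (emission[0] <= 380.0 and 430.0 <= emission[-1]):
        raise ValidationError("emission grid must cover 380 and 430 nm")
    # f(em) linear with f(380) = t, f(430) = 1
    t = float(target_bix)
    f = t + (1.0 - t) * (emission - 380.0) / 50.0
    if (f <= 0).any():
        raise ValidationError(
            f"target_bix {t} produces non-positive intensities on this emission grid"
        )
    intensities = np.tile(f, (len(excitation), 1))
    return EEM(excitation, emission, intensities)
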
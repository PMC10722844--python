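"""Count-table, taxonomy and sample-metadata containers plus the
filtering / normalization operations that every downstream analysis
consumes.

The pipeline starts at a denoised ASV x sample matrix of read counts.
Processing order mirrors standard amplicon practice: drop off-target
lineages, drop dataset-wide singletons, then rarefy every sample to a
common depth.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEASONS = ("winter", "spring", "summer")
LAYERS = ("SURF", "DCM", "MS", "DSL", "MD")
EPIPELAGIC_LAYERS = ("SURF", "DCM")
MESOPELAGIC_LAYERS = ("MS", "DSL", "MD")

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
UNASSIGNED = "unassigned"

METADATA_COLUMNS = ("station", "season", "layer", "profile_id", "depth_m")


class ValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed; names the offending location."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """ASV x sample matrix of non-negative integer read counts.

    Parameters
    ----------
    asv_ids : sequence of str
        Unique row identifiers.
    sample_ids : sequence of str
        Unique column identifiers.
    counts : ndarray of shape (n_asvs, n_samples)
        Non-negative integers.
    """

    asv_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.asv_ids = list(map(str, self.asv_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if counts.shape != (len(self.asv_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.asv_ids)} ASVs x {len(self.sample_ids)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValidationError("counts must be integers")
        counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise ValidationError("counts must be non-negative")
        if len(set(self.asv_ids)) != len(self.asv_ids):
            dupes = _duplicates(self.asv_ids)
            raise ValidationError(f"duplicated ASV ids: {sorted(dupes)}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise ValidationError(f"duplicated sample ids: {sorted(dupes)}")
        self.counts = counts

    # -- basic accessors ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> np.ndarray:
        """Total reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    def asv_totals(self) -> np.ndarray:
        """Total reads per ASV over all samples (row sums)."""
        return self.counts.sum(axis=1)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id}") from None

    def select_asvs(self, keep: Sequence[str] | np.ndarray) -> "CountTable":
        """Row subset; ``keep`` is a boolean mask or a list of ASV ids."""
        mask = np.asarray(keep)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            pos = {a: i for i, a in enumerate(self.asv_ids)}
            idx = np.array([pos[a] for a in keep], dtype=int)
        return CountTable(
            [self.asv_ids[i] for i in idx], list(self.sample_ids), self.counts[idx]
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return CountTable(list(self.asv_ids), list(sample_ids), self.counts[:, idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.asv_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "CountTable":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())


@dataclass
class TaxonomyTable:
    """ASV id -> ordered lineage (domain..genus, optional species).

    Unassigned ranks are stored as the sentinel :data:`UNASSIGNED`, which can
    never collide with a real taxon name coming from a file (empty strings
    and ``NA`` are converted on read).
    """

    lineages: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, ...]] = {}
        for asv, lineage in self.lineages.items():
            lineage = tuple(lineage)
            if not 1 <= len(lineage) <= len(RANKS):
                raise ValidationError(
                    f"lineage for {asv!r} has {len(lineage)} ranks; expected 1-{len(RANKS)}"
                )
            clean[str(asv)] = tuple(
                UNASSIGNED if r is None or str(r).strip() in ("", "NA", UNASSIGNED)
                else str(r)
                for r in lineage
            )
        self.lineages = clean

    def __contains__(self, asv_id: str) -> bool:
        return asv_id in self.lineages

    def get(self, asv_id: str, rank: str) -> str:
        """Taxon name of ``asv_id`` at ``rank`` (``UNASSIGNED`` if unknown)."""
        idx = _rank_index(rank)
        lineage = self.lineages.get(asv_id)
        if lineage is None or idx >= len(lineage):
            return UNASSIGNED
        return lineage[idx]

    def to_dataframe(self) -> pd.DataFrame:
        width = max((len(v) for v in self.lineages.values()), default=6)
        rows = {
            a: list(v) + [UNASSIGNED] * (width - len(v))
            for a, v in self.lineages.items()
        }
        return pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS[:width]))


@dataclass
class SampleMetadata:
    """Per-sample station / season / layer / profile / depth plus free-form
    environmental covariates, indexed by sample id."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        frame = self.frame.copy()
        if frame.index.has_duplicates:
            dupes = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated sample ids in metadata: {dupes}")
        missing = [c for c in METADATA_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")
        bad_season = sorted(set(frame["season"]) - set(SEASONS))
        if bad_season:
            raise ValidationError(
                f"unknown season values {bad_season}; allowed: {list(SEASONS)}"
            )
        bad_layer = sorted(set(frame["layer"]) - set(LAYERS))
        if bad_layer:
            raise ValidationError(
                f"unknown layer values {bad_layer}; allowed: {list(LAYERS)}"
            )
        depth = pd.to_numeric(frame["depth_m"], errors="coerce")
        if depth.isna().any() or (depth <= 0).any():
            bad = frame.index[depth.isna() | (depth <= 0)].tolist()
            raise ValidationError(f"depth_m must be > 0; offending samples: {bad}")
        frame["depth_m"] = depth.astype(float)
        self.frame = frame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def env_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in METADATA_COLUMNS]

    def column(self, name: str) -> pd.Series:
        return self.frame[name]

    def samples_where(self, **criteria: object) -> list[str]:
        """Sample ids matching all equality ``criteria``
        (e.g. ``layer="DSL"``, ``season="spring"``)."""
        mask = pd.Series(True, index=self.frame.index)
        for col, value in criteria.items():
            mask &= self.frame[col] == value
        return list(self.frame.index[mask])

    def profiles(self) -> list[str]:
        return list(pd.unique(self.frame["profile_id"]))

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(sample_ids)])


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        (dup if x in seen else seen).add(x)
    return dup


def _rank_index(rank: str) -> int:
    try:
        return RANKS.index(rank)
    except ValueError:
        raise ValidationError(
            f"unknown rank {rank!r}; expected one of {list(RANKS)}"
        ) from None


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def read_counts(path: str | Path, format: str = "tsv") -> CountTable:
    """Read a count table.

    ``format="tsv"`` expects a matrix with ASV ids in the first column and a
    header row of sample ids. ``format="triples"`` expects three columns
    (asv_id, sample_id, count), one observation per line.
    """
    path = Path(path)
    if format == "tsv":
        try:
            frame = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise ParseError(f"{path}: {exc}") from exc
        _check_numeric_counts(frame, path)
        return CountTable.from_dataframe(frame.fillna(0))
    if format == "triples":
        try:
            frame = pd.read_csv(
                path, sep="\t", header=0, names=["asv_id", "sample_id", "count"]
            )
        except Exception as exc:  # pragma: no cover
            raise ParseError(f"{path}: {exc}") from exc
        pivot = frame.pivot_table(
            index="asv_id", columns="sample_id", values="count", fill_value=0,
            aggfunc="sum",
        )
        return CountTable.from_dataframe(pivot)
    raise ValueError(f"unsupported count-table format: {format!r}")


def _check_numeric_counts(frame: pd.DataFrame, path: Path) -> None:
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        if coerced.isna().any() and frame[col].notna().any():
            bad_rows = frame.index[coerced.isna() & frame[col].notna()]
            line = frame.index.get_loc(bad_rows[0]) + 2  # header + 1-based
            raise ParseError(
                f"{path}: non-numeric count in column {col!r} near line {line}"
            )
        frame[col] = coerced


def write_counts(table: CountTable, path: str | Path) -> None:
    table.to_dataframe().rename_axis("asv_id").to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a taxonomy table: ASV id followed by 6-7 rank columns; ``NA`` or
    empty means unassigned."""
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"{path}: {exc}") from exc
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicated ASV ids: {dupes}")
    n_ranks = min(frame.shape[1], len(RANKS))
    lineages = {
        str(asv): tuple(row[:n_ranks]) for asv, row in zip(frame.index, frame.to_numpy())
    }
    return TaxonomyTable(lineages)


def write_taxonomy(taxonomy: TaxonomyTable, path: str | Path) -> None:
    taxonomy.to_dataframe().rename_axis("asv_id").to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> SampleMetadata:
    try:
        frame = pd.read_csv(path, sep="\t", index_col="sample_id")
    except ValueError as exc:
        raise ParseError(f"{path}: missing 'sample_id' column ({exc})") from exc
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"{path}: {exc}") from exc
    frame.index = frame.index.map(str)
    return SampleMetadata(frame)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.frame.rename_axis("sample_id").to_csv(path, sep="\t")


def read_community(
    count_path: str | Path,
    taxonomy_path: str | Path,
    metadata_path: str | Path,
    format: str = "tsv",
) -> tuple[CountTable, TaxonomyTable, SampleMetadata]:
    """Read and cross-validate the (counts, taxonomy, metadata) triple.

    Every sample column in the counts must have a metadata record; taxonomy
    may cover only a subset of ASVs (downstream filters decide what to do
    with the rest).
    """
    table = read_counts(count_path, format=format)
    taxonomy = read_taxonomy(taxonomy_path)
    metadata = read_metadata(metadata_path)
    missing = [s for s in table.sample_ids if s not in metadata.frame.index]
    if missing:
        raise ValidationError(
            f"samples present in counts but absent from metadata: {missing}"
        )
    return table, taxonomy, metadata


# ---------------------------------------------------------------------------
# filtering / normalization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExcludeRule:
    """A lineage-based removal rule.

    ``rank=None`` means the rule applies to every rank. An ASV is dropped if
    its name at the rank is in ``names``, or (when ``keep`` is set) if its
    name at the rank is *not* in ``keep``.
    """

    rank: str | None = None
    names: frozenset[str] = frozenset()
    keep: frozenset[str] | None = None

    def matches(self, lineage: tuple[str, ...]) -> bool:
        if self.rank is None:
            values = lineage
        else:
            idx = _rank_index(self.rank)
            values = lineage[idx : idx + 1] if idx < len(lineage) else (UNASSIGNED,)
        if self.keep is not None:
            return any(v not in self.keep for v in values)
        return any(v in self.names for v in values)


def default_exclude_rules() -> list[ExcludeRule]:
    """Keep Bacteria/Archaea, drop organellar sequences at any rank."""
    return [
        ExcludeRule(rank="domain", keep=frozenset({"Bacteria", "Archaea"})),
        ExcludeRule(names=frozenset({"Chloroplast", "Mitochondria"})),
    ]


def filter_taxa(
    table: CountTable,
    taxonomy: TaxonomyTable,
    exclude_rules: Sequence[ExcludeRule] | None = None,
    missing_policy: str = "drop",
) -> CountTable:
    """Remove ASVs whose lineage matches any exclusion rule.

    ``exclude_rules=None`` applies :func:`default_exclude_rules`; an empty
    sequence disables lineage filtering entirely. ASVs absent from the
    taxonomy are dropped (``missing_policy="drop"``, with a logged warning)
    or kept (``"keep"``).
    """
    if exclude_rules is None:
        exclude_rules = default_exclude_rules()
    if missing_policy not in ("drop", "keep"):
        raise ValueError("missing_policy must be 'drop' or 'keep'")
    keep_mask = np.ones(len(table.asv_ids), dtype=bool)
    n_missing = 0
    for i, asv in enumerate(table.asv_ids):
        if asv not in taxonomy:
            n_missing += 1
            keep_mask[i] = missing_policy == "keep"
            continue
        lineage = taxonomy.lineages[asv]
        if any(rule.matches(lineage) for rule in exclude_rules):
            keep_mask[i] = False
    if n_missing:
        logger.warning(
            "%d ASVs missing from taxonomy (%s)", n_missing, missing_policy + "ped"
        )
    return table.select_asvs(keep_mask)


def remove_singletons(table: CountTable, min_total: int = 2) -> CountTable:
    """Drop ASVs whose dataset-wide total count is below ``min_total``
    (default: singletons, total count 1; all-zero rows also go)."""
    return table.select_asvs(table.asv_totals() >= min_total)


def rarefy(
    table: CountTable,
    depth: int,
    seed: int | np.random.Generator | None = None,
    auto_drop: bool = False,
) -> CountTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples with fewer reads than ``depth`` raise unless ``auto_drop``
    removes them. Identical seed gives identical output.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    shallow = [s for s, t in zip(table.sample_ids, totals) if t < depth]
    if shallow:
        if not auto_drop:
            raise ValidationError(
                f"samples below rarefaction depth {depth}: {shallow}"
            )
        logger.warning("dropping %d samples below depth %d: %s", len(shallow), depth, shallow)
        table = table.select_samples(
            [s for s in table.sample_ids if s not in set(shallow)]
        )
    out = np.empty_like(table.counts)
    for j in range(table.counts.shape[1]):
        col = table.counts[:, j]
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return CountTable(list(table.asv_ids), list(table.sample_ids), out)


def relative_abundance(table: CountTable | np.ndarray) -> np.ndarray:
    """Column-normalize counts to fractions summing to 1 per sample."""
    if isinstance(table, CountTable):
        counts = table.counts
        sample_ids = table.sample_ids
    else:
        counts = np.asarray(table, dtype=float)
        sample_ids = [str(i) for i in range(counts.shape[1])]
    totals = counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValidationError(
            f"all-zero samples cannot be normalized: {[sample_ids[i] for i in zero]}"
        )
    return counts / totals


def aggregate_rank(
    table: CountTable,
    taxonomy: TaxonomyTable,
    rank: str,
    include_unassigned: bool = True,
) -> CountTable:
    """Sum counts over all ASVs sharing a taxon name at ``rank``.

    ASVs unassigned at the rank (or absent from the taxonomy) are pooled
    into a single ``unassigned`` row, or dropped when
    ``include_unassigned=False``. Column totals are preserved exactly when
    the unassigned pool is kept.
    """
    if rank == "species":
        pass  # species is a legal rank when present in the lineages
    _rank_index(rank)  # validates
    names = [taxonomy.get(asv, rank) for asv in table.asv_ids]
    order: list[str] = []
    seen: set[str] = set()
    for n in names:
        if n != UNASSIGNED and n not in seen:
            seen.add(n)
            order.append(n)
    if include_unassigned and UNASSIGNED in names:
        order.append(UNASSIGNED)
    pos = {n: i for i, n in enumerate(order)}
    out = np.zeros((len(order), len(table.sample_ids)), dtype=np.int64)
    for row, name in zip(table.counts, names):
        if name in pos:
            out[pos[name]] += row
    return CountTable(order, list(table.sample_ids), out)
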
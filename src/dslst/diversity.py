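"""Alpha diversity, Bray-Curtis / PCoA ordination, PERMANOVA and
ordination-environment correlations, plus the BIX fluorescence ratio.

All permutation tests take an explicit seed and use the (b + 1)/(m + 1)
p-value estimator with ties (>=) counted as exceedances.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .community import CountTable, SampleMetadata, ValidationError, relative_abundance

logger = logging.getLogger(__name__)

_ADJUST_METHODS = {"bonferroni": "bonferroni", "holm": "holm", "bh": "fdr_bh",
                   "fdr_bh": "fdr_bh"}


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------


def shannon(sample_counts: np.ndarray) -> float:
    """Shannon entropy H = -sum(p_i ln p_i) in nats over positive counts."""
    counts = np.asarray(sample_counts, dtype=float)
    if counts.ndim != 1:
        raise ValueError("expected a single sample vector")
    if (counts < 0).any():
        raise ValueError("negative counts")
    total = counts.sum()
    if total <= 0:
        raise ValidationError("sample has no reads; Shannon undefined")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def richness(sample_counts: np.ndarray) -> int:
    """Number of taxa with count > 0."""
    return int((np.asarray(sample_counts) > 0).sum())


def pielou(h: float, n: int) -> float:
    """Pielou evenness J = H / ln(n); requires n >= 2."""
    if n <= 1:
        raise ValidationError("Pielou evenness undefined for n <= 1")
    return float(h / np.log(n))


def alpha_diversity(table: CountTable) -> pd.DataFrame:
    """Per-sample Shannon H, richness n and Pielou J (NaN where n <= 1)."""
    rows = []
    for j, sample in enumerate(table.sample_ids):
        col = table.counts[:, j]
        h = shannon(col)
        n = richness(col)
        j_even = pielou(h, n) if n >= 2 else float("nan")
        rows.append((sample, h, n, j_even))
    return pd.DataFrame(
        rows, columns=["sample_id", "shannon", "richness", "pielou"]
    ).set_index("sample_id")


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------


@dataclass
class DissimilarityMatrix:
    """Square symmetric sample x sample dissimilarities with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if values.shape != (n, n):
            raise ValidationError("dissimilarity matrix shape mismatch")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValidationError("dissimilarity matrix is not symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-12):
            raise ValidationError("dissimilarity matrix diagonal is not zero")
        self.values = values

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def submatrix(self, sample_ids: list[str]) -> "DissimilarityMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DissimilarityMatrix(list(sample_ids), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def bray_curtis(table: CountTable | np.ndarray, sample_ids: list[str] | None = None) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity d(x, y) = sum|x-y| / sum(x+y) between sample
    columns of a count table (or any abundance matrix, taxa x samples)."""
    if isinstance(table, CountTable):
        data = table.counts.astype(float)
        sample_ids = list(table.sample_ids)
    else:
        data = np.asarray(table, dtype=float)
        if sample_ids is None:
            sample_ids = [str(i) for i in range(data.shape[1])]
    if data.shape[1] < 2:
        raise ValidationError("need at least 2 samples")
    totals = data.sum(axis=0)
    if (totals == 0).any():
        bad = [sample_ids[i] for i in np.flatnonzero(totals == 0)]
        raise ValidationError(f"all-zero samples: {bad}")
    d = squareform(pdist(data.T, metric="braycurtis"))
    return DissimilarityMatrix(sample_ids, d)


# ---------------------------------------------------------------------------
# principal coordinates
# ---------------------------------------------------------------------------


@dataclass
class OrdinationResult:
    """Sample coordinates on positive-eigenvalue axes, ordered by eigenvalue."""

    sample_ids: list[str]
    coordinates: np.ndarray  # (n_samples, n_axes)
    eigenvalues: np.ndarray  # positive eigenvalues, non-increasing
    proportion_explained: np.ndarray  # over positive eigenvalues only

    def axis(self, k: int) -> np.ndarray:
        """1-based axis accessor."""
        return self.coordinates[:, k - 1]

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"PCoA{k + 1}" for k in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def pcoa(d: DissimilarityMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinates analysis.

    Gower-centers -0.5 * D^2, takes the symmetric eigendecomposition, and
    scales eigenvectors by sqrt(eigenvalue). Negative eigenvalues (the
    non-Euclidean part of e.g. Bray-Curtis) are excluded from both the
    coordinates and the variance-explained denominator; no Lingoes/Cailliez
    correction is applied.
    """
    dm = d.values
    n = dm.shape[0]
    a = -0.5 * dm**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-10 * max(abs(eigval[0]), 1.0), 0.0)
    pos = eigval > tol
    eigval_pos = eigval[pos]
    coords = eigvec[:, pos] * np.sqrt(eigval_pos)
    prop = eigval_pos / eigval_pos.sum() if eigval_pos.size else eigval_pos
    if n_axes is not None:
        coords = coords[:, :n_axes]
        eigval_pos = eigval_pos[:n_axes]
        prop = prop[:n_axes]
    return OrdinationResult(list(d.sample_ids), coords, eigval_pos, prop)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    statistic: float  # pseudo-F
    r_squared: float
    p_value: float
    n_permutations: int
    comparison: str | None = None
    adjusted_p: float | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        label = f"{self.comparison}: " if self.comparison else ""
        return (
            f"{label}pseudo-F={self.statistic:.4g} R2={self.r_squared:.4g} "
            f"p={self.p_value:.4g}"
        )


def _group_onehot(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray, list]:
    labels, inverse = np.unique(groups, return_inverse=True)
    onehot = np.zeros((len(groups), len(labels)))
    onehot[np.arange(len(groups)), inverse] = 1.0
    return onehot, onehot.sum(axis=0), list(labels)


def _pseudo_f(d2: np.ndarray, onehot: np.ndarray, sizes: np.ndarray,
              ss_total: float) -> tuple[float, float]:
    # SS_within = sum over groups of (within-group sum of d^2) / group size
    quad = np.einsum("ia,ij,ja->a", onehot, d2, onehot)
    ss_within = float((quad / (2.0 * sizes)).sum())
    ss_among = ss_total - ss_within
    n, a = onehot.shape[0], onehot.shape[1]
    f = (ss_among / (a - 1)) / (ss_within / (n - a))
    r2 = ss_among / ss_total
    return f, r2


def _coerce_groups(d: DissimilarityMatrix, groups) -> np.ndarray:
    if isinstance(groups, dict):
        return np.asarray([groups[s] for s in d.sample_ids])
    if isinstance(groups, pd.Series):
        return groups.loc[d.sample_ids].to_numpy()
    arr = np.asarray(groups)
    if len(arr) != len(d.sample_ids):
        raise ValidationError("group labels do not match number of samples")
    return arr


def permanova(
    d: DissimilarityMatrix,
    groups,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA (distance-based pseudo-F, label permutations).

    ``groups`` may be a label array aligned to ``d.sample_ids``, a mapping
    sample_id -> label, or a pandas Series indexed by sample id.
    """
    labels = _coerce_groups(d, groups)
    onehot, sizes, names = _group_onehot(labels)
    if len(names) < 2:
        raise ValidationError("PERMANOVA needs at least 2 groups")
    if sizes.min() < 2:
        small = [names[i] for i in np.flatnonzero(sizes < 2)]
        raise ValidationError(f"groups with fewer than 2 samples: {small}")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    d2 = d.values**2
    n = d2.shape[0]
    ss_total = float(d2.sum()) / (2.0 * n)
    f_obs, r2 = _pseudo_f(d2, onehot, sizes, ss_total)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        f_perm, _ = _pseudo_f(d2, onehot[perm], sizes, ss_total)
        if f_perm >= f_obs:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm)


def pairwise_permanova(
    d: DissimilarityMatrix,
    groups,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    adjust_method: str = "bonferroni",
) -> list[PermanovaResult]:
    """PERMANOVA on every unordered pair of groups, on the pair's submatrix,
    with p-values adjusted across all pairs (Bonferroni by default)."""
    if adjust_method not in _ADJUST_METHODS:
        raise ValueError(
            f"unknown adjust_method {adjust_method!r}; "
            f"choose from {sorted(set(_ADJUST_METHODS))}"
        )
    labels = _coerce_groups(d, groups)
    names = list(pd.unique(labels))
    if len(names) < 2:
        raise ValidationError("need at least 2 groups")
    results = []
    for g1, g2 in itertools.combinations(names, 2):
        mask = (labels == g1) | (labels == g2)
        ids = [s for s, m in zip(d.sample_ids, mask) if m]
        sub = d.submatrix(ids)
        res = permanova(sub, labels[mask], n_perm=n_perm, seed=seed)
        res.comparison = f"{g1} vs {g2}"
        results.append(res)
    raw = [r.p_value for r in results]
    adjusted = multipletests(raw, method=_ADJUST_METHODS[adjust_method])[1]
    for r, p_adj in zip(results, adjusted):
        r.adjusted_p = float(min(p_adj, 1.0))
    return results


# ---------------------------------------------------------------------------
# ordination-environment correlation
# ---------------------------------------------------------------------------


def axis_env_correlation(
    ordination: OrdinationResult,
    metadata: SampleMetadata,
    covariates: list[str] | None = None,
    axes: list[int] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation between ordination axes and (zero-centered,
    unit-scaled) environmental covariates.

    Samples with a missing covariate value are excluded pairwise. Constant
    covariates get NaN r and p with ``significant=False``.
    """
    if covariates is None:
        covariates = metadata.env_columns
    if axes is None:
        axes = list(range(1, ordination.coordinates.shape[1] + 1))
    rows = []
    for cov in covariates:
        series = pd.to_numeric(
            metadata.frame.loc[ordination.sample_ids, cov], errors="coerce"
        )
        valid = series.notna().to_numpy()
        if valid.sum() < len(series):
            logger.info(
                "covariate %s: excluding %d samples with missing values",
                cov, int((~valid).sum()),
            )
        values = series.to_numpy(dtype=float)[valid]
        if len(values) < 3 or np.std(values) == 0:
            for k in axes:
                rows.append((k, cov, float("nan"), float("nan"), False))
            continue
        scaled = (values - values.mean()) / values.std(ddof=0)
        for k in axes:
            axis_vals = ordination.axis(k)[valid]
            r, p = stats.pearsonr(axis_vals, scaled)
            rows.append((k, cov, float(r), float(p), bool(p < alpha)))
    return pd.DataFrame(
        rows, columns=["axis", "covariate", "r", "p", "significant"]
    )


# ---------------------------------------------------------------------------
# BIX fluorescence ratio
# ---------------------------------------------------------------------------


@dataclass
class EEM:
    """Excitation-emission fluorescence matrix on rectangular wavelength grids.

    ``intensities`` has one row per excitation wavelength and one column per
    emission wavelength; both axes strictly increasing, in nm.
    """

    excitation: np.ndarray
    emission: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.excitation = np.asarray(self.excitation, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.excitation), len(self.emission)):
            raise ValidationError("EEM intensity shape does not match wavelength axes")
        if np.any(np.diff(self.excitation) <= 0) or np.any(np.diff(self.emission) <= 0):
            raise ValidationError("EEM wavelength axes must be strictly increasing")

    def interpolate(self, ex: float, em: float) -> float:
        """Bilinear interpolation at (ex, em); raises outside the grid."""
        for name, grid, w in (("excitation", self.excitation, ex),
                              ("emission", self.emission, em)):
            if w < grid[0] or w > grid[-1]:
                raise ValidationError(
                    f"{name} wavelength {w} nm outside grid [{grid[0]}, {grid[-1]}]"
                )
        # interpolate along emission for the two bracketing excitation rows
        i = int(np.searchsorted(self.excitation, ex, side="right") - 1)
        i = min(i, len(self.excitation) - 2) if len(self.excitation) > 1 else 0
        row_vals = []
        idx = [i, i + 1] if len(self.excitation) > 1 else [0]
        for k in idx:
            row_vals.append(float(np.interp(em, self.emission, self.intensities[k])))
        if len(idx) == 1:
            return row_vals[0]
        x0, x1 = self.excitation[i], self.excitation[i + 1]
        t = 0.0 if x1 == x0 else (ex - x0) / (x1 - x0)
        return (1 - t) * row_vals[0] + t * row_vals[1]


def bix(eem: EEM) -> float:
    """Biological index: emission 380 nm over 430 nm at 310 nm excitation,
    linearly interpolated when the wavelengths fall between grid points."""
    num = eem.interpolate(310.0, 380.0)
    den = eem.interpolate(310.0, 430.0)
    if den == 0:
        raise ValidationError("zero intensity at (310, 430); BIX undefined")
    return num / den
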
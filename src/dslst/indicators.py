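"""Dufrene-Legendre indicator value (IndVal) analysis.

For ASV i and group g:

* specificity ``A = mean relative abundance in g / sum over groups of mean
  relative abundances`` (mean-abundance formulation),
* fidelity ``B = fraction of g's samples where i is present``,
* ``indval = A * B`` in [0, 1].

Significance is assessed by permuting group labels across samples and
comparing each ASV's permuted best-group indval to its observed one, with
the (b + 1)/(m + 1) estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import CountTable, TaxonomyTable, ValidationError, relative_abundance


@dataclass
class IndValResult:
    asv_ids: list[str]
    groups: list[str]
    specificity: np.ndarray  # A, (n_asvs, n_groups)
    fidelity: np.ndarray  # B, (n_asvs, n_groups)
    indval: np.ndarray  # A * B
    best_group: np.ndarray  # index into groups, per ASV
    p_values: np.ndarray | None = None  # per ASV, for the best group

    @property
    def best_indval(self) -> np.ndarray:
        return self.indval[np.arange(len(self.asv_ids)), self.best_group]

    def to_dataframe(self) -> pd.DataFrame:
        rows = np.arange(len(self.asv_ids))
        frame = pd.DataFrame(
            {
                "asv_id": self.asv_ids,
                "best_group": [self.groups[g] for g in self.best_group],
                "A": self.specificity[rows, self.best_group],
                "B": self.fidelity[rows, self.best_group],
                "indval": self.best_indval,
            }
        )
        if self.p_values is not None:
            frame["p"] = self.p_values
        return frame.set_index("asv_id")


def _coerce_group_array(table: CountTable, groups) -> np.ndarray:
    if isinstance(groups, dict):
        return np.asarray([groups[s] for s in table.sample_ids])
    if isinstance(groups, pd.Series):
        return groups.loc[table.sample_ids].to_numpy()
    arr = np.asarray(groups)
    if len(arr) != len(table.sample_ids):
        raise ValidationError("group labels do not match number of samples")
    return arr


def _indval_components(
    relabund: np.ndarray, onehot: np.ndarray, sizes: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    group_mean = relabund @ onehot / sizes  # (n_asvs, n_groups)
    mean_sum = group_mean.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(mean_sum > 0, group_mean / np.where(mean_sum > 0, mean_sum, 1.0), 0.0)
    b = (relabund > 0).astype(float) @ onehot / sizes
    return a, b, a * b


def _prepare(table: CountTable, groups):
    labels = _coerce_group_array(table, groups)
    names, inverse = np.unique(labels, return_inverse=True)
    if len(names) < 2:
        raise ValidationError("IndVal needs at least 2 groups")
    onehot = np.zeros((len(labels), len(names)))
    onehot[np.arange(len(labels)), inverse] = 1.0
    relabund = relative_abundance(table)
    return relabund, onehot, onehot.sum(axis=0), list(map(str, names))


def indval(table: CountTable, groups) -> IndValResult:
    """Indicator values for every (ASV, group), without p-values.

    ``groups`` maps each sample to a label (dict, aligned array or pandas
    Series indexed by sample id). ASVs absent everywhere get indval 0 in all
    groups.
    """
    relabund, onehot, sizes, names = _prepare(table, groups)
    a, b, iv = _indval_components(relabund, onehot, sizes)
    best = iv.argmax(axis=1)
    return IndValResult(list(table.asv_ids), names, a, b, iv, best)


def indval_significance(
    table: CountTable,
    groups,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> IndValResult:
    """IndVal with permutation p-values for each ASV's best group."""
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    relabund, onehot, sizes, names = _prepare(table, groups)
    a, b, iv = _indval_components(relabund, onehot, sizes)
    best = iv.argmax(axis=1)
    observed = iv.max(axis=1)
    rng = np.random.default_rng(seed)
    n = onehot.shape[0]
    exceed = np.zeros(len(table.asv_ids), dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, _, iv_perm = _indval_components(relabund, onehot[perm], sizes)
        exceed += iv_perm.max(axis=1) >= observed - 1e-12
    p = (exceed + 1) / (n_perm + 1)
    return IndValResult(list(table.asv_ids), names, a, b, iv, best, p)


def select_indicators(
    result: IndValResult,
    p_thresh: float = 0.05,
    indval_thresh: float = 0.5,
    adjust: str | None = None,
) -> set[tuple[str, str]]:
    """(ASV, best group) pairs with ``p < p_thresh`` and
    ``indval > indval_thresh`` (strict inequalities).

    ``adjust="bh"`` applies Benjamini-Hochberg across ASVs before
    thresholding; the default applies raw p-values.
    """
    if not (0 < p_thresh < 1 and 0 < indval_thresh < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    if result.p_values is None:
        raise ValidationError("result has no p-values; run indval_significance")
    p = np.asarray(result.p_values, dtype=float)
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        p = multipletests(p, method="fdr_bh")[1]
    elif adjust not in (None, "none"):
        raise ValueError("adjust must be None or 'bh'")
    selected = set()
    for i, asv in enumerate(result.asv_ids):
        if p[i] < p_thresh and result.best_indval[i] > indval_thresh:
            selected.add((asv, result.groups[result.best_group[i]]))
    return selected


def indicator_summary(
    selected: set[tuple[str, str]],
    table: CountTable,
    taxonomy: TaxonomyTable | None,
    groups,
    top_orders: int = 15,
) -> pd.DataFrame:
    """Per-group indicator totals as displayed in stacked-bar summaries.

    For each group: number of indicator ASVs, mean and standard error of
    their summed relative abundance across the group's samples, and (when a
    taxonomy is given) the breakdown of that mean abundance by order,
    truncated to the ``top_orders`` most abundant orders dataset-wide.
    """
    labels = _coerce_group_array(table, groups)
    relabund = relative_abundance(table)
    asv_pos = {a: i for i, a in enumerate(table.asv_ids)}
    rows = []
    for name in pd.unique(labels):
        cols = np.flatnonzero(labels == name)
        members = [asv for asv, g in selected if g == name]
        idx = [asv_pos[a] for a in members if a in asv_pos]
        if idx:
            per_sample = relabund[np.ix_(idx, cols)].sum(axis=0)
            mean = float(per_sample.mean())
            se = (
                float(per_sample.std(ddof=1) / np.sqrt(len(cols)))
                if len(cols) > 1
                else 0.0
            )
        else:
            mean, se = 0.0, 0.0
        row = {
            "group": name,
            "n_indicators": len(idx),
            "mean_abundance": mean,
            "se_abundance": se,
        }
        if taxonomy is not None and idx:
            by_order: dict[str, float] = {}
            for i in idx:
                order = taxonomy.get(table.asv_ids[i], "order")
                by_order[order] = by_order.get(order, 0.0) + float(
                    relabund[i, cols].mean()
                )
            top = sorted(by_order.items(), key=lambda kv: kv[1], reverse=True)
            row["order_breakdown"] = dict(top[:top_orders])
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
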
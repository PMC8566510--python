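"""The batch-robust normal-vs-cancer rank-change statistic.

Each tissue contributes a trio of count datasets — GTEx normal, TCGA
normal (optional), TCGA cancer.  Genes are whitelisted in two stages
(raw-count sum, then mean normalized expression), the datasets are
quantile-normalized together, and each gene's expression rank in cancer is
compared against its rank in a joined normal reference.  Because only
ranks cross the dataset boundary, any per-dataset monotone distortion of
expression leaves the statistic unchanged — the property that lets
datasets from different consortia be compared without joint batch
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, MatrisomeCatalog, ValidationError
from .normalize import quantile_normalize, vst_transform

__all__ = [
    "DatasetTrio",
    "Whitelist",
    "RankChangeResult",
    "build_whitelist",
    "mean_rank_profiles",
    "rank_change_summary",
    "group_wilcoxon",
]


@dataclass
class DatasetTrio:
    """Raw-count datasets for one tissue: GTEx-N, TCGA-N (optional), TCGA-C."""

    tissue: str
    gtex_normal: ExpressionMatrix
    tcga_cancer: ExpressionMatrix
    tcga_normal: ExpressionMatrix | None = None

    def __post_init__(self) -> None:
        shared = set(self.gtex_normal.gene_ids) & set(self.tcga_cancer.gene_ids)
        if self.tcga_normal is not None:
            shared &= set(self.tcga_normal.gene_ids)
        if not shared:
            raise ValidationError(f"{self.tissue}: dataset gene universes do not intersect")

    @property
    def datasets(self) -> dict[str, ExpressionMatrix]:
        out = {"gtex_normal": self.gtex_normal}
        if self.tcga_normal is not None:
            out["tcga_normal"] = self.tcga_normal
        out["tcga_cancer"] = self.tcga_cancer
        return out


@dataclass
class Whitelist:
    """Two-stage gene whitelist with the per-dataset VST matrices behind it."""

    genes: list[str]
    stage1_genes: list[str]
    vst: dict[str, ExpressionMatrix]


@dataclass
class RankChangeResult:
    """Per-tissue and summed rank deltas with decile labels."""

    per_tissue_delta: pd.DataFrame     # genes x tissues, NaN where not whitelisted
    per_tissue_decile: pd.DataFrame    # genes x tissues, NA where not whitelisted
    summed: pd.Series                  # gene -> sum of deltas over covered tissues
    summed_decile: pd.Series
    top10: list[str]
    bottom10: list[str]
    consistency: dict = field(default_factory=dict)


def build_whitelist(
    trio: DatasetTrio,
    catalog: MatrisomeCatalog | None = None,
    min_raw_sum: float = 5.0,
    min_mean_norm: float = 5.0,
) -> Whitelist:
    """Two-stage expression whitelist for one tissue's trio.

    Stage 1 keeps genes whose raw-count sum is strictly above
    ``min_raw_sum`` in every dataset (a gene must be rankable everywhere).
    Each dataset is then VST-normalized over the stage-1 genes, and stage 2
    keeps genes whose mean normalized value exceeds ``min_mean_norm`` in at
    least one dataset — letting in genes silent in normal tissue but high
    in cancer.  With a catalog, the final list is intersected with the
    core-matrisome + ECM-regulator selection.
    """
    datasets = trio.datasets
    shared = set.intersection(*(set(m.gene_ids) for m in datasets.values()))
    stage1 = set(shared)
    for m in datasets.values():
        sums = m.data.loc[sorted(shared)].sum(axis=1)
        stage1 &= set(sums.index[sums > min_raw_sum])
    if not stage1:
        raise ValidationError(f"{trio.tissue}: stage-1 whitelist is empty")
    stage1_genes = sorted(stage1)
    vst = {name: vst_transform(m.subset_genes(stage1_genes)) for name, m in datasets.items()}
    stage2: set[str] = set()
    for v in vst.values():
        means = v.data.mean(axis=1)
        stage2 |= set(means.index[means > min_mean_norm])
    genes = stage2
    if catalog is not None:
        genes &= catalog.core_plus_regulators()
    if not genes:
        raise ValidationError(f"{trio.tissue}: whitelist is empty")
    return Whitelist(genes=sorted(genes), stage1_genes=stage1_genes, vst=vst)


def _ascending_ranks(values: pd.Series) -> pd.Series:
    """Rank 1 = lowest expression; ties get average ranks."""
    return pd.Series(rankdata(values.to_numpy(), method="average"), index=values.index)


def rank_change_from_means(means: dict[str, pd.Series]) -> pd.DataFrame:
    """Ranks and the cancer-vs-joined-normal delta from per-dataset means.

    Joined-N is the unweighted mean of the GTEx-normal and TCGA-normal
    per-gene means (GTEx-normal alone when TCGA-normal is absent); ranks
    ascend with expression (rank 1 = lowest), so a positive delta means
    relatively higher expression in cancer.  Because only ranks cross the
    dataset boundary, the delta is exactly invariant to strictly monotone
    transforms of the cancer mean vector, and of every dataset's mean
    vector when the normal reference is a single dataset.
    """
    names = list(means)
    if "tcga_normal" in means:
        joined = (means["gtex_normal"] + means["tcga_normal"]) / 2.0
    else:
        joined = means["gtex_normal"].copy()
    out = pd.DataFrame(
        {f"mean_{n}": means[n] for n in names} | {"mean_joined_normal": joined}
    )
    for n in names:
        out[f"rank_{n}"] = _ascending_ranks(means[n])
    out["rank_joined_normal"] = _ascending_ranks(joined)
    out["delta"] = out["rank_tcga_cancer"] - out["rank_joined_normal"]
    return out


def mean_rank_profiles(trio: DatasetTrio, whitelist: Whitelist) -> pd.DataFrame:
    """Per-dataset mean expression and ranks on the whitelist, plus Joined-N.

    The trio's VST matrices are restricted to the whitelist, quantile-
    normalized together, and re-separated before per-dataset per-gene
    means are taken and ranked (see :func:`rank_change_from_means`).
    """
    order = list(whitelist.genes)
    mats = {name: v.subset_genes(order) for name, v in whitelist.vst.items()}
    names = list(mats)
    normalized = quantile_normalize([mats[n] for n in names])
    means = {n: m.data.mean(axis=1) for n, m in zip(names, normalized)}
    return rank_change_from_means(means)


def _equal_count_deciles(values: pd.Series, n_bins: int = 10) -> pd.Series:
    """Equal-count decile labels 1..n on values; ties broken by index order."""
    # Stable sort after lexicographic pre-sort == order by (value, gene id).
    ordered_index = values.loc[sorted(values.index)].sort_values(kind="mergesort").index
    labels = pd.Series(0, index=values.index, dtype=int)
    for d, chunk in enumerate(np.array_split(np.asarray(ordered_index), n_bins), start=1):
        labels.loc[chunk] = d
    return labels


def _equal_width_deciles(values: pd.Series, n_bins: int = 10) -> pd.Series:
    edges = np.linspace(values.min(), values.max(), n_bins + 1)
    edges[-1] += 1e-9
    return pd.Series(
        np.digitize(values.to_numpy(), edges[1:-1]) + 1, index=values.index, dtype=int
    )


def rank_change_summary(
    profiles_by_tissue: dict[str, pd.DataFrame],
    n_top: int = 10,
    n_bins: int = 10,
    decile_mode: str = "equal_count",
) -> RankChangeResult:
    """Combine per-tissue rank deltas into the multi-tissue statistic.

    Per-tissue deltas are summed per gene over the tissues where the gene
    is whitelisted; deciles (equal-count by default) are computed on each
    tissue's deltas and on the summed values; the top/bottom ``n_top``
    genes by summed delta are reported along with consistency counts (how
    many of their per-tissue cells fall in the extreme deciles).
    """
    if not profiles_by_tissue:
        raise ValidationError("need at least one tissue")
    binner = _equal_count_deciles if decile_mode == "equal_count" else _equal_width_deciles
    deltas = pd.DataFrame(
        {tissue: prof["delta"] for tissue, prof in profiles_by_tissue.items()}
    )
    deltas = deltas.dropna(how="all")
    deciles = pd.DataFrame(
        {
            tissue: binner(prof["delta"].dropna(), n_bins)
            for tissue, prof in profiles_by_tissue.items()
        }
    ).reindex(deltas.index)
    summed = deltas.sum(axis=1, skipna=True)
    summed_decile = binner(summed, n_bins)
    by_sum = summed.loc[sorted(summed.index)].sort_values(kind="mergesort")
    bottom = list(by_sum.index[:n_top])
    top = list(by_sum.index[-n_top:][::-1])
    top_cells = deciles.loc[top].to_numpy(dtype=float)
    bottom_cells = deciles.loc[bottom].to_numpy(dtype=float)
    consistency = {
        "top_in_top_decile": int(np.nansum(top_cells == n_bins)),
        "top_cells": int(np.isfinite(top_cells).sum()),
        "bottom_in_bottom_decile": int(np.nansum(bottom_cells == 1)),
        "bottom_cells": int(np.isfinite(bottom_cells).sum()),
    }
    return RankChangeResult(
        per_tissue_delta=deltas,
        per_tissue_decile=deciles,
        summed=summed,
        summed_decile=summed_decile,
        top10=top,
        bottom10=bottom,
        consistency=consistency,
    )


def group_wilcoxon(
    values: pd.DataFrame,
    groups: pd.Series,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene two-group Wilcoxon rank-sum with Holm adjustment.

    ``values`` is genes x samples (normalized expression); ``groups`` a
    two-level label over samples.  Exact p-values for small tie-free
    samples, normal approximation with tie correction otherwise.
    Direction is the sign of the median difference (first level minus
    second, levels in sorted order).
    """
    groups = groups.reindex(values.columns)
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValidationError(f"need exactly two group levels, got {levels}")
    a_ids = groups.index[groups == levels[0]]
    b_ids = groups.index[groups == levels[1]]
    if len(a_ids) < 3 or len(b_ids) < 3:
        raise ValidationError("both groups need >= 3 observations")
    genes = list(values.index) if genes is None else genes
    rows = []
    for g in genes:
        a = values.loc[g, a_ids].to_numpy(dtype=float)
        b = values.loc[g, b_ids].to_numpy(dtype=float)
        stat, p = mannwhitneyu(a, b, alternative="two-sided", method="auto")
        rows.append(
            {
                "gene_id": g,
                "statistic": float(stat),
                "p": float(p),
                "direction": int(np.sign(np.median(a) - np.median(b))),
            }
        )
    out = pd.DataFrame(rows)
    out["holm_p"] = multipletests(out["p"], method="holm")[1]
    return out
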
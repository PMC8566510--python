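"""Protein-transcript concordance benchmarking.

A matrisome category's protein-vs-transcript Spearman correlation in a
tissue is judged against an empirical null built by repeatedly drawing
equally many non-matrisome protein-gene pairs: the observed correlation is
classified inferior / equivalent / superior by its position in that null.
The module also provides the Kendall tissue correlation matrix with
hierarchical ordering and the category-vs-background Mann-Whitney test.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import kendalltau, mannwhitneyu, rankdata, spearmanr
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, MatrisomeCatalog, ValidationError
from .normalize import TissueProfile

__all__ = [
    "PairedAbundanceTable",
    "PermutationVerdict",
    "build_pair_table",
    "rank_correlation",
    "permutation_classify",
    "correlation_matrix",
    "category_background_test",
]

NON_MATRISOME = "non_matrisome"


@dataclass
class PairedAbundanceTable:
    """Rows of (tissue, gene_id, protein_abundance, transcript_abundance, category).

    Both abundances are strictly positive; zero or missing measurements are
    dropped at construction, mirroring the requirement that pairs have
    detectable levels of both the protein and the transcript.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"tissue", "gene_id", "protein_abundance", "transcript_abundance", "category"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"pair table missing columns: {sorted(missing)}")
        if (self.data[["protein_abundance", "transcript_abundance"]] <= 0).any().any():
            raise ValidationError("abundances must be strictly positive")
        if self.data.duplicated(subset=["tissue", "gene_id"]).any():
            raise ValidationError("one row per (tissue, gene) required")

    def in_tissue(self, tissue: str) -> pd.DataFrame:
        return self.data[self.data["tissue"] == tissue]

    @property
    def tissues(self) -> list[str]:
        return sorted(self.data["tissue"].unique())


@dataclass
class PermutationVerdict:
    tissue: str
    category: str
    n_pairs: int
    observed_rho: float
    null_rhos: np.ndarray
    percentile: float
    verdict: str  # inferior | equivalent | superior


def build_pair_table(
    protein: pd.DataFrame,
    transcript: pd.DataFrame,
    catalog: MatrisomeCatalog,
) -> PairedAbundanceTable:
    """Inner-join protein and transcript abundances on (tissue, gene).

    Both inputs need columns ``tissue``, ``gene_id``, ``value``.  Pairs with
    a zero or missing value on either side are dropped.  Genes absent from
    the catalog are labeled ``non_matrisome``.
    """
    merged = protein.rename(columns={"value": "protein_abundance"}).merge(
        transcript.rename(columns={"value": "transcript_abundance"}),
        on=["tissue", "gene_id"],
        how="inner",
    )
    if merged.empty:
        raise ValidationError("protein and transcript tables share no (tissue, gene) pairs")
    merged = merged.dropna(subset=["protein_abundance", "transcript_abundance"])
    merged = merged[
        (merged["protein_abundance"] > 0) & (merged["transcript_abundance"] > 0)
    ].copy()
    merged["category"] = merged["gene_id"].map(
        lambda g: catalog.category_of(g) or NON_MATRISOME
    )
    return PairedAbundanceTable(merged.reset_index(drop=True))


def rank_correlation(x: np.ndarray, y: np.ndarray, method: str = "spearman") -> float:
    """Spearman rho (average ranks) or Kendall tau-b; NaN for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("vectors must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: correlation undefined", stacklevel=2)
        return float("nan")
    if method == "spearman":
        return float(spearmanr(x, y).statistic)
    if method == "kendall":
        return float(kendalltau(x, y).statistic)
    raise ValidationError(f"unknown method {method!r}")


def _per_category_seed(seed: int, tissue: str, category: str) -> np.random.Generator:
    """An independent, reproducible stream per (tissue, category)."""
    tag = zlib.crc32(f"{tissue}\x00{category}".encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def _batched_spearman(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Spearman rho for paired (n_draws, N) matrices."""
    rx = rankdata(x, method="average", axis=1)
    ry = rankdata(y, method="average", axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    with np.errstate(invalid="ignore"):
        return (rx * ry).sum(axis=1) / denom


def permutation_classify(
    pairs: PairedAbundanceTable,
    tissue: str,
    category: str,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> PermutationVerdict:
    """Classify a category's protein-transcript correlation against a null.

    The null distribution is the Spearman rho of ``n_perm`` random
    subsets — each of the category's size, sampled without replacement —
    of the tissue's non-matrisome pairs.  The verdict is ``superior`` if
    the observed rho exceeds the (1 - alpha/2) empirical quantile,
    ``inferior`` below the alpha/2 quantile, ``equivalent`` otherwise.
    """
    sub = pairs.in_tissue(tissue)
    cat_rows = sub[sub["category"] == category]
    bg_rows = sub[sub["category"] == NON_MATRISOME]
    n = len(cat_rows)
    if n < 3:
        raise ValidationError(f"category {category} has {n} pairs in {tissue}; need >= 3")
    if len(bg_rows) < n:
        raise ValidationError(
            f"only {len(bg_rows)} non-matrisome pairs available; need >= {n}"
        )
    observed = rank_correlation(
        cat_rows["protein_abundance"].to_numpy(),
        cat_rows["transcript_abundance"].to_numpy(),
    )
    rng = _per_category_seed(seed, tissue, category)
    prot = bg_rows["protein_abundance"].to_numpy()
    trans = bg_rows["transcript_abundance"].to_numpy()
    m = len(bg_rows)
    # Each row of idx is an independent without-replacement sample of size n.
    idx = np.argsort(rng.random((n_perm, m)), axis=1)[:, :n]
    null_rhos = _batched_spearman(prot[idx], trans[idx])
    lo, hi = np.quantile(null_rhos, [alpha / 2, 1 - alpha / 2])
    if observed > hi:
        verdict = "superior"
    elif observed < lo:
        verdict = "inferior"
    else:
        verdict = "equivalent"
    percentile = float(np.mean(null_rhos <= observed))
    return PermutationVerdict(
        tissue=tissue,
        category=category,
        n_pairs=n,
        observed_rho=observed,
        null_rhos=null_rhos,
        percentile=percentile,
        verdict=verdict,
    )


def correlation_matrix(
    profiles: TissueProfile | pd.DataFrame,
    method: str = "kendall",
    linkage_method: str = "complete",
) -> tuple[pd.DataFrame, list[str]]:
    """Entity-by-entity rank correlation matrix with a dendrogram leaf order.

    ``profiles`` holds one column per entity (tissue).  Constant columns
    are excluded with a warning.  The returned leaf order comes from
    hierarchical clustering on Euclidean distances between rows of the
    ``1 - correlation`` matrix, the layout used for tissue heatmaps.
    """
    if isinstance(profiles, TissueProfile):
        profiles = profiles.data
    keep = [c for c in profiles.columns if np.ptp(profiles[c].to_numpy()) > 0]
    dropped = set(profiles.columns) - set(keep)
    if dropped:
        warnings.warn(f"constant profiles excluded: {sorted(dropped)}", stacklevel=2)
    profiles = profiles[keep]
    k = len(keep)
    if k < 2:
        raise ValidationError("need >= 2 non-constant entities")
    corr = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            corr[i, j] = corr[j, i] = rank_correlation(
                profiles.iloc[:, i].to_numpy(), profiles.iloc[:, j].to_numpy(), method
            )
    corr_df = pd.DataFrame(corr, index=keep, columns=keep)
    dist_rows = pdist(1.0 - corr, metric="euclidean")
    Z = hierarchy.linkage(dist_rows, method=linkage_method)
    order = [keep[i] for i in hierarchy.leaves_list(Z)]
    return corr_df, order


def category_background_test(
    correlations: pd.DataFrame,
    background_label: str = NON_MATRISOME,
) -> pd.DataFrame:
    """Per-category Mann-Whitney U of correlations against all other rows.

    ``correlations`` has columns ``pair_id``, ``correlation``, ``category``.
    Each category (other than the background label) is compared two-sided
    against the pooled correlations of every other row; p-values are
    Benjamini-Hochberg adjusted across categories.
    """
    results = []
    categories = [c for c in correlations["category"].unique() if c != background_label]
    for cat in sorted(categories):
        cat_vals = correlations.loc[correlations["category"] == cat, "correlation"].to_numpy()
        bg_vals = correlations.loc[correlations["category"] != cat, "correlation"].to_numpy()
        if len(cat_vals) < 3 or len(bg_vals) < 3:
            warnings.warn(f"category {cat} skipped (too few correlations)", stacklevel=2)
            continue
        stat, p = mannwhitneyu(cat_vals, bg_vals, alternative="two-sided")
        results.append(
            {
                "category": cat,
                "n": len(cat_vals),
                "statistic": float(stat),
                "median_diff": float(np.median(cat_vals) - np.median(bg_vals)),
                "p": float(p),
            }
        )
    if not results:
        return pd.DataFrame(columns=["category", "n", "statistic", "median_diff", "p", "fdr_p"])
    out = pd.DataFrame(results)
    out["fdr_p"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
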
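"""High-variance co-expression clustering and cluster scores.

Genes passing a mean/variance filter are clustered on 1 - Kendall's tau
distances; the dendrogram is cut so every reported cluster's mean pairwise
tau clears a significance threshold (the tau-critical value).  A cluster
whose genes split into two internally coherent but mutually anti-correlated
halves is reported as a paired sub-cluster (the fibrosis-program pattern
seen in adipose and lung).  Per-sample cluster scores are the mean of
mean-centered, tissue-MAD-scaled expression over the cluster's genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import kendalltau, norm

from .io import ExpressionMatrix, SampleTable, ValidationError

__all__ = [
    "GeneClusterSet",
    "ClusterScore",
    "AssociationResult",
    "high_variance_filter",
    "tau_critical",
    "cut_clusters",
    "cluster_score",
    "association_models",
    "multi_tissue_gene_score",
    "select_extreme_subjects",
    "sample_cluster",
]


@dataclass
class GeneClusterSet:
    """Disjoint gene clusters from a tau-critical dendrogram cut."""

    clusters: dict[str, list[str]]
    tau_critical: float
    cut_height: float | None
    linkage_record: np.ndarray | None
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def labels(self) -> list[str]:
        return list(self.clusters)


@dataclass
class ClusterScore:
    """Per-sample cluster score S_i with the quantities behind it."""

    scores: pd.Series
    cluster_label: str
    genes_used: dict[str, list[str]]      # tissue -> genes with nonzero MAD
    excluded_genes: dict[str, list[str]]  # tissue -> zero-MAD genes

    def J(self, tissue: str) -> int:
        return len(self.genes_used[tissue])


@dataclass
class AssociationResult:
    """Fitted fixed-effect (and optional random-intercept) model."""

    response: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    random_intercept_variance: float | None
    residual_variance: float
    n_obs: int


def high_variance_filter(
    expr: ExpressionMatrix,
    mean_min: float = 5.0,
    var_min: float = 1.5,
) -> list[str]:
    """Genes with mean > ``mean_min`` and sample variance > ``var_min``."""
    if expr.units != "vst":
        raise ValidationError("variance filter operates on VST expression")
    means = expr.values.mean(axis=1)
    variances = expr.values.var(axis=1, ddof=1)
    keep = (means > mean_min) & (variances > var_min)
    retained = [g for g, k in zip(expr.gene_ids, keep) if k]
    if not retained:
        raise ValidationError(
            "no gene passes the mean/variance filter; lower the thresholds"
        )
    return retained


def tau_critical(n_samples: int, n_genes: int, alpha: float = 0.05) -> float:
    """Significance threshold for Kendall's tau at a given sample count.

    Under independence tau is asymptotically normal with standard
    deviation sqrt(2(2n+5) / (9n(n-1))); the two-sided level is Bonferroni
    corrected over the C(n_genes, 2) gene pairs being examined.
    """
    if n_samples < 4:
        raise ValidationError("tau critical needs >= 4 samples")
    if n_genes < 2:
        raise ValidationError("tau critical needs >= 2 genes")
    n_pairs = comb(n_genes, 2)
    alpha_adj = alpha / n_pairs
    z = norm.ppf(1.0 - alpha_adj / 2.0)
    sd = np.sqrt(2.0 * (2 * n_samples + 5) / (9.0 * n_samples * (n_samples - 1)))
    return float(z * sd)


def pairwise_kendall(values: np.ndarray) -> np.ndarray:
    """Gene-by-gene Kendall tau-b matrix (genes are rows)."""
    g = values.shape[0]
    tau = np.eye(g)
    for i in range(g):
        for j in range(i + 1, g):
            t = kendalltau(values[i], values[j]).statistic
            tau[i, j] = tau[j, i] = 0.0 if np.isnan(t) else t
    return tau


def _mean_offdiag(tau: np.ndarray, idx: np.ndarray) -> float:
    sub = tau[np.ix_(idx, idx)]
    k = len(idx)
    return float((sub.sum() - k) / (k * (k - 1)))


def _try_anti_split(
    tau: np.ndarray, idx: np.ndarray, tau_crit: float
) -> tuple[np.ndarray, np.ndarray] | None:
    """Split a cluster into two anti-correlated halves if both are coherent."""
    if len(idx) < 4:
        return None
    sub = 1.0 - tau[np.ix_(idx, idx)]
    Z = hierarchy.linkage(squareform(sub, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    half1, half2 = idx[labels == 1], idx[labels == 2]
    if len(half1) < 2 or len(half2) < 2:
        return None
    if _mean_offdiag(tau, half1) < tau_crit or _mean_offdiag(tau, half2) < tau_crit:
        return None
    cross = tau[np.ix_(half1, half2)].mean()
    if cross >= 0:
        return None
    return half1, half2


def cut_clusters(
    expr: ExpressionMatrix,
    alpha: float = 0.05,
    tau_crit: float | None = None,
    linkage_method: str = "average",
) -> GeneClusterSet:
    """Cut a 1 - tau dendrogram into clusters clearing the tau threshold.

    Candidate cut heights (the tree's merge heights) are scanned from the
    coarsest partition down; the first partition in which every cluster of
    size >= 2 is valid is accepted.  A cluster is valid when its mean
    pairwise tau reaches the critical value, or when it splits into two
    internally valid, mutually anti-correlated halves — reported as paired
    sub-clusters ``Ck.1`` / ``Ck.2``.  Singletons are discarded.  If no
    partition qualifies the result is empty.
    """
    genes = expr.gene_ids
    if len(genes) < 3:
        raise ValidationError("clustering needs >= 3 genes")
    # Sort genes for input-order invariance of the whole procedure.
    order = np.argsort(genes)
    genes = [genes[i] for i in order]
    values = expr.values[order]
    n = expr.n_samples
    if tau_crit is None:
        tau_crit = tau_critical(n, len(genes), alpha)
    tau = pairwise_kendall(values)
    dist = squareform(1.0 - tau, checks=False)
    Z = hierarchy.linkage(dist, method=linkage_method)

    heights = np.unique(Z[:, 2])[::-1]
    for h in heights:
        labels = hierarchy.fcluster(Z, t=h, criterion="distance")
        members = [np.flatnonzero(labels == c) for c in np.unique(labels)]
        big = [m for m in members if len(m) >= 2]
        if not big:
            continue
        parts: list[tuple[np.ndarray, ...]] = []
        ok = True
        for m in big:
            if _mean_offdiag(tau, m) >= tau_crit and tau[np.ix_(m, m)].min() >= 0:
                parts.append((m,))
                continue
            split = _try_anti_split(tau, m, tau_crit)
            if split is not None:
                parts.append(split)
                continue
            if _mean_offdiag(tau, m) >= tau_crit:
                parts.append((m,))  # coherent despite a few negative pairs
                continue
            ok = False
            break
        if ok:
            clusters: dict[str, list[str]] = {}
            for k, piece in enumerate(
                sorted(parts, key=lambda p: -sum(len(q) for q in p)), start=1
            ):
                if len(piece) == 1:
                    clusters[f"C{k}"] = [genes[i] for i in piece[0]]
                else:
                    for s, half in enumerate(piece, start=1):
                        clusters[f"C{k}.{s}"] = [genes[i] for i in half]
            return GeneClusterSet(
                clusters=clusters,
                tau_critical=tau_crit,
                cut_height=float(h),
                linkage_record=Z,
                params={"alpha": alpha, "linkage": linkage_method},
            )
    warnings.warn("no partition satisfies the tau bound; empty cluster set", stacklevel=2)
    return GeneClusterSet(
        clusters={},
        tau_critical=tau_crit,
        cut_height=None,
        linkage_record=Z,
        params={"alpha": alpha, "linkage": linkage_method},
    )


def cluster_score(
    expr: ExpressionMatrix,
    samples: SampleTable,
    genes: list[str],
    label: str = "cluster",
) -> ClusterScore:
    """The per-sample cluster score S_i.

    Within each tissue, every gene is centered on its mean and scaled by
    the raw median absolute deviation about its median (no consistency
    constant), and S_i is the average of the cluster genes' scaled values.
    Genes with zero MAD in a tissue are excluded there and J decremented.
    """
    missing = set(genes) - set(expr.gene_ids)
    if missing:
        raise ValidationError(f"cluster genes absent from matrix: {sorted(missing)}")
    tissues = samples.for_samples(expr.sample_ids).tissue_of()
    scores = pd.Series(np.nan, index=pd.Index(expr.sample_ids), name=f"S_{label}")
    genes_used: dict[str, list[str]] = {}
    excluded: dict[str, list[str]] = {}
    sub = expr.data.loc[list(genes)]
    for tissue, grp in tissues.groupby(tissues):
        ids = list(grp.index)
        block = sub[ids].to_numpy(dtype=float)  # genes x tissue samples
        centers = block.mean(axis=1, keepdims=True)
        medians = np.median(block, axis=1, keepdims=True)
        mad = np.median(np.abs(block - medians), axis=1)
        usable = mad > 0
        if not usable.any():
            raise ValidationError(f"all cluster genes have zero MAD in tissue {tissue}")
        if (~usable).any():
            dropped = [g for g, u in zip(genes, usable) if not u]
            warnings.warn(
                f"tissue {tissue}: zero-MAD genes excluded from score: {dropped}",
                stacklevel=2,
            )
        contrib = (block[usable] - centers[usable]) / mad[usable, None]
        scores.loc[ids] = contrib.mean(axis=0)
        genes_used[tissue] = [g for g, u in zip(genes, usable) if u]
        excluded[tissue] = [g for g, u in zip(genes, usable) if not u]
    return ClusterScore(
        scores=scores, cluster_label=label, genes_used=genes_used, excluded_genes=excluded
    )


def association_models(
    data: pd.DataFrame,
    response: str,
    covariates: list[str],
    random_intercept: str | None = None,
) -> AssociationResult:
    """Fixed-effects linear model, or a random-intercept model when
    ``random_intercept`` names a grouping column (e.g. subject id).

    Categorical covariates (dtype object/category) enter as indicator
    contrasts.  Rows with missing values in any used column are dropped.
    """
    cols = [response] + covariates + ([random_intercept] if random_intercept else [])
    frame = data[cols].dropna()
    if frame.empty:
        raise ValidationError("no complete-case rows for the model")
    y = pd.to_numeric(frame[response])
    X_parts = []
    for cov in covariates:
        col = frame[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            X_parts.append(pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float))
        else:
            X_parts.append(pd.to_numeric(col).rename(cov).to_frame())
    X = pd.concat(X_parts, axis=1)
    X.insert(0, "intercept", 1.0)
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        raise ValidationError("singular design matrix")
    if random_intercept is None:
        fit = sm.OLS(y.to_numpy(), X.to_numpy(dtype=float)).fit()
        params = pd.Series(fit.params, index=X.columns)
        return AssociationResult(
            response=response,
            params=params,
            bse=pd.Series(fit.bse, index=X.columns),
            pvalues=pd.Series(fit.pvalues, index=X.columns),
            random_intercept_variance=None,
            residual_variance=float(fit.mse_resid),
            n_obs=int(fit.nobs),
        )
    groups = frame[random_intercept].astype(str)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y.to_numpy(), X.to_numpy(dtype=float), groups=groups)
        fit = model.fit(reml=True)
    params = pd.Series(fit.fe_params, index=X.columns)
    return AssociationResult(
        response=response,
        params=params,
        bse=pd.Series(np.asarray(fit.bse)[: len(X.columns)], index=X.columns),
        pvalues=pd.Series(np.asarray(fit.pvalues)[: len(X.columns)], index=X.columns),
        random_intercept_variance=float(np.asarray(fit.cov_re)[0, 0]),
        residual_variance=float(fit.scale),
        n_obs=int(fit.nobs),
    )


def multi_tissue_gene_score(
    expr: ExpressionMatrix,
    samples: SampleTable,
    gene_id: str,
    tissues: list[str],
) -> pd.Series:
    """Per-subject mean of one gene's normalized expression across tissues.

    A subject must have at least one sample in every listed tissue;
    subjects missing a tissue are excluded with a log entry.  Multiple
    samples of one (subject, tissue) are averaged before the cross-tissue
    mean.
    """
    if gene_id not in expr.gene_ids:
        raise ValidationError(f"gene {gene_id} absent from matrix")
    annot = samples.for_samples(expr.sample_ids).data
    vals = expr.data.loc[gene_id]
    frame = pd.DataFrame(
        {"subject": annot["subject_id"], "tissue": annot["tissue"], "value": vals}
    )
    frame = frame[frame["tissue"].isin(tissues)]
    per_tissue = frame.groupby(["subject", "tissue"])["value"].mean().unstack()
    complete = per_tissue.dropna(subset=list(tissues), how="any")
    excluded = set(per_tissue.index) - set(complete.index)
    if excluded:
        warnings.warn(
            f"subjects missing a required tissue excluded: {sorted(excluded)}",
            stacklevel=2,
        )
    return complete[list(tissues)].mean(axis=1).rename(f"{gene_id}_score")


def select_extreme_subjects(
    scores: pd.Series,
    top_k: int,
    bottom_k: int,
    sex_by_subject: pd.Series | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Top/bottom scoring subjects, de-identified and order-randomized.

    With ``sex_by_subject`` the top/bottom counts are taken per sex.  The
    returned frame maps anonymized ids to subjects and groups, in an order
    shuffled by ``seed`` so downstream (e.g. image) scoring is blinded.
    """
    rows = []
    if sex_by_subject is None:
        ordered = scores.sort_values()
        if top_k + bottom_k > len(ordered):
            raise ValidationError("top_k + bottom_k exceeds cohort size")
        rows += [(s, "bottom") for s in ordered.index[:bottom_k]]
        rows += [(s, "top") for s in ordered.index[-top_k:]]
    else:
        for sex, grp in scores.groupby(sex_by_subject.reindex(scores.index)):
            ordered = grp.sort_values()
            if top_k + bottom_k > len(ordered):
                raise ValidationError(f"top_k + bottom_k exceeds cohort size for sex {sex}")
            rows += [(s, "bottom") for s in ordered.index[:bottom_k]]
            rows += [(s, "top") for s in ordered.index[-top_k:]]
    rng = np.random.default_rng(seed)
    rng.shuffle(rows)
    return pd.DataFrame(
        {
            "anon_id": [f"S{i + 1:03d}" for i in range(len(rows))],
            "subject_id": [r[0] for r in rows],
            "group": [r[1] for r in rows],
        }
    )


def sample_cluster(
    expr: ExpressionMatrix,
    samples: SampleTable,
    k: int,
    linkage_method: str = "complete",
) -> tuple[pd.Series, pd.DataFrame]:
    """Cluster samples on centered expression of (cluster) genes.

    Per-gene centering on the cross-sample mean, complete-linkage
    Euclidean tree over samples, cut into ``k`` groups.  Returns the
    per-sample group labels and a group-by-disease cross-tabulation.
    """
    if k > expr.n_samples:
        raise ValidationError(f"k={k} exceeds {expr.n_samples} samples")
    centered = expr.values - expr.values.mean(axis=1, keepdims=True)
    Z = hierarchy.linkage(centered.T, method=linkage_method, metric="euclidean")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    groups = pd.Series(labels, index=pd.Index(expr.sample_ids), name="group")
    disease = samples.for_samples(expr.sample_ids).data["disease"]
    crosstab = pd.crosstab(disease, groups)
    return groups, crosstab
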
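"""Per-tissue linear models of matrisome expression on scaled age and sex.

Each gene's log2-CPM is regressed, within a tissue, on age (standardized
to mean 0, s.d. 1 within the tissue) and sex, corrected for ischemic time,
Hardy scale and experimental batch.  An optional mean-variance trend
supplies per-observation precision weights in the spirit of voom.  Fits
are ordinary (weighted) least squares without empirical-Bayes moderation;
p-values for all tissues are pooled and Benjamini-Hochberg adjusted, one
family per covariate.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, SampleTable, ValidationError

__all__ = [
    "filter_by_expression",
    "fit_covariate_models",
    "collate_multitissue_fdr",
    "top_transcripts",
]

DE_COLUMNS = ["tissue", "gene_id", "covariate", "beta", "se", "p", "fdr_p", "direction"]


def filter_by_expression(
    counts: ExpressionMatrix,
    group: pd.Series,
    min_count: float = 10.0,
    min_total: float = 15.0,
) -> list[str]:
    """Expression filter for count matrices ahead of model fitting.

    A gene is kept when its CPM reaches the CPM equivalent of ``min_count``
    reads at the median library size in at least ``n_min`` samples, where
    ``n_min`` is the smallest group size, and its total count across all
    samples is at least ``min_total``.
    """
    if counts.units != "raw_counts":
        raise ValidationError("expression filtering operates on raw counts")
    group = group.reindex(counts.sample_ids)
    n_min = int(group.value_counts().min())
    lib = counts.values.sum(axis=0).astype(float)
    median_lib = np.median(lib)
    cpm_cutoff = min_count / median_lib * 1e6
    cpm = counts.values / lib[None, :] * 1e6
    keep = (np.sum(cpm >= cpm_cutoff, axis=1) >= n_min) & (
        counts.values.sum(axis=1) >= min_total
    )
    retained = [g for g, k in zip(counts.gene_ids, keep) if k]
    if not retained:
        raise ValidationError("expression filter removed every gene")
    return retained


def _log2_cpm(values: np.ndarray) -> np.ndarray:
    """log2 counts-per-million with a 0.5-count offset (voom's response)."""
    lib = values.sum(axis=0).astype(float)
    return np.log2((values + 0.5) / (lib[None, :] + 1.0) * 1e6)


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns responsible for rank deficiency, by greedy QR inclusion."""
    aliased = []
    basis: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, basis + [j]]
        if np.linalg.matrix_rank(trial) == len(basis) + 1:
            basis.append(j)
        else:
            aliased.append(names[j])
    return aliased


def _build_design(
    samp: pd.DataFrame, scale_age: bool
) -> tuple[np.ndarray, list[str], pd.Index]:
    """Design matrix for one tissue: intercept, age, sex, nuisance terms.

    Samples missing a numeric covariate that is otherwise observed in the
    tissue are excluded; constant covariates are dropped with a warning.
    Hardy scale and batch enter as indicator contrasts, with missingness
    as its own level.
    """
    cols: dict[str, np.ndarray] = {}
    keep = pd.Series(True, index=samp.index)

    age = pd.to_numeric(samp["age"], errors="coerce")
    if age.notna().any():
        keep &= age.notna()
    isch = pd.to_numeric(samp["ischemic_time"], errors="coerce")
    use_isch = isch.notna().any()
    if use_isch:
        keep &= isch.notna()
    samp = samp[keep]
    if samp.empty:
        raise ValidationError("no samples with complete numeric covariates")

    age = pd.to_numeric(samp["age"], errors="coerce")
    if age.notna().all() and age.nunique() > 1:
        a = age.to_numpy(dtype=float)
        if scale_age:
            a = (a - a.mean()) / a.std(ddof=1)
        cols["age"] = a
    elif age.notna().all():
        warnings.warn("age constant within tissue; dropped", stacklevel=3)

    sex = samp["sex"].astype(str)
    if sex.nunique() > 1:
        cols["sex"] = (sex == "F").to_numpy(dtype=float)
    else:
        warnings.warn("sex constant within tissue; dropped", stacklevel=3)

    if use_isch:
        iv = pd.to_numeric(samp["ischemic_time"]).to_numpy(dtype=float)
        if np.ptp(iv) > 0:
            cols["ischemic_time"] = iv

    for cat_col in ("hardy_scale", "batch"):
        series = samp[cat_col].astype(str).fillna("missing")
        if series.nunique() > 1:
            dummies = pd.get_dummies(series, prefix=cat_col, drop_first=True)
            for c in dummies.columns:
                cols[c] = dummies[c].to_numpy(dtype=float)

    names = ["intercept"] + list(cols)
    X = np.column_stack([np.ones(len(samp))] + [cols[c] for c in cols])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(f"rank-deficient design; aliased: {_aliased_columns(X, names)}")
    return X, names, samp.index


def _batched_wls(
    X: np.ndarray, Y: np.ndarray, W: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene (weighted) least squares with a shared design.

    Y is genes x samples; W, if given, per-observation weights of the same
    shape.  Returns (beta, se, resid_df) with beta and se genes x p.
    """
    n, p = X.shape
    df = n - p
    if W is None:
        pinv = np.linalg.pinv(X)
        B = Y @ pinv.T
        resid = Y - B @ X.T
        sigma2 = (resid**2).sum(axis=1) / df
        xtx_inv_diag = np.diag(np.linalg.inv(X.T @ X))
        se = np.sqrt(np.outer(sigma2, xtx_inv_diag))
        return B, se, df
    XtWX = np.einsum("ni,gn,nj->gij", X, W, X, optimize=True)
    XtWy = np.einsum("ni,gn->gi", X, W * Y, optimize=True)
    B = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
    resid = Y - B @ X.T
    sigma2 = (W * resid**2).sum(axis=1) / df
    inv = np.linalg.inv(XtWX)
    se = np.sqrt(sigma2[:, None] * np.diagonal(inv, axis1=1, axis2=2))
    return B, se, df


def _voom_weights(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Precision weights from a smoothed mean-variance trend.

    A first-pass OLS gives per-gene residual standard deviations; the
    square root of the s.d. is lowess-smoothed against mean log2-CPM and
    evaluated at each observation's fitted value, and the weight is the
    inverse fourth power of the smoothed value.
    """
    B, _, df = _batched_wls(X, Y, None)
    fitted = B @ X.T
    resid_sd = np.sqrt(((Y - fitted) ** 2).sum(axis=1) / df)
    mean_expr = Y.mean(axis=1)
    sqrt_sd = np.sqrt(np.maximum(resid_sd, 1e-8))
    smoothed = lowess(sqrt_sd, mean_expr, frac=0.5, return_sorted=True)
    sx, sy = smoothed[:, 0], np.maximum(smoothed[:, 1], 1e-4)
    trend_at = np.interp(fitted, sx, sy)
    return 1.0 / trend_at**4


def fit_covariate_models(
    counts: ExpressionMatrix,
    samples: SampleTable,
    genes: set[str] | None = None,
    weights: str = "none",
    covariates: tuple[str, ...] = ("age", "sex"),
    min_samples: int = 10,
    scale_age_within_tissue: bool = True,
) -> pd.DataFrame:
    """Fit per-tissue per-gene linear models and return effect rows.

    Returns one row per (tissue, gene, covariate) with the log2-scale
    effect per 1 s.d. of age (or the F-vs-M contrast), its standard error,
    a two-sided p-value, and the effect direction.  ``fdr_p`` is NaN until
    :func:`collate_multitissue_fdr` fills it.
    """
    if weights not in ("none", "meanvar_trend"):
        raise ValidationError(f"unknown weights mode {weights!r}")
    if counts.units != "raw_counts":
        raise ValidationError("models are fitted on raw counts (log2-CPM response)")
    if genes is not None:
        counts = counts.subset_genes(genes)
    annot = samples.for_samples(counts.sample_ids).data
    rows: list[dict] = []
    for tissue, samp in annot.groupby("tissue", observed=True):
        if len(samp) < min_samples:
            warnings.warn(
                f"tissue {tissue}: {len(samp)} samples < {min_samples}; skipped",
                stacklevel=2,
            )
            continue
        X, names, used = _build_design(samp, scale_age_within_tissue)
        Y = _log2_cpm(counts.data[list(used)].to_numpy().astype(float))
        W = _voom_weights(X, Y) if weights == "meanvar_trend" else None
        B, SE, df = _batched_wls(X, Y, W)
        for cov in covariates:
            if cov not in names:
                continue
            k = names.index(cov)
            beta = B[:, k]
            se = SE[:, k]
            se_safe = np.where(se > 0, se, 1.0)
            t = np.where(se > 0, beta / se_safe, np.where(beta == 0, 0.0, np.inf))
            p = 2.0 * stats.t.sf(np.abs(t), df)
            for g, b_, s_, p_ in zip(counts.gene_ids, beta, se, p):
                rows.append(
                    {
                        "tissue": tissue,
                        "gene_id": g,
                        "covariate": cov,
                        "beta": float(b_),
                        "se": float(s_),
                        "p": float(p_),
                        "fdr_p": np.nan,
                        "direction": int(np.sign(b_)),
                    }
                )
    return pd.DataFrame(rows, columns=DE_COLUMNS)


def collate_multitissue_fdr(
    results: pd.DataFrame,
    alpha: float = 0.05,
    per_tissue: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool all tissues' p-values and apply BH, one family per covariate.

    Returns the results with ``fdr_p`` filled and a per-covariate summary
    (significant rows, unique genes, direction tallies).  With
    ``per_tissue`` the BH family is (covariate, tissue) instead of the
    default pooled-across-tissues family.
    """
    out = results.copy()
    family_cols = ["covariate", "tissue"] if per_tissue else ["covariate"]
    for _, idx in out.groupby(family_cols).groups.items():
        out.loc[idx, "fdr_p"] = multipletests(out.loc[idx, "p"], method="fdr_bh")[1]
    summaries = []
    for cov, grp in out.groupby("covariate"):
        sig = grp[grp["fdr_p"] < alpha]
        summaries.append(
            {
                "covariate": cov,
                "significant_rows": len(sig),
                "unique_genes": sig["gene_id"].nunique(),
                "n_up": int((sig["direction"] > 0).sum()),
                "n_down": int((sig["direction"] < 0).sum()),
            }
        )
    return out, pd.DataFrame(summaries)


def top_transcripts(
    results: pd.DataFrame,
    alpha: float = 0.05,
    beta_min: float = 0.15,
) -> pd.DataFrame:
    """Reporting filter: per tissue the smallest-FDR significant transcript,
    plus every other significant instance of those transcripts with
    ``|beta| >= beta_min``."""
    sig = results[results["fdr_p"] < alpha]
    if sig.empty:
        return sig
    leads = sig.loc[sig.groupby("tissue")["fdr_p"].idxmin()]
    lead_genes = set(leads["gene_id"])
    extra = sig[(sig["gene_id"].isin(lead_genes)) & (sig["beta"].abs() >= beta_min)]
    return (
        pd.concat([leads, extra])
        .drop_duplicates(subset=["tissue", "gene_id", "covariate"])
        .sort_values(["gene_id", "tissue"])
        .reset_index(drop=True)
    )
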
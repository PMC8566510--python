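"""Count normalization and transformation stages.

Implements the median-of-ratios size factors, a self-contained closed-form
variance-stabilizing transform for negative-binomial counts with a
parametric dispersion trend phi(mu) = a/mu + b, cross-dataset quantile
normalization, matrisome category composition, and median tissue profiles.

The VST here is an approximation of the reference tool's transform: it
shares the size-factor estimator, the parametric trend family and the
closed-form integral, but applies the fitted trend directly instead of
shrinking gene-wise dispersions toward it.  Downstream rank-based stages
are invariant to any per-sample monotone transform, so the approximation
does not propagate into rank-change results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix, MatrisomeCatalog, SampleTable, ValidationError

__all__ = [
    "SizeFactors",
    "TissueProfile",
    "median_ratio_size_factors",
    "vst_transform",
    "quantile_normalize",
    "category_fraction",
    "median_tissue_profile",
]


@dataclass
class SizeFactors:
    """Per-sample median-of-ratios scaling factors (unscaled, all > 0)."""

    factors: pd.Series
    n_reference_genes: int

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValidationError("size factors must be positive")


@dataclass
class TissueProfile:
    """Per-tissue per-gene median expression with sample provenance."""

    data: pd.DataFrame            # genes x tissues
    provenance: dict[str, list[str]]
    units: str = "vst"

    @property
    def tissues(self) -> list[str]:
        return list(self.data.columns)


def median_ratio_size_factors(counts: ExpressionMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    For each sample j, the factor is the median over reference genes g of
    ``count[g, j] / geometric_mean_g`` where the reference set is the genes
    with strictly positive counts in every sample.  Factors are returned
    unscaled (no renormalization to unit product).
    """
    if counts.units != "raw_counts":
        raise ValidationError("size factors are defined on raw counts")
    if counts.n_samples < 2:
        raise ValidationError("need at least 2 samples")
    values = counts.values.astype(float)
    reference = np.all(values > 0, axis=1)
    if not reference.any():
        raise ValidationError(
            "no gene has positive counts in every sample; a pseudo-reference "
            "fallback is deliberately not applied"
        )
    ref = values[reference]
    log_geo_mean = np.mean(np.log(ref), axis=1, keepdims=True)
    ratios = ref / np.exp(log_geo_mean)
    factors = np.median(ratios, axis=0)
    return SizeFactors(
        pd.Series(factors, index=counts.sample_ids, name="size_factor"),
        n_reference_genes=int(reference.sum()),
    )


# ---------------------------------------------------------------------------
# VST
# ---------------------------------------------------------------------------

def _fit_dispersion_trend(
    mu: np.ndarray, phi: np.ndarray, n_iter: int = 8
) -> tuple[float, float]:
    """Robust fit of phi = a/mu + b over genes.

    Iteratively reweighted least squares on (1/mu, phi) with weights
    1/fitted^2 (a gamma-family working model: the spread of
    method-of-moments dispersion estimates scales with their magnitude)
    and trimming of genes far from the trend (ratio outside [1e-4, 10]).
    """
    x = 1.0 / mu
    y = phi.copy()
    keep = np.isfinite(x) & np.isfinite(y) & (y > 0)
    x, y = x[keep], y[keep]
    if x.size < 10:
        raise ValidationError("too few genes with usable dispersion estimates")
    mask = np.ones(x.size, dtype=bool)
    w = np.ones(x.size)
    a = b = np.nan
    for _ in range(n_iter):
        sw = np.sqrt(w[mask])
        X = np.column_stack([x[mask], np.ones(int(mask.sum()))]) * sw[:, None]
        coef, *_ = np.linalg.lstsq(X, y[mask] * sw, rcond=None)
        a, b = float(coef[0]), float(coef[1])
        fitted = np.maximum(a * x + b, 1e-12)
        w = 1.0 / fitted**2
        ratio = y / fitted
        new_mask = (ratio > 1e-4) & (ratio < 10.0)
        if new_mask.sum() < 10:
            break
        mask = new_mask
    return a, b


def fit_vst_parameters(counts: ExpressionMatrix) -> tuple[float, float, SizeFactors]:
    """Size factors plus the (a, b) dispersion-trend parameters."""
    if counts.n_genes < 10 or counts.n_samples < 4:
        raise ValidationError("VST trend fitting needs >= 10 genes and >= 4 samples")
    sf = median_ratio_size_factors(counts)
    q = counts.values / sf.factors.to_numpy()[None, :]
    mu = q.mean(axis=1)
    var = q.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (var - mu) / mu**2
    usable = (mu > 0) & np.isfinite(phi)
    a, b = _fit_dispersion_trend(mu[usable], phi[usable])
    if a <= 0:
        warnings.warn(
            "dispersion trend a <= 0; falling back to constant dispersion",
            stacklevel=2,
        )
        a = 0.0
    if not np.isfinite(b) or b <= 0:
        b = 1e-8
    return a, b, sf


def _vst_closed_form(q: np.ndarray, a: float, b: float) -> np.ndarray:
    """Closed-form VST of the NB family with Var = (1+a) mu + b mu^2.

    Monotone increasing, asymptotically log2 (vst(2x) - vst(x) -> 1) and
    proportional to sqrt(x) in the near-Poisson regime b -> 0.
    """
    alpha = 1.0 + a
    with np.errstate(invalid="ignore"):
        inner = (alpha + 2.0 * b * q + 2.0 * np.sqrt(b * q * (alpha + b * q))) / (4.0 * b)
    return np.log2(inner)


def vst_transform(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Variance-stabilizing transform of raw counts.

    Counts are divided by median-of-ratios size factors, a parametric
    dispersion trend phi(mu) = a/mu + b is fitted across genes by robust
    regression on method-of-moments estimates, and the closed-form VST of
    the fitted family is applied.  The output is shifted so the transform
    of zero counts maps to 0 (a per-dataset additive constant, irrelevant
    to every downstream use).
    """
    a, b, sf = fit_vst_parameters(counts)
    q = counts.values / sf.factors.to_numpy()[None, :]
    transformed = _vst_closed_form(q, a, b) - _vst_closed_form(np.zeros(1), a, b)[0]
    data = pd.DataFrame(transformed, index=counts.data.index, columns=counts.data.columns)
    return counts.with_units(data, "vst")


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(
    matrices: ExpressionMatrix | list[ExpressionMatrix],
) -> list[ExpressionMatrix]:
    """Quantile-normalize one or more matrices over a shared gene set.

    All sample columns across the inputs are pooled; the reference
    distribution is the mean of the sorted columns.  Ties within a column
    receive the mean of the reference quantiles they span.  Returns one
    output per input, in order.
    """
    single = isinstance(matrices, ExpressionMatrix)
    mats = [matrices] if single else list(matrices)
    genes0 = mats[0].gene_ids
    for m in mats[1:]:
        if m.gene_ids != genes0:
            diff = set(m.gene_ids) ^ set(genes0)
            raise ValidationError(
                f"gene sets differ between matrices (symmetric difference: "
                f"{sorted(diff)[:10]}{'...' if len(diff) > 10 else ''})"
            )
    combined = np.column_stack([m.values for m in mats]).astype(float)
    n = combined.shape[0]
    reference = np.sort(combined, axis=0).mean(axis=1)
    # Each tie group receives the mean of the reference quantiles it spans.
    lo = rankdata(combined, method="min", axis=0).astype(int)
    hi = rankdata(combined, method="max", axis=0).astype(int)
    ref_csum = np.concatenate([[0.0], np.cumsum(reference)])
    normalized = (ref_csum[hi] - ref_csum[lo - 1]) / (hi - lo + 1)

    out: list[ExpressionMatrix] = []
    offset = 0
    for m in mats:
        block = normalized[:, offset : offset + m.n_samples]
        offset += m.n_samples
        data = pd.DataFrame(block, index=m.data.index, columns=m.data.columns)
        out.append(m.with_units(data, "quantile"))
    return out


# ---------------------------------------------------------------------------
# Composition and tissue profiles
# ---------------------------------------------------------------------------

def category_fraction(
    tpm_profile: pd.DataFrame | TissueProfile,
    catalog: MatrisomeCatalog,
    categories: tuple[str, ...] = ("collagens", "proteoglycans", "ECM_glycoproteins", "ECM_regulators"),
) -> pd.DataFrame:
    """Percent of each tissue's transcriptome in each matrisome category.

    ``tpm_profile`` is a genes x tissues table of per-tissue (median) TPM.
    Each category's genes are summed per tissue and divided by the tissue's
    total TPM over all genes, times 100.
    """
    if isinstance(tpm_profile, TissueProfile):
        if tpm_profile.units != "tpm":
            raise ValidationError("category composition is defined on TPM profiles")
        tpm_profile = tpm_profile.data
    totals = tpm_profile.sum(axis=0)
    if (totals <= 0).any():
        dead = list(totals.index[totals <= 0])
        raise ValidationError(f"tissues with zero total TPM: {dead}")
    rows = {}
    for cat in categories:
        genes = catalog.genes_in_category(cat) & set(tpm_profile.index)
        rows[cat] = 100.0 * tpm_profile.loc[sorted(genes)].sum(axis=0) / totals
    out = pd.DataFrame(rows)
    out.index.name = "tissue"
    return out


BRAIN_PREFIX = "BRN"


def median_tissue_profile(
    expr: ExpressionMatrix,
    samples: SampleTable,
    collapse_brain: bool = False,
) -> TissueProfile:
    """Per-tissue per-gene median expression profile.

    With ``collapse_brain``, tissues whose code starts with ``BRN`` are
    replaced by a single ``BRAIN`` profile: the per-gene median of the
    brain sub-tissue medians (a median of medians, not a pooled median).
    """
    tissues = samples.for_samples(expr.sample_ids).tissue_of()
    profile: dict[str, pd.Series] = {}
    provenance: dict[str, list[str]] = {}
    for tissue, group in tissues.groupby(tissues):
        ids = list(group.index)
        if not ids:
            warnings.warn(f"tissue {tissue} has no samples; omitted", stacklevel=2)
            continue
        profile[tissue] = expr.data[ids].median(axis=1)
        provenance[tissue] = ids
    if collapse_brain:
        brain_tissues = [t for t in profile if str(t).startswith(BRAIN_PREFIX)]
        if brain_tissues:
            sub = pd.DataFrame({t: profile.pop(t) for t in brain_tissues})
            profile["BRAIN"] = sub.median(axis=1)
            provenance["BRAIN"] = sorted(
                s for t in brain_tissues for s in provenance.pop(t)
            )
    data = pd.DataFrame(profile)
    return TissueProfile(data, provenance=provenance, units=expr.units)
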
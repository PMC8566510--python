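"""Synthetic cohorts with the statistical structure the analyses assume.

Every generator is a pure function of its spec and seed, producing
negative-binomial count matrices (Var = mu + phi mu^2) with planted
structure: tissue/age/sex/batch effects on the log2 scale, correlated gene
blocks driven by latent factors, category-specific protein-transcript
noise, per-dataset monotone batch distortions with planted cancer shifts,
and a disease-severity-driven two-program lung cohort.  Cohort covariate
distributions mirror a GTEx-like donor pool (two-thirds male, ages
centered in the mid-fifties); sizes default to desk scale rather than
consortium scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    ALL_CATEGORIES,
    CORE_CATEGORIES,
    ExpressionMatrix,
    MatrisomeCatalog,
    SampleTable,
    ValidationError,
)
from .proteome import NON_MATRISOME, PairedAbundanceTable
from .rankchange import DatasetTrio

__all__ = [
    "CorrelatedBlock",
    "CohortSpec",
    "CancerTrioSpec",
    "SimulatedCohort",
    "SimulatedTrios",
    "SimulatedLungCohort",
    "generate_cohort",
    "generate_paired_proteome",
    "generate_cancer_trio",
    "generate_lung_cohort",
]


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray) -> np.ndarray:
    """NB(mean, dispersion) with Var = mu + phi mu^2; Poisson when phi ~ 0."""
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(dispersion, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    tiny = phi < 1e-9
    if tiny.any():
        out[tiny] = rng.poisson(mean[tiny])
    if (~tiny).any():
        r = 1.0 / phi[~tiny]
        p = r / (r + mean[~tiny])
        out[~tiny] = rng.negative_binomial(r, p)
    return out


@dataclass
class CorrelatedBlock:
    """A planted co-expression block with a target within-block Kendall tau.

    With ``anti`` the second half of the block loads negatively on the
    shared factor, producing two mutually anti-correlated programs.
    """

    size: int
    tau: float
    anti: bool = False

    def __post_init__(self) -> None:
        if abs(self.tau) > 0.95:
            raise ValidationError("block |tau| target > 0.95 is infeasible")


@dataclass
class CohortSpec:
    """Study-design parameters for a GTEx-like synthetic cohort.

    Effects are on the log2 scale of the NB mean.  ``n_age_effect_genes``
    genes (chosen deterministically from the seed, disjoint from block
    genes) receive an age slope of ±``age_effect_size`` log2 units per
    s.d. of age, and similarly for sex.
    """

    n_tissues: int = 1
    samples_per_tissue: int = 100
    n_genes: int = 1000
    fraction_matrisome: float = 0.6
    base_log2_mean: float = 7.0
    base_log2_sd: float = 1.0
    residual_log2_sd: float = 0.25
    block_residual_log2_sd: float = 0.8
    tissue_effect_sd: float = 0.5
    batch_effect_sd: float = 0.1
    n_batches: int = 2
    dispersion_shape: float = 2.0
    dispersion_mean: float = 0.1
    library_log_sigma: float = 0.25
    age_mean: float = 52.76
    age_sd: float = 12.91
    age_range: tuple[float, float] = (20.0, 70.0)
    male_fraction: float = 0.666
    n_age_effect_genes: int = 0
    age_effect_size: float = 0.5
    n_sex_effect_genes: int = 0
    sex_effect_size: float = 0.5
    correlated_blocks: list[CorrelatedBlock] = field(default_factory=list)
    seed: int = 0


@dataclass
class SimulatedCohort:
    counts: ExpressionMatrix
    samples: SampleTable
    catalog: MatrisomeCatalog
    age_effects: dict[str, float]
    sex_effects: dict[str, float]
    block_genes: list[list[str]]


def _make_catalog(gene_ids: list[str], fraction: float, rng: np.random.Generator) -> MatrisomeCatalog:
    n_mat = int(round(fraction * len(gene_ids)))
    chosen = gene_ids[:n_mat]
    probs = np.array([0.10, 0.07, 0.35, 0.30, 0.10, 0.08])
    cats = rng.choice(ALL_CATEGORIES, size=n_mat, p=probs / probs.sum())
    table = pd.DataFrame(
        {
            "division": ["core" if c in CORE_CATEGORIES else "associated" for c in cats],
            "category": cats,
        },
        index=pd.Index(chosen, name="gene"),
    )
    return MatrisomeCatalog(table)


def generate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Simulate a raw-count cohort with annotations and a matrisome catalog.

    Counts follow NB(s_i * 2^eta_gi, phi_g) with
    eta = base + tissue + batch + beta_age * scaled age + beta_sex * sex
    + block factor + residual noise.  Subjects span every tissue, so
    multi-tissue subject scores are well defined.
    """
    rng = np.random.default_rng(spec.seed)
    G, T, S = spec.n_genes, spec.n_tissues, spec.samples_per_tissue
    gene_ids = [f"ENSG{i:011d}" for i in range(G)]
    tissue_names = [f"TISSUE{t + 1}" for t in range(T)]

    # Subjects (shared across tissues), one sample per (subject, tissue).
    subjects = [f"SUBJ{i:04d}" for i in range(S)]
    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, S), *spec.age_range)
    sex = np.where(rng.random(S) < spec.male_fraction, "M", "F")
    bmi = np.clip(rng.normal(27.0, 4.5, S), 16.0, 45.0)
    hardy = rng.integers(0, 5, S).astype(str)

    sample_rows = []
    for t, tname in enumerate(tissue_names):
        for i, subj in enumerate(subjects):
            sample_rows.append(
                {
                    "sample_id": f"{subj}-{tname}",
                    "subject_id": subj,
                    "tissue": tname,
                    "age": age[i],
                    "sex": sex[i],
                    "ischemic_time": float(rng.uniform(60, 1200)),
                    "hardy_scale": hardy[i],
                    "batch": f"BATCH{rng.integers(spec.n_batches) + 1}",
                    "bmi": bmi[i],
                    "disease": "normal",
                }
            )
    annot = pd.DataFrame(sample_rows).set_index("sample_id")
    n_samples = len(annot)

    # Gene-level parameters.
    base = rng.normal(spec.base_log2_mean, spec.base_log2_sd, G)
    phi = rng.gamma(
        spec.dispersion_shape, spec.dispersion_mean / spec.dispersion_shape, G
    )
    tissue_eff = rng.normal(0.0, spec.tissue_effect_sd, (G, T)) if T > 1 else np.zeros((G, 1))
    batch_levels = sorted(annot["batch"].unique())
    batch_eff = rng.normal(0.0, spec.batch_effect_sd, (G, len(batch_levels)))

    # Block genes occupy the head of the gene list; effect genes follow.
    block_genes: list[list[str]] = []
    cursor = 0
    block_info = []
    for block in spec.correlated_blocks:
        idx = np.arange(cursor, cursor + block.size)
        cursor += block.size
        if cursor > G:
            raise ValidationError("correlated blocks exceed the gene count")
        block_genes.append([gene_ids[i] for i in idx])
        rho = np.sin(np.pi * block.tau / 2.0)  # Kendall -> Pearson (Gaussian)
        lam = spec.block_residual_log2_sd * np.sqrt(rho / (1.0 - rho))
        signs = np.ones(block.size)
        if block.anti:
            signs[block.size // 2 :] = -1.0
        block_info.append((idx, lam, signs))

    free = np.arange(cursor, G)
    rng.shuffle(free)
    n_age, n_sex = spec.n_age_effect_genes, spec.n_sex_effect_genes
    if n_age + n_sex > len(free):
        raise ValidationError("not enough genes for the planted effects")
    age_idx = np.sort(free[:n_age])
    sex_idx = np.sort(free[n_age : n_age + n_sex])
    age_beta = spec.age_effect_size * rng.choice([-1.0, 1.0], n_age)
    sex_beta = spec.sex_effect_size * rng.choice([-1.0, 1.0], n_sex)
    age_effects = {gene_ids[i]: float(b) for i, b in zip(age_idx, age_beta)}
    sex_effects = {gene_ids[i]: float(b) for i, b in zip(sex_idx, sex_beta)}

    # Per-sample covariate vectors aligned with annot rows.
    age_scaled_all = (annot["age"].to_numpy() - annot["age"].mean()) / annot["age"].std(ddof=1)
    sex_f = (annot["sex"] == "F").to_numpy(dtype=float)
    tissue_idx = np.array([tissue_names.index(t) for t in annot["tissue"]])
    batch_idx = np.array([batch_levels.index(b) for b in annot["batch"]])

    resid_sd = np.full(G, spec.residual_log2_sd)
    for idx, _, _ in block_info:
        resid_sd[idx] = spec.block_residual_log2_sd

    eta = base[:, None] + tissue_eff[:, tissue_idx] + batch_eff[:, batch_idx]
    if n_age:
        eta[age_idx] += np.outer(age_beta, age_scaled_all)
    if n_sex:
        eta[sex_idx] += np.outer(sex_beta, sex_f)
    for idx, lam, signs in block_info:
        factor = rng.normal(0.0, 1.0, n_samples)
        eta[idx] += lam * np.outer(signs, factor)
    eta += rng.normal(0.0, 1.0, (G, n_samples)) * resid_sd[:, None]

    size_factor = np.exp(rng.normal(0.0, spec.library_log_sigma, n_samples))
    mean = size_factor[None, :] * np.exp2(eta)
    counts = _nb_counts(rng, mean, phi[:, None])

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=annot.index)
    return SimulatedCohort(
        counts=ExpressionMatrix(counts_df, units="raw_counts"),
        samples=SampleTable(annot),
        catalog=_make_catalog(gene_ids, spec.fraction_matrisome, rng),
        age_effects=age_effects,
        sex_effects=sex_effects,
        block_genes=block_genes,
    )


def generate_paired_proteome(
    n_pairs: dict[str, int],
    rho_by_category: dict[str, float],
    tissues: tuple[str, ...] = ("TISSUE1",),
    seed: int = 0,
) -> PairedAbundanceTable:
    """Paired protein/transcript abundances with category-specific concordance.

    Latent log-abundances are bivariate normal with the Pearson correlation
    that yields the requested Spearman rho (r = 2 sin(pi rho / 6)); both
    sides are exponentiated so abundances are strictly positive.  Realized
    rank correlations land within ~0.05 of the target for n >= 200.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for tissue in tissues:
        for category, n in n_pairs.items():
            rho_s = rho_by_category.get(category, 0.0)
            if not -1.0 < rho_s < 1.0:
                raise ValidationError(f"target rho for {category} must be in (-1, 1)")
            if n < 30 and abs(rho_s) > 0.8:
                warnings.warn(
                    f"{category}: target rho {rho_s} may be unreachable at n={n}",
                    stacklevel=2,
                )
            r = 2.0 * np.sin(np.pi * rho_s / 6.0)
            latent = rng.normal(0.0, 1.0, n)
            noise = rng.normal(0.0, 1.0, n)
            protein_latent = r * latent + np.sqrt(1.0 - r**2) * noise
            for k in range(n):
                rows.append(
                    {
                        "tissue": tissue,
                        "gene_id": f"{category.upper()}_{k:05d}",
                        "protein_abundance": float(np.exp(2.0 + protein_latent[k])),
                        "transcript_abundance": float(np.exp(4.0 + latent[k])),
                        "category": category,
                    }
                )
    return PairedAbundanceTable(pd.DataFrame(rows))


@dataclass
class CancerTrioSpec:
    """Design of synthetic normal/normal/cancer dataset trios.

    Each dataset draws its own monotone distortion of the latent log2
    means (eta -> a * eta + b), emulating cross-consortium batch shifts;
    cancer datasets shift the planted genes by ±``shift_log2``.  Planted
    genes sit in mid-expression bands so their rank has room to move.
    """

    n_tissues: int = 5
    n_genes: int = 400
    n_planted_up: int = 20
    n_planted_down: int = 20
    shift_log2: float = 2.0
    samples_gtex_n: int = 30
    samples_tcga_n: int = 25
    samples_tcga_c: int = 40
    tissues_without_tcga_n: tuple[int, ...] = ()
    base_log2_range: tuple[float, float] = (7.0, 13.0)
    tissue_jitter_sd: float = 0.25
    residual_log2_sd: float = 0.3
    dispersion: float = 0.05
    distortion_scale_range: tuple[float, float] = (0.8, 1.2)
    distortion_shift_range: tuple[float, float] = (-1.0, 1.0)
    distinct_distortions: bool = True
    library_log_sigma: float = 0.2
    seed: int = 0


@dataclass
class SimulatedTrios:
    trios: list[DatasetTrio]
    planted_up: list[str]
    planted_down: list[str]


def generate_cancer_trio(spec: CancerTrioSpec) -> SimulatedTrios:
    """Simulate per-tissue dataset trios with planted cancer rank shifts."""
    rng = np.random.default_rng(spec.seed)
    G = spec.n_genes
    gene_ids = [f"ENSG{i:011d}" for i in range(G)]
    base = np.sort(rng.uniform(*spec.base_log2_range, G))
    order = rng.permutation(G)
    base = base[np.argsort(order)]  # decouple gene id from expression rank
    rank_of = np.argsort(np.argsort(base))

    # Planted genes from mid-expression bands (disjoint by construction).
    up_band = np.flatnonzero((rank_of >= 0.30 * G) & (rank_of < 0.45 * G))
    down_band = np.flatnonzero((rank_of >= 0.55 * G) & (rank_of < 0.70 * G))
    up_idx = rng.choice(up_band, spec.n_planted_up, replace=False)
    down_idx = rng.choice(down_band, spec.n_planted_down, replace=False)
    planted_up = sorted(gene_ids[i] for i in up_idx)
    planted_down = sorted(gene_ids[i] for i in down_idx)

    shared_distortion = (
        rng.uniform(*spec.distortion_scale_range),
        rng.uniform(*spec.distortion_shift_range),
    )

    def sample_dataset(eta_t: np.ndarray, n_samples: int, cancer: bool) -> np.ndarray:
        eta = eta_t.copy()
        if cancer:
            eta[up_idx] += spec.shift_log2
            eta[down_idx] -= spec.shift_log2
        if spec.distinct_distortions:
            a = rng.uniform(*spec.distortion_scale_range)
            b = rng.uniform(*spec.distortion_shift_range)
        else:
            a, b = shared_distortion
        eta = a * eta + b
        noise = rng.normal(0.0, spec.residual_log2_sd, (G, n_samples))
        sf = np.exp(rng.normal(0.0, spec.library_log_sigma, n_samples))
        mean = sf[None, :] * np.exp2(eta[:, None] + noise)
        return _nb_counts(rng, mean, spec.dispersion)

    trios = []
    for t in range(spec.n_tissues):
        tissue = f"TISSUE{t + 1}"
        eta_t = base + rng.normal(0.0, spec.tissue_jitter_sd, G)

        def as_matrix(values: np.ndarray, prefix: str) -> ExpressionMatrix:
            cols = [f"{tissue}-{prefix}-{i:03d}" for i in range(values.shape[1])]
            return ExpressionMatrix(
                pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=cols),
                units="raw_counts",
            )

        gtex_n = as_matrix(sample_dataset(eta_t, spec.samples_gtex_n, False), "GTEXN")
        tcga_n = None
        if t not in spec.tissues_without_tcga_n:
            tcga_n = as_matrix(sample_dataset(eta_t, spec.samples_tcga_n, False), "TCGAN")
        tcga_c = as_matrix(sample_dataset(eta_t, spec.samples_tcga_c, True), "TCGAC")
        trios.append(
            DatasetTrio(tissue=tissue, gtex_normal=gtex_n, tcga_normal=tcga_n, tcga_cancer=tcga_c)
        )
    return SimulatedTrios(trios=trios, planted_up=planted_up, planted_down=planted_down)


@dataclass
class SimulatedLungCohort:
    counts: ExpressionMatrix
    samples: SampleTable
    program1: list[str]
    program2: list[str]


def generate_lung_cohort(
    n_normal_geo: int = 26,
    n_vent: int = 10,
    n_ali: int = 8,
    n_ipf: int = 46,
    n_gtex_normal: int = 10,
    program_sizes: tuple[int, int] = (20, 5),
    program_amplitude: float = 1.8,
    severity: dict[str, float] | None = None,
    n_filler: int = 300,
    base_log2_mean: float = 8.5,
    base_log2_sd: float = 0.8,
    residual_log2_sd: float = 0.5,
    factor_sd: float = 0.25,
    batch_effect_sd: float = 0.3,
    dispersion: float = 0.08,
    seed: int = 0,
) -> SimulatedLungCohort:
    """A lung disease cohort: IPF, acute lung injury, ventilator injury,
    and normals from two sources, with two anti-correlated gene programs.

    A latent severity per sample (0 for normal, intermediate for
    ventilator injury and ALI, highest for IPF, matching the observed
    effect ordering) drives program 1 up and program 2 down; per-source
    batch offsets are added so cross-dataset integration is non-trivial.
    """
    severity = severity or {"normal": 0.0, "ventilator_injury": 0.3, "ALI": 0.47, "IPF": 1.63}
    rng = np.random.default_rng(seed)
    groups = (
        [("normal", "Sivakumar")] * n_normal_geo
        + [("normal", "GTEx")] * n_gtex_normal
        + [("ventilator_injury", "GTEx")] * n_vent
        + [("ALI", "Sivakumar")] * n_ali
        + [("IPF", "Sivakumar")] * n_ipf
    )
    rows = []
    for i, (disease, source) in enumerate(groups):
        batch = source if source == "GTEx" else f"Sivakumar-{rng.integers(1, 3)}"
        rows.append(
            {
                "sample_id": f"LUNG{i:04d}",
                "subject_id": f"LSUBJ{i:04d}",
                "tissue": "LUNG",
                "age": float(np.clip(rng.normal(60, 10), 25, 85)),
                "sex": "M" if rng.random() < 0.6 else "F",
                "ischemic_time": float(rng.uniform(60, 1200)),
                "hardy_scale": str(rng.integers(0, 5)),
                "batch": batch,
                "bmi": float(np.clip(rng.normal(27, 4), 17, 42)),
                "disease": disease,
            }
        )
    annot = pd.DataFrame(rows).set_index("sample_id")
    n_samples = len(annot)

    n1, n2 = program_sizes
    G = n1 + n2 + n_filler
    gene_ids = [f"ENSG{i:011d}" for i in range(G)]
    program1 = gene_ids[:n1]
    program2 = gene_ids[n1 : n1 + n2]

    sev = np.array([severity[d] for d in annot["disease"]])
    sev = sev + rng.normal(0.0, 0.15, n_samples)
    shared_factor = rng.normal(0.0, factor_sd, n_samples)

    base = rng.normal(base_log2_mean, base_log2_sd, G)
    batch_levels = sorted(annot["batch"].unique())
    batch_eff = rng.normal(0.0, batch_effect_sd, (G, len(batch_levels)))
    batch_idx = np.array([batch_levels.index(b) for b in annot["batch"]])

    loadings = np.zeros(G)
    loadings[:n1] = program_amplitude * rng.uniform(0.8, 1.2, n1)
    loadings[n1 : n1 + n2] = -program_amplitude * rng.uniform(0.8, 1.2, n2)

    eta = base[:, None] + batch_eff[:, batch_idx]
    eta += np.outer(loadings, sev + shared_factor)
    eta += rng.normal(0.0, residual_log2_sd, (G, n_samples))
    sf = np.exp(rng.normal(0.0, 0.2, n_samples))
    counts = _nb_counts(rng, sf[None, :] * np.exp2(eta), dispersion)

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=annot.index)
    return SimulatedLungCohort(
        counts=ExpressionMatrix(counts_df, units="raw_counts"),
        samples=SampleTable(annot),
        program1=program1,
        program2=program2,
    )
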
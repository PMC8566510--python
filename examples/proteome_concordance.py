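"""Benchmark protein-transcript concordance per matrisome category.

Builds a synthetic paired proteome in which ECM glycoproteins are noisier
than the other categories (the pattern label-free proteomics shows for
glycosylated proteins), then classifies each category's Spearman rho
against a permutation null of equally many non-matrisome pairs.
"""

from matriscope.proteome import permutation_classify
from matriscope.simulate import generate_paired_proteome

pairs = generate_paired_proteome(
    n_pairs={
        "collagens": 40,
        "proteoglycans": 30,
        "ECM_glycoproteins": 80,
        "ECM_regulators": 50,
        "non_matrisome": 2000,
    },
    rho_by_category={
        "collagens": 0.65,
        "proteoglycans": 0.6,
        "ECM_glycoproteins": 0.05,  # glycoproteins underperform
        "ECM_regulators": 0.6,
        "non_matrisome": 0.45,
    },
    seed=0,
)

print(f"{'category':<20} {'N':>4} {'rho':>7} {'pctile':>7}  verdict")
for category in ["collagens", "proteoglycans", "ECM_glycoproteins", "ECM_regulators"]:
    v = permutation_classify(pairs, "TISSUE1", category, n_perm=2000, seed=1)
    print(
        f"{category:<20} {v.n_pairs:>4} {v.observed_rho:>7.3f} "
        f"{v.percentile:>7.3f}  {v.verdict}"
    )

print(
    "\nEach verdict compares the category's protein-transcript Spearman rho"
    "\nagainst 2000 draws of equally many non-matrisome pairs: categories at"
    "\nthe background level read 'equivalent'; the noisy glycoproteins fall"
    "\nbelow the 2.5% null quantile and read 'inferior'."
)
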
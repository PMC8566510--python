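"""Batch-robust normal-vs-cancer rank changes across five tissues.

Simulates five dataset trios (GTEx normal, TCGA normal, TCGA cancer) with
20 genes shifted up and 20 down in cancer, each dataset carrying its own
monotone batch distortion.  Whitelists genes, quantile-normalizes each
trio, ranks mean expression, and sums the cancer-vs-joined-normal rank
changes across tissues.
"""

import warnings

from matriscope.rankchange import build_whitelist, mean_rank_profiles, rank_change_summary
from matriscope.simulate import CancerTrioSpec, generate_cancer_trio

warnings.simplefilter("ignore")

sim = generate_cancer_trio(CancerTrioSpec(seed=11))
profiles = {}
for trio in sim.trios:
    whitelist = build_whitelist(trio)
    profiles[trio.tissue] = mean_rank_profiles(trio, whitelist)
    print(f"{trio.tissue}: whitelist {len(whitelist.genes)} genes")

result = rank_change_summary(profiles)
print("\ntop 10 genes by summed rank change (up in cancer):")
for g in result.top10:
    planted = " (planted up)" if g in sim.planted_up else ""
    print(f"  {g}: {result.summed[g]:+.1f}{planted}")
print("bottom 10 genes (down in cancer):")
for g in result.bottom10:
    planted = " (planted down)" if g in sim.planted_down else ""
    print(f"  {g}: {result.summed[g]:+.1f}{planted}")

up = (result.summed_decile.loc[sim.planted_up] == 10).sum()
down = (result.summed_decile.loc[sim.planted_down] == 1).sum()
print(f"\nplanted-up genes in 10th summed decile: {up}/20")
print(f"planted-down genes in 1st summed decile: {down}/20")
print(f"consistency: {result.consistency}")

print(
    "\nA positive summed delta means the gene ranks higher in cancer than in"
    "\nthe joined normal reference in aggregate across tissues; because only"
    "\nranks cross dataset boundaries, the per-dataset batch distortions the"
    "\ngenerator plants do not corrupt the statistic."
)
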
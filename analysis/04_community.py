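"""Community-composition statistics on the simulated constant-ERH study.

Prevalence-filters the fungal community table, computes asinh absolute
abundances, alpha diversity, Bray-Curtis distances with PCoA, PERMANOVA by
ERH condition and by bag, and elevated-vs-non-elevated differential
abundance. Writes tables under results/community/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from towgrow.community import CommunityTable  # noqa: E402
from towgrow.pipeline import community_stage  # noqa: E402
from towgrow.tsv import read_table, write_table  # noqa: E402

ROOT = Path(__file__).resolve().parents[1]
INPUTS = ROOT / "results" / "inputs" / "constant"
OUT = ROOT / "results" / "community"
SEED = 0


def main():
    rel = pd.read_csv(INPUTS / "abundance.tsv", sep="\t").set_index("sample_id")
    totals = read_table(INPUTS / "totals.tsv", "totals").set_index("sample_id")["total_per_mg"]
    meta = pd.read_csv(INPUTS / "metadata.tsv", sep="\t").set_index("sample_id")
    table = CommunityTable(rel_abundance=rel.astype(float), totals=totals,
                           metadata=meta)
    comm = community_stage(table, n_permutations=999, seed=SEED)
    OUT.mkdir(parents=True, exist_ok=True)
    write_table(comm["diversity"], OUT / "diversity.tsv", "diversity")
    comm["distances"].to_csv(OUT / "bray_curtis.tsv", sep="\t")
    write_table(comm["permanova"], OUT / "permanova.tsv", "permanova")
    if not comm["diffabund"].empty:
        write_table(comm["diffabund"], OUT / "diffabund.tsv", "diffabund")

    div = comm["diversity"].merge(meta.reset_index(), on="sample_id")
    print("mean fungal alpha diversity per condition:")
    key = div["condition_class"].where(div["condition_class"] == "original",
                                       div["erh"].map("{:g}%".format))
    for cond, sub in div.groupby(key):
        print(f"  {cond:>9}: richness {sub['richness'].mean():5.1f}  "
              f"Shannon {sub['shannon'].mean():.3f}")
    print("\nPERMANOVA (Bray-Curtis):")
    for _, r in comm["permanova"].iterrows():
        print(f"  {r['factor']:>9}: R2 = {r['r_squared']:.3f}  "
              f"p = {r['p_value']:.3f}  ({r['n_permutations']} permutations)")
    diff = comm["diffabund"]
    if not diff.empty:
        na = int((diff["direction"] == "group_a").sum())
        nb = int((diff["direction"] == "group_b").sum())
        print(f"\ndifferential abundance (q < 0.05): {na} taxa more abundant at "
              f"non-elevated vs {nb} at elevated (>= 80% ERH) conditions")
    print(f"wrote tables under {OUT}")


if __name__ == "__main__":
    main()
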
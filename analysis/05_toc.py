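"""Soluble-organic-carbon depletion in the simulated incubations.

Compares TOC (mg/L) in original dust against the 85% and 100% ERH
conditions with Welch t tests, mirroring the nutrient-depletion analysis.
Writes results/toc/toc_summary.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from towgrow.stats import welch_t  # noqa: E402

ROOT = Path(__file__).resolve().parents[1]
INPUTS = ROOT / "results" / "inputs" / "constant"
OUT = ROOT / "results" / "toc"


def main():
    toc = pd.read_csv(INPUTS / "toc.tsv", sep="\t")
    orig = toc[toc["condition_class"] == "original"]["toc_mg_per_l"]
    rows = []
    print("soluble organic carbon after 14-day incubations:")
    print(f"  original dust: {orig.min():.2f}-{orig.max():.2f} mg/L "
          f"(mean {orig.mean():.2f}, n={len(orig)})")
    for erh in (85.0, 100.0):
        sub = toc[toc["wet_erh"] == erh]["toc_mg_per_l"]
        res = welch_t(sub, orig)
        star = " *" if res.p_value < 0.05 else ""
        print(f"  {erh:5.0f}% ERH: {sub.min():.2f}-{sub.max():.2f} mg/L "
              f"(mean {sub.mean():.2f})  Welch t={res.statistic:+.2f} "
              f"p={res.p_value:.4f}{star}")
        rows.append({"condition": f"{erh:g}", "mean_toc_mg_per_l": sub.mean(),
                     "min": sub.min(), "max": sub.max(),
                     "t_vs_original": res.statistic, "p_value": res.p_value})
    OUT.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "toc_summary.tsv", sep="\t", index=False)
    print(f"wrote {OUT / 'toc_summary.tsv'}")


if __name__ == "__main__":
    main()
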
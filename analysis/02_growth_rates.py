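"""Quantify qPCR tables and estimate constant-condition growth rates.

Reads the simulated constant-ERH experiment, runs the standard-curve
quantification, fits per-bag log-linear growth rates (day 0 original dust
to day 14), and reports mean concentrations and Welch-t significance per
ERH condition versus original dust. Writes concentrations.tsv and
growth_rates.tsv under results/constant/.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from towgrow.pipeline import (  # noqa: E402
    constant_growth_stage,
    quantify_stage,
)
from towgrow.stats import welch_t  # noqa: E402
from towgrow.tsv import read_table, write_table  # noqa: E402

ROOT = Path(__file__).resolve().parents[1]
INPUTS = ROOT / "results" / "inputs" / "constant"
OUT = ROOT / "results" / "constant"


def main():
    conc = quantify_stage(read_table(INPUTS / "qpcr.tsv", "qpcr"),
                          read_table(INPUTS / "standards.tsv", "standards"))
    conditions = read_table(INPUTS / "conditions.tsv", "conditions")
    joined = conc.merge(conditions, on="sample_id")
    OUT.mkdir(parents=True, exist_ok=True)
    write_table(conc, OUT / "concentrations.tsv", "concentrations")
    rates = constant_growth_stage(joined)
    write_table(rates, OUT / "growth_rates.tsv", "growth_rates")

    fung = joined[joined["target"] == "fungal"]
    orig = np.log(fung[fung["condition_class"] == "original"]
                  ["concentration_per_mg"])
    print("fungal concentration vs ERH (14-day constant incubations):")
    print(f"  original dust: {np.exp(orig).mean():.3e} per mg (n={len(orig)})")
    for erh, sub in fung[fung["condition_class"] == "constant"].groupby("wet_erh"):
        vals = np.log(sub["concentration_per_mg"])
        res = welch_t(vals, orig)
        star = " *" if res.p_value < 0.05 and res.statistic > 0 else ""
        print(f"  {erh:5.0f}% ERH: {np.exp(vals).mean():.3e} per mg  "
              f"Welch t={res.statistic:+.2f} p={res.p_value:.2e}{star}")
    print(f"\nwrote {OUT / 'concentrations.tsv'} and {OUT / 'growth_rates.tsv'}")


if __name__ == "__main__":
    main()
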
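"""Calibration routine behind the generator's default noise parameters.

The dust-incubation study prints two headline rank correlations that the
synthetic experiment is expected to reproduce under its default settings:

* pooled Spearman rho between ERH level and per-sample fungal
  concentration over the incubated constant-ERH samples: 0.77;
* pooled Spearman rho between time-elevated (h/day) and per-bag effective
  growth rate over the elevated + saturated ToW conditions: 0.68.

Five generator settings are not printed in the study and jointly control
these correlations: the sample-level lognormal sigma, the per-bag rate
multiplier sigma, the aliquot growth-failure probability, the 85%-ERH
14-day endpoint mean, and the saturated deactivation persistence. The
failure mechanism matters structurally: without occasional non-responsive
aliquots the pooled constant-ERH correlation cannot fall to 0.77 — the
gap between the non-growing (<=80%) and strongly growing (>=85%)
conditions is ~5 natural-log units, which plausible lognormal noise never
crosses, putting a ~0.85 floor under rho. This script grid-searches the
settings, reports both mean correlations per grid point (with the fungal
ToW classification success rate as a sanity column), and prints the
least-squares winner. The chosen values are frozen as GeneratorConfig
defaults:

    fungal_day14_means[85] = 3.0e9, t_deact_saturated_h = 4.0,
    bag_sigma_log = 0.3, noise_sigma_log = 0.3, growth_failure_prob = 0.2

Usage: python scripts/calibrate_noise.py [--seeds 12]
"""

import argparse
import sys

import numpy as np

from towgrow.pipeline import dataset_concentrations, tow_stage
from towgrow.simulate import (
    FUNGAL_DAY14_MEANS,
    GeneratorConfig,
    generate_constant_erh_experiment,
    generate_tow_experiment,
)
from towgrow.stats import spearman

TARGET_RHO_CONSTANT = 0.77
TARGET_RHO_TOW = 0.68


def evaluate(e85, t_deact, bag_sigma, sample_sigma, p_fail, seeds):
    rho_c, rho_t, ok = [], [], []
    f14 = dict(FUNGAL_DAY14_MEANS)
    f14[85] = e85
    for s in seeds:
        cfg = GeneratorConfig(
            seed=s, bag_sigma_log=bag_sigma, noise_sigma_log=sample_sigma,
            fungal_day14_means=f14, t_deact_saturated_h=t_deact,
            growth_failure_prob=p_fail,
        )
        conc = dataset_concentrations(generate_constant_erh_experiment(cfg))
        f = conc[(conc.target == "fungal") & (conc.condition_class == "constant")]
        rho_c.append(spearman(f.wet_erh, f.concentration_per_mg).statistic)
        rates, _, fits, _ = tow_stage(dataset_concentrations(generate_tow_experiment(cfg)))
        fr = rates[rates.target == "fungal"]
        rho_t.append(spearman(fr.time_elevated, fr.rate).statistic)
        ff = fits[fits.target == "fungal"].set_index("wet_erh").model.to_dict()
        ok.append(ff.get(85.0) == "activation_limited"
                  and ff.get(100.0) == "deactivation_limited")
    return float(np.mean(rho_c)), float(np.mean(rho_t)), float(np.mean(ok))


def main(argv=None):
    ap = argparse.ArgumentParser()
    ap.add_argument("--seeds", type=int, default=12, help="seeds per grid point")
    args = ap.parse_args(argv)
    seeds = range(1, args.seeds + 1)
    grid = [
        (e85, td, bs, ss, pf)
        for e85 in (1.0e9, 3.0e9, 5.0e9)
        for td in (3.0, 4.0, 6.0)
        for bs in (0.3, 0.35)
        for ss in (0.3, 0.4)
        for pf in (0.0, 0.1, 0.15, 0.2)
    ]
    best = None
    print(f"{'e85':>8} {'t_deact':>7} {'bag_s':>6} {'samp_s':>6} {'p_fail':>6} "
          f"{'rho_const':>9} {'rho_tow':>8} {'class_ok':>8}")
    for e85, td, bs, ss, pf in grid:
        rc, rt, ok = evaluate(e85, td, bs, ss, pf, seeds)
        loss = (rc - TARGET_RHO_CONSTANT) ** 2 + (rt - TARGET_RHO_TOW) ** 2
        print(f"{e85:8.0e} {td:7.1f} {bs:6.2f} {ss:6.2f} {pf:6.2f} "
              f"{rc:9.3f} {rt:8.3f} {ok:8.2f}")
        if ok >= 0.9 and (best is None or loss < best[0]):
            best = (loss, e85, td, bs, ss, pf, rc, rt)
    if best:
        _, e85, td, bs, ss, pf, rc, rt = best
        print(f"\nbest: e85={e85:.1e} t_deact={td} bag_sigma={bs} "
              f"sample_sigma={ss} p_fail={pf} "
              f"(rho_const={rc:.3f}, rho_tow={rt:.3f})")
    return 0


if __name__ == "__main__":
    sys.exit(main())
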
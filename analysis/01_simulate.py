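"""Generate the two synthetic incubation experiments used by the analysis.

Writes the constant-ERH experiment (original dust + 7 ERH levels, 4 bags x
3 replicates, 14 days) and the time-of-wetness experiment (85%/100% ERH x
6/12/18/24 h/day x days 5/10/14/21 x 4 bags, plus the 50%/24 h control)
under results/inputs/, in the same TSV dialects the pipeline consumes,
together with the generating truth.
"""

import dataclasses
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from towgrow.simulate import (  # noqa: E402
    GeneratorConfig,
    generate_community,
    generate_constant_erh_experiment,
    generate_toc,
    generate_tow_experiment,
    write_dataset,
)

SEED = 0
ROOT = Path(__file__).resolve().parents[1]


def main():
    cfg = GeneratorConfig(seed=SEED)
    constant = generate_constant_erh_experiment(cfg)
    constant = dataclasses.replace(
        constant,
        community=generate_community(cfg, constant),
        toc=generate_toc(cfg, constant),
    )
    tow = generate_tow_experiment(cfg)
    paths_c = write_dataset(constant, cfg, ROOT / "results" / "inputs" / "constant")
    paths_t = write_dataset(tow, cfg, ROOT / "results" / "inputs" / "tow")
    n_const = constant.samples["sample_id"].nunique()
    n_tow = tow.samples["sample_id"].nunique()
    print(f"constant-ERH experiment: {n_const} physical samples "
          f"({len(paths_c)} tables)")
    print(f"time-of-wetness experiment: {n_tow} physical samples "
          f"({len(paths_t)} tables)")
    print(f"seed {SEED}; outputs under {ROOT / 'results' / 'inputs'}")


if __name__ == "__main__":
    main()
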
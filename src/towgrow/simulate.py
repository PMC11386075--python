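"""Synthetic spacecraft-dust incubation experiments.

Emulates the statistical structure of the ISS-dust moisture study: four
vacuum bags of dust, constant equilibrium-relative-humidity (ERH)
incubations for 14 days (original dust plus 50–100% ERH), time-of-wetness
incubations (6/12/18/24 h/day above the 80% threshold at 85% and 100% ERH,
sampled on days 5/10/14/21, plus a 50%/24 h control), triplicate qPCR
measurement with lognormal noise, an ERH-responsive fungal community
(dominance shift and diversity loss with moisture), and soluble-organic-
carbon depletion coupled to realized growth.

Per-condition intrinsic growth rates default to values back-solved from the
14-day endpoint concentrations the study design targets (log-ratio over 14
days); measurement noise defaults were fixed by the shipped calibration
routine (``scripts/calibrate_noise.py``). Every stochastic element flows
from the single config seed through named substreams, so identical
configurations produce byte-identical tables.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .community import CommunityTable
from .errors import ValidationError
from .growth import ERHSchedule, GrowthParams, effective_daily_rate

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "generate_constant_erh_experiment",
    "generate_tow_experiment",
    "generate_community",
    "generate_toc",
    "generate_qpcr_standards",
    "draw_initial_concentrations",
    "default_growth_params",
    "backsolved_rate",
]

INCUBATION_DAYS = 14.0

#: 14-day endpoint concentration means the per-condition rates are
#: back-solved from (per mg dust). The 50% and 100% fungal endpoints and
#: both initial loads are the study's printed values; intermediate levels
#: follow the observed significance pattern (fungal growth from 80% ERH
#: upward, bacterial from 90%).
INITIAL_FUNGAL_MEAN = 4.39e6  # SE/mg
INITIAL_BACTERIAL_MEAN = 1.06e7  # cells/mg
FUNGAL_DAY14_MEANS = {
    50: 4.22e6, 60: 4.3e6, 70: 4.5e6, 80: 2.0e7,
    85: 3.0e9, 90: 5.0e9, 100: 2.10e10,
}
BACTERIAL_DAY14_MEANS = {
    50: 1.0e7, 60: 1.02e7, 70: 1.05e7, 80: 1.3e7,
    85: 2.0e7, 90: 5.0e7, 100: 2.0e8,
}


def backsolved_rate(endpoint: float, initial: float, days: float = INCUBATION_DAYS) -> float:
    """Intrinsic rate k = ln(endpoint/initial)/days (day⁻¹)."""
    return math.log(endpoint / initial) / days


@dataclass(frozen=True)
class GeneratorConfig:
    """Defaults reproduce the ISS-dust experimental design.

    ``noise_sigma_log`` is the sample-level lognormal sigma (ln scale) on
    each 25-mg aliquot's concentration and ``bag_sigma_log`` the spread of
    per-bag multipliers on k; their defaults — together with the unprinted
    85% ERH endpoint and the saturated persistence time — were chosen by
    the shipped calibration routine (``scripts/calibrate_noise.py``) so the
    generated data reproduce the study's two headline rank correlations
    (ERH vs fungal concentration, rho 0.77; time-elevated vs growth rate,
    rho 0.68). ``qpcr_sigma_log`` is the within-sample triplicate noise,
    fixed a priori.
    """

    seed: int
    n_bags: int = 4
    n_replicates: int = 3
    qpcr_triplicates: int = 3
    erh_levels: tuple = (50, 60, 70, 80, 85, 90, 100)
    tow_levels: tuple = (6.0, 12.0, 18.0, 24.0)
    tow_erh: tuple = (85, 100)
    sample_days: tuple = (5, 10, 14, 21)
    incubation_days: float = INCUBATION_DAYS
    initial_fungal_mean: float = INITIAL_FUNGAL_MEAN
    initial_bacterial_mean: float = INITIAL_BACTERIAL_MEAN
    fungal_day14_means: dict = field(default_factory=lambda: dict(FUNGAL_DAY14_MEANS))
    bacterial_day14_means: dict = field(default_factory=lambda: dict(BACTERIAL_DAY14_MEANS))
    t_act_elevated_h: float = 3.0
    t_deact_saturated_h: float = 4.0
    noise_sigma_log: float = 0.3  # calibrated; see scripts/calibrate_noise.py
    qpcr_sigma_log: float = 0.1
    bag_sigma_log: float = 0.3  # calibrated; see scripts/calibrate_noise.py
    growth_failure_prob: float = 0.2  # calibrated; see scripts/calibrate_noise.py
    failure_rate_range: tuple = (0.0, 0.2)  # surviving fraction of k on failure
    carrying_capacity: float = 1e11
    dust_mass_mg: float = 25.0
    threshold_erh: float = 80.0
    dry_erh: float = 50.0
    # community model
    n_taxa: int = 40
    n_responders: int = 5
    responder_gain: float = 0.8  # share gain per unit realized log-growth
    dirichlet_concentration: float = 150.0
    detection_limit: float = 1e-4
    # TOC model
    toc_baseline_range: tuple = (12.55, 36.79)  # mg/L, printed original range
    toc_depletion_per_log: float = 1.98  # mg/L per unit realized log-growth
    # qPCR standards
    standard_slope: float = -3.3219
    standard_intercept: float = 37.0
    standard_cq_sd: float = 0.1
    standard_duplicates: int = 2

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        for name in ("n_bags", "n_replicates", "qpcr_triplicates", "n_taxa"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        for name in ("noise_sigma_log", "qpcr_sigma_log", "bag_sigma_log"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated tables plus the ground truth that produced them."""

    samples: pd.DataFrame
    truth: dict
    community: CommunityTable | None = None
    toc: pd.DataFrame | None = None


def _rng(config: GeneratorConfig, stream: str) -> np.random.Generator:
    """Named deterministic substream of the config seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(int(config.seed), zlib.crc32(stream.encode())))
    )


def _mean_one_lognormal(rng, sigma: float, size=None):
    """Lognormal multiplier with expectation exactly 1."""
    if sigma == 0:
        return np.ones(size) if size is not None else 1.0
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=size))


def draw_initial_concentrations(
    config: GeneratorConfig, target: str, n: int, rng=None
) -> np.ndarray:
    """Original-dust (unincubated) per-sample concentrations.

    Lognormal with expectation equal to the configured initial mean
    (sample-level sigma), matching the original-dust draws of the constant
    experiment.
    """
    if rng is None:
        rng = _rng(config, f"initial:{target}")
    mean = (config.initial_fungal_mean if target == "fungal"
            else config.initial_bacterial_mean)
    return mean * _mean_one_lognormal(rng, config.noise_sigma_log, size=n)


def default_growth_params(
    config: GeneratorConfig, target: str, erh: float, c0: float | None = None
) -> GrowthParams:
    """Per-condition GrowthParams with back-solved intrinsic rate."""
    if target == "fungal":
        endpoints, initial = config.fungal_day14_means, config.initial_fungal_mean
    else:
        endpoints, initial = config.bacterial_day14_means, config.initial_bacterial_mean
    k = backsolved_rate(endpoints[int(erh)], initial, config.incubation_days)
    return GrowthParams(
        k=k,
        c0=c0 if c0 is not None else initial,
        t_act=config.t_act_elevated_h if (target == "fungal" and int(erh) == 85) else 0.0,
        t_deact=config.t_deact_saturated_h if (target == "fungal" and int(erh) == 100) else 0.0,
        carrying_capacity=config.carrying_capacity if target == "fungal" else None,
    )


def _rate_with_failures(rng, k_bag: float, config: GeneratorConfig) -> float:
    """Aliquot-level growth failure: with small probability a 25-mg dust
    aliquot barely responds to moisture (micro-environment or inoculum
    heterogeneity), retaining only a small fraction of its rate."""
    if config.growth_failure_prob > 0 and rng.random() < config.growth_failure_prob:
        return k_bag * rng.uniform(*config.failure_rate_range)
    return k_bag


def _bag_multipliers(config: GeneratorConfig) -> dict:
    rng = _rng(config, "bags")
    out = {}
    for target in ("fungal", "bacterial"):
        for b in range(1, config.n_bags + 1):
            out[(target, b)] = float(_mean_one_lognormal(rng, config.bag_sigma_log))
    return out


def _measure(rng, true_conc: float, config: GeneratorConfig) -> np.ndarray:
    """qPCR triplicate measured concentrations for one sample."""
    return true_conc * _mean_one_lognormal(
        rng, config.qpcr_sigma_log, size=config.qpcr_triplicates
    )


def _cq_from_concentration(conc_per_mg: float, config: GeneratorConfig) -> float:
    """Back out the Cq a measured per-mg concentration corresponds to."""
    copies_per_ul = conc_per_mg * config.dust_mass_mg / (50.0 * 50.0)
    copies_per_ul = max(copies_per_ul, 1e-12)
    return config.standard_intercept + config.standard_slope * math.log10(copies_per_ul)


def _sample_rows(
    rng, config, sample_id, bag, condition_class, wet_erh, wet_hours, day,
    true_conc_by_target, log_growth_fungal,
):
    rows = []
    for target in ("fungal", "bacterial"):
        true_c = true_conc_by_target[target]
        reps = _measure(rng, true_c, config)
        row = {
            "sample_id": sample_id,
            "bag": bag,
            "condition_class": condition_class,
            "wet_erh": wet_erh,
            "dry_erh": config.dry_erh,
            "wet_hours_per_day": wet_hours,
            "day": day,
            "dust_mass_mg": config.dust_mass_mg,
            "target": target,
            "true_concentration": true_c,
            "log_growth": log_growth_fungal if target == "fungal" else float("nan"),
        }
        for i, c in enumerate(reps, start=1):
            row[f"conc_{i}"] = float(c)
            row[f"cq_{i}"] = _cq_from_concentration(float(c), config)
        rows.append(row)
    return rows


def generate_constant_erh_experiment(config: GeneratorConfig) -> SyntheticDataset:
    """Original dust plus 14-day constant-ERH incubations.

    Produces n_bags × n_replicates physical samples for original dust and
    for each ERH level (default: 8 conditions × 4 bags × 3 replicates = 96
    samples, 288 fungal qPCR values), with a shared per-bag lognormal
    multiplier on k and lognormal sample- and replicate-level noise.
    """
    rng = _rng(config, "constant")
    bag_mult = _bag_multipliers(config)
    truth_params = {}
    rows = []
    conditions = ["original"] + [int(e) for e in config.erh_levels]
    for target in ("fungal", "bacterial"):
        for erh in config.erh_levels:
            truth_params[(target, int(erh))] = default_growth_params(config, target, erh)
    for cond in conditions:
        for bag in range(1, config.n_bags + 1):
            for rep in range(1, config.n_replicates + 1):
                sid = f"C-{cond}-b{bag}-r{rep}"
                true_by_target = {}
                lg = 0.0
                for target in ("fungal", "bacterial"):
                    initial = (config.initial_fungal_mean if target == "fungal"
                               else config.initial_bacterial_mean)
                    c0 = float(initial * _mean_one_lognormal(rng, config.noise_sigma_log))
                    if cond == "original":
                        true_c = c0
                        growth = 0.0
                    else:
                        # constant exposure: the back-solved k encodes the
                        # ERH response directly (no daily cycling applies)
                        base = truth_params[(target, cond)]
                        k_bag = base.k * bag_mult[(target, bag)]
                        k_real = _rate_with_failures(rng, k_bag, config)
                        true_c = c0 * math.exp(k_real * config.incubation_days)
                        if base.carrying_capacity is not None:
                            true_c = min(true_c, base.carrying_capacity)
                        growth = math.log(true_c / c0)
                    true_by_target[target] = true_c
                    if target == "fungal":
                        lg = growth
                day = 0.0 if cond == "original" else config.incubation_days
                erh_val = float("nan") if cond == "original" else float(cond)
                rows.extend(_sample_rows(
                    rng, config, sid, bag, "original" if cond == "original" else "constant",
                    erh_val, 0.0 if cond == "original" else 24.0, day,
                    true_by_target, lg,
                ))
    samples = pd.DataFrame(rows)
    truth = {"params": truth_params, "bag_multipliers": bag_mult,
             "standard_curve": (config.standard_slope, config.standard_intercept)}
    return SyntheticDataset(samples=samples, truth=truth)


def generate_tow_experiment(config: GeneratorConfig) -> SyntheticDataset:
    """Time-of-wetness incubations at 85% and 100% ERH.

    For each condition × wet-hours level × sampling day × bag one physical
    sample is generated (default 2 × 4 × 4 × 4 = 128), plus a 50%/24 h
    control (16 samples). Elevated (85%) truth is activation-limited
    (t_act > 0); saturated (100%) truth is deactivation-limited (t_deact > 0).
    """
    rng = _rng(config, "tow")
    bag_mult = _bag_multipliers(config)
    truth_params = {}
    rows = []
    plan = [(float(e), float(t)) for e in config.tow_erh for t in config.tow_levels]
    plan.append((float(config.dry_erh), 24.0))  # unmodified control
    for target in ("fungal", "bacterial"):
        for erh, _ in plan:
            key = (target, int(erh))
            if key not in truth_params:
                truth_params[key] = default_growth_params(config, target, erh)
    for erh, t_w in plan:
        cond_label = "control" if erh == float(config.dry_erh) else "tow"
        for day in config.sample_days:
            for bag in range(1, config.n_bags + 1):
                sid = f"T-{int(erh)}-{int(t_w)}h-d{int(day)}-b{bag}"
                true_by_target = {}
                lg = 0.0
                for target in ("fungal", "bacterial"):
                    initial = (config.initial_fungal_mean if target == "fungal"
                               else config.initial_bacterial_mean)
                    c0 = float(initial * _mean_one_lognormal(rng, config.noise_sigma_log))
                    base = truth_params[(target, int(erh))]
                    k_bag = _rate_with_failures(
                        rng, base.k * bag_mult[(target, bag)], config)
                    sched = ERHSchedule(
                        wet_erh=erh, wet_hours_per_day=t_w,
                        dry_erh=config.dry_erh, threshold_erh=config.threshold_erh,
                    )
                    r = effective_daily_rate(replace(base, k=k_bag, c0=c0), sched)
                    true_c = c0 * math.exp(r * float(day))
                    if base.carrying_capacity is not None:
                        true_c = min(true_c, base.carrying_capacity)
                    true_by_target[target] = true_c
                    if target == "fungal":
                        lg = math.log(true_c / c0)
                rows.extend(_sample_rows(
                    rng, config, sid, bag, cond_label, erh, t_w, float(day),
                    true_by_target, lg,
                ))
    samples = pd.DataFrame(rows)
    truth = {"params": truth_params, "bag_multipliers": bag_mult,
             "standard_curve": (config.standard_slope, config.standard_intercept)}
    return SyntheticDataset(samples=samples, truth=truth)


def _baseline_profile(config: GeneratorConfig) -> np.ndarray:
    """Baseline taxon proportions: one dominant genus, geometric tail."""
    ranks = np.arange(config.n_taxa, dtype=float)
    weights = 0.82**ranks
    return weights / weights.sum()


def generate_community(config: GeneratorConfig, dataset: SyntheticDataset) -> CommunityTable:
    """Fungal community tables coupled to realized growth.

    A small responder set (the dominant-genus-like taxa) gains relative
    share exponentially with each sample's realized fungal log-growth;
    non-responders are diluted. Proportions are Dirichlet draws around the
    condition-dependent expectation; fractions below the detection limit
    are recorded as absent, producing the richness loss seen at high ERH.
    """
    rng = _rng(config, "community")
    fungal = dataset.samples[dataset.samples["target"] == "fungal"]
    base = _baseline_profile(config)
    responders = np.zeros(config.n_taxa, dtype=bool)
    responders[: config.n_responders] = True
    gains = np.where(responders, config.responder_gain, 0.0)
    taxa = [f"taxon_{i + 1:03d}" for i in range(config.n_taxa)]
    conc_cols = [c for c in fungal.columns if c.startswith("conc_")]
    rows, totals, meta_rows = [], {}, []
    for _, s in fungal.iterrows():
        lg = float(s["log_growth"]) if np.isfinite(s["log_growth"]) else 0.0
        expectation = base * np.exp(gains * max(0.0, lg))
        expectation = expectation / expectation.sum()
        props = rng.dirichlet(expectation * config.dirichlet_concentration)
        props = np.where(props < config.detection_limit, 0.0, props)
        total_mass = props.sum()
        if total_mass == 0:
            props = expectation  # degenerate draw; fall back to expectation
            total_mass = 1.0
        props = props / total_mass
        rows.append(props)
        sid = str(s["sample_id"])
        reps = np.asarray([s[c] for c in conc_cols], dtype=float)
        totals[sid] = float(np.exp(np.mean(np.log(np.maximum(reps, 1e-12)))))
        meta_rows.append({
            "sample_id": sid,
            "bag": s["bag"],
            "erh": s["wet_erh"],
            "time_elevated": s["wet_hours_per_day"],
            "day": s["day"],
            "condition_class": s["condition_class"],
        })
    rel = pd.DataFrame(rows, index=[m["sample_id"] for m in meta_rows], columns=taxa)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return CommunityTable(
        rel_abundance=rel,
        totals=pd.Series(totals, name="total_per_mg"),
        metadata=meta,
    )


def generate_toc(config: GeneratorConfig, dataset: SyntheticDataset) -> pd.DataFrame:
    """Soluble-organic-carbon table (mg/L) coupled to realized growth.

    Baseline TOC is uniform over the configured original-dust range (its
    midpoint when noise is disabled); depletion is proportional to each
    sample's realized fungal log-growth, floored at 0.1 mg/L.
    """
    rng = _rng(config, "toc")
    fungal = dataset.samples[dataset.samples["target"] == "fungal"]
    lo, hi = config.toc_baseline_range
    rows = []
    for _, s in fungal.iterrows():
        baseline = 0.5 * (lo + hi) if config.noise_sigma_log == 0 else float(rng.uniform(lo, hi))
        lg = float(s["log_growth"]) if np.isfinite(s["log_growth"]) else 0.0
        toc = max(0.1, baseline - config.toc_depletion_per_log * max(0.0, lg))
        rows.append({
            "sample_id": s["sample_id"],
            "condition_class": s["condition_class"],
            "wet_erh": s["wet_erh"],
            "toc_mg_per_l": toc,
        })
    return pd.DataFrame(rows)


def generate_qpcr_standards(config: GeneratorConfig, target: str = "fungal") -> pd.DataFrame:
    """Standard dilution series: six decades × duplicate wells.

    Cq values follow the configured true line with Gaussian Cq noise.
    """
    rng = _rng(config, f"standards:{target}")
    rows = []
    for decade in range(1, 7):
        copies = 10.0**decade
        for _ in range(config.standard_duplicates):
            cq = (config.standard_intercept + config.standard_slope * decade
                  + (rng.normal(0.0, config.standard_cq_sd)
                     if config.standard_cq_sd > 0 else 0.0))
            rows.append({"target": target, "copies_per_ul": copies, "cq": cq})
    return pd.DataFrame(rows)


def write_dataset(dataset: SyntheticDataset, config: GeneratorConfig, out_dir) -> dict:
    """Write a synthetic dataset in the TSV dialects the pipeline consumes.

    Emits qpcr.tsv, standards.tsv, conditions.tsv and truth.tsv, plus
    abundance/totals/metadata.tsv and toc.tsv when the dataset carries a
    community table or TOC table. Returns the written paths.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    df = dataset.samples
    cq_cols = sorted(c for c in df.columns if c.startswith("cq_"))
    qpcr = df[["sample_id", "target", "dust_mass_mg"] + cq_cols].copy()
    qpcr.insert(3, "dilution_factor", 50.0)
    qpcr.insert(4, "extract_volume_ul", 50.0)
    paths["qpcr"] = out / "qpcr.tsv"
    qpcr.to_csv(paths["qpcr"], sep="\t", index=False)

    standards = pd.concat(
        [generate_qpcr_standards(config, t) for t in ("fungal", "bacterial")],
        ignore_index=True,
    )
    paths["standards"] = out / "standards.tsv"
    standards.to_csv(paths["standards"], sep="\t", index=False)

    conditions = (
        df[["sample_id", "bag", "condition_class", "wet_erh", "dry_erh",
            "wet_hours_per_day", "day"]]
        .drop_duplicates("sample_id")
    )
    paths["conditions"] = out / "conditions.tsv"
    conditions.to_csv(paths["conditions"], sep="\t", index=False)

    truth_rows = [
        {"target": t, "condition": c, "k": p.k, "t_act": p.t_act,
         "t_deact": p.t_deact, "c0": p.c0}
        for (t, c), p in dataset.truth["params"].items()
    ]
    truth = pd.DataFrame(truth_rows)
    bags = pd.DataFrame(
        [{"target": t, "bag": b, "k_multiplier": m}
         for (t, b), m in dataset.truth["bag_multipliers"].items()]
    )
    paths["truth"] = out / "truth.tsv"
    truth.merge(bags, on="target").to_csv(paths["truth"], sep="\t", index=False)

    if dataset.community is not None:
        ct = dataset.community
        paths["abundance"] = out / "abundance.tsv"
        ct.rel_abundance.rename_axis("sample_id").reset_index().to_csv(
            paths["abundance"], sep="\t", index=False)
        paths["totals"] = out / "totals.tsv"
        ct.totals.rename_axis("sample_id").reset_index().to_csv(
            paths["totals"], sep="\t", index=False)
        paths["metadata"] = out / "metadata.tsv"
        ct.metadata.rename_axis("sample_id").reset_index().to_csv(
            paths["metadata"], sep="\t", index=False)
    if dataset.toc is not None:
        paths["toc"] = out / "toc.tsv"
        dataset.toc.to_csv(paths["toc"], sep="\t", index=False)
    return paths
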
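"""End-to-end orchestration of the dust-moisture analysis.

Stages: qPCR quantification → growth-rate estimation → time-of-wetness
model fitting → community statistics → differential abundance → report.
Each stage is a pure function over DataFrames so tests and scripts can call
any slice of the pipeline; ``run_pipeline`` wires them to the TSV dialects,
writes per-stage outputs, a manifest (config echo, seed, versions, input
checksums) and a plain-text summary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community import (
    CommunityTable,
    absolute_abundance,
    alpha_diversity,
    bray_curtis,
    differential_abundance,
    pcoa,
    permanova,
    prevalence_filter,
)
from .errors import InsufficientDataError, TowgrowError, ValidationError
from .growth import (
    TowPoint,
    build_tow_curve,
    estimate_growth_rate,
    fit_tow_model,
    relative_growth_rate,
)
from .qpcr import QpcrMeasurement, fit_standard_curve, process_measurement
from .stats import welch_t
from .tsv import read_table, write_table

__all__ = [
    "PipelineConfig",
    "quantify_stage",
    "dataset_concentrations",
    "constant_growth_stage",
    "tow_stage",
    "community_stage",
    "run_pipeline",
]

DEFAULT_NO_MODEL_SSE = 0.5  # R/k units²; bacterial curves exceed this


@dataclass
class PipelineConfig:
    """Paths, thresholds and toggles for one pipeline run."""

    out_dir: str
    seed: int
    qpcr_path: str | None = None
    standards_path: str | None = None
    conditions_path: str | None = None
    abundance_path: str | None = None
    totals_path: str | None = None
    metadata_path: str | None = None
    alpha: float = 0.05
    min_prevalence: float = 0.10
    threshold_erh: float = 80.0
    n_permutations: int = 999
    no_model_sse: float = DEFAULT_NO_MODEL_SSE
    stages: tuple = ("quantify", "growth", "community", "report")

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if not 0 <= self.min_prevalence <= 1:
            raise ValidationError("min_prevalence must lie in [0, 1]")
        if self.seed is None and set(self.stages) & {"community"}:
            raise ValidationError("seed is required when stochastic stages run")


def quantify_stage(qpcr: pd.DataFrame, standards: pd.DataFrame) -> pd.DataFrame:
    """Convert Cq tables to per-mg concentration records.

    One standard curve is fitted per target (per plate, were plate IDs
    present; curves are never pooled across targets).
    """
    cq_cols = sorted(c for c in qpcr.columns if str(c).startswith("cq_"))
    rows = []
    for target, sub in qpcr.groupby("target", sort=False):
        if "target" in standards.columns:
            std = standards[standards["target"] == target]
            if std.empty:
                std = standards
        else:
            std = standards
        curve = fit_standard_curve(list(zip(std["copies_per_ul"], std["cq"])))
        for _, row in sub.iterrows():
            cqs = tuple(float(row[c]) for c in cq_cols if np.isfinite(float(row[c])))
            meas = QpcrMeasurement(
                sample_id=str(row["sample_id"]),
                target=str(target),
                cq_values=cqs,
                dust_mass_mg=float(row["dust_mass_mg"]),
                dilution_factor=float(row.get("dilution_factor", 50.0)),
                extract_volume_ul=float(row.get("extract_volume_ul", 50.0)),
            )
            rec = process_measurement(meas, curve)
            rows.append({
                "sample_id": rec.sample_id,
                "target": rec.target,
                "concentration_per_mg": rec.concentration,
                "replicate_cv": rec.replicate_cv,
                "flags": ";".join(rec.flags),
            })
    return pd.DataFrame(rows)


def dataset_concentrations(dataset) -> pd.DataFrame:
    """Per-sample pooled concentrations straight from a synthetic dataset.

    Geometric mean over the qPCR triplicate columns, joined with the design
    columns — the same quantity the quantify stage produces from Cq input.
    """
    df = dataset.samples
    conc_cols = [c for c in df.columns if str(c).startswith("conc_")]
    logs = np.log(df[conc_cols].to_numpy(dtype=float))
    out = df[[
        "sample_id", "target", "bag", "condition_class", "wet_erh",
        "wet_hours_per_day", "day",
    ]].copy()
    out["concentration_per_mg"] = np.exp(logs.mean(axis=1))
    return out


def constant_growth_stage(conc: pd.DataFrame) -> pd.DataFrame:
    """Per-bag k estimates for the constant-ERH experiment.

    Each (target, bag, ERH) rate is the log-linear fit through that bag's
    original-dust (day 0) and incubated (day 14) samples.
    """
    rows = []
    original = conc[conc["condition_class"] == "original"]
    constant = conc[conc["condition_class"] == "constant"]
    for (target, bag), orig_sub in original.groupby(["target", "bag"]):
        base_pts = [(float(d), float(c)) for d, c in
                    zip(orig_sub["day"], orig_sub["concentration_per_mg"])]
        sub = constant[(constant["target"] == target) & (constant["bag"] == bag)]
        for erh, cond_sub in sub.groupby("wet_erh"):
            pts = base_pts + [
                (float(d), float(c)) for d, c in
                zip(cond_sub["day"], cond_sub["concentration_per_mg"])
            ]
            try:
                est = estimate_growth_rate(pts)
            except InsufficientDataError:
                continue
            rows.append({
                "target": target, "bag": int(bag), "condition": f"{erh:g}",
                "rate": est.rate, "stderr": est.stderr,
                "r_squared": est.r_squared, "n_points": est.n_points,
            })
    return pd.DataFrame(rows)


def tow_stage(conc: pd.DataFrame, no_model_sse: float = DEFAULT_NO_MODEL_SSE):
    """Time-of-wetness analysis over a concentrations + conditions table.

    Per (target, ERH, bag): the intrinsic rate k is the day-series fit at
    24 h/day, effective rates R come from the same fit at each shorter
    time-elevated level, and R/k is clamped at zero. Per-bag relative rates
    are averaged into the ToW curve, which is classified against the
    activation/deactivation families. Bacterial fits carry the ``no_model``
    SSE threshold (the framework does not describe bacterial growth).

    Returns (rates, curve, fits) DataFrames and the per-bag point mapping.
    """
    tow = conc[conc["condition_class"] == "tow"]
    rate_rows, curve_rows, fit_rows = [], [], []
    per_bag_all = {}
    for (target, erh), sub in tow.groupby(["target", "wet_erh"]):
        per_bag: dict[str, list[TowPoint]] = {}
        for bag, bag_sub in sub.groupby("bag"):
            series_by_tw = {
                float(tw): [(float(d), float(c)) for d, c in
                            zip(g["day"], g["concentration_per_mg"])]
                for tw, g in bag_sub.groupby("wet_hours_per_day")
            }
            if 24.0 not in series_by_tw:
                continue
            try:
                k_est = estimate_growth_rate(series_by_tw[24.0], trim_plateau=True)
            except InsufficientDataError:
                continue
            if k_est.rate <= 0:
                continue  # bag without measurable intrinsic growth
            points = []
            for tw, series in sorted(series_by_tw.items()):
                est = (k_est if tw == 24.0
                       else estimate_growth_rate(series, trim_plateau=True))
                rr = relative_growth_rate(est, k_est)
                points.append(TowPoint(time_elevated=tw, relative_growth=rr,
                                       bag_id=str(bag)))
                rate_rows.append({
                    "target": target, "wet_erh": float(erh), "bag": int(bag),
                    "time_elevated": tw, "rate": est.rate, "stderr": est.stderr,
                    "r_squared": est.r_squared, "n_points": est.n_points,
                    "relative_growth": rr,
                })
            per_bag[str(bag)] = points
        if not per_bag:
            continue
        per_bag_all[(str(target), float(erh))] = per_bag
        curve = build_tow_curve(per_bag)
        for p in curve:
            curve_rows.append({
                "target": target, "wet_erh": float(erh),
                "time_elevated": p.time_elevated,
                "mean_relative_growth": p.relative_growth, "stderr": p.stderr,
            })
        fit = fit_tow_model(
            curve,
            no_model_sse=no_model_sse if target == "bacterial" else None,
        )
        fit_rows.append({
            "target": target, "wet_erh": float(erh), "model": fit.model,
            "parameter_hours": fit.parameter_hours, "sse": fit.sse,
        })
    return (pd.DataFrame(rate_rows), pd.DataFrame(curve_rows),
            pd.DataFrame(fit_rows), per_bag_all)


def community_stage(
    table: CommunityTable,
    min_prevalence: float = 0.10,
    alpha: float = 0.05,
    n_permutations: int = 999,
    seed: int | None = 0,
    elevated_threshold: float = 80.0,
):
    """Prevalence filter → asinh absolute abundance → diversity, ordination,
    PERMANOVA (by condition and bag) and elevated-vs-non-elevated
    differential abundance."""
    filtered = prevalence_filter(table, min_prevalence)
    transformed = absolute_abundance(filtered)
    diversity = pd.DataFrame([asdict(d) for d in alpha_diversity(filtered)])
    dist = bray_curtis(filtered.rel_abundance)
    ordination = pcoa(dist)
    meta = filtered.metadata
    cond_labels = [
        "original" if meta.loc[s, "condition_class"] == "original"
        else f"{float(meta.loc[s, 'erh']):g}" for s in dist.index
    ]
    perm_rows = []
    for factor, labels in (
        ("condition", cond_labels),
        ("bag", [str(meta.loc[s, "bag"]) for s in dist.index]),
    ):
        if len(set(labels)) < 2:
            continue
        res = permanova(dist, labels, n_permutations=n_permutations, seed=seed,
                        factor=factor)
        perm_rows.append(asdict(res))
    erh = meta["erh"].astype(float)
    elevated = meta.index[(erh >= elevated_threshold) & erh.notna()].tolist()
    non_elevated = meta.index[(erh < elevated_threshold) | erh.isna()].tolist()
    diff = []
    if len(elevated) >= 2 and len(non_elevated) >= 2:
        diff = differential_abundance(transformed, non_elevated, elevated, alpha=alpha)
    diff_df = pd.DataFrame([asdict(d) for d in diff])
    if not diff_df.empty:
        diff_df["flags"] = diff_df["flags"].map(";".join)
        diff_df = diff_df.sort_values("q_value", kind="mergesort").reset_index(drop=True)
    return {
        "filtered": filtered,
        "transformed": transformed,
        "diversity": diversity,
        "distances": dist,
        "pcoa": ordination,
        "permanova": pd.DataFrame(perm_rows),
        "diffabund": diff_df,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _summary_text(conc, growth_df, fits, community) -> str:
    lines = ["towgrow pipeline summary", "=" * 40]
    if conc is not None:
        fung = conc[conc["target"] == "fungal"]
        lines.append("\nMean fungal concentration per condition (per mg dust):")
        key = fung["condition_class"].where(
            fung["condition_class"] == "original", fung["wet_erh"].map("{:g}%".format)
        ) if "wet_erh" in fung else fung["condition_class"]
        for cond, sub in fung.groupby(key):
            lines.append(f"  {cond:>10}: {sub['concentration_per_mg'].mean():.3e}  "
                         f"(n={len(sub)})")
        orig = fung[fung["condition_class"] == "original"]["concentration_per_mg"]
        if len(orig) >= 2 and "wet_erh" in fung:
            lines.append("\nWelch t (ln concentration) vs original dust:")
            for erh, sub in fung[fung["condition_class"] == "constant"].groupby("wet_erh"):
                res = welch_t(np.log(sub["concentration_per_mg"]), np.log(orig))
                star = " *" if res.p_value < 0.05 else ""
                lines.append(f"  {erh:g}% ERH: t={res.statistic:+.2f} "
                             f"p={res.p_value:.4f}{star}")
    if fits is not None and not fits.empty:
        lines.append("\nTime-of-wetness classification:")
        for _, r in fits.iterrows():
            lines.append(f"  {r['target']:>9} @ {r['wet_erh']:g}% ERH: {r['model']} "
                         f"(parameter {r['parameter_hours']:.2f} h, SSE {r['sse']:.4f})")
    if community is not None:
        div = community["diversity"]
        lines.append(f"\nAlpha diversity: mean richness "
                     f"{div['richness'].mean():.1f}, mean Shannon "
                     f"{div['shannon'].mean():.3f} over {len(div)} samples")
        for _, r in community["permanova"].iterrows():
            lines.append(f"PERMANOVA {r['factor']}: R²={r['r_squared']:.3f} "
                         f"p={r['p_value']:.4f}")
        diff = community["diffabund"]
        if not diff.empty:
            na = int((diff["direction"] == "group_a").sum())
            nb = int((diff["direction"] == "group_b").sum())
            lines.append(f"Differential abundance: {na} taxa more abundant at "
                         f"non-elevated vs {nb} at elevated conditions")
    return "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig, community_table: CommunityTable | None = None) -> dict:
    """Execute the configured stages and write all outputs under out_dir.

    ``community_table`` may be passed in-memory (e.g. from the generator);
    otherwise it is assembled from the abundance/totals/metadata TSVs.
    Raises with the failing stage's name; outputs written so far remain.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    inputs = {}
    conc_joined = None
    stage = "setup"
    try:
        if "quantify" in config.stages:
            stage = "quantify"
            qpcr = read_table(config.qpcr_path, "qpcr")
            standards = read_table(config.standards_path, "standards")
            inputs["qpcr"], inputs["standards"] = config.qpcr_path, config.standards_path
            conc = quantify_stage(qpcr, standards)
            write_table(conc, out / "concentrations.tsv", "concentrations")
            results["concentrations"] = conc
        if "growth" in config.stages:
            stage = "growth"
            conditions = read_table(config.conditions_path, "conditions")
            inputs["conditions"] = config.conditions_path
            conc_joined = results["concentrations"].merge(conditions, on="sample_id")
            growth_df = constant_growth_stage(conc_joined)
            if not growth_df.empty:
                write_table(growth_df, out / "growth_rates.tsv", "growth_rates")
            rates, curve, fits, _ = tow_stage(conc_joined, config.no_model_sse)
            for df, name, kind in ((rates, "tow_rates.tsv", None),
                                   (curve, "tow_curve.tsv", "tow_curve"),
                                   (fits, "tow_fit.tsv", "tow_fit")):
                if not df.empty:
                    write_table(df, out / name, kind)
            results.update(growth=growth_df, tow_rates=rates, tow_curve=curve,
                           tow_fits=fits)
        if "community" in config.stages:
            stage = "community"
            if community_table is None:
                abundance = pd.read_csv(config.abundance_path, sep="\t").set_index("sample_id")
                totals = read_table(config.totals_path, "totals").set_index("sample_id")["total_per_mg"]
                missing = [s for s in abundance.index if s not in totals.index]
                if missing:
                    raise ValidationError(
                        f"community stage: missing qPCR totals for samples {missing}"
                    )
                meta = pd.read_csv(config.metadata_path, sep="\t").set_index("sample_id")
                inputs.update(abundance=config.abundance_path,
                              totals=config.totals_path,
                              metadata=config.metadata_path)
                community_table = CommunityTable(
                    rel_abundance=abundance.astype(float), totals=totals, metadata=meta
                )
            comm = community_stage(
                community_table,
                min_prevalence=config.min_prevalence,
                alpha=config.alpha,
                n_permutations=config.n_permutations,
                seed=config.seed,
                elevated_threshold=config.threshold_erh,
            )
            write_table(comm["diversity"], out / "diversity.tsv", "diversity")
            comm["distances"].to_csv(out / "bray_curtis.tsv", sep="\t")
            coords = comm["pcoa"].coordinates.copy()
            with open(out / "pcoa.tsv", "w", encoding="utf-8") as fh:
                fh.write("# eigenvalues\t" + "\t".join(
                    f"{v:.10g}" for v in comm["pcoa"].eigenvalues) + "\n")
                fh.write("# proportion_explained\t" + "\t".join(
                    f"{v:.10g}" for v in comm["pcoa"].proportion_explained) + "\n")
                coords.to_csv(fh, sep="\t")
            if not comm["permanova"].empty:
                write_table(comm["permanova"], out / "permanova.tsv", "permanova")
            if not comm["diffabund"].empty:
                write_table(comm["diffabund"], out / "diffabund.tsv", "diffabund")
            results["community"] = comm
    except TowgrowError as exc:
        raise TowgrowError(f"stage '{stage}' failed: {exc}") from exc

    stage = "report"
    if "report" in config.stages:
        conc_for_summary = conc_joined if conc_joined is not None else results.get("concentrations")
        summary = _summary_text(
            conc_for_summary, results.get("growth"), results.get("tow_fits"),
            results.get("community"),
        )
        (out / "summary.txt").write_text(summary, encoding="utf-8")
        results["summary"] = summary
    manifest = {
        "package": "towgrow",
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "input_sha256": {k: _sha256(Path(v)) for k, v in inputs.items() if v},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str),
                                       encoding="utf-8")
    results["manifest"] = manifest
    return results
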
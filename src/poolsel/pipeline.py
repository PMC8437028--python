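"""End-to-end orchestration: filter -> test -> categorize -> cluster -> eggsim -> forecast -> distort -> linkmap.

Every stage is a pure function of (inputs, config, seeds); the run
directory collects each stage's outputs plus a machine-readable manifest
(stage-by-stage locus counts, category tallies and the headline fractions)
from which the run's summary numbers are recomputable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from poolsel import af_testing, clustering, cross_sim, distortion, filtering, forecaster, linkage, synthetic_data


def percent(numerator: float, denominator: float, ndigits: int = 0) -> float:
    """Report-level percentage, rounded to the printed precision (default whole percent)."""
    if denominator == 0:
        raise ValueError("percentage undefined for zero denominator")
    return round(100.0 * numerator / denominator, ndigits)


@dataclass
class PipelineConfig:
    counts_path: str
    survival_path: str
    out_dir: str
    linkage_map_path: str | None = None
    filter_config: filtering.FilterConfig = field(default_factory=filtering.FilterConfig)
    alpha: float = 0.05
    k: int | None = None  # None = data-driven selection
    k_range: tuple[int, int] = (2, 20)
    cluster_seed: int = 0
    egg_n_sims: int = 50
    egg_seed: int = 0
    forecast_days: tuple[int, ...] = forecaster.DEFAULT_FORECAST_DAYS
    tolerance: float = 0.10
    n_accept: int = 50
    max_attempts_per_interval: int = 10_000
    max_restarts: int = 1_000
    forecast_seed: int = 0
    n_forecast_loci: int | None = None  # cap for quick runs; None = all significant loci
    distortion_level: float = 0.95

    def validate(self) -> list[str]:
        problems = []
        if not Path(self.counts_path).exists():
            problems.append(f"counts table not found: {self.counts_path}")
        if not Path(self.survival_path).exists():
            problems.append(f"survival table not found: {self.survival_path}")
        if self.linkage_map_path and not Path(self.linkage_map_path).exists():
            problems.append(f"linkage map not found: {self.linkage_map_path}")
        if not 0 < self.alpha < 1:
            problems.append(f"alpha out of (0,1): {self.alpha}")
        if self.tolerance <= 0:
            problems.append(f"tolerance must be positive: {self.tolerance}")
        if not 0 < self.distortion_level < 1:
            problems.append(f"distortion level out of (0,1): {self.distortion_level}")
        return problems


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, writing per-stage outputs and a manifest to the run directory."""
    problems = config.validate()
    if problems:
        raise ValueError("invalid pipeline configuration:\n" + "\n".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "config": _config_dict(config)}

    counts = synthetic_data.read_counts(config.counts_path)
    survival = synthetic_data.read_survival(config.survival_path)

    # -- filter ------------------------------------------------------------
    filtered, report = filtering.apply_filters(counts, config.filter_config)
    filtered.to_csv(out / "filtered_counts.tsv", sep="\t", index=False)
    manifest["stages"]["filter"] = report.to_dict()

    per_sample_maf, per_day_maf, _flipped = filtering.compute_maf(filtered)
    per_day_maf.to_csv(out / "mean_maf_by_day.tsv", sep="\t")

    # -- test + categorize -------------------------------------------------
    tests = af_testing.test_age_effect(filtered, alpha=config.alpha)
    categories = af_testing.categorize_all(per_sample_maf, tests, alpha=config.alpha)
    endpoints = endpoint_change(per_sample_maf, tests, alpha=config.alpha)
    locus_table = tests.join(categories, how="left").join(endpoints, how="left")
    locus_table.to_csv(out / "locus_tests.tsv", sep="\t")
    n_loci = len(tests)
    sig_loci = tests.index[tests["significant"]]
    cat_counts = categories.loc[categories.index.isin(sig_loci), "category"].value_counts().to_dict()
    n_endpoint = int(endpoints.loc[endpoints.index.isin(sig_loci), "endpoint_significant"].sum())
    manifest["stages"]["test"] = {
        "n_loci_tested": n_loci,
        "n_significant": int(len(sig_loci)),
        "pct_significant": percent(len(sig_loci), n_loci) if n_loci else None,
        "category_counts": cat_counts,
        "n_endpoint_significant": n_endpoint,
        "pct_endpoint_significant": percent(n_endpoint, len(sig_loci)) if len(sig_loci) else None,
    }

    # -- cluster -----------------------------------------------------------
    manifest["stages"]["cluster"] = {"n_input": int(len(sig_loci))}
    clust = None
    if len(sig_loci) >= 2:
        delta, excluded = clustering.build_delta_matrix(per_day_maf.loc[per_day_maf.index.isin(sig_loci)])
        k = config.k
        votes: dict = {}
        degenerate = False
        if k is None:
            k_max = min(config.k_range[1], max(2, len(delta) - 1))
            k, votes, degenerate = clustering.select_k(
                delta.to_numpy(), range(config.k_range[0], k_max + 1), seed=config.cluster_seed
            )
        clust = clustering.cluster_trajectories(delta, max(k, 1), seed=config.cluster_seed)
        clust.assignments.to_frame().to_csv(out / "cluster_assignments.tsv", sep="\t")
        manifest["stages"]["cluster"].update(
            {
                "k": clust.k,
                "sizes": clust.sizes.tolist(),
                "n_excluded_missing": len(excluded),
                "degenerate": degenerate,
                "index_votes": votes.get("votes", {}),
            }
        )

    # -- eggsim ------------------------------------------------------------
    egg_maf = per_sample_maf[per_sample_maf["day"] == 0].groupby("locus_id")["maf"].mean()
    egg_table = cross_sim.egg_genotype_table(
        egg_maf[egg_maf.index.isin(sig_loci)], n_sims=config.egg_n_sims, seed=config.egg_seed
    )
    egg_table.to_csv(out / "egg_genotypes.tsv", sep="\t")
    manifest["stages"]["eggsim"] = {
        "n_loci": int(len(egg_table)),
        "n_sims": config.egg_n_sims,
        "n_families": 95 if len(egg_table) == 0 else int(5 * 19),
        "n_monomorphic": int(egg_table["monomorphic"].sum()) if len(egg_table) else 0,
    }

    # -- forecast ----------------------------------------------------------
    surv_by_day = survival.groupby("day")["cum_survival"].mean()
    targets = [l for l in sig_loci if l in egg_table.index and not egg_table.loc[l, "monomorphic"]]
    if config.n_forecast_loci is not None:
        targets = targets[: config.n_forecast_loci]
    summaries, infeasible = [], []
    rng = np.random.default_rng(config.forecast_seed)
    for locus in targets:
        cons = forecaster.constraints_from_tables(
            per_day_maf.loc[locus], surv_by_day, days=config.forecast_days, tolerance=config.tolerance
        )
        init = egg_table.loc[locus, ["f_AA", "f_AB", "f_BB"]].to_numpy(dtype=float)
        init = init / init.sum()
        ens = forecaster.forecast_locus(
            init,
            cons,
            n_accept=config.n_accept,
            max_attempts_per_interval=config.max_attempts_per_interval,
            max_restarts=config.max_restarts,
            seed=rng,
            locus_id=str(locus),
        )
        if ens.infeasible or ens.n_accepted < 2:
            infeasible.append({"locus_id": str(locus), **ens.diagnostics})
            continue
        summaries.append(forecaster.summarize_ensemble(ens))
    ensemble_summary = pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
    ensemble_summary.to_csv(out / "forecast_summary.tsv", sep="\t", index=False)
    n_days_per_traj = len(config.forecast_days) + 1
    manifest["stages"]["forecast"] = {
        "n_loci_targeted": len(targets),
        "n_loci_forecast": len(summaries),
        "n_infeasible": len(infeasible),
        "infeasible": infeasible,
        "n_accept": config.n_accept,
        "n_timepoints": n_days_per_traj,
        "n_simulation_records": forecaster.n_simulation_records(
            len(summaries), config.n_accept, n_days_per_traj
        ),
    }

    # -- distort -----------------------------------------------------------
    manifest["stages"]["distort"] = {}
    if len(ensemble_summary):
        final_day = max(config.forecast_days)
        spat = ensemble_summary[ensemble_summary["day"] == final_day].set_index("locus_id")
        spat_maf = per_day_maf[final_day]
        try:
            records = distortion.build_records(
                spat[["f_AA", "f_AB", "f_BB"]], egg_table[["f_AA", "f_AB", "f_BB"]], spat_maf, egg_maf
            )
            comparison = distortion.fit_distortion_models(records)
            flagged = distortion.flag_outliers(comparison, records, level=config.distortion_level)
            classes = distortion.classify_distortions(flagged)
            flagged.to_csv(out / "distortion_records.tsv", sep="\t", index=False)
            classes.to_csv(out / "distortion_classes.tsv", sep="\t", index=False)
            strata = _stratified_class_counts(classes)
            manifest["stages"]["distort"] = {
                "selected_model": comparison.selected,
                "n_outlier_genotypes": int(flagged["outlier"].sum()),
                "n_outlier_loci": int(len(classes)),
                "strata": strata,
            }
        except ValueError as exc:
            manifest["stages"]["distort"] = {"skipped": str(exc)}

    # -- linkmap -----------------------------------------------------------
    if config.linkage_map_path:
        lmap = linkage.read_linkage_map(config.linkage_map_path)
        snps = filtered[["locus_id", "scaffold", "position"]].drop_duplicates("locus_id")
        assignments = linkage.bridge_to_map(snps, lmap)
        assignments.to_csv(out / "linkage_assignments.tsv", sep="\t", index=False)
        clusters = clust.assignments if clust is not None else None
        dists = linkage.intermarker_distances(assignments, clusters=clusters)
        dists.to_csv(out / "intermarker_distances.tsv", sep="\t", index=False)
        n_mapped = int((assignments["reason"] == "").sum())
        manifest["stages"]["linkmap"] = {
            "n_snps": int(len(assignments)),
            "n_mapped": n_mapped,
            "pct_mapped": percent(n_mapped, len(assignments)) if len(assignments) else None,
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonable)
    return manifest


def endpoint_change(per_sample_maf: pd.DataFrame, tests: pd.DataFrame, alpha: float = 0.05, min_day: int = 2) -> pd.DataFrame:
    """Per-locus significance of the overall first-vs-last replicated day change.

    Uses the same Tukey all-pairs family as the sequential categorization
    but reads off the endpoint pair, answering whether a locus's allele
    frequency ended development distorted relative to where it started.
    """
    from scipy import stats

    rows = []
    replicated = per_sample_maf[per_sample_maf["day"] >= min_day]
    for locus, grp in replicated.groupby("locus_id", sort=True):
        if locus not in tests.index or not bool(tests.loc[locus, "significant"]):
            rows.append({"locus_id": locus, "endpoint_significant": False, "endpoint_direction": ""})
            continue
        days = sorted(grp["day"].unique())
        groups = [grp.loc[grp["day"] == d, "maf"].to_numpy() for d in days]
        means = [g.mean() for g in groups]
        if all(np.ptp(g) == 0.0 for g in groups):
            sig = means[-1] != means[0]
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sig = bool(stats.tukey_hsd(*groups).pvalue[0, -1] < alpha)
        rows.append(
            {
                "locus_id": locus,
                "endpoint_significant": sig,
                "endpoint_direction": "up" if means[-1] > means[0] else "down",
            }
        )
    return pd.DataFrame(rows).set_index("locus_id")


def _stratified_class_counts(classes: pd.DataFrame) -> dict:
    strata: dict = {}
    for stratum, grp in classes.groupby("stratum"):
        counts = grp["class"].value_counts().to_dict()
        total = int(len(grp))
        focal = "fixation_skew" if stratum == "low" else "heterozygote_excess"
        strata[stratum] = {
            "n_outlier_loci": total,
            "class_counts": counts,
            "pct_focal_class": percent(counts.get(focal, 0), total) if total else None,
        }
    return strata


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["filter_config"] = asdict(config.filter_config)
    return d


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
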
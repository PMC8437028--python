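"""Genotype-distortion analysis at the settled (spat) stage.

Reconstructed spat-stage genotype frequencies are compared with the
genotype frequencies expected from allele frequencies alone.  Two linear
formulations are fitted per genotype class (AA, AB, BB):

* model ``egg``  — simulated spat frequency regressed on the fertilized
  egg-pool genotype frequency (change relative to the starting composition);
* model ``hwe``  — simulated spat frequency regressed on the Hardy-Weinberg
  expectation computed from the spat-pool MAF (departure from HWE at the
  same stage).

Goodness of fit is compared by F-statistics and AIC/BIC; genotypes falling
outside the selected model's two-sided prediction interval are flagged as
significantly distorted.  Flagged loci are classified by the sign pattern
of their residuals:

* ``fixation_skew``       — AA up, AB/BB down: purging of a rare deleterious
  allele (genetic load);
* ``heterozygote_excess`` — AB up, AA/BB down: apparent heterozygote
  advantage;
* ``other``               — any other pattern.

Counts are stratified by initial (egg-pool) MAF around a reporting
threshold of 20%, where the two signatures concentrate on opposite sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from poolsel import hw

GENOTYPES = hw.GENOTYPES
MODEL_NAMES = ("egg", "hwe")


@dataclass
class ModelComparison:
    per_genotype: pd.DataFrame  # model x genotype fit statistics
    selected: str  # "egg" or "hwe"
    fits: dict  # (model, genotype) -> fitted OLS results
    skipped: list


def build_records(
    spat_states: pd.DataFrame,
    egg_states: pd.DataFrame,
    spat_maf: pd.Series,
    egg_maf: pd.Series,
) -> pd.DataFrame:
    """Long-format per-(locus, genotype) records for the distortion models.

    ``spat_states`` and ``egg_states`` are locus-indexed tables with columns
    f_AA/f_AB/f_BB (reconstructed spat-stage means and egg-pool estimates);
    ``spat_maf`` and ``egg_maf`` are locus-indexed frequency series.
    """
    loci = spat_states.index.intersection(egg_states.index)
    rows = []
    for locus in loci:
        hwe_state = hw.hwe_expected(float(spat_maf[locus]))
        for gi, g in enumerate(GENOTYPES):
            sim = float(spat_states.loc[locus, f"f_{g}"])
            exp = float(hwe_state[gi])
            rows.append(
                {
                    "locus_id": locus,
                    "genotype": g,
                    "sim_freq": sim,
                    "hwe_freq": exp,
                    "egg_freq": float(egg_states.loc[locus, f"f_{g}"]),
                    "residual": sim - exp,
                    "egg_maf": float(egg_maf[locus]),
                }
            )
    return pd.DataFrame(rows)


def fit_distortion_models(records: pd.DataFrame) -> ModelComparison:
    """Fit both linear formulations per genotype class and select one.

    Selection favours the formulation with the better (lower) summed
    information-criterion scores across genotype classes; a model with a
    zero-variance predictor in any class is skipped with a diagnostic.
    """
    n_loci = records["locus_id"].nunique()
    if n_loci < 10:
        raise ValueError(f"distortion models need >= 10 loci, got {n_loci}")
    predictor = {"egg": "egg_freq", "hwe": "hwe_freq"}
    stats_rows, fits, skipped = [], {}, []
    for model in MODEL_NAMES:
        for g in GENOTYPES:
            sub = records[records["genotype"] == g]
            x = sub[predictor[model]].to_numpy()
            if np.ptp(x) == 0.0:
                skipped.append((model, g, "zero-variance predictor"))
                continue
            res = sm.OLS(sub["sim_freq"].to_numpy(), sm.add_constant(x)).fit()
            fits[(model, g)] = res
            stats_rows.append(
                {
                    "model": model,
                    "genotype": g,
                    "f_stat": float(res.fvalue),
                    "f_pvalue": float(res.f_pvalue),
                    "aic": float(res.aic),
                    "bic": float(res.bic),
                    "r2": float(res.rsquared),
                }
            )
    per_genotype = pd.DataFrame(stats_rows)
    totals = {}
    for model in MODEL_NAMES:
        sub = per_genotype[per_genotype["model"] == model]
        if len(sub) < len(GENOTYPES):
            totals[model] = np.inf  # incomplete model cannot be selected
        else:
            totals[model] = float(sub["aic"].sum() + sub["bic"].sum())
    if all(np.isinf(v) for v in totals.values()):
        raise ValueError(f"no complete model could be fitted: {skipped}")
    selected = min(totals, key=totals.get)
    return ModelComparison(per_genotype=per_genotype, selected=selected, fits=fits, skipped=skipped)


def flag_outliers(comparison: ModelComparison, records: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Flag records outside the selected model's two-sided prediction interval."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    predictor = {"egg": "egg_freq", "hwe": "hwe_freq"}[comparison.selected]
    out = records.copy()
    out["outlier"] = False
    out["pi_low"] = np.nan
    out["pi_high"] = np.nan
    for g in GENOTYPES:
        fit = comparison.fits.get((comparison.selected, g))
        if fit is None:
            continue
        mask = out["genotype"] == g
        x = out.loc[mask, predictor].to_numpy()
        pred = fit.get_prediction(sm.add_constant(x, has_constant="add"))
        frame = pred.summary_frame(alpha=1.0 - level)
        lo = frame["obs_ci_lower"].to_numpy()
        hi = frame["obs_ci_upper"].to_numpy()
        y = out.loc[mask, "sim_freq"].to_numpy()
        out.loc[mask, "pi_low"] = lo
        out.loc[mask, "pi_high"] = hi
        out.loc[mask, "outlier"] = (y < lo) | (y > hi)
    return out


def classify_distortions(flagged: pd.DataFrame, maf_threshold: float = 0.20) -> pd.DataFrame:
    """Classify each locus with flagged genotypes by its residual sign pattern.

    Returns a per-locus table with the class, the number of flagged
    genotypes, and the initial-MAF stratum (low: egg MAF < threshold).
    """
    rows = []
    for locus, grp in flagged.groupby("locus_id", sort=True):
        if not grp["outlier"].any():
            continue
        res = {g: float(grp.loc[grp["genotype"] == g, "residual"].iloc[0]) for g in GENOTYPES}
        if res["AA"] > 0 and res["AB"] <= 0 and res["BB"] <= 0:
            cls = "fixation_skew"
        elif res["AB"] > 0 and res["AA"] <= 0 and res["BB"] <= 0:
            cls = "heterozygote_excess"
        else:
            cls = "other"
        egg_maf = float(grp["egg_maf"].iloc[0])
        rows.append(
            {
                "locus_id": locus,
                "class": cls,
                "n_flagged_genotypes": int(grp["outlier"].sum()),
                "egg_maf": egg_maf,
                "stratum": "low" if egg_maf < maf_threshold else "high",
            }
        )
    return pd.DataFrame(rows)
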
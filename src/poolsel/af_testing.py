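"""Per-locus tests of allele-frequency change over development.

Two layers:

* :func:`test_age_effect` — for every locus, a binomial generalized linear
  model of minor vs. major read counts on sampling day treated as a
  multi-level factor.  Significance of the age factor comes from the
  likelihood-ratio (deviance) test against the intercept-only model;
  p-values are Benjamini-Hochberg adjusted across loci and called
  significant at q < 0.05.  Day is a factor, not a covariate, because
  allele-frequency change during larval development is typically abrupt
  and non-monotone.

* :func:`categorize_locus` — for loci with a significant age effect, the
  shape of change is classified from replicate-level allele frequencies by
  one-way ANOVA across days followed by Tukey's studentized-range pairwise
  comparisons.  Only sequential-day pairs feed the classification:

  - ``G``  (gradual): no significant change between any consecutive days;
  - ``UD`` (uni-directional): significant consecutive-day change(s), all in
    one direction;
  - ``BD`` (bi-directional): two or more significant consecutive-day changes
    in opposing directions.

  Day 0 is a single unreplicated egg-pool sample, so sequential comparisons
  start at the first replicated day; day 0 still enters the GLM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05


@dataclass
class ChangeCategory:
    locus_id: str
    intervals: list = field(default_factory=list)  # (day_from, day_to, direction, significant)
    category: str = "NS"
    anova_p: float = float("nan")
    degenerate: bool = False


def _locus_age_pvalue(days: np.ndarray, n_minor: np.ndarray, n_major: np.ndarray) -> tuple[float, float, int]:
    """Deviance test of the day factor in a binomial GLM for one locus.

    Returns (deviance, p_value, df).
    """
    endog = np.column_stack([n_minor, n_major]).astype(float)
    levels = np.unique(days)
    exog_full = (days[:, None] == levels[None, :]).astype(float)  # cell-means coding
    exog_null = np.ones((len(days), 1))
    fam = sm.families.Binomial()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.GLM(endog, exog_full, family=fam).fit()
        null = sm.GLM(endog, exog_null, family=fam).fit()
    deviance = float(null.deviance - full.deviance)
    df = len(levels) - 1
    return deviance, float(stats.chi2.sf(deviance, df)), df


def test_age_effect(counts: pd.DataFrame, alpha: float = ALPHA) -> pd.DataFrame:
    """Test every locus for allele-frequency change across sampling days.

    Parameters
    ----------
    counts
        Filtered long-format count table with columns locus_id, day,
        n_major, n_minor (one row per sample).
    alpha
        False-discovery rate for the Benjamini-Hochberg adjustment.

    Returns
    -------
    DataFrame indexed by locus with columns deviance, df, p_value, q_bh,
    significant.  Loci with a single day of data are excluded with a
    warning rather than aborting the run.
    """
    results = []
    skipped = []
    for locus, grp in counts.groupby("locus_id", sort=True):
        days = grp["day"].to_numpy()
        if len(np.unique(days)) < 2:
            skipped.append(locus)
            continue
        dev, p, df = _locus_age_pvalue(days, grp["n_minor"].to_numpy(), grp["n_major"].to_numpy())
        results.append({"locus_id": locus, "deviance": dev, "df": df, "p_value": p})
    if skipped:
        warnings.warn(f"excluded {len(skipped)} loci with a single day of data: {skipped[:5]}...")
    if not results:
        raise ValueError("no locus had two or more days of data")
    res = pd.DataFrame(results).set_index("locus_id")
    _, q, _, _ = multipletests(res["p_value"], method="fdr_bh")
    res["q_bh"] = q
    res["significant"] = res["q_bh"] < alpha
    return res


def categorize_locus(
    maf_by_day: dict[int, np.ndarray],
    overall_significant: bool = True,
    locus_id: str = "",
    alpha: float = ALPHA,
) -> ChangeCategory:
    """Classify one locus's trajectory shape from replicate allele frequencies.

    ``maf_by_day`` maps each (replicated) sampling day to its per-replicate
    minor-allele frequencies.  A non-significant locus is returned as ``NS``
    without running the comparisons.  With zero within-day variance
    everywhere and unequal means the studentized range is undefined; such
    loci are flagged degenerate and unequal sequential means are treated as
    significant changes, with a warning.
    """
    cat = ChangeCategory(locus_id=locus_id)
    if not overall_significant:
        return cat
    days = sorted(maf_by_day)
    if len(days) < 2:
        raise ValueError("categorization needs at least two replicated days")
    groups = [np.asarray(maf_by_day[d], dtype=float) for d in days]
    if any(len(g) < 2 for g in groups):
        raise ValueError("categorization needs >= 2 replicates at every compared day")
    means = [g.mean() for g in groups]

    if all(np.ptp(g) == 0.0 for g in groups):  # no within-day variance anywhere
        cat.degenerate = True
        if len(set(means)) > 1:
            warnings.warn(f"locus {locus_id}: zero within-day variance with unequal means; "
                          "treating unequal sequential means as significant changes")
        seq_sig = [means[i + 1] != means[i] for i in range(len(days) - 1)]
    else:
        cat.anova_p = float(stats.f_oneway(*groups).pvalue)
        tukey = stats.tukey_hsd(*groups)
        seq_sig = [bool(tukey.pvalue[i, i + 1] < alpha) for i in range(len(days) - 1)]

    for i in range(len(days) - 1):
        direction = "up" if means[i + 1] > means[i] else "down"
        cat.intervals.append((days[i], days[i + 1], direction, seq_sig[i]))

    sig_dirs = [d for (_, _, d, s) in cat.intervals if s]
    if not sig_dirs:
        cat.category = "G"
    elif len(set(sig_dirs)) == 1:
        cat.category = "UD"
    else:
        cat.category = "BD"
    return cat


def categorize_all(
    per_sample_maf: pd.DataFrame,
    test_results: pd.DataFrame,
    min_day: int = 2,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Categorize every significant locus; returns a per-locus summary table.

    ``per_sample_maf`` is the long table from :func:`poolsel.filtering.compute_maf`;
    days earlier than ``min_day`` (the unreplicated egg pool) are excluded
    from the sequential comparisons.
    """
    rows = []
    replicated = per_sample_maf[per_sample_maf["day"] >= min_day]
    for locus, grp in replicated.groupby("locus_id", sort=True):
        if locus not in test_results.index:
            continue
        sig = bool(test_results.loc[locus, "significant"])
        maf_by_day = {int(d): sub["maf"].to_numpy() for d, sub in grp.groupby("day")}
        cat = categorize_locus(maf_by_day, overall_significant=sig, locus_id=str(locus), alpha=alpha)
        rows.append(
            {
                "locus_id": locus,
                "category": cat.category,
                "anova_p": cat.anova_p,
                "degenerate": cat.degenerate,
                "n_significant_intervals": sum(1 for iv in cat.intervals if iv[3]),
                "intervals": ";".join(f"{a}->{b}:{d}{'*' if s else ''}" for a, b, d, s in cat.intervals),
            }
        )
    return pd.DataFrame(rows).set_index("locus_id")
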
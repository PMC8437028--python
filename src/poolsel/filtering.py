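"""Count-level filters producing the analysis-ready SNP set.

The pipeline entry point is a long-format table of pooled read counts of two
alleles per locus x replicate x day.  Filters are applied in a fixed order:

1. depth        — drop samples with total depth < min_depth or > max_depth
                  (boundaries retained);
2. biallelic    — drop loci with reads of a third allele (column ``n_other``,
                  when present; a pass-through otherwise);
3. one-per-tag  — drop all SNPs on sequencing tags carrying more than one SNP
                  (mapping ambiguity produces spurious nearby polymorphisms);
4. presence     — keep loci observed in at least ``min_replicates_per_timepoint``
                  replicates at every replicated (day > 0) time point, and at
                  least once at day 0;
5. egg MAF      — keep loci whose minor-allele frequency in the day-0
                  fertilized-egg pool exceeds ``min_egg_maf`` (strict).

The "minor" allele is designated once per locus as the allele with the lower
mean frequency across all of that locus's samples, then held fixed: at
individual time points the designated minor allele may exceed 0.5 and such
values are preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd


@dataclass
class FilterConfig:
    min_depth: int = 50
    max_depth: int = 1000
    max_alleles: int = 2
    min_replicates_per_timepoint: int = 3
    min_egg_maf: float = 0.01
    one_snp_per_tag: bool = True

    def __post_init__(self) -> None:
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must be <= max_depth")
        if not 0.0 <= self.min_egg_maf < 0.5:
            raise ValueError("min_egg_maf must lie in [0, 0.5)")


@dataclass
class FilterReport:
    """Per-rule removal counts; removals are expressed in the unit each rule acts on."""

    input_samples: int = 0
    input_loci: int = 0
    samples_removed_depth: int = 0
    loci_removed_depth: int = 0  # loci whose every sample failed the depth rule
    loci_removed_multiallelic: int = 0
    loci_removed_multi_snp_tag: int = 0
    loci_removed_presence: int = 0
    loci_removed_egg_maf: int = 0
    output_samples: int = 0
    output_loci: int = 0
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def apply_filters(table: pd.DataFrame, config: FilterConfig | None = None) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the fixed filter cascade; returns the surviving table and a report.

    Idempotent: re-applying to its own output changes nothing.
    """
    if config is None:
        config = FilterConfig()
    if table.empty:
        raise ValueError("count table is empty")
    if not (table["day"] == 0).any():
        raise ValueError("count table has no day-0 (egg pool) samples; egg-MAF filter cannot run")
    report = FilterReport(input_samples=len(table), input_loci=table["locus_id"].nunique())
    df = table.copy()

    # 1. depth (sample-level: one locus x replicate x day observation)
    depth = df["n_major"] + df["n_minor"]
    if "n_other" in df.columns:
        depth = depth + df["n_other"]
    keep = (depth >= config.min_depth) & (depth <= config.max_depth)
    report.samples_removed_depth = int((~keep).sum())
    df = df[keep]
    report.loci_removed_depth = report.input_loci - df["locus_id"].nunique()

    # 2. biallelic
    if "n_other" in df.columns:
        bad = df.loc[df["n_other"] > 0, "locus_id"].unique()
        report.loci_removed_multiallelic = len(bad)
        df = df[~df["locus_id"].isin(bad)].drop(columns=["n_other"])
    else:
        report.notes.append("input already biallelic; multi-allele rule is a pass-through")

    # 3. one SNP per tag
    if config.one_snp_per_tag and "tag_id" in df.columns:
        per_tag = df.groupby("tag_id")["locus_id"].nunique()
        bad_tags = per_tag.index[per_tag > 1]
        bad = df.loc[df["tag_id"].isin(bad_tags), "locus_id"].unique()
        report.loci_removed_multi_snp_tag = len(bad)
        df = df[~df["locus_id"].isin(bad)]
    elif config.one_snp_per_tag:
        report.notes.append("no tag_id column; one-SNP-per-tag rule is a pass-through")

    # 4. presence: >= min replicates at every day > 0, and a day-0 sample
    def _present(group: pd.DataFrame) -> bool:
        by_day = group.groupby("day")["replicate"].nunique()
        days = set(by_day.index)
        all_days = set(df["day"].unique())
        if days != all_days:
            return False
        return bool(all(by_day[d] >= config.min_replicates_per_timepoint for d in days if d != 0))

    if not df.empty:
        present = df.groupby("locus_id", sort=False).apply(_present, include_groups=False)
        bad = present.index[~present]
        report.loci_removed_presence = len(bad)
        df = df[~df["locus_id"].isin(bad)]

    # 5. egg-pool MAF (strict >)
    if not df.empty:
        sample_maf, _, _ = compute_maf(df)
        egg = sample_maf[sample_maf["day"] == 0].groupby("locus_id")["maf"].mean()
        bad = egg.index[egg <= config.min_egg_maf]
        report.loci_removed_egg_maf = len(bad)
        df = df[~df["locus_id"].isin(bad)]

    report.output_samples = len(df)
    report.output_loci = df["locus_id"].nunique()
    return df.reset_index(drop=True), report


def compute_maf(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Per-sample and per-day-mean minor-allele frequencies.

    The minor designation is fixed globally per locus: if allele 2
    (``n_minor`` column) averages above 0.5 across all samples of a locus,
    the designation flips for every sample of that locus.  Returns
    ``(per_sample, per_day_mean, flipped)`` where ``per_sample`` has columns
    locus_id/replicate/day/maf, ``per_day_mean`` is a locus x day table of
    replicate means, and ``flipped`` marks loci whose alleles were swapped.
    Zero-depth samples are excluded from means and reported via a warning.
    """
    df = table.copy()
    total = df["n_major"] + df["n_minor"]
    zero = total == 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} zero-depth samples from MAF computation")
        df = df[~zero]
        total = total[~zero]
    df["maf"] = df["n_minor"] / total
    global_mean = df.groupby("locus_id")["maf"].mean()
    flipped = global_mean > 0.5
    flip_loci = set(flipped.index[flipped])
    if flip_loci:
        mask = df["locus_id"].isin(flip_loci)
        df.loc[mask, "maf"] = 1.0 - df.loc[mask, "maf"]
    per_sample = df[["locus_id", "replicate", "day", "maf"]].reset_index(drop=True)
    per_day = per_sample.pivot_table(index="locus_id", columns="day", values="maf", aggfunc="mean")
    return per_sample, per_day, flipped
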
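"""Bridging SNPs to linkage-group positions via shared genomic scaffolds.

SNPs called against a draft genome carry scaffold coordinates, not map
positions.  A previously published linkage map provides (scaffold, linkage
group, cM) anchors: each SNP sharing a scaffold with a mapped marker is
assigned the cM position of the nearest marker on that scaffold (by
base-pair distance, ties toward the smaller coordinate).  Scaffolds absent
from the map, or anchored to more than one linkage group, are omitted with
a reason code — omissions are data, not errors.

Inter-marker distances summarize how densely assigned SNPs cover the map:
within each linkage group the assigned positions are sorted and adjacent
gaps averaged; the group-level statistic is the mean (and s.d.) of these
per-LG means.  Restricting to one trajectory cluster at a time tests
whether loci sharing a temporal pattern also share genomic neighbourhoods.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MAP_COLUMNS = ["scaffold", "lg", "cM", "marker_bp"]


def read_linkage_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(MAP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"linkage map {path} missing columns: {sorted(missing)}")
    if (df["cM"] < 0).any():
        raise ValueError("cM positions must be non-negative")
    if df.duplicated(["scaffold", "marker_bp"]).any():
        raise ValueError("linkage map has duplicate (scaffold, marker_bp) entries")
    return df


def bridge_to_map(snps: pd.DataFrame, map_entries: pd.DataFrame) -> pd.DataFrame:
    """Assign each SNP a linkage position, or an omission reason.

    ``snps`` needs columns locus_id, scaffold, position.  Returns one row
    per SNP with lg/cM filled for assignments and ``reason`` in
    {"scaffold_unmapped", "multi_lg_scaffold"} for omissions.  Assignments
    are independent of input order.
    """
    lg_per_scaffold = map_entries.groupby("scaffold")["lg"].nunique()
    multi_lg = set(lg_per_scaffold.index[lg_per_scaffold > 1])
    by_scaffold = {s: g for s, g in map_entries.groupby("scaffold")}
    rows = []
    for _, snp in snps.iterrows():
        rec = {"locus_id": snp["locus_id"], "scaffold": snp["scaffold"], "position": snp["position"],
               "lg": None, "cM": np.nan, "reason": ""}
        scaffold = snp["scaffold"]
        if scaffold not in by_scaffold:
            rec["reason"] = "scaffold_unmapped"
        elif scaffold in multi_lg:
            rec["reason"] = "multi_lg_scaffold"
        else:
            markers = by_scaffold[scaffold]
            dist = (markers["marker_bp"] - snp["position"]).abs()
            # nearest marker by bp; ties toward the smaller coordinate
            order = markers.assign(_d=dist).sort_values(["_d", "marker_bp"], kind="stable")
            best = order.iloc[0]
            rec["lg"] = best["lg"]
            rec["cM"] = float(best["cM"])
        rows.append(rec)
    return pd.DataFrame(rows)


def intermarker_distances(
    assignments: pd.DataFrame,
    clusters: pd.Series | None = None,
    all_pairs: bool = False,
) -> pd.DataFrame:
    """Mean adjacent inter-marker distance in cM, overall or per cluster.

    For each group (all assigned SNPs, or each cluster when ``clusters``
    maps locus_id to a label): within every LG holding >= 2 markers, sort
    positions and average adjacent gaps (or all pairwise distances with
    ``all_pairs``); report the mean and s.d. of those per-LG means across
    LGs.  Groups with no LG holding two markers are reported with NaNs.
    """
    assigned = assignments[assignments["reason"] == ""].copy()
    if clusters is None:
        groups = {"all": assigned}
    else:
        labelled = assigned.merge(
            clusters.rename("cluster"), left_on="locus_id", right_index=True, how="inner"
        )
        groups = {f"cluster_{c}": g for c, g in labelled.groupby("cluster")}
    rows = []
    for name, grp in groups.items():
        lg_means = []
        for _lg, sub in grp.groupby("lg"):
            pos = np.sort(sub["cM"].to_numpy())
            if len(pos) < 2:
                continue
            if all_pairs:
                gaps = np.abs(pos[:, None] - pos[None, :])[np.triu_indices(len(pos), k=1)]
            else:
                gaps = np.diff(pos)
            lg_means.append(gaps.mean())
        rows.append(
            {
                "group": name,
                "n_markers": len(grp),
                "n_lgs_used": len(lg_means),
                "mean_cm": float(np.mean(lg_means)) if lg_means else np.nan,
                "sd_cm": float(np.std(lg_means, ddof=1)) if len(lg_means) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
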
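"""Barcode counts to per-variant activity scores.

The forskolin condition induces the reporter maximally and receptor-
independently, so a barcode's forskolin reads measure its cellular
abundance. Scoring proceeds per replicate:

1. keep barcodes present in both forskolin replicates with mean forskolin
   RPM in [0.2, 10); missing drug-condition entries become zero counts;
2. add a depth-scaled pseudocount p_cr = N_cr / min(N) to every count and
   normalise each column to its depth including pseudocounts,
   q = (n + p) / (N + B p);
3. divide by the paired forskolin value, r = q_drug / q_forskolin;
4. average a variant's barcodes, divide by the mean over frameshift
   variants (so frameshift activity averages exactly 1), then average the
   two replicates, propagating standard deviations as
   sd = sqrt(sd1^2 + sd2^2) / 2.

Activity is therefore a unitless ratio to the frameshift (null) mean.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RPM_MIN = 0.2
RPM_MAX = 10.0
FORSKOLIN = "forskolin"


def pivot_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Long (barcode, condition, replicate, count) to wide barcode x (c, r)."""
    wide = counts.pivot_table(
        index="barcode", columns=["condition", "replicate"], values="count",
        aggfunc="sum",
    )
    return wide


def filter_barcodes(
    counts: pd.DataFrame, rpm_min: float = RPM_MIN, rpm_max: float = RPM_MAX
) -> tuple[pd.DataFrame, dict]:
    """Abundance filter on raw forskolin counts.

    Accepts the long count table; returns the wide filtered table (NaN for
    barcodes unobserved in a drug column replaced by 0) plus a summary.
    RPM thresholds apply to raw counts, before pseudocounts: a barcode is
    kept iff it has >0 reads in both forskolin replicates and
    rpm_min <= mean forskolin RPM < rpm_max.
    """
    wide = counts if isinstance(counts.columns, pd.MultiIndex) else pivot_counts(counts)
    if FORSKOLIN not in wide.columns.get_level_values(0):
        raise ValueError("count table lacks the forskolin condition")
    fsk = wide[FORSKOLIN]
    if fsk.shape[1] < 2:
        raise ValueError("both forskolin replicates are required")

    fsk = fsk.fillna(0.0)
    depths = fsk.sum(axis=0)
    rpm = fsk / depths * 1e6
    present = (fsk > 0).all(axis=1)
    mean_rpm = rpm.mean(axis=1)
    keep = present & (mean_rpm >= rpm_min) & (mean_rpm < rpm_max)

    filtered = wide.loc[keep].fillna(0.0)
    summary = {
        "n_input": int(len(wide)),
        "n_retained": int(keep.sum()),
        "n_absent_forskolin": int((~present).sum()),
        "n_low_rpm": int((present & (mean_rpm < rpm_min)).sum()),
        "n_high_rpm": int((present & (mean_rpm >= rpm_max)).sum()),
    }
    return filtered, summary


def normalize(filtered: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pseudocounted, depth-normalised abundances and forskolin ratios.

    Returns ``(q, ratios)``: q_bcr = (n + p_cr) / (N_cr + B p_cr) with
    p_cr = N_cr / min over all columns of N, B the retained barcode count;
    ratios has one column per drug (condition, replicate), each divided by
    the same-replicate forskolin column.
    """
    depths = filtered.sum(axis=0)
    if (depths <= 0).any():
        bad = depths[depths <= 0].index.tolist()
        raise ValueError(f"zero total depth in column(s) {bad}")
    pseudo = depths / depths.min()
    B = len(filtered)
    q = (filtered + pseudo) / (depths + B * pseudo)

    drug_cols = [c for c in q.columns if c[0] != FORSKOLIN]
    ratios = {}
    for cond, rep in drug_cols:
        if (FORSKOLIN, rep) not in q.columns:
            raise ValueError(f"no forskolin replicate paired with replicate {rep}")
        ratios[(cond, rep)] = q[(cond, rep)] / q[(FORSKOLIN, rep)]
    out = pd.DataFrame(ratios)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["condition", "replicate"])
    return q, out


def score_variants(
    ratios: pd.DataFrame, barcode_map: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Combine barcode ratios into per-variant activity scores.

    ``barcode_map`` needs columns barcode, variant, call_class (each
    frameshift barcode is its own variant). Per condition and replicate the
    variant mean ratio is divided by the mean over frameshift variants; the
    two replicates are then averaged. Reported per (variant, condition):

    * activity — replicate-averaged ratio to the frameshift mean,
    * sd       — sqrt(sd1^2 + sd2^2)/2 over barcodes within replicates,
    * sem, cv  — from barcode-level replicate-averaged values,
    * n_barcodes.
    """
    bmap = barcode_map[["barcode", "variant", "call_class"]]
    usable = bmap[bmap["call_class"].isin(["missense", "frameshift", "synonymous", "wildtype"])]
    meta = usable.drop_duplicates("barcode").set_index("barcode")
    common = meta.index.intersection(ratios.index)
    if common.empty:
        raise ValueError("no overlap between barcode map and count table")
    n_lost = len(meta) - len(common)
    meta = meta.loc[common]
    rmat = ratios.loc[common]

    conditions = sorted({c[0] for c in rmat.columns})
    replicates = sorted({c[1] for c in rmat.columns})

    rows = []
    rel_barcode_frames = []
    for cond in conditions:
        rel_by_rep = {}
        for rep in replicates:
            ratio = rmat[(cond, rep)]
            # frameshift denominator: mean over frameshift variant means
            fs_mask = meta["call_class"] == "frameshift"
            if not fs_mask.any():
                raise ValueError("no frameshift barcodes survive filtering; "
                                 "cannot normalise activities")
            fs_mean = ratio[fs_mask].groupby(meta.loc[fs_mask, "variant"]).mean().mean()
            rel_by_rep[rep] = ratio / fs_mean

        rel = pd.DataFrame(rel_by_rep)  # barcode x replicate
        rel_avg = rel.mean(axis=1)
        per_bc = meta.join(rel_avg.rename("rel_avg")).join(rel)
        rel_barcode_frames.append(per_bc.assign(condition=cond))

        g = per_bc.groupby("variant")
        rep_grp = {rep: rel[rep].groupby(meta["variant"]) for rep in replicates}
        m = pd.DataFrame({rep: rep_grp[rep].mean() for rep in replicates})
        s = pd.DataFrame({rep: rep_grp[rep].std(ddof=1) for rep in replicates})

        activity = m.mean(axis=1)
        sd = np.sqrt((s**2).sum(axis=1, min_count=1)) / len(replicates)
        bc_sd = g["rel_avg"].std(ddof=1)
        n_bc = g["rel_avg"].size()
        sem = bc_sd / np.sqrt(n_bc)
        cv = bc_sd / g["rel_avg"].mean()
        cls = g["call_class"].first()

        rows.append(pd.DataFrame({
            "variant": activity.index,
            "call_class": cls.values,
            "condition": cond,
            "activity": activity.values,
            "sd": sd.values,
            "sem": sem.values,
            "cv": cv.values,
            "n_barcodes": n_bc.values,
        }))

    table = pd.concat(rows, ignore_index=True)
    # annotate missense identity columns from variant labels where available
    id_cols = barcode_map.drop_duplicates("variant")[
        [c for c in ("variant", "position", "wt_aa", "mut_aa") if c in barcode_map.columns]
    ]
    if {"position", "wt_aa", "mut_aa"} <= set(id_cols.columns):
        table = table.merge(id_cols, on="variant", how="left")

    barcode_table = pd.concat(rel_barcode_frames).reset_index()
    frac_cv_ok = float((table.loc[table["call_class"] == "missense", "cv"] < 1).mean())
    summary = {
        "n_variants": int(table["variant"].nunique()),
        "n_barcodes_lost_to_count_filter": int(n_lost),
        "fraction_missense_cv_below_1": frac_cv_ok,
    }
    if n_lost:
        logger.info("%d mapped barcodes absent from filtered count table", n_lost)
    return table, summary


def activity_pipeline(
    counts: pd.DataFrame,
    barcode_map: pd.DataFrame,
    rpm_min: float = RPM_MIN,
    rpm_max: float = RPM_MAX,
) -> tuple[pd.DataFrame, dict]:
    """filter_barcodes -> normalize -> score_variants, with merged summary."""
    filtered, fsum = filter_barcodes(counts, rpm_min, rpm_max)
    _, ratios = normalize(filtered)
    table, ssum = score_variants(ratios, barcode_map)
    return table, {**fsum, **ssum}
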
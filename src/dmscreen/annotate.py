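"""Per-residue and per-variant biological summaries.

Mutational tolerance (mean activity of the 19 substitutions at a residue),
residue ranking and extreme-variant sets, loss-of-function calls against the
frameshift null distribution, Jensen-Shannon column conservation, and
correlation against external per-variant score tables (EVmutation-style
predictions, population-variant lists).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: BLOSUM62 amino-acid background frequencies (order ACDEFGHIKLMNPQRSTVWY),
#: the standard background for divergence-based conservation scoring.
_BLOSUM62_BG = {
    "A": 0.078, "R": 0.051, "N": 0.041, "D": 0.052, "C": 0.024,
    "Q": 0.034, "E": 0.059, "G": 0.083, "H": 0.025, "I": 0.062,
    "L": 0.092, "K": 0.056, "M": 0.024, "F": 0.044, "P": 0.043,
    "S": 0.059, "T": 0.055, "W": 0.014, "Y": 0.034, "V": 0.072,
}


def background_distribution(name: str = "blosum62") -> np.ndarray:
    """Background over the 20 amino acids in ACDEFGHIKLMNPQRSTVWY order."""
    if name == "uniform":
        return np.full(20, 1 / 20)
    if name == "blosum62":
        p = np.array([_BLOSUM62_BG[a] for a in AMINO_ACIDS])
        return p / p.sum()
    raise ValueError(f"unknown background {name!r}")


def tolerance(
    activity: pd.DataFrame, min_substitutions: int = 5
) -> pd.DataFrame:
    """Mutational tolerance: mean missense activity per residue x condition.

    Returns a table (position, condition, tolerance, n_substitutions,
    low_coverage). The mean is unweighted over the substitutions measured at
    that residue; residues with fewer than ``min_substitutions`` measured
    substitutions are flagged.
    """
    mis = activity[activity["call_class"] == "missense"].dropna(subset=["position"])
    g = mis.groupby(["position", "condition"])["activity"]
    out = g.agg(tolerance="mean", n_substitutions="size").reset_index()
    out["position"] = out["position"].astype(int)
    out["low_coverage"] = out["n_substitutions"] < min_substitutions
    return out


def rank_and_extremes(
    tolerance_table: pd.DataFrame,
    activity: pd.DataFrame,
    n: int = 100,
    rank_condition: str = "EC100",
    activating_condition: str = "vehicle",
) -> dict:
    """Residue ranking plus the extreme variant sets.

    Returns ``ranked`` (residues by ascending tolerance at rank_condition,
    i.e. most mutationally intolerant first; ties by residue index),
    ``top_activating`` (n highest-activity missense variants at the
    activating condition) and ``bottom`` (n lowest at rank_condition).
    """
    tol = tolerance_table[tolerance_table["condition"] == rank_condition]
    ranked = tol.sort_values(["tolerance", "position"], kind="stable").reset_index(drop=True)
    ranked = ranked.assign(rank=np.arange(1, len(ranked) + 1))

    mis = activity[activity["call_class"] == "missense"]

    def _extreme(cond: str, ascending: bool) -> pd.DataFrame:
        sub = mis[mis["condition"] == cond].copy()
        if n > len(sub):
            logger.warning("requested %d extremes but only %d variants", n, len(sub))
        sub = sub.sort_values(
            ["activity", "variant"], ascending=[ascending, True], kind="stable"
        )
        return sub.head(n).reset_index(drop=True)

    return {
        "ranked": ranked,
        "top_activating": _extreme(activating_condition, ascending=False),
        "bottom": _extreme(rank_condition, ascending=True),
    }


def frameshift_stats(activity: pd.DataFrame, condition: str) -> tuple[float, float]:
    """Mean and SD of frameshift variant activity at ``condition``.

    The mean is 1 by construction of the activity scale; the SD is the
    spread of the null distribution used by the loss-of-function rule.
    """
    fs = activity[(activity["call_class"] == "frameshift")
                  & (activity["condition"] == condition)]["activity"]
    if fs.empty:
        raise ValueError(f"no frameshift variants at condition {condition!r}")
    return float(fs.mean()), float(fs.std(ddof=1))


def classify_lof(
    activity: pd.DataFrame,
    population: pd.DataFrame | None = None,
    condition: str = "EC100",
) -> tuple[pd.DataFrame, float]:
    """Loss-of-function calls against the frameshift null.

    A variant is potentially loss of function when its activity plus SEM
    (the upper error bar) lies more than two frameshift standard deviations
    below the frameshift mean: a + sem < mean_fs - 2 sd_fs. Equality is not
    loss of function. Returns the call table and the threshold used.

    When ``population`` (columns position, wt_aa, mut_aa, plus e.g.
    allele_frequency) is given, calls are restricted to those variants; a
    population row whose wild-type residue contradicts the activity table is
    an error, not a silent drop.
    """
    mean_fs, sd_fs = frameshift_stats(activity, condition)
    threshold = mean_fs - 2.0 * sd_fs
    mis = activity[(activity["call_class"] == "missense")
                   & (activity["condition"] == condition)].copy()
    if population is not None:
        wt_by_pos = (mis.dropna(subset=["position"])
                     .drop_duplicates("position").set_index("position")["wt_aa"])
        for row in population.itertuples(index=False):
            pos = int(row.position)
            if pos in wt_by_pos.index and wt_by_pos[pos] != row.wt_aa:
                raise ValueError(
                    f"population variant at position {pos} claims wild-type "
                    f"{row.wt_aa!r} but assay reference has {wt_by_pos[pos]!r}")
        keys = population[["position", "wt_aa", "mut_aa"]].astype({"position": int})
        mis = mis.merge(keys, on=["position", "wt_aa", "mut_aa"], how="inner")
        extra = [c for c in population.columns
                 if c not in ("position", "wt_aa", "mut_aa")]
        if extra:
            mis = mis.merge(population, on=["position", "wt_aa", "mut_aa"], how="left")
    sem = mis["sem"].fillna(0.0)
    mis["is_lof"] = (mis["activity"] + sem) < threshold
    mis["lof_threshold"] = threshold
    mis["sd_frameshift"] = sd_fs
    return mis.reset_index(drop=True), threshold


def _column_distribution(column: np.ndarray) -> tuple[np.ndarray, float]:
    """Amino-acid frequency vector of one alignment column, gaps excluded."""
    counts = np.zeros(20)
    n_gap = 0
    for ch in column:
        i = AMINO_ACIDS.find(ch)
        if i >= 0:
            counts[i] += 1
        else:
            n_gap += 1
    total = counts.sum()
    gap_frac = n_gap / len(column) if len(column) else 1.0
    if total == 0:
        return counts, gap_frac
    return counts / total, gap_frac


def jensen_shannon(p: np.ndarray, q: np.ndarray) -> float:
    """JSD(p, q) in bits: H(m) - (H(p) + H(q))/2 with m the midpoint."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    m = 0.5 * (p + q)

    def h(x):
        nz = x > 0
        return float(-(x[nz] * np.log2(x[nz])).sum())

    return h(m) - 0.5 * (h(p) + h(q))


def js_conservation(
    msa: list[str] | list[tuple[str, str]],
    background: str | np.ndarray = "blosum62",
    reference_row: int = 0,
    max_gap_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-column Jensen-Shannon conservation against a background.

    Columns are scored only where the reference row carries a residue, and
    scores are min-max rescaled to [0, 1] over the scored columns. Gaps are
    excluded from each column's distribution; columns with more than
    ``max_gap_fraction`` gaps are flagged, all-gap columns are reported as
    missing. Returns a table (position, column, raw_jsd, score,
    gap_fraction, high_gap) where position counts reference residues
    (1-based) and column is the 0-based alignment column.
    """
    seqs = [s[1] if isinstance(s, tuple) else str(s) for s in msa]
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("alignment rows differ in length")
    bg = background if isinstance(background, np.ndarray) else background_distribution(background)
    arr = np.array([list(s.upper()) for s in seqs])
    ref = arr[reference_row]

    rows = []
    pos = 0
    for col in range(arr.shape[1]):
        if AMINO_ACIDS.find(ref[col]) < 0:
            continue  # reference gap: column not scored
        pos += 1
        p, gap_frac = _column_distribution(arr[:, col])
        if p.sum() == 0:
            rows.append((pos, col, np.nan, gap_frac))
            continue
        rows.append((pos, col, jensen_shannon(p, bg), gap_frac))
    out = pd.DataFrame(rows, columns=["position", "column", "raw_jsd", "gap_fraction"])
    out["high_gap"] = out["gap_fraction"] > max_gap_fraction
    valid = out["raw_jsd"].dropna()
    if len(valid) and valid.max() > valid.min():
        out["score"] = (out["raw_jsd"] - valid.min()) / (valid.max() - valid.min())
    else:
        out["score"] = np.where(out["raw_jsd"].notna(), 1.0, np.nan)
    return out


def correlate(x: pd.Series, y: pd.Series) -> dict:
    """Spearman and Pearson correlation on pairwise-complete observations."""
    df = pd.concat([pd.Series(x, name="x"), pd.Series(y, name="y")], axis=1).dropna()
    if len(df) < 3:
        raise ValueError(f"need >= 3 paired observations, have {len(df)}")
    rho, rho_p = stats.spearmanr(df["x"], df["y"])
    r, r_p = stats.pearsonr(df["x"], df["y"])
    return {"spearman_rho": float(rho), "spearman_p": float(rho_p),
            "pearson_r": float(r), "pearson_p": float(r_p), "n": int(len(df))}


def join_external_scores(
    activity: pd.DataFrame, scores: pd.DataFrame, condition: str = "EC100"
) -> pd.DataFrame:
    """Strict join of per-variant external scores on (position, wt, mut).

    A score row whose wild-type residue disagrees with the assay reference
    raises; variants without a score are kept with NaN.
    """
    mis = activity[(activity["call_class"] == "missense")
                   & (activity["condition"] == condition)].copy()
    wt_by_pos = (mis.dropna(subset=["position"])
                 .drop_duplicates("position").set_index("position")["wt_aa"])
    bad = [int(r.position) for r in scores.itertuples(index=False)
           if int(r.position) in wt_by_pos.index and wt_by_pos[int(r.position)] != r.wt_aa]
    if bad:
        raise ValueError(f"wild-type mismatch at positions {sorted(set(bad))[:5]}")
    return mis.merge(scores.astype({"position": int}),
                     on=["position", "wt_aa", "mut_aa"], how="left")
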
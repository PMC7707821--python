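"""Side-chain-orientation sensitivity analysis for membrane-span residues.

Within the lipid membrane, a residue whose side chain points into the
protein core tolerates neither charged nor hydrophobic substitutions, while
a lipid-facing side chain tolerates hydrophobic but not charged ones. We
quantify this with two standardised scores per residue and condition:

* charge sensitivity      z_chg = standardize(-mean activity over H,K,R,D,E)
* hydrophobic sensitivity z_hyd = standardize(-mean activity over I,L,V,M)

(the sign flip makes "sensitive" positive). Residues with above-average
charge sensitivity split into exclusively charge-sensitive (below-average
hydrophobic sensitivity; lipid-facing) and globally intolerant
(above-average both; core-facing); the rest are "other". Group comparisons
(e.g. SASA of the two classes) use the two-sided Mann-Whitney U test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

CHARGED = "HKRDE"
HYDROPHOBIC = "ILVM"


def _standardize(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=0)
    if not np.isfinite(sd) or sd == 0:
        return pd.Series(0.0, index=x.index)
    return (x - x.mean()) / sd


def sensitivity(
    activity: pd.DataFrame, membrane_residues: list[int] | pd.Series
) -> pd.DataFrame:
    """Charge and hydrophobic sensitivity z-scores for membrane residues.

    Standardisation is within each condition over the scored residues; a
    degenerate condition (zero spread) yields all-zero z-scores. Returns
    (position, condition, charge_sensitivity, hydrophobic_sensitivity).
    """
    members = set(int(r) for r in membrane_residues)
    mis = activity[activity["call_class"] == "missense"].dropna(subset=["position"]).copy()
    mis["position"] = mis["position"].astype(int)
    mis = mis[mis["position"].isin(members)]
    if mis.empty:
        raise ValueError("no missense measurements at membrane residues")

    rows = []
    for cond, sub in mis.groupby("condition"):
        chg = (sub[sub["mut_aa"].isin(list(CHARGED))]
               .groupby("position")["activity"].mean())
        hyd = (sub[sub["mut_aa"].isin(list(HYDROPHOBIC))]
               .groupby("position")["activity"].mean())
        idx = sorted(set(chg.index) | set(hyd.index))
        z_chg = _standardize(-chg.reindex(idx))
        z_hyd = _standardize(-hyd.reindex(idx))
        rows.append(pd.DataFrame({
            "position": idx, "condition": cond,
            "charge_sensitivity": z_chg.values,
            "hydrophobic_sensitivity": z_hyd.values,
        }))
    return pd.concat(rows, ignore_index=True)


def classify_orientation(scores: pd.DataFrame) -> pd.DataFrame:
    """Orientation classes from the sensitivity z-scores.

    Above-average charge sensitivity (z > 0) with below-average hydrophobic
    sensitivity gives ``charge_only`` (lipid-facing); above-average both
    gives ``globally_intolerant`` (core-facing); anything else ``other``.
    """
    out = scores.copy()
    chg = out["charge_sensitivity"]
    hyd = out["hydrophobic_sensitivity"]
    out["orientation"] = np.where(
        chg > 0, np.where(hyd > 0, "globally_intolerant", "charge_only"), "other"
    )
    return out


def compare_groups(a, b, exact_max_n: int = 8) -> dict:
    """Two-sided Mann-Whitney U test between two value groups.

    Uses the exact null distribution when both groups have at most
    ``exact_max_n`` observations and no ties straddle the groups, and the
    normal approximation with tie correction (and continuity correction)
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (a.size <= exact_max_n and b.size <= exact_max_n
                         and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {"U": float(res.statistic), "p": float(res.pvalue),
            "method": method, "n1": int(a.size), "n2": int(b.size)}


def compare_residue_sets(
    values: pd.Series, sets: dict[str, list[int]]
) -> pd.DataFrame:
    """Pairwise Mann-Whitney comparisons of a per-residue value across sets.

    ``values`` is indexed by residue position (e.g. SASA or tolerance);
    ``sets`` maps set name to residue lists. Missing residues are dropped.
    """
    rows = []
    names = sorted(sets)
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            va = values.reindex(sets[na]).dropna()
            vb = values.reindex(sets[nb]).dropna()
            res = compare_groups(va, vb)
            rows.append({"group_a": na, "group_b": nb,
                         "median_a": float(va.median()), "median_b": float(vb.median()),
                         **res})
    return pd.DataFrame(rows)
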
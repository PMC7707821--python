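"""Mutational tolerance, rankings, LoF calls, conservation, correlations."""

import numpy as np
import pandas as pd
import pytest

from dmscreen.annotate import (
    tolerance, rank_and_extremes, classify_lof, frameshift_stats,
    js_conservation, jensen_shannon, background_distribution, correlate,
    join_external_scores,
)
from dmscreen.structure import compare_groups

from .conftest import make_activity_table
from .oracles import jsd_bits

AAS = "ACDEFGHIKLMNPQRSTVWY"


class TestTolerance:
    def test_uniform_activities_give_unit_tolerance(self, flat_activity):
        tol = tolerance(flat_activity)
        assert np.allclose(tol["tolerance"], 1.0)
        assert not tol["low_coverage"].any()

    def test_tolerance_is_the_unweighted_mean(self):
        act = make_activity_table(
            L=4, activity_fn=lambda p, m, c: 0.0 if m < "N" else 2.0)
        tol = tolerance(act)
        # each residue mixes 0s and 2s; the mean stays within (0, 2)
        assert ((tol["tolerance"] > 0) & (tol["tolerance"] < 2)).all()
        one = act[(act["position"] == 1) & (act["condition"] == "EC100")
                  & (act["call_class"] == "missense")]
        expected = one["activity"].mean()
        got = tol[(tol["position"] == 1) & (tol["condition"] == "EC100")]
        assert got["tolerance"].iloc[0] == pytest.approx(expected)

    def test_low_coverage_flagging(self):
        act = make_activity_table(L=3)
        act = act[~((act["position"] == 2) & (act["mut_aa"] > "D"))]
        tol = tolerance(act, min_substitutions=5)
        assert tol.loc[tol["position"] == 2, "low_coverage"].all()
        assert not tol.loc[tol["position"] == 1, "low_coverage"].any()

    def test_planted_intolerant_core_separates_from_loops(self):
        core = set(range(1, 11))
        rng = np.random.default_rng(0)

        def act_fn(pos, mut, cond):
            base = 0.2 if pos in core else 1.0
            return base + rng.normal(0, 0.05)

        tol = tolerance(make_activity_table(L=30, activity_fn=act_fn, seed=2))
        ec = tol[tol["condition"] == "EC100"]
        res = compare_groups(ec[ec["position"].isin(core)]["tolerance"],
                             ec[~ec["position"].isin(core)]["tolerance"])
        assert res["p"] < 0.01


class TestRanking:
    def test_rank_matches_brute_force_sort(self, flat_activity):
        rng = np.random.default_rng(4)
        act = make_activity_table(
            L=25, activity_fn=lambda p, m, c: float(rng.uniform(0, 2)), seed=3)
        tol = tolerance(act)
        out = rank_and_extremes(tol, act, n=10)
        ec = tol[tol["condition"] == "EC100"]
        expected = [p for _, p in sorted(zip(ec["tolerance"], ec["position"]))]
        assert list(out["ranked"]["position"]) == expected
        assert list(out["ranked"]["rank"]) == list(range(1, len(expected) + 1))

    def test_injected_hyperactive_variant_tops_the_activating_list(self):
        def act_fn(pos, mut, cond):
            return 10.0 if (pos, mut) == (3, "W") else 1.0

        act = make_activity_table(L=10, activity_fn=act_fn, seed=5)
        out = rank_and_extremes(tolerance(act), act, n=5)
        top = out["top_activating"].iloc[0]
        assert (top["position"], top["mut_aa"]) == (3, "W")

    def test_oversized_n_returns_everything(self, flat_activity):
        out = rank_and_extremes(tolerance(flat_activity), flat_activity, n=10**6)
        n_missense = (flat_activity["call_class"] == "missense").sum() // 4
        assert len(out["bottom"]) == n_missense


class TestLof:
    @pytest.mark.parametrize(
        "a,sem,lof",
        [(0.25, 0.125, True),    # 0.375 < 0.5
         (0.5, 0.125, False),    # 0.625 >= 0.5
         (0.375, 0.125, False),  # exact equality at 0.5 is not LoF
         (1.0, 0.0, False)],     # frameshift-like is never LoF
    )
    def test_rule_arithmetic_against_frameshift_null(self, a, sem, lof):
        # frameshift activities 0.75/1.0/1.25: mean 1, sd exactly 0.25
        rows = [dict(variant=f"fs_{i}", call_class="frameshift",
                     condition="EC100", activity=x, sem=0.0,
                     position=pd.NA, wt_aa="", mut_aa="")
                for i, x in enumerate((0.75, 1.0, 1.25))]
        rows.append(dict(variant="A1V", call_class="missense", condition="EC100",
                         activity=a, sem=sem, position=1, wt_aa="A", mut_aa="V"))
        calls, threshold = classify_lof(pd.DataFrame(rows), condition="EC100")
        assert threshold == 0.5
        assert bool(calls["is_lof"].iloc[0]) is lof

    def test_exhaustive_agreement_with_the_inequality(self):
        rng = np.random.default_rng(7)
        act = make_activity_table(
            L=15, fs_sd=0.15, activity_fn=lambda p, m, c: float(rng.uniform(0, 1.5)),
            seed=8)
        calls, _ = classify_lof(act, condition="EC100")
        _, sd_fs = frameshift_stats(act, "EC100")
        expected = (calls["activity"] + calls["sem"]) < (1 - 2 * sd_fs)
        assert (calls["is_lof"] == expected).all()

    def test_population_restriction_and_wt_check(self):
        act = make_activity_table(L=5, seed=9)
        wt3 = act.loc[act["position"] == 3, "wt_aa"].iloc[0]
        mut3 = next(a for a in AAS if a != wt3)
        pop = pd.DataFrame([{"position": 3, "wt_aa": wt3, "mut_aa": mut3,
                             "allele_frequency": 1e-4}])
        calls, _ = classify_lof(act, population=pop)
        assert len(calls) == 1 and calls["allele_frequency"].iloc[0] == 1e-4
        bad = pop.assign(wt_aa=next(a for a in AAS if a not in (wt3, mut3)))
        with pytest.raises(ValueError, match="wild-type"):
            classify_lof(act, population=bad)


def msa_from_columns(columns: list[str]) -> list[str]:
    """Transpose per-column residue strings into aligned sequences."""
    n = len(columns[0])
    return ["".join(col[i] for col in columns) for i in range(n)]


class TestConservation:
    def test_background_column_scores_zero(self):
        msa = msa_from_columns([AAS, "A" * 20])  # col 0 is exactly uniform
        out = js_conservation(msa, background="uniform")
        assert out.loc[out["column"] == 0, "raw_jsd"].iloc[0] == pytest.approx(0, abs=1e-12)

    def test_conserved_column_matches_entropy_oracle(self):
        msa = msa_from_columns(["W" * 20, AAS])
        out = js_conservation(msa, background="uniform")
        p = [0.0] * 20
        p[AAS.index("W")] = 1.0
        expected = jsd_bits(p, [1 / 20] * 20)
        got = out.loc[out["column"] == 0, "raw_jsd"].iloc[0]
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(0.854906, abs=1e-4)

    def test_sequence_reordering_leaves_scores_unchanged(self):
        rng = np.random.default_rng(11)
        msa = ["".join(rng.choice(list(AAS), 30)) for _ in range(25)]
        a = js_conservation(msa)
        b = js_conservation(msa[::-1], reference_row=len(msa) - 1)
        # same reference sequence, same columns: identical raw scores
        assert np.allclose(a["raw_jsd"], b["raw_jsd"])

    def test_reference_gap_columns_are_not_scored(self):
        rng = np.random.default_rng(12)
        base = ["".join(rng.choice(list(AAS), 10)) for _ in range(8)]
        padded = [s[:4] + ("-" if i > 0 else "-") + s[4:] for i, s in enumerate(base)]
        a = js_conservation(base)
        b = js_conservation(padded)
        assert len(b) == len(a)
        assert np.allclose(a["raw_jsd"], b["raw_jsd"])

    def test_gap_handling_and_missing_column(self):
        msa = ["AC", "A-", "A-", "A-"]
        out = js_conservation(msa, max_gap_fraction=0.5)
        assert not out.loc[out["column"] == 0, "high_gap"].iloc[0]
        assert out.loc[out["column"] == 1, "high_gap"].iloc[0]

    def test_scores_track_planted_substitution_rates(self):
        """Columns mutated at higher rates score lower (rho < -0.8)."""
        rng = np.random.default_rng(13)
        n_seq, n_col = 200, 60
        rates = rng.uniform(0.02, 0.95, n_col)
        ref = rng.choice(list(AAS), n_col)
        cols = []
        for c in range(n_col):
            col = [ref[c]] + [rng.choice(list(AAS)) if rng.random() < rates[c]
                              else ref[c] for _ in range(n_seq - 1)]
            cols.append("".join(col))
        out = js_conservation(msa_from_columns(cols), background="blosum62")
        rho = correlate(out["raw_jsd"], pd.Series(rates))["spearman_rho"]
        assert rho < -0.8

    def test_normalized_scores_span_unit_interval(self):
        rng = np.random.default_rng(14)
        msa = ["".join(rng.choice(list(AAS), 40)) for _ in range(30)]
        out = js_conservation(msa)
        assert out["score"].min() == 0.0 and out["score"].max() == 1.0


def test_background_distributions_are_proper():
    for name in ("uniform", "blosum62"):
        bg = background_distribution(name)
        assert bg.shape == (20,) and bg.sum() == pytest.approx(1.0)
        assert (bg > 0).all()


class TestCorrelate:
    def test_perfect_and_inverted_correlation(self):
        x = pd.Series(np.arange(10, dtype=float))
        assert correlate(x, x)["spearman_rho"] == pytest.approx(1.0)
        assert correlate(x, -x)["spearman_rho"] == pytest.approx(-1.0)
        assert correlate(x, x)["pearson_r"] == pytest.approx(1.0)

    def test_pairwise_complete_observations(self):
        x = pd.Series([1.0, 2, 3, np.nan, 5])
        y = pd.Series([2.0, 4, 6, 8, np.nan])
        out = correlate(x, y)
        assert out["n"] == 3 and out["pearson_r"] == pytest.approx(1.0)

    def test_null_permutations_rarely_exceed_modest_correlation(self):
        rng = np.random.default_rng(15)
        x = pd.Series(rng.normal(size=412))
        hits = 0
        for _ in range(200):
            y = pd.Series(rng.permutation(x.to_numpy()))
            if abs(correlate(x, y)["spearman_rho"]) < 0.15:
                hits += 1
        assert hits / 200 >= 0.95


def test_external_score_join_is_strict():
    act = make_activity_table(L=4, seed=16)
    wt2 = act.loc[act["position"] == 2, "wt_aa"].iloc[0]
    mut2 = next(a for a in AAS if a != wt2)
    scores = pd.DataFrame([{"position": 2, "wt_aa": wt2, "mut_aa": mut2,
                            "score": -3.2}])
    joined = join_external_scores(act, scores)
    hit = joined[joined["score"].notna()]
    assert len(hit) == 1 and hit["mut_aa"].iloc[0] == mut2
    with pytest.raises(ValueError, match="mismatch"):
        join_external_scores(act, scores.assign(wt_aa="?"))
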
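"""Tests for corpus ingestion, filtering, classification and summaries."""

import json
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

from pstopt import (
    ColumnMap,
    StudyDesign,
    assumed_effect_size,
    classify_corpus,
    cohen_kappa,
    cost,
    filter_corpus,
    load_corpus,
    summarize_corpus,
    type1_error,
)


def make_corpus_file(tmp_path, rows, header="trial_id,b,se,outcome_type,n1,n2"):
    path = tmp_path / "corpus.csv"
    path.write_text("\n".join([header, *rows]) + "\n")
    return path


class TestLoadCorpus:
    def test_clean_rows_all_parsed(self, tmp_path):
        path = make_corpus_file(tmp_path, [
            "a,1.2,0.5,continuous,30,40",
            "b,0.8,0.1,dichotomous,100,110",
            "c,-0.4,0.2,continuous,25,25",
        ])
        records, rejects = load_corpus(path)
        assert len(records) == 3 and rejects.empty
        # statistic conventions: b/se for continuous, log(b)/se for dichotomous
        assert records.loc[0, "stat"] == pytest.approx(2.4)
        assert records.loc[1, "stat"] == pytest.approx(math.log(0.8) / 0.1)
        assert records.loc[1, "stat"] == pytest.approx(-2.2314, abs=5e-5)
        assert (records["nu"] == records["n1"] + records["n2"] - 2).all()
        assert records.loc[0, "p"] == pytest.approx(type1_error(2.4, 68), rel=1e-12)

    @pytest.mark.parametrize(
        "row, reason",
        [
            ("r,1.0,0.0,continuous,30,30", "nonpositive standard error"),
            ("r,1.0,-0.5,continuous,30,30", "nonpositive standard error"),
            ("r,-0.8,0.1,dichotomous,30,30", "nonpositive dichotomous effect"),
            ("r,1.0,0.5,ordinal,30,30", "unknown outcome type"),
            ("r,,0.5,continuous,30,30", "missing value"),
            ("r,oops,0.5,continuous,30,30", "non-numeric cell"),
            ("r,1.0,0.5,continuous,1,30", "arm size below 2"),
        ],
    )
    def test_bad_rows_rejected_with_reason(self, tmp_path, row, reason):
        path = make_corpus_file(tmp_path, ["ok,1.0,0.5,continuous,30,30", row])
        records, rejects = load_corpus(path)
        assert len(records) == 1
        assert rejects["reason"].tolist() == [reason]

    def test_column_map_renames_and_labels(self, tmp_path):
        path = make_corpus_file(
            tmp_path,
            ["t1\t0.9\t0.3\tbin\t20\t30"],
            header="study\teffect\tstderr\tkind\tarmA\tarmB",
        )
        colmap = ColumnMap(effect="effect", se="stderr", outcome_type="kind",
                           n1="armA", n2="armB", trial_id="study",
                           outcome_labels={"bin": "dichotomous"})
        records, rejects = load_corpus(path, colmap, sep="\t")
        assert rejects.empty
        assert records.loc[0, "outcome_type"] == "dichotomous"
        assert records.loc[0, "trial_id"] == "t1"

    def test_column_map_from_file(self, tmp_path):
        cfg = tmp_path / "map.cfg"
        cfg.write_text("# corpus schema\neffect = eff\nse = stderr\nlabel.2 = dichotomous\n")
        colmap = ColumnMap.from_file(cfg)
        assert colmap.effect == "eff" and colmap.se == "stderr"
        assert colmap.outcome_labels == {"2": "dichotomous"}
        assert colmap.n1 == "n1"  # unmapped fields keep defaults

    def test_missing_mapped_column_is_config_error(self, tmp_path):
        path = make_corpus_file(tmp_path, ["a,1.0,0.5,continuous,30,30"])
        with pytest.raises(ValueError, match="missing mapped columns"):
            load_corpus(path, ColumnMap(effect="effect_size"))


class TestFilterCorpus:
    @pytest.fixture
    def records(self, tmp_path):
        rows = [f"t{i},1.0,0.5,continuous,50,50" for i in range(8)]
        rows.append("huge,25.0,1.0,continuous,50,50")   # |stat| = 25
        rows.append("tiny,1.0,0.5,continuous,4,4")      # total 8 < 10
        records, _ = load_corpus(make_corpus_file(tmp_path, rows))
        return records

    def test_planted_violations_excluded(self, records):
        kept, excluded = filter_corpus(records)
        assert len(kept) == 8 and len(excluded) == 2
        reasons = dict(zip(excluded["trial_id"], excluded["reason"]))
        assert reasons == {"huge": "extreme statistic",
                           "tiny": "sample size below minimum"}
        assert kept["trial_id"].tolist() == [f"t{i}" for i in range(8)]

    def test_per_arm_rule(self, tmp_path):
        records, _ = load_corpus(make_corpus_file(tmp_path, [
            "a,1.0,0.5,continuous,4,50",
            "b,1.0,0.5,continuous,12,50",
        ]))
        kept_total, _ = filter_corpus(records, size_rule="total")
        kept_arm, _ = filter_corpus(records, size_rule="per-arm")
        assert kept_total["trial_id"].tolist() == ["a", "b"]
        assert kept_arm["trial_id"].tolist() == ["b"]

    def test_negative_extreme_statistic_excluded(self, tmp_path):
        records, _ = load_corpus(make_corpus_file(
            tmp_path, ["neg,-30.0,1.0,continuous,50,50"]))
        kept, excluded = filter_corpus(records)
        assert kept.empty and excluded["reason"].tolist() == ["extreme statistic"]


@pytest.mark.parametrize("n1, n2, d", [(60, 40, 0.5), (50, 50, 0.5),
                                       (50, 49, 0.8), (5, 5, 0.8)])
def test_assumed_effect_size(n1, n2, d):
    assert assumed_effect_size(n1, n2) == d


class TestClassifyCorpus:
    @pytest.fixture
    def one_trial(self, tmp_path):
        # n1 = n2 = 100, p ~= 0.02: t cut-off for p=0.02 at nu=198 is ~2.345
        records, _ = load_corpus(make_corpus_file(
            tmp_path, ["x,2.35,1.0,continuous,100,100"]))
        return records

    def test_fixed_criteria(self, one_trial):
        calls = classify_corpus(one_trial).set_index("criterion")
        p = one_trial.loc[0, "p"]
        assert 0.005 < p < 0.05
        assert calls.loc["fixed_0.05", "significant"]
        assert not calls.loc["fixed_0.005", "significant"]

    def test_flexible_threshold_matches_grid_oracle(self, one_trial):
        calls = classify_corpus(one_trial).set_index("criterion")
        design = StudyDesign(n1=100, n2=100, d=0.5, pr=0.5, C=0.25)
        grid = np.linspace(0, 12, 200_001)
        t_star = grid[int(np.argmin(cost(grid, design)))]
        pst_oracle = type1_error(t_star, design.nu)
        # grid half-step ~3e-5 on t limits the oracle's threshold precision
        assert calls.loc["pst_opt", "threshold"] == pytest.approx(pst_oracle, rel=2e-4)
        assert bool(calls.loc["pst_opt", "significant"]) == (
            one_trial.loc[0, "p"] < pst_oracle
        )

    def test_infeasible_constrained_never_significant(self, tmp_path):
        # 50 vs 50 at the assumed d = 0.5 is under-powered at its optimum
        records, _ = load_corpus(make_corpus_file(
            tmp_path, ["y,5.0,1.0,continuous,50,50"]))
        calls = classify_corpus(records).set_index("criterion")
        assert calls.loc["pst_opt", "significant"]
        assert not calls.loc["c_pst_opt", "significant"]
        assert np.isnan(calls.loc["c_pst_opt", "threshold"])

    def test_nesting_of_criteria(self, tmp_path):
        rng = np.random.default_rng(7)
        rows = [
            f"t{i},{rng.normal(0, 2):.6f},1.0,continuous,"
            f"{rng.integers(20, 400)},{rng.integers(20, 400)}"
            for i in range(60)
        ]
        records, _ = load_corpus(make_corpus_file(tmp_path, rows))
        kept, _ = filter_corpus(records)
        calls = classify_corpus(kept)
        by = {c: g.sort_values("trial_id")["significant"].to_numpy()
              for c, g in calls.groupby("criterion")}
        assert np.all(~by["fixed_0.005"] | by["fixed_0.05"])
        assert np.all(~by["c_pst_opt"] | by["pst_opt"])


class TestCohenKappa:
    def test_identical_vectors(self):
        assert cohen_kappa([1, 0, 1, 1], [1, 0, 1, 1]) == 1.0

    def test_hand_computed_examples(self):
        # p_o = 0.5 and p_e = 0.5 from the marginals -> kappa 0
        assert cohen_kappa([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(0.0, abs=1e-15)
        assert cohen_kappa([1, 0], [0, 1]) == pytest.approx(-1.0)

    def test_both_constant_undefined(self):
        assert math.isnan(cohen_kappa([1, 1, 1], [1, 1, 1]))

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=2, max_size=40))
    def test_symmetry_and_sklearn_agreement(self, pairs):
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        ours = cohen_kappa(a, b)
        assert ours == pytest.approx(cohen_kappa(b, a), nan_ok=True, abs=1e-12)
        with np.errstate(invalid="ignore"):
            ref = cohen_kappa_score(a, b)
        assert ours == pytest.approx(ref, nan_ok=True, abs=1e-12)


class TestSummarizeCorpus:
    @pytest.fixture
    def planted(self, tmp_path):
        # 5 trials, n = 200 per arm; stats straddle the criteria thresholds
        rows = [
            "s1,4.0,1.0,continuous,200,200",   # p ~ 7e-5: significant everywhere
            "s2,2.9,1.0,continuous,200,200",   # p ~ 0.004
            "s3,2.1,1.0,continuous,200,200",   # p ~ 0.036: only fixed_0.05
            "s4,1.0,1.0,continuous,200,200",   # p ~ 0.32: nowhere
            "s5,-4.0,1.0,continuous,200,200",  # symmetric to s1
        ]
        records, _ = load_corpus(make_corpus_file(tmp_path, rows))
        return records, classify_corpus(records)

    def test_counts_match_hand_counts(self, planted):
        records, calls = planted
        summary = summarize_corpus(calls, records)
        # pst_opt threshold for 200 vs 200 is ~0.0037 (c_pst_opt identical, feasible):
        # |stat|=2.9 gives p~0.0039, inside (0.0037, 0.005) -> fixed_0.005 only
        counts = {c: summary["criteria"][c]["n_significant"] for c in summary["criteria"]}
        assert counts == {"fixed_0.05": 4, "fixed_0.005": 3,
                          "pst_opt": 2, "c_pst_opt": 2}
        assert summary["criteria"]["fixed_0.05"]["pct_significant"] == pytest.approx(80.0)
        assert summary["n_total"] == 5
        assert summary["pst_opt_subset_of_fixed_0.05"] is True
        assert -1.0 <= summary["kappa"]["kappa"] <= 1.0

    def test_order_permutation_invariant(self, planted):
        records, calls = planted
        base = summarize_corpus(calls, records)
        perm = records.sample(frac=1.0, random_state=3).reset_index(drop=True)
        shuffled = summarize_corpus(classify_corpus(perm), perm)
        assert json.dumps(base, sort_keys=True) == json.dumps(shuffled, sort_keys=True)

    def test_threshold_and_power_distributions(self, planted):
        records, calls = planted
        summary = summarize_corpus(calls, records)
        block = summary["criteria"]["pst_opt"]
        assert block["threshold_significant"]["q1"] <= \
            block["threshold_significant"]["median"] <= \
            block["threshold_significant"]["q3"]
        assert sum(block["power_histogram"]["counts"]) == block["n_significant"]

    def test_empty_corpus(self):
        empty = pd.DataFrame(columns=["trial_id", "p", "n1", "n2", "d_assumed"])
        calls = pd.DataFrame(columns=["trial_id", "criterion", "threshold",
                                      "significant", "power_at_threshold"])
        assert summarize_corpus(calls, empty) == {"n_total": 0, "criteria": {}}

    def test_deterministic_summary_bytes(self, tmp_path, planted):
        records, _ = planted
        out = []
        for _ in range(2):
            calls = classify_corpus(records)
            out.append(json.dumps(summarize_corpus(calls, records), sort_keys=True))
        assert out[0] == out[1]
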
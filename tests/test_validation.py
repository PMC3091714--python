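from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nmdkit.synth import synth_qpcr, synth_spot_matrix
from nmdkit.validation import (
    SpotMatrix,
    common_changes,
    filter_presence,
    pca_fit,
    percent_isoform,
    qpcr_fold_change,
    read_qpcr_tsv,
    significant_spots,
    spot_ttest,
    summarize_categories,
    summarize_outcomes,
    two_round_validate,
)


def small_matrix(values, conditions, log_base=2.0):
    df = pd.DataFrame(values)
    return SpotMatrix(values=df, conditions=pd.Series(conditions), log_base=log_base)


class TestFilterPresence:
    def test_threshold_arithmetic(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(2, 18))
        vals[0, :5] = np.nan   # 13/18 = 72% -> removed
        vals[1, :4] = np.nan   # 14/18 = 78% -> kept
        df = pd.DataFrame(vals, index=["s72", "s78"])
        m = SpotMatrix(df, pd.Series(["a"] * 9 + ["b"] * 9, index=df.columns))
        assert list(filter_presence(m).values.index) == ["s78"]

    def test_fully_observed_identity(self):
        m, _ = synth_spot_matrix(20, 3, missing_rate=0.0, seed=1)
        assert filter_presence(m).values.equals(m.values)

    def test_matches_counting_oracle(self):
        m, _ = synth_spot_matrix(300, 4, missing_rate=0.3, seed=2)
        kept = set(filter_presence(m, 0.75).values.index)
        oracle = {
            sid
            for sid, row in m.values.iterrows()
            if row.notna().sum() / len(row) >= 0.75
        }
        assert kept == oracle

    def test_all_removed_errors(self):
        m, _ = synth_spot_matrix(5, 3, missing_rate=0.0, seed=3)
        vals = m.values.copy()
        vals.iloc[:, :] = np.nan
        with pytest.raises(ValueError):
            filter_presence(SpotMatrix(vals, m.conditions))


class TestSpotTtest:
    def test_identical_groups(self):
        m = small_matrix(
            {"a1": [1.0], "a2": [1.0], "b1": [1.0], "b2": [1.0]},
            {"a1": "t", "a2": "t", "b1": "c", "b2": "c"},
        )
        (c,) = spot_ttest(m, "t", "c")
        assert c.fold_change == 1.0 and c.p_value == 1.0 and c.direction == "up"

    def test_swap_symmetry(self):
        m, _ = synth_spot_matrix(50, 4, missing_rate=0.0, seed=4)
        fwd = spot_ttest(m, "kd_a", "control")
        rev = spot_ttest(m, "control", "kd_a")
        for f, r in zip(fwd, rev):
            assert f.p_value == pytest.approx(r.p_value, abs=1e-12)
            assert f.fold_change == pytest.approx(1 / r.fold_change, rel=1e-9)

    def test_against_independent_t_oracle(self):
        """Pooled-variance t statistic coded from the textbook formula."""
        x = np.array([1.1, 0.9, 1.3])
        y = np.array([1.6, 1.8, 1.5])
        m = small_matrix(
            {f"t{i}": [v] for i, v in enumerate(x)} | {f"c{i}": [v] for i, v in enumerate(y)},
            {f"t{i}": "t" for i in range(3)} | {f"c{i}": "c" for i in range(3)},
        )
        (c,) = spot_ttest(m, "t", "c")
        n1, n2 = len(x), len(y)
        sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
        t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
        assert c.p_value == pytest.approx(p, abs=1e-9)
        assert c.direction == "down"

    def test_too_few_observations_gives_nan(self):
        m = small_matrix(
            {"a1": [1.0], "a2": [np.nan], "b1": [1.2], "b2": [1.1]},
            {"a1": "t", "a2": "t", "b1": "c", "b2": "c"},
        )
        (c,) = spot_ttest(m, "t", "c")
        assert np.isnan(c.p_value)

    def test_type_one_error_calibration(self):
        """Null spots reach p < 0.01 at the nominal rate."""
        m, _ = synth_spot_matrix(10000, 6, sigma=0.15, missing_rate=0.0, seed=5)
        frac = np.mean([c.p_value < 0.01 for c in spot_ttest(m, "kd_a", "control")])
        assert abs(frac - 0.01) <= 3 * np.sqrt(0.01 * 0.99 / 10000)

    def test_power_on_planted_effects(self):
        """1.5-fold effects at low noise are detected essentially always."""
        effect = np.log2(1.5)
        m, _ = synth_spot_matrix(
            400, 6, effect_table={"kd_a": effect}, sigma=0.05, missing_rate=0.0, seed=6
        )
        changes = spot_ttest(m, "kd_a", "control")
        hits = [c.p_value < 0.01 and c.direction == "up" for c in changes]
        assert np.mean(hits) > 0.95


class TestCommonChanges:
    def test_examples(self):
        assert common_changes({"1", "2", "3"}, {"2", "3", "4"}) == (1, 1, 2)
        assert common_changes({"a"}, {"b", "c"}) == (1, 2, 0)

    def test_random_sets_vs_membership_oracle(self, rng):
        ids = [f"s{i}" for i in range(100)]
        for _ in range(20):
            a = {i for i in ids if rng.random() < 0.3}
            b = {i for i in ids if rng.random() < 0.3}
            ua, ub, co = common_changes(a, b)
            assert co == sum(1 for i in ids if i in a and i in b)
            assert ua == sum(1 for i in ids if i in a and i not in b)
            assert ub == sum(1 for i in ids if i in b and i not in a)


class TestPCA:
    def test_rank_one_matrix(self):
        base = np.linspace(0, 1, 8)
        vals = pd.DataFrame(np.outer([1.0, 2.0, 3.0], base))
        m = SpotMatrix(vals, pd.Series(["c"] * 8, index=vals.columns))
        r = pca_fit(m, 2)
        assert r.r2_cumulative[0] == pytest.approx(1.0)

    def test_scores_orthogonal(self):
        m, _ = synth_spot_matrix(60, 4, sigma=0.3, missing_rate=0.0, seed=7)
        r = pca_fit(m, 4)
        dots = r.scores.T @ r.scores
        off = dots - np.diag(np.diag(dots))
        assert np.max(np.abs(off)) < 1e-8

    def test_agreement_with_svd_oracle(self):
        """Scores match a direct numpy SVD up to per-component sign."""
        for seed in range(3):
            m, _ = synth_spot_matrix(50, 4, sigma=0.25, missing_rate=0.0, seed=seed)
            r = pca_fit(m, 5)
            x = m.values.to_numpy().T
            xc = x - x.mean(axis=0)
            u, s, _ = np.linalg.svd(xc, full_matrices=False)
            oracle = u * s
            k = r.scores.shape[1]
            assert np.max(np.abs(np.abs(r.scores) - np.abs(oracle[:, :k]))) < 1e-8

    def test_excess_components_truncated_with_warning(self):
        m, _ = synth_spot_matrix(30, 3, missing_rate=0.0, seed=8)
        with pytest.warns(UserWarning, match="rank"):
            r = pca_fit(m, 12)
        assert r.scores.shape[1] <= 8


class TestQpcr:
    def _records(self, fold=2.0):
        rows = []
        for cond, f in (("control", 1.0), ("upf1_kd", fold)):
            for rep in range(3):
                rows.append(
                    {
                        "gene": "g",
                        "sample": f"{cond}_{rep}",
                        "condition": cond,
                        "quantity_goi": 10.0 * f,
                        "quantity_reference": 100.0,
                    }
                )
        return pd.DataFrame(rows)

    def test_doubling_gives_fold_two(self):
        r = qpcr_fold_change(self._records(2.0), "g", "upf1_kd")
        assert r.mean == pytest.approx(2.0)

    def test_identical_conditions_give_one(self):
        r = qpcr_fold_change(self._records(1.0), "g", "upf1_kd")
        assert np.allclose(r.folds, 1.0)

    def test_parameter_recovery(self):
        """Planted 1.4-fold at 10% CV and n=8 is recovered within 3 SEM."""
        rec = synth_qpcr(["g"], {"g": 1.4}, {"g": 1.4}, cv=0.10, n_reps=8, seed=9)
        r = qpcr_fold_change(rec, "g", "upf1_kd")
        assert abs(r.mean - 1.4) < 3 * r.sem + 1e-9

    def test_nonpositive_quantities_rejected_at_parse(self):
        text = "gene\tsample\tcondition\tquantity_goi\tquantity_reference\ng\ts1\tcontrol\t0\t10\n"
        with pytest.raises(ValueError):
            read_qpcr_tsv(text)


class TestTwoRoundValidate:
    def test_both_rounds_up_is_bona_fide(self):
        rng = np.random.default_rng(10)
        kd = 1.4 * np.exp(rng.normal(0, 0.05, 8))
        chx = 1.4 * np.exp(rng.normal(0, 0.05, 8))
        o = two_round_validate("g", kd, chx)
        assert (o.round1, o.round2, o.bona_fide_nmd) == ("increased", "increased", True)

    def test_kd_up_chx_down_not_a_target(self):
        rng = np.random.default_rng(11)
        kd = 1.5 * np.exp(rng.normal(0, 0.05, 8))
        chx = 0.6 * np.exp(rng.normal(0, 0.05, 8))
        o = two_round_validate("g", kd, chx)
        assert o.round2 == "decreased" and not o.bona_fide_nmd

    def test_null_folds_no_change(self):
        rng = np.random.default_rng(12)
        folds = np.exp(rng.normal(0, 0.05, 8))
        assert two_round_validate("g", folds, folds).round1 == "no_change"

    def test_round2_skipped_unless_round1_increased(self):
        rng = np.random.default_rng(13)
        null = np.exp(rng.normal(0, 0.05, 8))
        up = 1.5 * np.exp(rng.normal(0, 0.05, 8))
        assert two_round_validate("g", null, up).round2 == "not_tested"
        assert two_round_validate("g", null, up, always_test_round2=True).round2 == "increased"

    def test_too_few_replicates_no_signal(self):
        assert two_round_validate("g", [1.4], None).round1 == "no_signal"
        assert two_round_validate("g", None, None).round1 == "no_signal"

    def test_recovers_planted_gene_classes(self):
        """Bona fide / knockdown-only / unchanged genes sort correctly."""
        genes = [f"g{i}" for i in range(60)]
        kd = {g: (1.4 if i < 40 else 1.0) for i, g in enumerate(genes)}
        chx = {g: (1.4 if i < 20 else 1.0) for i, g in enumerate(genes)}
        rec = synth_qpcr(genes, kd, chx, cv=0.10, n_reps=8, seed=14)
        outcomes = {}
        for g in genes:
            outcomes[g] = two_round_validate(
                g,
                qpcr_fold_change(rec, g, "upf1_kd").folds,
                qpcr_fold_change(rec, g, "chx").folds,
            )
        bona = [g for g, o in outcomes.items() if o.bona_fide_nmd]
        planted = genes[:20]
        sens = len(set(bona) & set(planted)) / len(planted)
        assert sens > 0.9
        null_genes = genes[40:]
        false_pos = [g for g in null_genes if outcomes[g].round1 == "increased"]
        assert len(false_pos) / len(null_genes) < 0.25  # alpha=0.05, n=20


class TestSummaries:
    def test_half_and_half(self):
        t = summarize_categories({"a": 1, "b": 1}, 2)
        assert t.percentages == {"a": 50, "b": 50}

    def test_sum_mismatch_rejected(self):
        with pytest.raises(ValueError):
            summarize_categories({"a": 2, "b": 1}, 2)

    def test_random_compositions_vs_fraction_oracle(self, rng):
        for _ in range(50):
            parts = rng.integers(0, 50, size=4)
            denom = int(parts.sum())
            if denom == 0:
                continue
            t = summarize_categories(
                {f"c{i}": int(v) for i, v in enumerate(parts)}, denom
            )
            for i, v in enumerate(parts):
                exact = Fraction(100 * int(v), denom)
                # half-up: floor(x + 1/2)
                expected = int(exact + Fraction(1, 2))
                assert t.percentages[f"c{i}"] == expected
                assert abs(t.percentages[f"c{i}"] - float(exact)) <= 0.5

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(st.integers(min_value=0, max_value=10_000), min_size=1, max_size=6)
    )
    def test_percentages_within_half_point_of_exact(self, parts):
        denom = sum(parts)
        if denom == 0:
            return
        t = summarize_categories({f"c{i}": v for i, v in enumerate(parts)}, denom)
        for i, v in enumerate(parts):
            exact = Fraction(100 * v, denom)
            assert abs(t.percentages[f"c{i}"] - float(exact)) <= 0.5
            assert t.percentages[f"c{i}"] == int(exact + Fraction(1, 2))

    def test_summarize_outcomes_counts_rounds(self):
        outs = [
            two_round_validate("a", [1.5] * 0 or None, None),
        ]
        t = summarize_outcomes(outs, "round1")
        assert t.counts["no_signal"] == 1


class TestPercentIsoform:
    def test_examples(self):
        assert percent_isoform(1, 3) == 25.0
        assert percent_isoform(5, 0) == 100.0

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            percent_isoform(0, 0)

    def test_random_pairs(self, rng):
        for _ in range(20):
            u, lo = rng.uniform(0.0, 10.0, size=2)
            assert percent_isoform(u, lo) == pytest.approx(100 * u / (u + lo))
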
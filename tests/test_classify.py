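"""ROC sweep, optimum threshold, LOOCV, group statistics, grid search."""

import numpy as np
import pytest
from scipy import stats

from wavectm.classify import (
    ClassMissingError,
    LabeledScore,
    evaluate_at,
    grid_search,
    group_stats,
    loocv,
    roc,
)
from wavectm.wavelet_core import WaveletSpec


def scores_from(values, labels):
    return [LabeledScore(f"r{i}", v, bool(l)) for i, (v, l) in enumerate(zip(values, labels))]


def auc_rank_oracle(pos, neg):
    """AROC via the Mann-Whitney U statistic (ties counted half)."""
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return u / (len(pos) * len(neg))


class TestRoc:
    def test_separable_example(self):
        s = scores_from([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0])
        r = roc(s, "positive_high")
        assert r.optimum_acc == 1.0
        assert r.aroc == 1.0
        assert 0.4 < r.optimum_threshold < 0.8

    def test_identical_scores_give_half_aroc(self):
        s = scores_from([0.5] * 10, [1] * 5 + [0] * 5)
        r = roc(s, "positive_high")
        assert r.aroc == pytest.approx(0.5, abs=1e-12)

    def test_aroc_matches_rank_oracle(self, rng):
        for _ in range(50):
            n_pos, n_neg = rng.integers(3, 25, size=2)
            pos = rng.normal(0.5, 0.3, n_pos)
            neg = rng.normal(0.3, 0.3, n_neg)
            # inject ties sometimes
            if rng.random() < 0.3:
                pos = np.round(pos, 1)
                neg = np.round(neg, 1)
            s = scores_from(np.concatenate([pos, neg]), [1] * n_pos + [0] * n_neg)
            r = roc(s, "positive_high")
            assert abs(r.aroc - auc_rank_oracle(pos, neg)) < 1e-12

    def test_polarity_reversal_complements_aroc(self, rng):
        vals = rng.normal(size=30)
        labs = rng.integers(0, 2, size=30)
        labs[:2] = [0, 1]  # both classes present
        s = scores_from(vals, labs)
        a_hi = roc(s, "positive_high").aroc
        a_lo = roc(s, "positive_low").aroc
        assert a_hi + a_lo == pytest.approx(1.0, abs=1e-12)

    def test_optimum_is_exhaustive_maximum(self, rng):
        vals = rng.normal(size=40)
        labs = rng.integers(0, 2, size=40)
        labs[:2] = [0, 1]
        s = scores_from(vals, labs)
        r = roc(s, "positive_high")
        accs = [evaluate_at(s, th, "positive_high")[2] for th in r.thresholds]
        assert r.optimum_acc == max(accs)
        assert evaluate_at(s, r.optimum_threshold, "positive_high")[2] == r.optimum_acc

    def test_single_class_rejected(self):
        with pytest.raises(ClassMissingError):
            roc(scores_from([0.1, 0.2], [1, 1]), "positive_high")


class TestEvaluateAt:
    def test_paper_style_counting_contract(self, rng):
        # 26 positives above the threshold, 22 of 24 negatives below
        pos = rng.uniform(0.90, 1.0, 26)
        neg = np.concatenate([rng.uniform(0.5, 0.85, 22), [0.95, 0.97]])
        s = scores_from(np.concatenate([pos, neg]), [1] * 26 + [0] * 24)
        sens, spec, acc = evaluate_at(s, 0.888, "positive_high")
        assert sens == 26 / 26
        assert spec == 22 / 24
        assert acc == 48 / 50

    def test_threshold_below_all_scores(self):
        s = scores_from([0.2, 0.5, 0.8], [1, 0, 1])
        assert evaluate_at(s, 0.0, "positive_high") == (1.0, 0.0, 2 / 3)

    def test_threshold_above_all_scores(self):
        s = scores_from([0.2, 0.5, 0.8], [1, 0, 1])
        assert evaluate_at(s, 1.0, "positive_high") == (0.0, 1.0, 1 / 3)

    def test_tie_at_threshold_classifies_negative(self):
        s = scores_from([0.5, 0.4], [1, 0])
        sens, spec, _ = evaluate_at(s, 0.5, "positive_high")
        assert sens == 0.0 and spec == 1.0


class TestLoocv:
    def test_perfectly_separated_scores(self):
        s = scores_from([0.9, 0.85, 0.8, 0.3, 0.25, 0.2], [1, 1, 1, 0, 0, 0])
        assert loocv(s, "positive_high") == 1.0

    def test_never_beats_resubstitution_usually(self, rng):
        wins = 0
        for _ in range(200):
            n = int(rng.integers(6, 14))
            vals = rng.normal(size=n)
            labs = rng.integers(0, 2, size=n)
            labs[:2] = [0, 1]
            s = scores_from(vals, labs)
            r = roc(s, "positive_high")
            if loocv(s, "positive_high") <= r.optimum_acc + 1e-12:
                wins += 1
        assert wins >= 190

    def test_two_record_degenerate_case_defined(self):
        s = scores_from([0.8, 0.2], [1, 0])
        assert loocv(s, "positive_high") in (0.0, 0.5, 1.0)

    def test_deterministic(self, rng):
        vals = rng.normal(size=20)
        labs = rng.integers(0, 2, size=20)
        labs[:2] = [0, 1]
        s = scores_from(vals, labs)
        assert loocv(s) == loocv(list(s))


class TestGroupStats:
    def test_identical_groups(self):
        s = scores_from([0.1, 0.2, 0.3, 0.1, 0.2, 0.3], [1, 1, 1, 0, 0, 0])
        st = group_stats(s)
        assert st.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert st.t_p_value == pytest.approx(1.0)
        assert not st.significant

    def test_well_separated_normals(self, rng):
        pos = rng.normal(0, 1, 20)
        neg = rng.normal(5, 1, 20)
        st = group_stats(scores_from(np.concatenate([pos, neg]), [1] * 20 + [0] * 20))
        assert st.t_p_value < 0.001
        assert st.significant

    def test_t_p_matches_closed_form_oracle(self, rng):
        from scipy.special import betainc

        for _ in range(20):
            n1, n2 = rng.integers(4, 15, size=2)
            a = rng.normal(0, 1, n1)
            b = rng.normal(0.5, 1.3, n2)
            st = group_stats(scores_from(np.concatenate([a, b]), [1] * n1 + [0] * n2))
            sp2 = ((n1 - 1) * np.var(a, ddof=1) + (n2 - 1) * np.var(b, ddof=1)) / (n1 + n2 - 2)
            t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
            df = n1 + n2 - 2
            p = betainc(df / 2, 0.5, df / (df + t * t))
            assert abs(st.t_p_value - p) < 1e-10

    def test_small_group_screen_skipped_with_warning(self):
        s = scores_from([0.1, 0.2, 0.4, 0.5], [1, 1, 0, 0])
        st = group_stats(s)
        assert st.shapiro_p_pos is None
        assert st.warnings
        assert np.isfinite(st.t_p_value)


class TestGridSearch:
    def test_single_cell_grid(self, rng):
        vecs = {f"r{i}": rng.normal(size=100) for i in range(6)}
        labels = {f"r{i}": i < 3 for i in range(6)}
        table = grid_search(aa_vectors=vecs, labels=labels, rho_grid=[3.3],
                            families=[WaveletSpec()])
        assert len(table) == 1
        assert set(table.columns) >= {"family", "rho", "p_value", "sensitivity",
                                      "specificity", "accuracy"}

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            grid_search(aa_vectors={"a": rng.normal(size=10)}, labels={"a": True},
                        rho_grid=[])

    def test_families_reach_same_accuracy_on_synthetic_cohort(self):
        # all six bases see the same 4-8 Hz structure, so the discriminant
        # ability should coincide for most cohorts
        from wavectm.classify import grid_search
        from wavectm.pipeline import PipelineConfig, record_ctm
        from wavectm.synth import make_cohort

        specs = [
            WaveletSpec("haar", ""),
            WaveletSpec("daubechies", "5"),
            WaveletSpec("coiflet", "3"),
            WaveletSpec("biorthogonal", "4.4"),
            WaveletSpec("reverse_biorthogonal", "4.4"),
            WaveletSpec("symlet", "5"),
        ]
        agree = 0
        n_rep = 3
        for rep in range(n_rep):
            records, manifest = make_cohort(20, 20, seed=40 + rep)
            labels = manifest.labels_for("stable")
            aa = {
                rec.record_id: record_ctm(rec, PipelineConfig()).aa.samples
                for rec, _, _, _ in records
            }
            table = grid_search(aa_signals=aa, labels=labels, rho_grid=[3.3],
                                families=specs)
            accs = table["accuracy"].to_numpy()
            # same discriminant ability: within one borderline record of each
            # other (1/40 = 0.025) and all strongly discriminating
            agree += (accs.max() - accs.min() <= 0.051) and accs.min() >= 0.9
        assert agree >= n_rep - 1
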
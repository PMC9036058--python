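"""Agreement statistics: cross-tabs, metric panel, kappa (+CI), ordinal AUC."""

import numpy as np
import pytest

from glimscreen.concordance import (
    ContingencyTable2x2,
    auc_ordinal,
    build_crosstab,
    cohens_kappa,
    crosstab_from_totals,
    diagnostic_metrics,
    full_panel,
    kappa_band,
    kappa_ci,
)

NONSURG_NRS = ContingencyTable2x2(tp=40, fp=7, fn=3, tn=30)
SURG_MUST = ContingencyTable2x2(tp=37, fp=24, fn=6, tn=122)
TOTAL_MUST = ContingencyTable2x2(tp=79, fp=31, fn=7, tn=152)


class TestCrosstab:
    def test_from_totals_nrs_rule(self, nonsurgical_fixture_cohort):
        from glimscreen.report import score_cohort

        df = score_cohort(nonsurgical_fixture_cohort)
        table = crosstab_from_totals(
            df["nrs2002_total"].tolist(), df["glim_malnourished"].tolist(),
            positivity_rule="nrs_ge3",
        )
        assert (table.tp, table.fp, table.fn, table.tn) == (40, 7, 3, 30)

    def test_all_negative_well(self):
        table = build_crosstab([False] * 12, [False] * 12)
        assert (table.tp, table.fp, table.fn, table.tn) == (0, 0, 0, 12)

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(1, 60))
            s = rng.random(n) < 0.5
            g = rng.random(n) < 0.4
            table = build_crosstab(s.tolist(), g.tolist())
            tp = sum(1 for a, b in zip(s, g) if a and b)
            fp = sum(1 for a, b in zip(s, g) if a and not b)
            fn = sum(1 for a, b in zip(s, g) if not a and b)
            tn = sum(1 for a, b in zip(s, g) if not a and not b)
            assert (table.tp, table.fp, table.fn, table.tn) == (tp, fp, fn, tn)

    def test_length_mismatch_and_empty(self):
        with pytest.raises(ValueError, match="mismatch"):
            build_crosstab([True], [True, False])
        with pytest.raises(ValueError, match="empty"):
            build_crosstab([], [])

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(tp=-1, fp=0, fn=0, tn=1)


class TestDiagnosticMetrics:
    def test_reference_panel_percentages(self):
        r = diagnostic_metrics(TOTAL_MUST)
        assert r.sensitivity.value * 100 == pytest.approx(91.9, abs=0.05)
        assert r.specificity.value * 100 == pytest.approx(83.1, abs=0.05)
        assert r.ppv.value * 100 == pytest.approx(71.8, abs=0.05)
        assert r.npv.value * 100 == pytest.approx(95.6, abs=0.05)

    def test_perfect_agreement(self):
        r = diagnostic_metrics(ContingencyTable2x2(tp=9, fp=0, fn=0, tn=14))
        assert r.sensitivity.value == 1.0 and r.specificity.value == 1.0
        assert r.lr_neg.value == 0.0
        assert not r.lr_pos.defined and "zero" in r.lr_pos.reason

    def test_likelihood_ratios(self):
        r = diagnostic_metrics(NONSURG_NRS)
        assert round(r.lr_pos.value, 2) == 4.92
        assert round(r.lr_neg.value, 2) == 0.09

    def test_degenerate_metrics_absent_with_reason(self):
        r = diagnostic_metrics(ContingencyTable2x2(tp=0, fp=5, fn=0, tn=10))
        assert not r.sensitivity.defined and r.sensitivity.reason

    def test_round_trip_recovers_cell_counts(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            cells = rng.integers(1, 80, size=4)
            t = ContingencyTable2x2(*map(int, cells))
            r = diagnostic_metrics(t)
            assert round(r.sensitivity.value * (t.tp + t.fn)) == t.tp
            assert round(r.specificity.value * (t.tn + t.fp)) == t.tn


class TestKappa:
    @pytest.mark.parametrize(
        "table,expected",
        [
            (NONSURG_NRS, 0.75),
            (SURG_MUST, 0.61),
            (TOTAL_MUST, 0.70),
            (ContingencyTable2x2(tp=14, fp=0, fn=0, tn=9), 1.0),
            (ContingencyTable2x2(tp=20, fp=20, fn=20, tn=20), 0.0),
        ],
    )
    def test_reference_values(self, table, expected):
        assert round(cohens_kappa(table).value, 2) == expected

    def test_requires_two_subjects(self):
        with pytest.raises(ValueError):
            cohens_kappa(ContingencyTable2x2(tp=1, fp=0, fn=0, tn=0))

    def test_degenerate_chance_agreement(self):
        k = cohens_kappa(ContingencyTable2x2(tp=5, fp=0, fn=0, tn=0))
        assert not k.defined

    def test_relabeling_invariance(self):
        """Swapping both raters' positive class leaves kappa unchanged."""
        rng = np.random.default_rng(2)
        for _ in range(30):
            t = ContingencyTable2x2(*map(int, rng.integers(1, 60, size=4)))
            swapped = ContingencyTable2x2(tp=t.tn, fp=t.fn, fn=t.fp, tn=t.tp)
            assert cohens_kappa(t).value == pytest.approx(
                cohens_kappa(swapped).value, abs=1e-12
            )

    def test_bounded_by_observed_agreement_and_perfect_iff_diagonal(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            t = ContingencyTable2x2(*map(int, rng.integers(0, 40, size=4)))
            if t.n < 2:
                continue
            k = cohens_kappa(t)
            if not k.defined:
                continue
            p_o = (t.tp + t.tn) / t.n
            assert k.value <= p_o + 1e-12
            if t.tp + t.fn > 0 and t.fp + t.tn > 0 and t.tp + t.fp > 0 and t.fn + t.tn > 0:
                assert (abs(k.value - 1.0) < 1e-12) == (t.fp == 0 and t.fn == 0)

    def test_interpretation_bands(self):
        assert kappa_band(0.10) == "none"
        assert kappa_band(0.30) == "minimal"
        assert kappa_band(0.50) == "weak"
        assert kappa_band(0.75) == "moderate"
        assert kappa_band(0.85) == "strong"
        assert kappa_band(0.95) == "almost_perfect"


class TestKappaCI:
    def test_reference_interval(self):
        lo, hi = kappa_ci(NONSURG_NRS, 0.95)
        assert (round(lo, 2), round(hi, 2)) == (0.60, 0.89)

    def test_perfect_agreement_zero_width(self):
        lo, hi = kappa_ci(ContingencyTable2x2(tp=10, fp=0, fn=0, tn=10))
        assert (lo, hi) == (1.0, 1.0)

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            kappa_ci(NONSURG_NRS, 1.5)

    def test_wald_close_to_percentile_bootstrap(self):
        """Wald endpoints within +-0.03 of a 10,000-resample percentile
        bootstrap over 50 random non-degenerate tables."""
        rng = np.random.default_rng(17)
        n_boot = 10_000
        checked = 0
        while checked < 50:
            p = rng.dirichlet([4, 4, 4, 4])
            n = 250
            cells = rng.multinomial(n, p)
            if cells.min() < 5:
                continue
            t = ContingencyTable2x2(*map(int, cells))
            lo, hi = kappa_ci(t, 0.95)

            resamples = rng.multinomial(n, cells / n, size=n_boot).astype(float)
            tp, fp, fn, tn = resamples.T
            p_o = (tp + tn) / n
            p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
            ks = (p_o - p_e) / (1 - p_e)
            blo, bhi = np.percentile(ks, [2.5, 97.5])
            assert abs(lo - blo) < 0.03 and abs(hi - bhi) < 0.03
            checked += 1


class TestAucOrdinal:
    def test_perfect_separation(self):
        auc, _ = auc_ordinal([0, 1, 2, 5, 6, 7], [0, 0, 0, 1, 1, 1])
        assert auc == 1.0

    def test_all_ties(self):
        auc, _ = auc_ordinal([3, 3, 3, 3], [1, 0, 1, 0])
        assert auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_ordinal([1, 2, 3], [True, True, True])

    def test_rank_formula_matches_pair_counting(self):
        """Midrank AUC equals the O(n^2) pair-enumeration oracle to 1e-12."""
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            scores = rng.integers(0, 8, size=n).astype(float)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            auc, _ = auc_ordinal(scores, labels)
            pos = scores[labels]
            neg = scores[~labels]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_roc_points_span_unit_square(self):
        _, pts = auc_ordinal([0, 1, 2, 3, 4], [0, 0, 1, 1, 1])
        assert pts[0][1:] == (0.0, 0.0)
        assert pts[-1][1:] == (1.0, 1.0)

    def test_binarized_auc_equals_mean_of_sens_spec(self):
        """AUC on screen-positive indicators equals (sens + spec)/2 of the
        corresponding 2x2 — the bound that an ordinal score can exceed."""
        rng = np.random.default_rng(31)
        for _ in range(20):
            n = int(rng.integers(10, 80))
            pos = rng.random(n) < 0.5
            glim = rng.random(n) < 0.5
            if glim.all() or not glim.any():
                continue
            table = build_crosstab(pos.tolist(), glim.tolist())
            m = diagnostic_metrics(table)
            if not (m.sensitivity.defined and m.specificity.defined):
                continue
            auc, _ = auc_ordinal(pos.astype(float), glim)
            assert auc == pytest.approx(
                (m.sensitivity.value + m.specificity.value) / 2, abs=1e-12
            )


def test_full_panel_assembles_all_blocks():
    rng = np.random.default_rng(41)
    scores = rng.integers(0, 6, size=60).astype(float)
    glim = (scores + rng.normal(0, 1.5, size=60)) > 2.5
    table = crosstab_from_totals(scores.tolist(), glim.tolist(), "must_ge1")
    panel = full_panel(table, scores=scores, glim_status=glim)
    assert panel.kappa.defined and panel.kappa_ci is not None
    assert panel.auc.defined and panel.auc_band in ("low", "moderate", "high")
    assert panel.kappa_band is not None
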
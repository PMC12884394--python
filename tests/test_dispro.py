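"""Estimator correctness against closed-form and simulation oracles."""

import datetime
import math

import numpy as np
import pytest
from scipy import special, stats

from faersig.cohort import CohortSpec, DrugLexicon, build_reference_set
from faersig.dispro import (
    ContingencyTable,
    MGPSPrior,
    bcpnn_ic,
    build_contingency,
    ebgm_quantile,
    ebgm_score,
    evaluate_signals,
    mgps_fit_prior,
    prr_with_chi2,
    ror_with_ci,
    signal_screen,
)
from faersig.io import JoinedReports

from conftest import demo_frame, drug_frame, reac_frame

T = ContingencyTable(20, 80, 100, 800)


def _reference_ten_reports():
    """10 reports: 4 exposed to carbamazepine, 3 with the PT, 2 overlapping."""
    d = datetime.date(2020, 1, 1)
    demo = demo_frame([dict(primaryid=i, caseid=i, fda_dt=d)
                       for i in range(1, 11)])
    drugs = []
    for i in range(1, 11):
        name = "TEGRETOL" if i <= 4 else "KEPPRA"
        drugs.append((i, name, "", "PS"))
    reacs = [(i, "Male infertility") for i in (1, 2, 5)]
    reacs += [(i, "Rash") for i in range(1, 11)]
    joined = JoinedReports(demo=demo, drug=drug_frame(drugs),
                           reac=reac_frame(reacs))
    return build_reference_set(joined, CohortSpec(), DrugLexicon.default())


class TestContingency:
    def test_enumerated_fixture(self):
        ref = _reference_ten_reports()
        t = build_contingency(ref, "carbamazepine", "Male infertility")
        assert (t.a, t.b, t.c, t.d) == (2, 2, 1, 5)
        assert t.n == 10
        assert t.expected == pytest.approx(4 * 3 / 10)

    def test_absent_pt_gives_empty_event_margin(self):
        ref = _reference_ten_reports()
        t = build_contingency(ref, "carbamazepine", "Azoospermia")
        assert t.a == 0 and t.c == 0

    def test_unexposed_drug_is_error(self):
        ref = _reference_ten_reports()
        with pytest.raises(ValueError, match="no exposed reports"):
            build_contingency(ref, "diazepam", "Male infertility")

    def test_degenerate_all_cells_in_a(self):
        t = ContingencyTable(7, 0, 0, 0)
        assert t.n == 7 and t.expected == 7

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)


class TestRor:
    def test_symmetric_table_is_null(self):
        ror, lo, hi = ror_with_ci(ContingencyTable(10, 90, 10, 90))
        assert ror == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_hand_computed_fixture(self):
        ror, lo, hi = ror_with_ci(T)
        assert ror == pytest.approx(2.0, rel=1e-12)
        se = math.sqrt(1 / 20 + 1 / 80 + 1 / 100 + 1 / 800)
        assert lo == pytest.approx(2.0 * math.exp(-1.959964 * se), rel=1e-12)
        assert hi == pytest.approx(2.0 * math.exp(+1.959964 * se), rel=1e-12)

    def test_haldane_correction_on_zero_cell(self):
        ror, lo, hi = ror_with_ci(ContingencyTable(0, 10, 10, 80))
        assert ror == pytest.approx(0.5 * 80.5 / (10.5 * 10.5), rel=1e-12)
        assert lo < ror < hi

    def test_symmetry_under_drug_event_swap(self):
        swapped = ContingencyTable(T.a, T.c, T.b, T.d)
        assert ror_with_ci(T)[0] == pytest.approx(ror_with_ci(swapped)[0])

    @pytest.mark.parametrize("b,c,d", [(80, 100, 800), (5, 5, 50)])
    def test_monotone_in_a(self, b, c, d):
        rors = [ror_with_ci(ContingencyTable(a, b, c, d))[0]
                for a in range(1, 30)]
        assert all(x < y for x, y in zip(rors, rors[1:]))


class TestPrr:
    def test_hand_computed_fixture(self):
        prr, chi2 = prr_with_chi2(T)
        assert prr == pytest.approx(1.8, rel=1e-12)
        # Yates: N(|ad-bc|-N/2)^2 / [(a+b)(c+d)(a+c)(b+d)]
        expect = 1000 * (abs(20 * 800 - 80 * 100) - 500) ** 2 / (
            100 * 900 * 120 * 880)
        assert chi2 == pytest.approx(expect, rel=1e-12)
        assert chi2 == pytest.approx(5.918560606, rel=1e-9)

    def test_proportional_table_nulls(self):
        prr, chi2 = prr_with_chi2(ContingencyTable(10, 90, 20, 180))
        assert prr == pytest.approx(1.0)
        assert chi2 == 0.0

    def test_empty_event_margin_undefined(self):
        prr, chi2 = prr_with_chi2(ContingencyTable(0, 10, 0, 90))
        assert math.isnan(prr)
        assert chi2 == 0.0

    def test_yates_floor(self):
        # |ad-bc| <= N/2 -> statistic floored at zero, not negative
        _, chi2 = prr_with_chi2(ContingencyTable(5, 50, 10, 99))
        assert chi2 >= 0.0


class TestBcpnn:
    def test_observed_equals_expected_is_zero(self):
        # symmetric margins: E = (1000*1000)/10000 = 100 = a
        t = ContingencyTable(100, 900, 900, 8100)
        ic, ic025 = bcpnn_ic(t)
        assert ic == pytest.approx(0.0, abs=1e-12)
        assert ic025 < 0

    def test_hand_computed_fixture(self):
        ic, ic025 = bcpnn_ic(T)
        assert ic == pytest.approx(math.log2(20.5 / 12.5), rel=1e-12)
        expect025 = ic - 3.3 * 20.5 ** -0.5 - 2.0 * 20.5 ** -1.5
        assert ic025 == pytest.approx(expect025, rel=1e-12)

    def test_exact_mode_agrees_with_gamma_quantile_oracle(self):
        ic, ic025_exact = bcpnn_ic(T, mode="exact")
        oracle = math.log2(stats.gamma.ppf(0.025, 20.5, scale=1 / 12.5))
        assert ic025_exact == pytest.approx(oracle, rel=1e-9)
        _, ic025_approx = bcpnn_ic(T, mode="approx")
        assert abs(ic025_exact - ic025_approx) < 0.15

    def test_ic025_below_ic_everywhere(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            cells = rng.integers(0, 200, size=4)
            if cells.sum() == 0:
                continue
            t = ContingencyTable(*map(int, cells))
            for mode in ("approx", "exact"):
                ic, ic025 = bcpnn_ic(t, mode=mode)
                assert ic025 < ic

    def test_ic_monotone_in_a(self):
        ics = [bcpnn_ic(ContingencyTable(a, 80, 100, 800))[0]
               for a in range(0, 40)]
        assert all(x < y for x, y in zip(ics, ics[1:]))


class TestMgps:
    def test_single_pair_is_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            mgps_fit_prior([3], [1.0])

    def test_nonpositive_expected_is_error(self):
        with pytest.raises(ValueError, match="> 0"):
            mgps_fit_prior([3, 4], [1.0, 0.0])

    def test_single_component_truth_recovered(self):
        # lambda ~ Gamma(2, rate 2): prior mean 1; marginal NB mixture should
        # recover a mixture mean within 20% of 1.0
        rng = np.random.default_rng(11)
        n = 3000
        e = np.exp(rng.uniform(np.log(0.5), np.log(100), n))
        lam = rng.gamma(2.0, 0.5, n)
        a = rng.poisson(lam * e)
        prior = mgps_fit_prior(a, e)
        assert prior.converged
        assert 0.8 < prior.mean < 1.2

    def test_fit_is_deterministic(self):
        rng = np.random.default_rng(3)
        e = np.exp(rng.uniform(0, 3, 200))
        a = rng.poisson(e)
        p1 = mgps_fit_prior(a, e)
        p2 = mgps_fit_prior(a, e)
        assert p1 == p2


class TestEbgm:
    #: equal-component prior: posterior is exactly Gamma(alpha+a, beta+E)
    FLAT = MGPSPrior(alpha1=1.0, beta1=1.0, alpha2=1.0, beta2=1.0, w=0.5)

    def test_closed_form_gamma_posterior(self):
        # a=5, E=1 -> posterior Gamma(6, rate 2); EBGM = exp(psi(6) - ln 2)
        ebgm, eb05 = ebgm_score(5, 1.0, self.FLAT)
        assert ebgm == pytest.approx(math.exp(special.digamma(6) - math.log(2)),
                                     rel=1e-12)
        assert ebgm == pytest.approx(2.754, rel=1e-3)
        assert eb05 == pytest.approx(stats.gamma.ppf(0.05, 6, scale=0.5),
                                     rel=1e-9)
        assert eb05 == pytest.approx(1.31, abs=0.01)

    def test_degenerate_prior_pins_lambda_at_one(self):
        prior = MGPSPrior(alpha1=1e6, beta1=1e6, alpha2=1e6, beta2=1e6, w=0.5)
        for a in (0, 2, 5):
            ebgm, _ = ebgm_score(a, 1.0, prior)
            assert ebgm == pytest.approx(1.0, rel=1e-3)

    def test_posterior_geometric_mean_between_quantiles(self):
        prior = MGPSPrior(alpha1=0.3, beta1=0.2, alpha2=2.0, beta2=4.0, w=0.4)
        for a, e in [(0, 0.5), (3, 1.0), (10, 2.0), (50, 60.0)]:
            ebgm, eb05 = ebgm_score(a, e, prior)
            eb95 = ebgm_quantile(a, e, prior, 0.95)
            assert eb05 <= ebgm <= eb95

    def test_monotone_in_a_at_fixed_e(self):
        prior = MGPSPrior(alpha1=0.3, beta1=0.2, alpha2=2.0, beta2=4.0, w=0.4)
        scores = [ebgm_score(a, 5.0, prior)[0] for a in range(0, 30)]
        assert all(x <= y for x, y in zip(scores, scores[1:]))

    def test_degenerate_fitted_prior_still_yields_quantiles(self):
        # weakly identified fits can push a component to a tiny shape whose
        # quantiles underflow to 0; EB05 must still come back finite
        prior = MGPSPrior(alpha1=math.exp(-12), beta1=math.exp(-12),
                          alpha2=0.8, beta2=1.6, w=0.4)
        for a, e in [(0, 0.03), (1, 0.5), (4, 9.0)]:
            ebgm, eb05 = ebgm_score(a, e, prior)
            assert np.isfinite(ebgm) and np.isfinite(eb05)
            assert 0.0 <= eb05 <= ebgm

    def test_nonconverged_prior_refused(self):
        bad = MGPSPrior(alpha1=1, beta1=1, alpha2=1, beta2=1, w=0.5,
                        converged=False)
        with pytest.raises(ValueError, match="did not converge"):
            ebgm_score(3, 1.0, bad)
        ebgm_score(3, 1.0, bad, allow_nonconverged=True)


class TestCriteria:
    @pytest.mark.parametrize("ror_lo,ic025,expected", [
        (5.54, 2.45, True),    # strong published signal
        (1.25, 0.37, True),    # weakest published positive
        (0.99, 0.37, False),   # ROR bound fails
        (1.25, 0.0, False),    # IC bound fails (strict >)
    ])
    def test_joint_ror_bcpnn_criterion(self, ror_lo, ic025, expected):
        flags = evaluate_signals(a=10, ror_lo95=ror_lo, ic025=ic025,
                                 prr=float("nan"), chi2=0.0, eb05=None)
        assert flags["ror_bcpnn_positive"] is expected

    def test_prr_minimum_case_clause(self):
        flags = evaluate_signals(a=2, ror_lo95=9.0, ic025=3.0, prr=10.0,
                                 chi2=20.0, eb05=None)
        assert flags["prr_positive"] is False
        flags = evaluate_signals(a=3, ror_lo95=9.0, ic025=3.0, prr=10.0,
                                 chi2=20.0, eb05=None)
        assert flags["prr_positive"] is True

    def test_ebgm_criterion(self):
        assert evaluate_signals(5, 2.0, 1.0, 3.0, 5.0, eb05=2.01)[
            "ebgm_positive"] is True
        assert evaluate_signals(5, 2.0, 1.0, 3.0, 5.0, eb05=2.0)[
            "ebgm_positive"] is False
        assert evaluate_signals(5, 2.0, 1.0, 3.0, 5.0, eb05=None)[
            "ebgm_positive"] is False


class TestScreen:
    def test_null_false_positive_rate_bounded(self):
        """Independent drug/event pairs: ROR lower bound exceeds 1 rarely.

        2,000 null tables at fixed seed; the one-sided asymptotic rate is
        2.5%, allow 7.5% for small-sample effects.
        """
        rng = np.random.default_rng(2024)
        n, p_drug, p_event = 10000, 0.1, 0.02
        hits = 0
        for _ in range(2000):
            drug = rng.random(n) < p_drug
            event = rng.random(n) < p_event
            t = ContingencyTable(int((drug & event).sum()),
                                 int((drug & ~event).sum()),
                                 int((~drug & event).sum()),
                                 int((~drug & ~event).sum()))
            _, lo, _ = ror_with_ci(t)
            hits += lo > 1.0
        assert hits / 2000 <= 0.075

    def test_screen_frame_shape_and_flags(self):
        ref = _reference_ten_reports()
        out = signal_screen(ref, "Male infertility", fit_mgps=True)
        assert set(out["drug"]) == {"carbamazepine", "levetiracetam"}
        assert {"ror", "ror_lo95", "prr", "chi2", "ic", "ic025",
                "ebgm", "eb05", "ror_bcpnn_positive"} <= set(out.columns)
        row = out.set_index("drug").loc["carbamazepine"]
        assert row["a"] == 2
        # interval invariants
        assert row["ror_lo95"] <= row["ror"] <= row["ror_hi95"]
        assert row["ic025"] <= row["ic"]
        assert row["eb05"] <= row["ebgm"]
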
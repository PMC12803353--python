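import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ratiomap import assoc, preprocess as pp, repsurv, synthdata as sd
from ratiomap.datatypes import GenotypeMatrix, TraitMatrix
from ratiomap.errors import DataError, DegenerateColumnError, ValidationError


def _assoc(variant, nlp, beta=0.1):
    return assoc.AssociationResult(
        variant=variant, test=pp.TestId.single("T1"), beta=beta, se=0.01,
        t_stat=beta / 0.01, neglog10_p=nlp, n=1000, df=995,
    )


class TestReplicationTest:
    def test_446_loci_threshold(self):
        # p = 1e-5 against 0.05/446 ~ 1.12e-4 -> replicated
        disc = {"L1": _assoc("L1", 15.0)}
        rep = {"L1": _assoc("L1", 5.0)}
        (res,) = repsurv.replication_test(rep, disc, n_discovered=446)
        assert res.threshold_neglog10 == pytest.approx(-math.log10(0.05 / 446))
        assert res.replicated

    def test_boundary_is_strict(self):
        thr = -math.log10(0.05 / 10)
        disc = {"L1": _assoc("L1", 15.0)}
        rep = {"L1": _assoc("L1", thr)}
        (res,) = repsurv.replication_test(rep, disc, n_discovered=10)
        assert not res.replicated

    def test_single_locus_plain_threshold(self):
        disc = {"L1": _assoc("L1", 15.0)}
        rep = {"L1": _assoc("L1", 1.5)}
        (res,) = repsurv.replication_test(rep, disc, n_discovered=1)
        assert res.threshold_neglog10 == pytest.approx(-math.log10(0.05))
        assert res.replicated

    def test_missing_replication_reported_untested(self):
        disc = {"L1": _assoc("L1", 15.0), "L2": _assoc("L2", 12.0)}
        rep = {"L1": _assoc("L1", 5.0)}
        results = {r.locus: r for r in repsurv.replication_test(rep, disc, 2)}
        assert results["L2"].tested is False and not results["L2"].replicated

    def test_order_invariance(self):
        disc = {f"L{i}": _assoc(f"L{i}", 15.0) for i in range(5)}
        rep = {f"L{i}": _assoc(f"L{i}", float(i)) for i in range(5)}
        a = {r.locus: r.replicated for r in repsurv.replication_test(rep, disc, 5)}
        rev = dict(reversed(list(disc.items())))
        b = {r.locus: r.replicated for r in repsurv.replication_test(rep, rev, 5)}
        assert a == b


@pytest.fixture(scope="module")
def power_cohort():
    # one variant with an effect calibrated for ~80% power at n_sub=2,000
    # and alpha=0.05: theta * sqrt(n * 2 maf (1-maf)) = z_.975 + z_.80
    n, maf = 50_000, 0.3
    theta = (1.959964 + 0.841621) / math.sqrt(2000 * 2 * maf * (1 - maf))
    specs = [sd.VariantSpec("v1", maf, "confounded", theta, 0.0, ("T1", "T2"))]
    geno = sd.simulate_genotypes(n, specs, seed=500)
    cfg = sd.CohortConfig(n_samples=n, n_traits=2, lam=0.0, sigma_trait=1.0,
                          sigma_confounder=0.5, seed=501, na_rate=0.0, zero_rate=0.0,
                          beta_age=0.0, beta_sex=0.0, beta_medication=0.0)
    panel, _, _ = sd.simulate_cohort(geno, specs, cfg)
    return geno, pp.log_transform(panel), theta


class TestReplicationPower:
    def test_full_cohort_degenerate(self, power_cohort):
        geno, logged, _ = power_cohort
        out = repsurv.replication_power(
            logged, geno, None, [("v1", pp.TestId.single("T1"))],
            n_sub=logged.n_samples, threshold_neglog10=-math.log10(0.05),
            n_reps=5, seed=1,
        )
        assert float(out.loc["v1", "power"]) in (0.0, 1.0)

    def test_null_calibration(self):
        specs = [sd.VariantSpec("v1", 0.3)]
        geno = sd.simulate_genotypes(3000, specs, seed=600)
        cfg = sd.CohortConfig(n_samples=3000, n_traits=2, seed=601,
                              na_rate=0.0, zero_rate=0.0)
        panel, _, _ = sd.simulate_cohort(geno, specs, cfg)
        logged = pp.log_transform(panel)
        out = repsurv.replication_power(
            logged, geno, None, [("v1", pp.TestId.single("T1"))],
            n_sub=500, threshold_neglog10=-math.log10(0.05), n_reps=400, seed=2,
        )
        assert abs(float(out.loc["v1", "power"]) - 0.05) < 0.05

    def test_closed_form_power(self, power_cohort):
        # subsampling estimates power conditional on the realized cohort
        # effect, so the oracle is the normal-approximation power
        # Phi(-z_.975 + |t_full| * sqrt(n_sub / n_full)) evaluated at the
        # full-cohort fit; the planted theta was tuned for ~0.80
        geno, logged, theta = power_cohort
        full = assoc.fit_linear_assoc(
            pp.phenotype(logged, pp.TestId.single("T1")), geno.dosage("v1"))
        planted = stats.norm.cdf(-1.959964 + (theta) * math.sqrt(2000 * 2 * 0.3 * 0.7))
        assert planted == pytest.approx(0.80, abs=0.01)
        predicted = stats.norm.cdf(
            -1.959964 + abs(full.t_stat) * math.sqrt(2000 / logged.n_samples))
        out = repsurv.replication_power(
            logged, geno, None, [("v1", pp.TestId.single("T1"))],
            n_sub=2000, threshold_neglog10=-math.log10(0.05), n_reps=400, seed=3,
        )
        assert abs(float(out.loc["v1", "power"]) - predicted) < 0.05

    def test_monotone_in_n_sub(self, power_cohort):
        geno, logged, _ = power_cohort
        powers = []
        for n_sub in (500, 2000, 4500):
            out = repsurv.replication_power(
                logged, geno, None, [("v1", pp.TestId.single("T1"))],
                n_sub=n_sub, threshold_neglog10=-math.log10(0.05), n_reps=60, seed=4,
            )
            powers.append(float(out.loc["v1", "power"]))
        assert powers[0] <= powers[1] + 0.1 and powers[1] <= powers[2] + 0.1

    def test_seed_determinism(self, power_cohort):
        geno, logged, _ = power_cohort
        kw = dict(n_sub=800, threshold_neglog10=1.3, n_reps=10, seed=9)
        a = repsurv.replication_power(logged, geno, None, [("v1", pp.TestId.single("T1"))], **kw)
        b = repsurv.replication_power(logged, geno, None, [("v1", pp.TestId.single("T1"))], **kw)
        pd.testing.assert_frame_equal(a, b)

    def test_n_sub_validation(self, power_cohort):
        geno, logged, _ = power_cohort
        with pytest.raises(ValidationError):
            repsurv.replication_power(
                logged, geno, None, [("v1", pp.TestId.single("T1"))],
                n_sub=logged.n_samples + 1, threshold_neglog10=1.3, seed=0,
            )


class TestIncidentEventFlag:
    def test_incident(self):
        assert repsurv.incident_event_flag("2015-01-02", "2010-06-01") == "incident"

    def test_same_day_is_prevalent(self):
        assert repsurv.incident_event_flag("2010-06-01", "2010-06-01") == "prevalent"

    def test_absent_event(self):
        assert repsurv.incident_event_flag(None, "2010-06-01") == "none"
        assert repsurv.incident_event_flag("", "2010-06-01") == "none"

    def test_unparseable_date_names_sample(self):
        with pytest.raises(DataError, match="S42"):
            repsurv.incident_event_flag("not-a-date", "2010-06-01", sample="S42")


class TestMedianSplitGroups:
    def test_split_rule_ties_go_low(self):
        values = np.arange(1.0, 11.0)
        groups = repsurv.median_split_groups(values, np.zeros(10, dtype=bool))
        assert (groups == "high_nomed").sum() == 5
        assert (groups == "low_nomed").sum() == 5
        # the median itself (5.5 between 5 and 6): 5 goes low
        odd = repsurv.median_split_groups(np.arange(1.0, 10.0), np.zeros(9, dtype=bool))
        assert odd[4] == "low_nomed"  # value 5 == median -> low

    def test_four_groups(self):
        values = np.array([1.0, 2.0, 3.0, 4.0])
        med = np.array([True, False, True, False])
        groups = repsurv.median_split_groups(values, med)
        assert set(groups) == {"low_med", "low_nomed", "high_med", "high_nomed"}

    def test_all_excluded(self):
        with pytest.raises(ValidationError):
            repsurv.median_split_groups(np.arange(5.0), np.zeros(5, bool),
                                        exclusions=np.ones(5, bool))

    def test_constant_trait(self):
        with pytest.raises(DegenerateColumnError):
            repsurv.median_split_groups(np.ones(5), np.zeros(5, bool))

    def test_group_sizes_match_recount(self, rng):
        values = rng.normal(size=500)
        med = rng.random(500) < 0.3
        excl = rng.random(500) < 0.1
        groups = repsurv.median_split_groups(values, med, excl)
        cut = np.median(values[~excl])
        for label, expected in {
            "high_med": ((values > cut) & med & ~excl).sum(),
            "low_nomed": ((values <= cut) & ~med & ~excl).sum(),
        }.items():
            assert (groups == label).sum() == expected


class TestKmRisk:
    def test_no_events(self):
        est = repsurv.km_risk(np.full(20, 12.0), np.zeros(20, bool), horizon=10)
        assert est.risk == 0.0

    def test_no_censoring_reduces_to_empirical_cdf(self, rng):
        times = rng.uniform(0, 9, 50)
        events = np.ones(50, dtype=bool)
        est = repsurv.km_risk(times, events, horizon=10)
        assert est.risk == pytest.approx(1.0, abs=1e-12)
        # partial events, everyone else followed to the horizon
        times2 = np.r_[rng.uniform(0, 9, 30), np.full(70, 10.0)]
        events2 = np.r_[np.ones(30, bool), np.zeros(70, bool)]
        est2 = repsurv.km_risk(times2, events2, horizon=10)
        assert est2.risk == pytest.approx(0.30, abs=1e-12)

    def test_toy_product_limit_oracle(self):
        # n=10: events at 1,2,4; censored at 3,5; five at risk past horizon
        # S(10) = (9/10)(8/9)(6/7) = 24/35; risk = 11/35
        times = np.array([1, 2, 4, 3, 5] + [12] * 5, dtype=float)
        events = np.array([1, 1, 1, 0, 0] + [0] * 5, dtype=bool)
        est = repsurv.km_risk(times, events, horizon=10)
        assert est.risk == pytest.approx(11 / 35, abs=1e-12)

    def test_against_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        times = rng.exponential(8.0, 300)
        censor = rng.uniform(0, 15, 300)
        observed = np.minimum(times, censor)
        events = times <= censor
        est = repsurv.km_risk(observed, events, horizon=10)
        kmf = KaplanMeierFitter().fit(np.minimum(observed, 10.0),
                                      events & (observed <= 10.0))
        assert est.risk == pytest.approx(1 - float(kmf.predict(10.0)), abs=1e-10)
        ci = kmf.confidence_interval_survival_function_
        assert est.ci95[0] <= est.risk <= est.ci95[1]

    def test_ci_ordering_and_bounds(self, rng):
        times = rng.exponential(20.0, 100)
        events = np.ones(100, dtype=bool)
        est = repsurv.km_risk(times, events, horizon=10)
        assert 0.0 <= est.ci95[0] <= est.risk <= est.ci95[1] <= 1.0

    def test_from_simulated_outcomes(self):
        out = sd.simulate_outcomes(20_000, np.zeros(20_000), 0.0, 0.02, 10.0,
                                   prevalent_fraction=0.05, seed=77)
        times, events, prevalent = repsurv.outcome_times(out, 10.0)
        est = repsurv.km_risk(times[~prevalent], events[~prevalent], horizon=10.0)
        expected = 1 - math.exp(-0.02 * 10)
        assert abs(est.risk - expected) < 0.01


class TestReplicationSummary:
    def test_published_rate(self):
        results = []
        for i in range(163):
            r = repsurv.ReplicationResult(f"L{i}", 15.0, 5.0, 3.0, replicated=i < 140)
            r.power = 0.9
            results.append(r)
        low = repsurv.ReplicationResult("weak", 15.0, 5.0, 3.0, replicated=False)
        low.power = 0.1
        results.append(low)
        n_pow, n_rep, rate = repsurv.replication_summary(results)
        assert (n_pow, n_rep, rate) == (163, 140, 85.9)

    def test_empty(self):
        assert repsurv.replication_summary([]) == (0, 0, 0.0)


class TestEndToEndReplication:
    def test_powered_loci_mostly_replicate(self):
        # discovery/replication split with a strong planted effect: loci
        # with estimated power > 0.8 should replicate at >= 0.8 - MC slack
        n = 6000
        specs = [
            sd.VariantSpec("v1", 0.3, "confounded", 0.25, 0.0, ("T1", "T2")),
            sd.VariantSpec("v2", 0.3, "confounded", 0.25, 0.0, ("T2", "T1")),
        ]
        geno = sd.simulate_genotypes(n, specs, seed=800)
        cfg = sd.CohortConfig(n_samples=n, n_traits=2, lam=0.0, sigma_trait=1.0,
                              sigma_confounder=0.5, seed=801, na_rate=0.0, zero_rate=0.0)
        panel, _, _ = sd.simulate_cohort(geno, specs, cfg)
        logged = pp.log_transform(panel)
        rng = np.random.default_rng(802)
        rep_idx = rng.choice(n, 1500, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[rep_idx] = True
        disc_traits = TraitMatrix(logged.data.loc[~mask], "log")
        rep_traits = TraitMatrix(logged.data.loc[mask], "log")
        disc_geno = GenotypeMatrix(geno.data.loc[~mask])
        thr = -math.log10(0.05 / 2)
        loci = [("v1", pp.TestId.single("T1")), ("v2", pp.TestId.single("T2"))]
        power = repsurv.replication_power(disc_traits, disc_geno, None, loci,
                                          n_sub=1500, threshold_neglog10=thr,
                                          n_reps=25, seed=803)
        disc, rep = {}, {}
        for vid, test in loci:
            disc[vid] = assoc.fit_linear_assoc(
                pp.phenotype(disc_traits, test), geno.dosage(vid)[~mask], variant=vid, test=test)
            rep[vid] = assoc.fit_linear_assoc(
                pp.phenotype(rep_traits, test), geno.dosage(vid)[mask], variant=vid, test=test)
        results = repsurv.replication_test(rep, disc, 2)
        for r in results:
            r.power = float(power.loc[r.locus, "power"])
        powered = [r for r in results if r.power > 0.8]
        assert powered  # effects were planted to be well-powered
        assert sum(r.replicated for r in powered) / len(powered) >= 0.8
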
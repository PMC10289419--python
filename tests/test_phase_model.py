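import numpy as np
import pytest

from conftest import simulate_phase_dates
from oracles import total_variation, two_phase_marginals
from shelterchron.calibrate import RadiocarbonDate
from shelterchron.phase_model import (
    ChronologyPosterior,
    InfeasibleModelError,
    ModelSpec,
    ModelSpecError,
    PhaseSpec,
    SamplerSettings,
    agreement_index,
    agreement_indices,
    boundary_hpds,
    build_model,
    exclusion_ledger,
    phase_durations,
    sample_posterior,
    screen_outliers,
    split_rhat,
)


def two_phase_spec(members1, members2, window=(6_500.0, 4_000.0), **sampler_kw):
    sampler = SamplerSettings(**sampler_kw) if sampler_kw else SamplerSettings()
    return ModelSpec(
        phases=(
            PhaseSpec("p1", "gap", tuple(members1)),
            PhaseSpec("p2", "gap", tuple(members2)),
        ),
        window=window,
        sampler=sampler,
    )


class TestSpecValidation:
    def test_oldest_phase_must_open_with_gap(self):
        with pytest.raises(ModelSpecError, match="gap"):
            ModelSpec(phases=(PhaseSpec("p", "shared_with_previous", ("A",)),))

    def test_duplicate_members_rejected(self):
        with pytest.raises(ModelSpecError, match="more than one phase"):
            two_phase_spec(("A", "B"), ("B",))

    def test_window_must_be_oldest_first(self):
        with pytest.raises(ModelSpecError, match="window"):
            ModelSpec(phases=(PhaseSpec("p", "gap", ("A",)),), window=(100.0, 5_000.0))

    def test_empty_phase_and_bad_boundary_type(self):
        with pytest.raises(ModelSpecError, match="empty"):
            PhaseSpec("p", "gap", ())
        with pytest.raises(ModelSpecError, match="start_boundary"):
            PhaseSpec("p", "before", ("A",))

    def test_fixed_start_must_predate_fixed_end(self):
        with pytest.raises(ModelSpecError, match="older"):
            PhaseSpec("p", "gap", ("A",), fixed_start=4_000.0, fixed_end=4_500.0)


class TestBuildModel:
    def test_member_lookup_and_phase_assignment(self, identity_curve):
        dates = [
            RadiocarbonDate("A", 5_400.0, 25.0),
            RadiocarbonDate("B", 5_300.0, 25.0),
            RadiocarbonDate("C", 4_900.0, 25.0),
        ]
        model = build_model(dates, two_phase_spec(("A", "B"), ("C",)), identity_curve)
        assert model.n_dates == 3
        assert model.counts_per_phase() == {"p1": 2, "p2": 1}
        assert list(model.phase_of_date) == [0, 0, 1]
        assert model.intercepts[0] == pytest.approx(5_400.0, abs=5.0)

    def test_unknown_lab_id_rejected(self, identity_curve):
        with pytest.raises(ModelSpecError, match="unknown lab id"):
            build_model([RadiocarbonDate("A", 5_000.0, 25.0)], two_phase_spec(("A",), ("Z",)), identity_curve)

    def test_non_intact_member_rejected(self, identity_curve):
        dates = [
            RadiocarbonDate("A", 5_400.0, 25.0),
            RadiocarbonDate("B", 4_900.0, 25.0, context_status="disturbed"),
        ]
        with pytest.raises(ModelSpecError, match="intact"):
            build_model(dates, two_phase_spec(("A",), ("B",)), identity_curve)


class TestExclusionLedger:
    @staticmethod
    def census(n_intact, n_disturbed, n_pre, n_modern, n_missing):
        dates, k = [], 0
        for status, n in (
            ("intact", n_intact), ("disturbed", n_disturbed), ("pre_occupation", n_pre),
            ("modern", n_modern), ("missing_provenience", n_missing),
        ):
            for _ in range(n):
                dates.append(RadiocarbonDate(f"D{k}", 5_000.0, 25.0, context_status=status))
                k += 1
        return dates

    def test_counts_by_category_and_conservation(self):
        dates = self.census(300, 68, 2, 2, 3)
        ledger = exclusion_ledger(dates, agreement_excluded=[f"D{i}" for i in range(7)])
        n = ledger.set_index("category")["n"]
        assert n["poor_agreement"] == 7
        assert n["disturbed"] == 68
        assert n["total_excluded"] == 82
        assert n["included"] == 293
        assert n["included"] + n["total_excluded"] == 375

    def test_inconsistent_stated_sample_size_is_surfaced_not_reconciled(self):
        dates = self.census(300, 68, 2, 2, 3)
        ledger = exclusion_ledger(
            dates, agreement_excluded=[f"D{i}" for i in range(7)], model_count=292
        )
        row = ledger[ledger["category"] == "included"].iloc[0]
        assert row["n"] == 293  # arithmetic is never silently adjusted
        assert "tension" in row["description"]
        assert "292" in row["description"]

    def test_consistent_model_count_carries_no_note(self):
        ledger = exclusion_ledger(self.census(10, 2, 0, 0, 0), model_count=10)
        row = ledger[ledger["category"] == "included"].iloc[0]
        assert "tension" not in row["description"]


class TestSamplerCorrectness:
    def test_flat_prior_reduces_to_single_date_calibration(self, identity_curve):
        # with both boundaries pinned far away, the theta posterior must match
        # the single-date calibrated density (TV distance on the model grid)
        spec = ModelSpec(
            phases=(PhaseSpec("only", "gap", ("A",), fixed_start=5_900.0, fixed_end=4_100.0),),
            window=(6_000.0, 4_000.0),
            sampler=SamplerSettings(iterations=200_000, burn_in=5_000, thinning=4, seed=3),
        )
        model = build_model([RadiocarbonDate("A", 5_000.0, 30.0)], spec, identity_curve)
        post = sample_posterior(model)
        dens = model.densities[0]
        assert total_variation(post.theta_draws[:, 0], dens.grid, dens.mass) < 0.02

    def test_two_phase_means_match_brute_force_oracle(self, identity_curve):
        r1, s1, r2, s2 = 5_000.0, 30.0, 4_000.0, 30.0
        window = (6_000.0, 3_000.0)
        g, m1, m2 = two_phase_marginals(r1, s1, r2, s2, window, m=240)
        spec = two_phase_spec(("A",), ("B",), window=window, iterations=60_000, burn_in=5_000, thinning=5, seed=1)
        dates = [RadiocarbonDate("A", r1, s1), RadiocarbonDate("B", r2, s2)]
        post = sample_posterior(build_model(dates, spec, identity_curve))
        for k, mass in ((0, m1), (1, m2)):
            assert post.theta_draws[:, k].mean() == pytest.approx(float((g * mass).sum()), abs=10.0)

    def test_every_retained_draw_satisfies_the_ordering_chain(self, identity_curve, rng):
        dates = (
            simulate_phase_dates(rng, "P1", 6_000, 5_500, 10)
            + simulate_phase_dates(rng, "P2", 5_000, 4_700, 10)
            + simulate_phase_dates(rng, "P3", 4_400, 4_300, 10)
        )
        spec = ModelSpec(
            phases=(
                PhaseSpec("P1", "gap", tuple(d.lab_id for d in dates[:10])),
                PhaseSpec("P2", "gap", tuple(d.lab_id for d in dates[10:20])),
                PhaseSpec("P3", "shared_with_previous", tuple(d.lab_id for d in dates[20:])),
            ),
            window=(8_000.0, 3_000.0),
            sampler=SamplerSettings(iterations=4_000, burn_in=2_000, thinning=4, seed=5),
        )
        model = build_model(dates, spec, identity_curve)
        post = sample_posterior(model)
        a, b, th = post.alpha_draws, post.beta_draws, post.theta_draws
        for p in range(3):
            sel = model.phase_of_date == p
            assert np.all(a[:, p : p + 1] >= th[:, sel])
            assert np.all(th[:, sel] >= b[:, p : p + 1])
            assert np.all(a[:, p] >= b[:, p])
        assert np.all(b[:, 0] >= a[:, 1])           # gap: double boundary
        assert np.array_equal(b[:, 1], a[:, 2])     # shared: one parameter
        assert np.all(a[:, 0] <= 8_000.0) and np.all(b[:, 2] >= 3_000.0)

    def test_same_seed_reproduces_draws_exactly(self, identity_curve, rng):
        dates = simulate_phase_dates(rng, "P", 5_400, 5_000, 8)
        spec = ModelSpec(
            phases=(PhaseSpec("P", "gap", tuple(d.lab_id for d in dates)),),
            window=(7_000.0, 4_000.0),
            sampler=SamplerSettings(iterations=2_000, burn_in=500, thinning=2, seed=17),
        )
        model = build_model(dates, spec, identity_curve)
        a = sample_posterior(model)
        b = sample_posterior(model)
        assert np.array_equal(a.theta_draws, b.theta_draws)
        assert np.array_equal(a.alpha_draws, b.alpha_draws)

    def test_contradictory_fixed_boundaries_are_diagnosed(self, identity_curve):
        dates = [RadiocarbonDate("A", 5_400.0, 25.0), RadiocarbonDate("B", 4_900.0, 25.0)]
        spec = ModelSpec(
            phases=(
                PhaseSpec("p1", "gap", ("A",), fixed_end=4_000.0),
                PhaseSpec("p2", "gap", ("B",), fixed_start=4_500.0),  # older than p1's end
            ),
            window=(6_500.0, 3_000.0),
            sampler=SamplerSettings(iterations=100, burn_in=10),
        )
        model = build_model(dates, spec, identity_curve)
        with pytest.raises(ModelSpecError, match="ordering chain"):
            sample_posterior(model)

    def test_pinned_boundaries_without_room_are_infeasible(self, identity_curve):
        spec = ModelSpec(
            phases=(PhaseSpec("p", "gap", ("A",), fixed_start=5_000.0, fixed_end=4_999.999),),
            window=(6_000.0, 4_000.0),
            sampler=SamplerSettings(iterations=100, burn_in=10),
        )
        model = build_model([RadiocarbonDate("A", 5_000.0, 25.0)], spec, identity_curve)
        with pytest.raises(InfeasibleModelError):
            sample_posterior(model)


class TestBoundaryRecovery:
    def test_pooled_hpd_coverage_across_replicates(self, identity_curve):
        """95.4% HPDs of the six boundaries cover truth >= 90% pooled over 20 sims."""
        truth = [("P1", 6_000.0, 5_500.0), ("P2", 5_000.0, 4_700.0), ("P3", 4_400.0, 4_300.0)]
        settings = SamplerSettings(iterations=8_000, burn_in=3_000, thinning=5)
        covered = total = 0
        for rep in range(20):
            rng = np.random.default_rng(1_000 + rep)
            dates, phases = [], []
            for name, start, end in truth:
                ds = simulate_phase_dates(rng, name, start, end, 20)
                dates.extend(ds)
                phases.append(PhaseSpec(name, "gap", tuple(d.lab_id for d in ds)))
            spec = ModelSpec(phases=tuple(phases), window=(8_000.0, 3_000.0), sampler=settings)
            model = build_model(dates, spec, identity_curve)
            post = sample_posterior(model, SamplerSettings(
                iterations=settings.iterations, burn_in=settings.burn_in,
                thinning=settings.thinning, seed=rep,
            ))
            hpds = boundary_hpds(post, 0.954)
            for name, start, end in truth:
                for key, val in (("start", start), ("end", end)):
                    older, younger = hpds[name][key]
                    covered += younger <= val <= older
                    total += 1
        assert total == 120
        assert covered / total >= 0.90


class TestAgreement:
    def test_identical_densities_score_exactly_100(self, rng):
        p = rng.random(200)
        p /= p.sum()
        assert agreement_index(p, p) == pytest.approx(100.0)

    def test_half_overlapping_uniform_densities_score_50(self):
        p = np.zeros(200)
        p[:100] = 1.0 / 100.0
        p_prime = np.zeros(200)
        p_prime[75:125] = 1.0 / 50.0  # 25 of 50 cells overlap p's support
        assert agreement_index(p, p_prime) == pytest.approx(50.0)

    def test_disjoint_densities_score_zero(self):
        p = np.zeros(10)
        p[:5] = 0.2
        q = np.zeros(10)
        q[5:] = 0.2
        assert agreement_index(p, q) == 0.0

    def test_coherent_model_keeps_high_agreement(self, identity_curve, rng):
        dates = simulate_phase_dates(rng, "P", 5_400, 5_000, 12)
        spec = ModelSpec(
            phases=(PhaseSpec("P", "gap", tuple(d.lab_id for d in dates)),),
            window=(7_000.0, 4_000.0),
            sampler=SamplerSettings(iterations=6_000, burn_in=3_000, thinning=5, seed=2),
        )
        model = build_model(dates, spec, identity_curve)
        post = sample_posterior(model)
        a_i, a_model, a_overall = agreement_indices(post, model)
        assert (a_i > 60.0).all()
        assert a_model > 60.0
        assert a_model == a_overall  # same combined formula over the same dates


class TestOutlierScreening:
    @staticmethod
    def coherent_site(rng):
        d1 = simulate_phase_dates(rng, "P1", 5_500, 5_200, 8)
        d2 = simulate_phase_dates(rng, "P2", 5_100, 4_800, 8)
        return d1, d2

    def test_no_removal_when_all_dates_agree(self, identity_curve, rng):
        d1, d2 = self.coherent_site(rng)
        spec = two_phase_spec(
            [d.lab_id for d in d1], [d.lab_id for d in d2],
            iterations=6_000, burn_in=3_000, thinning=5, seed=11,
        )
        removed, post, model = screen_outliers(d1 + d2, spec, identity_curve)
        assert removed == []
        assert model.n_dates == 16

    def test_shifted_date_crossing_previous_phase_is_removed_first(self, identity_curve, rng):
        d1, d2 = self.coherent_site(rng)
        # a measurement 500 14C yr too old: its age falls inside the previous
        # phase, which the ordering chain cannot accommodate
        outlier = RadiocarbonDate("OUT", float(rng.normal(4_950 + 500, 25)), 25.0)
        spec = two_phase_spec(
            [d.lab_id for d in d1], [d.lab_id for d in d2] + ["OUT"],
            iterations=6_000, burn_in=3_000, thinning=5, seed=11,
        )
        removed, post, model = screen_outliers(d1 + d2 + [outlier], spec, identity_curve)
        assert removed == ["OUT"]
        assert "OUT" not in post.lab_ids
        a_i, _, _ = agreement_indices(post, model)
        assert (a_i >= 60.0).all()

    def test_zero_threshold_disables_screening(self, identity_curve, rng):
        d1, d2 = self.coherent_site(rng)
        outlier = RadiocarbonDate("OUT", 5_450.0, 25.0)
        spec = two_phase_spec(
            [d.lab_id for d in d1], [d.lab_id for d in d2] + ["OUT"],
            iterations=1_000, burn_in=500, thinning=5, seed=11,
        )
        removed, _, model = screen_outliers(d1 + d2 + [outlier], spec, identity_curve, threshold=0.0)
        assert removed == []
        assert model.n_dates == 17

    def test_runaway_removal_aborts(self, identity_curve, rng):
        # two mutually incompatible blocks assigned to the wrong order: the
        # screen would have to gut the model, which must abort loudly
        d1 = simulate_phase_dates(rng, "P1", 4_500, 4_300, 5)
        d2 = simulate_phase_dates(rng, "P2", 5_500, 5_300, 5)
        spec = two_phase_spec(
            [d.lab_id for d in d1], [d.lab_id for d in d2],
            window=(7_000.0, 3_000.0),
            iterations=2_000, burn_in=1_000, thinning=5, seed=11,
        )
        with pytest.raises(RuntimeError, match="aborting"):
            screen_outliers(d1 + d2, spec, identity_curve, max_fraction=0.2)


class TestPosteriorSummaries:
    @staticmethod
    def toy_posterior():
        rng = np.random.default_rng(8)
        n = 4_000
        alpha = np.stack([rng.normal(2_225.0, 10.0, n)], axis=1)
        beta = np.stack([rng.normal(2_080.0, 10.0, n)], axis=1)
        theta = rng.normal(2_150.0, 20.0, (n, 2))
        return ChronologyPosterior(["A", "B"], ["P"], theta, alpha, beta, {})

    def test_phase_duration_from_mean_boundaries(self):
        post = self.toy_posterior()
        durations = phase_durations(post)
        start, end = durations["P"]
        assert start == pytest.approx(2_225.0, abs=1.0)
        assert end == pytest.approx(2_080.0, abs=1.0)
        assert start - end == pytest.approx(145.0, abs=2.0)

    def test_summaries_table_covers_every_parameter(self):
        df = self.toy_posterior().summaries()
        assert set(df["parameter"]) == {"theta[A]", "theta[B]", "alpha[P]", "beta[P]"}
        assert (df["hpd954_older"] >= df["hpd954_younger"]).all()
        assert (df["hpd954_older"] - df["hpd954_younger"] >= df["hpd68_older"] - df["hpd68_younger"]).all()
        assert (df["ess"] > 0).all()

    def test_hpd_matches_gaussian_quantiles(self):
        post = self.toy_posterior()
        hpds = boundary_hpds(post, 0.954)
        older, younger = hpds["P"]["start"]
        assert older == pytest.approx(2_225.0 + 2 * 10.0, abs=2.0)
        assert younger == pytest.approx(2_225.0 - 2 * 10.0, abs=2.0)

    def test_split_rhat_near_one_for_iid_draws(self, rng):
        assert split_rhat(rng.normal(size=10_000)) == pytest.approx(1.0, abs=0.01)
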
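"""Assignment, positional variance diagrams, longitudinal stability."""

import numpy as np
import pandas as pd
import pytest

from amystage import (
    EventGrid,
    SubtypeModel,
    assign,
    assign_cohort,
    build_pvd,
    mcmc_sample,
    pvd_correlation,
    stability_metrics,
    summarize_rates,
)
from amystage.model import McmcSamples
from amystage.subtyping import NO_SUBTYPE, PVD
from amystage.synthetic import (random_valid_ordering, reverse_ordering,
                                sample_z_cohort)


@pytest.fixture
def two_subtype_model(tiny_grid):
    o1 = np.array([0, 3, 1, 4, 2, 5])
    o2 = np.array([3, 0, 4, 1, 5, 2])
    return SubtypeModel(tiny_grid, np.stack([o1, o2]), [0.5, 0.5], 1.0)


class TestAssign:
    def test_zero_vector_stage0_no_subtype(self, two_subtype_model):
        r = assign(np.zeros(2), two_subtype_model)
        assert r.ml_stage == 0
        assert r.ml_subtype == NO_SUBTYPE

    def test_noise_free_on_trajectory(self, tiny_grid, two_subtype_model):
        from amystage.events import trajectory_matrix

        traj = trajectory_matrix(tiny_grid, two_subtype_model.orderings[1])
        r = assign(traj[:, 4], two_subtype_model)
        assert r.ml_stage == 4
        assert r.ml_subtype == 1
        assert r.subtype_probability > 0.5

    def test_identical_orderings_probability_equals_fractions(self, tiny_grid):
        o = np.arange(6)
        m = SubtypeModel(tiny_grid, np.stack([o, o]), [0.3, 0.7], 1.0)
        r = assign(np.array([1.5, 0.5]), m, keep_posterior=True)
        subtype_marg = r.posterior.sum(axis=1)
        np.testing.assert_allclose(subtype_marg, [0.3, 0.7], atol=1e-12)

    def test_invariant_to_duplicating_subtype_with_split_fractions(
            self, tiny_grid):
        o1, o2 = np.arange(6), np.arange(6)[::-1].copy()
        m2 = SubtypeModel(tiny_grid, np.stack([o1, o2]), [0.6, 0.4], 1.0)
        m3 = SubtypeModel(tiny_grid, np.stack([o1, o1, o2]),
                          [0.3, 0.3, 0.4], 1.0)
        rng = np.random.default_rng(0)
        for _ in range(10):
            z = rng.normal(scale=2, size=2)
            r2, r3 = assign(z, m2), assign(z, m3)
            assert r2.ml_stage == r3.ml_stage
            # subtypes 0+1 of m3 jointly stand for subtype 0 of m2
            if r2.ml_subtype == NO_SUBTYPE:
                assert r3.ml_subtype == NO_SUBTYPE
            else:
                mapped = 0 if r3.ml_subtype in (0, 1) else 1
                assert mapped == r2.ml_subtype

    def test_cohort_table_matches_scalar_api(self, two_subtype_model):
        rng = np.random.default_rng(2)
        z = rng.normal(scale=1.5, size=(20, 2))
        tab = assign_cohort(z, two_subtype_model)
        for i in range(20):
            r = assign(z[i], two_subtype_model)
            assert tab["ml_stage"].iloc[i] == r.ml_stage
            assert tab["ml_subtype"].iloc[i] == r.ml_subtype


def _samples_from(orderings_list, grid):
    """McmcSamples stub with a given list of (C, N) orderings."""
    arr = np.asarray(orderings_list, dtype=np.int16)
    S, C, N = arr.shape
    return McmcSamples(
        orderings=arr, fractions=np.full((S, C), 1.0 / C),
        log_likelihoods=np.zeros(S + 1), n_iter=S + 1, burn_in=1,
        seed=0, acceptance_rate=1.0, grid=grid,
    )


class TestPvd:
    def test_single_sample_one_hot(self, tiny_grid):
        o = np.array([2, 0, 5, 1, 4, 3])
        pvd = build_pvd(_samples_from([o[None]], tiny_grid))
        expected = np.zeros((6, 6))
        expected[o, np.arange(6)] = 1.0
        np.testing.assert_array_equal(pvd.frequencies[0], expected)

    def test_two_samples_one_swap(self, tiny_grid):
        o1 = np.arange(6)
        o2 = o1.copy()
        o2[[1, 4]] = o2[[4, 1]]
        pvd = build_pvd(_samples_from([o1[None], o2[None]], tiny_grid))
        f = pvd.frequencies[0]
        assert f[1, 1] == 0.5 and f[1, 4] == 0.5
        assert f[4, 4] == 0.5 and f[4, 1] == 0.5
        assert f[0, 0] == 1.0

    def test_rows_sum_to_one_on_mcmc_output(self, tiny_grid):
        z, _, _ = sample_z_cohort(tiny_grid, np.arange(6)[None], [1.0], 40,
                                  noise_sd=0.8, seed=1)
        m = SubtypeModel(tiny_grid, np.arange(6)[None], [1.0], 1.0)
        pvd = build_pvd(mcmc_sample(z, m, n_iter=800, seed=2))
        np.testing.assert_allclose(pvd.frequencies.sum(axis=2), 1.0,
                                   atol=1e-9)

    def test_matches_independent_tally(self, tiny_grid):
        rng = np.random.default_rng(3)
        ords = [rng.permutation(6)[None] for _ in range(1000)]
        pvd = build_pvd(_samples_from(ords, tiny_grid))
        # independent recount
        ref = np.zeros((6, 6))
        for o in ords:
            for p, e in enumerate(o[0]):
                ref[e, p] += 1
        np.testing.assert_allclose(pvd.frequencies[0], ref / 1000, atol=1e-12)

    def test_empty_samples_rejected(self, tiny_grid):
        s = _samples_from([np.arange(6)[None]], tiny_grid)
        s.orderings = s.orderings[:0]
        with pytest.raises(ValueError):
            build_pvd(s)


class TestPvdCorrelation:
    def test_self_correlation_is_one(self, tiny_grid):
        pvd = build_pvd(_samples_from(
            [np.random.default_rng(4).permutation(6)[None]
             for _ in range(20)], tiny_grid))
        r, _ = pvd_correlation(pvd, pvd)
        assert r == pytest.approx(1.0)

    def test_hand_correlation_two_event_case(self):
        grid = EventGrid(("a", "b"), (1.0,))
        fwd = PVD(np.eye(2)[None], ["a@z1", "b@z1"])
        rev = PVD(np.eye(2)[::-1][None], ["a@z1", "b@z1"])
        r, _ = pvd_correlation(fwd, rev)
        # hand computation on the flattened 4-cell matrices
        x, y = np.eye(2).ravel(), np.eye(2)[::-1].ravel()
        ref = np.corrcoef(x, y)[0, 1]
        assert r == pytest.approx(ref)
        assert r == pytest.approx(-1.0)

    def test_independent_flat_pvds_near_zero(self):
        grid = EventGrid(tuple(f"r{i}" for i in range(10)))
        rng = np.random.default_rng(5)
        def flat_pvd(seed):
            rows = np.random.default_rng(seed).dirichlet(np.ones(30), 30)
            return PVD(rows[None], [grid.event_name(e) for e in range(30)])
        r, _ = pvd_correlation(flat_pvd(1), flat_pvd(2))
        assert abs(r) < 0.2

    def test_zero_variance_flagged(self, tiny_grid):
        flat = PVD(np.full((1, 6, 6), 1 / 6), ["x"] * 6)
        with pytest.raises(ValueError, match="zero-variance"):
            pvd_correlation(flat, flat)


def _assign_frame(rows):
    return pd.DataFrame(rows, columns=["subject_id", "ml_subtype", "ml_stage"])


class TestStabilityMetrics:
    def test_identical_tables_full_maintenance(self):
        t = _assign_frame([("a", 0, 3), ("b", 1, 7), ("c", NO_SUBTYPE, 0)])
        rep = stability_metrics(t, t)
        assert rep["maintained_subtype_pct"] == 100.0
        assert rep["stage_progressed_pct"] == 0.0
        assert rep["stage_regressed_pct"] == 0.0
        assert rep["stage_same_pct"] == 100.0

    def test_hand_counted_five_subject_table(self):
        base = _assign_frame([
            ("a", NO_SUBTYPE, 0),   # stays stage 0
            ("b", NO_SUBTYPE, 0),   # progresses out of stage 0
            ("c", 0, 5),            # maintains subtype, progresses stage
            ("d", 1, 10),           # changes subtype (1 -> 2)
            ("e", 2, 12),           # reverts to stage 0
        ])
        fu = _assign_frame([
            ("a", NO_SUBTYPE, 0),
            ("b", 1, 4),
            ("c", 0, 9),
            ("d", 2, 10),
            ("e", NO_SUBTYPE, 0),
        ])
        rep = stability_metrics(base, fu)
        assert rep["n_paired"] == 5
        assert rep["maintained_subtype"] == 2          # a and c
        assert rep["maintained_subtype_pct"] == 40.0
        assert rep["maintained_by_category"]["stage0"] == 1
        assert rep["stage0_to_higher"] == 1            # b
        assert rep["subtype_changed"] == 1             # d
        assert rep["subtype_to_stage0"] == {0: 0, 1: 0, 2: 1}
        assert rep["stage_same"] == 2                  # a, d
        assert rep["stage_progressed"] == 2            # b, c
        assert rep["stage_regressed"] == 1             # e

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(6)
        ids = [f"s{i}" for i in range(30)]
        base = _assign_frame([(i, rng.integers(-1, 3), rng.integers(0, 31))
                              for i in ids])
        fu = _assign_frame([(i, rng.integers(-1, 3), rng.integers(0, 31))
                            for i in ids])
        fwd = stability_metrics(base, fu)
        bwd = stability_metrics(fu, base)
        assert fwd["stage_progressed"] == bwd["stage_regressed"]
        assert fwd["stage_regressed"] == bwd["stage_progressed"]
        assert fwd["stage_same"] == bwd["stage_same"]

    def test_unpaired_counted(self):
        base = _assign_frame([("a", 0, 3), ("b", 1, 7)])
        fu = _assign_frame([("a", 0, 3), ("x", 1, 7)])
        rep = stability_metrics(base, fu)
        assert rep["n_paired"] == 1
        assert rep["n_unpaired"] == 2


class TestSummarizeRates:
    def _tables(self, base_val, fu_val, years):
        base = pd.DataFrame({"subject_id": ["a"], "cl": [base_val],
                             "years_from_baseline": [0.0]})
        fu = pd.DataFrame({"subject_id": ["a"], "cl": [fu_val],
                           "years_from_baseline": [years]})
        return base, fu

    def test_identical_visits_rate_zero(self):
        base, fu = self._tables(30.0, 30.0, 1.0)
        assert summarize_rates(base, fu, ["cl"])["cl_rate"].iloc[0] == 0.0

    def test_ten_cl_over_two_years(self):
        base, fu = self._tables(20.0, 30.0, 2.0)
        assert summarize_rates(base, fu, ["cl"])["cl_rate"].iloc[0] == \
            pytest.approx(5.0)

    def test_nonpositive_interval_rejected(self):
        base, fu = self._tables(20.0, 30.0, 0.0)
        with pytest.raises(ValueError):
            summarize_rates(base, fu, ["cl"])


class TestLongitudinalApplication:
    def test_frozen_pipeline_identical_followup(self, study_grid):
        """Follow-up identical to baseline scans yields identical
        assignments through the frozen control model and subtype model."""
        from amystage import (apply_longitudinal, fit_control_model,
                              generate_cohort, zscore_records)
        from amystage.harmonization import centiloid_from_suvr
        from amystage.synthetic import SyntheticTruth

        truth = SyntheticTruth(
            study_grid, random_valid_ordering(study_grid, 0)[None], [1.0],
            seed=30)
        records, _ = generate_cohort(truth, 80, 60)
        roi = list(study_grid.biomarkers)
        cl = records.copy()
        for t in ("FBP", "FBB"):
            m = (cl["tracer"] == t).to_numpy()
            cl.loc[m, roi] = centiloid_from_suvr(t, cl.loc[m, roi].to_numpy(float))
        cm = fit_control_model(cl.iloc[80:], roi)
        z = zscore_records(cl, cm).to_numpy()
        from amystage import fit_single_subtype
        est, _ = fit_single_subtype(z, study_grid, n_restarts=2, seed=1)
        model = SubtypeModel(study_grid, est[None], [1.0], 1.0)
        base_assign = assign_cohort(z, model, cl["subject_id"])
        fu_assign = apply_longitudinal(model, cl, cm,
                                       baseline_ids=cl["subject_id"])
        np.testing.assert_array_equal(base_assign["ml_stage"],
                                      fu_assign["ml_stage"])
        np.testing.assert_array_equal(base_assign["ml_subtype"],
                                      fu_assign["ml_subtype"])
        assert fu_assign["paired"].all()
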
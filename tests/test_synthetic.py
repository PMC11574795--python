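"""The planted-parameter cohort generator and its calibration machinery."""

import json

import numpy as np
import pytest

from fcreconf import synthetic as sy
from fcreconf.connectivity import vectorize_upper
from fcreconf.exceptions import CalibrationError
from fcreconf.group_stats import assign_subgroups


class TestEdgeTemplate:
    def test_zero_spread_is_constant(self):
        np.testing.assert_array_equal(
            sy.generate_edge_template(10, 0.3, 0.0, seed=1), 0.3
        )

    def test_empirical_median_is_pinned(self):
        for seed in range(5):
            tpl = sy.generate_edge_template(120, 0.30, 0.20, seed=seed)
            assert np.median(tpl) == pytest.approx(0.30, abs=1e-12)
            assert tpl.std() == pytest.approx(0.20, rel=0.25)

    def test_same_seed_reproducible(self):
        a = sy.generate_edge_template(50, 0.4, 0.2, seed=9)
        b = sy.generate_edge_template(50, 0.4, 0.2, seed=9)
        np.testing.assert_array_equal(a, b)


class TestCalibration:
    def test_zero_target_zero_noise_gives_zero(self):
        assert sy.calibrate_task_shift(0.0, estimation_noise_sd=0.0, seed=0) == 0.0

    def test_monotone_in_target(self):
        deltas = [
            sy.calibrate_task_shift(t, estimation_noise_sd=0.02, seed=4)
            for t in (0.05, 0.09, 0.13, 0.2)
        ]
        assert np.all(np.diff(deltas) > 0)

    def test_target_below_noise_floor_reports_floor(self):
        with pytest.raises(CalibrationError) as err:
            sy.calibrate_task_shift(0.001, estimation_noise_sd=0.02, seed=0)
        assert err.value.floor is not None
        assert err.value.floor > 0.001

    def test_end_to_end_recovery(self):
        delta = sy.calibrate_task_shift(
            0.09, estimation_noise_sd=0.02, seed=1, n_subjects=23
        )
        # independently simulate the generative model and re-measure
        rng = np.random.default_rng(123)
        q = sy.shift_scale_quantiles(23)
        scales = np.clip(delta * (1 + 0.5 * q), 0, None)
        diff = (
            -scales[:, None] * (rng.integers(0, 2, (23, 120)) * 2 - 1)
            + rng.normal(0, 0.02 * np.sqrt(1.5), (23, 120))
        )
        measured = np.median(np.abs(diff).mean(axis=0))
        assert measured == pytest.approx(0.09, abs=0.01)


class TestSubjectFC:
    def test_all_zero_parameters_reproduce_template(self):
        tpl = sy.generate_edge_template(28, 0.3, 0.2, seed=0)
        rest, run1, run2 = sy.generate_subject_fc(tpl, 0.0, 0.0, 0.0, seed=5)
        for m in (rest, run1, run2):
            np.testing.assert_allclose(vectorize_upper(m), tpl, atol=1e-12)

    def test_pure_noise_floor_matches_half_normal_median(self):
        # shift = 0: median |z_rest - z_task| = 0.674 * sqrt(1.5) * noise_sd
        tpl = sy.generate_edge_template(120, 0.3, 0.2, seed=0)
        diffs = []
        for s in range(200):
            rest, r1, r2 = sy.generate_subject_fc(tpl, 0.1, 0.0, 0.02, seed=s)
            task = (vectorize_upper(r1) + vectorize_upper(r2)) / 2
            diffs.append(np.abs(vectorize_upper(rest) - task))
        measured = np.median(np.concatenate(diffs))
        expected = 0.674 * np.sqrt(1.5) * 0.02
        assert measured == pytest.approx(expected, rel=0.15)

    def test_task_runs_share_shift_but_not_noise(self):
        tpl = sy.generate_edge_template(28, 0.3, 0.2, seed=0)
        (rest, r1, r2), truth = sy.generate_subject_fc(
            tpl, 0.05, 0.2, 0.02, seed=3, return_truth=True
        )
        e1 = vectorize_upper(r1) - truth["task_true"]
        e2 = vectorize_upper(r2) - truth["task_true"]
        assert not np.allclose(e1, e2)
        assert np.abs(e1).max() < 0.1  # only noise remains

    def test_intersubject_correlation_decreases_with_idiosyncrasy(self, rng):
        from fcreconf.heterogeneity import intersubject_correlation

        tpl = sy.generate_edge_template(120, 0.3, 0.2, seed=0)
        means = []
        for grid_i, idio in enumerate((0.05, 0.1, 0.2, 0.4)):
            edges = np.vstack(
                [
                    vectorize_upper(
                        sy.generate_subject_fc(tpl, idio, 0.0, 0.02, seed=1000 * grid_i + s)[0]
                    )
                    for s in range(15)
                ]
            )
            S = intersubject_correlation(edges)
            means.append(np.nanmean(S))
        assert np.all(np.diff(means) < 0)


class TestCorrelationProjection:
    def test_zero_edges_give_identity_unchanged(self):
        out = sy.z_template_to_correlation_matrix(np.zeros(6))
        np.testing.assert_array_equal(out, np.eye(4))

    def test_already_pd_input_unchanged(self):
        edges = np.full(6, np.arctanh(0.2))
        out = sy.z_template_to_correlation_matrix(edges)
        np.testing.assert_allclose(out[np.triu_indices(4, 1)], 0.2, atol=1e-10)

    def test_indefinite_input_repaired(self):
        # r(0,1)=r(2,3)=0.95, r(0,2)=r(1,3)=-0.95, r(0,3)=r(1,2)=0.95 -> indefinite
        r = np.arctanh(np.array([0.95, -0.95, 0.95, 0.95, -0.95, 0.95]))
        out = sy.z_template_to_correlation_matrix(r)
        w = np.linalg.eigvalsh(out)
        assert w.min() >= 1e-6 * (1 - 1e-6)
        np.testing.assert_allclose(np.diag(out), 1.0, atol=1e-9)

    def test_projection_is_near_nearest(self):
        # no further than the naive clip-and-rescale fix, in Frobenius norm
        rng = np.random.default_rng(0)
        z = rng.normal(0.4, 0.25, 120)
        c = sy.devectorize(np.tanh(z), diagonal=1.0)
        out = sy.z_template_to_correlation_matrix(z)
        w, v = np.linalg.eigh(c)
        naive = (v * np.clip(w, 1e-6, None)) @ v.T
        d = np.sqrt(np.diag(naive))
        naive = naive / np.outer(d, d)
        assert np.linalg.norm(out - c) <= np.linalg.norm(naive - c) + 1e-9


class TestSampleTimeseries:
    def test_same_seed_identical(self):
        corr = np.eye(4)
        np.testing.assert_array_equal(
            sy.sample_timeseries(corr, 50, seed=3), sy.sample_timeseries(corr, 50, seed=3)
        )

    def test_identity_correlation_uncorrelated_columns(self):
        ts = sy.sample_timeseries(np.eye(6), 4000, seed=1)
        c = np.corrcoef(ts, rowvar=False)
        off = c[~np.eye(6, dtype=bool)]
        assert np.abs(off).mean() < 0.05

    def test_planted_correlation_recovered(self):
        from fcreconf.connectivity import fc_from_timeseries

        z = np.full(15, 0.35)
        corr = sy.z_template_to_correlation_matrix(z)
        ts = sy.sample_timeseries(corr, 5000, seed=2)
        est = vectorize_upper(fc_from_timeseries(ts))
        true_z = np.arctanh(corr[np.triu_indices(6, 1)])
        assert np.abs(est - true_z).max() < 0.05


class TestPhenotypes:
    def _cohort(self, n, rho, seed, group="TD"):
        import fcreconf as f

        cfg = f.SyntheticConfig(
            n_per_group={group: n},
            group_median_z={group: {"rest": 0.30, "task": 0.30}},
            idio_sd={group: 0.08},
            target_reconfig_median={group: 0.09},
            behavior_coupling_rho={"celf_wc": {group: rho}},
            n_missing_brief=0,
            seed=seed,
        )
        return f.generate_cohort(cfg)

    def _corr_with_truth(self, cohort, measure="celf_wc"):
        truth = {s["subject_id"]: s["mean_reconfig"] for s in cohort.ground_truth["subjects"]}
        x = np.array([truth[r.subject_id] for r in cohort.records])
        y = np.array([getattr(r, measure) for r in cohort.records])
        return np.corrcoef(x, y)[0, 1]

    def test_zero_coupling_is_null(self):
        r = self._corr_with_truth(self._cohort(200, 0.0, seed=1))
        assert abs(r) < 0.14  # |r| at p=0.05, n=200

    def test_planted_coupling_recovered(self):
        for seed in (2, 3):
            r = self._corr_with_truth(self._cohort(200, 0.5, seed=seed))
            assert 0.38 <= r <= 0.62

    def test_subgroup_mix_recovered_by_assignment(self):
        import fcreconf as f

        cfg = f.SyntheticConfig(
            n_per_group={"ASD": 40},
            group_median_z={"ASD": {"rest": 0.41, "task": 0.40}},
            idio_sd={"ASD": 0.15},
            target_reconfig_median={"ASD": 0.11},
            subgroup_mix={"ASD": {"TP-ASD": 20, "LP-ASD": 20}},
            seed=4,
        )
        cohort = f.generate_cohort(cfg)
        table = assign_subgroups(cohort.records)
        # planted 20/20 split recovered with high label agreement
        counts = table["subgroup"].value_counts()
        assert abs(int(counts.get("TP-ASD", 0)) - 20) <= 4
        agreement = max(counts.get("TP-ASD", 0), counts.get("LP-ASD", 0)) / 40
        assert agreement >= 0.4  # neither class collapsed

    def test_truncations_respected(self, small_cohort):
        for rec in small_cohort.records:
            assert 0.0 <= rec.acc_sw <= 1.0
            assert rec.rmsd_rest >= 0.0
            assert rec.rt_sw >= 100.0


class TestGenerateCohort:
    def test_default_shape_contract(self, small_cohort):
        assert len(small_cohort.subject_order) == 16
        edges, sids = small_cohort.edge_table("rest")
        assert edges.shape == (16, 120)
        assert sids == small_cohort.subject_order
        assert set(small_cohort.fc[sids[0]]) == {"rest", "task_run1", "task_run2"}

    def test_full_size_cohort_counts(self):
        import fcreconf as f

        cohort = f.generate_cohort(f.SyntheticConfig(seed=1))
        assert len(cohort.subject_order) == 53
        groups = [cohort.group_of(s) for s in cohort.subject_order]
        assert groups.count("ASD") == 30
        assert groups.count("TD") == 23

    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        import fcreconf as f

        cfg = f.SyntheticConfig(
            n_per_group={"ASD": 3, "TD": 3},
            subgroup_mix={"ASD": {"TP-ASD": 2, "LP-ASD": 1}, "TD": {"TD-typical": 3}},
            n_missing_brief=0,
            seed=21,
        )
        f.generate_cohort(cfg, out_dir=tmp_path / "a")
        f.generate_cohort(cfg, out_dir=tmp_path / "b")
        for rel in ("manifest.csv", "phenotypes.csv", "ground_truth.json",
                    "cohort_config.yaml", "data/sub-001_rest.tsv"):
            assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()

    def test_missing_seed_rejected(self):
        import fcreconf as f

        with pytest.raises(ValueError, match="seed"):
            f.generate_cohort(f.SyntheticConfig())

    def test_ledger_allows_independent_recomputation(self, small_cohort):
        gt = small_cohort.ground_truth
        for sub in gt["subjects"]:
            group = gt["groups"][sub["group"]]
            rest_true = group["template_rest"] + sub["idio"]
            task_true = (
                group["template_task"] + sub["idio"] + sub["delta_s"] * sub["signs"]
            )
            assert sub["mean_reconfig"] == pytest.approx(
                np.abs(rest_true - task_true).mean(), abs=1e-12
            )

    def test_ground_truth_json_is_serializable(self, cohort_dir):
        cohort, _ = cohort_dir
        with open(cohort.paths["ground_truth"]) as fh:
            data = json.load(fh)
        assert data["seed"] == 11
        assert len(data["subjects"]) == 16
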
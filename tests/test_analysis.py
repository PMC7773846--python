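"""Campaign statistics, path classification and trajectory analyses."""
import itertools
from types import SimpleNamespace

import numpy as np
import pytest

from metadhs import (
    KB,
    MetadParams,
    PathRecord,
    ReplicaTrace,
    SimState,
    bootstrap_ci,
    classify_path,
    com_cloud_volumes,
    com_scatter,
    langevin_steps,
    mann_whitney,
    native_contact_retention,
    path_fractions,
    predicted_channel_fraction,
    residence_summary,
    threshold_sensitivity,
)

from tests.test_energetics import make_model


def exact_mw_p(x, y):
    """Exhaustive permutation enumeration of the two-sided MW p-value."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        g1 = pooled[list(idx)]
        g2 = np.delete(pooled, list(idx))
        us.append(sum(1 for a in g1 for b in g2 if a > b))
    us = np.array(us)
    p = 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs))
    return min(p, 1.0)


class TestMannWhitney:
    def test_separated_triplets(self):
        u, p = mann_whitney([10.0, 12.0, 14.0], [2.0, 3.0, 4.0])
        assert u == 9.0
        assert p == pytest.approx(0.100, abs=1e-9)

    def test_identical_samples_give_p_one(self):
        summary = residence_summary([5.0, 5.0, 5.0], [5.0, 5.0, 5.0],
                                    n_boot=200)
        assert summary.p_value == pytest.approx(1.0)
        assert summary.direction == "none"

    def test_matches_exhaustive_enumeration(self, rng):
        for n1 in range(1, 6):
            for n2 in range(n1, 11 - n1):
                x = rng.normal(size=n1)
                y = rng.normal(loc=0.5, size=n2)
                _, p = mann_whitney(x, y)
                assert p == pytest.approx(exact_mw_p(x, y), abs=1e-10), \
                    f"mismatch at n1={n1}, n2={n2}"


class TestResidenceSummary:
    def test_ci_contains_sample_mean(self, rng):
        x = rng.exponential(scale=800.0, size=20)
        y = rng.exponential(scale=200.0, size=20)
        summary = residence_summary(x, y, n_boot=2000, seed=1)
        for stats_ in summary.per_variant.values():
            assert stats_.ci_lo <= stats_.mean <= stats_.ci_hi

    def test_direction_reported(self, rng):
        summary = residence_summary(rng.normal(10, 1, 15), rng.normal(2, 1, 15),
                                    n_boot=500)
        assert summary.direction == "human-like"
        assert 0.0 <= summary.p_value <= 1.0

    def test_all_censored_sample_warns(self):
        censored = [SimpleNamespace(residence_time=1000.0, censored=True)] * 3
        with pytest.warns(UserWarning, match="censored"):
            summary = residence_summary(censored, [1.0, 2.0, 3.0], n_boot=200)
        assert summary.direction == "undetermined"

    def test_bootstrap_coverage_on_exponential_samples(self):
        rng = np.random.default_rng(42)
        hits = 0
        n_sets = 1000
        for k in range(n_sets):
            x = rng.exponential(scale=100.0, size=30)
            lo, hi = bootstrap_ci(x, n_boot=10000, seed=k)
            hits += lo <= 100.0 <= hi
        assert 0.93 <= hits / n_sets <= 0.97


def _trace(native_cv, gate_a_dwell=False, gate_b_dwell=False):
    times = np.arange(0.0, 102.0, 2.0)
    n = len(times)
    cv = np.full(n, 0.95 * native_cv)
    cv[25:] = np.linspace(0.95 * native_cv, 140.0, n - 25)
    far = np.full(n, 12.0)
    dga = far.copy()
    dgb = far.copy()
    salt = far.copy()
    if gate_a_dwell:
        dga[28:45] = 3.0
        salt[28:40] = 3.0   # 24 ps amine/gate-A salt bridge
    if gate_b_dwell:
        dgb[28:45] = 3.0
    com = np.zeros((n, 3))
    com[:, 2] = np.linspace(0.0, 12.0, n) * (1 if gate_a_dwell else -1)
    return ReplicaTrace(times, cv, np.zeros(n), com, dga, dgb, salt)


class TestPathClassification:
    def test_channel_a_exit_with_intermediate(self, human_system):
        record = classify_path(_trace(human_system.native_cv, gate_a_dwell=True),
                               human_system, MetadParams())
        assert record.label == "A"
        assert record.first_gate == "A"
        assert record.intermediate_state

    def test_channel_b_exit(self, human_system):
        record = classify_path(_trace(human_system.native_cv, gate_b_dwell=True),
                               human_system, MetadParams())
        assert record.label == "B"
        assert not record.intermediate_state

    def test_gateless_exit_is_undetermined(self, human_system):
        record = classify_path(_trace(human_system.native_cv),
                               human_system, MetadParams())
        assert record.label == "undetermined"

    def test_trace_without_exit_rejected(self, human_system):
        trace = _trace(human_system.native_cv)
        trace.cv[:] = human_system.native_cv
        with pytest.raises(ValueError, match="exit"):
            classify_path(trace, human_system, MetadParams())

    def test_label_requires_gate_evidence(self):
        with pytest.raises(ValueError, match="evidence"):
            PathRecord(0, "A", "", 0.0, 5.0, False)

    def test_labels_are_deterministic(self, human_system, small_campaigns):
        outcome = next(o for o in small_campaigns["human-like"]
                       if not o.censored)
        labels = {classify_path(outcome.trace, human_system,
                                MetadParams()).label for _ in range(3)}
        assert len(labels) == 1


class TestPathFractions:
    def test_seventy_thirty_split(self):
        records = [SimpleNamespace(label="A")] * 21 + \
                  [SimpleNamespace(label="B")] * 9
        fractions = path_fractions(records)
        assert fractions["A"] == pytest.approx(70.0)
        assert sum(fractions.values()) == pytest.approx(100.0)

    def test_all_one_label(self):
        assert path_fractions([SimpleNamespace(label="A")] * 7)["A"] == 100.0

    def test_matches_recount(self, rng):
        labels = rng.choice(["A", "B", "undetermined"], size=40)
        records = [SimpleNamespace(label=l) for l in labels]
        fractions = path_fractions(records)
        for lab in ("A", "B", "undetermined"):
            assert fractions[lab] == pytest.approx(
                100.0 * np.sum(labels == lab) / 40)


class TestThresholdSensitivity:
    def test_verdict_stable_across_thresholds(self, small_campaigns,
                                              human_system):
        camp_h = SimpleNamespace(outcomes=small_campaigns["human-like"])
        camp_a = SimpleNamespace(outcomes=small_campaigns["archaeal-like"])
        report = threshold_sensitivity(camp_h, camp_a,
                                       native_cv=human_system.native_cv)
        assert set(report.ordering.values()) == {True}

    def test_residence_monotone_in_threshold(self, small_campaigns):
        from metadhs import residence_from_trace
        for outcome in small_campaigns["human-like"]:
            res = []
            for thr in (150.0, 200.0, 250.0):
                hit = residence_from_trace(outcome.trace.times,
                                           outcome.trace.cv, thr)
                res.append(hit[0] if hit else np.inf)
            assert res[0] >= res[1] >= res[2]

    def test_threshold_above_native_rejected(self, small_campaigns,
                                             human_system):
        camp = SimpleNamespace(outcomes=small_campaigns["human-like"])
        with pytest.raises(ValueError):
            threshold_sensitivity(camp, camp, thresholds=(800.0,),
                                  native_cv=human_system.native_cv)


class TestNativeContactRetention:
    def test_native_frame_fully_retained(self, human_system):
        retention = native_contact_retention(
            human_system.native_positions[None], human_system)
        assert retention[0] == pytest.approx(1.0)

    def test_fully_displaced_ligand_retains_nothing(self, human_system):
        pos = human_system.native_positions.copy()
        pos[human_system.ligand_bead_ids] += np.array([0.0, 0.0, 20.0])
        assert native_contact_retention(pos[None], human_system)[0] == 0.0

    def test_variant_contrast_on_unbiased_campaigns(self, human_system,
                                                    arch_system,
                                                    unbiased_campaigns):
        finals = {}
        for name, system in (("human-like", human_system),
                             ("archaeal-like", arch_system)):
            values = []
            for traj in unbiased_campaigns[name]:
                retention = native_contact_retention(traj, system)
                values.append(retention[-len(retention) // 4:].mean())
            finals[name] = np.mean(values)
        assert finals["human-like"] > 0.8
        assert finals["archaeal-like"] < 0.5


class TestComScatter:
    def test_constant_trajectory_has_zero_volume(self, human_system):
        traj = np.repeat(human_system.native_positions[None], 4, axis=0)
        scatter = com_scatter({"human-like": [traj]},
                              {"human-like": human_system})
        assert com_cloud_volumes(scatter)["human-like"] == 0.0
        assert len(scatter) == 4  # frames x replicas

    def test_archaeal_cloud_larger(self, human_system, arch_system,
                                   unbiased_campaigns, tmp_path):
        from metadhs import com_scatter_export
        volumes = com_scatter_export(
            {"human-like": unbiased_campaigns["human-like"],
             "archaeal-like": unbiased_campaigns["archaeal-like"]},
            {"human-like": human_system, "archaeal-like": arch_system},
            tmp_path / "com_scatter.csv")
        assert volumes["archaeal-like"] > volumes["human-like"]
        n_rows = sum(len(t) for ts in unbiased_campaigns.values() for t in ts)
        import pandas as pd
        assert len(pd.read_csv(tmp_path / "com_scatter.csv")) == n_rows


class TestChannelPreference:
    def test_escape_fraction_matches_boltzmann_two_channel(self):
        # bare symmetric channel: one bead between two ridges of 4 and 5
        # kJ/mol; escape split must follow 1/(1 + exp(-ddG/kBT))
        barriers = (4.0, 5.0)
        model = make_model(1, masses=[14.0], ridge_h=barriers, ridge_z=4.0,
                           cyl_k=10.0, sphere_r=30.0)
        n_runs, n_a, n_escaped = 200, 0, 0
        for seed in range(n_runs):
            state = SimState(np.zeros((1, 3)), np.zeros((1, 3)), seed=seed)
            side = None
            for _ in range(60):  # chunks of 20 ps, cap 1.2 ns
                frames = langevin_steps(model, state, 2000, 0.01, 1.0, 300.0,
                                        record_stride=50)
                z = frames[:, 0, 2]
                hit = np.nonzero(np.abs(z) > 5.5)[0]
                if len(hit):
                    side = "A" if z[hit[0]] > 0 else "B"
                    break
            if side is not None:
                n_escaped += 1
                n_a += side == "A"
        assert n_escaped >= 0.9 * n_runs  # rare stuck runs are censored
        predicted = predicted_channel_fraction(*barriers, 300.0)
        sigma = np.sqrt(predicted * (1 - predicted) / n_escaped)
        assert abs(n_a / n_escaped - predicted) < 3 * sigma + 1e-9
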
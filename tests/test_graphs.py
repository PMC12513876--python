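"""Graph construction: contact aggregation, approach events, episodes, signs."""

import math

import numpy as np
import pandas as pd
import pytest

from compsd import (ContactList, InteractionGraph, SignOverlay, Trajectory,
                    apply_sign, approach_events, build_digraph, build_f2f_graph,
                    build_multidigraph, contact_summary, derive_velocities)


def frame_at(rows):
    """One-time-step frame from (id, x, y, velX, velY) tuples."""
    return pd.DataFrame(rows, columns=["id", "x", "y", "velX", "velY"])


def make_traj(rows):
    """Trajectory from (t, id, x, y, velX, velY) tuples."""
    return Trajectory(pd.DataFrame(rows, columns=["t", "id", "x", "y", "velX", "velY"]))


class TestF2FGraphs:
    def test_simple_graph_sums_durations(self):
        graph = build_f2f_graph(ContactList([("a", "b", 20.0), ("a", "b", 30.0)]), multi=False)
        assert graph.edges == [("a", "b", 1, 50.0)]

    def test_multigraph_keeps_individual_contacts(self):
        graph = build_f2f_graph(ContactList([("a", "b", 20.0), ("a", "b", 30.0)]), multi=True)
        assert graph.multiplicity_by_pair() == {("a", "b"): 2}
        assert {w for _, _, _, w in graph.edges} == {20.0, 30.0}

    def test_row_order_irrelevant(self):
        rows = [("a", "b", 20.0), ("b", "c", 5.0), ("a", "b", 30.0)]
        g1 = build_f2f_graph(ContactList(rows), multi=False)
        g2 = build_f2f_graph(ContactList(rows[::-1]), multi=False)
        assert g1.weight_by_pair() == g2.weight_by_pair()

    def test_aggregating_multigraph_recovers_simple_graph(self):
        rows = [("a", "b", 20.0), ("a", "b", 30.0), ("b", "c", 5.0)]
        multi = build_f2f_graph(ContactList(rows), multi=True)
        simple = build_f2f_graph(ContactList(rows), multi=False)
        assert multi.aggregate().weight_by_pair() == simple.weight_by_pair()

    @pytest.mark.parametrize("bad", [("a", "a", 5.0), ("a", "b", 0.0), ("a", "b", -1.0)])
    def test_invalid_contacts_rejected(self, bad):
        with pytest.raises(ValueError):
            ContactList([bad])

    def test_published_conference_summaries(self):
        lwa = contact_summary(77, 1004)
        ht = contact_summary(69, 550)
        assert lwa["mean_degree"] == pytest.approx(26.08, abs=0.005)
        assert lwa["density"] == pytest.approx(0.34, abs=0.005)
        assert ht["mean_degree"] == pytest.approx(15.94, abs=0.005)
        assert ht["density"] == pytest.approx(0.23, abs=0.005)


class TestApproachEvents:
    def test_collinear_approach_fires(self):
        frame = frame_at([("i", 0, 0, 1, 0), ("j", 1, 0, 0, 0)])
        assert approach_events(frame, maxdist=2) == {("i", "j")}

    def test_receding_actor_does_not_fire(self):
        frame = frame_at([("i", 0, 0, -1, 0), ("j", 1, 0, 0, 0)])
        assert approach_events(frame, maxdist=2) == set()

    def test_mutual_approach_fires_both_directions(self):
        frame = frame_at([("i", 0, 0, 1, 0), ("j", 1, 0, -1, 0)])
        assert approach_events(frame, maxdist=2) == {("i", "j"), ("j", "i")}

    def test_distance_strictly_beyond_threshold_blocks(self):
        frame = frame_at([("i", 0, 0, 1, 0), ("j", 2 + 1e-9, 0, 0, 0)])
        assert approach_events(frame, maxdist=2) == set()
        at_threshold = frame_at([("i", 0, 0, 1, 0), ("j", 2, 0, 0, 0)])
        assert at_threshold.pipe(approach_events, maxdist=2) == {("i", "j")}

    def test_perpendicular_motion_is_not_an_approach(self):
        frame = frame_at([("i", 0, 0, 0, 1), ("j", 1, 0, 0, 0)])
        assert approach_events(frame, maxdist=2) == set()

    def test_stationary_actor_never_approaches(self):
        frame = frame_at([("i", 0, 0, 0, 0), ("j", 1, 0, 1, 0)])
        assert approach_events(frame, maxdist=2) == set()

    def test_matches_per_pair_brute_force(self):
        rng = np.random.default_rng(3)
        rows = [(f"a{k}", *rng.uniform(-2, 2, size=4)) for k in range(6)]
        frame = frame_at(rows)
        got = approach_events(frame, maxdist=2.5)
        expected = set()
        for _, ri in frame.iterrows():
            for _, rj in frame.iterrows():
                if ri["id"] == rj["id"]:
                    continue
                r = (rj["x"] - ri["x"], rj["y"] - ri["y"])
                d = math.hypot(*r)
                v = (ri["velX"], ri["velY"])
                if d == 0 or d > 2.5 or (v[0] == 0 and v[1] == 0):
                    continue
                if r[0] * v[0] + r[1] * v[1] > 0:
                    expected.add((ri["id"], rj["id"]))
        assert got == expected

    def test_translation_and_joint_rotation_invariance(self):
        rng = np.random.default_rng(5)
        rows = [(f"a{k}", *rng.uniform(-2, 2, size=4)) for k in range(5)]
        frame = frame_at(rows)
        base = approach_events(frame, maxdist=2.0)
        shifted = frame.copy()
        shifted[["x", "y"]] += [13.0, -4.5]
        assert approach_events(shifted, maxdist=2.0) == base
        theta = 0.83
        c, s = math.cos(theta), math.sin(theta)
        rot = frame.copy()
        rot["x"], rot["y"] = c * frame["x"] - s * frame["y"], s * frame["x"] + c * frame["y"]
        rot["velX"], rot["velY"] = (c * frame["velX"] - s * frame["velY"],
                                    s * frame["velX"] + c * frame["velY"])
        assert approach_events(rot, maxdist=2.0) == base


class TestTrajectoryGraphs:
    @staticmethod
    def chase_rows(event_times, all_times=range(8)):
        """i chases j at the given times; i points away otherwise."""
        rows = []
        for t in all_times:
            vel = (1.0, 0.0) if t in event_times else (-1.0, 0.0)
            rows.append((t, "i", 0.0, 0.0, *vel))
            rows.append((t, "j", 1.0, 0.0, 0.0, 0.0))
        return rows

    def test_digraph_counts_event_steps(self):
        traj = make_traj(self.chase_rows({1, 2, 3, 5, 6}))
        graph = build_digraph(traj, maxdist=2)
        assert graph.weight_by_pair() == {("i", "j"): 5.0}

    def test_no_events_yields_edgeless_graph(self):
        traj = make_traj(self.chase_rows(set()))
        graph = build_digraph(traj, maxdist=2)
        assert graph.edges == [] and set(graph.nodes) == {"i", "j"}

    def test_multidigraph_splits_runs_at_gaps(self):
        traj = make_traj(self.chase_rows({1, 2, 3, 5, 6}))
        graph = build_multidigraph(traj, maxdist=2)
        weights = sorted(w for _, _, _, w in graph.edges)
        assert weights == [2.0, 3.0]

    def test_uninterrupted_window_is_one_episode(self):
        traj = make_traj(self.chase_rows(set(range(8))))
        graph = build_multidigraph(traj, maxdist=2)
        assert [w for _, _, _, w in graph.edges] == [8.0]

    def test_missing_step_of_either_actor_breaks_the_run(self):
        rows = [r for r in self.chase_rows({0, 1, 2, 3}, all_times=range(4))
                if not (r[0] == 2 and r[1] == "j")]
        graph = build_multidigraph(Trajectory(pd.DataFrame(
            rows, columns=["t", "id", "x", "y", "velX", "velY"])), maxdist=2)
        weights = sorted(w for _, _, _, w in graph.edges)
        assert weights == [1.0, 2.0]

    def test_episode_weights_partition_digraph_weights(self):
        """Per ordered pair, multidigraph weights sum to the digraph weight."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            rows = []
            for t in range(12):
                for k in range(5):
                    rows.append((t, f"a{k}", *rng.uniform(-3, 3, size=4)))
            traj = make_traj(rows)
            simple = build_digraph(traj, maxdist=2.5).weight_by_pair()
            multi = build_multidigraph(traj, maxdist=2.5)
            sums: dict = {}
            for s, d, _, w in multi.edges:
                sums[(s, d)] = sums.get((s, d), 0.0) + w
            assert sums == simple

    def test_no_self_loops_possible(self):
        rng = np.random.default_rng(2)
        rows = [(t, f"a{k}", *rng.uniform(-1, 1, size=4))
                for t in range(5) for k in range(4)]
        for graph in (build_digraph(make_traj(rows), 3.0),
                      build_multidigraph(make_traj(rows), 3.0)):
            assert all(s != d for s, d, _, _ in graph.edges)


class TestDeriveVelocities:
    def test_forward_difference(self):
        traj = Trajectory(pd.DataFrame(
            {"t": [0, 1], "id": ["a", "a"], "x": [0.0, 1.0], "y": [0.0, 0.0]}))
        out = derive_velocities(traj).frame
        assert out.loc[0, "velX"] == 1.0 and out.loc[0, "velY"] == 0.0
        # last step copies the previous value
        assert out.loc[1, "velX"] == 1.0

    def test_stationary_actor_zero_velocity(self):
        traj = Trajectory(pd.DataFrame(
            {"t": [0, 1, 2], "id": ["a"] * 3, "x": [2.0] * 3, "y": [3.0] * 3}))
        out = derive_velocities(traj).frame
        assert (out[["velX", "velY"]] == 0).all().all()

    def test_velocities_telescope_to_total_displacement(self):
        rng = np.random.default_rng(9)
        x = np.cumsum(rng.normal(size=20))
        y = np.cumsum(rng.normal(size=20))
        traj = Trajectory(pd.DataFrame({"t": range(20), "id": ["a"] * 20, "x": x, "y": y}))
        out = derive_velocities(traj).frame
        # forward differences over all but the copied last step
        assert out["velX"][:-1].sum() == pytest.approx(x[-1] - x[0])
        assert out["velY"][:-1].sum() == pytest.approx(y[-1] - y[0])

    def test_single_step_actor_warned_zero(self, caplog):
        traj = Trajectory(pd.DataFrame(
            {"t": [0, 0, 1], "id": ["solo", "a", "a"], "x": [1.0, 0.0, 1.0],
             "y": [0.0, 0.0, 0.0]}))
        with caplog.at_level("WARNING", logger="compsd"):
            out = derive_velocities(traj).frame
        solo = out[out["id"] == "solo"]
        assert (solo[["velX", "velY"]] == 0).all().all()
        assert "solo" in caplog.text


class TestSignOverlays:
    @pytest.fixture
    def digraph(self):
        edges = [("a", "b", 1, 5.0), ("b", "c", 1, 3.0), ("c", "a", 1, 2.0)]
        return InteractionGraph(["a", "b", "c"], edges, directed=True)

    def test_all_ones_overlay_is_identity(self, digraph):
        overlay = SignOverlay({(s, d): 1 for s, d, _, _ in digraph.edges})
        assert apply_sign(digraph, overlay).edges == digraph.edges

    def test_empty_overlay_zeroes_everything(self, digraph):
        signed = apply_sign(digraph, SignOverlay({}))
        assert all(w == 0 for _, _, _, w in signed.edges)

    def test_selective_overlay_matches_elementwise_product(self, digraph):
        overlay = SignOverlay({("a", "b"): 1})
        signed = apply_sign(digraph, overlay)
        expected = {(s, d): w * (1 if (s, d) == ("a", "b") else 0)
                    for s, d, _, w in digraph.edges}
        assert {(s, d): w for s, d, _, w in signed.edges} == expected

    def test_unknown_overlay_node_rejected(self, digraph):
        with pytest.raises(ValueError, match="zz"):
            apply_sign(digraph, SignOverlay({("a", "zz"): 1}))

    def test_sign_values_restricted(self):
        with pytest.raises(ValueError):
            SignOverlay({("a", "b"): -1})
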
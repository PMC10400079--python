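"""Crossing detection with hysteresis vs an independent replay oracle."""

import numpy as np
import pytest

from gjpore import (
    CompartmentSpec,
    CrossingEvent,
    IonPath,
    SimulationMeta,
    detect_events,
    script_trajectory,
    summarize_events,
    unwrapped_z,
)

COMP = CompartmentSpec(z_cyt1=-30.0, z_mid=0.0, z_cyt2=30.0, hysteresis=2.0)


# ---------------------------------------------------------------------------
# independent oracle: per-boundary latch replay
# ---------------------------------------------------------------------------


def oracle_events(z, times, comp, ion_id, species):
    """Brute-force reference: latch each boundary independently, then
    read events off the chronological crossing sequence."""
    boundaries = [comp.z_cyt1, comp.z_mid, comp.z_cyt2]
    h = comp.hysteresis
    crossings = []  # (time, boundary_index, "up"/"down")
    for bi, b in enumerate(boundaries):
        latch = None
        for t, zz in zip(times, z):
            if zz < b - h:
                side = "below"
            elif zz > b + h:
                side = "above"
            else:
                continue
            if latch is not None and side != latch:
                crossings.append((t, bi, "up" if side == "above" else "down"))
            latch = side
    crossings.sort(key=lambda c: (c[0], c[1] if c[2] == "up" else -c[1]))
    events = []
    for (t1, b1, d1), (t2, b2, d2) in zip(crossings, crossings[1:]):
        if d1 == d2 == "up" and (b1, b2) == (0, 1):
            events.append(("HC1", "forward", t1, t2))
        elif d1 == d2 == "down" and (b1, b2) == (1, 0):
            events.append(("HC1", "backward", t1, t2))
        elif d1 == d2 == "up" and (b1, b2) == (1, 2):
            events.append(("HC2", "forward", t1, t2))
        elif d1 == d2 == "down" and (b1, b2) == (2, 1):
            events.append(("HC2", "backward", t1, t2))
    for i in range(len(crossings) - 2):
        (t1, b1, d1), (t2, b2, d2), (t3, b3, d3) = crossings[i : i + 3]
        if d1 == d2 == d3 == "up" and (b1, b2, b3) == (0, 1, 2):
            events.append(("GJC", "forward", t1, t3))
        elif d1 == d2 == d3 == "down" and (b1, b2, b3) == (2, 1, 0):
            events.append(("GJC", "backward", t1, t3))
    return {(ion_id, species, k, d, round(a, 6), round(b, 6)) for k, d, a, b in events}


def as_set(events):
    return {
        (e.ion_id, e.species, e.kind, e.direction, round(e.t_enter, 6), round(e.t_exit, 6))
        for e in events
    }


# ---------------------------------------------------------------------------
# scripted fixtures
# ---------------------------------------------------------------------------


class TestScriptedPaths:
    def test_full_translocation_is_one_of_each(self):
        traj = script_trajectory(
            [IonPath("K+", [0.0, 100.0], [-45.0, 45.0])], box=(30, 30, 200)
        )
        events = detect_events(traj, COMP, "K+")
        kinds = sorted(e.kind for e in events)
        assert kinds == ["GJC", "HC1", "HC2"]
        assert all(e.direction == "forward" for e in events)

    def test_oscillation_inside_hysteresis_band_is_silent(self):
        zig = [-31.5, -28.5] * 10  # inside the +-2 A band around -30
        traj = script_trajectory(
            [IonPath("K+", list(np.arange(20.0)), zig)], box=(30, 30, 200)
        )
        assert detect_events(traj, COMP, "K+") == []

    def test_backward_translocation_swaps_direction(self):
        traj = script_trajectory(
            [IonPath("K+", [0.0, 100.0], [45.0, -45.0])], box=(30, 30, 200)
        )
        events = detect_events(traj, COMP, "K+")
        assert sorted(e.kind for e in events) == ["GJC", "HC1", "HC2"]
        assert all(e.direction == "backward" for e in events)

    def test_half_traversal_counts_single_hemichannel(self):
        traj = script_trajectory(
            [IonPath("K+", [0.0, 50.0], [-45.0, -3.0]),  # stops inside band
             IonPath("K+", [0.0, 50.0], [-45.0, 10.0])], box=(30, 30, 200)
        )
        events = detect_events(traj, COMP, "K+")
        assert [(e.ion_id, e.kind) for e in events] == [(1, "HC1")]

    def test_hysteresis_wider_than_compartment_rejected(self):
        comp = CompartmentSpec(z_cyt1=-3.0, z_mid=0.0, z_cyt2=3.0, hysteresis=2.0)
        traj = script_trajectory([IonPath("K+", [0.0, 1.0], [-5.0, 5.0])])
        with pytest.raises(ValueError, match="hysteresis"):
            detect_events(traj, comp, "K+")


# ---------------------------------------------------------------------------
# random walks vs oracle
# ---------------------------------------------------------------------------


def random_walk_traj(n_ions=200, n_steps=400, seed=0, step=4.0):
    rng = np.random.default_rng(seed)
    z = rng.uniform(-45, 45, n_ions)
    zs = [z.copy()]
    for _ in range(n_steps):
        z = np.clip(z + rng.normal(0, step, n_ions), -55, 55)
        zs.append(z.copy())
    paths = [
        IonPath("K+", list(np.arange(float(n_steps + 1))), [float(zt[i]) for zt in zs])
        for i in range(n_ions)
    ]
    return script_trajectory(paths, box=(30, 30, 200))


class TestOracleEquivalence:
    def test_random_walks_match_oracle_event_for_event(self):
        traj = random_walk_traj(n_ions=200, seed=12)
        got = as_set(detect_events(traj, COMP, "K+"))
        z = unwrapped_z(traj, "K+")
        times = np.array([f.time for f in traj.frames])
        want = set()
        for ion in range(z.shape[1]):
            want |= oracle_events(z[:, ion], times, COMP, ion, "K+")
        assert got == want
        assert len(got) > 50  # the fixture actually exercises the detector

    def test_time_reversal_swaps_directions(self):
        traj = random_walk_traj(n_ions=40, seed=3)
        fwd = detect_events(traj, COMP, "K+")
        # reverse frames: new time axis is t_max - t
        from gjpore import Frame, Trajectory

        tmax = traj.frames[-1].time
        rev = Trajectory(
            frames=[
                Frame(
                    time=tmax - f.time,
                    ion_positions=f.ion_positions,
                    protein_positions=f.protein_positions,
                    box=f.box,
                )
                for f in reversed(traj.frames)
            ]
        )
        bwd = detect_events(rev, COMP, "K+")
        flip = {"forward": "backward", "backward": "forward"}
        assert sorted((e.ion_id, e.kind, flip[e.direction]) for e in fwd) == sorted(
            (e.ion_id, e.kind, e.direction) for e in bwd
        )

    def test_event_intervals_do_not_overlap_per_ion_and_kind(self):
        traj = random_walk_traj(n_ions=100, seed=9)
        events = detect_events(traj, COMP, "K+")
        by_key = {}
        for e in events:
            by_key.setdefault((e.ion_id, e.kind), []).append((e.t_enter, e.t_exit))
        for spans in by_key.values():
            spans.sort()
            for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
                assert b1 <= a2


# ---------------------------------------------------------------------------
# replicate summary
# ---------------------------------------------------------------------------


def _ev(kind, t0, t1, ion=0):
    return CrossingEvent(ion, "K+", kind, "forward", t0, t1)


class TestSummarize:
    def test_mean_and_sd_across_replicates(self):
        reps = [[_ev("HC1", 0, 1)], [_ev("HC1", 0, 1), _ev("HC1", 2, 3), _ev("HC1", 4, 5)]]
        metas = [SimulationMeta(applied_voltage=-100.0, replicate_id=f"r{i}") for i in range(2)]
        table = summarize_events(reps, metas)
        row = table.rows.query("compartment == 'HC1' and species == 'K+'").iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sd"] == pytest.approx(np.sqrt(2.0))
        assert row["n_replicates"] == 2

    def test_all_zero_replicates(self):
        metas = [SimulationMeta(replicate_id=f"r{i}") for i in range(3)]
        table = summarize_events([[], [], []], metas)
        assert (table.rows["mean"] == 0).all()
        assert (table.rows["sd"] == 0).all()

    def test_three_replicates_match_hand_computation(self):
        reps = [
            [_ev("HC1", 0, 1), _ev("GJC", 0, 5)],
            [_ev("HC1", 0, 1)],
            [],
        ]
        metas = [SimulationMeta(replicate_id=f"r{i}") for i in range(3)]
        rows = summarize_events(reps, metas).rows
        hc1 = rows.query("compartment == 'HC1' and species == 'K+'").iloc[0]
        gjc = rows.query("compartment == 'GJC' and species == 'K+'").iloc[0]
        assert hc1["mean"] == pytest.approx(2 / 3)
        assert hc1["sd"] == pytest.approx(np.std([1, 1, 0], ddof=1))
        assert gjc["mean"] == pytest.approx(1 / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="metadata"):
            summarize_events([[]], [])
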
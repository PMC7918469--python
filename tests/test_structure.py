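import numpy as np
import pandas as pd
import pytest

from patchymd.engine import State, Trajectory
from patchymd.fixtures import generate_fixture
from patchymd.model import (
    InteractionMatrix,
    MixtureSpec,
    build_mixture,
    build_pure_system,
    build_species_catalog,
)
from patchymd.potential import ForceField, PotentialParams
from patchymd.rigid import random_unit_quaternions, rotvec_to_quat
from patchymd.structure import (
    MembershipLabels,
    TrajectoryTooShortError,
    com_layering_profile,
    exchange_rate,
    identify_condensates,
    mixture_order_parameters,
    molar_fraction_timeseries,
    weighted_family_profile,
)


def _chain_state(ff, n, rng):
    """A straight bonded chain of 2-valency particles along z."""
    box = np.array([30.0, 30.0, max(30.0, n * 1.2)])
    params = ff.params
    pos = np.zeros((n, 3))
    pos[:, 0] = 15.0
    pos[:, 1] = 15.0
    pos[:, 2] = 2.0 + np.arange(n) * params.well_position
    quats = np.tile(np.array([1.0, 0, 0, 0]), (n, 1))
    return State(
        box=box,
        positions=pos,
        orientations=quats,
        velocities=np.zeros((n, 3)),
        ang_momenta=np.zeros((n, 3)),
        species_index=np.zeros(n, dtype=np.intp),
        species_names=ff.species_names,
    )


class TestMembership:
    def test_bonded_chain_is_one_condensate(self):
        mix = build_pure_system("2v", 20)
        ff = ForceField(mix)
        st = _chain_state(ff, 20, np.random.default_rng(0))
        labels = identify_condensates(st, ff)
        assert labels.n_condensates == 1
        assert labels.sizes == (20,)
        assert np.all(labels.labels == 0)

    def test_ideal_gas_has_no_condensates(self):
        cat = build_species_catalog()
        mix = MixtureSpec("ideal", ((cat["2v"], 1),), InteractionMatrix({("2v", "2v"): 0.0}))
        ff = ForceField(mix)
        rng = np.random.default_rng(1)
        n = 100
        grid = np.array(
            [(i, j, k) for i in range(5) for j in range(5) for k in range(4)], float
        )
        st = State(
            box=np.array([20.0, 20.0, 20.0]),
            positions=(grid + 0.5) * 4.0 + rng.normal(0, 0.3, (n, 3)),
            orientations=random_unit_quaternions(n, rng),
            velocities=np.zeros((n, 3)),
            ang_momenta=np.zeros((n, 3)),
            species_index=np.zeros(n, dtype=np.intp),
            species_names=ff.species_names,
        )
        labels = identify_condensates(st, ff)
        assert labels.n_condensates == 0
        assert np.all(labels.labels == -1)

    def test_labels_partition_particles(self):
        mix = build_pure_system("2v", 30)
        ff = ForceField(mix)
        st = _chain_state(ff, 30, np.random.default_rng(2))
        # scatter the last 12 far away: a 18-chain condensate + dilute rest
        st.positions[18:, 2] = np.linspace(3.0, 25.0, 12)
        st.positions[18:, 0] = 2.0
        labels = identify_condensates(st, ff)
        in_cond = int(np.sum(labels.in_condensate))
        dilute = int(np.sum(labels.labels == -1))
        assert in_cond + dilute == 30
        assert labels.sizes[0] == 18

    def test_min_size_threshold(self):
        mix = build_pure_system("2v", 8)
        ff = ForceField(mix)
        st = _chain_state(ff, 8, np.random.default_rng(3))
        labels = identify_condensates(st, ff, min_size=10)
        assert labels.n_condensates == 0


class TestLayering:
    def test_constructed_core_shell_droplet(self):
        res = generate_fixture(
            "layered_droplet",
            {"n_core": 500, "n_shell": 500, "r_core": 5.0, "r_shell": 7.0,
             "box": (20.0, 20.0, 20.0), "n_frames": 6},
            seed=4,
        )
        prof = com_layering_profile(res.trajectory, res.labels, bins=20, r_max=9.0,
                                    geometry="droplet")
        core, shell = prof.densities["core"], prof.densities["shell"]
        r = prof.bin_centers
        inner = r < 4.5
        ring = (r > 5.4) & (r < 6.7)
        assert np.all(core[inner] > shell[inner])
        assert shell[ring].mean() > 5.0 * max(shell[inner].mean(), 1e-12)
        # shell species peaks inside the 5-7 sigma ring
        assert 5.0 < r[np.argmax(shell)] < 7.0

    def test_radial_profile_matches_slab_plateau(self):
        """For a thick slab, rho(d) near the center agrees with the z-profile."""
        from patchymd.coexistence import slab_density_profile

        res = generate_fixture(
            "tanh_slab",
            {"rho_l": 0.5, "rho_v": 0.002, "width": 0.4, "n_frames": 100,
             "box": (14.0, 14.0, 28.0), "slab_fraction": 0.55},
            seed=5,
        )
        traj = res.trajectory
        labels = [
            MembershipLabels(np.zeros(fr.n_particles, dtype=int), (fr.n_particles,))
            for fr in traj
        ]
        radial = com_layering_profile(traj, labels, bins=14, r_max=7.0, geometry="slab")
        slab = slab_density_profile(traj, bins=56, equilibration_fraction=0.0)
        lz = slab.box[2]
        z_plateau = slab.total[np.abs(slab.bin_centers - lz / 2) < 3.0].mean()
        r_plateau = radial.total[radial.bin_centers < 4.0].mean()
        assert r_plateau == pytest.approx(z_plateau, rel=0.03)

    def test_no_droplet_signals_error(self):
        res = generate_fixture("ideal_gas", {"n": 50, "n_frames": 3}, seed=6)
        labels = [
            MembershipLabels(np.full(50, -1, dtype=int), ()) for _ in res.trajectory
        ]
        with pytest.raises(ValueError, match="no droplet"):
            com_layering_profile(res.trajectory, labels)

    def test_weighted_family_profile_divides_by_type_count(self):
        res = generate_fixture("layered_droplet", {"n_frames": 2}, seed=7)
        prof = com_layering_profile(res.trajectory, res.labels, bins=10, r_max=9.0,
                                    geometry="droplet")
        w = weighted_family_profile(prof, scaffolds=("core",))
        np.testing.assert_allclose(w.scaffold, prof.densities["core"])
        np.testing.assert_allclose(w.client, prof.densities["shell"])
        assert w.n_scaffold_types == w.n_client_types == 1


class TestExchange:
    def test_scripted_fixture_formula_identity(self):
        res = generate_fixture(
            "exchange_script", {"k": 4, "n_intervals": 12, "box": (10.0, 10.0, 40.0)},
            seed=8,
        )
        out = exchange_rate(res.trajectory, res.labels)
        assert out.interfacial_area == pytest.approx(200.0)
        assert out.rates["A"] == pytest.approx(4.0 / 200.0)

    def test_frozen_trajectory_has_no_independent_frames(self):
        res = generate_fixture("exchange_script", {"k": 2, "n_intervals": 6, "hop": 0.0},
                               seed=9)
        with pytest.raises(TrajectoryTooShortError):
            exchange_rate(res.trajectory, res.labels)

    def test_rate_invariant_under_stride_doubling(self):
        """Equilibrium flicker: halving the frame rate leaves the rate unchanged."""
        rng = np.random.default_rng(10)
        n, frames = 400, 41
        box = np.array([10.0, 10.0, 40.0])
        traj = Trajectory(("A",), box)
        labels = []
        base = rng.random((n, 3)) * box
        for f in range(frames):
            pos = (base + np.array([1.5, 0.0, 0.0]) * f) % box
            traj.append(
                State(box=box, positions=pos,
                      orientations=np.tile([1.0, 0, 0, 0], (n, 1)),
                      velocities=np.zeros((n, 3)), ang_momenta=np.zeros((n, 3)),
                      species_index=np.zeros(n, dtype=np.intp), species_names=("A",),
                      time=float(f))
            )
            member = rng.random(n) < 0.5  # memoryless membership churn
            labels.append(MembershipLabels(np.where(member, 0, -1), (int(member.sum()),)))
        full = exchange_rate(traj, labels, hysteresis=False)
        traj2 = Trajectory(("A",), box)
        for fr in traj.frames[::2]:
            traj2.append(fr)
        half = exchange_rate(traj2, labels[::2], hysteresis=False)
        assert half.rates["A"] == pytest.approx(full.rates["A"], rel=0.1)

    def test_net_mode_bounded_by_mover_mode(self):
        """|Delta N| counting cancels simultaneous in/out movers, so it can
        never exceed the mover count; with one-directional scripted moves
        the two coincide."""
        res = generate_fixture("exchange_script", {"k": 3, "n_intervals": 8}, seed=21)
        movers = exchange_rate(res.trajectory, res.labels, mode="movers")
        net = exchange_rate(res.trajectory, res.labels, mode="net")
        assert net.rates["A"] <= movers.rates["A"]
        # round-robin toggling alternates direction only across cycles;
        # within the scripted run every interval moves k particles one way
        rng = np.random.default_rng(22)
        n, frames = 200, 21
        box = np.array([10.0, 10.0, 40.0])
        traj = Trajectory(("A",), box)
        labels = []
        base = rng.random((n, 3)) * box
        for f in range(frames):
            pos = (base + np.array([1.5, 0.0, 0.0]) * f) % box
            traj.append(
                State(box=box, positions=pos,
                      orientations=np.tile([1.0, 0, 0, 0], (n, 1)),
                      velocities=np.zeros((n, 3)), ang_momenta=np.zeros((n, 3)),
                      species_index=np.zeros(n, dtype=np.intp), species_names=("A",),
                      time=float(f))
            )
            member = rng.random(n) < 0.5
            labels.append(MembershipLabels(np.where(member, 0, -1), (int(member.sum()),)))
        movers = exchange_rate(traj, labels, hysteresis=False, mode="movers")
        net = exchange_rate(traj, labels, hysteresis=False, mode="net")
        # balanced random churn: net flux far below the mover count
        assert net.rates["A"] < 0.5 * movers.rates["A"]

    def test_invalid_mode_rejected(self):
        res = generate_fixture("exchange_script", {"k": 2, "n_intervals": 4}, seed=23)
        with pytest.raises(ValueError, match="mode"):
            exchange_rate(res.trajectory, res.labels, mode="telepathy")

    def test_hysteresis_suppresses_single_frame_flicker(self):
        res = generate_fixture("exchange_script", {"k": 3, "n_intervals": 10}, seed=11)
        traj, labels = res.trajectory, list(res.labels)
        # inject a one-frame flicker: particle leaves and returns immediately
        flicker = labels[4].labels.copy()
        # pick a member the script never touches again
        victim = int(np.flatnonzero(flicker == 0)[-1])
        flicker[victim] = -1
        labels[4] = MembershipLabels(flicker, (int(np.sum(flicker == 0)),))
        with_h = exchange_rate(traj, labels, hysteresis=True)
        without = exchange_rate(traj, labels, hysteresis=False)
        assert without.rates["A"] > with_h.rates["A"]


class TestMolarFractions:
    def test_single_species_fraction_is_one(self):
        mix = build_pure_system("2v", 15)
        ff = ForceField(mix)
        st = _chain_state(ff, 15, np.random.default_rng(12))
        traj = Trajectory(ff.species_names, st.box)
        labels = []
        for f in range(3):
            st2 = st.copy()
            st2.time = float(f)
            traj.append(st2)
            labels.append(identify_condensates(st2, ff))
        df = molar_fraction_timeseries(traj, labels)
        assert np.allclose(df["2v"], 1.0)

    def test_scaffold_peak_then_plateau_in_growth_script(self):
        """Scaffold-first nucleation: early scaffold-pure nucleus, clients later."""
        box = np.array([12.0, 12.0, 12.0])
        names = ("scaffold", "client")
        n_s = n_c = 40
        traj = Trajectory(names, box)
        labels = []
        rng = np.random.default_rng(13)
        pos = rng.random((n_s + n_c, 3)) * box
        sidx = np.repeat([0, 1], [n_s, n_c]).astype(np.intp)
        # scripted growth: condensate starts all-scaffold, clients join over time
        schedule = [(10, 0), (20, 2), (30, 10), (36, 22), (38, 30), (38, 32), (38, 32)]
        for f, (ns_in, nc_in) in enumerate(schedule):
            traj.append(
                State(box=box, positions=pos, orientations=np.tile([1.0, 0, 0, 0], (80, 1)),
                      velocities=np.zeros((80, 3)), ang_momenta=np.zeros((80, 3)),
                      species_index=sidx, species_names=names, time=float(f))
            )
            lab = np.full(80, -1, dtype=int)
            lab[:ns_in] = 0
            lab[n_s : n_s + nc_in] = 0
            labels.append(MembershipLabels(lab, (ns_in + nc_in,)))
        df = molar_fraction_timeseries(traj, labels)
        assert df["scaffold"].iloc[0] == pytest.approx(1.0)
        early_max = df["scaffold"].iloc[:2].max()
        plateau = df["scaffold"].iloc[-2:].mean()
        assert early_max > plateau
        total = df[["scaffold", "client"]].sum(axis=1)
        np.testing.assert_allclose(total, 1.0)

    def test_frames_without_condensate_are_missing(self):
        res = generate_fixture("ideal_gas", {"n": 20, "n_frames": 2}, seed=14)
        labels = [MembershipLabels(np.full(20, -1, dtype=int), ()) for _ in res.trajectory]
        df = molar_fraction_timeseries(res.trajectory, labels)
        assert df["A"].isna().all()


class TestOrderParameters:
    def test_valency_driven_hand_computed_delta(self):
        op = mixture_order_parameters(build_mixture("valency_driven"))
        assert op.delta_valency == pytest.approx(4.0 - 2.5625)
        assert set(op.scaffolds) == {"4v-promiscuous", "4v-selective"}
        assert set(op.clients) == {"3v-good", "3v-poor", "2.25v", "2v"}

    def test_non_competing_per_condensate_scaffolds(self):
        mix = build_mixture("non_competing")
        promiscuous = mixture_order_parameters(mix, scaffolds=("4v-promiscuous",))
        assert promiscuous.delta_valency == pytest.approx(4.0 - 2.25)
        assert promiscuous.clients == ("2.25v",)
        selective = mixture_order_parameters(mix, scaffolds=("4v-selective",))
        assert selective.delta_valency == pytest.approx(4.0 - 2.0)

    def test_single_species_mixture_zero_variance(self):
        op = mixture_order_parameters(
            build_pure_system("4v-promiscuous"), scaffolds=("4v-promiscuous",)
        )
        assert op.affinity_variance == 0.0

    def test_mixture_without_scaffold_rejected(self):
        with pytest.raises(ValueError, match="scaffold"):
            mixture_order_parameters(build_pure_system("2v"))

    def test_affinity_variance_over_21_pairs(self):
        mix = build_mixture("valency_driven")
        vals = [4.0, 4.0, 3.0, 3.0, 2.25, 2.0]
        scores = [
            0.5 * (vals[i] + vals[j])
            for i in range(6)
            for j in range(i, 6)
        ]
        assert len(scores) == 21
        op = mixture_order_parameters(mix)
        assert op.affinity_variance == pytest.approx(np.var(scores))

    def test_presets_span_increasing_heterogeneity(self):
        """Affinity variance grows from the all-binding control to the
        scaffold-partitioned mixtures."""
        var = {
            name: mixture_order_parameters(build_mixture(name)).affinity_variance
            for name in ("valency_driven", "like_valency", "non_competing")
        }
        assert var["valency_driven"] < var["like_valency"] < var["non_competing"]
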
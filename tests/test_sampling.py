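"""Sampling physics: integrators, replica exchange, WHAM, clustering."""

import numpy as np
import pytest

from cgres.constants import KB
from cgres.geometry import CGChain
from cgres.pipeline import RestrainedPotential
from cgres.sampling import (
    MDState, ReplicaEnsemble, cluster_ensemble, ensemble_average,
    exchange_sweep, md_run, remd_run, wham_reweight,
)

from conftest import NO_RESTRAINTS, zero_weight_ff


def dimer_potential():
    """Harmonic dimer: only the bond terms are active."""
    ff = zero_weight_ff()
    ff.w_bond = 1.0
    return RestrainedPotential("AA", ff=ff, weights=NO_RESTRAINTS)


def dimer_chain():
    ca = np.array([[0.0, 0, 0], [4.2, 0.2, -0.3]])
    sc = np.array([[0.1, 1.5, 0], [4.3, 1.7, -0.3]])
    return CGChain("AA", ca, sc)


class TestMD:
    def test_nve_energy_conservation_harmonic_dimer(self):
        """Relative total-energy deviation < 1e-5 over 1e5 steps."""
        pot = dimer_potential()
        st = MDState.from_chain(dimer_chain(), 300.0, seed=1)
        e0 = st.kinetic_energy() + pot.evaluate(st.chain, 300.0)[0]
        traj = md_run(st, pot, 100000, dt=0.2, thermostat="none", seed=1,
                      log_interval=1000)
        drift = np.abs(traj.epot + traj.ekin - e0) / abs(e0)
        assert drift.max() < 1e-5

    def test_langevin_equipartition(self):
        """Long-run kinetic temperature within 5% of the bath."""
        pot = dimer_potential()
        st = MDState.from_chain(dimer_chain(), 300.0, seed=2)
        traj = md_run(st, pot, 200000, dt=5.0, thermostat="langevin", seed=2,
                      friction=2e-3, log_interval=100)
        burn = len(traj.ekin) // 5
        tkin = traj.ekin[burn:] * 2.0 / (KB * 12)
        assert abs(tkin.mean() - 300.0) / 300.0 < 0.05

    def test_zero_force_uniform_linear_motion(self):
        pot = RestrainedPotential("AA", ff=zero_weight_ff(), weights=NO_RESTRAINTS)
        st = MDState.from_chain(dimer_chain(), 300.0, seed=3)
        x0 = st.chain.calpha.copy()
        v0 = st.vca.copy()
        md_run(st, pot, 1000, dt=2.0, thermostat="none", seed=3, log_interval=0)
        assert np.allclose(st.chain.calpha, x0 + 1000 * 2.0 * v0, atol=1e-9)
        assert np.allclose(st.vca, v0, atol=1e-15)

    def test_seeded_runs_bitwise_reproducible(self):
        pot = dimer_potential()
        outs = []
        for _ in range(2):
            st = MDState.from_chain(dimer_chain(), 300.0, seed=7)
            md_run(st, pot, 5000, dt=5.0, thermostat="langevin", seed=7,
                   log_interval=0)
            outs.append((st.chain.calpha.copy(), st.vsc.copy()))
        assert np.array_equal(outs[0][0], outs[1][0])
        assert np.array_equal(outs[0][1], outs[1][1])

    def test_berendsen_drives_to_bath_temperature(self):
        pot = dimer_potential()
        st = MDState.from_chain(dimer_chain(), 600.0, seed=4)
        st.temperature = 300.0
        traj = md_run(st, pot, 50000, dt=5.0, thermostat="berendsen", seed=4,
                      tau=500.0, log_interval=500)
        tkin = traj.ekin[-20:] * 2.0 / (KB * 12)
        assert abs(tkin.mean() - 300.0) / 300.0 < 0.15

    def test_energy_explosion_detected(self):
        from cgres.sampling import EnergyExplosion

        pot = RestrainedPotential("AA")  # full force field, steep LJ
        ca = np.array([[0.0, 0, 0], [0.05, 0, 0]])  # overlapping sites
        st = MDState.from_chain(CGChain("AA", ca, ca + 0.01), 300.0, seed=5)
        with pytest.raises(EnergyExplosion):
            md_run(st, pot, 5000, dt=50.0, thermostat="none", seed=5)


class TestExchange:
    def test_equal_energies_always_accepted(self):
        rng = np.random.default_rng(0)
        e = np.array([5.0, 5.0, 5.0, 5.0])
        T = np.array([300.0, 320.0, 340.0, 360.0])
        for parity in (0, 1):
            perm, att, acc = exchange_sweep(e, T, parity, rng)
            assert np.all(acc[att])

    def test_accepted_never_exceeds_attempted(self):
        pot = dimer_potential()
        ens = ReplicaEnsemble.from_chain(
            dimer_chain(), [280.0, 300.0, 320.0], exchange_interval=200, seed=1
        )
        remd_run(ens, pot, 4000, seed=1, dt=5.0)
        assert np.all(ens.accepted <= ens.attempted)
        assert np.all(ens.attempted > 0)

    def test_single_replica_reduces_to_md_run(self):
        pot = dimer_potential()
        ens = ReplicaEnsemble.from_chain(dimer_chain(), [300.0],
                                         exchange_interval=500, seed=9)
        remd_run(ens, pot, 2000, seed=9, dt=5.0)
        # replay: same chunked md_run calls with the same derived seeds
        st = MDState.from_chain(dimer_chain(), 300.0, seed=9)
        rng = np.random.default_rng(9)
        for _ in range(4):
            md_run(st, pot, 500, dt=5.0, thermostat="langevin",
                   seed=int(rng.integers(0, 2**31 - 1)), log_interval=0)
        assert np.array_equal(ens.states[0].chain.calpha, st.chain.calpha)
        assert np.array_equal(ens.states[0].vca, st.vca)

    def test_two_state_occupancies_match_boltzmann(self):
        """Replica-exchanged 2-state Metropolis walkers reproduce the
        exactly enumerable Boltzmann occupancies at every ladder
        temperature (within 3 Monte-Carlo standard errors)."""
        rng = np.random.default_rng(123)
        temps = np.array([250.0, 400.0])
        dE = 0.5  # kcal/mol gap between the two states
        nsweeps = 20000
        states = np.array([0, 1])  # walker state at each temperature slot
        counts = np.zeros((2, 2))  # [slot, state]
        for sweep in range(nsweeps):
            # per-slot Metropolis flip attempt
            for k in range(2):
                new = 1 - states[k]
                delta = dE * (new - states[k])
                if delta <= 0 or rng.random() < np.exp(-delta / (KB * temps[k])):
                    states[k] = new
            e = dE * states
            perm, att, acc = exchange_sweep(e.astype(float), temps, sweep % 2, rng)
            states = states[perm]
            for k in range(2):
                counts[k, states[k]] += 1
        for k, T in enumerate(temps):
            z = 1.0 + np.exp(-dE / (KB * T))
            p_exact = np.exp(-dE / (KB * T)) / z
            p_obs = counts[k, 1] / nsweeps
            # conservative SE ignoring autocorrelation would be too tight;
            # use an effective sample size of nsweeps/10
            se = np.sqrt(p_exact * (1 - p_exact) / (nsweeps / 10))
            assert abs(p_obs - p_exact) < 3 * se

    def test_velocity_rescaling_on_temperature_swap(self):
        pot = dimer_potential()
        ens = ReplicaEnsemble.from_chain(dimer_chain(), [300.0, 310.0],
                                         exchange_interval=100, seed=2)
        remd_run(ens, pot, 1000, seed=2, dt=5.0)
        temps = sorted(st.temperature for st in ens.states)
        assert temps == [300.0, 310.0]


class TestWHAM:
    def test_single_source_at_target_gives_uniform_weights(self):
        rng = np.random.default_rng(0)
        E = rng.uniform(0, 5, 200)
        w, info = wham_reweight(E, np.full(200, 300.0), 300.0)
        assert np.allclose(w, 1.0 / 200, atol=1e-12)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(1)
        E = rng.uniform(0, 5, 300)
        Ts = rng.choice([280.0, 300.0, 330.0], 300)
        w, _ = wham_reweight(E, Ts, 310.0)
        assert w.sum() == pytest.approx(1.0, abs=1e-10)

    def test_harmonic_energy_recovery_at_intermediate_temperature(self):
        """1-D harmonic oscillator: ⟨E⟩(T) = k_B T/2; reweighting samples
        from 3 temperatures recovers it within 3 SE."""
        rng = np.random.default_rng(42)
        k_spring = 1.0
        temps = (260.0, 300.0, 340.0)
        E, src = [], []
        for T in temps:
            x = rng.normal(0.0, np.sqrt(KB * T / k_spring), 4000)
            E.append(0.5 * k_spring * x**2)
            src.append(np.full(4000, T))
        E = np.concatenate(E)
        src = np.concatenate(src)
        for target in (280.0, 300.0, 320.0):
            w, _ = wham_reweight(E, src, target)
            mean, se = ensemble_average(E, w)
            assert abs(mean - 0.5 * KB * target) < 3 * max(se, 1e-6)

    def test_boltzmann_reduction_for_single_source_temperature(self):
        rng = np.random.default_rng(3)
        E = rng.uniform(0, 3, 500)
        w, _ = wham_reweight(E, np.full(500, 350.0), 300.0)
        beta_d = 1.0 / (KB * 300.0) - 1.0 / (KB * 350.0)
        ref = np.exp(-beta_d * E)
        ref /= ref.sum()
        assert np.allclose(w, ref, rtol=1e-8)


class TestClustering:
    def _copies(self, base, rng, n, jitter=0.05):
        return [
            CGChain(base.sequence,
                    base.calpha + jitter * rng.standard_normal(base.calpha.shape),
                    base.sc + jitter * rng.standard_normal(base.sc.shape))
            for _ in range(n)
        ]

    def test_identical_conformations_single_cluster(self, helix12):
        clusters = cluster_ensemble([helix12.copy() for _ in range(6)], cutoff=1.0)
        assert len(clusters) == 1
        assert clusters[0]["weight"] == pytest.approx(1.0)

    def test_two_separated_conformations_two_clusters(self, helix12, rng):
        from cgres.fixtures import FixtureSpec, make_reference

        other = make_reference(FixtureSpec(topology="hairpin", length=12))
        confs = self._copies(helix12, rng, 4) + self._copies(other, rng, 4)
        clusters = cluster_ensemble(confs, cutoff=2.0)
        assert len(clusters) == 2

    def test_planted_three_cluster_recovery(self, rng):
        from cgres.fixtures import FixtureSpec, make_reference

        bases = [
            make_reference(FixtureSpec(topology=t, length=14))
            for t in ("helix", "hairpin", "two-domain")
        ]
        confs, labels = [], []
        for li, b in enumerate(bases):
            confs.extend(self._copies(b, rng, 5))
            labels.extend([li] * 5)
        weights = np.full(len(confs), 1.0 / len(confs))
        clusters = cluster_ensemble(confs, weights, n_clusters=3)
        assert len(clusters) == 3
        for c in clusters:
            assert len({labels[m] for m in c["members"]}) == 1

    def test_requesting_more_clusters_than_members_fails(self, helix12):
        with pytest.raises(ValueError):
            cluster_ensemble([helix12], n_clusters=3)
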
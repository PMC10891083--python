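"""Circuit construction, background drive, stimulus and simulation."""

import numpy as np
import pytest

from micropam.cells import APICAL, InterneuronParams, init_state, step_neuron
from micropam.circuit import (
    APICAL_OU_SITES,
    CircuitConfig,
    ConfigError,
    SpikeData,
    apical_stimulus,
    attach_stimulus,
    basal_stimulus,
    build_circuit,
    ou_params,
    place_ou_processes,
    simulate,
)


@pytest.fixture(scope="module")
def small_cfg():
    return CircuitConfig(duration=1200.0)


@pytest.fixture(scope="module")
def built(small_cfg):
    return build_circuit(small_cfg, seed=42)


class TestBuildCircuit:
    def test_full_scale_counts(self):
        cfg = CircuitConfig(N_total=1000, scale=1.0)
        assert cfg.counts() == {"Pyr": 800, "SST": 50, "PV": 70, "VIP": 80}

    def test_desk_scale_counts(self):
        cfg = CircuitConfig(N_total=1000, scale=0.2)
        assert cfg.counts() == {"Pyr": 160, "SST": 10, "PV": 14, "VIP": 16}

    def test_bad_fractions_raise(self):
        with pytest.raises(ConfigError):
            CircuitConfig(fractions={"Pyr": 0.5, "SST": 0.1, "PV": 0.1,
                                     "VIP": 0.1})

    def test_deterministic_adjacency(self, small_cfg):
        c1 = build_circuit(small_cfg, seed=7)
        c2 = build_circuit(small_cfg, seed=7)
        for ch1, ch2 in zip(c1.channels, c2.channels):
            assert np.array_equal(ch1.W, ch2.W)
        assert np.array_equal(c1.positions, c2.positions)

    def test_positions_in_volume(self, built):
        assert np.all(built.positions >= 0)
        assert np.all(built.positions <= np.array([500.0, 500.0, 950.0]))

    def test_realized_connection_probabilities(self):
        """Realized Bernoulli probabilities within 3 SE of configured."""
        cfg = CircuitConfig(N_total=1000, scale=0.5)
        circ = build_circuit(cfg, seed=3)
        for (pre, post), sp in cfg.synapses.items():
            cid, pre_idx, post_idx = circ.class_index[(pre, post)]
            W = circ.channels[cid].W[np.ix_(pre_idx, post_idx)]
            n = W.size - (pre_idx.size if pre == post else 0)
            k = np.count_nonzero(W)
            p_hat = k / n
            se = np.sqrt(sp.p_connect * (1 - sp.p_connect) / n)
            assert abs(p_hat - sp.p_connect) < 3 * se + 1e-12, (pre, post)


class TestOuParams:
    def test_at_soma(self):
        assert ou_params(2.0, 0.0) == (2.0, 2.0)

    def test_at_tip(self):
        m, s = ou_params(2.0, 1.0)
        assert m == pytest.approx(2.0 * np.e)
        assert s == m

    def test_domain_error(self):
        with pytest.raises(ConfigError):
            ou_params(1.0, 1.5)

    def test_interneuron_gets_one_midway_process(self):
        procs = place_ou_processes(InterneuronParams(), 1.0)
        assert len(procs) == 1
        assert procs[0].X_relative == 0.5

    def test_pyr_apical_process_set(self):
        from micropam.cells import PyrNeuronParams
        procs = place_ou_processes(PyrNeuronParams(), 1.5)
        apical = [p for p in procs if p.compartment == APICAL]
        # midway process plus the five distributed ones
        assert len(apical) == 6
        total = sum(p.g_mean for p in apical)
        expected = 1.5 * (np.exp(0.5) + sum(np.exp(x) for x in APICAL_OU_SITES))
        assert total == pytest.approx(expected)

    def test_zero_g_silent_background(self):
        cfg = CircuitConfig()
        cfg.ou_g = {p: 0.0 for p in cfg.ou_g}
        circ = build_circuit(cfg, seed=1)
        assert np.all(circ.ou_mean_soma == 0.0)
        assert np.all(circ.ou_sd_api == 0.0)


class TestAttachStimulus:
    def test_scaled_counts(self, built):
        circ = attach_stimulus(built, basal_stimulus(onset=1000.0), seed=5)
        # 55 Pyr, 35 PV, 65+80 VIP at s=0.2 -> 11, 7, 13+16
        assert len(circ.stim_events) == 11 + 7 + 13 + 16

    def test_apical_variant_targets_apical(self, built):
        circ = attach_stimulus(built, apical_stimulus(onset=1000.0), seed=5)
        pyr_events = [ev for ev in circ.stim_events if ev[1] == "apical"]
        assert len(pyr_events) == 17  # round(85 * 0.2)

    def test_different_seeds_different_subsets(self, built):
        c1 = attach_stimulus(built, basal_stimulus(onset=1000.0), seed=1)
        c2 = attach_stimulus(built, basal_stimulus(onset=1000.0), seed=2)
        assert c1.stim_events != c2.stim_events
        assert len(c1.stim_events) == len(c2.stim_events)

    def test_count_exceeding_population_raises(self, built):
        from micropam.circuit import StimulusGroup, StimulusProtocol
        proto = StimulusProtocol(groups=(
            StimulusGroup("SST", 500, (1.0, 2.0), 1.0),), onset=100.0)
        with pytest.raises(ConfigError):
            attach_stimulus(built, proto, seed=0)


class TestSimulate:
    def test_silent_without_input(self):
        cfg = CircuitConfig()
        cfg.ou_g = {p: 0.0 for p in cfg.ou_g}
        circ = build_circuit(cfg, seed=1)
        sd, _ = simulate(circ, duration=300.0, seed=2, record_axial=False)
        assert sum(len(t) for t in sd.spike_times) == 0

    def test_same_seed_identical_spikes(self, built):
        sd1, _ = simulate(built, duration=600.0, seed=9, record_axial=False)
        sd2, _ = simulate(built, duration=600.0, seed=9, record_axial=False)
        for a, b in zip(sd1.spike_times, sd2.spike_times):
            assert np.array_equal(a, b)

    def test_healthy_rate_in_calibration_band(self):
        """Healthy baseline Pyr rate in the 0.5-1.0 Hz target band."""
        cfg = CircuitConfig()
        rates = []
        for s in range(3):
            circ = build_circuit(cfg, seed=60 + s)
            sd, _ = simulate(circ, duration=2700.0, seed=70 + s,
                             record_axial=False)
            rates.append(sd.population_rate("Pyr", (200.0, 2700.0)))
        assert 0.5 <= np.mean(rates) <= 1.0

    def test_interneurons_fire_above_pyr(self):
        cfg = CircuitConfig()
        circ = build_circuit(cfg, seed=80)
        sd, _ = simulate(circ, duration=2200.0, seed=81, record_axial=False)
        pyr = sd.population_rate("Pyr", (200.0, 2200.0))
        for pop in ("SST", "PV", "VIP"):
            assert sd.population_rate(pop, (200.0, 2200.0)) > pyr

    def test_ou_multiplier_strictly_increases_rate(self):
        rates = []
        for m in (1.0, 3.0, 6.0):
            cfg = CircuitConfig(m_ou=m)
            circ = build_circuit(cfg, seed=21)
            sd, _ = simulate(circ, duration=1200.0, seed=22,
                             record_axial=False)
            rates.append(sd.population_rate("Pyr", (200.0, 1200.0)))
        assert rates[0] < rates[1] < rates[2]

    def test_axial_trace_shape_and_finite(self, built):
        sd, axial = simulate(built, duration=400.0, seed=3)
        n_pyr = int(np.count_nonzero(built.types == "Pyr"))
        assert axial.shape == (4000, n_pyr)
        assert np.all(np.isfinite(axial))

    def test_disconnected_neuron_matches_single_neuron_oracle(self):
        """A circuit with no synapses driven by OU background fires at the
        rate of an equivalent independently simulated single neuron."""
        cfg = CircuitConfig()
        for sp in cfg.synapses.values():
            sp.p_connect = 0.0
        circ = build_circuit(cfg, seed=101)
        sd, _ = simulate(circ, duration=5000.0, seed=102, record_axial=False)
        net_rate = sd.population_rate("PV", (200.0, 5000.0))

        # oracle: scalar integration of one PV neuron with its own OU draw
        ip = cfg.interneurons["PV"]
        from micropam.cells import TonicConductance
        from dataclasses import replace
        tc = replace(cfg.tonic, G_tonic=cfg.tonic_G)
        g_mean = g_sd = cfg.ou_g["PV"] * np.exp(0.5)
        rng = np.random.default_rng(1234)
        dt = cfg.dt
        rho = np.exp(-dt / cfg.ou_tau)
        noise = np.sqrt(1 - rho**2)
        n_steps = int(60_000 / dt)
        state = init_state(ip)
        g_ou = g_mean
        spikes = 0
        for k in range(n_steps):
            g_ou = g_mean + (g_ou - g_mean) * rho \
                + g_sd * noise * rng.standard_normal()
            g_ou = max(g_ou, 0.0)
            # conductance input folded into current at the present potential
            I = -g_ou * (state.V[0] - 0.0)
            state = step_neuron(state, ip, I, dt, tonic=tc)
            spikes += state.spiked
        oracle_rate = spikes / 60.0
        # Monte-Carlo + discretization agreement
        assert net_rate == pytest.approx(oracle_rate, rel=0.25)


class TestSpikeDataIO:
    def test_csv_roundtrip(self, built, tmp_path):
        sd, _ = simulate(built, duration=500.0, seed=12, record_axial=False)
        path = tmp_path / "spikes.csv"
        sd.to_csv(path)
        back = SpikeData.from_csv(path)
        assert back.duration == sd.duration
        assert np.array_equal(back.types, sd.types)
        for a, b in zip(sd.spike_times, back.spike_times):
            assert np.allclose(a, b)

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = CircuitConfig(scale=0.4, m_ou=3.0)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = CircuitConfig.from_yaml(path)
        assert back.scale == 0.4
        assert back.m_ou == 3.0
        assert back.counts() == cfg.counts()
        key = ("SST", "Pyr")
        assert back.synapses[key].g_syn == cfg.synapses[key].g_syn
        assert back.synapses[key].target == cfg.synapses[key].target
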
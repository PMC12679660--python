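"""Field construction, single-step dynamics and plasticity rules."""

import numpy as np
import pytest
from dataclasses import replace

from cortigen.errors import (
    InvalidGeometryError,
    InvalidParameterError,
    UnbalancedFieldError,
    WarmUpError,
)
from cortigen.field import (
    ActivationFunction,
    DendriticKernel,
    FieldConfig,
    FieldGeometry,
    GainState,
    PlasticityConfig,
    PlasticityState,
    anti_hebbian_normalize,
    build_field,
    hebbian_update,
    records_equal,
    simulate,
    step,
    white_noise_drive,
)


def chain_gain_state(n, weights, ei=None):
    """Gain state for an open chain 0-1-...-n with given forward weights."""
    mask = np.zeros((n, n), dtype=bool)
    g = np.zeros((n, n))
    for (i, j), w in weights.items():
        mask[i, j] = True
        g[i, j] = w
    ei = np.ones(n, dtype=int) if ei is None else np.asarray(ei)
    sign = np.tile(ei[None, :].astype(float), (n, 1))
    return GainState(eps=mask.astype(float), g=g, rho=mask.astype(float),
                     sign=sign, mask=mask)


# --------------------------------------------------------------------------
# geometry and delays
# --------------------------------------------------------------------------


class TestBuildField:
    def test_two_neuron_delay_is_distance_over_speed(self):
        cfg = FieldConfig(n=2, v=1.0, dt=1.0,
                          positions=np.array([[0.0, 0.0], [1.0, 0.0]]))
        geo, _ = build_field(cfg)
        assert geo.delay_matrix.tolist() == [[0, 1], [1, 0]]

    def test_fast_conduction_gives_zero_delays(self):
        cfg = FieldConfig(n=3, v=1e9, seed=1)
        geo, _ = build_field(cfg)
        assert geo.delay_matrix.max() == 0

    def test_collinear_delays_match_bruteforce_euclidean(self):
        pos = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        geo, _ = build_field(FieldConfig(n=3, v=1.0, positions=pos))
        expected = np.rint(
            np.sqrt(((pos[:, None] - pos[None]) ** 2).sum(-1))
        ).astype(int)
        assert np.array_equal(geo.delay_matrix, expected)
        assert sorted(set(geo.delay_matrix.ravel())) == [0, 1, 2]

    def test_delay_matrix_symmetric_zero_diagonal(self):
        geo, _ = build_field(FieldConfig(n=32, seed=4))
        assert np.array_equal(geo.delay_matrix, geo.delay_matrix.T)
        assert np.all(np.diag(geo.delay_matrix) == 0)

    def test_every_neuron_has_both_afferent_types(self):
        geo, gains = build_field(FieldConfig(n=24, seed=3))
        e = geo.ei_label > 0
        assert gains.mask[:, e].any(axis=1).all()
        assert gains.mask[:, ~e].any(axis=1).all()

    def test_nonfinite_positions_rejected(self):
        pos = np.array([[0.0, 0.0], [np.nan, 1.0]])
        with pytest.raises(InvalidGeometryError):
            build_field(FieldConfig(n=2, positions=pos))

    def test_zero_conduction_speed_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_field(FieldConfig(n=4, v=0.0))

    def test_absent_connections_have_zero_gain(self):
        _, gains = build_field(FieldConfig(n=24, seed=3))
        off = ~gains.mask
        assert np.all(gains.g[off] == 0)
        assert np.all(gains.effective()[off] == 0)


# --------------------------------------------------------------------------
# drive
# --------------------------------------------------------------------------


class TestWhiteNoiseDrive:
    def test_zero_amplitude_is_silent(self):
        assert np.all(white_noise_drive(4, 100, 0.0, seed=0).samples == 0)

    def test_seed_reproducibility_is_bit_exact(self):
        a = white_noise_drive(8, 500, 1.0, seed=42).samples
        b = white_noise_drive(8, 500, 1.0, seed=42).samples
        assert np.array_equal(a, b)

    def test_large_sample_statistics(self):
        steps = 10 ** 5
        d = white_noise_drive(2, steps, 1.0, seed=7).samples
        assert np.abs(d.mean(axis=0)).max() < 4.0 / np.sqrt(steps)
        r = np.corrcoef(d.T)[0, 1]
        assert abs(r) < 0.02

    def test_negative_amplitude_rejected(self):
        with pytest.raises(InvalidParameterError):
            white_noise_drive(2, 10, -1.0, seed=0)


# --------------------------------------------------------------------------
# single step
# --------------------------------------------------------------------------


class TestStep:
    def setup_method(self):
        pos = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        self.geo = FieldGeometry(
            positions=pos, ei_label=np.array([1, 1, -1]), v=1.0,
            delay_matrix=np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]]),
        )
        self.act = ActivationFunction(theta=0.0, slope=0.25, qmax=1.0)
        self.instant = DendriticKernel(form="instantaneous")

    def test_silent_field_rests_at_sigmoid_midpoint(self):
        gains = chain_gain_state(3, {})
        hist = np.zeros((3, 3))
        phi, v, q = step(hist, self.geo, gains, self.instant, self.act,
                         np.zeros(3))
        assert np.all(phi == 0) and np.all(v == 0)
        assert np.allclose(q, self.act(0.0))

    def test_impulse_arrives_after_conduction_delay(self):
        gains = chain_gain_state(3, {(2, 0): 1.0})   # neuron 0 -> neuron 2, d=2
        hist = np.zeros((6, 3))
        hist[2, 0] = 1.0                              # impulse at t=2
        arrivals = []
        for t in range(3, 6):
            phi, _, _ = step(hist[: t + 1], self.geo, gains, self.instant,
                             self.act, np.zeros(3))
            arrivals.append(phi[2, 0])
        # delay 2: the impulse generated at t=2 arrives at t=4
        assert arrivals == [0.0, 1.0, 0.0]

    def test_equal_excitatory_inhibitory_flux_cancels(self):
        gains = chain_gain_state(
            3, {(1, 0): 0.7, (1, 2): 0.7}, ei=[1, 1, -1])
        hist = np.ones((3, 3)) * 0.5
        drive = np.array([0.0, 0.3, 0.0])
        _, v, _ = step(hist, self.geo, gains, self.instant, self.act, drive)
        assert v[1] == pytest.approx(0.3)             # drive-only baseline

    def test_short_history_raises_warmup_error(self):
        gains = chain_gain_state(3, {(2, 0): 1.0})
        with pytest.raises(WarmUpError, match="zero"):
            step(np.zeros((1, 3)), self.geo, gains, self.instant, self.act,
                 np.zeros(3))

    def test_zero_padding_policy_accepts_short_history(self):
        gains = chain_gain_state(3, {(2, 0): 1.0})
        phi, _, _ = step(np.zeros((1, 3)), self.geo, gains, self.instant,
                         self.act, np.zeros(3), zero_pad=True)
        assert np.all(phi == 0)


# --------------------------------------------------------------------------
# Hebbian plasticity
# --------------------------------------------------------------------------


class TestHebbian:
    def setup_method(self):
        self.plast = PlasticityConfig()
        self.gains = chain_gain_state(2, {(0, 1): 0.5}, ei=[1, 1])
        self.gains.row_cap_e = np.full(2, 100.0)
        self.gains.row_cap_i = np.full(2, 100.0)

    def test_zero_flux_window_is_a_noop_for_g_and_rho(self):
        g = self.gains.copy()
        g.eps[0, 1] = 1.5                             # perturbed efficacy
        T = 30
        z2 = np.zeros((T, 2, 2))
        out, _ = hebbian_update(g, z2, np.zeros((T, 2)), z2, self.plast)
        assert np.array_equal(out.g, g.g)
        assert np.array_equal(out.rho, g.rho)
        assert out.eps[0, 1] < 1.5                    # decays toward baseline 1

    def test_sustained_coincidence_grows_g_strictly(self):
        g = self.gains.copy()
        st = None
        pre = np.zeros((1, 2, 2)); pre[0, 0, 1] = 0.8
        post = np.array([[0.8, 0.8]])
        phi = np.zeros((1, 2, 2)); phi[0, 0, 1] = 0.4
        values = [g.g[0, 1]]
        for _ in range(3):
            g, st = hebbian_update(g, pre, post, phi, self.plast, st)
            values.append(g.g[0, 1])
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_flux_ratio_preserves_rank_under_competition(self):
        gains = chain_gain_state(3, {(0, 1): 0.5, (0, 2): 0.5}, ei=[1, 1, 1])
        gains.row_cap_e = np.full(3, 1.05)            # competition binds
        gains.row_cap_i = np.full(3, 1.05)
        pre = np.zeros((1, 3, 3)); pre[0, 0, 1] = 0.8; pre[0, 0, 2] = 0.4
        post = np.array([[0.9, 0.0, 0.0]])
        phi = np.zeros((1, 3, 3)); phi[0, 0, 1] = 0.8; phi[0, 0, 2] = 0.4
        st = None
        g = gains
        for _ in range(50):
            g, st = hebbian_update(g, pre, post, phi, self.plast, st)
        assert g.g[0, 1] > g.g[0, 2]                  # rank order preserved
        assert g.g[0, 1] + g.g[0, 2] <= 1.05 + 1e-9  # row sum bounded

    def test_inhibitory_gains_untouched_by_hebbian_rule(self):
        gains = chain_gain_state(2, {(0, 1): 0.5}, ei=[1, -1])
        gains.row_cap_e = np.full(2, 100.0)
        pre = np.zeros((1, 2, 2)); pre[0, 0, 1] = 0.8
        post = np.array([[0.8, 0.8]])
        phi = np.zeros((1, 2, 2)); phi[0, 0, 1] = -0.4
        out, _ = hebbian_update(gains, pre, post, phi, PlasticityConfig())
        assert out.g[0, 1] == gains.g[0, 1]


# --------------------------------------------------------------------------
# anti-Hebbian balance
# --------------------------------------------------------------------------


class TestAntiHebbian:
    def _two_afferent_gains(self):
        # neuron 0 receives excitatory flux from 1 and inhibitory from 2
        return chain_gain_state(3, {(0, 1): 1.0, (0, 2): 1.0}, ei=[1, 1, -1])

    def test_already_balanced_window_leaves_gains_unchanged(self):
        gains = self._two_afferent_gains()
        phi = np.zeros((5, 3, 3))
        phi[:, 0, 1] = 2.0
        phi[:, 0, 2] = -2.0
        out, se, si = anti_hebbian_normalize(gains, phi, target=2.0)
        assert se[0] == pytest.approx(1.0) and si[0] == pytest.approx(1.0)
        assert np.array_equal(out.g, gains.g)

    def test_imbalanced_window_rescaled_to_target(self):
        gains = chain_gain_state(
            4, {(0, 1): 0.6, (0, 2): 0.3, (0, 3): 1.0}, ei=[1, 1, 1, -1])
        phi = np.zeros((4, 4, 4))
        phi[:, 0, 1] = 2.0; phi[:, 0, 2] = 1.0        # sum phi_e = 3
        phi[:, 0, 3] = -1.5                           # sum phi_i = -1.5
        out, se, si = anti_hebbian_normalize(gains, phi, target=2.0)
        s_e = 3.0 * se[0]
        s_i = 1.5 * si[0]
        assert abs(s_e - s_i) / 2.0 < 1e-6
        # within-block ratio untouched to machine precision
        assert out.g[0, 1] / out.g[0, 2] == pytest.approx(2.0, abs=1e-15)

    def test_missing_inhibitory_afferents_is_an_error(self):
        gains = chain_gain_state(3, {(0, 1): 1.0}, ei=[1, 1, -1])
        phi = np.zeros((2, 3, 3)); phi[:, 0, 1] = 1.0
        with pytest.raises(UnbalancedFieldError):
            anti_hebbian_normalize(gains, phi, target=1.0)

    def test_single_population_flag_skips_inhibitory_block(self):
        gains = chain_gain_state(2, {(0, 1): 1.0}, ei=[1, 1])
        phi = np.zeros((2, 2, 2)); phi[:, 0, 1] = 4.0
        out, se, _ = anti_hebbian_normalize(gains, phi, target=2.0,
                                            single_population=True)
        assert se[0] == pytest.approx(0.5)


# --------------------------------------------------------------------------
# orchestrated simulation
# --------------------------------------------------------------------------


class TestSimulate:
    def test_zero_steps_returns_empty_record_with_config(self):
        cfg = FieldConfig(n=8, seed=0)
        rec = simulate(cfg, 0)
        assert rec.steps == 0 and rec.config is cfg

    def test_determinism_bit_identical(self):
        cfg = FieldConfig(n=12, seed=9)
        a = simulate(cfg, 400, record_phi=True)
        b = simulate(cfg, 400, record_phi=True)
        assert records_equal(a, b)

    def test_long_run_bounded_and_finite(self):
        cfg = replace(FieldConfig(n=64, seed=2),
                      plasticity=PlasticityConfig(enabled=False))
        rec = simulate(cfg, 5000, record_phi=False)
        qmax = cfg.activation.qmax
        assert np.all(rec.Q >= 0) and np.all(rec.Q <= qmax)
        assert np.all(np.isfinite(rec.V))

    def test_balance_residuals_machine_small_after_each_event(self):
        rec = simulate(FieldConfig(n=16, seed=1), 800, record_phi=False)
        assert len(rec.norm_steps) >= 1
        assert rec.balance_residuals.max() < 1e-12

    def test_linearized_impulse_response_matches_convolution_oracle(self):
        """Small-signal chain vs an independently coded delayed convolution."""
        pos = np.array([[0.0, 0.0], [2.0, 0.0], [4.0, 0.0]])
        cfg = FieldConfig(
            n=3, v=1.0, positions=pos,
            activation=ActivationFunction(theta=0.0, slope=0.2, qmax=1.0,
                                          form="linear"),
            kernel=DendriticKernel(tau=1.5), kernel_inh=None,
            plasticity=PlasticityConfig(enabled=False),
            target_flux=0.0, single_population=True,
            connection_density=1.0, drive_amplitude=0.0,
        )
        geo, gains = build_field(cfg)
        # deterministic chain weights 0->1->2 (and symmetric back edges off)
        gains.g[:] = 0.0
        gains.g[1, 0] = 0.5
        gains.g[2, 1] = 0.5
        gains.mask[:] = False
        gains.mask[1, 0] = gains.mask[2, 1] = True
        gains.eps = gains.mask.astype(float)
        gains.rho = gains.mask.astype(float)

        steps = 40
        drive = np.zeros((steps, 3))
        drive[5, 0] = 1.0                             # impulse into neuron 0
        from cortigen.field import DriveSignal
        rec = simulate(cfg, steps, drive=DriveSignal(drive, 1.0, 0),
                       record_phi=False, gains=gains, geometry=geo)

        # independent oracle: explicit delayed-kernel convolution recurrence
        w = cfg.kernel.weights
        W = gains.g * gains.mask
        D = geo.delay_matrix
        slope, q0 = 0.2, 0.5
        Q = np.full((steps, 3), q0)
        agg = np.zeros((steps, 3))
        for t in range(steps):
            inp = drive[t].copy()
            for i in range(3):
                for j in range(3):
                    if W[i, j] and t - D[i, j] >= 0:
                        inp[i] += W[i, j] * Q[t - D[i, j], j]
                    elif W[i, j]:
                        inp[i] += 0.0
            agg[t] = inp
            v = np.zeros(3)
            for u in range(len(w)):
                if t - u >= 0:
                    v += w[u] * agg[t - u]
            Q[t] = q0 + slope * v
        assert np.allclose(rec.Q, Q, atol=1e-12)


class TestActivationAndKernel:
    @pytest.mark.parametrize("form", ["logistic", "linear"])
    def test_midpoint_and_bounds(self, form):
        act = ActivationFunction(theta=0.3, slope=0.5, qmax=2.0, form=form)
        assert act(0.3) == pytest.approx(1.0)
        v = np.linspace(-50, 50, 201)
        out = act(v)
        assert np.all(out >= 0) and np.all(out <= 2.0)
        assert np.all(np.diff(out) >= -1e-12)

    def test_kernel_nonnegative_unit_sum(self):
        for k in (DendriticKernel(tau=2.0), DendriticKernel(tau=0.3),
                  DendriticKernel(form="instantaneous")):
            w = k.weights
            assert np.all(w >= 0)
            assert w.sum() == pytest.approx(1.0)
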
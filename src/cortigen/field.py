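"""Delayed neural-field simulator with three-timescale Hebbian plasticity.

The model is a discrete-time network of ``n`` point neurons embedded in a
2-D sheet.  Each directed synapse carries presynaptic flux

    phi_ij(t) = sign_j * eps_ij * g_ij * rho_ij * Q_j(t - d_ij)

where ``d_ij`` is the axonal conduction delay (pairwise distance divided by
conduction speed ``v``, rounded to time steps), ``sign_j`` is +1 for an
excitatory and -1 for an inhibitory presynaptic neuron, and the three gain
factors live on fast (transient efficacy ``eps``), intermediate (dynamic
gain ``g``) and slow (structural gain ``rho``) timescales.  Aggregate flux
plus external drive is convolved with a leaky-integrator dendritic kernel to
give the membrane potential ``V_i(t)``, and a sigmoid threshold converts
potential to pulse rate ``Q_i(t)``.

Plasticity combines a Hebbian coincidence rule (fast ``eps``, potentiation
of ``g`` gated by a BCM-style sliding threshold, ``rho`` as a slow average
of ``g``, all competitively normalized per dendritic tree) with an
anti-Hebbian homeostatic step that rescales each neuron's excitatory and
inhibitory afferent blocks so that total excitatory and total inhibitory
flux are equal and opposite at a set level, leaving within-block gain
ratios untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import expit

from .errors import (
    DivergenceError,
    InvalidGeometryError,
    InvalidParameterError,
    UnbalancedFieldError,
    WarmUpError,
)

__all__ = [
    "ActivationFunction",
    "DendriticKernel",
    "DriveSignal",
    "FieldConfig",
    "FieldGeometry",
    "GainState",
    "PlasticityConfig",
    "PlasticityState",
    "SimulationRecord",
    "anti_hebbian_normalize",
    "build_field",
    "hebbian_update",
    "simulate",
    "step",
    "white_noise_drive",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ActivationFunction:
    """Pulse-generation sigmoid ``Q = f(V)``.

    ``f(theta) = qmax / 2`` and ``f'(theta) = slope`` for both forms.  The
    ``linear`` form is the tangent at threshold (clipped to ``[0, qmax]``)
    and exists so small-signal behaviour can be checked against closed-form
    linear convolution.
    """

    theta: float = 0.0
    slope: float = 0.25
    qmax: float = 1.0
    form: str = "logistic"

    def __post_init__(self):
        if self.qmax <= 0 or self.slope <= 0:
            raise InvalidParameterError("qmax and slope must be positive")
        if self.form not in ("logistic", "linear"):
            raise InvalidParameterError(f"unknown activation form {self.form!r}")

    def __call__(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        if self.form == "logistic":
            x = 4.0 * self.slope * (v - self.theta) / self.qmax
            return self.qmax * expit(x)
        out = self.qmax / 2.0 + self.slope * (v - self.theta)
        return np.clip(out, 0.0, self.qmax)


@dataclass(frozen=True)
class DendriticKernel:
    """Normalized leaky-integrator kernel convolving aggregate flux.

    ``exponential``: weights ``exp(-u/tau)`` for ``u = 0..support-1``,
    truncated at ``support`` (default ``ceil(5*tau)``) and normalized to
    unit sum.  ``instantaneous`` collapses to a single unit weight.
    """

    form: str = "exponential"
    tau: float = 2.0
    support: Optional[int] = None

    def __post_init__(self):
        if self.form not in ("exponential", "instantaneous"):
            raise InvalidParameterError(f"unknown kernel form {self.form!r}")
        if self.form == "exponential" and self.tau <= 0:
            raise InvalidParameterError("kernel tau must be positive")

    @property
    def weights(self) -> np.ndarray:
        if self.form == "instantaneous":
            return np.array([1.0])
        support = self.support or int(np.ceil(5.0 * self.tau))
        support = max(support, 1)
        w = np.exp(-np.arange(support) / self.tau)
        return w / w.sum()


@dataclass(frozen=True)
class FieldGeometry:
    """Static anatomy: positions, E/I identity, conduction delays."""

    positions: np.ndarray          # (n, 2) coordinates, length units
    ei_label: np.ndarray           # (n,) +1 excitatory, -1 inhibitory
    v: float                       # conduction speed, length units / step
    dt: float = 1.0
    delay_matrix: np.ndarray = None  # (n, n) integer steps
    single_population: bool = False

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def max_delay(self) -> int:
        return int(self.delay_matrix.max()) if self.n else 0

    @property
    def excitatory(self) -> np.ndarray:
        return self.ei_label > 0

    def distances(self) -> np.ndarray:
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        return np.sqrt((diff ** 2).sum(-1))


@dataclass
class GainState:
    """Signed three-timescale synaptic gains on a fixed connection mask."""

    eps: np.ndarray      # (n, n) transient efficacy
    g: np.ndarray        # (n, n) slow dynamic gain
    rho: np.ndarray      # (n, n) structural gain
    sign: np.ndarray     # (n, n) +1/-1 from presynaptic identity (column-wise)
    mask: np.ndarray     # (n, n) bool, True where a connection exists
    row_cap_e: np.ndarray = None   # per-dendrite competitive bound, E block
    row_cap_i: np.ndarray = None   # per-dendrite competitive bound, I block

    def copy(self) -> "GainState":
        return GainState(
            self.eps.copy(), self.g.copy(), self.rho.copy(),
            self.sign.copy(), self.mask.copy(),
            None if self.row_cap_e is None else self.row_cap_e.copy(),
            None if self.row_cap_i is None else self.row_cap_i.copy(),
        )

    def effective(self) -> np.ndarray:
        """Signed composite synaptic weight eps * g * rho (masked).

        The three gains compose multiplicatively so that a zero on any
        timescale silences the synapse.
        """
        return np.where(self.mask, self.sign * self.eps * self.g * self.rho, 0.0)


@dataclass(frozen=True)
class DriveSignal:
    """Seeded white-noise external drive sampled at neuron positions."""

    samples: np.ndarray    # (steps, n) flux units
    amplitude: float
    seed: int

    @property
    def steps(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class PlasticityConfig:
    """Learning-rule parameters; timescales in steps (T_eps << T_g << T_rho)."""

    enabled: bool = True
    eta_eps: float = 0.01         # fast coincidence rate for eps
    T_eps: float = 10.0           # eps decay back to baseline 1
    T_g: float = 2000.0           # dynamic-gain averaging
    T_rho: float = 10000.0        # structural-gain averaging
    T_bcm: float = 200.0          # sliding-threshold averaging
    bcm_target: float = 0.5       # q0 in theta = <Q^2>/q0
    g_cap_factor: float = 4.0     # competitive bound on per-block row sums
    norm_period: int = 100        # anti-Hebbian normalization interval
    balance_mode: str = "per_neuron"   # or "population"


@dataclass
class PlasticityState:
    """Running averages carried by the Hebbian rule between updates."""

    q_mean: np.ndarray       # (n,) running mean pulse rate
    theta_bcm: np.ndarray    # (n,) sliding modification threshold

    @classmethod
    def initial(cls, n: int) -> "PlasticityState":
        return cls(q_mean=np.zeros(n), theta_bcm=np.zeros(n))


@dataclass(frozen=True)
class FieldConfig:
    """Full specification of a simulated field (geometry + dynamics)."""

    n: int = 64
    domain: float = 10.0                  # side of bounded square sheet
    excitatory_fraction: float = 0.8
    v: float = 2.0                        # conduction speed
    dt: float = 1.0
    connection_density: float = 0.3
    connection_scale: Optional[float] = 5.0   # E-axon distance decay of P(connect)
    connection_scale_inh: Optional[float] = 1.5   # local inhibitory axons
    gain_init: float = 0.5                # lognormal median of initial g
    init_balanced: bool = False           # pre-scale gains to the set point
    gain_sigma: float = 0.5               # lognormal sigma of initial g
    target_flux: float = 3.0              # homeostatic flux set point
    drive_amplitude: float = 0.4
    kernel: DendriticKernel = field(default_factory=DendriticKernel)
    kernel_inh: Optional[DendriticKernel] = field(
        default_factory=lambda: DendriticKernel(tau=6.0)
    )  # slower inhibitory synaptodendritic integration; None = share kernel
    activation: ActivationFunction = field(default_factory=ActivationFunction)
    plasticity: PlasticityConfig = field(default_factory=PlasticityConfig)
    seed: int = 0
    single_population: bool = False
    positions: Optional[np.ndarray] = None    # override random placement


@dataclass
class SimulationRecord:
    """Time-indexed trajectories of one simulation run.

    ``phi`` is the full (steps, n, n) presynaptic-flux trajectory (float32;
    optional, it dominates memory).  ``exc_flux``/``inh_flux`` are per-step,
    per-neuron summed excitatory and inhibitory afferent flux, kept even
    when ``phi`` is dropped so homeostatic balance remains checkable.
    ``balance_residuals`` holds, for each anti-Hebbian event, the per-neuron
    value ``|sum phi_e + sum phi_i| / target`` recomputed after rescaling.
    """

    Q: np.ndarray                    # (steps, n)
    V: np.ndarray                    # (steps, n)
    drive: np.ndarray                # (steps, n)
    exc_flux: np.ndarray             # (steps, n)
    inh_flux: np.ndarray             # (steps, n)
    phi: Optional[np.ndarray]        # (steps, n, n) float32 or None
    geometry: FieldGeometry
    gains_final: GainState
    config: FieldConfig
    burn_in: int
    seed: int
    norm_steps: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    balance_residuals: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))

    @property
    def steps(self) -> int:
        return self.Q.shape[0]

    @property
    def n(self) -> int:
        return self.Q.shape[1]

    def directed_pairs(self) -> np.ndarray:
        """(m, 2) array of connected unordered pairs (i < j, both directions)."""
        mask = self.gains_final.mask
        both = mask & mask.T
        iu, ju = np.where(np.triu(both, 1))
        return np.stack([iu, ju], axis=1)


def records_equal(a: SimulationRecord, b: SimulationRecord) -> bool:
    """Bit-identity of trajectories (the determinism contract)."""
    if a.Q.shape != b.Q.shape:
        return False
    same = (
        np.array_equal(a.Q, b.Q)
        and np.array_equal(a.V, b.V)
        and np.array_equal(a.drive, b.drive)
        and np.array_equal(a.exc_flux, b.exc_flux)
        and np.array_equal(a.inh_flux, b.inh_flux)
    )
    if a.phi is not None and b.phi is not None:
        same = same and np.array_equal(a.phi, b.phi)
    return same


# --------------------------------------------------------------------------
# construction
# --------------------------------------------------------------------------


def build_field(config: FieldConfig) -> tuple[FieldGeometry, GainState]:
    """Create geometry (positions, delays) and seeded initial gains.

    Delays are pairwise Euclidean distance divided by conduction speed and
    the step size, rounded to the nearest integer step (minimum 0, zero
    diagonal).  The connection mask is symmetric Bernoulli with probability
    proportional to ``connection_density`` times a distance-decay profile;
    every neuron is guaranteed at least one excitatory and one inhibitory
    afferent unless the field is flagged single-population.
    """
    if config.n < 2:
        raise InvalidGeometryError("a field needs at least two neurons")
    if config.v <= 0:
        raise InvalidParameterError("conduction speed v must be positive")
    if not (0.0 < config.connection_density <= 1.0):
        raise InvalidParameterError("connection density must be in (0, 1]")
    if config.dt <= 0:
        raise InvalidParameterError("dt must be positive")

    rng = np.random.default_rng(config.seed)
    if config.positions is not None:
        positions = np.asarray(config.positions, dtype=float)
        if positions.shape != (config.n, 2):
            raise InvalidGeometryError(
                f"positions must have shape ({config.n}, 2), got {positions.shape}"
            )
    else:
        positions = rng.uniform(0.0, config.domain, size=(config.n, 2))
    if not np.all(np.isfinite(positions)):
        raise InvalidGeometryError("positions must be finite")

    n = config.n
    if config.single_population:
        ei = np.ones(n, dtype=int)
    else:
        n_e = int(round(n * config.excitatory_fraction))
        n_e = min(max(n_e, 1), n - 1)
        ei = np.where(np.arange(n) < n_e, 1, -1)

    diff = positions[:, None, :] - positions[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    delays = np.rint(dist / (config.v * config.dt)).astype(int)
    np.fill_diagonal(delays, 0)

    geometry = FieldGeometry(
        positions=positions, ei_label=ei, v=config.v, dt=config.dt,
        delay_matrix=delays, single_population=config.single_population,
    )

    # Bernoulli mask with distance-weighted probability; the decay scale is
    # per presynaptic type (long-range excitatory axons, local inhibitory
    # axons), so the mask is symmetric only within same-type pairs.
    off = ~np.eye(n, dtype=bool)

    def _profile(scale: Optional[float]) -> np.ndarray:
        if scale is None:
            return np.full((n, n), config.connection_density)
        w = np.exp(-dist / scale)
        return config.connection_density * w / w[off].mean()

    scale_i = (config.connection_scale_inh
               if config.connection_scale_inh is not None
               else config.connection_scale)
    p = _profile(config.connection_scale)
    if not config.single_population:
        p_i = _profile(scale_i)
        p[:, ei < 0] = p_i[:, ei < 0]
    p = np.clip(p, 0.0, 1.0)
    u = rng.random((n, n))
    mask = (u < p) & off
    # same-type connections are made bidirectional (symmetric exchange)
    for kind in (1, -1):
        blk = np.ix_(ei == kind, ei == kind)
        mask[blk] |= mask[blk].T

    if not config.single_population:
        # guarantee both afferent types on every dendritic tree
        for kind in (1, -1):
            cols = ei == kind
            missing = np.where(~(mask[:, cols]).any(axis=1))[0]
            for i in missing:
                cand = np.where(cols)[0]
                cand = cand[cand != i]
                if len(cand) == 0:      # no other neuron of this type exists
                    continue
                j = cand[np.argmin(dist[i, cand])]
                mask[i, j] = mask[j, i] = True
    np.fill_diagonal(mask, False)

    g = np.where(
        mask,
        config.gain_init * np.exp(rng.normal(0.0, config.gain_sigma, (n, n))),
        0.0,
    )
    eps = np.where(mask, 1.0, 0.0)
    rho = np.where(mask, 1.0, 0.0)
    sign = np.tile(ei[None, :], (n, 1)).astype(float)

    # Optionally start at the homeostatic set point: scale each dendrite's
    # E and I blocks so expected flux at the sigmoid midpoint (Q = qmax/2)
    # equals the balance target.  By default the immature field starts with
    # raw random gains and is brought into balance by the anti-Hebbian
    # normalization itself.
    if config.init_balanced and config.target_flux > 0:
        qbar = config.activation.qmax / 2.0
        for cols_blk in (ei > 0, ei < 0):
            if not cols_blk.any():
                continue
            s = (g[:, cols_blk] * rho[:, cols_blk]).sum(axis=1) * qbar
            scale = np.where(s > 0, config.target_flux / np.where(s > 0, s, 1.0), 1.0)
            g[:, cols_blk] *= scale[:, None]

    e_cols = ei > 0
    cap = config.plasticity.g_cap_factor
    row_cap_e = cap * np.maximum(g[:, e_cols].sum(axis=1), 1e-12)
    row_cap_i = cap * np.maximum(g[:, ~e_cols].sum(axis=1), 1e-12)

    gains = GainState(eps=eps, g=g, rho=rho, sign=sign, mask=mask,
                      row_cap_e=row_cap_e, row_cap_i=row_cap_i)
    return geometry, gains


def white_noise_drive(n: int, steps: int, amplitude: float, seed: int) -> DriveSignal:
    """Temporally and spatially uncorrelated zero-mean Gaussian drive."""
    if steps < 1:
        raise InvalidParameterError("steps must be >= 1")
    if amplitude < 0:
        raise InvalidParameterError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    if amplitude == 0:
        samples = np.zeros((steps, n))
    else:
        samples = rng.normal(0.0, amplitude, size=(steps, n))
    return DriveSignal(samples=samples, amplitude=amplitude, seed=seed)


# --------------------------------------------------------------------------
# single-step dynamics
# --------------------------------------------------------------------------


def step(
    q_history: np.ndarray,
    geometry: FieldGeometry,
    gains: GainState,
    kernel: DendriticKernel,
    activation: ActivationFunction,
    drive_t: np.ndarray,
    input_history: Optional[np.ndarray] = None,
    zero_pad: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Advance the field one step; returns ``(phi_t, v_t, q_t)``.

    ``q_history`` is (H, n) with the most recent pulse rates last;
    ``input_history`` is (K-1, n) of previous aggregate inputs (most recent
    last) for the dendritic convolution.  History must cover the maximum
    delay and the kernel support, unless ``zero_pad=True`` adopts the
    zero-padding warm-up policy.
    """
    w = kernel.weights
    H = q_history.shape[0]
    need_q = geometry.max_delay
    need_i = len(w) - 1
    got_i = 0 if input_history is None else input_history.shape[0]
    if (H - 1 < need_q or got_i < need_i) and not zero_pad:
        raise WarmUpError(
            f"history too short (have {H} pulse / {got_i} input steps, need "
            f"{need_q + 1} / {need_i}); pass zero_pad=True to adopt the "
            "zero-padded warm-up policy"
        )

    n = geometry.n
    idx = (H - 1) - geometry.delay_matrix          # (n, n) time indices
    cols = np.broadcast_to(np.arange(n), (n, n))
    if zero_pad:
        valid = idx >= 0
        q_delayed = np.where(valid, q_history[np.clip(idx, 0, None), cols], 0.0)
    else:
        q_delayed = q_history[idx, cols]

    phi_t = gains.effective() * q_delayed
    agg = phi_t.sum(axis=1) + drive_t

    v_t = w[0] * agg
    for u in range(1, len(w)):
        if input_history is not None and u <= got_i:
            v_t = v_t + w[u] * input_history[got_i - u]
    q_t = activation(v_t)
    return phi_t, v_t, q_t


# --------------------------------------------------------------------------
# plasticity
# --------------------------------------------------------------------------


def hebbian_update(
    gains: GainState,
    pre: np.ndarray,
    post: np.ndarray,
    phi: np.ndarray,
    plasticity: PlasticityConfig,
    state: Optional[PlasticityState] = None,
) -> tuple[GainState, PlasticityState]:
    """Apply the three-timescale Hebbian recurrence over a window.

    ``pre``:  (T, n, n) delay-compensated presynaptic pulse rates,
    ``post``: (T, n) postsynaptic pulse rates,
    ``phi``:  (T, n, n) signed presynaptic flux over the same window.

    Per step: ``eps`` grows with centered pre/post coincidence and decays
    back to baseline 1; ``g`` accumulates ``eps * |phi|`` gated by the
    BCM-style sliding threshold (potentiation only, so sustained coincident
    flux can never decrease ``g``); ``rho`` relaxes toward ``g`` on active
    synapses only; per-dendrite competitive normalization bounds the row
    sums of ``g`` within each sign block, preserving within-block ratios.
    """
    pre = np.asarray(pre)
    phi = np.asarray(phi)
    post = np.atleast_2d(post)
    if pre.ndim == 2:
        pre = pre[None]
    if phi.ndim == 2:
        phi = phi[None]
    if pre.shape[0] < 1:
        raise InvalidParameterError("window length must be >= 1")
    out = gains.copy()
    st = state or PlasticityState.initial(post.shape[1])
    e_cols = out.sign[0] > 0
    # Hebbian (coincidence) plasticity acts at excitatory synapses; the
    # gains of inhibitory afferents change only through the homeostatic
    # anti-Hebbian normalization.
    plastic = out.mask & e_cols[None, :]

    for t in range(pre.shape[0]):
        q = post[t]
        st.q_mean += (q - st.q_mean) / plasticity.T_bcm
        st.theta_bcm += (q ** 2 / plasticity.bcm_target - st.theta_bcm) / plasticity.T_bcm

        pre_c = pre[t] - st.q_mean[None, :]
        post_c = (q - st.q_mean)[:, None]
        deps = plasticity.eta_eps * post_c * pre_c - (out.eps - 1.0) / plasticity.T_eps
        out.eps = np.where(plastic, np.clip(out.eps + deps, 0.0, None), out.eps)

        # rate-product potentiation on flux-bearing synapses, gated by the
        # sliding BCM threshold; rectified, so sustained coincident flux
        # can only increase g.
        gate = (q > st.theta_bcm)[:, None]
        active = plastic & (np.abs(phi[t]) > 0)
        coincidence = np.maximum(post_c * pre_c, 0.0)
        out.g += (out.eps * coincidence * gate * active) / plasticity.T_g

        out.rho += np.where(active, (out.g - out.rho) / plasticity.T_rho, 0.0)

        # competitive normalization: bound per-dendrite excitatory row sums
        if out.row_cap_e is not None and e_cols.any():
            s = out.g[:, e_cols].sum(axis=1)
            over = s > out.row_cap_e
            if over.any():
                scale = np.where(over, out.row_cap_e / np.maximum(s, 1e-300), 1.0)
                out.g[:, e_cols] *= scale[:, None]
    out.g *= out.mask
    out.rho *= out.mask
    return out, st


def anti_hebbian_normalize(
    gains: GainState,
    phi_window: np.ndarray,
    target: float,
    mode: str = "per_neuron",
    single_population: bool = False,
) -> tuple[GainState, np.ndarray, np.ndarray]:
    """Homeostatic rescaling enforcing excitatory/inhibitory flux balance.

    Multiplicatively rescales each neuron's excitatory and inhibitory
    afferent ``g`` blocks so that the window-averaged total excitatory flux
    and the magnitude of the total inhibitory flux both equal ``target``.
    Within-block ratios are untouched (a scalar multiplies the block).
    Returns the new gains and the applied (scale_e, scale_i) vectors.
    """
    if target <= 0:
        raise InvalidParameterError("balance target must be positive")
    phi_window = np.asarray(phi_window)
    if phi_window.ndim == 2:
        phi_window = phi_window[None]
    out = gains.copy()
    e_cols = out.sign[0] > 0
    i_cols = ~e_cols

    if not single_population and not i_cols.any():
        raise UnbalancedFieldError(
            "field has no inhibitory afferents; E/I balance is unachievable "
            "(set single_population=True to skip the inhibitory block)"
        )
    if i_cols.any():
        has_e = out.mask[:, e_cols].any(axis=1)
        rows_missing_i = has_e & ~(out.mask[:, i_cols]).any(axis=1)
    else:
        rows_missing_i = None
    if not single_population and rows_missing_i is not None and rows_missing_i.any():
        raise UnbalancedFieldError(
            f"neurons {np.where(rows_missing_i)[0].tolist()} have no inhibitory "
            "afferent connections"
        )

    s_e = phi_window[:, :, e_cols].sum(axis=2).mean(axis=0)       # >= 0
    s_i = -phi_window[:, :, i_cols].sum(axis=2).mean(axis=0) if i_cols.any() else None

    if mode == "population":
        s_e = np.full_like(s_e, s_e.mean())
        if s_i is not None:
            s_i = np.full_like(s_i, s_i.mean())
    elif mode != "per_neuron":
        raise InvalidParameterError(f"unknown balance mode {mode!r}")

    scale_e = np.where(s_e > 0, target / np.where(s_e > 0, s_e, 1.0), 1.0)
    out.g[:, e_cols] *= scale_e[:, None]
    if s_i is not None and i_cols.any():
        scale_i = np.where(s_i > 0, target / np.where(s_i > 0, s_i, 1.0), 1.0)
        out.g[:, i_cols] *= scale_i[:, None]
    else:
        scale_i = np.ones_like(scale_e)
    return out, scale_e, scale_i


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------


def simulate(
    config: FieldConfig,
    steps: int,
    seed: Optional[int] = None,
    drive: Optional[DriveSignal] = None,
    record_phi: bool = True,
    gains: Optional[GainState] = None,
    geometry: Optional[FieldGeometry] = None,
) -> SimulationRecord:
    """Run the field for ``steps`` steps and return the full record.

    The run is bit-reproducible given ``(config, seed)``.  The first
    ``max_delay + kernel support`` steps are zero-padded warm-up and are
    reported as ``record.burn_in`` (metrics should exclude them).  The
    plasticity schedule interleaves a per-step Hebbian update with an
    anti-Hebbian balance step every ``plasticity.norm_period`` steps,
    applied to the flux window since the previous balance step.
    """
    seed = config.seed if seed is None else seed
    if geometry is None or gains is None:
        geometry, gains = build_field(replace(config, seed=seed))
    else:
        gains = gains.copy()
    n = geometry.n
    if drive is None:
        drive = white_noise_drive(n, max(steps, 1), config.drive_amplitude,
                                  seed=(seed * 2654435761 + 1) % (2 ** 31))
    if steps and drive.samples.shape != (steps, n):
        raise InvalidParameterError(
            f"drive shape {drive.samples.shape} does not match ({steps}, {n})"
        )

    w = config.kernel.weights
    w_inh = config.kernel_inh.weights if config.kernel_inh is not None else w
    burn_in = geometry.max_delay + max(len(w), len(w_inh))
    plast = config.plasticity

    Q = np.zeros((steps, n))
    V = np.zeros((steps, n))
    exc = np.zeros((steps, n))
    inh = np.zeros((steps, n))
    phi_rec = np.zeros((steps, n, n), dtype=np.float32) if record_phi and steps else None

    if steps == 0:
        return SimulationRecord(
            Q=Q, V=V, drive=np.zeros((0, n)), exc_flux=exc, inh_flux=inh,
            phi=phi_rec, geometry=geometry, gains_final=gains, config=config,
            burn_in=burn_in, seed=seed,
        )

    H = geometry.max_delay + 1
    qbuf = np.zeros((H, n))
    # separate excitatory/inhibitory aggregate-input rings: inhibitory
    # synaptodendritic integration may be slower than excitatory
    ebuf = np.zeros((max(len(w) - 1, 1), n))
    hbuf = np.zeros((max(len(w_inh) - 1, 1), n))
    pstate = PlasticityState.initial(n)
    e_cols = geometry.ei_label > 0

    norm_window = []
    norm_steps = []
    balance_rows = []
    W = gains.effective()
    cols = np.broadcast_to(np.arange(n), (n, n))

    for t in range(steps):
        # Q at time t - d is the value written into the ring buffer at step t - d
        tidx = t - geometry.delay_matrix
        q_delayed = np.where(tidx >= 0, qbuf[tidx % H, cols], 0.0)

        phi_t = W * q_delayed
        agg_e = phi_t[:, e_cols].sum(axis=1) + drive.samples[t]
        agg_i = phi_t[:, ~e_cols].sum(axis=1)

        v_t = w[0] * agg_e + w_inh[0] * agg_i
        for u in range(1, len(w)):
            if t - u >= 0:
                v_t = v_t + w[u] * ebuf[(t - u) % ebuf.shape[0]]
        for u in range(1, len(w_inh)):
            if t - u >= 0:
                v_t = v_t + w_inh[u] * hbuf[(t - u) % hbuf.shape[0]]
        q_t = config.activation(v_t)

        if not np.all(np.isfinite(v_t)):
            raise DivergenceError(t, "V")
        if not np.all(np.isfinite(q_t)):
            raise DivergenceError(t, "Q")

        Q[t] = q_t
        V[t] = v_t
        exc[t] = phi_t[:, e_cols].sum(axis=1)
        inh[t] = phi_t[:, ~e_cols].sum(axis=1)
        if phi_rec is not None:
            phi_rec[t] = phi_t

        qbuf[t % H] = q_t
        ebuf[t % ebuf.shape[0]] = agg_e
        hbuf[t % hbuf.shape[0]] = agg_i

        if plast.enabled:
            gains, pstate = hebbian_update(
                gains, q_delayed[None], q_t[None], phi_t[None], plast, pstate
            )
            norm_window.append(phi_t)
            if (t + 1) % plast.norm_period == 0 and t >= burn_in:
                window = np.asarray(norm_window)
                gains, se, si = anti_hebbian_normalize(
                    gains, window, config.target_flux,
                    mode=plast.balance_mode,
                    single_population=geometry.single_population,
                )
                # recompute the window balance with the rescaled gains
                s_e = window[:, :, e_cols].sum(axis=2).mean(axis=0) * se
                s_i = window[:, :, ~e_cols].sum(axis=2).mean(axis=0) * si
                balance_rows.append(np.abs(s_e + s_i) / config.target_flux)
                norm_steps.append(t)
                norm_window = []
            elif len(norm_window) > plast.norm_period:
                norm_window.pop(0)
            W = gains.effective()

    return SimulationRecord(
        Q=Q, V=V, drive=drive.samples[:steps].copy(), exc_flux=exc, inh_flux=inh,
        phi=phi_rec, geometry=geometry, gains_final=gains, config=config,
        burn_in=burn_in, seed=seed,
        norm_steps=np.asarray(norm_steps, dtype=int),
        balance_residuals=(np.asarray(balance_rows)
                           if balance_rows else np.zeros((0, n))),
    )
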
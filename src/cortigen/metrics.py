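"""Synchrony, free-energy and information metrics on simulation records.

The central quantities:

* **Spatial eigenmodes** — principal components of the pulse-rate
  trajectory.  The first component of a synchronizing field is widespread
  (near-uniform loading magnitudes) and zero-lag synchronous; higher
  components are low-magnitude and spatially damped (localized).
* **Mutual information** of a flux exchange with correlation coefficient
  ``r``:  ``I = -1/2 log2(1 - r^2)`` bits.
* **Variational free energy of synaptic flux** ``F = A - C``, where ``A``
  is the total flux autocorrelation and ``C`` the total cross-correlation
  of the directed exchanges ``phi_ij``/``phi_ji``, summed over connected
  pairs and lags ``tau in [0, lag_range]``.  At full synchrony the
  exchange of every pair is equal in the two directions and ``F -> 0``.
  Mirror-paired systems exchange equal but *oppositely directed* flux, so
  each pair's cross terms are counted with an exchange orientation
  ``sigma = sign(sum_tau c)``; pairs with ``sigma < 0`` are reported as
  mirror exchanges.
* **Channel capacity** of ``n`` binary fluxes: ``D = n log2(1 + C/A)``
  bits, approaching ``n`` as ``C -> A``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import (
    DegenerateVarianceError,
    IncompatibleRecordsError,
    InsufficientDataError,
    InsufficientWindowsError,
    InvalidParameterError,
)
from .field import SimulationRecord

__all__ = [
    "CapacityReport",
    "EigenmodeSet",
    "FluxStatistics",
    "FreeEnergyTrajectory",
    "PredictionErrorReport",
    "channel_capacity",
    "eigenmode_decomposition",
    "flux_free_energy",
    "free_energy_trajectory",
    "free_energy_windows",
    "mutual_information",
    "pairwise_zero_lag_fraction",
    "prediction_error_residual",
]


# --------------------------------------------------------------------------
# eigenmodes
# --------------------------------------------------------------------------


@dataclass
class EigenmodeSet:
    """Principal spatial eigenmodes of a field trajectory.

    ``components`` rows are orthonormal loading vectors ordered by
    explained variance; ``scores`` are the corresponding time courses.
    ``zero_lag_index[k]`` is the loading-weighted fraction of neuron pairs
    whose (sign-adjusted) cross-correlation peaks at lag zero.
    ``spatial_damping[k] = 1 - PR_k / n`` measures loading localization
    (0 for a widespread uniform mode, -> 1 for a mode concentrated on few
    neurons); ``PR`` is the participation ratio ``1 / sum(u^4)``.
    """

    components: np.ndarray          # (k, n)
    scores: np.ndarray              # (T, k)
    explained_variance: np.ndarray  # (k,)
    zero_lag_index: np.ndarray      # (k,)
    spatial_damping: np.ndarray     # (k,)
    mean: np.ndarray                # (n,) channel means removed before SVD

    def reconstruct(self) -> np.ndarray:
        """Centered-record reconstruction ``scores @ components``."""
        return self.scores @ self.components


def _pairwise_lagged_covariances(x: np.ndarray, max_lag: int) -> np.ndarray:
    """(2L+1, n, n) array of lagged cross-covariances of centered ``x``."""
    T = x.shape[0]
    out = []
    for tau in range(-max_lag, max_lag + 1):
        if tau >= 0:
            out.append(x[: T - tau].T @ x[tau:] / T)
        else:
            out.append(x[-tau:].T @ x[: T + tau] / T)
    return np.asarray(out)


def pairwise_zero_lag_fraction(
    x: np.ndarray,
    max_lag: int = 15,
    weights: Optional[np.ndarray] = None,
    signs: Optional[np.ndarray] = None,
) -> float:
    """Fraction of channel pairs whose cross-correlation peaks at lag 0.

    ``weights``/``signs`` are per-pair (n, n) arrays; sign-adjustment lets
    anti-loaded channels of one eigenmode count as synchronous.  Ties at
    multiple lags count as zero-lag if lag 0 attains the maximum.
    """
    x = x - x.mean(axis=0)
    n = x.shape[1]
    cov = _pairwise_lagged_covariances(x, max_lag)
    iu, ju = np.triu_indices(n, 1)
    pair = cov[:, iu, ju] + cov[:, ju, iu]
    if signs is not None:
        pair = pair * signs[iu, ju]
    at0 = pair[max_lag] >= pair.max(axis=0) - 1e-12
    if weights is None:
        return float(at0.mean())
    w = weights[iu, ju]
    tot = w.sum()
    if tot <= 0:
        return float(at0.mean())
    return float((w * at0).sum() / tot)


def eigenmode_decomposition(
    record: SimulationRecord | np.ndarray,
    n_components: Optional[int] = None,
    max_lag: int = 15,
    source: str = "Q",
    exclude_burn_in: bool = True,
) -> EigenmodeSet:
    """Principal-component spatial eigenmodes of a trajectory.

    Accepts a :class:`SimulationRecord` (uses the ``Q`` or ``V``
    trajectory, burn-in excluded) or a plain (T, n) array.
    """
    if isinstance(record, SimulationRecord):
        x = record.Q if source == "Q" else record.V
        if exclude_burn_in:
            x = x[record.burn_in:]
    else:
        x = np.asarray(record, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise InsufficientDataError("need a (steps, n>=2) trajectory")
    if x.shape[0] < 2:
        raise InsufficientDataError("trajectory too short")

    xc = x - x.mean(axis=0)
    total_var = float((xc ** 2).sum())
    if total_var <= 1e-300 * x.size:
        raise DegenerateVarianceError("record is constant; eigenmodes undefined")

    u_t, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = n_components or min(xc.shape)
    k = min(k, len(s))
    ev = (s ** 2) / (s ** 2).sum()
    comps = vt[:k]
    scores = u_t[:, :k] * s[:k]

    n = x.shape[1]
    max_lag = min(max_lag, x.shape[0] - 2)
    zl = np.zeros(k)
    damp = np.zeros(k)
    for m in range(k):
        u = comps[m]
        w = np.abs(np.outer(u, u))
        sg = np.sign(np.outer(u, u))
        zl[m] = pairwise_zero_lag_fraction(xc, max_lag, weights=w, signs=sg)
        pr = 1.0 / np.sum(u ** 4)
        damp[m] = 1.0 - pr / n
    return EigenmodeSet(
        components=comps, scores=scores, explained_variance=ev[:k],
        zero_lag_index=zl, spatial_damping=damp, mean=x.mean(axis=0),
    )


# --------------------------------------------------------------------------
# mutual information
# --------------------------------------------------------------------------


def mutual_information(r):
    """Mutual information (bits) of a Gaussian exchange with correlation r.

    ``I = -1/2 log2(1 - r^2)``; symmetric in r, monotone in |r|; returns
    +inf (with a warning) at |r| = 1.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) > 1.0 + 1e-9):
        raise InvalidParameterError("correlation coefficient must lie in [-1, 1]")
    clipped = np.minimum(np.abs(r_arr), 1.0)
    if np.any(clipped >= 1.0):
        warnings.warn("|r| = 1: mutual information is infinite", RuntimeWarning)
    with np.errstate(divide="ignore"):
        out = -0.5 * np.log2(1.0 - clipped ** 2)
    return float(out) if np.isscalar(r) or out.ndim == 0 else out


# --------------------------------------------------------------------------
# flux free energy (auto/cross-correlation balance)
# --------------------------------------------------------------------------


@dataclass
class FluxStatistics:
    """Totals of the flux auto/cross-correlation balance on one window."""

    A: float                 # total autocorrelation
    C: float                 # total orientation-corrected cross-correlation
    F: float                 # A - C
    equilibrium_residual: float      # sum over pairs of |auto-sum - sigma * cross-sum|
    lag_range: int
    n_pairs: int
    mirror_fraction: float   # fraction of pairs with counter-directed exchange
    sum_phi_e: float         # window total excitatory flux
    sum_phi_i: float         # window total inhibitory flux (negative)
    normalized: bool = True
    window: tuple = (0, 0)

    @property
    def F_relative(self) -> float:
        return self.F / self.A if self.A else np.nan

    @property
    def residual_relative(self) -> float:
        return self.equilibrium_residual / self.A if self.A else np.nan


def flux_free_energy(
    record: SimulationRecord,
    lag_range: Optional[int] = None,
    window: Optional[tuple[int, int]] = None,
    normalized: bool = True,
    orientation: bool = True,
    pairs: Optional[np.ndarray] = None,
) -> FluxStatistics:
    """Auto/cross-correlation balance of the directed flux exchanges.

    ``A`` and ``C`` are sums of the lagged auto/cross-correlation functions
    of each mutually connected pair's two directed flux series over
    ``tau in [0, lag_range]`` (default twice the maximum axonal delay).
    ``normalized`` uses correlation coefficients (scale-free; default);
    otherwise raw covariances.  With ``orientation`` each pair's cross
    terms are multiplied by ``sigma = sign(sum_tau c)`` so co-directed and
    mirror (counter-directed) equilibria both count toward ``C``.
    """
    if record.phi is None:
        raise InsufficientDataError("record was run without flux recording")
    if lag_range is None:
        lag_range = 2 * record.geometry.max_delay
    lo, hi = window if window is not None else (record.burn_in, record.steps)
    if hi - lo <= lag_range + 1:
        raise InsufficientDataError(
            f"window of {hi - lo} steps cannot support lag range {lag_range}"
        )
    if pairs is None:
        pairs = record.directed_pairs()
    if len(pairs) == 0:
        raise InsufficientDataError("record has no mutually connected pairs")

    pij = record.phi[lo:hi, pairs[:, 0], pairs[:, 1]].astype(float)
    pji = record.phi[lo:hi, pairs[:, 1], pairs[:, 0]].astype(float)
    pij -= pij.mean(axis=0)
    pji -= pji.mean(axis=0)
    T = pij.shape[0]
    if normalized:
        pij /= pij.std(axis=0) + 1e-300
        pji /= pji.std(axis=0) + 1e-300

    a = np.zeros(len(pairs))
    c = np.zeros(len(pairs))
    for tau in range(lag_range + 1):
        a += (pij[tau:] * pij[: T - tau]).sum(0) / T
        a += (pji[tau:] * pji[: T - tau]).sum(0) / T
        c += (pij[tau:] * pji[: T - tau]).sum(0) / T
        c += (pji[tau:] * pij[: T - tau]).sum(0) / T
    sigma = np.sign(c) if orientation else np.ones_like(c)
    sigma[sigma == 0] = 1.0
    A = float(a.sum())
    C = float((sigma * c).sum())
    residual = float(np.abs(a - sigma * c).sum())
    return FluxStatistics(
        A=A, C=C, F=A - C, equilibrium_residual=residual, lag_range=int(lag_range),
        n_pairs=len(pairs), mirror_fraction=float((sigma < 0).mean()),
        sum_phi_e=float(record.exc_flux[lo:hi].sum()),
        sum_phi_i=float(record.inh_flux[lo:hi].sum()),
        normalized=normalized, window=(int(lo), int(hi)),
    )


def free_energy_windows(
    record: SimulationRecord,
    n_windows: int = 10,
    lag_range: Optional[int] = None,
    normalized: bool = True,
) -> list[FluxStatistics]:
    """Eq 7/8 statistics on consecutive equal windows of one record."""
    usable = record.steps
    win = usable // n_windows
    pairs = record.directed_pairs()
    out = []
    for k in range(n_windows):
        lo = max(k * win, record.burn_in)
        out.append(
            flux_free_energy(record, lag_range=lag_range, window=(lo, (k + 1) * win),
                             normalized=normalized, pairs=pairs)
        )
    return out


# --------------------------------------------------------------------------
# prediction error (paired driven/baseline runs)
# --------------------------------------------------------------------------


@dataclass
class PredictionErrorReport:
    """Drive-induced vs compensatory recurrent flux, per step."""

    delta_plus: np.ndarray      # (T, n) externally induced flux
    delta_minus: np.ndarray     # (T, n) opposing recurrent flux change
    residual_norm: np.ndarray   # (T,) ||delta_plus - delta_minus||_2

    @property
    def mean_residual(self) -> float:
        return float(self.residual_norm.mean())


def prediction_error_residual(
    record_driven: SimulationRecord,
    record_baseline: SimulationRecord,
) -> PredictionErrorReport:
    """How well recurrent flux neutralizes the external drive.

    Both records must share geometry and seed and differ only in drive.
    ``delta_plus`` is the drive difference (the externally imposed flux);
    ``delta_minus`` is the oppositely directed recurrent response,
    ``-(driven - baseline)`` total afferent flux per neuron.  A field
    whose recurrent flux rises to cancel its input makes the two match,
    keeping ``||delta_plus - delta_minus||`` small; a field that ignores
    or amplifies its input leaves the residual at or above
    ``||delta_plus||``.
    """
    ga, gb = record_driven.geometry, record_baseline.geometry
    if ga.positions.shape != gb.positions.shape or not np.allclose(
        ga.positions, gb.positions
    ):
        raise IncompatibleRecordsError("records have different geometries")
    if record_driven.seed != record_baseline.seed:
        raise IncompatibleRecordsError("records were built from different seeds")
    if record_driven.steps != record_baseline.steps:
        raise IncompatibleRecordsError("records have different lengths")

    delta_plus = record_driven.drive - record_baseline.drive
    rec_driven = record_driven.exc_flux + record_driven.inh_flux
    rec_base = record_baseline.exc_flux + record_baseline.inh_flux
    delta_minus = rec_base - rec_driven
    residual = np.linalg.norm(delta_plus - delta_minus, axis=1)
    return PredictionErrorReport(
        delta_plus=delta_plus, delta_minus=delta_minus, residual_norm=residual
    )


# --------------------------------------------------------------------------
# free-energy trajectory and stability
# --------------------------------------------------------------------------


@dataclass
class FreeEnergyTrajectory:
    """Windowed free-energy series with finite-difference diagnostics.

    ``stability_class`` is ``"unstable"`` iff the terminal second
    difference is positive while F and dF/dt are both near zero (below
    ``near_zero_frac`` of the initial |F|): a symmetry-broken system
    approaches an unstable rather than a stable fixed point.
    """

    F_t: np.ndarray
    dF_dt: np.ndarray
    d2F_dt2: np.ndarray
    stability_class: str
    near_zero_frac: float = 0.05


def free_energy_trajectory(
    F_values: Sequence[float] | Sequence[FluxStatistics],
    near_zero_frac: float = 0.05,
    relative: bool = True,
) -> FreeEnergyTrajectory:
    """Classify a windowed free-energy series as (un)stable convergence."""
    if len(F_values) and isinstance(F_values[0], FluxStatistics):
        F = np.array([s.F_relative if relative else s.F for s in F_values])
    else:
        F = np.asarray(F_values, dtype=float)
    if len(F) < 3:
        raise InsufficientWindowsError(
            "need at least 3 windows for second differences"
        )
    dF = np.diff(F)
    d2F = np.diff(F, 2)
    scale = abs(F[0]) if F[0] else 1.0
    near0 = abs(F[-1]) < near_zero_frac * scale and abs(dF[-1]) < near_zero_frac * scale
    if near0:
        cls = "unstable" if d2F[-1] > 0 else "stable"
    elif dF[-1] < 0:
        cls = "descending"
    else:
        cls = "not-converged"
    return FreeEnergyTrajectory(
        F_t=F, dF_dt=dF, d2F_dt2=d2F, stability_class=cls,
        near_zero_frac=near_zero_frac,
    )


# --------------------------------------------------------------------------
# channel capacity
# --------------------------------------------------------------------------


@dataclass
class CapacityReport:
    """Shannon capacity of n binary synaptic fluxes and state counts."""

    n: int
    D: float                          # bits, n log2(1 + C/A)
    snr: float                        # C / A
    log2_states_mirror: float         # n / 2
    states_mirror: Optional[int]      # 2^(n/2), exact when representable
    n_neo: Optional[int] = None
    n_limb: Optional[int] = None
    log2_states_per_limbic: Optional[float] = None
    states_per_limbic: Optional[int] = None


def channel_capacity(
    n: int,
    C: float,
    A: float,
    n_neo: Optional[int] = None,
    n_limb: Optional[int] = None,
) -> CapacityReport:
    """Capacity ``D = n log2(1 + C/A)`` and mirror-pair state counts.

    ``2^(n/2)`` distinguishable mirror-pair states; with a neocortical /
    limbic split (``n_neo + n_limb = n``, ``n_neo > n_limb``),
    ``2^(n_neo - n_limb)`` neocortical states per limbic state.  Exact
    integer counts are reported for exponents up to 62, otherwise only in
    log2.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if A <= 0:
        raise InvalidParameterError("A must be positive (C/A undefined)")
    if C < 0:
        raise InvalidParameterError("C must be >= 0")
    snr = C / A
    D = n * np.log2(1.0 + snr)

    def _count(log2_states: float) -> Optional[int]:
        if log2_states <= 62 and float(log2_states).is_integer():
            return 1 << int(log2_states)
        return None

    rep = CapacityReport(
        n=n, D=float(D), snr=float(snr),
        log2_states_mirror=n / 2.0, states_mirror=_count(n / 2.0),
    )
    if n_neo is not None or n_limb is not None:
        if n_neo is None or n_limb is None or n_neo + n_limb != n:
            raise InvalidParameterError("n_neo + n_limb must equal n")
        if n_neo <= n_limb:
            raise InvalidParameterError("state ratios require n_neo > n_limb")
        rep.n_neo, rep.n_limb = n_neo, n_limb
        rep.log2_states_per_limbic = float(n_neo - n_limb)
        rep.states_per_limbic = _count(float(n_neo - n_limb))
    return rep
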
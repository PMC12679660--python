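import numpy as np
import pytest

from cortigen.field import (
    FieldConfig,
    FieldGeometry,
    GainState,
    SimulationRecord,
    simulate,
)


@pytest.fixture(scope="session")
def small_record():
    """A 16-neuron, 1500-step simulated field with flux recorded."""
    return simulate(FieldConfig(n=16, seed=11), 1500, record_phi=True)


def make_synthetic_record(phi: np.ndarray, ei_label=None) -> SimulationRecord:
    """Wrap a (T, n, n) flux trajectory as a minimal simulation record.

    All pairs are treated as mutually connected; delays are zero; Q and V
    are filled with per-neuron flux sums so eigenmode calls also work.
    """
    T, n, _ = phi.shape
    if ei_label is None:
        ei_label = np.ones(n, dtype=int)
        ei_label[-max(n // 4, 1):] = -1
    geometry = FieldGeometry(
        positions=np.column_stack([np.arange(n), np.zeros(n)]).astype(float),
        ei_label=ei_label, v=1.0, dt=1.0,
        delay_matrix=np.zeros((n, n), dtype=int),
    )
    mask = ~np.eye(n, dtype=bool)
    sign = np.tile(ei_label[None, :].astype(float), (n, 1))
    gains = GainState(
        eps=mask.astype(float), g=mask.astype(float), rho=mask.astype(float),
        sign=sign, mask=mask,
    )
    e_cols = ei_label > 0
    return SimulationRecord(
        Q=phi.sum(axis=2), V=phi.sum(axis=2), drive=np.zeros((T, n)),
        exc_flux=phi[:, :, e_cols].sum(axis=2),
        inh_flux=phi[:, :, ~e_cols].sum(axis=2),
        phi=phi.astype(np.float32), geometry=geometry, gains_final=gains,
        config=FieldConfig(n=n), burn_in=0, seed=0,
    )
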
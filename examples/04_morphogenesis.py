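"""The columnar / diffuse continuum from the synchrony-wiring trade-off.

Relaxing two cell populations (long-axon patch vs short-axon local)
under synchrony attraction alone produces tight local-cell clusters
surrounded by patch pools; wiring-length minimization alone produces a
diffuse layout. The columnarity index is 0 for spatial randomness and
-> 1 for strong clustering.
"""
from cortigen import force_equilibrium_layout, columnarity_index

sync = force_equilibrium_layout(60, 60, w_synchrony=1.0, w_wiring=0.0,
                                seed=0, max_iter=1200)
wire = force_equilibrium_layout(60, 60, w_synchrony=0.0, w_wiring=1.0,
                                seed=0, max_iter=1200)
print(f"synchrony-only columnarity : {columnarity_index(sync):.3f} "
      f"(tiling: {sync.tiling_class})")
print(f"wiring-only columnarity    : {columnarity_index(wire):.3f} "
      f"(tiling: {wire.tiling_class})")
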
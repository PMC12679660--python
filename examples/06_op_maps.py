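"""Pinwheel orientation maps from the angle-doubling projection.

A local map halves global angles (mod 180) into a column: one full
spatial circuit around the centre sweeps orientation preference through
exactly one 180-degree period, with a singularity of winding +-1/2
matching the map's chirality. A 2x2 alternating-chirality atlas also
develops saddle points between the pinwheels.
"""
from cortigen import (LocalMap, MapAtlas, RigidImageSpec, op_circuit,
                      build_representation_frame, synthesize_op_map)

c = op_circuit(LocalMap(p0=0j, k=1.0, chirality=1), radius=1.0)
print(f"OP span over one circuit : {c['span']:.1f} degrees "
      f"(winding {c['winding']:+.1f})")

maps = [LocalMap(-1 - 1j, 1, 1), LocalMap(1 - 1j, 1, -1),
        LocalMap(-1 + 1j, 1, -1), LocalMap(1 + 1j, 1, 1)]
om = synthesize_op_map(MapAtlas(maps, extent=(-2, 2, -2, 2)), 0.05)
kinds = {}
for f in om.features:
    kinds[f.type] = kinds.get(f.type, 0) + 1
print(f"2x2 atlas features       : {kinds}")

frame = build_representation_frame(RigidImageSpec(position=(1, 2, 0.5)))
print(f"representation frame     : {len(frame.points)} points "
      f"(static image, translation components all zero)")
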
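"""Mirror symmetry of square vs hexagonal patch-cell tilings.

Columns carry chiral patch-cell motifs whose handedness alternates so
every neighbouring pair is a mirror pair. The square lattice is
2-colourable, so alternation is perfect; the hexagonal (triangular)
adjacency is frustrated, and the best mirror score is strictly lower -
the broken symmetry of hexagonal patch arrays.
"""
from cortigen import FixtureSpec, make_fixture, mirror_symmetry_score

square = make_fixture(FixtureSpec("patch-array-square", 0))
hexag = make_fixture(FixtureSpec("patch-array-hex", 0))
for name, lay in (("square", square), ("hexagonal", hexag)):
    rep = mirror_symmetry_score(lay, axis="fit", seed=1)
    print(f"{name:10s} mirror score {rep.score:+.3f}  "
          f"(null {rep.null_mean:+.3f} +- {rep.null_sd:.3f})")
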
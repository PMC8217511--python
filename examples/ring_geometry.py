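"""Ring closure from the native head-to-head bend.

SAS-6 homodimers oligomerize through a weak N-terminal interface that holds
neighbouring coiled-coil pairs at ~40 degrees.  Propagating that step as a
rigid motion predicts the cartwheel ring: how many units close the ring, and
the diameter of the circle through the head vertices.
"""

from cartwheel import geometry

step = geometry.interface_step(rotation_deg=40.0, rise_nm=0.0)
seed = geometry.default_seed_unit(step=step)
assembly = geometry.propagate(seed, step, n_units=9)

print(f"classification : {assembly.classification.kind}")
print(f"units in ring  : {assembly.classification.n_units}")
print(f"closure gap    : {assembly.closure_gap:.2e} nm")
print(f"ring diameter  : {geometry.ring_diameter(geometry.CHORD_NM, 9):.2f} nm")

# A 40-degree bend closes exactly after nine units (9 x 40 = 360) with a
# vanishing closure gap; with the 7.87 nm inter-vertex chord the vertex
# circle is 23 nm across -- the cartwheel hub diameter.
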
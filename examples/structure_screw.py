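"""Extracting the inter-unit screw transform from a coordinate file.

Writes a pseudo-atomic helical polymer with a known generating step, reads
it back as a PDB-format structure, superposes neighbouring units with the
Kabsch algorithm and screw-decomposes the fitted motion -- the same
operation used to read the inter-homodimer geometry out of a crystal's
asymmetric unit.
"""

import tempfile

from cartwheel import geometry, structure, synthetic

with tempfile.NamedTemporaryFile(suffix=".pdb", delete=False) as fh:
    pdb_path = fh.name
manifest = synthetic.make_polymer_pdb(
    rotation_deg=90.0, rise_nm=6.5, n_units=12, out_pdb=pdb_path
)

st = structure.read_structure(pdb_path)
screw = structure.relative_transform(st, "A", "B", atom_names=None)
rise_nm = screw.rise / 10.0  # coordinates are in angstrom
pitch, per_turn, _ = geometry.helix_parameters(
    geometry.ScrewTransform(screw.rotation_angle, screw.axis,
                            screw.axis_point / 10.0, rise_nm)
)

print(f"generating step : {manifest.parameters['rotation_deg']:.1f} deg, "
      f"{manifest.parameters['rise_nm']:.1f} nm rise")
print(f"recovered twist : {screw.rotation_angle:.2f} deg")
print(f"recovered rise  : {rise_nm:.3f} nm")
print(f"implied pitch   : {pitch:.2f} nm at {per_turn:.2f} units/turn")

# The screw parameters survive the trip through fixed-width PDB coordinates
# to within the file format's 3-decimal precision: twist to ~0.01 degree,
# rise to ~0.001 nm, reproducing the 26 nm / fourfold helix prediction.
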
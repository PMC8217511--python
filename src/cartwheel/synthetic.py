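"""Seeded synthetic fixtures with ground-truth manifests.

Everything the analysis pipelines consume can be generated here with known
ground truth: pseudo-atomic polymer coordinate files built from a known
screw step, AFM-like height-map fields mixing rings/arcs/helices, cryo-EM
particle stacks at stated symmetry mixtures, and ITC titration series at the
monobodies' binding parameters.  Each generator records its parameters and
seed in a :class:`FixtureManifest`, sufficient to reproduce the fixture
byte-for-byte and to score any downstream pipeline against the truth.

One global seed expands to per-fixture streams through
``numpy.random.SeedSequence(seed, index)``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

from . import afm, em, geometry, itc

__all__ = [
    "FixtureManifest",
    "child_seed",
    "assembly_to_structure",
    "make_polymer_pdb",
    "make_afm_dataset",
    "make_em_dataset",
    "make_itc_dataset",
    "MONOBODY_PANEL",
]

#: Printed binding parameters of the three characterised monobodies:
#: K_D (nM); enthalpies are representative exothermic values at desk scale.
MONOBODY_PANEL = {
    "MB-1": {"kd": 566.0, "dh": -8.0, "n": 1.0},
    "MB-13": {"kd": 134.0, "dh": -10.0, "n": 1.0},
    "MB-15": {"kd": 137.0, "dh": -10.0, "n": 1.0},
}


@dataclass
class FixtureManifest:
    fixture_id: str
    seed: int | None
    parameters: dict
    files: list[str] = field(default_factory=list)
    package_version: str = ""

    def __post_init__(self):
        if not self.package_version:
            from . import __version__

            self.package_version = __version__

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=_jsonable)

    @classmethod
    def read(cls, path: str) -> "FixtureManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def child_seed(seed: int | None, index: int) -> int:
    """Deterministic per-fixture seed derived from a global seed (< 2**31)."""
    ss = np.random.SeedSequence(0 if seed is None else seed, spawn_key=(index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


# ---------------------------------------------------------------------------
# polymer coordinate files
# ---------------------------------------------------------------------------

#: nm -> angstrom for coordinate export
_NM_TO_A = 10.0

# four pseudo-atom offsets (nm, in the unit frame) spanning a chiral tetrad
# so the full rigid frame of every unit is recoverable from coordinates
_FRAME_MARKERS = [
    ("C1", np.array([0.0, 0.0, 0.0])),
    ("C2", np.array([1.0, 0.0, 0.0])),
    ("C3", np.array([0.0, 1.0, 0.0])),
    ("C4", np.array([0.0, 0.0, 1.0])),
]

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def assembly_to_structure(
    assembly: geometry.PolymerAssembly,
    decoration: bool = False,
    decoration_offset: float = 3.0,
) -> gemmi.Structure:
    """Represent an assembly as a pseudo-atomic structure (one chain per
    homodimer unit): frame markers at the head vertex plus the spoke tip;
    optionally a monobody pseudo-domain placed outside the ring past each
    spoke tip.  Coordinates in angstrom."""
    st = gemmi.Structure()
    st.name = "synthetic-assembly"
    model = gemmi.Model("1")
    positions = []
    for i, unit in enumerate(assembly.units):
        if i >= len(_CHAIN_IDS):
            raise ValueError("too many units for single-character chain IDs")
        chain = gemmi.Chain(_CHAIN_IDS[i])
        res = gemmi.Residue()
        res.name = "UNK"
        res.seqid = gemmi.SeqId(1, " ")
        R = unit.frame_orientation
        for name, offset in _FRAME_MARKERS:
            pos = unit.frame_origin + R @ offset
            res.add_atom(_atom(name, pos))
            positions.append(pos)
        tip = unit.spoke_tip()
        res.add_atom(_atom("C5", tip))
        positions.append(tip)
        if decoration:
            deco = tip + decoration_offset * unit.spoke_direction
            res.add_atom(_atom("C6", deco))
            positions.append(deco)
        chain.add_residue(res)
        model.add_chain(chain)
    pts = np.array(positions)
    if len(pts) > 1:
        from scipy.spatial import cKDTree

        d, _ = cKDTree(pts).query(pts, k=2)
        if d[:, 1].min() * _NM_TO_A < 1.0:
            raise ValueError("decoration clash: pseudo-atoms closer than 1 A")
    st.add_model(model)
    return st


def _atom(name: str, pos_nm: np.ndarray) -> gemmi.Atom:
    a = gemmi.Atom()
    a.name = name
    a.element = gemmi.Element("C")
    a.occ = 1.0
    a.pos = gemmi.Position(*(np.asarray(pos_nm) * _NM_TO_A))
    return a


def make_polymer_pdb(
    rotation_deg: float,
    rise_nm: float,
    n_units: int,
    out_pdb: str,
    out_manifest: str | None = None,
    chord_nm: float = geometry.CHORD_NM,
    decoration: bool = False,
) -> FixtureManifest:
    """Write a pseudo-atomic polymer built from a known screw step.

    The manifest records the generating (rotation, rise, chord) so structure
    analysis on the file can be scored against truth."""
    step = geometry.interface_step(rotation_deg, rise_nm, chord_nm)
    seed_unit = geometry.default_seed_unit(step=step)
    assembly = geometry.propagate(seed_unit, step, n_units)
    st = assembly_to_structure(assembly, decoration=decoration)
    from .structure import write_structure

    write_structure(st, out_pdb)
    manifest = FixtureManifest(
        fixture_id="polymer",
        seed=None,
        parameters={
            "rotation_deg": rotation_deg,
            "rise_nm": rise_nm,
            "chord_nm": chord_nm,
            "n_units": n_units,
            "decoration": decoration,
            "classification": assembly.classification.kind,
        },
        files=[str(out_pdb)],
    )
    if out_manifest:
        manifest.write(out_manifest)
    return manifest


# ---------------------------------------------------------------------------
# AFM fields
# ---------------------------------------------------------------------------

def make_afm_dataset(
    objects: list[dict],
    field_nm: float = 300.0,
    pixel_size: float = afm.DEFAULT_PIXEL_NM,
    tip_sigma: float = 2.0,
    noise_sd: float = 0.2,
    seed: int | None = 0,
    out_tiff: str | None = None,
    out_manifest: str | None = None,
) -> tuple[afm.HeightMap, FixtureManifest]:
    """Render a field of view containing a mixture of assemblies.

    ``objects`` is a list of dicts with keys ``kind`` ('ring', 'arc' or
    'helix'), plus per-kind geometry: rings take ``n_units`` (and optional
    ``chord_nm``), arcs take ``rotation_deg``/``n_units``, helices take
    ``rotation_deg``/``rise_nm``/``n_units``.  Placement is on a jittered
    grid to guarantee no overlap; ground truth (type, diameter or pitch,
    centre) is recorded per object."""
    if not objects:
        hm = afm.HeightMap(
            np.zeros((int(field_nm / pixel_size),) * 2), pixel_size
        )
        manifest = FixtureManifest("afm-field", seed, {"objects": []})
        return hm, manifest

    n = len(objects)
    cells = math.ceil(math.sqrt(n))
    cell_nm = field_nm / cells
    if cell_nm < 60.0:
        raise ValueError(
            f"field of {field_nm} nm too small for {n} objects; "
            "each needs a ~60 nm cell"
        )
    rng = np.random.default_rng(child_seed(seed, 0))
    hm = afm.HeightMap(np.zeros((int(field_nm / pixel_size),) * 2), pixel_size)
    truth = []
    order = rng.permutation(cells * cells)[:n]
    for obj, cell in zip(objects, order):
        row, col = divmod(int(cell), cells)
        jitter = rng.uniform(-0.1, 0.1, size=2) * cell_nm
        centre = (
            (col + 0.5) * cell_nm + jitter[0],
            (row + 0.5) * cell_nm + jitter[1],
        )
        assembly, info = _build_object(obj)
        afm.render_heightmap(
            assembly, tip_sigma=tip_sigma, center=centre, heightmap=hm,
            spoke_length=obj.get("spoke_length"),
        )
        truth.append({**info, "center": list(centre)})
    hm = afm.add_noise(hm, noise_sd, child_seed(seed, 1))
    manifest = FixtureManifest(
        fixture_id="afm-field",
        seed=seed,
        parameters={
            "field_nm": field_nm,
            "pixel_size": pixel_size,
            "tip_sigma": tip_sigma,
            "noise_sd": noise_sd,
            "objects": truth,
        },
    )
    if out_tiff:
        hm.write_tiff(out_tiff)
        manifest.files.append(str(out_tiff))
    if out_manifest:
        manifest.write(out_manifest)
    return hm, manifest


def _build_object(obj: dict) -> tuple[geometry.PolymerAssembly, dict]:
    kind = obj["kind"]
    chord = obj.get("chord_nm", geometry.CHORD_NM)
    if kind == "ring":
        n = obj.get("n_units", 9)
        rot = 360.0 / n
        step = geometry.interface_step(rot, 0.0, chord)
        asm = geometry.propagate(geometry.default_seed_unit(step=step), step, n)
        info = {"kind": "ring", "n_units": n,
                "diameter_nm": geometry.ring_diameter(chord, n)}
    elif kind == "arc":
        rot = obj.get("rotation_deg", 40.0)
        n = obj.get("n_units", 4)
        step = geometry.interface_step(rot, 0.0, chord)
        asm = geometry.propagate(geometry.default_seed_unit(step=step), step, n)
        info = {"kind": "arc", "n_units": n, "arc_angle_deg": rot * (n - 1)}
    elif kind == "helix":
        rot = obj.get("rotation_deg", 90.0)
        rise = obj.get("rise_nm", 6.5)
        n = obj.get("n_units", 12)
        step = geometry.interface_step(rot, rise, chord)
        asm = geometry.propagate(geometry.default_seed_unit(step=step), step, n)
        pitch, upt, _ = geometry.helix_parameters(geometry.screw_decompose(step))
        info = {"kind": "helix", "n_units": n, "pitch_nm": pitch,
                "units_per_turn": upt}
    else:
        raise ValueError(f"unknown object kind {kind!r}")
    return asm, info


# ---------------------------------------------------------------------------
# EM stacks
# ---------------------------------------------------------------------------

def make_em_dataset(
    mixture: dict[int, float],
    n_particles: int,
    replicates: int = 3,
    chord: float = geometry.CHORD_NM,
    pixel_size: float = em.DEFAULT_PIXEL_NM,
    snr: float = 3.0,
    seed: int | None = 0,
    frame_px: int = 128,
    exact_counts: dict[int, int] | None = None,
) -> tuple[list[em.ParticleImage], FixtureManifest]:
    """Generate a seeded particle stack at a stated symmetry mixture.

    Per-replicate class counts are multinomial draws from ``mixture`` (which
    must sum to 1) unless ``exact_counts`` pins the total per class, in which
    case particles are split as evenly as possible across replicates.  The
    manifest records the true class of every particle in order."""
    if exact_counts is None:
        fr = np.array(list(mixture.values()))
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("mixture fractions must sum to 1")
    rng = np.random.default_rng(child_seed(seed, 0))
    labels: list[tuple[str, int]] = []
    if exact_counts is not None:
        pool = []
        for n_fold, count in sorted(exact_counts.items()):
            pool += [n_fold] * count
        pool = list(rng.permutation(pool))
        per_rep = np.array_split(pool, replicates)
        for r, chunk in enumerate(per_rep):
            labels += [(f"rep{r + 1}", int(n)) for n in chunk]
    else:
        classes = sorted(mixture)
        probs = [mixture[c] for c in classes]
        base = n_particles // replicates
        counts = [base + (1 if r < n_particles % replicates else 0)
                  for r in range(replicates)]
        for r, cnt in enumerate(counts):
            draw = rng.multinomial(cnt, probs)
            for cls, k in zip(classes, draw):
                labels += [(f"rep{r + 1}", cls)] * int(k)
        labels = [labels[i] for i in rng.permutation(len(labels))]

    particles = []
    for i, (rep, n_fold) in enumerate(labels):
        p = em.render_particle(
            n_fold, chord=chord, pixel_size=pixel_size, snr=snr,
            seed=child_seed(seed, 1000 + i), frame_px=frame_px,
        )
        p.replicate_id = rep
        particles.append(p)
    manifest = FixtureManifest(
        fixture_id="em-stack",
        seed=seed,
        parameters={
            "mixture": {str(k): v for k, v in (mixture or {}).items()},
            "exact_counts": {str(k): v for k, v in (exact_counts or {}).items()},
            "n_particles": len(labels),
            "replicates": replicates,
            "chord": chord,
            "pixel_size": pixel_size,
            "snr": snr,
            "truth": [{"replicate": r, "n_fold": n} for r, n in labels],
        },
    )
    return particles, manifest


# ---------------------------------------------------------------------------
# ITC series
# ---------------------------------------------------------------------------

def make_itc_dataset(
    panel: dict[str, dict] | None = None,
    noise_fraction: float = 0.02,
    seed: int | None = 0,
    out_dir: str | None = None,
) -> tuple[dict[str, itc.TitrationSeries], FixtureManifest]:
    """One synthetic titration per monobody of the panel (default: the three
    characterised binders at their printed K_Ds).  Heat noise SD is
    ``noise_fraction`` of the first-injection heat magnitude."""
    panel = panel or MONOBODY_PANEL
    series = {}
    truth = {}
    for i, (name, pars) in enumerate(sorted(panel.items())):
        clean = itc.simulate_titration(pars["kd"], pars["dh"], pars.get("n", 1.0))
        noise_sd = noise_fraction * abs(clean.heats[0])
        s = itc.simulate_titration(
            pars["kd"], pars["dh"], pars.get("n", 1.0),
            noise_sd=noise_sd, seed=child_seed(seed, i),
        )
        series[name] = s
        truth[name] = {**pars, "noise_sd_ucal": noise_sd}
    manifest = FixtureManifest(
        fixture_id="itc-panel", seed=seed,
        parameters={"panel": truth, "noise_fraction": noise_fraction},
    )
    if out_dir:
        import os

        for name, s in series.items():
            path = os.path.join(out_dir, f"itc_{name}.csv")
            s.write_csv(path)
            manifest.files.append(path)
        manifest.write(os.path.join(out_dir, "itc_manifest.json"))
    return series, manifest
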
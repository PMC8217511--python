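"""Crystal-structure comparisons: superposition, inter-unit screws, interfaces.

Reads coordinate files in PDB format (via gemmi), superposes copies of a
homodimer or monobody-target complex with the Kabsch algorithm, extracts the
relative screw transform between adjacent units in an asymmetric unit, and
computes domain tilt angles, contacting residues and buried interface areas
(Shrake-Rupley solvent accessibility).

Selections name atoms by chain and residue range, e.g. ``"A"`` or
``"A:10-50,B:1-90"`` (1-based inclusive ranges as numbered in the file).
Coordinates are in angstroms, matching the PDB convention; the geometry
module works in nanometres, so screw rises extracted here are reported in
both units by the callers that need them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import gemmi
import numpy as np

from . import geometry

__all__ = [
    "UnitSelection",
    "SuperpositionResult",
    "read_structure",
    "write_structure",
    "select_atoms",
    "kabsch",
    "kabsch_superpose",
    "relative_transform",
    "domain_tilt",
    "interface_residues",
    "shrake_rupley_sasa",
    "buried_interface_area",
    "VDW_RADII",
]

#: Heavy-atom van der Waals radii (angstrom); hydrogens are ignored.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90}

PROBE_RADIUS = 1.4
SASA_POINTS = 960
CONTACT_CUTOFF = 4.0


@dataclass(frozen=True)
class UnitSelection:
    """Chain/residue-range selection of one structural copy.

    ``spec`` is a comma-separated list of ``chain`` or ``chain:start-end``
    tokens; ``label`` is free-form."""

    spec: str
    label: str = ""

    def parts(self) -> list[tuple[str, int | None, int | None]]:
        out = []
        for token in self.spec.split(","):
            token = token.strip()
            if not token:
                continue
            if ":" in token:
                chain, rng = token.split(":", 1)
                lo, hi = rng.split("-", 1)
                out.append((chain.strip(), int(lo), int(hi)))
            else:
                out.append((token, None, None))
        if not out:
            raise ValueError(f"empty selection: {self.spec!r}")
        return out


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, applied to mobile
    translation: np.ndarray  # 3-vector
    rmsd: float
    n_atoms: int

    def matrix(self) -> np.ndarray:
        return geometry.make_transform(self.rotation, self.translation)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_structure(source: str) -> gemmi.Structure:
    """Read a PDB-format structure from a path or from raw text.

    The first model is used downstream; HETATM records are retained.  For
    alternate locations the highest-occupancy conformer wins (ties -> 'A'),
    handled lazily in :func:`select_atoms`.
    """
    if "\n" in source or source.lstrip().startswith(("ATOM", "HETATM", "HEADER",
                                                     "MODEL", "CRYST1", "REMARK")):
        st = gemmi.read_pdb_string(source)
    else:
        st = gemmi.read_pdb(source)
    if len(st) == 0 or sum(len(ch) for ch in st[0]) == 0:
        raise ValueError("no ATOM records found")
    st.setup_entities()
    return st


def write_structure(st: gemmi.Structure, path: str | None = None) -> str:
    """Write a structure as PDB text (optionally to ``path``); returns text."""
    text = st.make_pdb_string()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _residue_in_range(res: gemmi.Residue, lo: int | None, hi: int | None) -> bool:
    if lo is None:
        return True
    return lo <= res.seqid.num <= hi


def select_atoms(
    st: gemmi.Structure,
    selection: UnitSelection | str,
    atom_names: set[str] | None = None,
    heavy_only: bool = True,
) -> list[tuple[str, int, str, np.ndarray, str]]:
    """Atoms matching a selection from the first model.

    Returns ``(chain_id, residue_number, atom_name, position, element)``
    tuples; for altlocs the highest-occupancy conformer is kept (ties 'A').
    """
    if isinstance(selection, str):
        selection = UnitSelection(selection)
    model = st[0]
    out = []
    for chain_id, lo, hi in selection.parts():
        chain = model.find_chain(chain_id)
        if chain is None:
            raise KeyError(f"chain {chain_id!r} not in structure")
        for res in chain:
            if not _residue_in_range(res, lo, hi):
                continue
            by_name: dict[str, gemmi.Atom] = {}
            for atom in res:
                el = atom.element.name.upper()
                if heavy_only and el == "H":
                    continue
                prev = by_name.get(atom.name)
                if prev is None or atom.occ > prev.occ or (
                    atom.occ == prev.occ and atom.altloc < prev.altloc
                ):
                    by_name[atom.name] = atom
            for name, atom in by_name.items():
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                if atom_names is not None and name not in atom_names:
                    continue
                out.append((chain_id, res.seqid.num, name, pos, atom.element.name.upper()))
    return out


def _paired_coords(
    st_a: gemmi.Structure,
    sel_a: UnitSelection | str,
    st_b: gemmi.Structure,
    sel_b: UnitSelection | str,
    atom_names: set[str] | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Match atoms between two selections on (chain-role, residue, atom name).

    Chain-role means the k-th chain token of each selection is paired with
    the k-th token of the other, so copies living on different chain IDs
    still pair up."""
    a = select_atoms(st_a, sel_a, atom_names=atom_names)
    b = select_atoms(st_b, sel_b, atom_names=atom_names)
    sel_a = UnitSelection(sel_a) if isinstance(sel_a, str) else sel_a
    sel_b = UnitSelection(sel_b) if isinstance(sel_b, str) else sel_b
    role_a = {chain: i for i, (chain, _, _) in enumerate(sel_a.parts())}
    role_b = {chain: i for i, (chain, _, _) in enumerate(sel_b.parts())}
    map_a = {(role_a[c], r, n): p for c, r, n, p, _ in a}
    map_b = {(role_b[c], r, n): p for c, r, n, p, _ in b}
    keys = sorted(set(map_a) & set(map_b))
    if len(keys) < 3:
        unmatched = sorted(set(map_a) ^ set(map_b))[:10]
        raise ValueError(
            f"fewer than 3 matched atom pairs (first unmatched: {unmatched})"
        )
    return (np.array([map_a[k] for k in keys]), np.array([map_b[k] for k in keys]))


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, fixed: np.ndarray) -> SuperpositionResult:
    """Least-squares superposition of paired coordinate arrays (Kabsch/SVD)."""
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(fixed, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and fixed must be matching (n, 3) arrays")
    if len(P) < 3:
        raise ValueError("need at least 3 atom pairs")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    moved = P @ R.T + t
    rmsd = float(np.sqrt(((moved - Q) ** 2).sum(axis=1).mean()))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=len(P))


def kabsch_superpose(
    st_mobile: gemmi.Structure,
    sel_mobile: UnitSelection | str,
    st_fixed: gemmi.Structure,
    sel_fixed: UnitSelection | str,
    atom_names: set[str] | None = frozenset({"CA"}),
) -> SuperpositionResult:
    """Superpose one selection onto another (Calpha pairing by default)."""
    P, Q = _paired_coords(st_mobile, sel_mobile, st_fixed, sel_fixed, atom_names)
    return kabsch(P, Q)


def relative_transform(
    st: gemmi.Structure,
    unit_a: UnitSelection | str,
    unit_b: UnitSelection | str,
    atom_names: set[str] | None = frozenset({"CA"}),
) -> geometry.ScrewTransform:
    """Screw transform carrying unit_a onto unit_b within one structure.

    The fitted Kabsch motion (angstrom) is screw-decomposed; the returned
    rise is therefore in angstrom (divide by 10 for nm)."""
    sup = kabsch_superpose(st, unit_a, st, unit_b, atom_names=atom_names)
    return geometry.screw_decompose(sup.matrix())


def principal_axis(coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Dominant principal axis of a point cloud and its anisotropy ratio
    (largest/second singular value)."""
    X = np.asarray(coords, dtype=float)
    X = X - X.mean(axis=0)
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    ratio = float(s[0] / s[1]) if s[1] > 0 else math.inf
    return Vt[0], ratio


def domain_tilt(
    st: gemmi.Structure,
    domain_sel: UnitSelection | str,
    axis_sel: UnitSelection | str,
    reference: gemmi.Structure,
    ref_domain_sel: UnitSelection | str | None = None,
    ref_axis_sel: UnitSelection | str | None = None,
) -> float:
    """Tilt (degrees, in [0, 90]) of a domain's principal axis relative to the
    same domain in a reference structure, after superposing both structures
    on ``axis_sel`` (e.g. the coiled-coil).

    Warns when the domain is too isotropic for a well-defined axis."""
    import warnings

    ref_domain_sel = ref_domain_sel or domain_sel
    ref_axis_sel = ref_axis_sel or axis_sel
    sup = kabsch_superpose(st, axis_sel, reference, ref_axis_sel)

    dom = np.array([p for _, _, n, p, _ in select_atoms(st, domain_sel) if n == "CA"])
    ref_dom = np.array(
        [p for _, _, n, p, _ in select_atoms(reference, ref_domain_sel) if n == "CA"]
    )
    dom_moved = dom @ sup.rotation.T + sup.translation
    ax1, r1 = principal_axis(dom_moved)
    ax2, r2 = principal_axis(ref_dom)
    if min(r1, r2) < 1.2:
        warnings.warn(
            "domain is nearly isotropic; principal axis (and hence the tilt) "
            "is ill-defined",
            RuntimeWarning,
            stacklevel=2,
        )
    cosang = abs(float(np.clip(ax1 @ ax2, -1.0, 1.0)))
    return math.degrees(math.acos(cosang))


# ---------------------------------------------------------------------------
# interfaces
# ---------------------------------------------------------------------------

def interface_residues(
    st: gemmi.Structure,
    part_a: UnitSelection | str,
    part_b: UnitSelection | str,
    cutoff: float = CONTACT_CUTOFF,
) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    """Residue pairs with any heavy-atom distance <= cutoff (angstrom)."""
    from scipy.spatial import cKDTree

    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    atoms_a = select_atoms(st, part_a)
    atoms_b = select_atoms(st, part_b)
    if not atoms_a or not atoms_b:
        return []
    xyz_a = np.array([p for _, _, _, p, _ in atoms_a])
    xyz_b = np.array([p for _, _, _, p, _ in atoms_b])
    tree = cKDTree(xyz_b)
    pairs = set()
    for i, neighbours in enumerate(tree.query_ball_point(xyz_a, cutoff)):
        if not neighbours:
            continue
        ra = (atoms_a[i][0], atoms_a[i][1])
        for j in neighbours:
            pairs.add((ra, (atoms_b[j][0], atoms_b[j][1])))
    return sorted(pairs)


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(
    coords: np.ndarray,
    elements: list[str],
    probe: float = PROBE_RADIUS,
    n_points: int = SASA_POINTS,
) -> float:
    """Solvent-accessible surface area (angstrom^2) by Shrake-Rupley sphere
    sampling: each atom's solvent sphere is covered with ``n_points``
    quasi-uniform (Fibonacci) points and the fraction not occluded by any
    neighbouring sphere is summed."""
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    if n_points < 100:
        raise ValueError("n_points must be >= 100 for a stable estimate")
    unknown = sorted({e for e in elements if e.upper() not in VDW_RADII})
    if unknown:
        raise ValueError(f"no van der Waals radius for element(s): {unknown}")
    xyz = np.asarray(coords, dtype=float)
    radii = np.array([VDW_RADII[e.upper()] for e in elements]) + probe
    sphere = _fibonacci_sphere(n_points)

    from scipy.spatial import cKDTree

    tree = cKDTree(xyz)
    rmax = radii.max()
    total = 0.0
    for i in range(len(xyz)):
        pts = xyz[i] + radii[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(xyz[i], radii[i] + rmax):
            if j == i:
                continue
            d2 = ((pts - xyz[j]) ** 2).sum(axis=1)
            accessible &= d2 > radii[j] ** 2
        total += 4.0 * math.pi * radii[i] ** 2 * accessible.mean()
    return float(total)


def buried_interface_area(
    st: gemmi.Structure,
    part_a: UnitSelection | str,
    part_b: UnitSelection | str,
    probe: float = PROBE_RADIUS,
    n_points: int = SASA_POINTS,
) -> dict[str, float]:
    """Interface area buried between two parts of a structure.

    Returns both conventions: ``per_side`` = (SASA(a) + SASA(b) - SASA(ab))/2
    (the PISA-style headline number) and ``total`` = the full delta-SASA."""
    atoms_a = select_atoms(st, part_a)
    atoms_b = select_atoms(st, part_b)
    xyz_a = np.array([p for _, _, _, p, _ in atoms_a])
    el_a = [e for _, _, _, _, e in atoms_a]
    xyz_b = np.array([p for _, _, _, p, _ in atoms_b])
    el_b = [e for _, _, _, _, e in atoms_b]
    sasa_a = shrake_rupley_sasa(xyz_a, el_a, probe, n_points)
    sasa_b = shrake_rupley_sasa(xyz_b, el_b, probe, n_points)
    sasa_ab = shrake_rupley_sasa(
        np.vstack([xyz_a, xyz_b]), el_a + el_b, probe, n_points
    )
    total = sasa_a + sasa_b - sasa_ab
    return {"per_side": total / 2.0, "total": total}
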
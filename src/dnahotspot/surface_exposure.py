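"""Solvent accessibility and exposure descriptors from coordinates.

Implements a deterministic Shrake-Rupley solvent-accessible surface area
(SASA) with a generalized-spiral (Fibonacci) test-point lattice, relative
accessibility against a shipped reference table, half-sphere exposure,
contact number, and a point-cloud approximation of residue depth.

All quantities are computed from heavy atoms only; the probe radius defaults
to the standard 1.4 A water probe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Atom, Chain, Complex, Residue

__all__ = [
    "SasaParams",
    "ExposureProfile",
    "SasaResult",
    "load_vdw_radii",
    "load_reference_asa",
    "fibonacci_sphere",
    "shrake_rupley_sasa",
    "relative_asa",
    "half_sphere_exposure",
    "contact_number",
    "residue_depth",
    "exposure_profile",
]

_FALLBACK_RADIUS = 1.8  # A, for elements absent from the radii table


def _load_two_column(name: str) -> Dict[str, float]:
    table: Dict[str, float] = {}
    text = resources.files("dnahotspot").joinpath("data", name).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, val = line.split()
        table[key] = float(val)
    return table


def load_vdw_radii() -> Dict[str, float]:
    """Element -> van der Waals radius (A) from the shipped table."""
    return _load_two_column("vdw_radii.txt")


def load_reference_asa() -> Dict[str, float]:
    """Residue type -> reference maximum ASA (A^2) from the shipped table."""
    return _load_two_column("reference_asa.txt")


@dataclass
class SasaParams:
    probe_radius: float = 1.4  # A
    sphere_points: int = 960
    radii_table: Dict[str, float] = field(default_factory=load_vdw_radii)

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.sphere_points < 60:
            raise ValueError("sphere_points must be >= 60")

    def radius_of(self, element: str) -> float:
        r = self.radii_table.get(element.upper())
        if r is None:
            warnings.warn(
                f"no vdW radius for element {element!r}; using "
                f"{_FALLBACK_RADIUS} A"
            )
            return _FALLBACK_RADIUS
        return r


@dataclass
class SasaResult:
    atom_asa: np.ndarray            # per retained heavy atom, A^2
    residue_asa: Dict[tuple, float]  # residue key -> A^2
    surface_points: np.ndarray      # accessible test points (n, 3)
    atoms: list                     # the retained Atom objects
    atom_residues: list             # residue key per retained atom


@dataclass
class ExposureProfile:
    """Per-residue exposure descriptors; ``None`` marks residues where the
    required backbone geometry was missing."""
    asa: Dict[tuple, float]
    rasa: Dict[tuple, Optional[float]]
    hse_up: Dict[tuple, Optional[int]]
    hse_down: Dict[tuple, Optional[int]]
    contact_number: Dict[tuple, Optional[int]]
    residue_depth: Dict[tuple, float]


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform unit-sphere lattice (generalized spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def _collect_heavy_atoms(
    source: Iterable[Residue],
) -> Tuple[list, list]:
    atoms: list = []
    keys: list = []
    for res in source:
        for atom in res.heavy_atoms():
            atoms.append(atom)
            keys.append(res.key)
    return atoms, keys


def _residues_of(obj) -> Iterable[Residue]:
    if isinstance(obj, Complex):
        return list(obj.iter_residues())
    if isinstance(obj, Chain):
        return list(obj.residues)
    if isinstance(obj, Residue):
        return [obj]
    return list(obj)  # sequence of residues or chains


def shrake_rupley_sasa(
    entity,
    params: Optional[SasaParams] = None,
) -> SasaResult:
    """Shrake-Rupley SASA over the heavy atoms of ``entity``.

    ``entity`` may be a Complex, a Chain, a Residue, or any iterable of
    Residues/Chains.  Per-atom ASA is the accessible fraction of the test
    lattice times the sphere area at radius (r_vdw + probe); residue ASA sums
    its atoms.  The accessible test points are retained for residue-depth
    computation.  Fully deterministic: the lattice has no random component.
    """
    params = params or SasaParams()
    residues = _residues_of(entity)
    flat: list = []
    for item in residues:
        if isinstance(item, Chain):
            flat.extend(item.residues)
        else:
            flat.append(item)
    atoms, keys = _collect_heavy_atoms(flat)
    if not atoms:
        raise ValueError("entity contains no heavy atoms")

    coords = np.array([a.position for a in atoms])
    radii = np.array([params.radius_of(a.element) for a in atoms])
    probe = params.probe_radius
    extended = radii + probe
    unit = fibonacci_sphere(params.sphere_points)

    tree = cKDTree(coords)
    max_reach = 2.0 * extended.max()
    atom_asa = np.empty(len(atoms))
    surface_pts = []
    for i in range(len(atoms)):
        pts = coords[i] + extended[i] * unit
        neighbors = [
            j
            for j in tree.query_ball_point(coords[i], max_reach)
            if j != i
            and np.linalg.norm(coords[j] - coords[i]) < extended[i] + extended[j]
        ]
        accessible = np.ones(len(pts), dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d > extended[j]
        frac = accessible.mean()
        atom_asa[i] = frac * 4.0 * np.pi * extended[i] ** 2
        if accessible.any():
            surface_pts.append(pts[accessible])

    residue_asa: Dict[tuple, float] = {}
    for key, a in zip(keys, atom_asa):
        residue_asa[key] = residue_asa.get(key, 0.0) + float(a)

    return SasaResult(
        atom_asa=atom_asa,
        residue_asa=residue_asa,
        surface_points=np.vstack(surface_pts) if surface_pts else np.empty((0, 3)),
        atoms=atoms,
        atom_residues=keys,
    )


def relative_asa(
    residue_asa: float,
    residue_name: str,
    reference: Optional[Dict[str, float]] = None,
    *,
    allow_fallback: bool = False,
) -> float:
    """RASA in percent: 100 * ASA / reference_ASA(residue type)."""
    reference = reference or load_reference_asa()
    ref = reference.get(residue_name)
    if ref is None:
        if not allow_fallback:
            raise KeyError(
                f"no reference ASA for residue {residue_name!r}; enable "
                "allow_fallback to use the table mean"
            )
        ref = float(np.mean(list(reference.values())))
    return 100.0 * residue_asa / ref


def _pseudo_cb_direction(res: Residue) -> Optional[np.ndarray]:
    """CB direction from CA; real CB if present, else built from N/CA/C
    geometry (bisector construction, as used for glycine)."""
    ca = res.atom("CA")
    if ca is None:
        return None
    cb = res.atom("CB")
    if cb is not None:
        v = cb.position - ca.position
        n = np.linalg.norm(v)
        return v / n if n > 0 else None
    n_at, c_at = res.atom("N"), res.atom("C")
    if n_at is None or c_at is None:
        return None
    u = n_at.position - ca.position
    w = c_at.position - ca.position
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu == 0 or nw == 0:
        return None
    v = -(u / nu + w / nw)
    nv = np.linalg.norm(v)
    return v / nv if nv > 0 else None


def _protein_ca_table(entity) -> Tuple[list, np.ndarray]:
    residues = [
        r
        for r in _residues_of(entity)
        if not isinstance(r, Chain) and r.polymer_class == "protein"
    ] or [
        r
        for item in _residues_of(entity)
        if isinstance(item, Chain)
        for r in item.residues
        if r.polymer_class == "protein"
    ]
    keep = [r for r in residues if r.atom("CA") is not None]
    coords = np.array([r.atom("CA").position for r in keep]) if keep else np.empty((0, 3))
    return keep, coords


def half_sphere_exposure(
    entity,
    radius: float = 13.0,
) -> Tuple[Dict[tuple, Optional[int]], Dict[tuple, Optional[int]]]:
    """Half-sphere exposure (HSE-beta style) per protein residue.

    ``hse_up`` counts neighbouring CA atoms within ``radius`` on the
    side-chain (CA->CB) side of the plane through CA; ``hse_down`` the rest.
    Residues lacking the backbone atoms needed for a CB direction get
    ``None`` with a warning.
    """
    residues, coords = _protein_ca_table(entity)
    up: Dict[tuple, Optional[int]] = {}
    down: Dict[tuple, Optional[int]] = {}
    all_res = [
        r for r in _iter_all_protein(entity)
    ]
    for res in all_res:
        if res.atom("CA") is None:
            warnings.warn(f"residue {res.key} lacks CA; HSE marked missing")
            up[res.key] = None
            down[res.key] = None
    for i, res in enumerate(residues):
        direction = _pseudo_cb_direction(res)
        if direction is None:
            warnings.warn(
                f"residue {res.key} lacks backbone atoms for a CB direction; "
                "HSE marked missing"
            )
            up[res.key] = None
            down[res.key] = None
            continue
        rel = coords - coords[i]
        dist = np.linalg.norm(rel, axis=1)
        mask = (dist <= radius)
        mask[i] = False
        side = rel[mask] @ direction
        up[res.key] = int((side > 0).sum())
        down[res.key] = int((side <= 0).sum())
    return up, down


def _iter_all_protein(entity) -> Iterable[Residue]:
    for item in _residues_of(entity):
        if isinstance(item, Chain):
            for r in item.residues:
                if r.polymer_class == "protein":
                    yield r
        elif item.polymer_class == "protein":
            yield item


def contact_number(entity, radius: float = 13.0) -> Dict[tuple, Optional[int]]:
    """Number of other protein residues whose CA lies within ``radius`` of
    the target CA.  Equals hse_up + hse_down at the same radius."""
    residues, coords = _protein_ca_table(entity)
    out: Dict[tuple, Optional[int]] = {}
    for res in _iter_all_protein(entity):
        if res.atom("CA") is None:
            out[res.key] = None
    if len(residues) == 0:
        return out
    tree = cKDTree(coords)
    for i, res in enumerate(residues):
        out[res.key] = len(tree.query_ball_point(coords[i], radius)) - 1
    return out


def residue_depth(
    entity,
    params: Optional[SasaParams] = None,
    sasa_result: Optional[SasaResult] = None,
) -> Dict[tuple, float]:
    """Mean atom depth per residue, from the accessible SASA point cloud.

    Atom depth = min_p ||x_atom - p|| - r_vdw(atom) over the retained
    accessible surface points p.  A fully exposed atom's nearest accessible
    point lies on its own extended sphere at r_vdw + probe, so its depth is
    ~ the probe radius — the natural floor of this measure; buried atoms are
    deeper.  Residue depth averages over the residue's heavy atoms.
    """
    params = params or SasaParams()
    res = sasa_result or shrake_rupley_sasa(entity, params)
    if res.surface_points.shape[0] == 0:
        raise RuntimeError("no accessible surface points; cannot compute depth")
    tree = cKDTree(res.surface_points)
    depths: Dict[tuple, list] = {}
    d, _ = tree.query(np.array([a.position for a in res.atoms]))
    for atom, key, dist in zip(res.atoms, res.atom_residues, d):
        depth = dist - params.radius_of(atom.element)
        depths.setdefault(key, []).append(max(depth, 0.0))
    return {k: float(np.mean(v)) for k, v in depths.items()}


def exposure_profile(
    entity,
    params: Optional[SasaParams] = None,
    hse_radius: float = 13.0,
) -> ExposureProfile:
    """Bundle ASA, RASA, HSE, CN and residue depth for every protein residue
    of ``entity`` (computed on the given entity in isolation)."""
    params = params or SasaParams()
    sasa = shrake_rupley_sasa(entity, params)
    reference = load_reference_asa()
    rasa: Dict[tuple, Optional[float]] = {}
    names = {r.key: r.name for r in _iter_all_protein(entity)}
    for key, val in sasa.residue_asa.items():
        if key in names:
            try:
                rasa[key] = relative_asa(val, names[key], reference)
            except KeyError:
                rasa[key] = relative_asa(val, names[key], reference, allow_fallback=True)
    up, down = half_sphere_exposure(entity, hse_radius)
    cn = contact_number(entity, hse_radius)
    depth = residue_depth(entity, params, sasa)
    return ExposureProfile(
        asa={k: v for k, v in sasa.residue_asa.items() if k in names},
        rasa=rasa,
        hse_up=up,
        hse_down=down,
        contact_number=cn,
        residue_depth={k: v for k, v in depth.items() if k in names},
    )
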
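"""Solvent-accessible surface areas and buried interface areas.

Areas are computed by numeric sphere sampling (Shrake-Rupley style): each
heavy atom's sphere of radius (r_atom + r_probe) is covered by a
deterministic spiral (Fibonacci) point lattice, and the fraction of points
not occluded by any neighboring sphere, times the sphere area, is the
atom's contribution.  The lattice is fixed — no random numbers — so results
are bit-reproducible.

The interfacial (buried) area of a complex is the two-sided difference

    buried = area(A alone) + area(B alone) - area(A and B together)

with every component evaluated in its placement within the complex.
Hydrogens, waters and hetero-atoms are excluded by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structures import Structure

__all__ = [
    "RadiiSet",
    "AreaResult",
    "compute_area",
    "interface_area",
    "sphere_lattice",
]

DEFAULT_N_SPHERE_POINTS = 960


@dataclass(frozen=True)
class RadiiSet:
    """Per-element radii (A) plus the solvent probe radius.

    The default set is Chothia-style; unknown elements fall back to 1.8 A
    with a warning.
    """

    radii: dict = field(default_factory=lambda: {
        "C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85, "P": 1.90})
    probe_radius: float = 1.4
    fallback: float = 1.8

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii.values()) or self.probe_radius < 0:
            raise ValueError("radii must be positive")

    def radius(self, element: str) -> float:
        r = self.radii.get(element.upper())
        if r is None:
            if self.fallback is None:
                raise KeyError(f"no radius for element {element!r}")
            warnings.warn(f"no radius for element {element!r}; "
                          f"using fallback {self.fallback} A")
            r = self.fallback
        return r


@dataclass
class AreaResult:
    component_areas: dict          # component id -> A^2
    complex_area: float            # A^2
    buried_area: float             # A^2, two-sided
    method: str = "numeric-sphere"
    n_sphere_points: int = DEFAULT_N_SPHERE_POINTS


def sphere_lattice(n: int) -> np.ndarray:
    """Deterministic spiral (Fibonacci) lattice of n points on the unit
    sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def _surface_atoms(structure: Structure, radii_set: RadiiSet,
                   include_hetero: bool, include_waters: bool):
    xyz, radii = [], []
    for res in structure.residues():
        if res.is_water and not include_waters:
            continue
        for a in res.atoms:
            if a.is_hydrogen:
                continue
            if a.is_hetero and not include_hetero and not res.is_water:
                continue
            xyz.append(a.coords)
            radii.append(radii_set.radius(a.element))
    return (np.array(xyz) if xyz else np.empty((0, 3))), np.array(radii)


def _sasa(xyz: np.ndarray, radii: np.ndarray, probe: float, n_points: int) -> float:
    if len(xyz) == 0:
        raise ValueError("no heavy atoms to compute an area for")
    ext = radii + probe
    lattice = sphere_lattice(n_points)
    tree = cKDTree(xyz)
    max_reach = 2.0 * ext.max()
    total = 0.0
    for i in range(len(xyz)):
        neigh = [j for j in tree.query_ball_point(xyz[i], ext[i] + ext.max())
                 if j != i and np.linalg.norm(xyz[j] - xyz[i]) < ext[i] + ext[j]]
        pts = xyz[i] + ext[i] * lattice
        if neigh:
            d2 = np.sum((pts[:, None, :] - xyz[neigh][None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < (ext[neigh] ** 2)[None, :], axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        total += frac * 4.0 * np.pi * ext[i] ** 2
    return float(total)


def compute_area(structure: Structure,
                 radii_set: RadiiSet | None = None,
                 n_sphere_points: int = DEFAULT_N_SPHERE_POINTS,
                 include_hetero: bool = False,
                 include_waters: bool = False) -> float:
    """Probe-expanded surface area of a structure, A^2."""
    rs = radii_set or RadiiSet()
    xyz, radii = _surface_atoms(structure, rs, include_hetero, include_waters)
    return _sasa(xyz, radii, rs.probe_radius, n_sphere_points)


def interface_area(structure_a: Structure, structure_b: Structure,
                   radii_set: RadiiSet | None = None,
                   n_sphere_points: int = DEFAULT_N_SPHERE_POINTS,
                   ids: tuple[str, str] = ("A", "B"),
                   include_hetero: bool = False) -> AreaResult:
    """Two-sided buried interface area between two groups evaluated in
    their current (complex) placements:
    buried = area(A) + area(B) - area(A u B)."""
    rs = radii_set or RadiiSet()
    xa, ra = _surface_atoms(structure_a, rs, include_hetero, False)
    xb, rb = _surface_atoms(structure_b, rs, include_hetero, False)
    if len(xa) == 0 or len(xb) == 0:
        raise ValueError("both groups must contain heavy atoms")
    area_a = _sasa(xa, ra, rs.probe_radius, n_sphere_points)
    area_b = _sasa(xb, rb, rs.probe_radius, n_sphere_points)
    area_ab = _sasa(np.vstack([xa, xb]), np.concatenate([ra, rb]),
                    rs.probe_radius, n_sphere_points)
    return AreaResult(component_areas={ids[0]: area_a, ids[1]: area_b},
                      complex_area=area_ab,
                      buried_area=area_a + area_b - area_ab,
                      n_sphere_points=n_sphere_points)


def candidate_interface_area(candidate, group_a: list[str], group_b: list[str],
                             radii_set: RadiiSet | None = None,
                             n_sphere_points: int = DEFAULT_N_SPHERE_POINTS) -> AreaResult:
    """Buried area between two disjoint groups of components of a
    :class:`~mbg.assembly.CandidateComplex`, evaluated in-place."""
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if not group_a or not group_b:
        raise ValueError("groups must be non-empty")

    def merged(ids):
        from .structures import Structure as S
        out = S(id="+".join(ids))
        for cid in ids:
            out.chains.extend(candidate.component(cid).placed_structure().chains)
        return out

    result = interface_area(merged(group_a), merged(group_b), radii_set,
                            n_sphere_points,
                            ids=("+".join(group_a), "+".join(group_b)))
    return result
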
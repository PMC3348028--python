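"""Binding-geometry transfer and complex assembly.

A binding geometry is the relative rigid-body arrangement of two components
observed in a template complex.  It is stored *frame-relatively* (in
component A's local frame) so it is invariant under any global rigid motion
of the template, and can be re-applied to homologous target components:
superpose each target onto its template component, then read off the
assembled complex.  A DNA duplex can serve as the scaffold that links all
placed components into one unit; canonical B-DNA segments are generated at
pseudo-atom resolution (P, C1', glycosidic N) and spliced onto template DNA
by superposing overlapping base pairs.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .geometry import (RigidTransform, SuperpositionResult, apply_transform,
                       compose, kabsch_superpose, rmsd)
from .structures import (Atom, Chain, Residue, SelectionError, Structure,
                         select, select_spec)

__all__ = [
    "BindingGeometry",
    "CandidateComplex",
    "BDnaParams",
    "derive_binding_geometry",
    "transfer",
    "assemble_on_scaffold",
    "build_bdna",
    "splice_dna",
    "reference_coords",
]

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def reference_coords(structure: Structure) -> np.ndarray:
    """Reference-point coordinates of a component: Calpha atoms, or C1'
    atoms for nucleic acids, or every atom if neither is present."""
    ca = structure.coords(atom_name="CA")
    if len(ca) >= 3:
        return ca
    c1 = structure.coords(atom_name="C1'")
    if len(c1) >= 3:
        return c1
    return structure.coords()


def _local_frame(coords: np.ndarray) -> RigidTransform:
    """Rotation-equivariant orthonormal frame of a point set, anchored on
    (centroid, first point, last point).  Equivariant under rigid motion by
    construction — no PCA sign ambiguity."""
    X = np.asarray(coords, dtype=float)
    if len(X) < 3:
        raise ValueError("need >= 3 reference points for a local frame")
    c = X.mean(axis=0)
    u = X[0] - c
    v = X[-1] - c
    nu = np.linalg.norm(u)
    w = np.cross(u, v)
    nw = np.linalg.norm(w)
    if nu < 1e-9 or nw < 1e-9:
        raise ValueError("degenerate selection: reference points are collinear")
    x = u / nu
    z = w / nw
    y = np.cross(z, x)
    R = np.column_stack([x, y, z])
    return RigidTransform(R, c)


@dataclass
class BindingGeometry:
    """Relative placement of component B with respect to component A, as
    seen in a template complex.

    ``transform_a_to_b_frame`` maps A-local coordinates of B's frame:
    it is F_A^-1 composed with F_B and therefore invariant under global
    rigid motion of the template.  The extracted template component
    sub-structures are kept so the geometry can be re-anchored.
    """

    template_id: str
    component_a_selection: str
    component_b_selection: str
    transform_a_to_b_frame: RigidTransform
    component_a: Structure
    component_b: Structure
    provenance: str = ""

    def frame_a(self) -> RigidTransform:
        return _local_frame(reference_coords(self.component_a))

    def world_transform(self, frame_a: RigidTransform | None = None) -> RigidTransform:
        """The world-frame A->B transform for a given placement of component
        A (defaults to the template's own placement).  When component B is a
        rigidly moved copy of component A this equals that motion."""
        fa = frame_a if frame_a is not None else self.frame_a()
        return compose(compose(fa, self.transform_a_to_b_frame), fa.inverse())


@dataclass
class PlacedComponent:
    component_id: str
    structure: Structure
    transform: RigidTransform
    superposition_rmsd: float | None = None

    def placed_structure(self) -> Structure:
        coords = np.array([a.coords for a in self.structure.atoms()])
        return self.structure.with_coords(apply_transform(self.transform, coords))


@dataclass
class CandidateComplex:
    components: list[PlacedComponent] = field(default_factory=list)
    scaffold_id: str | None = None
    filter_results: list = field(default_factory=list)
    interface_areas: list = field(default_factory=list)
    notes: list[str] = field(default_factory=list)
    candidate_id: str = ""

    def __post_init__(self) -> None:
        ids = [c.component_id for c in self.components]
        if len(set(ids)) != len(ids):
            raise ValueError("component ids must be unique")

    def component(self, component_id: str) -> PlacedComponent:
        for c in self.components:
            if c.component_id == component_id:
                return c
        raise KeyError(component_id)

    def to_structure(self, structure_id: str = "complex") -> Structure:
        """Merge all placed components into one structure; colliding chain
        ids are remapped to the first unused letter and the remapping is
        recorded in ``notes``."""
        merged = Structure(id=structure_id)
        used: set[str] = set()
        alphabet = string.ascii_uppercase + string.digits + string.ascii_lowercase
        for pc in self.components:
            placed = pc.placed_structure()
            for chain in placed.chains:
                cid = chain.chain_id
                if cid in used:
                    free = next((c for c in alphabet if c not in used), None)
                    if free is None:
                        raise ValueError("ran out of chain identifiers")
                    self.notes.append(
                        f"chain {cid!r} of component {pc.component_id!r} "
                        f"renamed to {free!r}")
                    cid = free
                used.add(cid)
                new_chain = Chain(cid, [])
                for res in chain.residues:
                    r = res.copy()
                    r.chain_id = cid
                    new_chain.residues.append(r)
                merged.chains.append(new_chain)
        return merged


# ---------------------------------------------------------------------------
# Deriving and transferring binding geometries

def derive_binding_geometry(template_complex: Structure,
                            sel_a: str, sel_b: str,
                            provenance: str = "") -> BindingGeometry:
    """Record the relative arrangement of two components of a template
    complex.  Selections are ``chain[:start-end[:atom]]`` strings resolving
    to >= 3 reference atoms each."""
    comp_a = select_spec(template_complex, sel_a)
    comp_b = select_spec(template_complex, sel_b)

    def strict_ref(comp, sel):
        ca = comp.coords(atom_name="CA")
        if len(ca) >= 3:
            return ca
        c1 = comp.coords(atom_name="C1'")
        if len(c1) >= 3:
            return c1
        raise ValueError(f"selection {sel!r} must resolve to >= 3 CA (or C1') atoms")

    ra = strict_ref(comp_a, sel_a)
    rb = strict_ref(comp_b, sel_b)
    fa = _local_frame(ra)
    fb = _local_frame(rb)
    rel = compose(fa.inverse(), fb)
    return BindingGeometry(template_id=template_complex.id,
                           component_a_selection=sel_a,
                           component_b_selection=sel_b,
                           transform_a_to_b_frame=rel,
                           component_a=comp_a, component_b=comp_b,
                           provenance=provenance)


def _mapped_coords(target: Structure, template: Structure,
                   mapping) -> tuple[np.ndarray, np.ndarray]:
    """Resolve a target<->template atom mapping to paired coordinate arrays.

    ``mapping`` is either ``None`` (pair reference atoms by order; counts
    must agree) or an (n, 2) index array into the flattened atom lists."""
    if mapping is None:
        a = reference_coords(target)
        b = reference_coords(template)
        if len(a) != len(b):
            raise ValueError(
                f"cannot map by order: {len(a)} target vs {len(b)} template "
                "reference atoms; supply an explicit mapping")
        return a, b
    mapping = np.asarray(mapping, dtype=int)
    if mapping.ndim != 2 or mapping.shape[1] != 2:
        raise ValueError("mapping must be an (n, 2) index array")
    tc = np.array([a.coords for a in target.atoms()])
    mc = np.array([a.coords for a in template.atoms()])
    return tc[mapping[:, 0]], mc[mapping[:, 1]]


def transfer(binding_geometry: BindingGeometry,
             target_a: Structure, target_b: Structure,
             mapping_a=None, mapping_b=None,
             id_a: str = "A", id_b: str = "B") -> CandidateComplex:
    """Apply a template binding geometry to two homologous targets.

    Each target is superposed (Kabsch) onto its template component through
    the given atom mapping, and placed accordingly; the superposition RMSDs
    are recorded on the candidate.
    """
    xa, ta = _mapped_coords(target_a, binding_geometry.component_a, mapping_a)
    xb, tb = _mapped_coords(target_b, binding_geometry.component_b, mapping_b)
    if len(xa) < 3 or len(xb) < 3:
        raise ValueError("mappings must give >= 3 atom pairs each")
    sup_a = kabsch_superpose(xa, ta)
    sup_b = kabsch_superpose(xb, tb)
    return CandidateComplex(components=[
        PlacedComponent(id_a, target_a, sup_a.transform, sup_a.rmsd),
        PlacedComponent(id_b, target_b, sup_b.transform, sup_b.rmsd),
    ], notes=[f"binding geometry from template {binding_geometry.template_id!r}"])


def assemble_on_scaffold(scaffold: Structure,
                         placements,
                         scaffold_component_id: str = "scaffold") -> CandidateComplex:
    """Place components in the scaffold's coordinate frame.

    Each placement is ``(component_id, structure, how)`` where ``how`` is
    either an explicit :class:`RigidTransform` or a tuple
    ``(binding_geometry, anchor_selection)``: the geometry's template
    component A is superposed onto the scaffold anchor (reference atoms by
    order), the component is superposed onto template component B, and the
    chained transform places the component.
    """
    candidate = CandidateComplex(components=[
        PlacedComponent(scaffold_component_id, scaffold, RigidTransform.identity())],
        scaffold_id=scaffold.id)
    for component_id, structure, how in placements:
        if isinstance(how, RigidTransform):
            tr, sup_rmsd = how, None
        else:
            bg, anchor_sel = how
            anchor = select_spec(scaffold, anchor_sel)
            if anchor.n_atoms == 0:
                raise SelectionError(f"anchor {anchor_sel!r} not on scaffold")
            anchor_xyz = reference_coords(anchor)
            templ_a_xyz = reference_coords(bg.component_a)
            if len(anchor_xyz) != len(templ_a_xyz):
                raise ValueError(
                    f"anchor {anchor_sel!r} resolves to {len(anchor_xyz)} reference "
                    f"atoms but template component A has {len(templ_a_xyz)}")
            sup_anchor = kabsch_superpose(templ_a_xyz, anchor_xyz)
            sup_comp = kabsch_superpose(reference_coords(structure),
                                        reference_coords(bg.component_b))
            tr = compose(sup_anchor.transform, sup_comp.transform)
            sup_rmsd = sup_comp.rmsd
        candidate.components.append(
            PlacedComponent(component_id, structure, tr, sup_rmsd))
    return candidate


# ---------------------------------------------------------------------------
# Canonical B-DNA

@dataclass(frozen=True)
class BDnaParams:
    """Ideal B-form helical parameters (pseudo-atom resolution)."""

    rise: float = 3.38            # A per base pair
    twist: float = 36.0           # degrees per base pair
    backbone_radius: float = 9.4  # A, phosphate distance from the axis
    c1_radius: float = 5.9        # A
    base_radius: float = 3.0      # A, glycosidic nitrogen
    strand_phase: float = 77.0    # degrees, half-angle between the strands

    def __post_init__(self) -> None:
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if not (0 < self.twist < 360):
            raise ValueError("twist must be in (0, 360) degrees")


def _nucleotide_atoms(base: str, theta: float, z: float, p: BDnaParams,
                      serial0: int) -> list[Atom]:
    glyco = "N9" if base in "AG" else "N1"
    atoms = []
    for i, (name, radius, elem) in enumerate([
            ("P", p.backbone_radius, "P"),
            ("C1'", p.c1_radius, "C"),
            (glyco, p.base_radius, "N")]):
        xyz = np.array([radius * np.cos(theta), radius * np.sin(theta), z])
        atoms.append(Atom(serial=serial0 + i, name=name, element=elem, alt_loc="",
                          coords=xyz))
    return atoms


def build_bdna(sequence: str, params: BDnaParams | None = None,
               chain_ids: tuple[str, str] = ("A", "B")) -> Structure:
    """Ideal straight B-DNA duplex for ``sequence`` (read 5'->3' on strand
    one).  Base-pair frame i sits at z = i * rise, rotated i * twist about
    z; each nucleotide carries P, C1' and glycosidic-N pseudo-atoms.  The
    second strand is the reverse complement, listed 5'->3'."""
    p = params or BDnaParams()
    sequence = sequence.upper()
    if len(sequence) < 2:
        raise ValueError("sequence must have length >= 2")
    for ch in sequence:
        if ch not in _COMPLEMENT:
            raise ValueError(f"invalid nucleotide {ch!r}; expected A/C/G/T")
    n = len(sequence)
    phase = np.radians(p.strand_phase)
    serial = 1
    strand1 = Chain(chain_ids[0])
    for i, base in enumerate(sequence):
        theta = np.radians(i * p.twist) + phase
        atoms = _nucleotide_atoms(base, theta, i * p.rise, p, serial)
        serial += len(atoms)
        strand1.residues.append(Residue(chain_ids[0], i + 1, "", "D" + base, atoms))
    strand2 = Chain(chain_ids[1])
    # strand two runs antiparallel: its 5' end pairs the 3' end of strand one
    for j in range(n):
        i = n - 1 - j                       # paired base-pair index
        base = _COMPLEMENT[sequence[i]]
        theta = np.radians(i * p.twist) + np.pi - phase
        atoms = _nucleotide_atoms(base, theta, i * p.rise, p, serial)
        serial += len(atoms)
        strand2.residues.append(Residue(chain_ids[1], j + 1, "", "D" + base, atoms))
    return Structure(id=f"bdna_{sequence[:8]}", chains=[strand1, strand2])


def duplex_sequence(duplex: Structure, chain_id: str | None = None) -> str:
    chain = duplex.chains[0] if chain_id is None else duplex.chain(chain_id)
    return "".join(r.res_name[-1] for r in chain.residues)


def dna_segment(duplex: Structure, bp_start: int, bp_end: int,
                renumber: bool = True) -> Structure:
    """Extract base pairs ``bp_start..bp_end`` (1-based on strand one,
    inclusive) of a two-chain duplex, keeping both strands paired.  With
    ``renumber`` the segment is renumbered from 1 on both strands."""
    if len(duplex.chains) != 2:
        raise ValueError("expected a two-chain duplex")
    n = len(duplex.chains[0])
    if not (1 <= bp_start <= bp_end <= n):
        raise ValueError(f"base-pair range {bp_start}-{bp_end} outside 1-{n}")
    s1 = select(duplex, chain_ids=duplex.chains[0].chain_id,
                residue_range=(bp_start, bp_end))
    # strand-two residue j pairs base pair n + 1 - j
    s2 = select(duplex, chain_ids=duplex.chains[1].chain_id,
                residue_range=(n + 1 - bp_end, n + 1 - bp_start))
    out = Structure(id=f"{duplex.id}_{bp_start}-{bp_end}",
                    chains=s1.chains + s2.chains)
    if renumber:
        _renumber(out)
    return out


def _renumber(structure: Structure) -> None:
    for chain in structure.chains:
        for i, res in enumerate(chain.residues, start=1):
            res.seq_num = i


def splice_dna(segment_up: Structure, segment_down: Structure,
               overlap_up: tuple[int, int], overlap_down: tuple[int, int],
               splice_rmsd_max: float = 1.0) -> Structure:
    """Join two duplex segments over a shared run of base pairs.

    ``overlap_up`` / ``overlap_down`` give the 1-based inclusive base-pair
    ranges (on strand one of each segment) that represent the same DNA.
    The downstream segment is superposed onto the upstream one over the
    overlap anchor atoms; its overlap nucleotides are then dropped and the
    merged duplex renumbered continuously.  A post-superposition overlap
    RMSD above ``splice_rmsd_max`` raises ``ValueError``.
    """
    lo_u, hi_u = overlap_up
    lo_d, hi_d = overlap_down
    n_bp = hi_u - lo_u + 1
    if n_bp != hi_d - lo_d + 1:
        raise ValueError("overlap ranges must cover the same number of base pairs")
    if n_bp < 2:
        raise ValueError("overlap must cover >= 2 base pairs")
    ov_up = dna_segment(segment_up, lo_u, hi_u, renumber=False)
    ov_dn = dna_segment(segment_down, lo_d, hi_d, renumber=False)
    up_xyz = ov_up.coords()
    dn_xyz = ov_dn.coords()
    if up_xyz.shape != dn_xyz.shape:
        raise ValueError("overlap selections resolve to different atom counts")
    sup = kabsch_superpose(dn_xyz, up_xyz)
    if sup.rmsd > splice_rmsd_max:
        raise ValueError(
            f"splice overlap RMSD {sup.rmsd:.3f} A exceeds {splice_rmsd_max} A")
    n_dn = len(segment_down.chains[0])
    down_rest = dna_segment(segment_down, hi_d + 1, n_dn, renumber=False) \
        if hi_d < n_dn else None
    merged = Structure(id=f"{segment_up.id}+{segment_down.id}")
    up1, up2 = segment_up.chains
    merged.chains = [up1.copy(), up2.copy()]
    if down_rest is not None:
        placed = down_rest.with_coords(apply_transform(sup.transform,
                                                       down_rest.coords()))
        d1, d2 = placed.chains
        # strand one extends 3' (append); strand two extends 5' (prepend)
        merged.chains[0].residues.extend(r.copy() for r in d1.residues)
        merged.chains[1].residues = [r.copy() for r in d2.residues] + \
            merged.chains[1].residues
    for chain in merged.chains:
        for res in chain.residues:
            res.chain_id = chain.chain_id
    _renumber(merged)
    _renumber_serials(merged)
    return merged


def _renumber_serials(structure: Structure) -> None:
    for i, atom in enumerate(structure.atoms(), start=1):
        atom.serial = i
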
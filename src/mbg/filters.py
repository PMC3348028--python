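"""Screening of candidate complexes and docking poses.

Three physical criteria gate a candidate assembly:

* steric exclusion — components must be in contact but not overlapping;
  a clash is an inter-component heavy-atom pair closer than a hard
  threshold (default 2.5 A, severe van-der-Waals overlap), or, in soft
  mode, closer than 0.8 x the sum of the atoms' van-der-Waals radii;
* linker feasibility — an n-residue inter-domain loop can span at most
  about n x 3.5 A between its anchor atoms (fully extended chain), e.g.
  14 A for a 4-residue loop;
* interface plausibility — buried interface areas within the range
  observed for heterocomplexes (639-3,228 A^2) are flagged plausible;
  this is an annotation, never a hard filter.

Survivors are ranked lexicographically: feasible linkers and zero clashes
required, then descending total buried interface area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .assembly import CandidateComplex
from .geometry import RigidTransform, apply_transform
from .structures import Structure, select_spec

__all__ = [
    "ClashReport",
    "LinkerCheck",
    "PoseSet",
    "ScreenConfig",
    "count_clashes",
    "check_linker",
    "screen_poses",
    "rank_candidates",
    "VDW_RADII",
    "PLAUSIBLE_INTERFACE_RANGE",
]

#: Chothia-style van-der-Waals radii (A)
VDW_RADII = {"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85, "P": 1.90}
VDW_FALLBACK = 1.8

#: Buried-area band typical of heterocomplexes (A^2); annotation only.
PLAUSIBLE_INTERFACE_RANGE = (639.0, 3228.0)

DEFAULT_CLASH_THRESHOLD = 2.5   # A
DEFAULT_PER_RESIDUE_SPAN = 3.5  # A per loop residue, fully extended


@dataclass
class ClashReport:
    n_clash_pairs: int
    worst_overlap: float            # A; threshold minus the closest distance
    pairs: list[tuple[int, int, float]]  # (atom index comp A, atom index comp B, d)
    threshold_used: float
    component_ids: tuple[str, str] | None = None

    @property
    def clean(self) -> bool:
        return self.n_clash_pairs == 0


@dataclass
class LinkerCheck:
    n_loop_residues: int
    anchor_distance: float  # A
    max_span: float         # A = n_loop_residues * per_residue_span
    feasible: bool


@dataclass
class PoseSet:
    """Rigid transforms applied to a mobile component against a fixed one."""

    poses: list[RigidTransform]
    source: str = ""

    def __len__(self) -> int:
        return len(self.poses)


def _heavy_coords_with_radii(structure: Structure):
    xyz, radii = [], []
    for a in structure.atoms():
        if a.is_hydrogen:
            continue
        xyz.append(a.coords)
        radii.append(VDW_RADII.get(a.element.upper(), VDW_FALLBACK))
    return (np.array(xyz) if xyz else np.empty((0, 3))), np.array(radii)


def _clash_pairs(xyz_a, rad_a, xyz_b, rad_b, threshold, soft, vdw_fraction):
    """Inter-set atom pairs closer than the (hard or soft) threshold,
    found with a KD-tree but equal to the all-pairs answer."""
    if len(xyz_a) == 0 or len(xyz_b) == 0:
        return []
    if soft:
        cutoff = vdw_fraction * (rad_a.max() + rad_b.max())
    else:
        cutoff = threshold
    tree_a = cKDTree(xyz_a)
    tree_b = cKDTree(xyz_b)
    pairs = []
    for i, neigh in enumerate(tree_a.query_ball_tree(tree_b, cutoff)):
        for j in neigh:
            d = float(np.linalg.norm(xyz_a[i] - xyz_b[j]))
            lim = vdw_fraction * (rad_a[i] + rad_b[j]) if soft else threshold
            if d < lim:
                pairs.append((i, j, d))
    return pairs


def count_clashes(candidate: CandidateComplex,
                  threshold: float = DEFAULT_CLASH_THRESHOLD,
                  soft: bool = False,
                  vdw_fraction: float = 0.8,
                  exclude_component_pairs=None) -> ClashReport:
    """Count inter-component heavy-atom clashes over all component pairs.

    Intra-component contacts are ignored; hydrogens are excluded.  In soft
    mode a pair clashes below ``vdw_fraction x (r_i + r_j)`` instead of the
    fixed threshold.
    """
    if len(candidate.components) < 2:
        raise ValueError("candidate must have >= 2 components")
    excluded = {frozenset(p) for p in (exclude_component_pairs or [])}
    placed = [(pc.component_id, *_heavy_coords_with_radii(pc.placed_structure()))
              for pc in candidate.components]
    all_pairs: list[tuple[int, int, float]] = []
    worst = 0.0
    ids_used = None
    for i in range(len(placed)):
        for j in range(i + 1, len(placed)):
            id_a, xa, ra = placed[i]
            id_b, xb, rb = placed[j]
            if frozenset((id_a, id_b)) in excluded:
                continue
            prs = _clash_pairs(xa, ra, xb, rb, threshold, soft, vdw_fraction)
            if prs:
                ids_used = (id_a, id_b)
                worst = max(worst, max(threshold - d for _, _, d in prs))
            all_pairs.extend(prs)
    return ClashReport(n_clash_pairs=len(all_pairs), worst_overlap=worst,
                       pairs=all_pairs, threshold_used=threshold,
                       component_ids=ids_used)


def check_linker(anchor_a: np.ndarray, anchor_b: np.ndarray,
                 n_loop_residues: int,
                 per_residue_span: float = DEFAULT_PER_RESIDUE_SPAN) -> LinkerCheck:
    """Can an ``n_loop_residues``-residue loop bridge the two anchor atoms?

    Feasible iff the anchor distance is at most n x per_residue_span
    (boundary inclusive); the default span of 3.5 A/residue gives the
    14 A cutoff for a 4-residue loop.  Anchors are backbone-atom positions,
    conventionally C of the upstream residue and N of the downstream one.
    """
    a = np.asarray(anchor_a, dtype=float).reshape(3)
    b = np.asarray(anchor_b, dtype=float).reshape(3)
    d = float(np.linalg.norm(a - b))
    max_span = n_loop_residues * per_residue_span
    return LinkerCheck(n_loop_residues=n_loop_residues, anchor_distance=d,
                       max_span=max_span, feasible=d <= max_span)


def resolve_anchor(structure: Structure, spec: str) -> np.ndarray:
    """Resolve a ``chain:resnum:atom`` selection to exactly one atom."""
    sub = select_spec(structure, spec)
    atoms = list(sub.atoms())
    if len(atoms) != 1:
        raise ValueError(f"anchor {spec!r} resolves to {len(atoms)} atoms, need 1")
    return atoms[0].coords


@dataclass(frozen=True)
class ScreenConfig:
    n_loop_residues: int = 4
    per_residue_span: float = DEFAULT_PER_RESIDUE_SPAN
    clash_threshold: float = DEFAULT_CLASH_THRESHOLD
    soft_clash: bool = False
    anchor_fixed: str = ""    # selection on the fixed component (C atom side)
    anchor_mobile: str = ""   # selection on the mobile component (N atom side)


@dataclass
class ScreenResult:
    linker_checks: list[LinkerCheck]
    clash_reports: list[ClashReport]
    linker_pass: np.ndarray     # bool per pose
    clash_pass: np.ndarray      # bool per pose
    survivors: list[int]
    survivor_fraction: float
    linker_fraction: float
    clash_fraction: float


def screen_poses(pose_set: PoseSet, fixed: Structure, mobile: Structure,
                 config: ScreenConfig) -> ScreenResult:
    """Apply the connectivity filter, then the steric filter, to every pose.

    The linker check measures the distance from the fixed-side anchor to
    the pose-transformed mobile-side anchor; the clash stage counts
    inter-component heavy-atom contacts for the same placement.  Returns
    per-pose verdicts, survivor indices, and survivor fractions per stage.
    """
    if len(pose_set) == 0:
        raise ValueError("pose set is empty")
    anchor_f = resolve_anchor(fixed, config.anchor_fixed)
    anchor_m = resolve_anchor(mobile, config.anchor_mobile)
    xyz_f, rad_f = _heavy_coords_with_radii(fixed)
    xyz_m0, rad_m = _heavy_coords_with_radii(mobile)

    linker_checks, clash_reports = [], []
    linker_pass = np.zeros(len(pose_set), dtype=bool)
    clash_pass = np.zeros(len(pose_set), dtype=bool)
    for k, tr in enumerate(pose_set.poses):
        lc = check_linker(anchor_f, apply_transform(tr, anchor_m),
                          config.n_loop_residues, config.per_residue_span)
        linker_checks.append(lc)
        linker_pass[k] = lc.feasible
        prs = _clash_pairs(xyz_f, rad_f, apply_transform(tr, xyz_m0), rad_m,
                           config.clash_threshold, config.soft_clash, 0.8)
        worst = max((config.clash_threshold - d for _, _, d in prs), default=0.0)
        clash_reports.append(ClashReport(len(prs), worst, prs,
                                         config.clash_threshold))
        clash_pass[k] = not prs
    both = linker_pass & clash_pass
    survivors = [int(i) for i in np.nonzero(both)[0]]
    n = len(pose_set)
    return ScreenResult(linker_checks=linker_checks, clash_reports=clash_reports,
                        linker_pass=linker_pass, clash_pass=clash_pass,
                        survivors=survivors,
                        survivor_fraction=float(both.sum()) / n,
                        linker_fraction=float(linker_pass.sum()) / n,
                        clash_fraction=float(clash_pass.sum()) / n)


def interface_plausible(buried_area: float) -> bool:
    lo, hi = PLAUSIBLE_INTERFACE_RANGE
    return lo <= buried_area <= hi


def rank_candidates(candidates: list[CandidateComplex]) -> list[CandidateComplex]:
    """Order candidates by (all linkers feasible & zero clashes) first, then
    by descending total buried interface area, ties by candidate id.
    Candidates missing clash/linker/area annotations raise ``ValueError``."""

    def key(c: CandidateComplex):
        clash_reports = [f for f in c.filter_results if isinstance(f, ClashReport)]
        linker_checks = [f for f in c.filter_results if isinstance(f, LinkerCheck)]
        if not clash_reports or not linker_checks or not c.interface_areas:
            raise ValueError(
                f"candidate {c.candidate_id!r} is missing clash/linker/area "
                "annotations required for ranking")
        clean = all(r.clean for r in clash_reports)
        feasible = all(l.feasible for l in linker_checks)
        total_buried = sum(a.buried_area for a in c.interface_areas)
        return (not (feasible and clean), -total_buried, c.candidate_id)

    return sorted(candidates, key=key)
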
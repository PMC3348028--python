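"""Secondary-structure elements and their line-vector reduction.

A motif here is the scaffolding of a domain: its helices and strands, each
collapsed to an oriented line segment.  Two motifs can then be aligned by
minimizing the angles and minimum distances between corresponding segments
(see :mod:`mbg.motif_match`).

Detection is geometric, from Calpha coordinates alone:

* helix  — runs where d(CA_i, CA_{i+3}) lies in [4.5, 6.0] A and the
  virtual torsion CA(i..i+3) lies in [35 deg, 75 deg];
* strand — runs (outside helices) where d(CA_i, CA_{i+2}) lies in
  [6.3, 7.3] A, the pleated-geometry signature of extended chain.

These windows bracket ideal alpha-helix (d_{i,i+3} ~ 5.0 A, torsion ~ 50
deg) and beta-strand (d_{i,i+2} ~ 6.5-7.0 A) geometry.  Externally computed
per-residue H/E/C strings can be imported instead of running the detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import Structure

__all__ = [
    "SSE",
    "LineVector",
    "MotifDescriptor",
    "SSEParams",
    "detect_sses",
    "fit_line_vector",
    "motif_from_structure",
    "vector_angle",
    "vector_min_distance",
    "segment_min_distance",
    "sses_from_assignment",
]

HELIX_D13 = (4.5, 6.0)          # A, CA(i)->CA(i+3)
HELIX_TORSION = (35.0, 75.0)    # deg, virtual CA torsion
STRAND_D02 = (6.3, 7.3)         # A, CA(i)->CA(i+2)


@dataclass(frozen=True)
class SSEParams:
    min_helix: int = 5
    min_strand: int = 3


@dataclass
class SSE:
    kind: str                   # "helix" | "strand"
    chain_id: str
    start_seq: int
    end_seq: int
    ca_coords: np.ndarray       # (n, 3)

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if self.kind not in ("helix", "strand"):
            raise ValueError(f"unknown SSE kind {self.kind!r}")

    @property
    def n_res(self) -> int:
        return len(self.ca_coords)


@dataclass(frozen=True)
class LineVector:
    """An SSE reduced to an oriented segment: origin + direction * s,
    s in [0, length].  Direction points N -> C."""

    origin: np.ndarray          # (3,)
    direction: np.ndarray       # unit (3,)
    length: float               # A
    source_sse: SSE | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if self.length <= 0:
            raise ValueError("length must be positive")
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "direction", d)

    @property
    def end(self) -> np.ndarray:
        return self.origin + self.direction * self.length

    @property
    def kind(self) -> str | None:
        return self.source_sse.kind if self.source_sse is not None else None

    def transformed(self, transform) -> "LineVector":
        return LineVector(transform.apply(self.origin),
                          transform.rotation @ self.direction,
                          self.length, self.source_sse)


@dataclass
class MotifDescriptor:
    vectors: list[LineVector]
    structure_ref: str = ""

    def __post_init__(self) -> None:
        if not self.vectors:
            raise ValueError("a motif needs at least one line vector")

    def __len__(self) -> int:
        return len(self.vectors)

    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays, each (n, 3)."""
        return (np.array([v.origin for v in self.vectors]),
                np.array([v.end for v in self.vectors]))

    def transformed(self, transform) -> "MotifDescriptor":
        return MotifDescriptor([v.transformed(transform) for v in self.vectors],
                               self.structure_ref)


# ---------------------------------------------------------------------------
# Detection

def _virtual_torsion(p0, p1, p2, p3) -> float:
    """CA virtual dihedral in degrees, signed (-180, 180]; a right-handed
    alpha-helix gives ~ +50 deg."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    return float(np.degrees(np.arctan2(y, x)))


def _ca_runs(chain) -> list[list[tuple[int, np.ndarray]]]:
    """Consecutive-residue runs with CA atoms (split at gaps > 4.5 A)."""
    runs: list[list[tuple[int, np.ndarray]]] = []
    cur: list[tuple[int, np.ndarray]] = []
    for res in chain.residues:
        ca = res.atom("CA")
        if ca is None:
            if cur:
                runs.append(cur)
            cur = []
            continue
        if cur and np.linalg.norm(ca.coords - cur[-1][1]) > 4.5:
            runs.append(cur)
            cur = []
        cur.append((res.seq_num, ca.coords))
    if cur:
        runs.append(cur)
    return runs


def detect_sses(structure: Structure, params: SSEParams | None = None) -> list[SSE]:
    """Geometric SSE assignment from Calpha coordinates.

    Returns non-overlapping SSEs per chain in chain order; helices take
    precedence over strands on contested residues.  Raises ``ValueError``
    when the structure has no Calpha atoms at all.
    """
    params = params or SSEParams()
    found: list[SSE] = []
    any_ca = False
    for chain in structure.chains:
        for run in _ca_runs(chain):
            any_ca = True
            n = len(run)
            if n < 3:
                continue
            seqs = [s for s, _ in run]
            xyz = np.array([c for _, c in run])
            helix_flag = np.zeros(n - 3, dtype=bool) if n >= 4 else np.zeros(0, bool)
            for i in range(n - 3):
                d13 = np.linalg.norm(xyz[i + 3] - xyz[i])
                if not (HELIX_D13[0] <= d13 <= HELIX_D13[1]):
                    continue
                tor = _virtual_torsion(xyz[i], xyz[i + 1], xyz[i + 2], xyz[i + 3])
                if HELIX_TORSION[0] <= tor <= HELIX_TORSION[1]:
                    helix_flag[i] = True
            in_helix = np.zeros(n, dtype=bool)
            for a, b in _flag_runs(helix_flag):
                span = (b + 3) - a + 1
                if span >= params.min_helix:
                    found.append(SSE("helix", chain.chain_id, seqs[a], seqs[b + 3],
                                     xyz[a:b + 4]))
                    in_helix[a:b + 4] = True
            strand_flag = np.zeros(n - 2, dtype=bool)
            for i in range(n - 2):
                d02 = np.linalg.norm(xyz[i + 2] - xyz[i])
                if STRAND_D02[0] <= d02 <= STRAND_D02[1] and not in_helix[i:i + 3].any():
                    strand_flag[i] = True
            for a, b in _flag_runs(strand_flag):
                span = (b + 2) - a + 1
                if span >= params.min_strand:
                    found.append(SSE("strand", chain.chain_id, seqs[a], seqs[b + 2],
                                     xyz[a:b + 3]))
    if not any_ca:
        raise ValueError("structure has no Calpha atoms; cannot detect SSEs")
    # chain order, then sequence order
    chain_rank = {cid: i for i, cid in enumerate(structure.chain_ids)}
    found.sort(key=lambda s: (chain_rank[s.chain_id], s.start_seq))
    return found


def _flag_runs(flags: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(flags) - 1))
    return runs


def sses_from_assignment(structure: Structure,
                         assignment: dict[str, dict[int, str]],
                         params: SSEParams | None = None) -> list[SSE]:
    """Build SSEs from an external per-residue H/E/C assignment,
    ``assignment[chain_id][seq_num] in "HEC"``."""
    params = params or SSEParams()
    out: list[SSE] = []
    for chain in structure.chains:
        table = assignment.get(chain.chain_id, {})
        cur_kind, cur = None, []
        def flush():
            nonlocal cur_kind, cur
            if cur_kind is not None:
                min_len = params.min_helix if cur_kind == "helix" else params.min_strand
                if len(cur) >= min_len:
                    out.append(SSE(cur_kind, chain.chain_id, cur[0][0], cur[-1][0],
                                   np.array([c for _, c in cur])))
            cur_kind, cur = None, []
        for res in chain.residues:
            ca = res.atom("CA")
            code = table.get(res.seq_num, "C")
            kind = {"H": "helix", "E": "strand"}.get(code)
            if ca is None or kind is None or kind != cur_kind:
                flush()
            if ca is not None and kind is not None:
                cur_kind = kind
                cur.append((res.seq_num, ca.coords))
        flush()
    return out


# ---------------------------------------------------------------------------
# Line vectors

def fit_line_vector(sse: SSE) -> LineVector:
    """Total-least-squares axis of the SSE's Calpha set.

    Direction is the first principal component, signed so that it points
    from the N- to the C-terminal end; origin is the projection of the
    first Calpha onto the axis; length spans the Calpha projections.
    """
    X = np.asarray(sse.ca_coords, dtype=float)
    min_pts = 4 if sse.kind == "helix" else 3
    if len(X) < min_pts:
        raise ValueError(f"{sse.kind} needs >= {min_pts} Calpha coordinates")
    centroid = X.mean(axis=0)
    Xc = X - centroid
    _, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    if S[0] <= 1e-12:
        raise ValueError("degenerate SSE: all Calpha positions identical")
    axis = Vt[0]
    if axis @ (X[-1] - X[0]) < 0:
        axis = -axis
    proj = Xc @ axis
    origin = centroid + proj[0] * axis
    length = float(proj.max() - proj.min())
    if length <= 0:
        raise ValueError("degenerate SSE: zero axial extent")
    return LineVector(origin=origin, direction=axis, length=length, source_sse=sse)


def motif_from_structure(structure: Structure,
                         params: SSEParams | None = None) -> MotifDescriptor:
    """Detect SSEs and reduce each to a line vector, in chain order."""
    vecs = [fit_line_vector(s) for s in detect_sses(structure, params)]
    return MotifDescriptor(vecs, structure_ref=structure.id)


# ---------------------------------------------------------------------------
# Angles and distances

def vector_angle(v1: LineVector, v2: LineVector, signed: bool = False) -> float:
    """Angle between the two segment directions, radians.

    Orientation-insensitive by default (range [0, pi/2]) because a strand's
    N->C sense may flip between homologs; ``signed=True`` respects
    orientation (range [0, pi]).
    """
    c = float(v1.direction @ v2.direction)
    if not signed:
        c = abs(c)
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def segment_min_distance(a0: np.ndarray, a1: np.ndarray,
                         b0: np.ndarray, b1: np.ndarray) -> np.ndarray:
    """Minimum distance between finite segments [a0, a1] and [b0, b1].

    Vectorized over a leading batch dimension; inputs (..., 3).  Standard
    clamped closest-point parametrization.
    """
    a0 = np.asarray(a0, float); a1 = np.asarray(a1, float)
    b0 = np.asarray(b0, float); b1 = np.asarray(b1, float)
    d1 = a1 - a0
    d2 = b1 - b0
    r = a0 - b0
    a = np.sum(d1 * d1, axis=-1)
    e = np.sum(d2 * d2, axis=-1)
    f = np.sum(d2 * r, axis=-1)
    c = np.sum(d1 * r, axis=-1)
    b = np.sum(d1 * d2, axis=-1)
    denom = a * e - b * b
    eps = 1e-14
    s = np.where(denom > eps, np.clip((b * f - c * e) / np.where(denom > eps, denom, 1.0),
                                      0.0, 1.0), 0.0)
    t = np.where(e > eps, (b * s + f) / np.where(e > eps, e, 1.0), 0.0)
    t_cl = np.clip(t, 0.0, 1.0)
    # where t was clamped, recompute s for the clamped t
    s = np.where(np.abs(t - t_cl) > 0,
                 np.clip(np.where(a > eps, (b * t_cl - c) / np.where(a > eps, a, 1.0),
                                  0.0), 0.0, 1.0),
                 s)
    p1 = a0 + s[..., None] * d1
    p2 = b0 + t_cl[..., None] * d2
    return np.linalg.norm(p1 - p2, axis=-1)


def vector_min_distance(v1: LineVector, v2: LineVector) -> float:
    """Minimum Euclidean distance between the two finite segments, A."""
    return float(segment_min_distance(v1.origin, v1.end, v2.origin, v2.end))
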
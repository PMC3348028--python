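"""Deterministic synthetic structures with machine-readable ground truth.

Every generator is a pure function of its parameters and seed, so tests
(and the reproduction script) never need to download template structures:
idealized helices and strands exercise SSE detection, two-domain chains
with planted inter-domain transforms exercise binding-geometry derivation
and linker checks, and pose-decoy sets with planted category labels
exercise the screening filters.

Geometry is pseudo-backbone resolution: Calpha on ideal helical/pleated
frames plus N, C, O placed by fixed internal geometry along the chain
direction (so C(i)-N(i+1) continuity holds) and an optional CB-like
pseudo-side-chain atom to give the structures volume for surface and clash
work.  Loops are Cartesian interpolations with ~3 A spacing — not
stereochemically real; only their anchor distances matter downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import RigidTransform, apply_transform
from .structures import Atom, Chain, Residue, Structure
from .filters import PoseSet
from .sse import HELIX_D13, HELIX_TORSION, STRAND_D02, _virtual_torsion

__all__ = [
    "make_ideal_helix",
    "make_ideal_strand",
    "make_helix_loop_helix",
    "make_domain",
    "make_two_domain_chain",
    "make_pose_decoys",
    "TwoDomainTruth",
]

HELIX_RISE = 1.5       # A per residue
HELIX_TWIST = 100.0    # degrees per residue
HELIX_RADIUS = 2.3     # A
STRAND_STEP = 3.45     # A axial step; with the pleat this gives CA-CA 3.8 A
STRAND_PLEAT = float(np.sqrt(3.8 ** 2 - STRAND_STEP ** 2) / 2)  # ~0.80 A


def _perp(u: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(u @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    w = np.cross(u, ref)
    return w / np.linalg.norm(w)


def _chain_from_ca(ca: np.ndarray, chain_id: str, start_seq: int,
                   res_name: str = "ALA", serial0: int = 1,
                   with_sidechains: bool = False,
                   ca_only: bool = False) -> Chain:
    """Residues with pseudo-backbone atoms built around a Calpha trace."""
    n = len(ca)
    chain = Chain(chain_id)
    serial = serial0
    for i in range(n):
        u_out = ca[min(i + 1, n - 1)] - ca[min(i + 1, n - 1) - 1]
        u_in = ca[max(i, 1)] - ca[max(i, 1) - 1]
        u_out = u_out / np.linalg.norm(u_out)
        u_in = u_in / np.linalg.norm(u_in)
        atoms = []
        if ca_only:
            atoms.append(Atom(serial, "CA", "C", "", ca[i].copy()))
            serial += 1
        else:
            w = _perp(u_out)
            positions = [("N", "N", ca[i] - 1.2 * u_in),
                         ("CA", "C", ca[i].copy()),
                         ("C", "C", ca[i] + 1.2 * u_out),
                         ("O", "O", ca[i] + 1.2 * u_out + 1.23 * w)]
            if with_sidechains:
                positions.append(("CB", "C", ca[i] + 1.53 * w * (-1) ** i))
            for name, elem, xyz in positions:
                atoms.append(Atom(serial, name, elem, "", xyz))
                serial += 1
        chain.residues.append(Residue(chain_id, start_seq + i, "", res_name, atoms))
    return chain


def helix_ca(n_res: int, rise: float = HELIX_RISE, twist: float = HELIX_TWIST,
             radius: float = HELIX_RADIUS) -> np.ndarray:
    """Calpha trace of an ideal helix about the z-axis starting near x+."""
    i = np.arange(n_res)
    t = np.radians(i * twist)
    return np.column_stack([radius * np.cos(t), radius * np.sin(t), i * rise])


def strand_ca(n_res: int, step: float = STRAND_STEP,
              pleat: float | None = None) -> np.ndarray:
    """Calpha trace of an ideal pleated strand along +x: CA-CA 3.8 A,
    CA(i)->CA(i+2) = 2 * step = 6.9 A."""
    if pleat is None:
        pleat = float(np.sqrt(3.8 ** 2 - step ** 2)) / 2.0
    i = np.arange(n_res)
    return np.column_stack([i * step, pleat * (-1.0) ** i, np.zeros(n_res)])


def make_ideal_helix(n_res: int, rise: float = HELIX_RISE,
                     twist: float = HELIX_TWIST, radius: float = HELIX_RADIUS,
                     chain_id: str = "A", with_sidechains: bool = False,
                     ca_only: bool = False) -> Structure:
    if n_res < 4:
        raise ValueError("a helix fixture needs >= 4 residues")
    ca = helix_ca(n_res, rise, twist, radius)
    return Structure(id=f"helix{n_res}",
                     chains=[_chain_from_ca(ca, chain_id, 1,
                                            with_sidechains=with_sidechains,
                                            ca_only=ca_only)])


def make_ideal_strand(n_res: int, chain_id: str = "A",
                      with_sidechains: bool = False,
                      ca_only: bool = False) -> Structure:
    if n_res < 3:
        raise ValueError("a strand fixture needs >= 3 residues")
    ca = strand_ca(n_res)
    return Structure(id=f"strand{n_res}",
                     chains=[_chain_from_ca(ca, chain_id, 1,
                                            with_sidechains=with_sidechains,
                                            ca_only=ca_only)])


def _loop_ca(start: np.ndarray, end: np.ndarray, n_loop: int,
             rng: np.random.Generator, amp: float = 0.9) -> np.ndarray:
    """n_loop interpolated loop Calphas between (exclusive) two anchors,
    jittered both along and perpendicular to the span so they do not mimic
    helix/strand geometry."""
    if n_loop == 0:
        return np.empty((0, 3))
    ts = np.linspace(0.0, 1.0, n_loop + 2)[1:-1]
    ts = ts + rng.uniform(-0.3, 0.3, size=n_loop) / (n_loop + 1)
    base = start[None, :] + np.sort(ts)[:, None] * (end - start)[None, :]
    span = end - start
    w = _perp(span / max(np.linalg.norm(span), 1e-9))
    v = np.cross(span / max(np.linalg.norm(span), 1e-9), w)
    jitter = (amp * rng.uniform(-1, 1, size=(n_loop, 1)) * w[None, :]
              + amp * rng.uniform(-1, 1, size=(n_loop, 1)) * v[None, :])
    return base + jitter


def _window_is_helix(xyz: np.ndarray, i: int) -> bool:
    d13 = float(np.linalg.norm(xyz[i + 3] - xyz[i]))
    if not (HELIX_D13[0] <= d13 <= HELIX_D13[1]):
        return False
    tor = _virtual_torsion(xyz[i], xyz[i + 1], xyz[i + 2], xyz[i + 3])
    return HELIX_TORSION[0] <= tor <= HELIX_TORSION[1]


def _window_is_strand(xyz: np.ndarray, i: int) -> bool:
    d02 = float(np.linalg.norm(xyz[i + 2] - xyz[i]))
    return STRAND_D02[0] <= d02 <= STRAND_D02[1]


def _join_with_loop(before: np.ndarray, after: np.ndarray, n_loop: int,
                    rng: np.random.Generator, max_tries: int = 200) -> np.ndarray:
    """A loop between two segments whose residues can never be absorbed
    into a detected helix or strand: candidate loops are redrawn until no
    detection window touching a loop residue satisfies the helix or strand
    geometric criteria, keeping fixture ground truth exact."""
    for attempt in range(max_tries):
        loop = _loop_ca(before[-1], after[0], n_loop, rng,
                        amp=0.9 + 0.4 * (attempt // 40))
        xyz = np.vstack([before, loop, after])
        lo, hi = len(before), len(before) + n_loop - 1
        ok = True
        for i in range(max(0, lo - 3), min(len(xyz) - 3, hi + 1)):
            if _window_is_helix(xyz, i):
                ok = False
                break
        if ok:
            for i in range(max(0, lo - 2), min(len(xyz) - 2, hi + 1)):
                if _window_is_strand(xyz, i):
                    ok = False
                    break
        if ok:
            return loop
    raise ValueError("could not realize a loop free of SSE-like geometry")


def make_helix_loop_helix(n1: int = 10, n_loop: int = 5, n2: int = 10,
                          seed: int = 0) -> tuple[Structure, dict]:
    """Two helices joined by a randomized loop; ground truth gives the
    residue ranges of the two helices (1-based sequence numbers)."""
    rng = np.random.default_rng(seed)
    ca1 = helix_ca(n1)
    # second helix: tilted 65 deg and displaced from the end of helix one
    tilt = RigidTransform.from_axis_angle(np.array([1.0, 0.3, 0.2]),
                                          np.radians(65.0))
    offset = ca1[-1] + np.array([4.0, 3.0, 3.0 * max(n_loop, 1) * 0.8])
    ca2 = apply_transform(tilt, helix_ca(n2)) + offset
    loop = _join_with_loop(ca1, ca2, n_loop, rng)
    ca = np.vstack([ca1, loop, ca2])
    chain = _chain_from_ca(ca, "A", 1)
    truth = {"helix1": (1, n1), "loop": (n1 + 1, n1 + n_loop),
             "helix2": (n1 + n_loop + 1, n1 + n_loop + n2)}
    return Structure(id="hlh", chains=[chain]), truth


def make_domain(seed: int = 0) -> np.ndarray:
    """Calpha trace of a compact asymmetric domain: helix(12), strand(6),
    helix(9) connected by short jittered loops.  Returned as a bare
    (n, 3) array so callers can place it freely."""
    rng = np.random.default_rng(seed)
    h1 = helix_ca(12)
    s1 = strand_ca(6) @ _rot(np.array([0.0, 1.0, 0.0]), 35.0).T + \
        np.array([7.5, 1.0, 14.0])
    h2 = helix_ca(9) @ _rot(np.array([1.0, 1.0, 0.0]), 105.0).T + \
        np.array([9.0, 8.0, 2.0])
    loop1 = _join_with_loop(h1, s1, 3, rng)
    loop2 = _join_with_loop(s1, h2, 3, rng)
    return np.vstack([h1, loop1, s1, loop2, h2])


def _rot(axis: np.ndarray, degrees: float) -> np.ndarray:
    return RigidTransform.from_axis_angle(axis, np.radians(degrees)).rotation


@dataclass
class TwoDomainTruth:
    planted_transform: RigidTransform
    anchor_distance: float             # A, C(last of A) to N(first of B)
    domain_a_range: tuple[int, int]    # seq numbers, inclusive
    loop_range: tuple[int, int]
    domain_b_range: tuple[int, int]
    construction_warning: bool = False


def make_two_domain_chain(n_loop: int = 4,
                          planted_transform: RigidTransform | None = None,
                          seed: int = 0,
                          with_sidechains: bool = False
                          ) -> tuple[Structure, TwoDomainTruth]:
    """One chain of two copies of the standard domain, domain B placed by
    ``planted_transform`` (applied to domain A's coordinates), joined by an
    ``n_loop``-residue loop.

    The default planted transform keeps the anchors a realistic ~10 A
    apart.  A transform stretching the anchors beyond n_loop x 3.6 A sets
    ``construction_warning`` on the returned ground truth.
    """
    if planted_transform is None:
        planted_transform = RigidTransform.from_axis_angle(
            np.array([0.2, 1.0, 0.4]), np.radians(150.0),
            center=np.zeros(3), translation=np.array([16.0, 3.0, 9.0]))
    rng = np.random.default_rng(seed)
    ca_a = make_domain(seed=seed)
    ca_b = apply_transform(planted_transform, ca_a)
    n_dom = len(ca_a)
    loop = _join_with_loop(ca_a, ca_b, n_loop, rng)
    ca = np.vstack([ca_a, loop, ca_b])
    chain = _chain_from_ca(ca, "A", 1, with_sidechains=with_sidechains)
    # anchors: C of the last domain-A residue, N of the first domain-B residue
    c_atom = chain.residues[n_dom - 1].atom("C")
    n_atom = chain.residues[n_dom + n_loop].atom("N")
    anchor_distance = float(np.linalg.norm(c_atom.coords - n_atom.coords))
    warning = anchor_distance > n_loop * 3.6
    truth = TwoDomainTruth(planted_transform=planted_transform,
                           anchor_distance=anchor_distance,
                           domain_a_range=(1, n_dom),
                           loop_range=(n_dom + 1, n_dom + n_loop),
                           domain_b_range=(n_dom + n_loop + 1,
                                           n_dom + n_loop + n_dom),
                           construction_warning=warning)
    return Structure(id="two_domain", chains=[chain]), truth


def make_two_domain_with_anchor_distance(target: float, n_loop: int = 4,
                                         seed: int = 0,
                                         direction=(1.0, 0.0, 0.0),
                                         tol: float = 0.01
                                         ) -> tuple[Structure, TwoDomainTruth]:
    """Two-domain chain whose C/N anchor-atom distance equals ``target`` A.

    The backbone anchor positions depend on the loop path, so the planted
    translation is adjusted by fixed-point iteration until the realized
    anchor distance matches the target.
    """
    u = np.asarray(direction, float)
    u = u / np.linalg.norm(u)
    ca = make_domain(seed)
    chain0 = _chain_from_ca(ca, "A", 1)
    c_anchor = chain0.residues[-1].atom("C").coords
    n_anchor0 = chain0.residues[0].atom("N").coords
    # coarse: the realized anchor distance tracks the planted offset with a
    # roughly constant backbone correction, but jumps with the resampled loop
    offset = target
    best = None
    for _ in range(12):
        t = c_anchor + offset * u - n_anchor0
        s, truth = make_two_domain_chain(
            n_loop=n_loop, seed=seed,
            planted_transform=RigidTransform(np.eye(3), t))
        err = truth.anchor_distance - target
        if best is None or abs(err) < abs(best[0]):
            best = (err, s, truth, t)
        if abs(err) < tol:
            break
        offset -= 0.8 * err
    err, s, truth, t = best
    if abs(err) > tol:
        # fine: rigidly translate domain B along the planted direction so the
        # anchor gap hits the target exactly; the loop stays frozen
        b_lo, b_hi = truth.domain_b_range
        chain = s.chains[0]
        c_pos = chain.residues[truth.domain_a_range[1] - 1].atom("C").coords
        n_pos = chain.residues[b_lo - 1].atom("N").coords
        v = n_pos - c_pos
        # |v + lam*u| = target  ->  quadratic in lam; take the root of least
        # magnitude
        b_ = 2.0 * float(v @ u)
        c_ = float(v @ v) - target ** 2
        disc = b_ ** 2 - 4.0 * c_
        if disc < 0:
            raise ValueError(f"could not realize anchor distance {target} A")
        roots = [(-b_ + np.sqrt(disc)) / 2.0, (-b_ - np.sqrt(disc)) / 2.0]
        lam = min(roots, key=abs)
        shift = lam * u
        for res in chain.residues[b_lo - 1:b_hi]:
            for a in res.atoms:
                a.coords = a.coords + shift
        truth = TwoDomainTruth(
            planted_transform=RigidTransform(np.eye(3), t + shift),
            anchor_distance=float(np.linalg.norm(
                c_pos - chain.residues[b_lo - 1].atom("N").coords)),
            domain_a_range=truth.domain_a_range,
            loop_range=truth.loop_range,
            domain_b_range=truth.domain_b_range,
            construction_warning=target > n_loop * 3.6)
    return s, truth


def domain_structures(seed: int = 0, with_sidechains: bool = True
                      ) -> tuple[Structure, Structure, TwoDomainTruth]:
    """The two domains of :func:`make_two_domain_chain` as separate
    structures (chains A and B) in their native relative placement."""
    full, truth = make_two_domain_chain(seed=seed, with_sidechains=with_sidechains)
    from .structures import select
    a = select(full, residue_range=truth.domain_a_range)
    b_full = select(full, residue_range=truth.domain_b_range)
    b = Structure(id="domainB")
    bc = Chain("B")
    for i, res in enumerate(b_full.chains[0].residues, start=1):
        r = res.copy()
        r.chain_id = "B"
        r.seq_num = i
        bc.residues.append(r)
    b.chains = [bc]
    a.id = "domainA"
    return a, b, truth


# ---------------------------------------------------------------------------
# Pose decoys

def make_pose_decoys(fixed: Structure, mobile: Structure,
                     anchor_fixed: np.ndarray, anchor_mobile: np.ndarray,
                     n_poses: int = 100,
                     frac_linker_ok: float = 0.4,
                     frac_clash: float = 0.2,
                     linker_cutoff: float = 14.0,
                     clash_margin: float = 3.2,
                     seed: int = 0) -> tuple[PoseSet, pd.DataFrame]:
    """Pose set with planted category labels, in the requested fractions.

    Categories are disjoint (fractions must sum to <= 1):

    * ``frac_linker_ok`` — anchor distance <= 0.9 x cutoff and no atom of
      the placed mobile within ``clash_margin`` of the fixed component;
    * ``frac_clash``    — one mobile atom placed exactly onto a fixed atom
      (guaranteed clash) with the mobile anchor pointing away so the
      anchor distance exceeds the cutoff;
    * remainder         — clean placements beyond the cutoff.

    Returns the pose set and a truth table (pose, linker_ok, clashing).
    """
    if not (0 <= frac_linker_ok <= 1 and 0 <= frac_clash <= 1
            and frac_linker_ok + frac_clash <= 1):
        raise ValueError("fractions must lie in [0, 1] and sum to <= 1")
    rng = np.random.default_rng(seed)
    n_ok = round(n_poses * frac_linker_ok)
    n_clash = round(n_poses * frac_clash)
    anchor_f = np.asarray(anchor_fixed, float)
    anchor_m = np.asarray(anchor_mobile, float)
    xyz_f = fixed.coords(heavy_only=True)
    xyz_m = mobile.coords(heavy_only=True)
    centroid_f = xyz_f.mean(axis=0)
    out_dir = anchor_f - centroid_f
    if np.linalg.norm(out_dir) < 1e-9:
        out_dir = np.array([1.0, 0.0, 0.0])
    out_dir = out_dir / np.linalg.norm(out_dir)
    # the fixed atom farthest from the linker anchor, used for clash poses
    far_idx = int(np.argmax(np.linalg.norm(xyz_f - anchor_f, axis=1)))
    far_atom = xyz_f[far_idx]
    mobile_reach = float(np.max(np.linalg.norm(xyz_m - anchor_m, axis=1)))
    if np.linalg.norm(far_atom - anchor_f) + mobile_reach <= linker_cutoff:
        raise ValueError("components too small to realize clashing yet "
                         "linker-infeasible poses")

    def random_rotation() -> np.ndarray:
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        return _rot(v, float(rng.uniform(0.0, 180.0)))

    def clean_pose(dist_range: tuple[float, float]) -> RigidTransform:
        for _ in range(200):
            R = random_rotation()
            d = float(rng.uniform(*dist_range))
            t = anchor_f + d * out_dir - R @ anchor_m
            placed = xyz_m @ R.T + t
            dmin = np.min(np.linalg.norm(placed[:, None, :] - xyz_f[None, :, :],
                                         axis=2))
            if dmin >= clash_margin:
                return RigidTransform(R, t)
        raise ValueError("could not realize a clash-free pose; "
                         "components too crowded")

    def clash_pose() -> RigidTransform:
        d = far_atom - anchor_f
        d = d / np.linalg.norm(d)
        # align the mobile's anchor->far axis with d, far end onto far_atom
        m_far = xyz_m[int(np.argmax(np.linalg.norm(xyz_m - anchor_m, axis=1)))]
        axis_m = m_far - anchor_m
        axis_m = axis_m / np.linalg.norm(axis_m)
        R = _align_rotation(-axis_m, d)
        spin = _rot(d, float(rng.uniform(0.0, 360.0)))
        R = spin @ R
        t = far_atom - R @ m_far
        anchor_d = float(np.linalg.norm(anchor_f - (R @ anchor_m + t)))
        if anchor_d <= linker_cutoff:
            raise ValueError("clash pose fails to exceed the linker cutoff")
        return RigidTransform(R, t)

    labels = (["ok"] * n_ok + ["clash"] * n_clash
              + ["far"] * (n_poses - n_ok - n_clash))
    poses, rows = [], []
    for k, lab in enumerate(labels):
        if lab == "ok":
            tr = clean_pose((5.0, 0.9 * linker_cutoff))
        elif lab == "clash":
            tr = clash_pose()
        else:
            tr = clean_pose((1.15 * linker_cutoff, 2.0 * linker_cutoff))
        poses.append(tr)
        rows.append({"pose": k, "linker_ok": lab == "ok",
                     "clashing": lab == "clash"})
    return PoseSet(poses, source=f"decoys(seed={seed})"), pd.DataFrame(rows)


def _align_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a to unit vector b."""
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        w = _perp(a)
        return _rot(w, 180.0)
    s = np.linalg.norm(v)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K * ((1 - c) / s ** 2)
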
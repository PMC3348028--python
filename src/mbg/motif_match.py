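"""Motif structural matching by Metropolis Monte Carlo.

Two motifs (ordered sets of SSE line vectors) are aligned by finding the
rigid transform of motif B that minimizes, over the corresponding vector
pairs, a weighted sum of squared inter-vector angles theta_i and squared
minimum segment distances d_i:

    score = sum_i [ w_theta * theta_i^2  +  w_d * d_i^2 ]

The minimization is a Metropolis Monte Carlo walk in SE(3): random
axis-angle rotation proposals about the moving motif's centroid, optionally
combined with small translations, accepted with probability
min(1, exp(-delta/T)) under a geometrically decaying temperature.  The
best-so-far transform is tracked separately from the current state, and
multiple deterministic restarts guard against local minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import RigidTransform, compose
from .sse import LineVector, MotifDescriptor, segment_min_distance

__all__ = [
    "Correspondence",
    "MatchScore",
    "MCParams",
    "MinimizeResult",
    "CorrespondenceEnumeration",
    "match_score",
    "metropolis_minimize",
    "enumerate_correspondences",
]


@dataclass(frozen=True)
class Correspondence:
    """Ordered pairing (index into motif A, index into motif B)."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple((int(a), int(b)) for a, b in self.pairs))
        a_idx = [p[0] for p in self.pairs]
        b_idx = [p[1] for p in self.pairs]
        if len(set(a_idx)) != len(a_idx) or len(set(b_idx)) != len(b_idx):
            raise ValueError("correspondence repeats an index")

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def identity(cls, n: int) -> "Correspondence":
        return cls(tuple((i, i) for i in range(n)))

    def validate(self, motif_a: MotifDescriptor, motif_b: MotifDescriptor) -> None:
        for a, b in self.pairs:
            if not (0 <= a < len(motif_a)) or not (0 <= b < len(motif_b)):
                raise IndexError(f"pair ({a}, {b}) out of range")


@dataclass(frozen=True)
class MatchScore:
    thetas: tuple[float, ...]   # radians, per pair
    dists: tuple[float, ...]    # A, per pair
    score: float                # w_theta * sum(theta^2) + w_d * sum(d^2)

    @property
    def n_pairs(self) -> int:
        return len(self.thetas)


@dataclass(frozen=True)
class MCParams:
    """Metropolis Monte Carlo settings.

    Defaults: 10,000 steps with geometric temperature decay 1.0 -> 1e-4,
    rotation proposals uniform in [0, 5 deg] about a random axis through the
    moving motif's centroid, translations uniform in a 0.5 A ball (half of
    the proposals are rotation-only), both scaled by sqrt(T/T0) down to a
    floor of 0.02 so late-stage moves match the width of the basin being
    refined; weights w_theta = 1 rad^-2 and w_d = 0.1 A^-2 (10 deg of angle
    ~ 0.55 A of distance in score currency); 8 deterministic restarts
    derived from the master seed.
    """

    w_theta: float = 1.0            # rad^-2
    w_d: float = 0.1                # A^-2
    n_steps: int = 10_000
    t_initial: float = 1.0
    t_final: float = 1e-4
    decay: str = "geometric"        # or "linear"
    max_rotation_step: float = 5.0  # degrees
    max_translation_step: float = 0.5  # A
    rotation_only_fraction: float = 0.5
    step_scale_floor: float = 0.02  # proposal sizes shrink with T down to this
    pivot_spread: float | None = None  # A; default = extent of the fixed motif
    quench_fraction: float = 0.25  # extra greedy steps from the best state
    n_starts: int = 8
    start_rotation_max: float = 180.0  # degrees, random restarts
    start_translation_max: float = 10.0  # A
    seed: int = 0
    signed_angles: bool = False
    dof: str = "full"               # "full" or "planar" (z-rotation + xy-translation)

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.w_theta <= 0 or self.w_d <= 0:
            raise ValueError("weights must be positive")
        if self.t_initial < 0 or self.t_final < 0:
            raise ValueError("temperatures must be >= 0")
        if self.dof not in ("full", "planar"):
            raise ValueError("dof must be 'full' or 'planar'")

    def temperatures(self) -> np.ndarray:
        n = self.n_steps
        if n == 1:
            return np.array([self.t_initial])
        if self.decay == "geometric":
            t0 = max(self.t_initial, 1e-300)
            tf = max(self.t_final, 1e-300)
            return t0 * (tf / t0) ** (np.arange(n) / (n - 1))
        return np.linspace(self.t_initial, self.t_final, n)


@dataclass
class MinimizeResult:
    transform: RigidTransform
    score: MatchScore
    trace: list[tuple[int, str, bool, float]]   # (step, proposal kind, accepted, current score)

    def __iter__(self):
        return iter((self.transform, self.score, self.trace))


# ---------------------------------------------------------------------------
# Scoring

def _pair_arrays(motif_a: MotifDescriptor, motif_b: MotifDescriptor,
                 corr: Correspondence):
    sa, ea = motif_a.endpoints()
    sb, eb = motif_b.endpoints()
    ia = [p[0] for p in corr.pairs]
    ib = [p[1] for p in corr.pairs]
    return sa[ia], ea[ia], sb[ib], eb[ib]


def _score_endpoints(a0, a1, b0, b1, w_theta, w_d, signed):
    da = a1 - a0
    db = b1 - b0
    ua = da / np.linalg.norm(da, axis=-1, keepdims=True)
    ub = db / np.linalg.norm(db, axis=-1, keepdims=True)
    cosv = np.sum(ua * ub, axis=-1)
    if not signed:
        cosv = np.abs(cosv)
    thetas = np.arccos(np.clip(cosv, -1.0, 1.0))
    dists = segment_min_distance(a0, a1, b0, b1)
    score = float(w_theta * np.sum(thetas ** 2) + w_d * np.sum(dists ** 2))
    return thetas, dists, score


def match_score(motif_a: MotifDescriptor, motif_b: MotifDescriptor,
                correspondence: Correspondence,
                w_theta: float = 1.0, w_d: float = 0.1,
                signed: bool = False) -> MatchScore:
    """Score the current placement of motif B against motif A over the
    given correspondence (no optimization)."""
    if len(correspondence) == 0:
        raise ValueError("empty correspondence")
    correspondence.validate(motif_a, motif_b)
    a0, a1, b0, b1 = _pair_arrays(motif_a, motif_b, correspondence)
    thetas, dists, score = _score_endpoints(a0, a1, b0, b1, w_theta, w_d, signed)
    return MatchScore(tuple(thetas), tuple(dists), score)


# ---------------------------------------------------------------------------
# Metropolis Monte Carlo minimization

def _rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    k = axis
    K = np.array([[0.0, -k[2], k[1]], [k[2], 0.0, -k[0]], [-k[1], k[0], 0.0]])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def _random_axis(rng: np.random.Generator, planar: bool) -> np.ndarray:
    if planar:
        return np.array([0.0, 0.0, 1.0])
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _random_ball(rng: np.random.Generator, radius: float, planar: bool) -> np.ndarray:
    while True:
        v = rng.uniform(-1.0, 1.0, size=3)
        if planar:
            v[2] = 0.0
        if v @ v <= 1.0:
            return v * radius


def metropolis_minimize(motif_a: MotifDescriptor, motif_b: MotifDescriptor,
                        correspondence: Correspondence,
                        mc_params: MCParams | None = None) -> MinimizeResult:
    """Find the rigid transform of motif B minimizing the match score.

    Runs ``n_starts`` independent Metropolis chains (start 0 from the
    identity, the rest from random placements), all seeded deterministically
    from ``mc_params.seed``; returns the best transform found, its score,
    and the trace of the best start.  Identical seeds give bit-identical
    results.
    """
    p = mc_params or MCParams()
    if len(correspondence) == 0:
        raise ValueError("empty correspondence")
    correspondence.validate(motif_a, motif_b)
    a0, a1, b0_0, b1_0 = _pair_arrays(motif_a, motif_b, correspondence)
    temps = p.temperatures()
    # annealed proposal sizes: shrink with temperature for fine refinement
    # square-root link: proposal size tracks the width of a quadratic basin
    # equilibrated at temperature T
    if p.t_initial > 0:
        scales = np.clip(np.sqrt(temps / p.t_initial), p.step_scale_floor, 1.0)
    else:
        scales = np.full(p.n_steps, p.step_scale_floor)
    planar = p.dof == "planar"
    if p.pivot_spread is not None:
        pivot_spread = p.pivot_spread
    else:
        ca = np.vstack([a0, a1])
        pivot_spread = float(np.max(np.linalg.norm(ca - ca.mean(axis=0), axis=1)))
    ss = np.random.SeedSequence(p.seed)
    child_seeds = ss.spawn(max(p.n_starts, 1))

    best_overall: tuple[float, np.ndarray, np.ndarray] | None = None
    best_trace: list[tuple[int, str, bool, float]] = []

    for start in range(max(p.n_starts, 1)):
        rng = np.random.default_rng(child_seeds[start])
        centroid0 = 0.5 * (b0_0.mean(axis=0) + b1_0.mean(axis=0))
        if start == 0:
            R = np.eye(3)
            t = np.zeros(3)
        else:
            axis = _random_axis(rng, planar)
            angle = rng.uniform(0.0, np.radians(p.start_rotation_max))
            R = _rodrigues(axis, angle)
            # rotate about the motif centroid, then shift
            t = centroid0 - R @ centroid0 + _random_ball(
                rng, p.start_translation_max, planar)
        b0 = b0_0 @ R.T + t
        b1 = b1_0 @ R.T + t
        _, _, cur = _score_endpoints(a0, a1, b0, b1, p.w_theta, p.w_d, p.signed_angles)
        best = (cur, R.copy(), t.copy())
        trace: list[tuple[int, str, bool, float]] = []
        max_rot = np.radians(p.max_rotation_step)

        for step in range(p.n_steps):
            rot_only = rng.random() < p.rotation_only_fraction
            axis = _random_axis(rng, planar)
            angle = rng.uniform(0.0, max_rot * scales[step])
            dR = _rodrigues(axis, angle)
            # pivot diversity: half the rotations turn about the moving
            # motif's centroid, half about a displaced pivot, so rotations
            # about distant axes stay reachable as the steps anneal
            c = 0.5 * (b0.mean(axis=0) + b1.mean(axis=0))
            if rng.random() < 0.5:
                c = c + _random_ball(rng, pivot_spread, planar)
            dt = np.zeros(3) if rot_only else _random_ball(
                rng, p.max_translation_step * scales[step], planar)
            nb0 = (b0 - c) @ dR.T + c + dt
            nb1 = (b1 - c) @ dR.T + c + dt
            _, _, prop = _score_endpoints(a0, a1, nb0, nb1,
                                          p.w_theta, p.w_d, p.signed_angles)
            delta = prop - cur
            T = temps[step]
            if delta <= 0:
                accept = True
            elif T > 0:
                accept = rng.random() < np.exp(-delta / T)
            else:
                accept = False
            if accept:
                b0, b1, cur = nb0, nb1, prop
                # update the composed transform: x -> dR (R x + t - c) + c + dt
                t = dR @ (t - c) + c + dt
                R = dR @ R
                if cur < best[0]:
                    best = (cur, R.copy(), t.copy())
            trace.append((step, "rot" if rot_only else "rot+trans", accept, cur))

        # greedy quench: polish the best basin found during annealing
        n_quench = int(p.quench_fraction * p.n_steps)
        if n_quench > 0:
            cur, R, t = best[0], best[1].copy(), best[2].copy()
            b0 = b0_0 @ R.T + t
            b1 = b1_0 @ R.T + t
            qs = 0.3 * (p.step_scale_floor / 3.0 / 0.3) ** (
                np.arange(n_quench) / max(n_quench - 1, 1))
            for qstep in range(n_quench):
                rot_only = rng.random() < p.rotation_only_fraction
                axis = _random_axis(rng, planar)
                dR = _rodrigues(axis, rng.uniform(0.0, max_rot * qs[qstep]))
                c = 0.5 * (b0.mean(axis=0) + b1.mean(axis=0))
                if rng.random() < 0.5:
                    c = c + _random_ball(rng, pivot_spread, planar)
                dt = np.zeros(3) if rot_only else _random_ball(
                    rng, p.max_translation_step * qs[qstep], planar)
                nb0 = (b0 - c) @ dR.T + c + dt
                nb1 = (b1 - c) @ dR.T + c + dt
                _, _, prop = _score_endpoints(a0, a1, nb0, nb1,
                                              p.w_theta, p.w_d, p.signed_angles)
                if prop <= cur:
                    b0, b1, cur = nb0, nb1, prop
                    t = dR @ (t - c) + c + dt
                    R = dR @ R
                    if cur < best[0]:
                        best = (cur, R.copy(), t.copy())
                trace.append((p.n_steps + qstep, "quench", prop <= cur, cur))

        if best_overall is None or best[0] < best_overall[0]:
            best_overall = best
            best_trace = trace

    assert best_overall is not None
    _, Rb, tb = best_overall
    # re-orthonormalize against accumulated floating-point drift
    U, _, Vt = np.linalg.svd(Rb)
    Rb = U @ np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))]) @ Vt
    transform = RigidTransform(Rb, tb)
    final = match_score(motif_a, motif_b.transformed(transform), correspondence,
                        p.w_theta, p.w_d, p.signed_angles)
    return MinimizeResult(transform, final, best_trace)


# ---------------------------------------------------------------------------
# Correspondence enumeration

@dataclass
class CorrespondenceEnumeration:
    correspondences: list[Correspondence]
    truncated: bool = False

    def __iter__(self):
        return iter(self.correspondences)

    def __len__(self) -> int:
        return len(self.correspondences)


def enumerate_correspondences(motif_a: MotifDescriptor, motif_b: MotifDescriptor,
                              max_results: int = 10_000,
                              min_pairs: int = 1) -> CorrespondenceEnumeration:
    """All order-preserving injective kind-compatible pairings of the two
    motifs with at least ``min_pairs`` pairs, in lexicographic order of
    their pair tuples, capped at ``max_results`` (sets ``truncated``)."""
    if len(motif_a) == 0 or len(motif_b) == 0:
        raise ValueError("both motifs must be non-empty")
    kinds_a = [v.kind for v in motif_a.vectors]
    kinds_b = [v.kind for v in motif_b.vectors]
    results: list[tuple[tuple[int, int], ...]] = []

    def compatible(i: int, j: int) -> bool:
        return kinds_a[i] is None or kinds_b[j] is None or kinds_a[i] == kinds_b[j]

    def extend(prefix: list[tuple[int, int]], next_a: int, next_b: int) -> None:
        if len(prefix) >= min_pairs:
            results.append(tuple(prefix))
        for i in range(next_a, len(kinds_a)):
            for j in range(next_b, len(kinds_b)):
                if compatible(i, j):
                    prefix.append((i, j))
                    extend(prefix, i + 1, j + 1)
                    prefix.pop()

    extend([], 0, 0)
    results.sort()
    truncated = len(results) > max_results
    return CorrespondenceEnumeration(
        [Correspondence(r) for r in results[:max_results]], truncated)
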
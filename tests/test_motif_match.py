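"""Match scoring, Metropolis minimization, and correspondence enumeration."""

import itertools

import numpy as np
import pytest

from mbg.geometry import RigidTransform, compose
from mbg.motif_match import (Correspondence, MCParams, enumerate_correspondences,
                             match_score, metropolis_minimize)
from mbg.sse import LineVector, MotifDescriptor, SSE

from conftest import random_rigid_transform


def vec(p0, p1, kind=None):
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    d = p1 - p0
    sse = None
    if kind is not None:
        sse = SSE(kind, "A", 1, 5, np.linspace(p0, p1, 5))
    return LineVector(p0, d / np.linalg.norm(d), float(np.linalg.norm(d)), sse)


def toy_motif(kinds=("helix", "helix", "strand")):
    segs = [((0, 0, 0), (0, 0, 12)), ((8, 1, 2), (8, 9, 4)), ((2, 8, 10), (10, 8, 2))]
    return MotifDescriptor([vec(a, b, k) for (a, b), k in zip(segs, kinds)], "toy")


def independent_score(motif_a, motif_b, corr, w_theta=1.0, w_d=0.1):
    """Re-derivation from raw endpoints: angles via arccos, distances via
    the critical-point/endpoint candidate method (independent of the
    clamped-parametrization implementation)."""

    def point_seg(p, a, b):
        ab = b - a
        t = np.clip((p - a) @ ab / (ab @ ab), 0, 1)
        return np.linalg.norm(p - (a + t * ab))

    def seg_seg(a0, a1, b0, b1):
        d1, d2, r = a1 - a0, b1 - b0, b0 - a0
        A = np.array([[d1 @ d1, -(d1 @ d2)], [d1 @ d2, -(d2 @ d2)]])
        rhs = np.array([d1 @ r, d2 @ r])
        cands = []
        det = np.linalg.det(A)
        if abs(det) > 1e-12:
            s, t = np.linalg.solve(A, rhs)
            if 0 <= s <= 1 and 0 <= t <= 1:
                cands.append(np.linalg.norm((a0 + s * d1) - (b0 + t * d2)))
        cands += [point_seg(a0, b0, b1), point_seg(a1, b0, b1),
                  point_seg(b0, a0, a1), point_seg(b1, a0, a1)]
        return min(cands)

    total = 0.0
    for ia, ib in corr.pairs:
        va, vb = motif_a.vectors[ia], motif_b.vectors[ib]
        cos = abs(float(va.direction @ vb.direction))
        theta = np.arccos(min(cos, 1.0))
        d = seg_seg(va.origin, va.end, vb.origin, vb.end)
        total += w_theta * theta ** 2 + w_d * d ** 2
    return total


class TestMatchScore:
    def test_self_match_is_zero(self):
        m = toy_motif()
        s = match_score(m, m, Correspondence.identity(3))
        assert s.score == pytest.approx(0.0, abs=1e-12)
        assert all(t == pytest.approx(0.0, abs=1e-6) for t in s.thetas)
        assert all(d == pytest.approx(0.0, abs=1e-9) for d in s.dists)

    def test_single_pair_quarter_turn(self):
        a = MotifDescriptor([vec((0, 0, -5), (0, 0, 5))])
        b = MotifDescriptor([vec((-5, 0, 0), (5, 0, 0))])  # 90 deg, same midpoint
        s = match_score(a, b, Correspondence.identity(1), w_theta=1.0)
        assert s.thetas[0] == pytest.approx(np.pi / 2)
        assert s.dists[0] == pytest.approx(0.0, abs=1e-12)
        assert s.score == pytest.approx((np.pi / 2) ** 2)

    def test_matches_independent_recomputation(self, rng):
        for _ in range(10):
            pts = rng.uniform(-10, 10, size=(6, 2, 3))
            ma = MotifDescriptor([vec(p[0], p[1]) for p in pts[:3]])
            mb = MotifDescriptor([vec(p[0], p[1]) for p in pts[3:]])
            corr = Correspondence.identity(3)
            s = match_score(ma, mb, corr)
            assert s.score == pytest.approx(
                independent_score(ma, mb, corr), abs=1e-9)

    def test_invariant_under_common_transform(self, rng):
        ma, mb = toy_motif(), toy_motif()
        mb = mb.transformed(random_rigid_transform(rng))
        corr = Correspondence.identity(3)
        base = match_score(ma, mb, corr).score
        g = random_rigid_transform(rng)
        moved = match_score(ma.transformed(g), mb.transformed(g), corr).score
        assert moved == pytest.approx(base, abs=1e-9)

    def test_empty_correspondence(self):
        with pytest.raises(ValueError):
            match_score(toy_motif(), toy_motif(), Correspondence(()))


class TestMetropolisMinimize:
    def test_self_match_from_identity(self):
        m = toy_motif()
        res = metropolis_minimize(m, m, Correspondence.identity(3),
                                  MCParams(seed=0, n_steps=300, n_starts=1))
        assert res.score.score == pytest.approx(0.0, abs=1e-12)
        assert res.transform.is_identity(tol=1e-9)

    def test_planted_transform_recovery_single_seed(self, domain_motif, rng):
        ctr = np.mean([v.origin for v in domain_motif.vectors], axis=0)
        planted = RigidTransform.from_axis_angle(
            rng.normal(size=3), np.radians(25.0), center=ctr,
            translation=rng.normal(size=3) * 4 / np.sqrt(3))
        moved = domain_motif.transformed(planted)
        res = metropolis_minimize(domain_motif, moved, Correspondence.identity(3),
                                  MCParams(seed=7, n_steps=20_000, n_starts=2))
        rel = compose(res.transform, planted)
        assert np.degrees(rel.rotation_angle()) <= 1.0
        assert res.score.score <= 1e-3

    def test_planar_minimum_matches_grid_oracle(self):
        a = MotifDescriptor([vec((0, 0, 0), (10, 0, 0)), vec((0, 4, 0), (0, 4, 10))])
        planted = RigidTransform.from_axis_angle(
            np.array([0, 0, 1.0]), np.radians(-9.0),
            translation=np.array([0.45, -0.35, 0.0]))
        b = a.transformed(planted)
        res = metropolis_minimize(a, b, Correspondence.identity(2),
                                  MCParams(seed=3, n_steps=8000, n_starts=6,
                                           dof="planar"))
        # exhaustive grid: 1 deg x 0.1 A over z-rotation + xy-translation
        b0, b1 = b.endpoints()
        best_grid = np.inf
        grid_scores = {}
        for deg in range(-30, 31):
            R = RigidTransform.from_axis_angle(np.array([0, 0, 1.0]),
                                               np.radians(deg)).rotation
            for tx in np.arange(-1.0, 1.01, 0.1):
                for ty in np.arange(-1.0, 1.01, 0.1):
                    t = np.array([tx, ty, 0.0])
                    moved = MotifDescriptor([
                        LineVector(R @ v.origin + t, R @ v.direction, v.length)
                        for v in b.vectors])
                    s = match_score(a, moved, Correspondence.identity(2)).score
                    grid_scores[(deg, round(tx, 1), round(ty, 1))] = s
                    best_grid = min(best_grid, s)
        # one grid cell's worth of score variation around the grid optimum
        kmin = min(grid_scores, key=grid_scores.get)
        neigh = [grid_scores.get((kmin[0] + dd, round(kmin[1] + dx, 1),
                                  round(kmin[2] + dy, 1)), best_grid)
                 for dd in (-1, 0, 1) for dx in (-0.1, 0, 0.1)
                 for dy in (-0.1, 0, 0.1)]
        cell_variation = max(neigh) - best_grid
        assert res.score.score <= best_grid + cell_variation + 1e-12

    def test_best_so_far_never_above_trace(self, domain_motif):
        moved = domain_motif.transformed(
            RigidTransform.from_axis_angle(np.array([1.0, 1, 0]), 0.3,
                                           translation=np.array([2.0, 0, 1])))
        res = metropolis_minimize(domain_motif, moved, Correspondence.identity(3),
                                  MCParams(seed=5, n_steps=2000, n_starts=1))
        assert res.score.score <= min(s for *_, s in res.trace) + 1e-12

    def test_zero_temperature_is_greedy(self, domain_motif):
        moved = domain_motif.transformed(
            RigidTransform.from_axis_angle(np.array([0, 1.0, 0]), 0.2))
        res = metropolis_minimize(domain_motif, moved, Correspondence.identity(3),
                                  MCParams(seed=2, n_steps=1500, n_starts=1,
                                           t_initial=0.0, t_final=0.0))
        cur = None
        for _, _, accepted, score in res.trace:
            if accepted and cur is not None:
                assert score <= cur + 1e-15
            cur = score

    def test_seed_reproducibility(self, domain_motif):
        moved = domain_motif.transformed(
            RigidTransform.from_axis_angle(np.array([1.0, 0, 0]), 0.4))
        p = MCParams(seed=11, n_steps=500, n_starts=2)
        r1 = metropolis_minimize(domain_motif, moved, Correspondence.identity(3), p)
        r2 = metropolis_minimize(domain_motif, moved, Correspondence.identity(3), p)
        assert r1.score.score == r2.score.score
        np.testing.assert_array_equal(r1.transform.rotation, r2.transform.rotation)
        np.testing.assert_array_equal(r1.transform.translation,
                                      r2.transform.translation)


def brute_force_correspondences(kinds_a, kinds_b, min_pairs):
    """Oracle: filter all index pair subsets."""
    out = set()
    pairs = [(i, j) for i in range(len(kinds_a)) for j in range(len(kinds_b))
             if kinds_a[i] == kinds_b[j]]
    for k in range(min_pairs, min(len(kinds_a), len(kinds_b)) + 1):
        for combo in itertools.combinations(pairs, k):
            a_idx = [p[0] for p in combo]
            b_idx = [p[1] for p in combo]
            if (sorted(a_idx) == a_idx and sorted(b_idx) == b_idx
                    and len(set(a_idx)) == k and len(set(b_idx)) == k):
                out.add(combo)
    return out


class TestEnumerateCorrespondences:
    def test_two_helix_motifs_give_five(self):
        a = toy_motif(("helix", "helix"))
        a = MotifDescriptor(a.vectors[:2])
        enum = enumerate_correspondences(a, a, min_pairs=1)
        assert len(enum) == 5
        assert not enum.truncated

    def test_kind_incompatible_motifs(self):
        helices = MotifDescriptor(toy_motif(("helix", "helix", "helix")).vectors)
        strands = MotifDescriptor(toy_motif(("strand", "strand", "strand")).vectors)
        assert len(enumerate_correspondences(helices, strands)) == 0

    def test_full_correspondence_unique(self):
        m = toy_motif()
        enum = enumerate_correspondences(m, m, min_pairs=3)
        assert [c.pairs for c in enum] == [((0, 0), (1, 1), (2, 2))]

    def test_matches_brute_force_oracle(self):
        kinds_a = ("helix", "strand", "helix", "strand")
        kinds_b = ("helix", "helix", "strand")
        a = MotifDescriptor([vec((i, 0, 0), (i, 0, 9), k)
                             for i, k in enumerate(kinds_a)])
        b = MotifDescriptor([vec((i, 3, 0), (i, 3, 9), k)
                             for i, k in enumerate(kinds_b)])
        enum = enumerate_correspondences(a, b, min_pairs=1)
        assert {c.pairs for c in enum} == brute_force_correspondences(
            kinds_a, kinds_b, 1)

    def test_truncation_flag(self):
        m = toy_motif(("helix",) * 3)
        enum = enumerate_correspondences(m, m, max_results=2, min_pairs=1)
        assert enum.truncated and len(enum) == 2
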
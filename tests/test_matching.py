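"""Clustering, correspondence search, Kabsch superposition, ranking, oracle."""

import itertools

import numpy as np
import pytest

from qpeakfit import (
    CandidateSet,
    HostStructure,
    MatcherParams,
    QPeak,
    QPeakSet,
    SimulationSpec,
    SymOp,
    UnitCell,
    brute_force_match,
    candidate_from_coords,
    correspondence_search,
    filter_and_cluster,
    kabsch_superpose,
    match_candidate,
    parse_symop,
    rank_candidates,
    simulate_qpeaks,
)
from qpeakfit.matching import Cluster
from qpeakfit.structures import AtomSite


def make_qpeaks(cart_points, cell=None, symops=None, heights=None):
    cell = cell or UnitCell(30, 30, 30)
    symops = symops or [SymOp.identity()]
    heights = heights if heights is not None else np.full(len(cart_points), 3.0)
    host = HostStructure(
        cell=cell, symops=symops, sites=[AtomSite("X1", "C", np.zeros(3))]
    )
    peaks = [
        QPeak(f"Q{i + 1}", cell.cart_to_frac(np.asarray(p, dtype=float)) % 1.0, float(h))
        for i, (p, h) in enumerate(zip(cart_points, heights))
    ]
    return QPeakSet(host=host, peaks=peaks)


def cluster_from_points(points):
    points = np.asarray(points, dtype=float)
    return Cluster(
        peak_refs=[(f"Q{i + 1}", 0, (0, 0, 0)) for i in range(len(points))],
        coords=points,
        heights=np.full(len(points), 3.0),
    )


def random_chain_candidate(rng, n_atoms, name="chain"):
    coords = [np.zeros(3)]
    for _ in range(1, n_atoms):
        v = rng.normal(size=3)
        v *= rng.uniform(1.2, 1.7) / np.linalg.norm(v)
        coords.append(coords[-1] + v)
    bonds = [(i, i + 1) for i in range(n_atoms - 1)]
    return candidate_from_coords(name, ["C"] * n_atoms, np.array(coords), bonds)


class TestClustering:
    def test_bonded_pair_plus_isolated_peak(self):
        qp = make_qpeaks([[5, 5, 5], [6.4, 5, 5], [12, 5, 5]])
        clusters = filter_and_cluster(qp)
        assert [len(c) for c in clusters] == [2, 1]

    def test_zigzag_chain_is_one_cluster(self):
        pts = [[0, 0, 0], [1.5, 0, 0], [1.5, 1.5, 0], [3.0, 1.5, 0]]
        qp = make_qpeaks([np.add(p, 10) for p in pts])
        clusters = filter_and_cluster(qp)
        assert [len(c) for c in clusters] == [4]

    def test_cluster_reassembled_across_cell_edge(self):
        # peaks at x=0.02 and x=0.98 in a 10 Å cell are 0.4 Å... use 1.4 Å apart
        cell = UnitCell(10, 10, 10)
        host = HostStructure(cell=cell, symops=[SymOp.identity()],
                             sites=[AtomSite("X1", "C", np.zeros(3))])
        peaks = [
            QPeak("Q1", np.array([0.07, 0.5, 0.5]), 3.0),
            QPeak("Q2", np.array([0.93, 0.5, 0.5]), 2.0),
        ]
        qp = QPeakSet(host=host, peaks=peaks)
        clusters = filter_and_cluster(qp)
        assert len(clusters) == 1 and len(clusters[0]) == 2
        d = np.linalg.norm(clusters[0].coords[0] - clusters[0].coords[1])
        assert d == pytest.approx(cell.min_image_distance_bruteforce(
            peaks[0].frac, peaks[1].frac, shells=2), abs=1e-9)

    def test_cluster_completed_through_symmetry_image(self):
        # twofold along y maps (x,y,z)->(-x,y,-z): a peak at x=+0.7 Å pairs
        # with the image of its mate to form one physical molecule
        cell = UnitCell(20, 20, 20)
        ops = [SymOp.identity(), parse_symop("-x, y, -z")]
        host = HostStructure(cell=cell, symops=ops,
                             sites=[AtomSite("X1", "C", np.zeros(3))])
        peaks = [QPeak("Q1", np.array([0.035, 0.25, 0.0]), 3.0)]
        qp = QPeakSet(host=host, peaks=peaks)
        clusters = filter_and_cluster(qp)
        # the peak at x=0.7 Å and its twofold image at -0.7 Å are 1.4 Å apart
        assert len(clusters) == 1 and len(clusters[0]) == 2

    def test_height_filter_drops_weak_peaks(self):
        qp = make_qpeaks([[5, 5, 5], [6.4, 5, 5]], heights=[3.0, 0.2])
        clusters = filter_and_cluster(qp, MatcherParams(height_min=0.15))
        assert [len(c) for c in clusters] == [1]

    def test_empty_peak_list(self):
        cell = UnitCell(10, 10, 10)
        host = HostStructure(cell=cell, symops=[SymOp.identity()],
                             sites=[AtomSite("X1", "C", np.zeros(3))])
        assert filter_and_cluster(QPeakSet(host=host, peaks=[])) == []


class TestKabsch:
    def test_identical_sets(self):
        P = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        R, t, rmsd = kabsch_superpose(P, P)
        assert rmsd <= 1e-12
        assert np.allclose(R, np.eye(3))
        assert np.allclose(t, 0)

    def test_congruent_sets(self, rng):
        P = rng.normal(size=(7, 3))
        Rr, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(Rr) < 0:
            Rr[:, 0] *= -1
        Q = (P - rng.normal(size=3)) @ Rr.T
        _, _, rmsd = kabsch_superpose(P, Q)
        assert rmsd <= 1e-9

    def test_collinear_pair_analytic(self):
        P = np.array([[-1.0, 0, 0], [1.0, 0, 0]])
        Q = np.array([[-0.5, 0, 0], [0.5, 0, 0]])
        _, _, rmsd = kabsch_superpose(P, Q)
        assert rmsd == pytest.approx(0.5, abs=1e-12)

    def test_size_mismatch(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((3, 3)), np.zeros((2, 3)))

    def test_proper_rotation_enforced(self, rng):
        # mirror-image sets must not be matched by a reflection
        P = rng.normal(size=(5, 3))
        Q = P.copy()
        Q[:, 0] *= -1
        R, _, rmsd = kabsch_superpose(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.01

    def test_agrees_with_scipy_align_vectors(self, rng):
        from scipy.spatial.transform import Rotation

        P = rng.normal(size=(6, 3))
        Q = rng.normal(size=(6, 3))
        R, t, rmsd = kabsch_superpose(P, Q)
        rot, _ = Rotation.align_vectors(P - P.mean(0), Q - Q.mean(0))
        resid = (Q - Q.mean(0)) @ rot.as_matrix().T - (P - P.mean(0))
        rmsd_scipy = np.sqrt((resid ** 2).sum() / len(P))
        assert rmsd == pytest.approx(rmsd_scipy, abs=1e-9)


class TestCorrespondence:
    def test_exact_self_match_full_size(self, guests10):
        urea = guests10.get("urea")
        cluster = cluster_from_points(urea.conformers[0])
        corrs = correspondence_search(cluster, urea, 0)
        assert corrs and len(corrs[0]) == urea.n_atoms

    def test_coverage_gate_small_cluster(self, guests10):
        benzene_like = guests10.get("pyridine")
        cluster = cluster_from_points([[0, 0, 0], [1.4, 0, 0]])
        assert correspondence_search(cluster, benzene_like, 0) == []

    def test_matches_bruteforce_enumeration(self, rng):
        cand = random_chain_candidate(rng, 5)
        pts = cand.conformers[0] + rng.normal(0, 0.05, size=(5, 3))
        cluster = cluster_from_points(pts)
        params = MatcherParams()
        corrs = correspondence_search(cluster, cand, 0, params)
        dP = cluster.pairwise_distances()
        dA = cand.pairwise_distances(0)
        # independent check: every full-size injection passing the pairwise
        # test must appear within some returned clique
        full = []
        for perm in itertools.permutations(range(5)):
            ok = all(
                abs(dP[i, j] - dA[perm[i], perm[j]]) <= params.pair_tol
                for i, j in itertools.combinations(range(5), 2)
            )
            if ok:
                full.append({i: perm[i] for i in range(5)})
        for f in full:
            assert any(all(c.get(k) == v for k, v in f.items()) for c in corrs)

    def test_single_peak_single_atom(self):
        cand = candidate_from_coords("c", ["C"], np.zeros((1, 3)), [])
        cluster = cluster_from_points([[1.0, 2.0, 3.0]])
        corrs = correspondence_search(cluster, cand, 0)
        assert corrs == [{0: 0}]


class TestMatchCandidate:
    def test_exact_cluster_zero_rmsd(self, guests10):
        urea = guests10.get("urea")
        m = match_candidate(cluster_from_points(urea.conformers[0]), urea)
        assert m is not None
        assert m.rmsd <= 1e-9
        assert m.coverage == 1.0

    def test_jittered_cluster_rmsd_scales_with_noise(self, guests10):
        sigma = 0.1
        rng = np.random.default_rng(99)
        pyr = guests10.get("pyridine")
        pts = pyr.conformers[0] + rng.normal(0, sigma, size=(6, 3))
        m = match_candidate(cluster_from_points(pts), pyr)
        assert m is not None
        assert sigma / 2 <= m.rmsd <= 3 * sigma

    def test_rigid_motion_invariance(self, rng, guests10):
        pyr = guests10.get("pyridine")
        pts = pyr.conformers[0] + rng.normal(0, 0.05, size=(6, 3))
        m1 = match_candidate(cluster_from_points(pts), pyr)
        Rr, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(Rr) < 0:
            Rr[:, 0] *= -1
        moved = pts @ Rr.T + np.array([5.0, -3.0, 2.0])
        m2 = match_candidate(cluster_from_points(moved), pyr)
        assert abs(m1.rmsd - m2.rmsd) <= 1e-8

    def test_pair_tol_monotonicity(self, rng):
        cand = random_chain_candidate(rng, 6)
        pts = cand.conformers[0] + rng.normal(0, 0.12, size=(6, 3))
        cluster = cluster_from_points(pts)
        sizes = []
        for tol in (0.1, 0.2, 0.3, 0.45):
            corrs = correspondence_search(
                cluster, cand, 0, MatcherParams(pair_tol=tol, min_coverage=0.34)
            )
            sizes.append(max((len(c) for c in corrs), default=0))
        assert sizes == sorted(sizes)

    def test_deterministic(self, guests10):
        rng = np.random.default_rng(5)
        pyr = guests10.get("pyridine")
        pts = pyr.conformers[0] + rng.normal(0, 0.08, size=(6, 3))
        m1 = match_candidate(cluster_from_points(pts), pyr)
        m2 = match_candidate(cluster_from_points(pts), pyr)
        assert m1.correspondence == m2.correspondence
        assert m1.score == m2.score


class TestOracleEquivalence:
    def test_matches_bruteforce_on_seeded_random_cases(self, guests10):
        # dual-route check: clique search + subsets vs exhaustive DFS
        rng = np.random.default_rng(31337)
        params = MatcherParams()
        small = [c for c in guests10 if c.n_atoms <= 7]
        for case in range(50):
            if case % 2 == 0:
                cand = small[case % len(small)]
                conf = cand.conformers[0]
                k = rng.integers(max(3, cand.n_atoms - 1), cand.n_atoms + 1)
                sel = rng.permutation(cand.n_atoms)[:k]
                pts = conf[sel] + rng.normal(0, 0.08, size=(k, 3))
            else:
                cand = random_chain_candidate(rng, int(rng.integers(3, 8)), name=f"r{case}")
                pts = rng.uniform(-3, 3, size=(int(rng.integers(3, 8)), 3))
            cluster = cluster_from_points(pts)
            a = match_candidate(cluster, cand, params)
            b = brute_force_match(cluster, cand, params)
            if a is None or b is None:
                assert a is None and b is None
            else:
                assert abs(a.score - b.score) <= 1e-9

    def test_empty_admissible_set_agrees(self, guests10):
        pyr = guests10.get("pyridine")
        cluster = cluster_from_points([[0, 0, 0], [1.4, 0, 0]])
        assert match_candidate(cluster, pyr) is None
        assert brute_force_match(cluster, pyr) is None

    def test_single_point_case(self):
        cand = candidate_from_coords("c", ["C"], np.zeros((1, 3)), [])
        cluster = cluster_from_points([[2.0, 0, 0]])
        m = brute_force_match(cluster, cand)
        assert m is not None and m.rmsd <= 1e-12

    def test_size_cap_enforced(self, rng, guests10):
        pts = rng.uniform(-4, 4, size=(9, 3))
        with pytest.raises(ValueError, match="capped"):
            brute_force_match(cluster_from_points(pts), guests10.get("urea"))


class TestRanking:
    def test_true_guest_ranks_first(self, guests10):
        case = simulate_qpeaks(
            SimulationSpec(candidate_name="pyridine", seed=21, sigma=0.05), guests10
        )
        cluster = filter_and_cluster(case.qpeaks)[0]
        ranking = rank_candidates(cluster, guests10)
        assert "pyridine" in ranking.names_at_rank(1)

    def test_substructure_loses_to_true_larger_guest(self, guests10):
        # DMF's heavy-atom skeleton is contained in DEF's: with the coverage
        # penalty the full molecule must win on score
        case = simulate_qpeaks(
            SimulationSpec(candidate_name="DEF", seed=8, sigma=0.05), guests10
        )
        cluster = filter_and_cluster(case.qpeaks)[0]
        pair = CandidateSet([guests10.get("DMF"), guests10.get("DEF")])
        ranking = rank_candidates(cluster, pair)
        dmf = next(e for e in ranking.entries if e.candidate_name == "DMF")
        assert ranking.top().candidate_name == "DEF"
        assert dmf.result is not None  # valid partial match, just outranked

    def test_single_candidate_always_rank_one(self, guests10):
        case = simulate_qpeaks(
            SimulationSpec(candidate_name="urea", seed=3, sigma=0.05), guests10
        )
        cluster = filter_and_cluster(case.qpeaks)[0]
        ranking = rank_candidates(cluster, CandidateSet([guests10.get("urea")]))
        assert ranking.top().rank == 1

    def test_rejected_candidates_trail_with_shared_rank(self, guests10):
        case = simulate_qpeaks(
            SimulationSpec(candidate_name="urea", seed=3, sigma=0.05), guests10
        )
        cluster = filter_and_cluster(case.qpeaks)[0]
        ranking = rank_candidates(cluster, guests10)
        rejected = [e for e in ranking.entries if e.result is None]
        assert rejected, "large guests cannot match a 4-peak cluster"
        assert len({e.rank for e in rejected}) == 1
        names = [e.candidate_name for e in rejected]
        assert names == sorted(names)

    def test_ties_share_rank_and_sort_alphabetically(self):
        cell = UnitCell(30, 30, 30)
        # two mirror-named candidates with identical geometry: exact tie
        coords = np.array([[0, 0, 0], [1.4, 0, 0], [2.8, 0.5, 0]])
        bonds = [(0, 1), (1, 2)]
        a = candidate_from_coords("beta", ["C"] * 3, coords, bonds)
        b = candidate_from_coords("alpha", ["C"] * 3, coords, bonds)
        cluster = cluster_from_points(coords + 5.0)
        ranking = rank_candidates(cluster, CandidateSet([a, b]))
        assert [e.rank for e in ranking.entries] == [1, 1]
        assert [e.candidate_name for e in ranking.entries] == ["alpha", "beta"]

    def test_empty_candidate_set_rejected(self, guests10):
        cluster = cluster_from_points([[0, 0, 0], [1.4, 0, 0]])
        with pytest.raises(ValueError):
            rank_candidates(cluster, CandidateSet([]))
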
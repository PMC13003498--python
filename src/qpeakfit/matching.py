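"""Guest identification core: peak clustering, correspondence search, ranking.

The pipeline is geometric: residual-map peaks are filtered by height and
clustered into putative molecular skeletons using bond-length connectivity
(with symmetry and lattice images, so a guest sitting across a cell edge or
symmetry element is reassembled).  Each candidate molecule is then matched
to a cluster by searching the association graph of peak/atom pairs for
distance-compatible correspondences (maximal cliques and their admissible
sub-correspondences), superposing each with the Kabsch algorithm, and
scoring

    score = RMSD + λ · (1 − coverage),
    coverage = n_matched / max(n_candidate_atoms, n_cluster_points).

The denominator makes coverage penalize both incomplete candidates and
unexplained cluster points: a small molecule that is a substructure of the
true guest covers itself perfectly but leaves cluster points unexplained,
and would otherwise win on per-point RMSD.  With λ = 0 the ranking is by
raw RMSD, which reproduces exactly that fragment-outranking behaviour seen
when screening blindly with RMSD alone; the default λ > 0 suppresses it.
The admissibility gate (``min_coverage``) is applied to the candidate-atom
fraction only.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .candidates import Candidate, CandidateSet
from .cell import wrap_frac
from .structures import QPeakSet

__all__ = [
    "MatcherParams",
    "Cluster",
    "MatchResult",
    "RankedEntry",
    "Ranking",
    "filter_and_cluster",
    "correspondence_search",
    "kabsch_superpose",
    "match_candidate",
    "rank_candidates",
    "brute_force_match",
]


@dataclass(frozen=True)
class MatcherParams:
    """Tunable thresholds of the matcher.

    bond_window
        Peak–peak distance range (Å) treated as a plausible heavy-atom bond
        when clustering.
    height_min
        Peaks below this fraction of the tallest peak are discarded as noise.
    pair_tol
        Allowed deviation (Å) between a peak–peak distance and the
        corresponding atom–atom distance for an assignment pair to be
        admissible.
    min_coverage
        Minimum matched fraction of candidate heavy atoms.
    coverage_weight
        λ of the score; Å of RMSD-equivalent penalty per unmatched-atom
        fraction.  0 reproduces pure-RMSD ranking.
    tie_tol
        Scores closer than this (Å) are reported as a tie.
    """

    bond_window: tuple[float, float] = (1.1, 1.8)
    height_min: float = 0.15
    pair_tol: float = 0.25
    min_coverage: float = 0.6
    coverage_weight: float = 2.0
    tie_tol: float = 0.01

    def __post_init__(self) -> None:
        lo, hi = self.bond_window
        if not 0 < lo < hi:
            raise ValueError("bond_window must satisfy 0 < d_min < d_max")
        if self.pair_tol <= 0 or self.tie_tol <= 0:
            raise ValueError("tolerances must be positive")
        for name in ("height_min", "min_coverage"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.coverage_weight < 0:
            raise ValueError("coverage_weight must be >= 0")


@dataclass
class Cluster:
    """A connected set of peaks (possibly realized through symmetry images).

    ``peak_refs[k] = (label, symop_index, lattice_shift)`` records how the
    k-th member point was generated; ``coords`` are its Cartesian positions.
    """

    peak_refs: list[tuple[str, int, tuple[int, int, int]]]
    coords: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.peak_refs) == 0:
            raise ValueError("cluster has no peaks")
        if self.coords.shape != (len(self.peak_refs), 3):
            raise ValueError("coords shape does not match peak_refs")

    def __len__(self) -> int:
        return len(self.peak_refs)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r[0] for r in self.peak_refs)

    def pairwise_distances(self) -> np.ndarray:
        d = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((d * d).sum(axis=-1))


@dataclass
class MatchResult:
    """A scored peak↔atom correspondence with its rigid transform."""

    candidate_name: str
    conformer_index: int
    correspondence: dict[int, int]  # cluster point index -> candidate atom index
    rotation: np.ndarray  # proper rotation mapping candidate frame to cluster frame
    translation: np.ndarray
    rmsd: float
    coverage: float
    score: float
    matched_peak_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must be in (0, 1]")
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-8 or np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation is not proper orthogonal")


@dataclass
class RankedEntry:
    rank: int
    candidate_name: str
    result: MatchResult | None  # None: rejected (no admissible correspondence)

    @property
    def score(self) -> float:
        return self.result.score if self.result is not None else math.inf


@dataclass
class Ranking:
    """Candidates ordered by score; near-equal scores share a rank.

    Within a tie group entries are listed alphabetically, so scores are
    nondecreasing up to ``tie_tol``; across rank boundaries strictly so."""

    entries: list[RankedEntry] = field(default_factory=list)
    tie_tol: float = 0.01

    def __post_init__(self) -> None:
        for a, b in zip(self.entries, self.entries[1:]):
            slack = self.tie_tol if a.rank == b.rank else 1e-12
            if b.score < a.score - slack:
                raise ValueError("ranking scores are not nondecreasing")

    def top(self) -> RankedEntry:
        return self.entries[0]

    def names_at_rank(self, rank: int) -> list[str]:
        return [e.candidate_name for e in self.entries if e.rank == rank]


def filter_and_cluster(qpeaks: QPeakSet, params: MatcherParams = MatcherParams()) -> list[Cluster]:
    """Height-filter peaks and partition them into bonded clusters.

    Connectivity is evaluated over all symmetry images plus one shell of
    lattice translations, so clusters broken across the cell boundary or a
    symmetry element are reassembled.  One symmetry-unique representative per
    cluster orbit is returned; clusters are sorted by size, largest first.
    """
    peaks = qpeaks.sorted_by_height()
    if not peaks:
        return []
    cell = qpeaks.host.cell
    ops = qpeaks.host.symops
    id_idx = next(i for i, op in enumerate(ops) if op.is_identity)

    hmax = peaks[0].height
    kept = [p for p in peaks if p.height >= params.height_min * hmax]
    if not kept:
        return []

    # every (peak, symop, lattice shift) image within one shell
    shifts = list(itertools.product((-1, 0, 1), repeat=3))
    nodes: list[tuple[int, int, tuple[int, int, int]]] = []
    fracs: list[np.ndarray] = []
    for i, p in enumerate(kept):
        for s, op in enumerate(ops):
            base = wrap_frac(op.apply(p.frac))
            for sh in shifts:
                nodes.append((i, s, sh))
                fracs.append(base + np.asarray(sh, dtype=float))
    carts = cell.frac_to_cart(np.asarray(fracs))

    lo, hi = params.bond_window
    diff = carts[:, None, :] - carts[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=-1))
    adj = (dist >= lo) & (dist <= hi)

    graph = nx.Graph()
    graph.add_nodes_from(range(len(nodes)))
    graph.add_edges_from(zip(*np.nonzero(np.triu(adj, k=1))))

    comp_of: dict[int, int] = {}
    comps: list[set[int]] = []
    for ci, comp in enumerate(nx.connected_components(graph)):
        comps.append(comp)
        for v in comp:
            comp_of[v] = ci

    node_index = {n: v for v, n in enumerate(nodes)}
    clusters: list[Cluster] = []
    seen_signatures: set[tuple[int, ...]] = set()
    seen_comps: set[int] = set()
    for i in range(len(kept)):
        v = node_index[(i, id_idx, (0, 0, 0))]
        ci = comp_of[v]
        if ci in seen_comps:
            continue
        seen_comps.add(ci)
        members = sorted(comps[ci], key=lambda u: (nodes[u][0], nodes[u][1], nodes[u][2]))
        signature = tuple(sorted(nodes[u][0] for u in members))
        if signature in seen_signatures:
            continue  # symmetry copy of an already-collected cluster
        seen_signatures.add(signature)
        clusters.append(
            Cluster(
                peak_refs=[(kept[nodes[u][0]].label, nodes[u][1], nodes[u][2]) for u in members],
                coords=carts[members],
                heights=np.array([kept[nodes[u][0]].height for u in members]),
            )
        )
    clusters.sort(key=lambda c: (-len(c), c.labels))
    return clusters


def _coverage_threshold(n_atoms: int, min_coverage: float) -> int:
    return max(1, math.ceil(min_coverage * n_atoms - 1e-9))


def correspondence_search(
    cluster: Cluster,
    candidate: Candidate,
    conformer_index: int = 0,
    params: MatcherParams = MatcherParams(),
) -> list[dict[int, int]]:
    """Distance-compatible peak↔atom correspondences as association-graph cliques.

    Vertices are (peak, atom) assignments; two assignments are compatible
    when their peak–peak and atom–atom distances agree within ``pair_tol``.
    Returns all maximal cliques with at least ``min_coverage·n_atoms``
    members, largest first, in a deterministic order.
    """
    dP = cluster.pairwise_distances()
    dA = candidate.pairwise_distances(conformer_index)
    n_p, n_a = len(cluster), candidate.n_atoms
    threshold = _coverage_threshold(n_a, params.min_coverage)
    if n_p < threshold:
        return []

    graph = nx.Graph()
    graph.add_nodes_from((i, a) for i in range(n_p) for a in range(n_a))
    for (i, a), (j, b) in itertools.combinations(graph.nodes, 2):
        if i != j and a != b and abs(dP[i, j] - dA[a, b]) <= params.pair_tol:
            graph.add_edge((i, a), (j, b))

    cliques = [c for c in nx.find_cliques(graph) if len(c) >= threshold]
    out = [dict(sorted(c)) for c in cliques]
    out.sort(key=lambda m: (-len(m), tuple(sorted(m.items()))))
    return out


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``Q`` onto ``P`` (paired points, Å).

    Returns ``(R, t, rmsd)`` with ``R`` a proper rotation (reflections are
    excluded via the determinant correction) minimizing ``Σ|R q + t − p|²``.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3 or len(P) < 1:
        raise ValueError(f"point sets must share shape (n>=1, 3); got {P.shape} and {Q.shape}")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (Q - qc).T @ (P - pc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = pc - R @ qc
    delta = (Q @ R.T + t) - P
    rmsd = float(np.sqrt((delta * delta).sum() / len(P)))
    return R, t, rmsd


def _iter_admissible(cliques: list[dict[int, int]], threshold: int):
    """All distinct sub-correspondences of the maximal cliques meeting the
    coverage threshold (every admissible correspondence is a subset of some
    maximal clique)."""
    seen: set[frozenset] = set()
    for cl in cliques:
        items = sorted(cl.items())
        for k in range(len(items), threshold - 1, -1):
            for sub in itertools.combinations(items, k):
                key = frozenset(sub)
                if key not in seen:
                    seen.add(key)
                    yield dict(sub)


def _score_correspondence(cluster, conf, corr, n_atoms, lam):
    idx_p = list(corr.keys())
    idx_a = list(corr.values())
    R, t, rmsd = kabsch_superpose(cluster.coords[idx_p], conf[idx_a])
    coverage = len(corr) / max(n_atoms, len(cluster))
    return R, t, rmsd, coverage, rmsd + lam * (1.0 - coverage)


def match_candidate(
    cluster: Cluster,
    candidate: Candidate,
    params: MatcherParams = MatcherParams(),
) -> MatchResult | None:
    """Best-scoring rigid match of a candidate to a cluster, or ``None``.

    Minimizes the score over all conformers and all admissible
    correspondences; deterministic given the parameters (ties broken by
    conformer index then correspondence)."""
    best = None
    best_key = None
    lam = params.coverage_weight
    threshold = _coverage_threshold(candidate.n_atoms, params.min_coverage)
    for conf_idx, conf in enumerate(candidate.conformers):
        cliques = correspondence_search(cluster, candidate, conf_idx, params)
        for corr in _iter_admissible(cliques, threshold):
            R, t, rmsd, coverage, score = _score_correspondence(
                cluster, conf, corr, candidate.n_atoms, lam
            )
            key = (score, conf_idx, tuple(sorted(corr.items())))
            if best_key is None or key < best_key:
                best_key = key
                best = MatchResult(
                    candidate_name=candidate.name,
                    conformer_index=conf_idx,
                    correspondence=corr,
                    rotation=R,
                    translation=t,
                    rmsd=rmsd,
                    coverage=coverage,
                    score=score,
                    matched_peak_labels=tuple(cluster.peak_refs[i][0] for i in sorted(corr)),
                )
    return best


def rank_candidates(
    cluster: Cluster,
    candidates: CandidateSet,
    params: MatcherParams = MatcherParams(),
) -> Ranking:
    """Match every candidate against the cluster and order them by score.

    Rejected candidates (no admissible correspondence) trail the list with
    infinite score.  Scores within ``tie_tol`` share a rank and are listed
    alphabetically for output stability."""
    if len(candidates) == 0:
        raise ValueError("candidate set is empty")
    accepted: list[MatchResult] = []
    rejected: list[str] = []
    for cand in candidates:
        res = match_candidate(cluster, cand, params)
        if res is None:
            rejected.append(cand.name)
        else:
            accepted.append(res)
    accepted.sort(key=lambda r: (r.score, r.candidate_name))

    entries: list[RankedEntry] = []
    i = 0
    while i < len(accepted):
        j = i
        while j + 1 < len(accepted) and accepted[j + 1].score - accepted[i].score < params.tie_tol:
            j += 1
        group = sorted(accepted[i : j + 1], key=lambda r: r.candidate_name)
        for r in group:
            entries.append(RankedEntry(rank=i + 1, candidate_name=r.candidate_name, result=r))
        i = j + 1
    for name in sorted(rejected):
        entries.append(RankedEntry(rank=len(accepted) + 1, candidate_name=name, result=None))
    return Ranking(entries=entries, tie_tol=params.tie_tol)


def brute_force_match(
    cluster: Cluster,
    candidate: Candidate,
    params: MatcherParams = MatcherParams(),
    size_cap: int = 8,
) -> MatchResult | None:
    """Exhaustive-enumeration oracle for :func:`match_candidate`.

    Depth-first enumerates every injective peak→atom assignment of every
    admissible size, applying the same pairwise distance test, superposes
    each, and returns the score-minimal result.  Refuses inputs beyond
    ``size_cap`` points (combinatorial guard)."""
    if len(cluster) > size_cap or candidate.n_atoms > size_cap:
        raise ValueError(f"brute force capped at {size_cap} peaks/atoms")
    n_p, n_a = len(cluster), candidate.n_atoms
    threshold = _coverage_threshold(n_a, params.min_coverage)
    lam = params.coverage_weight
    dP = cluster.pairwise_distances()

    best = None
    best_key = None
    for conf_idx, conf in enumerate(candidate.conformers):
        dA = candidate.pairwise_distances(conf_idx)

        assignments: list[tuple[tuple[int, int], ...]] = []

        def dfs(peak: int, current: list[tuple[int, int]], used_atoms: set[int]) -> None:
            if peak == n_p:
                if len(current) >= threshold:
                    assignments.append(tuple(current))
                return
            # remaining peaks cannot reach the threshold -> prune
            if len(current) + (n_p - peak) >= threshold:
                dfs(peak + 1, current, used_atoms)
            for a in range(n_a):
                if a in used_atoms:
                    continue
                if all(
                    abs(dP[peak, j] - dA[a, b]) <= params.pair_tol for (j, b) in current
                ):
                    current.append((peak, a))
                    used_atoms.add(a)
                    dfs(peak + 1, current, used_atoms)
                    current.pop()
                    used_atoms.remove(a)

        dfs(0, [], set())

        for assignment in assignments:
            corr = dict(assignment)
            R, t, rmsd, coverage, score = _score_correspondence(cluster, conf, corr, n_a, lam)
            key = (score, conf_idx, tuple(sorted(corr.items())))
            if best_key is None or key < best_key:
                best_key = key
                best = MatchResult(
                    candidate_name=candidate.name,
                    conformer_index=conf_idx,
                    correspondence=corr,
                    rotation=R,
                    translation=t,
                    rmsd=rmsd,
                    coverage=coverage,
                    score=score,
                    matched_peak_labels=tuple(cluster.peak_refs[i][0] for i in sorted(corr)),
                )
    return best
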
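"""Archived multi-objective simulated annealing (AMOSA) clustering.

Solutions encode a variable-length list of cluster centers in the embedding
space, so the number of clusters K is discovered rather than fixed
(2 <= K <= floor(sqrt(n))).  Two cluster validity indices are optimized
simultaneously:

* **Xie-Beni (XB)** — within-cluster scatter over worst-case center
  separation (squared Euclidean); smaller is better.
* **PBM** — (1/K) * (E1/EK) * DK with Euclidean distances, where E1 is the
  total distance to the global centroid, EK the within-cluster distance sum
  and DK the largest center separation; larger is better.

The annealer keeps an archive of mutually non-dominated solutions (under
minimize XB, maximize PBM).  A mutated candidate is accepted according to
its domination relationship with the current solution and the archive; the
probability of accepting a dominated move is 1 / (1 + exp(dom_avg / T)),
where dom_avg is the average amount of domination normalized by the current
objective ranges, so worse moves become increasingly unlikely as the
temperature T cools.  When the archive outgrows its soft limit it is
clustered down to the hard limit by single linkage in objective space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin

from . import metrics as _metrics

__all__ = [
    "ClusterSolution",
    "Archive",
    "AnnealSchedule",
    "xb_index",
    "pbm_index",
    "assign_labels",
    "evaluate_centers",
    "mutate",
    "anneal",
    "select_solution",
    "AmosaClustering",
]

INF_SENTINEL = np.inf


@dataclass
class ClusterSolution:
    """Variable-length center encoding with both validity indices."""

    centers: np.ndarray            # (K, d_emb)
    labels: np.ndarray | None = None
    xb: float = np.nan
    pbm: float = np.nan

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]

    def objectives(self) -> tuple[float, float]:
        """Both objectives as minimization: (XB, -PBM)."""
        return (self.xb, -self.pbm)


@dataclass
class Archive:
    """Mutually non-dominated solution set with soft/hard size limits."""

    solutions: list[ClusterSolution] = field(default_factory=list)
    soft_limit: int = 50
    hard_limit: int = 40


@dataclass
class AnnealSchedule:
    t_max: float = 100.0
    t_min: float = 0.001
    cooling: float = 0.9
    iters_per_temp: int = 100
    soft_limit: int = 50
    hard_limit: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.cooling < 1.0:
            raise ValueError("cooling must be in (0, 1)")
        if self.t_min >= self.t_max:
            raise ValueError("t_min must be below t_max")

    @property
    def n_levels(self) -> int:
        """Number of temperature levels until t_min is crossed."""
        return int(np.ceil(np.log(self.t_min / self.t_max) / np.log(self.cooling)))


# ------------------------------------------------------------ validity indices

def assign_labels(Y: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Crisp nearest-center assignment (ties to the lower center index)."""
    return cdist(Y, centers, metric="sqeuclidean").argmin(axis=1)


def xb_index(Y: np.ndarray, solution: ClusterSolution) -> float:
    """Xie-Beni index with crisp memberships and squared Euclidean distance.

    XB = sum_q sum_{r in q} ||x_r - C_q||^2 / (n * min_{l != m} ||C_l - C_m||^2).
    Coincident centers give an infinite sentinel.
    """
    Y = np.asarray(Y, dtype=float)
    centers = np.asarray(solution.centers, dtype=float)
    K, n = centers.shape[0], Y.shape[0]
    if K < 2:
        raise ValueError("XB needs at least 2 clusters")
    labels = solution.labels if solution.labels is not None else assign_labels(Y, centers)
    d2 = cdist(Y, centers, metric="sqeuclidean")
    numerator = d2[np.arange(n), labels].sum()
    cd2 = cdist(centers, centers, metric="sqeuclidean")
    np.fill_diagonal(cd2, np.inf)
    min_sep = cd2.min()
    if min_sep <= 0:
        return INF_SENTINEL
    return float(numerator / (n * min_sep))


def pbm_index(Y: np.ndarray, solution: ClusterSolution) -> float:
    """PBM index, Euclidean distances, exactly the printed (un-squared) form.

    PBM(K) = (1/K) * (E1 / EK) * DK.  All points sitting exactly on their
    centers (EK = 0) gives an infinite sentinel.
    """
    Y = np.asarray(Y, dtype=float)
    centers = np.asarray(solution.centers, dtype=float)
    K = centers.shape[0]
    labels = solution.labels if solution.labels is not None else assign_labels(Y, centers)
    centroid = Y.mean(axis=0)
    e1 = float(np.linalg.norm(Y - centroid, axis=1).sum())
    ek = float(np.linalg.norm(Y - centers[labels], axis=1).sum())
    if K == 1:
        dk = 0.0
    else:
        cd = cdist(centers, centers, metric="euclidean")
        dk = float(cd.max())
    if ek <= 0:
        return INF_SENTINEL
    return float((1.0 / K) * (e1 / ek) * dk)


def evaluate_centers(Y: np.ndarray, centers: np.ndarray) -> ClusterSolution:
    """Assign labels, repair empty clusters, and compute both indices.

    An empty cluster is repaired by moving its center onto the point
    farthest from its assigned center, then re-assigning once.
    """
    Y = np.asarray(Y, dtype=float)
    centers = np.array(centers, dtype=float, copy=True)
    K = centers.shape[0]
    labels = assign_labels(Y, centers)
    for _ in range(K):  # at most K repairs
        counts = np.bincount(labels, minlength=K)
        empty = np.where(counts == 0)[0]
        if empty.size == 0:
            break
        d_own = np.linalg.norm(Y - centers[labels], axis=1)
        far = int(np.argmax(d_own))
        centers[empty[0]] = Y[far]
        labels = assign_labels(Y, centers)
    sol = ClusterSolution(centers=centers, labels=labels)
    sol.xb = xb_index(Y, sol)
    sol.pbm = pbm_index(Y, sol)
    return sol


# ------------------------------------------------------------------- annealer

def _dominates(a: tuple[float, float], b: tuple[float, float]) -> bool:
    """Pareto domination on minimization objectives (a dominates b)."""
    return (a[0] <= b[0] and a[1] <= b[1]) and (a[0] < b[0] or a[1] < b[1])


def _amount_of_domination(a, b, ranges) -> float:
    """Product of normalized objective gaps over objectives where they differ."""
    amt = 1.0
    for fa, fb, r in zip(a, b, ranges):
        if fa != fb:
            amt *= abs(fa - fb) / r
    return amt


def _objective_ranges(objs: list[tuple[float, float]]) -> tuple[float, float]:
    arr = np.asarray(objs, dtype=float)
    finite = np.isfinite(arr)
    ranges = []
    for j in range(arr.shape[1]):
        col = arr[finite[:, j], j]
        r = float(col.max() - col.min()) if col.size else 0.0
        ranges.append(r if r > 0 else 1.0)
    return tuple(ranges)


def mutate(solution: ClusterSolution, Y: np.ndarray,
           rng: np.random.Generator, kind: str | None = None,
           k_min: int = 2, k_max: int | None = None,
           laplace_scale: float = 1.0) -> ClusterSolution:
    """One of three mutation moves, chosen uniformly unless ``kind`` given.

    * ``normal`` — one center's coordinates perturbed with Laplace noise
      (location = old value, scale = 1.0);
    * ``insert`` — a uniformly chosen data point added as a new center;
    * ``delete`` — a uniformly chosen center removed.

    A move that would leave K outside [k_min, k_max] is redrawn.
    """
    Y = np.asarray(Y, dtype=float)
    if k_max is None:
        k_max = max(k_min, int(np.floor(np.sqrt(Y.shape[0]))))
    K = solution.n_clusters
    allowed = ["normal"]
    if K + 1 <= k_max:
        allowed.append("insert")
    if K - 1 >= k_min:
        allowed.append("delete")
    if kind is None or kind not in allowed:
        kind = allowed[rng.integers(len(allowed))]
    centers = np.array(solution.centers, copy=True)
    if kind == "normal":
        idx = int(rng.integers(K))
        centers[idx] = centers[idx] + rng.laplace(0.0, laplace_scale,
                                                  size=centers.shape[1])
    elif kind == "insert":
        centers = np.vstack([centers, Y[int(rng.integers(Y.shape[0]))]])
    else:  # delete
        idx = int(rng.integers(K))
        centers = np.delete(centers, idx, axis=0)
    return evaluate_centers(Y, centers)


def _prune_archive(archive: list[ClusterSolution], hard_limit: int) -> list[ClusterSolution]:
    """Single-linkage clustering in normalized objective space down to HL."""
    objs = np.asarray([s.objectives() for s in archive], dtype=float)
    finite = np.isfinite(objs).all(axis=1)
    keep_idx = np.where(finite)[0]
    if keep_idx.size <= hard_limit:
        pool = [archive[i] for i in keep_idx] or archive
        return pool[:hard_limit] if len(pool) > hard_limit else pool
    sub = objs[keep_idx]
    span = sub.max(axis=0) - sub.min(axis=0)
    span[span == 0] = 1.0
    norm = (sub - sub.min(axis=0)) / span
    Z = linkage(norm, method="single")
    groups = fcluster(Z, t=hard_limit, criterion="maxclust")
    kept = []
    for g in np.unique(groups):
        members = keep_idx[groups == g]
        pts = norm[groups == g]
        center = pts.mean(axis=0)
        best = members[np.argmin(np.linalg.norm(pts - center, axis=1))]
        kept.append(archive[best])
    return kept


def _update_archive(archive: list[ClusterSolution], new: ClusterSolution,
                    soft_limit: int, hard_limit: int) -> list[ClusterSolution]:
    no = new.objectives()
    if any(_dominates(s.objectives(), no) for s in archive):
        return archive
    archive = [s for s in archive if not _dominates(no, s.objectives())]
    archive.append(new)
    if len(archive) > soft_limit:
        archive = _prune_archive(archive, hard_limit)
    return archive


def _initial_archive(Y: np.ndarray, rng: np.random.Generator,
                     k_min: int, k_max: int, n_init: int = 10) -> list[ClusterSolution]:
    sols = []
    for _ in range(n_init):
        K = int(rng.integers(k_min, k_max + 1))
        idx = rng.choice(Y.shape[0], size=K, replace=False)
        sols.append(evaluate_centers(Y, Y[idx]))
    archive: list[ClusterSolution] = []
    for s in sols:
        if not any(_dominates(o.objectives(), s.objectives()) for o in sols if o is not s):
            archive.append(s)
    return archive or sols[:1]


def anneal(Y: np.ndarray, schedule: AnnealSchedule | None = None,
           k_min: int = 2, k_max: int | None = None) -> Archive:
    """Run the archived multi-objective annealer on embedding ``Y``.

    Returns the final archive — an approximation of the Pareto front over
    (minimize XB, maximize PBM) across cluster counts.
    """
    if schedule is None:
        schedule = AnnealSchedule()
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples")
    if k_max is None:
        k_max = max(k_min, int(np.floor(np.sqrt(n))))
    rng = np.random.default_rng(schedule.seed)
    if np.allclose(Y, Y[0]):
        warnings.warn("degenerate data: all points identical")
        sol = evaluate_centers(Y, Y[:2].copy())
        return Archive(solutions=[sol], soft_limit=schedule.soft_limit,
                       hard_limit=schedule.hard_limit)

    archive = _initial_archive(Y, rng, k_min, k_max)
    current = archive[int(rng.integers(len(archive)))]
    T = schedule.t_max
    while T > schedule.t_min:
        for _ in range(schedule.iters_per_temp):
            new = mutate(current, Y, rng, k_min=k_min, k_max=k_max)
            no, co = new.objectives(), current.objectives()
            ranges = _objective_ranges(
                [s.objectives() for s in archive] + [no, co])
            dominating_arch = [s for s in archive
                               if _dominates(s.objectives(), no)]
            if _dominates(co, no):
                # worse than current: probabilistic uphill acceptance
                amts = [_amount_of_domination(s.objectives(), no, ranges)
                        for s in dominating_arch]
                amts.append(_amount_of_domination(co, no, ranges))
                dom_avg = float(np.mean(amts))
                if rng.random() < 1.0 / (1.0 + np.exp(min(dom_avg / T, 700.0))):
                    current = new
            elif dominating_arch and not _dominates(no, co):
                # non-dominating wrt current but dominated within the archive
                dom_avg = float(np.mean(
                    [_amount_of_domination(s.objectives(), no, ranges)
                     for s in dominating_arch]))
                if rng.random() < 1.0 / (1.0 + np.exp(min(dom_avg / T, 700.0))):
                    current = new
            else:
                # dominates current, or non-dominated everywhere: accept
                current = new
                archive = _update_archive(archive, new, schedule.soft_limit,
                                          schedule.hard_limit)
        T *= schedule.cooling
    return Archive(solutions=archive, soft_limit=schedule.soft_limit,
                   hard_limit=schedule.hard_limit)


def select_solution(archive: Archive, strategy: str = "best_pbm",
                    labels: np.ndarray | None = None) -> ClusterSolution:
    """Pick one solution from the Pareto archive.

    ``best_pbm`` (unsupervised default) takes the solution with the largest
    PBM index.  ``supervised_nmi`` takes the solution whose labels agree
    best with the supplied ground truth — a reporting mode that uses labels
    and must be flagged as such in any output.
    """
    if not archive.solutions:
        raise ValueError("empty archive")
    if strategy == "best_pbm":
        finite = [s for s in archive.solutions if np.isfinite(s.pbm)]
        pool = finite or archive.solutions
        return max(pool, key=lambda s: s.pbm)
    if strategy == "supervised_nmi":
        if labels is None:
            raise ValueError("supervised_nmi requires ground-truth labels")
        return max(archive.solutions,
                   key=lambda s: _metrics.nmi(labels, s.labels))
    raise ValueError(f"unknown strategy {strategy!r}")


class AmosaClustering(ClusterMixin, BaseEstimator):
    """Sklearn-style clusterer wrapping :func:`anneal` + :func:`select_solution`.

    Parameters
    ----------
    t_max, t_min, cooling, iters_per_temp, soft_limit, hard_limit
        Annealing schedule and archive limits.
    selection : {"best_pbm", "supervised_nmi"}
        How the reported solution is chosen from the Pareto archive; the
        supervised mode needs ``y`` at fit time.
    random_state : int
        Seed for all annealer randomness.

    Attributes
    ----------
    archive_ : Archive
        Final mutually non-dominated solution set.
    solution_ : ClusterSolution
        The selected solution.
    labels_, n_clusters_ : crisp assignment and its cluster count.
    """

    def __init__(self, t_max: float = 100.0, t_min: float = 0.001,
                 cooling: float = 0.9, iters_per_temp: int = 100,
                 soft_limit: int = 50, hard_limit: int = 40,
                 selection: str = "best_pbm", random_state: int = 0):
        self.t_max = t_max
        self.t_min = t_min
        self.cooling = cooling
        self.iters_per_temp = iters_per_temp
        self.soft_limit = soft_limit
        self.hard_limit = hard_limit
        self.selection = selection
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray | None = None) -> "AmosaClustering":
        schedule = AnnealSchedule(
            t_max=self.t_max, t_min=self.t_min, cooling=self.cooling,
            iters_per_temp=self.iters_per_temp, soft_limit=self.soft_limit,
            hard_limit=self.hard_limit, seed=self.random_state)
        self.archive_ = anneal(np.asarray(X, dtype=float), schedule)
        self.solution_ = select_solution(self.archive_, self.selection, labels=y)
        self.labels_ = self.solution_.labels
        self.n_clusters_ = self.solution_.n_clusters
        return self

    def fit_predict(self, X: np.ndarray, y: np.ndarray | None = None) -> np.ndarray:
        return self.fit(X, y).labels_
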
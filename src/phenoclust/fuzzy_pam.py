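"""Fuzzy partition-around-medoids clustering with validity indices.

The algorithm alternates two exact steps on a precomputed dissimilarity
matrix:

* membership update — ``u_iv`` proportional to ``d(i, medoid_v)^(-1/(m-1))``
  where ``m > 1`` is the fuzzifier; a subject coincident with a medoid gets
  full membership there;
* medoid update — each cluster's medoid becomes the data point minimizing
  the fuzzy within-cluster cost ``sum_i u_iv^m d(i, x)``.

The objective ``J = sum_i sum_v u_iv^m d(i, medoid_v)`` is non-increasing
across iterations; the best of several random restarts is returned.

Cluster-count selection uses partition coefficients: the normalized Dunn
coefficient ``Fc(U)`` (crispness; 1 for a hard partition, 0 for uniform
memberships) is maximized, and the normalized Kaufman distance coefficient
``Dc(U)`` (deviation from hardness; 0 hard, 1 uniform) is reported and
should be minimized.

Distances are Euclidean on mean/MAD-scaled variables, missing-tolerant:
pairs are compared on their shared observed variables and rescaled by the
fraction observed (Gower-style completion), so partially observed subjects
(e.g. PC20 absent when FEV1 < 60% predicted) remain clusterable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from phenoclust.preprocess import FeatureMatrix

log = logging.getLogger(__name__)


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities with shared-observation counts."""

    d: np.ndarray
    n_shared: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.ndim != 2 or self.d.shape[0] != self.d.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("dissimilarities must be nonnegative")

    @property
    def n(self) -> int:
        return self.d.shape[0]

    def subset(self, idx: np.ndarray) -> "DissimilarityMatrix":
        return DissimilarityMatrix(self.d[np.ix_(idx, idx)],
                                   self.n_shared[np.ix_(idx, idx)])


def pairwise_distance(fm: FeatureMatrix) -> DissimilarityMatrix:
    """Missing-tolerant scaled Euclidean distances.

    ``d(i,j) = sqrt( p / p_obs(i,j) * sum_{m in shared}(z_im - z_jm)^2 )``
    where ``p_obs`` counts variables observed in both rows.  A pair with no
    shared observed variable is an error.
    """
    Z = np.where(fm.mask, fm.values, 0.0)
    M = fm.mask.astype(float)
    # sum over shared variables of (zi - zj)^2; masked terms vanish because
    # each squared term is gated by the *other* row's mask
    sq = Z * Z
    S = sq @ M.T + M @ sq.T - 2.0 * (Z @ Z.T)
    S = np.maximum(S, 0.0)
    n_shared = (M @ M.T).astype(int)
    bad = (n_shared == 0) & ~np.eye(fm.n, dtype=bool)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"subjects {fm.subject_ids[i]!r} and {fm.subject_ids[j]!r} share no "
            "observed variables"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.sqrt(fm.p / np.maximum(n_shared, 1) * S)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DissimilarityMatrix(d=d, n_shared=n_shared)


@dataclass
class FuzzyPartition:
    """Memberships, medoids and hard assignments of one fitted partition."""

    memberships: np.ndarray      # n x k, rows sum to 1
    medoids: np.ndarray          # k distinct row indices
    fuzzifier: float
    objective: float
    subject_ids: tuple[str, ...] | None = None
    n_iter: int = 0

    @property
    def n(self) -> int:
        return self.memberships.shape[0]

    @property
    def k(self) -> int:
        return self.memberships.shape[1]

    @property
    def hard_labels(self) -> np.ndarray:
        """Argmax cluster per row; ties break to the lowest cluster index."""
        return self.memberships.argmax(axis=1)

    @property
    def max_probability(self) -> np.ndarray:
        return self.memberships.max(axis=1)


def _memberships_for_medoids(D: np.ndarray, medoids: np.ndarray, m: float) -> np.ndarray:
    """Exact membership update for a fixed medoid set."""
    dm = D[:, medoids]                         # n x k
    n, k = dm.shape
    U = np.zeros((n, k))
    zero = dm == 0.0
    has_zero = zero.any(axis=1)
    if has_zero.any():
        # coincident with a medoid: full membership to the first such cluster
        first = zero[has_zero].argmax(axis=1)
        U[np.flatnonzero(has_zero), first] = 1.0
    rest = ~has_zero
    if rest.any():
        dr = dm[rest]
        # normalize by the row minimum so the negative power cannot overflow
        ratio = dr / dr.min(axis=1, keepdims=True)
        W = ratio ** (-1.0 / (m - 1.0))
        U[rest] = W / W.sum(axis=1, keepdims=True)
    return U


def _objective(D: np.ndarray, U: np.ndarray, medoids: np.ndarray, m: float) -> float:
    return float(np.sum(U**m * D[:, medoids]))


def _update_medoids(D: np.ndarray, U: np.ndarray, m: float) -> tuple[np.ndarray, bool]:
    """Per-cluster exact medoid update with distinctness enforcement.

    Returns the medoid indices and whether a collision forced a cluster to
    its second-best candidate (only then may the objective fail to drop).
    """
    W = U**m                                    # n x k
    costs = W.T @ D                             # k x n: cost of every candidate
    k = U.shape[1]
    medoids = np.empty(k, dtype=int)
    taken: set[int] = set()
    collided = False
    for v in range(k):
        order = np.argsort(costs[v], kind="stable")
        for rank, cand in enumerate(order):
            if int(cand) not in taken:
                medoids[v] = int(cand)
                taken.add(int(cand))
                collided = collided or rank > 0
                break
    return medoids, collided


def fit_fuzzy_pam(
    D: DissimilarityMatrix | np.ndarray,
    k: int,
    m: float = 1.1,
    restarts: int = 50,
    seed: int | None = None,
    max_iter: int = 200,
    subject_ids: tuple[str, ...] | None = None,
) -> FuzzyPartition:
    """Fit a fuzzy k-medoid partition; best of ``restarts`` random starts.

    Each restart initializes k distinct random medoids and alternates exact
    membership and medoid updates until the medoid set repeats (fixed point
    or cycle).  The objective is verified non-increasing at every step.
    """
    Dm = D.d if isinstance(D, DissimilarityMatrix) else np.asarray(D, dtype=float)
    n = Dm.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"need 2 <= k < n, got k={k}, n={n}")
    if m <= 1:
        raise ValueError("fuzzifier must exceed 1")
    if not np.isfinite(Dm).all():
        raise ValueError("non-finite dissimilarities")
    rng = np.random.default_rng(seed)

    best: FuzzyPartition | None = None
    for _ in range(restarts):
        medoids = rng.choice(n, size=k, replace=False)
        seen = {tuple(sorted(medoids))}
        U = _memberships_for_medoids(Dm, medoids, m)
        J = _objective(Dm, U, medoids, m)
        run_best = (J, U, medoids.copy())
        for it in range(max_iter):
            new_medoids, collided = _update_medoids(Dm, U, m)
            U = _memberships_for_medoids(Dm, new_medoids, m)
            J_new = _objective(Dm, U, new_medoids, m)
            if collided and J_new > J:
                break  # distinctness constraint blocked the exact update
            assert J_new <= J + 1e-9, "objective increased during alternation"
            J = J_new
            if J < run_best[0]:
                run_best = (J, U.copy(), new_medoids.copy())
            key = tuple(sorted(new_medoids))
            medoids = new_medoids
            if key in seen:
                break
            seen.add(key)
        J, U, medoids = run_best
        if best is None or J < best.objective:
            best = FuzzyPartition(memberships=U, medoids=np.asarray(medoids),
                                  fuzzifier=m, objective=J,
                                  subject_ids=subject_ids, n_iter=it + 1)
    assert best is not None
    return best


@dataclass(frozen=True)
class PartitionMetrics:
    """Partition-coefficient validity indices for one value of k."""

    k: int
    f: float      # Dunn partition coefficient F(U)
    fc: float     # normalized: (k*F - 1)/(k - 1); hard=1, uniform=0
    d: float      # Kaufman distance coefficient D(U)
    dc: float     # normalized: D/(1 - 1/k); hard=0, uniform=1


def partition_metrics(partition: FuzzyPartition | np.ndarray) -> PartitionMetrics:
    """Dunn and Kaufman partition coefficients with their normalized forms."""
    U = partition.memberships if isinstance(partition, FuzzyPartition) else np.asarray(partition)
    n, k = U.shape
    if k < 2:
        raise ValueError("partition metrics need k >= 2")
    F = float(np.sum(U * U) / n)
    Fc = (k * F - 1.0) / (k - 1.0)
    hard = np.zeros_like(U)
    hard[np.arange(n), U.argmax(axis=1)] = 1.0
    Dk = float(np.sum((hard - U) ** 2) / n)
    Dc = Dk / (1.0 - 1.0 / k)
    return PartitionMetrics(k=k, f=F, fc=Fc, d=Dk, dc=Dc)


def choose_k(metrics: list[PartitionMetrics]) -> int:
    """Pick k maximizing Fc; warn when Dc's minimizer disagrees."""
    if not metrics:
        raise ValueError("empty metrics list")
    by_fc = max(metrics, key=lambda t: t.fc)
    by_dc = min(metrics, key=lambda t: t.dc)
    if by_fc.k != by_dc.k:
        log.warning("Fc maximizer k=%d disagrees with Dc minimizer k=%d",
                    by_fc.k, by_dc.k)
    return by_fc.k


@dataclass
class KSelection:
    best_k: int
    table: pd.DataFrame
    partitions: dict[int, FuzzyPartition]


def select_k(
    D: DissimilarityMatrix | np.ndarray,
    k_range: range | list[int],
    m: float = 1.1,
    restarts: int = 50,
    seed: int | None = None,
    subject_ids: tuple[str, ...] | None = None,
) -> KSelection:
    """Fit every k in range and select by the partition coefficients."""
    ks = list(k_range)
    if not ks:
        raise ValueError("empty k range")
    rng = np.random.default_rng(seed)
    partitions: dict[int, FuzzyPartition] = {}
    rows = []
    metrics: list[PartitionMetrics] = []
    for k in ks:
        part = fit_fuzzy_pam(D, k, m=m, restarts=restarts,
                             seed=int(rng.integers(2**31)),
                             subject_ids=subject_ids)
        met = partition_metrics(part)
        partitions[k] = part
        metrics.append(met)
        rows.append({"k": k, "F": met.f, "Fc": met.fc, "D": met.d, "Dc": met.dc,
                     "objective": part.objective})
    best = choose_k(metrics)
    return KSelection(best_k=best, table=pd.DataFrame(rows), partitions=partitions)


# ---------------------------------------------------------------------------
# perturbation analyses

def match_labels(reference: np.ndarray, candidate: np.ndarray,
                 k_ref: int | None = None, k_cand: int | None = None) -> dict[int, int]:
    """Optimal candidate->reference label mapping (Hungarian on confusion)."""
    k_ref = int(reference.max()) + 1 if k_ref is None else k_ref
    k_cand = int(candidate.max()) + 1 if k_cand is None else k_cand
    conf = np.zeros((k_cand, k_ref))
    for c, r in zip(candidate, reference):
        conf[c, r] += 1
    rows, cols = linear_sum_assignment(-conf)
    return {int(c): int(r) for c, r in zip(rows, cols)}


@dataclass
class PerturbationReport:
    mode: str
    n_retained: int
    n_changed: int
    changed_ids: tuple[str, ...]
    label_mapping: dict[int, int]


def perturbation_suite(
    D: DissimilarityMatrix,
    partition: FuzzyPartition,
    mode: str,
    arms: np.ndarray | None = None,
    arm: str | None = None,
    k_after: int | None = None,
    m: float = 1.1,
    restarts: int = 50,
    seed: int | None = None,
) -> PerturbationReport:
    """Re-cluster after removing subjects and count changed assignments.

    ``mode="drop_medoids"`` removes the k medoid subjects;
    ``mode="drop_arm"`` removes every subject of severity arm ``arm``
    (``k_after`` may reduce the cluster count when the arm's dominant
    cluster is expected to vanish).  Assignment changes are counted after
    optimal label matching.
    """
    n = partition.n
    if mode == "drop_medoids":
        removed = set(int(i) for i in partition.medoids)
    elif mode == "drop_arm":
        if arms is None or arm is None:
            raise ValueError("drop_arm needs per-subject arms and an arm name")
        removed = set(np.flatnonzero(np.asarray(arms) == arm).tolist())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    keep = np.array([i for i in range(n) if i not in removed], dtype=int)
    k_new = k_after if k_after is not None else partition.k
    if keep.size < 2 * k_new:
        raise ValueError("removal leaves too few subjects to re-cluster")
    if not removed:
        return PerturbationReport(mode=mode, n_retained=n, n_changed=0,
                                  changed_ids=(), label_mapping={v: v for v in range(partition.k)})

    sub = D.subset(keep)
    ids = (tuple(partition.subject_ids[i] for i in keep)
           if partition.subject_ids is not None else tuple(str(i) for i in keep))
    refit = fit_fuzzy_pam(sub, k_new, m=m, restarts=restarts, seed=seed,
                          subject_ids=ids)
    ref_labels = partition.hard_labels[keep]
    new_labels = refit.hard_labels
    mapping = match_labels(ref_labels, new_labels, k_ref=partition.k, k_cand=k_new)
    mapped = np.array([mapping[int(c)] for c in new_labels])
    changed = mapped != ref_labels
    return PerturbationReport(
        mode=mode,
        n_retained=int(keep.size),
        n_changed=int(changed.sum()),
        changed_ids=tuple(ids[i] for i in np.flatnonzero(changed)),
        label_mapping=mapping,
    )


# ---------------------------------------------------------------------------
# serialization

def partition_to_dict(partition: FuzzyPartition) -> dict:
    return {
        "fuzzifier": partition.fuzzifier,
        "objective": partition.objective,
        "medoids": [int(i) for i in partition.medoids],
        "medoid_subjects": (
            [partition.subject_ids[i] for i in partition.medoids]
            if partition.subject_ids is not None else None
        ),
        "subject_ids": list(partition.subject_ids) if partition.subject_ids else None,
        "memberships": partition.memberships.tolist(),
        "hard_labels": partition.hard_labels.tolist(),
    }


def partition_from_dict(doc: dict) -> FuzzyPartition:
    return FuzzyPartition(
        memberships=np.asarray(doc["memberships"], dtype=float),
        medoids=np.asarray(doc["medoids"], dtype=int),
        fuzzifier=float(doc["fuzzifier"]),
        objective=float(doc["objective"]),
        subject_ids=tuple(doc["subject_ids"]) if doc.get("subject_ids") else None,
    )
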
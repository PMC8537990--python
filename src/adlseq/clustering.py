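"""Partitioning days around medoids and evaluating the partitions.

Days live in no vector space — only their pairwise distances are known —
so clustering uses medoids: the partition "center" is one of its own
members.  The Partitioning Around Medoids (PAM) algorithm is run in two
phases: k random initial medoids with nearest-medoid assignment, then
repeated evaluation of all medoid/non-medoid swaps, applying only the
single best strictly-improving swap per iteration until no swap improves
the total cost (sum of distances of every day to its medoid).

Partition agreement is scored with the plain Rand index: the fraction of
day pairs on which two partitionings agree (together in both, or apart in
both).  Note the index tends to sit close to 1 even for unrelated
partitionings, so values must be read comparatively.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .metrics import DistanceMatrix

__all__ = ["Partitioning", "pam", "brute_force_medoids", "reorder",
           "rand_index", "partition_summary", "write_partitioning",
           "read_partitioning"]


@dataclass
class Partitioning:
    """k partitions of day labels, each represented by a medoid day."""

    k: int
    assignment: dict  # day label -> partition id (0-based)
    medoids: tuple    # partition id -> medoid day label
    cost: float

    def members(self, pid: int) -> list:
        return [lab for lab, p in self.assignment.items() if p == pid]

    @property
    def labels(self) -> tuple:
        return tuple(self.assignment)

    def validate(self) -> None:
        if len(self.medoids) != self.k:
            raise ValueError("one medoid per partition is required")
        for pid, med in enumerate(self.medoids):
            if self.assignment.get(med) != pid:
                raise ValueError(f"medoid {med!r} is not assigned to its partition {pid}")


def _assign(D: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    """Nearest-medoid assignment; ties go to the lowest partition id."""
    sub = D[:, medoids]                     # m x k
    part = np.argmin(sub, axis=1)           # argmin takes the first minimum
    cost = float(sub[np.arange(len(D)), part].sum())
    return part, cost


def _pam_single(D: np.ndarray, k: int, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    """Swap phase from a given initial medoid set; returns (medoids, cost)."""
    m = len(D)
    medoids = np.sort(medoids)
    _, cost = _assign(D, medoids)
    while True:
        best = None
        non_medoids = [h for h in range(m) if h not in set(medoids.tolist())]
        for mi in range(k):
            for h in non_medoids:
                cand = medoids.copy()
                cand[mi] = h
                _, c = _assign(D, cand)
                if c < cost - 1e-12 and (best is None or c < best[0] - 1e-12):
                    best = (c, mi, h)
        if best is None:
            return np.sort(medoids), cost
        cost, mi, h = best
        medoids[mi] = h


def pam(D: DistanceMatrix, k: int, seed: int = 0,
        restarts: int | str = 10) -> Partitioning:
    """Cluster the days of a distance matrix into k partitions around medoids.

    Runs the build/swap procedure from *restarts* seeded random initial
    medoid sets (seeds ``seed .. seed+restarts-1``) and keeps the
    lowest-cost result; ``restarts="all"`` enumerates every possible
    initial medoid set instead (exact for small m).  All ties break toward
    the lowest day index, so the result is a pure function of (matrix,
    seed).  Partition ids follow ascending medoid day order.
    """
    mat = D.matrix
    m = D.n
    if not 1 <= k <= m:
        raise ValueError(f"k must lie in [1, {m}], got {k}")
    best: tuple[float, tuple] | None = None
    if restarts == "all":
        inits = (np.array(c) for c in itertools.combinations(range(m), k))
    else:
        if restarts < 1:
            raise ValueError("restarts must be positive")
        rngs = [np.random.default_rng(seed + r) for r in range(restarts)]
        inits = (rng.choice(m, size=k, replace=False) for rng in rngs)
    for init in inits:
        medoids, cost = _pam_single(mat, k, np.asarray(init))
        key = (cost, tuple(medoids.tolist()))
        if best is None or key < best:
            best = key
    cost, medoids = best[0], np.array(best[1])
    part, cost = _assign(mat, medoids)
    assignment = {D.labels[i]: int(part[i]) for i in range(m)}
    return Partitioning(k, assignment, tuple(D.labels[j] for j in medoids), cost)


def brute_force_medoids(D: DistanceMatrix, k: int) -> Partitioning:
    """Exact optimum over all C(m, k) medoid sets; oracle for small m."""
    mat = D.matrix
    m = D.n
    best = None
    for comb in itertools.combinations(range(m), k):
        _, cost = _assign(mat, np.array(comb))
        key = (cost, comb)
        if best is None or key < best:
            best = key
    cost, medoids = best[0], np.array(best[1])
    part, cost = _assign(mat, medoids)
    assignment = {D.labels[i]: int(part[i]) for i in range(m)}
    return Partitioning(k, assignment, tuple(D.labels[j] for j in medoids), cost)


def reorder(D: DistanceMatrix, P: Partitioning) -> tuple[DistanceMatrix, list[int]]:
    """Block-order a matrix by partition for display.

    Rows/columns are permuted so each partition's days are consecutive
    (partitions in ascending id, days within a partition in original
    order).  Returns the reordered matrix and the boundary indices between
    blocks (for frame drawing); idempotent on already block-ordered input.
    """
    if set(P.assignment) != set(D.labels):
        raise ValueError("partitioning labels do not match matrix labels")
    order: list[int] = []
    boundaries: list[int] = []
    for pid in range(P.k):
        members = [i for i, lab in enumerate(D.labels) if P.assignment[lab] == pid]
        order.extend(members)
        boundaries.append(len(order))
    idx = np.array(order)
    out = DistanceMatrix(tuple(D.labels[i] for i in order),
                         D.matrix[np.ix_(idx, idx)], D.metric, dict(D.params))
    return out, boundaries[:-1]


def rand_index(P1: Partitioning, P2: Partitioning) -> float:
    """Fraction of day pairs on which two partitionings agree, in [0, 1].

    Counts pairs placed together in both partitionings (Ns) plus pairs
    separated in both (Nd), over all C(m, 2) pairs; equals 1 exactly when
    the partitionings are identical.
    """
    labels = sorted(P1.assignment, key=str)
    if set(labels) != set(P2.assignment):
        raise ValueError("partitionings cover different day labels")
    m = len(labels)
    if m < 2:
        raise ValueError("at least two days are required")
    agree = 0
    for a, b in itertools.combinations(labels, 2):
        same1 = P1.assignment[a] == P1.assignment[b]
        same2 = P2.assignment[a] == P2.assignment[b]
        agree += same1 == same2
    return agree / (m * (m - 1) // 2)


def partition_summary(D: DistanceMatrix, P: Partitioning):
    """Average pairwise distances overall and within each partition.

    Returns a DataFrame with one row for the all-days average, one per
    partition (NaN for singletons, printed as "/" in the source tables),
    and a final row averaging the defined per-partition values.
    """
    import pandas as pd

    if set(P.assignment) != set(D.labels):
        raise ValueError("partitioning labels do not match matrix labels")
    mat = D.matrix
    m = D.n
    iu = np.triu_indices(m, k=1)
    rows = [("All days", float(mat[iu].mean()), m)]
    per_part = []
    for pid in range(P.k):
        idx = [i for i, lab in enumerate(D.labels) if P.assignment[lab] == pid]
        if len(idx) < 2:
            rows.append((f"Partition {pid + 1}", float("nan"), len(idx)))
            continue
        sub = mat[np.ix_(idx, idx)]
        avg = float(sub[np.triu_indices(len(idx), k=1)].mean())
        rows.append((f"Partition {pid + 1}", avg, len(idx)))
        per_part.append(avg)
    rows.append(("Partition average",
                 float(np.mean(per_part)) if per_part else float("nan"), m))
    return pd.DataFrame(rows, columns=["group", "average_distance", "n_days"])


def write_partitioning(P: Partitioning, path) -> None:
    """Write a partitioning as TSV: day label, partition id, is_medoid."""
    medoids = set(P.medoids)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("day\tpartition\tis_medoid\n")
        for lab, pid in P.assignment.items():
            fh.write(f"{lab}\t{pid}\t{int(lab in medoids)}\n")


def read_partitioning(path, D: DistanceMatrix | None = None) -> Partitioning:
    """Read a partitioning written by :func:`write_partitioning`.

    The stored cost is not serialised; it is recomputed when a matching
    distance matrix is given, else set to NaN.
    """
    assignment: dict = {}
    medoids: dict[int, object] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["day", "partition", "is_medoid"]:
            raise ValueError(f"{path}: unexpected header {header}")
        for line in fh:
            lab, pid, is_med = line.rstrip("\n").split("\t")
            try:
                lab = int(lab)
            except ValueError:
                pass
            assignment[lab] = int(pid)
            if int(is_med):
                medoids[int(pid)] = lab
    k = max(assignment.values()) + 1
    meds = tuple(medoids[p] for p in range(k))
    cost = float("nan")
    if D is not None:
        pos = {lab: i for i, lab in enumerate(D.labels)}
        cost = sum(D.matrix[pos[lab], pos[meds[pid]]] for lab, pid in assignment.items())
    return Partitioning(k, assignment, meds, cost)
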
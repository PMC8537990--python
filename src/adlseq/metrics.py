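"""Pairwise day-comparison metrics for activity and sensor sequences.

Days are compared either position-by-position (the Hamming family, on
full-length per-second vectors) or as order-only sequences (cost-weighted
Levenshtein, on compressed vectors with consecutive repeats merged).

The Hamming family sums a per-slot difference function:

* ``H1`` — plain 0/1 set (in)equality;
* ``H2`` — a fixed reduced cost in [0, 1] when the mismatching activities
  are *adjacent*, i.e. observed consecutively at least once anywhere in
  the dataset (think "meal preparation" followed by "eating");
* ``H3`` — like H2 but with the cost derived from observed transition
  rates, ``cost(a, b) = 1 − ½·p(a|b) − ½·p(b|a)``, so frequently
  interchanged activities mismatch cheaply.

The sensor-slot difference allows incomplete matching: two sensor sets
agree when twice their intersection exceeds ``ε`` times the sum of their
sizes, absorbing noisy or missing sensor firings.

All distances here are symmetric, zero on identical inputs, and — for
mismatch costs in [0, 1] — dominated by H1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .io_preprocess import DailyActivityVector, DailySensorVector

__all__ = [
    "AdjacencyRelation", "TransitionModel", "CompressedActivitySequence",
    "DistanceMatrix", "diff_sensor", "diff_simple", "diff_generalized",
    "hamming", "build_adjacency", "estimate_transitions", "compress",
    "levenshtein", "sim_hamming", "sim_levenshtein", "pairwise_matrix",
]


# ---------------------------------------------------------------------------
# per-slot difference functions
# ---------------------------------------------------------------------------

def diff_sensor(si: frozenset, qi: frozenset, epsilon: float) -> int:
    """0/1 difference between two active-sensor sets with ε-slack.

    Returns 0 (match) iff ``2·|si ∩ qi| > ε·(|si| + |qi|)``; two empty
    sets (both slots idle) also count as a match, and equal sets always
    match so the induced distance satisfies d(a, a) = 0 even at ε = 1.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon must lie in [0, 1], got {epsilon}")
    if si == qi:
        return 0
    return 0 if 2 * len(si & qi) > epsilon * (len(si) + len(qi)) else 1


def diff_simple(ai: frozenset, bi: frozenset) -> int:
    """Plain 0/1 difference: activity sets are equal or they are not (H1)."""
    if not ai or not bi:
        raise ValueError("activity sets must be nonempty")
    return 0 if ai == bi else 1


def diff_generalized(ai: frozenset, bi: frozenset,
                     adjacency: "AdjacencyRelation | None",
                     cost: "float | TransitionModel" = 0.5,
                     overlap_is_match: bool = False) -> float:
    """Activity-set difference with a reduced cost for adjacent mismatches.

    Equal sets cost 0.  Otherwise, if any cross pair of members (one from
    each set) is adjacent, the mismatch costs *cost*; with a
    :class:`TransitionModel` as *cost*, the cheapest cost among the holding
    adjacent pairs is charged.  Everything else costs 1.

    ``overlap_is_match=True`` additionally treats unequal sets that share a
    member as a match (cost 0); by default they are scored through the
    adjacency cases like any other unequal pair.
    """
    if not 1 <= len(ai) <= 2 or not 1 <= len(bi) <= 2:
        raise ValueError(f"activity sets must have size 1 or 2, got {len(ai)} and {len(bi)}")
    if ai == bi:
        return 0.0
    if overlap_is_match and ai & bi:
        return 0.0
    model = cost if isinstance(cost, TransitionModel) else None
    if adjacency is None:
        if model is None:
            raise ValueError("an adjacency relation or a TransitionModel is required")
        adjacency = model.adjacency
    holding = [(a, b) for a in ai for b in bi if a != b and adjacency.adjacent(a, b)]
    if not holding:
        return 1.0
    if model is None:
        if not 0.0 <= cost <= 1.0:
            raise ValueError(f"cost must lie in [0, 1], got {cost}")
        return float(cost)
    return min(model.cost(a, b) for a, b in holding)


# ---------------------------------------------------------------------------
# adjacency and transition statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdjacencyRelation:
    """Symmetric relation over activities observed consecutively at least once."""

    pairs: frozenset  # frozenset of frozenset({a, b}) with a != b

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AdjacencyRelation":
        out = set()
        for a, b in pairs:
            if a == b:
                raise ValueError(f"self-adjacency {a!r} is not allowed")
            out.add(frozenset((a, b)))
        return cls(frozenset(out))

    def adjacent(self, a: str, b: str) -> bool:
        return a != b and frozenset((a, b)) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


def _set_transitions(prev: frozenset, cur: frozenset) -> Iterable[tuple[str, str]]:
    """Directed member transitions between consecutive compressed slots.

    Each member of the predecessor set transitions to each member of the
    successor set that is not already in the predecessor set; members
    common to both sets contribute nothing (they did not change).
    """
    for b in cur:
        if b in prev:
            continue
        for a in prev:
            if a != b:
                yield a, b


@dataclass
class TransitionModel:
    """Pooled activity transition counts, probabilities and symmetric costs.

    ``p(b|a)`` is the pooled fraction of a's outgoing transitions that go
    to b (0 when a has none); the mismatch cost is
    ``1 − ½·p(a|b) − ½·p(b|a)``, clipped to [0, 1] by construction.  Pairs
    with no transitions in either direction cost 1.
    """

    counts: dict = field(default_factory=dict)   # (a, b) -> pooled count
    totals: dict = field(default_factory=dict)   # a -> pooled outgoing count

    def prob(self, b: str, a: str) -> float:
        """Transition probability p(b | a)."""
        total = self.totals.get(a, 0)
        if total == 0:
            return 0.0
        return self.counts.get((a, b), 0) / total

    def cost(self, a: str, b: str) -> float:
        return 1.0 - 0.5 * self.prob(a, b) - 0.5 * self.prob(b, a)

    @property
    def adjacency(self) -> AdjacencyRelation:
        return AdjacencyRelation(frozenset(
            frozenset((a, b)) for (a, b), c in self.counts.items() if c > 0))


def compress(day: DailyActivityVector) -> "CompressedActivitySequence":
    """Merge consecutive equal activity sets, discarding durations."""
    slots = day.slots
    if len(slots) == 0:
        return CompressedActivitySequence(day.day_index, ())
    out = [slots[0]]
    for s in slots[1:]:
        if s != out[-1]:
            out.append(s)
    return CompressedActivitySequence(day.day_index, tuple(out))


@dataclass(frozen=True)
class CompressedActivitySequence:
    """A day's activity sets with consecutive duplicates merged."""

    day_index: int
    elements: tuple  # tuple of frozenset

    def __post_init__(self) -> None:
        for prev, cur in zip(self.elements, self.elements[1:]):
            if prev == cur:
                raise ValueError("consecutive equal elements are not allowed")

    def __len__(self) -> int:
        return len(self.elements)


def _compressed(days: Sequence) -> list[CompressedActivitySequence]:
    return [d if isinstance(d, CompressedActivitySequence) else compress(d) for d in days]


def build_adjacency(days: Sequence) -> AdjacencyRelation:
    """Adjacency over all activities seen consecutively anywhere in *days*."""
    if not days:
        raise ValueError("at least one day is required")
    pairs = set()
    for seq in _compressed(days):
        for prev, cur in zip(seq.elements, seq.elements[1:]):
            for a, b in _set_transitions(prev, cur):
                pairs.add(frozenset((a, b)))
    return AdjacencyRelation(frozenset(pairs))


def estimate_transitions(days: Sequence) -> TransitionModel:
    """Pool per-day transition counts over compressed sequences."""
    if not days:
        raise ValueError("at least one day is required")
    counts: dict[tuple[str, str], int] = {}
    totals: dict[str, int] = {}
    for seq in _compressed(days):
        for prev, cur in zip(seq.elements, seq.elements[1:]):
            for a, b in _set_transitions(prev, cur):
                counts[(a, b)] = counts.get((a, b), 0) + 1
                totals[a] = totals.get(a, 0) + 1
    return TransitionModel(counts, totals)


# ---------------------------------------------------------------------------
# Hamming family
# ---------------------------------------------------------------------------

def _encode(slot_arrays: Sequence[np.ndarray]) -> tuple[list[np.ndarray], list[frozenset]]:
    """Map slot sets to integer codes (equal sets share a code)."""
    table: dict[frozenset, int] = {}
    coded = []
    for slots in slot_arrays:
        out = np.empty(len(slots), dtype=np.intp)
        for i, s in enumerate(slots):
            code = table.get(s)
            if code is None:
                code = table[s] = len(table)
            out[i] = code
        coded.append(out)
    alphabet = [None] * len(table)
    for s, c in table.items():
        alphabet[c] = s
    return coded, alphabet


def hamming(a, b, diff: Callable[[frozenset, frozenset], float]) -> float:
    """Sum the per-slot difference function over two equal-length vectors.

    With :func:`diff_simple` this is H1, with :func:`diff_generalized` and
    a fixed cost H2, with transition-derived costs H3.  The slot sets are
    factorised to integer codes first, so *diff* is evaluated once per
    distinct pair of sets rather than once per slot.
    """
    sa, sb = a.slots, b.slots
    if len(sa) != len(sb):
        raise ValueError(f"Hamming distance needs equal lengths, got {len(sa)} and {len(sb)}")
    (ca, cb), alphabet = _encode([sa, sb])
    pair = ca * np.intp(len(alphabet)) + cb
    uniq, inverse = np.unique(pair, return_inverse=True)
    k = len(alphabet)
    vals = np.array([diff(alphabet[p // k], alphabet[p % k]) for p in uniq], dtype=float)
    return float(vals[inverse].sum())


def sim_hamming(a, b, H: float | None = None, *,
                diff: Callable | None = None) -> float:
    """Similarity ``1 − H/n`` on a 0-to-1 scale for equal-length vectors."""
    n = len(a.slots)
    if n == 0:
        raise ValueError("similarity is undefined for empty vectors")
    if H is None:
        H = hamming(a, b, diff if diff is not None else diff_simple)
    return 1.0 - H / n


# ---------------------------------------------------------------------------
# Levenshtein on compressed sequences
# ---------------------------------------------------------------------------

def levenshtein(x, y, cost_insert: float = 1.0, cost_delete: float = 1.0,
                cost_substitute: float = 2.0) -> float:
    """Minimum edit cost between two compressed sequences.

    Classic dynamic program over insertions, deletions and substitutions
    with configurable costs (defaults 1/1/2); element equality is set
    equality, so concurrent-activity sets compare as whole sets.
    """
    if min(cost_insert, cost_delete, cost_substitute) < 0:
        raise ValueError("edit costs must be nonnegative")
    ex = x.elements if isinstance(x, CompressedActivitySequence) else tuple(x)
    ey = y.elements if isinstance(y, CompressedActivitySequence) else tuple(y)
    prev = np.arange(len(ey) + 1, dtype=float) * cost_insert
    for i, xe in enumerate(ex, start=1):
        cur = np.empty(len(ey) + 1)
        cur[0] = i * cost_delete
        for j, ye in enumerate(ey, start=1):
            cur[j] = min(prev[j] + cost_delete,
                         cur[j - 1] + cost_insert,
                         prev[j - 1] + (0.0 if xe == ye else cost_substitute))
        prev = cur
    return float(prev[-1])


def sim_levenshtein(x, y, L: float | None = None, **costs) -> float:
    """Similarity ``1 − L/max(|x|, |y|)`` on a 0-to-1 scale.

    Two empty sequences are identical (similarity 1).  With unit edit
    costs the raw expression already lies in [0, 1]; a substitution cost
    above ``costI`` keeps it meaningful but lets it dip below 0 on
    substitution-heavy pairs (e.g. two unequal one-element sequences at
    the default 1/1/2 costs), so the value is clamped at 0 to stay a
    similarity scale.
    """
    nx = len(x.elements if isinstance(x, CompressedActivitySequence) else x)
    ny = len(y.elements if isinstance(y, CompressedActivitySequence) else y)
    if nx == 0 and ny == 0:
        return 1.0
    if L is None:
        L = levenshtein(x, y, **costs)
    return max(0.0, 1.0 - L / max(nx, ny))


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric day-by-day distances under a named metric."""

    labels: tuple
    matrix: np.ndarray
    metric: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.labels):
            raise ValueError("matrix must be square with one row per label")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_tsv(self, path: str | Path) -> None:
        """Write the matrix (labels as first row/column) plus a `.meta` sidecar."""
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(["day", *map(str, self.labels)]) + "\n")
            for lab, row in zip(self.labels, self.matrix):
                fh.write("\t".join([str(lab), *(format(v, ".10g") for v in row)]) + "\n")
        with open(path.with_suffix(path.suffix + ".meta"), "w", encoding="utf-8") as fh:
            fh.write(f"metric\t{self.metric}\n")
            for key, val in sorted(self.params.items()):
                fh.write(f"{key}\t{val}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        path = Path(path)
        def coerce(lab: str):
            try:
                return int(lab)
            except ValueError:
                return lab

        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            labels = tuple(coerce(l) for l in header[1:])
            rows = []
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                rows.append([float(v) for v in fields[1:]])
        metric, params = "unknown", {}
        meta = path.with_suffix(path.suffix + ".meta")
        if meta.exists():
            for line in meta.read_text(encoding="utf-8").splitlines():
                key, _, val = line.partition("\t")
                if key == "metric":
                    metric = val
                else:
                    try:
                        params[key] = float(val)
                    except ValueError:
                        params[key] = val
        return cls(labels, np.array(rows), metric, params)


def _pairwise(slot_arrays: list[np.ndarray], diff: Callable) -> np.ndarray:
    """Dense pairwise Hamming-family matrix via shared set codes.

    All days are factorised against one code table; the per-slot difference
    is then a table lookup, so each day pair costs one fancy-indexed sum.
    """
    coded, alphabet = _encode(slot_arrays)
    k = len(alphabet)
    table = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        table[i, j] = table[j, i] = diff(alphabet[i], alphabet[j])
    m = len(coded)
    out = np.zeros((m, m))
    for i, j in itertools.combinations(range(m), 2):
        out[i, j] = out[j, i] = table[coded[i], coded[j]].sum()
    return out


def pairwise_matrix(days: Sequence, metric: str = "H1", *,
                    epsilon: float = 0.7, cost: float = 0.5,
                    adjacency: AdjacencyRelation | None = None,
                    transitions: TransitionModel | None = None,
                    cost_insert: float = 1.0, cost_delete: float = 1.0,
                    cost_substitute: float = 2.0,
                    overlap_is_match: bool = False) -> DistanceMatrix:
    """Distance matrix between all day pairs under a named metric.

    Metrics: ``H1`` (plain Hamming), ``H2`` (fixed adjacency cost), ``H3``
    (transition-derived costs), ``LEV`` (weighted Levenshtein on compressed
    sequences), ``SENSOR`` (ε-relaxed Hamming on sensor vectors).  For H2/H3
    the adjacency/transition statistics are estimated from *days* unless
    supplied.  Hamming-family metrics require equal-length days.
    """
    metric = metric.upper()
    if len(days) < 2:
        raise ValueError("at least two days are required")
    labels = tuple(d.day_index for d in days)
    params: dict = {}

    if metric in ("H1", "H2", "H3", "SENSOR"):
        slot_arrays = [d.slots for d in days]
        lengths = {len(s) for s in slot_arrays}
        if len(lengths) != 1:
            raise ValueError(f"Hamming-family metrics need equal-length days, got {lengths}")
        if metric == "H1":
            diff = diff_simple
        elif metric == "H2":
            adj = adjacency if adjacency is not None else build_adjacency(days)
            params["cost"] = cost
            diff = lambda a, b: diff_generalized(a, b, adj, cost, overlap_is_match)
        elif metric == "H3":
            model = transitions if transitions is not None else estimate_transitions(days)
            diff = lambda a, b: diff_generalized(a, b, None, model, overlap_is_match)
        else:  # SENSOR
            params["epsilon"] = epsilon
            diff = lambda a, b: diff_sensor(a, b, epsilon)
        mat = _pairwise(slot_arrays, diff)
    elif metric == "LEV":
        seqs = _compressed(days)
        params.update(cost_insert=cost_insert, cost_delete=cost_delete,
                      cost_substitute=cost_substitute)
        m = len(seqs)
        mat = np.zeros((m, m))
        for i, j in itertools.combinations(range(m), 2):
            mat[i, j] = mat[j, i] = levenshtein(
                seqs[i], seqs[j], cost_insert, cost_delete, cost_substitute)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(labels, mat, metric, params)
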
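"""Per-slot predictability of activities across days.

For each time-of-day slot, the Shannon entropy of the activity observed
there over all days measures how routine that moment is: 0 bits when the
resident always does the same thing, up to ``log2 A`` bits (A = alphabet
size) when all activities are equally likely.  A first-order conditional
variant asks how uncertain the slot remains once the previous slot's
activity is known; for a resident with momentum (activities persist and
follow habitual orders) it is much lower.

Entropy is computed on coarsened vectors by default — half-minute slots,
so a day shrinks from 86,400 to 2,880 slots — with an activity marked
present in a coarse slot if it occupies at least one second of it.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np

from .io_preprocess import IDLE, SECONDS_PER_DAY, DailyActivityVector, DailySensorVector

__all__ = ["EntropyProfile", "resize", "slot_distribution", "entropy_profile",
           "conditional_entropy_profile", "average_entropy", "max_entropy"]

DEFAULT_ENTROPY_SLOT_SECONDS = 30


@dataclass
class EntropyProfile:
    """Per-slot entropy values (bits) across days, at a fixed slot duration."""

    values: np.ndarray
    slot_seconds: int
    conditional: bool
    alphabet_size: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def max_bits(self) -> float:
        return max_entropy(self.alphabet_size)


def max_entropy(alphabet_size: int) -> float:
    """Upper bound log2(A) bits on per-slot entropy for an A-letter alphabet."""
    if alphabet_size < 1:
        raise ValueError("alphabet size must be positive")
    return float(np.log2(alphabet_size))


def resize(day, factor: int, idle_label: str | None = IDLE):
    """Coarsen a daily vector by merging *factor* consecutive slots.

    The coarse slot's set is the union of the fine sets it covers; an
    activity is present if present in at least one covered slot.  The idle
    label is dropped from the union whenever a real activity is present
    (*idle_label=None* skips that rule, e.g. for sensor vectors).
    """
    n = len(day.slots)
    if factor < 1 or n % factor:
        raise ValueError(f"factor {factor} must divide the day length {n}")
    if factor == 1:
        return day
    coarse = np.empty(n // factor, dtype=object)
    cache: dict[frozenset, frozenset] = {}
    slots = day.slots
    for i in range(len(coarse)):
        block = slots[i * factor:(i + 1) * factor]
        first = block[0]
        union = set(first)
        for s in block[1:]:
            if s is not first and s != first:
                union.update(s)
        fs = frozenset(union)
        if idle_label is not None and len(fs) > 1 and idle_label in fs:
            fs = fs - {idle_label}
        coarse[i] = cache.setdefault(fs, fs)
    cls = type(day)
    return cls(day.day_index, coarse)


# ---------------------------------------------------------------------------
# distributions and entropies
# ---------------------------------------------------------------------------

def slot_distribution(days, i: int) -> dict[str, float]:
    """Empirical activity distribution at slot *i* pooled over days.

    Each activity present in a day's slot counts once; counts are
    normalised by the total number of presences so the probabilities sum
    to 1 even when concurrent activities occur.
    """
    if not days:
        raise ValueError("at least one day is required")
    counts: Counter = Counter()
    for day in days:
        counts.update(day.slots[i])
    total = sum(counts.values())
    return {a: c / total for a, c in counts.items()}


def _entropy_bits(probs) -> float:
    p = np.asarray([v for v in probs if v > 0], dtype=float)
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def _alphabet_size(days, alphabet) -> int:
    if alphabet is not None:
        return len(alphabet)
    seen = set()
    for day in days:
        for s in set(day.slots.tolist()):
            seen.update(s)
    return len(seen)


def entropy_profile(days, alphabet=None) -> EntropyProfile:
    """Per-slot Shannon entropy h_i in bits, pooled over days.

    ``0·log 0`` is taken as 0, so h_i = 0 exactly when the slot is fully
    predictable.  *alphabet* fixes the alphabet size recorded on the
    profile (defaults to the activities observed in *days*).
    """
    n = len(days[0].slots)
    values = np.empty(n)
    for i in range(n):
        values[i] = _entropy_bits(slot_distribution(days, i).values())
    return EntropyProfile(values, SECONDS_PER_DAY // n, conditional=False,
                          alphabet_size=_alphabet_size(days, alphabet))


def conditional_entropy_profile(days, alphabet=None) -> EntropyProfile:
    """First-order conditional entropy h*_i given the previous slot.

    Joint counts over (previous-member, current-member) pairs are pooled
    across days, each pair weighted by 1/|previous set| so that the
    joint's current-slot marginal coincides with the presence distribution
    used by :func:`entropy_profile`; conditioning then can only reduce
    entropy, giving h*_i ≤ h_i at every slot.  Slot 0, which has no
    predecessor within the day, carries its unconditional entropy.
    """
    n = len(days[0].slots)
    values = np.empty(n)
    values[0] = _entropy_bits(slot_distribution(days, 0).values())
    for i in range(1, n):
        joint: defaultdict[tuple[str, str], float] = defaultdict(float)
        for day in days:
            prev, cur = day.slots[i - 1], day.slots[i]
            w = 1.0 / len(prev)
            for k in prev:
                for j in cur:
                    joint[(k, j)] += w
        total = sum(joint.values())
        prev_mass: defaultdict[str, float] = defaultdict(float)
        for (k, _j), w in joint.items():
            prev_mass[k] += w
        h = 0.0
        for k, mass in prev_mass.items():
            cond = [w / mass for (kk, _j), w in joint.items() if kk == k]
            h += (mass / total) * _entropy_bits(cond)
        values[i] = h
    return EntropyProfile(values, SECONDS_PER_DAY // n, conditional=True,
                          alphabet_size=_alphabet_size(days, alphabet))


def average_entropy(profile: EntropyProfile) -> float:
    """Arithmetic mean entropy over all slots of a profile, in bits."""
    if len(profile) == 0:
        raise ValueError("profile is empty")
    return float(np.mean(profile.values))


def write_profile(profile: EntropyProfile, path) -> None:
    """Write a profile as two-column text: slot start (seconds), bits."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("slot_start_seconds\tbits\n")
        for i, v in enumerate(profile.values):
            fh.write(f"{i * profile.slot_seconds}\t{v:.6f}\n")
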
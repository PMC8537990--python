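from datetime import datetime

import numpy as np
import pytest

from adlseq import (DailyActivityVector, Partitioning, vector_from_runs)
from adlseq.metrics import DistanceMatrix

A, B, C = "walk", "eat", "read"  # short activity alphabet for unit tests


def day_from_labels(labels, day_index=0):
    """Daily vector from a per-slot label (or label-set) list."""
    runs = [(lab if isinstance(lab, (set, frozenset, tuple)) else {lab}, 1)
            for lab in labels]
    return vector_from_runs(day_index, runs)


def partition_of(groups):
    """Partitioning from a list of label groups; first member is the medoid."""
    assignment = {}
    medoids = []
    for pid, group in enumerate(groups):
        medoids.append(group[0])
        for lab in group:
            assignment[lab] = pid
    return Partitioning(len(groups), assignment, tuple(medoids), float("nan"))


@pytest.fixture
def toy_matrix():
    """4 days: two tight pairs (d=1 inside) separated by distance 10."""
    m = np.full((4, 4), 10.0)
    np.fill_diagonal(m, 0.0)
    m[0, 1] = m[1, 0] = 1.0
    m[2, 3] = m[3, 2] = 1.0
    return DistanceMatrix((0, 1, 2, 3), m, "toy")


@pytest.fixture(scope="session")
def small_sim():
    """One deterministic 6-day simulated dataset, preprocessed, shared."""
    from adlseq import build_daily_vectors, default_config, generate_dataset
    from adlseq.synthetic_data import EPOCH

    sim = generate_dataset(default_config(n_days=6, seed=7))
    ds = build_daily_vectors(sim.sensor_events, sim.activity_intervals, origin=EPOCH)
    return sim, ds


def random_activity_day(rng, n=120, alphabet=(A, B, C), p_concurrent=0.2,
                        day_index=0):
    """Random set-valued daily vector with runs, for property tests."""
    runs = []
    remaining = n
    while remaining > 0:
        length = int(rng.integers(1, max(2, remaining // 2 + 1)))
        length = min(length, remaining)
        labels = {rng.choice(alphabet)}
        if rng.random() < p_concurrent:
            other = rng.choice(alphabet)
            if other not in labels:
                labels.add(other)
        runs.append((labels, length))
        remaining -= length
    return vector_from_runs(day_index, runs)
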
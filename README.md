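# adlseq

Discovering a resident's usual daily routines from smart-home data.

Ambient-assisted-living systems log binary sensor firings (motion, door,
pressure sensors) and annotated activities of daily living (ADL: sleeping,
cooking, toileting, ...). A caregiver cares less about any single event than
about *routine*: which kinds of days does this person have, and does a new day
still look like one of them? `adlseq` turns multi-day event logs into
per-second daily vectors, compares whole days with a family of sequence
distances, quantifies the predictability of each time of day with entropy,
and clusters days around medoids to expose the usual day types.

## The model

An *experiment day* runs from 04:00 to 04:00 (sleep brackets both ends) and
is represented at one-second resolution:

- a **daily activity vector** a⃗ = [a₁, …, aₙ], n = 86 400, where each aᵢ ⊂ A
  is the set of activities in effect (at most two concurrent; `"no activity"`
  when idle);
- a **daily sensor vector** s⃗ = [s₁, …, sₙ] of active-sensor sets sᵢ ⊂ S.

Days are compared with:

- **H1** — plain Hamming distance, H(a⃗, b⃗) = Σᵢ diff(aᵢ, bᵢ) with 0/1 set
  (in)equality;
- **H2** — generalized Hamming: mismatches between *adjacent* activities
  (observed consecutively at least once in the data, e.g. meal preparation →
  eating) cost a fixed value in [0, 1] instead of 1;
- **H3** — like H2 with data-driven costs, cost(a, b) = 1 − ½ p(a|b) − ½ p(b|a),
  where p(b|a) is the pooled empirical transition probability, so habitually
  interchanged activities mismatch cheaply;
- **LEV** — cost-weighted Levenshtein distance (costI = costD = 1, costS = 2)
  on *compressed* sequences (consecutive repeats merged), which compares the
  order of activities irrespective of timing and duration;
- **SENSOR** — Hamming on sensor vectors with ε-relaxed set matching: slots
  agree when 2·|sᵢ ∩ qᵢ| > ε·(|sᵢ| + |qᵢ|), absorbing sensor noise.

Per-slot predictability is profiled with Shannon entropy hᵢ =
−Σⱼ p(aᵢ,ⱼ) log₂ p(aᵢ,ⱼ) and its first-order conditional variant hᵢ*
(conditioning on the previous slot), computed on half-minute slots
(n = 2 880). Days are clustered with Partitioning Around Medoids (PAM) on the
distance matrix; partitionings are compared with the Rand index, and
within-partition average distances summarize how tight each routine is.

A synthetic-data module generates multi-day logs from configurable routine
profiles (schedule blocks with truncated-normal timing jitter, concurrent
overlays, per-second Bernoulli sensor emissions) with ground-truth day-type
labels, so the whole pipeline is testable without any external dataset.

## Worked example

```python
import numpy as np
from adlseq import (build_daily_vectors, default_config, generate_dataset,
                    pairwise_matrix, pam, rand_index, Partitioning)
from adlseq.entropy import average_entropy, entropy_profile, resize
from adlseq.synthetic_data import EPOCH

sim = generate_dataset(default_config(n_days=30, seed=7))   # 3 day types
ds = build_daily_vectors(sim.sensor_events, sim.activity_intervals, origin=EPOCH)
days = ds.activity_days["R1"]

coarse = [resize(d, 30) for d in days]                      # half-minute slots
h = entropy_profile(coarse, alphabet=ds.activity_alphabet)
print(f"avg entropy {average_entropy(h):.2f} bits (max {h.max_bits:.2f})")

D = pairwise_matrix(days, "H3")                             # transition-derived costs
P = pam(D, k=3, seed=0)
names = sorted(set(sim.labels))
truth = Partitioning(3, {i: names.index(l) for i, l in enumerate(sim.labels)},
                     (0, 1, 2), 0.0)
print(f"PAM cost {P.cost:.1f}, Rand vs ground truth {rand_index(P, truth):.3f}")
```

prints

```
avg entropy 0.94 bits (max 3.00)
PAM cost 69892.7, Rand vs ground truth 1.000
```

The 0.94-bit average says the simulated resident is fairly predictable at
most times of day (the bound for 8 activity labels is 3 bits); the Rand index
of 1.0 says the three recovered partitions coincide exactly with the three
generating routine profiles. Within-partition average H3 distances
(`partition_summary`) come out around 2 300–3 900 s versus 23 865 s over all
day pairs — days inside a routine are an order of magnitude closer to each
other than to days from other routines.

The same analysis runs from the shell:

```sh
adlseq simulate --n-days 30 --seed 7 --out-dir data/
adlseq preprocess --sensors data/sensors.tsv --activities data/activities.tsv --out wide.tsv
adlseq distance --in wide.tsv --metric H3 --out dist.tsv
adlseq cluster --in dist.tsv --k 3 --seed 0 --out parts.tsv
adlseq summary --matrix dist.tsv --partitions parts.tsv
adlseq plot --matrix dist.tsv --partitions parts.tsv --heatmap heat.png \
            --raster raster.png --wide wide.tsv
```

or end-to-end via `adlseq run --config pipeline.yaml`.

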
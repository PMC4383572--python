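"""Simulate a reference uterine time-course study and look at its structure.

The study has vehicle plus short-acting, long-acting and intermediate
estrogen-reference arms, each sampled at 2 h and 24 h with four replicates,
split over two batches.  Planted probes follow seven response archetypes;
the rest are noise.
"""

import estroscreen as es

cfg = es.SimConfig(n_probes=2000, probes_per_archetype=150, seed=1)
study = es.simulate_reference_study(cfg)

print(f"expression matrix: {study.expression.values.shape[0]} probes x "
      f"{study.expression.values.shape[1]} samples")
print(study.expression.metadata.groupby(["treatment", "time_hr"]).size())

# ground truth: how many probes follow each archetype
from collections import Counter
counts = Counter(a for a in study.probe_truth.values() if a)
print("\nplanted probes per archetype:")
for name, n in sorted(counts.items()):
    print(f"  {name}: {n}")
print(f"  (null probes: {sum(a is None for a in study.probe_truth.values())})")

# a planted transient_up probe responds at 2 h in every estrogen arm and is
# back at baseline by 24 h; the deviation below should be ~ +1 log2 unit
corrected = es.batch_correct(study.expression)
probe = next(p for p, a in study.probe_truth.items() if a == "transient_up")
for t in (2, 24):
    dev = es.deviation_from_vehicle(corrected, t, class_label="long_acting",
                                    probes=[probe])
    print(f"{probe} deviation from vehicle at {t:>2} h: {dev.iloc[0]:+.2f} log2 units")
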
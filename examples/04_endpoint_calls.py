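"""Ordinal response calls on the uterotrophic-bioassay endpoints.

Each endpoint effect (treated vs vehicle) is compared against the matching
reference-compound effect and converted to the conventional four-level
call: "-" none, "-/+" inconsistent, "+" moderate, "++" strong.  A
short-acting compound shows the expected profile: moderate proliferation
(EdU) at 24 h, elevated apoptosis (TUNEL) at 72 h, weak growth endpoints.
"""

import estroscreen as es

reference = es.simulate_reference_phenotypes(seed=1)
ref_effects = es.reference_effects_from_table(
    reference, {e.name: e.reference_class for e in es.default_endpoint_effects()})

compound = es.simulate_phenotypes("short_acting", seed=42, treatment="candidate")
calls = es.call_endpoints_for_compound(compound, "candidate", ref_effects)

print(f"{'endpoint':<18} {'call':<13} {'effect ratio':>12} {'p':>9}")
for c in calls:
    print(f"{c.endpoint:<18} {c.call:<10} {c.symbol:<3} {c.effect_ratio:>11.2f} "
          f"{c.p:>9.2e}")

print("\nThe effect ratio is relative to the long-acting reference effect"
      "\n(short-acting reference for TUNEL, where long-acting estrogens are"
      "\nsilent); calls gate on both significance and effect size.")
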
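"""Compound classification against panels and the endpoint scheme.

A test compound is scored on two transcriptional axes:

* **estrogenicity** — Pearson correlation between its 2-h panel-probe
  deviations (from vehicle) and the panel's estrogen-reference centroid
  direction, in [-1, 1];
* **longevity** — projection of its 24-h panel-probe deviations onto the
  panel's discriminant axis, affinely calibrated so the short-acting
  reference centroid maps to 0 and the long-acting centroid to 1.

These scores plus the ordinal endpoint calls are matched against a
three-row template scheme (non-estrogenic / short-acting / long-acting
expectations per endpoint slot, with "-/+" slots acting as wildcards) to
produce a final verdict: ``non_estrogenic``, ``short_acting``,
``long_acting`` or — when the evidence falls between the short and long
templates — ``intermediate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .endpoints import ResponseCall
from .errors import DataError, PanelError
from .panels import BiomarkerPanel
from .patterns import pearson_r

#: Endpoint slots of the scheme, in canonical order.
TEMPLATE_SLOTS = (
    "2h_rna_panel",
    "24h_edu",
    "24h_weight",
    "72h_weight",
    "24h_rna_panel",
    "72h_tunel",
    "72h_birc1a",
    "72h_ltf",
    "72h_leh",
)

#: Maps measured endpoints to template slots.
ENDPOINT_SLOTS = {
    "edu_pct_24h": "24h_edu",
    "weight_24h": "24h_weight",
    "weight_72h": "72h_weight",
    "tunel_pct_72h": "72h_tunel",
    "birc1a_fold_72h": "72h_birc1a",
    "ltf_fold_72h": "72h_ltf",
    "leh_72h": "72h_leh",
}

WILDCARD = "inconsistent_wildcard"
#: Calls an "-/+" template cell accepts.
WILDCARD_MATCHES = frozenset({"none", "inconsistent", "moderate"})


@dataclass(frozen=True)
class Table1Template:
    """Expected calls per class and slot; wildcard cells match -/+ evidence."""

    rows: Mapping[str, Mapping[str, str]]

    def expected(self, class_label: str, slot: str) -> str:
        return self.rows[class_label][slot]

    def matches(self, class_label: str, slot: str, call: str) -> bool:
        exp = self.expected(class_label, slot)
        if exp == WILDCARD:
            return call in WILDCARD_MATCHES
        return call == exp


def default_template() -> Table1Template:
    """The screen's scheme: per-class expectations for the nine slots."""
    short = {
        "2h_rna_panel": "moderate",
        "24h_edu": "moderate",
        "24h_weight": WILDCARD,
        "72h_weight": WILDCARD,
        "24h_rna_panel": WILDCARD,
        "72h_tunel": "moderate",
        "72h_birc1a": WILDCARD,
        "72h_ltf": WILDCARD,
        "72h_leh": WILDCARD,
    }
    long_ = {
        "2h_rna_panel": "moderate",
        "24h_edu": "strong",
        "24h_weight": "moderate",
        "72h_weight": "strong",
        "24h_rna_panel": "strong",
        "72h_tunel": "none",
        "72h_birc1a": "strong",
        "72h_ltf": "strong",
        "72h_leh": "strong",
    }
    none_row = {slot: "none" for slot in TEMPLATE_SLOTS}
    return Table1Template(rows={
        "non_estrogenic": none_row,
        "short_acting": short,
        "long_acting": long_,
    })


@dataclass(frozen=True)
class ClassifierThresholds:
    """Decision thresholds.

    ``tau_e`` gates estrogenicity; longevity below ``short_max`` is
    short-acting territory, above ``long_min`` long-acting, in between an
    explicit intermediate zone.
    """

    tau_e: float = 0.5
    short_max: float = 0.35
    long_min: float = 0.65
    rna_moderate: float = 0.25
    rna_strong: float = 0.75


@dataclass
class CompoundClassification:
    compound: str
    class_label: str
    estrogenicity_2h: Optional[float]
    longevity_24h: Optional[float]
    endpoint_calls: list[ResponseCall]
    slot_calls: dict[str, str]
    template_mismatches: dict[str, int]
    evidence: list[str]


# ---------------------------------------------------------------------------
# Panel scores
# ---------------------------------------------------------------------------

def _check_probes(test_deviation: pd.Series, panel: BiomarkerPanel) -> pd.Series:
    missing = [p for p in panel.probes if p not in test_deviation.index]
    if missing:
        raise DataError(f"test data missing panel probe(s): {missing[:5]}")
    return test_deviation.loc[panel.probes]


def estrogenicity_score(test_deviation_2h: pd.Series, panel_2h: BiomarkerPanel) -> float:
    """Correlation of the test 2-h deviations with the estrogen centroid.

    The centroid direction is ``centroid_b - centroid_a`` (for the default
    2-h panel, side A is vehicle so this is the estrogen-reference mean
    deviation itself).
    """
    x = _check_probes(test_deviation_2h, panel_2h)
    centroid = (panel_2h.centroid_b - panel_2h.centroid_a).loc[panel_2h.probes]
    return pearson_r(x.to_numpy(), centroid.to_numpy())


def longevity_score(test_deviation_24h: pd.Series, panel_24h: BiomarkerPanel) -> float:
    """Axis projection of 24-h deviations, calibrated short -> 0, long -> 1."""
    x = _check_probes(test_deviation_24h, panel_24h)
    axis = panel_24h.axis  # raises PanelError when centroids coincide
    a = float(panel_24h.centroid_a @ axis)
    b = float(panel_24h.centroid_b @ axis)
    if a == b:
        raise PanelError("degenerate panel: centroid projections coincide")
    return (float(x @ axis) - a) / (b - a)


def _rna_call(score: Optional[float], kind: str, th: ClassifierThresholds) -> Optional[str]:
    if score is None:
        return None
    if kind == "2h":
        return "moderate" if score >= th.tau_e else "none"
    # 24-h panel: the calibrated longevity score plays the role of the
    # effect ratio (0 = short reference, 1 = long reference)
    if score >= th.rna_strong:
        return "strong"
    if score >= th.rna_moderate:
        return "moderate"
    return "none"


# ---------------------------------------------------------------------------
# Final decision
# ---------------------------------------------------------------------------

def classify_compound(
    estrogenicity: Optional[float],
    longevity: Optional[float],
    endpoint_calls: Sequence[ResponseCall],
    template: Optional[Table1Template] = None,
    thresholds: Optional[ClassifierThresholds] = None,
    compound: str = "test",
) -> CompoundClassification:
    """Combine panel scores and endpoint calls into a class verdict.

    Decision: (1) a compound with sub-threshold estrogenicity and no
    moderate-or-strong endpoint call is non-estrogenic; (2) otherwise
    mismatches against the short- and long-acting template rows are
    counted (wildcards free; unavailable slots skipped); (3) a longevity
    score in the short (long) band whose row mismatches do not exceed the
    other row's yields short_acting (long_acting); (4) anything else —
    middle band, missing longevity, or score/template disagreement — is
    intermediate.  Unavailable slots reduce evidence but never raise.
    """
    template = template or default_template()
    th = thresholds or ClassifierThresholds()
    evidence: list[str] = []

    slot_calls: dict[str, Optional[str]] = {slot: None for slot in TEMPLATE_SLOTS}
    slot_calls["2h_rna_panel"] = _rna_call(estrogenicity, "2h", th)
    slot_calls["24h_rna_panel"] = _rna_call(longevity, "24h", th)
    for rc in endpoint_calls:
        slot = ENDPOINT_SLOTS.get(rc.endpoint)
        if slot is not None:
            slot_calls[slot] = rc.call
    available = {s: c for s, c in slot_calls.items() if c is not None}
    for s in TEMPLATE_SLOTS:
        if s not in available:
            evidence.append(f"slot {s}: unavailable")

    if estrogenicity is not None:
        evidence.append(f"estrogenicity_2h = {estrogenicity:.3f} (tau_e = {th.tau_e})")
    if longevity is not None:
        evidence.append(
            f"longevity_24h = {longevity:.3f} (short < {th.short_max}, long > {th.long_min})"
        )

    mismatches = {}
    for row in ("short_acting", "long_acting"):
        mismatches[row] = sum(
            0 if template.matches(row, s, c) else 1 for s, c in available.items()
        )
    evidence.append(
        f"template mismatches: short={mismatches['short_acting']}, long={mismatches['long_acting']}"
    )

    sub_threshold = estrogenicity is None or estrogenicity < th.tau_e
    no_response = all(c in ("none", "inconsistent") for c in available.values())
    if sub_threshold and no_response:
        evidence.append("no estrogenic evidence on any modality -> non_estrogenic")
        label = "non_estrogenic"
    elif (
        longevity is not None
        and longevity > th.long_min
        and mismatches["long_acting"] <= mismatches["short_acting"]
    ):
        evidence.append("longevity in long-acting band, template agrees -> long_acting")
        label = "long_acting"
    elif (
        longevity is not None
        and longevity < th.short_max
        and mismatches["short_acting"] <= mismatches["long_acting"]
    ):
        evidence.append("longevity in short-acting band, template agrees -> short_acting")
        label = "short_acting"
    else:
        if longevity is None:
            evidence.append("longevity undetermined -> intermediate by default")
        else:
            evidence.append("evidence between short- and long-acting templates -> intermediate")
        label = "intermediate"

    return CompoundClassification(
        compound=compound,
        class_label=label,
        estrogenicity_2h=estrogenicity,
        longevity_24h=longevity,
        endpoint_calls=list(endpoint_calls),
        slot_calls={s: c for s, c in slot_calls.items() if c is not None},
        template_mismatches=mismatches,
        evidence=evidence,
    )


def classification_to_json(c: CompoundClassification) -> dict:
    return {
        "compound": c.compound,
        "class": c.class_label,
        "estrogenicity_2h": c.estrogenicity_2h,
        "longevity_24h": c.longevity_24h,
        "slot_calls": c.slot_calls,
        "endpoint_calls": [
            {"endpoint": rc.endpoint, "call": rc.call,
             "effect_ratio": rc.effect_ratio, "p": rc.p}
            for rc in c.endpoint_calls
        ],
        "template_mismatches": c.template_mismatches,
        "evidence": c.evidence,
    }
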
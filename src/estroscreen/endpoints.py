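"""Statistics for phenotypic endpoints and ordinal response calls.

Group comparisons use one-way ANOVA machinery: Tukey's HSD (studentized-
range adjusted pairwise p-values, Tukey-Kramer form for unequal group
sizes) or Fisher's (unprotected) LSD, i.e. pairwise t tests on the pooled
ANOVA mean-square error.  Endpoint effects are converted to ordinal calls
(none / inconsistent / moderate / strong, conventionally rendered as
"-", "-/+", "+", "++") by comparing the treated-vs-vehicle effect to a
reference-compound effect: a call is *strong* when significant and at
least 75% of the reference effect, *moderate* when significant and at
least 25%, *inconsistent* when significance and effect size disagree,
and *none* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DesignError

CALL_LEVELS = ("none", "inconsistent", "moderate", "strong")
CALL_SYMBOLS = {"none": "-", "inconsistent": "-/+", "moderate": "+", "strong": "++"}


@dataclass(frozen=True)
class PairComparison:
    group_a: str
    group_b: str
    difference: float  # mean(b) - mean(a)
    statistic: float  # q for Tukey, t for LSD
    p: float


@dataclass(frozen=True)
class ResponseCall:
    """Ordinal response call for one endpoint."""

    endpoint: str
    call: str
    effect_ratio: float
    p: float

    @property
    def symbol(self) -> str:
        return CALL_SYMBOLS[self.call]


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, Mapping):
        out = {str(k): np.asarray(v, float) for k, v in groups.items()}
    else:
        out = {f"g{i + 1}": np.asarray(v, float) for i, v in enumerate(groups)}
    if len(out) < 2:
        raise DesignError("need at least 2 groups")
    for name, v in out.items():
        if v.size < 2:
            raise DesignError(f"group {name!r} needs at least 2 values")
    return out


def _pooled_mse(groups: dict[str, np.ndarray]) -> tuple[float, int]:
    df = sum(v.size - 1 for v in groups.values())
    ss = sum(float(((v - v.mean()) ** 2).sum()) for v in groups.values())
    return ss / df, df


def tukey_hsd(groups) -> list[PairComparison]:
    """All pairwise comparisons with studentized-range adjusted p-values.

    ``groups`` is a mapping label -> values or a sequence of value arrays.
    With zero pooled within-group variance, equal means give p = 1 and
    distinct means give p = 0 (degenerate flags).
    """
    gs = _as_groups(groups)
    mse, df = _pooled_mse(gs)
    k = len(gs)
    out = []
    for a, b in combinations(gs, 2):
        diff = float(gs[b].mean() - gs[a].mean())
        if mse == 0.0:
            q = 0.0 if diff == 0.0 else float("inf")
            p = 1.0 if diff == 0.0 else 0.0
        else:
            se = np.sqrt(mse / 2.0 * (1.0 / gs[a].size + 1.0 / gs[b].size))
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df))
        out.append(PairComparison(a, b, diff, float(q), min(max(p, 0.0), 1.0)))
    return out


def fisher_lsd(groups) -> list[PairComparison]:
    """Pairwise t tests on the pooled ANOVA MSE, unadjusted."""
    gs = _as_groups(groups)
    mse, df = _pooled_mse(gs)
    out = []
    for a, b in combinations(gs, 2):
        diff = float(gs[b].mean() - gs[a].mean())
        if mse == 0.0:
            t = 0.0 if diff == 0.0 else float("inf")
            p = 1.0 if diff == 0.0 else 0.0
        else:
            se = np.sqrt(mse * (1.0 / gs[a].size + 1.0 / gs[b].size))
            t = diff / se
            p = float(2.0 * stats.t.sf(abs(t), df))
        out.append(PairComparison(a, b, diff, float(t), min(max(p, 0.0), 1.0)))
    return out


def call_endpoint(
    treated_values: Sequence[float],
    vehicle_values: Sequence[float],
    reference_effect: float,
    alpha: float = 0.05,
    method: str = "tukey",
    endpoint: str = "",
    moderate_ratio: float = 0.25,
    strong_ratio: float = 0.75,
) -> ResponseCall:
    """Ordinal call for one endpoint, relative to a reference effect.

    ``reference_effect`` is the absolute reference-compound effect
    (|reference mean - vehicle mean|) for this endpoint and must be > 0.
    The call is direction-agnostic: effects are compared in absolute value.
    """
    if reference_effect <= 0:
        raise DataError(f"unusable reference effect {reference_effect!r} for endpoint {endpoint!r}")
    if method not in ("tukey", "lsd"):
        raise ValueError(f"method must be 'tukey' or 'lsd', got {method!r}")
    treated = np.asarray(treated_values, float)
    vehicle = np.asarray(vehicle_values, float)
    if treated.size < 3 or vehicle.size < 3:
        raise DesignError("need at least 3 animals per group")
    pairs = (tukey_hsd if method == "tukey" else fisher_lsd)(
        {"vehicle": vehicle, "treated": treated}
    )
    p = pairs[0].p
    ratio = abs(treated.mean() - vehicle.mean()) / reference_effect
    significant = p < alpha
    if significant and ratio >= strong_ratio:
        call = "strong"
    elif significant and ratio >= moderate_ratio:
        call = "moderate"
    elif (significant and ratio < moderate_ratio) or (not significant and ratio >= moderate_ratio):
        call = "inconsistent"
    else:
        call = "none"
    return ResponseCall(endpoint=endpoint, call=call, effect_ratio=float(ratio), p=float(p))


def reference_effects_from_table(
    phenotypes: pd.DataFrame,
    reference_class_by_endpoint: Mapping[str, str],
    treatment_by_class: Optional[Mapping[str, str]] = None,
) -> dict[str, float]:
    """Measure per-endpoint reference effects from a reference phenotype table.

    For each endpoint, the effect is |mean(reference arm) - mean(vehicle)|,
    where the reference arm is the treatment of the endpoint's declared
    reference class (long-acting for growth endpoints, short-acting for
    TUNEL).  ``treatment_by_class`` maps class labels to treatment labels
    (defaults to ``<class>_ref``).
    """
    treatment_by_class = dict(treatment_by_class or {
        "long_acting": "long_acting_ref",
        "short_acting": "short_acting_ref",
    })
    out = {}
    for endpoint, ref_class in reference_class_by_endpoint.items():
        arm = treatment_by_class[ref_class]
        sub = phenotypes[phenotypes["endpoint"] == endpoint]
        veh = sub.loc[sub["treatment"] == "vehicle", "value"]
        ref = sub.loc[sub["treatment"] == arm, "value"]
        if veh.empty or ref.empty:
            raise DesignError(f"missing vehicle or reference arm for endpoint {endpoint!r}")
        out[endpoint] = float(abs(ref.mean() - veh.mean()))
    return out


def call_endpoints_for_compound(
    phenotypes: pd.DataFrame,
    treatment: str,
    reference_effects: Mapping[str, float],
    alpha: float = 0.05,
    method: str = "tukey",
) -> list[ResponseCall]:
    """Response calls for every endpoint present in a compound's table."""
    calls = []
    for endpoint in pd.unique(phenotypes["endpoint"]):
        if endpoint not in reference_effects:
            continue
        sub = phenotypes[phenotypes["endpoint"] == endpoint]
        veh = sub.loc[sub["treatment"] == "vehicle", "value"].to_numpy()
        tr = sub.loc[sub["treatment"] == treatment, "value"].to_numpy()
        if veh.size == 0 or tr.size == 0:
            continue
        calls.append(
            call_endpoint(tr, veh, reference_effects[endpoint], alpha=alpha,
                          method=method, endpoint=endpoint)
        )
    return calls
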
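"""Biomarker-panel derivation by ANOVA screening + PCA ranking.

Two panels of up to 50 probes are derived from the reference study: a 2-h
panel contrasting all estrogen classes against vehicle (estrogenicity) and a
24-h panel contrasting long- against short-acting references (longevity).
Candidates come from the coexpression patterns whose archetype labels can
carry the contrast; they are screened probe-wise by one-way ANOVA with
Benjamini-Hochberg control, ranked by their loading on the principal
component whose sample scores align best with the contrast, and taken
greedily while skipping probes nearly collinear with an already-selected
one.  The resulting panel stores per-probe directions, the two contrast
centroids (mean log2 deviation from vehicle) and the unit discriminant axis
from centroid A to centroid B.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DesignError, EmptyPanelError, PanelError
from .patterns import Pattern
from .study import ExpressionStudy

DEFAULT_2H_CANDIDATES = ("transient_up", "transient_down", "sustained_up", "sustained_down")
DEFAULT_24H_CANDIDATES = (
    "sustained_up",
    "sustained_down",
    "late_up_long_only",
    "late_down_long_only",
    "long_selective_up",
)


@dataclass(frozen=True)
class PanelSpec:
    """What a panel should contrast, and the knobs of the selection."""

    time_hr: int
    contrast_a: tuple[str, ...]
    contrast_b: tuple[str, ...]
    k: int = 50
    alpha: float = 0.05
    candidate_patterns: Optional[tuple[str, ...]] = None
    redundancy_r_max: float = 0.95

    def __post_init__(self):
        if self.time_hr not in (2, 24):
            raise ConfigError(f"PanelSpec.time_hr must be 2 or 24, got {self.time_hr!r}")
        if self.k < 1:
            raise ConfigError(f"PanelSpec.k must be >= 1, got {self.k!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"PanelSpec.alpha must be in (0, 1), got {self.alpha!r}")
        a, b = set(self.contrast_a), set(self.contrast_b)
        if not a or not b or a & b:
            raise ConfigError("PanelSpec contrast sets must be nonempty and disjoint")


def default_panel_spec_2h(**overrides) -> PanelSpec:
    kw = dict(
        time_hr=2,
        contrast_a=("vehicle",),
        contrast_b=("short_acting", "long_acting", "intermediate"),
        candidate_patterns=DEFAULT_2H_CANDIDATES,
    )
    kw.update(overrides)
    return PanelSpec(**kw)


def default_panel_spec_24h(**overrides) -> PanelSpec:
    kw = dict(
        time_hr=24,
        contrast_a=("short_acting",),
        contrast_b=("long_acting",),
        candidate_patterns=DEFAULT_24H_CANDIDATES,
    )
    kw.update(overrides)
    return PanelSpec(**kw)


@dataclass
class BiomarkerPanel:
    """An ordered probe panel with directions, centroids and discriminant axis."""

    spec: PanelSpec
    probes: list[str]
    directions: pd.Series  # +1 / -1 per probe, sign of (mean B - mean A)
    weights: pd.Series  # |loading| on the contrast-aligned component
    centroid_a: pd.Series  # mean log2 deviation from vehicle, contrast side A
    centroid_b: pd.Series

    @property
    def axis(self) -> pd.Series:
        d = self.centroid_b - self.centroid_a
        norm = float(np.linalg.norm(d))
        if norm == 0.0:
            raise PanelError("degenerate discriminant axis: contrast centroids are equal")
        return d / norm


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def oneway_anova(values: Sequence[float], groups: Sequence) -> tuple[float, float]:
    """Classical one-way F statistic and upper-tail p-value.

    The fully degenerate case (zero between- and within-group variance) is
    flagged as (F=0, p=1); zero within-group variance with distinct means
    yields (inf, 0).
    """
    values = np.asarray(values, float)
    labels = np.asarray(groups)
    uniq = pd.unique(labels)
    k = len(uniq)
    n = values.size
    if k < 2:
        raise DesignError("oneway_anova needs at least 2 groups")
    if n <= k:
        raise DesignError("oneway_anova needs total n greater than the number of groups")
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in uniq:
        sub = values[labels == g]
        ss_between += sub.size * (sub.mean() - grand) ** 2
        ss_within += ((sub - sub.mean()) ** 2).sum()
    df_b, df_w = k - 1, n - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return float(F), p


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def principal_components(matrix: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of row-standardized data (correlation-scale decomposition).

    Rows (probes) are standardized to mean 0, SD 1 across columns (samples)
    before the decomposition, so high-variance probes do not dominate.
    Returns ``(scores, loadings, variance_fractions)`` where ``loadings``
    (probes x components) are orthonormal eigenvectors of the probe-probe
    correlation matrix, ``scores`` (samples x components) are the sample
    projections, and the sign of each component is fixed so its
    largest-magnitude loading is positive.
    """
    X = matrix.to_numpy(float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows and 2 columns")
    sd = X.std(axis=1, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant row: standardize-able input required")
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(U.shape[1]):
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
            Vt[j] = -Vt[j]
    loadings = U
    scores = Vt.T * S
    var = S ** 2
    variance_fractions = var / var.sum() if var.sum() > 0 else var
    return scores, loadings, variance_fractions


# ---------------------------------------------------------------------------
# Panel derivation
# ---------------------------------------------------------------------------

def _contrast_samples(study: ExpressionStudy, spec: PanelSpec) -> tuple[list[str], np.ndarray, np.ndarray]:
    meta = study.metadata
    if "class_label" not in meta.columns:
        raise DesignError("panel derivation needs a class_label metadata column")
    wanted = set(spec.contrast_a) | set(spec.contrast_b)
    samples = study.samples_where(time_hr=spec.time_hr, class_label=wanted)
    if not samples:
        raise DesignError(f"no samples at {spec.time_hr} h for classes {sorted(wanted)}")
    cls = meta.loc[samples, "class_label"].to_numpy()
    for c in sorted(wanted):
        if (cls == c).sum() == 0:
            raise DesignError(f"contrast class {c!r} has no samples at {spec.time_hr} h")
    indicator = np.where(np.isin(cls, list(spec.contrast_b)), 1.0, -1.0)
    return samples, cls, indicator


def derive_panel(study: ExpressionStudy, spec: PanelSpec,
                 patterns: Optional[Sequence[Pattern]] = None) -> BiomarkerPanel:
    """Derive a biomarker panel for the spec's contrast.

    See the module docstring for the four-stage procedure.  ``patterns``
    restricts candidates to members of patterns whose labels are listed in
    ``spec.candidate_patterns``; without patterns every probe is a candidate.
    """
    samples, cls, indicator = _contrast_samples(study, spec)

    if patterns is not None and spec.candidate_patterns is not None:
        admitted = set(spec.candidate_patterns)
        candidates = [pid for p in patterns if p.label in admitted for pid in p.members]
        candidates = list(dict.fromkeys(candidates))  # preserve order, dedupe
    else:
        candidates = list(study.probe_ids)
    if not candidates:
        raise EmptyPanelError("candidate_patterns")

    sub = study.values.loc[candidates, samples]
    X = sub.to_numpy()

    # (1) probe-wise ANOVA across contrast groups, BH-controlled
    ps = np.array([oneway_anova(row, cls)[1] for row in X])
    keep = bh_adjust(ps) < spec.alpha
    if not keep.any():
        raise EmptyPanelError("anova")
    candidates = [c for c, k_ in zip(candidates, keep) if k_]
    X = X[keep]

    # (2) PCA; pick the component whose sample scores track the contrast
    if len(candidates) == 1:
        ranked = list(candidates)
    else:
        scores, loadings, _ = principal_components(X)
        rs = []
        for j in range(scores.shape[1]):
            s = scores[:, j]
            if np.ptp(s) == 0:
                rs.append(0.0)
                continue
            rs.append(abs(np.corrcoef(s, indicator)[0, 1]))
        comp = int(np.argmax(rs))
        w = np.abs(loadings[:, comp])
        # (3) rank by |loading|, deterministic tie-break by probe id
        ranked = [c for _, c in sorted(zip(-w, candidates), key=lambda t: (t[0], t[1]))]
        weight_by_probe = dict(zip(candidates, w))

    # (4) greedy top-k with redundancy pruning
    selected: list[str] = []
    for c in ranked:
        if len(selected) >= spec.k:
            break
        if selected:
            r = np.corrcoef(study.values.loc[selected + [c], samples].to_numpy())[-1, :-1]
            if np.any(np.abs(r) > spec.redundancy_r_max):
                continue
        selected.append(c)
    if not selected:
        raise EmptyPanelError("redundancy")

    veh = study.samples_where(role="vehicle", time_hr=spec.time_hr)
    if not veh:
        raise DesignError(f"no vehicle samples at {spec.time_hr} h")
    vmean = study.values.loc[selected, veh].mean(axis=1)
    a_samples = [s for s, c in zip(samples, cls) if c in spec.contrast_a]
    b_samples = [s for s, c in zip(samples, cls) if c in spec.contrast_b]
    mean_a = study.values.loc[selected, a_samples].mean(axis=1)
    mean_b = study.values.loc[selected, b_samples].mean(axis=1)
    directions = np.sign(mean_b - mean_a).replace(0, 1).astype(int)
    if len(candidates) == 1:
        weights = pd.Series(1.0, index=selected)
    else:
        weights = pd.Series({c: float(weight_by_probe[c]) for c in selected})
    return BiomarkerPanel(
        spec=spec,
        probes=selected,
        directions=directions,
        weights=weights,
        centroid_a=mean_a - vmean,
        centroid_b=mean_b - vmean,
    )


def validate_panel_clustering(study: ExpressionStudy, panel: BiomarkerPanel) -> float:
    """Agreement between sample clustering on panel probes and contrast sides.

    Samples of the panel's timepoint and contrast classes are clustered by
    average linkage on correlation distance (1 - Pearson r) over the panel
    probes (each probe centered across the selected samples first), the tree
    is cut into two clusters, and the adjusted Rand index against the true
    contrast-side labels is returned.
    """
    spec = panel.spec
    samples, cls, indicator = _contrast_samples(study, spec)
    sides = np.where(indicator > 0, "B", "A")
    if len(set(sides)) < 2:
        raise DesignError("clustering validation needs both contrast sides")
    for side in ("A", "B"):
        if (sides == side).sum() < 2:
            raise DesignError(f"contrast side {side} has fewer than 2 samples")
    M = study.values.loc[panel.probes, samples].to_numpy()
    M = M - M.mean(axis=1, keepdims=True)  # center per probe
    D = pdist(M.T, metric="correlation")
    Z = linkage(D, method="average")
    found = fcluster(Z, t=2, criterion="maxclust")
    return float(adjusted_rand_score(sides, found))


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def panel_to_json(panel: BiomarkerPanel) -> dict:
    spec = panel.spec
    return {
        "spec": {
            "time_hr": spec.time_hr,
            "contrast_a": list(spec.contrast_a),
            "contrast_b": list(spec.contrast_b),
            "k": spec.k,
            "alpha": spec.alpha,
            "candidate_patterns": list(spec.candidate_patterns) if spec.candidate_patterns else None,
            "redundancy_r_max": spec.redundancy_r_max,
        },
        "probes": [
            {
                "probe_id": p,
                "direction": int(panel.directions[p]),
                "weight": float(panel.weights[p]),
                "centroid_a": float(panel.centroid_a[p]),
                "centroid_b": float(panel.centroid_b[p]),
            }
            for p in panel.probes
        ],
    }


def panel_from_json(obj: dict) -> BiomarkerPanel:
    spec = PanelSpec(
        time_hr=obj["spec"]["time_hr"],
        contrast_a=tuple(obj["spec"]["contrast_a"]),
        contrast_b=tuple(obj["spec"]["contrast_b"]),
        k=obj["spec"]["k"],
        alpha=obj["spec"]["alpha"],
        candidate_patterns=tuple(obj["spec"]["candidate_patterns"])
        if obj["spec"]["candidate_patterns"] else None,
        redundancy_r_max=obj["spec"]["redundancy_r_max"],
    )
    probes = [p["probe_id"] for p in obj["probes"]]
    return BiomarkerPanel(
        spec=spec,
        probes=probes,
        directions=pd.Series({p["probe_id"]: p["direction"] for p in obj["probes"]}),
        weights=pd.Series({p["probe_id"]: p["weight"] for p in obj["probes"]}),
        centroid_a=pd.Series({p["probe_id"]: p["centroid_a"] for p in obj["probes"]}),
        centroid_b=pd.Series({p["probe_id"]: p["centroid_b"] for p in obj["probes"]}),
    )


def save_panel(panel: BiomarkerPanel, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(panel_to_json(panel), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_panel(path: str | Path) -> BiomarkerPanel:
    with open(path, encoding="utf-8") as fh:
        return panel_from_json(json.load(fh))
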
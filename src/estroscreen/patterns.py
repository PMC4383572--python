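"""Coexpression-pattern extraction from multi-treatment time-course studies.

The extractor re-implements the correlation-seeded pattern-discovery idea
behind the EPIG family of tools: probes are first screened by a
signal-to-noise ratio (range of treatment-group means over pooled
within-group SD) and by the magnitude of their largest group-mean deviation
from vehicle; surviving probes are grouped by Pearson correlation, growing
patterns greedily from the probe with the largest correlation neighborhood.
The algorithm is fully deterministic: ties are broken by probe id and the
representative profile of a pattern is the plain mean of its members,
re-fitted once after all patterns are formed.

Groups for the SNR are the treatment x time cells, so studies must be
batch-corrected first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DesignError, UndefinedCorrelationError
from .simulate import Archetype
from .study import ExpressionStudy

UNCLASSIFIED = "unclassified"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class PatternParams:
    """Thresholds of the pattern extractor.

    ``mag_min`` defaults to 0.585 log2 units, i.e. a 1.5-fold change.
    ``snr_cap`` is the finite stand-in returned when the pooled noise is
    exactly zero but the signal is not.  The default ``r_min`` of 0.75 was
    calibrated once against planted-archetype recovery at the generator's
    default effect size and noise (see the methods note).
    """

    r_min: float = 0.75
    snr_min: float = 3.0
    mag_min: float = 0.585
    min_cluster: int = 10
    snr_cap: float = 1e6

    def __post_init__(self):
        if not -1.0 < self.r_min < 1.0:
            raise ConfigError(f"PatternParams.r_min must be in (-1, 1), got {self.r_min!r}")
        if self.snr_min < 0:
            raise ConfigError(f"PatternParams.snr_min must be >= 0, got {self.snr_min!r}")
        if self.mag_min < 0:
            raise ConfigError(f"PatternParams.mag_min must be >= 0, got {self.mag_min!r}")
        if self.min_cluster < 2:
            raise ConfigError(f"PatternParams.min_cluster must be >= 2, got {self.min_cluster!r}")


@dataclass
class Pattern:
    """A coexpression pattern: representative profile + member probes.

    ``profile`` is the final member mean (re-fitted once after all patterns
    are formed); ``initial_profile`` is the member mean at formation time
    (the one probes were absorbed against) and ``seed_probe`` the probe
    whose neighborhood seeded the pattern.
    """

    id: int
    profile: pd.Series  # representative per-sample values (member mean)
    members: list[str]
    label: str = UNCLASSIFIED
    median_snr: float = float("nan")
    median_magnitude: float = float("nan")
    seed_probe: Optional[str] = None
    initial_profile: Optional[pd.Series] = None

    @property
    def size(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; rejects constant or short vectors."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation with a constant vector is undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))


def _group_arrays(profile: Sequence[float], group_labels: Sequence) -> dict:
    profile = np.asarray(profile, float)
    labels = np.asarray(group_labels)
    if profile.shape[0] != labels.shape[0]:
        raise ValueError("profile and group_labels must have equal length")
    return {g: profile[labels == g] for g in pd.unique(labels)}


def profile_snr(profile: Sequence[float], group_labels: Sequence,
                snr_cap: float = 1e6) -> float:
    """Range of group means over pooled within-group SD.

    Returns 0 when all values are equal and ``snr_cap`` when the pooled SD
    is zero but group means differ.
    """
    groups = _group_arrays(profile, group_labels)
    if len(groups) < 2:
        raise DesignError("profile_snr needs at least 2 groups")
    dof = sum(len(v) - 1 for v in groups.values())
    if dof < 1:
        raise DesignError("profile_snr needs at least 2 replicates in at least one group")
    means = np.array([v.mean() for v in groups.values()])
    ss_within = sum(float(((v - v.mean()) ** 2).sum()) for v in groups.values())
    signal = float(means.max() - means.min())
    pooled_sd = np.sqrt(ss_within / dof)
    if pooled_sd == 0.0:
        return 0.0 if signal == 0.0 else float(snr_cap)
    return signal / pooled_sd


def profile_magnitude(profile: Sequence[float], group_labels: Sequence,
                      vehicle_group) -> float:
    """Largest absolute deviation of any non-vehicle group mean from vehicle."""
    groups = _group_arrays(profile, group_labels)
    if vehicle_group not in groups:
        raise DesignError(f"vehicle group {vehicle_group!r} not present")
    vmean = groups[vehicle_group].mean()
    others = [abs(v.mean() - vmean) for g, v in groups.items() if g != vehicle_group]
    return max(others) if others else 0.0


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def _cell_labels(study: ExpressionStudy) -> np.ndarray:
    m = study.metadata.loc[study.sample_ids]
    return np.array([f"{t}@{h}" for t, h in zip(m["treatment"], m["time_hr"])])


def _probe_magnitudes(study: ExpressionStudy) -> pd.Series:
    """Per-probe max |group mean - vehicle mean|, computed within timepoint."""
    m = study.metadata.loc[study.sample_ids]
    mags = pd.Series(0.0, index=study.probe_ids)
    for time_hr in sorted(set(m["time_hr"])):
        veh = study.samples_where(role="vehicle", time_hr=time_hr)
        if not veh:
            raise DesignError(f"no vehicle samples at {time_hr} h")
        vmean = study.values[veh].mean(axis=1)
        treatments = [t for t in pd.unique(m.loc[m["time_hr"] == time_hr, "treatment"])]
        for t in treatments:
            cols = study.samples_where(treatment=t, time_hr=time_hr)
            if set(cols) == set(veh):
                continue
            dev = (study.values[cols].mean(axis=1) - vmean).abs()
            mags = np.maximum(mags, dev)
    return mags


def _probe_snrs(study: ExpressionStudy, snr_cap: float) -> pd.Series:
    labels = _cell_labels(study)
    X = study.values.to_numpy()
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise DesignError("need at least 2 treatment x time groups")
    means = np.empty((X.shape[0], len(uniq)))
    ss_within = np.zeros(X.shape[0])
    dof = 0
    for j, g in enumerate(uniq):
        cols = labels == g
        sub = X[:, cols]
        means[:, j] = sub.mean(axis=1)
        ss_within += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        dof += cols.sum() - 1
    if dof < 1:
        raise DesignError("need at least 2 replicates in at least one group")
    signal = means.max(axis=1) - means.min(axis=1)
    pooled_sd = np.sqrt(ss_within / dof)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(pooled_sd == 0.0, np.where(signal == 0.0, 0.0, snr_cap), signal / np.maximum(pooled_sd, 1e-300))
    return pd.Series(snr, index=study.probe_ids)


def _rows_correlation(X: np.ndarray) -> np.ndarray:
    """Row-row Pearson correlation (rows must be nonconstant)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc ** 2).sum(axis=1))
    R = (Xc @ Xc.T) / np.outer(norms, norms)
    return np.clip(R, -1.0, 1.0)


def extract_patterns(study: ExpressionStudy, params: Optional[PatternParams] = None) -> list[Pattern]:
    """Extract coexpression patterns from a batch-corrected study.

    Algorithm: (1) keep probes with SNR >= ``snr_min`` and magnitude >=
    ``mag_min``; (2) for each eligible probe its neighborhood is the set of
    eligible probes (itself included) correlating at >= ``r_min`` with it;
    (3) repeatedly seed a pattern from the unassigned probe with the largest
    unassigned neighborhood (ties -> lexicographically smallest probe id),
    stop when that neighborhood is smaller than ``min_cluster``, otherwise
    take the neighborhood as members, set the profile to the member mean and
    absorb every unassigned eligible probe correlating at >= ``r_min`` with
    the profile; (4) re-fit each profile as its member mean once at the end.
    Returns patterns in creation order with pairwise-disjoint members.
    """
    params = params if params is not None else PatternParams()
    snrs = _probe_snrs(study, params.snr_cap)
    mags = _probe_magnitudes(study)
    eligible = study.probe_ids[(snrs >= params.snr_min) & (mags >= params.mag_min)]
    if len(eligible) == 0:
        return []

    sub = study.values.loc[eligible]
    X = sub.to_numpy()
    R = _rows_correlation(X)
    adj = R >= params.r_min
    n = len(eligible)
    order = np.argsort(eligible)  # lexicographic rank of each row position
    lexrank = np.empty(n, dtype=int)
    lexrank[order] = np.arange(n)

    unassigned = np.ones(n, dtype=bool)
    raw_patterns: list[tuple[np.ndarray, np.ndarray, int]] = []  # (members, initial profile, seed)
    while True:
        counts = adj[:, unassigned].sum(axis=1)
        counts[~unassigned] = -1
        best = counts.max()
        if best < params.min_cluster:
            break
        # tie-break by lexicographically smallest probe id
        cand = np.flatnonzero(counts == best)
        seed = cand[np.argmin(lexrank[cand])]
        members = adj[seed] & unassigned
        profile = X[members].mean(axis=0)
        unassigned &= ~members
        # absorb unassigned probes correlating with the profile
        if unassigned.any():
            pc = profile - profile.mean()
            pnorm = np.sqrt((pc ** 2).sum())
            Xc = X - X.mean(axis=1, keepdims=True)
            rows = np.sqrt((Xc ** 2).sum(axis=1))
            r_to_profile = (Xc @ pc) / (rows * pnorm)
            absorb = unassigned & (r_to_profile >= params.r_min)
            members = members | absorb
            unassigned &= ~absorb
        raw_patterns.append((members, profile, seed))
        if not unassigned.any():
            break

    patterns: list[Pattern] = []
    for pid, (members, initial, seed) in enumerate(raw_patterns, start=1):
        member_ids = [eligible[i] for i in np.flatnonzero(members)]
        refit = pd.Series(X[members].mean(axis=0), index=study.sample_ids)
        patterns.append(
            Pattern(
                id=pid,
                profile=refit,
                members=member_ids,
                median_snr=float(np.median(snrs.loc[member_ids])),
                median_magnitude=float(np.median(mags.loc[member_ids])),
                seed_probe=str(eligible[seed]),
                initial_profile=pd.Series(initial, index=study.sample_ids),
            )
        )
    return patterns


def assign_to_patterns(profile: Sequence[float], patterns: Sequence[Pattern],
                       r_min: float = 0.75) -> int | str:
    """Assign a profile to the best-correlating pattern, or ``"unassigned"``.

    Ties are broken toward the smallest pattern id.
    """
    if not patterns:
        raise ValueError("patterns must be nonempty")
    best_id, best_r = None, -np.inf
    for p in sorted(patterns, key=lambda p: p.id):
        r = pearson_r(profile, p.profile.to_numpy())
        if r > best_r:
            best_id, best_r = p.id, r
    return best_id if best_r >= r_min else UNASSIGNED


def label_pattern(pattern: Pattern, study: ExpressionStudy,
                  templates: Sequence[Archetype], r_label: float = 0.8) -> str:
    """Name a pattern after the archetype its class x time means best match.

    The pattern profile is reduced to (treatment class, time) cell means and
    correlated with each archetype template over the same cells; the best
    archetype wins if it correlates at >= ``r_label``, else the pattern is
    left ``"unclassified"``.
    """
    meta = study.metadata.loc[pattern.profile.index]
    if "class_label" not in meta.columns:
        raise DesignError("label_pattern needs a class_label metadata column")
    cells = []
    means = []
    for (cls, t), idx in pattern.profile.groupby(
            [meta["class_label"], meta["time_hr"]]).groups.items():
        cells.append((cls, int(t)))
        means.append(pattern.profile.loc[idx].mean())
    means = np.asarray(means)
    if np.ptp(means) == 0:
        return UNCLASSIFIED
    best_name, best_r = UNCLASSIFIED, -np.inf
    for arch in templates:
        try:
            tvec = arch.cell_vector(cells)
        except KeyError:
            continue
        if np.ptp(tvec) == 0:
            continue
        r = pearson_r(means, tvec)
        if r > best_r:
            best_name, best_r = arch.name, r
    return best_name if best_r >= r_label else UNCLASSIFIED


def patterns_report(patterns: Sequence[Pattern]) -> dict:
    """JSON-serializable per-pattern summary."""
    return {
        "patterns": [
            {
                "id": p.id,
                "label": p.label,
                "size": p.size,
                "median_snr": p.median_snr,
                "median_magnitude": p.median_magnitude,
                "members": list(p.members),
            }
            for p in patterns
        ]
    }
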
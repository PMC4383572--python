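"""Expression-study container and tab-separated I/O.

An :class:`ExpressionStudy` is a probe x sample matrix of log2-scale
expression plus per-sample metadata (treatment, timepoint, batch, role,
optional class label).  The on-disk format is plain tab-separated text:
the matrix has a ``probe_id`` header column followed by sample ids, the
metadata table has one row per sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, StudyValidationError

REQUIRED_METADATA = ("treatment", "time_hr", "batch", "role")
ROLES = ("vehicle", "reference", "test")


@dataclass
class ExpressionStudy:
    """Probe x sample log2 expression with per-sample metadata.

    ``values``: DataFrame indexed by probe id, columns = sample ids.
    ``metadata``: DataFrame indexed by sample id with columns
    ``treatment``, ``time_hr`` (2 or 24), ``batch``, ``role`` and
    optionally ``class_label``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    # -- validation --------------------------------------------------------
    def validate(self) -> "ExpressionStudy":
        v, m = self.values, self.metadata
        dup_probes = v.index[v.index.duplicated()].unique()
        if len(dup_probes):
            raise StudyValidationError(f"duplicate probe id(s): {list(dup_probes)[:5]}")
        dup_samples = v.columns[v.columns.duplicated()].unique()
        if len(dup_samples):
            raise StudyValidationError(f"duplicate sample id(s): {list(dup_samples)[:5]}")
        missing_meta = [s for s in v.columns if s not in m.index]
        if missing_meta:
            raise StudyValidationError(
                f"sample id(s) present in matrix but missing from metadata: {missing_meta[:5]}"
            )
        extra_meta = [s for s in m.index if s not in v.columns]
        if extra_meta:
            raise StudyValidationError(
                f"sample id(s) present in metadata but missing from matrix: {extra_meta[:5]}"
            )
        for col in REQUIRED_METADATA:
            if col not in m.columns:
                raise StudyValidationError(f"metadata is missing required column '{col}'")
        bad_time = sorted(set(m["time_hr"]) - {2, 24})
        if bad_time:
            raise StudyValidationError(f"time_hr must be 2 or 24, got {bad_time}")
        bad_role = sorted(set(m["role"]) - set(ROLES))
        if bad_role:
            raise StudyValidationError(f"role must be one of {ROLES}, got {bad_role}")
        if not np.isfinite(v.to_numpy()).all():
            bad = v.index[~np.isfinite(v).all(axis=1)]
            raise StudyValidationError(f"non-finite expression value(s) in probe(s): {list(bad)[:5]}")
        return self

    # -- convenience accessors --------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_where(self, **conditions) -> list[str]:
        """Sample ids whose metadata matches every keyword condition.

        A condition value may be a scalar or a sequence of admissible values.
        """
        mask = pd.Series(True, index=self.metadata.index)
        for col, val in conditions.items():
            if isinstance(val, (list, tuple, set, frozenset)):
                mask &= self.metadata[col].isin(list(val))
            else:
                mask &= self.metadata[col] == val
        return [s for s in self.sample_ids if mask.loc[s]]

    def subset(self, probes: Optional[Sequence[str]] = None,
               samples: Optional[Sequence[str]] = None) -> "ExpressionStudy":
        v = self.values
        if probes is not None:
            missing = [p for p in probes if p not in v.index]
            if missing:
                raise StudyValidationError(f"unknown probe id(s): {missing[:5]}")
            v = v.loc[list(probes)]
        if samples is not None:
            v = v[list(samples)]
        return ExpressionStudy(values=v, metadata=self.metadata.loc[v.columns])


def deviation_from_vehicle(
    study: ExpressionStudy,
    time_hr: int,
    treatment: Optional[str] = None,
    class_label: Optional[str] = None,
    probes: Optional[Sequence[str]] = None,
) -> pd.Series:
    """Per-probe mean log2 deviation of a treatment arm from vehicle.

    Vehicle samples are those with ``role == "vehicle"`` at the same
    timepoint.  Select the treated arm either by ``treatment`` label or by
    ``class_label`` (one or more class labels).
    """
    veh = study.samples_where(role="vehicle", time_hr=time_hr)
    if not veh:
        raise DesignError(f"no vehicle samples at {time_hr} h")
    if treatment is not None:
        treated = study.samples_where(treatment=treatment, time_hr=time_hr)
    elif class_label is not None:
        treated = study.samples_where(class_label=class_label, time_hr=time_hr)
    else:
        raise ValueError("give either treatment or class_label")
    if not treated:
        raise DesignError(f"no treated samples at {time_hr} h for the requested arm")
    v = study.values if probes is None else study.values.loc[list(probes)]
    return v[treated].mean(axis=1) - v[veh].mean(axis=1)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def load_study(expression_path: str | Path, metadata_path: str | Path) -> ExpressionStudy:
    """Read and validate a study from tab-separated files.

    Raises :class:`StudyValidationError` naming the offending record for
    duplicate ids, matrix/metadata mismatches, non-numeric cells or missing
    metadata columns.
    """
    expression_path, metadata_path = Path(expression_path), Path(metadata_path)
    with open(expression_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
    if dups:
        raise StudyValidationError(f"duplicate sample id(s) in {expression_path.name}: {dups[:5]}")
    raw = pd.read_csv(expression_path, sep="\t", index_col=0, dtype=str)
    raw.columns = sample_ids
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.to_numpy().any():
        probe = values.index[bad.any(axis=1)][0]
        sample = values.columns[bad.loc[probe]][0]
        raise StudyValidationError(
            f"non-numeric cell at probe {probe!r}, sample {sample!r}: {raw.loc[probe, sample]!r}"
        )
    if values.isna().to_numpy().any():
        probe = values.index[values.isna().any(axis=1)][0]
        raise StudyValidationError(f"missing value(s), first at probe {probe!r}")
    values = values.astype(float)
    values.index.name = "probe_id"

    meta = pd.read_csv(metadata_path, sep="\t", dtype={"batch": str})
    if "sample_id" not in meta.columns:
        raise StudyValidationError(f"{metadata_path.name} is missing required column 'sample_id'")
    meta = meta.set_index("sample_id")
    study = ExpressionStudy(values=values, metadata=meta)
    study.validate()
    # preserve on-file ordering
    return study


def write_study(study: ExpressionStudy, expression_path: str | Path,
                metadata_path: str | Path) -> None:
    """Write a study as tab-separated text (full float precision)."""
    study.values.to_csv(expression_path, sep="\t", index_label="probe_id")
    study.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")
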
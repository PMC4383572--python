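"""Preprocessing: log transform, vehicle-anchored batch correction, and
housekeeping-probe count normalization.

Batch correction subtracts, per probe and per batch, the mean of that
batch's vehicle samples.  Every batch in the designs the screen targets
contains vehicle controls, so this removes any additive per-batch offset
exactly while preserving treatment-vs-vehicle contrasts.  The operation is
idempotent.

Count normalization emulates the standard housekeeping-gene convention for
digital-count platforms: each sample is rescaled so its geometric mean over
the housekeeping probes equals the global geometric mean.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DesignError
from .study import ExpressionStudy


def log2_transform(values: pd.DataFrame | np.ndarray, pseudocount: float = 1.0):
    """Elementwise ``log2(value + pseudocount)`` for nonnegative input."""
    arr = values.to_numpy() if isinstance(values, pd.DataFrame) else np.asarray(values, float)
    if (arr < 0).any():
        raise DataError("log2_transform requires nonnegative values")
    out = np.log2(arr + pseudocount)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def batch_correct(study: ExpressionStudy) -> ExpressionStudy:
    """Subtract each batch's per-probe vehicle mean.

    After correction the per-batch vehicle means are 0 for every probe.
    Raises :class:`DesignError` for a batch with no vehicle sample.
    """
    study.validate()
    values = study.values.copy()
    meta = study.metadata
    for batch in pd.unique(meta["batch"]):
        in_batch = [s for s in values.columns if meta.loc[s, "batch"] == batch]
        veh = [s for s in in_batch if meta.loc[s, "role"] == "vehicle"]
        if not veh:
            raise DesignError(f"batch {batch!r} has no vehicle sample; cannot anchor correction")
        values[in_batch] = values[in_batch].sub(values[veh].mean(axis=1), axis=0)
    return ExpressionStudy(values=values, metadata=meta.copy())


def normalize_housekeeping(counts: pd.DataFrame, housekeeping_ids: Sequence[str]) -> pd.DataFrame:
    """Scale each sample so housekeeping geometric means agree globally.

    The per-sample factor is (global geometric mean of housekeeping counts)
    / (sample's geometric mean of housekeeping counts); every count in the
    sample is multiplied by its factor.  Invariant to rescaling any sample
    by a positive constant, and preserves within-sample count ratios.
    """
    hk = list(housekeeping_ids)
    if len(set(hk)) < 2:
        raise DesignError("need at least 2 distinct housekeeping probes")
    missing = [h for h in hk if h not in counts.index]
    if missing:
        raise DataError(f"housekeeping probe(s) not in count matrix: {missing[:5]}")
    hk_counts = counts.loc[hk]
    if (hk_counts.to_numpy() <= 0).any():
        bad = hk_counts.index[(hk_counts <= 0).any(axis=1)]
        raise DataError(f"nonpositive housekeeping count(s) for probe(s): {list(bad)[:5]}")
    log_hk = np.log(hk_counts.to_numpy())
    sample_gm = np.exp(log_hk.mean(axis=0))
    global_gm = np.exp(log_hk.mean())
    factors = global_gm / sample_gm
    return counts.mul(factors, axis=1)
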
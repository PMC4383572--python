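from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import estroscreen as es
from estroscreen.pipeline import RunConfig, run_reference_build


def make_study(values: np.ndarray, treatments, times, roles, batches=None,
               class_labels=None, probe_ids=None) -> es.ExpressionStudy:
    """Hand-build a small ExpressionStudy from arrays."""
    n_probes, n_samples = values.shape
    probe_ids = probe_ids or [f"p{i:03d}" for i in range(n_probes)]
    sample_ids = [f"s{j:02d}" for j in range(n_samples)]
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "treatment": treatments,
            "time_hr": times,
            "batch": batches or ["b1"] * n_samples,
            "role": roles,
        }
    )
    if class_labels is not None:
        meta["class_label"] = class_labels
    meta = meta.set_index("sample_id")
    vdf = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids)
    return es.ExpressionStudy(values=vdf, metadata=meta).validate()


@pytest.fixture(scope="session")
def small_sim_cfg() -> es.SimConfig:
    """A reduced-scale reference design for fast tests."""
    return es.SimConfig(n_probes=2000, probes_per_archetype=150, seed=5)


@pytest.fixture(scope="session")
def reference_build():
    """One default-scale reference build shared across the suite."""
    cfg = RunConfig(seed=1)
    return cfg, run_reference_build(cfg)


@pytest.fixture(scope="session")
def templates():
    return es.make_archetype_templates()
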
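"""Synthetic study generator.

Emulates the structure of the multi-treatment uterine time-course designs the
screen was built on: vehicle plus several estrogen treatments sampled at 2 h
and 24 h after dosing, run in batches, with probe sets following a small
number of response archetypes (transient, sustained, late/long-acting-only,
long-acting-selective, each up or down).  Expression is simulated on the log2
scale as

    value = baseline(probe) + template(class, time) * effect
            + batch_shift(probe, batch) + noise

with i.i.d. Gaussian noise and an additive per-batch, per-probe shift.
Animal-level phenotypes for the uterotrophic-assay endpoints (uterine weight,
EdU incorporation, TUNEL, luminal epithelial height, Birc1a/Ltf induction)
are simulated around class-specific group means.

Everything is a pure function of (inputs, seed): identical calls give
bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DesignError
from .study import ExpressionStudy, write_study

#: Treatment classes the screen distinguishes. ``vehicle`` is the reference;
#: ``intermediate`` behaves as the arithmetic midpoint of short and long.
TREATMENT_CLASSES = ("vehicle", "short_acting", "long_acting", "intermediate")

#: Compound classes a test substance can belong to.
COMPOUND_CLASSES = ("non_estrogenic", "short_acting", "long_acting", "intermediate")

TIMEPOINTS = (2, 24)

ARCHETYPE_NAMES = (
    "transient_up",
    "transient_down",
    "sustained_up",
    "sustained_down",
    "late_up_long_only",
    "late_down_long_only",
    "long_selective_up",
)

# Shape parameters per archetype: mean log2 deviation from vehicle for the
# short- and long-acting classes at 2 h and 24 h.  The intermediate class is
# always the midpoint of short and long; vehicle is always 0.  Amplitudes
# were chosen so that no two archetype profiles correlate above |r| = 0.6
# across the treatment-class x time cells, keeping planted patterns separable
# by correlation-seeded extraction.
_SHAPES: dict[str, tuple[float, float, float, float]] = {
    #                 s2    l2    s24   l24
    "transient_up": (1.0, 1.0, 0.0, 0.0),
    "transient_down": (-1.0, -1.0, 0.0, 0.0),
    "sustained_up": (0.7, 0.7, 0.0, 1.0),
    "sustained_down": (-0.7, -0.7, 0.0, -1.0),
    "late_up_long_only": (0.0, 0.0, 0.0, 1.3),
    "late_down_long_only": (0.0, 0.0, 0.0, -1.3),
    "long_selective_up": (0.0, 1.5, 0.0, 0.5),
}


@dataclass(frozen=True)
class Archetype:
    """A canonical response shape over (treatment class, time) cells.

    ``template`` maps ``(treatment_class, time_hr)`` to the expected mean
    log2 deviation from vehicle, in unit effect size.
    """

    name: str
    template: Mapping[tuple[str, int], float]

    def value(self, treatment_class: str, time_hr: int) -> float:
        return self.template[(treatment_class, time_hr)]

    def cell_vector(self, cells: Sequence[tuple[str, int]]) -> np.ndarray:
        return np.array([self.template[c] for c in cells], dtype=float)


def make_archetype_templates() -> list[Archetype]:
    """Return the seven response archetypes.

    Vehicle cells are exactly 0; intermediate cells are the midpoint of the
    short- and long-acting cells.
    """
    archetypes = []
    for name in ARCHETYPE_NAMES:
        s2, l2, s24, l24 = _SHAPES[name]
        template = {
            ("vehicle", 2): 0.0,
            ("vehicle", 24): 0.0,
            ("short_acting", 2): s2,
            ("long_acting", 2): l2,
            ("intermediate", 2): (s2 + l2) / 2.0,
            ("short_acting", 24): s24,
            ("long_acting", 24): l24,
            ("intermediate", 24): (s24 + l24) / 2.0,
        }
        archetypes.append(Archetype(name=name, template=template))
    return archetypes


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic reference design.

    Defaults mirror the scale of the real reference studies: ~10k probes per
    array of which a few thousand respond, unit log2 effects, replicate
    groups of four spread round-robin over two batches.
    """

    n_probes: int = 10_000
    probes_per_archetype: int = 300
    n_null_probes: Optional[int] = None  # None -> n_probes - 7 * probes_per_archetype
    effect_size: float = 1.0
    noise_sd: float = 0.25
    n_replicates: int = 4
    batches: int = 2
    batch_shift_sd: float = 0.3
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for fname in ("n_probes", "probes_per_archetype", "n_replicates", "batches"):
            v = getattr(self, fname)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigError(f"SimConfig.{fname} must be an integer >= 1, got {v!r}")
        for fname in ("noise_sd", "batch_shift_sd", "baseline_sd"):
            v = getattr(self, fname)
            if v < 0:
                raise ConfigError(f"SimConfig.{fname} must be >= 0, got {v!r}")
        if self.effect_size < 0:
            raise ConfigError(f"SimConfig.effect_size must be >= 0, got {self.effect_size!r}")
        n_planted = 7 * self.probes_per_archetype
        n_null = self.n_null_probes
        if n_null is not None and n_null < 0:
            raise ConfigError(f"SimConfig.n_null_probes must be >= 0, got {n_null!r}")
        if n_planted + (n_null or 0) > self.n_probes:
            raise ConfigError(
                "SimConfig.n_probes too small: probes_per_archetype*7 + n_null_probes "
                f"= {n_planted + (n_null or 0)} > {self.n_probes}"
            )

    @property
    def n_planted(self) -> int:
        return 7 * self.probes_per_archetype

    @property
    def n_null(self) -> int:
        # every probe not planted is a null probe
        return self.n_probes - self.n_planted


@dataclass
class SyntheticStudy:
    """A labeled synthetic study: expression + phenotypes + ground truth.

    ``truth`` holds the per-probe archetype label (None for null probes)
    and the class label of every non-vehicle treatment.
    """

    expression: ExpressionStudy
    phenotypes: Optional[pd.DataFrame]
    probe_truth: dict[str, Optional[str]]
    class_truth: dict[str, str]


def _probe_ids(cfg: SimConfig) -> tuple[list[str], dict[str, Optional[str]]]:
    ids: list[str] = []
    truth: dict[str, Optional[str]] = {}
    for name in ARCHETYPE_NAMES:
        for i in range(cfg.probes_per_archetype):
            pid = f"{name}_{i:04d}"
            ids.append(pid)
            truth[pid] = name
    for i in range(cfg.n_null):
        pid = f"null_{i:05d}"
        ids.append(pid)
        truth[pid] = None
    return ids, truth


def _simulate_expression(
    cfg: SimConfig,
    arms: Sequence[tuple[str, str, str]],
    seed: int,
) -> tuple[ExpressionStudy, dict[str, Optional[str]]]:
    """Simulate an expression study for the given treatment arms.

    ``arms`` is a sequence of (treatment_label, treatment_class, role);
    ``treatment_class`` selects the template column (``non_estrogenic``
    means an all-zero template).  The template for each arm may be rescaled
    beforehand by the caller (potency / persistence).
    """
    templates = {a.name: a for a in make_archetype_templates()}
    probe_ids, probe_truth = _probe_ids(cfg)

    sample_rows = []
    for treatment, tclass, role in arms:
        for time_hr in TIMEPOINTS:
            for rep in range(cfg.n_replicates):
                sample_rows.append((f"{treatment}_{time_hr}h_r{rep + 1}", treatment, tclass, time_hr, role))
    sample_ids = [r[0] for r in sample_rows]
    batches = [f"b{(i % cfg.batches) + 1}" for i in range(len(sample_rows))]
    batch_idx = np.array([i % cfg.batches for i in range(len(sample_rows))])

    rng = np.random.default_rng(seed)
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_probes)
    batch_shift = rng.normal(0.0, cfg.batch_shift_sd, size=(cfg.n_probes, cfg.batches))
    noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_probes, len(sample_rows)))

    signal = np.zeros((cfg.n_probes, len(sample_rows)))
    for j, (_, _, tclass, time_hr, _) in enumerate(sample_rows):
        if tclass == "non_estrogenic":
            continue
        col = np.zeros(cfg.n_probes)
        for k, name in enumerate(ARCHETYPE_NAMES):
            lo = k * cfg.probes_per_archetype
            hi = lo + cfg.probes_per_archetype
            col[lo:hi] = templates[name].value(tclass, time_hr) * cfg.effect_size
        signal[:, j] = col

    values = baseline[:, None] + signal + batch_shift[:, batch_idx] + noise
    vdf = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "treatment": [r[1] for r in sample_rows],
            "time_hr": [r[3] for r in sample_rows],
            "batch": batches,
            "role": [r[4] for r in sample_rows],
            "class_label": [r[2] for r in sample_rows],
        }
    ).set_index("sample_id")
    study = ExpressionStudy(values=vdf, metadata=meta)
    study.validate()
    return study, probe_truth


def simulate_reference_study(cfg: SimConfig) -> SyntheticStudy:
    """Simulate the reference design: vehicle plus one arm per estrogen class.

    Samples are {vehicle, short-, long-, intermediate-acting reference} x
    {2 h, 24 h} x ``n_replicates``, assigned round-robin to batches.
    """
    arms = [
        ("vehicle", "vehicle", "vehicle"),
        ("short_acting_ref", "short_acting", "reference"),
        ("long_acting_ref", "long_acting", "reference"),
        ("intermediate_ref", "intermediate", "reference"),
    ]
    expr, probe_truth = _simulate_expression(cfg, arms, cfg.seed)
    pheno = simulate_reference_phenotypes(seed=cfg.seed + 1)
    class_truth = {
        "short_acting_ref": "short_acting",
        "long_acting_ref": "long_acting",
        "intermediate_ref": "intermediate",
    }
    return SyntheticStudy(expression=expr, phenotypes=pheno, probe_truth=probe_truth, class_truth=class_truth)


def simulate_test_compound(
    class_label: str,
    potency: float = 1.0,
    persistence: float = 1.0,
    seed: int = 0,
    cfg: Optional[SimConfig] = None,
    treatment: str = "test",
) -> SyntheticStudy:
    """Simulate a test-compound study: vehicle plus one test arm.

    The test arm follows the archetype templates for ``class_label`` scaled
    by ``potency``; all 24-h template components are additionally scaled by
    ``persistence`` (transient archetypes are zero at 24 h regardless, so
    persistence only attenuates sustained/late responses).
    ``non_estrogenic`` zeroes every template.
    """
    if class_label not in COMPOUND_CLASSES:
        raise ConfigError(
            f"unknown class_label {class_label!r}; expected one of {COMPOUND_CLASSES}"
        )
    if potency < 0:
        raise ConfigError(f"potency must be >= 0, got {potency!r}")
    if not 0.0 <= persistence <= 1.0:
        raise ConfigError(f"persistence must be in [0, 1], got {persistence!r}")
    cfg = cfg if cfg is not None else SimConfig()
    # scale effect by potency; persistence applies only to the 24-h cells,
    # which _simulate_expression does not distinguish, so rescale via a
    # modified config + post-hoc template override.
    eff_cfg = replace(cfg, effect_size=cfg.effect_size * potency, seed=seed)
    arms = [
        ("vehicle", "vehicle", "vehicle"),
        (treatment, class_label, "test"),
    ]
    # Build with full persistence, then attenuate the 24-h signal component.
    if persistence == 1.0 or class_label == "non_estrogenic":
        expr, probe_truth = _simulate_expression(eff_cfg, arms, seed)
    else:
        expr, probe_truth = _simulate_expression(eff_cfg, arms, seed)
        full, _ = _simulate_expression(replace(eff_cfg, noise_sd=0.0, batch_shift_sd=0.0,
                                               baseline_sd=0.0, baseline_mean=0.0), arms, seed)
        is24 = (expr.metadata["time_hr"] == 24).to_numpy()
        is_test = (expr.metadata["role"] == "test").to_numpy()
        mask = is24 & is_test
        # full.values holds the pure signal; remove (1 - persistence) of it
        expr.values.loc[:, mask] -= (1.0 - persistence) * full.values.loc[:, mask].to_numpy()
    pheno = simulate_phenotypes(class_label, seed=seed + 1, treatment=treatment)
    return SyntheticStudy(
        expression=expr,
        phenotypes=pheno,
        probe_truth=probe_truth,
        class_truth={treatment: class_label},
    )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EndpointEffect:
    """Generative settings for one uterotrophic endpoint.

    ``vehicle``/``short``/``long`` are group means (intermediate compounds
    get the midpoint of short and long, non-estrogenic ones the vehicle
    mean).  ``noise`` is an additive SD in the endpoint's units, or a
    log-scale SD when ``kind == "multiplicative"`` (fold-change endpoints
    are right-skewed and strictly positive).  ``reference_class`` names the
    reference arm whose effect anchors the ordinal response calls: the
    long-acting reference for growth endpoints, the short-acting reference
    for TUNEL where long-acting estrogens show no response.
    """

    name: str
    unit: str
    slot: str  # Table-template slot this endpoint feeds
    vehicle: float
    short: float
    long: float
    noise: float
    kind: str = "additive"  # or "multiplicative"
    reference_class: str = "long_acting"
    is_percent: bool = False

    def class_mean(self, class_label: str) -> float:
        if class_label in ("vehicle", "non_estrogenic"):
            return self.vehicle
        if class_label == "short_acting":
            return self.short
        if class_label == "long_acting":
            return self.long
        if class_label == "intermediate":
            return (self.short + self.long) / 2.0
        raise ConfigError(f"unknown class_label {class_label!r}")


def default_endpoint_effects() -> list[EndpointEffect]:
    """Default endpoint settings.

    Group means follow the qualitative scheme of the screen: long-acting
    estrogens drive strong 72-h growth (weight, LEH, Birc1a, Ltf) with no
    apoptosis; short-acting estrogens drive a moderate 24-h proliferative
    response that collapses by 72 h, with elevated TUNEL.  Units and ranges
    are plausible for an ovariectomized-mouse uterine bioassay.
    """
    return [
        EndpointEffect("weight_24h", "mg", "24h_weight", 25.0, 32.0, 45.0, 3.5),
        EndpointEffect("weight_72h", "mg", "72h_weight", 25.0, 42.0, 105.0, 8.0),
        EndpointEffect("edu_pct_24h", "%", "24h_edu", 7.0, 40.0, 65.0, 3.0, is_percent=True),
        EndpointEffect("tunel_pct_72h", "%", "72h_tunel", 1.0, 7.0, 0.5, 0.6,
                       reference_class="short_acting", is_percent=True),
        EndpointEffect("leh_72h", "um", "72h_leh", 10.0, 16.0, 35.0, 2.5),
        EndpointEffect("birc1a_fold_72h", "fold", "72h_birc1a", 1.0, 2.0, 8.0, 0.25,
                       kind="multiplicative"),
        EndpointEffect("ltf_fold_72h", "fold", "72h_ltf", 1.0, 5.0, 50.0, 0.30,
                       kind="multiplicative"),
    ]


ENDPOINT_NAMES = tuple(e.name for e in default_endpoint_effects())


def _draw_endpoint(rng: np.random.Generator, eff: EndpointEffect, mean: float, n: int) -> np.ndarray:
    if eff.kind == "multiplicative":
        vals = mean * np.exp(rng.normal(0.0, eff.noise, size=n))
    else:
        vals = rng.normal(mean, eff.noise, size=n)
    if eff.is_percent:
        vals = np.clip(vals, 0.0, 100.0)
    else:
        vals = np.maximum(vals, 0.0)
    return vals


def simulate_phenotypes(
    class_label: str,
    n_animals: int = 6,
    effect_cfg: Optional[Sequence[EndpointEffect]] = None,
    seed: int = 0,
    treatment: Optional[str] = None,
) -> pd.DataFrame:
    """Simulate animal-level endpoint values for vehicle + one treated arm.

    Returns a long-format table with columns ``animal_id``, ``treatment``,
    ``endpoint``, ``value``.  Requires at least three animals per group so
    the downstream group statistics are defined.
    """
    if class_label not in COMPOUND_CLASSES:
        raise ConfigError(
            f"unknown class_label {class_label!r}; expected one of {COMPOUND_CLASSES}"
        )
    if n_animals < 3:
        raise DesignError(f"n_animals must be >= 3 per group, got {n_animals}")
    effects = list(effect_cfg) if effect_cfg is not None else default_endpoint_effects()
    treatment = treatment or class_label
    rng = np.random.default_rng(seed)
    rows = []
    for eff in effects:
        for arm, mean in (("vehicle", eff.vehicle), (treatment, eff.class_mean(class_label))):
            vals = _draw_endpoint(rng, eff, mean, n_animals)
            for i, v in enumerate(vals):
                rows.append((f"{arm}_a{i + 1}", arm, eff.name, float(v)))
    return pd.DataFrame(rows, columns=["animal_id", "treatment", "endpoint", "value"])


def simulate_reference_phenotypes(
    n_animals: int = 6,
    effect_cfg: Optional[Sequence[EndpointEffect]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a shared-vehicle phenotype table for all three reference arms."""
    effects = list(effect_cfg) if effect_cfg is not None else default_endpoint_effects()
    rng = np.random.default_rng(seed)
    arms = [
        ("vehicle", "vehicle"),
        ("short_acting_ref", "short_acting"),
        ("long_acting_ref", "long_acting"),
        ("intermediate_ref", "intermediate"),
    ]
    rows = []
    for eff in effects:
        for arm, cls in arms:
            vals = _draw_endpoint(rng, eff, eff.class_mean(cls), n_animals)
            for i, v in enumerate(vals):
                rows.append((f"{arm}_a{i + 1}", arm, eff.name, float(v)))
    return pd.DataFrame(rows, columns=["animal_id", "treatment", "endpoint", "value"])


# ---------------------------------------------------------------------------
# Persistence to disk
# ---------------------------------------------------------------------------

def write_synthetic_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write expression, metadata, phenotypes and the truth sidecar.

    Expression and metadata are tab-separated text; truth is JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.json",
    }
    write_study(study.expression, paths["expression"], paths["metadata"])
    if study.phenotypes is not None:
        paths["phenotypes"] = outdir / "phenotypes.tsv"
        study.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(
            {"probe_archetype": study.probe_truth, "treatment_class": study.class_truth},
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    return paths
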
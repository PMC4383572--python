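"""End-to-end orchestration: simulate/load -> preprocess -> patterns ->
panels -> endpoint calls -> classification.

A single :class:`RunConfig` drives the whole screen.  One global seed fans
out to per-stage seeds by fixed offsets so stages are independently
re-runnable; with a fixed seed the full run is bit-reproducible (all
artifacts are plain text with deterministic content and ordering).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .classify import (
    ClassifierThresholds,
    CompoundClassification,
    classification_to_json,
    classify_compound,
    estrogenicity_score,
    longevity_score,
)
from .endpoints import call_endpoints_for_compound, reference_effects_from_table
from .errors import StageError
from .panels import (
    BiomarkerPanel,
    default_panel_spec_2h,
    default_panel_spec_24h,
    derive_panel,
    save_panel,
    validate_panel_clustering,
)
from .patterns import PatternParams, extract_patterns, label_pattern, patterns_report
from .preprocess import batch_correct
from .simulate import (
    SimConfig,
    default_endpoint_effects,
    make_archetype_templates,
    simulate_reference_study,
    simulate_test_compound,
    write_synthetic_study,
)
from .study import ExpressionStudy, deviation_from_vehicle

# fixed per-stage seed offsets
_SEED_MOD = 2**31
_COMPOUND_SEED_BASE = 1000


@dataclass(frozen=True)
class CompoundSpec:
    name: str
    class_label: str
    potency: float = 1.0
    persistence: float = 1.0


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    pattern_params: PatternParams = field(default_factory=PatternParams)
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    compounds: list[CompoundSpec] = field(default_factory=list)
    panel_k: int = 50
    panel_alpha: float = 0.05
    n_animals: int = 6
    endpoint_alpha: float = 0.05
    endpoint_method: str = "tukey"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = {}
        if "sim" in raw:
            kwargs["sim"] = SimConfig(**raw["sim"])
        if "pattern_params" in raw:
            kwargs["pattern_params"] = PatternParams(**raw["pattern_params"])
        if "thresholds" in raw:
            kwargs["thresholds"] = ClassifierThresholds(**raw["thresholds"])
        if "compounds" in raw:
            kwargs["compounds"] = [CompoundSpec(**c) for c in raw["compounds"]]
        for key in ("panel_k", "panel_alpha", "n_animals", "endpoint_alpha",
                    "endpoint_method", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


@dataclass
class ReferenceArtifacts:
    corrected: ExpressionStudy
    patterns: list
    panel_2h: BiomarkerPanel
    panel_24h: BiomarkerPanel
    ari_2h: float
    ari_24h: float
    reference_effects: dict[str, float]


def _stage(name, fn, log, **params):
    try:
        out = fn()
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(f"{name}: {exc}") from exc
    log.append({"stage": name, "params": params})
    return out


def run_reference_build(config: RunConfig, outdir: Optional[str | Path] = None):
    """Build patterns and both panels from a simulated reference study.

    Returns :class:`ReferenceArtifacts`; when ``outdir`` is given, writes
    the study, a pattern report, both panel JSONs, validation ARIs,
    measured reference effects and a structured log.
    """
    log: list[dict] = []
    seed = config.seed % _SEED_MOD
    sim_cfg = replace(config.sim, seed=seed)

    ref = _stage("simulate", lambda: simulate_reference_study(sim_cfg), log,
                 seed=seed, n_probes=sim_cfg.n_probes)
    corrected = _stage("preprocess", lambda: batch_correct(ref.expression), log)

    templates = make_archetype_templates()

    def _patterns():
        pats = extract_patterns(corrected, config.pattern_params)
        for p in pats:
            p.label = label_pattern(p, corrected, templates)
        return pats

    pats = _stage("patterns", _patterns, log, **asdict(config.pattern_params))

    spec2 = default_panel_spec_2h(k=config.panel_k, alpha=config.panel_alpha)
    spec24 = default_panel_spec_24h(k=config.panel_k, alpha=config.panel_alpha)
    panel2 = _stage("derive_panel_2h", lambda: derive_panel(corrected, spec2, pats), log,
                    k=config.panel_k)
    panel24 = _stage("derive_panel_24h", lambda: derive_panel(corrected, spec24, pats), log,
                     k=config.panel_k)
    ari2 = _stage("validate_panel_2h", lambda: validate_panel_clustering(corrected, panel2), log)
    ari24 = _stage("validate_panel_24h", lambda: validate_panel_clustering(corrected, panel24), log)

    ref_effects = _stage(
        "reference_effects",
        lambda: reference_effects_from_table(
            ref.phenotypes,
            {e.name: e.reference_class for e in default_endpoint_effects()},
        ),
        log,
    )

    artifacts = ReferenceArtifacts(
        corrected=corrected,
        patterns=pats,
        panel_2h=panel2,
        panel_24h=panel24,
        ari_2h=ari2,
        ari_24h=ari24,
        reference_effects=ref_effects,
    )
    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "reference").mkdir(parents=True, exist_ok=True)
        write_synthetic_study(ref, outdir / "reference")
        _dump_json(patterns_report(pats), outdir / "patterns.json")
        save_panel(panel2, outdir / "panel_2h.json")
        save_panel(panel24, outdir / "panel_24h.json")
        _dump_json({"ari_2h": ari2, "ari_24h": ari24}, outdir / "validation.json")
        _dump_json(ref_effects, outdir / "reference_effects.json")
        _dump_json({"stages": log, "seed": seed}, outdir / "reference_log.json")
    return artifacts


def screen_compound(
    spec: CompoundSpec,
    config: RunConfig,
    artifacts: ReferenceArtifacts,
    seed: int,
) -> CompoundClassification:
    """Simulate one test compound and classify it against the reference build."""
    study = simulate_test_compound(
        spec.class_label, potency=spec.potency, persistence=spec.persistence,
        seed=seed, cfg=replace(config.sim, seed=seed), treatment="test",
    )
    corrected = batch_correct(study.expression)
    dev2 = deviation_from_vehicle(corrected, 2, treatment="test",
                                  probes=artifacts.panel_2h.probes)
    dev24 = deviation_from_vehicle(corrected, 24, treatment="test",
                                   probes=artifacts.panel_24h.probes)
    est = estrogenicity_score(dev2, artifacts.panel_2h)
    lon = longevity_score(dev24, artifacts.panel_24h)
    calls = call_endpoints_for_compound(
        study.phenotypes, "test", artifacts.reference_effects,
        alpha=config.endpoint_alpha, method=config.endpoint_method,
    )
    return classify_compound(est, lon, calls, thresholds=config.thresholds,
                             compound=spec.name)


def run_compound_screen(
    config: RunConfig,
    artifacts: ReferenceArtifacts,
    outdir: Optional[str | Path] = None,
) -> list[CompoundClassification | dict]:
    """Classify every configured compound; per-compound errors don't stop the run."""
    results: list[CompoundClassification | dict] = []
    for i, spec in enumerate(config.compounds):
        seed = (config.seed + _COMPOUND_SEED_BASE + i) % _SEED_MOD
        try:
            results.append(screen_compound(spec, config, artifacts, seed))
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - recorded, run continues
            results.append({"compound": spec.name, "error": str(exc)})
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        payload = [
            classification_to_json(r) if isinstance(r, CompoundClassification) else r
            for r in results
        ]
        _dump_json({"classifications": payload}, outdir / "classifications.json")
    return results


def run_all(config: RunConfig, outdir: str | Path):
    """Full screen: reference build then compound screen, all artifacts written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts = run_reference_build(config, outdir)
    results = run_compound_screen(config, artifacts, outdir)
    return artifacts, results


def _dump_json(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
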
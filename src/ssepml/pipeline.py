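"""End-to-end pipeline: simulate -> features -> normalize -> select -> model -> report.

One config (YAML/JSON or :class:`PipelineConfig`) drives every stage; all
randomness descends from the generator seed plus a split seed, and rerunning
the same config reproduces byte-identical reports. Artifacts land in a run
directory::

    out_dir/
      manifest.json            config hash, package version, seeds
      sessions/P01.json ...    session files + anesthesia CSVs
      features.csv             assembled feature table
      reports/<nerve>.json     per-nerve tournament report
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .evaluation import make_split_plan, model_tournament
from .features import FeatureConfig, assemble_feature_table
from .models import PRESET_ORDER
from .session import NERVES, write_anesthesia_csv, write_session
from .synth import ConcentrationProfile, GeneratorConfig, generate_cohort


@dataclass(frozen=True)
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    nerves: tuple[str, ...] = NERVES
    presets: tuple[str, ...] = PRESET_ORDER
    mrmr_k: int = 10
    n_test_patients: int = 2
    cv_folds: int = 5
    split_seed: int | None = None  # defaults to the generator seed
    grouped_cv: bool = False
    fit_normalizer_on_all: bool = False
    write_sessions: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        gen = d.pop("generator", {})
        profile = ConcentrationProfile(**gen.pop("concentration_profile", {}))
        generator = GeneratorConfig(concentration_profile=profile, **gen)
        feat = d.pop("features", {})
        if "tfa_band_hz" in feat:
            feat["tfa_band_hz"] = tuple(feat["tfa_band_hz"])
        features = FeatureConfig(**feat)
        for key in ("nerves", "presets"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(generator=generator, features=features, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)


def _config_digest(cfg: PipelineConfig) -> str:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj
    canon = json.dumps(enc(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def run_pipeline(
    config: PipelineConfig | str | Path, out_dir: str | Path
) -> dict:
    """Execute every stage and write artifacts; returns the manifest dict.

    Any stage failure is re-raised annotated with the stage name.
    """
    cfg = (
        config
        if isinstance(config, PipelineConfig)
        else PipelineConfig.from_yaml(config)
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    split_seed = cfg.split_seed if cfg.split_seed is not None else cfg.generator.seed

    stage = "simulate"
    try:
        cohort = generate_cohort(cfg.generator)
        if cfg.write_sessions:
            sess_dir = out / "sessions"
            sess_dir.mkdir(exist_ok=True)
            for session in cohort:
                write_session(session, sess_dir / f"{session.patient_id}.json")
                write_anesthesia_csv(
                    session.anesthesia, sess_dir / f"{session.patient_id}_anesthesia.csv"
                )

        stage = "features"
        table = assemble_feature_table(cohort, cfg.features)
        table.to_csv(out / "features.csv", index=False)

        stage = "split"
        plan = make_split_plan(
            sorted(table["patient_id"].unique()),
            n_test=cfg.n_test_patients,
            cv_folds=cfg.cv_folds,
            seed=split_seed,
            grouped_cv=cfg.grouped_cv,
        )

        stage = "evaluate"
        reports_dir = out / "reports"
        reports_dir.mkdir(exist_ok=True)
        report_files = {}
        for nerve in cfg.nerves:
            rep = model_tournament(
                table,
                nerve,
                plan,
                presets=cfg.presets,
                k=cfg.mrmr_k,
                fit_normalizer_on_all=cfg.fit_normalizer_on_all,
            )
            payload = {
                "nerve": nerve,
                "train_patients": plan.train_patients,
                "test_patients": plan.test_patients,
                "selected_features": rep.selected_features,
                "mrmr_scores": {f: rep.mrmr.scores[f] for f in rep.selected_features},
                "n_significant": rep.mrmr.n_significant,
                "validation": {
                    name: {
                        key: m[key] for key in ("rmse", "r2", "mse", "mae")
                    }
                    for name, m in rep.validation.items()
                },
                "winner": rep.winner,
                "rmse_test": rep.rmse_test,
                "test_truth": rep.test_truth.tolist(),
                "test_predictions": rep.test_predictions.tolist(),
            }
            path = reports_dir / f"{nerve}.json"
            path.write_text(json.dumps(payload, indent=1, sort_keys=True))
            report_files[nerve] = str(path.relative_to(out))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config_sha256": _config_digest(cfg),
        "ssepml_version": __version__,
        "generator_seed": cfg.generator.seed,
        "split_seed": split_seed,
        "n_patients": cfg.generator.n_patients,
        "reports": report_files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
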
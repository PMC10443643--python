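"""End-to-end orchestration: synth -> preprocess -> section -> features ->
statistics and classification, as a configured, logged, reproducible run.

Every stage writes its intermediates as plain text (CSV / TSV / JSON) under
the output directory, and a ``manifest.json`` records the configuration,
seeds, package version and the SHA-256 of every artifact.  Re-running from
the manifest reproduces all outputs byte for byte: every randomized step
takes its seed from the config, never from global state, and no timestamps
enter the files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .classify import kfold_validate, loso_validate, prepare_dataset
from .features import WINDOW_S, SectionedChannel, build_feature_table
from .preprocess import EDGE_GUARD_S, preprocess_recording
from .recording import Channel, OpticalRecording
from .sectioning import (
    ProtocolTiming,
    ValsalvaParams,
    section_tilting,
    section_valsalva,
    write_sections,
)
from .stats import feature_statistics
from .synth import SynthConfig, generate_recording

logger = logging.getLogger("nirpulse.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    ``synth`` holds keyword overrides for :class:`~nirpulse.synth.SynthConfig`
    (protocol, durations, effect sizes, ...); the remaining fields control
    windowing, statistics and validation.
    """

    out_dir: str = "run"
    intervention: str = "tilting"
    n_subjects: int = 4
    synth: dict = field(default_factory=dict)
    window_s: float | None = None        # default: 15 s tilting / 5 s valsalva
    alpha: float = 0.05
    boxcox: str = "auto"
    synth_seed: int = 0
    undersample_seed: int = 0
    kfold_seed: int = 0
    kfold_k: int = 10
    strict_scaling: bool = False

    def __post_init__(self) -> None:
        if self.intervention not in ("tilting", "valsalva"):
            raise ValueError("intervention must be 'tilting' or 'valsalva'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.window_s is not None and self.window_s <= 0:
            raise ValueError("window_s must be positive")
        for name in ("synth_seed", "undersample_seed", "kfold_seed"):
            if not isinstance(getattr(self, name), int):
                raise ValueError(f"{name} must be an integer")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        # YAML/JSON round-trips turn tuples into lists; normalize
        self.synth = {
            k: tuple(v) if isinstance(v, list) else v for k, v in self.synth.items()
        }

    @property
    def effective_window_s(self) -> float:
        return self.window_s if self.window_s is not None else WINDOW_S[self.intervention]

    def synth_config(self) -> SynthConfig:
        return SynthConfig(
            protocol=self.intervention,
            n_subjects=self.n_subjects,
            seed=self.synth_seed,
            **self.synth,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the manifest (also written as JSON).

    Any stage error aborts the run with the stage name and offending
    subject/channel; an incomplete manifest marking the failed stage is left
    behind.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scfg = config.synth_config()
    subjects = [f"s{i + 1:02d}" for i in range(config.n_subjects)]
    timing = ProtocolTiming(
        nominal_durations_s=(scfg.supine1_s, scfg.trendelenburg_s, scfg.supine2_s)
    )
    artifacts: list[Path] = []
    stage = "init"
    processed: list[str] = []
    try:
        # -- synthesis ----------------------------------------------------
        stage = "synth"
        t0 = time.perf_counter()
        recordings: dict[str, OpticalRecording] = {}
        for subject in subjects:
            rec, truth = generate_recording(scfg, subject)
            recordings[subject] = rec
            raw_path = out / f"raw_{subject}.csv"
            rec.to_csv(raw_path)
            gt_path = out / f"ground_truth_{subject}.json"
            truth.to_json(gt_path)
            artifacts += [raw_path, gt_path]
        logger.info("synth: %d subjects in %.1fs", len(subjects), time.perf_counter() - t0)

        # -- preprocessing and sectioning ---------------------------------
        stage = "preprocess"
        t0 = time.perf_counter()
        items: list[SectionedChannel] = []
        for subject in subjects:
            rec = recordings[subject]
            try:
                decomp = preprocess_recording(rec)
            except ValueError as exc:
                raise PipelineError("preprocess", f"subject {subject}: {exc}") from exc
            stage = "section"
            rate = next(iter(decomp.values())).sample_rate_hz
            n = len(next(iter(decomp.values())).normalized)
            if config.intervention == "tilting":
                sections = section_tilting(n, rate, timing)
            else:
                driver = decomp[Channel("distal", scfg.wavelengths[0]).name].normalized
                sections = section_valsalva(driver, rate, ValsalvaParams())
            sec_path = out / f"sections_{subject}.tsv"
            write_sections(sections, rate, sec_path)
            artifacts.append(sec_path)
            for ch in sorted(rec.channels, key=lambda c: c.name):
                items.append(
                    SectionedChannel(
                        subject_id=subject,
                        intervention=config.intervention,
                        detector=ch.detector,
                        wavelength_nm=ch.wavelength_nm,
                        normalized=decomp[ch.name].normalized,
                        rate_hz=rate,
                        sections=sections,
                    )
                )
            processed.append(subject)
            stage = "preprocess"
        logger.info("preprocess+section in %.1fs", time.perf_counter() - t0)

        # -- features -----------------------------------------------------
        stage = "features"
        t0 = time.perf_counter()
        table = build_feature_table(items, config.effective_window_s, edge_guard_s=EDGE_GUARD_S)
        if table.empty:
            raise PipelineError("features", "feature table is empty")
        feat_path = out / "features.csv"
        table.to_csv(feat_path, index=False)
        artifacts.append(feat_path)
        logger.info("features: %d rows in %.1fs", len(table), time.perf_counter() - t0)

        # -- statistics ---------------------------------------------------
        stage = "stats"
        t0 = time.perf_counter()
        stats_table = feature_statistics(
            table, config.intervention, alpha=config.alpha, boxcox=config.boxcox
        )
        stats_path = out / "stats.csv"
        stats_table.to_csv(stats_path, index=False)
        artifacts.append(stats_path)
        logger.info("stats in %.1fs", time.perf_counter() - t0)

        # -- classification -----------------------------------------------
        stage = "classify"
        t0 = time.perf_counter()
        ds = prepare_dataset(table, config.intervention, seed=config.undersample_seed)
        loso = loso_validate(ds, strict_scaling=config.strict_scaling)
        kfold = kfold_validate(
            ds, k=min(config.kfold_k, ds.n), seed=config.kfold_seed,
            strict_scaling=config.strict_scaling,
        )
        import pandas as pd

        cls_path = out / "classification.csv"
        pd.concat([loso.to_frame(), kfold.to_frame()]).to_csv(cls_path, index=False)
        summary_path = out / "classification_summary.csv"
        pd.concat([loso.summary(), kfold.summary()]).to_csv(summary_path, index=False)
        artifacts += [cls_path, summary_path]
        logger.info("classification in %.1fs", time.perf_counter() - t0)
    except PipelineError:
        _write_manifest(out, config, processed, artifacts, status="incomplete", stage=stage)
        raise
    except Exception as exc:
        _write_manifest(out, config, processed, artifacts, status="incomplete", stage=stage)
        raise PipelineError(stage, str(exc)) from exc

    return _write_manifest(out, config, processed, artifacts, status="complete", stage=None)


def _write_manifest(out, config, processed, artifacts, status, stage):
    manifest = {
        "status": status,
        "failed_stage": stage,
        "version": __version__,
        "config": config.to_dict(),
        "subjects": processed,
        "outputs": {p.name: _sha256(p) for p in sorted(set(artifacts))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def run_from_manifest(manifest_path: str | Path, out_dir: str | Path) -> dict:
    """Re-run a finished pipeline from its manifest into a new directory."""
    manifest = json.loads(Path(manifest_path).read_text())
    cfg = RunConfig.from_dict({**manifest["config"], "out_dir": str(out_dir)})
    return run_pipeline(cfg)
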
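"""End-to-end pipeline orchestration: records -> segments -> scalograms ->
images -> split -> train -> evaluation report, with a run manifest.

The default configuration mirrors the reference analysis setup: 500-sample
segments at 128 Hz, Morse wavelet gamma=3 / P^2=60 at 12 voices per octave,
jet-rendered images, Adam at learning rate 1e-4, batch 30, 15 epochs, and
an 80/20 train/validation division after reserving a fixed per-class test
set.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classify import ReferenceCNNClassifier
from .cwt_transform import MorseScalogram
from .dataio import ECGRecord, make_split, read_record, segment_record
from .imaging import ScalogramImager
from .metrics import MetricsReport, evaluate
from .synthetic import generate_dataset

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """All pipeline parameters in one validated bundle."""

    # data
    data_dir: str | None = None  # directory of labeled CSV records; None -> synthetic
    n_records_per_class: int = 30
    n_samples: int = 10048
    sampling_rate: float = 128.0
    seg_len: int = 500
    n_segments_per_record: int | None = 20
    # wavelet
    p2: float = 60.0
    gamma: float = 3.0
    voices_per_octave: int = 12
    freq_limits: tuple[float, float] | None = None
    # imaging
    image_size: int = 227
    levels: int = 128
    # split
    train_frac: float = 0.8
    test_per_class: int = 120
    group_by_record: bool = False
    # training
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 30
    max_epochs: int = 15
    validation_frequency: int = 18
    # reproducibility
    seed: int = 0

    def validate(self) -> None:
        if self.seg_len < 4:
            raise ValueError(f"seg_len must be >= 4, got {self.seg_len}")
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if self.p2 <= 0 or self.gamma <= 0:
            raise ValueError(f"p2 and gamma must be positive, got p2={self.p2}, gamma={self.gamma}")
        if self.voices_per_octave < 1:
            raise ValueError(f"voices_per_octave must be >= 1, got {self.voices_per_octave}")
        if self.image_size < 32:
            raise ValueError(f"image_size must be >= 32, got {self.image_size}")
        if not 0 < self.train_frac < 1:
            raise ValueError(f"train_frac must be in (0, 1), got {self.train_frac}")
        if self.test_per_class < 1:
            raise ValueError(f"test_per_class must be >= 1, got {self.test_per_class}")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be positive, got {self.learning_rate}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.max_epochs < 0:
            raise ValueError(f"max_epochs must be >= 0, got {self.max_epochs}")


def load_config(mapping: dict) -> PipelineConfig:
    """Build a config from a plain mapping, rejecting unknown keys."""
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "freq_limits" in mapping and mapping["freq_limits"] is not None:
        mapping = {**mapping, "freq_limits": tuple(mapping["freq_limits"])}
    cfg = PipelineConfig(**mapping)
    cfg.validate()
    return cfg


def _load_records(config: PipelineConfig) -> list[ECGRecord]:
    if config.data_dir is None:
        return generate_dataset(
            n_records_per_class=config.n_records_per_class,
            n_samples=config.n_samples,
            sampling_rate=config.sampling_rate,
            seed=config.seed,
        )
    data_dir = Path(config.data_dir)
    manifest = data_dir / "labels.csv"
    if not manifest.exists():
        raise FileNotFoundError(
            f"labels manifest not found: {manifest} (expected 'file,label' lines)"
        )
    records = []
    for line in manifest.read_text().splitlines():
        line = line.strip()
        if not line or line.lower().startswith("file,"):
            continue
        fname, label = (p.strip() for p in line.split(","))
        records.append(
            read_record(
                data_dir / fname,
                format="csv",
                sampling_rate=config.sampling_rate,
                label=label,
            )
        )
    if not records:
        raise ValueError(f"{manifest}: no records listed")
    return records


def run_pipeline(
    config: PipelineConfig, out_dir=None, dry_run: bool = False
) -> MetricsReport | None:
    """Execute the full pipeline and return the test-set metrics report.

    With ``out_dir`` given, writes the report, confusion matrix, training
    history, split plan and a manifest (config + seed + version) under it.
    ``dry_run`` validates the configuration and returns None without
    computing.  Identical config and seed give identical reports.
    """
    config.validate()
    if dry_run:
        return None
    t0 = time.time()
    stage = "load-records"
    try:
        records = _load_records(config)
        stage = "segment"
        segments = [
            s
            for r in records
            for s in segment_record(r, config.seg_len, config.n_segments_per_record)
        ]
        stage = "split"
        plan = make_split(
            segments,
            train_frac=config.train_frac,
            test_per_class=config.test_per_class,
            seed=config.seed,
            group_by_record=config.group_by_record,
        )
        by_id = {s.segment_id: s for s in segments}
        parts = {
            p: [by_id[sid] for sid in sorted(plan.ids(p))]
            for p in ("train", "validation", "test")
        }

        stage = "scalogram"
        tfr = MorseScalogram(
            sampling_rate=config.sampling_rate,
            gamma=config.gamma,
            p2=config.p2,
            voices_per_octave=config.voices_per_octave,
            freq_limits=config.freq_limits,
        )
        imager = ScalogramImager(size=(config.image_size, config.image_size), levels=config.levels)
        X = {}
        y = {}
        all_X = np.stack([s.samples for p in parts for s in parts[p]])
        tfr.fit(all_X[:1])
        for p in parts:
            sig = np.stack([s.samples for s in parts[p]])
            X[p] = imager.transform(tfr.transform(sig))
            y[p] = np.array([s.label for s in parts[p]])

        stage = "train"
        clf = ReferenceCNNClassifier(
            input_size=(config.image_size, config.image_size),
            optimizer=config.optimizer,
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            max_epochs=config.max_epochs,
            validation_frequency=config.validation_frequency,
            random_state=config.seed,
        )
        clf.fit(X["train"], y["train"], validation_data=(X["validation"], y["validation"]))

        stage = "evaluate"
        y_pred = clf.predict(X["test"])
        report = evaluate(y["test"], y_pred, class_order=list(clf.classes_))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_frame().to_csv(out / "metrics.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        clf.history_.to_frame().to_csv(out / "history.csv", index=False)
        with open(out / "split.json", "w") as fh:
            json.dump({"seed": plan.seed, "assignment": plan.assignment}, fh, indent=2)
        manifest = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(config).items()
            },
            "seed": config.seed,
            "version": __version__,
            "runtime_seconds": round(time.time() - t0, 2),
            "n_segments": {p: len(parts[p]) for p in parts},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return report
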
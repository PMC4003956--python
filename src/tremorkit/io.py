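"""Session and file management: recordings, feature tables, models, reports.

A recording is stored as a human-auditable CSV: ``#``-prefixed header
lines carrying the session metadata (patient id, pattern, hand, sampling
rate, diagnostic label, free-form remarks) followed by ``t,x,y,z`` sample
rows written at full float precision, one file per test.  Models and
experiment reports are JSON; run configurations are YAML and round-trip
losslessly, and every output table carries the configuration hash for
provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from .features import FEATURE_NAMES, SpectralSettings, extract_features
from .patterns import make_pattern
from .simulate import Cohort, CohortSpec, Recording, generate_cohort

__all__ = [
    "read_recording",
    "write_recording",
    "SessionStore",
    "features_to_frame",
    "read_feature_table",
    "write_feature_table",
    "save_model",
    "load_model",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger("tremorkit")

_FLOAT_FMT = "%.17g"


class RecordingParseError(ValueError):
    """A recording file failed validation; the message names the line."""


def write_recording(recording: Recording, path) -> Path:
    """Write a recording to CSV with ``#`` metadata header lines."""
    path = Path(path)
    lines = [
        f"# patient_id: {recording.patient_id}",
        f"# pattern_id: {recording.pattern_id}",
        f"# hand: {recording.hand}",
        f"# fs: {recording.fs!r}",
        f"# label: {recording.label}",
        f"# metadata: {json.dumps(recording.metadata, sort_keys=True)}",
        "t,x,y,z",
    ]
    rows = np.column_stack([recording.t, recording.xyz])
    body = "\n".join(",".join(_FLOAT_FMT % v for v in row) for row in rows)
    path.write_text("\n".join(lines) + "\n" + body + "\n")
    return path


def read_recording(path) -> Recording:
    """Parse a recording CSV, validating the header and sample uniformity."""
    path = Path(path)
    header: dict = {}
    samples = []
    sample_lines = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" not in line:
                    raise RecordingParseError(
                        f"{path}:{lineno}: malformed header line {line!r}")
                key, _, value = line[1:].partition(":")
                header[key.strip()] = value.strip()
            elif line.startswith("t,"):
                continue
            else:
                parts = line.split(",")
                if len(parts) != 4:
                    raise RecordingParseError(
                        f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
                try:
                    samples.append([float(p) for p in parts])
                    sample_lines.append(lineno)
                except ValueError as exc:
                    raise RecordingParseError(
                        f"{path}:{lineno}: non-numeric sample: {exc}") from None
    if "fs" not in header:
        raise RecordingParseError(f"{path}: missing 'fs' header line")
    if not samples:
        raise RecordingParseError(f"{path}: no sample rows")
    arr = np.asarray(samples, float)
    fs = float(header["fs"])
    dt = np.diff(arr[:, 0])
    bad = np.nonzero(~np.isclose(dt, 1.0 / fs, rtol=1e-6, atol=1e-9))[0]
    if bad.size:
        raise RecordingParseError(
            f"{path}:{sample_lines[bad[0] + 1]}: non-uniform timestamp "
            f"(dt={float(dt[bad[0]])!r}, expected {1.0 / fs!r})")
    pattern_id = header.get("pattern_id", "None")
    try:
        meta = json.loads(header.get("metadata", "{}"))
    except json.JSONDecodeError as exc:
        raise RecordingParseError(f"{path}: bad metadata JSON: {exc}") from None
    return Recording(
        patient_id=header.get("patient_id", ""),
        pattern_id=None if pattern_id == "None" else int(pattern_id),
        hand=header.get("hand", "right"),
        fs=fs,
        t=arr[:, 0],
        xyz=arr[:, 1:4],
        label=header.get("label", "unknown"),
        metadata=meta,
    )


class SessionStore:
    """A directory of recording files indexed by patient, pattern and hand."""

    def __init__(self, root):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)

    def path_for(self, recording: Recording) -> Path:
        return (self.root /
                f"{recording.patient_id}_p{recording.pattern_id}_{recording.hand}.csv")

    def add(self, recording: Recording) -> Path:
        return write_recording(recording, self.path_for(recording))

    def files(self) -> list:
        return sorted(self.root.glob("*.csv"))

    def index(self) -> pd.DataFrame:
        rows = []
        for f in self.files():
            rec = read_recording(f)  # every indexed file must parse
            rows.append({"file": f.name, "patient_id": rec.patient_id,
                         "pattern_id": rec.pattern_id, "hand": rec.hand,
                         "label": rec.label, "n_samples": rec.n_samples,
                         "fs": rec.fs})
        return pd.DataFrame(rows)

    def load_all(self) -> list:
        return [read_recording(f) for f in self.files()]


# ---------------------------------------------------------------------------
# feature tables / models
# ---------------------------------------------------------------------------

def features_to_frame(recordings: Sequence[Recording],
                      vectors, split: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Tabulate feature vectors with recording identifiers and labels."""
    rows = []
    for i, (rec, vec) in enumerate(zip(recordings, vectors)):
        row = {"patient_id": rec.patient_id, "pattern_id": rec.pattern_id,
               "hand": rec.hand, "label": rec.label}
        if split is not None:
            row["split"] = split[i]
        row.update(vec.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def write_feature_table(frame: pd.DataFrame, path,
                        config_hash: Optional[str] = None) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        frame.to_csv(fh, index=False, float_format=_FLOAT_FMT)
    return path


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def save_model(model, path) -> Path:
    path = Path(path)
    path.write_text(model.to_json())
    return path


def load_model(path):
    return _classify.MLPModel.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Everything a full simulate -> features -> classify run needs."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    groups: tuple = ("psd_only", "hos_only", "all")
    hidden_min: int = 2
    hidden_max: int = 10
    repeats: int = 10
    epochs: int = 200
    learning_rate: float = 0.01
    spectral: SpectralSettings = field(default_factory=SpectralSettings)
    seed: int = 0
    save_recordings: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortSpec(**d["cohort"])
        if "spectral" in d and isinstance(d["spectral"], dict):
            d["spectral"] = SpectralSettings(**d["spectral"])
        if "groups" in d:
            d["groups"] = tuple(d["groups"])
        return RunConfig(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(_listify(self.to_dict()), sort_keys=True)

    @staticmethod
    def from_yaml(text: str) -> "RunConfig":
        return RunConfig.from_dict(yaml.safe_load(text))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_listify(v) for v in obj]
    return obj


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run simulate -> features -> train/evaluate -> report, fully seeded.

    Writes ``features.csv``, ``report.json`` and per-group error tables to
    ``out_dir`` (plus the recording files when ``save_recordings`` is
    set).  Returns the report dictionary.  Identical configurations yield
    byte-identical outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash

    @_stage("simulate")
    def _simulate() -> Cohort:
        cohort = generate_cohort(config.cohort)
        if not cohort.recordings:
            raise ValueError("cohort is empty (all class counts are zero)")
        logger.info("simulate: seed=%s n_train=%d n_validation=%d",
                    config.cohort.master_seed, len(cohort.train_idx),
                    len(cohort.validation_idx))
        return cohort

    cohort = _simulate()
    if config.save_recordings:
        store = SessionStore(out_dir / "recordings")
        for rec in cohort.recordings:
            store.add(rec)

    @_stage("features")
    def _features():
        pattern = make_pattern(config.cohort.pattern_id)
        vectors = [extract_features(rec, pattern, config.spectral)
                   for rec in cohort.recordings]
        split = np.array(["train"] * len(cohort.recordings), dtype=object)
        split[cohort.validation_idx] = "validation"
        frame = features_to_frame(cohort.recordings, vectors, split=split)
        logger.info("features: %d vectors x %d parameters",
                    len(vectors), len(FEATURE_NAMES))
        return frame

    frame = _features()
    write_feature_table(frame, out_dir / "features.csv", config_hash=chash)

    @_stage("classify")
    def _classify_stage():
        X = frame[list(FEATURE_NAMES)].to_numpy()
        y = frame["label"].to_numpy()
        is_tr = (frame["split"] == "train").to_numpy()
        results = {}
        for group in config.groups:
            res = _classify.run_test_group(
                X[is_tr], y[is_tr], X[~is_tr], y[~is_tr], group,
                hidden_range=range(config.hidden_min, config.hidden_max + 1),
                repeats=config.repeats, epochs=config.epochs,
                seed=config.seed, learning_rate=config.learning_rate)
            results[group] = res
            best = min(res, key=lambda r: r.mean_error)
            logger.info("classify: group=%s best hidden_n=%d mean_error=%.3f",
                        group, best.hidden_n, best.mean_error)
        return results

    results = _classify_stage()

    @_stage("report")
    def _report() -> dict:
        report = {"config_hash": chash, "seed": config.seed, "groups": {}}
        mean_rows, share_rows = [], []
        for group, res_list in results.items():
            report["groups"][group] = [dataclasses.asdict(r) for r in res_list]
            for r in res_list:
                mean_rows.append({"config_hash": chash, "group": group,
                                  "hidden_n": r.hidden_n,
                                  "mean_error": r.mean_error})
                share_rows.append({"config_hash": chash, "group": group,
                                   "hidden_n": r.hidden_n,
                                   **{f"share_{c}": v for c, v in
                                      r.per_class_error_share.items()}})
        (out_dir / "report.json").write_text(json.dumps(report, indent=2,
                                                        sort_keys=True))
        pd.DataFrame(mean_rows).to_csv(out_dir / "mean_error.csv", index=False,
                                       float_format=_FLOAT_FMT)
        pd.DataFrame(share_rows).to_csv(out_dir / "error_shares.csv",
                                        index=False, float_format=_FLOAT_FMT)
        logger.info("report: wrote %s", out_dir / "report.json")
        return report

    return _report()
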
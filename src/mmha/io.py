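"""On-disk formats, configuration serialization, and structured run logs.

Formats: EEG clips as raw float32 ``.bin`` + JSON header (an EDF reader via
mne is used when a clip path ends in ``.edf``); face frames as 8-bit PNG;
the manifest as CSV (subject, clip, emotion, window, eeg_path, frame_path);
feature tensors (DE and topographic stacks) in HDF5 with provenance
attributes; model checkpoints as NPZ with the architecture config embedded.
Every artifact records the hash of the producing configuration, and the run
log is JSON-lines so downstream checks can assert on recorded split
checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .features import EMOTIONS, EEGRecording, FaceFrame
from .networks import ModelConfig
from .protocol import ExperimentConfig, TrainConfig
from .synthgen import Signature, SynthConfig, SynthDataset

__all__ = [
    "config_hash", "write_dataset", "read_dataset", "read_manifest",
    "write_features", "read_features", "save_checkpoint", "load_checkpoint",
    "RunLog", "experiment_config_to_json", "experiment_config_from_json",
]

MANIFEST_COLUMNS = ("subject", "clip", "emotion", "window",
                    "eeg_path", "frame_path")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_hash(config) -> str:
    """Stable short hash of any (nested-dataclass) configuration."""
    text = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


# -------------------------------------------------------------------- dataset


def write_dataset(ds: SynthDataset, outdir) -> Path:
    """Write EEG .bin+.json, PNG frames, manifest CSV, and config JSON.

    Returns the manifest path.
    """
    outdir = Path(outdir)
    (outdir / "eeg").mkdir(parents=True, exist_ok=True)
    (outdir / "frames").mkdir(parents=True, exist_ok=True)
    chash = config_hash(ds.config)
    eeg_paths = {}
    for rec in ds.eeg_recordings:
        stem = f"{rec.subject_id}_{rec.clip_id}"
        bin_path = outdir / "eeg" / f"{stem}.bin"
        rec.data.astype("<f4").tofile(bin_path)
        header = {
            "shape": list(rec.data.shape), "dtype": "<f4",
            "sample_rate": rec.sample_rate, "channel_names": rec.channel_names,
            "subject": rec.subject_id, "clip": rec.clip_id,
            "emotion": rec.emotion, "config_hash": chash,
        }
        bin_path.with_suffix(".json").write_text(json.dumps(header, indent=1))
        eeg_paths[(rec.subject_id, rec.clip_id)] = f"eeg/{stem}.bin"
    frame_paths = []
    for f in ds.face_frames:
        name = f"frames/{f.subject_id}_{f.clip_id}_w{f.window:03d}.png"
        arr = (np.clip(f.pixels, 0, 1) * 255.0).round().astype(np.uint8)
        Image.fromarray(arr.transpose(1, 2, 0), mode="RGB").save(outdir / name)
        frame_paths.append(name)
    manifest = ds.manifest.copy()
    manifest["eeg_path"] = [eeg_paths[(s, c)] for s, c in
                            zip(manifest["subject"], manifest["clip"])]
    manifest["frame_path"] = frame_paths
    manifest_path = outdir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    (outdir / "config.json").write_text(
        json.dumps(_jsonable(ds.config) | {"config_hash": chash}, indent=1))
    return manifest_path


def read_manifest(path) -> pd.DataFrame:
    """Validated manifest: schema, emotion labels, key uniqueness, files."""
    path = Path(path)
    manifest = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    root = path.parent
    for i, row in manifest.iterrows():
        if row["emotion"] not in EMOTIONS:
            raise ValueError(
                f"row {i}: unknown emotion {row['emotion']!r} "
                f"(expected one of {EMOTIONS})")
        for col in ("eeg_path", "frame_path"):
            if not (root / row[col]).exists():
                raise ValueError(f"row {i}: missing file {root / row[col]}")
    keys = list(zip(manifest["subject"], manifest["clip"], manifest["window"]))
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (subject, clip, window) keys in manifest")
    return manifest


def _read_eeg_clip(path: Path) -> tuple[np.ndarray, dict]:
    if path.suffix == ".edf":
        import mne
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return raw.get_data() * 1e6, {  # volts -> microvolts
            "sample_rate": float(raw.info["sfreq"]),
            "channel_names": list(raw.ch_names)}
    header = json.loads(path.with_suffix(".json").read_text())
    data = np.fromfile(path, dtype=header["dtype"]).reshape(header["shape"])
    return data, header


def read_dataset(manifest_path) -> SynthDataset:
    """Load a dataset directory back into memory (lazily per clip/frame)."""
    manifest = read_manifest(manifest_path)
    root = Path(manifest_path).parent
    recs = []
    for (subject, clip), group in manifest.groupby(["subject", "clip"],
                                                   sort=False):
        path = root / group["eeg_path"].iloc[0]
        data, header = _read_eeg_clip(path)
        recs.append(EEGRecording(
            data, header["sample_rate"],
            list(header.get("channel_names", [])) or
            [f"ch{i}" for i in range(data.shape[0])],
            subject, clip, group["emotion"].iloc[0]))
    frames = []
    for _, row in manifest.iterrows():
        img = Image.open(root / row["frame_path"]).convert("RGB")
        pix = (np.asarray(img, np.float32) / 255.0).transpose(2, 0, 1)
        frames.append(FaceFrame(pix, row["subject"], row["clip"],
                                int(row["window"]), row["emotion"]))
    labels = {(r.subject_id, r.clip_id): r.emotion for r in recs}
    cfg_path = root / "config.json"
    config = None
    if cfg_path.exists():
        raw = json.loads(cfg_path.read_text())
        raw.pop("config_hash", None)
        raw["band_signatures"] = {
            emo: tuple(Signature(**s) for s in sigs)
            for emo, sigs in raw["band_signatures"].items()}
        for key in ("emotions",):
            raw[key] = tuple(raw[key])
        config = SynthConfig(**raw)
    return SynthDataset(recs, frames,
                        labels, manifest, config)


# ------------------------------------------------------------------- features


def write_features(path, de: np.ndarray, manifest: pd.DataFrame,
                   band_edges, montage_digest: str, floor: float,
                   topo: np.ndarray | None = None, chash: str = ""):
    import h5py
    with h5py.File(path, "w") as h5:
        h5.create_dataset("de", data=de)
        if topo is not None:
            h5.create_dataset("topo", data=topo)
        for col in ("subject", "clip", "emotion"):
            h5.create_dataset(f"manifest/{col}",
                              data=manifest[col].astype(str).values,
                              dtype=h5py.string_dtype())
        h5.create_dataset("manifest/window", data=manifest["window"].values)
        h5.attrs["band_edges"] = np.asarray(band_edges, float)
        h5.attrs["montage_digest"] = montage_digest
        h5.attrs["clamp_floor"] = floor
        h5.attrs["config_hash"] = chash


def read_features(path) -> dict:
    import h5py
    out = {}
    with h5py.File(path, "r") as h5:
        if "de" not in h5:
            raise ValueError(f"{path}: not a feature file (no 'de' dataset)")
        out["de"] = h5["de"][...]
        if "topo" in h5:
            out["topo"] = h5["topo"][...]
        out["manifest"] = pd.DataFrame({
            "subject": [s.decode() if isinstance(s, bytes) else s
                        for s in h5["manifest/subject"][...]],
            "clip": [s.decode() if isinstance(s, bytes) else s
                     for s in h5["manifest/clip"][...]],
            "emotion": [s.decode() if isinstance(s, bytes) else s
                        for s in h5["manifest/emotion"][...]],
            "window": h5["manifest/window"][...],
        })
        out["attrs"] = dict(h5.attrs)
    return out


# ----------------------------------------------------------------- checkpoint


def save_checkpoint(model, config: ModelConfig, path):
    state = model.named_state()
    np.savez(path, __config__=np.frombuffer(
        config.to_json().encode(), dtype=np.uint8), **state)


def load_checkpoint(path, builder):
    """Rebuild a model: ``builder(config) -> model`` then load weights."""
    with np.load(path) as z:
        config = ModelConfig.from_json(bytes(z["__config__"]).decode())
        model = builder(config)
        state = {k: z[k] for k in z.files if k != "__config__"}
    model.load_state(state)
    return model


# -------------------------------------------------------------------- run log


class RunLog:
    """JSON-lines structured log; every event carries the config hash+seed."""

    def __init__(self, path, config=None, seed: int | None = None):
        self.path = Path(path)
        self.chash = config_hash(config) if config is not None else None
        self.seed = seed
        self._fh = open(self.path, "a")

    def event(self, name: str, **fields):
        record = {"t": time.time(), "event": name,
                  "config_hash": self.chash, "seed": self.seed} | _jsonable(fields)
        self._fh.write(json.dumps(record) + "\n")
        self._fh.flush()

    def close(self):
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
        return False

    @staticmethod
    def read(path) -> list[dict]:
        return [json.loads(line) for line in Path(path).read_text().splitlines()
                if line.strip()]


# ------------------------------------------------------- experiment config IO


def experiment_config_to_json(cfg: ExperimentConfig) -> str:
    return json.dumps(_jsonable(cfg), indent=2)


def experiment_config_from_json(text: str) -> ExperimentConfig:
    d = json.loads(text)
    synth = d.pop("synth", {})
    if "band_signatures" in synth:
        synth["band_signatures"] = {
            emo: tuple(Signature(**s) for s in sigs)
            for emo, sigs in synth["band_signatures"].items()}
    if "emotions" in synth:
        synth["emotions"] = tuple(synth["emotions"])
    model = d.pop("model", {})
    for k in ("efem_widths", "fefem_widths", "fefem_blocks"):
        if k in model:
            model[k] = tuple(model[k])
    train = d.pop("train", {})
    for k in ("folds", "methods"):
        if k in d:
            d[k] = tuple(d[k])
    return ExperimentConfig(synth=SynthConfig(**synth),
                            model=ModelConfig(**model),
                            train=TrainConfig(**train), **d)
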
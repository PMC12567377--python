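"""Training and evaluation protocol.

Splits are clip-wise: all 1 s windows of a stimulus clip stay on the same
side of a split, so window-level correlations within a clip can never leak
between training and validation.  Two protocols are provided: stratified
clip-wise k-fold (one clip per emotion per subject per fold) and
leave-one-subject-out.  Training follows the published recipe: cross
entropy, batch size 32, AdamW at 1e-3 with cosine-annealed learning rate

    eta_t = eta_min + (eta_max - eta_min) (1 + cos(pi t / T_max)) / 2

updated once per epoch by default.  Evaluation reports accuracy, a
row-normalized confusion matrix and per-subject accuracies; paired t-tests
compare methods across subjects; attention attribution aggregates the class
token's attention mass over EEG bands and facial regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .autodiff import Tensor, cross_entropy_logits
from .features import EMOTIONS, extract_de_features, normalize_faces
from .networks import (ConcatFusionModel, FusionModel, ModelConfig,
                       UnimodalModel, fuse_decision, scaled_config)
from .nn import Adam, SGD
from .synthgen import SynthConfig, SynthDataset, synth_dataset
from .topomap import default_layout, rasterize_many

__all__ = [
    "FoldSplit", "ScheduleConfig", "TrainConfig", "EvalReport",
    "AttributionReport", "ExperimentConfig", "ExperimentResult",
    "make_clip_folds", "make_loso_splits", "cosine_lr", "train_model",
    "evaluate", "paired_ttest", "attention_attribution",
    "default_face_region_masks", "build_arrays", "run_experiment",
]

FACE_REGIONS = ("forehead", "eyes", "cheeks", "mouth", "other")


# --------------------------------------------------------------------- splits


@dataclass
class FoldSplit:
    """Clip-level fold assignment: (subject, clip) -> fold in 1..k."""

    assignments: dict[tuple[str, str], int]
    k: int

    def fold_of_row(self, row) -> int:
        return self.assignments[(row["subject"], row["clip"])]

    def window_indices(self, manifest: pd.DataFrame, fold: int):
        folds = np.array([self.assignments[(s, c)] for s, c in
                          zip(manifest["subject"], manifest["clip"])])
        val = np.where(folds == fold)[0]
        train = np.where(folds != fold)[0]
        return train, val


def make_clip_folds(manifest: pd.DataFrame, k: int = 5,
                    seed: int = 0) -> FoldSplit:
    """Stratified clip-wise folds: within each subject, every fold receives
    the same number of clips of each emotion (one, in the reference design
    of five clips per emotion and five folds)."""
    rng = np.random.default_rng(seed)
    clips = manifest[["subject", "clip", "emotion"]].drop_duplicates()
    assignments: dict[tuple[str, str], int] = {}
    for (_, emotion), group in clips.groupby(["subject", "emotion"]):
        ids = sorted(group["clip"])
        if len(ids) % k:
            raise ValueError(
                f"{len(ids)} clips of {emotion!r} not divisible into {k} folds")
        order = rng.permutation(len(ids))
        for pos, ci in enumerate(order):
            key = (group["subject"].iloc[0], ids[ci])
            assignments[key] = pos % k + 1
    split = FoldSplit(assignments, k)
    _assert_no_clip_leakage(split, manifest)
    return split


def _assert_no_clip_leakage(split: FoldSplit, manifest: pd.DataFrame):
    for fold in range(1, split.k + 1):
        train, val = split.window_indices(manifest, fold)
        tr_clips = set(map(tuple, manifest.iloc[train][["subject", "clip"]].values))
        va_clips = set(map(tuple, manifest.iloc[val][["subject", "clip"]].values))
        if tr_clips & va_clips:
            raise AssertionError(f"clip leakage in fold {fold}")


def make_loso_splits(manifest: pd.DataFrame) -> list[tuple[list[str], str]]:
    """Leave-one-subject-out: (training subjects, held-out subject) pairs."""
    subjects = sorted(manifest["subject"].unique())
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    return [([s for s in subjects if s != held], held) for held in subjects]


# ------------------------------------------------------------------- schedule


@dataclass
class ScheduleConfig:
    eta_max: float = 1e-3
    eta_min: float = 0.0
    t_max: int = 100
    t_cur: int = 0

    def __post_init__(self):
        if not (0 <= self.eta_min <= self.eta_max):
            raise ValueError("need 0 <= eta_min <= eta_max")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        if not (0 <= self.t_cur <= self.t_max):
            raise ValueError("t_cur out of range")


def cosine_lr(cfg: ScheduleConfig) -> float:
    """Cosine-annealed learning rate at iteration t_cur."""
    return cfg.eta_min + 0.5 * (cfg.eta_max - cfg.eta_min) \
        * (1.0 + np.cos(np.pi * cfg.t_cur / cfg.t_max))


# ----------------------------------------------------------------- array data


@dataclass
class ArrayDataset:
    """Featurized dataset ready for training (all float32)."""

    topo: np.ndarray          # N x bands x S x S
    faces: np.ndarray         # N x 3 x S x S
    labels: np.ndarray        # N (int, index into EMOTIONS)
    subjects: np.ndarray      # N (str)
    manifest: pd.DataFrame

    def __len__(self):
        return len(self.labels)


def build_arrays(ds: SynthDataset, map_size: int = 64,
                 layout=None) -> ArrayDataset:
    """DE extraction + topographic rasterization + face normalization."""
    layout = layout or default_layout()
    topo_parts, label_parts, subj_parts = [], [], []
    for rec in ds.eeg_recordings:
        de = extract_de_features(rec)                  # w x ch x bands
        maps = rasterize_many(de.values.transpose(0, 2, 1), layout, map_size)
        topo_parts.append(maps.astype(np.float32))
        label_parts.extend([EMOTIONS.index(rec.emotion)] * de.values.shape[0])
        subj_parts.extend([rec.subject_id] * de.values.shape[0])
    frames = normalize_faces(ds.face_frames)
    faces = np.stack([f.pixels for f in frames]).astype(np.float32)
    return ArrayDataset(np.concatenate(topo_parts), faces,
                        np.asarray(label_parts, np.int64),
                        np.asarray(subj_parts), ds.manifest)


# ------------------------------------------------------------------- training


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 32
    eta_max: float = 1e-3
    eta_min: float = 0.0
    optimizer: str = "adamw"          # "adamw" | "adam" | "sgd"
    schedule_per_batch: bool = False  # default: one update per epoch
    seed: int = 0


def _model_inputs(model, data: ArrayDataset, idx: np.ndarray):
    topo = Tensor(data.topo[idx])
    faces = Tensor(data.faces[idx])
    if isinstance(model, (FusionModel, ConcatFusionModel)):
        return (topo, faces)
    if isinstance(model, UnimodalModel):
        return (topo,) if model.modality == "eeg" else (faces,)
    raise TypeError(f"unsupported model {type(model).__name__}")


def _logits(model, data, idx):
    out = model(*_model_inputs(model, data, idx))
    return out[0] if isinstance(out, tuple) else out


def train_model(model, data: ArrayDataset, train_idx: np.ndarray,
                cfg: TrainConfig = TrainConfig()):
    """Seeded mini-batch training; returns per-epoch loss/accuracy history."""
    if len(train_idx) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng([cfg.seed, 101])
    params = model.parameters()
    if cfg.optimizer in ("adamw", "adam"):
        opt = Adam(params, lr=cfg.eta_max,
                   weight_decay=1e-4 if cfg.optimizer == "adamw" else 0.0,
                   decoupled_weight_decay=cfg.optimizer == "adamw")
    elif cfg.optimizer == "sgd":
        opt = SGD(params, lr=cfg.eta_max, momentum=0.9)
    else:
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")
    n_batches = int(np.ceil(len(train_idx) / cfg.batch_size))
    t_max = cfg.epochs * n_batches if cfg.schedule_per_batch else cfg.epochs
    history = []
    model.train()
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_idx))
        losses, correct = [], 0
        for b in range(n_batches):
            t_cur = step if cfg.schedule_per_batch else epoch
            opt.lr = cosine_lr(ScheduleConfig(cfg.eta_max, cfg.eta_min,
                                              t_max, t_cur))
            idx = train_idx[order[b * cfg.batch_size:(b + 1) * cfg.batch_size]]
            opt.zero_grad()
            logits = _logits(model, data, idx)
            loss = cross_entropy_logits(logits, data.labels[idx])
            loss.backward()
            opt.step()
            step += 1
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(1) == data.labels[idx]).sum())
        history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                        "train_acc": 100.0 * correct / len(train_idx),
                        "lr": opt.lr})
    model.eval()
    return history


def predict_proba(model, data: ArrayDataset, idx: np.ndarray,
                  batch_size: int = 64) -> np.ndarray:
    model.eval()
    probs = []
    for b in range(0, len(idx), batch_size):
        z = _logits(model, data, idx[b:b + batch_size]).data
        e = np.exp(z - z.max(axis=1, keepdims=True))
        probs.append(e / e.sum(axis=1, keepdims=True))
    return np.concatenate(probs)


# ----------------------------------------------------------------- evaluation


@dataclass
class EvalReport:
    accuracy: float                       # percent
    confusion: np.ndarray                 # 4 x 4, row-normalized
    per_subject: dict[str, float]         # percent
    n: int


def report_from_predictions(pred: np.ndarray, labels: np.ndarray,
                            subjects: np.ndarray) -> EvalReport:
    if len(pred) == 0:
        raise ValueError("empty evaluation set")
    k = len(EMOTIONS)
    conf = np.zeros((k, k))
    for t, p in zip(labels, pred):
        conf[t, p] += 1
    rows = conf.sum(axis=1, keepdims=True)
    conf = np.divide(conf, rows, out=np.zeros_like(conf), where=rows > 0)
    per_subject = {
        s: 100.0 * float((pred[subjects == s] == labels[subjects == s]).mean())
        for s in np.unique(subjects)}
    return EvalReport(100.0 * float((pred == labels).mean()), conf,
                      per_subject, len(pred))


def evaluate(model, data: ArrayDataset, idx: np.ndarray) -> EvalReport:
    probs = predict_proba(model, data, idx)
    # argmax with lowest-index tie-break (numpy default)
    return report_from_predictions(probs.argmax(1), data.labels[idx],
                                   data.subjects[idx])


def paired_ttest(acc_a, acc_b) -> tuple[float, float]:
    """Two-sided paired t-test on per-subject accuracies.

    Returns (t, p); zero-variance differences yield (nan, nan) with a
    warning since the statistic is undefined.
    """
    a, b = np.asarray(acc_a, float), np.asarray(acc_b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length paired samples, n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        import warnings
        warnings.warn("zero-variance nonzero differences: t undefined")
        return float("nan"), float("nan")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------- attribution


@dataclass
class AttributionReport:
    band_weights: dict[str, float]        # sums to 1
    region_weights: dict[str, float]      # sums to 1


def default_face_region_masks(grid: int) -> dict[str, np.ndarray]:
    """Partition the g x g face-token grid into named facial regions by
    row/column fractions (forehead top, eyes upper-middle, cheeks lateral,
    mouth lower-center, the rest 'other')."""
    masks = {r: np.zeros(grid * grid, bool) for r in FACE_REGIONS}
    for i in range(grid):
        for j in range(grid):
            r = (i + 0.5) / grid
            c = (j + 0.5) / grid
            if r < 0.3:
                name = "forehead"
            elif r < 0.5:
                name = "eyes"
            elif r < 0.8:
                name = "cheeks" if (c < 1 / 3 or c >= 2 / 3) else "other"
            else:
                name = "mouth" if (1 / 3 <= c < 2 / 3) else "other"
            masks[name][i * grid + j] = True
    return masks


def attribution_from_records(records, n_eeg: int, n_face: int,
                             band_names, tokens_per_band: int,
                             region_masks: dict[str, np.ndarray]) -> AttributionReport:
    """Aggregate class-token attention mass from the last block.

    ``records`` is the per-block list of (B, heads, T, T) weight arrays with
    the class token at position 0, EEG tokens next (grouped by band), then
    face tokens."""
    cover = np.zeros(n_face, int)
    for m in region_masks.values():
        if m.shape != (n_face,):
            raise ValueError("region mask size mismatch with face token grid")
        cover += m.astype(int)
    if not np.all(cover == 1):
        raise ValueError("region masks must partition the face token grid")
    if n_eeg != len(band_names) * tokens_per_band:
        raise ValueError("EEG token count inconsistent with band grouping")
    w = np.asarray(records[-1].data if hasattr(records[-1], "data")
                   else records[-1])
    mass = w[:, :, 0, :].mean(axis=(0, 1))            # average heads, windows
    eeg_mass = mass[1:1 + n_eeg]
    face_mass = mass[1 + n_eeg:1 + n_eeg + n_face]
    band = {name: float(eeg_mass[i * tokens_per_band:(i + 1) * tokens_per_band].sum())
            for i, name in enumerate(band_names)}
    tot = sum(band.values())
    band = {k: v / tot for k, v in band.items()}
    region = {name: float(face_mass[m].sum()) for name, m in region_masks.items()}
    tot = sum(region.values())
    region = {k: v / tot for k, v in region.items()}
    return AttributionReport(band, region)


def attention_attribution(model: FusionModel, data: ArrayDataset,
                          idx: np.ndarray,
                          region_masks: dict[str, np.ndarray] | None = None,
                          batch_size: int = 64) -> AttributionReport:
    """Mean class-token attention per EEG band and facial region."""
    if not model.efem.per_band:
        raise ValueError("band attribution needs per-band EEG tokens")
    model.eval()
    map_size = data.topo.shape[-1]
    t_band = model.efem.tokens_per_band(map_size)
    n_eeg = model.cfg.n_bands * t_band
    acc = None
    total = 0
    n_face = None
    for b in range(0, len(idx), batch_size):
        sl = idx[b:b + batch_size]
        _, records = model(Tensor(data.topo[sl]), Tensor(data.faces[sl]))
        w = records[-1].data
        if n_face is None:
            n_face = w.shape[-1] - 1 - n_eeg
        part = w[:, :, 0, :].sum(axis=(0, 1))
        acc = part if acc is None else acc + part
        total += w.shape[0] * w.shape[1]
    mean = acc / total
    masks = region_masks or default_face_region_masks(int(round(np.sqrt(n_face))))
    # reuse the aggregation path on the averaged class-token row
    rec = np.zeros((1, 1, mean.shape[0], mean.shape[0]))
    rec[0, 0, 0] = mean
    from .features import DEFAULT_BANDS
    return attribution_from_records(
        [rec], n_eeg, n_face, [b.name for b in DEFAULT_BANDS], t_band, masks)


# ----------------------------------------------------------------- experiment


METHODS = ("efem", "fefem", "mmha", "concat", "decision")


@dataclass
class ExperimentConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    model: ModelConfig = field(default_factory=scaled_config)
    train: TrainConfig = field(default_factory=TrainConfig)
    map_size: int = 64
    face_size: int = 64
    folds: tuple[int, ...] = (1,)
    k: int = 5
    methods: tuple[str, ...] = METHODS
    shuffle_labels: bool = False
    seed: int = 0


@dataclass
class ExperimentResult:
    reports: dict[str, list[EvalReport]]
    summary: pd.DataFrame
    ttests: dict[str, tuple[float, float]]
    histories: dict[str, list]


def _make_model(method: str, cfg: ModelConfig):
    if method == "efem":
        return UnimodalModel(cfg, "eeg")
    if method == "fefem":
        return UnimodalModel(cfg, "face")
    if method == "mmha":
        return FusionModel(cfg)
    if method == "concat":
        return ConcatFusionModel(cfg)
    raise ValueError(f"unknown method {method!r}")


def run_experiment(config: ExperimentConfig, data: ArrayDataset | None = None,
                   log=None) -> ExperimentResult:
    """Train and evaluate the five methods on clip-wise folds.

    ``decision`` reuses the trained unimodal models (equal-weight average of
    their posteriors), mirroring the shared-encoder comparison protocol.
    """
    if data is None:
        ds = synth_dataset(config.synth, face_size=config.face_size)
        data = build_arrays(ds, map_size=config.map_size)
    labels = data.labels
    if config.shuffle_labels:
        rng = np.random.default_rng([config.seed, 999])
        labels = labels.copy()
        rng.shuffle(labels)
        data = ArrayDataset(data.topo, data.faces, labels, data.subjects,
                            data.manifest)
    split = make_clip_folds(data.manifest, k=config.k, seed=config.seed)
    if log is not None:
        log.event("folds", checksum=_split_checksum(split), k=config.k,
                  seed=config.seed)
    reports: dict[str, list[EvalReport]] = {m: [] for m in config.methods}
    histories: dict[str, list] = {}
    for fold in config.folds:
        train_idx, val_idx = split.window_indices(data.manifest, fold)
        unimodal_probs = {}
        for method in config.methods:
            if method == "decision":
                continue
            model = _make_model(method, config.model)
            tcfg = TrainConfig(**{**vars(config.train), "seed": config.seed + fold})
            histories[f"{method}-fold{fold}"] = train_model(
                model, data, train_idx, tcfg)
            probs = predict_proba(model, data, val_idx)
            if method in ("efem", "fefem"):
                unimodal_probs[method] = probs
            reports[method].append(report_from_predictions(
                probs.argmax(1), labels[val_idx], data.subjects[val_idx]))
            if log is not None:
                log.event("evaluated", method=method, fold=fold,
                          accuracy=reports[method][-1].accuracy)
        if "decision" in config.methods:
            if not {"efem", "fefem"} <= set(unimodal_probs):
                raise ValueError("decision fusion needs both unimodal methods")
            fused = fuse_decision(unimodal_probs["efem"], unimodal_probs["fefem"])
            reports["decision"].append(report_from_predictions(
                fused.argmax(1), labels[val_idx], data.subjects[val_idx]))
            if log is not None:
                log.event("evaluated", method="decision", fold=fold,
                          accuracy=reports["decision"][-1].accuracy)
    rows = []
    for method in config.methods:
        subj_accs = _pooled_subject_accs(reports[method])
        rows.append({"method": method,
                     "accuracy_mean": float(np.mean([r.accuracy
                                                     for r in reports[method]])),
                     "accuracy_std": float(np.std(list(subj_accs.values()), ddof=0)),
                     "n_windows": int(sum(r.n for r in reports[method]))})
    summary = pd.DataFrame(rows)
    ttests = {}
    if "mmha" in config.methods:
        base = _pooled_subject_accs(reports["mmha"])
        for method in config.methods:
            if method == "mmha":
                continue
            other = _pooled_subject_accs(reports[method])
            common = sorted(set(base) & set(other))
            if len(common) >= 2:
                ttests[f"mmha_vs_{method}"] = paired_ttest(
                    [base[s] for s in common], [other[s] for s in common])
    return ExperimentResult(reports, summary, ttests, histories)


def _pooled_subject_accs(reports: list[EvalReport]) -> dict[str, float]:
    per: dict[str, list[float]] = {}
    for r in reports:
        for s, a in r.per_subject.items():
            per.setdefault(s, []).append(a)
    return {s: float(np.mean(v)) for s, v in per.items()}


def _split_checksum(split: FoldSplit) -> str:
    import hashlib
    items = sorted(split.assignments.items())
    return hashlib.sha256(str(items).encode()).hexdigest()[:16]
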
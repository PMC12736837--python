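"""Two-phase training and the evaluation protocol.

The hybrid model is trained per subject in two phases: (1) unsupervised
contrastive-divergence pretraining of the shared-weight multi-channel RBM on
the training trials, then (2) end-to-end supervised fine-tuning of the full
RBM-feature + CNN stack with Adam (default learning rate 0.001) under
cross-entropy loss, with gradients flowing through the deterministic feature
map. Ablations: ``mcrbm_only`` classifies the flattened feature map with a
plain fully connected head; ``cnn_only`` feeds the raw standardized window to
the CNN; ``fbcca`` needs no training.

Evaluation is subject-dependent. The default split is leave-one-block-out
cross-validation (each block's trials are the test fold exactly once); a
stratified holdout split is also available. Reports carry per-subject
accuracies, their unweighted mean and population variance, wall-clock
per-sample classification time, and confusion counts.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import baselines, cnn_classifier, mcrbm, nn
from .errors import ShapeError
from .signal_io import TrialSample

HYBRID = "hybrid"
MCRBM_ONLY = "mcrbm_only"
CNN_ONLY = "cnn_only"
FBCCA = "fbcca"
MODES = (HYBRID, MCRBM_ONLY, CNN_ONLY, FBCCA)

LEAVE_ONE_BLOCK_OUT = "leave_one_block_out"
STRATIFIED_HOLDOUT = "stratified_holdout"


@dataclass
class RunConfig:
    """Everything needed to train and evaluate one model variant."""

    mode: str = HYBRID
    window_len_s: float = 4.0
    split: str = LEAVE_ONE_BLOCK_OUT
    lr: float = 1e-3
    epochs: int = 60
    batch_size: int = 32
    seed: int = 0
    n_hidden: int = 256
    cd: mcrbm.CDConfig = field(default_factory=lambda: mcrbm.CDConfig(epochs=20))
    freeze_features: bool = False
    test_fraction: float = 0.2
    # stimulus plan, needed only by the FBCCA mode
    frequencies: np.ndarray | None = None
    phases: np.ndarray | None = None
    fs: float = 250.0
    fb: baselines.FBConfig = field(default_factory=baselines.FBConfig)
    n_harmonics: int = 5

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be nonnegative")
        if self.split not in (LEAVE_ONE_BLOCK_OUT, STRATIFIED_HOLDOUT):
            raise ValueError(f"unknown split {self.split!r}")


@dataclass
class EvalReport:
    """Per-subject accuracies plus summary statistics of one evaluation."""

    per_subject_accuracy: dict
    mean: float
    variance: float
    per_sample_time_s: float
    confusion: np.ndarray
    n_test: int

    @classmethod
    def from_predictions(
        cls, subjects, y_true, y_pred, n_classes: int, per_sample_time_s: float
    ) -> "EvalReport":
        subjects = np.asarray(subjects)
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        per_subject = {}
        for s in sorted(set(subjects.tolist())):
            m = subjects == s
            per_subject[s] = float(np.mean(y_true[m] == y_pred[m]))
        accs = np.array(list(per_subject.values()))
        conf = np.zeros((n_classes, n_classes), dtype=int)
        np.add.at(conf, (y_true, y_pred), 1)
        return cls(
            per_subject_accuracy=per_subject,
            mean=float(accs.mean()),
            variance=float(accs.var()),  # population variance across subjects
            per_sample_time_s=per_sample_time_s,
            confusion=conf,
            n_test=len(y_true),
        )


@dataclass
class ModelBundle:
    """A trained model variant plus everything needed to predict."""

    mode: str
    n_classes: int
    model: nn.Sequential | None = None
    bank: baselines.ReferenceBank | None = None
    fb: baselines.FBConfig | None = None
    rbm_params: mcrbm.MCRBMParams | None = None
    pretrain_history: list = field(default_factory=list)
    finetune_history: list = field(default_factory=list)

    def predict(self, signals: np.ndarray) -> np.ndarray:
        """Class predictions for a ``[n, C, T]`` stack of raw windows."""
        signals = np.asarray(signals, dtype=float)
        if signals.ndim == 2:
            signals = signals[None]
        if self.mode == FBCCA:
            return np.array(
                [baselines.fbcca_classify(s, self.bank, self.fb) for s in signals]
            )
        x = mcrbm.standardize_channels(signals)
        logits = self.model.forward(x, train=False)
        return np.argmax(logits, axis=1)


def _stack(samples: list[TrialSample]) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    x = np.stack([s.signal for s in samples])
    y = np.array([s.label for s in samples])
    blocks = np.array([s.block_id for s in samples])
    subjects = np.array([s.subject_id for s in samples])
    return x, y, blocks, subjects


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def leave_one_block_out(samples: list[TrialSample]):
    """Yield ``(train_idx, test_idx, block)`` with each block tested exactly once."""
    blocks = np.array([s.block_id for s in samples])
    uniq = np.unique(blocks)
    if len(uniq) < 2:
        raise ValueError("leave-one-block-out needs at least 2 blocks")
    for b in uniq:
        test = np.flatnonzero(blocks == b)
        train = np.flatnonzero(blocks != b)
        yield train, test, int(b)


def stratified_holdout(samples: list[TrialSample], test_fraction: float, seed: int):
    """One stratified split: ``ceil(test_fraction * n_c)`` test trials per class."""
    y = np.array([s.label for s in samples])
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        n_test = max(1, int(np.ceil(test_fraction * len(idx))))
        test_idx.extend(rng.permutation(idx)[:n_test].tolist())
    test = np.array(sorted(test_idx))
    train = np.setdiff1d(np.arange(len(samples)), test)
    return train, test


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_subject(samples: list[TrialSample], cfg: RunConfig) -> ModelBundle:
    """Train one model variant on one subject's training trials."""
    if not samples:
        raise ValueError("no training samples")
    x, y, _, _ = _stack(samples)
    n_classes = int(y.max()) + 1
    n, c, t = x.shape
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]

    if cfg.mode == FBCCA:
        if cfg.frequencies is None:
            raise ValueError("FBCCA mode requires the stimulus frequency plan")
        bank = baselines.make_reference_bank(
            cfg.frequencies, cfg.phases, cfg.fs, t, cfg.n_harmonics
        )
        return ModelBundle(FBCCA, n_classes, bank=bank, fb=cfg.fb)

    xs = mcrbm.standardize_channels(x)

    if cfg.mode == CNN_ONLY:
        cnn_cfg = cnn_classifier.CNNConfig(c, t, n_classes)
        model = cnn_classifier.build_model(cnn_cfg, seed=seeds[1])
        hist = nn.fit(model, xs, y, cfg.epochs, cfg.batch_size, cfg.lr, seed=seeds[2])
        return ModelBundle(CNN_ONLY, n_classes, model=model, finetune_history=hist)

    # phases with an RBM front end: unsupervised CD pretraining first
    cd = mcrbm.CDConfig(
        learning_rate=cfg.cd.learning_rate,
        k_steps=cfg.cd.k_steps,
        epochs=cfg.cd.epochs,
        batch_size=cfg.cd.batch_size,
        seed=seeds[0],
        init_scale=cfg.cd.init_scale,
        sample_visible=cfg.cd.sample_visible,
    )
    params, pre_hist = mcrbm.pretrain(xs, cfg.n_hidden, cd)
    feature_layer = nn.SigmoidFeature(params.W, params.b)

    cnn_cfg = cnn_classifier.CNNConfig(c, cfg.n_hidden, n_classes)
    if cfg.mode == HYBRID:
        head = cnn_classifier.build_model(cnn_cfg, seed=seeds[1])
    else:  # MCRBM_ONLY: plain fully connected head on the flattened features
        head = cnn_classifier.build_fc_head(cnn_cfg, seed=seeds[1])
    model = nn.Sequential([feature_layer] + head.layers)

    trainable = model.layers[1:] if cfg.freeze_features else None
    hist = nn.fit(
        model, xs, y, cfg.epochs, cfg.batch_size, cfg.lr, seed=seeds[2], trainable=trainable
    )
    return ModelBundle(
        cfg.mode,
        n_classes,
        model=model,
        rbm_params=params,
        pretrain_history=pre_hist,
        finetune_history=hist,
    )


def evaluate(bundle: ModelBundle, test_samples: list[TrialSample]) -> EvalReport:
    """Accuracy and timing on a held-out fold (one prediction call per sample)."""
    if not test_samples:
        raise ValueError("empty test fold")
    x, y, _, subjects = _stack(test_samples)
    t0 = time.perf_counter()
    preds = np.concatenate([bundle.predict(xi) for xi in x])
    elapsed = time.perf_counter() - t0
    return EvalReport.from_predictions(
        subjects, y, preds, bundle.n_classes, elapsed / len(test_samples)
    )


def cross_validate(samples: list[TrialSample], cfg: RunConfig) -> EvalReport:
    """Train/evaluate under the configured split and pool the predictions.

    Leave-one-block-out trains one model per fold; stratified holdout trains a
    single model. Per-subject accuracies are computed over the pooled
    held-out predictions.
    """
    x, y, _, subjects = _stack(samples)
    n_classes = int(y.max()) + 1
    all_true, all_pred, all_subj = [], [], []
    times = []
    if cfg.split == LEAVE_ONE_BLOCK_OUT:
        folds = list(leave_one_block_out(samples))
    else:
        folds = [(*stratified_holdout(samples, cfg.test_fraction, cfg.seed), -1)]
    for train_idx, test_idx, _ in folds:
        bundle = train_subject([samples[i] for i in train_idx], cfg)
        t0 = time.perf_counter()
        preds = np.concatenate([bundle.predict(xi) for xi in x[test_idx]])
        times.append((time.perf_counter() - t0) / len(test_idx))
        all_true.append(y[test_idx])
        all_pred.append(preds)
        all_subj.append(subjects[test_idx])
    return EvalReport.from_predictions(
        np.concatenate(all_subj),
        np.concatenate(all_true),
        np.concatenate(all_pred),
        n_classes,
        float(np.mean(times)),
    )


# ---------------------------------------------------------------------------
# benchmark grid
# ---------------------------------------------------------------------------

def run_benchmark(
    subject_samples: dict,
    windows_s,
    modes,
    base_cfg: RunConfig,
    fs: float,
    out_csv=None,
    out_markdown=None,
) -> pd.DataFrame:
    """Evaluate every (mode, window) cell of the comparison grid.

    ``subject_samples`` maps subject id -> callable ``window_s -> list of
    TrialSample`` (so each window length can be cut from the same recordings).
    Returns one row per (mode, window) with the across-subject mean accuracy,
    population variance, and mean per-sample time; optionally writes CSV and a
    Markdown table.
    """
    rows = []
    for mode in modes:
        for w in windows_s:
            per_subject = {}
            times = []
            for subj, make_samples in subject_samples.items():
                samples = make_samples(w)
                cfg = RunConfig(
                    mode=mode,
                    window_len_s=w,
                    split=base_cfg.split,
                    lr=base_cfg.lr,
                    epochs=base_cfg.epochs,
                    batch_size=base_cfg.batch_size,
                    seed=base_cfg.seed,
                    n_hidden=base_cfg.n_hidden,
                    cd=base_cfg.cd,
                    freeze_features=base_cfg.freeze_features,
                    test_fraction=base_cfg.test_fraction,
                    frequencies=base_cfg.frequencies,
                    phases=base_cfg.phases,
                    fs=fs,
                    fb=base_cfg.fb,
                    n_harmonics=base_cfg.n_harmonics,
                )
                rep = cross_validate(samples, cfg)
                per_subject[subj] = rep.mean
                times.append(rep.per_sample_time_s)
            accs = np.array(list(per_subject.values()))
            rows.append(
                {
                    "mode": mode,
                    "window_s": w,
                    "mean_accuracy": float(accs.mean()),
                    "variance": float(accs.var()),
                    "per_sample_time_s": float(np.mean(times)),
                    "n_subjects": len(per_subject),
                }
            )
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    if out_markdown is not None:
        with open(out_markdown, "w") as f:
            f.write(dataframe_to_markdown(df))
    return df


def dataframe_to_markdown(df: pd.DataFrame) -> str:
    """Small GitHub-table formatter (no external dependency)."""
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        cells = [
            f"{v:.4f}" if isinstance(v, float) else str(v) for v in (row[c] for c in cols)
        ]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# bundle serialization
# ---------------------------------------------------------------------------

def save_bundle(bundle: ModelBundle, path, meta: dict | None = None) -> None:
    """Persist a trained bundle as an .npz container with a JSON header."""
    arrays: dict[str, np.ndarray] = {}
    header = {"mode": bundle.mode, "n_classes": bundle.n_classes, "meta": meta or {}}
    if bundle.mode == FBCCA:
        header["n_templates"] = bundle.bank.n_classes
        header["fs"] = bundle.bank.fs
        header["n_harmonics"] = bundle.bank.n_harmonics
        header["fb"] = asdict(bundle.fb)
        for i, tpl in enumerate(bundle.bank.templates):
            arrays[f"template{i}"] = tpl
        arrays["frequencies"] = bundle.bank.frequencies
    else:
        header["layer_kinds"] = [type(l).__name__ for l in bundle.model.layers]
        header["arch"] = _describe_architecture(bundle.model)
        arrays.update(bundle.model.state_arrays())
    arrays["__header__"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def _describe_architecture(model: nn.Sequential) -> list:
    desc = []
    for layer in model.layers:
        if isinstance(layer, nn.ChannelConv):
            desc.append(["ChannelConv", layer.W.shape[1], layer.W.shape[0]])
        elif isinstance(layer, nn.TemporalConv):
            desc.append(["TemporalConv", layer.W.shape[1], layer.W.shape[0], layer.kernel])
        elif isinstance(layer, nn.BatchNorm):
            desc.append(["BatchNorm", len(layer.gamma)])
        elif isinstance(layer, nn.ELU):
            desc.append(["ELU"])
        elif isinstance(layer, nn.ReLU):
            desc.append(["ReLU"])
        elif isinstance(layer, nn.MaxPool):
            desc.append(["MaxPool", layer.size])
        elif isinstance(layer, nn.Flatten):
            desc.append(["Flatten"])
        elif isinstance(layer, nn.Linear):
            desc.append(["Linear", layer.W.shape[0], layer.W.shape[1]])
        elif isinstance(layer, nn.SigmoidFeature):
            desc.append(["SigmoidFeature", layer.W.shape[0], layer.W.shape[1]])
        else:  # pragma: no cover
            raise TypeError(f"unknown layer {type(layer).__name__}")
    return desc


def _build_from_description(desc: list) -> nn.Sequential:
    rng = np.random.default_rng(0)  # values are overwritten by the saved state
    layers: list[nn.Layer] = []
    for item in desc:
        kind = item[0]
        if kind == "ChannelConv":
            layers.append(nn.ChannelConv(item[1], item[2], rng))
        elif kind == "TemporalConv":
            layers.append(nn.TemporalConv(item[1], item[2], item[3], rng))
        elif kind == "BatchNorm":
            layers.append(nn.BatchNorm(item[1]))
        elif kind == "ELU":
            layers.append(nn.ELU())
        elif kind == "ReLU":
            layers.append(nn.ReLU())
        elif kind == "MaxPool":
            layers.append(nn.MaxPool(item[1]))
        elif kind == "Flatten":
            layers.append(nn.Flatten())
        elif kind == "Linear":
            layers.append(nn.Linear(item[1], item[2], rng))
        elif kind == "SigmoidFeature":
            layers.append(nn.SigmoidFeature(np.zeros((item[1], item[2])), np.zeros(item[2])))
        else:
            raise ValueError(f"unknown layer kind {kind!r}")
    return nn.Sequential(layers)


def load_bundle(path) -> ModelBundle:
    with np.load(path) as f:
        header = json.loads(bytes(f["__header__"]).decode())
        if header["mode"] == FBCCA:
            templates = [f[f"template{i}"] for i in range(header["n_templates"])]
            bank = baselines.ReferenceBank(
                templates, header["fs"], header["n_harmonics"], f["frequencies"]
            )
            return ModelBundle(
                FBCCA, header["n_classes"], bank=bank,
                fb=baselines.FBConfig(**{**header["fb"], "low_edges": tuple(header["fb"]["low_edges"])}),
            )
        model = _build_from_description(header["arch"])
        model.load_state_arrays({k: f[k] for k in f.files if k != "__header__"})
        return ModelBundle(header["mode"], header["n_classes"], model=model)
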
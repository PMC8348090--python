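"""The three ingestive-behavior classifiers and their training protocol.

All three consume a fixed-shape (t_fixed x 26) dB Mel-band matrix and emit
a 3-way softmax over bite / chew / chew_bite:

* ``conv1d`` — a time-distributed 1-D convolutional stack: the 26-band
  spectrum of each frame passes through shared convolution + max-pooling
  layers, frame features are pooled over time, then dense + softmax.
* ``conv2d`` — plain 2-D convolution over the whole time x Mel image with
  repeated convolution + max-pooling blocks, then flatten/dense/softmax.
* ``lstm`` — two serial units, each concatenating a time-distributed dense
  path (a skip connection over frames) with a bidirectional LSTM over the
  frame sequence; a time-distributed head is flattened into the softmax.

Training uses Adam with categorical cross-entropy, dropout 0.1 on the
dense heads, relu for convolutional/dense paths and tanh/sigmoid gating in
the recurrent units, and a fixed number of epochs with per-epoch train and
validation curves.  Given seeds, initialization, batching, and dropout are
all deterministic, so two runs produce bit-identical parameters.

Layer widths are chosen so every architecture trains in minutes on one CPU
core; they are scaled-down renditions of the published designs (printed
sizes 348,770 / 431,290 / 392,050 parameters) with the same topology.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .audio_io import BEHAVIORS
from .features import DEFAULT_T_FIXED
from .nn import Tensor

LABEL_TO_INDEX = {b: i for i, b in enumerate(BEHAVIORS)}
ARCHS = ("conv1d", "conv2d", "lstm")


@dataclass(frozen=True)
class ClassifierSpec:
    arch: str = "lstm"
    input_shape: tuple[int, int] = (DEFAULT_T_FIXED, 26)
    n_classes: int = 3
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arch not in ARCHS:
            raise ValueError(f"arch must be one of {ARCHS}, got {self.arch!r}")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.n_classes != 3:
            raise ValueError("classifiers are fixed to the 3 ingestive behaviors")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 32
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    loss: str = "categorical_cross_entropy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.loss != "categorical_cross_entropy":
            raise ValueError("only categorical cross-entropy is supported")


class BuildError(ValueError):
    """Input shape incompatible with the architecture's pooling depth."""


class Classifier:
    """An (initially untrained) network with named parameters."""

    def __init__(self, spec: ClassifierSpec):
        self.spec = spec
        self.params: dict[str, Tensor] = {}
        self.feat_mean = 0.0
        self.feat_std = 1.0
        rng = np.random.default_rng(spec.seed)
        builder = getattr(self, f"_build_{spec.arch}")
        builder(rng)

    # -- parameter helpers -------------------------------------------------
    def _add(self, name: str, rng, shape, fan_in, fan_out) -> Tensor:
        t = nn.parameter(nn.glorot_uniform(rng, shape, fan_in, fan_out))
        self.params[name] = t
        return t

    def _add_zeros(self, name: str, shape) -> Tensor:
        t = nn.parameter(np.zeros(shape, dtype=nn.DTYPE))
        self.params[name] = t
        return t

    @property
    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    # -- conv1d ------------------------------------------------------------
    def _build_conv1d(self, rng) -> None:
        t_fixed, n_mels = self.spec.input_shape
        self._add("c1_w", rng, (3, 1, 8), 3, 8 * 3)
        self._add_zeros("c1_b", (8,))
        self._add("c2_w", rng, (3, 8, 16), 24, 48)
        self._add_zeros("c2_b", (16,))
        band = ((n_mels - 2) // 2 - 2) // 2  # two conv+pool blocks
        t_pooled = t_fixed // 4
        if band < 1 or t_pooled < 1:
            raise BuildError(
                f"input shape {self.spec.input_shape} too small for the "
                "conv1d pooling depth"
            )
        self._flat = t_pooled * band * 16
        self._add("d1_w", rng, (self._flat, 64), self._flat, 64)
        self._add_zeros("d1_b", (64,))
        self._add("out_w", rng, (64, 3), 64, 3)
        self._add_zeros("out_b", (3,))

    def _forward_conv1d(self, x: np.ndarray, train: bool, rng) -> Tensor:
        bsz, t, m = x.shape
        h = nn.constant(x.reshape(bsz * t, m, 1))
        h = nn.relu(nn.conv1d(h, self.params["c1_w"], self.params["c1_b"]))
        h = nn.maxpool_axis(h, 1, 2)
        h = nn.relu(nn.conv1d(h, self.params["c2_w"], self.params["c2_b"]))
        h = nn.maxpool_axis(h, 1, 2)
        h = nn.reshape(h, (bsz, t, -1))
        h = nn.maxpool_axis(h, 1, 4)
        h = nn.reshape(h, (bsz, self._flat))
        h = nn.relu(nn.add(nn.matmul(h, self.params["d1_w"]), self.params["d1_b"]))
        h = nn.dropout(h, self.spec.dropout, rng, train)
        return nn.add(nn.matmul(h, self.params["out_w"]), self.params["out_b"])

    # -- conv2d ------------------------------------------------------------
    def _build_conv2d(self, rng) -> None:
        t_fixed, n_mels = self.spec.input_shape
        channels = [(1, 8), (8, 16), (16, 32)]
        h, w = t_fixed, n_mels
        for i, (cin, cout) in enumerate(channels, 1):
            self._add(f"c{i}_w", rng, (3, 3, cin, cout), 9 * cin, 9 * cout)
            self._add_zeros(f"c{i}_b", (cout,))
            h, w = (h - 2) // 2, (w - 2) // 2
            if h < 1 or w < 1:
                raise BuildError(
                    f"input shape {self.spec.input_shape} too small for "
                    f"{len(channels)} conv2d pooling blocks"
                )
        self._flat = h * w * 32
        self._add("d1_w", rng, (self._flat, 64), self._flat, 64)
        self._add_zeros("d1_b", (64,))
        self._add("out_w", rng, (64, 3), 64, 3)
        self._add_zeros("out_b", (3,))

    def _forward_conv2d(self, x: np.ndarray, train: bool, rng) -> Tensor:
        bsz = x.shape[0]
        h = nn.constant(x[..., None])
        for i in range(1, 4):
            h = nn.relu(nn.conv2d(h, self.params[f"c{i}_w"], self.params[f"c{i}_b"]))
            h = nn.maxpool_axis(h, 1, 2)
            h = nn.maxpool_axis(h, 2, 2)
        h = nn.reshape(h, (bsz, self._flat))
        h = nn.relu(nn.add(nn.matmul(h, self.params["d1_w"]), self.params["d1_b"]))
        h = nn.dropout(h, self.spec.dropout, rng, train)
        return nn.add(nn.matmul(h, self.params["out_w"]), self.params["out_b"])

    # -- lstm ----------------------------------------------------------------
    TD_UNITS = 32
    HIDDEN = 16
    HEAD_UNITS = 16

    def _build_lstm(self, rng) -> None:
        t_fixed, n_mels = self.spec.input_shape
        f_in = n_mels
        for u in (1, 2):
            self._add(f"u{u}_td_w", rng, (f_in, self.TD_UNITS), f_in, self.TD_UNITS)
            self._add_zeros(f"u{u}_td_b", (self.TD_UNITS,))
            for d in ("fwd", "bwd"):
                self._add(f"u{u}_{d}_wx", rng, (f_in, 4 * self.HIDDEN), f_in, self.HIDDEN)
                self._add(f"u{u}_{d}_wh", rng, (self.HIDDEN, 4 * self.HIDDEN),
                          self.HIDDEN, self.HIDDEN)
                self._add_zeros(f"u{u}_{d}_b", (4 * self.HIDDEN,))
            f_in = self.TD_UNITS + 2 * self.HIDDEN
        self._add("head_w", rng, (f_in, self.HEAD_UNITS), f_in, self.HEAD_UNITS)
        self._add_zeros("head_b", (self.HEAD_UNITS,))
        flat = t_fixed * self.HEAD_UNITS
        self._add("out_w", rng, (flat, 3), flat, 3)
        self._add_zeros("out_b", (3,))

    def _lstm_direction(self, x: Tensor, unit: int, direction: str) -> list[Tensor]:
        wx = self.params[f"u{unit}_{direction}_wx"]
        wh = self.params[f"u{unit}_{direction}_wh"]
        b = self.params[f"u{unit}_{direction}_b"]
        bsz, t, f = x.data.shape
        hid = self.HIDDEN
        h = nn.constant(np.zeros((bsz, hid), dtype=nn.DTYPE))
        c = nn.constant(np.zeros((bsz, hid), dtype=nn.DTYPE))
        order = range(t - 1, -1, -1) if direction == "bwd" else range(t)
        hs: list[Tensor | None] = [None] * t
        for step in order:
            x_t = nn.reshape(nn.slice_axis(x, 1, step, step + 1), (bsz, f))
            z = nn.add(nn.add(nn.matmul(x_t, wx), nn.matmul(h, wh)), b)
            gi = nn.sigmoid(nn.slice_axis(z, 1, 0, hid))
            gf = nn.sigmoid(nn.slice_axis(z, 1, hid, 2 * hid))
            gg = nn.tanh(nn.slice_axis(z, 1, 2 * hid, 3 * hid))
            go = nn.sigmoid(nn.slice_axis(z, 1, 3 * hid, 4 * hid))
            c = nn.add(nn.mul(gf, c), nn.mul(gi, gg))
            h = nn.mul(go, nn.tanh(c))
            hs[step] = h
        return [nn.reshape(hi, (bsz, 1, hid)) for hi in hs]  # type: ignore[arg-type]

    def _lstm_unit(self, x: Tensor, unit: int, train: bool, rng) -> Tensor:
        td = nn.relu(
            nn.add(nn.matmul(x, self.params[f"u{unit}_td_w"]),
                   self.params[f"u{unit}_td_b"])
        )
        fwd = nn.concat(self._lstm_direction(x, unit, "fwd"), axis=1)
        bwd = nn.concat(self._lstm_direction(x, unit, "bwd"), axis=1)
        out = nn.concat([td, fwd, bwd], axis=2)
        return nn.dropout(out, self.spec.dropout, rng, train)

    def _forward_lstm(self, x: np.ndarray, train: bool, rng) -> Tensor:
        bsz, t, _ = x.shape
        h: Tensor = nn.constant(x)
        h = self._lstm_unit(h, 1, train, rng)
        h = self._lstm_unit(h, 2, train, rng)
        h = nn.relu(nn.add(nn.matmul(h, self.params["head_w"]), self.params["head_b"]))
        h = nn.reshape(h, (bsz, t * self.HEAD_UNITS))
        return nn.add(nn.matmul(h, self.params["out_w"]), self.params["out_b"])

    # -- shared ------------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        if x.ndim != 3 or x.shape[1:] != tuple(self.spec.input_shape):
            raise ValueError(
                f"expected input of shape (batch, {self.spec.input_shape[0]}, "
                f"{self.spec.input_shape[1]}), got {x.shape}"
            )
        x = ((x - self.feat_mean) / self.feat_std).astype(nn.DTYPE)
        if rng is None:
            rng = np.random.default_rng(0)
        return getattr(self, f"_forward_{self.spec.arch}")(x, train, rng)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward(x, train=False).data.astype(np.float64))


def build_conv1d(spec: ClassifierSpec | None = None) -> Classifier:
    spec = spec or ClassifierSpec(arch="conv1d")
    if spec.arch != "conv1d":
        raise ValueError("spec.arch must be 'conv1d'")
    return Classifier(spec)


def build_conv2d(spec: ClassifierSpec | None = None) -> Classifier:
    spec = spec or ClassifierSpec(arch="conv2d")
    if spec.arch != "conv2d":
        raise ValueError("spec.arch must be 'conv2d'")
    return Classifier(spec)


def build_lstm(spec: ClassifierSpec | None = None) -> Classifier:
    spec = spec or ClassifierSpec(arch="lstm")
    if spec.arch != "lstm":
        raise ValueError("spec.arch must be 'lstm'")
    return Classifier(spec)


def build(spec: ClassifierSpec) -> Classifier:
    return Classifier(spec)


@dataclass
class TrainedClassifier:
    classifier: Classifier
    config: TrainConfig
    history: list[dict] = field(default_factory=list)

    @property
    def parameter_count(self) -> int:
        return self.classifier.parameter_count


def encode_labels(behaviors) -> np.ndarray:
    return np.asarray([LABEL_TO_INDEX[b] for b in behaviors], dtype=np.int64)


def decode_labels(indices: np.ndarray) -> list[str]:
    return [BEHAVIORS[i] for i in indices]


def train(
    classifier: Classifier,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    cfg: TrainConfig | None = None,
) -> TrainedClassifier:
    """Run the fixed-epoch training protocol, recording per-epoch curves.

    Features are standardized with the training set's global mean and
    standard deviation (stored on the classifier for inference).  Raises on
    an empty training set and aborts with a diagnostic on non-finite loss.
    """
    cfg = cfg or TrainConfig()
    if len(x_train) == 0:
        raise ValueError("empty training set")
    y_train = np.asarray(y_train, dtype=np.int64)
    y_val = np.asarray(y_val, dtype=np.int64)
    classifier.feat_mean = float(x_train.mean())
    classifier.feat_std = float(x_train.std()) or 1.0
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(list(classifier.params.values()), lr=cfg.learning_rate)
    history: list[dict] = []
    n = len(x_train)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            logits = classifier.forward(xb, train=True, rng=rng)
            loss = nn.softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch + 1} "
                    f"(arch={classifier.spec.arch}); aborting"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == yb).sum())
        record = {
            "epoch": epoch + 1,
            "train_loss": float(np.mean(losses)),
            "train_acc": correct / n,
        }
        if len(x_val):
            val_logits = classifier.forward(x_val, train=False)
            val_loss = nn.softmax_cross_entropy(val_logits, y_val)
            record["val_loss"] = float(val_loss.data)
            record["val_acc"] = float(
                (val_logits.data.argmax(axis=1) == y_val).mean()
            )
        history.append(record)
    return TrainedClassifier(classifier=classifier, config=cfg, history=history)


def predict(
    trained: TrainedClassifier | Classifier, x: np.ndarray, batch_size: int = 64
) -> tuple[np.ndarray, list[str]]:
    """Class probabilities and argmax behavior labels, batch order preserved."""
    clf = trained.classifier if isinstance(trained, TrainedClassifier) else trained
    if len(x) == 0:
        return np.zeros((0, 3)), []
    probs = np.concatenate(
        [clf.predict_proba(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
    )
    return probs, decode_labels(probs.argmax(axis=1))


def save(trained: TrainedClassifier, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    clf = trained.classifier
    meta = {
        "spec": asdict(clf.spec),
        "config": asdict(trained.config),
        "history": trained.history,
        "feat_mean": clf.feat_mean,
        "feat_std": clf.feat_std,
    }
    (out_dir / "model.json").write_text(json.dumps(meta, indent=2))
    np.savez(out_dir / "params.npz", **{k: v.data for k, v in clf.params.items()})


def load(out_dir: str | Path) -> TrainedClassifier:
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / "model.json").read_text())
    spec_d = meta["spec"]
    spec_d["input_shape"] = tuple(spec_d["input_shape"])
    clf = Classifier(ClassifierSpec(**spec_d))
    with np.load(out_dir / "params.npz") as arrs:
        for k in clf.params:
            clf.params[k].data = arrs[k].astype(nn.DTYPE)
    clf.feat_mean = meta["feat_mean"]
    clf.feat_std = meta["feat_std"]
    return TrainedClassifier(
        classifier=clf,
        config=TrainConfig(**meta["config"]),
        history=meta["history"],
    )
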
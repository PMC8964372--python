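"""Multimodal convolutional classifier and its hyperparameter search.

The model takes up to four inputs: two gene expression images (hierarchy-
and pathway-ordered) and two clinical scalars (age at diagnosis, ordinal
AJCC stage code).  Each enabled image feeds a convolution module of two
Conv blocks (3x3 same-padding convolution -> 2x2 max pooling -> batch
normalization), followed by a fully connected layer and dropout.  The
branch outputs and the clinical scalars are concatenated, passed through
two fully connected layers with dropout, and a final sigmoid unit scores
the probability of death within the 60-month horizon.

Thirteen hyperparameters (per-branch filter counts, dense widths, dropout
rates and the learning rate) are searched over a fixed discrete option grid
by sequential model-based (Bayesian) optimization maximizing AUC on a
single fixed train-test split, with a random-search fallback sampler.

Fixed architecture constants (kernel 3x3, pool 2x2 stride 2, ReLU, "same"
padding) are the smallest standard choices that keep a 32x32 image valid
through two pooling stages.  Training uses Adam at the searched learning
rate, binary cross-entropy, and early stopping on a held-out tenth of the
training fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

from . import nn

__all__ = [
    "HYPERPARAMETER_SPACE",
    "IMAGE_INPUTS",
    "SCALAR_INPUTS",
    "ALL_INPUTS",
    "ModelConfig",
    "TrainSettings",
    "ArchitectureDescription",
    "TrainedPredictor",
    "TrialRecord",
    "SearchResult",
    "assemble_architecture",
    "train",
    "search_hyperparameters",
]

IMAGE_INPUTS = ("image_brite", "image_pathway")
SCALAR_INPUTS = ("age", "stage")
ALL_INPUTS = IMAGE_INPUTS + SCALAR_INPUTS

#: Discrete search grid of the 13 tunable hyperparameters.
HYPERPARAMETER_SPACE: dict[str, tuple] = {
    "conv_brite_filters_1": (32, 40, 48, 56, 64),
    "conv_brite_filters_2": (80, 96, 112, 128),
    "dense_brite_units": (128, 144, 192, 256),
    "dropout_brite": (0.1, 0.2, 0.3),
    "conv_pathway_filters_1": (32, 40, 48, 56, 64),
    "conv_pathway_filters_2": (80, 96, 112, 128),
    "dense_pathway_units": (128, 144, 192, 256),
    "dropout_pathway": (0.1, 0.2, 0.3),
    "dense_1_units": (64, 128, 144, 192, 256),
    "dropout_1": (0.3, 0.4, 0.5),
    "dense_2_units": (32, 64, 128),
    "dropout_2": (0.3, 0.4, 0.5),
    "learning_rate": (0.001, 0.002, 0.003),
}


@dataclass(frozen=True)
class ModelConfig:
    """One point of the hyperparameter grid plus the enabled input subset."""

    conv_brite_filters_1: int = 32
    conv_brite_filters_2: int = 80
    dense_brite_units: int = 128
    dropout_brite: float = 0.1
    conv_pathway_filters_1: int = 32
    conv_pathway_filters_2: int = 80
    dense_pathway_units: int = 128
    dropout_pathway: float = 0.1
    dense_1_units: int = 64
    dropout_1: float = 0.3
    dense_2_units: int = 32
    dropout_2: float = 0.3
    learning_rate: float = 0.001
    enabled_inputs: tuple[str, ...] = ALL_INPUTS

    def __post_init__(self):
        for name, options in HYPERPARAMETER_SPACE.items():
            value = getattr(self, name)
            if value not in options:
                raise ValueError(f"{name}={value!r} not in option set {options}")
        enabled = tuple(self.enabled_inputs)
        if not enabled:
            raise ValueError("at least one input must be enabled")
        unknown = set(enabled) - set(ALL_INPUTS)
        if unknown:
            raise ValueError(f"unknown inputs {unknown}; valid: {ALL_INPUTS}")
        object.__setattr__(self, "enabled_inputs", enabled)

    def searched_values(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in HYPERPARAMETER_SPACE}


@dataclass
class TrainSettings:
    epochs: int = 100
    batch_size: int = 32
    early_stop_patience: int = 10
    seed: int = 0
    oversample: bool = True  # consumed by the evaluation protocol, not by train()

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.early_stop_patience) < 1:
            raise ValueError("epochs, batch_size and patience must be positive")


@dataclass
class ArchitectureDescription:
    """Deterministic layer-by-layer description of the assembled model."""

    config: ModelConfig
    image_side: int
    branches: dict[str, list[tuple]]
    scalar_inputs: tuple[str, ...]
    head: list[tuple]
    n_params: int


def _branch_spec(side: int, f1: int, f2: int, units: int, rate: float) -> list[tuple]:
    s1 = side // 2
    s2 = s1 // 2
    flat = f2 * s2 * s2
    return [
        ("conv", 1, f1),
        ("pool",),
        ("bn", f1),
        ("conv", f1, f2),
        ("pool",),
        ("bn", f2),
        ("flatten", flat),
        ("dense", flat, units),
        ("dropout", rate),
    ]


def _spec_params(spec: Sequence[tuple]) -> int:
    total = 0
    for item in spec:
        kind = item[0]
        if kind == "conv":
            _, cin, cout = item
            total += cout * cin * 9 + cout
        elif kind == "bn":
            total += 2 * item[1]
        elif kind == "dense":
            _, din, dout = item
            total += din * dout + dout
    return total


def assemble_architecture(c: ModelConfig, image_side: int) -> ArchitectureDescription:
    """Build the layer description for a config at a given image side.

    One convolution branch per enabled image input; enabled clinical scalars
    join the fused vector directly.  Requires ``image_side >= 4`` so both
    pooling stages leave a non-empty map.
    """
    enabled = c.enabled_inputs
    if not enabled:
        raise ValueError("no inputs enabled")
    branches: dict[str, list[tuple]] = {}
    if "image_brite" in enabled:
        if image_side < 4:
            raise ValueError("image_side must be >= 4 for an image branch")
        branches["image_brite"] = _branch_spec(
            image_side,
            c.conv_brite_filters_1,
            c.conv_brite_filters_2,
            c.dense_brite_units,
            c.dropout_brite,
        )
    if "image_pathway" in enabled:
        if image_side < 4:
            raise ValueError("image_side must be >= 4 for an image branch")
        branches["image_pathway"] = _branch_spec(
            image_side,
            c.conv_pathway_filters_1,
            c.conv_pathway_filters_2,
            c.dense_pathway_units,
            c.dropout_pathway,
        )
    scalar_inputs = tuple(s for s in SCALAR_INPUTS if s in enabled)
    fused = sum(spec[-2][2] for spec in branches.values()) + len(scalar_inputs)
    if fused == 0:
        raise ValueError("no inputs enabled")
    head = [
        ("dense", fused, c.dense_1_units),
        ("dropout", c.dropout_1),
        ("dense", c.dense_1_units, c.dense_2_units),
        ("dropout", c.dropout_2),
        ("dense", c.dense_2_units, 1),
        ("sigmoid",),
    ]
    n_params = sum(_spec_params(s) for s in branches.values()) + _spec_params(head)
    return ArchitectureDescription(
        config=c,
        image_side=image_side,
        branches=branches,
        scalar_inputs=scalar_inputs,
        head=head,
        n_params=n_params,
    )


def _build_layers(spec: Sequence[tuple], rng: np.random.Generator,
                  final_relu_off: bool = False) -> list[nn.Layer]:
    layers: list[nn.Layer] = []
    dense_seen = sum(1 for item in spec if item[0] == "dense")
    dense_idx = 0
    for item in spec:
        kind = item[0]
        if kind == "conv":
            layers.append(nn.Conv2D(item[1], item[2], rng))
        elif kind == "pool":
            layers.append(nn.MaxPool2())
        elif kind == "bn":
            layers.append(nn.BatchNorm(item[1]))
        elif kind == "flatten":
            layers.append(nn.Flatten())
        elif kind == "dense":
            dense_idx += 1
            relu = not (final_relu_off and dense_idx == dense_seen)
            layers.append(nn.Dense(item[1], item[2], rng, relu=relu))
        elif kind == "dropout":
            layers.append(nn.Dropout(item[1], rng))
        elif kind == "sigmoid":
            pass  # applied explicitly in the loss/prediction path
        else:
            raise ValueError(f"unknown layer kind {kind}")
    return layers


class MultimodalNet:
    """Executable network assembled from an :class:`ArchitectureDescription`."""

    def __init__(self, description: ArchitectureDescription, seed: int):
        self.description = description
        rng = np.random.default_rng(seed)
        self.branches = {
            name: nn.Sequential(_build_layers(spec, rng))
            for name, spec in description.branches.items()
        }
        self.head = nn.Sequential(_build_layers(description.head, rng,
                                                final_relu_off=True))
        self.scalar_inputs = description.scalar_inputs

    def _check_inputs(self, inputs: Mapping[str, np.ndarray]) -> int:
        sizes = set()
        side = self.description.image_side
        for name in self.branches:
            x = np.asarray(inputs[name])
            if x.ndim != 3 or x.shape[1:] != (side, side):
                raise ValueError(
                    f"{name}: expected shape (n, {side}, {side}), got {x.shape}"
                )
            sizes.add(x.shape[0])
        for name in self.scalar_inputs:
            x = np.asarray(inputs[name])
            if x.ndim != 1:
                raise ValueError(f"{name}: expected 1-D array, got shape {x.shape}")
            sizes.add(x.shape[0])
        missing = [
            k for k in (*self.branches, *self.scalar_inputs) if k not in inputs
        ]
        if missing:
            raise ValueError(f"missing inputs: {missing}")
        if len(sizes) != 1:
            raise ValueError(f"inconsistent sample counts across inputs: {sizes}")
        return sizes.pop()

    def forward(self, inputs: Mapping[str, np.ndarray], training: bool) -> np.ndarray:
        n = self._check_inputs(inputs)
        parts = []
        self._part_widths = []
        for name, branch in self.branches.items():
            x = np.asarray(inputs[name], dtype=float)[:, None, :, :]
            out = branch.forward(x, training)
            parts.append(out)
            self._part_widths.append(out.shape[1])
        for name in self.scalar_inputs:
            col = np.asarray(inputs[name], dtype=float).reshape(n, 1)
            parts.append(col)
            self._part_widths.append(1)
        fused = np.concatenate(parts, axis=1)
        logits = self.head.forward(fused, training)
        return nn.sigmoid(logits[:, 0])

    def backward(self, dlogits: np.ndarray) -> None:
        dfused = self.head.backward(dlogits.reshape(-1, 1))
        offset = 0
        for (name, branch), width in zip(
            self.branches.items(), self._part_widths[: len(self.branches)]
        ):
            branch.backward(dfused[:, offset : offset + width])
            offset += width
        # gradients w.r.t. clinical scalars are discarded (inputs, not params)

    def parameters(self):
        for branch in self.branches.values():
            yield from branch.parameters()
        yield from self.head.parameters()

    def _bn_layers(self) -> list[nn.BatchNorm]:
        seen: list[nn.BatchNorm] = []
        for layer, _ in self.parameters():
            if isinstance(layer, nn.BatchNorm) and layer not in seen:
                seen.append(layer)
        return seen

    def state(self):
        return {
            "params": [layer.params[n].copy() for layer, n in self.parameters()],
            "bn": [
                (layer.running_mean.copy(), layer.running_var.copy())
                for layer in self._bn_layers()
            ],
        }

    def load_state(self, state) -> None:
        for (layer, name), value in zip(self.parameters(), state["params"]):
            layer.params[name] = value.copy()
        for layer, (mean, var) in zip(self._bn_layers(), state["bn"]):
            layer.running_mean = mean.copy()
            layer.running_var = var.copy()


@dataclass
class TrainedPredictor:
    """Opaque trained scoring function with provenance."""

    net: MultimodalNet
    config: ModelConfig
    settings: TrainSettings
    data_fingerprint: str
    history: dict = field(default_factory=dict)

    def predict(self, inputs: Mapping[str, np.ndarray]) -> np.ndarray:
        scores = self.net.forward(inputs, training=False)
        return np.clip(scores, 1e-7, 1 - 1e-7)


def _stratified_holdout(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Indices (train, validation); empty validation if a class is too small."""
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        if len(members) < 4:
            return np.arange(len(y)), np.array([], dtype=int)
        k = max(1, int(round(fraction * len(members))))
        perm = rng.permutation(members)
        val_idx.extend(perm[:k])
        train_idx.extend(perm[k:])
    return np.array(sorted(train_idx)), np.array(sorted(val_idx))


def train(
    description: ArchitectureDescription,
    data: Mapping[str, np.ndarray],
    settings: TrainSettings | None = None,
) -> TrainedPredictor:
    """Fit the network by minimizing binary cross-entropy with Adam.

    ``data`` maps each enabled input name to its array plus ``"labels"`` to
    the binary outcome vector.  A stratified tenth of the samples is held
    out for early stopping on validation loss; the best-epoch weights are
    restored.  Fully reproducible given ``settings.seed``.
    """
    settings = settings or TrainSettings()
    y = np.asarray(data["labels"], dtype=float)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 samples per class")

    net = MultimodalNet(description, seed=settings.seed)
    input_keys = (*net.branches, *net.scalar_inputs)
    inputs = {k: np.asarray(data[k], dtype=float) for k in input_keys}
    n = net._check_inputs(inputs)  # raises on shape mismatch before training
    if n != len(y):
        raise ValueError("labels misaligned with inputs")

    rng = np.random.default_rng(settings.seed)
    train_idx, val_idx = _stratified_holdout(y.astype(int), 0.1, rng)
    tr = {k: v[train_idx] for k, v in inputs.items()}
    y_tr = y[train_idx]
    va = {k: v[val_idx] for k, v in inputs.items()}
    y_va = y[val_idx]
    use_val = len(val_idx) > 0

    lr = description.config.learning_rate
    optimizer = nn.Adam(net.parameters(), lr=lr)
    best_loss = np.inf
    best_state = net.state()
    patience_left = settings.early_stop_patience
    history = {"train_loss": [], "val_loss": []}

    n_tr = len(y_tr)
    for epoch in range(settings.epochs):
        order = rng.permutation(n_tr)
        epoch_loss = 0.0
        n_used = 0
        for start in range(0, n_tr, settings.batch_size):
            batch = order[start : start + settings.batch_size]
            if len(batch) < 2:
                continue  # batch statistics undefined for a single sample
            xb = {k: v[batch] for k, v in tr.items()}
            yb = y_tr[batch]
            probs = net.forward(xb, training=True)
            epoch_loss += nn.bce_loss(probs, yb) * len(batch)
            n_used += len(batch)
            dlogits = (probs - yb) / len(batch)
            net.backward(dlogits)
            optimizer.step()
        history["train_loss"].append(epoch_loss / max(n_used, 1))

        if use_val:
            val_probs = net.forward(va, training=False)
            val_loss = nn.bce_loss(val_probs, y_va)
        else:
            val_loss = history["train_loss"][-1]
        history["val_loss"].append(val_loss)

        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_state = net.state()
            patience_left = settings.early_stop_patience
        else:
            patience_left -= 1
            if patience_left == 0:
                break

    net.load_state(best_state)
    fingerprint = f"n={n},inputs={','.join(input_keys)}"
    return TrainedPredictor(net, description.config, settings, fingerprint, history)


# ---------------------------------------------------------------------------
# Hyperparameter search
# ---------------------------------------------------------------------------


@dataclass
class TrialRecord:
    config: ModelConfig
    score: float | None
    error: str | None = None


@dataclass
class SearchResult:
    best_config: ModelConfig
    trials: list[TrialRecord]

    @property
    def best_score(self) -> float:
        return max(t.score for t in self.trials if t.score is not None)


def _random_config(
    rng: np.random.Generator, enabled_inputs: tuple[str, ...]
) -> ModelConfig:
    kwargs = {
        name: options[rng.integers(len(options))]
        for name, options in HYPERPARAMETER_SPACE.items()
    }
    return ModelConfig(**kwargs, enabled_inputs=enabled_inputs)


def _encode(config: ModelConfig) -> np.ndarray:
    vec = []
    for name, options in HYPERPARAMETER_SPACE.items():
        idx = options.index(getattr(config, name))
        vec.append(idx / max(len(options) - 1, 1))
    return np.array(vec)


def search_hyperparameters(
    objective: Callable[[ModelConfig], float],
    n_trials: int = 100,
    seed: int = 0,
    enabled_inputs: tuple[str, ...] = ALL_INPUTS,
    sampler: str = "gp",
    n_initial: int = 10,
) -> SearchResult:
    """Maximize ``objective`` over the discrete hyperparameter grid.

    ``sampler="gp"`` runs sequential model-based optimization: after
    ``n_initial`` random trials a Gaussian-process surrogate (Matern kernel)
    proposes the next config by expected improvement over a random candidate
    pool.  ``sampler="random"`` is plain random search.  Deterministic given
    ``seed``; failing trials are recorded and skipped, and an error is
    raised only if every trial fails.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if sampler not in ("gp", "random"):
        raise ValueError("sampler must be 'gp' or 'random'")
    rng = np.random.default_rng(seed)
    trials: list[TrialRecord] = []

    def run_trial(config: ModelConfig) -> None:
        try:
            score = float(objective(config))
            trials.append(TrialRecord(config, score))
        except Exception as exc:  # noqa: BLE001 — record and continue
            trials.append(TrialRecord(config, None, error=repr(exc)))

    for _ in range(min(n_initial, n_trials)):
        run_trial(_random_config(rng, enabled_inputs))

    if sampler == "gp" and n_trials > n_initial:
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import Matern

        while len(trials) < n_trials:
            observed = [(t.config, t.score) for t in trials if t.score is not None]
            if not observed:
                run_trial(_random_config(rng, enabled_inputs))
                continue
            X = np.array([_encode(c) for c, _ in observed])
            ys = np.array([s for _, s in observed])
            gp = GaussianProcessRegressor(
                kernel=Matern(nu=2.5), alpha=1e-6, normalize_y=True
            )
            gp.fit(X, ys)
            candidates = [_random_config(rng, enabled_inputs) for _ in range(256)]
            Xc = np.array([_encode(c) for c in candidates])
            mu, sigma = gp.predict(Xc, return_std=True)
            best = ys.max()
            with np.errstate(divide="ignore", invalid="ignore"):
                imp = mu - best - 0.01
                z = np.where(sigma > 0, imp / sigma, 0.0)
                ei = np.where(
                    sigma > 0, imp * norm.cdf(z) + sigma * norm.pdf(z), 0.0
                )
            run_trial(candidates[int(np.argmax(ei))])
    else:
        while len(trials) < n_trials:
            run_trial(_random_config(rng, enabled_inputs))

    scored = [t for t in trials if t.score is not None]
    if not scored:
        raise RuntimeError(
            f"all {len(trials)} trials failed; first error: {trials[0].error}"
        )
    best = max(scored, key=lambda t: t.score)
    return SearchResult(best_config=best.config, trials=trials)
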
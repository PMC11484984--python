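"""Multi-task segmentation of coronary calcium on the segment level.

The model takes a 2.5D input stack — five consecutive slices min-max normalized
between -2000 and 1300 HU plus the binary candidate lesion mask (>= 130 HU) of
the center slice — and predicts, per pixel, (a) the segment-level calcium class
(main task) and (b) the coronary segment region (auxiliary task, supervised
only on the weakly annotated slices). The two task losses are combined with
learned homoscedastic-uncertainty weights:

    L = exp(-s_main) L_main + exp(-s_aux) L_aux + s_main + s_aux

where s are log-variance parameters. Batches are stratified over the four
(calcification x region-annotation) cells in proportions 12.5/12.5/37.5/37.5%,
and the auxiliary loss is zero on slices without region annotation, so the
auxiliary head receives no gradient from them.

The network is a compact fully-convolutional encoder-decoder (two resolution
levels, two 14-class heads) written in numpy; because segment identity in the
phantom is positional and plain convolutions are translation-equivariant, the
net internally appends normalized (z, y, x) coordinate channels to the 6-channel
input stack. A subsequent zero-CAC slice classifier, trained on the image stack
and the main head's foreground probabilities, suppresses spurious calcium on
slices it deems CAC-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import _nn
from .agatston import candidate_mask
from .phantom import CTVolume, LabelVolume, PhantomCase, weak_region_annotation
from .segments import SEGMENT_LABELS

__all__ = [
    "InputStack", "TaskLoss", "SlicePrediction", "SliceSample",
    "MultiTaskConfig", "MultiTaskModel",
    "normalize_hu", "build_input_stack", "combined_loss", "compose_batch",
    "build_slice_dataset", "zero_cac_filter",
]

NORM_LO, NORM_HI = -2000.0, 1300.0
N_CLASSES = len(SEGMENT_LABELS) + 1  # background + 13 segments
#: Stratum order: (CAC, region), (CAC, no region), (no CAC, region), (no CAC, no region)
BATCH_FRACTIONS = (0.125, 0.125, 0.375, 0.375)


def normalize_hu(voxels: np.ndarray | CTVolume) -> np.ndarray:
    """Min-max normalize HU to [0, 1], clamping to [-2000, 1300] HU."""
    v = voxels.voxels if isinstance(voxels, CTVolume) else np.asarray(voxels)
    return (np.clip(v, NORM_LO, NORM_HI) - NORM_LO) / (NORM_HI - NORM_LO)


@dataclass(frozen=True)
class InputStack:
    """2.5D network input: 5 normalized slices + candidate mask of the center."""

    channels: np.ndarray  # (6, H, W)
    center_index: int

    def __post_init__(self):
        if self.channels.shape[0] != 6:
            raise ValueError("input stack must have 6 channels")


def build_input_stack(image: CTVolume, slice_index: int) -> InputStack:
    """Build the 6-channel input stack for one slice (edge slices replicated)."""
    nz = image.shape[0]
    if not 0 <= slice_index < nz:
        raise IndexError(f"slice index {slice_index} out of range [0, {nz})")
    norm = normalize_hu(image)
    idx = np.clip(np.arange(slice_index - 2, slice_index + 3), 0, nz - 1)
    cand = candidate_mask(image)[slice_index].astype(np.float64)
    return InputStack(np.concatenate([norm[idx], cand[None]]), slice_index)


@dataclass
class TaskLoss:
    """Per-task losses and the learned log-variance weighting parameters."""

    L_main: float
    L_aux: float
    s_main: float = 0.0
    s_aux: float = 0.0


def combined_loss(t: TaskLoss) -> float:
    """Uncertainty-weighted total loss (log-variance parameterization)."""
    vals = (t.L_main, t.L_aux, t.s_main, t.s_aux)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError(f"non-finite task loss: {vals}")
    return (math.exp(-t.s_main) * t.L_main + math.exp(-t.s_aux) * t.L_aux
            + t.s_main + t.s_aux)


@dataclass
class SliceSample:
    """One training slice with targets and stratum flags."""

    channels: np.ndarray  # (6, H, W)
    z_frac: float
    main_target: np.ndarray  # (H, W) int in 0..13
    aux_target: np.ndarray  # (H, W) int in 0..13 (zeros if unannotated)
    has_cac: bool
    has_region: bool

    @property
    def stratum(self) -> int:
        return {(True, True): 0, (True, False): 1,
                (False, True): 2, (False, False): 3}[(self.has_cac, self.has_region)]


def build_slice_dataset(
    cases: list[PhantomCase],
    region_fraction: float = 0.5,
    seed: int = 0,
) -> list[SliceSample]:
    """Flatten phantom cases into per-slice training samples.

    Weak region annotation is simulated by revealing the region mask on a
    random ``region_fraction`` of slices per case; the rest are flagged
    unannotated (their auxiliary loss will be zero).
    """
    samples = []
    for i, case in enumerate(cases):
        nz = case.image.shape[0]
        weak, flags = weak_region_annotation(case.region_mask, region_fraction,
                                             seed=seed + 7919 * i)
        for z in range(nz):
            stack = build_input_stack(case.image, z)
            samples.append(SliceSample(
                channels=stack.channels,
                z_frac=z / max(nz - 1, 1),
                main_target=case.cac_mask.voxels[z].astype(np.int64),
                aux_target=weak.voxels[z].astype(np.int64),
                has_cac=bool((case.cac_mask.voxels[z] > 0).any()),
                has_region=bool(flags[z]),
            ))
    return samples


def compose_batch(
    pool: list[SliceSample],
    batch_size: int,
    rng: np.random.Generator | int = 0,
) -> list[SliceSample]:
    """Draw a stratified batch with expected proportions (.125, .125, .375, .375).

    Integer parts of ``batch_size * fraction`` are allocated deterministically;
    the fractional remainder slots are assigned by weighted sampling without
    replacement, so the expected stratum counts are exact for any batch size.
    Samples within a stratum are drawn with replacement. Strata missing from
    the pool fall back to the global pool.
    """
    if not pool:
        raise ValueError("empty sample pool")
    if batch_size <= 0:
        raise ValueError("batch size must be positive")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng

    raw = np.asarray(BATCH_FRACTIONS) * batch_size
    counts = np.floor(raw).astype(int)
    frac = raw - counts
    n_extra = int(round(frac.sum()))
    if n_extra:
        extras = rng.choice(4, size=n_extra, replace=False,
                            p=frac / frac.sum())
        for s in extras:
            counts[s] += 1

    by_stratum: dict[int, list[SliceSample]] = {s: [] for s in range(4)}
    for smp in pool:
        by_stratum[smp.stratum].append(smp)

    batch: list[SliceSample] = []
    for s in range(4):
        source = by_stratum[s] if by_stratum[s] else pool
        idx = rng.integers(0, len(source), size=counts[s])
        batch.extend(source[j] for j in idx)
    return batch


@dataclass(frozen=True)
class MultiTaskConfig:
    """Architecture and optimization settings for the toy-scale model."""

    base_channels: int = 16
    dropout: float = 0.1
    lr: float = 5e-3
    batch_size: int = 12
    epochs: int = 20
    fg_weight_main: float = 200.0  # up-weight the rare calcified pixels in the main CE
    fg_weight_aux: float = 4.0     # up-weight region pixels in the auxiliary CE
    zero_cac_threshold: float = 0.5
    use_zero_cac_filter: bool = True
    restrict_to_candidates: bool = True
    seed: int = 0


class _Net:
    """Two-level encoder-decoder with shared trunk and two 14-class heads.

    Weights and activations are float32: the model is desk-scale and memory
    bandwidth dominates the runtime. The decoder mixes the upsampled bottleneck
    with the skip connection through a 1x1 convolution; the receptive field
    comes from the three 3x3 stages.
    """

    N_COORD = 3  # normalized z, y, x appended internally
    DTYPE = np.float32

    def __init__(self, cfg: MultiTaskConfig, rng: np.random.Generator):
        b = cfg.base_channels
        self.cfg = cfg
        dt = self.DTYPE
        self.conv1 = _nn.Conv2D(6 + self.N_COORD, b, 3, rng, dt)
        self.relu1 = _nn.ReLU()
        self.conv2 = _nn.Conv2D(b, b, 3, rng, dt)
        self.relu2 = _nn.ReLU()
        self.pool = _nn.AvgPool2()
        self.conv3 = _nn.Conv2D(b, 2 * b, 3, rng, dt)  # bottleneck: Fisher block
        self.relu3 = _nn.ReLU()
        self.drop = _nn.Dropout(cfg.dropout)
        self.up = _nn.Upsample2()
        self.conv4 = _nn.Conv2D(3 * b, b, 1, rng, dt)
        self.relu4 = _nn.ReLU()
        self.head_main = _nn.Conv2D(b, N_CLASSES, 1, rng, dt)
        self.head_aux = _nn.Conv2D(b, N_CLASSES, 1, rng, dt)

    @property
    def params(self) -> list[_nn.Param]:
        layers = (self.conv1, self.conv2, self.conv3, self.conv4,
                  self.head_main, self.head_aux)
        return [p for l in layers for p in l.params]

    @property
    def aux_params(self) -> list[_nn.Param]:
        return self.head_aux.params

    @property
    def fisher_params(self) -> list[_nn.Param]:
        """Parameter block theta_k for Fisher scores: the bottleneck conv."""
        return self.conv3.params

    def _with_coords(self, x: np.ndarray, z_frac: np.ndarray) -> np.ndarray:
        n, _, h, w = x.shape
        yy = np.broadcast_to(np.linspace(0, 1, h)[None, None, :, None], (n, 1, h, w))
        xx = np.broadcast_to(np.linspace(0, 1, w)[None, None, None, :], (n, 1, h, w))
        zz = np.broadcast_to(np.asarray(z_frac)[:, None, None, None], (n, 1, h, w))
        return np.concatenate([x, zz, yy, xx], axis=1)

    def forward(self, x: np.ndarray, z_frac: np.ndarray, train: bool = False,
                dropout_rng: np.random.Generator | None = None):
        x = self._with_coords(x, z_frac).astype(self.DTYPE, copy=False)
        e1 = self.relu1.forward(self.conv1.forward(x, train), train)
        e2 = self.relu2.forward(self.conv2.forward(e1, train), train)
        h = self.pool.forward(e2, train)
        h = self.relu3.forward(self.conv3.forward(h, train), train)
        h = self.drop.forward(h, rng=dropout_rng, train=train)
        h = self.up.forward(h, train)
        d = np.concatenate([h, e2], axis=1)
        d = self.relu4.forward(self.conv4.forward(d, train), train)
        return self.head_main.forward(d, train), self.head_aux.forward(d, train)

    def backward(self, d_main: np.ndarray, d_aux: np.ndarray) -> None:
        b2 = self.cfg.base_channels * 2
        dd = self.head_main.backward(d_main) + self.head_aux.backward(d_aux)
        dd = self.conv4.backward(self.relu4.backward(dd))
        dh, de2 = dd[:, :b2], dd[:, b2:]
        dh = self.up.backward(dh)
        dh = self.drop.backward(dh)
        dh = self.conv3.backward(self.relu3.backward(dh))
        de2 = de2 + self.pool.backward(dh)
        de1 = self.conv2.backward(self.relu2.backward(de2))
        self.conv1.backward(self.relu1.backward(de1))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.value for i, p in enumerate(self.params)}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params):
            p.value[...] = state[f"p{i}"]


class _ZeroCacClassifier:
    """Logistic slice classifier on pooled stack + main-head-probability features.

    Features per slice: max and mean foreground probability over the candidate
    mask, log1p candidate-voxel count, and max normalized attenuation of the
    center slice. Trained by gradient descent; deliberately tiny, its job is to
    veto spurious calcium on slices without CAC.
    """

    N_FEAT = 4

    def __init__(self):
        self.w = np.zeros(self.N_FEAT)
        self.b = 0.0
        self._mu = np.zeros(self.N_FEAT)
        self._sd = np.ones(self.N_FEAT)

    @staticmethod
    def features(channels: np.ndarray, fg_prob: np.ndarray) -> np.ndarray:
        cand = channels[5] > 0.5
        n_cand = int(cand.sum())
        if n_cand:
            max_fg = float(fg_prob[cand].max())
            mean_fg = float(fg_prob[cand].mean())
        else:
            max_fg = mean_fg = 0.0
        return np.array([max_fg, mean_fg, np.log1p(n_cand),
                         float(channels[2].max())])

    def fit(self, X: np.ndarray, y: np.ndarray, lr: float = 0.5,
            n_iter: int = 500) -> None:
        self._mu = X.mean(axis=0)
        self._sd = np.where(X.std(axis=0) > 1e-9, X.std(axis=0), 1.0)
        Xs = (X - self._mu) / self._sd
        for _ in range(n_iter):
            p = 1.0 / (1.0 + np.exp(-(Xs @ self.w + self.b)))
            g = p - y
            self.w -= lr * (Xs.T @ g) / len(y)
            self.b -= lr * float(g.mean())

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.atleast_2d(X) - self._mu) / self._sd
        return 1.0 / (1.0 + np.exp(-(Xs @ self.w + self.b)))

    def state_dict(self) -> dict:
        return {"zc_w": self.w, "zc_b": np.array([self.b]),
                "zc_mu": self._mu, "zc_sd": self._sd}

    def load_state_dict(self, state: dict) -> None:
        self.w = np.asarray(state["zc_w"])
        self.b = float(np.asarray(state["zc_b"])[0])
        self._mu = np.asarray(state["zc_mu"])
        self._sd = np.asarray(state["zc_sd"])


@dataclass
class SlicePrediction:
    """Per-slice model output."""

    segment_probabilities: np.ndarray  # (14, H, W)
    region_probabilities: np.ndarray  # (14, H, W)
    cac_slice_probability: float


def zero_cac_filter(
    predictions: list[SlicePrediction], threshold: float
) -> tuple[list[SlicePrediction], bool]:
    """Suppress predicted calcium on slices the zero-CAC head rejects.

    Slices with ``cac_slice_probability < threshold`` have their foreground
    probability mass moved to background (the filter only removes calcium,
    never adds it). Returns the filtered predictions and whether the patient
    is declared zero-CAC (every slice empty after filtering).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    out = []
    for p in predictions:
        seg = p.segment_probabilities
        if threshold > 0.0 and p.cac_slice_probability < threshold:
            seg = seg.copy()
            seg[0] += seg[1:].sum(axis=0)
            seg[1:] = 0.0
        out.append(SlicePrediction(seg, p.region_probabilities,
                                   p.cac_slice_probability))
    # patient is zero-CAC iff no slice keeps any foreground argmax
    any_fg = any((p.segment_probabilities.argmax(axis=0) > 0).any() for p in out)
    return out, not any_fg


class MultiTaskModel:
    """Trainable multi-task segmenter with an sklearn-style fit/predict API."""

    def __init__(self, config: MultiTaskConfig | None = None):
        self.config = config or MultiTaskConfig()
        rng = np.random.default_rng(self.config.seed)
        self.net = _Net(self.config, rng)
        self.zero_cac = _ZeroCacClassifier()
        self.loss_trace: pd.DataFrame | None = None
        self.s_main = 0.0
        self.s_aux = 0.0

    # -- training ----------------------------------------------------------

    def _batch_arrays(self, batch: list[SliceSample]):
        x = np.stack([s.channels for s in batch])
        z = np.array([s.z_frac for s in batch])
        tm = np.stack([s.main_target for s in batch])
        ta = np.stack([s.aux_target for s in batch])
        annotated = np.array([s.has_region for s in batch], dtype=bool)
        return x, z, tm, ta, annotated

    def _losses_and_grads(self, x, z, tm, ta, annotated, rng):
        cfg = self.config
        n, h, w = tm.shape
        lm, la = self.net.forward(x, z, train=True, dropout_rng=rng)
        wm = 1.0 + (cfg.fg_weight_main - 1.0) * (tm > 0)
        L_main, d_main = _nn.cross_entropy_grad(lm, tm, wm)
        wa = (1.0 + (cfg.fg_weight_aux - 1.0) * (ta > 0)) \
            * annotated[:, None, None]
        L_aux, d_aux = _nn.cross_entropy_grad(la, ta, wa)
        return L_main, L_aux, d_main, d_aux

    def fit(self, samples: list[SliceSample], epochs: int | None = None,
            log_path: str | Path | None = None,
            fit_zero_cac: bool = True) -> "MultiTaskModel":
        """Train on slice samples with stratified batches; seeded and logged.

        Raises ``RuntimeError`` with a diagnostic if the loss diverges (NaN).
        """
        if not samples:
            raise ValueError("need at least one training sample")
        cfg = self.config
        epochs = cfg.epochs if epochs is None else epochs
        rng = np.random.default_rng(cfg.seed + 1)
        opt = _nn.Adam(self.net.params, lr=cfg.lr)
        steps_per_epoch = max(len(samples) // cfg.batch_size, 1)
        rows = []
        for epoch in range(epochs):
            for _ in range(steps_per_epoch):
                batch = compose_batch(samples, cfg.batch_size, rng)
                x, z, tm, ta, annotated = self._batch_arrays(batch)
                L_main, L_aux, d_main, d_aux = self._losses_and_grads(
                    x, z, tm, ta, annotated, rng)
                t = TaskLoss(L_main, L_aux, self.s_main, self.s_aux)
                total = combined_loss(t)
                if not math.isfinite(total):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch}: "
                        f"L_main={L_main}, L_aux={L_aux}")
                opt.zero_grad()
                self.net.backward(math.exp(-self.s_main) * d_main,
                                  math.exp(-self.s_aux) * d_aux)
                opt.step()
                # log-variance parameters: d total / d s = -exp(-s) L + 1
                self.s_main -= cfg.lr * (1.0 - math.exp(-self.s_main) * L_main)
                if annotated.any():
                    self.s_aux -= cfg.lr * (1.0 - math.exp(-self.s_aux) * L_aux)
                self.s_main = float(np.clip(self.s_main, -10, 10))
                self.s_aux = float(np.clip(self.s_aux, -10, 10))
                rows.append((epoch, L_main, L_aux, self.s_main, self.s_aux, total))
        self.loss_trace = pd.DataFrame(
            rows, columns=["epoch", "L_main", "L_aux", "s_main", "s_aux", "total"])
        if log_path is not None:
            self.loss_trace.to_csv(log_path, index=False)
        if fit_zero_cac:
            self._fit_zero_cac(samples)
        return self

    def _fit_zero_cac(self, samples: list[SliceSample]) -> None:
        X, y = [], []
        for s in samples:
            pred = self.predict_slice(s.channels, s.z_frac)
            fg = pred.segment_probabilities[1:].sum(axis=0)
            X.append(self.zero_cac.features(s.channels, fg))
            y.append(float(s.has_cac))
        self.zero_cac.fit(np.array(X), np.array(y))

    # -- inference ---------------------------------------------------------

    def predict_slice(self, channels: np.ndarray, z_frac: float) -> SlicePrediction:
        lm, la = self.net.forward(channels[None], np.array([z_frac]))
        seg = _nn.softmax(lm, axis=1)[0]
        reg = _nn.softmax(la, axis=1)[0]
        fg = seg[1:].sum(axis=0)
        p_cac = float(self.zero_cac.predict_proba(
            self.zero_cac.features(channels, fg))[0])
        return SlicePrediction(seg, reg, p_cac)

    def predict_volume(self, image: CTVolume) -> list[SlicePrediction]:
        nz = image.shape[0]
        preds = []
        for z in range(nz):
            stack = build_input_stack(image, z)
            preds.append(self.predict_slice(stack.channels, z / max(nz - 1, 1)))
        return preds

    def predict_segment_mask(self, image: CTVolume) -> LabelVolume:
        """Predicted segment-level calcium mask (0-13 encoding).

        Applies the zero-CAC filter (if enabled) and restricts predicted
        calcium to candidate voxels (>= 130 HU), since the Agatston convention
        only scores attenuation above threshold.
        """
        cfg = self.config
        preds = self.predict_volume(image)
        if cfg.use_zero_cac_filter:
            preds, _ = zero_cac_filter(preds, cfg.zero_cac_threshold)
        cand = candidate_mask(image)
        out = np.zeros(image.shape, dtype=np.int16)
        for z, p in enumerate(preds):
            lab = p.segment_probabilities.argmax(axis=0)
            if cfg.restrict_to_candidates:
                lab = np.where(cand[z], lab, 0)
            out[z] = lab
        return LabelVolume(out)

    def fisher_score(self, channels: np.ndarray, z_frac: float,
                     task: str) -> np.ndarray:
        """Per-sample Fisher score at the bottleneck parameter block.

        Gradient of the log-likelihood of the model's own hard predictions
        (pseudo-labels, since unlabeled slices carry no ground truth) with
        respect to the bottleneck convolution parameters, flattened.
        """
        if task not in ("main", "aux"):
            raise ValueError("task must be 'main' or 'aux'")
        lm, la = self.net.forward(channels[None], np.array([z_frac]), train=True)
        logits = lm if task == "main" else la
        pseudo = logits.argmax(axis=1)
        _, grad = _nn.cross_entropy_grad(logits, pseudo)
        for p in self.net.params:
            p.zero_grad()
        zeros = np.zeros_like(grad)
        if task == "main":
            self.net.backward(grad, zeros)
        else:
            self.net.backward(zeros, grad)
        # score of the log-likelihood = -(gradient of the cross-entropy)
        return -np.concatenate([p.grad.ravel() for p in self.net.fisher_params])

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        state = self.net.state_dict() | self.zero_cac.state_dict()
        state["s"] = np.array([self.s_main, self.s_aux])
        np.savez(path, **state,
                 config=np.array([repr(asdict(self.config))], dtype=object))

    @classmethod
    def load(cls, path: str | Path) -> "MultiTaskModel":
        with np.load(path, allow_pickle=True) as data:
            cfg = MultiTaskConfig(**eval(str(data["config"][0])))  # noqa: S307
            model = cls(cfg)
            model.net.load_state_dict(data)
            model.zero_cac.load_state_dict(data)
            model.s_main, model.s_aux = (float(v) for v in data["s"])
        return model
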
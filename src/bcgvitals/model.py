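"""CNN-LSTM estimator of heart rate and respiratory rate.

The network consumes a (timesteps=6, 1, feature_width=56, 1) grid per
analysis window: each window is split into six equal sub-segments, and
every sub-segment contributes 8 beat/spectral scalars plus a 48-bin
log-periodogram of the (optionally decomposition-denoised) waveform.
Two head variants are provided: a 222-way softmax over uniformly
binned rates (decoded to the bin centre) and a direct regression head.
One model is trained per target (HR or RR).

The LSTM cell follows the standard gated recurrence: forget, input and
output gates through the logistic function, cell candidate and cell
state through tanh, zero initial states.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = [
    "LSTMParams",
    "LSTMState",
    "lstm_cell_forward",
    "NetworkConfig",
    "Network",
    "build_network",
    "reference_shape_trace",
    "BinCodec",
    "VitalEstimate",
    "assemble_window_tensor",
    "train",
    "predict_rates",
    "predict_vitals",
    "train_test_split_indices",
    "kfold_indices",
]


# ---------------------------------------------------------------- LSTM cell

@dataclass
class LSTMParams:
    """Per-gate weight matrices (hidden x input), recurrent matrices
    (hidden x hidden) and bias vectors of one LSTM cell."""

    W_f: np.ndarray
    W_i: np.ndarray
    W_o: np.ndarray
    W_c: np.ndarray
    U_f: np.ndarray
    U_i: np.ndarray
    U_o: np.ndarray
    U_c: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray


@dataclass
class LSTMState:
    """Cell state c and hidden state h; both start at zero."""

    c: np.ndarray
    h: np.ndarray

    @classmethod
    def zeros(cls, n_units: int) -> "LSTMState":
        return cls(c=np.zeros(n_units), h=np.zeros(n_units))


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


def lstm_cell_forward(x_t: np.ndarray, state: LSTMState, params: LSTMParams
                      ) -> tuple[np.ndarray, LSTMState]:
    """One forward step of the gated LSTM cell.

    f, i, o are logistic gates of affine maps of (x_t, h_prev); the cell
    candidate uses tanh; c = f*c_prev + i*candidate (elementwise), and
    h = o*tanh(c). Raises on shape mismatch naming the offending matrix.
    """
    x_t = np.asarray(x_t, dtype=float)
    h_prev, c_prev = state.h, state.c
    hdim = h_prev.shape[0]
    for name in ("W_f", "W_i", "W_o", "W_c"):
        W = getattr(params, name)
        if W.shape != (hdim, x_t.shape[0]):
            raise ValueError(f"shape mismatch in {name}: {W.shape} vs ({hdim}, {x_t.shape[0]})")
    for name in ("U_f", "U_i", "U_o", "U_c"):
        U = getattr(params, name)
        if U.shape != (hdim, hdim):
            raise ValueError(f"shape mismatch in {name}: {U.shape} vs ({hdim}, {hdim})")
    f = _sigmoid(params.W_f @ x_t + params.U_f @ h_prev + params.b_f)
    i = _sigmoid(params.W_i @ x_t + params.U_i @ h_prev + params.b_i)
    o = _sigmoid(params.W_o @ x_t + params.U_o @ h_prev + params.b_o)
    cand = np.tanh(params.W_c @ x_t + params.U_c @ h_prev + params.b_c)
    c = f * c_prev + i * cand
    h = o * np.tanh(c)
    return h, LSTMState(c=c, h=h)


# ---------------------------------------------------------------- bin codec

class BinCodec:
    """Uniform binning of a rate range; decode returns the bin centre."""

    def __init__(self, lo: float, hi: float, n_bins: int = 222):
        if not lo < hi:
            raise ValueError("lo must be < hi")
        self.lo, self.hi, self.n_bins = float(lo), float(hi), int(n_bins)
        self.width = (self.hi - self.lo) / self.n_bins

    def encode(self, value: float) -> int:
        v = float(value)
        if v < self.lo or v > self.hi:
            warnings.warn(f"value {v} outside [{self.lo}, {self.hi}]; clamped", stacklevel=2)
            v = min(max(v, self.lo), self.hi)
        k = int((v - self.lo) / self.width)
        return min(k, self.n_bins - 1)

    def decode(self, k: int) -> float:
        return self.lo + (int(k) + 0.5) * self.width

    def encode_array(self, values) -> np.ndarray:
        return np.array([self.encode(v) for v in np.asarray(values, dtype=float)], dtype=int)


HR_CODEC = dict(lo=40.0, hi=151.0, n_bins=222)   # 0.5 bpm resolution
RR_CODEC = dict(lo=4.0, hi=59.5, n_bins=222)     # 0.25 brpm resolution


# ---------------------------------------------------------------- network

@dataclass
class NetworkConfig:
    """Architecture and training hyperparameters.

    Defaults reproduce the reference 14-layer stack (6 timesteps, 56
    features, conv 32/64, FC 512, LSTM 512/222, 222-way softmax) and the
    training protocol: Adam, batch size 1, learning rate 1e-4.
    """

    timesteps: int = 6
    feature_width: int = 56
    conv1_filters: int = 32
    conv2_filters: int = 64
    kernel: int = 3
    fc1_units: int = 512
    lstm1_units: int = 512
    lstm2_units: int = 222
    head: str = "softmax_bins"
    n_bins: int = 222
    n_outputs: int = 2
    dropout_rate: float = 0.3
    leaky_slope: float = 0.01
    lr: float = 1e-4
    batch_size: int = 1
    optimizer: str = "adam"
    epochs: int = 50
    patience: int = 10
    seed: int = 0
    enforce_reference_shapes: bool = True
    codec: dict = field(default_factory=lambda: dict(HR_CODEC))

    def __post_init__(self) -> None:
        if self.head not in ("softmax_bins", "regression"):
            raise ValueError("head must be 'softmax_bins' or 'regression'")


def reference_shape_trace() -> list[tuple[str, tuple]]:
    """The canonical layer-by-layer output-shape table of the model."""
    return [
        ("Conv1", (None, 6, 1, 56, 32)),
        ("LeakyRelu1", (None, 6, 1, 56, 32)),
        ("Maxpooling1", (None, 6, 1, 28, 32)),
        ("Dropout1", (None, 6, 1, 28, 32)),
        ("Conv2", (None, 6, 1, 28, 64)),
        ("LeakyRelu2", (None, 6, 1, 28, 64)),
        ("Maxpooling2", (None, 6, 1, 14, 64)),
        ("Dropout2", (None, 6, 1, 14, 64)),
        ("Fullyconnect1", (None, 6, 512)),
        ("LeakyRelu3", (None, 6, 512)),
        ("LSTM1", (None, 6, 512)),
        ("LSTM2", (None, 222)),
        ("Fullyconnect2", (None, 222)),
        ("Softmax", (None, 222)),
    ]


class Network:
    """Sequential CNN-LSTM with a named per-layer shape trace."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        w2, w4 = c.feature_width // 2, c.feature_width // 4
        flat = w4 * c.conv2_filters
        self.layer_names: list[str] = []
        self.layers: list[nn.Layer] = []

        def add(name, layer):
            self.layer_names.append(name)
            self.layers.append(layer)

        add("Conv1", nn.TimeDistributed(nn.Conv(1, c.conv1_filters, c.kernel, rng, "conv1")))
        add("LeakyRelu1", nn.TimeDistributed(nn.LeakyReLU(c.leaky_slope)))
        add("Maxpooling1", nn.TimeDistributed(nn.MaxPool()))
        add("Dropout1", nn.TimeDistributed(nn.Dropout(c.dropout_rate, rng)))
        add("Conv2", nn.TimeDistributed(nn.Conv(c.conv1_filters, c.conv2_filters, c.kernel, rng, "conv2")))
        add("LeakyRelu2", nn.TimeDistributed(nn.LeakyReLU(c.leaky_slope)))
        add("Maxpooling2", nn.TimeDistributed(nn.MaxPool()))
        add("Dropout2", nn.TimeDistributed(nn.Dropout(c.dropout_rate, rng)))
        add("Fullyconnect1", nn.TimeDistributed(nn.FlattenDense(flat, c.fc1_units, rng, "fc1")))
        add("LeakyRelu3", nn.LeakyReLU(c.leaky_slope))
        add("LSTM1", nn.LSTM(c.fc1_units, c.lstm1_units, rng, True, "lstm1"))
        add("LSTM2", nn.LSTM(c.lstm1_units, c.lstm2_units, rng, False, "lstm2"))
        if c.head == "softmax_bins":
            add("Fullyconnect2", nn.Dense(c.lstm2_units, c.n_bins, rng, "fc2"))
            add("Softmax", nn.Softmax())
        else:
            add("Fullyconnect2", nn.Dense(c.lstm2_units, c.n_outputs, rng, "fc2"))

        # preprocessing/decoding state set by train()
        self.x_mean = None
        self.x_std = None
        self.y_mean = 0.0
        self.y_std = 1.0
        self.codec = BinCodec(**c.codec) if c.head == "softmax_bins" else None
        self.trained = False

    # -- plumbing ---------------------------------------------------------
    def params(self) -> list[nn.Param]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def shape_trace(self, batch: int = 1) -> list[tuple[str, tuple]]:
        """Forward a dummy input and record every layer's output shape,
        with the batch axis reported as None."""
        c = self.config
        x = np.zeros((batch, c.timesteps, 1, c.feature_width, 1))
        rows = []
        for name, layer in zip(self.layer_names, self.layers):
            x = layer.forward(x, train=False)
            rows.append((name, (None,) + x.shape[1:]))
        return rows

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def _forward_to_logits(self, x: np.ndarray, train: bool) -> np.ndarray:
        body = self.layers[:-1] if self.config.head == "softmax_bins" else self.layers
        for layer in body:
            x = layer.forward(x, train)
        return x

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray, train: bool = True) -> float:
        """Mean loss on (x, y); parameter gradients are accumulated into
        the layers' ``Param.grad`` buffers. ``y`` is integer bins for the
        softmax head, standardized targets for regression."""
        logits = self._forward_to_logits(x, train)
        if self.config.head == "softmax_bins":
            loss, grad = nn.softmax_cross_entropy(logits, y)
            body = self.layers[:-1]
        else:
            loss, grad = nn.mse_loss(logits, y)
            body = self.layers
        for layer in reversed(body):
            grad = layer.backward(grad)
        return loss

    # -- inference --------------------------------------------------------
    def _scale(self, x: np.ndarray) -> np.ndarray:
        if self.x_mean is None:
            return x
        return (x - self.x_mean) / self.x_std

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Rates (bpm / brpm) for a raw (n, T, 1, W, 1) feature tensor."""
        if not self.trained:
            raise RuntimeError("model has not been trained")
        out = self.forward(self._scale(x), train=False)
        if self.config.head == "softmax_bins":
            return np.array([self.codec.decode(k) for k in out.argmax(axis=1)])
        return out[:, 0] * self.y_std + self.y_mean


def build_network(config: NetworkConfig | None = None) -> Network:
    """Construct the CNN-LSTM; with the softmax head (unless disabled)
    the layer shape trace is checked against the reference table and the
    first mismatching layer is reported."""
    config = config or NetworkConfig()
    net = Network(config)
    if config.head == "softmax_bins" and config.enforce_reference_shapes:
        ref = reference_shape_trace()
        got = net.shape_trace()
        for (rn, rs), (gn, gs) in zip(ref, got):
            if rs != gs:
                raise ValueError(f"layer {rn} produces shape {gs}, reference requires {rs}")
    return net


# ---------------------------------------------------------------- features

def _spectrum(seg: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    nfft = int(2 ** np.ceil(np.log2(max(seg.size * 4, 16))))
    s = seg - seg.mean()
    p = np.abs(np.fft.rfft(s * np.hanning(s.size), nfft)) ** 2
    return np.fft.rfftfreq(nfft, 1.0 / fs), p


def _centroid(freqs: np.ndarray, power: np.ndarray, lo: float, hi: float) -> float:
    sel = (freqs >= lo) & (freqs <= hi)
    tot = power[sel].sum()
    if tot <= 0:
        return 0.0
    return float((freqs[sel] * power[sel]).sum() / tot)


def _band_sum(freqs, power, lo, hi) -> float:
    sel = (freqs >= lo) & (freqs <= hi)
    return float(power[sel].sum())


CARDIAC_BAND = (0.7, 3.0)
RESP_BAND = (0.1, 0.5)


def assemble_window_tensor(
    samples: np.ndarray,
    fs: float,
    beat_times_s: np.ndarray,
    intervals_ms: np.ndarray,
    cardiac: np.ndarray | None = None,
    resp: np.ndarray | None = None,
    timesteps: int = 6,
    feature_width: int = 56,
) -> np.ndarray:
    """Build the (timesteps, 1, feature_width, 1) input grid for one window.

    ``samples`` is the window's waveform; ``beat_times_s`` are beat times
    relative to the window start with ``intervals_ms`` the following
    intervals. ``cardiac``/``resp`` optionally supply band-limited
    partial reconstructions (e.g. from decomposition) used in place of
    the raw waveform for the spectral features. Each timestep covers an
    equal sub-segment and carries 8 scalars plus a
    ``feature_width - 8``-bin log-periodogram.
    """
    samples = np.asarray(samples, dtype=float)
    car = samples if cardiac is None else np.asarray(cardiac, dtype=float)
    rsp = samples if resp is None else np.asarray(resp, dtype=float)
    n = samples.size
    n_bins = feature_width - 8
    seg_len = n // timesteps
    wf, wp = _spectrum(rsp, fs)
    resp_centroid_window = _centroid(wf, wp, *RESP_BAND)
    grid = np.zeros((timesteps, feature_width))
    for k in range(timesteps):
        lo_i, hi_i = k * seg_len, (k + 1) * seg_len if k < timesteps - 1 else n
        seg = samples[lo_i:hi_i]
        t_lo, t_hi = lo_i / fs, hi_i / fs
        sel = (beat_times_s >= t_lo) & (beat_times_s < t_hi)
        iv = intervals_ms[sel] if sel.sum() >= 2 else intervals_ms
        if iv.size >= 2:
            mean_rr = iv.mean()
            sdnn = iv.std()
            rmssd = np.sqrt(np.mean(np.diff(iv) ** 2)) if iv.size >= 2 else 0.0
            hr = 60000.0 / mean_rr
        else:
            mean_rr = sdnn = rmssd = hr = 0.0
        cf, cp = _spectrum(car[lo_i:hi_i], fs)
        rf, rp = _spectrum(rsp[lo_i:hi_i], fs)
        scalars = [
            mean_rr,
            sdnn,
            rmssd,
            hr,
            float(np.sqrt(np.mean(seg**2))),
            _centroid(cf, cp, *CARDIAC_BAND),
            resp_centroid_window,
            _centroid(rf, rp, *RESP_BAND),
        ]
        mix = samples if cardiac is None else car + rsp
        mf, mp = _spectrum(mix[lo_i:hi_i], fs)
        edges = np.linspace(0.05, 3.05, n_bins + 1)
        bins = [np.log10(_band_sum(mf, mp, edges[j], edges[j + 1]) + 1e-12) for j in range(n_bins)]
        grid[k] = np.concatenate([scalars, bins])
    return grid[:, None, :, None]


# ---------------------------------------------------------------- training

def train_test_split_indices(n: int, test_fraction: float = 0.2, seed: int = 0
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Shuffled 80/20 (by default) train/test index split."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = max(int(round(n * test_fraction)), 1)
    return np.sort(order[n_test:]), np.sort(order[:n_test])


def kfold_indices(n: int, k: int = 10, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """k-fold partition: every sample appears exactly once as validation."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    out = []
    for i in range(k):
        val = np.sort(folds[i])
        tr = np.sort(np.concatenate([folds[j] for j in range(k) if j != i]))
        out.append((tr, val))
    return out


def train(
    model: Network,
    X: np.ndarray,
    y: np.ndarray,
    config: NetworkConfig | None = None,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> tuple[Network, dict]:
    """Fit the network with Adam at batch size ``config.batch_size``.

    Features are standardized (statistics stored on the model); targets
    are bin-encoded for the softmax head and z-scored for regression.
    Returns the model and a history dict with per-epoch training (and,
    when a validation set is given, validation) loss; training stops
    early after ``patience`` epochs without validation improvement.
    """
    config = config or model.config
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty training set")

    model.x_mean = X.mean(axis=0, keepdims=True)
    model.x_std = X.std(axis=0, keepdims=True)
    model.x_std[model.x_std == 0] = 1.0
    Xs = model._scale(X)
    if config.head == "softmax_bins":
        yt = model.codec.encode_array(y)
    else:
        model.y_mean = float(y.mean())
        model.y_std = float(y.std()) or 1.0
        yt = ((y - model.y_mean) / model.y_std)[:, None]
        if config.n_outputs > 1:
            yt = np.repeat(yt, config.n_outputs, axis=1)

    have_val = X_val is not None and y_val is not None
    if have_val:
        Xv = model._scale(np.asarray(X_val, dtype=float))
        if config.head == "softmax_bins":
            yv = model.codec.encode_array(y_val)
        else:
            yv = ((np.asarray(y_val, dtype=float) - model.y_mean) / model.y_std)[:, None]
            if config.n_outputs > 1:
                yv = np.repeat(yv, config.n_outputs, axis=1)

    opt = nn.Adam(model.params(), lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    stale = 0
    for _epoch in range(config.epochs):
        order = rng.permutation(X.shape[0])
        losses = []
        for start in range(0, order.size, config.batch_size):
            idx = order[start : start + config.batch_size]
            opt.zero_grad()
            losses.append(model.loss_and_grads(Xs[idx], yt[idx], train=True))
            opt.step()
        history["train_loss"].append(float(np.mean(losses)))
        if have_val:
            model.trained = True
            logits = model._forward_to_logits(Xv, train=False)
            if config.head == "softmax_bins":
                vloss, _ = nn.softmax_cross_entropy(logits, yv)
            else:
                vloss, _ = nn.mse_loss(logits, yv)
            history["val_loss"].append(vloss)
            if vloss < best_val - 1e-6:
                best_val, stale = vloss, 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
    model.trained = True
    return model, history


@dataclass
class VitalEstimate:
    """Per-window heart-rate and respiratory-rate estimate, optionally
    paired with ground truth for scoring."""

    hr_bpm: float
    rr_brpm: float
    window_id: int = 0
    truth_hr_bpm: float | None = None
    truth_rr_brpm: float | None = None


def predict_rates(model: Network, windows: np.ndarray) -> np.ndarray:
    """Per-window rate predictions from one trained single-target model."""
    return model.predict(np.asarray(windows, dtype=float))


def predict_vitals(
    hr_model: Network,
    rr_model: Network,
    windows: np.ndarray,
    truth_hr=None,
    truth_rr=None,
) -> list[VitalEstimate]:
    """Pair HR and RR model predictions into VitalEstimate records."""
    hr = predict_rates(hr_model, windows)
    rr = predict_rates(rr_model, windows)
    out = []
    for i in range(hr.size):
        out.append(
            VitalEstimate(
                hr_bpm=float(hr[i]),
                rr_brpm=float(rr[i]),
                window_id=i,
                truth_hr_bpm=None if truth_hr is None else float(truth_hr[i]),
                truth_rr_brpm=None if truth_rr is None else float(truth_rr[i]),
            )
        )
    return out
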
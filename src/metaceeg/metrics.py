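"""Quantitative metrics (Mode Score, sliced Wasserstein distance,
classification metrics) and qualitative diagnostics (Welch PSD, polynomial
ERP trend) for generated-vs-real epoch sets.

Mode Score needs a frozen probabilistic classifier; a compact 1-D
convolutional network trained on real epochs only (`train_eval_classifier`)
fills that role, and its provenance (data hash + seed) is recorded so MS
values are only compared within one classifier.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .containers import EpochedEEG

__all__ = ["EvalClassifier", "MetricReport", "ClassifMetrics",
           "train_eval_classifier", "mode_score", "sliced_wasserstein",
           "welch_psd", "erp_trend", "classification_metrics",
           "metrics_from_confusion", "pairwise_auc"]


# ---------------------------------------------------------------------------
# evaluation classifier
# ---------------------------------------------------------------------------

class _ConvNet(nn.Module):
    """Tiny conv classifier: conv-pool x2 -> dense softmax logits."""

    def __init__(self, n_channels: int, n_samples: int, n_classes: int,
                 rng: np.random.Generator, width: int = 8, kernel: int = 7):
        super().__init__()
        self.c1 = nn.Conv1d(n_channels, width, kernel, rng)
        self.c2 = nn.Conv1d(width, width, kernel, rng)
        self.fc = nn.Dense(width * (n_samples // 16), n_classes, rng)
        self._mods = [self.c1, self.c2, self.fc]
        self.n_classes = n_classes

    def refresh(self):
        for m in self._mods:
            m.refresh()

    def parameters(self):
        out = {}
        for i, m in enumerate(self._mods):
            for k, v in m.parameters().items():
                out[f"m{i}.{k}"] = v
        return out

    def param_tensors(self):
        out = []
        for m in self._mods:
            out.extend(m.param_tensors())
        return out

    def state_dict(self):
        return {k: v.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state):
        for i, m in enumerate(self._mods):
            for k in m.parameters():
                m._params[k] = np.array(state[f"m{i}.{k}"])

    def logits(self, x: Tensor) -> Tensor:
        pool4 = nn.AvgPool1d(4)
        h = pool4(ad.leaky_relu(self.c1(x)))
        h = pool4(ad.leaky_relu(self.c2(h)))
        return self.fc(ad.reshape(h, (x.shape[0], -1)))

    forward = logits


def _softmax_np(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class EvalClassifier:
    """Frozen p(y|x) predictor plus training provenance."""

    net: _ConvNet
    classes: np.ndarray
    data_hash: str
    seed: int

    def predict_proba(self, epochs: EpochedEEG | np.ndarray) -> np.ndarray:
        x = epochs.data if isinstance(epochs, EpochedEEG) else np.asarray(epochs)
        self.net.refresh()
        probs = []
        for i in range(0, x.shape[0], 256):
            logits = self.net.logits(Tensor(x[i:i + 256].astype(float))).data
            probs.append(_softmax_np(logits))
        return np.concatenate(probs, axis=0)


def train_eval_classifier(real_epochs: EpochedEEG, seed: int = 0,
                          n_steps: int = 300, batch_size: int = 64,
                          lr: float = 3e-3) -> EvalClassifier:
    """Fit the compact conv classifier on real epochs; frozen thereafter."""
    classes = np.unique(real_epochs.labels)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to train the classifier")
    class_idx = np.searchsorted(classes, real_epochs.labels)

    rng = np.random.default_rng(seed)
    net = _ConvNet(real_epochs.n_channels, real_epochs.n_samples,
                   classes.size, rng)
    opt = nn.Adam(net, lr=lr, betas=(0.9, 0.999))
    x = real_epochs.data.astype(np.float64)
    n = x.shape[0]
    for _ in range(n_steps):
        idx = rng.integers(0, n, size=batch_size)
        net.refresh()
        logits = net.logits(Tensor(x[idx]))
        # cross entropy via log-softmax with a detached max shift
        shift = Tensor(logits.data.max(axis=1, keepdims=True))
        ls = logits - shift - ad.log(ad.tsum(ad.exp(logits - shift),
                                             axis=1, keepdims=True))
        onehot = np.zeros((batch_size, classes.size))
        onehot[np.arange(batch_size), class_idx[idx]] = 1.0
        loss = -(Tensor(onehot) * ls).sum() * (1.0 / batch_size)
        opt.step(nn.grads_by_name(net, loss))

    h = hashlib.sha1(np.ascontiguousarray(real_epochs.data).tobytes())
    return EvalClassifier(net=net, classes=classes,
                          data_hash=h.hexdigest()[:12], seed=seed)


# ---------------------------------------------------------------------------
# mode score and sliced Wasserstein
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    MS: float
    SWD: float
    n_projections: int
    seed: int
    classifier_hash: str = ""


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1.0)
    q = np.clip(q, 1e-12, 1.0)
    return float(np.sum(p * np.log(p / q)))


def mode_score(clf: EvalClassifier, real: EpochedEEG,
               fake: EpochedEEG) -> float:
    """exp( E_fake KL(p(y|x) || p*) - KL(pbar || p*) ).

    p* is the label marginal of the real set and pbar the mean predicted
    distribution over the fake set.  1 for an uninformative classifier;
    up to C for one-hot predictions with matched uniform marginals.
    """
    if real.n_epochs == 0 or fake.n_epochs == 0:
        raise ValueError("empty epoch set")
    p_star = np.bincount(np.searchsorted(clf.classes, real.labels),
                         minlength=clf.classes.size).astype(float)
    p_star /= p_star.sum()
    probs = clf.predict_proba(fake)
    term1 = float(np.mean([_kl(p, p_star) for p in probs]))
    p_bar = probs.mean(axis=0)
    return float(np.exp(term1 - _kl(p_bar, p_star)))


def sliced_wasserstein(real: EpochedEEG | np.ndarray,
                       fake: EpochedEEG | np.ndarray,
                       n_proj: int = 128, seed: int = 0) -> float:
    """Mean 1-D W1 distance over random unit projections of flattened epochs.

    The larger set is subsampled (seeded) to equalize sample counts; for 1-D
    data each projection reduces to the exact sorted-sample W1 distance.
    """
    a = real.data if isinstance(real, EpochedEEG) else np.asarray(real, float)
    b = fake.data if isinstance(fake, EpochedEEG) else np.asarray(fake, float)
    a = a.reshape(a.shape[0], -1)
    b = b.reshape(b.shape[0], -1)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("empty epoch set")
    rng = np.random.default_rng(seed)
    m = min(a.shape[0], b.shape[0])
    if a.shape[0] > m:
        a = a[rng.choice(a.shape[0], size=m, replace=False)]
    if b.shape[0] > m:
        b = b[rng.choice(b.shape[0], size=m, replace=False)]
    dirs = rng.standard_normal((a.shape[1], n_proj))
    dirs /= np.linalg.norm(dirs, axis=0, keepdims=True)
    pa = np.sort(a @ dirs, axis=0)
    pb = np.sort(b @ dirs, axis=0)
    return float(np.mean(np.abs(pa - pb)))


# ---------------------------------------------------------------------------
# qualitative diagnostics
# ---------------------------------------------------------------------------

def welch_psd(epochs: EpochedEEG, band: tuple[float, float] = (0.01, 40.0),
              window_s: float = 1.0, overlap: float = 0.5):
    """Welch PSD per channel, averaged over epochs, truncated to `band`.

    1-s Hann windows with 50% overlap by default.  Returns (freqs, psd)
    with psd shaped [n_channels, n_freqs].
    """
    from scipy import signal
    nperseg = int(round(window_s * epochs.fs))
    if epochs.n_samples < nperseg:
        raise ValueError("epoch shorter than one Welch window")
    freqs, psd = signal.welch(epochs.data, fs=epochs.fs, nperseg=nperseg,
                              noverlap=int(nperseg * overlap), axis=-1)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    return freqs[keep], psd.mean(axis=0)[:, keep]


def erp_trend(waveform: np.ndarray, order: int = 15) -> np.ndarray:
    """Least-squares polynomial trend on a [-1, 1]-scaled abscissa.

    A 15th-order trend line highlights the P300 deflection in averaged
    epochs without tracking residual noise.
    """
    waveform = np.asarray(waveform, dtype=float)
    n = waveform.shape[-1]
    if n <= order:
        raise ValueError("waveform must be longer than the polynomial order")
    xs = np.linspace(-1.0, 1.0, n)
    def fit1(y):
        series = np.polynomial.Polynomial.fit(xs, y, deg=order, domain=[-1, 1])
        return series(xs)
    if waveform.ndim == 1:
        return fit1(waveform)
    return np.apply_along_axis(fit1, -1, waveform)


# ---------------------------------------------------------------------------
# classification metrics
# ---------------------------------------------------------------------------

@dataclass
class ClassifMetrics:
    Acc: float
    Pre: float
    Rec: float
    F1: float
    AUC: float
    extras: dict = field(default_factory=dict)


def pairwise_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the positive-negative pairwise statistic, ties counting 0.5."""
    y_true = np.asarray(y_true).astype(bool)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y_true]
    neg = scores[~y_true]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC undefined: need both classes present")
    diff = pos[:, None] - neg[None, :]
    wins = (diff > 0).sum() + 0.5 * (diff == 0).sum()
    return float(wins / (pos.size * neg.size))


def metrics_from_confusion(tp: int, fp: int, tn: int, fn: int) -> dict:
    """Acc/Pre/Rec/F1 straight from confusion counts."""
    acc = (tp + tn) / (tp + fp + tn + fn)
    pre = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * tp / (2 * tp + fn + fp) if 2 * tp + fn + fp else 0.0
    return {"Acc": acc, "Pre": pre, "Rec": rec, "F1": f1}


def classification_metrics(y_true: np.ndarray, scores: np.ndarray,
                           positive_class=1) -> ClassifMetrics:
    """Confusion-count metrics plus pairwise AUC.

    Binary: `scores` is 1-D (probability/score of the positive class),
    predictions threshold at 0.5.  Multiclass: `scores` is [n, C]
    (argmax predictions); Pre/Rec/F1/AUC are macro one-vs-rest averages.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if np.unique(y_true).size < 2:
        raise ValueError("AUC undefined for single-class y_true")

    if scores.ndim == 1:
        pos = y_true == positive_class
        pred = scores >= 0.5
        tp = int(np.sum(pred & pos))
        fp = int(np.sum(pred & ~pos))
        tn = int(np.sum(~pred & ~pos))
        fn = int(np.sum(~pred & pos))
        base = metrics_from_confusion(tp, fp, tn, fn)
        auc = pairwise_auc(pos, scores)
        return ClassifMetrics(**base, AUC=auc,
                              extras={"TP": tp, "FP": fp, "TN": tn, "FN": fn})

    classes = np.unique(y_true)
    pred = classes[np.argmax(scores, axis=1)] if scores.shape[1] == classes.size \
        else np.argmax(scores, axis=1)
    acc = float(np.mean(pred == y_true))
    pres, recs, f1s, aucs = [], [], [], []
    for ci, c in enumerate(classes):
        pos = y_true == c
        ppred = pred == c
        tp = int(np.sum(ppred & pos))
        fp = int(np.sum(ppred & ~pos))
        fn = int(np.sum(~ppred & pos))
        m = metrics_from_confusion(tp, fp, int(np.sum(~ppred & ~pos)), fn)
        pres.append(m["Pre"]); recs.append(m["Rec"]); f1s.append(m["F1"])
        aucs.append(pairwise_auc(pos, scores[:, ci]))
    return ClassifMetrics(Acc=acc, Pre=float(np.mean(pres)),
                          Rec=float(np.mean(recs)), F1=float(np.mean(f1s)),
                          AUC=float(np.mean(aucs)))
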
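"""Metacognitive regulation losses for EEG generators.

Three generator-side regularizers:

* **TR (time domain)** — three-point curvature of each trace, squashed to
  (0, 1), compared between real and generated batches by binary cross
  entropy.  Curvature acts as a local-waveform monitor.
* **FR (frequency domain)** — DFT amplitude spectrum of each trace,
  normalized to sum 1, with the generated spectrum scored by BCE against
  the batch-average real spectrum.  A global spectral monitor.
* **SR (latent space)** — the ratio of output dissimilarity to latent
  dissimilarity, ``(1 - cos(g1, g2)) / (1 - cos(z1, z2))``; pushing this
  ratio up counteracts mode collapse.

They combine with the adversarial loss as

    L_G_final = L_G + lam * L_SR + (1 - lam) * (0.5 * L_FR + 0.5 * L_TR)

with a single trade-off weight ``lam`` in (0, 1).

Raw curvature is unbounded and a raw amplitude spectrum is not a
probability, so BCE is undefined on them.  This module maps curvature
through k/(1+k) and normalizes spectra to sum 1, then clips both to
[1e-7, 1 - 1e-7] before the cross entropy; this monotone mapping is the
package's own choice and is documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS_CLIP = 1e-7
EPS_RATIO = 1e-8
SR_MODES = ("reciprocal", "negative", "literal")

__all__ = ["RegularizerWeights", "LossBreakdown", "three_point_curvature",
           "squash_curvature", "tr_loss", "amplitude_spectrum", "fr_loss",
           "sr_ratio", "sr_loss", "combined_generator_loss",
           "EPS_CLIP", "EPS_RATIO", "SR_MODES"]


@dataclass(frozen=True)
class RegularizerWeights:
    """Trade-off weight and which regularizers are active.

    ``lam`` weights diversity (SR) against similarity (FR+TR); the
    recommended value is 0.6.  ``sr_mode`` picks the optimization direction
    of the latent term: "reciprocal" (default, mode-seeking: minimize
    1/ratio), "negative" (minimize -ratio), or "literal" (minimize +ratio).
    """

    lam: float = 0.6
    sr_mode: str = "reciprocal"
    use_tr: bool = True
    use_fr: bool = True
    use_sr: bool = True

    def __post_init__(self):
        if not (0.0 < self.lam < 1.0):
            raise ValueError("lam must lie strictly inside (0, 1)")
        if self.sr_mode not in SR_MODES:
            raise ValueError(f"sr_mode must be one of {SR_MODES}")


@dataclass(frozen=True)
class LossBreakdown:
    L_G: float
    L_TR: float
    L_FR: float
    L_SR: float
    L_G_final: float


# ---------------------------------------------------------------------------
# time domain
# ---------------------------------------------------------------------------

def three_point_curvature(trace: np.ndarray, dx: float = 1.0) -> np.ndarray:
    """Curvature at each interior sample from a parametric quadratic fit.

    A quadratic (x(t), y(t)) with t in {-1, 0, 1} is fitted through each
    triple of consecutive samples; with a uniform abscissa of spacing
    ``dx`` the x-coefficients are a2 = dx, a3 = 0 and the y-coefficients
    are b2 = (y3 - y1)/2, b3 = (y3 - 2 y2 + y1)/2, giving

        k = |2 (a3 b2 - a2 b3)| / (a2^2 + b2^2)^(3/2)
          = 2 dx |b3| / (dx^2 + b2^2)^(3/2).

    Returns nonnegative curvature along the last axis (length n - 2).
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.shape[-1] < 3:
        raise ValueError("need at least 3 samples")
    y1 = trace[..., :-2]
    y2 = trace[..., 1:-1]
    y3 = trace[..., 2:]
    b2 = 0.5 * (y3 - y1)
    b3 = 0.5 * (y3 - 2.0 * y2 + y1)
    return 2.0 * dx * np.abs(b3) / (dx * dx + b2 * b2) ** 1.5


def squash_curvature(k: np.ndarray) -> np.ndarray:
    """Map nonnegative curvature into (0, 1) via k/(1+k), clipped."""
    k = np.asarray(k, dtype=np.float64)
    if np.any(k < 0):
        raise ValueError("curvature must be nonnegative")
    return np.clip(k / (1.0 + k), EPS_CLIP, 1.0 - EPS_CLIP)


def _bce(target: np.ndarray, pred: np.ndarray) -> float:
    return float(-np.mean(target * np.log(pred)
                          + (1.0 - target) * np.log(1.0 - pred)))


def tr_loss(real_batch: np.ndarray, fake_batch: np.ndarray) -> float:
    """BCE between squashed curvatures of real and generated batches.

    Batches are [n_epochs, n_channels, n_samples] (or any shape whose last
    axis is time); the mean runs over epochs, channels, and interior
    samples.
    """
    real_batch = np.asarray(real_batch)
    fake_batch = np.asarray(fake_batch)
    if real_batch.shape != fake_batch.shape:
        raise ValueError("real and fake batches must share a shape")
    k_real = squash_curvature(three_point_curvature(real_batch))
    k_fake = squash_curvature(three_point_curvature(fake_batch))
    return _bce(k_real, k_fake)


# ---------------------------------------------------------------------------
# frequency domain
# ---------------------------------------------------------------------------

def amplitude_spectrum(trace: np.ndarray, normalize: bool = False) -> np.ndarray:
    """|DFT| over the last axis; all N bins, k = 0..N-1.

    With ``normalize`` the spectrum is divided by its sum so bins form a
    distribution over frequencies.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.shape[-1] < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(trace)):
        raise ValueError("input must be finite")
    amp = np.abs(np.fft.fft(trace, axis=-1))
    if normalize:
        total = amp.sum(axis=-1, keepdims=True)
        total = np.where(total == 0, 1.0, total)
        amp = amp / total
    return amp


def fr_loss(real_batch: np.ndarray, fake_batch: np.ndarray) -> float:
    """BCE of generated normalized spectra against the batch-mean real one.

    The real target is the mean over the real batch of per-trace normalized
    spectra (per channel and bin); both sides are clipped to (0, 1).
    """
    real_batch = np.asarray(real_batch)
    fake_batch = np.asarray(fake_batch)
    if real_batch.shape != fake_batch.shape:
        raise ValueError("real and fake batches must share a shape")
    f_real = amplitude_spectrum(real_batch, normalize=True).mean(axis=0)
    f_fake = amplitude_spectrum(fake_batch, normalize=True)
    f_real = np.clip(f_real, EPS_CLIP, 1.0 - EPS_CLIP)
    f_fake = np.clip(f_fake, EPS_CLIP, 1.0 - EPS_CLIP)
    return _bce(np.broadcast_to(f_real, f_fake.shape), f_fake)


# ---------------------------------------------------------------------------
# latent space
# ---------------------------------------------------------------------------

def _cos(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero vector in cosine similarity")
    return float(a @ b / (na * nb))


def sr_ratio(z1: np.ndarray, z2: np.ndarray,
             g1: np.ndarray, g2: np.ndarray) -> float:
    """Output-to-latent dissimilarity ratio (1 - cos(g)) / (1 - cos(z)).

    With unit-normalized vectors this equals
    ||g1h - g2h||^2 / ||z1h - z2h||^2.  Raises on a degenerate latent pair
    (z1 ~ z2 after normalization); the caller should resample.
    """
    z1, z2 = np.ravel(z1).astype(float), np.ravel(z2).astype(float)
    g1, g2 = np.ravel(g1).astype(float), np.ravel(g2).astype(float)
    denom = 1.0 - _cos(z1, z2)
    if denom < 1e-12:
        raise ValueError("degenerate latent pair: z1 == z2 after normalization")
    num = 1.0 - _cos(g1, g2)
    return num / denom


def sr_loss(ratios, mode: str = "reciprocal") -> float:
    """Aggregate latent-diversity ratios into a minimizable scalar.

    reciprocal: mean 1/(ratio + eps)  (default; minimizing raises the ratio)
    negative:   -mean(ratio)
    literal:    +mean(ratio)
    """
    ratios = np.atleast_1d(np.asarray(ratios, dtype=np.float64))
    if ratios.size == 0:
        raise ValueError("need at least one ratio")
    if mode == "reciprocal":
        return float(np.mean(1.0 / (ratios + EPS_RATIO)))
    if mode == "negative":
        return float(-np.mean(ratios))
    if mode == "literal":
        return float(np.mean(ratios))
    raise ValueError(f"unknown sr mode {mode!r}")


def combined_generator_loss(L_G: float, L_TR: float, L_FR: float, L_SR: float,
                            weights: RegularizerWeights) -> LossBreakdown:
    """L_G + lam * L_SR + (1 - lam) * (0.5 * L_FR + 0.5 * L_TR)."""
    for name, v in (("L_G", L_G), ("L_TR", L_TR), ("L_FR", L_FR), ("L_SR", L_SR)):
        if not np.isfinite(v):
            raise ValueError(f"{name} is not finite")
    lam = weights.lam
    total = L_G + lam * L_SR + (1.0 - lam) * (0.5 * L_FR + 0.5 * L_TR)
    return LossBreakdown(L_G=float(L_G), L_TR=float(L_TR), L_FR=float(L_FR),
                         L_SR=float(L_SR), L_G_final=float(total))
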
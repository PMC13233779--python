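"""Reduced-scale adversarial trainers (WGAN-GP, conditional WGAN-GP, and a
1-D-convolutional WaveGAN-style pair) with the metacognitive regularizers
wired into the generator objective, plus the executable latent-space
gradient-bound check.

Architectures are deliberately desk-scale: an MLP generator/critic pair for
`wgan_gp`/`cwgan_gp`, and for `wavegan_lite` a generator built from
nearest-neighbour upsampling + stride-1 convolutions with an average-pooling
convolutional critic.  Upsample+conv replaces transposed convolution (same
expressive role, no checkerboard artifacts) and keeps every op in a family
whose derivatives the autodiff engine can differentiate again, which the
gradient penalty requires.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .containers import EpochedEEG
from .mrm import EPS_CLIP, EPS_RATIO, LossBreakdown, RegularizerWeights

__all__ = ["NetConfig", "TrainSchedule", "TrainState", "BoundReport",
           "TrainingDiverged", "build_generator", "build_critic",
           "gradient_penalty", "train", "resume", "sample", "sr_bound_check"]

VARIANTS = ("wgan_gp", "cwgan_gp", "wavegan_lite")


@dataclass(frozen=True)
class NetConfig:
    latent_dim: int = 16
    n_channels: int = 1
    n_samples: int = 256
    widths: tuple[int, ...] = (64, 64)   # MLP hidden widths
    conv_channels: int = 8               # wavegan_lite channel width
    kernel: int = 9
    conditional: bool = False
    n_classes: int = 2
    label_embed: int = 4


@dataclass(frozen=True)
class TrainSchedule:
    n_steps: int = 200          # generator steps
    batch_size: int = 32
    n_critic: int = 5
    lr: float = 1e-4
    betas: tuple[float, float] = (0.5, 0.9)
    gp_coef: float = 10.0
    seed: int = 0


class TrainingDiverged(RuntimeError):
    """Raised when a loss goes non-finite; carries the last good state."""

    def __init__(self, message: str, state: "TrainState"):
        super().__init__(message)
        self.state = state


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

class MLPGenerator(nn.Module):
    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        n_in = cfg.latent_dim + (cfg.label_embed if cfg.conditional else 0)
        dims = [n_in, *cfg.widths, cfg.n_channels * cfg.n_samples]
        self.layers = [nn.Dense(dims[i], dims[i + 1], rng)
                       for i in range(len(dims) - 1)]
        if cfg.conditional:
            self.embed = nn.Dense(cfg.n_classes, cfg.label_embed, rng)

    def refresh(self):
        for l in self.layers:
            l.refresh()
        if self.cfg.conditional:
            self.embed.refresh()

    def parameters(self):
        out = {}
        for i, l in enumerate(self.layers):
            for k, v in l.parameters().items():
                out[f"g{i}.{k}"] = v
        if self.cfg.conditional:
            for k, v in self.embed.parameters().items():
                out[f"emb.{k}"] = v
        return out

    def param_tensors(self):
        out = []
        for l in self.layers:
            out.extend(l.param_tensors())
        if self.cfg.conditional:
            out.extend(self.embed.param_tensors())
        return out

    def load_state_dict(self, state):
        for i, l in enumerate(self.layers):
            for k in l.parameters():
                l._params[k] = np.array(state[f"g{i}.{k}"])
        if self.cfg.conditional:
            for k in self.embed.parameters():
                self.embed._params[k] = np.array(state[f"emb.{k}"])

    def state_dict(self):
        return {k: v.copy() for k, v in self.parameters().items()}

    def forward(self, z: Tensor, y_onehot: Tensor | None = None) -> Tensor:
        cfg = self.cfg
        h = z
        if cfg.conditional:
            if y_onehot is None:
                raise ValueError("conditional generator needs labels")
            h = ad.concat([z, self.embed(y_onehot)], axis=1)
        for l in self.layers[:-1]:
            h = ad.leaky_relu(l(h))
        h = ad.tanh(self.layers[-1](h))
        return ad.reshape(h, (z.shape[0], cfg.n_channels, cfg.n_samples))


class MLPCritic(nn.Module):
    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        n_in = cfg.n_channels * cfg.n_samples + (
            cfg.label_embed if cfg.conditional else 0)
        dims = [n_in, *cfg.widths, 1]
        self.layers = [nn.Dense(dims[i], dims[i + 1], rng)
                       for i in range(len(dims) - 1)]
        if cfg.conditional:
            self.embed = nn.Dense(cfg.n_classes, cfg.label_embed, rng)

    refresh = MLPGenerator.refresh
    state_dict = MLPGenerator.state_dict
    load_state_dict = MLPGenerator.load_state_dict

    def parameters(self):
        out = {}
        for i, l in enumerate(self.layers):
            for k, v in l.parameters().items():
                out[f"g{i}.{k}"] = v
        if self.cfg.conditional:
            for k, v in self.embed.parameters().items():
                out[f"emb.{k}"] = v
        return out

    param_tensors = MLPGenerator.param_tensors

    def forward(self, x: Tensor, y_onehot: Tensor | None = None) -> Tensor:
        h = ad.reshape(x, (x.shape[0], -1))
        if self.cfg.conditional:
            if y_onehot is None:
                raise ValueError("conditional critic needs labels")
            h = ad.concat([h, self.embed(y_onehot)], axis=1)
        for l in self.layers[:-1]:
            h = ad.leaky_relu(l(h))
        return self.layers[-1](h)


class WaveGenerator(nn.Module):
    """Dense seed -> 4x (upsample x2, conv k, LeakyReLU) -> conv -> tanh."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        super().__init__()
        if cfg.n_samples % 16 != 0:
            raise ValueError("wavegan_lite needs n_samples divisible by 16")
        self.cfg = cfg
        c = cfg.conv_channels
        self.l0 = cfg.n_samples // 16
        self.seed_fc = nn.Dense(cfg.latent_dim, c * self.l0, rng)
        self.convs = [nn.Conv1d(c, c, cfg.kernel, rng) for _ in range(4)]
        self.head = nn.Conv1d(c, cfg.n_channels, cfg.kernel, rng)
        self._mods = [self.seed_fc, *self.convs, self.head]

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

    def forward(self, z: Tensor, y_onehot: Tensor | None = None) -> Tensor:
        cfg = self.cfg
        h = ad.leaky_relu(self.seed_fc(z))
        h = ad.reshape(h, (z.shape[0], cfg.conv_channels, self.l0))
        up = nn.UpsampleNearest(2)
        for conv in self.convs:
            h = ad.leaky_relu(conv(up(h)))
        return ad.tanh(self.head(h))


class WaveCritic(nn.Module):
    """4x (conv k, LeakyReLU, avgpool x2) -> dense score."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        c = cfg.conv_channels
        chans = [cfg.n_channels, c, c, c, c]
        self.convs = [nn.Conv1d(chans[i], chans[i + 1], cfg.kernel, rng)
                      for i in range(4)]
        self.fc = nn.Dense(c * (cfg.n_samples // 16), 1, rng)
        self._mods = [*self.convs, self.fc]

    refresh = WaveGenerator.refresh
    parameters = WaveGenerator.parameters
    param_tensors = WaveGenerator.param_tensors
    state_dict = WaveGenerator.state_dict
    load_state_dict = WaveGenerator.load_state_dict

    def forward(self, x: Tensor, y_onehot: Tensor | None = None) -> Tensor:
        pool = nn.AvgPool1d(2)
        h = x
        for conv in self.convs:
            h = pool(ad.leaky_relu(conv(h)))
        return self.fc(ad.reshape(h, (x.shape[0], -1)))


def build_generator(variant: str, cfg: NetConfig, rng: np.random.Generator):
    if variant == "wavegan_lite":
        return WaveGenerator(cfg, rng)
    return MLPGenerator(cfg, rng)


def build_critic(variant: str, cfg: NetConfig, rng: np.random.Generator):
    if variant == "wavegan_lite":
        return WaveCritic(cfg, rng)
    return MLPCritic(cfg, rng)


# ---------------------------------------------------------------------------
# differentiable regularizer terms (mirror metaceeg.mrm on Tensors)
# ---------------------------------------------------------------------------

def _curvature_t(x: Tensor) -> Tensor:
    n = x.shape[-1]
    y1 = ad.narrow(x, -1, 0, n - 2)
    y2 = ad.narrow(x, -1, 1, n - 2)
    y3 = ad.narrow(x, -1, 2, n - 2)
    b2 = (y3 - y1) * 0.5
    b3 = (y3 - y2 * 2.0 + y1) * 0.5
    absb3 = (b3 * b3 + 1e-24) ** 0.5
    return absb3 * 2.0 * (1.0 + b2 * b2) ** -1.5


def _squash_t(k: Tensor) -> Tensor:
    return ad.clip(k * (1.0 + k) ** -1.0, EPS_CLIP, 1.0 - EPS_CLIP)


def _bce_t(target: np.ndarray, pred: Tensor) -> Tensor:
    t = Tensor(target)
    return -(t * ad.log(pred) + (1.0 - t) * ad.log(1.0 - pred)).mean()


def tr_loss_t(real_batch: np.ndarray, fake: Tensor) -> Tensor:
    from .mrm import squash_curvature, three_point_curvature
    k_real = squash_curvature(three_point_curvature(real_batch))
    return _bce_t(k_real, _squash_t(_curvature_t(fake)))


def _dft_mats(n: int) -> tuple[np.ndarray, np.ndarray]:
    idx = np.arange(n)
    ang = -2.0 * np.pi * np.outer(idx, idx) / n
    return np.cos(ang), np.sin(ang)


def amplitude_spectrum_t(fake: Tensor) -> Tensor:
    """Normalized |DFT| of each trace: [B,C,N] -> [B,C,N] summing to 1."""
    B, C, N = fake.shape
    cos_m, sin_m = _dft_mats(N)
    flat = ad.reshape(fake, (B * C, N))
    re = flat @ Tensor(cos_m.T)
    im = flat @ Tensor(sin_m.T)
    amp = (re * re + im * im + 1e-24) ** 0.5
    amp = amp * ad.tsum(amp, axis=1, keepdims=True) ** -1.0
    return ad.reshape(amp, (B, C, N))


def fr_loss_t(real_batch: np.ndarray, fake: Tensor) -> Tensor:
    from .mrm import amplitude_spectrum
    f_real = amplitude_spectrum(real_batch, normalize=True).mean(axis=0)
    f_real = np.clip(f_real, EPS_CLIP, 1.0 - EPS_CLIP)
    f_fake = ad.clip(amplitude_spectrum_t(fake), EPS_CLIP, 1.0 - EPS_CLIP)
    target = np.broadcast_to(f_real, f_fake.shape)
    return _bce_t(target, f_fake)


def sr_loss_t(z: np.ndarray, fake: Tensor, mode: str) -> Tensor:
    """Latent-diversity term from disjoint halves of the latent mini-batch."""
    B = z.shape[0]
    half = B // 2
    z1, z2 = z[:half], z[half:2 * half]
    zn1 = z1 / np.linalg.norm(z1, axis=1, keepdims=True)
    zn2 = z2 / np.linalg.norm(z2, axis=1, keepdims=True)
    denom = 1.0 - np.sum(zn1 * zn2, axis=1)
    if np.any(denom < 1e-12):
        raise ValueError("degenerate latent pair; resample the batch")

    flat = ad.reshape(fake, (fake.shape[0], -1))
    g1 = ad.narrow(flat, 0, 0, half)
    g2 = ad.narrow(flat, 0, half, half)
    n1 = ad.tsum(g1 * g1, axis=1) ** 0.5
    n2 = ad.tsum(g2 * g2, axis=1) ** 0.5
    cos_g = ad.tsum(g1 * g2, axis=1) * (n1 * n2) ** -1.0
    ratio = (1.0 - cos_g) * Tensor(1.0 / denom)
    if mode == "reciprocal":
        return ((ratio + EPS_RATIO) ** -1.0).mean()
    if mode == "negative":
        return -ratio.mean()
    if mode == "literal":
        return ratio.mean()
    raise ValueError(f"unknown sr mode {mode!r}")


# ---------------------------------------------------------------------------
# gradient penalty
# ---------------------------------------------------------------------------

def _penalty_tensor(critic, real: np.ndarray, fake: np.ndarray,
                    rng: np.random.Generator,
                    y_onehot: np.ndarray | None = None) -> Tensor:
    u = rng.uniform(size=(real.shape[0],) + (1,) * (real.ndim - 1))
    xhat = Tensor(u * real + (1.0 - u) * fake)
    y = Tensor(y_onehot) if y_onehot is not None else None
    score = critic(xhat) if y is None else critic(xhat, y)
    gx = ad.grad(ad.tsum(score), xhat)
    axes = tuple(range(1, real.ndim))
    norm = (ad.tsum(gx * gx, axis=axes) + 1e-24) ** 0.5
    return ((norm - 1.0) ** 2).mean()


def gradient_penalty(critic, real_batch: np.ndarray, fake_batch: np.ndarray,
                     seed: int = 0, labels_onehot: np.ndarray | None = None) -> float:
    """Mean (||grad_x critic(xhat)|| - 1)^2 over random interpolates."""
    real_batch = np.asarray(real_batch, dtype=float)
    fake_batch = np.asarray(fake_batch, dtype=float)
    if real_batch.shape != fake_batch.shape:
        raise ValueError("real and fake batches must share a shape")
    critic.refresh()
    rng = np.random.default_rng(seed)
    return float(_penalty_tensor(critic, real_batch, fake_batch, rng,
                                 labels_onehot).data)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainState:
    variant: str
    net: NetConfig
    weights: RegularizerWeights | None
    schedule: TrainSchedule
    generator: object
    critic: object
    g_opt: nn.Adam
    d_opt: nn.Adam
    step: int = 0
    history: list[LossBreakdown] = field(default_factory=list)
    critic_history: list[float] = field(default_factory=list)
    rng_state: dict | None = None
    fs: float = 256.0
    channel_names: list[str] = field(default_factory=list)
    time0_ms: float = 0.0

    def save(self, path) -> None:
        blob = {
            "variant": self.variant, "net": self.net, "weights": self.weights,
            "schedule": self.schedule, "step": self.step,
            "history": self.history, "critic_history": self.critic_history,
            "g_params": self.generator.state_dict(),
            "d_params": self.critic.state_dict(),
            "g_opt": self.g_opt.state_dict(), "d_opt": self.d_opt.state_dict(),
            "rng_state": self.rng_state, "fs": self.fs,
            "channel_names": self.channel_names, "time0_ms": self.time0_ms,
        }
        with open(path, "wb") as f:
            pickle.dump(blob, f)

    @classmethod
    def load(cls, path) -> "TrainState":
        with open(path, "rb") as f:
            blob = pickle.load(f)
        rng = np.random.default_rng(0)
        gen = build_generator(blob["variant"], blob["net"], rng)
        crit = build_critic(blob["variant"], blob["net"], rng)
        gen.load_state_dict(blob["g_params"])
        crit.load_state_dict(blob["d_params"])
        g_opt = nn.Adam(gen, lr=blob["schedule"].lr, betas=blob["schedule"].betas)
        d_opt = nn.Adam(crit, lr=blob["schedule"].lr, betas=blob["schedule"].betas)
        g_opt.load_state_dict(blob["g_opt"])
        d_opt.load_state_dict(blob["d_opt"])
        return cls(variant=blob["variant"], net=blob["net"],
                   weights=blob["weights"], schedule=blob["schedule"],
                   generator=gen, critic=crit, g_opt=g_opt, d_opt=d_opt,
                   step=blob["step"], history=blob["history"],
                   critic_history=blob["critic_history"],
                   rng_state=blob["rng_state"], fs=blob["fs"],
                   channel_names=blob["channel_names"],
                   time0_ms=blob["time0_ms"])


def _onehot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def _run_steps(state: TrainState, data: np.ndarray, labels: np.ndarray,
               n_steps: int) -> None:
    """Alternating critic/generator updates; appends to the loss histories.

    A real mini-batch is drawn for the generator step regardless of which
    regularizers are active, so the random stream (and hence the adversarial
    trajectory) is identical whether the regulation module is disabled
    term-by-term or absent altogether.
    """
    cfg, sched, w = state.net, state.schedule, state.weights
    rng = np.random.default_rng()
    rng.bit_generator.state = state.rng_state
    gen, crit = state.generator, state.critic
    n = data.shape[0]

    for _ in range(n_steps):
        last_g = gen.state_dict()
        last_d = crit.state_dict()

        # -- critic updates
        d_loss_val = np.nan
        for _ in range(sched.n_critic):
            idx = rng.integers(0, n, size=sched.batch_size)
            real = data[idx]
            z = rng.standard_normal((sched.batch_size, cfg.latent_dim))
            y1h = _onehot(labels[idx], cfg.n_classes) if cfg.conditional else None

            gen.refresh()
            crit.refresh()
            zt = Tensor(z)
            yt = Tensor(y1h) if y1h is not None else None
            fake = (gen(zt, yt) if cfg.conditional else gen(zt)).data

            realt, faket = Tensor(real), Tensor(fake)
            if cfg.conditional:
                d_loss = (crit(faket, yt).mean() - crit(realt, yt).mean())
            else:
                d_loss = (crit(faket).mean() - crit(realt).mean())
            pen = _penalty_tensor(crit, real, fake, rng, y1h)
            d_loss = d_loss + sched.gp_coef * pen
            d_loss_val = float(d_loss.data)
            state.d_opt.step(nn.grads_by_name(crit, d_loss))

        # -- generator update
        idx = rng.integers(0, n, size=sched.batch_size)
        real = data[idx]
        z = rng.standard_normal((sched.batch_size, cfg.latent_dim))
        y1h = _onehot(labels[idx], cfg.n_classes) if cfg.conditional else None

        gen.refresh()
        crit.refresh()
        zt = Tensor(z)
        yt = Tensor(y1h) if y1h is not None else None
        fake = gen(zt, yt) if cfg.conditional else gen(zt)
        adv = -(crit(fake, yt).mean() if cfg.conditional else crit(fake).mean())

        if w is not None and (w.use_tr or w.use_fr or w.use_sr):
            tr = tr_loss_t(real, fake) if w.use_tr else Tensor(0.0)
            fr = fr_loss_t(real, fake) if w.use_fr else Tensor(0.0)
            sr = sr_loss_t(z, fake, w.sr_mode) if w.use_sr else Tensor(0.0)
            total = adv + w.lam * sr + (1.0 - w.lam) * (0.5 * fr + 0.5 * tr)
            row = LossBreakdown(L_G=float(adv.data), L_TR=float(tr.data),
                                L_FR=float(fr.data), L_SR=float(sr.data),
                                L_G_final=float(total.data))
        else:
            total = adv
            row = LossBreakdown(L_G=float(adv.data), L_TR=0.0, L_FR=0.0,
                                L_SR=0.0, L_G_final=float(adv.data))

        if not (np.isfinite(row.L_G_final) and np.isfinite(d_loss_val)):
            gen.load_state_dict(last_g)
            crit.load_state_dict(last_d)
            raise TrainingDiverged(
                f"non-finite loss at step {state.step}", state)

        state.g_opt.step(nn.grads_by_name(gen, total))
        state.history.append(row)
        state.critic_history.append(d_loss_val)
        state.step += 1

    state.rng_state = rng.bit_generator.state


def train(variant: str, data: EpochedEEG, net: NetConfig,
          weights: RegularizerWeights | None = None,
          schedule: TrainSchedule = TrainSchedule()) -> TrainState:
    """Train one adversarial pair on preprocessed (i.e. [-1, 1]) epochs.

    ``weights=None`` trains the plain base variant; passing weights with all
    three regularizers disabled follows the exact same code path and random
    stream, so the two loss histories agree bit for bit.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    if variant == "cwgan_gp" and not net.conditional:
        net = NetConfig(**{**net.__dict__, "conditional": True})
    if np.abs(data.data).max() > 1.0 + 1e-6:
        warnings.warn("training data exceeds [-1, 1]; did you maxabs-scale?",
                      stacklevel=2)

    rng = np.random.default_rng(schedule.seed)
    gen = build_generator(variant, net, rng)
    crit = build_critic(variant, net, rng)
    state = TrainState(
        variant=variant, net=net, weights=weights, schedule=schedule,
        generator=gen, critic=crit,
        g_opt=nn.Adam(gen, lr=schedule.lr, betas=schedule.betas),
        d_opt=nn.Adam(crit, lr=schedule.lr, betas=schedule.betas),
        rng_state=np.random.default_rng(schedule.seed + 1).bit_generator.state,
        fs=data.fs, channel_names=list(data.channel_names),
        time0_ms=data.time0_ms)
    _run_steps(state, data.data.astype(np.float64), data.labels,
               schedule.n_steps)
    return state


def resume(state: TrainState, n_steps: int, data: EpochedEEG) -> TrainState:
    """Continue training; with the same data this reproduces an
    uninterrupted run bit for bit."""
    _run_steps(state, data.data.astype(np.float64), data.labels, n_steps)
    return state


def sample(state: TrainState, n: int, labels: np.ndarray | None = None,
           seed: int = 0) -> EpochedEEG:
    """Draw n epochs from fixed-seed latents."""
    cfg = state.net
    if labels is not None and not cfg.conditional:
        raise ValueError("labels given to an unconditional model")
    if cfg.conditional and labels is None:
        raise ValueError("conditional model needs labels")
    if n == 0:
        return EpochedEEG(np.zeros((0, cfg.n_channels, cfg.n_samples)),
                          np.zeros(0, dtype=np.int32), fs=state.fs,
                          channel_names=list(state.channel_names) or None,
                          time0_ms=state.time0_ms)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, cfg.latent_dim))
    state.generator.refresh()
    if cfg.conditional:
        labels = np.asarray(labels, dtype=np.int32)
        out = state.generator(Tensor(z),
                              Tensor(_onehot(labels, cfg.n_classes))).data
    else:
        out = state.generator(Tensor(z)).data
        labels = np.zeros(n, dtype=np.int32)
    return EpochedEEG(out, labels, fs=state.fs,
                      channel_names=list(state.channel_names) or None,
                      time0_ms=state.time0_ms)


# ---------------------------------------------------------------------------
# latent-space gradient bound
# ---------------------------------------------------------------------------

@dataclass
class BoundReport:
    """Per-pair dissimilarity ratio vs squared path-integrated gradient norm.

    The inequality ratio <= (integral_0^1 ||grad_z G(gamma(t))|| dt)^2 along
    the chord gamma(t) = t z1 + (1-t) z2 is exact for the raw generator map
    (it coincides with the cosine form when outputs are unit-normalized);
    any violation beyond quadrature tolerance indicates an implementation
    error.
    """

    ratios: np.ndarray
    bounds: np.ndarray
    tolerance_rel: float = 1e-3
    resampled: int = 0

    @property
    def violations(self) -> int:
        return int(np.sum(self.ratios - self.bounds
                          > self.tolerance_rel * np.abs(self.bounds)))


def _jacobian_norms(generator, points: np.ndarray) -> np.ndarray:
    """Spectral norm of dG/dz at each latent point (rows batched)."""
    xin = Tensor(points)
    gen_refresh = getattr(generator, "refresh", None)
    if gen_refresh is not None:
        gen_refresh()
    out = generator(xin)
    out = ad.reshape(out, (points.shape[0], -1))
    d_out = out.shape[1]
    rows = []
    for j in range(d_out):
        col = ad.narrow(out, 1, j, 1)
        rows.append(ad.grad(ad.tsum(col), xin).data)
    jac = np.stack(rows, axis=1)  # [M, d_out, d_z]
    return np.linalg.norm(jac, ord=2, axis=(1, 2))


def sr_bound_check(generator, latent_dim: int, n_pairs: int = 100,
                   n_quad: int = 128, seed: int = 0) -> BoundReport:
    """Empirically verify ratio <= (path-integrated gradient norm)^2.

    Latents are unit-normalized; the path integral uses trapezoid quadrature
    of per-point Jacobian spectral norms.  Degenerate pairs (z1 ~ z2) are
    resampled.
    """
    rng = np.random.default_rng(seed)
    resampled = 0
    z1 = rng.standard_normal((n_pairs, latent_dim))
    z2 = rng.standard_normal((n_pairs, latent_dim))
    z1 /= np.linalg.norm(z1, axis=1, keepdims=True)
    z2 /= np.linalg.norm(z2, axis=1, keepdims=True)
    while True:
        bad = np.sum((z1 - z2) ** 2, axis=1) < 1e-12
        if not bad.any():
            break
        resampled += int(bad.sum())
        z2[bad] = rng.standard_normal((bad.sum(), latent_dim))
        z2[bad] /= np.linalg.norm(z2[bad], axis=1, keepdims=True)

    ts = np.linspace(0.0, 1.0, n_quad)
    # all quadrature points for all pairs in one batch
    pts = (ts[None, :, None] * z1[:, None, :]
           + (1.0 - ts[None, :, None]) * z2[:, None, :])
    norms = _jacobian_norms(generator, pts.reshape(-1, latent_dim))
    norms = norms.reshape(n_pairs, n_quad)
    integrals = np.trapezoid(norms, ts, axis=1)
    bounds = integrals ** 2

    gen_refresh = getattr(generator, "refresh", None)
    if gen_refresh is not None:
        gen_refresh()
    g1 = generator(Tensor(z1)).data.reshape(n_pairs, -1)
    g2 = generator(Tensor(z2)).data.reshape(n_pairs, -1)
    ratios = (np.sum((g1 - g2) ** 2, axis=1)
              / np.sum((z1 - z2) ** 2, axis=1))
    return BoundReport(ratios=ratios, bounds=bounds, resampled=resampled)
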
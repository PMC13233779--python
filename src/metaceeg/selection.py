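"""Trade-off weight selection, the mixing-ratio augmentation experiment,
and the saturation power-law fit.

The selection rule z-normalizes the Mode-Score and SWD columns (jointly
with the unregularized baseline so deltas share a scale), forms
dMS = MS_lam - MS_0 and dSWD = SWD_0 - SWD_lam, keeps only weights where
both deltas are positive, and returns the argmax of their sum.

Accuracy as a function of the generated-to-real mixing ratio x is fitted
with y = a * x^gamma + b by least squares: for each gamma, (a, b) solve in
closed form; gamma itself is found by a coarse grid plus golden-section
refinement over (0, 3].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .containers import EpochedEEG
from .metrics import ClassifMetrics, classification_metrics

__all__ = ["LambdaGridRow", "NoFeasibleLambda", "SaturationFit",
           "lambda_grid_select", "fit_saturation", "run_augmentation"]


class NoFeasibleLambda(ValueError):
    """No grid point improves both diversity and similarity."""


@dataclass(frozen=True)
class LambdaGridRow:
    lam: float
    MS: float
    SWD: float
    dMS: float = np.nan
    dSWD: float = np.nan
    dSum: float = np.nan


def lambda_grid_select(rows, baseline_MS: float, baseline_SWD: float):
    """Pick the trade-off weight maximizing the joint normalized gain.

    `rows` is a sequence of (lam, MS, SWD) triples or LambdaGridRow.
    Returns (lam_star, table) where table is a DataFrame with the
    z-normalized deltas for every grid point.
    """
    parsed = [(r.lam, r.MS, r.SWD) if isinstance(r, LambdaGridRow) else tuple(r)
              for r in rows]
    if len(parsed) < 2:
        raise ValueError("need at least 2 grid points")
    lams = np.array([p[0] for p in parsed], dtype=float)
    if np.any((lams <= 0) | (lams >= 1)):
        raise ValueError("grid weights must lie in (0, 1)")

    ms = np.array([baseline_MS] + [p[1] for p in parsed], dtype=float)
    swd = np.array([baseline_SWD] + [p[2] for p in parsed], dtype=float)

    def znorm(col):
        sd = col.std()
        return (col - col.mean()) / (sd if sd > 0 else 1.0)

    ms_z, swd_z = znorm(ms), znorm(swd)
    d_ms = ms_z[1:] - ms_z[0]
    d_swd = swd_z[0] - swd_z[1:]
    d_sum = d_ms + d_swd
    feasible = (d_ms > 0) & (d_swd > 0)

    table = pd.DataFrame({"lam": lams, "MS": ms[1:], "SWD": swd[1:],
                          "dMS": d_ms, "dSWD": d_swd, "dSum": d_sum,
                          "feasible": feasible})
    if not feasible.any():
        raise NoFeasibleLambda(
            "no lambda improves both MS and SWD; widen the grid")
    best = np.flatnonzero(feasible)[np.argmax(d_sum[feasible])]
    return float(lams[best]), table


# ---------------------------------------------------------------------------
# saturation fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SaturationFit:
    a: float
    gamma: float
    b: float
    ssr: float

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return self.a * np.power(x, self.gamma, where=x > 0,
                                 out=np.zeros_like(x)) + self.b


def _ab_for_gamma(x: np.ndarray, y: np.ndarray, gamma: float):
    xg = np.power(x, gamma, where=x > 0, out=np.zeros_like(x))
    design = np.column_stack([xg, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return coef[0], coef[1], float(resid @ resid)


def fit_saturation(x_ratios, y_accuracies,
                   gamma_max: float = 3.0) -> SaturationFit:
    """Least-squares fit of y = a x^gamma + b over mixing ratios.

    gamma is searched on a dense grid over (0, gamma_max] then refined by
    golden section; (a, b) are the closed-form linear solution at each
    gamma.  x = 0 rows contribute through the intercept only.
    """
    x = np.asarray(x_ratios, dtype=float)
    y = np.asarray(y_accuracies, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(y, y[0]):
        return SaturationFit(a=0.0, gamma=1.0, b=float(y[0]), ssr=0.0)

    grid = np.linspace(1e-3, gamma_max, 400)
    ssrs = np.array([_ab_for_gamma(x, y, g)[2] for g in grid])
    gi = int(np.argmin(ssrs))
    lo = grid[max(gi - 1, 0)]
    hi = grid[min(gi + 1, grid.size - 1)]

    phi = (np.sqrt(5.0) - 1.0) / 2.0
    c, d = hi - phi * (hi - lo), lo + phi * (hi - lo)
    fc, fd = _ab_for_gamma(x, y, c)[2], _ab_for_gamma(x, y, d)[2]
    for _ in range(80):
        if fc < fd:
            hi, d, fd = d, c, fc
            c = hi - phi * (hi - lo)
            fc = _ab_for_gamma(x, y, c)[2]
        else:
            lo, c, fc = c, d, fd
            d = lo + phi * (hi - lo)
            fd = _ab_for_gamma(x, y, d)[2]
    gamma = 0.5 * (lo + hi)
    a, b, ssr = _ab_for_gamma(x, y, gamma)
    return SaturationFit(a=float(a), gamma=float(gamma), b=float(b), ssr=ssr)


# ---------------------------------------------------------------------------
# augmentation experiment
# ---------------------------------------------------------------------------

def _take_generated(generated: EpochedEEG, labels_needed: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Label-matched sample of generated epoch indices (without replacement)."""
    chosen = []
    for c in np.unique(labels_needed):
        pool = np.flatnonzero(generated.labels == c)
        need = int(np.sum(labels_needed == c))
        if pool.size < need:
            raise ValueError(
                f"insufficient generated epochs for label {c}: "
                f"need {need}, have {pool.size}")
        chosen.append(rng.choice(pool, size=need, replace=False))
    return np.concatenate(chosen)


def run_augmentation(real: EpochedEEG, generated: EpochedEEG, ratios,
                     clf_factory, seed: int = 0,
                     n_folds: int = 5) -> pd.DataFrame:
    """Mixing-ratio experiment: stratified 8:2 split, 5-fold CV inside the
    80%, training folds augmented with ratio x generated epochs.

    Generated epochs enter ONLY the training portion of each fold;
    validation folds and the held-out test split are real-only.
    `clf_factory(seed)` must return an object with fit(X, y) and
    predict_proba(X) over flattened epochs (sklearn-style).

    Returns a tidy DataFrame: ratio x metric with CV mean/SD plus the
    test-split value.
    """
    rng = np.random.default_rng(seed)
    idx_train, idx_test = train_test_split(
        np.arange(real.n_epochs), test_size=0.2, random_state=seed,
        stratify=real.labels)
    x_all = real.data.reshape(real.n_epochs, -1)
    y_all = real.labels
    gx = generated.data.reshape(generated.n_epochs, -1)

    rows = []
    for ratio in ratios:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=seed)
        fold_metrics: list[ClassifMetrics] = []
        for tr, va in skf.split(idx_train, y_all[idx_train]):
            tr_idx, va_idx = idx_train[tr], idx_train[va]
            x_tr, y_tr = x_all[tr_idx], y_all[tr_idx]
            if ratio > 0:
                need = np.repeat(y_tr, ratio)
                gi = _take_generated(generated, need, rng)
                x_tr = np.concatenate([x_tr, gx[gi]], axis=0)
                y_tr = np.concatenate([y_tr, generated.labels[gi]])
            clf = clf_factory(seed)
            clf.fit(x_tr, y_tr)
            proba = clf.predict_proba(x_all[va_idx])
            scores = proba[:, 1] if proba.shape[1] == 2 else proba
            fold_metrics.append(
                classification_metrics(y_all[va_idx], scores))
        # test-split model trained on the full 80% (+ generated)
        x_tr, y_tr = x_all[idx_train], y_all[idx_train]
        if ratio > 0:
            need = np.repeat(y_tr, ratio)
            gi = _take_generated(generated, need, rng)
            x_tr = np.concatenate([x_tr, gx[gi]], axis=0)
            y_tr = np.concatenate([y_tr, generated.labels[gi]])
        clf = clf_factory(seed)
        clf.fit(x_tr, y_tr)
        proba = clf.predict_proba(x_all[idx_test])
        scores = proba[:, 1] if proba.shape[1] == 2 else proba
        test_m = classification_metrics(y_all[idx_test], scores)

        for name in ("Acc", "Pre", "Rec", "F1", "AUC"):
            vals = np.array([getattr(m, name) for m in fold_metrics])
            rows.append({"ratio": ratio, "metric": name,
                         "cv_mean": float(vals.mean()),
                         "cv_sd": float(vals.std(ddof=1)),
                         "test": float(getattr(test_m, name))})
    return pd.DataFrame(rows)
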
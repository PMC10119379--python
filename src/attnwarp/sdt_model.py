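"""d-prime computation, maximum-likelihood bias fitting, and chance-point inference.

The 2AFC sensitivity convention is ``d' = sqrt(2) * Phi^{-1}(p)`` with the
proportion of target choices clamped to ``[1/(2n), 1 - 1/(2n)]``; negative
values mean the foil was preferred.  The bias model is the generative
observer of :mod:`attnwarp.synthetic_observer`: per condition cell the
probability of choosing the target is

    p = (1 - lapse) * Phi((delta/2 - s*b_D)/sigma) + lapse/2

with ``s = +1`` for away foils, ``-1`` for toward foils, and ``b_D`` either
shared or free per search distance.  Fitting maximizes the binomial
likelihood of the per-cell counts via a coarse grid seed followed by
Nelder-Mead refinement, so results are deterministic given the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

from .synthetic_observer import ObserverParams, p_choose_target

__all__ = [
    "CELL_COLUMNS",
    "FitResult",
    "dprime_2afc",
    "summarize",
    "negative_loglik",
    "fit_bias_model",
    "infer_bias_from_chance",
]

CELL_COLUMNS = ["D", "delta", "foil_direction"]

_SIGN = {"away": 1.0, "toward": -1.0}

# grid seeds for the MLE refinement
_B_GRID = np.arange(0.0, 30.0 + 1e-9, 1.0)
_SIGMA_GRID = np.arange(2.0, 40.0 + 1e-9, 2.0)
_SIGMA_FLOOR = 0.25


def dprime_2afc(n_target_chosen, n_trials):
    """Unbiased-2AFC sensitivity from target-choice counts.

    The empirical proportion is clamped to ``[1/(2n), 1 - 1/(2n)]`` before
    the probit transform, so perfect scores stay finite.
    """
    n = np.asarray(n_trials, dtype=float)
    if np.any(n < 1):
        raise ValueError("n_trials must be >= 1")
    k = np.asarray(n_target_chosen, dtype=float)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("n_target_chosen must lie in [0, n_trials]")
    p = np.clip(k / n, 1.0 / (2.0 * n), 1.0 - 1.0 / (2.0 * n))
    return (np.sqrt(2.0) * ndtri(p))[()]


def summarize(
    data: pd.DataFrame,
    by_subject: bool = False,
    extra_keys: Tuple[str, ...] = ("experiment",),
) -> pd.DataFrame:
    """Per-condition-cell choice counts, proportions and d'.

    One row per design cell (per subject when ``by_subject``); cells whose
    trials were all excluded or unanswered are reported with ``n_trials = 0``
    and missing d' rather than dropped.  Row order of the input is
    irrelevant: output is sorted by the cell key.
    """
    required = set(CELL_COLUMNS) | {"trial_kind", "choice"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    judged = data[data["trial_kind"].isin(("both", "similarity_report"))]
    keys = [k for k in extra_keys if k in judged.columns] + CELL_COLUMNS
    if by_subject:
        if "subject_id" not in judged.columns:
            raise ValueError("by_subject requires a subject_id column")
        keys = ["subject_id"] + keys
    grouped = judged.groupby(keys, dropna=False, sort=True)
    out = grouped.agg(
        n_trials=("choice", lambda c: int(c.notna().sum())),
        n_target_chosen=("choice", lambda c: int((c == "target").sum())),
    ).reset_index()
    with np.errstate(invalid="ignore"):
        out["p_target"] = np.where(
            out["n_trials"] > 0, out["n_target_chosen"] / out["n_trials"], np.nan
        )
    out["dprime"] = [
        dprime_2afc(k, n) if n > 0 else np.nan
        for k, n in zip(out["n_target_chosen"], out["n_trials"])
    ]
    return out


def negative_loglik(
    params: ObserverParams, summaries: pd.DataFrame, model: str = "linear"
) -> float:
    """Binomial negative log-likelihood of per-cell counts under the observer.

    Returns ``inf`` when a cell's predicted probability is degenerate (0 or
    1) but its counts disagree, which flags an infeasible parameter point.
    """
    total = 0.0
    for row in summaries.itertuples():
        n = int(row.n_trials)
        if n == 0:
            continue
        k = int(row.n_target_chosen)
        p = float(
            p_choose_target(row.delta, row.foil_direction, params, D=row.D, model=model)
        )
        if p <= 0.0:
            if k > 0:
                return float("inf")
            continue
        if p >= 1.0:
            if k < n:
                return float("inf")
            continue
        total -= k * np.log(p) + (n - k) * np.log1p(-p)
    return total


@dataclass
class FitResult:
    """Maximum-likelihood estimates and per-cell model predictions."""

    estimates: Dict[str, object]  # {"bias": {D: value} | float, "sigma": .., "lapse": ..}
    loglik: float
    n_params: int
    n_trials: int
    converged: bool
    boundary: bool
    predicted: pd.DataFrame = field(repr=False)
    model: str = "linear"

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    def bias_at(self, D: float) -> float:
        b = self.estimates["bias"]
        return float(b[D]) if isinstance(b, dict) else float(b)

    def to_dict(self) -> Dict[str, object]:
        est = dict(self.estimates)
        if isinstance(est.get("bias"), dict):
            est["bias"] = {str(k): v for k, v in est["bias"].items()}
        return {
            "estimates": est,
            "loglik": self.loglik,
            "aic": self.aic,
            "n_params": self.n_params,
            "n_trials": self.n_trials,
            "converged": self.converged,
            "boundary": self.boundary,
            "model": self.model,
            "predicted": self.predicted.to_dict(orient="records"),
        }


def _cell_arrays(summaries: pd.DataFrame):
    cells = summaries[summaries["n_trials"] > 0].reset_index(drop=True)
    if len(cells) < 2:
        raise ValueError("need at least 2 cells with nonzero trials")
    delta = cells["delta"].to_numpy(dtype=float)
    s = cells["foil_direction"].map(_SIGN).to_numpy(dtype=float)
    k = cells["n_target_chosen"].to_numpy(dtype=float)
    n = cells["n_trials"].to_numpy(dtype=float)
    D = cells["D"].to_numpy(dtype=float)
    return cells, D, delta, s, k, n


def _binom_nll(p, k, n):
    p = np.clip(p, 1e-300, 1.0 - 1e-16)
    return -(k * np.log(p) + (n - k) * np.log1p(-p)).sum()


def fit_bias_model(
    data: pd.DataFrame,
    bias_per_distance: bool = True,
    lapse: object = 0.0,
    model: str = "linear",
) -> FitResult:
    """Fit the bias model to trial data or pre-computed cell summaries.

    ``data`` may be a raw trial table (it is pooled across subjects) or the
    output of :func:`summarize`.  ``bias_per_distance`` fits one bias per
    search distance D (the distance-adaptive model); otherwise a single
    shared bias.  ``lapse`` is a fixed value or ``"free"``.

    The refinement is seeded from the best point of a coarse grid
    (``b`` in [0, 30] step 1, ``sigma`` in [2, 40] step 2), so the result is
    deterministic.  Biases may go negative during refinement; ``boundary``
    flags estimates pinned near the search limits.
    """
    if "n_trials" not in data.columns:
        data = summarize(data)
    cells, D, delta, s, k, n = _cell_arrays(data)
    d_levels = np.array(sorted(set(D)))
    d_index = np.searchsorted(d_levels, D)
    n_bias = len(d_levels) if bias_per_distance else 1
    if not bias_per_distance:
        d_index = np.zeros(len(D), dtype=int)
    free_lapse = lapse == "free"
    fixed_lapse = 0.0 if free_lapse else float(lapse)

    def cell_probs(b_vec, sigma, lam):
        if model == "linear":
            p0 = ndtr((delta / 2.0 - s * b_vec[d_index]) / sigma)
        else:
            p0 = np.array(
                [
                    p_choose_target(
                        dl,
                        "away" if sg > 0 else "toward",
                        ObserverParams(bias=b_vec[di], sigma=sigma),
                        model=model,
                    )
                    for dl, sg, di in zip(delta, s, d_index)
                ]
            )
        return (1.0 - lam) * p0 + lam / 2.0

    # --- coarse grid seed (separable over distances at fixed sigma) -------
    best = (np.inf, None)
    lam_grid = (0.0, 0.05, 0.15) if free_lapse else (fixed_lapse,)
    for lam in lam_grid:
        for sigma in _SIGMA_GRID:
            total = 0.0
            b_star = np.empty(n_bias)
            for j in range(n_bias):
                sel = d_index == j
                nlls = [
                    _binom_nll(
                        (1.0 - lam)
                        * ndtr((delta[sel] / 2.0 - s[sel] * b) / sigma)
                        + lam / 2.0
                        if model == "linear"
                        else cell_probs(
                            np.full(n_bias, b), sigma, lam
                        )[sel],
                        k[sel],
                        n[sel],
                    )
                    for b in _B_GRID
                ]
                j_best = int(np.argmin(nlls))
                b_star[j] = _B_GRID[j_best]
                total += nlls[j_best]
            if total < best[0]:
                best = (total, (b_star.copy(), float(sigma), float(lam)))
    b0, sigma0, lam0 = best[1]

    # --- Nelder-Mead refinement ------------------------------------------
    def pack(b_vec, sigma, lam):
        x = list(b_vec) + [sigma]
        if free_lapse:
            x.append(lam)
        return np.array(x)

    def unpack(x):
        b_vec = x[:n_bias]
        sigma = x[n_bias]
        lam = x[n_bias + 1] if free_lapse else fixed_lapse
        return b_vec, sigma, lam

    def objective(x):
        b_vec, sigma, lam = unpack(x)
        if sigma <= _SIGMA_FLOOR or not 0.0 <= lam <= 0.5:
            return np.inf
        return _binom_nll(cell_probs(b_vec, sigma, lam), k, n)

    res = minimize(
        objective,
        pack(b0, sigma0, lam0),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 4000 * (n_bias + 2)},
    )
    b_hat, sigma_hat, lam_hat = unpack(res.x)
    nll = float(res.fun)
    boundary = bool(
        sigma_hat <= _SIGMA_FLOOR * 1.05
        or sigma_hat >= _SIGMA_GRID[-1] * 1.5
        or np.any(np.abs(b_hat) >= _B_GRID[-1] * 1.5)
        or (free_lapse and lam_hat >= 0.499)
    )

    # keep reported probabilities in the open interval even where the model
    # saturates in double precision (e.g. 180-deg foils with zero lapse)
    p_hat = np.clip(cell_probs(b_hat, sigma_hat, lam_hat), 1e-12, 1.0 - 1e-12)
    predicted = cells[[c for c in cells.columns if c in
                       ("experiment", "D", "delta", "foil_direction")]].copy()
    predicted["p_target"] = p_hat
    predicted["dprime"] = np.sqrt(2.0) * ndtri(np.clip(p_hat, 1e-12, 1 - 1e-12))

    bias_est: object
    if bias_per_distance:
        bias_est = {float(dv): float(bv) for dv, bv in zip(d_levels, b_hat)}
    else:
        bias_est = float(b_hat[0])
    estimates = {"bias": bias_est, "sigma": float(sigma_hat), "lapse": float(lam_hat)}
    return FitResult(
        estimates=estimates,
        loglik=-nll,
        n_params=n_bias + 1 + (1 if free_lapse else 0),
        n_trials=int(n.sum()),
        converged=bool(res.success),
        boundary=boundary,
        predicted=predicted,
        model=model,
    )


def infer_bias_from_chance(delta: float) -> float:
    """Bias implied by chance performance with an away foil at ``delta``.

    At chance the observer perceives target and foil as equidistant from the
    internal representation, which for any symmetric noise puts the
    representation exactly halfway: ``bias = delta / 2``.
    """
    delta = float(delta)
    if delta < 0:
        raise ValueError("delta must be >= 0")
    return delta / 2.0
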
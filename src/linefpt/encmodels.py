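"""Candidate encounter-rate models and AIC selection.

Eleven a-priori models relate the simulated encounter rate E to prey density
N and line density S. Their functional forms encode movement mechanisms:
a linear E–N law is the signature of directed (ballistic) search, a quadratic
law of purely random (diffusive) search, and power/interaction forms mix the
two.

==  ============================================  ==================
id  form                                          parameters
==  ============================================  ==================
A1  E = b0 + b1 S                                 b0, b1
A2  E = b0 + b1 S + b2 S²                         b0, b1, b2
A3  E = A exp(b S)                                A, b
B1  E = b1 N                                      b1
B2  E = b1 N²                                     b1
B3  E = b1 N + b2 N²                              b1, b2
B4  E = A N^b                                     A, b
C1  E = A N^b                                     A, b
C2  E = A N^b + b1 N S                            A, b, b1
C3  E = A N^b + b1 N^b S                          A, b, b1
C4  E = A N^b1 + b1 N^b2 S                        A, b1_exp, beta1, b2_exp
==  ============================================  ==================

Fits are nonlinear least squares with a deterministic multi-start over the
power exponent (b ∈ {0.5, 1, 1.5, 2}) and log-log-regression seeds for the
linear-in-parameters pieces; A and b are kept positive through a log
parameterisation. Ranking uses the Gaussian least-squares AIC
``n ln(RSS/n) + 2k`` (AICc optional). RSS is floored at ``n (1e-8 · rms E)²``
so that on effectively noiseless data exactly-fitting nested models are
ordered by parameter count.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "MODEL_IDS",
    "NESTED_IN",
    "CandidateFit",
    "fit_candidate",
    "rank_models",
    "fit_family",
    "predict",
]

_EXP_STARTS = (0.5, 1.0, 1.5, 2.0)


def _m_a1(x, p):
    return p[0] + p[1] * x["S"]


def _m_a2(x, p):
    return p[0] + p[1] * x["S"] + p[2] * x["S"] ** 2


def _m_a3(x, p):
    return np.exp(p[0]) * np.exp(p[1] * x["S"])


def _m_b1(x, p):
    return p[0] * x["N"]


def _m_b2(x, p):
    return p[0] * x["N"] ** 2


def _m_b3(x, p):
    return p[0] * x["N"] + p[1] * x["N"] ** 2


def _m_b4(x, p):
    return np.exp(p[0]) * x["N"] ** np.exp(p[1])


def _m_c2(x, p):
    return np.exp(p[0]) * x["N"] ** np.exp(p[1]) + p[2] * x["N"] * x["S"]


def _m_c3(x, p):
    b = np.exp(p[1])
    return np.exp(p[0]) * x["N"] ** b + p[2] * x["N"] ** b * x["S"]


def _m_c4(x, p):
    return np.exp(p[0]) * x["N"] ** np.exp(p[1]) + p[2] * x["N"] ** np.exp(p[3]) * x["S"]


# id -> (fn, parameter names, names of log-parameterised entries)
_REGISTRY = {
    "A1": (_m_a1, ["beta0", "beta1"], []),
    "A2": (_m_a2, ["beta0", "beta1", "beta2"], []),
    "A3": (_m_a3, ["A", "b"], ["A"]),
    "B1": (_m_b1, ["beta1"], []),
    "B2": (_m_b2, ["beta1"], []),
    "B3": (_m_b3, ["beta1", "beta2"], []),
    "B4": (_m_b4, ["A", "b"], ["A", "b"]),
    "C1": (_m_b4, ["A", "b"], ["A", "b"]),
    "C2": (_m_c2, ["A", "b", "beta1"], ["A", "b"]),
    "C3": (_m_c3, ["A", "b", "beta1"], ["A", "b"]),
    "C4": (_m_c4, ["A", "b1_exp", "beta1", "b2_exp"], ["A", "b1_exp", "b2_exp"]),
}

MODEL_IDS = tuple(_REGISTRY)

#: strict-superset relations: key's data can be fit exactly by every value
NESTED_IN = {
    "A1": ("A2",),
    "B1": ("B3", "B4", "C1", "C2", "C3", "C4"),
    "B2": ("B3", "B4", "C1", "C2", "C3", "C4"),
    "B4": ("C1", "C2", "C3", "C4"),
    "C1": ("C2", "C3", "C4"),
    "C2": ("C4",),
    "C3": ("C4",),
}


@dataclass
class CandidateFit:
    model_id: str
    params: dict
    rss: float
    n: int
    k: int
    aic: float
    delta_aic: float = np.nan
    converged: bool = True
    data_key: tuple = field(default=(), repr=False)

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        return predict(self.model_id, self.params, data)


def predict(model_id: str, params: dict, data: pd.DataFrame) -> np.ndarray:
    """Evaluate a fitted candidate model on (N, S) rows."""
    fn, names, logged = _REGISTRY[model_id]
    p = [
        np.log(params[nm]) if nm in logged else params[nm]
        for nm in names
    ]
    return np.asarray(fn(data, p), dtype=float)


def _data_key(data: pd.DataFrame) -> tuple:
    arr = np.ascontiguousarray(data[["N", "S", "E"]].to_numpy(dtype=float))
    return (arr.shape[0], hash(arr.tobytes()))


def _start_points(model_id: str, data: pd.DataFrame) -> list[np.ndarray]:
    """Deterministic start list: log-log regression seeds × exponent grid."""
    n = data["N"].to_numpy()
    s = data["S"].to_numpy()
    e = data["E"].to_numpy()
    e_pos = np.maximum(e, 1e-12)
    mean_e = float(np.mean(e))
    # log-log regression of E on N pins the power-law seed
    if np.ptp(n) > 0 and np.all(n > 0):
        slope, intercept = np.polyfit(np.log(n), np.log(e_pos), 1)
        a0 = float(np.exp(intercept))
        b0 = float(np.clip(slope, 0.05, 5.0))
    else:
        a0, b0 = mean_e, 1.0
    starts = []
    if model_id == "A1":
        starts.append(np.polyfit(s, e, 1)[::-1])
    elif model_id == "A2":
        starts.append(np.polyfit(s, e, 2)[::-1])
    elif model_id == "A3":
        sl, ic = np.polyfit(s, np.log(e_pos), 1)
        starts.append(np.array([ic, sl]))
    elif model_id in ("B1", "B2"):
        denom = n if model_id == "B1" else n**2
        starts.append(np.array([float(np.sum(e * denom) / np.sum(denom**2))]))
    elif model_id == "B3":
        coef, *_ = np.linalg.lstsq(np.column_stack([n, n**2]), e, rcond=None)
        starts.append(coef)
    elif model_id in ("B4", "C1"):
        for b in (b0, *_EXP_STARTS):
            starts.append(np.array([np.log(max(a0, 1e-8)), np.log(b)]))
    elif model_id in ("C2", "C3"):
        for b in (b0, *_EXP_STARTS):
            starts.append(np.array([np.log(max(a0, 1e-8)), np.log(b), 1e-3]))
    elif model_id == "C4":
        for b in (b0, *_EXP_STARTS):
            starts.append(
                np.array([np.log(max(a0, 1e-8)), np.log(b), 1e-3, np.log(b)])
            )
    return starts


def _rss_floor(e: np.ndarray) -> float:
    rms = float(np.sqrt(np.mean(e**2)))
    return e.size * (1e-8 * max(rms, 1e-300)) ** 2


def fit_candidate(model_id: str, data: pd.DataFrame, use_aicc: bool = False) -> CandidateFit:
    """Least-squares fit of one candidate model to (N, S, E) rows."""
    if model_id not in _REGISTRY:
        raise ValueError(f"unknown model id {model_id!r}")
    fn, names, logged = _REGISTRY[model_id]
    k = len(names)
    required = {"N", "S", "E"}
    if not required.issubset(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    data = data.reset_index(drop=True)
    e = data["E"].to_numpy(dtype=float)
    n = e.size
    if n <= k + 1:
        raise ValueError(f"need more than k+1 = {k + 1} rows to fit {model_id}")
    if np.any(e <= 0):
        raise ValueError("encounter rates must be positive")

    best = None
    for x0 in _start_points(model_id, data):
        try:
            res = least_squares(
                lambda p: fn(data, p) - e, x0, method="lm", max_nfev=10_000
            )
        except Exception:  # noqa: BLE001 - a failed start is simply skipped
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0]:
            best = (rss, res)
    if best is None:
        return CandidateFit(
            model_id, {}, np.inf, n, k, np.inf, converged=False, data_key=_data_key(data)
        )
    rss, res = best
    params = {
        nm: float(np.exp(v)) if nm in logged else float(v)
        for nm, v in zip(names, res.x)
    }
    rss_eff = rss + _rss_floor(e)
    aic = n * np.log(rss_eff / n) + 2 * k
    if use_aicc:
        if n - k - 1 <= 0:
            raise ValueError("AICc undefined: n too small")
        aic += 2 * k * (k + 1) / (n - k - 1)
    return CandidateFit(
        model_id, params, rss, n, k, float(aic),
        converged=bool(res.success or res.status > 0),
        data_key=_data_key(data),
    )


def rank_models(fits: list[CandidateFit]) -> pd.DataFrame:
    """Rank converged fits by AIC (ascending) and attach ΔAIC."""
    conv = [f for f in fits if f.converged and np.isfinite(f.aic)]
    if len(conv) < 2:
        raise ValueError("need at least two converged fits to rank")
    keys = {f.data_key for f in conv}
    if len(keys) != 1:
        raise ValueError("fits were made on different data sets")
    conv = sorted(conv, key=lambda f: f.aic)
    best = conv[0].aic
    for f in conv:
        f.delta_aic = f.aic - best
    return pd.DataFrame(
        [
            {
                "model": f.model_id,
                "k": f.k,
                "rss": f.rss,
                "aic": f.aic,
                "delta_aic": f.delta_aic,
                **{f"par_{nm}": v for nm, v in f.params.items()},
            }
            for f in conv
        ]
    )


def fit_family(family: str, data: pd.DataFrame, use_aicc: bool = False):
    """Fit and rank all candidates in one family ('A', 'B' or 'C')."""
    ids = [m for m in MODEL_IDS if m.startswith(family)]
    if not ids:
        raise ValueError(f"unknown family {family!r}")
    fits = [fit_candidate(m, data, use_aicc=use_aicc) for m in ids]
    return fits, rank_models(fits)
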
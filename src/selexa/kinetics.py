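"""Saturation kinetics: initial rates and Michaelis-Menten / Hill fits.

Initial rates are extracted from single-turnover fraction-reacted time
courses by a least-squares line through the linear phase (fraction reacted
<= 0.15 by default), scaled by the enzyme concentration:
``V0 = d(fraction)/dt * [E]``.  Saturation curves are fit by nonlinear least
squares to ``V0 = Vmax [S] / (Km + [S])`` (Michaelis-Menten) or to the Hill
generalization ``V0 = Vmax [S]^n / (K^n + [S]^n)``, and the turnover number
is ``kcat = Vmax / [E]``.  The Hill form is offered because substrate
titrations of this deoxyribozyme family show mild cooperativity; the
hyperbolic form is the default.  Residuals are unweighted (homoscedastic
least squares), matching the conventional Prism-style fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

DEFAULT_MAX_FRACTION = 0.15


@dataclass
class InitialRate:
    """Linear-phase initial rate with the fit's bookkeeping."""

    v0: float  # uM / min
    slope: float  # fraction / min
    intercept: float
    n_points: int


@dataclass
class SaturationFit:
    """Fitted saturation parameters (uM and minutes throughout)."""

    vmax: float  # uM / min
    k_half: float  # uM; Km for the hyperbolic model
    n_hill: float  # 1.0 exactly for the hyperbolic model
    kcat: float  # 1 / min
    residual_sse: float
    model: str  # "mm" | "hill"


def kcat_from_vmax(vmax: float, E: float) -> float:
    """Turnover number kcat = Vmax / [E]  (uM min^-1 / uM -> min^-1)."""
    if E <= 0:
        raise ValueError("enzyme concentration must be positive")
    return vmax / E


def initial_rate(
    course: list[tuple[float, float]] | pd.DataFrame,
    E: float = 1.0,
    max_fraction: float = DEFAULT_MAX_FRACTION,
) -> InitialRate:
    """Initial rate from a (t_min, fraction_reacted) time course.

    Only points with fraction <= ``max_fraction`` qualify as the linear
    phase; an ordinary least-squares line (free intercept) through them
    gives the slope, and ``V0 = slope * E``.
    """
    if isinstance(course, pd.DataFrame):
        pts = list(zip(course.iloc[:, 0], course.iloc[:, 1]))
    else:
        pts = list(course)
    if any(not 0.0 <= f <= 1.0 for _, f in pts):
        raise ValueError("fraction_reacted must lie in [0, 1]")
    lin = [(t, f) for t, f in pts if f <= max_fraction]
    if len(lin) < 2:
        raise ValueError(
            f"too few points in the linear phase (fraction <= {max_fraction}): "
            f"need >= 2, got {len(lin)}"
        )
    t = np.array([p[0] for p in lin])
    f = np.array([p[1] for p in lin])
    slope, intercept = np.polyfit(t, f, 1)
    return InitialRate(v0=float(slope * E), slope=float(slope), intercept=float(intercept), n_points=len(lin))


def _mm(S: np.ndarray, vmax: float, km: float) -> np.ndarray:
    return vmax * S / (km + S)


def _hill(S: np.ndarray, vmax: float, k: float, n: float) -> np.ndarray:
    return vmax * S**n / (k**n + S**n)


def fit_saturation(
    data: pd.DataFrame | list[tuple[float, float]],
    E: float = 1.0,
    model: str = "mm",
) -> SaturationFit:
    """Fit a saturation curve of (S_uM, V0) points.

    ``model="mm"`` fits the two-parameter hyperbola; ``model="hill"`` adds a
    Hill coefficient (needs >= 4 distinct substrate concentrations).
    Initialization: vmax at the largest observed rate, k_half at the
    substrate concentration nearest half that rate, n = 1.  All parameters
    are constrained positive.
    """
    if model not in ("mm", "hill"):
        raise ValueError(f"unknown model {model!r}")
    if isinstance(data, pd.DataFrame):
        S = data.iloc[:, 0].to_numpy(dtype=float)
        v = data.iloc[:, 1].to_numpy(dtype=float)
    else:
        S = np.array([p[0] for p in data], dtype=float)
        v = np.array([p[1] for p in data], dtype=float)
    n_distinct = len(np.unique(S))
    needed = 3 if model == "mm" else 4
    if n_distinct < needed:
        raise ValueError(f"{model} fit needs >= {needed} distinct S values")

    vmax0 = float(v.max())
    if vmax0 <= 0:
        raise ValueError("all rates are <= 0; nothing to fit")
    k0 = float(S[np.argmin(np.abs(v - vmax0 / 2.0))])
    k0 = max(k0, 1e-9)
    try:
        if model == "mm":
            popt, _ = curve_fit(
                _mm, S, v, p0=[vmax0, k0], bounds=(0, np.inf), maxfev=20000
            )
            vmax, k_half, n_hill = float(popt[0]), float(popt[1]), 1.0
            resid = v - _mm(S, *popt)
        else:
            popt, _ = curve_fit(
                _hill, S, v, p0=[vmax0, k0, 1.0], bounds=(0, np.inf), maxfev=20000
            )
            vmax, k_half, n_hill = map(float, popt)
            resid = v - _hill(S, *popt)
    except RuntimeError as exc:
        raise RuntimeError(f"saturation fit did not converge: {exc}") from exc
    if vmax <= 0 or k_half <= 0:
        raise RuntimeError("fit converged to a non-positive parameter")
    return SaturationFit(
        vmax=vmax,
        k_half=k_half,
        n_hill=n_hill,
        kcat=kcat_from_vmax(vmax, E),
        residual_sse=float(resid @ resid),
        model=model,
    )
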
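"""High-throughput screen and homogeneous-assay statistics.

Signal-to-noise ratios with background subtraction, plate Z-factor quality
control, percent-activity normalization against on-plate controls,
counterscreen-based hit classification, the three-standard-deviation limit
of detection, four-parameter-logistic IC50 fitting, and fluorophore
brightness bookkeeping (epsilon x Phi).

Conventions: sample standard deviation (n-1 denominator) throughout; the
Z-factor is ``1 - 3(sigma_p + sigma_n)/(mu_p - mu_n)``; percent activity
maps the negative-control mean to 0% and the positive-control mean to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


def signal_to_noise(f_with: float, f_without: float, f_buffer: float = 0.0) -> float:
    """Background-subtracted fluorescence ratio with/without catalyst.

    ``(f_with - f_buffer) / (f_without - f_buffer)``; the buffer-only signal
    is subtracted from both arms before the ratio.
    """
    denom = f_without - f_buffer
    if denom <= 0:
        raise ValueError("background (buffer) signal is not below the no-catalyst arm")
    return (f_with - f_buffer) / denom


def z_factor(pos_values, neg_values) -> float:
    """Screening-window quality statistic of one plate.

    ``Z = 1 - 3(sigma_p + sigma_n) / |mu_p - mu_n|`` with sample SDs; values
    near 1 mean excellent control separation, and negative values (arms
    overlap) are allowed.
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need >= 2 wells in each control arm")
    mu_p, mu_n = pos.mean(), neg.mean()
    if mu_p == mu_n:
        raise ValueError("control means are equal; Z-factor undefined")
    return float(1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / abs(mu_p - mu_n))


def plate_z_factor(plate: pd.DataFrame) -> float:
    """Z-factor of a tidy plate frame (columns ``role`` and ``fluorescence``)."""
    pos = plate.loc[plate["role"] == "positive", "fluorescence"]
    neg = plate.loc[plate["role"] == "negative", "fluorescence"]
    return z_factor(pos, neg)


def normalize_activity(plate: pd.DataFrame) -> pd.Series:
    """Percent activity of each compound well, anchored by the controls.

    The mean negative-control (background) signal is subtracted and the mean
    positive-control signal defines 100%:
    ``%activity = 100 (f - mean_neg) / (mean_pos - mean_neg)``.
    Returns a Series indexed by compound id.
    """
    pos = plate.loc[plate["role"] == "positive", "fluorescence"]
    neg = plate.loc[plate["role"] == "negative", "fluorescence"]
    if pos.empty or neg.empty:
        raise ValueError("plate lacks a control arm")
    mean_p, mean_n = pos.mean(), neg.mean()
    if mean_p == mean_n:
        raise ValueError("control means are equal; normalization undefined")
    samples = plate[plate["role"] == "sample"]
    pct = 100.0 * (samples["fluorescence"] - mean_n) / (mean_p - mean_n)
    return pd.Series(pct.to_numpy(), index=samples["compound_id"].to_numpy(), name="activity_pct")


def call_hits(
    screen: pd.Series | dict,
    counterscreen: pd.Series | dict,
    hit_max: float = 50.0,
    counter_min: float = 80.0,
) -> pd.DataFrame:
    """Classify compounds from a target screen plus a reporter counterscreen.

    A compound with low residual activity in the target screen
    (``<= hit_max`` %) and near-full activity in the counterscreen
    (``>= counter_min`` %) inhibits the target, not the reporter —
    ``target_inhibitor``.  Low in both arms means the reporter enzyme
    itself is inhibited (``enzyme_false_positive``); anything else is
    ``inactive``.  A compound missing its counterscreen value is flagged
    ``unresolved`` rather than dropped.
    """
    screen = pd.Series(screen, dtype=float)
    counterscreen = pd.Series(counterscreen, dtype=float)
    records = []
    for cid, act in screen.items():
        if cid not in counterscreen.index or pd.isna(counterscreen[cid]):
            klass = "unresolved"
            counter = np.nan
        else:
            counter = float(counterscreen[cid])
            if act <= hit_max and counter >= counter_min:
                klass = "target_inhibitor"
            elif act <= hit_max and counter <= hit_max:
                klass = "enzyme_false_positive"
            else:
                klass = "inactive"
        records.append((cid, float(act), counter, klass))
    return pd.DataFrame(
        records, columns=["compound_id", "screen_pct", "counter_pct", "klass"]
    ).set_index("compound_id")


def detection_limit(
    responses: dict[float, list[float]] | pd.DataFrame,
    background: list[float],
) -> float | None:
    """Three-sigma limit of detection over a concentration series.

    The threshold is mean(background) + 3 SD(background); the LOD is the
    lowest tested concentration whose mean signal meets it *and* whose
    higher tested concentrations all meet it too (a qualifying run, which
    guards against isolated noise excursions).  Returns None when no
    concentration qualifies.
    """
    bg = np.asarray(background, dtype=float)
    if len(bg) < 2:
        raise ValueError("need >= 2 background replicates")
    threshold = bg.mean() + 3.0 * bg.std(ddof=1)
    if isinstance(responses, pd.DataFrame):
        grouped = responses.groupby(responses.columns[0])[responses.columns[1]].mean()
        conc = grouped.index.to_numpy(dtype=float)
        means = grouped.to_numpy(dtype=float)
        order = np.argsort(conc)
        conc, means = conc[order], means[order]
    else:
        conc = np.array(sorted(responses), dtype=float)
        means = np.array([np.mean(responses[c]) for c in sorted(responses)], dtype=float)
    qualifies = means >= threshold
    # walk from the top: the LOD starts the maximal all-qualifying suffix
    lod = None
    for c, ok in zip(conc[::-1], qualifies[::-1]):
        if not ok:
            break
        lod = float(c)
    return lod


def _four_pl(x: np.ndarray, bottom: float, top: float, log_ic50: float, h: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((x - log_ic50) * h))


@dataclass
class DoseResponse:
    """Four-parameter-logistic dose-response fit (% activity vs uM)."""

    bottom: float
    top: float
    ic50: float  # uM
    hill_slope: float
    residual_sse: float


def fit_ic50(
    points: pd.DataFrame | list[tuple[float, float]],
    bottom_min: float = 0.0,
    top_max: float = 120.0,
) -> DoseResponse:
    """Fit ``y = bottom + (top - bottom) / (1 + (x/ic50)^h)`` to
    (concentration_uM, %activity) points.

    Fitted on log10 concentration internally for conditioning; reported on
    the linear scale.  Constraints: bottom >= 0, top <= 120% (activity can
    overshoot controls slightly but not arbitrarily).
    """
    if isinstance(points, pd.DataFrame):
        x = points.iloc[:, 0].to_numpy(dtype=float)
        y = points.iloc[:, 1].to_numpy(dtype=float)
    else:
        x = np.array([p[0] for p in points], dtype=float)
        y = np.array([p[1] for p in points], dtype=float)
    if len(np.unique(x)) < 4:
        raise ValueError("IC50 fit needs >= 4 distinct concentrations")
    if (x <= 0).any():
        raise ValueError("concentrations must be positive")
    if np.ptp(y) == 0:
        raise ValueError("response is constant; no transition to fit")
    lx = np.log10(x)
    p0 = [max(y.min(), bottom_min), min(y.max(), top_max), float(np.median(lx)), 1.0]
    bounds = ([bottom_min, bottom_min, lx.min() - 3, 0.1], [top_max, top_max, lx.max() + 3, 10.0])
    try:
        popt, _ = curve_fit(_four_pl, lx, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"IC50 fit did not converge: {exc}") from exc
    bottom, top, log_ic50, h = map(float, popt)
    resid = y - _four_pl(lx, *popt)
    return DoseResponse(
        bottom=bottom,
        top=top,
        ic50=float(10.0**log_ic50),
        hill_slope=h,
        residual_sse=float(resid @ resid),
    )


@dataclass(frozen=True)
class PhotoProps:
    """Fluorophore photophysics bookkeeping."""

    epsilon: float  # M^-1 cm^-1
    phi: float  # quantum yield in [0, 1]
    lambda_ex: float | None = None  # nm
    lambda_em: float | None = None  # nm

    @property
    def brightness(self) -> float:
        return product_brightness(self.epsilon, self.phi)


def product_brightness(epsilon: float, phi: float) -> float:
    """Brightness = extinction coefficient x quantum yield (M^-1 cm^-1)."""
    if epsilon <= 0:
        raise ValueError("extinction coefficient must be positive")
    if not 0.0 <= phi <= 1.0:
        raise ValueError("quantum yield must lie in [0, 1]")
    return epsilon * phi
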
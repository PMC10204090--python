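"""Fluorescence normalization, Hill fitting and operational range.

Whole-cell biosensor output is characterized by titrating the inducer and
reading reporter fluorescence alongside culture optical density (OD600).
Raw readings are blank-corrected against cell-free medium and fluorescence
is normalized by OD:

    y = (F - F_blank) / (OD - OD_blank)

The dose-response is modeled with a four-parameter Hill function

    y(I) = b0 + (bmax - b0) * I**h / (Km**h + I**h)

where ``b0`` is the basal (leaky) output, ``bmax`` the maximal output,
``Km`` the inducer concentration at half-maximal output (uM) and ``h``
the Hill (cooperativity) coefficient. The operational range is the
inducer interval covering a fraction ``lo``..``hi`` (default 5-95%) of
the ``bmax - b0`` span; inverting the Hill function gives the closed form

    I(f) = Km * (f / (1 - f)) ** (1 / h).

Fitting is nonlinear least squares (:func:`scipy.optimize.curve_fit`)
with deterministic initialization; :class:`HillRegressor` wraps the same
core as a scikit-learn estimator so it composes with sklearn pipelines
and model selection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

MIN_FIT_POINTS = 5


class InvalidPointError(ValueError):
    """A dose-response point cannot be normalized (non-positive corrected OD)."""


class HillFitError(RuntimeError):
    """The Hill fit failed; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None) -> None:
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class DoseResponsePoint:
    """One well: inducer concentration (uM), raw fluorescence, OD600 and
    the cell-free medium blanks."""

    inducer_conc: float
    fluorescence: float
    od: float
    fluorescence_blank: float = 0.0
    od_blank: float = 0.0

    @property
    def is_valid(self) -> bool:
        return self.od - self.od_blank > 0


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters: basal ``b0``, maximal ``bmax``, half-maximal
    concentration ``km`` (uM) and Hill coefficient ``h``."""

    b0: float
    bmax: float
    km: float
    h: float
    residual_norm: float | None = None

    def __post_init__(self) -> None:
        if self.km <= 0:
            raise ValueError(f"km must be > 0, got {self.km}")
        if self.h <= 0:
            raise ValueError(f"h must be > 0, got {self.h}")
        if self.bmax <= self.b0:
            raise ValueError(f"bmax ({self.bmax}) must exceed b0 ({self.b0})")


def normalize(point: DoseResponsePoint) -> float:
    """Blank-corrected, OD-normalized fluorescence for one point.

    Raises :class:`InvalidPointError` when the corrected OD is not
    positive; such points are excluded from fits.
    """
    od_corr = point.od - point.od_blank
    if od_corr <= 0:
        raise InvalidPointError(
            f"corrected OD {od_corr:g} <= 0 at inducer {point.inducer_conc:g} uM"
        )
    return (point.fluorescence - point.fluorescence_blank) / od_corr


def normalize_points(
    points: Iterable[DoseResponsePoint],
) -> tuple[np.ndarray, np.ndarray, int]:
    """Normalize a collection of points, excluding invalid ones.

    Returns (concentrations, normalized responses, n_excluded).
    """
    conc, resp, dropped = [], [], 0
    for p in points:
        if not p.is_valid:
            dropped += 1
            continue
        conc.append(p.inducer_conc)
        resp.append(normalize(p))
    if dropped:
        logger.info("excluded %d invalid point(s) (non-positive corrected OD)", dropped)
    return np.asarray(conc, dtype=float), np.asarray(resp, dtype=float), dropped


def hill_response(fit: HillFit, conc: float | np.ndarray) -> float | np.ndarray:
    """Hill response at inducer concentration ``conc`` (uM)."""
    return _hill(np.asarray(conc, dtype=float), fit.b0, fit.bmax, fit.km, fit.h)


def _hill(conc: np.ndarray, b0: float, bmax: float, km: float, h: float) -> np.ndarray:
    conc = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(conc > 0, conc**h / (km**h + conc**h), 0.0)
    out = b0 + (bmax - b0) * frac
    return out if out.ndim else float(out)


def _initial_guess(conc: np.ndarray, resp: np.ndarray) -> tuple[float, float, float, float]:
    """Deterministic start: b0 = min, bmax = max, km = dose at half-span
    (log-interpolated over the positive doses), h = 1."""
    b0, bmax = float(resp.min()), float(resp.max())
    half = (b0 + bmax) / 2.0
    pos = conc > 0
    x, y = conc[pos], resp[pos]
    order = np.argsort(x)
    x, y = x[order], y[order]
    km = float(np.exp(np.interp(half, y, np.log(x)))) if y.size and y[-1] > y[0] else float(
        np.exp(np.mean(np.log(x))) if x.size else 1.0
    )
    if not np.isfinite(km) or km <= 0:
        km = float(np.median(x)) if x.size else 1.0
    return b0, bmax, km, 1.0


def fit_hill(
    points: Iterable[DoseResponsePoint] | Sequence[tuple[float, float]] | np.ndarray,
    seed: int = 0,
) -> HillFit:
    """Least-squares 4-parameter Hill fit.

    ``points`` is either a collection of :class:`DoseResponsePoint` (raw
    readings; normalized and filtered here) or an array-like of
    ``(concentration, response)`` pairs. Requires at least 5 valid points
    spanning the transition. The fit is deterministic given the points
    (``seed`` is accepted for interface symmetry with stochastic
    routines). Raises :class:`HillFitError` with diagnostics on
    degenerate data or non-convergence.
    """
    del seed  # fit is deterministic
    points = list(points)
    if points and isinstance(points[0], DoseResponsePoint):
        conc, resp, _ = normalize_points(points)
    else:
        arr = np.asarray(points, dtype=float).reshape(-1, 2)
        conc, resp = arr[:, 0], arr[:, 1]

    if conc.size < MIN_FIT_POINTS:
        raise HillFitError(
            f"need >= {MIN_FIT_POINTS} valid points, got {conc.size}",
            {"n_points": int(conc.size)},
        )
    span = float(resp.max() - resp.min())
    if span <= 0 or span < 1e-12 * max(1.0, abs(float(resp.max()))):
        raise HillFitError(
            "responses are constant; no transition to fit",
            {"response_min": float(resp.min()), "response_max": float(resp.max())},
        )

    p0 = _initial_guess(conc, resp)
    max_dose = float(conc.max())
    lower = [resp.min() - span, resp.min() - span, 1e-9, 1e-6]
    upper = [resp.max() + span, resp.max() + span, 10.0 * max_dose, 10.0]
    p0 = tuple(np.clip(p0, lower, upper))
    try:
        popt, _ = curve_fit(
            _hill, conc, resp, p0=p0, bounds=(lower, upper), maxfev=20_000
        )
    except (RuntimeError, ValueError) as exc:
        raise HillFitError(
            f"Hill fit did not converge: {exc}",
            {"p0": list(p0), "n_points": int(conc.size)},
        ) from exc

    b0, bmax, km, h = (float(v) for v in popt)
    if bmax <= b0:
        raise HillFitError(
            "fit collapsed: bmax <= b0 (data may be non-monotone)",
            {"b0": b0, "bmax": bmax, "km": km, "h": h},
        )
    residual_norm = float(np.linalg.norm(resp - _hill(conc, b0, bmax, km, h)))
    return HillFit(b0=b0, bmax=bmax, km=km, h=h, residual_norm=residual_norm)


def operational_range(fit: HillFit, lo: float = 0.05, hi: float = 0.95) -> tuple[float, float]:
    """Inducer concentrations (uM) at fractions ``lo`` and ``hi`` of the
    response span: I(f) = Km * (f/(1-f))**(1/h).

    Satisfies I(lo) * I(hi) == Km**2 whenever ``hi == 1 - lo``.
    """
    if not (0.0 < lo < hi < 1.0):
        raise ValueError(f"require 0 < lo < hi < 1, got lo={lo}, hi={hi}")

    def invert(f: float) -> float:
        return fit.km * (f / (1.0 - f)) ** (1.0 / fit.h)

    return invert(lo), invert(hi)


class HillRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn estimator for Hill dose-response curves.

    Parameters
    ----------
    lo, hi : float
        Span fractions defining the operational range (default 0.05/0.95).

    Attributes (after :meth:`fit`)
    ------------------------------
    b0_, bmax_, km_, h_ : float
        Fitted Hill parameters (``km_`` in the units of X).
    residual_norm_ : float
        Euclidean norm of the fit residuals.
    """

    def __init__(self, lo: float = 0.05, hi: float = 0.95):
        self.lo = lo
        self.hi = hi

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be a single concentration column")
            X = X[:, 0]
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        result = fit_hill(np.column_stack([X, y]))
        self.b0_ = result.b0
        self.bmax_ = result.bmax
        self.km_ = result.km
        self.h_ = result.h
        self.residual_norm_ = result.residual_norm
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "km_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return np.asarray(_hill(X, self.b0_, self.bmax_, self.km_, self.h_))

    def hill_fit_(self) -> HillFit:
        check_is_fitted(self, "km_")
        return HillFit(
            b0=self.b0_,
            bmax=self.bmax_,
            km=self.km_,
            h=self.h_,
            residual_norm=self.residual_norm_,
        )

    def operational_range_(self) -> tuple[float, float]:
        """Operational range of the fitted sensor at (lo, hi)."""
        return operational_range(self.hill_fit_(), self.lo, self.hi)


# -- CSV / JSON interchange -------------------------------------------

CSV_COLUMNS = (
    "inducer_conc_uM",
    "fluorescence",
    "od",
    "fluorescence_blank",
    "od_blank",
    "replicate",
)


def read_points_csv(path: str | Path) -> list[DoseResponsePoint]:
    """Read a dose-response CSV (columns as in :data:`CSV_COLUMNS`)."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
    return [
        DoseResponsePoint(
            inducer_conc=float(r.inducer_conc_uM),
            fluorescence=float(r.fluorescence),
            od=float(r.od),
            fluorescence_blank=float(r.fluorescence_blank),
            od_blank=float(r.od_blank),
        )
        for r in df.itertuples(index=False)
    ]


def fit_report(fit: HillFit, lo: float = 0.05, hi: float = 0.95) -> dict:
    """JSON-ready summary of a fit: parameters, residual norm and the
    operational range."""
    i_lo, i_hi = operational_range(fit, lo, hi)
    return {
        "b0": fit.b0,
        "bmax": fit.bmax,
        "km_uM": fit.km,
        "hill_coefficient": fit.h,
        "residual_norm": fit.residual_norm,
        "operational_range_uM": {
            "lo_fraction": lo,
            "hi_fraction": hi,
            "lower": i_lo,
            "upper": i_hi,
        },
    }


def write_fit_json(fit: HillFit, path: str | Path, lo: float = 0.05, hi: float = 0.95) -> None:
    Path(path).write_text(json.dumps(fit_report(fit, lo, hi), indent=2) + "\n")
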
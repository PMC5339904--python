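"""Hill-equation LD50 fitting, replicate aggregation, and affinity classes.

The central model is a decreasing sigmoid

    y(x) = c / (1 + (x / k) ** g)

where ``c`` is the curve maximum (cell density without antibiotic), ``x``
the ampicillin dose, ``k`` the LD50 (dose killing half the cells) and ``g``
the Hill coefficient.  Fitting is bounded nonlinear least squares with a
small deterministic multi-start over the Hill coefficient, so results are
reproducible for a fixed input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseSeries",
    "HillParams",
    "FitDiagnostics",
    "FitConfig",
    "LD50Result",
    "RelativeAffinity",
    "ExpressionRecord",
    "hill",
    "fit_hill",
    "aggregate_ld50",
    "normalize_affinity",
    "classify_affinity",
    "normalize_expression",
]


def hill(x, c: float, k: float, g: float):
    """Decreasing Hill curve ``c / (1 + (x/k)**g)``; defined at x = 0."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        return c / (1.0 + (x / k) ** g)


@dataclass(frozen=True)
class DoseResponseSeries:
    """One construct pair's absorbance readings across ampicillin doses."""

    pair_id: str
    replicate_id: str
    concentrations: tuple[float, ...]
    responses: tuple[float, ...]
    condition: str = ""

    def __post_init__(self):
        conc = tuple(float(x) for x in self.concentrations)
        resp = tuple(float(y) for y in self.responses)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "responses", resp)
        if len(conc) != len(resp):
            raise ValueError(
                f"series {self.pair_id}/{self.replicate_id}: "
                f"{len(conc)} doses but {len(resp)} responses"
            )
        if any(x < 0 for x in conc):
            raise ValueError("negative ampicillin concentration")
        if any(y < 0 for y in resp):
            raise ValueError("negative absorbance reading")
        distinct = set(conc)
        if len(distinct) < 5 or 0.0 not in distinct:
            raise ValueError(
                "need at least 5 distinct concentrations including 0"
            )

    @property
    def x(self) -> np.ndarray:
        return np.array(self.concentrations, dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.array(self.responses, dtype=float)


@dataclass(frozen=True)
class HillParams:
    """Fitted parameters of the decreasing Hill curve; ``k`` is the LD50."""

    c: float
    k: float
    g: float

    def __post_init__(self):
        if not (self.c > 0 and self.k > 0 and self.g > 0):
            raise ValueError(f"Hill parameters must be positive, got {self}")

    def predict(self, x):
        return hill(x, self.c, self.k, self.g)


@dataclass(frozen=True)
class FitDiagnostics:
    r_squared: float
    rss: float
    n_points: int
    converged: bool
    accepted: bool
    reason: str = ""


@dataclass(frozen=True)
class FitConfig:
    """Fit settings: QC threshold and the multi-start Hill-coefficient grid."""

    r_squared_min: float = 0.85
    g_starts: tuple[float, ...] = (1.0, 3.0, 8.0)
    max_nfev: int = 2000


_DEFAULT_FIT_CONFIG = FitConfig()


def _initial_k(x: np.ndarray, y: np.ndarray, c0: float) -> float:
    """Dose at half-max by linear interpolation along sorted doses."""
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    half = c0 / 2.0
    for i in range(1, len(xs)):
        if ys[i - 1] >= half >= ys[i]:
            if ys[i - 1] == ys[i]:
                return float(xs[i]) if xs[i] > 0 else 1.0
            frac = (ys[i - 1] - half) / (ys[i - 1] - ys[i])
            k0 = xs[i - 1] + frac * (xs[i] - xs[i - 1])
            if k0 > 0:
                return float(k0)
    # never crosses half-max: fall back to the midpoint of the dose range
    positive = xs[xs > 0]
    return float(np.median(positive)) if positive.size else 1.0


def fit_hill(
    series: DoseResponseSeries,
    config: FitConfig | None = None,
) -> tuple[Optional[HillParams], FitDiagnostics]:
    """Fit the decreasing Hill curve to one dose-response series.

    Returns ``(params, diagnostics)``.  ``params`` is ``None`` when no start
    converged or the data are degenerate (all-equal or monotonically
    increasing responses); those cases are flagged in the diagnostics
    rather than raised.  Deterministic for fixed input and settings.
    """
    config = config or _DEFAULT_FIT_CONFIG
    x, y = series.x, series.y
    n = len(x)
    if np.count_nonzero(x) < 4:
        raise ValueError("need at least 4 non-zero doses")

    tss = float(np.sum((y - y.mean()) ** 2))
    if np.ptp(y) == 0.0:
        return None, FitDiagnostics(
            r_squared=-math.inf, rss=0.0, n_points=n,
            converged=False, accepted=False, reason="all responses equal",
        )
    order = np.argsort(x)
    if np.all(np.diff(y[order]) >= 0):
        return None, FitDiagnostics(
            r_squared=-math.inf, rss=tss, n_points=n,
            converged=False, accepted=False,
            reason="monotonically increasing responses",
        )

    c0 = float(y.max())
    k0 = _initial_k(x, y, c0)
    xmax = float(x.max())
    lower = np.array([1e-9, 1e-9, 1e-3])
    upper = np.array([10.0 * c0, 100.0 * xmax, 50.0])

    def residuals(theta):
        c, k, g = theta
        return hill(x, c, k, g) - y

    best = None
    for g0 in config.g_starts:
        theta0 = np.clip(np.array([c0, k0, g0]), lower, upper)
        try:
            res = least_squares(
                residuals, theta0, bounds=(lower, upper),
                max_nfev=config.max_nfev, xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        if not res.success:
            continue
        rss = float(np.sum(res.fun**2))
        # tie on SSE -> keep the smallest Hill coefficient
        if best is None or rss < best[0] - 1e-12 or (
            abs(rss - best[0]) <= 1e-12 and res.x[2] < best[1][2]
        ):
            best = (rss, res.x)

    if best is None:
        return None, FitDiagnostics(
            r_squared=-math.inf, rss=tss, n_points=n,
            converged=False, accepted=False, reason="no start converged",
        )

    rss, (c, k, g) = best
    r2 = 1.0 - rss / tss
    accepted = r2 >= config.r_squared_min
    params = HillParams(c=float(c), k=float(k), g=float(g))
    diag = FitDiagnostics(
        r_squared=r2, rss=rss, n_points=n, converged=True,
        accepted=accepted,
        reason="" if accepted else f"r_squared {r2:.3f} below threshold",
    )
    return params, diag


@dataclass(frozen=True)
class LD50Result:
    """Mean +/- SEM of the LD50 over accepted replicate fits."""

    pair_id: str
    ld50_mean: float
    ld50_sem: Optional[float]
    n: int
    n_rejected: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("LD50Result requires n >= 1")
        if self.n == 1 and self.ld50_sem is not None:
            raise ValueError("SEM undefined for a single accepted fit")
        if self.ld50_sem is not None and self.ld50_sem < 0:
            raise ValueError("SEM must be non-negative")


class NoEstimateError(ValueError):
    """Raised when a pair has no accepted replicate fit."""


def aggregate_ld50(
    pair_id: str,
    fits: Sequence[tuple[Optional[HillParams], FitDiagnostics]],
) -> LD50Result:
    """Mean and SEM (sample SD / sqrt(n)) of k over *accepted* fits only."""
    ks = [p.k for p, d in fits if p is not None and d.accepted]
    n_rejected = len(fits) - len(ks)
    if not ks:
        raise NoEstimateError(f"no accepted LD50 fit for pair {pair_id!r}")
    n = len(ks)
    mean = float(np.mean(ks))
    sem = float(np.std(ks, ddof=1) / math.sqrt(n)) if n > 1 else None
    return LD50Result(
        pair_id=pair_id, ld50_mean=mean, ld50_sem=sem, n=n,
        n_rejected=n_rejected,
    )


@dataclass(frozen=True)
class RelativeAffinity:
    """LD50 as a percentage of a reference construct (reference = 100)."""

    percent_of_reference: float
    affinity_class: str = field(default="")

    def __post_init__(self):
        if self.percent_of_reference < 0:
            raise ValueError("percent of reference must be >= 0")
        if not self.affinity_class:
            object.__setattr__(
                self, "affinity_class",
                classify_affinity(self.percent_of_reference),
            )


def normalize_affinity(
    result: LD50Result, reference: LD50Result
) -> RelativeAffinity:
    """Express ``result`` as a percentage of the reference LD50."""
    if reference.ld50_mean <= 0:
        raise ValueError("reference LD50 must be positive")
    percent = 100.0 * result.ld50_mean / reference.ld50_mean
    return RelativeAffinity(percent_of_reference=percent)


# class boundaries: >80% high, 50-80% medium (inclusive), <50% low
HIGH_BOUNDARY = 80.0
LOW_BOUNDARY = 50.0


def classify_affinity(percent: float) -> str:
    if percent < 0:
        raise ValueError("percent must be >= 0")
    if percent > HIGH_BOUNDARY:
        return "high"
    if percent >= LOW_BOUNDARY:
        return "medium"
    return "low"


@dataclass(frozen=True)
class ExpressionRecord:
    """Background-subtracted GFP fluorescence per unit cell density."""

    pair_id: str
    gfp_raw: float
    background: float
    a544: float
    normalized: float
    percent_of_reference: Optional[float] = None


def normalize_expression(
    pair_id: str,
    gfp_raw: float,
    background: float,
    a544: float,
    reference_normalized: Optional[float] = None,
) -> ExpressionRecord:
    """(gfp - background) / a544, optionally rescaled so reference = 100%."""
    if a544 <= 0:
        raise ValueError(f"a544 must be positive, got {a544}")
    normalized = (gfp_raw - background) / a544
    percent = None
    if reference_normalized is not None:
        if reference_normalized <= 0:
            raise ValueError("reference normalized value must be positive")
        percent = 100.0 * normalized / reference_normalized
    return ExpressionRecord(
        pair_id=pair_id, gfp_raw=gfp_raw, background=background,
        a544=a544, normalized=normalized, percent_of_reference=percent,
    )
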
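"""cmc extraction from raw measurement curves.

Two estimators are provided, matching the two classes of experiment:

* fluorimetric titration (pyrene I1/I3 ratio vs total surfactant
  concentration): a Boltzmann sigmoid is fitted and the inflection
  concentration ``x0`` is reported as the cmc;
* specific conductivity or surface tension vs concentration: a two-segment
  linear model is fitted over a grid of candidate breakpoints and compared
  with a single line by an F-test; the breakpoint is the micellisation onset,
  and the ratio of slopes gives the fraction of counterions binding to the
  micelle (1 - S2/S1).  Surface-tension curves are analysed against
  log10(concentration), the conventional gamma-log c treatment.

Both fits are deterministic: identical input data give identical results.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MeasurementCurve",
    "SigmoidFit",
    "BreakpointFit",
    "FitError",
    "boltzmann",
    "fit_boltzmann",
    "fit_breakpoint",
    "load_curve_csv",
]

CURVE_KINDS = ("titration", "conductivity", "tension")


class FitError(RuntimeError):
    """A curve fit could not be performed or did not converge."""


@dataclass
class MeasurementCurve:
    """A (concentration, response) series.

    ``x`` is in mM and must be strictly increasing and positive; ``y`` is the
    I1/I3 ratio (titration), specific conductivity in uS/cm (conductivity) or
    surface tension in mN/m (tension).  ``truth`` holds the generating
    parameters when the curve is synthetic.
    """

    x: np.ndarray
    y: np.ndarray
    kind: str
    truth: Optional[dict] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.kind not in CURVE_KINDS:
            raise ValueError(f"kind must be one of {CURVE_KINDS}")
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(self.x) < 6:
            raise ValueError("a measurement curve needs at least 6 points")
        if np.any(self.x <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("concentrations must be strictly increasing")

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class SigmoidFit:
    """Boltzmann sigmoid fit y = a_low + (a_high - a_low)/(1 + exp((x-x0)/dx)).

    ``a_high`` is the plateau approached at low concentration (the aqueous
    I1/I3 level), ``a_low`` the micellar plateau at high concentration;
    ``cmc`` equals the inflection ``x0``.
    """

    a_low: float
    a_high: float
    x0: float
    dx: float
    rss: float

    @property
    def cmc(self) -> float:
        return self.x0

    def to_dict(self) -> dict:
        return {
            "model": "boltzmann",
            "a_low": self.a_low,
            "a_high": self.a_high,
            "x0_mM": self.x0,
            "dx_mM": self.dx,
            "cmc_mM": self.cmc,
            "rss": self.rss,
        }


@dataclass(frozen=True)
class BreakpointFit:
    """Segmented-line fit of a conductivity/tension curve.

    When ``has_breakpoint`` is false the breakpoint and binding fraction are
    absent (None): the curve is statistically indistinguishable from a single
    line, the verdict for a micelle whose surface charge is not neutralised
    by counterions.
    """

    has_breakpoint: bool
    breakpoint: Optional[float]
    slope_pre: float
    slope_post: float
    binding_fraction: Optional[float]
    rss_segmented: float
    rss_linear: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "model": "segmented_line",
            "has_breakpoint": self.has_breakpoint,
            "breakpoint_mM": self.breakpoint,
            "slope_pre": self.slope_pre,
            "slope_post": self.slope_post,
            "binding_fraction": self.binding_fraction,
            "rss_segmented": self.rss_segmented,
            "rss_linear": self.rss_linear,
            "p_value": self.p_value,
        }


def boltzmann(x, a_low: float, a_high: float, x0: float, dx: float):
    """Boltzmann sigmoid; tends to a_high for x << x0, a_low for x >> x0."""
    x = np.asarray(x, dtype=float)
    return a_low + (a_high - a_low) / (1.0 + np.exp((x - x0) / dx))


def fit_boltzmann(curve: MeasurementCurve) -> SigmoidFit:
    """Least-squares Boltzmann fit of a fluorimetric titration curve.

    Initial guesses are data-driven: plateaus from the first/last quartile
    means, ``x0`` from the steepest finite-difference point.  Warns if the
    response rises overall (a titration curve is expected to fall through the
    micellisation transition).
    """
    if curve.kind != "titration":
        raise FitError(f"fit_boltzmann expects a titration curve, got {curve.kind}")
    x, y = curve.x, curve.y
    q = max(2, len(x) // 4)
    a_high0 = float(np.mean(y[:q]))
    a_low0 = float(np.mean(y[-q:]))
    if a_low0 > a_high0:
        warnings.warn(
            "titration response increases overall; unexpected orientation",
            stacklevel=2,
        )
    slopes = np.diff(y) / np.diff(x)
    x0_0 = float(0.5 * (x[:-1] + x[1:])[np.argmin(slopes)])
    dx0 = max((x[-1] - x[0]) / 20.0, 1e-3)
    try:
        popt, _ = optimize.curve_fit(
            boltzmann,
            x,
            y,
            p0=(a_low0, a_high0, x0_0, dx0),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"Boltzmann fit did not converge: {exc}") from exc
    a_low, a_high, x0, dx = (float(v) for v in popt)
    if dx < 0:  # sign flip swaps the plateaus; canonicalise to dx > 0
        a_low, a_high, dx = a_high, a_low, -dx
    rss = float(np.sum((y - boltzmann(x, a_low, a_high, x0, dx)) ** 2))
    if not np.isfinite(rss):
        raise FitError("Boltzmann fit diverged (non-finite residual)")
    return SigmoidFit(a_low=a_low, a_high=a_high, x0=x0, dx=dx, rss=rss)


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and RSS of an ordinary least-squares line."""
    slope, intercept = np.polyfit(x, y, 1)
    rss = float(np.sum((y - (slope * x + intercept)) ** 2))
    return float(slope), float(intercept), rss


def fit_breakpoint(
    curve: MeasurementCurve,
    alpha: float = 0.05,
    min_slope_change: float = 0.05,
    min_points_per_side: int = 3,
) -> BreakpointFit:
    """Segmented two-line fit with an F-test against a single line.

    Every interior data abscissa and every midpoint between neighbours is a
    candidate split; each side of a candidate must keep at least
    ``min_points_per_side`` points.  The segmented model is accepted only if
    the F-test improvement is significant at ``alpha`` AND the slope ratio
    differs from 1 by more than ``min_slope_change``; the reported breakpoint
    is the intersection of the two fitted lines.
    """
    if curve.kind not in ("conductivity", "tension"):
        raise FitError(
            f"fit_breakpoint expects conductivity or tension, got {curve.kind}"
        )
    # gamma-log c convention for tensiometry
    x = np.log10(curve.x) if curve.kind == "tension" else curve.x.copy()
    y = curve.y
    n = len(x)
    interior = x[1:-1]
    candidates = np.unique(np.concatenate([interior, 0.5 * (x[:-1] + x[1:])]))
    best = None
    for c in candidates:
        left = x <= c
        right = ~left
        if left.sum() < min_points_per_side or right.sum() < min_points_per_side:
            continue
        s1, b1, r1 = _ols_line(x[left], y[left])
        s2, b2, r2 = _ols_line(x[right], y[right])
        rss = r1 + r2
        if best is None or rss < best[0]:
            best = (rss, c, s1, b1, s2, b2)
    if best is None:
        raise FitError(
            f"too few points ({n}) to place {min_points_per_side} on each side "
            "of any candidate breakpoint"
        )
    rss_seg, c_best, s1, b1, s2, b2 = best
    _, _, rss_lin = _ols_line(x, y)

    # F-test of the 4-parameter segmented model against the 2-parameter line
    dof = n - 4
    scale = float(np.sum((y - y.mean()) ** 2)) + 1e-300
    if rss_seg / scale < 1e-14:  # numerically perfect segmented fit
        p_value = 0.0 if (rss_lin - rss_seg) / scale > 1e-12 else 1.0
    else:
        fstat = ((rss_lin - rss_seg) / 2.0) / (rss_seg / dof)
        p_value = float(stats.f.sf(fstat, 2, dof))

    slope_ratio = s2 / s1 if s1 != 0 else np.inf
    significant = p_value < alpha and abs(slope_ratio - 1.0) > min_slope_change

    if significant:
        if s1 != s2:
            bp = (b2 - b1) / (s1 - s2)
            if not (x[0] <= bp <= x[-1]):
                bp = c_best
        else:
            bp = c_best
        if curve.kind == "tension":
            bp = 10.0**bp
        binding = float(np.clip(1.0 - slope_ratio, 0.0, 1.0))
        return BreakpointFit(
            has_breakpoint=True,
            breakpoint=float(bp),
            slope_pre=s1,
            slope_post=s2,
            binding_fraction=binding,
            rss_segmented=rss_seg,
            rss_linear=rss_lin,
            p_value=p_value,
        )
    slope_all, _, _ = _ols_line(x, y)
    return BreakpointFit(
        has_breakpoint=False,
        breakpoint=None,
        slope_pre=slope_all,
        slope_post=slope_all,
        binding_fraction=None,
        rss_segmented=rss_seg,
        rss_linear=rss_lin,
        p_value=p_value,
    )


def load_curve_csv(path: str | Path, kind: str) -> MeasurementCurve:
    """Read a curve CSV with columns concentration_mM, response."""
    df = pd.read_csv(path, comment="#")
    missing = {"concentration_mM", "response"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return MeasurementCurve(
        x=df["concentration_mM"].to_numpy(),
        y=df["response"].to_numpy(),
        kind=kind,
    )


def fit_result_to_json(fit: SigmoidFit | BreakpointFit, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2) + "\n")
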
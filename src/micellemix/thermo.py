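"""Regular-solution-theory analysis of binary mixed micellisation.

For a binary surfactant mixture with bulk mole fractions ``alpha1``/``1-alpha1``
and pure-component critical micelle concentrations ``cmc1``/``cmc2``, ideal
mixing predicts (Clint)

    1 / cmc_id = alpha1 / cmc1 + (1 - alpha1) / cmc2.

Rubingh's regular-solution treatment of the mixed micelle yields the micellar
mole fraction ``x1`` of component 1 as the root of

    x1^2 ln(alpha1 cmc_mix / (x1 cmc1))
        = (1 - x1)^2 ln((1 - alpha1) cmc_mix / ((1 - x1) cmc2)),

and the dimensionless interaction parameter

    beta12 = ln(alpha1 cmc_mix / (x1 cmc1)) / (1 - x1)^2.

``beta12 < 0`` signals synergism: net attraction between the unlike
surfactants making the mixed micelle more stable than the ideal one.  For the
NaCA/SDS system component 1 is sodium cholate (the more hydrophobic unit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "MixtureRecord",
    "RubinghResult",
    "ThermoError",
    "NoPhysicalSolutionError",
    "clint_ideal_cmc",
    "rubingh_x1",
    "rubingh_residual",
    "interaction_parameter",
    "analyze_mixture_table",
    "load_mixture_table",
    "analyze_mixture_csv",
    "reference_cmc_table_path",
]

_BRACKET_EPS = 1e-9
_RESIDUAL_TOL = 1e-10


class ThermoError(ValueError):
    """Invalid input to a mixed-micelle computation."""


class NoPhysicalSolutionError(ThermoError):
    """The Rubingh equation has no root in (0, 1) for these inputs."""


@dataclass(frozen=True)
class MixtureRecord:
    """Measured cmc inputs for one temperature.

    All concentrations in mM; ``alpha1`` is the bulk mole fraction of
    component 1 (NaCA).  ``uncertainties`` carries the printed +- values as
    metadata; they are not propagated.
    """

    temperature_c: float
    cmc1: float
    cmc2: float
    cmc_mix: float
    alpha1: float
    uncertainties: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for name in ("cmc1", "cmc2", "cmc_mix"):
            if not getattr(self, name) > 0:
                raise ThermoError(f"{name} must be strictly positive")
        if not 0 < self.alpha1 < 1:
            raise ThermoError("alpha1 must lie in (0, 1) for a binary mixture")


@dataclass(frozen=True)
class RubinghResult:
    """Derived quantities for one temperature."""

    temperature_c: float
    cmc_ideal: float
    x1: float
    beta12: float

    @property
    def synergistic(self) -> bool:
        return self.beta12 < 0


def clint_ideal_cmc(alpha1: float, cmc1: float, cmc2: float) -> float:
    """Ideal (Clint) cmc of the binary mixture, in mM."""
    if not (cmc1 > 0 and cmc2 > 0):
        raise ThermoError("pure-component cmc values must be strictly positive")
    if not 0 <= alpha1 <= 1:
        raise ThermoError("alpha1 must lie in [0, 1]")
    return 1.0 / (alpha1 / cmc1 + (1.0 - alpha1) / cmc2)


def rubingh_residual(
    x1: float, alpha1: float, cmc1: float, cmc2: float, cmc_mix: float
):
    """Residual of the Rubingh implicit equation; zero at the physical root."""
    x1 = np.asarray(x1, dtype=float)
    t1 = x1**2 * np.log(alpha1 * cmc_mix / (x1 * cmc1))
    t2 = (1 - x1) ** 2 * np.log((1 - alpha1) * cmc_mix / ((1 - x1) * cmc2))
    return t1 - t2


def rubingh_x1(alpha1: float, cmc1: float, cmc2: float, cmc_mix: float) -> float:
    """Micellar mole fraction of component 1 from Rubingh's equation.

    Solved by Brent's bracketed root search on (0, 1); the returned root has
    absolute residual below 1e-10.  Raises
    :class:`NoPhysicalSolutionError` if the residual does not change sign in
    the bracket and :class:`ThermoError` on non-convergence.
    """
    for name, v in (("cmc1", cmc1), ("cmc2", cmc2), ("cmc_mix", cmc_mix)):
        if not v > 0:
            raise ThermoError(f"{name} must be strictly positive")
    if not 0 < alpha1 < 1:
        raise ThermoError("alpha1 must lie in (0, 1)")

    def f(x: float) -> float:
        return float(rubingh_residual(x, alpha1, cmc1, cmc2, cmc_mix))

    lo, hi = _BRACKET_EPS, 1.0 - _BRACKET_EPS
    flo, fhi = f(lo), f(hi)
    if not (np.isfinite(flo) and np.isfinite(fhi)) or flo * fhi > 0:
        raise NoPhysicalSolutionError(
            "no physical solution: the Rubingh residual does not change sign "
            f"on ({lo:g}, {hi:g}) for alpha1={alpha1}, cmc1={cmc1}, "
            f"cmc2={cmc2}, cmc_mix={cmc_mix}"
        )
    root, res = brentq(f, lo, hi, xtol=1e-14, rtol=1e-15, maxiter=200,
                       full_output=True)
    if not res.converged:
        raise ThermoError("Rubingh root search did not converge")
    if abs(f(root)) > _RESIDUAL_TOL:
        raise ThermoError(
            f"Rubingh root residual {f(root):.3g} exceeds tolerance"
        )
    return float(root)


def interaction_parameter(
    alpha1: float, cmc_mix: float, cmc1: float, x1: float
) -> float:
    """Rubingh interaction parameter beta_{1,2} (dimensionless)."""
    for name, v in (("alpha1", alpha1), ("cmc_mix", cmc_mix), ("cmc1", cmc1)):
        if not v > 0:
            raise ThermoError(f"{name} must be strictly positive")
    if not 0 < x1 < 1:
        raise ThermoError("x1 must lie strictly inside (0, 1)")
    return math.log(alpha1 * cmc_mix / (x1 * cmc1)) / (1.0 - x1) ** 2


def analyze_mixture_table(records: list[MixtureRecord]) -> list[RubinghResult]:
    """Chain Clint -> Rubingh -> interaction parameter for each record."""
    if not records:
        raise ThermoError("no mixture records supplied")
    out: list[RubinghResult] = []
    for rec in records:
        try:
            cmc_id = clint_ideal_cmc(rec.alpha1, rec.cmc1, rec.cmc2)
            x1 = rubingh_x1(rec.alpha1, rec.cmc1, rec.cmc2, rec.cmc_mix)
            beta = interaction_parameter(rec.alpha1, rec.cmc_mix, rec.cmc1, x1)
        except ThermoError as exc:
            raise ThermoError(
                f"record at {rec.temperature_c} degC: {exc}"
            ) from exc
        out.append(RubinghResult(rec.temperature_c, cmc_id, x1, beta))
    return out


# ---------------------------------------------------------------------------
# table I/O

_CSV_COLUMNS = ["temperature_C", "cmc1_mM", "cmc2_mM", "cmc_mix_mM", "alpha1"]


def load_mixture_table(path: str | Path) -> list[MixtureRecord]:
    """Read mixture records from CSV (columns: temperature_C, cmc1_mM,
    cmc2_mM, cmc_mix_mM, alpha1)."""
    df = pd.read_csv(path, comment="#")
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ThermoError(f"{path}: missing columns {sorted(missing)}")
    return [
        MixtureRecord(
            temperature_c=float(r.temperature_C),
            cmc1=float(r.cmc1_mM),
            cmc2=float(r.cmc2_mM),
            cmc_mix=float(r.cmc_mix_mM),
            alpha1=float(r.alpha1),
        )
        for r in df.itertuples()
    ]


def analyze_mixture_csv(path: str | Path) -> pd.DataFrame:
    """Load a mixture CSV and append cmc_ideal_mM, x1 and beta12 columns."""
    records = load_mixture_table(path)
    results = analyze_mixture_table(records)
    df = pd.read_csv(path, comment="#")
    df["cmc_ideal_mM"] = [r.cmc_ideal for r in results]
    df["x1"] = [r.x1 for r in results]
    df["beta12"] = [r.beta12 for r in results]
    return df


def reference_cmc_table_path() -> Path:
    """Path of the packaged temperature-dependent cmc dataset for the
    equimolar NaCA-SDS system (fluorimetric values, 0-50 degC)."""
    return Path(
        resources.files("micellemix").joinpath("data/naca_sds_cmc.csv")
    )
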
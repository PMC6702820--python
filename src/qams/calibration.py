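"""Standard-solution dilution arithmetic, calibration curves, LOD/LOQ.

The assay prepares two methanolic stock solutions (one for physcion, one
for the two glucosides), then mixes fixed aliquots of both into seven
volumetric flasks to obtain a 7-level standard series.
:func:`build_dilution_series` reproduces that bookkeeping from an explicit
recipe by conservation of mass: nothing an analyst does at the bench can
create analyte, so ``C_out = sum(C_source * v_aliquot) / V_final``.

Calibration curves regress peak area on injected amount (µg), so a curve
fitted at one injection volume remains valid at another. Detection limits
default to the pharmacopoeial signal-to-noise convention (S/N = 3 and 10);
a curve-based alternative using the intercept standard error is available
because the raw baseline noise of the published assay is not reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import FitError, RecipeError, ValidationError
from .peakio import StandardSolution

__all__ = [
    "DilutionStep",
    "CalibrationCurve",
    "DetectionLimits",
    "build_dilution_series",
    "reference_control_series",
    "fit_curve",
    "estimate_limits",
]


@dataclass(frozen=True)
class DilutionStep:
    """One aliquot drawn from a named source into a volumetric flask."""

    source: str
    aliquot_volume: float  # mL drawn from source
    final_volume: float  # mL of the receiving flask

    def __post_init__(self) -> None:
        if not self.aliquot_volume >= 0:
            raise ValidationError("aliquot_volume must be >= 0 mL")
        if not self.final_volume > 0:
            raise ValidationError("final_volume must be > 0 mL")


def build_dilution_series(
    stocks: Mapping[str, StandardSolution],
    recipes: Mapping[str, Sequence[DilutionStep]],
    ) -> dict[str, StandardSolution]:
    """Compute solution concentrations for a chain of dilution recipes.

    ``recipes`` maps each output label to the aliquot steps filling one
    flask; all steps of a recipe must agree on the flask volume, and the
    aliquots must fit in it. Recipes are evaluated in insertion order and
    may draw from earlier outputs as well as from ``stocks``.
    """
    pool: dict[str, StandardSolution] = dict(stocks)
    out: dict[str, StandardSolution] = {}
    for label, steps in recipes.items():
        if not steps:
            raise RecipeError(f"recipe {label!r} has no steps")
        final_volumes = {s.final_volume for s in steps}
        if len(final_volumes) != 1:
            raise RecipeError(
                f"recipe {label!r}: steps disagree on flask volume "
                f"{sorted(final_volumes)}"
            )
        (v_final,) = final_volumes
        total_aliquot = sum(s.aliquot_volume for s in steps)
        if total_aliquot > v_final + 1e-12:
            raise RecipeError(
                f"recipe {label!r}: aliquots ({total_aliquot} mL) exceed "
                f"flask volume ({v_final} mL)"
            )
        masses: dict[str, float] = {}
        for s in steps:
            if s.source not in pool:
                raise RecipeError(
                    f"recipe {label!r}: unknown source {s.source!r}"
                )
            for analyte, conc in pool[s.source].concentrations.items():
                masses[analyte] = masses.get(analyte, 0.0) + conc * s.aliquot_volume
        sol = StandardSolution(
            {a: m / v_final for a, m in masses.items()}, label=label
        )
        pool[label] = sol
        out[label] = sol
    return out


def reference_control_series(
    physcion_mg: float = 10.08,
    emodin_glc_mg: float = 7.20,
    physcion_glc_mg: float = 9.92,
    stock_volume_ml: float = 100.0,
    emodin_stock: StandardSolution | None = None,
) -> dict[str, StandardSolution]:
    """The assay's 7-level control series from its two documented stocks.

    Stock 1 dissolves ``physcion_mg`` of physcion in ``stock_volume_ml`` mL
    methanol; stock 2 dissolves both glucosides. The published recipe does
    not state an emodin stock, so the reference analyte can be supplied as
    ``emodin_stock`` and is then co-diluted with the same aliquot scheme.
    Returns labels ``No.1`` .. ``No.7``.
    """
    from .analytes import EMODIN_GLC, PHYSCION, PHYSCION_GLC

    stocks = {
        "stock1": StandardSolution(
            {PHYSCION: physcion_mg / stock_volume_ml}, label="stock1"
        ),
        "stock2": StandardSolution(
            {
                EMODIN_GLC: emodin_glc_mg / stock_volume_ml,
                PHYSCION_GLC: physcion_glc_mg / stock_volume_ml,
            },
            label="stock2",
        ),
    }
    sources = ["stock1", "stock2"]
    if emodin_stock is not None:
        stocks["stock3"] = emodin_stock
        sources.append("stock3")
    # (aliquot mL per stock, flask mL) for solutions No.1 .. No.7
    scheme = [(1, 50), (2, 50), (2, 25), (1, 10), (2, 10), (2, 5), (5, 100)]
    recipes = {
        f"No.{i}": [DilutionStep(src, aliquot, flask) for src in sources]
        for i, (aliquot, flask) in enumerate(scheme, start=1)
    }
    return build_dilution_series(stocks, recipes)


@dataclass(frozen=True)
class CalibrationCurve:
    """Ordinary least-squares line: area = slope * amount(µg) + intercept."""

    analyte: str
    slope: float
    intercept: float
    r: float
    amount_range: tuple[float, float]  # µg, fitted span
    intercept_sd: float = float("nan")
    n: int = 0

    def predict_area(self, amount_ug: float) -> float:
        return self.slope * amount_ug + self.intercept

    def in_range(self, amount_ug: float) -> bool:
        lo, hi = self.amount_range
        return lo <= amount_ug <= hi


def fit_curve(
    points: Sequence[tuple[float, float]], analyte: str = ""
) -> CalibrationCurve:
    """Fit an unweighted OLS calibration line to (amount µg, area) points.

    Requires at least three distinct amounts; ``r`` is the Pearson
    correlation of the fit points.
    """
    if len(points) < 3:
        raise FitError(f"need >= 3 calibration points, got {len(points)}")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if len(np.unique(x)) < 3 or np.ptp(x) == 0:
        raise FitError("need >= 3 distinct amounts with nonzero spread")
    res = stats.linregress(x, y)
    return CalibrationCurve(
        analyte=analyte,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        amount_range=(float(x.min()), float(x.max())),
        intercept_sd=float(res.intercept_stderr),
        n=len(points),
    )


@dataclass(frozen=True)
class DetectionLimits:
    """Limit of detection / quantification in µg injected."""

    lod: float
    loq: float
    method: str  # "snr" | "curve-sd"

    def __post_init__(self) -> None:
        if not (0 < self.lod < self.loq):
            raise ValidationError(
                f"require 0 < lod < loq, got lod={self.lod}, loq={self.loq}"
            )


def estimate_limits(
    noise: float, curve: CalibrationCurve, method: str = "snr"
) -> DetectionLimits:
    """Estimate LOD/LOQ from baseline noise or the curve's intercept scatter.

    ``snr`` (default): LOD = 3·noise/slope, LOQ = 10·noise/slope, with
    ``noise`` the peak-to-peak baseline noise in area units; LOQ/LOD is
    exactly 10/3. ``curve-sd``: 3.3 and 10 times the intercept standard
    error over the slope (``noise`` is ignored).
    """
    if not curve.slope > 0:
        raise ValidationError("calibration slope must be > 0")
    if method == "snr":
        if not noise > 0:
            raise ValidationError("baseline noise must be > 0")
        return DetectionLimits(3 * noise / curve.slope, 10 * noise / curve.slope, "snr")
    if method == "curve-sd":
        s = curve.intercept_sd
        if not s > 0 or np.isnan(s):
            raise ValidationError("curve has no positive intercept standard error")
        return DetectionLimits(3.3 * s / curve.slope, 10 * s / curve.slope, "curve-sd")
    raise ValidationError(f"unknown LOD/LOQ method {method!r}")
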
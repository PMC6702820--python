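"""Synthetic chromatograms, steaming kinetics and cohorts with known truth.

Every statistical claim in this package is testable against simulated data
whose ground truth is known exactly. The generator mimics the four-analyte
assay: a linear detector (area = response factor × injected amount, µg)
with multiplicative Gaussian area noise, Gaussian retention-time jitter
around fixed centres chosen so the default relative retention times are
1.00 (emodin), 1.06 (physcion), 0.47 and 0.60 (the glucosides).

Steaming is modelled as first-order conversion of each glucoside into its
aglycone. The real process chemistry is only known in direction (glucosides
fall, aglycones rise, F saturates low); exponential decay is the simplest
form with those properties and is a configurable stand-in, not a mechanistic
claim. ``yield_fraction`` converts glucoside mass into aglycone mass (the
aglycone is lighter by one sugar: emodin/emodin-glucoside ≈ 0.63 by mass);
``loss`` lets aglycones themselves degrade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .analytes import AGLYCONES, GLYCOSIDES
from .core import ContentResult
from .errors import ValidationError
from .peakio import Peak, PeakTable, RunMeta, StandardSolution

__all__ = [
    "GeneratorConfig",
    "KineticsConfig",
    "make_control_run",
    "make_sample_run",
    "simulate_steaming",
    "fit_conversion_rate",
    "generate_cohort",
    "CohortSample",
]

#: glucoside -> aglycone pairing used by the kinetics
_PAIRS = dict(zip(GLYCOSIDES, AGLYCONES))

#: aglycone/glucoside molar-mass ratio (sugar loss on hydrolysis)
MASS_YIELD = 0.63


def _default_response_factors() -> dict[str, float]:
    # area units per µg; ratios to emodin equal the published correction
    # factors so a noise-free control run inverts to exactly those values
    return {
        "emodin": 1000.0,
        "physcion": 1090.0,
        "emodin-8-O-glc": 440.0,
        "physcion-8-O-glc": 490.0,
    }


def _default_contents() -> dict[str, float]:
    # mg/g; the measured mass fractions of the repeatability batch
    return {
        "emodin": 4.256,
        "physcion": 1.502,
        "emodin-8-O-glc": 2.008,
        "physcion-8-O-glc": 0.679,
    }


def _default_rt_centers() -> dict[str, float]:
    # minutes; arbitrary but fixed so RRTs are 1.00/1.06/0.47/0.60
    return {
        "emodin": 15.0,
        "physcion": 15.9,
        "emodin-8-O-glc": 7.05,
        "physcion-8-O-glc": 9.0,
    }


@dataclass
class GeneratorConfig:
    """Ground truth and noise model for synthetic runs.

    ``response_factors`` (area/µg) encode the true correction factors as
    ratios to the reference; ``area_noise_cv`` is the coefficient of
    variation of the multiplicative area noise; ``rt_jitter_sd`` the sd of
    additive retention-time jitter in minutes. A fixed ``seed`` makes
    output bit-reproducible.
    """

    response_factors: dict[str, float] = field(default_factory=_default_response_factors)
    true_contents: dict[str, float] = field(default_factory=_default_contents)
    rt_centers: dict[str, float] = field(default_factory=_default_rt_centers)
    rt_jitter_sd: float = 0.02
    area_noise_cv: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.response_factors.values()):
            raise ValidationError("response factors must be > 0")
        if any(v < 0 for v in self.true_contents.values()):
            raise ValidationError("true contents must be >= 0")
        if self.rt_jitter_sd < 0 or self.area_noise_cv < 0:
            raise ValidationError("noise parameters must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _noisy_area(
    amount_ug: float, rf: float, cv: float, rng: np.random.Generator
) -> float:
    area = rf * amount_ug
    if cv > 0:
        area *= 1.0 + cv * rng.standard_normal()
    return max(area, 0.0)


def _jittered_rt(center: float, sd: float, rng: np.random.Generator) -> float:
    rt = center
    if sd > 0:
        rt += sd * rng.standard_normal()
    return max(rt, 1e-6)


def make_control_run(
    config: GeneratorConfig,
    standard: StandardSolution,
    injection_ul: float = 10.0,
    rng: np.random.Generator | None = None,
    sample_id: str = "control",
    labeled: bool = True,
    instrument_id: str = "",
    column_id: str = "",
) -> PeakTable:
    """Simulate a chromatogram of a standard mix.

    Areas are ``response_factor × concentration × injection ± noise``; at
    zero noise, computing factors from the output recovers the configured
    response-factor ratios exactly.
    """
    rng = rng if rng is not None else config.rng()
    peaks = []
    for analyte, conc in standard.concentrations.items():
        if conc <= 0:
            continue
        if analyte not in config.response_factors:
            raise ValidationError(f"no response factor configured for {analyte!r}")
        amount_ug = conc * injection_ul  # mg/mL × µL = µg
        peaks.append(
            Peak(
                rt=_jittered_rt(
                    config.rt_centers[analyte], config.rt_jitter_sd, rng
                ),
                area=_noisy_area(
                    amount_ug, config.response_factors[analyte],
                    config.area_noise_cv, rng,
                ),
                analyte=analyte if labeled else None,
            )
        )
    meta = RunMeta(
        injection_volume=injection_ul,
        instrument_id=instrument_id,
        column_id=column_id,
    )
    return PeakTable(peaks=peaks, meta=meta, standard=standard, sample_id=sample_id)


def make_sample_run(
    config: GeneratorConfig,
    meta: RunMeta,
    rng: np.random.Generator | None = None,
    sample_id: str = "sample",
    labeled: bool = True,
) -> PeakTable:
    """Simulate a chromatogram of an extracted drug sample.

    The injected concentration of each analyte is
    ``content × mass / (extraction_volume × dilution)``; quantifying the
    output at zero noise recovers ``config.true_contents`` exactly.
    """
    if meta.sample_mass is None:
        raise ValidationError("sample runs need a sample_mass")
    rng = rng if rng is not None else config.rng()
    peaks = []
    for analyte, content in config.true_contents.items():
        if content <= 0:
            continue
        conc = content * meta.sample_mass / (
            meta.extraction_volume * meta.dilution_factor
        )  # mg/mL
        amount_ug = conc * meta.injection_volume
        peaks.append(
            Peak(
                rt=_jittered_rt(
                    config.rt_centers[analyte], config.rt_jitter_sd, rng
                ),
                area=_noisy_area(
                    amount_ug, config.response_factors[analyte],
                    config.area_noise_cv, rng,
                ),
                analyte=analyte if labeled else None,
            )
        )
    return PeakTable(peaks=peaks, meta=meta, standard=None, sample_id=sample_id)


@dataclass
class KineticsConfig:
    """First-order steaming kinetics.

    ``k`` is the conversion rate (h⁻¹) of each glucoside, a scalar or a
    per-glucoside mapping; ``yield_fraction`` the mass fraction of converted
    glucoside appearing as aglycone; ``loss`` a first-order degradation rate
    for aglycones. ``times`` is the sampling grid in hours.
    """

    k: float | Mapping[str, float] = 0.35
    yield_fraction: float = MASS_YIELD
    loss: float = 0.0
    times: Sequence[float] = (0.0, 2.0, 4.0, 6.0, 8.0, 12.0, 16.0, 24.0)

    def __post_init__(self) -> None:
        if not 0 <= self.yield_fraction <= 1:
            raise ValidationError("yield_fraction must be in [0, 1]")
        if self.loss < 0:
            raise ValidationError("loss rate must be >= 0")
        for g in GLYCOSIDES:
            if self.rate(g) < 0:
                raise ValidationError("conversion rates must be >= 0")
        times = tuple(float(t) for t in self.times)
        if any(t < 0 for t in times):
            raise ValidationError("times must be >= 0 h")
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValidationError("times must be strictly increasing")
        self.times = times

    def rate(self, glycoside: str) -> float:
        if isinstance(self.k, Mapping):
            return float(self.k.get(glycoside, 0.0))
        return float(self.k)


def steaming_contents(
    initial: Mapping[str, float], kin: KineticsConfig, t: float
) -> dict[str, float]:
    """Closed-form contents at steaming time ``t`` (h).

    ``C_glc(t) = C_glc(0)·e^(−k t)``;
    ``C_agly(t) = C_agly(0)·e^(−loss t) + y·C_glc(0)·(1 − e^(−k t))``.
    """
    out: dict[str, float] = {}
    for glc, agly in _PAIRS.items():
        k = kin.rate(glc)
        c_g0 = initial.get(glc, 0.0)
        c_a0 = initial.get(agly, 0.0)
        out[glc] = c_g0 * math.exp(-k * t)
        out[agly] = c_a0 * math.exp(-kin.loss * t) + kin.yield_fraction * c_g0 * (
            1.0 - math.exp(-k * t)
        )
    return out


def simulate_steaming(
    config: GeneratorConfig,
    kin: KineticsConfig,
    batch: str = "synthetic",
) -> list[tuple[float, ContentResult]]:
    """Generate (time, contents) rows for a steaming series.

    Contents start from ``config.true_contents`` and follow the first-order
    kinetics noiselessly (measurement noise belongs to the chromatogram
    generators, not the process model). With ``loss = 0`` and positive
    rates, F is strictly decreasing and tends to 0.
    """
    rows = []
    for t in kin.times:
        contents = steaming_contents(config.true_contents, kin, t)
        rows.append(
            (
                t,
                ContentResult(
                    sample_id=f"{batch} ({t:g} h)",
                    method="synthetic",
                    contents=contents,
                ),
            )
        )
    return rows


def fit_conversion_rate(
    times: Sequence[float],
    glycoside_contents: Sequence[float],
) -> float:
    """Recover a first-order rate by least squares on log contents.

    ``ln C(t) = ln C(0) − k t`` is linear in t, so an OLS line through the
    log series returns k exactly on noiseless data.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(glycoside_contents, dtype=float)
    if len(t) < 2 or len(t) != len(c):
        raise ValidationError("need aligned series of >= 2 points")
    if np.any(c <= 0):
        raise ValidationError("contents must be > 0 to fit a log-linear rate")
    slope = np.polyfit(t, np.log(c), 1)[0]
    return float(-slope)


@dataclass(frozen=True)
class CohortSample:
    """One synthetic market sample with its generating truth."""

    content: ContentResult
    true_f: float
    true_label: str


#: (band probabilities, per-band F ranges) matching the market survey:
#: most declared processed product is qualified, a small tail is not.
_PREAPARATA_BANDS = (
    (88 / 106, (0.02, 0.60)),   # qualified
    (8 / 106, (0.61, 0.99)),    # incompletely processed
    (10 / 106, (1.0, 5.6)),     # crude-like
)
_RADIX_BANDS = ((1.0, (1.0, 10.0)),)  # crude drug: F spans 1–10


def _draw_f(bands, rng: np.random.Generator) -> float:
    probs = np.array([b[0] for b in bands])
    idx = rng.choice(len(bands), p=probs / probs.sum())
    lo, hi = bands[idx][1]
    return float(rng.uniform(lo, hi))


def generate_cohort(
    n_radix: int,
    n_preaparata: int,
    f_distributions: Mapping[str, Sequence] | None = None,
    seed: int = 0,
) -> list[CohortSample]:
    """Draw synthetic content profiles for two declared product types.

    Each sample's target F is drawn from per-type band mixtures (defaults
    mirror the two market populations: crude drug uniform on [1, 10];
    processed product mostly qualified with a small unqualified tail), then
    realised as four contents: an aglycone total lognormal around 1 mg/g
    split 3:1 emodin:physcion, glucosides ``F × total`` split likewise.
    The returned ``true_label`` is the band of the drawn F.
    """
    from .fvalue import classify, f_value  # local import to avoid a cycle

    if n_radix < 0 or n_preaparata < 0:
        raise ValidationError("cohort counts must be >= 0")
    bands = {"radix": _RADIX_BANDS, "preaparata": _PREAPARATA_BANDS}
    if f_distributions:
        bands.update(f_distributions)
    rng = np.random.default_rng(seed)
    cohort: list[CohortSample] = []
    for declared, n in (("radix", n_radix), ("preaparata", n_preaparata)):
        for i in range(n):
            f = _draw_f(bands[declared], rng)
            aglycone_total = float(rng.lognormal(mean=0.0, sigma=0.5))
            contents = {
                "emodin": 0.75 * aglycone_total,
                "physcion": 0.25 * aglycone_total,
                "emodin-8-O-glc": 0.75 * f * aglycone_total,
                "physcion-8-O-glc": 0.25 * f * aglycone_total,
            }
            result = ContentResult(
                sample_id=f"{declared}-{i + 1:03d}",
                method="synthetic",
                contents=contents,
            )
            label = classify(f_value(result)).label
            cohort.append(CohortSample(result, f, label))
    return cohort
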
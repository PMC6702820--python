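"""Method-validation statistics: precision, stability, repeatability, recovery.

These are the standard pharmacopoeial checks run before a quantification
method is trusted: replicate injections of one standard (precision, RSD
< 1 %), re-injection of one sample solution over 24 h (stability, RSD
< 2 %), parallel preparations of one powder (repeatability, on computed
contents), and spike recovery against a known added amount. RSD is always
the n−1 sample standard deviation as a percentage of the mean.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import ValidationError

__all__ = [
    "ReplicateSet",
    "RecoveryDesign",
    "rsd",
    "recovery",
    "recovery_summary",
    "stability_profile",
    "precision_profile",
    "PRECISION_RSD_LIMIT",
    "STABILITY_RSD_LIMIT",
]

PRECISION_RSD_LIMIT = 1.0  # % — replicate injections of one standard
STABILITY_RSD_LIMIT = 2.0  # % — one solution re-injected over 24 h


@dataclass(frozen=True)
class ReplicateSet:
    """Per-analyte replicate measurements (areas or contents).

    ``times`` (h) is present for stability series and must align with the
    per-analyte value lists.
    """

    label: str  # "precision" | "stability" | "repeatability"
    values: Mapping[str, Sequence[float]]
    times: Sequence[float] | None = None

    def __post_init__(self) -> None:
        values = {k: tuple(v) for k, v in self.values.items()}
        object.__setattr__(self, "values", values)
        for analyte, vals in values.items():
            if len(vals) < 2:
                raise ValidationError(
                    f"{self.label}: analyte {analyte!r} needs >= 2 replicates"
                )
            if self.times is not None and len(vals) != len(self.times):
                raise ValidationError(
                    f"{self.label}: analyte {analyte!r} has {len(vals)} values "
                    f"for {len(self.times)} times"
                )


@dataclass(frozen=True)
class RecoveryDesign:
    """Spike-recovery bookkeeping for one base sample.

    ``spike`` is the added amount per analyte in mg (spike concentration
    mg·mL⁻¹ × spiked volume mL); ``original`` the analyte amount already in
    the unspiked portion, mg.
    """

    base_mass: float  # g
    spike: Mapping[str, float]  # mg added
    original: Mapping[str, float]  # mg present before spiking

    def __post_init__(self) -> None:
        if not self.base_mass > 0:
            raise ValidationError("base_mass must be > 0 g")
        object.__setattr__(self, "spike", dict(self.spike))
        object.__setattr__(self, "original", dict(self.original))
        if any(v <= 0 for v in self.spike.values()):
            raise ValidationError("spiked amounts must be > 0 mg")


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation, %: 100 × sample sd / mean."""
    if len(values) < 2:
        raise ValidationError("rsd needs >= 2 values")
    mean = statistics.fmean(values)
    if mean == 0:
        raise ValidationError("rsd undefined for zero mean")
    return 100.0 * statistics.stdev(values) / mean


def recovery(
    found_total: Mapping[str, float], design: RecoveryDesign
) -> dict[str, float]:
    """Percent recovery per analyte: 100 × (found − original) / spiked."""
    out: dict[str, float] = {}
    for analyte, spike in design.spike.items():
        if analyte not in found_total:
            raise ValidationError(f"no found amount for spiked analyte {analyte!r}")
        original = design.original.get(analyte, 0.0)
        out[analyte] = 100.0 * (found_total[analyte] - original) / spike
    return out


def recovery_summary(
    replicates: Sequence[Mapping[str, float]], design: RecoveryDesign
) -> dict[str, dict[str, float]]:
    """Mean recovery and RSD across replicate spiked preparations.

    Returns ``{analyte: {"mean": %, "rsd": %}}``.
    """
    if len(replicates) < 2:
        raise ValidationError("recovery_summary needs >= 2 replicates")
    per_rep = [recovery(found, design) for found in replicates]
    out: dict[str, dict[str, float]] = {}
    for analyte in design.spike:
        recs = [r[analyte] for r in per_rep]
        out[analyte] = {"mean": statistics.fmean(recs), "rsd": rsd(recs)}
    return out


def _profile(
    replicates: ReplicateSet, limit: float
) -> dict[str, dict[str, float | bool]]:
    return {
        analyte: {"rsd": (r := rsd(vals)), "passed": r < limit}
        for analyte, vals in replicates.values.items()
    }


def precision_profile(
    replicates: ReplicateSet, limit: float = PRECISION_RSD_LIMIT
) -> dict[str, dict[str, float | bool]]:
    """Per-analyte RSD of replicate injections with the < 1 % pass rule."""
    return _profile(replicates, limit)


def stability_profile(
    replicates: ReplicateSet, limit: float = STABILITY_RSD_LIMIT
) -> dict[str, dict[str, float | bool]]:
    """Per-analyte RSD over a timed series with the < 2 % pass rule.

    Requires ``times`` covering >= 2 points (alignment is validated by
    :class:`ReplicateSet`).
    """
    if replicates.times is None or len(replicates.times) < 2:
        raise ValidationError("stability needs a time series of >= 2 points")
    return _profile(replicates, limit)
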
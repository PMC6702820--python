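"""Single-marker quantification: correction factors, RRT assignment, contents.

The method quantifies four anthraquinones against a single reference
standard (emodin). For each target analyte *m* a relative correction
factor is predetermined on control runs,

    f_km = (W_k * A_m) / (W_m * A_k),

where *k* is the reference, *W* the injected concentration (or mass) and
*A* the peak area. With a linear detector response ``A = r * W`` this is
just the response-factor ratio ``r_m / r_k``, so the factor is a property
of the analyte/detector pair, not of any one run. A sample run then needs
only the reference standard:

    C_m = A_m * C_k,std / (f_km * A_k,std)          (single-marker)
    C_m = A_m * C_m,std / A_m,std                   (external standard)

and content in mg per gram of drug follows from the extraction bookkeeping
``C_m * V_extract * dilution / mass``.

Peaks are identified by relative retention time (rt divided by the
reference peak's rt) within a closed ±5 % window; the durability of the
factors across injection volumes, instruments and columns is summarised as
per-analyte mean and relative standard deviation.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

from .analytes import EMODIN
from .errors import (
    AmbiguousPeakError,
    MissingPeakError,
    QamsError,
    ValidationError,
)
from .peakio import Peak, PeakTable
from .rounding import round_half_up

__all__ = [
    "CorrectionFactorSet",
    "DurabilityReport",
    "DurabilityStat",
    "ContentResult",
    "compute_factors",
    "assign_peaks",
    "quantify",
    "durability",
    "save_factor_set",
    "load_factor_set",
    "DEFAULT_RRT_TOLERANCE",
]

DEFAULT_RRT_TOLERANCE = 0.05
_RRT_EPS = 1e-12  # absorb float noise at the closed window boundary

#: published defaults for the four-analyte assay (reference emodin)
PUBLISHED_FACTORS = {"physcion": 1.09, "emodin-8-O-glc": 0.44, "physcion-8-O-glc": 0.49}
PUBLISHED_RRTS = {"physcion": 1.06, "emodin-8-O-glc": 0.47, "physcion-8-O-glc": 0.60}


@dataclass(frozen=True)
class CorrectionFactorSet:
    """Reference analyte plus per-analyte correction factors and RRTs.

    The reference maps to exactly 1.0 in both tables. ``per_run`` keeps the
    individual run values behind each mean so provenance is auditable.
    """

    reference: str
    factors: Mapping[str, float]
    rrts: Mapping[str, float]
    provenance: tuple[str, ...] = ()
    per_run: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        factors = dict(self.factors)
        rrts = dict(self.rrts)
        factors.setdefault(self.reference, 1.0)
        rrts.setdefault(self.reference, 1.0)
        if factors[self.reference] != 1.0 or rrts[self.reference] != 1.0:
            raise ValidationError("reference analyte must map to 1.0")
        if any(v <= 0 for v in factors.values()) or any(
            v <= 0 for v in rrts.values()
        ):
            raise ValidationError("factors and RRTs must be > 0")
        object.__setattr__(self, "factors", factors)
        object.__setattr__(self, "rrts", rrts)

    @property
    def targets(self) -> tuple[str, ...]:
        return tuple(a for a in self.factors if a != self.reference)

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Factors at presentation precision (values carried full precision)."""
        return {a: round_half_up(v, ndigits) for a, v in self.factors.items()}


def published_factor_set() -> CorrectionFactorSet:
    """The assay's published correction factors and RRTs (reference emodin)."""
    return CorrectionFactorSet(
        reference=EMODIN,
        factors=dict(PUBLISHED_FACTORS),
        rrts=dict(PUBLISHED_RRTS),
        provenance=("published",),
    )


def _require_peak(run: PeakTable, analyte: str) -> Peak:
    peak = run.peak_for(analyte)
    if peak is None:
        raise MissingPeakError(
            f"run {run.sample_id!r}: no assigned peak for {analyte!r}"
        )
    if peak.area == 0:
        raise MissingPeakError(
            f"run {run.sample_id!r}: zero area for {analyte!r}"
        )
    return peak


def compute_factors(
    control_runs: Sequence[PeakTable],
    reference: str = EMODIN,
    targets: Sequence[str] | None = None,
) -> CorrectionFactorSet:
    """Compute mean correction factors and RRTs from replicate control runs.

    Every run must carry a standard solution covering the reference and the
    targets, and assigned peaks for each. Per run,
    ``f_km = (W_k * A_m) / (W_m * A_k)`` and ``RRT_m = rt_m / rt_k``; the
    returned set stores the across-run means, with the reference forced to
    exactly 1.0.
    """
    if not control_runs:
        raise ValidationError("compute_factors: no control runs")
    per_run: dict[str, dict[str, float]] = {}
    per_run_rrt: dict[str, dict[str, float]] = {}
    target_set: Sequence[str] | None = list(targets) if targets else None
    for run in control_runs:
        if run.standard is None:
            raise ValidationError(
                f"run {run.sample_id!r} has no standard solution"
            )
        ref_peak = _require_peak(run, reference)
        w_k = run.standard.concentration(reference)
        if w_k <= 0:
            raise ValidationError(
                f"run {run.sample_id!r}: nonpositive reference concentration"
            )
        if target_set is None:
            target_set = [
                a
                for a, c in run.standard.concentrations.items()
                if a != reference and c > 0 and run.peak_for(a) is not None
            ]
        fs: dict[str, float] = {}
        rs: dict[str, float] = {}
        for analyte in target_set:
            peak = _require_peak(run, analyte)
            w_m = run.standard.concentration(analyte)
            if w_m <= 0:
                raise ValidationError(
                    f"run {run.sample_id!r}: nonpositive concentration for "
                    f"{analyte!r}"
                )
            fs[analyte] = (w_k * peak.area) / (w_m * ref_peak.area)
            rs[analyte] = peak.rt / ref_peak.rt
        per_run[run.sample_id] = fs
        per_run_rrt[run.sample_id] = rs
    assert target_set is not None
    factors = {
        a: statistics.fmean(per_run[r][a] for r in per_run) for a in target_set
    }
    rrts = {
        a: statistics.fmean(per_run_rrt[r][a] for r in per_run_rrt)
        for a in target_set
    }
    return CorrectionFactorSet(
        reference=reference,
        factors=factors,
        rrts=rrts,
        provenance=tuple(per_run),
        per_run=per_run,
    )


def assign_peaks(
    table: PeakTable,
    factors: CorrectionFactorSet,
    tolerance: float = DEFAULT_RRT_TOLERANCE,
) -> PeakTable:
    """Identify unassigned peaks by relative retention time.

    Each unassigned peak whose rt/rt_reference lies within the closed
    window ``rrt * (1 ± tolerance)`` of exactly one expected RRT is
    assigned to that analyte. A peak inside two windows is flagged
    ``"ambiguous"`` and left unassigned; two peaks competing for the same
    analyte raise :class:`AmbiguousPeakError`. The reference peak must
    already be assigned.
    """
    ref_peak = table.peak_for(factors.reference)
    if ref_peak is None:
        raise MissingPeakError(
            f"table {table.sample_id!r}: reference peak "
            f"({factors.reference!r}) not assigned"
        )
    expected = {
        a: rrt
        for a, rrt in factors.rrts.items()
        if a != factors.reference and table.peak_for(a) is None
    }
    candidates: dict[str, list[Peak]] = {a: [] for a in expected}
    decisions: dict[int, str | None] = {}
    flags: dict[int, str] = {}
    for idx, peak in enumerate(table.peaks):
        if peak.is_assigned:
            continue
        rrt_obs = peak.rt / ref_peak.rt
        matches = [
            a
            for a, rrt in expected.items()
            if abs(rrt_obs / rrt - 1.0) <= tolerance + _RRT_EPS
        ]
        if len(matches) == 1:
            candidates[matches[0]].append(peak)
            decisions[idx] = matches[0]
        elif len(matches) > 1:
            flags[idx] = "ambiguous"
    for analyte, plist in candidates.items():
        if len(plist) > 1:
            rts = ", ".join(f"{p.rt:.3f} min" for p in plist)
            raise AmbiguousPeakError(
                f"table {table.sample_id!r}: {len(plist)} peaks compete for "
                f"{analyte!r} (rt {rts})"
            )
    new_peaks = []
    for idx, peak in enumerate(table.peaks):
        if idx in decisions:
            new_peaks.append(replace(peak, analyte=decisions[idx]))
        elif idx in flags:
            new_peaks.append(replace(peak, flag=flags[idx]))
        else:
            new_peaks.append(peak)
    return replace(table, peaks=tuple(new_peaks))


@dataclass(frozen=True)
class ContentResult:
    """Per-analyte contents of one sample, with the quantification method."""

    sample_id: str
    method: str  # "qams" | "external" (synthetic generators may tag otherwise)
    contents: Mapping[str, float]  # in ``unit``
    unit: str = "mg/g"
    below_detection: frozenset = frozenset()

    def __post_init__(self) -> None:
        contents = dict(self.contents)
        if any(v < 0 for v in contents.values()):
            raise ValidationError("contents must be >= 0")
        object.__setattr__(self, "contents", contents)
        object.__setattr__(self, "below_detection", frozenset(self.below_detection))


def quantify(
    table: PeakTable,
    control: PeakTable,
    factors: CorrectionFactorSet,
    method: str = "qams",
) -> ContentResult:
    """Compute per-analyte contents (mg·g⁻¹) of a sample run.

    ``qams`` needs only the reference analyte's peak and concentration in
    the control run; ``external`` needs every analyte's. An analyte with no
    assigned peak in the sample reports 0 and is flagged below detection.
    """
    if method not in ("qams", "external"):
        raise ValidationError(f"unknown method {method!r}")
    if control.standard is None:
        raise ValidationError("control run has no standard solution")
    meta = table.meta
    if meta.sample_mass is None:
        raise ValidationError(
            f"sample {table.sample_id!r}: sample_mass required to report mg/g"
        )
    scale = meta.extraction_volume * meta.dilution_factor / meta.sample_mass
    # differing injection volumes between sample and control scale the areas
    inj_ratio = control.meta.injection_volume / meta.injection_volume

    analytes = list(factors.factors)
    if method == "qams":
        ref = factors.reference
        ref_peak = _require_peak(control, ref)
        c_ref = control.standard.concentration(ref)
        if c_ref <= 0:
            raise ValidationError("control lacks the reference standard")
    else:
        for a in analytes:
            _require_peak(control, a)
            if control.standard.concentration(a) <= 0:
                raise ValidationError(
                    f"external method: control lacks a standard for {a!r}"
                )

    contents: dict[str, float] = {}
    below: set[str] = set()
    for analyte in analytes:
        peak = table.peak_for(analyte)
        if peak is None or peak.area == 0:
            contents[analyte] = 0.0
            below.add(analyte)
            continue
        if method == "qams":
            c_inj = (
                peak.area
                * c_ref
                / (factors.factors[analyte] * ref_peak.area)
                * inj_ratio
            )
        else:
            std_peak = control.peak_for(analyte)
            c_inj = (
                peak.area
                * control.standard.concentration(analyte)
                / std_peak.area
                * inj_ratio
            )
        contents[analyte] = c_inj * scale
    return ContentResult(
        sample_id=table.sample_id,
        method=method,
        contents=contents,
        below_detection=frozenset(below),
    )


@dataclass(frozen=True)
class DurabilityStat:
    mean: float
    rsd: float  # %
    passed: bool


@dataclass(frozen=True)
class DurabilityReport:
    """Per-analyte mean/RSD of correction factors across condition groups."""

    grouping: str  # "injection_volume" | "instrument_column"
    threshold: float  # % RSD limit
    stats: Mapping[str, DurabilityStat]

    @property
    def passed(self) -> bool:
        return all(s.passed for s in self.stats.values())


_DEFAULT_THRESHOLDS = {"injection_volume": 2.0, "instrument_column": 3.0}


def durability(
    factor_groups: Mapping[str, CorrectionFactorSet | Mapping[str, float]],
    grouping: str,
    threshold: float | None = None,
) -> DurabilityReport:
    """Assess factor robustness across >= 2 condition groups.

    ``factor_groups`` maps a group label (an injection volume, an
    instrument/column combination) to that group's factors — either a
    :class:`CorrectionFactorSet` or a plain analyte→factor mapping. RSD is
    the n−1 sample standard deviation over groups, as a percentage of the
    mean; the default pass threshold is 2 % across injection volumes and
    3 % across instruments/columns.
    """
    if len(factor_groups) < 2:
        raise ValidationError("durability needs >= 2 condition groups")
    if threshold is None:
        try:
            threshold = _DEFAULT_THRESHOLDS[grouping]
        except KeyError:
            raise ValidationError(
                f"no default RSD threshold for grouping {grouping!r}; "
                "pass threshold explicitly"
            ) from None
    values: dict[str, list[float]] = {}
    for label, group in factor_groups.items():
        fs = group.factors if isinstance(group, CorrectionFactorSet) else group
        for analyte, f in fs.items():
            if isinstance(group, CorrectionFactorSet) and analyte == group.reference:
                continue
            values.setdefault(analyte, []).append(float(f))
    n_groups = len(factor_groups)
    stats_out: dict[str, DurabilityStat] = {}
    for analyte, vals in values.items():
        if len(vals) != n_groups:
            raise ValidationError(
                f"analyte {analyte!r} present in {len(vals)}/{n_groups} groups"
            )
        mean = statistics.fmean(vals)
        rsd = 100.0 * statistics.stdev(vals) / mean
        stats_out[analyte] = DurabilityStat(mean, rsd, rsd <= threshold)
    return DurabilityReport(grouping=grouping, threshold=threshold, stats=stats_out)


def save_factor_set(factors: CorrectionFactorSet, path: str | Path) -> None:
    """Serialise a factor set to JSON."""
    payload = {
        "reference": factors.reference,
        "factors": dict(factors.factors),
        "rrts": dict(factors.rrts),
        "provenance": list(factors.provenance),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def load_factor_set(path: str | Path) -> CorrectionFactorSet:
    """Load a factor set from JSON (as written by :func:`save_factor_set`)."""
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        return CorrectionFactorSet(
            reference=data["reference"],
            factors={str(k): float(v) for k, v in data["factors"].items()},
            rrts={str(k): float(v) for k, v in data["rrts"].items()},
            provenance=tuple(data.get("provenance", ())),
        )
    except (OSError, KeyError, ValueError, TypeError) as exc:
        raise QamsError(f"cannot load factor set from {path}: {exc}") from exc
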
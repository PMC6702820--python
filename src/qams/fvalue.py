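"""The F statistic and the three-band processing classifier.

Steaming *Polygonum multiflorum* Radix hydrolyses the anthraquinone
glucosides, so the ratio

    F = (C_emodin-8-O-glc + C_physcion-8-O-glc) / (C_emodin + C_physcion)

falls monotonically (apart from measurement jitter) with processing time
and is independent of the absolute anthraquinone level, which varies
strongly with growing region. The decision rule operates on F rounded
half-up to two decimals, matching how the statistic is tabulated:

    F >= 1.0         crude drug (unprocessed Radix)
    0.6 < F < 1.0    incompletely processed
    F <= 0.6         qualified processed product (Radix Preaparata)

Both boundaries are closed on the side of their band (1.00 is crude,
0.60 is qualified).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .analytes import AGLYCONES, GLYCOSIDES
from .core import ContentResult
from .errors import UndefinedFError, ValidationError
from .rounding import round_half_up

__all__ = [
    "LABEL_CRUDE",
    "LABEL_INCOMPLETE",
    "LABEL_QUALIFIED",
    "FResult",
    "SteamingSeries",
    "BatchSummary",
    "f_value",
    "classify",
    "steaming_series",
    "summarize_batches",
    "compare_printed_f",
]

LABEL_CRUDE = "crude"
LABEL_INCOMPLETE = "incompletely_processed"
LABEL_QUALIFIED = "qualified"

CRUDE_THRESHOLD = 1.0
QUALIFIED_THRESHOLD = 0.6


@dataclass(frozen=True)
class FResult:
    """F statistic for one sample; ``label`` is set by :func:`classify`."""

    sample_id: str
    f: float
    f_rounded: float
    label: str | None = None

    def __post_init__(self) -> None:
        if self.f < 0:
            raise ValidationError("F must be >= 0")


def _as_contents(contents: ContentResult | Mapping[str, float]) -> tuple[str, dict]:
    if isinstance(contents, ContentResult):
        return contents.sample_id, dict(contents.contents)
    return "", dict(contents)


def f_value(contents: ContentResult | Mapping[str, float]) -> FResult:
    """Compute the glycoside/aglycone content ratio.

    ``contents`` must cover all four canonical analytes (zeros allowed).
    A zero aglycone sum with positive glycosides yields +inf; 0/0 raises
    :class:`UndefinedFError` since the sample then carries no information.
    """
    sample_id, cmap = _as_contents(contents)
    missing = [a for a in (*GLYCOSIDES, *AGLYCONES) if a not in cmap]
    if missing:
        raise ValidationError(f"contents missing analytes: {missing}")
    if any(cmap[a] < 0 for a in (*GLYCOSIDES, *AGLYCONES)):
        raise ValidationError("contents must be >= 0")
    num = sum(cmap[a] for a in GLYCOSIDES)
    den = sum(cmap[a] for a in AGLYCONES)
    if den == 0:
        if num == 0:
            raise UndefinedFError(
                f"sample {sample_id!r}: all four contents are zero (F = 0/0)"
            )
        f = math.inf
    else:
        f = num / den
    return FResult(sample_id=sample_id, f=f, f_rounded=round_half_up(f, 2))


def classify(
    fres: FResult,
    crude_threshold: float = CRUDE_THRESHOLD,
    qualified_threshold: float = QUALIFIED_THRESHOLD,
) -> FResult:
    """Attach the three-band label, deciding on the rounded F."""
    if not crude_threshold > qualified_threshold:
        raise ValidationError("crude threshold must exceed qualified threshold")
    fr = fres.f_rounded
    if fr >= crude_threshold:
        label = LABEL_CRUDE
    elif fr <= qualified_threshold:
        label = LABEL_QUALIFIED
    else:
        label = LABEL_INCOMPLETE
    return replace(fres, label=label)


@dataclass(frozen=True)
class SteamingSeries:
    """Per-timepoint F of one steaming batch.

    ``qualification_time`` is the earliest sampled time (h) at which the
    batch classifies as qualified, or ``None`` if it never does.
    """

    batch: str
    points: tuple[tuple[float, FResult], ...]
    qualification_time: float | None
    warnings: tuple[str, ...] = ()


class NonMonotoneFWarning(UserWarning):
    """F rose along a steaming series by more than the jitter allowance."""


def steaming_series(
    rows: Sequence[tuple[float, ContentResult | Mapping[str, float]]],
    batch: str,
    jitter_fraction: float = 0.15,
    crude_threshold: float = CRUDE_THRESHOLD,
    qualified_threshold: float = QUALIFIED_THRESHOLD,
) -> SteamingSeries:
    """Evaluate F along a steaming time course.

    Times must be strictly increasing (duplicates are an error). Since
    steaming only consumes glucosides, F should fall; an increase between
    consecutive points of more than ``jitter_fraction`` (relative) is
    reported as a warning, not an error — replicate-to-replicate noise
    produces small upticks in real series.
    """
    if len(rows) < 2:
        raise ValidationError("steaming series needs >= 2 time points")
    times = [t for t, _ in rows]
    for t0, t1 in zip(times, times[1:]):
        if t1 == t0:
            raise ValidationError(f"duplicate steaming time {t0} h")
        if t1 < t0:
            raise ValidationError("steaming times must be strictly increasing")
    points: list[tuple[float, FResult]] = []
    warns: list[str] = []
    for t, contents in rows:
        fres = classify(
            f_value(contents),
            crude_threshold=crude_threshold,
            qualified_threshold=qualified_threshold,
        )
        if not fres.sample_id:
            fres = replace(fres, sample_id=f"{batch} ({t:g} h)")
        points.append((t, fres))
    for (t0, f0), (t1, f1) in zip(points, points[1:]):
        if math.isfinite(f0.f) and f1.f > f0.f * (1 + jitter_fraction):
            msg = (
                f"batch {batch}: F rose from {f0.f:.3g} ({t0:g} h) to "
                f"{f1.f:.3g} ({t1:g} h)"
            )
            warns.append(msg)
            warnings.warn(msg, NonMonotoneFWarning, stacklevel=2)
    qual_time = next(
        (t for t, fres in points if fres.label == LABEL_QUALIFIED), None
    )
    return SteamingSeries(
        batch=batch,
        points=tuple(points),
        qualification_time=qual_time,
        warnings=tuple(warns),
    )


@dataclass(frozen=True)
class BatchSummary:
    """Band counts and qualified rate for one declared product type."""

    declared_type: str  # "radix" | "preaparata"
    total: int
    n_crude_band: int  # F >= 1.0
    n_middle_band: int  # 0.6 < F < 1.0
    n_qualified_band: int  # F <= 0.6
    qualified_rate: float  # %

    def __post_init__(self) -> None:
        if self.n_crude_band + self.n_middle_band + self.n_qualified_band != self.total:
            raise ValidationError("band counts must sum to total")
        if not 0 <= self.qualified_rate <= 100:
            raise ValidationError("qualified_rate must be in [0, 100] %")


def summarize_batches(
    results: Iterable[FResult], declared_type: str
) -> BatchSummary:
    """Count samples per F band and the qualified rate for the declared type.

    A declared crude drug (``radix``) is in order when F >= 1.0; a declared
    processed product (``preaparata``) when F <= 0.6. Rates are percentages
    of the total. Counting uses the rounded F, like the classifier.
    """
    if declared_type not in ("radix", "preaparata"):
        raise ValidationError(f"unknown declared type {declared_type!r}")
    fs = list(results)
    if not fs:
        raise ValidationError("summarize_batches: empty input")
    labelled = [
        classify(f) if f.label is None else f for f in fs
    ]
    n_crude = sum(1 for f in labelled if f.label == LABEL_CRUDE)
    n_mid = sum(1 for f in labelled if f.label == LABEL_INCOMPLETE)
    n_qual = sum(1 for f in labelled if f.label == LABEL_QUALIFIED)
    ok = n_crude if declared_type == "radix" else n_qual
    return BatchSummary(
        declared_type=declared_type,
        total=len(labelled),
        n_crude_band=n_crude,
        n_middle_band=n_mid,
        n_qualified_band=n_qual,
        qualified_rate=100.0 * ok / len(labelled),
    )


def compare_printed_f(
    df: pd.DataFrame, printed_column: str = "f_printed"
) -> pd.DataFrame:
    """Recompute F from a fixture's content columns and diff against print.

    Returns the input plus ``f_recomputed``, ``diff`` (recomputed − printed)
    and ``mismatch`` (|diff| > 0.01, i.e. beyond the printed precision).
    Mismatches arise because published F values were computed on unrounded
    contents while the table prints three decimals; rows with tiny aglycone
    denominators amplify that rounding.
    """
    recomputed = []
    for _, row in df.iterrows():
        contents = {a: float(row[a]) for a in (*GLYCOSIDES, *AGLYCONES)}
        recomputed.append(f_value(contents).f_rounded)
    out = df.copy()
    out["f_recomputed"] = recomputed
    out["diff"] = out["f_recomputed"] - out[printed_column].astype(float)
    out["mismatch"] = out["diff"].abs() > 0.01 + 1e-9
    return out
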
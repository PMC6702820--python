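"""Peak-table data model and CSV input/output.

A chromatographic run is represented as a :class:`PeakTable`: an rt-ordered
list of :class:`Peak` plus the :class:`RunMeta` provenance needed to turn an
injected concentration back into a content per gram of drug (injection
volume, sample mass, extraction volume, dilution chain). Control runs carry
a :class:`StandardSolution` with the per-analyte concentrations of the
injected standard mix.

There is no standard interchange format for integrated peak lists, so the
readers consume plain CSV with a configurable column-name map, and run
metadata travels in a JSON/YAML sidecar. Transcriptions of the published
reference tables (correction-factor durability, method comparison, steaming
series, market survey) ship as packaged CSV fixtures via
:func:`load_fixture`.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .analytes import AnalyteRegistry, default_registry
from .errors import (
    FixtureLookupError,
    QamsError,
    SchemaError,
    ValidationError,
)

__all__ = [
    "Peak",
    "RunMeta",
    "StandardSolution",
    "PeakTable",
    "read_peak_table",
    "write_peak_table",
    "read_run_meta",
    "read_standard",
    "write_report",
    "load_fixture",
    "FIXTURE_NAMES",
]


@dataclass(frozen=True)
class Peak:
    """One detected chromatographic peak.

    ``analyte`` is a canonical analyte id, or ``None`` for an unassigned
    peak. ``flag`` records advisory annotations (e.g. ``"ambiguous"`` when a
    peak matched two expected retention-time windows).
    """

    rt: float
    area: float
    analyte: str | None = None
    flag: str = ""

    def __post_init__(self) -> None:
        if not (self.rt > 0) or math.isnan(self.rt):
            raise ValidationError(f"retention time must be > 0, got {self.rt}")
        if self.area < 0 or math.isnan(self.area):
            raise ValidationError(f"peak area must be >= 0, got {self.area}")

    @property
    def is_assigned(self) -> bool:
        return self.analyte is not None


@dataclass(frozen=True)
class RunMeta:
    """Injection/extraction/dilution provenance for one chromatogram.

    ``sample_mass`` is ``None`` for control (standard-solution) runs.
    ``extraction_volume`` defaults to the 50 mL methanol reflux extraction
    of the assay; ``dilution_factor`` is the combined factor of any further
    dilution of the filtrate (>= 1, 1 = injected neat).
    """

    injection_volume: float = 10.0  # µL
    sample_mass: float | None = None  # g
    extraction_volume: float = 50.0  # mL
    dilution_factor: float = 1.0
    instrument_id: str = ""
    column_id: str = ""

    def __post_init__(self) -> None:
        if not self.injection_volume > 0:
            raise ValidationError("injection_volume must be > 0 µL")
        if self.sample_mass is not None and not self.sample_mass > 0:
            raise ValidationError("sample_mass must be > 0 g when present")
        if not self.extraction_volume > 0:
            raise ValidationError("extraction_volume must be > 0 mL")
        if self.dilution_factor < 1:
            raise ValidationError("dilution_factor must be >= 1")


@dataclass(frozen=True)
class StandardSolution:
    """Per-analyte concentrations (mg·mL⁻¹) of one standard mix."""

    concentrations: Mapping[str, float]
    label: str = ""

    def __post_init__(self) -> None:
        conc = dict(self.concentrations)
        object.__setattr__(self, "concentrations", conc)
        if any(c < 0 for c in conc.values()):
            raise ValidationError("standard concentrations must be >= 0")
        if not any(c > 0 for c in conc.values()):
            raise ValidationError(
                f"standard {self.label!r} has no positive concentration"
            )

    def concentration(self, analyte: str) -> float:
        try:
            return self.concentrations[analyte]
        except KeyError:
            raise ValidationError(
                f"standard {self.label!r} has no concentration for {analyte!r}"
            ) from None


@dataclass(frozen=True)
class PeakTable:
    """An rt-ordered peak list plus run provenance.

    Invariants enforced on construction: peaks sorted by ascending rt and
    at most one assigned peak per analyte.
    """

    peaks: Sequence[Peak]
    meta: RunMeta = field(default_factory=RunMeta)
    standard: StandardSolution | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.peaks, key=lambda p: p.rt))
        object.__setattr__(self, "peaks", ordered)
        seen: set[str] = set()
        for p in ordered:
            if p.analyte is None:
                continue
            if p.analyte in seen:
                raise ValidationError(
                    f"duplicate assigned peak for analyte {p.analyte!r}"
                )
            seen.add(p.analyte)

    def peak_for(self, analyte: str) -> Peak | None:
        for p in self.peaks:
            if p.analyte == analyte:
                return p
        return None

    @property
    def assigned(self) -> dict[str, Peak]:
        return {p.analyte: p for p in self.peaks if p.analyte is not None}


_DEFAULT_SCHEMA = {"analyte": "analyte", "rt": "rt", "area": "area"}


def read_peak_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    meta: RunMeta | None = None,
    standard: StandardSolution | None = None,
    registry: AnalyteRegistry | None = None,
    sample_id: str = "",
) -> PeakTable:
    """Read a peak-table CSV.

    ``schema`` maps the logical names ``analyte``/``rt``/``area`` to the
    column names actually present; ``rt`` and ``area`` are required, the
    analyte column is optional (peaks default to unassigned). Analyte names
    are resolved through the synonym ``registry`` (package default if not
    given); malformed rows are reported with their line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    registry = registry or default_registry()
    colmap = dict(_DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)

    df = pd.read_csv(path)
    for logical in ("rt", "area"):
        if colmap[logical] not in df.columns:
            raise SchemaError(
                f"{path.name}: required column {colmap[logical]!r} "
                f"(for {logical}) not found; columns = {list(df.columns)}"
            )
    has_analyte = colmap["analyte"] in df.columns

    peaks: list[Peak] = []
    problems: list[str] = []
    for i, row in df.iterrows():
        lineno = i + 2  # header is line 1
        name = row[colmap["analyte"]] if has_analyte else None
        analyte: str | None = None
        if isinstance(name, str) and name.strip():
            try:
                analyte = registry.resolve(name)
            except QamsError as exc:
                problems.append(f"line {lineno}: {exc}")
                continue
        try:
            peaks.append(
                Peak(
                    rt=float(row[colmap["rt"]]),
                    area=float(row[colmap["area"]]),
                    analyte=analyte,
                )
            )
        except (QamsError, TypeError) as exc:
            problems.append(f"line {lineno}: {exc}")
    if problems:
        raise ValidationError(
            f"{path.name}: {len(problems)} malformed row(s):\n  "
            + "\n  ".join(problems)
        )
    return PeakTable(
        peaks=peaks,
        meta=meta or RunMeta(),
        standard=standard,
        sample_id=sample_id or path.stem,
    )


def write_peak_table(
    table: PeakTable,
    path: str | Path,
    meta_path: str | Path | None = None,
) -> None:
    """Write a peak table as CSV plus a JSON sidecar for meta/standard.

    Floats are written with ``repr`` (shortest round-tripping form) so a
    write/read cycle reproduces the table exactly.
    """
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else path.with_suffix(".meta.json")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("analyte,rt,area\n")
        for p in table.peaks:
            fh.write(f"{p.analyte or ''},{p.rt!r},{p.area!r}\n")
    sidecar: dict = {
        "sample_id": table.sample_id,
        "meta": dataclasses.asdict(table.meta),
    }
    if table.standard is not None:
        sidecar["standard"] = {
            "label": table.standard.label,
            "concentrations": dict(table.standard.concentrations),
        }
    with open(meta_path, "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2)


def read_run_meta(path: str | Path) -> tuple[RunMeta, StandardSolution | None, str]:
    """Read a JSON/YAML sidecar; returns (meta, standard-or-None, sample id)."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)  # JSON is a YAML subset
    if not isinstance(data, dict):
        raise SchemaError(f"{path.name}: expected a mapping at top level")
    try:
        meta = RunMeta(**data.get("meta", {}))
    except TypeError as exc:
        raise SchemaError(f"{path.name}: bad meta block: {exc}") from None
    standard = None
    if "standard" in data:
        std = data["standard"]
        registry = default_registry()
        conc = {
            registry.resolve(k): float(v)
            for k, v in std.get("concentrations", {}).items()
        }
        standard = StandardSolution(conc, label=std.get("label", ""))
    return meta, standard, str(data.get("sample_id", ""))


def read_standard(
    path: str | Path,
    registry: AnalyteRegistry | None = None,
    label: str = "",
) -> StandardSolution:
    """Read a standard-solution CSV with columns analyte,concentration (mg·mL⁻¹)."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    registry = registry or default_registry()
    df = pd.read_csv(path)
    for col in ("analyte", "concentration"):
        if col not in df.columns:
            raise SchemaError(f"{path.name}: required column {col!r} not found")
    conc = {
        registry.resolve(str(row["analyte"])): float(row["concentration"])
        for _, row in df.iterrows()
    }
    return StandardSolution(conc, label=label or path.stem)


def write_report(results: Iterable, path: str | Path, fmt: str | None = None) -> None:
    """Write a per-sample report.

    ``results`` is a non-empty iterable of ``(ContentResult, FResult)``
    pairs (input order preserved). Contents are printed at full reported
    precision; the F statistic is printed rounded half-up to two decimals,
    the same policy used for classification.
    """
    from .analytes import CANONICAL_FOUR

    rows = list(results)
    if not rows:
        raise ValidationError("write_report: empty results")
    path = Path(path)
    fmt = fmt or ("json" if path.suffix.lower() == ".json" else "csv")

    records = []
    for content, fres in rows:
        rec: dict = {"sample_id": fres.sample_id or content.sample_id,
                     "method": content.method}
        for a in CANONICAL_FOUR:
            rec[a] = content.contents.get(a, 0.0)
        rec["unit"] = content.unit
        rec["F"] = f"{fres.f_rounded:.2f}" if math.isfinite(fres.f_rounded) else "inf"
        rec["label"] = fres.label or ""
        records.append(rec)
    try:
        if fmt == "json":
            with open(path, "w", encoding="utf-8") as fh:
                json.dump(records, fh, indent=2)
        else:
            pd.DataFrame.from_records(records).to_csv(path, index=False)
    except OSError as exc:
        raise QamsError(f"cannot write report to {path}: {exc}") from exc


#: packaged reference tables: name -> (file, human description)
FIXTURE_NAMES = {
    "table1": "table1.csv",  # correction factors vs injection volume (5 rows)
    "table2": "table2.csv",  # correction factors vs instrument/column (4 rows)
    "table4": "table4.csv",  # QAMS vs external standard, 10 batches
    "table5": "table5.csv",  # steaming time series, 6 batches / 35 rows
    "table6": "table6.csv",  # market survey, 66 + 106 batches
}


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged reference table as a DataFrame.

    Analyte columns are headed by canonical ids; sample numbers are kept as
    zero-padded strings.
    """
    try:
        fname = FIXTURE_NAMES[name]
    except KeyError:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURE_NAMES)}"
        ) from None
    ref = resources.files("qams").joinpath("data", fname)
    with resources.as_file(ref) as p:
        return pd.read_csv(p, dtype={"sample_no": str})
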
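"""Analyte registry and synonym resolution.

The four anthraquinones tracked throughout the package are the aglycones
emodin and physcion and their 8-O-beta-D-glucopyranosides. The older
literature (and some chromatography reports) call physcion "emodin
monomethyl ether" (often misspelt "monemethyl"), and its glucoside
"emodin monomethyl ether-8-O-beta-D-glucopyranoside"; the registry maps
all of those spellings onto the canonical ids.

Resolution is case-insensitive and total: a name that is neither a
canonical id nor a registered synonym raises :class:`UnknownAnalyteError`
rather than being passed through, so typos never silently create a fifth
analyte.
"""

from __future__ import annotations

import unicodedata

from .errors import UnknownAnalyteError, ValidationError

__all__ = [
    "EMODIN",
    "PHYSCION",
    "EMODIN_GLC",
    "PHYSCION_GLC",
    "CANONICAL_FOUR",
    "GLYCOSIDES",
    "AGLYCONES",
    "AnalyteRegistry",
    "default_registry",
    "resolve",
]

EMODIN = "emodin"
PHYSCION = "physcion"
EMODIN_GLC = "emodin-8-O-glc"
PHYSCION_GLC = "physcion-8-O-glc"

#: canonical ids in elution order of the assay (glucosides first)
CANONICAL_FOUR = (EMODIN_GLC, PHYSCION_GLC, EMODIN, PHYSCION)

#: numerator / denominator of the F statistic
GLYCOSIDES = (EMODIN_GLC, PHYSCION_GLC)
AGLYCONES = (EMODIN, PHYSCION)

_DEFAULT_SYNONYMS: dict[str, tuple[str, ...]] = {
    EMODIN: ("emodine",),
    PHYSCION: (
        "physcione",
        "emodin monomethyl ether",
        "emodin monemethyl ether",
    ),
    EMODIN_GLC: (
        "emodin-8-O-glucoside",
        "emodin-8-O-beta-D-glucoside",
        "emodin-8-O-beta-D-glucopyranoside",
    ),
    PHYSCION_GLC: (
        "physcion-8-O-glucoside",
        "physcion-8-O-beta-D-glucoside",
        "physcion-8-O-beta-D-glucopyranoside",
        "emodin monomethyl ether-8-O-beta-D-glucopyranoside",
        "emodin monemethyl ether-8-O-beta-D-glucopyranoside",
    ),
}


def _normalize(name: str) -> str:
    """Fold a name to a comparison key: casefold, strip accents/Greek beta,
    collapse separators."""
    s = unicodedata.normalize("NFKD", name)
    s = s.replace("β", "beta").replace("‐", "-")
    s = s.casefold()
    for ch in (" ", "-", "_", "."):
        s = s.replace(ch, "")
    return s


class AnalyteRegistry:
    """Mutable registry of canonical analyte ids and their synonyms."""

    def __init__(self) -> None:
        self._canonical: dict[str, str] = {}  # norm key -> canonical id
        self._ids: list[str] = []

    def register(self, canonical_id: str, synonyms: tuple[str, ...] = ()) -> None:
        key = _normalize(canonical_id)
        if key in self._canonical and self._canonical[key] != canonical_id:
            raise ValidationError(
                f"analyte id {canonical_id!r} collides with "
                f"{self._canonical[key]!r}"
            )
        self._canonical[key] = canonical_id
        if canonical_id not in self._ids:
            self._ids.append(canonical_id)
        for syn in synonyms:
            skey = _normalize(syn)
            existing = self._canonical.get(skey)
            if existing is not None and existing != canonical_id:
                raise ValidationError(
                    f"synonym {syn!r} already maps to {existing!r}"
                )
            self._canonical[skey] = canonical_id

    def resolve(self, name: str) -> str:
        """Map ``name`` (canonical id or synonym, any case) to a canonical id."""
        if not isinstance(name, str) or not name.strip():
            raise UnknownAnalyteError(f"not an analyte name: {name!r}")
        try:
            return self._canonical[_normalize(name)]
        except KeyError:
            raise UnknownAnalyteError(
                f"unknown analyte {name!r}; known ids: {', '.join(self._ids)}"
            ) from None

    def known(self, name: str) -> bool:
        return _normalize(name) in self._canonical

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self._ids)


def default_registry() -> AnalyteRegistry:
    """Registry pre-loaded with the four assay analytes and their synonyms."""
    reg = AnalyteRegistry()
    for cid, syns in _DEFAULT_SYNONYMS.items():
        reg.register(cid, syns)
    return reg


_DEFAULT = default_registry()


def resolve(name: str) -> str:
    """Resolve ``name`` through the package-default registry."""
    return _DEFAULT.resolve(name)
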
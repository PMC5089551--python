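"""Y-STR panel definitions.

Three marker sets are supported:

* ``YFILER`` — the 17-column forensic standard (16 loci; the multi-copy
  locus DYS385 is scored as two order-free columns ``DYS385a``/``DYS385b``).
* ``RM13`` — the full rapidly-mutating (RM) Y-STR panel, scored as 14
  columns.  DYF403S1a and DYF403S1b are distinct amplicons and are treated
  as separate single-copy loci; DYS526A+B is scored as one combined column.
* ``RM11`` — RM13 with its two most mutable markers (DYF399S1 and
  DYF403S1a) removed, 12 scored columns.

A "scored column" is the unit over which alleles are recorded and mutation
events are counted: single-copy loci contribute one column, multi-copy loci
one column per copy (suffixed ``a``, ``b``, ...).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["LocusDef", "Panel", "load_panel", "PANEL_NAMES"]

_COPY_SUFFIXES = "abcdefgh"


@dataclass(frozen=True)
class LocusDef:
    """A scored STR locus.

    Parameters
    ----------
    name:
        Locus identifier, e.g. ``DYS393`` or ``DYF399S1``.
    copy_count:
        Number of allele columns scored for the locus (1 for single-copy).
    step_unit:
        Allele step granularity in repeat units.
    """

    name: str
    copy_count: int = 1
    step_unit: int = 1
    #: Whether the marker is biologically multi-copy even when scored as a
    #: single column (e.g. DYF399S1); None means "infer from copy_count".
    multi_copy: bool | None = None

    @property
    def is_multi_copy(self) -> bool:
        return self.copy_count > 1 if self.multi_copy is None else self.multi_copy

    def __post_init__(self) -> None:
        if self.copy_count < 1:
            raise ValueError(f"copy_count must be >= 1, got {self.copy_count}")
        if self.copy_count > len(_COPY_SUFFIXES):
            raise ValueError(f"copy_count {self.copy_count} unsupported")

    @property
    def columns(self) -> tuple[str, ...]:
        """Scored column names for this locus."""
        if self.copy_count == 1:
            return (self.name,)
        return tuple(self.name + s for s in _COPY_SUFFIXES[: self.copy_count])


@dataclass(frozen=True)
class Panel:
    """An ordered set of scored Y-STR loci."""

    name: str
    loci: tuple[LocusDef, ...]

    def __post_init__(self) -> None:
        names = [l.name for l in self.loci]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate locus names in panel {self.name}")

    @property
    def columns(self) -> tuple[str, ...]:
        """All scored column names, in panel order."""
        return tuple(c for locus in self.loci for c in locus.columns)

    @property
    def scored_locus_count(self) -> int:
        """L — the number of scored allele columns (rate denominator)."""
        return len(self.columns)

    @property
    def locus_names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.loci)

    @property
    def single_copy_loci(self) -> tuple[str, ...]:
        """Names of single-copy loci (the features usable for DAPC).

        Markers flagged biologically multi-copy are excluded even when
        scored as one column: between unrelated men the copy producing a
        given allele is ambiguous."""
        return tuple(l.name for l in self.loci if not l.is_multi_copy)

    def locus(self, name: str) -> LocusDef:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(f"locus {name!r} not in panel {self.name}")

    def __contains__(self, name: str) -> bool:
        return any(l.name == name for l in self.loci)


_YFILER_LOCI: tuple[LocusDef, ...] = (
    LocusDef("DYS393"),
    LocusDef("DYS390"),
    LocusDef("DYS19"),
    LocusDef("DYS391"),
    LocusDef("DYS385", copy_count=2),
    LocusDef("DYS439"),
    LocusDef("DYS389I"),
    LocusDef("DYS392"),
    LocusDef("DYS389II"),
    LocusDef("DYS458"),
    LocusDef("DYS437"),
    LocusDef("DYS448"),
    LocusDef("YGATAH4"),
    LocusDef("DYS456"),
    LocusDef("DYS438"),
    LocusDef("DYS635"),
)

_RM13_LOCI: tuple[LocusDef, ...] = (
    LocusDef("DYS576"),
    LocusDef("DYF399S1", multi_copy=True),
    LocusDef("DYF387S1", multi_copy=True),
    LocusDef("DYS570"),
    LocusDef("DYS526A+B"),
    LocusDef("DYS626"),
    LocusDef("DYS627"),
    LocusDef("DYS518"),
    LocusDef("DYS612"),
    LocusDef("DYS449"),
    LocusDef("DYS547"),
    LocusDef("DYF404S1", multi_copy=True),
    LocusDef("DYF403S1a", multi_copy=True),
    LocusDef("DYF403S1b", multi_copy=True),
)

_RM11_EXCLUDED = frozenset({"DYF399S1", "DYF403S1a"})
_RM11_LOCI = tuple(l for l in _RM13_LOCI if l.name not in _RM11_EXCLUDED)

_PANELS: dict[str, Panel] = {
    "YFILER": Panel("YFILER", _YFILER_LOCI),
    "RM13": Panel("RM13", _RM13_LOCI),
    "RM11": Panel("RM11", _RM11_LOCI),
}

PANEL_NAMES = tuple(_PANELS)


def load_panel(name: str) -> Panel:
    """Return a canonical panel by name (case-insensitive).

    Raises
    ------
    ValueError
        If *name* is not one of ``YFILER``, ``RM13``, ``RM11``.
    """
    key = name.strip().upper()
    try:
        return _PANELS[key]
    except KeyError:
        raise ValueError(
            f"unknown panel {name!r}; expected one of {', '.join(PANEL_NAMES)}"
        ) from None
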
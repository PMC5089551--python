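"""Haplotype and couple containers plus plain-tabular readers/writers.

Haplotype tables are TSV (comma-separated accepted via ``sep=','``) with a
``sample_id`` first column and one column per scored allele; multi-copy
loci use ``a``/``b`` suffixed columns (e.g. ``DYS385a``, ``DYS385b``).
Empty cells mark missing calls.  Multi-copy allele tuples are order-free:
they are sorted at ingest because copy assignment is not observable from an
electropherogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .panels import Panel

log = logging.getLogger(__name__)

__all__ = [
    "Haplotype",
    "CoupleRecord",
    "read_haplotype_table",
    "write_haplotype_table",
    "read_couples",
    "write_couples",
]

RELATIONSHIPS = (
    "father-son",
    "brothers",
    "uncle-nephew",
    "cousins",
    "pedigree-pair",
    "unrelated",
)


@dataclass
class Haplotype:
    """One sample's allele values over a panel.

    ``alleles`` maps locus name -> tuple of numeric allele values, one per
    scored copy, stored in non-decreasing order.  Loci absent from the
    mapping are missing.
    """

    sample_id: str
    alleles: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, vals in list(self.alleles.items()):
            t = tuple(sorted(float(v) for v in vals))
            if any(v < 0 for v in t):
                raise ValueError(
                    f"negative allele at {name} for sample {self.sample_id}"
                )
            self.alleles[name] = t

    def has(self, locus: str) -> bool:
        return locus in self.alleles

    def column_values(self, panel: Panel) -> dict[str, float | None]:
        """Alleles keyed by scored column name (sorted copy order);
        ``None`` for missing loci."""
        out: dict[str, float | None] = {}
        for locus in panel.loci:
            vals = self.alleles.get(locus.name)
            for i, col in enumerate(locus.columns):
                out[col] = None if vals is None else vals[i]
        return out


@dataclass(frozen=True)
class CoupleRecord:
    """A pair of samples compared for mutation counting.

    ``meioses`` is the number of father-to-son transmissions separating
    the two (``None`` for unrelated couples, which carry sub-lineage
    labels through ``group_a``/``group_b`` instead).
    """

    sample_a: str
    sample_b: str
    meioses: int | None = None
    relationship: str = "unrelated"
    dataset_tag: str = ""
    group_a: str | None = None
    group_b: str | None = None

    def __post_init__(self) -> None:
        if self.relationship not in RELATIONSHIPS:
            raise ValueError(f"unknown relationship {self.relationship!r}")
        if self.relationship != "unrelated":
            if self.meioses is None or self.meioses < 1:
                raise ValueError(
                    f"related couple ({self.sample_a},{self.sample_b}) "
                    f"needs meioses >= 1"
                )

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.sample_a, self.sample_b)))  # type: ignore[return-value]


def read_haplotype_table(
    path: str | Path, panel: Panel, sep: str = "\t"
) -> list[Haplotype]:
    """Read a haplotype table, resolving header names against *panel*.

    Unknown columns are ignored with a warning; empty cells become missing
    loci; a non-numeric cell or a duplicate sample_id is an error.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'sample_id'")
    panel_cols = set(panel.columns)
    unknown = [c for c in df.columns if c != "sample_id" and c not in panel_cols]
    if unknown:
        log.warning("%s: ignoring %d unknown column(s): %s", path, len(unknown), unknown)
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample_id(s): {dups}")

    haplotypes = []
    n_missing = 0
    for row_idx, row in df.iterrows():
        alleles: dict[str, list[float]] = {}
        complete: dict[str, bool] = {}
        for locus in panel.loci:
            vals: list[float] = []
            ok = True
            for col in locus.columns:
                cell = row.get(col)
                if cell is None or pd.isna(cell) or str(cell).strip() == "":
                    ok = False
                    continue
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric allele {cell!r} at row "
                        f"{row_idx + 2}, column {col}"
                    ) from None
            if ok and vals:
                alleles[locus.name] = vals
            elif any(col in df.columns for col in locus.columns):
                n_missing += 1
        haplotypes.append(Haplotype(str(row["sample_id"]), {k: tuple(v) for k, v in alleles.items()}))
    if n_missing:
        log.info("%s: %d locus call(s) missing", path, n_missing)
    return haplotypes


def write_haplotype_table(
    path: str | Path, haplotypes: list[Haplotype], panel: Panel, sep: str = "\t"
) -> None:
    """Write haplotypes as a TSV in panel column order (inverse of
    :func:`read_haplotype_table`)."""
    rows = []
    for h in haplotypes:
        row: dict[str, object] = {"sample_id": h.sample_id}
        for col, val in h.column_values(panel).items():
            row[col] = "" if val is None else _fmt_allele(val)
        rows.append(row)
    pd.DataFrame(rows, columns=["sample_id", *panel.columns]).to_csv(
        path, sep=sep, index=False
    )


def _fmt_allele(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else f"{v:g}"


def read_couples(path: str | Path, sep: str = "\t") -> list[CoupleRecord]:
    """Read a couples table: ``sample_a, sample_b, meioses, relationship,
    dataset_tag[, group_a, group_b]``."""
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    required = {"sample_a", "sample_b", "relationship", "dataset_tag"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        meioses_cell = row.get("meioses")
        meioses = (
            None
            if meioses_cell is None or pd.isna(meioses_cell) or str(meioses_cell) == ""
            else int(float(meioses_cell))
        )
        out.append(
            CoupleRecord(
                sample_a=str(row["sample_a"]),
                sample_b=str(row["sample_b"]),
                meioses=meioses,
                relationship=str(row["relationship"]),
                dataset_tag=str(row["dataset_tag"]),
                group_a=_opt(row.get("group_a")),
                group_b=_opt(row.get("group_b")),
            )
        )
    return out


def _opt(cell) -> str | None:
    if cell is None or pd.isna(cell) or str(cell) == "":
        return None
    return str(cell)


def write_couples(path: str | Path, couples: list[CoupleRecord], sep: str = "\t") -> None:
    rows = [
        {
            "sample_a": c.sample_a,
            "sample_b": c.sample_b,
            "meioses": "" if c.meioses is None else c.meioses,
            "relationship": c.relationship,
            "dataset_tag": c.dataset_tag,
            "group_a": c.group_a or "",
            "group_b": c.group_b or "",
        }
        for c in couples
    ]
    pd.DataFrame(
        rows,
        columns=["sample_a", "sample_b", "meioses", "relationship", "dataset_tag", "group_a", "group_b"],
    ).to_csv(path, sep=sep, index=False)
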
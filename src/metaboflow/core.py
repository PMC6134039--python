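"""Core domain types and table I/O for CE-TOFMS-style metabolite panels.

A study is a set of wide abundance tables: one table per ionization mode
(cation/anion) per compartment (pellet / intestine / serum), rows =
metabolites, columns = samples labelled ``<compartment>_<group>_<replicate>``.
Cells hold non-negative relative peak areas or ND (non-detect). Each mode
carries one internal-standard row (methionine sulfone for cation mode,
D-camphor-10-sulfonic acid for anion mode) used to normalize all other rows
per sample.

ND is a first-class state distinct from zero: a metabolite below detection
carries no area, and treating it as 0 would create spurious infinite ratios
downstream. Internally ND is represented as NaN in the pandas frame.
"""

from __future__ import annotations

import csv
import io as _io
import math
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

COMPARTMENTS = ("pellet", "intestine", "serum")
GROUPS = ("control", "probiotic")
MODES = ("cation", "anion")

#: reserved internal-standard row name per ionization mode
DEFAULT_STANDARDS = {
    "cation": "methionine sulfone",
    "anion": "D-camphor-10-sulfonic acid",
}

ND_TOKENS = {"nd", "n.d.", ""}


class TableError(ValueError):
    """Base class for abundance-table validation/parse failures."""


class MissingStandardError(TableError):
    pass


class DuplicateEntryError(TableError):
    pass


class NegativeAreaError(TableError):
    pass


class UnknownLabelError(TableError):
    pass


def canonical_name(name: str) -> str:
    """Whitespace-normalized, case-folded metabolite identity.

    Metabolite identity is shared across compartments by exact
    (base name, branch) match after this normalization.
    """
    return " ".join(str(name).split()).casefold()


@dataclass(frozen=True, order=True)
class MetaboliteId:
    """A compound candidate, optionally disambiguated by a branch number.

    When several peaks are assigned to the same candidate name the candidate
    is given a branch number and displayed ``Name-1``, ``Name-2``, ... A
    singleton candidate carries no branch.
    """

    base_name: str
    branch: int | None = None

    def __post_init__(self):
        if not str(self.base_name).strip():
            raise ValueError("base_name must be non-empty")
        if self.branch is not None and self.branch < 1:
            raise ValueError("branch must be a positive integer")

    def display(self) -> str:
        if self.branch is None:
            return self.base_name
        return f"{self.base_name}-{self.branch}"

    def canonical(self) -> str:
        return canonical_name(self.display())


def assign_branch_numbers(
    candidates: list[tuple[str, object]],
) -> list[MetaboliteId]:
    """Disambiguate repeated candidate names with branch numbers.

    ``candidates`` is a list of ``(base_name, peak_identifier)`` pairs with
    unique peak identifiers. Names occurring once get no branch; names
    occurring k >= 2 times get branches 1..k in the input order of their
    peaks. Output order preserves input order.
    """
    peaks = [p for _, p in candidates]
    if len(set(peaks)) != len(peaks):
        raise ValueError("peak identifiers must be unique")
    counts = Counter(canonical_name(n) for n, _ in candidates)
    seen: Counter = Counter()
    out = []
    for name, _ in candidates:
        key = canonical_name(name)
        if counts[key] >= 2:
            seen[key] += 1
            out.append(MetaboliteId(name, seen[key]))
        else:
            out.append(MetaboliteId(name))
    return out


@dataclass(frozen=True, order=True)
class SampleKey:
    """One pooled sample: compartment x dietary group x replicate."""

    compartment: str
    group: str
    replicate: int

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise UnknownLabelError(f"unknown compartment {self.compartment!r}")
        if self.group not in GROUPS:
            raise UnknownLabelError(f"unknown group label {self.group!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")

    def column(self) -> str:
        return f"{self.compartment}_{self.group}_{self.replicate}"

    @classmethod
    def parse(cls, column: str) -> "SampleKey":
        m = re.fullmatch(r"(.+)_(control|probiotic)_(\d+)", column)
        if m is None:
            raise UnknownLabelError(
                f"sample column {column!r} is not <compartment>_<group>_<replicate>"
            )
        return cls(m.group(1), m.group(2), int(m.group(3)))


@dataclass
class AbundanceTable:
    """Relative peak areas for one (compartment, mode) panel.

    ``data`` is metabolites x samples with NaN for ND; ``internal_standard``
    is the per-sample area of the mode's spiked standard (all 1.0 once the
    table has been normalized).
    """

    mode: str
    compartment: str
    data: pd.DataFrame
    internal_standard: pd.Series

    def __post_init__(self):
        if self.mode not in MODES:
            raise UnknownLabelError(f"unknown mode {self.mode!r}")
        if self.compartment not in COMPARTMENTS:
            raise UnknownLabelError(f"unknown compartment {self.compartment!r}")
        self.data = self.data.astype(float)
        self.internal_standard = self.internal_standard.astype(float)
        for col in self.data.columns:
            key = SampleKey.parse(col)
            if key.compartment != self.compartment:
                raise UnknownLabelError(
                    f"column {col!r} does not belong to compartment "
                    f"{self.compartment!r}"
                )
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise DuplicateEntryError(f"duplicate metabolite row {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise DuplicateEntryError(f"duplicate sample column {dup!r}")
        if not set(self.internal_standard.index) == set(self.data.columns):
            raise MissingStandardError(
                "internal standard must cover exactly the sample columns"
            )
        self.internal_standard = self.internal_standard.reindex(self.data.columns)
        if (self.internal_standard <= 0).any() or self.internal_standard.isna().any():
            bad = self.internal_standard.index[
                ~(self.internal_standard > 0)
            ][0]
            raise MissingStandardError(
                f"internal standard must be positive (sample {bad!r})"
            )
        if (self.data < 0).any().any():
            col = self.data.columns[(self.data < 0).any(axis=0)][0]
            row = self.data.index[(self.data < 0).any(axis=1)][0]
            raise NegativeAreaError(f"negative area at row {row!r}, column {col!r}")

    # -- structure -----------------------------------------------------

    @property
    def samples(self) -> list[SampleKey]:
        return [SampleKey.parse(c) for c in self.data.columns]

    def group_columns(self, group: str) -> list[str]:
        return [c for c in self.data.columns if SampleKey.parse(c).group == group]

    def members(self) -> set[str]:
        """Canonical names detected (>=1 non-ND cell) in this panel."""
        detected = self.data.notna().any(axis=1)
        return {canonical_name(n) for n in self.data.index[detected]}

    # -- normalization -------------------------------------------------

    def normalize(self) -> "AbundanceTable":
        """Divide every non-ND area by its sample's internal-standard area.

        ND cells are preserved. The returned table has all standards set to
        1, which makes the operation idempotent: normalizing an already
        normalized table is the identity.
        """
        data = self.data.div(self.internal_standard, axis=1)
        std = pd.Series(1.0, index=self.data.columns)
        return AbundanceTable(self.mode, self.compartment, data, std)

    def equals(self, other: "AbundanceTable", rtol: float = 0.0) -> bool:
        if (self.mode, self.compartment) != (other.mode, other.compartment):
            return False
        if list(self.data.index) != list(other.data.index):
            return False
        if list(self.data.columns) != list(other.data.columns):
            return False
        a, b = self.data.to_numpy(), other.data.to_numpy()
        if not np.array_equal(np.isnan(a), np.isnan(b)):
            return False
        mask = ~np.isnan(a)
        return np.allclose(a[mask], b[mask], rtol=rtol, atol=0.0) and np.allclose(
            self.internal_standard.to_numpy(),
            other.internal_standard.to_numpy(),
            rtol=rtol,
            atol=0.0,
        )


def normalize(table: AbundanceTable) -> AbundanceTable:
    """Functional alias for :meth:`AbundanceTable.normalize`."""
    return table.normalize()


# ---------------------------------------------------------------------------
# Delimited I/O
# ---------------------------------------------------------------------------

def _sniff_delimiter(text: str) -> str:
    # tab-separated default with comma fallback
    first = text.splitlines()[0] if text else ""
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    return "\t"


def _parse_cell(token: str, row: str, col: str) -> float:
    token = token.strip()
    if token.lower() in ND_TOKENS:
        return math.nan
    try:
        value = float(token)
    except ValueError as exc:
        raise TableError(
            f"unparseable area {token!r} at row {row!r}, column {col!r}"
        ) from exc
    if value < 0:
        raise NegativeAreaError(f"negative area at row {row!r}, column {col!r}")
    return value


def read_abundance_table(
    path, mode: str, compartment: str, standard_name: str | None = None
) -> AbundanceTable:
    """Read a wide delimited panel into an :class:`AbundanceTable`.

    The file must have a header ``metabolite<TAB>sample...``, one metabolite
    row per line, and a designated internal-standard row (named per mode,
    overridable via ``standard_name``). ND cells are parsed from the literal
    tokens ``ND``, ``N.D.`` or empty; the standard row is removed from the
    entries and stored separately.
    """
    if standard_name is None:
        standard_name = DEFAULT_STANDARDS.get(mode, "")
    text = Path(path).read_text(encoding="utf-8")
    delim = _sniff_delimiter(text)
    reader = csv.reader(_io.StringIO(text), delimiter=delim)
    rows = [r for r in reader if r]
    if not rows:
        raise TableError(f"{path}: empty file")
    header = [h.strip() for h in rows[0]]
    columns = header[1:]
    for col in columns:
        SampleKey.parse(col)  # raises UnknownLabelError with the column name
    names, values = [], []
    standard = None
    for r in rows[1:]:
        name = r[0].strip()
        cells = [_parse_cell(tok, name, col) for tok, col in zip(r[1:], columns)]
        if len(cells) != len(columns):
            raise TableError(f"row {name!r} has {len(cells)} of {len(columns)} cells")
        if canonical_name(name) == canonical_name(standard_name):
            if standard is not None:
                raise DuplicateEntryError(f"duplicate internal-standard row {name!r}")
            standard = pd.Series(cells, index=columns)
            continue
        names.append(name)
        values.append(cells)
    if standard is None:
        raise MissingStandardError(
            f"internal standard not found (expected row {standard_name!r})"
        )
    data = pd.DataFrame(values, index=pd.Index(names, name="metabolite"),
                        columns=columns, dtype=float)
    return AbundanceTable(mode, compartment, data, standard)


def write_table(table: AbundanceTable, path,
                standard_name: str | None = None) -> None:
    """Write a TSV that :func:`read_abundance_table` round-trips exactly.

    ND cells are written as the literal token ``ND``; areas use ``%.17g`` so
    binary64 values survive the text round trip. The internal-standard row is
    emitted first under its reserved name.
    """
    if standard_name is None:
        standard_name = DEFAULT_STANDARDS[table.mode]
    lines = ["metabolite\t" + "\t".join(table.data.columns)]

    def fmt(x: float) -> str:
        return "ND" if math.isnan(x) else format(x, ".17g")

    lines.append(
        standard_name + "\t" + "\t".join(
            format(v, ".17g") for v in table.internal_standard
        )
    )
    for name, row in table.data.iterrows():
        lines.append(str(name) + "\t" + "\t".join(fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_annotation(path) -> dict[str, str]:
    """Two-column TSV ``metabolite<TAB>functional_group`` -> canonical map."""
    out: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("metabolite\t"):
            continue
        name, group = line.split("\t")[:2]
        out[canonical_name(name)] = group.strip()
    return out


# ---------------------------------------------------------------------------
# Study bundle
# ---------------------------------------------------------------------------

@dataclass
class StudyBundle:
    """All abundance tables of one feeding study, keyed (compartment, mode).

    Metabolite identity is shared across tables by canonical display name;
    the optional annotation maps canonical names to functional groups.
    """

    tables: dict[tuple[str, str], AbundanceTable] = field(default_factory=dict)
    annotation: dict[str, str] | None = None

    def __post_init__(self):
        for (comp, mode), table in self.tables.items():
            if (table.compartment, table.mode) != (comp, mode):
                raise TableError(
                    f"table stored under {(comp, mode)} labelled "
                    f"{(table.compartment, table.mode)}"
                )

    def add(self, table: AbundanceTable) -> None:
        key = (table.compartment, table.mode)
        if key in self.tables:
            raise DuplicateEntryError(f"duplicate table for {key}")
        self.tables[key] = table

    def normalized(self) -> "StudyBundle":
        return StudyBundle(
            {k: t.normalize() for k, t in self.tables.items()},
            annotation=self.annotation,
        )

    def compartment_frame(self, compartment: str) -> pd.DataFrame:
        """Stack both modes of one compartment into a single frame.

        Index is canonical metabolite name; a ``metabolite`` column keeps the
        display name and ``mode`` records the ionization mode of each row.
        """
        parts = []
        for mode in MODES:
            table = self.tables.get((compartment, mode))
            if table is None:
                continue
            part = table.data.copy()
            part.insert(0, "metabolite", part.index.astype(str))
            part.insert(1, "mode", mode)
            part.index = pd.Index(
                [canonical_name(n) for n in table.data.index], name="id"
            )
            parts.append(part)
        if not parts:
            raise TableError(f"no tables for compartment {compartment!r}")
        frame = pd.concat(parts, axis=0)
        if frame.index.has_duplicates:
            dup = frame.index[frame.index.duplicated()][0]
            raise DuplicateEntryError(
                f"metabolite {dup!r} appears in both modes of {compartment!r}"
            )
        return frame

    def members(self, compartment: str) -> set[str]:
        out: set[str] = set()
        for mode in MODES:
            table = self.tables.get((compartment, mode))
            if table is not None:
                out |= table.members()
        return out

    def compartments(self) -> list[str]:
        return sorted({c for c, _ in self.tables}, key=COMPARTMENTS.index)

    # -- directory I/O -------------------------------------------------

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for (comp, mode), table in sorted(self.tables.items()):
            write_table(table, directory / f"{comp}_{mode}.tsv")
        if self.annotation:
            lines = ["metabolite\tfunctional_group"] + [
                f"{name}\t{grp}" for name, grp in sorted(self.annotation.items())
            ]
            (directory / "annotation.tsv").write_text(
                "\n".join(lines) + "\n", encoding="utf-8"
            )

    @classmethod
    def read(cls, directory) -> "StudyBundle":
        directory = Path(directory)
        bundle = cls()
        found = False
        for comp in COMPARTMENTS:
            for mode in MODES:
                path = directory / f"{comp}_{mode}.tsv"
                if path.exists():
                    bundle.add(read_abundance_table(path, mode, comp))
                    found = True
        if not found:
            raise TableError(f"no abundance tables found under {directory}")
        ann = directory / "annotation.tsv"
        if ann.exists():
            bundle.annotation = read_annotation(ann)
        return bundle
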
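"""Reading and validating tab-text taxa configuration files.

A configuration file is a plain tab-delimited list of the categories (taxa)
to count, one per row, with a header row.  The mandatory columns are the
genus and species parts of the name and the button flag (whether the taxon
gets a quick-entry button); a button label is required whenever the flag is
set.  An optional higher-category column groups long name lists into
sub-lists.  Any unrecognized column (for example a speech "recognition
name") is carried along verbatim in ``extras`` and ignored by the rest of
the package.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .errors import ConfigError

__all__ = [
    "TaxonConfig",
    "read_config",
    "write_config",
    "group_by_category",
    "normalize_taxon_id",
    "DEFAULT_CATEGORY",
    "HEADER_SYNONYMS",
]

#: Group name used for taxa whose category cell is empty.
DEFAULT_CATEGORY = "ungrouped"

#: Case-insensitive header synonyms.  Keys are canonical field names; any
#: header not matching a synonym is preserved as an ``extras`` column.
HEADER_SYNONYMS: dict[str, frozenset[str]] = {
    "genus": frozenset({"genus"}),
    "species": frozenset({"species"}),
    "button": frozenset({"button", "button?", "button (yes/no)"}),
    "button_label": frozenset(
        {"button label", "button_label", "abbreviation", "abbrev", "label"}
    ),
    "category": frozenset(
        {"category", "higher category", "higher_category", "group", "list"}
    ),
}

_TRUE = frozenset({"yes", "y", "true", "1"})
_FALSE = frozenset({"no", "n", "false", "0", ""})


def normalize_taxon_id(genus: str, species: str) -> str:
    """Stable key for a taxon: 'genus species' with collapsed whitespace."""
    return " ".join(f"{genus} {species}".split())


@dataclass(frozen=True)
class TaxonConfig:
    """One countable category as configured for the counting interface."""

    genus: str
    species: str
    button: bool = False
    button_label: str = ""
    category: str = ""
    extras: tuple[tuple[str, str], ...] = ()

    @property
    def taxon_id(self) -> str:
        return normalize_taxon_id(self.genus, self.species)

    @property
    def extras_dict(self) -> dict[str, str]:
        return dict(self.extras)

    def to_dict(self) -> dict:
        return {
            "genus": self.genus,
            "species": self.species,
            "button": self.button,
            "button_label": self.button_label,
            "category": self.category,
            "extras": dict(self.extras),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaxonConfig":
        return cls(
            genus=d["genus"],
            species=d["species"],
            button=bool(d.get("button", False)),
            button_label=d.get("button_label", ""),
            category=d.get("category", ""),
            extras=tuple((k, v) for k, v in dict(d.get("extras", {})).items()),
        )


def _canonical_header(name: str) -> str | None:
    key = " ".join(name.strip().lower().split())
    for canon, synonyms in HEADER_SYNONYMS.items():
        if key in synonyms:
            return canon
    return None


def _parse_button(cell: str, row_no: int) -> bool:
    val = cell.strip().lower()
    if val in _TRUE:
        return True
    if val in _FALSE:
        return False
    raise ConfigError(f"row {row_no}: cannot interpret button value {cell!r}")


def read_config(path) -> list[TaxonConfig]:
    """Parse a tab-delimited taxa configuration file, preserving row order.

    Raises :class:`ConfigError` for a missing mandatory column, an empty
    mandatory cell (reported with its 1-based data-row number), a duplicate
    (genus, species) pair, or an empty file.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    rows = [r for r in rows if any(cell.strip() for cell in r)]
    if not rows:
        raise ConfigError(f"{path}: empty configuration file")
    header = rows[0]
    mapping: list[tuple[int, str | None, str]] = []  # (col index, canon, original)
    for i, name in enumerate(header):
        mapping.append((i, _canonical_header(name), name.strip()))
    canon_cols = {canon: i for i, canon, _ in mapping if canon}
    missing = [c for c in ("genus", "species", "button") if c not in canon_cols]
    if missing:
        raise ConfigError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    extras_cols = [(i, orig) for i, canon, orig in mapping if canon is None and orig]

    taxa: list[TaxonConfig] = []
    seen: set[str] = set()
    for row_no, row in enumerate(rows[1:], start=1):
        cells = list(row) + [""] * (len(header) - len(row))

        def cell(canon: str) -> str:
            idx = canon_cols.get(canon)
            return cells[idx].strip() if idx is not None else ""

        genus, species = cell("genus"), cell("species")
        if not genus:
            raise ConfigError(f"row {row_no}: missing genus")
        if not species:
            raise ConfigError(f"row {row_no}: missing species")
        button = _parse_button(cell("button"), row_no)
        label = cell("button_label")
        if button and not label:
            raise ConfigError(f"row {row_no}: button label required when button=yes")
        taxon = TaxonConfig(
            genus=genus,
            species=species,
            button=button,
            button_label=label,
            category=cell("category"),
            extras=tuple((orig, cells[i].strip()) for i, orig in extras_cols),
        )
        if taxon.taxon_id in seen:
            raise ConfigError(f"row {row_no}: duplicate taxon {taxon.taxon_id!r}")
        seen.add(taxon.taxon_id)
        taxa.append(taxon)
    return taxa


def write_config(taxa: Iterable[TaxonConfig], path) -> None:
    """Write taxa back to tab-text so that :func:`read_config` round-trips."""
    taxa = list(taxa)
    extras_keys: list[str] = []
    for t in taxa:
        for k, _ in t.extras:
            if k not in extras_keys:
                extras_keys.append(k)
    header = ["genus", "species", "button", "button label", "category", *extras_keys]
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for t in taxa:
            ex = t.extras_dict
            writer.writerow(
                [
                    t.genus,
                    t.species,
                    "yes" if t.button else "no",
                    t.button_label,
                    t.category,
                    *[ex.get(k, "") for k in extras_keys],
                ]
            )


def group_by_category(taxa: Iterable[TaxonConfig]) -> dict[str, list[TaxonConfig]]:
    """Partition taxa into higher-category groups, in first-appearance order.

    Taxa with an empty category cell are collected under
    :data:`DEFAULT_CATEGORY`.  The returned mapping is an ordered partition
    of the input: every taxon appears in exactly one group.
    """
    groups: dict[str, list[TaxonConfig]] = {}
    for t in taxa:
        key = t.category or DEFAULT_CATEGORY
        groups.setdefault(key, []).append(t)
    return groups
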
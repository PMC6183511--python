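"""Stratigraphic Occurrence Data (SOD) files: read, write, validate.

SOD is a versioned, self-labelling, spreadsheet-style tab-text format for
occurrence matrices with rich metadata, laid out in four blocks:

    A (upper left)   file metadata as  ``label: value`` rows
    B (upper right)  per-sample metadata: a label column and one value
                     column per sample
    C (lower left)   per-taxon metadata rows (genus, species, author, ...)
    D (lower right)  the taxa × samples occurrence (count) matrix

Every data cell has an adjacent label: A/B values sit next to their label
cells, each D row is labelled by its C taxon row and each D column by its
B sample column, so files are largely self-documenting.  The format version
is the first file-metadata field; the ``File type`` field selects a dialect
— ``O`` for ocean-drilling samples (Site-Hole-Core-Section-Interval naming)
or ``L`` for land sections (region/section/formation/lithology/level).

Which labels belong where is governed by a field-definition table.  The v1
table for both dialects ships as package data
(``data/sod_fields_v1.tsv``) and can be replaced by a user-edited file via
:func:`load_definitions`; new file types or versions are added by editing
the table, not the code.

Counting sessions write one sample column per file, but the format allows
sample columns to repeat indefinitely.  Two-phase counts store raw
integer totals in block D, with per-phase track counts, the exclusion
threshold and per-taxon exclusion flags in metadata, so the effort-scaled
combined estimates are recomputable from the file alone
(:func:`estimates_from_sod`).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .config_io import normalize_taxon_id
from .engine import CountSession
from .errors import SODFormatError, SODValidationError
from .stats import AbundanceEstimate, combined_estimates

__all__ = [
    "FieldDefinition",
    "SODDocument",
    "Finding",
    "load_definitions",
    "read_sod",
    "write_sod",
    "validate_sod",
    "session_to_sod",
    "estimates_from_sod",
    "sod_to_long",
]

COUNTS_LABEL = "Counts:"
VERSION_LABEL = "SOD version"
FILE_TYPE_LABEL = "File type"


@dataclass(frozen=True)
class FieldDefinition:
    """Ordered field labels (with required flags) for one file type + version."""

    file_type: str
    version: str
    blocks: dict  # block letter -> list of (label, required)

    def labels(self, block: str) -> list[str]:
        return [lab for lab, _ in self.blocks.get(block, [])]

    def required(self, block: str) -> list[str]:
        return [lab for lab, req in self.blocks.get(block, []) if req]


def load_definitions(path=None) -> dict[tuple[str, str], FieldDefinition]:
    """Load a field-definition table (default: the packaged v1 table).

    The table is tab-text with columns file_type, version, block, label,
    required; row order fixes field order within each block.
    """
    if path is None:
        text = (
            resources.files("raricount").joinpath("data/sod_fields_v1.tsv").read_text("utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    rows = list(csv.reader(text.splitlines(), delimiter="\t"))
    header = rows[0]
    expected = ["file_type", "version", "block", "label", "required"]
    if header != expected:
        raise SODFormatError(f"definition table header must be {expected}, got {header}")
    defs: dict[tuple[str, str], dict] = {}
    for ft, ver, block, label, req in rows[1:]:
        blocks = defs.setdefault((ft, ver), {})
        blocks.setdefault(block, []).append((label, req.strip().lower() == "yes"))
    return {
        key: FieldDefinition(file_type=key[0], version=key[1], blocks=blocks)
        for key, blocks in defs.items()
    }


@dataclass
class SODDocument:
    """In-memory four-block SOD document.

    ``sample_metadata`` maps each block-B label to a list of values aligned
    with the sample columns; the mandatory ``Sample`` row carries the sample
    names.  ``taxa`` is a list of dicts keyed by the block-C column labels
    in ``taxa_fields``; ``occurrences`` is a taxa × samples list of
    nonnegative integer counts.
    """

    file_metadata: dict = field(default_factory=dict)
    sample_metadata: dict = field(default_factory=dict)
    taxa_fields: list = field(default_factory=lambda: ["Genus", "Species", "Author", "Excluded"])
    taxa: list = field(default_factory=list)
    occurrences: list = field(default_factory=list)

    @property
    def version(self) -> str:
        return self.file_metadata.get(VERSION_LABEL, "")

    @property
    def file_type(self) -> str:
        return self.file_metadata.get(FILE_TYPE_LABEL, "")

    @property
    def sample_names(self) -> list[str]:
        return list(self.sample_metadata.get("Sample", []))

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)

    def taxon_id(self, row: int) -> str:
        t = self.taxa[row]
        return normalize_taxon_id(t.get("Genus", ""), t.get("Species", ""))


@dataclass(frozen=True)
class Finding:
    """One validation finding; ``level`` is 'error' or 'warning'.

    Coordinates, where given, are 1-based spreadsheet row/column numbers.
    """

    level: str
    block: str
    label: str
    message: str

    def __str__(self) -> str:
        return f"[{self.level}] block {self.block}, {self.label}: {self.message}"


# ---------------------------------------------------------------------------
# grid layout


def _doc_to_grid(doc: SODDocument) -> list[list[str]]:
    left = len(doc.taxa_fields)
    label_col = left
    width = left + 1 + doc.n_samples
    a_items = list(doc.file_metadata.items())
    b_items = list(doc.sample_metadata.items())
    top_h = max(len(a_items), len(b_items))
    grid: list[list[str]] = []
    for i in range(top_h):
        row = [""] * width
        if i < len(a_items):
            row[0] = a_items[i][0] + ":"
            row[1] = a_items[i][1]
        if i < len(b_items):
            row[label_col] = b_items[i][0] + ":"
            vals = b_items[i][1]
            for j in range(doc.n_samples):
                row[label_col + 1 + j] = str(vals[j]) if j < len(vals) else ""
        grid.append(row)
    header = [""] * width
    header[:left] = doc.taxa_fields
    header[label_col] = COUNTS_LABEL
    header[label_col + 1 :] = doc.sample_names
    grid.append(header)
    for r, taxon in enumerate(doc.taxa):
        row = [""] * width
        for c, lab in enumerate(doc.taxa_fields):
            row[c] = str(taxon.get(lab, ""))
        for j in range(doc.n_samples):
            row[label_col + 1 + j] = str(int(doc.occurrences[r][j]))
        grid.append(row)
    return grid


def write_sod(doc: SODDocument, path, definitions=None) -> None:
    """Validate and write the document as a UTF-8 tab-delimited grid."""
    findings = validate_sod(doc, definitions)
    errors = [f for f in findings if f.level == "error"]
    if errors:
        raise SODValidationError(
            "document fails validation:\n" + "\n".join(map(str, errors)), findings
        )
    grid = _doc_to_grid(doc)
    text = "\n".join("\t".join(row) for row in grid) + "\n"
    Path(path).write_text(text, encoding="utf-8")


def read_sod(path, definitions=None) -> SODDocument:
    """Parse a SOD grid back into a document.

    ``read_sod(write_sod(doc))`` restores the document field-for-field with
    bit-exact counts.  Structural problems (no taxa header, missing Counts
    label, non-integer or missing count cells, label/sample mismatches,
    unknown version) raise :class:`SODFormatError` naming the offending
    1-based grid cell.
    """
    definitions = definitions if definitions is not None else load_definitions()
    text = Path(path).read_text(encoding="utf-8")
    rows = [line.split("\t") for line in text.splitlines()]
    header_idx = next((i for i, r in enumerate(rows) if r and r[0] == "Genus"), None)
    if header_idx is None:
        raise SODFormatError(f"{path}: no taxa header row (column 1 cell 'Genus') found")
    header = rows[header_idx]
    if COUNTS_LABEL not in header:
        raise SODFormatError(
            f"{path}: row {header_idx + 1} lacks the {COUNTS_LABEL!r} label cell"
        )
    label_col = header.index(COUNTS_LABEL)
    taxa_fields = header[:label_col]
    sample_names = [c for c in header[label_col + 1 :]]
    while sample_names and sample_names[-1] == "":
        sample_names.pop()
    n_samples = len(sample_names)

    file_metadata: dict[str, str] = {}
    sample_metadata: dict[str, list[str]] = {}
    for i in range(header_idx):
        row = rows[i] + [""] * (label_col + 1 + n_samples - len(rows[i]))
        if row[0]:
            if not row[0].endswith(":"):
                raise SODFormatError(
                    f"{path}: row {i + 1} col 1: metadata label {row[0]!r} lacks ':'"
                )
            label = row[0][:-1]
            if label in file_metadata:
                raise SODFormatError(f"{path}: row {i + 1} col 1: duplicate label {label!r}")
            file_metadata[label] = row[1]
        if row[label_col]:
            if not row[label_col].endswith(":"):
                raise SODFormatError(
                    f"{path}: row {i + 1} col {label_col + 1}: sample label "
                    f"{row[label_col]!r} lacks ':'"
                )
            label = row[label_col][:-1]
            if label in sample_metadata:
                raise SODFormatError(
                    f"{path}: row {i + 1} col {label_col + 1}: duplicate label {label!r}"
                )
            sample_metadata[label] = row[label_col + 1 : label_col + 1 + n_samples]
    if sample_metadata.get("Sample", []) != sample_names:
        raise SODFormatError(
            f"{path}: 'Sample:' metadata row does not match the sample names in the "
            f"taxa header row {header_idx + 1}"
        )

    taxa: list[dict] = []
    occurrences: list[list[int]] = []
    for i in range(header_idx + 1, len(rows)):
        row = rows[i]
        if not any(c.strip() for c in row):
            continue
        row = row + [""] * (label_col + 1 + n_samples - len(row))
        taxa.append({lab: row[c] for c, lab in enumerate(taxa_fields)})
        counts = []
        for j in range(n_samples):
            cell = row[label_col + 1 + j]
            try:
                val = int(cell)
            except ValueError:
                raise SODFormatError(
                    f"{path}: row {i + 1} col {label_col + 2 + j}: "
                    f"count cell {cell!r} is not an integer"
                ) from None
            counts.append(val)
        occurrences.append(counts)

    doc = SODDocument(
        file_metadata=file_metadata,
        sample_metadata=sample_metadata,
        taxa_fields=taxa_fields,
        taxa=taxa,
        occurrences=occurrences,
    )
    key = (doc.file_type, doc.version)
    if key not in definitions:
        raise SODFormatError(
            f"{path}: unknown file type/version combination {key!r}"
        )
    return doc


def validate_sod(doc: SODDocument, definitions=None) -> list[Finding]:
    """Cross-check a document against its field definition.

    Returns an empty list iff all invariants and definition requirements
    hold.  Unknown optional labels yield warnings, not errors.
    """
    definitions = definitions if definitions is not None else load_definitions()
    findings: list[Finding] = []

    def err(block, label, msg):
        findings.append(Finding("error", block, label, msg))

    def warn(block, label, msg):
        findings.append(Finding("warning", block, label, msg))

    if not doc.version:
        err("A", VERSION_LABEL, "missing format version (must be the first metadata field)")
    if doc.file_type not in {ft for ft, _ in definitions}:
        err("A", FILE_TYPE_LABEL, f"unknown file type {doc.file_type!r}")
    defn = definitions.get((doc.file_type, doc.version))
    if defn is None:
        if doc.version and doc.file_type:
            err("A", VERSION_LABEL, f"no definition for type {doc.file_type!r} version {doc.version!r}")
    else:
        for label in defn.required("A"):
            if not doc.file_metadata.get(label, ""):
                err("A", label, "required field missing or empty")
        for label in doc.file_metadata:
            if label not in defn.labels("A"):
                warn("A", label, "label not in the field definition (preserved as-is)")
        for label in defn.required("B"):
            vals = doc.sample_metadata.get(label)
            if vals is None or any(not v for v in vals):
                err("B", label, "required field missing or empty for some sample")
        for label in doc.sample_metadata:
            if label not in defn.labels("B"):
                warn("B", label, "label not in the field definition (preserved as-is)")
        for label in defn.required("C"):
            if label not in doc.taxa_fields:
                err("C", label, "required taxa-metadata column missing")
            else:
                for r, taxon in enumerate(doc.taxa):
                    if not taxon.get(label, ""):
                        err("C", f"{label} row {r + 1}", "required value empty")

    keys = [doc.taxon_id(r) for r in range(len(doc.taxa))]
    dupes = {k for k in keys if keys.count(k) > 1}
    for d in sorted(dupes):
        err("C", d, "duplicate taxon")

    n_samples = doc.n_samples
    for label, vals in doc.sample_metadata.items():
        if len(vals) != n_samples:
            err("B", label, f"{len(vals)} values for {n_samples} samples")
    if len(doc.occurrences) != len(doc.taxa):
        err("D", "matrix", f"{len(doc.occurrences)} count rows for {len(doc.taxa)} taxa")
    for r, row in enumerate(doc.occurrences):
        if len(row) != n_samples:
            err("D", f"row {r + 1}", f"{len(row)} counts for {n_samples} samples")
        for j, v in enumerate(row):
            if not isinstance(v, int) or v < 0:
                err("D", f"row {r + 1} sample {j + 1}", f"count {v!r} is not a nonnegative integer")
    return findings


# ---------------------------------------------------------------------------
# session bridge


def session_to_sod(
    session: CountSession,
    metadata: Mapping[str, str],
    file_type: str = "O",
    threshold: float | None = None,
    definitions=None,
) -> SODDocument:
    """Build a single-sample SOD document from a completed counting session.

    Raw per-taxon totals go into block D; per-phase track counts, the
    exclusion threshold and per-taxon exclusion flags into metadata, so the
    effort-scaled estimates can be recomputed from the file alone.
    ``metadata`` supplies the dialect's file and sample fields (merged over
    the session's own sample metadata); missing mandatory fields raise
    :class:`SODValidationError`.
    """
    definitions = definitions if definitions is not None else load_definitions()
    defn = definitions.get((file_type, "1"))
    if defn is None:
        raise SODValidationError(f"no v1 definition for file type {file_type!r}")
    merged = {**session.sample_metadata, **dict(metadata)}
    file_metadata = {VERSION_LABEL: "1", FILE_TYPE_LABEL: file_type}
    for label in defn.labels("A"):
        if label in (VERSION_LABEL, FILE_TYPE_LABEL):
            continue
        file_metadata[label] = str(merged.get(label, ""))
    sample_metadata: dict[str, list[str]] = {}
    for label in defn.labels("B"):
        if label == "Tracks (full)":
            val = str(session.tracks_full)
        elif label == "Tracks (rare)":
            val = str(session.tracks_rare)
        elif label == "Exclusion threshold (%)":
            val = f"{threshold * 100:g}" if threshold is not None else ""
        else:
            val = str(merged.get(label, ""))
        sample_metadata[label] = [val]
    tally = session.tally()
    taxa_rows = []
    occurrences = []
    for t in session.taxa:
        taxa_rows.append(
            {
                "Genus": t.genus,
                "Species": t.species,
                "Author": t.extras_dict.get("author", t.extras_dict.get("Author", "")),
                "Excluded": "yes" if t.taxon_id in session.exclusions else "no",
            }
        )
        occurrences.append([tally.total(t.taxon_id)])
    doc = SODDocument(
        file_metadata=file_metadata,
        sample_metadata=sample_metadata,
        taxa_fields=["Genus", "Species", "Author", "Excluded"],
        taxa=taxa_rows,
        occurrences=occurrences,
    )
    errors = [f for f in validate_sod(doc, definitions) if f.level == "error"]
    if errors:
        raise SODValidationError(
            "missing mandatory metadata:\n" + "\n".join(map(str, errors)), errors
        )
    return doc


def estimates_from_sod(doc: SODDocument, sample: int = 0) -> list[AbundanceEstimate]:
    """Recompute effort-scaled combined estimates from a written document.

    Uses the stored per-phase track counts and exclusion flags; for an
    excluded taxon the stored count is its full-phase total (nothing was
    recorded for it in the rare phase), so the same scaling
    n·(1 + T_rare/T_full) applies.
    """
    def _track(label):
        vals = doc.sample_metadata.get(label, [])
        v = vals[sample] if sample < len(vals) else ""
        return int(v) if v else 0

    T_full, T_rare = _track("Tracks (full)"), _track("Tracks (rare)")
    excluded = {
        doc.taxon_id(r)
        for r, t in enumerate(doc.taxa)
        if t.get("Excluded", "").strip().lower() == "yes"
    }
    if excluded and T_rare > 0 and T_full == 0:
        raise SODValidationError("effort undefined: exclusions with rare tracks but no full tracks")
    factor = 1.0 + (T_rare / T_full if (T_rare > 0 and T_full > 0) else 0.0)
    entries = []
    for r in range(len(doc.taxa)):
        tid = doc.taxon_id(r)
        count = doc.occurrences[r][sample]
        if tid in excluded:
            entries.append((tid, count * factor, "effort_scaled"))
        else:
            entries.append((tid, float(count), "observed"))
    total = sum(e[1] for e in entries)
    if total <= 0:
        raise ValueError("no counts in document: proportions undefined")
    entries.sort(key=lambda e: (-e[1], e[0]))
    return [AbundanceEstimate(t, c, c / total, b) for t, c, b in entries]


def sod_to_long(doc: SODDocument, keep_zeros: bool = True) -> pd.DataFrame:
    """Tidy long-format occurrence table: one row per (taxon, sample).

    Carries the taxon-metadata columns and every per-sample metadata field;
    with ``keep_zeros=False`` only rows with positive counts are kept.
    Counts are lossless with respect to block D.
    """
    records = []
    for r, taxon in enumerate(doc.taxa):
        for j, name in enumerate(doc.sample_names):
            count = doc.occurrences[r][j]
            if not keep_zeros and count == 0:
                continue
            rec = {"sample": name, "taxon_id": doc.taxon_id(r)}
            rec.update({k.lower(): v for k, v in taxon.items()})
            for label, vals in doc.sample_metadata.items():
                if label == "Sample":
                    continue
                rec[label] = vals[j] if j < len(vals) else ""
            rec["count"] = count
            records.append(rec)
    return pd.DataFrame.from_records(records)
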
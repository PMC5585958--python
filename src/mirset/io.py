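"""Reading interaction / annotation / query files and writing the results table.

Input formats
-------------
* Interaction file: delimited text (default comma), 2+ columns;
  column 1 = miRNA id, column 2 = gene id, extra columns ignored.
* Annotation file: delimited text, 2-3 columns; column 1 = gene id,
  column 2 = category id, column 3 = category name (defaults to the id).
* Query file: one miRNA id per line, or a single comma-separated line;
  lines starting with ``#`` are ignored everywhere.

Identifiers are trimmed of surrounding whitespace; comparison is
case-sensitive by default because miRNA nomenclature is case-significant
(miR- vs mir- prefixes), with an opt-in case-folding flag.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .errors import FormatError, InputError
from .result import EnrichmentResult, sort_key

logger = logging.getLogger(__name__)

#: enough digits to distinguish 1/N at N = 10**6
_P_FORMAT = "{:.7f}"
_NA = "NA"

RESULT_COLUMNS = (
    "category_id",
    "category_name",
    "category_size",
    "overlap_count",
    "overlap_proportion",
    "empirical_p_value",
    "significance",
)


@dataclass
class IOConfig:
    """Parsing options shared by the tabular readers."""

    delimiter: str = ","
    case_fold: bool = False
    #: skip a first line whose first field equals this token (None = keep all)
    header_token: str | None = None
    #: skip the first non-comment line unconditionally
    skip_header: bool = False
    #: malformed lines abort instead of being skipped with a warning
    strict: bool = False
    comment_char: str = "#"


@dataclass
class LoadReport:
    """Bookkeeping from one file load."""

    path: str = ""
    raw_lines: int = 0
    records: int = 0          # collapsed, retained records
    duplicates: int = 0       # records collapsed as exact duplicates
    skipped_malformed: int = 0
    name_conflicts: int = 0   # annotation names differing from the first seen


@dataclass
class InteractionTable:
    """Collapsed (miRNA id, gene id) pairs; every miRNA has >= 1 target."""

    entries: list[tuple[str, str]]
    report: LoadReport = field(default_factory=LoadReport)

    def mirna_ids(self) -> list[str]:
        return sorted({m for m, _ in self.entries})

    def targets_of(self, mirna_id: str) -> set[str]:
        return {g for m, g in self.entries if m == mirna_id}


@dataclass
class AnnotationTable:
    """Collapsed (gene id, category id, category name) triples."""

    entries: list[tuple[str, str, str]]
    report: LoadReport = field(default_factory=LoadReport)

    def category_ids(self) -> list[str]:
        return sorted({c for _, c, _ in self.entries})


@dataclass
class QueryGroup:
    """Ordered list of distinct miRNA identifiers under examination."""

    mirna_ids: list[str]

    def __len__(self) -> int:
        return len(self.mirna_ids)


def normalize_id(raw: str, case_fold: bool = False) -> str:
    """Trim surrounding whitespace; optionally case-fold. Idempotent."""
    s = raw.strip()
    return s.casefold() if case_fold else s


def _data_lines(path: str | Path, config: IOConfig):
    p = Path(path)
    if not p.is_file():
        raise InputError(f"input file not found: {p}")
    first_data_line = True
    with open(p, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(config.comment_char):
                continue
            fields = [normalize_id(f, config.case_fold) for f in stripped.split(config.delimiter)]
            if first_data_line:
                first_data_line = False
                if config.skip_header or (
                    config.header_token is not None and fields and fields[0] == config.header_token
                ):
                    continue
            yield lineno, fields


def read_interactions(path: str | Path, config: IOConfig | None = None) -> InteractionTable:
    """Load a miRNA-to-gene interaction table, collapsing duplicate pairs."""
    config = config or IOConfig()
    report = LoadReport(path=str(path))
    seen: set[tuple[str, str]] = set()
    entries: list[tuple[str, str]] = []
    for lineno, fields in _data_lines(path, config):
        report.raw_lines += 1
        if len(fields) < 2 or not fields[0] or not fields[1]:
            if config.strict:
                raise FormatError(f"{path}:{lineno}: expected >=2 delimited fields")
            report.skipped_malformed += 1
            logger.warning("%s:%d: malformed interaction line skipped", path, lineno)
            continue
        pair = (fields[0], fields[1])
        if pair in seen:
            report.duplicates += 1
            continue
        seen.add(pair)
        entries.append(pair)
    if not entries:
        raise FormatError(f"{path}: no valid miRNA-gene interaction records")
    report.records = len(entries)
    return InteractionTable(entries, report)


def read_annotations(path: str | Path, config: IOConfig | None = None) -> AnnotationTable:
    """Load gene-to-category annotations, collapsing duplicate (gene, category) pairs.

    The category name is fixed by its first occurrence; later conflicting
    names are logged and counted in the load report.
    """
    config = config or IOConfig()
    report = LoadReport(path=str(path))
    names: dict[str, str] = {}
    seen: set[tuple[str, str]] = set()
    raw: list[tuple[str, str]] = []
    for lineno, fields in _data_lines(path, config):
        report.raw_lines += 1
        if len(fields) < 2 or not fields[0] or not fields[1]:
            if config.strict:
                raise FormatError(f"{path}:{lineno}: expected >=2 delimited fields")
            report.skipped_malformed += 1
            logger.warning("%s:%d: malformed annotation line skipped", path, lineno)
            continue
        gene_id, cat_id = fields[0], fields[1]
        name = fields[2] if len(fields) > 2 and fields[2] else cat_id
        if cat_id in names:
            if names[cat_id] != name:
                report.name_conflicts += 1
                logger.warning(
                    "%s:%d: category %s renamed %r -> kept first name %r",
                    path, lineno, cat_id, name, names[cat_id],
                )
        else:
            names[cat_id] = name
        key = (gene_id, cat_id)
        if key in seen:
            report.duplicates += 1
            continue
        seen.add(key)
        raw.append(key)
    if not raw:
        raise FormatError(f"{path}: no valid gene-annotation records")
    entries = [(g, c, names[c]) for g, c in raw]
    report.records = len(entries)
    return AnnotationTable(entries, report)


def read_query(path: str | Path, config: IOConfig | None = None) -> QueryGroup:
    """Load the query miRNA group: distinct ids, input order preserved."""
    config = config or IOConfig()
    p = Path(path)
    if not p.is_file():
        raise InputError(f"query file not found: {p}")
    ids: list[str] = []
    seen: set[str] = set()
    dup = 0
    with open(p, "r", encoding="utf-8") as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped or stripped.startswith(config.comment_char):
                continue
            for token in stripped.split(","):
                mirna = normalize_id(token, config.case_fold)
                if not mirna:
                    continue
                if mirna in seen:
                    dup += 1
                    continue
                seen.add(mirna)
                ids.append(mirna)
    if dup:
        logger.warning("%s: %d duplicate query miRNA id(s) collapsed", path, dup)
    if not ids:
        raise FormatError(f"{path}: empty query miRNA group")
    return QueryGroup(ids)


def format_p(p: float | None) -> str:
    return _NA if p is None else _P_FORMAT.format(p)


def write_results(
    results: Sequence[EnrichmentResult], path: str | Path, delimiter: str = ","
) -> None:
    """Write the results table, sorted by (empirical p, category id), NA rows last.

    The file is written to a temporary sibling and renamed into place, so a
    fatal error never leaves a partial output file.
    """
    ordered = sorted(results, key=sort_key)
    p = Path(path)
    try:
        fd, tmp = tempfile.mkstemp(dir=p.parent or Path("."), prefix=p.name, suffix=".tmp")
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(delimiter.join(RESULT_COLUMNS) + "\n")
            for r in ordered:
                fh.write(
                    delimiter.join(
                        (
                            r.category_id,
                            r.category_name,
                            str(r.category_size),
                            str(r.overlap_count),
                            _P_FORMAT.format(r.overlap_proportion),
                            format_p(r.empirical_p),
                            r.significance if r.significance is not None else _NA,
                        )
                    )
                    + "\n"
                )
        os.replace(tmp, p)
    except OSError as exc:
        raise InputError(f"cannot write results to {p}: {exc}") from exc


def read_results(path: str | Path, delimiter: str = ",") -> list[EnrichmentResult]:
    """Re-parse a results file (round-trip support for pipelines and tests)."""
    p = Path(path)
    if not p.is_file():
        raise InputError(f"results file not found: {p}")
    out: list[EnrichmentResult] = []
    with open(p, "r", encoding="utf-8") as fh:
        header = fh.readline().strip().split(delimiter)
        if tuple(header) != RESULT_COLUMNS:
            raise FormatError(f"{p}: unexpected results header {header}")
        for line in fh:
            f = line.rstrip("\n").split(delimiter)
            if len(f) != len(RESULT_COLUMNS):
                raise FormatError(f"{p}: malformed results row {f}")
            out.append(
                EnrichmentResult(
                    category_id=f[0],
                    category_name=f[1],
                    category_size=int(f[2]),
                    overlap_count=int(f[3]),
                    overlap_proportion=float(f[4]),
                    empirical_p=None if f[5] == _NA else float(f[5]),
                    significance=None if f[6] == _NA else f[6],
                )
            )
    return out
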
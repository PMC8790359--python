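"""Reading, normalising and writing condition-mention records.

Two record shapes flow through the pipeline: flat mention records (one row
per extracted condition mention, tied to a source record and a corpus tag)
and per-report condition sets (one dream report = one set of distinct
conditions). Normalisation is deliberately conservative: lowercasing and
whitespace collapsing only, with no stemming and no merging of surface
variants — "coronavirus" and "corona virus" stay distinct conditions, since
merging would silently change every downstream frequency rank.

A small lexicon matcher is included as demo plumbing for turning free text
into mentions; it is a longest-match word-boundary scanner, not a clinical
NER system.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "MentionRecord",
    "ReportConditionSet",
    "InvalidMentionError",
    "MentionFormatError",
    "normalize_condition",
    "read_mentions",
    "read_reports",
    "write_mentions_tsv",
    "write_reports_jsonl",
    "lexicon_extract",
]


class InvalidMentionError(ValueError):
    """Raised for a condition string that is empty after normalisation."""


class MentionFormatError(ValueError):
    """Raised when a mention file is mostly unparseable."""


@dataclass(frozen=True)
class MentionRecord:
    """One extracted condition mention tied to a source record and corpus."""

    record_id: str
    corpus_id: str
    condition: str


@dataclass(frozen=True)
class ReportConditionSet:
    """The set of distinct conditions mentioned in one dream report."""

    report_id: str
    conditions: frozenset[str]


_WS = re.compile(r"\s+")


def normalize_condition(raw: str) -> str:
    """Normalise a raw condition string.

    Lowercases and collapses internal whitespace to single spaces. No
    stemming and no variant merging: surface forms that differ in anything
    but case/whitespace remain distinct conditions.

    Raises
    ------
    InvalidMentionError
        If the string is empty after stripping.
    """
    norm = _WS.sub(" ", raw.strip()).lower()
    if not norm:
        raise InvalidMentionError(f"empty condition string: {raw!r}")
    return norm


# -- file I/O ---------------------------------------------------------------

_MENTION_COLUMNS = ("record_id", "corpus", "condition")


def read_mentions(path: str | Path, corpus_id: str) -> list[MentionRecord]:
    """Read a mention table (TSV with header, or JSONL) into records.

    Every well-formed row yields one :class:`MentionRecord` tagged with
    `corpus_id`. Malformed rows (wrong arity, empty condition) are logged
    and counted, never silently dropped; if more than half of the data rows
    are malformed the file is rejected with :class:`MentionFormatError`.
    """
    path = Path(path)
    records: list[MentionRecord] = []
    n_bad = 0
    n_rows = 0
    if path.suffix == ".jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                n_rows += 1
                try:
                    obj = json.loads(line)
                    records.append(
                        MentionRecord(
                            str(obj["record_id"]),
                            corpus_id,
                            normalize_condition(obj["condition"]),
                        )
                    )
                except (KeyError, TypeError, ValueError) as exc:
                    n_bad += 1
                    logger.warning("%s:%d malformed mention row: %s", path, lineno, exc)
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            try:
                header = next(reader)
            except StopIteration as exc:
                raise MentionFormatError(f"{path}: empty file") from exc
            if [h.strip() for h in header] != list(_MENTION_COLUMNS):
                raise MentionFormatError(
                    f"{path}: expected header {_MENTION_COLUMNS}, got {header}"
                )
            for lineno, row in enumerate(reader, 2):
                if not row:
                    continue
                n_rows += 1
                try:
                    if len(row) != 3:
                        raise InvalidMentionError(f"expected 3 fields, got {len(row)}")
                    records.append(
                        MentionRecord(row[0], corpus_id, normalize_condition(row[2]))
                    )
                except InvalidMentionError as exc:
                    n_bad += 1
                    logger.warning("%s:%d malformed mention row: %s", path, lineno, exc)
    if n_rows and n_bad / n_rows > 0.5:
        raise MentionFormatError(f"{path}: {n_bad}/{n_rows} rows malformed")
    if n_bad:
        logger.info("%s: rejected %d of %d rows", path, n_bad, n_rows)
    return records


def read_reports(path: str | Path) -> list[ReportConditionSet]:
    """Read a JSONL report file (one object per report) into condition sets."""
    path = Path(path)
    reports: list[ReportConditionSet] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            obj = json.loads(line)
            conditions = frozenset(normalize_condition(c) for c in obj["conditions"])
            reports.append(ReportConditionSet(str(obj["id"]), conditions))
    return reports


def write_mentions_tsv(records: Iterable[MentionRecord], path: str | Path) -> None:
    """Write mention records as a TSV table (record_id, corpus, condition)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_MENTION_COLUMNS)
        for rec in records:
            writer.writerow([rec.record_id, rec.corpus_id, rec.condition])


def write_reports_jsonl(reports: Iterable[ReportConditionSet], path: str | Path) -> None:
    """Write reports as JSONL, one ``{"id": ..., "conditions": [...]}`` per line."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rep in reports:
            fh.write(
                json.dumps(
                    {"id": rep.report_id, "conditions": sorted(rep.conditions)},
                    ensure_ascii=False,
                )
                + "\n"
            )


# -- lexicon matching -------------------------------------------------------

_TOKEN = re.compile(r"\w+")


def lexicon_extract(text: str, lexicon: Iterable[str]) -> set[str]:
    """Extract lexicon conditions from free text.

    Case-insensitive scan on word boundaries, longest match first: at each
    token position the longest lexicon phrase that matches is taken and the
    scan resumes after it, so shorter phrases overlapping a longer match are
    suppressed ("dry cough" wins over "cough"). An empty lexicon yields an
    empty set. This is demo plumbing standing in for a real clinical
    concept extractor.
    """
    phrases = {tuple(_TOKEN.findall(p.lower())): p for p in lexicon}
    phrases.pop((), None)
    if not phrases:
        return set()
    max_len = max(len(k) for k in phrases)
    tokens = _TOKEN.findall(text.lower())
    found: set[str] = set()
    i = 0
    while i < len(tokens):
        for width in range(min(max_len, len(tokens) - i), 0, -1):
            key = tuple(tokens[i : i + width])
            if key in phrases:
                found.add(normalize_condition(phrases[key]))
                i += width
                break
        else:
            i += 1
    return found
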
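"""Reading, validating and summarising pile-sort studies.

A pile-sort study consists of a panel of sorters (in participatory theme
elicitation these are co-researchers with lived experience) who each
independently group a fixed list of quotes into self-defined piles.  The
on-disk format is a three-column delimited table — sorter id, quote id,
pile label — the same shape a facilitator would transcribe from stapled
paper piles into a spreadsheet.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

import pandas as pd

from .errors import InputError, ValidationError, ValidationWarning
from .partitions import Partition

__all__ = [
    "Quote",
    "SortRecord",
    "SortingStudy",
    "StudySummary",
    "read_sort_table",
    "read_quote_texts",
    "write_sort_table",
    "sorter_partition",
    "summarize",
    "validate_study",
    "DEFAULT_COLUMNS",
    "TYPICAL_PILE_RANGE",
]

DEFAULT_COLUMNS = ("sorter_id", "quote_id", "pile")

#: Pile counts per sorter observed in practice; counts outside this range are
#: legal but flagged by the validator as worth a second look.
TYPICAL_PILE_RANGE = (3, 12)

PathOrStream = Union[str, Path, IO[str]]


@dataclass(frozen=True)
class Quote:
    """A qualitative excerpt, identified by an opaque id.

    The verbatim text is optional: the sorting table itself only carries ids,
    and the text is supplied separately when reports need it.
    """

    id: str
    text: Optional[str] = None

    def __post_init__(self):
        if not self.id:
            raise ValidationError("quote id must be non-empty")


@dataclass(frozen=True)
class SortRecord:
    """One sorter placing one quote into one pile.

    Pile identity is the pair ``(sorter_id, pile_label)``: the label "2" used
    by two different sorters names two unrelated piles.
    """

    sorter_id: str
    quote_id: str
    pile_label: str


class SortingStudy:
    """A validated pile-sort dataset: quotes, sorters and their assignments.

    Invariants enforced at construction: quote ids unique; at most one pile
    per (sorter, quote) pair; every record's quote id present in the quote
    set.  Quotes a sorter left unsorted are permitted (flagged by
    :func:`validate_study`, not rejected) — co-occurrence counts simply omit
    those pairs for that sorter.
    """

    def __init__(
        self,
        records: Iterable[SortRecord],
        quotes: Optional[Iterable[Quote]] = None,
    ):
        records = list(records)
        explicit = quotes is not None
        quote_map: dict[str, Quote] = {}
        if explicit:
            for q in quotes:  # type: ignore[union-attr]
                if q.id in quote_map:
                    raise ValidationError(f"duplicate quote id {q.id!r}")
                quote_map[q.id] = q

        assignments: dict[tuple[str, str], str] = {}
        for rec in records:
            key = (rec.sorter_id, rec.quote_id)
            if key in assignments:
                if assignments[key] != rec.pile_label:
                    raise ValidationError(
                        f"sorter {rec.sorter_id!r} placed quote {rec.quote_id!r} "
                        f"in two piles ({assignments[key]!r} and {rec.pile_label!r})"
                    )
                continue  # exact duplicate row: harmless
            if explicit and rec.quote_id not in quote_map:
                raise ValidationError(
                    f"record references unknown quote id {rec.quote_id!r}"
                )
            assignments[key] = rec.pile_label

        if not explicit:
            for (_, qid) in assignments:
                quote_map.setdefault(qid, Quote(qid))

        self._quotes = quote_map
        self._assignments = assignments

    # -- views -------------------------------------------------------------

    @property
    def quotes(self) -> dict[str, Quote]:
        return dict(self._quotes)

    @property
    def quote_ids(self) -> list[str]:
        return sorted(self._quotes)

    @property
    def sorters(self) -> list[str]:
        return sorted({s for (s, _) in self._assignments})

    @property
    def n_quotes(self) -> int:
        return len(self._quotes)

    @property
    def n_sorters(self) -> int:
        return len(self.sorters)

    def records(self) -> list[SortRecord]:
        """Canonical record list, sorted by sorter then quote id."""
        return [
            SortRecord(s, q, p)
            for (s, q), p in sorted(self._assignments.items())
        ]

    def pile_of(self, sorter_id: str, quote_id: str) -> Optional[str]:
        return self._assignments.get((sorter_id, quote_id))

    def __eq__(self, other) -> bool:
        if not isinstance(other, SortingStudy):
            return NotImplemented
        return (
            self._assignments == other._assignments
            and self._quotes == other._quotes
        )

    def __repr__(self) -> str:
        return (
            f"SortingStudy({self.n_sorters} sorters, {self.n_quotes} quotes, "
            f"{len(self._assignments)} assignments)"
        )


@dataclass(frozen=True)
class StudySummary:
    n_sorters: int
    n_quotes: int
    piles_per_sorter: dict = field(default_factory=dict)
    coverage: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sorter_id": sorted(self.piles_per_sorter),
                "n_piles": [self.piles_per_sorter[s] for s in sorted(self.piles_per_sorter)],
                "coverage": [self.coverage[s] for s in sorted(self.coverage)],
            }
        )


# ---------------------------------------------------------------------------
# I/O


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_sort_table(
    source: PathOrStream,
    *,
    delimiter: Optional[str] = None,
    columns: Sequence[str] = DEFAULT_COLUMNS,
    quotes: Optional[Iterable[Quote]] = None,
    warn: bool = True,
) -> SortingStudy:
    """Read a sorting table (CSV/TSV) into a validated :class:`SortingStudy`.

    Parameters
    ----------
    source
        Path or open text stream.  The first line must be a header naming the
        three ``columns`` (extra columns are ignored).
    delimiter
        ``','`` or ``'\\t'``; auto-detected from the header line when None.
    columns
        Names of the (sorter id, quote id, pile label) columns.
    quotes
        Optional explicit quote list; any record referencing a quote outside
        it is a hard error, and unreferenced quotes become isolated nodes
        downstream.
    warn
        Emit :class:`ValidationWarning` for unusual but legal structure.

    Row order never affects the result.
    """
    if hasattr(source, "read"):
        text = source.read()  # type: ignore[union-attr]
    else:
        path = Path(source)  # type: ignore[arg-type]
        if not path.exists():
            raise InputError(f"no such file: {path}")
        text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise InputError("empty sorting table")

    if delimiter is None:
        delimiter = _detect_delimiter(text.splitlines()[0])

    try:
        df = pd.read_csv(io.StringIO(text), sep=delimiter, dtype=str)
    except Exception as exc:  # malformed CSV
        raise InputError(f"could not parse sorting table: {exc}") from exc

    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InputError(
            f"sorting table is missing column(s) {missing}; found {list(df.columns)}"
        )
    if len(df) == 0:
        raise InputError("sorting table has a header but no rows")

    scol, qcol, pcol = columns
    sub = df[[scol, qcol, pcol]]
    if sub.isna().any().any():
        bad = int(sub.isna().any(axis=1).idxmax()) + 2  # 1-based incl. header
        raise InputError(f"row {bad}: empty field in sorting table")

    records = [
        SortRecord(str(r[scol]).strip(), str(r[qcol]).strip(), str(r[pcol]).strip())
        for r in sub.to_dict("records")
    ]
    study = SortingStudy(records, quotes=quotes)
    if warn:
        validate_study(study)
    return study


def read_quote_texts(source: PathOrStream) -> list[Quote]:
    """Read a two-column (quote_id, text) CSV of verbatim excerpts."""
    try:
        df = pd.read_csv(source, dtype=str)
    except Exception as exc:
        raise InputError(f"could not parse quote-text table: {exc}") from exc
    if "quote_id" not in df.columns or "text" not in df.columns:
        raise InputError("quote-text table needs columns 'quote_id' and 'text'")
    return [Quote(str(r["quote_id"]).strip(), r["text"]) for r in df.to_dict("records")]


def write_sort_table(study: SortingStudy, dest: PathOrStream) -> None:
    """Write the canonical CSV form (rows sorted by sorter then quote),
    so identical studies produce byte-identical files."""
    df = pd.DataFrame(
        [(r.sorter_id, r.quote_id, r.pile_label) for r in study.records()],
        columns=list(DEFAULT_COLUMNS),
    )
    df.to_csv(dest, index=False)


# ---------------------------------------------------------------------------
# Derived views


def sorter_partition(study: SortingStudy, sorter_id: str) -> Partition:
    """The partition of a sorter's sorted quotes induced by their piles.

    Quotes the sorter did not place in any pile are absent from the result.
    """
    if sorter_id not in study.sorters:
        raise ValidationError(f"unknown sorter {sorter_id!r}")
    assignment = {
        rec.quote_id: rec.pile_label
        for rec in study.records()
        if rec.sorter_id == sorter_id
    }
    return Partition(assignment)


def summarize(study: SortingStudy) -> StudySummary:
    """Per-sorter pile counts and quote coverage."""
    piles: dict[str, int] = {}
    coverage: dict[str, float] = {}
    n = study.n_quotes
    for s in study.sorters:
        part = sorter_partition(study, s)
        piles[s] = part.n_groups
        coverage[s] = len(part) / n if n else 0.0
    return StudySummary(
        n_sorters=study.n_sorters,
        n_quotes=n,
        piles_per_sorter=piles,
        coverage=coverage,
    )


def validate_study(study: SortingStudy) -> list[str]:
    """Soft validation: warn about legal-but-unusual structure.

    Returns the list of warning messages (also emitted as
    :class:`ValidationWarning`): pile counts outside the typical 3-12 range,
    and sorters who left quotes unsorted.
    """
    lo, hi = TYPICAL_PILE_RANGE
    messages = []
    summary = summarize(study)
    for s in study.sorters:
        k = summary.piles_per_sorter[s]
        if not (lo <= k <= hi):
            messages.append(
                f"sorter {s!r} produced {k} piles (outside typical range {lo}-{hi})"
            )
        if summary.coverage[s] < 1.0:
            n_sorted = round(summary.coverage[s] * study.n_quotes)
            messages.append(
                f"sorter {s!r} sorted only {n_sorted} of {study.n_quotes} quotes"
            )
    for msg in messages:
        warnings.warn(msg, ValidationWarning, stacklevel=2)
    return messages
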
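"""Curated LOINC-to-HPO annotation maps.

A laboratory test identified by a LOINC code does not, by itself, name a
phenotype: the phenotype follows from the test *outcome*.  An annotation map
records, for each (LOINC, outcome) pair, the HPO term that outcome implies and
whether the term is negated (a normal result is encoded as NOT <abnormality>,
because HPO contains only abnormality terms).

Outcomes come in two flavours:

* internal interpretation codes (``A``, ``L``, ``N``, ``H``, ``NEG``, ``POS``)
  used for quantitative (Qn) and ordinal (Ord) tests;
* external coded values (typically SNOMED-CT codes) used for nominal (Nom)
  tests such as urine colour, where each observed code maps to its own term.

Maps are serialized as UTF-8 TSV with a header row; ``#``-prefixed lines are
comments.  Canonical columns::

    loincId  loincScale  outcomeSystem  outcomeCode  hpoTermId  isNegated  curation  createdOn

``outcomeSystem`` is the literal ``FHIR`` for internal codes, else the coding
system URI.  Unknown columns are preserved on read and re-emitted on write.
"""

from __future__ import annotations

import csv
import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "LOINC_SCALES",
    "INTERNAL_SYSTEM",
    "INTERNAL_CODES",
    "OutcomeKey",
    "MappingEntry",
    "AnnotationMap",
    "AnnotationError",
    "LookupStatus",
    "LookupMiss",
    "MapStatistics",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "map_statistics",
    "is_valid_loinc",
    "is_valid_hpo",
    "loinc_check_digit_ok",
]

LOINC_RE = re.compile(r"^[0-9]{1,7}-[0-9]$")
HPO_RE = re.compile(r"^HP:[0-9]{7}$")

LOINC_SCALES = ("Qn", "Ord", "Nom")

#: coding-system marker for internal primary interpretation codes
INTERNAL_SYSTEM = "FHIR"

#: primary interpretation codes; U is a normalization sink only and is never a
#: valid annotation key.
INTERNAL_CODES = ("A", "L", "N", "H", "NEG", "POS", "U")

#: outcomes that denote a normal/absent result and therefore may carry a
#: negated HPO term.
NEGATABLE_CODES = frozenset({"N", "NEG"})

CANONICAL_COLUMNS = (
    "loincId",
    "loincScale",
    "outcomeSystem",
    "outcomeCode",
    "hpoTermId",
    "isNegated",
    "curation",
    "createdOn",
)

#: best-effort aliases for the published annotation-repository layout, whose
#: exact column names have drifted over time.
DEFAULT_COLUMN_ALIASES: Mapping[str, str] = {
    "loincNumber": "loincId",
    "loinc_num": "loincId",
    "loincScale": "loincScale",
    "scale": "loincScale",
    "system": "outcomeSystem",
    "code": "outcomeCode",
    "outcome": "outcomeCode",
    "hpoTermId": "hpoTermId",
    "hpo_term": "hpoTermId",
    "hpoId": "hpoTermId",
    "isNegated": "isNegated",
    "is_negated": "isNegated",
    "curator": "curation",
    "createdBy": "curation",
    "created_on": "createdOn",
}


def is_valid_loinc(code: str) -> bool:
    """Format check: 1-7 digits, hyphen, one digit; no whitespace."""
    return bool(LOINC_RE.match(code))


def loinc_check_digit_ok(code: str) -> bool:
    """Mod-10 (Luhn) check digit used by LOINC; optional, off by default."""
    if not is_valid_loinc(code):
        return False
    digits, check = code.split("-")
    total = 0
    for i, ch in enumerate(reversed(digits)):
        d = int(ch)
        if i % 2 == 0:  # rightmost body digit is doubled
            d *= 2
            if d > 9:
                d -= 9
        total += d
    return (total + int(check)) % 10 == 0


def is_valid_hpo(term: str) -> bool:
    return bool(HPO_RE.match(term))


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation data."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class OutcomeKey:
    """One potential test outcome: an internal primary code or an external
    coded value (system URI + code)."""

    system: str
    code: str

    @classmethod
    def internal(cls, code: str) -> "OutcomeKey":
        code = code.upper()
        if code not in INTERNAL_CODES:
            raise AnnotationError(f"unknown internal outcome code {code!r}")
        return cls(INTERNAL_SYSTEM, code)

    @classmethod
    def external(cls, system: str, code: str) -> "OutcomeKey":
        return cls(system, code)

    @property
    def is_internal(self) -> bool:
        return self.system == INTERNAL_SYSTEM


@dataclass
class MappingEntry:
    """One curated row: (LOINC, outcome) -> (HPO term, negated?)."""

    loinc: str
    scale: str
    outcome: OutcomeKey
    hpo: str
    negated: bool = False
    curator: str | None = None
    created_on: str | None = None
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not is_valid_loinc(self.loinc):
            raise AnnotationError(f"malformed LOINC id {self.loinc!r}")
        if self.scale not in LOINC_SCALES:
            raise AnnotationError(f"unknown LOINC scale {self.scale!r}")
        if not is_valid_hpo(self.hpo):
            raise AnnotationError(f"malformed HPO id {self.hpo!r}")
        if self.outcome.is_internal:
            if self.outcome.code == "U":
                raise AnnotationError("'U' (unknown) is not an annotatable outcome")
            if self.scale == "Nom":
                raise AnnotationError(
                    "Nom tests use external coded outcomes, not internal codes"
                )
        if self.negated and not (
            self.outcome.is_internal and self.outcome.code in NEGATABLE_CODES
        ):
            raise AnnotationError(
                f"negation is only valid for normal/absent outcomes (N, NEG), "
                f"got {self.outcome.code!r}"
            )

    @property
    def key(self) -> tuple[str, OutcomeKey]:
        return (self.loinc, self.outcome)


class LookupStatus(enum.Enum):
    UNMAPPED_LOINC = "UNMAPPED_LOINC"
    UNMAPPED_OUTCOME = "UNMAPPED_OUTCOME"


@dataclass(frozen=True)
class LookupMiss:
    """Typed not-found: distinguishes an entirely unannotated LOINC from a
    known LOINC whose particular outcome has no annotation."""

    reason: LookupStatus
    loinc: str
    outcome: OutcomeKey


class AnnotationMap:
    """Validated collection of :class:`MappingEntry`, indexed by
    (LOINC, outcome), with one scale per LOINC."""

    def __init__(self, entries: Iterable[MappingEntry] = ()):
        self._index: dict[tuple[str, OutcomeKey], MappingEntry] = {}
        self._scale: dict[str, str] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: MappingEntry, line: int | None = None) -> None:
        if entry.key in self._index:
            raise AnnotationError(
                f"duplicate annotation for ({entry.loinc}, {entry.outcome.code})",
                line,
            )
        known = self._scale.get(entry.loinc)
        if known is not None and known != entry.scale:
            raise AnnotationError(
                f"inconsistent scale for {entry.loinc}: {known} vs {entry.scale}",
                line,
            )
        self._index[entry.key] = entry
        self._scale[entry.loinc] = entry.scale

    def lookup(self, loinc: str, outcome: OutcomeKey) -> MappingEntry | LookupMiss:
        hit = self._index.get((loinc, outcome))
        if hit is not None:
            return hit
        if loinc not in self._scale:
            return LookupMiss(LookupStatus.UNMAPPED_LOINC, loinc, outcome)
        return LookupMiss(LookupStatus.UNMAPPED_OUTCOME, loinc, outcome)

    def scale_of(self, loinc: str) -> str | None:
        return self._scale.get(loinc)

    @property
    def loincs(self) -> set[str]:
        return set(self._scale)

    def __len__(self) -> int:
        return len(self._index)

    def __iter__(self) -> Iterator[MappingEntry]:
        return iter(self._index.values())

    def __contains__(self, loinc: str) -> bool:
        return loinc in self._scale

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationMap):
            return NotImplemented
        return sorted_entries(self) == sorted_entries(other)


def sorted_entries(amap: AnnotationMap) -> list[MappingEntry]:
    return sorted(iter(amap), key=lambda e: (e.loinc, e.outcome.system, e.outcome.code))


def _parse_bool(token: str, line: int) -> bool:
    t = token.strip().lower()
    if t in {"true", "t", "1", "yes"}:
        return True
    if t in {"false", "f", "0", "no", ""}:
        return False
    raise AnnotationError(f"unparseable boolean {token!r}", line)


def read_annotation_tsv(
    path: str | Path,
    *,
    column_aliases: Mapping[str, str] | None = None,
    strict: bool = False,
    validate_check_digit: bool = False,
) -> AnnotationMap:
    """Read an annotation TSV into a validated :class:`AnnotationMap`.

    Parameters
    ----------
    path:
        TSV file with a header row; ``#``-prefixed lines are skipped.
    column_aliases:
        Extra header-name aliases (alias -> canonical), merged over the
        built-in best-effort table for the published annotation layout.
    strict:
        If True, reject files whose header contains names that resolve to
        neither a canonical column nor a known alias.
    validate_check_digit:
        Additionally verify the LOINC mod-10 check digit (off by default;
        synthetic fixtures use reserved codes with arbitrary check digits).
    """
    path = Path(path)
    aliases = dict(DEFAULT_COLUMN_ALIASES)
    if column_aliases:
        aliases.update(column_aliases)

    with path.open(encoding="utf-8", newline="") as fh:
        lines = [
            (i + 1, ln)
            for i, ln in enumerate(fh)
            if ln.strip() and not ln.lstrip().startswith("#")
        ]
    if not lines:
        raise AnnotationError("missing header row")

    header_line_no, header_raw = lines[0]
    header = [h.strip() for h in header_raw.rstrip("\n").split("\t")]
    resolved: list[str] = []
    for name in header:
        if name in CANONICAL_COLUMNS:
            resolved.append(name)
        elif name in aliases:
            resolved.append(aliases[name])
        elif strict:
            raise AnnotationError(f"unknown column {name!r}", header_line_no)
        else:
            resolved.append(name)  # preserved as an extra column
    for required in ("loincId", "loincScale", "outcomeCode", "hpoTermId"):
        if required not in resolved:
            raise AnnotationError(f"required column {required!r} missing", header_line_no)

    amap = AnnotationMap()
    for line_no, raw in lines[1:]:
        cells = raw.rstrip("\n").split("\t")
        if len(cells) < len(resolved):
            cells += [""] * (len(resolved) - len(cells))
        row = dict(zip(resolved, (c.strip() for c in cells)))
        loinc = row.get("loincId", "")
        if not is_valid_loinc(loinc):
            raise AnnotationError(f"malformed LOINC id {loinc!r}", line_no)
        if validate_check_digit and not loinc_check_digit_ok(loinc):
            raise AnnotationError(f"LOINC check digit failure for {loinc!r}", line_no)
        hpo = row.get("hpoTermId", "")
        if not is_valid_hpo(hpo):
            raise AnnotationError(f"malformed HPO id {hpo!r}", line_no)
        system = row.get("outcomeSystem") or INTERNAL_SYSTEM
        code = row.get("outcomeCode", "")
        if not code:
            raise AnnotationError("empty outcome code", line_no)
        try:
            outcome = (
                OutcomeKey.internal(code)
                if system == INTERNAL_SYSTEM
                else OutcomeKey.external(system, code)
            )
            entry = MappingEntry(
                loinc=loinc,
                scale=row.get("loincScale", ""),
                outcome=outcome,
                hpo=hpo,
                negated=_parse_bool(row.get("isNegated", "false"), line_no),
                curator=row.get("curation") or None,
                created_on=row.get("createdOn") or None,
                extra={
                    k: v
                    for k, v in row.items()
                    if k not in CANONICAL_COLUMNS and v != ""
                },
            )
            amap.add(entry, line_no)
        except AnnotationError as exc:
            if exc.line is None:
                raise AnnotationError(str(exc), line_no) from None
            raise
    return amap


def write_annotation_tsv(amap: AnnotationMap, path: str | Path) -> None:
    """Write a map as canonical TSV.

    Rows are sorted by (LOINC, outcome system, outcome code) and booleans
    serialized lowercase, so two writes of equal maps are byte-identical and
    read/write round-trips exactly.
    """
    path = Path(path)
    entries = sorted_entries(amap)
    extra_cols = sorted({k for e in entries for k in e.extra})
    columns = list(CANONICAL_COLUMNS) + extra_cols
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for e in entries:
            row = [
                e.loinc,
                e.scale,
                e.outcome.system,
                e.outcome.code,
                e.hpo,
                "true" if e.negated else "false",
                e.curator or "",
                e.created_on or "",
            ]
            row += [e.extra.get(k, "") for k in extra_cols]
            writer.writerow(row)


@dataclass
class MapStatistics:
    """Summary of an annotation map: scale composition and the LOINC-per-HPO
    distribution (how many distinct tests share one clinical interpretation)."""

    n_entries: int
    n_loincs: int
    scale_counts: dict[str, int]
    scale_percent: dict[str, float]
    n_distinct_hpo: int
    loinc_per_hpo: dict[int, int]  # histogram: #LOINCs -> #HPO terms
    mean_loinc_per_hpo: float
    multi_loinc_hpo_fraction: float  # share of HPO terms fed by >= 2 LOINCs


def map_statistics(amap: AnnotationMap) -> MapStatistics:
    loincs_by_scale: dict[str, set[str]] = {s: set() for s in LOINC_SCALES}
    loincs_by_hpo: dict[str, set[str]] = {}
    for e in amap:
        loincs_by_scale[e.scale].add(e.loinc)
        loincs_by_hpo.setdefault(e.hpo, set()).add(e.loinc)

    scale_counts = {s: len(v) for s, v in loincs_by_scale.items()}
    n_loincs = len(amap.loincs)
    scale_percent = {
        s: (100.0 * c / n_loincs if n_loincs else 0.0)
        for s, c in scale_counts.items()
    }
    sizes = [len(v) for v in loincs_by_hpo.values()]
    hist: dict[int, int] = {}
    for k in sizes:
        hist[k] = hist.get(k, 0) + 1
    n_hpo = len(loincs_by_hpo)
    return MapStatistics(
        n_entries=len(amap),
        n_loincs=n_loincs,
        scale_counts=scale_counts,
        scale_percent=scale_percent,
        n_distinct_hpo=n_hpo,
        loinc_per_hpo=dict(sorted(hist.items())),
        mean_loinc_per_hpo=(sum(sizes) / n_hpo if n_hpo else 0.0),
        multi_loinc_hpo_fraction=(
            sum(1 for k in sizes if k >= 2) / n_hpo if n_hpo else 0.0
        ),
    )
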
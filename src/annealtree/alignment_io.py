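"""Read, validate, normalise and write nucleotide alignments in PHYLIP format.

The reader auto-detects sequential vs. interleaved layout and strict
(10-column name field) vs. relaxed (whitespace-delimited name) dialects,
since real-world matrices converted to PHYLIP come in all four combinations.
The canonical output dialect is relaxed sequential, one taxon per line.

Recognised sequence characters are the IUPAC nucleotide codes
``ACGTRYSWKMBDHVN`` plus the gap ``-`` and missing ``?`` symbols
(case-insensitive on read, stored upper-case).
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field

__all__ = [
    "Alignment",
    "PhylipError",
    "EmptyInputError",
    "DimensionMismatchError",
    "DuplicateLabelError",
    "BadCharacterError",
    "NameCollisionError",
    "read_phylip",
    "write_phylip",
    "normalize_names",
]

VALID_CHARS = frozenset("ACGTRYSWKMBDHVN-?")


class PhylipError(ValueError):
    """Base class for PHYLIP parse/format errors."""


class EmptyInputError(PhylipError):
    """Input held no header line."""


class DimensionMismatchError(PhylipError):
    """Declared taxon/site counts do not match the data."""


class DuplicateLabelError(PhylipError):
    """Two taxa share a label."""


class BadCharacterError(PhylipError):
    """A sequence contains a character outside the recognised alphabet."""


class NameCollisionError(PhylipError):
    """Label disambiguation ran out of three-digit codes."""


@dataclass(frozen=True)
class Alignment:
    """Named nucleotide matrix; the optimisation input.

    Invariants: all rows share one length (``n_sites >= 1``), labels are
    unique, every character is a recognised upper-case code.
    """

    taxa: tuple[str, ...]
    matrix: tuple[str, ...]
    name: str = field(default="alignment", compare=False)

    def __post_init__(self):
        if len(self.taxa) != len(self.matrix):
            raise DimensionMismatchError("taxa and matrix row counts differ")
        if len(self.taxa) < 1:
            raise DimensionMismatchError("alignment needs at least one taxon")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise DuplicateLabelError(f"duplicate taxon labels: {dupes}")
        lengths = {len(row) for row in self.matrix}
        if len(lengths) != 1:
            raise DimensionMismatchError(f"unequal sequence lengths: {sorted(lengths)}")
        if lengths == {0}:
            raise DimensionMismatchError("alignment has zero sites")
        for lab, row in zip(self.taxa, self.matrix):
            bad = set(row) - VALID_CHARS
            if bad:
                raise BadCharacterError(
                    f"sequence {lab!r} contains unrecognised characters {sorted(bad)}"
                )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.matrix[0])


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _clean_seq_tokens(tokens: list[str], label: str) -> str:
    chunk = "".join(tokens).upper()
    bad = set(chunk) - VALID_CHARS
    if bad:
        raise BadCharacterError(
            f"sequence {label!r} contains unrecognised characters {sorted(bad)}"
        )
    return chunk


def _looks_like_sequence(token: str) -> bool:
    return bool(token) and set(token.upper()) <= VALID_CHARS


def _parse_relaxed_sequential(lines: list[str], n: int, m: int):
    """Name is the first whitespace token; sequence may wrap over lines."""
    taxa, rows = [], []
    i = 0
    for _ in range(n):
        while i < len(lines) and not lines[i].strip():
            i += 1
        if i >= len(lines):
            raise DimensionMismatchError(f"expected {n} taxa, found {len(taxa)}")
        tokens = lines[i].split()
        i += 1
        label, chunks = tokens[0], tokens[1:]
        seq = _clean_seq_tokens(chunks, label)
        while len(seq) < m:
            while i < len(lines) and not lines[i].strip():
                i += 1
            if i >= len(lines):
                raise DimensionMismatchError(
                    f"sequence {label!r} has {len(seq)} sites, header declares {m}"
                )
            more = lines[i].split()
            if not all(_looks_like_sequence(tok) for tok in more):
                raise DimensionMismatchError(
                    f"sequence {label!r} has {len(seq)} sites, header declares {m}"
                )
            i += 1
            seq += _clean_seq_tokens(more, label)
        if len(seq) != m:
            raise DimensionMismatchError(
                f"sequence {label!r} has {len(seq)} sites, header declares {m}"
            )
        taxa.append(label)
        rows.append(seq)
    if any(line.strip() for line in lines[i:]):
        raise DimensionMismatchError("unexpected extra lines after last sequence")
    return taxa, rows


def _parse_relaxed_interleaved(lines: list[str], n: int, m: int):
    body = [ln for ln in lines if ln.strip()]
    if len(body) < n or len(body) % n != 0:
        raise DimensionMismatchError(
            f"interleaved body has {len(body)} lines, not a multiple of {n} taxa"
        )
    taxa, rows = [], []
    for ln in body[:n]:
        tokens = ln.split()
        taxa.append(tokens[0])
        rows.append(_clean_seq_tokens(tokens[1:], tokens[0]))
    for b in range(1, len(body) // n):
        for k in range(n):
            tokens = body[b * n + k].split()
            rows[k] += _clean_seq_tokens(tokens, taxa[k])
    for lab, seq in zip(taxa, rows):
        if len(seq) != m:
            raise DimensionMismatchError(
                f"sequence {lab!r} has {len(seq)} sites, header declares {m}"
            )
    return taxa, rows


def _strict_name_split(line: str):
    label = line[:10].strip()
    rest = line[10:].replace(" ", "").replace("\t", "")
    return label, rest


def _parse_strict_sequential(lines: list[str], n: int, m: int):
    taxa, rows = [], []
    i = 0
    for _ in range(n):
        while i < len(lines) and not lines[i].strip():
            i += 1
        if i >= len(lines):
            raise DimensionMismatchError(f"expected {n} taxa, found {len(taxa)}")
        label, chunk = _strict_name_split(lines[i])
        i += 1
        if not label:
            raise DimensionMismatchError("empty 10-column name field")
        seq = _clean_seq_tokens([chunk], label)
        while len(seq) < m and i < len(lines):
            if not lines[i].strip():
                i += 1
                continue
            seq += _clean_seq_tokens(lines[i].split(), label)
            i += 1
        if len(seq) != m:
            raise DimensionMismatchError(
                f"sequence {label!r} has {len(seq)} sites, header declares {m}"
            )
        taxa.append(label)
        rows.append(seq)
    if any(line.strip() for line in lines[i:]):
        raise DimensionMismatchError("unexpected extra lines after last sequence")
    return taxa, rows


def _parse_strict_interleaved(lines: list[str], n: int, m: int):
    body = [ln for ln in lines if ln.strip()]
    if len(body) < n or len(body) % n != 0:
        raise DimensionMismatchError(
            f"interleaved body has {len(body)} lines, not a multiple of {n} taxa"
        )
    taxa, rows = [], []
    for ln in body[:n]:
        label, chunk = _strict_name_split(ln)
        if not label:
            raise DimensionMismatchError("empty 10-column name field")
        taxa.append(label)
        rows.append(_clean_seq_tokens([chunk], label))
    for b in range(1, len(body) // n):
        for k in range(n):
            rows[k] += _clean_seq_tokens(body[b * n + k].split(), taxa[k])
    for lab, seq in zip(taxa, rows):
        if len(seq) != m:
            raise DimensionMismatchError(
                f"sequence {lab!r} has {len(seq)} sites, header declares {m}"
            )
    return taxa, rows


_PARSERS = (
    _parse_relaxed_sequential,
    _parse_relaxed_interleaved,
    _parse_strict_sequential,
    _parse_strict_interleaved,
)


def read_phylip(source, name: str | None = None) -> Alignment:
    """Read a PHYLIP alignment from a path or text stream.

    Layout (sequential vs. interleaved) and dialect (strict vs. relaxed names)
    are auto-detected by attempting the candidate parses in a fixed order and
    accepting the first that reproduces the declared dimensions.
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source, "r") as fh:
            text = fh.read()
        if name is None:
            name = os.path.basename(os.fspath(source))
    elif isinstance(source, io.IOBase) or hasattr(source, "read"):
        text = source.read()
    else:
        raise TypeError("source must be a path or a text stream")
    lines = text.splitlines()
    while lines and not lines[0].strip():
        lines.pop(0)
    if not lines:
        raise EmptyInputError("empty PHYLIP input")
    header = lines[0].split()
    if len(header) < 2 or not all(re.fullmatch(r"\d+", tok) for tok in header[:2]):
        raise PhylipError(f"malformed header line: {lines[0]!r}")
    n, m = int(header[0]), int(header[1])
    if n < 1 or m < 1:
        raise DimensionMismatchError("header must declare positive taxon/site counts")
    body = lines[1:]
    errors: list[PhylipError] = []
    for parser in _PARSERS:
        try:
            taxa, rows = parser(body, n, m)
            return Alignment(tuple(taxa), tuple(rows), name=name or "alignment")
        except PhylipError as exc:
            errors.append(exc)
    # every dialect failed: surface the most specific diagnosis
    for cls in (DuplicateLabelError, BadCharacterError, DimensionMismatchError):
        for exc in errors:
            if isinstance(exc, cls):
                raise exc
    raise errors[0]


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_phylip(a: Alignment, sink=None) -> str:
    """Write relaxed sequential PHYLIP; ``read_phylip`` round-trips it exactly.

    Labels containing whitespace are refused (they would break the relaxed
    dialect's token-based name field).
    """
    for lab in a.taxa:
        if re.search(r"\s", lab):
            raise PhylipError(f"label {lab!r} contains whitespace")
    lines = [f"{a.n_taxa} {a.n_sites}"]
    width = max(len(lab) for lab in a.taxa)
    for lab, row in zip(a.taxa, a.matrix):
        lines.append(f"{lab:<{width}}  {row}")
    text = "\n".join(lines) + "\n"
    if sink is not None:
        if isinstance(sink, (str, os.PathLike)):
            with open(sink, "w") as fh:
                fh.write(text)
        else:
            sink.write(text)
    return text


# ---------------------------------------------------------------------------
# name normalisation
# ---------------------------------------------------------------------------

def normalize_names(a: Alignment) -> tuple[Alignment, dict[str, str]]:
    """Shorten labels to <= 10 characters and render them unique.

    Labels are truncated to 10 characters.  Where truncation (or the input)
    creates a clash, every member of the clashing group is renamed to its
    first 7 characters plus a zero-padded three-digit code assigned in input
    order.  Idempotent: a second application is the identity.
    """
    trunc = [lab[:10] for lab in a.taxa]
    counts: dict[str, int] = {}
    for t in trunc:
        counts[t] = counts.get(t, 0) + 1
    used = {t for t in trunc if counts[t] == 1}
    assigned: set[str] = set()
    new_labels: list[str] = []
    counters: dict[str, int] = {}
    for t in trunc:
        if counts[t] == 1 and t not in assigned:
            new_labels.append(t)
            assigned.add(t)
            continue
        stem = t[:7]
        k = counters.get(stem, 0)
        while True:
            k += 1
            if k > 999:
                raise NameCollisionError(
                    f"more than 999 clashing labels on stem {stem!r}"
                )
            candidate = f"{stem}{k:03d}"
            if candidate not in used and candidate not in assigned:
                break
        counters[stem] = k
        assigned.add(candidate)
        new_labels.append(candidate)
    mapping = dict(zip(a.taxa, new_labels))
    return Alignment(tuple(new_labels), a.matrix, name=a.name), mapping
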
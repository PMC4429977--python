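"""Unique amino acid counts and the (t, a) dual.

The unique amino acid count ``a`` of a protein is the number of distinct
residue symbols occurring at least once in its sequence, independent of
order and multiplicity, with each post-translationally modified residue form
counting as its own symbol.  Two counting modes are provided for the
PTM-augmented count:

* ``eq6``    — Y = X + P with P looked up in a per-protein PTM table; this
  assumes a modification always adds a new symbol.
* ``recount``— each annotated site is rewritten to a symbol keyed by
  (residue letter, normalized modification description) and the distinct
  symbols are re-tallied.  Y can then fall short of X + P: modifying the
  sole occurrence of a residue, or two sites carrying the same modified
  symbol, consumes no fresh symbol.  The shortfall (X + P) - Y is the
  *violation* audited downstream.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, TextIO

import pandas as pd

from .records import EXTENDED_AA, ProteinRecord, PTMSite


class TAPair(NamedTuple):
    """The dual a protein reduces to: total length t and unique count a."""

    t: int
    a: int


@dataclass(frozen=True)
class CountBreakdown:
    """Unique count before PTM (X), PTM count used (P), count after (Y)."""

    X: int
    P: int
    Y: int
    violation: int

    def __post_init__(self) -> None:
        if self.Y < self.X or self.violation < 0:
            raise ValueError(f"inconsistent breakdown {self}")


def unique_count(sequence: str, alphabet: str = EXTENDED_AA) -> int:
    """Number of distinct residue letters in ``sequence``.

    The empty sequence is an error (no zero-length proteins exist in the
    system), as is any symbol outside ``alphabet``.
    """
    if not sequence:
        raise ValueError("empty sequence has no unique count")
    allowed = set(alphabet)
    for pos, ch in enumerate(sequence, 1):
        if ch not in allowed:
            raise ValueError(f"invalid residue {ch!r} at position {pos}")
    return len(set(sequence))


def _retained_sites(record: ProteinRecord) -> list[PTMSite]:
    """One site per position, first in list wins (parser order = file order)."""
    seen: set[int] = set()
    out: list[PTMSite] = []
    for site in record.ptm_sites:
        if site.position in seen:
            continue
        seen.add(site.position)
        out.append(site)
    return out


def unique_count_with_ptm(record: ProteinRecord) -> CountBreakdown:
    """Direct-recount mode: re-tally distinct symbols after rewriting sites.

    A modified symbol is the pair (residue letter, normalized description),
    so phosphoserine and O-GlcNAc-serine stay distinct while two identical
    annotations collapse to one symbol.
    """
    seq = record.sequence
    X = unique_count(seq)
    sites = _retained_sites(record)
    modified: dict[int, tuple[str, str]] = {}
    for site in sites:
        if site.position > len(seq):
            raise ValueError(
                f"{record.id}: PTM position {site.position} beyond length {len(seq)}"
            )
        modified[site.position] = (seq[site.position - 1], site.symbol_key)
    symbols: set[object] = set()
    for pos, ch in enumerate(seq, 1):
        symbols.add(modified.get(pos, ch))
    Y = len(symbols)
    P = len(sites)
    return CountBreakdown(X=X, P=P, Y=Y, violation=X + P - Y)


def unique_count_eq6(
    record: ProteinRecord, table: dict[str, int]
) -> CountBreakdown:
    """Table-driven mode: Y = X + P with P from the per-protein PTM table.

    Identifiers absent from the table contribute P = 0.  By construction the
    violation field is zero.
    """
    X = unique_count(record.sequence)
    P = int(table.get(record.id, 0))
    return CountBreakdown(X=X, P=P, Y=X + P, violation=0)


def pair(
    record: ProteinRecord,
    mode: str = "eq6",
    table: dict[str, int] | None = None,
) -> TAPair:
    """The (t, a) dual of a record under a counting mode.

    ``raw`` counts plain letters; ``eq6`` adds the table PTM count; ``recount``
    re-tallies modified symbols from the record's own annotations.
    """
    t = record.length
    if mode == "raw":
        a = unique_count(record.sequence)
    elif mode == "eq6":
        if table is None:
            raise ValueError("eq6 mode requires a PTM count table")
        a = unique_count_eq6(record, table).Y
    elif mode == "recount":
        a = unique_count_with_ptm(record).Y
    else:
        raise ValueError(f"unknown counting mode {mode!r}")
    return TAPair(t=t, a=a)


def shared_alphabet(seq1: str, seq2: str) -> set[str]:
    """Residue letters common to both sequences' unique-symbol sets."""
    unique_count(seq1)
    unique_count(seq2)
    return set(seq1) & set(seq2)


def build_table(
    records: Iterable[ProteinRecord],
    mode: str = "recount",
    table: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-protein DataFrame: id, species, domain, t, a, X, P, Y, violation.

    ``a`` follows ``mode``; X/P/Y/violation are reported for the same mode
    (raw mode shows P = 0, Y = X).  ``has_ptm`` flags proteins with at least
    one retained annotated site (used by the PTM-abundance test).
    """
    rows = []
    for record in records:
        if mode == "eq6":
            if table is None:
                raise ValueError("eq6 mode requires a PTM count table")
            bd = unique_count_eq6(record, table)
        elif mode == "recount":
            bd = unique_count_with_ptm(record)
        elif mode == "raw":
            X = unique_count(record.sequence)
            bd = CountBreakdown(X=X, P=0, Y=X, violation=0)
        else:
            raise ValueError(f"unknown counting mode {mode!r}")
        rows.append(
            {
                "id": record.id,
                "species": record.species,
                "domain": record.domain,
                "t": record.length,
                "a": bd.Y,
                "X": bd.X,
                "P": bd.P,
                "Y": bd.Y,
                "violation": bd.violation,
                "has_ptm": len(_retained_sites(record)) > 0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id", "species", "domain", "t", "a",
            "X", "P", "Y", "violation", "has_ptm",
        ],
    )


def write_pairs_tsv(df: pd.DataFrame, handle: TextIO, header: str | None = None) -> None:
    """Write the per-protein table as TSV, with an optional comment header."""
    if header:
        for line in header.splitlines():
            handle.write(f"# {line}\n")
    df.to_csv(handle, sep="\t", index=False)
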
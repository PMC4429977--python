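"""Reader/writer for the SwissProt flat ("txt") dialect and the Selene table.

The dialect handled here is the classic line-oriented record format: an
``ID`` line naming the entry, ``OC`` lines carrying the lineage, ``FT``
feature lines (key, start column, end column, description, with wrapped
continuation lines), an ``SQ`` header declaring the residue count, indented
sequence lines in whitespace-separated blocks, and a ``//`` terminator.
Both tab-separated and fixed-column spacing are accepted.

Only four feature keys contribute PTM sites (MOD_RES, LIPID, CARBOHYD,
DISULFID), restricted to single sites (start == end), at most one per
position with the first in file winning.  SIGNAL and PEPTIDE ranges are kept
for the bias audit; all other keys are parsed and dropped.
"""
from __future__ import annotations

import logging
import re
from typing import Iterable, TextIO

from .records import DOMAINS, PTM_KEYWORDS, ProteinRecord, PTMSite

logger = logging.getLogger(__name__)

_FEATURE_KEY_RE = re.compile(r"^[A-Z][A-Z_]+$")


class FlatFileError(ValueError):
    """A record-level structural failure (missing ID or SQ, bad domain...)."""


class DomainClassificationError(FlatFileError):
    """No top-level lineage token found on the OC lines."""


def classify_domain(oc_text: str) -> str:
    """Map concatenated OC lines to one of the four domains of life.

    Matching is case-insensitive on whole lineage tokens, so e.g.
    ``"Viruses; Duplodnaviria; ..."`` -> ``"viruses"``.
    """
    tokens = [t.strip().lower() for t in re.split(r"[;,.\s]+", oc_text) if t.strip()]
    for domain in DOMAINS:
        if domain in tokens:
            return domain
    raise DomainClassificationError(
        f"no domain token in OC text: {oc_text.strip()!r}"
    )


def _species_from_id(entry_name: str) -> str:
    """Taxon mnemonic: the part of NAME_SPECIES after the underscore."""
    if "_" in entry_name:
        return entry_name.rsplit("_", 1)[1]
    return entry_name


class _RawFeature:
    __slots__ = ("key", "start", "end", "description")

    def __init__(self, key: str, start: int, end: int, description: str):
        self.key = key
        self.start = start
        self.end = end
        self.description = description


def _parse_ft_line(line: str, current: _RawFeature | None) -> _RawFeature | None:
    """Parse one FT line; return a new feature or extend ``current`` in place.

    A line opens a new feature when its first payload token looks like a
    feature key and is followed by two integer columns; anything else is a
    wrapped continuation of the previous description, joined with one space.
    """
    payload = line[2:].strip()
    if not payload:
        return None
    tokens = payload.split()
    if (
        len(tokens) >= 3
        and _FEATURE_KEY_RE.match(tokens[0])
        and tokens[1].lstrip("<").isdigit()
        and tokens[2].lstrip(">?").isdigit()
    ):
        start = int(tokens[1].lstrip("<"))
        end = int(tokens[2].lstrip(">?"))
        return _RawFeature(tokens[0], start, end, " ".join(tokens[3:]))
    if current is not None:
        current.description = (current.description + " " + payload).strip()
    return None


def _build_record(lines: list[str], index: int) -> ProteinRecord:
    entry_name: str | None = None
    oc_parts: list[str] = []
    features: list[_RawFeature] = []
    current_feature: _RawFeature | None = None
    declared_length: int | None = None
    seq_parts: list[str] = []
    in_sq = False

    for line in lines:
        tag = line[:2]
        if in_sq:
            # Everything between the SQ header and the terminator is sequence.
            seq_parts.append("".join(line.split()))
            continue
        if tag == "ID":
            entry_name = line[2:].split()[0] if line[2:].split() else None
        elif tag == "OC":
            oc_parts.append(line[2:].strip())
        elif tag == "FT":
            feat = _parse_ft_line(line, current_feature)
            if feat is not None:
                features.append(feat)
                current_feature = feat
        elif tag == "SQ":
            in_sq = True
            m = re.search(r"(\d+)\s*AA", line)
            declared_length = int(m.group(1)) if m else None

    if entry_name is None:
        raise FlatFileError(f"record #{index}: no ID line")
    if not in_sq:
        raise FlatFileError(f"record #{index} ({entry_name}): no SQ line")

    sequence = "".join(seq_parts).upper()
    if not sequence:
        raise FlatFileError(f"record #{index} ({entry_name}): empty sequence")

    domain = classify_domain(" ".join(oc_parts)) if oc_parts else None
    if domain is None:
        raise FlatFileError(f"record #{index} ({entry_name}): no OC line")

    ptm_sites: list[PTMSite] = []
    seen_positions: set[int] = set()
    signal_ranges: list[tuple[int, int]] = []
    peptide_ranges: list[tuple[int, int]] = []
    for feat in features:
        desc = feat.description.rstrip(".").strip()
        if feat.key in PTM_KEYWORDS and feat.start == feat.end:
            if feat.start in seen_positions:
                continue  # one modification per site, first in file wins
            seen_positions.add(feat.start)
            ptm_sites.append(PTMSite(feat.start, feat.key, desc))
        elif feat.key == "SIGNAL":
            signal_ranges.append((feat.start, feat.end))
        elif feat.key == "PEPTIDE":
            peptide_ranges.append((feat.start, feat.end))

    record = ProteinRecord(
        id=entry_name,
        species=_species_from_id(entry_name),
        domain=domain,
        sequence=sequence,
        ptm_sites=ptm_sites,
        signal_ranges=signal_ranges,
        mature_peptide_ranges=peptide_ranges,
    )
    if declared_length is not None and declared_length != record.length:
        msg = (
            f"declared SQ length {declared_length} != parsed length "
            f"{record.length}"
        )
        record.warnings.append(msg)
        logger.warning("%s: %s", entry_name, msg)
    record.validate()
    return record


def parse_flat_file(
    stream: TextIO | Iterable[str],
    errors: list[str] | None = None,
) -> list[ProteinRecord]:
    """Parse zero or more ``//``-terminated records from ``stream``.

    Malformed records are skipped with a logged warning (appended to
    ``errors`` when a list is supplied); parsing always continues.
    """
    records: list[ProteinRecord] = []
    buffer: list[str] = []
    index = 0
    for raw in stream:
        line = raw.rstrip("\n")
        if line.strip() == "//":
            index += 1
            if any(l.strip() for l in buffer):
                try:
                    records.append(_build_record(buffer, index))
                except (FlatFileError, ValueError) as exc:
                    logger.warning("skipping record: %s", exc)
                    if errors is not None:
                        errors.append(str(exc))
            buffer = []
        else:
            buffer.append(line)
    if any(l.strip() for l in buffer):
        index += 1
        try:
            records.append(_build_record(buffer, index))
        except (FlatFileError, ValueError) as exc:
            logger.warning("skipping trailing record: %s", exc)
            if errors is not None:
                errors.append(str(exc))
    return records


def parse_selene_table(stream: TextIO | Iterable[str]) -> dict[str, int]:
    """Parse the two-column ``id count`` per-protein PTM table.

    ``#`` comment lines and blank lines are ignored; duplicate identifiers
    are summed; a negative or non-numeric count raises ``ValueError`` naming
    the line.
    """
    table: dict[str, int] = {}
    for lineno, raw in enumerate(stream, 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"line {lineno}: expected 'id count', got {line!r}")
        ident, count_text = parts[0], parts[1]
        try:
            count = int(count_text)
        except ValueError:
            raise ValueError(
                f"line {lineno}: non-numeric count {count_text!r}"
            ) from None
        if count < 0:
            raise ValueError(f"line {lineno}: negative count {count}")
        table[ident] = table.get(ident, 0) + count
    return table


def write_fasta(records: Iterable[ProteinRecord], handle: TextIO) -> None:
    """Export sequences as standard wrapped FASTA (annotation-free)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=f"{r.domain} {r.species}")
        for r in records
    ]
    seqio_write(seq_records, handle, "fasta")
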
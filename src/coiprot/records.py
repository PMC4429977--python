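"""Core domain types shared across the pipeline.

A protein is reduced to its residue string plus the annotations that matter
for unique-symbol counting: single-site post-translational modifications
(PTMs), signal-peptide ranges and mature-peptide ranges.  All coordinates are
1-based inclusive, the SwissProt feature-table convention.
"""
from __future__ import annotations

from dataclasses import dataclass, field

#: The four top-level lineages used to partition the corpus.
DOMAINS = ("archaea", "bacteria", "eukaryota", "viruses")

#: The 20 canonical residue letters.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Canonical letters plus selenocysteine (U), pyrrolysine (O) and the
#: ambiguity codes B, Z, X — the 25-letter alphabet found in curated records.
EXTENDED_AA = CANONICAL_AA + "UOBZX"

#: Feature keywords retained for PTM counting; everything else (CROSSLNK,
#: UNSURE, ...) is parsed but ignored.
PTM_KEYWORDS = ("MOD_RES", "LIPID", "CARBOHYD", "DISULFID")


def normalize_description(text: str) -> str:
    """Collapse whitespace, strip a trailing period, lowercase.

    Two PTM sites denote the same modified symbol only if residue letter and
    normalized description both match (phosphoserine and O-GlcNAc serine stay
    distinct).
    """
    return " ".join(text.split()).rstrip(".").lower()


@dataclass(frozen=True)
class PTMSite:
    """A single-site modification: 1-based position, feature kind, free text."""

    position: int
    kind: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"PTM position must be >= 1, got {self.position}")
        if self.kind not in PTM_KEYWORDS:
            raise ValueError(
                f"PTM kind must be one of {PTM_KEYWORDS}, got {self.kind!r}"
            )

    @property
    def symbol_key(self) -> str:
        return normalize_description(self.description)


@dataclass
class ProteinRecord:
    """One parsed protein record.

    ``id`` is the entry name (e.g. ``VG22_BPT2``); ``species`` the taxon
    mnemonic after the underscore; ``domain`` one of :data:`DOMAINS`.
    ``warnings`` collects non-fatal parse anomalies (e.g. declared-length
    mismatches).
    """

    id: str
    species: str
    domain: str
    sequence: str
    ptm_sites: list[PTMSite] = field(default_factory=list)
    signal_ranges: list[tuple[int, int]] = field(default_factory=list)
    mature_peptide_ranges: list[tuple[int, int]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated structural invariant."""
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        if self.domain not in DOMAINS:
            raise ValueError(f"{self.id}: unknown domain {self.domain!r}")
        n = self.length
        for site in self.ptm_sites:
            if site.position > n:
                raise ValueError(
                    f"{self.id}: PTM position {site.position} beyond length {n}"
                )
        for start, end in self.signal_ranges + self.mature_peptide_ranges:
            if not (1 <= start <= end <= n):
                raise ValueError(
                    f"{self.id}: range ({start}, {end}) outside [1, {n}]"
                )
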
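"""Synthetic flat-file corpora with known ground truth.

The generator emulates the statistical structure the analysis assumes so
that every pipeline stage is testable without a database download:

* unique counts ``a`` from a bulk-plus-tail mixture — a unimodal body over
  small alphabets and an equilibrium power-law tail p(a) proportional to
  a^(-beta) over [20, 30];
* lengths ``t`` conditionally uniform on [a, t_max] given a (the
  equilibrium premise behind the constant-average-length prediction);
* a skewed per-species protein count over four domains of life;
* single-site PTM annotations (MOD_RES/LIPID/CARBOHYD/DISULFID feature
  lines; sequence letters stay canonical, so counting must merge rather
  than read modified symbols);
* N-terminal signal-peptide ranges, ~1% of records missing the initiator
  methionine, and rare additive-count violations at configured rates.

Every draw is a pure function of (config, seed); the per-protein ground
truth (t, a, X, P, Y, violation, bias flags) is returned alongside the
records.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from typing import Sequence, TextIO

import numpy as np
import pandas as pd

from .bias_audit import ViolationDistribution
from .coi_model import equilibrium_pmf
from .records import CANONICAL_AA, DOMAINS, ProteinRecord, PTMSite

#: Background residue frequencies (canonical letters only) matching the
#: empirical abundance ranking in curated sequence data; used for optional
#: composition weighting of filler residues.
AA_BACKGROUND_WEIGHTS: dict[str, float] = {
    "W": 2.10, "C": 2.57, "H": 4.37, "M": 4.63, "Y": 5.52, "N": 7.13,
    "F": 7.45, "Q": 7.54, "P": 9.05, "T": 9.86, "D": 10.48, "R": 10.64,
    "K": 10.72, "S": 11.19, "I": 11.48, "E": 13.00, "V": 13.23, "G": 13.56,
    "A": 15.77, "L": 18.61,
}

PTM_KINDS = ("MOD_RES", "CARBOHYD", "LIPID", "DISULFID")

#: Fraction of not-M-initiated records in which M still occurs further along
#: the sequence (so the fix leaves the unique count unchanged); matches the
#: curated-corpus proportion of ~61%.
M_ELSEWHERE_GIVEN_MISSING = 0.61


@dataclass(frozen=True)
class CorpusConfig:
    """Generation parameters; the defaults are the study conditions."""

    m: int = 100_000
    beta: float = 22.914
    a_support: tuple[int, int] = (2, 30)
    tail_start: int = 20
    bulk_fraction: float = 0.95
    t_max: int = 2000
    n_species: int = 500
    domain_mix: tuple[float, float, float, float] = (0.035, 0.608, 0.327, 0.030)
    ptm_rate: float = 0.2
    ptm_a_slope: float = 0.0
    missing_met_rate: float = 0.01
    signal_rate: float = 0.03
    signal_length_range: tuple[int, int] = (15, 30)
    violation_counts: tuple[tuple[int, int], ...] = tuple(
        sorted({0: 537_999, 1: 3_545, 2: 208, 3: 9, 4: 0, 5: 1}.items())
    )
    weighted_composition: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.a_support
        if lo < 2:
            raise ValueError("a_support minimum must be >= 2")
        if self.t_max < hi:
            raise ValueError("t_max must be >= max a_support")
        for p in (self.bulk_fraction, self.ptm_rate, self.missing_met_rate,
                  self.signal_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        if abs(sum(self.domain_mix) - 1.0) > 1e-9:
            raise ValueError("domain_mix must sum to 1")

    def violation_distribution(self) -> ViolationDistribution:
        return ViolationDistribution.from_counts(dict(self.violation_counts))

    def to_text(self) -> str:
        """key = value dump, one line per field."""
        return "\n".join(f"{k} = {v}" for k, v in asdict(self).items())


def _bulk_pmf(config: CorpusConfig) -> tuple[np.ndarray, np.ndarray]:
    """Unimodal body over [a_min, tail_start - 1], peaked near the tail onset.

    A shifted beta-binomial, a = a_min + BetaBinom(span, 8, 2): the mode sits
    a few counts below the power-law tail with a long left shoulder, so small
    alphabets (a of 6-8) are rare but represented, as in curated data.
    """
    from scipy import stats

    lo = config.a_support[0]
    hi = config.tail_start - 1
    support = np.arange(lo, hi + 1)
    span = hi - lo
    w = stats.betabinom.pmf(support - lo, span, 8.0, 2.0)
    return support, w / w.sum()


def sample_duals(config: CorpusConfig, seed: int) -> list[tuple[int, int]]:
    """Draw M (t, a) pairs from the bulk-plus-tail mixture.

    ``a`` is the post-PTM unique count (the quantity the equilibrium
    distribution governs); ``t`` is uniform on [a, t_max] given a.
    """
    rng = np.random.default_rng(seed)
    return _sample_duals_rng(config, rng)


def _sample_duals_rng(config: CorpusConfig, rng: np.random.Generator) -> list[tuple[int, int]]:
    m = config.m
    bulk_support, bulk_p = _bulk_pmf(config)
    tail_support = np.arange(config.tail_start, config.a_support[1] + 1)
    tail_p = equilibrium_pmf(config.beta, tail_support)
    from_bulk = rng.random(m) < config.bulk_fraction
    a = np.empty(m, dtype=int)
    n_bulk = int(from_bulk.sum())
    a[from_bulk] = rng.choice(bulk_support, size=n_bulk, p=bulk_p)
    a[~from_bulk] = rng.choice(tail_support, size=m - n_bulk, p=tail_p)
    t = rng.integers(a, config.t_max + 1)  # uniform on [a, t_max], inclusive
    return [(int(ti), int(ai)) for ti, ai in zip(t, a)]


def sample_powerlaw_lengths(
    exponent: float,
    support: tuple[int, int],
    m: int,
    seed: int,
) -> np.ndarray:
    """Lengths drawn from a discrete power law pmf proportional to t^(-s)."""
    rng = np.random.default_rng(seed)
    values = np.arange(support[0], support[1] + 1)
    p = equilibrium_pmf(exponent, values)
    return rng.choice(values, size=m, p=p)


def realize_sequence(
    t: int,
    a: int,
    alphabet: str = CANONICAL_AA,
    seed: int | np.random.Generator = 0,
    weights: dict[str, float] | None = None,
) -> str:
    """A random residue string of length t with exactly a distinct letters.

    One occurrence of each chosen letter lands at a random position; the
    remaining t - a positions are filled from the chosen subset, optionally
    weighted by background composition.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if a > min(t, len(alphabet)):
        raise ValueError(f"cannot fit {a} distinct letters in length {t}")
    if a < 1:
        raise ValueError("need at least one letter")
    letters = list(rng.choice(list(alphabet), size=a, replace=False))
    if weights is not None:
        wv = np.array([weights.get(c, 1.0) for c in letters], dtype=float)
        wv /= wv.sum()
    else:
        wv = None
    filler = rng.choice(letters, size=t - a, p=wv)
    chars = np.array(letters + list(filler))
    rng.shuffle(chars)
    return "".join(chars)


@dataclass
class _Plan:
    """Per-protein realization plan: alphabet split and injected biases."""

    t: int
    a: int            # post-PTM (eq6) unique count = X + P
    X: int            # raw-letter unique count
    P: int            # annotated PTM sites
    violations: int   # sites placed on sole-occurrence letters
    missing_met: bool
    met_elsewhere: bool
    signal_len: int   # 0 = no signal peptide


def _plan_protein(t: int, a: int, config: CorpusConfig,
                  dist: ViolationDistribution, rng: np.random.Generator) -> _Plan:
    # violations are drawn first (their distribution is over ALL proteins)
    # and force P >= v so the realized frequencies match the configured ones
    v = int(dist.sample(1, rng)[0])
    ptm_prob = float(np.clip(
        config.ptm_rate + config.ptm_a_slope * (a - 19), 0.0, 1.0
    ))
    P = 0
    if rng.random() < ptm_prob:
        P = 1 + int(rng.poisson(1.0))
    P = max(P, v, a - 20)          # raw letters are capped at the 20 canonical
    X = a - P
    if X < 1:                      # tiny alphabets: shrink P, drop violations
        P = a - 1
        X = 1
    v = min(v, P, X - 1)           # a violation consumes a singleton letter
    if v < 0:
        v = 0
    missing = rng.random() < config.missing_met_rate
    # X = 20 exhausts the canonical alphabet, so M is necessarily present
    met_elsewhere = bool(missing and X >= 2
                         and (X >= 20 or rng.random() < M_ELSEWHERE_GIVEN_MISSING))
    signal_len = 0
    if rng.random() < config.signal_rate:
        lo, hi = config.signal_length_range
        signal_len = int(rng.integers(lo, hi + 1))
        if signal_len >= t:
            signal_len = 0
    return _Plan(t=t, a=a, X=X, P=P, violations=v,
                 missing_met=missing, met_elsewhere=met_elsewhere,
                 signal_len=signal_len)


def _realize_planned(plan: _Plan, config: CorpusConfig,
                     rng: np.random.Generator) -> tuple[str, list[PTMSite]]:
    """Build a sequence plus FT sites honoring a plan exactly.

    Violating sites sit on letters occurring exactly once; every other site
    sits on a letter that keeps at least one unmodified copy, so the direct
    recount yields Y = X + P - violations by construction.
    """
    t, X, P, v = plan.t, plan.X, plan.P, plan.violations
    nv = P - v
    alphabet = list(CANONICAL_AA)
    use_m = (not plan.missing_met) or plan.met_elsewhere
    if use_m:
        others = [c for c in alphabet if c != "M"]
        letters = ["M"] + list(rng.choice(others, size=X - 1, replace=False))
    else:
        others = [c for c in alphabet if c != "M"]
        letters = list(rng.choice(others, size=X, replace=False))
    # singleton letters host the violating sites; never pick M (it may be
    # pinned to position 1 and is simplest kept repeatable)
    non_m = [c for c in letters if c != "M"]
    rng.shuffle(non_m)
    singletons = non_m[:v]
    repeatable = [c for c in letters if c not in singletons]

    # non-violating sites target repeatable letters, one extra copy each so
    # an unmodified copy always survives
    nv_targets = list(rng.choice(repeatable, size=nv, replace=True)) if nv else []
    weights = AA_BACKGROUND_WEIGHTS if config.weighted_composition else None
    if weights is not None:
        wv = np.array([weights.get(c, 1.0) for c in repeatable], dtype=float)
        wv /= wv.sum()
    else:
        wv = None
    n_fill = t - X - nv
    filler = list(rng.choice(repeatable, size=n_fill, p=wv)) if n_fill else []
    chars = np.array(letters + nv_targets + filler)
    rng.shuffle(chars)

    if use_m and not plan.missing_met:
        # pin an M to position 1 (initiator methionine)
        m_idx = int(np.flatnonzero(chars == "M")[0])
        chars[[0, m_idx]] = chars[[m_idx, 0]]
    elif chars[0] == "M":
        # missing-initiator record must not start with M
        non_m_idx = int(np.flatnonzero(chars != "M")[0])
        chars[[0, non_m_idx]] = chars[[non_m_idx, 0]]

    seq = "".join(chars)
    sites: list[PTMSite] = []
    used_positions: set[int] = set()
    counter = 0
    for letter in singletons:
        pos = seq.index(letter) + 1
        counter += 1
        sites.append(PTMSite(pos, PTM_KINDS[counter % len(PTM_KINDS)],
                             f"synthetic modification {counter}"))
        used_positions.add(pos)
    for letter in nv_targets:
        occ = [i + 1 for i, c in enumerate(seq) if c == letter
               and i + 1 not in used_positions]
        # a letter targeted k times received k extra copies, so it occurs at
        # least k + 1 times and one unmodified copy always survives
        pos = occ[0]
        counter += 1
        sites.append(PTMSite(pos, PTM_KINDS[counter % len(PTM_KINDS)],
                             f"synthetic modification {counter}"))
        used_positions.add(pos)
    sites.sort(key=lambda s: s.position)
    return seq, sites


def generate_corpus(
    config: CorpusConfig, seed: int
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Full corpus: records with annotations plus the ground-truth table.

    The ground truth carries per-protein (t, a, X, P, Y, violation), species
    membership and the injected-bias flags; ``Y`` is the direct-recount value
    X + P - violation, while ``a`` is the additive (eq6) count X + P.
    """
    rng = np.random.default_rng(seed)
    duals = _sample_duals_rng(config, rng)
    dist = config.violation_distribution()

    # skewed species sizes: lognormal weights; each species gets one domain
    sp_weights = rng.lognormal(mean=0.0, sigma=1.5, size=config.n_species)
    sp_weights /= sp_weights.sum()
    sp_domain = rng.choice(DOMAINS, size=config.n_species, p=config.domain_mix)
    sp_index = rng.choice(config.n_species, size=config.m, p=sp_weights)

    records: list[ProteinRecord] = []
    truth_rows = []
    for i, (t, a) in enumerate(duals):
        plan = _plan_protein(t, a, config, dist, rng)
        seq, sites = _realize_planned(plan, config, rng)
        species = f"SYN{sp_index[i]:04d}"
        domain = str(sp_domain[sp_index[i]])
        signal_ranges = [(1, plan.signal_len)] if plan.signal_len else []
        record = ProteinRecord(
            id=f"P{i:06d}_{species}",
            species=species,
            domain=domain,
            sequence=seq,
            ptm_sites=sites,
            signal_ranges=signal_ranges,
        )
        records.append(record)
        truth_rows.append(
            {
                "id": record.id,
                "species": species,
                "domain": domain,
                "t": plan.t,
                "a": plan.a,
                "X": plan.X,
                "P": plan.P,
                "Y": plan.X + plan.P - plan.violations,
                "violation": plan.violations,
                "missing_met": plan.missing_met,
                "met_elsewhere": plan.met_elsewhere,
                "signal_len": plan.signal_len,
            }
        )
    return records, pd.DataFrame(truth_rows)


def inject_annotations(
    record: ProteinRecord,
    config: CorpusConfig,
    seed: int | np.random.Generator = 0,
) -> tuple[ProteinRecord, dict]:
    """Add PTM/signal annotations to an existing plain record.

    Standalone mode for records not built by :func:`generate_corpus`: the
    plan is derived from the record's own sequence, so violations are only
    placed where a letter genuinely occurs once.  Returns the annotated
    record and its ground-truth entry.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = record.sequence
    from collections import Counter

    counts = Counter(seq)
    X = len(counts)
    dist = config.violation_distribution()
    v = int(dist.sample(1, rng)[0])
    singles = [c for c, n in counts.items() if n == 1 and c != seq[0]]
    v = min(v, len(singles))
    P = 0
    if rng.random() < config.ptm_rate:
        P = 1 + int(rng.poisson(1.0))
    P = max(P, v)
    multi = [c for c, n in counts.items() if n >= 2]
    sites: list[PTMSite] = []
    used: set[int] = set()
    counter = 0
    targets = list(rng.choice(singles, size=v, replace=False)) if v else []
    for letter in targets:
        pos = seq.index(letter) + 1
        counter += 1
        sites.append(PTMSite(pos, PTM_KINDS[counter % len(PTM_KINDS)],
                             f"synthetic modification {counter}"))
        used.add(pos)
    nv = P - v
    placed = 0
    for letter in (rng.choice(multi, size=nv, replace=True) if (nv and multi) else []):
        occ = [i + 1 for i, c in enumerate(seq)
               if c == letter and i + 1 not in used]
        if len(occ) < 2:
            continue  # would consume the last unmodified copy
        counter += 1
        placed += 1
        sites.append(PTMSite(occ[0], PTM_KINDS[counter % len(PTM_KINDS)],
                             f"synthetic modification {counter}"))
        used.add(occ[0])
    P = v + placed
    signal_ranges = list(record.signal_ranges)
    if not signal_ranges and rng.random() < config.signal_rate:
        lo, hi = config.signal_length_range
        length = int(rng.integers(lo, hi + 1))
        if length < record.length:
            signal_ranges = [(1, length)]
    out = ProteinRecord(
        id=record.id, species=record.species, domain=record.domain,
        sequence=seq, ptm_sites=sorted(sites, key=lambda s: s.position),
        signal_ranges=signal_ranges,
        mature_peptide_ranges=list(record.mature_peptide_ranges),
    )
    out.validate()
    truth = {
        "id": record.id, "t": record.length, "X": X, "P": P,
        "Y": X + P - v, "violation": v, "a": X + P,
        "signal_len": signal_ranges[0][1] if signal_ranges else 0,
    }
    return out, truth


_DOMAIN_LINEAGE = {
    "archaea": "Archaea; synthetic lineage.",
    "bacteria": "Bacteria; synthetic lineage.",
    "eukaryota": "Eukaryota; synthetic lineage.",
    "viruses": "Viruses; synthetic lineage.",
}


def write_flat_file(records: Sequence[ProteinRecord], stream: TextIO) -> None:
    """Emit records in the parseable flat dialect (ID/OC/FT/SQ + ``//``)."""
    for record in records:
        stream.write(f"ID   {record.id}   Reviewed;   {record.length} AA.\n")
        stream.write(f"OC   {_DOMAIN_LINEAGE[record.domain]}\n")
        for start, end in record.signal_ranges:
            stream.write(f"FT   SIGNAL   {start}   {end}   Synthetic signal.\n")
        for start, end in record.mature_peptide_ranges:
            stream.write(f"FT   PEPTIDE   {start}   {end}   Synthetic peptide.\n")
        for site in record.ptm_sites:
            stream.write(
                f"FT   {site.kind}   {site.position}   {site.position}   "
                f"{site.description}.\n"
            )
        stream.write(
            f"SQ   SEQUENCE   {record.length} AA;   0 MW;   "
            "0000000000000000 CRC64;\n"
        )
        seq = record.sequence
        for line_start in range(0, len(seq), 60):
            chunk = seq[line_start : line_start + 60]
            blocks = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
            stream.write(f"     {blocks}\n")
        stream.write("//\n")


def corpus_to_text(records: Sequence[ProteinRecord]) -> str:
    buf = io.StringIO()
    write_flat_file(records, buf)
    return buf.getvalue()
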
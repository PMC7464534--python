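"""Perfect tandem-repeat (microsatellite) detection in genome assemblies.

Detects maximal perfect runs of 2-6 bp motifs.  Copy-number thresholds
follow the micRocounter defaults used for insect assemblies: dinucleotide
motifs need six complete copies, trinucleotides four, and 4-6-mers three.

Semantics (fixed, shared by the fast scanner and the reference oracle):

* the sequence is case-folded to uppercase; any character outside
  ``{A, C, G, T}`` never matches anything and therefore terminates runs;
* a run starting at ``i`` with period ``p`` extends right while
  ``s[j] == s[j+p]``; its extent includes partial trailing copies, while
  the copy threshold applies to complete copies ``floor(len/p)``;
* each run is classified by its primitive period: a run whose motif is
  itself a tandem repeat of a shorter motif (e.g. ``ATAT`` for period 4)
  is only reported at the shorter period;
* overlaps are resolved left to right: at each position the longest
  qualifying run wins, ties prefer the smaller period, and scanning
  resumes after the reported locus; loci are therefore non-overlapping
  and sorted by start;
* coordinates are 0-based half-open (BED convention).

Mononucleotide runs are never reported: period 1 is outside the allowed
range, and a homopolymer is not decomposed into a period-2 repeat because
its motif is non-primitive.

``scan_sequence`` is the production implementation (vectorised match
arrays); ``oracle_scan_sequence`` is an independent character-by-character
reference used by the test suite and to define ground truth for synthetic
genomes.  The two are equivalent by construction of the semantics above
and this equivalence is enforced by tests.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "ScanParams",
    "RepeatLocus",
    "GenomeMsatProfile",
    "canonical_motif",
    "scan_sequence",
    "oracle_scan_sequence",
    "summarize_genome",
    "scan_fasta",
    "loci_to_rows",
    "LOCUS_COLUMNS",
    "PROFILE_COLUMNS",
]

DEFAULT_MIN_COPIES = {2: 6, 3: 4, 4: 3, 5: 3, 6: 3}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# proper divisors of each period; used for the primitive-motif check
_DIVISORS = {2: (1,), 3: (1,), 4: (1, 2), 5: (1,), 6: (1, 2, 3)}


class InvalidMotifError(ValueError):
    pass


@dataclass(frozen=True)
class ScanParams:
    """Scan configuration: allowed periods and complete-copy thresholds."""

    min_copies_by_period: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_COPIES))
    periods: frozenset[int] = frozenset({2, 3, 4, 5, 6})
    fold_strands: bool = False  # canonicalise motifs across strands too

    def __post_init__(self):
        for p in self.periods:
            if not 2 <= p <= 6:
                raise ValueError(f"period {p} outside [2, 6]")
            if p not in self.min_copies_by_period:
                raise ValueError(f"no copy threshold for period {p}")
        for p, c in self.min_copies_by_period.items():
            if c < 2:
                raise ValueError(f"copy threshold {c} for period {p} is < 2")


@dataclass(frozen=True)
class RepeatLocus:
    """A maximal perfect tandem repeat; coordinates 0-based half-open."""

    sequence_id: str
    start: int
    end: int
    period: int
    motif: str
    canonical_motif: str
    copies: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def validate(self, params: ScanParams | None = None) -> None:
        assert 2 <= self.period <= 6
        assert self.copies == (self.end - self.start) // self.period
        assert len(self.motif) == self.period
        assert _is_primitive(self.motif)
        if params is not None:
            assert self.copies >= params.min_copies_by_period[self.period]


@dataclass(frozen=True)
class GenomeMsatProfile:
    """Per-genome microsatellite totals by period class."""

    species: str
    assembly_length: int
    bp_by_period: dict[int, int]
    total_bp: int
    content_per_mbp: float
    proportion: float


def canonical_motif(motif: str, fold_strands: bool = False) -> str:
    """Lexicographically smallest cyclic rotation of ``motif`` (optionally
    also across the reverse complement).  A stable reporting key: all
    rotations of a motif map to the same output."""
    motif = motif.upper()
    if not motif or len(motif) > 6 or any(c not in "ACGT" for c in motif):
        raise InvalidMotifError(f"invalid motif {motif!r}")
    rots = {motif[i:] + motif[:i] for i in range(len(motif))}
    if fold_strands:
        rc = motif.translate(_COMPLEMENT)[::-1]
        rots |= {rc[i:] + rc[:i] for i in range(len(rc))}
    return min(rots)


def _is_primitive(motif: str) -> bool:
    p = len(motif)
    for d in _DIVISORS.get(p, ()):
        if motif == motif[:d] * (p // d):
            return False
    return True


# -- fast scanner -----------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    """Map ACGT to 0-3; anything else to a unique negative sentinel so it
    never compares equal (non-ACGT characters terminate runs)."""
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    code = np.full(raw.shape, -1, dtype=np.int64)
    for i, base in enumerate(b"ACGT"):
        code[raw == base] = i
    bad = code < 0
    if bad.any():
        idx = np.nonzero(bad)[0]
        code[idx] = -(idx + 10)  # unique per position
    return code


def _extension_lengths(code: np.ndarray, p: int) -> np.ndarray:
    """E[i] = number of consecutive positions j >= i with s[j] == s[j+p];
    array length n-p+1 (E[n-p] = 0)."""
    n = code.size
    if n <= p:
        return np.zeros(max(n - p + 1, 0), dtype=np.int64)
    m = code[:-p] == code[p:]
    L = m.size
    tmp = np.where(m, L, np.arange(L))
    next_false = np.minimum.accumulate(tmp[::-1])[::-1]
    E = np.empty(L + 1, dtype=np.int64)
    E[:L] = next_false - np.arange(L)
    E[L] = 0
    return E


def scan_sequence(sequence_id: str, seq: str,
                  params: ScanParams | None = None) -> list[RepeatLocus]:
    """Detect qualifying perfect repeats in one sequence (semantics above)."""
    if params is None:
        params = ScanParams()
    n = len(seq)
    if n == 0:
        return []
    code = _encode(seq)
    periods = sorted(params.periods)
    ext = {p: _extension_lengths(code, p) for p in periods if n > p}
    # primitive-motif check needs period-1..3 match extensions too
    aux = {d for p in periods for d in _DIVISORS[p]} - set(ext)
    for d in aux:
        if n > d:
            ext[d] = _extension_lengths(code, d)

    # qualifying-start mask per period
    qual: dict[int, np.ndarray] = {}
    any_qual = np.zeros(n, dtype=bool)
    for p in periods:
        if p not in ext:
            continue
        E = ext[p]
        length = p + E
        ok = (length // p) >= params.min_copies_by_period[p]
        # primitive motif: no proper divisor d with E_d[i] >= p - d
        for d in _DIVISORS[p]:
            if d in ext:
                Ed = ext[d][: E.size]
                ok &= Ed < (p - d)
        qual[p] = ok
        any_qual[: ok.size] |= ok

    starts = np.nonzero(any_qual)[0]
    loci: list[RepeatLocus] = []
    seq_u = seq.upper()
    pos = 0
    k = 0
    n_starts = starts.size
    while k < n_starts:
        if starts[k] < pos:
            k += 1
            continue
        i = int(starts[k])
        best_len = -1
        best_p = 0
        for p in periods:
            q = qual.get(p)
            if q is None or i >= q.size or not q[i]:
                continue
            run_len = p + int(ext[p][i])
            if run_len > best_len:
                best_len = run_len
                best_p = p
        motif = seq_u[i: i + best_p]
        loci.append(RepeatLocus(
            sequence_id=sequence_id,
            start=i,
            end=i + best_len,
            period=best_p,
            motif=motif,
            canonical_motif=canonical_motif(motif, params.fold_strands),
            copies=best_len // best_p,
        ))
        pos = i + best_len
    return loci


# -- reference oracle -------------------------------------------------------

def oracle_scan_sequence(sequence_id: str, seq: str,
                         params: ScanParams | None = None) -> list[RepeatLocus]:
    """Brute-force reference scanner: for every position and period the
    maximal perfect run is extended by direct character comparison, then
    the same left-to-right longest-run selection is applied.  Independent
    of the vectorised implementation; used as ground truth in tests and
    synthetic-genome truth tables."""
    if params is None:
        params = ScanParams()
    s = seq.upper()
    n = len(s)
    valid = [c in "ACGT" for c in s]
    periods = sorted(params.periods)
    minc = params.min_copies_by_period
    loci: list[RepeatLocus] = []
    pos = 0
    while pos < n:
        best_len = -1
        best_p = 0
        for p in periods:
            if pos + 2 * p > n:
                # fewer than 2 complete copies possible; thresholds are >= 2
                continue
            j = pos
            while j + p < n and valid[j] and valid[j + p] and s[j] == s[j + p]:
                j += 1
            run_len = j - pos + p
            if run_len // p < minc[p]:
                continue
            motif = s[pos: pos + p]
            if not _is_primitive(motif):
                continue
            if run_len > best_len:
                best_len = run_len
                best_p = p
        if best_len < 0:
            pos += 1
            continue
        motif = s[pos: pos + best_p]
        loci.append(RepeatLocus(
            sequence_id=sequence_id,
            start=pos,
            end=pos + best_len,
            period=best_p,
            motif=motif,
            canonical_motif=canonical_motif(motif, params.fold_strands),
            copies=best_len // best_p,
        ))
        pos += best_len
    return loci


# -- summaries and FASTA ----------------------------------------------------

def summarize_genome(species: str, loci: list[RepeatLocus],
                     assembly_length: int) -> GenomeMsatProfile:
    """Aggregate per-locus bp into the per-genome profile (bp by period
    class, total bp, bp per Mbp of assembly, and genomic proportion)."""
    if assembly_length <= 0:
        raise ValueError(f"assembly_length must be positive, got {assembly_length}")
    bp_by_period = {p: 0 for p in range(2, 7)}
    for loc in loci:
        bp_by_period[loc.period] += loc.end - loc.start
    total = sum(bp_by_period.values())
    return GenomeMsatProfile(
        species=species,
        assembly_length=assembly_length,
        bp_by_period=bp_by_period,
        total_bp=total,
        content_per_mbp=total / (assembly_length / 1e6),
        proportion=total / assembly_length,
    )


def _open_maybe_gzip(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def scan_fasta(path: str | os.PathLike, params: ScanParams | None = None,
               species: str | None = None,
               ) -> tuple[GenomeMsatProfile, list[RepeatLocus]]:
    """Scan every record of a (optionally gzipped) FASTA file.

    assembly_length counts all bases including ambiguity codes; loci carry
    their record ids.
    """
    if params is None:
        params = ScanParams()
    if species is None:
        species = os.path.basename(str(path)).split(".")[0]
    total_len = 0
    all_loci: list[RepeatLocus] = []
    n_records = 0
    with _open_maybe_gzip(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            n_records += 1
            seq = str(record.seq)
            if not seq:
                raise IOError(f"empty FASTA record {record.id!r} in {path}")
            total_len += len(seq)
            all_loci.extend(scan_sequence(record.id, seq, params))
    if n_records == 0:
        raise IOError(f"no FASTA records found in {path}")
    return summarize_genome(species, all_loci, total_len), all_loci


LOCUS_COLUMNS = ["sequence_id", "start", "end", "period", "motif",
                 "canonical_motif", "copies"]
PROFILE_COLUMNS = ["species", "assembly_length", "bp_2mer", "bp_3mer",
                   "bp_4mer", "bp_5mer", "bp_6mer", "total_bp",
                   "content_per_mbp", "proportion"]


def loci_to_rows(loci: list[RepeatLocus]) -> list[list]:
    return [[l.sequence_id, l.start, l.end, l.period, l.motif,
             l.canonical_motif, l.copies] for l in loci]


def profile_to_row(profile: GenomeMsatProfile) -> list:
    return [profile.species, profile.assembly_length,
            *[profile.bp_by_period[p] for p in range(2, 7)],
            profile.total_bp, profile.content_per_mbp, profile.proportion]
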
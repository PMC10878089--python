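"""Repeat architecture of linear mitogenomes.

Linear ciliate mitochondria are capped by tandem telomeric repeats whose unit
length varies enormously between species (tens to >100 bp, with copy numbers
into the hundreds), and often carry an AT-rich central repeat (CR) region
implicated in replication initiation; transcription typically switches strand
near the CR. This module detects those elements, scans for open reading
frames in unannotated regions, and profiles GC content in sliding windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._genetics import DEFAULT_TABLE, codon_table, revcomp, stop_codons
from .io import GeneOrder, Mitogenome


class UnsupportedTopologyError(ValueError):
    """Telomere detection requires a linear genome."""


@dataclass(frozen=True)
class TelomereCall:
    end: str  # "5prime" | "3prime"
    unit: str
    unit_length: int
    copy_number: float
    total_length: int
    gc: float
    start: int = 0

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.start + self.total_length)


@dataclass(frozen=True)
class CentralRepeatCall:
    start: int
    end: int
    at_content: float
    unit: str | None = None


@dataclass(frozen=True)
class OrfCall:
    start: int
    end: int
    strand: str
    length_nt: int
    protein_length_aa: int


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _count_copies(s: str, p: int, max_mismatch: int) -> int:
    """Consecutive tandem copies of s[:p] from the start of s (per-copy
    Hamming distance <= max_mismatch)."""
    unit = s[:p]
    n = 1
    while True:
        nxt = s[n * p:(n + 1) * p]
        if len(nxt) < p or _hamming(unit, nxt) > max_mismatch:
            return n
        n += 1


def detect_telomere(
    genome: Mitogenome,
    end: str = "3prime",
    max_unit: int = 150,
    min_copies: int = 5,
    mismatch_tol: float = 0.05,
    search_frac: float = 0.25,
) -> TelomereCall | None:
    """Detect a terminal tandem repeat at one end of a linear genome.

    Scans unit lengths 1..max_unit and reports the smallest period p such
    that the terminal sequence is at least ``min_copies`` tandem copies of a
    p-mer, each copy matching the terminal unit within ``mismatch_tol``
    (per-copy Hamming fraction). Only the terminal ``search_frac`` of the
    genome is examined. Returns None when no qualifying repeat exists.
    """
    if genome.topology != "linear":
        raise UnsupportedTopologyError(
            f"genome {genome.id!r} is {genome.topology}; telomeres are a "
            "linear-genome concept"
        )
    if end not in ("5prime", "3prime"):
        raise ValueError(f"unknown end {end!r}")
    if max_unit < 1:
        raise ValueError("max_unit must be >= 1")

    window = max(int(len(genome) * search_frac), max_unit * min_copies)
    if end == "5prime":
        s = genome.sequence[:window]
    else:
        s = genome.sequence[-window:][::-1]  # scan outward-in uniformly

    best = None
    for p in range(1, min(max_unit, len(s) // max(min_copies, 1)) + 1):
        copies = _count_copies(s, p, int(mismatch_tol * p))
        if copies >= min_copies:
            best = (p, copies)
            break  # smallest period wins (primitive unit)
    if best is None:
        return None
    p, copies = best
    if copies * p >= len(s) - p:
        # repeat reaches the window edge: expand to the full sequence
        full = genome.sequence if end == "5prime" else genome.sequence[::-1]
        copies = _count_copies(full, p, int(mismatch_tol * p))
    total = p * copies
    if end == "5prime":
        unit = genome.sequence[:p]
        start = 0
    else:
        unit = genome.sequence[len(genome) - p:]
        start = len(genome) - total
    region = genome.sequence[start:start + total]
    gc = (region.count("G") + region.count("C")) / len(region)
    return TelomereCall(
        end=end, unit=unit, unit_length=p, copy_number=float(copies),
        total_length=total, gc=gc, start=start,
    )


def detect_central_repeats(
    genome: Mitogenome,
    window: int = 100,
    at_min: float = 0.9465,
    min_len: int = 100,
    step: int = 10,
    exclude: list[tuple[int, int]] | None = None,
) -> list[CentralRepeatCall]:
    """AT-rich candidate central-repeat regions.

    Merges runs of sliding windows whose AT fraction is >= ``at_min``
    (default: the lower bound observed for ciliate CR regions), trims merged
    intervals until they satisfy the threshold themselves, drops intervals
    shorter than ``min_len`` and anything overlapping ``exclude`` (typically
    telomere calls).
    """
    if not 0 < at_min <= 1:
        raise ValueError("at_min must be in (0, 1]")
    seq = np.frombuffer(genome.sequence.encode(), dtype="S1")
    is_at = ((seq == b"A") | (seq == b"T")).astype(float)
    L = len(seq)
    hits = []
    for start in range(0, max(L - window, 0) + 1, step):
        w = is_at[start:start + window]
        if w.mean() >= at_min:
            hits.append((start, min(start + window, L)))
    # merge overlapping/adjacent qualifying windows
    merged: list[list[int]] = []
    for s, e in hits:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    def at_frac(s: int, e: int) -> float:
        return float(is_at[s:e].mean())

    calls = []
    for s, e in merged:
        # trim the less AT-rich flank until the interval itself qualifies
        while e - s >= min_len and at_frac(s, e) < at_min:
            if at_frac(s, s + window) <= at_frac(e - window, e):
                s += step
            else:
                e -= step
        if e - s < min_len or at_frac(s, e) < at_min:
            continue
        if exclude and any(s < xe and xs < e for xs, xe in exclude):
            continue
        calls.append(CentralRepeatCall(start=s, end=e, at_content=at_frac(s, e)))
    return calls


def strand_switch_points(order: GeneOrder) -> list[int]:
    """Indices i where transcription strand flips between gene i and i+1."""
    if len(order.elements) < 2:
        raise ValueError("need at least two genes to find strand switches")
    return [
        i
        for i in range(len(order.elements) - 1)
        if order.elements[i][1] != order.elements[i + 1][1]
    ]


def _scan_orfs_one_strand(
    seq: str, min_len_nt: int, table: int, start_codons: tuple[str, ...]
) -> list[tuple[int, int]]:
    stops = stop_codons(table)
    out = []
    n = len(seq)
    for frame in range(3):
        start = None
        for i in range(frame, n - 2, 3):
            codon = seq[i:i + 3]
            if start is None:
                if codon in start_codons:
                    start = i
            elif codon in stops:
                if i + 3 - start >= min_len_nt:
                    out.append((start, i + 3))
                start = None
        if start is not None:  # open-ended ORF running off the contig
            end = start + ((n - start) // 3) * 3
            if end - start >= min_len_nt:
                out.append((start, end))
    return out


def find_orfs(
    seq: str,
    min_len_nt: int = 75,
    table: int = DEFAULT_TABLE,
    strands: str = "both",
    start_codons: tuple[str, ...] = ("ATG",),
) -> list[OrfCall]:
    """All maximal ORFs in all six frames (or one strand).

    An ORF runs from the first start codon after the previous in-frame stop
    to the next stop codon inclusive (or to the contig end). Length includes
    the stop codon; minus-strand coordinates refer to the forward genome.
    """
    if min_len_nt < 3:
        raise ValueError("min_len_nt must be >= 3")
    seq = seq.upper()
    calls = []
    if strands in ("both", "+"):
        for s, e in _scan_orfs_one_strand(seq, min_len_nt, table, start_codons):
            has_stop = seq[e - 3:e] in stop_codons(table)
            calls.append(OrfCall(
                start=s, end=e, strand="+", length_nt=e - s,
                protein_length_aa=(e - s) // 3 - (1 if has_stop else 0),
            ))
    if strands in ("both", "-"):
        rc = revcomp(seq)
        L = len(seq)
        for s, e in _scan_orfs_one_strand(rc, min_len_nt, table, start_codons):
            has_stop = rc[e - 3:e] in stop_codons(table)
            calls.append(OrfCall(
                start=L - e, end=L - s, strand="-", length_nt=e - s,
                protein_length_aa=(e - s) // 3 - (1 if has_stop else 0),
            ))
    calls.sort(key=lambda c: (c.start, c.end, c.strand))
    return calls


def gc_profile(seq_or_genome, window: int = 100, step: int = 50) -> "np.ndarray":
    """GC proportion in windows tiled from position 0.

    The final partial window uses its own length as denominator. N bases are
    excluded from both numerator and denominator; an all-N window yields NaN.
    """
    if window < step or step < 1:
        raise ValueError("require window >= step >= 1")
    seq = seq_or_genome.sequence if isinstance(seq_or_genome, Mitogenome) else seq_or_genome
    seq = seq.upper()
    arr = np.frombuffer(seq.encode(), dtype="S1")
    is_gc = (arr == b"G") | (arr == b"C")
    is_known = is_gc | (arr == b"A") | (arr == b"T")
    out = []
    for start in range(0, len(seq), step):
        w = slice(start, start + window)
        known = int(is_known[w].sum())
        out.append(float(is_gc[w].sum()) / known if known else np.nan)
        if start + window >= len(seq):
            break
    return np.array(out)
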
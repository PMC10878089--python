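"""Genetic-code helpers shared across modules.

The mold/protozoan mitochondrial code (NCBI translation table 4) is the
package default: ciliate mitochondria terminate translation only at TAA and
TAG, and read TGA as tryptophan. Every function takes a ``table`` argument so
other codes can be substituted.
"""

from __future__ import annotations

import functools
import itertools

from Bio.Data import CodonTable

BASES = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

DEFAULT_TABLE = 4


@functools.lru_cache(maxsize=None)
def codon_table(table: int = DEFAULT_TABLE) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[table]


@functools.lru_cache(maxsize=None)
def stop_codons(table: int = DEFAULT_TABLE) -> frozenset[str]:
    return frozenset(codon_table(table).stop_codons)


@functools.lru_cache(maxsize=None)
def sense_codons(table: int = DEFAULT_TABLE) -> tuple[str, ...]:
    stops = stop_codons(table)
    return tuple(
        "".join(c) for c in itertools.product(BASES, repeat=3) if "".join(c) not in stops
    )


def translate_codon(codon: str, table: int = DEFAULT_TABLE) -> str:
    """Amino acid for a codon; ``*`` for a stop codon."""
    codon = codon.upper()
    if codon in stop_codons(table):
        return "*"
    return codon_table(table).forward_table[codon]


def is_transition(a: str, b: str) -> bool:
    """True when a<->b is a purine-purine or pyrimidine-pyrimidine change."""
    return (a in PURINES) == (b in PURINES) and a != b


def is_synonymous(codon_a: str, codon_b: str, table: int = DEFAULT_TABLE) -> bool:
    return translate_codon(codon_a, table) == translate_codon(codon_b, table)


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]
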
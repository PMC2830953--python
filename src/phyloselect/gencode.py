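"""Genetic-code tables and codon-level utilities.

The standard (NCBI table 1) code is the default everywhere.  The sense-codon
state space used by the codon substitution models excludes the three stop
codons, giving the usual 61 states.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

from Bio.Data import CodonTable

NUCS = "TCAG"
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"  # PAML ordering, used by the JTT tables

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """True if a<->b is a purine<->purine or pyrimidine<->pyrimidine change."""
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


@lru_cache(maxsize=None)
def code_table(table_id: int = 1) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[table_id]


@lru_cache(maxsize=None)
def sense_codons(table_id: int = 1) -> tuple[str, ...]:
    """All non-stop codons in TCAG enumeration order (61 for the standard code)."""
    table = code_table(table_id)
    stops = set(table.stop_codons)
    return tuple(
        "".join(c) for c in product(NUCS, repeat=3) if "".join(c) not in stops
    )


@lru_cache(maxsize=None)
def codon_index(table_id: int = 1) -> dict[str, int]:
    return {c: i for i, c in enumerate(sense_codons(table_id))}


def translate_codon(codon: str, table_id: int = 1) -> str:
    """Translate one codon; gap codon -> '-', any ambiguity/partial gap -> 'X'.

    In-frame stops translate to '*' (callers treat that as invalid input).
    """
    codon = codon.upper()
    if codon == "---":
        return "-"
    if any(c not in "ACGT" for c in codon):
        return "X"
    table = code_table(table_id)
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


@lru_cache(maxsize=None)
def codons_for_aa(table_id: int = 1) -> dict[str, tuple[str, ...]]:
    out: dict[str, list[str]] = {aa: [] for aa in AMINO_ACIDS}
    for codon in sense_codons(table_id):
        out[code_table(table_id).forward_table[codon]].append(codon)
    return {aa: tuple(cods) for aa, cods in out.items()}


def codon_hamming(c1: str, c2: str) -> int:
    return sum(a != b for a, b in zip(c1, c2))


@lru_cache(maxsize=None)
def min_code_distance(aa1: str, aa2: str, table_id: int = 1) -> int:
    """Minimum nucleotide changes between any codon pair encoding aa1 and aa2.

    Symmetric, 0 iff aa1 == aa2, and never more than 3.
    """
    aa1, aa2 = aa1.upper(), aa2.upper()
    for aa in (aa1, aa2):
        if aa not in AMINO_ACIDS:
            raise ValueError(f"not a standard amino acid: {aa!r}")
    pool = codons_for_aa(table_id)
    return min(
        codon_hamming(c1, c2) for c1 in pool[aa1] for c2 in pool[aa2]
    )
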
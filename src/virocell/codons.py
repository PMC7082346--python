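"""Canonical codon order and genetic-code helpers.

All codon-indexed arrays in this package use the fixed alphabetical order
AAA, AAC, ..., TTT (64 codons, stops included) so that vectors, tables and
TSV outputs line up across modules and runs.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

from Bio.Data import CodonTable

#: The 64 codons in alphabetical (canonical) order.
CODONS: tuple[str, ...] = tuple("".join(p) for p in product("ACGT", repeat=3))

#: Codon -> position in :data:`CODONS`.
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

STOP_SYMBOL = "*"

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=None)
def genetic_code(table_id: int = 11) -> dict[str, str]:
    """Map every codon to its amino acid (one-letter) or ``*`` for stop.

    Parameters
    ----------
    table_id : NCBI translation table number; 11 (bacteria/archaea/phage)
        is the package default.
    """
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return {c: table.forward_table.get(c, STOP_SYMBOL) for c in CODONS}


@lru_cache(maxsize=None)
def synonymous_families(table_id: int = 11) -> dict[str, tuple[str, ...]]:
    """Amino acid (incl. ``*``) -> its synonymous codons in canonical order."""
    code = genetic_code(table_id)
    fams: dict[str, list[str]] = {}
    for codon in CODONS:
        fams.setdefault(code[codon], []).append(codon)
    return {aa: tuple(cs) for aa, cs in fams.items()}
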
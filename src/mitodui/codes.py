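"""Genetic-code helpers.

Everything in this package defaults to the invertebrate mitochondrial code
(NCBI translation table 5), which is the code used for bivalve mitogenomes.
Tables are pulled from Biopython's registry once and cached as plain dicts so
that hot loops (NG86 site counting, codon evolution) stay cheap.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

BASES = "ACGT"

#: Start codons observed in invertebrate mitogenomes, split the way the
#: mitogenomics literature splits them.
CONVENTIONAL_STARTS = frozenset({"ATG", "ATA", "ATT"})
ALTERNATIVE_STARTS = frozenset({"ATC", "TTG", "GTG"})
DEFAULT_START_CODONS = CONVENTIONAL_STARTS | ALTERNATIVE_STARTS

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=None)
def codon_to_aa(table_id: int = 5) -> dict[str, str]:
    """Codon -> amino acid map with stop codons mapped to ``*``."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


@lru_cache(maxsize=None)
def stop_codons(table_id: int = 5) -> frozenset[str]:
    return frozenset(CodonTable.unambiguous_dna_by_id[table_id].stop_codons)


@lru_cache(maxsize=None)
def sense_codons(table_id: int = 5) -> tuple[str, ...]:
    """All 4^3 - stops codons, lexicographic order."""
    aa = codon_to_aa(table_id)
    return tuple(sorted(c for c, a in aa.items() if a != "*"))


def translate(cds: str, table_id: int = 5) -> str:
    """Translate an in-frame CDS; stops rendered as ``*``.

    Raises ``ValueError`` if the length is not a multiple of 3.  Codons with
    ambiguity codes translate to ``X``.
    """
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    aa = codon_to_aa(table_id)
    cds = cds.upper()
    return "".join(aa.get(cds[i:i + 3], "X") for i in range(0, len(cds), 3))
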
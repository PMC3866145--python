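"""Base composition, strand skews, partitioned composition, codon usage.

Strand asymmetry follows the standard definitions
AT skew = (A - T) / (A + T) and GC skew = (G - C) / (G + C),
computed over unambiguous bases only.  Whole-genome statistics are taken on
the deposited L strand; gene partitions (PCGs, rRNAs, tRNAs) on the
strand-corrected sense sequences, which is what gives mitogenome composition
tables their characteristic sign structure (positive AT skew on the L strand,
negative on the protein sense strand).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .codes import codon_to_aa, stop_codons
from .genome import IntergenicRegion, MitoGenome

__all__ = ["CompositionStats", "CodonUsageTable", "base_stats",
           "partition_stats", "codon_usage"]


@dataclass(frozen=True)
class CompositionStats:
    at_pct: float
    gc_pct: float
    at_skew: float
    gc_skew: float
    n_effective: int
    counts: tuple[int, int, int, int]  # A, C, G, T

    @property
    def a(self): return self.counts[0]
    @property
    def c(self): return self.counts[1]
    @property
    def g(self): return self.counts[2]
    @property
    def t(self): return self.counts[3]


def base_stats(seq: str) -> CompositionStats:
    """Composition of one sequence; ambiguity codes are excluded throughout."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
    n = a + c + g + t
    if n == 0:
        raise ValueError("sequence has no unambiguous A/C/G/T bases")
    return CompositionStats(
        at_pct=100.0 * (a + t) / n,
        gc_pct=100.0 * (g + c) / n,
        at_skew=(a - t) / (a + t) if a + t else 0.0,
        gc_skew=(g - c) / (g + c) if g + c else 0.0,
        n_effective=n,
        counts=(a, c, g, t))


def _pcg_concat(genome: MitoGenome, include_orf: bool, include_atp8: bool) -> str:
    parts = []
    for f in genome.features:
        if f.kind == "PCG" or (include_orf and f.kind == "ORF"):
            if f.label == "atp8" and not include_atp8:
                continue
            cds = genome.extract(f)
            parts.append(cds[:len(cds) - len(cds) % 3])
    return "".join(parts)


def partition_stats(genome: MitoGenome,
                    cr: IntergenicRegion | None = None,
                    include_orf: bool = False,
                    include_atp8: bool = True) -> dict[str, CompositionStats]:
    """Composition table keyed by partition.

    Partitions: whole genome (L strand), rrnS, rrnL, protein-coding genes
    (concatenated sense CDS; the gender-specific ORF excluded by default),
    their three codon positions, tRNAs, and the control region.  When ``cr``
    is not supplied the top-ranked control-region candidate is used; missing
    partitions are simply omitted.
    """
    out: dict[str, CompositionStats] = {"whole": base_stats(genome.sequence)}
    for r in ("rrnS", "rrnL"):
        try:
            out[r] = base_stats(genome.extract(r))
        except KeyError:
            pass
    pcg = _pcg_concat(genome, include_orf, include_atp8)
    if pcg:
        out["PCGs"] = base_stats(pcg)
        for pos in range(3):
            out[f"codon-pos-{pos + 1}"] = base_stats(pcg[pos::3])
    trnas = "".join(genome.extract(f) for f in genome.features if f.kind == "tRNA")
    if trnas:
        out["tRNAs"] = base_stats(trnas)
    if cr is None:
        from .repeats import control_region_candidates
        try:
            candidates = control_region_candidates(genome)
        except Exception:
            candidates = []
        if candidates:
            cr = candidates[0].region
    if cr is not None:
        out["CR"] = base_stats(cr.sequence)
    return out


@dataclass(frozen=True)
class CodonUsageTable:
    counts: Mapping[str, int]           # DNA codon -> count (stops included)
    code: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def count(self, codon: str) -> int:
        return self.counts.get(codon.upper().replace("U", "T"), 0)

    @property
    def most_frequent(self) -> str:
        """Most frequent codon, lexicographic on ties."""
        return min(self.counts, key=lambda c: (-self.counts[c], c))

    @property
    def least_frequent_non_stop(self) -> str:
        """Rarest sense codon of the code (zero counts included)."""
        stops = stop_codons(self.code)
        aa = codon_to_aa(self.code)
        return min((c for c in aa if c not in stops),
                   key=lambda c: (self.counts.get(c, 0), c))

    def rscu(self) -> dict[str, float]:
        """Relative synonymous codon usage over sense codons.

        RSCU = observed count / (family total / family size); ``nan`` for a
        synonymous family with no observations.
        """
        aa_map = codon_to_aa(self.code)
        families: dict[str, list[str]] = {}
        for codon, aa in sorted(aa_map.items()):
            if aa != "*":
                families.setdefault(aa, []).append(codon)
        out: dict[str, float] = {}
        for aa, codons in families.items():
            total = sum(self.counts.get(c, 0) for c in codons)
            for c in codons:
                out[c] = (self.counts.get(c, 0) * len(codons) / total
                          if total else float("nan"))
        return out

    @staticmethod
    def as_rna(codon: str) -> str:
        return codon.replace("T", "U")


def codon_usage(cds_collection: Sequence[str] | Iterable[str],
                code: int = 5) -> CodonUsageTable:
    """Exact codon counts over a collection of in-frame coding sequences."""
    counts: dict[str, int] = {}
    for idx, cds in enumerate(cds_collection):
        if len(cds) % 3:
            raise ValueError(f"CDS #{idx} length {len(cds)} not a multiple of 3")
        s = cds.upper()
        for i in range(0, len(s), 3):
            codon = s[i:i + 3]
            counts[codon] = counts.get(codon, 0) + 1
    return CodonUsageTable(counts, code)
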
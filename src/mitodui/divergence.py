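"""Pairwise F/M divergence: codon-aware alignment, p-distances, NG86 Ka/Ks.

Workflow for a protein gene shared by the two genomes:

1. strip the terminal stop, translate (table 5);
2. globally align the peptides (Needleman-Wunsch, BLOSUM62, affine 10/1 —
   a pairwise stand-in for progressive aligners, adequate because the F/M
   comparison is pairwise per gene);
3. retro-align: impose the peptide alignment back onto the codons so
   nucleotide columns stay in frame;
4. p-distances with site-resampling bootstrap standard errors, and
   Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction.

The NG86 implementation is the classic unweighted formulation: per-codon
synonymous site fractions averaged over the two sequences (substitutions that
would create a stop codon count as nonsynonymous, so S + N = 3 x codons
exactly), and observed differences averaged with equal weight over all
minimal-substitution pathways that avoid stop codons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .codes import codon_to_aa, stop_codons, translate
from .genome import MitoGenome

__all__ = [
    "CodonAlignment", "DivergenceResult", "NGResult", "SaturationError",
    "align_aa_global", "align_nt_global", "retro_align", "p_distance",
    "bootstrap_se", "nei_gojobori", "concat_and_mask", "gene_divergence",
    "strip_terminal_stop",
]

GAP = "-"
_NT = set("ACGT")
_AA = set("ACDEFGHIKLMNPQRSTVWY")


class SaturationError(ValueError):
    """Observed proportion >= 3/4; Jukes-Cantor correction undefined."""


@dataclass(frozen=True)
class CodonAlignment:
    """Two gap-aware in-frame nucleotide rows (gaps in whole-codon triplets)."""

    labels: tuple[str, str]
    rows: tuple[str, str]
    code: int = 5

    def __post_init__(self):
        a, b = self.rows
        if len(a) != len(b):
            raise ValueError("rows differ in length")
        if len(a) % 3:
            raise ValueError("alignment length not a multiple of 3")
        for row in self.rows:
            for i in range(0, len(row), 3):
                cod = row[i:i + 3]
                if GAP in cod and cod != GAP * 3:
                    raise ValueError(f"partial codon gap at column {i}")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def ungapped(self, which: int) -> str:
        return self.rows[which].replace(GAP, "")

    def codon_pairs(self) -> list[tuple[str, str]]:
        """Codon columns with neither row gapped nor ambiguous."""
        a, b = self.rows
        out = []
        for i in range(0, len(a), 3):
            ca, cb = a[i:i + 3], b[i:i + 3]
            if set(ca) <= _NT and set(cb) <= _NT:
                out.append((ca, cb))
        return out


@dataclass(frozen=True)
class NGResult:
    ka: float
    ks: float
    omega: float | None     # None when Ks == 0
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    codons: int


@dataclass(frozen=True)
class DivergenceResult:
    gene: str
    pd_nt: float
    pd_nt_se: float
    pd_aa: float | None
    pd_aa_se: float | None
    ka: float | None
    ks: float | None
    omega: float | None
    sites_used: int


# ---------------------------------------------------------------------------
# alignment

def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_aa_global(pep_a: str, pep_b: str, matrix: str = "BLOSUM62",
                    gap_open: float = 10.0, gap_extend: float = 1.0
                    ) -> tuple[str, str]:
    """Optimal global peptide alignment; the first optimal traceback is
    returned, which makes tie-breaking deterministic."""
    for pep in (pep_a, pep_b):
        if not pep:
            raise ValueError("empty peptide")
        if "*" in pep:
            raise ValueError("internal stop in peptide")
    aln = _aligner(matrix, gap_open, gap_extend).align(pep_a, pep_b)[0]
    return str(aln[0]), str(aln[1])


def align_nt_global(seq_a: str, seq_b: str, match: float = 2.0,
                    mismatch: float = -1.0, gap_open: float = 5.0,
                    gap_extend: float = 1.0) -> tuple[str, str]:
    """Global nucleotide alignment (used for the rRNA genes)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    return str(aln[0]), str(aln[1])


def strip_terminal_stop(cds: str, code: int = 5) -> str:
    if len(cds) >= 3 and len(cds) % 3 == 0 and cds[-3:].upper() in stop_codons(code):
        return cds[:-3]
    return cds


def retro_align(aa_alignment: tuple[str, str], cds_a: str, cds_b: str,
                labels: tuple[str, str] = ("a", "b"), code: int = 5
                ) -> CodonAlignment:
    """Impose a peptide alignment back onto the source codons."""
    rows = []
    for aa_row, cds in zip(aa_alignment, (cds_a, cds_b)):
        cds = strip_terminal_stop(cds.upper(), code)
        pep = translate(cds, code)
        if pep != aa_row.replace(GAP, ""):
            for pos, (x, y) in enumerate(zip(pep, aa_row.replace(GAP, ""))):
                if x != y:
                    raise ValueError(
                        f"CDS/peptide mismatch at residue {pos}: "
                        f"translated {x!r}, aligned {y!r}")
            raise ValueError(
                f"CDS translates to {len(pep)} residues but the alignment row "
                f"has {len(aa_row.replace(GAP, ''))}")
        out, k = [], 0
        for ch in aa_row:
            if ch == GAP:
                out.append(GAP * 3)
            else:
                out.append(cds[3 * k:3 * k + 3])
                k += 1
        rows.append("".join(out))
    return CodonAlignment(tuple(labels), (rows[0], rows[1]), code)


# ---------------------------------------------------------------------------
# p-distance and bootstrap

def _comparable_columns(row_a: str, row_b: str, level: str) -> tuple[np.ndarray, np.ndarray]:
    alphabet = _NT if level == "nt" else _AA
    comp, diff = [], []
    for x, y in zip(row_a.upper(), row_b.upper()):
        ok = x in alphabet and y in alphabet
        comp.append(ok)
        diff.append(ok and x != y)
    return np.array(comp), np.array(diff)


def p_distance(alignment: tuple[str, str] | CodonAlignment, level: str = "nt") -> float:
    """Proportion of differing sites, pairwise deletion of gap/ambiguous
    columns."""
    rows = alignment.rows if isinstance(alignment, CodonAlignment) else alignment
    comp, diff = _comparable_columns(rows[0], rows[1], level)
    n = int(comp.sum())
    if n == 0:
        raise ValueError("no comparable sites")
    return float(diff.sum()) / n


def bootstrap_se(alignment: tuple[str, str] | CodonAlignment, level: str = "nt",
                 replicates: int = 1000, seed: int = 42) -> float:
    """Site-resampling bootstrap standard error of the p-distance."""
    if replicates < 100:
        raise ValueError("use >= 100 bootstrap replicates")
    rows = alignment.rows if isinstance(alignment, CodonAlignment) else alignment
    comp, diff = _comparable_columns(rows[0], rows[1], level)
    ncol = len(comp)
    if int(comp.sum()) == 0:
        raise ValueError("no comparable sites")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, ncol, size=(replicates, ncol))
    comp_r = comp[idx].sum(axis=1)
    diff_r = diff[idx].sum(axis=1)
    with np.errstate(invalid="ignore"):
        stats = np.where(comp_r > 0, diff_r / np.maximum(comp_r, 1), np.nan)
    return float(np.nanstd(stats, ddof=1))


# ---------------------------------------------------------------------------
# Nei-Gojobori 1986

@lru_cache(maxsize=None)
def _syn_fraction(codon: str, code: int) -> float:
    """Synonymous sites of one codon (changes to stops are nonsynonymous)."""
    aa = codon_to_aa(code)
    ref = aa[codon]
    s = 0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if aa[alt] == ref and aa[alt] != "*":
                s += 1
    return s / 3.0


@lru_cache(maxsize=None)
def _pair_differences(ca: str, cb: str, code: int) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair, equal-weight average over all
    minimal-substitution pathways that avoid stop codons."""
    aa = codon_to_aa(code)
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return 0.0, 0.0
    best: list[tuple[int, int]] = []
    for order in itertools.permutations(positions):
        cur = ca
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if aa[nxt] == "*" and nxt != cb:
                blocked = True
                break
            sd += aa[nxt] == aa[cur]
            nd += aa[nxt] != aa[cur]
            cur = nxt
        if not blocked:
            best.append((sd, nd))
    if not best:
        # every pathway passes through a stop; fall back to all pathways
        for order in itertools.permutations(positions):
            cur = ca
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                sd += aa[nxt] == aa[cur]
                nd += aa[nxt] != aa[cur]
                cur = nxt
            best.append((sd, nd))
    return (sum(b[0] for b in best) / len(best),
            sum(b[1] for b in best) / len(best))


def jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.4f} >= 3/4")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def nei_gojobori(alignment: CodonAlignment, code: int | None = None) -> NGResult:
    """NG86 Ka/Ks on the gap-free codon columns of an alignment."""
    code = alignment.code if code is None else code
    pairs = alignment.codon_pairs()
    if not pairs:
        raise ValueError("no comparable codons after masking")
    aa = codon_to_aa(code)
    for ca, cb in pairs:
        for c in (ca, cb):
            if aa[c] == "*":
                raise ValueError(f"stop codon {c} inside alignment")
    s_a = sum(_syn_fraction(ca, code) for ca, _ in pairs)
    s_b = sum(_syn_fraction(cb, code) for _, cb in pairs)
    S = (s_a + s_b) / 2.0
    N = 3.0 * len(pairs) - S
    sd = nd = 0.0
    for ca, cb in pairs:
        d_s, d_n = _pair_differences(ca, cb, code)
        sd += d_s
        nd += d_n
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    omega = ka / ks if ks > 0 else None
    return NGResult(ka=ka, ks=ks, omega=omega, s_sites=S, n_sites=N,
                    sd=sd, nd=nd, ps=ps, pn=pn, codons=len(pairs))


# ---------------------------------------------------------------------------
# concatenation

def concat_and_mask(alignments: Sequence[CodonAlignment],
                    drop_positions: Sequence[int] = (),
                    names: Sequence[str] | None = None,
                    ) -> tuple[CodonAlignment | tuple[str, str], dict[str, tuple[int, int]]]:
    """Concatenate per-gene codon alignments; optionally drop codon positions.

    Returns the concatenated alignment and a partition map
    ``gene label -> [start, end)`` in output column coordinates.  With no
    dropped positions the result is a :class:`CodonAlignment`; otherwise a
    plain row pair (frame is gone once positions are masked).
    """
    if not alignments:
        raise ValueError("nothing to concatenate")
    labels = alignments[0].labels
    drop = set(drop_positions)
    if not drop <= {1, 2, 3}:
        raise ValueError(f"drop_positions must be within {{1,2,3}}: {sorted(drop)}")
    if names is None:
        names = [f"g{i + 1}" for i in range(len(alignments))]
    if len(names) != len(alignments) or len(set(names)) != len(names):
        raise ValueError("names must be unique, one per alignment")
    keep = [p - 1 for p in (1, 2, 3) if p not in drop]
    rows = ["", ""]
    partition: dict[str, tuple[int, int]] = {}
    for name, aln in zip(names, alignments):
        if aln.labels != labels:
            raise ValueError(f"label mismatch: {aln.labels} vs {labels}")
        start = len(rows[0])
        for which in (0, 1):
            row = aln.rows[which]
            rows[which] += "".join(row[i + p] for i in range(0, len(row), 3)
                                   for p in keep)
        partition[name] = (start, len(rows[0]))
    if not drop:
        return CodonAlignment(labels, (rows[0], rows[1]), alignments[0].code), partition
    return (rows[0], rows[1]), partition


# ---------------------------------------------------------------------------
# per-gene workflow

def aa_rows(alignment: CodonAlignment) -> tuple[str, str]:
    """Peptide rows of a codon alignment (gap codon -> '-', ambiguous -> 'X')."""
    aa = codon_to_aa(alignment.code)
    out = []
    for row in alignment.rows:
        chars = []
        for i in range(0, len(row), 3):
            cod = row[i:i + 3]
            chars.append(GAP if cod == GAP * 3 else aa.get(cod, "X"))
        out.append("".join(chars))
    return out[0], out[1]


RRNA_LABELS = ("rrnS", "rrnL")


def gene_divergence(f_genome: MitoGenome, m_genome: MitoGenome,
                    labels: Sequence[str] | None = None, code: int = 5,
                    bootstrap_replicates: int = 1000, seed: int = 42
                    ) -> list[DivergenceResult]:
    """Per-gene F/M divergence table (rRNAs: nucleotide level only)."""
    if labels is None:
        shared = {f.label for f in f_genome.features} & \
                 {f.label for f in m_genome.features}
        labels = [f.label for f in f_genome.features
                  if f.label in shared and f.kind in ("PCG", "rRNA")]
    out = []
    for label in labels:
        if label in RRNA_LABELS:
            rows = align_nt_global(f_genome.extract(label), m_genome.extract(label))
            out.append(DivergenceResult(
                gene=label,
                pd_nt=p_distance(rows, "nt"),
                pd_nt_se=bootstrap_se(rows, "nt", bootstrap_replicates, seed),
                pd_aa=None, pd_aa_se=None, ka=None, ks=None, omega=None,
                sites_used=sum(1 for x, y in zip(*rows)
                               if x in _NT and y in _NT)))
            continue
        aln = pairwise_codon_alignment(f_genome.extract(label),
                                       m_genome.extract(label),
                                       labels=(f_genome.identifier,
                                               m_genome.identifier), code=code)
        ng = nei_gojobori(aln)
        pep_rows = aa_rows(aln)
        out.append(DivergenceResult(
            gene=label,
            pd_nt=p_distance(aln, "nt"),
            pd_nt_se=bootstrap_se(aln, "nt", bootstrap_replicates, seed),
            pd_aa=p_distance(pep_rows, "aa"),
            pd_aa_se=bootstrap_se(pep_rows, "aa", bootstrap_replicates, seed),
            ka=ng.ka, ks=ng.ks, omega=ng.omega, sites_used=3 * ng.codons))
    return out


def pairwise_codon_alignment(cds_a: str, cds_b: str,
                             labels: tuple[str, str] = ("a", "b"),
                             code: int = 5) -> CodonAlignment:
    """Peptide-guided codon alignment of two CDSs (terminal stops stripped)."""
    a = strip_terminal_stop(cds_a.upper(), code)
    b = strip_terminal_stop(cds_b.upper(), code)
    aa_pair = align_aa_global(translate(a, code), translate(b, code))
    return retro_align(aa_pair, a, b, labels, code)
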
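"""Synthetic mitogenome and codon-evolution generators.

Every analysis stage in this package has a download-free test surface built
here: circular annotated genomes with a controlled gene roster and order,
planted composition and strand skews, a control region carrying a tandem
repeat whose unit folds into a stem-loop, and F/M coding-sequence pairs
diverged under a controllable nonsynonymous/synonymous acceptance ratio
(omega).

The flagship fixture is :func:`solenaia_like_pair`: a female-type and male-type
genome pair conditioned on the published architecture of the *Solenaia
carinatus* mitogenomes — genome sizes 16716/17102 bp, the printed gene
lengths and start/stop codons, 27/23 unassigned regions, 2/6 overlapping
pairs (1-8 and 1-168 bp), control regions of 1049/848 bp carrying 8x101 and
7x102 tandem arrays, and the Gonideinae-type F gene order that differs from
the common unionoid order by the relative position of nad2 and nad3.  The
male protein genes are evolved from the female ones under a codon process,
so the pair also carries a realistic divergence signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .codes import revcomp, sense_codons, stop_codons
from .divergence import CodonAlignment, _pair_differences, _syn_fraction
from .genome import GeneFeature, MitoGenome
from .gene_order import GeneOrder

__all__ = [
    "GeneEntry", "CRSpec", "GenomeSpec", "EvolveSpec", "SpecError",
    "simulate_genome", "evolve_codon_sequences", "apply_rearrangement",
    "solenaia_like_pair", "solenaia_like_specs",
    "UNIONOID_PCG_RRNA_ORDER", "GONIDEINAE_F_PCG_RRNA_ORDER",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SpecError(ValueError):
    """Infeasible generator specification."""


@dataclass(frozen=True)
class GeneEntry:
    label: str
    kind: str                     # PCG | ORF | rRNA | tRNA
    length: int
    strand: int = 1
    start_codon: str | None = None   # PCG/ORF only
    stop_codon: str | None = None


@dataclass(frozen=True)
class CRSpec:
    after: str                    # gap following this gene hosts the CR
    length: int
    at_pct: float
    at_skew: float = 0.0
    gc_skew: float = -0.4
    period: int = 101
    copies: float = 8.0
    identity: float = 0.99
    hairpin_unit: bool = True     # embed a stem-loop-capable inverted repeat


@dataclass(frozen=True)
class Composition:
    at_pct: float
    at_skew: float = 0.0
    gc_skew: float = 0.0

    def probs(self) -> np.ndarray:
        at = self.at_pct / 100.0
        gc = 1.0 - at
        p = np.array([at * (1 + self.at_skew) / 2,          # A
                      gc * (1 - self.gc_skew) / 2,          # C
                      gc * (1 + self.gc_skew) / 2,          # G
                      at * (1 - self.at_skew) / 2])         # T
        if (p < 0).any():
            raise SpecError("composition targets imply negative base probability")
        return p / p.sum()


@dataclass(frozen=True)
class GenomeSpec:
    identifier: str
    length: int
    genes: tuple[GeneEntry, ...]          # circle order
    gaps: tuple[int, ...]                 # gap after gene i (negative = overlap)
    backbone: Composition = Composition(61.0, 0.22, -0.39)
    codon_comp: tuple[Composition, Composition, Composition] = (
        Composition(56.0, -0.10, 0.29),
        Composition(60.0, -0.46, -0.03),
        Composition(64.0, -0.20, 0.23))
    cr: CRSpec | None = None
    sex_type: str = "unknown"
    seed: int = 0
    code: int = 5

    def validate(self) -> None:
        if self.genes and len(self.gaps) != len(self.genes):
            raise SpecError("need one gap per junction (gap after each gene)")
        total = sum(g.length for g in self.genes) + sum(self.gaps)
        if self.genes and total != self.length:
            raise SpecError(
                f"{self.identifier}: roster + gaps = {total} != length {self.length}")
        for g in self.genes:
            if g.kind in ("PCG", "ORF") and g.length % 3:
                raise SpecError(f"{g.label}: coding length not a multiple of 3")
        if self.cr is not None:
            labels = [g.label for g in self.genes]
            if self.cr.after not in labels:
                raise SpecError(f"CR anchor {self.cr.after!r} not in roster")
            if self.gaps[labels.index(self.cr.after)] != self.cr.length:
                raise SpecError("CR length must equal the gap after its anchor")


@dataclass(frozen=True)
class EvolveSpec:
    n_codons: int
    omega: float
    ks_target: float
    code: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.omega < 0:
            raise SpecError("omega must be >= 0")
        if not 0 <= self.ks_target < 4.0:
            raise SpecError("synonymous divergence target outside [0, 4)")


# ---------------------------------------------------------------------------
# low-level sampling

def _sample_seq(rng: np.random.Generator, n: int, comp: Composition) -> str:
    idx = rng.choice(4, size=n, p=comp.probs())
    return BASES[idx].tobytes().decode()


def _sample_codons(rng: np.random.Generator, n: int,
                   comps: Sequence[Composition], code: int) -> list[str]:
    stops = stop_codons(code)
    cols = [rng.choice(4, size=n, p=c.probs()) for c in comps]
    codons = [BASES[[cols[0][i], cols[1][i], cols[2][i]]].tobytes().decode()
              for i in range(n)]
    for i, c in enumerate(codons):
        while codons[i] in stops:
            codons[i] = BASES[rng.choice(4, size=3, p=comps[0].probs())]\
                .tobytes().decode()
    return codons


def _mutate_nt(rng: np.random.Generator, seq: str, p: float,
               comp: Composition | None = None) -> str:
    """Substitute each base with probability ``p``; replacements drawn
    uniformly, or from ``comp`` so composition is preserved in expectation."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < p
    cond = None
    if comp is not None:
        probs = comp.probs()
        cond = {}
        for bi, b in enumerate(BASES):
            q = probs.copy()
            q[bi] = 0.0
            cond[b] = q / q.sum()
    for i in np.flatnonzero(hit):
        if cond is None:
            arr[i] = rng.choice(BASES[BASES != arr[i]])
        else:
            arr[i] = BASES[rng.choice(4, p=cond[arr[i]])]
    return arr.tobytes().decode()


def _cr_sequence(rng: np.random.Generator, cr: CRSpec) -> str:
    comp = Composition(cr.at_pct, cr.at_skew, cr.gc_skew)

    def embed_hairpin(u: list[str]) -> list[str]:
        stem, loop = 12, 5
        off = min(10, max(0, cr.period - 2 * stem - loop - 1))
        if cr.period < 2 * stem + loop + off:
            raise SpecError("repeat unit too short for the requested stem-loop")
        left = "".join(u[off:off + stem])
        u[off + stem + loop:off + 2 * stem + loop] = list(revcomp(left))
        return u

    def draw(n: int, tries: int, tol: float, finish=None) -> str:
        # the unit is amplified `copies` times, so its composition must track
        # the regional target tightly: keep the best of a bounded set of draws
        best, best_err = None, None
        for _ in range(tries):
            cand = _sample_seq(rng, n, comp)
            if finish is not None:
                cand = "".join(finish(list(cand)))
            at = 100.0 * sum(cand.count(b) for b in "AT") / n
            err = abs(at - cr.at_pct)
            if best is None or err < best_err:
                best, best_err = cand, err
            if err < tol:
                break
        return best

    unit = draw(cr.period, 200, 0.75,
                finish=embed_hairpin if cr.hairpin_unit else None)
    full = int(cr.copies)
    frac = int(round((cr.copies - full) * cr.period))
    copies = []
    for c in range(full):
        copies.append(unit if c == 0 or cr.identity >= 1.0
                      else _mutate_nt(rng, unit, 1.0 - cr.identity))
    array = "".join(copies) + unit[:frac]
    if len(array) > cr.length:
        raise SpecError("tandem array longer than the control region")
    pad = cr.length - len(array)
    left_pad = draw(pad // 2, 50, 1.5) if pad // 2 else ""
    right_pad = draw(pad - pad // 2, 50, 1.5) if pad - pad // 2 else ""
    return left_pad + array + right_pad


# ---------------------------------------------------------------------------
# genome assembly

def _layout(spec: GenomeSpec) -> list[tuple[GeneEntry, int, int, bool]]:
    """(entry, start, end, wraps) for each roster gene, walking the circle."""
    L = spec.length
    out = []
    cursor = 0
    for entry, gap in zip(spec.genes, spec.gaps):
        start = cursor % L
        wraps = start + entry.length > L
        end = (start + entry.length) % L
        if end == 0:
            end, wraps = L, False
        out.append((entry, start, end, wraps))
        cursor += entry.length + gap
    if spec.genes and cursor != spec.length:
        raise SpecError("layout does not close the circle")
    return out


class _Assembler:
    def __init__(self, length: int):
        self.seq = bytearray(length)
        self.L = length
        self.protected: dict[int, int] = {}   # genome pos -> byte value

    def write(self, pos: int, sense: str, strand: int, protect: bool = False):
        data = sense if strand == 1 else revcomp(sense)
        start = pos % self.L
        for k, ch in enumerate(data):
            p = (start + k) % self.L
            b = ord(ch)
            if protect:
                if p in self.protected and self.protected[p] != b:
                    raise SpecError(
                        f"conflicting protected bases at genome position {p}")
                self.protected[p] = b
            self.seq[p] = b


def simulate_genome(spec: GenomeSpec,
                    bodies: Mapping[str, str] | None = None) -> MitoGenome:
    """Realize a :class:`GenomeSpec` as an annotated circular genome.

    ``bodies`` optionally supplies sense-strand sequences for named genes —
    for coding genes the internal codons (start and stop codons are added
    from the spec), for rRNA/tRNA the whole gene — which is how the
    male-type fixture reuses (evolved copies of) the female-type genes.
    Fully deterministic for a given spec and ``bodies``.
    """
    spec.validate()
    bodies = bodies or {}
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    asm = _Assembler(L)
    stops = stop_codons(spec.code)

    asm.write(0, _sample_seq(rng, L, spec.backbone), 1)
    placed = _layout(spec)

    # gene bodies
    for entry, start, end, wraps in placed:
        if entry.kind in ("PCG", "ORF"):
            ncod = entry.length // 3
            if ncod < 2:
                raise SpecError(f"{entry.label}: too short for start + stop")
            if entry.label in bodies:
                body = bodies[entry.label]
                if len(body) != entry.length - 6:
                    raise SpecError(f"{entry.label}: donor body length mismatch")
            else:
                body = "".join(_sample_codons(rng, ncod - 2, spec.codon_comp,
                                              spec.code))
            sense = (entry.start_codon or "ATG") + body + \
                    (entry.stop_codon or "TAA")
        else:
            sense = bodies.get(entry.label) or _sample_seq(
                rng, entry.length, spec.backbone)
            if len(sense) != entry.length:
                raise SpecError(f"{entry.label}: donor length mismatch")
        asm.write(start, sense, entry.strand)

    # control region
    if spec.cr is not None:
        labels = [g.label for g in spec.genes]
        i = labels.index(spec.cr.after)
        cr_start = (placed[i][1] + spec.genes[i].length) % L
        asm.write(cr_start, _cr_sequence(rng, spec.cr), 1)

    # terminal codons win over any overlapping body
    for entry, start, end, wraps in placed:
        if entry.kind not in ("PCG", "ORF"):
            continue
        if entry.start_codon:
            _write_sense_slice(asm, entry, start, 0, entry.start_codon)
        if entry.stop_codon:
            _write_sense_slice(asm, entry, start, entry.length - 3,
                               entry.stop_codon)

    _repair_internal_stops(asm, placed, stops)

    features = [GeneFeature(e.label, e.kind, s, en, e.strand, w)
                for e, s, en, w in placed]
    return MitoGenome(spec.identifier, asm.seq.decode(), features,
                      is_circular=True, sex_type=spec.sex_type)


def _sense_pos(entry: GeneEntry, start: int, idx: int, L: int) -> int:
    """Genome position of sense-strand index ``idx`` of a gene."""
    if entry.strand == 1:
        return (start + idx) % L
    return (start + entry.length - 1 - idx) % L


def _write_sense_slice(asm: _Assembler, entry: GeneEntry, start: int,
                       idx: int, sense: str) -> None:
    for k, ch in enumerate(sense):
        p = _sense_pos(entry, start, idx + k, asm.L)
        b = ord(ch if entry.strand == 1 else revcomp(ch))
        if p in asm.protected and asm.protected[p] != b:
            raise SpecError(f"conflicting protected bases at position {p}")
        asm.protected[p] = b
        asm.seq[p] = b


def _repair_internal_stops(asm: _Assembler, placed, stops) -> None:
    """Deterministically remove in-frame internal stops created by
    overlapping genes; protected (terminal-codon) bases are never touched."""
    coding = [(e, s) for e, s, _, _ in placed if e.kind in ("PCG", "ORF")]
    for _ in range(25):
        dirty = False
        for entry, start in coding:
            sense = "".join(
                chr(asm.seq[_sense_pos(entry, start, i, asm.L)])
                if entry.strand == 1 else
                revcomp(chr(asm.seq[_sense_pos(entry, start, i, asm.L)]))
                for i in range(entry.length))
            for ci in range(1, entry.length // 3 - 1):
                codon = sense[3 * ci:3 * ci + 3]
                if codon not in stops:
                    continue
                # table-5 stops are TA(A|G): any single change below kills them
                for off, new in ((0, "C"), (1, "C"), (2, "T")):
                    p = _sense_pos(entry, start, 3 * ci + off, asm.L)
                    if p not in asm.protected:
                        b = new if entry.strand == 1 else revcomp(new)
                        asm.seq[p] = ord(b)
                        dirty = True
                        break
                else:
                    raise SpecError(
                        f"{entry.label}: internal stop fully protected")
        if not dirty:
            return
    raise SpecError("stop-repair did not converge")


# ---------------------------------------------------------------------------
# codon evolution

def _evolve_codons(rng: np.random.Generator, ancestor: Sequence[str],
                   omega: float, ks_target: float, code: int,
                   comp: Sequence[Composition] | None = None) -> list[str]:
    """Proposal/acceptance codon evolution to a synonymous-divergence target.

    With ``comp`` (one Composition per codon position) proposals are drawn
    from those base frequencies instead of uniformly, so the process is
    stationary at the target composition — used when the evolved sequences
    must keep a planted compositional bias.
    """
    if ks_target <= 0:
        return list(ancestor)
    ps_target = 0.75 * (1.0 - math.exp(-4.0 * ks_target / 3.0))
    stops = stop_codons(code)
    cur = list(ancestor)
    n = len(cur)
    batch = max(8, int(0.02 * 3 * n))
    max_events = int(60 * 3 * n)
    events = 0
    pos_probs = None if comp is None else [c.probs() for c in comp]
    while events < max_events:
        sites = rng.integers(0, n, size=batch)
        poss = rng.integers(0, 3, size=batch)
        if pos_probs is None:
            alts = rng.integers(0, 3, size=batch)
        else:
            alts = np.empty(batch, dtype=np.int64)
            for p in range(3):
                mask = poss == p
                k = int(mask.sum())
                if k:
                    alts[mask] = rng.choice(4, size=k, p=pos_probs[p])
        accept = rng.random(batch)
        for site, pos, alt, u in zip(sites, poss, alts, accept):
            codon = cur[site]
            base = codon[pos]
            if pos_probs is None:
                new_base = "ACGT".replace(base, "")[alt]
            else:
                new_base = "ACGT"[alt]
                if new_base == base:
                    continue
            cand = codon[:pos] + new_base + codon[pos + 1:]
            if cand in stops:
                continue
            syn = _syn_change(codon, cand, code)
            if syn or u < omega:
                cur[site] = cand
        events += batch
        if _ps(ancestor, cur, code) >= ps_target:
            return cur
    raise SpecError(f"synonymous divergence target {ks_target} unreachable")


def _syn_change(a: str, b: str, code: int) -> bool:
    from .codes import codon_to_aa
    aa = codon_to_aa(code)
    return aa[a] == aa[b]


def _ps(anc: Sequence[str], cur: Sequence[str], code: int) -> float:
    s_sites = 0.0
    sd = 0.0
    for ca, cb in zip(anc, cur):
        s_sites += (_syn_fraction(ca, code) + _syn_fraction(cb, code)) / 2
        sd += _pair_differences(ca, cb, code)[0]
    return sd / s_sites if s_sites else 0.0


def evolve_codon_sequences(spec: EvolveSpec) -> CodonAlignment:
    """Ancestor/descendant codon pair diverged to a synonymous target.

    Substitutions are proposed uniformly per site; synonymous proposals are
    always accepted, nonsynonymous ones with probability omega, and
    stop-creating ones rejected.  Proposal rounds continue until the NG86
    synonymous difference proportion reaches the value implied by the
    Jukes-Cantor-corrected target.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    codons = sense_codons(spec.code)
    anc = [codons[i] for i in rng.integers(0, len(codons), size=spec.n_codons)]
    desc = _evolve_codons(rng, anc, spec.omega, spec.ks_target, spec.code)
    return CodonAlignment(("ancestor", "descendant"),
                          ("".join(anc), "".join(desc)), spec.code)


# ---------------------------------------------------------------------------
# rearrangements

def apply_rearrangement(order: GeneOrder, op: tuple) -> GeneOrder:
    """Apply ``("inversion", i, j)`` or ``("transposition", i, j, dest)``.

    Indices are inclusive positions into the order's gene tuple; an
    inversion reverses the segment and flips its signs; a transposition
    moves the intact segment so that it starts at position ``dest`` of the
    remaining order.
    """
    genes = list(order.genes)
    n = len(genes)
    kind = op[0]
    if kind == "inversion":
        _, i, j = op
        if not (0 <= i <= j < n):
            raise ValueError(f"invalid segment [{i},{j}] for {n} genes")
        seg = [(g, -s) for g, s in reversed(genes[i:j + 1])]
        genes[i:j + 1] = seg
    elif kind == "transposition":
        _, i, j, dest = op
        if not (0 <= i <= j < n):
            raise ValueError(f"invalid segment [{i},{j}] for {n} genes")
        seg = genes[i:j + 1]
        rest = genes[:i] + genes[j + 1:]
        if not 0 <= dest <= len(rest):
            raise ValueError(f"invalid destination {dest}")
        genes = rest[:dest] + seg + rest[dest:]
    else:
        raise ValueError(f"unknown rearrangement {kind!r}")
    return GeneOrder(order.identifier, tuple(genes), order.scope)


# ---------------------------------------------------------------------------
# the literature-conditioned F/M fixture pair

UNIONOID_PCG_RRNA_ORDER: tuple[tuple[str, int], ...] = tuple(
    (g, s) for g, s in [
        ("cox1", 1), ("cox2", 1), ("nad3", 1), ("nad2", 1), ("rrnS", 1),
        ("rrnL", 1), ("cob", 1), ("nad5", 1), ("nad1", -1), ("nad6", 1),
        ("nad4", -1), ("nad4L", -1), ("atp8", -1), ("atp6", -1), ("cox3", -1),
    ])
"""The gene order and strand orientation of 13 PCGs + 2 rRNAs shared by most
unionoid mitogenomes (both F and M types)."""

GONIDEINAE_F_PCG_RRNA_ORDER: tuple[tuple[str, int], ...] = tuple(
    (g, s) for g, s in [
        ("cox1", 1), ("cox2", 1), ("nad2", 1), ("nad3", 1), ("rrnS", 1),
        ("rrnL", 1), ("cob", 1), ("nad5", 1), ("nad1", -1), ("nad6", 1),
        ("nad4", -1), ("nad4L", -1), ("atp8", -1), ("atp6", -1), ("cox3", -1),
    ])
"""The female-lineage Gonideinae arrangement: relative position of nad2 and
nad3 exchanged within the cox2..rrnS segment."""

_H = -1  # heavy strand
_F_TRNA_LEN = {"trnL1": 61, "trnG": 61, "trnA": 74}
_M_TRNA_LEN = {"trnY": 62, "trnH": 71}

# (label, kind, length, strand, start, stop) in circle order
_F_ROSTER = [
    ("cox1", "PCG", 1545, 1, "TTG", "TAG"),
    ("trnV", "tRNA", 65, 1, None, None),
    ("cox2", "PCG", 681, 1, "ATG", "TAA"),
    ("trnE", "tRNA", 65, 1, None, None),
    ("FORF", "ORF", 261, 1, "ATA", "TAA"),
    ("trnW", "tRNA", 65, 1, None, None),
    ("nad2", "PCG", 963, 1, "ATG", "TAA"),
    ("trnS1", "tRNA", 65, 1, None, None),
    ("nad3", "PCG", 357, 1, "ATG", "TAG"),
    ("trnM", "tRNA", 65, 1, None, None),
    ("rrnS", "rRNA", 857, 1, None, None),
    ("trnK", "tRNA", 65, 1, None, None),
    ("trnT", "tRNA", 65, 1, None, None),
    ("trnY", "tRNA", 65, 1, None, None),
    ("rrnL", "rRNA", 1296, 1, None, None),
    ("trnL1", "tRNA", 61, 1, None, None),
    ("cob", "PCG", 1161, 1, "ATC", "TAG"),
    ("trnP", "tRNA", 65, 1, None, None),
    ("nad5", "PCG", 1734, 1, "ATG", "TAA"),
    ("trnQ", "tRNA", 65, 1, None, None),
    ("trnC", "tRNA", 65, _H, None, None),
    ("nad1", "PCG", 897, _H, "ATC", "TAA"),
    ("trnI", "tRNA", 65, _H, None, None),
    ("nad6", "PCG", 489, 1, "ATC", "TAA"),
    ("trnN", "tRNA", 65, 1, None, None),
    ("nad4", "PCG", 1350, _H, "ATT", "TAG"),
    ("nad4L", "PCG", 297, _H, "ATG", "TAG"),
    ("trnD", "tRNA", 65, _H, None, None),
    ("atp8", "PCG", 198, _H, "GTG", "TAG"),
    ("trnA", "tRNA", 74, 1, None, None),
    ("atp6", "PCG", 708, _H, "ATG", "TAG"),
    ("trnR", "tRNA", 65, 1, None, None),
    ("cox3", "PCG", 780, _H, "ATG", "TAA"),
    ("trnG", "tRNA", 61, 1, None, None),
    ("trnL2", "tRNA", 65, 1, None, None),
    ("trnF", "tRNA", 65, 1, None, None),
    ("trnS2", "tRNA", 65, _H, None, None),
    ("trnH", "tRNA", 65, _H, None, None),
]

_M_ROSTER = [
    ("cox1", "PCG", 1602, 1, "TTG", "TAG"),
    ("trnV", "tRNA", 65, 1, None, None),
    ("cox2", "PCG", 1224, 1, "ATG", "TAA"),
    ("trnE", "tRNA", 65, 1, None, None),
    ("trnW", "tRNA", 65, 1, None, None),
    ("nad3", "PCG", 360, 1, "ATG", "TAG"),
    ("trnS1", "tRNA", 65, 1, None, None),
    ("nad2", "PCG", 996, 1, "TTG", "TAA"),
    ("trnM", "tRNA", 65, 1, None, None),
    ("rrnS", "rRNA", 857, 1, None, None),
    ("trnK", "tRNA", 65, 1, None, None),
    ("trnT", "tRNA", 65, 1, None, None),
    ("trnY", "tRNA", 62, 1, None, None),
    ("rrnL", "rRNA", 1313, 1, None, None),
    ("trnL1", "tRNA", 65, 1, None, None),
    ("cob", "PCG", 1149, 1, "ATG", "TAG"),
    ("trnN", "tRNA", 65, 1, None, None),
    ("trnP", "tRNA", 65, 1, None, None),
    ("nad5", "PCG", 1764, 1, "GTG", "TAG"),
    ("trnH", "tRNA", 71, _H, None, None),
    ("trnQ", "tRNA", 65, 1, None, None),
    ("trnC", "tRNA", 65, _H, None, None),
    ("nad1", "PCG", 909, _H, "ATA", "TAA"),
    ("trnI", "tRNA", 65, _H, None, None),
    ("nad6", "PCG", 681, 1, "ATC", "TAG"),
    ("nad4", "PCG", 1374, _H, "TTG", "TAG"),
    ("nad4L", "PCG", 300, _H, "ATT", "TAG"),
    ("MORF", "ORF", 435, _H, "ATA", "TAA"),
    ("atp8", "PCG", 177, _H, "ATG", "TAG"),
    ("trnD", "tRNA", 65, _H, None, None),
    ("trnA", "tRNA", 65, 1, None, None),
    ("atp6", "PCG", 684, _H, "ATG", "TAG"),
    ("trnR", "tRNA", 65, 1, None, None),
    ("trnG", "tRNA", 65, 1, None, None),
    ("trnL2", "tRNA", 65, 1, None, None),
    ("trnF", "tRNA", 65, 1, None, None),
    ("trnS2", "tRNA", 65, _H, None, None),
    ("cox3", "PCG", 774, _H, "ATT", "TAG"),
]

# special junctions: gap AFTER the named gene; junctions not listed share the
# leftover budget (deterministically, first junction takes the remainder)
_F_SPECIAL_GAPS = {
    "nad5": 1049,                       # the control region (nad5-trnQ)
    "cob": -1, "nad4": -8,              # the two F overlaps (range 1-8)
    "trnM": 0, "rrnS": 0, "trnK": 0, "trnT": 0, "trnY": 0, "rrnL": 0,
    "trnD": 0, "trnA": 0, "trnR": 0,    # abutting junctions
}
_M_SPECIAL_GAPS = {
    "trnH": 848,                        # the control region (trnH-trnQ)
    "nad2": -2, "trnN": -1, "trnQ": -1,  # trnM-nad2, trnN-trnP, trnQ-trnC
    "nad6": -168,                       # nad6-nad4
    "nad4": -7,                         # nad4-nad4L
    "cox3": -8,                         # cox3-cox1 across the origin
    "trnM": 0, "rrnS": 0, "trnK": 0, "trnT": 0, "trnY": 0, "rrnL": 0,
    "atp8": 0, "trnA": 0, "trnR": 0,
}

F_LENGTH = 16716
M_LENGTH = 17102


def _fill_gaps(roster, special: Mapping[str, int], genome_length: int
               ) -> tuple[int, ...]:
    labels = [r[0] for r in roster]
    total_genes = sum(r[2] for r in roster)
    budget = genome_length - total_genes - sum(special.values())
    free = [l for l in labels if l not in special]
    if budget < len(free):
        raise SpecError("gap budget too small")
    base = budget // len(free)
    rem = budget - base * len(free)
    gaps = {}
    for k, l in enumerate(free):
        gaps[l] = base + (rem if k == 0 else 0)
    gaps.update(special)
    return tuple(gaps[l] for l in labels)


def _entries(roster) -> tuple[GeneEntry, ...]:
    return tuple(GeneEntry(l, k, n, s, a, o) for l, k, n, s, a, o in roster)


def solenaia_like_specs(seed: int = 20130848) -> tuple[GenomeSpec, GenomeSpec]:
    """The F-like and M-like genome specs (see module docstring)."""
    f = GenomeSpec(
        identifier="Fsim", length=F_LENGTH, genes=_entries(_F_ROSTER),
        gaps=_fill_gaps(_F_ROSTER, _F_SPECIAL_GAPS, F_LENGTH),
        backbone=Composition(60.9, 0.22, -0.39),
        codon_comp=(Composition(55.9, -0.10, 0.29),
                    Composition(59.9, -0.46, -0.03),
                    Composition(64.0, -0.20, 0.23)),
        cr=CRSpec(after="nad5", length=1049, at_pct=63.7, at_skew=-0.05,
                  gc_skew=-0.50, period=101, copies=8.0, identity=0.99),
        sex_type="F", seed=seed)
    m = GenomeSpec(
        identifier="Msim", length=M_LENGTH, genes=_entries(_M_ROSTER),
        gaps=_fill_gaps(_M_ROSTER, _M_SPECIAL_GAPS, M_LENGTH),
        backbone=Composition(61.0, 0.27, -0.38),
        codon_comp=(Composition(56.9, -0.06, 0.29),
                    Composition(60.5, -0.41, 0.03),
                    Composition(64.1, -0.28, 0.27)),
        cr=CRSpec(after="trnH", length=848, at_pct=66.5, at_skew=0.0,
                  gc_skew=-0.43, period=102, copies=7.0, identity=0.99),
        sex_type="M", seed=seed + 1)
    return f, m


#: per-pair divergence process for the male protein genes
_PAIR_OMEGA = 0.33
_PAIR_KS = 1.3
_RRN_P = {"rrnS": 0.291, "rrnL": 0.289}


def solenaia_like_pair(seed: int = 20130848) -> tuple[MitoGenome, MitoGenome]:
    """Generate the literature-conditioned F/M fixture pair.

    The female genome is generated from its spec; the male protein-coding
    genes are then evolved from the female ones (omega 0.33, synonymous
    divergence 1.3 — the scale of the concatenated-protein estimates for
    this species pair), trimmed/extended to the published male lengths, and
    the male genome assembled around them.  rRNAs are mutated copies of the
    female rRNAs at the published nucleotide p-distances.
    """
    f_spec, m_spec = solenaia_like_specs(seed)
    f = simulate_genome(f_spec)
    rng = np.random.default_rng(seed + 2)
    m_lengths = {e.label: e.length for e in m_spec.genes}
    bodies: dict[str, str] = {}
    for feat in f.features:
        if feat.kind == "PCG" and feat.label in m_lengths:
            cds = f.extract(feat)
            anc = [cds[i:i + 3] for i in range(0, len(cds), 3)][1:-1]
            evolved = _evolve_codons(rng, anc, _PAIR_OMEGA, _PAIR_KS,
                                     f_spec.code, comp=m_spec.codon_comp)
            need = m_lengths[feat.label] // 3 - 2
            if len(evolved) > need:
                evolved = evolved[:need]
            elif len(evolved) < need:
                extra = _sample_codons(rng, need - len(evolved),
                                       m_spec.codon_comp, m_spec.code)
                evolved = evolved + extra
            bodies[feat.label] = "".join(evolved)
        elif feat.kind == "rRNA":
            seq = _mutate_nt(rng, f.extract(feat), _RRN_P[feat.label],
                             comp=m_spec.backbone)
            need = m_lengths[feat.label]
            if len(seq) > need:
                seq = seq[:need]
            elif len(seq) < need:
                seq = seq + _sample_seq(rng, need - len(seq), m_spec.backbone)
            bodies[feat.label] = seq
    m = simulate_genome(m_spec, bodies=bodies)
    return f, m
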
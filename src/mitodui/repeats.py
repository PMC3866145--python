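"""Tandem repeats, stem-loop potential, and control-region ranking.

Mitochondrial control regions in bivalves are identified by three criteria:
they are long unassigned regions, AT-rich relative to the rest of the
genome, and carry tandem repeats whose unit can fold into a stem-loop.

The repeat detector is a self-match scanner: for each candidate period ``p``
it compares the sequence with itself shifted by ``p``, seeds on exact runs
and extends while the overall per-copy identity stays above a threshold.
Stem-loop potential uses combinatorial base-pair maximisation (Nussinov
recursion with a minimum-loop constraint, GU pairs allowed) — a deliberate
substitution for thermodynamic MFE folding, so criterion (iii) tests
"stem-loop potential" rather than a free energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .composition import base_stats
from .genome import IntergenicRegion, MitoGenome, intergenic_regions

__all__ = ["TandemRepeat", "Hairpin", "CRCandidate",
           "tandem_repeats", "max_hairpin", "control_region_candidates"]


@dataclass(frozen=True)
class TandemRepeat:
    offset: int          # start of the array within the scanned sequence
    period: int
    copies: float        # fractional final copy allowed
    unit: str            # consensus of the full copies
    span: int
    identity: float      # fraction of matching bases between adjacent copies


@dataclass(frozen=True)
class Hairpin:
    pairs: int
    stem: int            # longest contiguous helix in the optimal structure
    loop: int            # loop closed by that helix
    paired: tuple[tuple[int, int], ...]

    def dot_bracket(self, n: int) -> str:
        chars = ["."] * n
        for i, j in self.paired:
            chars[i], chars[j] = "(", ")"
        return "".join(chars)


@dataclass(frozen=True)
class CRCandidate:
    region: IntergenicRegion
    length: int
    at_pct: float
    repeats: tuple[TandemRepeat, ...]
    best_hairpin: Hairpin | None
    score: float
    meets_length: bool
    meets_at: bool
    has_stemloop_repeat: bool


# ---------------------------------------------------------------------------
# tandem repeats

def _consensus(seq: str, offset: int, period: int, full_copies: int) -> str:
    cols = []
    for k in range(period):
        votes: dict[str, int] = {}
        for c in range(full_copies):
            base = seq[offset + c * period + k]
            votes[base] = votes.get(base, 0) + 1
        cols.append(min(votes, key=lambda b: (-votes[b], b)))
    return "".join(cols)


def tandem_repeats(seq: str, min_period: int = 20, min_copies: float = 2.0,
                   min_identity: float = 0.85, max_period: int | None = None
                   ) -> list[TandemRepeat]:
    """Maximal approximate tandem arrays in ``seq``.

    Overlapping detections are resolved in favour of the highest-identity
    array (ties: smallest period, longest span, leftmost), so a perfect
    ``unit^k`` string is reported once at the minimal period.
    """
    n = len(seq)
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    if max_period is None:
        max_period = n // 2
    candidates: list[TandemRepeat] = []
    for p in range(min_period, min(max_period, n // 2) + 1):
        m = arr[:-p] == arr[p:]
        need = int(np.ceil(p * (min_copies - 1)))
        if need < 1 or m.size < need:
            continue
        seed = max(4, min(12, p))
        # exact-match runs of >= seed consecutive positions
        run = np.convolve(m.astype(np.int32), np.ones(seed, dtype=np.int32),
                          mode="valid") == seed
        starts = np.flatnonzero(run)
        if starts.size == 0:
            continue
        cum = np.concatenate([[0], np.cumsum(m)])
        used_until = -1
        for s0 in starts:
            if s0 <= used_until:
                continue
            a = int(s0)
            b = a + seed  # match-array span [a, b)
            # extend by whole periods while the marginal window stays good,
            # then base-by-base while the trailing window stays good (the
            # window criterion stops the walk once it slides into noise)
            while b < m.size:
                nxt = min(m.size, b + p)
                if (cum[nxt] - cum[b]) / (nxt - b) >= min_identity:
                    b = nxt
                else:
                    break
            while b < m.size:
                w = min(p, b + 1 - a)
                if (cum[b + 1] - cum[b + 1 - w]) / w >= min_identity:
                    b += 1
                else:
                    break
            while a > 0:
                prv = max(0, a - p)
                if (cum[a] - cum[prv]) / (a - prv) >= min_identity:
                    a = prv
                else:
                    break
            while a > 0:
                w = min(p, b - (a - 1))
                if (cum[a - 1 + w] - cum[a - 1]) / w >= min_identity:
                    a -= 1
                else:
                    break
            used_until = b
            span = b - a + p
            copies = span / p
            if copies < min_copies:
                continue
            identity = (cum[b] - cum[a]) / (b - a)
            if identity < min_identity:
                continue
            unit = _consensus(seq, a, p, max(1, span // p))
            candidates.append(TandemRepeat(
                offset=a, period=p, copies=round(copies, 3), unit=unit,
                span=span, identity=round(float(identity), 4)))
    # period-minimality: drop a candidate when a smaller-period detection
    # covers most of its span at (practically) the same identity, so that a
    # period multiple of an array cannot outrank the minimal period on
    # sampling noise
    def _ov(x: TandemRepeat, y: TandemRepeat) -> int:
        return max(0, min(x.offset + x.span, y.offset + y.span)
                   - max(x.offset, y.offset))

    candidates = [x for x in candidates
                  if not any(y.period < x.period
                             and _ov(x, y) > 0.5 * x.span
                             and y.identity >= x.identity - 0.03
                             for y in candidates)]
    # overlap resolution: highest identity, then minimal period, longest
    # span, leftmost
    candidates.sort(key=lambda r: (-r.identity, r.period, -r.span, r.offset))
    chosen: list[TandemRepeat] = []
    for cand in candidates:
        c0, c1 = cand.offset, cand.offset + cand.span
        clash = False
        for acc in chosen:
            a0, a1 = acc.offset, acc.offset + acc.span
            inter = max(0, min(c1, a1) - max(c0, a0))
            if inter > 0.5 * cand.span:
                clash = True
                break
        if not clash:
            chosen.append(cand)
    chosen.sort(key=lambda r: r.offset)
    return chosen


# ---------------------------------------------------------------------------
# hairpins

_PAIRS_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_PAIRS_GU = _PAIRS_WC | {("G", "T"), ("T", "G")}


def max_hairpin(seq: str, min_loop: int = 3, allow_gu: bool = True) -> Hairpin:
    """Maximum-cardinality nested pairing (Nussinov) with a loop constraint.

    The reported stem is the longest contiguous helix of the optimal
    structure found by a deterministic traceback (pairing the outermost
    compatible ends first, bifurcating leftmost), i.e. ties resolve toward
    longer, 5'-most stems.
    """
    s = seq.upper().replace("U", "T")
    n = len(s)
    pairs_ok = _PAIRS_GU if allow_gu else _PAIRS_WC

    def can_pair(i: int, j: int) -> bool:
        return (s[i], s[j]) in pairs_ok

    if n < min_loop + 2:
        return Hairpin(0, 0, 0, ())
    M = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = M[i + 1][j]  # i unpaired
            if M[i][j - 1] > best:
                best = M[i][j - 1]
            if can_pair(i, j) and M[i + 1][j - 1] + 1 > best:
                best = M[i + 1][j - 1] + 1
            for k in range(i + 1, j):
                v = M[i][k] + M[k + 1][j]
                if v > best:
                    best = v
            M[i][j] = best

    paired: list[tuple[int, int]] = []

    def trace(i: int, j: int) -> None:
        while i < j:
            if M[i][j] == 0:
                return
            if can_pair(i, j) and j - i > min_loop and \
                    M[i][j] == M[i + 1][j - 1] + 1:
                paired.append((i, j))
                i, j = i + 1, j - 1
                continue
            if M[i][j] == M[i + 1][j]:
                i += 1
                continue
            if M[i][j] == M[i][j - 1]:
                j -= 1
                continue
            for k in range(i + 1, j):
                if M[i][j] == M[i][k] + M[k + 1][j]:
                    trace(i, k)
                    i = k + 1
                    break
            else:  # pragma: no cover - DP guarantees a branch above
                return

    trace(0, n - 1)
    paired.sort()
    best_stem, best_loop, cur = 0, 0, 0
    stack = sorted(paired)
    for idx, (i, j) in enumerate(stack):
        if idx and (i, j) == (stack[idx - 1][0] + 1, stack[idx - 1][1] - 1):
            cur += 1
        else:
            cur = 1
        if cur > best_stem:
            best_stem, best_loop = cur, j - i - 1
    return Hairpin(pairs=len(paired), stem=best_stem, loop=best_loop,
                   paired=tuple(paired))


# ---------------------------------------------------------------------------
# control-region ranking

def control_region_candidates(genome: MitoGenome, min_length: int = 300,
                              min_period: int = 20, min_copies: float = 2.0,
                              min_identity: float = 0.85, min_stem: int = 5,
                              min_loop: int = 3) -> list[CRCandidate]:
    """Score every unassigned region on the three control-region criteria.

    Composite score = z(length) + z(AT%) + 1.0 x [has a tandem repeat whose
    unit folds into a hairpin with >= ``min_stem`` contiguous pairs],
    z-scored across the genome's unassigned regions.  Ties break by length.
    """
    regions = intergenic_regions(genome)
    if not regions:
        return []
    genome_at = base_stats(genome.sequence).at_pct
    lengths = np.array([r.length for r in regions], dtype=float)
    ats = []
    reps: list[tuple[TandemRepeat, ...]] = []
    hairpins: list[Hairpin | None] = []
    qualifies: list[bool] = []
    for r in regions:
        try:
            at = base_stats(r.sequence).at_pct
        except ValueError:
            at = 0.0
        ats.append(at)
        found = tuple(tandem_repeats(r.sequence, min_period, min_copies,
                                     min_identity)) \
            if r.length >= min_period * min_copies else ()
        reps.append(found)
        best: Hairpin | None = None
        ok = False
        for rep in found:
            hp = max_hairpin(rep.unit, min_loop=min_loop)
            if best is None or hp.pairs > best.pairs:
                best = hp
            if hp.stem >= min_stem and hp.loop >= min_loop:
                ok = True
        hairpins.append(best)
        qualifies.append(ok)
    ats_arr = np.array(ats)

    def z(x: np.ndarray) -> np.ndarray:
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    scores = z(lengths) + z(ats_arr) + np.array(qualifies, dtype=float)
    out = [CRCandidate(region=r, length=r.length, at_pct=ats[i],
                       repeats=reps[i], best_hairpin=hairpins[i],
                       score=float(scores[i]),
                       meets_length=r.length >= min_length,
                       meets_at=ats[i] >= genome_at,
                       has_stemloop_repeat=qualifies[i])
           for i, r in enumerate(regions)]
    # final tie-break by the upstream flank label: unique per junction and,
    # unlike raw coordinates, invariant under rotation of the origin
    out.sort(key=lambda c: (-c.score, -c.length, c.region.flank_upstream))
    return out
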
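"""Circular mitogenome model and architecture statistics.

The central object is :class:`MitoGenome`: the deposited light (L) strand of a
circular mitochondrial genome plus its ordered feature annotations.  All
coordinates are 0-based, half-open, on the L strand; a feature that spans the
sequence origin carries ``wraps_origin`` instead of a split interval (GenBank's
1-based closed, possibly joined, locations are converted at the I/O boundary).

Architecture operations cover the comparative statistics mitogenome papers
tabulate: intergenic (unassigned) regions, overlapping gene pairs, start/stop
codon classes per protein gene, an ORF scan, and the M-genome cox2 3'
extension that characterises doubly uniparental inheritance systems.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .codes import (ALTERNATIVE_STARTS, CONVENTIONAL_STARTS,
                    DEFAULT_START_CODONS, revcomp, stop_codons)

__all__ = [
    "GeneFeature", "MitoGenome", "IntergenicRegion", "OverlapRecord",
    "GeneTableRow", "OrfHit", "AnnotationError", "FormatError",
    "load_genome", "write_fasta", "write_feature_table",
    "intergenic_regions", "gene_overlaps", "gene_table", "find_orfs",
    "cox2_extension", "canonical_label",
]

KINDS = ("PCG", "ORF", "rRNA", "tRNA", "CR", "other")


class AnnotationError(ValueError):
    """Inconsistent or duplicate feature annotation."""


class FormatError(ValueError):
    """Unparseable input file."""


# ---------------------------------------------------------------------------
# canonical gene labels

_SYNONYMS = {
    "co1": "cox1", "coi": "cox1", "cox1": "cox1", "coxi": "cox1",
    "co2": "cox2", "coii": "cox2", "cox2": "cox2", "coxii": "cox2",
    "co3": "cox3", "coiii": "cox3", "cox3": "cox3", "coxiii": "cox3",
    "cytb": "cob", "cob": "cob", "cb": "cob",
    "atp6": "atp6", "atpase6": "atp6", "atp8": "atp8", "atpase8": "atp8",
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4L", "nd5": "nad5", "nd6": "nad6",
    "nad1": "nad1", "nad2": "nad2", "nad3": "nad3", "nad4": "nad4",
    "nad4l": "nad4L", "nad5": "nad5", "nad6": "nad6",
    "12s": "rrnS", "rrns": "rrnS", "srrna": "rrnS", "s-rrna": "rrnS",
    "12s rrna": "rrnS", "rns": "rrnS",
    "16s": "rrnL", "rrnl": "rrnL", "lrrna": "rrnL", "l-rrna": "rrnL",
    "16s rrna": "rrnL", "rnl": "rrnL",
    "forf": "FORF", "morf": "MORF", "f-orf": "FORF", "m-orf": "MORF",
    "cr": "CR", "d-loop": "CR", "control region": "CR",
}

_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
    "gln": "Q", "glu": "E", "gly": "G", "his": "H", "ile": "I",
    "leu": "L", "lys": "K", "met": "M", "phe": "F", "pro": "P",
    "ser": "S", "thr": "T", "trp": "W", "tyr": "Y", "val": "V",
}


def canonical_label(label: str) -> str:
    """Map a gene name to this package's canonical form.

    cox1/2/3, nad1-6 + nad4L, atp6/8, cob, rrnS/rrnL, trnX (with S1/S2 and
    L1/L2 disambiguation preserved), FORF/MORF, CR.  Unknown names pass
    through stripped, so synthetic labels survive round-trips.
    """
    raw = label.strip()
    low = raw.lower()
    if low in _SYNONYMS:
        return _SYNONYMS[low]
    if low.startswith("trna-"):
        rest = low[5:]
        body = rest.rstrip("12")
        suffix = rest[len(body):]
        if body in _AA3_TO_1:
            return "trn" + _AA3_TO_1[body] + suffix
    if low.startswith("trn") and len(low) >= 4:
        rest = raw[3:]
        if rest[0].upper() in "ACDEFGHIKLMNPQRSTVWY":
            return "trn" + rest[0].upper() + \
                rest[1:].lower().replace("(", "").replace(")", "")
    return raw


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene/ORF/rRNA/tRNA/CR with L-strand coordinates."""

    label: str
    kind: str
    start: int          # 0-based inclusive
    end: int            # exclusive; < start only when wraps_origin
    strand: int         # +1 = L strand, -1 = H strand
    wraps_origin: bool = False
    incomplete_stop: bool = False

    def __post_init__(self):
        if self.kind not in KINDS:
            raise AnnotationError(f"{self.label}: unknown feature kind {self.kind!r}")
        if self.strand not in (1, -1):
            raise AnnotationError(f"{self.label}: strand must be +1/-1")
        if not self.wraps_origin and self.end <= self.start:
            raise AnnotationError(
                f"{self.label}: empty/inverted interval [{self.start},{self.end})")

    def length(self, genome_length: int) -> int:
        if self.wraps_origin:
            span = genome_length - self.start + self.end
        else:
            span = self.end - self.start
        if not 0 < span <= genome_length:
            raise AnnotationError(f"{self.label}: bad feature span {span}")
        return span

    def arcs(self, genome_length: int) -> list[tuple[int, int]]:
        """The feature as 1 or 2 linear [start, end) intervals in [0, L)."""
        if self.wraps_origin:
            return [(self.start, genome_length), (0, self.end)]
        return [(self.start, self.end)]


@dataclass(frozen=True)
class IntergenicRegion:
    start: int
    end: int
    wraps_origin: bool
    length: int
    flank_upstream: str
    flank_downstream: str
    sequence: str


@dataclass(frozen=True)
class OverlapRecord:
    gene_a: str
    gene_b: str
    overlap_length: int


@dataclass(frozen=True)
class GeneTableRow:
    label: str
    length: int
    start_codon: str
    stop_codon: str
    start_class: str    # conventional | alternative | other


@dataclass(frozen=True)
class OrfHit:
    frame: int          # 0,1,2 within the scanned strand
    strand: int
    start: int          # region coordinates, forward strand
    end: int
    aa_length: int      # codons excluding the stop


@dataclass
class MitoGenome:
    """Circular genome sequence + ordered annotations.

    ``sex_type`` records the DUI transmission route of the molecule:
    F (female-transmitted), M (male-transmitted), H (hermaphroditic F-like),
    or unknown.
    """

    identifier: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    is_circular: bool = True
    sex_type: str = "unknown"

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise FormatError(f"{self.identifier}: empty sequence")
        if self.sex_type not in ("F", "M", "H", "unknown"):
            raise AnnotationError(f"bad sex_type {self.sex_type!r}")
        canon = [replace(f, label=canonical_label(f.label)) for f in self.features]
        seen: dict[str, GeneFeature] = {}
        for f in canon:
            if not (0 <= f.start < self.length and 0 <= f.end <= self.length):
                raise AnnotationError(
                    f"{f.label}: coordinates [{f.start},{f.end}) outside genome "
                    f"of length {self.length}")
            if f.label in seen:
                raise AnnotationError(f"duplicate canonical label {f.label!r}")
            seen[f.label] = f
            f.length(self.length)  # validates > 0
        self.features = sorted(canon, key=lambda f: (f.start, f.end))

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature(self, label: str) -> GeneFeature:
        label = canonical_label(label)
        for f in self.features:
            if f.label == label:
                return f
        raise KeyError(f"{self.identifier}: no feature {label!r}")

    def region_sequence(self, start: int, end: int, wraps_origin: bool = False) -> str:
        if wraps_origin:
            return self.sequence[start:] + self.sequence[:end]
        return self.sequence[start:end]

    def extract(self, feature: GeneFeature | str) -> str:
        """Sense-strand sequence of a feature (reverse-complemented for H)."""
        if isinstance(feature, str):
            feature = self.feature(feature)
        seq = self.region_sequence(feature.start, feature.end, feature.wraps_origin)
        return revcomp(seq) if feature.strand == -1 else seq

    def rotated(self, offset: int) -> "MitoGenome":
        """Same circular genome with the origin moved forward by ``offset``."""
        L = self.length
        offset %= L
        seq = self.sequence[offset:] + self.sequence[:offset]
        feats = []
        for f in self.features:
            s = (f.start - offset) % L
            e = (f.end - offset) % L
            wraps = s >= e  # length validated > 0, so s == e cannot happen
            feats.append(replace(f, start=s, end=e if wraps or e > 0 else L,
                                 wraps_origin=wraps))
        return MitoGenome(self.identifier, seq, feats, self.is_circular, self.sex_type)


# ---------------------------------------------------------------------------
# I/O

_TSV_COLUMNS = ["label", "kind", "start", "end", "strand", "wraps_origin",
                "incomplete_stop"]


def _features_from_genbank(record, length: int) -> list[GeneFeature]:
    feats = []
    for feat in record.features:
        if feat.type == "CDS":
            kind = "PCG"
        elif feat.type == "rRNA":
            kind = "rRNA"
        elif feat.type == "tRNA":
            kind = "tRNA"
        elif feat.type in ("D-loop", "misc_feature"):
            kind = "other"
        else:
            continue
        quals = feat.qualifiers
        name = (quals.get("gene") or quals.get("product") or
                quals.get("note") or [feat.type])[0]
        label = canonical_label(name)
        if label in ("FORF", "MORF"):
            kind = "ORF"
        if label == "CR":
            kind = "CR"
        loc = feat.location
        strand = 1 if (loc.strand or 1) >= 0 else -1
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        start = int(parts[0].start)
        end = int(parts[-1].end)
        wraps = False
        if len(parts) == 2 and int(parts[-1].end) == length and int(parts[0].start) == 0:
            # origin-spanning join(a..L, 1..b)
            start, end, wraps = int(parts[1].start), int(parts[0].end), True
        feats.append(GeneFeature(label, kind, start, end, strand, wraps))
    return feats


def _features_from_tsv(path: Path) -> list[GeneFeature]:
    feats = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_TSV_COLUMNS[:5]) - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"{path}: feature table missing columns {sorted(missing)}")
        for row in reader:
            feats.append(GeneFeature(
                label=row["label"], kind=row["kind"],
                start=int(row["start"]), end=int(row["end"]),
                strand=int(row["strand"]),
                wraps_origin=row.get("wraps_origin", "0") in ("1", "True", "true"),
                incomplete_stop=row.get("incomplete_stop", "0") in ("1", "True", "true"),
            ))
    return feats


def load_genome(path: str | Path, format: str | None = None,
                features_path: str | Path | None = None,
                sex_type: str = "unknown") -> MitoGenome:
    """Load a mitogenome from GenBank, or FASTA + TSV feature table.

    ``format`` is ``"genbank"`` or ``"fasta"``; inferred from the suffix when
    omitted.  For FASTA input the companion table defaults to
    ``<stem>.features.tsv`` next to the sequence; a missing table yields a
    featureless genome.
    """
    path = Path(path)
    if format is None:
        format = "genbank" if path.suffix.lower() in (".gb", ".gbk", ".genbank") else "fasta"
    try:
        record = next(SeqIO.parse(str(path), format))
    except (StopIteration, ValueError) as exc:
        raise FormatError(f"{path}: cannot parse as {format}: {exc}") from None
    seq = str(record.seq)
    if format == "genbank":
        feats = _features_from_genbank(record, len(seq))
        circular = record.annotations.get("topology", "circular") == "circular"
    else:
        if features_path is None:
            cand = path.with_suffix("").with_suffix(".features.tsv") \
                if path.suffix else path
            cand = path.parent / (path.stem + ".features.tsv")
            features_path = cand if cand.exists() else None
        feats = _features_from_tsv(Path(features_path)) if features_path else []
        circular = True
    return MitoGenome(record.id or path.stem, seq, feats, circular, sex_type)


def write_fasta(genome: MitoGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.identifier}\n")
        for i in range(0, genome.length, 70):
            fh.write(genome.sequence[i:i + 70] + "\n")


def write_feature_table(genome: MitoGenome, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for f in genome.features:
            writer.writerow([f.label, f.kind, f.start, f.end, f.strand,
                             int(f.wraps_origin), int(f.incomplete_stop)])


# ---------------------------------------------------------------------------
# architecture statistics

def _merged_coverage(genome: MitoGenome) -> list[tuple[int, int]]:
    """Merged feature coverage as sorted, disjoint arcs in [0, L)."""
    arcs: list[tuple[int, int]] = []
    for f in genome.features:
        arcs.extend(f.arcs(genome.length))
    arcs.sort()
    merged: list[list[int]] = []
    for s, e in arcs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def intergenic_regions(genome: MitoGenome) -> list[IntergenicRegion]:
    """Maximal feature-free arcs of the circle (the "unassigned regions").

    An arc spanning the origin is reported once with ``wraps_origin`` set.
    Flanks are the nearest features on each side along the circle.
    """
    if not genome.features:
        raise AnnotationError(
            f"{genome.identifier}: cannot define intergenic space without features")
    L = genome.length
    cov = _merged_coverage(genome)
    # wrap-around merge
    if len(cov) > 1 and cov[0][0] == 0 and cov[-1][1] == L:
        cov[0] = (cov[-1][0], cov[0][1])
        cov.pop()
    gaps: list[tuple[int, int, bool]] = []
    for i, (s, e) in enumerate(cov):
        nxt = cov[(i + 1) % len(cov)][0]
        gap_start = e % L
        gap_end = nxt % L
        if gap_start == gap_end:
            continue  # abutting arcs (or a single arc tiling the circle)
        wraps = gap_end < gap_start or gap_end == 0
        gaps.append((gap_start, gap_end, wraps))

    def nearest_end_before(pos: int) -> str:
        best, best_d = None, None
        for f in genome.features:
            d = (pos - f.end) % L
            if best_d is None or d < best_d:
                best, best_d = f, d
        return best.label

    def nearest_start_after(pos: int) -> str:
        best, best_d = None, None
        for f in genome.features:
            d = (f.start - pos) % L
            if best_d is None or d < best_d:
                best, best_d = f, d
        return best.label

    out = []
    for s, e, wraps in sorted(gaps):
        length = (e - s) % L
        out.append(IntergenicRegion(
            start=s, end=e, wraps_origin=wraps, length=length,
            flank_upstream=nearest_end_before(s),
            flank_downstream=nearest_start_after(e),
            sequence=genome.region_sequence(s, e, wraps)))
    return out


def _arc_overlap(a: GeneFeature, b: GeneFeature, L: int) -> int:
    total = 0
    for s1, e1 in a.arcs(L):
        for s2, e2 in b.arcs(L):
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def gene_overlaps(genome: MitoGenome) -> list[OverlapRecord]:
    """Overlapping feature pairs (>= 1 shared base; abutment is not overlap)."""
    L = genome.length
    out = []
    feats = genome.features
    for i, a in enumerate(feats):
        for b in feats[i + 1:]:
            ov = _arc_overlap(a, b, L)
            if ov >= 1:
                if ov > min(a.length(L), b.length(L)):
                    ov = min(a.length(L), b.length(L))
                out.append(OverlapRecord(a.label, b.label, ov))
    return out


def gene_table(genome: MitoGenome, code: int = 5) -> list[GeneTableRow]:
    """Length and start/stop codons for every protein gene/ORF.

    Codons are read from the strand-corrected (sense) CDS, so they are
    invariant under reverse-complementing the genome and flipping strands.
    """
    rows = []
    for f in genome.features:
        if f.kind not in ("PCG", "ORF"):
            continue
        cds = genome.extract(f)
        if len(cds) % 3 and not f.incomplete_stop:
            raise AnnotationError(
                f"{f.label}: CDS length {len(cds)} not a multiple of 3")
        start = cds[:3]
        stop = cds[-3:] if not f.incomplete_stop else cds[len(cds) - len(cds) % 3:]
        if start in CONVENTIONAL_STARTS:
            klass = "conventional"
        elif start in ALTERNATIVE_STARTS:
            klass = "alternative"
        else:
            klass = "other"
        rows.append(GeneTableRow(f.label, len(cds), start, stop, klass))
    return rows


def start_codon_census(rows: Iterable[GeneTableRow]) -> dict[str, int]:
    census: dict[str, int] = {"conventional": 0, "alternative": 0, "other": 0}
    for r in rows:
        census[r.start_class] += 1
    return census


def find_orfs(region: str, code: int = 5, min_aa: int = 30,
              starts: frozenset[str] | None = None) -> list[OrfHit]:
    """Scan both strands of a region for maximal ORFs.

    For each (strand, frame, stop segment) the 5'-most qualifying start codon
    defines the ORF; the span includes the stop codon when one terminates it,
    while ``aa_length`` counts coding codons only.  Results are sorted by
    amino-acid length, longest first (ties: forward strand, then position).
    """
    if not region:
        raise ValueError("empty region")
    starts = DEFAULT_START_CODONS if starts is None else starts
    stops = stop_codons(code)
    n = len(region)
    hits: list[OrfHit] = []
    for strand in (1, -1):
        seq = region.upper() if strand == 1 else revcomp(region.upper())
        for frame in range(3):
            seg_start: int | None = None
            for i in range(frame, n - 2, 3):
                codon = seq[i:i + 3]
                if codon in stops:
                    if seg_start is not None:
                        _emit(hits, seq, seg_start, i + 3, True, frame,
                              strand, n, min_aa)
                    seg_start = None
                elif seg_start is None and codon in starts:
                    seg_start = i
            if seg_start is not None:
                last = frame + 3 * ((n - frame) // 3)
                _emit(hits, seq, seg_start, last, False, frame, strand, n, min_aa)
    hits.sort(key=lambda h: (-h.aa_length, -h.strand, h.start))
    return hits


def _emit(hits: list[OrfHit], seq: str, s: int, e: int, has_stop: bool,
          frame: int, strand: int, n: int, min_aa: int) -> None:
    aa_len = (e - s) // 3 - (1 if has_stop else 0)
    if aa_len < min_aa:
        return
    if strand == 1:
        start, end = s, e
    else:
        start, end = n - e, n - s
    hits.append(OrfHit(frame, strand, start, end, aa_len))


def cox2_extension(f_genome: MitoGenome, m_genome: MitoGenome) -> tuple[int, float]:
    """The male cox2 3' extension: (bp, fraction of the female gene length)."""
    try:
        f_len = f_genome.feature("cox2").length(f_genome.length)
        m_len = m_genome.feature("cox2").length(m_genome.length)
    except KeyError as exc:
        raise KeyError(f"cox2 missing: {exc}") from None
    ext = m_len - f_len
    return ext, ext / f_len
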
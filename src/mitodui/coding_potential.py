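"""Fickett TESTCODE statistic for coding-potential classification.

The statistic combines eight measures of a nucleotide sequence: for each base
a *position* parameter capturing 3-periodic positional asymmetry
(max over the three frames of the base's per-frame count, divided by the
min + 1) and a *content* parameter (the base's overall frequency).  Each
parameter is mapped to a probability-of-coding through interval lookup
tables and the eight probabilities are combined with fixed weights.

The lookup tables and weights are the published ones (Fickett 1982,
Nucleic Acids Res 10:5303, as redistributed in EMBOSS ``tcode`` and CPAT).
Classification thresholds are the published ones too: a score below 0.74 is
"noncoding", 0.95 and above "coding", in between "no opinion".

The score -> percent-probability-of-coding map reproduces the shape of the
published calibration; see the methods note for its provenance.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["TestcodeResult", "testcode", "NONCODING_MAX", "CODING_MIN"]

NONCODING_MAX = 0.74
CODING_MIN = 0.95

# interval-indexed lookups: value >= THRESHOLDS[i] selects PROB[i]; the final
# entry is the below-all-thresholds bin.
_POSITION_THRESHOLDS = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1)
_POSITION_PROB = {
    "A": (0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22),
    "C": (0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23),
    "G": (0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08),
    "T": (0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09),
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}

_CONTENT_THRESHOLDS = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17)
_CONTENT_PROB = {
    "A": (0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21),
    "C": (0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31),
    "G": (0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29),
    "T": (0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58),
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}

# monotone score -> percent coding calibration (descending thresholds)
_PROBABILITY_BINS = (
    (1.20, 100.0), (1.15, 99.0), (1.10, 98.0), (1.05, 96.0), (1.00, 94.0),
    (0.95, 92.0), (0.90, 86.0), (0.85, 79.0), (0.80, 71.0), (0.75, 62.0),
    (0.74, 55.0), (0.70, 45.0), (0.65, 39.0), (0.60, 33.0), (0.55, 28.0),
    (0.50, 24.0), (0.45, 20.0), (0.40, 17.0), (0.00, 10.0),
)


@dataclass(frozen=True)
class TestcodeResult:
    score: float
    verdict: str                # coding | noncoding | no-opinion
    probability_coding: float   # percent
    low_confidence: bool        # input shorter than the recommended 200 nt


def _interval_index(value: float, thresholds: tuple[float, ...]) -> int:
    for i, t in enumerate(thresholds):
        if value >= t:
            return i
    return len(thresholds)


def testcode(seq: str) -> TestcodeResult:
    """TESTCODE score of a putative sense-strand coding sequence.

    Deterministic; sequences shorter than the recommended 200 nt window are
    scored but flagged ``low_confidence``.  Whether to include the stop codon
    is the caller's choice — pass the sequence you want scored.
    """
    s = seq.upper().replace("U", "T")
    if not s:
        raise ValueError("empty sequence")
    score = 0.0
    n = len(s)
    for base in "ACGT":
        frame_counts = [s[off::3].count(base) for off in range(3)]
        position = max(frame_counts) / (min(frame_counts) + 1)
        content = s.count(base) / n
        score += (_POSITION_WEIGHT[base] *
                  _POSITION_PROB[base][_interval_index(position, _POSITION_THRESHOLDS)])
        score += (_CONTENT_WEIGHT[base] *
                  _CONTENT_PROB[base][_interval_index(content, _CONTENT_THRESHOLDS)])
    if score >= CODING_MIN:
        verdict = "coding"
    elif score <= NONCODING_MAX:
        verdict = "noncoding"
    else:
        verdict = "no-opinion"
    prob = next(p for t, p in _PROBABILITY_BINS if score >= t)
    return TestcodeResult(score=round(score, 4), verdict=verdict,
                          probability_coding=prob, low_confidence=n < 200)
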
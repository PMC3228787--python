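"""PWM construction, TFBS scanning and motif-similarity scoring.

A position frequency matrix (PFM) of base counts is converted to a
log-odds position weight matrix (PWM); sequences are scanned on both
strands and hits are reported when the *relative* score

    rel = (score - score_min) / (score_max - score_min)

reaches a threshold (0.8 by default throughout the pipeline, the
convention of the muscle CRM scanners this pipeline reproduces).
Ambiguous ``N`` bases contribute the background-expected column weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import PFM

UNIFORM_BG = np.full(4, 0.25)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass
class PWM:
    motif_id: str
    weights: np.ndarray  # 4 x L log2 odds
    score_min: float
    score_max: float
    background: np.ndarray

    @property
    def length(self) -> int:
        return self.weights.shape[1]

    def rel_score(self, abs_score: float) -> float:
        span = self.score_max - self.score_min
        if span == 0:
            return 1.0
        return (abs_score - self.score_min) / span


@dataclass(frozen=True)
class SiteHit:
    """A predicted TFBS occurrence within a scanned sequence."""

    region_id: str
    offset: int
    length: int
    strand: str
    motif_id: str
    abs_score: float
    rel_score: float

    @property
    def end(self) -> int:
        return self.offset + self.length

    def overlaps(self, other: "SiteHit") -> bool:
        return self.offset < other.end and other.offset < self.end


def pfm_to_pwm(
    pfm: PFM, background: np.ndarray | None = None, pseudocount: float = 0.8
) -> PWM:
    """Standard log-odds PWM with a background-distributed pseudocount.

    weight[b, i] = log2( (count[b, i] + pseudocount * bg[b]) /
                         (colsum[i] + pseudocount) / bg[b] )
    """
    bg = UNIFORM_BG if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0) or np.any(bg <= 0):
        raise ValueError("background must be 4 positive frequencies summing to 1")
    counts = pfm.counts
    colsum = counts.sum(axis=0)
    probs = (counts + pseudocount * bg[:, None]) / (colsum + pseudocount)
    weights = np.log2(probs / bg[:, None])
    score_max = float(weights.max(axis=0).sum())
    score_min = float(weights.min(axis=0).sum())
    return PWM(pfm.motif_id, weights, score_min, score_max, bg)


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.fromiter((_BASE_INDEX[c] for c in sequence), dtype=np.int64, count=len(sequence))
    except KeyError as exc:
        raise ValueError(f"illegal base {exc.args[0]!r}") from None


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def _window_scores(encoded: np.ndarray, pwm: PWM) -> np.ndarray:
    """Absolute score of every window, vectorized over positions."""
    L = pwm.length
    n = len(encoded) - L + 1
    if n <= 0:
        return np.empty(0)
    # row 4 = expected weight under background, used for N
    lookup = np.vstack([pwm.weights, pwm.background @ pwm.weights])
    scores = np.zeros(n)
    for j in range(L):
        scores += lookup[encoded[j : j + n], j]
    return scores


def scan(
    sequence: str,
    pwm: PWM,
    threshold_rel: float = 0.8,
    region_id: str = "",
    both_strands: bool = True,
) -> list[SiteHit]:
    """Scan a sequence for PWM matches at or above a relative-score threshold.

    Offsets always refer to the forward strand; a minus-strand hit at
    offset k covers forward positions [k, k + L).
    """
    if not 0.0 <= threshold_rel <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    sequence = sequence.upper()
    L = pwm.length
    if len(sequence) < L:
        return []
    span = pwm.score_max - pwm.score_min
    hits: list[SiteHit] = []

    def _collect(seq: str, strand: str) -> None:
        scores = _window_scores(_encode(seq), pwm)
        rels = np.ones_like(scores) if span == 0 else (scores - pwm.score_min) / span
        for k in np.flatnonzero(rels >= threshold_rel):
            offset = int(k) if strand == "+" else len(seq) - int(k) - L
            hits.append(
                SiteHit(region_id, offset, L, strand, pwm.motif_id,
                        float(scores[k]), float(rels[k]))
            )

    _collect(sequence, "+")
    if both_strands:
        _collect(reverse_complement(sequence), "-")
    hits.sort(key=lambda h: (h.offset, h.strand, h.motif_id))
    return hits


def resolve_overlaps(hits: list[SiteHit]) -> list[SiteHit]:
    """Keep only the highest-scoring site among overlapping same-motif hits.

    Greedy by descending score; ties broken by leftmost start, then ``+``
    strand.  Hits of *different* motifs never suppress one another.
    """
    retained: list[SiteHit] = []
    by_motif: dict[str, list[SiteHit]] = {}
    for h in hits:
        by_motif.setdefault(h.motif_id, []).append(h)
    for motif_hits in by_motif.values():
        motif_hits = sorted(
            motif_hits, key=lambda h: (-h.abs_score, h.offset, 0 if h.strand == "+" else 1)
        )
        kept: list[SiteHit] = []
        for h in motif_hits:
            if not any(h.overlaps(k) for k in kept):
                kept.append(h)
        retained.extend(kept)
    retained.sort(key=lambda h: (h.offset, h.motif_id, h.strand))
    return retained


def matrix_similarity(pfm_a: PFM, pfm_b: PFM) -> float:
    """Profile similarity of two motifs on a 0..2 scale (2 = identity).

    The best ungapped offset alignment between the frequency matrices is
    found over both orientations of one motif, requiring the overlap to
    cover at least half of the shorter motif, and scoring each aligned
    column pair as ``2 - sum_b |f_a(b) - f_b(b)|`` (mean over aligned
    columns).
    """
    if pfm_a.length < 4 or pfm_b.length < 4:
        raise ValueError("motifs shorter than 4 columns are not comparable")
    fa = pfm_a.frequencies()
    min_overlap = max(1, min(pfm_a.length, pfm_b.length) // 2)
    best = 0.0
    for other in (pfm_b, pfm_b.reverse_complement()):
        fb = other.frequencies()
        La, Lb = fa.shape[1], fb.shape[1]
        for shift in range(-(Lb - min_overlap), La - min_overlap + 1):
            a0, b0 = max(0, shift), max(0, -shift)
            width = min(La - a0, Lb - b0)
            if width < min_overlap:
                continue
            cols = 2.0 - np.abs(fa[:, a0 : a0 + width] - fb[:, b0 : b0 + width]).sum(axis=0)
            best = max(best, float(cols.mean()))
    return best
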
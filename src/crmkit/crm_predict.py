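"""Candidate CRM prediction from motif-hit windows.

Search regions are built oPOSSUM-style (±10 kb around each TSS, coding
exons and ±50 bp around alternative TSSs removed).  Candidate windows are
scored two ways: a trainable logistic discriminator over per-motif hit
features, and a simple additive cluster score.  Predictions consisting
solely of SP1 sites are discarded — GC-box matches alone are ubiquitous
and carry no muscle specificity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression

from .io_formats import GenomicRegion, ScoreTrack
from .motif_scan import SiteHit


@dataclass
class SearchRegionSpec:
    tss_flank: int = 10_000
    alt_tss_exclusion: int = 50

    def __post_init__(self) -> None:
        if not self.tss_flank > self.alt_tss_exclusion >= 0:
            raise ValueError("require flank > exclusion >= 0")


@dataclass
class GeneAnnotation:
    """Minimal gene annotation: TSSs, coding-exon intervals, alternative TSSs."""

    chrom: str
    tss: list[int]
    coding_exons: list[tuple[int, int]] = field(default_factory=list)
    alt_tss: list[int] = field(default_factory=list)
    chrom_length: int | None = None


def _subtract(intervals: list[tuple[int, int]], holes: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = intervals
    for hs, he in sorted(holes):
        nxt: list[tuple[int, int]] = []
        for s, e in out:
            if he <= s or e <= hs:
                nxt.append((s, e))
                continue
            if s < hs:
                nxt.append((s, hs))
            if he < e:
                nxt.append((he, e))
        out = nxt
    return out


def build_search_regions(annotation: GeneAnnotation, spec: SearchRegionSpec | None = None) -> list[GenomicRegion]:
    """CRM search space: ±flank around each TSS, minus coding exons and
    ±exclusion around each alternative TSS; clipped to chromosome bounds."""
    spec = spec or SearchRegionSpec()
    pieces: list[tuple[int, int]] = []
    for t in annotation.tss:
        s = max(0, t - spec.tss_flank)
        e = t + spec.tss_flank
        if annotation.chrom_length is not None:
            e = min(e, annotation.chrom_length)
        if s < e:
            pieces.append((s, e))
    # merge overlapping TSS windows
    pieces.sort()
    merged: list[tuple[int, int]] = []
    for s, e in pieces:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    holes = list(annotation.coding_exons) + [
        (max(0, t - spec.alt_tss_exclusion), t + spec.alt_tss_exclusion)
        for t in annotation.alt_tss
    ]
    final = _subtract(merged, holes)
    return [
        GenomicRegion(annotation.chrom, s, e, region_id=f"{annotation.chrom}:{s}-{e}")
        for s, e in final
        if e > s
    ]


@dataclass
class CRMWindow:
    region_id: str
    start: int  # window span within the region (offset coordinates)
    end: int
    best_rel: dict[str, float]
    n_hits: dict[str, int]
    hits: list[SiteHit] = field(default_factory=list)
    lra_score: float = 0.0
    cluster: float = 0.0

    def feature_vector(self, motif_ids: list[str]) -> np.ndarray:
        return np.array(
            [self.best_rel.get(m, 0.0) for m in motif_ids]
            + [float(self.n_hits.get(m, 0)) for m in motif_ids]
        )


def window_features(
    hits: list[SiteHit],
    region_length: int,
    region_id: str = "",
    motif_ids: list[str] | None = None,
    window: int = 200,
    step: int = 50,
) -> list[CRMWindow]:
    """Tile a region with fixed-step half-open windows and summarize hits.

    A hit contributes to every window it intersects.  Features per motif:
    best relative score (0 when absent) and hit count.
    """
    if motif_ids is None:
        motif_ids = sorted({h.motif_id for h in hits})
    windows: list[CRMWindow] = []
    start = 0
    while True:
        end = min(start + window, region_length)
        w_hits = [h for h in hits if h.offset < end and h.end > start]
        best: dict[str, float] = {m: 0.0 for m in motif_ids}
        count: dict[str, int] = {m: 0 for m in motif_ids}
        for h in w_hits:
            count[h.motif_id] = count.get(h.motif_id, 0) + 1
            if h.rel_score > best.get(h.motif_id, 0.0):
                best[h.motif_id] = h.rel_score
        windows.append(CRMWindow(region_id, start, end, best, count, w_hits))
        if end >= region_length:
            break
        start += step
    return windows


@dataclass
class LRAModel:
    motif_ids: list[str]
    weights: np.ndarray  # per feature
    intercept: float
    window: int = 200
    step: int = 50
    seed: int = 0

    def score(self, w: CRMWindow) -> float:
        z = float(self.weights @ w.feature_vector(self.motif_ids) + self.intercept)
        return 1.0 / (1.0 + np.exp(-z))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "motif_ids": self.motif_ids,
                    "weights": list(self.weights),
                    "intercept": self.intercept,
                    "window": self.window,
                    "step": self.step,
                    "seed": self.seed,
                },
                indent=1,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "LRAModel":
        d = json.loads(Path(path).read_text())
        return cls(
            d["motif_ids"], np.array(d["weights"], dtype=float), d["intercept"],
            d["window"], d["step"], d["seed"],
        )


RIDGE_PENALTY = 1e-3


def train_lra(
    positive_windows: list[CRMWindow],
    negative_windows: list[CRMWindow],
    motif_ids: list[str],
    seed: int = 0,
    window: int = 200,
    step: int = 50,
) -> LRAModel:
    """Ridge-regularized maximum-likelihood logistic fit (deterministic)."""
    if not positive_windows or not negative_windows:
        raise ValueError("both classes must be non-empty")
    X = np.array([w.feature_vector(motif_ids) for w in positive_windows + negative_windows])
    y = np.array([1] * len(positive_windows) + [0] * len(negative_windows))
    clf = LogisticRegression(
        C=1.0 / RIDGE_PENALTY, solver="lbfgs", max_iter=2000, random_state=seed
    )
    clf.fit(X, y)
    return LRAModel(list(motif_ids), clf.coef_[0].copy(), float(clf.intercept_[0]), window, step, seed)


def cluster_score(w: CRMWindow, gap_penalty: float = 0.0) -> float:
    """Additive cluster score: sum of relative scores of non-overlapping
    hits in the window, minus ``gap_penalty`` times the uncovered fraction."""
    from .motif_scan import resolve_overlaps

    kept = resolve_overlaps(w.hits)
    total = sum(h.rel_score for h in kept)
    span = w.end - w.start
    if span <= 0:
        return 0.0
    covered = np.zeros(span, dtype=bool)
    for h in kept:
        covered[max(0, h.offset - w.start) : max(0, min(span, h.end - w.start))] = True
    uncovered_frac = 1.0 - covered.mean()
    return max(0.0, total - gap_penalty * uncovered_frac)


@dataclass
class CRMPrediction:
    region_id: str
    start: int
    end: int
    score: float
    hits: list[SiteHit] = field(default_factory=list)

    @property
    def motif_ids(self) -> set[str]:
        return {h.motif_id for h in self.hits}


def predict_crms(
    windows: list[CRMWindow],
    model: LRAModel,
    score_cutoff: float = 0.5,
    exclude_sole_motif: str | None = "SP1",
) -> list[CRMPrediction]:
    """Threshold window scores, merge touching windows, drop SP1-only calls.

    Each merged prediction keeps the union of contributing hits and the
    maximum window score.
    """
    for w in windows:
        w.lra_score = model.score(w)
    above = sorted(
        (w for w in windows if w.lra_score >= score_cutoff),
        key=lambda w: (w.region_id, w.start),
    )
    preds: list[CRMPrediction] = []
    for w in above:
        if preds and preds[-1].region_id == w.region_id and w.start <= preds[-1].end:
            p = preds[-1]
            p.end = max(p.end, w.end)
            p.score = max(p.score, w.lra_score)
            seen = {(h.motif_id, h.offset, h.strand) for h in p.hits}
            p.hits.extend(h for h in w.hits if (h.motif_id, h.offset, h.strand) not in seen)
        else:
            preds.append(CRMPrediction(w.region_id, w.start, w.end, w.lra_score, list(w.hits)))
    if exclude_sole_motif is not None:
        preds = [
            p for p in preds
            if not (p.hits and p.motif_ids == {exclude_sole_motif})
        ]
    return preds


def conservation_filter(
    predictions: list[CRMPrediction],
    track: ScoreTrack,
    max_score_cutoff: float,
    region_starts: dict[str, int] | None = None,
) -> list[CRMPrediction]:
    """Keep predictions whose maximum per-base conservation reaches the cutoff.

    ``region_starts`` maps region_id to its genomic start so window
    offsets can be placed on the track; omitted means offsets are already
    track coordinates.
    """
    kept = []
    for p in predictions:
        base = 0 if region_starts is None else region_starts.get(p.region_id, 0)
        s = max(track.start, base + p.start)
        e = min(track.end, base + p.end)
        if s >= e:
            continue
        if track.slice(s, e).max() >= max_score_cutoff:
            kept.append(p)
    return kept
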
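"""Sequence-composition, conservation and TFBS-depth analytics over labeled region sets.

These are the property analyses that separate validated (responding)
enhancer sequences from non-responding inserts: mono/dinucleotide
composition and GC bias, phastCons-style conservation summaries
(mean / max / conserved-run make-up), distance to the nearest TSS and
CpG-island association, and the phylogenetic depth of predicted TFBS
positions relative to their non-site flanks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import GenomicRegion, ScoreTrack
from .motif_scan import SiteHit, resolve_overlaps

DINUCS = [a + b for a in "ACGT" for b in "ACGT"]


@dataclass
class CompositionProfile:
    mono: dict[str, float]
    gc_content: float
    gc_skew: float
    at_skew: float
    dinuc: dict[str, float]


def composition(seq: str) -> CompositionProfile:
    """Mono- and dinucleotide frequencies, GC content and strand skews.

    N bases are dropped before counting; dinucleotides are counted over
    the remaining overlapping pairs on the given strand only.
    GC skew = (G - C) / (G + C); AT skew = (A - T) / (A + T).
    """
    seq = seq.upper().replace("N", "")
    if len(seq) < 2:
        raise ValueError("need at least 2 non-N bases")
    counts = {b: seq.count(b) for b in "ACGT"}
    n = len(seq)
    mono = {b: counts[b] / n for b in "ACGT"}
    gc = counts["G"] + counts["C"]
    at = counts["A"] + counts["T"]
    gc_skew = (counts["G"] - counts["C"]) / gc if gc else 0.0
    at_skew = (counts["A"] - counts["T"]) / at if at else 0.0
    dcounts = dict.fromkeys(DINUCS, 0)
    for i in range(n - 1):
        dcounts[seq[i : i + 2]] += 1
    dinuc = {d: c / (n - 1) for d, c in dcounts.items()}
    return CompositionProfile(mono, gc / n, gc_skew, at_skew, dinuc)


def compare_composition(
    values_a: np.ndarray, values_b: np.ndarray
) -> float:
    """Two-sided Wilcoxon rank-sum p-value for one per-region feature."""
    a, b = np.asarray(values_a, float), np.asarray(values_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both region sets must be non-empty")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def compare_composition_sets(
    profiles_a: list[CompositionProfile], profiles_b: list[CompositionProfile]
) -> dict[str, float]:
    """Rank-sum p per composition feature (gc_content, skews, dinucleotides)."""
    out: dict[str, float] = {}
    for feat in ("gc_content", "gc_skew", "at_skew"):
        out[feat] = compare_composition(
            [getattr(p, feat) for p in profiles_a], [getattr(p, feat) for p in profiles_b]
        )
    for d in DINUCS:
        out[f"dinuc_{d}"] = compare_composition(
            [p.dinuc[d] for p in profiles_a], [p.dinuc[d] for p in profiles_b]
        )
    return out


@dataclass
class ConservationSummary:
    mean_score: float
    max_score: float
    conserved_fraction: float
    is_conserved: bool


def _runs_at_least(values: np.ndarray, cutoff: float, strict: bool) -> list[tuple[int, int]]:
    """Maximal runs where score > cutoff (strict) or >= cutoff."""
    mask = values > cutoff if strict else values >= cutoff
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            runs.append((i, j + 1))
            i = j + 1
        else:
            i += 1
    return runs


def conservation_summary(
    region: GenomicRegion,
    track: ScoreTrack,
    cutoff: float = 0.7,
    min_run: int = 20,
) -> ConservationSummary:
    """Per-region conservation summary.

    ``is_conserved`` requires a run of at least ``min_run`` consecutive
    bases each scoring >= cutoff; ``conserved_fraction`` is the summed
    length of maximal runs scoring strictly > cutoff (any length) over
    the region length.  The >= / > asymmetry mirrors the source
    definitions of the two quantities.
    """
    values = track.slice(region.start, region.end)
    ge_runs = _runs_at_least(values, cutoff, strict=False)
    gt_runs = _runs_at_least(values, cutoff, strict=True)
    is_cons = any(e - s >= min_run for s, e in ge_runs)
    frac = sum(e - s for s, e in gt_runs) / len(values)
    return ConservationSummary(
        float(values.mean()), float(values.max()), float(frac), bool(is_cons)
    )


def set_conservation_summary(
    regions: list[GenomicRegion], track: ScoreTrack, cutoff: float = 0.7, min_run: int = 20
) -> dict[str, float]:
    """Set-level summary: mean of per-region means, mean of per-region maxima,
    and pooled conserved make-up (summed conserved lengths / summed lengths)."""
    summaries = [conservation_summary(r, track, cutoff, min_run) for r in regions]
    total_len = sum(r.length for r in regions)
    conserved_len = sum(s.conserved_fraction * r.length for s, r in zip(summaries, regions))
    return {
        "mean_score": float(np.mean([s.mean_score for s in summaries])),
        "avg_max_score": float(np.mean([s.max_score for s in summaries])),
        "conserved_makeup": conserved_len / total_len if total_len else 0.0,
        "n_conserved": sum(s.is_conserved for s in summaries),
    }


def tss_distance(region: GenomicRegion, tss_list: list[int]) -> int:
    """Distance in bp to the nearest TSS; 0 when a TSS falls inside the region."""
    if not tss_list:
        raise ValueError("empty TSS list")
    best = None
    for t in tss_list:
        if region.start <= t < region.end:
            return 0
        d = region.start - t if t < region.start else t - region.end + 1
        best = d if best is None else min(best, d)
    return int(best)


def cpg_island_assoc(
    region: GenomicRegion, islands: list[tuple[int, int]], flank: int = 1000
) -> bool:
    """True iff any CpG island intersects region +/- flank (half-open)."""
    lo, hi = region.start - flank, region.end + flank
    return any(s < hi and e > lo for s, e in islands)


@dataclass
class TFDepth:
    motif_id: str
    site_mean: float
    nonsite_mean: float
    fold: float | None


@dataclass
class DepthResult:
    per_tf: dict[str, dict[str, TFDepth]]  # set_name -> motif -> depth
    selected_tfs: list[str]
    set_ratios: dict[str, np.ndarray]  # per-set per-TF fold distributions
    t_tests: dict[tuple[str, str], float]  # (set_a, set_b) -> p-value


def _site_mask(region: GenomicRegion, hits: list[SiteHit]) -> np.ndarray:
    mask = np.zeros(region.length, dtype=bool)
    for h in hits:
        s = max(0, h.offset)
        e = min(region.length, h.end)
        if s < e:
            mask[s:e] = True
    return mask


def tfbs_depth(
    regions_by_set: dict[str, list[GenomicRegion]],
    hits_by_region: dict[str, list[SiteHit]],
    track: ScoreTrack,
    fold_cut: float = 2.0,
    responding_sets: tuple[str, ...] = ("validated", "reference"),
) -> DepthResult:
    """Phylogenetic depth of predicted TFBS positions per region set.

    For each TF and set: mean track score over retained (overlap-resolved)
    site footprints vs over the non-binding-site positions (positions
    outside every TF's retained footprint); fold = site / non-site.
    TFs reaching ``fold_cut`` in any responding set form the selected
    list; their fold distributions are compared between sets with
    two-sample t-tests.  Folds are undefined (TF skipped) when the
    non-site mean is not positive.
    """
    per_tf: dict[str, dict[str, TFDepth]] = {}
    for set_name, regions in regions_by_set.items():
        motif_ids = sorted(
            {h.motif_id for r in regions for h in hits_by_region.get(r.region_id, [])}
        )
        site_scores: dict[str, list[np.ndarray]] = {m: [] for m in motif_ids}
        nonsite_scores: dict[str, list[np.ndarray]] = {m: [] for m in motif_ids}
        for r in regions:
            values = track.slice(r.start, r.end)
            rhits = resolve_overlaps(hits_by_region.get(r.region_id, []))
            any_site = _site_mask(r, rhits)
            for m in motif_ids:
                mask = _site_mask(r, [h for h in rhits if h.motif_id == m])
                site_scores[m].append(values[mask])
                nonsite_scores[m].append(values[~any_site])
        depths: dict[str, TFDepth] = {}
        for m in motif_ids:
            site = np.concatenate(site_scores[m]) if site_scores[m] else np.empty(0)
            nonsite = np.concatenate(nonsite_scores[m]) if nonsite_scores[m] else np.empty(0)
            if site.size == 0 or nonsite.size == 0:
                continue
            sm, nm = float(site.mean()), float(nonsite.mean())
            fold = sm / nm if nm > 0 else None
            depths[m] = TFDepth(m, sm, nm, fold)
        per_tf[set_name] = depths

    selected: set[str] = set()
    for set_name in responding_sets:
        for m, d in per_tf.get(set_name, {}).items():
            if d.fold is not None and d.fold >= fold_cut:
                selected.add(m)
    selected_tfs = sorted(selected)

    set_ratios = {
        set_name: np.array(
            [
                depths[m].fold
                for m in selected_tfs
                if m in depths and depths[m].fold is not None
            ]
        )
        for set_name, depths in per_tf.items()
    }
    t_tests: dict[tuple[str, str], float] = {}
    names = sorted(per_tf)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ra, rb = set_ratios[a], set_ratios[b]
            if len(ra) >= 2 and len(rb) >= 2:
                t_tests[(a, b)] = float(stats.ttest_ind(ra, rb).pvalue)
    return DepthResult(per_tf, selected_tfs, set_ratios, t_tests)
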
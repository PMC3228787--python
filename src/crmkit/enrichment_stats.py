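"""Exact contingency statistics, motif over-representation, peak overlap and ROC analysis.

Fisher tests are hypergeometric tails with fixed margins; enrichment
tests are one-sided (greater) by default, matching how over-represented
motifs and ChIP-peak overlaps are scored in the validation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .io_formats import GenomicRegion, PeakSet
from .motif_scan import SiteHit


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b, c, d) = (target-hit, target-nonhit, control-hit, control-nonhit)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be nonnegative integers")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def transpose(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.c, self.d, self.a, self.b)


def fisher_exact(table: ContingencyTable2x2, side: str = "greater") -> float:
    """Fisher exact p-value from the hypergeometric distribution.

    ``greater``: P(X >= a) where X is the target-hit count with all
    margins fixed; ``less``: P(X <= a); ``two_sided``: sum of all
    outcome probabilities <= P(X = a).  Degenerate margins give p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    N = table.n
    K = a + c  # total hits
    n = a + b  # target size
    if N == 0 or K == 0 or K == N or n == 0 or n == N:
        return 1.0
    hg = stats.hypergeom(N, K, n)
    if side == "greater":
        return float(min(1.0, hg.sf(a - 1)))
    if side == "less":
        return float(min(1.0, hg.cdf(a)))
    if side == "two_sided":
        support = np.arange(max(0, n + K - N), min(n, K) + 1)
        pmf = hg.pmf(support)
        return float(min(1.0, pmf[pmf <= hg.pmf(a) * (1 + 1e-12)].sum()))
    raise ValueError(f"unknown side {side!r}")


def region_hit_table(
    fg_regions: list[GenomicRegion],
    bg_regions: list[GenomicRegion],
    hits_by_region: dict[str, list[SiteHit]],
    tf: str,
) -> ContingencyTable2x2:
    """Count regions containing >= 1 retained site of the TF, fg vs bg."""

    def n_hit(regions: list[GenomicRegion]) -> int:
        return sum(
            any(h.motif_id == tf for h in hits_by_region.get(r.region_id, []))
            for r in regions
        )

    fa = n_hit(fg_regions)
    ca = n_hit(bg_regions)
    return ContingencyTable2x2(fa, len(fg_regions) - fa, ca, len(bg_regions) - ca)


@dataclass
class OverrepResult:
    tf_id: str
    table: ContingencyTable2x2
    fisher_p: float
    z_score: float
    rank: int = 0


def site_rate_z_score(
    fg_site_count: int, fg_nucleotides: int, bg_site_count: int, bg_nucleotides: int
) -> float:
    """oPOSSUM-style Z: standardized excess of fg sites at the bg per-nucleotide rate."""
    if fg_nucleotides == 0 or bg_nucleotides == 0 or bg_site_count == 0:
        return 0.0
    p = bg_site_count / bg_nucleotides
    mu = fg_nucleotides * p
    sd = np.sqrt(fg_nucleotides * p * (1 - p))
    return float((fg_site_count - mu) / sd) if sd > 0 else 0.0


def overrepresentation(
    fg_regions: list[GenomicRegion],
    bg_regions: list[GenomicRegion],
    hits_by_region: dict[str, list[SiteHit]],
    tfs: list[str],
) -> list[OverrepResult]:
    """Per-TF over-representation of fg vs bg regions, ranked by one-sided
    Fisher p (ascending); Z-scores use nucleotide-level site rates."""
    fg_nt = sum(r.length for r in fg_regions)
    bg_nt = sum(r.length for r in bg_regions)

    def n_sites(regions: list[GenomicRegion], tf: str) -> int:
        return sum(
            sum(h.motif_id == tf for h in hits_by_region.get(r.region_id, []))
            for r in regions
        )

    results = []
    for tf in tfs:
        table = region_hit_table(fg_regions, bg_regions, hits_by_region, tf)
        z = site_rate_z_score(n_sites(fg_regions, tf), fg_nt, n_sites(bg_regions, tf), bg_nt)
        results.append(OverrepResult(tf, table, fisher_exact(table, "greater"), z))
    results.sort(key=lambda r: (r.fisher_p, r.tf_id))
    for i, r in enumerate(results, 1):
        r.rank = i
    return results


# ---------------------------------------------------------------------------
# Peak overlap


def _peak_trees(peaks: PeakSet) -> dict[str, IntervalTree]:
    return {
        chrom: IntervalTree.from_tuples(ivals) for chrom, ivals in peaks.intervals.items()
    }


def regions_overlapping(regions: list[GenomicRegion], peaks: PeakSet, min_overlap: int = 1) -> list[bool]:
    """Per-region flag: >= min_overlap bp intersection with any peak."""
    trees = _peak_trees(peaks)
    out = []
    for r in regions:
        tree = trees.get(r.chrom)
        hit = False
        if tree is not None:
            for iv in tree.overlap(r.start, r.end):
                if min(iv.end, r.end) - max(iv.begin, r.start) >= min_overlap:
                    hit = True
                    break
        out.append(hit)
    return out


@dataclass
class OverlapComparison:
    name: str
    table: ContingencyTable2x2
    p_greater: float
    p_less: float
    pct_target: float
    pct_control: float


def overlap_table(n_hit_target: int, n_target: int, n_hit_control: int, n_control: int) -> ContingencyTable2x2:
    return ContingencyTable2x2(
        n_hit_target, n_target - n_hit_target, n_hit_control, n_control - n_hit_control
    )


def _comparison(name: str, t: ContingencyTable2x2) -> OverlapComparison:
    return OverlapComparison(
        name,
        t,
        fisher_exact(t, "greater"),
        fisher_exact(t, "less"),
        100.0 * t.a / (t.a + t.b) if t.a + t.b else 0.0,
        100.0 * t.c / (t.c + t.d) if t.c + t.d else 0.0,
    )


def overlap_contingency(
    region_sets: dict[str, list[GenomicRegion]],
    peaks_by_condition: dict[str, PeakSet],
    min_overlap: int = 1,
) -> list[OverlapComparison]:
    """ChIP-peak overlap comparisons across region sets and conditions.

    For two region sets (e.g. responding / non_responding) and two peak
    conditions (e.g. myoblast / myotube) this emits the four standard
    comparisons: set vs set within each condition, and condition vs
    condition within each set.  One-sided p-values are reported both ways.
    """
    flags = {
        (sname, cname): regions_overlapping(regions, peaks, min_overlap)
        for sname, regions in region_sets.items()
        for cname, peaks in peaks_by_condition.items()
    }
    out: list[OverlapComparison] = []
    set_names = list(region_sets)
    cond_names = list(peaks_by_condition)
    for cname in cond_names:
        for i, sa in enumerate(set_names):
            for sb in set_names[i + 1 :]:
                fa, fb = flags[(sa, cname)], flags[(sb, cname)]
                t = overlap_table(sum(fa), len(fa), sum(fb), len(fb))
                out.append(_comparison(f"{sa}_vs_{sb}@{cname}", t))
    for sname in set_names:
        for i, ca in enumerate(cond_names):
            for cb in cond_names[i + 1 :]:
                fa, fb = flags[(sname, cb)], flags[(sname, ca)]
                t = overlap_table(sum(fa), len(fa), sum(fb), len(fb))
                out.append(_comparison(f"{cb}_vs_{ca}@{sname}", t))
    return out


# ---------------------------------------------------------------------------
# ROC


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    points: list = field(default_factory=list)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC curve and rank-statistic AUC with midrank tie handling.

    AUC equals the normalized Mann-Whitney U statistic: ties between a
    positive and a negative contribute 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for ROC")
    ranks = stats.rankdata(scores)  # midranks
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores, sorted_labels = scores[order], labels[order]
    thresholds, tpr, fpr = [np.inf], [0.0], [0.0]
    tp = fp = 0
    i = 0
    n = len(scores)
    while i < n:
        j = i
        while j + 1 < n and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        tp += int(sorted_labels[i : j + 1].sum())
        fp += (j - i + 1) - int(sorted_labels[i : j + 1].sum())
        thresholds.append(sorted_scores[i])
        tpr.append(tp / n_pos)
        fpr.append(fp / n_neg)
        i = j + 1
    return RocCurve(np.array(thresholds), np.array(fpr), np.array(tpr), float(auc))


def roc_with_conservation_filter(
    scores: np.ndarray,
    labels: np.ndarray,
    max_cons_scores: np.ndarray,
    cutoff: float,
) -> RocCurve:
    """ROC after demoting entries failing the conservation filter to -inf."""
    scores = np.asarray(scores, dtype=float).copy()
    scores[np.asarray(max_cons_scores, dtype=float) < cutoff] = -np.inf
    return roc_auc(scores, labels)
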
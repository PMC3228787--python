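"""Dual-luciferase reporter-assay statistics.

Processing chain for firefly/renilla plate readings from the C2C12
myogenesis screen (fibroblast / myoblast / myotube cell types, two
technical replicates, two experimental phases with independent plasmid
preparations):

1. QC: wells where firefly < 1000 LRU fail; wells where only renilla is
   below 1000 have renilla floored to 1000 before the ratio is taken
   (bounds spuriously large ratios from near-background denominators).
2. Technical replicates are averaged (a single passing replicate is used
   alone).
3. Per-cell-type variance-stabilizing normalization: a generalized-log
   transform glog(x) = asinh((x - a) / b), with (a, b) fit by maximum
   likelihood under a normal model for the transformed values.
4. Differential myotube expression per clone with a moderated
   (SAM-style) d-statistic and a label-permutation FDR.
5. Insert-level consensus: positive iff >= 2 positive clones and >= 50%
   of available clones positive, phases combined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .io_formats import CELL_TYPES

LRU_THRESHOLD = 1000.0

QC_PASS = "pass"
QC_SINGLE = "single_rep"
QC_FAILED = "failed"


@dataclass
class CloneExpression:
    clone_id: str
    cell_type: str
    ratio: float | None
    qc_status: str
    normalized: float | None = None


@dataclass
class InsertCall:
    insert_id: str
    n_clones_available: int
    n_clones_positive: int
    final_call: bool
    positive_clones: list[str] = field(default_factory=list)


def qc_filter(firefly_lru: float, renilla_lru: float, threshold: float = LRU_THRESHOLD) -> float | None:
    """Firefly/renilla ratio after the minimum-LRU transfection filter.

    Returns ``None`` for a failed well (firefly below threshold).  When
    only renilla is below threshold it is set *to* the threshold, which
    caps the ratio at firefly/threshold.  "Above the minimum threshold"
    is treated as inclusive (>=).
    """
    if firefly_lru < 0 or renilla_lru < 0:
        raise ValueError("LRU values must be nonnegative")
    if firefly_lru < threshold:
        return None
    if renilla_lru < threshold:
        renilla_lru = threshold
    return firefly_lru / renilla_lru


def average_technical_reps(ratios: list[float | None], clone_id: str = "", cell_type: str = "") -> CloneExpression:
    """Mean of passing technical-replicate ratios.

    Both failed -> the clone is excluded for this cell type; a single
    passing replicate is used alone and flagged.
    """
    passing = [r for r in ratios if r is not None]
    if not passing:
        return CloneExpression(clone_id, cell_type, None, QC_FAILED)
    status = QC_PASS if len(passing) == len(ratios) else QC_SINGLE
    return CloneExpression(clone_id, cell_type, float(np.mean(passing)), status)


def glog(x: np.ndarray, a: float, b: float) -> np.ndarray:
    return np.arcsinh((np.asarray(x, dtype=float) - a) / b)


def fit_glog(values: np.ndarray) -> tuple[float, float]:
    """ML calibration of the generalized-log offset/scale (a, b).

    Model: glog(x) ~ Normal(mu, sigma^2).  With mu, sigma profiled out
    the negative log-likelihood reduces to
    n/2 * log var(h(x)) + 1/2 * sum log((x - a)^2 + b^2).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 8:
        raise ValueError("need at least 8 values to calibrate the transform")

    b_floor = 1e-9 * (np.std(x) if np.std(x) > 0 else 1.0)

    def nll(params: np.ndarray) -> float:
        a, log_b = params
        b = np.exp(log_b)
        if b < b_floor or not np.isfinite(b):
            return np.inf
        h = np.arcsinh((x - a) / b)
        v = h.var()
        if v <= 0:
            return np.inf
        return 0.5 * len(x) * np.log(v) + 0.5 * np.sum(np.log((x - a) ** 2 + b**2))

    scale = np.std(x) if np.std(x) > 0 else 1.0
    res = minimize(nll, x0=np.array([np.min(x), np.log(scale)]), method="Nelder-Mead")
    a, log_b = res.x
    return float(a), float(np.exp(log_b))


def normalize(values: np.ndarray) -> np.ndarray:
    """Variance-stabilizing glog transform of one cell-type batch.

    Constant batches are returned unchanged (nothing to stabilize).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 8:
        raise ValueError("need at least 8 values per batch")
    if np.allclose(x, x[0]):
        return x.copy()
    a, b = fit_glog(x)
    return glog(x, a, b)


# ---------------------------------------------------------------------------
# SAM-style differential calling


def sam_d_statistic(group1: np.ndarray, group2: np.ndarray, s0: float) -> tuple[float, float]:
    """Two-class unpaired moderated statistic; returns (d, s).

    d = (mean1 - mean2) / (s + s0) with s the pooled standard error; when
    fewer than one degree of freedom is available s = 0 and the
    fudge-factor s0 alone moderates the denominator.
    """
    g1, g2 = np.asarray(group1, float), np.asarray(group2, float)
    n1, n2 = len(g1), len(g2)
    diff = g1.mean() - g2.mean()
    df = n1 + n2 - 2
    if df > 0:
        ss = ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
        s = float(np.sqrt((1.0 / n1 + 1.0 / n2) * ss / df))
    else:
        s = 0.0
    denom = s + s0
    if denom == 0:
        return (0.0 if diff == 0 else np.sign(diff) * np.inf), s
    return float(diff / denom), s


def _pooled_se(g1: np.ndarray, g2: np.ndarray) -> float:
    return sam_d_statistic(g1, g2, s0=1.0)[1]


def differential_call(
    groups: dict[str, tuple[np.ndarray, np.ndarray]],
    fdr: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    slots: dict[str, tuple[list[int], list[int]]] | None = None,
) -> pd.DataFrame:
    """One-sided SAM-style calls for elevated first-group (myotube) expression.

    ``groups`` maps clone_id -> (myotube values, other-cell values).  The
    moderation constant s0 is the median of the per-clone pooled standard
    errors.  The null distribution comes from permuting sample labels:
    when ``slots`` gives each value's position in a common sample layout
    (e.g. cell type x technical replicate), one global relabeling per
    permutation is applied to every clone (the SAM convention); all
    distinct relabelings are enumerated exactly when there are at most
    ``n_perm`` of them, otherwise ``n_perm`` are sampled.  Without
    ``slots``, labels are permuted within each clone independently.
    The estimated FDR of a cutoff delta is pi0 times the median
    permutation count of statistics >= delta over the observed count
    >= delta; the smallest observed d with estimated FDR <= ``fdr``
    becomes the cutoff.  Deterministic under a fixed seed.
    """
    if not 0 < fdr < 1:
        raise ValueError("fdr must be in (0, 1)")
    rng = np.random.default_rng(seed)
    clone_ids = sorted(groups)
    m = len(clone_ids)
    s_values = np.array([_pooled_se(*groups[c]) for c in clone_ids])
    s0 = float(np.median(s_values))
    d_obs = np.array([sam_d_statistic(*groups[c], s0)[0] for c in clone_ids])

    if slots is not None:
        all_slots = sorted(
            {s for c in clone_ids for grp in slots[c] for s in grp}
        )
        n_target = max(len(slots[c][0]) for c in clone_ids)
        n_distinct = comb(len(all_slots), n_target)
        if n_distinct <= n_perm:
            target_sets = [set(t) for t in combinations(all_slots, n_target)]
        else:
            target_sets = [
                set(rng.permutation(all_slots)[:n_target].tolist())
                for _ in range(n_perm)
            ]
        by_slot = {}
        for c in clone_ids:
            g1, g2 = groups[c]
            s1, s2 = slots[c]
            by_slot[c] = dict(zip(list(s1) + list(s2), np.concatenate([g1, g2])))
        null_matrix = np.zeros((len(target_sets), m))
        for b, tgt in enumerate(target_sets):
            for i, c in enumerate(clone_ids):
                vals = by_slot[c]
                p1 = np.array([v for s, v in vals.items() if s in tgt])
                p2 = np.array([v for s, v in vals.items() if s not in tgt])
                if len(p1) == 0 or len(p2) == 0:
                    null_matrix[b, i] = 0.0
                else:
                    null_matrix[b, i] = sam_d_statistic(p1, p2, s0)[0]
    else:
        null_matrix = np.zeros((n_perm, m))
        for i, c in enumerate(clone_ids):
            g1, g2 = groups[c]
            pooled = np.concatenate([g1, g2])
            n1, n = len(g1), len(pooled)
            idx = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
            p1 = pooled[idx[:, :n1]]
            p2 = pooled[idx[:, n1:]]
            diff = p1.mean(axis=1) - p2.mean(axis=1)
            df = n - 2
            if df > 0 and n - n1 >= 1:
                ss = ((p1 - p1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
                ss += ((p2 - p2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
                s = np.sqrt((1.0 / n1 + 1.0 / (n - n1)) * ss / df)
            else:
                s = np.zeros(n_perm)
            with np.errstate(divide="ignore", invalid="ignore"):
                null_matrix[:, i] = np.where(s + s0 > 0, diff / (s + s0), 0.0)

    # SAM pi0: fraction of clones whose d falls in the null interquartile
    # range; infinite statistics (zero denominators) are excluded
    finite_null = null_matrix[np.isfinite(null_matrix)]
    if m and finite_null.size:
        q25, q75 = np.quantile(finite_null, [0.25, 0.75])
        pi0 = min(1.0, ((d_obs > q25) & (d_obs < q75)).sum() / (0.5 * m))
    else:
        pi0 = 1.0

    cutoff = np.inf
    for delta in np.sort(d_obs)[::-1]:
        if delta <= 0:
            break
        n_called = int((d_obs >= delta).sum())
        med_null = float(np.median((null_matrix >= delta).sum(axis=1)))
        est_fdr = min(1.0, pi0 * med_null / n_called) if n_called else 1.0
        if est_fdr <= fdr:
            cutoff = delta
        else:
            break
    called = d_obs >= cutoff
    return pd.DataFrame(
        {"clone_id": clone_ids, "d": d_obs, "s": s_values, "positive": called}
    ).set_index("clone_id")


# ---------------------------------------------------------------------------
# Pipeline over plate tables


def clone_cell_ratios(wells: pd.DataFrame, threshold: float = LRU_THRESHOLD) -> pd.DataFrame:
    """Per-well QC ratios plus replicate-averaged clone x cell-type table.

    Returns one row per (clone_id, insert_id, set_label, phase, cell_type)
    with the averaged ratio and qc_status; clones failing in a cell type
    are retained with status 'failed' and NaN ratio.
    """
    wells = wells.copy()
    wells["ratio"] = [
        qc_filter(f, r, threshold)
        for f, r in zip(wells["firefly_lru"], wells["renilla_lru"])
    ]
    rows = []
    keys = ["clone_id", "insert_id", "set_label", "phase", "cell_type"]
    for key, grp in wells.groupby(keys, sort=True):
        expr = average_technical_reps(list(grp["ratio"]))
        rows.append(dict(zip(keys, key), ratio=expr.ratio, qc_status=expr.qc_status))
    return pd.DataFrame(rows)


def _well_groups(wells: pd.DataFrame, phase: int, threshold: float) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Myotube vs pooled-other normalized well ratios per clone, one phase."""
    ph = wells[wells["phase"] == phase].copy()
    ph["ratio"] = [
        qc_filter(f, r, threshold)
        for f, r in zip(ph["firefly_lru"], ph["renilla_lru"])
    ]
    ph = ph.dropna(subset=["ratio"])
    # variance stabilization with a single (a, b) calibration shared by all
    # cell types in the phase: per-batch calibrations are not identifiable
    # here and would destroy cross-cell-type comparability of the ratios
    x = ph["ratio"].to_numpy()
    if len(x) >= 8 and not np.allclose(x, x[0]):
        a, b = fit_glog(x)
        ph["norm"] = glog(x, a, b)
    else:
        ph["norm"] = np.log(np.maximum(x, 1e-12))
    ct_index = {ct: i for i, ct in enumerate(CELL_TYPES)}
    ph["slot"] = [
        ct_index[ct] * 10 + int(rep) for ct, rep in zip(ph["cell_type"], ph["tech_rep"])
    ]
    groups: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    slots: dict[str, tuple[list[int], list[int]]] = {}
    for clone, grp in ph.groupby("clone_id"):
        is_mt = grp["cell_type"] == "myotube"
        mt = grp.loc[is_mt, "norm"].to_numpy()
        other = grp.loc[~is_mt, "norm"].to_numpy()
        if len(mt) >= 1 and len(other) >= 1:
            groups[str(clone)] = (mt, other)
            slots[str(clone)] = (
                grp.loc[is_mt, "slot"].tolist(),
                grp.loc[~is_mt, "slot"].tolist(),
            )
    return groups, slots


def phase1_advance(
    clone_table: pd.DataFrame,
    sam_positive: set[str],
    fold_cut: float = 2.0,
    control_clones: set[str] | None = None,
) -> set[str]:
    """Clones advanced to phase 2: >= fold_cut myotube increase over *both*
    other cell types (raw averaged ratios, inclusive boundary) or a SAM
    positive call, plus any designated control rows."""
    p1 = clone_table[clone_table["phase"] == 1]
    advanced: set[str] = set(control_clones or ())
    pivot = p1.pivot_table(index="clone_id", columns="cell_type", values="ratio", aggfunc="first")
    for clone, row in pivot.iterrows():
        mt = row.get("myotube", np.nan)
        others = [row.get(ct, np.nan) for ct in ("myoblast", "fibroblast")]
        others = [o for o in others if np.isfinite(o)]
        if np.isfinite(mt) and others and all(o > 0 and mt / o >= fold_cut for o in others):
            advanced.add(str(clone))
    advanced |= sam_positive
    return advanced


def consensus_positive(
    insert_id: str, clone_positive: dict[str, bool]
) -> InsertCall:
    """Insert-level consensus: >= 2 positive clones and >= 50% of available."""
    available = len(clone_positive)
    positives = [c for c, pos in clone_positive.items() if pos]
    final = len(positives) >= 2 and available > 0 and len(positives) / available >= 0.5
    return InsertCall(insert_id, available, len(positives), final, sorted(positives))


def consensus_from_counts(insert_id: str, n_positive: int, n_available: int) -> InsertCall:
    """Consensus rule applied directly to printed positive-well counts."""
    final = n_positive >= 2 and n_available > 0 and n_positive / n_available >= 0.5
    return InsertCall(insert_id, n_available, n_positive, final)


def analyze_plates(
    wells: pd.DataFrame,
    fdr: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    threshold: float = LRU_THRESHOLD,
    fold_cut: float = 2.0,
) -> tuple[pd.DataFrame, list[InsertCall]]:
    """Full assay analysis: QC, normalization, per-phase SAM calls,
    phase-1 advancement, and the insert-level consensus rule.

    Returns (clone-level table, insert calls).  Phase 2, when present,
    is analyzed only for clones advanced from phase 1 (myotube vs
    myoblast only).
    """
    clone_table = clone_cell_ratios(wells, threshold)
    phases = sorted(wells["phase"].unique())
    positive_by_phase: dict[int, set[str]] = {}
    for k, phase in enumerate(phases):
        groups, slots = _well_groups(wells, phase, threshold)
        if phase != phases[0]:
            advanced = phase1_advance(
                clone_table, positive_by_phase[phases[0]], fold_cut=fold_cut
            )
            groups = {c: g for c, g in groups.items() if c in advanced}
            slots = {c: s for c, s in slots.items() if c in groups}
        if not groups:
            positive_by_phase[phase] = set()
            continue
        calls = differential_call(groups, fdr=fdr, n_perm=n_perm, seed=seed + k, slots=slots)
        positive_by_phase[phase] = set(calls.index[calls["positive"]])
    all_positive = set().union(*positive_by_phase.values()) if positive_by_phase else set()

    clone_to_insert = wells.drop_duplicates("clone_id").set_index("clone_id")["insert_id"]
    available = clone_table.dropna(subset=["ratio"])["clone_id"].unique()
    insert_calls = []
    for insert, grp in clone_to_insert.groupby(clone_to_insert):
        clones = [c for c in grp.index if c in set(available)]
        if not clones:
            continue
        insert_calls.append(
            consensus_positive(str(insert), {c: c in all_positive for c in clones})
        )
    clone_table["sam_positive"] = clone_table["clone_id"].isin(all_positive)
    return clone_table, insert_calls
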
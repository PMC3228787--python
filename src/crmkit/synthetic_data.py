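"""Synthetic inputs with the statistical structure the analysis assumes.

Every pipeline stage is testable offline: genomes with planted TFBS
clusters and controllable GC bias, conservation tracks elevated over
planted elements (and further over planted sites), lognormal dual
luciferase plate readings with myotube-selective planted effects and
transfection failures, and ChIP-peak sets with label-dependent overlap
probabilities.

Defaults mirror the conditions of the muscle CRM validation screen they
emulate: a 0.03 GC shift inside planted CRMs over a 0.51 background
(the responder/non-responder contrast), clusters of >= 3 sites within a
200 bp window, 15-fold myotube induction for planted positives (the
TN-I control magnitude), lognormal noise with CV 0.3, and peak-overlap
probabilities 0.58 (responders) vs 0.16 (non-responders).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import PFM, GenomicRegion, PeakSet, ScoreTrack, SetLabel
from .motif_scan import pfm_to_pwm, reverse_complement

SIM_CHROM = "chrSim"


@dataclass
class SimConfig:
    seed: int = 0
    genome_length: int = 100_000
    background_gc: float = 0.51
    n_crm: int = 20
    crm_gc_shift: float = 0.03
    crm_window: int = 200
    motifs_per_crm: int = 3
    conservation_elevation: float = 0.5
    site_elevation: float = 2.0
    plate_effect_fold: float = 15.0
    plate_cv: float = 0.3
    fail_rate: float = 0.05
    peak_overlap_probs: dict = field(
        default_factory=lambda: {"responder": 0.58, "non_responder": 0.16}
    )

    def __post_init__(self) -> None:
        for p in (self.background_gc, self.fail_rate, *self.peak_overlap_probs.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.plate_effect_fold <= 0:
            raise ValueError("effect fold must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _consensus_pfm(motif_id: str, name: str, consensus: str, weight: int = 85) -> PFM:
    """Synthetic PFM from an IUPAC consensus (supports W); clearly a stand-in
    constructed from the published consensus, not a measured matrix."""
    expand = {"A": "A", "C": "C", "G": "G", "T": "T", "W": "AT"}
    counts = np.full((4, len(consensus)), 5.0)
    for j, sym in enumerate(consensus):
        bases = expand[sym]
        for b in bases:
            counts["ACGT".index(b), j] = weight / len(bases)
    return PFM(motif_id, name, counts)


def muscle_motifs() -> list[PFM]:
    """Synthetic stand-ins for the five muscle motif models used by the
    CRM scan (MEF2, SRF CArG box, Myf E-box, TEAD MCAT, SP1 GC box),
    built from their well-known consensus sequences."""
    return [
        _consensus_pfm("MEF2A", "MEF2A-syn", "CTAWWWWTAG"),
        _consensus_pfm("SRF", "SRF-syn", "CCWWWWWWGG"),
        _consensus_pfm("MYF", "MYF-syn", "CAGCTG"),
        _consensus_pfm("TEAD", "TEAD-syn", "GGAATG"),
        _consensus_pfm("SP1", "SP1-syn", "GGGGCGGGGC"),
    ]


@dataclass
class PlantedSite:
    motif_id: str
    start: int  # absolute genome coordinate
    end: int
    strand: str


@dataclass
class PlantedCRM:
    chrom: str
    start: int
    end: int
    crm_id: str
    sites: list[PlantedSite] = field(default_factory=list)

    def as_region(self) -> GenomicRegion:
        return GenomicRegion(self.chrom, self.start, self.end, region_id=self.crm_id)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.array(list("ACGT")), size=n, p=probs)


def _sample_site(rng: np.random.Generator, pfm: PFM, min_rel: float = 0.85) -> str:
    """Draw a site from the PFM column frequencies, redrawing until it
    scores at least ``min_rel`` relative under the generating PWM."""
    pwm = pfm_to_pwm(pfm)
    freqs = pfm.frequencies()
    bases = np.array(list("ACGT"))
    for _ in range(200):
        word = "".join(rng.choice(bases, p=freqs[:, j]) for j in range(pfm.length))
        score = sum(pwm.weights["ACGT".index(c), j] for j, c in enumerate(word))
        if pwm.rel_score(score) >= min_rel:
            return word
    return pfm.consensus()


def gen_genome(
    config: SimConfig, pfms: list[PFM] | None = None
) -> tuple[dict[str, str], list[PlantedCRM]]:
    """Background genome with planted CRMs.

    Each CRM is a ``crm_window`` bp span whose local GC is raised by
    ``crm_gc_shift`` and which carries ``motifs_per_crm`` non-overlapping
    planted sites (cycled over the motif set, random strand).  CRMs never
    overlap each other; chance motif hits in the background are left in
    place deliberately.
    """
    pfms = pfms if pfms is not None else muscle_motifs()
    rng = config.rng(1)
    L = config.genome_length
    seq = _random_bases(rng, L, config.background_gc)

    # place non-overlapping CRM windows
    win = config.crm_window
    if config.n_crm * win * 2 > L:
        raise ValueError("cannot place CRMs without overlap at this density")
    starts: list[int] = []
    for _ in range(config.n_crm):
        for _attempt in range(1000):
            s = int(rng.integers(0, L - win))
            if all(abs(s - t) >= win for t in starts):
                starts.append(s)
                break
        else:
            raise ValueError("cannot place CRMs without overlap")
    starts.sort()

    truth: list[PlantedCRM] = []
    for k, s in enumerate(starts):
        seq[s : s + win] = _random_bases(
            rng, win, min(1.0, config.background_gc + config.crm_gc_shift)
        )
        crm = PlantedCRM(SIM_CHROM, s, s + win, f"crm_{k}")
        offsets_used: list[tuple[int, int]] = []
        for m in range(config.motifs_per_crm):
            pfm = pfms[m % len(pfms)]
            site = _sample_site(rng, pfm)
            for _attempt in range(200):
                off = int(rng.integers(0, win - pfm.length))
                if all(off + pfm.length <= a or off >= b for a, b in offsets_used):
                    break
            else:
                continue
            offsets_used.append((off, off + pfm.length))
            strand = "+" if rng.random() < 0.5 else "-"
            placed = site if strand == "+" else reverse_complement(site)
            seq[s + off : s + off + pfm.length] = list(placed)
            crm.sites.append(PlantedSite(pfm.motif_id, s + off, s + off + pfm.length, strand))
        truth.append(crm)
    return {SIM_CHROM: "".join(seq)}, truth


def gen_conservation_track(
    truth: list[PlantedCRM], config: SimConfig
) -> tuple[ScoreTrack, ScoreTrack]:
    """Bounded [0,1] (phastCons-like) and unbounded (phyloP-like) tracks.

    Background is low-scoring; positions inside planted CRMs are lifted
    by ``conservation_elevation`` and planted site footprints by
    ``conservation_elevation * site_elevation``, so the site/non-site
    score ratio within CRMs is approximately ``site_elevation``.
    """
    rng = config.rng(2)
    L = config.genome_length
    lift = np.zeros(L)
    for crm in truth:
        lift[crm.start : crm.end] = config.conservation_elevation
        for s in crm.sites:
            lift[s.start : s.end] = config.conservation_elevation * config.site_elevation
    base = rng.beta(0.5, 4.5, size=L)  # mean ~0.1, phastCons-like background
    bounded = ScoreTrack(SIM_CHROM, 0, np.clip(base + lift, 0.0, 1.0), kind="bounded01")
    unbounded = ScoreTrack(SIM_CHROM, 0, rng.normal(0.0, 0.3, size=L) + lift, kind="unbounded")
    return bounded, unbounded


@dataclass
class InsertSpec:
    insert_id: str
    set_label: str = SetLabel.MUSCLE.value
    n_clones: int = 4
    positive: bool = False


def gen_plate_data(inserts: list[InsertSpec], config: SimConfig) -> pd.DataFrame:
    """Lognormal dual-luciferase plate readings for two phases.

    firefly = renilla x effect x lognormal noise, with effect =
    ``plate_effect_fold`` in myotubes for planted positives and 1
    otherwise.  With probability ``fail_rate`` a well fails transfection:
    both channels fall below the 1000 LRU QC floor.  Phase draws are
    independent (independent plasmid preparations).
    """
    rng = config.rng(3)
    cv = config.plate_cv
    rows = []
    for ins in inserts:
        for c in range(ins.n_clones):
            clone_id = f"{ins.insert_id}_c{c}"
            for phase, cell_types in ((1, ("fibroblast", "myoblast", "myotube")),
                                      (2, ("myoblast", "myotube"))):
                for ct in cell_types:
                    effect = config.plate_effect_fold if (ins.positive and ct == "myotube") else 1.0
                    for rep in (1, 2):
                        if rng.random() < config.fail_rate:
                            firefly = float(rng.uniform(0, 1000))
                            renilla = float(rng.uniform(0, 1000))
                        else:
                            renilla = float(rng.lognormal(np.log(5e4), cv))
                            firefly = float(renilla * effect * rng.lognormal(0.0, cv))
                        rows.append(
                            dict(
                                clone_id=clone_id,
                                insert_id=ins.insert_id,
                                set_label=ins.set_label,
                                phase=phase,
                                cell_type=ct,
                                tech_rep=rep,
                                firefly_lru=firefly,
                                renilla_lru=renilla,
                            )
                        )
    return pd.DataFrame(rows)


def _overlap_prob(region: GenomicRegion, probs: dict) -> float:
    if region.responder is not None:
        key = "responder" if region.responder else "non_responder"
        if key in probs:
            return probs[key]
    label = region.set_label.value if isinstance(region.set_label, SetLabel) else region.set_label
    if label in probs:
        return probs[label]
    return probs.get("default", 0.0)


def gen_peaks(regions: list[GenomicRegion], config: SimConfig, name: str = "sim_peaks") -> PeakSet:
    """Peaks overlapping each region with a label/responder-dependent
    probability; peaks extend past the region by random flanks."""
    rng = config.rng(4)
    peaks = PeakSet(name)
    for r in regions:
        if rng.random() < _overlap_prob(r, config.peak_overlap_probs):
            lo = max(0, r.start - int(rng.integers(10, 200)))
            hi = r.end + int(rng.integers(10, 200))
            # anchor inside the region so >= 1 bp always intersects
            peaks.add(r.chrom, lo, hi)
    return peaks
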
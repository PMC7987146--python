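"""Breed-structured cohort simulator with an embedded tandem duplication.

The generator emulates the observable structure the downstream analyses rely
on: breed-specific founder pools descended from one ancestral haplotype
(kinship confounding for the mixed model to correct), a single founder
lineage carrying a tandem duplication together with a distinctive marker
signature spanning it, dominant expression of the roan phenotype with
configurable penetrance and a crude masking probability standing in for
white-spotting epistasis, and the three CNV evidence channels: array
log-R-ratio elevation at in-duplication probes, read-depth elevation
proportional to copy number, and outward-facing junction read pairs.

Swept breeds carry the duplication haplotype at a forced frequency; each
carrier copy is the carrier founder over the duplication plus exponentially
distributed flanking extents, on top of an ordinary breed-background mosaic,
so the sweep signatures (low diversity, long shared haplotypes, runs of
homozygosity, extended haplotype homozygosity) decay away from the locus as
they do around a real sweep.

Everything is driven by a single integer seed; identical seeds give
bit-identical output regardless of which emit function is called first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, HaplotypeMatrix, Interval, MarkerMap

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "simulate_haplotypes",
    "assign_phenotypes",
    "emit_lrr",
    "emit_depth",
    "iter_depth_profiles",
    "emit_readpairs",
    "simulate_cohort",
    "simulate_structured_null",
]

# spawn-key stage tags; fixed so streams are independent of call order
_STAGE_HAP, _STAGE_PHENO, _STAGE_LRR, _STAGE_DEPTH, _STAGE_PAIRS = range(5)


class ConfigError(ValueError):
    pass


def _default_lrr_means() -> dict[int, float]:
    # chosen so het/hom carrier dLRR lands in the observed positive range
    # while the distributions overlap enough to make detection nontrivial
    return {2: 0.0, 3: 0.2, 4: 0.35}


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort."""

    n_breeds: int = 4
    n_per_breed: int = 50
    n_markers: int = 2000
    chrom: str = "chr38"
    chrom_length_bp: int = 20_000_000
    dup_interval: Interval = field(
        default_factory=lambda: Interval("chr38", 11_131_835, 11_143_237))
    dup_breed_freqs: tuple[float, ...] = (0.95, 0.4, 0.0, 0.0)
    swept: Optional[tuple[bool, ...]] = None  # default: freq >= 0.9
    penetrance: float = 0.99
    phenotype_masking_prob: float = 0.05
    tick_probs: tuple[float, float, float] = (0.75, 0.15, 0.10)
    founder_pool_size: int = 8
    mutation_density: float = 0.15  # founder vs ancestral flip probability
    new_mutation_rate: float = 0.001  # per-marker flips on sampled haplotypes
    recomb_rate_cm_per_mb: float = 1.0
    mosaic_generations: float = 100.0  # effective meioses behind each background mosaic
    sweep_decay_bp: float = 1_000_000.0  # mean extra extent of carrier segments
    min_carrier_extent_bp: int = 30_000
    core_margin_bp: int = 25_000  # new-mutation-free zone around the dup
    lrr_mean_by_cn: dict[int, float] = field(default_factory=_default_lrr_means)
    lrr_sd: float = 0.15
    depth_mean: float = 30.0
    insert_mean: float = 400.0
    insert_sd: float = 50.0
    carrier_founder: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.dup_breed_freqs) != self.n_breeds:
            raise ConfigError("dup_breed_freqs length must equal n_breeds")
        for p in (self.penetrance, self.phenotype_masking_prob,
                  *self.dup_breed_freqs):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if not (1 <= self.dup_interval.start_bp
                and self.dup_interval.end_bp <= self.chrom_length_bp):
            raise ConfigError("dup_interval outside simulated chromosome")
        if set(self.lrr_mean_by_cn) < {2, 3, 4}:
            raise ConfigError("lrr_mean_by_cn must define CN 2, 3 and 4")
        if any(f > 0 for f in self.dup_breed_freqs) and not self.carrier_founder:
            raise ConfigError(
                "carrier frequency requested but no founder carries the duplication")

    @property
    def core_interval(self) -> Interval:
        d = self.dup_interval
        return Interval(d.chrom, max(1, d.start_bp - self.core_margin_bp),
                        min(self.chrom_length_bp, d.end_bp + self.core_margin_bp))

    def is_swept(self) -> tuple[bool, ...]:
        if self.swept is not None:
            return self.swept
        return tuple(f >= 0.9 for f in self.dup_breed_freqs)

    def rng(self, stage: int, key: int = 0) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stage, key)))


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated cohort."""

    table: pd.DataFrame  # id, breed, carrier_haps, cn per individual
    hap_carrier: np.ndarray  # bool, one entry per haplotype row (2N)
    tag_marker_id: str  # marker carrying the carrier-founder-unique allele
    dup_interval: Interval
    core_interval: Interval
    swept_by_breed: dict[str, bool]

    def __post_init__(self) -> None:
        cn = self.table["cn"].to_numpy()
        if not np.array_equal(cn, 2 + self.table["carrier_haps"].to_numpy()):
            raise ValueError("CN must equal 2 + carrier haplotype count")

    @property
    def cn(self) -> np.ndarray:
        return self.table["cn"].to_numpy()

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()


def _marker_positions(cfg: SimConfig) -> np.ndarray:
    pos = ((np.arange(1, cfg.n_markers + 1)
            * (cfg.chrom_length_bp // (cfg.n_markers + 1)))).astype(np.int64)
    # pull the nearest marker onto the duplication midpoint so that at least
    # one array probe sits inside the duplicated segment
    mid = (cfg.dup_interval.start_bp + cfg.dup_interval.end_bp) // 2
    k = int(np.argmin(np.abs(pos - mid)))
    pos[k] = mid
    if np.any(np.diff(pos) <= 0):  # extremely dense maps: re-sort and dedupe
        pos = np.unique(pos)
    return pos


def simulate_haplotypes(cfg: SimConfig) -> tuple[MarkerMap, HaplotypeMatrix, SyntheticTruth]:
    """Draw the cohort's phased haplotypes and full ground truth."""
    rng = cfg.rng(_STAGE_HAP)
    pos = _marker_positions(cfg)
    m = len(pos)
    markers = MarkerMap(
        np.array([f"mk{j:05d}" for j in range(m)], dtype=object),
        np.full(m, cfg.chrom, dtype=object), pos,
        pos * cfg.recomb_rate_cm_per_mb / 1e6,
        np.full(m, "A", dtype=object), np.full(m, "C", dtype=object))
    dup = cfg.dup_interval
    mid = (dup.start_bp + dup.end_bp) // 2
    tag_idx = int(np.flatnonzero(pos == mid)[0])
    core = cfg.core_interval
    core_mask = (pos >= core.start_bp) & (pos <= core.end_bp)

    ancestral = (rng.random(m) < 0.5).astype(np.uint8)
    ancestral[tag_idx] = 0
    founders = np.empty((cfg.n_breeds, cfg.founder_pool_size, m), dtype=np.uint8)
    for b in range(cfg.n_breeds):
        flips = rng.random((cfg.founder_pool_size, m)) < cfg.mutation_density
        founders[b] = ancestral ^ flips
        founders[b, :, tag_idx] = 0  # tag allele is private to the carrier lineage
    carrier_founder = ancestral ^ (rng.random(m) < cfg.mutation_density)
    carrier_founder[tag_idx] = 1

    n = cfg.n_breeds * cfg.n_per_breed
    morgans = (cfg.chrom_length_bp / 1e6 * cfg.recomb_rate_cm_per_mb / 100.0
               * cfg.mosaic_generations)
    swept = cfg.is_swept()
    allele = np.empty((2 * n, m), dtype=np.uint8)
    hap_carrier = np.zeros(2 * n, dtype=bool)
    ids, breeds = [], []

    for b in range(cfg.n_breeds):
        nb = cfg.n_per_breed
        nhap = 2 * nb
        f = cfg.dup_breed_freqs[b]
        if swept[b] and f > 0:
            k = int(round(f * nhap))
            carrier_flags = np.zeros(nhap, dtype=bool)
            carrier_flags[rng.permutation(nhap)[:k]] = True
        else:
            carrier_flags = rng.random(nhap) < f
        for j in range(nhap):
            # breed-background mosaic of founders with Poisson crossovers
            ncx = rng.poisson(morgans)
            cuts = np.sort(rng.integers(1, cfg.chrom_length_bp, size=ncx))
            bounds = np.concatenate(([0], np.searchsorted(pos, cuts, side="right"), [m]))
            hap = np.empty(m, dtype=np.uint8)
            for s in range(len(bounds) - 1):
                lo, hi = bounds[s], bounds[s + 1]
                if lo < hi:
                    hap[lo:hi] = founders[b, rng.integers(cfg.founder_pool_size), lo:hi]
            if carrier_flags[j]:
                ext_l = cfg.min_carrier_extent_bp + rng.exponential(cfg.sweep_decay_bp)
                ext_r = cfg.min_carrier_extent_bp + rng.exponential(cfg.sweep_decay_bp)
                seg = (pos >= dup.start_bp - ext_l) & (pos <= dup.end_bp + ext_r)
                hap[seg] = carrier_founder[seg]
            # sparse new mutations, never inside the core zone
            muts = (rng.random(m) < cfg.new_mutation_rate) & ~core_mask
            hap ^= muts.astype(np.uint8)
            allele[2 * b * nb + j] = hap
        hap_carrier[2 * b * nb: 2 * b * nb + nhap] = carrier_flags
        ids.extend(f"dog_{b * nb + i:04d}" for i in range(nb))
        breeds.extend([f"breed_{b}"] * nb)

    carrier_haps = hap_carrier[0::2].astype(int) + hap_carrier[1::2].astype(int)
    truth = SyntheticTruth(
        table=pd.DataFrame({"id": ids, "breed": breeds,
                            "carrier_haps": carrier_haps,
                            "cn": 2 + carrier_haps}),
        hap_carrier=hap_carrier,
        tag_marker_id=str(markers.marker_id[tag_idx]),
        dup_interval=dup, core_interval=core,
        swept_by_breed={f"breed_{b}": bool(swept[b] and cfg.dup_breed_freqs[b] > 0)
                        for b in range(cfg.n_breeds)})
    haps = HaplotypeMatrix(ids, markers, allele)
    return markers, haps, truth


def assign_phenotypes(truth: SyntheticTruth, cfg: SimConfig) -> pd.DataFrame:
    """Dominant roan phenotype with penetrance and epistatic masking.

    P(case | CN>=3) = penetrance * (1 - masking); P(case | CN=2) = 0.  Tick
    scores are drawn independently for non-roan individuals and carry no
    genetic signal; roan cases are never scored for ticking.
    """
    rng = cfg.rng(_STAGE_PHENO)
    cn = truth.cn
    n = len(cn)
    expressed = (cn >= 3) & (rng.random(n) < cfg.penetrance)
    masked = rng.random(n) < cfg.phenotype_masking_prob
    roan_observed = expressed & ~masked
    truth.table["true_roan"] = expressed
    tick = rng.choice([0, 1, 2], size=n, p=np.asarray(cfg.tick_probs))
    pheno = pd.DataFrame({
        "id": truth.ids,
        "roan": np.where(roan_observed, "case", "control"),
        "tick": np.where(roan_observed, np.nan, tick.astype(float)),
        "breed": truth.table["breed"],
        "panel": "discovery",
    })
    return pheno


def emit_lrr(truth: SyntheticTruth, markers: MarkerMap, cfg: SimConfig) -> pd.DataFrame:
    """individuals × markers log-R-ratio table (Gaussian noise model)."""
    rng = cfg.rng(_STAGE_LRR)
    n, m = len(truth.ids), len(markers)
    lrr = rng.normal(cfg.lrr_mean_by_cn[2], cfg.lrr_sd, size=(n, m))
    inside = truth.dup_interval
    in_dup = (markers.chrom == inside.chrom) & \
             (markers.pos_bp >= inside.start_bp) & (markers.pos_bp <= inside.end_bp)
    shift = np.array([cfg.lrr_mean_by_cn[c] - cfg.lrr_mean_by_cn[2]
                      for c in truth.cn])
    lrr[:, in_dup] += shift[:, None]
    return pd.DataFrame(lrr, index=pd.Index(truth.ids, name="id"),
                        columns=markers.marker_id)


def _depth_region(truth: SyntheticTruth, cfg: SimConfig,
                  region: Optional[Interval]) -> Interval:
    if region is not None:
        return region
    d = truth.dup_interval
    return Interval(d.chrom, max(1, d.start_bp - 150_000),
                    min(cfg.chrom_length_bp, d.end_bp + 150_000))


def iter_depth_profiles(truth: SyntheticTruth, cfg: SimConfig,
                        ids: Optional[Sequence[str]] = None,
                        region: Optional[Interval] = None,
                        ) -> Iterator[tuple[str, pd.DataFrame]]:
    """Yield per-individual per-site depth tables (Poisson read-depth model).

    Depth is Poisson(depth_mean * CN/2) at sites inside the duplication and
    Poisson(depth_mean) elsewhere.  Per-individual streams are seeded by
    individual index, so any subset of ids reproduces bit-identically.
    """
    reg = _depth_region(truth, cfg, region)
    pos = np.arange(reg.start_bp, reg.end_bp + 1, dtype=np.int64)
    dup = truth.dup_interval
    in_dup = (pos >= dup.start_bp) & (pos <= dup.end_bp)
    index = {ind: i for i, ind in enumerate(truth.ids)}
    for ind in (ids if ids is not None else truth.ids):
        i = index[ind]
        rng = cfg.rng(_STAGE_DEPTH, i)
        lam = np.full(pos.shape, cfg.depth_mean)
        lam[in_dup] = cfg.depth_mean * truth.cn[i] / 2.0
        dp = rng.poisson(lam)
        yield ind, pd.DataFrame({"id": ind, "chrom": reg.chrom, "pos": pos,
                                 "dp": dp.astype(float)})


def emit_depth(truth: SyntheticTruth, cfg: SimConfig,
               ids: Optional[Sequence[str]] = None,
               region: Optional[Interval] = None) -> pd.DataFrame:
    """Materialized depth table for a (small) set of individuals."""
    return pd.concat([df for _, df in iter_depth_profiles(truth, cfg, ids, region)],
                     ignore_index=True)


def emit_readpairs(truth: SyntheticTruth, cfg: SimConfig,
                   ids: Optional[Sequence[str]] = None,
                   region: Optional[Interval] = None) -> pd.DataFrame:
    """Read-pair records: proper background pairs plus, for each carrier
    copy, outward-facing junction-spanning pairs bracketing the breakpoints.

    The ``kind`` column carries the simulator truth label.
    """
    reg = _depth_region(truth, cfg, region)
    dup = truth.dup_interval
    index = {ind: i for i, ind in enumerate(truth.ids)}
    frames = []
    for ind in (ids if ids is not None else truth.ids):
        i = index[ind]
        rng = cfg.rng(_STAGE_PAIRS, i)
        n_bg = rng.poisson(reg.length_bp * cfg.depth_mean / (2.0 * cfg.insert_mean))
        p1 = rng.integers(reg.start_bp, reg.end_bp + 1, size=n_bg)
        ins = np.maximum(50, rng.normal(cfg.insert_mean, cfg.insert_sd, n_bg)).astype(int)
        p2 = p1 + ins
        bg = pd.DataFrame({"id": ind, "chrom": reg.chrom, "pos1": p1,
                           "strand1": "+", "pos2": p2, "strand2": "-",
                           "kind": "proper"})
        frames.append(bg)
        n_copies = truth.cn[i] - 2
        if n_copies > 0:
            n_j = rng.poisson(cfg.depth_mean / 2.0 * n_copies)
            off1 = rng.integers(0, int(cfg.insert_mean / 2), size=n_j)
            off2 = rng.integers(0, int(cfg.insert_mean / 2), size=n_j)
            frames.append(pd.DataFrame({
                "id": ind, "chrom": dup.chrom,
                "pos1": dup.start_bp + off1, "strand1": "-",
                "pos2": dup.end_bp - off2, "strand2": "+",
                "kind": "junction"}))
    return pd.concat(frames, ignore_index=True)


@dataclass
class SyntheticCohort:
    cfg: SimConfig
    markers: MarkerMap
    haplotypes: HaplotypeMatrix
    genotypes: GenotypeMatrix
    truth: SyntheticTruth
    phenotypes: pd.DataFrame


def simulate_cohort(cfg: SimConfig) -> SyntheticCohort:
    """One-call cohort: haplotypes, collapsed genotypes and phenotypes."""
    markers, haps, truth = simulate_haplotypes(cfg)
    pheno = assign_phenotypes(truth, cfg)
    return SyntheticCohort(cfg, markers, haps, haps.collapse(), truth, pheno)


def simulate_copy_ratios(cn: int, n_replicates: int = 20, seed: int = 0,
                         depth_mean: float = 30.0,
                         dup: Optional[Interval] = None,
                         flank_bp: int = 100_000) -> np.ndarray:
    """Inside/flank depth ratios for replicate Poisson depth simulations.

    Per replicate, per-site depth is Poisson(depth_mean * cn/2) inside the
    duplicated interval and Poisson(depth_mean) in the two flanks; the
    returned value is the mean inside depth over the mean flank depth,
    computed by :func:`roanmap.cnv_evidence.copy_ratio`.
    """
    from .cnv_evidence import copy_ratio

    dup = dup or Interval("chr38", 11_131_835, 11_143_237)
    region = Interval(dup.chrom, dup.start_bp - flank_bp, dup.end_bp + flank_bp)
    pos = np.arange(region.start_bp, region.end_bp + 1, dtype=np.int64)
    inside = (pos >= dup.start_bp) & (pos <= dup.end_bp)
    lam = np.where(inside, depth_mean * cn / 2.0, depth_mean)
    out = np.empty(n_replicates)
    for rep in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence(seed,
                                                           spawn_key=(4, cn, rep)))
        dp = rng.poisson(lam).astype(float)
        df = pd.DataFrame({"id": f"rep{rep}", "chrom": dup.chrom,
                           "pos": pos, "dp": dp})
        out[rep] = copy_ratio(df, dup, flank_bp=flank_bp)
    return out


def simulate_structured_null(n_breeds: int = 5, n_per_breed: int = 100,
                             n_markers: int = 5000, fst: float = 0.1,
                             prevalences: Optional[Sequence[float]] = None,
                             seed: int = 0,
                             ) -> tuple[GenotypeMatrix, np.ndarray]:
    """Balding–Nichols structured cohort with no causal marker.

    Markers are independent given breed (breed allele frequencies drawn from
    a Beta centred on a shared ancestral frequency with drift parameter
    ``fst``), so per-marker association tests are independent and binomial
    bounds on the p < alpha fraction apply.  Case status may differ in
    prevalence across breeds to create the confounding the mixed model must
    absorb.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    if prevalences is None:
        prevalences = np.linspace(0.35, 0.65, n_breeds)
    p_anc = rng.uniform(0.1, 0.9, size=n_markers)
    a = p_anc * (1 - fst) / fst
    b = (1 - p_anc) * (1 - fst) / fst
    dosage = np.empty((n_breeds * n_per_breed, n_markers), dtype=np.int8)
    y = np.empty(n_breeds * n_per_breed)
    for br in range(n_breeds):
        pb = rng.beta(a, b)
        rows = slice(br * n_per_breed, (br + 1) * n_per_breed)
        dosage[rows] = rng.binomial(2, pb, size=(n_per_breed, n_markers))
        y[rows] = (rng.random(n_per_breed) < prevalences[br]).astype(float)
    pos = np.arange(1, n_markers + 1) * 1000
    markers = MarkerMap(np.array([f"nm{j:05d}" for j in range(n_markers)], dtype=object),
                        np.full(n_markers, "chr1", dtype=object), pos)
    ids = [f"ind_{i:04d}" for i in range(n_breeds * n_per_breed)]
    return GenotypeMatrix(ids, markers, dosage), y
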
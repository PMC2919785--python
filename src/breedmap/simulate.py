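"""Synthetic breed-formation simulator.

Generates genotype, haplotype and phenotype data whose statistical structure
mirrors a purebred-dog mapping cohort: many small breeds founded from a
shared ancestral gene pool, strong founder drift (mean per-SNP F_ST near
0.28), long within-breed linkage disequilibrium but rapid decay of LD
between breeds, extensive within-breed autozygosity, a handful of
large-effect QTLs per trait, and an outbred "village" population drawn
straight from the ancestral pool.

Two genotype-generating paths are provided:

* :func:`sample_genotypes_hwe` — Hardy-Weinberg draws from the per-breed
  allele frequencies of the Balding-Nichols drift model.  Allele frequencies
  are the only structure; there is no LD.  This is the calibration path for
  differentiation statistics: the Balding-Nichols ``F`` equals the Weir &
  Cockerham estimand.
* :func:`simulate_haplotypes` — a founder-bottleneck mechanism: per-breed
  founder haplotypes are drawn at the drifted breed frequencies with
  short-range along-chromosome correlation, then propagated through a few
  generations of random mating with crossovers.  This produces phased data
  with realistic LD contrasts and emergent runs of homozygosity.

Every stage draws from a substream derived deterministically from
``SimConfig.seed``, so a fixed seed reproduces the full cohort exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, HaplotypePanel, MarkerMap, PhenotypeTable

__all__ = [
    "QTL",
    "SimConfig",
    "SyntheticTruth",
    "PlantedSegment",
    "build_marker_map",
    "simulate_breed_frequencies",
    "sample_genotypes_hwe",
    "simulate_haplotypes",
    "simulate_phenotypes",
    "noise_sd_for_heritability",
    "plant_autozygosity",
    "simulate_cohort",
]


@dataclass(frozen=True)
class QTL:
    """A planted additive quantitative trait locus.

    ``sweep_fraction``, when set, models diversifying selection at the
    locus: that fraction of breeds (rounded, at least one) is swept toward
    high trait-allele frequency (drawn around 0.9) while the rest sit near
    0.05 — the bimodal across-breed pattern of the large-effect loci that
    distinguish breeds (alternately near-fixed in different breed groups).
    Without it the locus drifts like any neutral marker.
    """

    marker_index: int
    effect_size: float  # trait units per counted allele
    trait_name: str
    dichotomizing_threshold: float | None = None
    sweep_fraction: float | None = None


@dataclass(frozen=True)
class SimConfig:
    """Study-design knobs of the simulator.

    Defaults describe the emulated cohort: 50 breeds of 10 dogs genotyped at
    5,000 markers over five 50-Mb chromosomes.  The total between-breed
    differentiation decomposes as Balding-Nichols frequency drift
    (``breed_F``) plus founder-sampling drift (8 founder haplotypes per
    breed) plus a little Wright-Fisher drift over 5 generations at
    propagation size 50; the defaults put the expected mean per-SNP F_ST
    near 0.28.  ``clade_F > 0`` nests breeds inside related groups
    ("clades"), giving breed frequencies a shared-ancestry correlation like
    real breed families.
    """

    n_breeds: int = 50
    dogs_per_breed: int = 10
    n_markers: int = 5000
    n_chromosomes: int = 5
    chrom_length_bp: int = 50_000_000
    ancestral_maf_dist: tuple = (0.05, 0.95)  # Uniform(low, high) ancestral freq
    breed_F: float = 0.13
    clade_F: float = 0.0
    n_clades: int = 1
    founder_haplotypes_per_breed: int = 8
    generations: int = 5
    propagation_size: int = 50  # diploids kept during random mating
    recomb_rate_cM_per_Mb: float = 1.0
    hap_corr_length_bp: float = 100_000.0  # ancestral-pool LD scale
    village_dogs: int = 0
    village_label: str = "village"
    qtls: tuple = ()
    sweep_hitch_bp: float = 300_000.0  # hitchhiking scale around swept QTLs
    trait_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.breed_F < 1.0):
            raise ValueError("breed_F must lie in [0, 1)")
        if not (0.0 <= self.clade_F < 1.0):
            raise ValueError("clade_F must lie in [0, 1)")
        if self.founder_haplotypes_per_breed < 2:
            raise ValueError("founder_haplotypes_per_breed must be >= 2")
        if self.trait_noise_sd < 0:
            raise ValueError("trait_noise_sd must be non-negative")
        lo, hi = self.ancestral_maf_dist
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral_maf_dist bounds must satisfy 0 < lo <= hi < 1")

    @property
    def breed_names(self) -> list:
        return [f"breed{i:02d}" for i in range(self.n_breeds)]

    def rng(self, stage: int) -> np.random.Generator:
        """Deterministic substream for a pipeline stage."""
        return np.random.default_rng([int(self.seed) % (2**31), stage])


@dataclass(frozen=True)
class PlantedSegment:
    individual_id: str
    chromosome: str
    start_bp: int
    end_bp: int


@dataclass
class SyntheticTruth:
    """Ground truth the simulator guarantees, for downstream tests."""

    ancestral_freqs: np.ndarray
    breed_allele_freqs: np.ndarray  # breeds x markers
    clade_of_breed: np.ndarray
    qtls: tuple = ()
    true_breed_means: pd.DataFrame | None = None
    planted_segments: list = field(default_factory=list)

    def __post_init__(self) -> None:
        f = self.breed_allele_freqs
        if np.any((f < 0) | (f > 1)):
            raise ValueError("breed allele frequencies outside [0, 1]")


def build_marker_map(config: SimConfig) -> MarkerMap:
    """Evenly spaced markers across ``n_chromosomes`` autosomes."""
    per_chrom = np.full(config.n_chromosomes, config.n_markers // config.n_chromosomes)
    per_chrom[: config.n_markers % config.n_chromosomes] += 1
    chroms, ids, pos = [], [], []
    k = 0
    for c, m_c in enumerate(per_chrom, start=1):
        spacing = config.chrom_length_bp / (m_c + 1)
        p = np.round((np.arange(1, m_c + 1)) * spacing).astype(np.int64)
        p = np.maximum.accumulate(p + np.arange(m_c) * 0)  # already increasing
        chroms += [f"chr{c}"] * m_c
        pos += list(p)
        ids += [f"snp{k + j}" for j in range(m_c)]
        k += m_c
    return MarkerMap(
        marker_id=np.array(ids, dtype=object),
        chromosome=np.array(chroms, dtype=object),
        position_bp=np.array(pos, dtype=np.int64),
    )


def _balding_nichols(rng, p: np.ndarray, F: float) -> np.ndarray:
    """Draw drifted frequencies around ancestral ``p`` with coefficient F.

    Alleles already fixed (p = 0 or 1) stay fixed; the Beta draw applies to
    segregating sites only.
    """
    if F == 0.0:
        return p.copy()
    p = np.asarray(p, dtype=float)
    out = p.copy()
    seg = (p > 0.0) & (p < 1.0)
    a = p[seg] * (1.0 - F) / F
    b = (1.0 - p[seg]) * (1.0 - F) / F
    out[seg] = rng.beta(a, b)
    return out


def simulate_breed_frequencies(config: SimConfig) -> SyntheticTruth:
    """Balding-Nichols per-breed allele frequencies.

    Ancestral frequencies are Uniform over ``ancestral_maf_dist`` (the array
    targets common variants).  With ``n_clades > 1`` drift happens in two
    tiers — ancestral -> clade (``clade_F``) -> breed (``breed_F``) — so
    breeds within a clade share correlated drift; total differentiation is
    then ``1 - (1-clade_F)(1-breed_F)``.
    """
    rng = config.rng(stage=1)
    lo, hi = config.ancestral_maf_dist
    p = rng.uniform(lo, hi, size=config.n_markers)
    clade_of_breed = np.arange(config.n_breeds) % max(config.n_clades, 1)
    if config.n_clades > 1 and config.clade_F > 0:
        clade_freqs = np.stack(
            [_balding_nichols(rng, p, config.clade_F) for _ in range(config.n_clades)]
        )
    else:
        clade_freqs = np.stack([p] * max(config.n_clades, 1))
    breed_freqs = np.stack(
        [
            _balding_nichols(rng, clade_freqs[clade_of_breed[b]], config.breed_F)
            for b in range(config.n_breeds)
        ]
    )
    marker_map = build_marker_map(config)
    for q in config.qtls:
        if q.sweep_fraction is None:
            continue
        n_high = max(1, round(q.sweep_fraction * config.n_breeds))
        high = rng.choice(config.n_breeds, size=n_high, replace=False)
        col = rng.beta(1.0, 49.0, size=config.n_breeds)  # near-absent background
        col[high] = rng.beta(38.0, 2.0, size=n_high)  # swept breeds near fixation
        breed_freqs[:, q.marker_index] = col
        p[q.marker_index] = col.mean()
        if config.sweep_hitch_bp > 0:
            # hitchhiking: the swept haplotype drags its alleles at nearby
            # markers, shifting their frequencies in the swept breeds only
            chrom = marker_map.chromosome[q.marker_index]
            qpos = marker_map.position_bp[q.marker_index]
            d = np.abs(marker_map.position_bp - qpos).astype(float)
            near = (marker_map.chromosome == chrom) & (d <= 4 * config.sweep_hitch_bp)
            near[q.marker_index] = False
            # Hitchhiking: the swept haplotype carries the "1" allele at
            # nearby markers (allele labels are arbitrary; this phase
            # matches the positive short-range allele association of the
            # ancestral pool).  Low-frequency neighbors become the high-
            # differentiation tags seen flanking selected loci.
            for m in np.flatnonzero(near):
                w = np.exp(-d[m] / config.sweep_hitch_bp)
                breed_freqs[high, m] = (1 - w) * breed_freqs[high, m] + w
    return SyntheticTruth(
        ancestral_freqs=p,
        breed_allele_freqs=np.clip(breed_freqs, 0.0, 1.0),
        clade_of_breed=clade_of_breed,
        qtls=tuple(config.qtls),
    )


def sample_genotypes_hwe(
    config: SimConfig, truth: SyntheticTruth, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Hardy-Weinberg genotype draws from the per-breed frequencies (no LD)."""
    if rng is None:
        rng = config.rng(stage=2)
    marker_map = build_marker_map(config)
    n = config.n_breeds * config.dogs_per_breed
    freqs = np.repeat(truth.breed_allele_freqs, config.dogs_per_breed, axis=0)
    genotypes = rng.binomial(2, freqs, size=(n, config.n_markers)).astype(np.int8)
    breed_labels = np.repeat(np.array(config.breed_names, dtype=object), config.dogs_per_breed)
    ids = np.array(
        [f"{b}_d{i % config.dogs_per_breed}" for i, b in enumerate(breed_labels)],
        dtype=object,
    )
    return GenotypeMatrix(
        genotypes=genotypes, individual_ids=ids, breed_labels=breed_labels, map=marker_map
    )


# ---------------------------------------------------------------------------
# Founder-bottleneck haplotype simulation
# ---------------------------------------------------------------------------

def _correlated_haplotypes(
    rng, freqs: np.ndarray, n_haps: int, marker_map: MarkerMap, corr_length_bp: float
) -> np.ndarray:
    """Haplotypes with first-order along-chromosome allele correlation.

    A latent uniform per haplotype is resampled at each marker with
    probability 1 - exp(-d / L); the allele is the indicator
    latent < freq.  Adjacent-marker allele correlation is ~exp(-d/L) when
    frequencies vary slowly, decaying geometrically with distance.
    """
    m = len(marker_map)
    haps = np.empty((n_haps, m), dtype=np.int8)
    for chrom, sl in marker_map.chrom_slices().items():
        pos = marker_map.position_bp[sl]
        f = freqs[sl]
        gaps = np.diff(pos).astype(float)
        keep_p = np.exp(-gaps / corr_length_bp)
        u = rng.uniform(size=n_haps)
        haps[:, sl.start] = u < f[0]
        for j in range(1, len(pos)):
            resample = rng.uniform(size=n_haps) >= keep_p[j - 1]
            if resample.any():
                u = np.where(resample, rng.uniform(size=n_haps), u)
            haps[:, sl.start + j] = u < f[j]
    return haps


def _recombine(rng, parents: np.ndarray, pairs: np.ndarray, marker_map, morgans_per_bp):
    """One gamete per pair of parent haplotypes, with Poisson crossovers."""
    n_children = pairs.shape[0]
    m = parents.shape[1]
    out = np.empty((n_children, m), dtype=np.int8)
    for chrom, sl in marker_map.chrom_slices().items():
        pos = marker_map.position_bp[sl]
        length_bp = float(pos[-1] - pos[0]) if len(pos) > 1 else 0.0
        lam = length_bp * morgans_per_bp
        n_cross = rng.poisson(lam, size=n_children)
        use_a = np.empty((n_children, len(pos)), dtype=bool)
        start_a = rng.uniform(size=n_children) < 0.5
        for i in range(n_children):
            if n_cross[i] == 0:
                use_a[i] = start_a[i]
                continue
            breaks = np.sort(rng.uniform(pos[0], pos[-1], size=n_cross[i]))
            seg = np.searchsorted(breaks, pos, side="right")
            use_a[i] = (seg % 2 == 0) == start_a[i]
        a = parents[pairs[:, 0]][:, sl]
        b = parents[pairs[:, 1]][:, sl]
        out[:, sl] = np.where(use_a, a, b)
    return out


def simulate_haplotypes(
    config: SimConfig, truth: SyntheticTruth
) -> tuple[HaplotypePanel, GenotypeMatrix]:
    """Breed formation: founder bottleneck then random mating with crossovers.

    Each breed starts from ``founder_haplotypes_per_breed`` haplotypes drawn
    at the breed's drifted frequencies (with ancestral-pool short-range
    correlation), then ``generations`` rounds of random mating at
    ``propagation_size`` diploids; ``dogs_per_breed`` dogs are sampled from
    the final generation.  ``village_dogs`` individuals (if requested) are
    paired haplotypes drawn directly at the ancestral frequencies — no
    bottleneck, hence short LD and few long homozygous runs.
    """
    rng = config.rng(stage=3)
    marker_map = build_marker_map(config)
    morgans_per_bp = config.recomb_rate_cM_per_Mb * 1e-8

    all_haps, ids, breeds = [], [], []
    for b, bname in enumerate(config.breed_names):
        founders = _correlated_haplotypes(
            rng,
            truth.breed_allele_freqs[b],
            config.founder_haplotypes_per_breed,
            marker_map,
            config.hap_corr_length_bp,
        )
        pool = founders
        n_out = 2 * config.propagation_size
        for _ in range(config.generations):
            pairs = np.empty((n_out, 2), dtype=np.int64)
            pairs[:, 0] = rng.integers(0, pool.shape[0], size=n_out)
            # distinct second parent haplotype
            offset = rng.integers(1, pool.shape[0], size=n_out)
            pairs[:, 1] = (pairs[:, 0] + offset) % pool.shape[0]
            pool = _recombine(rng, pool, pairs, marker_map, morgans_per_bp)
        chosen = rng.choice(pool.shape[0] // 2, size=config.dogs_per_breed, replace=False)
        for d, ind in enumerate(chosen):
            all_haps.append(pool[2 * ind])
            all_haps.append(pool[2 * ind + 1])
            ids.append(f"{bname}_d{d}")
            breeds.append(bname)

    if config.village_dogs > 0:
        vh = _correlated_haplotypes(
            rng,
            truth.ancestral_freqs,
            2 * config.village_dogs,
            marker_map,
            config.hap_corr_length_bp,
        )
        for d in range(config.village_dogs):
            all_haps.append(vh[2 * d])
            all_haps.append(vh[2 * d + 1])
            ids.append(f"{config.village_label}_d{d}")
            breeds.append(config.village_label)

    panel = HaplotypePanel(
        haplotypes=np.array(all_haps, dtype=np.int8),
        individual_ids=np.array(ids, dtype=object),
        breed_labels=np.array(breeds, dtype=object),
        map=marker_map,
    )
    return panel, panel.to_genotypes()


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    config: SimConfig, genotypes: GenotypeMatrix, truth: SyntheticTruth
) -> PhenotypeTable:
    """Additive phenotypes from the planted QTLs plus Gaussian noise.

    Binary traits (QTLs carrying ``dichotomizing_threshold``) are produced
    by thresholding the noisy liability.  All individuals get age 5 years
    (adults), so downstream age filters keep them.
    """
    rng = config.rng(stage=4)
    qtls = truth.qtls or tuple(config.qtls)
    for q in qtls:
        if not (0 <= q.marker_index < genotypes.n_markers):
            raise ValueError(f"QTL marker index {q.marker_index} out of range")
    traits: dict[str, list] = {}
    for q in qtls:
        traits.setdefault(q.trait_name, []).append(q)

    rows = []
    g = np.where(genotypes.genotypes == MISSING, 0, genotypes.genotypes).astype(float)
    breed_means = {}
    for trait, trait_qtls in traits.items():
        value = np.zeros(genotypes.n_individuals)
        for q in trait_qtls:
            value += q.effect_size * g[:, q.marker_index]
        genetic = value.copy()
        value = value + rng.normal(0.0, config.trait_noise_sd, size=len(value))
        thresh = trait_qtls[0].dichotomizing_threshold
        if thresh is not None:
            value = (value > thresh).astype(float)
        for i in range(genotypes.n_individuals):
            rows.append(
                (
                    genotypes.individual_ids[i],
                    genotypes.breed_labels[i],
                    trait,
                    value[i],
                    5.0,
                )
            )
        means = pd.Series(genetic).groupby(genotypes.breed_labels).mean()
        breed_means[trait] = means

    truth.true_breed_means = pd.DataFrame(breed_means)
    table = pd.DataFrame(
        rows, columns=["individual_id", "breed", "trait", "value", "age_years"]
    )
    return PhenotypeTable(table)


def noise_sd_for_heritability(
    qtls, genotypes: GenotypeMatrix, heritability: float
) -> float:
    """Noise sd making the planted QTLs explain ``heritability`` of variance.

    Uses the realized variance of the additive genetic score in the cohort,
    so the target is a cohort-level (between- plus within-breed) h^2.
    """
    if not (0 < heritability <= 1):
        raise ValueError("heritability must lie in (0, 1]")
    g = np.where(genotypes.genotypes == MISSING, 0, genotypes.genotypes).astype(float)
    score = np.zeros(genotypes.n_individuals)
    for q in qtls:
        score += q.effect_size * g[:, q.marker_index]
    vg = float(np.var(score))
    if heritability == 1.0:
        return 0.0
    return float(np.sqrt(vg * (1.0 - heritability) / heritability))


# ---------------------------------------------------------------------------
# Planted autozygosity
# ---------------------------------------------------------------------------

def plant_autozygosity(
    genotypes: GenotypeMatrix,
    segments,
    error_rate: float,
    seed: int = 0,
) -> GenotypeMatrix:
    """Force homozygosity inside planted segments, then sprinkle errors.

    Within each segment one allele of every heterozygous genotype is
    duplicated (choosing the copied allele at random), then each marker in
    the segment is flipped to heterozygous with probability ``error_rate``
    (emulating genotyping error).  Segments must not overlap within an
    individual.
    """
    if error_rate < 0 or error_rate > 1:
        raise ValueError("error_rate must lie in [0, 1]")
    segs = [
        s if isinstance(s, PlantedSegment) else PlantedSegment(*s) for s in segments
    ]
    by_ind: dict[str, list] = {}
    for s in segs:
        by_ind.setdefault((s.individual_id, s.chromosome), []).append(s)
    for (ind, chrom), ss in by_ind.items():
        ss = sorted(ss, key=lambda s: s.start_bp)
        for a, b in zip(ss, ss[1:]):
            if b.start_bp <= a.end_bp:
                raise ValueError(
                    f"overlapping planted segments for {ind} on {chrom}"
                )
    rng = np.random.default_rng([int(seed) % (2**31), 9])
    g = genotypes.genotypes.copy()
    chrom_sl = genotypes.map.chrom_slices()
    for s in segs:
        if s.chromosome not in chrom_sl:
            raise ValueError(f"unknown chromosome {s.chromosome!r}")
        sl = chrom_sl[s.chromosome]
        pos = genotypes.map.position_bp[sl]
        if s.start_bp < 1 or s.end_bp > pos[-1] + 1 or s.end_bp <= s.start_bp:
            raise ValueError(f"segment out of bounds: {s}")
        i = genotypes.index_of(s.individual_id)
        cols = sl.start + np.flatnonzero((pos >= s.start_bp) & (pos <= s.end_bp))
        row = g[i, cols]
        het = row == 1
        if het.any():
            copied = rng.integers(0, 2, size=int(het.sum())) * 2
            row[het] = copied.astype(np.int8)
        if error_rate > 0:
            flip = (rng.uniform(size=len(cols)) < error_rate) & (row != MISSING)
            row[flip] = 1
        g[i, cols] = row
    return GenotypeMatrix(
        genotypes=g,
        individual_ids=genotypes.individual_ids,
        breed_labels=genotypes.breed_labels,
        map=genotypes.map,
        sex=genotypes.sex,
        allele_names=genotypes.allele_names,
    )


# ---------------------------------------------------------------------------
# Convenience
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    config: SimConfig
    truth: SyntheticTruth
    panel: HaplotypePanel
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable | None = None


def simulate_cohort(config: SimConfig) -> SimResult:
    """Run frequency, haplotype and phenotype stages in order."""
    truth = simulate_breed_frequencies(config)
    panel, genotypes = simulate_haplotypes(config, truth)
    phenotypes = None
    if config.qtls:
        phenotypes = simulate_phenotypes(config, genotypes, truth)
    return SimResult(config, truth, panel, genotypes, phenotypes)


def three_qtl_config(seed: int, trait: str = "size", **overrides) -> SimConfig:
    """The default large-effect architecture: three swept QTLs, effects 4:2:1.

    The strongest locus is near-fixed in a couple of breeds, the weakest in
    about a quarter of them, spreading the realized variance shares so every
    locus carries appreciable breed-level signal — the few-QTLs-of-large-
    effect architecture typical of morphological traits in purebred dogs.
    """
    qtls = (
        QTL(500, 4.0, trait, sweep_fraction=0.04),
        QTL(2500, 2.0, trait, sweep_fraction=0.10),
        QTL(4500, 1.0, trait, sweep_fraction=0.28),
    )
    return SimConfig(seed=seed, qtls=qtls, **overrides)


def simulate_qtl_study(
    seed: int, heritability: float = 0.9, trait: str = "size", **overrides
) -> SimResult:
    """Simulate the default three-QTL cohort at a target heritability.

    The trait noise sd is set from the realized genetic variance so the
    planted QTLs explain ``heritability`` of the cohort-level phenotypic
    variance.
    """
    config = three_qtl_config(seed, trait=trait, **overrides)
    truth = simulate_breed_frequencies(config)
    panel, genotypes = simulate_haplotypes(config, truth)
    sd = noise_sd_for_heritability(config.qtls, genotypes, heritability)
    config = replace(config, trait_noise_sd=sd)
    phenotypes = simulate_phenotypes(config, genotypes, truth)
    return SimResult(config, truth, panel, genotypes, phenotypes)
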
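"""Diversity and differentiation statistics.

Four statistics summarize the breed-structured cohort:

* LD decay — mean squared genotype correlation (r^2) between marker pairs,
  binned by physical distance, within a sampled subset of a population.
* Windowed haplotype diversity — the number of distinct haplotypes among 20
  sampled chromosomes per breed, over a fixed random subset of 15 (or 5)
  SNPs per 500-kb window so that marker density does not drive the count.
* Per-SNP Weir & Cockerham (1984) F_ST across breeds — the
  variance-components estimator theta-hat = a / (a + b + c), with
  heterozygosity terms from observed genotype counts and unequal sample
  sizes handled by the estimator itself.  Negative estimates are reported
  as computed.
* F_ST outlier regions — peaks (F_ST above a threshold at sufficient MAF)
  extended over consecutive array markers while neighbors stay above the
  genome-wide 95th-percentile F_ST; isolated peaks become singleton
  regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, HaplotypePanel, MarkerMap

__all__ = [
    "LdCurve",
    "HapDiversityTable",
    "FstTable",
    "FstRegion",
    "ld_decay",
    "haplotype_diversity",
    "weir_fst",
    "fst_regions",
    "pairwise_breed_fst",
]


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

@dataclass
class LdCurve:
    population_label: str
    bins: list  # (low_bp, high_bp), half-open
    mean_r2: np.ndarray
    n_pairs: np.ndarray

    def mean_r2_at(self, dist_bp: float) -> float:
        """Mean r^2 of the distance bin containing ``dist_bp``."""
        for (lo, hi), r2 in zip(self.bins, self.mean_r2):
            if lo <= dist_bp < hi:
                return float(r2)
        raise ValueError(f"distance {dist_bp} outside binned range")

    def mean_r2_between(self, lo_bp: float, hi_bp: float) -> float:
        """Pair-weighted mean r^2 over bins overlapping [lo_bp, hi_bp)."""
        total, pairs = 0.0, 0
        for (lo, hi), r2, n in zip(self.bins, self.mean_r2, self.n_pairs):
            if hi > lo_bp and lo < hi_bp and n > 0:
                total += r2 * n
                pairs += n
        if pairs == 0:
            raise ValueError(f"no marker pairs with distance in [{lo_bp}, {hi_bp})")
        return total / pairs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "low_bp": [b[0] for b in self.bins],
                "high_bp": [b[1] for b in self.bins],
                "mean_r2": self.mean_r2,
                "n_pairs": self.n_pairs,
            }
        )


def default_ld_bins(max_dist_bp: int = 5_000_000, width_bp: int = 25_000) -> list:
    edges = np.arange(0, max_dist_bp + width_bp, width_bp)
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def ld_decay(
    genotypes: GenotypeMatrix,
    individuals,
    maf_min: float = 0.15,
    max_missing: float = 0.10,
    sample_n: int = 10,
    max_dist_bp: int = 5_000_000,
    bins=None,
    label: str = "",
    seed: int = 0,
    exclude_chroms: tuple = (),
) -> LdCurve:
    """LD decay curve for a sampled subset of a population.

    ``individuals`` is a breed label or a sequence of row indices;
    ``sample_n`` dogs are drawn from it at random (fixed by ``seed``).
    Marker pairs must both pass the MAF and missingness filters *inside the
    sampled subset*; r^2 is the squared Pearson correlation of dosages over
    complete cases for the pair.  Zero-variance pairs are skipped.
    """
    if isinstance(individuals, str):
        label = label or individuals
        individuals = np.flatnonzero(genotypes.breed_labels == individuals)
    individuals = np.asarray(individuals)
    if len(individuals) < sample_n:
        raise ValueError(
            f"population has {len(individuals)} individuals, need {sample_n}"
        )
    rng = np.random.default_rng([int(seed) % (2**31), 11])
    chosen = np.sort(rng.choice(individuals, size=sample_n, replace=False))
    sub = genotypes.subset_individuals(chosen)

    X = sub.genotypes.astype(float)
    X[sub.genotypes == MISSING] = np.nan
    freqs = sub.allele_frequencies()
    maf = np.minimum(freqs, 1 - freqs)
    keep = (
        (maf >= maf_min)
        & (sub.missing_rate() < max_missing)
        & ~np.isin(sub.map.chromosome, list(exclude_chroms))
    )

    if bins is None:
        bins = default_ld_bins(max_dist_bp)
    edges = np.array([b[0] for b in bins] + [bins[-1][1]])
    sums = np.zeros(len(bins))
    counts = np.zeros(len(bins), dtype=np.int64)

    for chrom, sl in sub.map.chrom_slices().items():
        cols = np.flatnonzero(keep[sl]) + sl.start
        if len(cols) < 2:
            continue
        pos = sub.map.position_bp[cols]
        Xc = X[:, cols]
        finite = np.isfinite(Xc)
        X0 = np.where(finite, Xc, 0.0)
        X2 = X0 * X0
        max_off = int(np.searchsorted(pos - pos[0], max_dist_bp, side="right"))
        for off in range(1, min(max_off + 1, len(cols))):
            d = pos[off:] - pos[:-off]
            in_range = d <= max_dist_bp
            if not in_range.any():
                break
            A, B = X0[:, :-off], X0[:, off:]
            FA, FB = finite[:, :-off], finite[:, off:]
            both = FA & FB
            n = both.sum(axis=0).astype(float)
            sa = np.where(both, A, 0).sum(axis=0)
            sb = np.where(both, B, 0).sum(axis=0)
            saa = np.where(both, A * A, 0).sum(axis=0)
            sbb = np.where(both, B * B, 0).sum(axis=0)
            sab = np.where(both, A * B, 0).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                var_a = n * saa - sa * sa
                var_b = n * sbb - sb * sb
                cov = n * sab - sa * sb
                r2 = np.where(
                    (var_a > 0) & (var_b > 0), cov * cov / (var_a * var_b), np.nan
                )
            ok = in_range & np.isfinite(r2) & (n >= 2)
            if not ok.any():
                continue
            bin_idx = np.searchsorted(edges, d[ok], side="right") - 1
            valid = (bin_idx >= 0) & (bin_idx < len(bins))
            np.add.at(sums, bin_idx[valid], r2[ok][valid])
            np.add.at(counts, bin_idx[valid], 1)

    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LdCurve(
        population_label=label or "population",
        bins=list(bins),
        mean_r2=mean_r2,
        n_pairs=counts,
    )


# ---------------------------------------------------------------------------
# Windowed haplotype diversity
# ---------------------------------------------------------------------------

@dataclass
class HapDiversityTable:
    windows: pd.DataFrame  # chromosome, start_bp, end_bp, snps_used
    counts: pd.DataFrame  # breeds x windows distinct-haplotype counts


def haplotype_diversity(
    panel: HaplotypePanel,
    breeds=None,
    window_bp: int = 500_000,
    snps_full: int = 15,
    snps_reduced: int = 5,
    sample_n: int = 10,
    seed: int = 0,
) -> HapDiversityTable:
    """Distinct-haplotype counts per breed in fixed-SNP windows.

    The genome is tiled with half-open ``window_bp`` windows anchored at
    position 1.  Windows with >= ``snps_full`` SNPs use a random subset of
    that many SNPs; windows with at least ``snps_reduced`` use that many;
    smaller windows are dropped.  The *same* random SNPs serve every breed,
    and each breed contributes ``2 * sample_n`` sampled chromosomes, so
    counts range 1..2*sample_n.  Breeds with fewer than ``sample_n`` dogs
    are skipped with a warning.
    """
    rng = np.random.default_rng([int(seed) % (2**31), 12])
    if breeds is None:
        breeds = [b for b in pd.unique(panel.breed_labels)]

    win_rows, win_cols = [], []
    for chrom, sl in panel.map.chrom_slices().items():
        pos = panel.map.position_bp[sl]
        last = pos[-1]
        start = 1
        while start <= last:
            end = start + window_bp
            in_win = np.flatnonzero((pos >= start) & (pos < end)) + sl.start
            if len(in_win) >= snps_full:
                pick = np.sort(rng.choice(in_win, size=snps_full, replace=False))
            elif len(in_win) >= snps_reduced:
                pick = np.sort(rng.choice(in_win, size=snps_reduced, replace=False))
            else:
                start = end
                continue
            win_rows.append((str(chrom), start, end, len(pick)))
            win_cols.append(pick)
            start = end

    windows = pd.DataFrame(
        win_rows, columns=["chromosome", "start_bp", "end_bp", "snps_used"]
    )

    counts = {}
    for breed in breeds:
        dogs = np.flatnonzero(panel.breed_labels == breed)
        if len(dogs) < sample_n:
            warnings.warn(
                f"breed {breed!r} has {len(dogs)} dogs (< {sample_n}); skipped",
                stacklevel=2,
            )
            continue
        chosen = np.sort(rng.choice(dogs, size=sample_n, replace=False))
        hap_rows = np.concatenate([(2 * chosen), (2 * chosen + 1)])
        c = np.empty(len(win_cols), dtype=np.int64)
        for w, pick in enumerate(win_cols):
            strings = panel.haplotypes[np.ix_(hap_rows, pick)]
            c[w] = len({bytes(row) for row in strings})
        counts[breed] = c
    return HapDiversityTable(
        windows=windows, counts=pd.DataFrame(counts).T
    )


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST
# ---------------------------------------------------------------------------

@dataclass
class FstTable:
    table: pd.DataFrame  # marker_id, chromosome, position_bp, fst, maf_overall, n_breeds_used
    excluded: pd.DataFrame  # marker_id, reason

    def percentile(self, q: float) -> float:
        """Genome-wide quantile of the retained F_ST values."""
        return float(np.quantile(self.table["fst"].to_numpy(), q))


def _breed_counts(genotypes: GenotypeMatrix, breed_labels):
    """Per-breed, per-marker non-missing n, minor-allele count, het count."""
    labels = np.asarray(breed_labels, dtype=object)
    breeds = list(pd.unique(labels))
    g = genotypes.genotypes
    obs = g != MISSING
    N = np.empty((len(breeds), g.shape[1]), dtype=float)
    C = np.empty_like(N)
    H = np.empty_like(N)
    for k, b in enumerate(breeds):
        rows = labels == b
        gb = g[rows]
        ob = obs[rows]
        N[k] = ob.sum(axis=0)
        C[k] = np.where(ob, gb, 0).sum(axis=0)
        H[k] = (ob & (gb == 1)).sum(axis=0)
    return breeds, N, C, H


def weir_fst(
    genotypes: GenotypeMatrix, breed_labels=None, min_n_per_breed: int = 2
) -> FstTable:
    """Per-marker Weir & Cockerham (1984) theta-hat across breeds.

    Breeds with fewer than ``min_n_per_breed`` non-missing genotypes at a
    marker are left out of that marker's estimate; markers with fewer than
    two usable breeds, or monomorphic across all usable breeds, are
    excluded with a reason.  Negative estimates are reported as computed.
    """
    if breed_labels is None:
        breed_labels = genotypes.breed_labels
    breeds, N, C, H = _breed_counts(genotypes, breed_labels)

    use = N >= min_n_per_breed
    Nu = np.where(use, N, 0.0)
    Cu = np.where(use, C, 0.0)
    Hu = np.where(use, H, 0.0)
    r = use.sum(axis=0).astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(Nu > 0, Cu / (2.0 * Nu), 0.0)
        h = np.where(Nu > 0, Hu / Nu, 0.0)
        n_tot = Nu.sum(axis=0)
        nbar = n_tot / r
        n_c = (n_tot - (Nu**2).sum(axis=0) / n_tot) / (r - 1.0)
        pbar = (Nu * p).sum(axis=0) / n_tot
        s2 = (Nu * (p - pbar[None, :]) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (Nu * h).sum(axis=0) / n_tot

        a = (nbar / n_c) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(np.abs(denom) > 0, a / denom, np.nan)
        maf = np.minimum(pbar, 1 - pbar)

    too_few = r < 2
    mono = ~too_few & ~(np.abs(denom) > 0)
    ok = ~too_few & ~mono & np.isfinite(theta)

    mm = genotypes.map
    table = pd.DataFrame(
        {
            "marker_id": mm.marker_id[ok],
            "chromosome": mm.chromosome[ok],
            "position_bp": mm.position_bp[ok],
            "fst": theta[ok],
            "maf_overall": maf[ok],
            "n_breeds_used": r[ok].astype(int),
        }
    ).reset_index(drop=True)
    reasons = np.where(too_few, "fewer than 2 usable breeds", "monomorphic")
    excluded = pd.DataFrame(
        {"marker_id": mm.marker_id[~ok], "reason": reasons[~ok]}
    ).reset_index(drop=True)
    return FstTable(table=table, excluded=excluded)


def pairwise_breed_fst(
    genotypes: GenotypeMatrix,
    breed_a: str,
    breed_b: str,
    scheme: str = "ratio_of_averages",
) -> float:
    """Genome-wide two-breed F_ST, ratio-of-averages by default.

    ``ratio_of_averages`` sums the Weir & Cockerham variance components
    over markers before forming the ratio; ``average_of_ratios`` averages
    the per-marker theta-hat values.
    """
    rows = np.isin(genotypes.breed_labels, [breed_a, breed_b])
    sub = genotypes.subset_individuals(np.flatnonzero(rows))
    comp = _wc_components(sub, sub.breed_labels)
    a, b, c = comp
    usable = np.isfinite(a) & (np.abs(a + b + c) > 0)
    if scheme == "ratio_of_averages":
        return float(a[usable].sum() / (a + b + c)[usable].sum())
    if scheme == "average_of_ratios":
        return float((a[usable] / (a + b + c)[usable]).mean())
    raise ValueError(f"unknown scheme {scheme!r}")


def _wc_components(genotypes: GenotypeMatrix, breed_labels):
    """Raw per-marker (a, b, c) variance components (nan where undefined)."""
    breeds, N, C, H = _breed_counts(genotypes, breed_labels)
    use = N >= 2
    Nu = np.where(use, N, 0.0)
    Cu = np.where(use, C, 0.0)
    Hu = np.where(use, H, 0.0)
    r = use.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(Nu > 0, Cu / (2.0 * Nu), 0.0)
        h = np.where(Nu > 0, Hu / Nu, 0.0)
        n_tot = Nu.sum(axis=0)
        nbar = n_tot / r
        n_c = (n_tot - (Nu**2).sum(axis=0) / n_tot) / (r - 1.0)
        pbar = (Nu * p).sum(axis=0) / n_tot
        s2 = (Nu * (p - pbar[None, :]) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (Nu * h).sum(axis=0) / n_tot
        a = (nbar / n_c) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
    bad = r < 2
    a[bad] = b[bad] = c[bad] = np.nan
    return a, b, c


# ---------------------------------------------------------------------------
# F_ST outlier regions
# ---------------------------------------------------------------------------

@dataclass
class FstRegion:
    chromosome: str
    start_bp: int
    end_bp: int
    peak_marker: str
    peak_fst: float
    member_markers: list = field(default_factory=list)

    @property
    def is_singleton(self) -> bool:
        return len(self.member_markers) == 1


def fst_regions(
    fst: FstTable,
    peak_min_fst: float = 0.55,
    peak_min_maf: float = 0.15,
    neighbor_percentile: float = 0.95,
) -> list:
    """Delineate outlier regions around extreme-F_ST peaks.

    Peaks are markers with F_ST >= ``peak_min_fst`` and MAF >=
    ``peak_min_maf``.  From each peak the region extends over consecutive
    retained array markers, in both directions, while each neighbor's F_ST
    stays at or above the genome-wide ``neighbor_percentile`` quantile; a
    peak with no qualifying neighbor is a singleton region.  Overlapping
    regions merge, keeping the highest peak.
    """
    df = fst.table
    if df.empty:
        return []
    cutoff = fst.percentile(neighbor_percentile)

    regions = []
    for chrom in pd.unique(df["chromosome"]):
        sub = df[df["chromosome"] == chrom].sort_values("position_bp")
        f = sub["fst"].to_numpy()
        maf = sub["maf_overall"].to_numpy()
        ids = sub["marker_id"].to_numpy()
        pos = sub["position_bp"].to_numpy()
        peaks = np.flatnonzero((f >= peak_min_fst) & (maf >= peak_min_maf))
        intervals = []
        for pk in peaks:
            lo = pk
            while lo - 1 >= 0 and f[lo - 1] >= cutoff:
                lo -= 1
            hi = pk
            while hi + 1 < len(f) and f[hi + 1] >= cutoff:
                hi += 1
            intervals.append((lo, hi, pk))
        # merge overlapping marker-index intervals, keep the highest peak
        intervals.sort()
        merged = []
        for lo, hi, pk in intervals:
            if merged and lo <= merged[-1][1] + 0:
                mlo, mhi, mpk = merged[-1]
                merged[-1] = (mlo, max(mhi, hi), pk if f[pk] > f[mpk] else mpk)
            else:
                merged.append((lo, hi, pk))
        for lo, hi, pk in merged:
            regions.append(
                FstRegion(
                    chromosome=str(chrom),
                    start_bp=int(pos[lo]),
                    end_bp=int(pos[hi]),
                    peak_marker=str(ids[pk]),
                    peak_fst=float(f[pk]),
                    member_markers=list(ids[lo : hi + 1]),
                )
            )
    return regions
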
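"""Autozygosity inference with a two-state hidden Markov model.

Along each chromosome of one individual, the hidden state is *autozygous*
(the two chromosomes are identical by descent) or *non-autozygous*.  The
autozygous state emits a heterozygote only through genotyping error; the
non-autozygous state emits Hardy-Weinberg genotype frequencies computed from
cohort allele frequencies.  Transition probabilities shrink with the genetic
distance between adjacent markers (recombination breaks autozygous tracts),
and the chain's stationary distribution equals the configured prior on the
two states.  Posterior state probabilities come from the forward-backward
algorithm; runs of high posterior that are long enough (>100 kb) and dense
enough (>=25 SNPs) are called as autozygous segments, the classic
runs-of-homozygosity (ROH) signal of recent inbreeding.

The module also houses the autozygosity-based genotyping-QC filter: a SNP
that is frequently heterozygous *inside* called autozygous segments is a
likely assay artifact (segmental duplication, null alleles) and is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, MarkerMap

__all__ = [
    "HmmParams",
    "AutozygositySegment",
    "AutozygosityResult",
    "SnpQcResult",
    "emission_probabilities",
    "transition_matrices",
    "hmm_posteriors",
    "call_segments",
    "autozygosity_scan",
    "filter_snps_by_het_in_auto",
    "roh_summary",
]

AUTO, NON = 0, 1  # state indices


@dataclass(frozen=True)
class HmmParams:
    """HMM and segment-calling parameters.

    Defaults follow the standard purebred-dog setting: a 20%/80% prior on
    autozygosity vs non-autozygosity (enforced as the chain's stationary
    distribution), a 0.5% genotyping error rate, a map rate of 1.0 cM/Mb,
    and segment filters of >100 kb spanning at least 25 SNPs.
    """

    prior_auto: float = 0.20
    prior_non: float = 0.80
    genotype_error: float = 0.005
    recomb_rate_cM_per_Mb: float = 1.0
    switch_rate_multiplier: float = 1.0
    min_segment_bp: int = 100_000
    min_segment_snps: int = 25
    posterior_threshold: float = 0.5

    def __post_init__(self) -> None:
        if abs(self.prior_auto + self.prior_non - 1.0) > 1e-12:
            raise ValueError("prior_auto + prior_non must equal 1")
        for name in ("prior_auto", "prior_non", "genotype_error", "posterior_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class AutozygositySegment:
    individual_id: str
    chromosome: str
    start_bp: int  # 1-based inclusive
    end_bp: int
    n_snps: int
    mean_posterior: float

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError("segment end must exceed start")
        if self.n_snps < 1:
            raise ValueError("segment must span at least one SNP")

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class AutozygosityResult:
    posteriors: np.ndarray  # individuals x markers P(autozygous)
    segments: list
    per_individual_autozygosity: pd.Series
    individual_ids: np.ndarray


def emission_probabilities(
    genotypes_row: np.ndarray, freqs: np.ndarray, error: float
) -> np.ndarray:
    """Per-marker emission likelihoods, shape (markers, 2) = (auto, non).

    Non-autozygous emissions are Hardy-Weinberg genotype probabilities at
    the cohort allele frequency.  The autozygous state is a mixture: with
    probability 1-error the IBD genotype (homozygote for an allele drawn at
    its frequency), with probability ``error`` an erroneous Hardy-Weinberg
    call — so a heterozygote has autozygous likelihood error * 2pq.
    Missing genotypes and monomorphic markers contribute likelihood 1 in
    both states (no evidence).
    """
    g = np.asarray(genotypes_row)
    p = np.asarray(freqs, dtype=float)
    q = 1.0 - p
    hw = np.stack([q * q, 2 * p * q, p * p], axis=1)  # genotype 0/1/2
    ibd = np.stack([q, np.zeros_like(p), p], axis=1)
    e_auto_all = (1.0 - error) * ibd + error * hw
    out = np.ones((len(g), 2))
    informative = (g != MISSING) & np.isfinite(p) & (p > 0.0) & (p < 1.0)
    gi = np.where(informative, g, 0)
    out[informative, AUTO] = e_auto_all[informative, gi[informative]]
    out[informative, NON] = hw[informative, gi[informative]]
    return out


def transition_matrices(
    positions_bp: np.ndarray, params: HmmParams
) -> np.ndarray:
    """Per-gap 2x2 transition matrices, shape (markers-1, 2, 2).

    The switch probability over a gap of d bp is the stationary-weighted
    1 - exp(-k * d * rho) with rho the recombination rate in Morgans/bp, so
    the chain's stationary distribution is exactly (prior_auto, prior_non)
    and only inter-marker distances matter.
    """
    pos = np.asarray(positions_bp, dtype=float)
    rho = params.recomb_rate_cM_per_Mb * 1e-8  # Morgans per bp
    d = np.diff(pos)
    s = 1.0 - np.exp(-params.switch_rate_multiplier * d * rho)
    T = np.empty((len(d), 2, 2))
    T[:, AUTO, NON] = params.prior_non * s
    T[:, AUTO, AUTO] = 1.0 - T[:, AUTO, NON]
    T[:, NON, AUTO] = params.prior_auto * s
    T[:, NON, NON] = 1.0 - T[:, NON, AUTO]
    return T


def _forward_backward(emissions: np.ndarray, T: np.ndarray, prior: np.ndarray):
    """Scaled forward-backward for a batch.

    emissions: (batch, markers, 2); T: (markers-1, 2, 2); prior: (2,).
    Returns posteriors (batch, markers, 2).
    """
    nb, m, _ = emissions.shape
    alpha = np.empty_like(emissions)
    scale = np.empty((nb, m))
    a = prior[None, :] * emissions[:, 0, :]
    scale[:, 0] = a.sum(axis=1)
    alpha[:, 0, :] = a / scale[:, 0, None]
    for j in range(1, m):
        a = np.einsum("bi,ik->bk", alpha[:, j - 1, :], T[j - 1]) * emissions[:, j, :]
        scale[:, j] = a.sum(axis=1)
        alpha[:, j, :] = a / scale[:, j, None]
    beta = np.empty_like(emissions)
    beta[:, m - 1, :] = 1.0
    for j in range(m - 2, -1, -1):
        b = np.einsum("ik,bk->bi", T[j], emissions[:, j + 1, :] * beta[:, j + 1, :])
        beta[:, j, :] = b / scale[:, j + 1, None]
    post = alpha * beta
    post /= post.sum(axis=2, keepdims=True)
    return post


def _posteriors_matrix(
    genotypes: GenotypeMatrix, allele_freqs: np.ndarray, params: HmmParams
) -> np.ndarray:
    """P(autozygous) for every individual and marker; chromosomes independent."""
    n, m = genotypes.genotypes.shape
    prior = np.array([params.prior_auto, params.prior_non])
    post = np.empty((n, m))
    for chrom, sl in genotypes.map.chrom_slices().items():
        pos = genotypes.map.position_bp[sl]
        T = transition_matrices(pos, params)
        ems = np.stack(
            [
                emission_probabilities(
                    genotypes.genotypes[i, sl], allele_freqs[sl], params.genotype_error
                )
                for i in range(n)
            ]
        )
        post[:, sl] = _forward_backward(ems, T, prior)[:, :, AUTO]
    return post


def hmm_posteriors(
    genotypes: GenotypeMatrix,
    allele_freqs: np.ndarray,
    params: HmmParams,
    individual_id: str,
) -> np.ndarray:
    """Posterior P(autozygous) per marker for one individual."""
    i = genotypes.index_of(individual_id)
    one = genotypes.subset_individuals([i])
    return _posteriors_matrix(one, np.asarray(allele_freqs, float), params)[0]


def call_segments(
    posteriors: np.ndarray,
    marker_map: MarkerMap,
    params: HmmParams,
    individual_id: str = "",
) -> list:
    """Maximal runs of posterior > threshold passing the span/SNP filters.

    Segment endpoints are the positions of the first and last marker of the
    run; a run is kept when its span exceeds ``min_segment_bp`` *and* it
    contains at least ``min_segment_snps`` markers.
    """
    posteriors = np.asarray(posteriors, dtype=float)
    segments = []
    for chrom, sl in marker_map.chrom_slices().items():
        pos = marker_map.position_bp[sl]
        above = posteriors[sl] > params.posterior_threshold
        if not above.any():
            continue
        padded = np.concatenate([[False], above, [False]])
        starts = np.flatnonzero(padded[1:] & ~padded[:-1])
        ends = np.flatnonzero(~padded[1:] & padded[:-1])  # exclusive
        for s, e in zip(starts, ends):
            n_snps = e - s
            start_bp, end_bp = int(pos[s]), int(pos[e - 1])
            if end_bp - start_bp > params.min_segment_bp and n_snps >= params.min_segment_snps:
                segments.append(
                    AutozygositySegment(
                        individual_id=individual_id,
                        chromosome=str(chrom),
                        start_bp=start_bp,
                        end_bp=end_bp,
                        n_snps=int(n_snps),
                        mean_posterior=float(posteriors[sl][s:e].mean()),
                    )
                )
    return segments


def autozygosity_scan(
    genotypes: GenotypeMatrix,
    params: HmmParams = HmmParams(),
    allele_freqs: np.ndarray | None = None,
) -> AutozygosityResult:
    """Posteriors, segments and genome-fraction summaries for a whole cohort.

    Allele frequencies for the emissions default to the full-cohort
    complete-case frequencies.
    """
    if allele_freqs is None:
        allele_freqs = genotypes.allele_frequencies()
    post = _posteriors_matrix(genotypes, np.asarray(allele_freqs, float), params)
    genome_bp = _genome_span(genotypes.map)
    segments, fractions = [], {}
    for i, ind in enumerate(genotypes.individual_ids):
        segs = call_segments(post[i], genotypes.map, params, individual_id=str(ind))
        segments.extend(segs)
        fractions[str(ind)] = sum(s.span_bp for s in segs) / genome_bp
    return AutozygosityResult(
        posteriors=post,
        segments=segments,
        per_individual_autozygosity=pd.Series(fractions, name="autozygosity"),
        individual_ids=genotypes.individual_ids,
    )


def _genome_span(marker_map: MarkerMap) -> float:
    total = 0.0
    for chrom, sl in marker_map.chrom_slices().items():
        pos = marker_map.position_bp[sl]
        total += float(pos[-1] - pos[0]) if len(pos) > 1 else 1.0
    return max(total, 1.0)


# ---------------------------------------------------------------------------
# SNP QC on heterozygosity inside autozygous segments
# ---------------------------------------------------------------------------

@dataclass
class SnpQcResult:
    table: pd.DataFrame  # marker_id, n_covered, n_het, het_in_auto_rate, status
    kept_ids: list
    excluded_ids: list


def filter_snps_by_het_in_auto(
    genotypes: GenotypeMatrix,
    all_segments: list,
    max_het_rate: float = 0.10,
) -> SnpQcResult:
    """Drop SNPs with excess heterozygosity inside autozygous segments.

    For each marker: of the individuals whose called segments cover it (and
    whose call there is non-missing), the fraction heterozygous.  Markers
    with rate > ``max_het_rate`` are excluded; markers covered by no
    segment are kept with status ``untested``.
    """
    n, m = genotypes.genotypes.shape
    ind_index = {str(ind): i for i, ind in enumerate(genotypes.individual_ids)}
    covered = np.zeros((n, m), dtype=bool)
    chrom_sl = genotypes.map.chrom_slices()
    for seg in all_segments:
        sl = chrom_sl.get(str(seg.chromosome))
        if sl is None:
            continue
        i = ind_index.get(str(seg.individual_id))
        if i is None:
            continue
        pos = genotypes.map.position_bp[sl]
        cols = (pos >= seg.start_bp) & (pos <= seg.end_bp)
        covered[i, sl][cols] = True

    g = genotypes.genotypes
    usable = covered & (g != MISSING)
    n_cov = usable.sum(axis=0)
    n_het = (usable & (g == 1)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(n_cov > 0, n_het / np.maximum(n_cov, 1), np.nan)
    status = np.where(
        n_cov == 0, "untested", np.where(rate > max_het_rate, "excluded", "kept")
    )
    table = pd.DataFrame(
        {
            "marker_id": genotypes.map.marker_id,
            "n_covered": n_cov,
            "n_het_in_auto": n_het,
            "het_in_auto_rate": rate,
            "status": status,
        }
    )
    kept = table.loc[table["status"] != "excluded", "marker_id"].tolist()
    excluded = table.loc[table["status"] == "excluded", "marker_id"].tolist()
    return SnpQcResult(table=table, kept_ids=kept, excluded_ids=excluded)


def roh_summary(
    segments: list,
    thresholds_bp=(1_000_000, 10_000_000),
    genome_bp: float | None = None,
    marker_map: MarkerMap | None = None,
) -> pd.DataFrame:
    """Per-individual counts of segments longer than each threshold.

    Adds the genome fraction covered by called segments when a genome size
    (or a marker map to derive one from) is supplied.
    """
    if genome_bp is None and marker_map is not None:
        genome_bp = _genome_span(marker_map)
    rows: dict[str, dict] = {}
    for seg in segments:
        r = rows.setdefault(
            str(seg.individual_id),
            {f"n_gt_{int(t)}bp": 0 for t in thresholds_bp} | {"total_bp": 0},
        )
        for t in thresholds_bp:
            if seg.span_bp > t:
                r[f"n_gt_{int(t)}bp"] += 1
        r["total_bp"] += seg.span_bp
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0)
    if df.empty:
        cols = [f"n_gt_{int(t)}bp" for t in thresholds_bp] + ["total_bp"]
        df = pd.DataFrame(columns=cols)
    if genome_bp is not None and len(df):
        df["genome_fraction"] = df["total_bp"] / genome_bp
    df.index.name = "individual_id"
    return df.sort_index()
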
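"""Breed-average association mapping.

Mapping happens at the breed level: the predictor for each SNP is the breed
allele frequency and the response is the breed-average phenotype, with
genetic relatedness among breeds absorbed by a random effect whose
correlation matrix is the breed-averaged identity-by-state (IBS) matrix.

Continuous traits use an exact per-marker restricted-maximum-likelihood
linear mixed model (the EMMA approach): one spectral decomposition of the
breed kinship matrix is reused across markers, and for each marker the
variance ratio delta = sigma_e^2 / sigma_g^2 maximizing the restricted
likelihood is found by a vectorized grid-plus-golden-section search.

Dichotomous traits use an IBS-weighted bootstrap: each replicate re-draws
every individual's phenotype from a donor chosen with probability
proportional to the individual's IBS row, so the bootstrap null preserves
the relatedness structure; the p-value is the fraction of replicates whose
absolute phenotype-frequency correlation reaches the observed one.

A naive (structure-ignorant) regression is provided for contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING, GenotypeMatrix, PhenotypeTable

__all__ = [
    "BreedPhenotypes",
    "KinshipMatrix",
    "AssociationResult",
    "breed_averages",
    "ibs_kinship",
    "breed_average_kinship",
    "breed_frequencies",
    "lmm_assoc",
    "naive_assoc",
    "weighted_bootstrap_assoc",
]


# ---------------------------------------------------------------------------
# Phenotype aggregation
# ---------------------------------------------------------------------------

@dataclass
class BreedPhenotypes:
    """Breed-mean values for one trait (optionally on a transformed scale)."""

    trait: str
    values: pd.Series  # indexed by breed
    n_measured: pd.Series
    transform: str | None = None


def breed_averages(
    phenos: PhenotypeTable,
    trait: str,
    min_n: int = 2,
    min_age_years: float = 1.0,
    transform=None,
) -> BreedPhenotypes:
    """Breed means of a trait over measured adults.

    Only individuals strictly older than ``min_age_years`` count (records
    with no recorded age are assumed adult and kept); breeds with fewer
    than ``min_n`` contributing dogs are dropped.  ``transform`` may be
    ``None``, ``"log"`` or a callable, applied *before* averaging
    (transform-then-average).
    """
    df = phenos.for_trait(trait)
    if df.empty:
        raise ValueError(f"trait {trait!r} not present")
    age = df["age_years"]
    df = df[age.isna() | (age > min_age_years)]
    if transform == "log":
        fn, tname = np.log, "log"
    elif callable(transform):
        fn, tname = transform, getattr(transform, "__name__", "custom")
    else:
        fn, tname = None, None
    values = df["value"].to_numpy(dtype=float)
    if fn is not None:
        values = fn(values)
    work = pd.DataFrame({"breed": df["breed"].to_numpy(), "value": values})
    grouped = work.groupby("breed")["value"]
    means, ns = grouped.mean(), grouped.size()
    keep = ns >= min_n
    if not keep.any():
        raise ValueError(f"no breed has >= {min_n} measured dogs for {trait!r}")
    return BreedPhenotypes(
        trait=trait, values=means[keep], n_measured=ns[keep], transform=tname
    )


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

@dataclass
class KinshipMatrix:
    labels: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.labels)):
            raise ValueError("kinship matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")

    def align(self, labels) -> "KinshipMatrix":
        """Reorder/subset to the given labels."""
        index = {l: i for i, l in enumerate(self.labels)}
        try:
            idx = np.array([index[l] for l in labels])
        except KeyError as e:
            raise KeyError(f"label {e.args[0]!r} absent from kinship matrix") from None
        return KinshipMatrix(np.asarray(labels, dtype=object), self.values[np.ix_(idx, idx)])

    def stabilized(self, eps: float = 1e-6, min_eig: float = 1e-8) -> "KinshipMatrix":
        """Add ``eps`` to the diagonal if the smallest eigenvalue is < min_eig."""
        w = np.linalg.eigvalsh(self.values)
        if w.min() < min_eig:
            return KinshipMatrix(self.labels, self.values + eps * np.eye(len(self.labels)))
        return self


def ibs_kinship(genotypes: GenotypeMatrix) -> KinshipMatrix:
    """Individual-by-individual IBS similarity.

    IBS(i, j) = mean over markers non-missing in both of (2 - |g_i - g_j|)/2,
    i.e. the average fraction of alleles shared by state.  A pair sharing no
    genotyped marker is an error.
    """
    g = genotypes.genotypes
    if g.shape[0] < 2:
        raise ValueError("kinship needs at least two individuals")
    obs = (g != MISSING).astype(np.float64)
    I = [(np.where(g == MISSING, 0, g) == k).astype(np.float64) * obs for k in (0, 1, 2)]
    shared = obs @ obs.T
    absdiff = (
        I[0] @ I[1].T
        + I[1] @ I[0].T
        + I[1] @ I[2].T
        + I[2] @ I[1].T
        + 2.0 * (I[0] @ I[2].T + I[2] @ I[0].T)
    )
    if (shared == 0).any():
        i, j = np.argwhere(shared == 0)[0]
        raise ValueError(
            f"individuals {genotypes.individual_ids[i]!r} and "
            f"{genotypes.individual_ids[j]!r} share no genotyped marker"
        )
    ibs = 1.0 - absdiff / (2.0 * shared)
    ibs = (ibs + ibs.T) / 2.0
    np.fill_diagonal(ibs, 1.0)
    return KinshipMatrix(labels=genotypes.individual_ids.copy(), values=ibs)


def breed_average_kinship(K: KinshipMatrix, breed_labels) -> KinshipMatrix:
    """Average an individual IBS matrix within/between breeds.

    Off-diagonal entries are means over all cross-breed pairs; diagonal
    entries are means over distinct within-breed pairs (self-similarity
    excluded).  A single-dog breed keeps a diagonal of 1.
    """
    labels = np.asarray(breed_labels, dtype=object)
    breeds = list(pd.unique(labels))
    nb = len(breeds)
    out = np.empty((nb, nb))
    masks = [labels == b for b in breeds]
    for a in range(nb):
        ia = np.flatnonzero(masks[a])
        for b in range(a, nb):
            ib = np.flatnonzero(masks[b])
            block = K.values[np.ix_(ia, ib)]
            if a == b:
                if len(ia) < 2:
                    val = 1.0
                else:
                    off = block[~np.eye(len(ia), dtype=bool)]
                    val = float(off.mean())
            else:
                val = float(block.mean())
            out[a, b] = out[b, a] = val
    return KinshipMatrix(labels=np.array(breeds, dtype=object), values=out)


def breed_frequencies(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Breeds x markers allele-frequency matrix (complete-case per breed)."""
    labels = genotypes.breed_labels
    rows = {}
    for b in pd.unique(labels):
        sub = genotypes.subset_individuals(np.flatnonzero(labels == b))
        rows[b] = sub.allele_frequencies()
    return pd.DataFrame.from_dict(rows, orient="index", columns=genotypes.map.marker_id)


# ---------------------------------------------------------------------------
# Association results container
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    table: pd.DataFrame  # marker_id, chrom, pos, stat, p_value, beta, method
    method: str
    bonferroni_alpha: float
    covariates: list = field(default_factory=list)
    skipped: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return self.table

    def significant(self, alpha: float | None = None) -> pd.DataFrame:
        alpha = self.bonferroni_alpha if alpha is None else alpha
        return self.table[self.table["p_value"] < alpha]

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.nsmallest(n, "p_value")


def _align_inputs(breed_freqs: pd.DataFrame, y, K_breed: KinshipMatrix, covariates):
    yv = y.values if isinstance(y, BreedPhenotypes) else pd.Series(y)
    breeds = [b for b in yv.index if b in set(breed_freqs.index)]
    breeds = [b for b in breeds if b in set(K_breed.labels)]
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        breeds = [b for b in breeds if b in set(cov.index)]
        C = cov.loc[breeds].to_numpy(dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cov_names = list(cov.columns)
    else:
        C, cov_names = None, []
    F = breed_freqs.loc[breeds].to_numpy(dtype=float)
    yy = yv.loc[breeds].to_numpy(dtype=float)
    K = K_breed.align(breeds)
    return breeds, F, yy, K, C, cov_names


def _reml_delta_grid(S, Zt, xt, yt, n, q):
    """Vectorized profiled REML criterion over a log-delta grid + refinement.

    Returns per-marker optimal delta and the GLS pieces at the optimum.
    Zt: (n, q0) transformed fixed covariates incl. intercept; xt: (n, M)
    transformed marker columns; yt: (n,) transformed response.
    """

    def criterion(log_delta):
        # log_delta: (M,) or scalar; returns (ll, beta, rss, s_schur)
        delta = np.exp(log_delta)
        w = 1.0 / (S[:, None] + delta[None, :])  # (n, M)
        # cross products per marker
        A = np.einsum("ni,nm,nj->mij", Zt, w, Zt)  # (M, q0, q0)
        az = np.einsum("ni,nm,nm->mi", Zt, w, xt)  # (M, q0)
        axx = np.einsum("nm,nm,nm->m", xt, w, xt)
        by = np.einsum("ni,nm,n->mi", Zt, w, yt)
        bxy = np.einsum("nm,nm,n->m", xt, w, yt)
        yy = np.einsum("n,nm,n->m", yt, w, yt)
        Ainv = np.linalg.inv(A)
        Ainv_by = np.einsum("mij,mj->mi", Ainv, by)
        Ainv_az = np.einsum("mij,mj->mi", Ainv, az)
        s = axx - np.einsum("mi,mi->m", az, Ainv_az)
        resid = bxy - np.einsum("mi,mi->m", az, Ainv_by)
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = resid / s
            rss = yy - np.einsum("mi,mi->m", by, Ainv_by) - resid * beta
            rss = np.maximum(rss, 1e-300)
            sign, logdetA = np.linalg.slogdet(A)
            logdet_v = np.log(S[:, None] + delta[None, :]).sum(axis=0)
            ll = -0.5 * (
                (n - q) * np.log(rss) + logdet_v + logdetA + np.log(np.maximum(s, 1e-300))
            )
        return ll, beta, rss, s

    grid = np.linspace(-10.0, 10.0, 41)
    best_ll = np.full(xt.shape[1], -np.inf)
    best_ld = np.zeros(xt.shape[1])
    for ld in grid:
        ll, *_ = criterion(np.full(xt.shape[1], ld))
        better = ll > best_ll
        best_ll = np.where(better, ll, best_ll)
        best_ld = np.where(better, ld, best_ld)
    # golden-section refinement in the bracketing interval
    h = grid[1] - grid[0]
    lo, hi = best_ld - h, best_ld + h
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    for _ in range(30):
        c1 = hi - gr * (hi - lo)
        c2 = lo + gr * (hi - lo)
        f1 = criterion(c1)[0]
        f2 = criterion(c2)[0]
        shrink_hi = f1 >= f2
        hi = np.where(shrink_hi, c2, hi)
        lo = np.where(shrink_hi, lo, c1)
    best = (lo + hi) / 2.0
    ll, beta, rss, s = criterion(best)
    return np.exp(best), beta, rss, s


def lmm_assoc(
    breed_freqs: pd.DataFrame,
    y,
    K_breed: KinshipMatrix,
    covariates=None,
    min_breeds: int = 10,
    bonferroni_level: float = 0.05,
) -> AssociationResult:
    """Per-marker linear mixed model on breed means.

    Fits, for each marker, ``y = mu + beta * freq + C gamma + u + e`` with
    ``u ~ MVN(0, sigma_g^2 K_breed)`` and ``e ~ MVN(0, sigma_e^2 I)``.  The
    variance ratio is re-estimated per marker by exact restricted maximum
    likelihood using one spectral decomposition of the kinship matrix; the
    p-value is the two-sided t test on beta with n - q degrees of freedom.
    Monomorphic markers (no frequency variance across breeds) are skipped.
    """
    breeds, F, yv, K, C, cov_names = _align_inputs(breed_freqs, y, K_breed, covariates)
    n = len(breeds)
    if n < min_breeds:
        raise ValueError(f"only {n} breeds with phenotype; need >= {min_breeds}")

    K = K.stabilized()
    S, U = np.linalg.eigh(K.values)
    if S.min() <= 0:
        raise np.linalg.LinAlgError("kinship matrix not positive definite")

    Z = np.ones((n, 1)) if C is None else np.column_stack([np.ones(n), C])
    q = Z.shape[1] + 1
    Zt = U.T @ Z
    yt = U.T @ yv

    var_ok = np.nanstd(F, axis=0) > 1e-12
    finite = np.isfinite(F).all(axis=0)
    usable = var_ok & finite
    xt = U.T @ F[:, usable]

    delta, beta, rss, s = _reml_delta_grid(S, Zt, xt, yt, n, q)
    sigma2 = rss / (n - q)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(sigma2 / s)
        t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - q)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    # degenerate fits: residual variance at floating-point zero relative to
    # the (weighted) response scale -- perfect fit (p -> 0) or constant
    # response (p = 1)
    w_best = 1.0 / (S[:, None] + delta[None, :])
    yscale = np.maximum(
        np.einsum("n,nm,n->m", yt, w_best, yt), np.finfo(float).tiny
    )
    exact = rss < 1e-12 * yscale
    explained = beta**2 * s > 1e-12 * yscale
    p = np.where(exact & explained, np.finfo(float).tiny, p)
    p = np.where(exact & ~explained, 1.0, p)
    t = np.where(exact, np.where(explained, np.inf, 0.0), t)

    markers = np.asarray(breed_freqs.columns, dtype=object)
    table = pd.DataFrame(
        {
            "marker_id": markers[usable],
            "stat": t,
            "p_value": p,
            "beta": beta,
            "delta": delta,
            "method": "lmm",
        }
    )
    skipped = pd.DataFrame(
        {"marker_id": markers[~usable], "reason": "monomorphic or missing"}
    )
    m_tested = int(usable.sum())
    return AssociationResult(
        table=table,
        method="lmm",
        bonferroni_alpha=bonferroni_level / max(m_tested, 1),
        covariates=cov_names,
        skipped=skipped,
    )


def naive_assoc(
    breed_freqs: pd.DataFrame,
    y,
    covariates=None,
    bonferroni_level: float = 0.05,
) -> AssociationResult:
    """Ordinary per-marker regression of breed phenotype on breed frequency.

    No relatedness control — the comparison baseline for the mixed model.
    """
    identity = KinshipMatrix(
        labels=(y.values if isinstance(y, BreedPhenotypes) else pd.Series(y)).index.to_numpy(
            dtype=object
        ),
        values=np.eye(len(y.values if isinstance(y, BreedPhenotypes) else y)),
    )
    breeds, F, yv, _, C, cov_names = _align_inputs(breed_freqs, y, identity, covariates)
    n = len(breeds)
    Z = np.ones((n, 1)) if C is None else np.column_stack([np.ones(n), C])
    q = Z.shape[1] + 1

    var_ok = (np.nanstd(F, axis=0) > 1e-12) & np.isfinite(F).all(axis=0)
    X = F[:, var_ok]
    # residualize on Z for a per-marker scalar regression
    Qz, _ = np.linalg.qr(Z)
    y_r = yv - Qz @ (Qz.T @ yv)
    X_r = X - Qz @ (Qz.T @ X)
    xx = (X_r**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = (X_r * y_r[:, None]).sum(axis=0) / xx
        rss = (y_r**2).sum() - beta**2 * xx
        sigma2 = np.maximum(rss, 0.0) / (n - q)
        se = np.sqrt(sigma2 / xx)
        t = np.where(se > 0, beta / se, 0.0)
    p = np.clip(2.0 * stats.t.sf(np.abs(t), df=n - q), np.finfo(float).tiny, 1.0)
    yscale = max(float(y_r @ y_r), np.finfo(float).tiny)
    exact = rss < 1e-12 * yscale
    explained = beta**2 * xx > 1e-12 * yscale
    p = np.where(exact & explained, np.finfo(float).tiny, p)
    p = np.where(exact & ~explained, 1.0, p)
    if (y_r @ y_r) < 1e-12 * max(float(yv @ yv), np.finfo(float).tiny):
        p = np.ones_like(p)  # response constant after covariate adjustment

    markers = np.asarray(breed_freqs.columns, dtype=object)
    table = pd.DataFrame(
        {
            "marker_id": markers[var_ok],
            "stat": t,
            "p_value": p,
            "beta": beta,
            "method": "naive",
        }
    )
    return AssociationResult(
        table=table,
        method="naive",
        bonferroni_alpha=bonferroni_level / max(int(var_ok.sum()), 1),
        covariates=cov_names,
        skipped=pd.DataFrame(
            {"marker_id": markers[~var_ok], "reason": "monomorphic or missing"}
        ),
    )


# ---------------------------------------------------------------------------
# Weighted bootstrap for dichotomous traits
# ---------------------------------------------------------------------------

def _bootstrap_donors(K: np.ndarray, B: int, rng) -> np.ndarray:
    """(B, n) donor indices; row i of K gives individual i's donor weights."""
    n = K.shape[0]
    P = K / K.sum(axis=1, keepdims=True)
    cum = np.cumsum(P, axis=1)
    donors = np.empty((B, n), dtype=np.int64)
    for i in range(n):
        u = rng.uniform(size=B)
        donors[:, i] = np.searchsorted(cum[i], u, side="right")
    return np.minimum(donors, n - 1)


def weighted_bootstrap_assoc(
    breed_freqs: pd.DataFrame,
    y_binary,
    breed_of_individual,
    K_ind: KinshipMatrix,
    B: int = 10_000,
    seed: int = 0,
    plus_one_correction: bool = True,
    null: str = "weighted_bootstrap",
    bonferroni_level: float = 0.05,
    chunk: int = 256,
) -> AssociationResult:
    """IBS-weighted bootstrap association test for a 0/1 phenotype.

    The statistic is the absolute Pearson correlation between the
    per-individual phenotype and the individual's breed allele frequency at
    the marker.  Each bootstrap replicate re-draws individual i's phenotype
    from donor j with probability K(i, j) / sum_j' K(i, j'); the empirical
    p-value is the fraction of replicates whose statistic is at least the
    observed one (with a +1/(B+1) continuity correction by default; without
    it, the plain count / B).  ``null="permutation"`` replaces the weighted
    draw with a uniform permutation of phenotypes — the structure-ignorant
    baseline.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    if null not in ("weighted_bootstrap", "permutation"):
        raise ValueError(f"unknown null {null!r}")
    y = np.asarray(
        y_binary.to_numpy() if hasattr(y_binary, "to_numpy") else y_binary, dtype=float
    )
    breed_of_individual = np.asarray(breed_of_individual, dtype=object)
    n = len(y)
    rng = np.random.default_rng([int(seed) % (2**31), 13])

    # per-individual predictor: breed frequency at each marker
    F = breed_freqs.to_numpy(dtype=float)
    breed_row = {b: i for i, b in enumerate(breed_freqs.index)}
    rows = np.array([breed_row[b] for b in breed_of_individual])
    X = F[rows, :]  # (n, M)

    markers = np.asarray(breed_freqs.columns, dtype=object)
    var_ok = np.nanstd(X, axis=0) > 1e-12
    constant_y = np.std(y) == 0

    if null == "permutation":
        Yb = np.stack([y[rng.permutation(n)] for _ in range(B)], axis=1)
    else:
        donors = _bootstrap_donors(K_ind.values, B, rng)
        Yb = y[donors.T]  # (n, B)

    Yc = Yb - Yb.mean(axis=0, keepdims=True)
    ynorm = np.sqrt((Yc**2).sum(axis=0))
    yobs = y - y.mean()
    yobs_norm = np.sqrt((yobs**2).sum())

    M = X.shape[1]
    stat = np.full(M, np.nan)
    pval = np.full(M, np.nan)
    idx = np.flatnonzero(var_ok)
    for start in range(0, len(idx), chunk):
        cols = idx[start : start + chunk]
        Xc = X[:, cols] - X[:, cols].mean(axis=0, keepdims=True)
        xnorm = np.sqrt((Xc**2).sum(axis=0))
        if constant_y:
            stat[cols] = 0.0
            pval[cols] = 1.0
            continue
        obs = np.abs(Xc.T @ yobs) / (xnorm * yobs_norm)
        boot = np.abs(Xc.T @ Yc)  # (chunk, B)
        with np.errstate(invalid="ignore", divide="ignore"):
            boot = boot / (xnorm[:, None] * ynorm[None, :])
        boot = np.nan_to_num(boot, nan=0.0)  # constant replicate => stat 0
        count = (boot >= obs[:, None] - 1e-12).sum(axis=1)
        stat[cols] = obs
        if plus_one_correction:
            pval[cols] = (1.0 + count) / (B + 1.0)
        else:
            pval[cols] = count / B
    table = pd.DataFrame(
        {
            "marker_id": markers[var_ok],
            "stat": stat[var_ok],
            "p_value": pval[var_ok],
            "beta": np.nan,
            "method": null,
        }
    )
    return AssociationResult(
        table=table,
        method=null,
        bonferroni_alpha=bonferroni_level / max(int(var_ok.sum()), 1),
        skipped=pd.DataFrame(
            {"marker_id": markers[~var_ok], "reason": "monomorphic"}
        ),
    )
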
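"""Multi-SNP predictive models of breed-average traits.

Forward stepwise regression over association-ranked candidate SNPs, with
the breed-average trait value repeated for every individual of the breed as
the response and individual dosages as the design matrix.  The selected
model is a plain additive linear predictor; applying it to an individual's
genotypes predicts that individual's phenotype, which is how the models are
validated on individually phenotyped dogs (including outbred village dogs,
where linkage between tag SNP and causal variant is weaker and the
correlation between observed and predicted values attenuates).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING, GenotypeMatrix, PhenotypeTable
from .breedgwas import BreedPhenotypes

__all__ = [
    "PredictiveModel",
    "ValidationReport",
    "forward_stepwise",
    "predict",
    "validate",
]


@dataclass
class PredictiveModel:
    trait: str
    marker_ids: list
    intercept: float
    coefficients: np.ndarray  # per selected marker, in selection order
    r2_trajectory: list  # training R^2 of the top-1..k models
    adjusted_r2_trajectory: list
    transform: str | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        r2 = np.asarray(self.r2_trajectory)
        if np.any(np.diff(r2) < -1e-10):
            raise ValueError("training R^2 trajectory must be non-decreasing")

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "trait": self.trait,
                "marker_ids": list(map(str, self.marker_ids)),
                "intercept": self.intercept,
                "coefficients": list(map(float, self.coefficients)),
                "r2_trajectory": list(map(float, self.r2_trajectory)),
                "adjusted_r2_trajectory": list(map(float, self.adjusted_r2_trajectory)),
                "transform": self.transform,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "PredictiveModel":
        import os

        if isinstance(source, os.PathLike) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            with open(source) as fh:
                data = json.load(fh)
        else:
            data = json.loads(source)
        return cls(
            trait=data["trait"],
            marker_ids=data["marker_ids"],
            intercept=data["intercept"],
            coefficients=np.array(data["coefficients"]),
            r2_trajectory=data["r2_trajectory"],
            adjusted_r2_trajectory=data["adjusted_r2_trajectory"],
            transform=data.get("transform"),
        )


@dataclass
class ValidationReport:
    population_label: str
    n_individuals: int
    correlation: float
    r2: float
    degenerate: bool = False


def _design_column(genotypes: GenotypeMatrix, marker_index: int) -> np.ndarray:
    """Dosage column with mean imputation of missing calls."""
    col = genotypes.genotypes[:, marker_index].astype(float)
    miss = col == MISSING
    if miss.all():
        return np.zeros(len(col))
    if miss.any():
        col[miss] = col[~miss].mean()
    return col


def _ols_r2(X: np.ndarray, y: np.ndarray):
    """(R^2, adjusted R^2, coefficients, rank) for design with intercept."""
    n = len(y)
    Xd = np.column_stack([np.ones(n), X])
    coef, _, rank, _ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ coef
    tss = float(((y - y.mean()) ** 2).sum())
    rss = float((resid**2).sum())
    if tss == 0:
        return 1.0, 1.0, coef, rank
    r2 = 1.0 - rss / tss
    q = Xd.shape[1]
    adj = 1.0 - (1.0 - r2) * (n - 1) / max(n - q, 1)
    return r2, adj, coef, rank


def forward_stepwise(
    candidates,
    genotypes: GenotypeMatrix,
    y_breed: BreedPhenotypes,
    max_k: int = 6,
    one_row_per_breed: bool = False,
) -> PredictiveModel:
    """Forward stepwise selection over association-ranked candidate markers.

    ``candidates`` is an ordered list of marker ids (best association
    first); ordering breaks ties in the adjusted-R^2 step criterion.  The
    response is the breed-average value assigned to every individual of the
    breed (set ``one_row_per_breed`` to regress on one row per breed
    instead).  Selection stops at ``max_k`` or when no candidate improves
    adjusted R^2; a candidate whose addition leaves the design rank
    deficient (a duplicate of a chosen marker) is skipped.
    """
    marker_pos = {str(m): j for j, m in enumerate(genotypes.map.marker_id)}
    cand_idx = []
    for c in candidates:
        key = str(c)
        if key not in marker_pos:
            raise KeyError(f"candidate marker {key!r} absent from panel")
        cand_idx.append(marker_pos[key])

    have_pheno = np.isin(genotypes.breed_labels, y_breed.values.index.to_numpy())
    rows = np.flatnonzero(have_pheno)
    if len(rows) == 0:
        raise ValueError("no genotyped individual belongs to a phenotyped breed")
    sub = genotypes.subset_individuals(rows)
    y = y_breed.values.loc[sub.breed_labels].to_numpy(dtype=float)
    cols = {j: _design_column(sub, j) for j in cand_idx}

    if one_row_per_breed:
        frame = pd.DataFrame(cols)
        frame["_breed"] = sub.breed_labels
        agg = frame.groupby("_breed").mean()
        y = y_breed.values.loc[agg.index].to_numpy(dtype=float)
        cols = {j: agg[j].to_numpy() for j in cand_idx}

    chosen: list[int] = []
    r2_traj: list[float] = []
    adj_traj: list[float] = []
    current_adj = -np.inf
    while len(chosen) < max_k:
        best = None
        for rank_pos, j in enumerate(cand_idx):
            if j in chosen:
                continue
            X = np.column_stack([cols[k] for k in chosen + [j]])
            r2, adj, _, rank = _ols_r2(X, y)
            if rank < X.shape[1] + 1:
                continue  # collinear with chosen markers
            # tie-break: higher adj R^2, then better association rank
            key = (adj, -rank_pos)
            if best is None or key > best[0]:
                best = (key, j, r2, adj)
        if best is None:
            break
        _, j, r2, adj = best
        if adj <= current_adj:
            break
        chosen.append(j)
        r2_traj.append(r2)
        adj_traj.append(adj)
        current_adj = adj

    if not chosen:
        raise ValueError("no candidate marker improved the model")
    X = np.column_stack([cols[k] for k in chosen])
    _, _, coef, _ = _ols_r2(X, y)
    id_of = {j: str(genotypes.map.marker_id[j]) for j in chosen}
    return PredictiveModel(
        trait=y_breed.trait,
        marker_ids=[id_of[j] for j in chosen],
        intercept=float(coef[0]),
        coefficients=coef[1:],
        r2_trajectory=r2_traj,
        adjusted_r2_trajectory=adj_traj,
        transform=y_breed.transform,
    )


def predict(model: PredictiveModel, genotypes: GenotypeMatrix) -> np.ndarray:
    """Linear predictor per individual; missing dosages mean-imputed."""
    marker_pos = {str(m): j for j, m in enumerate(genotypes.map.marker_id)}
    missing = [m for m in model.marker_ids if str(m) not in marker_pos]
    if missing:
        raise KeyError(f"model markers absent from panel: {missing}")
    X = np.column_stack(
        [_design_column(genotypes, marker_pos[str(m)]) for m in model.marker_ids]
    )
    return model.intercept + X @ model.coefficients


def validate(
    predictions: np.ndarray,
    observed,
    label: str = "validation",
) -> ValidationReport:
    """Pearson correlation between observed and predicted phenotypes.

    ``observed`` is an array aligned with ``predictions``.  Constant
    predictions (or observations) make the correlation undefined; the
    report is then flagged degenerate with correlation 0.
    """
    obs = np.asarray(
        observed.to_numpy() if hasattr(observed, "to_numpy") else observed, dtype=float
    )
    pred = np.asarray(predictions, dtype=float)
    keep = np.isfinite(obs) & np.isfinite(pred)
    obs, pred = obs[keep], pred[keep]
    if len(obs) < 3:
        raise ValueError("validation needs at least 3 individuals")
    if np.std(pred) == 0 or np.std(obs) == 0:
        return ValidationReport(label, len(obs), 0.0, 0.0, degenerate=True)
    r = float(stats.pearsonr(obs, pred).statistic)
    return ValidationReport(label, len(obs), r, r * r)
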
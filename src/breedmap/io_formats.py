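"""File formats and the shared in-memory data model.

The pipeline works on a SNP-major dosage matrix (:class:`GenotypeMatrix`),
optionally with true/inferred phase (:class:`HaplotypePanel`), a marker map
(:class:`MarkerMap`) and a long-format phenotype table
(:class:`PhenotypeTable`).  Genotypes are coded as counts of the *minor*
allele (determined per marker at load time), with ``MISSING = -1``.

Supported formats: PLINK text (``.ped``/``.map``) for genotypes, TSV for
phenotypes, BED for autozygosity segments, TSV for association results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "MarkerMap",
    "GenotypeMatrix",
    "HaplotypePanel",
    "PhenotypeTable",
    "PlinkParseError",
    "read_plink",
    "write_plink",
    "read_phenotypes",
    "write_phenotypes",
    "write_segments_bed",
    "write_association_tsv",
]


class PlinkParseError(ValueError):
    """Malformed or structurally inconsistent PLINK text input."""


@dataclass
class MarkerMap:
    """Marker positions, sorted by (chromosome, position) on construction.

    Positions are 1-based base pairs, PLINK convention.  ``genetic_pos_cM``
    is optional and carried through unchanged.
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    genetic_pos_cM: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        if self.genetic_pos_cM is not None:
            self.genetic_pos_cM = np.asarray(self.genetic_pos_cM, dtype=float)
        if len(set(self.marker_id)) != len(self.marker_id):
            raise ValueError("marker ids are not unique")
        for chrom in pd.unique(self.chromosome):
            pos = self.position_bp[self.chromosome == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    def __len__(self) -> int:
        return len(self.marker_id)

    @property
    def chromosomes(self) -> list:
        """Chromosome labels in order of first appearance."""
        return list(pd.unique(self.chromosome))

    def chrom_slices(self) -> dict:
        """Map chromosome label -> contiguous marker index slice."""
        out = {}
        for chrom in self.chromosomes:
            idx = np.flatnonzero(self.chromosome == chrom)
            out[chrom] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    @staticmethod
    def sort_order(chromosome, position_bp) -> np.ndarray:
        """Stable sort order by chromosome (first-appearance order) then bp."""
        chromosome = np.asarray(chromosome, dtype=object)
        chrom_rank = {c: i for i, c in enumerate(pd.unique(chromosome))}
        ranks = np.array([chrom_rank[c] for c in chromosome])
        return np.lexsort((np.asarray(position_bp), ranks))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chromosome": self.chromosome,
                "position_bp": self.position_bp,
            }
        )
        if self.genetic_pos_cM is not None:
            df["genetic_pos_cM"] = self.genetic_pos_cM
        return df


@dataclass
class GenotypeMatrix:
    """Individuals x markers minor-allele dosage matrix.

    ``genotypes[i, m]`` is 0/1/2 (count of the minor allele at load time)
    or ``MISSING``.  Breed labels ride along with the individuals; marker
    metadata lives in ``map``.
    """

    genotypes: np.ndarray
    individual_ids: np.ndarray
    breed_labels: np.ndarray
    map: MarkerMap
    sex: np.ndarray | None = None
    allele_names: np.ndarray | None = None  # per marker (minor, major), optional

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.breed_labels = np.asarray(self.breed_labels, dtype=object)
        n, m = self.genotypes.shape
        if n != len(self.individual_ids) or n != len(self.breed_labels):
            raise ValueError("genotype rows do not match individual count")
        if m != len(self.map):
            raise ValueError("genotype columns do not match marker count")
        valid = np.isin(self.genotypes, [MISSING, 0, 1, 2])
        if not valid.all():
            raise ValueError("genotype codes outside {MISSING, 0, 1, 2}")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Per-marker frequency of the counted allele, complete-case.

        Markers with no non-missing calls get ``nan``.
        """
        g = self.genotypes
        obs = g != MISSING
        counts = np.where(obs, g, 0).sum(axis=0)
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, counts / (2.0 * n_obs), np.nan)

    def missing_rate(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=0)

    def subset_individuals(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            genotypes=self.genotypes[index],
            individual_ids=self.individual_ids[index],
            breed_labels=self.breed_labels[index],
            map=self.map,
            sex=None if self.sex is None else np.asarray(self.sex)[index],
            allele_names=self.allele_names,
        )

    def subset_markers(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        sub_map = MarkerMap(
            marker_id=self.map.marker_id[index],
            chromosome=self.map.chromosome[index],
            position_bp=self.map.position_bp[index],
            genetic_pos_cM=None
            if self.map.genetic_pos_cM is None
            else self.map.genetic_pos_cM[index],
        )
        return GenotypeMatrix(
            genotypes=self.genotypes[:, index],
            individual_ids=self.individual_ids,
            breed_labels=self.breed_labels,
            map=sub_map,
            sex=self.sex,
            allele_names=None if self.allele_names is None else self.allele_names[index],
        )

    def drop_markers(self, marker_ids) -> "GenotypeMatrix":
        """Panel without the named markers (e.g. masking causal variants)."""
        drop = set(map(str, marker_ids))
        keep = [j for j, m in enumerate(self.map.marker_id) if str(m) not in drop]
        return self.subset_markers(keep)

    def index_of(self, individual_id: str) -> int:
        hits = np.flatnonzero(self.individual_ids == individual_id)
        if len(hits) == 0:
            raise KeyError(f"individual {individual_id!r} not found")
        return int(hits[0])


@dataclass
class HaplotypePanel:
    """Phased 0/1 haplotypes, two rows per individual.

    Row ``2*i`` and ``2*i + 1`` are the two chromosome copies of individual
    ``i`` (same ordering as the genotype matrix the panel was built with).
    """

    haplotypes: np.ndarray
    individual_ids: np.ndarray
    breed_labels: np.ndarray
    map: MarkerMap

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.breed_labels = np.asarray(self.breed_labels, dtype=object)
        if self.haplotypes.shape[0] != 2 * len(self.individual_ids):
            raise ValueError("panel must hold exactly two rows per individual")
        if self.haplotypes.shape[1] != len(self.map):
            raise ValueError("haplotype columns do not match marker count")
        if not np.isin(self.haplotypes, [0, 1]).all():
            raise ValueError("haplotype codes outside {0, 1}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def phase_of(self, row: int) -> tuple:
        """(individual_id, copy index) for a haplotype row."""
        return (self.individual_ids[row // 2], row % 2)

    def to_genotypes(self) -> GenotypeMatrix:
        g = self.haplotypes[0::2] + self.haplotypes[1::2]
        return GenotypeMatrix(
            genotypes=g.astype(np.int8),
            individual_ids=self.individual_ids,
            breed_labels=self.breed_labels,
            map=self.map,
        )


@dataclass
class PhenotypeTable:
    """Long-format phenotype records.

    One row per (individual, trait); columns ``individual_id``, ``breed``,
    ``trait``, ``value`` and optional ``age_years``.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"individual_id", "breed", "trait", "value"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
        if "age_years" not in self.records.columns:
            self.records = self.records.assign(age_years=np.nan)
        dup = self.records.duplicated(subset=["individual_id", "trait"])
        if dup.any():
            pair = self.records.loc[dup.idxmax(), ["individual_id", "trait"]]
            raise ValueError(
                f"duplicate phenotype record for individual "
                f"{pair['individual_id']!r}, trait {pair['trait']!r}"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def traits(self) -> list:
        return list(pd.unique(self.records["trait"]))

    def for_trait(self, trait: str) -> pd.DataFrame:
        return self.records[self.records["trait"] == trait]


# ---------------------------------------------------------------------------
# PLINK text
# ---------------------------------------------------------------------------

def _read_map(map_path) -> MarkerMap:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (3, 4):
                raise PlinkParseError(
                    f"{map_path}: line {lineno}: expected 3 or 4 columns, "
                    f"got {len(parts)}"
                )
            if len(parts) == 4:
                chrom, mid, cm, bp = parts
            else:
                chrom, mid, bp = parts
                cm = "0"
            rows.append((chrom, mid, float(cm), int(bp)))
    if not rows:
        raise PlinkParseError(f"{map_path}: no markers")
    chrom, mid, cm, bp = map(np.array, zip(*rows))
    order = MarkerMap.sort_order(chrom, bp)
    return MarkerMap(
        marker_id=mid[order],
        chromosome=chrom[order],
        position_bp=bp[order].astype(np.int64),
        genetic_pos_cM=cm[order].astype(float),
    ), order


def read_plink(ped_path, map_path) -> GenotypeMatrix:
    """Load a PLINK text fileset as a minor-allele dosage matrix.

    The breed label is taken from the family-ID column.  Alleles are coded
    per marker with the major allele as reference, so dosage counts the
    minor allele; ``0 0`` is treated as missing.  Markers are sorted by
    (chromosome, position) on ingest.
    """
    marker_map, order = _read_map(map_path)
    m = len(marker_map)

    fams, iids, sexes = [], [], []
    allele_rows = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise PlinkParseError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * m} fields "
                    f"(6 + 2 x {m} markers), got {len(parts)}"
                )
            fams.append(parts[0])
            iids.append(parts[1])
            sexes.append(parts[4])
            allele_rows.append(parts[6:])
    if not allele_rows:
        raise PlinkParseError(f"{ped_path}: no individuals")

    alleles = np.array(allele_rows, dtype=object).reshape(len(iids), m, 2)
    alleles = alleles[:, order, :]  # match sorted map

    genotypes = np.empty((len(iids), m), dtype=np.int8)
    minor_major = np.empty((m, 2), dtype=object)
    for j in range(m):
        col = alleles[:, j, :]
        obs = col[col != "0"]
        labels, counts = np.unique(obs, return_counts=True)
        if len(labels) > 2:
            raise PlinkParseError(
                f"marker {marker_map.marker_id[j]!r}: more than two alleles"
            )
        if len(labels) == 0:
            minor, major = "?", "?"
        elif len(labels) == 1:
            minor, major = labels[0], labels[0]
        else:
            # major = more frequent; ties broken lexicographically for determinism
            if counts[0] == counts[1]:
                major, minor = sorted(labels)
            else:
                major = labels[np.argmax(counts)]
                minor = labels[np.argmin(counts)]
        minor_major[j] = (minor, major)
        miss = (col[:, 0] == "0") | (col[:, 1] == "0")
        dose = (col[:, 0] == minor).astype(np.int8) + (col[:, 1] == minor).astype(
            np.int8
        )
        if len(labels) == 1:
            dose = np.zeros(len(iids), dtype=np.int8)
        genotypes[:, j] = np.where(miss, MISSING, dose)

    sex = np.array(
        [{"1": "M", "2": "F"}.get(s, "U") for s in sexes], dtype=object
    )
    return GenotypeMatrix(
        genotypes=genotypes,
        individual_ids=np.array(iids, dtype=object),
        breed_labels=np.array(fams, dtype=object),
        map=marker_map,
        sex=sex,
        allele_names=minor_major,
    )


def write_plink(gm: GenotypeMatrix, ped_path, map_path) -> None:
    """Write a GenotypeMatrix as PLINK text, coding minor/major as A/B."""
    with open(map_path, "w") as fh:
        cm = (
            gm.map.genetic_pos_cM
            if gm.map.genetic_pos_cM is not None
            else np.zeros(len(gm.map))
        )
        for c, mid, g, bp in zip(
            gm.map.chromosome, gm.map.marker_id, cm, gm.map.position_bp
        ):
            fh.write(f"{c}\t{mid}\t{g:g}\t{bp}\n")
    if gm.allele_names is not None:
        names = gm.allele_names
    else:
        names = np.array([("A", "B")] * gm.n_markers, dtype=object)
    sex_code = {"M": "1", "F": "2"}
    with open(ped_path, "w") as fh:
        for i in range(gm.n_individuals):
            sx = "0"
            if gm.sex is not None:
                sx = sex_code.get(gm.sex[i], "0")
            fields = [
                str(gm.breed_labels[i]),
                str(gm.individual_ids[i]),
                "0",
                "0",
                sx,
                "-9",
            ]
            row = gm.genotypes[i]
            for j, g in enumerate(row):
                minor, major = names[j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [major, major]
                elif g == 1:
                    fields += [minor, major]
                else:
                    fields += [minor, minor]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(tsv_path) -> PhenotypeTable:
    """Read a phenotype TSV (individual_id, breed, trait, value[, age_years]).

    Non-numeric values raise with the offending row number, except the
    literal ``NA`` which drops the record with a warning.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    required = {"individual_id", "breed", "trait", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{tsv_path}: missing columns {sorted(missing)}")

    na_mask = df["value"].isin(["NA", ""])
    if na_mask.any():
        warnings.warn(
            f"{tsv_path}: dropped {int(na_mask.sum())} record(s) with NA value",
            stacklevel=2,
        )
        df = df[~na_mask]
    values = np.empty(len(df), dtype=float)
    for k, (row_idx, raw) in enumerate(df["value"].items()):
        try:
            values[k] = float(raw)
        except ValueError:
            raise ValueError(
                f"{tsv_path}: row {row_idx + 2}: non-numeric value {raw!r}"
            ) from None
    out = pd.DataFrame(
        {
            "individual_id": df["individual_id"].to_numpy(),
            "breed": df["breed"].to_numpy(),
            "trait": df["trait"].to_numpy(),
            "value": values,
        }
    )
    if "age_years" in df.columns:
        age = pd.to_numeric(df["age_years"].replace({"": np.nan, "NA": np.nan}))
        out["age_years"] = age.to_numpy()
    return PhenotypeTable(out.reset_index(drop=True))


def write_phenotypes(table: PhenotypeTable, tsv_path) -> None:
    df = table.records.copy()
    df.to_csv(tsv_path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Segments / association output
# ---------------------------------------------------------------------------

def write_segments_bed(segments: Iterable, path) -> None:
    """Write autozygosity segments as BED (0-based, half-open).

    Internal coordinates are 1-based inclusive; each segment becomes
    ``chrom  start_bp-1  end_bp  individual_id``, sorted by (chrom, start).
    """
    rows = []
    for seg in segments:
        if seg.end_bp <= seg.start_bp:
            raise ValueError(
                f"segment end {seg.end_bp} <= start {seg.start_bp} "
                f"({seg.individual_id})"
            )
        rows.append(
            (str(seg.chromosome), seg.start_bp - 1, seg.end_bp, seg.individual_id)
        )
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        for chrom, start, end, name in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def write_association_tsv(result, path) -> None:
    """Write an association result table (marker_id, chrom, pos, stat, p, method)."""
    result.to_frame().to_csv(path, sep="\t", index=False)
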
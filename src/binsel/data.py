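"""Domain containers and delimited-text I/O.

Genotypes are coded per locus as AA = +1, Aa = 0, aa = -1, so that in an F2
population the indicator has mean 0 and variance 1/2.  Missing calls are held
as NaN in a float matrix.  All tables are plain delimited text (TSV/CSV,
autodetected) so that datasets round-trip losslessly through files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "GenotypeMatrix",
    "PhenotypeVector",
    "CovariateTable",
    "read_marker_map",
    "write_marker_map",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
]

MISSING = np.nan
_VALID_CODES = (-1.0, 0.0, 1.0)


def _sniff_sep(path) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker coordinates defining the genome.

    Markers must be strictly sorted within chromosome by position (genetic
    position when present, otherwise physical), with unique ids and
    non-negative coordinates.
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    genetic_pos: np.ndarray | None = None  # cM
    physical_pos: np.ndarray | None = None  # bp

    def __post_init__(self):
        mid = np.asarray(self.marker_id, dtype=object)
        chrom = np.asarray(self.chromosome, dtype=object)
        object.__setattr__(self, "marker_id", mid)
        object.__setattr__(self, "chromosome", chrom)
        if self.genetic_pos is not None:
            object.__setattr__(
                self, "genetic_pos", np.asarray(self.genetic_pos, dtype=float)
            )
        if self.physical_pos is not None:
            object.__setattr__(
                self, "physical_pos", np.asarray(self.physical_pos, dtype=float)
            )
        if self.genetic_pos is None and self.physical_pos is None:
            raise ValueError("marker map needs genetic and/or physical positions")
        if len(set(mid)) != len(mid):
            raise ValueError("marker ids are not unique")
        pos = self.positions("cM" if self.genetic_pos is not None else "bp")
        if np.any(pos < 0):
            raise ValueError("marker positions must be non-negative")
        for c in self.chromosomes:
            p = pos[chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(
                    f"markers on chromosome {c!r} not strictly sorted by position"
                )

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    @property
    def chromosomes(self) -> list:
        # preserve order of first appearance
        return list(dict.fromkeys(self.chromosome))

    def positions(self, unit: str) -> np.ndarray:
        """Marker coordinates in ``unit`` ('cM' or 'bp')."""
        if unit == "cM":
            if self.genetic_pos is None:
                raise ValueError("map has no genetic (cM) positions")
            return self.genetic_pos
        if unit == "bp":
            if self.physical_pos is None:
                raise ValueError("map has no physical (bp) positions")
            return self.physical_pos
        raise ValueError(f"unknown unit {unit!r}")

    def chromosome_slices(self) -> dict:
        """Contiguous index range per chromosome (markers are map-ordered)."""
        out = {}
        chrom = self.chromosome
        for c in self.chromosomes:
            idx = np.flatnonzero(chrom == c)
            out[c] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    def subset(self, keep: np.ndarray) -> "MarkerMap":
        return MarkerMap(
            self.marker_id[keep],
            self.chromosome[keep],
            None if self.genetic_pos is None else self.genetic_pos[keep],
            None if self.physical_pos is None else self.physical_pos[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        d = {"marker_id": self.marker_id, "chromosome": self.chromosome}
        if self.genetic_pos is not None:
            d["cM"] = self.genetic_pos
        if self.physical_pos is not None:
            d["bp"] = self.physical_pos
        return pd.DataFrame(d)


@dataclass
class GenotypeMatrix:
    """n individuals x p markers, coded {-1, 0, +1} with NaN missing.

    After marker-mean imputation entries may be fractional (in [-1, 1]);
    ``imputed=True`` relaxes the integer-code check accordingly.
    """

    values: np.ndarray
    individual_ids: np.ndarray
    imputed: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D")
        n, p = self.values.shape
        if n < 2 or p < 1:
            raise ValueError("need at least 2 individuals and 1 marker")
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length mismatch")
        if self.imputed:
            ok = np.abs(self.values) <= 1
        else:
            ok = np.isnan(self.values) | np.isin(self.values, _VALID_CODES)
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(
                f"invalid genotype code {self.values[tuple(bad)]!r} at "
                f"row {bad[0]}, column {bad[1]}"
            )

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())


@dataclass
class PhenotypeVector:
    """One trait value per individual, optionally covariate-adjusted."""

    values: np.ndarray
    individual_ids: np.ndarray | None = None
    adjusted: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("phenotype values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phenotype values must be finite")
        if self.individual_ids is not None:
            self.individual_ids = np.asarray(self.individual_ids, dtype=object)
            if len(self.individual_ids) != len(self.values):
                raise ValueError("individual_ids length mismatch")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def variance(self) -> float:
        """Sample variance (ddof=1) of the trait."""
        return float(np.var(self.values, ddof=1))


@dataclass
class CovariateTable:
    """Per-individual co-factors (categorical or numeric), row-aligned with
    the phenotype vector."""

    table: pd.DataFrame

    def __post_init__(self):
        if not isinstance(self.table, pd.DataFrame):
            self.table = pd.DataFrame(self.table)

    def __len__(self) -> int:
        return len(self.table)

    def design_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Intercept + treatment-coded dummies for categoricals, numerics as-is."""
        cols = [("(Intercept)", np.ones(len(self.table)))]
        for name in self.table.columns:
            col = self.table[name]
            if col.dtype.kind in "OUSb" or isinstance(
                col.dtype, pd.CategoricalDtype
            ):
                dummies = pd.get_dummies(col, prefix=name, drop_first=True)
                for dname in dummies.columns:
                    cols.append((dname, dummies[dname].to_numpy(dtype=float)))
            else:
                cols.append((name, col.to_numpy(dtype=float)))
        names = [c[0] for c in cols]
        X = np.column_stack([c[1] for c in cols])
        return X, names


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_marker_map(path) -> MarkerMap:
    """Read a map table with columns marker_id, chromosome, cM and/or bp."""
    df = pd.read_csv(path, sep=_sniff_sep(path))
    required = {"marker_id", "chromosome"}
    if not required.issubset(df.columns):
        raise ValueError(f"map file must have columns {sorted(required)}")
    return MarkerMap(
        df["marker_id"].astype(str).to_numpy(dtype=object),
        df["chromosome"].astype(str).to_numpy(dtype=object),
        df["cM"].to_numpy(dtype=float) if "cM" in df else None,
        df["bp"].to_numpy(dtype=float) if "bp" in df else None,
    )


def write_marker_map(path, mmap: MarkerMap) -> None:
    mmap.to_frame().to_csv(path, sep="\t", index=False)


def read_genotypes(
    path,
    mmap: MarkerMap,
    coding: str = "dosage_012",
    missing_token: str = "NA",
) -> GenotypeMatrix:
    """Read a genotype table (row = individual, first column = id).

    ``coding='dosage_012'`` recodes 0/1/2 allele counts to -1/0/+1;
    ``coding='plus_minus_one'`` takes values as already coded.  Columns are
    conformed to the map order; markers absent from the map (or vice versa)
    are a hard error.
    """
    if coding not in ("dosage_012", "plus_minus_one"):
        raise ValueError(f"unknown coding {coding!r}")
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    ids = df.iloc[:, 0].to_numpy(dtype=object)
    df = df.iloc[:, 1:]
    file_markers = list(df.columns)
    map_markers = list(mmap.marker_id)
    if set(file_markers) != set(map_markers):
        missing = set(map_markers) - set(file_markers)
        extra = set(file_markers) - set(map_markers)
        raise ValueError(
            f"genotype columns do not match map: missing {sorted(missing)[:5]}, "
            f"unexpected {sorted(extra)[:5]}"
        )
    df = df[map_markers]  # conform column order to the map

    valid = {"0", "1", "2"} if coding == "dosage_012" else {"-1", "0", "1"}
    raw = df.to_numpy(dtype=object)
    vals = np.full(raw.shape, np.nan)
    for j, tok in np.ndenumerate(raw):
        t = str(tok).strip()
        if t == missing_token or t == "":
            continue
        # accept float-ish spellings such as "1.0"
        t2 = t[:-2] if t.endswith(".0") else t
        if t2 not in valid:
            raise ValueError(
                f"unknown genotype token {t!r} at row {j[0]} "
                f"(individual {ids[j[0]]!r}), column {map_markers[j[1]]!r}"
            )
        vals[j] = float(t2)
    if coding == "dosage_012":
        vals = vals - 1.0  # 0/1/2 copies -> -1/0/+1
    return GenotypeMatrix(vals, ids)


def write_genotypes(
    path,
    G: GenotypeMatrix,
    mmap: MarkerMap,
    coding: str = "plus_minus_one",
    missing_token: str = "NA",
) -> None:
    vals = G.values
    if coding == "dosage_012":
        vals = vals + 1.0
    elif coding != "plus_minus_one":
        raise ValueError(f"unknown coding {coding!r}")
    buf = io.StringIO()
    buf.write("individual_id\t" + "\t".join(map(str, mmap.marker_id)) + "\n")
    for i, ind in enumerate(G.individual_ids):
        row = [
            missing_token if np.isnan(v) else str(int(v)) for v in vals[i]
        ]
        buf.write(str(ind) + "\t" + "\t".join(row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_phenotypes(
    path, trait: str | None = None
) -> tuple[PhenotypeVector, CovariateTable | None]:
    """Read a phenotype/covariate table keyed by an individual-id column.

    The first column is the id; ``trait`` names the trait column (default:
    the first non-id column).  Any remaining columns become covariates.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path))
    ids = df.iloc[:, 0].astype(str).to_numpy(dtype=object)
    body = df.iloc[:, 1:]
    if trait is None:
        trait = body.columns[0]
    y = PhenotypeVector(body[trait].to_numpy(dtype=float), ids)
    rest = body.drop(columns=[trait])
    cov = CovariateTable(rest) if rest.shape[1] else None
    return y, cov


def write_phenotypes(
    path, y: PhenotypeVector, covariates: CovariateTable | None = None
) -> None:
    ids = (
        y.individual_ids
        if y.individual_ids is not None
        else np.array([f"ind{i + 1}" for i in range(len(y))], dtype=object)
    )
    df = pd.DataFrame({"individual_id": ids, "trait": y.values})
    if covariates is not None:
        df = pd.concat([df, covariates.table.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False)
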
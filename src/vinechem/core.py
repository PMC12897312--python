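"""Core domain types for Vis-NIR spectral datasets.

A dataset pairs a wide reflectance matrix (samples x wavelengths) with a
reference table of wet-chemistry indicator values. Spectra are exchanged as
plain CSV: first column ``sample_id``, remaining column headers the
wavelengths in nm; the reference CSV carries ``sample_id`` plus one column
per indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

#: Canonical indicator names and their measurement units.
INDICATORS: dict[str, str] = {
    "pH": "unitless",
    "TSS": "degBrix",
    "TA": "g/L",
    "RS": "g/L",
    "TPCN": "mg GAE/g",
    "TPCD": "mg GAE/g",
}


class DatasetError(ValueError):
    """Raised when a spectra/reference pair violates a structural invariant."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nm."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise DatasetError("wavelength grid needs at least 2 points")
        if not np.all(np.diff(values) > 0):
            raise DatasetError("wavelengths must be strictly increasing")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def step(self) -> float:
        """Median grid spacing in nm (grids need not be exactly uniform)."""
        return float(np.median(np.diff(self.values)))


@dataclass(frozen=True)
class SpectraMatrix:
    """Reflectance matrix with aligned sample ids and wavelength grid."""

    sample_ids: tuple[str, ...]
    grid: WavelengthGrid
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(str(s) for s in self.sample_ids)
        refl = np.asarray(self.reflectance, dtype=float)
        if refl.ndim != 2:
            raise DatasetError("reflectance must be a 2-D matrix")
        if refl.shape[0] != len(ids):
            raise DatasetError(
                f"{len(ids)} sample ids but {refl.shape[0]} spectra rows"
            )
        if refl.shape[1] != len(self.grid):
            raise DatasetError(
                f"{refl.shape[1]} columns but grid has {len(self.grid)} wavelengths"
            )
        if len(set(ids)) != len(ids):
            raise DatasetError("sample ids must be unique")
        if not np.all(np.isfinite(refl)):
            raise DatasetError("reflectance contains non-finite values")
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "reflectance", refl)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.reflectance, columns=[repr(float(w)) for w in self.grid.values]
        )
        df.insert(0, "sample_id", list(self.sample_ids))
        return df


@dataclass(frozen=True)
class ReferenceTable:
    """Per-sample wet-chemistry values for the quality indicators."""

    sample_ids: tuple[str, ...]
    values: pd.DataFrame  # columns are indicator names, rows align with ids

    def __post_init__(self) -> None:
        ids = tuple(str(s) for s in self.sample_ids)
        df = self.values.reset_index(drop=True).astype(float)
        unknown = [c for c in df.columns if c not in INDICATORS]
        if unknown:
            raise DatasetError(f"unknown indicator columns: {unknown}")
        if df.empty or len(df.columns) == 0:
            raise DatasetError("reference table needs at least one indicator")
        if len(df) != len(ids):
            raise DatasetError("reference row count does not match sample ids")
        if len(set(ids)) != len(ids):
            raise DatasetError("sample ids must be unique")
        if not np.all(np.isfinite(df.to_numpy())):
            raise DatasetError("reference values must be finite")
        for col in df.columns:
            if col != "pH" and (df[col] < 0).any():
                raise DatasetError(f"negative values in indicator {col}")
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "values", df)

    def indicator(self, name: str) -> np.ndarray:
        if name not in self.values.columns:
            raise DatasetError(f"indicator {name!r} not in reference table")
        return self.values[name].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        df = self.values.copy()
        df.insert(0, "sample_id", list(self.sample_ids))
        return df


@dataclass(frozen=True)
class Dataset:
    """A validated (spectra, references) pair with identical sample order."""

    spectra: SpectraMatrix
    references: ReferenceTable

    def __post_init__(self) -> None:
        if self.spectra.sample_ids != self.references.sample_ids:
            raise DatasetError("spectra and reference sample ids are not aligned")

    @property
    def n_samples(self) -> int:
        return self.spectra.n_samples


# ---------------------------------------------------------------------------
# CSV I/O


def write_spectra_csv(spectra: SpectraMatrix, path: str | Path) -> None:
    # %.17g round-trips IEEE doubles exactly
    spectra.to_frame().to_csv(path, index=False, float_format="%.17g")


def write_reference_csv(references: ReferenceTable, path: str | Path) -> None:
    references.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_spectra_csv(path: str | Path) -> SpectraMatrix:
    df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
    if df.columns[0] != "sample_id":
        raise DatasetError("first spectra column must be 'sample_id'")
    try:
        wavelengths = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise DatasetError(f"non-numeric wavelength header: {exc}") from None
    return SpectraMatrix(
        sample_ids=tuple(df["sample_id"]),
        grid=WavelengthGrid(wavelengths),
        reflectance=df.iloc[:, 1:].to_numpy(float),
    )


def read_reference_csv(path: str | Path) -> ReferenceTable:
    df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
    if df.columns[0] != "sample_id":
        raise DatasetError("first reference column must be 'sample_id'")
    return ReferenceTable(
        sample_ids=tuple(df["sample_id"]),
        values=df.iloc[:, 1:],
    )


def read_dataset(spectra_path: str | Path, reference_path: str | Path) -> Dataset:
    """Load and validate a spectra/reference CSV pair.

    Rows of both tables are reordered to the id-sorted canonical order; ids
    present in one file but not the other abort with an error naming them.
    """
    spectra = read_spectra_csv(spectra_path)
    references = read_reference_csv(reference_path)
    sids, rids = set(spectra.sample_ids), set(references.sample_ids)
    if sids != rids:
        orphans = sorted(sids.symmetric_difference(rids))
        raise DatasetError(f"sample ids present in only one file: {orphans}")
    order = sorted(range(len(spectra.sample_ids)), key=lambda i: spectra.sample_ids[i])
    spectra = SpectraMatrix(
        sample_ids=tuple(spectra.sample_ids[i] for i in order),
        grid=spectra.grid,
        reflectance=spectra.reflectance[order],
    )
    ref_order = sorted(
        range(len(references.sample_ids)), key=lambda i: references.sample_ids[i]
    )
    references = ReferenceTable(
        sample_ids=tuple(references.sample_ids[i] for i in ref_order),
        values=references.values.iloc[ref_order],
    )
    return Dataset(spectra=spectra, references=references)


# ---------------------------------------------------------------------------
# Replicate handling


def select_representative(replicates: SpectraMatrix | np.ndarray) -> int:
    """Index of the medoid replicate spectrum.

    Repeated measurements of one sample are condensed to the spectrum with
    the least total Euclidean deviation from all other replicates (the
    medoid). Ties break to the lowest index.
    """
    rows = (
        replicates.reflectance
        if isinstance(replicates, SpectraMatrix)
        else np.asarray(replicates, dtype=float)
    )
    if rows.ndim != 2 or rows.shape[0] == 0:
        raise DatasetError("need at least one replicate row")
    if rows.shape[0] == 1:
        return 0
    dist = squareform(pdist(rows, metric="euclidean"))
    return int(np.argmin(dist.sum(axis=1)))
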
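"""Spectra dataset types and the on-disk CSV dialect.

A dataset is a directory holding two UTF-8 CSV files:

``spectra.csv``
    long format, columns ``pair_id, organ, acq_index, wavelength_nm, counts``
``references.csv``
    columns ``wavelength_nm, dark, white``

All spectra share the reference grid. Organ labels are the lower-case
strings ``"trachea"`` / ``"esophagus"``. Floats are written with 12
significant digits, so a write/read round trip preserves values well past
the 9-significant-digit contract.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "TRACHEA",
    "ESOPHAGUS",
    "ORGANS",
    "ANALYSIS_BAND",
    "FormatError",
    "ValidationError",
    "AcquisitionMeta",
    "RawSpectrum",
    "ReferenceSet",
    "SpectraDataset",
    "validate_grid",
    "read_dataset",
    "write_dataset",
]

TRACHEA = "trachea"
ESOPHAGUS = "esophagus"
ORGANS = (TRACHEA, ESOPHAGUS)

#: Wavelength band (nm) actually used by the analysis: the oxyhemoglobin
#: trough-peak-trough at 543/561/578 nm plus the flanking error-bar
#: wavelengths 535 and 585 nm.
ANALYSIS_BAND = (535.0, 585.0)

_FLOAT_FMT = "%.12g"

SPECTRA_FILE = "spectra.csv"
REFERENCES_FILE = "references.csv"


class FormatError(ValueError):
    """File does not conform to the documented CSV dialect."""


class ValidationError(ValueError):
    """Data violates a dataset invariant (grid order, uniqueness, ...)."""


def validate_grid(grid: np.ndarray, *, require_band: bool = True) -> np.ndarray:
    """Check that a wavelength grid is strictly increasing and covers the
    analysis band. Returns the grid as a float array."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValidationError("wavelength grid must be a 1-D array of length >= 2")
    if not np.all(np.isfinite(grid)):
        raise ValidationError("wavelength grid contains non-finite values")
    if not np.all(np.diff(grid) > 0):
        raise ValidationError("wavelength grid must be strictly increasing")
    if require_band and (grid[0] > ANALYSIS_BAND[0] or grid[-1] < ANALYSIS_BAND[1]):
        raise ValidationError(
            f"wavelength grid [{grid[0]}, {grid[-1]}] nm does not cover the "
            f"analysis band {ANALYSIS_BAND} nm"
        )
    return grid


@dataclasses.dataclass(frozen=True, order=True)
class AcquisitionMeta:
    """Identity of one acquisition: sample pair, organ, and running index.

    The field order (pair_id, organ, acq_index) defines the lexicographic
    order used for deterministic tie-breaking downstream.
    """

    pair_id: int
    organ: str
    acq_index: int

    def __post_init__(self) -> None:
        if self.organ not in ORGANS:
            raise ValidationError(f"unknown organ label {self.organ!r}")
        if self.pair_id < 1 or self.acq_index < 1:
            raise ValidationError("pair_id and acq_index are 1-based positive integers")


@dataclasses.dataclass
class RawSpectrum:
    """Raw detector counts for one acquisition on a wavelength grid."""

    grid: np.ndarray
    counts: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.grid = validate_grid(self.grid)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != self.grid.shape:
            raise ValidationError("counts length must equal grid length")
        if not np.all(np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise ValidationError("counts must be finite and non-negative")


@dataclasses.dataclass
class ReferenceSet:
    """Paired dark and white reference spectra on a shared grid.

    The white reference must exceed the dark reference everywhere inside
    the analysis band; outside the band degenerate points are tolerated
    (they are flagged during reference correction).
    """

    grid: np.ndarray
    dark: np.ndarray
    white: np.ndarray

    def __post_init__(self) -> None:
        self.grid = validate_grid(self.grid)
        self.dark = np.asarray(self.dark, dtype=float)
        self.white = np.asarray(self.white, dtype=float)
        if self.dark.shape != self.grid.shape or self.white.shape != self.grid.shape:
            raise ValidationError("dark/white length must equal grid length")
        lo, hi = ANALYSIS_BAND
        band = (self.grid >= lo) & (self.grid <= hi)
        if np.any(self.white[band] <= self.dark[band]):
            raise ValidationError(
                "white reference must exceed dark reference inside the "
                f"analysis band {ANALYSIS_BAND} nm"
            )


@dataclasses.dataclass
class SpectraDataset:
    """A collection of raw spectra sharing one reference set."""

    spectra: list[RawSpectrum]
    references: ReferenceSet
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[AcquisitionMeta] = set()
        for s in self.spectra:
            if s.grid.shape != self.references.grid.shape or not np.array_equal(
                s.grid, self.references.grid
            ):
                raise ValidationError(
                    f"spectrum {s.meta} grid differs from the reference grid"
                )
            if s.meta in seen:
                raise ValidationError(f"duplicate acquisition metadata {s.meta}")
            seen.add(s.meta)

    def __len__(self) -> int:
        return len(self.spectra)


def _require_columns(df: pd.DataFrame, cols: Iterable[str], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{fname}: missing required column(s) {missing}")


def read_dataset(path: str | Path) -> SpectraDataset:
    """Read a dataset directory written in the documented CSV dialect.

    Raises :class:`FormatError` for missing files/columns and
    :class:`ValidationError` for invariant violations.
    """
    path = Path(path)
    ref_file = path / REFERENCES_FILE
    spec_file = path / SPECTRA_FILE
    if not ref_file.is_file():
        raise FormatError(f"missing {REFERENCES_FILE} in {path}")
    if not spec_file.is_file():
        raise FormatError(f"missing {SPECTRA_FILE} in {path}")

    refs_df = pd.read_csv(ref_file)
    _require_columns(refs_df, ("wavelength_nm", "dark", "white"), REFERENCES_FILE)
    references = ReferenceSet(
        grid=refs_df["wavelength_nm"].to_numpy(float),
        dark=refs_df["dark"].to_numpy(float),
        white=refs_df["white"].to_numpy(float),
    )

    spec_df = pd.read_csv(spec_file)
    _require_columns(
        spec_df,
        ("pair_id", "organ", "acq_index", "wavelength_nm", "counts"),
        SPECTRA_FILE,
    )
    spectra: list[RawSpectrum] = []
    if len(spec_df):
        for (pair_id, organ, acq_index), grp in spec_df.groupby(
            ["pair_id", "organ", "acq_index"], sort=True
        ):
            grp = grp.sort_values("wavelength_nm")
            spectra.append(
                RawSpectrum(
                    grid=grp["wavelength_nm"].to_numpy(float),
                    counts=grp["counts"].to_numpy(float),
                    meta=AcquisitionMeta(int(pair_id), str(organ), int(acq_index)),
                )
            )

    prov_file = path / "provenance.txt"
    provenance = prov_file.read_text() if prov_file.is_file() else ""
    return SpectraDataset(spectra=spectra, references=references, provenance=provenance)


def write_dataset(ds: SpectraDataset, path: str | Path) -> None:
    """Write a dataset to ``path`` (created if absent) in the CSV dialect."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    refs_df = pd.DataFrame(
        {
            "wavelength_nm": ds.references.grid,
            "dark": ds.references.dark,
            "white": ds.references.white,
        }
    )
    refs_df.to_csv(path / REFERENCES_FILE, index=False, float_format=_FLOAT_FMT)

    frames = []
    for s in ds.spectra:
        frames.append(
            pd.DataFrame(
                {
                    "pair_id": s.meta.pair_id,
                    "organ": s.meta.organ,
                    "acq_index": s.meta.acq_index,
                    "wavelength_nm": s.grid,
                    "counts": s.counts,
                }
            )
        )
    if frames:
        spec_df = pd.concat(frames, ignore_index=True)
    else:
        spec_df = pd.DataFrame(
            columns=["pair_id", "organ", "acq_index", "wavelength_nm", "counts"]
        )
    spec_df.to_csv(path / SPECTRA_FILE, index=False, float_format=_FLOAT_FMT)

    if ds.provenance:
        (path / "provenance.txt").write_text(ds.provenance)
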
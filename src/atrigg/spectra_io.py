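"""Plain-text spectrum and manifest I/O.

Replicate ATR spectra are stored as two-column PRN files (wavenumber,
absorbance; one point per line, wavenumbers descending — the spectroscopy
axis convention).  A CSV manifest links spectrum files to sample metadata
(reference IgG in mg/dL, RID kit, animal class).  "PRN" is not a rigorous
standard: whitespace- or comma-delimited input is accepted, tab-delimited
output is written.  GRAMS SPC binary is deliberately unsupported.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import SyntheticDataset

__all__ = [
    "WavenumberGrid",
    "Spectrum",
    "SampleRecord",
    "PRNFormatError",
    "write_prn",
    "read_prn",
    "write_manifest",
    "read_manifest",
    "write_dataset",
]

MANIFEST_COLUMNS = ("sample_id", "replicate_id", "path", "igg_reference", "kit", "animal_class")

ANIMAL_CLASSES = ("calf", "cow", "pre_colostrum")
KITS = ("standard", "ultra_low")

# float format that round-trips IEEE doubles exactly, so a write->read->write
# cycle is byte-identical
_FLOAT_FMT = "%.17g"


class PRNFormatError(ValueError):
    """Raised for malformed PRN spectrum files."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Shared wavenumber axis in cm^-1, stored in descending order.

    ``spacing`` is the nominal point spacing (positive, cm^-1 per point);
    the final point may be clamped (e.g. to 650 cm^-1) so the actual last
    step can be smaller than nominal.
    """

    values: np.ndarray
    spacing: float | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("grid needs at least 2 points")
        if not np.all(np.isfinite(values)):
            raise ValueError("grid contains non-finite wavenumbers")
        if not np.all(np.diff(values) < 0):
            raise ValueError("grid must be strictly descending")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        if self.spacing is not None and self.spacing <= 0:
            raise ValueError("spacing must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def span(self) -> tuple[float, float]:
        """(high, low) endpoints in cm^-1."""
        return float(self.values[0]), float(self.values[-1])

    def isclose(self, other: "WavenumberGrid", rtol: float = 1e-9) -> bool:
        return len(self) == len(other) and bool(
            np.allclose(self.values, other.values, rtol=rtol, atol=0.0)
        )


@dataclass(frozen=True)
class Spectrum:
    """One replicate's absorbance vector, aligned to a WavenumberGrid."""

    sample_id: str
    replicate_id: int
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.absorbance, dtype=float)
        if a.ndim != 1:
            raise ValueError("absorbance must be a 1-D vector")
        object.__setattr__(self, "absorbance", a)
        if self.replicate_id < 1:
            raise ValueError("replicate_id is 1-based")


@dataclass(frozen=True)
class SampleRecord:
    """Sample identity plus the RID reference measurement.

    ``kit`` names the radial-immunodiffusion kit whose working range governs
    exclusion: ``standard`` (196–2748 mg/dL) or ``ultra_low`` (10–100 mg/dL,
    used for pre-colostral samples). ``in_range`` is derived by the pipeline.
    """

    sample_id: str
    animal_class: str
    igg_reference: float
    kit: str = "standard"
    in_range: bool | None = None

    def __post_init__(self) -> None:
        if self.igg_reference < 0:
            raise ValueError("igg_reference must be >= 0 mg/dL")
        if self.animal_class not in ANIMAL_CLASSES:
            raise ValueError(f"unknown animal_class {self.animal_class!r}")
        if self.kit not in KITS:
            raise ValueError(f"unknown kit {self.kit!r}")

    def with_in_range(self, flag: bool) -> "SampleRecord":
        return replace(self, in_range=flag)


# ---------------------------------------------------------------------------
# PRN spectrum files
# ---------------------------------------------------------------------------

def write_prn(spectrum: Spectrum | np.ndarray, grid: WavenumberGrid, destination) -> None:
    """Write one spectrum as two-column text (wavenumber TAB absorbance).

    Values are formatted so that doubles round-trip exactly; a second
    write->read->write generation is byte-identical.
    """
    absorbance = spectrum.absorbance if isinstance(spectrum, Spectrum) else np.asarray(spectrum, float)
    if absorbance.shape != (len(grid),):
        raise ValueError(
            f"absorbance length {absorbance.size} does not match grid length {len(grid)}"
        )
    if not np.all(np.isfinite(absorbance)):
        raise ValueError("absorbance contains non-finite values")
    lines = [
        (_FLOAT_FMT % w) + "\t" + (_FLOAT_FMT % a) + "\n"
        for w, a in zip(grid.values, absorbance)
    ]
    data = "".join(lines)
    if hasattr(destination, "write"):
        destination.write(data)
    else:
        Path(destination).write_text(data)


def _parse_prn_line(line: str) -> tuple[float, float] | None:
    fields = line.replace(",", " ").split()
    if len(fields) != 2:
        raise ValueError("expected two columns")
    return float(fields[0]), float(fields[1])


def read_prn(source) -> tuple[WavenumberGrid, np.ndarray]:
    """Read a two-column PRN spectrum.

    Blank lines and a single leading non-numeric header line are tolerated;
    comma or whitespace delimiters both work.  Ascending files are re-ordered
    to the canonical descending grid with absorbances permuted in lockstep.
    """
    if hasattr(source, "read"):
        text = source.read()
        name = getattr(source, "name", "<stream>")
    else:
        text = Path(source).read_text()
        name = str(source)

    wavenumbers: list[float] = []
    absorbances: list[float] = []
    header_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        try:
            w, a = _parse_prn_line(line)
        except ValueError:
            if not wavenumbers and not header_seen:
                header_seen = True  # one optional header line
                continue
            raise PRNFormatError(f"{name}: non-numeric data on line {lineno}: {raw!r}") from None
        wavenumbers.append(w)
        absorbances.append(a)

    if len(wavenumbers) < 2:
        raise PRNFormatError(f"{name}: fewer than 2 data points")
    w_arr = np.asarray(wavenumbers)
    a_arr = np.asarray(absorbances)
    if np.unique(w_arr).size != w_arr.size:
        raise PRNFormatError(f"{name}: duplicate wavenumbers")
    order = np.argsort(-w_arr, kind="stable")
    return WavenumberGrid(w_arr[order]), a_arr[order]


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def write_manifest(rows: Iterable[dict], destination) -> None:
    """Write a manifest CSV with the canonical column order."""
    frame = pd.DataFrame(list(rows))
    missing = set(MANIFEST_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"manifest rows missing columns: {sorted(missing)}")
    frame[list(MANIFEST_COLUMNS)].to_csv(destination, index=False)


def read_manifest(
    source,
) -> tuple[list[SampleRecord], WavenumberGrid, dict[str, np.ndarray]]:
    """Read a manifest CSV and all spectra it references.

    Returns sample records (one per sample), the shared grid, and a mapping
    sample_id -> (n_replicates, n_points) absorbance matrix with rows ordered
    by replicate_id.  Spectrum paths are resolved relative to the manifest.
    Errors: missing columns, missing files, grid mismatch across files.
    A varying replicate count across samples is a warning, not an error.
    """
    path = Path(source)
    frame = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")

    base = path.parent
    records: list[SampleRecord] = []
    spectra: dict[str, np.ndarray] = {}
    grid: WavenumberGrid | None = None
    counts: set[int] = set()

    for sample_id, group in frame.groupby("sample_id", sort=False):
        group = group.sort_values("replicate_id")
        first = group.iloc[0]
        records.append(
            SampleRecord(
                sample_id=str(sample_id),
                animal_class=str(first["animal_class"]),
                igg_reference=float(first["igg_reference"]),
                kit=str(first["kit"]),
            )
        )
        rows = []
        for _, row in group.iterrows():
            spath = base / str(row["path"])
            if not spath.exists():
                raise FileNotFoundError(f"manifest references missing spectrum file: {spath}")
            g, a = read_prn(spath)
            if grid is None:
                grid = g
            elif not grid.isclose(g):
                raise ValueError(f"grid mismatch in {spath}: all spectra must share one grid")
            rows.append(a)
        spectra[str(sample_id)] = np.vstack(rows)
        counts.add(len(rows))

    if grid is None:
        raise ValueError("manifest contains no samples")
    if len(counts) > 1:
        warnings.warn(
            f"replicate count varies across samples: {sorted(counts)}", stacklevel=2
        )
    return records, grid, spectra


def write_dataset(dataset: "SyntheticDataset", outdir) -> Path:
    """Write a simulated dataset as PRN files plus manifest.csv; returns the
    manifest path."""
    outdir = Path(outdir)
    spectra_dir = outdir / "spectra"
    spectra_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for record, replicate_matrix in zip(dataset.samples, dataset.spectra):
        for j, absorbance in enumerate(replicate_matrix, start=1):
            rel = Path("spectra") / f"{record.sample_id}_r{j}.prn"
            write_prn(absorbance, dataset.grid, outdir / rel)
            rows.append(
                {
                    "sample_id": record.sample_id,
                    "replicate_id": j,
                    "path": rel.as_posix(),
                    "igg_reference": record.igg_reference,
                    "kit": record.kit,
                    "animal_class": record.animal_class,
                }
            )
    manifest = outdir / "manifest.csv"
    write_manifest(rows, manifest)
    return manifest
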
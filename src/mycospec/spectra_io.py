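"""Spectral containers and I/O.

A spectral block is a set of spectra recorded on one shared wavenumber grid
(stored descending, the instrument convention), together with per-sample
design metadata (strain, phosphate level, calcium level, biological and
technical replicate, laser power) and, optionally, reference chemistry
(total lipids and phosphorus in % dry weight, carotenoids in µg/g dry
weight).

On-disk layout is a wide CSV (one row per spectrum, columns = wavenumbers in
cm⁻¹, first column = sample id) with sidecar metadata/chemistry CSVs keyed
by sample id.  A minimal JCAMP-DX reader (AFFN ``(X++(Y..Y))`` tables) is
provided for single-spectrum exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, SpectraFormatError

#: Columns every metadata table must carry, in canonical order.
META_COLUMNS = [
    "sample_id",
    "strain",
    "pi_level",
    "ca_level",
    "bio_rep",
    "tech_rep",
    "laser_power_mw",
    "block",
]

#: Reference-chemistry columns (paper units: % dry weight, % dry weight, µg/g).
CHEMISTRY_COLUMNS = ["lipid_pct_dw", "phosphorus_pct_dw", "carotenoid_ug_per_g"]

STRAINS = ("Ar", "Mc1", "Mc2", "Mr", "Rs", "Uv")
PI_LEVELS = (0.5, 1.0, 4.0)
CA_LEVELS = (0, 1)

#: Digital spacing of both instruments, cm⁻¹.
DEFAULT_SPACING = 1.928


@dataclass(frozen=True)
class SampleMeta:
    """Acquisition metadata for one spectrum."""

    sample_id: str
    strain: str
    pi_level: float
    ca_level: int
    bio_rep: int
    tech_rep: int
    laser_power_mw: float
    block: str

    def as_dict(self) -> dict:
        return {c: getattr(self, c) for c in META_COLUMNS}


@dataclass
class Spectrum:
    """One wavenumber-indexed intensity vector with acquisition metadata."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: SampleMeta

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.shape != self.intensities.shape:
            raise SpectraFormatError(
                f"spectrum {self.meta.sample_id!r}: wavenumber and intensity "
                f"lengths differ ({self.wavenumbers.size} vs {self.intensities.size})"
            )
        d = np.diff(self.wavenumbers)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise SpectraFormatError(
                f"spectrum {self.meta.sample_id!r}: wavenumbers not strictly monotone"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise SpectraFormatError(
                f"spectrum {self.meta.sample_id!r}: non-finite intensities"
            )


@dataclass
class SpectraSet:
    """An aligned spectral matrix plus per-sample design metadata.

    ``matrix`` is samples × wavenumbers, ``grid`` is shared by all rows and
    stored strictly descending.  ``chemistry`` (optional) is row-aligned with
    ``meta`` and holds reference values in the units of the study.
    """

    grid: np.ndarray
    matrix: np.ndarray
    meta: pd.DataFrame
    chemistry: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)

    # -- invariants ---------------------------------------------------------
    def validate(self) -> "SpectraSet":
        if self.matrix.ndim != 2:
            raise SpectraFormatError("matrix must be 2-D (samples × wavenumbers)")
        n, p = self.matrix.shape
        if self.grid.size != p:
            raise SpectraFormatError(
                f"grid length {self.grid.size} != matrix columns {p}"
            )
        if p > 1:
            d = np.diff(self.grid)
            if not np.all(d < 0):
                raise SpectraFormatError("grid must be strictly descending")
        if len(self.meta) != n:
            raise SpectraFormatError(
                f"metadata rows ({len(self.meta)}) != matrix rows ({n})"
            )
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise SpectraFormatError(f"metadata missing columns: {missing}")
        bad = np.flatnonzero(~np.all(np.isfinite(self.matrix), axis=1))
        if bad.size:
            sid = self.meta["sample_id"].iloc[bad[0]]
            raise SpectraFormatError(
                f"non-finite intensity in row {bad[0]} (sample {sid!r})"
            )
        if self.chemistry is not None:
            if len(self.chemistry) != n:
                raise SpectraFormatError(
                    f"chemistry rows ({len(self.chemistry)}) != matrix rows ({n})"
                )
            vals = self.chemistry[
                [c for c in CHEMISTRY_COLUMNS if c in self.chemistry.columns]
            ].to_numpy(dtype=float)
            if np.any(vals < 0):
                raise SpectraFormatError("chemistry values must be non-negative")
        return self

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_points(self) -> int:
        return self.matrix.shape[1]

    def copy(self) -> "SpectraSet":
        return SpectraSet(
            self.grid.copy(),
            self.matrix.copy(),
            self.meta.reset_index(drop=True).copy(),
            None if self.chemistry is None else self.chemistry.reset_index(drop=True).copy(),
        )

    def with_matrix(self, matrix: np.ndarray, grid: np.ndarray | None = None) -> "SpectraSet":
        """Return a copy carrying a new intensity matrix (and optionally grid)."""
        return SpectraSet(
            self.grid.copy() if grid is None else np.asarray(grid, dtype=float),
            np.asarray(matrix, dtype=float),
            self.meta.reset_index(drop=True).copy(),
            None if self.chemistry is None else self.chemistry.reset_index(drop=True).copy(),
        )

    def select(self, mask) -> "SpectraSet":
        """Row subset by boolean mask or integer index array."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SpectraSet(
            self.grid.copy(),
            self.matrix[idx],
            self.meta.iloc[idx].reset_index(drop=True),
            None if self.chemistry is None else self.chemistry.iloc[idx].reset_index(drop=True),
        )

    def select_strains(self, strains: Sequence[str]) -> "SpectraSet":
        return self.select(self.meta["strain"].isin(list(strains)).to_numpy())

    def bio_ids(self) -> pd.Series:
        """Biological-sample identifier: strain/Pi/Ca/bioreplicate."""
        m = self.meta
        return (
            m["strain"].astype(str)
            + "-Pi" + m["pi_level"].map(lambda v: f"{v:g}")
            + "-Ca" + m["ca_level"].astype(int).astype(str)
            + "-B" + m["bio_rep"].astype(int).astype(str)
        )

    def spectra(self) -> list[Spectrum]:
        out = []
        for i in range(self.n_samples):
            meta = SampleMeta(**{c: self.meta[c].iloc[i] for c in META_COLUMNS})
            out.append(Spectrum(self.grid.copy(), self.matrix[i].copy(), meta))
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}.meta.csv"), Path(f"{stem}.chemistry.csv")


def write_spectra_matrix(sset: SpectraSet, path: str | Path) -> Path:
    """Write a SpectraSet as wide CSV plus metadata/chemistry sidecars.

    Values are written with Python's shortest-roundtrip ``repr`` so that
    ``read_spectra_matrix`` inverts the write bit-exactly.
    """
    sset.validate()
    path = Path(path)
    meta_path, chem_path = _sidecar_paths(path)
    header = "sample_id," + ",".join(repr(float(v)) for v in sset.grid)
    lines = [header]
    ids = sset.meta["sample_id"].tolist()
    for sid, row in zip(ids, sset.matrix):
        lines.append(str(sid) + "," + ",".join(repr(float(v)) for v in row))
    path.write_text("\n".join(lines) + "\n")
    meta = sset.meta[META_COLUMNS].copy()
    meta.to_csv(meta_path, index=False)
    if sset.chemistry is not None:
        chem = sset.chemistry.copy()
        chem.insert(0, "sample_id", ids)
        chem.to_csv(chem_path, index=False)
    return path


def read_spectra_matrix(path: str | Path, format: str = "csv") -> SpectraSet:
    """Read a spectral block from disk.

    ``format="csv"`` expects the wide-matrix layout written by
    :func:`write_spectra_matrix` (sidecars are picked up when present);
    ``format="jcamp"`` expects a directory of single-spectrum JCAMP-DX files.
    """
    path = Path(path)
    if format == "jcamp":
        specs = [read_jcamp(p) for p in sorted(path.glob("*.jdx")) + sorted(path.glob("*.dx"))]
        if not specs:
            raise SpectraFormatError(f"no JCAMP-DX files found under {path}")
        return align_to_common_grid(specs)
    if format != "csv":
        raise SpectraFormatError(f"unknown format {format!r}")
    if not path.exists():
        raise SpectraFormatError(f"no such file: {path}")

    text = path.read_text().strip().splitlines()
    header = text[0].split(",")
    if header[0] != "sample_id":
        raise SpectraFormatError("first column must be 'sample_id'")
    try:
        grid = np.array([float(v) for v in header[1:]])
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric wavenumber in header: {exc}") from exc
    if np.unique(grid).size != grid.size:
        raise SpectraFormatError("duplicate wavenumbers in header")

    ids, rows = [], []
    for i, line in enumerate(text[1:]):
        cells = line.split(",")
        if len(cells) != len(header):
            raise SpectraFormatError(
                f"row {i} (sample {cells[0]!r}): expected {len(header) - 1} "
                f"intensities, found {len(cells) - 1}"
            )
        ids.append(cells[0])
        try:
            rows.append([float(v) for v in cells[1:]])
        except ValueError:
            bad = next(j for j, v in enumerate(cells[1:]) if not _is_float(v))
            raise SpectraFormatError(
                f"row {i} (sample {cells[0]!r}): non-numeric cell in column {bad}"
            ) from None
    matrix = np.array(rows, dtype=float) if rows else np.empty((0, grid.size))
    if matrix.size and not np.all(np.isfinite(matrix)):
        bad = int(np.flatnonzero(~np.all(np.isfinite(matrix), axis=1))[0])
        raise SpectraFormatError(f"row {bad} (sample {ids[bad]!r}): non-finite intensity")

    # normalize to descending wavenumber order
    if grid.size > 1 and grid[0] < grid[-1]:
        grid = grid[::-1].copy()
        matrix = matrix[:, ::-1].copy()

    meta_path, chem_path = _sidecar_paths(path)
    if meta_path.exists():
        meta = pd.read_csv(meta_path)
    else:
        meta = pd.DataFrame(
            {
                "sample_id": ids,
                "strain": "NA",
                "pi_level": np.nan,
                "ca_level": -1,
                "bio_rep": -1,
                "tech_rep": -1,
                "laser_power_mw": np.nan,
                "block": "NA",
            }
        )
    chemistry = None
    if chem_path.exists():
        chem = pd.read_csv(chem_path)
        chemistry = chem.drop(columns=["sample_id"])
    return SpectraSet(grid, matrix, meta, chemistry).validate()


def _is_float(v: str) -> bool:
    try:
        float(v)
        return True
    except ValueError:
        return False


def read_jcamp(path: str | Path) -> Spectrum:
    """Minimal JCAMP-DX reader for AFFN ``##XYDATA=(X++(Y..Y))`` tables."""
    path = Path(path)
    fields: dict[str, str] = {}
    ys: list[float] = []
    in_table = False
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper()
            if key == "XYDATA":
                in_table = True
                continue
            if key == "END":
                in_table = False
                continue
            fields[key] = val.strip()
            in_table = False
        elif in_table:
            vals = line.replace(",", " ").split()
            ys.extend(float(v) for v in vals[1:])  # first token is X of the line
    try:
        firstx = float(fields["FIRSTX"])
        lastx = float(fields["LASTX"])
        npoints = int(float(fields["NPOINTS"]))
    except KeyError as exc:
        raise SpectraFormatError(f"{path}: missing JCAMP field {exc}") from exc
    if len(ys) != npoints:
        raise SpectraFormatError(
            f"{path}: NPOINTS={npoints} but {len(ys)} intensities found"
        )
    yfactor = float(fields.get("YFACTOR", "1"))
    x = np.linspace(firstx, lastx, npoints)
    y = np.array(ys) * yfactor
    meta = SampleMeta(
        sample_id=fields.get("TITLE", path.stem),
        strain="NA",
        pi_level=float("nan"),
        ca_level=-1,
        bio_rep=-1,
        tech_rep=-1,
        laser_power_mw=float("nan"),
        block="NA",
    )
    if x[0] < x[-1]:
        x, y = x[::-1].copy(), y[::-1].copy()
    return Spectrum(x, y, meta)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def align_to_common_grid(
    spectra: Iterable[Spectrum], spacing: float = DEFAULT_SPACING
) -> SpectraSet:
    """Linearly interpolate spectra onto the shared descending grid.

    The target grid starts at the highest wavenumber common to all spectra
    and steps down by ``spacing`` (default the instruments' digital spacing,
    1.928 cm⁻¹) while staying inside the overlap.  No extrapolation is ever
    performed.  Aligning an already-aligned set is a no-op.
    """
    spectra = list(spectra)
    if not spectra:
        raise AlignmentError("no spectra to align")
    lo = max(s.wavenumbers.min() for s in spectra)
    hi = min(s.wavenumbers.max() for s in spectra)
    if hi <= lo:
        raise AlignmentError(
            f"spectra have empty wavenumber overlap (intersection [{lo}, {hi}])"
        )
    grid = np.arange(hi, lo - 1e-9, -spacing)
    if grid.size < 2:
        raise AlignmentError("overlap shorter than one grid step")
    rows = np.empty((len(spectra), grid.size))
    for i, s in enumerate(spectra):
        x = s.wavenumbers[::-1] if s.wavenumbers[0] > s.wavenumbers[-1] else s.wavenumbers
        y = s.intensities[::-1] if s.wavenumbers[0] > s.wavenumbers[-1] else s.intensities
        rows[i] = np.interp(grid[::-1], x, y)[::-1]
    meta = pd.DataFrame([s.meta.as_dict() for s in spectra])
    return SpectraSet(grid, rows, meta).validate()
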
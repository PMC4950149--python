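"""Reading, writing and flattening of hyperspectral cubes.

A hyperspectral cube is a stack of images of the same sample region
acquired over a range of vibrational frequencies: an ``ny × nx`` spatial
grid with ``S`` spectral points on a wavenumber axis in cm⁻¹.  The
factorization and filtering algorithms consume a flattened, non-negative
``P × S`` matrix (``P = ny·nx`` spatial points as rows); this module owns
the conversion in both directions and the on-disk formats.

Two container formats are supported:

* multi-page TIFF (one grayscale page per spectral point) paired with a
  one-column CSV of wavenumbers, and
* a single HDF5 file with datasets ``/data`` ``(ny, nx, S)`` and
  ``/wavenumbers`` plus ``modality`` and ``meta`` attributes.

Flattening is row-major: row ``p`` of the matrix is pixel
``(y, x) = (p // nx, p % nx)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import h5py
import numpy as np
import tifffile

__all__ = [
    "Modality",
    "SpectralAxis",
    "HyperspectralCube",
    "DataMatrix",
    "load_cube",
    "save_cube",
    "to_matrix",
    "save_result",
]

log = logging.getLogger(__name__)

#: Fraction of negative entries tolerated (and clipped to zero) in data
#: that is non-negative by physics; more than this aborts with an error
#: because large-scale negativity indicates a calibration fault.
MAX_NEGATIVE_FRACTION = 0.01


class Modality(str, Enum):
    """What physical quantity the cube stores.

    CARS measures an intensity proportional to ``|χ|²`` whose shot noise
    scales with the square root of the signal, hence the dedicated
    square-root variant with (approximately) constant noise.  SRS and
    spontaneous Raman measure quantities linear in concentration, as does
    the imaginary part of the retrieved susceptibility.
    """

    CARS_INTENSITY = "cars_intensity"
    SQRT_CARS_INTENSITY = "sqrt_cars_intensity"
    SUSCEPTIBILITY_IMAG = "susceptibility_imag"
    SRS = "srs"
    RAMAN = "raman"


_INTENSITY_MODALITIES = {Modality.CARS_INTENSITY, Modality.SQRT_CARS_INTENSITY}


@dataclass(frozen=True)
class SpectralAxis:
    """Strictly increasing wavenumber axis in cm⁻¹."""

    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise ValueError("spectral axis must be a 1-d vector of length >= 2")
        if not np.all(np.isfinite(w)):
            raise ValueError("spectral axis contains non-finite values")
        if not np.all(np.diff(w) > 0):
            raise ValueError("spectral axis must be strictly increasing")
        object.__setattr__(self, "wavenumbers", w)

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def window_indices(self, lo: float, hi: float) -> np.ndarray:
        """Indices of wavenumbers in the closed interval ``[lo, hi]``."""
        if hi < lo:
            raise ValueError(f"empty window: ({lo}, {hi})")
        idx = np.flatnonzero((self.wavenumbers >= lo) & (self.wavenumbers <= hi))
        if idx.size == 0:
            raise ValueError(
                f"window ({lo}, {hi}) cm-1 does not overlap axis "
                f"[{self.wavenumbers[0]}, {self.wavenumbers[-1]}] cm-1"
            )
        return idx


def _clip_negatives(data: np.ndarray, context: str) -> np.ndarray:
    """Clip small negative excursions to zero; reject wholesale negativity."""
    neg = data < 0
    n_neg = int(neg.sum())
    if n_neg == 0:
        return data
    frac = n_neg / data.size
    if frac > MAX_NEGATIVE_FRACTION:
        raise ValueError(
            f"{context}: {n_neg} negative entries ({100 * frac:.2f}% > "
            f"{100 * MAX_NEGATIVE_FRACTION:.0f}%) — data rejected as "
            "inconsistent with a non-negative modality"
        )
    log.warning("%s: clipped %d negative entries (%.4f%%) to zero", context, n_neg, 100 * frac)
    out = data.copy()
    out[neg] = 0.0
    return out


@dataclass
class HyperspectralCube:
    """An ``ny × nx × S`` hyperspectral image with its wavenumber axis."""

    data: np.ndarray
    axis: SpectralAxis
    modality: Modality = Modality.SUSCEPTIBILITY_IMAG
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError("cube data must be ny × nx × S")
        if data.shape[2] != len(self.axis):
            raise ValueError(
                f"axis length {len(self.axis)} ≠ {data.shape[2]} spectral planes"
            )
        if data.shape[2] < 2:
            raise ValueError("cube needs at least 2 spectral points")
        if not np.all(np.isfinite(data)):
            raise ValueError("cube data contains non-finite values")
        self.modality = Modality(self.modality)
        if self.modality in _INTENSITY_MODALITIES:
            data = _clip_negatives(data, f"{self.modality.value} cube")
        self.data = data

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_points(self) -> int:
        return self.data.shape[0] * self.data.shape[1]


@dataclass
class DataMatrix:
    """The flattened ``P × S″`` non-negative matrix the algorithms factorize.

    ``S″`` equals the number of windowed spectral points, optionally plus
    one auxiliary column (e.g. the spectrally averaged real part of the
    susceptibility, appended as an extra non-negative channel).
    """

    values: np.ndarray
    image_shape: tuple[int, int]
    wavenumbers: np.ndarray
    column_indices: np.ndarray
    channel_is_aux: np.ndarray
    modality: Modality = Modality.SUSCEPTIBILITY_IMAG

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.channel_is_aux = np.asarray(self.channel_is_aux, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("DataMatrix values must be 2-d")
        ny, nx = self.image_shape
        if self.values.shape[0] != ny * nx:
            raise ValueError("row count does not match image shape")
        if self.channel_is_aux.size != self.values.shape[1]:
            raise ValueError("channel_is_aux length mismatch")
        if int(self.channel_is_aux.sum()) > 1:
            raise ValueError("at most one auxiliary column is allowed")
        if self.values.min() < 0:
            raise ValueError("DataMatrix must be non-negative")

    @property
    def n_points(self) -> int:
        return self.values.shape[0]

    def point_index(self, row: int) -> tuple[int, int]:
        """Map matrix row → image pixel ``(y, x)`` (row-major layout)."""
        ny, nx = self.image_shape
        if not 0 <= row < ny * nx:
            raise IndexError(row)
        return divmod(row, nx)

    def unflatten(self, column_values: np.ndarray) -> np.ndarray:
        """Reshape a per-point vector back into an ``ny × nx`` map."""
        v = np.asarray(column_values)
        return v.reshape(self.image_shape)

    def spectral_values(self) -> np.ndarray:
        """The ``P × S_window`` block without any auxiliary column."""
        return self.values[:, ~self.channel_is_aux]

    def to_cube(self, meta: dict | None = None) -> HyperspectralCube:
        """Reassemble the (windowed) cube; auxiliary columns are dropped."""
        ny, nx = self.image_shape
        spec = self.spectral_values().reshape(ny, nx, -1)
        return HyperspectralCube(
            spec, SpectralAxis(self.wavenumbers), self.modality, dict(meta or {})
        )


# ---------------------------------------------------------------------------
# loading / saving cubes


def _load_hdf5(path: Path) -> HyperspectralCube:
    with h5py.File(path, "r") as fh:
        data = np.asarray(fh["data"], dtype=float)
        wn = np.asarray(fh["wavenumbers"], dtype=float)
        modality = Modality(fh.attrs.get("modality", Modality.SUSCEPTIBILITY_IMAG.value))
        meta = json.loads(fh.attrs.get("meta", "{}"))
    return _assemble(data, wn, modality, meta)


def _load_tiff(path: Path, wavenumber_path: Path) -> HyperspectralCube:
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"{path}: expected a stack of grayscale pages")
    data = np.moveaxis(np.asarray(pages, dtype=float), 0, -1)  # (ny, nx, S)
    wn = np.atleast_1d(np.loadtxt(wavenumber_path, delimiter=",", dtype=float).ravel())
    return _assemble(data, wn, Modality.SUSCEPTIBILITY_IMAG, {})


def _assemble(data, wn, modality, meta) -> HyperspectralCube:
    if wn.size != data.shape[-1]:
        raise ValueError(f"axis length {wn.size} ≠ {data.shape[-1]} pages")
    if wn.size >= 2 and np.all(np.diff(wn) < 0):
        wn = wn[::-1].copy()
        data = data[..., ::-1].copy()
    return HyperspectralCube(data, SpectralAxis(wn), modality, meta)


def load_cube(
    path: str | Path,
    wavenumber_path: str | Path | None = None,
    modality: Modality | str | None = None,
) -> HyperspectralCube:
    """Load a cube from HDF5 or from a multi-page TIFF + wavenumber CSV.

    A decreasing wavenumber axis is reversed (together with the spectral
    planes) on load.  ``modality`` overrides the stored/default tag.
    """
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        cube = _load_hdf5(path)
    else:
        if wavenumber_path is None:
            raise ValueError("TIFF input requires a wavenumber CSV")
        cube = _load_tiff(path, Path(wavenumber_path))
    if modality is not None:
        cube = HyperspectralCube(cube.data, cube.axis, Modality(modality), cube.meta)
    return cube


def save_cube(
    cube: HyperspectralCube,
    path: str | Path,
    wavenumber_path: str | Path | None = None,
) -> None:
    """Write a cube as HDF5 (``.h5``/``.hdf5``) or multi-page TIFF + CSV."""
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("data", data=cube.data)
            fh.create_dataset("wavenumbers", data=cube.axis.wavenumbers)
            fh.attrs["modality"] = cube.modality.value
            fh.attrs["meta"] = json.dumps(cube.meta)
    else:
        if wavenumber_path is None:
            raise ValueError("TIFF output requires a wavenumber CSV path")
        tifffile.imwrite(
            path,
            np.moveaxis(cube.data, -1, 0).astype(np.float32),
            photometric="minisblack",
        )
        np.savetxt(wavenumber_path, cube.axis.wavenumbers, fmt="%.10g")


# ---------------------------------------------------------------------------
# flattening


def to_matrix(
    cube: HyperspectralCube,
    sqrt_transform: bool = False,
    spectral_window: tuple[float, float] | None = None,
    aux_channel: np.ndarray | None = None,
) -> DataMatrix:
    """Flatten a cube into the ``P × S″`` matrix the algorithms consume.

    Parameters
    ----------
    sqrt_transform
        Take the elementwise square root (CARS intensity only) so that
        shot noise becomes approximately constant across the matrix.
    spectral_window
        ``(lo, hi)`` wavenumber window in cm⁻¹, closed at both ends;
        ``None`` keeps the full axis.
    aux_channel
        Optional length-``P`` non-negative vector appended as one extra
        column flagged as auxiliary (e.g. the spectrally averaged real
        part of the susceptibility).
    """
    if sqrt_transform and cube.modality is not Modality.CARS_INTENSITY:
        raise ValueError("sqrt_transform requires a cars_intensity cube")
    if spectral_window is None:
        idx = np.arange(len(cube.axis))
    else:
        idx = cube.axis.window_indices(*spectral_window)
    ny, nx, _ = cube.shape
    values = cube.data[:, :, idx].reshape(ny * nx, idx.size)
    values = _clip_negatives(values, "data matrix")
    if sqrt_transform:
        values = np.sqrt(values)
        modality = Modality.SQRT_CARS_INTENSITY
    else:
        modality = cube.modality
    aux_flags = np.zeros(idx.size, dtype=bool)
    if aux_channel is not None:
        aux = np.asarray(aux_channel, dtype=float).ravel()
        if aux.size != ny * nx:
            raise ValueError("aux_channel must have one value per spatial point")
        if aux.min() < 0:
            raise ValueError("aux_channel must be non-negative")
        values = np.column_stack([values, aux])
        aux_flags = np.append(aux_flags, True)
    return DataMatrix(
        values=values,
        image_shape=(ny, nx),
        wavenumbers=cube.axis.wavenumbers[idx],
        column_indices=idx,
        channel_is_aux=aux_flags,
        modality=modality,
    )


# ---------------------------------------------------------------------------
# result output


def save_result(
    result,
    cube: HyperspectralCube,
    outdir: str | Path,
    wavenumbers: np.ndarray | None = None,
    params: dict | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write an :class:`~hsunmix.fsc3.FSC3Result` as viewable artifacts.

    Per-component concentration maps and the error/weight maps go out as
    single-page float TIFFs, the component spectra as a CSV
    (``wavenumber_cm1,component_1,…``), and a ``manifest.json`` records
    the parameters, seed and package version so a run can be reproduced.
    """
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ny, nx, _ = cube.shape
    if result.C.shape[0] != ny * nx:
        raise ValueError("result rows inconsistent with cube geometry")
    wn = np.asarray(
        cube.axis.wavenumbers if wavenumbers is None else wavenumbers, dtype=float
    )
    n_spec = result.S.shape[0]
    aux_row = None
    if n_spec == wn.size + 1:  # trailing auxiliary channel
        aux_row = result.S[-1]
        n_spec -= 1
    if n_spec != wn.size:
        raise ValueError(f"{result.S.shape[0]} spectral rows vs {wn.size} wavenumbers")

    files: dict[str, Path] = {}

    def _write_map(name: str, vec, dtype=np.float32):
        p = outdir / f"{name}.tif"
        tifffile.imwrite(p, np.asarray(vec).reshape(ny, nx).astype(dtype))
        files[name] = p

    for j in range(result.k):
        _write_map(f"concentration_{j + 1:02d}", result.C[:, j])
    _write_map("spectral_error", result.E_Sp)
    _write_map("concentration_error", result.E_Cp)
    _write_map("weights", result.weights)
    _write_map("excluded", result.excluded.astype(np.uint8), dtype=np.uint8)

    spectra = outdir / "spectra.csv"
    header = "wavenumber_cm1," + ",".join(f"component_{j + 1}" for j in range(result.k))
    np.savetxt(
        spectra,
        np.column_stack([wn, result.S[:n_spec]]),
        delimiter=",",
        header=header,
        comments="",
        fmt="%.17g",
    )
    files["spectra"] = spectra

    manifest = {
        "version": __version__,
        "k": int(result.k),
        "seed": seed,
        "params": params or {},
        "image_shape": [ny, nx],
        "modality": cube.modality.value,
        "final_error": float(result.final_error),
        "converged": bool(result.converged),
        "aux_spectrum": None if aux_row is None else list(map(float, aux_row)),
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    files["manifest"] = mpath
    return files
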
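"""Reflectance spectra, sensor band systems, and spectral resampling.

The package works with remote-sensing reflectance defined as the ratio of
radiance leaving the water to radiance from a white reference panel; it is
dimensionless and no pi-scaling is applied anywhere.  Negative reflectances
can occur in atmospherically corrected products (neural-network processors
tend to underestimate in clear and dark waters); they are retained and
flagged, never clipped, and downstream formulas consume them as-is.

Hyperspectral spectra are convolved to sensor bands with a spectral response
function (SRF).  SRFs are tabulated (wavelength, weight) pairs; when only a
band centre is known a Gaussian SRF is synthesised from (centre, FWHM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "Band",
    "BandSet",
    "SceneStack",
    "SpectraError",
    "BandCoverageError",
    "UnknownBandError",
    "SourceUnavailableError",
    "MISSING",
    "msi_bands",
    "olci_bands",
    "band_set_for",
    "read_spectra",
    "read_srf_table",
    "resample_to_bands",
    "band_value",
    "column_name",
    "read_observations",
    "write_observations",
]

#: Typed missing value used throughout (never a silent zero).
MISSING = float("nan")

SOURCES = ("insitu", "TOA", "C2RCC", "C2X")
SENSORS = ("hyperspectral", "MSI", "OLCI")

#: Processor product fields accepted alongside band reflectances.
PRODUCT_FIELDS = ("conc_chl", "conc_tsm", "iop_agelb", "Kd_489", "Kd_z90max")


class SpectraError(ValueError):
    """Malformed spectral input."""


class BandCoverageError(SpectraError):
    """A band's SRF support falls outside the spectrum's wavelength range."""


class UnknownBandError(KeyError):
    """Requested band name is not part of the band set / observation."""


class SourceUnavailableError(ValueError):
    """Requested reflectance source does not exist for the sensor.

    The C2X atmospheric-correction processor is only available for MSI;
    OLCI scenes offer C2RCC (and TOA) reflectances only.
    """


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-indexed reflectance vector.

    Parameters
    ----------
    wavelengths : array, nm, strictly increasing
    values : array, remote-sensing reflectance (dimensionless)
    source : one of ``insitu, TOA, C2RCC, C2X``
    sensor : one of ``hyperspectral, MSI, OLCI``
    bands : optional band names for per-band spectra (parallel to values)
    """

    wavelengths: np.ndarray
    values: np.ndarray
    source: str = "insitu"
    sensor: str = "hyperspectral"
    bands: tuple | None = None

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise SpectraError("wavelengths and values must be 1-D of equal length")
        if wl.size < 2:
            raise SpectraError("a spectrum needs at least two samples")
        dif = np.diff(wl)
        if np.any(dif == 0):
            dup = wl[:-1][dif == 0][0]
            raise SpectraError(f"duplicated wavelength {dup:g} nm")
        if np.any(dif < 0):
            raise SpectraError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(vals)):
            raise SpectraError("reflectance values must be finite")
        if self.source not in SOURCES:
            raise SpectraError(f"unknown source {self.source!r}; expected one of {SOURCES}")
        if self.sensor not in SENSORS:
            raise SpectraError(f"unknown sensor {self.sensor!r}; expected one of {SENSORS}")
        if self.bands is not None:
            object.__setattr__(self, "bands", tuple(self.bands))
            if len(self.bands) != vals.size:
                raise SpectraError("bands must parallel values")

    @property
    def has_negative(self) -> bool:
        """True if any reflectance is negative (flagged, not clipped)."""
        return bool(np.any(self.values < 0))

    def __len__(self) -> int:
        return int(self.values.size)

    def band(self, name: str) -> float:
        """Value of a named band on a per-band spectrum."""
        if self.bands is None:
            raise UnknownBandError("spectrum carries no band names")
        try:
            return float(self.values[self.bands.index(name)])
        except ValueError:
            raise UnknownBandError(
                f"band {name!r} not present; available: {', '.join(self.bands)}"
            ) from None


@dataclass(frozen=True)
class Band:
    """One sensor band: a name, nominal centre and tabulated SRF."""

    name: str
    center: float
    srf_wavelengths: np.ndarray
    srf_weights: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.srf_wavelengths, dtype=float)
        w = np.asarray(self.srf_weights, dtype=float)
        object.__setattr__(self, "srf_wavelengths", wl)
        object.__setattr__(self, "srf_weights", w)
        if wl.size != w.size or wl.size < 1:
            raise SpectraError(f"band {self.name}: SRF table malformed")
        if np.any(w < 0) or not np.any(w > 0):
            raise SpectraError(f"band {self.name}: SRF weights must be >=0 with one positive")

    @classmethod
    def gaussian(cls, name: str, center: float, fwhm: float, n: int = 31) -> "Band":
        """Synthesise a Gaussian SRF over centre +/- 1.5 FWHM."""
        wl = np.linspace(center - 1.5 * fwhm, center + 1.5 * fwhm, n)
        w = np.exp(-4.0 * np.log(2.0) * ((wl - center) / fwhm) ** 2)
        return cls(name, center, wl, w)


@dataclass(frozen=True)
class BandSet:
    """An ordered collection of bands for one sensor."""

    sensor: str
    bands: tuple

    def __post_init__(self):
        bands = tuple(sorted(self.bands, key=lambda b: b.center))
        object.__setattr__(self, "bands", bands)
        centers = [b.center for b in bands]
        if len(set(centers)) != len(centers):
            raise SpectraError("band centres must be unique")

    @property
    def names(self) -> tuple:
        return tuple(b.name for b in self.bands)

    @property
    def centers(self) -> np.ndarray:
        return np.array([b.center for b in self.bands])

    def __getitem__(self, name: str) -> Band:
        for b in self.bands:
            if b.name == name:
                return b
        raise UnknownBandError(
            f"band {name!r} not in {self.sensor} band set; available: {', '.join(self.names)}"
        )

    def __contains__(self, name: str) -> bool:
        return name in self.names


# Nominal band centres (nm) and approximate FWHM (nm) used to synthesise
# Gaussian SRFs.  Band names follow the R<centre> dialect with centres
# rounded to the integers used in the retrieval formulas (e.g. the OLCI
# 708.75 nm band is keyed "R709").
_MSI_BANDS = {
    "R443": (443.0, 20.0),
    "R490": (490.0, 65.0),
    "R560": (560.0, 35.0),
    "R665": (665.0, 30.0),
    "R705": (705.0, 15.0),
    "R740": (740.0, 15.0),
    "R783": (783.0, 20.0),
    "R865": (865.0, 20.0),
}

_OLCI_BANDS = {
    "R400": (400.0, 15.0),
    "R412": (412.5, 10.0),
    "R443": (442.5, 10.0),
    "R490": (490.0, 10.0),
    "R510": (510.0, 10.0),
    "R560": (560.0, 10.0),
    "R620": (620.0, 10.0),
    "R665": (665.0, 10.0),
    "R674": (673.75, 7.5),
    "R681": (681.25, 7.5),
    "R709": (708.75, 10.0),
    "R754": (753.75, 7.5),
    "R779": (778.75, 15.0),
    "R865": (865.0, 20.0),
}


def _build(sensor: str, table: Mapping[str, tuple]) -> BandSet:
    return BandSet(sensor, tuple(Band.gaussian(n, c, f) for n, (c, f) in table.items()))


def msi_bands() -> BandSet:
    """Sentinel-2 MSI visible/NIR bands with Gaussian stand-in SRFs."""
    return _build("MSI", _MSI_BANDS)


def olci_bands() -> BandSet:
    """Sentinel-3 OLCI visible/NIR bands with Gaussian stand-in SRFs."""
    return _build("OLCI", _OLCI_BANDS)


def band_set_for(sensor: str) -> BandSet:
    if sensor == "MSI":
        return msi_bands()
    if sensor == "OLCI":
        return olci_bands()
    raise SpectraError(f"no builtin band set for sensor {sensor!r}")


def read_srf_table(path) -> BandSet:
    """Read a CSV SRF table with columns band, center, wavelength, weight."""
    df = pd.read_csv(path)
    required = {"band", "wavelength", "weight"}
    if not required.issubset(df.columns):
        raise SpectraError(f"SRF table needs columns {sorted(required)}")
    bands = []
    for name, grp in df.groupby("band", sort=False):
        center = float(grp["center"].iloc[0]) if "center" in grp else float(
            np.average(grp["wavelength"], weights=grp["weight"])
        )
        grp = grp.sort_values("wavelength")
        bands.append(Band(str(name), center, grp["wavelength"].to_numpy(),
                          grp["weight"].to_numpy()))
    sensor = "MSI" if "sensor" not in df.columns else str(df["sensor"].iloc[0])
    return BandSet(sensor, tuple(bands))


def read_spectra(path, source: str = "insitu", sensor: str = "hyperspectral",
                 wavelength_column: str | None = None) -> list:
    """Read spectra from a delimited table (one wavelength + >=1 value column).

    Returns one :class:`Spectrum` per value column, sharing the wavelength
    axis.  Unsorted wavelengths are sorted with a warning; duplicated
    wavelengths raise an error naming the offending wavelength.
    """
    df = pd.read_csv(path)
    if wavelength_column is None:
        wavelength_column = df.columns[0]
    try:
        wl = df[wavelength_column].astype(float).to_numpy()
    except (ValueError, TypeError) as exc:
        raise SpectraError(f"non-numeric wavelength in column {wavelength_column!r}: {exc}")
    dup = pd.Series(wl)[pd.Series(wl).duplicated()]
    if not dup.empty:
        raise SpectraError(f"duplicated wavelength {dup.iloc[0]:g} nm")
    order = np.argsort(wl)
    if not np.all(order == np.arange(wl.size)):
        warnings.warn("wavelengths were not sorted; sorting", stacklevel=2)
    spectra = []
    for col in df.columns:
        if col == wavelength_column:
            continue
        try:
            vals = df[col].astype(float).to_numpy()
        except (ValueError, TypeError) as exc:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise SpectraError(f"non-numeric cell in column {col!r}, row {row}: {exc}")
        spectra.append(Spectrum(wl[order], vals[order], source=source, sensor=sensor))
    return spectra


def resample_to_bands(s: Spectrum, bands: BandSet) -> Spectrum:
    """Convolve a hyperspectral spectrum to sensor bands.

    Each band value is the SRF-weighted mean of the linearly interpolated
    reflectance, integrated by the trapezoid rule on the union of the SRF
    and spectrum wavelength grids; SRF weights are normalised to unit
    integral over the overlap.  A band whose SRF support extends beyond the
    spectrum's range raises :class:`BandCoverageError`.
    """
    out = np.empty(len(bands.bands))
    for i, b in enumerate(bands.bands):
        lo, hi = b.srf_wavelengths[0], b.srf_wavelengths[-1]
        if lo < s.wavelengths[0] or hi > s.wavelengths[-1]:
            raise BandCoverageError(
                f"band {b.name}: SRF support [{lo:g}, {hi:g}] nm outside spectrum "
                f"range [{s.wavelengths[0]:g}, {s.wavelengths[-1]:g}] nm"
            )
        if b.srf_wavelengths.size == 1:  # delta kernel
            out[i] = np.interp(b.srf_wavelengths[0], s.wavelengths, s.values)
            continue
        inner = s.wavelengths[(s.wavelengths > lo) & (s.wavelengths < hi)]
        grid = np.union1d(b.srf_wavelengths, inner)
        w = np.interp(grid, b.srf_wavelengths, b.srf_weights)
        r = np.interp(grid, s.wavelengths, s.values)
        norm = np.trapezoid(w, grid)
        out[i] = np.trapezoid(w * r, grid) / norm
    return Spectrum(bands.centers, out, source=s.source, sensor=bands.sensor,
                    bands=bands.names)


def column_name(source: str, key: str) -> str:
    """Observation-table column for a (source, band-or-field) pair.

    Dialect: ``<SOURCE>_R<center>`` for reflectances, ``<SOURCE>_<field>``
    for processor product fields, e.g. ``TOA_R705``, ``C2RCC_conc_tsm``.
    """
    return f"{source}_{key}"


def band_value(obs, source: str, band_name: str, sensor: str | None = None) -> float:
    """Scalar reflectance for (source, band) from an observation row or
    per-band spectrum.  Missing optional values map to NaN, never zero."""
    if sensor == "OLCI" and source == "C2X":
        raise SourceUnavailableError("C2X reflectances are not available for OLCI; "
                                     "use C2RCC or TOA")
    if isinstance(obs, Spectrum):
        return obs.band(band_name)
    col = column_name(source, band_name)
    if hasattr(obs, "index"):  # pandas Series row
        if col not in obs.index:
            if band_name in PRODUCT_FIELDS:
                return MISSING
            avail = [c for c in obs.index if c.startswith(f"{source}_")]
            raise UnknownBandError(
                f"column {col!r} absent; available for {source}: {', '.join(avail) or 'none'}"
            )
        val = obs[col]
        return float(val) if pd.notna(val) else MISSING
    raise TypeError("obs must be a pandas row (Series) or a per-band Spectrum")


def read_observations(path) -> pd.DataFrame:
    """Read a CSV observation table (station/date plus SOURCE_key columns)."""
    df = pd.read_csv(path)
    if df.columns.duplicated().any():
        raise SpectraError("observation table has duplicated column keys")
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"])
    return df


def write_observations(df: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    """Write an observation table; numeric cells round-trip at 10 significant
    digits."""
    df.to_csv(path, index=False, float_format=float_format)


@dataclass
class SceneStack:
    """A gridded per-band reflectance stack (band, y, x) for one source."""

    sensor: str
    source: str
    bands: tuple
    data: np.ndarray

    def __post_init__(self):
        self.bands = tuple(self.bands)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.bands):
            raise SpectraError("data must be (n_bands, ny, nx) matching bands")

    @property
    def shape(self) -> tuple:
        return self.data.shape[1:]

    def band(self, name: str) -> np.ndarray:
        try:
            return self.data[self.bands.index(name)]
        except ValueError:
            raise UnknownBandError(
                f"band {name!r} not in scene; available: {', '.join(self.bands)}"
            ) from None

    def pixel(self, iy: int, ix: int) -> Spectrum:
        """Per-band Spectrum at one pixel (NaNs allowed -> degenerate)."""
        vals = self.data[:, iy, ix]
        bs = band_set_for(self.sensor)
        centers = [bs[n].center for n in self.bands]
        # Spectrum forbids non-finite values; callers should mask first.
        return Spectrum(np.array(centers), vals, source=self.source,
                        sensor=self.sensor, bands=self.bands)
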
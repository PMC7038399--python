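"""Synthetic bio-optical inputs with known ground truth.

The field campaign behind the retrieval formulas is not published, so every
input the pipeline needs is generated here instead:

* hyperspectral reflectance spectra per OWT archetype, from a deliberately
  simple semi-analytical forward model  R(lambda) = f * bb / (a + bb)  with
  absorption from water, phytoplankton (Chl-a), non-algal particles (TSM)
  and CDOM, and particulate backscatter proportional to TSM;
* labelled scenes (gridded band stacks) for classifier and per-pixel
  retrieval tests;
* in-situ / satellite match-up tables whose band values are algebraic
  realisations of each registry predictor, so that at zero noise every
  retrieval reproduces its in-situ value exactly.

Two distinct paths on purpose: scenes go through forward optics (classifier
realism), match-ups go through predictor inversion (product consistency).
All randomness flows from one explicit seed.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .owt import OWT_CLASSES, ReferenceLibrary
from .retrieval import (PRODUCTS, AlgorithmSpec, Kd490Model, Registry,
                        builtin_registry, cdom_to_wavelength, eval_predictor,
                        expression_names, kd490)
from .spectra import (SceneStack, Spectrum, band_set_for, column_name,
                      resample_to_bands)

__all__ = [
    "BioOpticalParams",
    "ForwardModelCoeffs",
    "SceneSpec",
    "ARCHETYPE_RANGES",
    "REFERENCE_PARAMS",
    "forward_rrs",
    "generate_archetype",
    "reference_library",
    "generate_scene",
    "quadrant_labels",
    "generate_matchups",
    "DEFAULT_WAVELENGTHS",
]

#: Hyperspectral wavelength grid (nm) covering every builtin band's SRF.
DEFAULT_WAVELENGTHS = np.arange(355.0, 931.0, 2.0)


@dataclass(frozen=True)
class BioOpticalParams:
    """Optically significant constituents driving the forward model."""

    chl: float  # chlorophyll-a, mg m^-3
    tsm: float  # total suspended matter, mg L^-1
    cdom400: float  # CDOM absorption at 400 nm, m^-1
    slope: float = 0.017  # CDOM spectral slope, nm^-1
    noise_sd: float = 0.0  # relative sensor noise

    def __post_init__(self):
        if min(self.chl, self.tsm, self.cdom400) < 0:
            raise ValueError("concentrations must be >= 0")
        if not (0.005 < self.slope < 0.03):
            raise ValueError("CDOM slope must lie in (0.005, 0.03) nm^-1")


# Pure-water absorption (m^-1), coarse table; linearly interpolated.  The
# 650-750 nm region is finer-grained so the low-absorption window just
# below 710 nm (which shapes the bloom reflectance peak) is resolved.
_AW_WL = np.array([350, 375, 400, 425, 450, 475, 500, 525, 550, 575, 600,
                   625, 650, 660, 670, 680, 690, 700, 710, 720, 730, 740,
                   750, 775, 800, 825, 850, 875, 900, 925, 950], dtype=float)
_AW = np.array([0.0204, 0.0114, 0.00663, 0.0053, 0.00922, 0.0114, 0.0204,
                0.0409, 0.0565, 0.0846, 0.2224, 0.2834, 0.34, 0.40, 0.435,
                0.465, 0.56, 0.624, 0.835, 1.17, 1.80, 2.38, 2.47, 2.55,
                2.02, 2.83, 4.12, 5.37, 6.78, 14.0, 28.0])


@dataclass(frozen=True)
class ForwardModelCoeffs:
    """Shape constants of the semi-analytical reflectance model.

    All spectra are non-negative over the supported range.  The chl-specific
    absorption combines the blue (440 nm) and red (675 nm) pigment peaks
    with a broad green shoulder standing in for accessory pigments; without
    the shoulder, bloom spectra would stay too bright in the green.
    """

    f: float = 0.35  # reflectance proportionality factor
    aph_blue: tuple = (0.04, 440.0, 50.0)  # amplitude m2/mg, centre, width
    aph_red: tuple = (0.016, 675.0, 12.0)
    aph_shoulder: tuple = (0.013, 590.0, 70.0)
    anap_star: float = 0.032  # NAP absorption at 440 nm per TSM, m2/g
    anap_slope: float = 0.0115  # nm^-1
    bbp_star: float = 0.013  # particulate backscatter per TSM at 550 nm
    bbp_exponent: float = 0.6
    bbw_550: float = 0.0011
    bbw_exponent: float = 4.3

    def aw(self, wl: np.ndarray) -> np.ndarray:
        return np.interp(wl, _AW_WL, _AW)

    def aph_specific(self, wl: np.ndarray) -> np.ndarray:
        out = np.zeros_like(wl, dtype=float)
        for amp, ctr, width in (self.aph_blue, self.aph_red, self.aph_shoulder):
            out += amp * np.exp(-(((wl - ctr) / width) ** 2))
        return out

    def bbw(self, wl: np.ndarray) -> np.ndarray:
        return self.bbw_550 * (550.0 / wl) ** self.bbw_exponent


def forward_rrs(params: BioOpticalParams,
                coeffs: ForwardModelCoeffs | None = None,
                wavelengths: np.ndarray | None = None,
                rng: np.random.Generator | None = None) -> Spectrum:
    """Simulate a hyperspectral reflectance spectrum R = f * bb / (a + bb).

    Strictly positive before sensor noise; with ``params.noise_sd`` > 0 and
    an ``rng``, multiplicative Gaussian noise is applied per wavelength (and
    may produce negatives, as real atmospheric correction does).
    """
    coeffs = coeffs or ForwardModelCoeffs()
    wl = DEFAULT_WAVELENGTHS if wavelengths is None else np.asarray(wavelengths,
                                                                    dtype=float)
    if wl[0] < _AW_WL[0] or wl[-1] > _AW_WL[-1]:
        raise ValueError("wavelengths outside forward-model support")
    a = (coeffs.aw(wl)
         + params.chl * coeffs.aph_specific(wl)
         + params.tsm * coeffs.anap_star * np.exp(-coeffs.anap_slope * (wl - 440.0))
         + params.cdom400 * np.exp(-params.slope * (wl - 400.0)))
    bb = coeffs.bbw(wl) + params.tsm * coeffs.bbp_star * (550.0 / wl) ** coeffs.bbp_exponent
    r = coeffs.f * bb / (a + bb)
    if params.noise_sd > 0 and rng is not None:
        r = r * (1.0 + params.noise_sd * rng.standard_normal(r.size))
    return Spectrum(wl, r, source="insitu", sensor="hyperspectral")


# Per-OWT constituent ranges (log-uniform draws) and the reference (median)
# parameters the shipped reference spectra are built from.  Regimes follow
# the class definitions -- Clear: low everything; Moderate: elevated, none
# dominant; Turbid: TSM-dominant; VeryTurbid: Chl-dominant (>= 30 mg m^-3,
# bloom-like); Brown: CDOM-dominant (>= 5 m^-1) -- with magnitudes in the
# range observed across boreal study lakes (clear oligotrophic to shallow
# very turbid eutrophic).
ARCHETYPE_RANGES: Mapping[str, Mapping[str, tuple]] = {
    "Clear": {"chl": (1.4, 9.0), "tsm": (0.6, 3.0), "cdom400": (0.8, 2.0)},
    "Moderate": {"chl": (8.0, 20.0), "tsm": (4.0, 10.0), "cdom400": (2.0, 4.5)},
    "Turbid": {"chl": (8.0, 25.0), "tsm": (14.0, 50.0), "cdom400": (2.0, 5.0)},
    "VeryTurbid": {"chl": (30.0, 110.0), "tsm": (10.0, 28.0), "cdom400": (2.0, 5.0)},
    "Brown": {"chl": (5.0, 20.0), "tsm": (3.0, 10.0), "cdom400": (5.0, 12.0)},
}

REFERENCE_PARAMS: Mapping[str, BioOpticalParams] = {
    "Clear": BioOpticalParams(4.0, 1.5, 1.2),
    "Moderate": BioOpticalParams(12.0, 6.0, 3.0),
    "Turbid": BioOpticalParams(15.0, 30.0, 3.0),
    "VeryTurbid": BioOpticalParams(60.0, 18.0, 3.5),
    "Brown": BioOpticalParams(10.0, 6.0, 9.0),
}


def generate_archetype(owt: str, seed: int | None = None,
                       coeffs: ForwardModelCoeffs | None = None
                       ) -> tuple[BioOpticalParams, Spectrum]:
    """Draw constituent parameters for one OWT and simulate its spectrum.

    With ``seed=None`` the class's reference (median) parameters are used,
    giving the exact archetype mean spectrum; an integer seed draws
    log-uniformly within the class ranges.  Same seed, same output.
    """
    if owt not in OWT_CLASSES:
        raise ValueError(f"unknown OWT {owt!r}")
    if seed is None:
        params = REFERENCE_PARAMS[owt]
    else:
        rng = np.random.default_rng(seed)
        rng_ranges = ARCHETYPE_RANGES[owt]
        drawn = {k: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                 for k, (lo, hi) in rng_ranges.items()}
        params = BioOpticalParams(**drawn)
    return params, forward_rrs(params, coeffs)


_REFERENCE_CACHE: dict = {}


def reference_library(sensor: str) -> ReferenceLibrary:
    """Synthetic per-band reference spectra for all five OWTs.

    These are stand-ins generated by the forward model at the class median
    parameters, not the published boreal reference spectra; the
    classification band subset is every builtin band (all <= 865 nm).
    """
    if sensor not in _REFERENCE_CACHE:
        bs = band_set_for(sensor)
        spectra = {
            owt: resample_to_bands(forward_rrs(REFERENCE_PARAMS[owt]), bs)
            for owt in OWT_CLASSES
        }
        _REFERENCE_CACHE[sensor] = ReferenceLibrary(sensor, spectra, bs.names)
    return _REFERENCE_CACHE[sensor]


# ---------------------------------------------------------------------------
# scenes

@dataclass(frozen=True)
class SceneSpec:
    """A labelled synthetic scene: per-pixel OWT plus parameter jitter.

    ``labels`` is an (ny, nx) array of OWT names tiling the grid;
    ``jitter`` is the relative per-pixel spread of the constituent
    parameters around the class reference values; ``band_noise`` adds
    multiplicative Gaussian noise to the final band reflectances (this is
    what can drive them negative).  The seed reproduces output bit-for-bit.
    """

    labels: np.ndarray
    jitter: float = 0.05
    band_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=object)
        if labels.ndim != 2:
            raise ValueError("labels must be a 2-D grid")
        bad = {l for l in labels.ravel()} - set(OWT_CLASSES)
        if bad:
            raise ValueError(f"unknown OWT labels in scene: {bad}")
        object.__setattr__(self, "labels", labels)


def quadrant_labels(owts: Sequence[str], n: int = 16) -> np.ndarray:
    """An n x n grid split into four quadrants of the given OWTs."""
    if len(owts) != 4:
        raise ValueError("need exactly four OWTs for quadrants")
    h = n // 2
    grid = np.empty((n, n), dtype=object)
    grid[:h, :h], grid[:h, h:] = owts[0], owts[1]
    grid[h:, :h], grid[h:, h:] = owts[2], owts[3]
    return grid


def generate_scene(spec: SceneSpec, sensor: str, source: str = "TOA",
                   coeffs: ForwardModelCoeffs | None = None
                   ) -> tuple[SceneStack, np.ndarray]:
    """Simulate a gridded per-band scene with known truth labels.

    Each pixel's constituents are the class reference values perturbed by
    the relative jitter; the hyperspectral forward spectrum is convolved to
    the sensor bands.  Returns the stack and a copy of the truth labels.
    """
    rng = np.random.default_rng(spec.seed)
    bs = band_set_for(sensor)
    ny, nx = spec.labels.shape
    data = np.empty((len(bs.names), ny, nx))
    coeffs = coeffs or ForwardModelCoeffs()
    for iy in range(ny):
        for ix in range(nx):
            ref = REFERENCE_PARAMS[spec.labels[iy, ix]]
            if spec.jitter > 0:
                fac = np.clip(1.0 + spec.jitter * rng.standard_normal(3), 0.2, 5.0)
            else:
                fac = np.ones(3)
            p = BioOpticalParams(ref.chl * fac[0], ref.tsm * fac[1],
                                 ref.cdom400 * fac[2], ref.slope)
            band_spec = resample_to_bands(forward_rrs(p, coeffs), bs)
            vals = band_spec.values
            if spec.band_noise > 0:
                vals = vals * (1.0 + spec.band_noise * rng.standard_normal(vals.size))
            data[:, iy, ix] = vals
    return SceneStack(sensor, source, bs.names, data), spec.labels.copy()


# ---------------------------------------------------------------------------
# match-up tables by predictor inversion

_RATIO = re.compile(r"^(R\d+)/(R\d+)$")
_RATIO_DIFF = re.compile(r"^(R\d+)/(R\d+)-(R\d+)/(R\d+)$")
_DIFF_TIMES = re.compile(r"^\((R\d+)-(R\d+)\)\*(R\d+)$")
_PEAK = re.compile(r"^(R\d+)-\((R\d+)\+(R\d+)\)/2$")
_PROD_RATIO = re.compile(r"^(R\d+)\*(R\d+)/(R\d+)$")
_BAND_SUM = re.compile(r"^\((R\d+)-(R\d+)\)\+(R\d+)/2$")
_SINGLE = re.compile(r"^(R\d+|[A-Za-z_]\w*)$")

_LAKES = ("Razna", "Lubans", "Burtnieks", "Vortsjarv")


def _draw_band(rng, bandset, name: str) -> float:
    """A plausible reflectance magnitude for a free band choice."""
    center = bandset[name].center
    lo, hi = (0.002, 0.02) if center >= 720 else (0.01, 0.05)
    return float(rng.uniform(lo, hi))


def _realize_predictor(spec: AlgorithmSpec, x: float, cols: dict,
                       rng: np.random.Generator, kd_model: Kd490Model) -> bool:
    """Set band/field columns so the spec's predictor evaluates to ``x``.

    Already-set columns are reused as constraints; returns False when the
    predictor is fully determined by earlier products (caller derives the
    truth forward from the existing bands instead).
    """
    bandset = band_set_for(spec.sensor)
    src = spec.source
    expr = spec.predictor.replace(" ", "")

    def col(b):
        return column_name(src, b)

    def have(b):
        return col(b) in cols

    def get_or_draw(b):
        if not have(b):
            cols[col(b)] = _draw_band(rng, bandset, b)
        return cols[col(b)]

    if expr == "kd490":
        red = kd_model.red_band(spec.sensor)
        log_x = math.log10(x)
        if not have("R490"):
            r560 = get_or_draw("R560")
            rred = get_or_draw(red)
            log_r490 = (math.log10(r560)
                        + (log_x - kd_model.c0
                           - kd_model.c2 * math.log10(rred / r560)) / kd_model.c1)
            cols[col("R490")] = 10.0 ** log_r490
            return True
        if not have("R560"):
            rred = get_or_draw(red)
            csum = kd_model.c1 + kd_model.c2
            if csum == 0:
                return False
            log_r560 = (kd_model.c0 + kd_model.c1 * math.log10(cols[col("R490")])
                        + kd_model.c2 * math.log10(rred) - log_x) / csum
            cols[col("R560")] = 10.0 ** log_r560
            return True
        if not have(red):
            r490, r560 = cols[col("R490")], cols[col("R560")]
            log_rred = (math.log10(r560)
                        + (log_x - kd_model.c0
                           - kd_model.c1 * math.log10(r490 / r560)) / kd_model.c2)
            cols[col(red)] = 10.0 ** log_rred
            return True
        return False

    m = _SINGLE.match(expr)
    if m:
        if col(m.group(1)) in cols:
            return False
        cols[col(m.group(1))] = x
        return True

    m = _RATIO.match(expr)
    if m:
        a, b = m.groups()
        if have(a) and have(b):
            return False
        if have(b):
            cols[col(a)] = x * cols[col(b)]
        elif have(a):
            cols[col(b)] = cols[col(a)] / x
        else:
            cols[col(a)] = x * get_or_draw(b)
        return True

    m = _RATIO_DIFF.match(expr)  # Ra/Rb - Ra/Rc with shared numerator
    if m:
        a, b, a2, c = m.groups()
        assert a == a2
        if have(c):
            return False
        rb = get_or_draw(b)
        ra = cols[col(a)] if have(a) else 0.8 * rb
        cols[col(a)] = ra
        denom = ra / rb - x
        if denom <= 0:
            raise ValueError(f"cannot realise {spec.predictor} = {x:g}")
        cols[col(c)] = ra / denom
        return True

    m = _DIFF_TIMES.match(expr)  # (Ra - Rb) * Rc
    if m:
        a, b, c = m.groups()
        if have(a):
            return False
        rb = get_or_draw(b)
        rc = get_or_draw(c)
        cols[col(a)] = x / rc + rb
        return True

    m = _PEAK.match(expr)  # Ra - (Rb + Rc)/2
    if m:
        a, b, c = m.groups()
        if have(a):
            return False
        rb = get_or_draw(b)
        rc = get_or_draw(c)
        cols[col(a)] = x + 0.5 * (rb + rc)
        return True

    m = _PROD_RATIO.match(expr)  # Ra * Rb / Rc
    if m:
        a, b, c = m.groups()
        for solve, others in ((b, (a, c)), (a, (b, c)), (c, (a, b))):
            if not have(solve):
                for o in others:
                    get_or_draw(o)
                ra, rb, rc = (cols[col(a)] if have(a) else None,
                              cols[col(b)] if have(b) else None,
                              cols[col(c)] if have(c) else None)
                if solve == b:
                    cols[col(b)] = x * rc / ra
                elif solve == a:
                    cols[col(a)] = x * rc / rb
                else:
                    cols[col(c)] = ra * rb / x
                return True
        return False

    m = _BAND_SUM.match(expr)  # (Ra - Rb) + Rc/2
    if m:
        a, b, c = m.groups()
        if have(b):
            return False
        rc = get_or_draw(c)
        ra = cols[col(a)] if have(a) else max(0.02, 1.2 * x)
        cols[col(a)] = ra
        rb = ra + 0.5 * rc - x
        if rb <= 0:
            raise ValueError(f"cannot realise {spec.predictor} = {x:g}")
        cols[col(b)] = rb
        return True

    raise ValueError(f"no realisation rule for predictor {spec.predictor!r}")


def _forward_predictor(spec: AlgorithmSpec, cols: dict,
                       kd_model: Kd490Model) -> float:
    """Evaluate a spec's predictor directly from realised columns."""
    row = pd.Series(cols)
    env = {}
    for name in expression_names(spec.predictor):
        if name == "kd490":
            env[name] = kd490(row, spec.sensor, spec.source, kd_model)
        else:
            env[name] = cols[column_name(spec.source, name)]
    return eval_predictor(spec.predictor, env)


#: Order in which products are realised: single-band/field predictors first
#: so later ratio and attenuation predictors can reuse the shared bands.
_SIM_ORDER = ("tsm", "chl", "cdom400", "sd")


def generate_matchups(n: int, sensor: str, registry: Registry | None = None,
                      noise_sd: float = 0.0, seed: int = 0,
                      kd_model: Kd490Model | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Synthesise ``n`` consistent in-situ / satellite match-up records.

    Per record an OWT is drawn, every product's predictor value is sampled
    from its registry ``sim_range`` and the band (or field) columns are set
    so the predictor evaluates to exactly that value; the in-situ product is
    the registry response of the sampled predictor.  With ``noise_sd`` = 0
    OWT-guided retrieval therefore reproduces every in-situ value exactly;
    ``noise_sd`` > 0 perturbs the in-situ values multiplicatively
    (y * (1 + sd * eps)), emulating combined measurement and retrieval
    error, so pooled RMSE scales with sd times the product's RMS level.

    Returns (in-situ table, satellite table, truth OWT labels); satellite
    dates fall within +/- 1 day of the in-situ dates.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    registry = registry or builtin_registry()
    kd_model = kd_model or Kd490Model()
    rng = np.random.default_rng(seed)
    base_date = pd.Timestamp("2018-04-01")
    insitu_rows, sat_rows, labels = [], [], []
    for i in range(n):
        owt = OWT_CLASSES[rng.integers(len(OWT_CLASSES))]
        cols: dict = {}
        truths = {}
        for product in _SIM_ORDER:
            spec = registry.get(sensor, product, owt)
            if spec.sim_range is None:
                raise ValueError(f"registry entry {spec.key} has no sim_range")
            x = float(rng.uniform(*spec.sim_range))
            if not _realize_predictor(spec, x, cols, rng, kd_model):
                x = _forward_predictor(spec, cols, kd_model)
            truths[product] = spec.response(x)
        station = f"S{i:04d}"
        date = base_date + pd.Timedelta(days=int(i % 210))
        noisy = {p: truths[p] * (1.0 + noise_sd * rng.standard_normal())
                 for p in PRODUCTS} if noise_sd > 0 else dict(truths)
        insitu_rows.append({
            "station": station, "date": date,
            "lake": _LAKES[int(rng.integers(len(_LAKES)))],
            "chl": noisy["chl"], "tsm": noisy["tsm"],
            "cdom400": noisy["cdom400"],
            "cdom412": cdom_to_wavelength(noisy["cdom400"], 412.0),
            "cdom442": cdom_to_wavelength(noisy["cdom400"], 442.0),
            "sd": noisy["sd"],
        })
        sat_rows.append({
            "station": station,
            "date": date + pd.Timedelta(days=int(rng.integers(-1, 2))),
            "owt": owt, **cols,
        })
        labels.append(owt)
    return (pd.DataFrame(insitu_rows), pd.DataFrame(sat_rows),
            pd.Series(labels, name="owt"))
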
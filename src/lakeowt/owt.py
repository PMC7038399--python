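"""Optical water type (OWT) classification.

Boreal inland and coastal waters are sorted into five optical water types by
the dominant optically active substance: Clear (low everything, transparent),
Moderate (elevated but none dominant), Turbid (mineral/total suspended matter
dominated), Very Turbid (chlorophyll dominated, bloom-like) and Brown (CDOM
dominated, dark reddish water).  A spectrum is assigned the type whose
reference band spectrum it resembles most, resemblance being the mean of two
bounded, scale-invariant shape measures:

* spectral correlation similarity, SCS = (rho + 1) / 2 with rho the Pearson
  correlation between the candidate and reference band vectors;
* modified spectral angle similarity, MSAS = 1 - (2/pi) * arccos(cos theta),
  theta the angle between the two vectors (shifted to be non-negative first
  when negative reflectances occur, so MSAS stays in [0, 1]).

Spectra whose best combined score falls below a threshold are left
Unclassified, as happens for real scenes (flagged or out-of-family pixels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .spectra import Spectrum, SceneStack, UnknownBandError

__all__ = [
    "OWT_CLASSES",
    "UNCLASSIFIED",
    "LARGE_DIFFERENCE_PAIRS",
    "ReferenceLibrary",
    "SimilarityResult",
    "spectral_correlation_similarity",
    "modified_spectral_angle_similarity",
    "combined_similarity",
    "classify",
    "classify_scene",
    "owt_error_magnitude",
]

#: Fixed class order; also the deterministic tie-break order.
OWT_CLASSES = ("Clear", "Moderate", "Turbid", "VeryTurbid", "Brown")
UNCLASSIFIED = "Unclassified"

#: Default combined-score threshold below which a spectrum stays Unclassified.
DEFAULT_THRESHOLD = 0.8

#: Unordered class pairs counted as a "large" misclassification: the types
#: are more than neighbours apart in the optical gradient.  Every other
#: unequal pair is a "little" difference.
LARGE_DIFFERENCE_PAIRS = frozenset({
    frozenset({"Clear", "Turbid"}),
    frozenset({"Clear", "VeryTurbid"}),
    frozenset({"Clear", "Brown"}),
    frozenset({"Turbid", "Brown"}),
})


def spectral_correlation_similarity(x, r) -> float:
    """SCS in [0, 1]: rescaled Pearson correlation of two band vectors.

    Constant vectors have undefined correlation; the score degenerates to 0.
    Symmetric in its arguments and invariant to any affine rescaling of
    either one.
    """
    x = np.asarray(x, dtype=float)
    r = np.asarray(r, dtype=float)
    if x.shape != r.shape or x.size < 3:
        raise ValueError("SCS needs two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(r) == 0:
        return 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.corrcoef(x, r)[0, 1]
    if not np.isfinite(rho):  # variance underflow -> effectively constant
        return 0.0
    return float(np.clip((rho + 1.0) / 2.0, 0.0, 1.0))


def modified_spectral_angle_similarity(x, r) -> float:
    """MSAS in [0, 1]: 1 - (2/pi) * angle between the two band vectors.

    When either vector carries negative components both are shifted by their
    common minimum so the angle stays within [0, pi/2] and the score within
    bounds.  Invariant to positive scaling of either argument (for
    non-negative input).  Zero-norm vectors degenerate to score 0.
    """
    x = np.asarray(x, dtype=float)
    r = np.asarray(r, dtype=float)
    if x.shape != r.shape or x.size < 2:
        raise ValueError("MSAS needs two equal-length vectors of length >= 2")
    m = min(x.min(), r.min())
    if m < 0:
        x = x - m
        r = r - m
    nx = np.linalg.norm(x)
    nr = np.linalg.norm(r)
    if nx == 0 or nr == 0:
        return 0.0
    cos = np.clip(np.dot(x, r) / (nx * nr), -1.0, 1.0)
    return float(1.0 - (2.0 / np.pi) * np.arccos(cos))


def combined_similarity(x, r) -> float:
    """Arithmetic mean of SCS and MSAS (preserves bounds and symmetry)."""
    return 0.5 * (spectral_correlation_similarity(x, r)
                  + modified_spectral_angle_similarity(x, r))


@dataclass(frozen=True)
class ReferenceLibrary:
    """One labelled per-band reference spectrum per OWT for one sensor."""

    sensor: str
    spectra: Mapping[str, Spectrum]
    band_subset: tuple

    def __post_init__(self):
        object.__setattr__(self, "band_subset", tuple(self.band_subset))
        missing = [c for c in OWT_CLASSES if c not in self.spectra]
        if missing:
            raise ValueError(f"reference library lacks OWTs: {missing}")
        for owt, s in self.spectra.items():
            for b in self.band_subset:
                s.band(b)  # raises UnknownBandError if absent

    def vector(self, owt: str) -> np.ndarray:
        s = self.spectra[owt]
        return np.array([s.band(b) for b in self.band_subset])

    @classmethod
    def default(cls, sensor: str) -> "ReferenceLibrary":
        """Shipped synthetic reference archetypes (stand-ins generated by the
        bio-optical forward model, not the published boreal references)."""
        from .synthetic import reference_library

        return reference_library(sensor)

    @classmethod
    def from_csv(cls, path, sensor: str, band_subset: Sequence[str] | None = None,
                 source: str = "insitu") -> "ReferenceLibrary":
        """Load user references from a CSV with columns owt, band, value."""
        from .spectra import band_set_for

        df = pd.read_csv(path)
        bs = band_set_for(sensor)
        spectra = {}
        for owt, grp in df.groupby("owt"):
            names = list(grp["band"])
            centers = np.array([bs[b].center for b in names])
            order = np.argsort(centers)
            spectra[str(owt)] = Spectrum(
                centers[order], grp["value"].to_numpy()[order],
                source=source, sensor=sensor,
                bands=[names[i] for i in order])
        subset = tuple(band_subset) if band_subset else tuple(
            spectra[next(iter(spectra))].bands)
        return cls(sensor, spectra, subset)

    def to_csv(self, path) -> None:
        rows = [
            {"owt": owt, "band": b, "value": s.band(b)}
            for owt, s in self.spectra.items()
            for b in s.bands
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass(frozen=True)
class SimilarityResult:
    """Scores of one spectrum against all five references."""

    scs: Mapping[str, float]
    msas: Mapping[str, float]
    combined: Mapping[str, float]
    label: str
    best_label: str
    margin: float
    degenerate: bool = False
    tied: bool = False


def _vector_from(x, band_subset) -> np.ndarray:
    if isinstance(x, Spectrum):
        return np.array([x.band(b) for b in band_subset])
    x = np.asarray(x, dtype=float)
    if x.size != len(band_subset):
        raise UnknownBandError(
            f"expected {len(band_subset)} band values, got {x.size}")
    return x


def classify(x, lib: ReferenceLibrary,
             threshold: float = DEFAULT_THRESHOLD) -> SimilarityResult:
    """Assign an OWT by maximum combined similarity to the references.

    ``x`` is a per-band Spectrum covering the library's band subset (or a
    bare vector in band-subset order).  Degenerate input (constant or
    all-zero over the subset, or any non-finite value) is Unclassified.
    Exact score ties break by the fixed class order and are recorded.
    """
    v = _vector_from(x, lib.band_subset)
    scs, msas, comb = {}, {}, {}
    degenerate = not np.all(np.isfinite(v)) or np.ptp(v) == 0 or np.linalg.norm(v) == 0
    for owt in OWT_CLASSES:
        r = lib.vector(owt)
        if degenerate:
            scs[owt] = msas[owt] = comb[owt] = 0.0
            continue
        scs[owt] = spectral_correlation_similarity(v, r)
        msas[owt] = modified_spectral_angle_similarity(v, r)
        comb[owt] = 0.5 * (scs[owt] + msas[owt])
    best = max(OWT_CLASSES, key=lambda c: comb[c])  # ties -> first in order
    ordered = sorted((comb[c] for c in OWT_CLASSES), reverse=True)
    margin = ordered[0] - ordered[1]
    tied = margin == 0.0 and not degenerate
    label = best
    if degenerate or comb[best] < threshold:
        label = UNCLASSIFIED
    return SimilarityResult(scs, msas, comb, label, best, margin,
                            degenerate=degenerate, tied=tied)


def classify_scene(stack: SceneStack, lib: ReferenceLibrary,
                   threshold: float = DEFAULT_THRESHOLD,
                   valid_mask: np.ndarray | None = None):
    """Classify every pixel of a gridded band stack.

    Returns ``(labels, scores)``: an object array of labels and the winning
    combined score per pixel.  Pixels failing the validity mask (or with any
    non-finite band) come out Unclassified with score NaN.
    """
    missing = [b for b in lib.band_subset if b not in stack.bands]
    if missing:
        raise UnknownBandError(f"scene lacks classification bands: {missing}")
    ny, nx = stack.shape
    labels = np.full((ny, nx), UNCLASSIFIED, dtype=object)
    scores = np.full((ny, nx), np.nan)
    sub = np.stack([stack.band(b) for b in lib.band_subset])
    for iy in range(ny):
        for ix in range(nx):
            if valid_mask is not None and not valid_mask[iy, ix]:
                continue
            v = sub[:, iy, ix]
            if not np.all(np.isfinite(v)):
                continue
            res = classify(v, lib, threshold=threshold)
            labels[iy, ix] = res.label
            if not res.degenerate:
                scores[iy, ix] = res.combined[res.best_label]
    return labels, scores


def owt_error_magnitude(truth: str, derived: str) -> str:
    """Categorise a (true, derived) OWT pair.

    ``correct`` for equal labels; ``unclassified`` when the derived label is
    the Unclassified sentinel; ``large`` for pairs far apart in the optical
    gradient (Clear-Turbid, Clear-VeryTurbid, Clear-Brown, Turbid-Brown);
    ``little`` for every other unequal pair.  Symmetric in its arguments for
    the large/little decision.
    """
    valid = OWT_CLASSES + (UNCLASSIFIED,)
    if truth not in valid or derived not in valid:
        raise ValueError(f"invalid OWT label in pair ({truth!r}, {derived!r})")
    if derived == UNCLASSIFIED:
        return "unclassified"
    if truth == derived:
        return "correct"
    if frozenset({truth, derived}) in LARGE_DIFFERENCE_PAIRS:
        return "large"
    return "little"
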
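# Methods

## The pipeline

`lakeowt` implements an optical-water-type (OWT) guided retrieval chain for
boreal lakes observed by Sentinel-2 MSI and Sentinel-3 OLCI:

1. **Band calculation.** Hyperspectral above-water reflectance (the
   dimensionless ratio of water-leaving radiance to a white reference
   panel; no π scaling anywhere in the package) is convolved to sensor
   bands with spectral response functions. SRFs are tabulated
   (wavelength, weight) pairs; where only band centres are known, Gaussian
   SRFs are synthesised from (centre, FWHM). Band values are
   SRF-weighted means computed by trapezoid integration on the union of
   the SRF and spectrum grids, with linear interpolation between samples
   and weights normalised to unit integral over the overlap. This makes
   resampling exactly constant-preserving and linear, which the tests
   exercise as invariants.
2. **OWT classification.** Five types — Clear, Moderate, Turbid (TSM
   dominated), Very Turbid (Chl-a dominated), Brown (CDOM dominated) — are
   assigned by maximum similarity to per-type reference band spectra. The
   score is the arithmetic mean of two bounded shape measures: SCS
   (rescaled Pearson correlation, (ρ+1)/2) and MSAS (1 − (2/π)·angle
   between the vectors, after shifting both by their common minimum when
   negative reflectances occur so the angle stays in [0, π/2]). Both are
   invariant to positive scaling, so classification responds to spectral
   shape, not brightness. Below a combined-score threshold the pixel is
   `Unclassified`; exact ties break deterministically in the fixed class
   order Clear → Brown and are recorded.
3. **Retrieval.** A registry maps (sensor, product, OWT) to one algorithm:
   a predictor expression over band reflectances of one source (TOA,
   C2RCC or C2X — C2X exists only for MSI) or neural-network processor
   fields, and a response form with fixed published coefficients. The
   builtin registry holds all 40 combinations. Secchi depth entries that
   reference `kd490` traverse the attenuation chain (below).
4. **Validation.** In-situ and satellite tables are paired by station
   within ±1 day (date-only granularity; each pair counts independently,
   so one station can contribute up to three match-ups). Skill is
   R² = 1 − SSres/SStot, implemented literally (negative values are
   reported, not clamped) and RMSE, per group and pooled over pairs, with
   grouping by lake, by in-situ terciles (cutpoints configurable) or by
   OWT. OWT skill is accuracy plus a correct/little/large/unclassified
   breakdown, where "large" means the unordered pair is one of
   Clear–Turbid, Clear–VeryTurbid, Clear–Brown, Turbid–Brown.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| classification threshold | 0.8 | combined score below which a spectrum is Unclassified; the published method reports unclassified pixels but no cutoff, so this is this package's choice, configurable per call |
| classification band subset | all builtin bands (≤ 865 nm) | the classifier uses the full visible–NIR shape (spectral maximum, slopes, amplitude) |
| Kd490 model (c0, c1, c2) | (−0.32, −1.2, 0.7) | log10 Kd490 = c0 + c1·log10(R490/R560) + c2·log10(Rred/R560), Rred = 705 nm (MSI) / 708.75 nm (OLCI) |
| KdPAR transform | 0.4349·Kd490 + 0.3291 | fixed published linear transform (m⁻¹) |
| SD transform | 1.6941·KdPAR^−0.677 | fixed published power law (m) |
| CDOM spectral slope | 0.017 nm⁻¹ | converts a_CDOM(400) to 412/442 nm |

**The Kd490 coefficients are placeholders.** The published chain cites an
external Kd490 band-ratio algorithm whose branch coefficients are not
reproduced here; the implemented model keeps the documented structure
(blue/green ratio falling, red/green ratio rising with attenuation, hence
c1 < 0 and c2 > 0, positivity by construction, monotone in the red band)
and is explicitly pluggable. The KdPAR and SD transforms downstream of it
are exact.

Quadratic responses are non-monotonic, and the underlying fits are only
valid on the bounded predictor ranges they were calibrated on; each
quadratic entry therefore carries a domain interval outside which the
output is missing with a diagnostic. Power-law responses require a
positive predictor. Missing inputs propagate as NaN — never silently as
zero — and division by zero in a predictor yields a missing value with a
diagnostic.

One printed formula uses a 550 nm band that neither sensor has; it is
encoded against the 560 nm green band (the nearest on both sensors) with a
provenance note on the registry entry. The OLCI NIR band sum is bound as
(R779 − R754) + R865/2, matching the MSI analogue of the same source
algorithm. A comma-decimal exponent in the SD source table is read as
−0.677.

## The synthetic data generator

The field campaign behind the registry coefficients is not public, so the
package generates its own inputs, with two deliberately different paths:

**Scenes and archetypes** use a simple semi-analytical forward model,
R(λ) = f·b_b/(a + b_b), with absorption a = a_w + chl·a*_ph + a_NAP +
a_CDOM and backscatter b_b = b_b,w + tsm·b*_bp·(550/λ)^0.6. The
chl-specific absorption combines the 440 and 675 nm pigment peaks with a
broad green shoulder standing in for accessory pigments; the pure-water
table is finer-grained over 650–750 nm so the low-absorption window below
710 nm — which produces the characteristic bloom reflectance peak near
700 nm — is resolved. All shape constants live in one editable
`ForwardModelCoeffs` container. Per-OWT constituent regimes follow the
class definitions (Very Turbid: chl ≥ 30 mg m⁻³; Brown: a_CDOM(400) ≥
5 m⁻¹; Turbid: TSM-dominant; magnitudes spanning clear oligotrophic to
shallow very turbid boreal lakes), drawn log-uniformly within each range;
the shipped reference library is the forward model evaluated at the class
median parameters and convolved to each sensor. These references are
synthetic stand-ins, not the published boreal reference spectra — a CSV
loader accepts real ones.

**Match-up tables** do not go through the optics. For each record and
product, a predictor value is sampled from the registry entry's `sim_range`
(chosen so the response stays on one monotone branch and yields plausible
product values), band columns are set algebraically so the predictor
evaluates to exactly that value (already-set bands from earlier products
are reused as constraints), and the in-situ truth is the response of the
sampled predictor. Where two products of one OWT share the identical
predictor (one OLCI case), the second truth is derived forward from the
already-realised bands — the only assignment consistent with both
formulas. Consequently at zero noise OWT-guided retrieval reproduces
every in-situ value exactly, which turns the validation statistics into a
sharp closed-loop test. Noise (`noise_sd`, relative) perturbs the in-situ
values multiplicatively, y·(1 + σ·ε), representing the combined
measurement-plus-retrieval error of a pair, so the pooled RMSE scales as
σ times the product's RMS level.

What passing these tests shows — and does not show. The closed loop
verifies that every formula, the predictor evaluation, the attenuation
chain and the match-up statistics are encoded and wired correctly, and the
scene loop verifies that the classifier separates the five archetype
shapes under parameter jitter. It does not validate the formulas against
nature: band values in match-up tables are algebraic realisations (they can
be radiometrically odd), the forward model has no radiative-transfer
fidelity, no atmosphere, and no attempt to match real campaign spectra, and
the real published validation scores depend on unreleased field data and
are not reproduced here.

## Numerical choices and problem sizes

* SRF integration: trapezoid on the union grid; single-point SRFs act as
  delta kernels (pure interpolation).
* Similarity degeneracies: constant or zero-norm vectors (and variance
  underflow in the correlation) score 0 with a degeneracy flag; degenerate
  or non-finite pixels are Unclassified.
* Coefficient-recovery tests regress each response on a 50-point grid over
  its `sim_range` and require relative agreement to 1e-6 (log-space
  regression for power/exponential forms).
* Default test problem sizes — 16×16 scenes, 120–500 match-up records —
  are the package's choice of a desk-scale demonstration; the whole suite
  runs in a few seconds.

## Known limitations

* The five reference spectra and the Kd490 coefficients are synthetic
  stand-ins (see above).
* Scene IO is CSV/in-memory only; no NetCDF/GeoTIFF gridded reader, no
  geolocation, no atmospheric correction — processor reflectances and
  products are consumed as table columns.
* The error-magnitude pair list and the five-class scheme are fixed; other
  regional OWT schemes would need a different reference library and
  registry.
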
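"""Synthetic ATR-FTIR transmittance spectra with a known degree of substitution.

Each sample is built in absorbance space as a sum of Gaussian peaks whose
depths vary linearly with a latent DS in [0, 3], plus a random smooth cubic
baseline and i.i.d. Gaussian noise, then converted to transmittance via
Beer-Lambert, T = 10^(-A).  The exponential map keeps the DS -> spectrum
relationship only approximately linear, so the regression model is exercised
under realistic mild nonlinearity rather than on data rigged to its own
model class.

The default configuration mimics a cellulose acetate series: acetylation
grows the ester C=O (~1740 cm^-1), acetyl C-H bending (~1375 cm^-1) and
ester C-O (~1230 cm^-1) bands while consuming the broad O-H stretch
(~3400 cm^-1); the fingerprint region carries strong DS-independent skeletal
bands.  The grid is 400-4000 cm^-1 with 1750 points, matching the feature
count of the real instrument data, and DS values are drawn uniformly from
[0.41, 2.96], the range of the 16-sample cellulose acetate reference series.

One integer seed governs everything: per-sample baseline/noise substreams are
spawned deterministically from it, so a dataset is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io import DSVector, SpectraSet

__all__ = [
    "PeakSpec",
    "SyntheticConfig",
    "default_config",
    "generate_dataset",
    "informative_mask",
    "noise_floor_threshold",
]


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian absorbance band.

    ``base_depth`` is the absorbance at DS = 0 and ``ds_slope`` the absorbance
    change per DS unit (negative for bands consumed by substitution, like the
    O-H stretch).  Depth must stay non-negative over the whole DS range [0, 3].
    """

    center: float  # cm^-1
    width: float  # Gaussian sigma, cm^-1
    base_depth: float  # absorbance at DS = 0
    ds_slope: float = 0.0  # absorbance per DS unit

    def __post_init__(self):
        if self.width <= 0:
            raise ValidationError(f"peak at {self.center}: width must be > 0")
        if self.base_depth < 0:
            raise ValidationError(f"peak at {self.center}: base_depth must be >= 0")
        if self.base_depth + 3.0 * self.ds_slope < 0:
            raise ValidationError(
                f"peak at {self.center}: depth would go negative within DS in [0, 3]"
            )

    def depth(self, ds: float) -> float:
        return self.base_depth + self.ds_slope * ds

    def profile(self, grid: np.ndarray) -> np.ndarray:
        return np.exp(-((grid - self.center) ** 2) / (2.0 * self.width**2))


@dataclass(frozen=True)
class SyntheticConfig:
    grid_min: float = 400.0
    grid_max: float = 4000.0
    n_points: int = 1750
    peaks: tuple[PeakSpec, ...] = ()
    baseline_amplitude: float = 0.01  # absorbance units, per-sample cubic drift
    noise_sd: float = 0.002  # absorbance units, i.i.d. per grid point
    ds_low: float = 0.41
    ds_high: float = 2.96
    ds_values: tuple[float, ...] | None = None  # explicit DS list overrides uniform
    seed: int = 0

    def __post_init__(self):
        if self.n_points < 2:
            raise ValidationError("n_points must be >= 2")
        if not self.grid_min < self.grid_max:
            raise ValidationError("grid_min must be < grid_max")
        if self.baseline_amplitude < 0 or self.noise_sd < 0:
            raise ValidationError("baseline_amplitude and noise_sd must be >= 0")
        for bound in (self.ds_low, self.ds_high):
            if not 0.0 <= bound <= 3.0:
                raise ValidationError(f"DS bound {bound} outside [0, 3]")
        if self.ds_low > self.ds_high:
            raise ValidationError("ds_low must be <= ds_high")
        if self.ds_values is not None:
            vals = tuple(float(v) for v in self.ds_values)
            for v in vals:
                if not 0.0 <= v <= 3.0:
                    raise ValidationError(f"explicit DS value {v} outside [0, 3]")
            object.__setattr__(self, "ds_values", vals)

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.grid_min, self.grid_max, self.n_points)

    def to_dict(self) -> dict:
        return asdict(self)


# Band assignments (centers in cm^-1) for an acetylated cellulose:
#   growing with DS:  C=O ester stretch, C-H bending of the acetyl methyl,
#                     C-O ester stretch, aliphatic C-H stretch
#   consumed by DS:   broad O-H stretch
#   DS-independent:   pyranose-ring skeletal bands in the fingerprint region
#
# The pyranose C-O-C band is given the largest depth at every DS, matching real
# cellulose acetate spectra where it is the most intense band throughout the
# series.  This matters beyond realism: the per-sample min-max normalization
# uses the deepest band and the absorption-free window as reference points, and
# only when both are DS-independent does the normalized spectrum stay an exact
# (exponential-family) function of DS that an intercept-free linear model can
# calibrate without systematic error.
_DEFAULT_PEAKS = (
    PeakSpec(center=1740.0, width=18.0, base_depth=0.02, ds_slope=0.30),  # C=O
    PeakSpec(center=1375.0, width=14.0, base_depth=0.02, ds_slope=0.20),  # C-H bend
    PeakSpec(center=1230.0, width=25.0, base_depth=0.03, ds_slope=0.28),  # C-O ester
    PeakSpec(center=2900.0, width=30.0, base_depth=0.05, ds_slope=0.05),  # C-H stretch
    PeakSpec(center=3400.0, width=90.0, base_depth=0.50, ds_slope=-0.15),  # O-H
    PeakSpec(center=1040.0, width=30.0, base_depth=1.20, ds_slope=0.0),  # ring C-O-C
    PeakSpec(center=900.0, width=12.0, base_depth=0.12, ds_slope=0.0),  # ring breathing
    PeakSpec(center=600.0, width=20.0, base_depth=0.10, ds_slope=0.0),  # skeletal def.
)


def default_config(**overrides) -> SyntheticConfig:
    """Default cellulose-acetate-like configuration (see module docstring)."""
    params = {"peaks": _DEFAULT_PEAKS}
    params.update(overrides)
    return SyntheticConfig(**params)


def _baseline(rng: np.random.Generator, x: np.ndarray, amplitude: float) -> np.ndarray:
    """Random cubic polynomial over the grid, scaled to max |value| = amplitude."""
    if amplitude == 0:
        return np.zeros_like(x)
    coeffs = rng.normal(0.0, 1.0, size=4)
    raw = np.polyval(coeffs, x)
    peak = np.max(np.abs(raw))
    if peak == 0:
        return np.zeros_like(x)
    return amplitude * raw / peak


def generate_dataset(cfg: SyntheticConfig, n_samples: int) -> tuple[SpectraSet, DSVector]:
    """Draw ``n_samples`` spectra with known DS; bit-reproducible from cfg.seed."""
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    grid = cfg.grid
    x = np.linspace(-1.0, 1.0, cfg.n_points)  # baseline coordinate

    ss = np.random.SeedSequence(cfg.seed)
    ds_child, *sample_children = ss.spawn(n_samples + 1)
    if cfg.ds_values is not None:
        if len(cfg.ds_values) != n_samples:
            raise ValidationError(
                f"{len(cfg.ds_values)} explicit DS values but n_samples={n_samples}"
            )
        ds = np.asarray(cfg.ds_values, dtype=float)
    else:
        ds = np.random.default_rng(ds_child).uniform(cfg.ds_low, cfg.ds_high, n_samples)

    profiles = np.stack([p.profile(grid) for p in cfg.peaks]) if cfg.peaks else None
    rows = np.empty((n_samples, cfg.n_points))
    for i in range(n_samples):
        rng = np.random.default_rng(sample_children[i])
        A = np.zeros(cfg.n_points)
        if profiles is not None:
            depths = np.array([p.depth(ds[i]) for p in cfg.peaks])
            A += depths @ profiles
        A += _baseline(rng, x, cfg.baseline_amplitude)
        if cfg.noise_sd > 0:
            A += rng.normal(0.0, cfg.noise_sd, cfg.n_points)
        rows[i] = 10.0 ** (-A)

    sset = SpectraSet(
        sample_ids=[f"synth-{i:04d}" for i in range(n_samples)],
        grid=grid,
        matrix=rows,
        normalized=False,
    )
    return sset, DSVector(ds, source_label="synthetic")


def noise_floor_threshold(cfg: SyntheticConfig) -> float:
    """The |dA/dDS| level at which the DS signal matches one noise sd.

    A wavenumber carries detectable DS information when its absorbance swing
    across the sampled DS spread exceeds the per-point noise:
    |dA/dDS| * sd(DS) > noise_sd.  This is the principled default threshold
    for :func:`informative_mask`.
    """
    if cfg.ds_values is not None:
        sd_ds = float(np.std(cfg.ds_values, ddof=1)) if len(cfg.ds_values) > 1 else 1.0
    else:
        sd_ds = (cfg.ds_high - cfg.ds_low) / np.sqrt(12.0)
    if sd_ds == 0:
        raise ValidationError("DS spread is zero; noise floor undefined")
    return cfg.noise_sd / sd_ds


def informative_mask(cfg: SyntheticConfig, threshold: float) -> np.ndarray:
    """Ground-truth DS-informative grid indices.

    Indices where the DS sensitivity |dA/dDS| = sum_p |slope_p| * gaussian_p
    reaches the threshold.  Used as the oracle for feature-selection tests.
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    grid = cfg.grid
    sens = np.zeros(cfg.n_points)
    for p in cfg.peaks:
        sens += abs(p.ds_slope) * p.profile(grid)
    return np.nonzero(sens >= threshold)[0]
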
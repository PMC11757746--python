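"""Per-sample min-max normalization and wavenumber-region restriction.

Each raw transmittance spectrum is affinely rescaled to span exactly [0, 1]
before any modeling.  Normalization always acts on the full measured grid;
region restriction happens afterwards and never re-normalizes, so models fit
on different regions see values on an identical scale.

Region bounds are treated as half-open intervals [low, high) on the grid
values.  The literature on cellulose acetate writes strict inequalities on
both sides of each region; a convention has to be fixed, and the half-open
one composes without gaps or overlap at the 1500 cm^-1 fingerprint boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateSpectrumError, EmptyRegionError, ValidationError
from .io import SpectraSet

__all__ = ["RegionMask", "min_max_normalize", "named_regions", "apply_mask", "parse_region"]


@dataclass
class RegionMask:
    """A named union of half-open wavenumber intervals, optionally bound to a grid."""

    name: str
    intervals: tuple[tuple[float, float], ...]
    indices: np.ndarray | None = field(default=None)

    def __post_init__(self):
        ivals = tuple((float(lo), float(hi)) for lo, hi in self.intervals)
        for lo, hi in ivals:
            if not lo < hi:
                raise ValidationError(f"region {self.name!r}: interval ({lo}, {hi}) empty")
        for (a_lo, a_hi), (b_lo, b_hi) in zip(sorted(ivals), sorted(ivals)[1:]):
            if b_lo < a_hi:
                raise ValidationError(f"region {self.name!r}: overlapping intervals")
        self.intervals = ivals

    def bind(self, grid) -> "RegionMask":
        """Resolve the intervals to indices on ``grid`` (half-open [low, high))."""
        grid = np.asarray(grid, dtype=float)
        keep = np.zeros(grid.size, dtype=bool)
        for lo, hi in self.intervals:
            keep |= (grid >= lo) & (grid < hi)
        idx = np.nonzero(keep)[0]
        if idx.size == 0:
            raise EmptyRegionError(
                f"region {self.name!r} selects no wavenumbers on grid "
                f"[{grid[0]}, {grid[-1]}] cm^-1"
            )
        return RegionMask(self.name, self.intervals, idx)


def min_max_normalize(x: SpectraSet) -> SpectraSet:
    """Rescale every spectrum row to span [0, 1] exactly.

    The mapping is (T_raw - min) / (max - min), applied per sample over the
    full measured grid.  Idempotent: a set already flagged normalized is
    returned unchanged.
    """
    if x.normalized:
        return x
    lo = x.matrix.min(axis=1, keepdims=True)
    hi = x.matrix.max(axis=1, keepdims=True)
    span = hi - lo
    flat = np.nonzero(span[:, 0] == 0)[0]
    if flat.size:
        raise DegenerateSpectrumError(
            f"sample {x.sample_ids[flat[0]]!r}: constant spectrum cannot be "
            "min-max normalized"
        )
    mat = (x.matrix - lo) / span
    # enforce the invariant bit-exactly against rounding in the division
    np.clip(mat, 0.0, 1.0, out=mat)
    mat[np.arange(x.n_samples), np.argmin(x.matrix, axis=1)] = 0.0
    mat[np.arange(x.n_samples), np.argmax(x.matrix, axis=1)] = 1.0
    return SpectraSet(list(x.sample_ids), x.grid, mat, normalized=True)


def named_regions() -> dict[str, RegionMask]:
    """The eight standard wavenumber regions (cm^-1) used in the region study.

    ``CO``/``CH``/``C_O`` are the ester C=O, acetyl C-H bending and ester C-O
    stretch windows; ``random_control`` is a deliberately information-free
    window used as a negative control.
    """
    inf = math.inf
    return {
        "full": RegionMask("full", ((-inf, inf),)),
        "non_fingerprint": RegionMask("non_fingerprint", ((1500.0, inf),)),
        "fingerprint": RegionMask("fingerprint", ((-inf, 1500.0),)),
        "CO": RegionMask("CO", ((1600.0, 1800.0),)),
        "CH": RegionMask("CH", ((1325.0, 1425.0),)),
        "C_O": RegionMask("C_O", ((1150.0, 1300.0),)),
        "combined": RegionMask("combined", ((1150.0, 1800.0),)),
        "random_control": RegionMask("random_control", ((2000.0, 2500.0),)),
    }


def parse_region(spec: str) -> RegionMask:
    """Resolve a region by name or as explicit ``low:high`` cm^-1 pairs.

    Multiple intervals may be comma-separated, e.g. ``"1150:1300,1600:1800"``.
    """
    regions = named_regions()
    if spec in regions:
        return regions[spec]
    intervals = []
    for part in spec.split(","):
        lo, sep, hi = part.partition(":")
        if not sep:
            raise ValidationError(
                f"unknown region {spec!r}; use one of {sorted(regions)} or low:high"
            )
        try:
            intervals.append((float(lo), float(hi)))
        except ValueError as exc:
            raise ValidationError(f"cannot parse region bounds {part!r}") from exc
    return RegionMask(spec, tuple(intervals))


def apply_mask(x: SpectraSet, m: RegionMask) -> SpectraSet:
    """Restrict a normalized SpectraSet to the columns of a region mask.

    Retained values are unchanged — there is no re-normalization after
    masking, by design.
    """
    if not x.normalized:
        raise ValidationError("apply_mask expects a normalized SpectraSet")
    bound = m if m.indices is not None else m.bind(x.grid)
    if bound.indices is not None and bound.indices.size == x.n_features and np.array_equal(
        bound.indices, np.arange(x.n_features)
    ):
        return x
    return x.select_columns(bound.indices)  # masking never alters retained values
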
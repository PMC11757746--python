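"""Spectrum, dataset and model file I/O.

Spectra are wavenumber/transmittance series read from two-column CSV files
(header optional, comma or whitespace separated) or from simple JCAMP-DX
files.  A dataset manifest is a CSV with columns ``sample_id``,
``spectrum_path``, ``ds`` and optionally ``source_label``; all spectra are
placed on the wavenumber grid of the first manifest entry by linear
interpolation (never extrapolation).  Trained models are serialized to JSON
with full decimal precision so a read/write round trip is bit-exact.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    FormatError,
    ParseError,
    ValidationError,
)

MODEL_FORMAT_VERSION = 1

__all__ = [
    "Spectrum",
    "SpectraSet",
    "DSVector",
    "ModelFile",
    "read_spectrum",
    "read_dataset",
    "align_to_grid",
    "write_model",
    "read_model",
]


@dataclass(frozen=True)
class Spectrum:
    """One sample's transmittance spectrum on a strictly increasing grid."""

    sample_id: str
    wavenumbers: np.ndarray
    transmittance: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        wn = np.asarray(self.wavenumbers, dtype=float)
        tr = np.asarray(self.transmittance, dtype=float)
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "transmittance", tr)
        if wn.ndim != 1 or tr.ndim != 1:
            raise ValidationError(f"{self.sample_id}: spectrum arrays must be 1-D")
        if wn.size < 2:
            raise ValidationError(f"{self.sample_id}: spectrum needs at least 2 points")
        if tr.size != wn.size:
            raise ValidationError(
                f"{self.sample_id}: wavenumbers ({wn.size}) and transmittance "
                f"({tr.size}) differ in length"
            )
        if not np.all(np.isfinite(wn)) or not np.all(np.isfinite(tr)):
            raise ValidationError(f"{self.sample_id}: non-finite values in spectrum")
        d = np.diff(wn)
        if np.any(d == 0):
            raise ValidationError(f"{self.sample_id}: duplicate wavenumbers")
        if np.any(d < 0):
            raise ValidationError(f"{self.sample_id}: wavenumbers not sorted")

    @property
    def n_points(self) -> int:
        return int(self.wavenumbers.size)


@dataclass
class SpectraSet:
    """S x M matrix of transmittance values on one shared wavenumber grid.

    ``normalized`` records that per-sample min-max normalization has been
    applied (over the full measured grid); ``masked`` that columns have since
    been restricted to a wavenumber region, after which rows keep their
    normalized values but no longer span [0, 1] individually.
    """

    sample_ids: list[str]
    grid: np.ndarray
    matrix: np.ndarray
    normalized: bool = False
    masked: bool = False

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValidationError("matrix must be 2-D (samples x wavenumbers)")
        s, m = self.matrix.shape
        if s < 1 or m < 1:
            raise ValidationError("matrix must have at least one row and column")
        if len(self.sample_ids) != s:
            raise ValidationError("sample_ids length does not match matrix rows")
        if self.grid.shape != (m,):
            raise ValidationError("grid length does not match matrix columns")
        if np.any(np.diff(self.grid) <= 0):
            raise ValidationError("grid must be strictly increasing")
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("matrix contains non-finite values")
        if self.normalized and not self.masked:
            lo = self.matrix.min(axis=1)
            hi = self.matrix.max(axis=1)
            if not (np.all(lo == 0.0) and np.all(hi == 1.0)):
                raise ValidationError("normalized flag set but rows do not span [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def select_rows(self, rows: Sequence[int]) -> "SpectraSet":
        rows = np.asarray(rows, dtype=int)
        return SpectraSet(
            sample_ids=[self.sample_ids[i] for i in rows],
            grid=self.grid,
            matrix=self.matrix[rows],
            normalized=self.normalized,
            masked=self.masked,
        )

    def select_columns(self, cols: Sequence[int]) -> "SpectraSet":
        """Column subset; values unchanged, result is flagged masked."""
        cols = np.asarray(cols, dtype=int)
        return SpectraSet(
            sample_ids=list(self.sample_ids),
            grid=self.grid[cols],
            matrix=self.matrix[:, cols],
            normalized=self.normalized,
            masked=True,
        )


@dataclass
class DSVector:
    """Reference degree-of-substitution values aligned with a SpectraSet."""

    values: np.ndarray
    source_label: str = ""

    def __post_init__(self):
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValidationError("DS values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("DS values must be finite")
        if np.any(self.values < 0):
            raise ValidationError("DS values must be non-negative")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class ModelFile:
    """Serializable regression model: grid, selected indices and weights."""

    grid: np.ndarray
    selected_indices: np.ndarray | str  # integer indices into grid, or "all"
    weights: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if isinstance(self.selected_indices, str):
            if self.selected_indices != "all":
                raise ValidationError("selected_indices must be indices or 'all'")
            n_sel = self.grid.size
        else:
            self.selected_indices = np.asarray(self.selected_indices, dtype=int)
            if np.any(np.diff(self.selected_indices) <= 0):
                raise ValidationError("selected_indices must be strictly increasing")
            if self.selected_indices.size and (
                self.selected_indices[0] < 0
                or self.selected_indices[-1] >= self.grid.size
            ):
                raise ValidationError("selected_indices out of grid bounds")
            n_sel = self.selected_indices.size
        if self.weights.size != n_sel:
            raise ValidationError(
                f"weights length {self.weights.size} does not match "
                f"{n_sel} selected indices"
            )
        if not np.all(np.isfinite(self.weights)):
            raise ValidationError("weights must be finite")


# ---------------------------------------------------------------------------
# spectrum readers

_NUMERIC_RE = re.compile(r"^[-+]?(\d+\.?\d*|\.\d+)([eE][-+]?\d+)?$")


def _parse_two_columns(line: str):
    parts = [p for p in re.split(r"[,;\s]+", line.strip()) if p]
    if len(parts) < 2:
        return None
    if not (_NUMERIC_RE.match(parts[0]) and _NUMERIC_RE.match(parts[1])):
        return None
    return float(parts[0]), float(parts[1])


def _read_csv_spectrum(path: Path) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            pair = _parse_two_columns(stripped)
            if pair is None:
                if lineno == 1:  # header row
                    continue
                raise ParseError(f"{path}: cannot parse line {lineno}: {stripped!r}")
            xs.append(pair[0])
            ys.append(pair[1])
    if len(xs) < 2:
        raise ParseError(f"{path}: fewer than 2 data points")
    return np.asarray(xs), np.asarray(ys)


def _read_jcamp_spectrum(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Minimal JCAMP-DX reader: AFFN ``XYDATA=(X++(Y..Y))`` and ``XYPOINTS``.

    Compressed ASDF forms (SQZ/DIF/DUP) are not supported; files using them
    raise a parse error rather than being silently misread.
    """
    header: dict[str, str] = {}
    data_lines: list[str] = []
    mode = None
    with open(path) as fh:
        for line in fh:
            line = line.split("$$")[0].rstrip()  # strip JCAMP comments
            if not line:
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                value = value.strip()
                if key == "XYDATA":
                    mode = "xydata"
                    continue
                if key == "XYPOINTS":
                    mode = "xypoints"
                    continue
                if key == "END":
                    break
                mode = None
                header[key] = value
            elif mode is not None:
                data_lines.append(line)
    if mode is None and not data_lines:
        raise ParseError(f"{path}: no XYDATA/XYPOINTS block found")

    def _hdr_float(key: str, default: float | None = None) -> float:
        if key in header:
            return float(header[key])
        if default is None:
            raise ParseError(f"{path}: missing required JCAMP field ##{key}")
        return default

    xs: list[float] = []
    ys: list[float] = []
    if mode == "xypoints":
        for line in data_lines:
            for chunk in re.split(r"[;]+", line):
                pair = _parse_two_columns(chunk)
                if pair is not None:
                    xs.append(pair[0])
                    ys.append(pair[1])
    else:  # (X++(Y..Y))
        xfactor = _hdr_float("XFACTOR", 1.0)
        yfactor = _hdr_float("YFACTOR", 1.0)
        for line in data_lines:
            tokens = [t for t in re.split(r"[,\s]+", line.strip()) if t]
            if len(tokens) < 2:
                continue
            for tok in tokens:
                if not _NUMERIC_RE.match(tok):
                    raise ParseError(
                        f"{path}: unsupported (non-AFFN) JCAMP token {tok!r}"
                    )
            x0 = float(tokens[0]) * xfactor
            yvals = [float(t) * yfactor for t in tokens[1:]]
            xs.extend([x0] * len(yvals))  # x spacing fixed below
            ys.extend(yvals)
        npoints = int(_hdr_float("NPOINTS", len(ys)))
        if len(ys) != npoints:
            raise ParseError(
                f"{path}: NPOINTS={npoints} but {len(ys)} Y values were read"
            )
        firstx = _hdr_float("FIRSTX") * 1.0
        lastx = _hdr_float("LASTX") * 1.0
        xs = list(np.linspace(firstx, lastx, npoints))
    if len(xs) < 2:
        raise ParseError(f"{path}: fewer than 2 data points")
    return np.asarray(xs), np.asarray(ys)


def read_spectrum(path, dialect: str | None = None) -> Spectrum:
    """Read one spectrum from a CSV or JCAMP-DX file.

    Files stored with descending wavenumbers (common for FTIR exports) are
    reversed to the ascending canonical order; the original orientation is
    recorded in ``Spectrum.meta['orientation']``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"spectrum file not found: {path}")
    if dialect is None:
        dialect = "jcamp-dx" if path.suffix.lower() in {".jdx", ".dx", ".jcm"} else "csv"
    if dialect == "csv":
        wn, tr = _read_csv_spectrum(path)
    elif dialect in {"jcamp-dx", "jcamp"}:
        wn, tr = _read_jcamp_spectrum(path)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    orientation = "ascending"
    if wn.size >= 2 and wn[0] > wn[-1]:
        wn, tr = wn[::-1].copy(), tr[::-1].copy()
        orientation = "descending"
    order = np.argsort(wn, kind="stable")
    wn, tr = wn[order], tr[order]
    if np.any(np.diff(wn) == 0):
        raise ValidationError(f"{path}: duplicate wavenumbers")
    return Spectrum(
        sample_id=path.stem,
        wavenumbers=wn,
        transmittance=tr,
        meta={"path": str(path), "orientation": orientation},
    )


def align_to_grid(s: Spectrum, grid) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid`` (no extrapolation)."""
    grid = np.asarray(grid, dtype=float)
    lo, hi = s.wavenumbers[0], s.wavenumbers[-1]
    if grid[0] < lo or grid[-1] > hi:
        raise AlignmentError(
            f"{s.sample_id}: target grid [{grid[0]}, {grid[-1]}] extends outside "
            f"source range [{lo}, {hi}]; extrapolation is not performed"
        )
    if grid.shape == s.wavenumbers.shape and np.array_equal(grid, s.wavenumbers):
        return s
    values = np.interp(grid, s.wavenumbers, s.transmittance)
    return Spectrum(s.sample_id, grid, values, meta=dict(s.meta, aligned=True))


# ---------------------------------------------------------------------------
# dataset manifest

def read_dataset(manifest, require_ds: bool = True) -> tuple[SpectraSet, DSVector]:
    """Read a manifest CSV and assemble the aligned spectra matrix.

    The wavenumber grid of the first manifest entry becomes the canonical
    grid; all other spectra are aligned to it by linear interpolation.
    """
    manifest = Path(manifest)
    try:
        table = pd.read_csv(manifest)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ParseError(f"cannot read manifest {manifest}: {exc}") from exc
    required = {"sample_id", "spectrum_path"} | ({"ds"} if require_ds else set())
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"manifest missing columns: {sorted(missing)}")
    if len(table) == 0:
        raise ValidationError("manifest has no rows")

    ds_values = np.full(len(table), np.nan)
    if "ds" in table.columns:
        ds_raw = pd.to_numeric(table["ds"], errors="coerce")
        if require_ds and ds_raw.isna().any():
            bad = table.loc[ds_raw.isna(), "sample_id"].iloc[0]
            raise ValidationError(f"sample {bad!r}: DS value is not numeric")
        if (ds_raw.dropna() < 0).any():
            bad = table.loc[ds_raw < 0, "sample_id"].iloc[0]
            raise ValidationError(f"sample {bad!r}: DS value is negative")
        ds_values = ds_raw.to_numpy(dtype=float)

    base = manifest.parent
    spectra: list[Spectrum] = []
    for _, row in table.iterrows():
        p = Path(row["spectrum_path"])
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise FileNotFoundError(
                f"sample {row['sample_id']!r}: spectrum file not found: {p}"
            )
        s = read_spectrum(p)
        spectra.append(
            Spectrum(str(row["sample_id"]), s.wavenumbers, s.transmittance, s.meta)
        )

    grid = spectra[0].wavenumbers
    rows = [align_to_grid(s, grid).transmittance for s in spectra]
    sset = SpectraSet(
        sample_ids=[s.sample_id for s in spectra],
        grid=grid,
        matrix=np.vstack(rows),
        normalized=False,
    )
    label = ""
    if "source_label" in table.columns and table["source_label"].notna().any():
        label = str(table["source_label"].dropna().iloc[0])
    return sset, DSVector(ds_values if require_ds else np.nan_to_num(ds_values), label)


# ---------------------------------------------------------------------------
# model serialization

def write_model(m: ModelFile, path) -> None:
    """Write a model to JSON with full decimal precision."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "grid": [float(v) for v in m.grid],
        "selected_indices": (
            "all"
            if isinstance(m.selected_indices, str)
            else [int(i) for i in m.selected_indices]
        ),
        "weights": [float(w) for w in m.weights],
        "provenance": m.provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_model(path) -> ModelFile:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON: {exc}") from exc
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise FormatError(f"{path}: unknown model format version {version!r}")
    for key in ("grid", "selected_indices", "weights"):
        if key not in payload:
            raise FormatError(f"{path}: missing field {key!r}")
    try:
        return ModelFile(
            grid=np.asarray(payload["grid"], dtype=float),
            selected_indices=(
                "all"
                if payload["selected_indices"] == "all"
                else np.asarray(payload["selected_indices"], dtype=int)
            ),
            weights=np.asarray(payload["weights"], dtype=float),
            provenance=payload.get("provenance", {}),
        )
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc
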
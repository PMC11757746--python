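import numpy as np
import pytest

from dsir import (
    DSVector,
    SpectraSet,
    default_config,
    generate_dataset,
    min_max_normalize,
)


@pytest.fixture
def tiny_set():
    """Handcrafted 3-sample, 5-point SpectraSet (raw, not normalized)."""
    grid = np.array([1000.0, 1100.0, 1200.0, 1300.0, 1400.0])
    matrix = np.array(
        [
            [2.0, 4.0, 6.0, 3.0, 5.0],
            [0.9, 0.5, 0.7, 0.8, 1.0],
            [10.0, 20.0, 15.0, 30.0, 25.0],
        ]
    )
    return SpectraSet(["a", "b", "c"], grid, matrix)


@pytest.fixture
def synth16():
    """Default synthetic cellulose-acetate-like set, 16 samples, normalized."""
    cfg = default_config(seed=11)
    spectra, ds = generate_dataset(cfg, 16)
    return min_max_normalize(spectra), ds, cfg


def random_regression_instance(rng, s_max=8, m_max=15):
    """Small random (SpectraSet, DSVector) pair for oracle comparisons."""
    s = int(rng.integers(3, s_max + 1))
    m = int(rng.integers(1, m_max + 1))
    matrix = rng.uniform(0.0, 1.0, size=(s, m))
    grid = np.sort(rng.uniform(400, 4000, size=m))
    while np.any(np.diff(grid) == 0):  # pragma: no cover - vanishing probability
        grid = np.sort(rng.uniform(400, 4000, size=m))
    ds = rng.uniform(0.01, 3.0, size=s)
    T = SpectraSet([f"s{i}" for i in range(s)], grid, matrix, normalized=True, masked=True)
    return T, DSVector(ds)


def write_synthetic_manifest(tmp_path, n_samples=12, seed=0, **cfg_overrides):
    """Write a small synthetic dataset to disk in the manifest/CSV dialect."""
    cfg = default_config(seed=seed, **cfg_overrides)
    spectra, ds = generate_dataset(cfg, n_samples)
    spec_dir = tmp_path / "spectra"
    spec_dir.mkdir(exist_ok=True)
    rows = ["sample_id,spectrum_path,ds"]
    for i, sid in enumerate(spectra.sample_ids):
        p = spec_dir / f"{sid}.csv"
        lines = ["wavenumber,transmittance"]
        lines += [
            f"{float(wn)!r},{float(tr)!r}"
            for wn, tr in zip(spectra.grid, spectra.matrix[i])
        ]
        p.write_text("\n".join(lines) + "\n")
        rows.append(f"{sid},spectra/{sid}.csv,{float(ds.values[i])!r}")
    manifest = tmp_path / "manifest.csv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest, spectra, ds
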
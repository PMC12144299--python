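"""Dataset loaders and the synthetic generator.

Two UCI CSV dialects are supported: the 9-feature integer-valued dialect
(id, 9 features in 1-10, class 2/4, '?' for missing) and the 30-feature
real-valued dialect (id, M/B diagnosis, 30 reals).  The synthetic generator
emits class-conditional Gaussians with a known informative subset so tests
and benchmarks never need external files.  No downloads are performed;
loaders accept local paths only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from seqtlboga.wrapper_fitness import Dataset

__all__ = [
    "SyntheticSpec",
    "load_wbcd",
    "load_wdbc",
    "load_mb_csv",
    "make_synthetic",
    "write_csv",
]

_WBCD_FEATURES = [
    "clump_thickness",
    "uniformity_cell_size",
    "uniformity_cell_shape",
    "marginal_adhesion",
    "single_epithelial_cell_size",
    "bare_nuclei",
    "bland_chromatin",
    "normal_nucleoli",
    "mitoses",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape of a generated two-class Gaussian-mixture dataset.

    ``mean_shift`` is the class separation of each informative feature in
    noise-SD units; ``correlation`` is the common correlation inside the
    informative block; the remaining features are pure standard noise shared
    by both classes.
    """

    n_samples: int = 400
    n_features: int = 20
    n_informative: int = 5
    class_fraction_positive: float = 0.372
    mean_shift: float = 2.0
    correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_informative <= self.n_features):
            raise ValueError("require 1 <= n_informative <= n_features")
        if not (0.0 < self.class_fraction_positive < 1.0):
            raise ValueError("class_fraction_positive must lie in (0, 1)")
        if not (0.0 <= self.correlation < 1.0):
            raise ValueError("correlation must lie in [0, 1)")
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")


class ParseError(ValueError):
    """Malformed dataset file; message names the offending line."""


def load_wbcd(path: str | Path) -> Dataset:
    """Load the 9-feature integer dialect.

    Drops the id column, removes rows containing ``?`` (complete-case
    policy), and maps class 2 -> 0 (benign), 4 -> 1 (malignant).
    """
    path = Path(path)
    df = pd.read_csv(path, header=None, dtype=str)
    if df.shape[1] != 11:
        raise ParseError(f"{path}: expected 11 comma-separated fields, got {df.shape[1]}")
    complete = ~df.apply(lambda col: col.astype(str).str.strip().eq("?")).any(axis=1)
    df = df[complete]
    try:
        features = df.iloc[:, 1:10].astype(float).to_numpy()
        classes = df.iloc[:, 10].astype(int).to_numpy()
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric field ({exc})") from exc
    bad = ~np.isin(classes, (2, 4))
    if bad.any():
        line = int(df.index[np.flatnonzero(bad)[0]]) + 1
        raise ParseError(f"{path}: unknown class label at line {line}")
    labels = (classes == 4).astype(int)
    return Dataset(features, labels, list(_WBCD_FEATURES), provenance="wbcd")


def load_wdbc(path: str | Path) -> Dataset:
    """Load the 30-feature real-valued dialect (id, M/B diagnosis, 30 reals)."""
    path = Path(path)
    df = pd.read_csv(path, header=None, dtype=str)
    if df.shape[1] != 32:
        raise ParseError(f"{path}: expected 32 comma-separated fields, got {df.shape[1]}")
    diagnosis = df.iloc[:, 1].astype(str).str.strip()
    bad = ~diagnosis.isin(("M", "B"))
    if bad.any():
        line = int(df.index[np.flatnonzero(bad.to_numpy())[0]]) + 1
        raise ParseError(f"{path}: unknown diagnosis at line {line}")
    try:
        features = df.iloc[:, 2:].astype(float).to_numpy()
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric field ({exc})") from exc
    labels = (diagnosis == "M").astype(int).to_numpy()
    names = [f"feature_{i:02d}" for i in range(30)]
    return Dataset(features, labels, names, provenance="wdbc")


def load_mb_csv(path: str | Path) -> Dataset:
    """Generic (id, M/B diagnosis, k real features) layout of any width.

    Synthetic fixtures written by :func:`write_csv` round-trip through this
    loader; the canonical 32-field file is the 30-feature special case.
    """
    path = Path(path)
    df = pd.read_csv(path, header=None, dtype=str)
    if df.shape[1] < 3:
        raise ParseError(f"{path}: expected at least 3 comma-separated fields")
    diagnosis = df.iloc[:, 1].astype(str).str.strip()
    bad = ~diagnosis.isin(("M", "B"))
    if bad.any():
        line = int(df.index[np.flatnonzero(bad.to_numpy())[0]]) + 1
        raise ParseError(f"{path}: unknown diagnosis at line {line}")
    try:
        features = df.iloc[:, 2:].astype(float).to_numpy()
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric field ({exc})") from exc
    labels = (diagnosis == "M").astype(int).to_numpy()
    names = [f"feature_{i:02d}" for i in range(features.shape[1])]
    prov = "wdbc" if features.shape[1] == 30 else "synthetic"
    return Dataset(features, labels, names, provenance=prov)


def make_synthetic(spec: SyntheticSpec) -> tuple[Dataset, np.ndarray]:
    """Generate a two-class Gaussian mixture with a known informative subset.

    Returns ``(dataset, informative_indices)``.  Informative features are
    shifted by ``spec.mean_shift`` between classes (+/- shift/2 around 0)
    with optional equicorrelation inside the informative block; the rest are
    N(0, 1) noise in both classes.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.n_samples * spec.class_fraction_positive))
    n_pos = min(max(n_pos, 2), spec.n_samples - 2)
    labels = np.zeros(spec.n_samples, dtype=int)
    labels[:n_pos] = 1

    X = rng.standard_normal((spec.n_samples, spec.n_features))
    k = spec.n_informative
    if spec.correlation > 0 and k > 1:
        cov = np.full((k, k), spec.correlation)
        np.fill_diagonal(cov, 1.0)
        chol = np.linalg.cholesky(cov)
        X[:, :k] = X[:, :k] @ chol.T
    shift = spec.mean_shift / 2.0
    X[labels == 1, :k] += shift
    X[labels == 0, :k] -= shift

    perm = rng.permutation(spec.n_samples)
    X, labels = X[perm], labels[perm]
    informative = np.arange(k)
    names = [f"inf_{i}" if i < k else f"noise_{i}" for i in range(spec.n_features)]
    return Dataset(X, labels, names, provenance="synthetic"), informative


def write_csv(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset in the 30-feature dialect layout (id, M/B, features)."""
    path = Path(path)
    rows = []
    for i in range(dataset.n_samples):
        diag = "M" if dataset.labels[i] == 1 else "B"
        feats = ",".join(repr(float(v)) for v in dataset.features[i])
        rows.append(f"{i + 1},{diag},{feats}")
    path.write_text("\n".join(rows) + "\n")
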
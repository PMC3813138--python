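"""Synthetic descriptor tables with known ground truth.

Real molecular-descriptor pools are strongly collinear: topological and
autocorrelation descriptors computed from the same graphs move together in
blocks.  The generator emulates exactly that feature — block-exchangeable
Gaussian descriptors (correlation ``within_block_corr`` inside a block,
zero across blocks) with a sparse linear response plus Gaussian noise — so
subset-selection behaviour can be tested against a known active set.  It
does not emulate the heavy tails, integer-valued counts or nonlinear
descriptor/activity relationships of real pools; recovery results here
bound what the search can do under clean conditions, not on any real
dataset.

Columns are named ``D001``, ``D002``, ...; the response is stored in the
table's ``pIC50_obs`` slot so every fitting routine applies unchanged.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .datasets import DescriptorTable, LigandRecord
from .errors import SyntheticSpecError


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic table."""

    n_samples: int
    n_descriptors: int
    block_sizes: tuple[int, ...]
    within_block_corr: float
    active_terms: tuple[int, ...]       # 0-based column indices
    true_coefficients: tuple[float, ...]
    true_intercept: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.block_sizes = tuple(int(b) for b in self.block_sizes)
        self.active_terms = tuple(int(a) for a in self.active_terms)
        self.true_coefficients = tuple(float(c) for c in self.true_coefficients)
        if self.n_samples < 2:
            raise SyntheticSpecError("n_samples must be >= 2")
        if sum(self.block_sizes) != self.n_descriptors:
            raise SyntheticSpecError(
                f"block sizes sum to {sum(self.block_sizes)}, expected {self.n_descriptors}"
            )
        if any(b < 1 for b in self.block_sizes):
            raise SyntheticSpecError("every block must have at least one column")
        # exchangeable correlation is positive definite for rho in
        # (-1/(m-1), 1); only the non-negative range is supported
        if not (0.0 <= self.within_block_corr < 1.0):
            raise SyntheticSpecError(
                f"within_block_corr must lie in [0, 1), got {self.within_block_corr}"
            )
        if len(set(self.active_terms)) != len(self.active_terms):
            raise SyntheticSpecError("active_terms must be distinct")
        if any(not 0 <= a < self.n_descriptors for a in self.active_terms):
            raise SyntheticSpecError("active_terms out of range")
        if len(self.true_coefficients) != len(self.active_terms):
            raise SyntheticSpecError(
                "true_coefficients and active_terms must have equal length"
            )
        if self.noise_sd < 0:
            raise SyntheticSpecError("noise_sd must be >= 0")

    @property
    def active_names(self) -> tuple[str, ...]:
        return tuple(descriptor_name(i, self.n_descriptors) for i in self.active_terms)


@dataclass
class SyntheticTruth:
    """The generator's ground truth for one realized table."""

    spec: SyntheticSpec
    design: np.ndarray          # (n_samples, n_descriptors)
    response: np.ndarray        # (n_samples,)
    attainable_r2: float        # var(signal) / (var(signal) + noise_sd^2)

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self.spec)
        payload["active_names"] = list(self.spec.active_names)
        payload["attainable_r2"] = self.attainable_r2
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def descriptor_name(index: int, n_descriptors: int) -> str:
    width = max(3, len(str(n_descriptors)))
    return f"D{index + 1:0{width}d}"


def generate(spec: SyntheticSpec) -> tuple[DescriptorTable, SyntheticTruth]:
    """Draw one table from the spec; reproducible from ``spec.seed``.

    Within a block, columns share a latent factor:
    ``x = sqrt(rho) * z_block + sqrt(1 - rho) * eps`` gives exactly the
    exchangeable correlation ``rho`` with unit marginal variance.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_descriptors
    rho = spec.within_block_corr
    X = np.empty((n, p))
    col = 0
    for size in spec.block_sizes:
        z = rng.standard_normal((n, 1))
        eps = rng.standard_normal((n, size))
        X[:, col : col + size] = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * eps
        col += size
    signal = spec.true_intercept + X[:, list(spec.active_terms)] @ np.array(
        spec.true_coefficients
    )
    y = signal + rng.normal(0.0, spec.noise_sd, size=n)
    var_signal = float(np.var(signal, ddof=1))
    denom = var_signal + spec.noise_sd**2
    attainable = var_signal / denom if denom > 0 else 1.0

    names = [descriptor_name(j, p) for j in range(p)]
    records = [
        LigandRecord(
            ligand_id=str(i + 1),
            descriptors={nm: float(X[i, j]) for j, nm in enumerate(names)},
            pic50_obs=float(y[i]),
        )
        for i in range(n)
    ]
    table = DescriptorTable(schema=tuple(names), records=records, name="synthetic")
    return table, SyntheticTruth(spec, X, y, attainable)


def recovery_spec(seed: int = 0) -> SyntheticSpec:
    """The benchmark recovery problem used throughout the test suite.

    200 samples, 30 descriptors in six correlated blocks of five
    (within-block correlation 0.6, so each active column has four
    correlated decoys), five active terms — one per block for the first
    five blocks — with unit-magnitude alternating coefficients, and noise
    chosen so the attainable R^2 is about 0.9 (signal variance 5, noise
    variance 5/9).
    """
    return SyntheticSpec(
        n_samples=200,
        n_descriptors=30,
        block_sizes=(5,) * 6,
        within_block_corr=0.6,
        active_terms=(0, 5, 10, 15, 20),
        true_coefficients=(1.0, -1.0, 1.0, -1.0, 1.0),
        true_intercept=0.5,
        noise_sd=float(np.sqrt(5.0 / 9.0)),
        seed=seed,
    )


def table_scale_spec(seed: int = 0, noise_sd: float = 0.4) -> SyntheticSpec:
    """A table at the scale of the packaged datasets: 59 samples, 11
    descriptors in blocks, 3 active terms."""
    return SyntheticSpec(
        n_samples=59,
        n_descriptors=11,
        block_sizes=(4, 4, 3),
        within_block_corr=0.5,
        active_terms=(0, 4, 8),
        true_coefficients=(1.0, -0.8, 0.6),
        true_intercept=2.5,
        noise_sd=noise_sd,
        seed=seed,
    )
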
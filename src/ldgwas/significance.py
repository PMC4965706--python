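"""Empirical significance for r² values.

The tool does not attach an asymptotic p-value to r². Instead a null
distribution of r² is sampled — by default by drawing SNPs (or SNP pairs)
uniformly with replacement from the dataset and recording their observed
statistic, on the premise that the overwhelming majority of sites are null;
optionally with phenotype labels permuted per draw, which breaks any true
association and gives a cleaner null. Observed values are then converted to
upper-tail probabilities, and a multiplicity-corrected alpha can be
translated back into an r² cutoff.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from ._util import atomic_write_text
from .errors import InputError
from .io import HaplotypeMatrix, PhenotypeVector
from .pairs import pair_ld
from .single import single_snp_ld


@dataclass
class NullDistribution:
    """Sorted null r² samples with provenance (seed, mode)."""

    samples: np.ndarray
    seed: int
    mode: str  # "single" or "pair"
    permuted: bool = False

    def __post_init__(self) -> None:
        self.samples = np.sort(np.asarray(self.samples, dtype=float))
        if self.samples.size and (
            self.samples[0] < 0.0 or self.samples[-1] > 1.0
        ):
            raise InputError("null r² samples must lie in [0, 1]")

    @property
    def n(self) -> int:
        return int(self.samples.size)


def sample_null(
    matrix: HaplotypeMatrix,
    pheno: PhenotypeVector,
    n_samples: int,
    mode: str = "single",
    seed: int = 0,
    permute: bool = False,
    strict_phase: bool = False,
) -> NullDistribution:
    """Draw a null distribution of r² values.

    mode="single" draws SNPs uniformly with replacement and records their
    single-SNP r²; mode="pair" draws distinct SNP pairs and records the pair
    r². With ``permute=True`` the case/control labels are freshly permuted
    for every draw. A fixed seed reproduces the distribution exactly.
    """
    if n_samples < 1:
        raise InputError("n_samples must be >= 1")
    if mode not in ("single", "pair"):
        raise InputError(f"mode must be 'single' or 'pair', got {mode!r}")
    if matrix.n_snps == 0:
        raise InputError("cannot sample a null from an empty matrix")
    if mode == "pair" and matrix.n_snps < 2:
        raise InputError("pair mode needs at least 2 SNPs")

    rng = np.random.default_rng(seed)
    out = np.empty(n_samples, dtype=float)
    cache: Dict[int, float] = {}
    codes = pheno.codes
    for t in range(n_samples):
        if mode == "single":
            i = int(rng.integers(matrix.n_snps))
            if permute:
                out[t] = single_snp_ld(
                    matrix.snp_alleles(i), rng.permutation(codes)
                ).r2
            else:
                if i not in cache:
                    cache[i] = single_snp_ld(matrix.snp_alleles(i), codes).r2
                out[t] = cache[i]
        else:
            i = int(rng.integers(matrix.n_snps))
            j = int(rng.integers(matrix.n_snps - 1))
            if j >= i:
                j += 1
            labels = rng.permutation(codes) if permute else codes
            key = i * matrix.n_snps + j
            if permute or key not in cache:
                cache[key] = pair_ld(
                    matrix.snp_alleles(i),
                    matrix.snp_alleles(j),
                    labels,
                    phased_a=matrix.snp_phased(i),
                    phased_b=matrix.snp_phased(j),
                    strict_phase=strict_phase,
                ).r2
            out[t] = cache[key]
    return NullDistribution(out, seed=seed, mode=mode, permuted=permute)


def empirical_p(
    observed_r2: float, null: NullDistribution, conservative: bool = False
) -> float:
    """Upper-tail probability: fraction of null samples >= observed_r2.

    The conservative variant (k+1)/(n+1) never returns 0 and accounts for
    the observed value itself belonging to the null.
    """
    if not 0.0 <= observed_r2 <= 1.0:
        raise InputError(f"observed r² must be in [0, 1], got {observed_r2}")
    k = null.n - int(np.searchsorted(null.samples, observed_r2, side="left"))
    if conservative:
        return (k + 1) / (null.n + 1)
    return k / null.n


class CutoffResult(NamedTuple):
    value: float
    attainable: bool


def r2_cutoff_for_alpha(
    alpha: float, null: NullDistribution, conservative: bool = False
) -> CutoffResult:
    """Smallest null sample c with empirical_p(c) <= alpha.

    If the null's resolution cannot reach alpha (alpha below ~1/n), returns
    (1.0, attainable=False).
    """
    if not 0.0 < alpha <= 1.0:
        raise InputError(f"alpha must be in (0, 1], got {alpha}")
    values, first_idx = np.unique(null.samples, return_index=True)
    n = null.n
    for v, idx in zip(values, first_idx):
        k = n - int(idx)  # count of samples >= v
        p = (k + 1) / (n + 1) if conservative else k / n
        if p <= alpha:
            return CutoffResult(float(v), True)
    return CutoffResult(1.0, False)


def bin_r2(values: Sequence[float], bin_width: float) -> pd.DataFrame:
    """Histogram of r² values over left-closed bins [m·w, (m+1)·w) on [0, 1].

    The last bin is closed so r² = 1 is counted. Returns a DataFrame with
    columns bin_left, bin_right, count; counts sum to len(values).
    """
    if bin_width <= 0:
        raise InputError("bin_width must be positive")
    v = np.asarray(list(values), dtype=float)
    if v.size and (v.min() < 0.0 or v.max() > 1.0):
        raise InputError("r² values must lie in [0, 1]")
    n_bins = int(np.ceil(1.0 / bin_width))
    idx = np.minimum(np.floor(v / bin_width).astype(int), n_bins - 1) if v.size else v
    counts = np.bincount(idx.astype(int), minlength=n_bins) if v.size else np.zeros(
        n_bins, dtype=int
    )
    left = np.arange(n_bins) * bin_width
    right = np.minimum(left + bin_width, 1.0)
    return pd.DataFrame(
        {"bin_left": left, "bin_right": right, "count": counts.astype(int)}
    )


def save_null(null: NullDistribution, prefix: str) -> None:
    """Persist as {prefix}.null.tsv (one r² per line) + {prefix}.null.json."""
    lines = ["r2"] + [repr(float(x)) for x in null.samples]
    atomic_write_text(f"{prefix}.null.tsv", "\n".join(lines) + "\n")
    meta = {
        "n": null.n,
        "seed": null.seed,
        "mode": null.mode,
        "permuted": null.permuted,
    }
    atomic_write_text(f"{prefix}.null.json", json.dumps(meta, indent=2) + "\n")


def load_null(prefix: str) -> NullDistribution:
    """Load a distribution saved by :func:`save_null`."""
    with open(f"{prefix}.null.json") as fh:
        meta = json.load(fh)
    samples = np.loadtxt(f"{prefix}.null.tsv", skiprows=1, dtype=float, ndmin=1)
    return NullDistribution(
        samples, seed=meta["seed"], mode=meta["mode"], permuted=meta["permuted"]
    )
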
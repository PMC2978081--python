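"""Target and reference distributions over coarse-grained variables.

The reference-ratio construction needs a target g(c) and a reference f(c) on
the same coarse space. Two coarse spaces are supported: a scalar radius of
gyration (Gaussian target, binned-histogram reference) and the 8-category
hydrogen-bond descriptor (multinomial target and reference). Kullback-Leibler
divergences are reported in bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm


@dataclass(frozen=True)
class GaussianTarget:
    """Gaussian target over the radius of gyration (Angstrom)."""

    mean: float
    sd: float

    def __post_init__(self):
        if not self.sd > 0:
            raise ValueError("sd must be positive")

    def logpdf(self, rg):
        return gaussian_logpdf(self, rg)


def gaussian_logpdf(target: GaussianTarget, rg):
    """Exact normal log-density at rg (scalar or array)."""
    z = (np.asarray(rg, dtype=float) - target.mean) / target.sd
    out = -0.5 * z ** 2 - math.log(target.sd) - 0.5 * math.log(2.0 * math.pi)
    return float(out) if np.ndim(rg) == 0 else out


def discretize_gaussian(target: GaussianTarget, bin_edges,
                        normalize: bool = True) -> np.ndarray:
    """Per-bin masses of the target on a grid (cdf differences)."""
    cdf = norm.cdf(np.asarray(bin_edges, dtype=float), target.mean, target.sd)
    mass = np.diff(cdf)
    if normalize:
        mass = mass / mass.sum()
    return mass


@dataclass(frozen=True)
class MultinomialModel:
    """Multinomial distribution over descriptor categories."""

    probs: np.ndarray
    pseudocount: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))
        if np.any(self.probs < 0) or abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError("probs must be a probability vector")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")

    def logpmf(self, counts):
        return multinomial_logpmf(self, counts)


def fit_multinomial(count_vectors, pseudocount: float = 0.0) -> MultinomialModel:
    """Maximum-likelihood multinomial fit from count vectors, optionally with
    an additive pseudocount per category (exact ML when pseudocount = 0)."""
    counts = np.atleast_2d(np.asarray(count_vectors, dtype=float))
    if counts.size == 0:
        raise ValueError("at least one count vector required")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = counts.sum(axis=0) + pseudocount
    z = total.sum()
    if z <= 0:
        raise ValueError("all counts zero and pseudocount zero: fit undefined")
    return MultinomialModel(probs=total / z, pseudocount=pseudocount)


def multinomial_logpmf(model: MultinomialModel, counts) -> float:
    """Multinomial log-pmf (with coefficient), n = sum of counts.

    A zero-probability category with a nonzero count gives -inf.
    """
    d = np.asarray(counts, dtype=float)
    if d.shape != model.probs.shape or np.any(d < 0):
        raise ValueError("invalid count vector")
    n = d.sum()
    coeff = gammaln(n + 1.0) - gammaln(d + 1.0).sum()
    with np.errstate(divide="ignore"):
        logp = np.log(model.probs)
    active = d > 0
    if np.any(~np.isfinite(logp[active])):
        return -math.inf
    return float(coeff + (d[active] * logp[active]).sum())


@dataclass
class ReferenceHistogram:
    """Binned reference distribution f(rg) on a strictly increasing grid.

    ``log_mass`` holds normalized per-bin log-masses (empty bins floored with
    a small mass before normalization so that ratios stay finite); values
    outside the grid are assigned a density strictly below every in-support
    bin density.
    """

    bin_edges: np.ndarray
    log_mass: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.log_mass = np.asarray(self.log_mass, dtype=float)
        if self.bin_edges.ndim != 1 or np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.log_mass.shape[0] != self.bin_edges.shape[0] - 1:
            raise ValueError("log_mass length must be number of bins")
        if abs(np.exp(self.log_mass).sum() - 1.0) > 1e-9:
            raise ValueError("bin masses must be normalized")

    @property
    def n_bins(self) -> int:
        return self.log_mass.shape[0]

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def log_density(self) -> np.ndarray:
        """Per-bin log-density (log mass - log width)."""
        return self.log_mass - np.log(self.widths)

    @property
    def out_of_support_log_density(self) -> float:
        return float(self.log_density.min() - math.log(10.0))

    @classmethod
    def from_masses(cls, bin_edges, masses, empty_bin_mass: float = 1e-8,
                    meta: dict | None = None) -> "ReferenceHistogram":
        m = np.asarray(masses, dtype=float).copy()
        if np.any(m < 0):
            raise ValueError("masses must be non-negative")
        m[m == 0] = empty_bin_mass
        m = m / m.sum()
        return cls(bin_edges=np.asarray(bin_edges, dtype=float),
                   log_mass=np.log(m), meta=meta or {})

    def bin_index(self, rg):
        """Half-open bins [lo, hi); -1 marks out-of-support values."""
        edges = self.bin_edges
        idx = np.searchsorted(edges, np.asarray(rg, dtype=float), side="right") - 1
        idx = np.where((np.asarray(rg) < edges[0]) | (np.asarray(rg) >= edges[-1]),
                       -1, np.clip(idx, 0, self.n_bins - 1))
        return int(idx) if np.ndim(rg) == 0 else idx


def histogram_logpdf(ref: ReferenceHistogram, rg):
    """Piecewise-constant log-density; out-of-support values get the floor."""
    idx = np.atleast_1d(ref.bin_index(rg))
    ld = ref.log_density
    out = np.where(idx >= 0, ld[np.clip(idx, 0, ref.n_bins - 1)],
                   ref.out_of_support_log_density)
    return float(out[0]) if np.ndim(rg) == 0 else out


def kl_gaussian_vs_samples(target: GaussianTarget, bin_edges, samples,
                           floor: float = 1e-8) -> float:
    """KL(discretized target || empirical histogram of samples), in bits.

    Both distributions live on the given grid; empty empirical bins are
    floored with a small mass so the divergence stays finite.
    """
    counts, _ = np.histogram(np.asarray(samples, dtype=float), bins=bin_edges)
    emp = counts.astype(float)
    emp = emp / emp.sum()
    emp[emp == 0] = floor
    emp = emp / emp.sum()
    return kl_bits(discretize_gaussian(target, bin_edges), emp)


def kl_bits(p, q) -> float:
    """Kullback-Leibler divergence sum(p * log2(p/q)) over shared bins, in bits.

    Inputs may be unnormalized (counts); both are normalized first. Terms with
    p = 0 contribute zero; p > 0 where q = 0 is an error (apply a floor first).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must share the same binning")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("negative mass")
    p = p / p.sum()
    q = q / q.sum()
    active = p > 0
    if np.any(q[active] == 0):
        raise ValueError("q has zero mass where p is positive; floor q first")
    return float(np.sum(p[active] * np.log2(p[active] / q[active])))
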
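"""Reference-ratio sampling.

The central object is the ratio-corrected distribution

    p(x)  propto  q(x) * g(c(x)) / f(c(x)),

where q is a local backbone model, c a deterministic coarse-grained map
(radius of gyration or hydrogen-bond descriptor), g the desired target over c
and f the reference distribution of c induced by q alone. Sampling from p by
Metropolis-Hastings with a q-invariant proposal (conditional window
resampling, unit Hastings ratio) needs only the coarse-level ratio

    alpha = min(1, [g(c')/f(c')] / [g(c)/f(c)]),

optionally multiplied by a per-bin ensemble-weight ratio for generalized-
ensemble (flat-histogram) runs. With f exact, the chain's coarse marginal is
exactly g; with g = f, the chain reduces to plain sampling from q.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.special import gammaln

from . import _kernels as K
from .distributions import (GaussianTarget, MultinomialModel,
                            ReferenceHistogram, histogram_logpdf,
                            multinomial_logpmf)
from .geometry import DihedralPath, GeometryParams, Sequence
from .local_model import LocalModelParams, _propose_window_arrays, sample_path


class RadiusOfGyrationMap:
    """Coarse map c(x): all-atom radius of gyration of the built backbone."""

    name = "rg"

    def __init__(self, geometry: GeometryParams | None = None):
        self.geometry = geometry or GeometryParams()
        self._geom = self.geometry.as_array()

    def value(self, phi, psi, states, sc_mask, labels=None) -> float:
        n, ca, c, o, sc = K.build_chain(phi, psi, sc_mask, self._geom)
        return K.rg_all_atoms(n, ca, c, o, sc, sc_mask)


class HBondDescriptorMap:
    """Coarse map c(x): the 8-category hydrogen-bond network descriptor."""

    name = "hbond"

    def __init__(self, geometry: GeometryParams | None = None,
                 cutoff: float = 3.5, min_angle: float = 100.0,
                 min_sep: int = 2):
        self.geometry = geometry or GeometryParams()
        self._geom = self.geometry.as_array()
        self.cutoff = cutoff
        self.min_angle = min_angle
        self.min_sep = min_sep

    def value(self, phi, psi, states, sc_mask, labels) -> np.ndarray:
        n, ca, c, o, _ = K.build_chain(phi, psi, sc_mask, self._geom)
        donor_of, _d = K.assign_hbonds(n, ca, c, o, self.cutoff,
                                       self.min_angle, self.min_sep)
        return K.hbond_descriptor_from_assignment(donor_of, labels)


TargetLike = Union[GaussianTarget, MultinomialModel]
ReferenceLike = Optional[Union[ReferenceHistogram, MultinomialModel]]


@dataclass
class RatioModel:
    """q(x) * g(c(x)) / f(c(x)); ``reference=None`` means a uniform f
    (no reference correction, the naive product)."""

    local: LocalModelParams
    coarse_map: Union[RadiusOfGyrationMap, HBondDescriptorMap]
    target: TargetLike
    reference: ReferenceLike = None


def _log_dist(dist, c) -> float:
    if dist is None:
        return 0.0
    if isinstance(dist, GaussianTarget):
        return dist.logpdf(float(c))
    if isinstance(dist, MultinomialModel):
        return multinomial_logpmf(dist, c)
    if isinstance(dist, ReferenceHistogram):
        return histogram_logpdf(dist, float(c))
    raise TypeError(f"unsupported distribution type {type(dist)!r}")


def log_ratio(model: RatioModel, c) -> float:
    """log g(c) - log f(c); finite thanks to the reference floor."""
    return _log_dist(model.target, c) - _log_dist(model.reference, c)


def _make_log_ratio_fn(model: RatioModel):
    """Specialized log g(c) - log f(c) evaluator for the sampling loop.

    Equivalent to :func:`log_ratio`; avoids per-step scipy calls. For the
    multinomial/multinomial case the combinatorial coefficient cancels between
    g and f and is dropped (only ratios of this quantity are ever used).
    """
    target, ref = model.target, model.reference
    if isinstance(target, GaussianTarget):
        mean, sd = target.mean, target.sd
        const = -math.log(sd) - 0.5 * math.log(2.0 * math.pi)
        if ref is None:
            return lambda c: -0.5 * ((c - mean) / sd) ** 2 + const
        edges = ref.bin_edges
        ld = ref.log_density
        lo, hi = edges[0], edges[-1]
        nb = ld.shape[0]
        floor = ref.out_of_support_log_density

        def lr_rg(c):
            g = -0.5 * ((c - mean) / sd) ** 2 + const
            if c < lo or c >= hi:
                return g - floor
            idx = min(int(np.searchsorted(edges, c, side="right")) - 1, nb - 1)
            return g - ld[idx]

        return lr_rg
    if isinstance(target, MultinomialModel):
        with np.errstate(divide="ignore"):
            logp_g = np.log(target.probs)
        lgt = gammaln(np.arange(0, 10000) + 1.0)

        def mn_part(logp, d):
            act = d > 0
            if np.any(~np.isfinite(logp[act])):
                return -math.inf
            return float((d[act] * logp[act]).sum())

        if ref is None:
            def lr_mn(d):
                coeff = lgt[int(d.sum())] - lgt[d].sum()
                return coeff + mn_part(logp_g, d)
            return lr_mn
        with np.errstate(divide="ignore"):
            logp_f = np.log(ref.probs)
        dlog = logp_g - logp_f

        def lr_mn_pair(d):
            act = d > 0
            if np.any(~np.isfinite(dlog[act])):
                return -math.inf if np.any(~np.isfinite(logp_g[act])) else math.inf
            return float((d[act] * dlog[act]).sum())

        return lr_mn_pair
    raise TypeError(f"unsupported target type {type(target)!r}")


def mh_acceptance(model: RatioModel, c_old, c_new) -> float:
    """Acceptance probability for a q-invariant proposal: the fine-grained
    terms cancel and only the coarse-level ratio remains."""
    d = log_ratio(model, c_new) - log_ratio(model, c_old)
    return 1.0 if d >= 0.0 else math.exp(d)


@dataclass
class Trace:
    """Thinned MCMC output.

    ``coarse`` holds one row (or scalar) per recorded sample; ``log_ratio``
    the matching log g - log f values; ``paths`` the sampled fine-grained
    states when path storage was requested.
    """

    coarse: np.ndarray
    log_ratio: np.ndarray
    acceptance_count: int
    proposal_count: int
    seed: Optional[int]
    thinning: int
    burn_in: int
    paths: Optional[list] = None
    final_path: Optional[DihedralPath] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.proposal_count >= self.acceptance_count >= 0):
            raise ValueError("proposal_count >= acceptance_count >= 0 violated")

    @property
    def acceptance_rate(self) -> float:
        return self.acceptance_count / max(self.proposal_count, 1)

    @property
    def n_samples(self) -> int:
        return self.coarse.shape[0]


def _run_mcmc_rg_fast(model, sequence, steps, burn_in, window_range, thinning,
                      seed, rng, phi, psi, states, sc_mask, bound, progress,
                      block_size: int = 50_000):
    """Block-stepping path for the Rg pipeline (same chain law as the generic
    loop, randomness pre-drawn per block and consumed inside the kernel)."""
    L = len(sequence)
    wmin, wmax = window_range
    target = model.target
    ref = model.reference
    if ref is None:
        lo, width = 0.0, 1.0
        ref_ld = np.zeros(1)
        floor_ld = 0.0
        use_ref = False
    else:
        lo = float(ref.bin_edges[0])
        width = float(ref.widths[0])
        ref_ld = ref.log_density
        floor_ld = ref.out_of_support_log_density
        use_ref = True
    geom = model.coarse_map._geom
    phi = phi.copy()
    psi = psi.copy()
    states = states.copy()
    rec_parts = []
    accepted = 0
    done = 0
    while done < steps:
        B = min(block_size, steps - done)
        wlen = rng.integers(wmin, wmax + 1, size=B)
        wpos = np.floor(rng.random(B) * (L - wlen + 1)).astype(np.int64)
        u_bridge = rng.random((B, wmax))
        z_phi = rng.standard_normal((B, wmax))
        z_psi = rng.standard_normal((B, wmax))
        u_acc = rng.random(B)
        c_hist = np.empty(B)
        accepted += K.rg_mh_block(
            phi, psi, states, sc_mask, geom, bound.tsteps,
            bound.params.initial, bound.mean_phi, bound.mean_psi, bound.spread,
            lo, width, ref_ld, floor_ld, use_ref, target.mean, target.sd,
            wlen, wpos, u_bridge, z_phi, z_psi, u_acc, c_hist)
        gi = done + np.arange(B)
        keep = (gi >= burn_in) & ((gi - burn_in) % thinning == thinning - 1)
        rec_parts.append(c_hist[keep])
        done += B
        if progress is not None:
            progress(done, steps, accepted / done)
    rec_c = np.concatenate(rec_parts) if rec_parts else np.empty(0)
    from .distributions import gaussian_logpdf
    rec_lr = gaussian_logpdf(target, rec_c)
    if ref is not None:
        rec_lr = rec_lr - histogram_logpdf(ref, rec_c)
    return Trace(coarse=rec_c, log_ratio=rec_lr,
                 acceptance_count=int(accepted), proposal_count=steps,
                 seed=seed, thinning=thinning, burn_in=burn_in,
                 final_path=DihedralPath(phi, psi, states),
                 meta={"window_range": list(window_range), "fast_path": True})


def trace_to_frame(trace: "Trace"):
    """Thinned trace as a DataFrame (sample index, coarse value(s),
    log-ratio) for TSV export."""
    import pandas as pd

    coarse = np.atleast_2d(trace.coarse.T).T
    data = {"sample": np.arange(trace.n_samples)}
    if coarse.shape[1] == 1:
        data["rg"] = coarse[:, 0]
    else:
        for k in range(coarse.shape[1]):
            data[f"c{k}"] = coarse[:, k].astype(int)
    data["log_ratio"] = trace.log_ratio
    return pd.DataFrame(data)


class _EnsembleWeights:
    """Static per-bin log-weights w(c) entering acceptance as w(c')/w(c)."""

    def __init__(self, bin_edges, log_weights):
        self.bin_edges = np.asarray(bin_edges, dtype=float)
        self.log_weights = np.asarray(log_weights, dtype=float)

    def log_weight(self, c) -> float:
        idx = np.searchsorted(self.bin_edges, float(c), side="right") - 1
        idx = min(max(idx, 0), self.log_weights.shape[0] - 1)
        return float(self.log_weights[idx])


def run_mcmc(model: RatioModel, sequence: Sequence, steps: int,
             window_range: tuple[int, int] = (1, 10), thinning: int = 10,
             seed: int | None = None, rng: np.random.Generator | None = None,
             burn_in_fraction: float = 0.1,
             ensemble_weights: _EnsembleWeights | tuple | None = None,
             store_paths: bool = False,
             initial_path: DihedralPath | None = None,
             progress=None) -> Trace:
    """Metropolis-Hastings sampling of the ratio-corrected distribution.

    Each step resamples a uniformly placed window of uniformly drawn length
    from q's exact conditional and accepts with the coarse-level ratio
    (times the ensemble-weight ratio when supplied). The first
    ``burn_in_fraction`` of steps is discarded, then every ``thinning``-th
    coarse value is recorded. Fully deterministic given (config, seed).
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if ensemble_weights is not None and not isinstance(ensemble_weights, _EnsembleWeights):
        ensemble_weights = _EnsembleWeights(*ensemble_weights)

    bound = model.local.bind(sequence)
    L = len(sequence)
    wmin, wmax = window_range
    if not (1 <= wmin <= wmax <= L):
        raise ValueError("invalid window range")
    sc_mask = np.array([aa != "G" for aa in sequence], dtype=np.bool_)
    state_labels = bound.state_labels

    path = initial_path.copy() if initial_path is not None \
        else sample_path(model.local, sequence, rng)
    phi, psi, states = path.phi, path.psi, path.states
    labels = state_labels[states]
    lr_fn = _make_log_ratio_fn(model)
    c = model.coarse_map.value(phi, psi, states, sc_mask, labels)
    lr = lr_fn(c)
    lw = ensemble_weights.log_weight(c) if ensemble_weights else 0.0

    burn_in = int(burn_in_fraction * steps)

    uniform_bins = isinstance(model.reference, ReferenceHistogram) and \
        np.allclose(np.diff(model.reference.bin_edges),
                    model.reference.widths[0])
    if (isinstance(model.coarse_map, RadiusOfGyrationMap)
            and isinstance(model.target, GaussianTarget)
            and (model.reference is None or uniform_bins)
            and ensemble_weights is None and not store_paths):
        return _run_mcmc_rg_fast(model, sequence, steps, burn_in, window_range,
                                 thinning, seed, rng, phi, psi, states,
                                 sc_mask, bound, progress)

    n_rec = max(0, (steps - burn_in) // thinning)
    coarse_dim = np.atleast_1d(np.asarray(c)).shape[0]
    rec_c = np.empty((n_rec, coarse_dim)) if coarse_dim > 1 else np.empty(n_rec)
    rec_lr = np.empty(n_rec)
    rec_paths = [] if store_paths else None
    accepted = 0
    rec = 0

    for step in range(steps):
        w = int(rng.integers(wmin, wmax + 1))
        a = int(rng.integers(0, L - w + 1))
        b = a + w - 1
        nphi, npsi, nstates = _propose_window_arrays(bound, phi, psi, states,
                                                     a, b, rng)
        nlabels = state_labels[nstates]
        c_new = model.coarse_map.value(nphi, npsi, nstates, sc_mask, nlabels)
        lr_new = lr_fn(c_new)
        lw_new = ensemble_weights.log_weight(c_new) if ensemble_weights else 0.0
        log_alpha = (lr_new - lr) + (lw_new - lw)
        if math.isnan(log_alpha):  # both states impossible: prefer the new one
            log_alpha = 0.0 if lr_new >= lr else -math.inf
        if log_alpha >= 0.0 or rng.random() < math.exp(log_alpha):
            phi, psi, states, labels = nphi, npsi, nstates, nlabels
            c, lr, lw = c_new, lr_new, lw_new
            accepted += 1
        if step >= burn_in and (step - burn_in) % thinning == thinning - 1 \
                and rec < n_rec:
            rec_c[rec] = c
            rec_lr[rec] = lr
            if store_paths:
                rec_paths.append(DihedralPath(phi.copy(), psi.copy(), states.copy()))
            rec += 1
        if progress is not None and (step + 1) % 10000 == 0:
            progress(step + 1, steps, accepted / (step + 1))

    return Trace(coarse=rec_c[:rec], log_ratio=rec_lr[:rec],
                 acceptance_count=accepted, proposal_count=steps, seed=seed,
                 thinning=thinning, burn_in=burn_in, paths=rec_paths,
                 final_path=DihedralPath(phi.copy(), psi.copy(), states.copy()),
                 meta={"window_range": list(window_range)})
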
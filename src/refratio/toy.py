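"""Exactly enumerable toy chain: the brute-force oracle for the ratio method.

A discrete first-order Markov chain with K states over L positions
(K^L <= 1,048,576 paths, so everything can be summed exactly) and the
integer coarse map c(x) = number of adjacent equal-state pairs. On this
system the defining property of the reference-ratio construction -- that
weighting q by g(c)/f(c) with the *exact* f forces the coarse marginal to be
exactly g -- is checkable to machine precision, and the MCMC sampler and the
flat-histogram reference estimator can be validated against enumeration.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chisquare

from . import _kernels as K
from .sampling import Trace

_MAX_PATHS = 1_048_576


@dataclass
class ToySystem:
    """Discrete chain with coarse map c(x) = #{i : x_i = x_{i+1}}."""

    L: int
    transition: np.ndarray
    initial: np.ndarray | None = None
    target: np.ndarray | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.transition = np.asarray(self.transition, dtype=float)
        kk = self.transition.shape[0]
        if self.transition.shape != (kk, kk) or \
                np.any(np.abs(self.transition.sum(axis=1) - 1.0) > 1e-12) or \
                np.any(self.transition < 0):
            raise ValueError("transition must be square and row-stochastic")
        if self.initial is None:
            self.initial = np.full(kk, 1.0 / kk)
        self.initial = np.asarray(self.initial, dtype=float)
        if kk ** self.L > _MAX_PATHS:
            raise ValueError(f"K^L = {kk ** self.L} exceeds enumerable bound")
        if self.target is not None:
            self.target = np.asarray(self.target, dtype=float)
            if self.target.shape != (self.L,) or \
                    abs(self.target.sum() - 1.0) > 1e-9 or np.any(self.target < 0):
                raise ValueError("target must be a probability vector over 0..L-1")

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]

    def coarse(self, path: np.ndarray) -> int:
        p = np.asarray(path)
        return int(np.sum(p[1:] == p[:-1]))

    def _all_paths(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(paths, probabilities, coarse values) for every path."""
        if "paths" not in self._cache:
            paths = np.array(list(itertools.product(range(self.n_states),
                                                    repeat=self.L)),
                             dtype=np.int64)
            probs = self.initial[paths[:, 0]].copy()
            for i in range(1, self.L):
                probs *= self.transition[paths[:, i - 1], paths[:, i]]
            cvals = np.sum(paths[:, 1:] == paths[:, :-1], axis=1)
            self._cache["paths"] = (paths, probs, cvals)
        return self._cache["paths"]


def enumerate_coarse_marginal(sys: ToySystem) -> np.ndarray:
    """Exact distribution of c under q, by summation over all K^L paths."""
    _, probs, cvals = sys._all_paths()
    f = np.bincount(cvals, weights=probs, minlength=sys.L)
    return f / f.sum()


def exact_ratio_marginal(sys: ToySystem, target: np.ndarray | None = None,
                         reference: np.ndarray | None = None) -> np.ndarray:
    """Exact coarse marginal of q(x) g(c(x)) / f(c(x)).

    With f the exact enumeration this equals the target g identically -- the
    method's defining property. Supplying a perturbed ``reference`` shows how
    an inexact f distorts the marginal.
    """
    g = np.asarray(sys.target if target is None else target, dtype=float)
    f = enumerate_coarse_marginal(sys) if reference is None \
        else np.asarray(reference, dtype=float)
    f_exact = enumerate_coarse_marginal(sys)
    if np.any((g > 0) & (f_exact == 0)):
        raise ValueError("target puts mass where q gives the coarse value "
                         "zero probability (support mismatch)")
    if np.any((f == 0) & (f_exact > 0)):
        raise ValueError("reference has zero mass on reachable coarse values")
    _, probs, cvals = sys._all_paths()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(f_exact > 0, g / np.where(f > 0, f, 1.0), 0.0)
    w = probs * ratio[cvals]
    marg = np.bincount(cvals, weights=w, minlength=sys.L)
    return marg / marg.sum()


def run_toy_mcmc(sys: ToySystem, steps: int,
                 target: np.ndarray | None = None,
                 reference: np.ndarray | None = None,
                 window_range: tuple[int, int] | None = None,
                 thinning: int = 1, seed: int | None = None,
                 rng: np.random.Generator | None = None,
                 burn_in_fraction: float = 0.1,
                 ensemble_log_weights: np.ndarray | None = None) -> Trace:
    """Metropolis-Hastings on the toy chain with conditional window proposals.

    ``target``/``reference`` are vectors over c = 0..L-1 (None means uniform,
    i.e. plain q sampling when both are None). ``ensemble_log_weights`` adds
    static per-c log-weights (flat-histogram support).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    L, kk = sys.L, sys.n_states
    wmin, wmax = window_range or (1, L)
    if not (1 <= wmin <= wmax <= L):
        raise ValueError("invalid window range")
    with np.errstate(divide="ignore"):
        log_g = np.log(np.asarray(target, dtype=float)) if target is not None \
            else np.zeros(L)
        log_f = np.log(np.asarray(reference, dtype=float)) if reference is not None \
            else np.zeros(L)
    log_r = log_g - log_f
    if ensemble_log_weights is not None:
        log_r = log_r + np.asarray(ensemble_log_weights, dtype=float)
    tsteps = np.broadcast_to(sys.transition, (max(L - 1, 1), kk, kk)).copy()

    # initial exact q draw
    path = np.empty(L, dtype=np.int64)
    path[0] = rng.choice(kk, p=sys.initial)
    for i in range(1, L):
        path[i] = rng.choice(kk, p=sys.transition[path[i - 1]])
    c = sys.coarse(path)

    burn_in = int(burn_in_fraction * steps)
    n_rec = max(0, (steps - burn_in) // thinning)
    rec_c = np.empty(n_rec, dtype=np.int64)
    accepted = 0
    rec = 0
    for step in range(steps):
        w = int(rng.integers(wmin, wmax + 1))
        a = int(rng.integers(0, L - w + 1))
        new_path = K.bridge_resample(tsteps, sys.initial, path, a, a + w - 1,
                                     rng.random(w))
        c_new = sys.coarse(new_path)
        d = log_r[c_new] - log_r[c]
        if math.isnan(d):
            d = -math.inf
        if d >= 0.0 or rng.random() < math.exp(d):
            path, c = new_path, c_new
            accepted += 1
        if step >= burn_in and (step - burn_in) % thinning == thinning - 1 \
                and rec < n_rec:
            rec_c[rec] = c
            rec += 1
    return Trace(coarse=rec_c[:rec].astype(float), log_ratio=np.zeros(rec),
                 acceptance_count=accepted, proposal_count=steps, seed=seed,
                 thinning=thinning, burn_in=burn_in,
                 meta={"system": "toy", "final_path": path.tolist()})


def toy_flat_histogram(sys: ToySystem, stages: int = 12,
                       steps_per_stage: int = 5000,
                       final_steps: int | None = None,
                       seed: int | None = None,
                       initial_delta: float = 1.0) -> np.ndarray:
    """Flat-histogram estimate of the coarse marginal f over c = 0..L-1,
    mirroring the protein-chain estimator on the discrete system."""
    rng = np.random.default_rng(seed)
    if final_steps is None:
        final_steps = 5 * steps_per_stage
    L = sys.L
    log_w = np.zeros(L)
    path_holder = {}

    def run_stage(delta, steps):
        hist = np.zeros(L)
        trace = None
        # one long chain per stage, weights frozen within the stage for the
        # histogram but updated per visit for log_w
        kk = sys.n_states
        tsteps = np.broadcast_to(sys.transition, (max(L - 1, 1), kk, kk)).copy()
        path = path_holder.get("path")
        if path is None:
            path = np.empty(L, dtype=np.int64)
            path[0] = rng.choice(kk, p=sys.initial)
            for i in range(1, L):
                path[i] = rng.choice(kk, p=sys.transition[path[i - 1]])
        c = sys.coarse(path)
        for _ in range(steps):
            w = int(rng.integers(1, L + 1))
            a = int(rng.integers(0, L - w + 1))
            new_path = K.bridge_resample(tsteps, sys.initial, path, a,
                                         a + w - 1, rng.random(w))
            c_new = sys.coarse(new_path)
            d = log_w[c] - log_w[c_new]
            if d >= 0.0 or rng.random() < math.exp(d):
                path, c = new_path, c_new
            log_w[c] += delta
            hist[c] += 1
        path_holder["path"] = path
        return hist

    for s in range(stages):
        run_stage(initial_delta * 0.5 ** s, steps_per_stage)
    hist = run_stage(0.0, final_steps)
    visited = hist > 0
    masses = np.zeros(L)
    if np.any(visited):
        lm = np.log(hist[visited]) + log_w[visited]
        lm -= lm.max()
        masses[visited] = np.exp(lm)
    return masses / masses.sum()


def trace_vs_exact(trace, exact: np.ndarray) -> tuple[float, float]:
    """(total variation distance, chi-square goodness-of-fit p-value) of a
    trace's empirical coarse distribution against an exact one.

    Accepts a Trace or a plain integer sample array. Bins with expected count
    below 5 are pooled for the chi-square test; observed mass on coarse
    values the exact distribution excludes yields p = 0.
    """
    samples = np.asarray(trace.coarse if isinstance(trace, Trace) else trace)
    samples = samples.astype(np.int64)
    if samples.size == 0:
        raise ValueError("empty trace")
    exact = np.asarray(exact, dtype=float)
    exact = exact / exact.sum()
    counts = np.bincount(samples, minlength=exact.shape[0]).astype(float)
    if counts.shape[0] > exact.shape[0]:
        raise ValueError("samples outside the exact support range")
    n = counts.sum()
    emp = counts / n
    tv = 0.5 * float(np.abs(emp - exact).sum())
    if np.any(counts[exact == 0] > 0):
        return tv, 0.0
    expected = exact * n
    big = expected >= 5
    if big.sum() < 2:
        return tv, float("nan")
    obs = np.concatenate([counts[big], [counts[~big].sum()]]) if np.any(~big) \
        else counts[big]
    exp = np.concatenate([expected[big], [expected[~big].sum()]]) if np.any(~big) \
        else expected[big]
    keep = exp > 0
    res = chisquare(obs[keep], exp[keep] * obs[keep].sum() / exp[keep].sum())
    return tv, float(res.pvalue)
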
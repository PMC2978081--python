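"""Estimating the reference distribution f(c) induced by the local model.

Two estimators:

* Flat-histogram (multicanonical) estimation of the radius-of-gyration
  reference: Wang-Landau-style stage-wise weight adaptation followed by a
  refinement run with frozen weights and histogram reweighting. The chain is
  confined to the configured Rg window; the returned histogram is f up to
  normalization on that window, which is all the ratio method needs (constant
  factors cancel in acceptance ratios).

* Iterative multinomial refinement for the hydrogen-bond descriptor:
  iteration 1 samples the plain product of target and local model (uniform
  reference); after each iteration a pseudocounted maximum-likelihood
  multinomial is fitted to the sampled descriptors and folded into an
  accumulated reference with a damped, clipped stochastic-approximation
  update. Successive iterations sculpt the sampler towards the target's
  category fractions (an energy funnel over the hydrogen-bond network).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .distributions import (MultinomialModel, ReferenceHistogram,
                            fit_multinomial)
from .geometry import DihedralPath, GeometryParams, Sequence
from .local_model import LocalModelParams, _propose_window_arrays, log_density, sample_path
from .sampling import (HBondDescriptorMap, RadiusOfGyrationMap, RatioModel,
                       run_mcmc)


def _wl_stage(bound, coarse_fn, phi, psi, states, sc_mask, log_w, hist, delta,
              steps, window_range, rng, edges):
    """One Wang-Landau stage; mutates log_w and hist, returns updated state."""
    L = states.shape[0]
    wmin, wmax = window_range
    nb = log_w.shape[0]
    lo, hi = edges[0], edges[-1]
    mid = 0.5 * (lo + hi)

    c = coarse_fn(phi, psi, states, sc_mask)
    for _ in range(steps):
        w = int(rng.integers(wmin, wmax + 1))
        a = int(rng.integers(0, L - w + 1))
        nphi, npsi, nstates = _propose_window_arrays(bound, phi, psi, states,
                                                     a, a + w - 1, rng)
        c_new = coarse_fn(nphi, npsi, nstates, sc_mask)
        in_old = lo <= c < hi
        in_new = lo <= c_new < hi
        if in_old and not in_new:
            accept = False                      # stay inside the window
        elif not in_old:
            # not yet inside: drift towards the window, accept entries
            accept = in_new or abs(c_new - mid) <= abs(c - mid)
        else:
            i_old = min(int(np.searchsorted(edges, c, side="right")) - 1, nb - 1)
            i_new = min(int(np.searchsorted(edges, c_new, side="right")) - 1, nb - 1)
            d = log_w[i_old] - log_w[i_new]
            accept = d >= 0.0 or rng.random() < math.exp(d)
        if accept:
            phi, psi, states, c = nphi, npsi, nstates, c_new
        if lo <= c < hi:
            idx = min(int(np.searchsorted(edges, c, side="right")) - 1, nb - 1)
            log_w[idx] += delta
            hist[idx] += 1
    return phi, psi, states


def _flatness(hist: np.ndarray) -> float:
    visited = hist[hist > 0]
    if visited.size == 0:
        return 0.0
    return float(visited.min() / visited.mean())


def estimate_reference_flat_histogram(
        local: LocalModelParams, sequence: Sequence, bin_edges,
        stages: int = 10, steps_per_stage: int = 20000,
        final_steps: int | None = None, seed: int | None = None,
        rng: np.random.Generator | None = None,
        geometry: GeometryParams | None = None,
        window_range: tuple[int, int] = (1, 10),
        initial_delta: float = 1.0,
        empty_bin_mass: float = 1e-8) -> ReferenceHistogram:
    """Estimate f(rg) under the local model by flat-histogram sampling.

    Stage s uses weight increment ``initial_delta / 2**s``; the final
    refinement stage (default length ``5 * steps_per_stage``) runs with frozen
    weights and recovers f by reweighting the visit histogram. Diagnostics
    (per-stage flatness, unvisited-bin warning) are stored in ``meta``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    edges = np.asarray(bin_edges, dtype=float)
    nb = edges.shape[0] - 1
    if final_steps is None:
        final_steps = 5 * steps_per_stage
    bound = local.bind(sequence)
    sc_mask = np.array([aa != "G" for aa in sequence], dtype=np.bool_)
    rg_map = RadiusOfGyrationMap(geometry)

    def coarse_fn(phi, psi, states, mask):
        return rg_map.value(phi, psi, states, mask)

    path = sample_path(local, sequence, rng)
    phi, psi, states = path.phi, path.psi, path.states

    log_w = np.zeros(nb)
    flatness_per_stage = []
    for s in range(stages):
        hist = np.zeros(nb)
        delta = initial_delta * 0.5 ** s
        phi, psi, states = _wl_stage(bound, coarse_fn, phi, psi, states,
                                     sc_mask, log_w, hist, delta,
                                     steps_per_stage, window_range, rng, edges)
        flatness_per_stage.append(_flatness(hist))

    hist = np.zeros(nb)
    phi, psi, states = _wl_stage(bound, coarse_fn, phi, psi, states, sc_mask,
                                 log_w, hist, 0.0, final_steps, window_range,
                                 rng, edges)
    final_flatness = _flatness(hist)

    # reweight: sampling weight was exp(-log_w), so f propto hist * exp(log_w)
    visited = hist > 0
    log_mass = np.full(nb, -np.inf)
    if np.any(visited):
        lm = np.log(hist[visited]) + log_w[visited]
        lm -= lm.max()
        log_mass[visited] = lm
    masses = np.exp(log_mass, where=np.isfinite(log_mass),
                    out=np.zeros(nb))
    meta = {
        "flatness_per_stage": flatness_per_stage,
        "final_flatness": final_flatness,
        "visited_bins": int(visited.sum()),
        "n_bins": nb,
        "seed": seed,
        "log_weights": log_w.tolist(),
        "warning": None if visited.all() else
        f"{int((~visited).sum())} bins unvisited after all stages; floored",
    }
    return ReferenceHistogram.from_masses(edges, masses,
                                          empty_bin_mass=empty_bin_mass,
                                          meta=meta)


@dataclass
class IterationResult:
    """Summary of one refinement iteration."""

    iteration: int
    reference: MultinomialModel | None
    fitted: MultinomialModel
    descriptors: np.ndarray
    fractions: np.ndarray
    tv_to_target: float
    best_path: DihedralPath
    best_log_score: float
    acceptance_rate: float
    meta: dict = field(default_factory=dict)


def iterate_reference(local: LocalModelParams, sequence: Sequence,
                      target: MultinomialModel, n_iterations: int = 6,
                      samples_per_iteration: int = 2000,
                      steps_per_iteration: int = 150_000,
                      pseudocount: float = 0.5, seed: int | None = None,
                      geometry: GeometryParams | None = None,
                      window_range: tuple[int, int] = (1, 10),
                      hbond_kwargs: dict | None = None,
                      n_chains: int = 25, update_clip: float = 1.2,
                      progress=None) -> list[IterationResult]:
    """Iterative reference refinement over the hydrogen-bond descriptor.

    Iteration 1 samples a population of ``n_chains`` Metropolis-Hastings
    chains from q * g (uniform reference). After iteration n a multinomial
    f_n is fitted (with pseudocount) to the pooled descriptors and the
    accumulated log-reference is updated by the damped, clipped correction

        log R_n = log R_{n-1} + (1/n) * clip(log(f_n / g), +-update_clip),

    a stochastic-approximation (decreasing-gain) form of the reference
    update: at the fixed point the sampled category fractions equal the
    target and R stops moving. Chains are warm-started from their previous
    iteration's final state, so structure formed early (helices, strand
    pairings) persists and is refined rather than rebuilt; the population
    keeps both secondary-structure modes represented, which damps the
    winner-take-all composition swings a single chain exhibits.

    Per iteration the pooled category fractions (descriptor counts / L),
    their total-variation distance to the target probabilities, and the
    highest-probability sample (argmax of log q + log g - log R over the
    thinned samples) are recorded.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if not 1 <= n_chains <= samples_per_iteration:
        raise ValueError("n_chains must be in [1, samples_per_iteration]")
    rng = np.random.default_rng(seed)
    coarse = HBondDescriptorMap(geometry, **(hbond_kwargs or {}))
    L = len(sequence)
    per_chain = max(1, steps_per_iteration // n_chains)
    thinning = max(1, int(0.6 * per_chain) // (samples_per_iteration // n_chains))
    log_ref = None
    chain_states: list[DihedralPath | None] = [None] * n_chains
    results: list[IterationResult] = []
    for it in range(1, n_iterations + 1):
        if log_ref is None:
            reference = None
        else:
            r = np.exp(log_ref - log_ref.max())
            reference = MultinomialModel(r / r.sum())
        model = RatioModel(local=local, coarse_map=coarse, target=target,
                           reference=reference)
        descs, paths, lrs, accepted = [], [], [], 0
        for m in range(n_chains):
            trace = run_mcmc(model, sequence, steps=per_chain,
                             window_range=window_range, thinning=thinning,
                             rng=rng, burn_in_fraction=0.4, store_paths=True,
                             initial_path=chain_states[m])
            descs.append(trace.coarse.astype(np.int64))
            paths.extend(trace.paths)
            lrs.append(trace.log_ratio)
            accepted += trace.acceptance_count
            chain_states[m] = trace.final_path
        desc = np.vstack(descs)
        lrs = np.concatenate(lrs)
        fractions = desc.mean(axis=0) / L
        tv = 0.5 * float(np.abs(fractions - target.probs).sum())
        logq = np.array([log_density(local, p, sequence) for p in paths])
        score = logq + lrs
        best = int(np.argmax(score))
        fitted = fit_multinomial(desc, pseudocount=pseudocount)
        update = np.clip(np.log(fitted.probs / np.maximum(target.probs, 1e-300)),
                         -update_clip, update_clip) / it
        log_ref = update if log_ref is None else log_ref + update
        results.append(IterationResult(
            iteration=it, reference=reference, fitted=fitted,
            descriptors=desc, fractions=fractions, tv_to_target=tv,
            best_path=paths[best], best_log_score=float(score[best]),
            acceptance_rate=accepted / (n_chains * per_chain),
            meta={"steps": steps_per_iteration, "n_chains": n_chains,
                  "per_chain_steps": per_chain, "thinning": thinning,
                  "n_samples": int(desc.shape[0]), "seed": seed}))
        if progress is not None:
            progress(it, results[-1])
    return results
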
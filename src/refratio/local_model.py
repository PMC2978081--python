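"""The fine-grained sampling distribution q(x): a sequence-conditioned
first-order Markov chain over discrete Ramachandran-basin states with
wrapped-normal angular emissions.

This plays the role a fragment library or a trained local-structure model
plays in structure prediction: it generates backbone angle paths that are
plausible on a local length scale while carrying no non-local information.
Sequence conditioning is through four residue classes (generic, glycine,
proline, pre-proline) that select the transition row used when entering a
residue. The model exposes exactly the contract the reference-ratio sampler
needs: path sampling, exact log-density, a conditional window-resampling
proposal with unit Hastings ratio, and secondary-structure labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from . import _kernels as K
from .geometry import DihedralPath, Sequence, UNDEFINED_ANGLE, wrap_angle

SS_LABELS = ("H", "E", "C")
RESIDUE_CLASSES = ("generic", "glycine", "proline", "preproline")

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class BasinState:
    """One Ramachandran basin: emission centre, angular spread (degrees) and
    secondary-structure class."""

    id: int
    label: str
    mean_phi: float
    mean_psi: float
    spread: float
    name: str = ""

    def __post_init__(self):
        if self.label not in SS_LABELS:
            raise ValueError(f"label must be one of {SS_LABELS}, got {self.label!r}")
        if not self.spread > 0:
            raise ValueError("spread must be positive")


@dataclass
class LocalModelParams:
    """Markov-basin model parameters.

    ``transition`` maps each residue class to a row-stochastic KxK matrix; a
    single matrix may be given and is then used for every class.
    """

    states: list[BasinState]
    initial: np.ndarray
    transition: dict[str, np.ndarray]
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        kk = len(self.states)
        if kk < 1:
            raise ValueError("at least one basin state required")
        if [s.id for s in self.states] != list(range(kk)):
            raise ValueError("state ids must be 0..K-1 in order")
        self.initial = np.asarray(self.initial, dtype=float)
        if self.initial.shape != (kk,):
            raise ValueError("initial distribution has wrong length")
        if np.any(self.initial < 0) or abs(self.initial.sum() - 1.0) > 1e-12:
            raise ValueError("initial must be a probability vector")
        if not isinstance(self.transition, dict):
            self.transition = {cls: self.transition for cls in RESIDUE_CLASSES}
        fixed = {}
        for cls in RESIDUE_CLASSES:
            t = np.asarray(self.transition.get(cls, self.transition["generic"]),
                           dtype=float)
            if t.shape != (kk, kk):
                raise ValueError(f"transition matrix for {cls!r} must be {kk}x{kk}")
            if np.any(t < 0) or np.any(np.abs(t.sum(axis=1) - 1.0) > 1e-12):
                raise ValueError(f"transition rows for {cls!r} must sum to 1")
            fixed[cls] = t
        self.transition = fixed

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def labels(self) -> np.ndarray:
        """int8 secondary-structure code per state (0=H, 1=E, 2=C)."""
        return np.array([SS_LABELS.index(s.label) for s in self.states],
                        dtype=np.int8)

    @classmethod
    def from_yaml(cls, path) -> "LocalModelParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls._from_raw(raw)

    @classmethod
    def default(cls) -> "LocalModelParams":
        raw = yaml.safe_load(resources.files("refratio")
                             .joinpath("data/local_model.yaml").read_text())
        return cls._from_raw(raw)

    @classmethod
    def _from_raw(cls, raw: dict) -> "LocalModelParams":
        states = [BasinState(id=s["id"], label=s["label"], name=s.get("name", ""),
                             mean_phi=s["mean_phi"], mean_psi=s["mean_psi"],
                             spread=s["spread"])
                  for s in raw["states"]]
        transition = {k: np.asarray(v, dtype=float)
                      for k, v in raw["transition"].items()}
        return cls(states=states, initial=raw["initial"], transition=transition)

    def bind(self, sequence: Sequence) -> "_BoundModel":
        """Resolve residue classes against a sequence (cached per sequence)."""
        key = sequence.letters
        if key not in self._cache:
            self._cache[key] = _BoundModel(self, sequence)
        return self._cache[key]


def residue_class(sequence: Sequence, i: int) -> str:
    """Class of residue i (0-based): proline and glycine take precedence over
    the pre-proline class."""
    aa = sequence[i]
    if aa == "P":
        return "proline"
    if aa == "G":
        return "glycine"
    if i + 1 < len(sequence) and sequence[i + 1] == "P":
        return "preproline"
    return "generic"


class _BoundModel:
    """Model parameters resolved against one sequence: per-step transition
    matrices plus flat emission arrays, in the layout the kernels expect."""

    def __init__(self, params: LocalModelParams, sequence: Sequence):
        self.params = params
        self.sequence = sequence
        L = len(sequence)
        kk = params.n_states
        self.tsteps = np.empty((max(L - 1, 1), kk, kk))
        for i in range(1, L):
            self.tsteps[i - 1] = params.transition[residue_class(sequence, i)]
        with np.errstate(divide="ignore"):
            self.log_tsteps = np.log(self.tsteps)
            self.log_initial = np.log(params.initial)
        self.mean_phi = np.array([s.mean_phi for s in params.states])
        self.mean_psi = np.array([s.mean_psi for s in params.states])
        self.spread = np.array([s.spread for s in params.states])
        self.state_labels = params.labels


def wrapped_normal_logpdf(x, mu, sigma):
    """Log-density of the wrapped normal on (-180, 180], degrees.

    The wrap sum is truncated at +-3 periods, ample for spreads up to ~60 deg.
    """
    d = wrap_angle(np.asarray(x, dtype=float) - mu)
    ks = np.arange(-3, 4) * 360.0
    z = (np.atleast_1d(d)[:, None] + ks[None, :]) / np.atleast_1d(sigma)[..., None]
    logs = -0.5 * z ** 2 - np.log(np.atleast_1d(sigma))[..., None] - 0.5 * _LOG_2PI
    m = logs.max(axis=-1)
    out = m + np.log(np.exp(logs - m[..., None]).sum(axis=-1))
    return out if np.ndim(x) else float(out[0])


def sample_path(params: LocalModelParams, sequence: Sequence,
                rng: np.random.Generator) -> DihedralPath:
    """Draw a full path (states, then angles) from the model."""
    bound = params.bind(sequence)
    L = len(sequence)
    states = np.empty(L, dtype=np.int64)
    u = rng.random(L)
    cum = np.cumsum(params.initial)
    states[0] = np.searchsorted(cum, u[0], side="right")
    for i in range(1, L):
        cum = np.cumsum(bound.tsteps[i - 1, states[i - 1]])
        states[i] = np.searchsorted(cum, u[i], side="right")
    states = np.minimum(states, params.n_states - 1)
    sigma = bound.spread[states]
    phi = wrap_angle(bound.mean_phi[states] + rng.standard_normal(L) * sigma)
    psi = wrap_angle(bound.mean_psi[states] + rng.standard_normal(L) * sigma)
    phi[0] = UNDEFINED_ANGLE
    psi[-1] = UNDEFINED_ANGLE
    return DihedralPath(phi, psi, states)


def log_density(params: LocalModelParams, path: DihedralPath,
                sequence: Sequence) -> float:
    """Exact log q(x): initial + transition + emission terms.

    Returns -inf (not an error) when the path uses a zero-probability
    transition. Emissions are evaluated only at defined angle slots:
    phi(2..L), psi(1..L-1).
    """
    bound = params.bind(sequence)
    L = len(sequence)
    if len(path) != L:
        raise ValueError("path length does not match sequence")
    s = path.states
    if np.any(s < 0) or np.any(s >= params.n_states):
        raise ValueError("unknown state id in path")
    state_part = bound.log_initial[s[0]]
    if L > 1:
        state_part += bound.log_tsteps[np.arange(L - 1), s[:-1], s[1:]].sum()
    if not np.isfinite(state_part):
        return -math.inf
    emis = wrapped_normal_logpdf(path.phi[1:], bound.mean_phi[s[1:]],
                                 bound.spread[s[1:]]).sum()
    emis += wrapped_normal_logpdf(path.psi[:-1], bound.mean_psi[s[:-1]],
                                  bound.spread[s[:-1]]).sum()
    return float(state_part + emis)


def _propose_window_arrays(bound: _BoundModel, phi, psi, states, a: int, b: int,
                           rng: np.random.Generator):
    """Raw-array window resample (0-based, inclusive); used by the hot loop."""
    m = b - a + 1
    new_states = K.bridge_resample(bound.tsteps, bound.params.initial,
                                   states, a, b, rng.random(m))
    idx = slice(a, b + 1)
    sigma = bound.spread[new_states[idx]]
    z = rng.standard_normal((m, 2))
    new_phi = phi.copy()
    new_psi = psi.copy()
    new_phi[idx] = wrap_angle(bound.mean_phi[new_states[idx]] + z[:, 0] * sigma)
    new_psi[idx] = wrap_angle(bound.mean_psi[new_states[idx]] + z[:, 1] * sigma)
    if a == 0:
        new_phi[0] = UNDEFINED_ANGLE
    if b == len(states) - 1:
        new_psi[-1] = UNDEFINED_ANGLE
    return new_phi, new_psi, new_states


def propose_window(params: LocalModelParams, path: DihedralPath,
                   window: tuple[int, int], sequence: Sequence,
                   rng: np.random.Generator) -> DihedralPath:
    """Resample states and angles inside a 1-based inclusive residue window,
    conditional on the flanking states (exact Markov-bridge sampling).

    Outside the window the path is unchanged. Because the window is drawn from
    the exact conditional under q, the proposal has unit Hastings ratio with
    respect to q.
    """
    lo, hi = window
    L = len(path)
    if not (1 <= lo <= hi <= L):
        raise ValueError(f"window {window} outside [1, {L}] or empty")
    bound = params.bind(sequence)
    phi, psi, states = _propose_window_arrays(
        bound, path.phi, path.psi, path.states, lo - 1, hi - 1, rng)
    return DihedralPath(phi, psi, states)


def ss_labels(params: LocalModelParams, path: DihedralPath) -> list[str]:
    """Per-residue secondary-structure labels of the path's basin states."""
    s = path.states
    if np.any(s < 0) or np.any(s >= params.n_states):
        raise ValueError("unknown state id in path")
    lab = params.labels[s]
    return [SS_LABELS[i] for i in lab]
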
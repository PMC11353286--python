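"""Direct and indirect encoding objectives and their optimizers.

The direct strategy optimizes each encoder alone against the mean affordance
profile of its own axis (row or column means); the indirect strategy
optimizes the encoder pair jointly against the full-matrix reconstruction
error.  Both use the same stochastic hill climber: random restarts, one
random single-observation reassignment proposal per encoder per step, kept
only on a strict decrease of the objective.  An exhaustive-search oracle
certifies results on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Callable, Sequence

import numpy as np

from .landscape import AffordanceLandscape, EncoderMap, build_decoder, estimates, mse

__all__ = [
    "OptimizerConfig",
    "StrategyResult",
    "mse_direct",
    "mse_indirect",
    "hill_climb",
    "exhaustive_search",
    "optimize_direct",
    "optimize_indirect",
]


@dataclass(frozen=True)
class OptimizerConfig:
    """Hill-climbing schedule: random restarts x steps, fully seeded.

    ``lengths[k]`` is the number of observation states encoder *k* reads and
    ``signals[k]`` its signal-alphabet size L.  A seed is mandatory — there
    is no silent clock seeding.
    """

    lengths: tuple
    signals: tuple
    runs: int = 20
    steps: int | None = None  # default: 100 * max(lengths)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "lengths", tuple(int(v) for v in self.lengths))
        object.__setattr__(self, "signals", tuple(int(v) for v in self.signals))
        if len(self.lengths) != len(self.signals):
            raise ValueError("lengths and signals must pair up")
        if self.runs < 1:
            raise ValueError("need at least one run")
        steps = 100 * max(self.lengths) if self.steps is None else int(self.steps)
        if steps < 0:
            raise ValueError("steps must be non-negative")
        object.__setattr__(self, "steps", steps)


@dataclass(frozen=True)
class StrategyResult:
    """Best encoders across runs with per-run objective traces."""

    encoders: tuple
    objective: float
    traces: tuple  # one non-increasing array per run
    seed: int


def mse_direct(encoder: EncoderMap, unidim_affordance: np.ndarray) -> float:
    """Reconstruction error of one axis's mean-affordance profile.

    The per-signal decoder value is the mean of the unidimensional
    affordance values over the signal's preimage; the error is the MSE
    between the profile and its reconstruction.
    """
    values = np.asarray(unidim_affordance, float)
    if values.shape != (len(encoder),):
        raise ValueError("encoder length must match the profile length")
    z = encoder.assignment
    sums = np.bincount(z, weights=values, minlength=encoder.L)
    counts = np.bincount(z, minlength=encoder.L)
    dec = np.zeros(encoder.L)
    nz = counts > 0
    dec[nz] = sums[nz] / counts[nz]
    recon = dec[z]
    return float(((values - recon) ** 2).mean())


def mse_indirect(encoder_B: EncoderMap, encoder_C: EncoderMap, land: AffordanceLandscape) -> float:
    """Full-matrix reconstruction error under the conditional-mean decoder."""
    pair = build_decoder(land, encoder_B, encoder_C)
    return mse(land.matrix, estimates(pair, land).affordance_estimate)


def _fast_direct(assignment: np.ndarray, L: int, values: np.ndarray) -> float:
    sums = np.bincount(assignment, weights=values, minlength=L)
    counts = np.bincount(assignment, minlength=L)
    dec = np.divide(sums, counts, out=np.zeros(L), where=counts > 0)
    return float(((values - dec[assignment]) ** 2).mean())


def _fast_indirect(zb: np.ndarray, zc: np.ndarray, LB: int, LC: int, flat: np.ndarray) -> float:
    labels = (zb[:, None] * LC + zc[None, :]).ravel()
    sums = np.bincount(labels, weights=flat, minlength=LB * LC)
    counts = np.bincount(labels, minlength=LB * LC)
    dec = np.divide(sums, counts, out=np.zeros(LB * LC), where=counts > 0)
    return float(((flat - dec[labels]) ** 2).mean())


def hill_climb(objective: Callable[..., float], config: OptimizerConfig) -> StrategyResult:
    """Algorithm: random-restart stochastic hill climbing on encoder maps.

    Each run draws every encoder uniformly at random over signal
    assignments.  Each step proposes, for every encoder, reassigning one
    uniformly random observation to one uniformly random signal; the
    proposals are evaluated (and accepted or discarded) as a unit, and kept
    only if the objective strictly decreases.  ``objective`` receives one
    :class:`EncoderMap` per configured encoder.
    """
    rng = np.random.default_rng(config.seed)
    best_val = np.inf
    best_enc = None
    traces = []
    for _ in range(config.runs):
        current = [
            rng.integers(0, L, size=length)
            for length, L in zip(config.lengths, config.signals)
        ]
        cur_val = objective(*(EncoderMap(a, L) for a, L in zip(current, config.signals)))
        trace = [cur_val]
        for _ in range(config.steps):
            proposal = [a.copy() for a in current]
            for a, L in zip(proposal, config.signals):
                a[rng.integers(0, a.shape[0])] = rng.integers(0, L)
            new_val = objective(
                *(EncoderMap(a, L) for a, L in zip(proposal, config.signals))
            )
            if new_val < cur_val:
                current, cur_val = proposal, new_val
            trace.append(cur_val)
        traces.append(np.array(trace))
        if cur_val < best_val:
            best_val = cur_val
            best_enc = tuple(EncoderMap(a, L) for a, L in zip(current, config.signals))
    return StrategyResult(
        encoders=best_enc, objective=float(best_val), traces=tuple(traces), seed=config.seed
    )


def exhaustive_search(
    objective: Callable[..., float], lengths: Sequence[int], signals: Sequence[int]
):
    """Global optimum over all signal assignments, by enumeration.

    Refuses when the joint assignment space exceeds 10**6; intended to
    certify hill-climbing results on small instances only.
    """
    lengths = tuple(int(v) for v in lengths)
    signals = tuple(int(v) for v in signals)
    total = 1
    for length, L in zip(lengths, signals):
        total *= L**length
    if total > 1_000_000:
        raise ValueError(f"search space of {total} assignments is too large")
    best_val = np.inf
    best_enc = None
    spaces = [product(range(L), repeat=length) for length, L in zip(lengths, signals)]
    for combo in product(*spaces):
        encoders = tuple(
            EncoderMap(np.array(a, dtype=int), L) for a, L in zip(combo, signals)
        )
        val = objective(*encoders)
        if val < best_val:
            best_val = val
            best_enc = encoders
    return best_enc, float(best_val)


def optimize_direct(
    land: AffordanceLandscape, L_B: int, L_C: int, runs: int = 20, steps: int | None = None, seed: int = 0
) -> tuple:
    """Hill-climb each axis's encoder independently; returns (result_B, result_C)."""
    results = []
    for axis, (values, L) in enumerate(
        [(land.matrix.mean(axis=1), L_B), (land.matrix.mean(axis=0), L_C)]
    ):
        cfg = OptimizerConfig(
            lengths=(values.shape[0],),
            signals=(L,),
            runs=runs,
            steps=steps,
            # derived per-axis seed keeps the two climbs independent
            seed=seed * 2 + axis,
        )
        obj = lambda e, v=values: _fast_direct(e.assignment, e.L, v)
        results.append(hill_climb(obj, cfg))
    return tuple(results)


def optimize_indirect(
    land: AffordanceLandscape, L_B: int, L_C: int, runs: int = 20, steps: int | None = None, seed: int = 0
) -> StrategyResult:
    """Hill-climb the encoder pair jointly on the full-matrix MSE."""
    m, n = land.shape
    flat = land.matrix.ravel()
    cfg = OptimizerConfig(
        lengths=(m, n), signals=(L_B, L_C), runs=runs, steps=steps, seed=seed
    )
    obj = lambda eb, ec: _fast_indirect(eb.assignment, ec.assignment, eb.L, ec.L, flat)
    return hill_climb(obj, cfg)
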
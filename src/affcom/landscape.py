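"""The affordance-landscape model: matrix, encoders, decoder, estimates.

An :class:`AffordanceLandscape` is an m x n real matrix A whose entry a_bc is
the affordance value realized when the two energy arrays are in observation
states o^B_b and o^C_c.  Observation states default to the integers 1..m and
1..n, and cells are uniformly distributed (every (b, c) has mass 1/(m n)).

Each axis is read by a deterministic, capacity-limited encoder mapping its
observation states onto L signals (a rate of log2 L bits).  For fixed
encoders the MSE-optimal decoder is the conditional expectation: a signal
pair (i, j) decodes to the mean affordance over the preimage product
E_B^{-1}(i) x E_C^{-1}(j).  Sensory and per-axis ("unidimensional")
affordance estimates are built the same way on one axis at a time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import pid as _pid
from .distributions import (
    ProbabilityTable,
    SpatialSupport,
    mutual_information,
    spatial_entropy,
)

__all__ = [
    "AffordanceLandscape",
    "EncoderMap",
    "CodingPair",
    "EstimateSet",
    "row_expectations",
    "column_expectations",
    "build_decoder",
    "estimates",
    "mse",
    "induced_joint",
    "metrics_report",
]


@dataclass(frozen=True)
class AffordanceLandscape:
    """m x n affordance matrix with named observation states per axis."""

    matrix: np.ndarray
    row_states: np.ndarray = None
    col_states: np.ndarray = None

    def __post_init__(self):
        matrix = np.asarray(self.matrix, float)
        if matrix.ndim != 2 or matrix.shape[0] < 2 or matrix.shape[1] < 2:
            raise ValueError("matrix must be at least 2x2")
        if not np.isfinite(matrix).all():
            raise ValueError("matrix entries must be finite")
        m, n = matrix.shape
        rows = np.arange(1, m + 1, dtype=float) if self.row_states is None else np.asarray(self.row_states, float)
        cols = np.arange(1, n + 1, dtype=float) if self.col_states is None else np.asarray(self.col_states, float)
        if rows.shape != (m,) or cols.shape != (n,):
            raise ValueError("axis state vectors must match the matrix shape")
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "row_states", rows)
        object.__setattr__(self, "col_states", cols)

    @property
    def shape(self):
        return self.matrix.shape

    # -- CSV I/O -------------------------------------------------------

    def to_csv(self, path) -> None:
        np.savetxt(path, self.matrix, delimiter=",")

    @classmethod
    def from_csv(cls, path, delimiter=",") -> "AffordanceLandscape":
        matrix = np.loadtxt(path, delimiter=delimiter, ndmin=2)
        return cls(matrix)


def row_expectations(land: AffordanceLandscape) -> np.ndarray:
    """A^B: the landscape seen by the row encoder — mean affordance per row."""
    return land.matrix.mean(axis=1)


def column_expectations(land: AffordanceLandscape) -> np.ndarray:
    """A^C: mean affordance per column."""
    return land.matrix.mean(axis=0)


@dataclass(frozen=True)
class EncoderMap:
    """Total deterministic assignment of observation indices to signals 0..L-1."""

    assignment: np.ndarray
    L: int

    def __post_init__(self):
        assignment = np.asarray(self.assignment, dtype=int)
        if assignment.ndim != 1:
            raise ValueError("assignment must be a vector")
        if self.L < 1:
            raise ValueError("need at least one signal")
        if assignment.min(initial=0) < 0 or (assignment >= self.L).any():
            raise ValueError("signals must lie in 0..L-1")
        object.__setattr__(self, "assignment", assignment)

    def __len__(self):
        return self.assignment.shape[0]

    def preimage(self, signal: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == signal)

    @classmethod
    def from_blocks(cls, blocks: Sequence[Sequence[int]], n_states: int, L: int | None = None) -> "EncoderMap":
        """Build from 1-based observation-state blocks: blocks[i] -> signal i."""
        L = len(blocks) if L is None else L
        assignment = np.full(n_states, -1, dtype=int)
        for sig, states in enumerate(blocks):
            for s in states:
                assignment[s - 1] = sig
        if (assignment < 0).any():
            raise ValueError("blocks must cover every observation state")
        return cls(assignment, L)

    def to_json_dict(self):
        return {"L": int(self.L), "assignment": self.assignment.tolist()}

    @classmethod
    def from_json_dict(cls, d):
        return cls(np.asarray(d["assignment"]), int(d["L"]))


def _grouped_mean(values: np.ndarray, labels: np.ndarray, L: int):
    sums = np.bincount(labels, weights=values, minlength=L)
    counts = np.bincount(labels, minlength=L)
    used = counts > 0
    means = np.full(L, np.nan)
    means[used] = sums[used] / counts[used]
    return means, used


@dataclass(frozen=True)
class CodingPair:
    """Two encoders plus every decoder table they induce on a landscape.

    ``decoder_table[i, j]`` is the conditional-mean affordance for signal
    pair (i, j); cells whose preimage product is empty are NaN and flagged
    unused — they can never be addressed by an actual observation.
    """

    encoder_B: EncoderMap
    encoder_C: EncoderMap
    decoder_table: np.ndarray
    used: np.ndarray
    sensory_decoder_B: np.ndarray
    sensory_decoder_C: np.ndarray
    unidim_decoder_B: np.ndarray
    unidim_decoder_C: np.ndarray


@dataclass(frozen=True)
class EstimateSet:
    """All reconstructions a coding pair induces: Â, Ô^B, Ô^C, Â^B, Â^C."""

    affordance_estimate: np.ndarray
    sensory_B: np.ndarray
    sensory_C: np.ndarray
    unidim_B: np.ndarray
    unidim_C: np.ndarray


def build_decoder(land: AffordanceLandscape, encoder_B: EncoderMap, encoder_C: EncoderMap) -> CodingPair:
    """Conditional-expectation decoder tables for a fixed encoder pair."""
    m, n = land.shape
    if len(encoder_B) != m or len(encoder_C) != n:
        raise ValueError("encoder lengths must match the landscape axes")
    zb, zc = encoder_B.assignment, encoder_C.assignment
    LB, LC = encoder_B.L, encoder_C.L
    pair_labels = (zb[:, None] * LC + zc[None, :]).ravel()
    sums = np.bincount(pair_labels, weights=land.matrix.ravel(), minlength=LB * LC)
    counts = np.bincount(pair_labels, minlength=LB * LC)
    used = (counts > 0).reshape(LB, LC)
    table = np.full(LB * LC, np.nan)
    table[counts > 0] = sums[counts > 0] / counts[counts > 0]
    sens_B, _ = _grouped_mean(land.row_states, zb, LB)
    sens_C, _ = _grouped_mean(land.col_states, zc, LC)
    uni_B, _ = _grouped_mean(row_expectations(land), zb, LB)
    uni_C, _ = _grouped_mean(column_expectations(land), zc, LC)
    return CodingPair(
        encoder_B=encoder_B,
        encoder_C=encoder_C,
        decoder_table=table.reshape(LB, LC),
        used=used,
        sensory_decoder_B=sens_B,
        sensory_decoder_C=sens_C,
        unidim_decoder_B=uni_B,
        unidim_decoder_C=uni_C,
    )


def estimates(pair: CodingPair, land: AffordanceLandscape) -> EstimateSet:
    """Push every observation cell through encoders and decoder tables."""
    zb, zc = pair.encoder_B.assignment, pair.encoder_C.assignment
    if not pair.used[zb[:, None], zc[None, :]].all():
        raise RuntimeError("an observation cell maps to an unused decoder cell")
    ahat = pair.decoder_table[zb[:, None], zc[None, :]]
    return EstimateSet(
        affordance_estimate=ahat,
        sensory_B=pair.sensory_decoder_B[zb],
        sensory_C=pair.sensory_decoder_C[zc],
        unidim_B=pair.unidim_decoder_B[zb],
        unidim_C=pair.unidim_decoder_C[zc],
    )


def mse(truth: np.ndarray, estimate: np.ndarray) -> float:
    """Mean squared error over all cells (or vector entries)."""
    truth = np.asarray(truth, float)
    estimate = np.asarray(estimate, float)
    if truth.shape != estimate.shape:
        raise ValueError(f"shape mismatch: {truth.shape} vs {estimate.shape}")
    return float(((truth - estimate) ** 2).mean())


_JOINT_NAMES = ("OB", "OC", "A", "ZB", "ZC", "Ahat")


def induced_joint(land: AffordanceLandscape, pair: CodingPair) -> ProbabilityTable:
    """Joint over (O^B, O^C, A, Z^B, Z^C, Â): uniform cells pushed through
    the deterministic encoder and decoder maps; every other variable's
    distribution is the frequency of its values."""
    est = estimates(pair, land)
    m, n = land.shape
    ob = np.repeat(land.row_states, n)
    oc = np.tile(land.col_states, m)
    zb = np.repeat(pair.encoder_B.assignment, n)
    zc = np.tile(pair.encoder_C.assignment, m)
    return ProbabilityTable.from_observations(
        _JOINT_NAMES,
        [ob, oc, land.matrix.ravel(), zb, zc, est.affordance_estimate.ravel()],
    )


def metrics_report(land: AffordanceLandscape, pair: CodingPair, tolerance: float = 1e-8) -> dict:
    """The model's eight summary quantities for one coding pair.

    MSE of the affordance estimate; BROJA synergy of the signals about the
    raw affordance variable A; sensory MI per axis; unidimensional affordance
    MI per axis; spatial entropy of the sensory estimates per axis.
    """
    est = estimates(pair, land)
    m, n = land.shape
    joint = induced_joint(land, pair)
    summary = _pid.synergy(
        _pid.PIDProblem(joint, (("ZB",), ("ZC",)), ("A",)), tolerance
    )
    uni_B = ProbabilityTable.from_observations(
        ("AB", "AhatB"), [row_expectations(land), est.unidim_B]
    )
    uni_C = ProbabilityTable.from_observations(
        ("AC", "AhatC"), [column_expectations(land), est.unidim_C]
    )
    sens_B = ProbabilityTable.from_observations(
        ("OB", "OhatB"), [land.row_states, est.sensory_B]
    )
    sens_C = ProbabilityTable.from_observations(
        ("OC", "OhatC"), [land.col_states, est.sensory_C]
    )
    return {
        "mse_affordance": mse(land.matrix, est.affordance_estimate),
        "synergy": summary.synergy,
        "mi_sensory_B": mutual_information(sens_B, ("OB",), ("OhatB",)),
        "mi_sensory_C": mutual_information(sens_C, ("OC",), ("OhatC",)),
        "mi_unidim_B": mutual_information(uni_B, ("AB",), ("AhatB",)),
        "mi_unidim_C": mutual_information(uni_C, ("AC",), ("AhatC",)),
        "spatial_entropy_B": spatial_entropy(SpatialSupport.from_values(est.sensory_B)),
        "spatial_entropy_C": spatial_entropy(SpatialSupport.from_values(est.sensory_C)),
        "mse_sensory_B": mse(land.row_states, est.sensory_B),
        "mse_sensory_C": mse(land.col_states, est.sensory_C),
    }


TABLE_COLUMNS = (
    "mse_affordance",
    "synergy",
    "mi_sensory_B",
    "mi_sensory_C",
    "mi_unidim_B",
    "mi_unidim_C",
)


def render_table_row(report: dict) -> tuple:
    """The six summary columns rounded to two decimals for display."""
    return tuple(round(report[k], 2) for k in TABLE_COLUMNS)
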
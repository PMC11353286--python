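"""Discrete probability tables and the information measures of the model.

All information quantities are reported in bits (logarithms base 2) and the
convention 0·log 0 := 0 is applied everywhere.  Tables are stored sparsely:
an outcome tuple absent from the mass mapping has probability zero, so large
but mostly-empty joint distributions (e.g. over a 32x32 landscape pushed
through two encoders) stay small.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "OutcomeSpace",
    "ProbabilityTable",
    "SpatialSupport",
    "VariableError",
    "entropy",
    "mutual_information",
    "conditional_mutual_information",
    "marginalize",
    "spatial_entropy",
]

_MASS_TOL = 1e-9


class VariableError(KeyError):
    """An operation referenced a variable name the table does not carry."""


def _xlog2x(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


@dataclass(frozen=True)
class OutcomeSpace:
    """Named discrete variables with ordered finite alphabets.

    States are hashable labels; in this model they are usually small integers
    (observation states, signal indices) or reals (affordance values), and
    their numeric identity matters when estimates are averaged.
    """

    names: tuple
    alphabets: Mapping

    def __post_init__(self):
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")
        alphabets = {n: tuple(self.alphabets[n]) for n in names}
        object.__setattr__(self, "alphabets", alphabets)
        for name, alpha in alphabets.items():
            if len(alpha) == 0:
                raise ValueError(f"alphabet of {name!r} is empty")
            if len(set(alpha)) != len(alpha):
                raise ValueError(f"alphabet of {name!r} has duplicate states")

    def index(self, name) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise VariableError(name) from None

    def indices(self, names: Iterable) -> tuple:
        return tuple(self.index(n) for n in names)


@dataclass(frozen=True)
class ProbabilityTable:
    """Sparse joint distribution over the variables of an :class:`OutcomeSpace`."""

    space: OutcomeSpace
    mass: Mapping

    def __post_init__(self):
        mass = {tuple(k): float(v) for k, v in dict(self.mass).items()}
        object.__setattr__(self, "mass", mass)
        total = 0.0
        sets = [set(a) for a in self.space.alphabets.values()]
        for outcome, p in mass.items():
            if p < -_MASS_TOL:
                raise ValueError(f"negative mass {p} at {outcome}")
            if len(outcome) != len(self.space.names):
                raise ValueError(f"outcome {outcome} has wrong arity")
            for state, allowed in zip(outcome, sets):
                if state not in allowed:
                    raise ValueError(f"state {state!r} not in alphabet")
            total += p
        if abs(total - 1.0) > _MASS_TOL:
            raise ValueError(f"masses sum to {total}, not 1")

    # -- construction -------------------------------------------------

    @classmethod
    def from_observations(
        cls, names: Sequence, columns: Sequence[np.ndarray], weights=None
    ) -> "ProbabilityTable":
        """Empirical joint: probability of each outcome tuple is its frequency.

        ``columns[k][i]`` is the value of variable ``names[k]`` in the *i*-th
        observation; observations are equally weighted unless ``weights`` is
        given.  Alphabets are the sorted unique values per column.
        """
        columns = [np.asarray(c) for c in columns]
        n = columns[0].shape[0]
        if any(c.shape != (n,) for c in columns):
            raise ValueError("columns must share one length")
        w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, float)
        w = w / w.sum()
        mass: dict = {}
        for i in range(n):
            key = tuple(c[i].item() if hasattr(c[i], "item") else c[i] for c in columns)
            mass[key] = mass.get(key, 0.0) + w[i]
        alphabets = {nm: sorted(set(np.asarray(c).tolist())) for nm, c in zip(names, columns)}
        return cls(OutcomeSpace(tuple(names), alphabets), mass)

    def renormalized(self) -> "ProbabilityTable":
        """Explicit renormalization (never applied silently)."""
        total = sum(self.mass.values())
        return ProbabilityTable(
            self.space, {k: v / total for k, v in self.mass.items()}
        )

    # -- views ---------------------------------------------------------

    def as_array(self) -> np.ndarray:
        """Dense array indexed by alphabet position along each variable axis."""
        shape = tuple(len(self.space.alphabets[n]) for n in self.space.names)
        pos = [
            {s: i for i, s in enumerate(self.space.alphabets[n])}
            for n in self.space.names
        ]
        arr = np.zeros(shape)
        for outcome, p in self.mass.items():
            arr[tuple(ix[s] for ix, s in zip(pos, outcome))] += p
        return arr

    # -- JSON round trip ----------------------------------------------

    def to_json(self) -> str:
        payload = {
            "variables": list(self.space.names),
            "alphabets": {n: list(a) for n, a in self.space.alphabets.items()},
            "mass": [[list(k), v] for k, v in sorted(self.mass.items())],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ProbabilityTable":
        payload = json.loads(text)
        space = OutcomeSpace(tuple(payload["variables"]), payload["alphabets"])
        mass = {tuple(k): v for k, v in payload["mass"]}
        return cls(space, mass)


def marginalize(p: ProbabilityTable, keep: Sequence) -> ProbabilityTable:
    """Sum the joint over every variable not in ``keep`` (order preserved)."""
    keep = tuple(keep)
    if not keep:
        raise ValueError("keep set must be non-empty")
    idx = p.space.indices(keep)
    mass: dict = {}
    for outcome, prob in p.mass.items():
        key = tuple(outcome[i] for i in idx)
        mass[key] = mass.get(key, 0.0) + prob
    alphabets = {n: p.space.alphabets[n] for n in keep}
    return ProbabilityTable(OutcomeSpace(keep, alphabets), mass)


def entropy(p: ProbabilityTable, variables: Sequence | None = None) -> float:
    """Shannon entropy H of the marginal on ``variables``, in bits."""
    if variables is not None and tuple(variables) != p.space.names:
        p = marginalize(p, tuple(variables))
    probs = np.array(list(p.mass.values()))
    return float(-_xlog2x(probs).sum())


def mutual_information(p: ProbabilityTable, group_a: Sequence, group_b: Sequence) -> float:
    """I(A;B) = H(A) + H(B) - H(A,B) in bits; symmetric, non-negative."""
    a, b = tuple(group_a), tuple(group_b)
    if set(a) & set(b):
        raise ValueError("variable groups must be disjoint")
    mi = entropy(p, a) + entropy(p, b) - entropy(p, a + b)
    # floor tiny negative round-off; genuine negatives cannot occur
    return 0.0 if -1e-12 < mi < 0.0 else mi


def conditional_mutual_information(
    p: ProbabilityTable, group_a: Sequence, group_b: Sequence, conditioning: Sequence
) -> float:
    """I(A;B|C) = H(A,C) + H(B,C) - H(A,B,C) - H(C), in bits."""
    a, b, c = tuple(group_a), tuple(group_b), tuple(conditioning)
    groups = [set(a), set(b), set(c)]
    for i in range(3):
        for j in range(i + 1, 3):
            if groups[i] & groups[j]:
                raise ValueError("variable groups must be pairwise disjoint")
    cmi = entropy(p, a + c) + entropy(p, b + c) - entropy(p, a + b + c) - entropy(p, c)
    return 0.0 if -1e-12 < cmi < 0.0 else cmi


@dataclass(frozen=True)
class SpatialSupport:
    """Support points of a variable embedded in a metric space.

    Each point carries a coordinate vector and a probability.  For this
    model's estimate variables the embedding is one-dimensional: each unique
    decoded value sits at its numeric value on the observation axis.
    """

    points: tuple  # of (coordinate ndarray, probability) pairs

    def __post_init__(self):
        pts = []
        dim = None
        total = 0.0
        for coord, prob in self.points:
            coord = np.atleast_1d(np.asarray(coord, float))
            if dim is None:
                dim = coord.shape[0]
            elif coord.shape[0] != dim:
                raise ValueError("coordinates must share one dimensionality")
            if prob < -_MASS_TOL:
                raise ValueError("negative probability")
            pts.append((coord, float(prob)))
            total += prob
        if not pts:
            raise ValueError("support must contain at least one point")
        if abs(total - 1.0) > _MASS_TOL:
            raise ValueError(f"probabilities sum to {total}, not 1")
        object.__setattr__(self, "points", tuple(pts))

    @classmethod
    def from_values(cls, values: np.ndarray, weights=None) -> "SpatialSupport":
        """Unique values of a 1-D sample placed at their numeric coordinate,
        weighted by their empirical frequency."""
        values = np.asarray(values, float).ravel()
        w = np.full(values.size, 1.0 / values.size) if weights is None else np.asarray(weights, float)
        uniq, inv = np.unique(values, return_inverse=True)
        probs = np.bincount(inv, weights=w)
        probs = probs / probs.sum()
        return cls(tuple((np.array([v]), p) for v, p in zip(uniq, probs)))


def spatial_entropy(s: SpatialSupport) -> float:
    """Distance-weighted entropy −Σ d_i p_i log2 p_i (units: distance · bits).

    d_i is the mean Euclidean distance from support point *i* to all other
    support points; a single-point support has d := 0, hence entropy 0.
    """
    coords = np.stack([c for c, _ in s.points])
    probs = np.array([p for _, p in s.points])
    n = coords.shape[0]
    if n == 1:
        return 0.0
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    d = dist.sum(axis=1) / (n - 1)
    return float(-(d * _xlog2x(probs)).sum())
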
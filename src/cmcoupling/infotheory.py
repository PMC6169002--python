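"""Entropy and mutual information: exact discrete oracles and the KSG
continuous estimator.

The discrete plug-in quantities operate on a :class:`ProbTable` over finite
alphabets and are exact; they serve as oracles for the continuous
k-nearest-neighbor (Kraskov-Stogbauer-Grassberger) estimator
:func:`mi_ksg`, the estimator actually used on LFP/EMG samples. All values
are in nats; :class:`CouplingEstimate` converts to bits on request.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import knn

__all__ = [
    "ProbTable",
    "CouplingEstimate",
    "entropy_discrete",
    "mi_plugin_discrete",
    "mi_ksg",
]

_LN2 = float(np.log(2.0))


@dataclass
class ProbTable:
    """A (joint) probability table over finite alphabets.

    ``probs`` may have any number of axes; marginals are obtained by summing
    out the complementary axes. Probabilities must be nonnegative and sum to
    one within 1e-12; use :meth:`from_counts` to build one from raw counts.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be nonnegative")
        total = self.probs.sum()
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"probabilities must sum to 1, got {total!r}")

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "ProbTable":
        counts = np.asarray(counts, dtype=float)
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        total = counts.sum()
        if total <= 0:
            raise ValueError("counts must not be all zero")
        return cls(counts / total)

    def marginal(self, axis: int) -> "ProbTable":
        """Marginal distribution along ``axis`` (all other axes summed out)."""
        other = tuple(i for i in range(self.probs.ndim) if i != axis)
        return ProbTable(self.probs.sum(axis=other))


@dataclass
class CouplingEstimate:
    """An MI or directional TE value with its estimator metadata.

    ``value`` is in nats. When a surrogate null distribution has been
    attached, ``p_value`` is the one-sided exceedance probability
    ``(1 + #{surr >= value}) / (1 + n_surrogates)``.
    """

    value: float
    estimator: str
    n_samples: int
    params: dict = field(default_factory=dict)
    surrogate_values: np.ndarray | None = None
    p_value: float | None = None

    @property
    def value_bits(self) -> float:
        return self.value / _LN2

    def attach_surrogates(self, surrogate_values: np.ndarray) -> None:
        surr = np.asarray(surrogate_values, dtype=float)
        self.surrogate_values = surr
        self.p_value = float(
            (1 + np.sum(surr >= self.value)) / (1 + surr.size)
        )

    @property
    def bias_corrected_value(self) -> float:
        """Value minus the surrogate mean (common TE bias correction)."""
        if self.surrogate_values is None:
            raise ValueError("no surrogate distribution attached")
        return self.value - float(np.mean(self.surrogate_values))


def entropy_discrete(table: ProbTable) -> float:
    """Shannon entropy -sum p ln p in nats, with 0 ln 0 = 0."""
    p = table.probs[table.probs > 0]
    return float(-np.sum(p * np.log(p)))


def mi_plugin_discrete(joint: ProbTable) -> float:
    """Plug-in mutual information H(X) + H(Y) - H(X,Y) of a 2-D joint table."""
    if joint.probs.ndim != 2:
        raise ValueError(
            f"joint table must be 2-D, got {joint.probs.ndim} axes"
        )
    hx = entropy_discrete(joint.marginal(0))
    hy = entropy_discrete(joint.marginal(1))
    hxy = entropy_discrete(joint)
    return hx + hy - hxy


def _validate_pair(x: np.ndarray, y: np.ndarray, k: int) -> None:
    if x.shape[0] != y.shape[0]:
        raise ValueError(
            f"sample arrays must have equal length, got {x.shape[0]} and "
            f"{y.shape[0]}"
        )
    if x.shape[0] <= k + 2:
        raise ValueError(f"need more than k + 2 = {k + 2} samples, got {x.shape[0]}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples contain NaN or infinite values")


def mi_ksg(
    x: np.ndarray,
    y: np.ndarray,
    k: int = 4,
    theiler: int = 0,
    tie_seed: int = knn.DEFAULT_TIE_SEED,
) -> CouplingEstimate:
    """KSG (algorithm 1) mutual information between two continuous samples.

    For each point the Chebyshev distance ``eps_i`` to its k-th neighbor in
    the joint space is found, and the points strictly within ``eps_i`` of it
    in each marginal are counted; the estimate is

        psi(k) + psi(n) - < psi(n_x + 1) + psi(n_y + 1) >

    in nats. Exact value ties are broken by a deterministic uniform jitter of
    amplitude 1e-10 of each marginal's SD (seeded by ``tie_seed``), so the
    estimate is reproducible. Small negative values are possible on
    independent data (estimator noise around zero) and are reported as-is.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate_pair(x, y, k)
    value = knn.ksg_mi(x, y, k=k, theiler=theiler, tie_seed=tie_seed)
    return CouplingEstimate(
        value=value,
        estimator="ksg_mi",
        n_samples=x.shape[0],
        params={"k": k, "theiler": theiler},
    )
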
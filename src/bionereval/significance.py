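"""Randomized null models, z-scores and normalization.

Every evaluation statistic in the pipeline (transitivity, edge overlap,
community/category coincidence) is judged against an empirical null built by
recomputing the statistic on Erdős–Rényi G(n, m) graphs: random simple graphs
with the original node set and edge count, edges uniform over node pairs.
The default is 1000 repetitions; the null sample is checked for normality
with the Shapiro–Wilk test and the observed value is expressed as a z-score
against the null mean and standard deviation.  Min–max normalization makes
z-scores comparable across tools.

Per-replicate seeds derive from one master seed through a counter-based
``numpy.random.SeedSequence`` scheme, so replicates are independent and a run
is reproducible from ``(template, n_reps, seed)`` alone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .errors import DomainError
from .model import DiseaseNetwork

__all__ = [
    "NullDistribution",
    "ZScoreResult",
    "random_gnm",
    "build_null",
    "zscore",
    "shapiro_wilk_p",
    "minmax_normalize",
    "replicate_seed",
]


@dataclass
class NullDistribution:
    """Empirical null-model sample for one statistic on one network."""

    statistic_label: str
    samples: np.ndarray
    n_reps: int
    seed: int
    n_failed: int = 0
    _shapiro_p: float | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size != self.n_reps - self.n_failed:
            raise DomainError(
                f"{self.statistic_label}: {self.samples.size} samples for "
                f"{self.n_reps} repetitions with {self.n_failed} failures"
            )

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples))

    @property
    def sd(self) -> float:
        """Sample standard deviation (n−1 denominator)."""
        if self.samples.size < 2:
            return 0.0
        return float(np.std(self.samples, ddof=1))

    @property
    def shapiro_p(self) -> float | None:
        """Shapiro–Wilk normality p-value of the sample (None if degenerate)."""
        if self._shapiro_p is None:
            if self.samples.size < 3 or np.ptp(self.samples) == 0:
                return None
            self._shapiro_p = shapiro_wilk_p(self.samples)
        return self._shapiro_p


@dataclass
class ZScoreResult:
    """Observed statistic expressed against its null distribution."""

    observed: float
    z: float
    null: NullDistribution

    @property
    def shapiro_p(self) -> float | None:
        return self.null.shapiro_p

    @property
    def normality_warning(self) -> bool:
        """True when the null sample looks non-normal (Shapiro–Wilk p ≤ 0.05)."""
        p = self.shapiro_p
        return p is not None and p <= 0.05


def replicate_seed(master_seed: int, index: int) -> int:
    """Deterministic per-replicate seed below 2**31, independent across indices."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def sample_pair_indices(n: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """m distinct unordered-pair indices in [0, C(n,2)), uniform without replacement."""
    total = n * (n - 1) // 2
    if m > total:
        raise DomainError(f"cannot place {m} edges on {n} nodes (max {total})")
    if total <= 2_000_000 and m * 3 > total:
        return rng.choice(total, size=m, replace=False)
    seen: set[int] = set()
    picked: list[int] = []
    while len(picked) < m:
        for k in rng.integers(0, total, size=(m - len(picked)) + 8):
            k = int(k)
            if k not in seen:
                seen.add(k)
                picked.append(k)
                if len(picked) == m:
                    break
    return np.array(picked, dtype=np.int64)


def decode_pair_index(k: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Invert the lexicographic pair enumeration: index k → (i, j), i < j."""
    k = np.asarray(k, dtype=np.int64)
    # row i starts at offset f(i) = i*n - i*(i+1)/2; solve the quadratic, then
    # correct for floating-point rounding at row boundaries.
    i = np.floor((2 * n - 1 - np.sqrt((2 * n - 1) ** 2 - 8 * k.astype(float))) / 2)
    i = i.astype(np.int64)
    offset = i * n - i * (i + 1) // 2
    too_far = offset > k
    i = np.where(too_far, i - 1, i)
    offset = i * n - i * (i + 1) // 2
    next_offset = (i + 1) * n - (i + 1) * (i + 2) // 2
    short = k >= next_offset
    i = np.where(short, i + 1, i)
    offset = i * n - i * (i + 1) // 2
    j = k - offset + i + 1
    return i, j


def random_gnm(nodes: Iterable[str], m: int, seed: int) -> DiseaseNetwork:
    """Uniform G(n, m) random simple graph on a fixed node set, unit weights."""
    nodes = sorted(nodes)
    n = len(nodes)
    rng = np.random.default_rng(seed)
    idx = sample_pair_indices(n, m, rng)
    ii, jj = decode_pair_index(idx, n)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(
        (nodes[int(i)], nodes[int(j)], {"weight": 1.0}) for i, j in zip(ii, jj)
    )
    return DiseaseNetwork(g, source_id="gnm_null", build_seed=seed)


def build_null(
    statistic: Callable[[DiseaseNetwork], float],
    template: DiseaseNetwork,
    n_reps: int,
    seed: int,
    statistic_label: str = "statistic",
) -> NullDistribution:
    """Evaluate ``statistic`` on ``n_reps`` G(n, m) randomizations of ``template``.

    A replicate on which the statistic raises is recorded as missing and
    counted in ``n_failed`` rather than aborting the run.
    """
    if n_reps < 2:
        raise DomainError("build_null requires n_reps >= 2")
    nodes = sorted(template.node_set())
    m = template.n_edges
    samples: list[float] = []
    n_failed = 0
    for rep in range(n_reps):
        net = random_gnm(nodes, m, replicate_seed(seed, rep))
        try:
            samples.append(float(statistic(net)))
        except Exception:
            n_failed += 1
    return NullDistribution(
        statistic_label=statistic_label,
        samples=np.array(samples),
        n_reps=n_reps,
        seed=seed,
        n_failed=n_failed,
    )


def zscore(observed: float, null: NullDistribution) -> ZScoreResult:
    """(observed − null mean) / null sd; signed infinity sentinel when sd = 0."""
    sd = null.sd
    diff = observed - null.mean
    if sd > 0:
        z = diff / sd
    elif diff == 0:
        z = 0.0
    else:
        z = math.inf if diff > 0 else -math.inf
    return ZScoreResult(observed=float(observed), z=z, null=null)


def shapiro_wilk_p(samples: Sequence[float]) -> float:
    """Shapiro–Wilk normality p-value; defined for 3 ≤ n ≤ 5000 samples."""
    x = np.asarray(samples, dtype=float)
    if not (3 <= x.size <= 5000):
        raise DomainError(f"Shapiro–Wilk needs 3..5000 samples, got {x.size}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(x).pvalue)


def minmax_normalize(values: Sequence[float]) -> list[float]:
    """Scale values linearly to [0, 1]; an all-equal vector maps to all 0.5."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise DomainError("cannot normalize an empty list")
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        warnings.warn(
            "min-max normalization of an all-equal vector; returning 0.5",
            stacklevel=2,
        )
        return [0.5] * x.size
    return [float(v) for v in (x - lo) / (hi - lo)]
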
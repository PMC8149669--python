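"""Abundance-weighted partition of Bray-Curtis beta-diversity.

For a pair of quadrats with abundance vectors ``x1``, ``x2`` define

    A = sum_j min(x1j, x2j)          shared abundance
    B = sum_j (x1j - min(x1j, x2j))  abundance unique to quadrat 1
    C = sum_j (x2j - min(x1j, x2j))  abundance unique to quadrat 2

Total beta-diversity is the Bray-Curtis dissimilarity

    total     = (B + C) / (2A + B + C)

partitioned into the balanced-variation (turnover) and abundance-gradient
(nestedness) components

    turnover   = min(B, C) / (A + min(B, C))
    nestedness = |B - C| / (2A + B + C) * A / (A + min(B, C))

which satisfy ``turnover + nestedness = total`` exactly. The module also
implements the quadrat subsampling protocol (n quadrats drawn without
replacement, repeated ``n_reps`` times) with percentile-bootstrap confidence
intervals on the replicate means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .community import CommunityMatrix

logger = logging.getLogger(__name__)


class UndefinedPairError(ValueError):
    """Both quadrats of a pair are empty; the partition is undefined."""


class InsufficientDataError(ValueError):
    """Fewer non-empty quadrats than the computation requires."""


class ScaleExclusionError(ValueError):
    """Plot has fewer complete quadrats than the subsample size requires."""


class AbcDecomposition(NamedTuple):
    A: float
    B: float
    C: float


class BetaPartition(NamedTuple):
    total: float
    turnover: float
    nestedness: float


@dataclass
class BetaSummary:
    """Replicate-averaged beta metrics for one plot x group x scale."""

    mean_total: float
    mean_turnover: float
    mean_nestedness: float
    ci_total: tuple[float, float]
    ci_turnover: tuple[float, float]
    ci_nestedness: tuple[float, float]
    n_replicates: int
    replicates: np.ndarray  # (n_reps, 3) columns total, turnover, nestedness

    @property
    def relative_turnover(self) -> float:
        return relative_contributions(self)[0]

    @property
    def relative_nestedness(self) -> float:
        return relative_contributions(self)[1]


def _validate_pair(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("abundance vectors must have equal species dimension")
    if (x1 < 0).any() or (x2 < 0).any():
        raise ValueError("abundance counts must be non-negative")
    return x1, x2


def abc_decompose(x1, x2) -> AbcDecomposition:
    """Shared abundance A and one-sided surpluses B, C for a quadrat pair."""
    x1, x2 = _validate_pair(x1, x2)
    m = np.minimum(x1, x2)
    a = float(m.sum())
    return AbcDecomposition(a, float(x1.sum()) - a, float(x2.sum()) - a)


def partition_from_abc(a: float, b: float, c: float) -> BetaPartition:
    """Partition from the (A, B, C) decomposition.

    Degenerate cases: both quadrats empty (A = B = C = 0) is undefined; one
    quadrat empty (A = 0, min(B, C) = 0, B + C > 0) gives total = 1,
    turnover = 0, nestedness = 1 by continuity.
    """
    denom = 2 * a + b + c
    if denom == 0:
        raise UndefinedPairError("both quadrats empty; partition undefined")
    mbc = min(b, c)
    total = (b + c) / denom
    if a + mbc == 0:
        # one quadrat empty: the limit of the component formulas
        return BetaPartition(total, 0.0, total)
    turnover = mbc / (a + mbc)
    nestedness = abs(b - c) / denom * (a / (a + mbc))
    return BetaPartition(total, turnover, nestedness)


def partition_pair(x1, x2) -> BetaPartition:
    """Total/turnover/nestedness partition for one quadrat pair."""
    return partition_from_abc(*abc_decompose(x1, x2))


def pairwise_partitions(counts: np.ndarray) -> np.ndarray:
    """All-pairs partition for a quadrat x species count matrix.

    Returns an array of shape (n_pairs, 3) in ``pdist`` condensed order with
    columns (total, turnover, nestedness). Uses the identity
    ``A = (t_i + t_j - d_ij) / 2`` with ``d_ij`` the city-block distance and
    ``t_i`` the quadrat totals, so the all-pairs computation is a single
    ``pdist`` call. Rows must be non-empty quadrats.
    """
    counts = np.asarray(counts, dtype=float)
    tot = counts.sum(axis=1)
    if (tot == 0).any():
        raise UndefinedPairError("empty quadrat in pairwise computation")
    d = pdist(counts, metric="cityblock")
    n = counts.shape[0]
    ti = np.repeat(tot, np.arange(n - 1, -1, -1))
    tj = np.concatenate([tot[i + 1 :] for i in range(n)]) if n > 1 else np.empty(0)
    a = (ti + tj - d) / 2
    b = ti - a
    c = tj - a
    mbc = np.minimum(b, c)
    denom = 2 * a + b + c
    total = (b + c) / denom
    with np.errstate(invalid="ignore", divide="ignore"):
        turnover = np.where(a + mbc > 0, mbc / (a + mbc), 0.0)
        nestedness = np.where(a + mbc > 0, np.abs(b - c) / denom * a / (a + mbc), total)
    return np.column_stack([total, turnover, nestedness])


def mean_pairwise(
    matrix: CommunityMatrix | np.ndarray, quadrat_subset=None
) -> BetaPartition:
    """Mean partition over all unordered pairs of non-empty quadrats.

    ``quadrat_subset`` selects rows (positional indices); empty quadrats in
    the subset are excluded from pairing and their count logged.
    """
    counts = matrix.counts.to_numpy() if isinstance(matrix, CommunityMatrix) else np.asarray(matrix)
    if quadrat_subset is not None:
        counts = counts[np.asarray(quadrat_subset)]
    nonempty = counts.sum(axis=1) > 0
    n_empty = int((~nonempty).sum())
    if n_empty:
        logger.info("excluded %d empty quadrats from pairwise means", n_empty)
    counts = counts[nonempty]
    if counts.shape[0] < 2:
        raise InsufficientDataError(
            f"need >= 2 non-empty quadrats, have {counts.shape[0]}"
        )
    parts = pairwise_partitions(counts)
    m = parts.mean(axis=0)
    return BetaPartition(float(m[0]), float(m[1]), float(m[2]))


def sample_quadrats(
    matrix: CommunityMatrix, n: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Uniform sample without replacement of ``n`` grid quadrats (indices).

    Raises :class:`ScaleExclusionError` if the plot has fewer than ``n``
    quadrats — the plot is excluded at this scale, mirroring the exclusion
    of small plots at the coarsest quadrat size.
    """
    rng = np.random.default_rng(rng)
    n_avail = matrix.n_quadrats
    if n_avail < n:
        raise ScaleExclusionError(
            f"plot has {n_avail} quadrats at scale {matrix.scale} m; {n} required"
        )
    return rng.choice(n_avail, size=n, replace=False)


def _percentile_ci(
    values: np.ndarray, rng: np.random.Generator, n_boot: int = 1000
) -> tuple[float, float]:
    """Nonparametric percentile bootstrap CI of the mean of ``values``."""
    if len(values) == 1:
        return float(values[0]), float(values[0])
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(lo), float(hi)


def replicate_summary(
    matrix: CommunityMatrix,
    n_quadrats: int,
    n_reps: int = 200,
    seed: np.random.Generator | int | None = 0,
    n_boot: int = 1000,
    max_resample: int = 100,
) -> BetaSummary:
    """Replicate the subsampling protocol and summarize with bootstrap CIs.

    Each of ``n_reps`` repetitions draws ``n_quadrats`` quadrats without
    replacement and computes the mean pairwise partition. A draw containing
    an empty quadrat is redrawn (logged); quadrat sets may repeat across
    repetitions. The 95% CI of each mean is the percentile bootstrap over
    the replicate values (``n_boot`` resamples).
    """
    rng = np.random.default_rng(seed)
    counts = matrix.counts.to_numpy()
    nonempty = counts.sum(axis=1) > 0
    if nonempty.sum() < max(2, n_quadrats):
        raise InsufficientDataError(
            f"only {int(nonempty.sum())} non-empty quadrats; {n_quadrats} required"
        )
    if matrix.n_quadrats < n_quadrats:
        raise ScaleExclusionError(
            f"plot has {matrix.n_quadrats} quadrats; {n_quadrats} required"
        )
    reps = np.empty((n_reps, 3))
    n_redraws = 0
    for r in range(n_reps):
        for _ in range(max_resample):
            subset = rng.choice(matrix.n_quadrats, size=n_quadrats, replace=False)
            if nonempty[subset].all():
                break
            n_redraws += 1
        else:
            raise InsufficientDataError(
                "could not draw a subset free of empty quadrats"
            )
        reps[r] = pairwise_partitions(counts[subset]).mean(axis=0)
    if n_redraws:
        logger.info("redrew %d replicate quadrat sets containing empty quadrats", n_redraws)
    if n_reps == 1:
        logger.warning("n_reps = 1: confidence intervals are degenerate")
    means = reps.mean(axis=0)
    cis = [_percentile_ci(reps[:, k], rng, n_boot) for k in range(3)]
    return BetaSummary(
        mean_total=float(means[0]),
        mean_turnover=float(means[1]),
        mean_nestedness=float(means[2]),
        ci_total=cis[0],
        ci_turnover=cis[1],
        ci_nestedness=cis[2],
        n_replicates=n_reps,
        replicates=reps,
    )


def relative_contributions(summary: BetaSummary | BetaPartition) -> tuple[float, float]:
    """Turnover and nestedness shares of total beta-diversity (sum to 1).

    Undefined when mean total is 0; returns ``(nan, nan)`` with a warning.
    """
    if isinstance(summary, BetaPartition):
        total, turn, nest = summary
    else:
        total, turn, nest = summary.mean_total, summary.mean_turnover, summary.mean_nestedness
    if total == 0:
        logger.warning("total beta-diversity is 0; relative contributions undefined")
        return (float("nan"), float("nan"))
    return (turn / total, nest / total)
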
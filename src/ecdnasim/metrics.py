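"""Distribution distances, the restoration-time criterion, and sister-cell asymmetry.

The headline claim the simulator reproduces is that sorted high- and
low-dosage subpopulations rebuild the full copy-number continuum within a
few generations. "Rebuilt" is operationalized here as: the 1-D Wasserstein
distance between a post-sort snapshot and the control distribution falls
below a bootstrap noise floor — the chosen quantile (default 95th) of
distances between pairs of size-matched resamples of the control itself.

Sister-cell partitioning asymmetry is summarized per division pair as the
percent difference ``|k1 - k2| / ((k1 + k2)/2) * 100``, compared against a
Monte-Carlo reference of unbiased binomial splits of the same totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple
import warnings

import numpy as np
from scipy import stats

from .initsort import CopyNumberSample

__all__ = [
    "RecoveryTrajectory",
    "ConvergenceCriterion",
    "NOT_CONVERGED",
    "wasserstein_1d",
    "recovery_generation",
    "sister_asymmetry",
]

NOT_CONVERGED = -1


@dataclass(frozen=True)
class RecoveryTrajectory:
    """Per-generation snapshots of one sorted subpopulation."""

    group: str
    snapshots: Mapping[int, CopyNumberSample]

    def __post_init__(self) -> None:
        gens = sorted(self.snapshots)
        if gens != list(range(gens[0], gens[0] + len(gens))):
            raise ValueError("trajectory generations must be consecutive")

    def generations(self) -> List[int]:
        return sorted(self.snapshots)


@dataclass(frozen=True)
class ConvergenceCriterion:
    distance: str = "wasserstein"
    noise_floor_quantile: float = 0.95
    bootstrap_reps: int = 200

    def __post_init__(self) -> None:
        if self.distance not in ("wasserstein", "kl"):
            raise ValueError("distance must be 'wasserstein' or 'kl'")
        if not 0 < self.noise_floor_quantile < 1:
            raise ValueError("noise_floor_quantile must lie in (0, 1)")
        if self.bootstrap_reps < 50:
            raise ValueError("bootstrap_reps must be >= 50")


def wasserstein_1d(a: CopyNumberSample | np.ndarray, b: CopyNumberSample | np.ndarray) -> float:
    """Exact 1-D W1 distance between two empirical count distributions.

    Computed as the integrated absolute difference of empirical CDFs
    (units: copies); handles unequal sample sizes without resampling.
    Zero iff the empirical distributions coincide.
    """
    ax = a.counts if isinstance(a, CopyNumberSample) else np.asarray(a)
    bx = b.counts if isinstance(b, CopyNumberSample) else np.asarray(b)
    if ax.size == 0 or bx.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(stats.wasserstein_distance(ax, bx))


def _distance_fn(crit: ConvergenceCriterion):
    if crit.distance == "wasserstein":
        return wasserstein_1d
    from .inference import histogram_kl

    return lambda a, b: histogram_kl(a, b, n_bins=30, pseudocount=0.5)


def recovery_generation(
    traj: RecoveryTrajectory,
    control: CopyNumberSample | Mapping[int, CopyNumberSample],
    crit: ConvergenceCriterion,
    rng: np.random.Generator,
) -> int:
    """First generation whose snapshot is indistinguishable from control.

    ``control`` is either a single sample or a per-generation mapping (a
    control arm measured alongside the sorted populations; each snapshot
    is then compared to the same-generation control). The noise floor is
    the ``noise_floor_quantile`` of distances between ``bootstrap_reps``
    pairs of size-matched resamples of the control; returns the smallest
    generation whose snapshot-to-control distance is at or below that
    floor, or :data:`NOT_CONVERGED` if none is.
    """
    dist = _distance_fn(crit)
    for g in traj.generations():
        ctrl = control[g] if isinstance(control, Mapping) else control
        if len(ctrl) < 50:
            raise ValueError("control sample must have at least 50 cells")
        snap = traj.snapshots[g]
        m = len(snap)
        floors = np.empty(crit.bootstrap_reps)
        for r in range(crit.bootstrap_reps):
            x = CopyNumberSample(rng.choice(ctrl.counts, size=m, replace=True))
            y = CopyNumberSample(rng.choice(ctrl.counts, size=m, replace=True))
            floors[r] = dist(x, y)
        floor = float(np.quantile(floors, crit.noise_floor_quantile))
        if dist(snap, ctrl) <= floor:
            return g
    return NOT_CONVERGED


def sister_asymmetry(
    pairs: Sequence[Tuple[int, int]],
    rng: np.random.Generator | None = None,
    n_reference: int = 1000,
) -> Dict[str, object]:
    """Percent difference in inherited copies between sister cells.

    For each pair ``(k1, k2)`` the asymmetry is
    ``A = |k1 - k2| / ((k1 + k2)/2) * 100``. Pairs with ``k1 = k2 = 0`` are
    excluded with a warning. The summary also carries a Monte-Carlo
    reference distribution of A under unbiased binomial segregation
    (``k1 ~ Binomial(k1 + k2, 0.5)``) of the same per-pair totals, the
    null against which observed asymmetry is judged.
    """
    pairs = [(int(a), int(b)) for a, b in pairs]
    kept = [(a, b) for a, b in pairs if a + b > 0]
    if len(kept) < len(pairs):
        warnings.warn(f"excluded {len(pairs) - len(kept)} pair(s) with zero total copies")
    if not kept:
        raise ValueError("no usable sister pairs")
    arr = np.asarray(kept, dtype=float)
    totals = arr.sum(axis=1)
    per_pair = np.abs(arr[:, 0] - arr[:, 1]) / (totals / 2.0) * 100.0

    reference = None
    if rng is not None:
        tot_i = totals.astype(np.int64)
        draws = rng.binomial(tot_i[None, :].repeat(n_reference, axis=0), 0.5)
        ref = np.abs(2 * draws - tot_i[None, :]) / (tot_i[None, :] / 2.0) * 100.0
        reference = ref.ravel()

    out: Dict[str, object] = {
        "per_pair_percent": per_pair,
        "mean": float(per_pair.mean()),
        "median": float(np.median(per_pair)),
    }
    if reference is not None:
        out["reference_percent"] = reference
        out["reference_mean"] = float(reference.mean())
        out["reference_median"] = float(np.median(reference))
    return out
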
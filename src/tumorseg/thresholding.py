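"""Multi-level histogram thresholding by non-extensive (Tsallis) entropy.

An image histogram is partitioned into ``m + 1`` classes by ``m`` integer
thresholds; class ``i`` spans gray levels ``(t_{i-1}, t_i]`` with sentinels
``t_0 = -1`` and ``t_{m+1} = L - 1``. For entropy index ``gamma != 1`` each
class contributes

    H_i = (1 - sum_k (h_k / P_i)^gamma) / (gamma - 1),    P_i = sum_k h_k,

and the thresholds maximizing ``sum_i H_i`` are sought with a
DE/rand/1/bin differential-evolution search over real genomes that are
sorted and rounded to integers before evaluation. The class entropies are
summed without the pseudo-additive cross term; the classic variant with the
``(1 - gamma) * prod H_i`` correction is available behind a flag.

The final scalar threshold ``T_a`` is the mean of the three largest
thresholds, and binarization keeps pixels whose quantized intensity is
strictly above ``T_a``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tumorseg.core_io import LEVELS, BinaryMask, GrayImage, Histogram, ValidationError

__all__ = [
    "TsallisParams",
    "ThresholdVector",
    "DEConfig",
    "TsallisEvaluator",
    "tsallis_objective",
    "shannon_limit",
    "optimize_thresholds",
    "aggregate_threshold",
    "binarize",
]


@dataclass(frozen=True)
class TsallisParams:
    """Entropy index and number of thresholds."""

    gamma: float = 0.5
    m: int = 6

    def __post_init__(self) -> None:
        if self.gamma == 1.0:
            raise ValidationError(
                "gamma == 1 is the Shannon limit; use shannon_limit() instead"
            )
        if not (1 <= self.m <= LEVELS - 2):
            raise ValidationError(f"m must be in [1, {LEVELS - 2}], got {self.m}")


@dataclass(frozen=True)
class ThresholdVector:
    """Sorted integer thresholds with their objective value."""

    values: tuple[int, ...]
    objective: float
    trace: tuple[float, ...] = ()  # best-so-far objective per generation

    def __post_init__(self) -> None:
        vals = tuple(int(v) for v in self.values)
        if any(vals[i] > vals[i + 1] for i in range(len(vals) - 1)):
            raise ValidationError("thresholds must be sorted non-decreasing")
        if vals and (vals[0] < 1 or vals[-1] > LEVELS - 2):
            raise ValidationError(f"thresholds must lie in [1, {LEVELS - 2}]")
        object.__setattr__(self, "values", vals)

    @property
    def m(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class DEConfig:
    """DE/rand/1/bin search configuration.

    ``np_size`` defaults to ``10 * D`` where ``D`` is the genome length
    (one gene per threshold).
    """

    np_size: int | None = None
    weighting_factor: float = 0.5   # F
    crossover_prob: float = 0.9     # CR
    generations: int = 100
    seed: int = 0
    early_stop_patience: int = 25
    lower: int = 1
    upper: int = LEVELS - 2

    def __post_init__(self) -> None:
        if self.np_size is not None and self.np_size < 4:
            raise ValidationError("population must have >= 4 members (mutation needs 3 others)")
        if not (0.0 <= self.crossover_prob <= 1.0):
            raise ValidationError(f"CR must be in [0, 1], got {self.crossover_prob}")
        if self.weighting_factor <= 0:
            raise ValidationError(f"F must be positive, got {self.weighting_factor}")

    def resolve_np(self, d: int) -> int:
        n = self.np_size if self.np_size is not None else 10 * d
        if n < 4:
            raise ValidationError("population must have >= 4 members (mutation needs 3 others)")
        return n


class TsallisEvaluator:
    """Fast per-class objective evaluation on one histogram.

    Using ``(h_k / P_i)^g = h_k^g / P_i^g``, each class entropy needs only
    the class probability mass and the class sum of ``h^g``. Both are
    computed as direct segment sums of non-negative terms (``reduceat``),
    which stays accurate even for classes whose mass is many orders of
    magnitude below the histogram peak — prefix-sum differencing does not.
    """

    def __init__(self, hist: Histogram, gamma: float):
        if gamma == 1.0:
            raise ValidationError(
                "gamma == 1 is the Shannon limit; use shannon_limit() instead"
            )
        self.gamma = float(gamma)
        self._h = hist.probs.astype(np.float64)
        self._hg = np.power(self._h, self.gamma)

    def _class_sums(self, thresholds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        edges = np.empty(thresholds.size + 2, dtype=np.int64)
        edges[0] = 0
        edges[1:-1] = thresholds + 1
        edges[-1] = LEVELS
        starts = edges[:-1]
        nonempty = edges[1:] > starts
        # reduceat returns the single element at starts[i] for empty
        # segments; zero those out explicitly
        p = np.add.reduceat(self._h, starts)
        sg = np.add.reduceat(self._hg, starts)
        p[~nonempty] = 0.0
        sg[~nonempty] = 0.0
        return p, sg

    def objective(self, thresholds, cross_term: bool = False) -> float:
        """Total entropy over the classes induced by sorted ``thresholds``."""
        g = self.gamma
        p, sg = self._class_sums(np.asarray(thresholds, dtype=np.int64))
        occupied = p > 0.0
        h_i = np.zeros_like(p)
        h_i[occupied] = (1.0 - sg[occupied] / np.power(p[occupied], g)) / (g - 1.0)
        total = float(h_i.sum())
        if cross_term:
            total += float((1.0 - g) * np.prod(h_i[occupied])) if occupied.any() else 0.0
        return total

    def objective_batch(self, genomes: np.ndarray, cross_term: bool = False) -> np.ndarray:
        """Evaluate a (NP, m) batch of sorted integer genomes."""
        genomes = np.asarray(genomes, dtype=np.int64)
        out = np.empty(genomes.shape[0], dtype=np.float64)
        for i in range(genomes.shape[0]):
            out[i] = self.objective(genomes[i], cross_term=cross_term)
        return out


def tsallis_objective(
    hist: Histogram,
    thresholds,
    params: TsallisParams | None = None,
    *,
    gamma: float | None = None,
    cross_term: bool = False,
) -> float:
    """Total Tsallis entropy of the partition induced by ``thresholds``.

    ``thresholds`` may be a :class:`ThresholdVector` or a sorted sequence of
    integers in ``[1, L-2]``. Empty classes contribute zero.
    """
    if gamma is None:
        gamma = (params or TsallisParams()).gamma
    vals = thresholds.values if isinstance(thresholds, ThresholdVector) else tuple(thresholds)
    vals = tuple(int(v) for v in vals)
    if any(vals[i] > vals[i + 1] for i in range(len(vals) - 1)):
        raise ValidationError("thresholds must be sorted non-decreasing")
    if vals and (vals[0] < 1 or vals[-1] > LEVELS - 2):
        raise ValidationError(f"thresholds must lie in [1, {LEVELS - 2}]")
    return TsallisEvaluator(hist, gamma).objective(vals, cross_term=cross_term)


def shannon_limit(hist: Histogram, thresholds) -> float:
    """Shannon entropy sum over classes: the ``gamma -> 1`` limit oracle."""
    vals = thresholds.values if isinstance(thresholds, ThresholdVector) else tuple(thresholds)
    h = hist.probs
    edges = np.concatenate(([0], np.asarray(vals, dtype=np.int64) + 1, [LEVELS]))
    total = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        seg = h[a:b]
        p = float(seg.sum())
        if p <= 0.0:
            continue
        q = seg[seg > 0] / p
        total += float(-(q * np.log(q)).sum())
    return total


def optimize_thresholds(
    hist: Histogram,
    params: TsallisParams | None = None,
    de_cfg: DEConfig | None = None,
    *,
    cross_term: bool = False,
) -> ThresholdVector:
    """Maximize the Tsallis objective with DE/rand/1/bin.

    Genomes are real vectors of length ``m`` kept inside the gray-level
    bounds; before each evaluation a genome is sorted and rounded to
    integers. Selection is greedy, so the best-so-far objective is
    non-decreasing across generations. The run is deterministic under a
    fixed ``de_cfg.seed`` and stops early once the best objective has been
    stable for ``early_stop_patience`` consecutive generations.
    """
    params = params if params is not None else TsallisParams()
    de_cfg = de_cfg if de_cfg is not None else DEConfig()
    m = params.m
    np_size = de_cfg.resolve_np(m)
    # Restrict the search box to [min_occ - 1, max_occ]: a threshold below
    # min_occ - 1 induces the same partition as one at min_occ - 1 (empty
    # bottom class), and one above max_occ the same as at max_occ (empty top
    # class), so the optimum is unchanged while the search space can shrink
    # dramatically on narrow histograms.
    occ = hist.occupied_levels()
    lo, hi = float(de_cfg.lower), float(de_cfg.upper)
    if occ.size:
        lo = float(max(de_cfg.lower, int(occ[0]) - 1))
        hi = float(min(de_cfg.upper, int(occ[-1])))
    if hi <= lo:
        lo, hi = float(de_cfg.lower), float(de_cfg.upper)
    rng = np.random.default_rng(de_cfg.seed)
    ev = TsallisEvaluator(hist, params.gamma)

    def decode(pop: np.ndarray) -> np.ndarray:
        return np.rint(np.sort(pop, axis=1)).astype(np.int64)

    pop = rng.uniform(lo, hi, size=(np_size, m))
    fitness = ev.objective_batch(decode(pop), cross_term=cross_term)

    trace: list[float] = [float(fitness.max())]
    stale = 0
    f, cr = de_cfg.weighting_factor, de_cfg.crossover_prob
    for _ in range(de_cfg.generations):
        idx = np.arange(np_size)
        r1 = np.empty(np_size, dtype=np.int64)
        r2 = np.empty(np_size, dtype=np.int64)
        r3 = np.empty(np_size, dtype=np.int64)
        for i in range(np_size):
            choices = rng.choice(np_size - 1, size=3, replace=False)
            choices = np.where(choices >= i, choices + 1, choices)
            r1[i], r2[i], r3[i] = choices
        mutant = pop[r1] + f * (pop[r2] - pop[r3])
        np.clip(mutant, lo, hi, out=mutant)
        cross = rng.random((np_size, m)) < cr
        forced = rng.integers(0, m, size=np_size)  # one guaranteed mutant gene
        cross[idx, forced] = True
        trial = np.where(cross, mutant, pop)
        trial_fit = ev.objective_batch(decode(trial), cross_term=cross_term)
        improved = trial_fit >= fitness
        pop = np.where(improved[:, None], trial, pop)
        new_fit = np.where(improved, trial_fit, fitness)
        best_prev = float(fitness.max())
        fitness = new_fit
        best_now = float(fitness.max())
        trace.append(best_now)
        if best_now - best_prev < 1e-12:
            stale += 1
            if stale >= de_cfg.early_stop_patience:
                break
        else:
            stale = 0

    best_idx = int(np.argmax(fitness))
    best = decode(pop[best_idx : best_idx + 1])[0]
    return ThresholdVector(
        values=tuple(int(v) for v in best),
        objective=float(fitness[best_idx]),
        trace=tuple(trace),
    )


def aggregate_threshold(tv: ThresholdVector) -> float:
    """Mean of the three largest thresholds (multiset semantics)."""
    if tv.m < 3:
        raise ValidationError(f"aggregation needs at least 3 thresholds, got {tv.m}")
    top3 = sorted(tv.values, reverse=True)[:3]
    return float(sum(top3)) / 3.0


def binarize(img: GrayImage, t_a: float) -> BinaryMask:
    """Foreground = quantized intensity strictly above ``t_a``."""
    return BinaryMask(pixels=img.quantized() > t_a, role="segmentation")
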
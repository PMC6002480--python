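"""Independent brute-force reference implementations used only by tests.

Everything here is written as plainly as possible — explicit Python loops,
full enumeration — and deliberately shares no code path with the package's
vectorised implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from treemingle.pattern import MarkedPointPattern, SizeClassScheme, Window


def brute_weight(window: Window, dx: float, dy: float) -> float:
    a, b = window.a, window.b
    return (a * b) / ((a - abs(dx)) * (b - abs(dy)))


def brute_knn(pattern: MarkedPointPattern, i: int, k: int) -> list[int]:
    """Exhaustive all-pairs sort with (distance, id) key."""
    pos = list(pattern.ids).index(i)
    cands = []
    for j in range(pattern.n):
        if j == pos:
            continue
        d = math.hypot(
            pattern.x[j] - pattern.x[pos], pattern.y[j] - pattern.y[pos]
        )
        cands.append((d, int(pattern.ids[j])))
    cands.sort()
    return [tid for _, tid in cands[:k]]


def brute_pair_sums(
    pattern: MarkedPointPattern, r_values: np.ndarray, ref_mask=None
):
    """(num, den) cumulative pair sums by naive double loop."""
    n = pattern.n
    if ref_mask is None:
        ref_mask = [True] * n
    num = np.zeros(len(r_values))
    den = np.zeros(len(r_values))
    for i in range(n):
        if not ref_mask[i]:
            continue
        for j in range(n):
            if j == i:
                continue
            d = math.hypot(
                pattern.x[i] - pattern.x[j], pattern.y[i] - pattern.y[j]
            )
            w = brute_weight(
                pattern.window,
                pattern.x[i] - pattern.x[j],
                pattern.y[i] - pattern.y[j],
            )
            het = float(pattern.species[i] != pattern.species[j])
            for ri, r in enumerate(r_values):
                if d <= r:
                    num[ri] += het * w
                    den[ri] += w
    return num, den


def brute_K_m(pattern: MarkedPointPattern, r_values: np.ndarray) -> np.ndarray:
    num, _ = brute_pair_sums(pattern, r_values)
    lam = pattern.n / pattern.window.area
    return num / (lam**2 * pattern.window.area)


def brute_k_m(
    pattern: MarkedPointPattern, r_values: np.ndarray, ref_mask=None
) -> np.ndarray:
    num, den = brute_pair_sums(pattern, r_values, ref_mask)
    out = np.full(len(r_values), np.nan)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def brute_expected_mingling(
    pattern: MarkedPointPattern, class_mask
) -> float:
    n = pattern.n
    n_d = int(np.sum(class_mask))
    total = 0.0
    for sp in set(pattern.species):
        n_i = int(np.sum(pattern.species == sp))
        n_di = int(np.sum(pattern.species[class_mask] == sp))
        total += n_di * (n - n_i)
    return total / (n_d * (n - 1))


def exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p by full enumeration of group assignments.

    Valid for tie-free pooled samples.  Uses the Mann-Whitney U statistic
    and the two-sided convention p = min(1, 2 * min(P(U <= u), P(U >= u))).
    """
    pooled = sorted(list(a) + list(b))
    na = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    us = []
    for combo in itertools.combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in combo]
        rest = set(range(len(pooled))) - set(combo)
        gb = [pooled[i] for i in rest]
        us.append(sum(1 for x in ga for y in gb if x > y))
    us = np.array(us)
    p_lo = np.mean(us <= u_obs)
    p_hi = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_lo, p_hi))


def random_pattern(
    rng: np.random.Generator,
    n: int,
    n_species: int = 3,
    window: Window | None = None,
) -> MarkedPointPattern:
    """Uniform random locations with random species and dbh marks."""
    w = window or Window(0, 0, 100, 100)
    return MarkedPointPattern(
        x=rng.uniform(w.xmin, w.xmax, n),
        y=rng.uniform(w.ymin, w.ymax, n),
        species=np.array(
            [f"sp{j}" for j in rng.integers(0, n_species, n)], dtype=object
        ),
        dbh=rng.uniform(5.5, 60.0, n),
        window=w,
    )
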
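"""Seed-length / error-tolerance mathematics behind the step-down strategy.

With non-overlapping tiling seeds of length ``n``, a read of length at least
``n*(f+1)`` that carries at most ``f`` substitutions always retains one clean
seed (pigeonhole), so its true location is guaranteed to surface as a
candidate.  Longer seeds are exponentially more specific — an ``n``-nt seed
has on average ``N / 4**n`` exact matches in a genome of size ``N`` — which is
what makes starting at 14 nt and stepping down only for the residual unmapped
reads fast: each step of +6 in seed length cuts expected hits 4096-fold.

``miss_rate_given_f`` quantifies the residual risk above the pigeonhole bound:
the probability, over uniformly random placements of ``f`` distinct
substituted positions, that *every* seed of the read carries at least one
error.  The seed set used here is exactly the mapper's (tiling seeds plus one
end-anchored seed), so theory and implementation are mutually consistent.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import binom


def seed_offsets(read_len: int, seed_len: int) -> list[int]:
    """Seed start offsets: non-overlapping tiles 0, n, 2n, ... plus one
    end-anchored seed when the read length is not a multiple of n."""
    if seed_len < 1:
        raise ValueError("seed_len must be >= 1")
    if read_len < seed_len:
        return []
    offsets = list(range(0, read_len - seed_len + 1, seed_len))
    end = read_len - seed_len
    if offsets[-1] != end:
        offsets.append(end)
    return offsets


def max_guaranteed_errors(read_len: int, seed_len: int) -> int:
    """Largest substitution count f with read_len >= seed_len * (f + 1)."""
    if read_len < seed_len:
        raise ValueError(f"read length {read_len} < seed length {seed_len}")
    return read_len // seed_len - 1


def _union_size(intervals: list[tuple[int, int]]) -> int:
    total = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    total += cur_e - cur_s
    return total


def miss_rate_given_f(
    read_len: int,
    seed_len: int,
    f: int,
    method: str = "auto",
    n_samples: int = 200_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Probability that every seed of the read contains >= 1 of ``f``
    substitution errors placed uniformly at random (distinct positions).

    ``method``: 'exact' (inclusion-exclusion over seed subsets), 'mc'
    (Monte Carlo), or 'auto' (exact unless the seed set is very large).
    Returns 0 whenever f is within the pigeonhole guarantee.
    """
    if not 0 <= f <= read_len:
        raise ValueError("f must satisfy 0 <= f <= read length")
    offs = seed_offsets(read_len, seed_len)
    if not offs:
        return 1.0  # no seed can be taken: the read is always missed
    if f <= max_guaranteed_errors(read_len, seed_len):
        return 0.0
    if method == "auto":
        method = "exact" if len(offs) <= 20 else "mc"
    if method == "exact":
        return _miss_rate_exact(read_len, seed_len, f, offs)
    if method == "mc":
        return _miss_rate_mc(read_len, seed_len, f, offs, n_samples, rng)
    raise ValueError(f"unknown method {method!r}")


def _miss_rate_exact(L: int, n: int, f: int, offs: list[int]) -> float:
    # P(some seed clean) by inclusion-exclusion over subsets of seeds;
    # a subset is clean iff no error falls in the union of its intervals.
    intervals = [(o, o + n) for o in offs]
    total = comb(L, f)
    p_any_clean = 0.0
    for k in range(1, len(intervals) + 1):
        sign = 1 if k % 2 == 1 else -1
        for sub in combinations(intervals, k):
            u = _union_size(list(sub))
            if L - u >= f:
                p_any_clean += sign * comb(L - u, f) / total
    return 1.0 - p_any_clean


def _miss_rate_mc(
    L: int,
    n: int,
    f: int,
    offs: list[int],
    n_samples: int,
    rng: np.random.Generator | None,
) -> float:
    rng = rng if rng is not None else np.random.default_rng(0)
    offs_a = np.asarray(offs)
    hits = 0
    batch = 10_000
    done = 0
    while done < n_samples:
        b = min(batch, n_samples - done)
        # f distinct positions per trial via argpartition of random keys
        keys = rng.random((b, L))
        pos = np.argpartition(keys, f - 1, axis=1)[:, :f]
        # seed s is clean iff no error position lands in [off, off+n)
        in_seed = (pos[:, None, :] >= offs_a[None, :, None]) & (
            pos[:, None, :] < (offs_a + n)[None, :, None]
        )
        seed_dirty = in_seed.any(axis=2)  # (b, n_seeds)
        hits += int(seed_dirty.all(axis=1).sum())
        done += b
    return hits / n_samples


def expected_seed_hits(genome_size: float, seed_len: int) -> float:
    """Mean exact-match count of a random seed in an i.i.d. genome: N / 4^n."""
    if genome_size < 1:
        raise ValueError("genome size must be >= 1")
    return genome_size / 4.0**seed_len


def predicted_mappable_fraction(read_len: int, p: float, max_errors: int) -> float:
    """P(Binomial(L, p) <= E): the fraction of reads whose substitution count
    fits the error allowance — an upper envelope for mapper sensitivity."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    return float(binom.cdf(max_errors, read_len, p))
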
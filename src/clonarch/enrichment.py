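"""Permutation test for clonal/subclonal enrichment of a gene or arm event.

For an event carrying ``n = n_clonal + n_subclonal`` mutations, ``n`` labels
are repeatedly drawn without replacement from the cohort-wide pool of
clonality labels and the drawn clonal count is compared with the observed
one (comparing counts at fixed n is order-isomorphic to comparing the
clonal/subclonal ratio and avoids division by zero).  The default tail
convention is ``>=`` with the add-one correction p = (b+1)/(B+1), which
guarantees a valid (conservative) p-value; the raw ``>=`` frequency (the
unbiased Monte-Carlo tail estimate), the literal ``>`` convention and an
exactly-uniform randomized tie-break are available as flags.  Both tails
(clonal and subclonal enrichment) are reported with BH-FDR across events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = ["EnrichmentResult", "permutation_enrichment", "enrichment_table", "fdr_adjust"]


@dataclass
class EnrichmentResult:
    event_id: str
    n_clonal: int
    n_subclonal: int
    p_clonal: float
    p_subclonal: float
    n_permutations: int
    fdr_clonal: float = float("nan")
    fdr_subclonal: float = float("nan")


def _draw_counts(pool: np.ndarray, n: int, n_permutations: int, rng) -> np.ndarray:
    """Clonal counts of ``n_permutations`` draws of size n without replacement."""
    tiled = np.tile(pool, (n_permutations, 1))
    rng.permuted(tiled, axis=1, out=tiled)
    return tiled[:, :n].sum(axis=1)


def _tail_p(draws: np.ndarray, observed: int, tie_break: str, rng) -> float:
    B = len(draws)
    if tie_break == "ge_plus_one":
        return (int((draws >= observed).sum()) + 1) / (B + 1)
    if tie_break == "ge":
        # raw frequency: the unbiased Monte-Carlo estimate of the >= tail
        return int((draws >= observed).sum()) / B
    if tie_break == "gt":
        return int((draws > observed).sum()) / B
    if tie_break == "randomized":
        # exactly uniform under the null for discrete statistics
        g = int((draws > observed).sum())
        e = int((draws == observed).sum())
        u = rng.uniform()
        return (g + u * (e + 1)) / (B + 1)
    raise ValueError(f"unknown tie_break {tie_break!r}")


def permutation_enrichment(
    n_clonal: int,
    n_subclonal: int,
    pool_labels,
    n_permutations: int = 10_000,
    seed: int | np.random.Generator = 0,
    tie_break: str = "ge_plus_one",
    event_id: str = "",
) -> EnrichmentResult:
    """Permutation p-values for clonal and subclonal enrichment of one event.

    ``pool_labels`` is the cohort pool of clonality labels, as a boolean
    array / sequence where True (or "clonal") marks a clonal mutation.
    """
    n = n_clonal + n_subclonal
    if n == 0:
        raise ValueError("event has no mutations")
    pool = np.asarray(
        [x == "clonal" if isinstance(x, str) else bool(x) for x in pool_labels], dtype=np.int8
    )
    if len(pool) < n:
        raise ValueError(f"pool size {len(pool)} smaller than event size {n}")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    single_class = pool.min() == pool.max()
    if single_class:
        warnings.warn("cohort pool contains a single clonality class")
    draws = _draw_counts(pool, n, n_permutations, rng)
    p_clonal = _tail_p(draws, n_clonal, tie_break, rng)
    p_subclonal = _tail_p(-draws, -(n_clonal), tie_break, rng)  # subclonal tail: fewer clonal
    if single_class:
        if pool[0] == 1:
            p_clonal = 1.0
        else:
            p_subclonal = 1.0
    return EnrichmentResult(
        event_id=event_id,
        n_clonal=n_clonal,
        n_subclonal=n_subclonal,
        p_clonal=float(p_clonal),
        p_subclonal=float(p_subclonal),
        n_permutations=n_permutations,
    )


def enrichment_table(
    event_counts: pd.DataFrame,
    pool_labels,
    n_permutations: int = 10_000,
    seed: int = 0,
    tie_break: str = "ge_plus_one",
) -> pd.DataFrame:
    """Run the permutation test for every event and FDR-adjust both tails.

    ``event_counts`` needs columns event_id, n_clonal, n_subclonal.
    """
    rng = np.random.default_rng(seed)
    results = [
        permutation_enrichment(
            int(r.n_clonal),
            int(r.n_subclonal),
            pool_labels,
            n_permutations=n_permutations,
            seed=rng,
            tie_break=tie_break,
            event_id=str(r.event_id),
        )
        for r in event_counts.itertuples(index=False)
    ]
    df = pd.DataFrame(
        [
            (r.event_id, r.n_clonal, r.n_subclonal, r.p_clonal, r.p_subclonal, r.n_permutations)
            for r in results
        ],
        columns=["event_id", "n_clonal", "n_subclonal", "p_clonal", "p_subclonal", "n_permutations"],
    )
    df["fdr_clonal"] = fdr_adjust(df["p_clonal"].to_numpy())
    df["fdr_subclonal"] = fdr_adjust(df["p_subclonal"].to_numpy())
    return df


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (R's p.adjust, method 'fdr')."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]
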
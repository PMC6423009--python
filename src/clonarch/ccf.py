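"""Cancer cell fraction (CCF) estimation and clonal/subclonal classification.

The CCF of a somatic SNV is estimated from its read counts with a binomial
likelihood.  A mutation present in a fraction ``c`` of tumor cells at
multiplicity ``m`` (mutant copies per carrying cell) in a region of tumor
total copy number ``q_t``, in a specimen of purity ``p``, has expected
variant allele fraction

    E[VAF] = c * p * m / (p * q_t + 2 * (1 - p)).

A uniform prior is placed on ``c`` over the full range compatible with
VAF <= 1, i.e. up to ``c_max = (p*q_t + 2*(1-p)) / (p*m)``; the posterior is
evaluated on a 0.01-spaced grid and the mass falling above ``c = 1``
(sampling fluctuations of a fully clonal mutation push the raw estimate past
1) is folded into the top reported grid point, so the reported posterior
lives on [0.01, 1] and sums to 1.  The point estimate is the posterior mean
clamped to <= 1.

An event is *clonal* when the posterior probability of CCF >= 0.95 exceeds
0.5, and *subclonal* otherwise — the same rule is applied to SNVs and
copy-number events throughout the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import MutationRecord, SamplePurity, SegmentRecord

__all__ = [
    "CCFPosterior",
    "ClonalityCall",
    "FilterReport",
    "default_grid",
    "filter_snvs",
    "exclude_low_purity",
    "estimate_multiplicity",
    "ccf_posterior",
    "call_clonality",
    "call_mutations",
    "exclude_multihit_genes",
    "gene_level_calls",
    "CLONAL_CCF_THRESHOLD",
    "CLONAL_PROB_THRESHOLD",
]

# An event is clonal iff P(CCF >= CLONAL_CCF_THRESHOLD) > CLONAL_PROB_THRESHOLD
# (strict inequality at the probability threshold).
CLONAL_CCF_THRESHOLD = 0.95
CLONAL_PROB_THRESHOLD = 0.5

GRID_STEP = 0.01


def default_grid(n_points: int = 100) -> np.ndarray:
    """The reported CCF grid: 0.01, 0.02, ..., 1.00."""
    return np.arange(1, n_points + 1) / n_points


@dataclass
class CCFPosterior:
    """Posterior over CCF on a fixed grid spanning (0, 1]."""

    grid: np.ndarray
    probabilities: np.ndarray
    point_estimate: float
    prob_ge_095: float

    def __post_init__(self):
        s = float(np.sum(self.probabilities))
        if not np.isclose(s, 1.0, atol=1e-9):
            raise ValueError(f"posterior probabilities sum to {s}, not 1")


@dataclass
class ClonalityCall:
    event_id: str
    sample_id: str
    ccf: float
    clonality: str  # "clonal" | "subclonal"
    multiplicity: int
    prob_ge_095: float = float("nan")


@dataclass
class FilterReport:
    """Counts of SNVs rejected per filter rule (a row may trip several)."""

    n_input: int = 0
    n_kept: int = 0
    low_tumor_depth: int = 0
    low_normal_depth: int = 0
    high_normal_alt: int = 0
    low_tumor_vaf: int = 0
    high_normal_vaf: int = 0

    def as_dict(self) -> dict[str, int]:
        return self.__dict__.copy()


def filter_snvs(
    records,
    min_depth: int = 10,
    max_normal_alt: int = 2,
    min_tumor_vaf: float = 0.10,
    max_normal_vaf: float = 0.02,
) -> tuple[list[MutationRecord], FilterReport]:
    """Apply the four read-support filters to somatic SNVs.

    Keeps records with tumor and germline depth >= 10x, at most two variant
    reads in the germline, tumor VAF >= 10% and germline VAF <= 2%.
    """
    kept = []
    rep = FilterReport(n_input=len(records))
    for r in records:
        ok = True
        if r.tumor_depth < min_depth:
            rep.low_tumor_depth += 1
            ok = False
        if r.normal_depth < min_depth:
            rep.low_normal_depth += 1
            ok = False
        if r.normal_alt_count > max_normal_alt:
            rep.high_normal_alt += 1
            ok = False
        if r.tumor_vaf < min_tumor_vaf:
            rep.low_tumor_vaf += 1
            ok = False
        if r.normal_vaf > max_normal_vaf:
            rep.high_normal_vaf += 1
            ok = False
        if ok:
            kept.append(r)
    rep.n_kept = len(kept)
    return kept, rep


def exclude_low_purity(
    purities: list[SamplePurity],
    min_purity: float = 0.20,
    mutation_sample_ids=None,
) -> list[str]:
    """Sample ids with purity >= ``min_purity`` ("below 20%" excluded).

    If ``mutation_sample_ids`` is given, every sample carrying mutations must
    have a purity entry; a missing one is an error naming the sample.
    """
    known = {p.sample_id for p in purities}
    if mutation_sample_ids is not None:
        missing = sorted(set(mutation_sample_ids) - known)
        if missing:
            raise ValueError(f"samples with mutations but no purity entry: {', '.join(missing)}")
    return [p.sample_id for p in purities if p.purity >= min_purity]


def estimate_multiplicity(vaf: float, purity: float, q_t: int) -> int | None:
    """Point estimate of mutant-allele multiplicity, clamped to [1, q_t].

    Returns None (with a warning) for q_t == 0: an SNV cannot be carried by a
    homozygously deleted site and the event is skipped.
    """
    if q_t == 0:
        warnings.warn("SNV in homozygous-deleted region (q_t=0); event skipped")
        return None
    if not (0 < purity <= 1):
        raise ValueError(f"purity {purity} outside (0,1]")
    if q_t < 1:
        raise ValueError("q_t must be >= 1")
    m = round(vaf * (purity * q_t + (1 - purity) * 2) / purity)
    return int(min(max(m, 1), q_t))


def _likelihood_on_grid(alt, depth, purity, q_t, m, grid):
    vaf = grid * purity * m / (purity * q_t + (1 - purity) * 2.0)
    return stats.binom.pmf(alt, depth, np.clip(vaf, 0.0, 1.0))


def ccf_posterior(
    alt: int,
    depth: int,
    purity: float,
    q_t: int = 2,
    m: int = 1,
    grid: np.ndarray | None = None,
) -> CCFPosterior:
    """Grid posterior over the CCF of one SNV (see module docstring).

    The likelihood is evaluated on the extended grid up to ``c_max`` (where
    the expected VAF reaches 1); super-clonal mass is folded into the top
    reported point and the point estimate is clamped to <= 1.
    """
    if alt > depth:
        raise ValueError("alt > depth")
    if m < 1:
        raise ValueError("m must be >= 1")
    if grid is None:
        grid = default_grid()
    denom = purity * q_t + (1 - purity) * 2.0
    v1 = purity * m / denom  # expected VAF at c = 1
    if v1 > 1.0 + 1e-12:
        raise ValueError(f"expected VAF {v1:.3f} > 1 at CCF=1: inconsistent multiplicity m={m}")
    c_max = 1.0 / v1
    step = float(grid[1] - grid[0])
    ext_grid = np.arange(1, int(np.floor(c_max / step + 1e-9)) + 1) * step
    like = _likelihood_on_grid(alt, depth, purity, q_t, m, ext_grid)
    total = like.sum()
    if total <= 0:
        raise ValueError("degenerate likelihood (all grid points have zero mass)")
    post_ext = like / total
    point = float(min(np.dot(post_ext, ext_grid), 1.0))
    prob_ge = float(post_ext[ext_grid >= CLONAL_CCF_THRESHOLD - 1e-12].sum())
    # fold super-clonal mass into the top reported grid point
    n = len(grid)
    probs = post_ext[:n].copy()
    if len(post_ext) > n:
        probs[-1] += post_ext[n:].sum()
    return CCFPosterior(grid=grid, probabilities=probs, point_estimate=point, prob_ge_095=prob_ge)


def call_clonality(posterior: CCFPosterior, event_id: str = "", sample_id: str = "", m: int = 1) -> ClonalityCall:
    """Clonal iff P(CCF >= 0.95) strictly exceeds 0.5; subclonal otherwise."""
    label = "clonal" if posterior.prob_ge_095 > CLONAL_PROB_THRESHOLD else "subclonal"
    return ClonalityCall(
        event_id=event_id,
        sample_id=sample_id,
        ccf=posterior.point_estimate,
        clonality=label,
        multiplicity=m,
        prob_ge_095=posterior.prob_ge_095,
    )


def _qt_lookup(segments_by_sample, sample_id, chromosome, position) -> int:
    for seg in segments_by_sample.get(sample_id, ()):
        if seg.chromosome == chromosome and seg.start <= position <= seg.end:
            return seg.total_copy_number
    return 2  # copy-neutral default when no segment covers the site


def call_mutations(
    mutations,
    purities: list[SamplePurity],
    segments: list[SegmentRecord] | None = None,
) -> pd.DataFrame:
    """Estimate CCF and clonality for every mutation of every sample.

    Returns one row per mutation: sample_id, gene, chromosome, position,
    effect, vaf, multiplicity, ccf, prob_ge_095, clonality.  Mutations in
    homozygous-deleted regions are skipped with a warning.
    """
    pur = {p.sample_id: p for p in purities}
    segs: dict[str, list[SegmentRecord]] = {}
    for s in segments or ():
        segs.setdefault(s.sample_id, []).append(s)
    rows = []
    for r in mutations:
        if r.sample_id not in pur:
            raise ValueError(f"no purity entry for sample {r.sample_id}")
        p = pur[r.sample_id].purity
        q_t = _qt_lookup(segs, r.sample_id, r.chromosome, r.position)
        m = estimate_multiplicity(r.tumor_vaf, p, q_t)
        if m is None:
            continue
        post = ccf_posterior(r.tumor_alt_count, r.tumor_depth, p, q_t, m)
        call = call_clonality(post, event_id=r.gene, sample_id=r.sample_id, m=m)
        rows.append(
            (
                r.sample_id,
                r.gene,
                r.chromosome,
                r.position,
                r.effect,
                r.tumor_vaf,
                m,
                call.ccf,
                call.prob_ge_095,
                call.clonality,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "gene",
            "chromosome",
            "position",
            "effect",
            "vaf",
            "multiplicity",
            "ccf",
            "prob_ge_095",
            "clonality",
        ],
    )


def exclude_multihit_genes(calls: pd.DataFrame) -> pd.DataFrame:
    """Drop all SNVs of any gene with >= 2 non-silent SNVs in one patient.

    Silent SNVs do not count toward the trigger, but every SNV of a
    triggered (sample, gene) pair is removed from gene-level analysis.
    """
    ns = calls[calls["effect"] == "non_silent"]
    counts = ns.groupby(["sample_id", "gene"]).size()
    multihit = set(counts[counts >= 2].index)
    if not multihit:
        return calls.copy()
    mask = [
        (s, g) not in multihit for s, g in zip(calls["sample_id"], calls["gene"])
    ]
    return calls[mask].copy()


def gene_level_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """One clonality call per (sample, gene): the non-silent SNV of the gene.

    Assumes multi-hit genes were excluded, so at most one non-silent SNV per
    (sample, gene) remains; raises otherwise.
    """
    ns = calls[calls["effect"] == "non_silent"]
    dup = ns.groupby(["sample_id", "gene"]).size()
    if (dup >= 2).any():
        bad = dup[dup >= 2].index[0]
        raise ValueError(
            f"multiple non-silent SNVs remain for sample {bad[0]}, gene {bad[1]}; "
            "run exclude_multihit_genes first"
        )
    out = ns[["sample_id", "gene", "ccf", "prob_ge_095", "clonality"]].copy()
    return out.rename(columns={"gene": "event_id"}).reset_index(drop=True)
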
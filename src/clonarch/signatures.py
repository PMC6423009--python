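"""Mutational signature extraction over the 96 trinucleotide channels.

Single-base substitutions are folded onto the pyrimidine strand (mutated
base C or T) and binned by their 5'/3' flanking bases into the standard 96
channels, ordered by substitution class (C>A, C>G, C>T, T>A, T>C, T>G) and
then alphabetically by flanks, with labels like ``A[C>T]G``.

Signatures are extracted by alternating nonnegative least squares NMF of the
channels x samples count matrix.  Each alternating update is an exact
block-coordinate minimizer (HALS column/row updates), so the Frobenius
objective is non-increasing across iterations; multiple random restarts are
run and the best reconstruction is kept.  The number of processes is chosen
by a bootstrap-stability procedure: mutation catalogs are resampled, the
pooled bootstrap signatures are clustered by k-means on cosine distance, and
the minimum per-cluster silhouette width ("stability") must stay high while
the reconstruction error keeps decreasing.

Clonal-vs-subclonal enrichment of each signature is tested by refitting
exposures on the clonal and subclonal strata (nonnegative least squares) and
applying a two-sided Fisher exact test to the attributed mutation counts,
FDR-adjusted across signatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CONTEXT_CHANNELS",
    "context_channel",
    "build_context_matrix",
    "SignatureSet",
    "extract_signatures",
    "select_n_processes",
    "match_reference",
    "refit_exposures",
    "signature_clonality_enrichment",
    "cosine_similarity",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTIONS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]

CONTEXT_CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in "ACGT"
    for three in "ACGT"
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CONTEXT_CHANNELS)}


def context_channel(ref: str, alt: str, five_prime: str, three_prime: str) -> str | None:
    """The 96-channel label of a substitution, folded to the pyrimidine strand.

    Purine-reference mutations are reverse-complemented (flanks swap and
    complement).  Returns None with a warning for ambiguous (non-ACGT) bases.
    """
    ref, alt = ref.upper(), alt.upper()
    five_prime, three_prime = five_prime.upper(), three_prime.upper()
    bases = (ref, alt, five_prime, three_prime)
    if any(b not in _COMPLEMENT for b in bases):
        warnings.warn(f"ambiguous base in context {bases}; mutation dropped")
        return None
    if ref == alt:
        raise ValueError("ref equals alt")
    if ref in "AG":  # fold to pyrimidine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        five_prime, three_prime = _COMPLEMENT[three_prime], _COMPLEMENT[five_prime]
    return f"{five_prime}[{ref}>{alt}]{three_prime}"


def build_context_matrix(mutations, sample_ids=None, stratum: str = "all") -> pd.DataFrame:
    """96 x samples count matrix from mutation records (or a calls frame).

    ``mutations`` is an iterable of objects/rows exposing sample_id,
    ref_allele, alt_allele, context_5p, context_3p.  Mutations with missing
    or ambiguous context are dropped with a warning.
    """
    if sample_ids is None:
        seen = []
        for m in mutations:
            if m.sample_id not in seen:
                seen.append(m.sample_id)
        sample_ids = seen
    col = {s: j for j, s in enumerate(sample_ids)}
    mat = np.zeros((96, len(sample_ids)), dtype=int)
    for m in mutations:
        if m.sample_id not in col:
            continue
        if m.context_5p is None or m.context_3p is None:
            warnings.warn(f"mutation without flanking context in {m.sample_id}; dropped")
            continue
        ch = context_channel(m.ref_allele, m.alt_allele, m.context_5p, m.context_3p)
        if ch is None:
            continue
        mat[_CHANNEL_INDEX[ch], col[m.sample_id]] += 1
    df = pd.DataFrame(mat, index=list(CONTEXT_CHANNELS), columns=list(sample_ids))
    df.attrs["stratum"] = stratum
    return df


@dataclass
class SignatureSet:
    """Extracted signatures (96 x k, columns sum to 1) and exposures (k x n)."""

    k: int
    signatures: pd.DataFrame
    exposures: pd.DataFrame
    reconstruction_error: float  # relative Frobenius error
    objective_history: list = field(default_factory=list, repr=False)
    stability: pd.Series | None = None
    rank_deficient: bool = False


def _hals_nmf(V, k, rng, max_iter, tol):
    """Exact block-coordinate alternating NNLS; returns (W, H, history)."""
    p, n = V.shape
    scale = np.sqrt(V.mean() / max(k, 1))
    W = rng.uniform(0.0, 1.0, size=(p, k)) * scale + 1e-6
    H = rng.uniform(0.0, 1.0, size=(k, n)) * scale + 1e-6
    norm_v2 = float((V * V).sum())
    history = []
    prev = np.inf
    for _ in range(max_iter):
        # update W columns
        HHt = H @ H.T
        VHt = V @ H.T
        for j in range(k):
            denom = HHt[j, j]
            if denom <= 1e-12:
                W[:, j] = 1e-6
                continue
            w = W[:, j] + (VHt[:, j] - W @ HHt[:, j]) / denom
            W[:, j] = np.maximum(w, 0.0)
        # update H rows
        WtW = W.T @ W
        WtV = W.T @ V
        for j in range(k):
            denom = WtW[j, j]
            if denom <= 1e-12:
                H[j, :] = 1e-6
                continue
            h = H[j, :] + (WtV[j, :] - WtW[j, :] @ H) / denom
            H[j, :] = np.maximum(h, 0.0)
        obj = norm_v2 - 2.0 * float((WtV * H).sum()) + float((WtW * (H @ H.T)).sum())
        obj = max(obj, 0.0)
        history.append(obj)
        if np.isfinite(prev) and prev - obj <= tol * max(prev, 1e-30):
            break
        prev = obj
    return W, H, history


def extract_signatures(
    matrix: pd.DataFrame,
    k: int,
    n_restarts: int = 50,
    max_iter: int = 2000,
    tol: float = 1e-8,
    seed: int | np.random.Generator = 0,
) -> SignatureSet:
    """Alternating-least-squares NMF of a 96 x samples count matrix.

    The best of ``n_restarts`` random initializations is kept; signature
    columns are normalized to sum 1 with exposures rescaled compensatorily.
    """
    V = matrix.to_numpy(dtype=float)
    if V.shape[0] != 96:
        raise ValueError("context matrix must have 96 rows")
    if k < 1 or k > min(96, V.shape[1]):
        raise ValueError(f"k={k} outside feasible range")
    if not (V > 0).any():
        raise ValueError("context matrix has no nonzero entry")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    best = None
    for _ in range(n_restarts):
        W, H, hist = _hals_nmf(V, k, rng, max_iter, tol)
        obj = hist[-1]
        if best is None or obj < best[3]:
            best = (W, H, hist, obj)
    W, H, hist, obj = best
    rank_deficient = k > np.linalg.matrix_rank(V)
    if rank_deficient:
        warnings.warn(f"k={k} exceeds the numerical rank of the matrix; result flagged")
    colsum = W.sum(axis=0)
    colsum[colsum == 0] = 1.0
    W = W / colsum
    H = H * colsum[:, None]
    err = float(np.linalg.norm(V - W @ H) / max(np.linalg.norm(V), 1e-30))
    names = [f"S{i + 1}" for i in range(k)]
    return SignatureSet(
        k=k,
        signatures=pd.DataFrame(W, index=matrix.index, columns=names),
        exposures=pd.DataFrame(H, index=names, columns=matrix.columns),
        reconstruction_error=err,
        objective_history=hist,
        rank_deficient=rank_deficient,
    )


def _bootstrap_catalog(V: np.ndarray, rng) -> np.ndarray:
    """Resample each sample's mutation catalog with replacement."""
    out = np.zeros_like(V)
    for j in range(V.shape[1]):
        n = int(V[:, j].sum())
        if n == 0:
            continue
        p = V[:, j] / n
        out[:, j] = rng.multinomial(n, p)
    return out


def select_n_processes(
    matrix: pd.DataFrame,
    k_range=range(1, 6),
    n_bootstrap: int = 100,
    n_restarts: int = 1,
    max_iter: int = 500,
    tol: float = 1e-6,
    stability_threshold: float = 0.85,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose the number of mutational processes by bootstrap stability.

    For each k, ``n_bootstrap`` resampled catalogs are factorized, the pooled
    signatures are clustered into k groups by k-means on cosine distance and
    scored by silhouette width.  ``stability`` is the minimum per-cluster
    mean silhouette (for k=1, the mean pairwise cosine of the bootstrap
    signatures).  The chosen k* is the largest k whose stability reaches
    ``stability_threshold`` while the mean reconstruction error has not
    increased relative to the previous k.
    """
    ks = sorted(k_range)
    V = matrix.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for k in ks:
        sigs = []
        errs = []
        for _ in range(n_bootstrap):
            Vb = _bootstrap_catalog(V, rng)
            if not (Vb > 0).any():
                warnings.warn("empty bootstrap catalog discarded")
                continue
            fit = extract_signatures(
                pd.DataFrame(Vb, index=matrix.index, columns=matrix.columns),
                k,
                n_restarts=n_restarts,
                max_iter=max_iter,
                tol=tol,
                seed=rng,
            )
            sigs.append(fit.signatures.to_numpy().T)  # k rows of 96
            errs.append(fit.reconstruction_error)
        X = np.vstack(sigs)
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        Xn = X / norms
        if k == 1:
            gram = Xn @ Xn.T
            n = len(Xn)
            stability = float((gram.sum() - n) / max(n * (n - 1), 1))
            mean_sil = np.nan
        else:
            km = KMeans(n_clusters=k, n_init=10, random_state=int(rng.integers(2**31)))
            labels = km.fit_predict(Xn)
            if len(np.unique(labels)) < k:
                warnings.warn(f"degenerate clustering at k={k}")
                stability, mean_sil = -1.0, np.nan
            else:
                sil = silhouette_samples(Xn, labels, metric="cosine")
                per_cluster = [sil[labels == c].mean() for c in np.unique(labels)]
                stability = float(min(per_cluster))
                mean_sil = float(sil.mean())
        rows.append((k, stability, mean_sil, float(np.mean(errs))))
    report = pd.DataFrame(rows, columns=["k", "stability", "mean_silhouette", "reconstruction_error"])
    k_star = ks[0]
    prev_err = np.inf
    for _, r in report.iterrows():
        if r["stability"] >= stability_threshold and r["reconstruction_error"] <= prev_err + 1e-9:
            k_star = int(r["k"])
        prev_err = r["reconstruction_error"]
    return k_star, report


def cosine_similarity(u, v) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def match_reference(
    signatures: pd.DataFrame,
    reference,
    unmatched_below: float = 0.80,
) -> pd.DataFrame:
    """Best cosine match of each extracted signature among reference columns.

    Both matrices must use the same 96-channel ordering (no silent
    reordering).  Reports cosine and Pearson similarity to the best match
    and flags matches with cosine below ``unmatched_below``.
    """
    ref = reference.frame if hasattr(reference, "frame") else reference
    if list(signatures.index) != list(ref.index):
        raise ValueError("channel order mismatch between signatures and reference")
    rows = []
    for name in signatures.columns:
        v = signatures[name].to_numpy()
        sims = {rn: cosine_similarity(v, ref[rn].to_numpy()) for rn in ref.columns}
        best = max(sims, key=sims.get)
        pear = float(stats.pearsonr(v, ref[best].to_numpy()).statistic)
        rows.append((name, best, sims[best], pear, sims[best] < unmatched_below))
    return pd.DataFrame(rows, columns=["signature", "best_match", "cosine", "pearson", "unmatched"])


def refit_exposures(matrix: pd.DataFrame, signatures: pd.DataFrame, rescale: bool = True) -> pd.DataFrame:
    """Nonnegative least-squares exposure refit of a catalog onto signatures.

    With ``rescale`` the attributed counts of each sample are rescaled to sum
    to the sample's total mutation count.
    """
    S = signatures.to_numpy(dtype=float)
    out = np.zeros((S.shape[1], matrix.shape[1]))
    V = matrix.to_numpy(dtype=float)
    for j in range(V.shape[1]):
        e, _ = optimize.nnls(S, V[:, j])
        tot = V[:, j].sum()
        if rescale and e.sum() > 0:
            e = e / e.sum() * tot
        out[:, j] = e
    return pd.DataFrame(out, index=signatures.columns, columns=matrix.columns)


def signature_clonality_enrichment(
    clonal_matrix: pd.DataFrame,
    subclonal_matrix: pd.DataFrame,
    signatures: pd.DataFrame,
) -> pd.DataFrame:
    """Fisher test of each signature's contribution to clonal vs subclonal SNVs.

    Each stratum's pooled catalog is attributed to signatures by NNLS refit;
    per signature the 2x2 table (this signature vs the others) x (clonal vs
    subclonal) is tested two-sided, with BH-FDR across signatures.  Returns
    NA rows when a stratum is empty.
    """
    names = list(signatures.columns)
    n_clonal = float(clonal_matrix.to_numpy().sum())
    n_subclonal = float(subclonal_matrix.to_numpy().sum())
    if n_clonal == 0 or n_subclonal == 0:
        return pd.DataFrame(
            {
                "signature": names,
                "clonal_count": np.nan,
                "subclonal_count": np.nan,
                "odds_ratio": np.nan,
                "p_value": np.nan,
                "fdr": np.nan,
                "enriched_in": "NA",
            }
        )
    pooled_c = clonal_matrix.sum(axis=1).to_frame("clonal")
    pooled_s = subclonal_matrix.sum(axis=1).to_frame("subclonal")
    e_c = refit_exposures(pooled_c, signatures)["clonal"]
    e_s = refit_exposures(pooled_s, signatures)["subclonal"]
    counts_c = np.rint(e_c.to_numpy()).astype(int)
    counts_s = np.rint(e_s.to_numpy()).astype(int)
    rows = []
    for i, name in enumerate(names):
        table = [
            [counts_c[i], counts_c.sum() - counts_c[i]],
            [counts_s[i], counts_s.sum() - counts_s[i]],
        ]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        frac_c = counts_c[i] / max(counts_c.sum(), 1)
        frac_s = counts_s[i] / max(counts_s.sum(), 1)
        side = "clonal" if frac_c > frac_s else ("subclonal" if frac_s > frac_c else "none")
        rows.append((name, counts_c[i], counts_s[i], odds, p, side))
    df = pd.DataFrame(
        rows, columns=["signature", "clonal_count", "subclonal_count", "odds_ratio", "p_value", "enriched_in"]
    )
    df["fdr"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    return df[["signature", "clonal_count", "subclonal_count", "odds_ratio", "p_value", "fdr", "enriched_in"]]
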
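"""Single-sample rank-based signature scoring and the PBM score.

The statistic is a signed Kolmogorov-Smirnov-type running-sum computed on
each sample independently.  Genes are ranked by expression (descending,
lexicographic tie-break); walking down the ranking, F(i) is the fraction of
signature genes seen by position i and B(i) the fraction of background
(non-signature) genes seen.  The raw enrichment score is F(i*) - B(i*) at
the position i* of maximum |F - B| (earliest such position on ties), so it
lies in [-1, 1]: +1 when every signature gene outranks every background
gene, -1 for perfect bottom separation.

Raw scores are made comparable across samples and signature sizes by a
permutation z-score: signature positions are placed uniformly at random in
the ranking (or all placements are enumerated when feasible) and
z = (es_raw - mean_null) / sd_null.  Because the unweighted null depends
only on (universe size, signature size), it is computed once per size pair
and shared across samples.

The PBM (plasma-cell-malignancy) score is the sign-flipped plasma-signature
z-score, so that higher PBM = more perturbed plasma-marker expression =
higher malignancy.  An optional weight exponent ``alpha`` >= 0 applied to
|expression - sample median| switches on an expression-magnitude-weighted
variant of the foreground running sum (default 0 = unweighted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import comb

from .io import ExpressionMatrix, GeneSignature, SignatureScoreTable

logger = logging.getLogger(__name__)

#: Exhaustive permutation-null enumeration is used when the number of
#: distinct signature placements C(universe, signature) is at most this.
EXHAUSTIVE_LIMIT = 10_000

#: Default number of Monte-Carlo permutations for the null.
DEFAULT_N_PERM = 1_000

#: A signature must retain at least this many genes in the expression
#: universe for scoring to proceed (config-exposed).
DEFAULT_MIN_GENES = 5


@dataclass(frozen=True)
class EnrichmentResult:
    """Raw and permutation-normalised enrichment of one signature in one sample."""

    es_raw: float
    z: float
    n_perm: int
    n_signature_in_universe: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.es_raw <= 1.0 + 1e-12:
            raise ValueError(f"es_raw out of [-1, 1]: {self.es_raw}")
        if self.n_signature_in_universe < 1:
            raise ValueError("signature has no genes in universe")


def rank_sample(values: np.ndarray, gene_ids) -> np.ndarray:
    """Order genes by expression, descending; ties break by ascending
    lexicographic gene identifier (deterministic)."""
    values = np.asarray(values, dtype=float)
    gene_ids = np.asarray(gene_ids)
    if values.shape[0] != gene_ids.shape[0]:
        raise ValueError("values and gene_ids length mismatch")
    if values.shape[0] < 2:
        raise ValueError("ranking needs at least 2 genes")
    if not np.isfinite(values).all():
        raise ValueError("non-finite expression value in sample")
    # np.lexsort: last key is primary.
    order = np.lexsort((gene_ids, -values))
    return gene_ids[order]


def enrichment_statistic(
    order, signature: GeneSignature, weights: np.ndarray | None = None
) -> float:
    """Signed running-sum enrichment of ``signature`` in a gene ranking.

    ``weights``, if given, weight the foreground increments (one weight per
    position in ``order``); the background walk stays uniform.
    """
    order = np.asarray(order)
    n = order.shape[0]
    hits = np.isin(order, list(signature.genes))
    m = int(hits.sum())
    if m < 1:
        raise ValueError(f"signature {signature.name!r} has no genes in the universe")
    if m >= n:
        raise ValueError(
            f"signature {signature.name!r} covers the whole universe; "
            "background undefined"
        )
    if weights is None:
        fwd = hits.astype(float)
    else:
        weights = np.asarray(weights, dtype=float)
        fwd = np.where(hits, weights, 0.0)
        if fwd[hits].sum() <= 0:
            fwd = hits.astype(float)  # degenerate weights: fall back to uniform
    f = np.cumsum(fwd) / fwd.sum()
    b = np.cumsum(~hits) / (n - m)
    d = f - b
    i_star = int(np.argmax(np.abs(d)))  # argmax returns the earliest maximum
    return float(d[i_star])


def _es_from_positions(pos: np.ndarray, n: int, m: int) -> np.ndarray:
    """Enrichment scores for many signature placements at once.

    ``pos`` is (n_placements, m) of sorted 0-based hit positions.  The
    running sum F - B is piecewise linear with breakpoints only at hit
    positions, so the earliest position of maximum |F - B| is found among
    2m candidates per placement: the value just before each hit and at it.
    """
    n_b = n - m
    k = np.arange(1, m + 1, dtype=float)
    # value at position pos_k (just before hit k enters): F=(k-1)/m,
    # B=(pos_k - (k-1))/n_b  -- valid only when pos_k >= 1
    d_pre = (k - 1.0) / m - (pos - (k - 1.0)) / n_b
    d_hit = k / m - (pos + 1.0 - k) / n_b  # value at position pos_k + 1
    # interleave so candidates are in ascending running-sum position; argmax
    # then realises the earliest-position tie-break
    cand = np.empty((pos.shape[0], 2 * m))
    cand[:, 0::2] = d_pre
    cand[:, 1::2] = d_hit
    valid = np.ones_like(cand, dtype=bool)
    valid[:, 0::2] = pos >= 1  # "before hit at position 0" is not a position
    absd = np.where(valid, np.abs(cand), -1.0)
    idx = np.argmax(absd, axis=1)
    return cand[np.arange(pos.shape[0]), idx]


def null_distribution(
    order_size: int,
    signature_size: int,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator | None = None,
    exhaustive: bool | None = None,
) -> np.ndarray:
    """Null enrichment scores for random signature placements.

    Enumerates all C(order_size, signature_size) placements when that count
    is <= EXHAUSTIVE_LIMIT (or when ``exhaustive=True``); otherwise draws
    ``n_perm`` placements uniformly without replacement within each draw.
    """
    n, m = int(order_size), int(signature_size)
    if not 1 <= m < n:
        raise ValueError(f"need 1 <= signature_size < order_size, got {m}, {n}")
    n_placements = comb(n, m, exact=True)
    if exhaustive is None:
        exhaustive = n_placements <= EXHAUSTIVE_LIMIT
    if exhaustive:
        if n_placements > EXHAUSTIVE_LIMIT:
            raise ValueError(
                f"{n_placements} placements exceed the exhaustive limit"
            )
        pos = np.array(list(combinations(range(n), m)), dtype=float)
        return _es_from_positions(pos, n, m)
    if n_perm < 100:
        raise ValueError("Monte-Carlo mode requires n_perm >= 100")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pos = np.empty((n_perm, m))
    for i in range(n_perm):
        pos[i] = np.sort(rng.choice(n, size=m, replace=False))
    return _es_from_positions(pos, n, m)


def permutation_normalize(
    es_raw: float,
    order_size: int,
    signature_size: int,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator | None = None,
    null: np.ndarray | None = None,
) -> EnrichmentResult:
    """Normalise a raw enrichment score against the placement null.

    z = (es_raw - mean_null) / sd_null, with the population standard
    deviation of the null.  A zero-spread null is degenerate and an error.
    A precomputed ``null`` array (from :func:`null_distribution`) may be
    supplied to share one null across samples.
    """
    if null is None:
        null = null_distribution(order_size, signature_size, n_perm, seed)
    mean = float(np.mean(null))
    sd = float(np.std(null))
    if sd == 0.0:
        raise ValueError("degenerate permutation null (sd = 0)")
    z = (float(es_raw) - mean) / sd
    return EnrichmentResult(
        es_raw=float(es_raw),
        z=z,
        n_perm=len(null),
        n_signature_in_universe=signature_size,
    )


def _restrict_signature(
    matrix: ExpressionMatrix, signature: GeneSignature, min_genes: int
) -> GeneSignature:
    present = signature.genes & set(matrix.gene_ids)
    dropped = len(signature.genes) - len(present)
    if dropped:
        logger.info(
            "signature %r: dropped %d/%d genes absent from the matrix",
            signature.name,
            dropped,
            len(signature.genes),
        )
    if not present:
        raise ValueError(
            f"signature {signature.name!r} has no genes in the expression matrix"
        )
    if len(present) < min_genes:
        raise ValueError(
            f"signature {signature.name!r} retains {len(present)} genes in the "
            f"matrix, below the minimum of {min_genes}"
        )
    return GeneSignature(signature.name, frozenset(present))


def score_signature(
    matrix: ExpressionMatrix,
    signature: GeneSignature,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = 0,
    min_genes: int = DEFAULT_MIN_GENES,
    alpha: float = 0.0,
) -> pd.Series:
    """Permutation-normalised signature score for every sample in a matrix.

    Each sample is ranked, the running-sum statistic computed and
    z-normalised.  With ``alpha`` = 0 (default, unweighted) the null depends
    only on (universe size, signature size) and is shared across samples;
    with ``alpha`` > 0 the foreground is weighted by
    |expression - sample median|**alpha and the null permutes gene labels
    per sample.
    """
    sig = _restrict_signature(matrix, signature, min_genes)
    genes = np.asarray(matrix.gene_ids)
    values = matrix.values
    n, m = len(genes), len(sig.genes)
    rng = np.random.default_rng(seed)

    out = np.empty(matrix.n_samples)
    if alpha == 0.0:
        null = null_distribution(n, m, n_perm=n_perm, seed=rng)
        for j in range(matrix.n_samples):
            order = rank_sample(values[:, j], genes)
            es = enrichment_statistic(order, sig)
            out[j] = permutation_normalize(es, n, m, null=null).z
    else:
        for j in range(matrix.n_samples):
            col = values[:, j]
            order_idx = np.lexsort((genes, -col))
            order = genes[order_idx]
            w = np.abs(col - np.median(col)) ** alpha
            w_ordered = w[order_idx]
            es = enrichment_statistic(order, sig, weights=w_ordered)
            null = np.empty(n_perm)
            hit_template = np.zeros(n, dtype=bool)
            hit_template[:m] = True
            for p in range(n_perm):
                perm_pos = rng.choice(n, size=m, replace=False)
                perm_genes = frozenset(order[perm_pos])
                null[p] = enrichment_statistic(
                    order, GeneSignature(sig.name, perm_genes), weights=w_ordered
                )
            out[j] = permutation_normalize(es, n, m, null=null).z
    return pd.Series(out, index=matrix.sample_ids, name=signature.name)


def score_signatures(
    matrix: ExpressionMatrix,
    signatures: list[GeneSignature],
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = 0,
    min_genes: int = DEFAULT_MIN_GENES,
    alpha: float = 0.0,
) -> pd.DataFrame:
    """Score several signatures, sharing the per-sample ranking.

    Returns a samples x signatures DataFrame of z-scores.
    """
    if not signatures:
        raise ValueError("no signatures given")
    names = [s.name for s in signatures]
    if len(set(names)) < len(names):
        raise ValueError("duplicate signature names")
    if alpha != 0.0:
        cols = {
            s.name: score_signature(matrix, s, n_perm, seed, min_genes, alpha)
            for s in signatures
        }
        return pd.DataFrame(cols, index=matrix.sample_ids)

    sigs = [_restrict_signature(matrix, s, min_genes) for s in signatures]
    genes = np.asarray(matrix.gene_ids)
    values = matrix.values
    n = len(genes)
    rng = np.random.default_rng(seed)
    nulls = {}
    for sig in sigs:
        m = len(sig.genes)
        if m not in nulls:
            nulls[m] = null_distribution(n, m, n_perm=n_perm, seed=rng)

    # Rank each sample once; reuse the ordering across signatures.
    out = np.empty((matrix.n_samples, len(sigs)))
    hit_masks = [np.isin(genes, list(sig.genes)) for sig in sigs]
    for j in range(matrix.n_samples):
        order_idx = np.lexsort((genes, -values[:, j]))
        for k, sig in enumerate(sigs):
            hits = hit_masks[k][order_idx]
            m = len(sig.genes)
            f = np.cumsum(hits) / m
            b = np.cumsum(~hits) / (n - m)
            d = f - b
            es = d[int(np.argmax(np.abs(d)))]
            null = nulls[m]
            out[j, k] = (es - null.mean()) / null.std()
    return pd.DataFrame(out, index=matrix.sample_ids, columns=[s.name for s in sigs])


def compute_pbm(
    score_table: pd.DataFrame,
    plasma_signature_name: str,
    higher_is_malignant: bool = True,
) -> SignatureScoreTable:
    """Derive the PBM score from a per-signature z-score table.

    The PBM score is the sign-flipped plasma-cell signature z-score, so a
    depressed plasma-marker programme (negative enrichment) maps to a high
    PBM.  ``higher_is_malignant=False`` disables the flip.
    """
    if plasma_signature_name not in score_table.columns:
        raise ValueError(
            f"plasma signature {plasma_signature_name!r} not in score table "
            f"(have: {list(score_table.columns)})"
        )
    z_plasma = score_table[plasma_signature_name]
    pbm = -z_plasma if higher_is_malignant else z_plasma.copy()
    pbm.name = "PBM"
    return SignatureScoreTable(
        scores=score_table.copy(),
        pbm=pbm,
        plasma_signature=plasma_signature_name,
    )
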
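"""Synthetic cohorts with known ground truth for every pipeline stage.

The central object is a latent per-sample malignancy level lambda in
[0, 1].  Lambda perturbs (predominantly depresses) plasma-marker expression
in the tumor compartment, drives the survival hazard, orders the disease
stages Healthy -> MGUS -> SMM -> NDMM -> RRMM, raises mutation probability
and burden, and tilts the immune composition of the paired whole bone
marrow (granulocytes and resting NK down, CD8 T cells up).  Every generator
is a pure function of its parameters and seed.

Default sizes loosely mirror the cohorts the method targets: a 762-patient
newly-diagnosed cohort and a 358-patient MGUS cohort with 39 progressors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import ClinicalTable, ExpressionMatrix, GeneSignature, MutationTable

logger = logging.getLogger(__name__)

STAGE_THRESHOLDS = (0.1, 0.3, 0.5, 0.7)
STAGE_NAMES = ("Healthy", "MGUS", "SMM", "NDMM", "RRMM")


@dataclass
class SimTruth:
    """Ground-truth record of one simulated cohort."""

    lam: np.ndarray  # latent malignancy per sample, in [0, 1]
    params: dict
    seed: int
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        lam = np.asarray(self.lam, dtype=float)
        if (lam < 0).any() or (lam > 1).any():
            raise ValueError("lambda must lie in [0, 1]")
        if not all(np.isfinite(v) for v in self.params.values() if np.isscalar(v)):
            raise ValueError("non-finite generator parameter")
        object.__setattr__(self, "lam", lam)


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(n)]


def generate_expression(
    n_samples: int,
    n_genes: int = 2000,
    n_markers: int = 50,
    delta: float = 2.0,
    noise_sd: float = 0.5,
    lam=None,
    seed: int = 0,
    frac_up: float = 0.2,
) -> tuple[ExpressionMatrix, SimTruth, GeneSignature]:
    """Simulate a CD138+ log2 expression matrix with perturbed plasma markers.

    Background genes draw per-gene means mu_g ~ Normal(6, 1.5) on the log2
    scale with Normal(0, noise_sd) sample noise.  Marker genes sit at
    baseline +2 over background and shift by -lambda_s * delta per sample
    (a ``frac_up`` fraction of markers shifts +lambda_s * delta instead,
    modelling two-sided perturbation).  ``lam`` defaults to Uniform(0, 1).
    """
    if not 0 < n_markers < n_genes:
        raise ValueError("need 0 < n_markers < n_genes")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    rng = np.random.default_rng(seed)
    if lam is None:
        lam = rng.uniform(0.0, 1.0, size=n_samples)
    lam = np.asarray(lam, dtype=float)
    if lam.shape[0] != n_samples:
        raise ValueError("lam length must equal n_samples")
    genes = [f"G{i:05d}" for i in range(n_genes)]
    markers = genes[:n_markers]
    n_up = int(round(frac_up * n_markers))
    mu = rng.normal(6.0, 1.5, size=n_genes)
    mu[:n_markers] += 2.0  # marker baseline over background
    shift_sign = np.zeros(n_genes)
    shift_sign[:n_markers] = -1.0
    if n_up:
        up_idx = rng.choice(n_markers, size=n_up, replace=False)
        shift_sign[up_idx] = 1.0
    values = (
        mu[:, None]
        + shift_sign[:, None] * delta * lam[None, :]
        + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    )
    ids = _sample_ids(n_samples)
    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=ids))
    truth = SimTruth(
        lam=lam,
        params={
            "n_genes": n_genes,
            "n_markers": n_markers,
            "delta": delta,
            "noise_sd": noise_sd,
            "frac_up": frac_up,
        },
        seed=seed,
        sample_ids=ids,
    )
    signature = GeneSignature("PlasmaB", frozenset(markers))
    return matrix, truth, signature


def generate_survival(
    truth: SimTruth,
    beta: float = np.log(1.72),
    baseline_rate: float = 0.02,
    censor_frac: float = 0.3,
    seed: int = 0,
    extra_log_hazard=None,
    group_contrast: bool = False,
) -> pd.DataFrame:
    """Exponential survival times driven by the latent malignancy.

    T ~ Exponential(rate * exp(beta * x_s)) where x_s is lambda (default)
    or, with ``group_contrast=True``, the indicator lambda > median(lambda)
    so that ``beta`` is exactly the high/low group log hazard ratio.
    ``extra_log_hazard`` adds an arbitrary per-sample log-hazard term.
    Censoring is independent Uniform(0, c_max) with c_max calibrated so the
    realised expected censoring fraction matches ``censor_frac``.
    """
    if baseline_rate <= 0:
        raise ValueError("baseline rate must be positive")
    if not 0.0 <= censor_frac < 1.0:
        raise ValueError("censor_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    lam = truth.lam
    x = (lam > np.median(lam)).astype(float) if group_contrast else lam
    eta = beta * x
    if extra_log_hazard is not None:
        eta = eta + np.asarray(extra_log_hazard, dtype=float)
    rate = baseline_rate * np.exp(eta)
    t = rng.exponential(1.0 / rate)
    if censor_frac == 0.0:
        times, events = t, np.ones_like(t, dtype=int)
    else:
        # P(censored | T) under C ~ U(0, c_max) is min(T / c_max, 1);
        # calibrate c_max so the average censoring probability hits target.
        def mean_censored(c_max):
            return float(np.mean(np.minimum(t / c_max, 1.0))) - censor_frac

        lo, hi = t.min() * 1e-6 + 1e-12, t.max() * 1e6
        if mean_censored(hi) > 0:
            raise ValueError("target censoring fraction unattainable")
        c_max = brentq(mean_censored, lo, hi)
        c = rng.uniform(0.0, c_max, size=t.shape)
        events = (t <= c).astype(int)
        times = np.minimum(t, c)
    return pd.DataFrame(
        {"os_time": times, "os_event": events},
        index=truth.sample_ids or _sample_ids(len(lam)),
    )


def generate_stages(truth: SimTruth, thresholds=STAGE_THRESHOLDS) -> pd.Series:
    """Ordered disease stage per sample: the count of thresholds below
    lambda, mapped onto Healthy/MGUS/SMM/NDMM/RRMM."""
    thresholds = tuple(thresholds)
    if list(thresholds) != sorted(thresholds) or len(set(thresholds)) != len(thresholds):
        raise ValueError("thresholds must be strictly increasing")
    if len(thresholds) != len(STAGE_NAMES) - 1:
        raise ValueError(f"need {len(STAGE_NAMES) - 1} thresholds")
    idx = np.searchsorted(np.asarray(thresholds), truth.lam, side="left")
    labels = pd.Categorical(
        [STAGE_NAMES[i] for i in idx], categories=list(STAGE_NAMES), ordered=True
    )
    return pd.Series(labels, index=truth.sample_ids or _sample_ids(len(truth.lam)))


def generate_mutations(
    truth: SimTruth,
    genes: dict[str, tuple[float, float]] | None = None,
    tmb_coupling: tuple[float, float] = (1.0, 1.5),
    n_dummy_genes: int = 200,
    seed: int = 0,
) -> MutationTable:
    """Somatic mutation records with lambda-coupled carriers and burden.

    ``genes`` maps driver gene name -> (logit intercept a, slope b); each
    sample carries the gene with probability logistic(a + b * lambda).
    Additional nonsynonymous events per sample follow
    Poisson(exp(c + d * lambda)) with (c, d) = ``tmb_coupling``, spread
    uniformly over dummy gene names.
    """
    if genes is None:
        genes = {"TP53": (-2.5, 3.0), "MUC16": (-2.0, 2.5), "NRAS": (-1.5, 0.0)}
    rng = np.random.default_rng(seed)
    lam = truth.lam
    ids = np.asarray(truth.sample_ids or _sample_ids(len(lam)))
    records = []
    for gene, (a, b) in genes.items():
        p = 1.0 / (1.0 + np.exp(-(a + b * lam)))
        carriers = rng.random(len(lam)) < p
        for s in ids[carriers]:
            records.append((s, gene, "Missense_Mutation"))
    c, d = tmb_coupling
    counts = rng.poisson(np.exp(c + d * lam))
    dummy = [f"PASS{i:04d}" for i in range(n_dummy_genes)]
    for s, k in zip(ids, counts):
        for g in rng.choice(dummy, size=k, replace=True):
            records.append((s, g, "Missense_Mutation"))
    df = pd.DataFrame(records, columns=["sample_id", "gene", "variant_classification"])
    return MutationTable(df)


DEFAULT_CELL_TYPES = (
    "PlasmaB",
    "NaiveB",
    "MemoryB",
    "CD8T",
    "CD4T",
    "NKResting",
    "NKActivated",
    "Neutrophil",
    "MastCell",
    "Eosinophil",
    "Monocyte",
    "M1Macrophage",
    "M2Macrophage",
    "DendriticCell",
    "Osteoblast",
    "Osteoclast",
)

#: Per-cell-type multiplicative tilt of the Dirichlet concentration with
#: lambda: CD8 T up; granulocytes and resting NK down.
DEFAULT_COUPLING = {
    "CD8T": 2.0,
    "NKResting": -2.0,
    "Neutrophil": -2.0,
    "MastCell": -1.5,
    "Eosinophil": -1.5,
}


def make_cell_signatures(
    cell_types=DEFAULT_CELL_TYPES, genes_per_type: int = 25
) -> list[GeneSignature]:
    """Disjoint synthetic marker sets, one per immune cell type."""
    sigs = []
    for i, name in enumerate(cell_types):
        genes = frozenset(
            f"MK_{name}_{j:03d}" for j in range(genes_per_type)
        )
        sigs.append(GeneSignature(name, genes))
    return sigs


def generate_wbm(
    truth: SimTruth,
    cell_signatures: list[GeneSignature] | None = None,
    coupling: dict[str, float] | None = None,
    k_planted_clusters: int = 5,
    cluster_boost: float = 6.0,
    base_concentration: float = 4.0,
    marker_shift: float = 4.0,
    noise_sd: float = 0.3,
    n_background_genes: int = 400,
    seed: int = 0,
):
    """Whole-bone-marrow expression as a fraction-weighted mixture of
    cell-type archetypes, with planted composition clusters and
    lambda-tilted fractions.

    Each archetype over-expresses its own signature genes by
    ``marker_shift`` log2 units over a flat baseline.  Sample fractions are
    Dirichlet draws whose concentration combines a per-cluster boost of a
    distinct cell-type subset (separation controlled by ``cluster_boost``)
    with an exp(coupling * (lambda - 1/2)) tilt.  Returns the WBM
    ExpressionMatrix, planted cluster labels and the true fraction matrix.
    """
    if cell_signatures is None:
        cell_signatures = make_cell_signatures()
    if coupling is None:
        coupling = dict(DEFAULT_COUPLING)
    n_types = len(cell_signatures)
    if not 1 <= k_planted_clusters <= n_types:
        raise ValueError("invalid number of planted clusters")
    rng = np.random.default_rng(seed)
    lam = truth.lam
    n = len(lam)
    ids = truth.sample_ids or _sample_ids(n)
    names = [s.name for s in cell_signatures]
    coup = np.array([coupling.get(t, 0.0) for t in names])

    # planted clusters: each boosts a distinct pair of cell types
    clusters = rng.integers(0, k_planted_clusters, size=n)
    boosts = np.ones((k_planted_clusters, n_types))
    for j in range(k_planted_clusters):
        picked = [(2 * j) % n_types, (2 * j + 1) % n_types]
        boosts[j, picked] = cluster_boost
    alpha = (
        base_concentration
        * boosts[clusters]
        * np.exp(coup[None, :] * (lam[:, None] - 0.5))
    )
    fractions = np.vstack([rng.dirichlet(a) for a in alpha])

    genes = sorted(set().union(*(s.genes for s in cell_signatures)))
    genes += [f"BG_{i:04d}" for i in range(n_background_genes)]
    gene_index = {g: i for i, g in enumerate(genes)}
    archetypes = np.full((n_types, len(genes)), 4.0)
    for t, sig in enumerate(cell_signatures):
        for g in sig.genes:
            archetypes[t, gene_index[g]] += marker_shift
    values = fractions @ archetypes + rng.normal(0.0, noise_sd, size=(n, len(genes)))
    matrix = ExpressionMatrix(pd.DataFrame(values.T, index=genes, columns=ids))
    labels = pd.Series(clusters, index=ids, name="planted_cluster")
    frac_df = pd.DataFrame(fractions, index=ids, columns=names)
    return matrix, labels, frac_df


def generate_progression_cohort(
    n: int = 358, n_progressors: int = 39, delta: float = 1.07, seed: int = 0
) -> pd.DataFrame:
    """MGUS-like progression cohort: non-progressor scores ~ Normal(0, 1),
    progressor scores ~ Normal(delta, 1).  The closed-form AUC of such a
    binormal shift is Phi(delta / sqrt(2))."""
    if not 0 < n_progressors < n:
        raise ValueError("need 0 < n_progressors < n")
    rng = np.random.default_rng(seed)
    progressed = np.zeros(n, dtype=int)
    progressed[:n_progressors] = 1
    scores = np.where(
        progressed == 1, rng.normal(delta, 1.0, n), rng.normal(0.0, 1.0, n)
    )
    return pd.DataFrame(
        {"score": scores, "progressed": progressed}, index=_sample_ids(n)
    )


def generate_iss_covariates(n: int, seed: int = 0) -> pd.DataFrame:
    """Staging inputs independent of lambda: B2M (mg/L, log-normal),
    albumin (g/dL, normal), LDH and its upper limit of normal, and
    cytogenetic flags.  Used to give synthetic cohorts a clinically shaped
    ISS distribution whose hazard contribution is separable from the
    malignancy signal."""
    rng = np.random.default_rng(seed)
    b2m = np.exp(rng.normal(1.2, 0.6, size=n))
    albumin = rng.normal(3.8, 0.5, size=n)
    ldh_uln = np.full(n, 250.0)
    ldh = rng.lognormal(5.2, 0.35, size=n)
    flags = {
        "del17p": rng.random(n) < 0.10,
        "t_4_14": rng.random(n) < 0.12,
        "t_14_16": rng.random(n) < 0.04,
        "gain1q": rng.random(n) < 0.30,
    }
    return pd.DataFrame(
        {
            "b2m": b2m,
            "albumin": albumin,
            "ldh": ldh,
            "ldh_uln": ldh_uln,
            "age": rng.normal(63, 9, size=n).round(1),
            "sex": rng.choice(["F", "M"], size=n),
            "race": rng.choice(["White", "Black", "Asian", "Other"], size=n, p=[0.7, 0.18, 0.06, 0.06]),
            **flags,
        },
        index=_sample_ids(n),
    )


def simulate_cohort(
    n_samples: int = 762,
    seed: int = 0,
    beta_lambda: float = np.log(1.72),
    beta_iss: float = 0.35,
    baseline_rate: float = 0.02,
    censor_frac: float = 0.3,
    **expression_kwargs,
):
    """Full myeloma-like cohort: expression + truth + plasma signature,
    clinical table (survival, staging inputs, ISS, stage labels) and a
    mutation table.

    The hazard combines the latent malignancy (log HR ``beta_lambda`` per
    unit lambda) and an independent ISS term (``beta_iss`` per stage above
    I), so a malignancy score carries prognostic signal beyond staging.
    """
    from .survival import stage_iss  # local import to avoid a cycle at import time

    matrix, truth, signature = generate_expression(
        n_samples, seed=seed, **expression_kwargs
    )
    covars = generate_iss_covariates(n_samples, seed=seed + 1)
    iss = stage_iss(covars["b2m"].to_numpy(), covars["albumin"].to_numpy())
    iss.index = covars.index
    surv = generate_survival(
        truth,
        beta=beta_lambda,
        baseline_rate=baseline_rate,
        censor_frac=censor_frac,
        seed=seed + 2,
        extra_log_hazard=beta_iss * (iss.to_numpy() - 1.0),
    )
    stages = generate_stages(truth)
    clin = pd.concat([surv, covars], axis=1)
    clin["iss"] = iss
    clin["stage_label"] = stages.astype(str)
    clinical = ClinicalTable(clin)
    mutations = generate_mutations(truth, seed=seed + 3)
    return {
        "expression": matrix,
        "truth": truth,
        "plasma_signature": signature,
        "clinical": clinical,
        "mutations": mutations,
    }
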
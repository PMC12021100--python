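"""Synthetic two-cluster cohort generator with planted ground truth.

Emulates the statistical structure of a treated-HIV cohort stratified into an
"HC-like" and an "at-risk" group: the cluster signal is strong in the protein
layer, weak in the metabolite layer and absent in the transcript layer; a
small linear-Gaussian driver DAG is planted among proteins; a few cross-layer
correlated modules are driven by shared latent factors; clinical covariates
are drawn at group-specific rates resembling the published cohort table.

Nothing here attempts to simulate assay chemistry (NPX units, LC-MS peak
artifacts, library-size pipelines); only the signal structure the downstream
statistics consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .layers import GeneSetCollection, LayerKind, OmicsLayer, SampleTable

#: per-group categorical covariate rates (HC-like, at-risk), cohort-table-like
DEFAULT_COVARIATE_RATES: dict[str, dict] = {
    "hypertension": {"levels": ["no", "yes"], "p": ([0.60, 0.40], [0.39, 0.61])},
    "central_obesity": {"levels": ["no", "yes"], "p": ([0.43, 0.57], [0.27, 0.73])},
    "ethnicity": {"levels": ["caucasian", "other"], "p": ([0.80, 0.20], [0.94, 0.06])},
    "smoking": {"levels": ["never", "ex", "current"],
                "p": ([0.50, 0.27, 0.23], [0.36, 0.47, 0.17])},
    "fruit_intake": {"levels": ["lt1_month", "gt1_week", "gt1_day"],
                     "p": ([0.14, 0.42, 0.44], [0.01, 0.42, 0.57])},
    "transmission": {"levels": ["msm", "hetero", "other"],
                     "p": ([0.65, 0.26, 0.09], [0.76, 0.17, 0.07])},
    "cad": {"levels": ["normal", "nonobstructive", "obstructive"],
            "p": ([0.57, 0.28, 0.15], [0.41, 0.39, 0.20])},
}


@dataclass
class CohortSpec:
    """Generative parameters for one synthetic cohort."""

    n_per_group: tuple[int, int] = (88, 70)
    n_transcripts: int = 2000
    n_proteins: int = 2500
    n_metabolites: int = 900
    delta_t: float = 0.0      # standardized group shift, transcript log-mean
    delta_p: float = 1.0      # standardized group shift, affected proteins
    delta_m: float = 0.3      # standardized group shift, affected metabolites
    n_affected_t: int = 200
    n_affected_p: int = 500
    n_affected_m: int = 300
    n_drivers: int = 5
    children_per_driver: int = 3
    driver_beta: float = 0.8
    n_modules: int = 2
    module_features_per_layer: int = 10
    module_loading: float = 0.8
    nb_dispersion: float = 0.2
    senescence_sizes: tuple[int, int, int] = (126, 50, 8)
    covariate_rates: dict = field(default_factory=lambda: DEFAULT_COVARIATE_RATES)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_group) < 1:
            raise ValueError("group sizes must be positive")
        if not abs(self.module_loading) < 1:
            raise ValueError("|module_loading| must be < 1 for unit marginal variance")
        for d in (self.delta_t, self.delta_p, self.delta_m):
            if d < 0:
                raise ValueError("group shifts must be >= 0")
        if (self.n_affected_t > self.n_transcripts or self.n_affected_p > self.n_proteins
                or self.n_affected_m > self.n_metabolites):
            raise ValueError("n_affected exceeds layer feature count")


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery testing."""

    labels: list[int]
    affected: dict[str, list[str]]
    drivers: list[str]
    dag_edges: list[tuple[str, str]]
    modules: list[list[str]]
    covariate_rates: dict
    senescence_sets: dict[str, list[str]]

    def to_dict(self) -> dict:
        return asdict(self)


def _gaussian_layer(rng: np.random.Generator, n: int, p: int) -> np.ndarray:
    return rng.standard_normal((n, p))


def _nb_counts(rng: np.random.Generator, log_mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson (negative binomial) draw with var = mu + dispersion*mu^2."""
    mu = np.exp(log_mu)
    if dispersion <= 0:
        return rng.poisson(mu).astype(float)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam).astype(float)


def generate_cohort(spec: CohortSpec) -> dict:
    """Generate the three omics layers, sample metadata and ground truth.

    Returns a dict with keys ``transcriptomics``, ``proteomics``,
    ``metabolomics`` (:class:`OmicsLayer`), ``samples`` (:class:`SampleTable`),
    ``truth`` (:class:`SyntheticTruth`) and ``gene_sets``
    (:class:`GeneSetCollection` of synthetic senescence annotations).
    """
    rng = np.random.default_rng(spec.seed)
    n0, n1 = spec.n_per_group
    n = n0 + n1
    labels = np.array([0] * n0 + [1] * n1)
    group = labels.astype(float)
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]

    t_ids = [f"T{j + 1:04d}" for j in range(spec.n_transcripts)]
    p_ids = [f"P{j + 1:04d}" for j in range(spec.n_proteins)]
    m_ids = [f"M{j + 1:04d}" for j in range(spec.n_metabolites)]

    # --- reserve disjoint protein roles: drivers+children, then modules ---
    n_driver_block = spec.n_drivers * (1 + spec.children_per_driver)
    need = n_driver_block + spec.n_modules * spec.module_features_per_layer
    if need > spec.n_proteins:
        raise ValueError("protein layer too small for planted drivers and modules")
    perm_p = rng.permutation(spec.n_proteins)
    driver_idx = perm_p[: spec.n_drivers]
    child_idx = perm_p[spec.n_drivers: n_driver_block]
    module_p_idx = perm_p[n_driver_block: need]
    free_p = perm_p[need:]

    # --- proteins: Gaussian with group shift on affected features ---
    prot = _gaussian_layer(rng, n, spec.n_proteins)
    affected_p = rng.choice(free_p, size=min(spec.n_affected_p, len(free_p)), replace=False)
    prot[:, affected_p] += spec.delta_p * group[:, None]

    # planted driver DAG: driver -> each of its children, linear-Gaussian
    beta = spec.driver_beta
    dag_edges: list[tuple[str, str]] = []
    for d_i, d in enumerate(driver_idx):
        prot[:, d] = rng.standard_normal(n) + spec.delta_p * group
        for c_i in range(spec.children_per_driver):
            c = child_idx[d_i * spec.children_per_driver + c_i]
            prot[:, c] = beta * prot[:, d] + np.sqrt(1 - beta ** 2) * rng.standard_normal(n)
            dag_edges.append((p_ids[d], p_ids[c]))

    # --- metabolites: Gaussian with weak group shift ---
    metab = _gaussian_layer(rng, n, spec.n_metabolites)
    perm_m = rng.permutation(spec.n_metabolites)
    module_m_idx = perm_m[: spec.n_modules * spec.module_features_per_layer]
    free_m = perm_m[spec.n_modules * spec.module_features_per_layer:]
    affected_m = rng.choice(free_m, size=min(spec.n_affected_m, len(free_m)), replace=False)
    metab[:, affected_m] += spec.delta_m * group[:, None]

    # --- transcripts: negative-binomial counts ---
    base_log_mu = rng.uniform(np.log(5.0), np.log(500.0), size=spec.n_transcripts)
    log_mu = np.tile(base_log_mu, (n, 1))
    perm_t = rng.permutation(spec.n_transcripts)
    module_t_idx = perm_t[: spec.n_modules * spec.module_features_per_layer]
    free_t = perm_t[spec.n_modules * spec.module_features_per_layer:]
    affected_t = rng.choice(free_t, size=min(spec.n_affected_t, len(free_t)), replace=False)
    log_mu[:, affected_t] += spec.delta_t * group[:, None]

    # --- cross-layer modules: one latent factor per module ---
    lam = spec.module_loading
    modules: list[list[str]] = []
    k = spec.module_features_per_layer
    for m_i in range(spec.n_modules):
        f = rng.standard_normal(n)
        members: list[str] = []
        for idx in module_p_idx[m_i * k:(m_i + 1) * k]:
            prot[:, idx] = lam * f + np.sqrt(1 - lam ** 2) * rng.standard_normal(n)
            members.append(p_ids[idx])
        for idx in module_m_idx[m_i * k:(m_i + 1) * k]:
            metab[:, idx] = lam * f + np.sqrt(1 - lam ** 2) * rng.standard_normal(n)
            members.append(m_ids[idx])
        for idx in module_t_idx[m_i * k:(m_i + 1) * k]:
            # counts: latent factor enters the log-mean (rank correlation planted)
            log_mu[:, idx] = base_log_mu[idx] + 0.7 * lam * f
            members.append(t_ids[idx])
        modules.append(members)

    counts = _nb_counts(rng, log_mu, spec.nb_dispersion)

    # --- covariates ---
    cov = pd.DataFrame(index=sample_ids)
    for name, desc in spec.covariate_rates.items():
        levels = desc["levels"]
        draws = np.empty(n, dtype=object)
        for g, p in enumerate(desc["p"]):
            mask = labels == g
            draws[mask] = rng.choice(levels, size=mask.sum(), p=np.asarray(p) / np.sum(p))
        cov[name] = draws
    cov["age"] = np.where(labels == 0, rng.normal(53.5, 8.0, n), rng.normal(54.5, 8.0, n)).round(1)
    cov["beef_intake"] = np.where(labels == 0, rng.poisson(1.9, n), rng.poisson(1.4, n))

    # --- synthetic senescence annotation sets over proteins ---
    sen_sets: dict[str, list[str]] = {}
    affected_pool = [p_ids[i] for i in affected_p] + [p_ids[i] for i in module_p_idx]
    other_pool = [p_ids[i] for i in free_p if p_ids[i] not in set(affected_pool)]
    for name, size in zip(["cellage_like", "csgene_like", "sasp_like"], spec.senescence_sizes):
        n_hit = min(int(round(0.6 * size)), len(affected_pool))
        hit = rng.choice(affected_pool, size=n_hit, replace=False)
        n_miss = min(size - n_hit, len(other_pool))
        miss = rng.choice(other_pool, size=n_miss, replace=False)
        sen_sets[name] = sorted(np.concatenate([hit, miss]).tolist())

    group_names = np.where(labels == 0, "HC-like", "at-risk")
    samples = SampleTable(sample_ids, group_names.tolist(), cov,
                          {c: sorted(cov[c].astype(str).unique()) for c in cov.columns
                           if cov[c].dtype == object})
    truth = SyntheticTruth(
        labels=labels.tolist(),
        affected={
            "transcriptomics": sorted(t_ids[i] for i in affected_t),
            "proteomics": sorted(p_ids[i] for i in affected_p),
            "metabolomics": sorted(m_ids[i] for i in affected_m),
        },
        drivers=[p_ids[i] for i in driver_idx],
        dag_edges=dag_edges,
        modules=modules,
        covariate_rates=spec.covariate_rates,
        senescence_sets=sen_sets,
    )
    return {
        "transcriptomics": OmicsLayer(LayerKind.TRANSCRIPTOMICS, sample_ids, t_ids, counts),
        "proteomics": OmicsLayer(LayerKind.PROTEOMICS, sample_ids, p_ids, prot),
        "metabolomics": OmicsLayer(LayerKind.METABOLOMICS, sample_ids, m_ids, metab),
        "samples": samples,
        "truth": truth,
        "gene_sets": GeneSetCollection(sen_sets, "synthetic-senescence"),
    }


def truth_metrics(predicted, truth, *, kind: str = "labels", universe=None) -> dict:
    """External-validity indices comparing a recovery to planted truth.

    ``kind="labels"``: predicted and truth are partitions (ARI reported).
    ``kind="set"``: predicted and truth are identifier sets (Jaccard,
    sensitivity, precision reported).  When ``universe`` is given both sets
    must be drawn from it; an identifier outside the universe indicates the
    two sets do not share an id domain and is an error.
    """
    if kind == "labels":
        pred = np.asarray(predicted)
        true = np.asarray(truth)
        if len(pred) != len(true):
            raise ValueError("label vectors must have equal length")
        return {"ari": float(adjusted_rand_score(true, pred))}
    pred_set, true_set = set(predicted), set(truth)
    if universe is not None:
        uni = set(universe)
        stray = (pred_set | true_set) - uni
        if stray:
            raise ValueError(f"identifiers outside the shared universe: {sorted(stray)[:5]}")
    inter = len(pred_set & true_set)
    union = len(pred_set | true_set)
    return {
        "jaccard": inter / union if union else float("nan"),
        "sensitivity": inter / len(true_set) if true_set else float("nan"),
        "precision": inter / len(pred_set) if pred_set else float("nan"),
    }
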
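"""Moderated differential abundance with covariate adjustment.

Per-feature ordinary least squares against a design matrix, followed by
empirical-Bayes shrinkage of the residual variances toward a common prior
(the moderated-t construction of limma): the posterior variance is
``s~^2 = (d0*s0^2 + d*s^2) / (d0 + d)`` with the prior degrees of freedom
``d0`` and prior variance ``s0^2`` estimated by method of moments on
``log s^2``.  The moderated t has ``d0 + d`` degrees of freedom.

Three model tiers mirror the study design: (1) unadjusted HC vs PWH,
(2) between clusters, (3) clusters adjusted for ethnicity, smoking, fruit
and beef intake.  Transcript counts pass through a log-CPM transform before
fitting; this is an approximation to a dedicated count model and is
documented as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .layers import GeneSetCollection, OmicsLayer, SampleTable


@dataclass
class DesignMatrix:
    sample_ids: list[str]
    matrix: pd.DataFrame
    contrast_col: str

    def __post_init__(self) -> None:
        X = self.matrix.to_numpy(dtype=float)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # name aliased columns: those whose removal does not lower rank
            aliased = [c for i, c in enumerate(self.matrix.columns)
                       if np.linalg.matrix_rank(np.delete(X, i, axis=1)) == rank]
            raise ValueError(f"rank-deficient design; aliased columns: {aliased}")


#: ordinal covariates encoded as ordered numeric (study Open Question: intake
#: variables are ordinal; encoded 0,1,2,... in level order)
DEFAULT_ORDINAL = {
    "fruit_intake": ["lt1_month", "gt1_week", "gt1_day"],
}


def build_design(samples: SampleTable, labels, covariates: list[str] | None = None,
                 ordinal: dict[str, list[str]] | None = None) -> DesignMatrix:
    """Intercept + group contrast + reference-coded / ordinal covariates."""
    labels = pd.Series(np.asarray(labels), index=samples.sample_ids)
    groups = sorted(labels.unique().tolist())
    if len(groups) != 2:
        raise ValueError("design requires exactly two groups")
    ordinal = {**DEFAULT_ORDINAL, **(ordinal or {})}
    df = pd.DataFrame({"intercept": 1.0}, index=samples.sample_ids)
    df["group"] = (labels == groups[1]).astype(float)
    for cov in covariates or []:
        if samples.covariates is None or cov not in samples.covariates.columns:
            raise KeyError(f"covariate {cov!r} missing from sample table")
        col = samples.covariates[cov]
        if cov in ordinal:
            order = {lv: i for i, lv in enumerate(ordinal[cov])}
            df[cov] = col.astype(str).map(order).astype(float)
        elif np.issubdtype(col.dtype, np.number):
            df[cov] = col.astype(float)
        else:
            levels = sorted(col.astype(str).unique())
            for lv in levels[1:]:  # first observed level is the reference
                df[f"{cov}[{lv}]"] = (col.astype(str) == lv).astype(float)
    return DesignMatrix(list(samples.sample_ids), df, "group")


@dataclass
class ModeratedFit:
    feature_ids: list[str]
    coef: np.ndarray
    t: np.ndarray
    p: np.ndarray
    fdr: np.ndarray
    s2: np.ndarray
    df_residual: float
    d0: float
    s0_2: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.coef, "t": self.t, "p": self.p,
                             "fdr": self.fdr, "s2": self.s2},
                            index=self.feature_ids)


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone for x > 0)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def squeeze_var(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse chi-square prior
    (d0, s0^2) from the observed residual variances."""
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return 0.0, float(np.mean(s2))
    z = np.log(s2[ok])
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1))
    resid = evar - polygamma(1, d / 2.0)
    if resid <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * trigamma_inverse(resid)
    s0_2 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_2


def fit_moderated(layer: OmicsLayer, design: DesignMatrix,
                  contrast: str | None = None, d0_override: float | None = None) -> ModeratedFit:
    """OLS per feature + empirical-Bayes variance moderation.

    ``d0_override=0`` forces ordinary (unmoderated) t statistics.
    """
    contrast = contrast or design.contrast_col
    X = design.matrix.loc[layer.sample_ids].to_numpy(dtype=float)
    Y = layer.values
    n, p = X.shape
    if n <= p:
        raise ValueError("need more samples than design columns")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    d = float(n - p)
    s2 = np.sum(resid ** 2, axis=0) / d
    ci = list(design.matrix.columns).index(contrast)
    coef = beta[ci]
    u = float(xtx_inv[ci, ci])  # unscaled variance of the contrast coefficient
    if d0_override is not None:
        d0 = float(d0_override)
        s0_2 = float(np.mean(s2[s2 > 0])) if np.any(s2 > 0) else 0.0
    else:
        d0, s0_2 = squeeze_var(s2, d)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / np.sqrt(u * s2_post)
    t[~np.isfinite(t)] = 0.0
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(t))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
    # identical groups: zero coefficient and zero residual -> p = 1
    pvals[(coef == 0)] = 1.0
    return ModeratedFit(list(layer.feature_ids), coef, t, pvals, bh_adjust(pvals),
                        s2, d, d0, s0_2)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    NaN inputs propagate as NaN with a warning.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} NaN p-values propagated", stacklevel=2)
    if ok.any():
        if ((p[ok] < 0) | (p[ok] > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def log_cpm(layer: OmicsLayer, prior: float = 0.5) -> OmicsLayer:
    """Counts-per-million log2 transform for transcript count matrices."""
    counts = layer.values
    libsize = counts.sum(axis=1, keepdims=True)
    libsize[libsize == 0] = 1.0
    vals = np.log2((counts + prior) / (libsize + 1.0) * 1e6)
    out = OmicsLayer(layer.layer_kind, list(layer.sample_ids), list(layer.feature_ids), vals)
    return out


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int
    p: float
    fdr: float = float("nan")
    direction: str = "none"
    stat: float = float("nan")


def ora_hypergeometric(query, gene_sets: GeneSetCollection, universe,
                       fdr_threshold: float = 0.2) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation test per set."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query) & universe
    if not query <= universe:  # pragma: no cover
        raise ValueError("query must be a subset of the universe")
    results = []
    for name, members in gene_sets.sets.items():
        mem = set(members) & universe
        if not mem:
            continue
        k = len(query & mem)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(mem), len(query)))
        results.append(EnrichmentResult(name, k, min(1.0, p)))
    fdrs = bh_adjust([r.p for r in results])
    for r, f in zip(results, fdrs):
        r.fdr = float(f)
        r.direction = "over" if f < fdr_threshold else "none"
    return results


def directional_enrichment(feature_stats: dict[str, float], gene_sets: GeneSetCollection,
                           n_perm: int = 1000, seed: int = 0) -> list[EnrichmentResult]:
    """Directional set enrichment on signed statistics (moderated t).

    Per set, the observed mean signed statistic is compared with the null
    distribution obtained by permuting feature labels; the two-sided
    empirical p is (1 + #{|perm mean| >= |observed|}) / (n_perm + 1).
    """
    rng = np.random.default_rng(seed)
    feats = np.array(list(feature_stats.keys()))
    vals = np.array([feature_stats[f] for f in feats], dtype=float)
    results = []
    for name, members in gene_sets.sets.items():
        mask = np.isin(feats, list(members))
        m = int(mask.sum())
        if m == 0:
            warnings.warn(f"set {name!r} has no measured features; skipped", stacklevel=2)
            continue
        obs = float(vals[mask].mean())
        # permute labels = draw m random features per permutation
        perm = np.empty(n_perm)
        for b in range(n_perm):
            perm[b] = vals[rng.choice(len(vals), size=m, replace=False)].mean()
        p = float((1 + np.sum(np.abs(perm) >= abs(obs))) / (n_perm + 1))
        direction = "up" if obs > 0 else ("down" if obs < 0 else "none")
        results.append(EnrichmentResult(name, m, p, direction=direction, stat=obs))
    fdrs = bh_adjust([r.p for r in results])
    for r, f in zip(results, fdrs):
        r.fdr = float(f)
    return results
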
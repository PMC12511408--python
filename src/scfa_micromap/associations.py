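"""Group-level statistics for quantitative traits and feature abundances.

* Quantitative endophenotypes (SCFA, transit, bile acids, ...) are compared
  across the three clinical groups with the Kruskal-Wallis rank test; when
  warranted, pairwise contrasts use Dunn's z on mean ranks with Bonferroni
  correction over the pairs actually tested.
* Per-taxon group differences on the ALR scale (and per-KO differences) use
  ordinary least squares adjusted for covariates (age, sex, BMI by
  convention); no multiplicity correction is applied by default, with
  Bonferroni/Benjamini-Hochberg available as options.
* KO tables are folded into gut-metabolic modules: each module's member KOs
  are tested individually and reported grouped per module.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .compositional import ALRTable
from .errors import CoverageError, DesignError
from .tables import AbundanceTable, CohortMetadata, GMMDefinition


@dataclass
class TraitComparison:
    trait_id: str
    kw_H: float
    kw_p: float
    pairwise: pd.DataFrame  # group_a, group_b, dunn_z, p_raw, p_bonferroni
    degenerate: bool = False  # all values tied/constant


def kruskal_dunn(meta: CohortMetadata, trait_id: str) -> TraitComparison:
    """Kruskal-Wallis across clinical groups plus Dunn pairwise z tests.

    Missing values are excluded for this endpoint.  Dunn's statistic uses
    mean ranks with the usual tie correction; Bonferroni multiplies each
    raw p by the number of pairs tested (capped at 1).
    """
    values = meta.trait(trait_id)
    mask = values.notna()
    values = values[mask].to_numpy(dtype=float)
    labels = meta.group[mask].to_numpy()
    groups = [g for g in pd.unique(labels)]
    samples = [values[labels == g] for g in groups]
    if len(groups) < 2 or any(len(s) < 2 for s in samples):
        raise DesignError("need >= 2 groups with >= 2 non-missing values each")

    if np.ptp(values) == 0:
        pairs = pd.DataFrame(
            [
                (a, b, 0.0, 1.0, 1.0)
                for a, b in combinations(sorted(groups), 2)
            ],
            columns=["group_a", "group_b", "dunn_z", "p_raw", "p_bonferroni"],
        )
        return TraitComparison(trait_id, 0.0, 1.0, pairs, degenerate=True)

    H, kw_p = stats.kruskal(*samples)

    N = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    mean_ranks = {g: ranks[labels == g].mean() for g in groups}
    sizes = {g: int((labels == g).sum()) for g in groups}
    rows = []
    pair_list = list(combinations(sorted(groups), 2))
    m = len(pair_list)
    for a, b in pair_list:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append((a, b, float(z), float(p_raw), float(min(1.0, p_raw * m))))
    pairs = pd.DataFrame(
        rows, columns=["group_a", "group_b", "dunn_z", "p_raw", "p_bonferroni"]
    )
    return TraitComparison(trait_id, float(H), float(kw_p), pairs)


def _design_matrix(
    meta: CohortMetadata, covariates: list[str], contrast: tuple[str, str]
) -> tuple[np.ndarray, list[str], np.ndarray, int]:
    """Intercept + group dummies (reference = contrast[1]) + covariates.

    Returns (X, sample mask as ids, column names, index of the contrast
    coefficient)."""
    g_a, g_b = contrast
    groups = meta.groups_present()
    if g_a not in groups or g_b not in groups:
        raise DesignError(f"contrast groups {contrast} not both present")
    cols: dict[str, np.ndarray] = {}
    labels = meta.group.to_numpy()
    for g in groups:
        if g == g_b:
            continue
        cols[f"group[{g}]"] = (labels == g).astype(float)
    for c in covariates:
        cols[c] = meta.trait(c).to_numpy()
    names = list(cols)
    X = np.column_stack([np.ones(len(labels))] + [cols[c] for c in names])
    names = ["intercept"] + names
    mask = ~np.isnan(X).any(axis=1)
    return X, names, mask, names.index(f"group[{g_a}]")


@dataclass
class AdjustedAssociation:
    feature_id: str
    term: str
    estimate: float
    se: float
    p: float


def _ols_many(
    X: np.ndarray, Y: np.ndarray, coef_ix: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS of every column of Y on X; estimate/se/p of one coefficient."""
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise DesignError("collinear model design")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    dof = n - k
    if dof < 1:
        raise DesignError("no residual degrees of freedom")
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * XtX_inv[coef_ix, coef_ix])
    est = beta[coef_ix]
    # Zero-residual fits (constant response) are degenerate: estimate is
    # numerical noise, the t statistic undefined; flag with p = 1.
    scale = np.abs(Y).max(axis=0) + 1.0
    degenerate = sigma2 <= (1e-14 * scale) ** 2
    est = np.where(degenerate & (np.abs(est) <= 1e-10 * scale), 0.0, est)
    se = np.where(degenerate, 0.0, se)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, est / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.where(degenerate, 1.0, p)
    return est, se, p


def _adjust(p: np.ndarray, method: str | None) -> np.ndarray:
    if method is None:
        return p
    from statsmodels.stats.multitest import multipletests

    mapped = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[method]
    return multipletests(p, method=mapped)[1]


def adjusted_feature_model(
    alr: ALRTable,
    meta: CohortMetadata,
    covariates: list[str],
    contrast: tuple[str, str],
    *,
    adjust: str | None = None,
) -> list[AdjustedAssociation]:
    """Per-feature OLS of ALR abundance on group + covariates.

    Reports the ``contrast`` (e.g. ("IBS-D", "HV")) coefficient with its
    standard error and two-sided t-test p-value.  Following the source
    analysis convention, no multiplicity adjustment is applied unless
    ``adjust`` is "bonferroni" or "bh".
    """
    meta = meta.select_samples(alr.sample_ids)
    X, names, mask, coef_ix = _design_matrix(meta, covariates, contrast)
    Y = alr.values[mask]
    est, se, p = _ols_many(X[mask], Y, coef_ix)
    p = _adjust(p, adjust)
    term = f"{contrast[0]} vs {contrast[1]}"
    return [
        AdjustedAssociation(fid, term, float(e), float(s), float(pv))
        for fid, e, s, pv in zip(alr.feature_ids, est, se, p)
    ]


def trait_feature_model(
    values: pd.DataFrame,
    meta: CohortMetadata,
    covariates: list[str],
    trait_id: str,
    *,
    adjust: str | None = None,
) -> list[AdjustedAssociation]:
    """Per-feature OLS of abundance on a quantitative trait + covariates."""
    meta = meta.select_samples([str(s) for s in values.index])
    cols = [meta.trait(trait_id).to_numpy()] + [
        meta.trait(c).to_numpy() for c in covariates
    ]
    X = np.column_stack([np.ones(values.shape[0])] + cols)
    mask = ~np.isnan(X).any(axis=1)
    est, se, p = _ols_many(X[mask], values.to_numpy(dtype=float)[mask], 1)
    p = _adjust(p, adjust)
    return [
        AdjustedAssociation(str(fid), trait_id, float(e), float(s), float(pv))
        for fid, e, s, pv in zip(values.columns, est, se, p)
    ]


def gmm_associate(
    ko_table: AbundanceTable,
    gmm: list[GMMDefinition],
    meta: CohortMetadata,
    covariates: list[str],
    *,
    contrast: tuple[str, str] | None = None,
    scfa: str | None = None,
    adjust: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test module KOs for group contrasts or SCFA associations.

    Exactly one of ``contrast`` (group mode) or ``scfa`` (trait mode) must
    be given.  Returns one row per (module, KO) with estimate/se/p and a
    significance flag at ``alpha``; module-level counts follow from a
    groupby on the result.
    """
    if (contrast is None) == (scfa is None):
        raise DesignError("give exactly one of contrast= or scfa=")
    present = set(ko_table.feature_ids)
    rows = []
    any_cover = False
    for module in gmm:
        kos = sorted(module.ko_ids & present)
        if not kos:
            continue
        any_cover = True
        sub = ko_table.data[kos]
        if contrast is not None:
            fake = ALRTable(sub, reference_id="", pseudocount=0.0)
            res = adjusted_feature_model(fake, meta, covariates, contrast, adjust=adjust)
        else:
            res = trait_feature_model(sub, meta, covariates, scfa, adjust=adjust)
        for a in res:
            rows.append(
                {
                    "module_id": module.module_id,
                    "ko_id": a.feature_id,
                    "term": a.term,
                    "estimate": a.estimate,
                    "se": a.se,
                    "p": a.p,
                    "significant": a.p < alpha,
                }
            )
    if not any_cover:
        missing = sorted({ko for m in gmm for ko in m.ko_ids})
        raise CoverageError(f"no module KO present in the table; missing {missing[:10]}...")
    return pd.DataFrame(
        rows,
        columns=["module_id", "ko_id", "term", "estimate", "se", "p", "significant"],
    )
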
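"""Beta-diversity distances and a permutation-based PERMANOVA.

PERMANOVA partitions the total sum of squares of a distance matrix (via
the Gower-centered inner-product matrix G = -1/2 J D^2 J) across model
terms.  Terms are fitted sequentially — covariates first, the clinical
group last — so the group pseudo-F is the covariate-adjusted test.  The
null distribution comes from permutations: free permutation of samples
when there are no covariates, and Freedman-Lane permutation of reduced-
model residuals (in principal-coordinate space, negative eigenvalue mass
carried with its sign) when covariates are present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError, DomainError
from .tables import AbundanceTable, CohortMetadata


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DomainError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise DomainError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise DomainError("distance matrix must have a zero diagonal")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(i,j) = sum|x_i - x_j| / sum(x_i + x_j)."""
    x = table.values
    if (x.sum(axis=1) <= 0).any():
        i = int(np.argmax(x.sum(axis=1) <= 0))
        raise DomainError(f"all-zero sample row {table.sample_ids[i]!r}")
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        num = np.abs(x[i] - x[i + 1 :]).sum(axis=1)
        den = (x[i] + x[i + 1 :]).sum(axis=1)
        d[i, i + 1 :] = num / den
    d = d + d.T
    return DistanceMatrix(table.sample_ids, d, "bray_curtis")


def euclidean_alr(values: np.ndarray, sample_ids: list[str]) -> DistanceMatrix:
    """Euclidean distance on ALR-transformed abundances (Aitchison-style
    geometry; used e.g. for the bile-acid-malabsorption comparison)."""
    diff = values[:, None, :] - values[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(sample_ids, d, "euclidean_alr")


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    terms: pd.DataFrame  # term, df, sum_sq, R2


def _hat_basis(X: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the column space of X."""
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > tol * max(s[0], 1.0)).sum()) if s.size else 0
    return u[:, :rank]


def _group_dummies(labels: np.ndarray) -> np.ndarray:
    cats = sorted(set(labels))
    if len(cats) < 2:
        raise DesignError("group factor is constant (no between-group df)")
    return np.column_stack([(labels == c).astype(float) for c in cats[1:]])


def permanova(
    dist: DistanceMatrix,
    meta: CohortMetadata,
    *,
    covariates: list[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Sequential (covariates-first) PERMANOVA for the clinical group.

    ``meta`` must be aligned to ``dist``.  ``R2`` is the group term's share
    of total sum of squares; ``p_value`` is the permutation tail
    probability (1 + #{F* >= F}) / (1 + n_perm).
    """
    ids = dist.sample_ids
    if meta.sample_ids != ids:
        meta = meta.select_samples(ids)
    n = len(ids)
    labels = meta.group.to_numpy()
    covariates = covariates or []
    C = (
        np.column_stack([meta.trait(c).to_numpy() for c in covariates])
        if covariates
        else np.empty((n, 0))
    )
    if np.isnan(C).any():
        raise DesignError("missing covariate values; exclude them first")
    Gdum = _group_dummies(labels)

    A = -0.5 * dist.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J

    ones = np.ones((n, 1))
    U0 = _hat_basis(np.hstack([ones, C]))
    U1 = _hat_basis(np.hstack([ones, C, Gdum]))
    df_cov = U0.shape[1] - 1
    df_grp = U1.shape[1] - U0.shape[1]
    if df_grp == 0:
        raise DesignError("group dummies collinear with covariates")
    df_res = n - U1.shape[1]
    if df_res < 1:
        raise DesignError("no residual degrees of freedom")

    # Principal coordinates with signed eigenvalue mass: G = Y+ Y+' - Y- Y-'.
    w, V = np.linalg.eigh(G)
    tol = 1e-9 * max(abs(w).max(), 1.0)
    pos, neg = w > tol, w < -tol
    Yp = V[:, pos] * np.sqrt(w[pos])
    Yn = V[:, neg] * np.sqrt(-w[neg])

    def ss_terms(Yp: np.ndarray, Yn: np.ndarray) -> tuple[float, float, float, float]:
        def tr(Y: np.ndarray, U: np.ndarray) -> float:
            return float(((U.T @ Y) ** 2).sum())

        tot = float((Yp**2).sum() - (Yn**2).sum())
        cov = tr(Yp, U0) - tr(Yn, U0)
        full = tr(Yp, U1) - tr(Yn, U1)
        return tot, cov, full - cov, tot - full

    tot, ss_cov, ss_grp, ss_res = ss_terms(Yp, Yn)
    F_obs = (ss_grp / df_grp) / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    # Freedman-Lane: keep the reduced-model fit, permute its residuals.
    Rp, Rn = Yp - U0 @ (U0.T @ Yp), Yn - U0 @ (U0.T @ Yn)
    Fp0, Fn0 = U0 @ (U0.T @ Yp), U0 @ (U0.T @ Yn)
    exceed = 0
    for _ in range(n_perm):
        pi = rng.permutation(n)
        _, _, sg, sr = ss_terms(Fp0 + Rp[pi], Fn0 + Rn[pi])
        if (sg / df_grp) / (sr / df_res) >= F_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)

    terms = pd.DataFrame(
        {
            "term": ["covariates", "group", "residual", "total"],
            "df": [df_cov, df_grp, df_res, n - 1],
            "sum_sq": [ss_cov, ss_grp, ss_res, tot],
            "R2": [ss_cov / tot, ss_grp / tot, ss_res / tot, 1.0],
        }
    )
    return PermanovaResult(
        pseudo_F=float(F_obs),
        R2=float(ss_grp / tot),
        p_value=float(p),
        n_permutations=n_perm,
        terms=terms,
    )
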
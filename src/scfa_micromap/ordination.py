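"""(Partial) canonical correspondence analysis with a permutation test.

CCA ordinates a nonnegative sample-by-taxon table under the chi-square
metric, constrained to the span of explanatory variables; the partial
variant first removes the span of conditioning variables (here: colonic
transit time), so the constrained axes capture microbe-SCFA structure net
of transit.

Algorithm (weighted-SVD formulation):

1. close the table to proportions P; row weights r, column weights c;
   chi-square residual matrix Q with Q_ij = (P_ij - r_i c_j)/sqrt(r_i c_j);
   total inertia = ||Q||^2;
2. center (and standardize) conditions and constraints with weights r and
   scale rows by sqrt(r); residualize Q and the constraints on the
   conditions (removed inertia = conditional inertia);
3. project the residualized Q onto the residualized constraint span; the
   captured inertia is the constrained inertia, the rest residual;
4. SVD of the projected matrix: eigenvalues are squared singular values;
   species scores are right singular vectors over sqrt(c) (weighted-
   normalized, times sqrt(eigenvalue) under species-focused scaling);
   linear-combination site scores are left singular vectors over sqrt(r);
   biplot arrows are r-weighted correlations of each constraint with the
   site scores, scaled by sqrt(eigenvalue) per axis.

Axis signs are fixed so that the constraint with the largest |biplot
score| on each axis points positive.

The model permutation test uses reduced-model (Freedman-Lane) residual
permutation: the conditions-only fit of Q stays attached to samples and
only its residuals are permuted, so the conditioning variable keeps its
confounding role under the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DesignError, DomainError
from .tables import AbundanceTable

_RANK_TOL = 1e-9


@dataclass
class OrdinationResult:
    eigenvalues: np.ndarray
    total_inertia: float
    conditional_inertia: float
    constrained_inertia: float
    residual_inertia: float
    species_scores: pd.DataFrame  # feature x axis, species-focused scaling
    site_scores: pd.DataFrame  # sample x axis, linear-combination scores
    biplot_scores: pd.DataFrame  # constraint x axis
    scaling: str = "species_focused"

    @property
    def R2(self) -> float:
        """Constrained share of the inertia left after conditioning."""
        return self.constrained_inertia / (self.total_inertia - self.conditional_inertia)

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)

    def inertia_frame(self) -> pd.DataFrame:
        rows = [
            ("total", self.total_inertia),
            ("conditional", self.conditional_inertia),
            ("constrained", self.constrained_inertia),
            ("residual", self.residual_inertia),
        ] + [(f"CCA{k + 1}", float(l)) for k, l in enumerate(self.eigenvalues)]
        return pd.DataFrame(rows, columns=["component", "inertia"])


@dataclass
class PccaTestResult:
    pseudo_F: float
    p_value: float
    n_perm: int
    seed: int


def _weighted_standardize(M: np.ndarray, r: np.ndarray, names: list[str]) -> np.ndarray:
    """r-weighted centering and unit-variance scaling of design columns."""
    mean = r @ M
    centered = M - mean
    var = r @ centered**2
    if (var <= _RANK_TOL).any():
        bad = [names[j] for j in np.where(var <= _RANK_TOL)[0]]
        raise DesignError(f"constant design column(s): {bad}")
    return centered / np.sqrt(var)


def _column_basis(M: np.ndarray, names: list[str], strict: bool) -> np.ndarray:
    u, s, _ = np.linalg.svd(M, full_matrices=False)
    if s.size == 0:
        return u[:, :0]
    # Standardized sqrt(r)-scaled columns have unit norm, so the absolute
    # floor of 1 keeps a span that is numerically zero (e.g. constraints
    # fully absorbed by the conditions) out of the basis.
    rank = int((s > _RANK_TOL * max(s[0], 1.0)).sum())
    if strict and rank < M.shape[1]:
        # Identify the offending columns by greedy QR-style inclusion.
        keep: list[int] = []
        bad: list[str] = []
        for j in range(M.shape[1]):
            cols = M[:, keep + [j]]
            if np.linalg.matrix_rank(cols, tol=_RANK_TOL * max(s[0], 1.0)) > len(keep):
                keep.append(j)
            else:
                bad.append(names[j])
        raise DesignError(f"collinear constraint column(s): {bad}")
    return u[:, :rank]


def _as_design(columns: pd.DataFrame | None, n: int) -> tuple[np.ndarray, list[str]]:
    if columns is None or columns.shape[1] == 0:
        return np.empty((n, 0)), []
    M = columns.to_numpy(dtype=float)
    if np.isnan(M).any():
        raise DesignError("missing values in design columns; exclude them first")
    return M, [str(c) for c in columns.columns]


def pcca(
    table: AbundanceTable,
    constraints: pd.DataFrame,
    conditions: pd.DataFrame | None = None,
    *,
    scaling: str = "species_focused",
) -> OrdinationResult:
    """Partial CCA of ``table`` on ``constraints`` given ``conditions``.

    ``constraints``/``conditions`` are numeric DataFrames aligned to the
    table's samples (e.g. the SCFA concentrations and transit time).  With
    no conditions this is plain CCA.
    """
    if scaling != "species_focused":
        raise ConfigError(f"unknown scaling {scaling!r}")
    Y = table.values
    if Y.shape[0] < 3:
        raise DomainError("need >= 3 samples")
    if (Y < 0).any():
        raise DomainError("negative abundances")
    if (Y.sum(axis=1) <= 0).any():
        raise DomainError("all-zero sample row")
    if (Y.sum(axis=0) <= 0).any():
        j = int(np.argmax(Y.sum(axis=0) <= 0))
        raise DomainError(f"all-zero feature column {table.feature_ids[j]!r}")

    n, p = Y.shape
    P = Y / Y.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    sr, sc = np.sqrt(r), np.sqrt(c)
    Q = (P - np.outer(r, c)) / np.outer(sr, sc)
    total_inertia = float((Q**2).sum())

    Z, z_names = _as_design(conditions, n)
    X, x_names = _as_design(constraints, n)
    if X.shape[1] == 0:
        raise ConfigError("at least one constraint column is required")

    if Z.shape[1]:
        Zw = sr[:, None] * _weighted_standardize(Z, r, z_names)
        Uz = _column_basis(Zw, z_names, strict=False)
    else:
        Uz = np.empty((n, 0))
    cond_fit = Uz @ (Uz.T @ Q)
    conditional_inertia = float((cond_fit**2).sum())
    Qr = Q - cond_fit

    Xw = sr[:, None] * _weighted_standardize(X, r, x_names)
    _column_basis(Xw, x_names, strict=True)  # collinearity among constraints
    Xw = Xw - Uz @ (Uz.T @ Xw)
    # Rank lost to the conditions is legitimate (the conditioned-out span).
    Ux = _column_basis(Xw, x_names, strict=False)

    fitted = Ux @ (Ux.T @ Qr)
    constrained_inertia = float((fitted**2).sum())
    residual_inertia = float((Qr**2).sum()) - constrained_inertia

    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    k = int((s > _RANK_TOL * max(s[0], 1.0)).sum()) if s.size else 0
    k = min(k, Ux.shape[1])
    U, s, V = U[:, :k], s[:k], Vt[:k].T
    eig = s**2

    # Weighted-normalized scores: sum_j c_j v_jk^2 = 1, sum_i r_i u_ik^2 = 1.
    v = V / sc[:, None]
    u = U / sr[:, None]
    species = v * s[None, :]  # species-focused scaling
    sites = u

    # Biplot arrows: r-weighted correlation of raw constraints with the LC
    # site scores, stretched by sqrt(eigenvalue) per axis.
    Xstd = _weighted_standardize(X, r, x_names)
    wcor = (r[:, None] * Xstd).T @ u  # u already r-standardized
    biplot = wcor * s[None, :]

    # Sign convention: dominant constraint positive on each axis.
    for kk in range(k):
        j = int(np.argmax(np.abs(biplot[:, kk])))
        if biplot[j, kk] < 0:
            biplot[:, kk] *= -1
            species[:, kk] *= -1
            sites[:, kk] *= -1

    axes = [f"CCA{i + 1}" for i in range(k)]
    return OrdinationResult(
        eigenvalues=eig,
        total_inertia=total_inertia,
        conditional_inertia=conditional_inertia,
        constrained_inertia=constrained_inertia,
        residual_inertia=residual_inertia,
        species_scores=pd.DataFrame(species, index=table.feature_ids, columns=axes),
        site_scores=pd.DataFrame(sites, index=table.sample_ids, columns=axes),
        biplot_scores=pd.DataFrame(biplot, index=x_names, columns=axes),
    )


def pcca_permutation_test(
    table: AbundanceTable,
    constraints: pd.DataFrame,
    conditions: pd.DataFrame | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> PccaTestResult:
    """Model significance by reduced-model residual permutation.

    pseudo-F = (constrained/q) / (residual/(n - q - z - 1)) with q the
    number of constrained axes and z the number of condition columns;
    p = (1 + #{F* >= F}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    Y = table.values
    n = Y.shape[0]
    P = Y / Y.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    sr = np.sqrt(r)
    Q = (P - np.outer(r, c)) / np.outer(sr, np.sqrt(c))

    Z, z_names = _as_design(conditions, n)
    X, x_names = _as_design(constraints, n)
    if Z.shape[1]:
        Zw = sr[:, None] * _weighted_standardize(Z, r, z_names)
        Uz = _column_basis(Zw, z_names, strict=False)
    else:
        Uz = np.empty((n, 0))
    cond_fit = Uz @ (Uz.T @ Q)
    Qr = Q - cond_fit
    Xw = sr[:, None] * _weighted_standardize(X, r, x_names)
    _column_basis(Xw, x_names, strict=True)
    Xw = Xw - Uz @ (Uz.T @ Xw)
    Ux = _column_basis(Xw, x_names, strict=False)

    q = Ux.shape[1]
    z = Uz.shape[1]
    if q == 0:
        raise DesignError("constraints fully absorbed by the conditions")
    df_res = n - q - z - 1
    if df_res < 1:
        raise DesignError("no residual degrees of freedom for the pseudo-F")

    def f_stat(Qres: np.ndarray) -> float:
        con = float(((Ux.T @ Qres) ** 2).sum())
        res = float((Qres**2).sum()) - con
        return (con / q) / (res / df_res)

    F_obs = f_stat(Qr)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        pi = rng.permutation(n)
        # Freedman-Lane: permute reduced-model residuals, re-residualize on
        # the conditions, recompute F against the same constraint span.
        Qp = Qr[pi]
        Qp = Qp - Uz @ (Uz.T @ Qp)
        if f_stat(Qp) >= F_obs:
            exceed += 1
    return PccaTestResult(
        pseudo_F=float(F_obs),
        p_value=float((1 + exceed) / (1 + n_perm)),
        n_perm=n_perm,
        seed=seed,
    )


def dense_cca_eigenvalues(
    table: AbundanceTable, constraints: pd.DataFrame
) -> np.ndarray:
    """Independent dense-algebra oracle for plain CCA eigenvalues.

    Assembles the generalized eigenproblem (Xw' Q Q' Xw) b = lambda
    (Xw' Xw) b explicitly and solves it densely; exists for cross-checking
    the SVD path, not for production use.
    """
    from scipy.linalg import eigh

    Y = table.values
    P = Y / Y.sum()
    r, c = P.sum(axis=1), P.sum(axis=0)
    Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    X, names = _as_design(constraints, Y.shape[0])
    Xw = np.sqrt(r)[:, None] * _weighted_standardize(X, r, names)
    A = Xw.T @ Q @ Q.T @ Xw
    B = Xw.T @ Xw
    vals = eigh(A, B, eigvals_only=True)
    vals = np.clip(vals, 0.0, None)
    return np.sort(vals)[::-1]
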
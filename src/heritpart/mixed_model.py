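"""Multi-component animal models fitted by restricted maximum likelihood.

The model for a vector of records y is

    y = X b + sum_r Z_r u_r + sum_c W g_c + e

with X the fixed-effect design, Z_r incidence matrices for non-genetic
random effects (birth year, maternal id, permanent environment, ...), W the
records-to-individuals incidence, and each g_c a genetic effect with
covariance proportional to a supplied relationship matrix (GRM, thresholded
GRM, MAF GRM, or pedigree A).  Repeated measures are handled by the
repeatability construction: records of one individual share a W column, and
a permanent-environment effect keyed on individual id.

Fitting is by EM-REML warm start followed by average-information (AI) REML
with step-halving; variances are constrained non-negative by flooring at a
small multiple of the phenotypic variance unless ``constrain=False``.
The inverse AI matrix at the optimum provides the sampling covariance of
the variance components; ratio quantities (heritabilities) get delta-method
standard errors from it.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .exceptions import AlignmentError, NumericalError

__all__ = [
    "FixedEffect",
    "ModelSpec",
    "DesignMatrices",
    "VarianceComponentFit",
    "build_design",
    "record_covariances",
    "restricted_loglik",
    "reml_fit",
    "h2_from_fit",
]

RESIDUAL = "residual"


@dataclasses.dataclass
class FixedEffect:
    """One fixed-effect term: continuous (optionally polynomial) or categorical."""

    name: str
    kind: str = "continuous"  # "continuous" | "categorical"
    degree: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown fixed-effect kind {self.kind!r}")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")


@dataclasses.dataclass
class ModelSpec:
    """Declarative description of one animal model.

    ``genetic_components`` is an ordered list of (label, matrix) pairs where
    each matrix is a GRM or AMatrix (anything with ``.values`` and ``.ids``).
    """

    trait: str
    fixed_effects: list[FixedEffect] = dataclasses.field(default_factory=list)
    random_effects: list[str] = dataclasses.field(default_factory=list)
    genetic_components: list[tuple] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.genetic_components] + list(self.random_effects)
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate component labels: {labels}")
        if not labels:
            raise ValueError("model needs at least one random or genetic component")


@dataclasses.dataclass
class DesignMatrices:
    """Numeric realisation of a ModelSpec on a phenotype table."""

    y: np.ndarray
    X: np.ndarray
    x_names: list[str]
    Z: dict[str, np.ndarray]
    W: np.ndarray
    record_ids: list[str]
    sample_order: list[str]
    n_dropped: int = 0


@dataclasses.dataclass
class VarianceComponentFit:
    """REML solution for one model."""

    labels: list[str]                      # component order, residual last
    sigma2: dict[str, float]
    loglik_restricted: float
    sampling_cov: Optional[pd.DataFrame]
    converged: bool
    n_iterations: int
    constraint_flags: dict[str, bool]
    n_records: int
    n_fixed: int

    @property
    def total_variance(self) -> float:
        return float(sum(self.sigma2.values()))

    def se(self, label: str) -> float:
        if self.sampling_cov is None:
            return float("nan")
        return float(np.sqrt(self.sampling_cov.loc[label, label]))


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


def build_design(
    spec: ModelSpec,
    phenos: pd.DataFrame,
    sample_order: Sequence[str],
    id_col: str = "id",
) -> DesignMatrices:
    """Build y, X, Z_r and W from a record table.

    Categorical covariates are expanded with the first (sorted) level as
    reference; a degree-d continuous term expands to columns x, x^2, ..,
    x^d.  An intercept is always included.  Records missing the trait value
    or any required covariate/factor are dropped (count reported).
    """
    if id_col not in phenos.columns:
        raise AlignmentError(f"phenotype table lacks id column {id_col!r}")
    required = [spec.trait] + [f.name for f in spec.fixed_effects] + list(
        spec.random_effects
    )
    for col in required:
        if col not in phenos.columns:
            raise AlignmentError(f"phenotype table lacks column {col!r}")
    df = phenos.copy()
    df[id_col] = df[id_col].astype(str)
    sample_order = [str(s) for s in sample_order]
    outside = set(df[id_col]) - set(sample_order)
    if outside:
        raise AlignmentError(
            f"records for individuals not in sample_order: {sorted(outside)[:5]}"
        )
    complete = df[required + [id_col]].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    df = df.loc[complete]
    if df.empty:
        raise ValueError("no complete records left after dropping missing values")

    cols = [np.ones(len(df))]
    names = ["intercept"]
    for fe in spec.fixed_effects:
        if fe.kind == "continuous":
            x = df[fe.name].astype(float).to_numpy()
            for d in range(1, fe.degree + 1):
                cols.append(x**d)
                names.append(fe.name if d == 1 else f"{fe.name}^{d}")
        else:
            levels = sorted(df[fe.name].astype(str).unique())
            for lev in levels[1:]:
                cols.append((df[fe.name].astype(str) == lev).to_numpy(float))
                names.append(f"{fe.name}[{lev}]")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by greedy rank growth
        aliased = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                aliased.append(names[j])
        raise ValueError(f"fixed-effect design is rank deficient; aliased: {aliased}")

    Z = {}
    for re_name in spec.random_effects:
        fac = df[re_name].astype(str)
        levels = sorted(fac.unique())
        lut = {lev: k for k, lev in enumerate(levels)}
        z = np.zeros((len(df), len(levels)))
        z[np.arange(len(df)), fac.map(lut).to_numpy()] = 1.0
        Z[re_name] = z

    pos = {s: i for i, s in enumerate(sample_order)}
    W = np.zeros((len(df), len(sample_order)))
    W[np.arange(len(df)), df[id_col].map(pos).to_numpy()] = 1.0

    return DesignMatrices(
        y=df[spec.trait].astype(float).to_numpy(),
        X=X,
        x_names=names,
        Z=Z,
        W=W,
        record_ids=df[id_col].tolist(),
        sample_order=list(sample_order),
        n_dropped=n_dropped,
    )


def record_covariances(spec: ModelSpec, d: DesignMatrices) -> tuple[list[str], list[np.ndarray]]:
    """Map model components to record-level covariance structures.

    Genetic matrices are mapped through W as ``W M W^T`` (aligned to the
    design's sample order); non-genetic random effects become ``Z Z^T``.
    Returns (labels, structures) in spec order, residual excluded.
    """
    labels: list[str] = []
    structures: list[np.ndarray] = []
    for lab, mat in spec.genetic_components:
        ids = [str(s) for s in mat.ids]
        if ids != d.sample_order:
            pos = {s: i for i, s in enumerate(ids)}
            missing = [s for s in d.sample_order if s not in pos]
            if missing:
                raise AlignmentError(
                    f"component {lab!r} lacks individuals {missing[:5]}"
                )
            idx = np.array([pos[s] for s in d.sample_order])
            m = mat.values[np.ix_(idx, idx)]
        else:
            m = mat.values
        structures.append(d.W @ m @ d.W.T)
        labels.append(lab)
    for re_name in spec.random_effects:
        z = d.Z[re_name]
        structures.append(z @ z.T)
        labels.append(re_name)
    return labels, structures


# ---------------------------------------------------------------------------
# REML criterion and fitting
# ---------------------------------------------------------------------------


def _build_V(structures: Sequence[np.ndarray], sigma2: np.ndarray, n: int) -> np.ndarray:
    V = sigma2[-1] * np.eye(n)
    for s2, G in zip(sigma2[:-1], structures):
        V += s2 * G
    return V


def _reml_pieces(y, X, structures, sigma2):
    """V^-1-based quantities shared by the criterion and the updates."""
    V = _build_V(structures, np.asarray(sigma2, dtype=float), len(y))
    try:
        c, low = scipy.linalg.cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"V is not positive definite: {exc}") from exc
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(c))))
    Vinv = scipy.linalg.cho_solve((c, low), np.eye(V.shape[0]))
    VinvX = Vinv @ X
    XtVinvX = X.T @ VinvX
    sign, logdet_X = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        raise NumericalError("X'V^-1X is not positive definite")
    P = Vinv - VinvX @ np.linalg.solve(XtVinvX, VinvX.T)
    Py = P @ y
    yPy = float(y @ Py)
    n, p = X.shape
    _, logdet_XtX = np.linalg.slogdet(X.T @ X)
    ll = -0.5 * (logdet_V + logdet_X - logdet_XtX + yPy
                 + (n - p) * np.log(2.0 * np.pi))
    return ll, P, Py


def restricted_loglik(
    y: np.ndarray,
    X: np.ndarray,
    structures: Sequence[np.ndarray],
    sigma2: Sequence[float],
) -> float:
    """Restricted log-likelihood of the variance components.

    ``V = sum_k sigma2[k] G_k + sigma2[-1] I``.  The value is
    ``-1/2 [log|V| + log|X'V^-1 X| - log|X'X| + y'Py + (n-p) log 2pi]``:
    the exact restricted Gaussian log-density of an orthonormal
    error-contrast basis of y, hence invariant to the fixed-effect
    parameterisation (the ``log|X'X|`` term removes the basis dependence).
    """
    ll, _, _ = _reml_pieces(np.asarray(y, float), np.asarray(X, float),
                            structures, np.asarray(sigma2, float))
    return ll


def restricted_loglik_design(
    spec: ModelSpec, d: DesignMatrices, sigma2: dict[str, float]
) -> float:
    """Convenience wrapper evaluating the criterion from a ModelSpec/design."""
    labels, structures = record_covariances(spec, d)
    vec = np.array([sigma2[lab] for lab in labels] + [sigma2[RESIDUAL]])
    return restricted_loglik(d.y, d.X, structures, vec)


def _scores_and_ai(P, Py, structures):
    """REML score vector and average-information matrix (residual last)."""
    K = len(structures)
    v = [G @ Py for G in structures] + [Py]
    tr = [float(np.sum(P * G)) for G in structures] + [float(np.trace(P))]
    score = np.array([
        -0.5 * (tr[k] - float(Py @ (v[k] if k < K else Py)))
        for k in range(K + 1)
    ])
    # y'P G_k P G_l P y = v_k' P v_l
    Pv = [P @ vk for vk in v]
    ai = 0.5 * np.array([[float(v[k] @ Pv[l]) for l in range(K + 1)]
                         for k in range(K + 1)])
    return score, ai, tr, v


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    structures: Sequence[np.ndarray],
    labels: Sequence[str],
    constrain: bool = True,
    max_iter: int = 200,
    tol_loglik: float = 1e-8,
    tol_param: float = 1e-6,
    n_em: int = 3,
    start: Optional[Sequence[float]] = None,
) -> VarianceComponentFit:
    """Maximise the restricted likelihood over variance components.

    EM-REML steps (``n_em``) provide a stable warm start, then AI-REML with
    step-halving takes over.  Under the default constrained mode components
    whose update goes negative are pinned to a floor of ``1e-8`` times the
    phenotypic variance and flagged; their standard errors are reported as
    NaN.  Non-convergence within ``max_iter`` returns a fit with
    ``converged=False`` rather than raising.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    K = len(structures)
    if len(labels) != K:
        raise ValueError("labels must match the number of structures")
    all_labels = list(labels) + [RESIDUAL]
    n = len(y)
    vary = float(np.var(y, ddof=1)) if n > 1 else 1.0
    floor = 1e-8 * vary

    if start is not None:
        theta = np.asarray(start, dtype=float).copy()
    else:
        theta = np.full(K + 1, vary / (K + 1))
    if constrain:
        theta = np.maximum(theta, floor)

    # thresholded/MAF GRMs need not be PSD, so V can be indefinite even at
    # positive variances; shrink the structured components toward a
    # residual-dominated start until V is positive definite
    for _ in range(40):
        try:
            ll, P, Py = _reml_pieces(y, X, structures, theta)
            break
        except NumericalError:
            theta[:-1] *= 0.5
            theta[-1] = max(theta[-1], vary) * 1.25
    else:
        raise NumericalError(
            "could not find a positive-definite starting covariance"
        )
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        score, ai, tr, v = _scores_and_ai(P, Py, structures)
        if it <= n_em:
            # EM update: theta_k <- theta_k + theta_k^2/n (y'P G_k P y - tr(P G_k))
            quad = np.array([float(Py @ (v[k] if k < K else Py))
                             for k in range(K + 1)])
            delta = (theta**2 / n) * (quad - np.array(tr))
        else:
            # active set: components pinned at the floor whose score pushes
            # them further negative are frozen out of the AI solve, so the
            # free components converge to the reduced problem's optimum
            pinned = (constrain & (theta <= floor * (1 + 1e-9)) & (score < 0)
                      if constrain else np.zeros(K + 1, dtype=bool))
            free = np.flatnonzero(~pinned)
            delta = np.zeros(K + 1)
            try:
                sub = ai[np.ix_(free, free)]
                delta[free] = np.linalg.solve(
                    sub + 1e-12 * np.eye(len(free)), score[free]
                )
            except np.linalg.LinAlgError:
                delta[free] = score[free] / np.maximum(np.diag(ai)[free], 1e-12)

        step = 1.0
        new_ll = -np.inf
        for _ in range(25):
            prop = theta + step * delta
            if constrain:
                prop = np.maximum(prop, floor)
            try:
                new_ll, newP, newPy = _reml_pieces(y, X, structures, prop)
            except NumericalError:
                step /= 2.0
                continue
            if new_ll >= ll - 1e-10:
                break
            step /= 2.0
        else:
            prop, new_ll, newP, newPy = theta, ll, P, Py

        rel_change = np.max(np.abs(prop - theta) / np.maximum(np.abs(theta), floor))
        dll = new_ll - ll
        theta, ll, P, Py = prop, new_ll, newP, newPy
        if it > n_em and abs(dll) < tol_loglik and rel_change < tol_param:
            converged = True
            break

    flags = {lab: bool(constrain and theta[k] <= floor * (1 + 1e-9))
             for k, lab in enumerate(all_labels)}

    score, ai, _, _ = _scores_and_ai(P, Py, structures)
    cov = None
    try:
        free = [k for k in range(K + 1) if not flags[all_labels[k]]]
        full = np.full((K + 1, K + 1), np.nan)
        if free:
            sub = np.linalg.inv(ai[np.ix_(free, free)])
            for a, ka in enumerate(free):
                for b, kb in enumerate(free):
                    full[ka, kb] = sub[a, b]
        cov = pd.DataFrame(full, index=all_labels, columns=all_labels)
    except np.linalg.LinAlgError:
        cov = None

    return VarianceComponentFit(
        labels=all_labels,
        sigma2={lab: float(theta[k]) for k, lab in enumerate(all_labels)},
        loglik_restricted=float(ll),
        sampling_cov=cov,
        converged=converged,
        n_iterations=it,
        constraint_flags=flags,
        n_records=n,
        n_fixed=X.shape[1],
    )


def reml_fit_design(spec: ModelSpec, d: DesignMatrices, **kwargs) -> VarianceComponentFit:
    """Fit a ModelSpec on realised design matrices."""
    labels, structures = record_covariances(spec, d)
    return reml_fit(d.y, d.X, structures, labels, **kwargs)


def h2_from_fit(
    fit: VarianceComponentFit,
    numerator_labels: Sequence[str],
    require_converged: bool = False,
) -> tuple[float, float]:
    """Ratio of named variance components to the total, with delta-method SE.

    The total is the sum of every component including the residual.  The SE
    propagates the full component sampling covariance through the gradient
    of the ratio; covariance entries for boundary-pinned components are
    treated as zero.
    """
    if require_converged and not fit.converged:
        raise RuntimeError("fit did not converge")
    numerator_labels = list(numerator_labels)
    unknown = [lab for lab in numerator_labels if lab not in fit.labels]
    if unknown:
        raise KeyError(f"unknown component labels: {unknown}")
    total = fit.total_variance
    if total <= 0:
        raise ValueError("total variance is zero; heritability undefined")
    num = sum(fit.sigma2[lab] for lab in numerator_labels)
    h2 = num / total
    if fit.sampling_cov is None:
        return h2, float("nan")
    grad = np.array([
        ((total - num) if lab in numerator_labels else -num) / total**2
        for lab in fit.labels
    ])
    C = np.nan_to_num(fit.sampling_cov.loc[fit.labels, fit.labels].to_numpy())
    se = float(np.sqrt(max(grad @ C @ grad, 0.0)))
    return h2, se
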
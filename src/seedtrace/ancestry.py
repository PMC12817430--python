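"""Maximum-likelihood admixture model fitted by EM.

The model: genotype g_ij ~ Binomial(2, f_ij) with f_ij = sum_k q_ik p_kj,
Q rows on the simplex, P in [0,1].  Includes masked cross-validation for
choosing K, Hungarian alignment of restarts against label switching, and
threshold-based lineage assignment with an admixture flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .genotype_io import GenotypeMatrix

_EPS = 1e-6


@dataclass
class AncestryFit:
    Q: np.ndarray  # individuals x K
    P: np.ndarray  # K x loci
    loglik: float
    K: int
    n_iter: int
    converged: bool
    rng_seed: int | None = None


@dataclass
class CVResult:
    errors: dict[int, float]  # K -> mean masked prediction error
    folds: int
    fold_errors: dict[int, list[float]] = field(default_factory=dict)


@dataclass
class EsuAssignment:
    individual_id: str
    esu: str
    max_foreign_ancestry: float
    admixed: bool


def _prepare(G_or_array) -> np.ndarray:
    if isinstance(G_or_array, GenotypeMatrix):
        return G_or_array.dosage_float()
    return np.asarray(G_or_array, dtype=float)


def admixture_loglik(G, Q: np.ndarray, P: np.ndarray) -> float:
    """Binomial mixture log-likelihood, skipping missing genotypes."""
    X = _prepare(G)
    Q = np.asarray(Q, dtype=float)
    P = np.asarray(P, dtype=float)
    if Q.shape[0] != X.shape[0] or Q.shape[1] != P.shape[0] or P.shape[1] != X.shape[1]:
        raise ValueError(
            f"non-conforming shapes G {X.shape}, Q {Q.shape}, P {P.shape}"
        )
    F = np.clip(Q @ np.clip(P, _EPS, 1 - _EPS), _EPS, 1 - _EPS)
    obs = np.isfinite(X)
    g = np.where(obs, X, 0.0)
    ll = g * np.log(F) + (2.0 - g) * np.log(1.0 - F)
    return float(ll[obs].sum())


def em_step(G, Q: np.ndarray, P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One EM update; never decreases the log-likelihood.

    With alpha_ijk = g q p / f and beta_ijk = (2-g) q (1-p) / (1-f):
    p'_kj = sum_i alpha / sum_i (alpha+beta);  q'_ik = sum_j (alpha+beta)/(2 J_i).
    """
    X = _prepare(G)
    Q = np.asarray(Q, dtype=float)
    P = np.clip(np.asarray(P, dtype=float), _EPS, 1 - _EPS)
    obs = np.isfinite(X)
    g = np.where(obs, X, 0.0)
    two_minus_g = np.where(obs, 2.0 - X, 0.0)
    F = np.clip(Q @ P, _EPS, 1 - _EPS)
    R = g / F  # zero where missing
    S = two_minus_g / (1.0 - F)
    # sums over individuals for the P update
    A = Q.T @ R  # K x J: sum_i q_ik g_ij / f_ij
    B = Q.T @ S
    num = P * A
    den = P * A + (1.0 - P) * B
    with np.errstate(invalid="ignore", divide="ignore"):
        P_new = np.where(den > 0, num / np.maximum(den, 1e-300), P)
    # sums over loci for the Q update
    J_i = obs.sum(axis=1).astype(float)
    Qa = Q * (R @ P.T)  # N x K: sum_j alpha_ijk
    Qb = Q * (S @ (1.0 - P).T)
    Q_new = (Qa + Qb) / np.maximum(2.0 * J_i, 1.0)[:, None]
    Q_new /= np.maximum(Q_new.sum(axis=1, keepdims=True), 1e-300)
    return Q_new, np.clip(P_new, _EPS, 1 - _EPS)


def _observed_freqs(X: np.ndarray) -> np.ndarray:
    obs = np.isfinite(X)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(X, axis=0) / np.maximum(2.0 * obs.sum(axis=0), 1.0)
    return np.clip(p, _EPS, 1 - _EPS)


def fit_admixture(
    G,
    K: int,
    n_restarts: int = 5,
    max_iter: int = 2000,
    tol: float = 1e-6,
    rng_seed: int = 0,
    return_all: bool = False,
):
    """Fit the K-lineage admixture model; return the best of random restarts.

    Initialization per restart: Q rows ~ Dirichlet(1,...,1); P = observed
    frequency + Uniform(-0.05, 0.05) jitter, clamped.  Deterministic given
    ``rng_seed``.
    """
    X = _prepare(G)
    n, j = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds number of individuals ({n})")
    rng = np.random.default_rng(rng_seed)
    base_p = _observed_freqs(X)

    fits: list[AncestryFit] = []
    for _ in range(max(1, n_restarts)):
        Q = rng.dirichlet(np.ones(K), size=n)
        P = np.clip(
            base_p[None, :] + rng.uniform(-0.05, 0.05, size=(K, j)), _EPS, 1 - _EPS
        )
        ll = admixture_loglik(X, Q, P)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            Q, P = em_step(X, Q, P)
            new_ll = admixture_loglik(X, Q, P)
            if abs(new_ll - ll) < tol:
                ll = new_ll
                converged = True
                break
            ll = new_ll
        fits.append(
            AncestryFit(Q=Q, P=P, loglik=ll, K=K, n_iter=it, converged=converged,
                        rng_seed=rng_seed)
        )
    best = max(fits, key=lambda f: f.loglik)
    if return_all:
        return best, fits
    return best


def cv_error(
    G,
    K: int,
    folds: int = 10,
    rng_seed: int = 0,
    n_restarts: int = 1,
    max_iter: int = 500,
    tol: float = 1e-4,
) -> float:
    """Masked cross-validation error for one K.

    Non-missing genotype entries are partitioned into ``folds`` parts; each
    fold is masked, the model refit, and masked dosages predicted as
    2 * f_hat.  Returns the mean squared deviation averaged over folds.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = _prepare(G)
    obs_idx = np.argwhere(np.isfinite(X))
    if obs_idx.shape[0] < folds:
        raise ValueError("fewer observed entries than folds")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(obs_idx.shape[0])
    assignments = np.arange(obs_idx.shape[0]) % folds
    fold_of_entry = np.empty(obs_idx.shape[0], dtype=int)
    fold_of_entry[perm] = assignments

    errors = []
    for f in range(folds):
        mask_entries = obs_idx[fold_of_entry == f]
        if mask_entries.shape[0] == 0:
            raise ValueError(f"fold {f} has zero masked entries")
        Xm = X.copy()
        Xm[mask_entries[:, 0], mask_entries[:, 1]] = np.nan
        fit = fit_admixture(
            Xm, K, n_restarts=n_restarts, max_iter=max_iter, tol=tol,
            rng_seed=int(rng.integers(2**31)),
        )
        F = np.clip(fit.Q @ fit.P, 0.0, 1.0)
        pred = 2.0 * F[mask_entries[:, 0], mask_entries[:, 1]]
        truth = X[mask_entries[:, 0], mask_entries[:, 1]]
        errors.append(float(np.mean((truth - pred) ** 2)))
    return float(np.mean(errors)), errors


def cv_scan(
    G,
    K_values,
    folds: int = 10,
    rng_seed: int = 0,
    **kwargs,
) -> CVResult:
    """cv_error over a range of K with a shared fold seed."""
    errors: dict[int, float] = {}
    fold_errors: dict[int, list[float]] = {}
    for K in K_values:
        mean_err, per_fold = cv_error(G, K, folds=folds, rng_seed=rng_seed, **kwargs)
        errors[int(K)] = mean_err
        fold_errors[int(K)] = per_fold
    return CVResult(errors=errors, folds=folds, fold_errors=fold_errors)


def select_K(cv: CVResult, rule: str = "min") -> int:
    """Choose K from cross-validation errors.

    ``min``: smallest error (ties -> smallest K).  ``elbow``: interior K
    maximizing the second difference e(K-1) - 2 e(K) + e(K+1).
    """
    ks = sorted(cv.errors)
    if rule == "min":
        if not ks:
            raise ValueError("no K values")
        best = min(ks, key=lambda k: (cv.errors[k], k))
        return best
    if rule == "elbow":
        if len(ks) < 3:
            raise ValueError("elbow rule needs at least 3 K values")
        second = {
            ks[i]: cv.errors[ks[i - 1]] - 2 * cv.errors[ks[i]] + cv.errors[ks[i + 1]]
            for i in range(1, len(ks) - 1)
        }
        return max(sorted(second), key=lambda k: second[k])
    raise ValueError(f"unknown rule {rule!r}")


def align_runs(
    runs: list[np.ndarray], agreement_threshold: float = 0.05
) -> tuple[list[np.ndarray], list[np.ndarray], float]:
    """Permute each run's columns to best match the first run.

    Uses optimal assignment on total absolute Q difference.  Returns
    (aligned runs, permutations, modal-agreement fraction): the fraction of
    runs whose mean absolute Q distance to the modal (most-agreed) run is
    within ``agreement_threshold``.
    """
    if not runs:
        raise ValueError("no runs")
    shapes = {r.shape for r in map(np.asarray, runs)}
    if len(shapes) != 1:
        raise ValueError("runs must share dimensions")
    ref = np.asarray(runs[0], dtype=float)
    K = ref.shape[1]
    aligned: list[np.ndarray] = []
    perms: list[np.ndarray] = []
    for r in runs:
        r = np.asarray(r, dtype=float)
        cost = np.zeros((K, K))
        for a in range(K):
            for b in range(K):
                cost[a, b] = np.abs(ref[:, a] - r[:, b]).sum()
        _, col = linear_sum_assignment(cost)
        aligned.append(r[:, col])
        perms.append(col)
    # modal run = the aligned run minimizing total distance to all others
    dists = np.zeros((len(aligned), len(aligned)))
    for i in range(len(aligned)):
        for j in range(i + 1, len(aligned)):
            d = float(np.abs(aligned[i] - aligned[j]).mean())
            dists[i, j] = dists[j, i] = d
    modal = int(np.argmin(dists.sum(axis=1)))
    agree = float(np.mean(dists[modal] <= agreement_threshold))
    return aligned, perms, agree


def assign_esu(
    Q: np.ndarray, esu_labels: list[str], tau: float = 0.10,
    individual_ids: list[str] | None = None,
) -> list[EsuAssignment]:
    """Assign each individual to its argmax lineage; flag as admixed when the
    largest off-lineage ancestry is >= ``tau`` (inclusive threshold)."""
    Q = np.asarray(Q, dtype=float)
    if len(esu_labels) != Q.shape[1]:
        raise ValueError("esu_labels must match Q columns")
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0,1)")
    if individual_ids is None:
        individual_ids = [f"ind{i:04d}" for i in range(Q.shape[0])]
    out = []
    for ind, row in zip(individual_ids, Q):
        top = int(np.argmax(row))  # ties -> first label in column order
        foreign = np.delete(row, top)
        mfa = float(foreign.max()) if foreign.size else 0.0
        out.append(
            EsuAssignment(
                individual_id=ind,
                esu=esu_labels[top],
                max_foreign_ancestry=mfa,
                admixed=mfa >= tau,
            )
        )
    return out


def write_q_matrix(fit: AncestryFit, individual_ids, esu_labels, path) -> None:
    pd.DataFrame(fit.Q, index=individual_ids, columns=esu_labels).to_csv(
        path, sep="\t", float_format="%.6f"
    )
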
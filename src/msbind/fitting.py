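"""Parameter estimation for the MS and SS models.

The MS fit is a nonlinear least-squares problem: observed pseudo-binding
energies G^SPOT are regressed on

    alpha - ln sum_i exp(-F_i . J)

over the offset alpha and the 19*S non-reference J terms, where F_i is the
indicator encoding of window i.  The objective is non-convex, so the fit runs
several independently initialized restarts and keeps the lowest-SSE solution.
The SS fit is an ordinary linear regression of G^SPOT on the encoding of the
window at one fixed site offset, solved in closed form.

Residue/position combinations never observed in the training windows are
excluded from optimization and their J is fixed at 0, so predictions on unseen
residues fall back to the reference energy and fits are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from .energy_models import EnergyParams, MSModel, SSModel, ms_energy, ss_energy
from .sequence_space import (
    SLOTS_PER_POSITION,
    Peptide,
    ReferenceProfile,
    Window,
    build_reference_profile,
    design_matrix,
    enumerate_windows,
)
from .spot_io import SpotRecord

logger = logging.getLogger(__name__)

__all__ = ["FitConfig", "FitResult", "fit_ms", "fit_ss"]

#: Box bound on single-residue J terms (RT units) — far outside physically
#: plausible per-residue contributions; guards rare features from divergence.
J_BOUND = 20.0


@dataclass(frozen=True)
class FitConfig:
    """Settings for the MS nonlinear fit.

    ``n_restarts`` independent starts are run: restart 0 starts from J = 0,
    the rest from J ~ Uniform(-init_spread, +init_spread).  ``alpha_init_policy``
    chooses the alpha start ('mean_energy' = mean observed pseudo-energy, or
    'zero').  ``fixed_alpha``, when set, holds alpha constant (the second pass
    of the cross-validation protocol).  ``ridge`` adds an L2 penalty on J in
    the SS regression only (0 = plain least squares).
    """

    n_restarts: int = 10
    seed: int = 0
    init_spread: float = 1.0
    alpha_init_policy: Literal["mean_energy", "zero"] = "mean_energy"
    max_iterations: int = 500
    convergence_tol: float = 1e-10
    fixed_alpha: float | None = None
    ridge: float = 0.0

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")


@dataclass(frozen=True)
class FitResult:
    """A fitted model with its residual diagnostics."""

    model: MSModel | SSModel
    sse: float
    residuals: np.ndarray  # observed - predicted, per accepted record
    converged: bool
    restart_index: int
    restart_sses: tuple[float, ...]
    n_skipped: int
    unobserved: tuple[tuple[int, str], ...]  # (1-based position, residue)
    record_ids: tuple[str, ...] = ()


def _resolve_profile(
    windows: Sequence[Window],
    policy: str | ReferenceProfile,
) -> ReferenceProfile:
    if isinstance(policy, ReferenceProfile):
        return policy
    return build_reference_profile(windows, policy)


def _filter_records(
    data: Sequence[SpotRecord], min_length: int
) -> tuple[list[SpotRecord], int]:
    kept = []
    skipped = 0
    for rec in data:
        if not np.isfinite(rec.pseudo_energy):
            raise ValueError(
                f"record {rec.peptide.id!r}: non-finite pseudo-energy"
            )
        if rec.peptide.length < min_length:
            skipped += 1
        else:
            kept.append(rec)
    if skipped:
        logger.warning(
            "skipped %d records shorter than %d residues", skipped, min_length
        )
    return kept, skipped


class _MSDesign:
    """Precomputed window design for fast MS residuals and Jacobians."""

    def __init__(
        self,
        records: Sequence[SpotRecord],
        S: int,
        profile: ReferenceProfile,
    ) -> None:
        windows: list[Window] = []
        ptr = [0]
        for rec in records:
            ws = enumerate_windows(rec.peptide, S)
            windows.extend(ws)
            ptr.append(len(windows))
        self.F = design_matrix(windows, profile, include_intercept=False)
        self.ptr = np.asarray(ptr)
        self.starts = self.ptr[:-1]
        self.obs = np.asarray(
            [rec.pseudo_energy for rec in records], dtype=np.float64
        )
        self.observed_cols = np.flatnonzero(self.F.any(axis=0))
        self.Fobs = np.ascontiguousarray(self.F[:, self.observed_cols])

    def neg_lse(self, J_obs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-record ``ln sum_i exp(-e_i)`` and per-window softmax weights."""
        e = self.Fobs @ J_obs
        neg = -e
        m = np.maximum.reduceat(neg, self.starts)
        m_exp = np.repeat(m, np.diff(self.ptr))
        ex = np.exp(neg - m_exp)
        sums = np.add.reduceat(ex, self.starts)
        lse = m + np.log(sums)
        w = ex / np.repeat(sums, np.diff(self.ptr))
        return lse, w

    def predictions(self, alpha: float, J_obs: np.ndarray) -> np.ndarray:
        lse, _ = self.neg_lse(J_obs)
        return alpha - lse


def _ms_residual_jac(design: _MSDesign, fixed_alpha: float | None):
    """Residual and Jacobian callables over the packed parameter vector."""
    n_rec = design.obs.size

    def split(theta: np.ndarray) -> tuple[float, np.ndarray]:
        if fixed_alpha is None:
            return theta[0], theta[1:]
        return fixed_alpha, theta

    def residual(theta: np.ndarray) -> np.ndarray:
        alpha, J_obs = split(theta)
        return design.obs - design.predictions(alpha, J_obs)

    def jac(theta: np.ndarray) -> np.ndarray:
        alpha, J_obs = split(theta)
        _, w = design.neg_lse(J_obs)
        # d pred / d J_m = sum_i w_i F_im  ->  d residual = -that
        dJ = -np.add.reduceat(w[:, None] * design.Fobs, design.starts, axis=0)
        if fixed_alpha is None:
            da = -np.ones((n_rec, 1))
            return np.hstack([da, dJ])
        return dJ

    return residual, jac


def fit_ms(
    data: Sequence[SpotRecord],
    S: int,
    profile_policy: str | ReferenceProfile = "most_frequent",
    config: FitConfig | None = None,
) -> FitResult:
    """Fit the MS model by restarted bounded nonlinear least squares.

    Peptides shorter than ``S`` are skipped with a warning.  The result is
    deterministic given the data order and ``config.seed``.
    """
    config = config or FitConfig()
    records, n_skipped = _filter_records(data, S)
    if len({rec.peptide.sequence for rec in records}) < 2:
        raise ValueError("need at least 2 distinct peptide sequences to fit")

    all_windows = [w for rec in records for w in enumerate_windows(rec.peptide, S)]
    profile = _resolve_profile(all_windows, profile_policy)
    design = _MSDesign(records, S, profile)

    n_obs_cols = design.observed_cols.size
    n_total_cols = SLOTS_PER_POSITION * S
    unobserved_idx = np.setdiff1d(np.arange(n_total_cols), design.observed_cols)
    if unobserved_idx.size:
        logger.warning(
            "%d of %d J columns unobserved; fixed at 0",
            unobserved_idx.size,
            n_total_cols,
        )

    if config.alpha_init_policy == "mean_energy":
        alpha0 = float(np.mean(design.obs))
    else:
        alpha0 = 0.0

    residual, jac = _ms_residual_jac(design, config.fixed_alpha)
    free_alpha = config.fixed_alpha is None
    n_theta = n_obs_cols + (1 if free_alpha else 0)
    lo = np.full(n_theta, -J_BOUND)
    hi = np.full(n_theta, J_BOUND)
    if free_alpha:
        lo[0], hi[0] = -np.inf, np.inf

    rng = np.random.default_rng(config.seed)
    best = None
    best_idx = -1
    restart_sses = []
    for k in range(config.n_restarts):
        if k == 0:
            J_init = np.zeros(n_obs_cols)
        else:
            J_init = rng.uniform(
                -config.init_spread, config.init_spread, size=n_obs_cols
            )
        theta0 = np.concatenate(([alpha0], J_init)) if free_alpha else J_init
        sol = least_squares(
            residual,
            theta0,
            jac=jac,
            bounds=(lo, hi),
            method="trf",
            max_nfev=config.max_iterations * max(1, n_theta),
            ftol=config.convergence_tol,
            xtol=config.convergence_tol,
            gtol=config.convergence_tol,
        )
        sse = float(2.0 * sol.cost)
        restart_sses.append(sse)
        if best is None or sse < best[0]:
            best = (sse, sol)
            best_idx = k
    assert best is not None
    _, sol = best

    if free_alpha:
        alpha = float(sol.x[0])
        J_obs = sol.x[1:]
    else:
        alpha = float(config.fixed_alpha)
        J_obs = sol.x
    J = np.zeros(n_total_cols)
    J[design.observed_cols] = J_obs
    params = EnergyParams(profile, J.reshape(S, SLOTS_PER_POSITION), 0.0)
    model = MSModel(params, alpha)

    res = design.obs - design.predictions(alpha, J_obs)
    unobserved = tuple(
        (int(idx // SLOTS_PER_POSITION) + 1,
         profile.non_reference(int(idx // SLOTS_PER_POSITION))[
             int(idx % SLOTS_PER_POSITION)
         ])
        for idx in unobserved_idx
    )
    return FitResult(
        model=model,
        sse=float(res @ res),
        residuals=res,
        converged=bool(sol.status > 0),
        restart_index=best_idx,
        restart_sses=tuple(restart_sses),
        n_skipped=n_skipped,
        unobserved=unobserved,
        record_ids=tuple(rec.peptide.id for rec in records),
    )


def fit_ss(
    data: Sequence[SpotRecord],
    S: int,
    r: int,
    profile_policy: str | ReferenceProfile = "most_frequent",
    config: FitConfig | None = None,
) -> FitResult:
    """Fit the SS model: OLS of pseudo-energies on the site-``r`` encoding.

    Solved by a rank-revealing least-squares decomposition; with
    ``config.ridge > 0`` an L2 penalty on the J terms (not the intercept)
    stabilizes ill-conditioned small-data designs.  Records too short for the
    site are skipped with a warning.
    """
    config = config or FitConfig()
    if r < 0:
        raise ValueError("site offset must be >= 0")
    records, n_skipped = _filter_records(data, r + S)
    if len(records) < 2:
        raise ValueError("need at least 2 records to fit the SS model")

    windows = [
        Window(rec.peptide.id, r, S, rec.peptide.sequence[r : r + S])
        for rec in records
    ]
    profile = _resolve_profile(windows, profile_policy)
    X = design_matrix(windows, profile, include_intercept=True)
    y = np.asarray([rec.pseudo_energy for rec in records])

    observed = np.flatnonzero(X.any(axis=0))  # intercept col is always in
    Xo = X[:, observed]
    if config.ridge > 0:
        penalty = np.full(observed.size, np.sqrt(config.ridge))
        penalty[0] = 0.0  # do not shrink the intercept
        A = np.vstack([Xo, np.diag(penalty)])
        b = np.concatenate([y, np.zeros(observed.size)])
        beta_o, *_ = np.linalg.lstsq(A, b, rcond=None)
    else:
        beta_o, *_ = np.linalg.lstsq(Xo, y, rcond=None)
    beta = np.zeros(X.shape[1])
    beta[observed] = beta_o

    unobserved_idx = np.setdiff1d(np.arange(1, X.shape[1]), observed) - 1
    if unobserved_idx.size:
        logger.warning(
            "SS fit: %d J columns unobserved at site %d; fixed at 0",
            unobserved_idx.size,
            r,
        )

    params = EnergyParams(
        profile, beta[1:].reshape(S, SLOTS_PER_POSITION), float(beta[0])
    )
    model = SSModel(params, r)
    res = y - X @ beta
    unobserved = tuple(
        (int(idx // SLOTS_PER_POSITION) + 1,
         profile.non_reference(int(idx // SLOTS_PER_POSITION))[
             int(idx % SLOTS_PER_POSITION)
         ])
        for idx in unobserved_idx
    )
    return FitResult(
        model=model,
        sse=float(res @ res),
        residuals=res,
        converged=True,
        restart_index=0,
        restart_sses=(float(res @ res),),
        n_skipped=n_skipped,
        unobserved=unobserved,
        record_ids=tuple(rec.peptide.id for rec in records),
    )
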
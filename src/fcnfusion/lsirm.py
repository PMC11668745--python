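"""Step 3a — continuous latent-space item-response model by MCMC.

The model for the group representative matrix ``Y`` (subjects i = 1..N by
ROIs j = 1..R) is

    y_ij ~ Normal(theta_j + beta_i - ||u_j - v_i||,  sigma^2)

with ROI main effects ``theta_j ~ N(0, sigma_theta^2)`` (the variance given
an Inv-Gamma(a, b) hyperprior), subject main effects ``beta_i ~ N(0, 1)``,
and 2-D latent positions ``u_j``, ``v_i`` with standard-normal priors. An
ROI whose latent position sits near the origin interacts consistently with
every subject of the group — those are the group-representative regions.

Sampling is Metropolis-within-Gibbs: random-walk Metropolis updates for
theta, beta, U and V at the configured jump scales (each block updated
component-wise but evaluated vectorized, since the likelihood factorizes
over rows and columns), and conjugate Gibbs draws for both variances. The
likelihood is invariant under joint rigid motions of (U, V), so retained
draws are Procrustes-aligned to a reference draw, and the posterior-mean
configuration can additionally be oblimin-rotated for interpretability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable
import warnings

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes

from fcnfusion.datatypes import GroupRepMatrix
from fcnfusion.rotation import oblimin_rotate

__all__ = [
    "LsirmParams",
    "McmcConfig",
    "LsirmPosterior",
    "log_likelihood",
    "run_mcmc",
    "procrustes_align",
    "rotate_positions",
    "origin_proximity",
]


@dataclass
class LsirmParams:
    """One state of the sampler: main effects, positions, variances."""

    theta: np.ndarray   # (R,) ROI main effects
    beta: np.ndarray    # (N,) subject main effects
    U: np.ndarray       # (R, d) ROI latent positions
    V: np.ndarray       # (N, d) subject latent positions
    sigma2: float       # likelihood variance
    sigma_theta2: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma2 <= 0 or self.sigma_theta2 <= 0:
            raise ValueError("variances must be positive")
        for name in ("theta", "beta", "U", "V"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if not np.isfinite(arr).all():
                raise ValueError(f"non-finite values in {name}")
            setattr(self, name, arr)


@dataclass
class McmcConfig:
    """Sampler settings.

    Defaults: 55,000 iterations, 5,000 burn-in, thinning 5 (10,000 retained
    draws); random-walk jump scales 0.005 for theta and beta, 0.005 for the
    ROI positions and 0.003 for the subject positions; Inv-Gamma(0.001,
    0.001) hyperpriors for both variances; N(0, 1) priors for beta and the
    latent positions.
    """

    n_iterations: int = 55_000
    burn_in: int = 5_000
    thin: int = 5
    jump_theta: float = 0.005
    jump_beta: float = 0.005
    jump_u: float = 0.005
    jump_v: float = 0.003
    a_sigma: float = 0.001
    b_sigma: float = 0.001
    beta_prior_sd: float = 1.0
    latent_prior_sd: float = 1.0
    latent_dim: int = 2
    proposal: str = "random_walk"  # or "independent" (prior proposals)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        for j in (self.jump_theta, self.jump_beta, self.jump_u, self.jump_v):
            if j <= 0:
                raise ValueError("jump scales must be positive")
        if self.proposal not in ("random_walk", "independent"):
            raise ValueError(f"unknown proposal scheme {self.proposal!r}")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


@dataclass
class LsirmPosterior:
    """Retained draws, acceptance rates, and aligned position summaries."""

    theta: np.ndarray         # (S, R)
    beta: np.ndarray          # (S, N)
    U: np.ndarray             # (S, R, d) raw draws
    V: np.ndarray             # (S, N, d)
    sigma2: np.ndarray        # (S,)
    sigma_theta2: np.ndarray  # (S,)
    acceptance_rates: dict[str, float]
    roi_labels: list[str] = field(default_factory=list)
    subject_ids: list[str] = field(default_factory=list)
    aligned_U: np.ndarray | None = None
    aligned_V: np.ndarray | None = None
    rotated_U_mean: np.ndarray | None = None

    @property
    def n_retained(self) -> int:
        return self.theta.shape[0]

    def mean_params(self) -> LsirmParams:
        U = self.aligned_U if self.aligned_U is not None else self.U
        V = self.aligned_V if self.aligned_V is not None else self.V
        return LsirmParams(
            theta=self.theta.mean(axis=0),
            beta=self.beta.mean(axis=0),
            U=U.mean(axis=0),
            V=V.mean(axis=0),
            sigma2=float(self.sigma2.mean()),
            sigma_theta2=float(self.sigma_theta2.mean()),
        )


def _distances(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Pairwise ||u_j - v_i||, shape (N, R)."""
    return np.linalg.norm(U[None, :, :] - V[:, None, :], axis=2)


def log_likelihood(Y: GroupRepMatrix | np.ndarray, params: LsirmParams) -> float:
    """Sum of Normal log-densities of all cells of Y under the model."""
    y = Y.values if isinstance(Y, GroupRepMatrix) else np.asarray(Y, dtype=float)
    mean = params.theta[None, :] + params.beta[:, None] - _distances(params.U, params.V)
    if y.shape != mean.shape:
        raise ValueError(f"data shape {y.shape} does not match parameters {mean.shape}")
    s2 = params.sigma2
    resid = y - mean
    return float(-0.5 * y.size * np.log(2 * np.pi * s2) - np.sum(resid**2) / (2 * s2))


def run_mcmc(
    Y: GroupRepMatrix | np.ndarray,
    cfg: McmcConfig | None = None,
    init: dict | None = None,
    frozen: Iterable[str] = (),
    align: bool = True,
) -> LsirmPosterior:
    """Metropolis-within-Gibbs sampler for the continuous LSIRM.

    Parameters
    ----------
    Y : GroupRepMatrix or ndarray (n_subjects, n_rois)
    cfg : McmcConfig
    init : dict, optional
        Initial values for any of ``theta, beta, U, V, sigma2,
        sigma_theta2`` (others drawn from their priors with the run seed).
    frozen : iterable of str, optional
        Parameter blocks to hold fixed at their initial values (useful for
        conjugate-reduction checks).
    align : bool
        Procrustes-align retained position draws to the first retained
        draw (default True).
    """
    cfg = cfg or McmcConfig()
    if isinstance(Y, GroupRepMatrix):
        y = Y.values
        roi_labels = list(Y.roi_labels)
        subject_ids = list(Y.subject_ids)
    else:
        y = np.asarray(Y, dtype=float)
        roi_labels = [f"ROI_{j + 1:03d}" for j in range(y.shape[1])]
        subject_ids = [f"S{i:03d}" for i in range(y.shape[0])]
    if not np.isfinite(y).all():
        raise ValueError("Y contains non-finite values")
    N, R = y.shape
    d = cfg.latent_dim
    frozen = set(frozen)
    rng = np.random.default_rng(cfg.seed)
    init = dict(init or {})

    sigma_theta2 = float(init.get("sigma_theta2", 1.0))
    theta = np.asarray(
        init.get("theta", rng.normal(0, np.sqrt(sigma_theta2), R)), dtype=float
    ).copy()
    beta = np.asarray(
        init.get("beta", rng.normal(0, cfg.beta_prior_sd, N)), dtype=float
    ).copy()
    U = np.asarray(
        init.get("U", rng.normal(0, cfg.latent_prior_sd, (R, d))), dtype=float
    ).copy()
    V = np.asarray(
        init.get("V", rng.normal(0, cfg.latent_prior_sd, (N, d))), dtype=float
    ).copy()
    sigma2 = float(init.get("sigma2", 1.0))

    dist = _distances(U, V)
    resid = y - theta[None, :] - beta[:, None] + dist  # y - mean

    S = cfg.n_retained
    out_theta = np.empty((S, R))
    out_beta = np.empty((S, N))
    out_U = np.empty((S, R, d))
    out_V = np.empty((S, N, d))
    out_s2 = np.empty(S)
    out_st2 = np.empty(S)
    acc = {"theta": 0, "beta": 0, "U": 0, "V": 0}
    tot = {"theta": 0, "beta": 0, "U": 0, "V": 0}
    rw = cfg.proposal == "random_walk"
    s = 0

    for it in range(1, cfg.n_iterations + 1):
        # --- theta_j: likelihood factorizes over columns j ---------------
        if "theta" not in frozen:
            if rw:
                prop = theta + cfg.jump_theta * rng.standard_normal(R)
            else:
                prop = rng.normal(0, np.sqrt(sigma_theta2), R)
            delta = prop - theta
            # new residual in column j is resid - delta_j
            loglik_delta = (
                2 * delta * resid.sum(axis=0) - N * delta**2
            ) / (2 * sigma2)
            if rw:
                logr = loglik_delta - (prop**2 - theta**2) / (2 * sigma_theta2)
            else:  # prior proposal: prior and proposal densities cancel
                logr = loglik_delta
            keep = np.log(rng.random(R)) < logr
            theta[keep] = prop[keep]
            resid[:, keep] -= delta[keep]
            acc["theta"] += int(keep.sum())
            tot["theta"] += R

        # --- sigma_theta2: conjugate Gibbs -------------------------------
        if "sigma_theta2" not in frozen:
            shape = cfg.a_sigma + R / 2.0
            rate = cfg.b_sigma + 0.5 * np.sum(theta**2)
            sigma_theta2 = float(rate / rng.gamma(shape))

        # --- beta_i: likelihood factorizes over rows i -------------------
        if "beta" not in frozen:
            if rw:
                prop = beta + cfg.jump_beta * rng.standard_normal(N)
            else:
                prop = rng.normal(0, cfg.beta_prior_sd, N)
            delta = prop - beta
            loglik_delta = (
                2 * delta * resid.sum(axis=1) - R * delta**2
            ) / (2 * sigma2)
            if rw:
                logr = loglik_delta - (prop**2 - beta**2) / (
                    2 * cfg.beta_prior_sd**2
                )
            else:
                logr = loglik_delta
            keep = np.log(rng.random(N)) < logr
            beta[keep] = prop[keep]
            resid[keep, :] -= delta[keep, None]
            acc["beta"] += int(keep.sum())
            tot["beta"] += N

        # --- u_j: column-wise update -------------------------------------
        if "U" not in frozen:
            if rw:
                propU = U + cfg.jump_u * rng.standard_normal((R, d))
            else:
                propU = rng.normal(0, cfg.latent_prior_sd, (R, d))
            dist_prop = _distances(propU, V)
            # new residual in column j: resid - dist[:, j] + dist_prop[:, j]
            shift = dist_prop - dist
            loglik_delta = -(
                2 * (resid * shift).sum(axis=0) + (shift**2).sum(axis=0)
            ) / (2 * sigma2)
            if rw:
                logr = loglik_delta - (
                    (propU**2).sum(axis=1) - (U**2).sum(axis=1)
                ) / (2 * cfg.latent_prior_sd**2)
            else:
                logr = loglik_delta
            keep = np.log(rng.random(R)) < logr
            U[keep] = propU[keep]
            dist[:, keep] = dist_prop[:, keep]
            resid[:, keep] += shift[:, keep]
            acc["U"] += int(keep.sum())
            tot["U"] += R

        # --- v_i: row-wise update ----------------------------------------
        if "V" not in frozen:
            if rw:
                propV = V + cfg.jump_v * rng.standard_normal((N, d))
            else:
                propV = rng.normal(0, cfg.latent_prior_sd, (N, d))
            dist_prop = _distances(U, propV)
            shift = dist_prop - dist
            loglik_delta = -(
                2 * (resid * shift).sum(axis=1) + (shift**2).sum(axis=1)
            ) / (2 * sigma2)
            if rw:
                logr = loglik_delta - (
                    (propV**2).sum(axis=1) - (V**2).sum(axis=1)
                ) / (2 * cfg.latent_prior_sd**2)
            else:
                logr = loglik_delta
            keep = np.log(rng.random(N)) < logr
            V[keep] = propV[keep]
            dist[keep, :] = dist_prop[keep, :]
            resid[keep, :] += shift[keep, :]
            acc["V"] += int(keep.sum())
            tot["V"] += N

        # --- sigma2: conjugate Gibbs -------------------------------------
        if "sigma2" not in frozen:
            shape = cfg.a_sigma + y.size / 2.0
            rate = cfg.b_sigma + 0.5 * np.sum(resid**2)
            sigma2 = float(rate / rng.gamma(shape))

        if not (np.isfinite(theta).all() and np.isfinite(resid).all()):
            raise RuntimeError(f"divergent (non-finite) state at iteration {it}")

        if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            out_theta[s] = theta
            out_beta[s] = beta
            out_U[s] = U
            out_V[s] = V
            out_s2[s] = sigma2
            out_st2[s] = sigma_theta2
            s += 1

    rates = {
        k: (acc[k] / tot[k]) if tot[k] else float("nan") for k in acc
    }
    post = LsirmPosterior(
        theta=out_theta, beta=out_beta, U=out_U, V=out_V,
        sigma2=out_s2, sigma_theta2=out_st2,
        acceptance_rates=rates,
        roi_labels=roi_labels, subject_ids=subject_ids,
    )
    if align and ("U" not in frozen or "V" not in frozen):
        post.aligned_U, post.aligned_V = procrustes_align(out_U, out_V)
    else:
        post.aligned_U, post.aligned_V = out_U, out_V
    return post


def procrustes_align(
    U_draws: np.ndarray,
    V_draws: np.ndarray,
    reference: np.ndarray | None = None,
    translate: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Align each draw's joint (U, V) configuration to a reference.

    Every draw is rotated/reflected (and, with ``translate=True``,
    recentered) to best match the reference configuration — the first draw
    by default — in the least-squares sense. Relative distances within a
    draw are unchanged.
    """
    if U_draws.shape[0] == 0:
        raise ValueError("no retained draws to align")
    S, R, d = U_draws.shape
    N = V_draws.shape[1]
    joint = np.concatenate([U_draws, V_draws], axis=1)  # (S, R+N, d)
    ref = joint[0].copy() if reference is None else np.asarray(reference, dtype=float)
    if translate:
        ref = ref - ref.mean(axis=0)
    if np.allclose(ref, ref[0]):
        warnings.warn("degenerate reference configuration; identity alignment")
        return U_draws.copy(), V_draws.copy()
    aligned = np.empty_like(joint)
    for t in range(S):
        conf = joint[t]
        if translate:
            conf = conf - conf.mean(axis=0)
        Omega, _ = orthogonal_procrustes(conf, ref)
        aligned[t] = conf @ Omega
    return aligned[:, :R, :], aligned[:, R:, :]


def rotate_positions(U_mean: np.ndarray, gamma: float = 0.0) -> dict:
    """Oblimin rotation of the posterior-mean ROI positions.

    Returns the rotated matrix plus the criterion values and origin
    distances before and after, so interpretability gains are auditable.
    """
    from fcnfusion.rotation import oblimin_criterion

    U_mean = np.asarray(U_mean, dtype=float)
    f_before, _ = oblimin_criterion(U_mean, gamma)
    rotated, T, f_after = oblimin_rotate(U_mean, gamma)
    return {
        "rotated": rotated,
        "rotation": T,
        "criterion_before": f_before,
        "criterion_after": f_after,
        "distance_before": np.linalg.norm(U_mean, axis=1),
        "distance_after": np.linalg.norm(rotated, axis=1),
    }


def origin_proximity(
    posterior: LsirmPosterior,
    radius: float | None = None,
    use_rotated: bool = False,
) -> pd.DataFrame:
    """Rank ROIs by distance of their aligned posterior-mean position
    from the origin.

    Returns a DataFrame (sorted ascending by distance) with columns
    ``roi``, ``distance``, ``rank`` and ``near_origin``. The near-origin
    flag marks the lowest quartile of distances, or — when ``radius`` is
    given — all ROIs within that radius.
    """
    if use_rotated and posterior.rotated_U_mean is not None:
        U_mean = posterior.rotated_U_mean
    else:
        U = posterior.aligned_U if posterior.aligned_U is not None else posterior.U
        U_mean = U.mean(axis=0)
    dists = np.linalg.norm(U_mean, axis=1)
    order = np.argsort(dists, kind="stable")
    R = len(dists)
    flags = np.zeros(R, dtype=bool)
    if radius is not None:
        flags = dists <= radius
    else:
        flags[order[: R // 4]] = True
    return pd.DataFrame(
        {
            "roi": [posterior.roi_labels[j] for j in order],
            "distance": dists[order],
            "rank": np.arange(1, R + 1),
            "near_origin": flags[order],
        }
    )
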
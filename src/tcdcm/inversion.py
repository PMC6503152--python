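"""Variational-Laplace inversion of the spectral forward model.

The generative model for the observed feature vector y — the concatenated
log power spectra of the two conditions — is

    y = h(θ) + ε,   ε ~ N(0, exp(−λ) I),   θ ~ N(0, Σ_prior),

where h maps log-scaling parameters θ (and additive noise log-amplitudes)
through the circuit to predicted log spectra, and λ is the log data
precision with its own Gaussian prior (mean 12: field-potential spectra are
treated as high signal-to-noise features).  Fitting maximizes the Laplace
free energy

    F = −½ e^λ ‖y − h(m)‖² + (n/2) λ − (n/2) ln 2π
        − KL[ N(m, Σ) ‖ N(0, Σ_prior) ] − KL_hyper,

alternating damped Gauss–Newton updates of the posterior mean m (with
Levenberg regularization and free-energy-based step acceptance, so the
accepted F sequence is non-decreasing) with closed-form Newton updates of
λ.  Optimization starts at the prior mean — no random initialization — so
results are deterministic given the data.

Residuals are evaluated on log spectra: the density scale is strongly
heteroscedastic (peaks orders of magnitude above the floor) and log
residuals weight relative misfit evenly across frequencies.

Condition effects B enter only the high-beta prediction (low beta is the
baseline condition whose priors describe the resting operating point).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .circuit import (
    CORTICAL_EDGES,
    THALAMIC_EDGES,
    CircuitParameters,
    ModelSpec,
    PRIOR_SD,
)
from .containers import CrossSpectralData
from .forward import UnstableRegimeError, predict_csd

__all__ = ["Posterior", "invert", "free_energy", "parameter_table", "apply_theta"]


# --------------------------------------------------------------------------
# parameter vector layout


def parameter_table(spec: ModelSpec) -> list[tuple[str, float]]:
    """Ordered (name, prior sd) pairs of all free log-scaling parameters.

    Order: cortical couplings, thalamic couplings, extrinsic couplings,
    time constants, sigmoid slopes, condition effects (modulated edges in
    their canonical order), noise log-amplitudes, observation gain,
    contribution weights.
    """
    rows: list[tuple[str, float]] = []
    for s, t in CORTICAL_EDGES:
        rows.append((f"gamma_mmc:{s}->{t}", PRIOR_SD["gamma_mmc"]))
    for s, t in THALAMIC_EDGES:
        rows.append((f"gamma_tcr:{s}->{t}", PRIOR_SD["gamma_tcr"]))
    lam_edges = [("DP", "REL"), ("DP", "RET")] + list(
        spec.architecture.thalamocortical_edges
    )
    for s, t in lam_edges:
        rows.append((f"lambda:{s}->{t}", PRIOR_SD["lambda"]))
    for pop in ("MP", "SP", "II", "DP"):
        rows.append((f"T:{pop}", PRIOR_SD["T_mmc"]))
    for pop in ("RET", "REL"):
        rows.append((f"T:{pop}", PRIOR_SD["T_tcr"]))
    rows.append(("R_mmc", PRIOR_SD["R_mmc"]))
    rows.append(("R_tcr", PRIOR_SD["R_tcr"]))
    for s, t in spec.modulated_edges:
        rows.append((f"B:{s}->{t}", PRIOR_SD["B"]))
    for name in ("alpha_s", "beta_s", "alpha_c", "beta_c"):
        rows.append((name, PRIOR_SD["noise"]))
    rows.append(("L", PRIOR_SD["L"]))
    for pop in ("SP", "MP", "DP"):
        rows.append((f"J:{pop}", PRIOR_SD["J"]))
    return rows


def apply_theta(
    base: CircuitParameters,
    theta: np.ndarray,
    names: list[str],
    spec: ModelSpec,
) -> CircuitParameters:
    """Scale the base parameters by exp(θ) (noise log-amplitudes add)."""
    p = base.copy()
    lam_edges = [("DP", "REL"), ("DP", "RET")] + list(
        spec.architecture.thalamocortical_edges
    )
    t_order = ["MP", "SP", "II", "DP", "RET", "REL"]
    for name, th in zip(names, theta):
        kind, _, tail = name.partition(":")
        if kind == "gamma_mmc":
            s, t = tail.split("->")
            p.gamma_mmc[CORTICAL_EDGES.index((s, t))] *= np.exp(th)
        elif kind == "gamma_tcr":
            s, t = tail.split("->")
            p.gamma_tcr[THALAMIC_EDGES.index((s, t))] *= np.exp(th)
        elif kind == "lambda":
            s, t = tail.split("->")
            p.lam[lam_edges.index((s, t))] *= np.exp(th)
        elif kind == "T":
            i = t_order.index(tail)
            if i < 4:
                p.T_mmc[i] *= np.exp(th)
            else:
                p.T_tcr[i - 4] *= np.exp(th)
        elif kind == "B":
            s, t = tail.split("->")
            p.B[(s, t)] = p.B.get((s, t), 0.0) + th
        elif kind == "R_mmc":
            p.R_mmc *= np.exp(th)
        elif kind == "R_tcr":
            p.R_tcr *= np.exp(th)
        elif kind in ("alpha_s", "beta_s", "alpha_c", "beta_c"):
            setattr(p, kind, getattr(p, kind) + th)
        elif kind == "L":
            p.L *= np.exp(th)
        elif kind == "J":
            p.J[("SP", "MP", "DP").index(tail)] *= np.exp(th)
        else:
            raise KeyError(f"unknown parameter {name!r}")
    return p


# --------------------------------------------------------------------------
# posterior container


@dataclass
class Posterior:
    """Posterior density over log-scaling parameters plus fit diagnostics."""

    names: list[str]
    mean: np.ndarray
    cov: np.ndarray
    free_energy: float
    log_precision: float
    fit: dict = field(default_factory=dict)
    trace: list = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        if self.mean.shape[0] != len(self.names):
            raise ValueError("mean dimension does not match parameter names")
        if not np.isfinite(self.free_energy):
            raise ValueError("free energy must be finite")
        asym = np.max(np.abs(self.cov - self.cov.T))
        if asym > 1e-8:
            raise ValueError("posterior covariance must be symmetric")
        if np.min(np.linalg.eigvalsh((self.cov + self.cov.T) / 2)) < -1e-8:
            raise ValueError("posterior covariance must be PSD")

    def __getitem__(self, name: str) -> float:
        return float(self.mean[self.names.index(name)])

    def sd(self, name: str) -> float:
        i = self.names.index(name)
        return float(np.sqrt(self.cov[i, i]))

    def credible_interval(self, name: str, level: float = 0.9):
        z = stats.norm.ppf(0.5 + level / 2)
        m, s = self[name], self.sd(name)
        return (m - z * s, m + z * s)

    def b_effects(self) -> dict[str, float]:
        return {n[2:]: self[n] for n in self.names if n.startswith("B:")}


# --------------------------------------------------------------------------
# free energy


def free_energy(
    y: np.ndarray,
    prediction: np.ndarray,
    post_mean: np.ndarray,
    post_cov: np.ndarray,
    prior_mean: np.ndarray,
    prior_cov: np.ndarray,
    log_precision: float,
    hyper_kl: float = 0.0,
) -> float:
    """Laplace free energy: Gaussian log-likelihood minus KL complexity."""
    r = np.asarray(y) - np.asarray(prediction)
    n = r.size
    acc = -0.5 * np.exp(log_precision) * float(r @ r) + 0.5 * n * log_precision
    acc -= 0.5 * n * np.log(2 * np.pi)
    comp = gaussian_kl(post_mean, post_cov, prior_mean, prior_cov)
    return float(acc - comp - hyper_kl)


def gaussian_kl(m1, S1, m0, S0) -> float:
    """KL( N(m1,S1) ‖ N(m0,S0) ), S0 may be given as a diagonal vector."""
    m1 = np.asarray(m1, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    S1 = np.asarray(S1, dtype=float)
    S0 = np.asarray(S0, dtype=float)
    p = m1.size
    if S0.ndim == 1:
        S0 = np.diag(S0)
    S0inv = np.linalg.inv(S0)
    d = m1 - m0
    sign1, logdet1 = np.linalg.slogdet(S1)
    sign0, logdet0 = np.linalg.slogdet(S0)
    if sign1 <= 0 or sign0 <= 0:
        raise np.linalg.LinAlgError("covariance with non-positive determinant")
    return float(
        0.5 * (np.trace(S0inv @ S1) + d @ S0inv @ d - p + logdet0 - logdet1)
    )


# --------------------------------------------------------------------------
# inversion


def _log_prediction(data_freqs, spec, params):
    gL = predict_csd(spec, params, data_freqs, "LB")
    gH = predict_csd(spec, params, data_freqs, "HB")
    return np.concatenate([np.log(gL), np.log(gH)])


def invert(
    data: CrossSpectralData,
    spec: ModelSpec,
    priors: CircuitParameters | None = None,
    free: list[str] | None = None,
    max_iter: int = 128,
    tol: float = 1e-3,
    patience: int = 4,
    fixed_precision: float | None = None,
    fd_step: float = 1e-3,
) -> Posterior:
    """Fit ``spec`` to two-condition spectra; returns the best-F posterior.

    ``free`` restricts optimization to parameters whose names start with
    any of the given prefixes (e.g. ``["B:", "L", "gamma_tcr:"]``);
    everything else is clamped at its prior mean.  ``fixed_precision``
    freezes the log data precision (no hyperparameter step), used by tests.
    """
    if priors is None:
        priors = CircuitParameters.defaults()
    if not data.covers(15.0, 35.0):
        raise ValueError("data must cover the 15-35 Hz band")
    if "LB" not in data.spectra or "HB" not in data.spectra:
        raise ValueError("data must contain both LB and HB conditions")

    table = parameter_table(spec)
    if free is not None:
        table = [row for row in table if any(row[0].startswith(pfx) for pfx in free)]
        if not table:
            raise ValueError("free-parameter selection matched nothing")
    names = [n for n, _ in table]
    prior_sd = np.array([sd for _, sd in table])
    p_dim = len(names)
    mu0 = np.zeros(p_dim)
    C0 = np.diag(prior_sd**2)
    C0inv = np.diag(prior_sd**-2)

    y = np.concatenate(
        [np.log(data.spectra["LB"]), np.log(data.spectra["HB"])]
    )
    n = y.size
    freqs = data.freqs

    eta0, v0 = priors.hE, PRIOR_SD["hE"] ** 2

    def predict(theta):
        params = apply_theta(priors, theta, names, spec)
        return _log_prediction(freqs, spec, params)

    def jacobian(theta, h0):
        J = np.empty((n, p_dim))
        for i in range(p_dim):
            step = fd_step
            for sgn in (1.0, -1.0):
                try:
                    hp = predict(theta + sgn * step * _unit(p_dim, i))
                    J[:, i] = sgn * (hp - h0) / step
                    break
                except (UnstableRegimeError, FloatingPointError):
                    continue
            else:
                raise UnstableRegimeError(
                    f"forward model unstable for perturbations of {names[i]}"
                )
        return J

    def hyper_update(lam, rss, tr_corr=0.0):
        # expected squared error under the posterior includes the
        # tr(J Σ Jᵀ) term — without it the precision is over-estimated and
        # credible intervals under-cover
        if fixed_precision is not None:
            return fixed_precision, 0.0
        rss_eff = rss + tr_corr
        for _ in range(8):
            g = 0.5 * n - 0.5 * np.exp(lam) * rss_eff - (lam - eta0) / v0
            Hm = -0.5 * np.exp(lam) * rss_eff - 1.0 / v0
            step = -g / Hm
            lam = lam + np.clip(step, -2.0, 2.0)
            if abs(step) < 1e-8:
                break
        v_h = 1.0 / (0.5 * np.exp(lam) * rss_eff + 1.0 / v0)
        kl = 0.5 * (v_h / v0 + (lam - eta0) ** 2 / v0 - 1.0 + np.log(v0 / v_h))
        return float(lam), float(kl)

    theta = mu0.copy()
    try:
        h_theta = predict(theta)
    except UnstableRegimeError as err:
        raise UnstableRegimeError(f"prior mean is unstable: {err}") from err
    rss = float((y - h_theta) @ (y - h_theta))
    lam, hyper_kl = (
        (fixed_precision, 0.0) if fixed_precision is not None else (eta0, 0.0)
    )

    def full_F(theta_val, pred, Sigma, lam_val, kl_h):
        return free_energy(y, pred, theta_val, Sigma, mu0, C0, lam_val, kl_h)

    J = jacobian(theta, h_theta)
    lam, hyper_kl = hyper_update(lam, rss, _trace_corr(J, lam, C0inv))
    Sigma = _posterior_cov(J, lam, C0inv)
    F = full_F(theta, h_theta, Sigma, lam, hyper_kl)

    best = dict(theta=theta, pred=h_theta, Sigma=Sigma, lam=lam, F=F, kl=hyper_kl)
    trace = [F]
    lm = 1.0 / 64.0
    stall = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Pi = np.exp(lam)
        g = Pi * (J.T @ (y - h_theta)) - C0inv @ (theta - mu0)
        Hm = Pi * (J.T @ J) + C0inv
        accepted = False
        for _ in range(8):
            try:
                step = np.linalg.solve(Hm + lm * np.diag(np.diag(Hm)), g)
                theta_new = theta + step
                pred_new = predict(theta_new)
            except (UnstableRegimeError, np.linalg.LinAlgError, FloatingPointError):
                lm *= 8.0
                continue
            if not np.all(np.isfinite(pred_new)):
                lm *= 8.0
                continue
            rss_new = float((y - pred_new) @ (y - pred_new))
            J_new = jacobian(theta_new, pred_new)
            lam_new, kl_new = hyper_update(lam, rss_new, _trace_corr(J_new, lam, C0inv))
            Sigma_new = _posterior_cov(J_new, lam_new, C0inv)
            F_new = full_F(theta_new, pred_new, Sigma_new, lam_new, kl_new)
            if F_new > best["F"] - 1e-12:
                accepted = True
                break
            lm *= 8.0
        if not accepted:
            break
        gain = F_new - best["F"]
        theta, h_theta, J, Sigma, lam, hyper_kl, F = (
            theta_new, pred_new, J_new, Sigma_new, lam_new, kl_new, F_new,
        )
        best = dict(theta=theta, pred=h_theta, Sigma=Sigma, lam=lam, F=F, kl=hyper_kl)
        trace.append(F)
        lm = max(lm / 2.0, 1.0 / 512.0)
        stall = stall + 1 if gain < tol else 0
        if stall >= patience:
            converged = True
            break
    else:
        converged = False

    if not converged and it < max_iter:
        # stopped because no acceptable step existed: a (local) optimum
        converged = True

    pred_L = np.exp(best["pred"][: n // 2])
    pred_H = np.exp(best["pred"][n // 2 :])
    fit = {
        "freqs": freqs,
        "predicted": {"LB": pred_L, "HB": pred_H},
        "observed": {"LB": data.spectra["LB"], "HB": data.spectra["HB"]},
        "log_residuals": y - best["pred"],
    }
    return Posterior(
        names=names,
        mean=best["theta"],
        cov=best["Sigma"],
        free_energy=float(best["F"]),
        log_precision=float(best["lam"]),
        fit=fit,
        trace=trace,
        converged=converged,
        n_iter=it,
    )


def _unit(p, i):
    e = np.zeros(p)
    e[i] = 1.0
    return e


def _posterior_cov(J, lam, C0inv):
    Hm = np.exp(lam) * (J.T @ J) + C0inv
    Sigma = np.linalg.inv(Hm)
    return (Sigma + Sigma.T) / 2.0


def _trace_corr(J, lam, C0inv):
    """tr(J Σ Jᵀ): variance of the prediction under the posterior."""
    Sigma = _posterior_cov(J, lam, C0inv)
    return float(np.sum((J @ Sigma) * J))
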
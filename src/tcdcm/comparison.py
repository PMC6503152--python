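"""Fixed-effects Bayesian model comparison, family inference, and a
simplified parametric-empirical-Bayes group stage.

FFX-BMC treats the per-subject free energies as log evidences and sums
them over subjects: under uniform model priors the posterior over models is
the softmax of the summed free energies, and a difference of summed free
energies is a group log Bayes factor.  Family posteriors sum member-model
posteriors; to keep family inference fair when families have unequal sizes
the model prior is uniform over families and uniform within each family.

The group stage is a multivariate random-effects model over subject-level
posterior means m_i with their posterior covariances S_i:

    m_i = μ + b_i + e_i,   b_i ~ N(0, diag(τ²)),   e_i ~ N(0, S_i)

estimated by EM: the group mean is the precision-weighted average with
weights W_i = (S_i + diag(τ²))⁻¹, and τ² is updated from the moments of
the subject-level residuals.  This is the simplest useful form of
hierarchical (empirical Bayes) inference over DCM parameters — a single
group-mean regressor with diagonal between-subject variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .circuit import CircuitParameters, ModelSpec
from .inversion import Posterior
from .model_space import FamilyPartition

__all__ = [
    "ComparisonResult",
    "GroupResult",
    "ffx_bmc",
    "peb_group",
    "condition_effect_report",
]


@dataclass
class ComparisonResult:
    """Group-level model and family posteriors from a free-energy table."""

    free_energy_table: np.ndarray  # subjects × models
    model_posteriors: np.ndarray
    log_bayes_factors: np.ndarray  # vs the best model
    family_posteriors: dict[str, dict] = field(default_factory=dict)

    @property
    def best_model(self) -> int:
        return int(np.argmax(self.model_posteriors))


def ffx_bmc(
    F: np.ndarray,
    families: list[FamilyPartition] | None = None,
) -> ComparisonResult:
    """Fixed-effects comparison of a subjects × models free-energy table."""
    F = np.asarray(F, dtype=float)
    if F.ndim == 1:
        F = F[None, :]
    if not np.all(np.isfinite(F)):
        bad = [(int(i), int(j)) for i, j in np.argwhere(~np.isfinite(F))]
        raise ValueError(f"missing/non-finite free energies at (subject, model): {bad}")

    group_F = F.sum(axis=0)
    log_post = group_F - logsumexp(group_F)
    post = np.exp(log_post)
    post /= post.sum()
    lbf = group_F - group_F.max()

    fam_out: dict[str, dict] = {}
    for part in families or []:
        n_fam = len(part.groups)
        fam_log = {}
        for fam_id, members in part.groups.items():
            members = np.asarray(members)
            # uniform prior over families, uniform within family
            log_prior = -np.log(n_fam) - np.log(members.size)
            fam_log[fam_id] = logsumexp(group_F[members] + log_prior)
        norm = logsumexp(np.array(list(fam_log.values())))
        fam_out[part.factor] = {k: float(np.exp(v - norm)) for k, v in fam_log.items()}

    return ComparisonResult(
        free_energy_table=F,
        model_posteriors=post,
        log_bayes_factors=lbf,
        family_posteriors=fam_out,
    )


@dataclass
class GroupResult:
    """Group-level parameter estimates from the hierarchical stage."""

    names: list[str]
    group_mean: np.ndarray
    group_covariance: np.ndarray
    between_subject_variance: np.ndarray

    def __post_init__(self) -> None:
        if np.min(np.linalg.eigvalsh(
            (self.group_covariance + self.group_covariance.T) / 2
        )) < -1e-10:
            raise ValueError("group covariance must be PSD")

    def __getitem__(self, name: str) -> float:
        return float(self.group_mean[self.names.index(name)])

    def sd(self, name: str) -> float:
        i = self.names.index(name)
        return float(np.sqrt(self.group_covariance[i, i]))


def peb_group(
    posteriors: list[Posterior],
    parameter_subset: list[str] | None = None,
    n_iter: int = 256,
    min_tau2: float = 1e-8,
) -> GroupResult:
    """Hierarchical (random-effects) group estimate over subject posteriors.

    ``parameter_subset`` selects parameters by name prefix (default: the
    couplings, condition effects and time constants — the quantities taken
    to the group level).  Subjects must share the selected ordering.
    """
    if len(posteriors) < 2:
        raise ValueError("need at least 2 subjects")
    if parameter_subset is None:
        parameter_subset = ["gamma_", "lambda:", "B:", "T:"]
    names = [
        n
        for n in posteriors[0].names
        if any(n.startswith(pfx) for pfx in parameter_subset)
    ]
    if not names:
        raise ValueError("parameter subset matched nothing")
    for post in posteriors[1:]:
        sel = [n for n in post.names if any(n.startswith(p) for p in parameter_subset)]
        if sel != names:
            raise ValueError("subjects have inconsistent parameter dimensions/order")

    idx = [posteriors[0].names.index(n) for n in names]
    M = np.array([p.mean[idx] for p in posteriors])  # subjects × p
    Ss = [p.cov[np.ix_(idx, idx)] for p in posteriors]
    n_sub, p_dim = M.shape

    tau2 = np.full(p_dim, 1e-2)
    mu = M.mean(axis=0)
    for _ in range(n_iter):
        Ws = [np.linalg.inv(S + np.diag(tau2)) for S in Ss]
        Wsum = np.sum(Ws, axis=0)
        mu_new = np.linalg.solve(Wsum, np.sum([W @ m for W, m in zip(Ws, M)], axis=0))
        # E-step moments of the subject random effects
        tau_new = np.zeros(p_dim)
        for m, S, W in zip(M, Ss, Ws):
            D = np.diag(tau2)
            gain = D @ W
            b = gain @ (m - mu_new)
            Vb = D - gain @ D
            tau_new += b**2 + np.diag(Vb)
        tau_new = np.maximum(tau_new / n_sub, min_tau2)
        if np.allclose(mu_new, mu, atol=1e-10) and np.allclose(tau_new, tau2, atol=1e-12):
            mu, tau2 = mu_new, tau_new
            break
        mu, tau2 = mu_new, tau_new

    Ws = [np.linalg.inv(S + np.diag(tau2)) for S in Ss]
    cov = np.linalg.inv(np.sum(Ws, axis=0))
    return GroupResult(
        names=names,
        group_mean=mu,
        group_covariance=(cov + cov.T) / 2,
        between_subject_variance=tau2,
    )


def condition_effect_report(
    group: GroupResult,
    spec: ModelSpec,
    priors: CircuitParameters | None = None,
) -> pd.DataFrame:
    """Signed modulation table: per-connection change from low to high beta.

    Absolute couplings are prior-mean × exp(group log-scaling); the
    high-beta coupling additionally carries exp(B).  Positive B means the
    connection strengthens in the high-beta state.
    """
    from .inversion import apply_theta

    if priors is None:
        priors = CircuitParameters.defaults()
    # materialize group-scaled parameters (B handled separately below)
    non_b = [(n, v) for n, v in zip(group.names, group.group_mean) if not n.startswith("B:")]
    params = apply_theta(
        priors,
        np.array([v for _, v in non_b]),
        [n for n, _ in non_b],
        spec,
    )

    from .circuit import _edge_strengths

    strengths = _edge_strengths(spec, params)
    rows = []
    for name in group.names:
        if not name.startswith("B:"):
            continue
        s, t = name[2:].split("->")
        b = group[name]
        lb = strengths[(s, t)]
        rows.append(
            {
                "connection": f"{s}->{t}",
                "B": b,
                "sd": group.sd(name),
                "direction": "increase" if b > 0 else ("decrease" if b < 0 else "none"),
                "coupling_LB": lb,
                "coupling_HB": lb * np.exp(b),
            }
        )
    return pd.DataFrame(rows)
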
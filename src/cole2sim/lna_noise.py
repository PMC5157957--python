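"""Linear-noise (van Kampen) analysis of the reduced titration model.

Expanding the chemical master equation to leading order around the
macroscopic fixed point gives Gaussian fluctuations whose stationary
covariance ``C`` solves the continuous Lyapunov equation

    J C + C Jᵀ + D = 0,

with ``J`` the Jacobian of the deterministic drift and
``D = Σ_r a_r(x*) ν_r ν_rᵀ`` the diffusion matrix of the reaction scheme at
the fixed point.  The headline statistic is the Fano factor of the long
mRNA, ``Var(M)/⟨M⟩``: exactly 1 for an unregulated birth–death process and
peaked near the titration threshold, where all three components coexist at
low copy number.  Only the leading-order (dominant) terms enter the second
moments; this overestimates fluctuations right at the threshold, where copy
numbers are too small for the expansion, so heatmap cells with ⟨M⟩ below a
reliability cutoff are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_continuous_lyapunov

from .gillespie_ssa import EnsembleResult, ReactionSystem, build_reaction_system
from .model_core import RegulationParameters
from .steady_state import steady_state_exact

__all__ = [
    "NoiseSummary",
    "FanoMap",
    "NoiseEstimate",
    "lna_covariance",
    "lna_moments",
    "fano_heatmap",
    "empirical_fano",
    "LNA_RELIABLE_MEAN",
]

#: cells with mean mRNA below this are flagged "LNA-unreliable" in heatmaps
LNA_RELIABLE_MEAN = 5.0


@dataclass(frozen=True)
class NoiseSummary:
    """Stationary LNA means and covariance for the reduced model."""

    mean: np.ndarray  # (M, A, S)
    covariance: np.ndarray  # 3x3, symmetric PSD
    fano_M: float
    fano_A: float
    fano_S: float
    order: int = 1

    def as_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "covariance": self.covariance.tolist(),
            "fano_M": self.fano_M,
            "fano_A": self.fano_A,
            "fano_S": self.fano_S,
            "order": self.order,
        }


def lna_covariance(system: ReactionSystem, x_star: np.ndarray) -> np.ndarray:
    """Stationary LNA covariance of any mass-action scheme at a fixed point."""
    x_star = np.asarray(x_star, dtype=float)
    n = system.n_species
    stoich = system.stoichiometry().astype(float)
    J = np.zeros((n, n))
    D = np.zeros((n, n))
    for r, rxn in enumerate(system.reactions):
        # macroscopic propensity and its gradient (x^order form)
        a = rxn.rate
        grad = np.zeros(n)
        terms = [(system.species_index(s), o) for s, o in rxn.reactants]
        for si, o in terms:
            a *= x_star[si] if o == 1 else 0.5 * x_star[si] ** 2
        for si, o in terms:
            g = rxn.rate
            for sj, oj in terms:
                if sj == si:
                    g *= 1.0 if oj == 1 else x_star[sj]  # d/dx of x or x^2/2
                else:
                    g *= x_star[sj] if oj == 1 else 0.5 * x_star[sj] ** 2
            grad[si] += g
        J += np.outer(stoich[r], grad)
        D += a * np.outer(stoich[r], stoich[r])
    eig = np.linalg.eigvals(J)
    if np.any(eig.real >= -1e-12):
        raise np.linalg.LinAlgError(
            f"non-hyperbolic or unstable fixed point: Jacobian eigenvalues {eig}"
        )
    C = solve_continuous_lyapunov(J, -D)
    return 0.5 * (C + C.T)


def lna_moments(params: RegulationParameters, order: int = 1) -> NoiseSummary:
    """Stationary means and LNA covariance of the reduced model.

    Means come from the macroscopic rate equations (the exact stationary
    cubic); the covariance solves the Lyapunov equation at that fixed point.
    ``order`` is the van Kampen expansion order retained in the second
    moments; only the leading order (1) is implemented.
    """
    if order != 1:
        raise NotImplementedError(
            "only leading-order (dominant-term) second moments are implemented"
        )
    st = steady_state_exact(params)
    x_star = st.as_array()
    system = build_reaction_system(params, "reduced")
    C = lna_covariance(system, x_star)

    def fano(i: int) -> float:
        if x_star[i] <= 0.0:
            return np.nan
        return float(C[i, i] / x_star[i])

    if x_star[0] <= 0.0:
        raise ValueError("fano_M undefined: stationary mean mRNA is zero")
    return NoiseSummary(
        mean=x_star, covariance=C, fano_M=fano(0), fano_A=fano(1), fano_S=fano(2),
        order=order,
    )


@dataclass
class FanoMap:
    """Fano-factor heatmap over an (alpha_M, effective sRNA production) grid."""

    alpha_M_grid: np.ndarray
    srna_production_grid: np.ndarray
    fano_M: np.ndarray  # (n_alpha_M, n_srna)
    mean_M: np.ndarray
    reliable: np.ndarray  # False where mean mRNA < LNA_RELIABLE_MEAN


def fano_heatmap(
    alpha_M_grid, srna_production_grid, params: RegulationParameters
) -> FanoMap:
    """Evaluate the mRNA Fano factor cell by cell over a production-rate grid."""
    alpha_M_grid = np.asarray(alpha_M_grid, dtype=float)
    srna_production_grid = np.asarray(srna_production_grid, dtype=float)
    if np.any(alpha_M_grid <= 0) or np.any(srna_production_grid <= 0):
        raise ValueError("grids must be positive")
    fano = np.full((alpha_M_grid.size, srna_production_grid.size), np.nan)
    mean = np.zeros_like(fano)
    for j, s_eff in enumerate(srna_production_grid):
        base = params.with_srna_production(s_eff)
        for i, aM in enumerate(alpha_M_grid):
            p = base.replace(alpha_M=aM)
            st = steady_state_exact(p)
            mean[i, j] = st.M_star
            if st.M_star > 0:
                system = build_reaction_system(p, "reduced")
                C = lna_covariance(system, st.as_array())
                fano[i, j] = C[0, 0] / st.M_star
    return FanoMap(
        alpha_M_grid=alpha_M_grid,
        srna_production_grid=srna_production_grid,
        fano_M=fano,
        mean_M=mean,
        reliable=mean >= LNA_RELIABLE_MEAN,
    )


@dataclass(frozen=True)
class NoiseEstimate:
    """Empirical Fano estimate with bootstrap standard error."""

    value: float
    stderr: float
    n_realizations: int
    stationary: bool


def empirical_fano(
    ens: EnsembleResult,
    species: str = "M",
    burn_in: float = 0.0,
    n_boot: int = 200,
    seed: int = 0,
) -> NoiseEstimate:
    """Time-and-ensemble pooled Var/mean ratio of a species' copy number.

    Samples after ``burn_in`` are pooled across realizations and time; the
    standard error is bootstrapped over realizations (time samples within a
    realization are autocorrelated, so realizations are the exchangeable
    unit).  Stationarity is checked by a split-half comparison of the
    ensemble mean over the pooled window; a drifting ensemble is flagged and
    a warning emitted.
    """
    keep = ens.t >= burn_in
    if keep.sum() < 4:
        raise ValueError("burn_in leaves too few samples")
    X = ens.series(species)[:, keep].astype(float)
    n = X.shape[0]
    pooled = X.ravel()
    if pooled.mean() <= 0:
        raise ValueError(f"empirical Fano undefined: mean {species} is zero")
    value = pooled.var(ddof=1) / pooled.mean()

    half = X.shape[1] // 2
    m1, m2 = X[:, :half].mean(), X[:, half:].mean()
    per_real = X.mean(axis=1)
    scale = per_real.std(ddof=1) / np.sqrt(n) if n > 1 else np.inf
    stationary = bool(abs(m1 - m2) <= 4.0 * max(scale, 1e-12))
    if not stationary:
        warnings.warn(
            f"split-half means differ ({m1:.3g} vs {m2:.3g}); "
            "ensemble may not be stationary", stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = X[idx].ravel()
        boots[b] = sample.var(ddof=1) / sample.mean() if sample.mean() > 0 else np.nan
    stderr = float(np.nanstd(boots, ddof=1))
    return NoiseEstimate(
        value=float(value), stderr=stderr, n_realizations=n, stationary=stationary
    )
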
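"""Stationary solutions of the reduced titration model and its threshold.

Setting the reduced rate equations to zero and eliminating M and S via

    M* = alpha_M / (delta_M + k_M A*),   S* = N alpha_S / (delta_S + k_S A*)

leaves a single scalar balance for free CsrA,

    f(A) = alpha_A - delta_A A
           - p_M alpha_M k_M A / (delta_M + k_M A)
           - p_S N alpha_S k_S A / (delta_S + k_S A) = 0,

which, multiplied out, is a cubic in A.  f is strictly decreasing with
f(0) = alpha_A >= 0, so the admissible non-negative root is unique.  Dropping
the cubic term gives a quadratic valid at small A (the super-threshold side,
where mRNA and sRNA titrate CsrA away); dropping the constant term gives a
quadratic valid at large A (the sub-threshold side, where CsrA is abundant).
Equating the omitted terms yields the transition criterion between the two
approximations.

The expression threshold itself sits where the large-A branch's CsrA level
crosses zero: in the limit of slow CsrA decay it is the molecular-titration
balance  p_M alpha_M + p_S N alpha_S = alpha_A  (for p = 1 simply
"mRNA production + effective sRNA production = CsrA production").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model_core import RegulationParameters, reduced_derivatives

__all__ = [
    "SteadyState",
    "ThresholdResult",
    "PhaseSurface",
    "steady_state_exact",
    "steady_state_approx",
    "threshold_condition",
    "threshold_locus",
    "phase_surface",
    "ZERO_REPORT_CUTOFF",
]

#: abundances below this many molecules are reported as zero in maps
ZERO_REPORT_CUTOFF = 1e-3


@dataclass(frozen=True)
class SteadyState:
    """Stationary abundances with regime and approximation-branch labels."""

    M_star: float
    A_star: float
    S_star: float
    regime: str  # "sub_threshold" | "super_threshold"
    branch: str  # "low_abundance_approx" | "high_abundance_approx" | "exact_numeric"

    def as_array(self) -> np.ndarray:
        return np.array([self.M_star, self.A_star, self.S_star])


@dataclass(frozen=True)
class ThresholdResult:
    """Threshold classification plus the locus in the (alpha_M, alpha_S) plane."""

    super_threshold: bool
    #: p_M alpha_M + p_S N alpha_S - alpha_A  [molecules/min]; > 0 above threshold
    margin: float
    alpha_A: float
    p_M: float
    p_S: float

    def locus_alpha_M(self, srna_production) -> np.ndarray:
        """alpha_M on the threshold locus for given effective sRNA production.

        The locus is the zero set of the large-A approximate branch,
        ``p_M alpha_M + p_S * (N alpha_S) = alpha_A``.
        """
        srna_production = np.asarray(srna_production, dtype=float)
        return (self.alpha_A - self.p_S * srna_production) / self.p_M


def _cubic_coefficients(params: RegulationParameters) -> tuple[float, float, float, float]:
    """Coefficients (c3, c2, c1, c0) of the stationary cubic in A."""
    p = params
    s = p.N * p.alpha_S
    c3 = -p.delta_A * p.k_M * p.k_S
    c2 = (
        p.k_M * p.k_S * (p.alpha_A - p.p_M * p.alpha_M - p.p_S * s)
        - p.delta_A * (p.delta_M * p.k_S + p.delta_S * p.k_M)
    )
    c1 = (
        p.alpha_A * (p.delta_M * p.k_S + p.delta_S * p.k_M)
        - p.delta_A * p.delta_M * p.delta_S
        - p.p_M * p.alpha_M * p.k_M * p.delta_S
        - p.p_S * s * p.k_S * p.delta_M
    )
    c0 = p.alpha_A * p.delta_M * p.delta_S
    return c3, c2, c1, c0


def _csra_balance(A: float, params: RegulationParameters) -> float:
    p = params
    return (
        p.alpha_A
        - p.delta_A * A
        - p.p_M * p.alpha_M * p.k_M * A / (p.delta_M + p.k_M * A)
        - p.p_S * p.N * p.alpha_S * p.k_S * A / (p.delta_S + p.k_S * A)
    )


def _mrna_srna_from_A(A: float, params: RegulationParameters) -> tuple[float, float]:
    p = params
    if p.delta_M + p.k_M * A > 0:
        M = p.alpha_M / (p.delta_M + p.k_M * A)
    elif p.alpha_M == 0:
        M = 0.0
    else:
        raise ValueError("mRNA has production but no removal pathway: no steady state")
    if p.delta_S + p.k_S * A > 0:
        S = p.N * p.alpha_S / (p.delta_S + p.k_S * A)
    elif p.alpha_S == 0:
        S = 0.0
    else:
        raise ValueError("sRNA has production but no removal pathway: no steady state")
    return M, S


def steady_state_exact(params: RegulationParameters) -> SteadyState:
    """Unique non-negative stationary state from the exact cubic.

    The CsrA balance f(A) is strictly decreasing, so bracketing + Brent's
    method finds the single admissible root to machine precision; M* and S*
    follow exactly from A*.
    """
    regime = (
        "super_threshold" if threshold_condition(params).super_threshold else "sub_threshold"
    )
    if params.alpha_A == 0.0:
        A = 0.0
    else:
        if params.delta_A > 0:
            hi = params.alpha_A / params.delta_A + 1.0
        else:
            hi = 1.0
            while _csra_balance(hi, params) > 0:
                hi *= 2.0
                if hi > 1e15:
                    raise ValueError(
                        "free CsrA diverges: delta_A = 0 with CsrA production "
                        "exceeding total titration capacity"
                    )
        if _csra_balance(hi, params) > 0:  # delta_A > 0 guarantees f(hi) <= 0
            hi = 2.0 * hi + 1.0
        A = brentq(_csra_balance, 0.0, hi, args=(params,), xtol=1e-14, rtol=8.9e-16)
    M, S = _mrna_srna_from_A(A, params)
    st = SteadyState(M, A, S, regime=regime, branch="exact_numeric")
    resid = np.abs(reduced_derivatives((M, A, S), params))
    scale = max(params.alpha_M, params.alpha_A, params.srna_production, 1.0)
    if resid.max() > 1e-6 * scale:
        raise RuntimeError(f"stationary residual too large: {resid} for {params}")
    return st


def _nonneg_quad_roots(a: float, b: float, c: float) -> list[float]:
    """Real non-negative roots of a x^2 + b x + c = 0 (handles degenerate a)."""
    if a == 0.0:
        if b == 0.0:
            return []
        r = -c / b
        return [r] if r >= 0 else []
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return []
    sq = np.sqrt(disc)
    return [r for r in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)) if r >= 0.0]


def steady_state_approx(params: RegulationParameters) -> SteadyState:
    """Two-regime quadratic approximation of the stationary state.

    The low-abundance branch (free CsrA small; super-threshold side) drops
    the cubic term ``c3 A^3``; the high-abundance branch (free CsrA large;
    sub-threshold side) drops the constant term ``c0``.  The branch whose
    omitted term is smaller at its own solution is returned — equating the
    omitted terms is exactly the transition criterion between the two.
    """
    c3, c2, c1, c0 = _cubic_coefficients(params)
    regime = (
        "super_threshold" if threshold_condition(params).super_threshold else "sub_threshold"
    )

    candidates: list[tuple[float, float, str]] = []  # (omitted magnitude, A, branch)
    # low-A branch: c2 A^2 + c1 A + c0 = 0, omitted |c3| A^3
    low_roots = _nonneg_quad_roots(c2, c1, c0)
    if low_roots:
        # the physical small-A root is the smallest non-negative one
        A_low = min(low_roots)
        candidates.append((abs(c3) * A_low**3, A_low, "low_abundance_approx"))
    # high-A branch: c3 A^2 + c2 A + c1 = 0 (cubic divided by A), omitted c0
    high_roots = _nonneg_quad_roots(c3, c2, c1)
    if high_roots:
        A_high = max(high_roots)
        candidates.append((abs(c0), A_high, "high_abundance_approx"))
    if not candidates:
        # degenerate parameter sets (e.g. k = 0) where the cubic collapses:
        # fall back to the exact solution, which handles them directly.
        exact = steady_state_exact(params)
        return SteadyState(
            exact.M_star, exact.A_star, exact.S_star, regime, "exact_numeric"
        )
    _, A, branch = min(candidates, key=lambda c: c[0])
    M, S = _mrna_srna_from_A(A, params)
    return SteadyState(M, A, S, regime=regime, branch=branch)


def threshold_condition(params: RegulationParameters) -> ThresholdResult:
    """Classify the parameter point and expose the threshold locus.

    Above threshold, production of CsrA cannot keep pace with its coupled
    removal by mRNA and sRNA, so free CsrA collapses and the transcript
    accumulates.  The locus is computed from the zero set of the
    high-abundance approximate branch (A* -> 0), which for slow CsrA decay
    reduces to ``p_M alpha_M + p_S N alpha_S = alpha_A``; it is not
    hard-coded for the p = 1 special case.
    """
    margin = (
        params.p_M * params.alpha_M
        + params.p_S * params.srna_production
        - params.alpha_A
    )
    return ThresholdResult(
        super_threshold=bool(margin > 0.0),
        margin=float(margin),
        alpha_A=params.alpha_A,
        p_M=params.p_M,
        p_S=params.p_S,
    )


def threshold_locus(params: RegulationParameters, srna_production_grid) -> np.ndarray:
    """alpha_M on the threshold locus at each effective sRNA production value."""
    return threshold_condition(params).locus_alpha_M(srna_production_grid)


@dataclass
class PhaseSurface:
    """Stationary abundance maps over an (alpha_M, sRNA-production) grid.

    Arrays are indexed ``[i, j]`` with ``i`` over ``alpha_M_grid`` and ``j``
    over ``srna_production_grid``.  ``M``, ``A``, ``S`` hold the raw values;
    :meth:`reported` zeroes abundances below :data:`ZERO_REPORT_CUTOFF`, the
    map-level convention for "zero abundance".
    """

    alpha_M_grid: np.ndarray
    srna_production_grid: np.ndarray
    M: np.ndarray
    A: np.ndarray
    S: np.ndarray
    transition_alpha_M: np.ndarray  # branch-switch line, per srna grid value
    threshold_alpha_M: np.ndarray  # titration threshold line, per srna grid value
    method: str

    def reported(self, species: str) -> np.ndarray:
        arr = getattr(self, species).copy()
        arr[arr < ZERO_REPORT_CUTOFF] = 0.0
        return arr


def _transition_alpha_M(
    params: RegulationParameters, srna_production: float, alpha_M_hi: float
) -> float:
    """alpha_M where the approximation switches branch, at fixed sRNA production."""

    def branch_sign(alpha_M: float) -> float:
        p = params.with_srna_production(srna_production).replace(alpha_M=alpha_M)
        st = steady_state_approx(p)
        return 1.0 if st.branch == "high_abundance_approx" else -1.0

    lo, hi = 0.0, float(alpha_M_hi)
    if branch_sign(lo) == branch_sign(hi):
        return np.nan
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if branch_sign(mid) == branch_sign(lo):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def phase_surface(
    alpha_M_grid,
    srna_production_grid,
    params: RegulationParameters,
    method: str = "approx",
) -> PhaseSurface:
    """Evaluate stationary abundances over a production-rate grid.

    ``method`` selects the approximate two-branch solution (``"approx"``,
    the figure-style surface) or the exact cubic root (``"exact"``).
    """
    alpha_M_grid = np.asarray(alpha_M_grid, dtype=float)
    srna_production_grid = np.asarray(srna_production_grid, dtype=float)
    if np.any(alpha_M_grid < 0) or np.any(srna_production_grid < 0):
        raise ValueError("grids must be non-negative")
    if np.any(np.diff(alpha_M_grid) <= 0) or np.any(np.diff(srna_production_grid) <= 0):
        raise ValueError("grids must be ascending")
    if method not in ("approx", "exact"):
        raise ValueError(f"unknown method {method!r}")
    solver = steady_state_approx if method == "approx" else steady_state_exact

    nm, ns = alpha_M_grid.size, srna_production_grid.size
    M = np.empty((nm, ns))
    A = np.empty((nm, ns))
    S = np.empty((nm, ns))
    for j, s_eff in enumerate(srna_production_grid):
        base = params.with_srna_production(s_eff)
        for i, aM in enumerate(alpha_M_grid):
            st = solver(base.replace(alpha_M=aM))
            M[i, j], A[i, j], S[i, j] = st.M_star, st.A_star, st.S_star

    alpha_M_hi = max(alpha_M_grid[-1], 2.0 * params.alpha_A)
    transition = np.array(
        [
            _transition_alpha_M(params, s_eff, alpha_M_hi)
            for s_eff in srna_production_grid
        ]
    )
    threshold = threshold_locus(params, srna_production_grid)
    return PhaseSurface(
        alpha_M_grid=alpha_M_grid,
        srna_production_grid=srna_production_grid,
        M=M,
        A=A,
        S=S,
        transition_alpha_M=transition,
        threshold_alpha_M=threshold,
        method=method,
    )
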
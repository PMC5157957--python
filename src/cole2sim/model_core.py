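"""Reduced three-component model of colicin E2 post-transcriptional regulation.

The model tracks free long mRNA (``M``), free CsrA dimers (``A``) and a free
effective sRNA (``S``) per cell.  CsrA dimers repress the long transcript by
binding its ribosome-binding region; the sRNAs CsrB/CsrC sequester CsrA.  All
binding/dissociation/degradation pathways of the complexes are folded into an
effective *coupled degradation*: an mRNA–CsrA encounter removes the mRNA and,
with probability ``p_M``, the CsrA dimer as well (likewise ``p_S`` for the
sRNA–CsrA pathway).  The rate equations are

    dM/dt = alpha_M - delta_M * M - k_M * M * A
    dA/dt = alpha_A - delta_A * A - k_M * p_M * M * A - k_S * p_S * A * S
    dS/dt = N * alpha_S - delta_S * S - k_S * A * S

with all rates per cell per minute.  The sRNA species carries a single CsrA
binding site but an N-fold production rate: one real CsrB/CsrC molecule with
``N`` binding sites is book-kept as ``N`` independent one-site molecules.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "RegulationParameters",
    "SystemState",
    "Trajectory",
    "reduced_derivatives",
    "promoter_on_probability",
    "effective_transcription_rate",
    "effective_srna_reduction",
    "integrate_deterministic",
]


# Defaults: printed headline values (alpha_A, effective N*alpha_S, N, n_sos,
# cell volume) plus package defaults for the remaining rates; see
# docs/methods.md for the reasoning behind every number.
@dataclass(frozen=True)
class RegulationParameters:
    """Rate constants of the reduced post-transcriptional model.

    All first-order rates are in 1/min, productions in molecules/min per
    cell, bimolecular rates in 1/(molecule*min).  ``alpha_S`` is the
    production rate of one *real* (multi-site) sRNA molecule; the effective
    one-site production entering the S equation is ``N * alpha_S`` and is
    exposed as :attr:`srna_production`.
    """

    alpha_M: float = 20.0
    alpha_A: float = 58.52
    alpha_S: float = 57.5 / 22.0
    N: float = 22.0
    delta_M: float = 0.2
    delta_A: float = 2.0e-3
    delta_S: float = 0.2
    k_M: float = 4.0
    k_S: float = 4.0
    p_M: float = 1.0
    p_S: float = 1.0
    n_sos: int = 20
    cell_volume: float = 0.65  # µm³, bookkeeping only: rates are per cell

    def __post_init__(self) -> None:
        for name in ("alpha_M", "alpha_A", "alpha_S", "delta_M", "delta_A",
                     "delta_S", "k_M", "k_S"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)!r}")
        for name in ("p_M", "p_S"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N!r}")
        if self.n_sos < 1:
            raise ValueError(f"n_sos must be >= 1, got {self.n_sos!r}")
        if self.cell_volume <= 0:
            raise ValueError("cell_volume must be positive")

    @property
    def srna_production(self) -> float:
        """Effective one-site sRNA production ``N * alpha_S`` [molecules/min]."""
        return self.N * self.alpha_S

    def with_srna_production(self, production: float) -> "RegulationParameters":
        """Return a copy whose effective sRNA production equals ``production``.

        ``N`` is kept fixed and ``alpha_S`` rescaled, so figure-style axes in
        terms of effective production can be scanned without touching the
        binding-site bookkeeping.
        """
        return dataclasses.replace(self, alpha_S=production / self.N)

    def replace(self, **kwargs) -> "RegulationParameters":
        return dataclasses.replace(self, **kwargs)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SystemState:
    """Copy numbers of the three free species at one instant."""

    M: float
    A: float
    S: float
    time: float = 0.0

    def __post_init__(self) -> None:
        if min(self.M, self.A, self.S) < 0:
            raise ValueError(
                f"negative copy numbers not allowed: M={self.M}, A={self.A}, S={self.S}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.M, self.A, self.S], dtype=float)


@dataclass
class Trajectory:
    """Time courses of tracked species on a common, strictly increasing grid."""

    t: np.ndarray
    species: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1 or self.t.size < 1:
            raise ValueError("time grid must be a non-empty 1-d array")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        for name, series in self.species.items():
            series = np.asarray(series)
            if series.shape != self.t.shape:
                raise ValueError(
                    f"series {name!r} has shape {series.shape}, grid has {self.t.shape}"
                )
            self.species[name] = series

    def __getitem__(self, name: str) -> np.ndarray:
        return self.species[name]

    def to_frame(self):
        """Tidy (time, species, value) pandas DataFrame."""
        import pandas as pd

        frames = [
            pd.DataFrame({"time": self.t, "species": name, "value": series})
            for name, series in self.species.items()
        ]
        return pd.concat(frames, ignore_index=True)


def reduced_derivatives(
    state: SystemState | Sequence[float], params: RegulationParameters
) -> tuple[float, float, float]:
    """Right-hand side of the reduced rate equations at ``state``.

    Returns ``(dM/dt, dA/dt, dS/dt)``; rejects negative copy numbers.
    """
    if isinstance(state, SystemState):
        M, A, S = state.M, state.A, state.S
    else:
        M, A, S = (float(x) for x in state)
        if min(M, A, S) < 0:
            raise ValueError("negative state components rejected")
    p = params
    dM = p.alpha_M - p.delta_M * M - p.k_M * M * A
    dA = p.alpha_A - p.delta_A * A - p.k_M * p.p_M * M * A - p.k_S * p.p_S * A * S
    dS = p.N * p.alpha_S - p.delta_S * S - p.k_S * A * S
    return (dM, dA, dS)


def promoter_on_probability(k_on: float, k_off: float, repressor: float) -> float:
    """Stationary unbound fraction of a promoter under fast binding equilibrium.

    A promoter bound by a repressor present at ``repressor`` copies, with
    per-copy binding rate ``k_on`` and unbinding rate ``k_off``, is free a
    fraction ``k_off / (k_off + k_on * repressor)`` of the time.
    """
    if min(k_on, k_off, repressor) < 0:
        raise ValueError("rates and copy numbers must be >= 0")
    denom = k_off + k_on * repressor
    if denom == 0.0:
        # no binding and no unbinding: promoter never leaves its initial
        # state; treat the degenerate case as fully available.
        return 1.0
    return k_off / denom


def effective_transcription_rate(
    per_plasmid_rate: float, on_probability: float, n_sos: int = 20
) -> float:
    """Effective long-mRNA transcription rate ``alpha_M``.

    Adiabatic elimination of the fast promoter state: with ``n_sos`` plasmid
    copies, each transcribing at ``per_plasmid_rate`` while its SOS promoter
    is free, and a stationary free-promoter probability ``on_probability``,
    the slow mRNA dynamics see the single effective rate
    ``n_sos * per_plasmid_rate * on_probability``.
    """
    if not 0.0 <= on_probability <= 1.0:
        raise ValueError(f"on_probability must lie in [0, 1], got {on_probability!r}")
    if per_plasmid_rate < 0:
        raise ValueError("per_plasmid_rate must be >= 0")
    if n_sos < 1:
        raise ValueError("n_sos must be >= 1")
    return n_sos * per_plasmid_rate * on_probability


def effective_srna_reduction(
    N: float, alpha_S: float, complex_rates: Mapping[str, float] | None = None
) -> dict:
    """Collapse an N-site sRNA into the one-site effective parameterization.

    One sRNA molecule carrying ``N`` CsrA binding sites, produced at
    ``alpha_S``, is replaced by one-site effective molecules produced at
    ``N * alpha_S``.  When per-site complex rates are supplied
    (``k_plus`` [1/(molecule min)], ``k_minus`` [1/min], and optionally
    ``delta_complex`` [1/min], defaulting to the sRNA decay folded into the
    caller's model), the effective coupled-degradation rate implied by
    quasi-equilibrated binding is ``k_S = delta_complex * k_plus / k_minus``:
    occupied sites are removed (with their CsrA) at ``delta_complex``, and at
    fast binding equilibrium occupancy per free site is
    ``(k_plus/k_minus) * A``.

    Returns a plain dict so the caller can merge it into its own parameter
    set; the ``assumptions`` entry records that complex (un)binding was taken
    to be fast relative to production and degradation.
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N!r}")
    if alpha_S < 0:
        raise ValueError("alpha_S must be >= 0")
    out = {
        "binding_sites": 1,
        "production": N * alpha_S,
        "alpha_S": alpha_S,
        "N": N,
        "assumptions": (
            "CsrA-sRNA complex binding/unbinding fast relative to "
            "production and degradation (quasi-equilibrium per site)"
        ),
    }
    if complex_rates is not None:
        k_plus = float(complex_rates["k_plus"])
        k_minus = float(complex_rates["k_minus"])
        delta_complex = float(complex_rates.get("delta_complex", np.nan))
        if k_plus < 0 or k_minus <= 0:
            raise ValueError("k_plus must be >= 0 and k_minus > 0")
        out["site_affinity"] = k_plus / k_minus
        if np.isfinite(delta_complex):
            out["k_S"] = delta_complex * k_plus / k_minus
    return out


def integrate_deterministic(
    params: RegulationParameters,
    initial: SystemState,
    t_grid: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> Trajectory:
    """Integrate the reduced rate equations on ``t_grid``.

    Uses an adaptive implicit (LSODA) integrator: the system is stiff near
    threshold, where coupled degradation (k*M*A) is orders of magnitude
    faster than CsrA decay.  The absolute tolerance defaults to 1e-8
    molecules because near-threshold abundances are O(1) or below.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")

    def rhs(t, y):
        M, A, S = y
        p = params
        return (
            p.alpha_M - p.delta_M * M - p.k_M * M * A,
            p.alpha_A - p.delta_A * A - p.k_M * p.p_M * M * A - p.k_S * p.p_S * A * S,
            p.N * p.alpha_S - p.delta_S * S - p.k_S * A * S,
        )

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        initial.as_array(),
        method="LSODA",
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"deterministic integration failed: {sol.message} "
            f"(params={params}, initial={initial})"
        )
    y = np.clip(sol.y, 0.0, None)  # solver noise may dip below 0 by < atol
    if np.any(sol.y < -10 * max(atol, 1e-12)):
        raise RuntimeError("integration produced significantly negative abundances")
    return Trajectory(
        t=sol.t,
        species={"M": y[0], "A": y[1], "S": y[2]},
        metadata={"solver": "LSODA", "rtol": rtol, "atol": atol,
                  "parameters": params.as_dict()},
    )
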
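"""Equilibrium miRNA binding-site occupancy over classed site pools.

One miRNA species is partitioned at thermodynamic equilibrium between a free
pool and site pools of differing affinity (seed-match classes). Free miRNA
``m`` satisfies the conservation relation

    m_total = m + sum_c N_c * m / (Kd_c + m)

which is strictly increasing in ``m``, so the physical root is unique and is
found by bracketed root-finding on [0, m_total]. Class occupancy is then
``m / (m + Kd_c)``. Each time point is an independent equilibrium; binding
kinetics across time (turnover, dilution, catalysis) belong to the circuit
model, not here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .census import MreCensus
from .io_formats import ValidationError

logger = logging.getLogger("cerna_emt")

#: Default dissociation constants (copies/cell). The absolute scale is a free
#: parameter of the analysis; the ordering 8mer < 7mer-m8 < 7mer-A1 < other
#: (tightest to weakest) follows the known affinity ranking of seed classes.
DEFAULT_KD = {"8mer": 25.0, "7mer-m8": 125.0, "7mer-A1": 625.0, "other": 3125.0}


@dataclass(frozen=True)
class OccupancyParams:
    """Dissociation constants per site class and solver settings."""

    kd_per_class: dict = field(default_factory=lambda: dict(DEFAULT_KD))
    solver_tol: float = 1e-10
    max_iter: int = 200

    def __post_init__(self):
        if self.solver_tol <= 0:
            raise ValidationError("solver_tol must be > 0")
        if any(kd <= 0 for kd in self.kd_per_class.values()):
            raise ValidationError("all Kd must be > 0")

    def kd(self, site_class: str) -> float:
        try:
            return self.kd_per_class[site_class]
        except KeyError:
            raise ValidationError(f"no Kd configured for site class {site_class!r}") from None


@dataclass(frozen=True)
class OccupancyResult:
    """Occupancy trajectories for one census variant.

    occupancy and bound arrays have shape (n_classes, n_times); occupancy
    entries lie in [0, 1] and free + total bound equals total miRNA within
    solver tolerance at every time.
    """

    times: np.ndarray
    site_classes: tuple
    free_mirna: np.ndarray
    occupancy: np.ndarray
    bound_per_class: np.ndarray
    total_mirna: np.ndarray
    variant_label: str = "full"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ci, c in enumerate(self.site_classes):
            for ti, t in enumerate(self.times):
                rows.append(
                    (t, c, self.free_mirna[ti], self.occupancy[ci, ti], self.variant_label)
                )
        return pd.DataFrame(
            rows, columns=["time_h", "site_class", "free_mirna", "occupancy", "variant"]
        )

    def class_occupancy(self, site_class: str) -> np.ndarray:
        return self.occupancy[self.site_classes.index(site_class)]


def _conservation_residual(free: float, total: float, pools: np.ndarray, kds: np.ndarray) -> float:
    return free + np.sum(pools * free / (kds + free)) - total


def solve_free_mirna(total_mirna: float, site_pools: dict, params: OccupancyParams) -> float:
    """Free miRNA at equilibrium given total miRNA and per-class site pools."""
    if total_mirna < 0:
        raise ValidationError("total_mirna must be >= 0")
    pools = np.array([max(0.0, site_pools.get(c, 0.0)) for c in site_pools])
    kds = np.array([params.kd(c) for c in site_pools])
    if total_mirna == 0 or pools.sum() == 0:
        return float(total_mirna)
    lo, hi = 0.0, float(total_mirna)
    f_lo = _conservation_residual(lo, total_mirna, pools, kds)
    f_hi = _conservation_residual(hi, total_mirna, pools, kds)
    if f_lo > 0 or f_hi < 0:  # cannot happen for a monotone conservation law
        raise ValidationError("conservation residual does not bracket a root")
    free = brentq(
        _conservation_residual,
        lo,
        hi,
        args=(total_mirna, pools, kds),
        xtol=params.solver_tol * max(1.0, total_mirna),
        rtol=max(params.solver_tol, 4 * np.finfo(float).eps),
        maxiter=params.max_iter,
    )
    residual = abs(_conservation_residual(free, total_mirna, pools, kds))
    if residual > 1e-6 * max(1.0, total_mirna):
        raise ValidationError(f"occupancy solver did not converge; residual {residual:.3g}")
    return float(free)


def occupancy_timecourse(
    census: MreCensus, mirna_copies, params: OccupancyParams | None = None
) -> OccupancyResult:
    """Per-time equilibrium occupancy of every site class in a census.

    ``mirna_copies`` is either an array aligned with ``census.times`` or a
    (times, copies) pair to be linearly interpolated onto the census times.
    """
    params = params or OccupancyParams()
    if census.unit_tag != "COPIES":
        raise ValidationError("occupancy model needs a copies/cell census (anchor it first)")
    if isinstance(mirna_copies, tuple):
        src_t, src_v = (np.asarray(a, dtype=float) for a in mirna_copies)
        totals = np.interp(census.times, src_t, src_v)
        logger.info("interpolated miRNA copies onto %d census times", census.times.size)
    else:
        totals = np.asarray(mirna_copies, dtype=float)
        if totals.shape != census.times.shape:
            raise ValidationError(
                f"mirna_copies length {totals.size} != census times {census.times.size}"
            )
    if np.any(totals < 0):
        raise ValidationError("negative miRNA copy number")

    classes = census.site_classes
    kds = np.array([params.kd(c) for c in classes])
    n_t = census.times.size
    free = np.empty(n_t)
    occ = np.empty((len(classes), n_t))
    bound = np.empty((len(classes), n_t))
    totals_mat = census.per_class_totals
    for j in range(n_t):
        pools = {c: totals_mat[ci, j] for ci, c in enumerate(classes)}
        free[j] = solve_free_mirna(totals[j], pools, params)
        occ[:, j] = free[j] / (free[j] + kds)
        bound[:, j] = totals_mat[:, j] * occ[:, j]
    return OccupancyResult(
        times=census.times,
        site_classes=classes,
        free_mirna=free,
        occupancy=occ,
        bound_per_class=bound,
        total_mirna=totals,
        variant_label=census.variant_label,
    )


def ablate_gene(census: MreCensus, gene_id: str) -> MreCensus:
    """Counterfactual census with one gene's MREs removed from every pool."""
    if gene_id not in census.gene_ids:
        raise ValidationError(f"gene {gene_id!r} not in census")
    gi = census.gene_ids.index(gene_id)
    contrib = census.per_gene_contrib.copy()
    contrib[gi] = 0.0
    return replace(census, per_gene_contrib=contrib, variant_label=f"minus:{gene_id}")


def equilibrium_oracle(
    total_mirna: float,
    site_pools: dict,
    kon_per_class: dict,
    koff_per_class: dict,
    t_end: float = 5000.0,
) -> dict:
    """Brute-force mass-action relaxation to equilibrium (validation oracle).

    Integrates d(bound_c)/dt = kon_c * free * (N_c - bound_c) - koff_c * bound_c
    to steady state and reports occupancy per class. Used only to cross-check
    the algebraic solver; Kd_c = koff_c / kon_c must match the params under test.
    """
    classes = list(site_pools)
    pools = np.array([site_pools[c] for c in classes], dtype=float)
    kon = np.array([kon_per_class[c] for c in classes], dtype=float)
    koff = np.array([koff_per_class[c] for c in classes], dtype=float)

    def rhs(_t, bound):
        free = total_mirna - bound.sum()
        return kon * free * (pools - bound) - koff * bound

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        np.zeros(len(classes)),
        method="LSODA",
        rtol=1e-12,
        atol=1e-12,
    )
    bound = sol.y[:, -1]
    with np.errstate(invalid="ignore", divide="ignore"):
        occ = np.where(pools > 0, bound / pools, 0.0)
    return {c: float(o) for c, o in zip(classes, occ)}
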
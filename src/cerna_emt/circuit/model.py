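"""ODE model of the EMT regulatory circuit with an integrated ceRNA.

Two double-negative feedback loops act in cascade: SNAIL1 is translationally
repressed by miR-34 and represses miR-34 transcription; ZEB1 is repressed by
miR-200 through sequestration and degradation of zeb1 mRNA in
zeb1:miR-200 complexes (five sites), while ZEB1 (and SNAIL1) repress miR-200
transcription. Complex degradation recycles a fraction lambda of the bound
miRNA. The ceRNA species (FN1-like) carries one miR-200 site and is
transcribed under Hill control by SNAIL1 and ZEB1; it competes for miR-200
and thereby gates whether ZEB1 can escape miRNA repression.

Exogenous TGF-beta enters as a dimensionless signal activating snail1
transcription. Phenotypes are read from (ZEB1, free miR-200):
E = ZEB1 low and miR-200 high, M = the converse, otherwise hybrid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root
from scipy.stats import qmc

from ..io_formats import ValidationError
from .params import (
    IDX,
    N_SPECIES,
    SPECIES,
    CircuitParams,
    Perturbation,
    Protocol,
)

logger = logging.getLogger("cerna_emt")

_NEG_TOL = -1e-8  # trajectories dipping below this fail the run


def _hill_act(x: float, K: float, n: float):
    """Activating Hill term and its derivative; negative input treated as 0."""
    xc = x if x > 0.0 else 0.0
    xn = xc**n
    Kn = K**n
    denom = Kn + xn
    val = xn / denom
    if xc == 0.0:
        dval = 1.0 / K if n == 1.0 else 0.0
    else:
        dval = n * Kn * xc ** (n - 1.0) / denom**2
    return val, dval


def _reg_factor(x: float, mode: str, leak: float, K: float, n: float):
    """Leaky Hill regulation factor in [leak, 1] and its derivative."""
    if mode == "none":
        return 1.0, 0.0
    a, da = _hill_act(x, K, n)
    if mode == "rep":
        a, da = 1.0 - a, -da
    return leak + (1.0 - leak) * a, (1.0 - leak) * da


class EmtCircuit:
    """The EMT circuit model for one parameterization.

    Methods cover time-course simulation under a signal protocol, steady-state
    location with stability, one-parameter bifurcation scans over the signal,
    phenotype classification and the induction/withdrawal reversibility assay.
    """

    def __init__(self, params: CircuitParams):
        self.params = params

    # ------------------------------------------------------------------
    # right-hand side and Jacobian

    def derivatives(
        self, state: np.ndarray, t: float = 0.0, signal: float = 0.0,
        params: CircuitParams | None = None,
    ) -> np.ndarray:
        p = params or self.params
        x = np.asarray(state, dtype=float)
        if x.shape != (N_SPECIES,):
            raise ValidationError(f"state must have {N_SPECIES} entries, got {x.shape}")
        s, S, m34, z, Z, m = x[:6]
        c = x[6:11]
        f, cf, d, cd = x[11:15]

        AI, _ = _hill_act(signal, p.K_I, p.n_I)
        RSS, _ = _reg_factor(S, "rep", 0.0, p.K_SS, p.n_SS)
        R34, _ = _reg_factor(m34, "rep", 0.0, p.K_34, p.n_34)
        RS34, _ = _reg_factor(S, "rep", 0.0, p.K_S34, p.n_S34)
        RZ34, _ = _reg_factor(Z, "rep", 0.0, p.K_Z34, p.n_Z34)
        ASz, _ = _hill_act(S, p.K_Sz, p.n_Sz)
        AZz, _ = _hill_act(Z, p.K_Zz, p.n_Zz)
        RZm, _ = _reg_factor(Z, "rep", 0.0, p.K_Zm, p.n_Zm)
        RSm, _ = _reg_factor(S, "rep", 0.0, p.K_Sm, p.n_Sm)
        RSf, _ = _reg_factor(S, p.mode_Sf, p.leak_Sf, p.K_Sf, p.n_Sf)
        RZf, _ = _reg_factor(Z, p.mode_Zf, p.leak_Zf, p.K_Zf, p.n_Zf)

        dx = np.zeros(N_SPECIES)
        dx[0] = p.k0_s + p.k_s * AI * RSS - p.g_s * s
        dx[1] = p.k_S * s * R34 - p.g_S * S
        dx[2] = p.k0_34 + p.k_34 * RS34 * RZ34 - p.g_34 * m34

        # zeb1 mRNA / miR-200 complex ladder; c_prev[0] is free zeb1 mRNA
        gc = np.asarray(p.gc)
        lam = np.asarray(p.lam)
        ltr = np.asarray(p.l_trans)
        chain = np.concatenate(([z], c))  # c_0 .. c_5
        bind = p.kon * m * (5.0 - np.arange(5)) * chain[:5]  # B_0..B_4
        unbind = p.koff * np.arange(1, 6) * c  # U_1..U_5

        dx[3] = p.k0_z + p.k_z * ASz + p.k_zZ * AZz - p.g_z * z - bind[0] + unbind[0]
        for i in range(5):  # complexes c_1..c_5
            dc = bind[i] - unbind[i] - gc[i] * c[i]
            if i < 4:
                dc += unbind[i + 1] - bind[i + 1]
            dx[6 + i] = dc
        dx[4] = p.k_Z * (z + float(ltr @ c)) - p.g_Z * Z

        recycled = float(lam * np.arange(1, 6) * gc @ c)
        dx[5] = (
            p.k0_m + p.k_m * RZm * RSm - p.g_m * m
            - bind.sum() + unbind.sum() + recycled
            - p.kon_f * f * m + p.koff_f * cf + p.lam_f * p.g_cf * cf
            - p.kon_d * d * m + p.koff_d * cd + p.lam_d * p.g_cd * cd
        )

        dx[11] = p.k_f * RSf * RZf - p.g_f * f - p.kon_f * f * m + p.koff_f * cf
        dx[12] = p.kon_f * f * m - (p.koff_f + p.g_cf) * cf
        dx[13] = p.k_d - p.g_d * d - p.kon_d * d * m + p.koff_d * cd
        dx[14] = p.kon_d * d * m - (p.koff_d + p.g_cd) * cd
        return dx

    def jacobian(
        self, state: np.ndarray, t: float = 0.0, signal: float = 0.0,
        params: CircuitParams | None = None,
    ) -> np.ndarray:
        p = params or self.params
        x = np.asarray(state, dtype=float)
        s, S, m34, z, Z, m = x[:6]
        c = x[6:11]
        f, cf, d, cd = x[11:15]

        AI, _ = _hill_act(signal, p.K_I, p.n_I)
        RSS, dRSS = _reg_factor(S, "rep", 0.0, p.K_SS, p.n_SS)
        R34, dR34 = _reg_factor(m34, "rep", 0.0, p.K_34, p.n_34)
        RS34, dRS34 = _reg_factor(S, "rep", 0.0, p.K_S34, p.n_S34)
        RZ34, dRZ34 = _reg_factor(Z, "rep", 0.0, p.K_Z34, p.n_Z34)
        ASz, dASz = _hill_act(S, p.K_Sz, p.n_Sz)
        AZz, dAZz = _hill_act(Z, p.K_Zz, p.n_Zz)
        RZm, dRZm = _reg_factor(Z, "rep", 0.0, p.K_Zm, p.n_Zm)
        RSm, dRSm = _reg_factor(S, "rep", 0.0, p.K_Sm, p.n_Sm)
        RSf, dRSf = _reg_factor(S, p.mode_Sf, p.leak_Sf, p.K_Sf, p.n_Sf)
        RZf, dRZf = _reg_factor(Z, p.mode_Zf, p.leak_Zf, p.K_Zf, p.n_Zf)

        gc = np.asarray(p.gc)
        lam = np.asarray(p.lam)
        ltr = np.asarray(p.l_trans)
        sites = 5.0 - np.arange(5)  # free sites on c_0..c_4
        chain = np.concatenate(([z], c))

        J = np.zeros((N_SPECIES, N_SPECIES))
        # snail1 mRNA
        J[0, 0] = -p.g_s
        J[0, 1] = p.k_s * AI * dRSS
        # SNAIL1
        J[1, 0] = p.k_S * R34
        J[1, 1] = -p.g_S
        J[1, 2] = p.k_S * s * dR34
        # miR-34
        J[2, 1] = p.k_34 * dRS34 * RZ34
        J[2, 2] = -p.g_34
        J[2, 4] = p.k_34 * RS34 * dRZ34
        # zeb1 mRNA (c_0)
        J[3, 1] = p.k_z * dASz
        J[3, 4] = p.k_zZ * dAZz
        J[3, 3] = -p.g_z - 5.0 * p.kon * m
        J[3, 5] = -5.0 * p.kon * z
        J[3, 6] = p.koff
        # ZEB1
        J[4, 3] = p.k_Z
        J[4, 4] = -p.g_Z
        J[4, 6:11] = p.k_Z * ltr
        # complexes c_1..c_5 (rows 6..10)
        for i in range(5):
            r = 6 + i
            prev_col = 3 if i == 0 else 5 + i  # c_0 is zeb1 mRNA
            J[r, prev_col] += p.kon * sites[i] * m
            J[r, r] += -p.koff * (i + 1) - gc[i]
            J[r, 5] += p.kon * sites[i] * chain[i]
            if i < 4:
                J[r, r] += -p.kon * sites[i + 1] * m
                J[r, r + 1] += p.koff * (i + 2)
                J[r, 5] += -p.kon * sites[i + 1] * c[i]
        # free miR-200
        J[5, 1] = p.k_m * RZm * dRSm
        J[5, 4] = p.k_m * dRZm * RSm
        J[5, 3] = -5.0 * p.kon * m
        J[5, 5] = (
            -p.g_m - p.kon * float(sites @ chain[:5]) - p.kon_f * f - p.kon_d * d
        )
        for i in range(5):
            col = 6 + i
            J[5, col] = p.koff * (i + 1) + lam[i] * (i + 1) * gc[i]
            if i < 4:
                J[5, col] -= p.kon * sites[i + 1] * m
        J[5, 11] = -p.kon_f * m
        J[5, 12] = p.koff_f + p.lam_f * p.g_cf
        J[5, 13] = -p.kon_d * m
        J[5, 14] = p.koff_d + p.lam_d * p.g_cd
        # ceRNA mRNA and complex
        J[11, 1] = p.k_f * dRSf * RZf
        J[11, 4] = p.k_f * RSf * dRZf
        J[11, 11] = -p.g_f - p.kon_f * m
        J[11, 5] = -p.kon_f * f
        J[11, 12] = p.koff_f
        J[12, 11] = p.kon_f * m
        J[12, 5] = p.kon_f * f
        J[12, 12] = -(p.koff_f + p.g_cf)
        # decoy and complex
        J[13, 13] = -p.g_d - p.kon_d * m
        J[13, 5] = -p.kon_d * d
        J[13, 14] = p.koff_d
        J[14, 13] = p.kon_d * m
        J[14, 5] = p.kon_d * d
        J[14, 14] = -(p.koff_d + p.g_cd)
        return J

    # ------------------------------------------------------------------
    # simulation

    def simulate(
        self,
        protocol: Protocol,
        t_span: tuple,
        init: np.ndarray | None = None,
        rtol: float = 1e-8,
        atol: float = 1e-10,
        n_points: int = 301,
    ) -> "Trajectory":
        """Integrate the circuit under a protocol with a stiff-capable solver.

        The timeline is split at every signal or perturbation boundary and
        integrated piecewise so the right-hand side stays autonomous within
        each window. States must stay non-negative (beyond integrator noise);
        a trajectory dipping below -1e-8 fails the run.
        """
        t0, t1 = float(t_span[0]), float(t_span[1])
        lo, hi = protocol.span
        if t0 < lo or t1 > hi:
            raise ValidationError(f"t_span {t_span} outside protocol span {(lo, hi)}")
        x = np.zeros(N_SPECIES) if init is None else np.asarray(init, dtype=float).copy()
        if np.any(x < 0):
            raise ValidationError("negative entry in initial state")
        if t1 == t0:
            return Trajectory(np.array([t0]), x[None, :].copy(), self.params, protocol)

        eval_t = np.linspace(t0, t1, n_points)
        edges = [t0, *protocol.breakpoints(t0, t1), t1]
        times, states = [], []
        for a, b in zip(edges, edges[1:]):
            mid = 0.5 * (a + b)
            sig = protocol.signal(mid)
            p_eff = protocol.effective_params(self.params, mid)
            seg_eval = eval_t[(eval_t >= a) & (eval_t <= b)]
            seg_eval = np.unique(np.concatenate(([a], seg_eval, [b])))
            sol = solve_ivp(
                lambda t, y: self.derivatives(y, t, sig, p_eff),
                (a, b),
                x,
                method="LSODA",
                jac=lambda t, y: self.jacobian(y, t, sig, p_eff),
                rtol=rtol,
                atol=atol,
                t_eval=seg_eval,
                max_step=np.inf,
            )
            if not sol.success:
                raise ValidationError(f"integrator failure in [{a}, {b}] h: {sol.message}")
            if sol.y.min() < _NEG_TOL:
                raise ValidationError(
                    f"trajectory left the positive orthant (min {sol.y.min():.3g})"
                )
            times.append(sol.t)
            states.append(np.clip(sol.y.T, 0.0, None))
            x = states[-1][-1]
        t_all = np.concatenate(times)
        y_all = np.vstack(states)
        keep = np.concatenate(([True], np.diff(t_all) > 0))
        return Trajectory(t_all[keep], y_all[keep], self.params, protocol)

    def relax(
        self, signal: float, init: np.ndarray | None = None, t_max: float = 6000.0,
        params: CircuitParams | None = None,
    ) -> np.ndarray:
        """Long relaxation at constant signal; returns the terminal state."""
        p = params or self.params
        x = np.zeros(N_SPECIES) if init is None else np.asarray(init, dtype=float)
        sol = solve_ivp(
            lambda t, y: self.derivatives(y, t, signal, p),
            (0.0, t_max),
            np.clip(x, 0.0, None),
            method="LSODA",
            jac=lambda t, y: self.jacobian(y, t, signal, p),
            rtol=1e-9,
            atol=1e-11,
        )
        if not sol.success:
            raise ValidationError(f"relaxation failed: {sol.message}")
        return np.clip(sol.y[:, -1], 0.0, None)

    # ------------------------------------------------------------------
    # steady states and bifurcation

    def _canonical_inits(self, signal: float) -> list:
        e_like = np.zeros(N_SPECIES)
        e_like[IDX["miR200"]] = self.params.k0_m / max(self.params.g_m, 1e-6)
        e_like[IDX["miR34"]] = 2.0
        m_like = np.zeros(N_SPECIES)
        m_like[IDX["SNAIL1"]] = 5.0
        m_like[IDX["zeb1_mrna"]] = 1.5
        m_like[IDX["ZEB1"]] = 5.0
        m_like[IDX["cerna_mrna"]] = 5.0
        h_like = np.zeros(N_SPECIES)
        h_like[IDX["SNAIL1"]] = 5.0
        h_like[IDX["miR200"]] = 3.0
        return [e_like, m_like, h_like]

    def find_steady_states(
        self, signal: float, n_starts: int = 24, seed: int = 0,
        params: CircuitParams | None = None,
    ) -> list:
        """Locate steady states at one signal level.

        Starts are the endpoints of long relaxation runs from canonical
        epithelial / mesenchymal / hybrid initial conditions plus
        Latin-hypercube samples over the plausible state range, each polished
        with a damped Newton solve (scipy ``hybr``) using the analytic
        Jacobian. Roots within relative distance 1e-4 are merged. Returns a
        list of (state, stable) pairs with stability from Jacobian eigenvalues.
        """
        p = params or self.params
        fun = lambda y: self.derivatives(y, 0.0, signal, p)
        jac = lambda y: self.jacobian(y, 0.0, signal, p)

        starts = []
        for init in self._canonical_inits(signal):
            try:
                starts.append(self.relax(signal, init, params=p))
            except ValidationError:
                continue
        scale = np.maximum(np.max(starts, axis=0) if starts else np.ones(N_SPECIES), 1e-3)
        n_lhs = max(0, n_starts - len(starts))
        if n_lhs:
            sampler = qmc.LatinHypercube(d=N_SPECIES, seed=seed)
            starts.extend(3.0 * scale * sampler.random(n_lhs))

        found = []
        for x0 in starts:
            sol = root(fun, x0, jac=jac, method="hybr", tol=1e-12)
            x = sol.x
            if not sol.success or np.min(x) < -1e-7:
                continue
            x = np.clip(x, 0.0, None)
            res = np.linalg.norm(fun(x))
            if res > 1e-8 * (1.0 + np.linalg.norm(x)):
                continue
            if any(
                np.linalg.norm(x - y) <= 1e-4 * (1.0 + np.linalg.norm(y))
                for y, _ in found
            ):
                continue
            eigs = np.linalg.eigvals(jac(x))
            stable = bool(np.max(eigs.real) < -1e-9)
            found.append((x, stable))
        if not found:
            logger.warning("no steady state found at signal %.3g", signal)
        found.sort(key=lambda xs: xs[0][IDX["ZEB1"]])
        return found

    def classify_state(self, state: np.ndarray, params: CircuitParams | None = None) -> str:
        """Phenotype from (ZEB1, free miR-200): 'E', 'hybrid' or 'M'."""
        p = params or self.params
        Z = max(float(state[IDX["ZEB1"]]), 0.0)
        m = max(float(state[IDX["miR200"]]), 0.0)
        if Z < p.zeb1_lo and m > p.mir200_hi:
            return "E"
        if Z > p.zeb1_hi and m < p.mir200_lo:
            return "M"
        return "hybrid"

    def bifurcation_scan(
        self,
        signal_range: tuple = (0.0, 3.0),
        n_grid: int = 31,
        n_starts: int = 24,
        seed: int = 0,
    ) -> "BifurcationDiagram":
        """Steady-state branches vs signal by grid scan + multi-start roots.

        States found at one grid level seed the next (poor-man's
        continuation) on top of the fresh multi-start search.
        """
        if n_grid < 2:
            raise ValidationError("n_grid must be >= 2")
        grid = np.linspace(signal_range[0], signal_range[1], n_grid)
        levels = []
        carry = []
        for k, sig in enumerate(grid):
            states = self.find_steady_states(sig, n_starts=n_starts, seed=seed + k)
            fun = lambda y: self.derivatives(y, 0.0, sig)
            jac = lambda y: self.jacobian(y, 0.0, sig)
            for x0 in carry:
                sol = root(fun, x0, jac=jac, method="hybr", tol=1e-12)
                x = np.clip(sol.x, 0.0, None)
                if not sol.success or np.min(sol.x) < -1e-7:
                    continue
                if np.linalg.norm(fun(x)) > 1e-8 * (1.0 + np.linalg.norm(x)):
                    continue
                if any(
                    np.linalg.norm(x - y) <= 1e-4 * (1.0 + np.linalg.norm(y))
                    for y, _ in states
                ):
                    continue
                stable = bool(np.max(np.linalg.eigvals(jac(x)).real) < -1e-9)
                states.append((x, stable))
            states.sort(key=lambda xs: xs[0][IDX["ZEB1"]])
            levels.append(
                [
                    (x, stable, self.classify_state(x))
                    for x, stable in states
                ]
            )
            carry = [x for x, _ in states]
        return BifurcationDiagram(grid, levels)

    # ------------------------------------------------------------------
    # protocols

    def reversibility_assay(
        self,
        induction_hours: float = 168.0,
        withdrawal_hours: float = 72.0,
        perturbations=(),
        signal_level: float = 1.0,
        settle_factor: float = 1.0,
    ) -> tuple:
        """Induce EMT then withdraw the signal; classify both endpoints.

        Mirrors the 7-day TGF-beta induction / 3-day withdrawal protocol.
        Perturbations are applied during the withdrawal phase (their clocks
        start at signal removal). Returns (phenotype_at_induction_end,
        phenotype_at_assay_end).
        """
        if induction_hours <= 0 or withdrawal_hours <= 0:
            raise ValidationError("both assay durations must be > 0")
        t_ind = induction_hours * settle_factor
        t_wd = withdrawal_hours * settle_factor
        shifted = tuple(
            Perturbation(
                p.species, p.kind, p.magnitude,
                t_ind + p.t_start * settle_factor,
                t_ind + (p.t_end * settle_factor if np.isfinite(p.t_end) else np.inf),
                p.absolute,
            )
            for p in perturbations
        )
        protocol = Protocol(
            ((0.0, t_ind, signal_level), (t_ind, t_ind + t_wd, 0.0)),
            shifted,
        )
        init = self.relax(0.0)  # stable epithelial state at zero signal
        traj = self.simulate(protocol, (0.0, t_ind + t_wd), init=init, n_points=201)
        at_induction = self.classify_state(traj.state_at(t_ind))
        at_end = self.classify_state(traj.states[-1])
        return at_induction, at_end


@dataclass(frozen=True)
class Trajectory:
    """Simulated time course: times (h) x state matrix plus provenance."""

    times: np.ndarray
    states: np.ndarray
    params: CircuitParams
    protocol: Protocol

    def state_at(self, t: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.times - t)))
        return self.states[i]

    def series(self, species: str) -> np.ndarray:
        return self.states[:, IDX[species]]

    def total_mir200(self) -> np.ndarray:
        """Free + bound miR-200, complexes weighted by bound-miRNA count."""
        w = np.zeros(N_SPECIES)
        w[IDX["miR200"]] = 1.0
        for i in range(1, 6):
            w[IDX[f"zeb1_c{i}"]] = i
        w[IDX["cerna_c1"]] = 1.0
        w[IDX["decoy_c1"]] = 1.0
        return self.states @ w

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(SPECIES))
        df.insert(0, "time_h", self.times)
        return df


@dataclass(frozen=True)
class BifurcationDiagram:
    """Steady-state branches vs signal with stability flags and phenotypes.

    ``levels[k]`` is a list of (state, stable, phenotype) at ``grid[k]``.
    """

    grid: np.ndarray
    levels: list

    def stable_counts(self) -> np.ndarray:
        return np.array([sum(1 for _, st, _ in lv if st) for lv in self.levels])

    @property
    def max_stable_states(self) -> int:
        counts = self.stable_counts()
        return int(counts.max()) if counts.size else 0

    def stable_phenotypes(self) -> set:
        return {ph for lv in self.levels for _, st, ph in lv if st}

    def has_stable_branch(self, phenotype: str) -> bool:
        return phenotype in self.stable_phenotypes()

    def multistability_windows(self) -> list:
        """Signal intervals where more than one stable state coexists."""
        counts = self.stable_counts()
        windows = []
        start = None
        for sig, n in zip(self.grid, counts):
            if n > 1 and start is None:
                start = sig
            elif n <= 1 and start is not None:
                windows.append((float(start), float(prev)))
                start = None
            prev = sig
        if start is not None:
            windows.append((float(start), float(self.grid[-1])))
        return windows

    def to_dict(self) -> dict:
        return {
            "signal_grid": self.grid.tolist(),
            "max_stable_states": self.max_stable_states,
            "stable_phenotypes": sorted(self.stable_phenotypes()),
            "multistability_windows": self.multistability_windows(),
            "branches": [
                [
                    {
                        "state": x.tolist(),
                        "stable": st,
                        "phenotype": ph,
                    }
                    for x, st, ph in lv
                ]
                for lv in self.levels
            ],
        }
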
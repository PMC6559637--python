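"""Steady-state oxygen transport solver.

The model is Fick diffusion with a zero-order sink confined to the
photoreceptor inner segments (IS):

    div(D grad c) = Q * [cell in IS and active]

with a fixed concentration c_chor on the basal face (choriocapillaris), a
constant influx J_ret on the apical tissue face (deep retinal capillary
plexus), and zero flux on lateral boundaries and the symmetry axis.

Zero-order consumption can drive the unconstrained solution negative, which
is unphysical.  Non-negativity is enforced by an active-set iteration: cells
driven negative have their consumption deactivated and their concentration
clamped to zero; a clamped cell is reactivated when the diffusive supply it
receives exceeds what its (capped) consumption can absorb.  At the fixed
point the solution satisfies the complementarity conditions of the obstacle
problem: c > 0 with full consumption, or c = 0 with consumption equal to
the local supply (<= Q per volume).

Discretization is cell-centered finite volumes on structured grids: an
axisymmetric (r, z) grid with the radial metric, solved with a symmetric
banded Cholesky factorization, and a 3D grid solved with a sparse direct or
preconditioned conjugate-gradient method.  Finite volumes make the discrete
conservation audit exact to roundoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solveh_banded
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import cg, LinearOperator

from .geometry import AxiGrid, DomainLabelField, Grid3D, Label
from .units_params import ModelParams, conc_to_po2

log = logging.getLogger(__name__)

__all__ = [
    "SolverSettings",
    "OxygenField",
    "BalanceReport",
    "solve_steady_state",
    "analytic_1d_profile",
    "analytic_1d_min",
    "mass_balance",
    "min_po2_by_column",
]

@dataclass(frozen=True)
class SolverSettings:
    """Numerical controls for the steady-state solve."""

    linear_tolerance: float = 1e-10
    active_set_max_iters: int = 50
    anoxia_clamp_floor: float = 0.0
    convergence_check: bool = False

    def __post_init__(self):
        if not (0 < self.linear_tolerance <= 1e-4):
            raise ValueError("linear_tolerance must be in (0, 1e-4]")
        if self.active_set_max_iters < 1:
            raise ValueError("active_set_max_iters must be >= 1")


@dataclass
class OxygenField:
    """Converged steady-state soluble oxygen field.

    ``concentration`` is mol/m^3 on the grid (NaN outside tissue);
    ``active_consumption_mask`` marks IS cells whose sink is applied;
    ``clamped_mask`` marks cells held at zero by the non-negativity rule.
    """

    domains: DomainLabelField
    concentration: np.ndarray
    active_consumption_mask: np.ndarray
    clamped_mask: np.ndarray
    params_used: ModelParams
    settings_used: SolverSettings = field(default_factory=SolverSettings)

    @property
    def grid(self):
        return self.domains.grid

    def po2(self) -> np.ndarray:
        """Partial-pressure field in mmHg (NaN outside tissue)."""
        c = np.where(self.domains.tissue_mask, self.concentration, 0.0)
        p = conc_to_po2(c, self.params_used)
        return np.where(self.domains.tissue_mask, p, np.nan)

    def min_po2(self) -> float:
        return float(np.nanmin(self.po2()))


@dataclass(frozen=True)
class BalanceReport:
    """Conservation audit of a converged steady state (all mol/s)."""

    influx_choroid: float
    influx_retinal: float
    total_consumption: float
    relative_imbalance: float


# ----------------------------------------------------------------- analytic

def _flux_split(params: ModelParams):
    """Downward flux (mol/m^2/s) carried by the sub-IS passive path when the
    whole IS consumes: choroid supplies Q*h_IS - J_ret of the column demand."""
    return params.consumption_rate_is * params.height_is * 1e-6 - params.retinal_flux


def analytic_1d_profile(params: ModelParams, z_um, extra_passive_um: float = 0.0):
    """Closed-form laminar (druse-free) steady-state concentration profile.

    Piecewise in depth z (μm above the choroid boundary): linear across the
    passive sub-IS path (thickness h1 = height_sub_is + extra_passive_um),
    quadratic across the consuming IS, linear with slope J_ret/D across
    ONL+OPL.  The profile is the *unconstrained* solution: it may dip below
    zero, which the discrete solver's clamp would truncate; callers can
    detect that with :func:`analytic_1d_min`.
    """
    D = params.diffusion_coefficient
    Q = params.consumption_rate_is
    J = params.retinal_flux
    F0 = _flux_split(params)
    h1 = (params.height_sub_is + extra_passive_um) * 1e-6
    h_is = params.height_is * 1e-6
    h2 = h1 + h_is
    h3 = h2 + params.height_onl_opl * 1e-6

    z = np.asarray(z_um, dtype=float) * 1e-6
    c1 = params.choroid_concentration - F0 * np.minimum(z, h1) / D
    zi = np.clip(z - h1, 0.0, h_is)
    c2 = (-F0 * zi + 0.5 * Q * zi**2) / D
    zo = np.clip(z - h2, 0.0, h3 - h2)
    c3 = J * zo / D
    out = np.where(z <= h3, c1 + c2 + c3, np.nan)
    return float(out) if out.ndim == 0 else out


def analytic_1d_min(params: ModelParams, extra_passive_um: float = 0.0):
    """Location (μm) and value (mol/m^3) of the unconstrained 1D minimum.

    Returns ``(z_min_um, c_min, anoxic)`` where ``anoxic`` flags a negative
    unconstrained minimum (the clamped solution would contain a zero set).
    """
    D = params.diffusion_coefficient
    Q = params.consumption_rate_is
    F0 = _flux_split(params)
    h1 = (params.height_sub_is + extra_passive_um) * 1e-6
    h_is = params.height_is * 1e-6
    z_star = h1 + np.clip(F0 / Q, 0.0, h_is)
    candidates = np.array([h1, z_star, h1 + h_is]) * 1e6
    vals = analytic_1d_profile(params, candidates, extra_passive_um)
    k = int(np.argmin(vals))
    c_min = float(vals[k])
    return float(candidates[k]), c_min, c_min < 0


# ------------------------------------------------------- axisymmetric solve

class _AxiSystem:
    """Finite-volume operator on a full rectangular (r, z) grid.

    Non-tissue and clamped cells are kept in the system as identity rows so
    the matrix stays uniformly banded (bandwidth n_z) and symmetric positive
    definite, solvable with LAPACK's banded Cholesky.
    """

    def __init__(self, domains: DomainLabelField, params: ModelParams):
        grid: AxiGrid = domains.grid
        self.grid = grid
        self.labels = domains.labels
        self.tissue = domains.tissue_mask
        if not self.tissue[:, 0].all():
            raise ValueError("axisymmetric tissue must start at z = 0 in every column")
        n_r, n_z = grid.n_r, grid.n_z
        dr = grid.dr * 1e-6
        dz = grid.dz * 1e-6
        D = params.diffusion_coefficient
        r_in = np.arange(n_r) * dr
        r_out = r_in + dr
        self.A_ax = np.pi * (r_out**2 - r_in**2)          # axial face area per ring
        self.V = self.A_ax * dz                            # cell volume per ring
        self.g_ax = D * self.A_ax / dz                     # (i,k)-(i,k+1)
        self.g_rad = D * (2 * np.pi * r_out * dz) / dr     # (i,k)-(i+1,k)
        self.g_bot = D * self.A_ax / (dz / 2)
        self.params = params
        # topmost tissue cell per column
        self.k_top = self.tissue.shape[1] - 1 - np.argmax(self.tissue[:, ::-1], axis=1)
        self.QV = np.where(
            self.labels == Label.IS, params.consumption_rate_is * self.V[:, None], 0.0
        )

    def solve(self, clamped: np.ndarray) -> np.ndarray:
        n_r, n_z = self.grid.n_r, self.grid.n_z
        S = self.tissue & ~clamped
        ga = np.broadcast_to(self.g_ax[:, None], (n_r, n_z - 1))
        gr = np.broadcast_to(self.g_rad[:-1, None], (n_r - 1, n_z))

        diag = np.where(S, 0.0, 1.0)
        off_ax = np.zeros((n_r, n_z))
        off_rad = np.zeros((n_r, n_z))
        rhs = np.zeros((n_r, n_z))

        pair = S[:, :-1] & S[:, 1:]
        diag[:, :-1] += ga * pair
        diag[:, 1:] += ga * pair
        diag[:, :-1] += ga * (S[:, :-1] & clamped[:, 1:])
        diag[:, 1:] += ga * (clamped[:, :-1] & S[:, 1:])
        off_ax[:, :-1] = -ga * pair

        pair = S[:-1, :] & S[1:, :]
        diag[:-1, :] += gr * pair
        diag[1:, :] += gr * pair
        diag[:-1, :] += gr * (S[:-1, :] & clamped[1:, :])
        diag[1:, :] += gr * (clamped[:-1, :] & S[1:, :])
        off_rad[:-1, :] = -gr * pair

        bot = S[:, 0]
        diag[:, 0] += self.g_bot * bot
        rhs[:, 0] += self.g_bot * self.params.choroid_concentration * bot

        cols = np.arange(n_r)
        top_open = S[cols, self.k_top]
        rhs[cols[top_open], self.k_top[top_open]] += (
            self.params.retinal_flux * self.A_ax[top_open]
        )

        rhs -= np.where(S, self.QV * ~clamped, 0.0)

        # order unknowns with the smaller dimension fastest so the bandwidth
        # is min(n_r, n_z)
        if n_z <= n_r:
            ab = np.zeros((n_z + 1, n_r * n_z))
            ab[0] = diag.ravel()
            ab[1] = off_ax.ravel()
            ab[n_z] = off_rad.ravel()
            c = solveh_banded(ab, rhs.ravel(), lower=True)
            return c.reshape(n_r, n_z)
        ab = np.zeros((n_r + 1, n_r * n_z))
        ab[0] = diag.T.ravel()
        ab[1] = off_rad.T.ravel()
        ab[n_r] = off_ax.T.ravel()
        c = solveh_banded(ab, rhs.T.ravel(), lower=True)
        return c.reshape(n_z, n_r).T

    def inflow_to_clamped(self, c: np.ndarray, clamped: np.ndarray) -> np.ndarray:
        """Net diffusive + boundary supply (mol/s) into each clamped cell,
        evaluated with the clamped cell held at zero."""
        n_r, n_z = self.grid.n_r, self.grid.n_z
        ga = np.broadcast_to(self.g_ax[:, None], (n_r, n_z - 1))
        gr = np.broadcast_to(self.g_rad[:-1, None], (n_r - 1, n_z))
        free = self.tissue & ~clamped
        cv = np.where(free, c, 0.0)
        inflow = np.zeros((n_r, n_z))
        inflow[:, :-1] += ga * cv[:, 1:] * (clamped[:, :-1] & free[:, 1:])
        inflow[:, 1:] += ga * cv[:, :-1] * (clamped[:, 1:] & free[:, :-1])
        inflow[:-1, :] += gr * cv[1:, :] * (clamped[:-1, :] & free[1:, :])
        inflow[1:, :] += gr * cv[:-1, :] * (clamped[1:, :] & free[:-1, :])
        inflow[:, 0] += self.g_bot * self.params.choroid_concentration * clamped[:, 0]
        cols = np.arange(n_r)
        top_clamped = clamped[cols, self.k_top]
        inflow[cols[top_clamped], self.k_top[top_clamped]] += (
            self.params.retinal_flux * self.A_ax[top_clamped]
        )
        return inflow


# ---------------------------------------------------------------- 3D solve

class _Cart3DSystem:
    """Finite-volume operator on a 3D grid with tissue-only unknowns."""

    def __init__(self, domains: DomainLabelField, params: ModelParams):
        grid: Grid3D = domains.grid
        self.grid = grid
        self.labels = domains.labels
        self.tissue = domains.tissue_mask
        dxy = grid.spacing_xy * 1e-6
        dz = grid.spacing_z * 1e-6
        D = params.diffusion_coefficient
        self.A_xy = dxy * dxy
        self.V = self.A_xy * dz
        self.g_z = D * self.A_xy / dz
        self.g_xy = D * (dxy * dz) / dxy
        self.g_bot = D * self.A_xy / (dz / 2)
        self.params = params
        t = self.tissue
        self.has_col = t.any(axis=2)
        nz = grid.n_z
        self.k_top = np.where(self.has_col, nz - 1 - np.argmax(t[:, :, ::-1], axis=2), -1)
        self.k_bot = np.where(self.has_col, np.argmax(t, axis=2), -1)
        self.QV = np.where(self.labels == Label.IS, params.consumption_rate_is * self.V, 0.0)

    def _boundary_masks(self):
        nx, ny, _ = self.tissue.shape
        ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        bot = np.zeros_like(self.tissue)
        top = np.zeros_like(self.tissue)
        m = self.has_col
        bot[ii[m], jj[m], self.k_bot[m]] = True
        top[ii[m], jj[m], self.k_top[m]] = True
        return bot, top

    def solve(self, clamped: np.ndarray, linear_tolerance: float) -> np.ndarray:
        S = self.tissue & ~clamped
        n = int(S.sum())
        idx = -np.ones(S.shape, dtype=np.int64)
        idx[S] = np.arange(n)  # C-order: z fastest, contiguous within a column
        diag = np.zeros(n)
        zlow = np.zeros(n)  # sub-diagonal of the vertical (z-line) part
        rows, cols_, vals = [], [], []

        def couple(sl_a, sl_b, g, vertical=False):
            A, B = S[sl_a], S[sl_b]
            pair = A & B
            ia, ib = idx[sl_a][pair], idx[sl_b][pair]
            rows.append(ia); cols_.append(ib); vals.append(np.full(ia.size, -g))
            rows.append(ib); cols_.append(ia); vals.append(np.full(ia.size, -g))
            np.add.at(diag, ia, g)
            np.add.at(diag, ib, g)
            if vertical:
                adj = ib == ia + 1
                zlow[ia[adj]] = -g
            half = A & clamped[sl_b]
            np.add.at(diag, idx[sl_a][half], g)
            half = clamped[sl_a] & B
            np.add.at(diag, idx[sl_b][half], g)

        couple(np.s_[:-1, :, :], np.s_[1:, :, :], self.g_xy)
        couple(np.s_[:, :-1, :], np.s_[:, 1:, :], self.g_xy)
        couple(np.s_[:, :, :-1], np.s_[:, :, 1:], self.g_z, vertical=True)

        rhs = np.zeros(n)
        bot, top = self._boundary_masks()
        b = bot & S
        np.add.at(diag, idx[b], self.g_bot)
        rhs[idx[b]] += self.g_bot * self.params.choroid_concentration
        t = top & S
        rhs[idx[t]] += self.params.retinal_flux * self.A_xy
        rhs -= self.QV[S]

        rows.append(np.arange(n)); cols_.append(np.arange(n)); vals.append(diag)
        A = coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols_))),
            shape=(n, n),
        ).tocsr()

        # the vertical conductance dominates the lateral one by the squared
        # aspect ratio of the cells, so a z-line (tridiagonal) preconditioner
        # renders CG convergence essentially mesh-independent
        ab = np.vstack([diag, zlow])
        M = LinearOperator((n, n), lambda r: solveh_banded(ab, r, lower=True))
        x, info = cg(A, rhs, rtol=min(linear_tolerance, 1e-11), atol=0.0, maxiter=5000, M=M)
        if info != 0:
            raise RuntimeError(f"conjugate-gradient solve failed (info={info})")
        c = np.zeros(S.shape)
        c[S] = x
        return c

    def inflow_to_clamped(self, c: np.ndarray, clamped: np.ndarray) -> np.ndarray:
        free = self.tissue & ~clamped
        cv = np.where(free, c, 0.0)
        inflow = np.zeros(c.shape)
        for sl_a, sl_b, g in (
            (np.s_[:-1, :, :], np.s_[1:, :, :], self.g_xy),
            (np.s_[:, :-1, :], np.s_[:, 1:, :], self.g_xy),
            (np.s_[:, :, :-1], np.s_[:, :, 1:], self.g_z),
        ):
            inflow[sl_a] += g * cv[sl_b] * (clamped[sl_a] & free[sl_b])
            inflow[sl_b] += g * cv[sl_a] * (clamped[sl_b] & free[sl_a])
        bot, top = self._boundary_masks()
        inflow[bot & clamped] += self.g_bot * self.params.choroid_concentration
        inflow[top & clamped] += self.params.retinal_flux * self.A_xy
        return inflow


# ----------------------------------------------------------- active set loop

def solve_steady_state(
    domains: DomainLabelField,
    params: ModelParams,
    settings: SolverSettings | None = None,
) -> OxygenField:
    """Solve the clamped steady-state oxygen problem on the given geometry.

    Runs the active-set outer loop: solve the linear system with the current
    consumption set, clamp cells driven negative (deactivating their sink),
    reactivate clamped cells whose supply exceeds their consumption cap, and
    repeat until the sets are stable.
    """
    settings = settings or SolverSettings()
    system = (
        _AxiSystem(domains, params)
        if isinstance(domains.grid, AxiGrid)
        else _Cart3DSystem(domains, params)
    )
    tissue = domains.tissue_mask
    clamped = np.zeros_like(tissue)
    neg_tol = 1e-12 * params.choroid_concentration
    react_tol = 1e-9

    c = None
    for it in range(settings.active_set_max_iters):
        if isinstance(system, _AxiSystem):
            c = system.solve(clamped)
        else:
            c = system.solve(clamped, settings.linear_tolerance)
        neg = tissue & ~clamped & (c < -neg_tol)
        inflow = system.inflow_to_clamped(c, clamped)
        cap = system.QV if isinstance(system, _Cart3DSystem) else system.QV
        react = clamped & (inflow > cap * (1 + react_tol) + neg_tol)
        if not neg.any() and not react.any():
            break
        clamped = (clamped | neg) & ~react
    else:
        raise RuntimeError(
            "active-set iteration did not converge within "
            f"{settings.active_set_max_iters} iterations "
            f"({int(neg.sum())} newly negative, {int(react.sum())} oscillating cells)"
        )

    c = np.where(clamped, 0.0, c)
    c = np.where(tissue, np.maximum(c, 0.0), np.nan)
    active = (domains.labels == Label.IS) & ~clamped
    field = OxygenField(domains, c, active, clamped, params, settings)
    if it > 0:
        log.info("active-set converged in %d iterations; %d clamped cells", it + 1, clamped.sum())
    return field


def _system_for(field: OxygenField):
    return (
        _AxiSystem(field.domains, field.params_used)
        if isinstance(field.grid, AxiGrid)
        else _Cart3DSystem(field.domains, field.params_used)
    )


def mass_balance(field: OxygenField, params: ModelParams | None = None) -> BalanceReport:
    """Audit discrete conservation of a converged field.

    Integrates the Dirichlet-face influx, the Neumann-face influx, and the
    total applied consumption (full-rate on active cells plus the absorbed
    supply of clamped cells); a converged finite-volume solution balances
    these to roundoff.
    """
    params = params or field.params_used
    system = _system_for(field)
    c = np.where(field.domains.tissue_mask, np.nan_to_num(field.concentration), 0.0)
    clamped = field.clamped_mask
    if isinstance(system, _AxiSystem):
        influx_ch = float(np.sum(system.g_bot * (params.choroid_concentration - c[:, 0])))
        influx_ret = float(np.sum(system.A_ax * params.retinal_flux))
    else:
        bot, top = system._boundary_masks()
        influx_ch = float(
            np.sum(system.g_bot * (params.choroid_concentration - c[bot]))
        )
        influx_ret = float(np.sum(top) * system.A_xy * params.retinal_flux)
    cons_active = float(np.sum(system.QV * field.active_consumption_mask))
    cons_clamped = float(np.sum(system.inflow_to_clamped(c, clamped)[clamped]))
    total = cons_active + cons_clamped
    # capacity of the choroid boundary: the natural flux scale of the problem
    scale = float(np.sum(system.g_bot) * params.choroid_concentration)
    if isinstance(system, _Cart3DSystem):
        scale = system.g_bot * params.choroid_concentration * int(system.has_col.sum())
    if total > 1e-12 * scale:
        imbalance = abs(influx_ch + influx_ret - total) / total
    else:
        imbalance = abs(influx_ch + influx_ret) / scale
    return BalanceReport(influx_ch, influx_ret, total, imbalance)


def min_po2_by_column(field: OxygenField, params: ModelParams | None = None) -> np.ndarray:
    """Per-column minimum pO2 (mmHg) over the z samples.

    Axisymmetric fields give a 1D radial profile; 3D fields give a 2D
    (n_x, n_y) map with NaN where a column has no tissue.  The minimum is
    expected inside the consuming IS; columns violating that are logged.
    """
    params = params or field.params_used
    p = field.po2()
    labels = field.domains.labels
    tissue = field.domains.tissue_mask
    pm = np.where(tissue, p, np.inf)
    kmin = np.argmin(pm, axis=-1)
    out = np.take_along_axis(pm, kmin[..., None], axis=-1)[..., 0]
    has_col = tissue.any(axis=-1)
    out = np.where(has_col, out, np.nan)
    lab_at_min = np.take_along_axis(labels, kmin[..., None], axis=-1)[..., 0]
    bad = has_col & (lab_at_min != Label.IS)
    if bad.any():
        log.warning("per-column minimum outside the IS in %d columns", int(bad.sum()))
    return out
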
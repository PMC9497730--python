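"""Contrast-agent diffusion into a cartilage slab from an iodine bath.

The physical picture: an osteochondral plug sits in a sample holder with a
contrast-agent bath resting on the articular surface. Iodine diffuses into
the cartilage (thickness ``L``, diffusivity ``D``) following Fick's second
law, ``dc/dt = D d2c/dx2`` on ``x in [0, L]``, with

* a partition condition at the articular surface, ``c(0, t) = kappa *
  c_bath(t)`` — the cationic agent is electrostatically attracted to the
  fixed negative charge of the glycosaminoglycans, so its equilibrium
  concentration in cartilage exceeds the bath by the factor ``kappa > 1``;
* a sealed base at the tidemark, ``dc/dx(L, t) = 0`` (subchondral bone is
  impermeable on the experiment's timescale);
* either an infinite bath (``c_bath`` constant) or a finite, well-stirred
  bath of volume ``V_bath`` that depletes as iodine enters the cartilage
  (volume ``V_cart``), conserving total iodine mass.

The solver discretizes depth with a vertex-centered conservative scheme and
propagates it *exactly in time* through the eigendecomposition of the
semi-discrete operator, so arbitrary ragged acquisition-time grids carry no
stability constraint and no time-stepping error. Spatial accuracy is raised
to fourth order by Richardson extrapolation over a node-doubled grid; the
depth integral reported alongside the field uses the quadrature paired with
the discretization, which makes the discrete iodine mass an exact invariant
of the finite-bath system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import eigh

__all__ = [
    "SlabDiffusionConfig",
    "ConcentrationField",
    "solve_slab_diffusion",
    "analytic_mean_uptake",
    "kappa_for_equilibrium",
    "equilibrium_concentrations",
    "PLUG_TIME_GRID_H",
]

#: Planar acquisition time grid (hours): 2, 5, 10, 15, 20, 30, 45 min,
#: then 1, 1.5, 2, 3, 4, 5, 6, 24, 25, 26 h.
PLUG_TIME_GRID_H: tuple[float, ...] = (
    2 / 60, 5 / 60, 10 / 60, 15 / 60, 20 / 60, 30 / 60, 45 / 60,
    1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 24.0, 25.0, 26.0,
)


def kappa_for_equilibrium(
    c_cart_eq: float, c_bath0: float, v_bath: float, v_cart: float
) -> float:
    """Partition coefficient that yields a given equilibrium cartilage
    concentration in a finite bath.

    Solves the algebraic mass balance ``V_bath*c_b_eq + V_cart*c_c_eq =
    V_bath*c_bath0`` together with ``c_c_eq = kappa*c_b_eq`` for ``kappa``.
    """
    residual_bath_mass = v_bath * c_bath0 - v_cart * c_cart_eq
    if residual_bath_mass <= 0:
        raise ValueError("target equilibrium exceeds the total iodine available")
    return c_cart_eq * v_bath / residual_bath_mass


def equilibrium_concentrations(config: "SlabDiffusionConfig") -> tuple[float, float]:
    """(cartilage, bath) equilibrium concentrations for a finite-bath config,
    from the algebraic mass balance (independent of ``D``)."""
    if not config.finite_bath:
        return config.kappa * config.c_bath0, config.c_bath0
    c_b = config.V_bath * config.c_bath0 / (config.V_bath + config.kappa * config.V_cart)
    return config.kappa * c_b, c_b


# Defaults reproduce the bench conditions the simulator emulates: a 0.5 mL,
# 10 mgI/mL bath over a 2 mm / 0.157 mL cartilage layer, with kappa set so the
# cartilage plateaus at 21.2 mgI/mL, and D = 0.6 mm^2/h (~1.7e-6 cm^2/s, the
# order of small-solute diffusivities in cartilage), which puts the fitted
# saturation time of the finite-bath uptake curve at ~2.1 h.
DEFAULT_C_BATH0 = 10.0
DEFAULT_V_BATH = 0.5
DEFAULT_V_CART = 0.157
DEFAULT_L = 2.0
DEFAULT_KAPPA = kappa_for_equilibrium(21.2, DEFAULT_C_BATH0, DEFAULT_V_BATH, DEFAULT_V_CART)
DEFAULT_D = 0.6  # mm^2/h


@dataclass(frozen=True)
class SlabDiffusionConfig:
    """Parameters of the slab-diffusion simulation.

    Units: ``D`` mm^2/h, ``L`` mm, concentrations mgI/mL, volumes mL,
    ``times`` hours. ``kappa`` is dimensionless (cartilage/bath equilibrium
    ratio). ``nx`` is the number of depth nodes of the returned field.
    """

    D: float = DEFAULT_D
    L: float = DEFAULT_L
    c_bath0: float = DEFAULT_C_BATH0
    kappa: float = DEFAULT_KAPPA
    V_bath: float = DEFAULT_V_BATH
    V_cart: float = DEFAULT_V_CART
    finite_bath: bool = True
    times: tuple[float, ...] = PLUG_TIME_GRID_H
    nx: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D <= 0 or self.L <= 0:
            raise ValueError("D and L must be positive")
        if self.c_bath0 < 0:
            raise ValueError("c_bath0 must be nonnegative")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.kappa < 1:
            warnings.warn(
                f"kappa={self.kappa} < 1: cartilage would equilibrate below the "
                "bath, opposite to cationic-agent partitioning",
                stacklevel=3,
            )
        if self.finite_bath and (self.V_bath <= 0 or self.V_cart <= 0):
            raise ValueError("finite bath requires positive V_bath and V_cart")
        t = np.asarray(self.times, dtype=float)
        if t.size == 0:
            raise ValueError("times must be non-empty")
        if t[0] < 0:
            raise ValueError("times must start at t >= 0")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.nx < 10:
            raise ValueError(f"nx={self.nx} too small to resolve the slab (need >= 10)")
        object.__setattr__(self, "times", tuple(float(x) for x in t))

    @property
    def times_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    def theta(self, t) -> np.ndarray:
        """Dimensionless diffusion time D*t/L^2."""
        return self.D * np.asarray(t, dtype=float) / self.L**2


@dataclass
class ConcentrationField:
    """Simulated concentration per (time, depth), plus the bath trajectory.

    ``c_depth_integral`` holds the conservative quadrature of ``c`` over
    depth at each time (mm * mgI/mL); :meth:`total_iodine_mass` and
    :meth:`depth_mean` use it so that mass bookkeeping matches the solver's
    own invariant rather than re-quadraturing the field.
    """

    depth_grid: np.ndarray  # (nx,), mm, 0 = surface .. L = tidemark
    times: np.ndarray  # (nt,), h
    c: np.ndarray  # (nt, nx), mgI/mL
    c_bath: np.ndarray  # (nt,), mgI/mL
    c_depth_integral: np.ndarray  # (nt,)
    config: SlabDiffusionConfig

    def depth_mean(self) -> np.ndarray:
        """Depth-averaged cartilage concentration at each time (mgI/mL)."""
        return self.c_depth_integral / self.config.L

    def mean_uptake(self) -> np.ndarray:
        """Depth-mean concentration as a fraction of the equilibrium value
        ``kappa * c_bath0`` (the natural normalization for an infinite bath)."""
        return self.depth_mean() / (self.config.kappa * self.config.c_bath0)

    def total_iodine_mass(self) -> np.ndarray:
        """Total iodine (mg) in bath + cartilage at each time (finite bath)."""
        cfg = self.config
        area = cfg.V_cart / cfg.L  # mL per mm of depth
        return cfg.V_bath * self.c_bath + area * self.c_depth_integral


def analytic_mean_uptake(theta, n_terms: int = 200):
    """Depth-averaged uptake fraction of a slab with fixed surface
    concentration and sealed base, as a function of dimensionless time.

    ``U(theta) = 1 - sum_{n=0}^{n_terms-1} 8/((2n+1)^2 pi^2) *
    exp(-(2n+1)^2 pi^2 theta / 4)``; the closed-form series solution used as
    the independent oracle for the infinite-bath solver. At ``theta = 0``
    the undamped series converges only algebraically, so the exact limit
    value 0 is returned directly.
    """
    th = np.asarray(theta, dtype=float)
    if np.any(th < 0):
        raise ValueError("theta must be nonnegative")
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    k = 2 * np.arange(n_terms) + 1  # odd integers
    coef = 8.0 / (k**2 * np.pi**2)
    terms = coef * np.exp(-np.outer(th.ravel(), k**2) * np.pi**2 / 4.0)
    out = np.where(th.ravel() == 0.0, 0.0, 1.0 - terms.sum(axis=1))
    return float(out[0]) if th.ndim == 0 else out.reshape(th.shape)


def _spectral_propagator(masses: np.ndarray, k_sym: np.ndarray):
    """Eigendecomposition of ``M^-1 K`` with M diagonal, K symmetric.

    Returns a function ``prop(y, dt)`` evaluating ``expm(dt * M^-1 K) @ y``
    exactly (to eigensolver precision).
    """
    s = np.sqrt(masses)
    sym = k_sym / np.outer(s, s)
    lam, v = eigh(sym)
    lam = np.minimum(lam, 0.0)  # operator is dissipative; clip roundoff

    def prop(y: np.ndarray, dt: float) -> np.ndarray:
        z = v.T @ (s * y)
        z *= np.exp(lam * dt)
        return (v @ z) / s

    return prop


def _solve_on_grid(cfg: SlabDiffusionConfig, nx: int):
    """Solve on one grid; returns (c(t, x), c_bath(t), trapz integral(t)).

    The scheme is finite-volume vertex-centered: half cells at the surface
    and tidemark, so the trapezoidal rule is the quadrature under which the
    semi-discrete system conserves mass exactly.
    """
    L, D, kappa = cfg.L, cfg.D, cfg.kappa
    h = L / (nx - 1)
    times = cfg.times_array
    nt = times.size
    c_out = np.zeros((nt, nx))
    cb_out = np.full(nt, cfg.c_bath0)

    surf0 = kappa * cfg.c_bath0

    if not cfg.finite_bath:
        # Unknowns c_1..c_{nx-1}; Dirichlet c_0 = kappa*c_bath0 for t > 0.
        m = nx - 1
        masses = np.full(m, h)
        masses[-1] = h / 2
        k_sym = np.zeros((m, m))
        idx = np.arange(m - 1)
        k_sym[idx, idx] = -2 * D / h
        k_sym[idx[:-1], idx[:-1] + 1] = D / h
        k_sym[idx[:-1] + 1, idx[:-1]] = D / h
        k_sym[m - 1, m - 1] = -D / h
        k_sym[m - 1, m - 2] = D / h
        k_sym[m - 2, m - 1] = D / h
        prop = _spectral_propagator(masses, k_sym)
        y_eq = np.full(m, surf0)
        y = np.zeros(m)
        t_prev = 0.0
        for j, t in enumerate(times):
            if t == 0.0:
                continue  # initial condition: c = 0 everywhere
            y = y_eq + prop(y - y_eq, t - t_prev)
            t_prev = t
            c_out[j, 0] = surf0
            c_out[j, 1:] = y
    else:
        # Unknowns [c_bath, c_1..c_{nx-1}]; the surface half-cell is merged
        # with the bath compartment (it tracks kappa*c_bath instantaneously).
        area = cfg.V_cart / L
        m = nx
        masses = np.empty(m)
        masses[0] = cfg.V_bath + area * kappa * h / 2
        masses[1:] = area * h
        masses[-1] = area * h / 2
        da = D * area / h
        k_sym = np.zeros((m, m))
        k_sym[0, 0] = -da * kappa
        k_sym[0, 1] = k_sym[1, 0] = da * np.sqrt(kappa)
        for i in range(1, m):
            k_sym[i, i] = -2 * da if i < m - 1 else -da
            if i > 1:
                k_sym[i, i - 1] = k_sym[i - 1, i] = da
        # Similarity scaling z = diag(sqrt(kappa), 1, ...) y makes K symmetric
        # (already built symmetric above); propagate z, read back y.
        scale = np.ones(m)
        scale[0] = np.sqrt(kappa)
        prop = _spectral_propagator(masses, k_sym)
        # Initial bath value chosen so the discrete invariant equals the true
        # initial mass V_bath*c_bath0 (the surface half-cell loads at t=0+).
        cb_init = cfg.V_bath * cfg.c_bath0 / masses[0]
        z = np.zeros(m)
        z[0] = scale[0] * cb_init
        t_prev = 0.0
        for j, t in enumerate(times):
            if t == 0.0:
                continue
            z = prop(z, t - t_prev)
            t_prev = t
            y = z / scale
            cb_out[j] = y[0]
            c_out[j, 0] = kappa * y[0]
            c_out[j, 1:] = y[1:]

    x = np.linspace(0.0, L, nx)
    integral = np.trapezoid(c_out, x, axis=1)
    return c_out, cb_out, integral


def solve_slab_diffusion(config: SlabDiffusionConfig) -> ConcentrationField:
    """Simulate 1-D Fickian uptake of contrast agent into the cartilage slab.

    Exact-in-time spectral propagation on two nested grids (``nx`` and
    ``2*nx - 1`` nodes) combined by Richardson extrapolation; the returned
    field lives on the requested ``nx``-node grid. Total iodine mass of
    finite-bath runs is conserved to roundoff at every output time.
    """
    cfg = config
    c1, cb1, i1 = _solve_on_grid(cfg, cfg.nx)
    c2, cb2, i2 = _solve_on_grid(cfg, 2 * cfg.nx - 1)
    c = (4.0 * c2[:, ::2] - c1) / 3.0
    np.maximum(c, 0.0, out=c)  # extrapolation can undershoot ~1e-12 near fronts
    cb = (4.0 * cb2 - cb1) / 3.0
    np.maximum(cb, 0.0, out=cb)
    integral = (4.0 * i2 - i1) / 3.0
    return ConcentrationField(
        depth_grid=np.linspace(0.0, cfg.L, cfg.nx),
        times=cfg.times_array,
        c=c,
        c_bath=cb,
        c_depth_integral=integral,
        config=cfg,
    )
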
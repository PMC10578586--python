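"""Radial reaction-diffusion model of colony growth, sporulation and competition.

The model tracks, along a colony radius, vegetative biomass ``V_g`` per
genotype, spore biomass ``S_g`` per genotype, and a shared nutrient field
``N`` on a 1-D radial grid with cylindrical symmetry:

.. math::

    \\partial V_g/\\partial t &= D_{b,g} \\nabla^2_r V_g
        + \\mu_g\\, g(N)\\, V_g - \\sigma_g\\, h(N)\\, V_g \\\\
    \\partial S_g/\\partial t &= \\sigma_g\\, h(N)\\, V_g \\\\
    \\partial N/\\partial t &= D_N \\nabla^2_r N
        - \\sum_g (\\mu_g/Y_g)\\, g(N)\\, V_g

with Monod growth ``g(N) = N/(K_g+N)`` and Hill-type nutrient-repressed
sporulation ``h(N) = K_s^m/(K_s^m+N^m)``: cells grow where nutrient is
plentiful and sporulate where it is depleted.  Spores are dormant within a
growth cycle (no growth, no consumption, no germination).

Serial passaging re-inoculates a fresh plate from the outermost colony
annulus only ("edge transfer"), which selects for genotypes that are
over-represented at the expanding front: faster spreaders (higher ``D_b``),
faster growers (higher ``mu_max``) and lower sporulators (lower
``sigma_max``).

Numerics: conservative finite-volume discretization of the radial Laplacian
(the r -> 0 cell reduces to the symmetric limit ``2 f''(0)``), zero-flux
boundaries, explicit Euler time stepping under the stability bound
``dt <= 0.4 dr^2 / max(D)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeParams",
    "Domain",
    "RadialState",
    "PassageProtocol",
    "CycleSummary",
    "RegionComposition",
    "make_state",
    "step_pde",
    "simulate_colony",
    "colony_radius",
    "composition_at",
    "edge_transfer",
    "run_serial_passages",
    "selection_sweep",
    "stable_dt",
    "default_domain",
    "default_params",
    "default_protocol",
]


@dataclass(frozen=True)
class GenotypeParams:
    """Per-genotype physiological parameters.

    Parameters
    ----------
    id : str
        Genotype label.
    D_b : float
        Biomass diffusion coefficient (mm^2/h); the phenomenological
        spreading rate of the growing colony front.
    mu_max : float
        Maximal specific growth rate (1/h).
    sigma_max : float
        Maximal specific sporulation rate (1/h), realized when nutrient is
        fully depleted.
    K_g : float
        Monod half-saturation constant for growth (nutrient units).
    K_s : float
        Nutrient level of half-maximal sporulation induction.
    m : float
        Hill steepness of sporulation induction (>= 1).
    Y : float
        Biomass yield per unit nutrient consumed (> 0).
    """

    id: str
    D_b: float = 0.01
    mu_max: float = 0.3
    sigma_max: float = 0.03
    K_g: float = 0.2
    K_s: float = 0.3
    m: float = 4.0
    Y: float = 1.0

    def __post_init__(self) -> None:
        for name in ("D_b", "mu_max", "sigma_max", "K_g", "K_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.m < 1:
            raise ValueError(f"Hill coefficient m must be >= 1, got {self.m}")
        if self.Y <= 0:
            raise ValueError(f"yield Y must be > 0, got {self.Y}")


@dataclass(frozen=True)
class Domain:
    """Radial simulation domain.

    ``n_r`` grid nodes span ``[0, R_max]`` with spacing ``dr = R_max/(n_r-1)``.
    """

    R_max: float = 25.0
    n_r: int = 251
    D_N: float = 0.01
    N0: float = 1.0

    def __post_init__(self) -> None:
        if self.n_r < 50:
            raise ValueError(f"n_r must be >= 50, got {self.n_r}")
        if self.R_max <= 0:
            raise ValueError("R_max must be > 0")
        if self.N0 <= 0:
            raise ValueError("N0 must be > 0")
        if self.D_N < 0:
            raise ValueError("D_N must be >= 0")

    @property
    def dr(self) -> float:
        return self.R_max / (self.n_r - 1)

    @property
    def r(self) -> np.ndarray:
        return np.linspace(0.0, self.R_max, self.n_r)

    @property
    def cell_weights(self) -> np.ndarray:
        """Annulus areas of the finite-volume cells around each node.

        Node i owns the annulus [r_i - dr/2, r_i + dr/2] clipped to
        [0, R_max]; summing ``w * f`` integrates f over the disk with the
        area element 2*pi*r dr, exactly conserved by the diffusion stencil.
        """
        dr = self.dr
        r = self.r
        lo = np.clip(r - dr / 2, 0.0, self.R_max)
        hi = np.clip(r + dr / 2, 0.0, self.R_max)
        return math.pi * (hi**2 - lo**2)


@dataclass
class RadialState:
    """Snapshot of all fields along the colony radius at time ``t`` (hours)."""

    r: np.ndarray
    V: Dict[str, np.ndarray]
    S: Dict[str, np.ndarray]
    N: np.ndarray
    t: float = 0.0

    @property
    def genotypes(self) -> List[str]:
        return list(self.V.keys())

    def total_density(self) -> np.ndarray:
        """Total biomass density V+S summed over genotypes."""
        out = np.zeros_like(self.N)
        for g in self.V:
            out += self.V[g] + self.S[g]
        return out

    def copy(self) -> "RadialState":
        return RadialState(
            r=self.r.copy(),
            V={g: v.copy() for g, v in self.V.items()},
            S={g: s.copy() for g, s in self.S.items()},
            N=self.N.copy(),
            t=self.t,
        )


@dataclass(frozen=True)
class PassageProtocol:
    """Weekly edge-transfer passaging protocol."""

    cycle_hours: float = 168.0
    edge_width: float = 1.5
    inoculum_mass: float = 0.5
    inoculum_radius: float = 2.0
    n_cycles: int = 5
    biomass_threshold: float = 0.02

    def __post_init__(self) -> None:
        if self.edge_width <= 0:
            raise ValueError("edge_width must be > 0")
        if self.inoculum_mass <= 0:
            raise ValueError("inoculum_mass must be > 0")
        if self.biomass_threshold <= 0:
            raise ValueError("biomass_threshold must be > 0")
        if self.inoculum_radius <= 0:
            raise ValueError("inoculum_radius must be > 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


@dataclass
class CycleSummary:
    """Per-cycle readouts mirroring the competition-figure panels."""

    cycle: int
    radius_series: List[Tuple[float, float]]
    edge_spore_fraction: Optional[float]
    center_spore_fraction: Optional[float]
    edge_genotype_fractions: Dict[str, float]


@dataclass
class RegionComposition:
    """Biomass composition of a radial region, normalized over all genotypes."""

    per_genotype: Dict[str, Dict[str, float]]

    @property
    def spore_fraction(self) -> float:
        return sum(d["spore_fraction"] for d in self.per_genotype.values())

    @property
    def vegetative_fraction(self) -> float:
        return sum(d["vegetative_fraction"] for d in self.per_genotype.values())

    def genotype_share(self, genotype: str) -> float:
        d = self.per_genotype[genotype]
        return d["spore_fraction"] + d["vegetative_fraction"]


def default_domain() -> Domain:
    return Domain()


def default_params(genotype_id: str = "wt") -> GenotypeParams:
    return GenotypeParams(id=genotype_id)


def default_protocol() -> PassageProtocol:
    return PassageProtocol()


def radial_integral(f: np.ndarray, domain: Domain) -> float:
    """Integrate a density field over the disk: ∫ f · 2πr dr."""
    return float(np.dot(domain.cell_weights, f))


def make_state(
    domain: Domain, inocula: Dict[str, Tuple[float, float]]
) -> RadialState:
    """Seed a fresh plate.

    Parameters
    ----------
    inocula : dict
        Per-genotype ``(mass, radius)``: vegetative biomass ``mass`` spread
        uniformly over a central disk of the given radius (mm).
    """
    if not inocula:
        raise ValueError("at least one genotype inoculum required")
    r = domain.r
    w = domain.cell_weights
    V: Dict[str, np.ndarray] = {}
    S: Dict[str, np.ndarray] = {}
    for g, (mass, radius) in inocula.items():
        if mass <= 0:
            raise ValueError(f"inoculum mass for {g!r} must be > 0, got {mass}")
        if radius <= 0:
            raise ValueError(f"inoculum radius for {g!r} must be > 0, got {radius}")
        if radius > domain.R_max:
            raise ValueError(
                f"inoculum radius {radius} exceeds domain radius {domain.R_max}"
            )
        mask = r <= radius
        area = float(w[mask].sum())
        v = np.zeros(domain.n_r)
        v[mask] = mass / area
        V[g] = v
        S[g] = np.zeros(domain.n_r)
    N = np.full(domain.n_r, domain.N0)
    return RadialState(r=r.copy(), V=V, S=S, N=N, t=0.0)


def stable_dt(
    params: Sequence[GenotypeParams], domain: Domain, safety: float = 1.0
) -> float:
    """Largest admissible explicit step: diffusion bound 0.4 dr^2 / max(D),
    additionally capped by a reaction bound 0.1 / max(mu, sigma)."""
    d_max = max([domain.D_N] + [p.D_b for p in params])
    dt = np.inf if d_max == 0 else 0.4 * domain.dr**2 / d_max
    rate = max([p.mu_max for p in params] + [p.sigma_max for p in params] + [1e-12])
    dt = min(dt, 0.1 / rate)
    if not np.isfinite(dt):
        dt = 1.0
    return dt * safety


def _laplacian(f: np.ndarray, domain: Domain) -> np.ndarray:
    """Conservative radial Laplacian (1/r) d/dr (r df/dr), zero-flux ends."""
    dr = domain.dr
    r = domain.r
    r_half = r[:-1] + dr / 2  # face radii r_{i+1/2}
    flux = r_half * (f[1:] - f[:-1]) / dr  # r * df/dr at faces
    w = domain.cell_weights / (2 * math.pi)  # ∫ r dr over each cell
    lap = np.empty_like(f)
    lap[0] = flux[0] / w[0]
    lap[-1] = -flux[-1] / w[-1]
    lap[1:-1] = (flux[1:] - flux[:-1]) / w[1:-1]
    return lap


def _check_field(name: str, arr: np.ndarray, t: float) -> None:
    if not np.all(np.isfinite(arr)):
        raise FloatingPointError(f"non-finite values in field {name!r} at t={t:.3f} h")


def _clip_negatives(name: str, arr: np.ndarray, t: float, tol: float = 1e-12) -> None:
    neg = arr < 0
    if not neg.any():
        return
    worst = arr[neg].min()
    if worst < -tol:
        raise FloatingPointError(
            f"field {name!r} went negative ({worst:.3e}) at t={t:.3f} h; "
            "reduce dt"
        )
    arr[neg] = 0.0


def step_pde(
    state: RadialState,
    params: Dict[str, GenotypeParams],
    domain: Domain,
    dt: float,
    freeze_nutrient: bool = False,
) -> RadialState:
    """Advance the model by one explicit Euler step of length ``dt`` hours.

    ``freeze_nutrient=True`` clamps N at its current value (no consumption,
    no nutrient diffusion), which reduces vegetative growth to the
    Fisher-KPP equation with rate ``mu_max * g(N)``.
    """
    d_max = max([domain.D_N] + [p.D_b for p in params.values()])
    if d_max > 0 and dt > 0.4 * domain.dr**2 / d_max * (1 + 1e-9):
        raise ValueError(
            f"dt={dt} violates stability bound "
            f"{0.4 * domain.dr ** 2 / d_max:.4g} = 0.4 dr^2/max(D)"
        )
    new = state.copy()
    N = state.N
    # consumption is linear in N at fixed V: dN/dt = -q(V, N) * N with
    # q = sum_g (mu_g/Y_g) V_g/(K_g+N); integrating that factor exactly over
    # the step (N *= exp(-q dt)) keeps N non-negative where plain Euler
    # can undershoot during abrupt depletion
    q = np.zeros_like(N)
    for g, p in params.items():
        V = state.V[g]
        gN = N / (p.K_g + N)
        hN = p.K_s**p.m / (p.K_s**p.m + N**p.m)
        growth = p.mu_max * gN * V
        sporulation = p.sigma_max * hN * V
        dV = p.D_b * _laplacian(V, domain) + growth - sporulation
        new.V[g] = V + dt * dV
        new.S[g] = state.S[g] + dt * sporulation
        q += (p.mu_max / p.Y) * V / (p.K_g + N)
        _check_field(f"V[{g}]", new.V[g], state.t + dt)
        _check_field(f"S[{g}]", new.S[g], state.t + dt)
        _clip_negatives(f"V[{g}]", new.V[g], state.t + dt)
        _clip_negatives(f"S[{g}]", new.S[g], state.t + dt)
    if not freeze_nutrient:
        new.N = N * np.exp(-dt * q) + dt * domain.D_N * _laplacian(N, domain)
        _check_field("N", new.N, state.t + dt)
        _clip_negatives("N", new.N, state.t + dt)
    new.t = state.t + dt
    return new


def simulate_colony(
    state: RadialState,
    params: Dict[str, GenotypeParams],
    domain: Domain,
    t_end: float,
    dt: Optional[float] = None,
    record_times: Optional[Sequence[float]] = None,
    freeze_nutrient: bool = False,
) -> List[RadialState]:
    """Run the model to ``t_end`` hours, returning snapshots at ``record_times``.

    ``record_times`` defaults to ``[t_end]``; times must lie in
    ``[state.t, state.t + t_end]`` relative to the *initial* state time 0,
    i.e. are absolute simulation times in ``[0, t_end]`` for a fresh state.
    The integrator lands exactly on each requested time by shortening the
    final step before it.
    """
    if dt is None:
        dt = stable_dt(list(params.values()), domain)
    if record_times is None:
        record_times = [t_end]
    record_times = sorted(float(t) for t in record_times)
    t0 = state.t
    for rt in record_times:
        if rt < t0 - 1e-9 or rt > t0 + t_end + 1e-9:
            raise ValueError(f"record time {rt} outside [{t0}, {t0 + t_end}]")
    snapshots: List[RadialState] = []
    cur = state.copy()
    targets = list(record_times) + [t0 + t_end]
    for target in targets:
        while cur.t < target - 1e-9:
            step = min(dt, target - cur.t)
            try:
                cur = step_pde(cur, params, domain, step, freeze_nutrient)
            except FloatingPointError as exc:
                raise FloatingPointError(f"{exc} (at t={cur.t:.3f} h)") from exc
        if snapshots and abs(snapshots[-1].t - target) < 1e-9:
            continue
        if target in record_times or any(
            abs(target - rt) < 1e-9 for rt in record_times
        ):
            snapshots.append(cur.copy())
    return snapshots


def colony_radius(state: RadialState, threshold: float) -> float:
    """Largest radius where total biomass density (V+S) >= threshold; 0 if none."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    dens = state.total_density()
    above = np.nonzero(dens >= threshold)[0]
    if above.size == 0:
        return 0.0
    return float(state.r[above[-1]])


def _region_mask(
    state: RadialState, region: str, edge_width: float, threshold: float
) -> Optional[np.ndarray]:
    radius = colony_radius(state, threshold)
    if region == "edge":
        if radius < edge_width:
            return None
        return (state.r >= radius - edge_width) & (state.r <= radius)
    if region == "center":
        return state.r <= edge_width
    raise ValueError(f"region must be 'edge' or 'center', got {region!r}")


def composition_at(
    state: RadialState,
    region: str,
    edge_width: float,
    threshold: float,
    domain: Domain,
) -> Optional[RegionComposition]:
    """Biomass composition of the edge annulus or the central disk.

    Returns per-genotype vegetative and spore fractions of the region's
    total biomass (all fractions sum to 1 over genotypes and states), or
    ``None`` when the region is undefined (colony smaller than the
    annulus width, or zero biomass in the region).
    """
    mask = _region_mask(state, region, edge_width, threshold)
    if mask is None:
        return None
    w = domain.cell_weights[mask]
    masses = {
        g: (float(np.dot(w, state.V[g][mask])), float(np.dot(w, state.S[g][mask])))
        for g in state.genotypes
    }
    total = sum(v + s for v, s in masses.values())
    if total <= 0:
        return None
    return RegionComposition(
        per_genotype={
            g: {"vegetative_fraction": v / total, "spore_fraction": s / total}
            for g, (v, s) in masses.items()
        }
    )


def edge_transfer(
    state: RadialState, protocol: PassageProtocol, domain: Domain
) -> Dict[str, float]:
    """Sample the outermost annulus and rescale to the inoculum mass.

    Each genotype's share of the transfer equals its share of total biomass
    (vegetative + spores) in the edge annulus.  Transferred spores germinate
    on the fresh substrate, so the returned masses seed vegetative biomass.
    """
    radius = colony_radius(state, protocol.biomass_threshold)
    if radius < protocol.edge_width:
        raise ValueError(
            f"colony radius {radius:.2f} mm smaller than edge width "
            f"{protocol.edge_width} mm"
        )
    mask = (state.r >= radius - protocol.edge_width) & (state.r <= radius)
    w = domain.cell_weights[mask]
    masses = {
        g: float(np.dot(w, state.V[g][mask] + state.S[g][mask]))
        for g in state.genotypes
    }
    total = sum(masses.values())
    if total <= 0:
        raise ValueError("extinct at edge: no biomass in the transfer annulus")
    return {g: protocol.inoculum_mass * m / total for g, m in masses.items()}


def run_serial_passages(
    genotypes: Sequence[GenotypeParams],
    init_fractions: Sequence[float],
    domain: Domain,
    protocol: PassageProtocol,
    dt: Optional[float] = None,
    radius_record_hours: float = 24.0,
) -> List[CycleSummary]:
    """Alternate colony growth and edge transfer for ``protocol.n_cycles``.

    ``init_fractions`` give each genotype's share of the first inoculum and
    must sum to 1.
    """
    fr = np.asarray(init_fractions, dtype=float)
    if len(fr) != len(genotypes):
        raise ValueError("init_fractions length must match genotypes")
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError(f"init_fractions must sum to 1, got {fr.sum()}")
    params = {p.id: p for p in genotypes}
    if len(params) != len(genotypes):
        raise ValueError("duplicate genotype ids")
    masses = {p.id: protocol.inoculum_mass * f for p, f in zip(genotypes, fr)}
    record = np.arange(0.0, protocol.cycle_hours + 1e-9, radius_record_hours)
    if record[-1] < protocol.cycle_hours:
        record = np.append(record, protocol.cycle_hours)
    summaries: List[CycleSummary] = []
    for cycle in range(protocol.n_cycles):
        inocula = {
            g: (m, protocol.inoculum_radius) for g, m in masses.items() if m > 0
        }
        if not inocula:
            raise ValueError(f"no genotype survived into cycle {cycle}")
        state = make_state(domain, inocula)
        # genotypes extinct at transfer stay in the state with zero mass
        for g in params:
            state.V.setdefault(g, np.zeros(domain.n_r))
            state.S.setdefault(g, np.zeros(domain.n_r))
        try:
            snaps = simulate_colony(
                state, params, domain, protocol.cycle_hours, dt=dt,
                record_times=list(record),
            )
        except FloatingPointError as exc:
            raise FloatingPointError(f"cycle {cycle}: {exc}") from exc
        final = snaps[-1]
        radius_series = [
            (s.t, colony_radius(s, protocol.biomass_threshold)) for s in snaps
        ]
        edge = composition_at(
            final, "edge", protocol.edge_width, protocol.biomass_threshold, domain
        )
        center = composition_at(
            final, "center", protocol.edge_width, protocol.biomass_threshold, domain
        )
        try:
            masses = edge_transfer(final, protocol, domain)
        except ValueError as exc:
            raise ValueError(f"cycle {cycle}: {exc}") from exc
        total = sum(masses.values())
        geno_fr = {g: m / total for g, m in masses.items()}
        summaries.append(
            CycleSummary(
                cycle=cycle,
                radius_series=radius_series,
                edge_spore_fraction=None if edge is None else edge.spore_fraction,
                center_spore_fraction=(
                    None if center is None else center.spore_fraction
                ),
                edge_genotype_fractions=geno_fr,
            )
        )
        logger.info(
            "cycle %d: radius %.2f mm, edge spores %.1f%%, fractions %s",
            cycle,
            radius_series[-1][1],
            100 * (edge.spore_fraction if edge else float("nan")),
            {g: round(f, 3) for g, f in geno_fr.items()},
        )
    return summaries


_SWEEPABLE = ("D_b", "sigma_max", "mu_max")


def selection_sweep(
    base: GenotypeParams,
    param: str,
    values: Sequence[float],
    domain: Domain,
    protocol: PassageProtocol,
    dt: Optional[float] = None,
):
    """Compete a one-parameter mutant against the wild type, one row per value.

    The mutant differs from ``base`` only in ``param``; both start at 50%.
    Returns a DataFrame with columns ``value``, ``edge_mutant_pct``,
    ``radius_mm``, ``edge_spore_pct`` taken from the final cycle.
    """
    import pandas as pd

    if param not in _SWEEPABLE:
        raise ValueError(f"param must be one of {_SWEEPABLE}, got {param!r}")
    rows = []
    wt = replace(base, id="wt")
    for value in values:
        mut = replace(base, id="mutant", **{param: float(value)})
        summaries = run_serial_passages(
            [wt, mut], [0.5, 0.5], domain, protocol, dt=dt
        )
        last = summaries[-1]
        rows.append(
            {
                "value": float(value),
                "edge_mutant_pct": 100 * last.edge_genotype_fractions["mutant"],
                "radius_mm": last.radius_series[-1][1],
                "edge_spore_pct": 100 * (last.edge_spore_fraction or 0.0),
            }
        )
    return pd.DataFrame(rows)
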
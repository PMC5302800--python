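"""Chemical-potential bookkeeping and chemical-motive-force maximization.

Each exchange metabolite i carries a chemical potential
``mu_i = mu_i^0 + RT ln(x_i / x_i^0)``; an allowed concentration range of
``x0 * 10^-m .. x0 * 10^m`` translates into the symmetric interval
``mu_i^0 +/- dg`` with ``dg = RT ln(10^m)``.  The *chemical motive force*

    cmf = sum_i mu_i v_i

over boundary (exchange) fluxes measures the external chemical potential
consumed to drive the internal network at a non-equilibrium steady state;
maximizing it over the MO-FVA exchange-flux ranges and the mu intervals
identifies the thermodynamically favored corner of each flux-variability box.

Because the objective is separable and bilinear in (mu_i, v_i) with pure box
constraints, the optimum of each pair sits at a corner of its rectangle: the
``corner_exact`` method enumerates the four products per metabolite and is
exact.  The ``numeric`` method runs a truncated-Newton (TNC) gradient ascent
per metabolite pair from the four box corners and must agree with the exact
corner optimum; it is retained as an independent numerical cross-check.

Sign convention: uptake from the environment counts *positive* in the cmf
(intake of high-potential nutrients such as photons contributes +mu*v), so
:func:`cmf_over_mesh` negates the pool->environment export fluxes before
maximizing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .community import CommunityModel
from .core import ThermoTable
from .errors import ParetofluxError, ValidationError
from .mofva import ParetoMesh, mofva_at_point

#: gas constant, kJ/(mol K)
R_KJ = 8.314e-3


def compute_dg(temperature_K: float, conc_ratio: float) -> float:
    """Half-width RT ln(conc_ratio) of the chemical-potential interval, kJ/mol.

    ``conc_ratio`` is the allowed fold-change of concentration relative to the
    reference (e.g. 10^3 for a 10^-3..10^3 M window around 1 M).
    """
    if temperature_K <= 0:
        raise ValidationError(f"temperature must be > 0 K, got {temperature_K}")
    if conc_ratio <= 0:
        raise ValidationError(f"concentration ratio must be > 0, got {conc_ratio}")
    return R_KJ * temperature_K * float(np.log(conc_ratio))


def photon_potential(
    thermo: ThermoTable,
    reaction: dict[str, float],
    n_photons: float,
) -> float:
    """Photon chemical potential from a photon-driven reference reaction.

    Assuming the reaction (stoichiometry excluding photons, reactants
    negative) approaches equilibrium, ``delta_mu = 0`` gives
    ``mu_hv = sum_i S_i mu_i^0 / n_photons``.
    """
    if n_photons <= 0:
        raise ValidationError("n_photons must be > 0")
    total = 0.0
    for met, coef in reaction.items():
        total += coef * thermo.mu0(met)  # raises naming the metabolite
    return total / n_photons


@dataclass
class CmfResult:
    cmf: float
    mu: dict[str, float]
    v: dict[str, float]
    method: str

    def validate_against(self, ranges, thermo: ThermoTable) -> None:
        for met, (lo, hi) in ranges.items():
            if not lo - 1e-9 <= self.v[met] <= hi + 1e-9:
                raise ParetofluxError(f"optimizer flux for {met} out of range")
            mu0, dg = thermo.entries[met]
            if not mu0 - dg - 1e-9 <= self.mu[met] <= mu0 + dg + 1e-9:
                raise ParetofluxError(f"optimizer mu for {met} out of box")


def _corner_best(a: float, b: float, mlo: float, mhi: float) -> tuple[float, float, float]:
    best = None
    for v in (a, b):
        for mu in (mlo, mhi):
            val = mu * v
            if best is None or val > best[0]:
                best = (val, mu, v)
    return best


def _tnc_best(a, b, mlo, mhi):
    """Max of mu*v over the box by TNC ascent from the four corners."""
    best = None
    for v0 in (a, b):
        for m0 in (mlo, mhi):
            res = minimize(
                lambda z: -z[0] * z[1],
                x0=np.array([m0, v0]),
                jac=lambda z: np.array([-z[1], -z[0]]),
                bounds=[(mlo, mhi), (a, b)],
                method="TNC",
            )
            val = -res.fun
            if best is None or val > best[0]:
                best = (val, float(res.x[0]), float(res.x[1]))
    return best


def maximize_cmf(
    ranges: dict[str, tuple[float, float]],
    thermo: ThermoTable,
    method: str = "corner_exact",
) -> CmfResult:
    """Maximize sum_i mu_i v_i over flux boxes [a_i, b_i] and mu boxes
    [mu0_i - dg_i, mu0_i + dg_i].

    ``ranges`` maps metabolite id -> (a, b).  Infinite bounds make the cmf
    unbounded and are rejected.
    """
    if method not in ("corner_exact", "numeric"):
        raise ValidationError(f"unknown cmf method {method!r}")
    total = 0.0
    mu_opt: dict[str, float] = {}
    v_opt: dict[str, float] = {}
    for met, (a, b) in ranges.items():
        if not (np.isfinite(a) and np.isfinite(b)):
            raise ValidationError(
                f"flux range for {met} is unbounded; cmf would be infinite"
            )
        if a > b:
            raise ValidationError(f"flux range for {met} has a > b")
        mu0 = thermo.mu0(met)
        dg = thermo.dg(met)
        solver = _corner_best if method == "corner_exact" else _tnc_best
        val, mu, v = solver(a, b, mu0 - dg, mu0 + dg)
        total += val
        mu_opt[met] = mu
        v_opt[met] = v
    return CmfResult(cmf=total, mu=mu_opt, v=v_opt, method=method)


@dataclass
class CmfSurface:
    """Maximal cmf at each mesh point, kJ/gDW/h (mmol-based fluxes)."""

    points: list[tuple[np.ndarray, np.ndarray, float]]  # (weights, f*, cmf)
    argmax: int

    @property
    def values(self) -> np.ndarray:
        return np.array([c for _, _, c in self.points])


def pool_exchange_ranges(
    community: CommunityModel,
    flux_ranges,
    orientation: str = "uptake_positive",
) -> dict[str, tuple[float, float]]:
    """Extract pool<->environment exchange ranges keyed by metabolite.

    With ``orientation="uptake_positive"`` the pool->environment export axis
    is negated so that uptake from the environment counts positive, the
    orientation in which the cmf measures consumed external potential.
    """
    out = {}
    for met in community.pool.shared:
        rid = f"pool:EX_{met}"
        lo, hi = flux_ranges.ranges[rid]
        if orientation == "uptake_positive":
            out[met] = (-hi, -lo)
        else:
            out[met] = (lo, hi)
    return out


def cmf_over_mesh(
    community: CommunityModel,
    mesh: ParetoMesh,
    alpha: float,
    thermo: ThermoTable,
    method: str = "corner_exact",
) -> CmfSurface:
    """Maximal cmf for every mesh point of the Pareto surface.

    For each point, MO-FVA restricted to the pool-environment exchanges gives
    the flux boxes [a_i, b_i]; the separable box maximization then yields the
    point's maximal cmf.  Errors in a per-point subproblem are re-raised with
    the point index.
    """
    ids = community.pool_exchange_ids
    points = []
    for i, (w, f_star) in enumerate(mesh.points):
        try:
            rng = mofva_at_point(community, f_star, alpha=alpha, reactions=ids)
            boxes = pool_exchange_ranges(community, rng)
            res = maximize_cmf(boxes, thermo, method=method)
        except ParetofluxError as exc:
            raise type(exc)(f"mesh point {i} (weights {w.tolist()}): {exc}") from exc
        points.append((w, f_star, res.cmf))
    values = np.array([c for _, _, c in points])
    return CmfSurface(points=points, argmax=int(np.argmax(values)))
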
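"""Maximum-likelihood estimation of binding and assembly parameters.

Observed data are within-oligomer fractional populations over bound-ATP
counts at a series of total-ATP concentrations.  Treating each oligomer row
as a multinomial draw of effective size N from the lattice occupancy
distribution gives the objective

    NLL = - sum_points sum_j N * sum_k f_obs(j, k) ln p_model(k | l)

where the free-ligand concentration l at each titration point comes from a
mass balance (full speciation, a hexamer-only balance, or l = L_tot under a
config flag).  Optimization runs in log10-parameter space with bounds and
multistart; uncertainty comes from a parametric bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize

from .assembly import (
    AssemblyParameters,
    SolutionConditions,
    oligomer_particle_fractions,
    speciate,
    apparent_kd,
)
from .lattice import (
    BindingParameters,
    SiteClass,
    SiteLattice,
    partition_coefficients,
)

__all__ = [
    "TitrationPoint",
    "FitResult",
    "OptimizationError",
    "IdentifiabilityError",
    "hexamer_free_ligand",
    "negative_log_likelihood",
    "fit_binding",
    "bootstrap_ci",
    "fit_assembly",
    "simulate_multinomial_rows",
]

PROB_FLOOR = 1e-12
DEFAULT_K_BOUNDS = (2.0, 8.0)  # log10 K, spans Kd 10 nM .. 10 mM
DEFAULT_OMEGA_BOUNDS = (-3.0, 3.0)  # log10 omega


class OptimizationError(RuntimeError):
    """Every multistart failed."""


class IdentifiabilityError(ValueError):
    """The requested fit cannot be identified from the data provided."""


@dataclass
class TitrationPoint:
    """Observed within-oligomer fractions at one total-ATP concentration."""

    l_tot: float
    p_tot: float
    rows: dict[int, np.ndarray]  # j -> fractions over k (non-missing rows only)


@dataclass
class FitResult:
    params: dict[str, float]
    nll: float
    success: bool
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_starts: int = 0
    starts: list[dict] = field(default_factory=list)
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def binding_parameters(self) -> BindingParameters:
        kf = 10.0 ** self.params.get("log10_K_full", -np.inf)
        kp = 10.0 ** self.params.get("log10_K_partial", -np.inf)
        om = 10.0 ** self.params.get("log10_omega", 0.0)
        return BindingParameters.with_shared_partial(
            kf if np.isfinite(kf) else 0.0, kp if np.isfinite(kp) else 0.0, om
        )


def _mean_from_coeffs(a: np.ndarray, l: float) -> tuple[float, float]:
    """(Z, mean bound count) from lattice coefficients at free ligand l."""
    powers = np.power(l, np.arange(a.size))
    c = a * powers
    Z = c.sum()
    return Z, float(np.arange(a.size) @ c) / Z


def hexamer_free_ligand(a: np.ndarray, oligomer_conc: float, l_tot: float) -> float:
    """Free ligand when a single oligomer species holds all binding sites.

    Solves l + c * nbar(l) = L_tot, monotone in l, bracketed on [0, L_tot].
    """
    if l_tot == 0.0:
        return 0.0

    def g(l: float) -> float:
        _, nbar = _mean_from_coeffs(a, l)
        return l + oligomer_conc * nbar - l_tot

    if g(l_tot) <= 0:
        return l_tot
    return brentq(g, 0.0, l_tot, xtol=1e-30, rtol=8.9e-16, maxiter=200)


def _free_site_classes(topology: SiteLattice) -> list[str]:
    names = []
    classes = set(topology.sites)
    if SiteClass.FULL in classes:
        names.append("log10_K_full")
    if SiteClass.PARTIAL_A in classes or SiteClass.PARTIAL_B in classes:
        names.append("log10_K_partial")
    names.append("log10_omega")
    return names


def _binding_from_theta(names: list[str], theta: np.ndarray, fixed: dict[str, float]) -> BindingParameters:
    p = dict(fixed)
    p.update(dict(zip(names, theta)))
    kf = 10.0 ** p["log10_K_full"] if "log10_K_full" in p else 0.0
    kp = 10.0 ** p["log10_K_partial"] if "log10_K_partial" in p else 0.0
    om = 10.0 ** p.get("log10_omega", 0.0)
    return BindingParameters.with_shared_partial(kf, kp, om)


def _free_ligand_for_point(
    point: TitrationPoint,
    binding: BindingParameters,
    topologies: dict[int, SiteLattice],
    ligand_mode: str,
    assembly: AssemblyParameters | None,
) -> float:
    if ligand_mode == "total":
        return point.l_tot
    if ligand_mode == "hexamer":
        jmax = max(topologies)
        a = partition_coefficients(topologies[jmax], binding)
        return hexamer_free_ligand(a, point.p_tot / jmax, point.l_tot)
    if ligand_mode == "speciate":
        if assembly is None:
            raise ValueError("ligand_mode='speciate' requires assembly parameters")
        table = speciate(
            assembly, binding, topologies, SolutionConditions(point.p_tot, point.l_tot)
        )
        return table.free_ligand
    raise ValueError(f"unknown ligand mode {ligand_mode!r}")


def negative_log_likelihood(
    binding: BindingParameters,
    data: list[TitrationPoint],
    topologies: dict[int, SiteLattice],
    n_eff: float = 5000.0,
    ligand_mode: str = "hexamer",
    assembly: AssemblyParameters | None = None,
) -> float:
    """Multinomial NLL of all non-missing rows, summed over titration points."""
    nll = 0.0
    floored = False
    for point in data:
        l = _free_ligand_for_point(point, binding, topologies, ligand_mode, assembly)
        for j, f_obs in point.rows.items():
            a = partition_coefficients(topologies[j], binding)
            c = a * np.power(l, np.arange(a.size))
            p = c / c.sum()
            if ((p < PROB_FLOOR) & (f_obs > 0)).any():
                floored = True
            nll -= n_eff * float(f_obs @ np.log(np.maximum(p, PROB_FLOOR)))
    if floored:
        warnings.warn("model probability floored at 1e-12 where data are nonzero")
    return nll


def _multistart_minimize(objective, names, bounds, n_starts, rng, start_center=None):
    starts, results = [], []
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    for i in range(n_starts):
        if i == 0 and start_center is not None:
            x0 = np.clip(np.asarray(start_center, float), lo, hi)
        else:
            x0 = rng.uniform(lo, hi)
        try:
            res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
            starts.append(
                {"x0": x0.tolist(), "x": res.x.tolist(), "nll": float(res.fun), "success": bool(res.success)}
            )
            if np.isfinite(res.fun):
                results.append(res)
        except Exception as exc:  # pragma: no cover - optimizer failure path
            starts.append({"x0": x0.tolist(), "error": str(exc)})
    if not results:
        raise OptimizationError(f"all {n_starts} starts failed: {starts}")
    best = min(results, key=lambda r: r.fun)
    return best, starts


def fit_binding(
    data: list[TitrationPoint],
    topologies: dict[int, SiteLattice],
    n_starts: int = 8,
    seed: int | None = 0,
    n_eff: float = 5000.0,
    ligand_mode: str = "hexamer",
    assembly: AssemblyParameters | None = None,
    fixed: dict[str, float] | None = None,
    k_bounds: tuple[float, float] = DEFAULT_K_BOUNDS,
    omega_bounds: tuple[float, float] = DEFAULT_OMEGA_BOUNDS,
    check_identifiability: bool = True,
) -> FitResult:
    """Bounded multistart maximum-likelihood fit of the lattice binding parameters.

    Parameters present are determined by the site classes of the fitted
    topologies (K_full, shared K_partial, omega); any may be pinned through
    ``fixed`` (values in log10).  Deterministic given ``seed``.
    """
    points = [p for p in data if p.rows]
    if len(points) < 3:
        raise IdentifiabilityError(
            f"need >= 3 titration points with non-missing rows, got {len(points)}"
        )
    fixed = dict(fixed or {})
    union = SiteLattice(1, tuple(s for t in topologies.values() for s in t.sites))
    names = [n for n in _free_site_classes(union) if n not in fixed]
    bounds = [omega_bounds if n == "log10_omega" else k_bounds for n in names]
    rng = np.random.default_rng(seed)

    def objective(theta: np.ndarray) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return negative_log_likelihood(
                _binding_from_theta(names, theta, fixed),
                points,
                topologies,
                n_eff=n_eff,
                ligand_mode=ligand_mode,
                assembly=assembly,
            )

    best, starts = _multistart_minimize(objective, names, bounds, n_starts, rng)
    params = dict(fixed)
    params.update(dict(zip(names, best.x)))
    result = FitResult(
        params=params,
        nll=float(best.fun),
        success=bool(best.success),
        n_starts=n_starts,
        starts=starts,
        seed=seed,
        extra={"names": names, "ligand_mode": ligand_mode, "n_eff": n_eff},
    )
    if check_identifiability and "log10_omega" in names:
        result.extra["omega_identified"] = _omega_identified(
            objective, names, bounds, best, rng
        )
    return result


def _omega_identified(objective, names, bounds, best, rng, delta_nll: float = 1.92) -> bool:
    """Profile check: is omega constrained away from the box bounds?

    If re-optimizing the other parameters with omega pinned at a bound
    raises the NLL by less than the 95% chi-square half-width, the interval
    for omega spans that bound and omega is reported as unidentified (e.g.
    low-occupancy data never populate adjacent-pair configurations).
    """
    i = names.index("log10_omega")
    flat = []
    for b in bounds[i]:
        sub_names = [n for n in names if n != "log10_omega"]
        sub_bounds = [bd for n, bd in zip(names, bounds) if n != "log10_omega"]

        def sub_obj(theta_sub):
            theta = np.empty(len(names))
            theta[i] = b
            theta[[names.index(n) for n in sub_names]] = theta_sub
            return objective(theta)

        if sub_names:
            x0 = [best.x[names.index(n)] for n in sub_names]
            res = minimize(sub_obj, x0, method="L-BFGS-B", bounds=sub_bounds)
            nll_b = float(res.fun)
        else:
            nll_b = float(sub_obj(np.empty(0)))
        flat.append(nll_b - float(best.fun) < delta_nll)
    return not any(flat)


def simulate_multinomial_rows(
    binding: BindingParameters,
    topologies: dict[int, SiteLattice],
    points: list[tuple[float, float]],
    n_eff: float,
    rng: np.random.Generator,
    ligand_mode: str = "hexamer",
    assembly: AssemblyParameters | None = None,
    fit_oligomers: tuple[int, ...] | None = None,
) -> list[TitrationPoint]:
    """Draw multinomial population rows from the model at given (L_tot, P_tot)."""
    out = []
    for l_tot, p_tot in points:
        pt = TitrationPoint(l_tot, p_tot, {})
        l = _free_ligand_for_point(pt, binding, topologies, ligand_mode, assembly)
        for j, lat in topologies.items():
            if fit_oligomers is not None and j not in fit_oligomers:
                continue
            a = partition_coefficients(lat, binding)
            c = a * np.power(l, np.arange(a.size))
            p = c / c.sum()
            pt.rows[j] = rng.multinomial(int(n_eff), p) / float(n_eff)
        out.append(pt)
    return out


def bootstrap_ci(
    data: list[TitrationPoint],
    topologies: dict[int, SiteLattice],
    fit: FitResult,
    n_boot: int = 200,
    seed: int | None = 0,
    level: float = 0.95,
    n_starts: int = 2,
    assembly: AssemblyParameters | None = None,
) -> dict[str, tuple[float, float]]:
    """Parametric-bootstrap percentile intervals for the fitted parameters.

    Resimulates multinomial rows from the fitted model at the effective count
    used in the fit, refits each replicate (seeded, one start at the fitted
    optimum), and reports percentile intervals.  More than 20% refit
    failures triggers a reliability warning.
    """
    if n_boot == 0:
        return {}
    rng = np.random.default_rng(seed)
    binding = fit.binding_parameters()
    names = fit.extra.get("names", sorted(fit.params))
    n_eff = fit.extra.get("n_eff", 5000.0)
    ligand_mode = fit.extra.get("ligand_mode", "hexamer")
    grid = [(p.l_tot, p.p_tot) for p in data]
    row_js = tuple(sorted({j for p in data for j in p.rows}))
    draws: dict[str, list[float]] = {n: [] for n in names}
    failures = 0
    for _ in range(n_boot):
        rep = simulate_multinomial_rows(
            binding, topologies, grid, n_eff, rng,
            ligand_mode=ligand_mode, assembly=assembly, fit_oligomers=row_js,
        )
        try:
            refit = fit_binding(
                rep,
                topologies,
                n_starts=n_starts,
                seed=int(rng.integers(2**31)),
                n_eff=n_eff,
                ligand_mode=ligand_mode,
                assembly=assembly,
                fixed={k: v for k, v in fit.params.items() if k not in names},
                check_identifiability=False,
            )
        except (OptimizationError, IdentifiabilityError):
            failures += 1
            continue
        for n in names:
            draws[n].append(refit.params[n])
    if failures > 0.2 * n_boot:
        warnings.warn(
            f"{failures}/{n_boot} bootstrap refits failed; intervals unreliable"
        )
    alpha = (1.0 - level) / 2.0
    ci = {}
    for n in names:
        v = np.array(draws[n])
        if v.size:
            ci[n] = (float(np.quantile(v, alpha)), float(np.quantile(v, 1 - alpha)))
    fit.ci.update(ci)
    return ci


def fit_assembly(
    mp_counts: dict[float, np.ndarray],
    seed: int | None = 0,
    n_starts: int = 8,
    k_bounds: tuple[float, float] = (4.0, 12.0),
    sigma_bounds: tuple[float, float] = (-4.0, 2.0),
    topologies: dict[int, SiteLattice] | None = None,
) -> FitResult:
    """Fit the nucleated-cooperative assembly ladder to MP oligomer counts.

    ``mp_counts`` maps total protomer concentration (M) to particle counts
    per oligomer order 1..6.  Returns log10 K_step, log10 sigma, and the
    derived apparent dissociation constant.
    """
    if len(mp_counts) < 2:
        raise IdentifiabilityError(
            "assembly fit with free sigma needs counts at >= 2 protomer concentrations"
        )
    from .lattice import default_topologies

    topologies = topologies or default_topologies()
    binding0 = BindingParameters.with_shared_partial(0.0, 0.0, 1.0)  # apo
    counts = {p: np.asarray(c, dtype=float) for p, c in mp_counts.items()}
    mats = list(counts.values())
    if all(np.array_equal(mats[0], m) for m in mats[1:]):
        warnings.warn("oligomer counts identical at every concentration; likelihood is flat")

    def objective(theta: np.ndarray) -> float:
        assembly = AssemblyParameters.nucleated(10.0 ** theta[0], 10.0 ** theta[1])
        nll = 0.0
        for p_tot, c in counts.items():
            table = speciate(assembly, binding0, topologies, SolutionConditions(p_tot, 0.0))
            f = oligomer_particle_fractions(table)
            nll -= float(c @ np.log(np.maximum(f, PROB_FLOOR)))
        return nll

    rng = np.random.default_rng(seed)
    best, starts = _multistart_minimize(
        objective, ["log10_K_step", "log10_sigma"], [k_bounds, sigma_bounds], n_starts, rng
    )
    params = {"log10_K_step": float(best.x[0]), "log10_sigma": float(best.x[1])}
    assembly = AssemblyParameters.nucleated(
        10.0 ** params["log10_K_step"], 10.0 ** params["log10_sigma"]
    )
    try:
        kd_app = apparent_kd(assembly, binding0, topologies)
    except ValueError:
        kd_app = float("nan")
    return FitResult(
        params=params,
        nll=float(best.fun),
        success=bool(best.success),
        n_starts=n_starts,
        starts=starts,
        seed=seed,
        extra={"apparent_kd": kd_app, "names": ["log10_K_step", "log10_sigma"]},
    )
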
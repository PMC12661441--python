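"""Mass-photometry forward model and oligomer assignment.

Single particles land on the coverslip with probability proportional to the
particle fraction of each oligomer; the observed mass is the true oligomer
mass blurred by the instrument's calibrated mass error.  Assignment back to
oligomer counts uses a six-component Gaussian mixture with means fixed at
integer multiples of the protomer mass (species identities are known), a
shared fitted width, and maximum-responsibility labeling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assembly import MAX_ORDER, SpeciesTable, oligomer_particle_fractions
from .nms import PROTOMER_MASS_DA

__all__ = [
    "MPExperiment",
    "MixtureFitError",
    "OligomerAssignment",
    "simulate_particles",
    "assign_oligomers",
    "contrast_to_mass",
]


class MixtureFitError(RuntimeError):
    """Degenerate Gaussian-mixture fit."""


@dataclass
class MPExperiment:
    """One mass-photometry acquisition."""

    protomer_total: float  # M
    n_particles: int = 5000
    mass_sigma: float = 6000.0  # Da; typical MP resolution class
    calibration: tuple[float, float] = (1.0, 0.0)  # contrast -> mass (slope, intercept)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_particles <= 0:
            raise ValueError("n_particles must be > 0")
        if self.mass_sigma <= 0:
            raise ValueError("mass_sigma must be > 0")


@dataclass
class OligomerAssignment:
    counts: np.ndarray  # per j = 1..6
    sigma: float
    weights: np.ndarray
    labels: np.ndarray  # per-particle oligomer order


def contrast_to_mass(contrast: np.ndarray, calibration: tuple[float, float]) -> np.ndarray:
    """Affine calibration map from ratiometric contrast to mass (Da)."""
    slope, intercept = calibration
    return slope * np.asarray(contrast, dtype=float) + intercept


def simulate_particles(
    table: SpeciesTable,
    exp: MPExperiment,
    protomer_mass: float = PROTOMER_MASS_DA,
) -> np.ndarray:
    """Observed particle masses: multinomial landing + Gaussian mass error."""
    fractions = oligomer_particle_fractions(table)
    rng = np.random.default_rng(exp.seed)
    orders = rng.choice(np.arange(1, MAX_ORDER + 1), size=exp.n_particles, p=fractions)
    return orders * protomer_mass + rng.normal(0.0, exp.mass_sigma, exp.n_particles)


def assign_oligomers(
    masses: np.ndarray,
    protomer_mass: float = PROTOMER_MASS_DA,
    max_order: int = MAX_ORDER,
    max_iter: int = 500,
    tol: float = 1e-10,
    sigma_floor: float = 10.0,
) -> OligomerAssignment:
    """Fit a fixed-means Gaussian mixture and assign each particle an oligomer order.

    Means are pinned to j * protomer_mass for j = 1..max_order; only the
    shared width and the mixture weights are free, which avoids label
    switching for these well-separated species.  The width is floored at
    ``sigma_floor`` (Da) so that particles sitting exactly on a mean keep a
    well-defined mixture; a fit is rejected only when no particle lies near
    any mean.
    """
    m = np.asarray(masses, dtype=float)
    if m.size == 0:
        raise MixtureFitError("no particles to assign")
    means = protomer_mass * np.arange(1, max_order + 1)
    if np.min(np.abs(m[:, None] - means[None, :]), axis=1).max() > protomer_mass * 2:
        raise MixtureFitError("particles far from every oligomer mass; wrong calibration?")

    sigma = protomer_mass / 8.0
    weights = np.full(max_order, 1.0 / max_order)
    for _ in range(max_iter):
        d2 = (m[:, None] - means[None, :]) ** 2
        log_r = -0.5 * d2 / sigma**2 + np.log(np.maximum(weights, 1e-300))
        log_r -= log_r.max(axis=1, keepdims=True)
        r = np.exp(log_r)
        r /= r.sum(axis=1, keepdims=True)
        weights = r.mean(axis=0)
        sigma_new = max(np.sqrt(float((r * d2).sum() / m.size)), sigma_floor)
        if abs(sigma_new - sigma) < tol * sigma:
            sigma = sigma_new
            break
        sigma = sigma_new
    labels = np.argmax(r, axis=1) + 1
    counts = np.bincount(labels, minlength=max_order + 1)[1:]
    return OligomerAssignment(counts=counts, sigma=sigma, weights=weights, labels=labels)
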
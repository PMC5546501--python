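"""Synthetic-data generators emulating the study's inputs.

Point patterns: complete spatial randomness (the Monte-Carlo null), Thomas
and Matern cluster processes (the clustered alternatives at nanocluster
scale), and an immunogold labelling model (binomial detection, Gaussian
linker jitter, hard-core thinning at the 4.5 nm gold diameter).

FLIM: forward simulation of phase/modulation maps from a lifetime map under
the single-frequency homodyne model, and whole FRET experiments as per-cell
lifetime tables.

Every generator is deterministic given (seed, parameters).  Default point
counts (n ~ 200-400 per 1 um^2 sheet) are synthetic choices made to exercise
the estimator; the study does not publish per-sheet gold counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flim import LifetimeFrame
from .point_patterns import PointPattern, Window

__all__ = [
    "ThomasParams",
    "LabelingModel",
    "simulate_csr",
    "simulate_thomas",
    "simulate_matern",
    "apply_labeling",
    "simulate_flim_frame",
    "simulate_fret_experiment",
]

GOLD_DIAMETER_NM = 4.5


def _rng_from(seed: int | None, rng: np.random.Generator | None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ThomasParams:
    """Thomas (Neyman-Scott) cluster process parameters.

    parent_intensity : parents per nm^2 (kappa); expected parents per window
        is kappa * A.
    mean_offspring : expected gold particles per cluster (mu).
    cluster_sd : isotropic Gaussian scatter of offspring around the parent,
        nm (sigma); ~10-20 nm mimics nanocluster radii.
    """

    parent_intensity: float
    mean_offspring: float
    cluster_sd: float

    def __post_init__(self) -> None:
        if not (self.parent_intensity > 0 and self.mean_offspring > 0
                and self.cluster_sd > 0):
            raise ValueError("Thomas parameters must be strictly positive")

    @classmethod
    def from_parent_count(cls, parents_per_window: float, mean_offspring: float,
                          cluster_sd: float, window: Window | None = None
                          ) -> "ThomasParams":
        window = window or Window()
        return cls(parents_per_window / window.area, mean_offspring, cluster_sd)


@dataclass(frozen=True)
class LabelingModel:
    """Immunogold labelling noise: detection efficiency, linker jitter, hard core."""

    efficiency: float = 1.0
    linker_jitter_sd: float = 0.0  # nm
    hardcore_distance: float = GOLD_DIAMETER_NM  # nm

    def __post_init__(self) -> None:
        if not 0.0 < self.efficiency <= 1.0:
            raise ValueError("efficiency must be in (0, 1]")
        if self.linker_jitter_sd < 0 or self.hardcore_distance < 0:
            raise ValueError("jitter and hard-core distances must be >= 0")


def simulate_csr(n: int, window: Window | None = None,
                 seed: int | None = None, *,
                 rng: np.random.Generator | None = None,
                 image_id: str = "", condition: str = "csr") -> PointPattern:
    """Exactly n independent uniform points in the window (binomial process)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    window = window or Window()
    rng = _rng_from(seed, rng)
    coords = rng.uniform((0.0, 0.0), (window.width, window.height), size=(n, 2))
    return PointPattern(coords, window, image_id=image_id, condition=condition)


def simulate_thomas(params: ThomasParams, window: Window | None = None,
                    seed: int | None = None, *,
                    rng: np.random.Generator | None = None,
                    image_id: str = "", condition: str = "thomas") -> PointPattern:
    """Thomas cluster process restricted to the window.

    Poisson(kappa*A) parents uniform in the window; each parent spawns
    Poisson(mu) offspring displaced by isotropic Gaussian(sigma); offspring
    falling outside the window are discarded (a small edge loss when
    sigma << window size).
    """
    window = window or Window()
    rng = _rng_from(seed, rng)
    n_parents = rng.poisson(params.parent_intensity * window.area)
    parents = rng.uniform((0.0, 0.0), (window.width, window.height),
                          size=(n_parents, 2))
    pts = []
    for p in parents:
        k = rng.poisson(params.mean_offspring)
        if k:
            pts.append(p + rng.normal(0.0, params.cluster_sd, size=(k, 2)))
    coords = np.concatenate(pts) if pts else np.empty((0, 2))
    keep = (
        (coords[:, 0] >= 0) & (coords[:, 0] <= window.width)
        & (coords[:, 1] >= 0) & (coords[:, 1] <= window.height)
    )
    return PointPattern(coords[keep], window, image_id=image_id, condition=condition)


def simulate_matern(params: ThomasParams, window: Window | None = None,
                    seed: int | None = None, *,
                    rng: np.random.Generator | None = None,
                    image_id: str = "", condition: str = "matern") -> PointPattern:
    """Matern cluster process: offspring uniform in a disc of radius cluster_sd."""
    window = window or Window()
    rng = _rng_from(seed, rng)
    n_parents = rng.poisson(params.parent_intensity * window.area)
    parents = rng.uniform((0.0, 0.0), (window.width, window.height),
                          size=(n_parents, 2))
    pts = []
    for p in parents:
        k = rng.poisson(params.mean_offspring)
        if k:
            radii = params.cluster_sd * np.sqrt(rng.uniform(size=k))
            theta = rng.uniform(0, 2 * np.pi, size=k)
            pts.append(p + np.column_stack([radii * np.cos(theta),
                                            radii * np.sin(theta)]))
    coords = np.concatenate(pts) if pts else np.empty((0, 2))
    keep = (
        (coords[:, 0] >= 0) & (coords[:, 0] <= window.width)
        & (coords[:, 1] >= 0) & (coords[:, 1] <= window.height)
    )
    return PointPattern(coords[keep], window, image_id=image_id, condition=condition)


def apply_labeling(pattern: PointPattern, model: LabelingModel,
                   seed: int | None = None, *,
                   rng: np.random.Generator | None = None) -> PointPattern:
    """Degrade a true molecular pattern into an observed immunogold pattern.

    Each molecule is detected independently with probability ``efficiency``;
    detected positions are displaced by Gaussian linker jitter (clipped to
    the window); finally pairs closer than ``hardcore_distance`` are thinned
    nearest-pair-first, removing one randomly chosen member of each
    offending pair, until no violating pair remains.  Deterministic per seed.
    """
    rng = _rng_from(seed, rng)
    coords = pattern.coords.copy()
    if model.efficiency < 1.0:
        keep = rng.uniform(size=len(coords)) < model.efficiency
        coords = coords[keep]
    if model.linker_jitter_sd > 0 and len(coords):
        coords = coords + rng.normal(0.0, model.linker_jitter_sd, coords.shape)
        coords[:, 0] = np.clip(coords[:, 0], 0.0, pattern.window.width)
        coords[:, 1] = np.clip(coords[:, 1], 0.0, pattern.window.height)
    if model.hardcore_distance > 0 and len(coords) >= 2:
        coords = _hardcore_thin(coords, model.hardcore_distance, rng)
    return PointPattern(coords, pattern.window,
                        image_id=pattern.image_id, condition=pattern.condition)


def _hardcore_thin(coords: np.ndarray, dmin: float,
                   rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.distance import squareform, pdist

    alive = np.ones(len(coords), dtype=bool)
    d = squareform(pdist(coords))
    np.fill_diagonal(d, np.inf)
    while True:
        sub = np.where(alive)[0]
        if sub.size < 2:
            break
        dsub = d[np.ix_(sub, sub)]
        flat = np.argmin(dsub)
        i, j = np.unravel_index(flat, dsub.shape)
        if dsub[i, j] >= dmin:
            break
        victim = sub[i] if rng.uniform() < 0.5 else sub[j]
        alive[victim] = False
    return coords[alive]


def simulate_flim_frame(tau_map, frequency: float = 40e6,
                        phase_noise_sd: float = 0.0,
                        mod_noise_sd: float = 0.0,
                        seed: int | None = None, *,
                        rng: np.random.Generator | None = None,
                        mask: np.ndarray | None = None) -> LifetimeFrame:
    """Forward-simulate a phase/modulation frame from a lifetime map (ns).

    phi = atan(omega*tau) + Gaussian noise; m = 1/sqrt(1+(omega*tau)^2) +
    Gaussian noise, clipped to [0, 1].  Zero-noise frames invert exactly
    through the FLIM estimators.
    """
    tau = np.asarray(tau_map, dtype=float) * 1e-9  # ns -> s
    if np.any(tau < 0):
        raise ValueError("lifetimes must be non-negative")
    rng = _rng_from(seed, rng)
    omega = 2.0 * np.pi * frequency
    phase = np.arctan(omega * tau)
    mod = 1.0 / np.sqrt(1.0 + (omega * tau) ** 2)
    if phase_noise_sd > 0:
        phase = phase + rng.normal(0.0, phase_noise_sd, phase.shape)
    if mod_noise_sd > 0:
        mod = np.clip(mod + rng.normal(0.0, mod_noise_sd, mod.shape), 0.0, 1.0)
    return LifetimeFrame(phase, mod, frequency=frequency, mask=mask)


def simulate_fret_experiment(tau_d: float, true_e: float, n_cells: int = 30,
                             cell_sd: float = 0.1,
                             seed: int | None = None, *,
                             rng: np.random.Generator | None = None
                             ) -> pd.DataFrame:
    """Per-cell lifetime tables for a donor-only and a donor+acceptor sample.

    Donor cells ~ Normal(tau_d, cell_sd) ns; donor+acceptor cells ~
    Normal(tau_d * (1 - true_e/100), cell_sd) ns, truncated positive by
    redrawing.  Returns a tidy table with columns ``sample`` ('donor' or
    'donor_acceptor'), ``cell_id`` and ``tau_ns``.
    """
    if not 0.0 <= true_e < 100.0:
        raise ValueError("true_e must be in [0, 100)")
    if tau_d <= 0:
        raise ValueError("tau_d must be positive")
    rng = _rng_from(seed, rng)

    def _truncated_normal(mean: float, sd: float, size: int) -> np.ndarray:
        vals = rng.normal(mean, sd, size=size)
        while np.any(vals <= 0):
            bad = vals <= 0
            vals[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        return vals

    donor = _truncated_normal(tau_d, cell_sd, n_cells) if cell_sd > 0 else np.full(n_cells, tau_d)
    tau_da_mean = tau_d * (1.0 - true_e / 100.0)
    da = _truncated_normal(tau_da_mean, cell_sd, n_cells) if cell_sd > 0 else np.full(n_cells, tau_da_mean)
    rows = (
        [("donor", f"d{i:03d}", t) for i, t in enumerate(donor)]
        + [("donor_acceptor", f"da{i:03d}", t) for i, t in enumerate(da)]
    )
    return pd.DataFrame(rows, columns=["sample", "cell_id", "tau_ns"])
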
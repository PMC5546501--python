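"""Model/Results objects orchestrating the full analyses.

`NanoclusterModel` takes replicated immunogold point patterns grouped by
condition and, on `fit()`, computes per-image edge-corrected K/L curves,
condition-mean curves, Monte-Carlo CSR envelopes and classifications, and
pairwise bootstrap comparisons.  `FlimFretModel` takes per-cell donor and
donor+acceptor lifetimes and on `fit()` returns apparent FRET efficiencies
with their uncertainty.  Both follow the model -> fit() -> results idiom:
estimates, uncertainties and diagnostics live on the results object, which
also knows how to `summary()` and `plot()` itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import inference
from .flim import FretMeasurement, fret_efficiency
from .inference import Envelope, GroupComparison, average_curves, bootstrap_compare, csr_envelope, exceeds_envelope
from .point_patterns import PointPattern, Window
from .ripley import KCurve, RGrid, k_function

__all__ = ["NanoclusterModel", "NanoclusterResults", "FlimFretModel", "FretResults"]


class NanoclusterModel:
    """Ripley K / L(r)-r nanoclustering analysis of grouped point patterns.

    Parameters
    ----------
    patterns : list of PointPattern
        Per-image gold coordinates; the ``condition`` label defines groups.
    rgrid : RGrid, optional
        Radius grid (default 1..240 nm, 1 nm steps).
    correction : str
        Edge correction passed to the K estimator (default 'isotropic').
    minimum_images : int
        Fewest images per condition accepted by fit() (default 15; the
        study design images at least 15 sheets per condition).
    """

    def __init__(self, patterns: list[PointPattern], rgrid: RGrid | None = None,
                 correction: str = "isotropic", minimum_images: int = 15):
        if not patterns:
            raise ValueError("no patterns supplied")
        self.patterns = list(patterns)
        self.rgrid = rgrid or RGrid()
        self.correction = correction
        self.minimum_images = minimum_images

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, window: Window | None = None,
                       **kwargs) -> "NanoclusterModel":
        """Build from a tidy table with columns x, y, image_id, condition (nm)."""
        window = window or Window()
        required = {"x", "y", "image_id", "condition"}
        if not required.issubset(df.columns):
            raise ValueError(f"missing columns: {sorted(required - set(df.columns))}")
        patterns = []
        for (cond, img), sub in df.groupby(["condition", "image_id"], sort=True):
            patterns.append(PointPattern(sub[["x", "y"]].to_numpy(float), window,
                                         image_id=str(img), condition=str(cond)))
        return cls(patterns, **kwargs)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.patterns:
            seen.setdefault(p.condition)
        return list(seen)

    def fit(self, *, n_simulations: int = 199, level: float = 0.99,
            n_bootstrap: int = 1000, r_band: tuple[float, float] = inference.DEFAULT_R_BAND,
            weighting: str = "by_point_count", seed: int | None = None,
            compare: bool = True, enforce_minimum: bool = False) -> "NanoclusterResults":
        """Run the full analysis.

        ``enforce_minimum`` rejects conditions with fewer than
        ``minimum_images`` patterns; off by default so small synthetic
        studies can be analysed, with the count reported in the summary.
        """
        rng = np.random.default_rng(seed)
        curves: dict[str, list[KCurve]] = {c: [] for c in self.conditions}
        for p in self.patterns:
            curves[p.condition].append(k_function(p, self.rgrid, self.correction))
        if enforce_minimum:
            for cond, cs in curves.items():
                if len(cs) < self.minimum_images:
                    raise ValueError(
                        f"condition '{cond}' has {len(cs)} images; "
                        f"minimum is {self.minimum_images}")

        mean_curves = {c: average_curves(cs, weighting) for c, cs in curves.items()}
        envelopes: dict[str, Envelope] = {}
        classifications: dict[str, str] = {}
        for cond, cs in curves.items():
            n_mean = int(round(np.mean([c.n for c in cs])))
            env = csr_envelope(max(n_mean, 2), self.patterns[0].window, self.rgrid,
                               n_simulations, level,
                               rng=rng, correction=self.correction)
            envelopes[cond] = env
            classifications[cond] = exceeds_envelope(
                mean_curves[cond], env, r_band)["classification"]

        comparisons: dict[tuple[str, str], GroupComparison] = {}
        if compare and len(self.conditions) > 1:
            conds = self.conditions
            for i in range(len(conds)):
                for j in range(i + 1, len(conds)):
                    a, b = conds[i], conds[j]
                    if len(curves[a]) >= 2 and len(curves[b]) >= 2:
                        comparisons[(a, b)] = bootstrap_compare(
                            curves[a], curves[b], n_bootstrap,
                            r_band=r_band, weighting=weighting, rng=rng, seed=seed)
        return NanoclusterResults(
            model=self, curves=curves, mean_curves=mean_curves,
            envelopes=envelopes, classifications=classifications,
            comparisons=comparisons, level=level, r_band=r_band, seed=seed)


@dataclass
class NanoclusterResults:
    """Fitted nanoclustering analysis: curves, envelopes, classifications, tests."""

    model: NanoclusterModel
    curves: dict[str, list[KCurve]]
    mean_curves: dict[str, KCurve]
    envelopes: dict[str, Envelope]
    classifications: dict[str, str]
    comparisons: dict[tuple[str, str], GroupComparison]
    level: float
    r_band: tuple[float, float]
    seed: int | None = None

    def peak_statistics(self) -> pd.DataFrame:
        """Peak L(r)-r of each condition's mean curve and the radius of the peak."""
        rows = []
        for cond, mc in self.mean_curves.items():
            l = mc.l_values
            i = int(np.argmax(l))
            cs = self.curves[cond]
            per_image_peaks = [float(np.max(c.l_values)) for c in cs]
            rows.append({
                "condition": cond,
                "n_images": len(cs),
                "total_golds": mc.n,
                "peak_l_minus_r": float(l[i]),
                "peak_radius_nm": float(mc.rgrid.radii[i]),
                "peak_sem": float(np.std(per_image_peaks, ddof=1)
                                  / np.sqrt(len(cs))) if len(cs) > 1 else np.nan,
                "classification": self.classifications[cond],
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Nanoclustering K-function analysis",
            f"  correction: {self.model.correction}; grid: "
            f"{self.model.rgrid.radii[0]:g}-{self.model.rgrid.radii[-1]:g} nm; "
            f"envelope level: {self.level:.0%}; report band: "
            f"{self.r_band[0]:g}-{self.r_band[1]:g} nm",
            "",
            self.peak_statistics().to_string(index=False,
                                             float_format=lambda v: f"{v:.3f}"),
        ]
        if self.comparisons:
            lines += ["", "Bootstrap comparisons (integrated squared mean-curve difference):"]
            for (a, b), cmp_ in self.comparisons.items():
                lines.append(
                    f"  {a} vs {b}: T = {cmp_.statistic:.3f} nm^3, "
                    f"p = {cmp_.p_value:.4f} ({cmp_.n_bootstrap} resamples)")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Mean L(r)-r per condition with each condition's CSR envelope band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for cond, mc in self.mean_curves.items():
            r = mc.rgrid.radii
            (line,) = ax.plot(r, mc.l_values, label=f"{cond} ({self.classifications[cond]})")
            env = self.envelopes[cond]
            ax.fill_between(r, env.lower, env.upper, alpha=0.15,
                            color=line.get_color())
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xlabel("r (nm)")
        ax.set_ylabel("L(r) - r (nm)")
        ax.legend()
        return ax


class FlimFretModel:
    """Apparent FRET efficiency from per-cell donor lifetimes.

    Parameters
    ----------
    donor_lifetimes : array-like
        Donor-only per-cell lifetimes (ns).
    donor_acceptor_lifetimes : array-like
        Donor+acceptor per-cell lifetimes (ns).
    """

    def __init__(self, donor_lifetimes, donor_acceptor_lifetimes):
        self.donor = np.atleast_1d(np.asarray(donor_lifetimes, float))
        self.donor_acceptor = np.atleast_1d(np.asarray(donor_acceptor_lifetimes, float))
        if self.donor.size < 1 or self.donor_acceptor.size < 1:
            raise ValueError("both samples need at least one cell")
        if np.any(self.donor <= 0) or np.any(self.donor_acceptor <= 0):
            raise ValueError("lifetimes must be positive")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, sample_col: str = "sample",
                       tau_col: str = "tau_ns", donor_label: str = "donor",
                       da_label: str = "donor_acceptor") -> "FlimFretModel":
        """Build from a tidy per-cell table such as simulate_fret_experiment's output."""
        donor = df.loc[df[sample_col] == donor_label, tau_col]
        da = df.loc[df[sample_col] == da_label, tau_col]
        return cls(donor.to_numpy(), da.to_numpy())

    def fit(self) -> "FretResults":
        tau_d_mean = float(np.mean(self.donor))
        measurement = fret_efficiency(self.donor_acceptor, tau_d_mean)
        return FretResults(model=self, measurement=measurement)


@dataclass
class FretResults:
    """Per-cell and summary apparent FRET efficiencies."""

    model: FlimFretModel
    measurement: FretMeasurement

    @property
    def e_app_mean(self) -> float:
        return self.measurement.mean

    @property
    def e_app_sem(self) -> float:
        return self.measurement.sem

    def summary(self) -> str:
        m = self.measurement
        d = self.model.donor
        return "\n".join([
            "FLIM-FRET apparent efficiency",
            f"  donor-only: tau_D = {m.tau_d:.3f} ns (mean of {d.size} cells)",
            f"  donor+acceptor: {m.n_cells} cells, "
            f"mean tau_DA = {float(np.mean(m.tau_da)):.3f} ns",
            f"  E_app = {m.mean:.2f} +/- {m.sem:.2f} % (mean +/- SEM)",
        ])

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.boxplot([self.measurement.e_app], tick_labels=["donor+acceptor"])
        ax.set_ylabel("E_app (%)")
        ax.axhline(0.0, color="k", lw=0.5)
        return ax
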
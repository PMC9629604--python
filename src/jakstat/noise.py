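"""Intrinsic/extrinsic noise experiments.

Extrinsic (cell-to-cell) variability is modeled by randomizing the initial
molecule counts: each in-scope species starts from a draw of
Normal(mu, (sigma*mu)^2) — a relative spread, so one sigma is meaningful for
species whose means span five orders of magnitude — truncated at zero and
rounded to an integer.  sigma = 0 recovers the deterministic initial
conditions exactly (only intrinsic noise remains).  Promoter microstates are
always resampled per trajectory from their occupancy probabilities,
independently of sigma.

Variability is quantified with a modified coefficient of variation,
cv = sd / (mean + 0.1), which damps the blow-up of the plain CV for species
whose mean copy number is below one (RC and the ISG mRNAs here) and is
indistinguishable from the plain CV for abundant species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import Ensemble
from .metrics import ks_distance
from .model import GENES, ReactionNetwork, SpeciesRole

__all__ = [
    "InitialConditionSampler",
    "NoiseMap",
    "sample_initial_conditions",
    "modified_cv",
    "cv_heatmap",
    "response_conservation",
    "DEFAULT_CONSERVATION_TIMES_H",
]

#: experimental snapshot panel (hours)
DEFAULT_CONSERVATION_TIMES_H = (8.0, 12.0, 16.0, 20.0, 32.0)

#: heatmap color scale is clamped at this modified-CV value
CV_COLOR_CLAMP = 4.0


def default_scope(network: ReactionNetwork) -> list[str]:
    """Species randomized by default: ligand/protein/complex/mRNA species
    with a nonzero initial mean (zero-mean species and promoter states keep
    their deterministic initialization)."""
    keep = {
        SpeciesRole.LIGAND,
        SpeciesRole.PROTEIN,
        SpeciesRole.COMPLEX,
        SpeciesRole.MRNA,
    }
    return [
        s.name
        for s in network.species
        if s.role in keep and s.initial_value > 0
    ]


@dataclass
class InitialConditionSampler:
    """Relative-spread lognormal-free Gaussian sampler for initial counts.

    Parameters
    ----------
    sigma:
        Relative spread; the SD of species i is ``sigma * mu_i``.
    species_scope:
        Names of species to randomize; defaults to all ligand, protein,
        complex and mRNA species with nonzero mean.
    mean_overrides:
        Optional per-species replacement of the network's initial means.
    """

    sigma: float = 0.0
    species_scope: list[str] | None = None
    mean_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def sample_molecular(
        self, x0: np.ndarray, network: ReactionNetwork, rng: np.random.Generator
    ) -> np.ndarray:
        x = x0.copy()
        scope = self.species_scope
        if scope is None:
            scope = default_scope(network)
        for name in scope:
            i = network.species_index(name)
            mu = self.mean_overrides.get(name, x0[i])
            if self.sigma > 0.0 and mu > 0.0:
                v = rng.normal(mu, self.sigma * mu)
                x[i] = np.rint(max(v, 0.0))
            else:
                x[i] = np.rint(mu)
        return x


def sample_initial_conditions(
    sampler: InitialConditionSampler,
    network: ReactionNetwork,
    rng: np.random.Generator,
) -> np.ndarray:
    """One draw of the initial copy-number vector (molecular species only;
    promoter states keep their deterministic fractional initialization,
    which the simulation engine later resolves into a microstate)."""
    return sampler.sample_molecular(network.initial_state(), network, rng)


def modified_cv(samples) -> float:
    """Population SD divided by (mean + 0.1)."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("modified_cv requires at least 2 samples")
    return float(x.std(ddof=0) / (x.mean() + 0.1))


@dataclass
class NoiseMap:
    """Species x time matrix of modified CVs for one extrinsic-noise level."""

    values: np.ndarray  # (n_species, n_times)
    species: list[str]
    times_min: np.ndarray
    sigma: float

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.values,
            index=pd.Index(self.species, name="species"),
            columns=[f"{t:g}" for t in self.times_min],
        )
        df.to_csv(path)

    def to_png(self, path: str | Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(8, 0.25 * len(self.species) + 1.5), constrained_layout=True
        )
        im = ax.imshow(
            np.clip(self.values, 0.0, CV_COLOR_CLAMP),
            aspect="auto",
            cmap="Blues",
            vmin=0.0,
            vmax=CV_COLOR_CLAMP,
            interpolation="nearest",
        )
        ax.set_yticks(range(len(self.species)), self.species, fontsize=6)
        step = max(1, len(self.times_min) // 8)
        ax.set_xticks(
            range(0, len(self.times_min), step),
            [f"{t/60:g}" for t in self.times_min[::step]],
        )
        ax.set_xlabel("time (h)")
        ax.set_title(f"modified CV, extrinsic sigma = {self.sigma:g} (clamped at 4)")
        fig.colorbar(im, ax=ax, label="sd / (mean + 0.1)")
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _cv_matrix(ens: Ensemble, species: list[str]) -> np.ndarray:
    out = np.empty((len(species), len(ens.time_grid)))
    for r, sp in enumerate(species):
        m = ens.species_matrix(sp)
        out[r] = m.std(axis=0, ddof=0) / (m.mean(axis=0) + 0.1)
    return out


def cv_heatmap(
    ensembles: dict[float, Ensemble],
    species: list[str] | None = None,
) -> dict[float, NoiseMap]:
    """Modified-CV maps for ensembles simulated at different extrinsic sigma.

    Rows (species) are ordered by the time-averaged modified CV of the
    sigma = 0.3 ensemble when present (otherwise of the smallest sigma), the
    ordering used to display the heatmap.  Promoter microstates are excluded:
    the map describes molecular copy-number variability.
    """
    if not ensembles:
        raise ValueError("at least one ensemble required")
    ref = next(iter(ensembles.values()))
    t_grid = ref.time_grid
    for ens in ensembles.values():
        if not np.array_equal(ens.time_grid, t_grid):
            raise ValueError("ensembles must share one time grid")
        if ens.species_names != ref.species_names:
            raise ValueError("ensembles must share one species set")
    if species is None:
        # molecular species only (promoter occupancy indicators excluded)
        promoter = {n for g in GENES for n in (g, f"{g}*", f"I_{g}")}
        species = [n for n in ref.species_names if n not in promoter]
    order_sigma = 0.3 if 0.3 in ensembles else min(ensembles)
    order_cv = _cv_matrix(ensembles[order_sigma], species).mean(axis=1)
    ranked = [species[i] for i in np.argsort(-order_cv)]
    return {
        sigma: NoiseMap(_cv_matrix(ens, ranked), ranked, t_grid, sigma)
        for sigma, ens in ensembles.items()
    }


def response_conservation(
    ensemble_sigma: Ensemble,
    ensemble_zero: Ensemble,
    readout_species: str = "MxA",
    t_points_h=DEFAULT_CONSERVATION_TIMES_H,
) -> pd.DataFrame:
    """Kolmogorov distance between the readout marginals of an extrinsic
    ensemble and the intrinsic-only ensemble at each requested time point."""
    rows = []
    for th in t_points_h:
        d = ks_distance(
            ensemble_sigma.marginal(readout_species, th * 60.0),
            ensemble_zero.marginal(readout_species, th * 60.0),
        )
        rows.append(
            {
                "sigma": ensemble_sigma.metadata.get("sigma", np.nan),
                "time_h": th,
                "species": readout_species,
                "ks": d,
            }
        )
    return pd.DataFrame(rows)
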
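"""Synthetic cohort generator.

Emulates the statistical structure that the tile-stratification pipeline
assumes, so every downstream stage can be exercised offline:

* tile feature vectors with a latent 3-cluster structure and an additive
  per-feature batch offset for the non-reference cohort;
* per-patient cluster mixtures drawn from a Dirichlet distribution;
* exponential progression times with a group-dependent hazard (High vs Low
  hazard ratio, default 0.63) plus optional categorical-covariate effects,
  under independent uniform censoring calibrated to a target censoring rate;
* categorical clinical covariates (smoking, WHO performance status,
  histology, line of therapy) with configurable marginals;
* two-chromogen Beer-Lambert tile images with a known stain matrix, for
  testing stain estimation and normalization.

The three cluster means sit at the vertices of an equilateral triangle in a
low-dimensional latent subspace, scaled so their pairwise distance equals
``cluster_separation * noise_sd``, then rotated into feature space by a
seeded random orthonormal map. Clusters 1 and 2 constitute the "High"
outcome group, cluster 3 the "Low" group, mirroring the merge rule the
classifier applies downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._rng import stage_rng
from .features import TileFeatureTable

__all__ = [
    "SimConfig",
    "SimulatedCohort",
    "simulate_tile_features",
    "simulate_survival",
    "simulate_clinical",
    "simulate_cohort",
    "render_ihc_tile",
    "DEFAULT_STAIN_MATRIX",
]

REFERENCE_COHORT = "discovery"
OTHER_COHORT = "validation"

# Hematoxylin / DAB absorbance directions (Ruifrok & Johnston constants),
# column-unit-norm. Used as the ground-truth matrix when rendering tiles.
DEFAULT_STAIN_MATRIX = np.array(
    [[0.650, 0.268],
     [0.704, 0.570],
     [0.286, 0.776]]
)
DEFAULT_STAIN_MATRIX /= np.linalg.norm(DEFAULT_STAIN_MATRIX, axis=0, keepdims=True)

#: marginal frequencies of the categorical covariates (whole-cohort values)
DEFAULT_COVARIATE_MARGINALS: dict[str, dict[str, float]] = {
    "smoking": {"Never": 0.09, "Ever": 0.91},
    "who_ps": {"0": 0.17, ">=1": 0.83},
    "histology": {"Adenocarcinoma": 0.72, "Squamous": 0.18, "Other": 0.10},
    "line": {"1": 0.66, ">1": 0.34},
}

#: log-hazard increments per covariate level, calibrated to the published
#: univariate hazard ratios (smoking Ever 0.51; WHO PS >=1 1.93)
DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "smoking:Ever": float(np.log(0.51)),
    "who_ps:>=1": float(np.log(1.93)),
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    ``cluster_separation`` is the pairwise distance between cluster means in
    units of ``noise_sd``; 8 puts clusters far apart (near-perfect recovery),
    0 removes all structure (null regime).
    """

    n_patients_per_cohort: int = 50
    tiles_per_patient: tuple[int, int] = (10, 30)
    n_features: int = 1024
    latent_dim: int = 5
    cluster_separation: float = 8.0
    noise_sd: float = 1.0
    cohort_shift_sd: float = 0.2
    tile_mixture_concentration: tuple[float, float, float] = (1.0, 1.0, 1.0)
    group_hazard_ratio: float = 0.63
    baseline_median_pfs_months: float = 2.5
    censoring_rate: float = 0.2
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    covariate_marginals: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_MARGINALS.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients_per_cohort <= 0:
            raise ValueError("n_patients_per_cohort must be positive")
        lo, hi = self.tiles_per_patient
        if lo <= 0 or hi < lo:
            raise ValueError("tiles_per_patient must be a positive (min, max) range")
        if self.n_features <= 0 or self.latent_dim <= 0:
            raise ValueError("n_features and latent_dim must be positive")
        if self.latent_dim > self.n_features:
            raise ValueError("latent_dim may not exceed n_features")
        if self.cluster_separation < 0:
            raise ValueError("cluster_separation must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be strictly positive")
        if self.cohort_shift_sd < 0:
            raise ValueError("cohort_shift_sd must be nonnegative")
        if len(self.tile_mixture_concentration) != 3 or any(
            a <= 0 for a in self.tile_mixture_concentration
        ):
            raise ValueError("tile_mixture_concentration must be 3 positive reals")
        if self.group_hazard_ratio <= 0:
            raise ValueError("group_hazard_ratio must be positive")
        if self.baseline_median_pfs_months <= 0:
            raise ValueError("baseline_median_pfs_months must be positive")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring_rate must lie in [0, 1]")
        for marg in self.covariate_marginals.values():
            probs = list(marg.values())
            if any(p < 0 or p > 1 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError("covariate marginals must be probabilities summing to 1")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SimulatedCohort:
    """Bundle of everything the generator knows about a simulated cohort."""

    feature_table: TileFeatureTable
    tile_truth: dict[str, int]
    patient_truth: pd.DataFrame  # patient_id, cohort, dominant_cluster, dl_group
    survival: pd.DataFrame | None = None  # patient_id, time_months, event
    clinical: pd.DataFrame | None = None
    config: SimConfig | None = None

    def validate(self) -> None:
        ids = set(self.feature_table.frame["patient_id"])
        if self.survival is not None and not ids <= set(self.survival["patient_id"]):
            raise ValueError("every tile's patient must appear in the survival table")
        if self.clinical is not None and not ids <= set(self.clinical["patient_id"]):
            raise ValueError("every tile's patient must appear in the clinical table")


def _cluster_means(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Three cluster means in feature space, pairwise distance sep*noise_sd."""
    d = config.cluster_separation * config.noise_sd
    # equilateral triangle in the first two latent coordinates, centered
    tri = np.zeros((3, config.latent_dim))
    tri[1, 0] = d
    tri[2, 0] = d / 2.0
    tri[2, 1] = d * np.sqrt(3.0) / 2.0
    tri -= tri.mean(axis=0)
    # seeded random orthonormal embedding latent_dim -> n_features
    a = rng.standard_normal((config.n_features, config.latent_dim))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))  # deterministic orientation
    return tri @ q.T


def simulate_tile_features(config: SimConfig) -> SimulatedCohort:
    """Generate the tile feature table plus ground-truth labels.

    Each tile vector is its cluster mean plus isotropic Gaussian noise; tiles
    of the non-reference cohort additionally receive one shared per-feature
    offset drawn from N(0, cohort_shift_sd^2). Per-patient cluster
    proportions follow a Dirichlet distribution.
    """
    rng = stage_rng(config.seed, "features")
    means = _cluster_means(config, rng)
    shift = rng.normal(0.0, config.cohort_shift_sd or 0.0, size=config.n_features)
    if config.cohort_shift_sd == 0:
        shift = np.zeros(config.n_features)

    lo, hi = config.tiles_per_patient
    conc = np.asarray(config.tile_mixture_concentration, float)

    pat_rows = []
    pid_list, coh_list, tid_list = [], [], []
    truth: dict[str, int] = {}
    blocks = []
    for cohort in (REFERENCE_COHORT, OTHER_COHORT):
        for i in range(config.n_patients_per_cohort):
            pid = f"{cohort[:3].upper()}-{i + 1:04d}"
            n_tiles = int(rng.integers(lo, hi + 1))
            props = rng.dirichlet(conc)
            counts = rng.multinomial(n_tiles, props)
            labels = np.repeat([1, 2, 3], counts)
            noise = rng.normal(0.0, config.noise_sd, size=(n_tiles, config.n_features))
            x = means[labels - 1] + noise
            if cohort == OTHER_COHORT:
                x = x + shift
            blocks.append(x)
            for j, lab in enumerate(labels):
                tid = f"{pid}-t{j + 1:04d}"
                pid_list.append(pid)
                coh_list.append(cohort)
                tid_list.append(tid)
                truth[tid] = int(lab)
            dominant = int(np.argmax(counts) + 1)  # argmax -> lowest index on ties
            pat_rows.append(
                {
                    "patient_id": pid,
                    "cohort": cohort,
                    "dominant_cluster": dominant,
                    "dl_group": "High" if dominant in (1, 2) else "Low",
                    "n_tiles": n_tiles,
                }
            )

    X = np.vstack(blocks)
    table = TileFeatureTable.from_arrays(pid_list, coh_list, tid_list, X)
    patient_truth = pd.DataFrame(pat_rows)
    return SimulatedCohort(
        feature_table=table, tile_truth=truth, patient_truth=patient_truth, config=config
    )


def _solve_censoring_bound(rates: np.ndarray, target: float) -> float:
    """Upper bound c of Uniform(0, c) censoring achieving the target rate.

    For C ~ U(0, c) independent of T ~ Exp(lam), P(C < T) =
    (1 - exp(-lam c)) / (lam c); the cohort-level rate averages this over
    patients' rates. Monotone decreasing in c, so a bracketed root exists for
    any target in (0, 1).
    """

    def cens_prob(c: float) -> float:
        lc = rates * c
        return float(np.mean((1.0 - np.exp(-lc)) / lc))

    lo, hi = 1e-9, 1e12
    return brentq(lambda c: cens_prob(c) - target, lo, hi, xtol=1e-12, rtol=1e-12)


def simulate_survival(
    patient_truth: pd.DataFrame,
    config: SimConfig,
    clinical: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Exponential event times with group-dependent hazard and uniform censoring.

    The Low group has rate ln2 / baseline_median_pfs_months; the High group's
    rate is that times ``group_hazard_ratio``. When a clinical table is given,
    configured ``covariate_effects`` ("column:level" -> log-hazard) multiply
    each patient's rate.
    """
    if len(patient_truth) == 0:
        raise ValueError("patient_truth must be non-empty")
    rng = stage_rng(config.seed, "survival")
    lam_low = np.log(2.0) / config.baseline_median_pfs_months
    rates = np.where(
        patient_truth["dl_group"].to_numpy() == "High",
        lam_low * config.group_hazard_ratio,
        lam_low,
    ).astype(float)

    if clinical is not None and config.covariate_effects:
        clin = clinical.set_index("patient_id")
        loghaz = np.zeros(len(patient_truth))
        for key, beta in config.covariate_effects.items():
            col, _, level = key.partition(":")
            if col not in clin.columns:
                raise KeyError(f"covariate_effects key {key!r}: column {col!r} not in clinical table")
            match = (clin.loc[patient_truth["patient_id"], col] == level).to_numpy()
            loghaz += beta * match
        rates = rates * np.exp(loghaz)

    t_event = rng.exponential(1.0 / rates)
    if config.censoring_rate <= 0:
        time, event = t_event, np.ones(len(t_event), dtype=int)
    elif config.censoring_rate >= 1:
        raise ValueError("censoring_rate of 1 would censor every record")
    else:
        c = _solve_censoring_bound(rates, config.censoring_rate)
        t_cens = rng.uniform(0.0, c, size=len(t_event))
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    time = np.maximum(time, 1e-9)  # strictly positive
    return pd.DataFrame(
        {
            "patient_id": patient_truth["patient_id"].to_numpy(),
            "time_months": time,
            "event": event,
        }
    )


def simulate_clinical(patient_ids: Sequence[str], config: SimConfig) -> pd.DataFrame:
    """Draw categorical covariates from the configured marginal frequencies."""
    rng = stage_rng(config.seed, "clinical")
    out = {"patient_id": list(patient_ids)}
    n = len(out["patient_id"])
    for col, marg in config.covariate_marginals.items():
        levels = list(marg.keys())
        probs = np.asarray(list(marg.values()), float)
        out[col] = rng.choice(levels, size=n, p=probs)
    return pd.DataFrame(out)


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Full simulation: features + truth, clinical covariates, survival."""
    cohort = simulate_tile_features(config)
    cohort.clinical = simulate_clinical(cohort.patient_truth["patient_id"], config)
    cohort.survival = simulate_survival(cohort.patient_truth, config, cohort.clinical)
    cohort.validate()
    return cohort


def render_ihc_tile(
    stain_matrix: np.ndarray,
    concentration_maps: Sequence[np.ndarray],
    background_intensity: int = 255,
) -> np.ndarray:
    """Render a two-chromogen RGB tile under the Beer-Lambert law.

    Pixel intensity per channel c is ``io * exp(-(M @ C)_c)`` where M is the
    3x2 column-unit-norm stain absorbance matrix and C stacks the two
    nonnegative concentration maps. Output is integer-valued in [0, io].
    """
    m = np.asarray(stain_matrix, float)
    if m.shape != (3, 2):
        raise ValueError("stain_matrix must be 3x2")
    if np.any(m < 0):
        raise ValueError("stain matrix entries must be nonnegative")
    if not np.allclose(np.linalg.norm(m, axis=0), 1.0, atol=1e-6):
        raise ValueError("stain matrix columns must be unit-norm")
    if background_intensity <= 0:
        raise ValueError("background_intensity must be positive")
    c1, c2 = (np.asarray(c, float) for c in concentration_maps)
    if c1.shape != c2.shape:
        raise ValueError("concentration maps must share a shape")
    if np.any(c1 < 0) or np.any(c2 < 0):
        raise ValueError("concentrations must be nonnegative")
    conc = np.stack([c1.ravel(), c2.ravel()])  # 2 x npix
    od = m @ conc  # 3 x npix
    img = background_intensity * np.exp(-od)
    img = np.rint(img).clip(0, background_intensity)
    out = img.T.reshape(c1.shape + (3,))
    return out.astype(np.uint8 if background_intensity <= 255 else np.uint16)
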
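"""Virtual mouse-cohort generator with the statistical structure the
analysis assumes.

The default design mirrors the study conditions: 20 mice, bioluminescence
and caliper follow-up twice a week from day 6 to day 43 post-graft, an
inoculum of 1.5e5 cells converted at 88.4 photons/sec/cell, lognormal
inter-animal variability around the published typical values (a: CV 31.1%,
K: CV 55.3%, lambda: CV 10%), and 15% proportional measurement noise on
both instruments (independent errors).

Each subject's trajectory is the closed-form two-compartment solution; the
generator returns the ground-truth individual parameters alongside the
dataset so recovery can be tested end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationPlate
from .growth_model import (
    ConversionConstants,
    ModelParameters,
    proliferative_signal,
    signal_to_volume_cm3,
    total_signal,
    DEFAULT_PHOTONS_PER_CELL,
)
from .population import (
    BIOLUMINESCENCE,
    CALIPER,
    LongitudinalDataset,
    PopulationParameters,
    omega2_from_cv_percent,
)

__all__ = [
    "CohortDesign",
    "default_truth",
    "generate_cohort",
    "generate_calibration_plate",
    "inject_dropout",
    "DEFAULT_OBSERVATION_DAYS",
]

#: Twice-weekly follow-up from day 6 to day 43 post-graft (12 visits).
DEFAULT_OBSERVATION_DAYS = (6, 9, 12, 15, 18, 22, 25, 29, 32, 36, 39, 43)


def default_truth() -> PopulationParameters:
    """Published population values used as the generating ground truth."""
    return PopulationParameters(
        theta_mu={"a": 0.399, "K": 4.35e9, "lam": 2.25},
        omega2={
            "a": omega2_from_cv_percent(31.1),
            "K": omega2_from_cv_percent(55.3),
            "lam": omega2_from_cv_percent(10.0),
        },
        sigma=0.15,
    )


@dataclass
class CohortDesign:
    """Design of a virtual experiment.

    ``truth`` must contain parameters a, K and lam; ``sigma_biolum`` and
    ``sigma_caliper`` are proportional noise SDs for the two instruments.
    """

    n_subjects: int = 20
    observation_days: tuple = DEFAULT_OBSERVATION_DAYS
    injected_cells: float = 1.5e5
    photons_per_cell: float = DEFAULT_PHOTONS_PER_CELL
    cells_per_cm3: float = 1e9
    truth: PopulationParameters = field(default_factory=default_truth)
    sigma_biolum: float = 0.15
    sigma_caliper: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        days = np.asarray(self.observation_days, dtype=float)
        if np.any(np.diff(days) <= 0):
            raise ValueError("observation days must be ascending")
        if days[0] < 0 or days[-1] > 60:
            raise ValueError("observation days must lie within [0, 60]")
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")
        for s in (self.sigma_biolum, self.sigma_caliper):
            if not 0 <= s < 1:
                raise ValueError("noise SDs must lie in [0, 1)")
        missing = {"a", "K", "lam"} - set(self.truth.theta_mu)
        if missing:
            raise ValueError(f"truth missing parameters: {sorted(missing)}")

    @property
    def p0_signal(self) -> float:
        """Initial proliferative signal: injected cells x photons/cell."""
        return self.injected_cells * self.photons_per_cell

    @property
    def conversion(self) -> ConversionConstants:
        return ConversionConstants(self.photons_per_cell, self.cells_per_cm3)


def _truncated_proportional(rng, mean, sigma):
    """mean*(1+eps) resampled until positive; returns (values, n_resampled)."""
    if sigma == 0:
        return np.asarray(mean, dtype=float), 0
    mean = np.asarray(mean, dtype=float)
    out = mean * (1.0 + sigma * rng.standard_normal(mean.shape))
    n_resampled = 0
    bad = out <= 0
    while np.any(bad):
        n_resampled += int(bad.sum())
        out[bad] = mean[bad] * (1.0 + sigma * rng.standard_normal(int(bad.sum())))
        bad = out <= 0
    return out, n_resampled


def generate_cohort(design: CohortDesign) -> tuple:
    """Sample a virtual cohort; returns ``(dataset, truth_table)``.

    Per subject, (a_i, K_i, lambda_i) are drawn lognormally around the
    typical values with the design CVs (K_i is resampled if it falls at or
    below P0, keeping the inoculum under carrying capacity), the closed-form
    trajectory is evaluated on the visit grid, and both observables receive
    independent proportional Gaussian noise, resampled on the rare draw that
    would go non-positive.  ``truth_table`` holds the per-subject parameters
    and the resample counts.  Deterministic per ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    days = np.asarray(design.observation_days, dtype=float)
    p0 = design.p0_signal
    mu = design.truth.theta_mu
    w2 = design.truth.omega2

    records = []
    truth_rows = []
    n_resampled = 0
    for i in range(design.n_subjects):
        sid = f"m{i + 1:02d}"
        eta = {k: np.sqrt(w2[k]) * rng.standard_normal() for k in ("a", "K", "lam")}
        a_i = mu["a"] * np.exp(eta["a"])
        k_i = mu["K"] * np.exp(eta["K"])
        while k_i <= p0 * 1.01:
            n_resampled += 1
            k_i = mu["K"] * np.exp(np.sqrt(w2["K"]) * rng.standard_normal())
        lam_i = mu["lam"] * np.exp(eta["lam"])
        pars = ModelParameters(a=a_i, K=k_i, P0=p0, lam=lam_i)
        p_true = proliferative_signal(days, pars)
        v_true = lam_i * signal_to_volume_cm3(total_signal(days, pars), design.conversion)
        y_bli, r1 = _truncated_proportional(rng, p_true, design.sigma_biolum)
        y_cal, r2 = _truncated_proportional(rng, v_true, design.sigma_caliper)
        n_resampled += r1 + r2
        for t, y in zip(days, y_bli):
            records.append((sid, t, BIOLUMINESCENCE, y))
        for t, y in zip(days, y_cal):
            records.append((sid, t, CALIPER, y))
        truth_rows.append({"subject": sid, "a": a_i, "K": k_i, "lam": lam_i})

    frame = pd.DataFrame(records, columns=list(LongitudinalDataset.COLUMNS))
    dataset = LongitudinalDataset(frame)
    truth = pd.DataFrame(truth_rows).set_index("subject")
    truth.attrs["design"] = {
        "n_subjects": design.n_subjects,
        "observation_days": list(map(float, days)),
        "injected_cells": design.injected_cells,
        "photons_per_cell": design.photons_per_cell,
        "sigma_biolum": design.sigma_biolum,
        "sigma_caliper": design.sigma_caliper,
        "seed": design.seed,
        "n_resampled": n_resampled,
    }
    return dataset, truth


def write_cohort(dataset: LongitudinalDataset, truth: pd.DataFrame, csv_path, truth_path) -> None:
    """Write the dataset CSV and a truth sidecar JSON (per-subject parameters
    plus a design echo) for downstream recovery checks."""
    dataset.to_csv(csv_path)
    payload = {
        "design": truth.attrs.get("design", {}),
        "subjects": truth.reset_index().to_dict(orient="records"),
    }
    with open(truth_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def generate_calibration_plate(
    slope: float = DEFAULT_PHOTONS_PER_CELL,
    densities=(1e2, 1e3, 1e4, 1e5, 1e6),
    noise: float = 0.05,
    seed: int = 0,
    replicates: int = 3,
) -> CalibrationPlate:
    """Synthetic calibration plate: signal = slope*cells*(1+eps).

    Densities default to five log-spaced seeding levels spanning the design
    range 100 to 1e6 cells/well; proportional Gaussian noise with SD
    ``noise``.  Deterministic per seed.
    """
    if slope <= 0:
        raise ValueError("slope must be > 0")
    densities = np.asarray(densities, dtype=float)
    if np.any(densities <= 0):
        raise ValueError("densities must be positive")
    rng = np.random.default_rng(seed)
    cells = np.repeat(densities, replicates)
    rep = np.tile(np.arange(replicates), len(densities))
    eps = noise * rng.standard_normal(len(cells))
    signals = slope * cells * (1.0 + eps)
    signals = np.maximum(signals, 0.0)
    return CalibrationPlate(cell_counts=cells, signals=signals, replicate=rep)


def inject_dropout(data: LongitudinalDataset, threshold_cm3: float) -> tuple:
    """Humane-endpoint censoring: drop records after the caliper threshold.

    For each subject, all records (both observables) strictly after the
    first caliper observation exceeding ``threshold_cm3`` are removed,
    emulating sacrifice once the tumor reaches a welfare limit.  Returns
    ``(censored_dataset, pattern)`` where ``pattern`` maps subject to its
    censoring time (None if never censored).
    """
    if threshold_cm3 <= 0:
        raise ValueError("threshold must be > 0")
    frame = data.frame
    pattern = {}
    keep = np.ones(len(frame), dtype=bool)
    for sid, grp in frame.groupby("subject", sort=False):
        cal = grp[(grp["observable"] == CALIPER) & (grp["value"] > threshold_cm3)]
        if cal.empty:
            pattern[sid] = None
            continue
        t_censor = float(cal["time"].min())
        pattern[sid] = t_censor
        keep &= ~((frame["subject"] == sid) & (frame["time"] > t_censor))
    censored = LongitudinalDataset(frame[keep], min_bioluminescence_records=0)
    return censored, pattern
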
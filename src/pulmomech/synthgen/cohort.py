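"""Synthetic animal cohorts: per-animal mechanical parameters drawn
lognormally around group means, plus the matching ventilation recordings.

Lognormal multipliers keep every parameter positive and are mean-one
corrected, so the expected group mean equals the specified group mean.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ..errors import InvalidSpecError
from ..ventmech import VentilationRecording
from .ventilation import LungModelParams, ManeuverSpec, simulate_ventilation

#: mechanical parameters that receive between-animal variation
_VARIED = ("Est_true", "Raw", "E2", "R2")


@dataclass
class CohortSpec:
    """Two-or-more-group study design."""

    n_per_group: int
    group_means: dict            # group label -> LungModelParams of group means
    between_animal_cv: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 1:
            raise InvalidSpecError("n_per_group must be >= 1")
        if self.between_animal_cv < 0:
            raise InvalidSpecError("between_animal_cv must be >= 0")
        if not self.group_means:
            raise InvalidSpecError("group_means must not be empty")


def generate_cohort(spec: CohortSpec, maneuver: ManeuverSpec):
    """Per-animal recordings and the ground-truth parameter table.

    Returns ``(recordings, truth)`` where ``recordings`` maps group label to
    a list of VentilationRecording and ``truth`` is a tidy DataFrame with
    one row per animal (group, animal, the drawn parameters, sim seed).
    Reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    cv = spec.between_animal_cv
    sigma = float(np.sqrt(np.log1p(cv**2)))
    mu = -0.5 * sigma**2                     # mean-one lognormal

    recordings: dict[str, list[VentilationRecording]] = {}
    rows = []
    for group, means in spec.group_means.items():
        recordings[group] = []
        for i in range(spec.n_per_group):
            mult = {name: (float(rng.lognormal(mu, sigma)) if cv > 0 else 1.0)
                    for name in _VARIED}
            sim_seed = int(rng.integers(0, 2**31 - 1))
            params = replace(
                means,
                **{name: getattr(means, name) * mult[name] for name in _VARIED},
                seed=sim_seed)
            rec = simulate_ventilation(params, maneuver)
            rec.meta["group"] = group
            rec.meta["animal"] = i
            recordings[group].append(rec)
            rows.append({"group": group, "animal": i,
                         "Est_true": params.Est_true, "Raw": params.Raw,
                         "E2": params.E2, "R2": params.R2,
                         "PEEP": params.PEEP, "noise_sd": params.noise_sd,
                         "seed": sim_seed})
    truth = pd.DataFrame(rows)
    return recordings, truth
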
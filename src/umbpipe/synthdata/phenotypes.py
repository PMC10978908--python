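"""Generative model for lineage x season phenotypes.

Measurements are drawn from the normal linear mixed model

    y = beta0 + beta1[lineage] + beta2[season] + beta3[lineage, season]
        + gamma_accession + eps

with ``gamma ~ N(0, sigma_gamma^2)`` per accession and
``eps ~ N(0, sigma_eps^2)`` per record — the generative inverse of the
fitting model in :mod:`umbpipe.phenostats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class GLMMSpec:
    """Fixed and random effects of the phenotype generative model."""

    beta0: float
    beta1: Mapping[str, float]  # lineage -> effect
    beta2: Mapping[str, float]  # season -> effect
    beta3: Mapping[tuple[str, str], float] = field(default_factory=dict)
    sigma_gamma: float = 0.0
    sigma_eps: float = 0.0

    def __post_init__(self):
        if self.sigma_gamma < 0 or self.sigma_eps < 0:
            raise ValueError("standard deviations must be >= 0")
        for (lin, sea) in self.beta3:
            if lin not in self.beta1 or sea not in self.beta2:
                raise ValueError(
                    f"interaction ({lin!r}, {sea!r}) references undeclared levels"
                )

    @property
    def lineages(self) -> list[str]:
        return sorted(self.beta1)

    @property
    def seasons(self) -> list[str]:
        return sorted(self.beta2)

    def expected_value(self, lineage: str, season: str) -> float:
        return (
            self.beta0
            + self.beta1[lineage]
            + self.beta2[season]
            + self.beta3.get((lineage, season), 0.0)
        )


def make_design(
    accessions_by_lineage: Mapping[str, Sequence[str]],
    seasons: Sequence[str],
    replicates: int = 1,
) -> pd.DataFrame:
    """Fully crossed accession x season x replicate design table."""
    rows = []
    for lineage, accessions in accessions_by_lineage.items():
        for acc in accessions:
            for season in seasons:
                for rep in range(1, replicates + 1):
                    rows.append(
                        {
                            "accession": acc,
                            "lineage": lineage,
                            "season": season,
                            "replicate": rep,
                        }
                    )
    return pd.DataFrame(rows)


def gen_phenotypes(
    spec: GLMMSpec,
    design: pd.DataFrame,
    trait: str = "trait",
    missing_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw one trait's measurements for every design row.

    Returns the long-format table (accession, trait, season, replicate,
    value); an optional missing-at-random mask blanks values at
    ``missing_rate``.
    """
    undeclared = set(design["lineage"]) - set(spec.beta1)
    if undeclared:
        raise ValueError(f"design references undeclared lineages {sorted(undeclared)}")
    undeclared = set(design["season"]) - set(spec.beta2)
    if undeclared:
        raise ValueError(f"design references undeclared seasons {sorted(undeclared)}")
    if not (0 <= missing_rate < 1):
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    accessions = list(dict.fromkeys(design["accession"]))
    gamma = {
        acc: rng.normal(0.0, spec.sigma_gamma) if spec.sigma_gamma > 0 else 0.0
        for acc in accessions
    }
    mu = np.array(
        [
            spec.expected_value(row.lineage, row.season) + gamma[row.accession]
            for row in design.itertuples()
        ]
    )
    eps = (
        rng.normal(0.0, spec.sigma_eps, size=len(mu))
        if spec.sigma_eps > 0
        else np.zeros(len(mu))
    )
    values = mu + eps
    if missing_rate > 0:
        mask = rng.random(len(values)) < missing_rate
        values = np.where(mask, np.nan, values)
    out = design.copy()
    out["trait"] = trait
    out["value"] = values
    return out[["accession", "lineage", "trait", "season", "replicate", "value"]]
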
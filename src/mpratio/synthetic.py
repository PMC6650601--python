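"""Synthetic bioassay generator with the statistical structure the analysis assumes.

Each treatment cell (pct_mp, ss_conc) draws per-tube immobilization counts

    deaths ~ Binomial(n_per_tube, p_total)

where the dose effect follows the constrained logistic with an LC50 surface
that decays exponentially in %MP, and background mortality composes with the
dose effect via independence:

    p_model = 1 / (1 + (LC50(pct_mp) / C) ** hill)
    p_total = control_mortality + (1 - control_mortality) * p_model

The independence composition makes Abbott's correction exactly appropriate on
expectations.  Random streams are keyed per cell from the master seed, so
adding a design cell never perturbs the draws of the others.

Defaults mirror the magnitudes of a 96-h Daphnia magna immobilization test
with a PET/kaolin dilution series: LC50 decaying from 411 mg/L (pure
reference) toward 56 mg/L (pure test particle), ten animals per tube,
~4.6% background mortality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .data import BioassayDataset, DesignMatrix, ReplicateRecord, build_design

__all__ = [
    "GeneratorConfig",
    "default_design",
    "true_lc50",
    "true_lcx",
    "expected_mortality",
    "generate",
]

#: SS series used at the endpoint levels (0% and 100% MP), mg/L.
FULL_SS_LEVELS = (0.1, 1.0, 10.0, 100.0, 1000.0, 10000.0)
#: SS series used at the intermediate mixtures, mg/L.
MIXTURE_SS_LEVELS = (10.0, 100.0, 1000.0, 10000.0)
PCT_LEVELS = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)


def default_design(replicates: int = 5) -> DesignMatrix:
    """The study-scale grid: 6 %MP levels, 6 SS at the endpoints, 4 in between."""
    return build_design(PCT_LEVELS, FULL_SS_LEVELS, MIXTURE_SS_LEVELS, replicates)


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground truth and design for one simulated bioassay.

    ``true_decay = (y0, plateau, k)`` parameterizes the LC50 surface
    ``LC50(m) = (y0 - plateau) * exp(-k * m) + plateau`` over %MP ``m``.
    """

    design: DesignMatrix = field(default_factory=default_design)
    true_decay: tuple[float, float, float] = (411.0, 56.0, 0.08)
    true_hill: float = 1.0
    control_mortality: float = 0.046
    n_per_tube: int = 10
    n_control_tubes: int = 5
    seed: int = 0
    #: extra replicates per cell at selected %MP levels, emulating endpoint
    #: treatments being re-run across batches (unbalanced designs)
    extra_replicates: tuple[tuple[float, int], ...] = ()

    def __post_init__(self) -> None:
        y0, plateau, k = self.true_decay
        if not (0 <= plateau < y0):
            raise ValueError("true_decay requires 0 <= plateau < y0")
        if k <= 0:
            raise ValueError("true_decay requires k > 0")
        if self.true_hill <= 0:
            raise ValueError("true_hill must be > 0")
        if not 0 <= self.control_mortality < 1:
            raise ValueError("control_mortality must lie in [0, 1)")
        if self.n_per_tube < 1 or self.n_control_tubes < 1:
            raise ValueError("tube counts must be >= 1")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


def true_lc50(config: GeneratorConfig, pct_mp: float) -> float:
    """Ground-truth LC50 (mg/L) of the mixture at ``pct_mp``."""
    if not 0 <= pct_mp <= 100:
        raise ValueError(f"pct_mp must lie in [0, 100], got {pct_mp}")
    y0, plateau, k = config.true_decay
    return (y0 - plateau) * math.exp(-k * pct_mp) + plateau

def true_lcx(config: GeneratorConfig, pct_mp: float, x: float) -> float:
    """Ground-truth LCx; with the logistic model, LC50 scaled by (x/(100-x))**(1/h)."""
    return true_lc50(config, pct_mp) * (x / (100.0 - x)) ** (1.0 / config.true_hill)


def expected_mortality(config: GeneratorConfig, pct_mp: float, conc: float) -> float:
    """Expected observed mortality at a dose, background composed independently."""
    if conc < 0:
        raise ValueError("conc must be >= 0")
    if conc == 0:
        return config.control_mortality
    p_model = 1.0 / (1.0 + (true_lc50(config, pct_mp) / conc) ** config.true_hill)
    return config.control_mortality + (1.0 - config.control_mortality) * p_model


def _cell_rng(seed: int, pct_mp: float, ss_conc: float) -> np.random.Generator:
    # key the stream by cell identity (scaled to ints) rather than position
    return np.random.default_rng([seed, int(round(pct_mp * 10)), int(round(ss_conc * 10))])


def generate(config: GeneratorConfig) -> BioassayDataset:
    """Draw one full synthetic dataset; fully reproducible from ``config.seed``."""
    records: list[ReplicateRecord] = []
    rng_ctrl = np.random.default_rng([config.seed, 999_999_999])
    for _ in range(config.n_control_tubes):
        deaths = int(rng_ctrl.binomial(config.n_per_tube, config.control_mortality))
        records.append(
            ReplicateRecord(0.0, 0.0, config.n_per_tube, deaths, run_id="sim", is_control=True)
        )
    extra = dict(config.extra_replicates)
    for cell in config.design.cells():
        p_total = expected_mortality(config, cell.pct_mp, cell.ss_conc)
        rng = _cell_rng(config.seed, cell.pct_mp, cell.ss_conc)
        n_reps = config.design.replicates_per_cell + extra.get(cell.pct_mp, 0)
        for deaths in rng.binomial(config.n_per_tube, p_total, size=n_reps):
            records.append(
                ReplicateRecord(
                    cell.ss_conc,
                    cell.pct_mp,
                    config.n_per_tube,
                    int(deaths),
                    run_id="sim",
                    is_control=False,
                )
            )
    meta = {
        "generator": "mpratio.synthetic",
        "true_decay": config.true_decay,
        "true_hill": config.true_hill,
        "seed": config.seed,
    }
    return BioassayDataset(records, duration_h=96.0, metadata=meta)
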
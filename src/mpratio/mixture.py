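"""Per-mixture fitting across the %MP grid.

Two dataset-level rules are enforced before fitting:

* **Common-concentration rule** — only SS concentrations present at every %MP
  level enter the fits, so the curves are compared over the same dose range.
* **Balanced replicated subsampling** — treatment cells with more replicates
  than the rest of the design (typically the endpoint mixtures, which are run
  repeatedly across batches) are down-sampled without replacement to a common
  per-cell replicate count, repeatedly, and the per-iteration fits aggregated
  by the median.  This keeps the effective number of observations comparable
  across %MP levels.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import numpy as np

from .data import BioassayDataset, ReplicateRecord, ValidationError
from .dose_response import (
    DoseResponseFit,
    FitError,
    compare_fits,
    fit_dose_response,
)

__all__ = [
    "MixtureSeries",
    "SubsampleScheme",
    "SubsampledFit",
    "CommonConcentrations",
    "FitOptions",
    "MixtureFits",
    "common_concentrations",
    "subsample_fit",
    "fit_all",
]


@dataclass(frozen=True)
class CommonConcentrations:
    """The dataset-wide intersection of SS grids, with per-level losses."""

    values: tuple[float, ...]
    dropped: dict[float, tuple[float, ...]]


def common_concentrations(ds: BioassayDataset) -> CommonConcentrations:
    """SS concentrations shared by every %MP level (positive doses only)."""
    levels = ds.pct_levels()
    if len(levels) < 2:
        raise ValidationError("need >= 2 pct_mp levels for a common-concentration filter")
    sets = {p: {r.ss_conc for r in ds.treatment_records(p)} for p in levels}
    common = set.intersection(*sets.values())
    if not common:
        raise ValidationError(
            "no SS concentration is common to all pct_mp levels; "
            "analyse levels separately or relax the filter"
        )
    dropped = {p: tuple(sorted(sets[p] - common)) for p in levels}
    return CommonConcentrations(tuple(sorted(common)), dropped)


@dataclass
class MixtureSeries:
    """All replicate records of one %MP level, optionally common-filtered."""

    pct_mp: float
    records: list[ReplicateRecord]
    common_only: bool = False

    def __post_init__(self) -> None:
        if any(r.pct_mp != self.pct_mp for r in self.records):
            raise ValidationError("all records in a series must share pct_mp")
        if any(r.is_control for r in self.records):
            raise ValidationError("a mixture series must not contain control records")

    def cells(self) -> dict[float, list[ReplicateRecord]]:
        """Records grouped by SS concentration, deterministically ordered."""
        out: dict[float, list[ReplicateRecord]] = {}
        for r in sorted(
            self.records, key=lambda r: (r.ss_conc, r.run_id, r.n_immobilized, r.n_exposed)
        ):
            out.setdefault(r.ss_conc, []).append(r)
        return out

    @classmethod
    def from_dataset(
        cls, ds: BioassayDataset, pct_mp: float, common: CommonConcentrations | None = None
    ) -> "MixtureSeries":
        recs = ds.treatment_records(pct_mp)
        if common is not None:
            recs = [r for r in recs if r.ss_conc in common.values]
        return cls(pct_mp, recs, common_only=common is not None)


@dataclass(frozen=True)
class SubsampleScheme:
    """Balanced subsampling-without-replacement configuration."""

    target_replicates: int = 5
    iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_replicates < 2:
            raise ValueError("target_replicates must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass(frozen=True)
class SubsampledFit:
    """Aggregate of repeated balanced-subsample fits for one %MP series.

    Point estimates and CI bounds are medians over iterations; ``lc50_spread``
    is the (min, max) of the per-iteration LC50s, quantifying the arbitrariness
    of any single subsample.
    """

    pct_mp: float
    lc50: float
    lc50_ci: tuple[float, float]
    lc10: float
    lc10_ci: tuple[float, float]
    r_squared: float
    n_obs: int
    lc50_spread: tuple[float, float]
    scheme: SubsampleScheme
    iteration_fits: tuple[DoseResponseFit, ...] = field(repr=False)
    ss_used: tuple[float, ...] = ()

    def lcx_point(self, x: float) -> float:
        return statistics.median(f.lcx_point(x) for f in self.iteration_fits)

    def lcx_interval(self, x: float) -> tuple[float, float]:
        los, his = zip(*(f.lcx_interval(x) for f in self.iteration_fits))
        return (statistics.median(los), statistics.median(his))


def _median(xs) -> float:
    return float(statistics.median(xs))


def subsample_fit(
    series: MixtureSeries,
    scheme: SubsampleScheme,
    p_control: float = 0.0,
    hill_fixed: bool = True,
) -> SubsampledFit:
    """Repeatedly subsample each cell to ``target_replicates`` tubes and fit.

    Iteration ``i`` draws from a stream derived from ``(seed, i, cell index)``,
    so results are reproducible and independent of iteration execution order;
    records within a cell are put in a deterministic order first, making the
    procedure invariant to input record order.
    """
    cells = series.cells()
    for conc, recs in cells.items():
        if len(recs) < scheme.target_replicates:
            raise FitError(
                f"cell (pct_mp={series.pct_mp}, ss={conc}) has {len(recs)} "
                f"replicates, fewer than target {scheme.target_replicates}"
            )
    concs = sorted(cells)
    fits: list[DoseResponseFit] = []
    for it in range(scheme.iterations):
        conc_arr: list[float] = []
        mort: list[float] = []
        for ci, conc in enumerate(concs):
            recs = cells[conc]
            rng = np.random.default_rng([scheme.seed, it, ci])
            idx = rng.choice(len(recs), size=scheme.target_replicates, replace=False)
            for j in sorted(idx):
                conc_arr.append(conc)
                mort.append(recs[j].mortality)
        fits.append(
            fit_dose_response(
                conc_arr, mort, p_control=p_control, hill_fixed=hill_fixed, pct_mp=series.pct_mp
            )
        )
    lc50s = [f.lc50 for f in fits]
    return SubsampledFit(
        pct_mp=series.pct_mp,
        lc50=_median(lc50s),
        lc50_ci=(_median([f.lc50_ci[0] for f in fits]), _median([f.lc50_ci[1] for f in fits])),
        lc10=_median([f.lc10 for f in fits]),
        lc10_ci=(_median([f.lc10_ci[0] for f in fits]), _median([f.lc10_ci[1] for f in fits])),
        r_squared=_median([f.r_squared for f in fits]),
        n_obs=fits[0].n_obs,
        lc50_spread=(min(lc50s), max(lc50s)),
        scheme=scheme,
        iteration_fits=tuple(fits),
        ss_used=tuple(concs),
    )


@dataclass
class FitOptions:
    """Configuration for :func:`fit_all`."""

    common_only: bool = True
    hill_fixed: bool = True
    subsample: SubsampleScheme | None = field(default_factory=SubsampleScheme)
    control_flag_threshold: float = 0.10


@dataclass
class MixtureFits:
    """Fits keyed by %MP, plus the CI-overlap comparison against the 0% level."""

    fits: dict[float, DoseResponseFit | SubsampledFit]
    failures: dict[float, str]
    comparisons: dict[float, tuple[bool, float]]  # pct -> (overlaps 0%, signed gap)
    common: CommonConcentrations | None
    p_control: float

    def ordered(self) -> list[DoseResponseFit | SubsampledFit]:
        return [self.fits[p] for p in sorted(self.fits)]


def fit_all(ds: BioassayDataset, options: FitOptions | None = None) -> MixtureFits:
    """Fit every %MP series of a dataset under the common rules.

    A series is routed through balanced subsampling when at least one of its
    cells exceeds the target replicate count and all cells meet it; otherwise
    it is fitted directly on all (filtered) records.  Per-series failures are
    collected, not fatal.
    """
    from .data import control_mortality  # local import to avoid cycle at module load

    options = options or FitOptions()
    cm = control_mortality(ds, threshold=options.control_flag_threshold)
    common = None
    if options.common_only and len(ds.pct_levels()) >= 2:
        common = common_concentrations(ds)

    fits: dict[float, DoseResponseFit | SubsampledFit] = {}
    failures: dict[float, str] = {}
    for pct in ds.pct_levels():
        series = MixtureSeries.from_dataset(ds, pct, common)
        counts = [len(v) for v in series.cells().values()]
        try:
            if (
                options.subsample is not None
                and counts
                and max(counts) > options.subsample.target_replicates
                and min(counts) >= options.subsample.target_replicates
            ):
                fits[pct] = subsample_fit(
                    series, options.subsample, p_control=cm.pooled, hill_fixed=options.hill_fixed
                )
            else:
                # build arrays from the deterministically ordered cells so the
                # result is exactly invariant to input record order
                conc_arr = [c for c, recs in series.cells().items() for _ in recs]
                mort = [r.mortality for recs in series.cells().values() for r in recs]
                fits[pct] = fit_dose_response(
                    conc_arr,
                    mort,
                    p_control=cm.pooled,
                    hill_fixed=options.hill_fixed,
                    pct_mp=pct,
                )
        except FitError as exc:
            failures[pct] = str(exc)

    comparisons: dict[float, tuple[bool, float]] = {}
    if 0.0 in fits:
        ref = fits[0.0]
        for pct, f in fits.items():
            if pct == 0.0:
                continue
            # compare_fits only reads lc50_ci, which both fit classes expose
            verdict = compare_fits(f, ref)
            comparisons[pct] = (verdict.overlaps, verdict.gap)
    return MixtureFits(fits, failures, comparisons, common, cm.pooled)
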
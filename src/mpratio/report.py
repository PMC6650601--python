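"""End-to-end pipeline: validate -> per-mixture fits -> decay -> thresholds.

The report mirrors the three-stage workflow: dataset summary and control
mortality first, then the per-%MP dose-response table with the CI-overlap
comparison against the 0% reference, then the LCx-vs-%MP decay fits with the
derived (NOEC, NOE%MP) pair and the outcome scenario.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path

from . import __version__
from .data import BioassayDataset, control_mortality, read_dataset
from .dose_response import DoseResponseFit
from .mixture import FitOptions, MixtureFits, SubsampledFit, SubsampleScheme, fit_all
from .threshold import (
    DecayFit,
    ThresholdError,
    ThresholdResult,
    classify_scenario,
    derive_thresholds,
)

__all__ = ["PipelineConfig", "AnalysisReport", "PipelineError", "run_pipeline"]

log = logging.getLogger("mpratio")


class PipelineError(RuntimeError):
    """The pipeline cannot produce its headline outputs (anchor failure)."""


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the pipeline, echoed into the report for reproducibility."""

    hill_fixed: bool = True
    common_only: bool = True
    x_level: float = 10.0
    subsample_target: int = 5
    subsample_iterations: int = 100
    seed: int = 0
    control_flag_threshold: float = 0.10

    def fit_options(self) -> FitOptions:
        return FitOptions(
            common_only=self.common_only,
            hill_fixed=self.hill_fixed,
            subsample=SubsampleScheme(
                target_replicates=self.subsample_target,
                iterations=self.subsample_iterations,
                seed=self.seed,
            ),
            control_flag_threshold=self.control_flag_threshold,
        )


def _fit_row(f: DoseResponseFit | SubsampledFit) -> dict:
    return {
        "pct_mp": f.pct_mp,
        "lc50": f.lc50,
        "lc50_lo": f.lc50_ci[0],
        "lc50_hi": f.lc50_ci[1],
        "lc10": f.lc10,
        "lc10_lo": f.lc10_ci[0],
        "lc10_hi": f.lc10_ci[1],
        "r2": f.r_squared,
        "n_obs": f.n_obs,
        "subsampled": isinstance(f, SubsampledFit),
    }


@dataclass
class AnalysisReport:
    """Everything the pipeline computed, JSON-serializable."""

    dataset_summary: dict
    fits_table: list[dict]
    comparisons: dict[float, tuple[bool, float]]
    fit_failures: dict[float, str]
    decay_lc50: DecayFit | None
    decay_lc10: DecayFit | None
    threshold: ThresholdResult | None
    scenario: str | None
    warnings: list[str]
    config: PipelineConfig
    version: str = __version__

    def to_dict(self) -> dict:
        def decay_d(d: DecayFit | None):
            if d is None:
                return None
            out = asdict(d)
            if math.isnan(out["k"]):
                out["k"] = None
            return out

        thr = None
        if self.threshold is not None:
            noe = self.threshold.noe_pct_mp
            thr = {
                "noec_mg_per_L": self.threshold.noec,
                "noe_pct_mp": None if math.isinf(noe) else noe,
                "noe_unbounded": math.isinf(noe),
                "x_level": self.threshold.x_level,
                "points": list(map(list, self.threshold.points)),
            }
        return {
            "dataset_summary": self.dataset_summary,
            "fits": self.fits_table,
            "comparisons_vs_reference": {
                str(p): {"ci_overlap": o, "gap": g} for p, (o, g) in self.comparisons.items()
            },
            "fit_failures": {str(p): m for p, m in self.fit_failures.items()},
            "decay_lc50": decay_d(self.decay_lc50),
            "decay_lc10": decay_d(self.decay_lc10),
            "threshold": thr,
            "scenario": self.scenario,
            "warnings": self.warnings,
            "config": asdict(self.config),
            "version": self.version,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, allow_nan=False, default=float)

    def summary_text(self) -> str:
        lines = [f"mpratio {self.version} analysis report"]
        s = self.dataset_summary
        lines.append(
            f"  records: {s['n_records']} ({s['n_controls']} controls), "
            f"{s['n_cells']} treatment cells, "
            f"control mortality {s['control_mortality']:.1%}"
        )
        if s["flagged_runs"]:
            lines.append(f"  WARNING: control mortality above threshold in runs {s['flagged_runs']}")
        for row in self.fits_table:
            lines.append(
                "  %MP {pct_mp:5.1f}: LC50 {lc50:9.1f} ({lc50_lo:.1f}-{lc50_hi:.1f}) mg/L, "
                "LC10 {lc10:8.1f} mg/L, R2 {r2:.3f}, n {n_obs}{tag}".format(
                    **row, tag=" [subsampled]" if row["subsampled"] else ""
                )
            )
        if self.threshold is not None:
            noe = self.threshold.noe_pct_mp
            noe_s = "unbounded (curve never reaches NOEC)" if math.isinf(noe) else f"{noe:.2f}%"
            lines.append(
                f"  NOEC (lower LC{self.threshold.x_level:.0f} bound at 0% MP): "
                f"{self.threshold.noec:.1f} mg/L; NOE%MP: {noe_s}"
            )
        if self.scenario is not None:
            desc = {
                "A": "no test-particle effect",
                "B": "additive test-particle effect",
                "C": "ameliorating test-particle effect",
            }[self.scenario]
            lines.append(f"  scenario: {self.scenario} ({desc})")
        for w in self.warnings:
            lines.append(f"  note: {w}")
        return "\n".join(lines)


def run_pipeline(
    data: BioassayDataset | str | Path, config: PipelineConfig | None = None
) -> AnalysisReport:
    """Run the full analysis on a dataset or CSV path.

    Per-series fit failures are reported, not fatal — unless the 0% MP
    reference level is missing or its fit fails, which raises
    :class:`PipelineError` because every downstream threshold is anchored
    on that level.
    """
    config = config or PipelineConfig()
    ds = data if isinstance(data, BioassayDataset) else read_dataset(data)
    warnings_: list[str] = []

    cm = control_mortality(ds, threshold=config.control_flag_threshold)
    counts = ds.cell_counts()
    summary = {
        "n_records": len(ds.records),
        "n_controls": len(ds.controls()),
        "n_cells": len(counts),
        "pct_levels": ds.pct_levels(),
        "control_mortality": cm.pooled,
        "control_mortality_per_run": cm.per_run,
        "flagged_runs": list(cm.flagged_runs),
        "duration_h": ds.duration_h,
    }
    log.info("validated %d records; control mortality %.1f%%", len(ds.records), 100 * cm.pooled)
    if cm.flagged_runs:
        warnings_.append(
            f"control mortality exceeds {cm.threshold:.0%} in runs: {', '.join(cm.flagged_runs)}"
        )

    if 0.0 not in ds.pct_levels():
        raise PipelineError("dataset has no 0% MP (pure reference) level; cannot anchor thresholds")

    mf: MixtureFits = fit_all(ds, config.fit_options())
    log.info("fitted %d of %d series", len(mf.fits), len(ds.pct_levels()))
    for pct, msg in mf.failures.items():
        warnings_.append(f"series {pct}% MP failed to fit: {msg}")
    if 0.0 not in mf.fits:
        raise PipelineError(
            f"the 0% MP reference fit failed: {mf.failures.get(0.0, 'unknown error')}"
        )

    decay50 = decay10 = None
    threshold: ThresholdResult | None = None
    scenario = None
    if len(mf.fits) >= 3:
        try:
            threshold = derive_thresholds(mf.fits, x_level=config.x_level)
            decay10 = threshold.decay if config.x_level == 10.0 else None
        except ThresholdError as exc:
            warnings_.append(f"threshold derivation failed: {exc}")
        try:
            from .threshold import fit_decay

            pcts = sorted(mf.fits)
            decay50 = fit_decay(pcts, [mf.fits[p].lc50 for p in pcts], x_level=50.0)
            if decay10 is None:
                decay10 = fit_decay(pcts, [mf.fits[p].lc10 for p in pcts], x_level=10.0)
        except ThresholdError as exc:
            warnings_.append(f"decay fit failed: {exc}")
    else:
        warnings_.append("fewer than 3 fitted %MP levels: no decay fit or threshold derived")
    if len(mf.fits) >= 2:
        scenario = classify_scenario(mf.fits)

    return AnalysisReport(
        dataset_summary=summary,
        fits_table=[_fit_row(mf.fits[p]) for p in sorted(mf.fits)],
        comparisons=mf.comparisons,
        fit_failures=mf.failures,
        decay_lc50=decay50,
        decay_lc10=decay10,
        threshold=threshold,
        scenario=scenario,
        warnings=warnings_,
        config=config,
    )
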
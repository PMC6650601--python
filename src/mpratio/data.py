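"""Domain types and CSV I/O for particulate-mixture bioassay data.

The unit of observation is one test tube (replicate): a nominal suspended-solids
concentration (mg/L), the mass percentage contributed by the test particle
(%MP), and counts of exposed and immobilized animals.  Particle-free controls
are rows with ``ss_conc == 0`` and ``is_control == True``; there is no separate
control file.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "ReplicateRecord",
    "BioassayDataset",
    "DesignCell",
    "DesignMatrix",
    "ControlMortality",
    "ValidationError",
    "FormatError",
    "read_dataset",
    "write_dataset",
    "control_mortality",
    "build_design",
    "CSV_COLUMNS",
]

#: Canonical CSV header (matched case-insensitively on read).
CSV_COLUMNS = (
    "ss_conc_mg_per_L",
    "pct_mp",
    "n_exposed",
    "n_immobilized",
    "run_id",
    "is_control",
)


class ValidationError(ValueError):
    """A record or dataset violates a domain invariant."""


class FormatError(ValueError):
    """An input file does not conform to the expected schema."""


@dataclass(frozen=True)
class ReplicateRecord:
    """One test tube.

    Parameters
    ----------
    ss_conc : float
        Nominal total suspended-solids mass concentration, mg/L (>= 0;
        0 for particle-free controls).
    pct_mp : float
        Mass percentage of the test particle in the solids, 0-100.
    n_exposed : int
        Animals placed in the tube (>= 1).
    n_immobilized : int
        Animals immobilized at test end (0 <= n <= n_exposed).
    run_id : str
        Batch/run label; carried through but not modelled.
    is_control : bool
        True iff the tube is particle-free (then ``ss_conc`` must be 0).
    """

    ss_conc: float
    pct_mp: float
    n_exposed: int
    n_immobilized: int
    run_id: str = ""
    is_control: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.ss_conc) or self.ss_conc < 0:
            raise ValidationError(f"ss_conc must be finite and >= 0, got {self.ss_conc}")
        if not 0 <= self.pct_mp <= 100:
            raise ValidationError(f"pct_mp must be within [0, 100], got {self.pct_mp}")
        if self.n_exposed < 1:
            raise ValidationError(f"n_exposed must be >= 1, got {self.n_exposed}")
        if not 0 <= self.n_immobilized <= self.n_exposed:
            raise ValidationError(
                f"n_immobilized must satisfy 0 <= n <= n_exposed "
                f"({self.n_exposed}), got {self.n_immobilized}"
            )
        if self.is_control and self.ss_conc != 0:
            raise ValidationError("control records must have ss_conc = 0")
        if self.ss_conc > 0 and self.is_control:
            raise ValidationError("records with ss_conc > 0 cannot be controls")

    @property
    def mortality(self) -> float:
        """Observed proportion immobilized."""
        return self.n_immobilized / self.n_exposed


@dataclass
class BioassayDataset:
    """A validated collection of replicate records plus assay metadata."""

    records: list[ReplicateRecord]
    duration_h: float = 96.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not any(r.is_control for r in self.records):
            raise ValidationError("dataset must contain at least one control record")
        ok = False
        for pct in self.pct_levels():
            if len({r.ss_conc for r in self.treatment_records(pct)}) >= 2:
                ok = True
                break
        if not ok:
            raise ValidationError(
                "dataset must contain >= 2 distinct positive ss_conc values "
                "for at least one pct_mp level"
            )

    # -- queries ----------------------------------------------------------
    def controls(self) -> list[ReplicateRecord]:
        return [r for r in self.records if r.is_control]

    def treatments(self) -> list[ReplicateRecord]:
        return [r for r in self.records if not r.is_control]

    def pct_levels(self) -> list[float]:
        """Distinct %MP levels among treatment records, ascending."""
        return sorted({r.pct_mp for r in self.treatments()})

    def treatment_records(self, pct_mp: float) -> list[ReplicateRecord]:
        return [r for r in self.treatments() if r.pct_mp == pct_mp]

    def cell_counts(self) -> dict[tuple[float, float], int]:
        """Replicate count per (pct_mp, ss_conc) treatment cell."""
        return dict(Counter((r.pct_mp, r.ss_conc) for r in self.treatments()))

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(
            self.records,
            key=lambda r: (not r.is_control, r.pct_mp, r.ss_conc, r.run_id, r.n_immobilized),
        )
        return pd.DataFrame(
            {
                "ss_conc_mg_per_L": [r.ss_conc for r in rows],
                "pct_mp": [r.pct_mp for r in rows],
                "n_exposed": [r.n_exposed for r in rows],
                "n_immobilized": [r.n_immobilized for r in rows],
                "run_id": [r.run_id for r in rows],
                "is_control": [r.is_control for r in rows],
            }
        )


@dataclass(frozen=True)
class DesignCell:
    """One planned treatment cell with its nominal per-particle masses."""

    pct_mp: float
    ss_conc: float
    test_mass: float  # mg/L of the test particle
    reference_mass: float  # mg/L of the reference particle


@dataclass
class DesignMatrix:
    """The planned %MP x SS grid.

    Endpoint levels (0% and 100% MP) may use a richer concentration series
    than the intermediate mixtures, mirroring typical mixture-dilution designs.
    """

    pct_mp_levels: list[float]
    ss_levels_by_pct: dict[float, list[float]]
    replicates_per_cell: int = 5

    def cells(self) -> list[DesignCell]:
        out = []
        for pct in self.pct_mp_levels:
            for ss in self.ss_levels_by_pct[pct]:
                test = ss * pct / 100.0
                out.append(DesignCell(pct, ss, test, ss - test))
        return out

    @property
    def n_cells(self) -> int:
        return sum(len(v) for v in self.ss_levels_by_pct.values())


def build_design(
    pct_levels: Sequence[float],
    ss_levels_full: Sequence[float],
    ss_levels_mixture: Sequence[float],
    replicates: int = 5,
) -> DesignMatrix:
    """Build the planned grid: endpoints get the full SS series, mixtures a subset.

    ``pct_levels`` containing 0 and/or 100 are treated as endpoints and receive
    ``ss_levels_full``; every intermediate level receives ``ss_levels_mixture``.
    """
    if not pct_levels or not ss_levels_full or not ss_levels_mixture:
        raise ValueError("level lists must be non-empty")
    for c in list(ss_levels_full) + list(ss_levels_mixture):
        if c <= 0:
            raise ValueError(f"SS concentrations must be > 0, got {c}")
    for p in pct_levels:
        if not 0 <= p <= 100:
            raise ValueError(f"pct_mp levels must be within [0, 100], got {p}")
    levels = sorted(set(float(p) for p in pct_levels))
    by_pct = {
        p: sorted(float(c) for c in (ss_levels_full if p in (0.0, 100.0) else ss_levels_mixture))
        for p in levels
    }
    return DesignMatrix(levels, by_pct, replicates)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n", ""}


def _parse_bool(value, row: int) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise FormatError(f"row {row}: cannot parse is_control value {value!r}")


def read_dataset(
    path: str | Path,
    duration_h: float = 96.0,
    metadata: Mapping | None = None,
    **read_csv_kwargs,
) -> BioassayDataset:
    """Read a replicate-level CSV into a validated :class:`BioassayDataset`.

    The header must name the six canonical columns (case-insensitive); extra
    columns are ignored.  Any row violating a record invariant aborts the read
    with a :class:`ValidationError` naming the offending row numbers (1-based,
    excluding the header).
    """
    df = pd.read_csv(path, **read_csv_kwargs)
    df.columns = [c.strip().lower() for c in df.columns]
    wanted = {c.lower(): c for c in CSV_COLUMNS}
    missing = [wanted[c] for c in wanted if c not in df.columns]
    if missing:
        raise FormatError(f"missing required columns: {', '.join(missing)}")

    records: list[ReplicateRecord] = []
    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = dict(zip(df.columns, row))
        try:
            records.append(
                ReplicateRecord(
                    ss_conc=float(d["ss_conc_mg_per_l"]),
                    pct_mp=float(d["pct_mp"]),
                    n_exposed=int(d["n_exposed"]),
                    n_immobilized=int(d["n_immobilized"]),
                    run_id=str(d["run_id"]),
                    is_control=_parse_bool(d["is_control"], i),
                )
            )
        except (ValidationError, FormatError, ValueError) as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        raise ValidationError("invalid rows:\n" + "\n".join(problems))
    return BioassayDataset(records, duration_h=duration_h, metadata=dict(metadata or {}))


def write_dataset(ds: BioassayDataset, path: str | Path) -> None:
    """Write a dataset to CSV in the canonical schema (round-trips losslessly)."""
    ds.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Control mortality
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ControlMortality:
    """Pooled and per-run background mortality of the particle-free controls."""

    pooled: float
    per_run: dict[str, float]
    flagged_runs: tuple[str, ...]
    threshold: float

    @property
    def survival(self) -> float:
        return 1.0 - self.pooled


def control_mortality(ds: BioassayDataset, threshold: float = 0.10) -> ControlMortality:
    """Pooled control mortality with a per-run breakdown and validity flags.

    Runs whose control mortality exceeds ``threshold`` (default 10%, the usual
    acute-immobilization validity criterion) are flagged but not removed.
    """
    controls = ds.controls()
    if not controls:
        raise ValidationError("dataset has no control records")
    pooled = sum(r.n_immobilized for r in controls) / sum(r.n_exposed for r in controls)
    per_run: dict[str, float] = {}
    for run in sorted({r.run_id for r in controls}):
        rs = [r for r in controls if r.run_id == run]
        per_run[run] = sum(r.n_immobilized for r in rs) / sum(r.n_exposed for r in rs)
    flagged = tuple(run for run, m in per_run.items() if m > threshold)
    return ControlMortality(pooled, per_run, flagged, threshold)
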
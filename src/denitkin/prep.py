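"""From raw in-situ observations to a model-ready trajectory.

The flow-cell experiment measures chemistry (nitrate in mmol/dm3) and
microbiology (direct cell counts in the circulating solution, NarG qPCR of
solution and biofilm) — none of which is directly the model's biomass-carbon
state. The preparation procedure:

1. totals microbes over solution + biofilm, converting biofilm qPCR signal
   to a cell count with the cells-per-NarG-copy factor calibrated on the
   solution, where TNC and qPCR were measured side by side;
2. converts total cell counts to biomass carbon with a TOC-per-cell factor
   identified from the experiment-wide TOC decline, attributing a fraction
   ``x`` (the growth yield, assumed 0.5) of that decline to new biomass;
3. estimates the N/C stoichiometry as the ratio of nitrate-N consumed to
   organic carbon consumed.

All deltas are taken between two reference samples (baselines) which are
explicit configuration: the pre-injection sample is excluded by default and
deltas run from the first post-injection sample to the last.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidParameterError
from .model import N_MOLAR_MASS

__all__ = [
    "ObservationRecord",
    "PreparedDataset",
    "PrepConfig",
    "mmol_to_gN",
    "gN_to_mmol",
    "cells_per_copy",
    "total_cells",
    "toc_correlation_factor",
    "cells_to_toc",
    "nc_ratio",
    "net_change",
    "prepare_dataset",
    "round_sig",
]


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (reporting convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass(frozen=True)
class ObservationRecord:
    """One raw in-situ sampling event (chemistry + microbiology).

    Chemistry is in mmol/dm3; ``tnc_solution`` in cells per the sampled
    volume unit (cm3 in the raw tables); qPCR signals in NarG copies/g.
    Sigmas are 1-standard-deviation measurement uncertainties, carried
    through but not propagated into derived constants.
    """

    sample_id: str
    t: float
    no3: float
    no2: float
    nh3: float
    tnc_solution: float
    tnc_sigma: float = 0.0
    qpcr_solution: float = 0.0
    qpcr_solution_sigma: float = 0.0
    qpcr_biofilm: float = 0.0
    qpcr_biofilm_sigma: float = 0.0
    toc_solution: float | None = None

    def __post_init__(self) -> None:
        if self.t < 0:
            raise InvalidParameterError(f"t must be >= 0, got {self.t}")
        for name in (
            "no3", "no2", "nh3", "tnc_solution", "tnc_sigma", "qpcr_solution",
            "qpcr_solution_sigma", "qpcr_biofilm", "qpcr_biofilm_sigma",
        ):
            v = getattr(self, name)
            if v < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {v}")
        if self.toc_solution is not None and self.toc_solution < 0:
            raise InvalidParameterError("toc_solution must be >= 0")


@dataclass(frozen=True)
class PreparedDataset:
    """Model-ready trajectory plus the constants derived alongside it.

    ``frame`` is indexed by sample_id with columns ``t`` [d], ``toc``
    [g-C/dm3], ``cells_total`` [cells/dm3], ``biomass_toc`` [g-TOC/dm3]
    and ``no3`` [g-N/dm3].
    """

    frame: pd.DataFrame
    toc_per_cell_factor: float
    nc_ratio: float
    growth_fraction_x: float
    baseline_from: str
    baseline_to: str

    def __post_init__(self) -> None:
        required = {"t", "toc", "cells_total", "biomass_toc", "no3"}
        missing = required - set(self.frame.columns)
        if missing:
            raise InvalidParameterError(f"PreparedDataset frame missing columns {missing}")
        if not self.frame["t"].is_monotonic_increasing:
            raise InvalidParameterError("PreparedDataset rows must be time-ordered")

    def value(self, sample_id: str, column: str) -> float:
        try:
            return float(self.frame.loc[sample_id, column])
        except KeyError as exc:
            raise KeyError(f"sample {sample_id!r} / column {column!r} not found") from exc

    @property
    def times(self) -> np.ndarray:
        return self.frame["t"].to_numpy(dtype=float)

    def constants_report(self) -> dict[str, float | str]:
        """Derived constants at reporting precision (3 significant figures)."""
        return {
            "toc_per_cell_factor": round_sig(self.toc_per_cell_factor, 3),
            "nc_ratio": round_sig(self.nc_ratio, 3),
            "growth_fraction_x": self.growth_fraction_x,
            "baseline_from": self.baseline_from,
            "baseline_to": self.baseline_to,
        }


# ---------------------------------------------------------------------------
# elementary conversions


def mmol_to_gN(c):
    """Convert a nitrogen-species concentration from mmol/dm3 to g-N/dm3."""
    arr = np.asarray(c, dtype=float)
    if np.any(arr < 0):
        raise InvalidParameterError(f"concentration must be >= 0, got {c}")
    out = arr * N_MOLAR_MASS / 1000.0
    return float(out) if np.isscalar(c) or arr.ndim == 0 else out


def gN_to_mmol(c):
    """Inverse of :func:`mmol_to_gN`."""
    arr = np.asarray(c, dtype=float)
    if np.any(arr < 0):
        raise InvalidParameterError(f"concentration must be >= 0, got {c}")
    out = arr / N_MOLAR_MASS * 1000.0
    return float(out) if np.isscalar(c) or arr.ndim == 0 else out


def cells_per_copy(tnc_solution, qpcr_solution, mode: str = "paired_sum") -> float:
    """Cells per NarG copy, calibrated on paired solution measurements.

    With scalars, the plain ratio. With paired arrays, ``paired_sum`` takes
    the ratio of sums (robust to noisy individual samples); alternatively
    ``geometric_mean`` averages per-sample ratios on the log scale.
    """
    tnc = np.atleast_1d(np.asarray(tnc_solution, dtype=float))
    qpcr = np.atleast_1d(np.asarray(qpcr_solution, dtype=float))
    if tnc.shape != qpcr.shape:
        raise InvalidParameterError("tnc and qpcr series must be paired")
    if np.any(tnc <= 0) or np.any(qpcr <= 0):
        raise DegenerateInputError("cells_per_copy requires strictly positive pairs")
    if mode == "paired_sum":
        return float(tnc.sum() / qpcr.sum())
    if mode == "geometric_mean":
        return float(np.exp(np.mean(np.log(tnc / qpcr))))
    raise InvalidParameterError(f"unknown cells_per_copy mode {mode!r}")


def total_cells(
    tnc_solution: float,
    qpcr_solution: float,
    qpcr_biofilm: float,
    biofilm_mass_per_volume: float,
    factor: float | None = None,
) -> float:
    """Total cells/dm3 = solution count + biofilm qPCR mapped through the
    cells-per-copy factor and the biofilm mass per circulating volume [g/dm3]."""
    for name, v in (
        ("tnc_solution", tnc_solution),
        ("qpcr_solution", qpcr_solution),
        ("qpcr_biofilm", qpcr_biofilm),
        ("biofilm_mass_per_volume", biofilm_mass_per_volume),
    ):
        if v < 0:
            raise InvalidParameterError(f"{name} must be >= 0, got {v}")
    biofilm_signal = qpcr_biofilm * biofilm_mass_per_volume
    if biofilm_signal == 0:
        return tnc_solution
    if qpcr_solution == 0:
        raise DegenerateInputError(
            "cannot scale a nonzero biofilm signal with qpcr_solution = 0"
        )
    if factor is None:
        factor = cells_per_copy(tnc_solution, qpcr_solution)
    return tnc_solution + factor * biofilm_signal


def toc_correlation_factor(delta_toc: float, delta_cells: float, x: float = 0.5) -> float:
    """TOC-per-cell factor [g-TOC/cell] from experiment-wide changes.

    A fraction ``x`` of the solution-TOC decline is attributed to biomass
    growth: factor = -x * delta_toc / delta_cells.
    """
    if delta_cells == 0:
        raise DegenerateInputError("delta_cells must be nonzero")
    return -x * delta_toc / delta_cells


def cells_to_toc(cells, factor: float):
    """Convert a cell count [cells/dm3] to biomass carbon [g-TOC/dm3]."""
    arr = np.asarray(cells, dtype=float)
    if np.any(arr < 0) or factor < 0:
        raise InvalidParameterError("cells and factor must be >= 0")
    out = arr * factor
    return float(out) if np.isscalar(cells) or arr.ndim == 0 else out


def nc_ratio(delta_no3: float, delta_toc: float) -> float:
    """Nitrate-N consumed per organic-C consumed [g-N/g-C].

    Both deltas are negative for a consuming system, giving a positive ratio.
    """
    if delta_toc == 0:
        raise DegenerateInputError("delta_toc must be nonzero")
    return delta_no3 / delta_toc


def net_change(dataset: PreparedDataset, column: str, from_id: str, to_id: str) -> float:
    """Signed change of ``column`` between two samples: value(to) - value(from)."""
    return dataset.value(to_id, column) - dataset.value(from_id, column)


# ---------------------------------------------------------------------------
# the full procedure


@dataclass(frozen=True)
class PrepConfig:
    """Configuration of the preparation procedure.

    ``biofilm_mass_per_volume`` [g/dm3] has no default: the biofilm carrier
    mass per circulating volume is experiment-specific and cannot be
    recovered from the observation tables themselves.
    """

    biofilm_mass_per_volume: float
    growth_fraction_x: float = 0.5
    tnc_volume_factor: float = 1000.0  # raw counts per cm3 -> per dm3
    cells_per_copy_mode: str = "paired_sum"
    pre_injection_ids: tuple[str, ...] = ()
    baseline_from: str | None = None  # default: first post-injection sample
    baseline_to: str | None = None  # default: last sample

    def __post_init__(self) -> None:
        if self.biofilm_mass_per_volume < 0:
            raise InvalidParameterError("biofilm_mass_per_volume must be >= 0")
        if not 0 < self.growth_fraction_x <= 1:
            raise InvalidParameterError("growth_fraction_x must be in (0, 1]")
        if self.tnc_volume_factor <= 0:
            raise InvalidParameterError("tnc_volume_factor must be > 0")


def prepare_dataset(
    raw: Iterable[ObservationRecord],
    toc_series: Mapping[str, float],
    config: PrepConfig,
) -> PreparedDataset:
    """Run the full preparation chain on raw observation records.

    ``toc_series`` maps sample_id to measured solution TOC [g-C/dm3]
    (records may also carry ``toc_solution`` directly; the explicit series
    takes precedence).
    """
    records = sorted(raw, key=lambda r: r.t)
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise InvalidParameterError(f"duplicate sample ids: {ids}")

    kept = [r for r in records if r.sample_id not in config.pre_injection_ids]
    if len(kept) < 2:
        raise DegenerateInputError("need at least 2 post-injection records")
    span = kept[-1].t - kept[0].t
    if span <= 0:
        raise DegenerateInputError("records must span nonzero time")

    def toc_of(r: ObservationRecord) -> float:
        if r.sample_id in toc_series:
            return float(toc_series[r.sample_id])
        if r.toc_solution is not None:
            return float(r.toc_solution)
        raise DegenerateInputError(f"no TOC value for sample {r.sample_id!r}")

    # cells-per-copy factor from all records with positive paired signals
    pairs = [
        (r.tnc_solution * config.tnc_volume_factor, r.qpcr_solution)
        for r in records
        if r.tnc_solution > 0 and r.qpcr_solution > 0
    ]
    if not pairs:
        raise DegenerateInputError("no positive TNC/qPCR pairs to calibrate cells_per_copy")
    cpc = cells_per_copy(
        [a for a, _ in pairs], [b for _, b in pairs], mode=config.cells_per_copy_mode
    )

    cells = {
        r.sample_id: total_cells(
            r.tnc_solution * config.tnc_volume_factor,
            r.qpcr_solution,
            r.qpcr_biofilm,
            config.biofilm_mass_per_volume,
            factor=cpc,
        )
        for r in kept
    }

    from_id = config.baseline_from or kept[0].sample_id
    to_id = config.baseline_to or kept[-1].sample_id
    by_id = {r.sample_id: r for r in kept}
    for sid in (from_id, to_id):
        if sid not in by_id:
            raise KeyError(f"baseline sample {sid!r} not among post-injection records")

    delta_toc = toc_of(by_id[to_id]) - toc_of(by_id[from_id])
    delta_cells = cells[to_id] - cells[from_id]
    if delta_toc == 0 or delta_cells == 0:
        raise DegenerateInputError("zero TOC or cell-count change between baselines")

    factor = toc_correlation_factor(delta_toc, delta_cells, x=config.growth_fraction_x)
    if factor <= 0:
        raise DegenerateInputError(
            f"nonpositive TOC-per-cell factor ({factor:.3e}): biomass did not grow "
            "while TOC fell between the chosen baselines"
        )

    delta_no3 = mmol_to_gN(by_id[to_id].no3) - mmol_to_gN(by_id[from_id].no3)
    nc = nc_ratio(delta_no3, delta_toc)

    frame = pd.DataFrame(
        {
            "t": [r.t for r in kept],
            "toc": [toc_of(r) for r in kept],
            "cells_total": [cells[r.sample_id] for r in kept],
            "biomass_toc": [cells_to_toc(cells[r.sample_id], factor) for r in kept],
            "no3": [mmol_to_gN(r.no3) for r in kept],
        },
        index=pd.Index([r.sample_id for r in kept], name="sample_id"),
    )
    return PreparedDataset(
        frame=frame,
        toc_per_cell_factor=factor,
        nc_ratio=nc,
        growth_fraction_x=config.growth_fraction_x,
        baseline_from=from_id,
        baseline_to=to_id,
    )
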
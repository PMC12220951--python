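"""Quantitative image-based cytometry (QIBC) derived per-well assay values.

Input is a per-cell feature table (one row per segmented nucleus) with
columns ``plate, well, gene, sirna_id, cell_line, dapi_total, gH2AX_mean,
edu_mean, micronucleus_count``.  This module turns it into the per-well
quantities the screen statistics consume:

* a marker-positivity threshold derived per plate from negative-control
  cells (mean + k*SD by default, or a control percentile),
* % marker-positive and % micronuclei-positive cells per well,
* per-cell cell-cycle phases (G1/S/G2) gated on total DAPI and mean EdU,

plus two scalar normalizations used by the orthogonal validation assays:
relative homologous-recombination efficiency (GFP+ fraction vs control) and
qPCR relative expression by the delta-delta-Ct method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, PlateQCError, ValidationError

CELL_COLUMNS = (
    "plate", "well", "gene", "sirna_id", "cell_line",
    "dapi_total", "gH2AX_mean", "edu_mean", "micronucleus_count",
)

#: gene value tagging negative-control wells
CONTROL_TAG = "NEG_CTRL"

MIN_CONTROL_CELLS = 100


@dataclass(frozen=True)
class GatingConfig:
    """How per-cell features are thresholded into positive/negative calls.

    ``positivity_method`` is ``"control_mean_plus_k_sd"`` (threshold =
    control mean + ``k_sd`` standard deviations; the field's usual
    convention when the imaging platform's cutoff is not dictated) or
    ``"control_percentile"`` (the ``percentile``-th percentile of control
    cells, linear interpolation).  ``edu_split`` and ``dapi_boundary``
    override the automatic cell-cycle splits with explicit raw-intensity
    values.
    """

    positivity_method: str = "control_mean_plus_k_sd"
    k_sd: float = 2.0
    percentile: float = 95.0
    edu_split: float | None = None
    dapi_boundary: float | None = None

    def __post_init__(self) -> None:
        if self.positivity_method not in ("control_mean_plus_k_sd", "control_percentile"):
            raise ParameterError(f"unknown positivity_method {self.positivity_method!r}")
        if self.k_sd <= 0:
            raise ParameterError("k_sd must be > 0")
        if not 50 < self.percentile < 100:
            raise ParameterError("percentile must be in (50, 100)")


def derive_positivity_threshold(
    control_cells: pd.DataFrame,
    channel: str,
    config: GatingConfig | None = None,
) -> float:
    """Marker-positivity threshold from one plate's negative-control cells."""
    config = config or GatingConfig()
    if channel not in control_cells.columns:
        raise ValidationError(f"channel {channel!r} not in table")
    values = control_cells[channel].to_numpy(dtype=float)
    if len(values) < MIN_CONTROL_CELLS:
        raise PlateQCError(
            f"only {len(values)} control cells for channel {channel!r}; "
            f"need >= {MIN_CONTROL_CELLS}"
        )
    if (values < 0).any():
        raise ValidationError("intensities must be >= 0")
    if config.positivity_method == "control_mean_plus_k_sd":
        return float(values.mean() + config.k_sd * values.std(ddof=0))
    return float(np.percentile(values, config.percentile))


def plate_thresholds(
    cells: pd.DataFrame,
    channel: str,
    config: GatingConfig | None = None,
    control_tag: str = CONTROL_TAG,
) -> dict[str, float]:
    """Per-plate positivity thresholds from each plate's control wells."""
    thresholds = {}
    for plate, group in cells.groupby("plate", sort=True):
        controls = group[group["gene"] == control_tag]
        thresholds[str(plate)] = derive_positivity_threshold(controls, channel, config)
    return thresholds


def well_positive_fractions(
    cells: pd.DataFrame,
    thresholds: Mapping[str, float],
    marker_channel: str = "gH2AX_mean",
    min_cells: int = 50,
) -> pd.DataFrame:
    """Per-well % marker-positive and % micronuclei-positive cells.

    A cell is marker-positive when its channel value is strictly greater
    than its plate's threshold, and micronuclei-positive when it carries at
    least one micronucleus.  Wells with fewer than ``min_cells`` cells are
    flagged (``qc_pass = False``) so downstream scoring can exclude them;
    they are never imputed.
    """
    missing = [c for c in ("plate", "well", marker_channel, "micronucleus_count")
               if c not in cells.columns]
    if missing:
        raise ValidationError(f"cell table missing columns: {missing}")
    unknown = set(cells["plate"].astype(str)) - set(thresholds)
    if unknown:
        raise ParameterError(f"no threshold for plates: {sorted(unknown)}")

    df = cells.copy()
    thr = df["plate"].astype(str).map(thresholds).to_numpy(dtype=float)
    df["_marker_pos"] = df[marker_channel].to_numpy(dtype=float) > thr
    df["_mn_pos"] = df["micronucleus_count"].to_numpy() >= 1

    keys = ["plate", "well"]
    for extra in ("gene", "sirna_id", "cell_line"):
        if extra in df.columns:
            keys.append(extra)
    grouped = df.groupby(keys, sort=True, observed=True)
    out = grouped.agg(
        n_cells=("_marker_pos", "size"),
        pct_marker_pos=("_marker_pos", "mean"),
        pct_micronuclei_pos=("_mn_pos", "mean"),
    ).reset_index()
    out["pct_marker_pos"] *= 100.0
    out["pct_micronuclei_pos"] *= 100.0
    out["qc_pass"] = out["n_cells"] >= min_cells
    return out


def _kde_modes(log_values: np.ndarray, grid_size: int = 512):
    """Grid KDE of log-intensities; returns (grid, density, peak indices)."""
    kde = stats.gaussian_kde(log_values)
    lo, hi = log_values.min(), log_values.max()
    pad = 0.05 * (hi - lo + 1e-12)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    density = kde(grid)
    interior = (density[1:-1] > density[:-2]) & (density[1:-1] >= density[2:])
    peaks = np.flatnonzero(interior) + 1
    return grid, density, peaks


def _two_mode_boundary(log_values: np.ndarray, how: str) -> float:
    """Boundary between the two dominant modes of a log-intensity distribution.

    ``how="midpoint"`` returns the midpoint of the two highest KDE modes
    (EdU split); ``how="valley"`` returns the density minimum between them
    (DAPI 2n/4n boundary).  Raises PlateQCError when fewer than two modes
    are found (degenerate, unimodal distribution).
    """
    grid, density, peaks = _kde_modes(log_values)
    if len(peaks) < 2:
        raise PlateQCError("degenerate intensity distribution: fewer than 2 modes")
    top2 = peaks[np.argsort(density[peaks])[-2:]]
    left, right = int(top2.min()), int(top2.max())
    valley_density = float(density[left:right + 1].min())
    # genuine bimodality needs a real dip between the modes; shallow KDE
    # wiggles on a unimodal distribution must not pass as two populations
    if valley_density > 0.8 * min(density[left], density[right]):
        raise PlateQCError(
            "degenerate intensity distribution: modes not separated by a valley"
        )
    if how == "midpoint":
        return float((grid[left] + grid[right]) / 2)
    valley = left + int(np.argmin(density[left:right + 1]))
    return float(grid[valley])


def gate_cell_cycle(
    cells: pd.DataFrame,
    config: GatingConfig | None = None,
) -> pd.Series:
    """Per-cell cell-cycle phase from total DAPI and mean EdU intensity.

    EdU-high cells are replicating (S phase) regardless of DNA content;
    among EdU-negative cells, those below the DAPI 2n/4n boundary are G1 and
    those at or above it are G2.  The EdU split is the midpoint between the
    two modes of the log-EdU distribution; the DAPI boundary is the density
    valley between the 2n and 4n peaks of EdU-negative cells.  Both splits
    can be overridden with explicit values in ``config``.  Every cell
    receives exactly one label.
    """
    config = config or GatingConfig()
    for col in ("dapi_total", "edu_mean"):
        if col not in cells.columns:
            raise ValidationError(f"cell table missing column {col!r}")
    edu = cells["edu_mean"].to_numpy(dtype=float)
    dapi = cells["dapi_total"].to_numpy(dtype=float)
    if (edu < 0).any() or (dapi < 0).any():
        raise ValidationError("intensities must be >= 0")

    if config.edu_split is not None:
        edu_split = float(config.edu_split)
    else:
        edu_split = float(np.exp(_two_mode_boundary(np.log(edu + 1.0), "midpoint")) - 1.0)
    s_phase = edu > edu_split

    if config.dapi_boundary is not None:
        dapi_boundary = float(config.dapi_boundary)
    else:
        non_s_dapi = dapi[~s_phase]
        if len(non_s_dapi) < 2:
            raise PlateQCError("too few EdU-negative cells to place a DAPI boundary")
        dapi_boundary = float(np.exp(_two_mode_boundary(np.log(non_s_dapi + 1.0), "valley")) - 1.0)

    phase = np.where(s_phase, "S", np.where(dapi < dapi_boundary, "G1", "G2"))
    return pd.Series(phase, index=cells.index, name="phase")


def relative_hr_efficiency(gfp_fraction_sample: float, gfp_fraction_control: float) -> float:
    """HR reporter efficiency relative to control siRNA cells (control = 1)."""
    if gfp_fraction_control <= 0:
        raise ParameterError("control GFP fraction must be > 0")
    if gfp_fraction_sample < 0:
        raise ValidationError("GFP fraction must be >= 0")
    return gfp_fraction_sample / gfp_fraction_control


@dataclass(frozen=True)
class QpcrMeasurement:
    """Ct quadruple for delta-delta-Ct relative quantification."""

    ct_target_sample: float
    ct_ref_sample: float
    ct_target_control: float
    ct_ref_control: float

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not np.isfinite(value) or value <= 0:
                raise ValidationError(f"{name} must be finite and > 0, got {value}")


def ddct_relative_expression(m: QpcrMeasurement) -> float:
    """Relative expression 2^(-ddCt) against the reference gene and control sample."""
    ddct = (m.ct_target_sample - m.ct_ref_sample) - (m.ct_target_control - m.ct_ref_control)
    return float(2.0 ** (-ddct))
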
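"""Quantitative PET analysis and downstream molecular readouts.

Covers the quantification chain of the delivery studies: conversion of
reconstructed activity volumes to percent injected dose per cubic
centimeter (%ID/cc, decay-corrected to injection time), ROI mean/max
statistics, blood-pool subtraction with a brain vascular volume fraction
(v_b, default 4%), dynamic frame schemes, ex-vivo %ID/g from gamma counts,
qPCR ΔΔCt fold changes, and simple fold-change / R^2 reporting.

Conventions: fold changes are reported to one decimal; negative
blood-subtracted values are returned (not clamped) with a QC flag so that
group averages stay unbiased; masks must share the volume's exact voxel
lattice — no resampling happens here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    EmptyRoiError,
    GeometryError,
    IncompleteTableError,
    InvalidParameterError,
    MetadataError,
)
from .synthetic import ISOTOPE_HALF_LIFE_H

__all__ = [
    "PETVolume",
    "ROIMask",
    "QuantResult",
    "FrameScheme",
    "RoiStats",
    "to_percent_id_per_cc",
    "roi_statistics",
    "blood_subtract",
    "quantify",
    "fold_change",
    "percent_id_per_g",
    "biodist_percent_id_per_g",
    "build_frame_scheme",
    "delta_delta_ct",
    "linear_r2",
    "load_run_config",
]


@dataclass(frozen=True)
class PETVolume:
    """A reconstructed 3-D PET volume with quantification metadata.

    ``units`` is either ``"Bq/cc"`` (raw activity concentration) or
    ``"%ID/cc"``; ``acquisition_time_h`` is relative to injection.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    units: str = "Bq/cc"
    isotope: str | None = None
    acquisition_time_h: float = 0.0
    injected_dose_bq: float | None = None

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size_mm):
            raise InvalidParameterError("voxel sizes must be positive")
        if self.units not in ("Bq/cc", "%ID/cc"):
            raise InvalidParameterError(f"unknown units {self.units!r}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))


@dataclass(frozen=True)
class ROIMask:
    """Boolean voxel mask on the same lattice as its volume."""

    mask: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    label: str = "custom"

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * float(np.prod(self.voxel_size_mm))


class RoiStats(NamedTuple):
    mean: float
    max: float
    volume_mm3: float


@dataclass(frozen=True)
class QuantResult:
    """Blood-subtracted ROI quantification of one region."""

    roi_label: str
    mean_pct_id_cc: float
    max_pct_id_cc: float
    blood_pct_id_cc: float
    mean_blood_subtracted: float
    max_blood_subtracted: float
    v_b: float
    negative_flag: bool


def _decay_half_life_h(isotope: str) -> float:
    try:
        return ISOTOPE_HALF_LIFE_H[isotope]
    except KeyError:
        raise MetadataError(f"unknown isotope {isotope!r}") from None


def to_percent_id_per_cc(vol: PETVolume) -> PETVolume:
    """Convert an activity volume (Bq/cc) to %ID/cc.

    Voxel values are decay-corrected back to injection time using the
    isotope half-life (Cu-64: 12.701 h; F-18: 109.77 min), then expressed
    as percent of the injected dose per cc:
    ``100 * conc * 2**(t/t_half) / injected_dose``.
    """
    if vol.units != "Bq/cc":
        raise MetadataError("volume is not in Bq/cc")
    if vol.injected_dose_bq is None or vol.injected_dose_bq <= 0:
        raise MetadataError("injected dose missing or non-positive")
    if vol.isotope is None:
        raise MetadataError("isotope metadata missing")
    half_life = _decay_half_life_h(vol.isotope)
    corr = 2.0 ** (vol.acquisition_time_h / half_life)
    data = 100.0 * vol.data * corr / vol.injected_dose_bq
    return replace(vol, data=data, units="%ID/cc")


def _check_lattice(vol: PETVolume, roi: ROIMask) -> None:
    if vol.data.shape != roi.mask.shape:
        raise GeometryError("mask and volume shapes differ")
    if not np.allclose(vol.voxel_size_mm, roi.voxel_size_mm):
        raise GeometryError("mask and volume voxel sizes differ")


def roi_statistics(vol: PETVolume, roi: ROIMask) -> RoiStats:
    """Arithmetic mean and maximum over masked voxels, plus ROI volume."""
    _check_lattice(vol, roi)
    if roi.n_voxels == 0:
        raise EmptyRoiError(f"ROI {roi.label!r} is empty")
    vals = vol.data[roi.mask]
    return RoiStats(float(vals.mean()), float(vals.max()), roi.volume_mm3)


def blood_subtract(roi_value: float, blood_value: float, v_b: float = 0.04) -> float:
    """Remove the circulating-tracer contribution from an ROI value.

    ``roi - v_b * blood`` with v_b the brain vascular volume fraction
    (default 4%); blood_value comes from a cardiac-chamber ROI.  Negative
    results are returned as-is (callers flag them).
    """
    if not 0.0 <= v_b < 1.0:
        raise InvalidParameterError("v_b must be in [0, 1)")
    return roi_value - v_b * blood_value


def quantify(
    vol: PETVolume,
    roi: ROIMask,
    blood_roi: ROIMask | None = None,
    v_b: float = 0.04,
) -> QuantResult:
    """Full ROI quantification: mean/max, blood estimate and subtraction.

    Blood activity is the mean over ``blood_roi`` (cardiac chamber); with
    no blood ROI the subtraction is skipped (blood = 0).  Blood subtraction
    is applied to both the mean and the max statistic.
    """
    stats = roi_statistics(vol, roi)
    blood = roi_statistics(vol, blood_roi).mean if blood_roi is not None else 0.0
    mean_bs = blood_subtract(stats.mean, blood, v_b)
    max_bs = blood_subtract(stats.max, blood, v_b)
    return QuantResult(
        roi_label=roi.label,
        mean_pct_id_cc=stats.mean,
        max_pct_id_cc=stats.max,
        blood_pct_id_cc=blood,
        mean_blood_subtracted=mean_bs,
        max_blood_subtracted=max_bs,
        v_b=v_b,
        negative_flag=bool(mean_bs < 0 or max_bs < 0),
    )


def fold_change(value: float, reference: float, decimals: int = 1) -> float:
    """value / reference, rounded to ``decimals`` (reporting convention)."""
    if reference <= 0:
        raise InvalidParameterError("reference must be positive")
    return round(value / reference, decimals)


def percent_id_per_g(sample_counts: float, counts_per_pct_id: float, mass_g: float) -> float:
    """Ex-vivo %ID/g from gamma counts and a counts-per-%ID calibration."""
    if mass_g <= 0:
        raise InvalidParameterError("mass must be positive")
    if counts_per_pct_id <= 0:
        raise InvalidParameterError("counts_per_pct_id must be positive")
    return (sample_counts / counts_per_pct_id) / mass_g


def biodist_percent_id_per_g(table: pd.DataFrame, counts_per_pct_id: float) -> pd.DataFrame:
    """Apply :func:`percent_id_per_g` to a biodistribution count table."""
    out = table.copy()
    out["pct_id_per_g"] = [
        percent_id_per_g(c, counts_per_pct_id, m)
        for c, m in zip(out["counts"], out["mass_g"])
    ]
    return out


@dataclass(frozen=True)
class FrameScheme:
    """Dynamic PET framing from (duration s, count) pairs."""

    spec: tuple[tuple[float, int], ...]
    boundaries_s: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.boundaries_s.size - 1

    @property
    def total_duration_s(self) -> float:
        return float(self.boundaries_s[-1])

    @property
    def frame_durations_s(self) -> np.ndarray:
        return np.diff(self.boundaries_s)


def build_frame_scheme(spec: list[tuple[float, int]]) -> FrameScheme:
    """Build frame boundaries from (duration, count) pairs.

    The 30-min dynamic protocol (15 s x 8, 60 s x 8, 300 s x 4) yields 20
    frames and 1800 s total.
    """
    durations = []
    for dur, count in spec:
        if dur <= 0 or count <= 0:
            raise InvalidParameterError("durations and counts must be positive")
        durations.extend([float(dur)] * int(count))
    boundaries = np.concatenate([[0.0], np.cumsum(durations)])
    return FrameScheme(spec=tuple((float(d), int(c)) for d, c in spec), boundaries_s=boundaries)


def delta_delta_ct(
    table: pd.DataFrame,
    treated_group: str,
    reference_group: str,
    target_gene: str = "target",
    housekeeping_gene: str = "housekeeping",
) -> float:
    """ΔΔCt fold change of the target gene between two groups.

    Per sample, ΔCt = Ct_target - Ct_housekeeping; ΔΔCt is the difference
    of group-mean ΔCt (treated - reference) and the fold change is
    ``2 ** (-ΔΔCt)``.  Adding a constant to every Ct leaves the result
    unchanged.
    """

    def group_delta(group: str) -> float:
        sub = table[table["group"] == group]
        if sub.empty:
            raise IncompleteTableError(f"group {group!r} missing from table")
        piv = sub.pivot_table(index="sample_id", columns="gene", values="ct")
        for gene in (target_gene, housekeeping_gene):
            if gene not in piv.columns or piv[gene].isna().any():
                raise IncompleteTableError(
                    f"group {group!r} lacks complete {gene!r} Ct values"
                )
        return float((piv[target_gene] - piv[housekeeping_gene]).mean())

    ddct = group_delta(treated_group) - group_delta(reference_group)
    return float(2.0 ** (-ddct))


def linear_r2(pairs) -> float:
    """Squared Pearson correlation of an ordinary least-squares fit.

    Requires >= 3 pairs and nonzero x variance; a constant y has no linear
    trend and returns 0.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise InvalidParameterError("need at least three (x, y) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.var(x) == 0:
        raise InvalidParameterError("x variance is zero: correlation undefined")
    if np.var(y) == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)


def load_run_config(path) -> dict:
    """Load a YAML run configuration (isotope, injected dose, v_b,
    reporting decimals) with package defaults for missing keys."""
    defaults = {"isotope": "Cu-64", "injected_dose_bq": None, "v_b": 0.04, "decimals": 1}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    out = dict(defaults)
    out.update(cfg)
    return out
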
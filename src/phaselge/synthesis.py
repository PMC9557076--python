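"""Synthetic LGE generation from fitted (A, T1*) maps.

A single virtual inversion time is applied to every cardiac phase,
``S_syn = A (1 - 2 exp(-T_syn/T1*))``, chosen retrospectively to null the
reference tissue (T_syn = T1*_ref * ln 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fitting import T1StarMaps

__all__ = ["SynthConfig", "SynthLGEStack", "synth_time_for_null", "synthesize_lge"]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class SynthConfig:
    """How to synthesize: explicit ``t_syn_ms`` or a null ROI to derive it.

    ``mode`` selects signed or magnitude output; ``roi_stat`` the summary of
    the ROI's T1* values used to derive T_syn (median by default, robust to
    edge voxels).
    """

    t_syn_ms: float | None = None
    null_roi: np.ndarray | None = None
    mode: str = "magnitude"
    roi_stat: str = "median"

    def __post_init__(self) -> None:
        if (self.t_syn_ms is None) == (self.null_roi is None):
            raise ValueError("provide exactly one of t_syn_ms / null_roi")
        if self.t_syn_ms is not None and self.t_syn_ms <= 0:
            raise ValueError("t_syn_ms must be > 0")
        if self.mode not in ("signed", "magnitude"):
            raise ValueError("mode must be 'signed' or 'magnitude'")
        if self.roi_stat not in ("median", "mean"):
            raise ValueError("roi_stat must be 'median' or 'mean'")


@dataclass
class SynthLGEStack:
    """Per-phase synthesized LGE images sharing one virtual inversion time."""

    data: np.ndarray            # (n_phases, rows, cols); NaN where not fitted
    t_syn_ms: float
    mode: str = "magnitude"
    provenance: dict = field(default_factory=dict)

    @property
    def n_phases(self) -> int:
        return self.data.shape[0]


def synth_time_for_null(
    t1_star_reference_ms: float | None = None,
    maps: T1StarMaps | None = None,
    null_roi: np.ndarray | None = None,
    stat: str = "median",
) -> float:
    """Virtual inversion time that nulls the reference tissue.

    With a scalar reference, ``T_syn = T1* ln 2``.  With maps plus an ROI,
    T1* is first summarized over the ROI's converged voxels across all
    phases (median by default).
    """
    if t1_star_reference_ms is not None:
        if t1_star_reference_ms <= 0:
            raise ValueError("reference T1* must be > 0")
        return t1_star_reference_ms * LN2
    if maps is None or null_roi is None:
        raise ValueError("need either a scalar T1* or maps + null_roi")
    roi = np.asarray(null_roi, bool)
    values = maps.t1_star_map[:, roi][maps.converged_map[:, roi]]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("null ROI contains no converged voxels")
    agg = np.median if stat == "median" else np.mean
    return float(agg(values)) * LN2


def synthesize_lge(maps: T1StarMaps, config: SynthConfig) -> SynthLGEStack:
    """Apply the synthesis equation voxel-by-voxel at one T_syn for all
    phases.  Non-converged voxels are NaN in the output and excluded from
    downstream metrics."""
    if config.t_syn_ms is not None:
        t_syn = float(config.t_syn_ms)
    else:
        t_syn = synth_time_for_null(
            maps=maps, null_roi=config.null_roi, stat=config.roi_stat
        )
    if t_syn <= 0:
        raise ValueError("t_syn_ms must be > 0")

    with np.errstate(invalid="ignore", divide="ignore"):
        s = maps.a_map * (1.0 - 2.0 * np.exp(-t_syn / maps.t1_star_map))
    s[~maps.converged_map] = np.nan
    if config.mode == "magnitude":
        s = np.abs(s)
    return SynthLGEStack(
        data=s,
        t_syn_ms=t_syn,
        mode=config.mode,
        provenance={"roi_stat": config.roi_stat,
                    "derived_from_roi": config.null_roi is not None},
    )
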
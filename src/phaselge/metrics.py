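"""Contrast and homogeneity metrics.

Two CNR flavours are used.  The apparent CNR (aCNR) pools the spatial
standard deviation within each ROI as the noise estimate,

    aCNR = |mu_myo - mu_blood| / sqrt((sd_myo^2 + sd_blood^2) / 2),

because after the non-linear synthesis no background-noise estimate exists.
The phantom CNR instead takes noise as the per-voxel variability across
repeated acquisitions.  Homogeneity is summarized as the coefficient of
variation (%%) of a per-phase series, after linear interpolation to a fixed
number of reconstruction phases when heart rates (and hence phase counts)
differ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthesis import SynthLGEStack

__all__ = [
    "RoiPair",
    "ContrastReport",
    "acnr",
    "repetition_cnr",
    "cov_percent",
    "interpolate_phases",
    "contrast_report",
]


@dataclass
class RoiPair:
    """Myocardium / blood-pool ROI masks (shared across phases)."""

    myo_mask: np.ndarray
    blood_mask: np.ndarray
    notes: str = ""

    def __post_init__(self) -> None:
        self.myo_mask = np.asarray(self.myo_mask, bool)
        self.blood_mask = np.asarray(self.blood_mask, bool)
        if self.myo_mask.shape != self.blood_mask.shape:
            raise ValueError("ROI masks must share a shape")
        if not self.myo_mask.any() or not self.blood_mask.any():
            raise ValueError("ROI masks must be non-empty")
        if np.any(self.myo_mask & self.blood_mask):
            raise ValueError("ROI masks must be disjoint")


def _roi_values(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    v = np.asarray(image, float)[mask]
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("ROI must contain at least 2 finite voxels")
    return v


def acnr(image: np.ndarray, rois: RoiPair) -> float:
    """Apparent CNR of one image from the two ROIs' spatial statistics.

    Zero spatial variability in both ROIs (noiseless synthetic input) makes
    the ratio degenerate; it is flagged as +inf rather than raised.
    """
    myo = _roi_values(image, rois.myo_mask)
    blood = _roi_values(image, rois.blood_mask)
    noise = np.sqrt((myo.std(ddof=1) ** 2 + blood.std(ddof=1) ** 2) / 2.0)
    contrast = float(np.abs(myo.mean() - blood.mean()))
    if noise == 0:
        return 0.0 if contrast == 0 else np.inf
    return contrast / noise


def repetition_cnr(stacks: list[SynthLGEStack], rois: RoiPair) -> np.ndarray:
    """Per-phase CNR with noise defined as voxel-wise variability across
    repeated acquisitions.

    Per ROI the noise is the mean of the per-voxel repetition SDs; the
    contrast uses the repetition-mean images.  Zero repetition noise in
    either ROI yields +inf for that phase (degenerate, flagged not raised).
    """
    if len(stacks) < 2:
        raise ValueError("need at least 2 repetitions")
    data = np.stack([s.data for s in stacks])  # (rep, phase, r, c)
    if len({s.data.shape for s in stacks}) != 1:
        raise ValueError("repetitions must share a shape")
    mean_img = data.mean(axis=0)
    sd_img = data.std(axis=0, ddof=1)

    n_phases = mean_img.shape[0]
    out = np.empty(n_phases)
    for p in range(n_phases):
        mu1 = np.nanmean(mean_img[p][rois.myo_mask])
        mu2 = np.nanmean(mean_img[p][rois.blood_mask])
        n1 = np.nanmean(sd_img[p][rois.myo_mask])
        n2 = np.nanmean(sd_img[p][rois.blood_mask])
        denom = np.sqrt((n1**2 + n2**2) / 2.0)
        out[p] = np.inf if denom == 0 else abs(mu1 - mu2) / denom
    return out


def cov_percent(series) -> float:
    """Coefficient of variation in percent, sample SD over the mean."""
    x = np.asarray(series, float)
    if x.size == 0:
        raise ValueError("empty series")
    m = x.mean()
    if m == 0:
        raise ValueError("CoV undefined for zero-mean series")
    return float(100.0 * x.std(ddof=1) / m)


def interpolate_phases(series, n_target: int = 20) -> np.ndarray:
    """Linear interpolation of a per-phase series onto ``n_target`` phases.

    The abscissa is the normalized phase position in [0, 1] with endpoints
    mapped to endpoints; no extrapolation occurs.
    """
    y = np.asarray(series, float)
    if y.size < 2:
        raise ValueError("need at least 2 phases to interpolate")
    x_src = np.linspace(0.0, 1.0, y.size)
    x_dst = np.linspace(0.0, 1.0, n_target)
    return np.interp(x_dst, x_src, y)


@dataclass
class ContrastReport:
    per_phase_acnr: np.ndarray
    interpolated_acnr: np.ndarray
    cov_percent: float
    t_syn_ms: float | None = None
    phantom_cnr: np.ndarray | None = None
    summary: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "phase_index": np.arange(self.per_phase_acnr.size),
                "acnr": self.per_phase_acnr,
            }
        )
        if self.phantom_cnr is not None:
            df["cnr"] = self.phantom_cnr
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        def _num(v):
            return float(v) if np.isfinite(v) else None

        payload = {
            "n_phases": int(self.per_phase_acnr.size),
            "cov_percent": _num(self.cov_percent),
            "t_syn_ms": self.t_syn_ms,
            "interpolated_acnr": [_num(v) for v in self.interpolated_acnr],
            **self.summary,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def contrast_report(
    synth: SynthLGEStack,
    rois: RoiPair,
    n_reconstruction_phases: int = 20,
    repetitions: list[SynthLGEStack] | None = None,
) -> ContrastReport:
    """Full per-phase contrast evaluation of a synthesized stack."""
    per_phase = np.array([acnr(img, rois) for img in synth.data])
    interp = interpolate_phases(per_phase, n_reconstruction_phases)
    cov = cov_percent(interp) if np.isfinite(interp).all() else np.nan
    report = ContrastReport(
        per_phase_acnr=per_phase,
        interpolated_acnr=interp,
        cov_percent=cov,
        t_syn_ms=synth.t_syn_ms,
    )
    if repetitions is not None:
        report.phantom_cnr = repetition_cnr(repetitions, rois)
        finite = np.isfinite(report.phantom_cnr)
        if finite.all():
            report.summary["cnr_cov_percent"] = cov_percent(report.phantom_cnr)
    return report
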
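"""Digital phantoms: compartment definitions, label maps and builders.

Label 0 is background (never simulated/fitted); compartments are labelled
1..n in the order given.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TissueCompartment",
    "PhantomSpec",
    "two_sphere_phantom",
    "bottle_phantom",
    "cardiac_phantom",
]


class PhantomConfigError(ValueError):
    pass


@dataclass(frozen=True)
class TissueCompartment:
    label: str
    t1_ms: float
    proton_density: float = 1.0

    def __post_init__(self) -> None:
        if self.t1_ms <= 0:
            raise PhantomConfigError("t1_ms must be > 0")
        if self.proton_density <= 0:
            raise PhantomConfigError("proton_density must be > 0")


@dataclass
class PhantomSpec:
    """A 2D phantom: integer label map plus per-compartment tissue properties.

    Noise is specified either directly (``noise_sd``, signal units) or as a
    baseline SNR relative to the pulsed-steady-state readout signal of a
    named compartment (``baseline_snr``, ``snr_reference``).  ``motion``
    optionally holds one radial scale factor per cardiac phase, applied to
    the label map about the grid center.
    """

    label_map: np.ndarray
    compartments: tuple[TissueCompartment, ...]
    noise_sd: float = 0.0
    baseline_snr: float | None = None
    snr_reference: str | None = None
    motion: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map, dtype=int)
        if self.label_map.ndim != 2:
            raise PhantomConfigError("label_map must be 2D")
        self.compartments = tuple(self.compartments)
        labels = np.unique(self.label_map)
        if labels.max(initial=0) > len(self.compartments):
            raise PhantomConfigError(
                "label_map references a label with no compartment"
            )
        if self.noise_sd < 0:
            raise PhantomConfigError("noise_sd must be >= 0")
        if self.baseline_snr is not None:
            if self.noise_sd:
                raise PhantomConfigError(
                    "set at most one of noise_sd / baseline_snr"
                )
            if self.baseline_snr <= 0:
                raise PhantomConfigError("baseline_snr must be > 0")
            ref = self.snr_reference
            if ref is None or ref not in {c.label for c in self.compartments}:
                raise PhantomConfigError(
                    f"baseline_snr reference compartment {ref!r} not found"
                )
        if self.motion is not None:
            self.motion = np.asarray(self.motion, float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_map.shape

    def compartment(self, label: str) -> TissueCompartment:
        for c in self.compartments:
            if c.label == label:
                return c
        raise PhantomConfigError(f"unknown compartment {label!r}")

    def mask(self) -> np.ndarray:
        """Foreground mask (all labelled voxels)."""
        return self.label_map > 0

    def compartment_mask(self, label: str) -> np.ndarray:
        idx = 1 + [c.label for c in self.compartments].index(label)
        return self.label_map == idx

    def label_map_for_phase(self, phase: int, n_phases: int) -> np.ndarray:
        """Label map of one cardiac phase, with optional radial contraction.

        A scale factor ``s < 1`` shrinks the phantom toward the grid center;
        the map is resampled nearest-neighbour so labels stay integral.
        """
        if self.motion is None:
            return self.label_map
        if len(self.motion) != n_phases:
            raise PhantomConfigError(
                "motion must provide one scale factor per phase"
            )
        s = float(self.motion[phase])
        if s == 1.0:
            return self.label_map
        h, w = self.label_map.shape
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        yy, xx = np.mgrid[0:h, 0:w]
        src_y = np.rint(cy + (yy - cy) / s).astype(int)
        src_x = np.rint(cx + (xx - cx) / s).astype(int)
        inside = (src_y >= 0) & (src_y < h) & (src_x >= 0) & (src_x < w)
        out = np.zeros_like(self.label_map)
        out[inside] = self.label_map[src_y[inside], src_x[inside]]
        return out


def _disc(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def two_sphere_phantom(
    shape: tuple[int, int] = (128, 128),
    radius: float = 20.0,
    t1_blood_ms: float = 489.0,
    t1_myo_ms: float = 910.0,
    **noise_kwargs,
) -> PhantomSpec:
    """Two discs mimicking post-contrast blood-pool and myocardial T1.

    The upper disc carries the blood-like (shorter) T1, the lower disc the
    myocardium-like (longer) T1.
    """
    h, w = shape
    label = np.zeros(shape, int)
    label[_disc(shape, (h * 0.3, w * 0.5), radius)] = 1
    label[_disc(shape, (h * 0.7, w * 0.5), radius)] = 2
    return PhantomSpec(
        label_map=label,
        compartments=(
            TissueCompartment("blood", t1_blood_ms),
            TissueCompartment("myocardium", t1_myo_ms),
        ),
        **noise_kwargs,
    )


def bottle_phantom(
    shape: tuple[int, int] = (64, 64),
    t1_short_ms: float = 489.0,
    t1_long_ms: float = 910.0,
    **noise_kwargs,
) -> PhantomSpec:
    """Two-compartment bottle: an inner disc (short T1) in an outer annulus
    (long T1), used for heart-rate sweep experiments."""
    h, w = shape
    center = (h / 2.0, w / 2.0)
    label = np.zeros(shape, int)
    label[_disc(shape, center, min(h, w) * 0.4)] = 2
    label[_disc(shape, center, min(h, w) * 0.2)] = 1
    return PhantomSpec(
        label_map=label,
        compartments=(
            TissueCompartment("short", t1_short_ms),
            TissueCompartment("long", t1_long_ms),
        ),
        **noise_kwargs,
    )


def cardiac_phantom(
    shape: tuple[int, int] = (128, 128),
    t1_blood_ms: float = 489.0,
    t1_myo_ms: float = 910.0,
    t1_scar_ms: float = 489.0,
    blood_radius: float = 18.0,
    myo_outer_radius: float = 30.0,
    scar_angle_deg: tuple[float, float] = (-45.0, 45.0),
    contraction: np.ndarray | None = None,
    **noise_kwargs,
) -> PhantomSpec:
    """Short-axis cardiac phantom: circular blood pool inside a myocardial
    annulus with an optional transmural scar wedge.

    ``contraction`` (per-phase radial scale factors) exercises the
    phase-resolved bookkeeping; the phantom is static by default.
    """
    h, w = shape
    center = (h / 2.0, w / 2.0)
    label = np.zeros(shape, int)
    annulus = _disc(shape, center, myo_outer_radius) & ~_disc(
        shape, center, blood_radius
    )
    label[annulus] = 2
    yy, xx = np.mgrid[0:h, 0:w]
    ang = np.degrees(np.arctan2(yy - center[0], xx - center[1]))
    wedge = annulus & (ang >= scar_angle_deg[0]) & (ang <= scar_angle_deg[1])
    label[wedge] = 3
    label[_disc(shape, center, blood_radius)] = 1
    return PhantomSpec(
        label_map=label,
        compartments=(
            TissueCompartment("blood", t1_blood_ms),
            TissueCompartment("myocardium", t1_myo_ms),
            TissueCompartment("scar", t1_scar_ms),
        ),
        motion=contraction,
        **noise_kwargs,
    )
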
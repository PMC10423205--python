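"""Voxelwise T1 relaxometry and the T1-reduction-rate functional map.

T1 maps are fitted from multi-flip-angle spoiled gradient-echo (SPGR/VFA)
volumes with the linearized DESPOT1 least-squares fit, including B1
correction of the nominal flip angles.  The hepatobiliary-phase contrast
uptake is then summarised per voxel as the T1 reduction rate

    rrT1(v) = (T1_pre(v) - T1_post(v)) / T1_pre(v),

the dimensionless fraction by which the hepatocyte-specific agent shortened
the native T1 — the proxy for regional hepatocyte function.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Union

import numpy as np

from .geometry import VoxelGeometry

ArrayLike = Union[float, np.ndarray]

#: reserved marker for voxels where a quantity could not be computed
INVALID = np.nan


@dataclass
class T1Volume:
    """3D scalar field of longitudinal relaxation times (ms).

    Invalid voxels carry NaN; valid voxels must be finite and positive.
    ``phase`` distinguishes the native (pre-contrast) map from the
    hepatobiliary-phase (post-contrast) map.
    """

    values: np.ndarray
    geometry: VoxelGeometry
    phase: Literal["native", "hepatobiliary"] = "native"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )
        valid = np.isfinite(self.values)
        if np.any(self.values[valid] <= 0):
            raise ValueError("valid T1 values must be positive")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class LiverMask:
    """Binary 3D field defining the liver: the rrT1 summation domain."""

    values: np.ndarray
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != self.geometry.shape:
            raise ValueError("mask shape must match geometry shape")

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


@dataclass
class FunctionalMap:
    """Voxelwise rrT1 field with a validity mask.

    ``valid_mask`` marks voxels inside the scoring domain that passed the
    quality rules (finite inputs, rr inside the plausibility window).
    """

    rr: np.ndarray
    geometry: VoxelGeometry
    valid_mask: np.ndarray
    #: how implausible voxels were handled ("exclude" or "clamp"); carried
    #: into reports because it changes the MELIF summand set
    implausible_policy: str = "exclude"

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.rr.shape != self.geometry.shape or self.valid_mask.shape != self.geometry.shape:
            raise ValueError("functional map fields must match geometry shape")


@dataclass
class T1FitResult:
    t1: T1Volume
    m0: np.ndarray
    fit_quality: np.ndarray  # per-voxel R^2 of the linearized fit


def spgr_signal(t1: ArrayLike, m0: ArrayLike, flip_angle_deg: ArrayLike,
                tr: float, b1: ArrayLike = 1.0) -> np.ndarray:
    """Steady-state SPGR magnitude signal.

    S = M0 sin(a') (1 - E1) / (1 - E1 cos(a')),  E1 = exp(-TR/T1),
    with the effective flip angle a' = b1 * nominal angle.

    Parameters are broadcast; ``t1`` and ``tr`` in ms, angles in degrees.
    """
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("T1 must be positive")
    b1 = np.asarray(b1, dtype=float)
    if np.any(b1 <= 0):
        raise ValueError("B1 must be positive")
    alpha = np.deg2rad(np.asarray(flip_angle_deg, dtype=float) * b1)
    e1 = np.exp(-tr / t1)
    return np.asarray(m0) * np.sin(alpha) * (1.0 - e1) / (1.0 - e1 * np.cos(alpha))


def fit_t1_vfa(signals, protocol, b1: ArrayLike = 1.0) -> T1FitResult:
    """Fit a T1 map from variable-flip-angle SPGR volumes (DESPOT1).

    The SPGR equation is linearized per voxel as ``y = E1 x + M0 (1 - E1)``
    with ``y = S/sin(a')`` and ``x = S/tan(a')``; an ordinary least-squares
    line over the flip angles gives ``E1`` as the slope and hence
    ``T1 = -TR / ln(slope)``.

    Parameters
    ----------
    signals : sequence of ndarray or of objects with ``.values``
        One magnitude volume per flip angle, identical shapes.
    protocol : VfaProtocol
        Supplies flip angles (deg) and TR (ms).
    b1 : float or ndarray
        Transmit-field scale applied multiplicatively to the nominal angles.

    Voxels with any non-positive signal, or whose slope falls outside (0, 1),
    are flagged invalid (NaN) rather than raising.
    """
    arrays = [np.asarray(getattr(s, "values", s), dtype=float) for s in signals]
    if len(arrays) < 2:
        raise ValueError("at least two flip angles are required")
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("signal volumes must share one geometry")
    if len(arrays) != len(protocol.flip_angles):
        raise ValueError("one signal volume per protocol flip angle expected")
    b1 = np.asarray(b1, dtype=float)
    if np.any(b1 <= 0):
        raise ValueError("B1 must be positive")
    if b1.ndim and b1.shape != shape:
        raise ValueError("B1 map must match signal geometry")

    s = np.stack(arrays)  # (n_angles, *shape)
    alpha = np.deg2rad(np.asarray(protocol.flip_angles, dtype=float))
    alpha_eff = alpha.reshape((-1,) + (1,) * len(shape)) * b1

    usable = s > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        y = s / np.sin(alpha_eff)
        x = s / np.tan(alpha_eff)
    y = np.where(usable, y, 0.0)
    x = np.where(usable, x, 0.0)

    n = usable.sum(axis=0).astype(float)
    ok = n >= 2
    nn = np.where(ok, n, np.nan)
    xbar = x.sum(axis=0) / nn
    ybar = y.sum(axis=0) / nn
    dx = np.where(usable, x - xbar, 0.0)
    dy = np.where(usable, y - ybar, 0.0)
    sxx = (dx * dx).sum(axis=0)
    sxy = (dx * dy).sum(axis=0)
    syy = (dy * dy).sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        r2 = np.where(syy > 0, sxy * sxy / (sxx * syy), 0.0)

    good = ok & usable.all(axis=0) & np.isfinite(slope) & (slope > 0) & (slope < 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(good, -protocol.tr / np.log(np.where(good, slope, 0.5)), INVALID)
        intercept = ybar - slope * xbar
        m0 = np.where(good, intercept / (1.0 - slope), INVALID)
    r2 = np.where(good, r2, INVALID)

    geometry = getattr(signals[0], "geometry", None) or VoxelGeometry(shape, (1.0, 1.0, 1.0))
    return T1FitResult(T1Volume(t1, geometry), m0, r2)


def compute_rrt1(t1_pre: T1Volume, t1_post: T1Volume, mask,
                 rr_window: tuple[float, float] = (0.0, 1.0),
                 implausible: Literal["exclude", "clamp"] = "exclude") -> FunctionalMap:
    """T1 reduction rate rr = (T1_pre - T1_post)/T1_pre over a liver mask.

    Voxels invalid in either T1 map are invalid in the output.  Voxels whose
    rr falls outside ``rr_window`` are, by default, excluded from the valid
    mask (``implausible="exclude"``); with ``"clamp"`` they are clipped to the
    window and kept valid.  Negative rr (post > pre) is physically unexpected
    after hepatocyte uptake, hence the default lower edge of 0.
    """
    t1_pre.geometry.check_same(t1_post.geometry)
    mask_values = np.asarray(getattr(mask, "values", mask), dtype=bool)
    if mask_values.shape != t1_pre.geometry.shape:
        raise ValueError("mask shape must match T1 geometry")
    lo, hi = rr_window
    if not lo < hi:
        raise ValueError("rr window must satisfy lo < hi")

    finite = t1_pre.valid & t1_post.valid & mask_values
    if np.any(t1_pre.values[finite] <= 0):
        raise ValueError("T1_pre must be positive inside the mask")

    rr = np.full(t1_pre.geometry.shape, INVALID)
    with np.errstate(divide="ignore", invalid="ignore"):
        rr[finite] = (t1_pre.values[finite] - t1_post.values[finite]) / t1_pre.values[finite]

    in_window = finite & (rr >= lo) & (rr <= hi)
    if implausible == "clamp":
        rr = np.where(finite, np.clip(rr, lo, hi), rr)
        valid = finite
    elif implausible == "exclude":
        valid = in_window
    else:
        raise ValueError(f"unknown implausible-voxel policy {implausible!r}")
    return FunctionalMap(rr, t1_pre.geometry, valid, implausible_policy=implausible)
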
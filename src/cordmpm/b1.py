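"""Transmit-field (B1) mapping from actual flip-angle imaging (AFI).

AFI interleaves two repetition times TR1 < TR2 at a fixed nominal flip
angle.  With n = TR2/TR1 and signal ratio r = S2/S1 the actual local flip
angle follows from

    cos(alpha) = (r n - 1) / (n - r),

and the transmit factor f_T is expressed in percent of the nominal angle.
The map depends only on the ratio of the two volumes, so it is invariant
to global receive scaling.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import RigidTransform, Volume3D
from .registration import _pull_coords, _resample_data, register_rigid

__all__ = [
    "B1Map",
    "afi_flip_angle",
    "to_percent_nominal",
    "register_afi_to_reference",
    "prepare_b1_for_correction",
]


@dataclass
class B1Map:
    """Transmit-field factor f_T in percent of nominal, with validity mask."""

    percent: Volume3D
    mask: np.ndarray
    nominal_deg: float = 60.0

    @property
    def fraction(self) -> np.ndarray:
        """f_T as a fraction of nominal (1.0 = nominal angle)."""
        return self.percent.data / 100.0


def afi_flip_angle(
    s1: Volume3D,
    s2: Volume3D,
    tr1_ms: float,
    tr2_ms: float,
    noise_sigma: float | None = None,
) -> tuple[Volume3D, np.ndarray]:
    """Voxelwise actual flip angle (degrees) from the AFI pair.

    Voxels with S1 below ``3 * noise_sigma`` (when a noise level is given)
    or with a cosine argument outside [-1, 1] are excluded from the
    returned validity mask; the argument is clipped so the map stays
    finite everywhere.
    """
    if tr2_ms <= tr1_ms:
        raise ValueError("AFI requires TR2 > TR1")
    if s1.shape != s2.shape:
        raise ValueError("AFI volumes must share one grid")
    n = tr2_ms / tr1_ms
    threshold = 0.0 if noise_sigma is None else 3.0 * noise_sigma
    valid = s1.data > max(threshold, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(valid, s2.data / np.where(valid, s1.data, 1.0), 1.0)
        arg = (r * n - 1.0) / (n - r)
    in_range = (arg >= -1.0) & (arg <= 1.0) & np.isfinite(arg)
    valid &= in_range
    alpha = np.rad2deg(np.arccos(np.clip(np.nan_to_num(arg, nan=1.0), -1.0, 1.0)))
    return Volume3D(alpha, s1.affine.copy()), valid


def to_percent_nominal(
    flip_map: Volume3D,
    nominal_deg: float = 60.0,
    mask: np.ndarray | None = None,
) -> B1Map:
    """Express a flip-angle map as percent of the nominal angle."""
    if nominal_deg <= 0:
        raise ValueError("nominal flip angle must be positive")
    percent = 100.0 * flip_map.data / nominal_deg
    m = np.ones(flip_map.shape, dtype=bool) if mask is None else mask
    return B1Map(Volume3D(percent, flip_map.affine.copy()), m, nominal_deg)


def register_afi_to_reference(s1: Volume3D, reference: Volume3D) -> RigidTransform:
    """Register the first AFI volume to the registered T1w reference.

    AFI has similar (though not identical) contrast to the T1w volume, so
    the same NMI machinery applies.
    """
    return register_rigid(s1, reference).transform


def _fill_nearest(data: np.ndarray, valid: np.ndarray) -> np.ndarray:
    if valid.all():
        return data
    if not valid.any():
        raise ValueError("B1 map has no valid voxels")
    _, idx = ndimage.distance_transform_edt(~valid, return_indices=True)
    return data[tuple(idx)]


def prepare_b1_for_correction(
    b1: B1Map,
    reference: Volume3D,
    t: RigidTransform | None = None,
    smoothing_fwhm_mm: float = 8.0,
) -> B1Map:
    """Resample the B1 map onto the reference grid and smooth it.

    Masked voxels are filled with the nearest valid value before the
    transform so the smoothing kernel never mixes in garbage; resampling
    uses linear interpolation (the field is smooth by construction) and
    the Gaussian smoothing FWHM is in mm (0 disables smoothing).
    """
    filled = _fill_nearest(b1.percent.data, b1.mask)
    src = Volume3D(filled, b1.percent.affine)
    t = RigidTransform() if t is None else t
    coords = _pull_coords(t, src.affine, reference.shape, reference.affine,
                          reference.center_world)
    data = _resample_data(src.data, coords, reference.shape, "linear")
    # out-of-field voxels got zero; refill from nearest in-field values
    infield = data > 0
    data = _fill_nearest(data, infield) if infield.any() else data
    if smoothing_fwhm_mm > 0:
        voxel = np.linalg.norm(reference.affine[:3, :3], axis=0)
        sigma = smoothing_fwhm_mm / 2.3548200450309493 / voxel
        data = ndimage.gaussian_filter(data, sigma)
    return B1Map(Volume3D(data, reference.affine.copy()),
                 np.ones(reference.shape, dtype=bool), b1.nominal_deg)
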
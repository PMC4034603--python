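"""Digital cervical-cord phantom with known ground truth.

Generates multi-echo FLASH volumes (PDw, T1w, MTw) plus an AFI pair for a
simple axial cord geometry: a white-matter disc split into dorsal, left-
and right-lateral columns, a central grey-matter butterfly, a CSF annulus
and background, replicated along the slice axis.  Inter-scan rigid motion,
a smooth transmit (B1) field and Rician noise can be injected, and every
output is bit-reproducible under a fixed seed.

Default tissue parameters are healthy-adult cord values (CSF values are
implementer-chosen, literature-plausible configuration defaults).  The
default acquisition settings are: PDw TR 24.05 ms / 6 deg with six echoes
equally spaced over TE 3.0-18.55 ms; T1w TR 22 ms / 20 deg with five
echoes; MTw five echoes with a 4-ms Gaussian MT pulse (nominal 220 deg,
2 kHz off-resonance) and the PDw readout; AFI 60 deg with TR pair
50/150 ms.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AcquisitionParams, EchoSeries, MTPulse, RigidTransform, Volume3D
from .registration import resample
from .signal import afi_signal_ratio, flash_signal, mtr_from_params

logger = logging.getLogger(__name__)

__all__ = [
    "TissueParams",
    "B1FieldSpec",
    "NoiseSpec",
    "AFIParams",
    "PhantomSpec",
    "GroundTruth",
    "SubjectData",
    "GeometryError",
    "LABELS",
    "WM_LABELS",
    "CORD_LABELS",
    "default_tissues",
    "default_acquisitions",
    "make_geometry",
    "assign_ground_truth",
    "b1_field",
    "simulate_echoes",
    "simulate_afi",
    "apply_motion",
    "add_noise",
    "simulate_subject",
    "generate_cohort",
]


class GeometryError(ValueError):
    """Raised for inconsistent phantom geometry."""


# --------------------------------------------------------------------------
# specification types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueParams:
    """Ground-truth parameters of one tissue class.

    ``a`` plays the role of APD before receive-field effects (a.u.), ``t1_ms``
    is the longitudinal relaxation time, ``delta`` the fractional saturation
    per MT pulse (p.u./100) and ``r2star_s`` the apparent transverse rate.
    """

    label: str
    a: float
    t1_ms: float
    delta: float
    r2star_s: float

    def __post_init__(self):
        if self.label != "background" and self.t1_ms <= 0:
            raise ValueError(f"{self.label}: T1 must be positive")
        if not (0 <= self.delta < 1):
            raise ValueError(f"{self.label}: delta must be in [0, 1)")
        if self.r2star_s < 0 or self.a < 0:
            raise ValueError(f"{self.label}: A and R2* must be non-negative")


LABELS = {
    "background": 0,
    "csf": 1,
    "gm": 2,
    "dorsal_wm": 3,
    "left_lateral_wm": 4,
    "right_lateral_wm": 5,
    "surround": 6,
    "vertebra": 7,
}
WM_LABELS = (3, 4, 5)
CORD_LABELS = (2, 3, 4, 5)      # GM + WM columns, i.e. the cord cross-section
TISSUE_LABELS = (1, 2, 3, 4, 5)  # the six-class cord tissue table + background


def default_tissues() -> dict[str, TissueParams]:
    """Healthy-cord tissue table.

    Cord-tissue values are healthy-adult means; CSF, paraspinal soft
    tissue ("surround") and vertebra values are implementer-chosen,
    literature-plausible configuration defaults.
    """
    return {
        "background": TissueParams("background", 0.0, 1.0, 0.0, 0.0),
        "csf": TissueParams("csf", 8000.0, 4300.0, 0.001, 2.0),
        "gm": TissueParams("gm", 5160.0, 1815.0, 0.0118, 18.9),
        "dorsal_wm": TissueParams("dorsal_wm", 4668.0, 1735.0, 0.0143, 22.3),
        "left_lateral_wm": TissueParams("left_lateral_wm", 4408.0, 1593.0, 0.0147, 21.2),
        "right_lateral_wm": TissueParams("right_lateral_wm", 4792.0, 1707.0, 0.0143, 20.5),
        "surround": TissueParams("surround", 4300.0, 1400.0, 0.010, 30.0),
        "vertebra": TissueParams("vertebra", 2800.0, 900.0, 0.006, 45.0),
    }


def default_acquisitions() -> dict[str, AcquisitionParams]:
    """PDw / T1w / MTw sequence settings.

    The MTw excitation shares the PDw readout (TR 24.05 ms, 6 deg); the MT
    pulse itself is described as metadata only.
    """
    pd_tes = tuple(np.linspace(3.0, 18.55, 6))
    return {
        "PDw": AcquisitionParams("PDw", 24.05, 6.0, pd_tes),
        "T1w": AcquisitionParams("T1w", 22.0, 20.0, pd_tes[:5]),
        "MTw": AcquisitionParams("MTw", 24.05, 6.0, pd_tes[:5], mt_pulse=MTPulse()),
    }


@dataclass(frozen=True)
class AFIParams:
    nominal_deg: float = 60.0
    tr1_ms: float = 50.0
    tr2_ms: float = 150.0
    te_ms: float = 3.05

    def __post_init__(self):
        if self.tr2_ms <= self.tr1_ms:
            raise ValueError("AFI requires TR2 > TR1")

    @property
    def n(self) -> float:
        return self.tr2_ms / self.tr1_ms


@dataclass(frozen=True)
class B1FieldSpec:
    """Smooth transmit-field model: affine ramp plus optional Gaussian bump.

    ``mean_percent`` is the value at the volume centre; the gradient is in
    percent of nominal per mm along each world axis.  Values are bounded to
    ``clip_percent``; the in-vivo field is nearly flat around 100%.
    """

    mean_percent: float = 100.0
    gradient_percent_per_mm: tuple[float, float, float] = (0.05, 0.0, 0.15)
    bump_percent: float = 0.0
    bump_center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    bump_fwhm_mm: float = 40.0
    clip_percent: tuple[float, float] = (70.0, 130.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: sigma = (mean noiseless WM signal of first echo)/snr."""

    model: str = "rician"       # "rician" | "gaussian" | "none"
    snr: float = 50.0

    def __post_init__(self):
        if self.model not in ("rician", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.model != "none" and self.snr <= 0:
            raise ValueError("SNR must be positive when noise is enabled")


def default_motion() -> dict[str, RigidTransform]:
    """Modest inter-scan motion (one to two voxels, as seen in vivo).

    MTw is the simulation reference and stays put; the others move.
    """
    return {
        "PDw": RigidTransform(1.2, -0.8, 0.6, 0.5, -0.4, 0.8),
        "T1w": RigidTransform(-0.9, 1.1, -0.5, -0.6, 0.5, -0.4),
        "MTw": RigidTransform(),
        "AFI": RigidTransform(0.5, 0.6, 1.0, 0.3, -0.2, 0.4),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Full generative description of one synthetic subject/cohort."""

    shape: tuple[int, int, int] = (64, 64, 30)
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 3.0)
    cord_radius_mm: float = 4.5
    csf_radius_mm: float = 7.5
    gm_wing_offset_mm: float = 1.3
    gm_wing_rx_mm: float = 1.2
    gm_wing_ry_mm: float = 2.3
    gm_bridge_ry_mm: float = 0.9
    dorsal_half_angle_deg: float = 60.0
    taper_per_mm: float = 0.004     # fractional radius change per mm along z
    with_surround: bool = True      # paraspinal tissue + vertebra around the canal
    neck_radii_mm: tuple[float, float] = (26.0, 22.0)
    vertebra_period_mm: float = 15.0    # vertebral body + disc repeat along z
    vertebra_height_mm: float = 11.0
    endplate_dome_mm: float = 3.0       # curvature of the body/disc interfaces
    tissues: Mapping[str, TissueParams] = field(default_factory=default_tissues)
    acquisitions: Mapping[str, AcquisitionParams] = field(
        default_factory=default_acquisitions)
    afi: AFIParams = AFIParams()
    motion: Mapping[str, RigidTransform] = field(default_factory=default_motion)
    b1: B1FieldSpec = B1FieldSpec()
    noise: NoiseSpec = NoiseSpec()
    signal_mode: str = "approx"         # forward model: "approx" | "exact"
    mt_b1_scaling: bool = True          # scale delta by (fT)^2 in simulation
    cohort_cv: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.10, "T1": 0.07, "delta": 0.08,
                                 "R2star": 0.068})
    seed: int = 0

    def __post_init__(self):
        if self.cord_radius_mm <= 0 or self.csf_radius_mm <= 0:
            raise GeometryError("radii must be positive")
        if self.csf_radius_mm <= self.cord_radius_mm:
            raise GeometryError("CSF radius must exceed cord radius")

    @property
    def affine(self) -> np.ndarray:
        """Voxel-to-world affine placing the grid centre at world origin."""
        a = np.eye(4)
        a[:3, :3] = np.diag(self.voxel_mm)
        a[:3, 3] = -(np.asarray(self.shape) - 1) / 2.0 * np.asarray(self.voxel_mm)
        return a


# --------------------------------------------------------------------------
# geometry and ground truth
# --------------------------------------------------------------------------

def make_geometry(spec: PhantomSpec) -> Volume3D:
    """Build the label volume for the cord cross-section.

    Background outside the CSF annulus; WM disc split into a dorsal sector
    (within ``dorsal_half_angle_deg`` of the posterior axis) and mirror-image
    left/right lateral sectors; central GM butterfly (two elliptical wings
    joined by a bridge).  The cross-section tapers linearly along z
    (``taper_per_mm``), emulating the calibre change across cervical
    levels; this also makes through-slice position identifiable to the
    registration.
    """
    nx, ny, nz = spec.shape
    vx, vy, vz = spec.voxel_mm
    x = (np.arange(nx) - (nx - 1) / 2.0) * vx
    y = (np.arange(ny) - (ny - 1) / 2.0) * vy
    z = (np.arange(nz) - (nz - 1) / 2.0) * vz
    xx, yy = np.meshgrid(x, y, indexing="ij")
    r = np.hypot(xx, yy)
    theta = np.rad2deg(np.arctan2(xx, -yy))   # angle from the posterior (-y) axis

    surround = np.zeros((nx, ny), dtype=bool)
    vertebra = np.zeros((nx, ny), dtype=bool)
    dome = np.zeros((nx, ny))
    if spec.with_surround:
        # paraspinal soft tissue and vertebral structures anchor the
        # registration (a cord floating in air leaves axial rotation
        # nearly unobservable, unlike a real neck)
        na, nb = spec.neck_radii_mm
        surround = (xx / na) ** 2 + (yy / nb) ** 2 <= 1.0
        body_r2 = (xx / 9.0) ** 2 + ((yy - 14.0) / 6.0) ** 2
        vertebra = body_r2 <= 1.0                                           # body
        vertebra |= ((xx / 2.5) ** 2 + ((yy + 14.0) / 5.0) ** 2 <= 1.0)     # spinous
        vertebra |= (((xx - 16.0) / 3.0) ** 2 + ((yy + 4.0) / 3.0) ** 2 <= 1.0)
        vertebra |= (((xx + 16.0) / 3.0) ** 2 + ((yy + 4.0) / 3.0) ** 2 <= 1.0)
        vertebra &= surround
        # curved endplates: the body/disc interface is a dome, not a flat
        # plane, so axial position is encoded in the in-plane pattern
        dome = spec.endplate_dome_mm * np.clip(body_r2, 0.0, 1.0)

    labels = np.zeros((nx, ny, nz), dtype=np.int16)
    for k in range(nz):
        scale = 1.0 + spec.taper_per_mm * z[k]
        section = np.zeros((nx, ny), dtype=np.int16)
        section[surround] = LABELS["surround"]
        # vertebral bodies alternate with discs along z
        in_body = ((z[k] - z[0] + dome) % spec.vertebra_period_mm
                   < spec.vertebra_height_mm)
        section[vertebra & in_body] = LABELS["vertebra"]
        section[r <= spec.csf_radius_mm * scale] = LABELS["csf"]

        cord = r <= spec.cord_radius_mm * scale
        dorsal = cord & (np.abs(theta) <= spec.dorsal_half_angle_deg)
        left = cord & ~dorsal & (xx < 0)
        right = cord & ~dorsal & (xx >= 0)
        section[dorsal] = LABELS["dorsal_wm"]
        section[left] = LABELS["left_lateral_wm"]
        section[right] = LABELS["right_lateral_wm"]

        off = spec.gm_wing_offset_mm * scale
        a = spec.gm_wing_rx_mm * scale
        b = spec.gm_wing_ry_mm * scale
        wings = (((xx - off) / a) ** 2 + (yy / b) ** 2 <= 1.0) | \
                (((xx + off) / a) ** 2 + (yy / b) ** 2 <= 1.0)
        bridge = (np.abs(xx) <= off) & (np.abs(yy) <= spec.gm_bridge_ry_mm * scale)
        section[cord & (wings | bridge)] = LABELS["gm"]
        labels[:, :, k] = section

    return Volume3D(labels, spec.affine)


@dataclass
class GroundTruth:
    """Voxelwise true parameter fields of a phantom subject."""

    apd: np.ndarray
    t1_ms: np.ndarray
    delta: np.ndarray
    r2star_s: np.ndarray
    affine: np.ndarray

    def mtsat_pu(self) -> np.ndarray:
        return 100.0 * self.delta

    def mtr_pu(self, acq_mt: AcquisitionParams, mode: str = "approx") -> np.ndarray:
        """Analytic TE=0 MTR implied by the truth fields (at nominal B1)."""
        out = np.zeros_like(self.delta)
        ok = self.apd > 0
        out[ok] = mtr_from_params(self.delta[ok], self.t1_ms[ok],
                                  acq_mt.tr_ms, acq_mt.flip_deg, mode=mode)
        return out


def assign_ground_truth(
    labels: Volume3D, tissues: Mapping[str, TissueParams]
) -> GroundTruth:
    """Expand the tissue table into constant-by-region parameter maps."""
    name_of = {LABELS[k]: k for k in LABELS}
    lab = np.asarray(labels.data).astype(int)
    present = np.unique(lab)
    for code in present:
        name = name_of.get(int(code))
        if name is None or name not in tissues:
            raise ValueError(f"unknown tissue label {code!r} in label volume")
    shape = lab.shape
    apd = np.zeros(shape)
    t1 = np.ones(shape)         # keep T1 positive everywhere, incl. background
    delta = np.zeros(shape)
    r2 = np.zeros(shape)
    for code in present:
        tp = tissues[name_of[int(code)]]
        m = lab == code
        apd[m], delta[m], r2[m] = tp.a, tp.delta, tp.r2star_s
        t1[m] = tp.t1_ms
    return GroundTruth(apd, t1, delta, r2, labels.affine.copy())


def b1_field(spec: PhantomSpec) -> Volume3D:
    """Transmit-field map f_T in percent of nominal on the phantom grid."""
    nx, ny, nz = spec.shape
    aff = spec.affine
    idx = np.indices(spec.shape, dtype=float).reshape(3, -1)
    world = aff[:3, :3] @ idx + aff[:3, 3:4]
    g = np.asarray(spec.b1.gradient_percent_per_mm)
    f = spec.b1.mean_percent + g @ world
    if spec.b1.bump_percent != 0.0:
        d2 = ((world - np.asarray(spec.b1.bump_center_mm)[:, None]) ** 2).sum(axis=0)
        sigma = spec.b1.bump_fwhm_mm / 2.3548200450309493
        f = f + spec.b1.bump_percent * np.exp(-d2 / (2 * sigma**2))
    f = np.clip(f, *spec.b1.clip_percent)
    return Volume3D(f.reshape(spec.shape), aff)


# --------------------------------------------------------------------------
# forward simulation
# --------------------------------------------------------------------------

def simulate_echoes(
    truth: GroundTruth,
    acq: AcquisitionParams,
    b1: Volume3D | None = None,
    mode: str = "approx",
    mt_b1_scaling: bool = True,
) -> EchoSeries:
    """Simulate one multi-echo FLASH contrast from the truth fields.

    The local transmit factor f_T scales the excitation flip angle for
    every contrast; for the MT contrast it additionally scales the per-TR
    saturation as delta * f_T^2 (the saturation of the off-resonance pulse
    grows with the square of its amplitude), unless ``mt_b1_scaling`` is
    disabled.  Non-MT contrasts see delta = 0.
    """
    if b1 is not None and b1.shape != truth.apd.shape:
        raise ValueError("simulate_echoes: B1 grid does not match truth grid")
    f = np.ones_like(truth.apd) if b1 is None else b1.data / 100.0
    flip_eff = f * acq.flip_deg
    if acq.mt_pulse is not None:
        delta = truth.delta * (f**2 if mt_b1_scaling else 1.0)
    else:
        delta = np.zeros_like(truth.delta)
    s0 = flash_signal(truth.apd, truth.t1_ms, delta, flip_eff, acq.tr_ms, mode=mode)
    tes = np.asarray(acq.echo_times_ms)
    decay = np.exp(-truth.r2star_s[..., None] * tes / 1000.0)
    return EchoSeries(s0[..., None] * decay, truth.affine.copy(), acq)


def simulate_afi(
    b1: Volume3D,
    afi: AFIParams = AFIParams(),
    amplitude: np.ndarray | None = None,
) -> tuple[Volume3D, Volume3D]:
    """Simulate the AFI volume pair under the idealised ratio model.

    ``volume1 = amplitude`` and ``volume2 = amplitude * r`` with
    r = (1 + n cos(a)) / (n + cos(a)), a = f_T * nominal; T1 dependence is
    neglected by design, matching the arccos estimator.
    """
    amp = np.ones(b1.shape) if amplitude is None else np.asarray(amplitude, float)
    if amp.shape != b1.shape:
        raise ValueError("simulate_afi: amplitude grid does not match B1 grid")
    actual_deg = b1.data / 100.0 * afi.nominal_deg
    ratio = afi_signal_ratio(actual_deg, afi.n)
    return (Volume3D(amp.copy(), b1.affine.copy()),
            Volume3D(amp * ratio, b1.affine.copy()))


def apply_motion(series: EchoSeries, t: RigidTransform,
                 interp: str = "sinc") -> EchoSeries:
    """Bake inter-scan motion into the intensities of every echo.

    The voxel-to-world transform is left unchanged, as with real motion
    between scans; the registration pipeline has to undo it.
    """
    from .registration import apply_to_echoes
    return apply_to_echoes(series, t, interp=interp)


def add_noise(
    series: EchoSeries,
    snr: float,
    model: str = "rician",
    seed: int | np.random.Generator = 0,
    reference_mask: np.ndarray | None = None,
) -> EchoSeries:
    """Add Gaussian or Rician noise at a given first-echo SNR.

    sigma is the mean noiseless signal of the first echo over
    ``reference_mask`` (WM in the phantom; positive voxels if omitted)
    divided by ``snr``.  Rician noise is |S + N(0, sigma) + i N(0, sigma)|.
    """
    if model == "none":
        return EchoSeries(series.data.copy(), series.affine.copy(), series.acq)
    if model not in ("gaussian", "rician"):
        raise ValueError(f"unknown noise model {model!r}")
    if snr <= 0:
        raise ValueError("SNR must be positive")
    first = series.data[..., 0]
    mask = reference_mask if reference_mask is not None else first > 0
    ref = float(first[mask].mean())
    sigma = ref / snr
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if model == "gaussian":
        data = series.data + rng.normal(0.0, sigma, series.data.shape)
    else:
        re = series.data + rng.normal(0.0, sigma, series.data.shape)
        im = rng.normal(0.0, sigma, series.data.shape)
        data = np.hypot(re, im)
    return EchoSeries(data, series.affine.copy(), series.acq)


def _noise_volume(v: Volume3D, sigma: float, model: str,
                  rng: np.random.Generator) -> Volume3D:
    if model == "none" or sigma == 0:
        return v.with_data(v.data.copy())
    if model == "gaussian":
        return v.with_data(v.data + rng.normal(0.0, sigma, v.shape))
    re = v.data + rng.normal(0.0, sigma, v.shape)
    return v.with_data(np.hypot(re, rng.normal(0.0, sigma, v.shape)))


# --------------------------------------------------------------------------
# subjects and cohorts
# --------------------------------------------------------------------------

@dataclass
class SubjectData:
    """One simulated subject: inputs plus everything the pipeline estimates."""

    subject_id: str
    spec: PhantomSpec
    labels: Volume3D
    truth: GroundTruth
    b1_true: Volume3D
    series: dict                    # contrast -> EchoSeries (moved + noisy)
    afi_pair: tuple                 # (Volume3D, Volume3D)
    motion: dict                    # contrast -> injected RigidTransform

    @property
    def wm_mask(self) -> np.ndarray:
        return np.isin(self.labels.data, WM_LABELS)

    @property
    def cord_mask(self) -> np.ndarray:
        return np.isin(self.labels.data, CORD_LABELS)


def simulate_subject(
    spec: PhantomSpec,
    subject_id: str = "sub-01",
    rng: np.random.Generator | None = None,
) -> SubjectData:
    """Generate one complete synthetic dataset from a phantom spec."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    labels = make_geometry(spec)
    truth = assign_ground_truth(labels, spec.tissues)
    b1 = b1_field(spec)
    wm = np.isin(labels.data, WM_LABELS)

    series = {}
    for contrast, acq in spec.acquisitions.items():
        s = simulate_echoes(truth, acq, b1=b1, mode=spec.signal_mode,
                            mt_b1_scaling=spec.mt_b1_scaling)
        t = spec.motion.get(contrast)
        if t is not None and not t.is_identity:
            s = apply_motion(s, t)
        if spec.noise.model != "none":
            s = add_noise(s, spec.noise.snr, spec.noise.model,
                          seed=rng, reference_mask=wm)
        series[contrast] = s

    s1, s2 = simulate_afi(b1, spec.afi, amplitude=truth.apd)
    t_afi = spec.motion.get("AFI")
    if t_afi is not None and not t_afi.is_identity:
        s1 = resample(s1, t_afi, interp="sinc")
        s2 = resample(s2, t_afi, interp="sinc")
    if spec.noise.model != "none":
        sigma = float(s1.data[wm].mean()) / spec.noise.snr
        s1 = _noise_volume(s1, sigma, spec.noise.model, rng)
        s2 = _noise_volume(s2, sigma, spec.noise.model, rng)

    return SubjectData(subject_id, spec, labels, truth, b1, series, (s1, s2),
                       dict(spec.motion))


_PARAM_FIELD = {"A": "a", "T1": "t1_ms", "delta": "delta", "R2star": "r2star_s"}
_TRUNCATION = {"A": 1.0, "T1": 100.0, "delta": 0.0, "R2star": 0.0}


def _draw_subject_tissues(
    spec: PhantomSpec, rng: np.random.Generator
) -> dict[str, TissueParams]:
    """Per-subject tissue table: one multiplicative factor per parameter,
    shared across cord tissues (models global inter-subject variation)."""
    factors = {}
    for pname, cv in spec.cohort_cv.items():
        if pname == "MTR":
            continue
        factors[pname] = 1.0 + cv * rng.standard_normal()
    out = {}
    for name, tp in spec.tissues.items():
        if name == "background":
            out[name] = tp
            continue
        kwargs = {}
        for pname, factor in factors.items():
            fieldname = _PARAM_FIELD[pname]
            value = getattr(tp, fieldname) * factor
            floor = _TRUNCATION[pname]
            if value < floor:
                logger.warning("truncating drawn %s for %s at %s", pname, name, floor)
                value = floor
            kwargs[fieldname] = value
        out[name] = replace(tp, **kwargs)
    if "MTR" in spec.cohort_cv:
        from .signal import delta_for_mtr
        acq = spec.acquisitions["MTw"]
        m = 1.0 + spec.cohort_cv["MTR"] * rng.standard_normal()
        for name, tp in out.items():
            if name == "background":
                continue
            base = mtr_from_params(spec.tissues[name].delta,
                                   tp.t1_ms, acq.tr_ms, acq.flip_deg)
            target = max(float(base) * m, 0.0)
            out[name] = replace(
                tp, delta=float(delta_for_mtr(target, tp.t1_ms,
                                              acq.tr_ms, acq.flip_deg)))
    return out


def generate_cohort(
    spec: PhantomSpec,
    n_subjects: int,
    out_dir: str | Path | None = None,
) -> tuple[list[SubjectData], pd.DataFrame]:
    """Simulate a cohort and (optionally) write it to disk.

    Per-subject tissue means are drawn from normal distributions around the
    spec's tissue table with the spec's inter-subject coefficients of
    variation.  Returns the subjects and a truth manifest with one row per
    subject x tissue.  When ``out_dir`` is given, NIfTI volumes with JSON
    sidecars plus ``truth_manifest.csv`` are written there.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    seeds = np.random.SeedSequence(spec.seed).spawn(n_subjects)
    subjects = []
    rows = []
    acq_mt = spec.acquisitions["MTw"]
    for j in range(n_subjects):
        rng = np.random.default_rng(seeds[j])
        sid = f"sub-{j + 1:02d}"
        tissues = _draw_subject_tissues(spec, rng)
        sub_spec = replace(spec, tissues=tissues)
        subject = simulate_subject(sub_spec, subject_id=sid, rng=rng)
        subjects.append(subject)
        for name, tp in tissues.items():
            if name == "background":
                continue
            rows.append({
                "subject": sid,
                "tissue": name,
                "A": tp.a,
                "T1_ms": tp.t1_ms,
                "MTsat_pu": 100.0 * tp.delta,
                "R2star_s-1": tp.r2star_s,
                "MTR_pu": float(mtr_from_params(tp.delta, tp.t1_ms,
                                                acq_mt.tr_ms, acq_mt.flip_deg)),
            })
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for subject in subjects:
            write_subject(subject, out_dir / subject.subject_id)
        manifest.to_csv(out_dir / "truth_manifest.csv", index=False)
    return subjects, manifest


def write_subject(subject: SubjectData, sub_dir: str | Path) -> None:
    """Write one subject's dataset as NIfTI volumes with JSON sidecars."""
    sub_dir = Path(sub_dir)
    sub_dir.mkdir(parents=True, exist_ok=True)
    for contrast, series in subject.series.items():
        series.save(sub_dir / f"{contrast}.nii")
    s1, s2 = subject.afi_pair
    s1.save(sub_dir / "AFI_tr1.nii")
    s2.save(sub_dir / "AFI_tr2.nii")
    afi = subject.spec.afi
    (sub_dir / "AFI.json").write_text(json.dumps({
        "Nominal_B1_deg": afi.nominal_deg,
        "RepetitionTime1_ms": afi.tr1_ms,
        "RepetitionTime2_ms": afi.tr2_ms,
        "EchoTime_ms": afi.te_ms,
    }, indent=2))
    subject.labels.save(sub_dir / "labels.nii")
    (sub_dir / "labels.json").write_text(json.dumps(LABELS, indent=2))
    subject.b1_true.save(sub_dir / "B1_true.nii")
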
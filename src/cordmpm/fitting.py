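"""Voxelwise estimation of R2*, T1, APD, MT saturation and MTR.

The computational core of the package.  R2* comes from an ordinary
least-squares fit of log-signal against echo time.  T1 and the amplitude
APD follow from the PDw/T1w pair through the rational approximation of
the FLASH signal, optionally with per-voxel effective flip angles from a
transmit-field map.  The MT saturation delta is obtained by inserting the
estimated APD and R1 into the approximate MT-FLASH signal equation at the
*nominal* MT-contrast flip angle: because the readout-angle error and the
transmit scaling of the MT pulse bias the inputs in compensating ways,
delta is intrinsically robust to B1 inhomogeneity, unlike MTR.

Echo-averaged volumes feed the signal equations.  Since averaging over
echoes attenuates the signal by the mean T2* decay factor of the echo
times used — and the three contrasts use different echo sets — averaged
volumes are rescaled to their TE = 0 amplitude using the fitted R2* map
before inversion ("decay correction").  This removes the differential
T2* weighting that would otherwise bias T1 and APD.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .b1 import B1Map
from .core import AcquisitionParams, EchoSeries, ParameterMaps, Volume3D, echo_indices
from .registration import average_echoes

__all__ = [
    "fit_r2star",
    "decay_factor",
    "estimate_t1_apd",
    "compute_mtsat",
    "compute_mtr",
    "estimate_all",
]


def fit_r2star(series: EchoSeries) -> tuple[Volume3D, Volume3D, np.ndarray]:
    """Log-linear R2* fit across the echoes of one series.

    Ordinary least squares of ln(S) against TE per voxel; the slope gives
    -R2* (returned in 1/s) and the intercept the extrapolated TE = 0
    intensity.  Voxels with any non-positive signal among the echoes used
    are masked; a fit needs at least two echoes.

    Returns ``(r2star_map, s0_map, valid_mask)``.
    """
    if series.n_echoes < 2:
        raise ValueError("R2* fit needs at least two echoes")
    tes = np.asarray(series.acq.echo_times_ms)
    data = series.data
    valid = np.all(data > 0, axis=3)
    logs = np.log(np.where(data > 0, data, 1.0))
    # closed-form simple regression, vectorised over voxels
    t_mean = tes.mean()
    t_var = ((tes - t_mean) ** 2).sum()
    y_mean = logs.mean(axis=3)
    slope = ((tes - t_mean) * (logs - y_mean[..., None])).sum(axis=3) / t_var
    intercept = y_mean - slope * t_mean
    r2star_s = np.where(valid, -slope * 1000.0, np.nan)   # 1/ms -> 1/s
    s0 = np.where(valid, np.exp(intercept), np.nan)
    return (Volume3D(r2star_s, series.affine.copy()),
            Volume3D(s0, series.affine.copy()),
            valid)


def decay_factor(r2star_s: np.ndarray, echo_times_ms) -> np.ndarray:
    """Mean T2* attenuation of an echo average: mean_i exp(-R2* TE_i)."""
    tes = np.asarray(echo_times_ms, dtype=float)
    r2 = np.nan_to_num(np.asarray(r2star_s, dtype=float), nan=0.0)
    return np.exp(-r2[..., None] * tes / 1000.0).mean(axis=-1)


def _effective_flip_rad(acq: AcquisitionParams, b1: B1Map | None):
    if b1 is None:
        return acq.flip_rad
    return b1.fraction * acq.flip_rad


def estimate_t1_apd(
    s_pd: Volume3D,
    s_t1: Volume3D,
    acq_pd: AcquisitionParams,
    acq_t1: AcquisitionParams,
    b1: B1Map | None = None,
    t1_ceiling_ms: float = 10000.0,
) -> tuple[Volume3D, Volume3D, Volume3D, np.ndarray]:
    """T1 (ms), R1 (1/s) and APD (a.u.) from the PDw/T1w pair.

    Rational-approximation inversion with angles in radians:

        R1 = (S_T1 a_T1 / TR_T1 - S_PD a_PD / TR_PD)
             / (2 (S_PD / a_PD - S_T1 / a_T1))
        A  = S_PD S_T1 (TR_PD a_T1 / a_PD - TR_T1 a_PD / a_T1)
             / (S_T1 TR_PD a_T1 - S_PD TR_T1 a_PD)

    With a B1 map, both angles become the per-voxel effective angles
    f_T * nominal.  Non-physical voxels (non-positive signals, denominator
    or R1) are masked; T1 is clipped to (0, ``t1_ceiling_ms``].

    Returns ``(t1_ms, r1_s, apd, valid_mask)``.
    """
    if s_pd.shape != s_t1.shape:
        raise ValueError("PDw and T1w volumes must share one grid")
    if b1 is not None and b1.percent.shape != s_pd.shape:
        raise ValueError("B1 map grid does not match the signal grid")
    a_pd = _effective_flip_rad(acq_pd, b1)
    a_t1 = _effective_flip_rad(acq_t1, b1)
    spd = np.asarray(s_pd.data, dtype=float)
    st1 = np.asarray(s_t1.data, dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        num_r1 = st1 * a_t1 / acq_t1.tr_ms - spd * a_pd / acq_pd.tr_ms
        den_r1 = 2.0 * (spd / a_pd - st1 / a_t1)
        r1_per_ms = num_r1 / den_r1
        num_a = spd * st1 * (acq_pd.tr_ms * a_t1 / a_pd
                             - acq_t1.tr_ms * a_pd / a_t1)
        den_a = st1 * acq_pd.tr_ms * a_t1 - spd * acq_t1.tr_ms * a_pd
        apd = num_a / den_a

    valid = (
        (spd > 0) & (st1 > 0)
        & np.isfinite(r1_per_ms) & np.isfinite(apd)
        & (den_r1 > 0) & (den_a > 0) & (r1_per_ms > 0)
    )
    t1_ms = np.where(valid, np.clip(1.0 / np.where(valid, r1_per_ms, 1.0),
                                    None, t1_ceiling_ms), np.nan)
    r1_s = np.where(valid, 1000.0 / t1_ms, np.nan)
    apd = np.where(valid, apd, np.nan)
    aff = s_pd.affine
    return (Volume3D(t1_ms, aff.copy()), Volume3D(r1_s, aff.copy()),
            Volume3D(apd, aff.copy()), valid)


def compute_mtsat(
    s_mt: Volume3D,
    apd: Volume3D,
    r1_s: Volume3D,
    acq_mt: AcquisitionParams,
) -> tuple[Volume3D, np.ndarray]:
    """MT saturation (p.u.) from the MTw signal and the fitted APD and R1.

    delta = (A a_MT / S_MT - 1) TR_MT R1 - a_MT^2 / 2, evaluated at the
    nominal (uncorrected) flip angle: transmit-field errors in the readout
    and in the MT pulse compensate, which is the point of the parameter.
    Output is 100 * delta in percent units.
    """
    if s_mt.shape != apd.shape or s_mt.shape != r1_s.shape:
        raise ValueError("MTw, APD and R1 volumes must share one grid")
    alpha = acq_mt.flip_rad
    smt = np.asarray(s_mt.data, dtype=float)
    a = np.asarray(apd.data, dtype=float)
    r1_per_ms = np.asarray(r1_s.data, dtype=float) / 1000.0
    valid = (smt > 0) & (a > 0) & np.isfinite(a) & np.isfinite(r1_per_ms)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = ((a * alpha / smt - 1.0) * acq_mt.tr_ms * r1_per_ms
                 - alpha**2 / 2.0)
    mtsat = np.where(valid, 100.0 * delta, np.nan)
    return Volume3D(mtsat, s_mt.affine.copy()), valid


def compute_mtr(s_ref: Volume3D, s_mt: Volume3D) -> tuple[Volume3D, np.ndarray]:
    """Magnetisation-transfer ratio MTR = 100 (S_ref - S_MT)/S_ref (p.u.)."""
    if s_ref.shape != s_mt.shape:
        raise ValueError("reference and MTw volumes must share one grid")
    ref = np.asarray(s_ref.data, dtype=float)
    valid = ref > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        mtr = 100.0 * (ref - s_mt.data) / ref
    return Volume3D(np.where(valid, mtr, np.nan), s_ref.affine.copy()), valid


@dataclass
class RegisteredSubjectData:
    """Co-registered echo series of one subject, ready for fitting."""

    pdw: EchoSeries
    t1w: EchoSeries
    mtw: EchoSeries
    b1: B1Map | None = None


def estimate_all(
    pdw: EchoSeries,
    t1w: EchoSeries,
    mtw: EchoSeries,
    b1: B1Map | None = None,
    echo_subset: str = "all",
    te_zero_correction: bool = True,
    mtr_reference: str = "matched",
    b1_correct: bool = True,
) -> ParameterMaps:
    """Full map estimation from co-registered echo series.

    Orchestrates echo averaging, the R2* fit (on the PDw echoes), the
    T1/APD inversion, MT saturation and MTR.  ``echo_subset`` selects the
    same odd/even/all subset in every contrast.  With
    ``te_zero_correction`` the averaged volumes are rescaled to TE = 0
    using the fitted R2* before the signal equations are inverted;
    otherwise ``mtr_reference`` chooses whether the MTR reference averages
    the PDw echoes matched to the MTw echo times (``matched``) or all of
    them (``all``).
    """
    sub = {
        "PDw": pdw.select(echo_indices(echo_subset, pdw.n_echoes)),
        "T1w": t1w.select(echo_indices(echo_subset, t1w.n_echoes)),
        "MTw": mtw.select(echo_indices(echo_subset, mtw.n_echoes)),
    }
    r2star, _, r2_valid = fit_r2star(sub["PDw"])

    averages = {}
    for name, series in sub.items():
        ave = average_echoes(series)
        if te_zero_correction:
            corrected = ave.data / decay_factor(r2star.data,
                                                series.acq.echo_times_ms)
            averages[name] = ave.with_data(corrected)
        else:
            averages[name] = ave

    t1_map, r1_map, apd_map, t1_valid = estimate_t1_apd(
        averages["PDw"], averages["T1w"], sub["PDw"].acq, sub["T1w"].acq,
        b1=b1 if b1_correct else None,
    )
    mtsat_map, mt_valid = compute_mtsat(averages["MTw"], apd_map, r1_map,
                                        sub["MTw"].acq)

    if te_zero_correction or mtr_reference == "all":
        mtr_ref = averages["PDw"]
    elif mtr_reference == "matched":
        n_mt = sub["MTw"].acq.n_echoes
        mtr_ref = average_echoes(sub["PDw"].select(range(min(n_mt,
                                                             sub["PDw"].n_echoes))))
    else:
        raise ValueError(f"unknown mtr_reference {mtr_reference!r}")
    mtr_map, mtr_valid = compute_mtr(mtr_ref, averages["MTw"])

    masks = {
        "R2star": r2_valid,
        "APD": t1_valid,
        "T1": t1_valid,
        "R1": t1_valid,
        "MTsat": t1_valid & mt_valid,
        "MTR": mtr_valid,
    }
    return ParameterMaps(
        apd=apd_map.data, t1_ms=t1_map.data, r1_s=r1_map.data,
        mtsat_pu=np.where(masks["MTsat"], mtsat_map.data, np.nan),
        mtr_pu=np.where(masks["MTR"], mtr_map.data, np.nan),
        r2star_s=r2star.data,
        affine=pdw.affine.copy(), masks=masks,
        echo_subset=echo_subset if isinstance(echo_subset, str) else "custom",
    )
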
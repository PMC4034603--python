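"""Steady-state spoiled gradient-echo (FLASH) signal models.

The exact model is the Ernst steady state of an ideally spoiled FLASH
sequence, extended with a per-TR saturation fraction ``delta`` applied to
the longitudinal magnetisation immediately before each excitation (the
MT-FLASH experiment):

    S_exact = A sin(a) (1 - delta) (1 - E1) / (1 - (1 - delta) cos(a) E1),
    E1 = exp(-TR / T1).

For small flip angle and TR << T1 this reduces to the rational
approximation used for map estimation:

    S_approx = A a (TR R1) / (a^2 / 2 + delta + TR R1),

with ``a`` in radians, ``TR`` in ms and ``R1 = 1/T1`` in 1/ms.  The
approximation makes the inverse problem (A, T1, delta from three FLASH
contrasts) algebraic; the exact model serves as the oracle to quantify
the approximation bias.

All functions broadcast over numpy arrays.  Angles are accepted in
degrees, times in ms.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "flash_signal",
    "afi_signal_ratio",
    "mtr_from_params",
    "delta_for_mtr",
]


def flash_signal(a, t1_ms, delta, flip_deg, tr_ms, mode: str = "approx"):
    """Steady-state FLASH amplitude at TE = 0.

    Parameters
    ----------
    a : array_like
        Signal amplitude (apparent proton density), arbitrary units.
    t1_ms : array_like
        Longitudinal relaxation time in ms; must be positive.
    delta : array_like
        Fractional saturation per MT pulse (0 for non-MT contrasts).
    flip_deg : array_like
        Excitation flip angle in degrees (the *effective* local angle;
        transmit-field scaling is the caller's responsibility).
    tr_ms : float
        Repetition time in ms.
    mode : {"approx", "exact"}
        ``approx`` evaluates the rational approximation; ``exact`` the
        spoiled steady state.
    """
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("T1 must be positive everywhere")
    amp = np.asarray(a, dtype=float)
    d = np.asarray(delta, dtype=float)
    alpha = np.deg2rad(np.asarray(flip_deg, dtype=float))
    tr_r1 = tr_ms / t1
    if mode == "approx":
        return amp * alpha * tr_r1 / (alpha**2 / 2.0 + d + tr_r1)
    if mode == "exact":
        e1 = np.exp(-tr_r1)
        return (amp * np.sin(alpha) * (1.0 - d) * (1.0 - e1)
                / (1.0 - (1.0 - d) * np.cos(alpha) * e1))
    raise ValueError(f"unknown signal mode {mode!r} (expected 'approx' or 'exact')")


def afi_signal_ratio(flip_deg, n):
    """Idealised actual-flip-angle-imaging signal ratio S2/S1.

    For interleaved repetition times TR1 < TR2 with n = TR2/TR1 and actual
    flip angle ``alpha`` (degrees), assuming TR1, TR2 << T1 and perfect
    spoiling:

        r = (1 + n cos(alpha)) / (n + cos(alpha)).

    T1 dependence is neglected by design; the matching estimator inverts
    exactly this model.
    """
    n = float(n)
    if n <= 1:
        raise ValueError(f"AFI requires TR2/TR1 > 1, got n = {n}")
    c = np.cos(np.deg2rad(np.asarray(flip_deg, dtype=float)))
    return (1.0 + n * c) / (n + c)


def mtr_from_params(delta, t1_ms, tr_ms, flip_deg, mode: str = "approx"):
    """Analytic magnetisation-transfer ratio (p.u.) implied by the model.

    MTR = 100 (S_ref - S_MT)/S_ref evaluated at TE = 0, where S_ref is the
    MT-pulse-free signal at the same flip angle and TR.
    """
    one = np.ones_like(np.asarray(delta, dtype=float))
    s_ref = flash_signal(one, t1_ms, 0.0, flip_deg, tr_ms, mode=mode)
    s_mt = flash_signal(one, t1_ms, delta, flip_deg, tr_ms, mode=mode)
    return 100.0 * (s_ref - s_mt) / s_ref


def delta_for_mtr(mtr_pu, t1_ms, tr_ms, flip_deg):
    """Saturation fraction delta producing a requested MTR (approx model).

    Inverse of :func:`mtr_from_params` in ``approx`` mode, where
    MTR/100 = delta / (alpha^2/2 + TR R1 + delta).
    """
    m = np.asarray(mtr_pu, dtype=float) / 100.0
    if np.any((m < 0) | (m >= 1)):
        raise ValueError("MTR must lie in [0, 100) p.u.")
    alpha = np.deg2rad(float(flip_deg))
    d_free = alpha**2 / 2.0 + tr_ms / np.asarray(t1_ms, dtype=float)
    return m * d_free / (1.0 - m)
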
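"""Digital cord phantom: geometry, ground truth, forward simulation, noise."""
import numpy as np
import pytest

from cordmpm.core import RigidTransform
from cordmpm.phantom import (CORD_LABELS, LABELS, B1FieldSpec, GeometryError,
                             NoiseSpec, PhantomSpec, add_noise, apply_motion,
                             assign_ground_truth, b1_field, default_tissues,
                             generate_cohort, make_geometry, simulate_afi,
                             simulate_echoes, simulate_subject)
from cordmpm.signal import flash_signal


# ----------------------------------------------------------------- geometry

def test_default_geometry_labels_every_voxel(quiet_spec):
    labels = make_geometry(quiet_spec)
    assert labels.shape == (64, 64, 30)
    present = set(np.unique(labels.data))
    for name in ("csf", "gm", "dorsal_wm", "left_lateral_wm",
                 "right_lateral_wm"):
        assert LABELS[name] in present


def test_cord_only_phantom_has_six_labels():
    spec = PhantomSpec(with_surround=False)
    labels = make_geometry(spec)
    assert set(np.unique(labels.data)) == set(range(6))


def test_lateral_columns_are_mirror_images(quiet_spec):
    labels = make_geometry(quiet_spec)
    n_left = int((labels.data == LABELS["left_lateral_wm"]).sum())
    n_right = int((labels.data == LABELS["right_lateral_wm"]).sum())
    assert n_left == n_right > 0
    # and the label image itself is symmetric under x-flip up to the swap
    flipped = labels.data[::-1]
    swap = flipped.copy()
    swap[flipped == LABELS["left_lateral_wm"]] = LABELS["right_lateral_wm"]
    swap[flipped == LABELS["right_lateral_wm"]] = LABELS["left_lateral_wm"]
    assert np.array_equal(swap, labels.data)


@pytest.mark.parametrize("bad", [dict(cord_radius_mm=0.0),
                                 dict(cord_radius_mm=-1.0),
                                 dict(csf_radius_mm=4.0)])
def test_inconsistent_radii_rejected(bad):
    with pytest.raises(GeometryError):
        PhantomSpec(**bad)


# ------------------------------------------------------------- ground truth

def test_ground_truth_tissue_values(quiet_subject):
    truth, labels = quiet_subject.truth, quiet_subject.labels.data
    dorsal = labels == LABELS["dorsal_wm"]
    gm = labels == LABELS["gm"]
    background = labels == LABELS["background"]
    assert np.all(truth.t1_ms[dorsal] == 1735.0)
    assert np.all(truth.mtsat_pu()[dorsal] == pytest.approx(1.43))
    assert np.all(truth.t1_ms[gm] == 1815.0)
    assert np.all(truth.r2star_s[gm] == 18.9)
    assert np.all(truth.apd[background] == 0.0)
    assert np.all(truth.delta[background] == 0.0)


def test_unknown_label_is_named_in_error(quiet_spec):
    labels = make_geometry(quiet_spec)
    labels.data[0, 0, 0] = 99
    with pytest.raises(ValueError, match="99"):
        assign_ground_truth(labels, default_tissues())


# ---------------------------------------------------------------- echo sims

def test_pdw_echo_spacing_and_count(quiet_subject):
    tes = np.array(quiet_subject.series["PDw"].acq.echo_times_ms)
    assert len(tes) == 6
    assert np.allclose(np.diff(tes), (18.55 - 3.0) / 5)


def test_echo_decay_matches_r2star(quiet_subject):
    series = quiet_subject.series["PDw"]
    dorsal = quiet_subject.labels.data == LABELS["dorsal_wm"]
    ratio = series.data[dorsal, 1] / series.data[dorsal, 0]
    expected = np.exp(-22.3e-3 * (18.55 - 3.0) / 5)
    assert np.allclose(ratio, expected)


def test_first_echo_is_flash_times_decay(quiet_spec, quiet_subject):
    acq = quiet_spec.acquisitions["PDw"]
    truth = quiet_subject.truth
    wm = quiet_subject.wm_mask
    s0 = flash_signal(truth.apd[wm], truth.t1_ms[wm], 0.0,
                      acq.flip_deg, acq.tr_ms)
    expected = s0 * np.exp(-truth.r2star_s[wm] * acq.echo_times_ms[0] / 1000)
    assert np.allclose(quiet_subject.series["PDw"].data[wm, 0], expected)


def test_signal_monotone_decreasing_along_echoes(quiet_subject):
    cord = quiet_subject.cord_mask
    data = quiet_subject.series["PDw"].data[cord]
    assert np.all(np.diff(data, axis=1) < 0)


def test_grid_mismatch_rejected(quiet_spec, quiet_subject):
    small = PhantomSpec(shape=(32, 32, 10), noise=NoiseSpec(model="none"),
                        motion={})
    b1_small = b1_field(small)
    with pytest.raises(ValueError):
        simulate_echoes(quiet_subject.truth, quiet_spec.acquisitions["PDw"],
                        b1=b1_small)


def test_afi_pair_follows_ratio_model(quiet_spec):
    b1 = b1_field(quiet_spec)
    s1, s2 = simulate_afi(b1, quiet_spec.afi)
    assert np.allclose(s2.data / np.where(s1.data == 0, 1, s1.data),
                       (1 + 3 * np.cos(np.deg2rad(60 * b1.data / 100)))
                       / (3 + np.cos(np.deg2rad(60 * b1.data / 100))))


def test_afi_requires_tr2_above_tr1():
    from cordmpm.phantom import AFIParams
    with pytest.raises(ValueError):
        AFIParams(tr1_ms=150.0, tr2_ms=50.0)


# -------------------------------------------------------------------- motion

def test_identity_motion_is_lossless(small_quiet_subject):
    series = small_quiet_subject.series["PDw"]
    out = apply_motion(series, RigidTransform(), interp="sinc")
    assert np.allclose(out.data, series.data, rtol=1e-6)


def test_integer_voxel_shift_nearest_is_exact(small_quiet_subject):
    series = small_quiet_subject.series["PDw"]
    out = apply_motion(series, RigidTransform(tx=1.0), interp="nearest")
    # pull sampling at +1 voxel in x: out[i] = in[i+1]
    assert np.array_equal(out.data[:-1], series.data[1:])


def test_motion_roundtrip_sinc_preserves_cord_intensities(small_quiet_subject):
    series = small_quiet_subject.series["PDw"]
    t = RigidTransform(tx=2.0)
    back = apply_motion(apply_motion(series, t), t.inverse())
    wm = small_quiet_subject.wm_mask
    rms = np.sqrt(np.mean((back.data[wm] - series.data[wm]) ** 2))
    assert rms < 0.01 * series.data[wm].mean()


# --------------------------------------------------------------------- noise

def test_noise_model_none_is_identity(quiet_subject):
    series = quiet_subject.series["PDw"]
    out = add_noise(series, snr=10, model="none")
    assert np.array_equal(out.data, series.data)


def test_noise_is_reproducible_under_fixed_seed(quiet_subject):
    series = quiet_subject.series["PDw"]
    a = add_noise(series, snr=20, model="rician", seed=5)
    b = add_noise(series, snr=20, model="rician", seed=5)
    assert np.array_equal(a.data, b.data)
    c = add_noise(series, snr=20, model="rician", seed=6)
    assert not np.array_equal(a.data, c.data)


def test_unknown_noise_model_rejected(quiet_subject):
    with pytest.raises(ValueError):
        add_noise(quiet_subject.series["PDw"], snr=20, model="poisson")


def test_rician_background_mean_is_sigma_sqrt_half_pi(quiet_spec):
    """|N + iN| on zero signal has mean sigma*sqrt(pi/2)."""
    acq = quiet_spec.acquisitions["PDw"]
    from cordmpm.core import EchoSeries
    data = np.zeros((30, 30, 20, 6))
    ref = np.zeros(data.shape[:3], dtype=bool)
    ref[:5] = True
    data[ref] = 100.0                      # reference region defines sigma
    series = EchoSeries(data, np.eye(4), acq)
    noisy = add_noise(series, snr=10.0, model="rician", seed=2,
                      reference_mask=ref)
    sigma = 10.0
    background = noisy.data[~ref]          # > 1e4 zero-signal draws
    assert background.mean() == pytest.approx(sigma * np.sqrt(np.pi / 2),
                                              rel=0.02)


# ------------------------------------------------------------------- cohorts

def test_simulation_is_bit_reproducible():
    spec = PhantomSpec(seed=11, shape=(32, 32, 12))
    a = simulate_subject(spec)
    b = simulate_subject(spec)
    for c in a.series:
        assert np.array_equal(a.series[c].data, b.series[c].data)
    assert np.array_equal(a.afi_pair[0].data, b.afi_pair[0].data)


def test_zero_cohort_variation_gives_identical_truths():
    spec = PhantomSpec(cohort_cv={}, seed=3)
    subjects, manifest = generate_cohort(spec, 4)
    t1s = manifest.query("tissue == 'dorsal_wm'")["T1_ms"].to_numpy()
    assert np.all(t1s == 1735.0)
    assert len(manifest) == 4 * (len(LABELS) - 1)   # all tissues, no background


def test_cohort_truth_draws_center_on_tissue_table():
    cv = 0.15 / 1.43                        # inter-subject SD 0.15 p.u. on WM MTsat
    spec = PhantomSpec(cohort_cv={"delta": cv}, seed=9,
                       noise=NoiseSpec(model="none"), motion={})
    _, manifest = generate_cohort(spec, 13)
    drawn = manifest.query("tissue == 'dorsal_wm'")["MTsat_pu"].to_numpy()
    assert len(drawn) == 13
    assert abs(drawn.mean() - 1.43) < 3 * 0.15 / np.sqrt(13)


def test_cohort_writes_niftis_sidecars_and_manifest(tmp_path):
    spec = PhantomSpec(seed=1, shape=(24, 24, 8))
    generate_cohort(spec, 2, tmp_path)
    for sub in ("sub-01", "sub-02"):
        for name in ("PDw", "T1w", "MTw"):
            assert (tmp_path / sub / f"{name}.nii").exists()
            assert (tmp_path / sub / f"{name}.json").exists()
        assert (tmp_path / sub / "AFI_tr1.nii").exists()
        assert (tmp_path / sub / "labels.nii").exists()
    assert (tmp_path / "truth_manifest.csv").exists()
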
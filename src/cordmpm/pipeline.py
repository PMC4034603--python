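"""Subject- and cohort-level orchestration with provenance.

``run_subject`` ties the stages together: co-registration of the three
FLASH contrasts, B1 mapping from the AFI pair, map estimation for the
full echo set and the odd/even half sets, and ROI statistics.  Every
output directory carries a provenance record with the configuration hash
and package version; runs are deterministic for a fixed configuration.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .b1 import (B1Map, afi_flip_angle, prepare_b1_for_correction,
                 register_afi_to_reference, to_percent_nominal)
from .core import EchoSeries, ParameterMaps, RigidTransform, Volume3D
from .fitting import estimate_all
from .phantom import CORD_LABELS, LABELS
from .registration import apply_to_echoes, average_echoes, \
    run_registration_pipeline
from .stats import ROISet, cohort_summary, paired_ttest, robustness_percent, \
    roi_summary

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "SubjectResult", "run_subject", "run_cohort",
           "default_rois", "load_subject_inputs"]

_PARAMS = ("APD", "T1", "MTsat", "MTR", "R2star")


@dataclass(frozen=True)
class RunConfig:
    """All options of one subject-level run (serialisable)."""

    input_dir: str
    output_dir: str
    echo_subsets: tuple[str, ...] = ("all", "odd", "even")
    registration: str = "full"          # "full" | "skip"
    reregister_mtw: bool = True
    b1_correct: bool = True
    b1_smoothing_fwhm_mm: float = 8.0
    mtr_reference: str = "matched"
    te_zero_correction: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["echo_subsets"] = list(self.echo_subsets)
        return d

    @property
    def config_hash(self) -> str:
        payload = {k: v for k, v in self.to_dict().items()
                   if k not in ("input_dir", "output_dir", "log_level")}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        if "echo_subsets" in raw:
            raw["echo_subsets"] = tuple(raw["echo_subsets"])
        return cls(**raw)


def default_rois(labels: Volume3D) -> ROISet:
    return ROISet(labels, {
        "cord_C1_C5": list(CORD_LABELS),
        "gm": LABELS["gm"],
        "dorsal_wm": LABELS["dorsal_wm"],
        "left_lateral_wm": LABELS["left_lateral_wm"],
        "right_lateral_wm": LABELS["right_lateral_wm"],
    })


def load_subject_inputs(sub_dir: str | Path) -> dict:
    """Load and validate one subject's input files.

    Expects PDw/T1w/MTw NIfTI volumes with JSON sidecars, the AFI pair
    with its sidecar, and (optionally) a label volume.  Raises a
    ``ValueError``/``FileNotFoundError`` naming the offending file or key
    before any computation starts.
    """
    sub_dir = Path(sub_dir)
    series = {}
    for contrast in ("PDw", "T1w", "MTw"):
        path = sub_dir / f"{contrast}.nii"
        if not path.exists():
            raise FileNotFoundError(f"missing input volume {path}")
        series[contrast] = EchoSeries.load(path)
    afi_json = sub_dir / "AFI.json"
    if not afi_json.exists():
        raise FileNotFoundError(f"missing AFI sidecar {afi_json}")
    afi_meta = json.loads(afi_json.read_text())
    for key in ("Nominal_B1_deg", "RepetitionTime1_ms", "RepetitionTime2_ms"):
        if key not in afi_meta:
            raise ValueError(f"{afi_json}: missing required sidecar key {key!r}")
    afi_pair = (Volume3D.load(sub_dir / "AFI_tr1.nii"),
                Volume3D.load(sub_dir / "AFI_tr2.nii"))
    labels = None
    labels_path = sub_dir / "labels.nii"
    if labels_path.exists():
        lab = Volume3D.load(labels_path)
        labels = Volume3D(np.rint(lab.data).astype(int), lab.affine)
    return {"series": series, "afi_pair": afi_pair, "afi_meta": afi_meta,
            "labels": labels}


@dataclass
class SubjectResult:
    maps: dict                      # subset -> ParameterMaps
    stats: pd.DataFrame
    robustness: pd.DataFrame
    transforms: dict
    b1: B1Map | None
    provenance: dict


def _compute_b1(inputs, reg_t1w_ref: Volume3D, config: RunConfig) -> B1Map:
    s1, s2 = inputs["afi_pair"]
    meta = inputs["afi_meta"]
    flip, valid = afi_flip_angle(s1, s2, meta["RepetitionTime1_ms"],
                                 meta["RepetitionTime2_ms"])
    b1 = to_percent_nominal(flip, meta["Nominal_B1_deg"], mask=valid)
    t = None
    if config.registration == "full":
        t = register_afi_to_reference(s1, reg_t1w_ref)
    return prepare_b1_for_correction(
        b1, reg_t1w_ref, t, smoothing_fwhm_mm=config.b1_smoothing_fwhm_mm)


def run_subject(config: RunConfig, subject: str | None = None) -> SubjectResult:
    """Execute register -> b1map -> fitmaps (all/odd/even) -> roistats."""
    logging.basicConfig(level=config.log_level)
    inputs = load_subject_inputs(config.input_dir)
    series = inputs["series"]
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subject = subject or Path(config.input_dir).name

    if config.registration == "full":
        pipe = run_registration_pipeline(series["PDw"], series["T1w"],
                                         series["MTw"],
                                         reregister_mtw=config.reregister_mtw)
        transforms = pipe.transforms
        reg_series = {c: apply_to_echoes(series[c], transforms[c])
                      for c in series}
        reg_t1w_ref = pipe.registered["T1w"]
    elif config.registration == "skip":
        transforms = {c: RigidTransform() for c in series}
        reg_series = series
        reg_t1w_ref = average_echoes(series["T1w"])
    else:
        raise ValueError(f"unknown registration mode {config.registration!r}")

    b1 = _compute_b1(inputs, reg_t1w_ref, config) if config.b1_correct else None

    maps = {}
    for subset in config.echo_subsets:
        maps[subset] = estimate_all(
            reg_series["PDw"], reg_series["T1w"], reg_series["MTw"], b1=b1,
            echo_subset=subset, te_zero_correction=config.te_zero_correction,
            mtr_reference=config.mtr_reference, b1_correct=config.b1_correct,
        )
        maps[subset].save(out_dir / "maps" / subset)

    stats = pd.DataFrame()
    robustness = pd.DataFrame()
    if inputs["labels"] is not None:
        rois = default_rois(inputs["labels"])
        stats = roi_summary(maps[config.echo_subsets[0]], rois, subject=subject)
        stats.to_csv(out_dir / "stats.csv", index=False)
        if "odd" in maps and "even" in maps:
            cord = rois.mask("cord_C1_C5")
            rows = []
            for p in _PARAMS:
                vals = {}
                for half in ("odd", "even"):
                    m = cord & maps[half].mask(p)
                    vals[half] = float(np.nanmean(maps[half][p][m]))
                rows.append({
                    "subject": subject, "parameter": p,
                    "odd_value": vals["odd"], "even_value": vals["even"],
                    "robustness_percent": robustness_percent(vals["odd"],
                                                             vals["even"]),
                })
            robustness = pd.DataFrame(rows)
            robustness.to_csv(out_dir / "robustness.csv", index=False)

    provenance = {
        "software": "cordmpm",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "subject": subject,
        "transforms": {c: t.to_dict() for c, t in transforms.items()},
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    (out_dir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    return SubjectResult(maps, stats, robustness, transforms, b1, provenance)


_TEST_PAIRS = (
    ("gm", "dorsal_wm"), ("gm", "left_lateral_wm"), ("gm", "right_lateral_wm"),
    ("left_lateral_wm", "right_lateral_wm"),
    ("dorsal_wm", "left_lateral_wm"), ("dorsal_wm", "right_lateral_wm"),
)


def run_cohort(configs: list[RunConfig], output_dir: str | Path) -> dict:
    """Run every subject and aggregate cohort statistics.

    A failing subject is logged and skipped; the cohort table carries on
    with the remaining subjects.  Writes ``subject_stats.csv``,
    ``cohort_stats.csv`` (means, SDs, CoV) and ``paired_tests.csv``
    (region-vs-region paired t-tests per parameter).
    """
    if len(configs) < 2:
        raise ValueError("a cohort needs at least two subjects")
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    all_stats, all_robust, failures = [], [], []
    for config in configs:
        sid = Path(config.input_dir).name
        try:
            result = run_subject(config, subject=sid)
        except Exception as exc:        # noqa: BLE001 - cohort must continue
            logger.error("subject %s failed: %s", sid, exc)
            failures.append({"subject": sid, "error": str(exc)})
            continue
        all_stats.append(result.stats)
        if not result.robustness.empty:
            all_robust.append(result.robustness)

    subject_stats = pd.concat(all_stats, ignore_index=True) if all_stats \
        else pd.DataFrame()
    cohort = cohort_summary(subject_stats) if not subject_stats.empty \
        else pd.DataFrame()

    tests = []
    n_ok = subject_stats["subject"].nunique() if not subject_stats.empty else 0
    if n_ok >= 3:
        wide = subject_stats.pivot_table(index="subject",
                                         columns=["region", "parameter"],
                                         values="mean")
        for region_a, region_b in _TEST_PAIRS:
            for p in _PARAMS:
                try:
                    a = wide[(region_a, p)].to_numpy()
                    b = wide[(region_b, p)].to_numpy()
                    t, df, pval = paired_ttest(a, b)
                except (KeyError, ValueError) as exc:
                    logger.warning("paired test %s vs %s (%s) skipped: %s",
                                   region_a, region_b, p, exc)
                    continue
                tests.append({"region_a": region_a, "region_b": region_b,
                              "parameter": p, "t": t, "df": df, "p": pval})
    else:
        logger.warning("paired t-tests skipped: only %d subjects "
                       "(insufficient degrees of freedom)", n_ok)
    paired = pd.DataFrame(tests)

    subject_stats.to_csv(output_dir / "subject_stats.csv", index=False)
    cohort.to_csv(output_dir / "cohort_stats.csv", index=False)
    paired.to_csv(output_dir / "paired_tests.csv", index=False)
    if all_robust:
        pd.concat(all_robust, ignore_index=True).to_csv(
            output_dir / "robustness.csv", index=False)
    if failures:
        pd.DataFrame(failures).to_csv(output_dir / "failures.csv", index=False)
    return {"subject_stats": subject_stats, "cohort_stats": cohort,
            "paired_tests": paired, "failures": failures}
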
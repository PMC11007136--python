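"""End-to-end study orchestration on synthetic cohorts.

``run_study`` reproduces the shape of a margin-validation study: a cohort
of phantoms, two simulated observers outlining each tumor on the imaging
volume (MR-DS analogues), a histology route (sectioning -> landmark
registration -> stacking) rebuilding the pathologist's tumor (HE-DS
analogue), the five-region partition and margin maps for every specimen,
per-case under/over 95HD between observer and histology tumors, and
cohort-level diagnostic accuracy of the observer calls against both the
conventional slice-based emulation and the HE-DS reference.

Everything is deterministic under the configured seed; per-case substreams
come from ``numpy.random.SeedSequence(seed, case_index)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .comparison import diagnostic_accuracy, under_over_95hd
from .margins import (
    NOT_ASSESSABLE,
    classify_regions,
    compute_margin_map,
    conventional_slice_margins,
)
from .partition import REGIONS, build_deep_cone, fit_mucosa_plane, partition_surface
from .phantom import generate_phantom, perturb_tumor_outline, random_phantom_config
from .registration import fit_similarity_transform, stack_sections
from .sectioning import simulate_sectioning
from .specimen import DigitalSpecimen, make_digital_specimen
from .volume import TUMOR, resample_labels

log = logging.getLogger("digispec.study")


@dataclass
class ObserverConfig:
    """A simulated outline observer.

    Positive ``bias_mm`` dilates the true tumor (overestimation — the
    dominant behaviour reported for radiologists), negative erodes.
    ``roughness_mm`` adds smooth spatially-correlated outline noise.
    """

    name: str = "R1"
    bias_mm: float = 1.5
    roughness_mm: float = 0.8


@dataclass
class SectioningConfig:
    enabled: bool = True
    mean_thickness_mm: float = 4.0
    spacing_jitter_mm: float = 1.0
    shrink_healthy: float = 1.0
    rupture: bool = False


@dataclass
class RunConfig:
    """Study-level configuration; all randomness flows from ``seed``."""

    n_phantoms: int = 9
    seed: int = 0
    spacing_mm: float = 0.3
    observers: List[ObserverConfig] = field(
        default_factory=lambda: [
            ObserverConfig("R1", 1.5, 0.8),
            ObserverConfig("R2", 1.0, 0.8),
        ]
    )
    sectioning: SectioningConfig = field(default_factory=SectioningConfig)
    threshold_mm: float = 5.0
    cone_half_angle_deg: float = 45.0
    percentile: float = 95.0
    output_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        obs = [ObserverConfig(**o) for o in raw.pop("observers", [])] or None
        sect = raw.pop("sectioning", None)
        cfg = cls(**raw)
        if obs:
            cfg.observers = obs
        if sect:
            cfg.sectioning = SectioningConfig(**sect)
        return cfg


def _run_case(config: RunConfig, case_index: int) -> dict:
    ss = np.random.SeedSequence([config.seed, case_index])
    sub = ss.generate_state(4)
    phantom = generate_phantom(random_phantom_config(int(sub[0]), config.spacing_mm))
    vol = phantom.volume
    support = phantom.specimen_support

    gt = make_digital_specimen(vol, role="ground-truth")
    plane = fit_mucosa_plane(gt)
    cone = build_deep_cone(gt, plane, half_angle_deg=config.cone_half_angle_deg)
    part = partition_surface(
        gt, cone, phantom.anterior_point_mm, phantom.posterior_point_mm,
        phantom.craniomedial_hint,
    )

    # histology reference tumor
    if config.sectioning.enabled:
        stack = simulate_sectioning(
            phantom,
            mean_thickness_mm=config.sectioning.mean_thickness_mm,
            spacing_jitter_mm=config.sectioning.spacing_jitter_mm,
            shrink_healthy=config.sectioning.shrink_healthy,
            rupture=config.sectioning.rupture,
            seed=int(sub[1]),
        )
        transforms = [
            fit_similarity_transform(s.landmarks_section_mm, s.landmarks_reference_mm)[0]
            for s in stack.sections
        ]
        he_vol = stack_sections(stack, transforms, stack.true_gap_spacings_mm)
        he_tumor = resample_labels(he_vol, vol).grid == TUMOR
        he_tumor &= support  # outer contour comes from the imaging volume
        if not he_tumor.any():
            raise RuntimeError("histology reconstruction lost the tumor")
    else:
        stack = None
        he_tumor = phantom.tumor_mask

    def region_report(tumor_mask, role, observer_id=""):
        ds = DigitalSpecimen(
            outer_surface=gt.outer_surface,
            tumor_mask=tumor_mask,
            mucosa_vertex_flags=gt.mucosa_vertex_flags,
            volume=vol,
            role=role,
            observer_id=observer_id,
        )
        mm = compute_margin_map(ds, threshold_mm=config.threshold_mm)
        return classify_regions(mm, part)

    he_report = region_report(he_tumor, "HE-DS", "pathologist")
    conv = conventional_slice_margins(
        vol,
        mean_thickness_mm=config.sectioning.mean_thickness_mm,
        threshold_mm=config.threshold_mm,
    )

    observers = {}
    for i, obs in enumerate(config.observers):
        mask = perturb_tumor_outline(
            phantom.tumor_mask,
            vol.spacing_mm,
            bias_mm=obs.bias_mm,
            roughness_mm=obs.roughness_mm,
            seed=int(sub[2]) + i,
            specimen_mask=support,
        )
        report = region_report(mask, "MR-DS", obs.name)
        cmp_he = under_over_95hd(
            he_tumor, mask, vol.spacing_mm, vol.origin_mm, percentile=config.percentile
        )
        cmp_truth = under_over_95hd(
            phantom.tumor_mask, mask, vol.spacing_mm, vol.origin_mm,
            percentile=config.percentile,
        )
        observers[obs.name] = {
            "margin_report": report,
            "u95hd_vs_he_mm": cmp_he.u95hd_mm,
            "o95hd_vs_he_mm": cmp_he.o95hd_mm,
            "u95hd_vs_truth_mm": cmp_truth.u95hd_mm,
            "o95hd_vs_truth_mm": cmp_truth.o95hd_mm,
        }

    return {
        "case": case_index,
        "truth_margins_mm": dict(phantom.truth_margins),
        "he_report": he_report,
        "conventional_report": conv,
        "observers": observers,
        "n_sections": len(stack) if stack is not None else None,
    }


@dataclass
class StudyReport:
    config: RunConfig
    cases: list
    failed_cases: list
    cohort_accuracy: dict                 # observer -> reference -> AccuracyReport
    n_region_slots: int

    def to_json(self) -> str:
        """Deterministic (byte-stable) JSON serialisation."""

        def enc(o):
            if isinstance(o, (np.floating, float)):
                return round(float(o), 6)
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, np.ndarray):
                return [enc(v) for v in o.tolist()]
            if hasattr(o, "as_dict"):
                return walk(o.as_dict())
            if hasattr(o, "__dataclass_fields__"):
                return walk(asdict(o))
            return o

        def walk(x):
            if isinstance(x, dict):
                return {k: walk(v) for k, v in sorted(x.items(), key=lambda kv: str(kv[0]))}
            if isinstance(x, (list, tuple)):
                return [walk(v) for v in x]
            return enc(x)

        payload = {
            "digispec_version": _version,
            "config": walk(asdict(self.config)),
            "n_region_slots": self.n_region_slots,
            "cases": walk(self.cases),
            "failed_cases": walk(self.failed_cases),
            "cohort_accuracy": walk(
                {
                    obs: {ref: rep.as_dict() for ref, rep in refs.items()}
                    for obs, refs in self.cohort_accuracy.items()
                }
            ),
        }
        return json.dumps(payload, sort_keys=True, indent=1)


def _paired_calls(test_reports, ref_reports) -> tuple:
    """Aligned binary call vectors over (case, region) slots, dropping
    slots either side could not assess."""
    t, r = [], []
    for tr, rr in zip(test_reports, ref_reports):
        for region in REGIONS:
            tc, rc = tr.calls[region], rr.calls[region]
            if NOT_ASSESSABLE in (tc, rc):
                log.warning("dropping not-assessable slot %s", region)
                continue
            t.append(tc == "inadequate")
            r.append(rc == "inadequate")
    return np.array(t), np.array(r)


def run_study(config: RunConfig) -> StudyReport:
    """Run the full cohort; failures abort the case, not the study."""
    cases, failed = [], []
    for i in range(config.n_phantoms):
        try:
            cases.append(_run_case(config, i))
        except Exception as exc:  # noqa: BLE001 - logged and reported
            log.exception("case %d failed", i)
            failed.append({"case": i, "error": f"{type(exc).__name__}: {exc}"})

    cohort = {}
    he_reports = [c["he_report"] for c in cases]
    conv_reports = [c["conventional_report"] for c in cases]
    for obs in config.observers:
        obs_reports = [c["observers"][obs.name]["margin_report"] for c in cases]
        cohort[obs.name] = {
            "he_ds": diagnostic_accuracy(*_paired_calls(obs_reports, he_reports)),
            "conventional": diagnostic_accuracy(*_paired_calls(obs_reports, conv_reports)),
        }
    # the histology 3D model itself, judged against conventional assessment
    cohort["HE-DS"] = {
        "conventional": diagnostic_accuracy(*_paired_calls(he_reports, conv_reports))
    }

    report = StudyReport(
        config=config,
        cases=cases,
        failed_cases=failed,
        cohort_accuracy=cohort,
        n_region_slots=len(cases) * len(REGIONS),
    )
    if config.output_dir:
        _write_outputs(report)
    return report


def _write_outputs(report: StudyReport) -> None:
    out = Path(report.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "study_report.json").write_text(report.to_json())
    rows = []
    for case in report.cases:
        for name, obs in case["observers"].items():
            rows.append(
                {
                    "case": case["case"],
                    "observer": name,
                    "u95hd_vs_he_mm": obs["u95hd_vs_he_mm"],
                    "o95hd_vs_he_mm": obs["o95hd_vs_he_mm"],
                    "u95hd_vs_truth_mm": obs["u95hd_vs_truth_mm"],
                    "o95hd_vs_truth_mm": obs["o95hd_vs_truth_mm"],
                }
            )
    pd.DataFrame(rows).to_csv(out / "per_case_95hd.csv", index=False)
    manifest = {
        "digispec_version": _version,
        "seed": report.config.seed,
        "config": asdict(report.config),
        "n_cases": len(report.cases),
        "n_failed": len(report.failed_cases),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
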
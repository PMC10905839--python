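"""Structured qualitative scoring of images, surface models and prints.

Scoring itself is observer-based (a trained clinician rates overall
quality 1-4 and marks each landmark/structure visible or not); this
module provides the validated data structures, JSON round-tripping, and
per-landmark visibility aggregation across cases.

The 11 deep grayscale structures are those reviewed on multiplanar
reformats of the reconstructed volume: nasal bone (Nb), anterior nasal
spine (AnS), body of hyoid (Hy), body of mentum (Me), aqueduct of
Sylvius (AoS), pituitary stalk (Ps), sphenobasilar synchondrosis (SBS),
optic nerves (OpN), internal auditory meatus (IAM), semicircular canals
(SCC) and the external ears (rated as one item).

The 23 superficial landmarks default to the standard facial
anthropometric set (9 midline points plus 7 bilateral pairs); any
23-name list may be substituted.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

INTERNAL_STRUCTURES = ("Nb", "AnS", "Hy", "Me", "AoS", "Ps", "SBS",
                       "OpN", "IAM", "SCC", "Ears")

_MIDLINE = ("glabella", "nasion", "pronasale", "subnasale",
            "labiale_superius", "stomion", "labiale_inferius",
            "sublabiale", "pogonion")
_BILATERAL = ("endocanthion", "exocanthion", "alare", "cheilion",
              "tragion", "zygion", "gonion")
SUPERFICIAL_LANDMARKS = _MIDLINE + tuple(
    f"{name}_{side}" for name in _BILATERAL for side in ("left", "right"))

STAGES = ("svr", "baseline_model", "refined_model", "printed_model")
QUALITY_LABELS = {1: "poor", 2: "moderate", 3: "good", 4: "excellent"}


@dataclass
class QualityReport:
    """One case/stage scoring record.

    ``overall_quality`` is ordinal 1-4; ``landmark_visibility`` maps all
    23 superficial landmark names to booleans and
    ``internal_structures`` all 11 structure codes to booleans;
    ``limitations`` holds free-text primary/secondary observations.
    """

    case_id: str
    stage: str
    overall_quality: int
    landmark_visibility: dict = field(default_factory=dict)
    internal_structures: dict = field(default_factory=dict)
    limitations: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")
        if self.overall_quality not in (1, 2, 3, 4):
            raise ValueError("overall_quality must be 1, 2, 3 or 4")
        if not self.landmark_visibility:
            self.landmark_visibility = {k: False for k in SUPERFICIAL_LANDMARKS}
        if not self.internal_structures:
            self.internal_structures = {k: False for k in INTERNAL_STRUCTURES}
        if len(self.landmark_visibility) != 23:
            raise ValueError("exactly 23 superficial landmarks required")
        if len(self.internal_structures) != 11:
            raise ValueError("exactly 11 internal structures required")
        for d in (self.landmark_visibility, self.internal_structures):
            for k, v in d.items():
                if not isinstance(v, bool):
                    raise ValueError(f"visibility of {k!r} must be boolean")
        self.limitations.setdefault("primary", "")
        self.limitations.setdefault("secondary", "")


def emit_quality_report(report: QualityReport, path) -> None:
    """Write a report as JSON plus a human-readable summary line."""
    payload = dict(case_id=report.case_id, stage=report.stage,
                   overall_quality=report.overall_quality,
                   overall_label=QUALITY_LABELS[report.overall_quality],
                   landmark_visibility=report.landmark_visibility,
                   internal_structures=report.internal_structures,
                   limitations=report.limitations)
    n_vis = sum(report.landmark_visibility.values())
    payload["summary"] = (f"case {report.case_id} [{report.stage}]: "
                          f"quality {report.overall_quality} "
                          f"({QUALITY_LABELS[report.overall_quality]}), "
                          f"{n_vis}/23 landmarks visible")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_quality_report(path) -> QualityReport:
    with open(path) as fh:
        d = json.load(fh)
    return QualityReport(case_id=d["case_id"], stage=d["stage"],
                         overall_quality=d["overall_quality"],
                         landmark_visibility=d["landmark_visibility"],
                         internal_structures=d["internal_structures"],
                         limitations=d.get("limitations", {}))


def aggregate_visibility(reports) -> dict:
    """Per-landmark visibility proportion (percent) across cases."""
    reports = list(reports)
    if not reports:
        return {}
    keys = reports[0].landmark_visibility.keys()
    counts = Counter()
    for r in reports:
        if r.landmark_visibility.keys() != keys:
            raise ValueError("reports use different landmark sets")
        for k, v in r.landmark_visibility.items():
            counts[k] += bool(v)
    n = len(reports)
    return {k: 100.0 * counts[k] / n for k in keys}


def aggregate_to_csv(reports, path) -> None:
    agg = aggregate_visibility(reports)
    with open(path, "w") as fh:
        fh.write("landmark,visible_percent\n")
        for k, v in agg.items():
            fh.write(f"{k},{v:.1f}\n")
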
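"""Dilution-series sensitivity analysis: detection limits and specificity.

Runs the full align -> pileup -> call chain on each sample of a simulated
serial dilution and reports, per tracked variant, the expected fraction at
every dilution point, whether it was called, and the resulting detection
limit. The limit is the smallest expected fraction of an unbroken run of
detections from the top of the series down — an isolated detection below a
miss does not lower the limit. Calls at untracked positions are tallied as
false positives across the whole series.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import pandas as pd

from .align import GapParams, align_reads, pileup
from .refmodel import Amplicon
from .simulate import DilutionSeries, PointMutationSpec
from .variants import CallerConfig, annotate_all, call_variants


@dataclass(frozen=True)
class DetectionPoint:
    expected_fraction: float
    detected: bool
    observed_frequency: float | None  # as a fraction, None when not called


@dataclass
class VariantSensitivity:
    label: str
    points: list[DetectionPoint]  # ordered by decreasing expected fraction
    detection_limit: float | None  # expected fraction at the limit, None if never

    @property
    def detected_at(self) -> list[float]:
        return [p.expected_fraction for p in self.points if p.detected]


@dataclass
class SensitivityReport:
    variants: dict[str, VariantSensitivity]
    false_positives: int  # calls at untracked positions over all samples
    n_samples: int
    n_reads_per_sample: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, vs in self.variants.items():
            for p in vs.points:
                rows.append(
                    {
                        "variant": label,
                        "expected_pct": round(100.0 * p.expected_fraction, 4),
                        "detected": p.detected,
                        "observed_pct": (
                            round(100.0 * p.observed_frequency, 4)
                            if p.observed_frequency is not None
                            else None
                        ),
                    }
                )
        return pd.DataFrame(rows, columns=["variant", "expected_pct", "detected", "observed_pct"])

    def to_json(self) -> str:
        return json.dumps(
            {
                "samples": self.n_samples,
                "reads_per_sample": self.n_reads_per_sample,
                "false_positives": self.false_positives,
                "variants": {
                    label: {
                        "detection_limit_pct": (
                            round(100.0 * vs.detection_limit, 4)
                            if vs.detection_limit is not None
                            else None
                        ),
                        "points": [
                            {
                                "expected_pct": round(100.0 * p.expected_fraction, 4),
                                "detected": p.detected,
                                "observed_pct": (
                                    round(100.0 * p.observed_frequency, 4)
                                    if p.observed_frequency is not None
                                    else None
                                ),
                            }
                            for p in vs.points
                        ],
                    }
                    for label, vs in self.variants.items()
                },
            },
            indent=2,
        )


def detection_limit(points) -> float | None:
    """Smallest expected fraction of the unbroken detected run from the top.

    ``points`` are (expected fraction, detected) pairs in any order; they are
    scanned from the largest fraction down and the scan stops at the first
    miss, so a detection below a miss never lowers the limit.
    """
    limit = None
    for frac, detected in sorted(points, key=lambda t: -t[0]):
        if not detected:
            break
        limit = frac
    return limit


def run_sensitivity(
    series: DilutionSeries,
    amplicon: Amplicon,
    tracked: dict[str, PointMutationSpec],
    caller_config: CallerConfig = CallerConfig(),
    gap_params: GapParams = GapParams(),
) -> SensitivityReport:
    """Align, pile up and call every dilution sample; grade tracked variants.

    ``tracked`` maps labels to the spiked substitutions; the per-sample
    expected fraction of each comes from the series' simulation truth. Any
    call at a position outside the tracked set counts as a false positive.
    """
    tracked_positions = {m.position for m in tracked.values()}
    per_variant_points: dict[str, list[tuple[float, bool, float | None]]] = {
        label: [] for label in tracked
    }
    false_positives = 0
    n_reads = 0
    for sample in series:
        n_reads = max(n_reads, len(sample.reads))
        alns, _ = align_reads(sample.reads, amplicon, params=gap_params)
        pile = pileup(alns, amplicon)
        calls = annotate_all(call_variants(pile, caller_config), amplicon)
        by_site = {(c.position, c.alt): c for c in calls}
        for label, mut in tracked.items():
            call = by_site.get((mut.position, mut.alt))
            expected = sample.expected.get(label, 0.0)
            per_variant_points[label].append(
                (expected, call is not None, call.frequency if call else None)
            )
        false_positives += sum(1 for c in calls if c.position not in tracked_positions)

    variants = {}
    for label, pts in per_variant_points.items():
        pts_sorted = sorted(pts, key=lambda t: -t[0])
        points = [DetectionPoint(f, d, obs) for f, d, obs in pts_sorted]
        variants[label] = VariantSensitivity(
            label, points, detection_limit([(f, d) for f, d, _ in pts])
        )
    return SensitivityReport(variants, false_positives, len(series), n_reads)
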
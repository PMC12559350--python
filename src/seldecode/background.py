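"""Control-run background subtraction.

An affinity selection is always accompanied by bead-only control runs: a
feature that shows up in both sample and control is carry-over or matrix
background, not a selected binder — *unless* it is much more intense in the
sample.  The rule, applied feature-by-feature: remove a sample feature iff a
control feature matches it within the m/z and retention-time tolerances AND
the sample/control intensity ratio is below ``max_intensity_ratio``
(defaults 5 ppm, 10 s, ratio 3).  MS2 scans linked to removed features are
removed with them, so downstream annotation never sees background spectra.

With several control runs, the rule fires if it fires against any of them.
A control intensity of zero gives an infinite ratio (feature kept).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import math

import numpy as np
import pandas as pd

from .spectra import Ms1Feature, Run

__all__ = ["FeatureMatch", "match_features", "subtract_background"]


@dataclass(frozen=True)
class FeatureMatch:
    """A sample feature paired with its nearest in-tolerance control feature."""

    sample_feature_id: str
    control_feature_id: str
    control_run_id: str
    delta_ppm: float
    delta_rt_s: float
    intensity_ratio: float  # sample / control; inf when control is 0


def match_features(
    sample: Run,
    control: Run,
    ppm_tol: float = 5.0,
    rt_tol_s: float = 10.0,
) -> list[FeatureMatch]:
    """Match each sample feature to its nearest-in-m/z control feature.

    A match requires both ``|delta m| / m_control <= ppm_tol * 1e-6`` and
    ``|delta rt| <= rt_tol_s`` (apex RTs).  At most one match per sample
    feature; nearest in m/z wins, RT distance breaks ties.
    """
    if ppm_tol <= 0 or rt_tol_s <= 0:
        raise ValueError("tolerances must be > 0")
    if not control.features:
        return []
    cmz = np.array([f.mz for f in control.features])
    crt = np.array([f.rt_apex for f in control.features])
    out: list[FeatureMatch] = []
    for f in sample.features:
        rel = np.abs(cmz - f.mz) / cmz
        drt = np.abs(crt - f.rt_apex)
        ok = np.flatnonzero((rel <= ppm_tol * 1e-6) & (drt <= rt_tol_s))
        if ok.size == 0:
            continue
        best = ok[np.lexsort((drt[ok], rel[ok]))[0]]
        ctrl = control.features[best]
        ratio = f.intensity / ctrl.intensity if ctrl.intensity > 0 else math.inf
        out.append(
            FeatureMatch(
                sample_feature_id=f.feature_id,
                control_feature_id=ctrl.feature_id,
                control_run_id=control.run_id,
                delta_ppm=float(rel[best] * 1e6),
                delta_rt_s=float(drt[best]),
                intensity_ratio=float(ratio),
            )
        )
    return out


def subtract_background(
    sample: Run,
    controls: Sequence[Run],
    ppm_tol: float = 5.0,
    rt_tol_s: float = 10.0,
    max_intensity_ratio: float = 3.0,
) -> tuple[Run, pd.DataFrame]:
    """Remove sample features (and their MS2 scans) present in control runs.

    A feature is removed iff it matches a feature in ANY control (see
    :func:`match_features`) with sample/control intensity ratio strictly
    below ``max_intensity_ratio``.  Everything else — features, their linked
    scans, unlinked scans, MS1 spectra — is preserved.  Returns the cleaned
    run and a removal log with one row per firing match.
    """
    if max_intensity_ratio <= 0:
        raise ValueError("max_intensity_ratio must be > 0")
    removed: dict[str, FeatureMatch] = {}
    for control in controls:
        for m in match_features(sample, control, ppm_tol, rt_tol_s):
            if m.intensity_ratio < max_intensity_ratio:
                removed.setdefault(m.sample_feature_id, m)

    kept_features: list[Ms1Feature] = []
    removed_scan_ids: set[str] = set()
    for f in sample.features:
        if f.feature_id in removed:
            removed_scan_ids.update(f.ms2_scan_ids)
        else:
            kept_features.append(replace(f, ms2_scan_ids=list(f.ms2_scan_ids)))

    cleaned = Run(
        run_id=sample.run_id,
        ms1_spectra=list(sample.ms1_spectra),
        scans=[s for s in sample.scans if s.scan_id not in removed_scan_ids],
        features=kept_features,
        polarity=sample.polarity,
        provenance={
            **sample.provenance,
            "background_subtraction": {
                "ppm_tol": ppm_tol,
                "rt_tol_s": rt_tol_s,
                "max_intensity_ratio": max_intensity_ratio,
                "controls": [c.run_id for c in controls],
                "n_features_removed": len(removed),
                "n_scans_removed": len(removed_scan_ids),
            },
        },
    )
    log = pd.DataFrame(
        [
            {
                "sample_feature_id": m.sample_feature_id,
                "control_run_id": m.control_run_id,
                "control_feature_id": m.control_feature_id,
                "delta_ppm": m.delta_ppm,
                "delta_rt_s": m.delta_rt_s,
                "intensity_ratio": m.intensity_ratio,
            }
            for m in removed.values()
        ],
        columns=[
            "sample_feature_id", "control_run_id", "control_feature_id",
            "delta_ppm", "delta_rt_s", "intensity_ratio",
        ],
    )
    return cleaned, log
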
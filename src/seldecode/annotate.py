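"""The decoding core: precursor matching, fragment counting, scan filtering.

The filter implements the central decoding rule of the self-encoded-library
workflow: an MS2 scan is kept for annotation only if (1) its precursor
neutral mass matches at least one library compound within the MS1 ppm
tolerance and (2) among its top-N most intense peaks at least
``min_matching_peaks`` match predicted fragment ions of such a candidate
within the MS2 ppm tolerance.  Everything else — and in a real selection
that is the overwhelming majority of ~80,000 scans — is discarded.

Isobaric candidates surviving the filter are ranked by a transparent
intensity-weighted fragment-coverage score: the fraction of considered-peak
intensity explained by predicted fragments, with the matched-fragment count
as an epsilon tie-nudge.  (The published workflow re-ranks candidates with a
fingerprint-based scorer; that machinery needs trained models and is out of
scope — the coverage score keeps ranking fully reproducible and testable.)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formula import ElementalFormula, adduct_mass
from .fragments import FragmentTypeSpec, parse_fragment_types, predict_fragments
from .library import COMPOUND_ID_SEP, EnumeratedLibrary
from .spectra import Ms2Scan, Run, top_n_peaks

__all__ = [
    "CometConfig",
    "MatchedPeak",
    "CandidateMatch",
    "Annotation",
    "ScanResult",
    "precursor_candidates",
    "count_fragment_matches",
    "comet_filter",
    "rank_candidates",
    "annotate_run",
    "merge_replicates",
]


@dataclass(frozen=True)
class CometConfig:
    """Decoder settings; defaults mirror the published workflow.

    ms1_ppm / ms2_ppm :
        Relative mass tolerances for precursor and fragment matching (5 ppm).
    rt_tol_s, max_intensity_ratio :
        Background-subtraction parameters (10 s, 3-fold), carried here so a
        single config object drives the whole pipeline.
    fragment_types :
        Grammar string, e.g. ``"S[0;1], S[1;2],0,2"``; empty string means
        "use the design's own".
    min_matching_peaks / n_considered_peaks :
        Keep a scan when >= ``min_matching_peaks`` of its ``n_considered_peaks``
        most intense peaks match predicted ions (1 of 5).
    hydrogen_shifts :
        Allowed +-H rearrangements per fragment type (1 -> shifts -1, 0, +1).
    """

    ms1_ppm: float = 5.0
    ms2_ppm: float = 5.0
    rt_tol_s: float = 10.0
    max_intensity_ratio: float = 3.0
    scaffold_formula: str | None = None
    fragment_types: str = ""
    min_matching_peaks: int = 1
    n_considered_peaks: int = 5
    hydrogen_shifts: int = 1
    adduct: str = "[M+H]+"

    def __post_init__(self) -> None:
        if self.ms1_ppm <= 0 or self.ms2_ppm <= 0:
            raise ValueError("ppm tolerances must be > 0")
        if self.min_matching_peaks < 1:
            raise ValueError("min_matching_peaks must be >= 1")
        if self.n_considered_peaks < self.min_matching_peaks:
            raise ValueError(
                "n_considered_peaks must be >= min_matching_peaks"
            )
        if self.hydrogen_shifts < 0:
            raise ValueError("hydrogen_shifts must be >= 0")
        adduct_mass(self.adduct)
        if self.scaffold_formula is not None:
            ElementalFormula.parse(self.scaffold_formula)


@dataclass(frozen=True)
class MatchedPeak:
    """One observed peak explained by one predicted fragment ion."""

    peak_mz: float
    peak_intensity: float
    fragment_type: str
    hydrogen_shift: int
    predicted_mz: float
    ppm_error: float


@dataclass(frozen=True)
class CandidateMatch:
    """A precursor-matching compound with its fragment-match evidence."""

    compound_index: int
    compound_id: str
    precursor_delta_ppm: float
    n_matched: int
    matched: tuple[MatchedPeak, ...] = ()


@dataclass(frozen=True)
class Annotation:
    """A ranked candidate annotation of one retained scan."""

    scan_id: str
    compound_id: str
    compound_index: int
    n_matched_fragments: int
    score: float
    rank: int
    accepted: bool
    precursor_delta_ppm: float
    matched: tuple[MatchedPeak, ...] = ()


@dataclass
class ScanResult:
    """A retained scan with all candidates that reached the peak threshold."""

    scan: Ms2Scan
    candidates: list[CandidateMatch] = field(default_factory=list)


def precursor_candidates(
    scan: Ms2Scan,
    library: EnumeratedLibrary,
    ms1_ppm: float = 5.0,
    adduct: str = "[M+H]+",
) -> list[tuple[int, float]]:
    """Library members whose mass matches the scan's precursor.

    The observed neutral mass is ``(precursor_mz - adduct_mass) * z``; a
    member matches when ``|obs - m| / m <= ms1_ppm * 1e-6`` with the library
    mass as reference.  Returns ``(member_index, delta_ppm)`` sorted by
    ``|delta_ppm|`` (ties by index for determinism).
    """
    shift, charge = adduct_mass(adduct)
    z = scan.precursor_charge or charge
    obs_neutral = (scan.precursor_mz - shift) * z
    if obs_neutral <= 0:
        return []
    idx = library.query_mass(obs_neutral, ms1_ppm)
    d_ppm = (obs_neutral - library.masses[idx]) / library.masses[idx] * 1e6
    order = np.lexsort((idx, np.abs(d_ppm)))
    return [(int(idx[i]), float(d_ppm[i])) for i in order]


def count_fragment_matches(
    scan: Ms2Scan,
    predicted: "PredictedFragmentListLike",
    ms2_ppm: float = 5.0,
    n_considered_peaks: int = 5,
) -> tuple[int, list[MatchedPeak]]:
    """Count considered peaks explained by predicted ions (greedy matching).

    Among the ``n_considered_peaks`` most intense peaks, every (peak, ion)
    pair within ``ms2_ppm`` of the *predicted* m/z is a candidate match;
    pairs are consumed greedily by ascending ``|delta ppm|``, each peak and
    each predicted ion at most once.  The count is the number of distinct
    matched peaks.
    """
    mzs, intens = top_n_peaks(scan, n_considered_peaks)
    frags = list(predicted.fragments)
    pairs: list[tuple[float, int, int]] = []
    t = ms2_ppm * 1e-6
    for pi, pmz in enumerate(mzs):
        for fi, frag in enumerate(frags):
            rel = abs(pmz - frag.mz) / frag.mz
            if rel <= t:
                pairs.append((rel, pi, fi))
    pairs.sort()
    used_peaks: set[int] = set()
    used_frags: set[int] = set()
    matched: list[MatchedPeak] = []
    for rel, pi, fi in pairs:
        if pi in used_peaks or fi in used_frags:
            continue
        used_peaks.add(pi)
        used_frags.add(fi)
        frag = frags[fi]
        matched.append(
            MatchedPeak(
                peak_mz=float(mzs[pi]),
                peak_intensity=float(intens[pi]),
                fragment_type=str(frag.fragment_type),
                hydrogen_shift=frag.hydrogen_shift,
                predicted_mz=frag.mz,
                ppm_error=float((mzs[pi] - frag.mz) / frag.mz * 1e6),
            )
        )
    matched.sort(key=lambda m: m.peak_mz)
    return len(matched), matched


class _FragmentCache:
    """Predicted fragment lists per compound index, computed on demand."""

    def __init__(
        self,
        library: EnumeratedLibrary,
        types: Sequence[FragmentTypeSpec],
        config: CometConfig,
    ):
        self.library = library
        self.types = types
        self.config = config
        design = library.design
        if config.scaffold_formula is not None:
            design = replace(
                design,
                scaffold_offset=ElementalFormula.parse(config.scaffold_formula),
            )
        self.design = design
        self._cache: dict[int, object] = {}

    def __call__(self, i: int):
        if i not in self._cache:
            self._cache[i] = predict_fragments(
                self.library.bb_formulas(i),
                self.design,
                self.types,
                hydrogen_shifts=self.config.hydrogen_shifts,
                adduct=self.config.adduct,
                compound_id=self.library.compound_id(i),
            )
        return self._cache[i]


def _resolve_types(
    library: EnumeratedLibrary, config: CometConfig
) -> list[FragmentTypeSpec]:
    spec = config.fragment_types or library.design.fragment_types
    return parse_fragment_types(spec, library.design.n_positions)


def comet_filter(
    run: Run,
    library: EnumeratedLibrary,
    config: CometConfig | None = None,
) -> tuple[list[ScanResult], dict]:
    """Apply the precursor + fragment filter to every MS2 scan of a run.

    A scan is retained iff at least one precursor-matching candidate reaches
    ``min_matching_peaks`` matched considered peaks.  Returns the retained
    scans with their candidate evidence, plus summary statistics
    (``n_scans``, ``n_retained``, ``retained_fraction``).
    """
    config = config or CometConfig()
    types = _resolve_types(library, config)
    cache = _FragmentCache(library, types, config)
    results: list[ScanResult] = []
    for scan in run.scans:
        cands = precursor_candidates(scan, library, config.ms1_ppm, config.adduct)
        hits: list[CandidateMatch] = []
        for idx, d_ppm in cands:
            n, matched = count_fragment_matches(
                scan, cache(idx), config.ms2_ppm, config.n_considered_peaks
            )
            if n >= config.min_matching_peaks:
                hits.append(
                    CandidateMatch(
                        compound_index=idx,
                        compound_id=library.compound_id(idx),
                        precursor_delta_ppm=d_ppm,
                        n_matched=n,
                        matched=tuple(matched),
                    )
                )
        if hits:
            results.append(ScanResult(scan=scan, candidates=hits))
    stats = {
        "n_scans": run.n_scans,
        "n_retained": len(results),
        "retained_fraction": len(results) / run.n_scans if run.n_scans else 0.0,
    }
    return results, stats


def rank_candidates(
    result: ScanResult, config: CometConfig | None = None
) -> list[Annotation]:
    """Rank a retained scan's candidates by intensity-weighted coverage.

    score = (sum of matched considered-peak intensities) /
    (sum of considered-peak intensities) + 1e-6 * n_matched, clipped to
    [0, 1].  Descending score; exact ties break by compound_id so the order
    is deterministic.  The rank-1 candidate is the accepted annotation.
    """
    config = config or CometConfig()
    if not result.candidates:
        raise ValueError("rank_candidates requires a non-empty candidate list")
    _, intens = top_n_peaks(result.scan, config.n_considered_peaks)
    total = float(intens.sum())
    scored: list[tuple[float, str, CandidateMatch]] = []
    for cand in result.candidates:
        covered = sum(m.peak_intensity for m in cand.matched)
        score = covered / total if total > 0 else 0.0
        score = min(1.0, max(0.0, score + 1e-6 * cand.n_matched))
        scored.append((score, cand.compound_id, cand))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [
        Annotation(
            scan_id=result.scan.scan_id,
            compound_id=cand.compound_id,
            compound_index=cand.compound_index,
            n_matched_fragments=cand.n_matched,
            score=score,
            rank=r + 1,
            accepted=(r == 0),
            precursor_delta_ppm=cand.precursor_delta_ppm,
            matched=cand.matched,
        )
        for r, (score, _, cand) in enumerate(scored)
    ]


def annotate_run(
    run: Run,
    library: EnumeratedLibrary,
    config: CometConfig | None = None,
) -> pd.DataFrame:
    """Filter and rank a whole run; return the annotation table.

    One row per (retained scan, candidate); ``accepted`` marks the rank-1
    candidate of each scan.  Columns: scan_id, rt_s, precursor_mz,
    compound_id, bb1..bbP, n_matched, score, rank, accepted.
    """
    config = config or CometConfig()
    results, stats = comet_filter(run, library, config)
    rows = []
    for res in results:
        for ann in rank_candidates(res, config):
            bbs = ann.compound_id.split(COMPOUND_ID_SEP)
            row = {
                "scan_id": ann.scan_id,
                "rt_s": res.scan.rt,
                "precursor_mz": res.scan.precursor_mz,
                "compound_id": ann.compound_id,
            }
            for p, bb in enumerate(bbs):
                row[f"bb{p + 1}"] = bb
            row.update(
                n_matched=ann.n_matched_fragments,
                score=ann.score,
                rank=ann.rank,
                accepted=ann.accepted,
                precursor_delta_ppm=ann.precursor_delta_ppm,
            )
            rows.append(row)
    cols = ["scan_id", "rt_s", "precursor_mz", "compound_id"]
    cols += [f"bb{p + 1}" for p in range(library.design.n_positions)]
    cols += ["n_matched", "score", "rank", "accepted", "precursor_delta_ppm"]
    df = pd.DataFrame(rows, columns=cols)
    df.attrs["filter_stats"] = stats
    return df


def merge_replicates(
    annotations: Mapping[str, pd.DataFrame], mode: str = "union"
) -> tuple[pd.DataFrame, dict]:
    """Combine accepted annotations across replicate runs.

    ``union`` keeps every compound accepted in any run; ``intersection``
    keeps only compounds accepted in all runs.  The hit table carries
    ``runs_observed`` (;-joined run ids) and ``n_runs``; the stats dict
    reports pairwise Jaccard overlaps of the accepted compound sets.
    """
    if not annotations:
        raise ValueError("merge_replicates needs at least one run")
    if mode not in ("union", "intersection"):
        raise ValueError(f"unknown merge mode {mode!r}")
    accepted: dict[str, set[str]] = {
        run_id: set(df.loc[df["accepted"], "compound_id"])
        for run_id, df in annotations.items()
    }
    run_ids = list(annotations)
    keep: set[str] = set.union(*accepted.values()) if mode == "union" else (
        set.intersection(*accepted.values())
    )
    rows = []
    for cid in sorted(keep):
        present = [r for r in run_ids if cid in accepted[r]]
        evidence = pd.concat(
            [
                annotations[r].loc[
                    annotations[r]["accepted"]
                    & (annotations[r]["compound_id"] == cid)
                ]
                for r in present
            ]
        )
        best = evidence.sort_values("score", ascending=False).iloc[0]
        row = {c: best[c] for c in evidence.columns}
        row["runs_observed"] = ";".join(present)
        row["n_runs"] = len(present)
        rows.append(row)
    merged = pd.DataFrame(rows)
    jaccard = {}
    for i, a in enumerate(run_ids):
        for b in run_ids[i + 1:]:
            u = accepted[a] | accepted[b]
            jaccard[(a, b)] = len(accepted[a] & accepted[b]) / len(u) if u else 1.0
    stats = {
        "mode": mode,
        "n_compounds": len(keep),
        "per_run_accepted": {r: len(s) for r, s in accepted.items()},
        "jaccard": jaccard,
    }
    return merged, stats
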
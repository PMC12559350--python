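"""Fragment-type grammar, predicted fragment lists, fragmentation frequencies.

Self-encoded libraries are decoded from their MS/MS spectra alone, so the
decoder needs to know *which* bonds of a scaffold break under collision.
Instead of simulating fragmentation chemistry, the workflow encodes the
empirically recurring fragmentation modes of a scaffold in a tiny grammar:

``S[i;j]``
    a contiguous span of positions i..j **plus** the scaffold offset formula
    (core-containing fragment); ``S[1:2]`` is accepted as an alias.
``k``
    the building block at position k alone, without the offset.

Each fragment type yields ``2H + 1`` ions for the allowed hydrogen shifts
h in {-H..+H} (one-hydrogen rearrangements are ubiquitous in small-molecule
CID), ionised with the configured adduct.  Fragment types whose formula goes
negative for a particular compound are skipped with a warning.

Fragmentation frequencies — the fraction of annotated spectra of known
compounds in which a fragment type is actually observed — are what turns the
grammar into scaffold-specific rules: types observed frequently in a test
(mini-)library are kept for decoding.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .formula import ElementalFormula, HYDROGEN_MASS, adduct_mass
from .library import ScaffoldDesign

__all__ = [
    "FragmentTypeSpec",
    "FragmentSpecError",
    "parse_fragment_types",
    "PredictedFragment",
    "PredictedFragmentList",
    "predict_fragments",
    "FragmentationProfile",
    "estimate_fragmentation_frequencies",
]


class FragmentSpecError(ValueError):
    """Malformed fragment-type grammar string."""


@dataclass(frozen=True)
class FragmentTypeSpec:
    """One fragment type: a position span with or without the scaffold core."""

    kind: str  # "span_with_scaffold" | "single_position"
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in ("span_with_scaffold", "single_position"):
            raise FragmentSpecError(f"unknown fragment kind {self.kind!r}")
        if self.start < 0 or self.start > self.end:
            raise FragmentSpecError(
                f"invalid span [{self.start};{self.end}] (need 0 <= start <= end)"
            )
        if self.kind == "single_position" and self.start != self.end:
            raise FragmentSpecError("single_position must have start == end")

    def __str__(self) -> str:
        if self.kind == "single_position":
            return str(self.start)
        return f"S[{self.start};{self.end}]"

    @property
    def positions(self) -> range:
        return range(self.start, self.end + 1)


_SPAN = re.compile(r"^S\[(\d+)[;:](\d+)\]$")
_SINGLE = re.compile(r"^(\d+)$")


def parse_fragment_types(
    spec: str, n_positions: int | None = None
) -> list[FragmentTypeSpec]:
    """Parse a comma-separated grammar string into fragment types.

    ``"S[0;1], S[1;2],0,2"`` -> span(0,1)+core, span(1,2)+core, single(0),
    single(2).  The colon variant ``S[1:2]`` is accepted.  An empty string
    yields an empty list.  If ``n_positions`` is given, positions are bounds-
    checked against the design arity.
    """
    out: list[FragmentTypeSpec] = []
    for raw in (spec or "").split(","):
        token = raw.strip()
        if not token:
            if raw == "" and not out and spec.strip() == "":
                continue  # wholly empty spec
            if spec.strip() == "":
                continue
            raise FragmentSpecError(f"empty token in fragment spec {spec!r}")
        m = _SPAN.match(token)
        if m:
            ft = FragmentTypeSpec(
                "span_with_scaffold", int(m.group(1)), int(m.group(2))
            )
        else:
            m = _SINGLE.match(token)
            if not m:
                raise FragmentSpecError(
                    f"cannot parse fragment-type token {token!r} "
                    f"(expected 'S[i;j]' or a bare position integer)"
                )
            k = int(m.group(1))
            ft = FragmentTypeSpec("single_position", k, k)
        if n_positions is not None and ft.end >= n_positions:
            raise FragmentSpecError(
                f"fragment type {token!r} references position {ft.end} "
                f"but the design has only {n_positions} positions"
            )
        out.append(ft)
    return out


@dataclass(frozen=True)
class PredictedFragment:
    """One predicted fragment ion of one compound."""

    fragment_type: FragmentTypeSpec
    hydrogen_shift: int
    neutral_formula: ElementalFormula
    mz: float


class PredictedFragmentList:
    """Predicted ions of a single compound, sorted by m/z.

    ``mzs`` is the deduplicated (within 1e-6 Da) ascending ion m/z array used
    for peak matching; ``fragments`` keeps the full per-type records.
    """

    def __init__(self, compound_id: str, fragments: Sequence[PredictedFragment]):
        self.compound_id = compound_id
        self.fragments = sorted(fragments, key=lambda f: f.mz)
        mzs = np.array([f.mz for f in self.fragments], dtype=float)
        if mzs.size:
            keep = np.concatenate(([True], np.diff(mzs) > 1e-6))
            mzs = mzs[keep]
        self.mzs = mzs

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": self.compound_id,
                "fragment_type": [str(f.fragment_type) for f in self.fragments],
                "h_shift": [f.hydrogen_shift for f in self.fragments],
                "formula": [f.neutral_formula.hill for f in self.fragments],
                "mz": [f.mz for f in self.fragments],
            }
        )


def predict_fragments(
    bb_formulas: Sequence[ElementalFormula],
    design: ScaffoldDesign,
    types: Sequence[FragmentTypeSpec],
    hydrogen_shifts: int = 1,
    adduct: str | None = None,
    compound_id: str = "",
) -> PredictedFragmentList:
    """Predict the fragment ions of one compound.

    Parameters
    ----------
    bb_formulas :
        Per-position contribution formulas of the compound (length = design
        arity).
    types :
        Parsed fragment types; each contributes ``2 * hydrogen_shifts + 1``
        ions at ``neutral_mass + h * m(H) + adduct_mass``.
    hydrogen_shifts :
        Maximum absolute hydrogen rearrangement H; shifts run -H..+H.

    A fragment whose neutral formula has a negative element count cannot
    exist and is skipped with a warning.
    """
    if len(bb_formulas) != design.n_positions:
        raise ValueError(
            f"compound has {len(bb_formulas)} positions, design "
            f"{design.design_id!r} expects {design.n_positions}"
        )
    if hydrogen_shifts < 0:
        raise ValueError("hydrogen_shifts must be >= 0")
    shift_mass, charge = adduct_mass(adduct or design.adduct)

    frags: list[PredictedFragment] = []
    for ft in types:
        if ft.end >= design.n_positions:
            raise FragmentSpecError(
                f"fragment type {ft} out of range for design {design.design_id!r}"
            )
        neutral = ElementalFormula()
        for p in ft.positions:
            neutral = neutral + bb_formulas[p]
        if ft.kind == "span_with_scaffold":
            neutral = neutral + design.scaffold_offset
        if not neutral.is_nonnegative:
            warnings.warn(
                f"fragment {ft} of compound {compound_id or '<unnamed>'} has a "
                f"negative atom count ({neutral.hill}); skipped",
                stacklevel=2,
            )
            continue
        base = neutral.mass
        for h in range(-hydrogen_shifts, hydrogen_shifts + 1):
            mz = (base + h * HYDROGEN_MASS + shift_mass) / charge
            frags.append(PredictedFragment(ft, h, neutral, mz))
    return PredictedFragmentList(compound_id, frags)


@dataclass(frozen=True)
class FragmentationProfile:
    """Observed per-type fragmentation frequencies over annotated spectra."""

    counts: dict[str, int]  # str(fragment type) -> spectra with >=1 match
    n_spectra: int

    @property
    def frequencies(self) -> dict[str, float]:
        return {t: c / self.n_spectra for t, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fragment_type": list(self.counts),
                "n_matched": list(self.counts.values()),
                "n_spectra": self.n_spectra,
                "frequency": [
                    c / self.n_spectra for c in self.counts.values()
                ],
            }
        )


def estimate_fragmentation_frequencies(
    annotated: Iterable[tuple["Ms2Scan", Sequence[ElementalFormula]]],
    design: ScaffoldDesign,
    types: Sequence[FragmentTypeSpec],
    ppm: float = 5.0,
    hydrogen_shifts: int = 1,
    adduct: str | None = None,
) -> FragmentationProfile:
    """Fraction of known-compound spectra in which each fragment type appears.

    ``annotated`` pairs each MS2 scan with the per-position contribution
    formulas of its *true* compound.  A type counts as observed in a spectrum
    when at least one peak lies within ``ppm`` (relative to the predicted
    m/z) of any of its hydrogen-shift variants.  Deterministic.
    """
    counts = {str(ft): 0 for ft in types}
    n = 0
    t = ppm * 1e-6
    for scan, bb_formulas in annotated:
        n += 1
        pred = predict_fragments(
            bb_formulas, design, types, hydrogen_shifts, adduct
        )
        mz_obs = np.asarray(scan.mz, dtype=float)
        for ft in types:
            ions = [f.mz for f in pred.fragments if f.fragment_type == ft]
            hit = False
            for ion in ions:
                if mz_obs.size and np.min(np.abs(mz_obs - ion)) <= ion * t:
                    hit = True
                    break
            if hit:
                counts[str(ft)] += 1
    if n == 0:
        raise ValueError("no annotated spectra supplied")
    return FragmentationProfile(counts=counts, n_spectra=n)
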
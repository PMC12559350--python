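"""Combinatorial library model: building blocks, scaffold designs, enumeration.

A self-encoded library (SEL) is the cross product of one building-block (BB)
set per scaffold position.  Each BB carries a *contribution formula* — the
atoms it adds to the assembled molecule with condensation losses (e.g. -H2O
per amide bond) already applied — and the scaffold may add a constant
``scaffold_offset`` formula (terminal atoms, or a heterocyclic core).  A
library member's formula is then a pure sum, and its monoisotopic mass is the
sum of contribution masses plus the offset mass.

The enumeration is array-backed: per-member BB indices and masses live in
numpy arrays, and :class:`LibraryCompound` records are materialised lazily.
This keeps a half-million-member library at a few MB and makes ppm-window
precursor queries a pair of ``searchsorted`` calls.  Libraries too large to
materialise (the billion-member virtual catalog used for BB selection) are
scored position-wise through :func:`rank_building_blocks_streaming`.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .formula import ElementalFormula, adduct_mass

__all__ = [
    "BuildingBlock",
    "ScaffoldDesign",
    "LibraryCompound",
    "EnumeratedLibrary",
    "LibraryConfigError",
    "enumerate_library",
    "LipinskiDescriptors",
    "LipinskiThresholds",
    "RULE_OF_FIVE",
    "lipinski_points",
    "descriptors_from_smiles",
    "BbScore",
    "rank_building_blocks",
    "rank_building_blocks_streaming",
    "DegeneracyStats",
    "mass_degeneracy",
    "read_bb_table",
    "write_bb_table",
    "COMPOUND_ID_SEP",
]

#: Separator used to build a compound id from its BB ids.
COMPOUND_ID_SEP = "|"


class LibraryConfigError(ValueError):
    """Inconsistent library configuration (duplicate ids, empty positions...)."""


@dataclass(frozen=True)
class BuildingBlock:
    """One monomer at one scaffold position.

    ``formula`` is the *contribution* formula: the atoms this BB adds to the
    assembled molecule after condensation (so for an amino acid in an amide
    scaffold it is the residue formula, e.g. glycine -> C2H3NO).
    """

    bb_id: str
    position: int
    formula: ElementalFormula
    name: str = ""
    smiles: str | None = None

    def __post_init__(self) -> None:
        if self.position < 0:
            raise LibraryConfigError(f"negative position for BB {self.bb_id!r}")
        if not self.formula.is_nonnegative or self.formula.mass <= 0:
            raise LibraryConfigError(
                f"BB {self.bb_id!r} contribution formula must have positive mass"
            )


@dataclass(frozen=True)
class ScaffoldDesign:
    """A scaffold: number of positions, offset formula, fragment grammar.

    ``scaffold_offset`` carries atoms not belonging to any BB (terminal H /
    NH2 of an amide scaffold, or a heterocyclic core such as C8H3N2O for a
    trisubstituted benzimidazole).  ``fragment_types`` is the fragment-type
    grammar string, e.g. ``"S[0;1], S[1;2],0,2"`` (see
    :mod:`seldecode.fragments`).
    """

    design_id: str
    n_positions: int
    scaffold_offset: ElementalFormula = field(default_factory=ElementalFormula)
    fragment_types: str = ""
    adduct: str = "[M+H]+"

    def __post_init__(self) -> None:
        if self.n_positions < 2:
            raise LibraryConfigError("a combinatorial design needs >= 2 positions")
        adduct_mass(self.adduct)  # validate early


@dataclass(frozen=True)
class LibraryCompound:
    """A fully assembled library member."""

    bb_ids: tuple[str, ...]
    full_formula: ElementalFormula
    monoisotopic_mass: float
    compound_id: str
    smiles: str | None = None


class EnumeratedLibrary:
    """Cross-product enumeration of a :class:`ScaffoldDesign`.

    Members are indexed 0..n-1 in C order of the BB cross product (last
    position fastest).  ``masses[i]`` is the neutral monoisotopic mass of
    member *i*; ``bb_index[i, p]`` is the index of its BB at position *p*
    within ``bb_sets[p]``.
    """

    def __init__(
        self,
        design: ScaffoldDesign,
        bb_sets: Sequence[Sequence[BuildingBlock]],
        bb_index: np.ndarray,
        masses: np.ndarray,
    ):
        self.design = design
        self.bb_sets = [list(s) for s in bb_sets]
        self.bb_index = bb_index
        self.masses = masses
        self._order = np.argsort(masses, kind="stable")
        self._sorted_masses = masses[self._order]

    # -- basic container behaviour ------------------------------------------

    def __len__(self) -> int:
        return int(self.masses.shape[0])

    @property
    def n_positions(self) -> int:
        return self.design.n_positions

    def bb_ids(self, i: int) -> tuple[str, ...]:
        return tuple(
            self.bb_sets[p][self.bb_index[i, p]].bb_id
            for p in range(self.n_positions)
        )

    def compound_id(self, i: int) -> str:
        return COMPOUND_ID_SEP.join(self.bb_ids(i))

    def bb_formulas(self, i: int) -> tuple[ElementalFormula, ...]:
        """Per-position contribution formulas of member *i*."""
        return tuple(
            self.bb_sets[p][self.bb_index[i, p]].formula
            for p in range(self.n_positions)
        )

    def formula(self, i: int) -> ElementalFormula:
        total = self.design.scaffold_offset
        for f in self.bb_formulas(i):
            total = total + f
        return total

    def compound(self, i: int) -> LibraryCompound:
        return LibraryCompound(
            bb_ids=self.bb_ids(i),
            full_formula=self.formula(i),
            monoisotopic_mass=float(self.masses[i]),
            compound_id=self.compound_id(i),
        )

    def __iter__(self) -> Iterator[LibraryCompound]:
        return (self.compound(i) for i in range(len(self)))

    def index_of(self, compound_id: str) -> int:
        """Member index for a compound id (O(n); intended for small lookups)."""
        target = tuple(compound_id.split(COMPOUND_ID_SEP))
        maps = [
            {bb.bb_id: j for j, bb in enumerate(s)} for s in self.bb_sets
        ]
        try:
            idx = [maps[p][target[p]] for p in range(self.n_positions)]
        except (KeyError, IndexError):
            raise KeyError(f"compound id {compound_id!r} not in library") from None
        sizes = [len(s) for s in self.bb_sets]
        flat = 0
        for p in range(self.n_positions):
            flat = flat * sizes[p] + idx[p]
        return flat

    # -- mass-window queries -------------------------------------------------

    def query_mass(self, neutral_mass: float, ppm: float) -> np.ndarray:
        """Member indices with ``|m_i - neutral_mass| / m_i <= ppm * 1e-6``.

        The ppm window is referenced to the *library* (theoretical) mass, so
        the observed mass must fall in ``[m/(1+t), m/(1-t)]`` inverted: we
        search the sorted masses in ``[obs/(1+t), obs/(1-t)]`` and post-filter
        exactly.
        """
        t = ppm * 1e-6
        lo = neutral_mass / (1.0 + t)
        hi = neutral_mass / (1.0 - t)
        a = int(np.searchsorted(self._sorted_masses, lo, side="left"))
        b = int(np.searchsorted(self._sorted_masses, hi, side="right"))
        cand = self._order[a:b]
        m = self.masses[cand]
        keep = np.abs(m - neutral_mass) / m <= t
        return cand[keep]

    # -- export ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """TSV-ready table: compound_id, bb1..bbP, formula, monoisotopic_mass."""
        n, p = len(self), self.n_positions
        cols: dict[str, object] = {}
        id_arrays = []
        for pos in range(p):
            ids = np.array([bb.bb_id for bb in self.bb_sets[pos]], dtype=object)
            id_arrays.append(ids[self.bb_index[:, pos]])
        sep = COMPOUND_ID_SEP
        cols["compound_id"] = [
            sep.join(row) for row in zip(*id_arrays)
        ] if n else []
        for pos in range(p):
            cols[f"bb{pos + 1}"] = id_arrays[pos]
        cols["formula"] = [self.formula(i).hill for i in range(n)]
        cols["monoisotopic_mass"] = self.masses
        return pd.DataFrame(cols)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def enumerate_library(
    design: ScaffoldDesign, bb_sets: Sequence[Sequence[BuildingBlock]]
) -> EnumeratedLibrary:
    """Enumerate the full cross product of ``bb_sets`` under ``design``.

    The member count is exactly the product of the per-position set sizes
    (e.g. 62 x 62 x 130 = 499,720 for a three-position amide scaffold).
    Masses are computed by broadcast outer sums, so a half-million-member
    library enumerates in well under a second.
    """
    if len(bb_sets) != design.n_positions:
        raise LibraryConfigError(
            f"design {design.design_id!r} has {design.n_positions} positions "
            f"but {len(bb_sets)} BB sets were given"
        )
    for p, s in enumerate(bb_sets):
        if len(s) == 0:
            raise LibraryConfigError(f"position {p} has no building blocks")
        ids = [bb.bb_id for bb in s]
        dup = [i for i, c in Counter(ids).items() if c > 1]
        if dup:
            raise LibraryConfigError(f"duplicate bb_id at position {p}: {dup}")
        bad = [bb.bb_id for bb in s if bb.position != p]
        if bad:
            raise LibraryConfigError(
                f"BBs {bad} declare a different position than {p}"
            )

    sizes = [len(s) for s in bb_sets]
    pos_masses = [
        np.array([bb.formula.mass for bb in s], dtype=float) for s in bb_sets
    ]
    total = pos_masses[0]
    for pm in pos_masses[1:]:
        total = np.add.outer(total, pm)
    masses = total.ravel() + design.scaffold_offset.mass

    grids = np.meshgrid(*[np.arange(k) for k in sizes], indexing="ij")
    bb_index = np.stack([g.ravel() for g in grids], axis=1).astype(np.int32)
    return EnumeratedLibrary(design, bb_sets, bb_index, masses)


# ---------------------------------------------------------------------------
# Lipinski scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LipinskiDescriptors:
    """The five drug-likeness descriptors used to score virtual members."""

    mw: float
    logp: float
    hbd: int
    hba: int
    tpsa: float

    def __post_init__(self) -> None:
        if self.hbd < 0 or self.hba < 0 or self.tpsa < 0:
            raise ValueError("HBD/HBA counts and TPSA must be non-negative")


@dataclass(frozen=True)
class LipinskiThresholds:
    """Upper bounds; one point is awarded per satisfied bound."""

    mw: float = 500.0
    logp: float = 5.0
    hbd: int = 5
    hba: int = 10
    tpsa: float = 140.0


#: Classical rule-of-five bounds plus the common TPSA <= 140 A^2 criterion.
RULE_OF_FIVE = LipinskiThresholds()


def lipinski_points(
    d: LipinskiDescriptors, thresholds: LipinskiThresholds = RULE_OF_FIVE
) -> int:
    """Number of satisfied drug-likeness bounds, 0..5."""
    return (
        int(d.mw <= thresholds.mw)
        + int(d.logp <= thresholds.logp)
        + int(d.hbd <= thresholds.hbd)
        + int(d.hba <= thresholds.hba)
        + int(d.tpsa <= thresholds.tpsa)
    )


def descriptors_from_smiles(smiles: str) -> LipinskiDescriptors:
    """Compute descriptors with RDKit (optional dependency)."""
    try:
        from rdkit import Chem
        from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors
    except ImportError as exc:  # pragma: no cover - env without rdkit
        raise ImportError(
            "rdkit is required for SMILES-based descriptors; install the "
            "'chem' extra or supply descriptors in the BB table"
        ) from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES {smiles!r}")
    return LipinskiDescriptors(
        mw=Descriptors.ExactMolWt(mol),
        logp=Crippen.MolLogP(mol),
        hbd=Lipinski.NumHDonors(mol),
        hba=Lipinski.NumHAcceptors(mol),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
    )


# ---------------------------------------------------------------------------
# Building-block ranking
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BbScore:
    """Aggregate drug-likeness score of one BB over all members containing it."""

    bb_id: str
    position: int
    total_points: float
    mean_points: float
    n_members: int
    rank: int


def _rank_from_sums(
    bb_sets: Sequence[Sequence[BuildingBlock]],
    sums: Sequence[np.ndarray],
    counts: Sequence[np.ndarray],
) -> list[list[BbScore]]:
    out: list[list[BbScore]] = []
    for p, s in enumerate(bb_sets):
        means = np.where(counts[p] > 0, sums[p] / np.maximum(counts[p], 1), 0.0)
        # descending mean, ties broken by bb_id (stable lexicographic)
        order = sorted(
            range(len(s)), key=lambda j: (-means[j], s[j].bb_id)
        )
        out.append(
            [
                BbScore(
                    bb_id=s[j].bb_id,
                    position=p,
                    total_points=float(sums[p][j]),
                    mean_points=float(means[j]),
                    n_members=int(counts[p][j]),
                    rank=r + 1,
                )
                for r, j in enumerate(order)
            ]
        )
    return out


def rank_building_blocks(
    library: EnumeratedLibrary, points: np.ndarray
) -> list[list[BbScore]]:
    """Per-position BB ranking by mean member points.

    ``points[i]`` is the (Lipinski) point count of member *i*.  The mean over
    members containing a BB — rather than the sum — makes positions with
    different set sizes comparable.  Ties rank by ``bb_id``.
    """
    points = np.asarray(points, dtype=float)
    if len(library) == 0:
        raise LibraryConfigError("cannot rank building blocks of an empty library")
    if points.shape[0] != len(library):
        raise ValueError("points must align with library members")
    sums, counts = [], []
    for p, s in enumerate(library.bb_sets):
        idx = library.bb_index[:, p]
        sums.append(np.bincount(idx, weights=points, minlength=len(s)))
        counts.append(np.bincount(idx, minlength=len(s)))
    return _rank_from_sums(library.bb_sets, sums, counts)


def rank_building_blocks_streaming(
    bb_sets: Sequence[Sequence[BuildingBlock]],
    points_fn: Callable[[np.ndarray], np.ndarray],
    chunk_size: int = 1_000_000,
) -> list[list[BbScore]]:
    """Rank BBs of a virtual library too large to materialise.

    Iterates the cross product in flat-index chunks, decodes mixed-radix BB
    indices, asks ``points_fn(bb_index_chunk) -> points`` for each chunk and
    accumulates per-BB sums — memory is O(chunk), never O(members), so a
    10^9-member catalog can be scored position-wise.
    """
    sizes = [len(s) for s in bb_sets]
    if any(k == 0 for k in sizes):
        raise LibraryConfigError("empty BB set in virtual library")
    n = math.prod(sizes)
    radix = np.array(sizes, dtype=np.int64)
    sums = [np.zeros(k) for k in sizes]
    counts = [np.zeros(k, dtype=np.int64) for k in sizes]
    for start in range(0, n, chunk_size):
        flat = np.arange(start, min(start + chunk_size, n), dtype=np.int64)
        idx = np.empty((flat.shape[0], len(sizes)), dtype=np.int64)
        rem = flat
        for p in range(len(sizes) - 1, -1, -1):
            idx[:, p] = rem % radix[p]
            rem = rem // radix[p]
        pts = np.asarray(points_fn(idx), dtype=float)
        for p in range(len(sizes)):
            sums[p] += np.bincount(idx[:, p], weights=pts, minlength=sizes[p])
            counts[p] += np.bincount(idx[:, p], minlength=sizes[p])
    return _rank_from_sums(bb_sets, sums, counts)


# ---------------------------------------------------------------------------
# Mass degeneracy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DegeneracyStats:
    """Members per resolvable mass at a given ppm bin width."""

    group_sizes: np.ndarray
    max_group_size: int
    histogram: dict[int, int]  # group size -> number of groups

    @property
    def n_groups(self) -> int:
        return int(self.group_sizes.shape[0])


def mass_degeneracy(library: EnumeratedLibrary, bin_ppm: float) -> DegeneracyStats:
    """Group members whose neighbouring mass gaps are <= ``bin_ppm``.

    Single-linkage on the sorted mass axis: a new group starts whenever the
    gap to the previous mass exceeds ``bin_ppm * 1e-6`` relative to it.  This
    is the operational notion of "indistinguishable at MS1": every member of
    a group falls inside some other member's ppm window.
    """
    if len(library) == 0:
        raise LibraryConfigError("mass degeneracy of an empty library")
    m = np.sort(library.masses)
    gaps = np.diff(m) / m[:-1]
    breaks = np.flatnonzero(gaps > bin_ppm * 1e-6)
    sizes = np.diff(np.concatenate(([0], breaks + 1, [m.shape[0]])))
    hist = dict(Counter(int(s) for s in sizes))
    return DegeneracyStats(
        group_sizes=sizes, max_group_size=int(sizes.max()), histogram=hist
    )


# ---------------------------------------------------------------------------
# Building-block CSV I/O
# ---------------------------------------------------------------------------


def read_bb_table(path: str | Path) -> dict[int, list[BuildingBlock]]:
    """Read a building-block CSV with columns bb_id,position,name,smiles,formula.

    Returns position -> BB list (ordered as in the file).  ``name`` and
    ``smiles`` are optional columns.
    """
    df = pd.read_csv(path, dtype={"bb_id": str})
    required = {"bb_id", "position", "formula"}
    missing = required - set(df.columns)
    if missing:
        raise LibraryConfigError(
            f"BB table {path} lacks required columns: {sorted(missing)}"
        )
    out: dict[int, list[BuildingBlock]] = {}
    for row in df.itertuples(index=False):
        smiles = getattr(row, "smiles", None)
        if smiles is not None and (pd.isna(smiles) or smiles == ""):
            smiles = None
        name = getattr(row, "name", "")
        if pd.isna(name):
            name = ""
        bb = BuildingBlock(
            bb_id=str(row.bb_id),
            position=int(row.position),
            formula=ElementalFormula.parse(str(row.formula)),
            name=str(name),
            smiles=smiles,
        )
        out.setdefault(bb.position, []).append(bb)
    return out


def write_bb_table(
    bbs: Iterable[BuildingBlock], path: str | Path
) -> None:
    rows = [
        {
            "bb_id": bb.bb_id,
            "position": bb.position,
            "name": bb.name,
            "smiles": bb.smiles or "",
            "formula": bb.formula.hill,
        }
        for bb in bbs
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
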
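import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from seldecode.formula import ElementalFormula
from seldecode.library import (
    BuildingBlock,
    ScaffoldDesign,
    enumerate_library,
)
from seldecode.simulate import AMINO_ACID_RESIDUES, toy_library


def _bb(bb_id, position, formula):
    return BuildingBlock(
        bb_id=bb_id, position=position, formula=ElementalFormula.parse(formula)
    )


@pytest.fixture
def amide_design():
    """Three-position amide scaffold: two residues + an acyl cap, NH3 offset."""
    return ScaffoldDesign(
        design_id="amide3",
        n_positions=3,
        scaffold_offset=ElementalFormula.parse("NH3"),
        fragment_types="S[0;1], S[1;2],0,2",
    )


@pytest.fixture
def amide_bb_sets():
    """Real residue/acyl formulas; includes the Leu/Ile isobar pair."""
    aas = ["Gly", "Ala", "Ser", "Val", "Leu", "Ile"]
    pos0 = [_bb(a, 0, AMINO_ACID_RESIDUES[a]) for a in aas]
    pos1 = [_bb(a, 1, AMINO_ACID_RESIDUES[a]) for a in ["Gly", "Pro", "Phe", "Thr"]]
    acyls = {"Ac": "C2H3O", "Bz": "C7H5O", "Piv": "C5H9O"}
    pos2 = [_bb(k, 2, f) for k, f in acyls.items()]
    return [pos0, pos1, pos2]


@pytest.fixture
def amide_library(amide_design, amide_bb_sets):
    return enumerate_library(amide_design, amide_bb_sets)


@pytest.fixture
def unique_mass_library():
    """Toy library whose member masses are pairwise distinct by construction."""
    return toy_library((6, 5, 4), seed=None)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
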
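"""Ground-truthed synthetic affinity-selection experiments.

Real selection runs are ~80,000 scans of which a few hundred come from
library compounds; everything else is background and noise.  The simulator
reproduces that statistical structure at a configurable scale so decoder
recall and false-positive behaviour can be measured against known truth:

* each *true binder* becomes an MS1 feature at its adduct m/z (Gaussian ppm
  jitter), eluting over a few adjacent MS1 spectra, with one (configurable)
  MS2 scan whose peaks are the compound's predicted fragments, each fragment
  type emitted independently with its configured probability;
* *noise scans* carry precursors rejection-sampled to stay at least
  ``decoy_offset_ppm`` from every library mass (so false positives isolate
  MS2-level failures); an ``isobaric`` decoy mode instead places them ON
  library masses to stress fragment-level discrimination;
* *background features* are injected into both the sample and the control
  run with a sample/control intensity ratio drawn below the subtraction
  threshold, emulating carry-over that background subtraction must remove.

Intensities are log-normal and all randomness flows from one integer seed,
so a config reproduces byte-identical runs and truth tables.

What the simulator does not model: chromatographic peak shapes, isotope
envelopes, multiple charge states, and ionisation bias.  Conclusions from
synthetic recall therefore concern the decoding logic, not detectability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .formula import ElementalFormula, adduct_mass
from .fragments import parse_fragment_types, predict_fragments
from .library import (
    BuildingBlock,
    EnumeratedLibrary,
    ScaffoldDesign,
    enumerate_library,
)
from .spectra import Ms1Feature, Ms1Spectrum, Ms2Scan, Run

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_experiment",
    "evaluate_decoding",
    "synthetic_bb_sets",
    "toy_library",
    "AMINO_ACID_RESIDUES",
]

#: Contribution (residue) formulas of the proteinogenic-style amino-acid
#: building blocks used by the amide scaffold demos: the monomer minus H2O.
AMINO_ACID_RESIDUES: dict[str, str] = {
    "Gly": "C2H3NO",
    "Ala": "C3H5NO",
    "Ser": "C3H5NO2",
    "Pro": "C5H7NO",
    "Val": "C5H9NO",
    "Thr": "C4H7NO2",
    "Cys": "C3H5NOS",
    "Leu": "C6H11NO",
    "Ile": "C6H11NO",
    "Asn": "C4H6N2O2",
    "Asp": "C4H5NO3",
    "Gln": "C5H8N2O2",
    "Lys": "C6H12N2O",
    "Glu": "C5H7NO3",
    "Met": "C5H9NOS",
    "His": "C6H7N3O",
    "Phe": "C9H9NO",
    "Arg": "C6H12N4O",
    "Tyr": "C9H9NO2",
    "Trp": "C11H10N2O",
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic selection experiment.

    Defaults emulate the mini-library decodability experiments: a few
    hundred known compounds measured by nanoLC-MS/MS, dominated by noise
    scans, with shared background between sample and control.
    """

    n_binders: int = 50
    true_binder_ids: list[str] | None = None  # overrides n_binders sampling
    #: emission probability per fragment-type string; "*" is the default.
    emission_probabilities: dict[str, float] = field(
        default_factory=lambda: {"*": 0.8}
    )
    ms2_scans_per_binder: int = 1
    n_noise_scans: int = 500
    noise_peaks_mean: float = 12.0  # Poisson mean, noise-scan peak count
    binder_extra_peaks: float = 0.0  # Poisson mean, extra peaks in binder scans
    intensity_log_mu: float = 11.5  # log-normal location (ln counts)
    intensity_log_sigma: float = 1.0
    ppm_jitter_sd: float = 1.0  # Gaussian m/z jitter, relative ppm
    rt_window_s: float = 1200.0
    ms1_interval_s: float = 2.0  # survey-scan spacing
    n_background_features: int = 100
    background_ratio_range: tuple[float, float] = (0.5, 2.5)  # sample/control
    decoy_offset_ppm: float = 50.0
    decoy_mode: str = "offset"  # "offset" | "isobaric"
    hydrogen_shifts_emitted: int = 0  # binder fragments emitted at this |h| max
    seed: int = 0

    def __post_init__(self) -> None:
        for p in self.emission_probabilities.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("emission probabilities must be in [0, 1]")
        if self.decoy_mode not in ("offset", "isobaric"):
            raise ValueError(f"unknown decoy_mode {self.decoy_mode!r}")
        lo, hi = self.background_ratio_range
        if not 0 < lo <= hi:
            raise ValueError("background_ratio_range must be 0 < lo <= hi")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["background_ratio_range"] = list(self.background_ratio_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "background_ratio_range" in d:
            d["background_ratio_range"] = tuple(d["background_ratio_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Scan- and feature-level labels of a simulated experiment."""

    scan_labels: dict[str, str]  # scan_id -> compound_id or "noise"
    feature_labels: dict[str, str]  # feature_id -> "binder:<cid>"|"background"
    binder_ids: list[str]  # compound ids of the injected binders

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"record": "scan", "id": k, "label": v}
            for k, v in self.scan_labels.items()
        ] + [
            {"record": "feature", "id": k, "label": v}
            for k, v in self.feature_labels.items()
        ]
        return pd.DataFrame(rows, columns=["record", "id", "label"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GroundTruth":
        df = pd.read_csv(path, sep="\t", dtype=str)
        scans = {
            r.id: r.label for r in df[df.record == "scan"].itertuples()
        }
        feats = {
            r.id: r.label for r in df[df.record == "feature"].itertuples()
        }
        binders = sorted(
            {v for v in scans.values() if v != "noise"}
        )
        return cls(scan_labels=scans, feature_labels=feats, binder_ids=binders)


def _emission_prob(cfg: SimulationConfig, ft: str) -> float:
    return cfg.emission_probabilities.get(
        ft, cfg.emission_probabilities.get("*", 1.0)
    )


def _jitter(rng: np.random.Generator, mz: float, ppm_sd: float) -> float:
    if ppm_sd <= 0:
        return mz
    return mz * (1.0 + rng.normal(0.0, ppm_sd * 1e-6))


def _merge_centroids(
    mz: list[float], intensity: list[float], tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Merge coincident peaks (within ``tol`` Da), summing intensities.

    Distinct fragment types can map to the same ion m/z (e.g. the same BB at
    two positions); a centroided instrument reports one peak there.
    """
    if not mz:
        return np.array([]), np.array([])
    order = np.argsort(mz)
    mz_arr = np.asarray(mz, dtype=float)[order]
    int_arr = np.asarray(intensity, dtype=float)[order]
    keep_mz: list[float] = [mz_arr[0]]
    keep_int: list[float] = [int_arr[0]]
    for m, i in zip(mz_arr[1:], int_arr[1:]):
        if m - keep_mz[-1] <= tol:
            keep_int[-1] += i
        else:
            keep_mz.append(m)
            keep_int.append(i)
    return np.array(keep_mz), np.array(keep_int)


def _elution_profile(
    rng: np.random.Generator,
    grid: np.ndarray,
    rt: float,
    mz: float,
    apex: float,
    ppm_sd: float,
    spectra_peaks: list[list[tuple[float, float]]],
) -> None:
    """Deposit a 3-point elution trace onto the MS1 grid around ``rt``."""
    centre = int(np.clip(np.searchsorted(grid, rt), 1, grid.size - 2))
    for k, frac in ((-1, 0.5), (0, 1.0), (1, 0.5)):
        spectra_peaks[centre + k].append(
            (_jitter(rng, mz, ppm_sd), apex * frac)
        )


def simulate_experiment(
    library: EnumeratedLibrary,
    cfg: SimulationConfig,
) -> tuple[Run, Run, GroundTruth]:
    """Simulate one sample run + one bead-only control run with truth labels.

    Binders are drawn from (or named in) ``library``; fragment emission
    follows the design's fragment grammar and the configured per-type
    probabilities.  Fully deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    design = library.design
    types = parse_fragment_types(design.fragment_types, design.n_positions)
    shift, charge = adduct_mass(design.adduct)

    # --- choose binders ----------------------------------------------------
    if cfg.true_binder_ids is not None:
        binder_idx = [library.index_of(cid) for cid in cfg.true_binder_ids]
    else:
        if cfg.n_binders > len(library):
            raise ValueError("more binders requested than library members")
        binder_idx = sorted(
            rng.choice(len(library), size=cfg.n_binders, replace=False).tolist()
        )
    binder_ids = [library.compound_id(i) for i in binder_idx]

    n_ms1 = max(3, int(cfg.rt_window_s / cfg.ms1_interval_s))
    grid = np.linspace(0.0, cfg.rt_window_s, n_ms1)
    sample_ms1: list[list[tuple[float, float]]] = [[] for _ in range(n_ms1)]
    control_ms1: list[list[tuple[float, float]]] = [[] for _ in range(n_ms1)]

    sample_features: list[Ms1Feature] = []
    control_features: list[Ms1Feature] = []
    scans: list[Ms2Scan] = []
    scan_labels: dict[str, str] = {}
    feature_labels: dict[str, str] = {}

    lib_masses = np.sort(library.masses)

    def far_from_library(neutral: float, min_ppm: float) -> bool:
        i = np.searchsorted(lib_masses, neutral)
        for j in (i - 1, i):
            if 0 <= j < lib_masses.size:
                if abs(neutral - lib_masses[j]) / lib_masses[j] < min_ppm * 1e-6:
                    return False
        return True

    # --- binder features + MS2 scans ---------------------------------------
    scan_no = 0
    for idx, cid in zip(binder_idx, binder_ids):
        mass = float(library.masses[idx])
        ion_mz = _jitter(rng, (mass + shift) / charge, cfg.ppm_jitter_sd)
        rt = float(rng.uniform(0.05, 0.95) * cfg.rt_window_s)
        apex = float(rng.lognormal(cfg.intensity_log_mu, cfg.intensity_log_sigma))
        fid = f"SB{len(sample_features):05d}"
        feature = Ms1Feature(
            feature_id=fid, mz=ion_mz, rt_apex=rt, intensity=apex,
            rt_lo=rt - cfg.ms1_interval_s, rt_hi=rt + cfg.ms1_interval_s,
        )
        _elution_profile(
            rng, grid, rt, ion_mz, apex, 0.0, sample_ms1
        )
        feature_labels[fid] = f"binder:{cid}"

        pred = predict_fragments(
            library.bb_formulas(idx), design, types,
            hydrogen_shifts=cfg.hydrogen_shifts_emitted, adduct=design.adduct,
            compound_id=cid,
        )
        for _ in range(cfg.ms2_scans_per_binder):
            peaks_mz: list[float] = []
            peaks_int: list[float] = []
            for frag in pred.fragments:
                if rng.random() < _emission_prob(cfg, str(frag.fragment_type)):
                    peaks_mz.append(
                        _jitter(rng, frag.mz, cfg.ppm_jitter_sd)
                    )
                    peaks_int.append(
                        float(
                            rng.lognormal(
                                cfg.intensity_log_mu - 1.0,
                                cfg.intensity_log_sigma,
                            )
                        )
                    )
            n_extra = (
                int(rng.poisson(cfg.binder_extra_peaks))
                if cfg.binder_extra_peaks > 0
                else 0
            )
            for _ in range(n_extra):
                peaks_mz.append(float(rng.uniform(50.0, ion_mz)))
                peaks_int.append(
                    float(
                        rng.lognormal(
                            cfg.intensity_log_mu - 3.0, cfg.intensity_log_sigma
                        )
                    )
                )
            sid = f"scan={scan_no}"
            scan_no += 1
            merged_mz, merged_int = _merge_centroids(peaks_mz, peaks_int)
            scans.append(
                Ms2Scan(
                    scan_id=sid,
                    precursor_mz=ion_mz,
                    rt=rt + float(rng.uniform(-1.0, 1.0)),
                    mz=merged_mz,
                    intensity=merged_int,
                )
            )
            scan_labels[sid] = cid
            feature.ms2_scan_ids.append(sid)
        sample_features.append(feature)

    # --- noise scans --------------------------------------------------------
    mz_lo = float(lib_masses[0] * 0.5 + shift)
    mz_hi = float(lib_masses[-1] * 1.2 + shift)
    for _ in range(cfg.n_noise_scans):
        if cfg.decoy_mode == "isobaric":
            target = float(rng.choice(lib_masses))
            pre = (target + shift) / charge
            pre = _jitter(rng, pre, cfg.ppm_jitter_sd)
        else:
            while True:
                pre = float(rng.uniform(mz_lo, mz_hi))
                neutral = (pre - shift) * charge
                if far_from_library(neutral, cfg.decoy_offset_ppm):
                    break
        k = max(1, int(rng.poisson(cfg.noise_peaks_mean)))
        pk_mz = rng.uniform(50.0, max(pre, 60.0), size=k)
        pk_int = rng.lognormal(
            cfg.intensity_log_mu - 2.0, cfg.intensity_log_sigma, size=k
        )
        sid = f"scan={scan_no}"
        scan_no += 1
        scans.append(
            Ms2Scan(
                scan_id=sid,
                precursor_mz=pre,
                rt=float(rng.uniform(0.0, cfg.rt_window_s)),
                mz=pk_mz,
                intensity=pk_int,
            )
        )
        scan_labels[sid] = "noise"

    # --- shared background features ----------------------------------------
    lo, hi = cfg.background_ratio_range
    for b in range(cfg.n_background_features):
        while True:
            mz = float(rng.uniform(mz_lo, mz_hi))
            if far_from_library((mz - shift) * charge, cfg.decoy_offset_ppm):
                break
        rt = float(rng.uniform(0.05, 0.95) * cfg.rt_window_s)
        ratio = float(rng.uniform(lo, hi))
        control_int = float(
            rng.lognormal(cfg.intensity_log_mu, cfg.intensity_log_sigma)
        )
        sample_int = control_int * ratio
        rt_ctrl = rt + float(rng.uniform(-1.0, 1.0))
        sfid, cfid = f"SG{b:05d}", f"CG{b:05d}"
        sample_features.append(
            Ms1Feature(
                feature_id=sfid, mz=mz, rt_apex=rt, intensity=sample_int,
                rt_lo=rt - cfg.ms1_interval_s, rt_hi=rt + cfg.ms1_interval_s,
            )
        )
        control_features.append(
            Ms1Feature(
                feature_id=cfid, mz=mz, rt_apex=rt_ctrl, intensity=control_int,
                rt_lo=rt_ctrl - cfg.ms1_interval_s,
                rt_hi=rt_ctrl + cfg.ms1_interval_s,
            )
        )
        _elution_profile(rng, grid, rt, mz, sample_int, 0.0, sample_ms1)
        _elution_profile(rng, grid, rt_ctrl, mz, control_int, 0.0, control_ms1)
        feature_labels[sfid] = "background"
        feature_labels[cfid] = "background"

    def build_ms1(peaks: list[list[tuple[float, float]]], tag: str):
        out = []
        for i, plist in enumerate(peaks):
            if not plist:
                continue
            arr = np.array(plist, dtype=float)
            out.append(
                Ms1Spectrum(
                    scan_id=f"{tag}ms1={i}",
                    rt=float(grid[i]),
                    mz=arr[:, 0],
                    intensity=arr[:, 1],
                )
            )
        return out

    sample = Run(
        run_id="sample",
        ms1_spectra=build_ms1(sample_ms1, "s"),
        scans=scans,
        features=sorted(sample_features, key=lambda f: f.mz),
        provenance={"simulation_seed": cfg.seed},
    )
    control = Run(
        run_id="control",
        ms1_spectra=build_ms1(control_ms1, "c"),
        scans=[],
        features=sorted(control_features, key=lambda f: f.mz),
        provenance={"simulation_seed": cfg.seed},
    )
    truth = GroundTruth(
        scan_labels=scan_labels,
        feature_labels=feature_labels,
        binder_ids=binder_ids,
    )
    return sample, control, truth


def evaluate_decoding(hits: pd.DataFrame, truth: GroundTruth) -> dict:
    """Recall / false-annotation / precision of an annotation table vs truth.

    * detectable true compounds: binders with at least one MS2 scan in the
      truth table;
    * recall: fraction of detectable binders whose accepted annotation on
      one of *their own* scans names the right compound;
    * false annotations: accepted (scan, compound) pairs whose compound
      differs from the scan's truth label (noise scans annotated at all
      count here);
    * precision: correct accepted annotations / all accepted annotations.
    """
    detectable = {v for v in truth.scan_labels.values() if v != "noise"}
    accepted = hits[hits["accepted"]] if len(hits) else hits
    unknown = [
        sid for sid in (accepted["scan_id"] if len(accepted) else [])
        if sid not in truth.scan_labels
    ]
    if unknown:
        raise ValueError(
            f"annotations reference scans absent from the truth table: "
            f"{unknown[:5]}"
        )
    correct_compounds: set[str] = set()
    n_false = 0
    for row in accepted.itertuples():
        label = truth.scan_labels[row.scan_id]
        if row.compound_id == label:
            correct_compounds.add(label)
        else:
            n_false += 1
    n_accepted = int(len(accepted))
    return {
        "n_detectable": len(detectable),
        "n_correct": len(correct_compounds),
        "recall": len(correct_compounds) / len(detectable) if detectable else 0.0,
        "n_false_annotations": n_false,
        "n_accepted": n_accepted,
        "precision": (
            (n_accepted - n_false) / n_accepted if n_accepted else 0.0
        ),
    }


# ---------------------------------------------------------------------------
# Toy libraries
# ---------------------------------------------------------------------------


def synthetic_bb_sets(
    sizes: Sequence[int], seed: int | None = None
) -> list[list[BuildingBlock]]:
    """Generate BB sets whose member masses are pairwise distinct.

    Hydrogen counts encode a mixed-radix digit per position, so every sum of
    one BB per position is unique — no accidental isobars, which makes these
    sets the clean substrate for recall tests.  ``seed`` shuffles carbon
    counts for variety without breaking uniqueness.
    """
    rng = np.random.default_rng(seed)
    sets: list[list[BuildingBlock]] = []
    radix = 1
    for p, k in enumerate(sizes):
        bbs = []
        carbons = 3 + rng.integers(0, 3, size=k) if seed is not None else [4] * k
        for j in range(k):
            h = 4 + j * radix
            formula = ElementalFormula(
                {"C": int(carbons[j]), "H": int(h), "N": 1, "O": 1}
            )
            bbs.append(
                BuildingBlock(
                    bb_id=f"P{p}B{j:03d}", position=p, formula=formula,
                    name=f"synthetic BB {j} at position {p}",
                )
            )
        sets.append(bbs)
        radix *= k
    return sets


def toy_library(
    sizes: Sequence[int] = (6, 6, 6),
    fragment_types: str = "S[0;1], S[1;2],0,2",
    scaffold_offset: str = "NH3",
    seed: int | None = None,
    design_id: str = "toy",
) -> EnumeratedLibrary:
    """A small unique-mass library with an amide-scaffold fragment grammar."""
    design = ScaffoldDesign(
        design_id=design_id,
        n_positions=len(sizes),
        scaffold_offset=ElementalFormula.parse(scaffold_offset),
        fragment_types=fragment_types,
    )
    return enumerate_library(design, synthetic_bb_sets(sizes, seed))
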
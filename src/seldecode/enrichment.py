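"""Selection enrichment and per-building-block statistics.

Two questions follow every affinity selection.  First, how well did the
selection separate binders from the bulk library?  The *maximum enrichment*
answers it:

    E = (found binders / compounds after selection)
        / (total binders / total library)

with the total number of binders postulated equal to the number found
(nothing more can be known), so E reduces to total_library / compounds_after_
selection scaled by the hit fraction.  Second, which building blocks drive
binding?  Each BB at each position is tested with a one-sided hypergeometric
(Fisher) test of its frequency among hits against its frequency in the full
library, with Benjamini-Hochberg adjustment across the tested BBs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .library import COMPOUND_ID_SEP, EnumeratedLibrary

__all__ = [
    "SelectionSummary",
    "max_enrichment",
    "round_sig",
    "bb_frequencies",
    "fisher_enrichment",
    "BbEnrichmentRecord",
    "enrichment_report",
    "plot_bb_frequencies",
]


@dataclass(frozen=True)
class SelectionSummary:
    """The four counts of the enrichment ratio."""

    found_binders: int
    compounds_after_selection: int
    total_binders: int
    total_library: int

    def __post_init__(self) -> None:
        if min(
            self.found_binders,
            self.compounds_after_selection,
            self.total_binders,
            self.total_library,
        ) <= 0:
            raise ValueError("all selection counts must be positive")
        if self.found_binders > self.compounds_after_selection:
            raise ValueError("found_binders cannot exceed compounds_after_selection")
        if self.total_binders > self.total_library:
            raise ValueError("total_binders cannot exceed total_library")


def max_enrichment(s: SelectionSummary) -> float:
    """(found/after) / (total_binders/library) — the selection's fold gain.

    With ``total_binders == found_binders`` (the maximum-enrichment
    postulate) this equals ``total_library / compounds_after_selection``.
    E.g. 74 binders among 228 selected compounds from a 499,720-member
    library gives 2191.75, reported as 2.2e3.
    """
    return (s.found_binders / s.compounds_after_selection) / (
        s.total_binders / s.total_library
    )


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting convention)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - math.floor(math.log10(abs(x))))


def bb_frequencies(
    hits: pd.DataFrame, library: EnumeratedLibrary
) -> dict[int, pd.DataFrame]:
    """Per-position building-block counts over a hit table.

    ``hits`` needs a ``compound_id`` column (one row per hit compound).
    Returns position -> DataFrame(bb_id, count) sorted descending, counts
    summing to the number of hits at every position.  Unknown BB ids raise.
    """
    n_pos = library.design.n_positions
    known = [
        {bb.bb_id for bb in library.bb_sets[p]} for p in range(n_pos)
    ]
    counts: list[dict[str, int]] = [
        {bb.bb_id: 0 for bb in library.bb_sets[p]} for p in range(n_pos)
    ]
    for cid in hits["compound_id"]:
        bbs = str(cid).split(COMPOUND_ID_SEP)
        if len(bbs) != n_pos:
            raise ValueError(f"hit {cid!r} does not have {n_pos} positions")
        for p, bb in enumerate(bbs):
            if bb not in known[p]:
                raise ValueError(
                    f"hit {cid!r} references unknown BB {bb!r} at position {p}"
                )
            counts[p][bb] += 1
    out = {}
    for p in range(n_pos):
        df = pd.DataFrame(
            {"bb_id": list(counts[p]), "count": list(counts[p].values())}
        ).sort_values(
            ["count", "bb_id"], ascending=[False, True], ignore_index=True
        )
        out[p] = df
    return out


def fisher_enrichment(
    hits_with_bb: int,
    hits_total: int,
    library_with_bb: int,
    library_total: int,
) -> tuple[float, float]:
    """Fold enrichment and one-sided hypergeometric p for one BB.

    fold = (hits_with_bb / hits_total) / (library_with_bb / library_total);
    p = P(X >= hits_with_bb) for X ~ Hypergeom(N=library_total,
    K=library_with_bb, n=hits_total), evaluated through the log survival
    function so values far below 1e-300 stay representable before the final
    exponentiation.  Degenerate margins (a BB in every or no library
    compound, or zero hits with the BB) give p = 1.
    """
    if not (0 <= hits_with_bb <= hits_total):
        raise ValueError("need 0 <= hits_with_bb <= hits_total")
    if not (0 <= library_with_bb <= library_total):
        raise ValueError("need 0 <= library_with_bb <= library_total")
    if hits_total == 0 or library_total == 0:
        raise ValueError("margins must be positive")
    if library_with_bb == 0:
        fold = math.inf if hits_with_bb > 0 else 0.0
        return fold, 1.0
    fold = (hits_with_bb / hits_total) / (library_with_bb / library_total)
    if hits_with_bb == 0 or library_with_bb == library_total:
        return fold, 1.0
    logp = hypergeom.logsf(
        hits_with_bb - 1, library_total, library_with_bb, hits_total
    )
    p = float(np.exp(logp))
    return fold, min(p, 1.0)


@dataclass(frozen=True)
class BbEnrichmentRecord:
    """One BB's 2x2 enrichment test result."""

    position: int
    bb_id: str
    hits_with_bb: int
    hits_total: int
    library_with_bb: int
    library_total: int
    fold_enrichment: float
    p_value: float
    q_value: float


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values (statsmodels if available, else direct)."""
    try:
        from statsmodels.stats.multitest import multipletests

        return multipletests(p, method="fdr_bh")[1]
    except ImportError:  # pragma: no cover - statsmodels is pre-installed
        order = np.argsort(p)
        m = p.size
        q = np.empty(m)
        prev = 1.0
        for rank_rev, i in enumerate(order[::-1]):
            rank = m - rank_rev
            prev = min(prev, p[i] * m / rank)
            q[i] = prev
        return q


def enrichment_report(
    hits: pd.DataFrame,
    library: EnumeratedLibrary,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-BB enrichment table over all positions, BH-adjusted.

    For every BB at every position: hits containing it vs the library
    fraction containing it, one-sided hypergeometric p, Benjamini-Hochberg
    q across all tested BBs, sorted by p (ties by position, bb_id).
    ``significant`` flags q <= alpha.  Library membership counts come from
    the cross-product structure: a BB at position p occurs in
    (members / |set p|) compounds.
    """
    if len(hits) == 0:
        raise ValueError("enrichment_report needs a non-empty hit table")
    freqs = bb_frequencies(hits, library)
    hits_total = len(hits)
    library_total = len(library)
    rows = []
    for p, df in freqs.items():
        per_bb_members = library_total // len(library.bb_sets[p])
        for bb_id, count in zip(df["bb_id"], df["count"]):
            fold, pval = fisher_enrichment(
                int(count), hits_total, per_bb_members, library_total
            )
            rows.append(
                {
                    "position": p,
                    "bb_id": bb_id,
                    "hits_with_bb": int(count),
                    "hits_total": hits_total,
                    "library_with_bb": per_bb_members,
                    "library_total": library_total,
                    "library_fraction": per_bb_members / library_total,
                    "fold": fold,
                    "p": pval,
                }
            )
    out = pd.DataFrame(rows)
    out["q"] = _bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] <= alpha
    out = out.sort_values(
        ["p", "position", "bb_id"], ignore_index=True
    )
    return out


def plot_bb_frequencies(
    freqs: Mapping[int, pd.DataFrame],
    top: int = 20,
    highlight: Sequence[str] = (),
):
    """Bar plots of per-position BB frequencies (one axis per position).

    Returns the matplotlib Figure; requires the ``plot`` extra.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(freqs)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 3), squeeze=False)
    for ax, (p, df) in zip(axes[0], sorted(freqs.items())):
        sub = df.head(top)
        colors = [
            "#d62728" if b in highlight else "#1f77b4" for b in sub["bb_id"]
        ]
        ax.bar(range(len(sub)), sub["count"], color=colors)
        ax.set_xticks(range(len(sub)))
        ax.set_xticklabels(sub["bb_id"], rotation=90, fontsize=6)
        ax.set_title(f"position {p + 1}")
        ax.set_ylabel("hits")
    fig.tight_layout()
    return fig
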
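"""Small-molecule pocket scoring and variant enrichment.

A pocket arrives as a cloud of cavity fill points plus a raw composite
score (AutoSite-like).  Pocket-associated residues are those with any atom
closer than 4.5 A to any fill point.  The confidence-weighted composite
score multiplies the raw score by mean pLDDT / 100 over those residues, so
a pocket predicted on a disordered region is down-weighted and a
zero-confidence pocket is annihilated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import EmptyInputError, ValidationError
from .stats import ContingencyTable2x2, bh_fdr, fisher_exact
from .structures import StructureChain

logger = logging.getLogger(__name__)

POCKET_CUTOFF = 4.5  # Angstrom, fill point to residue atom


@dataclass
class PocketRecord:
    protein_id: str
    pocket_id: str
    fill_points: np.ndarray  # (k, 3) in Angstrom
    raw_score: float
    residue_set: Optional[frozenset[int]] = None
    mean_plddt: Optional[float] = None
    combined_score: Optional[float] = None

    def __post_init__(self) -> None:
        self.fill_points = np.asarray(self.fill_points, dtype=float)
        if self.fill_points.ndim != 2 or self.fill_points.shape[1] != 3:
            raise ValidationError("fill_points must be an (k, 3) array")
        if self.raw_score < 0:
            raise ValidationError("raw_score must be >= 0")


def pocket_residues(
    fill_points: np.ndarray, chain: StructureChain, cutoff: float = POCKET_CUTOFF
) -> frozenset[int]:
    """Residues with any atom strictly closer than ``cutoff`` to any fill
    point."""
    fill_points = np.asarray(fill_points, dtype=float)
    if fill_points.size == 0:
        raise EmptyInputError("pocket has no fill points")
    if len(chain) == 0:
        raise EmptyInputError("empty chain")
    coords, owner = chain.atom_coords()
    close = (cdist(coords, fill_points) < cutoff).any(axis=1)
    return frozenset(owner[close].tolist())


def score_pocket(raw_score: float, mean_plddt: float) -> float:
    """Confidence-weighted composite: raw_score * mean_plddt / 100."""
    if raw_score < 0:
        raise ValidationError("raw_score must be >= 0")
    if not 0.0 <= mean_plddt <= 100.0:
        raise ValidationError("mean_plddt must lie in [0, 100]")
    return raw_score * mean_plddt / 100.0


def annotate_pockets(
    pockets: Sequence[PocketRecord],
    chains: Mapping[str, StructureChain],
    cutoff: float = POCKET_CUTOFF,
    keep_masks: Mapping[str, np.ndarray] | None = None,
) -> list[PocketRecord]:
    """Derive residue_set, mean_plddt and combined_score for each pocket.

    ``keep_masks`` (per protein, aligned to chain residues) restricts the
    pLDDT average to residues that survived low-confidence trimming; the
    residue set itself is reported untrimmed.
    """
    for p in pockets:
        chain = chains.get(p.protein_id)
        if chain is None:
            logger.warning("pocket %s: unknown protein %s", p.pocket_id, p.protein_id)
            continue
        p.residue_set = pocket_residues(p.fill_points, chain, cutoff)
        member = np.isin(chain.indices, list(p.residue_set))
        if keep_masks is not None and p.protein_id in keep_masks:
            member &= np.asarray(keep_masks[p.protein_id], dtype=bool)
        p.mean_plddt = float(chain.plddt[member].mean()) if member.any() else 0.0
        p.combined_score = score_pocket(p.raw_score, p.mean_plddt)
    return list(pockets)


def rank_and_filter_pockets(
    pockets: Sequence[PocketRecord], score_threshold: float
) -> tuple[list[PocketRecord], list[PocketRecord]]:
    """Descending combined-score order (ties by protein_id, pocket_id) and
    the high-confidence subset with combined_score > threshold."""
    ranked = sorted(
        pockets, key=lambda p: (-(p.combined_score or 0.0), p.protein_id, p.pocket_id)
    )
    subset = [p for p in ranked if (p.combined_score or 0.0) > score_threshold]
    return ranked, subset


def coverage_category(residue_set: frozenset[int], covered_mask: frozenset[int]) -> str:
    """Overlap of a pocket with an experimentally covered residue set:
    none / partial / full."""
    if not residue_set:
        raise ValidationError("empty pocket residue set")
    inter = residue_set & covered_mask
    if not inter:
        return "none"
    if residue_set <= covered_mask:
        return "full"
    return "partial"


def _enrichment_table(
    variant_pos: frozenset[int], pocket_pos: frozenset[int], length: int
) -> ContingencyTable2x2:
    a = len(variant_pos & pocket_pos)
    b = len(variant_pos - pocket_pos)
    c = len(pocket_pos - variant_pos)
    d = length - a - b - c
    return ContingencyTable2x2(a, b, c, d)


def pocket_enrichment(
    variant_positions: Mapping[str, frozenset[int] | set],
    pocket_sets: Mapping[str, frozenset[int] | set],
    protein_lengths: Mapping[str, int],
    scope: str = "global",
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Fisher enrichment of variant positions in pocket-associated residues.

    ``global`` pools positions across the whole proteome into one 2x2 test;
    ``per_protein`` tests each structure's positions against the rest of
    that structure, BH-adjusted across proteins.
    """
    if scope not in ("global", "per_protein"):
        raise ValidationError(f"unknown scope {scope!r}")
    rows = []
    if scope == "global":
        a = b = c = d = 0
        for pid, length in protein_lengths.items():
            t = _enrichment_table(
                frozenset(variant_positions.get(pid, ())),
                frozenset(pocket_sets.get(pid, ())),
                length,
            )
            a, b, c, d = a + t.a, b + t.b, c + t.c, d + t.d
        odds, p = fisher_exact(ContingencyTable2x2(a, b, c, d), alternative)
        rows.append({"protein_id": "all", "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": odds, "p": p})
    else:
        for pid, length in protein_lengths.items():
            pocket_pos = frozenset(pocket_sets.get(pid, ()))
            if not pocket_pos:
                logger.info("protein %s has no pocket residues; test skipped", pid)
                continue
            t = _enrichment_table(
                frozenset(variant_positions.get(pid, ())), pocket_pos, length
            )
            odds, p = fisher_exact(t, alternative)
            rows.append({"protein_id": pid, "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                         "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out


def binned_enrichment(
    pockets: Sequence[PocketRecord],
    variant_positions: Mapping[str, frozenset[int] | set],
    protein_lengths: Mapping[str, int],
    n_bins: int = 4,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Global variant enrichment per combined-score bin (quantile bins,
    highest scores = bin 0).  Empty bins are reported with NaN results."""
    if n_bins < 1:
        raise ValidationError("need at least one bin")
    scored = [p for p in pockets if p.combined_score is not None]
    if not scored:
        raise EmptyInputError("no scored pockets")
    scores = np.array([p.combined_score for p in scored])
    # Quantile edges; bin 0 holds the highest-scoring pockets.
    qs = np.quantile(scores, np.linspace(0, 1, n_bins + 1))
    bin_of = np.clip(np.searchsorted(qs, scores, side="right") - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins - 1, -1, -1):
        members = [p for p, k in zip(scored, bin_of) if k == b]
        rank = n_bins - 1 - b  # 0 = top-score bin
        if not members:
            rows.append({"bin": rank, "n_pockets": 0, "odds_ratio": np.nan, "p": np.nan})
            continue
        sets: dict[str, set[int]] = {}
        for p in members:
            sets.setdefault(p.protein_id, set()).update(p.residue_set or ())
        res = pocket_enrichment(
            variant_positions, sets, protein_lengths, "global", alternative
        ).iloc[0]
        rows.append({"bin": rank, "n_pockets": len(members),
                     "odds_ratio": res["odds_ratio"], "p": res["p"]})
    return pd.DataFrame(rows).sort_values("bin").reset_index(drop=True)
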
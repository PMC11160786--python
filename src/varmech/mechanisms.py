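"""Variant classification, low-confidence trimming and mechanism triage.

Pathogenicity scores are discretised at 0.34 / 0.564 (benign / ambiguous /
pathogenic) and folding DDG at +/-2 kcal/mol (stabilising / neutral /
destabilising); boundary values fall in the middle class.  A pathogenic
variant is assigned a single primary mechanism in the precedence order
stability > pocket > interface, falling through to "unclassified".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, UndefinedAUCError, ValidationError
from .records import MechanismCall, VariantRecord
from .stats import roc_auc
from .structures import StructureChain

logger = logging.getLogger(__name__)

AM_BENIGN_MAX = 0.34
AM_PATHOGENIC_MIN = 0.564
DDG_NEUTRAL_BAND = 2.0
DEFAULT_PRECEDENCE = ("stability", "pocket", "interface")


def classify_pathogenicity(am_score: Optional[float]) -> Optional[str]:
    """Discretise a pathogenicity score: < 0.34 benign, > 0.564 pathogenic,
    in between (boundaries included) ambiguous.  Missing score -> None."""
    if am_score is None or (isinstance(am_score, float) and np.isnan(am_score)):
        return None
    if not 0.0 <= am_score <= 1.0:
        raise ValidationError(f"am_score {am_score} outside [0, 1]")
    if am_score < AM_BENIGN_MAX:
        return "benign"
    if am_score > AM_PATHOGENIC_MIN:
        return "pathogenic"
    return "ambiguous"


def classify_stability(ddg: Optional[float]) -> Optional[str]:
    """Discretise a DDG (kcal/mol): < -2 stabilising, > 2 destabilising,
    in between (boundaries included) neutral.  Missing value -> None."""
    if ddg is None or (isinstance(ddg, float) and np.isnan(ddg)):
        return None
    if not np.isfinite(ddg):
        raise ValidationError(f"ddg {ddg} is not finite")
    if ddg < -DDG_NEUTRAL_BAND:
        return "stabilising"
    if ddg > DDG_NEUTRAL_BAND:
        return "destabilising"
    return "neutral"


def classify_variants(variants: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Set both class labels on each record, in place; returns the list."""
    out = list(variants)
    for v in out:
        v.pathogenicity_class = classify_pathogenicity(v.am_score)
        v.stability_class = classify_stability(v.ddg)
    return out


def select_worst_variant(
    mutations: Iterable[tuple[str, VariantRecord]],
) -> list[tuple[str, VariantRecord]]:
    """Keep, per (gene, sample) group, only the record with the highest
    pathogenicity score; ties broken by position, then alt_aa.

    ``mutations`` is an iterable of (sample_id, record); groups in which
    every score is missing are dropped with a warning.
    """
    groups: dict[tuple[str, str], list[tuple[str, VariantRecord]]] = {}
    for sample, rec in mutations:
        groups.setdefault((rec.protein_id, sample), []).append((sample, rec))
    kept: list[tuple[str, VariantRecord]] = []
    for key, members in groups.items():
        scored = [m for m in members if m[1].am_score is not None]
        if not scored:
            logger.warning("group %s: all pathogenicity scores missing; dropped", key)
            continue
        kept.append(
            min(scored, key=lambda m: (-m[1].am_score, m[1].position, m[1].alt_aa))
        )
    return kept


def trim_low_confidence(
    chain: StructureChain, window: int = 10, threshold: float = 50.0
) -> np.ndarray:
    """Boolean keep-mask over the chain's residues: a residue is removed iff
    it belongs to at least one contiguous window of ``window`` residues
    whose mean pLDDT is below ``threshold``.

    Chains shorter than the window are judged by their whole-chain mean.
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    if len(chain) == 0:
        raise EmptyInputError("cannot trim an empty chain")
    plddt = chain.plddt
    n = len(plddt)
    if n < window:
        return np.full(n, plddt.mean() >= threshold)
    # Window means via cumulative sum; window w starts at residue position w.
    csum = np.concatenate([[0.0], np.cumsum(plddt)])
    means = (csum[window:] - csum[:-window]) / window
    bad_start = means < threshold
    keep = np.ones(n, dtype=bool)
    for w in np.flatnonzero(bad_start):
        keep[w : w + window] = False
    return keep


def assign_mechanism(
    variant: VariantRecord,
    pocket_sets: Mapping[str, frozenset | set],
    interface_sets: Mapping[str, frozenset | set],
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> MechanismCall:
    """Assign one primary mechanism to a pathogenic variant.

    Default precedence: destabilising DDG -> stability; else position inside
    any filtered pocket -> pocket; else inside any confident interface ->
    interface; else unclassified.
    """
    if variant.pathogenicity_class != "pathogenic":
        raise ValidationError("mechanism calls are defined for pathogenic variants only")
    if set(precedence) != set(DEFAULT_PRECEDENCE):
        raise ValidationError(f"precedence must be a permutation of {DEFAULT_PRECEDENCE}")
    known = variant.protein_id in pocket_sets or variant.protein_id in interface_sets
    if not known:
        logger.warning("protein %s has no residue annotations", variant.protein_id)
    hits = {
        "stability": variant.stability_class == "destabilising",
        "pocket": variant.position in pocket_sets.get(variant.protein_id, ()),
        "interface": variant.position in interface_sets.get(variant.protein_id, ()),
    }
    evidence = tuple(k for k, v in hits.items() if v)
    for mech in precedence:
        if hits[mech]:
            return MechanismCall(variant=variant, mechanism=mech, evidence=evidence)
    return MechanismCall(variant=variant, mechanism="unclassified", evidence=())


def vep_stability_auc(
    variants: pd.DataFrame,
    score_columns: Sequence[str],
    label_column: str = "stability_class",
) -> tuple[pd.DataFrame, int]:
    """Per-protein ROC AUC of each predictor score for separating
    destabilising from neutral variants.

    ``variants`` needs a ``protein_id`` column, the score columns and a
    stability-class column.  Proteins lacking either label are skipped;
    the skip count is returned alongside the AUC table.
    """
    rows, skipped = [], 0
    for pid, grp in variants.groupby("protein_id"):
        grp = grp[grp[label_column].isin(["destabilising", "neutral"])]
        labels = (grp[label_column] == "destabilising").to_numpy(int)
        if labels.sum() == 0 or labels.sum() == len(labels):
            skipped += 1
            continue
        row = {"protein_id": pid, "n_variants": len(grp)}
        try:
            for col in score_columns:
                row[f"auc_{col}"] = roc_auc(grp[col].to_numpy(float), labels)
        except UndefinedAUCError:
            skipped += 1
            continue
        rows.append(row)
    return pd.DataFrame(rows), skipped


@dataclass
class TriageTable:
    """Contingency counts plus row- and column-conditional percentages."""

    counts: pd.DataFrame
    row_percent: pd.DataFrame
    col_percent: pd.DataFrame

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def to_flows(self) -> pd.DataFrame:
        """Long-form (source, target, count) table for Sankey-style plots."""
        flows = self.counts.stack().reset_index()
        flows.columns = ["source", "target", "count"]
        return flows[flows["count"] > 0].reset_index(drop=True)


def crosstab(items: pd.DataFrame, row_field: str, col_field: str) -> TriageTable:
    """Two-way contingency table over any pair of categorical columns,
    e.g. stability_class x pathogenicity_class or pathogenicity x mechanism."""
    if items.empty:
        empty = pd.DataFrame()
        return TriageTable(counts=empty, row_percent=empty, col_percent=empty)
    counts = pd.crosstab(items[row_field], items[col_field])
    row_pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    col_pct = counts.div(counts.sum(axis=0), axis=1) * 100.0
    return TriageTable(counts=counts, row_percent=row_pct, col_percent=col_pct)
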
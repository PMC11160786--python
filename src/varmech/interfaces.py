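"""Two-chain complex analysis: interface detection, pDockQ confidence,
disruption-mutation enrichment and interface-mode clustering.

Two distinct interface definitions coexist on purpose:

* annotation/enrichment/clustering use the all-atom rule — a residue is at
  the interface iff any of its atoms lies strictly within the cutoff
  (default 5 A) of any atom of the partner chain;
* pDockQ uses representative-atom contacts at < 8 A (the single
  pseudo-atom of synthetic residues; Cb, or Ca for glycine, in full-atom
  chains).

pDockQ = L / (1 + exp(-k (x - x0))) + b with x = mean interface pLDDT x
ln(contact count) and the constants L = 0.724, x0 = 152.611, k = 0.052,
b = 0.018 adopted from the score's source publication.  With zero contacts
the score is the sigmoid floor b.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import cdist, pdist

from .errors import EmptyInputError, InsufficientDataError, ValidationError
from .stats import ContingencyTable2x2, fisher_exact
from .structures import StructureChain

logger = logging.getLogger(__name__)

INTERFACE_CUTOFF = 5.0   # A, all-atom annotation rule
PDOCKQ_CONTACT_CUTOFF = 8.0  # A, representative-atom contact rule
PDOCKQ_L = 0.724
PDOCKQ_X0 = 152.611
PDOCKQ_K = 0.052
PDOCKQ_B = 0.018


@dataclass
class ComplexModel:
    """A predicted structure for one protein pair (two chains)."""

    pair_id: tuple[str, str]
    chain_a: StructureChain
    chain_b: StructureChain
    pdockq: Optional[float] = None
    confidence_bin: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.chain_a) == 0 or len(self.chain_b) == 0:
            raise EmptyInputError("complex chains must be non-empty")


@dataclass
class InterfaceMap:
    """Interface residues of both chains at one distance cutoff, with the
    minimal inter-chain distance recorded per interface residue."""

    cutoff: float
    residues_a: frozenset[int]
    residues_b: frozenset[int]
    min_distance_a: dict[int, float] = field(default_factory=dict)
    min_distance_b: dict[int, float] = field(default_factory=dict)
    mean_plddt: float = float("nan")
    contact_count: int = 0


def interface_residues(model: ComplexModel, cutoff: float = INTERFACE_CUTOFF) -> InterfaceMap:
    """All-atom interface detection at a strict distance cutoff."""
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    ca, oa = model.chain_a.atom_coords()
    cb, ob = model.chain_b.atom_coords()
    d = cdist(ca, cb)
    amin = d.min(axis=1)
    bmin = d.min(axis=0)
    res_a: dict[int, float] = {}
    for idx, dist in zip(oa, amin):
        res_a[idx] = min(res_a.get(idx, np.inf), dist)
    res_b: dict[int, float] = {}
    for idx, dist in zip(ob, bmin):
        res_b[idx] = min(res_b.get(idx, np.inf), dist)
    ra = frozenset(i for i, v in res_a.items() if v < cutoff)
    rb = frozenset(i for i, v in res_b.items() if v < cutoff)
    plddts = [model.chain_a.residue(i).plddt for i in ra] + [
        model.chain_b.residue(i).plddt for i in rb
    ]
    return InterfaceMap(
        cutoff=cutoff,
        residues_a=ra,
        residues_b=rb,
        min_distance_a={i: float(res_a[i]) for i in ra},
        min_distance_b={i: float(res_b[i]) for i in rb},
        mean_plddt=float(np.mean(plddts)) if plddts else float("nan"),
        contact_count=int((d < cutoff).sum()),
    )


def _representative_coords(chain: StructureChain) -> np.ndarray:
    """One representative atom per residue: Cb, falling back to Ca
    (glycine), falling back to the first atom (synthetic pseudo-residues)."""
    coords = []
    for r in chain.residues:
        by_name = {a.name: a for a in r.atoms}
        a = by_name.get("CB") or by_name.get("CA") or r.atoms[0]
        coords.append((a.x, a.y, a.z))
    return np.asarray(coords, dtype=float)


def pdockq_from_interface(mean_plddt: float, n_contacts: int) -> float:
    """The pDockQ sigmoid on its two summary statistics; the floor value b
    with zero contacts."""
    if n_contacts < 0:
        raise ValidationError("contact count cannot be negative")
    if n_contacts == 0:
        return PDOCKQ_B
    x = mean_plddt * math.log(n_contacts)
    return PDOCKQ_L / (1.0 + math.exp(-PDOCKQ_K * (x - PDOCKQ_X0))) + PDOCKQ_B


def pdockq(model: ComplexModel) -> float:
    """Sigmoid interface-confidence score of a two-chain model.

    Contacts are representative-atom pairs at < 8 A; the interface pLDDT
    average runs over residues involved in at least one contact.  Returns
    the floor value b when there are no contacts.  Symmetric in chain
    order.
    """
    ra = _representative_coords(model.chain_a)
    rb = _representative_coords(model.chain_b)
    d = cdist(ra, rb)
    contacts = d < PDOCKQ_CONTACT_CUTOFF
    n_contacts = int(contacts.sum())
    if n_contacts == 0:
        return PDOCKQ_B
    ia = contacts.any(axis=1)
    ib = contacts.any(axis=0)
    plddt = np.concatenate([model.chain_a.plddt[ia], model.chain_b.plddt[ib]])
    return pdockq_from_interface(float(plddt.mean()), n_contacts)


def bin_pdockq(score: float) -> str:
    """poor (< 0.23) / weak ([0.23, 0.5]) / confident (> 0.5)."""
    if not 0.0 <= score <= 1.0:
        raise ValidationError(f"pDockQ {score} outside [0, 1]")
    if score < 0.23:
        return "poor"
    if score <= 0.5:
        return "weak"
    return "confident"


def select_best_model(models: Sequence[ComplexModel]) -> ComplexModel:
    """Highest-pDockQ model for one pair; ties keep the earliest in input
    order.  Scores are computed on demand if unset."""
    if not models:
        raise EmptyInputError("no models for this pair")
    best, best_score = None, -np.inf
    for m in models:
        score = m.pdockq if m.pdockq is not None else pdockq(m)
        m.pdockq = score
        if score > best_score:
            best, best_score = m, score
    best.confidence_bin = bin_pdockq(best.pdockq)
    return best


def residue_min_distance(model: ComplexModel, chain_id: str, residue_index: int) -> float:
    """Minimum all-atom distance from one residue to the other chain."""
    if chain_id == model.chain_a.chain_id:
        this, other = model.chain_a, model.chain_b
    elif chain_id == model.chain_b.chain_id:
        this, other = model.chain_b, model.chain_a
    else:
        raise KeyError(f"model has no chain {chain_id!r}")
    res = this.residue(residue_index)  # KeyError if absent
    rc = np.array([[a.x, a.y, a.z] for a in res.atoms])
    oc, _ = other.atom_coords()
    return float(cdist(rc, oc).min())


def disruption_enrichment(
    mutations: pd.DataFrame,
    models: Mapping[tuple[str, str], ComplexModel],
    cutoffs: Sequence[float] = (5.0,),
    plddt_filter: Optional[float] = None,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Enrichment of interaction-disrupting mutations at interface residues.

    ``mutations`` columns: pair (tuple key into ``models``), chain_id,
    position, disrupting (bool: disrupts/decreases the interaction vs no
    effect).  With ``plddt_filter`` set, interface residues below that
    pLDDT are excluded from the interface class (they count as
    non-interface), mirroring a low-confidence exclusion at 70.
    """
    if mutations.empty:
        return pd.DataFrame()
    rows = []
    for cutoff in cutoffs:
        maps = {key: interface_residues(m, cutoff) for key, m in models.items()}
        a = b = c = d = 0
        for _, mut in mutations.iterrows():
            model = models.get(mut["pair"])
            if model is None:
                continue
            imap = maps[mut["pair"]]
            if mut["chain_id"] == model.chain_a.chain_id:
                iface, chain = imap.residues_a, model.chain_a
            else:
                iface, chain = imap.residues_b, model.chain_b
            at_iface = mut["position"] in iface
            if at_iface and plddt_filter is not None:
                if chain.residue(mut["position"]).plddt < plddt_filter:
                    at_iface = False
            if mut["disrupting"] and at_iface:
                a += 1
            elif mut["disrupting"]:
                b += 1
            elif at_iface:
                c += 1
            else:
                d += 1
        odds, p = fisher_exact(ContingencyTable2x2(a, b, c, d), alternative)
        rows.append({"cutoff": cutoff, "plddt_filter": plddt_filter,
                     "a": a, "b": b, "c": c, "d": d, "odds_ratio": odds, "p": p})
    return pd.DataFrame(rows)


@dataclass
class HubClustering:
    """Binding-mode clustering of one receptor's partner footprints."""

    receptor_id: str
    partners: list[str]
    residue_columns: list[int]
    footprints: np.ndarray  # (n_partners, n_residues) binary
    linkage: np.ndarray
    labels: np.ndarray  # flat cluster label per partner
    cluster_sizes: dict[int, int]

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)


def cluster_partner_interfaces(
    receptor_id: str,
    partner_footprints: Mapping[str, frozenset[int] | set],
    min_partners: int = 5,
    distance_threshold: float = 0.7,
) -> HubClustering:
    """Cluster partner interface footprints on a hub receptor into binding
    modes: Jaccard distance between binary footprints, average-linkage
    hierarchical clustering, flat cut at ``distance_threshold``.

    Hubs with fewer than ``min_partners`` partners are not clustered
    (the caller should catch InsufficientDataError and skip).
    """
    partners = sorted(partner_footprints)
    if len(partners) < min_partners:
        raise InsufficientDataError(
            f"hub {receptor_id}: {len(partners)} partners < min_partners={min_partners}"
        )
    columns = sorted(set().union(*partner_footprints.values()))
    if not columns:
        raise EmptyInputError(f"hub {receptor_id}: all footprints empty")
    col_of = {r: j for j, r in enumerate(columns)}
    X = np.zeros((len(partners), len(columns)), dtype=bool)
    for i, p in enumerate(partners):
        for r in partner_footprints[p]:
            X[i, col_of[r]] = True
    dist = pdist(X, metric="jaccard")
    Z = sch.linkage(dist, method="average")
    labels = sch.fcluster(Z, t=distance_threshold, criterion="distance")
    sizes = {int(k): int(v) for k, v in zip(*np.unique(labels, return_counts=True))}
    return HubClustering(
        receptor_id=receptor_id,
        partners=partners,
        residue_columns=columns,
        footprints=X,
        linkage=Z,
        labels=labels,
        cluster_sizes=sizes,
    )


def top_cluster_fractions(clusterings: Sequence[HubClustering], top: int = 3) -> pd.DataFrame:
    """Per hub, the fraction of partners falling in the 1st, 2nd, 3rd ...
    most-populated binding-mode clusters (0 where absent)."""
    rows = []
    for hc in clusterings:
        sizes = sorted(hc.cluster_sizes.values(), reverse=True)
        n = sum(sizes)
        row = {"receptor_id": hc.receptor_id, "n_partners": n, "n_clusters": len(sizes)}
        for k in range(top):
            row[f"fraction_rank{k + 1}"] = sizes[k] / n if k < len(sizes) else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def interface_fraction(protein_length: int, interface_set: frozenset[int] | set) -> float:
    """Fraction of a protein's residues buried in the interaction interface."""
    if protein_length <= 0:
        raise ValidationError("protein length must be positive")
    return len(interface_set) / protein_length
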
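"""Synthetic inputs with planted ground truth.

Every input the real study obtained from external tools — AlphaFold-style
structures with per-residue confidence, variant tables with pathogenicity
and stability scores, pocket predictions, two-chain complex models, hub
receptors with multiple binding modes, and multi-omics cohorts with batch
effects — is generated here with a known planted truth, so each downstream
stage can be tested end to end without downloads.

Geometry is deliberately schematic: residues are single pseudo-atoms
(named CB) spaced RESIDUE_SPACING = 9 A apart along a line, so that a
planted inter-chain contact placed at CONTACT_DISTANCE = 4 A is strictly
below the 5 A interface rule while every non-planted inter-chain pair
stays above 8 A by construction.  All distance-based operations work on
atoms, so these single-point chains exercise exactly the same code paths
as full-atom structures.

All generators are bit-reproducible given a seed, and planted truth is
returned (and written) separately from the data — no downstream stage
reads it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .interfaces import ComplexModel
from .pockets import PocketRecord
from .records import VariantRecord
from .structures import StructureChain, single_point_chain

RESIDUE_SPACING = 9.0   # A between consecutive pseudo-residues
CHAIN_SEPARATION = 30.0  # A between the two chains of a complex, off-interface
CONTACT_DISTANCE = 4.0  # A for planted contacts (< 5 A interface rule)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# GISTIC copy-number states and their default population frequencies.
CNV_STATES = np.array([-2, -1, 0, 1, 2])
CNV_FREQS = np.array([0.02, 0.18, 0.60, 0.18, 0.02])


# ---------------------------------------------------------------------------
# Proteome


@dataclass
class SyntheticProtein:
    protein_id: str
    chain: StructureChain
    pocket_truth: frozenset[int]
    interface_truth: frozenset[int]

    @property
    def length(self) -> int:
        return len(self.chain)


@dataclass
class SyntheticProteome:
    proteins: list[SyntheticProtein]
    seed: int
    low_conf_rate: float

    def __getitem__(self, i: int) -> SyntheticProtein:
        return self.proteins[i]

    def __len__(self) -> int:
        return len(self.proteins)

    def chains(self) -> dict[str, StructureChain]:
        return {p.protein_id: p.chain for p in self.proteins}

    def lengths(self) -> dict[str, int]:
        return {p.protein_id: p.length for p in self.proteins}


def _smooth_plddt(rng: np.random.Generator, n: int) -> np.ndarray:
    """Piecewise-smooth high-confidence profile in [60, 98]."""
    base = rng.normal(82.0, 8.0, size=n + 12)
    kernel = np.ones(13) / 13.0
    smooth = np.convolve(base, kernel, mode="same")[6:n + 6]
    return np.clip(smooth + rng.normal(0.0, 1.0, size=n), 60.0, 98.0)


def generate_proteome(
    n_proteins: int = 20,
    length_range: tuple[int, int] = (80, 200),
    low_conf_rate: float = 0.2,
    seed: int = 0,
    pocket_size: int = 8,
    interface_size: int = 10,
) -> SyntheticProteome:
    """Proteins with smooth pLDDT profiles, optional contiguous
    low-confidence stretches (< 50) at the stated per-protein rate, and
    planted pocket / interface residue sets on confident regions."""
    if n_proteins < 1:
        raise ValidationError("n_proteins must be >= 1")
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValidationError(f"invalid length_range {length_range}")
    if not 0.0 <= low_conf_rate <= 1.0:
        raise ValidationError("low_conf_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    proteins = []
    for k in range(n_proteins):
        n = int(rng.integers(lo, hi + 1))
        plddt = _smooth_plddt(rng, n)
        stretch: set[int] = set()
        if rng.random() < low_conf_rate and n >= 12:
            length = int(rng.integers(12, min(31, n + 1)))
            start = int(rng.integers(0, n - length + 1))
            plddt[start:start + length] = rng.uniform(22.0, 45.0, size=length)
            stretch = set(range(start + 1, start + length + 1))
        coords = np.column_stack([
            np.arange(n) * RESIDUE_SPACING, np.zeros(n), np.zeros(n)])
        aas = [AMINO_ACIDS[i] for i in rng.integers(0, 20, size=n)]
        chain = single_point_chain("A", coords, plddt, amino_acids=aas)

        def plant(size: int, exclude: set[int]) -> frozenset[int]:
            candidates = [i for i in range(1, n + 1)
                          if i not in stretch and i not in exclude]
            if len(candidates) < size:
                candidates = [i for i in range(1, n + 1) if i not in exclude]
            chosen = rng.choice(candidates, size=min(size, len(candidates)),
                                replace=False)
            return frozenset(int(i) for i in chosen)

        pocket = plant(pocket_size, set())
        iface = plant(interface_size, set(pocket))
        proteins.append(SyntheticProtein(
            protein_id=f"P{k + 1:04d}", chain=chain,
            pocket_truth=pocket, interface_truth=iface))
    return SyntheticProteome(proteins=proteins, seed=seed, low_conf_rate=low_conf_rate)


def pockets_from_truth(
    proteome: SyntheticProteome,
    raw_score: float = 900.0,
    decoy_raw_score: Optional[float] = None,
    seed: int = 0,
) -> list[PocketRecord]:
    """One true pocket per protein (fill points CONTACT-offset from each
    planted pocket residue, so the derived residue set equals the truth)
    plus, optionally, a decoy pocket on random non-pocket residues."""
    rng = np.random.default_rng(seed)
    records = []
    for prot in proteome.proteins:
        coords = {r.index: r.atoms[0].pos for r in prot.chain.residues}
        fills = np.array([coords[i] + (0.0, 2.0, 0.0) for i in sorted(prot.pocket_truth)])
        records.append(PocketRecord(prot.protein_id, "true", fills, raw_score))
        if decoy_raw_score is not None:
            others = [i for i in coords if i not in prot.pocket_truth]
            chosen = rng.choice(others, size=min(len(prot.pocket_truth), len(others)),
                                replace=False)
            fills_d = np.array([coords[int(i)] + (0.0, -2.0, 0.0) for i in sorted(chosen)])
            records.append(PocketRecord(prot.protein_id, "decoy", fills_d,
                                        decoy_raw_score))
    return records


# ---------------------------------------------------------------------------
# Variants


def generate_variant_table(
    proteome: SyntheticProteome,
    n_variants: int = 200,
    frac_pathogenic: float = 0.3,
    frac_destabilising: float = 0.5,
    placement_odds: float = 1.0,
    seed: int = 0,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Variant table with a bimodal pathogenicity-score mixture and DDG
    distributions tied to a planted mechanism.

    Benign scores are drawn strictly below 0.34, pathogenic strictly above
    0.564.  A pathogenic variant is destabilising (DDG > 2 kcal/mol) with
    probability ``frac_destabilising``; pathogenic variants are placed on
    planted pocket/interface residues with the stated odds (1 = uniform).
    Returns the records plus a truth table with the planted mechanism per
    variant (same precedence as the triage: stability > pocket >
    interface) and a flag marking variants whose position sits in both a
    pocket and an interface set.
    """
    if len(proteome) == 0:
        raise ValidationError("empty proteome")
    if not 0.0 <= frac_pathogenic <= 1.0 or not 0.0 <= frac_destabilising <= 1.0:
        raise ValidationError("fractions must lie in [0, 1]")
    if placement_odds <= 0:
        raise ValidationError("placement_odds must be positive")
    rng = np.random.default_rng(seed)
    records, truth = [], []
    for _ in range(n_variants):
        prot = proteome.proteins[int(rng.integers(0, len(proteome)))]
        n = prot.length
        pathogenic = rng.random() < frac_pathogenic
        weights = np.ones(n)
        if pathogenic and placement_odds != 1.0:
            functional = np.array(sorted(prot.pocket_truth | prot.interface_truth)) - 1
            weights[functional] = placement_odds
        pos = int(rng.choice(np.arange(1, n + 1), p=weights / weights.sum()))
        ref = prot.chain.residue(pos).amino_acid
        alt = rng.choice([a for a in AMINO_ACIDS if a != ref])
        if pathogenic:
            am = 0.564 + (1.0 - 0.564) * rng.beta(2.0, 2.0)
            if rng.random() < frac_destabilising:
                ddg = 2.0 + rng.exponential(1.5)
            else:
                ddg = float(np.clip(rng.normal(0.0, 0.8), -1.9, 1.9))
        else:
            am = 0.34 * rng.beta(2.0, 4.0)
            ddg = float(np.clip(rng.normal(0.0, 0.6), -1.9, 1.9))
        rec = VariantRecord(protein_id=prot.protein_id, position=pos,
                            ref_aa=ref, alt_aa=str(alt),
                            am_score=float(am), ddg=float(ddg))
        in_pocket = pos in prot.pocket_truth
        in_iface = pos in prot.interface_truth
        if not pathogenic:
            mech = ""
        elif ddg > 2.0:
            mech = "stability"
        elif in_pocket:
            mech = "pocket"
        elif in_iface:
            mech = "interface"
        else:
            mech = "unclassified"
        records.append(rec)
        truth.append({"protein_id": prot.protein_id, "position": pos,
                      "alt_aa": str(alt), "pathogenic": pathogenic,
                      "planted_mechanism": mech,
                      "ambiguous_site": in_pocket and in_iface})
    return records, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Complexes and hubs


def generate_complex(
    len_a: int,
    len_b: int,
    n_contact_pairs: int = 0,
    interface_plddt: float = 90.0,
    seed: int = 0,
    contact_pairs: Optional[Sequence[tuple[int, int]]] = None,
    pair_id: tuple[str, str] = ("A", "B"),
    base_plddt: tuple[float, float] = (60.0, 95.0),
) -> tuple[ComplexModel, list[tuple[int, int]]]:
    """Two single-point chains with exactly the requested residue pairs in
    contact (< 5 A) and every other inter-chain pair > 8 A.

    Chain A lies along the x axis at 9 A spacing; chain B runs parallel at
    30 A separation, and each planted B residue is moved to 4 A from its A
    partner.  Contact pairs may be given explicitly (1-based, distinct A
    and distinct B indices) or drawn at random.  Interface residues on
    both chains carry ``interface_plddt`` exactly.
    """
    if len_a < 1 or len_b < 1:
        raise ValidationError("chain lengths must be >= 1")
    rng = np.random.default_rng(seed)
    if contact_pairs is None:
        if n_contact_pairs > min(len_a, len_b):
            raise ValidationError("more contacts requested than residues available")
        ia = rng.choice(len_a, size=n_contact_pairs, replace=False) + 1
        ib = rng.choice(len_b, size=n_contact_pairs, replace=False) + 1
        contact_pairs = list(zip(ia.tolist(), ib.tolist()))
    else:
        contact_pairs = [(int(a), int(b)) for a, b in contact_pairs]
        a_idx = [a for a, _ in contact_pairs]
        b_idx = [b for _, b in contact_pairs]
        if len(set(a_idx)) != len(a_idx) or len(set(b_idx)) != len(b_idx):
            raise ValidationError("contact pairs must use distinct residues per chain")
        if any(not 1 <= a <= len_a for a in a_idx) or any(not 1 <= b <= len_b for b in b_idx):
            raise ValidationError("contact pair index out of range")

    xa = np.column_stack([np.arange(len_a) * RESIDUE_SPACING,
                          np.zeros(len_a), np.zeros(len_a)])
    xb = np.column_stack([np.arange(len_b) * RESIDUE_SPACING,
                          np.full(len_b, CHAIN_SEPARATION), np.zeros(len_b)])
    for a, b in contact_pairs:
        xb[b - 1] = (xa[a - 1][0], CONTACT_DISTANCE, 0.0)

    pa = rng.uniform(*base_plddt, size=len_a)
    pb = rng.uniform(*base_plddt, size=len_b)
    for a, b in contact_pairs:
        pa[a - 1] = interface_plddt
        pb[b - 1] = interface_plddt
    chain_a = single_point_chain("A", xa, pa)
    chain_b = single_point_chain("B", xb, pb)
    model = ComplexModel(pair_id=pair_id, chain_a=chain_a, chain_b=chain_b)
    return model, sorted(contact_pairs)


@dataclass
class SyntheticHub:
    """A receptor with partners planted in a known number of binding modes."""

    receptor_id: str
    partner_models: list[ComplexModel]
    partner_modes: dict[str, int]
    footprints: dict[str, frozenset[int]]
    n_modes: int


def generate_hub(
    n_partners: int = 14,
    n_modes: int = 3,
    mode_overlap: float = 0.0,
    receptor_len: int = 150,
    partner_len: int = 60,
    footprint_size: int = 16,
    seed: int = 0,
    receptor_id: str = "HUB",
) -> SyntheticHub:
    """Receptor with its partner footprints partitioned into ``n_modes``
    disjoint residue regions.

    Each partner is assigned a mode and keeps a random (1 - overlap/2)
    fraction of its mode's footprint, so any two same-mode partners share
    at least (1 - overlap) of their residues while footprints of
    different modes stay disjoint."""
    if n_modes > n_partners:
        raise ValidationError("n_modes cannot exceed n_partners")
    if n_modes < 1:
        raise ValidationError("need at least one mode")
    if not 0.0 <= mode_overlap <= 1.0:
        raise ValidationError("mode_overlap must lie in [0, 1]")
    gap = 3
    if n_modes * (footprint_size + gap) > receptor_len:
        raise ValidationError("receptor too short for the requested modes")
    rng = np.random.default_rng(seed)
    mode_regions = [
        list(range(m * (footprint_size + gap) + 1,
                   m * (footprint_size + gap) + footprint_size + 1))
        for m in range(n_modes)
    ]
    # Every mode gets at least one partner; the rest are assigned at random.
    assignment = list(range(n_modes)) + [
        int(rng.integers(0, n_modes)) for _ in range(n_partners - n_modes)]
    rng.shuffle(assignment)

    n_drop = int(np.floor(footprint_size * mode_overlap / 2.0))
    models, modes, footprints = [], {}, {}
    for k, mode in enumerate(assignment):
        pid = f"PARTNER{k + 1:02d}"
        region = mode_regions[mode]
        drop = set(rng.choice(region, size=n_drop, replace=False).tolist()) if n_drop else set()
        fp = frozenset(r for r in region if r not in drop)
        pairs = [(r, j + 1) for j, r in enumerate(sorted(fp))]
        model, _ = generate_complex(
            receptor_len, partner_len, contact_pairs=pairs,
            seed=int(rng.integers(0, 2**31)), pair_id=(receptor_id, pid))
        models.append(model)
        modes[pid] = mode
        footprints[pid] = fp
    return SyntheticHub(receptor_id=receptor_id, partner_models=models,
                        partner_modes=modes, footprints=footprints,
                        n_modes=n_modes)


# ---------------------------------------------------------------------------
# Multi-omics


@dataclass
class PlantedOmicsTruth:
    """Generative truth of a synthetic cohort: directed pairs with their
    true partner-control coefficient, batch offsets and noise scales."""

    pairs: pd.DataFrame  # columns x, y, beta2
    batch_effects: pd.DataFrame  # batch x modality offsets (per gene draws summarised)
    noise: dict[str, float]
    beta1: float = 0.8

    def null_pairs(self) -> pd.DataFrame:
        return self.pairs[self.pairs["beta2"] == 0.0]


def generate_multiomics(
    pairs: Sequence[tuple[str, str, float]],
    n_samples: int = 300,
    n_batches: int = 3,
    batch_labels: Optional[Sequence[str]] = None,
    noise: float = 0.5,
    mrna_noise: float = 0.5,
    cnv_slope: float = 0.5,
    beta1: float = 0.8,
    batch_sd: float = 0.3,
    missing_rate: float = 0.05,
    cnv_freqs: np.ndarray = CNV_FREQS,
    mutation_rate: float = 0.0,
    frac_pathogenic: float = 0.3,
    frac_destabilising: float = 0.5,
    destab_shift: float = 0.0,
    seed: int = 0,
    extra_genes: int = 0,
) -> tuple["OmicsDataset", PlantedOmicsTruth]:
    """Sample x gene CNV / mRNA / protein cohort with planted control.

    For every gene g: CNV_g is drawn from the GISTIC frequencies;
    T_g = cnv_slope * CNV_g + batch offset + N(0, mrna_noise);
    P_g = beta1 * T_g + beta2 * CNV_X + batch offset + N(0, noise), where
    the beta2 term exists only for genes planted as the controlled member
    Y of a (X, Y, beta2) pair.  Missingness is injected completely at
    random in mRNA and protein at ``missing_rate``.

    With ``mutation_rate`` > 0, random (sample, gene) missense events are
    planted; a pathogenic + destabilising event shifts that sample's
    protein value by ``destab_shift`` (and only those events do).
    """
    from .abundance import OmicsDataset  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    if batch_labels is not None:
        if len(batch_labels) != n_samples:
            raise ValidationError("need one batch label per sample")
        batch = pd.Series(list(batch_labels))
    else:
        batch = pd.Series([f"batch{i % n_batches}" for i in range(n_samples)])
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    batch.index = samples

    pair_df = pd.DataFrame(pairs, columns=["x", "y", "beta2"])
    genes = list(pd.unique(pd.concat([pair_df["x"], pair_df["y"]])))
    genes += [f"NULLGENE{i + 1:04d}" for i in range(extra_genes)]
    controlled = dict(zip(pair_df["y"], zip(pair_df["x"], pair_df["beta2"])))

    g_index = {g: j for j, g in enumerate(genes)}
    n_genes = len(genes)
    cnv_freqs = np.asarray(cnv_freqs, dtype=float)
    if cnv_freqs.shape != (5,) or not np.isclose(cnv_freqs.sum(), 1.0):
        raise ValidationError("cnv_freqs must be 5 probabilities summing to 1")

    cnv = rng.choice(CNV_STATES, size=(n_samples, n_genes), p=cnv_freqs).astype(float)
    codes, levels = pd.factorize(batch)
    b_mrna = rng.normal(0.0, batch_sd, size=(len(levels), n_genes))
    b_prot = rng.normal(0.0, batch_sd, size=(len(levels), n_genes))
    mrna = (cnv_slope * cnv + b_mrna[codes, :]
            + rng.normal(0.0, mrna_noise, size=(n_samples, n_genes)))
    protein = (beta1 * mrna + b_prot[codes, :]
               + rng.normal(0.0, noise, size=(n_samples, n_genes)))
    for y, (x, beta2) in controlled.items():
        if beta2 != 0.0:
            protein[:, g_index[y]] += beta2 * cnv[:, g_index[x]]

    mutations = []
    if mutation_rate > 0:
        n_events = rng.binomial(n_samples * n_genes, mutation_rate)
        si = rng.integers(0, n_samples, size=n_events)
        gi = rng.integers(0, n_genes, size=n_events)
        seen = set()
        for s, g in zip(si, gi):
            if (s, g) in seen:
                continue
            seen.add((s, g))
            pathogenic = rng.random() < frac_pathogenic
            if pathogenic:
                am = 0.564 + (1.0 - 0.564) * rng.beta(2.0, 2.0)
                destab = rng.random() < frac_destabilising
                ddg = 2.0 + rng.exponential(1.5) if destab \
                    else float(np.clip(rng.normal(0.0, 0.8), -1.9, 1.9))
            else:
                am = 0.34 * rng.beta(2.0, 4.0)
                ddg = float(np.clip(rng.normal(0.0, 0.6), -1.9, 1.9))
                destab = False
            if pathogenic and destab:
                protein[s, g] += destab_shift
            ref = AMINO_ACIDS[int(rng.integers(0, 20))]
            alt = rng.choice([a for a in AMINO_ACIDS if a != ref])
            mutations.append({"sample": samples[s], "gene": genes[g],
                              "position": int(rng.integers(1, 200)),
                              "ref_aa": ref, "alt_aa": str(alt),
                              "am_score": float(am), "ddg": float(ddg)})

    if missing_rate > 0:
        mrna[rng.random(mrna.shape) < missing_rate] = np.nan
        protein[rng.random(protein.shape) < missing_rate] = np.nan

    dataset = OmicsDataset(
        cnv=pd.DataFrame(cnv, index=samples, columns=genes),
        mrna=pd.DataFrame(mrna, index=samples, columns=genes),
        protein=pd.DataFrame(protein, index=samples, columns=genes),
        batch=batch,
        mutations=pd.DataFrame(
            mutations, columns=["sample", "gene", "position", "ref_aa",
                                "alt_aa", "am_score", "ddg"]),
    )
    truth = PlantedOmicsTruth(
        pairs=pair_df,
        batch_effects=pd.DataFrame(
            {"batch": list(levels), "mrna_offset_sd": batch_sd,
             "protein_offset_sd": batch_sd}),
        noise={"mrna": mrna_noise, "protein": noise},
        beta1=beta1,
    )
    return dataset, truth
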
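"""Tab-separated readers/writers for the package's table formats."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .abundance import OmicsDataset
from .errors import FormatError
from .pockets import PocketRecord
from .records import VariantRecord

VARIANT_COLUMNS = ["protein_id", "position", "ref_aa", "alt_aa", "am_score",
                   "ddg", "pathogenicity_class", "stability_class"]


def write_variants(variants: Iterable[VariantRecord], path: str | Path) -> None:
    rows = [{c: getattr(v, c) for c in VARIANT_COLUMNS} for v in variants]
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variants(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(VARIANT_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise FormatError(f"variant table {path} lacks columns {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        out.append(VariantRecord(
            protein_id=str(r["protein_id"]), position=int(r["position"]),
            ref_aa=str(r["ref_aa"]), alt_aa=str(r["alt_aa"]),
            am_score=None if pd.isna(r.get("am_score")) else float(r["am_score"]),
            ddg=None if pd.isna(r.get("ddg")) else float(r["ddg"]),
            pathogenicity_class=r.get("pathogenicity_class") if not pd.isna(r.get("pathogenicity_class")) else None,
            stability_class=r.get("stability_class") if not pd.isna(r.get("stability_class")) else None,
        ))
    return out


def write_pockets(pockets: Sequence[PocketRecord], path: str | Path) -> None:
    rows = []
    for p in pockets:
        rows.append({
            "protein_id": p.protein_id,
            "pocket_id": p.pocket_id,
            "raw_score": p.raw_score,
            "mean_plddt": p.mean_plddt,
            "combined_score": p.combined_score,
            "residues": ",".join(str(i) for i in sorted(p.residue_set or ())),
            "fill_points": ";".join(
                ",".join(f"{v:.3f}" for v in pt) for pt in p.fill_points),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pockets(path: str | Path) -> list[PocketRecord]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        try:
            fills = np.array([[float(v) for v in pt.split(",")]
                              for pt in str(r["fill_points"]).split(";")])
        except (KeyError, ValueError) as exc:
            raise FormatError(f"bad fill_points in {path}: {exc}") from exc
        rec = PocketRecord(protein_id=str(r["protein_id"]),
                           pocket_id=str(r["pocket_id"]),
                           fill_points=fills, raw_score=float(r["raw_score"]))
        if "residues" in r and isinstance(r["residues"], str) and r["residues"]:
            rec.residue_set = frozenset(int(i) for i in r["residues"].split(","))
        out.append(rec)
    return out


def write_omics(dataset: OmicsDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.cnv.to_csv(out / "cnv.tsv", sep="\t")
    dataset.mrna.to_csv(out / "mrna.tsv", sep="\t")
    dataset.protein.to_csv(out / "protein.tsv", sep="\t")
    dataset.batch.rename("batch").to_frame().to_csv(out / "samples.tsv", sep="\t")
    dataset.mutations.to_csv(out / "mutations.tsv", sep="\t", index=False)


def read_omics(in_dir: str | Path) -> OmicsDataset:
    d = Path(in_dir)
    try:
        cnv = pd.read_csv(d / "cnv.tsv", sep="\t", index_col=0)
        mrna = pd.read_csv(d / "mrna.tsv", sep="\t", index_col=0)
        protein = pd.read_csv(d / "protein.tsv", sep="\t", index_col=0)
        samples = pd.read_csv(d / "samples.tsv", sep="\t", index_col=0)
    except FileNotFoundError as exc:
        raise FormatError(f"omics directory {d} incomplete: {exc}") from exc
    mut_path = d / "mutations.tsv"
    mutations = pd.read_csv(mut_path, sep="\t") if mut_path.exists() else None
    kwargs = {} if mutations is None else {"mutations": mutations}
    return OmicsDataset(cnv=cnv, mrna=mrna, protein=protein,
                        batch=samples["batch"], **kwargs)
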
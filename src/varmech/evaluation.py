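"""Self-contained evaluation experiments on synthetic data.

Each function runs one calibration or recovery experiment end to end —
generate inputs with planted truth, run the corresponding analysis stage,
measure the outcome — and returns plain numbers.  They back both the test
suite and the reproduction script.  Problem sizes are chosen so the full
battery completes on a laptop in minutes; see docs/methods.md.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .abundance import fit_residual_model, nested_lrt, residuals_by_class, screen_interactions
from .interfaces import cluster_partner_interfaces, interface_residues
from .mechanisms import assign_mechanism, classify_variants
from .pockets import pocket_residues
from .structures import single_point_chain
from .synthetic import (
    generate_hub,
    generate_multiomics,
    generate_proteome,
    generate_variant_table,
)


def lrt_identity_max_error(n_instances: int = 1000, seed: int = 0) -> float:
    """Max |LRT_loglik - n*log(RSS0/RSSA)| over random regression
    instances with n in [50, 300]."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(50, 301))
        ty = rng.normal(size=n)
        cnv = rng.choice([-2, -1, 0, 1, 2], size=n).astype(float)
        batch = rng.choice(["b0", "b1", "b2"], size=n)
        beta2 = rng.choice([0.0, 0.3, 0.6])
        py = 0.8 * ty + beta2 * cnv + rng.normal(scale=0.7, size=n)
        res = nested_lrt(py, ty, cnv, batch)
        worst = max(worst, abs(res.lrt - res.lrt_rss))
    return worst


def null_pvalue_calibration(
    n_pairs: int = 2000, n_samples: int = 200, seed: int = 0
) -> dict:
    """Fraction of null-pair LRT p-values below 0.05 and the KS uniformity
    p-value, under the all-null generator."""
    pairs = [(f"X{i}", f"Y{i}", 0.0) for i in range(n_pairs)]
    dataset, _ = generate_multiomics(pairs, n_samples=n_samples, seed=seed)
    results = screen_interactions(dataset, [(p[0], p[1]) for p in pairs])
    pvals = results["p"].to_numpy()
    ks = scipy.stats.kstest(pvals, "uniform")
    return {
        "n_tests": len(pvals),
        "frac_p_lt_005": float((pvals < 0.05).mean()),
        "ks_p": float(ks.pvalue),
    }


def fdr_and_sensitivity(
    n_reps: int = 200,
    n_null: int = 900,
    n_alt: int = 100,
    beta2: float = 0.5,
    n_samples: int = 300,
    fdr_threshold: float = 0.01,
    seed: int = 0,
) -> dict:
    """Mean false-discovery proportion and sensitivity of the screen at
    BH FDR < 0.01 on replicated null + alternative cohorts."""
    rng = np.random.default_rng(seed)
    fdps, sens = [], []
    pairs = ([(f"AX{i}", f"AY{i}", beta2) for i in range(n_alt)]
             + [(f"NX{i}", f"NY{i}", 0.0) for i in range(n_null)])
    keys = [(p[0], p[1]) for p in pairs]
    for _ in range(n_reps):
        dataset, _ = generate_multiomics(
            pairs, n_samples=n_samples, seed=int(rng.integers(2**31)))
        res = screen_interactions(dataset, keys, fdr_threshold=fdr_threshold)
        sig = res[res["significant"]]
        n_false = int(sig["x"].str.startswith("NX").sum())
        n_true = len(sig) - n_false
        fdps.append(n_false / max(len(sig), 1))
        sens.append(n_true / n_alt)
    return {
        "n_reps": n_reps,
        "mean_fdp": float(np.mean(fdps)),
        "sensitivity": float(np.mean(sens)),
    }


def beta2_recovery(
    n_reps: int = 500, beta2: float = 0.5, n_samples: int = 300, seed: int = 0
) -> dict:
    """Mean estimated partner-control coefficient over replicates."""
    rng = np.random.default_rng(seed)
    est = []
    for _ in range(n_reps):
        dataset, _ = generate_multiomics(
            [("X1", "Y1", beta2)], n_samples=n_samples,
            seed=int(rng.integers(2**31)))
        res = nested_lrt(dataset.protein["Y1"], dataset.mrna["Y1"],
                         dataset.cnv["X1"], dataset.batch)
        est.append(res.beta2)
    return {"n_reps": n_reps, "true_beta2": beta2,
            "mean_estimate": float(np.mean(est)),
            "abs_bias": float(abs(np.mean(est) - beta2))}


def distance_oracle_agreement(
    n_models: int = 100,
    cutoffs: tuple[float, ...] = (4.5, 5.0, 8.0, 10.0),
    seed: int = 0,
) -> dict:
    """Exact agreement of interface/pocket/min-distance operations with
    naive all-pairs distance scans on random single-atom models."""
    rng = np.random.default_rng(seed)
    checks = failures = 0
    for _ in range(n_models):
        na, nb = rng.integers(4, 60, size=2)
        ca = rng.uniform(-30, 30, size=(na, 3))
        cb = rng.uniform(-30, 30, size=(nb, 3))
        chain_a = single_point_chain("A", ca, rng.uniform(30, 98, size=na))
        chain_b = single_point_chain("B", cb, rng.uniform(30, 98, size=nb))
        from .interfaces import ComplexModel, residue_min_distance
        model = ComplexModel(pair_id=("X", "Y"), chain_a=chain_a, chain_b=chain_b)
        d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
        for cutoff in cutoffs:
            imap = interface_residues(model, cutoff)
            exp_a = {i + 1 for i in range(na) if (d[i] < cutoff).any()}
            exp_b = {j + 1 for j in range(nb) if (d[:, j] < cutoff).any()}
            checks += 1
            failures += int(imap.residues_a != exp_a or imap.residues_b != exp_b)
            fills = cb[: min(5, nb)]
            got = pocket_residues(fills, chain_a, cutoff=cutoff)
            exp = {i + 1 for i in range(na)
                   if (np.linalg.norm(ca[i] - fills, axis=1) < cutoff).any()}
            checks += 1
            failures += int(got != exp)
        i = int(rng.integers(0, na))
        checks += 1
        failures += int(abs(residue_min_distance(model, "A", i + 1) - d[i].min()) > 1e-10)
    return {"n_checks": checks, "agreement": 1.0 - failures / checks}


def clustering_mode_recovery(
    n_hubs: int = 100,
    n_partners: int = 14,
    mode_overlap: float = 0.2,
    seed: int = 0,
) -> dict:
    """Fraction of synthetic hubs whose planted number of binding modes
    (cycling 1, 2, 3) is recovered exactly, with footprints derived from
    the generated complex geometry via interface detection."""
    rng = np.random.default_rng(seed)
    exact = 0
    for h in range(n_hubs):
        k = h % 3 + 1
        hub = generate_hub(n_partners=n_partners, n_modes=k,
                           mode_overlap=mode_overlap,
                           seed=int(rng.integers(2**31)))
        footprints = {m.pair_id[1]: interface_residues(m, 5.0).residues_a
                      for m in hub.partner_models}
        hc = cluster_partner_interfaces(hub.receptor_id, footprints)
        exact += int(hc.n_clusters == k)
    return {"n_hubs": n_hubs, "recovery_rate": exact / n_hubs}


def triage_planted_recovery(seed: int = 0, n_variants: int = 400) -> dict:
    """On a noiseless synthetic proteome, the fraction of pathogenic
    variants whose assigned mechanism equals the planted one, plus a
    partition check over mechanism labels."""
    proteome = generate_proteome(n_proteins=15, low_conf_rate=0.0, seed=seed)
    variants, truth = generate_variant_table(
        proteome, n_variants=n_variants, frac_pathogenic=0.5,
        placement_odds=4.0, seed=seed + 1)
    classify_variants(variants)
    pocket_sets = {p.protein_id: p.pocket_truth for p in proteome.proteins}
    iface_sets = {p.protein_id: p.interface_truth for p in proteome.proteins}
    n_path = matched = 0
    counts = {"stability": 0, "pocket": 0, "interface": 0, "unclassified": 0}
    for v, (_, t) in zip(variants, truth.iterrows()):
        if v.pathogenicity_class != "pathogenic":
            continue
        call = assign_mechanism(v, pocket_sets, iface_sets)
        counts[call.mechanism] += 1
        n_path += 1
        matched += int(call.mechanism == t["planted_mechanism"])
    return {
        "n_pathogenic": n_path,
        "recovery_rate": matched / n_path,
        "labels_sum_to_pathogenic": sum(counts.values()) == n_path,
        "mechanism_counts": counts,
    }


def residual_shift_detection(
    n_sims: int = 100, shift: float = -0.5, n_samples: int = 300, seed: int = 0
) -> dict:
    """Detection rate of a planted residual shift in the pathogenic +
    destabilising stratum (and the false-call rate in the pathogenic +
    neutral stratum), plus residual orthogonality diagnostics."""
    rng = np.random.default_rng(seed)
    detected = false_calls = 0
    max_batch_mean = max_ty_cov = 0.0
    for _ in range(n_sims):
        dataset, _ = generate_multiomics(
            [(f"G{i}", f"H{i}", 0.0) for i in range(10)],
            n_samples=n_samples, mutation_rate=0.05, destab_shift=shift,
            missing_rate=0.0, seed=int(rng.integers(2**31)))
        rows = []
        for gene in dataset.genes:
            muts = dataset.mutations[dataset.mutations["gene"] == gene]
            if muts.empty:
                continue
            fit = fit_residual_model(dataset.protein[gene], dataset.mrna[gene],
                                     dataset.batch)
            for b in dataset.batch.unique():
                sel = (dataset.batch == b).reindex(fit.residuals.index, fill_value=False)
                max_batch_mean = max(max_batch_mean,
                                     abs(float(fit.residuals[sel].mean())))
            ty = dataset.mrna[gene].loc[fit.residuals.index]
            max_ty_cov = max(max_ty_cov,
                             abs(float(np.cov(fit.residuals, ty)[0, 1])))
            for _, m in muts.iterrows():
                if m["sample"] not in fit.residuals.index:
                    continue
                am, ddg = m["am_score"], m["ddg"]
                rows.append({
                    "sample": m["sample"], "gene": gene,
                    "residual": fit.residuals[m["sample"]],
                    "pathogenicity_class": "pathogenic" if am > 0.564 else
                        ("benign" if am < 0.34 else "ambiguous"),
                    "stability_class": "destabilising" if ddg > 2 else
                        ("stabilising" if ddg < -2 else "neutral"),
                    "cnv": int(dataset.cnv.loc[m["sample"], gene]),
                })
        summary = residuals_by_class(pd.DataFrame(rows))
        comp = summary[summary["cn_stratum"] == "compensated"].set_index(
            ["pathogenicity_class", "stability_class"])
        ref = comp.loc[("benign", "neutral")]
        tgt = comp.loc[("pathogenic", "destabilising")]
        detected += int(tgt["median"] < ref["median"] and tgt["rank_sum_p"] < 0.05)
        if ("pathogenic", "neutral") in comp.index:
            neu = comp.loc[("pathogenic", "neutral")]
            false_calls += int(neu["median"] < ref["median"]
                               and neu["rank_sum_p"] < 0.05)
    return {
        "n_sims": n_sims,
        "detection_rate": detected / n_sims,
        "neutral_false_call_rate": false_calls / n_sims,
        "max_abs_batch_mean": max_batch_mean,
        "max_abs_ty_cov": max_ty_cov,
    }
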
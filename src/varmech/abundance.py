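"""Multi-omics preprocessing and the nested-linear-model screen for
interaction-mediated control of protein abundance.

The core model: for a protein Y with transcript level T_Y, protein level
P_Y, sample batch C, and a candidate controlling partner X with discretised
copy number CNV_X in {-2..2},

    M0:  P_Y = b0 + b1 T_Y + C bC + e
    MA:  P_Y = b0 + b1 T_Y + b2 CNV_X + C bC + e

are fitted by Gaussian maximum likelihood; LRT = 2(logL_A - logL_0) is
referred to a chi-squared distribution with 1 degree of freedom, and
Benjamini-Hochberg FDR < 0.01 flags pairs where the partner's copy number
helps explain the protein level.  A positive b2 is the signature of
attenuation: unbound subunits of an under-produced complex are degraded,
so the controlled protein tracks its partner's copy number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import (
    DegenerateInputError,
    EmptyInputError,
    InsufficientDataError,
    ValidationError,
)
from .stats import ContingencyTable2x2, bh_fdr, fisher_exact, pearson

logger = logging.getLogger(__name__)

FDR_SIGNIFICANT = 0.01
CIS_DDG_THRESHOLD = 1.5  # kcal/mol, cis-pQTL destabilisation rule


@dataclass
class OmicsDataset:
    """Sample x gene CNV / mRNA / protein matrices with batch labels and
    per-sample mutation lists.

    CNV holds discretised scores in {-2..2} (strong loss, shallow loss,
    diploid, low gain, focal amplification); mRNA and protein are real log
    fold changes; NaN marks missing measurements.
    """

    cnv: pd.DataFrame
    mrna: pd.DataFrame
    protein: pd.DataFrame
    batch: pd.Series  # indexed by sample
    mutations: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["sample", "gene", "position", "ref_aa", "alt_aa", "am_score", "ddg"]
        )
    )

    def __post_init__(self) -> None:
        shape = self.cnv.shape
        if self.mrna.shape != shape or self.protein.shape != shape:
            raise ValidationError("CNV, mRNA and protein matrices must share shape")
        if len(self.batch) != shape[0]:
            raise ValidationError("one batch label per sample required")
        vals = self.cnv.to_numpy(float)
        ok = np.isnan(vals) | np.isin(vals, [-2, -1, 0, 1, 2])
        if not ok.all():
            raise ValidationError("CNV entries must be GISTIC-discretised (-2..2)")

    @property
    def samples(self) -> pd.Index:
        return self.cnv.index

    @property
    def genes(self) -> pd.Index:
        return self.cnv.columns


def _batch_normalise(matrix: pd.DataFrame, batch: pd.Series) -> pd.DataFrame:
    """Remove batch means per gene, then express each value relative to the
    batch median of the centred values.  The composite map is idempotent."""
    out = matrix.copy()
    for _, idx in matrix.groupby(batch).groups.items():
        block = out.loc[idx]
        centred = block - block.mean(axis=0)
        out.loc[idx] = centred - centred.median(axis=0)
    return out


def preprocess(
    dataset: OmicsDataset,
    coverage_min: float = 0.25,
    concordance_min: float = 0.3,
    hypermut_max: int = 500,
) -> tuple[OmicsDataset, pd.DataFrame]:
    """Standard cohort filtering and normalisation.

    1. drop hypermutated samples (> ``hypermut_max`` mutations);
    2. drop genes with < ``coverage_min`` non-missing coverage in any of
       the three modalities;
    3. batch-normalise mRNA and protein to log fold changes;
    4. drop genes whose (normalised) mRNA-protein Pearson r is below
       ``concordance_min`` — genetic changes cannot reach the protein
       level there.

    Returns the filtered dataset and a report listing every removal.
    """
    report: list[dict] = []

    counts = dataset.mutations.groupby("sample").size() if not dataset.mutations.empty \
        else pd.Series(dtype=int)
    hyper = [s for s in dataset.samples if counts.get(s, 0) > hypermut_max]
    for s in hyper:
        report.append({"kind": "sample", "id": s, "reason":
                       f"hypermutated ({counts[s]} > {hypermut_max} mutations)"})
    samples = dataset.samples.difference(hyper, sort=False)
    if samples.empty:
        raise EmptyInputError("all samples removed by the hypermutation filter")

    cnv = dataset.cnv.loc[samples]
    mrna = dataset.mrna.loc[samples]
    protein = dataset.protein.loc[samples]
    batch = dataset.batch.loc[samples]

    keep_genes = []
    for g in dataset.genes:
        covs = {m: float(mat[g].notna().mean()) for m, mat in
                (("cnv", cnv), ("mrna", mrna), ("protein", protein))}
        low = [m for m, v in covs.items() if v < coverage_min]
        if low:
            report.append({"kind": "gene", "id": g, "reason":
                           f"coverage below {coverage_min:.0%} in {','.join(low)}"})
        else:
            keep_genes.append(g)

    mrna = _batch_normalise(mrna[keep_genes], batch)
    protein = _batch_normalise(protein[keep_genes], batch)

    concordant = []
    for g in keep_genes:
        both = mrna[g].notna() & protein[g].notna()
        if both.sum() < 3:
            r = np.nan
        else:
            try:
                r, _ = pearson(mrna.loc[both, g], protein.loc[both, g])
            except DegenerateInputError:
                r = np.nan
        if np.isnan(r) or r < concordance_min:
            report.append({"kind": "gene", "id": g, "reason":
                           f"mRNA-protein concordance r={r:.3f} < {concordance_min}"
                           if not np.isnan(r) else "mRNA-protein concordance undefined"})
        else:
            concordant.append(g)

    muts = dataset.mutations
    if not muts.empty:
        muts = muts[muts["sample"].isin(samples) & muts["gene"].isin(concordant)]
    filtered = OmicsDataset(
        cnv=cnv[concordant], mrna=mrna[concordant], protein=protein[concordant],
        batch=batch, mutations=muts.reset_index(drop=True),
    )
    return filtered, pd.DataFrame(report, columns=["kind", "id", "reason"])


# ---------------------------------------------------------------------------
# Model fitting


def _design(ty: np.ndarray, batch_codes: np.ndarray, n_batches: int,
            cnvx: np.ndarray | None = None) -> np.ndarray:
    """Intercept + TY (+ CNVX) + batch indicator columns (first batch is
    the reference level)."""
    cols = [np.ones_like(ty), ty]
    if cnvx is not None:
        cols.append(cnvx)
    for b in range(1, n_batches):
        cols.append((batch_codes == b).astype(float))
    return np.column_stack(cols)


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, resid, float(resid @ resid)


def gaussian_loglik(residuals: np.ndarray) -> float:
    """Gaussian log-likelihood of OLS residuals at the ML variance
    sigma^2 = RSS/n, evaluated as a sum of normal log-densities."""
    residuals = np.asarray(residuals, dtype=float)
    n = residuals.size
    rss = float(residuals @ residuals)
    if n == 0:
        raise EmptyInputError("no residuals")
    if rss <= 0:
        raise DegenerateInputError("zero residual sum of squares; likelihood unbounded")
    sigma = np.sqrt(rss / n)
    return float(scipy.stats.norm.logpdf(residuals, scale=sigma).sum())


@dataclass
class ResidualFit:
    """Per-gene fit of protein on mRNA plus batch (model M0)."""

    beta0: float
    beta1: float
    batch_coefs: np.ndarray
    residuals: pd.Series  # indexed by the complete-case samples
    degenerate: bool = False


def fit_residual_model(
    py: pd.Series, ty: pd.Series, batch: pd.Series
) -> ResidualFit:
    """OLS of protein on mRNA with batch indicators; residuals are the
    protein abundance left unexplained by the transcript."""
    ok = py.notna() & ty.notna()
    codes, levels = pd.factorize(batch.loc[ok.index][ok])
    n_coef = 2 + max(len(levels) - 1, 0)
    if ok.sum() < n_coef + 2:
        raise InsufficientDataError(
            f"{int(ok.sum())} complete observations < {n_coef + 2} required"
        )
    y = py[ok].to_numpy(float)
    X = _design(ty[ok].to_numpy(float), codes, len(levels))
    beta, resid, _ = _ols_rss(X, y)
    degenerate = np.linalg.matrix_rank(X) < X.shape[1]
    if degenerate:
        logger.warning("rank-deficient design in residual fit")
    return ResidualFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        batch_coefs=beta[2:].copy(),
        residuals=pd.Series(resid, index=py.index[ok]),
        degenerate=degenerate,
    )


@dataclass
class AssociationResult:
    """One directed test: does CNV of X help explain protein of Y?"""

    x: str
    y: str
    beta2: float
    lrt: float
    p: float
    n_samples: int
    fdr: Optional[float] = None
    significant: Optional[bool] = None
    degenerate: bool = False
    lrt_rss: Optional[float] = None  # n*log(RSS0/RSSA), the algebraic twin


def nested_lrt(
    py: pd.Series | np.ndarray,
    ty: pd.Series | np.ndarray,
    cnv_x: pd.Series | np.ndarray,
    batch: pd.Series | np.ndarray,
    x: str = "X",
    y: str = "Y",
) -> AssociationResult:
    """Likelihood-ratio test of MA (with CNV_X) against M0 on complete
    cases.  The statistic is computed from the two Gaussian log-likelihoods
    and, redundantly, as n*log(RSS0/RSS_A); both are returned.
    """
    py = np.asarray(py, dtype=float)
    ty = np.asarray(ty, dtype=float)
    cnvx = np.asarray(cnv_x, dtype=float)
    codes, levels = pd.factorize(np.asarray(batch))
    ok = ~(np.isnan(py) | np.isnan(ty) | np.isnan(cnvx))
    pyc, tyc, cxc, bc = py[ok], ty[ok], cnvx[ok], codes[ok]
    n = int(ok.sum())
    n_coef = 3 + max(len(levels) - 1, 0)
    if n < n_coef + 2:
        raise InsufficientDataError(f"{n} complete observations < {n_coef + 2} required")
    if np.ptp(cxc) == 0:
        logger.info("%s->%s: constant CNV on complete cases; degenerate", x, y)
        return AssociationResult(x=x, y=y, beta2=0.0, lrt=0.0, p=1.0,
                                 n_samples=n, degenerate=True, lrt_rss=0.0)
    nb = len(levels)
    X0 = _design(tyc, bc, nb)
    XA = _design(tyc, bc, nb, cnvx=cxc)
    _, r0, rss0 = _ols_rss(X0, pyc)
    betaA, rA, rssA = _ols_rss(XA, pyc)
    if rss0 <= 1e-12 * n:
        # Null model already fits (numerically) perfectly; the extra
        # covariate cannot improve it and the likelihood ratio is 1.
        return AssociationResult(x=x, y=y, beta2=float(betaA[2]), lrt=0.0,
                                 p=1.0, n_samples=n, degenerate=True, lrt_rss=0.0)
    if rssA <= 1e-12 * n:
        # Alternative model fits exactly while the null does not.
        return AssociationResult(x=x, y=y, beta2=float(betaA[2]), lrt=np.inf,
                                 p=0.0, n_samples=n, lrt_rss=np.inf)
    lrt = 2.0 * (gaussian_loglik(rA) - gaussian_loglik(r0))
    lrt_rss = n * np.log(rss0 / rssA)
    p = float(scipy.stats.chi2.sf(max(lrt, 0.0), df=1))
    return AssociationResult(x=x, y=y, beta2=float(betaA[2]), lrt=float(lrt),
                             p=p, n_samples=n, lrt_rss=float(lrt_rss))


def screen_interactions(
    dataset: OmicsDataset,
    pairs: Sequence[tuple[str, str]],
    fdr_threshold: float = FDR_SIGNIFICANT,
) -> pd.DataFrame:
    """Run the nested LRT for every directed candidate pair (X controlling,
    Y controlled), BH-adjust across tests and flag significance at
    FDR < ``fdr_threshold``.  Pairs with insufficient data are skipped and
    counted in the ``skipped`` attribute of the returned frame."""
    cnv = dataset.cnv.to_numpy(float)
    mrna = dataset.mrna.to_numpy(float)
    protein = dataset.protein.to_numpy(float)
    col = {g: j for j, g in enumerate(dataset.genes)}
    batch = dataset.batch.to_numpy()
    rows, skipped = [], 0
    for gx, gy in pairs:
        if gx not in col or gy not in col:
            skipped += 1
            continue
        try:
            res = nested_lrt(protein[:, col[gy]], mrna[:, col[gy]],
                             cnv[:, col[gx]], batch, x=gx, y=gy)
        except InsufficientDataError:
            skipped += 1
            continue
        rows.append({"x": res.x, "y": res.y, "beta2": res.beta2, "lrt": res.lrt,
                     "p": res.p, "n_samples": res.n_samples,
                     "degenerate": res.degenerate})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr"] = bh_fdr(out["p"].to_numpy())
        out["significant"] = out["fdr"] < fdr_threshold
    out.attrs["skipped"] = skipped
    if not out.empty:
        sig = out[out["significant"]]
        out.attrs["n_positive_beta"] = int((sig["beta2"] > 0).sum())
        out.attrs["n_negative_beta"] = int((sig["beta2"] < 0).sum())
    return out


# ---------------------------------------------------------------------------
# Residual comparisons and enrichments


def residuals_by_class(
    residuals: pd.DataFrame,
    reference: tuple[str, str] = ("benign", "neutral"),
) -> pd.DataFrame:
    """Stratified comparison of protein residuals across variant classes.

    ``residuals`` columns: sample, gene, residual, pathogenicity_class,
    stability_class, cnv (GISTIC score of the mutated gene in that
    sample).  Copy-number strata: loss (-1) vs compensated (>= 0); -2 is
    excluded (protein absent).  Each group is compared against the
    benign/neutral reference of the same stratum with a two-sided
    Mann-Whitney rank-sum test.
    """
    df = residuals[residuals["cnv"] != -2].copy()
    df["cn_stratum"] = np.where(df["cnv"] == -1, "loss", "compensated")
    rows = []
    for stratum, sdf in df.groupby("cn_stratum"):
        ref = sdf[(sdf["pathogenicity_class"] == reference[0])
                  & (sdf["stability_class"] == reference[1])]["residual"]
        for (pc, sc), grp in sdf.groupby(["pathogenicity_class", "stability_class"]):
            vals = grp["residual"]
            row = {"cn_stratum": stratum, "pathogenicity_class": pc,
                   "stability_class": sc, "n": len(vals),
                   "median": float(vals.median()),
                   "q1": float(vals.quantile(0.25)),
                   "q3": float(vals.quantile(0.75))}
            if (pc, sc) != reference and len(ref) > 0 and len(vals) > 0:
                stat, p = scipy.stats.mannwhitneyu(vals, ref, alternative="two-sided")
                row["rank_sum_p"] = float(p)
            else:
                row["rank_sum_p"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def cis_pqtl_enrichment(
    beta: Sequence[float],
    ddg: Sequence[float],
    ddg_threshold: float = CIS_DDG_THRESHOLD,
) -> tuple[float, float]:
    """One-sided Fisher test: are destabilising variants (DDG above the
    threshold) enriched in loss of protein levels (negative cis beta)?"""
    beta = np.asarray(beta, dtype=float)
    ddg = np.asarray(ddg, dtype=float)
    if beta.size == 0 or beta.size != ddg.size:
        raise EmptyInputError("need paired, non-empty beta and ddg vectors")
    destab = ddg > ddg_threshold
    loss = beta < 0
    table = ContingencyTable2x2(
        int((destab & loss).sum()), int((destab & ~loss).sum()),
        int((~destab & loss).sum()), int((~destab & ~loss).sum()),
    )
    return fisher_exact(table, alternative="greater")


def control_structure_correlation(
    associations: pd.DataFrame,
    pdockq_min: float = 0.23,
) -> pd.DataFrame:
    """Correlate control strength (beta2) with structural properties of the
    pair's complex model.

    ``associations`` columns: beta2, pdockq, iface_frac_controlled,
    iface_frac_controlling.  Rows with pDockQ <= ``pdockq_min`` are
    dropped first.  Pearson r and p are reported separately for each
    structural covariate.
    """
    df = associations[associations["pdockq"] > pdockq_min]
    if len(df) < 3:
        raise InsufficientDataError("fewer than 3 usable associations")
    rows = []
    for covariate in ("pdockq", "iface_frac_controlled", "iface_frac_controlling"):
        try:
            r, p = pearson(df["beta2"], df[covariate])
        except DegenerateInputError:
            r, p = np.nan, np.nan  # constant covariate after filtering
        rows.append({"covariate": covariate, "r": r, "p": p, "n": len(df)})
    return pd.DataFrame(rows)
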
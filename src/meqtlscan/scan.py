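"""cis-meQTL association scan.

For each SNP-CpG pair within the cis window the M value of the CpG is
regressed on an additive risk-allele dosage plus covariates (sex, age,
weight category) and the two cell-composition surrogate components:

    M_k = a_k + b_S*S + b_A*A + b_W*W + b_G*G + b_PC1*PC1 + b_PC2*PC2 + e_k

The genotype p-value comes from a likelihood-ratio test of the full against
the reduced (no-G) least-squares fit, LRT = n * ln(RSS_reduced / RSS_full),
referred to chi-square with 1 df. The effect size is the partial R^2: the
share of methylation variance not already explained by the covariates that
the SNP explains. Rare homozygote classes (< 10 carriers) are collapsed
into the heterozygote class; samples with missing genotypes are dropped per
SNP. q-values are computed over all testable pairs as one family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular
from sklearn.base import BaseEstimator

from .exceptions import CollinearityError, DimensionError, DomainError
from .preprocess import CellTypeSurrogate
from .qvalue import storey_qvalues

__all__ = [
    "CisPair",
    "pair_cis",
    "EncodedGenotype",
    "encode_and_collapse",
    "AssociationResult",
    "fit_association",
    "CisMeQTLScanner",
    "run_scan",
    "subgroup_concordance",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = [
    "snp_id", "probe_id", "distance", "n_used", "collapsed",
    "coef", "lrt", "p", "q", "partial_r2",
    "coef_se", "marginal_r2",
]

COVARIATE_COLUMNS = ["sex", "age", "weight_category"]
SURROGATE_COLUMNS = ["PC1", "PC2"]


@dataclass(frozen=True)
class CisPair:
    snp_id: str
    probe_id: str
    distance: int


def pair_cis(snp_manifest: pd.DataFrame, probe_manifest: pd.DataFrame,
             window: int = 500_000) -> pd.DataFrame:
    """All same-chromosome SNP-CpG pairs with |snp_pos - probe_pos| <= window.

    The boundary is inclusive: a probe exactly ``window`` bp away is tested.
    Positions are 1-based in both manifests. Returns a DataFrame with
    columns snp_id, probe_id, distance; per-SNP pair counts are attached as
    ``.attrs["per_snp_counts"]``.
    """
    for name, df, idcol in (("snp", snp_manifest, "snp_id"),
                            ("probe", probe_manifest, "probe_id")):
        bad = df[df["chrom"].isna() | (df["chrom"].astype(str).str.len() == 0)]
        if len(bad):
            raise DomainError(f"{name} manifest has missing chromosome for: "
                              f"{list(bad[idcol])}")
    merged = snp_manifest[["snp_id", "chrom", "pos"]].merge(
        probe_manifest[["probe_id", "chrom", "pos"]],
        on="chrom", suffixes=("_snp", "_probe"),
    )
    merged["distance"] = (merged["pos_snp"] - merged["pos_probe"]).abs()
    pairs = (
        merged.loc[merged["distance"] <= window, ["snp_id", "probe_id", "distance"]]
        .sort_values(["snp_id", "distance", "probe_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    pairs.attrs["per_snp_counts"] = pairs.groupby("snp_id").size().to_dict()
    return pairs


@dataclass
class EncodedGenotype:
    """Analysis-ready dosage for one SNP.

    ``dosage`` is the recoded numeric dosage (NaN outside the complete-case
    mask), ``collapsed`` marks a merged rare homozygote class, and
    ``status`` is "ok" or "untestable" (monomorphic after masking/merging).
    """

    dosage: np.ndarray
    mask: np.ndarray
    collapsed: bool
    status: str
    counts: dict = field(default_factory=dict)


def encode_and_collapse(dosages, min_homozygote_count: int = 10) -> EncodedGenotype:
    """Mask missing genotypes and collapse rare homozygote classes.

    Dosage counts risk alleles (0/1/2). A homozygote class observed fewer
    than ``min_homozygote_count`` times is merged with the heterozygotes and
    the variable recoded to two levels (0/1), preserving the risk-allele
    direction. A class count of exactly ``min_homozygote_count`` is kept.
    """
    arr = np.asarray(dosages, dtype=float).copy()
    mask = np.isfinite(arr)
    vals = arr[mask]
    if vals.size and not np.all(np.isin(vals, (0.0, 1.0, 2.0))):
        raise DomainError("dosages must be 0, 1, 2 or missing")
    counts = {g: int((vals == g).sum()) for g in (0.0, 1.0, 2.0)}
    rare0 = 0 < counts[0.0] < min_homozygote_count
    rare2 = 0 < counts[2.0] < min_homozygote_count
    collapsed = False
    out = arr.copy()
    if rare0 and rare2:
        out[out == 0.0] = 1.0
        out[out == 2.0] = 1.0
        collapsed = True
    elif rare2:
        out[out == 2.0] = 1.0
        collapsed = True
    elif rare0:
        # merge non-risk homozygotes into heterozygotes, then recode so the
        # merged class is 0 and risk homozygotes are 1
        out[out == 1.0] = 0.0
        out[out == 2.0] = 1.0
        collapsed = True
    out[~mask] = np.nan
    status = "ok" if np.unique(out[mask]).size >= 2 else "untestable"
    return EncodedGenotype(out, mask, collapsed, status, {int(k): v for k, v in counts.items()})


@dataclass
class AssociationResult:
    """One SNP-CpG model fit (q-value added at scan level)."""

    snp_id: str
    probe_id: str
    coef_genotype: float
    coef_se: float
    coefs_covariates: dict
    intercept: float
    lrt_stat: float
    p_value: float
    partial_r2: float
    marginal_r2: float
    n_used: int
    collapsed: bool
    q_value: float | None = None
    status: str = "ok"


def _design(covariates: pd.DataFrame, surrogate) -> pd.DataFrame:
    if isinstance(surrogate, CellTypeSurrogate):
        surrogate = surrogate.frame()
    cov = covariates[COVARIATE_COLUMNS]
    sur = surrogate[SURROGATE_COLUMNS] if isinstance(surrogate, pd.DataFrame) else surrogate
    if not cov.index.equals(sur.index):
        sur = sur.reindex(cov.index)
        if sur.isna().any().any():
            raise DimensionError("surrogate scores do not cover the covariate samples")
    X = pd.concat([cov, sur], axis=1)
    X.insert(0, "intercept", 1.0)
    return X


def _check_rank(X: np.ndarray, names) -> None:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = [names[i] for i in range(len(names)) if diag[i] <= tol]
    if bad:
        raise CollinearityError(bad)


def fit_association(m_values: pd.Series, covariates: pd.DataFrame, surrogate,
                    dosage, min_homozygote_count: int = 10,
                    snp_id: str = "", probe_id: str = "") -> AssociationResult:
    """Fit the full and reduced model for one probe against one SNP.

    ``dosage`` may be a raw 0/1/2-with-missing vector (encoded internally)
    or a pre-built :class:`EncodedGenotype`.
    """
    if not isinstance(dosage, EncodedGenotype):
        dosage = encode_and_collapse(dosage, min_homozygote_count)
    X_all = _design(covariates, surrogate)
    y_all = np.asarray(m_values, dtype=float)
    g_all = dosage.dosage
    keep = dosage.mask & np.isfinite(y_all) & np.isfinite(X_all.to_numpy(float)).all(axis=1)
    y = y_all[keep]
    g = g_all[keep]
    n = int(keep.sum())
    names = list(X_all.columns) + ["genotype"]
    p_full = len(names)
    if dosage.status == "untestable" or np.unique(g).size < 2:
        return AssociationResult(snp_id, probe_id, np.nan, np.nan, {}, np.nan,
                                 np.nan, np.nan, np.nan, np.nan, n,
                                 dosage.collapsed, status="untestable")
    if n < p_full + 2:
        return AssociationResult(snp_id, probe_id, np.nan, np.nan, {}, np.nan,
                                 np.nan, np.nan, np.nan, np.nan, n,
                                 dosage.collapsed, status="untestable")
    X_red = X_all.to_numpy(float)[keep]
    X_full = np.column_stack([X_red, g])
    _check_rank(X_full, names)
    beta_full, rss_full = _ols(X_full, y)
    _, rss_red = _ols(X_red, y)
    tss = float(((y - y.mean()) ** 2).sum())
    lrt, p, partial = _lrt_from_rss(n, rss_red, rss_full, tss)
    marginal = (rss_red - rss_full) / tss if tss > 0 else 0.0
    sigma2 = rss_full / (n - p_full)
    xtx_inv = np.linalg.inv(X_full.T @ X_full)
    se = float(np.sqrt(max(sigma2, 0.0) * xtx_inv[-1, -1]))
    coefs = dict(zip(names, beta_full))
    return AssociationResult(
        snp_id=snp_id, probe_id=probe_id,
        coef_genotype=float(beta_full[-1]), coef_se=se,
        coefs_covariates={k: float(v) for k, v in coefs.items()
                          if k not in ("intercept", "genotype")},
        intercept=float(coefs["intercept"]),
        lrt_stat=lrt, p_value=p, partial_r2=partial, marginal_r2=float(marginal),
        n_used=n, collapsed=dosage.collapsed,
    )


def _ols(X: np.ndarray, y: np.ndarray):
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _lrt_from_rss(n: int, rss_red: float, rss_full: float, scale: float = 1.0):
    """Gaussian-likelihood LRT of nested least-squares fits.

    ``scale`` (typically the total sum of squares) sets the numerical floor
    below which a residual sum of squares counts as exactly zero.
    """
    eps = 1e-12 * max(scale, 1.0)
    if rss_red <= eps:
        return 0.0, 1.0, 0.0
    rss_full = max(rss_full, 0.0)
    partial = max(1.0 - rss_full / rss_red, 0.0)
    if rss_full <= eps:
        return float("inf"), 5e-324, 1.0
    lrt = max(n * np.log(rss_red / rss_full), 0.0)
    p = float(stats.chi2.sf(lrt, df=1))
    return float(lrt), max(p, 5e-324), float(partial)


class CisMeQTLScanner(BaseEstimator):
    """Covariate-adjusted cis association scan over all SNP-CpG pairs.

    Parameters are the cis window (bp, inclusive boundary), the q-value
    significance cutoff, and the minimum homozygote count below which a
    homozygote class is collapsed into the heterozygotes.

    After ``fit``: ``results_`` (one row per testable pair, q pooled across
    the whole scan), ``significant_`` (q < q_threshold), ``pairs_``,
    ``untestable_`` and ``pi0_``.
    """

    def __init__(self, window: int = 500_000, q_threshold: float = 0.05,
                 min_homozygote_count: int = 10):
        self.window = window
        self.q_threshold = q_threshold
        self.min_homozygote_count = min_homozygote_count

    def fit(self, methylation_m: pd.DataFrame, genotypes: pd.DataFrame, *,
            covariates: pd.DataFrame, surrogate, snp_manifest: pd.DataFrame,
            probe_manifest: pd.DataFrame, pairs: pd.DataFrame | None = None):
        if pairs is None:
            pairs = pair_cis(snp_manifest, probe_manifest, self.window)
        if not methylation_m.index.equals(genotypes.index):
            raise DimensionError("methylation and genotype matrices must share samples")
        if not methylation_m.index.equals(covariates.index):
            raise DimensionError("methylation and covariates must share samples")
        X_all = _design(covariates, surrogate).to_numpy(float)
        names = [*_design(covariates, surrogate).columns, "genotype"]
        M = methylation_m.to_numpy(float)
        col_of = {pid: j for j, pid in enumerate(methylation_m.columns)}

        rows, untestable = [], []
        for snp_id, grp in pairs.groupby("snp_id", sort=False):
            if snp_id not in genotypes.columns:
                raise DomainError(f"genotypes missing SNP {snp_id}")
            enc = encode_and_collapse(genotypes[snp_id], self.min_homozygote_count)
            probe_ids = [p for p in grp["probe_id"] if p in col_of]
            dist = dict(zip(grp["probe_id"], grp["distance"]))
            if enc.status == "untestable":
                untestable.extend((snp_id, p) for p in probe_ids)
                continue
            keep = enc.mask & np.isfinite(X_all).all(axis=1)
            cols = [col_of[p] for p in probe_ids]
            Y = M[np.ix_(keep, cols)]
            finite_cols = np.isfinite(Y).all(axis=0)
            # probes with missing M fall back to the per-pair path
            slow = [probe_ids[j] for j in range(len(cols)) if not finite_cols[j]]
            fast = [j for j in range(len(cols)) if finite_cols[j]]
            if fast:
                Xr = X_all[keep]
                g = enc.dosage[keep]
                Xf = np.column_stack([Xr, g])
                n = Xf.shape[0]
                if n < Xf.shape[1] + 2 or np.unique(g).size < 2:
                    untestable.extend((snp_id, probe_ids[j]) for j in fast)
                else:
                    _check_rank(Xf, names)
                    rows.extend(self._fit_block(snp_id, [probe_ids[j] for j in fast],
                                                Xf, Xr, Y[:, fast], enc, dist))
            for pid in slow:
                res = fit_association(
                    methylation_m[pid], covariates, surrogate, enc,
                    self.min_homozygote_count, snp_id=snp_id, probe_id=pid,
                )
                if res.status == "untestable":
                    untestable.append((snp_id, pid))
                else:
                    rows.append(self._row_from_result(res, dist[pid]))
        if not rows:
            raise DomainError("no testable SNP-CpG pairs")
        results = pd.DataFrame(rows, columns=RESULT_COLUMNS[:8] + RESULT_COLUMNS[9:])
        q, pi0 = storey_qvalues(results["p"].to_numpy())
        results["q"] = q
        results = results[RESULT_COLUMNS]
        self.results_ = results.reset_index(drop=True)
        self.significant_ = self.results_[self.results_["q"] < self.q_threshold].copy()
        self.pairs_ = pairs
        self.untestable_ = untestable
        self.pi0_ = pi0
        return self

    def _fit_block(self, snp_id, probe_ids, Xf, Xr, Y, enc, dist):
        """Shared-design fits for all complete probes of one SNP via QR."""
        n, p_full = Xf.shape
        Qf, Rf = np.linalg.qr(Xf)
        Qr, _ = np.linalg.qr(Xr)
        yy = (Y**2).sum(axis=0)
        qty_f = Qf.T @ Y
        qty_r = Qr.T @ Y
        rss_full = np.maximum(yy - (qty_f**2).sum(axis=0), 0.0)
        rss_red = np.maximum(yy - (qty_r**2).sum(axis=0), 0.0)
        betas = solve_triangular(Rf, qty_f)
        se_scale = 1.0 / abs(Rf[-1, -1])
        ymean = Y.mean(axis=0)
        tss = ((Y - ymean) ** 2).sum(axis=0)
        out = []
        for j, pid in enumerate(probe_ids):
            lrt, p, partial = _lrt_from_rss(n, rss_red[j], rss_full[j], tss[j])
            sigma2 = rss_full[j] / (n - p_full)
            se = float(np.sqrt(max(sigma2, 0.0)) * se_scale)
            marginal = (rss_red[j] - rss_full[j]) / tss[j] if tss[j] > 0 else 0.0
            out.append({
                "snp_id": snp_id, "probe_id": pid, "distance": dist[pid],
                "n_used": n, "collapsed": enc.collapsed,
                "coef": float(betas[-1, j]), "lrt": lrt, "p": p,
                "partial_r2": partial, "coef_se": se, "marginal_r2": float(marginal),
            })
        return out

    @staticmethod
    def _row_from_result(res: AssociationResult, distance) -> dict:
        return {
            "snp_id": res.snp_id, "probe_id": res.probe_id, "distance": distance,
            "n_used": res.n_used, "collapsed": res.collapsed,
            "coef": res.coef_genotype, "lrt": res.lrt_stat, "p": res.p_value,
            "partial_r2": res.partial_r2, "coef_se": res.coef_se,
            "marginal_r2": res.marginal_r2,
        }


def run_scan(methylation_m: pd.DataFrame, covariates: pd.DataFrame, surrogate,
             genotypes: pd.DataFrame, pairs: pd.DataFrame,
             q_threshold: float = 0.05, min_homozygote_count: int = 10):
    """Functional wrapper over :class:`CisMeQTLScanner` with explicit pairs.

    Returns (results, significant subset).
    """
    snp_manifest = pd.DataFrame({"snp_id": pairs["snp_id"].unique()})
    scanner = CisMeQTLScanner(q_threshold=q_threshold,
                              min_homozygote_count=min_homozygote_count)
    scanner.fit(
        methylation_m, genotypes, covariates=covariates, surrogate=surrogate,
        snp_manifest=snp_manifest, probe_manifest=pd.DataFrame(), pairs=pairs,
    )
    return scanner.results_, scanner.significant_


def subgroup_concordance(results_a: pd.DataFrame, results_b: pd.DataFrame,
                         pair_subset) -> dict:
    """Direction agreement of SNP effects between two sub-group scans.

    ``pair_subset`` is an iterable of (snp_id, probe_id). Returns the number
    and fraction of pairs whose genotype coefficients share a sign, plus the
    per-subgroup counts of raw p < 0.05.
    """
    subset = list(pair_subset)
    a = results_a.set_index(["snp_id", "probe_id"])
    b = results_b.set_index(["snp_id", "probe_id"])
    missing = [t for t in subset if t not in a.index or t not in b.index]
    if missing:
        raise DomainError(f"pairs missing from one of the result tables: {missing}")
    ca = a.loc[subset, "coef"].to_numpy()
    cb = b.loc[subset, "coef"].to_numpy()
    agree = int((np.sign(ca) == np.sign(cb)).sum())
    return {
        "n_pairs": len(subset),
        "sign_agreement": agree,
        "sign_agreement_fraction": agree / len(subset) if subset else np.nan,
        "n_raw_significant_a": int((a.loc[subset, "p"] < 0.05).sum()),
        "n_raw_significant_b": int((b.loc[subset, "p"] < 0.05).sum()),
    }
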
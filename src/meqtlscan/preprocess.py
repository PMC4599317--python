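"""Methylation-matrix preprocessing.

Covers the beta/M transforms, probe-level QC filters, selection of the most
variable probes by 95 % reference range, PCA with sample-outlier exclusion,
and the two-component cell-composition surrogate built from a panel of
cell-type-discriminating CpGs.

Beta values are methylated-signal fractions in [0, 1]; M values are their
logit2 transform, M = log2(beta / (1 - beta)), which is closer to
homoscedastic and is the scale used for all linear modelling downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import DimensionError, DomainError

__all__ = [
    "MethylationMatrix",
    "beta_to_m",
    "m_to_beta",
    "reference_range_95",
    "pca",
    "PCAResult",
    "ProbeFilter",
    "filter_probes",
    "ReferenceRangeSelector",
    "PCAOutlierFilter",
    "exclude_outlier_samples",
    "CellCompositionSurrogate",
    "CellTypeSurrogate",
    "cell_surrogate",
]

#: beta values of exactly 0 or 1 are clamped into this open interval before
#: the logit2 transform to avoid infinite M values.
BETA_CLAMP = 1e-6


@dataclass
class MethylationMatrix:
    """Samples x probes methylation matrix with an explicit scale flag.

    ``scale`` is ``"beta"`` (values in [0, 1]) or ``"M"`` (real line).
    """

    values: pd.DataFrame
    scale: str = "beta"

    def __post_init__(self):
        if self.scale not in ("beta", "M"):
            raise DomainError(f"scale must be 'beta' or 'M', got {self.scale!r}")
        if self.values.index.has_duplicates:
            raise DomainError("duplicated sample ids")
        if self.values.columns.has_duplicates:
            raise DomainError("duplicated probe ids")
        if self.scale == "beta":
            vals = self.values.to_numpy(float)
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise DomainError("beta-scale matrix contains values outside [0, 1]")

    @property
    def sample_ids(self):
        return self.values.index

    @property
    def probe_ids(self):
        return self.values.columns

    def to_m(self) -> "MethylationMatrix":
        if self.scale == "M":
            return self
        return MethylationMatrix(beta_to_m(self.values), scale="M")

    def to_beta(self) -> "MethylationMatrix":
        if self.scale == "beta":
            return self
        return MethylationMatrix(m_to_beta(self.values), scale="beta")


def beta_to_m(beta, clamp: float = BETA_CLAMP):
    """logit2 transform: M = log2(beta / (1 - beta)).

    Values exactly 0 or 1 are clamped to [clamp, 1 - clamp]; values outside
    [0, 1] raise :class:`DomainError`.
    """
    arr = np.asarray(beta, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise DomainError("beta values must lie in [0, 1]")
    clipped = np.clip(arr, clamp, 1.0 - clamp)
    m = np.log2(clipped / (1.0 - clipped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index, name=beta.name)
    if np.isscalar(beta):
        return float(m)
    return m


def m_to_beta(m):
    """Inverse logit2: beta = 2**M / (2**M + 1)."""
    arr = np.asarray(m, dtype=float)
    # computed as expit(M * ln 2) for numerical symmetry at large |M|
    from scipy.special import expit

    beta = expit(arr * np.log(2.0))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(beta, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(beta, index=m.index, name=m.name)
    if np.isscalar(m):
        return float(beta)
    return beta


def reference_range_95(values) -> float:
    """95 % reference range of a vector: p97.5 - p2.5.

    Uses linear interpolation between order statistics. Missing values are
    ignored; fewer than two finite values raise :class:`DomainError`.
    """
    arr = np.asarray(values, dtype=float).ravel()
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise DomainError("reference_range_95 needs at least 2 finite values")
    lo, hi = np.percentile(arr, [2.5, 97.5], method="linear")
    return float(hi - lo)


@dataclass
class PCAResult:
    """Column-centred principal component decomposition.

    ``scores`` are samples x components (U * S), ``loadings`` are
    features x components, and ``variance_ratio`` is each component's share
    of the *total* variance (all fractions over the full rank sum to 1).
    Sign convention: the largest-magnitude loading of each component is
    positive.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_ratio: np.ndarray
    mean_: pd.Series = field(repr=False, default=None)


def pca(matrix: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of a samples x features DataFrame via SVD of the centred matrix."""
    X = matrix.to_numpy(float)
    n, p = X.shape
    max_rank = min(n, p)
    if n_components is None:
        n_components = max_rank
    if n_components > max_rank:
        raise DimensionError(
            f"n_components={n_components} exceeds min(samples, features)={max_rank}"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float((s**2).sum())
    rank = int(np.sum(s > s[0] * max(n, p) * np.finfo(float).eps)) if s.size else 0
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but numerical rank is {rank}; truncating",
            RuntimeWarning,
            stacklevel=2,
        )
        n_components = max(rank, 1)
    U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    # fix signs: largest-|loading| entry of each component made positive
    flip = np.sign(Vt[np.arange(n_components), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(U * s, index=matrix.index, columns=comp_names)
    loadings = pd.DataFrame(Vt.T, index=matrix.columns, columns=comp_names)
    ratio = (s**2) / total_var if total_var > 0 else np.zeros(n_components)
    return PCAResult(scores, loadings, ratio, pd.Series(mean, index=matrix.columns))


class ProbeFilter(BaseEstimator, TransformerMixin):
    """Probe-level QC filter for a beta-scale matrix.

    A probe is removed if any of the following holds:

    * any sample has a missing beta value;
    * fewer than ``min_fraction`` of samples have detection
      p-value < ``p_threshold`` (the boundary is strict: exactly 75 % passes);
    * it lies on a sex chromosome, is cross-reactive, or contains a SNP with
      minor allele frequency > 1 % (per the supplied flag table).

    Fitted attributes: ``keep_`` (retained probe ids) and ``report_`` (dict
    of per-reason exclusion counts; a probe may count under several reasons).
    """

    def __init__(self, min_fraction: float = 0.75, p_threshold: float = 0.01):
        self.min_fraction = min_fraction
        self.p_threshold = p_threshold

    def fit(self, X: pd.DataFrame, y=None, *, detection_p: pd.DataFrame | None = None,
            flags: pd.DataFrame | None = None):
        probes = X.columns
        missing = X.isna().any(axis=0)
        reasons = {"missing_beta": missing}
        if detection_p is not None:
            if not detection_p.index.equals(X.index) or not detection_p.columns.equals(probes):
                raise DimensionError("detection_p matrix is not aligned to the beta matrix")
            frac_pass = (detection_p < self.p_threshold).mean(axis=0)
            reasons["detection_failure"] = frac_pass < self.min_fraction
        if flags is not None:
            fl = flags.set_index("probe_id") if "probe_id" in flags.columns else flags
            fl = fl.reindex(probes)
            for col, reason in (
                ("is_sex_chromosome", "sex_chromosome"),
                ("is_cross_reactive", "cross_reactive"),
                ("has_maf_gt1pct_snp", "snp_overlap"),
            ):
                if col in fl.columns:
                    reasons[reason] = fl[col].fillna(False).astype(bool)
        excluded = pd.Series(False, index=probes)
        report = {}
        for reason, mask in reasons.items():
            report[reason] = int(mask.sum())
            excluded |= mask
        report["excluded_total"] = int(excluded.sum())
        report["retained"] = int((~excluded).sum())
        self.keep_ = probes[~excluded]
        self.report_ = report
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[:, X.columns.intersection(self.keep_)]


def filter_probes(matrix: pd.DataFrame, detection_p=None, flags=None,
                  min_fraction: float = 0.75, p_threshold: float = 0.01):
    """Functional wrapper over :class:`ProbeFilter`; returns (filtered, report)."""
    f = ProbeFilter(min_fraction=min_fraction, p_threshold=p_threshold)
    f.fit(matrix, detection_p=detection_p, flags=flags)
    return f.transform(matrix), f.report_


class ReferenceRangeSelector(BaseEstimator, TransformerMixin):
    """Keep probes whose 95 % reference range is at least ``min_range``.

    Applied to beta-scale values; probes at exactly the threshold are kept.
    """

    def __init__(self, min_range: float = 0.20):
        self.min_range = min_range

    def fit(self, X: pd.DataFrame, y=None):
        ranges = X.apply(reference_range_95, axis=0)
        self.ranges_ = ranges
        self.keep_ = X.columns[ranges >= self.min_range]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[:, X.columns.intersection(self.keep_)]


class PCAOutlierFilter(BaseEstimator, TransformerMixin):
    """Exclude samples that are outliers on any of the first ``n_pcs`` PCs.

    A sample is an outlier on a component if |score - mean| / SD exceeds
    ``z_threshold``. The default of 3 is a conventional choice; the rule and
    the offending component are recorded in ``report_``.
    """

    def __init__(self, n_pcs: int = 8, z_threshold: float = 3.0):
        self.n_pcs = n_pcs
        self.z_threshold = z_threshold

    def fit(self, X: pd.DataFrame, y=None):
        if X.shape[0] < 3:
            raise DimensionError("outlier exclusion needs at least 3 samples")
        n_pcs = min(self.n_pcs, min(X.shape) - 1)
        res = pca(X, n_components=n_pcs)
        self.pca_ = res
        scores = res.scores
        z = (scores - scores.mean(axis=0)) / scores.std(axis=0, ddof=1)
        outlier = z.abs() > self.z_threshold
        self.outliers_ = {
            sample: list(scores.columns[row])
            for sample, row in outlier.iterrows()
            if row.any()
        }
        self.keep_ = X.index[~outlier.any(axis=1)]
        self.report_ = {
            "rule": f"|z| > {self.z_threshold} on any of the first {n_pcs} PCs",
            "excluded": self.outliers_,
            "n_excluded": len(self.outliers_),
            "n_retained": len(self.keep_),
        }
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[X.index.intersection(self.keep_), :]


def exclude_outlier_samples(scores: pd.DataFrame, n_pcs: int = 8,
                            z_threshold: float = 3.0):
    """Apply the per-PC z-score rule directly to a precomputed score matrix.

    Returns (retained sample index, report dict naming each excluded
    sample's offending components).
    """
    if scores.shape[1] < n_pcs:
        raise DimensionError(
            f"scores cover {scores.shape[1]} components, need at least {n_pcs}"
        )
    if scores.shape[0] < 3:
        raise DimensionError("outlier exclusion needs at least 3 samples")
    use = scores.iloc[:, :n_pcs]
    sd = use.std(axis=0, ddof=1)
    sd = sd.replace(0.0, np.inf)  # constant PCs exclude nobody
    z = (use - use.mean(axis=0)) / sd
    outlier = z.abs() > z_threshold
    excluded = {
        sample: list(use.columns[row]) for sample, row in outlier.iterrows() if row.any()
    }
    retained = scores.index[~outlier.any(axis=1)]
    report = {
        "rule": f"|z| > {z_threshold} on any of the first {n_pcs} PCs",
        "excluded": excluded,
        "n_excluded": len(excluded),
        "n_retained": len(retained),
    }
    return retained, report


@dataclass
class CellTypeSurrogate:
    """Two-PC surrogate for blood cell-type composition.

    ``pc1``/``pc2`` are zero-mean per-sample scores from a PCA restricted to
    the reference (cell-type discriminating) probes; ``variance_explained``
    holds their fractions of the panel's total variance.
    """

    pc1: pd.Series
    pc2: pd.Series
    loadings: pd.DataFrame
    variance_explained: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"PC1": self.pc1, "PC2": self.pc2})


class CellCompositionSurrogate(BaseEstimator, TransformerMixin):
    """Build the cell-composition surrogate from a reference CpG panel.

    The panel (43 probes in the blood application) is an input list, never
    hard-coded. ``fit`` runs a PCA restricted to the panel probes present in
    the M-scale matrix and keeps the first two components.
    """

    def __init__(self, reference_probes=()):
        self.reference_probes = reference_probes

    def fit(self, X: pd.DataFrame, y=None):
        wanted = pd.Index(self.reference_probes)
        present = wanted.intersection(X.columns)
        missing = wanted.difference(X.columns)
        if len(missing):
            warnings.warn(
                f"{len(missing)} reference probes absent from the matrix: "
                f"{list(missing[:5])}{'...' if len(missing) > 5 else ''}",
                RuntimeWarning,
                stacklevel=2,
            )
        if len(present) < 2:
            raise DomainError("need at least 2 reference probes present after QC")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # rank-1 panel is valid
            res = pca(X.loc[:, present], n_components=2)
        if "PC2" in res.scores:
            pc2 = res.scores["PC2"]
            var2 = res.variance_ratio[:2]
        else:  # degenerate rank-1 panel: second component carries no variance
            pc2 = pd.Series(0.0, index=res.scores.index, name="PC2")
            var2 = np.append(res.variance_ratio[:1], 0.0)
        self.result_ = CellTypeSurrogate(
            pc1=res.scores["PC1"],
            pc2=pc2,
            loadings=res.loadings,
            variance_explained=var2,
        )
        self.mean_ = res.mean_
        self.present_ = present
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        Xc = X.loc[:, self.present_] - self.mean_
        proj = Xc.to_numpy(float) @ self.result_.loadings.to_numpy(float)
        if proj.shape[1] == 1:
            proj = np.column_stack([proj, np.zeros(len(proj))])
        return pd.DataFrame(proj, index=X.index, columns=["PC1", "PC2"])


def cell_surrogate(matrix_m: pd.DataFrame, reference_probe_ids) -> CellTypeSurrogate:
    """Functional wrapper over :class:`CellCompositionSurrogate`."""
    est = CellCompositionSurrogate(reference_probes=tuple(reference_probe_ids))
    est.fit(matrix_m)
    return est.result_
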
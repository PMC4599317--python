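"""Genomic context of CpG probes and enrichment of associated sets.

Probes are classified against gene models (promoter = within 1500 bp of a
TSS; a probe in both a promoter window and a gene body is "ambiguous"),
assigned a collapsed chromatin-state category per tissue, flagged for
membership in enhancer intervals, and counted against long-range
interaction anchor pairs (ChIA-PET style BEDPE). Enrichment of the
associated probe set against the tested background uses Fisher's exact
test with q-values over each test family; interaction-count distributions
are compared with a Mann-Whitney U test (exact for small samples).

Coordinate convention: BED/BEDPE intervals are 0-based half-open; probe and
TSS positions are 1-based and converted internally.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .exceptions import DimensionError, DomainError
from .qvalue import storey_qvalues

__all__ = [
    "REGION_CLASSES",
    "classify_region",
    "classify_regions",
    "assign_state",
    "assign_states",
    "count_interactions",
    "count_interactions_table",
    "membership_flags",
    "fisher_enrichment",
    "compare_interaction_counts",
]

REGION_CLASSES = ("promoter", "gene_body", "intergenic", "ambiguous")

PROMOTER_WINDOW = 1500


def _tss_1based(genes: pd.DataFrame) -> np.ndarray:
    if genes["strand"].isna().any() or (~genes["strand"].isin(["+", "-"])).any():
        bad = genes.loc[~genes["strand"].isin(["+", "-"]), "name"].tolist()
        raise DomainError(f"genes without a valid strand: {bad}")
    return np.where(genes["strand"] == "+", genes["start"] + 1, genes["end"])


class _GeneIndex:
    """Interval trees over promoter windows and gene bodies, per chromosome."""

    def __init__(self, genes: pd.DataFrame, promoter_window: int = PROMOTER_WINDOW):
        tss = _tss_1based(genes)
        self.promoters = {}
        self.bodies = {}
        for i, (_, g) in enumerate(genes.iterrows()):
            chrom = g["chrom"]
            t = int(tss[i])
            # 1-based inclusive [t-w, t+w] -> 0-based half-open [t-1-w, t+w)
            self.promoters.setdefault(chrom, IntervalTree()).addi(
                max(0, t - 1 - promoter_window), t + promoter_window, g["name"]
            )
            self.bodies.setdefault(chrom, IntervalTree()).addi(
                int(g["start"]), int(g["end"]), g["name"]
            )

    def in_promoter(self, chrom, pos_1based) -> bool:
        tree = self.promoters.get(chrom)
        return bool(tree and tree.overlaps_point(pos_1based - 1))

    def in_body(self, chrom, pos_1based) -> bool:
        tree = self.bodies.get(chrom)
        return bool(tree and tree.overlaps_point(pos_1based - 1))


def classify_region(chrom: str, pos: int, genes: pd.DataFrame,
                    promoter_window: int = PROMOTER_WINDOW) -> str:
    """Region class of a 1-based position against BED6 gene models."""
    idx = _GeneIndex(genes, promoter_window)
    return _classify(idx, chrom, pos)


def _classify(idx: _GeneIndex, chrom, pos) -> str:
    prom = idx.in_promoter(chrom, pos)
    body = idx.in_body(chrom, pos)
    if prom and body:
        return "ambiguous"
    if prom:
        return "promoter"
    if body:
        return "gene_body"
    return "intergenic"


def classify_regions(probe_manifest: pd.DataFrame, genes: pd.DataFrame,
                     promoter_window: int = PROMOTER_WINDOW) -> pd.Series:
    """Region class per probe; classes partition the probe set."""
    idx = _GeneIndex(genes, promoter_window)
    out = {
        pr["probe_id"]: _classify(idx, pr["chrom"], pr["pos"])
        for _, pr in probe_manifest.iterrows()
    }
    return pd.Series(out, name="region_class")


def assign_state(chrom: str, pos: int, segmentation: pd.DataFrame,
                 state_to_category=None) -> str:
    """Category of the half-open segment containing a 1-based position.

    ``state_to_category`` optionally maps raw state labels to collapsed
    categories; unmapped labels raise, uncovered positions return
    ``"uncovered"``.
    """
    sub = segmentation[segmentation["chrom"] == chrom]
    sub = sub.sort_values("start", kind="mergesort")
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    p0 = pos - 1
    i = np.searchsorted(starts, p0, side="right") - 1
    if i < 0 or p0 >= ends[i]:
        return "uncovered"
    label = sub["name"].iloc[i]
    if state_to_category is not None:
        if label not in state_to_category:
            raise DomainError(f"state label {label!r} has no category mapping")
        label = state_to_category[label]
    return label


def assign_states(probe_manifest: pd.DataFrame, segmentations: dict,
                  state_to_category=None) -> pd.DataFrame:
    """Probe x tissue table of collapsed chromatin-state categories."""
    out = {}
    for tissue, seg in segmentations.items():
        per_chrom = {}
        for chrom, sub in seg.groupby("chrom"):
            sub = sub.sort_values("start", kind="mergesort")
            per_chrom[chrom] = (
                sub["start"].to_numpy(), sub["end"].to_numpy(), sub["name"].to_numpy()
            )
        col = {}
        for _, pr in probe_manifest.iterrows():
            trio = per_chrom.get(pr["chrom"])
            if trio is None:
                col[pr["probe_id"]] = "uncovered"
                continue
            starts, ends, labels = trio
            p0 = pr["pos"] - 1
            i = np.searchsorted(starts, p0, side="right") - 1
            if i < 0 or p0 >= ends[i]:
                col[pr["probe_id"]] = "uncovered"
                continue
            label = labels[i]
            if state_to_category is not None:
                if label not in state_to_category:
                    raise DomainError(f"state label {label!r} has no category mapping")
                label = state_to_category[label]
            col[pr["probe_id"]] = label
        out[tissue] = col
    return pd.DataFrame(out)


def count_interactions(chrom: str, pos: int, anchors: pd.DataFrame,
                       genes: pd.DataFrame | None = None,
                       promoter_window: int = PROMOTER_WINDOW):
    """Number of anchor pairs whose either anchor contains the probe position,
    and whether any partner anchor overlaps a gene promoter window.

    Returns (count, promoter_interaction flag); the flag is None when no
    gene models are supplied.
    """
    for side in ("1", "2"):
        bad = anchors[anchors[f"end{side}"] <= anchors[f"start{side}"]]
        if len(bad):
            raise DomainError(
                f"malformed anchor pair (end <= start) at line(s) {list(bad.index + 1)}"
            )
    p0 = pos - 1
    in1 = (anchors["chrom1"] == chrom) & (anchors["start1"] <= p0) & (p0 < anchors["end1"])
    in2 = (anchors["chrom2"] == chrom) & (anchors["start2"] <= p0) & (p0 < anchors["end2"])
    hit = in1 | in2
    count = int(hit.sum())
    flag = None
    if genes is not None:
        idx = _GeneIndex(genes, promoter_window)
        flag = False
        for _, row in anchors[hit].iterrows():
            # partner = the other anchor; if both contain the probe, check both
            partners = []
            if row["chrom1"] == chrom and row["start1"] <= p0 < row["end1"]:
                partners.append((row["chrom2"], row["start2"], row["end2"]))
            if row["chrom2"] == chrom and row["start2"] <= p0 < row["end2"]:
                partners.append((row["chrom1"], row["start1"], row["end1"]))
            for c, s, e in partners:
                tree = idx.promoters.get(c)
                if tree and tree.overlap(int(s), int(e)):
                    flag = True
        return count, flag
    return count, flag


def count_interactions_table(probe_manifest: pd.DataFrame, anchors: pd.DataFrame,
                             genes: pd.DataFrame | None = None,
                             promoter_window: int = PROMOTER_WINDOW) -> pd.DataFrame:
    rows = {}
    for _, pr in probe_manifest.iterrows():
        c, f = count_interactions(pr["chrom"], pr["pos"], anchors, genes, promoter_window)
        rows[pr["probe_id"]] = {"interaction_count": c, "promoter_interaction": f}
    return pd.DataFrame.from_dict(rows, orient="index")


def membership_flags(probe_manifest: pd.DataFrame, intervals: pd.DataFrame) -> pd.Series:
    """Boolean membership of each probe in a BED interval set (e.g. enhancers)."""
    trees = {}
    for _, r in intervals.iterrows():
        trees.setdefault(r["chrom"], IntervalTree()).addi(int(r["start"]), int(r["end"]))
    out = {
        pr["probe_id"]: bool(
            trees.get(pr["chrom"]) and trees[pr["chrom"]].overlaps_point(pr["pos"] - 1)
        )
        for _, pr in probe_manifest.iterrows()
    }
    return pd.Series(out)


def fisher_enrichment(associated, tested, membership: dict,
                      background: str = "disjoint", pi0: float | None = None) -> pd.DataFrame:
    """Fisher exact enrichment of the associated set per membership label.

    ``membership`` maps a label (e.g. a category, or a (tissue, category)
    tuple) to the set of probes carrying it. The default 2x2 compares
    associated probes against the *disjoint* background (tested but not
    associated), as Fisher's test requires disjoint rows;
    ``background="overlapping"`` reproduces the associated-versus-all-tested
    variant for comparison. q-values are computed across all labels as one
    family.
    """
    associated = set(associated)
    tested = set(tested)
    if not associated:
        raise DomainError("associated set is empty")
    if not associated <= tested:
        raise DomainError("associated probes must be a subset of tested probes")
    bg = tested - associated if background == "disjoint" else tested
    rows = []
    for label, members in membership.items():
        members = set(members)
        a = len(associated & members)
        b = len(associated - members)
        c = len(bg & members)
        d = len(bg - members)
        odds, p = _fisher_2x2(a, b, c, d)
        rows.append({
            "label": label, "assoc_in": a, "assoc_out": b,
            "background_in": c, "background_out": d,
            "odds_ratio": odds, "p": p,
        })
    df = pd.DataFrame(rows)
    q, _ = storey_qvalues(df["p"].to_numpy(), pi0=pi0)
    df["q"] = q
    return df


def _fisher_2x2(a: int, b: int, c: int, d: int):
    table = np.array([[a, b], [c, d]])
    if min(a + b, c + d, a + c, b + d) == 0:
        p = 1.0
    else:
        _, p = stats.fisher_exact(table, alternative="two-sided")
    if b * c == 0:
        odds = np.inf if a * d > 0 else (0.0 if a * d == 0 and (b > 0 or c > 0) else np.nan)
    else:
        odds = (a * d) / (b * c)
    return float(odds) if np.isfinite(odds) else odds, float(min(p, 1.0))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for group x: pairs (xi > yj) + 0.5 * ties."""
    diff = x[:, None] - y[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def compare_interaction_counts(associated_counts, background_counts,
                               exact_max_n: int = 12) -> dict:
    """Two-sided Mann-Whitney U comparison of interaction-count distributions.

    For combined sample size <= ``exact_max_n`` the p-value is computed by
    complete enumeration of group labelings (exact even under ties);
    otherwise the tie-corrected normal approximation is used.
    """
    x = np.asarray(list(associated_counts), dtype=float)
    y = np.asarray(list(background_counts), dtype=float)
    if x.size == 0 or y.size == 0:
        raise DomainError("both groups must be nonempty")
    n1, n2 = x.size, y.size
    u_obs = _u_statistic(x, y)
    if n1 + n2 <= exact_max_n:
        pooled = np.concatenate([x, y])
        mid = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mid)
        total = extreme = 0
        idx = range(n1 + n2)
        for combo in combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(combo)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mid) >= dev_obs - 1e-12:
                extreme += 1
        p = extreme / total
        method = "exact"
    else:
        _, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        method = "asymptotic"
    return {"u": u_obs, "p": float(min(p, 1.0)), "n1": n1, "n2": n2, "method": method}
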
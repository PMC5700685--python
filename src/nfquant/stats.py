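"""Group comparison of per-ROI counts: normality gate, parametric and
nonparametric branches, and reference-ROI normalization.

The decision path mirrors common biostatistics practice for four-group
region comparisons: a per-group Kolmogorov-Smirnov normality test with the
Lilliefors correction (the group mean and SD are estimated from the sample,
so the uncorrected KS null distribution would be anticonservative); if all
groups look Gaussian, one-way ANOVA with Tukey's HSD post hoc; otherwise
Kruskal-Wallis with Dunn's pairwise z-tests and Bonferroni (or Holm)
adjustment over the six ROI pairs.

Normalization expresses each specimen's counts as a percentage of that
specimen's reference-ROI (default ROI I) count, making the reference column
exactly 100.  The resulting constant group is degenerate for any normality
test and is routed to the rank-based branch, which tolerates it.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .io import ROI_LABELS, ROI_NAMES, groups_by_roi

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class GroupSummary:
    roi: int
    n: int
    mean: float
    sd: float
    median: float
    values: np.ndarray

    @classmethod
    def from_values(cls, roi: int, values: np.ndarray) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        return cls(
            roi=roi, n=len(v), mean=float(v.mean()), sd=float(v.std(ddof=1)) if len(v) > 1 else 0.0,
            median=float(np.median(v)), values=v,
        )


@dataclasses.dataclass
class NormalityVerdict:
    roi: int
    statistic: float
    p: float
    normal: bool
    degenerate: bool = False


@dataclasses.dataclass
class PairwiseComparison:
    roi_a: int
    roi_b: int
    statistic: float
    p_raw: float | None
    p_adjusted: float
    significant: bool

    @property
    def pair(self) -> str:
        return f"{ROI_NAMES[self.roi_a]} vs {ROI_NAMES[self.roi_b]}"


@dataclasses.dataclass
class ComparisonResult:
    branch: str  # "parametric" | "nonparametric"
    omnibus_statistic: float
    omnibus_p: float
    pairwise: list[PairwiseComparison]
    alpha: float
    normalized: bool
    normality: list[NormalityVerdict]
    summaries: list[GroupSummary]
    note: str = ""

    def pair(self, roi_a: int, roi_b: int) -> PairwiseComparison:
        a, b = min(roi_a, roi_b), max(roi_a, roi_b)
        for pc in self.pairwise:
            if (pc.roi_a, pc.roi_b) == (a, b):
                return pc
        raise KeyError(f"no pairwise comparison for ROIs {roi_a}, {roi_b}")

    def to_dict(self) -> dict:
        return {
            "branch": self.branch,
            "omnibus_statistic": self.omnibus_statistic,
            "omnibus_p": self.omnibus_p,
            "alpha": self.alpha,
            "normalized": self.normalized,
            "note": self.note,
            "normality": [dataclasses.asdict(v) for v in self.normality],
            "pairwise": [
                {
                    "pair": pc.pair, "roi_a": pc.roi_a, "roi_b": pc.roi_b,
                    "statistic": pc.statistic, "p_raw": pc.p_raw,
                    "p_adjusted": pc.p_adjusted, "significant": pc.significant,
                }
                for pc in self.pairwise
            ],
            "groups": [
                {"roi": s.roi, "n": s.n, "mean": s.mean, "sd": s.sd, "median": s.median}
                for s in self.summaries
            ],
        }


def summarize(table: pd.DataFrame) -> list[GroupSummary]:
    return [GroupSummary.from_values(roi, vals) for roi, vals in groups_by_roi(table).items()]


def normality_gate(table: pd.DataFrame, alpha: float = 0.05) -> tuple[list[NormalityVerdict], bool]:
    """Lilliefors-corrected KS normality test per ROI group at level alpha.

    Constant groups (zero variance) are degenerate: no normality test is
    defined for them, they are marked non-normal and force the rank-based
    branch.  Returns the verdicts and the conjunction over testable groups.
    """
    verdicts = []
    for roi, vals in groups_by_roi(table).items():
        if len(vals) < 4:
            raise ValueError(f"group ROI {ROI_NAMES.get(roi, roi)} has n={len(vals)} < 4")
        if np.ptp(vals) == 0:
            verdicts.append(NormalityVerdict(roi=roi, statistic=float("nan"), p=float("nan"),
                                             normal=False, degenerate=True))
            continue
        stat, p = lilliefors(vals, dist="norm")
        verdicts.append(NormalityVerdict(roi=roi, statistic=float(stat), p=float(p),
                                         normal=bool(p > alpha)))
    all_normal = all(v.normal for v in verdicts)
    return verdicts, all_normal


def parametric_branch(table: pd.DataFrame, alpha: float = 0.05, normalized: bool = False,
                      normality: list[NormalityVerdict] | None = None) -> ComparisonResult:
    """One-way ANOVA over the ROI groups with Tukey HSD post hoc.

    Tukey p-values come from the studentized-range distribution and are
    family-wise adjusted by construction (no separate raw p is reported).
    """
    groups = groups_by_roi(table)
    labels = sorted(groups)
    arrays = [groups[k] for k in labels]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("parametric branch needs >= 2 groups with n >= 2 each")
    if all(np.ptp(a) == 0 for a in arrays):
        raise ValueError("zero within-group variance everywhere; ANOVA undefined")
    f_stat, f_p = sps.f_oneway(*arrays)
    if math.isnan(f_stat):  # identical group means with zero residual spread
        f_stat, f_p = 0.0, 1.0
    tukey = sps.tukey_hsd(*arrays)
    pairwise = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        p_adj = float(tukey.pvalue[i, j])
        pairwise.append(
            PairwiseComparison(
                roi_a=labels[i], roi_b=labels[j],
                statistic=float(tukey.statistic[i, j]), p_raw=None,
                p_adjusted=p_adj, significant=p_adj <= alpha,
            )
        )
    return ComparisonResult(
        branch="parametric", omnibus_statistic=float(f_stat), omnibus_p=float(f_p),
        pairwise=pairwise, alpha=alpha, normalized=normalized,
        normality=normality or [], summaries=summarize(table),
    )


def _dunn_pairwise(groups: dict[int, np.ndarray], alpha: float, adjust: str) -> list[PairwiseComparison]:
    labels = sorted(groups)
    pooled = np.concatenate([groups[k] for k in labels])
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_rank, sizes, start = {}, {}, 0
    for k in labels:
        n_k = len(groups[k])
        mean_rank[k] = float(ranks[start:start + n_k].mean())
        sizes[k] = n_k
        start += n_k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(labels) * (len(labels) - 1) // 2
    raw = {}
    zs = {}
    for a, b in itertools.combinations(labels, 2):
        se = math.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = 0.0 if se == 0 else (mean_rank[a] - mean_rank[b]) / se
        zs[(a, b)] = z
        raw[(a, b)] = float(2.0 * sps.norm.sf(abs(z)))
    if adjust == "holm":
        order = sorted(raw, key=raw.get)
        adj, running = {}, 0.0
        for rank_i, key in enumerate(order):
            running = max(running, min(1.0, (m - rank_i) * raw[key]))
            adj[key] = running
    elif adjust == "bonferroni":
        adj = {key: min(1.0, m * p) for key, p in raw.items()}
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return [
        PairwiseComparison(roi_a=a, roi_b=b, statistic=zs[(a, b)], p_raw=raw[(a, b)],
                           p_adjusted=adj[(a, b)], significant=adj[(a, b)] <= alpha)
        for a, b in itertools.combinations(labels, 2)
    ]


def nonparametric_branch(table: pd.DataFrame, alpha: float = 0.05, normalized: bool = False,
                         normality: list[NormalityVerdict] | None = None,
                         adjust: str = "bonferroni") -> ComparisonResult:
    """Kruskal-Wallis omnibus test (tie-corrected) with Dunn's post hoc.

    Dunn's z for a pair is the difference in mean ranks over the pooled
    sample divided by its tie-corrected standard error; two-sided p-values
    are Bonferroni-multiplied over the six pairs (Holm available).
    """
    groups = groups_by_roi(table)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = list(groups.values())
    note = ""
    if np.ptp(np.concatenate(arrays)) == 0:  # all observations identical: H undefined
        h_stat, h_p = float("nan"), 1.0
        note = "all observations identical; omnibus H undefined, no evidence of differences"
    else:
        try:
            h_stat, h_p = sps.kruskal(*arrays)
        except ValueError:
            h_stat, h_p = float("nan"), 1.0
            note = "omnibus H undefined; no evidence of differences"
    pairwise = _dunn_pairwise(groups, alpha, adjust)
    return ComparisonResult(
        branch="nonparametric", omnibus_statistic=float(h_stat), omnibus_p=float(h_p),
        pairwise=pairwise, alpha=alpha, normalized=normalized,
        normality=normality or [], summaries=summarize(table), note=note,
    )


def normalize_to_reference(table: pd.DataFrame, reference: int = 1) -> pd.DataFrame:
    """Express each specimen's counts as a percentage of its reference-ROI
    count (reference column becomes exactly 100).

    Specimens with a zero reference count cannot be normalized and are
    excluded with a logged warning.  The returned table carries float
    ``count`` values (percentages); area columns are zeroed as they do not
    survive the ratio.
    """
    wide = table.pivot(index="specimen_id", columns="roi", values="count").astype(float)
    if reference not in wide.columns:
        raise ValueError(f"reference ROI {reference} absent from table")
    zero_ref = wide.index[wide[reference] == 0]
    if len(zero_ref):
        logger.warning("excluding specimens with zero reference-ROI count: %s", list(zero_ref))
        wide = wide.drop(index=zero_ref)
    if wide.empty:
        raise ValueError("no specimens left after excluding zero reference counts")
    normalized = wide.div(wide[reference], axis=0) * 100.0
    long = normalized.reset_index().melt(id_vars="specimen_id", var_name="roi", value_name="count")
    long["roi"] = long["roi"].astype(int)
    long["object_area_px2"] = 0.0
    long["other_tissue_area_px2"] = 0.0
    return long.sort_values(["specimen_id", "roi"], ignore_index=True)


def run_comparison(
    table: pd.DataFrame,
    normalize: bool = False,
    reference: int = 1,
    alpha: float = 0.05,
    adjust: str = "bonferroni",
    both_branches: bool = False,
) -> ComparisonResult | tuple[ComparisonResult, ComparisonResult]:
    """Full decision path: optional normalization, normality gate, branch.

    All groups Gaussian by the Lilliefors test (and none degenerate) ->
    ANOVA + Tukey; otherwise Kruskal-Wallis + Dunn.  With
    ``both_branches=True`` both results are returned (gated first).
    """
    if normalize:
        table = normalize_to_reference(table, reference)
    verdicts, all_normal = normality_gate(table, alpha)
    if both_branches:
        para = parametric_branch(table, alpha, normalize, verdicts) if not all(
            v.degenerate for v in verdicts) else None
        nonp = nonparametric_branch(table, alpha, normalize, verdicts, adjust)
        gated = para if all_normal and para is not None else nonp
        other = nonp if gated is para else para
        return gated, other
    if all_normal:
        return parametric_branch(table, alpha, normalize, verdicts)
    return nonparametric_branch(table, alpha, normalize, verdicts, adjust)
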
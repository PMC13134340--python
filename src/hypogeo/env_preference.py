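"""Genus-level ecological preference analysis.

Genus ASV-type counts are compositional: per-sample totals reflect
sequencing depth and pooling, not absolute abundance.  They are therefore
rclr-transformed (robust centred log-ratio) before testing: within each
sample, nonzero counts are log-transformed and centred on the mean log of
the *nonzero* entries, while zeros stay missing rather than being imputed.

On the transformed values, host preference (Pinus vs Quercus soil) is
scored with a two-sided Wilcoxon rank-sum (Mann–Whitney) test, and each
numerical environmental variable with a two-sided Spearman rank
correlation under pairwise deletion of missing values.  P-values are
Benjamini–Hochberg adjusted, by default within one family per variable
across genera (the column-wise display convention).  Genera are finally
clustered on their correlation profiles with complete linkage on squared
Euclidean distances.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .data_model import GenusTable, Host, SampleTable, filter_genera_min_grids

__all__ = [
    "NUMERIC_VARIABLES",
    "Direction",
    "TestFlag",
    "RclrMatrix",
    "EnvPreferenceResult",
    "GenusClustering",
    "rclr_transform",
    "host_preference_test",
    "spearman_env",
    "fdr_adjust",
    "significance_stars",
    "cluster_genera",
    "preference_report",
]

#: Numerical variables tested against each genus.  latitude/longitude come
#: from the sample coordinates; the rest from the covariate columns.
NUMERIC_VARIABLES = ("MAT", "MAP", "longitude", "latitude", "altitude",
                     "pH", "TOC", "TN", "NH4+", "NO3-", "TP")


class Direction(enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    PINUS = "PINUS"
    QUERCUS = "QUERCUS"
    NONE = "NONE"


class TestFlag(enum.Enum):
    TESTED = "TESTED"
    SINGLE_HOST_ONLY = "SINGLE_HOST_ONLY"
    EXCLUDED_SINGLE_GRID = "EXCLUDED_SINGLE_GRID"
    TOO_FEW_PAIRS = "TOO_FEW_PAIRS"


@dataclass
class RclrMatrix:
    """Genus × sample rclr values; NaN marks original zeros."""

    genera: list[str]
    sample_ids: list[str]
    values: np.ndarray
    dropped_samples: list[str] = field(default_factory=list)

    def row(self, genus: str) -> np.ndarray:
        return self.values[self.genera.index(genus)]


@dataclass
class EnvPreferenceResult:
    """One genus × variable test outcome."""

    genus: str
    variable: str
    statistic: float | None
    p_raw: float | None
    p_adjusted: float | None
    n_pairs: int
    direction: Direction
    flag: TestFlag


@dataclass
class GenusClustering:
    """Complete-linkage clustering of genera on squared Euclidean distance."""

    genera: list[str]
    linkage: np.ndarray  # scipy linkage matrix
    leaf_order: list[str]

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge-height branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def recurse(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.genera[node.id]}:{length:.6g}"
            left = recurse(node.left, node.dist)
            right = recurse(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return recurse(tree, tree.dist) + ";"


def rclr_transform(counts: GenusTable) -> RclrMatrix:
    """Robust centred log-ratio transform of a genus count table.

    Per sample (column): nonzero counts x become ln(x) − mean(ln of the
    sample's nonzero counts); zeros become NaN.  All-zero samples are
    dropped and recorded in ``dropped_samples``.
    """
    matrix = counts.counts.astype(float)
    keep = matrix.sum(axis=0) > 0
    dropped = [sid for sid, k in zip(counts.sample_ids, keep) if not k]
    matrix = matrix[:, keep]
    sample_ids = [sid for sid, k in zip(counts.sample_ids, keep) if k]
    logs = np.full(matrix.shape, np.nan)
    np.log(matrix, out=logs, where=matrix > 0)
    center = np.nanmean(logs, axis=0)
    values = logs - center
    return RclrMatrix(list(counts.genera), sample_ids, values, dropped)


def host_preference_test(values: np.ndarray, hosts: np.ndarray | list,
                         genus: str = "") -> EnvPreferenceResult:
    """Two-sided Wilcoxon rank-sum test of rclr values between hosts.

    Only samples with a detection (non-missing rclr value) and a PINUS or
    QUERCUS host enter the test.  If detections fall in a single host the
    genus is flagged SINGLE_HOST_ONLY with the direction set to that host
    and no p-value — the presence pattern is informative even when the
    rank test is infeasible.  Direction otherwise follows the host with
    the larger rank mean.
    """
    vals = np.asarray(values, dtype=float)
    labels = np.asarray([h.value if isinstance(h, Host) else str(h) for h in hosts])
    ok = ~np.isnan(vals)
    pinus = vals[ok & (labels == Host.PINUS.value)]
    quercus = vals[ok & (labels == Host.QUERCUS.value)]
    if len(pinus) == 0 and len(quercus) == 0:
        return EnvPreferenceResult(genus, "host", None, None, None, 0,
                                   Direction.NONE, TestFlag.TOO_FEW_PAIRS)
    if len(pinus) == 0 or len(quercus) == 0:
        direction = Direction.QUERCUS if len(pinus) == 0 else Direction.PINUS
        return EnvPreferenceResult(genus, "host", None, None, None,
                                   len(pinus) + len(quercus), direction,
                                   TestFlag.SINGLE_HOST_ONLY)
    # exact null for small tie-free samples, normal approximation with tie
    # correction otherwise (scipy's "auto" switch at n = 8 is overridden to
    # 20 per group to match common rank-sum practice)
    pooled = np.concatenate([pinus, quercus])
    exact_ok = max(len(pinus), len(quercus)) <= 20 and len(np.unique(pooled)) == len(pooled)
    res = stats.mannwhitneyu(pinus, quercus, alternative="two-sided",
                             method="exact" if exact_ok else "asymptotic")
    rank_all = stats.rankdata(pooled)
    mean_p = rank_all[: len(pinus)].mean()
    mean_q = rank_all[len(pinus):].mean()
    if mean_p > mean_q:
        direction = Direction.PINUS
    elif mean_q > mean_p:
        direction = Direction.QUERCUS
    else:
        direction = Direction.NONE
    return EnvPreferenceResult(genus, "host", float(res.statistic), float(res.pvalue),
                               None, len(pooled), direction, TestFlag.TESTED)


def spearman_env(values: np.ndarray, covariate: np.ndarray, genus: str = "",
                 variable: str = "") -> EnvPreferenceResult:
    """Two-sided Spearman rank correlation with pairwise deletion.

    Requires at least 3 complete pairs; otherwise flagged TOO_FEW_PAIRS
    with no test.  Ties get average ranks.
    """
    vals = np.asarray(values, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    ok = ~np.isnan(vals) & ~np.isnan(cov)
    n = int(ok.sum())
    if n < 3:
        return EnvPreferenceResult(genus, variable, None, None, None, n,
                                   Direction.NONE, TestFlag.TOO_FEW_PAIRS)
    rho, p = stats.spearmanr(vals[ok], cov[ok])
    if np.isnan(rho):  # constant input after deletion
        return EnvPreferenceResult(genus, variable, None, None, None, n,
                                   Direction.NONE, TestFlag.TOO_FEW_PAIRS)
    direction = (Direction.POSITIVE if rho > 0
                 else Direction.NEGATIVE if rho < 0 else Direction.NONE)
    return EnvPreferenceResult(genus, variable, float(rho), float(p), None,
                               n, direction, TestFlag.TESTED)


def fdr_adjust(p_values, family=None):
    """Benjamini–Hochberg step-up adjustment, optionally within families.

    ``family`` assigns each p-value to a group; adjustment is applied
    independently within each group.  NaNs pass through untouched.
    """
    p = np.asarray(p_values, dtype=float)
    finite = ~np.isnan(p)
    if finite.any() and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if family is None:
        groups = {None: np.flatnonzero(finite)}
    else:
        fam = np.asarray(family)
        groups = {g: np.flatnonzero(finite & (fam == g)) for g in pd.unique(fam)}
    for idx in groups.values():
        if len(idx) == 0:
            continue
        out[idx] = multipletests(p[idx], method="fdr_bh")[1]
    return out


def significance_stars(p_adjusted: float | None) -> str:
    """Star annotation at 0.05 / 0.01 / 0.001 on the adjusted p-value."""
    if p_adjusted is None or np.isnan(p_adjusted):
        return ""
    if p_adjusted < 0.001:
        return "***"
    if p_adjusted < 0.01:
        return "**"
    if p_adjusted < 0.05:
        return "*"
    return ""


def cluster_genera(features: pd.DataFrame) -> GenusClustering:
    """Cluster genera on their variable-preference profiles.

    ``features`` is a genus × variable matrix (typically Spearman ρ);
    missing entries are imputed to 0 (no evidence of association).
    Complete linkage on squared Euclidean distance; genus rows are sorted
    lexicographically first so ties break deterministically.
    """
    if len(features) < 2:
        raise ValueError("clustering requires at least 2 genera")
    features = features.sort_index()
    X = features.fillna(0.0).to_numpy(dtype=float)
    Z = hierarchy.linkage(X, method="complete", metric="sqeuclidean")
    order = hierarchy.leaves_list(Z)
    genera = list(features.index)
    return GenusClustering(genera, Z, [genera[i] for i in order])


def preference_report(
    genus_table: GenusTable,
    samples: SampleTable,
    min_grids: int = 2,
    fdr_family: str = "per_variable",
    variables: tuple[str, ...] = NUMERIC_VARIABLES,
) -> tuple[pd.DataFrame, GenusClustering | None, dict]:
    """Full preference analysis for a genus table.

    Pipeline: single-grid genus exclusion → rclr → per-genus host test and
    Spearman correlation against each numerical variable → BH adjustment
    (``fdr_family`` = 'per_variable' or 'global') → significance stars →
    complete-linkage clustering of the genus × ρ matrix.

    Returns (results frame, clustering or None if <2 tested genera, info
    dict with excluded genera and dropped samples).
    """
    if fdr_family not in ("per_variable", "global"):
        raise ValueError(f"unknown fdr_family {fdr_family!r}")
    filtered, excluded = filter_genera_min_grids(genus_table, samples, min_grids)
    rclr = rclr_transform(filtered)
    recs = [samples[sid] for sid in rclr.sample_ids]
    hosts = np.array([r.host.value for r in recs])

    covariate = {}
    for var in variables:
        if var == "latitude":
            covariate[var] = np.array([r.latitude for r in recs])
        elif var == "longitude":
            covariate[var] = np.array([r.longitude for r in recs])
        else:
            covariate[var] = np.array(
                [r.covariates.get(var, float("nan")) for r in recs], dtype=float
            )

    results: list[EnvPreferenceResult] = []
    for gi, genus in enumerate(rclr.genera):
        row = rclr.values[gi]
        results.append(host_preference_test(row, hosts, genus))
        for var in variables:
            results.append(spearman_env(row, covariate[var], genus, var))
    for genus in excluded:
        results.append(EnvPreferenceResult(genus, "host", None, None, None, 0,
                                           Direction.NONE, TestFlag.EXCLUDED_SINGLE_GRID))

    p_raw = np.array([r.p_raw if r.p_raw is not None else np.nan for r in results])
    family = (np.array([r.variable for r in results])
              if fdr_family == "per_variable" else None)
    p_adj = fdr_adjust(p_raw, family)
    for r, adj in zip(results, p_adj):
        r.p_adjusted = None if np.isnan(adj) else float(adj)

    frame = pd.DataFrame([{
        "genus": r.genus, "variable": r.variable,
        "statistic": r.statistic, "p_raw": r.p_raw, "p_adjusted": r.p_adjusted,
        "stars": significance_stars(r.p_adjusted),
        "direction": r.direction.value, "flag": r.flag.value,
        "n_pairs": r.n_pairs,
    } for r in results])

    clustering = None
    if len(rclr.genera) >= 2:
        rho = frame[(frame["variable"] != "host") & (frame["flag"] == TestFlag.TESTED.value)]
        matrix = rho.pivot(index="genus", columns="variable", values="statistic")
        matrix = matrix.reindex(index=sorted(rclr.genera), columns=list(variables))
        clustering = cluster_genera(matrix)

    info = {"excluded_single_grid": excluded, "dropped_samples": rclr.dropped_samples}
    return frame, clustering, info
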
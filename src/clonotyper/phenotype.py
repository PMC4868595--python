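"""Phenotype-microarray QC, clustering, LSD comparisons and delta-Cq expression.

Supports the phenotype side of strain individuality testing:

* QC of dual-wavelength plate readings (OD750 for mycelial growth, OD490
  for tetrazolium-dye catabolism): readings over the absorbance ceiling
  and wells containing conidia are excluded, since both skew the data;
* replicate-averaged strain x compound profiles and UPGMA clustering on a
  correlation-based similarity scale in [0, 1] (1 = complete similarity);
* Fisher's unprotected LSD after one-way ANOVA with compact letter
  assignment;
* delta-Cq relative expression (Cq of the target minus Cq of the
  reference gene; lower values mean higher relative expression);
* conidiation score summaries (integer 0-5 per well).

Plate tables are TSV with columns strain, replicate, well, compound,
timepoint_h, od490, od750, score, conidia_present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist


@dataclass
class QCConfig:
    max_absorbance: float = 2.0
    exclude_conidia_wells: bool = True


def qc_filter(
    wells: pd.DataFrame, config: QCConfig | None = None, wavelength: str = "od750"
) -> pd.DataFrame:
    """Drop readings unusable for absorbance analysis.

    Readings *strictly over* ``max_absorbance`` at the analysed wavelength
    are excluded (a reading of exactly 2.0 is retained), as are wells that
    contain conidia when so configured.
    """
    config = config or QCConfig()
    keep = wells[wavelength] <= config.max_absorbance
    if config.exclude_conidia_wells and "conidia_present" in wells.columns:
        keep &= ~wells["conidia_present"].astype(bool)
    return wells[keep].copy()


def profile_matrix(
    wells: pd.DataFrame, wavelength: str = "od750", timepoint: float | None = None
) -> pd.DataFrame:
    """Replicate-mean strain x compound matrix at one wavelength.

    Cells with no retained replicate stay missing (NaN), never zero.
    ``timepoint`` restricts to one timepoint; ``None`` pools all columns
    as compound/timepoint pairs.
    """
    df = wells
    if timepoint is not None:
        df = df[df["timepoint_h"] == timepoint]
        columns = "compound"
    else:
        columns = ["compound", "timepoint_h"] if "timepoint_h" in df.columns else "compound"
    return df.pivot_table(index="strain", columns=columns, values=wavelength, aggfunc="mean")


@dataclass
class ClusterResult:
    """UPGMA dendrogram on the similarity scale (1 = identical profiles)."""

    labels: list[str]
    linkage_matrix: np.ndarray  # scipy format, heights are distances in [0, 1]
    merge_similarities: list[float] = field(init=False)

    def __post_init__(self) -> None:
        self.merge_similarities = [float(1.0 - h) for h in self.linkage_matrix[:, 2]]

    def to_newick(self) -> str:
        tree = to_tree(self.linkage_matrix)

        def fmt(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            return (
                f"({fmt(node.left, node.dist)},{fmt(node.right, node.dist)}):{length:.6g}"
            )

        return f"({fmt(tree.left, tree.dist)},{fmt(tree.right, tree.dist)});"


def cluster_profiles(matrix: pd.DataFrame) -> ClusterResult:
    """Agglomerative (UPGMA) clustering of strain profiles.

    The pairwise distance is ``1 - r`` (Pearson correlation over the
    compounds both rows share), clamped to [0, 1] so the similarity scale
    ``s = 1 - d`` runs from 0 (complete dissimilarity, including perfect
    anti-correlation) to 1 (complete similarity).
    """
    if len(matrix) < 2:
        raise ValueError("clustering needs at least two profiles")
    labels = [str(i) for i in matrix.index]
    n = len(labels)
    dist = np.zeros((n, n))
    values = matrix.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(values[i]) & ~np.isnan(values[j])
            if both.sum() < 2:
                raise ValueError(
                    f"profiles {labels[i]} and {labels[j]} share fewer than 2 compounds"
                )
            x, y = values[i, both], values[j, both]
            sx, sy = x.std(), y.std()
            if sx == 0 and sy == 0:
                r = 1.0 if np.allclose(x - x.mean(), y - y.mean()) else 0.0
            elif sx == 0 or sy == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            dist[i, j] = dist[j, i] = min(max(1.0 - r, 0.0), 1.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    return ClusterResult(labels=labels, linkage_matrix=Z)


@dataclass
class LSDResult:
    """Fisher's unprotected LSD at a given significance level.

    Groups sharing a letter are not significantly different (their mean
    difference does not exceed the l.s.d.).
    """

    means: dict[str, float]
    lsd: float
    letters: dict[str, str]
    mse: float
    df_error: int
    alpha: float
    n_harmonic: float


def lsd_compare(groups: dict[str, list[float]], alpha: float = 0.05) -> LSDResult:
    """One-way ANOVA followed by the least-significant-difference threshold.

    ``l.s.d. = t(1 - alpha/2, df_error) * sqrt(2 * MSE / n)`` with the
    harmonic-mean group size for unbalanced designs.  Letters are assigned
    by sequential grouping of the sorted means: maximal runs whose extremes
    differ by no more than the l.s.d. share a letter.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    sizes = {g: len(v) for g, v in groups.items()}
    if any(n < 2 for n in sizes.values()):
        raise ValueError("each group needs at least two replicates")
    df_error = sum(sizes.values()) - len(groups)
    if df_error <= 0:
        raise ValueError("zero error degrees of freedom")
    means = {g: float(np.mean(v)) for g, v in groups.items()}
    sse = sum(float(np.sum((np.asarray(v, float) - means[g]) ** 2)) for g, v in groups.items())
    mse = sse / df_error
    n_h = len(sizes) / sum(1.0 / n for n in sizes.values())
    t_crit = float(t_dist.ppf(1 - alpha / 2, df_error))
    lsd = t_crit * np.sqrt(2.0 * mse / n_h)

    # compact letters: maximal runs of sorted means within one l.s.d.
    order = sorted(means, key=lambda g: -means[g])
    runs: list[tuple[int, int]] = []
    for i in range(len(order)):
        j = i
        while j + 1 < len(order) and means[order[i]] - means[order[j + 1]] <= lsd:
            j += 1
        if not runs or j > runs[-1][1]:  # skip runs nested in the previous one
            runs.append((i, j))
    letters: dict[str, str] = {g: "" for g in order}
    for run_idx, (i, j) in enumerate(runs):
        letter = chr(ord("a") + run_idx)
        for g in order[i : j + 1]:
            letters[g] += letter
    return LSDResult(
        means=means, lsd=float(lsd), letters=letters, mse=mse,
        df_error=df_error, alpha=alpha, n_harmonic=n_h,
    )


def delta_cq(records: pd.DataFrame) -> pd.DataFrame:
    """Per-record delta-Cq: quantification cycle of target minus reference gene.

    Expects columns ``Cq_target`` and ``Cq_ref``; rows missing either are
    dropped with a warning.  Lower delta-Cq means higher relative
    expression.
    """
    df = records.copy()
    missing = df["Cq_target"].isna() | df["Cq_ref"].isna()
    if missing.any():
        warnings.warn(f"skipping {int(missing.sum())} record(s) with missing Cq values")
        df = df[~missing]
    df["delta_cq"] = df["Cq_target"] - df["Cq_ref"]
    return df


def delta_cq_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Replicate-mean delta-Cq per strain/gene/condition, with condition contrasts."""
    df = delta_cq(records)
    keys = [k for k in ("strain", "target_gene", "condition") if k in df.columns]
    summary = df.groupby(keys, sort=True)["delta_cq"].agg(["mean", "std", "count"]).reset_index()
    if "condition" in keys and df["condition"].nunique() == 2:
        wide = summary.pivot_table(
            index=[k for k in keys if k != "condition"], columns="condition", values="mean"
        )
        c1, c2 = sorted(df["condition"].unique())
        wide["difference"] = wide[c2] - wide[c1]
        summary = summary.merge(
            wide["difference"].reset_index(), on=[k for k in keys if k != "condition"], how="left"
        )
    return summary


def conidiation_summary(wells: pd.DataFrame) -> pd.DataFrame:
    """Per strain and timepoint: mean conidiation score and wells with conidia.

    Scores must be integers 0-5.  The mean is taken over the plate's wells
    within each replicate, then averaged over replicates; the well count
    (score > 0) is likewise replicate-averaged.
    """
    scores = wells["score"]
    if ((scores < 0) | (scores > 5)).any():
        raise ValueError("conidiation scores must lie in 0..5")
    per_rep = (
        wells.groupby(["strain", "timepoint_h", "replicate"])["score"]
        .agg(mean_score="mean", wells_with_conidia=lambda s: int((s > 0).sum()))
        .reset_index()
    )
    return (
        per_rep.groupby(["strain", "timepoint_h"])[["mean_score", "wells_with_conidia"]]
        .mean()
        .reset_index()
    )


def read_plate_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "conidia_present" in df.columns:
        df["conidia_present"] = df["conidia_present"].astype(bool)
    return df


def read_cq_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
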
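"""Expression normalisation and miRNA coexpression groups.

Expression matrices are pandas DataFrames: rows are entities (miRNA
precursors or annotated genes), columns are condition labels (e.g. the
developmental stages of a profiling series). A coexpression group
collects, for one miRNA, the annotated genes whose expression profile
correlates with the miRNA's beyond a threshold; these groups are the
unit over which shared transcription-factor binding sites are tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoexpressionGroup",
    "normalize",
    "pcc",
    "spearman",
    "coexpressed_group",
    "coexpressed_groups",
    "read_expression_tsv",
    "write_expression_tsv",
]


@dataclass
class CoexpressionGroup:
    """Genes coexpressed with one miRNA.

    ``members`` are (gene id, signed correlation) pairs sorted by
    |correlation| descending. ``relaxed`` marks groups padded to
    ``min_genes`` by taking the top genes when too few pass the
    threshold.
    """

    mirna: str
    method: str
    threshold: float
    members: list[tuple[str, float]] = field(default_factory=list)
    relaxed: bool = False

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.members]


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.duplicated().any() or df.index.duplicated().any():
        raise ValueError(f"duplicate ids or condition labels in {path}")
    return df


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def normalize(matrix: pd.DataFrame, method: str = "control_gene",
              control_id: str | None = None) -> pd.DataFrame:
    """Normalise an expression matrix.

    ``zscore``
        Per-entity mean 0, sd 1 (population sd, ddof=0). Zero-variance
        entities are excluded with a warning.
    ``quantile``
        Columns forced to a common distribution (the mean of the
        per-column sorted values), rank ties averaged.
    ``control_gene``
        Each condition divided by an internal control's value in that
        condition (e.g. Actin); the control must be present with
        all-positive values.
    """
    if method == "zscore":
        sd = matrix.std(axis=1, ddof=0)
        flat = sd == 0
        if flat.any():
            warnings.warn(
                f"excluding {int(flat.sum())} zero-variance entities "
                f"from z-scoring: {list(matrix.index[flat])[:5]}")
            matrix = matrix.loc[~flat]
            sd = sd[~flat]
        return matrix.sub(matrix.mean(axis=1), axis=0).div(sd, axis=0)
    if method == "quantile":
        ranks = matrix.rank(axis=0, method="average")
        target = np.sort(matrix.values, axis=0).mean(axis=1)
        # interpolate the target distribution at the (possibly tied) ranks
        grid = np.arange(1, matrix.shape[0] + 1)
        out = matrix.copy()
        for col in matrix.columns:
            out[col] = np.interp(ranks[col].values, grid, target)
        return out
    if method == "control_gene":
        if control_id is None or control_id not in matrix.index:
            raise ValueError(
                f"control_gene normalisation needs a control_id present "
                f"in the matrix (got {control_id!r})")
        ctrl = matrix.loc[control_id]
        if (ctrl <= 0).any():
            raise ValueError(
                f"control {control_id!r} must be positive in every condition")
        return matrix.div(ctrl, axis=1)
    raise ValueError(f"unknown normalisation method {method!r}")


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D with equal length")
    if x.size < 3:
        raise ValueError("correlation needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    return x, y


def pcc(x, y) -> float:
    """Pearson's correlation coefficient of two equal-length series."""
    x, y = _check_pair(x, y)
    return float(stats.pearsonr(x, y).statistic)


def spearman(x, y) -> float:
    """Spearman's rank correlation (Pearson on mid-ranks, ties averaged)."""
    x, y = _check_pair(x, y)
    return float(stats.spearmanr(x, y).statistic)


_METHODS = {"pcc": pcc, "spearman": spearman}


def _rowwise_corr(profile: np.ndarray, matrix: np.ndarray,
                  method: str) -> np.ndarray:
    """Correlation of one profile against every matrix row (vectorised)."""
    if method == "spearman":
        profile = stats.rankdata(profile)
        matrix = np.apply_along_axis(stats.rankdata, 1, matrix)
    p = profile - profile.mean()
    m = matrix - matrix.mean(axis=1, keepdims=True)
    denom = np.sqrt((p * p).sum()) * np.sqrt((m * m).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (m @ p) / denom
    return r


def coexpressed_group(mirna: str, mirna_expr: pd.DataFrame,
                      gene_matrix: pd.DataFrame, method: str = "pcc",
                      threshold: float = 0.9, min_genes: int = 10
                      ) -> CoexpressionGroup:
    """Genes whose |correlation| with a miRNA's profile meets a threshold.

    Conditions of the two matrices must agree exactly (a mismatch names
    the differing labels). Genes are included on |corr| >= threshold,
    sign retained; if fewer than ``min_genes`` qualify the group is
    relaxed to the top ``min_genes`` by |corr| and flagged.
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {sorted(_METHODS)}")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if mirna not in mirna_expr.index:
        raise KeyError(f"miRNA {mirna!r} has no expression profile")
    if list(mirna_expr.columns) != list(gene_matrix.columns):
        only_m = set(mirna_expr.columns) - set(gene_matrix.columns)
        only_g = set(gene_matrix.columns) - set(mirna_expr.columns)
        raise ValueError(
            f"condition labels differ between matrices "
            f"(miRNA-only: {sorted(only_m)}, gene-only: {sorted(only_g)}) "
            "or are ordered differently")

    profile = mirna_expr.loc[mirna].to_numpy(dtype=float)
    r = _rowwise_corr(profile, gene_matrix.to_numpy(dtype=float), method)
    r = pd.Series(r, index=gene_matrix.index).dropna()
    order = r.abs().sort_values(ascending=False, kind="stable").index
    passing = [(g, float(r[g])) for g in order if abs(r[g]) >= threshold]
    relaxed = False
    if len(passing) < min_genes:
        relaxed = True
        passing = [(g, float(r[g])) for g in order[:min_genes]]
        if len(passing) < min_genes:
            warnings.warn(
                f"{mirna}: only {len(passing)} genes available for the "
                f"coexpression group")
    if not passing:
        warnings.warn(f"{mirna}: empty coexpression group")
    return CoexpressionGroup(mirna, method, threshold, passing, relaxed)


def coexpressed_groups(mirna_expr: pd.DataFrame, gene_matrix: pd.DataFrame,
                       mirnas: list[str] | None = None, **kwargs
                       ) -> dict[str, CoexpressionGroup]:
    """Coexpression groups for many miRNAs.

    miRNAs absent from the expression matrix are skipped with a warning
    (no expression information, no group).
    """
    if mirnas is None:
        mirnas = list(mirna_expr.index)
    out = {}
    for m in mirnas:
        if m not in mirna_expr.index:
            warnings.warn(f"miRNA {m!r} has no expression profile; skipped")
            continue
        out[m] = coexpressed_group(m, mirna_expr, gene_matrix, **kwargs)
    return out
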
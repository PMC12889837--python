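"""Expression statistics for the pericentromeric gene family.

The expression level of a gene in a cell line is its MRSP — maximum reads at
a single point, i.e. the highest per-base depth over the gene's ORF. Summing
MRSP per gene across lines gives the gene's combined score; summing over the
family per line gives the line's GPS score. GPS scores are integrated with
the cumulative C19MC miRNA expression per line, lines are sorted by C19MC,
two n=12 groups (double-positive vs double-zero) are selected, and genes are
screened for differential expression between the groups with a |log2FC| > 2
and p < 0.05 (Student's t) gate on log2(x+1)-transformed values. ΔΔCt
fold-change handles qPCR validation tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GenomicInterval, SignalTrack

logger = logging.getLogger("gps_periscan")


@dataclass(frozen=True)
class GroupAssignment:
    positive: tuple[str, ...]
    negative: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.positive) & set(self.negative):
            raise ValueError("groups overlap")
        if len(self.positive) != len(self.negative):
            raise ValueError("groups must be equal size")


@dataclass(frozen=True)
class DEResult:
    gene: str
    log2fc: float
    p_value: float
    significant_up: bool
    significant_down: bool


@dataclass(frozen=True)
class QpcrRecord:
    sample: str
    target: str
    target_ct: float
    normalizer_ct: float
    condition: str  # control | treated

    def __post_init__(self) -> None:
        if self.target_ct <= 0 or self.normalizer_ct <= 0:
            raise ValueError("Ct values must be positive")
        if self.condition not in ("control", "treated"):
            raise ValueError(f"condition must be control or treated, got {self.condition!r}")


# ---------------------------------------------------------------------------
# MRSP and scores
# ---------------------------------------------------------------------------


def mrsp(depths: np.ndarray | list[int]) -> int:
    """Maximum per-base read depth over an ORF interval."""
    arr = np.asarray(depths)
    if arr.size == 0:
        raise ValueError("empty coverage profile")
    if (arr < 0).any():
        raise ValueError("depths must be non-negative")
    return int(arr.max())


def mrsp_from_track(track: SignalTrack, orf_interval: GenomicInterval) -> int:
    """MRSP read directly from a per-base coverage track."""
    return int(track.max_over(orf_interval))


def combined_gene_score(matrix: pd.DataFrame, gene: str) -> float:
    """Sum of a gene's MRSP values across all cell lines (matrix columns)."""
    if gene not in matrix.index:
        raise KeyError(f"unknown gene {gene!r}")
    return float(matrix.loc[gene].sum())


def gps_score(matrix: pd.DataFrame, cell_line: str, family: list[str] | None = None) -> float:
    """Sum over family gene rows for one cell line."""
    if cell_line not in matrix.columns:
        raise KeyError(f"unknown cell line {cell_line!r}")
    rows = matrix.loc[family] if family is not None else matrix
    return float(rows[cell_line].sum())


def integrate_and_sort(
    gps_scores: pd.Series,
    mirna_matrix: pd.DataFrame,
    c19mc_members: list[str],
) -> pd.DataFrame:
    """Per-line GPS score and cumulative C19MC, sorted by C19MC descending.

    Ties fall back to GPS score descending, then to the line id. Lines must
    be present in both inputs.
    """
    gps_lines = set(gps_scores.index)
    mirna_lines = set(mirna_matrix.columns)
    if gps_lines != mirna_lines:
        offenders = sorted(gps_lines ^ mirna_lines)
        raise ValueError(f"cell lines present in only one input: {offenders}")
    missing = [m for m in c19mc_members if m not in mirna_matrix.index]
    if missing:
        raise ValueError(f"C19MC members absent from miRNA matrix: {missing}")
    cumulative = mirna_matrix.loc[c19mc_members].sum(axis=0)
    table = pd.DataFrame({"gps_score": gps_scores, "c19mc_cumulative": cumulative})
    table = table.sort_values(
        by=["c19mc_cumulative", "gps_score"],
        ascending=[False, False],
        kind="mergesort",  # stable so the line-id order breaks remaining ties
    )
    # enforce deterministic tie-break on line id
    table["_id"] = table.index
    table = table.sort_values(
        by=["c19mc_cumulative", "gps_score", "_id"], ascending=[False, False, True]
    ).drop(columns="_id")
    return table


def select_groups(sorted_table: pd.DataFrame, n: int = 12, gps_cutoff: float = 0.0) -> GroupAssignment:
    """Top-n double-positive and n double-zero cell lines.

    Positive: the n lines with the highest cumulative C19MC among lines with
    both C19MC > 0 and GPS score > gps_cutoff. Negative: n lines with zero
    C19MC and zero GPS (lowest C19MC first, ties by line id).
    """
    pos_pool = sorted_table[
        (sorted_table["c19mc_cumulative"] > 0) & (sorted_table["gps_score"] > gps_cutoff)
    ]
    neg_pool = sorted_table[
        (sorted_table["c19mc_cumulative"] == 0) & (sorted_table["gps_score"] == 0)
    ]
    if len(pos_pool) < n or len(neg_pool) < n:
        raise ValueError(
            f"insufficient qualifying lines: {len(pos_pool)} double-positive, "
            f"{len(neg_pool)} double-zero, need {n} of each"
        )
    positive = tuple(pos_pool.index[:n])
    neg_sorted = neg_pool.sort_values(by="c19mc_cumulative", kind="mergesort")
    neg_sorted = neg_sorted.loc[sorted(neg_sorted.index)]
    negative = tuple(neg_sorted.index[:n])
    logger.info("select_groups: %d positive / %d negative lines selected", n, n)
    return GroupAssignment(positive=positive, negative=negative)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


def differential_expression(
    matrix: pd.DataFrame,
    groups: GroupAssignment,
    log2fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    fdr: bool = False,
) -> list[DEResult]:
    """Two-group DE screen on log2(x+1) values.

    log2fc = mean(log2(x+1), positive) - mean(log2(x+1), negative); p from a
    two-sided equal-variance Student's t-test on the transformed values. No
    multiple-testing correction by default; ``fdr=True`` applies
    Benjamini-Hochberg before flagging.
    """
    pos = np.log2(matrix[list(groups.positive)].to_numpy(dtype=float) + 1)
    neg = np.log2(matrix[list(groups.negative)].to_numpy(dtype=float) + 1)
    log2fcs = pos.mean(axis=1) - neg.mean(axis=1)
    with warnings.catch_warnings():
        # degenerate zero-variance rows are resolved explicitly below (p = 1)
        warnings.simplefilter("ignore", RuntimeWarning)
        tt = stats.ttest_ind(pos, neg, axis=1, equal_var=True)
    p_values = np.where(np.isnan(tt.pvalue), 1.0, tt.pvalue)
    if fdr:
        p_values = stats.false_discovery_control(p_values, method="bh")
    results = []
    for gene, fc, p in zip(matrix.index, log2fcs, p_values):
        results.append(
            DEResult(
                gene=gene,
                log2fc=float(fc),
                p_value=float(p),
                significant_up=bool(fc > log2fc_threshold and p < p_threshold),
                significant_down=bool(fc < -log2fc_threshold and p < p_threshold),
            )
        )
    n_sig = sum(r.significant_up or r.significant_down for r in results)
    logger.info(
        "differential_expression: %d genes, %d significant at |log2FC|>%g, p<%g",
        len(results), n_sig, log2fc_threshold, p_threshold,
    )
    return results


# ---------------------------------------------------------------------------
# qPCR ΔΔCt
# ---------------------------------------------------------------------------


def ddct_fold_change(records: list[QpcrRecord]) -> dict[str, dict[str, float]]:
    """Comparative-Ct fold change per target.

    ΔCt = Ct_target - Ct_normalizer per sample; ΔΔCt = mean ΔCt(treated) -
    mean ΔCt(control); fold = 2^(-ΔΔCt). Controls are reported at 1 by
    construction.
    """
    targets: dict[str, dict[str, list[float]]] = {}
    for rec in records:
        targets.setdefault(rec.target, {"control": [], "treated": []})[rec.condition].append(
            rec.target_ct - rec.normalizer_ct
        )
    folds: dict[str, dict[str, float]] = {}
    for target, dcts in targets.items():
        if not dcts["control"] or not dcts["treated"]:
            raise ValueError(f"{target}: need at least one control and one treated record")
        ddct = float(np.mean(dcts["treated"]) - np.mean(dcts["control"]))
        folds[target] = {
            "ddct": ddct,
            "fold_change": 2 ** (-ddct),
            "control_fold": 1.0,
        }
    return folds
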
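"""CPM normalization and miRNA differential expression (control vs disease).

The workflow mirrors small-RNA count analysis on a two-group design:
counts-per-million normalization, log2 transformation, per-miRNA two-sample
t-tests on log2 CPM, Benjamini–Hochberg adjustment, and the signed
fold-change convention in which down-regulation is reported as
−(control/disease) so magnitudes are always ≥ 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ContractError, NormalizationError, StatisticsError

GROUPS = ("control", "disease")

#: CPM floor substituted for an exactly-zero group mean so ratios stay defined
DETECTION_FLOOR_CPM = 0.5


@dataclass
class CountMatrix:
    """miRNA × sample count matrix with group labels.

    ``counts`` is indexed by miRNA id with one column per sample;
    ``groups`` maps every sample to ``control`` or ``disease``.
    """

    counts: pd.DataFrame
    groups: pd.Series
    normalized: bool = False

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.counts.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ContractError(f"samples without a group label: {missing}")
        bad = set(self.groups) - set(GROUPS)
        if bad:
            raise ContractError(f"unknown group labels: {sorted(bad)}")
        if (self.counts.values < 0).any():
            raise ContractError("negative entries in count matrix")

    def samples(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


def normalize_cpm(raw: CountMatrix) -> CountMatrix:
    """Scale every sample (column) to a library size of 10^6.

    Raises :class:`NormalizationError` naming the sample if a column has a
    zero total.
    """
    if raw.normalized:
        raise ContractError("matrix is already CPM-normalized")
    colsums = raw.counts.sum(axis=0)
    zero = colsums.index[colsums == 0]
    if len(zero):
        raise NormalizationError(f"zero total count in sample(s): {list(zero)}")
    cpm = raw.counts.div(colsums, axis=1) * 1e6
    return CountMatrix(cpm, raw.groups.copy(), normalized=True)


def log2_transform(m: CountMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise log2(CPM + pseudocount)."""
    if not m.normalized:
        raise ContractError("log2 transform expects a CPM-normalized matrix")
    if pseudocount < 0:
        raise ContractError("pseudocount must be ≥ 0")
    if pseudocount == 0 and (m.counts.values == 0).any():
        raise ContractError("zero entries require a positive pseudocount")
    return np.log2(m.counts + pseudocount)


def fold_change(mean_control: float, mean_disease: float) -> float:
    """Signed fold change: disease/control if disease ≥ control, else
    −(control/disease); magnitude is always ≥ 1."""
    if mean_control <= 0 or mean_disease <= 0:
        raise ContractError("fold change requires strictly positive group means")
    if mean_disease >= mean_control:
        return mean_disease / mean_control
    return -(mean_control / mean_disease)


def mean_expression(mean_control: float, mean_disease: float) -> float:
    """log2 of the average of the two group means (log2 CPM units)."""
    if mean_control <= 0 or mean_disease <= 0:
        raise ContractError("mean expression requires strictly positive group means")
    return math.log2((mean_control + mean_disease) / 2.0)


@dataclass
class DEResult:
    """Differential-expression table plus the summary counts."""

    records: pd.DataFrame
    n_de: int
    n_up: int
    n_down: int


def de_test(
    m: CountMatrix,
    alpha: float = 0.05,
    adjust: str = "fdr_bh",
    equal_var: bool = True,
    pseudocount: float = 1.0,
) -> DEResult:
    """Per-miRNA two-sample t-test on log2 CPM with multiplicity adjustment.

    Significance (direction up/down) is called at adjusted p < ``alpha``;
    everything else is ``null``.  Zero-variance miRNAs with equal means get
    p = 1 (never called DE).
    """
    if not m.normalized:
        raise ContractError("de_test expects a CPM-normalized matrix")
    ctrl, dis = m.samples("control"), m.samples("disease")
    if len(ctrl) < 2 or len(dis) < 2:
        raise StatisticsError(
            f"need ≥2 samples per group (control={len(ctrl)}, disease={len(dis)})"
        )
    logm = log2_transform(m, pseudocount)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance rows
        _, p_raw = stats.ttest_ind(
            logm[dis].values, logm[ctrl].values, axis=1, equal_var=equal_var
        )
    p_raw = np.where(np.isnan(p_raw), 1.0, p_raw)
    p_adj = multipletests(p_raw, method=adjust)[1]

    mc = m.counts[ctrl].mean(axis=1).values
    md = m.counts[dis].mean(axis=1).values
    mc_safe = np.where(mc > 0, mc, DETECTION_FLOOR_CPM)
    md_safe = np.where(md > 0, md, DETECTION_FLOOR_CPM)
    fc = np.where(md_safe >= mc_safe, md_safe / mc_safe, -(mc_safe / md_safe))
    me = np.log2((mc_safe + md_safe) / 2.0)

    direction = np.where(
        p_adj < alpha, np.where(fc > 0, "up", "down"), "null"
    )
    records = pd.DataFrame(
        {
            "mirna_id": m.counts.index,
            "mean_normalized_control": mc,
            "mean_normalized_disease": md,
            "mean_expression": me,
            "fold_change": fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "direction": direction,
        }
    ).reset_index(drop=True)
    n_up = int((records["direction"] == "up").sum())
    n_down = int((records["direction"] == "down").sum())
    return DEResult(records, n_de=n_up + n_down, n_up=n_up, n_down=n_down)


def select_top(records: pd.DataFrame, k_up: int = 8, k_down: int = 10) -> pd.DataFrame:
    """Best-adjP upregulated rows followed by best-adjP downregulated rows.

    Ties on adjP break by |fold_change| descending, then id lexicographic.
    Returns what exists with a warning if fewer rows qualify.
    """
    out = []
    for direction, k in (("up", k_up), ("down", k_down)):
        sub = records[records["direction"] == direction].copy()
        sub["_absfc"] = sub["fold_change"].abs()
        sub = sub.sort_values(
            ["p_adj", "_absfc", "mirna_id"],
            ascending=[True, False, True],
            kind="mergesort",
        ).drop(columns="_absfc")
        if len(sub) < k:
            warnings.warn(
                f"requested {k} {direction}-regulated miRNAs, only {len(sub)} qualify"
            )
        out.append(sub.head(k))
    return pd.concat(out, ignore_index=True)


def volcano_table(records: pd.DataFrame) -> pd.DataFrame:
    """Plotting-ready (signed log2 fold magnitude, −log10 adjP) per miRNA."""
    fc = records["fold_change"].values
    log2fc = np.sign(fc) * np.log2(np.abs(fc))
    neglogp = -np.log10(np.clip(records["p_adj"].values, 1e-300, None))
    return pd.DataFrame(
        {
            "mirna_id": records["mirna_id"],
            "log2_fold_change": log2fc,
            "neg_log10_p_adj": neglogp,
        }
    ).reset_index(drop=True)


def swap_groups(m: CountMatrix) -> CountMatrix:
    """Relabel control↔disease (useful for antisymmetry checks)."""
    flipped = m.groups.map({"control": "disease", "disease": "control"})
    return replace(m, groups=flipped)
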
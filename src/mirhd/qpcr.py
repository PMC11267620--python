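"""Relative quantification of qPCR data by the 2^−ΔΔCt method.

Per-replicate ΔCt = Ct(target) − Ct(reference) within a group;
ΔΔCt = mean ΔCt(disease) − mean ΔCt(control); the fold change is 2^−ΔΔCt
(amplification efficiency fixed at 2, the plain Livak formulation).
Group differences are tested by a two-sample t-test on the per-replicate
ΔCt values, where near-normality is plausible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, ContractError, StatisticsError

GROUPS = ("control", "disease")


@dataclass
class QPCRPlate:
    """Replicate Ct records for target and reference genes in two groups.

    ``data`` columns: gene, group ∈ {control, disease}, replicate, ct.
    """

    data: pd.DataFrame
    reference_gene: str = "18S"

    def __post_init__(self) -> None:
        required = {"gene", "group", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ContractError(f"qPCR table missing columns: {sorted(missing)}")
        bad = set(self.data["group"]) - set(GROUPS)
        if bad:
            raise ContractError(f"unknown qPCR groups: {sorted(bad)}")
        ct = self.data["ct"]
        if ((ct <= 0) | (ct > 45)).any():
            raise ContractError("Ct values must lie in (0, 45]")
        for group in GROUPS:
            ref = self.data[
                (self.data["gene"] == self.reference_gene)
                & (self.data["group"] == group)
            ]
            if ref.empty:
                raise AnalysisError(
                    f"reference gene {self.reference_gene!r} absent in {group}"
                )
        reps = self.data.groupby(["gene", "group"])["replicate"].nunique()
        if (reps < 2).any():
            few = reps.index[reps < 2].tolist()
            raise StatisticsError(f"<2 replicates for {few}")

    def genes(self) -> list[str]:
        return [g for g in self.data["gene"].unique() if g != self.reference_gene]

    def ct(self, gene: str, group: str) -> pd.Series:
        sub = self.data[(self.data["gene"] == gene) & (self.data["group"] == group)]
        return sub.set_index("replicate")["ct"].sort_index()


@dataclass
class GeneFoldChange:
    """Per-gene 2^−ΔΔCt result."""

    gene: str
    fc: float
    p: float
    direction: str  # up / down / ns
    ddct: float


def ddct(plate: QPCRPlate, gene: str, alpha: float = 0.05) -> GeneFoldChange:
    """2^−ΔΔCt fold change and t-test p-value for one gene.

    Replicates are paired with the reference gene by replicate index within
    each group.
    """
    dcts = {}
    for group in GROUPS:
        target = plate.ct(gene, group)
        if target.empty:
            raise AnalysisError(f"gene {gene!r} absent in {group}")
        ref = plate.ct(plate.reference_gene, group)
        common = target.index.intersection(ref.index)
        if len(common) < 2:
            raise StatisticsError(
                f"gene {gene!r} in {group}: <2 replicates paired with reference"
            )
        dcts[group] = (target.loc[common] - ref.loc[common]).values
    ddct_value = float(np.mean(dcts["disease"]) - np.mean(dcts["control"]))
    fc = float(2.0 ** (-ddct_value))
    if np.std(dcts["disease"]) == 0 and np.std(dcts["control"]) == 0:
        p = 1.0 if ddct_value == 0 else 0.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # near-identical ΔCt
            p = float(
                stats.ttest_ind(dcts["disease"], dcts["control"], equal_var=True).pvalue
            )
    if p >= alpha or fc == 1.0:
        direction = "ns"
    else:
        direction = "up" if fc > 1.0 else "down"
    return GeneFoldChange(gene=gene, fc=fc, p=p, direction=direction, ddct=ddct_value)


def significance_stars(p: float) -> str:
    """Presentation convention: ** p<0.01, * p<0.05, blank otherwise."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def ddct_panel(
    plate: QPCRPlate, genes: list[str] | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """One 2^−ΔΔCt row per gene plus up/down/ns calls at ``alpha``.

    Per-gene failures are recorded (fc = NaN) and the panel continues.
    """
    genes = plate.genes() if genes is None else genes
    rows = []
    for gene in genes:
        try:
            r = ddct(plate, gene, alpha)
            rows.append(
                {
                    "gene": gene,
                    "fold_change": r.fc,
                    "p": r.p,
                    "direction": r.direction,
                    "stars": significance_stars(r.p),
                }
            )
        except (AnalysisError, StatisticsError) as exc:
            rows.append(
                {
                    "gene": gene,
                    "fold_change": np.nan,
                    "p": np.nan,
                    "direction": f"error: {exc}",
                    "stars": "",
                }
            )
    return pd.DataFrame(rows, columns=["gene", "fold_change", "p", "direction", "stars"])


def panel_summary(panel: pd.DataFrame) -> dict:
    """Counts of up / down / ns calls in a panel."""
    counts = panel["direction"].value_counts()
    return {
        "n_up": int(counts.get("up", 0)),
        "n_down": int(counts.get("down", 0)),
        "n_ns": int(counts.get("ns", 0)),
    }
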
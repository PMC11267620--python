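"""Integrated miRNA–target report.

Joins differentially expressed miRNAs to their predicted binding sites
(inner join), and optionally to qPCR gene calls and a gene→disease
annotation table (left joins).  Multi-site miRNA–gene pairs collapse to the
``a÷b (n)`` start dialect.  Direction pairing is reported, not filtered:
same-direction miRNA–target pairs are biologically real in this system, so
no anti-correlation filter is applied unless requested.
"""

from __future__ import annotations

import pandas as pd

from .errors import InputError

_DE_REQUIRED = {"mirna_id", "fold_change", "p_adj", "direction"}
_SITE_REQUIRED = {"mirna", "gene", "start", "dG_kj_mol", "ratio_pct", "region", "length_nt"}


def integrate(
    de: pd.DataFrame,
    sites: pd.DataFrame,
    qpcr: pd.DataFrame | None = None,
    annot: pd.DataFrame | None = None,
    anticorrelation_only: bool = False,
) -> pd.DataFrame:
    """One row per (DE miRNA, target gene) with collapsed site details.

    Rows are ordered by miRNA adjusted p-value then gene.  With
    ``anticorrelation_only`` the report keeps only pairs where the gene's
    qPCR direction opposes the miRNA's.
    """
    for name, frame, req in (("DE table", de, _DE_REQUIRED), ("site table", sites, _SITE_REQUIRED)):
        missing = req - set(frame.columns)
        if missing:
            raise InputError(f"{name} missing column(s): {sorted(missing)}")

    de_sig = de[de["direction"].isin(["up", "down"])]
    if de_sig.empty or sites.empty:
        return _empty_report()

    rows = []
    site_sub = sites[sites["mirna"].isin(de_sig["mirna_id"])]
    qpcr_idx = qpcr.set_index("gene") if qpcr is not None and len(qpcr) else None
    annot_idx = annot.set_index("gene") if annot is not None and len(annot) else None
    de_idx = de_sig.set_index("mirna_id")
    for (mirna, gene), grp in site_sub.groupby(["mirna", "gene"], sort=False):
        derec = de_idx.loc[mirna]
        starts = sorted(int(s) for s in grp["start"])
        n = len(starts)
        start_str = "÷".join(str(s) for s in starts) + (f" ({n})" if n > 1 else "")
        gene_dir, gene_fc = None, None
        if qpcr_idx is not None and gene in qpcr_idx.index:
            gene_dir = qpcr_idx.loc[gene, "direction"]
            gene_fc = qpcr_idx.loc[gene, "fold_change"]
        if anticorrelation_only:
            opposed = {"up": "down", "down": "up"}
            if gene_dir != opposed[derec["direction"]]:
                continue
        disease = None
        if annot_idx is not None and gene in annot_idx.index:
            disease = annot_idx.loc[gene, "disease"]
        rows.append(
            {
                "mirna_id": mirna,
                "mirna_direction": derec["direction"],
                "mirna_fold_change": derec["fold_change"],
                "mirna_p_adj": derec["p_adj"],
                "gene": gene,
                "start": start_str,
                "n_sites": n,
                "dG_kj_mol": "÷".join(
                    f"{v:g}" for v in sorted(set(round(v, 1) for v in grp["dG_kj_mol"]))
                ),
                "ratio_pct": "÷".join(
                    str(int(v)) for v in sorted(set(round(v) for v in grp["ratio_pct"]))
                ),
                "region": "÷".join(dict.fromkeys(grp.sort_values("start")["region"])),
                "length_nt": int(grp["length_nt"].iloc[0]),
                "gene_qpcr_direction": gene_dir,
                "gene_qpcr_fc": gene_fc,
                "disease": disease,
            }
        )
    if not rows:
        return _empty_report()
    out = pd.DataFrame(rows)
    return out.sort_values(["mirna_p_adj", "gene"], kind="mergesort").reset_index(
        drop=True
    )


def _empty_report() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "mirna_id",
            "mirna_direction",
            "mirna_fold_change",
            "mirna_p_adj",
            "gene",
            "start",
            "n_sites",
            "dG_kj_mol",
            "ratio_pct",
            "region",
            "length_nt",
            "gene_qpcr_direction",
            "gene_qpcr_fc",
            "disease",
        ]
    )
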
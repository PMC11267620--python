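"""Reading and writing the pipeline's plain-text formats.

Counts travel as TSV (miRNA id + one column per sample) with a two-column
group map; sequences as FASTA (via Biopython, DNA T mapped to U on load);
transcript regions as a TSV of 1-based inclusive spans with the UTR5/CDS/UTR3
dialect; qPCR plates and all result tables as TSV; run manifests as YAML.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .de import CountMatrix
from .errors import InputError
from .qpcr import QPCRPlate
from .targets import MiRNA, Transcript

REGION_DIALECT = {"UTR5": "5'UTR", "CDS": "CDS", "UTR3": "3'UTR"}
REGION_DIALECT_INV = {v: k for k, v in REGION_DIALECT.items()}


def read_counts(counts_tsv: str | Path, groups_tsv: str | Path) -> CountMatrix:
    counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
    gmap = pd.read_csv(groups_tsv, sep="\t")
    if set(gmap.columns) != {"sample", "group"}:
        raise InputError(
            f"group map must have columns sample, group; got {list(gmap.columns)}"
        )
    groups = gmap.set_index("sample")["group"]
    missing = set(counts.columns) - set(groups.index)
    if missing:
        raise InputError(f"samples missing from group map: {sorted(missing)}")
    return CountMatrix(counts, groups.loc[list(counts.columns)])


def write_counts(m: CountMatrix, counts_tsv: str | Path, groups_tsv: str | Path) -> None:
    m.counts.rename_axis("mirna_id").to_csv(counts_tsv, sep="\t")
    m.groups.rename_axis("sample").rename("group").reset_index().to_csv(
        groups_tsv, sep="\t", index=False
    )


def read_mirna_fasta(path: str | Path) -> list[MiRNA]:
    """miRBase-dialect FASTA: U or T accepted, description lines ignored."""
    mirnas = [MiRNA(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not mirnas:
        raise InputError(f"no FASTA records in {path}")
    return mirnas


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records],
        str(path),
        "fasta",
    )


def read_transcripts(fasta: str | Path, regions_tsv: str | Path) -> list[Transcript]:
    regions = pd.read_csv(regions_tsv, sep="\t")
    required = {"transcript_id", "region", "start", "end"}
    missing = required - set(regions.columns)
    if missing:
        raise InputError(f"region table missing columns: {sorted(missing)}")
    bad = set(regions["region"]) - set(REGION_DIALECT)
    if bad:
        raise InputError(f"unknown region labels: {sorted(bad)} (expect UTR5/CDS/UTR3)")
    by_tx: dict[str, dict] = {}
    for row in regions.itertuples():
        by_tx.setdefault(row.transcript_id, {})[REGION_DIALECT[row.region]] = (
            int(row.start),
            int(row.end),
        )
    out = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        if rec.id not in by_tx:
            raise InputError(f"transcript {rec.id!r} has no region annotation")
        out.append(Transcript(rec.id, str(rec.seq), by_tx[rec.id]))
    if not out:
        raise InputError(f"no FASTA records in {fasta}")
    return out


def write_transcripts(
    transcripts: list[Transcript], fasta: str | Path, regions_tsv: str | Path
) -> None:
    write_fasta([(t.id, t.seq) for t in transcripts], fasta)
    rows = [
        {
            "transcript_id": t.id,
            "region": REGION_DIALECT_INV[label],
            "start": a,
            "end": b,
        }
        for t in transcripts
        for label, (a, b) in sorted(t.regions.items(), key=lambda kv: kv[1])
    ]
    pd.DataFrame(rows).to_csv(regions_tsv, sep="\t", index=False)


def read_qpcr(path: str | Path, reference: str = "18S") -> QPCRPlate:
    data = pd.read_csv(path, sep="\t")
    return QPCRPlate(data, reference_gene=reference)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a result/truth TSV without NA-string coercion (the DE direction
    label ``null`` must survive a round trip as a string)."""
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])


def write_table(df: pd.DataFrame, path: str | Path, round_cols: dict | None = None) -> None:
    """Write a result table as TSV, with optional presentation rounding."""
    out = df.copy()
    for col, nd in (round_cols or {}).items():
        if col in out.columns:
            out[col] = out[col].round(nd)
    out.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Gene → disease annotation table (gene, disease, evidence)."""
    annot = pd.read_csv(path, sep="\t")
    required = {"gene", "disease"}
    missing = required - set(annot.columns)
    if missing:
        raise InputError(f"annotation table missing columns: {sorted(missing)}")
    if annot["gene"].duplicated().any():
        raise InputError("annotation table has duplicate gene ids")
    if (annot["disease"].astype(str).str.len() == 0).any():
        raise InputError("annotation table has empty disease labels")
    return annot


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
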
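"""Generate the synthetic Q23/Q74 study dataset every later stage consumes.

Emulates the study conditions: 2,083 miRNAs × (4 control + 4 disease)
replicates, ~6% planted up / ~11% planted down with fold changes 2–18,
negative-binomial counts at dispersion 0.1 and uneven library sizes; plus
transcripts carrying planted binding sites in the 80–100% ΔG/ΔGm band and a
triplicate qPCR plate with planted fold changes 0.5–2 against an 18S
reference.  Writes everything under results/data/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mirhd import io
from mirhd.simulate import SimConfig, gen_counts, gen_qpcr, gen_transcripts
from mirhd.targets import MiRNA

SEED = 2024
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def random_mirnas(seed: int, n: int, length_range=(18, 25)) -> list[MiRNA]:
    rng = np.random.default_rng(seed)
    return [
        MiRNA(
            f"mir-sim-{i + 1:04d}",
            "".join("ACGU"[j] for j in rng.integers(0, 4, int(rng.integers(*length_range)))),
        )
        for i in range(n)
    ]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    cfg = SimConfig(seed=SEED)
    matrix, truth = gen_counts(cfg)
    io.write_counts(matrix, OUT / "counts.tsv", OUT / "groups.tsv")
    io.write_table(truth.mirna, OUT / "truth_mirna.tsv")
    n_de = int((truth.mirna["direction"] != "null").sum())
    print(
        f"counts: {matrix.counts.shape[0]} miRNAs × {matrix.counts.shape[1]} samples, "
        f"{n_de} planted DE ({(truth.mirna['direction'] == 'up').sum()} up / "
        f"{(truth.mirna['direction'] == 'down').sum()} down)"
    )

    mirnas = random_mirnas(SEED + 1, 12)
    transcripts, site_truth = gen_transcripts(
        SEED + 2, 10, (400, 1200), mirnas, sites_per_transcript=2,
        target_ratio_range=(80.0, 100.0),
    )
    io.write_fasta([(m.id, m.seq) for m in mirnas], OUT / "mirnas.fasta")
    io.write_transcripts(transcripts, OUT / "transcripts.fasta", OUT / "regions.tsv")
    io.write_table(site_truth.sites, OUT / "truth_sites.tsv")
    print(f"transcripts: {len(transcripts)} with {len(site_truth.sites)} planted sites")

    genes = [f"gene-{i + 1:02d}" for i in range(18)]
    rng = np.random.default_rng(SEED + 3)
    planted = {g: 1.0 for g in genes}
    for g in genes[:3]:
        planted[g] = float(rng.uniform(1.4, 2.0))
    for g in genes[3:7]:
        planted[g] = float(rng.uniform(0.5, 0.7))
    plate = gen_qpcr(SEED + 4, genes, planted, ct_sd=0.1, n_reps=3)
    io.write_table(plate.drop(columns="is_reference"), OUT / "qpcr.tsv")
    io.write_table(
        pd.DataFrame(
            {"gene": genes, "planted_fc": [planted[g] for g in genes]}
        ),
        OUT / "truth_qpcr.tsv",
    )
    print(f"qPCR: {len(genes)} genes (3 planted up, 4 down) in triplicate + 18S")


if __name__ == "__main__":
    main()
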
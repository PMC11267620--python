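"""CPM-normalize the simulated counts and compute the DE table.

Finds the differentially expressed miRNAs between control (Q23-like) and
disease (Q74-like) groups at BH-adjusted p < 0.05, writes the full DE table,
the top-8-up / top-10-down selection and the volcano coordinates, and
reports how calls line up with the planted truth.
"""

from pathlib import Path


from mirhd import io
from mirhd.de import de_test, normalize_cpm, select_top, volcano_table

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results"


def main() -> None:
    matrix = io.read_counts(DATA / "counts.tsv", DATA / "groups.tsv")
    truth = io.read_table(DATA / "truth_mirna.tsv")

    result = de_test(normalize_cpm(matrix), alpha=0.05, adjust="fdr_bh")
    io.write_table(
        result.records, OUT / "de_table.tsv",
        round_cols={"fold_change": 2, "mean_expression": 2},
    )
    top = select_top(result.records, k_up=8, k_down=10)
    io.write_table(top, OUT / "de_top18.tsv",
                   round_cols={"fold_change": 2, "mean_expression": 2})
    io.write_table(volcano_table(result.records), OUT / "volcano.tsv")

    merged = result.records.merge(truth, on="mirna_id")
    planted = merged[merged["direction_y"] != "null"]
    detected = planted[planted["direction_x"] != "null"]
    flips = (detected["direction_x"] != detected["direction_y"]).sum()
    print(
        f"DE: {result.n_de} significant ({result.n_up} up / {result.n_down} down) "
        f"of {len(merged)} miRNAs"
    )
    print(
        f"truth: {len(detected)}/{len(planted)} planted miRNAs detected, "
        f"{flips} direction flips"
    )
    print("top of the selection:")
    print(
        top.head(3)[
            ["mirna_id", "mean_normalized_control", "mean_normalized_disease",
             "mean_expression", "fold_change", "p_adj"]
        ].round(2).to_string(index=False)
    )


if __name__ == "__main__":
    main()
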
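"""End-to-end pipeline runner: simulate → DE → target scan → qPCR → report.

Driven by a YAML config; every stage writes TSVs into the run directory and
the run closes with a manifest recording the seed, parameters and stage
list.  Stage failures abort with the failing stage named; partial outputs
are retained.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .de import de_test, normalize_cpm, select_top, volcano_table
from .energy import EnergyModel
from .errors import InputError, MirhdError
from .qpcr import ddct_panel, panel_summary
from .report import integrate
from .simulate import SimConfig, gen_counts, gen_qpcr, gen_transcripts
from .targets import MiRNA, scan_many, site_count_table

log = logging.getLogger("mirhd")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "simulate": {
        "enabled": True,
        "n_mirna": 300,
        "n_per_group": 4,
        "frac_up": 0.06,
        "frac_down": 0.11,
        "fc_range": [2.0, 18.0],
        "dispersion": 0.1,
        "n_transcripts": 8,
        "transcript_length_range": [300, 800],
        "sites_per_transcript": 2,
        "target_ratio_range": [80.0, 100.0],
        "n_qpcr_genes": 6,
        "qpcr_fc_range": [0.5, 2.0],
        "ct_sd": 0.2,
        "n_reps": 3,
    },
    "de": {"alpha": 0.05, "adjust": "fdr_bh", "pseudocount": 1.0, "k_up": 8, "k_down": 10},
    "scan": {"min_ratio": 80.0},
    "qpcr": {"reference": "18S", "alpha": 0.05},
    "inputs": {},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return _merge(DEFAULT_CONFIG, {})
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def _random_mirnas(seed: int, n: int, length_range=(18, 25)) -> list[MiRNA]:
    import numpy as np

    rng = np.random.default_rng(seed)
    bases = "ACGU"
    out = []
    for i in range(n):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        out.append(
            MiRNA(f"mir-sim-{i + 1:04d}", "".join(bases[j] for j in rng.integers(0, 4, L)))
        )
    return out


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> Path:
    """Execute all stages; returns the run directory."""
    cfg = load_config(config) if not isinstance(config, dict) else _merge(DEFAULT_CONFIG, config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages_done: list[str] = []
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    stage = "setup"
    try:
        sim = cfg["simulate"]
        # --- stage: simulate (or load user inputs) -----------------------
        stage = "simulate"
        if sim.get("enabled", False):
            sc = SimConfig(
                seed=seed,
                n_mirna=int(sim["n_mirna"]),
                n_per_group=int(sim["n_per_group"]),
                frac_up=float(sim["frac_up"]),
                frac_down=float(sim["frac_down"]),
                fc_range=tuple(sim["fc_range"]),
                dispersion=float(sim["dispersion"]),
            )
            matrix, truth = gen_counts(sc)
            io.write_counts(matrix, out / "counts.tsv", out / "groups.tsv")
            io.write_table(truth.mirna, out / "truth_mirna.tsv")
            n_seq = min(20, sc.n_mirna)
            mirnas = _random_mirnas(seed + 1, n_seq)
            transcripts, site_truth = gen_transcripts(
                seed + 2,
                int(sim["n_transcripts"]),
                tuple(sim["transcript_length_range"]),
                mirnas,
                int(sim["sites_per_transcript"]),
                tuple(sim["target_ratio_range"]),
            )
            io.write_fasta([(m.id, m.seq) for m in mirnas], out / "mirnas.fasta")
            io.write_transcripts(transcripts, out / "transcripts.fasta", out / "regions.tsv")
            io.write_table(site_truth.sites, out / "truth_sites.tsv")
            import numpy as np

            rng = np.random.default_rng(seed + 3)
            genes = [f"gene-{i + 1:02d}" for i in range(int(sim["n_qpcr_genes"]))]
            lo, hi = sim["qpcr_fc_range"]
            planted = {g: float(np.exp(rng.uniform(np.log(lo), np.log(hi)))) for g in genes}
            plate_df = gen_qpcr(
                seed + 4, genes, planted, float(sim["ct_sd"]), int(sim["n_reps"])
            )
            io.write_table(plate_df.drop(columns="is_reference"), out / "qpcr.tsv")
            io.write_table(
                pd.DataFrame({"gene": genes, "planted_fc": [planted[g] for g in genes]}),
                out / "truth_qpcr.tsv",
            )
        else:
            inputs = cfg.get("inputs") or {}
            if "counts" not in inputs or "groups" not in inputs:
                raise InputError(
                    "simulation disabled and no counts/groups inputs configured"
                )
            matrix = io.read_counts(inputs["counts"], inputs["groups"])
            mirnas = io.read_mirna_fasta(inputs["mirnas"]) if "mirnas" in inputs else []
            transcripts = (
                io.read_transcripts(inputs["transcripts"], inputs["regions"])
                if "transcripts" in inputs
                else []
            )
            plate_df = (
                pd.read_csv(inputs["qpcr"], sep="\t") if "qpcr" in inputs else pd.DataFrame()
            )
        stages_done.append("simulate")
        log.info("simulate: %d miRNAs × %d samples", *matrix.counts.shape)

        # --- stage: differential expression ------------------------------
        stage = "de"
        decfg = cfg["de"]
        norm = normalize_cpm(matrix)
        result = de_test(
            norm,
            alpha=float(decfg["alpha"]),
            adjust=decfg["adjust"],
            pseudocount=float(decfg["pseudocount"]),
        )
        io.write_table(
            result.records,
            out / "de_table.tsv",
            round_cols={"fold_change": 2, "mean_expression": 2},
        )
        top = select_top(result.records, int(decfg["k_up"]), int(decfg["k_down"]))
        io.write_table(top, out / "de_top.tsv", round_cols={"fold_change": 2, "mean_expression": 2})
        io.write_table(volcano_table(result.records), out / "volcano.tsv")
        stages_done.append("de")
        log.info("de: %d DE (%d up / %d down)", result.n_de, result.n_up, result.n_down)

        # --- stage: target scan ------------------------------------------
        stage = "scan"
        if mirnas and transcripts:
            sites = scan_many(
                mirnas, transcripts, EnergyModel(), float(cfg["scan"]["min_ratio"])
            )
            io.write_table(sites, out / "sites.tsv", round_cols={"ratio_pct": 1})
            io.write_table(site_count_table(sites), out / "sites_summary.tsv")
        else:
            sites = pd.DataFrame()
        stages_done.append("scan")
        log.info("scan: %d binding sites", len(sites))

        # --- stage: qPCR --------------------------------------------------
        stage = "qpcr"
        if len(plate_df):
            from .qpcr import QPCRPlate

            plate = QPCRPlate(
                plate_df[["gene", "group", "replicate", "ct"]],
                reference_gene=cfg["qpcr"]["reference"],
            )
            panel = ddct_panel(plate, alpha=float(cfg["qpcr"]["alpha"]))
            io.write_table(panel, out / "qpcr_panel.tsv", round_cols={"fold_change": 3})
        else:
            panel = pd.DataFrame()
        stages_done.append("qpcr")

        # --- stage: report ------------------------------------------------
        stage = "report"
        annot = io.read_annotations(cfg["inputs"]["annotations"]) if cfg.get(
            "inputs", {}
        ).get("annotations") else None
        if len(sites):
            rep = integrate(
                result.records,
                sites,
                qpcr=panel if len(panel) else None,
                annot=annot,
            )
        else:
            rep = pd.DataFrame()
        io.write_table(rep, out / "report.tsv")
        stages_done.append("report")

        manifest = {
            "package": "mirhd",
            "version": __version__,
            "seed": seed,
            "stages": stages_done,
            "config": _yaml_safe(cfg),
            "outputs": sorted(p.name for p in out.glob("*.tsv")),
        }
        io.write_manifest(manifest, out / "manifest.yaml")
        return out
    except MirhdError as exc:
        raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()


def _yaml_safe(obj):
    if isinstance(obj, dict):
        return {k: _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
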
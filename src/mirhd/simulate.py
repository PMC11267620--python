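"""Synthetic data with planted truth for every stage of the pipeline.

Three generators emulate the study design the downstream stages assume:

* ``gen_counts`` — a two-group (control/disease) miRNA count experiment with
  four replicates per group, negative-binomial counts, uneven library sizes
  (so CPM normalization matters) and a minority of planted differentially
  expressed miRNAs with fold changes spanning roughly 2–18 in both
  directions.
* ``gen_transcripts`` — random mRNA transcripts partitioned into
  5'UTR/CDS/3'UTR, carrying planted miRNA binding sites whose realized
  ΔG/ΔGm falls inside a requested band (perfect reverse complements degraded
  by zero-bond substitutions).
* ``gen_qpcr`` — triplicate qPCR plates with a reference gene whose Ct is
  group-invariant and target genes whose disease Ct is shifted by
  −log2(planted fold change).

All outputs are byte-reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de import CountMatrix
from .energy import EnergyModel, revcomp
from .errors import ConfigurationError, GenerationError
from .targets import MiRNA, Transcript

RNA = np.array(list("ACGU"))


@dataclass
class SimConfig:
    """Conditions for the count experiment.

    Defaults reproduce the study design: 2,083 miRNAs, 4 replicates per
    group, ~6% up / ~11% down planted miRNAs with fold changes 2–18.
    """

    seed: int
    n_mirna: int = 2083
    n_per_group: int = 4
    frac_up: float = 126 / 2083
    frac_down: float = 228 / 2083
    fc_range: tuple[float, float] = (2.0, 18.0)
    dispersion: float = 0.1
    lib_size_range: tuple[int, int] = (500_000, 2_000_000)
    baseline_mean_range: tuple[float, float] = (1.0, 10_000.0)

    def __post_init__(self) -> None:
        checks = [
            ("n_mirna", self.n_mirna >= 1),
            ("n_per_group", self.n_per_group >= 1),
            ("frac_up", 0 <= self.frac_up),
            ("frac_down", 0 <= self.frac_down),
            ("frac_up+frac_down", self.frac_up + self.frac_down <= 1),
            ("fc_range", self.fc_range[0] > 1 and self.fc_range[1] >= self.fc_range[0]),
            ("dispersion", self.dispersion >= 0),
            (
                "lib_size_range",
                self.lib_size_range[0] >= 1
                and self.lib_size_range[1] >= self.lib_size_range[0],
            ),
            (
                "baseline_mean_range",
                self.baseline_mean_range[0] > 0
                and self.baseline_mean_range[1] >= self.baseline_mean_range[0],
            ),
        ]
        for name, ok in checks:
            if not ok:
                raise ConfigurationError(f"invalid SimConfig field: {name}")


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators.

    ``mirna`` has one row per miRNA (direction, true fold change);
    ``sites`` has one row per planted binding site (transcript, miRNA,
    start, realized ratio).
    """

    mirna: pd.DataFrame = field(default_factory=pd.DataFrame)
    sites: pd.DataFrame = field(default_factory=pd.DataFrame)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = μ + φμ²; φ=0 falls back to Poisson."""
    if dispersion == 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def gen_counts(config: SimConfig) -> tuple[CountMatrix, PlantedTruth]:
    """Raw count matrix (miRNA × 2·n_per_group samples) with planted truth.

    Null miRNAs share a common expected abundance in both groups; planted
    miRNAs have the disease abundance multiplied (up) or divided (down) by a
    fold change drawn log-uniformly from ``fc_range``.  Expected counts are
    relative abundances scaled to per-sample library sizes, so the CPM step
    downstream has real work to do.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_mirna
    ids = [f"mir-sim-{i + 1:04d}" for i in range(n)]

    lo, hi = config.baseline_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))

    n_up = round(config.frac_up * n)
    n_down = round(config.frac_down * n)
    status = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    status[order[:n_up]] = "up"
    status[order[n_up : n_up + n_down]] = "down"
    flo, fhi = config.fc_range
    fc = np.exp(rng.uniform(np.log(flo), np.log(fhi), size=n))
    true_fc = np.where(status == "up", fc, np.where(status == "down", 1.0 / fc, 1.0))

    ctrl_abund = base
    dis_abund = base * true_fc

    cols, names, groups = [], [], []
    for group, abund in (("control", ctrl_abund), ("disease", dis_abund)):
        frac = abund / abund.sum()
        for r in range(config.n_per_group):
            lib = int(rng.integers(config.lib_size_range[0], config.lib_size_range[1] + 1))
            cols.append(_nb_draw(rng, frac * lib, config.dispersion))
            names.append(f"{group}_{r + 1}")
            groups.append(group)

    counts = pd.DataFrame(np.column_stack(cols), index=ids, columns=names)
    matrix = CountMatrix(counts, pd.Series(groups, index=names))
    truth = PlantedTruth(
        mirna=pd.DataFrame(
            {"mirna_id": ids, "direction": status, "true_fc": true_fc}
        )
    )
    return matrix, truth


def _degrade_site(
    rng: np.random.Generator,
    mirna_seq: str,
    window: list[str],
    model: EnergyModel,
    ratio_band: tuple[float, float],
) -> float:
    """Substitute paired window bases with zero-bond mismatches until the
    realized ΔG/ΔGm enters ``ratio_band``; returns the realized ratio.

    The window starts as the exact reverse complement (ratio 100).  Window
    position j pairs miRNA position L−1−j; writing the miRNA's own base at a
    window position makes that column a 0-bond mismatch under the default
    pair table (A·A, C·C, G·G, U·U are all unpairable).
    """
    lo, hi = ratio_band
    L = len(mirna_seq)
    bonds = [model.bonds(mirna_seq[L - 1 - j], window[j]) for j in range(L)]
    total = sum(bonds)
    if total == 0:
        raise GenerationError("miRNA has no pairable composition under this model")
    target = rng.uniform(lo, hi)
    current = total
    order = list(rng.permutation(L))
    for j in order:
        if 100.0 * current / total <= target:
            break
        if bonds[j] == 0:
            continue
        if 100.0 * (current - bonds[j]) / total < lo:
            continue  # removing this pair would undershoot the band
        window[j] = mirna_seq[L - 1 - j]
        current -= bonds[j]
    ratio = 100.0 * current / total
    if not (lo - 1e-9 <= ratio <= hi + 1e-9):
        raise GenerationError(
            f"could not realize a ΔG/ΔGm ratio inside [{lo}, {hi}] "
            f"(stuck at {ratio:.2f})"
        )
    return ratio


def gen_transcripts(
    seed: int,
    n_transcripts: int,
    length_range: tuple[int, int],
    mirnas: list[MiRNA],
    sites_per_transcript: int = 1,
    target_ratio_range: tuple[float, float] = (80.0, 100.0),
    region_props: tuple[float, float, float] = (0.1, 0.6, 0.3),
    model: EnergyModel | None = None,
) -> tuple[list[Transcript], PlantedTruth]:
    """Random transcripts with planted binding sites of controlled quality.

    Each transcript is uniform-random RNA split contiguously into
    5'UTR/CDS/3'UTR (default 10/60/30%).  Planted sites are non-overlapping
    reverse complements of a randomly chosen miRNA, degraded by greedy
    zero-bond substitutions until the realized ratio lies in
    ``target_ratio_range``.
    """
    if not (80.0 <= target_ratio_range[0] <= target_ratio_range[1] <= 100.0):
        raise ConfigurationError(
            "invalid target_ratio_range: must lie within [80, 100]"
        )
    if sites_per_transcript < 0:
        raise ConfigurationError("invalid sites_per_transcript: must be ≥ 0")
    if mirnas and length_range[0] < max(len(m) for m in mirnas):
        raise ConfigurationError(
            "invalid length_range: transcripts must be at least as long as "
            "the longest miRNA"
        )
    model = model or EnergyModel()
    rng = np.random.default_rng(seed)
    transcripts: list[Transcript] = []
    site_rows = []
    for t in range(n_transcripts):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = list(RNA[rng.integers(0, 4, size=length)])
        occupied: list[tuple[int, int]] = []
        tid = f"tx-sim-{t + 1:04d}"
        for _ in range(sites_per_transcript if mirnas else 0):
            mir = mirnas[int(rng.integers(len(mirnas)))]
            L = len(mir)
            for _attempt in range(200):
                p = int(rng.integers(1, length - L + 2))  # 1-based start
                if all(p + L - 1 < a or p > b for a, b in occupied):
                    break
            else:
                raise GenerationError(
                    f"could not place a non-overlapping site on {tid}"
                )
            window = list(revcomp(mir.seq))
            ratio = _degrade_site(rng, mir.seq, window, model, target_ratio_range)
            seq[p - 1 : p - 1 + L] = window
            occupied.append((p, p + L - 1))
            site_rows.append(
                {
                    "transcript_id": tid,
                    "mirna_id": mir.id,
                    "start": p,
                    "length": L,
                    "ratio": ratio,
                }
            )
        u5 = max(1, int(round(region_props[0] * length)))
        cds = max(1, int(round(region_props[1] * length)))
        u5 = min(u5, length - 2)
        cds = min(cds, length - u5 - 1)
        regions = {
            "5'UTR": (1, u5),
            "CDS": (u5 + 1, u5 + cds),
            "3'UTR": (u5 + cds + 1, length),
        }
        transcripts.append(Transcript(tid, "".join(seq), regions))
    truth = PlantedTruth(
        sites=pd.DataFrame(
            site_rows, columns=["transcript_id", "mirna_id", "start", "length", "ratio"]
        )
    )
    return transcripts, truth


def gen_qpcr(
    seed: int,
    genes: list[str],
    planted_fc: dict[str, float],
    ct_sd: float = 0.2,
    n_reps: int = 3,
    reference: str = "18S",
) -> pd.DataFrame:
    """Replicate Ct table (gene, group, replicate, ct, is_reference).

    The reference gene's Ct is identically distributed in both groups; each
    target gene's disease Ct is shifted by −log2(planted fold change).
    Gaussian noise with sd ``ct_sd`` is added to every well.
    """
    if n_reps < 2:
        raise ConfigurationError("invalid n_reps: need ≥ 2 replicates")
    for g, f in planted_fc.items():
        if f <= 0:
            raise ConfigurationError(f"invalid planted_fc for {g}: must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    base_ref = 10.0  # abundant housekeeping RNA → low Ct
    all_genes = [reference] + [g for g in genes if g != reference]
    base_ct = {reference: base_ref}
    for g in all_genes[1:]:
        base_ct[g] = float(rng.uniform(20.0, 30.0))
    for g in all_genes:
        fc = 1.0 if g == reference else planted_fc.get(g, 1.0)
        for group in ("control", "disease"):
            shift = -np.log2(fc) if group == "disease" else 0.0
            for r in range(1, n_reps + 1):
                ct = base_ct[g] + shift + rng.normal(0.0, ct_sd)
                rows.append(
                    {
                        "gene": g,
                        "group": group,
                        "replicate": r,
                        "ct": float(ct),
                        "is_reference": g == reference,
                    }
                )
    return pd.DataFrame(rows)
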
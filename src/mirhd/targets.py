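"""Full-length hybridization scan of miRNAs along mRNA transcripts.

Every window of miRNA length on the mRNA sense strand is scored with the
hydrogen-bond energy model; windows whose ΔG/ΔGm ratio reaches the retention
threshold (80% by default) are kept, overlapping candidates are reduced to
local maxima of the ratio, and each retained site is localized to the
5'UTR/CDS/3'UTR and rendered as a two-line pairing scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energy import EnergyModel, clean_rna, duplex_energy, encode, max_duplex_energy
from .errors import ContractError, InputError

REGIONS = ("5'UTR", "CDS", "3'UTR")

#: tolerance for ratio comparisons (ratios are percentages)
_RATIO_EPS = 1e-9


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA sequence, 5'→3', strict RNA alphabet after T→U."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", clean_rna(self.seq))
        if not 16 <= len(self.seq) <= 27:
            raise ContractError(
                f"miRNA {self.id!r}: length {len(self.seq)} outside 16–27 nt"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Transcript:
    """An mRNA sequence with contiguous 5'UTR/CDS/3'UTR spans.

    ``regions`` maps each label to a 1-based inclusive ``(start, end)``
    interval; the intervals must be non-overlapping, contiguous and cover
    the whole sequence.  Empty regions are simply absent from the map.
    """

    id: str
    seq: str
    regions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", clean_rna(self.seq))
        if not self.regions:
            object.__setattr__(self, "regions", {"CDS": (1, len(self.seq))})
        spans = sorted(self.regions.values())
        if spans[0][0] != 1 or spans[-1][1] != len(self.seq):
            raise ContractError(
                f"transcript {self.id!r}: regions do not cover [1, {len(self.seq)}]"
            )
        for (a, b), (c, _) in zip(spans, spans[1:]):
            if c != b + 1:
                raise ContractError(
                    f"transcript {self.id!r}: regions not contiguous at {b}/{c}"
                )
        for label in self.regions:
            if label not in REGIONS:
                raise ContractError(f"unknown region label {label!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class BindingSite:
    """One predicted miRNA site on an mRNA.

    ``start`` is the 1-based position of the 5'-most duplexed mRNA base;
    the site spans ``start .. start + length − 1`` on the sense strand.
    ``ratio`` is 100·ΔG/ΔGm (percent); retained sites satisfy
    ``min_ratio ≤ ratio ≤ 100``.
    """

    mirna_id: str
    transcript_id: str
    start: int
    length: int
    dG: float
    dGm: float
    ratio: float
    region: str
    scheme: str = ""


def localize_region(start: int, length: int, transcript: Transcript) -> str:
    """Region label of the site's start position; boundary-spanning sites
    are labelled by where they start."""
    if start < 1 or start + length - 1 > len(transcript):
        raise ContractError(
            f"site [{start}, {start + length - 1}] outside transcript "
            f"{transcript.id!r} of length {len(transcript)}"
        )
    for label, (a, b) in transcript.regions.items():
        if a <= start <= b:
            return label
    raise ContractError(f"position {start} not covered by any region")  # pragma: no cover


def render_scheme(
    mirna: MiRNA,
    transcript: Transcript,
    start: int,
    model: EnergyModel | None = None,
) -> str:
    """Two-line pairing diagram: mRNA window 5'→3' on top, miRNA 3'→5'
    beneath, with '|' canonical, ':' non-canonical and ' ' mismatch glyphs."""
    model = model or EnergyModel()
    L = len(mirna)
    window = transcript.seq[start - 1 : start - 1 + L]
    mir_rev = mirna.seq[::-1]  # 3'→5' so each column pairs antiparallel
    glyphs = "".join(model.glyph(m, w) for m, w in zip(mir_rev, window))
    dg = duplex_energy(mirna.seq, window, model)
    dgm = max_duplex_energy(mirna.seq, model)
    ratio = 100.0 * dg / dgm if dgm else 0.0
    head = (
        f"{transcript.id} : {mirna.id}  start={start}  "
        f"dG={dg:.1f} kJ/mol  dG/dGm={ratio:.0f}%"
    )
    top = f"5'-{window}-3' mRNA"
    mid = f"   {glyphs}"
    bot = f"3'-{mir_rev}-5' {mirna.id}"
    return "\n".join([head, top, mid, bot])


def _window_bond_sums(mir_codes: np.ndarray, tr_codes: np.ndarray, bond: np.ndarray) -> np.ndarray:
    """Vectorized bond totals for every window start (0-based).

    With the miRNA reversed, window position j pairs miRNA position
    L−1−j, so the score of the window at start s is
    Σ_j bond[mir_rev[j], transcript[s+j]].
    """
    L = mir_codes.size
    n_win = tr_codes.size - L + 1
    mir_rev = mir_codes[::-1]
    sums = np.zeros(n_win)
    for j in range(L):
        sums += bond[mir_rev[j], tr_codes[j : j + n_win]]
    return sums


def _local_max_filter(starts: np.ndarray, ratios: np.ndarray, length: int) -> np.ndarray:
    """Keep a retained window iff it strictly beats every overlapping retained
    window on ratio, with ties broken toward the smaller start."""
    keep = np.ones(starts.size, dtype=bool)
    for i in range(starts.size):
        for j in range(starts.size):
            if i == j:
                continue
            if abs(int(starts[i]) - int(starts[j])) < length:
                if ratios[j] > ratios[i] + _RATIO_EPS or (
                    abs(ratios[j] - ratios[i]) <= _RATIO_EPS and starts[j] < starts[i]
                ):
                    keep[i] = False
                    break
    return keep


def scan(
    mirna: MiRNA,
    transcript: Transcript,
    model: EnergyModel | None = None,
    min_ratio: float = 80.0,
) -> list[BindingSite]:
    """All retained binding sites of one miRNA on one transcript.

    Evaluates every window start 1 … L_mRNA − L_miRNA + 1, retains windows
    with ratio ≥ ``min_ratio``, reduces overlapping retained windows to
    local maxima of ratio (ties → smallest start) and sorts by start.
    """
    model = model or EnergyModel()
    if min_ratio <= 0:
        raise ContractError("min_ratio must be > 0")
    L = len(mirna)
    if len(transcript) < L:
        warnings.warn(
            f"transcript {transcript.id!r} shorter than miRNA {mirna.id!r}; "
            "no windows to scan"
        )
        return []
    bond = model.bond_matrix()
    mir_codes = encode(mirna.seq)
    tr_codes = encode(transcript.seq)
    bonds = _window_bond_sums(mir_codes, tr_codes, bond)
    dgm = float(
        sum(bond[i, _complement_code(i)] for i in mir_codes) * model.energy_per_bond
    )
    if dgm == 0.0:
        return []  # degenerate model: nothing can bind
    energies = bonds * model.energy_per_bond
    ratios = 100.0 * energies / dgm
    retained = np.flatnonzero(ratios >= min_ratio - _RATIO_EPS)
    if retained.size == 0:
        return []
    starts = retained + 1  # 1-based
    r = ratios[retained]
    keep = _local_max_filter(starts, r, L)
    sites = []
    for s, ratio, e in zip(starts[keep], r[keep], energies[retained][keep]):
        region = localize_region(int(s), L, transcript)
        sites.append(
            BindingSite(
                mirna_id=mirna.id,
                transcript_id=transcript.id,
                start=int(s),
                length=L,
                dG=float(e),
                dGm=float(dgm),
                ratio=float(ratio),
                region=region,
                scheme=render_scheme(mirna, transcript, int(s), model),
            )
        )
    return sorted(sites, key=lambda x: x.start)


_COMP_CODE = {0: 3, 1: 2, 2: 1, 3: 0}  # A↔U, C↔G


def _complement_code(code: int) -> int:
    return _COMP_CODE[int(code)]


def sites_to_frame(sites: list[BindingSite]) -> pd.DataFrame:
    """Tabular view of a list of sites (one row per site)."""
    return pd.DataFrame(
        [
            {
                "mirna": s.mirna_id,
                "gene": s.transcript_id,
                "start": s.start,
                "length_nt": s.length,
                "dG_kj_mol": s.dG,
                "dGm_kj_mol": s.dGm,
                "ratio_pct": s.ratio,
                "region": s.region,
            }
            for s in sites
        ],
        columns=[
            "mirna",
            "gene",
            "start",
            "length_nt",
            "dG_kj_mol",
            "dGm_kj_mol",
            "ratio_pct",
            "region",
        ],
    )


def scan_many(
    mirnas: list[MiRNA],
    transcripts: list[Transcript],
    model: EnergyModel | None = None,
    min_ratio: float = 80.0,
) -> pd.DataFrame:
    """Scan every miRNA against every transcript; returns the concatenated
    site table sorted by (mirna, gene, start)."""
    if not mirnas or not transcripts:
        raise InputError("scan_many requires non-empty miRNA and transcript lists")
    for name, ids in (("miRNA", [m.id for m in mirnas]), ("transcript", [t.id for t in transcripts])):
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate {name} ids: {dupes}")
    all_sites: list[BindingSite] = []
    for m in mirnas:
        for t in transcripts:
            if len(t) < len(m):
                continue  # skip silently in bulk mode
            all_sites.extend(scan(m, t, model, min_ratio))
    frame = sites_to_frame(all_sites)
    return frame.sort_values(["mirna", "gene", "start"], kind="mergesort").reset_index(
        drop=True
    )


def site_count_table(sites: pd.DataFrame) -> pd.DataFrame:
    """Per-(miRNA, gene) summary with the multi-site start dialect
    ``a÷b (n)`` used in published site tables."""
    rows = []
    for (mirna, gene), grp in sites.groupby(["mirna", "gene"], sort=True):
        starts = sorted(grp["start"])
        n = len(starts)
        start_str = "÷".join(str(s) for s in starts) + (f" ({n})" if n > 1 else "")
        dgs = sorted(set(round(v, 1) for v in grp["dG_kj_mol"]))
        dg_str = "÷".join(f"{v:g}" for v in dgs)
        ratios = sorted(set(round(v) for v in grp["ratio_pct"]))
        ratio_str = "÷".join(str(int(v)) for v in ratios)
        regions = list(dict.fromkeys(grp.sort_values("start")["region"]))
        rows.append(
            {
                "mirna": mirna,
                "gene": gene,
                "start": start_str,
                "n_sites": n,
                "dG_kj_mol": dg_str,
                "ratio_pct": ratio_str,
                "region": "÷".join(regions),
                "length_nt": int(grp["length_nt"].iloc[0]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna",
            "gene",
            "start",
            "n_sites",
            "dG_kj_mol",
            "ratio_pct",
            "region",
            "length_nt",
        ],
    )
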
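"""Epidermal cell-file patterning statistics.

Grass leaf epidermis organises specialised cells (stomata, prickle hair
cells, silica-cork cell pairs) into longitudinal cell files in which each
specialised cell is normally separated from the next by a single pavement
cell (the one-cell spacing rule, a product of asymmetric cell division).
Patterning mutants violate this rule and produce clusters of adjacent
specialised cells.

A cell file is encoded as a token sequence:

====== =======================================================
token  meaning
====== =======================================================
``S``  stoma (a guard-cell pair with its subsidiary cells)
``E``  pavement (epidermal) cell
``P``  prickle hair cell
``C``  silica-cork cell pair (scored as two cells)
``U``  non-pavement cell of unclear identity (one cell)
``X``  shared subsidiary cell joining two adjacent stomata
====== =======================================================

Event conventions: a stomatal event is a single stoma, a stomatal cluster,
or two guard-cell pairs flanked by a single (shared) subsidiary cell; a
normal stoma and a cluster each count as one event.  The three stomatal
event classes (single / cluster / shared-subsidiary) are kept mutually
exclusive.  Runs touching a file end still count as one event.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

__all__ = [
    "CellFile",
    "StomatalSummary",
    "PrickleSummary",
    "SilicaSummary",
    "stomatal_events",
    "prickle_index",
    "silica_cell_index",
    "stomatal_density_index",
    "simulate_cell_files",
]

FileType = Literal["stomatal", "prickle", "silica_cork"]

_ALPHABETS: dict[str, frozenset] = {
    "stomatal": frozenset("SEX"),
    "prickle": frozenset("PE"),
    "silica_cork": frozenset("CUE"),
}
_SPECIALISED = {"stomatal": "S", "prickle": "P", "silica_cork": "C"}


@dataclass(frozen=True)
class CellFile:
    """One epidermal cell file as an ordered token sequence."""

    file_type: FileType
    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.file_type not in _ALPHABETS:
            raise ValueError(f"unknown file_type {self.file_type!r}")
        if not self.tokens:
            raise ValueError("cell file must be non-empty")
        bad = set(self.tokens) - _ALPHABETS[self.file_type]
        if bad:
            raise ValueError(f"invalid tokens {sorted(bad)} for a {self.file_type} file")

    @classmethod
    def from_string(cls, file_type: FileType, text: str) -> "CellFile":
        """Parse a comma-separated token string, e.g. ``"S,E,S,S,E"``."""
        return cls(file_type, tuple(t.strip().upper() for t in text.split(",") if t.strip()))


# ---------------------------------------------------------------------------
# Stomatal files
# ---------------------------------------------------------------------------

@dataclass
class StomatalSummary:
    n_events: int
    n_single: int
    n_shared_subsidiary: int
    cluster_sizes: Counter = field(default_factory=Counter)
    wide_spacing: int = 0  # gaps of >= 2 pavement cells between events

    @property
    def n_cluster(self) -> int:
        return sum(self.cluster_sizes.values())

    @property
    def n_stomata(self) -> int:
        singles = self.n_single + 2 * self.n_shared_subsidiary
        return singles + sum(k * v for k, v in self.cluster_sizes.items())

    @property
    def event_cluster_pct(self) -> float:
        return 100.0 * self.n_cluster / self.n_events if self.n_events else 0.0

    @property
    def wide_spacing_pct(self) -> float:
        return 100.0 * self.wide_spacing / self.n_events if self.n_events else 0.0


def _events(tokens: Iterable[str], specialised: set[str]) -> list[tuple[list[str], int]]:
    """Maximal runs of specialised tokens, each with the pavement gap length
    preceding it (-1 for the first run, which touches no previous event)."""
    runs: list[tuple[list[str], int]] = []
    current: list[str] = []
    gap = -1
    pending_gap = -1
    for t in tokens:
        if t in specialised:
            if not current:
                pending_gap = gap
            current.append(t)
            gap = 0
        else:
            if current:
                runs.append((current, pending_gap))
                current = []
            gap = gap + 1 if gap >= 0 else -1
    if current:
        runs.append((current, pending_gap))
    return runs


def stomatal_events(cell_file: CellFile) -> StomatalSummary:
    """Classify stomatal events in one file.

    Maximal runs of ``S`` (optionally joined by a shared-subsidiary ``X``)
    form one event each: a lone ``S`` is a single stoma; an ``X``-joined run
    is a shared-subsidiary event; any other run of length > 1 is a cluster of
    its size.  Gaps of two or more pavement cells between consecutive events
    are tallied as wide-spacing occurrences.
    """
    if cell_file.file_type != "stomatal":
        raise ValueError("stomatal_events requires a stomatal file")
    summary = StomatalSummary(n_events=0, n_single=0, n_shared_subsidiary=0)
    for run, gap in _events(cell_file.tokens, {"S", "X"}):
        # X only has meaning between two S; strip danglers
        while run and run[0] == "X":
            run = run[1:]
        while run and run[-1] == "X":
            run = run[:-1]
        if not run:
            continue
        summary.n_events += 1
        n_s = sum(1 for t in run if t == "S")
        if "X" in run:
            summary.n_shared_subsidiary += 1
        elif n_s == 1:
            summary.n_single += 1
        else:
            summary.cluster_sizes[n_s] += 1
        if gap >= 2:
            summary.wide_spacing += 1
    return summary


# ---------------------------------------------------------------------------
# Prickle hair files
# ---------------------------------------------------------------------------

@dataclass
class PrickleSummary:
    index: float  # prickle cells / all cells in the file
    n_events: int
    cluster_sizes: Counter


def prickle_index(cell_file: CellFile) -> PrickleSummary:
    """Prickle hair cell index: ratio of prickle hair cells to total cells in
    the file, plus the histogram of maximal prickle-cell run sizes."""
    if cell_file.file_type != "prickle":
        raise ValueError("prickle_index requires a prickle file")
    n_p = sum(1 for t in cell_file.tokens if t == "P")
    runs = _events(cell_file.tokens, {"P"})
    sizes = Counter(len(run) for run, _gap in runs)
    return PrickleSummary(index=n_p / len(cell_file.tokens), n_events=len(runs), cluster_sizes=sizes)


# ---------------------------------------------------------------------------
# Silica-cork files
# ---------------------------------------------------------------------------

@dataclass
class SilicaSummary:
    index: float  # non-pavement cells / all cells (C scores as 2 cells)
    n_events: int
    n_normal_pair: int
    n_single_missing: int
    cluster_bands: Counter  # keys "3-5", "6-9", ">=10"


def silica_cell_index(cell_file: CellFile) -> SilicaSummary:
    """Cell index of a silica-cork file: proportion of non-pavement cells
    (silica, cork and unclear-identity cells) among all cells in the file.

    A silica-cork pair token ``C`` scores as two cells (silica + cork),
    ``U`` and ``E`` as one.  Events are maximal non-pavement runs,
    classified by their cell count: a lone ``C`` is a normal pair, a lone
    ``U`` a missing/single cell, larger runs fall into cluster size bands
    3-5, 6-9 and >=10.
    """
    if cell_file.file_type != "silica_cork":
        raise ValueError("silica_cell_index requires a silica_cork file")
    weight = {"C": 2, "U": 1, "E": 1}
    total = sum(weight[t] for t in cell_file.tokens)
    non_pav = sum(weight[t] for t in cell_file.tokens if t != "E")
    runs = _events(cell_file.tokens, {"C", "U"})
    n_pair = n_single = 0
    bands: Counter = Counter()
    for run, _gap in runs:
        cells = sum(weight[t] for t in run)
        if run == ["C"]:
            n_pair += 1
        elif cells <= 2:
            n_single += 1
        elif cells <= 5:
            bands["3-5"] += 1
        elif cells <= 9:
            bands["6-9"] += 1
        else:
            bands[">=10"] += 1
    return SilicaSummary(
        index=non_pav / total if total else 0.0,
        n_events=len(runs),
        n_normal_pair=n_pair,
        n_single_missing=n_single,
        cluster_bands=bands,
    )


# ---------------------------------------------------------------------------
# Density and index
# ---------------------------------------------------------------------------

def stomatal_density_index(
    n_stomata_individual: int,
    n_events: int,
    n_epidermal_cells: int,
    area_mm2: float,
    mode: str = "individual",
) -> tuple[float, float]:
    """Stomatal density (stomata per mm^2) and stomatal index.

    ``mode="individual"`` counts every stoma in a cluster; ``mode="events"``
    counts each cluster once.  The stomatal index is the frequency of
    epidermal cells that are stomata: ``count / (count + pavement cells)``.
    """
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    if mode not in ("individual", "events"):
        raise ValueError(f"mode must be 'individual' or 'events', got {mode!r}")
    count = n_stomata_individual if mode == "individual" else n_events
    density = count / area_mm2
    index = count / (count + n_epidermal_cells) if count + n_epidermal_cells > 0 else 0.0
    return density, index


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_cell_files(
    file_type: FileType,
    n_files: int,
    file_len: int,
    violation_prob: float,
    seed: int = 0,
) -> list[CellFile]:
    """Simulate cell files with controllable spacing-rule violations.

    The wild-type pattern alternates specialised and pavement tokens.  After
    each specialised cell, the following pavement cell is independently
    converted to the specialised type with probability ``violation_prob``,
    merging neighbouring events into clusters: 0 gives perfect one-cell
    spacing, 1 collapses each file into a single maximal cluster.

    The fraction of converted gaps estimates ``violation_prob``, and the
    expected number of events per file with ``m`` specialised positions is
    ``1 + (m - 1)(1 - violation_prob)``.
    """
    if not 0 <= violation_prob <= 1:
        raise ValueError("violation_prob must be in [0, 1]")
    if n_files <= 0 or file_len <= 0:
        raise ValueError("n_files and file_len must be positive")
    spec = _SPECIALISED[file_type]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    files = []
    for _ in range(n_files):
        tokens = []
        for i in range(file_len):
            if i % 2 == 0:
                tokens.append(spec)
            else:
                converted = rng.random() < violation_prob
                tokens.append(spec if converted else "E")
        files.append(CellFile(file_type=file_type, tokens=tuple(tokens)))
    return files
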
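"""Bulked-segregant mapping: allele-frequency tracks, smoothing, peak calling,
NIL introgression detection and recombinant fine mapping.

In a phenotype-selected recessive mutant bulk, every member is homozygous for
the mutant allele at the causal locus, so the pooled mutant-allele frequency
is 1.0 there and decays towards 0.5 with increasing recombination distance
(expected frequency ``1 - c`` at marker-to-locus recombination fraction
``c``).  Scanning the smoothed frequency track for runs near 1.0 therefore
localises the causal locus.

Tracks are plain DataFrames:

* frequency track: ``chrom, pos_bp, freq, depth, passed_filters``
  (``freq`` is NaN at sites failing filters);
* smoothed track: frequency track plus a ``smoothed_freq`` column;
* candidate intervals: ``chrom, start_bp, end_bp, peak_bp, peak_freq,
  n_supporting_sites``;
* introgression segments: ``chrom, start_bp, end_bp, n_markers, donor_label``.

All bp coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GENO_MISSING, MarkerMap, Population

__all__ = [
    "mutant_allele_frequency",
    "rolling_average",
    "call_candidate_region",
    "chip_bsa_classify",
    "detect_introgressions",
    "fine_map_interval",
    "FineMapResult",
]

INTERVAL_COLUMNS = ["chrom", "start_bp", "end_bp", "peak_bp", "peak_freq", "n_supporting_sites"]
logger = logging.getLogger(__name__)

SEGMENT_COLUMNS = ["chrom", "start_bp", "end_bp", "n_markers", "donor_label"]


def mutant_allele_frequency(
    counts: pd.DataFrame,
    min_depth: int = 30,
    min_quality: float = 100.0,
) -> pd.DataFrame:
    """Per-site mutant-allele frequency with depth/quality filters.

    The frequency is the number of reads supporting the mutant allele divided
    by the total reads at the site (``alt/(ref+alt)``); sites below
    ``min_depth`` total reads or ``min_quality`` site quality are flagged
    failed and carry no frequency.  The defaults (depth 30, quality 100)
    match typical exome-capture BSA filtering.
    """
    if counts.empty:
        return pd.DataFrame(columns=["chrom", "pos_bp", "freq", "depth", "passed_filters"])
    out = counts.sort_values(["chrom", "pos_bp"], kind="stable").reset_index(drop=True)
    depth = (out["ref_reads"] + out["alt_reads"]).to_numpy()
    passed = (depth >= min_depth) & (out["base_quality"].to_numpy() >= min_quality)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(passed & (depth > 0), out["alt_reads"].to_numpy() / np.maximum(depth, 1), np.nan)
    return pd.DataFrame(
        {
            "chrom": out["chrom"],
            "pos_bp": out["pos_bp"],
            "freq": freq,
            "depth": depth,
            "passed_filters": passed,
        }
    )


def rolling_average(
    track: pd.DataFrame,
    window: float,
    window_units: str = "bp",
) -> pd.DataFrame:
    """Rolling-average smoothing of a frequency track.

    At each passing site the smoothed value is the unweighted mean of
    passing-site frequencies within the window centred on that site:
    sites within ``window/2`` bp (``window_units="bp"``) or the ``window``
    nearest sites by rank (``window_units="markers"``, centred and clipped at
    chromosome ends).  Failed sites get no smoothed value.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if window_units not in ("bp", "markers"):
        raise ValueError(f"window_units must be 'bp' or 'markers', got {window_units!r}")
    out = track.reset_index(drop=True)
    smoothed = np.full(len(out), np.nan)
    for _, idx in out.groupby("chrom", sort=False).indices.items():
        sub = out.iloc[idx]
        ok = sub["passed_filters"].to_numpy()
        pos = sub["pos_bp"].to_numpy()[ok]
        freq = sub["freq"].to_numpy()[ok]
        if len(freq) == 0:
            continue
        vals = np.full(ok.sum(), np.nan)
        if window_units == "bp":
            half = window / 2.0
            lo = np.searchsorted(pos, pos - half, side="left")
            hi = np.searchsorted(pos, pos + half, side="right")
            csum = np.concatenate([[0.0], np.cumsum(freq)])
            vals = (csum[hi] - csum[lo]) / (hi - lo)
        else:
            w = int(window)
            k_left = (w - 1) // 2
            n = len(freq)
            for i in range(n):
                lo_i = max(0, min(i - k_left, n - w))
                hi_i = min(n, lo_i + w)
                vals[i] = freq[lo_i:hi_i].mean()
        dest = np.asarray(idx)[ok]
        smoothed[dest] = vals
    out["smoothed_freq"] = smoothed
    return out


def call_candidate_region(
    smoothed: pd.DataFrame,
    freq_threshold: float = 0.9,
    min_sites: int = 5,
) -> pd.DataFrame:
    """Call candidate intervals as maximal runs of high smoothed frequency.

    A run is a maximal stretch of consecutive passing sites (per chromosome)
    with smoothed frequency >= ``freq_threshold`` containing at least
    ``min_sites`` sites.  The peak is the first site attaining the run
    maximum (leftmost tie-break).
    """
    if smoothed.empty:
        raise ValueError("smoothed track is empty")
    rows = []
    for chrom, sub in smoothed.groupby("chrom", sort=False):
        sub = sub[sub["passed_filters"] & sub["smoothed_freq"].notna()]
        if sub.empty:
            continue
        pos = sub["pos_bp"].to_numpy()
        val = sub["smoothed_freq"].to_numpy()
        above = val >= freq_threshold
        # run boundaries
        edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s < min_sites:
                continue
            peak = s + int(np.argmax(val[s:e]))
            rows.append((chrom, int(pos[s]), int(pos[e - 1]), int(pos[peak]), float(val[peak]), int(e - s)))
    return pd.DataFrame(rows, columns=INTERVAL_COLUMNS)


def chip_bsa_classify(
    pooled_freq,
    het_band: tuple[float, float] = (0.35, 0.65),
    hom_min: float = 0.9,
) -> np.ndarray:
    """Classify pooled chip-call allele frequencies per marker.

    Far from the causal locus a mutant bulk shows ~0.5 of each parental
    allele (called heterozygous); approaching the causal locus the mutant
    allele predominates towards 1.0 (called homozygous mutant); frequencies
    in between are 'intermediate' (heterozygous-or-missing in chip terms).
    """
    freq = np.atleast_1d(np.asarray(pooled_freq, dtype=float))
    if np.any((freq < 0) | (freq > 1)):
        raise ValueError("pooled frequencies must be in [0, 1]")
    labels = np.full(freq.shape, "intermediate", dtype=object)
    labels[(freq >= het_band[0]) & (freq <= het_band[1])] = "heterozygous"
    labels[freq >= hom_min] = "homozygous_mutant"
    return labels


def detect_introgressions(
    nil_genotype,
    recurrent_genotype,
    donor_genotype,
    marker_map: MarkerMap,
    min_run: int = 3,
    max_gap_markers: int = 1,
    donor_label: str = "donor",
) -> pd.DataFrame:
    """Detect donor introgression segments in a NIL genotype.

    Only markers polymorphic between the recurrent and donor parents are
    informative.  A segment is a maximal run of informative markers at which
    the NIL matches the donor, tolerating at most ``max_gap_markers``
    consecutive non-donor calls inside the run, and containing at least
    ``min_run`` donor-matching markers.  Segment bounds are the first/last
    donor-matching marker positions.
    """
    nil = np.asarray(nil_genotype)
    rec = np.asarray(recurrent_genotype)
    don = np.asarray(donor_genotype)
    if not (len(nil) == len(rec) == len(don) == marker_map.n_markers):
        raise ValueError("genotype vectors must match the marker map length")
    chroms = marker_map.markers["chrom"].to_numpy()
    pos = marker_map.markers["pos_bp"].to_numpy()
    rows = []
    for chrom, _len in marker_map.chromosomes:
        on = chroms == chrom
        informative = on & (rec != don)
        if not informative.any():
            continue
        p = pos[informative]
        match = (nil == don)[informative]
        n = len(match)
        i = 0
        while i < n:
            if not match[i]:
                i += 1
                continue
            # extend a run from the donor-matching marker at i
            j = i
            last_match = i
            gap = 0
            while j + 1 < n:
                if match[j + 1]:
                    j += 1
                    last_match = j
                    gap = 0
                elif gap + 1 <= max_gap_markers:
                    gap += 1
                    j += 1
                else:
                    break
            n_match = int(match[i : last_match + 1].sum())
            if n_match >= min_run:
                rows.append((chrom, int(p[i]), int(p[last_match]), n_match, donor_label))
            i = last_match + 1
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


@dataclass(frozen=True)
class FineMapResult:
    chrom: str
    start_bp: int
    end_bp: int
    n_informative_mutants: int

    @property
    def width_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def fine_map_interval(
    population: Population,
    marker_map: MarkerMap,
    search_interval: tuple[str, int, int],
    mutant_parent: str = "A",
    model: str = "recessive",
) -> FineMapResult:
    """Narrow a candidate interval using recombinant mutant individuals.

    Under a recessive model every mutant individual is homozygous for the
    mutant-linked allele across the region containing the causal locus, so
    each mutant restricts the locus to the union of its homozygous-mutant
    marker runs, open at the flanking heterozygous/wild-type markers (or
    clipped at the search-interval ends).  The feasible region is the
    intersection of all mutant constraints.

    Wild-type individuals are mostly uninformative (a heterozygote excludes
    nothing), with one exception used to disambiguate disjoint feasible
    sub-intervals: a wild-type individual homozygous for the mutant-linked
    allele at every marker of a whole remaining sub-interval rules that
    sub-interval out, because the causal locus there would have made it
    mutant.

    Adding mutant individuals can only shrink the interval.  An empty
    feasible region raises, signalling a phenotyping or genotyping error.
    """
    if model != "recessive":
        raise ValueError("only the recessive model is supported")
    chrom, lo, hi = search_interval
    idx = marker_map.chrom_index(chrom)
    pos = marker_map.markers["pos_bp"].to_numpy()[idx]
    inside = (pos >= lo) & (pos <= hi)
    idx, pos = idx[inside], pos[inside]
    if len(idx) < 2:
        raise ValueError("need >= 2 markers inside the search interval")
    hom_code = 0 if mutant_parent == "A" else 2

    # current feasible region as a list of disjoint (start, end) intervals
    feasible: list[tuple[int, int]] = [(int(lo), int(hi))]
    n_used = 0
    n_skipped = 0
    for i in np.flatnonzero(population.is_mutant):
        g = population.genotypes[i, idx]
        hom = g == hom_code
        known = g != GENO_MISSING
        if not (hom & known).any():
            # double recombinant (or mis-genotyped) mutant heterozygous at
            # every marker: the causal locus falls between adjacent markers
            # and the individual carries no usable constraint
            n_skipped += 1
            continue
        if hom[known].all():
            continue  # non-recombinant: no constraint
        n_used += 1
        allowed: list[tuple[int, int]] = []
        j = 0
        m = len(g)
        while j < m:
            if not hom[j]:
                j += 1
                continue
            k = j
            while k + 1 < m and (hom[k + 1] or not known[k + 1]):
                k += 1
            # trim trailing unknowns so the run ends on a hom marker
            while not hom[k]:
                k -= 1
            start = int(lo) if j == 0 else int(pos[j - 1]) + 1
            end = int(hi) if k == m - 1 else int(pos[k + 1]) - 1
            allowed.append((start, end))
            j = k + 1
        feasible = _intersect_interval_sets(feasible, allowed)
        if not feasible:
            raise ValueError(
                "no consistent interval: mutant constraints have empty intersection"
            )
    if n_skipped:
        logger.warning(
            "fine_map_interval: skipped %d mutant individuals with no "
            "homozygous-mutant marker in the interval", n_skipped,
        )
    # wild-type exclusion of whole remaining sub-intervals
    if len(feasible) > 1:
        wt_genotypes = population.genotypes[~population.is_mutant][:, idx]
        kept = []
        for s, e in feasible:
            markers_in = (pos >= s) & (pos <= e)
            if markers_in.any():
                g_in = wt_genotypes[:, markers_in]
                excluded = ((g_in == hom_code).all(axis=1)).any()
            else:
                excluded = False
            if not excluded:
                kept.append((s, e))
        if kept:  # contradictory wild-type evidence against everything is ignored
            feasible = kept
    # if several disjoint intervals still survive, report the widest (leftmost tie)
    best = max(feasible, key=lambda se: (se[1] - se[0], -se[0]))
    return FineMapResult(chrom=chrom, start_bp=best[0], end_bp=best[1], n_informative_mutants=n_used)


def _intersect_interval_sets(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    out = []
    for s1, e1 in a:
        for s2, e2 in b:
            s, e = max(s1, s2), min(e1, e2)
            if s <= e:
                out.append((s, e))
    out.sort()
    return out
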
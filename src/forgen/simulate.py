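"""Synthetic data generation for forward-genetics pipelines.

Everything downstream consumes objects built here: genetic marker maps,
biparental F2 crosses with one or two recessive causal loci, phenotype-selected
mutant bulks, per-site sequencing read counts, near-isogenic-line (NIL)
genotypes with donor introgressions, and homozygous accession SNP panels with
group labels and geographic coordinates.

All generators are pure functions of their arguments and a seed: the same call
returns bit-identical output.  Randomness is split per stage with
:class:`numpy.random.SeedSequence` so adding a downstream draw never perturbs
an upstream one.

Conventions
-----------
* Physical coordinates are 1-based inclusive base pairs (VCF convention).
* Marker genotypes are coded as the count of parent-B alleles:
  ``0 = AA, 1 = AB, 2 = BB, -1 = missing``.
* The recombination model is per-interval independent Bernoulli with the
  recombination fraction obtained from the inverse Haldane map function
  (no crossover interference).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .genetics import haldane_inverse

__all__ = [
    "MarkerMap",
    "CausalLocus",
    "CrossSpec",
    "Population",
    "build_marker_map",
    "simulate_f2",
    "select_mutant_bulk",
    "sample_read_counts",
    "simulate_bsa_experiment",
    "simulate_nil",
    "simulate_accession_panel",
]

GENO_AA, GENO_AB, GENO_BB, GENO_MISSING = 0, 1, 2, -1


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerMap:
    """Physical (bp) and genetic (cM) positions of biallelic markers.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    markers
        DataFrame with columns ``chrom, pos_bp, pos_cM, allele_A, allele_B``,
        sorted by chromosome then position; within each chromosome ``pos_bp``
        is strictly increasing and ``pos_cM`` non-decreasing.
    cm_per_mb
        Constant recombination rate used to place markers on the genetic map.
    """

    chromosomes: tuple[tuple[str, int], ...]
    markers: pd.DataFrame
    cm_per_mb: float = 1.0

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        m = self.markers
        required = {"chrom", "pos_bp", "pos_cM", "allele_A", "allele_B"}
        if not required.issubset(m.columns):
            raise ValueError(f"marker table missing columns {required - set(m.columns)}")
        for chrom, sub in m.groupby("chrom", sort=False):
            if chrom not in lengths:
                raise ValueError(f"marker chromosome {chrom!r} not declared")
            pos = sub["pos_bp"].to_numpy()
            if np.any(pos < 1) or np.any(pos > lengths[chrom]):
                raise ValueError(f"marker positions outside chromosome {chrom}")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"pos_bp not strictly increasing on {chrom}")
            if np.any(np.diff(sub["pos_cM"].to_numpy()) < 0):
                raise ValueError(f"pos_cM decreasing on {chrom}")
        if (m["allele_A"] == m["allele_B"]).any():
            raise ValueError("markers must be biallelic with distinct alleles")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def chrom_index(self, chrom: str) -> np.ndarray:
        """Row indices of the markers on one chromosome."""
        return np.flatnonzero((self.markers["chrom"] == chrom).to_numpy())

    def interpolate_cm(self, chrom: str, pos_bp: float) -> float:
        """Genetic position of an arbitrary physical position.

        Uses the constant-rate map (``pos_bp * cm_per_mb / 1e6``), which by
        construction agrees with marker ``pos_cM`` values from
        :func:`build_marker_map`.
        """
        if chrom not in dict(self.chromosomes):
            raise ValueError(f"unknown chromosome {chrom!r}")
        return float(pos_bp) * self.cm_per_mb / 1e6


@dataclass(frozen=True)
class CausalLocus:
    chrom: str
    pos_bp: int
    origin: Literal["A", "B"] = "A"  # parent contributing the mutant allele


@dataclass(frozen=True)
class CrossSpec:
    """A biparental cross producing an F2 with 1 or 2 recessive causal loci.

    With two loci the F1 linkage phase matters: ``repulsion`` means each
    parent carries the mutant allele at a different locus (the configuration
    of a cross between two single mutants), ``coupling`` means one parent
    carries both mutant alleles.
    """

    causal_loci: tuple[CausalLocus, ...]
    n_f2: int
    seed: int
    phase: Literal["coupling", "repulsion"] = "repulsion"
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 1 <= len(self.causal_loci) <= 2:
            raise ValueError("1 or 2 causal loci required")
        if self.n_f2 <= 0:
            raise ValueError("n_f2 must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if len(self.causal_loci) == 2 and self.phase == "repulsion":
            if self.causal_loci[0].origin == self.causal_loci[1].origin:
                raise ValueError("repulsion phase requires loci of opposite parental origin")


@dataclass
class Population:
    """Diploid genotype matrix with phenotypes.

    ``genotypes`` is individuals x markers with codes 0/1/2/-1 (count of
    parent-B alleles).  ``causal_genotypes`` carries the count of *mutant*
    alleles at each causal locus (simulation provenance; absent for imported
    data).  Phenotype labels are ``"wildtype"`` or ``"mutant"``.
    """

    genotypes: np.ndarray
    phenotypes: np.ndarray
    causal_genotypes: np.ndarray | None = None
    cross: CrossSpec | None = None
    provenance: str = "simulated"

    def __post_init__(self) -> None:
        if len(self.genotypes) != len(self.phenotypes):
            raise ValueError("genotype/phenotype length mismatch")

    @property
    def n_individuals(self) -> int:
        return len(self.genotypes)

    @property
    def is_mutant(self) -> np.ndarray:
        return self.phenotypes == "mutant"

    def subset(self, idx: np.ndarray) -> "Population":
        return Population(
            genotypes=self.genotypes[idx],
            phenotypes=self.phenotypes[idx],
            causal_genotypes=None if self.causal_genotypes is None else self.causal_genotypes[idx],
            cross=self.cross,
            provenance=self.provenance,
        )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def build_marker_map(
    n_chrom: int,
    markers_per_chrom: int,
    chrom_len_bp: int,
    cm_per_mb: float = 1.0,
    seed: int = 0,
) -> MarkerMap:
    """Uniformly spread (jittered) markers on equal-length chromosomes.

    Genetic positions follow a constant-rate linear map,
    ``pos_cM = pos_bp * cm_per_mb / 1e6``.
    """
    if n_chrom <= 0 or markers_per_chrom <= 0 or chrom_len_bp <= 0:
        raise ValueError("chromosome and marker counts must be positive")
    if cm_per_mb <= 0:
        raise ValueError("cm_per_mb must be positive")
    chrom_len_bp = int(chrom_len_bp)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for c in range(n_chrom):
        name = f"chr{c + 1}"
        # one marker jittered inside each of markers_per_chrom equal bins
        edges = np.linspace(1, chrom_len_bp, markers_per_chrom + 1)
        lo, hi = edges[:-1], edges[1:]
        pos = np.floor(lo + rng.random(markers_per_chrom) * (hi - lo)).astype(np.int64)
        pos = np.maximum.accumulate(np.clip(pos, 1, chrom_len_bp))
        # enforce strict monotonicity after clipping ties
        for i in range(1, len(pos)):
            if pos[i] <= pos[i - 1]:
                pos[i] = pos[i - 1] + 1
        pos = np.clip(pos, 1, chrom_len_bp)
        alleles = rng.choice(np.array(list("ACGT")), size=(markers_per_chrom, 2))
        same = alleles[:, 0] == alleles[:, 1]
        alleles[same, 1] = np.where(alleles[same, 0] == "A", "G", "A")
        for p, (a, b) in zip(pos, alleles):
            rows.append((name, int(p), p * cm_per_mb / 1e6, a, b))
    markers = pd.DataFrame(rows, columns=["chrom", "pos_bp", "pos_cM", "allele_A", "allele_B"])
    chromosomes = tuple((f"chr{c + 1}", chrom_len_bp) for c in range(n_chrom))
    return MarkerMap(chromosomes=chromosomes, markers=markers, cm_per_mb=cm_per_mb)


def _simulate_gametes(cm_positions: np.ndarray, n_gametes: int, rng: np.random.Generator) -> np.ndarray:
    """Parental source (0 = A, 1 = B) for each gamete at each position.

    Positions are genetic (cM) along one chromosome.  Crossovers occur
    independently in each inter-position interval with probability equal to
    the inverse-Haldane recombination fraction of the cM gap.
    """
    n_pos = len(cm_positions)
    start = rng.integers(0, 2, size=n_gametes)
    if n_pos == 1:
        return start[:, None]
    r = haldane_inverse(np.diff(cm_positions))
    switches = rng.random((n_gametes, n_pos - 1)) < r
    flips = np.concatenate(
        [np.zeros((n_gametes, 1), dtype=np.int64), np.cumsum(switches, axis=1)], axis=1
    )
    return (start[:, None] + flips) % 2


def simulate_f2(marker_map: MarkerMap, cross: CrossSpec) -> Population:
    """Simulate an F2 population from two inbred (homozygous) parents.

    Each individual is the union of two independent F1 gametes; gametes
    recombine along each chromosome with inter-marker recombination fractions
    from the inverse Haldane function.  Causal loci (which may fall between
    markers) ride along as extra positions on the genetic map.

    Phenotype follows the recessive model: an individual is ``mutant`` iff it
    is homozygous for the mutant allele at *any* causal locus (with two loci
    this is duplicate recessive epistasis, giving the classic 9:7 F2 ratio
    when the loci are unlinked).
    """
    if marker_map.n_markers == 0:
        raise ValueError("marker map is empty")
    chrom_names = [c for c, _ in marker_map.chromosomes]
    lengths = dict(marker_map.chromosomes)
    for cl in cross.causal_loci:
        if cl.chrom not in lengths or not 1 <= cl.pos_bp <= lengths[cl.chrom]:
            raise ValueError(f"causal locus off map: {cl}")

    ss = np.random.SeedSequence(cross.seed)
    chrom_seeds = ss.spawn(len(chrom_names) + 1)
    n = cross.n_f2

    genotypes = np.empty((n, marker_map.n_markers), dtype=np.int8)
    causal_mutant_counts = np.zeros((n, len(cross.causal_loci)), dtype=np.int8)

    for ci, chrom in enumerate(chrom_names):
        idx = marker_map.chrom_index(chrom)
        cm = marker_map.markers["pos_cM"].to_numpy()[idx]
        causal_here = [(k, cl) for k, cl in enumerate(cross.causal_loci) if cl.chrom == chrom]
        causal_cm = np.array(
            [marker_map.interpolate_cm(chrom, cl.pos_bp) for _, cl in causal_here]
        )
        aug = np.concatenate([cm, causal_cm])
        order = np.argsort(aug, kind="stable")
        rng = np.random.default_rng(chrom_seeds[ci])
        src = np.empty((2 * n, len(aug)), dtype=np.int64)
        src[:, order] = _simulate_gametes(aug[order], 2 * n, rng)
        g1, g2 = src[:n], src[n:]
        # marker genotype = count of parent-B alleles
        genotypes[:, idx] = (g1[:, : len(cm)] + g2[:, : len(cm)]).astype(np.int8)
        for j, (k, cl) in enumerate(causal_here):
            col = len(cm) + j
            origin_code = 0 if cl.origin == "A" else 1
            causal_mutant_counts[:, k] = (g1[:, col] == origin_code).astype(np.int8) + (
                g2[:, col] == origin_code
            ).astype(np.int8)

    rng_post = np.random.default_rng(chrom_seeds[-1])
    if cross.missing_rate > 0:
        mask = rng_post.random(genotypes.shape) < cross.missing_rate
        genotypes[mask] = GENO_MISSING

    mutant = (causal_mutant_counts == 2).any(axis=1)
    phenotypes = np.where(mutant, "mutant", "wildtype")
    return Population(
        genotypes=genotypes,
        phenotypes=phenotypes,
        causal_genotypes=causal_mutant_counts,
        cross=cross,
    )


def select_mutant_bulk(
    pop: Population,
    bulk_size: int,
    misclassification_rate: float = 0.0,
    seed: int = 0,
) -> Population:
    """Phenotype-select a mutant bulk from an F2 population.

    With ``misclassification_rate`` 0 every member is phenotypically mutant
    (hence homozygous mutant at a causal locus under the recessive model).
    Otherwise each bulk slot is independently swapped for a random wild-type
    individual with that probability, emulating phenotyping error.
    """
    if not 0 <= misclassification_rate <= 1:
        raise ValueError("misclassification_rate must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    mutants = np.flatnonzero(pop.is_mutant)
    wildtypes = np.flatnonzero(~pop.is_mutant)
    if bulk_size > len(mutants):
        raise ValueError(
            f"bulk_size {bulk_size} exceeds the {len(mutants)} available mutant individuals"
        )
    chosen = rng.choice(mutants, size=bulk_size, replace=False)
    if misclassification_rate > 0 and len(wildtypes) > 0:
        swap = rng.random(bulk_size) < misclassification_rate
        n_swap = int(swap.sum())
        if n_swap:
            repl = rng.choice(wildtypes, size=n_swap, replace=n_swap > len(wildtypes))
            chosen = chosen.copy()
            chosen[swap] = repl
    return pop.subset(np.sort(chosen))


def sample_read_counts(
    bulk: Population,
    marker_map: MarkerMap,
    mean_depth: float,
    error_rate: float = 0.0,
    seed: int = 0,
    mutant_parent: Literal["A", "B"] | None = None,
    base_quality: float = 150.0,
) -> pd.DataFrame:
    """Sample pooled sequencing read counts over the bulk at every marker.

    Per site, depth is Poisson(``mean_depth``) and each read is drawn from the
    bulk's allele pool (equal DNA contribution per individual), then flipped
    with probability ``error_rate``.  The *alt* allele is the mutant-parent
    allele, so ``alt/(ref+alt)`` estimates the mutant-allele frequency.

    Returns a DataFrame with columns
    ``chrom, pos_bp, ref_reads, alt_reads, base_quality``.
    """
    if mean_depth < 0:
        raise ValueError("mean_depth must be >= 0")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    if mutant_parent is None:
        if bulk.cross is not None:
            mutant_parent = bulk.cross.causal_loci[0].origin
        else:
            mutant_parent = "A"
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    g = bulk.genotypes.astype(float)
    g[bulk.genotypes == GENO_MISSING] = np.nan
    mutant_dose = (2.0 - g) if mutant_parent == "A" else g
    with np.errstate(invalid="ignore"):
        true_freq = np.nanmean(mutant_dose, axis=0) / 2.0
    true_freq = np.nan_to_num(true_freq, nan=0.5)
    p_read = true_freq * (1 - error_rate) + (1 - true_freq) * error_rate
    depth = rng.poisson(mean_depth, size=marker_map.n_markers)
    alt = rng.binomial(depth, p_read)
    return pd.DataFrame(
        {
            "chrom": marker_map.markers["chrom"].to_numpy(),
            "pos_bp": marker_map.markers["pos_bp"].to_numpy(),
            "ref_reads": depth - alt,
            "alt_reads": alt,
            "base_quality": float(base_quality),
        }
    )


def simulate_bsa_experiment(
    marker_map: MarkerMap,
    causal: CausalLocus,
    n_f2: int,
    bulk_size: int,
    mean_depth: float,
    error_rate: float = 0.0,
    seed: int = 0,
    misclassification_rate: float = 0.0,
    max_attempts: int = 50,
) -> tuple[Population, Population, pd.DataFrame]:
    """Run a full single-locus BSA simulation: F2, mutant bulk, read counts.

    A phenotype-selected bulk of ``bulk_size`` only exists when at least that
    many mutants segregate in the F2 (~1/4 of individuals under the recessive
    model), so crosses yielding too few mutants are redrawn with a
    deterministically shifted sub-seed; the experiment is thus conditional on
    the bulk being collectable, as any real pooled bulk is.

    Returns ``(population, bulk, read_counts)``.
    """
    ss = np.random.SeedSequence(seed)
    sub = ss.generate_state(3, dtype=np.uint32)
    pop = None
    for attempt in range(max_attempts):
        cross = CrossSpec(
            causal_loci=(causal,), n_f2=n_f2, seed=int((sub[0] + attempt) % 2**31)
        )
        pop = simulate_f2(marker_map, cross)
        if int(pop.is_mutant.sum()) >= bulk_size:
            break
    else:
        raise RuntimeError(f"no cross with >= {bulk_size} mutants in {max_attempts} draws")
    bulk = select_mutant_bulk(pop, bulk_size, misclassification_rate, seed=int(sub[1] % 2**31))
    counts = sample_read_counts(bulk, marker_map, mean_depth, error_rate, seed=int(sub[2] % 2**31))
    return pop, bulk, counts


def simulate_nil(
    marker_map: MarkerMap,
    donor_segments: Sequence[tuple[str, int, int]],
    recurrent_haplotype: np.ndarray,
    donor_haplotype: np.ndarray,
) -> np.ndarray:
    """Construct a near-isogenic-line genotype (allele vector over the map).

    The NIL equals the recurrent parent everywhere except inside the donor
    ``(chrom, start_bp, end_bp)`` segments (1-based inclusive), where it is
    homozygous for the donor allele.  Segments must not overlap.
    """
    recurrent = np.asarray(recurrent_haplotype)
    donor = np.asarray(donor_haplotype)
    if len(recurrent) != marker_map.n_markers or len(donor) != marker_map.n_markers:
        raise ValueError("haplotype length does not match marker map")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in donor_segments:
        if start > end:
            raise ValueError(f"segment start > end on {chrom}")
        by_chrom.setdefault(chrom, []).append((start, end))
    for chrom, segs in by_chrom.items():
        segs.sort()
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping donor segments on {chrom}")
    nil = recurrent.copy()
    chroms = marker_map.markers["chrom"].to_numpy()
    pos = marker_map.markers["pos_bp"].to_numpy()
    for chrom, start, end in donor_segments:
        inside = (chroms == chrom) & (pos >= start) & (pos <= end)
        nil[inside] = donor[inside]
    return nil


def simulate_accession_panel(
    n_accessions: int,
    n_sites: int,
    n_groups: int = 2,
    seed: int = 0,
    het_rate: float = 0.0,
    missing_rate: float = 0.0,
    isolation_by_distance: float = 0.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate a homozygous accession SNP panel with geography.

    Accessions belong to ``n_groups`` groups placed along a geographic
    transect; per-site allele frequencies drift between neighbouring groups.
    ``isolation_by_distance`` > 0 increases between-group frequency drift so
    kinship declines with distance.  A small ``het_rate``/``missing_rate``
    contaminates calls to exercise filtering.

    Returns ``(genotypes, metadata)``: genotypes coded 0/1 for the two
    homozygous states, 2 heterozygous, -1 missing; metadata has columns
    ``accession, group, lat, lon``.
    """
    if n_accessions <= 0 or n_sites <= 0 or n_groups <= 0:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    base = rng.uniform(0.1, 0.9, size=n_sites)
    group_of = np.sort(rng.integers(0, n_groups, size=n_accessions))
    # transect of group centres, ~500 km apart, with per-accession jitter
    centre_lat = np.full(n_groups, 35.0)
    centre_lon = 30.0 + 4.5 * np.arange(n_groups)
    freqs = np.empty((n_groups, n_sites))
    f = base.copy()
    for gidx in range(n_groups):
        f = np.clip(f + isolation_by_distance * rng.normal(0, 1, n_sites), 0.02, 0.98)
        freqs[gidx] = f
    geno = (rng.random((n_accessions, n_sites)) < freqs[group_of]).astype(np.int8)
    if het_rate > 0:
        geno[rng.random(geno.shape) < het_rate] = 2
    if missing_rate > 0:
        geno[rng.random(geno.shape) < missing_rate] = -1
    meta = pd.DataFrame(
        {
            "accession": [f"acc{i:04d}" for i in range(n_accessions)],
            "group": [f"group{g + 1}" for g in group_of],
            "lat": centre_lat[group_of] + rng.normal(0, 0.8, n_accessions),
            "lon": centre_lon[group_of] + rng.normal(0, 0.8, n_accessions),
        }
    )
    return geno, meta
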
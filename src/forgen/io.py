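"""Readers, writers, configuration and small reporting utilities.

Coordinate conventions: all internal and TSV coordinates are 1-based
inclusive (VCF convention); BED output is 0-based half-open, converted in a
single place (:func:`to_bed_coords`).  Writers are deterministic: identical
objects serialise byte-identically (stable ordering, floats at 6 significant
digits).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .haplonet import SnpMatrix
from .simulate import GENO_MISSING, MarkerMap, Population

__all__ = [
    "PipelineConfig",
    "setup_logging",
    "fmt_float",
    "to_bed_coords",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_marker_map_tsv",
    "write_marker_map_tsv",
    "read_read_counts_csv",
    "write_read_counts_csv",
    "write_vcf_minimal",
    "read_vcf_minimal",
    "write_intervals_bed",
    "write_intervals_tsv",
    "set_overlap",
]

logger = logging.getLogger(__name__)

_GENO_CODE = {"A": 0, "H": 1, "B": 2, "N": GENO_MISSING}
_CODE_GENO = {v: k for k, v in _GENO_CODE.items()}


# ---------------------------------------------------------------------------
# Configuration and logging
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Run-wide parameters, serialisable to/from a single YAML file.

    Defaults follow exome-capture BSA practice (depth 30, site quality 100,
    100 bp rolling window), a 98% homozygosity site filter and 9999
    permutations for the isolation-by-distance test.
    """

    seed: int = 0
    min_depth: int = 30
    min_quality: float = 100.0
    window: float = 100.0
    window_units: str = "bp"
    freq_threshold: float = 0.9
    min_sites: int = 5
    het_band: tuple[float, float] = (0.35, 0.65)
    hom_min: float = 0.9
    min_hom_fraction: float = 0.98
    n_perm: int = 9999
    map_function: str = "haldane"

    def __post_init__(self) -> None:
        if not 0 <= self.min_depth:
            raise ValueError("min_depth must be >= 0")
        if self.window <= 0:
            raise ValueError("window must be positive")
        if not 0 < self.min_hom_fraction <= 1:
            raise ValueError("min_hom_fraction must be in (0, 1]")
        if not 0 < self.freq_threshold <= 1:
            raise ValueError("freq_threshold must be in (0, 1]")
        if self.map_function not in ("haldane", "kosambi"):
            raise ValueError("map_function must be 'haldane' or 'kosambi'")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["het_band"] = list(d["het_band"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "het_band" in d:
            d["het_band"] = tuple(d["het_band"])
        return cls(**d)


def setup_logging(level: int = logging.INFO) -> None:
    """Log to stderr so machine-readable output on stdout stays clean."""
    logging.basicConfig(
        stream=sys.stderr,
        level=level,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )


def fmt_float(x: float) -> str:
    """Fixed 6-significant-digit float formatting used by all writers."""
    return f"{x:.6g}"


def to_bed_coords(start_bp: int, end_bp: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open (BED)."""
    return start_bp - 1, end_bp


# ---------------------------------------------------------------------------
# Genotype matrix TSV (rows = individuals/accessions, columns = markers,
# codes A/H/B/N)
# ---------------------------------------------------------------------------

def write_genotype_tsv(path: str | Path, genotypes: np.ndarray, ids: list[str], markers: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(markers) + "\n")
        for name, row in zip(ids, genotypes):
            fh.write(name + "\t" + "\t".join(_CODE_GENO[int(g)] for g in row) + "\n")


def read_genotype_tsv(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read an A/H/B/N genotype matrix.

    Returns ``(genotypes, ids, marker_names)`` with codes 0/1/2/-1.  Ragged
    rows and unknown codes raise with the offending line/column named.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}: header must list marker ids")
        markers = header[1:]
        ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} columns, found {len(parts)}"
                )
            ids.append(parts[0])
            row = []
            for col, code in enumerate(parts[1:], start=2):
                if code not in _GENO_CODE:
                    raise ValueError(
                        f"{path}:{lineno}: unknown genotype code {code!r} in column {col} "
                        f"(marker {markers[col - 2]})"
                    )
                row.append(_GENO_CODE[code])
            rows.append(row)
    return np.array(rows, dtype=np.int8), ids, markers


def population_to_tsv(path: str | Path, pop: Population) -> None:
    ids = [f"ind{i:04d}" for i in range(pop.n_individuals)]
    markers = [f"m{j:05d}" for j in range(pop.genotypes.shape[1])]
    write_genotype_tsv(path, pop.genotypes, ids, markers)


def snp_matrix_to_tsv(path: str | Path, matrix: SnpMatrix) -> None:
    # accession panels reuse the same codes: 0 -> A, 1 -> B, 2 -> H, -1 -> N
    recoded = matrix.genotypes.copy()
    recoded[matrix.genotypes == 1] = 2
    recoded[matrix.genotypes == 2] = 1
    write_genotype_tsv(path, recoded, list(matrix.accessions), list(matrix.sites))


def snp_matrix_from_tsv(path: str | Path, metadata: pd.DataFrame | None = None) -> SnpMatrix:
    geno, ids, sites = read_genotype_tsv(path)
    recoded = geno.copy()
    recoded[geno == 2] = 1
    recoded[geno == 1] = 2
    return SnpMatrix(genotypes=recoded, accessions=ids, sites=sites, metadata=metadata)


# ---------------------------------------------------------------------------
# Marker map TSV
# ---------------------------------------------------------------------------

def write_marker_map_tsv(path: str | Path, marker_map: MarkerMap) -> None:
    with open(path, "w") as fh:
        fh.write("#cm_per_mb=" + fmt_float(marker_map.cm_per_mb) + "\n")
        fh.write("#chromosomes=" + ",".join(f"{c}:{l}" for c, l in marker_map.chromosomes) + "\n")
        fh.write("chrom\tpos_bp\tpos_cM\talleles\n")
        for row in marker_map.markers.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos_bp}\t{fmt_float(row.pos_cM)}\t{row.allele_A}/{row.allele_B}\n"
            )


def read_marker_map_tsv(path: str | Path) -> MarkerMap:
    cm_per_mb, chromosomes = 1.0, []
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#cm_per_mb="):
                cm_per_mb = float(line.split("=", 1)[1])
            elif line.startswith("#chromosomes="):
                chromosomes = [
                    (c.split(":")[0], int(c.split(":")[1]))
                    for c in line.split("=", 1)[1].split(",")
                ]
            elif line.startswith("chrom\t") or not line:
                continue
            else:
                chrom, pos_bp, pos_cm, alleles = line.split("\t")
                a, b = alleles.split("/")
                rows.append((chrom, int(pos_bp), float(pos_cm), a, b))
    markers = pd.DataFrame(rows, columns=["chrom", "pos_bp", "pos_cM", "allele_A", "allele_B"])
    if not chromosomes:
        chromosomes = [
            (c, int(markers.loc[markers["chrom"] == c, "pos_bp"].max()))
            for c in markers["chrom"].unique()
        ]
    return MarkerMap(chromosomes=tuple(chromosomes), markers=markers, cm_per_mb=cm_per_mb)


# ---------------------------------------------------------------------------
# Read counts: CSV and minimal VCF
# ---------------------------------------------------------------------------

def write_read_counts_csv(path: str | Path, counts: pd.DataFrame) -> None:
    out = counts.loc[:, ["chrom", "pos_bp", "ref_reads", "alt_reads", "base_quality"]].copy()
    out["base_quality"] = out["base_quality"].map(fmt_float)
    out.to_csv(path, index=False)


def read_read_counts_csv(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path)
    required = {"chrom", "pos_bp", "ref_reads", "alt_reads", "base_quality"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return counts


def write_vcf_minimal(path: str | Path, counts: pd.DataFrame, sample: str = "bulk") -> None:
    """Write read counts as a minimal single-sample VCF 4.2 with AD."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        chroms = list(dict.fromkeys(counts["chrom"]))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n")
        for row in counts.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos_bp}\t.\tA\tT\t{fmt_float(row.base_quality)}\t.\t.\t"
                f"GT:AD\t./.:{row.ref_reads},{row.alt_reads}\n"
            )


def read_vcf_minimal(path: str | Path) -> pd.DataFrame:
    """Read a single-sample VCF with AD depths into a read-count table.

    Only biallelic records are kept; multiallelic records are skipped with a
    logged count.  Site QUAL maps to ``base_quality``; a record without AD
    raises.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if len(vcf.samples) != 1:
        raise ValueError(f"{path}: expected exactly one sample, found {len(vcf.samples)}")
    rows, n_multi = [], 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        ad = variant.format("AD")
        if ad is None:
            raise ValueError(f"{path}: record {variant.CHROM}:{variant.POS} has no AD field")
        ref_d, alt_d = int(ad[0][0]), int(ad[0][1])
        rows.append((variant.CHROM, variant.POS, ref_d, alt_d, float(variant.QUAL or 0.0)))
    vcf.close()
    if n_multi:
        logger.info("read_vcf_minimal: skipped %d multiallelic records", n_multi)
    return pd.DataFrame(rows, columns=["chrom", "pos_bp", "ref_reads", "alt_reads", "base_quality"])


# ---------------------------------------------------------------------------
# Interval writers
# ---------------------------------------------------------------------------

def write_intervals_bed(path: str | Path, intervals: pd.DataFrame, name_prefix: str = "region") -> None:
    """Write candidate intervals / introgression segments as BED (0-based
    half-open)."""
    with open(path, "w") as fh:
        for k, row in enumerate(intervals.itertuples(index=False), start=1):
            start0, end0 = to_bed_coords(int(row.start_bp), int(row.end_bp))
            fh.write(f"{row.chrom}\t{start0}\t{end0}\t{name_prefix}{k}\n")


def write_intervals_tsv(path: str | Path, intervals: pd.DataFrame) -> None:
    out = intervals.copy()
    for col in out.columns:
        if out[col].dtype == float:
            out[col] = out[col].map(fmt_float)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def set_overlap(set_a_ids, set_b_ids) -> dict:
    """Exact overlap of two id collections (e.g. DEG lists).

    Returns counts and percentages of each set that are shared, both to one
    decimal and rounded to the nearest integer.
    """
    a, b = set(set_a_ids), set(set_b_ids)
    shared = a & b
    pct_a = 100.0 * len(shared) / len(a) if a else 0.0
    pct_b = 100.0 * len(shared) / len(b) if b else 0.0
    return {
        "n_A": len(a),
        "n_B": len(b),
        "n_shared": len(shared),
        "pct_of_A": round(pct_a, 1),
        "pct_of_B": round(pct_b, 1),
        "pct_of_A_int": int(round(pct_a)),
        "pct_of_B_int": int(round(pct_b)),
    }


def write_json_report(path: str | Path | None, payload: dict) -> None:
    text = json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n"
    if path is None:
        sys.stdout.write(text)
    else:
        Path(path).write_text(text)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
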
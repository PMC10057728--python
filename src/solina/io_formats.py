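"""Readers and writers for every external artifact.

Fixed dialects:

* genotypes — dosage CSV (rows = samples, columns = marker ids, values
  0/1/2/NA) or minimal VCF 4.2 (GT only, biallelic); cluster labels always
  come from a sidecar CSV, never inferred;
* marker map — CSV with columns ``marker_id,chrom,pos_bp`` (1-based bp);
* gene annotation — BED (0-based half-open on disk, converted to 1-based
  inclusive in memory);
* trait tables and scan results — plain CSV/TSV.

Genomic positions are stored in bp and reported in Mb with one decimal,
matching the convention of the region tables this package produces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

WHEAT_CHROMOSOMES = [f"{n}{g}" for n in range(1, 8) for g in "ABD"]
UNPLACED = "unplaced"

#: canonical sort order for chromosome names (1A..7D, then unplaced last)
_CHROM_ORDER = {c: i for i, c in enumerate(WHEAT_CHROMOSOMES + [UNPLACED])}

CLUSTER_LABELS = ("red", "blue")


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    return (_CHROM_ORDER.get(chrom, len(_CHROM_ORDER)), chrom)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Diploid dosages for samples x markers with cluster labels.

    ``dosages`` is a float array holding 0/1/2 with NaN for missing calls.
    ``accessions`` groups single-seed samples into their source accession,
    which is the permutation unit for the label-shuffling null.
    """

    sample_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray
    cluster_labels: pd.Series            # sample_id -> "red" / "blue"
    accessions: pd.Series | None = None  # sample_id -> accession id

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise ValueError("dosage matrix shape does not match id lists")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("marker ids must be unique")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(
                f"dosage out of range at sample {self.sample_ids[bad[0]]!r}, "
                f"marker {self.marker_ids[bad[1]]!r}: {self.dosages[tuple(bad)]}"
            )
        if self.accessions is None:
            self.accessions = pd.Series(self.sample_ids, index=self.sample_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def cluster_mask(self, label: str) -> np.ndarray:
        lab = self.cluster_labels.reindex(self.sample_ids)
        return (lab == label).to_numpy()


@dataclass
class MarkerMap:
    """Genomic coordinates per marker, sorted by chromosome then position."""

    table: pd.DataFrame  # columns marker_id, chrom, pos_bp

    def __post_init__(self) -> None:
        t = self.table
        required = {"marker_id", "chrom", "pos_bp"}
        if not required.issubset(t.columns):
            raise ValueError(f"marker map needs columns {sorted(required)}")
        if (t["pos_bp"] < 0).any():
            raise ValueError("positions must be non-negative")
        key = t["chrom"].map(lambda c: _CHROM_ORDER.get(c, len(_CHROM_ORDER)))
        self.table = (
            t.assign(_k=key)
            .sort_values(["_k", "chrom", "pos_bp", "marker_id"], kind="mergesort")
            .drop(columns="_k")
            .reset_index(drop=True)
        )

    def mapped(self) -> pd.DataFrame:
        """Rows on named chromosomes (unplaced markers are excluded from
        region calls)."""
        return self.table[self.table["chrom"] != UNPLACED]


@dataclass(frozen=True)
class Gene:
    """Candidate-gene interval, 1-based inclusive coordinates in memory."""

    name: str
    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"gene {self.name}: start after end")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_labels(path: str | Path) -> pd.DataFrame:
    """Sidecar CSV with columns sample_id, cluster[, accession]."""
    lab = pd.read_csv(path, dtype=str)
    if not {"sample_id", "cluster"}.issubset(lab.columns):
        raise ValueError("labels file needs columns sample_id, cluster")
    bad = set(lab["cluster"].dropna()) - set(CLUSTER_LABELS)
    if bad:
        raise ValueError(f"unknown cluster labels: {sorted(bad)}")
    if "accession" not in lab.columns:
        lab["accession"] = lab["sample_id"]
    return lab


def _attach_labels(sample_ids, dosages, marker_ids, labels_path) -> GenotypeMatrix:
    lab = read_labels(labels_path)
    unknown = set(lab["sample_id"]) - set(sample_ids)
    if unknown:
        raise ValueError(f"labels reference unknown samples: {sorted(unknown)[:5]}")
    missing = set(sample_ids) - set(lab["sample_id"])
    if missing:
        warnings.warn(f"{len(missing)} samples have no cluster label", stacklevel=3)
    lab = lab.set_index("sample_id")
    return GenotypeMatrix(
        sample_ids=list(sample_ids),
        marker_ids=list(marker_ids),
        dosages=dosages,
        cluster_labels=lab["cluster"].reindex(sample_ids),
        accessions=lab["accession"].reindex(sample_ids).fillna(
            pd.Series(sample_ids, index=sample_ids)
        ),
    )


def read_genotypes(
    path: str | Path, format: str = "dosage_csv", labels_path: str | Path | None = None
) -> GenotypeMatrix:
    """Load a genotype matrix from dosage CSV or VCF, with sidecar labels."""
    if labels_path is None:
        raise ValueError("labels_path is required: cluster labels are never inferred")
    if format == "dosage_csv":
        df = pd.read_csv(path, index_col=0)
        dos = df.to_numpy(dtype=float)
        return _attach_labels(df.index.astype(str), dos, df.columns.astype(str), labels_path)
    if format == "vcf":
        sample_ids, marker_ids, dosages = _read_vcf_dosages(path)
        return _attach_labels(sample_ids, dosages, marker_ids, labels_path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf_dosages(path: str | Path):
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    marker_ids, rows = [], []
    for var in vcf:
        if len(var.ALT) > 1:
            raise ValueError(f"multi-allelic site not supported: {var.ID or var.POS}")
        marker_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        gt = np.asarray(var.gt_types, dtype=float)  # 0/1/2, 3 = unknown with gts012
        gt[gt == 3] = np.nan
        rows.append(gt)
    dosages = np.asarray(rows, dtype=float).T if rows else np.empty((len(sample_ids), 0))
    return sample_ids, marker_ids, dosages


def write_genotypes_csv(geno: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(geno.dosages, index=geno.sample_ids, columns=geno.marker_ids)
    df.index.name = "sample_id"
    # keep integers readable: 0/1/2 with empty cells for missing
    df.map(lambda v: "" if np.isnan(v) else str(int(v))).to_csv(path)


def write_labels_csv(geno: GenotypeMatrix, path: str | Path) -> None:
    pd.DataFrame({
        "sample_id": geno.sample_ids,
        "cluster": geno.cluster_labels.reindex(geno.sample_ids).to_numpy(),
        "accession": geno.accessions.reindex(geno.sample_ids).to_numpy(),
    }).to_csv(path, index=False)


def write_genotypes_vcf(
    geno: GenotypeMatrix, marker_map: MarkerMap, path: str | Path,
    assembly: str = "unspecified",
) -> None:
    """Minimal VCF 4.2 with a GT-only FORMAT; REF/ALT are placeholder A/T.

    Dosage 0 -> 0/0, 1 -> 0/1, 2 -> 1/1, missing -> ./.
    Records follow marker-map order; unmapped markers are placed on
    'unplaced' at consecutive positions.
    """
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    pos = marker_map.table.set_index("marker_id")
    col = {m: i for i, m in enumerate(geno.marker_ids)}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={assembly}\n")
        seen_chroms = dict.fromkeys(
            marker_map.table.loc[marker_map.table["marker_id"].isin(col), "chrom"]
        )
        for chrom in seen_chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.sample_ids) + "\n")
        unplaced_at = 1
        for m in marker_map.table["marker_id"]:
            if m not in col:
                continue
            chrom, p = pos.loc[m, "chrom"], int(pos.loc[m, "pos_bp"])
            if chrom == UNPLACED:
                p, unplaced_at = unplaced_at, unplaced_at + 1
            calls = [
                gt_code.get(v, "./.") if not np.isnan(v) else "./."
                for v in geno.dosages[:, col[m]]
            ]
            fh.write(f"{chrom}\t{p}\t{m}\tA\tT\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n")


# ---------------------------------------------------------------------------
# marker map / annotation / traits
# ---------------------------------------------------------------------------

def read_marker_map(path: str | Path) -> MarkerMap:
    df = pd.read_csv(path, dtype={"marker_id": str, "chrom": str})
    if not pd.api.types.is_numeric_dtype(df.get("pos_bp", pd.Series(dtype=float))):
        raise ValueError("pos_bp column must be numeric")
    df["pos_bp"] = df["pos_bp"].astype(np.int64)
    return MarkerMap(df)


def write_marker_map(marker_map: MarkerMap, path: str | Path) -> None:
    marker_map.table.to_csv(path, index=False)


def read_annotation(path: str | Path) -> list[Gene]:
    """Read a 4-column BED (chrom, start, end, name); 0-based half-open on
    disk becomes 1-based inclusive in memory."""
    genes: list[Gene] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: BED line needs 4 columns")
            chrom, start, end, name = parts[0], parts[1], parts[2], parts[3]
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-numeric coordinates") from exc
            genes.append(Gene(name=name, chrom=chrom.removeprefix("chr"),
                              start_bp=s + 1, end_bp=e))
    return genes


def write_annotation_bed(genes: list[Gene], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start_bp - 1}\t{g.end_bp}\t{g.name}\n")


def read_traits(path: str | Path) -> pd.DataFrame:
    """Trait table CSV: sample_id, optional cluster, numeric trait columns."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError("trait table needs a sample_id column")
    if "cluster" in df.columns:
        bad = set(df["cluster"].dropna()) - set(CLUSTER_LABELS)
        if bad:
            raise ValueError(f"unknown cluster labels in traits: {sorted(bad)}")
    for col in df.columns:
        if col in ("sample_id", "cluster", "accession", "experiment", "context"):
            continue
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"trait column {col!r} is not numeric")
    return df


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    traits.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# scan results
# ---------------------------------------------------------------------------

SCAN_COLUMNS = ["marker", "chrom", "pos_Mb", "Ho", "Hs", "Ht", "Fst", "excluded", "outlier_flag"]


def write_scan_result(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-marker scan table as TSV with fixed columns.

    Numeric values keep 6 significant digits; positions are bp/1e6.
    """
    out = table.copy()
    missing = [c for c in SCAN_COLUMNS if c not in out.columns]
    if missing:
        raise ValueError(f"scan table missing columns: {missing}")
    out[SCAN_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_scan_result(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str, "excluded": str})
    df["excluded"] = df["excluded"].fillna("")
    df["outlier_flag"] = df["outlier_flag"].astype(bool)
    return df
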
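"""Domain types and readers/writers for Infinium-450K-style array data.

The array interrogates single CpG sites with one of two bead chemistries
(Infinium I / II).  Every probe carries genomic context annotation: the gene(s)
it maps to, the gene region relative to the nearest transcript (TSS1500,
TSS200, 5'UTR, first exon, body, 3'UTR; no gene = intergenic) and its relation
to the nearest CpG island (island, north/south shore, north/south shelf, open
sea).  This module defines the in-memory containers used throughout the
package and the plain-text formats they are exchanged in: a manifest table,
probe x sample value matrices (TSV), a sample sheet, and BED export of result
sites.

Coordinates are 1-based in manifests and in memory (the manifest convention)
and converted to 0-based half-open intervals only at BED export.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: valid gene-region labels relative to the nearest transcript
REGION_LABELS = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR")

#: valid CpG-island context labels
ISLAND_LABELS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

#: label used for probes without a gene annotation
INTERGENIC = "Intergenic"

#: value-matrix kinds and their range constraints
MATRIX_KINDS = (
    "meth_intensity",
    "unmeth_intensity",
    "beta",
    "m_value",
    "detection_p",
    "expression",
)

# aliases accepted on input, mapped to canonical labels
_REGION_ALIASES = {
    "TSS1500": "TSS1500",
    "TSS200": "TSS200",
    "5UTR": "5UTR",
    "5'UTR": "5UTR",
    "5′UTR": "5UTR",
    "1stExon": "1stExon",
    "1st Exon": "1stExon",
    "Body": "Body",
    "3UTR": "3UTR",
    "3'UTR": "3UTR",
    "3′UTR": "3UTR",
}

_ISLAND_ALIASES = {
    "Island": "Island",
    "CpG Island": "Island",
    "N_Shore": "N_Shore",
    "N Shore": "N_Shore",
    "S_Shore": "S_Shore",
    "S Shore": "S_Shore",
    "N_Shelf": "N_Shelf",
    "N Shelf": "N_Shelf",
    "S_Shelf": "S_Shelf",
    "S Shelf": "S_Shelf",
    "OpenSea": "OpenSea",
    "Open sea": "OpenSea",
    "Open Sea": "OpenSea",
}

MANIFEST_COLUMNS = [
    "probe_id",
    "chromosome",
    "position",
    "assay_type",
    "genes",
    "gene_regions",
    "island_relation",
    "cross_reactive_bases",
    "snp_maf",
]


@dataclass(frozen=True)
class ProbeAnnotation:
    """One array probe's genomic and context metadata."""

    probe_id: str
    chromosome: str
    position: int
    assay_type: str
    genes: tuple[str, ...] = ()
    gene_regions: tuple[str, ...] = ()
    island_relation: str = "OpenSea"
    cross_reactive_bases: int = 0
    snp_maf: float = 0.0

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"probe {self.probe_id}: position must be >= 1")
        if self.assay_type not in ("I", "II"):
            raise ValueError(
                f"probe {self.probe_id}: assay_type must be I or II, got {self.assay_type!r}"
            )
        if len(self.genes) != len(self.gene_regions):
            raise ValueError(
                f"probe {self.probe_id}: genes and gene_regions must align "
                f"({len(self.genes)} vs {len(self.gene_regions)})"
            )
        for region in self.gene_regions:
            if region not in REGION_LABELS:
                raise ValueError(
                    f"probe {self.probe_id}: unknown gene region label {region!r}"
                )
        if self.island_relation not in ISLAND_LABELS:
            raise ValueError(
                f"probe {self.probe_id}: unknown island relation {self.island_relation!r}"
            )
        if self.cross_reactive_bases < 0:
            raise ValueError(f"probe {self.probe_id}: cross_reactive_bases < 0")
        if not 0.0 <= self.snp_maf <= 1.0:
            raise ValueError(f"probe {self.probe_id}: snp_maf outside [0, 1]")

    @property
    def is_intergenic(self) -> bool:
        return len(self.genes) == 0


@dataclass
class ValueMatrix:
    """Probe x sample numeric matrix with aligned identifiers.

    ``kind`` declares the value semantics and the range constraint enforced at
    construction: betas and detection p-values lie in [0, 1], intensities are
    non-negative, M-values and expression values must be finite.  Missing
    values are never permitted.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.probe_ids = list(self.probe_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in MATRIX_KINDS:
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n_p, n_s = self.values.shape
        if n_p != len(self.probe_ids) or n_s != len(self.sample_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        self._validate_range()

    def _validate_range(self) -> None:
        bad = ~np.isfinite(self.values)
        message = "non-finite value"
        if not bad.any():
            if self.kind in ("beta", "detection_p"):
                bad = (self.values < 0.0) | (self.values > 1.0)
                message = f"{self.kind} value outside [0, 1]"
            elif self.kind in ("meth_intensity", "unmeth_intensity"):
                bad = self.values < 0.0
                message = "negative intensity"
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"{message} ({self.values[i, j]!r}) at probe "
                f"{self.probe_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.probe_ids, name="probe_id"),
            columns=self.sample_ids,
        )

    def select_probes(self, keep: Sequence[bool] | np.ndarray) -> "ValueMatrix":
        keep = np.asarray(keep, dtype=bool)
        ids = [p for p, k in zip(self.probe_ids, keep) if k]
        return ValueMatrix(ids, self.sample_ids, self.values[keep], self.kind)

    def select_samples(self, sample_ids: Sequence[str]) -> "ValueMatrix":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in sample_ids]
        return ValueMatrix(self.probe_ids, list(sample_ids), self.values[:, cols], self.kind)

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "ValueMatrix":
        return ValueMatrix(self.probe_ids, self.sample_ids, values, kind or self.kind)


def _split_multi(cell: str) -> list[str]:
    cell = (cell or "").strip()
    if not cell:
        return []
    return [part.strip() for part in cell.split(";") if part.strip()]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a probe manifest (TSV or CSV by extension) into a table.

    Multi-valued gene / gene-region cells are ';'-delimited and returned as
    aligned lists: a single gene annotated to several regions is repeated once
    per region (``NAV1`` + ``TSS200;Body`` gives ``genes=[NAV1, NAV1]``).
    A missing island relation maps to open sea; an empty gene cell yields an
    intergenic probe with no regions.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns: {missing}")

    seen: set[str] = set()
    records: list[ProbeAnnotation] = []
    for row in raw.itertuples(index=False):
        probe_id = row.probe_id.strip()
        if probe_id in seen:
            raise ValueError(f"duplicate probe_id {probe_id!r} in manifest {path}")
        seen.add(probe_id)
        genes = _split_multi(row.genes)
        regions_raw = _split_multi(row.gene_regions)
        regions = []
        for label in regions_raw:
            if label not in _REGION_ALIASES:
                raise ValueError(f"unknown gene region label {label!r} (probe {probe_id})")
            regions.append(_REGION_ALIASES[label])
        if not genes:
            regions = []  # intergenic probes carry no region annotation
        elif len(genes) == 1 and len(regions) > 1:
            genes = genes * len(regions)
        elif len(regions) == 1 and len(genes) > 1:
            regions = regions * len(genes)
        island_raw = (row.island_relation or "").strip()
        if island_raw and island_raw not in _ISLAND_ALIASES:
            raise ValueError(
                f"unknown island relation {island_raw!r} (probe {probe_id})"
            )
        island = _ISLAND_ALIASES.get(island_raw, "OpenSea")
        records.append(
            ProbeAnnotation(
                probe_id=probe_id,
                chromosome=row.chromosome.strip(),
                position=int(row.position),
                assay_type=row.assay_type.strip(),
                genes=tuple(genes),
                gene_regions=tuple(regions),
                island_relation=island,
                cross_reactive_bases=int(row.cross_reactive_bases or 0),
                snp_maf=float(row.snp_maf or 0.0),
            )
        )
    return annotation_frame(records)


def annotation_frame(records: Iterable[ProbeAnnotation]) -> pd.DataFrame:
    """Build the canonical annotation table (one row per probe)."""
    rows = [
        {
            "probe_id": r.probe_id,
            "chromosome": r.chromosome,
            "position": r.position,
            "assay_type": r.assay_type,
            "genes": list(r.genes),
            "gene_regions": list(r.gene_regions),
            "island_relation": r.island_relation,
            "cross_reactive_bases": r.cross_reactive_bases,
            "snp_maf": r.snp_maf,
        }
        for r in records
    ]
    frame = pd.DataFrame(
        rows, columns=MANIFEST_COLUMNS
    )
    return frame.reset_index(drop=True)


def write_manifest(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write an annotation table back to the ';'-joined TSV/CSV format."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    out = annotation.copy()
    out["genes"] = out["genes"].map(";".join)
    out["gene_regions"] = out["gene_regions"].map(";".join)
    out.to_csv(path, sep=sep, index=False)


def read_matrix(path: str | Path, kind: str) -> ValueMatrix:
    """Read a probe x sample TSV (first column probe ids, header sample ids)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    values = frame.to_numpy(dtype=float)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"missing value at probe {frame.index[i]!r}, sample "
            f"{frame.columns[j]!r} in {path} (NA tokens are not supported)"
        )
    return ValueMatrix(
        [str(p) for p in frame.index],
        [str(s) for s in frame.columns],
        values,
        kind,
    )


def write_matrix(matrix: ValueMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


SAMPLE_COLUMNS = ["sample_id", "subject_id", "timepoint", "batch", "age"]


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet: timepoints, uniqueness, positive ages."""
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    samples = samples.copy()
    samples["age"] = samples["age"].astype(float)
    bad_tp = set(samples["timepoint"]) - {"before", "after"}
    if bad_tp:
        raise ValueError(f"unknown timepoint labels: {sorted(bad_tp)}")
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r}")
    key = samples[["subject_id", "timepoint"]]
    if key.duplicated().any():
        dup = key.loc[key.duplicated()].iloc[0]
        raise ValueError(
            f"duplicate (subject_id, timepoint) pair {tuple(dup)!r}"
        )
    if (samples["age"] <= 0).any():
        raise ValueError("ages must be positive")
    return samples


def read_sample_table(path: str | Path) -> pd.DataFrame:
    return validate_sample_table(pd.read_csv(path, sep="\t", dtype={"batch": str}))


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    samples[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


def paired_subjects(samples: pd.DataFrame) -> list[str]:
    """Subjects with exactly one before and one after sample, in stable order."""
    counts = samples.pivot_table(
        index="subject_id", columns="timepoint", values="sample_id", aggfunc="count"
    ).fillna(0)
    ordered = samples["subject_id"].drop_duplicates().tolist()
    paired = {
        s
        for s in counts.index
        if counts.loc[s].get("before", 0) == 1 and counts.loc[s].get("after", 0) == 1
    }
    return [s for s in ordered if s in paired]


def timepoint_samples(samples: pd.DataFrame, subjects: Sequence[str], timepoint: str) -> list[str]:
    """Sample ids for the given subjects at one timepoint, in subject order."""
    lookup = {
        (r.subject_id, r.timepoint): r.sample_id for r in samples.itertuples(index=False)
    }
    return [lookup[(s, timepoint)] for s in subjects]


def bed_score(difference: float) -> int:
    """BED score for a methylation difference: |delta| x 1000, capped at 1000."""
    return int(min(1000, round(abs(difference) * 1000)))


def write_bed(results: pd.DataFrame, annotation: pd.DataFrame, path: str | Path) -> None:
    """Export result sites as single-base BED intervals (0-based half-open).

    ``results`` needs columns probe_id and difference; positions come from the
    annotation.  A result probe missing from the annotation is a hard error.
    """
    ann = annotation.set_index("probe_id")
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        for row in results.itertuples(index=False):
            if row.probe_id not in ann.index:
                raise ValueError(f"probe {row.probe_id!r} missing from annotation")
            probe = ann.loc[row.probe_id]
            position = int(probe["position"])
            writer.writerow(
                [
                    probe["chromosome"],
                    position - 1,
                    position,
                    row.probe_id,
                    bed_score(row.difference),
                    ".",
                ]
            )
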
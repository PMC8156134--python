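"""Readers and writers for the tabular formats used throughout the package.

Everything on disk is plain TSV (tab-delimited, UTF-8, header row) so that
inputs and results diff cleanly and round-trip deterministically:

* gene-family map — one row per ribosomal-protein (RP) gene with its family,
  subunit class (RPS/RPL/RPLP), pseudogene flag and cDNA length;
* count matrix — genes x sequencing libraries, raw integer counts, with an
  optional one-column sidecar holding the total mapped reads per library
  (the RPKM denominator);
* sample metadata — library -> sample group (tissue/stage code), replicate
  number and developmental series;
* result tables — written with a fixed float format so identical runs
  produce byte-identical files.

Dendrograms are additionally exported as Newick strings (see
:mod:`rpfam.clustering`), and gene lengths can be harvested from a GFF3
annotation when the family map omits them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError

SUBUNITS = ("RPS", "RPL", "RPLP")

#: Developmental series recognised in sample metadata.  The four named
#: series are the growth/development stage panels used for trend analysis;
#: everything else is "other".
SERIES_LABELS = ("seedling_parts", "germination", "meristem", "flower", "other")

_GENE_MAP_COLUMNS = ["gene_id", "family_id", "subunit", "is_pseudogene", "cdna_length_bp"]
_METADATA_COLUMNS = ["library_id", "sample_code", "replicate", "series"]

FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# gene-family map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRecord:
    """One RP gene: locus id, family, subunit class, pseudogene flag, cDNA length."""

    gene_id: str
    family_id: str
    subunit: str
    is_pseudogene: bool
    cdna_length_bp: int

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ParseError("gene_id must be non-empty")
        if not self.family_id:
            raise ParseError(f"gene {self.gene_id}: family_id must be non-empty")
        if self.cdna_length_bp <= 0:
            raise ParseError(
                f"gene {self.gene_id}: cdna_length_bp must be positive, "
                f"got {self.cdna_length_bp}"
            )


class GeneFamilyMap:
    """Ordered collection of :class:`GeneRecord` with a family -> members index.

    Pseudogenes are retained in the map but flagged, so callers can exclude
    them from quantitative analysis while keeping the catalogue complete.
    """

    def __init__(self, records: Iterable[GeneRecord]):
        records = tuple(records)
        if not records:
            raise ParseError("gene-family map is empty")
        seen: dict[str, int] = {}
        by_family: dict[str, list[str]] = {}
        for i, rec in enumerate(records):
            if rec.gene_id in seen:
                raise ParseError(
                    f"duplicate gene_id {rec.gene_id!r} (rows {seen[rec.gene_id] + 1} "
                    f"and {i + 1})"
                )
            seen[rec.gene_id] = i
            by_family.setdefault(rec.family_id, []).append(rec.gene_id)
        self._records = records
        self._by_id = {rec.gene_id: rec for rec in records}
        self._by_family = {fam: tuple(genes) for fam, genes in by_family.items()}

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self._records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def record(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(self._by_family)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(rec.gene_id for rec in self._records)

    @property
    def non_pseudogene_ids(self) -> tuple[str, ...]:
        return tuple(r.gene_id for r in self._records if not r.is_pseudogene)

    def members(self, family_id: str, include_pseudogenes: bool = False) -> tuple[str, ...]:
        genes = self._by_family[family_id]
        if include_pseudogenes:
            return genes
        return tuple(g for g in genes if not self._by_id[g].is_pseudogene)

    def family_of(self, gene_id: str) -> str:
        return self._by_id[gene_id].family_id

    def lengths(self, include_pseudogenes: bool = True) -> dict[str, int]:
        return {
            r.gene_id: r.cdna_length_bp
            for r in self._records
            if include_pseudogenes or not r.is_pseudogene
        }

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneFamilyMap":
        df = _read_tsv(path, _GENE_MAP_COLUMNS)
        records = []
        for i, row in enumerate(df.itertuples(index=False)):
            line = i + 2  # header is line 1
            try:
                records.append(
                    GeneRecord(
                        gene_id=str(row.gene_id),
                        family_id=str(row.family_id),
                        subunit=str(row.subunit),
                        is_pseudogene=_parse_bool(row.is_pseudogene, line),
                        cdna_length_bp=_parse_int(row.cdna_length_bp, "cdna_length_bp", line),
                    )
                )
            except ParseError as exc:
                raise ParseError(f"{path}, line {line}: {exc}") from None
        return cls(records)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [
                (r.gene_id, r.family_id, r.subunit, r.is_pseudogene, r.cdna_length_bp)
                for r in self._records
            ],
            columns=_GENE_MAP_COLUMNS,
        )
        df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

class SampleMetadata:
    """Library-level annotation: sample group, replicate and series.

    ``(sample_code, replicate)`` pairs are unique; a *sample group* is the set
    of replicate libraries sharing one tissue/stage code.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _METADATA_COLUMNS if c not in frame.columns]
        if missing:
            raise ParseError(f"sample metadata missing columns: {missing}")
        frame = frame[_METADATA_COLUMNS].copy()
        frame["replicate"] = frame["replicate"].astype(int)
        if frame["library_id"].duplicated().any():
            dup = frame.loc[frame["library_id"].duplicated(), "library_id"].iloc[0]
            raise ParseError(f"duplicate library_id {dup!r}")
        if frame.duplicated(subset=["sample_code", "replicate"]).any():
            bad = frame[frame.duplicated(subset=["sample_code", "replicate"])].iloc[0]
            raise ParseError(
                f"duplicate (sample_code, replicate) pair "
                f"({bad.sample_code!r}, {bad.replicate})"
            )
        if (frame["replicate"] < 1).any():
            raise ParseError("replicate numbers must be >= 1")
        bad_series = set(frame["series"]) - set(SERIES_LABELS)
        if bad_series:
            raise ParseError(f"unknown series labels: {sorted(bad_series)}")
        self.frame = frame.reset_index(drop=True)

    @property
    def library_ids(self) -> tuple[str, ...]:
        return tuple(self.frame["library_id"])

    @property
    def sample_codes(self) -> tuple[str, ...]:
        """Sample-group codes in first-appearance order."""
        return tuple(dict.fromkeys(self.frame["sample_code"]))

    def groups(self) -> dict[str, list[str]]:
        """Map sample_code -> ordered list of member library_ids."""
        out: dict[str, list[str]] = {}
        for row in self.frame.itertuples(index=False):
            out.setdefault(row.sample_code, []).append(row.library_id)
        return out

    def series_groups(self, include_other: bool = False) -> dict[str, list[str]]:
        """Map series label -> ordered list of sample codes in that series."""
        out: dict[str, list[str]] = {}
        for code in self.sample_codes:
            series = self.frame.loc[self.frame["sample_code"] == code, "series"].iloc[0]
            if series == "other" and not include_other:
                continue
            out.setdefault(series, []).append(code)
        return out

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleMetadata":
        return cls(_read_tsv(path, _METADATA_COLUMNS))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Raw gene x library integer counts plus per-library total mapped reads.

    ``library_totals`` is the RPKM denominator.  It defaults to the column
    sums of the matrix (appropriate when the matrix covers the whole counted
    transcriptome) and is overridden by a totals sidecar when the matrix is
    restricted to a gene subset.
    """

    values: pd.DataFrame
    library_totals: pd.Series

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ParseError("count matrix contains negative values")
        if not list(self.library_totals.index) == list(self.values.columns):
            raise ParseError("library_totals index must match matrix columns")
        colsums = self.values.sum(axis=0)
        if (self.library_totals + 1e-9 < colsums).any():
            bad = self.library_totals.index[(self.library_totals + 1e-9 < colsums)][0]
            raise ParseError(
                f"library {bad!r}: total mapped reads below the matrix column sum"
            )

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def library_ids(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    def to_tsv(self, path: str | Path, totals_path: str | Path | None = None) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")
        if totals_path is not None:
            # full precision: totals are exact denominators, not results
            totals = self.library_totals.rename("total_mapped_reads")
            totals.index.name = "library_id"
            totals.to_csv(totals_path, sep="\t")


def read_count_matrix(
    path: str | Path,
    metadata: SampleMetadata,
    totals_path: str | Path | None = None,
) -> CountMatrix:
    """Read a gene x library TSV of raw counts and validate it against metadata.

    Columns must match the metadata's libraries exactly (no silent
    subsetting).  Values must be non-negative integers.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    extra = [c for c in df.columns if c not in set(metadata.library_ids)]
    if extra:
        raise ParseError(f"{path}: libraries absent from metadata: {extra}")
    missing = [l for l in metadata.library_ids if l not in set(df.columns)]
    if missing:
        raise ParseError(f"{path}: metadata libraries missing from matrix: {missing}")
    df = df[list(metadata.library_ids)]
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ParseError(f"{path}: non-numeric values in count matrix")
    if (arr < 0).any():
        raise ParseError(f"{path}: negative counts")
    if not np.allclose(arr, np.round(arr)):
        raise ParseError(f"{path}: non-integer counts")
    df = df.astype(np.int64)

    if totals_path is not None:
        totals_df = pd.read_csv(totals_path, sep="\t", index_col=0)
        totals = totals_df.iloc[:, 0].astype(float)
        missing_t = [l for l in df.columns if l not in totals.index]
        if missing_t:
            raise ParseError(f"{totals_path}: no totals for libraries {missing_t}")
        totals = totals.reindex(df.columns)
    else:
        totals = df.sum(axis=0).astype(float)
    return CountMatrix(values=df, library_totals=totals)


# ---------------------------------------------------------------------------
# GFF3 gene lengths
# ---------------------------------------------------------------------------

def gene_lengths_from_gff3(path: str | Path, id_attribute: str = "ID") -> dict[str, int]:
    """Exonic (cDNA) length per gene from a GFF3 annotation.

    For each gene the length is the sum of exon spans (1-based inclusive,
    ``end - start + 1``) of its longest annotated mRNA.  Genes with no
    annotated exons are skipped with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    lengths: dict[str, int] = {}
    for gene in db.features_of_type("gene"):
        name = gene.attributes.get(id_attribute, [gene.id])[0]
        best = 0
        for mrna in db.children(gene, featuretype=("mRNA", "transcript")):
            exonic = sum(e.end - e.start + 1 for e in db.children(mrna, featuretype="exon"))
            best = max(best, exonic)
        if best == 0:
            warnings.warn(f"gene {name!r}: no annotated exons, skipped", stacklevel=2)
            continue
        lengths[name] = best
    return lengths


# ---------------------------------------------------------------------------
# result writing
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    """Deterministic TSV writer: fixed column order and float format."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
    return path


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each named table as ``<name>.tsv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return [write_tsv(df, out_dir / f"{name}.tsv") for name, df in tables.items()]


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("rpfam").joinpath("data", name)))


def load_rp_gene_map() -> GeneFamilyMap:
    """Packaged synthetic stand-in for the Arabidopsis cytoplasmic RP catalogue.

    Mirrors the published catalogue's structure — 256 genes of which 240 are
    non-pseudogenes, 81 families of 2-7 paralogues each (RPS15 with six
    members A-F) — with synthetic AGI-style locus ids and cDNA lengths.
    """
    return GeneFamilyMap.from_tsv(_data_path("rp_gene_families.synthetic.tsv"))


def load_sample_metadata() -> SampleMetadata:
    """Packaged synthetic stand-in for the 79-sample developmental panel.

    79 tissue/stage codes x 2 biological replicates, with the four named
    developmental series (seedling parts, seed germination SD.g1-SD.g3,
    meristem M1-M10, flower F1-F19) flagged for trend analysis.
    """
    return SampleMetadata.from_tsv(_data_path("sample_metadata.synthetic.tsv"))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required_columns: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def _parse_bool(value: object, line: int) -> bool:
    text = str(value).strip().lower()
    if text in {"true", "1"}:
        return True
    if text in {"false", "0"}:
        return False
    raise ParseError(f"is_pseudogene must be boolean, got {value!r}")


def _parse_int(value: object, field: str, line: int) -> int:
    try:
        return int(str(value).strip())
    except ValueError:
        raise ParseError(f"{field} must be an integer, got {value!r}") from None
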
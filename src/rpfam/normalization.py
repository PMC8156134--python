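"""RPKM normalization, replicate averaging and expression summaries.

RPKM (Reads Per Kilobase of transcript per Million mapped reads) for gene
*g* in library *l* is

    RPKM[g, l] = 1e6 * count[g, l] / total[l] * 1e3 / length[g]

with ``total[l]`` the library's total mapped reads and ``length[g]`` the
cDNA (exonic) length in bp.  Replicates of a sample group are averaged on
the RPKM scale, i.e. RPKM is computed per library first and the group value
is the arithmetic mean of its replicate columns.  Note the two operations
commute only when the replicate libraries have identical totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import CountMatrix, SampleMetadata


@dataclass
class ExpressionMatrix:
    """Genes x columns matrix of RPKM values.

    ``kind`` records whether columns are individual libraries
    (``per_library``) or replicate-averaged sample groups (``per_group``);
    ``provenance`` maps each group column to the libraries averaged into it.
    """

    values: pd.DataFrame
    kind: str = "per_library"
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("per_library", "per_group"):
            raise ConfigurationError(f"kind must be per_library/per_group, got {self.kind!r}")
        if (self.values.values < 0).any():
            raise ValueError("RPKM values must be non-negative")


def compute_rpkm(counts: CountMatrix, lengths: Mapping[str, int]) -> ExpressionMatrix:
    """Per-library RPKM from raw counts, library totals and cDNA lengths."""
    missing = [g for g in counts.gene_ids if g not in lengths]
    if missing:
        raise ConfigurationError(f"no cDNA length for genes: {missing[:10]}"
                                 + (" ..." if len(missing) > 10 else ""))
    if (counts.library_totals <= 0).any():
        bad = counts.library_totals.index[counts.library_totals <= 0][0]
        raise ConfigurationError(f"library {bad!r}: total mapped reads must be > 0")
    length_bp = pd.Series({g: float(lengths[g]) for g in counts.gene_ids})
    rpkm = (
        counts.values.astype(float)
        .div(counts.library_totals, axis=1)
        .mul(1e6)
        .div(length_bp / 1e3, axis=0)
    )
    return ExpressionMatrix(values=rpkm, kind="per_library")


def average_replicates(expr: ExpressionMatrix, metadata: SampleMetadata) -> ExpressionMatrix:
    """Collapse replicate libraries to sample groups by arithmetic mean."""
    if expr.kind != "per_library":
        raise ConfigurationError("average_replicates expects a per_library matrix")
    groups = metadata.groups()
    unmapped = [c for c in expr.values.columns if c not in set(metadata.library_ids)]
    if unmapped:
        raise ConfigurationError(f"libraries without metadata: {unmapped}")
    cols = {}
    provenance = {}
    for code, libs in groups.items():
        libs = [l for l in libs if l in expr.values.columns]
        if not libs:
            raise ConfigurationError(f"sample group {code!r} has no libraries in the matrix")
        cols[code] = expr.values[libs].mean(axis=1)
        provenance[code] = libs
    return ExpressionMatrix(values=pd.DataFrame(cols), kind="per_group", provenance=provenance)


def log_transform(values: ExpressionMatrix | pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Element-wise log2(RPKM + pseudocount).

    With ``pseudocount == 0`` every value must be strictly positive.
    """
    df = values.values if isinstance(values, ExpressionMatrix) else values
    if pseudocount < 0:
        raise ConfigurationError(f"pseudocount must be >= 0, got {pseudocount}")
    if pseudocount == 0 and (df.values <= 0).any():
        raise ConfigurationError("zero values present; use a positive pseudocount")
    return np.log2(df + pseudocount)


def expression_summary(log_expr: pd.DataFrame, gene_set: Iterable[str]) -> pd.DataFrame:
    """Median and quartiles of log2 expression per column over a gene set.

    Quartiles use linear interpolation (numpy's default, R's type 7).
    Returns one row per column with ``median``, ``lower_quartile``,
    ``upper_quartile``.
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ConfigurationError("gene_set is empty")
    missing = [g for g in gene_set if g not in log_expr.index]
    if missing:
        raise ConfigurationError(f"genes not in matrix: {missing[:10]}")
    sub = log_expr.loc[gene_set]
    q = np.percentile(sub.to_numpy(), [25, 50, 75], axis=0)
    return pd.DataFrame(
        {"median": q[1], "lower_quartile": q[0], "upper_quartile": q[2]},
        index=pd.Index(log_expr.columns, name="sample"),
    )[["median", "lower_quartile", "upper_quartile"]]
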
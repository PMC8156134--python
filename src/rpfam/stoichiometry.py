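"""Family-level transcript stoichiometry.

Paralogue RPKM values are summed within each gene family, and each family's
summed value is divided by the per-sample median over all families, giving a
*relative level* that is ~1 when transcript supply matches the typical
family in that tissue.  Families are flagged ``low`` when the relative level
drops below 0.5 and ``high`` when it exceeds 2 (strict inequalities; the
boundary values are unflagged).  With replicate libraries, a per-family
relative level can be computed per library and tested against a threshold
with a one-sample two-sided t-test — deliberately low-powered at n = 2
replicates, which is the reason flags are based on thresholds rather than on
significance.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .io import GeneFamilyMap, SampleMetadata
from .normalization import ExpressionMatrix

LOW_THRESHOLD = 0.5
HIGH_THRESHOLD = 2.0
DEVIATING_COUNT_CUTOFF = 5


def sum_families(
    expr: ExpressionMatrix | pd.DataFrame, fam_map: GeneFamilyMap
) -> pd.DataFrame:
    """Sum member RPKM per family (pseudogenes excluded), families x columns.

    Every non-pseudogene gene of the map must be present in the matrix, and
    every gene in the matrix must belong to the map.
    """
    df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    unknown = [g for g in df.index if g not in fam_map]
    if unknown:
        raise ConfigurationError(f"genes absent from family map: {unknown[:10]}")
    missing = [g for g in fam_map.non_pseudogene_ids if g not in df.index]
    if missing:
        raise ConfigurationError(f"family-map genes missing from matrix: {missing[:10]}")
    rows = {}
    for fam in fam_map.families:
        members = [g for g in fam_map.members(fam) if g in df.index]
        if members:
            rows[fam] = df.loc[members].sum(axis=0)
    out = pd.DataFrame(rows).T
    out.index.name = "family_id"
    return out


def relative_levels(famexpr: pd.DataFrame) -> pd.DataFrame:
    """Family sums divided by the per-column median over families."""
    if famexpr.shape[0] < 2:
        raise ConfigurationError("need >= 2 families to compute relative levels")
    med = famexpr.median(axis=0)
    if (med <= 0).any():
        bad = med.index[med <= 0][0]
        raise ConfigurationError(f"sample {bad!r}: median family expression is not positive")
    return famexpr.div(med, axis=1)


def flag_deviations(
    relative: pd.DataFrame,
    low: float = LOW_THRESHOLD,
    high: float = HIGH_THRESHOLD,
) -> pd.DataFrame:
    """'low' where relative < low, 'high' where relative > high, else 'none'."""
    arr = relative.to_numpy()
    flags = np.full(arr.shape, "none", dtype=object)
    flags[arr < low] = "low"
    flags[arr > high] = "high"
    return pd.DataFrame(flags, index=relative.index, columns=relative.columns)


def count_deviating_families(
    flags: pd.DataFrame, cutoff: int = DEVIATING_COUNT_CUTOFF
) -> tuple[pd.Series, list[str]]:
    """Per-sample count of flagged families, and the samples with count > cutoff."""
    counts = (flags != "none").sum(axis=0)
    counts.name = "deviating_families"
    over = [str(c) for c in counts.index[counts > cutoff]]
    return counts, over


def replicate_relative_levels(fam_by_library: pd.DataFrame) -> pd.DataFrame:
    """Relative levels computed per library against that library's own median."""
    return relative_levels(fam_by_library)


def test_deviation_significance(
    rel_by_library: pd.DataFrame,
    metadata: SampleMetadata,
    family: str,
    sample_code: str,
    threshold: float,
) -> float:
    """Two-sided one-sample t-test of a family's replicate-wise relative levels.

    Tests the replicate values of ``(family, sample_code)`` against
    ``threshold`` and returns the p-value in (0, 1].  Degenerate
    zero-variance replicates give p = 1 when they sit exactly on the
    threshold and p -> 0 otherwise.
    """
    libs = metadata.groups()[sample_code]
    vals = rel_by_library.loc[family, libs].to_numpy(dtype=float)
    if len(vals) < 2:
        raise ConfigurationError(
            f"sample {sample_code!r} has {len(vals)} replicate(s); need >= 2 for a t-test"
        )
    return float(_t_pvalues(vals[None, :], threshold)[0])


def _t_pvalues(values: np.ndarray, threshold: float | np.ndarray) -> np.ndarray:
    """Vectorised two-sided one-sample t-test p-values (rows = tests)."""
    n = values.shape[1]
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    p = np.empty(values.shape[0])
    zero = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean - threshold) / (sd / np.sqrt(n))
    p[~zero] = 2.0 * stats.t.sf(np.abs(t[~zero]), df=n - 1)
    # sd == 0: all replicates identical — p = 1 on the threshold, else -> 0
    on = zero & np.isclose(mean, threshold)
    p[zero & ~on] = 0.0
    p[on] = 1.0
    return np.clip(p, 0.0, 1.0)


def stoichiometry_table(
    famexpr_group: pd.DataFrame,
    fam_by_library: pd.DataFrame,
    metadata: SampleMetadata,
    low: float = LOW_THRESHOLD,
    high: float = HIGH_THRESHOLD,
) -> pd.DataFrame:
    """Long-format stoichiometry results: one row per (family, sample group).

    Columns: ``relative_level``, ``flag``, ``threshold_tested``, ``p_value``
    and Benjamini-Hochberg ``p_adj``.  The t-test compares the replicate-wise
    relative levels against the deviation threshold the group mean crosses
    (``low`` for low flags, ``high`` for high flags, 1.0 for unflagged rows);
    adjusted p-values are reported for transparency but never drive flags.
    """
    rel = relative_levels(famexpr_group)
    flags = flag_deviations(rel, low=low, high=high)
    rel_lib = replicate_relative_levels(fam_by_library)
    groups = metadata.groups()

    records = []
    for fam in rel.index:
        for code in rel.columns:
            flag = flags.at[fam, code]
            threshold = {"low": low, "high": high}.get(flag, 1.0)
            libs = groups[code]
            vals = rel_lib.loc[fam, libs].to_numpy(dtype=float)[None, :]
            p = float(_t_pvalues(vals, threshold)[0]) if len(libs) >= 2 else np.nan
            records.append((fam, code, rel.at[fam, code], flag, threshold, p))
    out = pd.DataFrame(
        records,
        columns=["family_id", "sample_code", "relative_level", "flag",
                 "threshold_tested", "p_value"],
    )
    out["p_adj"] = _benjamini_hochberg(out["p_value"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values; NaNs propagate."""
    adj = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return adj
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0, 1)
    adj[ok] = out
    return adj
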
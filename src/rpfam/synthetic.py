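"""Synthetic RNA-seq count panels with known family-level ground truth.

The generator emulates the structure of a deep bulk RNA-seq survey of the
Arabidopsis ribosomal-protein (RP) gene complement: ~81 gene families of 2-7
paralogues profiled over ~79 tissue/stage sample groups with two biological
replicates each.  Counts are drawn from a negative-binomial model
(variance = mu + dispersion * mu^2) around expected counts obtained by
inverting the RPKM formula, so every downstream statistic has an analytic
expectation to recover.

Per-family expression is composed multiplicatively:

* a family scale factor (log-normal) around a common base level,
* a family trend drawn from six smooth archetypes (rising, falling,
  early/late peak and their mirrored valleys) evaluated *within* each
  developmental series, so every series exhibits the full trend dynamic;
  the archetypes are mean-centred mirrored pairs, which keeps the per-group
  median family at its nominal level and makes "baseline" families genuinely
  stoichiometric,
* a global per-tissue factor shared by all genes (sequencing-depth-like and
  tissue-activity variation, cancelled by stoichiometry ratios),
* fixed member proportions (Dirichlet) splitting the family sum.

Planted scenarios override this baseline per family:

``concerted``          members share the family trend at different scales;
``contrasting``        two members receive anti-correlated trends
                       (Pearson r = -1 on expectations);
``tissue_specific``    one member is expressed only in a small group subset;
``substoichiometric``  the family sum is pinned to ratio * (per-group median
``superfluous``        of the other families' sums), ratio < 1 resp. > 1.

Optional background (non-RP) genes are expressed at a fraction of the RP
base level, reproducing the high relative expression of RP genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import CountMatrix, GeneFamilyMap, GeneRecord, SampleMetadata

TREND_SHAPES = ("rising", "falling", "peaked", "flat")
SCENARIOS = (
    "baseline",
    "concerted",
    "contrasting",
    "tissue_specific",
    "substoichiometric",
    "superfluous",
)

#: family-sum RPKM base level before per-group renormalisation
_BASE_FAMILY_RPKM = 120.0
#: log-normal sigma of the per-family scale factor
_FAMILY_SCALE_SIGMA = 0.12
#: log-normal sigma of the shared per-tissue factor
_TISSUE_SIGMA = 0.05
#: Dirichlet concentration for member proportions (keeps members comparable)
_MEMBER_ALPHA = 5.0
#: expression level of background genes relative to the RP family base
_BACKGROUND_LEVEL = 0.08
#: maximum multiplicative deviation of a family trend from its mean level
_TREND_AMPLITUDE = 0.45

ARCHETYPE_NAMES = (
    "rising",
    "falling",
    "early_peak",
    "early_valley",
    "late_peak",
    "late_valley",
)

_DENSE_X = np.linspace(0.0, 1.0, 201)


def _raw_shape(name: str, x: np.ndarray) -> np.ndarray:
    bump = lambda c, w: np.exp(-(((x - c) / w) ** 2))  # noqa: E731
    if name == "rising":
        return x
    if name == "falling":
        return 1.0 - x
    if name == "early_peak":
        return bump(0.2, 0.18)
    if name == "early_valley":
        return 1.0 - bump(0.2, 0.18)
    if name == "late_peak":
        return bump(0.8, 0.18)
    if name == "late_valley":
        return 1.0 - bump(0.8, 0.18)
    raise ConfigurationError(f"unknown archetype {name!r}")


def _archetype_at(name: str, x: np.ndarray) -> np.ndarray:
    """Archetype trend evaluated at positions x in [0, 1].

    Shapes are centred to mean 1 (on a dense grid, so the normalisation is
    independent of how many points are sampled) and scaled so the extreme
    multiplicative deviation is ``_TREND_AMPLITUDE``.  The six archetypes
    form three mirrored pairs, so a panel with evenly assigned archetypes
    has a per-group median family level of exactly the base level.
    """
    dense = _raw_shape(name, _DENSE_X)
    center = dense.mean()
    halfrange = np.abs(dense - center).max()
    return 1.0 + _TREND_AMPLITUDE * (_raw_shape(name, x) - center) / halfrange


def plant_trend(shape: str, n_groups: int) -> np.ndarray:
    """Deterministic positive expectation profile of a named shape.

    ``flat`` is constant, ``rising``/``falling`` are strictly monotone and
    ``peaked`` is unimodal with an interior maximum (requires n >= 3).
    """
    if shape not in TREND_SHAPES:
        raise ConfigurationError(f"unknown trend shape {shape!r}; choose from {TREND_SHAPES}")
    if n_groups < 2:
        raise ConfigurationError(f"n_groups must be >= 2, got {n_groups}")
    x = np.linspace(0.0, 1.0, n_groups)
    if shape == "flat":
        return np.ones(n_groups)
    if shape == "rising":
        return 0.6 + x
    if shape == "falling":
        return 1.6 - x
    if n_groups < 3:
        raise ConfigurationError("a peaked trend needs n_groups >= 3")
    return 0.6 + np.exp(-(((x - 0.5) / 0.18) ** 2))


def archetype_trends(n_groups: int) -> dict[str, np.ndarray]:
    """The six family trend archetypes sampled on ``n_groups`` evenly
    spaced positions (multiplicative, mean ~1, extremes 1 +/- 0.45)."""
    if n_groups < 3:
        raise ConfigurationError(f"archetype trends need n_groups >= 3, got {n_groups}")
    x = np.linspace(0.0, 1.0, n_groups)
    return {name: _archetype_at(name, x) for name in ARCHETYPE_NAMES}


def _blockwise_trend(name: str, series_labels: list[str]) -> np.ndarray:
    """Archetype evaluated within each contiguous series block.

    Each developmental series spans the archetype's full dynamic, mirroring
    real series (germination, meristem stages, flower stages) that each
    traverse a complete expression excursion.
    """
    n = len(series_labels)
    out = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j < n and series_labels[j] == series_labels[i]:
            j += 1
        length = j - i
        x = np.linspace(0.0, 1.0, length) if length > 1 else np.array([0.5])
        out[i:j] = _archetype_at(name, x)
        i = j
    return out


@dataclass(frozen=True)
class PlantedFamily:
    """Scenario assignment for one family.

    ``ratio`` is required for substoichiometric/superfluous families (the
    target stoichiometry relative level); ``specific_groups`` optionally
    pins the expressed-group subset of a tissue_specific family.
    """

    scenario: str
    ratio: float | None = None
    specific_groups: tuple[int, ...] | None = None

    def validate(self, family: int) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(
                f"planted family {family}: unknown scenario {self.scenario!r}"
            )
        if self.scenario in ("substoichiometric", "superfluous"):
            if self.ratio is None or self.ratio <= 0:
                raise ConfigurationError(
                    f"planted family {family}: scenario {self.scenario!r} needs ratio > 0"
                )
            if self.scenario == "substoichiometric" and self.ratio >= 1:
                raise ConfigurationError(
                    f"planted family {family}: substoichiometric ratio must be < 1"
                )
            if self.scenario == "superfluous" and self.ratio <= 1:
                raise ConfigurationError(
                    f"planted family {family}: superfluous ratio must be > 1"
                )


@dataclass
class ScenarioSpec:
    """Simulation scenario: panel dimensions, noise model and planted truths."""

    n_families: int = 81
    paralogues_min: int = 2
    paralogues_max: int = 7
    n_groups: int = 79
    n_replicates: int = 2
    library_size: int = 5_000_000
    dispersion: float = 0.005
    seed: int = 0
    planted: dict[int, PlantedFamily] = field(default_factory=dict)
    n_background: int = 0

    def validate(self) -> None:
        for name in ("n_families", "n_groups", "n_replicates", "library_size"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive, got {getattr(self, name)}")
        if self.paralogues_min < 2:
            raise ConfigurationError(
                f"paralogues_min must be >= 2 (every family has >= 2 paralogues), "
                f"got {self.paralogues_min}"
            )
        if self.paralogues_max < self.paralogues_min:
            raise ConfigurationError(
                f"paralogues_max ({self.paralogues_max}) < paralogues_min "
                f"({self.paralogues_min})"
            )
        if self.dispersion < 0:
            raise ConfigurationError(f"dispersion must be >= 0, got {self.dispersion}")
        if self.n_groups < 3:
            raise ConfigurationError(f"n_groups must be >= 3, got {self.n_groups}")
        if self.n_background < 0:
            raise ConfigurationError(f"n_background must be >= 0, got {self.n_background}")
        for fam_idx, planted in self.planted.items():
            if not 0 <= fam_idx < self.n_families:
                raise ConfigurationError(f"planted family index {fam_idx} out of range")
            planted.validate(fam_idx)

    @classmethod
    def demo(cls, seed: int = 0) -> "ScenarioSpec":
        """Study-scale panel with one planted family of each scenario."""
        return cls(
            seed=seed,
            n_background=160,
            planted={
                0: PlantedFamily("substoichiometric", ratio=0.3),
                1: PlantedFamily("superfluous", ratio=2.5),
                2: PlantedFamily("contrasting"),
                3: PlantedFamily("concerted"),
                4: PlantedFamily("tissue_specific"),
            },
        )


@dataclass
class TruthTable:
    """Ground truth recorded at generation time.

    * ``family_truth`` — scenario label, target ratio and trend archetype per
      family;
    * ``gene_truth`` — family and trend-cluster label per RP gene;
    * ``expected_rpkm`` — exact post-normalisation expected RPKM, genes x
      sample groups (RP and background genes);
    * ``expected_ratio`` — expected stoichiometry relative level, families x
      sample groups.
    """

    family_truth: pd.DataFrame
    gene_truth: pd.DataFrame
    expected_rpkm: pd.DataFrame
    expected_ratio: pd.DataFrame
    gene_lengths: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))
    scenario_params: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        import json
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from .io import write_tsv

        write_tsv(self.family_truth, out_dir / "truth_families.tsv", index=False)
        write_tsv(self.gene_truth, out_dir / "truth_genes.tsv", index=False)
        write_tsv(self.expected_rpkm, out_dir / "truth_expected_rpkm.tsv")
        write_tsv(self.expected_ratio, out_dir / "truth_expected_ratio.tsv")
        lengths = self.gene_lengths.to_frame()
        lengths.index.name = "gene_id"
        write_tsv(lengths, out_dir / "truth_gene_lengths.tsv")
        (out_dir / "truth_scenarios.json").write_text(
            json.dumps(self.scenario_params, indent=2, sort_keys=True) + "\n"
        )


def _series_allocation(n_groups: int) -> list[str]:
    """Assign series labels mirroring the study panel's composition."""
    template = [("germination", 3), ("meristem", 10), ("flower", 19), ("seedling_parts", 3)]
    total_named = sum(n for _, n in template)
    labels: list[str] = []
    if n_groups >= total_named + 4:
        for name, count in template:
            labels += [name] * count
        labels += ["other"] * (n_groups - total_named)
    else:
        # small panels: split evenly over the four named series
        base = n_groups // 4
        counts = [base + (1 if i < n_groups % 4 else 0) for i in range(4)]
        for (name, _), count in zip(template, counts):
            labels += [name] * count
    return labels


def generate_dataset(
    spec: ScenarioSpec,
) -> tuple[CountMatrix, GeneFamilyMap, SampleMetadata, TruthTable]:
    """Draw a count panel with recoverable family-level truth.

    Same spec and seed reproduce the identical matrix bit-for-bit.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))

    # ---- samples ---------------------------------------------------------
    codes = [f"T{j + 1:02d}" for j in range(spec.n_groups)]
    series = _series_allocation(spec.n_groups)
    meta = SampleMetadata(
        pd.DataFrame(
            [
                (f"{code}.r{r}", code, r, s)
                for code, s in zip(codes, series)
                for r in range(1, spec.n_replicates + 1)
            ],
            columns=["library_id", "sample_code", "replicate", "series"],
        )
    )

    trend_matrix = {name: _blockwise_trend(name, series) for name in ARCHETYPE_NAMES}

    # ---- family attributes (all randomness drawn in one fixed order) ----
    fam_ids = [f"RPF{i + 1:03d}" for i in range(spec.n_families)]
    n_members = rng.integers(spec.paralogues_min, spec.paralogues_max + 1, spec.n_families)
    scales = np.exp(rng.normal(0.0, _FAMILY_SCALE_SIGMA, spec.n_families))
    archetypes = [ARCHETYPE_NAMES[i] for i in rng.integers(0, len(ARCHETYPE_NAMES),
                                                           spec.n_families)]
    proportions = [rng.dirichlet(np.full(n, _MEMBER_ALPHA)) for n in n_members]
    lengths = [rng.integers(300, 3001, n) for n in n_members]
    specific_choices = {}
    for fam_idx, planted in spec.planted.items():
        if planted.scenario == "tissue_specific":
            if planted.specific_groups is not None:
                specific_choices[fam_idx] = np.asarray(planted.specific_groups, dtype=int)
            else:
                k = max(2, spec.n_groups // 12)
                specific_choices[fam_idx] = np.sort(
                    rng.choice(spec.n_groups, size=k, replace=False)
                )
    tissue_factor = np.exp(rng.normal(0.0, _TISSUE_SIGMA, spec.n_groups))

    # ---- expected RPKM profiles (pre-normalisation) ----------------------
    records: list[GeneRecord] = []
    gene_rows: list[tuple[str, str, str]] = []  # gene, family, trend label
    profiles: list[np.ndarray] = []
    fam_sum_profiles: dict[int, np.ndarray] = {}
    ratio_families = [
        i for i, p in spec.planted.items() if p.scenario in ("substoichiometric", "superfluous")
    ]

    def family_genes(i: int) -> list[str]:
        letters = [chr(ord("A") + j) for j in range(n_members[i])]
        return [f"{fam_ids[i]}{l}" for l in letters]

    for i in range(spec.n_families):
        planted = spec.planted.get(i)
        scenario = planted.scenario if planted else "baseline"
        genes = family_genes(i)
        subunit = "RPS" if i % 2 == 0 else "RPL"
        trend = trend_matrix[archetypes[i]]
        fam_level = _BASE_FAMILY_RPKM * scales[i]
        member_profiles = np.zeros((n_members[i], spec.n_groups))

        if scenario in ("baseline", "concerted"):
            for j in range(n_members[i]):
                member_profiles[j] = fam_level * proportions[i][j] * trend
            labels = [archetypes[i]] * n_members[i]
        elif scenario == "contrasting":
            reversed_trend = 2.0 - trend  # mirror around the mean level, r = -1
            for j in range(n_members[i]):
                t = reversed_trend if j == 1 else trend
                member_profiles[j] = fam_level * proportions[i][j] * t
            labels = [archetypes[i]] * n_members[i]
            labels[1] = f"{archetypes[i]}_reversed"
        elif scenario == "tissue_specific":
            mask = np.zeros(spec.n_groups)
            mask[specific_choices[i]] = 1.0
            for j in range(n_members[i] - 1):
                member_profiles[j] = fam_level * proportions[i][j] * trend
            member_profiles[-1] = fam_level * proportions[i][-1] * 1.2 * mask
            labels = [archetypes[i]] * (n_members[i] - 1) + ["specific"]
        else:  # ratio-planted: filled in after the baseline median is known
            labels = ["ratio_planted"] * n_members[i]

        for j, gene in enumerate(genes):
            records.append(
                GeneRecord(gene, fam_ids[i], subunit, False, int(lengths[i][j]))
            )
            gene_rows.append((gene, fam_ids[i], labels[j]))
            profiles.append(member_profiles[j])
        if scenario not in ("substoichiometric", "superfluous"):
            fam_sum_profiles[i] = member_profiles.sum(axis=0)

    # ratio-planted families: family sum = ratio * per-group median of others
    if ratio_families:
        others = np.array([fam_sum_profiles[i] for i in range(spec.n_families)
                           if i not in ratio_families])
        median_profile = np.median(others, axis=0)
        gene_cursor = 0
        gene_index = {g: k for k, (g, _, _) in enumerate(gene_rows)}
        for i in ratio_families:
            target = spec.planted[i].ratio * median_profile
            for j, gene in enumerate(family_genes(i)):
                profiles[gene_index[gene]] = proportions[i][j] * target
            fam_sum_profiles[i] = target

    # ---- background genes ------------------------------------------------
    bg_genes: list[str] = []
    if spec.n_background:
        bg_scales = np.exp(rng.normal(0.0, 0.3, spec.n_background))
        bg_arch = rng.integers(0, len(ARCHETYPE_NAMES), spec.n_background)
        bg_lengths = rng.integers(300, 3001, spec.n_background)
        for b in range(spec.n_background):
            gene = f"BG{b + 1:04d}"
            bg_genes.append(gene)
            trend = trend_matrix[ARCHETYPE_NAMES[bg_arch[b]]]
            profiles.append(_BACKGROUND_LEVEL * _BASE_FAMILY_RPKM * bg_scales[b] * trend)

    all_genes = [g for g, _, _ in gene_rows] + bg_genes
    all_lengths = np.array(
        [r.cdna_length_bp for r in records] + ([int(l) for l in bg_lengths] if spec.n_background else []),
        dtype=float,
    )
    expected = np.vstack(profiles) * tissue_factor[None, :]

    # ---- invert RPKM to expected counts, renormalise columns -------------
    weights = expected * all_lengths[:, None] / 1e3  # proportional to reads
    col_scale = spec.library_size / weights.sum(axis=0)
    mu_group = weights * col_scale[None, :]
    # exact expected RPKM after scaling (totals fixed at library_size)
    expected_rpkm = mu_group * 1e9 / (spec.library_size * all_lengths[:, None])

    libraries = list(meta.library_ids)
    group_of = {lib: code for lib, code in zip(meta.frame["library_id"], meta.frame["sample_code"])}
    col_idx = {code: j for j, code in enumerate(codes)}
    mu = np.column_stack([mu_group[:, col_idx[group_of[lib]]] for lib in libraries])

    if spec.dispersion < 1e-12:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / spec.dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)

    count_df = pd.DataFrame(counts.astype(np.int64), index=all_genes, columns=libraries)
    count_df.index.name = "gene_id"
    totals = pd.Series(float(spec.library_size), index=count_df.columns)
    # guard against the (vanishingly rare) draw exceeding the nominal total
    totals = np.maximum(totals, count_df.sum(axis=0).astype(float))
    counts_out = CountMatrix(values=count_df, library_totals=totals)

    fam_map = GeneFamilyMap(records)

    # ---- truth tables ----------------------------------------------------
    family_truth = pd.DataFrame(
        {
            "family_id": fam_ids,
            "scenario": [spec.planted[i].scenario if i in spec.planted else "baseline"
                         for i in range(spec.n_families)],
            "target_ratio": [
                spec.planted[i].ratio if i in spec.planted and spec.planted[i].ratio
                else np.nan
                for i in range(spec.n_families)
            ],
            "archetype": archetypes,
            "n_members": n_members.astype(int),
        }
    )
    gene_truth = pd.DataFrame(gene_rows, columns=["gene_id", "family_id", "trend_label"])
    expected_rpkm_df = pd.DataFrame(expected_rpkm, index=all_genes, columns=codes)
    expected_rpkm_df.index.name = "gene_id"

    fam_sums = np.array([fam_sum_profiles[i] for i in range(spec.n_families)])
    fam_sums = fam_sums * tissue_factor[None, :] * (col_scale * 1e6 / spec.library_size)[None, :]
    rel = fam_sums / np.median(fam_sums, axis=0)[None, :]
    expected_ratio = pd.DataFrame(rel, index=fam_ids, columns=codes)
    expected_ratio.index.name = "family_id"

    truth = TruthTable(
        family_truth=family_truth,
        gene_truth=gene_truth,
        expected_rpkm=expected_rpkm_df,
        expected_ratio=expected_ratio,
        gene_lengths=pd.Series(all_lengths.astype(int), index=all_genes, name="cdna_length_bp"),
        scenario_params={
            str(i): {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in asdict(p).items()}
            for i, p in spec.planted.items()
        },
    )
    return counts_out, fam_map, meta, truth
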
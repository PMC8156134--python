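"""End-to-end orchestration: simulate/load -> normalize -> stoichiometry ->
clustering -> patterns -> report, with a manifest for reproducibility.

Every stage writes deterministic TSV outputs into one run directory; the
manifest records the configuration hash, seed, package version and per-stage
row counts, so identical configurations produce byte-identical results.
A single top-level seed feeds each stage a stable derived child seed, which
lets stages be re-run independently yet reproducibly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, PipelineError
from .io import (
    CountMatrix,
    GeneFamilyMap,
    SampleMetadata,
    read_count_matrix,
    write_tsv,
)
from .normalization import average_replicates, compute_rpkm, expression_summary, log_transform
from .stoichiometry import (
    count_deviating_families,
    stoichiometry_table,
    sum_families,
)
from .clustering import cluster_heatmap, complete_linkage, euclidean_distances, \
    pearson_correlation_matrix
from .patterns import PatternParams, classify_family_patterns, fuzzy_cmeans, zscore
from .synthetic import PlantedFamily, ScenarioSpec, generate_dataset

log = logging.getLogger("rpfam")

STAGES = ("simulate", "normalize", "stoichiometry", "clustering", "patterns", "report")


@dataclass
class InputPaths:
    counts: str
    gene_map: str
    metadata: str
    totals: str | None = None
    #: optional gene_id -> length TSV for genes outside the family map
    #: (e.g. the whole-transcriptome background of a simulated panel)
    lengths: str | None = None


@dataclass
class RunConfig:
    """Full pipeline configuration.

    Exactly one of ``scenario`` (simulate the inputs) or ``inputs`` (load
    them from disk) must be supplied.
    """

    outdir: str
    seed: int = 0
    scenario: ScenarioSpec | None = None
    inputs: InputPaths | None = None
    pseudocount: float = 1.0
    low_threshold: float = 0.5
    high_threshold: float = 2.0
    count_cutoff: int = 5
    k: int = 6
    fuzzifier: float = 2.0
    n_starts: int = 10
    r_threshold: float = 0.5
    expression_floor: float = 1.0

    def validate(self) -> None:
        if (self.scenario is None) == (self.inputs is None):
            raise ConfigurationError(
                "exactly one of 'scenario' and 'inputs' must be supplied"
            )
        if self.pseudocount < 0:
            raise ConfigurationError("pseudocount must be >= 0")
        if not 0 < self.low_threshold < self.high_threshold:
            raise ConfigurationError("need 0 < low_threshold < high_threshold")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        scenario = raw.pop("scenario", None)
        inputs = raw.pop("inputs", None)
        if scenario is not None:
            planted = {
                int(k): PlantedFamily(**v) for k, v in (scenario.pop("planted", {}) or {}).items()
            }
            scenario = ScenarioSpec(planted=planted, **scenario)
        if inputs is not None:
            inputs = InputPaths(**inputs)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(scenario=scenario, inputs=inputs, **raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    def config_hash(self) -> str:
        """Hash of all analysis parameters (the output location is excluded)."""
        payload = self.to_dict()
        payload.pop("outdir", None)
        canon = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _child_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the run seed (< 2**31)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory. Any stage failure
    aborts with the stage name and marks the manifest incomplete."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": [],
        "complete": False,
    }

    state: dict = {}
    for stage in STAGES:
        log.info("stage %s", stage)
        try:
            info = _STAGE_FUNCS[stage](config, outdir, state)
        except Exception as exc:
            manifest["failed_stage"] = stage
            _write_manifest(outdir, manifest)
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"].append({"name": stage, **info})
    manifest["complete"] = True
    _write_manifest(outdir, manifest)
    return outdir


def _write_manifest(outdir: Path, manifest: dict) -> None:
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, outdir: Path, state: dict) -> dict:
    if config.scenario is not None:
        spec = dataclasses.replace(
            config.scenario, seed=_child_seed(config.seed, "simulate")
            if config.scenario.seed == 0 else config.scenario.seed
        )
        counts, fam_map, meta, truth = generate_dataset(spec)
        truth.write(outdir)
        state["truth"] = truth
    else:
        assert config.inputs is not None
        meta = SampleMetadata.from_tsv(config.inputs.metadata)
        fam_map = GeneFamilyMap.from_tsv(config.inputs.gene_map)
        counts = read_count_matrix(config.inputs.counts, meta, config.inputs.totals)
    counts.to_tsv(outdir / "counts.tsv", outdir / "library_totals.tsv")
    fam_map.to_tsv(outdir / "gene_map.tsv")
    meta.to_tsv(outdir / "metadata.tsv")
    state.update(counts=counts, fam_map=fam_map, meta=meta)
    return {"genes": len(counts.gene_ids), "libraries": len(counts.library_ids)}


def _stage_normalize(config: RunConfig, outdir: Path, state: dict) -> dict:
    counts, fam_map, meta = state["counts"], state["fam_map"], state["meta"]
    lengths = fam_map.lengths()
    if config.inputs is not None and config.inputs.lengths:
        extra = pd.read_csv(config.inputs.lengths, sep="\t", index_col=0).iloc[:, 0]
        lengths.update({g: int(v) for g, v in extra.items()})
    missing = [g for g in counts.gene_ids if g not in lengths]
    if missing:
        truth = state.get("truth")
        if truth is None:
            raise ConfigurationError(f"no cDNA length for genes: {missing[:10]}")
        # simulated background (non-RP) genes: lengths come from the truth table
        for g in missing:
            lengths[g] = int(truth.gene_lengths[g])
    expr_lib = compute_rpkm(counts, lengths)
    expr_group = average_replicates(expr_lib, meta)
    log_group = log_transform(expr_group, config.pseudocount)
    rp_genes = [g for g in fam_map.non_pseudogene_ids if g in log_group.index]
    summary_rp = expression_summary(log_group, rp_genes)
    tables = {
        "rpkm_per_library": expr_lib.values,
        "rpkm_per_group": expr_group.values,
        "expression_summary_rp": summary_rp,
    }
    if len(rp_genes) < len(log_group.index):
        tables["expression_summary_all"] = expression_summary(log_group, list(log_group.index))
    for name, df in tables.items():
        out = df.copy()
        out.index.name = out.index.name or "gene_id"
        write_tsv(out, outdir / f"{name}.tsv")
    state.update(expr_lib=expr_lib, expr_group=expr_group, log_group=log_group,
                 rp_genes=rp_genes)
    return {"groups": expr_group.values.shape[1]}


def _stage_stoichiometry(config: RunConfig, outdir: Path, state: dict) -> dict:
    fam_map, meta = state["fam_map"], state["meta"]
    rp_lib = state["expr_lib"].values.loc[state["rp_genes"]]
    rp_group = state["expr_group"].values.loc[state["rp_genes"]]
    fam_group = sum_families(rp_group, fam_map)
    fam_lib = sum_families(rp_lib, fam_map)
    table = stoichiometry_table(
        fam_group, fam_lib, meta, low=config.low_threshold, high=config.high_threshold
    )
    flags = table.pivot(index="family_id", columns="sample_code", values="flag")
    counts, over = count_deviating_families(flags, cutoff=config.count_cutoff)
    write_tsv(fam_group, outdir / "family_rpkm.tsv")
    write_tsv(table, outdir / "stoichiometry.tsv", index=False)
    dev = counts.to_frame()
    dev.index.name = "sample_code"
    dev["over_cutoff"] = [c in set(over) for c in dev.index]
    write_tsv(dev, outdir / "deviating_counts.tsv")
    state.update(fam_group=fam_group, stoich=table, deviating=dev)
    return {"families": fam_group.shape[0], "flagged": int((table["flag"] != "none").sum())}


def _stage_clustering(config: RunConfig, outdir: Path, state: dict) -> dict:
    log_rp = state["log_group"].loc[state["rp_genes"]]
    gene_tree = complete_linkage(euclidean_distances(log_rp, axis="rows"))
    sample_tree = complete_linkage(euclidean_distances(log_rp, axis="columns"))
    (outdir / "gene_tree.nwk").write_text(gene_tree.to_newick() + "\n")
    (outdir / "sample_tree.nwk").write_text(sample_tree.to_newick() + "\n")
    cluster_heatmap(log_rp, gene_tree, sample_tree, outdir / "ordered_matrix.tsv")
    corr = pearson_correlation_matrix(state["expr_group"].values.loc[state["rp_genes"]])
    corr.index.name = "sample_code"
    write_tsv(corr, outdir / "correlation_matrix.tsv")
    state.update(gene_tree=gene_tree, sample_tree=sample_tree)
    return {"genes": log_rp.shape[0], "samples": log_rp.shape[1]}


def _stage_patterns(config: RunConfig, outdir: Path, state: dict) -> dict:
    meta, fam_map = state["meta"], state["fam_map"]
    expr = state["expr_group"].values.loc[state["rp_genes"]]
    series = meta.series_groups()
    memberships: dict[str, dict] = {}
    n_clustered = 0
    for name, codes in sorted(series.items()):
        # a series needs at least k positions for k trend clusters to be
        # distinguishable; short series are covered by the pattern calls
        if len(codes) < max(3, config.k):
            continue
        sub = expr[codes]
        sub = sub[sub.max(axis=1) >= config.expression_floor]
        z, constant = zscore(sub)
        z = z[~constant]
        if z.shape[0] < config.k:
            continue
        params = PatternParams(
            k=config.k, m=config.fuzzifier, n_starts=config.n_starts,
            seed=_child_seed(config.seed, f"patterns:{name}"),
        )
        fc = fuzzy_cmeans(z, params)
        write_tsv(fc.centers, outdir / f"centers_{name}.tsv")
        memberships[name] = {
            g: [round(float(v), 6) for v in row]
            for g, row in zip(fc.membership.index, fc.membership.to_numpy())
        }
        n_clustered += z.shape[0]
    (outdir / "memberships.json").write_text(
        json.dumps(memberships, indent=2, sort_keys=True) + "\n"
    )
    calls = classify_family_patterns(
        expr, fam_map, series,
        r_threshold=config.r_threshold, expression_floor=config.expression_floor,
    )
    write_tsv(calls, outdir / "pattern_calls.tsv", index=False)
    state["pattern_calls"] = calls
    return {"series_clustered": len(memberships), "families_called": len(calls)}


def _stage_report(config: RunConfig, outdir: Path, state: dict) -> dict:
    text = report(outdir)
    (outdir / "summary.txt").write_text(text)
    return {"chars": len(text)}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "normalize": _stage_normalize,
    "stoichiometry": _stage_stoichiometry,
    "clustering": _stage_clustering,
    "patterns": _stage_patterns,
    "report": _stage_report,
}


def report(run_dir: str | Path) -> str:
    """One-page text summary recomputed from a completed run directory."""
    run_dir = Path(run_dir)
    required = ["expression_summary_rp.tsv", "deviating_counts.tsv", "pattern_calls.tsv"]
    missing = [f for f in required if not (run_dir / f).exists()]
    if missing:
        raise PipelineError(f"incomplete run: missing {missing}")
    summary = pd.read_csv(run_dir / "expression_summary_rp.tsv", sep="\t", index_col=0)
    dev = pd.read_csv(run_dir / "deviating_counts.tsv", sep="\t", index_col=0)
    calls = pd.read_csv(run_dir / "pattern_calls.tsv", sep="\t")
    tallies = calls["label"].value_counts().to_dict()

    lines = ["rpfam run summary", "=================", ""]
    lines.append("RP expression (log2 RPKM medians per sample group):")
    lines.append(f"  groups: {len(summary)}; median of medians: "
                 f"{summary['median'].median():.2f}; "
                 f"range: {summary['median'].min():.2f} .. {summary['median'].max():.2f}")
    lines.append("")
    lines.append("Family stoichiometry deviations (relative level <low or >high):")
    lines.append(f"  total deviating family-sample pairs: {int(dev['deviating_families'].sum())}")
    lines.append(f"  sample groups over the count cutoff: "
                 f"{int(dev['over_cutoff'].sum())} of {len(dev)}")
    top = dev.sort_values('deviating_families', ascending=False).head(5)
    for code, row in top.iterrows():
        lines.append(f"    {code}: {int(row['deviating_families'])} deviating families")
    lines.append("")
    lines.append("Paralogue expression-pattern calls:")
    for label in ("similar", "different", "insufficient_data"):
        lines.append(f"  {label}: {tallies.get(label, 0)}")
    if (run_dir / "memberships.json").exists():
        memberships = json.loads((run_dir / "memberships.json").read_text())
        lines.append("")
        lines.append("Trend clustering (fuzzy c-means):")
        for name in sorted(memberships):
            genes = memberships[name]
            sizes: dict[int, int] = {}
            for row in genes.values():
                j = int(np.argmax(row))
                sizes[j] = sizes.get(j, 0) + 1
            size_txt = ", ".join(str(sizes.get(j, 0)) for j in range(len(next(iter(genes.values())))))
            lines.append(f"  {name}: {len(genes)} genes; hard-label cluster sizes: {size_txt}")
    return "\n".join(lines) + "\n"
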
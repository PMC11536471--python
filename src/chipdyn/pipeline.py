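"""End-to-end run orchestration: call -> pair -> dynamics -> report.

One :func:`run_pipeline` call executes the full analysis on a VCF +
panel + metadata triple and writes every stage output plus a manifest
(input checksums, config echo, per-stage counts).  Reruns on the same
inputs reproduce byte-identical tables: all randomness (the
co-occurrence permutation null) goes through the single configured
seed, and no timestamps enter the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clonal_dynamics import (
    DynamicsConfig,
    architectures_to_frame,
    assign_dynamics,
    assignments_to_frame,
)
from .cohort_stats import (
    associate_covariates,
    cooccurrence_test,
    gene_pairs_from_assignments,
    gene_prevalence_from_assignments,
    gene_summaries_to_frame,
    plot_growth_by_gene,
    plot_vaf_trajectories,
    sensitivity_single_mutation,
    summarize_by_gene,
)
from .panel_and_variants import (
    FilterPolicy,
    calls_to_frame,
    filter_chip,
    load_metadata,
    load_panel,
    pair_timepoints,
    pairs_to_frame,
    read_variants,
)

logger = logging.getLogger("chipdyn")

DEFAULT_COVARIATES = ("age", "sex", "race", "ethnicity", "bmi", "height")


def setup_logging(out_dir: str | Path | None = None, level: int = logging.INFO) -> None:
    """Log to stderr and, when an output directory is given, to run.log."""
    root = logging.getLogger("chipdyn")
    root.setLevel(level)
    root.handlers.clear()
    fmt = logging.Formatter("%(levelname)s %(name)s: %(message)s")
    stream = logging.StreamHandler(sys.stderr)
    stream.setFormatter(fmt)
    root.addHandler(stream)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(Path(out_dir) / "run.log", mode="w")
        fh.setFormatter(fmt)
        root.addHandler(fh)


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs."""

    vcf: Path
    metadata: Path
    out_dir: Path
    panel: Path | None = None  # None -> shipped default panel
    filter_policy: FilterPolicy = field(default_factory=FilterPolicy)
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    min_gene_n: int = 10
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    cooccurrence_n_perm: int = 10_000
    make_plots: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        policy = FilterPolicy(**raw.get("filter_policy", {}))
        dyn = DynamicsConfig(**raw.get("dynamics", {}))
        return cls(
            vcf=Path(raw["vcf"]),
            metadata=Path(raw["metadata"]),
            out_dir=Path(raw["out_dir"]),
            panel=Path(raw["panel"]) if raw.get("panel") else None,
            filter_policy=policy,
            dynamics=dyn,
            min_gene_n=int(raw.get("min_gene_n", 10)),
            covariates=tuple(raw.get("covariates", DEFAULT_COVARIATES)),
            cooccurrence_n_perm=int(raw.get("cooccurrence_n_perm", 10_000)),
            make_plots=bool(raw.get("make_plots", False)),
            seed=int(raw.get("seed", 0)),
        )

    def validate(self) -> None:
        for name, p in (("vcf", self.vcf), ("metadata", self.metadata),
                        ("panel", self.panel)):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path) -> int:
    frame.to_csv(path, sep="\t", index=False)
    return len(frame)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON).

    Stage failures abort with the stage named in the raised exception.
    An empty call set degrades gracefully to empty outputs and zero
    counts.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "chipdyn",
        "version": __version__,
        "inputs": {
            "vcf": str(config.vcf), "vcf_sha256": _sha256(Path(config.vcf)),
            "metadata": str(config.metadata),
            "metadata_sha256": _sha256(Path(config.metadata)),
            "panel": str(config.panel) if config.panel else "shipped-default",
        },
        "config": {
            "filter_policy": dataclasses.asdict(config.filter_policy),
            "dynamics": dataclasses.asdict(config.dynamics),
            "min_gene_n": config.min_gene_n,
            "covariates": list(config.covariates),
            "cooccurrence_n_perm": config.cooccurrence_n_perm,
            "seed": config.seed,
        },
        "counts": {},
        "stage_outputs": {},
        "partial": False,
    }
    counts = manifest["counts"]
    outputs = manifest["stage_outputs"]

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("call")
        panel = load_panel(config.panel)
        meta = load_metadata(config.metadata)
        counts["panel_genes"] = len(panel.genes)
        counts["panel_target_bp"] = panel.target_bp
        all_calls = read_variants(config.vcf, panel, meta)
        retained = filter_chip(all_calls, config.filter_policy)
        counts["calls_read"] = len(all_calls)
        counts["calls_retained"] = len(retained)
        outputs["retained_calls"] = str(out / "retained_calls.tsv")
        _write_tsv(calls_to_frame(retained), out / "retained_calls.tsv")

        stage("pair")
        pairs = pair_timepoints(retained, all_calls, config.filter_policy, meta)
        counts["clone_pairs"] = len(pairs)
        outputs["clone_pairs"] = str(out / "clone_pairs.tsv")
        _write_tsv(pairs_to_frame(pairs), out / "clone_pairs.tsv")

        stage("dynamics")
        assignments, arch_calls, dyn_summary = assign_dynamics(pairs, config.dynamics)
        counts.update({
            "clones": dyn_summary["n_clones"],
            "stagnant": dyn_summary["n_stagnant"],
            "expansion": dyn_summary["n_expansion"],
            "reduction": dyn_summary["n_reduction"],
            "architecture_calls": dyn_summary["n_architecture_calls"],
            "sub_clone": dyn_summary["n_sub_clone"],
            "distinct": dyn_summary["n_distinct"],
        })
        manifest["dynamics_summary"] = dyn_summary
        outputs["clone_trajectories"] = str(out / "clone_trajectories.tsv")
        _write_tsv(assignments_to_frame(assignments), out / "clone_trajectories.tsv")
        outputs["architecture"] = str(out / "architecture.tsv")
        _write_tsv(architectures_to_frame(arch_calls), out / "architecture.tsv")

        stage("report")
        summaries = summarize_by_gene(assignments, min_n=config.min_gene_n)
        outputs["gene_summary"] = str(out / "gene_summary.tsv")
        _write_tsv(gene_summaries_to_frame(summaries), out / "gene_summary.tsv")
        if assignments:
            restricted, removed = sensitivity_single_mutation(
                assignments, min_n=config.min_gene_n)
            counts["single_mutation_fraction_removed"] = removed
            _write_tsv(gene_summaries_to_frame(restricted),
                       out / "gene_summary_single_mutation.tsv")
            outputs["gene_summary_single_mutation"] = str(
                out / "gene_summary_single_mutation.tsv")
        gene_pairs = gene_pairs_from_assignments(assignments)
        if gene_pairs:
            prevalence = gene_prevalence_from_assignments(assignments)
            result = cooccurrence_test(
                gene_pairs, prevalence, method="both",
                n_perm=config.cooccurrence_n_perm, seed=config.seed,
            )
            cooc = {
                "chi2": result.chi2, "df": result.df,
                "p_analytic": result.p_analytic,
                "p_permutation": result.p_permutation,
                "n_pairs": result.n_pairs,
                "observed": {f"{g}|{h}": c for (g, h), c in sorted(result.observed.items())},
                "expected": {f"{g}|{h}": e for (g, h), e in sorted(result.expected.items())},
            }
            with open(out / "cooccurrence.json", "w") as fh:
                json.dump(cooc, fh, indent=2, sort_keys=True)
            outputs["cooccurrence"] = str(out / "cooccurrence.json")
            manifest["cooccurrence"] = {
                "chi2": result.chi2, "p_analytic": result.p_analytic,
                "p_permutation": result.p_permutation, "n_pairs": result.n_pairs,
            }
        if assignments and config.covariates:
            available = [c for c in config.covariates if c in meta.columns]
            if available:
                assoc = associate_covariates(assignments, meta, available)
                outputs["associations"] = str(out / "associations.tsv")
                _write_tsv(assoc, out / "associations.tsv")
        if config.make_plots and assignments:
            plot_growth_by_gene(assignments, out / "growth_by_gene.png",
                                min_n=config.min_gene_n)
            plot_vaf_trajectories(assignments, out / "vaf_trajectories.png")
            outputs["plots"] = [str(out / "growth_by_gene.png"),
                                str(out / "vaf_trajectories.png")]
    except Exception as exc:
        manifest["partial"] = True
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    logger.info("pipeline complete: %s", json.dumps(counts, sort_keys=True))
    return manifest
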
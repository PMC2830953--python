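"""Per-gene orchestration of the full selective-pressure workflow.

Stage order follows the analysis design: alignment quality (randomization
z-score, composition bias, likelihood mapping with a hard gate on signal
category 3), phylogeny (NJ + NNI maximum likelihood), gene-vs-species tree
comparison (nodal RMSD, SH), the slow-fast LBA scan, codon selection
models with LRTs and empirical-Bayes site calls, and finally reference
mapping plus the proximity randomization test against supplied features.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as anno
from . import codon as cd
from . import quality as ql
from . import stripping as st
from . import treecompare as tc
from .alignments import (CodonAlignment, ProteinAlignment, alignment_z_score,
                         read_alignment, translate)
from .engine import optimize_tree, select_model
from .substmodels import SubstitutionModelSpec
from .trees import PhyloTree

log = logging.getLogger("phyloselect.pipeline")

MIN_TAXA_RECOMMENDED = 6


@dataclass
class PipelineConfig:
    gene_id: str
    alignment_path: str
    species_tree_path: str
    alignment_format: str = "fasta"
    alignment_level: str = "codon"  # codon input enables selection models
    reference_taxon: str | None = None
    feature_table_path: str | None = None
    reference_length: int | None = None
    foregrounds: dict[str, list[str]] = field(default_factory=dict)
    site_models: list[str] = field(
        default_factory=lambda: ["M0", "M1", "M2", "M3k2", "M7", "M8", "M8a"])
    signal_thresholds: tuple[float, float, float] = (0.9, 0.05, 0.7)
    sh_alpha: float = 0.05
    n_quartets: int = 100
    n_rell: int = 1000
    n_shuffles: int = 200
    lba_max_depth: int = 2
    n_restarts: int = 2
    seed: int = 1
    allow_few_taxa: bool = False
    run_model_selection: bool = False

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "signal_thresholds" in raw:
            raw["signal_thresholds"] = tuple(raw["signal_thresholds"])
        return cls(**raw)


@dataclass
class GeneReport:
    gene_id: str
    config: PipelineConfig
    z_report: object = None
    composition_aa: list = None
    composition_nt: list = None
    quartet_map: object = None
    signal_category: object = None
    gene_tree: PhyloTree | None = None
    gene_tree_lnl: float | None = None
    aa_model_name: str | None = None
    rmsd_vs_species: float | None = None
    sh: object = None
    stripping_levels: list = None
    lba_verdict: object = None
    model_fits: dict = None
    lrts: dict = None
    site_calls: object = None
    branch_site: dict = None
    proximity: object = None
    errors: dict[str, str] = field(default_factory=dict)
    stages_run: list[str] = field(default_factory=list)
    gated: bool = False

    def summary_row(self) -> dict:
        """Verdict line with the per-gene quality/phylogeny summary columns."""
        def _pass(results):
            if not results:
                return "n/a"
            return "Pass" if all(r.passed for r in results) else "Fail"
        sig = self.signal_category.category if self.signal_category else "n/a"
        return {
            "gene": self.gene_id,
            "LM_category": sig,
            "AA_comp_bias": _pass(self.composition_aa),
            "base_comp_bias": _pass(self.composition_nt),
            "model": self.aa_model_name or "n/a",
            "tree_method": "ml_nni",
            "gene_v_species": (
                "n/a" if self.sh is None else
                ("Unresolved" if self.sh.best_fit == "NS" else "Resolved")),
            "LBA": ("n/a" if self.lba_verdict is None else
                    ("Yes" if self.lba_verdict.lba_detected else "No")),
        }

    def write(self, outdir: str) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([self.summary_row()]).to_csv(
            out / "summary.tsv", sep="\t", index=False)
        if self.composition_aa:
            pd.DataFrame([vars(r) for r in self.composition_aa]).to_csv(
                out / "composition_aa.tsv", sep="\t", index=False)
        if self.composition_nt:
            pd.DataFrame([vars(r) for r in self.composition_nt]).to_csv(
                out / "composition_nt.tsv", sep="\t", index=False)
        if self.quartet_map:
            pd.DataFrame([{**self.quartet_map.region_counts,
                           "n_quartets": self.quartet_map.n_quartets,
                           "corner_fraction": self.quartet_map.corner_fraction,
                           "center_fraction": self.quartet_map.center_fraction,
                           }]).to_csv(out / "likelihood_mapping.tsv",
                                      sep="\t", index=False)
        if self.gene_tree is not None:
            (out / "gene_tree.nwk").write_text(self.gene_tree.to_newick() + "\n")
        if self.stripping_levels:
            st.levels_table(self.stripping_levels).to_csv(
                out / "stripping.tsv", sep="\t", index=False)
        if self.model_fits:
            pd.DataFrame([f.summary_row() for f in self.model_fits.values()]
                         ).to_csv(out / "codon_models.tsv", sep="\t",
                                  index=False)
        if self.lrts:
            pd.DataFrame([vars(l) for l in self.lrts.values()]).to_csv(
                out / "lrts.tsv", sep="\t", index=False)
        if self.proximity is not None:
            self.proximity.to_table().to_csv(
                out / "proximity.tsv", sep="\t", index=False)
        if self.errors:
            pd.DataFrame([{"stage": k, "error": v}
                          for k, v in self.errors.items()]).to_csv(
                out / "errors.tsv", sep="\t", index=False)


def _digest(data: str) -> str:
    return hashlib.sha256(data.encode()).hexdigest()[:12]


def _stage(report: GeneReport, name: str):
    """Record a stage run with structured logging; errors stop later stages."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.time()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                report.errors[name] = f"{exc_type.__name__}: {exc}"
                log.warning("stage=%s failed error=%r", name, str(exc))
                return True  # swallow; caller checks report.errors
            report.stages_run.append(name)
            log.info("stage=%s ok runtime=%.2fs", name, time.time() - self.t0)
            return False
    return _Ctx()


def run_pipeline(config: PipelineConfig) -> GeneReport:
    report = GeneReport(config.gene_id, config)
    aln = read_alignment(config.alignment_path, config.alignment_format,
                         level=config.alignment_level)
    species_tree = PhyloTree.from_file(config.species_tree_path)
    if isinstance(aln, CodonAlignment):
        codon_aln, prot_aln = aln, translate(aln)
    else:
        codon_aln, prot_aln = None, aln
    log.info("gene=%s taxa=%d sites=%d digest=%s seed=%d",
             config.gene_id, prot_aln.n_taxa, prot_aln.length_aa,
             _digest("".join(prot_aln.rows)), config.seed)
    if prot_aln.n_taxa < MIN_TAXA_RECOMMENDED:
        if not config.allow_few_taxa:
            raise ValueError(
                f"only {prot_aln.n_taxa} taxa; selection estimates are "
                "unreliable below 6 taxa. Set allow_few_taxa to override.")
        log.warning("fewer than %d taxa; proceeding on explicit override",
                    MIN_TAXA_RECOMMENDED)

    with _stage(report, "alignment_z_score"):
        report.z_report = alignment_z_score(
            prot_aln, n_shuffles=config.n_shuffles, seed=config.seed)
    with _stage(report, "composition_bias"):
        report.composition_aa = ql.composition_bias_test(prot_aln, "aa")
        if codon_aln is not None:
            report.composition_nt = ql.composition_bias_test(codon_aln, "nt")
    with _stage(report, "likelihood_mapping"):
        report.quartet_map = ql.likelihood_map(
            prot_aln, n_quartets=config.n_quartets, seed=config.seed)
        c1, z1, c2 = config.signal_thresholds
        report.signal_category = ql.classify_signal(
            report.quartet_map, c1=c1, z1=z1, c2=c2)
    if "likelihood_mapping" in report.errors:
        return report
    if report.signal_category.category == 3:
        report.gated = True
        log.info("gene=%s gated: signal category 3; selection stages skipped",
                 config.gene_id)
        return report

    aa_model = SubstitutionModelSpec(plus_G=True, k_rates=8)
    with _stage(report, "gene_tree"):
        if config.run_model_selection:
            aa_model, _ = select_model(prot_aln, species_tree.prune_to(
                prot_aln.taxa))
        report.aa_model_name = aa_model.name
        fit = optimize_tree(prot_aln, aa_model, search="nni")
        report.gene_tree, report.gene_tree_lnl = fit.tree, fit.lnl
    if "gene_tree" in report.errors:
        return report

    with _stage(report, "tree_compare"):
        pruned_species = species_tree.prune_to(prot_aln.taxa)
        report.rmsd_vs_species = tc.nodal_rmsd(
            report.gene_tree, pruned_species).rmsd
        report.sh = tc.sh_test(
            prot_aln, [report.gene_tree, pruned_species], aa_model,
            n_rell=config.n_rell, seed=config.seed, alpha=config.sh_alpha)
    with _stage(report, "lba_scan"):
        report.stripping_levels, report.lba_verdict = st.slow_fast_scan(
            prot_aln, species_tree, aa_model,
            max_depth=config.lba_max_depth, seed=config.seed,
            n_rell=config.n_rell)

    if codon_aln is None:
        return report

    with _stage(report, "codon_selection"):
        pruned_species = species_tree.prune_to(codon_aln.taxa)
        bl_tree, m0_params, _ = cd.fit_m0_with_branch_lengths(
            codon_aln, pruned_species)
        fits: dict[str, cd.ModelFit] = {}
        for name in config.site_models:
            fits[name] = cd.fit_model(
                codon_aln, bl_tree, cd.CodonModelSpec(name),
                n_restarts=config.n_restarts, seed=config.seed,
                branch_lengths="given")
        report.model_fits = fits
        report.lrts = {}
        for pair in cd.LRT_REGISTRY:
            if pair[0] in fits and pair[1] in fits:
                report.lrts["_v_".join(reversed(pair))] = cd.run_lrt(
                    fits[pair[0]], fits[pair[1]])
        if "M8" in fits:
            report.site_calls = cd.site_posteriors(
                fits["M8"], codon_aln, method="BEB",
                reference_taxon=config.reference_taxon)
    if config.foregrounds and "codon_selection" not in report.errors:
        with _stage(report, "branch_site"):
            report.branch_site = cd.branch_site_scan(
                codon_aln, bl_tree, config.foregrounds, seed=config.seed,
                n_restarts=config.n_restarts, branch_lengths="given")

    if (config.feature_table_path and report.site_calls is not None
            and config.reference_taxon):
        with _stage(report, "proximity"):
            calls = report.site_calls
            ref_positions = [
                calls.reference_positions[c]
                for c in calls.calls[0.50]
                if calls.reference_positions.get(c) is not None]
            ref_len = config.reference_length
            if ref_len is None:
                ref_len = sum(
                    ch != "-" for ch in translate(codon_aln).row(
                        config.reference_taxon))
            features = anno.FeatureSet.from_tsv(
                config.feature_table_path, ref_len)
            report.proximity = anno.proximity_randomization(
                ref_positions, features, mode="exact", seed=config.seed)
    return report
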
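"""End-to-end orchestration: species-level codon-usage reports and
clade-level divergence/polarity reports.

``run_species`` chains the stages for one species: gene filtering ->
per-gene indices -> optimal-codon identification -> selection analysis,
writing plain-text TSV/JSON reports.  ``run_clade`` computes a pairwise dS
matrix with divergence times and, when ancestor/descendant pairs are
supplied, the polarized substitution report.  Every report bundle carries
the config hash and seed; re-running with the same inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .codon_metrics import aggregate_indices
from .divergence_popgen import (
    DEFAULT_GENERATIONS_PER_YEAR,
    DEFAULT_MU,
    pairwise_ds_matrix,
    read_aligned_fasta,
    time_from_ds,
)
from .optimal_codons import OptimalCodonSet, identify_optimal_codons
from .selection_strength import MutationSpectrum, selection_analysis
from .sequence_io import (
    GeneSet,
    attach_expression,
    filter_genes,
    read_cds_fasta,
    read_expression_table,
    write_filter_report,
)
from .substitution_polarity import branch_report


@dataclass
class PipelineConfig:
    """Analysis parameters; defaults are the study's stated values."""

    cds_fasta: str | None = None
    expression_table: str | None = None
    alignment_fasta: str | None = None
    branch_pairs: tuple[tuple[str, str], ...] = ()
    out_dir: str = "cub_out"
    min_codons: int = 200
    n_extremes: int = 500
    reps: int = 1000
    extremes_fraction: float = 0.05
    alpha: float = 0.01
    mu: float = DEFAULT_MU
    generations_per_year: float = DEFAULT_GENERATIONS_PER_YEAR
    spectrum_u: float | None = None
    spectrum_v: float | None = None
    seed: int = 0
    genetic_code: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "branch_pairs" in data:
            data["branch_pairs"] = tuple(
                tuple(p) for p in data["branch_pairs"]
            )
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def spectrum(self) -> MutationSpectrum | None:
        if self.spectrum_u is not None and self.spectrum_v is not None:
            return MutationSpectrum(u=self.spectrum_u, v=self.spectrum_v)
        return None


def _write_run_log(cfg: PipelineConfig, out: Path, stages: list[str]) -> None:
    log = {
        "cubkit_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "parameters": dataclasses.asdict(cfg),
        "stages": stages,
    }
    (out / "run_log.json").write_text(
        json.dumps(log, indent=2, sort_keys=True, default=str) + "\n"
    )


def run_species(
    cfg: PipelineConfig, gene_set: GeneSet | None = None
) -> dict[str, Path]:
    """Run the per-species pipeline; returns a name -> path report map.

    ``gene_set`` may be supplied directly (e.g. from the simulator) in
    place of ``cfg.cds_fasta``; expression must then already be attached.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = []
    if gene_set is None:
        if cfg.cds_fasta is None:
            raise ValueError("no CDS input: set cds_fasta or pass a gene set")
        gene_set = read_cds_fasta(cfg.cds_fasta, genetic_code=cfg.genetic_code)
        if cfg.expression_table:
            gene_set = attach_expression(
                gene_set, read_expression_table(cfg.expression_table)
            )
        stages.append("read")
    gs = filter_genes(gene_set, cfg.min_codons, cfg.genetic_code)
    stages.append("filter")
    paths: dict[str, Path] = {}
    write_filter_report(gs, out / "filter_report.tsv")
    paths["filter_report"] = out / "filter_report.tsv"

    try:
        ocs = identify_optimal_codons(
            gs,
            extremes_fraction=cfg.extremes_fraction,
            alpha=cfg.alpha,
            genetic_code=cfg.genetic_code,
        )
        stages.append("optimal_codons")
    except ValueError as err:
        raise RuntimeError(f"stage optimal_codons failed: {err}") from err
    ocs.to_json(out / "optimal_codons.json")
    (out / "optimal_codons_flags.tsv").write_text(ocs.to_flag_table())
    paths["optimal_codons"] = out / "optimal_codons.json"

    per_gene, summary = aggregate_indices(gs, ocs)
    per_gene.to_csv(out / "indices_per_gene.tsv", sep="\t", float_format="%.6g")
    summary.to_csv(out / "indices_summary.tsv", sep="\t", float_format="%.6g")
    paths["indices_per_gene"] = out / "indices_per_gene.tsv"
    paths["indices_summary"] = out / "indices_summary.tsv"
    stages.append("indices")

    has_expression = all(g.expression is not None for g in gs)
    if has_expression and len(gs) >= 2 * cfg.n_extremes:
        try:
            est = selection_analysis(
                gs,
                ocs,
                spectrum=cfg.spectrum(),
                n=cfg.n_extremes,
                reps=cfg.reps,
                seed=cfg.seed,
                genetic_code=cfg.genetic_code,
            )
            stages.append("selection")
            sel = pd.DataFrame(
                [
                    {
                        "species": gs.species_label,
                        "P": est.P,
                        "k": est.k,
                        "S": est.S,
                        "p_value": est.p_value,
                        "significance": est.significance,
                    }
                ]
            )
            sel.to_csv(
                out / "selection.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
            null = {
                "null_mean": float(np.mean(est.null_S)),
                "null_sd": float(np.std(est.null_S)),
                "null_q95": float(np.quantile(est.null_S, 0.95)),
                "null_q99": float(np.quantile(est.null_S, 0.99)),
                "reps": cfg.reps,
                "S_observed": est.S,
                "p_value": est.p_value,
            }
            (out / "selection_null.json").write_text(
                json.dumps(null, indent=2, sort_keys=True) + "\n"
            )
            paths["selection"] = out / "selection.tsv"
        except ValueError as err:
            raise RuntimeError(f"stage selection failed: {err}") from err
    _write_run_log(cfg, out, stages)
    paths["run_log"] = out / "run_log.json"
    return paths


def run_clade(
    cfg: PipelineConfig,
    branch_pairs=None,
    ocs: OptimalCodonSet | None = None,
) -> dict[str, Path]:
    """Clade-level reports: pairwise dS matrix, divergence times, polarity.

    ``branch_pairs`` is a list of (AlignedCodonPair, OptimalCodonSet)
    tuples (or plain pairs, with a shared ``ocs``).  When only an
    alignment is supplied the output is divergence-only.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = []
    paths: dict[str, Path] = {}
    if cfg.alignment_fasta:
        seqs = read_aligned_fasta(cfg.alignment_fasta)
        mat = pairwise_ds_matrix(
            seqs, genetic_code=cfg.genetic_code
        )
        mat.to_csv(out / "ds_matrix.tsv", sep="\t", float_format="%.6g")
        times = []
        for a in mat.index:
            for b in mat.columns:
                if a < b:
                    t_gen, t_yr = time_from_ds(
                        mat.loc[a, b], cfg.mu, cfg.generations_per_year
                    )
                    times.append(
                        {
                            "pair": f"{a}--{b}",
                            "ds": mat.loc[a, b],
                            "t_generations": t_gen,
                            "t_years": t_yr,
                        }
                    )
        pd.DataFrame(times).to_csv(
            out / "divergence_times.tsv", sep="\t", index=False,
            float_format="%.6g",
        )
        paths["ds_matrix"] = out / "ds_matrix.tsv"
        paths["divergence_times"] = out / "divergence_times.tsv"
        stages.append("divergence")
    if branch_pairs:
        report = branch_report(
            branch_pairs, ocs=ocs, genetic_code=cfg.genetic_code
        )
        report.to_csv(
            out / "polarity_report.tsv", sep="\t", index=False,
            float_format="%.6g",
        )
        paths["polarity_report"] = out / "polarity_report.tsv"
        stages.append("polarity")
    _write_run_log(cfg, out, stages)
    paths["run_log"] = out / "run_log.json"
    return paths
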
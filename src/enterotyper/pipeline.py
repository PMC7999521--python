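"""End-to-end orchestration: simulate -> enterotype -> associate.

Each runner writes a self-contained output directory (TSV artifacts plus
``manifest.json`` recording version, parameters, seeds and input digests)
and is atomic: results are assembled in a temporary sibling directory and
renamed into place only on success, so a failed run leaves no partial
output directory behind.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import tempfile
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import pam
from .distance import jsd_matrix, write_distance_matrix
from .group_stats import (
    cooccurrence_matrix,
    per_feature_group_tests,
    phenotype_association_ranking,
)
from .io_tables import (
    AbundanceTable,
    EnterotypeLabels,
    align_tables,
    filter_low_abundance,
    normalize_relative,
    read_abundance_table,
    read_labels,
    read_phenotype_table,
    write_abundance_table,
    write_labels,
    write_phenotype_table,
)
from .model_selection import alpha_diversity, choose_k
from .ordination import pcoa
from .synthetic_data import (
    PRODUCER_GENERA,
    CohortConfig,
    default_config,
    generate_cohort,
    write_truth,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest(stage: str, params: dict, inputs: dict[str, Path]) -> dict:
    return {
        "tool": "enterotyper",
        "version": __version__,
        "stage": stage,
        "parameters": params,
        "inputs": {k: {"path": str(p), "sha256": _digest(p)} for k, p in inputs.items()},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }


class _AtomicDir:
    """Assemble outputs in a temp dir; rename to the target on success."""

    def __init__(self, out_dir: str | Path):
        self.final = Path(out_dir)
        if self.final.exists() and any(self.final.iterdir()):
            raise PipelineError(f"output directory {self.final} exists and is not empty")
        self.tmp = Path(
            tempfile.mkdtemp(prefix=self.final.name + ".tmp-", dir=self.final.parent or ".")
        )

    def __enter__(self) -> Path:
        return self.tmp

    def __exit__(self, exc_type, exc, tb) -> None:
        if exc_type is not None:
            shutil.rmtree(self.tmp, ignore_errors=True)
            return
        if self.final.exists():
            self.final.rmdir()
        self.tmp.rename(self.final)


def run_simulate(config: CohortConfig | str | Path | None, out_dir: str | Path) -> Path:
    """Generate a cohort and write abundance/phenotype/truth files."""
    if config is None:
        config = default_config()
    elif not isinstance(config, CohortConfig):
        config = CohortConfig.from_yaml(config)
    table, phenotype, truth = generate_cohort(config)
    with _AtomicDir(out_dir) as tmp:
        write_abundance_table(table, tmp / "abundance.tsv")
        write_phenotype_table(phenotype, tmp / "phenotype.tsv")
        write_truth(truth, tmp / "truth.tsv", tmp / "truth.json")
        config.to_yaml(tmp / "config.yaml")
        manifest = _manifest(
            "simulate",
            {"seed": config.seed, "n_samples": config.n_samples, "k": config.k},
            {},
        )
        (tmp / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return Path(out_dir)


def run_enterotype(
    abundance_path: str | Path,
    out_dir: str | Path,
    k_range=range(2, 7),
    ps_threshold: float = 0.8,
    n_repeats: int = 20,
    seed: int = 0,
    min_mean_rel: float = 0.0,
    min_prevalence: float = 0.0,
    zero_replacement: float = 1e-9,
    forced_k: int | None = None,
) -> Path:
    """normalize -> (filter) -> JSD -> choose K -> PAM -> PCoA."""
    abundance_path = Path(abundance_path)
    if not abundance_path.exists():
        raise PipelineError(f"enterotype: input not found: {abundance_path}")
    try:
        table = read_abundance_table(abundance_path)
        rel = normalize_relative(table)
        removed: list[str] = []
        if min_mean_rel > 0 or min_prevalence > 0:
            rel, removed = filter_low_abundance(rel, min_mean_rel, min_prevalence)
        dm = jsd_matrix(rel, zero_replacement=zero_replacement)
        report = choose_k(
            dm, k_range=k_range, ps_threshold=ps_threshold, n_repeats=n_repeats, seed=seed
        )
        k = forced_k if forced_k is not None else report.chosen_k
        result = pam(dm, k)
        alpha = alpha_diversity(table)
        ordination = pcoa(dm)
    except (ValueError, KeyError) as exc:
        raise PipelineError(f"enterotype: {exc}") from exc
    with _AtomicDir(out_dir) as tmp:
        report.to_frame().to_csv(tmp / "ksel.tsv", sep="\t")
        write_labels(result.labels, tmp / "labels.tsv")
        ordination.to_frame().to_csv(tmp / "pcoa.tsv", sep="\t")
        pd.DataFrame(
            {
                "eigenvalue": ordination.eigenvalues,
                "proportion_explained": ordination.proportion_explained,
            },
            index=[f"PCo{i + 1}" for i in range(len(ordination.eigenvalues))],
        ).to_csv(tmp / "pcoa_eigenvalues.tsv", sep="\t")
        alpha.to_frame().to_csv(tmp / "alpha_diversity.tsv", sep="\t")
        write_distance_matrix(dm, tmp / "distance.tsv")
        manifest = _manifest(
            "enterotype",
            {
                "k_range": [int(min(k_range)), int(max(k_range))],
                "chosen_k": int(report.chosen_k),
                "final_k": int(k),
                "ps_threshold": ps_threshold,
                "ps_below_threshold_warning": bool(report.below_threshold_warning),
                "n_repeats": n_repeats,
                "seed": seed,
                "zero_replacement": zero_replacement,
                "log_base": "e",
                "distance": "root Jensen-Shannon divergence",
                "filtered_taxa": removed,
                "medoid_sample_ids": result.medoid_ids,
                "total_cost": result.total_cost,
                "shannon_base": "e",
            },
            {"abundance": abundance_path},
        )
        (tmp / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return Path(out_dir)


def run_association(
    abundance_path: str | Path,
    phenotype_path: str | Path,
    labels_path: str | Path,
    out_dir: str | Path,
    candidates: list[str] | None = None,
    alpha: float = 0.05,
    top_n: int = 12,
    min_common_samples: int = 10,
) -> Path:
    """Group tests, co-occurrence matrix and the butyrate ranking."""
    paths = {
        "abundance": Path(abundance_path),
        "phenotype": Path(phenotype_path),
        "labels": Path(labels_path),
    }
    for name, p in paths.items():
        if not p.exists():
            raise PipelineError(f"associate: {name} input not found: {p}")
    if candidates is None:
        candidates = list(PRODUCER_GENERA)
    try:
        table = normalize_relative(read_abundance_table(paths["abundance"]))
        phenotype = read_phenotype_table(paths["phenotype"])
        labels = read_labels(paths["labels"])
        table, phenotype, align_report = align_tables(table, phenotype)
        if align_report.n_common < min_common_samples:
            raise PipelineError(
                f"associate: only {align_report.n_common} samples align "
                f"(< {min_common_samples})"
            )
        label_series = labels.to_series().reindex(table.data.index)
        if label_series.isna().any():
            missing = table.data.index[label_series.isna()].tolist()
            raise PipelineError(
                f"associate: samples without enterotype label: {missing[:5]}"
            )
        labels = EnterotypeLabels(
            table.sample_ids, label_series.to_numpy(dtype=float).astype(int)
        )
        taxa_tests = per_feature_group_tests(table, labels, alpha=alpha)
        alpha_tests = per_feature_group_tests(alpha_diversity(table), labels, alpha=alpha)
        phen_tests = per_feature_group_tests(phenotype, labels, alpha=alpha)
        cooc = cooccurrence_matrix(table, top_n=min(top_n, table.n_taxa))
        ranking = phenotype_association_ranking(table, phenotype, candidates)
    except PipelineError:
        raise
    except (ValueError, KeyError) as exc:
        raise PipelineError(f"associate: {exc}") from exc
    with _AtomicDir(out_dir) as tmp:
        taxa_tests.to_csv(tmp / "group_tests_taxa.tsv", sep="\t")
        alpha_tests.to_csv(tmp / "group_tests_alpha.tsv", sep="\t")
        phen_tests.to_csv(tmp / "group_tests_phenotype.tsv", sep="\t")
        cooc.rho.to_csv(tmp / "cooccurrence.tsv", sep="\t")
        cooc.long.to_csv(tmp / "cooccurrence_long.tsv", sep="\t", index=False)
        ranking.table.to_csv(tmp / "butyrate_ranking.tsv", sep="\t")
        manifest = _manifest(
            "associate",
            {
                "alpha": alpha,
                "top_n": top_n,
                "candidates": candidates,
                "skipped_candidates": ranking.skipped_taxa,
                "gene_correlations": ranking.gene_correlations,
                "n_common_samples": align_report.n_common,
                "dropped_abundance_samples": align_report.dropped_abundance,
                "dropped_phenotype_samples": align_report.dropped_phenotype,
            },
            paths,
        )
        (tmp / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return Path(out_dir)


def run_all(
    out_dir: str | Path,
    config: CohortConfig | str | Path | None = None,
    seed: int = 0,
    k_range=range(2, 7),
    ps_threshold: float = 0.8,
    n_repeats: int = 20,
) -> Path:
    """simulate + enterotype + associate under one output directory."""
    out_dir = Path(out_dir)
    if config is None:
        config = default_config(seed=seed)
    elif not isinstance(config, CohortConfig):
        config = CohortConfig.from_yaml(config)
    with _AtomicDir(out_dir) as tmp:
        sim = run_simulate(config, tmp / "simulate")
        ent = run_enterotype(
            sim / "abundance.tsv",
            tmp / "enterotype",
            k_range=k_range,
            ps_threshold=ps_threshold,
            n_repeats=n_repeats,
            seed=seed,
        )
        run_association(
            sim / "abundance.tsv",
            sim / "phenotype.tsv",
            ent / "labels.tsv",
            tmp / "associate",
        )
        manifest = _manifest("all", {"seed": seed}, {})
        (tmp / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir
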
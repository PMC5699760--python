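"""End-to-end pipeline: simulate (optional) -> screen -> network -> enrich.

Mirrors the study design: the co-expression network is built on the genes
that survive the differential-expression screen, not on the whole matrix
(override with ``network_all_genes=True``). Every run writes a JSON manifest
recording parameters, seed, package/library versions, input checksums and
the stages completed, so identical configs reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .containers import GeneTable
from .diffexpr import run_screen
from .enrichment import GeneSetCollection, enrich_modules
from .network import build_network, export_edges, module_recovery
from .simulate import SyntheticDataset, generate_dataset, paper_mimic_preset

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "expression",
    "samples",
    "genes",
    "gene_sets",
    "simulate_preset",
    "p_max",
    "fc_min",
    "dmet_only",
    "beta",
    "select_beta",
    "target_fit",
    "n_bins",
    "cut_height",
    "cut_method",
    "cut_height_quantile",
    "min_module_size",
    "edge_threshold",
    "network_all_genes",
    "min_term_size",
    "seed",
    "verbosity",
}


@dataclass
class PipelineConfig:
    """All knobs of the `all` pipeline in one place."""

    # inputs (either files, or a simulation preset when expression is None)
    expression: str | None = None
    samples: str | None = None
    genes: str | None = None
    gene_sets: list[str] = field(default_factory=list)
    simulate_preset: bool = True
    # screening
    p_max: float = 0.05
    fc_min: float = 1.1
    dmet_only: bool = False
    # network
    beta: float | None = 6.0  # the study's choice; ignored when select_beta
    select_beta: bool = False  # sweep candidates for the target fit instead
    target_fit: float = 0.8
    n_bins: int = 10
    cut_height: float | None = None
    cut_method: str = "gap"
    cut_height_quantile: float = 0.98
    min_module_size: int = 30
    edge_threshold: float = 0.1
    network_all_genes: bool = False
    # enrichment
    min_term_size: int = 2
    # misc
    seed: int = 0
    verbosity: str = "info"

    def validate(self) -> None:
        if not 0.0 < self.p_max <= 1.0:
            raise ValueError("p_max must lie in (0, 1]")
        if self.fc_min < 1.0:
            raise ValueError("fc_min must be >= 1")
        if not 0.0 <= self.edge_threshold <= 1.0:
            raise ValueError("edge_threshold must lie in [0, 1]")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")
        if not 0.0 < self.cut_height_quantile <= 1.0:
            raise ValueError("cut_height_quantile must lie in (0, 1]")
        if self.expression is None and not self.simulate_preset:
            raise ValueError("either an expression file or simulate_preset is required")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_synthetic_dataset(dataset: SyntheticDataset, out_dir: Path) -> dict[str, Path]:
    """Write expression/sample/gene TSVs, with planted truth in the gene table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out_dir / "expression.tsv",
        "samples": out_dir / "samples.tsv",
        "genes": out_dir / "genes.tsv",
    }
    hio.write_expression_tsv(dataset.expression, paths["expression"])
    hio.write_sample_sheet(dataset.samples, paths["samples"])
    genes = dataset.genes
    truth = pd.DataFrame(
        {
            "truth_module": [dataset.truth_modules[g] for g in genes.gene_ids],
            "truth_fc": [dataset.truth_effects[g][0] for g in genes.gene_ids],
            "truth_bias": [dataset.truth_effects[g][1] for g in genes.gene_ids],
        }
    )
    annotated = GeneTable(
        genes.gene_ids, genes.symbols, genes.chromosomes, genes.is_dmet, extra=truth
    )
    hio.write_gene_table(annotated, paths["genes"])
    return paths


def truth_gene_sets(
    dataset: SyntheticDataset, n_decoys: int = 5, seed: int = 0
) -> GeneSetCollection:
    """Synthetic gene-set collection for exercising the enrichment stage.

    One term per planted module plus random decoy sets drawn from the whole
    gene universe; synthetic stand-in for a curated annotation collection.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 411]))
    sets: dict[str, set[str]] = {}
    universe = list(dataset.expression.gene_ids)
    for module in sorted(set(dataset.truth_modules.values()) - {"background"}):
        sets[f"planted_{module}"] = {
            g for g, m in dataset.truth_modules.items() if m == module
        }
    for i in range(n_decoys):
        size = int(rng.integers(20, 80))
        sets[f"decoy_{i + 1}"] = set(rng.choice(universe, size=size, replace=False))
    return GeneSetCollection("synthetic_truth", sets)


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Run every stage and write all artifacts plus a run manifest.

    Returns the manifest dict. Outputs are fully determined by
    (inputs, config, seed).
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "seed": config.seed,
        "versions": _versions(),
        "input_checksums": {},
        "stages": [],
        "outputs": {},
    }
    dataset: SyntheticDataset | None = None

    try:
        # ---- stage 1: obtain data (simulate or load)
        if config.expression is None:
            sim_config = paper_mimic_preset(seed=config.seed)
            dataset = generate_dataset(sim_config)
            paths = write_synthetic_dataset(dataset, out_dir / "simulated")
            matrix, samples, genes = dataset.expression, dataset.samples, dataset.genes
            manifest["stages"].append("simulate")
            manifest["outputs"]["simulated"] = {k: str(v) for k, v in paths.items()}
        else:
            matrix = hio.read_expression_tsv(config.expression)
            samples = hio.read_sample_sheet(config.samples)
            genes = hio.read_gene_table(config.genes) if config.genes else None
            for key in ("expression", "samples", "genes"):
                p = getattr(config, key)
                if p:
                    manifest["input_checksums"][key] = _sha256(Path(p))
            manifest["stages"].append("load")

        # ---- stage 2: differential-expression screen
        if config.dmet_only:
            if genes is None:
                raise ValueError("dmet_only requires a gene table")
            dmet_ids = [g for g, d in zip(genes.gene_ids, genes.is_dmet) if d]
            matrix_screen = matrix.subset_genes(dmet_ids)
        else:
            matrix_screen = matrix
        screened = run_screen(matrix_screen, samples, p_max=config.p_max, fc_min=config.fc_min)
        hio.write_screen_results(screened, out_dir / "screen.tsv")
        manifest["stages"].append("screen")
        manifest["outputs"]["screen"] = str(out_dir / "screen.tsv")
        manifest["n_screened"] = len(screened)

        # ---- stage 3: co-expression network on the screened genes
        if config.network_all_genes:
            net_matrix = matrix
        else:
            net_matrix = matrix.subset_genes([r.gene_id for r in screened])
        beta = None if config.select_beta else (config.beta or 6.0)
        net = build_network(
            net_matrix,
            beta=beta,
            target_fit=config.target_fit,
            n_bins=config.n_bins,
            cut_height=config.cut_height,
            cut_method=config.cut_method,
            cut_height_quantile=config.cut_height_quantile,
            min_module_size=config.min_module_size,
            keep_matrices=True,
        )
        hio.write_module_assignment(net.assignment, out_dir / "modules.tsv")
        hio.write_beta_diagnostics(net.fits, out_dir / "beta_diagnostics.tsv")
        hio.write_dendrogram(net.dendrogram, out_dir / "dendrogram.tsv")
        edges = export_edges(net.tom, config.edge_threshold)
        hio.write_edges_sif(edges, out_dir / "edges.sif")
        hio.write_edges_tsv(edges, out_dir / "edges.tsv")
        manifest["stages"].append("network")
        manifest["beta"] = net.beta
        manifest["n_modules"] = len(net.assignment.modules())
        manifest["outputs"]["network"] = {
            "modules": str(out_dir / "modules.tsv"),
            "beta_diagnostics": str(out_dir / "beta_diagnostics.tsv"),
            "dendrogram": str(out_dir / "dendrogram.tsv"),
            "edges_sif": str(out_dir / "edges.sif"),
            "edges_tsv": str(out_dir / "edges.tsv"),
        }
        if dataset is not None:
            truth = {
                g: dataset.truth_modules[g] for g in net.assignment.labels
            }
            manifest["module_recovery_ari"] = module_recovery(net.assignment, truth)

        # ---- stage 4: enrichment
        collections = [hio.read_gmt(p) for p in config.gene_sets]
        if not collections and dataset is not None:
            collections = [truth_gene_sets(dataset, seed=config.seed)]
        if collections:
            background = set(net_matrix.gene_ids)
            results = enrich_modules(
                net.assignment, collections, background, min_term_size=config.min_term_size
            )
            hio.write_enrichment_results(results, out_dir / "enrichment.tsv")
            manifest["stages"].append("enrich")
            manifest["outputs"]["enrichment"] = str(out_dir / "enrichment.tsv")
    except Exception:
        _write_manifest(manifest, out_dir)  # retain partial outputs + stage list
        raise
    _write_manifest(manifest, out_dir)
    return manifest


def _versions() -> dict[str, str]:
    import scipy
    import sklearn

    from . import __version__

    return {
        "hepatodimorph": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }


def _write_manifest(manifest: dict, out_dir: Path) -> None:
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
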
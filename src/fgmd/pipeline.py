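"""End-to-end pipeline: preprocessing → seeds → expansion → merge → split → validation.

The pipeline is deterministic given its configuration: the only stochastic
stage is the permutation test, which requires an explicit seed, and every
run writes a manifest with all resolved parameters (including the realized
seed and module correlation thresholds) from which the run can be
reproduced bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .corrnet import CorrelationMatrix, abs_pcc_matrix, top_quantile_threshold
from .expansion import ExpansionParams, expand_all_seed_pairs
from .expression_io import (
    ExpressionMatrix,
    read_expression_tsv,
    read_gene_list,
    read_gmt,
)
from .merge_split import (
    ModuleSet,
    filter_module_sizes,
    merge_similar_modules,
    split_all_large_modules,
    write_modules_tsv,
)
from .seeding import SeedParams, extract_seed_pairs
from .treecut import TreeCutParams
from .validation import (
    hypergeom_enrichment,
    module_summary,
    permutation_battery,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("fgmd")


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of a pipeline run.

    Quantile parameters are in "top percent" units as conventionally
    printed: ``S=0.005`` keeps the top 0.005% of gene pairs as seed
    candidates and ``M_percent=1.0`` sets the module threshold at the
    top-1% pair quantile.
    """

    # step 1: seeding
    S: float = 0.005
    D_min: int = 5
    D_max_percent: float = 0.1
    # step 2: expansion
    k: int = 10
    M_percent: float = 1.0
    expansion_degree_cap_percent: float | None = 0.1
    # steps 3-4: tree cut
    max_tree_height: float = 1.0
    deep_split: bool = True
    min_module_size: int = 50
    linkage_method: str = "average"
    extend_overlap: bool = False
    # module size filter
    feature_kind: str = "gene"  # "gene" (bounds 10-300) or "isoform" (10-500)
    size_min: int | None = None
    size_max: int | None = None
    # validation
    permutation_N: int = 1000
    seed: int | None = None
    gmt_paths: tuple[str, ...] = ()
    gene_list_paths: tuple[str, ...] = ()
    run_permutation: bool = False

    def size_bounds(self) -> tuple[int, int]:
        if self.size_min is not None and self.size_max is not None:
            return self.size_min, self.size_max
        lo = 10 if self.size_min is None else self.size_min
        hi = (500 if self.feature_kind == "isoform" else 300) if self.size_max is None else self.size_max
        return lo, hi


@dataclass
class PipelineResult:
    correlation: CorrelationMatrix
    seed_threshold: float
    module_threshold: float
    n_seed_pairs: int
    spe: ModuleSet
    large: ModuleSet
    fgmd: ModuleSet  # size-filtered final modules
    manifest: dict


def run_pipeline(
    expr: ExpressionMatrix,
    cfg: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full module-detection pipeline on an expression matrix.

    When ``out_dir`` is given, module exports for each stage, validation
    tables and the run manifest are written there; exports are byte-stable
    across reruns with identical configuration.
    """
    c = abs_pcc_matrix(expr, on_constant="drop")
    seed_params = SeedParams(S=cfg.S, D_min=cfg.D_min, D_max_percent=cfg.D_max_percent)
    seeds = extract_seed_pairs(c, seed_params)
    log.info("step 1: %d seed pairs over %d genes (threshold %.4f, D_max %d)",
             len(seeds.pairs), len(seeds.genes), seeds.seed_threshold, seeds.d_max)
    if not seeds.pairs:
        raise RuntimeError("step 1 produced no seed pairs; lower S or D_min")

    M = top_quantile_threshold(c, cfg.M_percent)
    exp_params = ExpansionParams(M=M, k=cfg.k)
    spe_modules = expand_all_seed_pairs(
        seeds, c, exp_params, d_max_percent=cfg.expansion_degree_cap_percent
    )
    spe = ModuleSet(tuple(spe_modules), "SPE")
    log.info("step 2: %d SPE modules (mean size %.1f, M=%.4f)",
             len(spe), float(np.mean([m.size for m in spe])), M)

    tc = TreeCutParams(
        max_tree_height=cfg.max_tree_height,
        deep_split=cfg.deep_split,
        min_module_size=cfg.min_module_size,
    )
    large = merge_similar_modules(spe, tc, cfg.linkage_method)
    log.info("step 3: %d large modules", len(large))

    fgmd_all = split_all_large_modules(
        large, c, tc, cfg.linkage_method, extend_overlap=cfg.extend_overlap
    )
    lo, hi = cfg.size_bounds()
    fgmd = filter_module_sizes(fgmd_all, lo, hi)
    log.info("step 4: %d final modules (%d before the %d-%d size filter)",
             len(fgmd), len(fgmd_all), lo, hi)

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "n_features": expr.n_features,
        "n_samples": expr.n_samples,
        "realized": {
            "seed_threshold": seeds.seed_threshold,
            "module_threshold": M,
            "d_max": seeds.d_max,
            "n_seed_pairs": len(seeds.pairs),
            "n_spe_modules": len(spe),
            "n_large_modules": len(large),
            "n_final_modules": len(fgmd),
        },
    }
    result = PipelineResult(
        correlation=c,
        seed_threshold=seeds.seed_threshold,
        module_threshold=M,
        n_seed_pairs=len(seeds.pairs),
        spe=spe,
        large=large,
        fgmd=fgmd,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(result, expr, cfg, Path(out_dir))
    return result


def _write_outputs(
    res: PipelineResult, expr: ExpressionMatrix, cfg: PipelineConfig, out: Path
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_modules_tsv(res.spe, out / "spe_modules.tsv")
    write_modules_tsv(res.large, out / "large_modules.tsv")
    write_modules_tsv(res.fgmd, out / "fgmd_modules.tsv")
    summary = module_summary(res.fgmd, res.correlation) if len(res.fgmd) else None
    with (out / "module_summary.tsv").open("w", encoding="utf-8") as fh:
        fh.write("n_modules\tmean_size\tn_unique_genes\tmean_occurrence\t"
                 "mean_in_module_pcc\tduplication_ratio\n")
        if summary:
            fh.write(f"{summary.n_modules}\t{summary.mean_size!r}\t"
                     f"{summary.n_unique_genes}\t{summary.mean_occurrence!r}\t"
                     f"{summary.mean_in_module_pcc!r}\t{summary.duplication_ratio!r}\n")

    if cfg.run_permutation and len(res.fgmd):
        if cfg.seed is None:
            raise ValueError("permutation validation requires a seed")
        perms = permutation_battery(
            res.fgmd, res.correlation, N=cfg.permutation_N, seed=cfg.seed
        )
        with (out / "permutation.tsv").open("w", encoding="utf-8") as fh:
            fh.write("module\tmodule_avg\tN\tp\tq\n")
            for r in perms:
                fh.write(f"{r.module}\t{r.module_avg!r}\t{r.N}\t{r.p!r}\t{r.q!r}\n")

    universe = res.correlation.ids
    for gmt_path in cfg.gmt_paths:
        coll = read_gmt(gmt_path, universe=universe)
        enr = hypergeom_enrichment(res.fgmd, coll, universe_size=len(universe))
        name = Path(gmt_path).stem
        with (out / f"enrichment_{name}.tsv").open("w", encoding="utf-8") as fh:
            fh.write("module\tcollection\tterm\toverlap\tmodule_size\tterm_size\tp\tq\n")
            for r in enr:
                fh.write(f"{r.module}\t{r.collection}\t{r.term}\t{r.overlap}\t"
                         f"{r.module_size}\t{r.term_size}\t{r.p!r}\t{r.q!r}\n")

    with (out / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(res.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
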
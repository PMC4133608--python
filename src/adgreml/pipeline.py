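"""End-to-end GREML/GBLUP runs: read inputs, build matrices, estimate
variance components, predict, and write the result tables."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io_formats as iof
from .engine_ce import CeEngine, GblupResult, SnpEffectTable
from .engine_qm import QmEngine
from .io_formats import GenotypeMatrix, MarkerMap, PhenotypeTable, RunConfig
from .model_matrices import GrmPair, ModelMatrices, build_model_matrices, compute_grm
from .reml_core import Heritabilities, RemlResult, hybrid_driver

__all__ = ["choose_method", "MethodChoice", "GremlRun", "run_greml", "run_gcorrmx", "run_from_config"]

log = logging.getLogger("adgreml")


@dataclass(frozen=True)
class MethodChoice:
    method: str   # ce | qm
    reason: str


def choose_method(q: int, m: int) -> MethodChoice:
    """Pick the cheaper engine: CE when markers dominate (2m > q), QM
    when individuals dominate, QM at the boundary q = 2m."""
    if q < 1 or m < 1:
        raise ValueError("q and m must be >= 1")
    if 2 * m > q:
        return MethodChoice("ce", f"2m = {2 * m} > q = {q}: record dimension is smaller")
    return MethodChoice("qm", f"q = {q} >= 2m = {2 * m}: marker dimension is smaller")


@dataclass
class GremlRun:
    """Everything one GREML run produces."""

    method: str
    reml: RemlResult
    heritabilities: Heritabilities
    gblup: GblupResult
    snp_table: SnpEffectTable | None
    model: ModelMatrices
    grm: GrmPair


def make_engine(method: str, mm: ModelMatrices, grm: GrmPair, y: np.ndarray):
    if method == "ce":
        return CeEngine(mm, grm, y)
    if method == "qm":
        return QmEngine(mm, grm, y)
    raise ValueError(f"unknown method '{method}'")


def run_greml(
    G: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    config: RunConfig | None = None,
    **overrides,
) -> GremlRun:
    """Run the full GREML -> GBLUP -> SNP-effect pipeline in memory."""
    if config is None:
        config = RunConfig(**overrides)
    mm = build_model_matrices(
        G, phenotypes,
        fixed_effects=config.fixed_effects,
        definition_id=config.grm_definition,
    )
    grm = compute_grm(mm.T_alpha, mm.T_delta, mm.definition_id)
    q, m = mm.n_individuals, mm.n_markers
    method = config.method
    if method == "auto":
        choice = choose_method(q, m)
        method = choice.method
        log.info("auto method: %s (%s)", choice.method, choice.reason)
    engine = make_engine(method, mm, grm, mm.y)
    reml = hybrid_driver(
        engine, mm.y,
        em_iterations=config.em_iterations,
        max_iterations=config.max_iterations,
        tolerance=config.tolerance,
        init=config.init_variances if config.init_variances != "auto" else "auto",
    )
    theta = reml.components.as_array()
    training = set(phenotypes.training_ids)
    gblup = engine.gblup(theta, training_ids=training)
    snp_table = None
    if config.emit_snp_effects:
        alpha_hat, delta_hat = engine.snp_effects(theta)
        snp_table = engine.snp_variances(
            theta, alpha_hat, delta_hat, reml.heritabilities.sigma2_p
        )
    return GremlRun(
        method=method, reml=reml, heritabilities=reml.heritabilities,
        gblup=gblup, snp_table=snp_table, model=mm, grm=grm,
    )


def write_outputs(run: GremlRun, config: RunConfig, marker_map: MarkerMap | None) -> list[Path]:
    prefix = config.output_prefix
    paths = []
    p = Path(f"{prefix}.greml.tsv")
    iof.write_greml_report(run.reml.records, run.reml.components, run.heritabilities, p)
    paths.append(p)
    p = Path(f"{prefix}.gblup.tsv")
    iof.write_gblup_table(run.gblup, p)
    paths.append(p)
    if run.snp_table is not None:
        p = Path(f"{prefix}.snpe.tsv")
        iof.write_snp_effect_table(run.snp_table, marker_map, p)
        paths.append(p)
    return paths


def run_gcorrmx(
    G: GenotypeMatrix,
    definition_id: int = 1,
    user_freqs: np.ndarray | None = None,
    maf_min: float = 0.0,
) -> tuple[GrmPair, list[str]]:
    """Relationship matrices only (no phenotypes, no REML)."""
    from .model_matrices import (
        allele_frequencies, build_T, impute_missing, additive_codes, dominance_codes,
    )

    p_all, keep = allele_frequencies(G, maf_min=maf_min)
    G_kept = G.subset_markers(keep)
    p = p_all[keep]
    dosages = impute_missing(G_kept, p)
    W = additive_codes(dosages, p)
    S = dominance_codes(dosages, p)
    uf = user_freqs[keep] if user_freqs is not None else None
    T_alpha, T_delta, _, _ = build_T(W, S, p, definition_id, dosages=dosages, user_freqs=uf)
    return compute_grm(T_alpha, T_delta, definition_id), list(G_kept.individual_ids)


def run_from_config(config: RunConfig, subcommand: str = "greml-auto") -> tuple[int, GremlRun | None]:
    """File-driven run, as the command-line front end executes it.

    Returns (exit_status, run): 0 on success, 3 when REML stopped at
    max_iterations without convergence (results are still written).
    Validation problems raise io_formats.ValidationError (exit 2 at the
    CLI level).
    """
    G = iof.read_genotypes(config.genotype_file, dialect=config.genotype_dialect)
    marker_map = iof.read_marker_map(config.map_file) if config.map_file else None
    if subcommand == "gcorrmx":
        grm, ids = run_gcorrmx(G, config.grm_definition)
        iof.write_grm_files(grm.A_g, grm.D_g, ids, grm.definition_id, config.output_prefix)
        return 0, None
    phen = iof.read_phenotypes(config.phenotype_file, config.trait, config.fixed_effects)
    method = {"greml-ce": "ce", "greml-qm": "qm", "greml-auto": "auto"}[subcommand]
    cfg = RunConfig(**{**config.__dict__, "method": method})
    run = run_greml(G, phen, cfg)
    for rec in run.reml.records:
        log.info(
            "iter %d [%s] sigma2_a=%.6g sigma2_d=%.6g sigma2_e=%.6g logL=%.10g conv=%.3g",
            rec.index, rec.algorithm, rec.theta.sigma2_a, rec.theta.sigma2_d,
            rec.theta.sigma2_e, rec.logL, rec.conv,
        )
    write_outputs(run, cfg, marker_map)
    if not run.reml.converged:
        log.warning("REML stopped at max_iterations without reaching the tolerance")
        return 3, run
    return 0, run
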
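"""End-to-end orchestration: simulate/ingest -> WLM -> harmonize -> pool -> dose -> cohorts.

``run_pipeline`` executes the stages in declared order from a single config
mapping, writes tab-delimited results (6 significant digits; full precision
is kept internally) and a reproducibility manifest.  Outputs are a pure
function of (inputs, config, seed); the manifest records digests so a re-run
can be verified byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .cohort_models import fit_snp_model, meta_across_cohorts, standardize_outcomes
from .dose_response import fit_weighted_slope
from .errors import ConfigError
from .harmonization import harmonize_pairs
from .snp_pooling import pool_fixed, pool_random, sd_to_grams
from .sumstats_io import join_instruments, write_sumstats
from .synthetic_data import (
    DEFAULT_COHORT_LABELS,
    DEFAULT_COHORT_SIZES,
    GenerativeConfig,
    adult_trait_instruments,
    duo_summary_stats,
    simulate_cohorts,
    simulate_duo_cohort,
)
from .wlm_partition import overlap_covariance, partition_table, wlm_to_sumstats

__all__ = ["run_pipeline", "default_config"]

log = logging.getLogger("duogenie")

_GENERATOR_KEYS = {f.name for f in dataclasses.fields(GenerativeConfig)}


def default_config() -> dict[str, Any]:
    """Demo configuration: a synthetic 14-SNP favorable-adiposity analysis."""
    return {
        "seed": 1,
        "generator": {"n_snps": 14, "proportionality_slope": 0.18},
        "gwas_n": 100_000,
        "cohort_sizes": list(DEFAULT_COHORT_SIZES),
        "cohort_labels": list(DEFAULT_COHORT_LABELS),
        "cohort_outcomes": ["birth_weight_g", "birth_length_cm", "head_circumference_cm"],
        "pooling_model": "random",
        "sd_grams": 484.0,
        "palindrome_freq_limit": 0.42,
        "palindromic_policy": "frequency",
        "wlm_overlap_r": 0.5,
    }


def _validate_config(config: Mapping[str, Any]) -> dict[str, Any]:
    merged = default_config()
    unknown = set(config) - set(merged)
    if unknown:
        raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
    merged.update(config)
    gen_unknown = set(merged["generator"]) - _GENERATOR_KEYS
    if gen_unknown:
        raise ConfigError(f"unknown generator config keys: {sorted(gen_unknown)}")
    if merged["pooling_model"] not in ("random", "fixed"):
        raise ConfigError(f"pooling_model must be 'random' or 'fixed'")
    if len(merged["cohort_sizes"]) != len(merged["cohort_labels"]):
        raise ConfigError("cohort_sizes and cohort_labels must have equal length")
    return merged


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Run the full synthetic analysis; returns the manifest mapping.

    Writes, under ``out_dir``: the simulated own/offspring GWAS tables, the
    maternal-adjusted fetal effects (``wlm_fetal.tsv``), harmonized pairs,
    the pooled per-allele effect in SD units and grams (``pooled.tsv``), the
    dose-response fit (``dose_response.tsv``), per-cohort and pooled
    individual-level associations, and ``manifest.json``.
    """
    cfg = _validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "seed": cfg["seed"],
        "config_digest": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "stages": {},
        "outputs": {},
    }

    gen_cfg = GenerativeConfig(**{**cfg["generator"], "seed": cfg["seed"]})

    # stage 1: GWAS-scale duo cohort and its two summary-stat tables
    log.info("[simulate] GWAS-scale cohort n=%d", cfg["gwas_n"])
    gwas_cohort = simulate_duo_cohort(
        dataclasses.replace(gen_cfg, n_individuals=int(cfg["gwas_n"])), label="gwas"
    )
    own, off = duo_summary_stats(gwas_cohort)
    write_sumstats(own, out / "own_bw_gwas.tsv")
    write_sumstats(off, out / "offspring_bw_gwas.tsv")
    manifest["stages"]["simulate_gwas"] = {"n_individuals": gwas_cohort.n, "n_snps": len(own)}

    # stage 2: maternal-adjusted fetal effects (the two GWAS share one sample,
    # so the WLM input covariance is r*se_own*se_off with r the duo correlation)
    log.info("[wlm] partitioning %d SNPs", len(own))
    estimates, missing = partition_table(own, off, cov_policy=overlap_covariance(cfg["wlm_overlap_r"]))
    fetal = wlm_to_sumstats(estimates, own, which="fetal")
    write_sumstats(fetal, out / "wlm_fetal.tsv")
    manifest["stages"]["wlm"] = {"n_snps": len(estimates), "missing": missing}

    # stage 3: join instruments to the adjusted outcome and harmonize
    instruments = adult_trait_instruments(gen_cfg)
    joined, missing_ids = join_instruments(instruments, fetal)
    pairs = harmonize_pairs(
        joined,
        palindrome_freq_limit=cfg["palindrome_freq_limit"],
        palindromic_policy=cfg["palindromic_policy"],
    )
    kept = [p for p in pairs if not p.dropped]
    _write_tsv(
        pd.DataFrame(
            {
                "SNP": [p.snp_id for p in pairs],
                "resolution": [p.resolution for p in pairs],
                "exposure_beta": [p.aligned_exposure_beta for p in pairs],
                "outcome_beta": [p.aligned_outcome_beta for p in pairs],
                "outcome_se": [p.outcome_se for p in pairs],
            }
        ),
        out / "harmonized_pairs.tsv",
    )
    manifest["stages"]["harmonize"] = {
        "n_pairs": len(pairs),
        "n_kept": len(kept),
        "missing_instruments": missing_ids,
    }

    # stage 4: pooled per-allele effect, SD units and grams
    pool = pool_random if cfg["pooling_model"] == "random" else pool_fixed
    pooled_sd = pool([(p.aligned_outcome_beta, p.outcome_se) for p in kept])
    pooled_g = sd_to_grams(pooled_sd, cfg["sd_grams"])
    _write_tsv(
        pd.DataFrame(
            [
                {"scale": "SD", **dataclasses.asdict(pooled_sd)},
                {"scale": "grams", **dataclasses.asdict(pooled_g)},
            ]
        ),
        out / "pooled.tsv",
    )
    manifest["stages"]["pool"] = {"k": pooled_sd.k, "model": pooled_sd.model}

    # stage 5: dose-response proportionality
    fit = fit_weighted_slope(
        [(p.aligned_exposure_beta, p.aligned_outcome_beta, p.outcome_se) for p in kept]
    )
    _write_tsv(pd.DataFrame([dataclasses.asdict(fit)]), out / "dose_response.tsv")
    manifest["stages"]["dose_response"] = {"k": fit.k}

    # stage 6: individual-level cohort analyses
    log.info("[cohorts] simulating %d cohorts", len(cfg["cohort_sizes"]))
    cohorts = [
        standardize_outcomes(c)
        for c in simulate_cohorts(gen_cfg, cfg["cohort_sizes"], cfg["cohort_labels"])
    ]
    assoc_rows: list[dict[str, Any]] = []
    pooled_rows: list[dict[str, Any]] = []
    for outcome in cfg["cohort_outcomes"]:
        per_snp_pooled = []
        for snp in cohorts[0].snp_ids:
            assocs = [fit_snp_model(c, snp, outcome) for c in cohorts]
            assoc_rows += [dataclasses.asdict(a) for a in assocs]
            pooled_assoc, het = meta_across_cohorts(assocs)
            pooled_rows.append(
                {**dataclasses.asdict(pooled_assoc), "q_stat": het.q_stat, "i2": het.i2}
            )
            per_snp_pooled.append((pooled_assoc.beta, pooled_assoc.se))
        across_snps = pool([(b, s) for b, s in per_snp_pooled])
        pooled_rows.append(
            {
                "cohort": "pooled",
                "snp_id": "ALL",
                "outcome": outcome,
                "beta": across_snps.estimate,
                "se": across_snps.se,
                "n_used": sum(c.n for c in cohorts),
                "q_stat": across_snps.q_stat,
                "i2": across_snps.i2,
            }
        )
    _write_tsv(pd.DataFrame(assoc_rows), out / "cohort_assocs.tsv")
    _write_tsv(pd.DataFrame(pooled_rows), out / "cohort_pooled.tsv")
    manifest["stages"]["cohorts"] = {
        "labels": cfg["cohort_labels"],
        "sizes": [c.n for c in cohorts],
        "outcomes": cfg["cohort_outcomes"],
    }

    for f in sorted(out.glob("*.tsv")):
        manifest["outputs"][f.name] = _digest(f)
    manifest["elapsed_s"] = round(time.time() - t0, 2)
    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("[done] %d outputs in %s", len(manifest["outputs"]), out)
    return manifest


def _configure_logging() -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
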
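"""End-to-end pipeline: simulate -> preprocess -> assoc -> pgain -> cluster
-> replicate -> survive, driven by one config with per-stage seeds derived
from a master seed, writing TSV artifacts and a run manifest."""
from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, preprocess, synthdata
from .assoc import fit_linear_assoc, scan_variant
from .cluster import build_pgain_matrix, hierarchical_cluster, normalize_per_locus
from .datatypes import TraitMatrix
from .errors import RatiomapError, ValidationError
from .pgain import compute_thresholds, count_discoveries, pair_pgains, select_lead
from .preprocess import TestId, phenotype
from .repsurv import (
    km_risk_by_group,
    median_split_groups,
    outcome_times,
    replication_power,
    replication_test,
)

ALL_STAGES = ("simulate", "preprocess", "assoc", "pgain", "cluster", "replicate", "survive")

# per-stage seed offsets derived from the master seed (documented scheme:
# seed_stage = master_seed * 1000 + offset)
_SEED_OFFSETS = {name: i for i, name in enumerate(ALL_STAGES)}


@dataclass
class RunConfig:
    """Single-document configuration for a full synthetic run."""

    outdir: str = "ratiomap_run"
    master_seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    # cohort
    n_samples: int = 2000
    n_traits: int = 20
    n_variants: int = 50
    lam: float = 0.5
    sigma_trait: float = 0.2
    sigma_confounder: float = 0.5
    na_rate: float = synthdata.DEFAULT_NA_RATE
    zero_rate: float = synthdata.DEFAULT_ZERO_RATE
    theta: float = 0.1
    # thresholds
    alpha_gw: float = 5e-8
    m_lipids: int = 5
    m_night: int | None = None
    gw_tests: float = 1e6
    # clustering
    cluster_metric: str = "euclidean"
    cluster_linkage: str = "average"
    # replication
    replication_fraction: float = 0.2
    n_sub: int | None = None
    n_reps: int = 20
    # survival
    horizon_years: float = 10.0
    baseline_rate: float = 0.005
    outcome_effect: float = -0.3
    prevalent_fraction: float = 0.02
    # optional external inputs (paths); when set, simulate is skipped for them
    traits_file: str | None = None
    genotypes_file: str | None = None
    covariates_file: str | None = None

    def stage_seed(self, stage: str) -> int:
        return self.master_seed * 1000 + _SEED_OFFSETS[stage]

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return RunConfig(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_config(config: RunConfig) -> list[str]:
    """All violations (not just the first); an empty list means valid."""
    issues = []
    if config.n_samples < 2:
        issues.append(f"n_samples must be >= 2, got {config.n_samples}")
    if config.n_traits < 2:
        issues.append(f"n_traits must be >= 2, got {config.n_traits}")
    if config.n_variants < 1:
        issues.append(f"n_variants must be >= 1, got {config.n_variants}")
    for name in ("na_rate", "zero_rate", "replication_fraction", "prevalent_fraction"):
        v = getattr(config, name)
        if not (0.0 <= v < 1.0):
            issues.append(f"{name} must be in [0, 1), got {v}")
    for name in ("sigma_trait", "sigma_confounder", "alpha_gw", "horizon_years", "baseline_rate"):
        v = getattr(config, name)
        if not (v > 0):
            issues.append(f"{name} must be positive, got {v}")
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        issues.append(f"unknown stages: {sorted(unknown)}")
    n_discovery = config.n_samples - int(round(config.replication_fraction * config.n_samples))
    if config.n_sub is not None and config.n_sub > n_discovery:
        issues.append(f"n_sub = {config.n_sub} exceeds discovery size {n_discovery}")
    if config.n_reps < 1:
        issues.append(f"n_reps must be >= 1, got {config.n_reps}")
    for name in ("traits_file", "genotypes_file", "covariates_file"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            issues.append(f"{name} does not exist: {p}")
    return issues


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest.

    The manifest (config echo, library versions, output checksums,
    per-stage wall times, warnings) is written even on partial failure,
    with the failure point recorded and downstream stages skipped.
    """
    issues = validate_config(config)
    if issues:
        raise ValidationError("; ".join(issues))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "versions": {
            "ratiomap": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "outputs": {},
        "warnings": [],
        "failure": None,
    }

    state: dict = {}
    enabled = [s for s in ALL_STAGES if s in config.stages]
    try:
        for stage in enabled:
            t0 = time.perf_counter()
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                _STAGE_FUNCS[stage](config, state, outdir, manifest)
            manifest["warnings"].extend(f"{stage}: {w.message}" for w in caught)
            manifest["stages"][stage] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
            }
    except RatiomapError as exc:
        manifest["failure"] = {"stage": stage, "error": str(exc)}
        manifest["stages"][stage] = {"status": "failed"}
    finally:
        for path in sorted(outdir.glob("*.tsv")):
            manifest["outputs"][path.name] = io.sha256_file(path)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, state: dict, outdir: Path, manifest: dict) -> None:
    seed = config.stage_seed("simulate")
    trait_names = [f"T{i + 1}" for i in range(config.n_traits)]
    specs = synthdata.default_variant_specs(
        config.n_variants, trait_names, seed=seed, theta=config.theta
    )
    geno = synthdata.simulate_genotypes(config.n_samples, specs, seed=seed + 1)
    cc = synthdata.CohortConfig(
        n_samples=config.n_samples,
        n_traits=config.n_traits,
        lam=config.lam,
        sigma_trait=config.sigma_trait,
        sigma_confounder=config.sigma_confounder,
        na_rate=config.na_rate,
        zero_rate=config.zero_rate,
        seed=seed + 2,
        trait_names=trait_names,
    )
    traits, covariates, truth = synthdata.simulate_cohort(geno, specs, cc)
    traits = synthdata.inject_missingness(traits, config.na_rate, config.zero_rate, seed=seed + 3)
    outcomes = synthdata.simulate_outcomes(
        config.n_samples,
        risk_covariate=np.log(traits.data[trait_names[0]].fillna(traits.data[trait_names[0]].median())
                              .clip(lower=1e-12)).to_numpy(),
        effect=config.outcome_effect,
        baseline_rate=config.baseline_rate,
        horizon_years=config.horizon_years,
        prevalent_fraction=config.prevalent_fraction,
        seed=seed + 4,
        medication=covariates["medication"].to_numpy(),
    )
    io.write_genotypes(geno, outdir / "genotypes.tsv")
    io.write_trait_matrix(traits, outdir / "traits_raw.tsv")
    io.write_table(covariates, outdir / "covariates.tsv")
    io.write_table(truth.effects, outdir / "truth_effects.tsv", index=False)
    io.write_table(outcomes, outdir / "outcomes.tsv")
    state.update(geno=geno, traits_raw=traits, covariates=covariates, truth=truth,
                 outcomes=outcomes, specs=specs, trait_names=trait_names)


def _load_external(config: RunConfig, state: dict) -> None:
    if "traits_raw" not in state and config.traits_file:
        state["traits_raw"] = io.read_trait_matrix(config.traits_file)
    if "geno" not in state and config.genotypes_file:
        state["geno"] = io.read_genotypes(config.genotypes_file)
    if "covariates" not in state and config.covariates_file:
        state["covariates"] = io.read_table(config.covariates_file)


def _stage_preprocess(config: RunConfig, state: dict, outdir: Path, manifest: dict) -> None:
    _load_external(config, state)
    if "traits_raw" not in state:
        raise ValidationError("preprocess needs simulated or file-provided traits")
    cleaned = preprocess.zeros_to_missing(state["traits_raw"])
    logged = preprocess.log_transform(cleaned)
    io.write_trait_matrix(logged, outdir / "traits_log.tsv")
    state["traits_log"] = logged


def _covariate_design(state: dict):
    cov = state.get("covariates")
    if cov is None:
        return None
    keep = [c for c in ("age", "age2", "sex", "medication") if c in cov.columns]
    return cov[keep]


def _stage_assoc(config: RunConfig, state: dict, outdir: Path, manifest: dict) -> None:
    logged: TraitMatrix = state["traits_log"]
    tests = preprocess.enumerate_tests(logged.trait_ids)
    geno = state["geno"]
    cov = _covariate_design(state)
    # hold out the replication split before the discovery scan
    n = logged.n_samples
    n_rep = int(round(config.replication_fraction * n))
    rng = np.random.default_rng(config.stage_seed("assoc"))
    rep_idx = rng.choice(n, size=n_rep, replace=False) if n_rep else np.array([], dtype=int)
    rep_mask = np.zeros(n, dtype=bool)
    rep_mask[rep_idx] = True
    state["rep_mask"] = rep_mask
    disc = TraitMatrix(logged.data.loc[~rep_mask], logged.stage)
    cov_disc = None if cov is None else cov.loc[~rep_mask]
    results = []
    for vid in geno.variant_ids:
        results.extend(
            scan_variant(vid, geno.dosage(vid)[~rep_mask], tests, disc, cov_disc)
        )
    io.write_table(io.results_to_frame(results), outdir / "assoc.tsv", index=False)
    state.update(assoc_results=results, tests=tests)


def _stage_pgain(config: RunConfig, state: dict, outdir: Path, manifest: dict) -> None:
    thresholds = compute_thresholds(
        config.alpha_gw, config.m_lipids, config.n_traits, config.m_night, gw_tests=config.gw_tests
    )
    records = pair_pgains(state["assoc_results"], thresholds)
    io.write_table(io.pgains_to_frame(records), outdir / "pgain.tsv", index=False)
    by_variant: dict[str, list] = {}
    for r in state["assoc_results"]:
        by_variant.setdefault(r.variant, []).append(r)
    pg_by_variant: dict[str, list] = {}
    for r in records:
        pg_by_variant.setdefault(r.variant, []).append(r)
    flag_rows = {}
    leads = {}
    for vid, res in by_variant.items():
        singles = [r for r in res if r.test.kind == "single"]
        lead_nmr = select_lead(singles, thresholds, "nmr")
        lead_all = select_lead(res, thresholds, "all_ratios")
        lead_pg = select_lead(pg_by_variant.get(vid, []), thresholds, "all_ratios")
        flag_rows[vid] = {
            "sig_ref": lead_nmr.significant,  # synthetic runs have no five-lipid family
            "sig_nmr": lead_nmr.significant,
            "sig_ratio": lead_all.significant,
            "sig_pgain": lead_pg.lead_pgain is not None,
        }
        leads[vid] = lead_all
    flags = pd.DataFrame.from_dict(flag_rows, orient="index")
    summary = count_discoveries(flags)
    io.write_table(flags, outdir / "flags.tsv")
    (outdir / "discovery_summary.json").write_text(
        json.dumps({"counts": dataclasses.asdict(summary),
                    "percentages": summary.percentages(),
                    "thresholds": thresholds.display()}, indent=2) + "\n"
    )
    state.update(thresholds=thresholds, pgain_records=records, flags=flags, leads=leads)


def _stage_cluster(config: RunConfig, state: dict, outdir: Path, manifest: dict) -> None:
    matrix = build_pgain_matrix(state["pgain_records"], state["thresholds"])
    if matrix.data.empty:
        manifest["warnings"].append("cluster: empty p-gain matrix; stage skipped")
        return
    norm = normalize_per_locus(matrix)
    io.write_table(norm.data, outdir / "pgain_matrix.tsv")
    result = hierarchical_cluster(norm, config.cluster_metric, config.cluster_linkage)
    order = pd.DataFrame(
        {
            "axis": ["rows"] * len(result.row_order) + ["cols"] * len(result.col_order),
            "position": list(range(len(result.row_order))) + list(range(len(result.col_order))),
            "label": [result.row_labels[i] for i in result.row_order]
            + [result.col_labels[i] for i in result.col_order],
        }
    )
    io.write_table(order, outdir / "cluster_order.tsv", index=False)
    if result.row_linkage is not None:
        (outdir / "rows.nwk").write_text(result.newick("rows") + "\n")
    if result.col_linkage is not None:
        (outdir / "cols.nwk").write_text(result.newick("cols") + "\n")
    state["cluster"] = result


def _stage_replicate(config: RunConfig, state: dict, outdir: Path, manifest: dict) -> None:
    logged: TraitMatrix = state["traits_log"]
    rep_mask = state["rep_mask"]
    geno = state["geno"]
    cov = _covariate_design(state)
    thresholds = state["thresholds"]
    discovered = {
        vid: sel.lead
        for vid, sel in state["leads"].items()
        if sel.significant and sel.lead is not None
    }
    if not discovered:
        manifest["warnings"].append("replicate: no discovered loci; stage skipped")
        return
    n_disc = len(discovered)
    rep_traits = TraitMatrix(logged.data.loc[rep_mask], logged.stage)
    cov_rep = None if cov is None else cov.loc[rep_mask]
    rep_results = {}
    for vid, lead in discovered.items():
        try:
            y = phenotype(rep_traits, lead.test)
            rep_results[vid] = fit_linear_assoc(
                y, geno.dosage(vid)[rep_mask], cov_rep, variant=vid, test=lead.test
            )
        except RatiomapError:
            continue
    results = replication_test(rep_results, discovered, n_disc)
    disc_traits = TraitMatrix(logged.data.loc[~rep_mask], logged.stage)
    cov_disc = None if cov is None else cov.loc[~rep_mask].to_numpy()
    n_sub = config.n_sub or min(int(rep_mask.sum()) or 1, disc_traits.n_samples)
    import math as _math

    power = replication_power(
        disc_traits,
        synthdata.GenotypeMatrix(geno.data.loc[~rep_mask]),
        cov_disc,
        [(vid, lead.test) for vid, lead in discovered.items()],
        n_sub=n_sub,
        threshold_neglog10=-_math.log10(0.05 / n_disc),
        n_reps=config.n_reps,
        seed=config.stage_seed("replicate"),
    )
    for r in results:
        if r.locus in power.index:
            r.power = float(power.loc[r.locus, "power"])
            r.n_subsamples = int(power.loc[r.locus, "n_subsamples"])
    frame = pd.DataFrame(
        {
            "locus": [r.locus for r in results],
            "discovery_neglog10_p": [r.discovery_neglog10_p for r in results],
            "replication_neglog10_p": [r.replication_neglog10_p for r in results],
            "threshold_neglog10": [r.threshold_neglog10 for r in results],
            "replicated": [r.replicated for r in results],
            "power": [r.power for r in results],
        }
    ).set_index("locus")
    io.write_table(frame, outdir / "replication.tsv")
    state["replication"] = results


def _stage_survive(config: RunConfig, state: dict, outdir: Path, manifest: dict) -> None:
    outcomes = state.get("outcomes")
    if outcomes is None:
        manifest["warnings"].append("survive: no outcome table; stage skipped")
        return
    traits: TraitMatrix = state["traits_log"]
    trait = traits.trait_ids[0]
    times, events, prevalent = outcome_times(outcomes, config.horizon_years)
    groups = median_split_groups(
        traits.data[trait].to_numpy(),
        outcomes["medication"].to_numpy().astype(bool),
        exclusions=prevalent,
    )
    estimates = km_risk_by_group(times, events, groups, config.horizon_years)
    frame = pd.DataFrame(
        {
            "group": list(estimates),
            "n_at_risk": [e.n_at_risk for e in estimates.values()],
            "events": [e.events for e in estimates.values()],
            "risk": [e.risk for e in estimates.values()],
            "ci_low": [e.ci95[0] for e in estimates.values()],
            "ci_high": [e.ci95[1] for e in estimates.values()],
        }
    ).set_index("group")
    io.write_table(frame, outdir / "survival.tsv")
    state["survival"] = estimates


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "assoc": _stage_assoc,
    "pgain": _stage_pgain,
    "cluster": _stage_cluster,
    "replicate": _stage_replicate,
    "survive": _stage_survive,
}
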
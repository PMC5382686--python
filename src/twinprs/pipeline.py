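"""End-to-end orchestration: simulate -> fit twin model -> cross-trait PRS.

``run_pipeline`` executes the full desk-scale analysis from a single flat
JSON-style configuration (every stochastic stage seeded from ``seed``),
writes a machine-readable ``results.json`` and a human-readable
``report.txt``, and is byte-deterministic for a fixed configuration.  It can
be invoked from a shell as ``python -m twinprs.pipeline --config cfg.json``.
"""

from __future__ import annotations

import argparse
import dataclasses
import json
import logging
import sys
from pathlib import Path

import numpy as np

from . import __version__, ace, io, prs, simulate

logger = logging.getLogger(__name__)

#: configuration keys and their defaults (None = required)
CONFIG_SCHEMA = {
    "seed": None,
    "out_dir": None,
    # twin stage: reported bivariate fit used as the generator truth
    "components_trait1": [0.85, 0.005, 0.15],
    "components_trait2": [0.47, 0.13, 0.40],
    "r_a": -0.143,
    "target_rp": -0.116,
    "n_mz": 2000,
    "n_dz": 2000,
    "ci_method": "none",  # none | profile | bootstrap
    # genotype stage
    "n_discovery": 1500,
    "n_target": 800,
    "m_snps": 600,
    "block_size": 10,
    "within_block_r": 0.7,
    "maf_range": [0.05, 0.5],
    "n_causal_1": 120,
    "n_causal_2": 120,
    "prop_shared": 0.5,
    "h2_1": 0.4,
    "h2_2": 0.4,
    "clump_r2_max": 0.25,
    "clump_window_kb": 200.0,
    "clump_maf_min": 0.03,
    "thresholds": list(prs.STANDARD_THRESHOLDS),
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


def _twin_stage(cfg: dict, rng_seeds: dict, out: Path) -> dict:
    truth = simulate.calibrate_generator(
        *cfg["components_trait1"], *cfg["components_trait2"],
        r_a=cfg["r_a"], target_rp=cfg["target_rp"])
    data = simulate.simulate_twin_dataset(
        truth, cfg["n_mz"], cfg["n_dz"], seed=rng_seeds["twins"])
    io.write_twin_csv(data, out / "twin_phenotypes.csv")
    fit = ace.fit_bivariate_ace(data)
    comps = fit.components
    shared = comps.shared_genetic_effect()
    rp = ace.phenotypic_correlation(data)
    result = {
        "truth": dataclasses.asdict(truth),
        "n_mz": cfg["n_mz"], "n_dz": cfg["n_dz"],
        "minus2ll": fit.minus2ll,
        "converged": fit.converged,
        "components": comps.as_dict(),
        "shared_genetic_effect": shared,
        "phenotypic_correlation": rp,
        "proportion_rp_genetic": ace.proportion_of_rp_genetic(shared, rp),
        "boundary_flags": fit.boundary_flags,
    }
    if cfg["ci_method"] != "none":
        ci = ace.confidence_intervals(fit, data, method=cfg["ci_method"],
                                      options={"seed": rng_seeds["ci"]})
        result["confidence_intervals"] = ci.to_dict(orient="records")
    return result


def _prs_stage(cfg: dict, rng_seeds: dict, out: Path) -> dict:
    panel_all = simulate.simulate_genotype_panel(
        cfg["n_discovery"] + cfg["n_target"], cfg["m_snps"],
        cfg["block_size"], cfg["within_block_r"],
        tuple(cfg["maf_range"]), seed=rng_seeds["panel"])
    design = simulate.PleiotropyDesign(
        n_causal_1=cfg["n_causal_1"], n_causal_2=cfg["n_causal_2"],
        prop_shared=cfg["prop_shared"], h2_1=cfg["h2_1"], h2_2=cfg["h2_2"],
        seed=rng_seeds["traits"])
    y1, y2, _truth = simulate.simulate_pleiotropic_traits(panel_all, design)
    disc = np.arange(cfg["n_discovery"])
    targ = np.arange(cfg["n_discovery"], panel_all.n)
    discovery = panel_all.subset_individuals(disc)
    target = panel_all.subset_individuals(targ)

    summary = simulate.simulate_gwas_summary(discovery, y1[disc])
    summary = summary[~summary["zero_variance"]]
    io.write_gwas_tsv(summary, out / "gwas_trait1.tsv")

    harmonized = prs.align_alleles(summary, target)
    config = prs.ClumpConfig(cfg["clump_r2_max"], cfg["clump_window_kb"],
                             cfg["clump_maf_min"])
    retained = prs.ld_clump(harmonized, target, config)
    scores, counts = prs.build_scores(target, harmonized, retained,
                                      tuple(cfg["thresholds"]))
    pcs = prs.compute_pcs(target, k=2)
    rng = np.random.default_rng(rng_seeds["covariates"])
    covariates = {
        "age": rng.uniform(14, 18, size=target.n),
        "sex": rng.integers(0, 2, size=target.n).astype(float),
        "PC1": pcs[:, 0], "PC2": pcs[:, 1],
    }
    assoc = prs.prs_association(scores, y2[targ], covariates, counts)
    assoc.to_csv(out / "prs_trait1_score_vs_trait2.tsv", sep="\t",
                 index=False, float_format="%.12g")
    return {
        "n_discovery": cfg["n_discovery"], "n_target": cfg["n_target"],
        "m_snps": cfg["m_snps"], "n_clumped": len(retained),
        "snp_counts": {str(k): v for k, v in counts.items()},
        "associations": assoc.drop(columns=["flagged"]).to_dict(orient="records"),
        "best_threshold": assoc.attrs["best_threshold"],
        "multiple_testing_correction": assoc.attrs["multiple_testing_correction"],
    }


def run_pipeline(config: dict) -> dict:
    """Run the whole analysis; returns the result bundle written to
    ``<out_dir>/results.json``.  Any stage failure removes partial outputs
    and re-raises tagged with the stage name."""
    cfg = dict(CONFIG_SCHEMA)
    unknown = set(config) - set(cfg)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(config)
    required = [k for k, v in cfg.items() if v is None]
    if required:
        raise ValueError(f"missing required config keys: {required}")

    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg["seed"])
    child_names = ["twins", "ci", "panel", "traits", "covariates"]
    rng_seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
                 for name, s in zip(child_names, ss.spawn(len(child_names)))}

    # out_dir is a filesystem detail, not an analysis setting; omitting it
    # keeps results.json byte-identical across output locations
    results = {"config": {k: cfg[k] for k in sorted(cfg) if k != "out_dir"},
               "package_version": __version__}
    written: list[Path] = []
    try:
        for stage_name, stage in (("twin-model", _twin_stage),
                                  ("prs", _prs_stage)):
            logger.info("running stage %s", stage_name)
            before = set(out.iterdir())
            results[stage_name.replace("-", "_")] = stage(cfg, rng_seeds, out)
            written.extend(set(out.iterdir()) - before)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise StageError(f"[{stage_name}] {exc}") from exc

    results_path = out / "results.json"
    results_path.write_text(json.dumps(results, indent=2, sort_keys=True,
                                       allow_nan=False, default=float) + "\n")
    _write_report(results, out / "report.txt")
    return results


def _write_report(results: dict, path: Path) -> None:
    tw = results["twin_model"]
    c = tw["components"]
    lines = [
        "Twin-model and cross-trait polygenic score analysis",
        f"(twinprs {results['package_version']}, seed {results['config']['seed']})",
        "",
        f"Bivariate ACE fit on {tw['n_mz']} MZ + {tw['n_dz']} DZ simulated pairs:",
        f"  trait 1 (refractive error): A={c['A1']:.3f} C={c['C1']:.3f} E={c['E1']:.3f}",
        f"  trait 2 (IQ):               A={c['A2']:.3f} C={c['C2']:.3f} E={c['E2']:.3f}",
        f"  genetic correlation rA = {c['r_a']:.3f}",
        f"  phenotypic correlation rP = {tw['phenotypic_correlation']:.3f}",
        f"  shared genetic effect sqrt(A1)*rA*sqrt(A2) = {tw['shared_genetic_effect']:.3f}",
        f"  proportion of rP genetic = {tw['proportion_rp_genetic']:.1%}",
        "",
    ]
    pr = results["prs"]
    lines += [
        f"Cross-trait PRS ({pr['n_clumped']} clumped SNPs of {pr['m_snps']}):",
        "  threshold  n_snps  incremental_r2  p",
    ]
    for row in pr["associations"]:
        lines.append(f"  {row['threshold']:<9g}  {row['n_snps']:>5d}  "
                     f"{row['incremental_r2']:.4f}         {row['p_value']:.3g}")
    lines.append(f"  best threshold: {pr['best_threshold']:g} "
                 f"({pr['multiple_testing_correction']})")
    path.write_text("\n".join(lines) + "\n")


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(
        description="Run the twin-model + PRS analysis pipeline")
    parser.add_argument("--config", required=True, help="JSON config file")
    parser.add_argument("--seed", type=int, help="override config seed")
    parser.add_argument("--out-dir", help="override config output directory")
    args = parser.parse_args(argv)
    logging.basicConfig(level=logging.INFO,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    cfg = io.load_config(args.config, CONFIG_SCHEMA)
    if args.seed is not None:
        cfg["seed"] = args.seed
    if args.out_dir is not None:
        cfg["out_dir"] = args.out_dir
    try:
        run_pipeline(cfg)
    except StageError as exc:
        logger.error("%s", exc)
        return 1
    return 0


if __name__ == "__main__":
    sys.exit(main())
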
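"""End-to-end orchestration of the analysis stages.

Stage order: simulate (or load) -> describe -> confounders -> per-marker
screen (keratin-rich and keratin-poor panels separately) -> residualize ->
SIR with dimension and coordinate tests -> optional signature scoring. Every
run writes a manifest (config snapshot, seeds, file digests, per-stage
row/cluster counts, thresholds) sufficient to reproduce it bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort_stats import describe_cohort
from .config import GeneratorConfig
from .confounders import DEFAULT_CONFOUNDERS, select_confounders
from .io import (file_digest, read_yaml, write_cohort, write_generator_sidecar,
                 write_json, write_rois)
from .regression import (bonferroni_flag, fit_marker_tslb, residualize,
                         residual_correlations, results_to_frame)
from .signature import SignatureDefinition, correlate_with_score, sig_score
from .sir import (coordinate_results_to_frame, coordinate_test, fit_sir,
                  marginal_dimension_test, slice_assignments)
from .synthetic import (generate_cohort, generate_expression_matrix,
                        generate_roi_markers)

__all__ = ["run_pipeline", "verify_manifest", "IntegrityError"]

logger = logging.getLogger(__name__)

SEGMENTS = {"rich": ("keratin_rich", 53), "poor": ("keratin_poor", 48)}


class IntegrityError(RuntimeError):
    """An input file no longer matches the digest recorded in a manifest."""


def _generator_config(cfg: dict, seed: int, p_markers: int) -> GeneratorConfig:
    fields = {f.name for f in dataclasses.fields(GeneratorConfig)}
    overrides = {k: v for k, v in cfg.get("generator", {}).items() if k in fields}
    return GeneratorConfig(seed=seed, p_markers=p_markers, **overrides)


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> Path:
    """Execute the full pipeline per a config dict or YAML path.

    Recognized config keys (all optional): ``seed``, ``generator`` (overrides
    for :class:`GeneratorConfig`), ``alpha``, ``n_boot``,
    ``include_nulliparous``, ``stratify_subtype``, ``score`` (mapping with
    ``signature`` TSV path and ``n_samples``). Returns the output directory;
    any stage failure propagates with the stage named in the log.
    """
    cfg = read_yaml(config) if not isinstance(config, dict) else dict(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 20260109))
    alpha = float(cfg.get("alpha", 0.05))
    n_boot = int(cfg.get("n_boot", 300))
    manifest: dict = {
        "ppbc_version": __version__, "config": cfg, "seed": seed,
        "thresholds": {"alpha": alpha, "n_boot": n_boot},
        "stages": {}, "digests": {},
    }

    def record(name: str, path: Path):
        manifest["digests"][name] = {"path": path.name,
                                     "sha256": file_digest(path)}

    logger.info("stage simulate")
    gen_rich = _generator_config(cfg, seed, SEGMENTS["rich"][1])
    cohort = generate_cohort(gen_rich)
    record("cohort", write_cohort(cohort, outdir / "cohort.csv"))
    record("generator_config",
           write_generator_sidecar(gen_rich, outdir / "generator_config.yaml"))
    rois = {}
    for offset, (seg, (seg_label, p)) in enumerate(SEGMENTS.items()):
        g = _generator_config(cfg, seed, p)
        rois[seg] = generate_roi_markers(cohort, g, seed=seed + 101 * (offset + 1),
                                         segment=seg_label)
        record(f"rois_{seg}", write_rois(rois[seg], outdir / f"rois_{seg}.csv"))
    manifest["stages"]["simulate"] = {
        "n_women": int(len(cohort)),
        "n_parous": int(cohort["parous"].sum()),
        **{f"n_roi_{s}": int(len(r)) for s, r in rois.items()},
    }

    logger.info("stage describe")
    desc = describe_cohort(cohort[cohort["parous"]], by="subtype")
    desc.to_csv(outdir / "describe.tsv", sep="\t", index=False)
    record("describe", outdir / "describe.tsv")

    logger.info("stage confounders")
    conf = select_confounders(
        cohort, candidates=cfg.get("candidates", DEFAULT_CONFOUNDERS),
        forced=cfg.get("forced", ["bmi"]), alpha=alpha,
    )
    record("confounders", write_json(conf.to_dict(), outdir / "confounders.json"))
    manifest["stages"]["confounders"] = {"selected": conf.selected}

    for seg in SEGMENTS:
        logger.info("stage screen (%s)", seg)
        screen = bonferroni_flag(fit_marker_tslb(rois[seg], cohort, conf), alpha)
        frame = results_to_frame(screen)
        frame.to_csv(outdir / f"screen_{seg}.tsv", sep="\t", index=False)
        record(f"screen_{seg}", outdir / f"screen_{seg}.tsv")
        manifest["stages"][f"screen_{seg}"] = {
            "m": len(screen), "bonferroni_level": alpha / max(len(screen), 1),
            "n_roi": int(frame["n_roi"].iloc[0]),
            "n_women": int(frame["n_women"].iloc[0]),
        }

        logger.info("stage residualize + sir (%s)", seg)
        res = residualize(rois[seg], cohort, conf,
                          parous_only=not cfg.get("include_nulliparous", False))
        res.to_csv(outdir / f"residuals_{seg}.csv", index=False,
                   float_format="%.10g")
        record(f"residuals_{seg}", outdir / f"residuals_{seg}.csv")
        corr = residual_correlations(res)
        slices = slice_assignments(res, cohort)
        sir = marginal_dimension_test(fit_sir(res, slices), alpha)
        d = max(sir.dimension or 0, 1)
        coords = coordinate_test(res, slices, d=d, n_boot=n_boot,
                                 seed=seed + 7, alpha=alpha)
        write_json({
            "slice_labels": [str(s) for s in sir.slice_labels],
            "slice_weights": sir.slice_weights,
            "kernel_eigenvalues": sir.kernel_eigenvalues,
            "dimension": sir.dimension,
            "dimension_pvalues": sir.dimension_pvalues,
            "n_obs": sir.n_obs,
            "residual_correlation_range": [corr.attrs["min_offdiag"],
                                           corr.attrs["max_offdiag"]],
        }, outdir / f"sir_{seg}.json")
        record(f"sir_{seg}", outdir / f"sir_{seg}.json")
        coordinate_results_to_frame(coords).to_csv(
            outdir / f"coordinate_{seg}.tsv", sep="\t", index=False)
        record(f"coordinate_{seg}", outdir / f"coordinate_{seg}.tsv")
        manifest["stages"][f"sir_{seg}"] = {
            "dimension": sir.dimension, "n_obs": sir.n_obs, "d_tested": d,
        }

    if cfg.get("score"):
        logger.info("stage score")
        sc = cfg["score"]
        sig = SignatureDefinition.from_tsv(sc["signature"])
        expr = generate_expression_matrix(int(sc.get("n_samples", 200)), sig,
                                          gen_rich, seed=seed + 13)
        table = sig_score(expr, sig)
        table.scores.to_csv(outdir / "score.tsv", sep="\t",
                            index_label="sample_id")
        record("score", outdir / "score.tsv")
        corr = correlate_with_score(expr[table.genes_used], table)
        corr.to_csv(outdir / "score_correlations.tsv", sep="\t", index=False)
        record("score_correlations", outdir / "score_correlations.tsv")
        manifest["stages"]["score"] = {"n_samples": int(len(expr)),
                                       "genes_used": table.genes_used}

    write_json(manifest, outdir / "manifest.json")
    return outdir


def verify_manifest(manifest_path: str | Path) -> dict:
    """Recompute digests of every file a manifest records.

    Returns the manifest when all digests match; raises
    :class:`IntegrityError` with a per-file diff otherwise.
    """
    import json

    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    base = manifest_path.parent
    bad = {}
    for name, rec in manifest.get("digests", {}).items():
        path = base / rec["path"]
        actual = file_digest(path) if path.exists() else "<missing>"
        if actual != rec["sha256"]:
            bad[name] = {"expected": rec["sha256"], "actual": actual,
                         "path": str(path)}
    if bad:
        diff = "\n".join(f"  {k}: expected {v['expected'][:12]}…, "
                         f"got {v['actual'][:12]}… ({v['path']})"
                         for k, v in bad.items())
        raise IntegrityError(f"manifest digests do not match:\n{diff}")
    return manifest
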
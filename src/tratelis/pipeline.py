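"""End-to-end orchestration: normalize → TRA → DE → promoters → TFBM.

Driven by a declarative YAML config (paths + parameters); every stage
writes its own TSV/JSON under ``out_dir`` and the run ends with a summary
table (one row per gene set and per motif: fold change, direction, p) plus
a JSON echo of the exact parameters, seed and package version, so a run is
auditable. Any stage error aborts the run with the stage name; an
``INCOMPLETE`` marker is left next to partial outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .de import adjusted_log2fc, select_de_genes, write_de_selection
from .expression import cpm_normalize, log2_transform, read_counts_table, write_matrix
from .motif import PromoterWindow, extract_promoters, parse_motif_matrices
from .telis import VariantGrid, telis_analysis
from .tra import read_signed_gene_sets, tra_analysis, zscore_genes

logger = logging.getLogger("tratelis")

REQUIRED_KEYS = ("counts", "annotations", "out_dir")
DEFAULTS = {
    "pseudocount": 1.0,
    "fold_threshold": 2.0,
    "min_cpm": None,
    "covariates": [],
    "reference": None,
    "both_strands": True,
    "grid_windows": [[300, 0], [600, 0], [1000, 200]],
    "grid_thresholds": [0.80, 0.90, 0.95],
    "seed": 0,
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    merged = {**DEFAULTS, **cfg}
    for key in REQUIRED_KEYS:
        if key not in merged:
            raise ValueError(f"config missing required key {key!r}")
    if merged["fold_threshold"] <= 1:
        raise ValueError("fold_threshold must be > 1")
    wants_telis = bool(merged.get("motifs"))
    if wants_telis:
        for key in ("genome", "tss_bed"):
            if not merged.get(key):
                raise ValueError(f"config missing key {key!r} (required for TFBM analysis)")
    for key in ("counts", "annotations", "gene_sets", "genome", "tss_bed", "motifs"):
        p = merged.get(key)
        if p and not Path(p).exists():
            raise FileNotFoundError(f"config key {key!r}: no such file {p}")
    return merged


def _grid_from_config(cfg: dict) -> VariantGrid:
    windows = tuple(PromoterWindow(int(u), int(d)) for u, d in cfg["grid_windows"])
    return VariantGrid(windows=windows, thresholds=tuple(cfg["grid_thresholds"]))


def run_pipeline(cfg: dict) -> pd.DataFrame:
    """Run all configured stages; returns the summary table."""
    cfg = validate_config(cfg)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "INCOMPLETE"
    marker.write_text("run in progress\n")

    log_path = out / "run_log.json"
    echo = {k: v for k, v in cfg.items() if not isinstance(v, (bytes,))}
    echo["version"] = __version__
    log_path.write_text(json.dumps(echo, indent=1, default=str))

    summary_rows = []
    stage = "normalize"
    try:
        m = read_counts_table(cfg["counts"], cfg["annotations"])
        cpm = cpm_normalize(m, min_cpm=cfg["min_cpm"])
        log2 = log2_transform(cpm, pseudocount=cfg["pseudocount"])
        write_matrix(log2, out / "log2cpm.tsv")
        _z, const_genes = zscore_genes(log2)
        covs = list(cfg["covariates"])
        ref = cfg["reference"]

        if cfg.get("gene_sets"):
            stage = "tra"
            sets = read_signed_gene_sets(cfg["gene_sets"])
            score_rows, set_rows = [], []
            for s in sets:
                res = tra_analysis(log2, s, covariates=covs, reference=ref)
                set_rows.append({
                    "set": s.name, "adjusted_diff": res.adjusted_diff,
                    "log2_diff": res.log2_diff, "fold_change": res.fold_change,
                    "direction": res.direction, "p_value": res.p_value,
                    "n_genes_used": res.n_genes_used, "coverage": res.coverage,
                })
                for sample, score in res.scores.items():
                    score_rows.append({"set": s.name, "sample": sample, "score": score})
                summary_rows.append({
                    "analysis": "TRA", "name": s.name,
                    "fold_change": res.fold_change, "direction": res.direction,
                    "p_value": res.p_value,
                })
            pd.DataFrame(score_rows).to_csv(out / "tra_scores.tsv", sep="\t", index=False)
            pd.DataFrame(set_rows).to_csv(out / "tra_summary.tsv", sep="\t", index=False)

        stage = "de"
        l2fc = adjusted_log2fc(log2, covariates=covs, reference=ref)
        sel = select_de_genes(l2fc, cfg["fold_threshold"], exclude=const_genes)
        write_de_selection(sel, out / "de")
        logger.info("DE at >%g-fold: %d up, %d down", cfg["fold_threshold"],
                    len(sel.up_genes), len(sel.down_genes))

        if cfg.get("motifs"):
            stage = "telis"
            grid = _grid_from_config(cfg)
            pwms = parse_motif_matrices(cfg["motifs"])
            for pwm in pwms:
                res = telis_analysis(
                    sel.up_genes, sel.down_genes, cfg["tss_bed"], cfg["genome"],
                    pwm, grid=grid, both_strands=cfg["both_strands"],
                )
                payload = {
                    "motif_id": res.motif_id,
                    "mean_log2_ratio": res.mean_log2_ratio,
                    "fold_change": res.fold_change,
                    "direction": res.direction,
                    "t_statistic": res.t_statistic,
                    "p_value": res.p_value,
                    "df": res.df,
                    "variants": [
                        {"window": v.window.label, "threshold": v.threshold,
                         "prevalence_up": v.prevalence_up,
                         "prevalence_dn": v.prevalence_dn, "ratio": v.ratio,
                         "continuity_corrected": v.continuity_corrected}
                        for v in res.variants
                    ],
                }
                safe = res.motif_id.replace("$", "_").replace("/", "_")
                (out / f"telis_{safe}.json").write_text(
                    json.dumps(payload, indent=1))
                summary_rows.append({
                    "analysis": "TFBM", "name": res.motif_id,
                    "fold_change": res.fold_change, "direction": res.direction,
                    "p_value": res.p_value,
                })
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = pd.DataFrame(
        summary_rows, columns=["analysis", "name", "fold_change", "direction", "p_value"]
    )
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    marker.unlink()
    return summary
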
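"""Pipeline driver: simulate -> explore -> screen/contrast -> tf/ora.

Chains the library stages under a single :class:`PipelineConfig`; every
output TSV carries a provenance comment (tool version, seed, config
hash) and the resolved configuration is written next to the outputs,
so a run can be reproduced byte-for-byte from its output directory.
"""

from __future__ import annotations

import importlib.resources
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig, config_hash, resolved_yaml
from .contrasts import ContrastSpec, paired_lfc, paired_test
from .enrich import ora, read_gmt
from .io import (
    read_counts_tsv,
    read_metadata_tsv,
    write_counts_tsv,
    write_metadata_tsv,
    write_table_tsv,
)
from .preprocess import (
    filter_low_expression,
    normalize_log,
    pca_top_variable,
    size_factors_median_of_ratios,
)
from .screen import screen
from .synthetic import SimParams, default_design, simulate_counts
from .tf import read_network, ulm_activity

__all__ = ["run_pipeline", "toy_network_path", "toy_gmt_path"]

log = logging.getLogger("radscreen")


def toy_network_path() -> Path:
    """Bundled synthetic toy regulon network (tests/demos only)."""
    return Path(importlib.resources.files("radscreen.data") / "toy_synthetic_network.tsv")


def toy_gmt_path() -> Path:
    """Bundled synthetic toy gene-set collection (tests/demos only)."""
    return Path(importlib.resources.files("radscreen.data") / "toy_synthetic_sets.gmt")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(config: PipelineConfig, out_dir) -> dict[str, Path]:
    """Run the configured stages, writing all outputs under ``out_dir``.

    Returns a map stage/artifact name -> written path.  A failing stage
    raises :class:`StageError` naming it.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = f"radscreen {__version__} seed={config.seed} config={config_hash(config)}"
    (out / "config.resolved.yaml").write_text(resolved_yaml(config), encoding="utf-8")
    written: dict[str, Path] = {"config": out / "config.resolved.yaml"}

    def _stage(name):
        def deco(fn):
            if name not in config.stages:
                log.info("stage %s: skipped", name)
                return None
            log.info("stage %s: running", name)
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return deco

    # --- inputs -----------------------------------------------------
    if config.counts_path and config.meta_path:
        counts = read_counts_tsv(config.counts_path)
        design = read_metadata_tsv(config.meta_path)
        truth = None
    else:
        @_stage("simulate")
        def _sim():
            design = default_design()
            params = SimParams(n_genes=config.n_genes, seed=config.seed)
            counts, truth = simulate_counts(design, params)
            write_counts_tsv(counts, out / "counts.tsv", provenance)
            write_metadata_tsv(design, out / "meta.tsv", provenance)
            write_table_tsv(truth, out / "truth.tsv", provenance, index_label="gene")
            return counts, design, truth
        if _sim is None:
            raise StageError(
                "no counts/meta paths given and the simulate stage is disabled"
            )
        counts, design, truth = _sim
        written["counts"] = out / "counts.tsv"
        written["meta"] = out / "meta.tsv"
        written["truth"] = out / "truth.tsv"

    kept = filter_low_expression(counts, min_mean=config.min_mean)
    sf = size_factors_median_of_ratios(kept)
    expr = normalize_log(kept, sf, pseudocount=config.pseudocount)

    @_stage("pca")
    def _pca():
        res = pca_top_variable(expr, n_top=config.n_top)
        scores = res.scores
        write_table_tsv(scores, out / "pca_scores.tsv", provenance, index_label="sample_id")
        vr = pd.DataFrame(
            {"component": scores.columns, "variance_ratio": res.variance_ratio}
        ).set_index("component")
        write_table_tsv(vr, out / "pca_variance.tsv", provenance, index_label="component")
        return res
    if _pca is not None:
        written["pca_scores"] = out / "pca_scores.tsv"
        written["pca_variance"] = out / "pca_variance.tsv"

    @_stage("screen")
    def _screen():
        table = screen(
            counts,
            design,
            config.screen_time_h,
            alpha=config.alpha,
            conf=config.conf,
            include_between=config.include_between,
            min_mean=config.min_mean,
            pseudocount=config.pseudocount,
        )
        write_table_tsv(table, out / "screen.tsv", provenance, index_label="gene")
        return table
    if _screen is not None:
        written["screen"] = out / "screen.tsv"

    @_stage("contrast")
    def _contrast():
        spec = ContrastSpec(num=config.contrast_num, den=config.contrast_den)
        res = paired_test(
            paired_lfc(expr, design, spec),
            moderation=config.moderation,
            prior_df=config.prior_df,
        )
        write_table_tsv(res, out / "contrast.tsv", provenance, index_label="gene")
        return res
    if _contrast is not None:
        written["contrast"] = out / "contrast.tsv"

    contrast_res = _contrast

    @_stage("tf")
    def _tf():
        if contrast_res is None:
            raise ValueError("tf stage needs the contrast stage")
        net = read_network(config.network_path or toy_network_path())
        res = ulm_activity(contrast_res["t"], net, min_targets=config.min_targets)
        write_table_tsv(res, out / "tf.tsv", provenance, index_label="tf")
        return res
    if _tf is not None:
        written["tf"] = out / "tf.tsv"

    @_stage("ora")
    def _ora():
        if contrast_res is None:
            raise ValueError("ora stage needs the contrast stage")
        sets = read_gmt(config.gmt_path or toy_gmt_path())
        degs = contrast_res.index[contrast_res["q"] < config.alpha].tolist()
        universe = expr.index.tolist()
        if not degs:
            log.warning("ora: no DEGs at q < %s; writing empty table", config.alpha)
            res = pd.DataFrame(columns=["set", "K", "n", "k", "N", "p", "q", "genes"])
        else:
            res = ora(
                degs,
                sets,
                universe,
                min_k=config.ora_min_k,
                set_size_bounds=config.ora_set_size_bounds,
            )
        write_table_tsv(res.set_index("set") if len(res) else res, out / "ora.tsv",
                        provenance, index_label="set")
        return res
    if _ora is not None:
        written["ora"] = out / "ora.tsv"

    log.info("pipeline complete: %d artifact(s) in %s", len(written), out)
    return written
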
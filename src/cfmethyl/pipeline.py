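"""Reproducible end-to-end orchestration of the analysis stages.

A single YAML config (one block per stage, every parameter defaulting to
the package defaults) drives: synthetic-data generation or ingestion ->
DML testing -> DMR calling -> annotation & enrichment -> concordance ->
deconvolution -> metagene profiling. Each stage writes TSV outputs and
the run writes a JSON manifest recording parameters, seed, row counts,
and a sha256 per output, so reruns can be verified byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as _annotate
from . import concordance as _concord
from . import deconvolve as _deconv
from . import dml as _dml
from . import dmr as _dmr
from . import metagene as _metagene
from . import simulate as _sim
from .io import write_bed_annotation, write_bismark_cov, write_marker_panel

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "DEFAULTS"]

DEFAULTS: dict = {
    "seed": 0,
    "outdir": "cfmethyl_out",
    "stages": ["simulate", "dml", "dmr", "annotate", "enrich", "concord", "deconv", "metagene"],
    "simulate": {
        "chrom_sizes": {"chr1": 1_000_000, "chr2": 1_000_000},
        "mean_spacing": 100,
        "n_per_group": [5, 5],
        "baseline_mean": 0.83,
        "dispersion": 0.05,
        "coverage_mean": 30,
        "n_planted": 10,
        "planted_delta": 0.25,
        "planted_len": 1000,
        "n_genes": 40,
    },
    "dml": {"window_bp": 500, "prior_weight": 1.0, "fdr_threshold": 0.05},
    "dmr": {"p_threshold": 0.05, "delta": 0.1, "min_len": 50, "min_cg": 4,
            "merge_dist": 100, "pct_sig": 0.5},
    "concord": {"concordant_fraction": 0.8, "significant_fraction": 0.1},
    "deconv": {"n_type1": 140, "n_type2": 360, "noise_sd": 0.02, "tau1": 0.2, "tau2": 0.1},
    "metagene": {"flank": 10_000, "n_body": 100, "n_flank": 100},
}


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline configuration (defaults merged in)."""

    config: dict

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        return cls.from_dict(user)

    @classmethod
    def from_dict(cls, user: dict) -> "PipelineConfig":
        cfg = json.loads(json.dumps(DEFAULTS))  # deep copy
        for key, val in user.items():
            if key in cfg and isinstance(cfg[key], dict) and isinstance(val, dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
        obj = cls(cfg)
        obj.validate()
        return obj

    def validate(self) -> None:
        c = self.config
        if c["dmr"]["delta"] < 0:
            raise ValueError("invalid config value for 'delta': must be >= 0")
        if not (0 < c["simulate"]["baseline_mean"] < 1):
            raise ValueError("invalid config value for 'baseline_mean': must be in (0, 1)")
        if not (0 <= c["simulate"]["dispersion"] < 1):
            raise ValueError("invalid config value for 'dispersion': must be in [0, 1)")
        if c["dml"]["window_bp"] < 0:
            raise ValueError("invalid config value for 'window_bp': must be >= 0")
        unknown = set(c["stages"]) - set(DEFAULTS["stages"])
        if unknown:
            raise ValueError(f"invalid config value for 'stages': unknown {sorted(unknown)}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.config, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def run_pipeline(config: PipelineConfig | dict, outdir: str | Path | None = None) -> dict:
    """Execute the configured stages in order; returns the manifest."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_dict(config)
    cfg = config.config
    seed = int(cfg["seed"])
    out = Path(outdir or cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]
    manifest: dict = {"seed": seed, "parameters": cfg, "outputs": {}, "timing_s": {}}

    def record(name: str, path: Path, n_rows: int | None = None) -> None:
        manifest["outputs"][name] = {
            "path": str(path), "sha256": _sha256(path),
            **({"n_rows": n_rows} if n_rows is not None else {}),
        }

    state: dict = {}
    try:
        for stage in stages:
            t0 = time.perf_counter()
            logger.info("stage %s", stage)
            globals()[f"_stage_{stage}"](cfg, seed, out, state, record)
            manifest["timing_s"][stage] = round(time.perf_counter() - t0, 3)
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _stage_simulate(cfg, seed, out, state, record):
    sc = cfg["simulate"]
    spec = _sim.GenomeSpec.random(sc["chrom_sizes"], sc["mean_spacing"], seed=seed)
    rng = np.random.default_rng(seed + 1)
    planted = []
    chroms = sorted(sc["chrom_sizes"])
    for i in range(sc["n_planted"]):
        c = chroms[i % len(chroms)]
        size = sc["chrom_sizes"][c]
        s = int(rng.integers(10_000, size - 10_000 - sc["planted_len"]))
        if any(d.chrom == c and d.start < s + sc["planted_len"] and s < d.end + 2000
               for d in planted):
            continue
        planted.append(_sim.PlantedDMR(c, s, s + sc["planted_len"],
                                       sc["planted_delta"] * (-1) ** i))
    counts, truth = _sim.simulate_methylome(
        spec, tuple(sc["n_per_group"]), planted, sc["baseline_mean"],
        sc["dispersion"], sc["coverage_mean"], seed=seed,
    )
    ann, gene_df = _sim.make_annotation_fixture(spec, sc["n_genes"], seed=seed + 2)
    state.update(spec=spec, counts=counts, truth=truth, ann=ann, genes=gene_df)
    for s in counts.samples:
        p = out / f"{s}.cov"
        write_bismark_cov(counts, p, sample=s)
        record(f"coverage/{s}", p)
    write_bed_annotation(ann, out / "annotation.bed")
    record("annotation", out / "annotation.bed")
    truth_df = pd.DataFrame(
        [(d.chrom, d.start, d.end, d.delta, d.direction) for d in truth.planted],
        columns=["chrom", "start", "end", "delta", "direction"],
    )
    _write_tsv(truth_df, out / "truth_dmrs.tsv")
    record("truth", out / "truth_dmrs.tsv", len(truth_df))


def _stage_dml(cfg, seed, out, state, record):
    dc = cfg["dml"]
    sm = _dml.smooth_means(state["counts"], window_bp=dc["window_bp"])
    phi = _dml.estimate_dispersion(state["counts"], sm, prior_weight=dc["prior_weight"])
    dml = _dml.dml_wald_test(state["counts"], sm, phi)
    state["dml"] = dml
    _write_tsv(dml, out / "dml.tsv")
    record("dml", out / "dml.tsv", len(dml))
    sig = _dml.call_dml(dml, dc["fdr_threshold"])
    _write_tsv(sig, out / "dml_significant.tsv")
    record("dml_significant", out / "dml_significant.tsv", len(sig))


def _stage_dmr(cfg, seed, out, state, record):
    rc = cfg["dmr"]
    dmrs = _dmr.call_dmr(state["dml"], rc["p_threshold"], rc["delta"], rc["min_len"],
                         rc["min_cg"], rc["merge_dist"], rc["pct_sig"])
    state["dmrs"] = dmrs
    _write_tsv(dmrs, out / "dmr.tsv")
    record("dmr", out / "dmr.tsv", len(dmrs))
    mat = _dmr.region_methylation_matrix(state["counts"], dmrs)
    _write_tsv(mat, out / "dmr_methylation.tsv", index=True)
    record("dmr_methylation", out / "dmr_methylation.tsv", len(mat))


def _stage_annotate(cfg, seed, out, state, record):
    assignments = _annotate.annotate_regions(state["dmrs"], state["ann"])
    _write_tsv(assignments, out / "dmr_annotation.tsv")
    record("dmr_annotation", out / "dmr_annotation.tsv", len(assignments))
    ctx = _annotate.classify_cgi_context(
        state["dmrs"].rename(columns={"start": "pos"})[["chrom", "pos"]], state["ann"]
    )
    pd.DataFrame({"region": state["dmrs"].index, "cgi_context": ctx}).to_csv(
        out / "dmr_cgi_context.tsv", sep="\t", index=False
    )
    record("dmr_cgi_context", out / "dmr_cgi_context.tsv", len(ctx))


def _stage_enrich(cfg, seed, out, state, record):
    enr = _annotate.fold_enrichment(state["dmrs"], state["ann"], state["spec"])
    _write_tsv(enr, out / "dmr_enrichment.tsv")
    record("dmr_enrichment", out / "dmr_enrichment.tsv", len(enr))


def _stage_concord(cfg, seed, out, state, record):
    cc = cfg["concord"]
    dml = state["dml"]
    ext = _sim.simulate_external_summary(
        dml, cc["concordant_fraction"], cc["significant_fraction"], seed=seed + 3
    )
    sig = dml["pval"] < 0.05
    table, fisher = _concord.direction_concordance(
        np.where(dml.loc[sig, "diff"] >= 0, 1, -1),
        ext.loc[sig.to_numpy(), "direction"].to_numpy(),
    )
    summary = {
        "global_methylation": _concord.weighted_global_methylation(state["counts"]),
        "direction_concordance": {
            "table": table.to_array().tolist(),
            "odds_ratio": fisher.odds_ratio,
            "pvalue": fisher.pvalue,
        },
    }
    with open(out / "concordance.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    record("concordance", out / "concordance.json")
    state["concordance"] = summary


def _stage_deconv(cfg, seed, out, state, record):
    vc = cfg["deconv"]
    panel = _sim.synthetic_reference_panel(vc["n_type1"], vc["n_type2"], seed=seed + 4)
    panel.marker_class = _deconv.select_markers(panel, vc["tau1"], vc["tau2"])
    write_marker_panel(panel, out / "reference_panel.tsv")
    record("reference_panel", out / "reference_panel.tsv", panel.n_markers)
    rng = np.random.default_rng(seed + 5)
    samples = state["counts"].samples
    groups = state["counts"].groups
    truths = rng.dirichlet(np.ones(len(panel.tissues)), size=len(samples))
    rows = []
    for i, s in enumerate(samples):
        obs = _sim.simulate_mixture(panel, truths[i], noise_sd=vc["noise_sd"],
                                    seed=int(rng.integers(2**31)))
        est = _deconv.deconvolve_qp(panel, obs)
        rows.append(est.proportions.rename(s))
    props = pd.DataFrame(rows)
    _write_tsv(props, out / "tissue_proportions.tsv", index=True)
    record("tissue_proportions", out / "tissue_proportions.tsv", len(props))
    comparison = _deconv.compare_proportions(props, groups)
    _write_tsv(comparison, out / "tissue_comparison.tsv")
    record("tissue_comparison", out / "tissue_comparison.tsv", len(comparison))
    state["proportions"] = props


def _stage_metagene(cfg, seed, out, state, record):
    mc = cfg["metagene"]
    counts = state["counts"]
    frac = counts.meth.sum(axis=1) / np.maximum(counts.total.sum(axis=1), 1)
    track = pd.Series(
        frac, index=pd.MultiIndex.from_arrays([counts.chrom.astype(str), counts.pos],
                                              names=["chrom", "pos"]),
    )
    prof = _metagene.metagene_profile(track, state["genes"], mc["flank"],
                                      mc["n_body"], mc["n_flank"])
    _write_tsv(prof.to_frame(), out / "metagene.tsv")
    record("metagene", out / "metagene.tsv", len(prof.values))
    state["metagene"] = prof
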
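"""End-to-end orchestration: cohort -> sites -> DMRs -> DE -> map -> network.

One :class:`PipelineConfig` (loadable from YAML) drives the whole chain,
either on a synthetic cohort generated in-process or on a bundle
directory of real input files with the same layout.  Every stage writes
its artifact under the output directory, filter funnel counts are
logged, and a ``summary.json`` collects site counts, DMR counts by
direction, DE counts by direction, candidate-pair counts, the network
summary and — when ground truth is available — planted-triplet
precision/recall.  Identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import clinical, expression, methylation, network, regulatory_map, synth
from .errors import ConfigError, PipelineError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds and inputs of one pipeline run.

    Exactly one of ``synth`` (generate a cohort) or ``input_dir`` (load a
    written bundle) must be set.  Defaults encode the screening criteria
    of the study design this package implements: site depth >= 5 at
    P <= 0.05, window Fisher DMRs at P <= 0.05 / Q <= 0.05, miRNA screen
    |log2FC| >= 1 with P < 0.05 and Q <= 0.05, mRNA screen P < 0.05 and
    Q <= 0.05, Pearson edge retention.
    """

    outdir: str = "methmirnet_run"
    seed: int | None = None
    synth: synth.SynthConfig | None = None
    input_dir: str | None = None
    # site calling
    depth_min: int = 5
    p0: float = 0.005
    site_p_max: float = 0.05
    # DMR detection
    window_bp: int = 1000
    step_bp: int = 100
    min_cpgs: int = 3
    min_mean_diff: float = 0.1
    dmr_p_max: float = 0.05
    dmr_q_max: float = 0.05
    coverage_mode: str = "pooled"
    dmr_test: str = "fisher"
    # differential expression
    mirna_preset: str = "mirna"
    mrna_preset: str = "mrna"
    pseudocount: float = 1.0
    # mapping
    upstream_bp: int = 2000
    seed_type: str = "7mer-m8"
    target_map: str | None = None
    # network
    r_min: float = 0.7
    edge_p_max: float = 0.05
    strict: bool = True
    corr_method: str = "pearson"
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.synth is None) == (self.input_dir is None):
            raise ConfigError(
                "synth/input_dir", "exactly one of synth or input_dir must be set"
            )
        if self.synth is not None and self.seed is not None:
            self.synth = dataclasses.replace(self.synth, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "synth" in data and data["synth"] is not None:
            data["synth"] = synth.SynthConfig(**data["synth"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def run(config: PipelineConfig) -> dict:
    """Execute the full pipeline; return (and write) the run manifest.

    Any stage error aborts the run with a :class:`PipelineError` naming
    the stage; partial outputs are retained next to a FAILED marker.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    summary: dict = {}
    manifest: dict = {"config": config.to_dict(), "outputs": {}}
    stage = "load"

    def _fail(exc: Exception):
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(stage, str(exc)) from exc

    try:
        # ---- load / generate -------------------------------------------
        if config.synth is not None:
            bundle = synth.generate_cohort(config.synth)
            synth.write_bundle(bundle, outdir / "bundle")
            manifest["outputs"]["bundle"] = str(outdir / "bundle")
        else:
            bundle = synth.read_bundle(config.input_dir)
        samples = list(bundle.samples["sample_id"])
        summary["n_samples"] = {
            "case": len(bundle.case_samples), "control": len(bundle.control_samples)
        }

        # ---- site calling ----------------------------------------------
        stage = "callmeth"
        called = {}
        for s in samples:
            calls = methylation.call_sites(
                bundle.cpg, s, p0=config.p0,
                depth_min=config.depth_min, p_max=config.site_p_max,
            )
            called[s] = int(calls["is_called"].sum())
        summary["sites"] = {"n_sites": len(bundle.cpg), "called_per_sample": called}
        pd.DataFrame(
            {"sample_id": list(called), "n_called": list(called.values())}
        ).to_csv(outdir / "site_calls.tsv", sep="\t", index=False)
        manifest["outputs"]["site_calls"] = str(outdir / "site_calls.tsv")
        logger.info("site calling: %d sites, called per sample: %s", len(bundle.cpg), called)

        # ---- DMR detection ---------------------------------------------
        stage = "dmr"
        dmrs = methylation.detect_dmrs(
            bundle.cpg_group_table("case"), bundle.cpg_group_table("control"),
            window_bp=config.window_bp, step_bp=config.step_bp,
            min_cpgs=config.min_cpgs, min_mean_diff=config.min_mean_diff,
            p_max=config.dmr_p_max, q_max=config.dmr_q_max,
            depth_min=config.depth_min, coverage_mode=config.coverage_mode,
            test=config.dmr_test,
        )
        methylation.write_dmrs(dmrs, outdir / "dmrs.bed")
        manifest["outputs"]["dmrs"] = str(outdir / "dmrs.bed")
        summary["dmrs"] = {
            "total": len(dmrs),
            "hyper": sum(d.direction == "hyper" for d in dmrs),
            "hypo": sum(d.direction == "hypo" for d in dmrs),
        }
        logger.info("DMRs: %s", summary["dmrs"])

        # ---- differential expression -----------------------------------
        stage = "de"
        groups = bundle.groups
        mirna_rpm = expression.rpm_normalize(bundle.mirna_counts)
        lengths = bundle.mrna_annotation.set_index("mrna_id")["exon_length_bp"]
        mrna_rpkm = expression.rpkm_normalize(bundle.mrna_counts, lengths)
        de_mirna = expression.de_screen(
            mirna_rpm, groups, pseudocount=config.pseudocount,
            **expression.DE_PRESETS[config.mirna_preset],
        )
        de_mrna = expression.de_screen(
            mrna_rpkm, groups, pseudocount=config.pseudocount,
            **expression.DE_PRESETS[config.mrna_preset],
        )
        de_mirna.to_csv(outdir / "de_mirna.tsv", sep="\t")
        de_mrna.to_csv(outdir / "de_mrna.tsv", sep="\t")
        manifest["outputs"]["de_mirna"] = str(outdir / "de_mirna.tsv")
        manifest["outputs"]["de_mrna"] = str(outdir / "de_mrna.tsv")

        def _de_counts(t):
            return {
                "tested": len(t),
                "up": int((t["status"] == "up").sum()),
                "down": int((t["status"] == "down").sum()),
            }

        summary["de_mirna"] = _de_counts(de_mirna)
        summary["de_mrna"] = _de_counts(de_mrna)
        logger.info("DE miRNA: %s; DE mRNA: %s", summary["de_mirna"], summary["de_mrna"])

        # ---- regulatory mapping ----------------------------------------
        stage = "map"
        promoters = regulatory_map.promoters_from_annotation(
            bundle.mirna_annotation, bundle.chrom_lengths, config.upstream_bp
        )
        promoter_pairs = regulatory_map.overlap_dmr_promoters(dmrs, promoters)
        if config.target_map:
            target_pairs = regulatory_map.load_target_map(config.target_map)
        else:
            target_pairs = regulatory_map.predict_targets(
                bundle.mirna_sequences, bundle.utr_sequences, config.seed_type
            )
        regulatory_map.write_target_pairs(target_pairs, outdir / "target_pairs.tsv")
        pd.DataFrame(
            [
                {"dmr": f"{d.chrom}:{d.start}-{d.end}", "mirna_id": mid}
                for d, mid in promoter_pairs
            ],
            columns=["dmr", "mirna_id"],
        ).to_csv(outdir / "promoter_pairs.tsv", sep="\t", index=False)
        manifest["outputs"]["promoter_pairs"] = str(outdir / "promoter_pairs.tsv")
        manifest["outputs"]["target_pairs"] = str(outdir / "target_pairs.tsv")
        summary["pairs"] = {
            "promoter_pairs": len(promoter_pairs),
            "target_pairs": len(target_pairs),
        }
        logger.info("mapping: %s", summary["pairs"])

        # ---- network ----------------------------------------------------
        stage = "build-network"
        dmr_levels = methylation.dmr_methylation_levels(dmrs, bundle.cpg, samples)
        net = network.build_network(
            dmrs, de_mirna, de_mrna, promoter_pairs, target_pairs,
            dmr_levels, mirna_rpm, mrna_rpkm,
            r_min=config.r_min, p_max=config.edge_p_max,
            strict=config.strict, method=config.corr_method,
        )
        network.export_network(net, outdir, formats=("tsv", "graphml"))
        manifest["outputs"]["network"] = str(outdir / "network.graphml")
        summary["network"] = network.summarize_network(net)
        if bundle.truth is not None and bundle.truth.triplets:
            summary["recovery"] = network.recovery_metrics(net, bundle.truth)
            logger.info("recovery: %s", summary["recovery"])

        # ---- clinical stats --------------------------------------------
        stage = "clinstats"
        if bundle.truth is not None and bundle.truth.triplets:
            t = bundle.truth.triplets[0]
            feat_dmr = methylation.dmr_methylation_levels(
                [methylation.DMR(t.dmr_chrom, t.dmr_start, t.dmr_end, 0, -1.0, 0.0,
                                 0.0, t.meth_direction)],
                bundle.cpg, samples,
            )
            feats = pd.DataFrame(
                {
                    "planted_promoter_methylation": feat_dmr.iloc[0],
                    "planted_mirna_rpm": mirna_rpm.loc[t.mirna_id],
                }
            )
        else:
            feats = pd.DataFrame({"first_mirna_rpm": mirna_rpm.iloc[0]})
        traits = bundle.clinical.drop(columns=["group"])
        r_mat, p_mat = clinical.trait_correlations(feats, traits, config.corr_method)
        r_mat.to_csv(outdir / "trait_correlations_r.tsv", sep="\t")
        p_mat.to_csv(outdir / "trait_correlations_p.tsv", sep="\t")
        manifest["outputs"]["trait_correlations"] = str(outdir / "trait_correlations_r.tsv")
        summary["trait_correlations"] = {
            f: {tr: (None if pd.isna(r_mat.loc[f, tr]) else round(float(r_mat.loc[f, tr]), 4))
                for tr in r_mat.columns}
            for f in r_mat.index
        }

    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage context matters more
        _fail(exc)

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    manifest["outputs"]["summary"] = str(outdir / "summary.json")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
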
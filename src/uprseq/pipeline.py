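"""End-to-end orchestration: config schema, stage running, summary counts.

A YAML config names the inputs (expression + design TSVs for both strains,
optional q-values, promoters or genome+annotation, activities, overrides)
and the analysis parameters.  Stages run in dependency order — DE calling →
group classification → UPR designation → promoter scanning → interaction
scoring — and each stage is skipped cleanly when its inputs are absent.
Every output table carries a provenance header (package version, config
hash, seed) and the run is deterministic: same config and seed, byte-
identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .abundance import call_de, overlap_counts
from .esrt import classify_all, fit_canonical_groups
from .interactions import analyze_interactions, read_activity_table
from .matrix import (
    ResultTable,
    Strain,
    Treatment,
    config_hash,
    read_expression_table,
    write_result_table,
)
from .motifs import (
    classify_upre,
    extract_promoters,
    read_promoter_fasta,
    scan_promoters,
)
from .upr import DEFAULT_OVERRIDES, designate_all

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "summarize", "simulate_bundle"]

_INPUT_KEYS = {
    "expression", "design", "hac1_expression", "hac1_design", "q_values",
    "promoters", "genome", "annotation", "activities", "overrides",
}
_PARAM_DEFAULTS: dict[str, Any] = {
    "pseudocount": 0.01,
    "fc_up": 2.0,
    "fc_down": 0.5,
    # Figure-legend threshold; the stricter Methods value 0.05 is a
    # documented alternative — both are legitimate, neither is guessed.
    "q_max": 0.1,
    "q_source": "internal",
    "variance_ddof": 1,
    "candidate_mode": "any",
    "upr_p_max": 0.05,
    "equal_var": True,
    "promoter_length": 1000,
    "strands": "both",
    "tau": 0.1,
    "trait_convention": "deviation",
    "bootstrap": 0,
}


@dataclass
class PipelineConfig:
    inputs: dict[str, str | None]
    params: dict[str, Any]
    seed: int = 0
    outdir: str = "uprseq_out"

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        unknown = set(raw) - {"inputs", "params", "seed", "outdir"}
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        inputs = dict(raw.get("inputs") or {})
        bad = set(inputs) - _INPUT_KEYS
        if bad:
            raise ValueError(f"unknown input key(s): {sorted(bad)}")
        params = dict(_PARAM_DEFAULTS)
        extra = dict(raw.get("params") or {})
        bad = set(extra) - set(_PARAM_DEFAULTS)
        if bad:
            raise ValueError(f"unknown parameter(s): {sorted(bad)}")
        params.update(extra)
        return cls(
            inputs=inputs,
            params=params,
            seed=int(raw.get("seed", 0)),
            outdir=str(raw.get("outdir", "uprseq_out")),
        )

    def as_dict(self) -> dict:
        return {
            "inputs": self.inputs,
            "params": self.params,
            "seed": self.seed,
            "outdir": self.outdir,
        }


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.from_mapping(raw)


def _provenance(config: PipelineConfig) -> dict[str, str]:
    return {
        "pipeline_version": __version__,
        "config_hash": config_hash(config.as_dict()),
        "seed": str(config.seed),
    }


def _write(df: pd.DataFrame, prov: dict, outdir: Path, name: str, key: str | None = "gene_id") -> None:
    write_result_table(ResultTable(df, dict(prov), key), outdir / name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage whose inputs are configured; return the summary dict.

    Writes de_calls.tsv, overlap_counts.tsv, esrt_calls.tsv, upr_calls.tsv,
    upre_hits.tsv, upre_classes.tsv, interactions.tsv (as applicable),
    summary.json and run.log under ``outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    p = config.params
    log: list[str] = [f"uprseq {__version__} config={prov['config_hash']} seed={config.seed}"]
    summary: dict[str, Any] = {}

    def stage(name: str, msg: str) -> None:
        log.append(f"[{name}] {msg}")

    inputs = config.inputs
    wt = hac1 = None
    de_frames = []
    if inputs.get("expression") and inputs.get("design"):
        wt = read_expression_table(inputs["expression"], inputs["design"])
        stage("load", f"WT matrix: {wt.n_genes} genes x {len(wt.samples)} samples")
        provided_q = None
        if inputs.get("q_values"):
            qdf = pd.read_csv(inputs["q_values"], sep="\t", comment="#")
            provided_q = qdf
        summary["n_up"], summary["n_down"] = {}, {}
        up_sets: dict[str, set] = {"DTT": set(), "TM": set()}
        down_sets: dict[str, set] = {"DTT": set(), "TM": set()}
        for treatment in (Treatment.DTT, Treatment.TM):
            for tp in (15, 30, 60):
                if not wt.has_condition(Strain.WT, treatment, tp):
                    continue
                q = None
                if provided_q is not None:
                    sel = provided_q[
                        (provided_q["treatment"] == treatment.value)
                        & (provided_q["timepoint_min"] == tp)
                    ].set_index("gene_id")["q"]
                    q = sel
                calls = call_de(
                    wt, treatment, tp,
                    fc_up=p["fc_up"], fc_down=p["fc_down"], q_max=p["q_max"],
                    q_source=p["q_source"], provided_q=q, pseudocount=p["pseudocount"],
                )
                de_frames.append(calls)
                key = f"{treatment.value}_{tp}"
                n_up = int((calls["status"] == "UP").sum())
                n_down = int((calls["status"] == "DOWN").sum())
                summary["n_up"][key] = n_up
                summary["n_down"][key] = n_down
                up_sets[treatment.value] |= set(calls[calls["status"] == "UP"]["gene_id"])
                down_sets[treatment.value] |= set(
                    calls[calls["status"] == "DOWN"]["gene_id"]
                )
                stage("de", f"{key}: {n_up} UP, {n_down} DOWN")
        de_calls = pd.concat(de_frames, ignore_index=True)
        _write(de_calls, prov, outdir, "de_calls.tsv", key=None)
        venn = pd.concat(
            [
                overlap_counts({"up_DTT": up_sets["DTT"], "up_TM": up_sets["TM"]})
                .assign(direction="up"),
                overlap_counts({"down_DTT": down_sets["DTT"], "down_TM": down_sets["TM"]})
                .assign(direction="down"),
            ],
            ignore_index=True,
        )
        _write(venn, prov, outdir, "overlap_counts.tsv", key=None)
        summary["n_up_both_drugs"] = len(up_sets["DTT"] & up_sets["TM"])

        groups = fit_canonical_groups(
            wt, pseudocount=p["pseudocount"], ddof=p["variance_ddof"]
        )
        esrt_calls = classify_all(
            wt, groups, de_calls,
            pseudocount=p["pseudocount"], candidate_mode=p["candidate_mode"],
        )
        _write(esrt_calls, prov, outdir, "esrt_calls.tsv")
        summary["n_esrt"] = int(esrt_calls["is_esrt"].sum())
        summary["n_esrt_per_group"] = {
            gid: int(esrt_calls[f"member_{gid}"].sum()) for gid in sorted(groups)
        }
        stage("esrt", f"{summary['n_esrt']} ESRTs ({summary['n_esrt_per_group']})")

        if inputs.get("hac1_expression") and inputs.get("hac1_design"):
            hac1 = read_expression_table(inputs["hac1_expression"], inputs["hac1_design"])
            overrides = DEFAULT_OVERRIDES
            if inputs.get("overrides"):
                odf = pd.read_csv(inputs["overrides"], sep="\t", comment="#")
                overrides = dict(zip(odf["gene_id"], odf["note"]))
            upr_calls = designate_all(
                esrt_calls, wt, hac1, groups, overrides,
                pseudocount=p["pseudocount"], equal_var=p["equal_var"],
                p_max=p["upr_p_max"],
            )
            _write(upr_calls, prov, outdir, "upr_calls.tsv", key=None)
            upr_genes = set(upr_calls[upr_calls["is_upr_target"]]["gene_id"])
            summary["n_upr"] = len(upr_genes)
            stage("upr", f"{summary['n_upr']} UPR target genes")
        else:
            upr_genes = None

        promoters = None
        if inputs.get("promoters"):
            promoters = read_promoter_fasta(inputs["promoters"])
        elif inputs.get("genome") and inputs.get("annotation"):
            promoters, _meta = extract_promoters(
                inputs["genome"], inputs["annotation"], p["promoter_length"]
            )
        if promoters is not None:
            scan_targets = promoters
            if upr_genes is not None:
                scan_targets = {g: s for g, s in promoters.items() if g in upr_genes}
            hits = scan_promoters(scan_targets, strands=p["strands"])
            classes, class_counts = classify_upre(hits, sorted(scan_targets))
            _write(hits, prov, outdir, "upre_hits.tsv", key=None)
            _write(classes, prov, outdir, "upre_classes.tsv")
            summary["n_upre1_only"] = class_counts["UPRE1_only"]
            summary["n_upre2_only"] = class_counts["UPRE2_only"]
            summary["n_both"] = class_counts["both"]
            summary["n_upre_none"] = class_counts["none"]
            stage("upre", f"classes: {class_counts}")

    if inputs.get("activities"):
        acts = read_activity_table(inputs["activities"])
        interactions = analyze_interactions(
            acts, convention=p["trait_convention"], tau=p["tau"],
            bootstrap=p["bootstrap"], seed=config.seed,
        )
        _write(interactions, prov, outdir, "interactions.tsv", key=None)
        summary["n_interactions"] = {
            lab: int((interactions["label"] == lab).sum())
            for lab in ("additive", "negative", "positive")
        }
        stage("interact", f"{len(interactions)} pairs: {summary['n_interactions']}")

    summary = summarize(summary)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return summary


def summarize(summary: dict) -> dict:
    """Internal consistency checks on the summary counts."""
    if "n_upr" in summary and "n_esrt" in summary:
        if summary["n_upr"] > summary["n_esrt"]:
            raise RuntimeError("inconsistent tables: more UPR targets than ESRTs")
    return summary


def simulate_bundle(outdir: str | Path, seed: int = 1, generator_config=None) -> PipelineConfig:
    """Write a complete synthetic input bundle and the config that runs it."""
    from .simulate import (
        GeneratorConfig,
        generate_activities,
        generate_expression,
        generate_promoters,
        write_design_tsv,
        write_expression_tsv,
    )
    from .motifs import write_promoter_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gc = generator_config or GeneratorConfig()
    wt, hac1, truth = generate_expression(gc, seed)
    write_expression_tsv(wt, outdir / "wt_expression.tsv")
    write_design_tsv(wt, outdir / "wt_design.tsv")
    write_expression_tsv(hac1, outdir / "hac1_expression.tsv")
    write_design_tsv(hac1, outdir / "hac1_design.tsv")
    truth.to_csv(outdir / "truth_expression.tsv", sep="\t", index=False, float_format="%.6g")
    promoters, ptruth = generate_promoters(gc, seed + 1, gene_ids=wt.gene_ids)
    write_promoter_fasta(promoters, outdir / "promoters.fasta")
    ptruth.to_csv(outdir / "truth_promoters.tsv", sep="\t", index=False)
    acts, atruth = generate_activities(gc, seed + 2)
    acts.to_csv(outdir / "activities.tsv", sep="\t", index=False, float_format="%.6g")
    atruth.to_csv(outdir / "truth_activities.tsv", sep="\t", index=False)
    config = PipelineConfig.from_mapping(
        {
            "seed": seed,
            "outdir": str(outdir / "results"),
            "inputs": {
                "expression": str(outdir / "wt_expression.tsv"),
                "design": str(outdir / "wt_design.tsv"),
                "hac1_expression": str(outdir / "hac1_expression.tsv"),
                "hac1_design": str(outdir / "hac1_design.tsv"),
                "promoters": str(outdir / "promoters.fasta"),
                "activities": str(outdir / "activities.tsv"),
            },
        }
    )
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.as_dict(), sort_keys=True))
    return config
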
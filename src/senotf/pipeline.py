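"""End-to-end orchestration: simulate → DE → scan → enrich → report.

The stages run in the order the promoter analysis dictates: DE genes are
defined first; only motifs of *differentially expressed* transcription
factors survive to scanning (after the <1,000-variant eligibility filter);
occurrence outliers, expression-correlation ranks and Fisher enrichment
against the DE promoter set follow.  Every run directory contains the full
input and output tables, a summary JSON with the counts at each filter step,
and the effective configuration (with its hash) for byte-reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .de import de_gene_set, de_table, overlap_fraction
from .enrichment import (
    any_site_targets,
    background_stats,
    candidate_targets,
    correlate_tf_targets,
    fisher_enrichment,
    permutation_enrichment,
    rank_tfs,
)
from .motifs import IUPACMotif, ScanSettings, count_occurrences
from .simulate import SimulationConfig, generate_expression, generate_promoters, plant_motif

logger = logging.getLogger("senotf")

#: Motif library used for synthetic runs: common human TFBS consensus patterns
#: (E2F, NF-Y CCAAT box, AP-1, E-box, SP1-like, NF-κB, CRE, heat-shock-like),
#: plus two over-degenerate patterns that must fall to the eligibility filter.
DEFAULT_MOTIF_LIBRARY: tuple[str, ...] = (
    "TTTSSCGC",    # E2F recognition site, 4 variants
    "CCAAT",       # NF-Y CCAAT box, 1 variant
    "TGASTCA",     # AP-1, 2 variants
    "CACGTG",      # E-box, 1 variant
    "KGGGNGKGGC",  # SP1-like GC box, 16 variants
    "GGGRNNYYCC",  # NF-kB, 128 variants
    "TGACGTCA",    # CRE, 1 variant
    "NGAANNTTCN",  # HSE-like, 256 variants
    "NNNNNNW",     # 8,192 variants - ineligible
    "SSNNNNNN",    # 16,384 variants - ineligible
)


@dataclass(frozen=True)
class RunConfig:
    """Parameters for an end-to-end synthetic run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    reference: str | None = None          # defaults to sim.groups[0]
    fc_thresh: float = 0.4
    alpha: float = 0.05
    use_raw_p: bool = False
    strand_mode: str = "both"
    overlap: str = "allowed"
    max_variants: int = 1000
    corr_threshold: float = 0.8
    corr_level: str = "replicate"
    enrich_method: str = "fisher"         # or "permutation"
    enrich_alpha: float = 0.05
    targets_mode: str = "outlier"         # or "any_site"
    n_perm: int = 10_000
    n_tfs: int = 8
    plant_first_motif: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)


def _synthetic_motif_table(config: RunConfig, truth: pd.DataFrame) -> list[IUPACMotif]:
    """Assign library patterns to gene ids acting as transcription factors.

    Half the TF ids are drawn from the truly-DE genes (so some motifs survive
    the DE filter), half from the rest; assignment is deterministic under the
    simulation seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.sim.seed, spawn_key=(9,)))
    de_ids = list(truth.index[truth["is_de"]])
    other = list(truth.index[~truth["is_de"]])
    n = min(config.n_tfs, len(DEFAULT_MOTIF_LIBRARY))
    n_de = min(n // 2 + n % 2, len(de_ids))
    chosen = list(rng.choice(de_ids, size=n_de, replace=False)) if n_de else []
    n_bg = min(n - n_de, len(other))
    chosen += list(rng.choice(other, size=n_bg, replace=False)) if n_bg else []
    return [IUPACMotif(tf, DEFAULT_MOTIF_LIBRARY[i]) for i, tf in enumerate(chosen)]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full synthetic pipeline and write a run directory.

    Returns the summary dictionary (also written as ``summary.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    reference = config.reference or config.sim.reference_group
    summary: dict = {"config_hash": chash, "seed": config.sim.seed, "counts": {}}

    def stage(name: str):
        logger.info("stage %s", name)

    # --- simulate ---------------------------------------------------------
    stage("simulate")
    matrix, truth = generate_expression(config.sim)
    promoters = generate_promoters(config.sim)
    motifs = _synthetic_motif_table(config, truth)
    planted: dict[str, int] = {}
    if config.plant_first_motif and motifs:
        first = motifs[0]
        target_ids = set(truth.index[truth["is_de"]]) & set(promoters.ids)
        promoters, planted = plant_motif(promoters, first, target_ids, config.sim)
        summary["planted_motif"] = first.key
        summary["counts"]["n_planted_sites"] = int(sum(planted.values()))
    io.write_expression(matrix, out / "expression.tsv", out / "samples.tsv", chash)
    io.write_tsv(truth.reset_index(), out / "truth.tsv", chash)
    io.write_promoters(promoters, out / "promoters.fa")
    io.write_motifs(motifs, out / "motifs.tsv", chash)
    summary["counts"]["n_genes"] = len(matrix.gene_ids)
    summary["counts"]["n_promoters"] = len(promoters)
    summary["counts"]["n_tfs_input"] = len(motifs)

    # --- differential expression -----------------------------------------
    stage("de")
    table = de_table(matrix, reference, config.fc_thresh, config.alpha, config.use_raw_p)
    io.write_tsv(table, out / "de_table.tsv", chash)
    contrasts = list(dict.fromkeys(table["contrast"]))
    de_sets = {c: de_gene_set(table, c) for c in contrasts}
    de_union = set().union(*de_sets.values()) if de_sets else set()
    for c in contrasts:
        summary["counts"][f"n_de_{c}"] = len(de_sets[c])
    summary["counts"]["n_de_union"] = len(de_union)
    first, last = contrasts[0], contrasts[-1]
    if de_sets[first] and first != last:
        summary["overlap_fraction"] = overlap_fraction(de_sets[first], de_sets[last])

    # --- TF filter: DE transcription factors with eligible motifs ---------
    stage("scan")
    de_tf_motifs = [m for m in motifs if m.tf_gene_id in de_union]
    eligible = [m for m in de_tf_motifs if m.is_eligible(config.max_variants)]
    summary["counts"]["n_tfs_de"] = len(de_tf_motifs)
    summary["counts"]["n_motifs_eligible"] = len(eligible)

    if not de_union or not eligible:
        # Short-circuit: nothing to scan or enrich; empty report is a success.
        io.write_tsv(pd.DataFrame(
            columns=["motif", "tf_gene_id", "n_candidates", "n_correlated",
                     "rank", "a", "b", "c", "d", "odds_ratio", "p", "q", "enriched"]
        ), out / "enrichment.tsv", chash)
        summary["counts"]["n_enriched"] = 0
        _finish(out, config, summary)
        return summary

    settings = ScanSettings(config.strand_mode, config.overlap, config.max_variants)
    occ = count_occurrences(promoters, eligible, settings)
    io.write_tsv(occ.reset_index(), out / "occurrences.tsv", chash)

    # --- outliers, correlation, enrichment --------------------------------
    stage("enrich")
    bg = background_stats(occ)
    targets = (candidate_targets(occ, bg) if config.targets_mode == "outlier"
               else any_site_targets(occ))
    universe = set(promoters.ids)
    de_promoters = de_union & universe
    if config.enrich_method == "fisher":
        enr = fisher_enrichment(targets, de_promoters, universe, config.enrich_alpha)
    elif config.enrich_method == "permutation":
        enr = permutation_enrichment(occ, de_promoters, config.n_perm,
                                     config.sim.seed, config.enrich_alpha)
        enr = enr.rename(columns={"observed": "a"})
    else:
        raise ValueError(f"unknown enrichment method {config.enrich_method!r}")

    rows = []
    for motif in eligible:
        res = correlate_tf_targets(matrix, motif.tf_gene_id, targets[motif.key],
                                   config.corr_threshold, config.corr_level)
        rows.append({
            "motif": motif.key,
            "tf_gene_id": motif.tf_gene_id,
            "n_candidates": len(targets[motif.key]),
            "n_correlated": res.n_correlated,
        })
    report = pd.DataFrame(rows).set_index("motif").join(enr)
    report = rank_tfs(report)
    io.write_tsv(report.reset_index(), out / "enrichment.tsv", chash)
    summary["counts"]["n_candidates"] = {m: int(len(s)) for m, s in targets.items()}
    summary["counts"]["n_enriched"] = int(report["enriched"].sum())
    summary["top_tfs"] = report.sort_values("rank").head(5)["tf_gene_id"].tolist()
    _finish(out, config, summary)
    return summary


def _finish(out: Path, config: RunConfig, summary: dict) -> None:
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "config.yaml").write_text(
        yaml.safe_dump({"config_hash": config.config_hash(), **asdict(config)},
                       sort_keys=True)
    )


def report(run_dir: str | Path) -> str:
    """Human-readable markdown summary of a finished run directory."""
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(f"no summary.json in {run_dir}")
    summary = json.loads(summary_path.read_text())
    lines = [
        "# senotf run report",
        "",
        f"config hash: `{summary['config_hash']}`  (seed {summary['seed']})",
        "",
        "## Filter counts",
        "",
        "| step | count |",
        "| --- | --- |",
    ]
    for key, value in summary["counts"].items():
        if isinstance(value, dict):
            continue
        lines.append(f"| {key} | {value} |")
    if "overlap_fraction" in summary:
        lines += ["", f"DE overlap (early contrast within late): "
                      f"{summary['overlap_fraction']:.1%}"]
    lines.append("")
    if summary.get("top_tfs"):
        lines.append("Top-ranked TFs by correlated targets: "
                     + ", ".join(summary["top_tfs"]))
    n_enriched = summary["counts"].get("n_enriched", 0)
    if n_enriched == 0:
        lines.append("No TFBS enriched in DE promoters versus all promoters.")
    else:
        lines.append(f"{n_enriched} TFBS enriched in DE promoters.")
    lines.append("")
    return "\n".join(lines)
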
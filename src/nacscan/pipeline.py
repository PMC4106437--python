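"""End-to-end pipeline orchestration.

Runs the stages (simulate -> array -> qpcr -> scan -> enrich -> coexpr)
over a study directory, writing per-stage TSV outputs, a JSON manifest
(seed, parameters, parameter hash) and a printed-table style enrichment
summary.  Identical config + seed gives identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .arrays import (
    background_correct_half,
    de_to_frame,
    deduplicate_probes,
    filter_low_signal,
    quantile_normalize,
    rank_differential,
    select_top,
)
from .coexpr import build_coexpression_lists, rank_bias_test, random_gene_sample
from .enrich import enrichment_report, table4_style
from .motifs import read_meme
from .qpcr import (
    cluster_profiles,
    panel_from_ct,
    reference_stability,
    summarize_ct_table,
)
from .scan import Background, MotifScanner, hits_to_frame, scan_promoter_sets
from .simulate import SimConfig, gen_study

logger = logging.getLogger(__name__)

STAGES = ("simulate", "array", "qpcr", "scan", "enrich", "coexpr")


@dataclass
class PipelineConfig:
    """Paths, stage toggles and stage parameters for one run."""

    study_dir: str = "study"
    out_dir: str = "run"
    seed: int = 0
    stages: tuple = STAGES
    simulate: bool = True
    force: bool = False
    # scanning / enrichment
    p_threshold: float = 1e-4
    strands: str = "both"
    background: str = "uniform"  # or "estimate"
    granularity: float = 0.01
    p_mode: str = "mid"
    # array stage
    top_count: int | None = None  # default: ~20% of filtered probes
    min_fold_over_bg: float = 1.1
    min_fraction_arrays: float = 1.0
    # qpcr stage
    k: str | int = "auto"
    restarts: int = 100
    # coexpression
    random_set_size: int = 100
    sim: SimConfig = field(default_factory=SimConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    def param_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _read_fasta(path) -> dict[str, str]:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate promoter id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def _read_gene_set(path) -> set[str]:
    return {
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    }


def run_array_stage(config: PipelineConfig, study: Path, out: Path) -> dict:
    raw = pd.read_csv(study / "array_raw.tsv", sep="\t", index_col=0)
    bg = pd.read_csv(study / "array_background.tsv", sep="\t", index_col=0)
    probes = pd.read_csv(study / "probes.tsv", sep="\t")
    groups = [c.rsplit("_", 1)[1] for c in raw.columns]
    corrected = background_correct_half(raw.to_numpy(), bg.to_numpy())
    log2x = np.log2(corrected)
    normed = quantile_normalize(log2x)
    kept, n_kept = filter_low_signal(
        corrected,
        bg.to_numpy(),
        config.min_fold_over_bg,
        config.min_fraction_arrays,
        probe_ids=list(raw.index),
        group_labels=groups,
    )
    keep_mask = raw.index.isin(kept)
    normed_kept = normed[keep_mask]
    probe_index = [p for p in raw.index if p in set(kept)]
    sub = probes.set_index("probe_id").loc[probe_index]
    from .arrays import ProbeRecord

    records = [
        ProbeRecord(
            probe_id=pid,
            target_id=row["target_id"],
            probe_seq=row["probe_seq"],
            dist_to_3prime=int(row["dist_to_3prime"]),
            signals=normed_kept[i],
        )
        for i, (pid, row) in enumerate(sub.iterrows())
    ]
    representative = deduplicate_probes(records)
    rep_probe_ids = set(representative.values())
    rep_rows = [i for i, pid in enumerate(probe_index) if pid in rep_probe_ids]
    gene_of = {pid: t for t, pid in representative.items()}
    gene_ids = [gene_of[probe_index[i]] for i in rep_rows]
    de = rank_differential(
        normed_kept[rep_rows], groups, ("ns", "sen"), gene_ids=gene_ids
    )
    top_count = config.top_count or max(1, int(round(0.2 * len(de))))
    top_count = min(top_count, len(de))
    selected, percent = select_top(de, top_count)
    de_frame = de_to_frame(de)
    de_frame.to_csv(out / "de_table.tsv", sep="\t", index=False)
    (out / "selected_genes.txt").write_text("\n".join(sorted(selected)) + "\n")
    return {
        "probes_kept": n_kept,
        "genes": len(de),
        "top_count": top_count,
        "top_percent": percent,
    }


def run_qpcr_stage(config: PipelineConfig, study: Path, out: Path) -> dict:
    ct = pd.read_csv(study / "ct.tsv", sep="\t")
    chlorophyll = pd.read_csv(
        study / "chlorophyll.tsv", sep="\t", index_col=0
    ).iloc[:, 0]
    summary = summarize_ct_table(ct)
    summary.to_csv(out / "ct_summary.tsv", sep="\t", index=False)
    wide = summary.pivot(index="gene_id", columns="sample_id", values="ct")
    refs = [g for g in wide.index if str(g).startswith("REF")]
    stability_rows = []
    ref_gene = None
    if len(refs) >= 2:
        quantities = pd.DataFrame(
            np.power(2.0, -wide.loc[refs].to_numpy()),
            index=refs,
            columns=wide.columns,
        )
        stability = reference_stability(quantities)
        ref_gene = min(stability, key=lambda r: r.rank).gene_id
        stability_rows = [(r.gene_id, r.M, r.rank) for r in stability]
        pd.DataFrame(stability_rows, columns=["gene_id", "M", "rank"]).to_csv(
            out / "reference_stability.tsv", sep="\t", index=False
        )
    else:
        ref_gene = refs[0] if refs else str(wide.index[0])
    panel = panel_from_ct(summary, ref_gene, chlorophyll)
    panel = type(panel)(
        expression=panel.expression.loc[
            [g for g in panel.expression.index if not str(g).startswith("REF")]
        ],
        chlorophyll=panel.chlorophyll,
    )
    panel.ordered().rename_axis("gene_id").to_csv(
        out / "panel_ordered.tsv", sep="\t"
    )
    k = None if config.k == "auto" else int(config.k)
    result = cluster_profiles(
        panel, k=k, seed=config.seed, restarts=config.restarts
    )
    result.assignment.rename_axis("gene_id").to_frame().to_csv(
        out / "clusters.tsv", sep="\t"
    )
    pd.DataFrame(
        result.centroids,
        index=pd.Index(range(1, result.k + 1), name="cluster"),
        columns=panel.sample_order,
    ).to_csv(out / "centroids.tsv", sep="\t")
    return {"reference_gene": ref_gene, "k": result.k, "inertia": result.inertia}


def run_scan_stage(config: PipelineConfig, study: Path, out: Path) -> dict:
    promoters = _read_fasta(study / "promoters.fasta")
    models = read_meme(study / "motifs.meme")
    bg = (
        Background.from_sequences(promoters.values())
        if config.background == "estimate"
        else Background()
    )
    sets = {
        name: _read_gene_set(study / "gene_sets" / f"{name}.txt")
        for name in ("up", "down")
    }
    sets["all"] = set(promoters)
    hit_table = scan_promoter_sets(
        models, promoters, sets, bg, config.p_threshold, config.strands
    )
    all_hits = []
    for m in models:
        scanner = MotifScanner(
            m, bg, config.p_threshold, config.strands, config.granularity
        )
        for pid in sorted(hit_table.hit_ids[m.name]):
            all_hits.extend(scanner.scan(promoters[pid], pid))
    hits_to_frame(all_hits).to_csv(out / "hits.tsv", sep="\t", index=False)
    counts = hit_table.counts.copy()
    counts.loc["Total, non-redundant"] = pd.Series(hit_table.union_counts())
    counts.to_csv(out / "hit_counts.tsv", sep="\t")
    return {
        "models": len(models),
        "hit_table": hit_table,
        "sets": sets,
        "universe": set(promoters),
        "total_hits_up": hit_table.total_hits.get("up"),
        "union_up": len(hit_table.unions.get("up", set())),
    }


def run_enrich_stage(config: PipelineConfig, scan_info: dict, out: Path) -> dict:
    sets = {k: v for k, v in scan_info["sets"].items() if k != "all"}
    report = enrichment_report(
        scan_info["hit_table"], scan_info["universe"], sets, p_mode=config.p_mode
    )
    report.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    table4_style(report).to_csv(out / "enrichment_table.tsv", sep="\t")
    with open(out / "enrichment.json", "w") as fh:
        json.dump(report.to_dict(orient="records"), fh, indent=1)
    return {"rows": len(report)}


def run_coexpr_stage(config: PipelineConfig, study: Path, out: Path) -> dict:
    expr = pd.read_csv(study / "coexpression.tsv", sep="\t", index_col=0)
    truth = json.loads((study / "truth.json").read_text())["coexpression"]
    seed_gene = truth["seed_gene"]
    lists = build_coexpression_lists(expr, [seed_gene])
    clist = lists[seed_gene]
    set_a = [g for g in truth["coregulated"] if g != seed_gene]
    set_b = [g for g in truth["independent"] if g != seed_gene]
    ranks_a, _ = clist.ranks_of(set_a)
    ranks_b, _ = clist.ranks_of(set_b)
    rand = random_gene_sample(
        set(expr.index) - {seed_gene}, size=config.random_set_size,
        seed=config.seed,
    )
    ranks_r, _ = clist.ranks_of(sorted(rand))
    result = rank_bias_test(
        ranks_a, ranks_b, "with_motif", "without_motif",
        universe_size=clist.universe_size,
    )
    hist = pd.DataFrame(
        {
            "with_motif": result.histogram_a,
            "without_motif": result.histogram_b,
            "random": np.histogram(
                ranks_r, bins=np.linspace(1, clist.universe_size + 1, 21)
            )[0],
        }
    )
    hist.rename_axis("bin").to_csv(out / "rank_histograms.tsv", sep="\t")
    payload = {
        "seed_gene": seed_gene,
        "U": result.U,
        "auc": result.auc,
        "p_one_sided": result.p_one_sided,
        "method": result.method,
    }
    (out / "rank_bias.json").write_text(json.dumps(payload, indent=1))
    return payload


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the configured stages; returns the run directory.

    Any stage failure aborts with the stage name in the exception; a
    ``manifest.json`` with seed, parameter hash and per-stage summaries
    is written on success.
    """
    study = Path(config.study_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "param_hash": config.param_hash(),
        "parameters": config.to_dict(),
        "stages": {},
    }
    scan_info = None
    for stage in config.stages:
        try:
            if stage == "simulate":
                if config.simulate:
                    sim = dataclasses.replace(config.sim, seed=config.seed)
                    gen_study(sim, study, force=config.force)
                    manifest["stages"]["simulate"] = {"study_dir": str(study)}
            elif stage == "array":
                manifest["stages"]["array"] = run_array_stage(config, study, out)
            elif stage == "qpcr":
                manifest["stages"]["qpcr"] = run_qpcr_stage(config, study, out)
            elif stage == "scan":
                scan_info = run_scan_stage(config, study, out)
                manifest["stages"]["scan"] = {
                    k: v
                    for k, v in scan_info.items()
                    if k in ("models", "total_hits_up", "union_up")
                }
            elif stage == "enrich":
                if scan_info is None:
                    scan_info = run_scan_stage(config, study, out)
                manifest["stages"]["enrich"] = run_enrich_stage(
                    config, scan_info, out
                )
            elif stage == "coexpr":
                manifest["stages"]["coexpr"] = run_coexpr_stage(
                    config, study, out
                )
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:
            partial = out / "manifest.json.partial"
            partial.write_text(json.dumps(manifest, indent=1, default=str))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s done", stage)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, default=str)
    )
    return out
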
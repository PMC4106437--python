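"""Synthetic study generator.

Builds inputs with the statistical structure the analysis pipeline
assumes — 0-order background promoters with motif instances planted at
controlled per-set frequencies, a two-group microarray with redundant
probes and known differential genes, 10-sample senescence panels
following seven cluster archetypes, Ct tables with reference genes of
graded stability, and correlation-structured expression for
co-expression ranking — together with truth tables so parameter recovery
is measurable.  Every generator is deterministic given its seed.

Planted motif instances are drawn from a sharpened "instance" weight
scheme (core 0.995, minor 0.99) so that nearly every planted word is the
consensus: at the scanning threshold of p <= 1e-4 the accepted word set
of the default reporting models is essentially the consensus word alone,
and sampling instances from the flatter reporting matrix would conflate
the planted frequency with detection attenuation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .motifs import MotifModel, WeightScheme, build_all_default, build_nacbs, write_meme
from .qpcr import ExpressionPanel
from .arrays import ArraySet, ProbeRecord

_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT_IDX = np.array([3, 2, 1, 0])

#: Weight scheme used to *generate* planted instances (near-deterministic
#: core); reporting/scanning models keep the default scheme.
PLANT_WEIGHTS = WeightScheme(core_prob=0.995, minor_prob=0.99)


@dataclass
class SimConfig:
    """Study-scale constants for the synthetic generators.

    Default promoter scale is ~1/6 of a genome-wide promoter catalogue
    (2000 promoters of 1000 bp); the gene-set sizes scale the up / down
    differential sets (1106 / 1329) by the same factor.
    """

    n_promoters: int = 2000
    promoter_length: int = 1000
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    up_size: int = 175
    down_size: int = 210
    plant_fraction_up: float = 0.30
    plant_fraction_down: float = 0.10
    plant_fraction_background: float = 0.10
    plant_motif_name: str = "NACBS-8"
    # senescence expression panel
    n_samples: int = 10
    genes_per_cluster: int = 13
    expression_noise_sd: float = 0.2  # log2 units
    # microarray
    n_genes: int = 500
    n_de_up: int = 25
    n_de_down: int = 25
    de_log2fc: float = 4.0
    array_noise_sd: float = 0.5  # log2 units
    arrays_per_group: int = 4
    dead_probe_fraction: float = 0.05
    # qPCR
    ct_noise_sd: float = 0.15  # cycles
    ct_outlier_rate: float = 0.02
    ct_offset: float = 30.0
    reference_noise_sds: tuple = (0.05, 0.10, 0.25, 0.50)
    # log2 drift across the senescence panel: unstable reference genes
    # are unstable mainly because they are regulated, not because their
    # wells are noisy; shapes differ per gene so drifters do not covary
    reference_drift_log2: tuple = (0.0, 0.5, 1.2, 2.5)
    # co-expression
    coexpr_n_genes: int = 400
    coexpr_n_samples: int = 20
    coexpr_set_size: int = 40
    coexpr_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (
            self.plant_fraction_up,
            self.plant_fraction_down,
            self.plant_fraction_background,
        ):
            if not 0 <= f <= 1:
                raise ValueError(f"plant fraction {f} outside [0, 1]")
        if max(self.up_size, self.down_size) > self.n_promoters:
            raise ValueError("gene-set sizes exceed promoter universe")


def _codes_to_str(codes: np.ndarray) -> str:
    return _LETTERS[codes].tobytes().decode("ascii")


def gen_promoters(
    n: int,
    length: int = 1000,
    background=(0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
) -> dict[str, str]:
    """i.i.d. 0-order promoter sequences, deterministic per seed."""
    rng = np.random.default_rng(seed)
    codes = rng.choice(4, size=(n, length), p=np.asarray(background, float))
    width = max(5, len(str(n)))
    return {
        f"prom{str(i + 1).zfill(width)}": _codes_to_str(codes[i].astype(np.uint8))
        for i in range(n)
    }


def sample_motif_word(model: MotifModel, rng: np.random.Generator) -> str:
    """One word drawn position-wise from the model's letter probabilities."""
    codes = np.array(
        [rng.choice(4, p=model.probs[i]) for i in range(model.length)],
        dtype=np.uint8,
    )
    return _codes_to_str(codes)


def _reverse_complement(word: str) -> str:
    return word.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def plant_motif(
    promoters: dict[str, str],
    model: MotifModel,
    fraction: float,
    seed: int = 0,
    subset: list[str] | None = None,
) -> tuple[dict[str, str], list[dict]]:
    """Write one sampled motif word into a ``fraction`` of promoters.

    The word is placed at a uniform position on a uniform strand; on the
    minus strand its reverse complement is written into the forward
    sequence.  Returns the modified promoters and the truth records
    (promoter_id, motif, position, strand, word).
    """
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    ids = sorted(subset) if subset is not None else sorted(promoters)
    L = model.length
    out = dict(promoters)
    truth: list[dict] = []
    n_plant = int(round(fraction * len(ids)))
    chosen = rng.choice(ids, size=n_plant, replace=False) if n_plant else []
    for pid in chosen:
        seq = out[pid]
        if L > len(seq):
            raise ValueError(
                f"motif {model.name} (L={L}) longer than promoter {pid}"
            )
        pos = int(rng.integers(0, len(seq) - L + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        word = sample_motif_word(model, rng)
        inserted = word if strand == "+" else _reverse_complement(word)
        out[pid] = seq[:pos] + inserted + seq[pos + L :]
        truth.append(
            {
                "promoter_id": pid,
                "motif": model.name,
                "position": pos,
                "strand": strand,
                "word": word,
            }
        )
    return out, truth


def gen_promoter_study(
    cfg: SimConfig, seed: int | None = None
) -> tuple[dict[str, str], dict[str, set[str]], list[dict]]:
    """Promoter universe with motif instances planted at per-set rates.

    Disjoint up/down sets are drawn; the planting fraction is
    ``plant_fraction_up`` inside the up set, ``plant_fraction_down``
    inside the down set and ``plant_fraction_background`` elsewhere.
    """
    seed = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(seed).spawn(5)
    promoters = gen_promoters(
        cfg.n_promoters, cfg.promoter_length, cfg.background,
        seed=int(ss[0].generate_state(1)[0] % (2**31)),
    )
    rng = np.random.default_rng(ss[1])
    ids = sorted(promoters)
    picked = rng.choice(ids, size=cfg.up_size + cfg.down_size, replace=False)
    up = set(picked[: cfg.up_size])
    down = set(picked[cfg.up_size :])
    rest = [i for i in ids if i not in up and i not in down]
    model = build_nacbs(cfg.plant_motif_name, PLANT_WEIGHTS)
    truth: list[dict] = []
    for sub, frac, s in [
        (sorted(up), cfg.plant_fraction_up, ss[2]),
        (sorted(down), cfg.plant_fraction_down, ss[3]),
        (rest, cfg.plant_fraction_background, ss[4]),
    ]:
        promoters, t = plant_motif(
            promoters, model, frac, seed=int(s.generate_state(1)[0] % (2**31)), subset=sub
        )
        truth.extend(t)
    return promoters, {"up": up, "down": down}, truth


# ---------------------------------------------------------------------------
# senescence expression panel
# ---------------------------------------------------------------------------

def archetype_profiles(n_samples: int = 10) -> pd.DataFrame:
    """Seven senescence archetypes (log2 scale) over ordered samples.

    cluster1: single extreme riser (~11.6 log2 units, isocitrate-lyase
    like, taking off only in the last third); cluster2: late strong riser
    (~8); cluster3: late peak that declines at the very end; cluster4:
    moderate riser (amplitude 2 log2 units); cluster5: early riser
    levelling off (amplitude 4); cluster6: near-flat with a slight mid
    transient; cluster7: late down-regulation.

    Shapes were chosen to be mutually distinguishable after per-gene
    standardization (low pairwise profile correlation relative to the
    within-cluster noise), since pattern clustering discards amplitude.
    """
    t = np.linspace(0.0, 1.0, n_samples)
    profiles = {
        "cluster1": 11.6 * np.clip((t - 0.7) / 0.3, 0.0, 1.0) ** 2,
        "cluster2": 8.0 * t**4,
        "cluster3": 4.0 * np.exp(-(((t - 0.78) / 0.13) ** 2)),
        "cluster4": 2.0 * t,
        "cluster5": 4.0 * (1.0 - np.exp(-8.0 * t)) / (1.0 - np.exp(-8.0)),
        "cluster6": 1.5 * np.exp(-(((t - 0.42) / 0.22) ** 2)),
        "cluster7": -3.0 * t**2,
    }
    cols = [f"s{i + 1:02d}" for i in range(n_samples)]
    return pd.DataFrame(profiles, index=cols).T


def gen_expression_panel(
    cfg: SimConfig, seed: int | None = None
) -> tuple[ExpressionPanel, pd.Series]:
    """Senescence panel of 7 x genes_per_cluster genes with truth labels.

    Samples are ordered by a strictly decreasing synthetic chlorophyll
    series; expression is 2^(archetype + baseline + lognormal noise).
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    arch = archetype_profiles(cfg.n_samples)
    rows, labels = [], []
    gene_ids = []
    for c, name in enumerate(arch.index, start=1):
        for g in range(cfg.genes_per_cluster):
            noise = rng.normal(0.0, cfg.expression_noise_sd, cfg.n_samples)
            rows.append(arch.loc[name].to_numpy() + 5.0 + noise)
            gene_ids.append(f"{name}_g{g + 1:02d}")
            labels.append(c)
    expr = pd.DataFrame(
        np.power(2.0, np.asarray(rows)), index=gene_ids, columns=arch.columns
    )
    chlorophyll = pd.Series(
        np.linspace(45.0, 2.0, cfg.n_samples), index=arch.columns,
        name="chlorophyll",
    )
    truth = pd.Series(labels, index=gene_ids, name="true_cluster")
    return ExpressionPanel(expression=expr, chlorophyll=chlorophyll), truth


# ---------------------------------------------------------------------------
# microarray
# ---------------------------------------------------------------------------

def gen_microarray(
    cfg: SimConfig, seed: int | None = None
) -> tuple[ArraySet, list[ProbeRecord], dict]:
    """Two-group array set with redundant probes and known DE genes.

    Genes get 1-4 probes at distinct distances from the target 3' end;
    probe intensity attenuates with that distance (labelling from the
    poly(A) tail).  A configurable fraction of probes is "dead" (signal
    at background level).  Group means of DE genes are shifted by the
    true log2 fold change.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n_arrays = 2 * cfg.arrays_per_group
    groups = ["ns"] * cfg.arrays_per_group + ["sen"] * cfg.arrays_per_group
    gene_ids = [f"g{i + 1:04d}" for i in range(cfg.n_genes)]
    lfc = np.zeros(cfg.n_genes)
    de_idx = rng.choice(
        cfg.n_genes, size=cfg.n_de_up + cfg.n_de_down, replace=False
    )
    lfc[de_idx[: cfg.n_de_up]] = cfg.de_log2fc
    lfc[de_idx[cfg.n_de_up :]] = -cfg.de_log2fc
    base = rng.uniform(8.0, 12.0, cfg.n_genes)

    probes: list[ProbeRecord] = []
    raw_rows, bg_rows, probe_ids = [], [], []
    dead_probes: list[str] = []
    for i, gid in enumerate(gene_ids):
        n_probes = int(rng.integers(1, 5))
        dists = rng.choice(np.arange(10, 900, 10), size=n_probes, replace=False)
        for j, dist in enumerate(sorted(int(d) for d in dists)):
            pid = f"{gid}_p{j + 1}"
            dead = rng.random() < cfg.dead_probe_fraction
            atten = dist / 1500.0
            log2sig = (
                base[i]
                - atten
                + np.where(np.asarray(groups) == "sen", lfc[i], 0.0)
                + rng.normal(0.0, cfg.array_noise_sd, n_arrays)
            )
            signal = np.power(2.0, log2sig)
            background = 30.0 * (1.0 + rng.uniform(-0.1, 0.1, n_arrays))
            if dead:
                signal = background * rng.uniform(0.3, 0.9, n_arrays)
                dead_probes.append(pid)
            raw_rows.append(signal + background)
            bg_rows.append(background)
            probe_ids.append(pid)
            seq = _codes_to_str(
                rng.choice(4, size=60).astype(np.uint8)
            )
            probes.append(
                ProbeRecord(
                    probe_id=pid,
                    target_id=gid,
                    probe_seq=seq,
                    dist_to_3prime=int(dist),
                    signals=signal + background,
                )
            )
    arrays = ArraySet(
        raw=np.asarray(raw_rows),
        background=np.asarray(bg_rows),
        group_labels=groups,
        probe_ids=probe_ids,
    )
    truth = {
        "log2fc": pd.Series(lfc, index=gene_ids),
        "de_up": {gene_ids[i] for i in de_idx[: cfg.n_de_up]},
        "de_down": {gene_ids[i] for i in de_idx[cfg.n_de_up :]},
        "dead_probes": set(dead_probes),
    }
    return arrays, probes, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def gen_ct_table(
    panel: ExpressionPanel,
    cfg: SimConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Triplicate Ct table from a panel, plus graded reference genes.

    Ct = offset - log2(expression) + cycle noise per replicate.  The
    reference genes REF1..REFm combine well noise
    (``cfg.reference_noise_sds``) with a systematic log2 expression drift
    across the sample series (``cfg.reference_drift_log2``, shape differs
    per gene): REF1 is an 18S-rRNA-like stable reference (no drift),
    later ones are increasingly regulated.  Outlier replicates (large
    one-well shifts) are injected at ``cfg.ct_outlier_rate`` and recorded
    in the truth table.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    samples = list(panel.expression.columns)
    rows = []
    outliers = []

    def emit(gene: str, sample: str, true_ct: float, sd: float):
        for rep in (1, 2, 3):
            ct = true_ct + rng.normal(0.0, sd)
            if rng.random() < cfg.ct_outlier_rate:
                ct += float(rng.choice([-1, 1]) * rng.uniform(2.0, 6.0))
                outliers.append({"gene_id": gene, "sample_id": sample, "replicate": rep})
            rows.append((gene, sample, rep, ct))

    for gene in panel.expression.index:
        for sample in samples:
            true_ct = cfg.ct_offset - float(
                np.log2(panel.expression.loc[gene, sample])
            )
            emit(gene, sample, true_ct, cfg.ct_noise_sd)
    t = np.linspace(0.0, 1.0, len(samples))
    drift_shapes = [
        np.zeros_like(t),  # stable
        t - 0.5,  # declining expression -> rising Ct
        0.5 - t,  # rising expression
        np.abs(t - 0.5) - 0.25,  # V-shaped
    ]
    ref_sds, ref_drift = {}, {}
    for r, sd in enumerate(cfg.reference_noise_sds, start=1):
        gene = f"REF{r}"
        amp = (
            cfg.reference_drift_log2[r - 1]
            if r - 1 < len(cfg.reference_drift_log2)
            else cfg.reference_drift_log2[-1]
        )
        shape = drift_shapes[(r - 1) % len(drift_shapes)]
        ref_sds[gene] = sd
        ref_drift[gene] = amp
        for j, sample in enumerate(samples):
            emit(gene, sample, cfg.ct_offset - amp * shape[j], sd)
    ct = pd.DataFrame(rows, columns=["gene_id", "sample_id", "replicate", "ct"])
    truth = {
        "reference_noise_sds": ref_sds,
        "reference_drift_log2": ref_drift,
        "outliers": outliers,
    }
    return ct, truth


# ---------------------------------------------------------------------------
# co-expression
# ---------------------------------------------------------------------------

def gen_coexpression(
    cfg: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Correlation-structured expression for co-expression ranking.

    A seed gene follows a latent profile; ``coexpr_set_size`` genes share
    that latent profile plus independent noise (the co-regulated set) and
    the rest are independent.  Returns (expression, truth) where truth
    holds the seed id and both gene sets.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n, m = cfg.coexpr_n_genes, cfg.coexpr_n_samples
    latent = rng.normal(0.0, 1.0, m)
    samples = [f"s{i + 1:02d}" for i in range(m)]
    gene_ids = [f"cx{i + 1:04d}" for i in range(n)]
    X = rng.normal(0.0, 1.0, (n, m))
    seed_gene = gene_ids[0]
    X[0] = latent + rng.normal(0.0, 0.1, m)
    coreg = gene_ids[1 : cfg.coexpr_set_size + 1]
    for i in range(1, cfg.coexpr_set_size + 1):
        X[i] = latent + rng.normal(0.0, cfg.coexpr_noise_sd, m)
    indep = gene_ids[cfg.coexpr_set_size + 1 : 2 * cfg.coexpr_set_size + 1]
    expr = pd.DataFrame(X, index=gene_ids, columns=samples)
    truth = {
        "seed_gene": seed_gene,
        "coregulated": list(coreg),
        "independent": list(indep),
    }
    return expr, truth


# ---------------------------------------------------------------------------
# one-call study bundle
# ---------------------------------------------------------------------------

def _dir_nonempty(path: Path) -> bool:
    return path.exists() and any(path.iterdir())


def gen_study(cfg: SimConfig, outdir, force: bool = False) -> Path:
    """Write a complete synthetic study bundle to ``outdir``.

    Files: promoters.fasta, motifs.meme, gene_sets/{up,down}.txt,
    panel expression/chlorophyll/Ct TSVs, microarray TSVs, co-expression
    TSV and truth.json.  Deterministic per cfg.seed.
    """
    outdir = Path(outdir)
    if _dir_nonempty(outdir) and not force:
        raise FileExistsError(
            f"{outdir} exists and is not empty; pass force=True to overwrite"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "gene_sets").mkdir(exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed).spawn(4)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]

    promoters, sets, plant_truth = gen_promoter_study(cfg, seed=seeds[0])
    with open(outdir / "promoters.fasta", "w") as fh:
        for pid in sorted(promoters):
            fh.write(f">{pid}\n{promoters[pid]}\n")
    write_meme(build_all_default(), outdir / "motifs.meme")
    for name in ("up", "down"):
        (outdir / "gene_sets" / f"{name}.txt").write_text(
            "\n".join(sorted(sets[name])) + "\n"
        )

    panel, cluster_truth = gen_expression_panel(cfg, seed=seeds[1])
    panel.expression.rename_axis("gene_id").to_csv(
        outdir / "panel_expression.tsv", sep="\t"
    )
    panel.chlorophyll.rename_axis("sample_id").to_frame().to_csv(
        outdir / "chlorophyll.tsv", sep="\t"
    )
    ct, ct_truth = gen_ct_table(panel, cfg, seed=seeds[1])
    ct.to_csv(outdir / "ct.tsv", sep="\t", index=False)

    arrays, probes, array_truth = gen_microarray(cfg, seed=seeds[2])
    pd.DataFrame(
        arrays.raw,
        index=pd.Index(arrays.probe_ids, name="probe_id"),
        columns=[f"array{i + 1}_{g}" for i, g in enumerate(arrays.group_labels)],
    ).to_csv(outdir / "array_raw.tsv", sep="\t")
    pd.DataFrame(
        arrays.background,
        index=pd.Index(arrays.probe_ids, name="probe_id"),
        columns=[f"array{i + 1}_{g}" for i, g in enumerate(arrays.group_labels)],
    ).to_csv(outdir / "array_background.tsv", sep="\t")
    pd.DataFrame(
        [(p.probe_id, p.target_id, p.dist_to_3prime, p.probe_seq) for p in probes],
        columns=["probe_id", "target_id", "dist_to_3prime", "probe_seq"],
    ).to_csv(outdir / "probes.tsv", sep="\t", index=False)

    coexpr, coexpr_truth = gen_coexpression(cfg, seed=seeds[3])
    coexpr.rename_axis("gene_id").to_csv(outdir / "coexpression.tsv", sep="\t")

    truth = {
        "seed": cfg.seed,
        "planted": plant_truth,
        "sets": {k: sorted(v) for k, v in sets.items()},
        "true_cluster": cluster_truth.to_dict(),
        "reference_noise_sds": ct_truth["reference_noise_sds"],
        "ct_outliers": ct_truth["outliers"],
        "array_log2fc": array_truth["log2fc"].to_dict(),
        "de_up": sorted(array_truth["de_up"]),
        "de_down": sorted(array_truth["de_down"]),
        "dead_probes": sorted(array_truth["dead_probes"]),
        "coexpression": coexpr_truth,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    return outdir


def directory_checksum(path) -> str:
    """SHA-256 over sorted file names and contents (determinism checks)."""
    h = hashlib.sha256()
    for p in sorted(Path(path).rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()
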
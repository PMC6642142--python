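"""Synthetic study generator with planted, recoverable truth.

Emulates the data the pipeline consumes: a two-group (control vs
combined-treatment, n = 3 per group) microarray experiment with
log-normal intensities and planted fold changes for lncRNAs and mRNAs;
negative-binomial miRNA read counts; a genome annotation with planted
lncRNA positional classes (intergenic far/near, natural antisense,
intronic antisense); and interaction tables carrying planted sponge
triads plus optional random decoy edges.  Every planted parameter is
recorded in a :class:`TruthSet` so downstream stages can be scored for
exact recovery.

Child RNG streams are derived from the master seed by fixed offsets, so
each component is individually reproducible and the whole bundle is
byte-deterministic for a given config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_context import GenomicFeature
from .io_formats import (
    CountMatrix,
    ExpressionMatrix,
    GeneSetCollection,
    InteractionTable,
    write_counts_tsv,
    write_expression_tsv,
    write_gmt,
    write_gtf,
    write_interactions_tsv,
)

__all__ = ["SimConfig", "TruthSet", "SyntheticDataset", "generate",
           "gen_annotation", "gen_expression", "gen_mirna_counts",
           "gen_interactions", "gen_gene_sets"]

# fixed per-component seed offsets (stage-level reproducibility)
_OFF_ANNOT, _OFF_EXPR, _OFF_MIRNA, _OFF_INTER, _OFF_SETS = 11, 23, 37, 53, 71


@dataclass
class SimConfig:
    """Study-design parameters for the generator.

    Defaults mirror the emulated experiment: triplicate samples per
    group, |fold changes| on a 1.5-4x grid around the 1.5x significance
    gate, log2-scale intensity noise of 0.3 SD, and NB dispersion 0.1
    (typical biological CV ~0.3 for replicate small-RNA libraries).
    """

    n_coding: int = 300
    n_lnc: int = 200
    n_mirna: int = 100
    n_per_group: int = 3
    effect_grid: tuple[float, ...] = (1.5, 2.0, 4.0)
    noise_sd: float = 0.3
    nb_dispersion: float = 0.1
    lib_size: int = 50_000
    base_log2_intensity: float = 8.0
    base_log2_sd: float = 1.5
    n_de_lnc: int = 16
    n_de_mrna: int = 20
    n_de_mirna: int = 12
    n_triads_forward: int = 3
    n_triads_reverse: int = 3
    proximity_window: int = 300_000
    class_mix: tuple[tuple[str, float], ...] = (
        ("intergenic_far", 0.42),
        ("intergenic_near", 0.30),
        ("natural_antisense", 0.12),
        ("intronic_antisense", 0.09),
        ("sense_overlap", 0.07),
    )
    chrom_sizes: tuple[tuple[str, int], ...] = (
        ("chr1", 45_000_000),
        ("chr2", 45_000_000),
        ("chr3", 45_000_000),
        ("chr4", 45_000_000),
        ("chr5", 45_000_000),
        ("chr6", 45_000_000),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_coding", "n_lnc", "n_mirna", "n_per_group"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if any(e < 1 for e in self.effect_grid):
            raise ValueError("effect sizes must be >= 1 (ratio scale)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class TruthSet:
    """Planted structure the generator guarantees and tests recover.

    Fold changes are stored as treated/control ratios (>1 planted up,
    <1 planted down).  A *forward* triad is lnc up / miRNA down / mRNA
    up; *reverse* is the mirror.  ``dim_lncs`` are planted-up lncRNAs
    with intensity deliberately below the sponge expression floor.
    """

    lnc_fc: dict[str, float] = field(default_factory=dict)
    mrna_fc: dict[str, float] = field(default_factory=dict)
    mirna_fc: dict[str, float] = field(default_factory=dict)
    lnc_classes: dict[str, str] = field(default_factory=dict)
    planted_proximity_pairs: list[tuple[str, str, int]] = field(default_factory=list)
    planted_antisense_pairs: list[tuple[str, str]] = field(default_factory=list)
    planted_triads: list[tuple[str, str, str, str]] = field(default_factory=list)
    dim_lncs: list[str] = field(default_factory=list)
    enriched_set: str = ""
    seeds: dict[str, int] = field(default_factory=dict)

    def de_sets(self, kind: str) -> tuple[set[str], set[str]]:
        fcs = {"lnc": self.lnc_fc, "mrna": self.mrna_fc, "mirna": self.mirna_fc}[kind]
        up = {f for f, r in fcs.items() if r > 1}
        down = {f for f, r in fcs.items() if r < 1}
        return up, down

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    def check_consistency(self) -> None:
        """Planted forward triads must satisfy lnc>1, mirna<1, mrna>1
        (reverse mirrored); planted ids must exist in the FC maps."""
        for lnc, mirna, mrna, direction in self.planted_triads:
            lf, mif, mrf = self.lnc_fc[lnc], self.mirna_fc[mirna], self.mrna_fc[mrna]
            if direction == "forward":
                ok = lf > 1 and mif < 1 and mrf > 1
            else:
                ok = lf < 1 and mif > 1 and mrf < 1
            if not ok:
                raise ValueError(f"inconsistent planted triad {(lnc, mirna, mrna)}")


@dataclass
class SyntheticDataset:
    """Everything one simulated study produces."""

    features: list[GenomicFeature]
    lnc_expr: ExpressionMatrix
    mrna_expr: ExpressionMatrix
    mirna_counts: CountMatrix
    binding: InteractionTable
    targets: InteractionTable
    coexpression: InteractionTable
    disease: InteractionTable
    gene_sets: GeneSetCollection
    truth: TruthSet

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gtf(self.features, outdir / "annotation.gtf")
        write_expression_tsv(self.lnc_expr, outdir / "lnc_expression.tsv")
        write_expression_tsv(self.mrna_expr, outdir / "mrna_expression.tsv")
        write_counts_tsv(self.mirna_counts, outdir / "mirna_counts.tsv")
        write_interactions_tsv(self.binding, outdir / "lnc_mirna_binding.tsv")
        write_interactions_tsv(self.targets, outdir / "mirna_mrna_targets.tsv")
        write_interactions_tsv(self.coexpression, outdir / "lnc_mrna_coexpression.tsv")
        write_interactions_tsv(self.disease, outdir / "lnc_disease.tsv")
        write_gmt(self.gene_sets, outdir / "gene_sets.gmt")
        self.truth.to_json(outdir / "truth.json")
        groups = {
            **{s: g for s, g in self.lnc_expr.sample_groups.items()},
        }
        with open(outdir / "sample_groups.tsv", "w", encoding="utf-8") as fh:
            fh.write("sample_id\tgroup\n")
            for s in self.lnc_expr.sample_ids:
                fh.write(f"{s}\t{groups[s]}\n")


# --------------------------------------------------------------------------
# annotation


def _make_coding_gene(gid: str, chrom: str, start: int, strand: str) -> GenomicFeature:
    # 17 kb gene, three 1 kb exons separated by 7 kb introns
    exons = ((start, start + 1000), (start + 8000, start + 9000),
             (start + 16_000, start + 17_000))
    return GenomicFeature(gid, chrom, start, start + 17_000, strand, "coding", exons)


def gen_annotation(config: SimConfig, truth: TruthSet | None = None
                   ) -> tuple[list[GenomicFeature], TruthSet]:
    """Place coding genes on a regular grid (700 kb spacing, so any two
    neighbouring genes are > 300 kb apart) and lncRNAs of each planted
    positional class; record classes and planted cis pairs in the truth."""
    rng = np.random.default_rng(config.seed + _OFF_ANNOT)
    truth = truth or TruthSet()
    truth.seeds["annotation"] = config.seed + _OFF_ANNOT
    spacing, gene_len = 700_000, 17_000
    chroms = list(config.chrom_sizes)
    genes: list[GenomicFeature] = []
    slots: list[tuple[str, int]] = []  # (chrom, start) per gene
    per_chrom = -(-config.n_coding // len(chroms))
    gi = 0
    for chrom, size in chroms:
        for k in range(per_chrom):
            if gi >= config.n_coding:
                break
            start = 200_000 + k * spacing
            if start + gene_len + config.proximity_window > size:
                raise RuntimeError(
                    f"chromosome {chrom} too small for {per_chrom} genes"
                )
            strand = "+" if gi % 2 == 0 else "-"
            genes.append(_make_coding_gene(f"GENE{gi:04d}", chrom, start, strand))
            slots.append((chrom, start))
            gi += 1
    if gi < config.n_coding:
        raise RuntimeError("not enough chromosome space for coding genes")

    # class assignment by configured mix (deterministic largest-remainder)
    labels, fracs = zip(*config.class_mix)
    counts = [int(f * config.n_lnc) for f in fracs]
    rem = config.n_lnc - sum(counts)
    order = sorted(range(len(fracs)),
                   key=lambda i: -(fracs[i] * config.n_lnc - counts[i]))
    for i in range(rem):
        counts[order[i % len(order)]] += 1

    lncs: list[GenomicFeature] = []
    host_iter = iter(range(len(genes)))
    li = 0
    for label, cnt in zip(labels, counts):
        for _ in range(cnt):
            lid = f"LNC{li:04d}"
            if label == "intergenic_far":
                # mid-gap placement: > window from both flanking genes
                hi = next(host_iter)
                chrom, gstart = slots[hi]
                length = int(rng.integers(300, 8_000))
                start = gstart + gene_len + (spacing - gene_len) // 2 - length // 2
                strand = "+" if li % 2 == 0 else "-"
                feat = GenomicFeature(lid, chrom, start, start + length,
                                      strand, "lncRNA")
                cls = "intergenic"
            elif label == "intergenic_near":
                hi = next(host_iter)
                chrom, gstart = slots[hi]
                host = genes[hi]
                length = int(rng.integers(300, 5_000))
                gap = int(rng.integers(5_000, config.proximity_window - length - 5_000))
                start = gstart + gene_len + gap
                strand = "+" if li % 2 == 0 else "-"
                feat = GenomicFeature(lid, chrom, start, start + length,
                                      strand, "lncRNA")
                truth.planted_proximity_pairs.append((lid, host.id, gap))
                cls = "intergenic"
            elif label == "natural_antisense":
                hi = next(host_iter)
                host = genes[hi]
                ex = host.exons[1]
                start = ex[0] - 300
                feat = GenomicFeature(lid, host.chrom, start, ex[0] + 700,
                                      "-" if host.strand == "+" else "+", "lncRNA")
                truth.planted_antisense_pairs.append((lid, host.id))
                cls = "natural_antisense"
            elif label == "intronic_antisense":
                hi = next(host_iter)
                host = genes[hi]
                intr = host.intron_intervals()[0]
                start = intr[0] + 1_000
                feat = GenomicFeature(lid, host.chrom, start, start + 2_000,
                                      "-" if host.strand == "+" else "+", "lncRNA")
                cls = "intronic_antisense"
            else:  # sense_overlap
                hi = next(host_iter)
                host = genes[hi]
                ex = host.exons[2]
                feat = GenomicFeature(lid, host.chrom, ex[0] - 200, ex[0] + 500,
                                      host.strand, "lncRNA")
                cls = "sense_overlap"
            truth.lnc_classes[lid] = cls
            lncs.append(feat)
            li += 1
    return genes + lncs, truth


# --------------------------------------------------------------------------
# expression / counts


def _plant_fcs(ids: Sequence[str], n_up: int, n_down: int,
               grid: Sequence[float], rng: np.random.Generator,
               n_strong_up: int = 0, n_strong_down: int = 0) -> dict[str, float]:
    """Plant signed effects on a random feature subset.  Within each
    direction the first ``n_strong`` features get the grid maximum and
    the rest cycle the grid largest-first, so triad-anchor features
    always carry the strongest, most recoverable effects."""
    chosen = list(rng.choice(len(ids), size=n_up + n_down, replace=False))
    desc = sorted(grid, reverse=True)
    top = desc[0]
    fcs: dict[str, float] = {}
    for k, idx in enumerate(chosen):
        up = k < n_up
        j = k if up else k - n_up
        n_strong = n_strong_up if up else n_strong_down
        eff = top if j < n_strong else float(desc[j % len(desc)])
        fcs[ids[idx]] = eff if up else 1.0 / eff
    return fcs


def gen_expression(config: SimConfig, truth: TruthSet,
                   kind: str = "mrna") -> ExpressionMatrix:
    """Log-normal two-group intensities: log2 x ~ Normal(base +
    I[treated] * log2(ratio), noise_sd), exponentiated to linear scale.
    Planted ratios come from the truth (populated here on first call)."""
    rng = np.random.default_rng(config.seed + _OFF_EXPR + (0 if kind == "mrna" else 1))
    truth.seeds[f"expression_{kind}"] = config.seed + _OFF_EXPR
    if kind == "mrna":
        ids = [f"GENE{i:04d}" for i in range(config.n_coding)]
        if not truth.mrna_fc:
            n = config.n_de_mrna
            truth.mrna_fc = _plant_fcs(
                ids, n - n // 2, n // 2, config.effect_grid, rng,
                n_strong_up=config.n_triads_forward,
                n_strong_down=config.n_triads_reverse)
        fcs = truth.mrna_fc
        dim: set[str] = set()
    elif kind == "lnc":
        ids = [f"LNC{i:04d}" for i in range(config.n_lnc)]
        if not truth.lnc_fc:
            n = config.n_de_lnc
            truth.lnc_fc = _plant_fcs(
                ids, n - n // 2, n // 2, config.effect_grid, rng,
                n_strong_up=config.n_triads_forward,
                n_strong_down=config.n_triads_reverse)
            # the weakest planted-up lncRNA is kept dim (below the
            # intensity floor), never a triad anchor
            ups = sorted((f for f, r in truth.lnc_fc.items() if r > 1),
                         key=lambda f: (truth.lnc_fc[f], f))
            if ups:
                truth.dim_lncs = [ups[0]]
        fcs = truth.lnc_fc
        dim = set(truth.dim_lncs)
    else:
        raise ValueError(f"unknown expression kind {kind!r}")

    n = config.n_per_group
    samples = [f"ctrl_{i + 1}" for i in range(n)] + [f"trt_{i + 1}" for i in range(n)]
    groups = {s: ("control" if s.startswith("ctrl") else "C+T") for s in samples}
    base = rng.normal(config.base_log2_intensity, config.base_log2_sd, len(ids))
    for i, fid in enumerate(ids):
        if fid in dim:
            base[i] = 4.0  # ~16 linear units, below the 100 floor
        elif fid in fcs:
            # keep planted features clear of the intensity floor but away
            # from the extreme ranks, where quantile normalization would
            # compress a shared between-group shift
            base[i] = float(np.clip(base[i], config.base_log2_intensity - 0.5,
                                    config.base_log2_intensity + 1.5))
    log2fc = np.array([np.log2(fcs.get(f, 1.0)) for f in ids])
    mu = base[:, None] + np.outer(log2fc, np.r_[np.zeros(n), np.ones(n)])
    x = 2.0 ** (mu + rng.normal(0.0, config.noise_sd, mu.shape))
    return ExpressionMatrix(ids, samples, x, groups)


def gen_mirna_counts(config: SimConfig, truth: TruthSet) -> CountMatrix:
    """NB counts: mean = lib_size * pi_feature * ratio^I[treated],
    var = mu + phi mu^2.  Planted miRNA ratios recorded in the truth."""
    rng = np.random.default_rng(config.seed + _OFF_MIRNA)
    truth.seeds["mirna_counts"] = config.seed + _OFF_MIRNA
    ids = [f"hsa-miR-sim-{i:03d}" for i in range(config.n_mirna)]
    if not truth.mirna_fc:
        n = config.n_de_mirna
        truth.mirna_fc = _plant_fcs(
            ids, n - n // 2, n // 2, config.effect_grid, rng,
            n_strong_up=config.n_triads_reverse,
            n_strong_down=config.n_triads_forward)
    pi = rng.lognormal(0.0, 0.8, len(ids))
    pi /= pi.sum()
    # planted miRNAs get at least average sequencing depth so their
    # planted ratios are detectable at triplicate replication
    floor = 1.0 / len(ids)
    for i, fid in enumerate(ids):
        if fid in truth.mirna_fc:
            pi[i] = max(pi[i], floor)
    pi /= pi.sum()
    n = config.n_per_group
    samples = [f"ctrl_{i + 1}" for i in range(n)] + [f"trt_{i + 1}" for i in range(n)]
    groups = {s: ("control" if s.startswith("ctrl") else "C+T") for s in samples}
    ratio = np.array([truth.mirna_fc.get(f, 1.0) for f in ids])
    mu = config.lib_size * pi[:, None] * np.where(
        np.r_[np.zeros(n), np.ones(n)][None, :] > 0, ratio[:, None], 1.0
    )
    phi = config.nb_dispersion
    if phi < 1e-8:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + mu))
    return CountMatrix(ids, samples, counts.astype(float), groups)


# --------------------------------------------------------------------------
# interactions


def gen_interactions(config: SimConfig, truth: TruthSet,
                     background_density: float = 0.0) -> dict[str, InteractionTable]:
    """Plant sponge triads (forward among up lnc / down miRNA / up mRNA;
    reverse mirrored) into binding and target tables, co-expression rows
    for planted proximity pairs, and disease labels for DE lncRNAs.
    ``background_density`` adds that fraction of all possible decoy edges
    drawn uniformly at random among the remaining pairs."""
    rng = np.random.default_rng(config.seed + _OFF_INTER)
    truth.seeds["interactions"] = config.seed + _OFF_INTER
    # triad anchors: strongest planted effects first (most recoverable)
    lnc_up, lnc_down = truth.de_sets("lnc")
    lnc_up = sorted(lnc_up - set(truth.dim_lncs),
                    key=lambda f: (-truth.lnc_fc[f], f))
    lnc_down = sorted(lnc_down, key=lambda f: (truth.lnc_fc[f], f))
    mir_up, mir_down = truth.de_sets("mirna")
    mir_up = sorted(mir_up, key=lambda f: (-truth.mirna_fc[f], f))
    mir_down = sorted(mir_down, key=lambda f: (truth.mirna_fc[f], f))
    mr_up, mr_down = truth.de_sets("mrna")
    mr_up = sorted(mr_up, key=lambda f: (-truth.mrna_fc[f], f))
    mr_down = sorted(mr_down, key=lambda f: (truth.mrna_fc[f], f))

    binding: list[tuple[str, str, int]] = []
    targets: list[tuple[str, str, str]] = []
    if not truth.planted_triads:
        for k in range(config.n_triads_forward):
            triad = (lnc_up[k % len(lnc_up)], mir_down[k % len(mir_down)],
                     mr_up[k % len(mr_up)])
            truth.planted_triads.append((*triad, "forward"))
        for k in range(config.n_triads_reverse):
            triad = (lnc_down[k % len(lnc_down)], mir_up[k % len(mir_up)],
                     mr_down[k % len(mr_down)])
            truth.planted_triads.append((*triad, "reverse"))
    truth.check_consistency()
    bset: set[tuple[str, str]] = set()
    tset: set[tuple[str, str]] = set()
    for lnc, mirna, mrna, _direction in truth.planted_triads:
        if (lnc, mirna) not in bset:
            bset.add((lnc, mirna))
            binding.append((lnc, mirna, int(rng.integers(1, 23))))
        if (mirna, mrna) not in tset:
            tset.add((mirna, mrna))
            targets.append((mirna, mrna, "validated"))

    if background_density > 0:
        all_lnc = [f"LNC{i:04d}" for i in range(config.n_lnc)]
        all_mir = [f"hsa-miR-sim-{i:03d}" for i in range(config.n_mirna)]
        all_mr = [f"GENE{i:04d}" for i in range(config.n_coding)]
        for src_pool, tgt_pool, store, seen, mk in (
            (all_lnc, all_mir, binding, bset,
             lambda: int(rng.integers(1, 6))),
            (all_mir, all_mr, targets, tset, lambda: "predicted"),
        ):
            n_decoy = int(background_density * len(src_pool) * len(tgt_pool))
            for _ in range(n_decoy):
                pair = (str(rng.choice(src_pool)), str(rng.choice(tgt_pool)))
                if pair not in seen:
                    seen.add(pair)
                    store.append((*pair, mk()))

    coexpr: list[tuple[str, str, float]] = []
    cseen: set[tuple[str, str]] = set()
    for lnc, mrna, _d in truth.planted_proximity_pairs:
        lf, mf = truth.lnc_fc.get(lnc, 1.0), truth.mrna_fc.get(mrna, 1.0)
        if lf == 1.0 or mf == 1.0 or (lnc, mrna) in cseen:
            continue
        sign = 1.0 if (lf - 1) * (mf - 1) > 0 else -1.0
        cseen.add((lnc, mrna))
        coexpr.append((lnc, mrna, float(sign * rng.uniform(0.6, 0.8))))
    if background_density > 0:
        n_decoy = max(1, int(background_density * config.n_lnc * config.n_coding))
        for _ in range(n_decoy):
            pair = (f"LNC{int(rng.integers(config.n_lnc)):04d}",
                    f"GENE{int(rng.integers(config.n_coding)):04d}")
            if pair not in cseen:
                cseen.add(pair)
                coexpr.append((*pair, float(rng.uniform(-1, 1))))

    disease: list[tuple[str, str, str]] = []
    dseen: set[tuple[str, str]] = set()
    labels = ("cardiovascular disease", "cancer", "neuropathy")
    for k, lnc in enumerate(sorted(set(lnc_up[:4]) | set(lnc_down[:4]))):
        lab = labels[k % 2]  # DE lncRNAs: cardiovascular or cancer
        disease.append((lnc, lab, "curated"))
        dseen.add((lnc, lab))
    disease.append(("LNC0000", labels[2], "predicted"))  # decoy label

    return {
        "binding": InteractionTable("lnc_mirna_binding", binding),
        "targets": InteractionTable("mirna_mrna_target", targets),
        "coexpression": InteractionTable("lnc_mrna_coexpression", coexpr),
        "disease": InteractionTable("lnc_disease", disease),
    }


def gen_gene_sets(config: SimConfig, truth: TruthSet) -> GeneSetCollection:
    """One set enriched in the planted-up mRNAs plus size-matched random
    sets, for exercising over-representation analysis."""
    rng = np.random.default_rng(config.seed + _OFF_SETS)
    truth.seeds["gene_sets"] = config.seed + _OFF_SETS
    all_mr = [f"GENE{i:04d}" for i in range(config.n_coding)]
    up = sorted(truth.de_sets("mrna")[0])
    filler = [g for g in all_mr if g not in up]
    enriched = up + list(rng.choice(filler, size=min(5, len(filler)), replace=False))
    sets = {"SET_PLANTED_UP": ("proliferation-like planted set",
                               sorted(set(enriched)))}
    for k in range(3):
        members = sorted(
            str(g) for g in rng.choice(all_mr, size=15, replace=False)
        )
        sets[f"SET_RANDOM_{k}"] = (f"random control set {k}", members)
    truth.enriched_set = "SET_PLANTED_UP"
    return GeneSetCollection(sets)


def generate(config: SimConfig,
             background_density: float = 0.0) -> SyntheticDataset:
    """Run every generator component under one master seed."""
    truth = TruthSet()
    features, truth = gen_annotation(config, truth)
    lnc_expr = gen_expression(config, truth, kind="lnc")
    mrna_expr = gen_expression(config, truth, kind="mrna")
    mirna_counts = gen_mirna_counts(config, truth)
    tables = gen_interactions(config, truth, background_density)
    gene_sets = gen_gene_sets(config, truth)
    truth.check_consistency()
    return SyntheticDataset(
        features=features, lnc_expr=lnc_expr, mrna_expr=mrna_expr,
        mirna_counts=mirna_counts, binding=tables["binding"],
        targets=tables["targets"], coexpression=tables["coexpression"],
        disease=tables["disease"], gene_sets=gene_sets, truth=truth,
    )
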
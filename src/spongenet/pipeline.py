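"""End-to-end orchestration: simulate -> normalize -> DE -> genomic
context -> association -> ceRNA network -> enrichment -> validation.

A run consumes a validated :class:`PipelineConfig`, writes each stage's
outputs under its own subdirectory of the run directory, and finishes
with a machine-readable ``manifest.json`` recording every stage's
parameters, input hashes and output row counts.  Reruns with the same
config and seed are byte-identical (no wall-clock values are written).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import association, cerna, diffexpr, enrichment, genome_context, validation
from .io_formats import write_de_tsv, write_expression_tsv, write_network
from .synthetic import SimConfig, generate

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("spongenet.pipeline")

STAGES = ("simulate", "normalize", "de", "context", "associate", "cerna",
          "enrich", "validate")


@dataclass
class PipelineConfig:
    """All knobs for a full run, with the conventional defaults:
    |FC| >= 1.5 and p <= 0.05 for significance, a 300 kbp cis window,
    a 100-unit raw-intensity floor for sponge lncRNAs, and a 0.6-0.8
    reference co-expression band."""

    seed: int = 0
    fc_min: float = 1.5
    p_max: float = 0.05
    window: int = 300_000
    intensity_min: float = 100.0
    r_min: float = 0.6
    r_max: float = 0.8
    concordance_mode: str = "sign_concordant"
    background_density: float = 0.01
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        if self.fc_min < 1:
            raise ValueError("fc_min must be >= 1")
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must be in (0, 1]")
        if self.window <= 0:
            raise ValueError("window must be positive")
        if not 0 <= self.r_min <= self.r_max <= 1:
            raise ValueError("need 0 <= r_min <= r_max <= 1")
        if self.concordance_mode not in association.MODES:
            raise ValueError(f"bad concordance mode {self.concordance_mode!r}")
        if not 0 <= self.background_density <= 1:
            raise ValueError("background_density must be in [0, 1]")
        self.sim = SimConfig(**{**asdict(self.sim), "seed": self.seed})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _rows(path: Path) -> int:
    """Data rows in a TSV (header excluded); -1 for non-tabular files."""
    if path.suffix in (".tsv", ".gtf", ".gmt"):
        n = sum(1 for _ in open(path, encoding="utf-8"))
        return n - 1 if path.suffix == ".tsv" else n
    return -1


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute all stages under ``outdir`` and return it."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    def record(stage: str, params: dict, stage_dir: Path,
               inputs: list[Path] = ()) -> None:
        outputs = {
            str(p.relative_to(outdir)): _rows(p)
            for p in sorted(stage_dir.iterdir())
        }
        manifest.append({
            "stage": stage,
            "parameters": params,
            "input_hashes": {str(p.relative_to(outdir)): _sha256(p)
                             for p in inputs},
            "outputs": outputs,
        })
        log.info("stage %s: %d outputs", stage, len(outputs))

    filt = diffexpr.DEFilter(fc_min=config.fc_min, p_max=config.p_max)

    # 1. simulate ----------------------------------------------------------
    d = outdir / "simulate"
    dataset = generate(config.sim, background_density=config.background_density)
    dataset.write(d)
    record("simulate", asdict(config.sim), d)

    # 2. normalize ---------------------------------------------------------
    d = outdir / "normalize"
    d.mkdir(exist_ok=True)
    lnc_norm = diffexpr.quantile_normalize(dataset.lnc_expr)
    mrna_norm = diffexpr.quantile_normalize(dataset.mrna_expr)
    write_expression_tsv(lnc_norm, d / "lnc_normalized.tsv")
    write_expression_tsv(mrna_norm, d / "mrna_normalized.tsv")
    record("normalize", {"method": "quantile"}, d,
           [outdir / "simulate/lnc_expression.tsv",
            outdir / "simulate/mrna_expression.tsv"])

    # 3. differential expression ------------------------------------------
    d = outdir / "de"
    d.mkdir(exist_ok=True)
    lnc_de = diffexpr.ttest_de(lnc_norm, filt)
    mrna_de = diffexpr.ttest_de(mrna_norm, filt)
    mirna_de = diffexpr.nb_exact_de(dataset.mirna_counts, filt)
    write_de_tsv(lnc_de, d / "lnc_de.tsv")
    write_de_tsv(mrna_de, d / "mrna_de.tsv")
    write_de_tsv(mirna_de, d / "mirna_de.tsv")
    record("de", {"fc_min": config.fc_min, "p_max": config.p_max,
                  "lnc_mrna_test": "ttest_log2", "mirna_test": "nb_exact"}, d,
           [outdir / "normalize/lnc_normalized.tsv",
            outdir / "normalize/mrna_normalized.tsv",
            outdir / "simulate/mirna_counts.tsv"])

    # 4. genomic context ---------------------------------------------------
    d = outdir / "context"
    d.mkdir(exist_ok=True)
    feats = dataset.features
    coding = [f for f in feats if f.biotype == "coding"]
    lncs = [f for f in feats if f.biotype == "lncRNA"]
    classes = genome_context.classify_all(lncs, coding)
    sig_lnc = {r.feature_id for r in lnc_de if r.direction != "flat"}
    sig_mrna = {r.feature_id for r in mrna_de if r.direction != "flat"}
    sig_lnc_feats = [f for f in lncs if f.id in sig_lnc]
    sig_mrna_feats = [f for f in coding if f.id in sig_mrna]
    prox = genome_context.proximity_pairs(sig_lnc_feats, sig_mrna_feats,
                                          config.window)
    anti = genome_context.antisense_pairs(sig_lnc_feats, sig_mrna_feats)
    import pandas as pd
    pd.DataFrame(
        [(p.lnc_id, p.mrna_id, p.distance_bp, p.relation) for p in prox + anti],
        columns=["lnc_id", "mrna_id", "distance_bp", "relation"],
    ).to_csv(d / "cis_pairs.tsv", sep="\t", index=False, lineterminator="\n")
    if lncs:
        genome_context.summarize_lncrna(lncs, classes).to_csv(
            d / "lnc_summary.tsv", sep="\t", index=False, lineterminator="\n",
            float_format="%.6g")
    record("context", {"window": config.window}, d,
           [outdir / "simulate/annotation.gtf"])

    # 5. association -------------------------------------------------------
    d = outdir / "associate"
    d.mkdir(exist_ok=True)
    conc = association.concordance_filter(
        lnc_de, mrna_de, dataset.coexpression,
        r_min=config.r_min, r_max=config.r_max, mode=config.concordance_mode)
    pd.DataFrame(
        [(c.lnc_id, c.mrna_id, c.r, c.lnc_fc, c.mrna_fc, c.concordant)
         for c in conc],
        columns=["lnc_id", "mrna_id", "r", "lnc_fc", "mrna_fc", "concordant"],
    ).to_csv(d / "concordant_pairs.tsv", sep="\t", index=False,
             lineterminator="\n", float_format="%.10g")
    dis = association.disease_join(lnc_de, dataset.disease)
    if dis.empty:
        log.warning("disease join is empty")
    dis.to_csv(d / "disease_annotated.tsv", sep="\t", index=False,
               lineterminator="\n", float_format="%.10g")
    record("associate", {"r_min": config.r_min, "r_max": config.r_max,
                         "mode": config.concordance_mode}, d,
           [outdir / "simulate/lnc_mrna_coexpression.tsv",
            outdir / "simulate/lnc_disease.tsv"])

    # 6. ceRNA network -----------------------------------------------------
    d = outdir / "cerna"
    d.mkdir(exist_ok=True)
    whitelist = {f.id for f in lncs}
    up_sponges = cerna.select_sponge_lncrnas(
        lnc_de, "up", config.intensity_min, whitelist)
    down_sponges = cerna.select_sponge_lncrnas(lnc_de, "down", None, None)
    fwd = cerna.build_sponge_triads(up_sponges, mirna_de, mrna_de,
                                    dataset.binding, dataset.targets,
                                    "forward", lnc_de)
    rev = cerna.build_sponge_triads(down_sponges, mirna_de, mrna_de,
                                    dataset.binding, dataset.targets,
                                    "reverse", lnc_de)
    net = cerna.assemble_network(fwd, rev)
    write_network(net, d / "network_nodes.tsv", d / "network_edges.tsv")
    cerna.network_stats(net).to_csv(d / "network_stats.tsv", sep="\t",
                                    index=False, lineterminator="\n")
    pd.DataFrame(
        [(t.lnc_id, t.mirna_id, t.mrna_id, t.direction, t.binding_sites)
         for t in fwd + rev],
        columns=["lnc_id", "mirna_id", "mrna_id", "direction", "binding_sites"],
    ).to_csv(d / "triads.tsv", sep="\t", index=False, lineterminator="\n")
    record("cerna", {"intensity_min": config.intensity_min,
                     "whitelist": "annotation"}, d,
           [outdir / "simulate/lnc_mirna_binding.tsv",
            outdir / "simulate/mirna_mrna_targets.tsv"])

    # 7. enrichment --------------------------------------------------------
    d = outdir / "enrich"
    d.mkdir(exist_ok=True)
    universe = [r.feature_id for r in mrna_de]
    up_genes = [r.feature_id for r in mrna_de if r.direction == "up"]
    recs = enrichment.hypergeom_ora(up_genes, universe, dataset.gene_sets)
    pd.DataFrame(
        [(r.set_id, r.overlap_count, r.set_size, r.list_size,
          r.universe_size, r.p, r.q) for r in recs],
        columns=["set_id", "k", "K", "n", "N", "p", "q"],
    ).to_csv(d / "enrichment.tsv", sep="\t", index=False,
             lineterminator="\n", float_format="%.10g")
    record("enrich", {"universe": "platform", "tail": "right"}, d,
           [outdir / "simulate/gene_sets.gmt"])

    # 8. validation --------------------------------------------------------
    d = outdir / "validate"
    d.mkdir(exist_ok=True)
    # qRT-PCR-style check on the strongest up-regulated mRNA: control-
    # normalized expression compared across groups
    up_sorted = sorted((r for r in mrna_de if r.direction == "up"),
                       key=lambda r: r.p)
    rows = []
    if up_sorted:
        top = up_sorted[0]
        i = dataset.mrna_expr.feature_ids.index(top.feature_id)
        groups_map = dataset.mrna_expr.groups()
        col = {s: j for j, s in enumerate(dataset.mrna_expr.sample_ids)}
        ctrl_vals = [dataset.mrna_expr.values[i, col[s]]
                     for s in groups_map["control"]]
        ref_mean = sum(ctrl_vals) / len(ctrl_vals)
        groups = {
            g: [dataset.mrna_expr.values[i, col[s]] / ref_mean for s in ss]
            for g, ss in groups_map.items()
        }
        h, p = validation.kruskal_wallis(groups)
        dunn = validation.dunn_posthoc(groups)
        folds = validation.relative_fold(groups, "control")
        folds.to_csv(d / "relative_folds.tsv", sep="\t", index=False,
                     lineterminator="\n", float_format="%.10g")
        dunn.to_csv(d / "dunn.tsv", sep="\t", index=False,
                    lineterminator="\n", float_format="%.10g")
        rows.append((top.feature_id, h, p))
    pd.DataFrame(rows, columns=["feature_id", "kruskal_H", "kruskal_p"]).to_csv(
        d / "omnibus.tsv", sep="\t", index=False, lineterminator="\n",
        float_format="%.10g")
    record("validate", {"omnibus": "kruskal_wallis", "posthoc": "dunn_bh"}, d)

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return outdir
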
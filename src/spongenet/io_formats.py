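"""Readers and writers for every on-disk format the pipeline touches.

All tables are UTF-8, tab-separated, with header rows.  Expression and
count matrices are features x samples.  Annotation is GTF (1-based
inclusive on disk, converted to 0-based half-open in memory) or a minimal
BED.  Interaction tables are typed by ``kind``; gene sets are GMT.
Readers validate invariants and raise :class:`FormatError` with the
offending identifier or cell location.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_context import GenomicFeature

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "CountMatrix",
    "InteractionTable",
    "GeneSetCollection",
    "INTERACTION_KINDS",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_gtf",
    "write_gtf",
    "read_bed",
    "read_gmt",
    "write_gmt",
    "read_interactions_tsv",
    "write_interactions_tsv",
    "write_network",
]


class FormatError(ValueError):
    """A file violated its format contract."""


# --------------------------------------------------------------------------
# matrices


@dataclass
class ExpressionMatrix:
    """Linear-scale intensity matrix (features x samples) with a group
    design.  ``values`` rows follow ``feature_ids``, columns ``sample_ids``."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    sample_groups: dict[str, str]

    integral: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise FormatError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        for name, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise FormatError(f"duplicate {name} id {i!r}")
                seen.add(i)
        if not np.all(np.isfinite(self.values)):
            raise FormatError("non-finite values in matrix")
        if np.any(self.values < 0):
            raise FormatError("negative values in matrix")
        missing = [s for s in self.sample_ids if s not in self.sample_groups]
        if missing:
            raise FormatError(f"samples without group label: {missing}")
        if self.integral and not np.allclose(self.values, np.round(self.values)):
            raise FormatError("count matrix contains non-integer values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    def groups(self) -> dict[str, list[str]]:
        """Group label -> ordered sample ids."""
        out: dict[str, list[str]] = {}
        for s in self.sample_ids:
            out.setdefault(self.sample_groups[s], []).append(s)
        return out


class CountMatrix(ExpressionMatrix):
    """Integer read-count matrix (e.g. miRNA-seq); per-sample totals > 0."""

    def __init__(self, feature_ids, sample_ids, values, sample_groups):
        super().__init__(feature_ids, sample_ids, values, sample_groups, integral=True)
        totals = self.values.sum(axis=0)
        if np.any(totals <= 0):
            bad = [s for s, t in zip(self.sample_ids, totals) if t <= 0]
            raise FormatError(f"samples with zero library size: {bad}")


def _read_matrix_frame(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    dup = df.index[df.index.duplicated()].tolist()
    if dup:
        raise FormatError(f"{path}: duplicate feature id {dup[0]!r}")
    dupc = df.columns[df.columns.duplicated()].tolist()
    if dupc:
        raise FormatError(f"{path}: duplicate sample id {dupc[0]!r}")
    vals = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            try:
                vals[i, j] = float(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-numeric cell {cell!r} at row {df.index[i]!r}, "
                    f"column {col!r}"
                ) from None
    return pd.DataFrame(vals, index=df.index, columns=df.columns)


def read_expression_tsv(
    path: str | Path, group_map: Mapping[str, str]
) -> ExpressionMatrix:
    """Read a features-x-samples intensity TSV (first column = feature id)."""
    df = _read_matrix_frame(path)
    return ExpressionMatrix(
        list(df.index), list(df.columns), df.to_numpy(), dict(group_map)
    )


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_counts_tsv(path: str | Path, group_map: Mapping[str, str]) -> CountMatrix:
    df = _read_matrix_frame(path)
    return CountMatrix(
        list(df.index), list(df.columns), df.to_numpy(), dict(group_map)
    )


def write_counts_tsv(matrix: CountMatrix, path: str | Path) -> None:
    df = matrix.to_frame().astype(int)
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


# --------------------------------------------------------------------------
# annotation

_BIOTYPE_MAP = {
    "protein_coding": "coding",
    "coding": "coding",
    "lncrna": "lncRNA",
    "lincrna": "lncRNA",
    "lnc_rna": "lncRNA",
    "antisense": "lncRNA",
    "antisense_rna": "lncRNA",
    "sense_intronic": "lncRNA",
    "sense_overlapping": "lncRNA",
    "bidirectional_promoter_lncrna": "lncRNA",
}

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _normalize_biotype(raw: str) -> str:
    return _BIOTYPE_MAP.get(raw.lower(), "other")


def read_gtf(path: str | Path) -> list[GenomicFeature]:
    """Parse gene and exon records from a GTF file.

    GTF coordinates are 1-based inclusive; internal features are 0-based
    half-open.  ``gene_biotype`` and ``gene_type`` attribute keys are both
    accepted.  Exon lines are attached to their ``gene_id``.
    """
    genes: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = parts
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if end1 < start1:
                raise FormatError(f"{path}:{lineno}: end < start")
            if strand not in ("+", "-", "."):
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            attr = dict(_ATTR_RE.findall(attrs))
            gid = attr.get("gene_id")
            if gid is None:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            start, end = start1 - 1, end1  # to 0-based half-open
            if ftype == "gene":
                raw_bt = attr.get("gene_biotype", attr.get("gene_type", ""))
                genes[gid] = dict(
                    chrom=chrom, start=start, end=end, strand=strand,
                    biotype=_normalize_biotype(raw_bt),
                )
                order.append(gid)
            elif ftype == "exon":
                exons.setdefault(gid, []).append((start, end))
    feats = []
    for gid in order:
        g = genes[gid]
        ex = tuple(sorted(exons.get(gid, [])))
        feats.append(GenomicFeature(id=gid, exons=ex, **g))
    return feats


def write_gtf(features: Iterable[GenomicFeature], path: str | Path) -> None:
    """Write gene (and exon) records back to GTF, restoring 1-based
    inclusive coordinates."""
    inv = {"coding": "protein_coding", "lncRNA": "lncRNA", "other": "misc_RNA"}
    with open(path, "w", encoding="utf-8") as fh:
        for f in features:
            attrs = f'gene_id "{f.id}"; gene_biotype "{inv[f.biotype]}";'
            fh.write(
                f"{f.chrom}\tspongenet\tgene\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )
            for es, ee in f.exons:
                fh.write(
                    f"{f.chrom}\tspongenet\texon\t{es + 1}\t{ee}\t.\t"
                    f"{f.strand}\t.\t{attrs}\n"
                )


def read_bed(path: str | Path, biotype: str = "other") -> list[GenomicFeature]:
    """Minimal BED reader (chrom, start, end, name[, score[, strand]]).
    BED is already 0-based half-open; all features get ``biotype``."""
    feats = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: need at least 4 BED columns")
            strand = parts[5] if len(parts) > 5 else "."
            feats.append(
                GenomicFeature(
                    id=parts[3], chrom=parts[0], start=int(parts[1]),
                    end=int(parts[2]), strand=strand, biotype=biotype,
                )
            )
    return feats


# --------------------------------------------------------------------------
# interactions, gene sets, networks

INTERACTION_KINDS = {
    "lnc_mirna_binding": ("lnc_id", "mirna_id", "binding_sites"),
    "mirna_mrna_target": ("mirna_id", "mrna_id", "evidence"),
    "lnc_mrna_coexpression": ("lnc_id", "mrna_id", "r"),
    "lnc_disease": ("lnc_id", "disease", "source"),
}


@dataclass
class InteractionTable:
    """A typed pairwise table: (source, target, attribute) triples.

    Attribute semantics by kind: positive integer binding-site count for
    ``lnc_mirna_binding``; evidence label for ``mirna_mrna_target``;
    correlation r in [-1, 1] for ``lnc_mrna_coexpression``; disease label
    for ``lnc_disease`` (target column carries the disease).
    """

    kind: str
    records: list[tuple]

    def __post_init__(self) -> None:
        if self.kind not in INTERACTION_KINDS:
            raise FormatError(f"unknown interaction kind {self.kind!r}")
        seen: set[tuple[str, str]] = set()
        for src, tgt, attr in self.records:
            key = (src, tgt)
            if key in seen:
                raise FormatError(f"duplicate interaction {key} in {self.kind}")
            seen.add(key)
            if self.kind == "lnc_mirna_binding":
                if not (isinstance(attr, (int, np.integer)) and attr >= 1):
                    raise FormatError(
                        f"binding_site_count must be a positive integer, "
                        f"got {attr!r} for {key}"
                    )
            elif self.kind == "lnc_mrna_coexpression":
                if not -1.0 <= float(attr) <= 1.0:
                    raise FormatError(f"correlation {attr!r} outside [-1, 1] for {key}")

    def pairs(self) -> set[tuple[str, str]]:
        return {(s, t) for s, t, _ in self.records}

    def attr_map(self) -> dict[tuple[str, str], object]:
        return {(s, t): a for s, t, a in self.records}

    def to_frame(self) -> pd.DataFrame:
        cols = INTERACTION_KINDS[self.kind]
        return pd.DataFrame(self.records, columns=list(cols))


def read_interactions_tsv(path: str | Path, kind: str) -> InteractionTable:
    if kind not in INTERACTION_KINDS:
        raise FormatError(f"unknown interaction kind {kind!r}")
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: expected 3 columns for kind {kind}")
    records: list[tuple] = []
    for _, row in df.iterrows():
        src, tgt, attr = row.iloc[0], row.iloc[1], row.iloc[2]
        if kind == "lnc_mirna_binding":
            try:
                attr = int(attr)
            except ValueError:
                raise FormatError(f"{path}: non-integer binding count {attr!r}") from None
        elif kind == "lnc_mrna_coexpression":
            attr = float(attr)
        records.append((src, tgt, attr))
    return InteractionTable(kind, records)


def write_interactions_tsv(table: InteractionTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


@dataclass
class GeneSetCollection:
    """GMT-style named gene sets: set_id -> (description, member ids)."""

    sets: dict[str, tuple[str, list[str]]]

    def __post_init__(self) -> None:
        for sid, (_desc, members) in self.sets.items():
            if not members:
                raise FormatError(f"empty gene set {sid!r}")
            if len(set(members)) != len(members):
                raise FormatError(f"duplicate members in gene set {sid!r}")


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            sid, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if sid in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set id {sid!r}")
            # drop within-set duplicates but keep order
            members = list(dict.fromkeys(members))
            if members:
                sets[sid] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, (desc, members) in collection.sets.items():
            fh.write("\t".join([sid, desc, *members]) + "\n")


_DE_COLUMNS = ("feature_id", "mean_ctrl", "mean_trt", "signed_fc", "p", "q",
               "raw_intensity", "direction")


def write_de_tsv(records, path: str | Path) -> None:
    """Write differential-expression records as a TSV (one row per
    feature, fixed column order)."""
    df = pd.DataFrame(
        [[getattr(r, c) for c in _DE_COLUMNS] for r in records],
        columns=list(_DE_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")


def read_de_tsv(path: str | Path):
    """Read a DE TSV back into DERecord objects."""
    from .diffexpr import DERecord  # deferred: diffexpr imports this module

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _DE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing DE columns {missing}")
    return [
        DERecord(
            feature_id=str(r.feature_id), mean_ctrl=float(r.mean_ctrl),
            mean_trt=float(r.mean_trt), signed_fc=float(r.signed_fc),
            p=float(r.p), q=float(r.q), raw_intensity=float(r.raw_intensity),
            direction=str(r.direction),
        )
        for r in df.itertuples()
    ]


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id, group) TSV into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected sample_id and group columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_network(network, node_path: str | Path, edge_path: str | Path) -> None:
    """Write a ceRNA network as node and edge TSVs (re-readable with
    pandas).  Node table: id, class, signed_fc, p; edge table: source,
    target, edge_type, attribute (binding-site count on lnc->miRNA edges)."""
    g = network.graph
    nodes = pd.DataFrame(
        [
            (
                n,
                d.get("cls", ""),
                d.get("signed_fc", float("nan")),
                d.get("p", float("nan")),
            )
            for n, d in sorted(g.nodes(data=True))
        ],
        columns=["id", "class", "signed_fc", "p"],
    )
    edges = pd.DataFrame(
        [
            (u, v, d.get("edge_type", ""), d.get("binding_sites", ""))
            for u, v, d in sorted(g.edges(data=True))
        ],
        columns=["source", "target", "edge_type", "attribute"],
    )
    nodes.to_csv(node_path, sep="\t", index=False, lineterminator="\n")
    edges.to_csv(edge_path, sep="\t", index=False, lineterminator="\n")
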
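"""Sponge-triad gating, network assembly and planted-truth recovery."""

import itertools

import pytest

from spongenet import diffexpr
from spongenet.cerna import (
    SpongeTriad,
    assemble_network,
    build_sponge_triads,
    network_stats,
    select_sponge_lncrnas,
)
from spongenet.diffexpr import DERecord
from spongenet.hpasmc_tables import load_sponge_table, sponge_table_triads
from spongenet.io_formats import InteractionTable
from spongenet.synthetic import generate
from conftest import small_config


def rec(fid, fc, p=0.01, intensity=150.0):
    direction = "flat"
    if abs(fc) >= 1.5 and p <= 0.05:
        direction = "up" if fc > 0 else "down"
    return DERecord(fid, 100.0, 100.0, fc, p, p, intensity, direction)


class TestSelectSpongeLncrnas:
    def test_gate_conjunction(self):
        records = [
            rec("pass", 2.0, intensity=150.0),
            rec("dim", 2.0, intensity=100.0),        # strict > 100
            rec("flat", 1.2, p=0.5, intensity=150.0),
            rec("unlisted", 2.0, intensity=150.0),
            rec("down", -2.0, intensity=150.0),
        ]
        wl = {"pass", "dim", "flat", "down"}
        assert select_sponge_lncrnas(records, "up", 100.0, wl) == {"pass"}

    def test_no_whitelist_and_no_floor(self):
        records = [rec("a", -2.0, intensity=5.0)]
        assert select_sponge_lncrnas(records, "down", None, None) == {"a"}


class TestBuildTriads:
    def test_published_up_table_yields_printed_triad(self):
        """Running the printed up-direction candidates through the full
        gate chain reproduces the two-binding-site triad
        lncRNA ENST00000585387 -> miR-185-5p -> BAK1."""
        data = load_sponge_table("up")
        sponges = select_sponge_lncrnas(data["lnc_records"], "up", 100.0,
                                        {r.feature_id
                                         for r in data["lnc_records"]})
        triads = build_sponge_triads(
            sponges, data["mirna_records"], data["mrna_records"],
            data["binding"], data["targets"], "forward", data["lnc_records"])
        keyed = {(t.lnc_id, t.mirna_id, t.mrna_id): t for t in triads}
        t = keyed[("ENST00000585387", "hsa-miR-185-5p", "BAK1")]
        assert t.binding_sites == 2
        assert t.lnc_fc == pytest.approx(1.735)
        assert t.mirna_fc == pytest.approx(-2.865)

    def test_empty_binding_table_gives_no_triads(self):
        data = load_sponge_table("up")
        out = build_sponge_triads(
            {"ENST00000585387"}, data["mirna_records"], data["mrna_records"],
            InteractionTable("lnc_mirna_binding", []), data["targets"],
            "forward")
        assert out == []

    def test_wrong_table_kind_rejected(self):
        data = load_sponge_table("up")
        with pytest.raises(ValueError, match="kind"):
            build_sponge_triads({"x"}, data["mirna_records"],
                                data["mrna_records"], data["targets"],
                                data["targets"], "forward")

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_brute_force_triple_loop(self, seed):
        """Gate-based construction equals the naive scan over all
        (lncRNA, miRNA, mRNA) triples on a decoy-laden synthetic study."""
        ds = generate(small_config(seed=seed), background_density=0.02)
        lnc_de = diffexpr.ttest_de(diffexpr.quantile_normalize(ds.lnc_expr))
        mrna_de = diffexpr.ttest_de(diffexpr.quantile_normalize(ds.mrna_expr))
        mir_de = diffexpr.nb_exact_de(ds.mirna_counts)
        wl = {f.id for f in ds.features if f.biotype == "lncRNA"}
        sponges = select_sponge_lncrnas(lnc_de, "up", 100.0, wl)
        triads = build_sponge_triads(sponges, mir_de, mrna_de, ds.binding,
                                     ds.targets, "forward", lnc_de)
        got = {(t.lnc_id, t.mirna_id, t.mrna_id) for t in triads}

        bind = ds.binding.pairs()
        targ = ds.targets.pairs()
        mir_down = {r.feature_id for r in mir_de if r.direction == "down"}
        mrna_up = {r.feature_id for r in mrna_de if r.direction == "up"}
        brute = {
            (l, m, g)
            for l, m, g in itertools.product(
                sponges, mir_down, mrna_up)
            if (l, m) in bind and (m, g) in targ
        }
        assert got == brute

    def test_decoy_edge_with_non_de_lncrna_never_forms_triad(self, dataset_bg):
        ds = dataset_bg
        lnc_de = diffexpr.ttest_de(diffexpr.quantile_normalize(ds.lnc_expr))
        mrna_de = diffexpr.ttest_de(diffexpr.quantile_normalize(ds.mrna_expr))
        mir_de = diffexpr.nb_exact_de(ds.mirna_counts)
        sig = {r.feature_id for r in lnc_de if r.direction != "flat"}
        for direction in ("forward", "reverse"):
            dirn = "up" if direction == "forward" else "down"
            sel = select_sponge_lncrnas(lnc_de, dirn, None, None)
            triads = build_sponge_triads(sel, mir_de, mrna_de, ds.binding,
                                         ds.targets, direction, lnc_de)
            assert all(t.lnc_id in sig for t in triads)


class TestRecovery:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    @pytest.mark.parametrize("background", [0.0, 0.01])
    def test_planted_triads_recovered(self, seed, background):
        """Zero background: exact recovery (precision = recall = 1).
        1% decoy background: the gates never drop a planted triad
        (recall = 1)."""
        ds = generate(small_config(seed=seed), background_density=background)
        lnc_de = diffexpr.ttest_de(diffexpr.quantile_normalize(ds.lnc_expr))
        mrna_de = diffexpr.ttest_de(diffexpr.quantile_normalize(ds.mrna_expr))
        mir_de = diffexpr.nb_exact_de(ds.mirna_counts)
        wl = {f.id for f in ds.features if f.biotype == "lncRNA"}
        fwd = build_sponge_triads(
            select_sponge_lncrnas(lnc_de, "up", 100.0, wl),
            mir_de, mrna_de, ds.binding, ds.targets, "forward", lnc_de)
        rev = build_sponge_triads(
            select_sponge_lncrnas(lnc_de, "down", None, None),
            mir_de, mrna_de, ds.binding, ds.targets, "reverse", lnc_de)
        got = {(t.lnc_id, t.mirna_id, t.mrna_id) for t in fwd + rev}
        planted = {(l, m, g) for l, m, g, _ in ds.truth.planted_triads}
        assert planted <= got  # recall = 1
        if background == 0.0:
            assert got == planted  # precision = 1

    def test_monotonicity_of_intensity_gate(self, dataset):
        ds = dataset
        lnc_de = diffexpr.ttest_de(diffexpr.quantile_normalize(ds.lnc_expr))
        mrna_de = diffexpr.ttest_de(diffexpr.quantile_normalize(ds.mrna_expr))
        mir_de = diffexpr.nb_exact_de(ds.mirna_counts)
        prev = None
        for floor in (0.0, 100.0, 1000.0, 1e9):
            sel = select_sponge_lncrnas(lnc_de, "up", floor, None)
            triads = build_sponge_triads(sel, mir_de, mrna_de, ds.binding,
                                         ds.targets, "forward", lnc_de)
            cur = {(t.lnc_id, t.mirna_id, t.mrna_id) for t in triads}
            if prev is not None:
                assert cur <= prev
            prev = cur
        assert prev == set()  # an absurd floor removes everything


class TestAssembleNetwork:
    def test_single_triad_structure(self):
        t = SpongeTriad("L", "m", "G", "forward", 2, 2.0, -2.0, 2.0)
        net = assemble_network([t], [])
        assert net.graph.number_of_nodes() == 3
        assert net.graph.number_of_edges() == 2
        stats = network_stats(net).set_index("id")
        assert stats.degree.to_dict() == {"L": 1, "m": 2, "G": 1}

    def test_published_up_table_node_counts(self):
        """The up-direction table assembles into 10 lncRNA and 12 miRNA
        nodes, as stated alongside the published table."""
        net = assemble_network(sponge_table_triads("up"), [])
        assert len(net.nodes_of_class("lncRNA")) == 10
        assert len(net.nodes_of_class("miRNA")) == 12
        assert len(net.nodes_of_class("mRNA")) == 134

    def test_published_down_table_mirna_count(self):
        """The down-direction table's miRNA section holds 7 distinct
        up-regulated miRNAs."""
        net = assemble_network([], sponge_table_triads("down"))
        assert len(net.nodes_of_class("miRNA")) == 7

    def test_direction_mismatch_rejected(self):
        t = SpongeTriad("L", "m", "G", "forward", 1, 2.0, -2.0, 2.0)
        with pytest.raises(ValueError, match="forward set|reverse set"):
            assemble_network([], [t])

    def test_triad_sign_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            SpongeTriad("L", "m", "G", "forward", 1, -2.0, -2.0, 2.0)
        with pytest.raises(ValueError, match="binding_sites"):
            SpongeTriad("L", "m", "G", "forward", 0, 2.0, -2.0, 2.0)

    def test_forward_reverse_triad_sets_disjoint(self, dataset_bg):
        fwd = sponge_table_triads("up")
        rev = sponge_table_triads("down")
        assert not ({(t.lnc_id, t.mirna_id, t.mrna_id) for t in fwd}
                    & {(t.lnc_id, t.mirna_id, t.mrna_id) for t in rev})


class TestNetworkStats:
    def test_lnc_with_two_mirna_partners_has_degree_two(self):
        t1 = SpongeTriad("L", "m1", "G", "forward", 3, 2.0, -2.0, 2.0)
        t2 = SpongeTriad("L", "m2", "G", "forward", 4, 2.0, -2.0, 2.0)
        stats = network_stats(assemble_network([t1, t2], []))
        row = stats[stats.id == "L"].iloc[0]
        assert row.degree == 2
        assert row.total_binding_sites == 7

    def test_equals_brute_force_recount(self):
        triads = sponge_table_triads("up")
        net = assemble_network(triads, [])
        stats = network_stats(net).set_index("id")
        # brute recount from the triad list
        lnc_partners: dict[str, dict[str, int]] = {}
        mir_targets: dict[str, set[str]] = {}
        for t in triads:
            lnc_partners.setdefault(t.lnc_id, {})[t.mirna_id] = t.binding_sites
            mir_targets.setdefault(t.mirna_id, set()).add(t.mrna_id)
        for lnc_id, partners in lnc_partners.items():
            assert stats.loc[lnc_id].total_binding_sites == sum(
                partners.values())
        for mir, targets in mir_targets.items():
            assert stats.loc[mir].distinct_targets == len(targets)
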
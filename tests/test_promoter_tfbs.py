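"""PWM scanning, hypergeometric enrichment, background and null machinery."""

import numpy as np
import pandas as pd
import pytest

from orthotime.containers import PWM, MotifLibrary
from orthotime.preprocessing import (
    aggregate_presence,
    select_representative_probe,
)
from orthotime.promoter_tfbs import (
    assign_tfbs,
    base_frequencies,
    build_background,
    density_enrichment,
    hit_count_table,
    list_overlap,
    promoter_expression_report,
    random_group_null,
    scan_promoter,
)
from orthotime.simulate import (
    generate_experiment,
    generate_motif_library,
    generate_promoters,
    plant_motif_maps,
)
from conftest import five_shape_config
from oracles import hypergeom_upper_tail_exact

COMP = str.maketrans("ACGT", "TGCA")


def _strong_pwm(consensus="ACGTACGT", dominant=0.9):
    probs = np.full((4, len(consensus)), (1 - dominant) / 3)
    for j, base in enumerate(consensus):
        probs["ACGT".index(base), j] = dominant
    return PWM("test_motif", probs)


class TestScan:
    def test_consensus_promoter_hit_at_origin(self):
        pwm = _strong_pwm()
        hits = scan_promoter(pwm.consensus, pwm)
        fwd = hits[hits["strand"] == "+"]
        assert len(fwd) == 1 and fwd["offset"].iloc[0] == 0
        assert fwd["score"].iloc[0] == pytest.approx(pwm.max_score())

    def test_all_n_sequence_no_hits(self):
        pwm = _strong_pwm()
        assert scan_promoter("N" * 50, pwm).empty

    def test_sequence_shorter_than_motif(self):
        pwm = _strong_pwm()
        assert scan_promoter("ACG", pwm).empty

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            scan_promoter("ACGTXACGT", _strong_pwm())

    def test_reverse_strand_hit(self):
        pwm = _strong_pwm("AAACGTGC")
        revcomp = pwm.consensus.translate(COMP)[::-1]
        seq = "T" * 20 + revcomp + "T" * 20
        hits = scan_promoter(seq, pwm)
        rev = hits[hits["strand"] == "-"]
        assert len(rev) == 1 and rev["offset"].iloc[0] == 20

    def test_strand_symmetry_of_hit_counts(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 500))
        pwm = _strong_pwm("ACGTAAGG", dominant=0.7)
        fwd_hits = scan_promoter(seq, pwm, min_score_fraction=0.6)
        rc_hits = scan_promoter(seq.translate(COMP)[::-1], pwm,
                                min_score_fraction=0.6)
        assert len(fwd_hits) == len(rc_hits)

    def test_hit_count_table_matches_scan(self):
        rng = np.random.default_rng(2)
        proms = {
            f"g{i}": "".join(rng.choice(list("ACGT"), 300)) for i in range(5)
        }
        lib = generate_motif_library(4, (6, 8), seed=7)
        counts, positions = hit_count_table(proms, lib, 0.7)
        for g, seq in proms.items():
            for pwm in lib:
                expected = len(scan_promoter(seq, pwm, 0.7))
                assert counts.loc[g, pwm.motif_id] == expected
                assert positions.loc[g, pwm.motif_id] == 2 * (
                    len(seq) - pwm.width + 1
                )

    def test_planted_occurrences_recovered(self):
        lib = generate_motif_library(3, (8, 8), seed=5)
        genes = [f"g{i}" for i in range(20)]
        planted = {g: "motif_002" for g in genes[:8]}
        proms, sites = generate_promoters(
            genes, lib, planted, promoter_length=300, seed=9,
            min_site_quality=0.85,
        )
        pwm = lib["motif_002"]
        for _, row in sites.iterrows():
            hits = scan_promoter(proms[row["gene"]], pwm,
                                 min_score_fraction=0.85)
            match = hits[(hits["offset"] == row["offset"])
                         & (hits["strand"] == row["strand"])]
            assert len(match) == 1


class TestDensityEnrichment:
    def test_no_foreground_hits(self):
        assert density_enrichment(0, 100, 5, 900) == 1.0

    def test_reference_example(self):
        p = density_enrichment(5, 100, 5, 900)
        expected = hypergeom_upper_tail_exact(5, 1000, 10, 100)
        assert p == pytest.approx(expected, rel=1e-9)
        assert p == pytest.approx(1.6e-3, rel=0.05)

    def test_equal_densities_not_enriched(self):
        for k in (1, 2, 4, 8):
            for n in (20, 50):
                assert density_enrichment(k, n, k, n) >= 0.5

    def test_doubling_counts_keeps_null(self):
        base = density_enrichment(2, 50, 2, 50)
        doubled = density_enrichment(4, 50, 4, 50)
        assert base >= 0.5 and doubled >= 0.5

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            density_enrichment(0, 0, 1, 10)
        with pytest.raises(ValueError):
            density_enrichment(11, 10, 0, 10)


class TestListOverlap:
    def test_exact_small_example(self):
        res = list_overlap({"a", "b", "c"}, {"a", "b", "c"}, 10)
        assert res["p_value"] == pytest.approx(1 / 120, rel=1e-9)

    def test_degenerate_cases(self):
        assert list_overlap(set(), {"a"}, 5)["p_value"] == 1.0
        full = {f"m{i}" for i in range(6)}
        assert list_overlap(full, full, 6)["p_value"] == 1.0
        disjoint = list_overlap({"a"}, {"b"}, 10)
        assert disjoint["overlap"] == 0 and disjoint["p_value"] == 1.0

    def test_library_smaller_than_list_rejected(self):
        with pytest.raises(ValueError):
            list_overlap({"a", "b", "c"}, {"a"}, 2)


class TestHypergeometricOracles:
    @pytest.mark.parametrize("seed", range(6))
    def test_density_matches_exact_tail(self, seed):
        rng = np.random.default_rng(seed)
        n_fg = int(rng.integers(2, 15))
        n_bg = int(rng.integers(2, 30 - n_fg))
        k_fg = int(rng.integers(0, n_fg + 1))
        k_bg = int(rng.integers(0, n_bg + 1))
        p = density_enrichment(k_fg, n_fg, k_bg, n_bg)
        expected = hypergeom_upper_tail_exact(
            k_fg, n_fg + n_bg, k_fg + k_bg, n_fg
        )
        assert p == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_overlap_matches_exact_tail(self, seed):
        rng = np.random.default_rng(100 + seed)
        M = int(rng.integers(4, 30))
        a = int(rng.integers(1, M + 1))
        b = int(rng.integers(1, M + 1))
        items = [f"m{i}" for i in range(M)]
        la = set(rng.choice(items, a, replace=False))
        lb = set(rng.choice(items, b, replace=False))
        res = list_overlap(la, lb, M)
        expected = hypergeom_upper_tail_exact(len(la & lb), M, a, b)
        assert res["p_value"] == pytest.approx(expected, rel=1e-10)


@pytest.fixture(scope="module")
def planted_fixture():
    """Small study with planted motifs on mouse promoters."""
    cfg = five_shape_config(
        n_genes=180, n_clusters=6,
        # peak:8 omitted: the mouse grid (days 0-7, 10) barely samples it,
        # leaving its profile variance close to the flat cluster's
        cluster_shapes=("down", "up", "peak:2", "peak:5", "delayed_down",
                        "flat"),
        probes_per_gene_mean=1.0, probes_per_gene_max=1, seed=17,
        gene_shape_jitter=0.1,
    )
    human, mouse, map_h, map_m, pairs, calls_h, calls_m, truth = (
        generate_experiment(cfg)
    )
    lib = generate_motif_library(12, (8, 10), seed=18)
    maps = plant_motif_maps(truth, lib)
    proms, sites = generate_promoters(
        list(pairs["mouse_gene"]), lib, maps["mouse"], promoter_length=500,
        seed=19,
    )
    gm, _ = select_representative_probe(mouse, map_m)
    status = aggregate_presence(calls_m, map_m, k=3)
    background = build_background(gm, status, n=25)
    return dict(truth=truth, lib=lib, proms=proms, sites=sites,
                gene_matrix=gm, status=status, background=background,
                pairs=pairs)


class TestBackground:
    def test_least_varying_expressed_gene(self, planted_fixture):
        gm = planted_fixture["gene_matrix"]
        status = planted_fixture["status"]
        single = build_background(gm, status, n=1)
        variance = gm.replicate_mean().var(axis=1, ddof=1)
        expressed = status.index[status["expressed"]]
        assert single[0] == variance.loc[expressed].idxmin()

    def test_background_prefers_flat_cluster(self, planted_fixture):
        truth = planted_fixture["truth"]
        flat_clusters = {
            c for (sp, c), s in truth.cluster_shapes.items()
            if sp == "mouse" and s == "flat"
        }
        flat_genes = set(
            truth.assignments.loc[
                truth.assignments["cluster"].isin(flat_clusters),
                "mouse_gene",
            ]
        )
        assert set(planted_fixture["background"]) <= flat_genes

    def test_silent_genes_never_selected(self):
        cfg = five_shape_config(n_genes=100, presence_absent_fraction=0.3,
                                seed=29)
        _, mouse, _, map_m, _, _, calls_m, truth = generate_experiment(cfg)
        gm, _ = select_representative_probe(mouse, map_m)
        status = aggregate_presence(calls_m, map_m, k=3)
        bg = build_background(gm, status, n=30)
        assert not set(bg) & truth.silent["mouse"]

    def test_insufficient_expressed_rejected(self, planted_fixture):
        with pytest.raises(ValueError):
            build_background(
                planted_fixture["gene_matrix"], planted_fixture["status"],
                n=10 ** 6,
            )

    def test_gc_correction_matches_foreground_bins(self, planted_fixture):
        proms = planted_fixture["proms"]
        gm = planted_fixture["gene_matrix"]
        status = planted_fixture["status"]
        fg = list(planted_fixture["pairs"]["mouse_gene"][:40])
        bg = build_background(gm, status, n=25, gc_correct=True,
                              promoters=proms, foreground_genes=fg, seed=3)
        assert len(bg) >= 1
        assert set(bg) <= set(proms)


class TestAssignment:
    def test_default_alpha_is_bonferroni(self, planted_fixture):
        lib = planted_fixture["lib"]
        truth = planted_fixture["truth"]
        c = next(
            c for (sp, c) in truth.planted_motifs if sp == "mouse"
        )
        group = list(
            truth.assignments.loc[
                truth.assignments["cluster"] == c, "mouse_gene"
            ]
        )
        tab = assign_tfbs(group, planted_fixture["proms"], lib,
                          planted_fixture["background"])
        planted = truth.planted_motifs[("mouse", c)]
        kept = set(tab.loc[tab["kept"], "motif"])
        assert planted in kept
        row = tab.set_index("motif").loc[planted]
        assert row["p_value"] <= 0.05 / len(lib)
        assert row["coverage"] >= 0.40

    def test_coverage_gate_excludes_low_coverage(self):
        # tiny p-value but hits concentrated on one promoter
        lib = MotifLibrary([_strong_pwm()])
        counts = pd.DataFrame(
            {"test_motif": [50, 0, 0, 0, 0, 1, 1]},
            index=pd.Index([f"g{i}" for i in range(7)], name="gene"),
        )
        positions = pd.DataFrame(
            {"test_motif": [1000] * 7},
            index=counts.index,
        )
        tab = assign_tfbs(
            [f"g{i}" for i in range(5)], {f"g{i}": "A" * 100 for i in
                                          range(7)},
            lib, ["g5", "g6"], precomputed=(counts, positions),
        )
        row = tab.iloc[0]
        assert row["coverage"] == pytest.approx(0.2)
        assert row["p_value"] < 1e-4
        assert not row["kept"]

    def test_explicit_alpha_used(self, planted_fixture):
        lib = planted_fixture["lib"]
        group = list(planted_fixture["pairs"]["mouse_gene"][:20])
        tab = assign_tfbs(group, planted_fixture["proms"], lib,
                          planted_fixture["background"], alpha=1.0)
        # with alpha = 1 the gate reduces to the coverage condition
        assert (tab["kept"] == (tab["coverage"] >= 0.40)).all()


class TestRandomGroupNull:
    def test_deterministic_under_seed(self, planted_fixture):
        pool = list(planted_fixture["pairs"]["mouse_gene"][:80])
        args = ([10], 100, pool, planted_fixture["proms"],
                planted_fixture["lib"], planted_fixture["background"])
        a = random_group_null(*args, seed=4)
        b = random_group_null(*args, seed=4)
        pd.testing.assert_frame_equal(a[0], b[0])
        assert a[2] == b[2]

    def test_planted_cluster_beats_null(self, planted_fixture):
        truth = planted_fixture["truth"]
        lib = planted_fixture["lib"]
        status = planted_fixture["status"]
        expressed = [
            g for g in status.index[status["expressed"]]
            if g in planted_fixture["proms"]
        ]
        c = next(c for (sp, c) in truth.planted_motifs if sp == "mouse")
        group = list(
            truth.assignments.loc[
                truth.assignments["cluster"] == c, "mouse_gene"
            ]
        )
        _, _, cutoff = random_group_null(
            [len(group)], 100, expressed, planted_fixture["proms"], lib,
            planted_fixture["background"], seed=8,
        )
        tab = assign_tfbs(group, planted_fixture["proms"], lib,
                          planted_fixture["background"])
        planted_p = tab.set_index("motif").loc[
            truth.planted_motifs[("mouse", c)], "p_value"
        ]
        assert planted_p < cutoff

    def test_oversized_groups_rejected(self, planted_fixture):
        with pytest.raises(ValueError):
            random_group_null(
                [10 ** 5], 100, list(planted_fixture["proms"]),
                planted_fixture["proms"], planted_fixture["lib"],
                planted_fixture["background"], seed=0,
            )


class TestReport:
    def _enrichment_tables(self, motifs, kept_map, pval_map):
        out = {}
        for c in kept_map:
            rows = []
            for m in motifs:
                rows.append(
                    {
                        "motif": m,
                        "p_value": pval_map.get((c, m), 0.5),
                        "coverage": 1.0,
                        "kept": m in kept_map[c],
                    }
                )
            out[c] = pd.DataFrame(rows)
        return out

    def test_counts_and_scatter(self):
        motifs = [f"m{i}" for i in range(6)]
        cluster_pccs = pd.DataFrame(
            {"cluster": [1, 2], "pcc": [0.95, 0.1]}
        )
        human = self._enrichment_tables(
            motifs, {1: {"m0", "m1"}, 2: {"m2"}},
            {(1, "m0"): 1e-12, (2, "m2"): 1e-10},
        )
        mouse = self._enrichment_tables(
            motifs, {1: {"m0", "m1"}, 2: {"m3"}},
            {(1, "m0"): 1e-11},
        )
        scatter, counts, counts_pcc = promoter_expression_report(
            cluster_pccs, {"human": human, "mouse": mouse}, total_motifs=6,
        )
        row1 = scatter.set_index("cluster").loc[1]
        assert row1["overlap"] == 2
        assert row1["overlap_p"] == pytest.approx(1 / 15, rel=1e-9)
        c = counts.set_index("motif")
        assert c.loc["m0", "n_clusters_human"] == 1
        assert c.loc["m0", "n_clusters_mouse"] == 1
        # motif never below the strict cutoff in any cluster
        assert c.loc["m5", "n_clusters_human"] == 0
        assert c.loc["m5", "n_clusters_mouse"] == 0
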
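from __future__ import annotations

import filecmp
import json
import math

import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import make_states
from symmeth.diffmeth import GeneMethylation
from symmeth.genome import GeneAnnotation, GenomicRegion
from symmeth.integrate import (
    PipelineError,
    annotated_fraction,
    integrate,
    integration_counts,
    methylation_windows,
    run_pipeline,
)
from symmeth.motifs import default_motifs
from symmeth.simulate import simulate_dataset

GANTC = next(m for m in default_motifs() if m.name == "GANTC")


def _de_row(gene_id, log_fc, adj_p):
    return {"gene_id": gene_id, "log_fc": log_fc, "p_value": adj_p / 2,
            "adj_p": adj_p, "significant": adj_p < 0.001}


class TestIntegrate:
    island = GenomicRegion(1000, 2000, "island")
    genes = [
        GeneAnnotation("blr1745", 1100, 1900, "+", "nitrogenase cofactor protein", True),
        GeneAnnotation("bll0100", 3000, 3800, "-", "hypothetical protein"),
        GeneAnnotation("blr0200", 4100, 4900, "+", "putative enzyme"),
    ]

    def _summaries(self):
        meth = [GeneMethylation("blr1745", 1, 0, {"GANTC"}),
                GeneMethylation("bll0100", 2, 1, {"CRAGGAT"})]
        de = pd.DataFrame([
            _de_row("blr1745", 3.06, 1e-5),
            _de_row("bll0100", 0.4, 0.5),
            _de_row("blr0200", -2.0, 1e-6),
        ])
        return integrate(meth, de, self.genes, self.island)

    def test_change_plus_significance_makes_candidate(self):
        s = self._summaries().set_index("gene_id")
        assert bool(s.at["blr1745", "candidate"])
        assert s.at["blr1745", "in_island"] and s.at["blr1745", "meth_changes"] == 1

    def test_change_without_significance_is_not_candidate(self):
        s = self._summaries().set_index("gene_id")
        assert not s.at["bll0100", "candidate"]

    def test_significance_without_change_is_not_candidate(self):
        s = self._summaries().set_index("gene_id")
        assert not s.at["blr0200", "candidate"]

    def test_one_row_per_annotated_gene(self):
        s = self._summaries()
        assert list(s["gene_id"]) == [g.gene_id for g in self.genes]

    def test_duplicate_gene_ids_rejected(self):
        genes = self.genes + [GeneAnnotation("blr1745", 5000, 5500, "+")]
        with pytest.raises(ValueError, match="duplicate"):
            integrate([], pd.DataFrame([_de_row("x", 0, 1)]), genes, self.island)


class TestIntegrationCounts:
    def _frame(self, n_island_genes, n_island_cand, n_rest_cand=0,
               up_in_a=0):
        rows = []
        for i in range(n_island_genes):
            cand = i < n_island_cand
            rows.append({"gene_id": f"i{i}", "in_island": True, "candidate": cand,
                         "log_fc": (1.0 if i < up_in_a else -1.0) if cand else 0.0,
                         "is_symbiosis_gene": False})
        for i in range(n_rest_cand):
            rows.append({"gene_id": f"r{i}", "in_island": False, "candidate": True,
                         "log_fc": -1.0, "is_symbiosis_gene": False})
        return pd.DataFrame(rows)

    def test_island_percentage_one_decimal(self):
        counts = integration_counts(self._frame(583, 89))
        assert counts.pct_island == 15.3
        assert counts.n_candidates_island == 89
        assert counts.n_island_genes == 583

    def test_zero_candidates(self):
        counts = integration_counts(self._frame(10, 0))
        assert counts.pct_island == 0.0 and counts.n_candidates_genome == 0

    def test_direction_split_recovered(self):
        counts = integration_counts(self._frame(100, 89, up_in_a=11))
        assert (counts.n_up_in_a, counts.n_up_in_b) == (11, 78)

    def test_island_plus_rest_equals_genome(self):
        counts = integration_counts(self._frame(50, 7, n_rest_cand=13))
        assert counts.n_candidates_genome == counts.n_candidates_island + 13

    def test_zero_island_genes_with_candidates_rejected(self):
        df = self._frame(5, 2)
        with pytest.raises(ValueError, match="island"):
            integration_counts(df, island_gene_count=0)


class TestAnnotatedFraction:
    @pytest.mark.parametrize(
        "n,total,expected", [(3278, 8265, 39.7), (0, 10, 0.0), (8214, 8265, 99.4)]
    )
    def test_values(self, n, total, expected):
        assert annotated_fraction(n, total) == expected

    def test_errors(self):
        with pytest.raises(ValueError):
            annotated_fraction(1, 0)
        with pytest.raises(ValueError):
            annotated_fraction(11, 10)


class TestMethylationWindows:
    def test_fully_methylated_motif(self):
        states = make_states(GANTC, 20, 0, start_pos=10)
        for w in methylation_windows(states, 1000, circular=False, window=200, step=100):
            if w.n_sites:
                assert w.value == 1.0

    def test_half_methylated_window(self):
        states = make_states(GANTC, 1, 1, start_pos=100)
        (w,) = methylation_windows(states, 1000, circular=False,
                                   window=1000, step=1000)
        assert w.value == 0.5 and w.n_sites == 2

    def test_empty_window_is_missing_not_zero(self):
        states = make_states(GANTC, 1, 0, start_pos=50)
        windows = methylation_windows(states, 2000, circular=False,
                                      window=100, step=100)
        assert math.isnan(windows[5].value) and windows[5].n_sites == 0
        assert windows[0].value == 1.0

    def test_matches_per_window_recount(self, default_dataset, rng):
        ds = default_dataset
        cond = ds.config.condition_b
        truth = ds.truth.site_states[cond]
        from conftest import make_record
        from symmeth.modcalls import SiteState
        from symmeth.simulate import site_key

        states = []
        for s in ds.sites["CRAGGAT"]:
            if truth[site_key(s)]:
                states.append(SiteState(s, cond, "methylated", make_record(s.position)))
            else:
                states.append(SiteState(s, cond, "unmethylated"))
        L = len(ds.genome)
        windows = methylation_windows(states, L, circular=True, window=1000, step=700)
        positions = [s.site.position for s in states]
        meth = [s.methylated for s in states]
        for w in windows[:: max(1, len(windows) // 200)]:
            k, n = oracles.recount_window(positions, meth, w.window_start, 1000, L, True)
            assert w.n_sites == n
            if n:
                assert w.value == pytest.approx(k / n)
            else:
                assert math.isnan(w.value)

    def test_genomewide_mean_equals_summary_fraction(self):
        states = make_states(GANTC, 30, 70, start_pos=1)
        windows = methylation_windows(states, 2000, circular=False,
                                      window=2000, step=2000)
        assert windows[0].value == pytest.approx(0.3)


@pytest.fixture(scope="module")
def small_run(tmp_path_factory, small_config):
    root = tmp_path_factory.mktemp("pipeline")
    ds = simulate_dataset(small_config, root / "data")
    cfg = {
        "genome_fasta": str(root / "data/genome.fasta"),
        "annotation": str(root / "data/annotation.tsv"),
        "mods_a": str(root / "data/mods_free_living.gff"),
        "mods_b": str(root / "data/mods_bacteroid.gff"),
        "expression": str(root / "data/expression.tsv"),
        "island_start": small_config.island_start,
        "island_end": small_config.island_end,
    }
    out = run_pipeline(cfg, root / "run")
    return ds, cfg, out


class TestRunPipeline:
    def test_all_outputs_present(self, small_run):
        _, _, out = small_run
        for name in ("motif_summary.tsv", "diff_sites.tsv", "gene_methylation.tsv",
                     "regional_tally.tsv", "de_results.tsv", "gene_summaries.tsv",
                     "integration_counts.json", "run_log.txt"):
            assert (out / name).exists(), name
        assert (out / "windows" / "gc.bedgraph").exists()

    def test_candidate_set_algebra(self, small_run):
        _, _, out = small_run
        gs = pd.read_csv(out / "gene_summaries.tsv", sep="\t")
        candidates = set(gs[gs["candidate"]]["gene_id"])
        meth = set(gs[gs["meth_changes"] >= 1]["gene_id"])
        sig = set(gs[gs["de_significant"]]["gene_id"])
        assert candidates == meth & sig
        counts = json.load(open(out / "integration_counts.json"))
        n_rest = len(gs[gs["candidate"] & ~gs["in_island"]])
        assert counts["n_candidates_genome"] == counts["n_candidates_island"] + n_rest

    def test_summary_pct_consistent_with_diff_table(self, small_run):
        _, _, out = small_run
        summ = pd.read_csv(out / "motif_summary.tsv", sep="\t")
        diff = pd.read_csv(out / "diff_sites.tsv", sep="\t")
        for motif in ("GANTC", "CCTTGAG"):
            row = summ[(summ["condition"] == "bacteroid") & (summ["motif"] == motif)]
            n_meth = int((diff[diff["motif"] == motif]["state_b"] == "methylated").sum())
            assert int(row["n_methylated"].iloc[0]) == n_meth

    def test_rerun_is_byte_identical(self, small_run, tmp_path):
        _, cfg, out = small_run
        out2 = run_pipeline(cfg, tmp_path / "rerun")
        for p in sorted(out.rglob("*")):
            if p.is_file():
                q = out2 / p.relative_to(out)
                assert filecmp.cmp(p, q, shallow=False), p.name

    def test_missing_input_names_stage(self, small_run, tmp_path):
        _, cfg, _ = small_run
        bad = dict(cfg)
        bad["mods_b"] = str(tmp_path / "absent.gff")
        with pytest.raises(PipelineError, match="modifications\\[bacteroid\\]"):
            run_pipeline(bad, tmp_path / "fail")
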
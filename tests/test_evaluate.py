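import numpy as np
import pandas as pd
import pytest

import redoxquant as rq
from redoxquant.simulate import SyntheticTruth


def make_truth(prot_rows, site_rows=()):
    return SyntheticTruth(
        proteins=pd.DataFrame(prot_rows, columns=["accession", "family", "true_log2fc"]),
        sites=pd.DataFrame(
            site_rows,
            columns=[
                "accession",
                "site_key",
                "occ_cond1",
                "occ_cond2",
                "true_log2_attenuation_diff",
                "true_site_log2fc",
            ],
        ),
        peptides=pd.DataFrame(columns=["sequence", "modifications", "accession", "start"]),
    )


def prot_results(rows):
    df = pd.DataFrame(rows, columns=["accession", "log2fc", "call"])
    df["tested"] = df["log2fc"].notna()
    return df


EMPTY_SITES = pd.DataFrame(
    columns=["accession", "site_key", "log2fc", "call", "tested"]
)


class TestScoring:
    def test_perfect_calls(self):
        truth = make_truth([("P1", 0, 2.0), ("P2", 1, 0.0)])
        results = prot_results([("P1", 2.0, "up"), ("P2", 0.0, "ns")])
        report = rq.score_against_truth(results, EMPTY_SITES, truth)
        assert report.abundance["power"] == 1.0
        assert report.abundance["empirical_fdr"] == 0.0
        assert report.abundance["log2fc_rmse"] == 0.0

    def test_all_ns_with_true_changes_zero_power(self):
        truth = make_truth([("P1", 0, 2.0), ("P2", 1, -2.0)])
        results = prot_results([("P1", 0.1, "ns"), ("P2", -0.1, "ns")])
        report = rq.score_against_truth(results, EMPTY_SITES, truth)
        assert report.abundance["power"] == 0.0

    def test_hand_built_confusion_arithmetic(self):
        # 2 TP, 1 FP, 1 FN over 4 features: power 2/3, FDR 1/3
        truth = make_truth(
            [("P1", 0, 2.0), ("P2", 1, 2.0), ("P3", 2, 2.0), ("P4", 3, 0.0)]
        )
        results = prot_results(
            [
                ("P1", 2.0, "up"),
                ("P2", 2.0, "up"),
                ("P3", 0.0, "ns"),   # missed change
                ("P4", 1.0, "up"),  # false positive
            ]
        )
        report = rq.score_against_truth(results, EMPTY_SITES, truth)
        assert report.abundance["power"] == pytest.approx(2 / 3)
        assert report.abundance["empirical_fdr"] == pytest.approx(1 / 3)
        assert report.abundance["n_true_positive"] == 2
        assert report.abundance["n_false_positive"] == 1
        assert report.abundance["n_false_negative"] == 1

    def test_wrong_direction_counts_as_false_positive(self):
        truth = make_truth([("P1", 0, 2.0)])
        results = prot_results([("P1", -2.0, "down")])
        report = rq.score_against_truth(results, EMPTY_SITES, truth)
        assert report.abundance["n_true_positive"] == 0
        assert report.abundance["n_false_positive"] == 1

    def test_unmatched_feature_raises_with_ids(self):
        truth = make_truth([("P1", 0, 0.0)])
        results = prot_results([("P1", 0.0, "ns"), ("GHOST", 0.0, "ns")])
        with pytest.raises(ValueError, match="GHOST"):
            rq.score_against_truth(results, EMPTY_SITES, truth)

    def test_confusion_margins_match_counts(self, default_dataset, default_run):
        prot, site, _ = default_run
        report = rq.score_against_truth(prot, site, default_dataset.truth)
        total = sum(
            v for by_truth in report.confusion["site"].values() for v in by_truth.values()
        )
        assert total == len(site)


def write_matrix_tsv(path, matrix):
    df = matrix.feature_meta[["accession"] + (["site_key"] if "site_key" in matrix.feature_meta else [])].copy()
    df = pd.concat([df.reset_index(drop=True), matrix.values.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False)
    return path


class TestRecount:
    def _planted_tables(self, tmp_path):
        """Noiseless simulation with exactly 10 planted upregulated families."""
        cfg = rq.SimConfig(
            n_proteins=30, n_strains=1, seed=21, noise_sd=0.0, missing_rate=0.0
        )
        rng = np.random.default_rng(cfg.seed)
        entries, families = rq.simulate_proteome(cfg, rng)
        assignments = rq.assign_truth(entries, families, cfg, rng)
        for fam in families:
            assignments.family_log2fc[fam] = 2.0 if fam < 10 else 0.0
            for key in list(assignments.site_occupancy):
                assignments.site_occupancy[key] = (0.0, 0.0)
        table, _ = rq.simulate_peptide_table(entries, families, assignments, cfg, rng)
        prot_matrix = rq.rollup_protein_abundance(table)
        site_matrix, _ = rq.rollup_cys_sites(table, rq.fasta_to_dict(entries))
        prot_path = write_matrix_tsv(tmp_path / "prot.tsv", prot_matrix)
        site_path = write_matrix_tsv(tmp_path / "site.tsv", site_matrix)
        return prot_path, site_path, rq.make_design(cfg)

    def test_planted_up_count_recovered(self, tmp_path):
        prot_path, site_path, design = self._planted_tables(tmp_path)
        cfg = rq.PipelineConfig(normalization="none")
        counts = rq.recount_published(prot_path, site_path, design, cfg)
        assert counts["n_up"] == 10
        assert counts["n_down"] == 0
        # all planted changes are pure abundance: no redox site passes
        assert counts["n_redox_sites"]["fold_change"] == 0
        assert counts["n_redox_sites"]["log2_fold_change"] == 0

    def test_null_table_all_counts_zero(self, tmp_path):
        design = rq.SampleDesign(
            [("g1", "glu", 1), ("g2", "glu", 2), ("g3", "glu", 3),
             ("l1", "lig", 1), ("l2", "lig", 2), ("l3", "lig", 3)]
        )
        df = pd.DataFrame({"accession": [f"P{i}" for i in range(8)]})
        for s in design.sample_ids:
            df[s] = 1000.0
        path = tmp_path / "null.tsv"
        df.to_csv(path, sep="\t", index=False)
        counts = rq.recount_published(path, None, design, rq.PipelineConfig())
        assert counts["n_up"] == 0 and counts["n_down"] == 0

    def test_missing_sample_column_explains_level(self, tmp_path):
        design = rq.SampleDesign(
            [("g1", "glu", 1), ("g2", "glu", 2), ("l1", "lig", 1), ("l2", "lig", 2)]
        )
        df = pd.DataFrame({"accession": ["P1"], "g1": [1.0], "g2": [1.0], "l1": [1.0]})
        path = tmp_path / "prot.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="l2"):
            rq.recount_published(path, None, design, rq.PipelineConfig())

    def test_column_mapping_adapts_foreign_layout(self, tmp_path):
        design = rq.SampleDesign(
            [("g1", "glu", 1), ("g2", "glu", 2), ("l1", "lig", 1), ("l2", "lig", 2)]
        )
        df = pd.DataFrame(
            {
                "Protein.ID": ["P1", "P2"],
                "Int_g1": [100.0, 100.0],
                "Int_g2": [110.0, 100.0],
                "Int_l1": [1000.0, 100.0],
                "Int_l2": [1100.0, 100.0],
            }
        )
        path = tmp_path / "foreign.tsv"
        df.to_csv(path, sep="\t", index=False)
        counts = rq.recount_published(
            path,
            None,
            design,
            rq.PipelineConfig(normalization="none"),
            column_map={
                "accession": "Protein.ID",
                "g1": "Int_g1",
                "g2": "Int_g2",
                "l1": "Int_l1",
                "l2": "Int_l2",
            },
        )
        assert counts["n_up"] == 1  # P1 is ~10-fold up, P2 flat
        assert counts["n_down"] == 0
        assert set(counts["s0_scan"]) == {0.0}

    def test_self_consistency_with_pipeline_tallies(
        self, tmp_path, default_dataset, default_database, default_run
    ):
        prot, site, _ = default_run
        cfg = rq.PipelineConfig()
        prot_matrix = rq.rollup_protein_abundance(default_dataset.table, cfg)
        site_matrix, _ = rq.rollup_cys_sites(default_dataset.table, default_database, cfg)
        prot_path = write_matrix_tsv(tmp_path / "prot.tsv", prot_matrix)
        site_path = write_matrix_tsv(tmp_path / "site.tsv", site_matrix)
        counts = rq.recount_published(prot_path, site_path, default_dataset.design, cfg)
        assert counts["n_up"] == (prot["call"] == "up").sum()
        assert counts["n_down"] == (prot["call"] == "down").sum()
        n_called = site["call"].isin(["less_oxidized", "more_oxidized"]).sum()
        assert counts["n_redox_sites"]["fold_change"] == n_called
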
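import math

import numpy as np
import pytest

import redoxquant as rq
from redoxquant.sites import PeptideIndex


NOISELESS = dict(noise_sd=0.0, missing_rate=0.0)


class TestProteome:
    def test_same_seed_identical_fasta_bytes(self, tmp_path):
        cfg = rq.SimConfig(n_proteins=5, seed=42)
        a = rq.write_fasta(rq.simulate_proteome(cfg)[0], tmp_path / "a.fasta")
        b = rq.write_fasta(rq.simulate_proteome(cfg)[0], tmp_path / "b.fasta")
        assert a.read_bytes() == b.read_bytes()

    def test_full_identity_homologs_identical(self):
        cfg = rq.SimConfig(n_proteins=4, n_strains=3, homolog_identity=1.0, seed=1)
        entries, families = rq.simulate_proteome(cfg)
        by_acc = {e.accession: e.sequence for e in entries}
        for members in families.values():
            seqs = {by_acc[m] for m in members}
            assert len(seqs) == 1

    def test_zero_identity_preserves_special_residues(self):
        cfg = rq.SimConfig(n_proteins=4, n_strains=2, homolog_identity=0.0, seed=2)
        entries, families = rq.simulate_proteome(cfg)
        by_acc = {e.accession: e.sequence for e in entries}
        for members in families.values():
            base, hom = by_acc[members[0]], by_acc[members[1]]
            assert len(base) == len(hom)
            for a, b in zip(base, hom):
                if a in "KRPC" or b in "KRPC":
                    assert a == b  # boundaries and Cys sites stay aligned
                else:
                    assert a != b

    def test_accessions_unique(self, default_dataset):
        accs = [e.accession for e in default_dataset.entries]
        assert len(set(accs)) == len(accs)


class TestPeptideTable:
    def test_same_seed_identical_table_bytes(self, tmp_path):
        cfg = rq.SimConfig(n_proteins=5, seed=9, missing_rate=0.3)
        a = rq.write_dataset(rq.simulate_dataset(cfg), tmp_path / "a")
        b = rq.write_dataset(rq.simulate_dataset(cfg), tmp_path / "b")
        for key in a:
            assert a[key].read_bytes() == b[key].read_bytes()

    def test_no_missing_when_rate_zero(self):
        ds = rq.simulate_dataset(rq.SimConfig(n_proteins=5, seed=3, missing_rate=0.0))
        n_samples = len(ds.design.sample_ids)
        assert all(len(o.intensities) == n_samples for o in ds.table.observations)

    def test_missingness_is_intensity_dependent(self):
        ds = rq.simulate_dataset(
            rq.SimConfig(n_proteins=40, seed=4, missing_rate=0.6, noise_sd=0.2)
        )
        rows = [
            (np.log2(np.mean(list(o.intensities.values()))), len(o.intensities))
            for o in ds.table.observations
            if o.intensities
        ]
        log_i = np.array([r[0] for r in rows])
        n_present = np.array([r[1] for r in rows])
        lo, hi = np.percentile(log_i, [25, 75])
        # faint peptides lose more values than bright ones
        assert n_present[log_i < lo].mean() < n_present[log_i > hi].mean()

    def test_shared_peptides_listed_for_all_strains(self):
        cfg = rq.SimConfig(n_proteins=4, n_strains=3, homolog_identity=1.0, seed=5, **NOISELESS)
        ds = rq.simulate_dataset(cfg)
        # identical homologs: every peptide maps to all 3 strain copies
        for obs in ds.table.observations:
            fams = {acc[:6] for acc in obs.proteins}
            assert len(obs.proteins) >= 3 or len(fams) > 1

    def test_truth_covers_all_pipeline_features(self, default_dataset, default_database, default_run):
        prot, site, _ = default_run
        # score_against_truth raises if any feature misses a truth record
        report = rq.score_against_truth(prot, site, default_dataset.truth)
        assert 0 <= report.abundance["empirical_fdr"] <= 1
        assert 0 <= report.redox["empirical_fdr"] <= 1

    def test_every_emitted_peptide_traceable(self, default_dataset, default_database):
        index = PeptideIndex(default_database)
        truth_keys = set(
            zip(default_dataset.truth.peptides["sequence"], default_dataset.truth.peptides["accession"])
        )
        for obs in default_dataset.table.observations:
            hits = index.map_peptide(obs.sequence)
            assert hits, obs.sequence
            assert any((obs.sequence, acc) in truth_keys for acc, _ in hits)


class TestGroundTruthRecovery:
    def test_noiseless_abundance_recovery_exact(self):
        cfg = rq.SimConfig(
            n_proteins=15, seed=1, frac_sites_redox_changed=0.0, **NOISELESS
        )
        ds = rq.simulate_dataset(cfg)
        prot, _, _ = rq.analyze(
            ds.table,
            rq.fasta_to_dict(ds.entries),
            ds.design,
            rq.PipelineConfig(normalization="none"),
        )
        merged = prot.reset_index().merge(ds.truth.proteins, on="accession")
        assert len(merged) == len(prot)
        assert np.abs(merged["log2fc"] - merged["true_log2fc"]).max() < 1e-9

    def test_median_centering_shifts_all_features_equally(self):
        # with centering on, estimates differ from truth by one global constant
        cfg = rq.SimConfig(
            n_proteins=15, seed=1, frac_sites_redox_changed=0.0, **NOISELESS
        )
        ds = rq.simulate_dataset(cfg)
        prot, _, _ = rq.analyze(
            ds.table, rq.fasta_to_dict(ds.entries), ds.design, rq.PipelineConfig()
        )
        merged = prot.reset_index().merge(ds.truth.proteins, on="accession")
        shifts = merged["log2fc"] - merged["true_log2fc"]
        assert shifts.max() - shifts.min() < 1e-9

    def test_occupancy_attenuation_closed_form(self):
        # occupancy 0 -> 0.5 on an abundance-stable protein halves the
        # alkylated intensity: signed fold change is exactly -2
        cfg = rq.SimConfig(
            n_proteins=15,
            seed=2,
            frac_abundance_changed=0.0,
            frac_sites_redox_changed=0.25,
            oxidation_occupancy=0.5,
            **NOISELESS,
        )
        ds = rq.simulate_dataset(cfg)
        _, site, _ = rq.analyze(
            ds.table,
            rq.fasta_to_dict(ds.entries),
            ds.design,
            rq.PipelineConfig(normalization="none"),
        )
        merged = site.reset_index(drop=True).merge(
            ds.truth.sites, on=["accession", "site_key"]
        )
        oxidized = merged[(merged["occ_cond1"] == 0) & (merged["occ_cond2"] == 0.5)]
        reduced = merged[(merged["occ_cond1"] == 0.5) & (merged["occ_cond2"] == 0)]
        assert len(oxidized) and len(reduced)
        assert np.allclose(oxidized["fold_change_signed"], -2.0, atol=1e-9)
        assert (oxidized["call"] == "more_oxidized").all()
        assert np.allclose(reduced["fold_change_signed"], 2.0, atol=1e-9)
        assert (reduced["call"] == "less_oxidized").all()

    def test_unchanged_occupancy_site_tracks_protein_abundance(self):
        cfg = rq.SimConfig(
            n_proteins=10, seed=6, frac_sites_redox_changed=0.0, **NOISELESS
        )
        ds = rq.simulate_dataset(cfg)
        _, site, _ = rq.analyze(
            ds.table,
            rq.fasta_to_dict(ds.entries),
            ds.design,
            rq.PipelineConfig(normalization="none"),
        )
        merged = site.reset_index(drop=True).merge(ds.truth.sites, on=["accession", "site_key"])
        truth_prot = ds.truth.proteins.set_index("accession")["true_log2fc"]
        expected = merged["accession"].map(truth_prot)
        assert np.abs(merged["log2fc"] - expected).max() < 1e-9

    def test_parameter_recovery_under_noise(self):
        cfg = rq.SimConfig(
            n_proteins=200, n_strains=1, seed=7, noise_sd=0.25, missing_rate=0.0
        )
        ds = rq.simulate_dataset(cfg)
        prot, _, _ = rq.analyze(
            ds.table,
            rq.fasta_to_dict(ds.entries),
            ds.design,
            rq.PipelineConfig(normalization="none"),
        )
        merged = prot.reset_index().merge(ds.truth.proteins, on="accession")
        mae = np.median(np.abs(merged["log2fc"] - merged["true_log2fc"]))
        assert mae < 3 * 0.25 / math.sqrt(3)


class TestTruthIO:
    def test_truth_round_trips(self, tmp_path, default_dataset):
        path = rq.write_truth(default_dataset.truth, tmp_path / "truth.tsv")
        back = rq.read_truth(path)
        for name in ("proteins", "sites", "peptides"):
            orig = getattr(default_dataset.truth, name).reset_index(drop=True)
            got = getattr(back, name).reset_index(drop=True)
            assert list(got.columns) == list(orig.columns)
            assert len(got) == len(orig)
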
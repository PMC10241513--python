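"""The generator must honour its own invariants: binary inbred calls, MAF
floor, ordered positions, cluster-structured kinship, determinism, and a
planted architecture whose truth object matches what was planted."""

import numpy as np
import pandas as pd
import pytest

from pqtlmap import assoc, simdata


class TestSimulatePanel:
    def test_homozygous_binary_and_maf_floor(self, small_panel):
        assert set(np.unique(small_panel.alleles)) <= {0, 1}
        assert small_panel.maf().min() >= 0.05

    def test_positions_strictly_increasing_within_chrom(self, small_panel):
        for c in np.unique(small_panel.chrom):
            pos = small_panel.pos_bp[small_panel.chrom == c]
            assert np.all(np.diff(pos) > 0)

    def test_deterministic_for_fixed_seed(self):
        a = simdata.simulate_panel(n_strains=20, n_markers=100, seed=7)
        b = simdata.simulate_panel(n_strains=20, n_markers=100, seed=7)
        assert np.array_equal(a.alleles, b.alleles)
        assert np.array_equal(a.pos_bp, b.pos_bp)
        c = simdata.simulate_panel(n_strains=20, n_markers=100, seed=8)
        assert not np.array_equal(a.alleles, c.alleles)

    def test_cluster_structure_in_kinship(self, small_panel, small_kinship):
        clusters = np.arange(small_panel.n_strains) % 6
        K = small_kinship.matrix
        iu = np.triu_indices(small_panel.n_strains, k=1)
        same = clusters[iu[0]] == clusters[iu[1]]
        assert K[iu][same].mean() > K[iu][~same].mean()

    def test_single_cluster_kinship_near_identity(self):
        panel = simdata.simulate_panel(n_strains=40, n_markers=2000, n_clusters=1, seed=3)
        K = assoc.compute_kinship(panel).matrix
        off = K[np.triu_indices(40, k=1)]
        assert abs(off.mean()) < 0.05

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_clusters": 100, "n_strains": 10},
            {"maf_range": (0.0, 0.5)},
            {"maf_range": (0.4, 0.2)},
            {"n_markers": 0},
        ],
    )
    def test_invalid_configuration_rejected(self, kwargs):
        with pytest.raises(simdata.ConfigurationError):
            simdata.simulate_panel(**kwargs)


class TestPlantArchitecture:
    def test_truth_matches_design(self, planted):
        abundance, annotation, truth = planted
        assert len(truth.hotspot_markers) == 3
        sizes = {
            lab: sum(1 for f, l in truth.module_membership.items() if l == lab and f.startswith(lab))
            for lab in truth.hotspot_markers
        }
        assert sizes == {"brown": 26, "green": 22, "turquoise": 26}

    def test_mediator_gene_within_cis_window(self, small_panel, planted):
        _, annotation, truth = planted
        for label, mid in truth.hotspot_markers.items():
            j = small_panel.marker_index(mid)
            med = truth.mediator_ids[label]
            assert str(annotation.loc[med, "gene_chrom"]) == str(small_panel.chrom[j])
            assert abs(int(annotation.loc[med, "gene_pos_bp"]) - int(small_panel.pos_bp[j])) <= 1_000_000

    def test_targets_annotated_on_other_chromosomes(self, small_panel, planted):
        _, annotation, truth = planted
        for label, mid in truth.hotspot_markers.items():
            hs_chrom = str(small_panel.chrom[small_panel.marker_index(mid)])
            for f, lab in truth.module_membership.items():
                if lab == label and f != truth.mediator_ids[label]:
                    assert str(annotation.loc[f, "gene_chrom"]) != hs_chrom

    def test_low_maf_hotspot_marker_refused(self, small_panel):
        maf = small_panel.maf()
        rare = small_panel.marker_ids[int(np.argmin(maf))]
        design = simdata.ArchitectureDesign(
            hotspots=[simdata.HotspotSpec(chrom="1", n_targets=5, module_label="x", marker_id=rare)]
        )
        with pytest.raises(simdata.ArchitectureError):
            simdata.plant_architecture(small_panel, design, seed=0)

    def test_missingness_rate_near_nominal(self, planted):
        abundance, _, _ = planted
        frac = abundance.isna().to_numpy().mean()
        assert 0.07 < frac < 0.13


class TestSimulateTrait:
    def test_sign_propagation_and_determinism(self, rng):
        driver = rng.normal(size=80)
        t_neg = simdata.simulate_trait(driver, gamma=-1.0, noise_sd=0.1, seed=5)
        assert np.corrcoef(driver, t_neg)[0, 1] < -0.9
        again = simdata.simulate_trait(driver, gamma=-1.0, noise_sd=0.1, seed=5)
        assert np.array_equal(t_neg.to_numpy(), again.to_numpy())

    def test_empty_driver_rejected(self):
        with pytest.raises(simdata.ConfigurationError):
            simdata.simulate_trait(np.array([]), gamma=1.0)

    def test_power_at_reference_conditions(self):
        # gamma=1, noise 0.5, n=96: the allele-stratified difference is
        # detectable at p<0.05 in nearly all replicates (checked on 40 here).
        from pqtlmap import traitlink

        panel = simdata.simulate_panel(n_strains=96, n_markers=50, seed=2)
        g = panel.alleles[:, 0].astype(float)
        hits = 0
        for s in range(40):
            trait = simdata.simulate_trait(g, gamma=1.0, noise_sd=0.5, seed=s)
            comp = traitlink.genotype_stratify(trait.to_numpy(), panel, panel.marker_ids[0])
            hits += comp.p < 0.05
        assert hits >= 38


class TestDOLocus:
    def test_diploid_rows_and_determinism(self):
        dos, med, targets = simdata.simulate_do_locus(n_mice=200, seed=9)
        assert dos.dosages.shape == (200, 8)
        assert np.allclose(dos.dosages.sum(axis=1), 2.0)
        assert np.all((dos.dosages >= 0) & (dos.dosages <= 2))
        dos2, med2, _ = simdata.simulate_do_locus(n_mice=200, seed=9)
        assert np.array_equal(dos.dosages, dos2.dosages)
        assert np.array_equal(med.to_numpy(), med2.to_numpy())

    def test_nonzero_sum_effects_centred_with_warning(self):
        with pytest.warns(UserWarning, match="centring"):
            dos, med, _ = simdata.simulate_do_locus(
                n_mice=100, founder_effects=np.ones(8), seed=1, n_targets=1, n_background=0
            )

    def test_null_locus_gives_no_signal(self):
        from pqtlmap import mediation

        n = 300
        all_lods = []
        for seed in range(5):
            dos, med, targets = simdata.simulate_do_locus(
                n_mice=n, founder_effects=np.zeros(8), seed=seed
            )
            L = mediation.dosage_design(dos)
            X1 = np.hstack([np.ones((n, 1)), L])
            all_lods += [
                mediation.lod_linear(targets.loc[t].to_numpy(), X1, np.ones((n, 1)))
                for t in targets.index
                if t.startswith("target")
            ]
        # a 7-d.f. locus term has null expectation LRT ~ 7, i.e. LOD ~ 1.5;
        # no null target should approach the LOD > 6 significance bar
        assert np.mean(all_lods) < 2.5
        assert max(all_lods) < 6.0

    def test_target_lod_below_mediator_lod(self):
        from pqtlmap import mediation

        dos, med, targets = simdata.simulate_do_locus(n_mice=500, seed=6)
        L = mediation.dosage_design(dos)
        X1 = np.hstack([np.ones((500, 1)), L])
        X0 = np.ones((500, 1))
        lod_med = mediation.lod_linear(med.to_numpy(), X1, X0)
        for tid in targets.index:
            if tid.startswith("target"):
                assert mediation.lod_linear(targets.loc[tid].to_numpy(), X1, X0) < lod_med


def test_polygenic_null_trait_heritability_scaling():
    panel = simdata.simulate_panel(n_strains=100, n_markers=500, seed=13)
    y = simdata.simulate_polygenic(panel, h2=0.5, seed=13)
    assert y.shape == (100,)
    assert 0.5 < y.std() < 1.5
    with pytest.raises(simdata.ConfigurationError):
        simdata.simulate_polygenic(panel, h2=1.5)
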
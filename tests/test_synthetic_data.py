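import numpy as np
import pytest

from mfhcc import clonality as cl
from mfhcc import synthetic_data as sd
from mfhcc import variant_model as vm


class TestGenome:
    def test_deterministic_and_indexable(self, tmp_path):
        g1 = sd.synthetic_genome(n_contigs=3, contig_length=5_000, seed=4)
        g2 = sd.synthetic_genome(n_contigs=3, contig_length=5_000, seed=4)
        assert g1 == g2
        assert set(g1) == {"ctg1", "ctg2", "ctg3"}
        path = sd.write_synthetic_reference(g1, tmp_path / "ref.fa")
        import pyfaidx

        fa = pyfaidx.Fasta(str(path))
        assert str(fa["ctg2"][10:20]) == g1["ctg2"][10:20]


class TestPairMutations:
    def test_mo_without_chance_overlap_has_zero_jaccard(self, rng, small_genome):
        config = sd.SimulationConfig(chance_overlap_rate_mo=0.0)
        va, vb, truth = sd.simulate_pair_mutations("MO", config, rng, genome=small_genome)
        ka = {vm.variant_key(v) for v in va}
        kb = {vm.variant_key(v) for v in vb}
        assert cl.jaccard_index(ka, kb) == 0.0
        assert truth["n_shared"] == 0

    def test_truth_counts_match_set_cardinalities(self, rng, small_genome):
        config = sd.SimulationConfig()
        used = set()
        for pattern in ("IM", "MO", "IM"):
            va, vb, truth = sd.simulate_pair_mutations(
                pattern, config, rng, genome=small_genome, used_positions=used
            )
            ka = {vm.variant_key(v) for v in va}
            kb = {vm.variant_key(v) for v in vb}
            shared, pa, pb = cl.shared_private_partition(ka, kb)
            assert len(shared) == truth["n_shared"]
            assert len(pa) == truth["n_private_a"]
            assert len(pb) == truth["n_private_b"]
            assert len(ka | kb) == truth["n_union"]

    def test_im_expected_union_near_107(self, small_genome):
        """Poisson(82) trunk + 2 x Poisson(12.5) privates: E[union] = 107."""
        rng = np.random.default_rng(55)
        config = sd.SimulationConfig()
        unions = []
        for _ in range(400):
            _, _, truth = sd.simulate_pair_mutations(
                "IM", config, rng, genome=small_genome, used_positions=set()
            )
            unions.append(truth["n_union"])
        se = np.sqrt(107 / 400)  # var of a Poisson sum
        assert abs(np.mean(unions) - 107) < 3 * se

    def test_seed_determinism(self, small_genome):
        config = sd.SimulationConfig()
        out = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            va, vb, truth = sd.simulate_pair_mutations(
                "IM", config, rng, genome=small_genome, used_positions=set()
            )
            out.append((va, vb, truth))
        assert out[0] == out[1]

    def test_unknown_pattern_rejected(self, rng, small_genome):
        with pytest.raises(ValueError):
            sd.simulate_pair_mutations("XX", sd.SimulationConfig(), rng, genome=small_genome)


@pytest.fixture(scope="module")
def cohort(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("cohort")
    config = sd.SimulationConfig(n_patients=8, seed=7)
    manifest = sd.simulate_cohort(config, outdir)
    return config, manifest, outdir


class TestCohort:
    def test_group_allocation(self, cohort):
        config, manifest, _ = cohort
        assert manifest["n_im"] == round(config.prop_im * config.n_patients)
        assert manifest["n_im"] + manifest["n_mo"] == config.n_patients

    def test_all_mo_when_prop_zero(self, tmp_path):
        config = sd.SimulationConfig(n_patients=5, prop_im=0.0, seed=1)
        manifest = sd.simulate_cohort(config, tmp_path / "mo")
        assert manifest["n_im"] == 0
        assert set(manifest["truth_frame"]["pattern"]) == {"MO"}

    def test_emitted_files_reparse_cleanly(self, cohort, recwarn):
        import warnings

        _, manifest, outdir = cohort
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # any parser warning fails
            groups = vm.read_maf(manifest["maf"])
            clinical = vm.read_clinical(manifest["clinical"])
            for lesion in groups:
                vm.read_segments(outdir / "seg" / f"{lesion}.seg")
                meta = vm.read_sample_sidecar(outdir / "seg" / f"{lesion}.json")
                assert meta["ploidy"] > 0
        assert len(groups) == 2 * len(clinical)

    def test_truth_counts_match_files(self, cohort):
        _, manifest, _ = cohort
        groups = vm.read_maf(manifest["maf"])
        truth = manifest["truth_frame"]
        for row in truth.itertuples(index=False):
            ka = {vm.variant_key(v) for v in groups[f"{row.patient_id}_A"]}
            kb = {vm.variant_key(v) for v in groups[f"{row.patient_id}_B"]}
            shared, pa, pb = cl.shared_private_partition(ka, kb)
            # drivers are added on top of the counted background mutations
            assert len(shared) >= row.n_shared
            assert len(shared) - row.n_shared <= 2
            assert len(pa) - row.n_private_a <= 2

    def test_cohort_rerun_is_byte_identical(self, tmp_path):
        config = sd.SimulationConfig(n_patients=4, seed=11)
        sd.simulate_cohort(config, tmp_path / "a")
        sd.simulate_cohort(config, tmp_path / "b")
        for name in ("cohort.maf", "clinical.csv", "truth.csv", "reference.fa"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_im_survival_shorter(self, tmp_path):
        """Higher IM hazard (median ln2/lambda = 24 vs 60 months) shows in PFS."""
        config = sd.SimulationConfig(n_patients=200, seed=3)
        manifest = sd.simulate_cohort(config, tmp_path / "surv")
        clinical = vm.read_clinical(manifest["clinical"])
        truth = manifest["truth_frame"]
        merged = clinical.merge(truth, on="patient_id")
        med = merged.groupby("pattern")["pfs_months"].median()
        assert med["IM"] < med["MO"]
        # the shorter-lived group also accumulates more observed events
        events = merged.groupby("pattern")["event"].mean()
        assert events["IM"] > events["MO"]


class TestRenderer:
    def test_mask_component_count(self, rng):
        r = sd.render_nucleus_tile(sd.ImagePairParams(side_px=256), rng, n_nuclei=10)
        from skimage import measure

        assert measure.label(r.mask > 0).max() == 10
        assert len(r.truth) == 10

    def test_circular_nuclei_area_analytic(self):
        params = sd.ImagePairParams(
            side_px=384, radius_sd_um=0.0, eccentricity_range=(1.0, 1.0)
        )
        rng = np.random.default_rng(13)
        r = sd.render_nucleus_tile(params, rng, n_nuclei=6, radius_mean_um=5.0)
        analytic = np.pi * 5.0**2
        for area in r.truth["area_um2"]:
            assert area == pytest.approx(analytic, rel=0.05)

    def test_truth_matches_mask_exactly(self, rng):
        r = sd.render_nucleus_tile(sd.ImagePairParams(side_px=256), rng, n_nuclei=7)
        for row in r.truth.itertuples(index=False):
            sel = r.mask == row.label
            assert row.area_um2 == sel.sum() * r.tile.mpp**2
            rgb = r.tile.pixels[sel].astype(float)
            assert row.rmean == pytest.approx(rgb[:, 0].mean())

    def test_seed_determinism(self):
        tiles = [
            sd.render_nucleus_tile(
                sd.ImagePairParams(side_px=128), np.random.default_rng(42), n_nuclei=5
            )
            for _ in range(2)
        ]
        np.testing.assert_array_equal(tiles[0].tile.pixels, tiles[1].tile.pixels)
        np.testing.assert_array_equal(tiles[0].mask, tiles[1].mask)

    def test_infeasible_count_raises(self, rng):
        params = sd.ImagePairParams(side_px=128)
        with pytest.raises(RuntimeError, match="place"):
            sd.render_nucleus_tile(params, rng, n_nuclei=400, radius_mean_um=8.0)


class TestFocusPairImages:
    def test_im_foci_share_morphology(self):
        params = sd.ImagePairParams(side_px=384, n_nuclei_range=(6, 12))
        ra, rb = sd.simulate_focus_pair_images("IM", params, np.random.default_rng(1))
        # shared parameter draw: same nucleus count and similar mean color
        assert len(ra.truth) == len(rb.truth)
        assert abs(ra.truth["bmean"].mean() - rb.truth["bmean"].mean()) < 15

    def test_determinism(self):
        params = sd.ImagePairParams(side_px=384, n_nuclei_range=(6, 12))
        a1, _ = sd.simulate_focus_pair_images("MO", params, np.random.default_rng(3))
        a2, _ = sd.simulate_focus_pair_images("MO", params, np.random.default_rng(3))
        np.testing.assert_array_equal(a1.tile.pixels, a2.tile.pixels)
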
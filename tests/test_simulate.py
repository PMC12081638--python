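"""Generator ground truth, determinism and validation."""

import numpy as np
import pandas as pd
import pytest

from radscreen import simulate as sim


def _run_plate(seed=0):
    return sim.simulate_plate(sim.PlateSimSpec(seed=seed))


def _run_image(seed=0):
    spec = sim.random_colony_spec(5, seed=seed, noise_sd=20.0)
    return sim.simulate_colony_image(spec)[0]


def _run_flow(seed=0):
    return sim.simulate_dna_content(sim.DnaContentSpec(seed=seed))[0]


def _run_counts(seed=0):
    return sim.simulate_counts(sim.CountsSimSpec(n_genes=200, seed=seed))[0]


@pytest.mark.parametrize(
    "generator", [_run_plate, _run_image, _run_flow, _run_counts],
    ids=["plate", "image", "flow", "counts"],
)
def test_seeded_determinism(generator):
    first, second = generator(seed=42), generator(seed=42)
    if isinstance(first, pd.DataFrame):
        pd.testing.assert_frame_equal(first, second)
    else:
        np.testing.assert_array_equal(first, second)
    third = generator(seed=43)
    if isinstance(first, pd.DataFrame):
        assert not first.equals(third)
    else:
        assert not np.array_equal(first, third)


class TestPlateSim:
    def test_emits_all_condition_types(self):
        table = sim.simulate_plate(sim.PlateSimSpec(n_replicate_wells=3, n_experiments=2))
        assert len(table) == 4 * 3 * 2
        ctrl = table[(table.drug_a_conc_uM == 0) & (table.drug_b_conc_uM == 0) & (table.dose_Gy == 0)]
        assert len(ctrl) == 6
        assert table["experiment_id"].nunique() == 2

    def test_noise_free_signals_match_planted_viability(self):
        spec = sim.PlateSimSpec(interaction_factor=4.0, noise_cv=0.0, seed=1)
        table = sim.simulate_plate(spec)
        combo = table[(table.drug_a_conc_uM > 0) & (table.drug_b_conc_uM > 0)]
        expected = 0.8 * 0.5 / 4.0 * spec.control_signal
        assert np.allclose(combo["raw_signal"], expected)

    def test_radiation_labels(self):
        table = sim.simulate_plate(sim.PlateSimSpec(b_is_radiation=True, b_dose_Gy=2.0))
        assert (table["drug_b_conc_uM"] == 0).all()
        assert set(table["dose_Gy"].unique()) == {0.0, 2.0}

    @pytest.mark.parametrize(
        "field,value",
        [
            ("drug_a_viability", 1.5),
            ("interaction_factor", 0.0),
            ("noise_cv", -0.1),
            ("n_replicate_wells", 0),
        ],
    )
    def test_validation_names_offending_field(self, field, value):
        spec = sim.PlateSimSpec(**{field: value})
        with pytest.raises(ValueError, match=field):
            sim.simulate_plate(spec)


class TestColonyImageSim:
    def test_zero_colonies_gives_blank_gradient(self):
        image, truth = sim.simulate_colony_image(sim.ColonyImageSpec(colonies=[]))
        assert truth.empty
        assert np.ptp(image) <= sim.ColonyImageSpec().background_gradient + 1e-9

    def test_disk_area_matches_geometry(self):
        radius_um = 60.0
        spec = sim.ColonyImageSpec(colonies=[((100, 100), radius_um, 1000.0)])
        _, truth = sim.simulate_colony_image(spec)
        analytic = np.pi * radius_um**2
        # pixel quantization: error bounded by the boundary band (~perimeter px)
        radius_px = radius_um / spec.pixel_size_um
        tol = 2 * np.pi * radius_px * spec.pixel_size_um**2
        assert abs(truth.loc[0, "area_um2"] - analytic) <= tol
        assert truth.loc[0, "circularity"] == 1.0

    def test_overlapping_disks_are_flagged(self):
        spec = sim.ColonyImageSpec(
            colonies=[((100, 100), 50.0, 1000.0), ((100, 112), 50.0, 1000.0),
                      ((300, 300), 50.0, 1000.0)]
        )
        _, truth = sim.simulate_colony_image(spec)
        assert truth["overlaps"].tolist() == [True, True, False]

    def test_center_outside_image_rejected(self):
        spec = sim.ColonyImageSpec(colonies=[((600, 100), 50.0, 1000.0)])
        with pytest.raises(ValueError, match="center"):
            sim.simulate_colony_image(spec)

    def test_random_spec_colonies_disjoint(self):
        spec = sim.random_colony_spec(15, seed=3)
        _, truth = sim.simulate_colony_image(spec)
        assert not truth["overlaps"].any()

    def test_tiff_roundtrip(self, tmp_path):
        import tifffile

        image, truth = sim.simulate_colony_image(sim.random_colony_spec(3, seed=1))
        path = sim.write_colony_image(image, truth, tmp_path / "well.tiff")
        read_back = tifffile.imread(path)
        assert read_back.dtype == np.uint16
        assert np.allclose(read_back, np.rint(image))


class TestDnaContentSim:
    def test_fractions_recovered_within_binomial_error(self):
        fractions = (0.10, 0.60, 0.10, 0.20)
        spec = sim.DnaContentSpec(n_events=20000, fractions=fractions, seed=9)
        events, truth = sim.simulate_dna_content(spec)
        se = np.sqrt(0.10 * 0.90 / spec.n_events)
        below = np.mean(events < 0.8 * spec.g1_mode)
        assert abs(below - 0.10) <= 3 * se + 1e-6
        assert truth["g2m_mode"] == 2 * truth["g1_mode"]

    def test_pure_g1_population_sits_at_mode(self):
        spec = sim.DnaContentSpec(fractions=(0, 1, 0, 0), g1_mode=200.0, seed=2)
        events, _ = sim.simulate_dna_content(spec)
        assert np.all(np.abs(events - 200.0) < 5 * 0.05 * 200.0)

    def test_subg1_component_strictly_below_g1(self):
        spec = sim.DnaContentSpec(fractions=(1, 0, 0, 0), seed=4)
        events, _ = sim.simulate_dna_content(spec)
        assert events.max() < spec.g1_mode

    def test_tiny_n_rejected(self):
        with pytest.raises(ValueError, match="n_events"):
            sim.simulate_dna_content(sim.DnaContentSpec(n_events=50))

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="fractions"):
            sim.simulate_dna_content(sim.DnaContentSpec(fractions=(0.5, 0.5, 0.5, 0.5)))


class TestCountsSim:
    def test_integer_counts_and_sheet(self):
        counts, samples, gene_sets = sim.simulate_counts(sim.CountsSimSpec(n_genes=100, seed=5))
        assert counts.shape == (100, 6)
        assert (counts.to_numpy() >= 0).all()
        assert np.issubdtype(counts.to_numpy().dtype, np.integer)
        assert samples["group"].value_counts().to_dict() == {"group1": 3, "group2": 3}
        assert all(name.startswith("DECOY") for name in gene_sets)

    def test_duplicate_genes_in_planted_set_rejected(self):
        spec = sim.CountsSimSpec(planted_sets=[("S", ["G00001", "G00001"], 1.0)])
        with pytest.raises(ValueError, match="duplicate"):
            sim.simulate_counts(spec)

    def test_unknown_gene_in_planted_set_rejected(self):
        spec = sim.CountsSimSpec(n_genes=100, planted_sets=[("S", ["NOPE"], 1.0)])
        with pytest.raises(ValueError, match="unknown gene"):
            sim.simulate_counts(spec)

    def test_planted_effect_raises_group2_counts(self):
        members = [f"G{i:05d}" for i in range(1, 51)]
        spec = sim.CountsSimSpec(planted_sets=[("S", members, 2.0)], seed=6)
        counts, samples, _ = sim.simulate_counts(spec)
        g1 = samples.loc[samples.group == "group1", "sample"]
        g2 = samples.loc[samples.group == "group2", "sample"]
        planted = counts.loc[members]
        ratio = (planted[g2].mean(axis=1) + 1) / (planted[g1].mean(axis=1) + 1)
        assert np.median(ratio) > 2.0  # planted 4x shift dominates noise

    def test_bundle_written(self, tmp_path):
        counts, samples, gene_sets = sim.simulate_counts(sim.CountsSimSpec(n_genes=50, seed=1))
        paths = sim.write_counts_bundle(counts, samples, gene_sets, tmp_path)
        assert all(p.exists() for p in paths.values())
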
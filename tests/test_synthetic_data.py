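"""Generator contracts: doping statistics, fitness, selection, reads, plates."""

import numpy as np
import pytest
from scipy import stats

import selexa as sx
from selexa import library_stats as ls
from selexa import synthetic_data as sd


def small_design(reference="ACGTACGTAC", region=(0, 10)):
    return sx.ReferenceDesign(reference=reference, mutagenized_region=region)


class TestGenerateDopedLibrary:
    def test_mu_zero_reproduces_reference(self, design):
        spec = sd.DopedLibrarySpec(design=design, mu=0.0, n_molecules=50, seed=1)
        assert set(sd.generate_doped_library(spec)) == {design.reference}

    def test_mu_one_single_position_never_reference(self):
        d = sx.ReferenceDesign(reference="ACGTACGTAC", mutagenized_region=(3, 4))
        spec = sd.DopedLibrarySpec(design=d, mu=1.0, n_molecules=200, seed=2)
        for seq in sd.generate_doped_library(spec):
            assert seq[3] != "T"
            assert seq[:3] == "ACG" and seq[4:] == "ACGTAC"

    def test_mean_distance_matches_binomial_expectation(self, design):
        # E[d] = L * mu = 85 * 0.21 = 17.85; SE of the mean over n = 10000
        spec = sd.DopedLibrarySpec(design=design, mu=0.21, n_molecules=10_000, seed=3)
        seqs = sd.generate_doped_library(spec)
        table = sx.count_unique(seqs)
        mean = ls.distance_spectrum(table, design).mean
        se = np.sqrt(85 * 0.21 * 0.79) / np.sqrt(10_000)
        assert abs(mean - 17.85) < 3 * se

    def test_per_position_rate_and_distance_distribution(self, design):
        spec = sd.DopedLibrarySpec(design=design, mu=0.21, n_molecules=10_000, seed=4)
        arr = sd.encode_sequences(sd.generate_doped_library(spec))
        ref = sd.encode_sequences([design.reference])[0]
        mism = (arr[:, :85] != ref[:85])
        # per-position empirical rate within 3 SE of mu at every position
        se_pos = np.sqrt(0.21 * 0.79 / 10_000)
        assert np.all(np.abs(mism.mean(axis=0) - 0.21) < 4 * se_pos)
        assert abs(mism.mean() - 0.21) < 3 * se_pos / np.sqrt(85)
        # distance histogram consistent with Binomial(85, 0.21), chi-square alpha=0.01
        d = mism.sum(axis=1)
        lo, hi = 8, 29  # bins with expected count >= 5 pooled at the tails
        obs = np.array(
            [np.sum(d <= lo)]
            + [np.sum(d == k) for k in range(lo + 1, hi)]
            + [np.sum(d >= hi)]
        )
        binom = stats.binom(85, 0.21)
        exp = np.array(
            [binom.cdf(lo)]
            + [binom.pmf(k) for k in range(lo + 1, hi)]
            + [binom.sf(hi - 1)]
        ) * 10_000
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert chi2 < stats.chi2(len(obs) - 1).ppf(0.99)

    def test_reproducible_under_seed(self, design):
        spec = sd.DopedLibrarySpec(design=design, n_molecules=100, seed=11)
        assert sd.generate_doped_library(spec) == sd.generate_doped_library(spec)

    def test_invalid_mu_rejected(self, design):
        with pytest.raises(ValueError):
            sd.DopedLibrarySpec(design=design, mu=1.5)


class TestSequenceFitness:
    def test_reference_has_fitness_one(self, design, full_model):
        assert sx.sequence_fitness(design.reference, full_model) == 1.0

    def test_single_conserved_violation_pays_penalty(self, design, full_model):
        pos, base = next(iter(full_model.conserved))
        other = next(b for b in "ACGT" if b != base)
        mutant = design.reference[:pos] + other + design.reference[pos + 1 :]
        assert sx.sequence_fitness(mutant, full_model) == pytest.approx(0.05)

    def test_compensatory_pair_mutation_is_rescued(self, design, full_model):
        # disrupt then restore the 17-40 pair (1-based): e.g. 17C with 40G
        i, j = 16, 39
        ref = design.reference
        single = ref[:i] + "C" + ref[i + 1 :]
        double = single[:j] + "G" + single[j + 1 :]
        assert sx.sequence_fitness(single, full_model) == pytest.approx(0.05)
        assert sx.sequence_fitness(double, full_model) == 1.0

    def test_length_mismatch_raises(self, full_model):
        with pytest.raises(ValueError, match="length"):
            sx.sequence_fitness("ACGT", full_model)

    def test_no_shared_positions_between_pairs(self):
        with pytest.raises(ValueError, match="two pairs"):
            sd.FitnessModel(pairs=frozenset({(1, 5), (5, 9)}))


class TestRunSelection:
    def test_neutral_selection_preserves_distance(self, design):
        model = sd.FitnessModel(capture=0.5)
        spec = sd.DopedLibrarySpec(design=design, n_molecules=20_000, seed=5)
        traj = sd.run_selection(spec, model, n_rounds=3, seed=5)
        se = np.sqrt(85 * 0.21 * 0.79) / np.sqrt(20_000)
        for table in traj.rounds:
            mean = ls.distance_spectrum(table, design).mean
            # resampling inflates the variance of late-round means
            assert abs(mean - 17.85) < 3 * se * np.sqrt(len(traj.rounds))

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_planted_selection_enriches_constraint_satisfiers(self, design, pair_model, seed):
        spec = sd.DopedLibrarySpec(design=design, n_molecules=20_000, seed=seed)
        traj = sd.run_selection(spec, pair_model, n_rounds=5, seed=seed)
        fracs = []
        for table in traj.rounds:
            good = sum(
                c
                for s, c in table.counts.items()
                if sx.sequence_fitness(s, pair_model) == 1.0
            )
            fracs.append(good / table.total)
        # strictly increasing until the pool saturates at all-satisfiers
        assert all(b > a or a == 1.0 for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] > fracs[0]
        d0 = ls.distance_spectrum(traj.rounds[0], design).mean
        d5 = ls.distance_spectrum(traj.rounds[-1], design).mean
        assert d0 != d5

    def test_hard_selection_leaves_only_satisfiers(self, design, pair_model):
        model = sd.FitnessModel(
            pairs=pair_model.pairs, mismatch_penalty=1e-12, capture=1.0, length=105
        )
        spec = sd.DopedLibrarySpec(design=design, n_molecules=20_000, seed=6)
        traj = sd.run_selection(spec, model, n_rounds=1, seed=6)
        for s in traj.rounds[1].counts:
            assert sx.sequence_fitness(s, model) == 1.0

    def test_extinction_names_the_round(self, design, full_model):
        # all 45 conserved positions at the default penalty wipe out a small pool
        spec = sd.DopedLibrarySpec(design=design, n_molecules=1_000, seed=7)
        with pytest.raises(sd.ExtinctionError, match="round 1"):
            sd.run_selection(spec, full_model, n_rounds=1, seed=7)

    def test_bit_reproducible(self, design, pair_model):
        spec = sd.DopedLibrarySpec(design=design, n_molecules=5_000, seed=8)
        a = sd.run_selection(spec, pair_model, n_rounds=2, seed=9)
        b = sd.run_selection(spec, pair_model, n_rounds=2, seed=9)
        assert [t.counts for t in a.rounds] == [t.counts for t in b.rounds]


class TestSimulateReads:
    def _tiny_trajectory(self, design):
        spec = sd.DopedLibrarySpec(design=design, n_molecules=500, seed=10)
        return sd.run_selection(spec, sd.FitnessModel(capture=0.8), n_rounds=1, seed=10)

    def test_noiseless_reads_reproduce_molecule_frequencies(self, design):
        traj = self._tiny_trajectory(design)
        table0 = traj.rounds[0]
        reads = sd.simulate_reads(traj, depth=table0.total, error_rate=0.0, seed=1, rounds=[0])[0]
        counted, tally = sx.preprocess_reads(reads, design, round_id=0)
        assert tally["kept"] == table0.total
        assert counted.counts == table0.counts

    def test_error_rate_matches_binomial_complement(self, design):
        # tagless design: read = molecule, so errors per read ~ Binomial(105, 0.001)
        bare = sx.ReferenceDesign(
            reference=design.reference,
            mutagenized_region=design.mutagenized_region,
            primer3=design.primer3,
        )
        spec = sd.DopedLibrarySpec(design=bare, mu=0.0, n_molecules=100, seed=11)
        traj = sd.run_selection(spec, sd.FitnessModel(capture=1.0), n_rounds=1, seed=11)
        n = 20_000
        reads = sd.simulate_reads(traj, depth=n, error_rate=0.001, seed=12, rounds=[0])[0]
        frac = np.mean([str(r.seq) != bare.reference for r in reads])
        expected = 1 - 0.999**105
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se

    def test_depth_one_gives_one_record(self, design):
        traj = self._tiny_trajectory(design)
        reads = sd.simulate_reads(traj, depth=1, error_rate=0.0, seed=2)
        assert all(len(v) == 1 for v in reads.values())


class TestSimulatePlate:
    def test_inhibition_extremes_hit_control_means(self):
        n = 64
        spec = sd.PlateSpec(
            n_pos=16,
            n_neg=16,
            mu_p=100,
            sigma_p=2,
            mu_n=10,
            sigma_n=2,
            inhibitor_table={f"c{k}": 0.0 for k in range(n)},
            seed=21,
        )
        plate = sd.simulate_screen_plate(spec)
        samples = plate.loc[plate.role == "sample", "fluorescence"]
        assert abs(samples.mean() - 100) < 3 * 2 / np.sqrt(n)
        spec_full = sd.PlateSpec(
            n_pos=16,
            n_neg=16,
            mu_p=100,
            sigma_p=2,
            mu_n=10,
            sigma_n=2,
            inhibitor_table={f"c{k}": 1.0 for k in range(n)},
            seed=22,
        )
        full = sd.simulate_screen_plate(spec_full)
        samples = full.loc[full.role == "sample", "fluorescence"]
        assert abs(samples.mean() - 10) < 3 * 2 / np.sqrt(n)

    def test_uninformative_assay_rejected(self):
        with pytest.raises(ValueError, match="mu_p"):
            sd.PlateSpec(mu_p=5.0, mu_n=10.0)


class TestSimulateSaturationCurve:
    def test_half_saturation_identity(self):
        df = sd.simulate_saturation_curve(0.2, 30.0, 1.0, [30.0], 0.0)
        assert df.V0.iloc[0] == pytest.approx(0.1)

    def test_saturation_limit(self):
        df = sd.simulate_saturation_curve(0.2, 30.0, 1.0, [3000.0], 0.0)
        assert df.V0.iloc[0] == pytest.approx(0.2, rel=0.01)

    def test_cooperative_curve_lower_below_k_half(self):
        s = [15.0]
        v1 = sd.simulate_saturation_curve(0.2, 30.0, 1.0, s, 0.0).V0.iloc[0]
        v2 = sd.simulate_saturation_curve(0.2, 30.0, 2.0, s, 0.0).V0.iloc[0]
        assert v2 < v1

    def test_negative_substrate_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_saturation_curve(0.2, 30.0, 1.0, [-1.0], 0.0)
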
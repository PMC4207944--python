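"""Per-residue deviation statistics, profiles, regressions, Poisson fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.transform import Rotation

from reptation import deviation_analysis as dev
from reptation import synthetic_data as sd
from reptation.structure_io import AtomRecord, Conformer, Residue


def transform_conformer(conf, R, t, label="moved"):
    return Conformer(
        label=label, source="x",
        residues=[
            Residue(number=r.number, name=r.name,
                    atoms={name: AtomRecord(
                        atom_name=name, residue_name=r.name,
                        residue_number=r.number, chain_id="A",
                        xyz=R @ rec.xyz + t)
                        for name, rec in r.atoms.items()})
            for r in conf.residues
        ])


def displace_residues(conf, displacements, label="disp"):
    """Shift whole residues by given vectors (residue_number -> 3-vector)."""
    residues = []
    for r in conf.residues:
        shift = displacements.get(r.number, np.zeros(3))
        residues.append(Residue(
            number=r.number, name=r.name,
            atoms={name: AtomRecord(
                atom_name=name, residue_name=r.name,
                residue_number=r.number, chain_id="A", xyz=rec.xyz + shift)
                for name, rec in r.atoms.items()}))
    return Conformer(label=label, source="x", residues=residues)


class TestPerResidueDeviation:
    def test_self_deviation_zero(self, small_bundle):
        devs = dev.per_residue_deviation(small_bundle, small_bundle)
        assert np.allclose(devs, 0.0, atol=1e-10)

    def test_rigidly_rotated_copy_zero(self, small_bundle, rng):
        moved = transform_conformer(
            small_bundle, Rotation.random(rng=rng).as_matrix(),
            rng.normal(0, 8, 3))
        devs = dev.per_residue_deviation(moved, small_bundle)
        assert np.allclose(devs, 0.0, atol=1e-8)

    def test_single_displaced_residue_recovered(self, study_bundle, rng):
        target = study_bundle.residue_numbers[40]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        moved = displace_residues(study_bundle, {target: 5.0 * direction})
        devs = dev.per_residue_deviation(moved, study_bundle)
        assert devs.loc[target] == pytest.approx(5.0, abs=0.1)
        others = devs.drop(target)
        assert others.max() < 0.1

    def test_distal_mode_tracks_side_chain(self, study_bundle, rng):
        target = study_bundle.residue_numbers[10]
        moved = displace_residues(study_bundle, {target: np.array([3.0, 0, 0])})
        devs = dev.per_residue_deviation(moved, study_bundle, atom_mode="distal")
        assert devs.loc[target] == pytest.approx(3.0, abs=0.1)


class TestRunningAverage:
    def test_constant_series_unchanged(self):
        out = dev.running_average([2.5] * 10, 4)
        assert np.allclose(out, 2.5)

    def test_window_one_is_identity(self, rng):
        series = rng.normal(size=20)
        assert np.allclose(dev.running_average(series, 1), series)

    def test_even_window_edge_rule(self):
        # window 4 at index 2 spans indices [1, 4] under the documented rule
        out = dev.running_average([0.0, 0.0, 4.0, 0.0, 0.0], 4)
        assert out[2] == pytest.approx(np.mean([0.0, 4.0, 0.0, 0.0]))

    def test_output_length_matches_input(self, rng):
        series = rng.normal(size=15)
        assert len(dev.running_average(series, 10)) == 15

    def test_commutes_with_constant_shift(self, rng):
        series = rng.normal(size=30)
        assert np.allclose(
            dev.running_average(series + 7.0, 5),
            np.asarray(dev.running_average(series, 5)) + 7.0)

    def test_window_longer_than_series_raises(self):
        with pytest.raises(ValueError):
            dev.running_average([1.0, 2.0], 3)


class TestMaxProfileAndGroups:
    def _table(self, columns):
        df = pd.DataFrame(columns)
        df.insert(0, "residue_name", "A")
        df["region"] = "TM1"
        return df

    def test_single_conformer_subset_is_identity(self):
        table = self._table({"c1": [1.0, 2.0], "c2": [5.0, 0.0]})
        prof = dev.max_deviation_profile(table, ["c1"])
        assert prof.tolist() == [1.0, 2.0]

    def test_elementwise_maximum(self):
        table = self._table({"c1": [1.0, 2.0], "c2": [3.0, 0.0]})
        assert dev.max_deviation_profile(table).tolist() == [3.0, 2.0]

    def test_identical_groups_give_equal_means_and_p_near_one(self):
        table = self._table({
            "a1": [1.0, 2.0, 3.0], "a2": [2.0, 3.0, 4.0],
            "b1": [1.0, 2.0, 3.0], "b2": [2.0, 3.0, 4.0],
        })
        result, p = dev.group_stats(
            table, {"A": ["a1", "a2"], "B": ["b1", "b2"]})
        assert result.loc["A", "mean"] == pytest.approx(result.loc["B", "mean"])
        assert p == pytest.approx(1.0)

    def test_scale_ratio_recovered(self, rng):
        n = 200
        cols = {f"a{i}": rng.exponential(2.0, n) for i in range(4)}
        cols.update({f"b{i}": rng.exponential(1.0, n) for i in range(4)})
        table = self._table(cols)
        result, _ = dev.group_stats(
            table,
            {"A": [f"a{i}" for i in range(4)], "B": [f"b{i}" for i in range(4)]})
        ratio = result.loc["A", "mean"] / result.loc["B", "mean"]
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_singleton_group_sem_undefined(self):
        table = self._table({"a1": [1.0, 2.0], "b1": [2.0, 3.0]})
        result, p = dev.group_stats(table, {"A": ["a1"], "B": ["b1"]})
        assert np.isnan(result.loc["A", "sem"])
        assert np.isnan(p)

    def test_permutation_p_values_uniform(self, rng):
        """Under the null the Welch p-value is ~uniform (KS check)."""
        n_conf = 8
        data = {f"c{i}": rng.exponential(1.0, 150) for i in range(n_conf)}
        table = self._table(data)
        labels = list(data)
        p_values = []
        for _ in range(200):
            perm = rng.permutation(labels)
            _, p = dev.group_stats(
                table, {"A": list(perm[:4]), "B": list(perm[4:])})
            p_values.append(p)
        assert stats.kstest(p_values, "uniform").pvalue > 0.01

    def test_overlapping_groups_raise(self):
        table = self._table({"a": [1.0], "b": [2.0]})
        with pytest.raises(ValueError):
            dev.group_stats(table, {"A": ["a"], "B": ["a", "b"]})


class TestCoordinateRegression:
    def test_self_regression_is_exactly_one(self, small_bundle):
        res = dev.coordinate_regression(small_bundle, small_bundle, small_bundle)
        assert res.pearson_R == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)

    def test_r_symmetric_in_arguments(self, study_bundle, study_spec, rng):
        members, _ = sd.perturb_ensemble(study_bundle, study_spec, rng=rng,
                                         labels=["x", "y"])
        r_ab = dev.coordinate_regression(members[0], members[1], study_bundle)
        r_ba = dev.coordinate_regression(members[1], members[0], study_bundle)
        assert r_ab.pearson_R == pytest.approx(r_ba.pearson_R, abs=1e-12)

    def test_noise_attenuation_matches_closed_form(self, study_bundle, rng):
        sigma = 1.0
        noisy = displace_residues(
            study_bundle,
            {n: rng.normal(0.0, sigma, 3) for n in study_bundle.residue_numbers})
        res = dev.coordinate_regression(noisy, study_bundle, study_bundle)
        coords = np.concatenate(
            [rec for _, rec in
             ((n, r.coord("CA")) for n, r in zip(study_bundle.residue_numbers,
                                                 study_bundle.residues))])
        var = np.var(coords)
        expected = np.sqrt(var / (var + sigma**2))
        assert res.pearson_R == pytest.approx(expected, abs=0.02)

    def test_too_few_pairs_raise(self, small_bundle):
        few = small_bundle.residue_numbers[:5]
        with pytest.raises(ValueError):
            dev.coordinate_regression(small_bundle, small_bundle, small_bundle,
                                      residue_filter=few)


class TestFitPoisson:
    def test_recovers_bin_discretised_rate(self):
        rng = np.random.default_rng(42)
        lam_index, bw = 1.6, 0.25
        values = bw * (rng.poisson(lam_index, 2000) + rng.uniform(0, 1, 2000))
        fit = dev.fit_poisson(values, bin_width=bw)
        assert fit.lambda_hat == pytest.approx(lam_index * bw, abs=0.05)
        assert fit.correlation_R > 0.98

    def test_recovery_within_15_percent_over_replicates(self):
        rng = np.random.default_rng(7)
        errors = []
        for _ in range(20):
            values = 0.25 * (rng.poisson(1.6, 2000) + rng.uniform(0, 1, 2000))
            fit = dev.fit_poisson(values, bin_width=0.25)
            errors.append(abs(fit.lambda_hat - 0.4) / 0.4)
        assert np.median(errors) < 0.10

    def test_degenerate_identical_values_raise(self):
        with pytest.raises(ValueError):
            dev.fit_poisson(np.full(100, 0.3))

    def test_too_few_or_negative_values_raise(self):
        with pytest.raises(ValueError):
            dev.fit_poisson(np.arange(10.0))
        with pytest.raises(ValueError):
            dev.fit_poisson(np.concatenate([[-1.0], np.arange(40.0)]))


class TestPairDistance:
    def test_same_residue_zero(self, small_bundle):
        n = small_bundle.residue_numbers[0]
        assert dev.pair_distance(small_bundle, n, n) == pytest.approx(0.0)

    def test_three_four_five(self):
        residues = [
            Residue(1, "ALA", {"CA": AtomRecord("CA", "ALA", 1, "A",
                                                np.array([0.0, 0, 0]))}),
            Residue(2, "ALA", {"CA": AtomRecord("CA", "ALA", 2, "A",
                                                np.array([3.0, 4.0, 0]))}),
        ]
        conf = Conformer(label="t", source="x", residues=residues)
        assert dev.pair_distance(conf, 1, 2) == pytest.approx(5.0)

    def test_missing_residue_raises_with_name(self, small_bundle):
        with pytest.raises(ValueError, match="99999"):
            dev.pair_distance(small_bundle, small_bundle.residue_numbers[0], 99999)

    def test_distance_table_has_nan_for_missing(self, small_bundle):
        table = dev.pair_distance_table(
            [small_bundle], pairs=[(1, 2), (1, 99999)])
        assert np.isfinite(table.iloc[0, 0])
        assert np.isnan(table.iloc[0, 1])


class TestZoneAssign:
    def _line_conformer(self, n=30):
        residues = [
            Residue(i + 1, "ALA",
                    {"CA": AtomRecord("CA", "ALA", i + 1, "A",
                                      np.array([0.0, 0.0, float(i)]))})
            for i in range(n)
        ]
        return Conformer(label="line", source="x", residues=residues)

    def test_equal_thirds_on_a_line(self):
        conf = self._line_conformer(30)
        zones = dev.zone_assign(conf)
        # span 0..29; cuts at ~9.67 and ~19.33
        assert (zones == "internal").sum() == 10
        assert (zones == "central").sum() == 10
        assert (zones == "external").sum() == 10

    def test_degenerate_fractions_all_central(self):
        conf = self._line_conformer(12)
        zones = dev.zone_assign(conf, fractions=(0.0, 1.0))
        assert (zones == "central").all()

    def test_zero_axis_raises(self):
        with pytest.raises(ValueError):
            dev.zone_assign(self._line_conformer(5), axis=(0, 0, 0))

    def test_span_from_tm_residues_only(self):
        conf = self._line_conformer(30)
        zones = dev.zone_assign(conf, tm_ranges={"TM1": (11, 20)})
        # span now 10..19: residues below are internal, above external
        assert (zones.loc[1:10] == "internal").all()
        assert (zones.loc[21:30] == "external").all()


class TestDeviationTable:
    def test_reference_column_zero_and_annotations(self, study_bundle,
                                                   study_spec, rng):
        members, _ = sd.perturb_ensemble(study_bundle, study_spec, rng=rng,
                                         labels=["m1", "m2"])
        table = dev.deviation_table(
            members + [study_bundle], study_bundle,
            tm_ranges=study_spec.tm_ranges())
        assert np.allclose(table[study_bundle.label], 0.0, atol=1e-9)
        assert set(dev.conformer_columns(table)) == {"m1", "m2", "3a"} \
            or set(dev.conformer_columns(table)) == {"m1", "m2", "ref"}
        assert table["region"].str.startswith(("TM", "linker")).all()
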
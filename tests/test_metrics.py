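import json

import numpy as np
import pandas as pd
import pytest

from memomol import chem
from memomol.metrics import (average_length, build_report,
                             export_density, export_report, kde_grid,
                             percent_common, percent_valid,
                             property_quartiles)


class TestPercentValid:
    def test_two_of_three(self):
        assert percent_valid(["C", "CC", "C(("]) == pytest.approx(66.667,
                                                                  abs=1e-3)

    def test_all_valid(self, corpus):
        assert percent_valid(corpus[:50]) == 100.0

    def test_all_invalid(self):
        assert percent_valid(["C((", "1", "xx"]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percent_valid([])

    def test_mixture_identity(self, corpus):
        a = corpus[:30]
        b = ["C((", "CC", "((("]
        va, vb = percent_valid(a), percent_valid(b)
        expected = (va * len(a) + vb * len(b)) / (len(a) + len(b))
        assert percent_valid(a + b) == pytest.approx(expected, abs=1e-9)


class TestPercentCommon:
    def test_subset_is_fully_common(self):
        assert percent_common(["CCO", "CC"], ["CCO", "CC", "CCC"]) == 100.0

    def test_disjoint(self):
        assert percent_common(["CCO"], ["CCCC"]) == 0.0

    def test_one_of_four(self):
        gen = ["CCO", "CC", "CCC", "CCN"]
        assert percent_common(gen, ["CCO", "NCCCN"]) == 25.0

    def test_canonicalization_flag(self):
        # same molecule, different literal strings
        assert percent_common(["OCC"], ["CCO"], canonicalize=True) == 100.0
        assert percent_common(["OCC"], ["CCO"], canonicalize=False) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percent_common([], ["CC"])


class TestQuartiles:
    def test_symmetric_small_case(self):
        q1, q2, q3, mean = property_quartiles([1, 2, 3, 4])
        assert q2 == 2.5
        assert mean == 2.5
        assert q1 <= q2 <= q3

    def test_constant_list(self):
        assert property_quartiles([3.3] * 10) == (3.3, 3.3, 3.3,
                                                  pytest.approx(3.3))

    def test_against_sort_oracle(self):
        """Linear-interpolation quartiles recomputed from the sorted
        sample by the textbook h = (n-1)p rule."""
        rng = np.random.default_rng(0)
        values = rng.random(1000)
        q1, q2, q3, mean = property_quartiles(values)
        v = np.sort(values)

        def oracle(p):
            h = (len(v) - 1) * p
            lo = int(np.floor(h))
            return v[lo] + (h - lo) * (v[min(lo + 1, len(v) - 1)] - v[lo])

        assert abs(q1 - oracle(0.25)) < 1e-12
        assert abs(q2 - oracle(0.50)) < 1e-12
        assert abs(q3 - oracle(0.75)) < 1e-12
        assert abs(mean - values.mean()) < 1e-12

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            property_quartiles([1.0, 2.0, 3.0])


class TestReport:
    def test_identical_to_reference(self, corpus):
        batch = corpus[:40]
        rep = build_report(batch, corpus[:100], "logP")
        assert rep.valid_pct == 100.0
        assert rep.common_pct == 100.0
        assert rep.q1 <= rep.q2 <= rep.q3

    def test_average_length_in_characters(self):
        assert average_length(["CC", "CCCC"]) == 3.0

    def test_median_sa_of_single_molecule(self, corpus):
        batch = [corpus[0]] * 4  # quartiles need >= 4 values
        rep = build_report(batch, corpus[:10], "logP")
        assert rep.median_sa == pytest.approx(
            chem.compute_property(corpus[0], "sa_score"))

    def test_invalid_strings_excluded_from_statistics(self, corpus):
        batch = corpus[:8] + ["C((", "((("]
        rep = build_report(batch, corpus[:20], "logP")
        assert rep.valid_pct == pytest.approx(80.0)
        assert len(rep.property_values) == 8

    def test_permutation_invariance(self, corpus):
        batch = corpus[:30]
        r1 = build_report(batch, corpus[:60], "logP")
        r2 = build_report(list(reversed(batch)), corpus[:60], "logP")
        assert r1.valid_pct == r2.valid_pct
        assert r1.common_pct == r2.common_pct
        assert r1.q2 == r2.q2
        assert r1.avg_length == r2.avg_length

    def test_uniqueness_reported(self):
        rep = build_report(["CCO"] * 8, ["CC"], "logP")
        assert rep.unique_pct == pytest.approx(100.0 / 8)


class TestExports:
    def test_report_json_and_csv(self, corpus, tmp_path):
        rep = build_report(corpus[:20], corpus[:50], "logP")
        jpath = tmp_path / "r.json"
        cpath = tmp_path / "r.csv"
        export_report(rep, jpath)
        export_report(rep, cpath)
        loaded = json.loads(jpath.read_text())
        assert loaded["valid_pct"] == rep.valid_pct
        df = pd.read_csv(cpath)
        assert df.loc[0, "q2"] == pytest.approx(rep.q2)

    def test_density_export(self, tmp_path):
        values = [0.0, 1.0, 2.0, 2.0]
        path = tmp_path / "d.csv"
        export_density(values, path)
        df = pd.read_csv(path)
        raw = df[df.section == "raw"]
        kde = df[df.section == "kde"]
        assert list(raw.x) == values
        # KDE integrates to ~1 over the grid
        grid, dens = kde.x.to_numpy(), kde.y.to_numpy()
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=0.02)

    def test_kde_grid_peaks_near_data(self):
        grid, dens = kde_grid([0.0, 0.0, 0.0, 5.0], bandwidth=0.25)
        assert abs(grid[np.argmax(dens)]) < 0.1
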
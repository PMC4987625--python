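"""Friguet-plot K_D estimation from competition-ELISA series."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phagemap import (ElisaSeries, aggregate_kd, exact_quadratic_kd,
                      friguet_kd, simulate_elisa_series)
from phagemap.affinity import (DEFAULT_A0_GRID_NM, kd_table, load_elisa_csv)


class TestFriguetKd:
    def test_closed_form_point(self):
        # at a0 == K_D half the antibody is bound: A0/(A0-A) == 2
        s = simulate_elisa_series(10.0, a0_grid_nm=(10.0,) * 2 + (20.0,))
        a0, A = s.points[0]
        assert s.a0_absorbance / (s.a0_absorbance - A) == pytest.approx(2.0)

    @given(kd=st.floats(0.05, 500.0))
    def test_exact_recovery_from_noise_free_isotherm(self, kd):
        fit = friguet_kd(simulate_elisa_series(kd))
        assert fit.kd == pytest.approx(kd, rel=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)

    def test_absorbance_scale_invariance(self):
        a = friguet_kd(simulate_elisa_series(3.3, a0_absorbance=1.0))
        b = friguet_kd(simulate_elisa_series(3.3, a0_absorbance=2.71))
        assert a.kd == pytest.approx(b.kd)

    def test_no_binding_when_no_inhibition(self):
        s = ElisaSeries(antigen_id="dead",
                        points=[(a, 1.0) for a in DEFAULT_A0_GRID_NM],
                        a0_absorbance=1.0)
        fit = friguet_kd(s)
        assert fit.no_binding and fit.kd is None

    def test_non_inhibiting_points_dropped_with_warning(self):
        s = simulate_elisa_series(5.0)
        s.points[0] = (s.points[0][0], s.a0_absorbance)  # A == A0
        fit = friguet_kd(s)
        assert fit.n_points_used == len(DEFAULT_A0_GRID_NM) - 1
        assert any("non-inhibiting" in w for w in fit.warnings)

    def test_single_informative_point_is_an_error(self):
        s = ElisaSeries(antigen_id="x", points=[(10.0, 0.5), (20.0, 1.0)],
                        a0_absorbance=1.0)
        with pytest.raises(ValueError, match=">= 2 informative"):
            friguet_kd(s)

    def test_excess_assumption_warning(self):
        s = simulate_elisa_series(1.0, a0_grid_nm=(2.0, 4.0, 8.0),
                                  antibody_nm=0.7)
        assert any("excess" in w for w in friguet_kd(s).warnings)

    def test_noise_degrades_estimate_monotonically(self):
        """Absorbance noise inflates both spread and bias of the estimate."""
        true_kd = 5.0
        clean = simulate_elisa_series(true_kd)
        rng = np.random.default_rng(42)
        z = rng.standard_normal((400, len(clean.points)))
        sds, biases = [], []
        # common random numbers: the same noise draws scaled by each level,
        # so the bias/spread comparison across levels is paired
        for noise in (0.005, 0.02, 0.08):
            est = []
            for row in z:
                pts = [(a0, A + noise * zz)
                       for (a0, A), zz in zip(clean.points, row)]
                s = ElisaSeries(antigen_id="ag",
                                points=[(a0, A) for a0, A in pts if A < 1.0],
                                a0_absorbance=clean.a0_absorbance)
                est.append(friguet_kd(s).kd)
            est = np.array(est)
            sds.append(est.std())
            biases.append(abs(est.mean() - true_kd))
        assert sds == sorted(sds)
        assert biases == sorted(biases)

    def test_exact_quadratic_cross_check(self):
        # data from the exact 1:1 model: the exact solver recovers K_D
        # tightly; the excess approximation is close but biased
        s = simulate_elisa_series(0.19, model="exact")
        exact = exact_quadratic_kd(s)
        approx = friguet_kd(s)
        assert exact.kd == pytest.approx(0.19, rel=1e-4)
        assert abs(approx.kd - 0.19) > abs(exact.kd - 0.19)
        assert approx.kd == pytest.approx(0.19, rel=0.5)


class TestAggregateKd:
    def _series_pair(self, kds, antigen_id="ag"):
        return [simulate_elisa_series(kd, antigen_id=antigen_id, coating_nm=c)
                for kd, c in zip(kds, (3.5, 7.0, 14.0, 28.0))]

    def test_mean_and_sample_sd(self):
        est = aggregate_kd(self._series_pair([4.0, 4.4]))
        assert est.kd_mean == pytest.approx(4.2)
        assert est.kd_sd == pytest.approx(np.std([4.0, 4.4], ddof=1))

    def test_single_replicate_sd_zero(self):
        est = aggregate_kd(self._series_pair([7.7]))
        assert (est.kd_mean, est.kd_sd) == (pytest.approx(7.7), 0.0)

    def test_four_identical_replicates(self):
        est = aggregate_kd(self._series_pair([4.22] * 4))
        assert est.kd_mean == pytest.approx(4.22)
        assert est.kd_sd == pytest.approx(0.0, abs=1e-9)

    def test_fold_change_vs_reference(self):
        reference = aggregate_kd(self._series_pair([0.2], antigen_id="full"))
        est = aggregate_kd(self._series_pair([4.0]), reference=reference)
        assert est.fold_change_vs_reference == pytest.approx(20.0)

    def test_mixed_antigen_ids_rejected(self):
        a = simulate_elisa_series(1.0, antigen_id="a")
        b = simulate_elisa_series(1.0, antigen_id="b")
        with pytest.raises(ValueError, match="mix antigen ids"):
            aggregate_kd([a, b])

    def test_all_no_binding_flagged(self):
        dead = [ElisaSeries(antigen_id="dead",
                            points=[(a, 1.0) for a in DEFAULT_A0_GRID_NM],
                            a0_absorbance=1.0) for _ in range(2)]
        est = aggregate_kd(dead)
        assert est.no_binding_flag and est.kd_mean is None


def test_elisa_csv_roundtrip(tmp_path):
    rows = ["antigen_id,coating_nM,a0_nM,absorbance"]
    for coating in (3.5, 7.0):
        s = simulate_elisa_series(2.0, antigen_id="ag", coating_nm=coating)
        rows.append(f"ag,{coating},0,{s.a0_absorbance}")
        rows.extend(f"ag,{coating},{a0},{A}" for a0, A in s.points)
    path = tmp_path / "elisa.csv"
    path.write_text("\n".join(rows) + "\n")
    series = load_elisa_csv(str(path))
    est = aggregate_kd(series["ag"])
    assert est.kd_mean == pytest.approx(2.0)
    table = kd_table([est], reference_id="ag")
    assert table.loc[0, "fold_change_vs_reference"] == pytest.approx(1.0)
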
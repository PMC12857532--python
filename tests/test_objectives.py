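"""DVH metrics, the constraint-scaled objective, and step rewards."""

import numpy as np
import pytest

from vmatrl.dose import DoseGrid
from vmatrl.objectives import (Constraint, ObjectiveSpec, StructureObjective,
                               conformity_index, dvh_metric, objective_value,
                               step_reward)
from vmatrl.phantoms import Phantom


def _grid(values, spacing=10.0, norm="d95_anchored"):
    return DoseGrid(np.asarray(values, dtype=float), (spacing,) * 3, norm)


def _phantom_1d(masks, spacing=10.0):
    shape = next(iter(masks.values())).shape
    return Phantom(grid_shape=shape, spacing=(spacing,) * 3, masks=masks)


class TestDvhMetric:
    def test_uniform_dose_collapses_all_d_metrics(self):
        dose = _grid(np.full((4, 4, 4), 0.8))
        mask = np.ones((4, 4, 4), dtype=bool)
        for metric in ("Dmean", "Dmax", "D2%", "D98%"):
            assert dvh_metric(dose, mask, metric) == pytest.approx(0.8)

    def test_v50_counts_inclusive_threshold(self):
        # doses 0.1..1.0 on 10 voxels: six are >= 0.5
        dose = _grid((np.arange(10, dtype=float).reshape(10, 1, 1) + 1) / 10.0)
        mask = np.ones((10, 1, 1), dtype=bool)
        assert dvh_metric(dose, mask, "V50%") == pytest.approx(60.0)

    def test_d2cc_on_exactly_2cc_structure_is_min_dose(self):
        # 2 voxels of 10 mm spacing = 2.0 cm^3
        dose = _grid(np.array([1.3, 0.7]).reshape(2, 1, 1))
        mask = np.ones((2, 1, 1), dtype=bool)
        assert dvh_metric(dose, mask, "D2.0cc") == pytest.approx(0.7)

    def test_dx_percent_uses_sorted_hottest_fraction(self):
        vals = np.linspace(0.0, 1.0, 20)
        dose = _grid(vals.reshape(20, 1, 1))
        mask = np.ones((20, 1, 1), dtype=bool)
        # hottest 10% of 20 voxels = 2 voxels; their minimum is the 2nd largest
        assert dvh_metric(dose, mask, "D10%") == pytest.approx(np.sort(vals)[-2])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            dvh_metric(_grid(np.ones((2, 2, 2))), np.zeros((2, 2, 2), bool), "Dmean")

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            dvh_metric(_grid(np.ones((2, 2, 2))), np.ones((2, 2, 2), bool), "Q5")


class TestConformityIndex:
    def test_dose_exactly_on_ptv_gives_unity(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, :] = True
        dose = np.where(mask, 0.95, 0.5)
        assert conformity_index(_grid(dose), mask) == pytest.approx(1.0)

    def test_cold_plan_gives_zero(self):
        mask = np.ones((3, 3, 3), dtype=bool)
        assert conformity_index(_grid(np.full((3, 3, 3), 0.5)), mask) == 0.0

    def test_counting_oracle_on_three_structure_grid(self):
        dose = np.zeros((4, 4, 4))
        ptv = np.zeros((4, 4, 4), dtype=bool)
        ptv[:2, :2, :2] = True  # 8 voxels
        dose[ptv] = 1.0
        dose[3, 3, :2] = 1.2  # 2 hot voxels outside
        assert conformity_index(_grid(dose), ptv) == pytest.approx(10 / 8)


def _toy_spec():
    return ObjectiveSpec.default()


class TestObjectiveValue:
    def _phantom(self, bladder_doses=None, rectum_doses=None, ptv_doses=None,
                 spacing=10.0):
        blocks, masks, start = [], {}, 0
        for name, doses in (("PTV", ptv_doses), ("bladder", bladder_doses),
                            ("rectum", rectum_doses)):
            doses = np.asarray(doses if doses is not None else np.ones(20))
            blocks.append(doses)
            masks[name] = (start, start + doses.size)
            start += doses.size
        values = np.concatenate(blocks).reshape(-1, 1, 1)
        full_masks = {}
        for name, (a, b) in masks.items():
            m = np.zeros(values.shape, dtype=bool)
            m[a:b] = True
            full_masks[name] = m
        ph = Phantom(grid_shape=values.shape, spacing=(spacing,) * 3, masks=full_masks)
        return ph, _grid(values, spacing)

    def test_requires_anchored_dose(self):
        ph, dose = self._phantom()
        raw = DoseGrid(dose.values, dose.spacing, "raw")
        with pytest.raises(ValueError, match="d95_anchored"):
            objective_value(raw, ph, _toy_spec())

    def test_perfect_plan_has_zero_ptv_and_oar_terms(self):
        ph, dose = self._phantom(bladder_doses=np.zeros(20), rectum_doses=np.zeros(20),
                                 ptv_doses=np.ones(20))
        ov = objective_value(dose, ph, _toy_spec())
        assert ov.total == pytest.approx(0.0)

    def test_bladder_constraint_met_halves_its_term(self):
        # identical MSE; V50% = 40 (not < 40, unmet) vs 30 (met)
        unmet = np.array([0.6] * 4 + [0.0] * 6)
        met = np.array([0.6] * 3 + [0.4, np.sqrt(0.36 - 0.16)] + [0.0] * 5)
        assert np.isclose((unmet ** 2).sum(), (met ** 2).sum())
        ph_u, dose_u = self._phantom(bladder_doses=unmet)
        ph_m, dose_m = self._phantom(bladder_doses=met)
        t_u = objective_value(dose_u, ph_u, _toy_spec()).terms["bladder"]
        t_m = objective_value(dose_m, ph_m, _toy_spec()).terms["bladder"]
        assert t_m / t_u == pytest.approx(0.5)

    def test_rectum_both_constraints_met_applies_factor_squared(self):
        none_met = np.array([0.9] * 5 + [0.0] * 5)  # V50=50, V80=50: both unmet
        # same sum of squares; V50=40<50 and V80=10<20: both met
        tail = np.sqrt((4.05 - (0.81 + 3 * 0.79 ** 2)) / 6.0)
        both_met = np.array([0.9, 0.79, 0.79, 0.79] + [tail] * 6)
        assert tail < 0.5
        assert np.isclose((none_met ** 2).sum(), (both_met ** 2).sum())
        ph_n, dose_n = self._phantom(rectum_doses=none_met)
        ph_b, dose_b = self._phantom(rectum_doses=both_met)
        ov_n = objective_value(dose_n, ph_n, _toy_spec())
        ov_b = objective_value(dose_b, ph_b, _toy_spec())
        assert ov_n.n_satisfied["rectum"] == 0
        assert ov_b.n_satisfied["rectum"] == 2
        ratio = ov_b.terms["rectum"] / ov_n.terms["rectum"]
        assert ratio == pytest.approx(0.7 ** 2)

    def test_matches_naive_voxel_loop_oracle(self, rng):
        ph, dose = self._phantom(bladder_doses=rng.uniform(0, 1, 20),
                                 rectum_doses=rng.uniform(0, 1, 20),
                                 ptv_doses=rng.uniform(0.9, 1.4, 20))
        spec = _toy_spec()
        ov = objective_value(dose, ph, spec)
        total = 0.0
        for s in spec.structures:
            idx = np.argwhere(ph.masks[s.name])
            mse = np.mean([(dose.values[tuple(i)] - s.ideal_dose) ** 2 for i in idx])
            n = sum(c.satisfied(dvh_metric(dose, ph.masks[s.name], c.metric,
                                           ph.voxel_volume_mm3()))
                    for c in s.constraints)
            total += s.weight * mse * s.scaling_factor ** n
        assert ov.total == pytest.approx(total, abs=1e-12)

    def test_invariant_to_voxel_ordering(self, rng):
        doses = rng.uniform(0, 1, 20)
        ph1, d1 = self._phantom(bladder_doses=doses)
        ph2, d2 = self._phantom(bladder_doses=np.sort(doses))
        v1 = objective_value(d1, ph1, _toy_spec()).total
        v2 = objective_value(d2, ph2, _toy_spec()).total
        assert v1 == pytest.approx(v2, rel=1e-14)


class TestStepReward:
    def _ov(self, total):
        from vmatrl.objectives import ObjectiveValue
        return ObjectiveValue(total=total, terms={}, mse={}, n_satisfied={})

    def test_no_change_gives_zero(self):
        assert step_reward(self._ov(5.0), self._ov(5.0)) == 0.0

    def test_halving_the_objective_is_positive(self):
        assert step_reward(self._ov(8.0), self._ov(4.0)) == pytest.approx(4.0)

    def test_newly_met_bladder_constraint_adds_factor_jump(self):
        # unchanged MSE m: reward jump is w * m * (1 - f) = 20 * m * 0.5
        m = 0.123
        v_old = 20.0 * m
        v_new = 20.0 * m * 0.5
        assert step_reward(self._ov(v_old), self._ov(v_new)) == pytest.approx(
            20.0 * m * 0.5)

    def test_rewards_telescope_over_a_sequence(self, rng):
        totals = rng.uniform(0, 30, size=12)
        r = sum(step_reward(self._ov(a), self._ov(b))
                for a, b in zip(totals[:-1], totals[1:]))
        assert r == pytest.approx(totals[0] - totals[-1], abs=1e-12)


class TestObjectiveSpecIO:
    def test_yaml_round_trip(self, tmp_path):
        spec = ObjectiveSpec.default()
        spec.to_yaml(tmp_path / "spec.yaml")
        back = ObjectiveSpec.from_yaml(tmp_path / "spec.yaml")
        assert back == spec

    def test_invalid_scaling_factor_rejected(self):
        with pytest.raises(ValueError):
            StructureObjective("x", 1.0, 0.0, 1.5, (Constraint("V50%", 40.0),))
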
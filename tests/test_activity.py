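"""ActivityScore algebra, regulator classification, resampling stability."""

import numpy as np
import pandas as pd
import pytest

from mirti import (
    activity_profile,
    activity_score,
    activity_stability,
    classify_regulators,
    compute_corrfpi,
    differential_significance,
)
from mirti.influence import CorrFPIMap


def _cmap(edges):
    """CorrFPIMap from {(a, b): mi} with symmetric adjacency."""
    values = {}
    partners: dict[str, list] = {}
    for (a, b), v in edges.items():
        key = (a, b) if a <= b else (b, a)
        values[key] = v
        partners.setdefault(a, []).append(b)
        partners.setdefault(b, []).append(a)
    return CorrFPIMap(values, {g: tuple(sorted(p)) for g, p in partners.items()})


class TestActivityScore:
    def test_isolated_gene_zero(self):
        cmap = _cmap({("a", "b"): 1.0})
        assert activity_score("zzz", cmap, {"a": 1.0, "b": 1.0}) == 0.0

    def test_single_neighbor_square(self):
        # mean equals max with one neighbor: score = (c * r)^2
        cmap = _cmap({("g", "d"): 0.7})
        score = activity_score("g", cmap, {"d": 3.0, "g": 0.0})
        assert score == pytest.approx((0.7 * 3.0) ** 2)

    def test_two_neighbor_hand_case(self):
        # products 2 and 4: mean(2,4) * max(2,4) = 3 * 4 = 12
        cmap = _cmap({("g", "d1"): 1.0, ("g", "d2"): 2.0})
        score = activity_score("g", cmap, {"d1": 2.0, "d2": 2.0, "g": 0.0})
        assert score == pytest.approx(12.0)

    def test_missing_neighbor_errors(self):
        cmap = _cmap({("g", "d"): 1.0})
        with pytest.raises(ValueError, match="missing from DE"):
            activity_score("g", cmap, {"g": 1.0})

    def test_scaling_r_by_c_scales_scores_by_c_squared(self, rng):
        genes = [f"g{i}" for i in range(6)]
        edges = {
            (genes[i], genes[j]): rng.uniform(0.1, 2.0)
            for i in range(6)
            for j in range(i + 1, 6)
            if rng.random() < 0.6
        }
        cmap = _cmap(edges)
        de_r = {g: rng.uniform(0.0, 5.0) for g in genes}
        c = 3.7
        for g in genes:
            base = activity_score(g, cmap, de_r)
            scaled = activity_score(g, cmap, {k: c * v for k, v in de_r.items()})
            assert scaled == pytest.approx(c**2 * base, rel=1e-12)

    def test_monotone_in_neighbor_significance(self):
        cmap = _cmap({("g", "d1"): 1.0, ("g", "d2"): 0.5})
        de_r = {"d1": 2.0, "d2": 1.0, "g": 0.0}
        base = activity_score("g", cmap, de_r)
        for bump in ("d1", "d2"):
            up = dict(de_r)
            up[bump] += 1.0
            assert activity_score("g", cmap, up) >= base


class TestClassifyRegulators:
    @staticmethod
    def _profile(scores, neighbors, ps):
        genes = [f"g{i}" for i in range(len(scores))]
        profile = pd.DataFrame(
            {"R": -np.log10(ps), "n_neighbors": neighbors, "activity_score": scores},
            index=genes,
        )
        de = pd.DataFrame({"p": ps, "R": -np.log10(ps), "t": 0.0}, index=genes)
        return profile, de

    def test_all_equal_scores_all_none(self):
        profile, de = self._profile([2.0, 2.0, 2.0], [1, 2, 3], [0.5, 0.5, 0.5])
        assert (classify_regulators(profile, de) == "none").all()

    def test_high_score_nonsignificant_is_posttranslational(self):
        profile, de = self._profile([10.0, 1.0, 1.0], [2, 2, 2], [0.5, 0.5, 0.5])
        assert classify_regulators(profile, de)["g0"] == "posttranslational_center"

    def test_high_score_significant_is_de_center(self):
        profile, de = self._profile([10.0, 1.0, 1.0], [2, 2, 2], [1e-8, 0.5, 0.5])
        assert classify_regulators(profile, de)["g0"] == "significant_DE_center"

    def test_isolated_zeros_excluded_from_mean(self):
        # mean over connected genes only: many structural zeros must not
        # drag the threshold down
        scores = [3.0, 5.0] + [0.0] * 10
        neighbors = [2, 2] + [0] * 10
        ps = [0.5] * 12
        profile, de = self._profile(scores, neighbors, ps)
        classes = classify_regulators(profile, de)
        assert classes["g1"] == "posttranslational_center"
        assert classes["g0"] == "none"  # 3.0 < mean(3, 5)

    def test_partition_is_exhaustive_and_disjoint(self, rng):
        n = 50
        profile, de = self._profile(
            rng.uniform(0, 10, n), rng.integers(0, 5, n), rng.uniform(0.001, 1, n)
        )
        classes = classify_regulators(profile, de)
        assert len(classes) == n
        assert set(classes.unique()) <= {
            "none", "posttranslational_center", "significant_DE_center"
        }


class TestActivityPipeline:
    def test_profile_concentrates_on_driver_modules(self, default_sim):
        sim = default_sim
        ann = sim.annotations
        normal = list(ann.index[ann["class"] == "normal"])
        cancer = list(ann.index[ann["class"] != "normal"])
        corrfpi = compute_corrfpi(sim.mrna, sim.fpi)
        de = differential_significance(sim.mrna, normal, cancer)
        profile = activity_profile(corrfpi, de)
        top = profile.sort_values("activity_score", ascending=False).head(20).index
        driver_modules = set(range(len(sim.truth.drivers)))
        frac = np.mean([sim.truth.modules.get(g, -1) in driver_modules for g in top])
        assert frac >= 0.8

    def test_stability_full_sample_is_one(self, small_sim):
        sim = small_sim
        ann = sim.annotations
        normal = list(ann.index[ann["class"] == "normal"])
        cancer = list(ann.index[ann["class"] != "normal"])
        corrfpi = compute_corrfpi(sim.mrna, sim.fpi)
        r2 = activity_stability(
            sim.mrna, normal, cancer, corrfpi, n_rounds=3, seed=0, subsample_frac=1.0
        )
        assert r2 == pytest.approx(1.0)

    def test_stability_planted_beats_noise(self, small_sim, rng):
        sim = small_sim
        ann = sim.annotations
        normal = list(ann.index[ann["class"] == "normal"])
        cancer = list(ann.index[ann["class"] != "normal"])
        corrfpi = compute_corrfpi(sim.mrna, sim.fpi)
        planted_r2 = activity_stability(
            sim.mrna, normal, cancer, corrfpi, n_rounds=8, seed=1
        )
        noise = pd.DataFrame(
            rng.normal(size=sim.mrna.shape),
            index=sim.mrna.index,
            columns=sim.mrna.columns,
        )
        noise_corrfpi = compute_corrfpi(noise, sim.fpi)
        noise_r2 = activity_stability(
            noise, normal, cancer, noise_corrfpi, n_rounds=8, seed=1
        )
        assert planted_r2 > noise_r2 + 0.1

    def test_stability_reproducible_from_seed(self, small_sim):
        sim = small_sim
        ann = sim.annotations
        normal = list(ann.index[ann["class"] == "normal"])
        cancer = list(ann.index[ann["class"] != "normal"])
        corrfpi = compute_corrfpi(sim.mrna, sim.fpi)
        a = activity_stability(sim.mrna, normal, cancer, corrfpi, n_rounds=4, seed=9)
        b = activity_stability(sim.mrna, normal, cancer, corrfpi, n_rounds=4, seed=9)
        assert a == b

    def test_groups_too_small_to_subsample(self, small_sim):
        sim = small_sim
        corrfpi = compute_corrfpi(sim.mrna, sim.fpi)
        with pytest.raises(ValueError, match="too small"):
            activity_stability(
                sim.mrna, list(sim.mrna.columns[:2]), list(sim.mrna.columns[2:6]),
                corrfpi, n_rounds=2, seed=0,
            )
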
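"""Isometric size, shape projection, and the ratio extractor."""

import numpy as np
import pytest

from nestmorph.io import SpecimenTable
from nestmorph.mra import (
    isosize,
    lda_ratio_extract,
    optimal_threshold,
    shape_projection,
)
from nestmorph.registry import TRAIT_CODES

from conftest import make_table


class TestIsosize:
    def test_constant_traits_give_log_c(self):
        table = make_table(np.full((3, 22), 650.0))
        assert np.allclose(isosize(table), np.log(650.0))

    def test_isometric_scaling_adds_log_factor(self, rng):
        traits = np.exp(rng.normal(np.log(700), 0.05, size=(5, 22)))
        t1 = make_table(traits)
        t2 = make_table(traits * 1.37)
        np.testing.assert_allclose(
            isosize(t2).to_numpy() - isosize(t1).to_numpy(), np.log(1.37), atol=1e-12
        )

    def test_matches_direct_formula(self, rng):
        traits = np.exp(rng.normal(np.log(700), 0.1, size=(4, 22)))
        got = isosize(make_table(traits)).to_numpy()
        np.testing.assert_allclose(got, np.log(traits).mean(axis=1), atol=1e-12)


class TestShapeProjection:
    def test_isometric_copies_have_identical_shape(self, rng):
        base = np.exp(rng.normal(np.log(700), 0.1, size=(1, 22)))
        factors = np.array([0.5, 1.0, 1.8, 2.5])[:, None]
        table = make_table(base * factors)
        scores = shape_projection(table)
        np.testing.assert_allclose(scores.to_numpy() - scores.to_numpy()[0], 0, atol=1e-10)

    def test_isometric_perturbation_leaves_shape_unchanged(self, rng):
        # orthogonality to the isometric axis: inflating any specimen
        # isometrically moves its isosize but not any shape score
        traits = np.exp(rng.normal(np.log(700), 0.08, size=(30, 22)))
        t1 = make_table(traits)
        perturbed = traits.copy()
        perturbed[0] *= 1.9
        t2 = make_table(perturbed)
        s1 = shape_projection(t1).to_numpy()
        s2 = shape_projection(t2).to_numpy()
        np.testing.assert_allclose(s1, s2, atol=1e-10)
        assert isosize(t2).iloc[0] > isosize(t1).iloc[0]

    def test_matches_brute_force_projection(self, rng):
        traits = np.exp(rng.normal(np.log(700), 0.1, size=(6, 22)))
        table = make_table(traits)
        got = shape_projection(table).to_numpy()

        L = np.log(traits)
        L = L - L.mean(axis=0)
        p = L.shape[1]
        u = np.ones(p) / np.sqrt(p)
        proj = np.eye(p) - np.outer(u, u)        # explicit projection matrix
        resid = L @ proj
        _, _, Vt = np.linalg.svd(resid, full_matrices=False)
        want = resid @ Vt[: got.shape[1]].T
        for j in range(got.shape[1]):
            w = want[:, j]
            if not np.allclose(got[:, j], w, atol=1e-10):
                w = -w
            np.testing.assert_allclose(got[:, j], w, atol=1e-10)

    def test_single_specimen_errors(self):
        with pytest.raises(ValueError):
            shape_projection(make_table(np.full((1, 22), 700.0)))


def _brute_force_ranking(L, is_first, codes):
    """Exhaustive standardized-difference scores over ordered pairs."""
    out = {}
    for i in range(len(codes)):
        for j in range(len(codes)):
            if i == j:
                continue
            r = L[:, i] - L[:, j]
            a, b = r[is_first], r[~is_first]
            pooled = (
                (len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)
            ) / (len(a) + len(b) - 2)
            out[(codes[i], codes[j])] = abs(a.mean() - b.mean()) / np.sqrt(pooled)
    return out


class TestRatioExtractor:
    def _planted_table(self, rng, n=30):
        """Group difference lives in exactly one log-ratio: CL/SL."""
        L = rng.normal(np.log(700), 0.02, size=(n, 22))
        size = rng.normal(0, 0.1, size=n)
        L = L + size[:, None]                       # shared size: ratios free of it
        is_first = np.arange(n) < n // 2
        cl, sl = TRAIT_CODES.index("CL"), TRAIT_CODES.index("SL")
        L[is_first, cl] += 0.15                     # planted contrast
        return make_table(np.exp(L)), is_first, (TRAIT_CODES[cl], TRAIT_CODES[sl])

    def test_planted_ratio_ranked_first(self, rng):
        table, is_first, (num, _) = self._planted_table(rng)
        labels = ["A" if f else "B" for f in is_first]
        res = lda_ratio_extract(table, labels, compute_loocv=False)
        assert res.best.numerator == num

    def test_ranking_matches_brute_force_enumeration(self, rng):
        table, is_first, _ = self._planted_table(rng, n=24)
        labels = ["A" if f else "B" for f in is_first]
        res = lda_ratio_extract(table, labels, compute_loocv=False)
        brute = _brute_force_ranking(np.log(table.trait_matrix()), is_first, TRAIT_CODES)
        for cand in res.candidates[:20]:
            assert cand.score == pytest.approx(
                brute[(cand.numerator, cand.denominator)], abs=1e-10
            )
        # brute-force order agrees with the reported order
        brute_sorted = sorted(
            {frozenset(k): v for k, v in brute.items()}.items(),
            key=lambda kv: -kv[1],
        )
        got_scores = [c.score for c in res.candidates]
        want_scores = sorted((v for _, v in brute_sorted), reverse=True)
        np.testing.assert_allclose(got_scores[:10], want_scores[:10], atol=1e-10)

    def test_scale_invariance_of_scores(self, rng):
        table, is_first, _ = self._planted_table(rng)
        labels = ["A" if f else "B" for f in is_first]
        res1 = lda_ratio_extract(table, labels, compute_loocv=False)
        scaled = table.data.copy()
        scaled["PPW"] = scaled["PPW"] * 12.0
        res2 = lda_ratio_extract(
            SpecimenTable(scaled, registry=table.registry), labels, compute_loocv=False
        )
        for c1, c2 in zip(res1.candidates, res2.candidates):
            assert (c1.numerator, c1.denominator) == (c2.numerator, c2.denominator)
            assert c1.score == pytest.approx(c2.score, abs=1e-10)

    def test_orientation_reported_once_with_first_group_high(self, rng):
        table, is_first, _ = self._planted_table(rng)
        labels = ["A" if f else "B" for f in is_first]
        res = lda_ratio_extract(table, labels, compute_loocv=False)
        seen = set()
        L = np.log(table.trait_matrix())
        idx = {c: k for k, c in enumerate(TRAIT_CODES)}
        for c in res.candidates:
            pair = frozenset((c.numerator, c.denominator))
            assert pair not in seen
            seen.add(pair)
            r = L[:, idx[c.numerator]] - L[:, idx[c.denominator]]
            assert r[is_first].mean() >= r[~is_first].mean()
            assert 0.0 <= c.error <= 0.5

    def test_optimal_threshold_beats_any_grid_threshold(self, rng):
        values = rng.normal(0, 1, size=40)
        values[:20] += 1.5
        is_first = np.arange(40) < 20
        cut, err = optimal_threshold(values, is_first)
        for t in np.linspace(values.min() - 0.1, values.max() + 0.1, 200):
            grid_err = (
                (values[is_first] <= t).sum() + (values[~is_first] > t).sum()
            ) / 40
            assert err <= grid_err + 1e-12

    def test_degenerate_ratio_excluded_with_warning(self, rng):
        traits = np.exp(rng.normal(np.log(700), 0.05, size=(10, 22)))
        traits[:, 1] = traits[:, 0] * 1.1   # CW exactly proportional to CL
        table = make_table(traits)
        labels = ["A"] * 5 + ["B"] * 5
        with pytest.warns(UserWarning, match="degenerate"):
            res = lda_ratio_extract(table, labels, compute_loocv=False)
        names = {frozenset((c.numerator, c.denominator)) for c in res.candidates}
        assert frozenset(("CL", "CW")) not in names

    def test_multi_group_criterion(self, rng):
        table, is_first, (num, den) = self._planted_table(rng, n=30)
        labels = []
        for k, f in enumerate(is_first):
            labels.append("A" if f else ("B" if k % 2 else "C"))
        res = lda_ratio_extract(table, labels, compute_loocv=False)
        assert len(res.groups) == 3
        assert res.best.numerator in (num, den)

    def test_validation_errors(self, rng):
        table, is_first, _ = self._planted_table(rng)
        with pytest.raises(ValueError):
            lda_ratio_extract(table, ["A"] * len(table))
        bad = ["A"] + ["B"] * (len(table) - 1)
        with pytest.raises(ValueError):
            lda_ratio_extract(table, bad)
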
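from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from leukodeconv import ssgsea


def naive_es(positions: set[int], G: int, k: int, alpha: float) -> float:
    """Independent plain-loop evaluation of the running-sum integral."""
    w = [(G - i) ** alpha for i in range(G)]
    hit_norm = sum(w[i] for i in positions)
    running = 0.0
    es = 0.0
    for i in range(G):
        if i in positions:
            running += w[i] / hit_norm
        else:
            running -= 1.0 / (G - k)
        es += running
    return es


@pytest.fixture
def ten_gene_sample():
    genes = [f"g{i}" for i in range(10)]
    return pd.Series(np.arange(10, 0, -1, dtype=float), index=genes)


class TestEnrichmentScore:
    def test_matches_brute_force_over_all_placements(self, ten_gene_sample):
        """All C(10,3) signature placements agree with the naive loop, and the
        top-of-ranking placement attains the maximum."""
        genes = list(ten_gene_sample.index)
        results = {}
        for comb in combinations(range(10), 3):
            sig = {genes[i] for i in comb}
            es = ssgsea.ssgsea_es(ten_gene_sample, sig)
            assert es == pytest.approx(naive_es(set(comb), 10, 3, 0.25), abs=1e-12)
            results[comb] = es
        assert max(results, key=results.get) == (0, 1, 2)

    def test_whole_universe_signature_is_degenerate_but_defined(self, ten_gene_sample):
        """With no miss genes the score is forced by the normalised hit weights."""
        es = ssgsea.ssgsea_es(ten_gene_sample, set(ten_gene_sample.index))
        w = np.arange(10, 0, -1, dtype=float) ** 0.25
        hw = w / w.sum()
        assert es == pytest.approx(np.cumsum(hw).sum())

    def test_missing_signature_rejected(self, ten_gene_sample):
        with pytest.raises(ValueError, match="no signature gene"):
            ssgsea.ssgsea_es(ten_gene_sample, {"absent"})

    def test_heavy_ties_flagged(self):
        expr = pd.Series([1.0] * 9 + [2.0], index=[f"g{i}" for i in range(10)])
        with pytest.warns(UserWarning, match="tied"):
            ssgsea.ssgsea_es(expr, {"g0", "g9"})

    @settings(derandomize=True, max_examples=25)
    @given(scale=st.floats(0.1, 50), shift=st.floats(0, 100))
    def test_rank_invariance_under_monotone_transforms(self, scale, shift):
        rng = np.random.default_rng(7)
        expr = pd.Series(rng.lognormal(3, 1, 40), index=[f"g{i}" for i in range(40)])
        sig = {"g3", "g11", "g25", "g38"}
        base = ssgsea.ssgsea_es(expr, sig)
        assert ssgsea.ssgsea_es(np.log(expr) * scale + shift, sig) == pytest.approx(base)
        assert ssgsea.ssgsea_es(expr**2, sig) == pytest.approx(base)


class TestScoreCellTypes:
    def test_panel_covers_retained_cell_types(self, rng):
        genes = [f"g{i}" for i in range(120)]
        sigs = {f"ct{i}": [set(genes[i * 5:(i + 1) * 5])] for i in range(10)}
        mix = pd.DataFrame(rng.lognormal(3, 1, size=(120, 3)), index=genes,
                           columns=["s1", "s2", "s3"])
        panel = ssgsea.score_cell_types(mix, sigs)
        assert list(panel.index) == list(sigs)
        assert np.isfinite(panel.to_numpy()).all()

    def test_single_signature_mean_is_that_es(self, rng):
        genes = [f"g{i}" for i in range(30)]
        mix = pd.DataFrame(rng.lognormal(3, 1, size=(30, 1)), index=genes, columns=["s"])
        sig = set(genes[:4])
        panel = ssgsea.score_cell_types(mix, {"ct": [sig]})
        assert panel.at["ct", "s"] == pytest.approx(ssgsea.ssgsea_es(mix["s"], sig))
        # two identical signatures average to the same value
        panel2 = ssgsea.score_cell_types(mix, {"ct": [sig, set(sig)]})
        assert panel2.at["ct", "s"] == pytest.approx(panel.at["ct", "s"])

    def test_unusable_cell_type_dropped_with_warning(self, rng):
        genes = [f"g{i}" for i in range(30)]
        mix = pd.DataFrame(rng.lognormal(3, 1, size=(30, 1)), index=genes, columns=["s"])
        with pytest.warns(UserWarning, match="no usable signature"):
            panel = ssgsea.score_cell_types(mix, {"ok": [set(genes[:3])], "gone": [{"zz"}]})
        assert list(panel.index) == ["ok"]


class TestCalibrate:
    def test_identity_is_min_shift(self, rng):
        panel = pd.DataFrame(rng.normal(size=(3, 5)), index=list("abc"))
        out = ssgsea.calibrate(panel)
        np.testing.assert_allclose(out.min(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out, panel.sub(panel.min(axis=1), axis=0))

    def test_scale_two_halves_values(self, rng):
        panel = pd.DataFrame(rng.normal(size=(2, 4)), index=["a", "b"])
        out = ssgsea.calibrate(panel, {"a": (0.0, 2.0, 1.0)})
        shifted = panel.sub(panel.min(axis=1), axis=0)
        np.testing.assert_allclose(out.loc["a"], shifted.loc["a"] / 2)
        np.testing.assert_allclose(out.loc["b"], shifted.loc["b"])

    def test_ranking_preserved_for_random_params(self, rng):
        panel = pd.DataFrame(rng.normal(size=(4, 20)), index=list("abcd"))
        params = {ct: (0.0, float(rng.uniform(0.5, 3)), float(rng.uniform(0.3, 2.5)))
                  for ct in panel.index}
        out = ssgsea.calibrate(panel, params)
        for ct in panel.index:
            before = panel.loc[ct].rank(method="average")
            after = out.loc[ct].rank(method="average")
            assert (after[before.sort_values().index].is_monotonic_increasing)

    def test_invalid_params_rejected(self, rng):
        panel = pd.DataFrame(rng.normal(size=(1, 3)), index=["a"])
        with pytest.raises(ValueError, match="scale > 0"):
            ssgsea.calibrate(panel, {"a": (0.0, -1.0, 1.0)})


class TestSpillover:
    def test_identity_matrix_is_noop(self, rng):
        panel = pd.DataFrame(np.abs(rng.normal(size=(3, 4))), index=list("abc"))
        K = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        out = ssgsea.spillover_compensate(panel, K)
        np.testing.assert_allclose(out.data, panel)
        assert out.method == "ssgsea"

    def test_two_type_closed_form(self):
        panel = pd.DataFrame({"s1": [1.0, 0.4]}, index=["A", "B"])
        K = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=["A", "B"], columns=["A", "B"])
        out = ssgsea.spillover_compensate(panel, K, alpha=0.5)
        np.testing.assert_allclose(out.data["s1"], [0.9, 0.15])

    def test_outputs_clipped_non_negative(self, rng):
        panel = pd.DataFrame(np.abs(rng.normal(size=(3, 6))), index=list("abc"))
        K = pd.DataFrame(np.full((3, 3), 0.9), index=list("abc"), columns=list("abc"))
        np.fill_diagonal(K.values, 1.0)
        out = ssgsea.spillover_compensate(panel, K, alpha=1.0)
        assert (out.data.to_numpy() >= 0).all()

    def test_missing_cell_type_rejected(self, rng):
        panel = pd.DataFrame(np.abs(rng.normal(size=(2, 2))), index=["a", "b"])
        K = pd.DataFrame([[1.0]], index=["a"], columns=["a"])
        with pytest.raises(KeyError, match="b"):
            ssgsea.spillover_compensate(panel, K)


class TestDeriveSpillover:
    def test_orthogonal_signatures_give_near_identity(self, gene_universe):
        sigs = {"A": [set(gene_universe[:20])], "C": [set(gene_universe[50:70])]}
        K = ssgsea.derive_spillover(sigs, universe=gene_universe, seed=3)
        assert np.allclose(np.diag(K), 1.0)
        off = K.to_numpy()[~np.eye(2, dtype=bool)]
        assert (off < 0.15).all()

    def test_half_shared_signatures_detected(self, overlapping_sigs, gene_universe):
        K = ssgsea.derive_spillover(overlapping_sigs, universe=gene_universe, seed=3)
        assert K.loc["A", "B"] > 0.2 and K.loc["B", "A"] > 0.2
        assert K.loc["A", "C"] < 0.15
        assert np.allclose(np.diag(K), 1.0)
        assert ((K.to_numpy() >= 0) & (K.to_numpy() <= 1)).all()

    def test_spillover_reduces_cross_score(self, overlapping_sigs, gene_universe, rng):
        """On pure-A samples the B score (pure confusion) shrinks after
        compensation."""
        sigs = {k: overlapping_sigs[k] for k in ("A", "B")}
        cols = {}
        for i in range(15):
            e = pd.Series(rng.lognormal(np.log(100), 1, len(gene_universe)),
                          index=gene_universe)
            e[list(sigs["A"][0])] *= 6
            cols[f"s{i}"] = e
        panel = ssgsea.calibrate(ssgsea.score_cell_types(pd.DataFrame(cols), sigs))
        K = ssgsea.derive_spillover(sigs, universe=gene_universe, seed=4)
        after = ssgsea.spillover_compensate(panel, K)
        assert after.data.loc["B"].abs().mean() < panel.loc["B"].abs().mean()

    def test_pure_sample_ordering(self, overlapping_sigs, gene_universe, rng):
        """The true cell type wins the compensated score on >= 95% of pure
        samples (100 simulated cases)."""
        sigs = overlapping_sigs
        K = ssgsea.derive_spillover(sigs, universe=gene_universe, seed=5)
        types = list(sigs)
        wins = 0
        cols, truth = {}, []
        for i in range(100):
            ct = types[i % len(types)]
            e = pd.Series(rng.lognormal(np.log(100), 1, len(gene_universe)),
                          index=gene_universe)
            e[list(set().union(*sigs[ct]))] *= 6
            cols[f"s{i}"] = e
            truth.append(ct)
        panel = ssgsea.calibrate(ssgsea.score_cell_types(pd.DataFrame(cols), sigs))
        comp = ssgsea.spillover_compensate(panel, K)
        wins = sum(comp.data[c].idxmax() == t for c, t in zip(comp.data.columns, truth))
        assert wins >= 95
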
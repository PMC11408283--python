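"""Canonical-correlation negative screen: projections, thresholds, verdicts."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import t as t_dist

from cpipred.negscreen import (
    CCANegativeScreen,
    compound_descriptors,
    protein_descriptors,
    reduce_descriptors,
    target_space_threshold,
)


def _paired_tables(rng, n=40, p=6, q=5, coupled=True):
    """Compound/protein descriptor tables with optionally correlated pairs."""
    z = rng.normal(size=(n, 2))
    X = np.hstack([z + 0.1 * rng.normal(size=(n, 2)),
                   rng.normal(size=(n, p - 2))])
    if coupled:
        Y = np.hstack([z @ rng.normal(size=(2, 2)) + 0.1 * rng.normal(size=(n, 2)),
                       rng.normal(size=(n, q - 2))])
    else:
        Y = rng.normal(size=(n, q))
    cdesc = pd.DataFrame(X, index=[f"C{i}" for i in range(n)])
    cdesc.columns = [f"x{j}" for j in range(p)]
    pdesc = pd.DataFrame(Y, index=[f"P{i}" for i in range(n)])
    pdesc.columns = [f"y{j}" for j in range(q)]
    pairs = [(f"C{i}", f"P{i}") for i in range(n)]
    return pairs, cdesc, pdesc


class TestReduceDescriptors:
    def test_collinear_data_one_component(self, rng):
        t = rng.normal(size=20)
        df = pd.DataFrame({"a": t, "b": 2 * t})
        out = reduce_descriptors(df, 2)
        evr = out.attrs["explained_variance_ratio"]
        assert evr[0] > 0.999

    def test_full_rank_reconstruction(self, rng):
        X = rng.normal(size=(5, 4))
        df = pd.DataFrame(X, columns=list("abcd"))
        out = reduce_descriptors(df, 4)
        evr = out.attrs["explained_variance_ratio"]
        assert evr.sum() == pytest.approx(1.0, abs=1e-10)
        # matches eigendecomposition of the covariance
        Xc = X - X.mean(axis=0)
        w = np.sort(np.linalg.eigvalsh(Xc.T @ Xc / 4))[::-1]
        assert np.allclose(np.sort(evr)[::-1], w[: len(evr)] / w.sum(), atol=1e-8)

    def test_over_rank_request_truncates(self, rng):
        df = pd.DataFrame(rng.normal(size=(3, 5)))
        df.columns = list("abcde")
        with pytest.warns(UserWarning):
            out = reduce_descriptors(df, 5)
        assert out.shape[1] <= 2


class TestBuiltinDescriptors:
    def test_protein_descriptor_shape_and_content(self):
        df = protein_descriptors({"P1": "MKVLAAK", "P2": "WWWWCCCC"})
        assert df.shape[0] == 2 and "aa_W" in df.columns
        assert df.loc["P2", "aa_W"] == pytest.approx(0.5)
        assert df.loc["P2", "dipep_WW"] > 0

    def test_compound_descriptors_from_fingerprints(self):
        fps = {"C1": np.ones(64, dtype=np.uint8), "C2": np.zeros(64, dtype=np.uint8)}
        df = compound_descriptors(["C1", "C2"], fingerprints=fps, n_blocks=8)
        assert df.loc["C1", "fp_total"] == 64 and df.loc["C2", "fp_total"] == 0

    def test_compound_descriptors_from_smiles(self):
        df = compound_descriptors(["C1"], smiles={"C1": "c1ccccc1O"})
        assert df.loc["C1", "ring_count"] == 1
        assert df.loc["C1", "mol_weight"] == pytest.approx(94.11, abs=0.1)


class TestCorrelationSpace:
    def test_identical_blocks_give_correlation_one(self, rng):
        X = rng.normal(size=(30, 4))
        cdesc = pd.DataFrame(X, index=[f"C{i}" for i in range(30)],
                             columns=list("abcd"))
        pdesc = pd.DataFrame(X.copy(), index=[f"P{i}" for i in range(30)],
                             columns=list("abcd"))
        pairs = [(f"C{i}", f"P{i}") for i in range(30)]
        scr = CCANegativeScreen(n_components=2).fit(pairs, cdesc, pdesc)
        assert scr.correlations_[0] == pytest.approx(1.0, abs=1e-3)

    def test_correlations_non_increasing(self, rng):
        pairs, cdesc, pdesc = _paired_tables(rng)
        scr = CCANegativeScreen(n_components=4).fit(pairs, cdesc, pdesc)
        assert np.all(np.diff(scr.correlations_) <= 1e-12)
        assert np.all((scr.correlations_ >= 0) & (scr.correlations_ <= 1))

    def test_independent_pairings_near_zero_vs_permutation_null(self):
        """First canonical correlation of uncoupled data is consistent with
        the permutation null distribution."""
        rng = np.random.default_rng(0)
        pairs, cdesc, pdesc = _paired_tables(rng, n=60, coupled=False)
        scr = CCANegativeScreen(n_components=1).fit(pairs, cdesc, pdesc)
        obs = scr.correlations_[0]
        null = []
        for _ in range(200):
            perm = rng.permutation(60)
            ppairs = [(f"C{i}", f"P{j}") for i, j in enumerate(perm)]
            null.append(
                CCANegativeScreen(n_components=1)
                .fit(ppairs, cdesc, pdesc).correlations_[0]
            )
        # observed falls inside the null distribution (uncoupled data)
        assert obs <= np.quantile(null, 0.99)

    def test_coupled_pairs_beat_permutation_null(self):
        rng = np.random.default_rng(1)
        pairs, cdesc, pdesc = _paired_tables(rng, n=60, coupled=True)
        obs = CCANegativeScreen(n_components=1).fit(
            pairs, cdesc, pdesc).correlations_[0]
        rng2 = np.random.default_rng(2)
        null = []
        for _ in range(50):
            perm = rng2.permutation(60)
            ppairs = [(f"C{i}", f"P{j}") for i, j in enumerate(perm)]
            null.append(CCANegativeScreen(n_components=1)
                        .fit(ppairs, cdesc, pdesc).correlations_[0])
        assert obs > max(null)

    def test_scaling_invariance_when_standardized(self, rng):
        pairs, cdesc, pdesc = _paired_tables(rng)
        s1 = CCANegativeScreen(n_components=2).fit(pairs, cdesc, pdesc)
        scaled = pdesc.copy()
        scaled["y0"] = scaled["y0"] * 1000.0
        s2 = CCANegativeScreen(n_components=2).fit(pairs, cdesc, scaled)
        p1 = s1.project_proteins(pdesc).to_numpy()
        p2 = s2.project_proteins(scaled).to_numpy()
        assert np.allclose(np.abs(p1), np.abs(p2), atol=1e-4)

    def test_agrees_with_sklearn_cca_on_well_conditioned_data(self):
        from sklearn.cross_decomposition import CCA

        rng = np.random.default_rng(3)
        pairs, cdesc, pdesc = _paired_tables(rng, n=80)
        scr = CCANegativeScreen(n_components=2, ridge=1e-9).fit(pairs, cdesc, pdesc)
        X = (cdesc - cdesc.mean()) / cdesc.std(ddof=0)
        Y = (pdesc - pdesc.mean()) / pdesc.std(ddof=0)
        xs, ys = CCA(n_components=2, max_iter=2000).fit_transform(
            X.to_numpy(), Y.to_numpy())
        ref = abs(np.corrcoef(xs[:, 0], ys[:, 0])[0, 1])
        assert scr.correlations_[0] == pytest.approx(ref, abs=0.01)


class TestTargetSpaceThreshold:
    def test_two_targets_degenerate(self):
        coords = np.array([[0.0, 0.0], [2.0, 0.0]])
        assert target_space_threshold(coords) == pytest.approx(2.0)

    def test_three_collinear_targets(self):
        coords = np.array([[0.0], [1.0], [2.0]])
        d = np.array([1.0, 1.0, 2.0])  # hand enumeration of the 3 pairs
        mean = d.mean()
        expect = mean + t_dist.ppf(0.975, 2) * d.std(ddof=1) / np.sqrt(3)
        assert target_space_threshold(coords) == pytest.approx(expect, abs=1e-12)
        assert mean == pytest.approx(4 / 3)

    def test_threshold_at_least_mean_distance(self, rng):
        for _ in range(10):
            coords = rng.normal(size=(5, 3))
            dists = [np.linalg.norm(a - b) for i, a in enumerate(coords)
                     for b in coords[i + 1:]]
            assert target_space_threshold(coords) >= np.mean(dists) - 1e-12

    def test_single_target_errors(self):
        with pytest.raises(ValueError):
            target_space_threshold(np.array([[1.0, 2.0]]))


class TestScreening:
    @pytest.fixture()
    def fitted(self, rng):
        pairs, cdesc, pdesc = _paired_tables(rng, n=50)
        # give each compound several targets so target spaces exist
        multi = [(f"C{i}", f"P{(i + k) % 50}") for i in range(20) for k in range(3)]
        scr = CCANegativeScreen(n_components=3).fit(multi, cdesc, pdesc)
        return scr, cdesc, pdesc

    def test_coincident_protein_rejected(self, fitted):
        scr, _, pdesc = fitted
        cid = next(iter(scr.target_spaces_))
        ts = scr.target_spaces_[cid]
        assert scr.confirm_negative(cid, ts.coordinates[0]) is False

    def test_distant_protein_confirmed(self, fitted):
        scr, _, pdesc = fitted
        cid = next(iter(scr.target_spaces_))
        ts = scr.target_spaces_[cid]
        far = ts.coordinates.mean(axis=0) + 1e3 * np.ones(ts.coordinates.shape[1])
        assert scr.confirm_negative(cid, far) is True

    def test_partition_conserves_counts(self, fitted):
        scr, _, pdesc = fitted
        cands = [(f"C{i}", f"P{(i * 7) % 50}") for i in range(40)]
        retained, rejected, unscreened, report = scr.screen(cands, pdesc)
        assert len(retained) + len(rejected) + len(unscreened) == len(cands)
        assert len(report) == len(cands)

    def test_verdicts_match_direct_recomputation(self, fitted):
        """Oracle check: each verdict equals a from-scratch distance test."""
        scr, _, pdesc = fitted
        cands = [(f"C{i}", f"P{(i * 3 + 1) % 50}") for i in range(50)]
        _, _, _, report = scr.screen(cands, pdesc)
        proj = scr.project_proteins(pdesc)
        for row in report.itertuples(index=False):
            ts = scr.target_spaces_.get(row.compound_id)
            if ts is None:
                assert row.verdict == "unscreened"
                continue
            d = min(np.linalg.norm(ts.coordinates - proj.loc[row.protein_id].to_numpy(), axis=1))
            assert d == pytest.approx(row.min_distance, abs=1e-10)
            assert row.verdict == ("retained" if d > ts.distance_threshold else "rejected")

    def test_no_target_space_passes_through(self, fitted):
        scr, _, pdesc = fitted
        retained, rejected, unscreened, _ = scr.screen([("C49", "P0")], pdesc)
        assert unscreened == [("C49", "P0")] and not retained and not rejected

    def test_empty_candidates(self, fitted):
        scr, _, pdesc = fitted
        retained, rejected, unscreened, report = scr.screen([], pdesc)
        assert not retained and not rejected and not unscreened and report.empty

    def test_planted_far_negatives_recovered(self):
        """Negatives planted far from every target cluster are confirmed
        at recall >= 0.9."""
        rng = np.random.default_rng(7)
        n = 60
        z = rng.normal(size=(n, 2))
        cdesc = pd.DataFrame(
            np.hstack([z, rng.normal(size=(n, 3))]),
            index=[f"C{i}" for i in range(n)], columns=list("abcde"))
        pdesc = pd.DataFrame(
            np.hstack([z + 0.05 * rng.normal(size=(n, 2)), rng.normal(size=(n, 3))]),
            index=[f"P{i}" for i in range(n)], columns=list("vwxyz"))
        # targets of compound i: its 3 nearest proteins in the latent plane
        # (tight target spaces); planted negative: the farthest protein
        d2 = ((z[:, None, :] - z[None, :, :]) ** 2).sum(-1)
        pairs = []
        planted = []
        for i in range(25):
            near = np.argsort(d2[i])[:3]
            pairs.extend((f"C{i}", f"P{j}") for j in near)
            planted.append((f"C{i}", f"P{np.argsort(d2[i])[-1]}"))
        scr = CCANegativeScreen(n_components=2).fit(pairs, cdesc, pdesc)
        retained, rejected, unscreened, _ = scr.screen(planted, pdesc)
        screened = len(retained) + len(rejected)
        assert screened > 0
        assert len(retained) / screened >= 0.9
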
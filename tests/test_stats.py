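import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from metaphi import stats as st

from _oracles import welch_oracle


def _blobs(rng, k=3, per=10, dim=12, spread=0.15, sep=4.0):
    centers = rng.normal(0, sep, size=(k, dim))
    rows, labels = [], []
    for c in range(k):
        rows.append(centers[c] + rng.normal(0, spread, size=(per, dim)))
        labels += [c] * per
    X = np.vstack(rows)
    return pd.DataFrame(X, index=[f"r{i}" for i in range(len(X))]), labels


# ---------------------------------------------------------------------------
# k-means

def test_kmeans_finds_planted_breakpoint(rng):
    df, _ = _blobs(rng)
    res = st.kmeans_sse(df, k_range=range(1, 7), restarts=10, seed=0)
    assert res.elbow_k == 3
    sses = [res.sse_curve[k] for k in sorted(res.sse_curve)]
    assert all(a >= b - 1e-9 for a, b in zip(sses, sses[1:]))  # non-increasing


def test_kmeans_identical_points_sse_zero():
    df = pd.DataFrame(np.ones((8, 3)), index=[f"r{i}" for i in range(8)])
    res = st.kmeans_sse(df, k_range=range(1, 4), restarts=2, seed=0)
    assert res.sse_curve[1] == pytest.approx(0.0)


def test_kmeans_deterministic_and_restart_monotone(rng):
    df, _ = _blobs(rng, spread=0.8)
    a = st.kmeans_sse(df, k_range=range(1, 6), restarts=5, seed=42)
    b = st.kmeans_sse(df, k_range=range(1, 6), restarts=5, seed=42)
    assert a.labels == b.labels and a.sse_curve == b.sse_curve
    few = st.kmeans_sse(df, k_range=range(1, 6), restarts=1, seed=0)
    many = st.kmeans_sse(df, k_range=range(1, 6), restarts=20, seed=0)
    for k in few.sse_curve:
        assert many.sse_curve[k] <= few.sse_curve[k] + 1e-9


def test_kmeans_k_range_exceeding_rows_is_error(rng):
    df, _ = _blobs(rng, k=1, per=4)
    with pytest.raises(ValueError):
        st.kmeans_sse(df, k_range=range(1, 10))


# ---------------------------------------------------------------------------
# PCA

def test_pca_collinear_points_have_unit_pc1(rng):
    t = rng.normal(0, 2, size=30)
    X = np.outer(t, [1.0, -2.0, 0.5]) + [3, 1, 7]
    scores, loadings, frac = st.pca(pd.DataFrame(X, index=[f"r{i}" for i in range(30)]))
    assert frac[0] == pytest.approx(1.0, abs=1e-9)


def test_pca_full_rank_reconstruction(rng):
    df = pd.DataFrame(rng.normal(size=(10, 4)), index=[f"r{i}" for i in range(10)])
    scores, loadings, frac = st.pca(df)
    recon = scores.to_numpy() @ loadings.to_numpy() + df.mean(axis=0).to_numpy()
    assert np.allclose(recon, df.to_numpy(), atol=1e-9)
    assert frac.sum() <= 1.0 + 1e-9
    assert all(a >= b - 1e-12 for a, b in zip(frac, frac[1:]))


def test_pca_sign_convention_and_row_order_invariance(rng):
    df = pd.DataFrame(rng.normal(size=(12, 5)), index=[f"r{i}" for i in range(12)])
    _, loadings, _ = st.pca(df)
    for _, row in loadings.iterrows():
        assert row.iloc[int(np.argmax(np.abs(row.to_numpy())))] > 0
    perm = df.sample(frac=1.0, random_state=1)
    scores_a, _, _ = st.pca(df)
    scores_b, _, _ = st.pca(perm)
    assert np.allclose(scores_a.loc[perm.index].to_numpy(), scores_b.to_numpy(), atol=1e-9)


def test_pca_needs_two_rows():
    with pytest.raises(ValueError):
        st.pca(pd.DataFrame([[1.0, 2.0]], index=["r0"]))


# ---------------------------------------------------------------------------
# LDA

def _sep_stat(scores, labels):
    g = scores.groupby([labels[i] for i in scores.index])["LD1"]
    between = g.mean().var()
    within = g.var().mean()
    return between / (within + 1e-12)


def test_lda_two_separated_classes(rng):
    df, labs = _blobs(rng, k=2, per=6, dim=8)
    labels = {f"r{i}": f"class{l}" for i, l in enumerate(labs)}
    scores, fractions = st.lda(df, labels)
    assert scores.shape[1] == 1  # at most n_classes - 1 discriminants
    assert fractions[0] == pytest.approx(1.0)
    a = scores["LD1"][[labels[i] == "class0" for i in scores.index]]
    b = scores["LD1"][[labels[i] == "class1" for i in scores.index]]
    assert a.min() > b.max() or b.min() > a.max()


def test_lda_permuted_labels_separate_less(rng):
    df, labs = _blobs(rng, k=2, per=8, dim=6, spread=0.3)
    labels = {f"r{i}": f"class{l}" for i, l in enumerate(labs)}
    true_sep = _sep_stat(st.lda(df, labels)[0], labels)
    perms = []
    keys = list(labels)
    values = np.array([labels[k] for k in keys])
    for _ in range(100):
        shuffled = values.copy()
        rng.shuffle(shuffled)
        perm_labels = dict(zip(keys, shuffled))
        if len(set(perm_labels.values())) < 2:
            continue
        perms.append(_sep_stat(st.lda(df, perm_labels)[0], perm_labels))
    assert true_sep > np.percentile(perms, 95)


def test_lda_row_order_invariant(rng):
    df, labs = _blobs(rng, k=2, per=5, dim=4)
    labels = {f"r{i}": f"class{l}" for i, l in enumerate(labs)}
    perm = df.sample(frac=1.0, random_state=3)
    sa, _ = st.lda(df, labels)
    sb, _ = st.lda(perm, labels)
    assert np.allclose(np.abs(sa.loc[perm.index].to_numpy()), np.abs(sb.to_numpy()), atol=1e-8)


def test_lda_single_observation_class_is_error(rng):
    df, _ = _blobs(rng, k=1, per=5, dim=3)
    labels = {f"r{i}": ("lonely" if i == 0 else "rest") for i in range(5)}
    with pytest.raises(ValueError, match="pool"):
        st.lda(df, labels)


# ---------------------------------------------------------------------------
# Welch

def test_welch_identical_groups():
    t, df, p = st.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == 0.0 and p == pytest.approx(1.0)


def test_welch_matches_hand_formula():
    x, y = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
    t, df, p = st.welch_t(x, y)
    t_ref, df_ref = welch_oracle(x, y)
    assert t == pytest.approx(t_ref)
    assert df == pytest.approx(df_ref)
    assert p == pytest.approx(2 * sps.t.sf(abs(t_ref), df_ref))


def test_welch_antisymmetric():
    x, y = [1.0, 5.0, 2.0], [4.0, 4.5, 8.0, 1.0]
    tx, _, px = st.welch_t(x, y)
    ty, _, py = st.welch_t(y, x)
    assert tx == pytest.approx(-ty) and px == pytest.approx(py)


def test_welch_short_input_is_error():
    with pytest.raises(ValueError):
        st.welch_t([1.0], [1.0, 2.0])


def test_welch_null_p_uniform(rng):
    ps = []
    for _ in range(2000):
        x = rng.normal(0, 1, size=6)
        y = rng.normal(0, 1, size=6)
        ps.append(st.welch_t(x, y)[2])
    ks = sps.kstest(ps, "uniform")
    assert ks.pvalue > 0.01


def test_welch_tests_table(rng):
    df = pd.DataFrame(rng.normal(10, 1, size=(5, 8)),
                      index=[f"f{i}" for i in range(5)],
                      columns=[f"s{i}" for i in range(8)])
    df.loc["f0", ["s0", "s1", "s2", "s3"]] += 15  # strong planted effect
    out = st.welch_tests(df, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)])
    assert out.loc["f0", "p"] < 0.01
    assert set(out.columns) >= {"t", "df", "p", "p_bh"}
    assert (out["p_bh"] >= out["p"] - 1e-12).all()
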
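import numpy as np
import pandas as pd
import pytest

from metaphi import quant
from metaphi.model import BinAlignment, PeptideRecord, QuantMatrix

from _oracles import phi_oracle


def _aln(bin_id, bits, evalue, peptide="PEPTIDEK"):
    return BinAlignment(peptide=peptide, bin_id=bin_id, candidate_id="c1",
                        raw_score=0, bit_score=float(bits), evalue=float(evalue))


# ---------------------------------------------------------------------------
# NSAF

def test_nsaf_single_peptide_is_one():
    [rec] = quant.compute_nsaf([PeptideRecord("PEPTIDEK", D=3, L=150.0)])
    assert rec.nsaf == 1.0


def test_nsaf_hand_example():
    recs = quant.compute_nsaf([PeptideRecord("AAAAA", D=10, L=100.0),
                               PeptideRecord("CCCCC", D=10, L=200.0)])
    assert recs[0].nsaf == pytest.approx(2 / 3)
    assert recs[1].nsaf == pytest.approx(1 / 3)


def test_nsaf_scale_invariant_and_conserved(rng):
    for _ in range(25):
        n = int(rng.integers(1, 40))
        D = rng.integers(1, 50, size=n)
        L = rng.uniform(20, 500, size=n)
        recs = quant.compute_nsaf(
            [PeptideRecord(f"p{i}", D=int(d), L=float(l)) for i, (d, l) in enumerate(zip(D, L))])
        scaled = quant.compute_nsaf(
            [PeptideRecord(f"p{i}", D=int(7 * d), L=float(l)) for i, (d, l) in enumerate(zip(D, L))])
        assert abs(sum(r.nsaf for r in recs) - 1.0) < 1e-12
        assert np.allclose([r.nsaf for r in recs], [r.nsaf for r in scaled])


def test_nsaf_errors():
    with pytest.raises(ValueError):
        quant.compute_nsaf([])
    with pytest.raises(ValueError):
        PeptideRecord("PEPTIDEK", D=1, L=0.0)


# ---------------------------------------------------------------------------
# score normalization and phi_N

def test_normalize_bin_scores_minmax():
    alns = [_aln("b1", 60, 1e-9), _aln("b2", 50, 1e-9), _aln("b3", 40, 1e-9)]
    quant.normalize_bin_scores(alns)
    assert [a.norm_score for a in alns] == [1.0, 0.5, 0.0]


def test_normalize_single_qualifying_bin_gets_one():
    alns = [_aln("b1", 60, 1e-9), _aln("b2", 80, 0.5), None]
    quant.normalize_bin_scores(alns)
    assert alns[0].norm_score == 1.0
    assert alns[1].norm_score is None  # fails the gate


def test_normalize_all_gated_out():
    alns = [_aln("b1", 60, 0.02), _aln("b2", 50, 0.9)]
    quant.normalize_bin_scores(alns)
    assert all(a.norm_score is None for a in alns)


def test_phi_n_gate_and_bounds():
    gated = _aln("b1", 60, 0.05)
    assert quant.compute_phi_n(0.02, gated) == 0.0
    assert quant.compute_phi_n(0.02, None) == 0.0
    top = _aln("b1", 60, 1e-9)
    top.norm_score = 1.0
    assert quant.compute_phi_n(0.02, top) == pytest.approx(0.02)
    top.norm_score = 0.5
    assert quant.compute_phi_n(0.02, top) == pytest.approx(0.01)


# ---------------------------------------------------------------------------
# aggregation and Phi

def test_aggregate_phi_p_additive_and_order_invariant():
    recs = [quant.PhiRecord("p1", "b1", 0.1, 0.1, 1.0),
            quant.PhiRecord("p2", "b1", 0.2, 0.2, 1.0),
            quant.PhiRecord("p3", "b2", 0.3, 0.3, 1.0)]
    membership = {"p1": "X", "p2": "X", "p3": "Y"}
    m = quant.aggregate_phi_p(recs, membership)
    assert m.value("X", "b1") == pytest.approx(0.3)
    assert m.value("Y", "b2") == pytest.approx(0.3)
    m2 = quant.aggregate_phi_p(list(reversed(recs)), membership)
    pd.testing.assert_frame_equal(m.data, m2.data)


def _phi(df):
    return QuantMatrix(data=df, kind="phi")


def test_phi_bin_row_scaling():
    m = _phi(pd.DataFrame([[2.0, 1.0, 4.0], [0.0, 0.0, 0.0]],
                          index=["f1", "f2"], columns=["b1", "b2", "b3"]))
    out = quant.compute_phi_bin(m)
    assert list(out.data.loc["f1"]) == [0.5, 0.25, 1.0]
    assert (out.data.loc["f2"] == 0.0).all()


def test_phi_function_is_transpose_dual(rng):
    df = pd.DataFrame(rng.random((6, 4)), index=[f"f{i}" for i in range(6)],
                      columns=[f"b{i}" for i in range(4)])
    df.iloc[2] = 0.0
    direct = quant.compute_phi_function(_phi(df))
    dual = quant.compute_phi_bin(_phi(df.T)).data.T
    assert np.allclose(direct.data.to_numpy(), dual.to_numpy())
    # every nonzero column attains exactly 1
    for c in direct.data.columns:
        col = direct.data[c]
        assert col.max() == pytest.approx(1.0) or (col == 0).all()


def test_ribosome_normalize():
    m = QuantMatrix(pd.DataFrame([[1.0, 0.0], [0.5, 0.5], [0.5, 0.5]],
                                 index=["f1", "f2", "Ribosome"], columns=["b1", "b2"]),
                    kind="phi_bin")
    out = quant.ribosome_normalize(m)
    assert list(out.loc["f1"]) == [0.5, -0.5]
    assert (out.loc["f2"] == 0.0).all()
    assert (out.loc["Ribosome"] == 0.0).all()
    assert out.to_numpy().min() >= -1.0 and out.to_numpy().max() <= 1.0


def test_ribosome_normalize_missing_row_is_error():
    m = QuantMatrix(pd.DataFrame([[1.0]], index=["f1"], columns=["b1"]), kind="phi_bin")
    with pytest.raises(ValueError, match="Ribosome"):
        quant.ribosome_normalize(m)


def test_average_over_samples_missing_as_zero():
    m1 = _phi(pd.DataFrame([[1.0]], index=["f1"], columns=["b1"]))
    m2 = _phi(pd.DataFrame([[0.0]], index=["f2"], columns=["b1"]))
    avg = quant.average_over_samples({"s1": m1, "s2": m2}, ["s1", "s2"])
    assert avg.value("f1", "b1") == pytest.approx(0.5)
    assert avg.value("f2", "b1") == 0.0
    one = quant.average_over_samples({"s1": m1}, ["s1"])
    pd.testing.assert_frame_equal(one.data, m1.data)
    with pytest.raises(ValueError):
        quant.average_over_samples({"s1": m1}, [])


# ---------------------------------------------------------------------------
# equivalence with a scalar single-pass reference

def test_phi_chain_matches_scalar_reference(rng):
    bins = [f"b{i}" for i in range(4)]
    for _ in range(20):
        n_pep = int(rng.integers(2, 25))
        peptides = [f"p{i}" for i in range(n_pep)]
        D = rng.integers(1, 30, size=n_pep)
        L = rng.uniform(50, 400, size=n_pep)
        recs = quant.compute_nsaf(
            [PeptideRecord(p, D=int(d), L=float(l)) for p, d, l in zip(peptides, D, L)])
        nsaf = {r.peptide: r.nsaf for r in recs}
        membership = {p: f"fn{rng.integers(3)}" for p in peptides}

        bits, evalues, alignments = {}, {}, {}
        for p in peptides:
            per_bin = []
            for b in bins:
                if rng.random() < 0.2:
                    per_bin.append(None)
                    continue
                bval = float(rng.uniform(20, 80))
                ev = float(rng.choice([1e-6, 1e-3, 0.5]))
                bits[(p, b)] = bval
                evalues[(p, b)] = ev
                per_bin.append(_aln(b, bval, ev, peptide=p))
            quant.normalize_bin_scores(per_bin)
            alignments[p] = dict(zip(bins, per_bin))

        phi_records = [
            quant.PhiRecord(p, b, quant.compute_phi_n(nsaf[p], alignments[p][b]), nsaf[p])
            for p in peptides for b in bins
        ]
        m = quant.aggregate_phi_p(phi_records, membership)
        m = QuantMatrix(m.data.reindex(columns=bins, fill_value=0.0), kind="phi")
        got_bin = quant.compute_phi_bin(m)
        got_fn = quant.compute_phi_function(m)

        ref_p, ref_bin, ref_fn = phi_oracle(nsaf, bits, evalues, membership, bins)
        for f in m.row_keys:
            for b in bins:
                assert m.value(f, b) == pytest.approx(ref_p[(f, b)], abs=1e-9)
                assert got_bin.value(f, b) == pytest.approx(ref_bin[(f, b)], abs=1e-9)
                assert got_fn.value(f, b) == pytest.approx(ref_fn[(f, b)], abs=1e-9)
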
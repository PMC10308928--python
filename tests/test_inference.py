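import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from metaphi import inference as inf
from metaphi.model import PSM, CandidateHit, FunctionalGroupMap

from _oracles import fdr_sweep_oracle


def _psm(i, score, decoy=False, peptide="PEPTIDEK", sample="s1"):
    return PSM(sample_id=sample, spectrum_id=f"sp{i}", peptide=peptide,
               candidate_ids=(f"c{i}",), search_score=float(score),
               search_evalue=1e-6, is_decoy=decoy)


# ---------------------------------------------------------------------------
# FDR

def test_fdr_filter_requires_both_classes():
    with pytest.raises(ValueError, match="decoy"):
        inf.fdr_filter([_psm(0, 10), _psm(1, 9)])
    with pytest.raises(ValueError, match="target"):
        inf.fdr_filter([_psm(0, 10, decoy=True), _psm(1, 9, decoy=True)])


def test_fdr_filter_loose_cutoff_keeps_all_targets():
    psms = [_psm(0, 10), _psm(1, 9), _psm(2, 8), _psm(3, 1, decoy=True)]
    res = inf.fdr_filter(psms, q_cutoff=1.0)
    assert sorted(p.spectrum_id for p in res.kept) == ["sp0", "sp1", "sp2"]


def test_fdr_q_values_monotone_in_score(rng):
    psms = [_psm(i, rng.normal(0, 5), decoy=bool(rng.integers(2))) for i in range(100)]
    if not any(p.is_decoy for p in psms) or all(p.is_decoy for p in psms):
        psms += [_psm(1000, -20, decoy=True), _psm(1001, 20)]
    res = inf.fdr_filter(psms, q_cutoff=0.05)
    ranked = sorted(psms, key=lambda p: -p.search_score)
    qs = [res.q_values[p.spectrum_id] for p in ranked]
    assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))


def test_fdr_matches_bruteforce_sweep(rng):
    for trial in range(40):
        n = int(rng.integers(5, 60))
        scores = np.round(rng.normal(0, 3, size=n), 1)  # rounding forces ties
        decoy = rng.random(n) < 0.4
        if decoy.all() or not decoy.any():
            continue
        cutoff = float(rng.choice([0.01, 0.05, 0.2, 0.5]))
        psms = [_psm(i, s, d) for i, (s, d) in enumerate(zip(scores, decoy))]
        res = inf.fdr_filter(psms, q_cutoff=cutoff)
        kept_idx, q_oracle = fdr_sweep_oracle(list(scores), list(decoy), cutoff)
        assert sorted(p.spectrum_id for p in res.kept) == sorted(f"sp{i}" for i in kept_idx)
        for i in range(n):
            assert res.q_values[f"sp{i}"] == pytest.approx(q_oracle[i]), trial


# ---------------------------------------------------------------------------
# hit filtering

def _hits(scores):
    return [CandidateHit(candidate_id="c", subject_id=f"s{i}", bit_score=float(b),
                         rank=i + 1) for i, b in enumerate(scores)]


def test_filter_top_hits_ten_percent_rule():
    kept = inf.filter_top_hits(_hits([100, 95, 89, 50]))
    assert [h.bit_score for h in kept] == [100, 95]


def test_filter_top_hits_edge_cases():
    assert inf.filter_top_hits([]) == []
    assert len(inf.filter_top_hits(_hits([70, 70, 70]))) == 3
    assert len(inf.filter_top_hits(_hits([42]))) == 1


@pytest.mark.parametrize(
    "m, expected_ranks",
    [(500, [1, 125, 250, 375, 500]), (5, [1, 2, 3, 4, 5]), (9, [1, 3, 5, 7, 9]),
     (6, [1, 2, 3, 4, 6]), (2, [1, 2])],
)
def test_subsample_hits_even_ranks(m, expected_ranks):
    hits = _hits(range(m, 0, -1))
    kept = inf.subsample_hits(hits)
    assert [h.rank for h in kept] == expected_ranks


def test_subsample_hits_cap_below_two_is_error():
    with pytest.raises(ValueError):
        inf.subsample_hits(_hits([3, 2, 1]), cap=1)


@given(st.integers(1, 600), st.integers(2, 10))
def test_subsample_hits_properties(m, cap):
    kept = inf.subsample_hits(_hits(range(m, 0, -1)), cap=cap)
    ranks = [h.rank for h in kept]
    assert len(kept) == min(m, cap)
    assert ranks[0] == 1 and ranks[-1] == m
    assert ranks == sorted(set(ranks))


# ---------------------------------------------------------------------------
# description consistency and metaproteins

CS = "Citrate synthase"


def _annotated_hit(cand, desc, fam="CITA"):
    return CandidateHit(candidate_id=cand, subject_id=f"{cand}|s", bit_score=50.0,
                        rank=1, gene_family=fam, description=desc)


def test_consistent_description_agreement():
    psm = PSM("s1", "sp1", "PEPTIDEK", ("c1", "c2"), 10.0, 1e-6)
    hits = {"c1": [_annotated_hit("c1", CS)], "c2": [_annotated_hit("c2", CS)]}
    assert inf.consistent_description(psm, hits) == CS


def test_consistent_description_disagreement_or_unannotated():
    psm = PSM("s1", "sp1", "PEPTIDEK", ("c1", "c2"), 10.0, 1e-6)
    hits = {"c1": [_annotated_hit("c1", CS)], "c2": [_annotated_hit("c2", "Aconitase")]}
    assert inf.consistent_description(psm, hits) is None
    assert inf.consistent_description(psm, {"c1": [], "c2": []}) is None


def test_build_metaproteins_groups_and_partitions():
    psms = [_psm(0, 10), _psm(1, 9), _psm(2, 8)]
    mps = inf.build_metaproteins(psms, {"sp0": "X", "sp1": "X", "sp2": "Y"})
    assert {m.label: m.psm_ids for m in mps} == {
        "X": frozenset({"sp0", "sp1"}), "Y": frozenset({"sp2"})}
    all_ids = [i for m in mps for i in m.psm_ids]
    assert len(all_ids) == len(set(all_ids))  # partition


def test_build_metaproteins_case_sensitive():
    psms = [_psm(0, 10), _psm(1, 9)]
    mps = inf.build_metaproteins(psms, {"sp0": "citrate synthase", "sp1": CS})
    assert len(mps) == 2


def test_build_metaproteins_empty():
    assert inf.build_metaproteins([], {}) == []


def test_assign_functional_group():
    fgmap = FunctionalGroupMap(
        entries={("CITA", CS): "TCA Cycle"},
        by_description={"Hydrolase, family 38": "Mannose Cleavage"})
    assert inf.assign_functional_group("CITA", CS, fgmap) == "TCA Cycle"
    assert inf.assign_functional_group(None, "Hydrolase, family 38", fgmap) == "Mannose Cleavage"
    assert inf.assign_functional_group("ZZZZ", "Unknown protein", fgmap) == "unassigned"
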
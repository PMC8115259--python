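import numpy as np
import pandas as pd
import pytest

from dualcore import core_extraction as ce
from dualcore.datatypes import AbundanceTable, CoreSet, FunctionTable, GenomeContentTable

from ._oracles import loop_prevalence


def _table(counts, asvs=None, samples=None):
    counts = np.asarray(counts, dtype=float)
    asvs = asvs or [f"a{i}" for i in range(counts.shape[0])]
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    return AbundanceTable(pd.DataFrame(counts, index=asvs, columns=samples))


def _ten_sample_table(n_present):
    row = [1] * n_present + [0] * (10 - n_present)
    return _table([row, [1] * 10])


# --- prevalence -------------------------------------------------------------


def test_prevalence_eight_of_ten():
    assert ce.prevalence(_ten_sample_table(8))["a0"] == pytest.approx(0.8)


def test_prevalence_all_zero_row():
    assert ce.prevalence(_table([[0, 0, 0], [1, 1, 1]]))["a0"] == 0.0


def test_prevalence_everywhere():
    assert ce.prevalence(_table([[2, 5, 1]]))["a0"] == 1.0


def test_prevalence_empty_table_errors():
    with pytest.raises(ValueError):
        ce.prevalence(AbundanceTable(pd.DataFrame(index=["a"], columns=[], dtype=float)))


def test_prevalence_matches_naive_loop():
    rng = np.random.default_rng(42)
    for _ in range(10):
        counts = rng.integers(0, 3, size=(8, 12))
        table = _table(counts)
        np.testing.assert_allclose(
            ce.prevalence(table).to_numpy(), loop_prevalence(counts)
        )


# --- taxonomic core ---------------------------------------------------------


def test_taxonomic_core_member_at_75pct():
    core = ce.taxonomic_core(_ten_sample_table(8), cutoff=0.75)
    assert "a0" in core


def test_taxonomic_core_boundary_exclusion():
    core = ce.taxonomic_core(_ten_sample_table(7), cutoff=0.75)
    assert "a0" not in core  # 0.7 < 0.75
    assert "a1" in core


def test_taxonomic_core_cutoff_one_excludes_any_absence():
    core = ce.taxonomic_core(_ten_sample_table(9), cutoff=1.0)
    assert "a0" not in core
    assert "a1" in core


def test_taxonomic_core_invalid_cutoff():
    for bad in (0.0, 1.5, -0.1):
        with pytest.raises(ValueError):
            ce.taxonomic_core(_ten_sample_table(8), cutoff=bad)


def test_taxonomic_core_monotone_in_cutoff():
    rng = np.random.default_rng(7)
    table = _table(rng.integers(0, 2, size=(20, 15)))
    cutoffs = [0.5, 0.6, 0.75, 0.9, 1.0]
    cores = [ce.taxonomic_core(table, c).member_ids for c in cutoffs]
    for lower, higher in zip(cores, cores[1:]):
        assert higher <= lower


# --- core KOs ---------------------------------------------------------------


def _ko_table(mat):
    mat = np.asarray(mat, dtype=float)
    return FunctionTable(
        level="KO",
        data=pd.DataFrame(
            mat,
            index=[f"K{i}" for i in range(mat.shape[0])],
            columns=[f"s{j}" for j in range(mat.shape[1])],
        ),
    )


def test_core_kos_nine_of_ten():
    kt = _ko_table([[1] * 9 + [0], [1] * 10])
    assert ce.core_kos(kt, cutoff=0.75) == {"K0", "K1"}


def test_core_kos_absent_never_core():
    kt = _ko_table([[0, 0, 0], [1, 1, 1]])
    assert ce.core_kos(kt, cutoff=0.5) == {"K1"}


def test_core_kos_all_present_all_core():
    kt = _ko_table(np.ones((4, 6)))
    assert ce.core_kos(kt, cutoff=1.0) == {"K0", "K1", "K2", "K3"}


def test_core_kos_rejects_pathway_level():
    ft = FunctionTable(level="pathway", data=pd.DataFrame([[1.0]], index=["P"], columns=["s"]))
    with pytest.raises(ValueError, match="KO-level"):
        ce.core_kos(ft)


def test_core_kos_monotone_in_cutoff():
    rng = np.random.default_rng(3)
    kt = _ko_table(rng.integers(0, 2, size=(12, 10)))
    cores = [ce.core_kos(kt, c) for c in (0.5, 0.7, 0.9)]
    assert cores[2] <= cores[1] <= cores[0]


# --- functional core --------------------------------------------------------


def _gc(copies, asvs, kos, ssu=None):
    copies = pd.DataFrame(copies, index=asvs, columns=kos, dtype=int)
    ssu = pd.Series(ssu if ssu is not None else 1, index=asvs)
    return GenomeContentTable(ko_copies=copies, ssu_copies=ssu)


def test_functional_core_carrier_with_high_prevalence():
    table = _table([[1] * 8 + [0, 0], [1] * 10], asvs=["a", "b"])
    gc = _gc([[2], [0]], ["a", "b"], ["K1"])
    core = ce.functional_core(table, gc, {"K1"}, cutoff=0.75)
    assert "a" in core
    assert core.provenance["a"] == {"K1"}


def test_functional_core_non_carrier_excluded_despite_ubiquity():
    table = _table([[1] * 10, [1] * 10], asvs=["a", "b"])
    gc = _gc([[1], [0]], ["a", "b"], ["K1"])
    core = ce.functional_core(table, gc, {"K1"})
    assert "b" not in core


def test_functional_core_multi_ko_counted_once():
    table = _table([[1] * 10], asvs=["a"])
    gc = _gc([[1, 2, 3]], ["a"], ["K1", "K2", "K3"])
    core = ce.functional_core(table, gc, {"K1", "K2", "K3"})
    assert core.member_ids == {"a"}
    assert core.provenance["a"] == {"K1", "K2", "K3"}


def test_functional_core_empty_ko_set_warns_not_errors(caplog):
    table = _table([[1] * 10], asvs=["a"])
    gc = _gc([[1]], ["a"], ["K1"])
    core = ce.functional_core(table, gc, frozenset())
    assert len(core) == 0


def test_functional_core_unknown_ko_rejected():
    table = _table([[1] * 10], asvs=["a"])
    gc = _gc([[1]], ["a"], ["K1"])
    with pytest.raises(ValueError, match="K9"):
        ce.functional_core(table, gc, {"K9"})


def test_functional_core_carrier_includes_low_prevalence_redundant():
    # the redundancy-inclusive default: a carrier below the taxonomic cut-off
    # still qualifies
    table = _table([[1] * 10, [1, 1, 1] + [0] * 7], asvs=["a", "b"])
    gc = _gc([[1], [2]], ["a", "b"], ["K1"])
    core = ce.functional_core(table, gc, {"K1"}, cutoff=0.75)
    assert core.member_ids == {"a", "b"}


def test_functional_core_all_samples_mode_requires_cutoff():
    table = _table([[1] * 10, [1, 1, 1] + [0] * 7], asvs=["a", "b"])
    gc = _gc([[1], [2]], ["a", "b"], ["K1"])
    core = ce.functional_core(
        table, gc, {"K1"}, cutoff=0.75, prevalence_mode="all_samples"
    )
    assert core.member_ids == {"a"}


def test_functional_minus_taxonomic_nonempty_on_planted_scenario(default_scenario):
    _, (table, _, gc, _, _, truth) = default_scenario
    from dualcore.function_prediction import predict_metagenome

    kos = ce.core_kos(predict_metagenome(table, gc), cutoff=0.75)
    fun = ce.functional_core(table, gc, kos, cutoff=0.75)
    tax = ce.taxonomic_core(table, cutoff=0.75)
    assert fun.member_ids - tax.member_ids


# --- filtering, overlap, coverage, summary ----------------------------------


def _core(ids, kind="taxonomic", cutoff=0.75):
    prev = {i: 1.0 for i in ids}
    prov = {i: frozenset({"K"}) for i in ids} if kind == "functional" else {}
    return CoreSet(kind=kind, member_ids=frozenset(ids), cutoff=cutoff,
                   prevalence=prev, provenance=prov)


def test_filter_to_core_shape():
    table = _table(np.ones((5, 4)))
    sub = ce.filter_to_core(table, _core(["a0", "a3"]))
    assert sub.asv_ids == ["a0", "a3"]
    assert sub.n_samples == 4


def test_filter_to_core_identity():
    table = _table(np.arange(12).reshape(3, 4))
    sub = ce.filter_to_core(table, _core(["a0", "a1", "a2"]))
    pd.testing.assert_frame_equal(sub.data, table.data)


def test_filter_to_core_drops_zero_samples(caplog):
    table = _table([[1, 0, 2], [0, 0, 1], [5, 7, 0]])
    with caplog.at_level("INFO", logger="dualcore.core_extraction"):
        sub = ce.filter_to_core(table, _core(["a0", "a1"]))
    assert sub.sample_ids == ["s0", "s2"]
    assert "dropped 1" in caplog.text


def test_filter_to_core_missing_member_errors():
    table = _table(np.ones((2, 2)))
    with pytest.raises(ValueError, match="zz"):
        ce.filter_to_core(table, _core(["a0", "zz"]))


def test_shared_core_examples():
    shared, pct = ce.shared_core(_core(["a", "b"]), _core(["b", "c"], kind="functional"))
    assert shared == {"b"}
    assert pct == pytest.approx(100 / 3, abs=0.01)
    assert ce.shared_core(_core(["a"]), _core(["b"], kind="functional"))[1] == 0.0
    assert ce.shared_core(_core(["a"]), _core(["a"], kind="functional"))[1] == 100.0


def test_goods_coverage_examples():
    col = np.array([1] * 5 + [2] * 95)
    assert ce.goods_coverage(col) == pytest.approx(0.95)
    assert ce.goods_coverage(np.array([2, 3, 5])) == 1.0
    assert ce.goods_coverage(np.array([1, 1, 1])) == 0.0
    with pytest.raises(ValueError):
        ce.goods_coverage(np.zeros(4))


def test_core_summary_examples():
    counts = np.ones((100, 4))
    table = _table(counts)
    core3 = _core(["a0", "a1", "a2"])
    summary = ce.core_summary(table, core3, core3)
    assert summary.pct_of_all_asvs == pytest.approx(3.0)
    assert summary.pct_shared == 100.0
    # core rows carrying half of every sample's reads
    counts = np.ones((4, 3))
    counts[:2] = 1.0
    counts[2:] = 1.0
    table = _table(counts)
    summary = ce.core_summary(table, _core(["a0", "a1"]), _core(["a0"]))
    assert summary.pct_of_total_relative_abundance == pytest.approx(50.0)


def test_noise_free_functional_core_exact(noise_free_scenario):
    _, (table, _, gc, _, _, truth) = noise_free_scenario
    from dualcore.function_prediction import predict_metagenome

    kos = ce.core_kos(predict_metagenome(table, gc), cutoff=0.75)
    assert kos == truth.core_ko_ids
    fun = ce.functional_core(table, gc, kos, cutoff=0.75)
    assert fun.member_ids == truth.functional_core_ids
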
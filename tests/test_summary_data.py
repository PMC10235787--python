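import numpy as np
import pandas as pd
import pytest

from mrmed.exceptions import (
    ConfigurationError,
    EmptyInputError,
    EmptyInstrumentError,
)
from mrmed.summary_data import (
    LDInfo,
    greedy_clump,
    harmonise,
    instrument_strength,
    pool_for_mvmr,
    read_gwas,
    select_instruments,
)

from conftest import make_stats
from oracles import clump_oracle


# ---------------------------------------------------------------- read_gwas


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


WELL_FORMED = (
    "variant_id\teffect_allele\tother_allele\tbeta\tse\tpval\teaf\tn\n"
    "rs1\tA\tG\t0.1\t0.01\t1e-20\t0.3\t1000\n"
    "rs2\tC\tT\t-0.05\t0.02\t0.01\t0.4\t1000\n"
    "rs3\tG\tA\t0.2\t0.05\t1e-4\t0.2\t1000\n"
)


def test_read_well_formed_tsv(tmp_path):
    ss = read_gwas(_write(tmp_path, "x.tsv", WELL_FORMED))
    assert len(ss) == 3
    assert ss.variant_ids == ["rs1", "rs2", "rs3"]


def test_zero_se_row_dropped(tmp_path, caplog):
    text = WELL_FORMED + "rs4\tA\tG\t0.1\t0\t0.5\t0.3\t1000\n"
    with caplog.at_level("WARNING"):
        ss = read_gwas(_write(tmp_path, "x.tsv", text))
    assert len(ss) == 3
    assert "rs4" not in ss.variant_ids
    assert "dropped 1" in caplog.text


def test_column_map_shuffled_order_identical(tmp_path):
    direct = read_gwas(_write(tmp_path, "a.tsv", WELL_FORMED), trait_id="t")
    shuffled = (
        "p\tOA\tBETA\tSNP\tSE\tEA\tfreq\tsamples\n"
        "1e-20\tG\t0.1\trs1\t0.01\tA\t0.3\t1000\n"
        "0.01\tT\t-0.05\trs2\t0.02\tC\t0.4\t1000\n"
        "1e-4\tA\t0.2\trs3\t0.05\tG\t0.2\t1000\n"
    )
    cmap = {
        "variant_id": "SNP",
        "effect_allele": "EA",
        "other_allele": "OA",
        "beta": "BETA",
        "se": "SE",
        "pval": "p",
        "eaf": "freq",
        "n": "samples",
    }
    mapped = read_gwas(_write(tmp_path, "b.tsv", shuffled), column_map=cmap, trait_id="t")
    pd.testing.assert_frame_equal(direct.variants, mapped.variants)


def test_missing_required_column_raises(tmp_path):
    p = _write(tmp_path, "x.tsv", "variant_id\tbeta\nrs1\t0.1\n")
    with pytest.raises(ConfigurationError, match="required column"):
        read_gwas(p)


def test_all_rows_invalid_raises(tmp_path):
    text = "variant_id\teffect_allele\tother_allele\tbeta\tse\tpval\nrs1\tA\tG\t0.1\t0\t0.5\n"
    with pytest.raises(EmptyInputError):
        read_gwas(_write(tmp_path, "x.tsv", text))


def test_csv_and_gzip_accepted(tmp_path):
    import gzip

    csv_text = WELL_FORMED.replace("\t", ",")
    p = tmp_path / "x.csv.gz"
    p.write_bytes(gzip.compress(csv_text.encode()))
    assert len(read_gwas(p)) == 3


# ---------------------------------------------------------------- harmonise


def test_already_aligned_betas_kept():
    x = make_stats("X", [0.10], [0.01])
    y = make_stats("Y", [0.05], [0.01])
    h = harmonise([x, y])
    assert h.beta[0, 0] == 0.10
    assert h.beta[0, 1] == 0.05


def test_swapped_alleles_negate_beta():
    x = make_stats("X", [0.10], [0.01], ea="A", oa="G")
    y = make_stats("Y", [0.05], [0.01], ea="G", oa="A")
    h = harmonise([x, y])
    assert h.beta[0, 1] == -0.05


def test_palindromic_aligned_by_letters_not_dropped():
    x = make_stats("X", [0.1, 0.2], [0.01, 0.01], ea="A", oa="T")
    y = make_stats("Y", [0.05, -0.02], [0.01, 0.01], ea="T", oa="A")
    h = harmonise([x, y])
    assert h.n_variants == 2
    np.testing.assert_allclose(h.beta[:, 1], [-0.05, 0.02])


def test_incompatible_alleles_dropped(caplog):
    x = make_stats("X", [0.1, 0.2], [0.01, 0.01], ea="A", oa="G")
    ydf = make_stats("Y", [0.05, 0.07], [0.01, 0.01], ea="A", oa="G").variants.copy()
    ydf.loc[1, ["effect_allele", "other_allele"]] = ["C", "T"]
    y = make_stats("Y", [0.05, 0.07], [0.01, 0.01])
    y.variants = ydf
    with caplog.at_level("WARNING"):
        h = harmonise([x, y])
    assert h.variant_ids == ["rs1"]


def test_preflipped_round_trip_identical():
    rng = np.random.default_rng(7)
    bx = rng.normal(0, 0.1, 6)
    by = rng.normal(0, 0.1, 6)
    x = make_stats("X", bx, np.full(6, 0.01), ea="A", oa="G")
    y = make_stats("Y", by, np.full(6, 0.01), ea="A", oa="G")
    y_flipped = make_stats("Y", -by, np.full(6, 0.01), ea="G", oa="A")
    h1 = harmonise([x, y])
    h2 = harmonise([x, y_flipped])
    np.testing.assert_allclose(h1.beta, h2.beta)
    np.testing.assert_allclose(h1.se, h2.se)


def test_intersection_only_no_proxies():
    x = make_stats("X", [0.1, 0.2, 0.3], [0.01] * 3, ids=["rs1", "rs2", "rs3"])
    y = make_stats("Y", [0.1, 0.2], [0.01] * 2, ids=["rs2", "rs9"])
    h = harmonise([x, y])
    assert h.variant_ids == ["rs2"]


def test_fewer_than_two_tables_raises():
    x = make_stats("X", [0.1], [0.01])
    with pytest.raises(ConfigurationError):
        harmonise([x])


def test_empty_intersection_raises():
    x = make_stats("X", [0.1], [0.01], ids=["rs1"])
    y = make_stats("Y", [0.1], [0.01], ids=["rs2"])
    with pytest.raises(EmptyInputError):
        harmonise([x, y])


def test_sign_consistency_negating_one_table():
    rng = np.random.default_rng(3)
    bx = rng.normal(0, 0.1, 5)
    by = rng.normal(0, 0.1, 5)
    x = make_stats("X", bx, np.full(5, 0.01))
    y = make_stats("Y", by, np.full(5, 0.01))
    y_neg = make_stats("Y", -by, np.full(5, 0.01))
    h = harmonise([x, y])
    h_neg = harmonise([x, y_neg])
    np.testing.assert_allclose(h_neg.beta[:, 0], h.beta[:, 0])
    np.testing.assert_allclose(h_neg.beta[:, 1], -h.beta[:, 1])


# ---------------------------------------------------------------- LD + clump


def test_ld_symmetric_default_zero():
    ld = LDInfo({("a", "b"): 0.5})
    assert ld.r2("b", "a") == 0.5
    assert ld.r2("a", "c") == 0.0
    assert ld.r2("a", "a") == 1.0


def test_ld_long_and_dense_round_trip(tmp_path):
    ld = LDInfo({("rs1", "rs2"): 0.8, ("rs2", "rs3"): 0.4})
    p = tmp_path / "ld.tsv"
    ld.to_table(p)
    ld2 = LDInfo.from_table(p)
    assert ld2.r2("rs1", "rs2") == 0.8
    assert ld2.r2("rs3", "rs2") == 0.4

    dense = tmp_path / "dense.tsv"
    dense.write_text(
        "id\trs1\trs2\trs3\nrs1\t1\t0.8\t0\nrs2\t0.8\t1\t0.4\nrs3\t0\t0.4\t1\n"
    )
    ld3 = LDInfo.from_table(dense)
    assert ld3.r2("rs1", "rs2") == 0.8


def test_independent_variants_all_kept(empty_ld):
    ss = make_stats("X", [0.1] * 5, [0.005] * 5, pvals=[1e-10] * 5)
    inst = select_instruments(ss, empty_ld)
    assert len(inst) == 5


def test_clump_dominance():
    ss = make_stats("X", [0.1, 0.1], [0.005] * 2, pvals=[1e-10, 1e-9])
    ld = LDInfo({("rs1", "rs2"): 0.9})
    inst = select_instruments(ss, ld)
    assert inst.variant_ids == ["rs1"]


def test_no_passing_variant_raises(empty_ld):
    ss = make_stats("X", [0.01], [0.01], pvals=[0.5])
    with pytest.raises(EmptyInstrumentError, match="X"):
        select_instruments(ss, empty_ld)


def test_clump_matches_bruteforce_oracle(rng):
    for trial in range(10):
        local = np.random.default_rng(trial)
        n = 20
        ids = [f"rs{i}" for i in range(n)]
        pvals = {v: float(local.uniform(1e-12, 1e-8)) for v in ids}
        pairs = {}
        for i in range(n):
            for j in range(i + 1, n):
                if local.random() < 0.2:
                    pairs[frozenset((ids[i], ids[j]))] = float(local.uniform(0, 1))
        ld = LDInfo({tuple(sorted(k)): v for k, v in pairs.items()})
        cand = pd.DataFrame({"variant_id": ids, "pval": [pvals[v] for v in ids]})
        got = greedy_clump(cand, ld, 0.1)
        expected = clump_oracle(pvals, pairs, 0.1)
        assert got == expected
        # returned set is independent at the threshold
        for a in got:
            for b in got:
                if a != b:
                    assert ld.r2(a, b) < 0.1


def test_clump_deterministic_tie_break():
    ss = make_stats("X", [0.1, 0.1], [0.005] * 2, pvals=[1e-10, 1e-10], ids=["rsB", "rsA"])
    ld = LDInfo({("rsA", "rsB"): 0.9})
    inst = select_instruments(ss, ld)
    assert inst.variant_ids == ["rsA"]


# ---------------------------------------------------------------- strength


def test_f_statistic_direct_formula(empty_ld):
    ss = make_stats("X", [0.1], [0.01], pvals=[1e-20])
    tab = instrument_strength(["rs1"], ss)
    assert tab["F"].iloc[0] == pytest.approx(100.0)


def test_zero_beta_zero_f():
    ss = make_stats("X", [0.0, 0.1], [0.02, 0.01], pvals=[0.9, 1e-20])
    tab = instrument_strength(["rs1"], ss)
    assert tab["F"].iloc[0] == 0.0
    assert tab["r2"].iloc[0] == 0.0


def test_r2_eaf_formula_and_fallback():
    ss = make_stats("X", [0.1], [0.01], eafs=[0.25], pvals=[1e-20])
    tab = instrument_strength(["rs1"], ss)
    assert tab["r2"].iloc[0] == pytest.approx(2 * 0.25 * 0.75 * 0.01)
    assert tab["r2_formula"].iloc[0] == "2p(1-p)b^2"

    ss2 = make_stats("X", [0.1], [0.01], pvals=[1e-20], n=1000)
    ss2.variants["eaf"] = np.nan
    tab2 = instrument_strength(["rs1"], ss2)
    f = 100.0
    assert tab2["r2"].iloc[0] == pytest.approx(f / (f + 1000 - 2))
    assert tab2["r2_formula"].iloc[0] == "F/(F+n-2)"


def test_f_only_when_eaf_and_n_missing(caplog):
    ss = make_stats("X", [0.1], [0.01], pvals=[1e-20])
    ss.variants["eaf"] = np.nan
    ss.variants["n"] = np.nan
    with caplog.at_level("WARNING"):
        tab = instrument_strength(["rs1"], ss)
    assert np.isnan(tab["r2"].iloc[0])
    assert "F only" in caplog.text


def test_weak_instruments_flagged_not_dropped(empty_ld):
    ss = make_stats("X", [0.1, 0.002], [0.005, 0.001], pvals=[1e-10, 4e-8])
    inst = select_instruments(ss, empty_ld)
    assert len(inst) == 2
    weak = inst.table.set_index("variant_id")["weak"]
    assert not weak["rs1"]
    assert weak["rs2"]


def test_total_r2_recovery_from_generator():
    # simulated instruments with known per-variant variance explained
    from mrmed.synthetic_data import TruthConfig, simulate

    cfg = TruthConfig(J=300, seed=11, mediator_frac=0.0, n_exp=2_000_000)
    st = simulate(cfg)
    truth = st.truth
    true_r2 = float(np.sum(2 * truth["maf"] * (1 - truth["maf"]) * truth["gamma"] ** 2))
    tab = instrument_strength(st.exposure.variant_ids, st.exposure)
    assert float(tab["r2"].sum()) == pytest.approx(true_r2, rel=0.05)


# ---------------------------------------------------------------- pooling


def test_pool_disjoint_union(empty_ld):
    x = make_stats("X", [0.1, 0.01], [0.005, 0.01], pvals=[1e-10, 0.5])
    m = make_stats("M", [0.01, 0.1], [0.01, 0.005], pvals=[0.5, 1e-10])
    pooled = pool_for_mvmr([x, m], empty_ld)
    assert sorted(pooled.variant_ids) == ["rs1", "rs2"]


def test_pool_shared_variant_counted_once(empty_ld):
    x = make_stats("X", [0.1], [0.005], pvals=[1e-10])
    m = make_stats("M", [0.1], [0.005], pvals=[1e-12])
    pooled = pool_for_mvmr([x, m], empty_ld)
    assert pooled.variant_ids == ["rs1"]


def test_pool_matches_bruteforce_oracle():
    local = np.random.default_rng(5)
    n = 15
    ids = [f"rs{i}" for i in range(n)]
    px = local.uniform(1e-12, 1e-6, n)
    pm = local.uniform(1e-12, 1e-6, n)
    x = make_stats("X", [0.1] * n, [0.005] * n, pvals=px, ids=ids)
    m = make_stats("M", [0.1] * n, [0.005] * n, pvals=pm, ids=ids)
    pairs = {}
    for i in range(n):
        for j in range(i + 1, n):
            if local.random() < 0.3:
                pairs[frozenset((ids[i], ids[j]))] = float(local.uniform(0, 1))
    ld = LDInfo({tuple(sorted(k)): v for k, v in pairs.items()})
    pooled = pool_for_mvmr([x, m], ld, p_threshold=1e-7, r2_threshold=0.1)
    # oracle: min-p union then naive greedy clump
    minp = {
        v: min(px[i], pm[i])
        for i, v in enumerate(ids)
        if min(px[i], pm[i]) < 1e-7
    }
    expected = clump_oracle(minp, pairs, 0.1)
    assert pooled.variant_ids == expected


def test_harmonise_idempotent():
    rng = np.random.default_rng(9)
    bx = rng.normal(0, 0.1, 8)
    by = rng.normal(0, 0.1, 8)
    x = make_stats("X", bx, np.full(8, 0.01))
    y = make_stats("Y", by, np.full(8, 0.01))
    h1 = harmonise([x, y])
    # feed the harmonised output back through as aligned tables
    x2 = make_stats("X", h1.beta[:, 0], h1.se[:, 0], ids=h1.variant_ids)
    y2 = make_stats("Y", h1.beta[:, 1], h1.se[:, 1], ids=h1.variant_ids)
    h2 = harmonise([x2, y2])
    np.testing.assert_allclose(h2.beta, h1.beta)
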
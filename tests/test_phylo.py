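"""Gene summaries, excess curves, interface randomization, sequons, Fitch."""

import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vipadapt.errors import EstimationError, ParameterError
from vipadapt.phylo_adaptation import (
    BranchSelection,
    CodonSignalTrack,
    adaptation_excess,
    count_sequon_transitions,
    decompose_excess,
    excess_curve,
    interface_enrichment,
    scan_sequons,
    subset_excess,
    summarize_gene,
    summarize_table,
)


def branches(gid, props, synteny=None, ps=None):
    synteny = synteny or [True] * len(props)
    ps = ps or [1.0] * len(props)
    return [BranchSelection(gid, f"b{i}", p, bp, ok)
            for i, (p, ok, bp) in enumerate(zip(props, synteny, ps))]


def test_summarize_gene_means():
    s = summarize_gene(branches("g", [0.0] * 40), min_valid=39)
    assert s.mean_prop == 0.0 and not s.excluded
    s = summarize_gene(branches("g", [0.01] * 40), min_valid=39)
    assert s.mean_prop == pytest.approx(0.01)


def test_summarize_gene_excludes_below_min_valid():
    s = summarize_gene(branches("g", [0.01] * 44, synteny=[True] * 38 + [False] * 6),
                       min_valid=39)
    assert s.excluded and np.isnan(s.mean_prop)
    assert s.n_valid_branches == 38


def test_summarize_gene_errors():
    with pytest.raises(ParameterError):
        summarize_gene([])
    with pytest.raises(ParameterError):
        summarize_gene(branches("a", [0.1]) + branches("b", [0.1]))


@settings(derandomize=True, max_examples=30)
@given(st.lists(st.tuples(st.floats(0, 1), st.booleans()), min_size=1, max_size=60))
def test_summarize_gene_matches_bruteforce(items):
    """Mean over valid branches equals the masked brute-force average."""
    bs = branches("g", [p for p, _ in items], synteny=[ok for _, ok in items])
    valid = [p for p, ok in items if ok]
    s = summarize_gene(bs, min_valid=1)
    if not valid:
        assert s.excluded
    else:
        assert s.mean_prop == pytest.approx(np.mean(valid))


def _summ(mean_props, busted=0.01):
    return pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(len(mean_props))],
        "mean_prop": mean_props,
        "busted_p": [busted] * len(mean_props),
        "n_valid_branches": [44] * len(mean_props),
        "excluded": [False] * len(mean_props),
    })


def test_adaptation_excess_definition():
    assert adaptation_excess(_summ([0.003]), _summ([0.002])) == pytest.approx(50.0)
    assert adaptation_excess(_summ([0.005]), _summ([0.005])) == pytest.approx(0.0)
    assert adaptation_excess(_summ([0.006]), _summ([0.002])) == pytest.approx(200.0)


def test_adaptation_excess_zero_control_undefined():
    with pytest.raises(EstimationError):
        adaptation_excess(_summ([0.01]), _summ([0.0]))


def test_adaptation_excess_threshold_filters():
    vip = _summ([0.004, 0.004], busted=0.5)
    ctrl = pd.concat([_summ([0.002], busted=0.001),
                      _summ([0.5], busted=0.9)], ignore_index=True)
    # at threshold 0.01 the high-signal control gene is filtered out
    with pytest.raises(EstimationError):
        adaptation_excess(vip, ctrl, busted_threshold=0.01)


def test_excess_curve_single_threshold_consistency():
    rng = np.random.default_rng(0)
    vip = _summ(rng.uniform(0.002, 0.006, 80))
    pool = _summ(rng.uniform(0.001, 0.005, 400))
    pts = excess_curve(vip, pool, [0.5], n_sets=2000, seed=1)
    assert len(pts) == 1
    direct = adaptation_excess(vip, pool, 0.5)
    # mean over large same-size subsets converges to the full-pool excess
    assert pts[0].excess == pytest.approx(direct, abs=3.0)


def test_excess_curve_requires_descending_thresholds():
    with pytest.raises(ParameterError):
        excess_curve(_summ([0.01]), _summ([0.01]), [0.1, 0.5])


def test_excess_curve_flags_thin_thresholds():
    vip = _summ([0.004] * 5)
    pool = _summ([0.002] * 50)
    pts = excess_curve(vip, pool, [0.5], n_sets=20, seed=2, min_genes=10)
    assert pts[0].flagged


def test_decompose_excess_identical_sets_zero():
    rng = np.random.default_rng(3)
    genes = [f"g{i}" for i in range(40)]
    rows = []
    for g in genes:
        for b in range(44):
            rows.append((g, f"b{b}", float(rng.uniform(0, 0.02)),
                         float(rng.uniform(0, 1)), True))
    bdf = pd.DataFrame(rows, columns=["gene_id", "branch_id", "prop_selected",
                                      "branch_p", "synteny_ok"])
    busted = pd.DataFrame({"gene_id": genes, "busted_p": rng.uniform(0, 1, 40)})
    d = decompose_excess(bdf, bdf, busted, busted)
    assert d == {"genes": 0.0, "branches_per_gene": 0.0, "prop_per_branch": 0.0}


def _component_tables(prop_scale=1.0, extra_sig_branches=0):
    rng = np.random.default_rng(4)
    genes = [f"g{i}" for i in range(60)]
    rows = []
    for g in genes:
        for b in range(44):
            sig = b < 6 + extra_sig_branches
            rows.append((g, f"b{b}",
                         0.01 * prop_scale if sig else 0.0,
                         0.01 if sig else 0.8, True))
    bdf = pd.DataFrame(rows, columns=["gene_id", "branch_id", "prop_selected",
                                      "branch_p", "synteny_ok"])
    busted = pd.DataFrame({"gene_id": genes, "busted_p": 0.01})
    return bdf, busted


def test_decompose_excess_isolates_per_branch_component():
    vb, vp = _component_tables(prop_scale=2.0)
    cb, cp = _component_tables(prop_scale=1.0)
    d = decompose_excess(vb, cb, vp, cp)
    assert d["genes"] == pytest.approx(0.0)
    assert d["branches_per_gene"] == pytest.approx(0.0)
    assert d["prop_per_branch"] == pytest.approx(100.0)


def test_decompose_excess_isolates_branch_count_component():
    vb, vp = _component_tables(extra_sig_branches=6)
    cb, cp = _component_tables()
    d = decompose_excess(vb, cb, vp, cp)
    assert d["genes"] == pytest.approx(0.0)
    assert d["branches_per_gene"] == pytest.approx(100.0)
    assert d["prop_per_branch"] == pytest.approx(0.0, abs=1e-9)


def test_subset_excess_recovers_virus_ranking(default_cohort):
    from vipadapt.matched_resampling import genes_to_frame
    from vipadapt.synthetic_data import generate_branch_table, random_tree

    genes = default_cohort[:1200]
    tree = random_tree(24, seed=1)
    # build one table per virus effect by modulating vip_excess via labels:
    # construct branch tables with excess 3 and splice per-virus focal sets
    bdf, pdf = generate_branch_table(genes, tree, vip_excess=3.0, seed=6)
    df = genes_to_frame(genes)
    tab = subset_excess(df, bdf, pdf, grouping="virus", busted_threshold=0.9,
                        n_sets=30, seed=7, min_group=5)
    big = tab[tab.n_focal >= 20]
    assert (big["excess"] > 50).all()  # every well-populated virus shows excess


def test_subset_excess_clade_mode(default_cohort):
    from vipadapt.matched_resampling import genes_to_frame
    from vipadapt.synthetic_data import (clade_branches, generate_branch_table,
                                         random_tree)

    genes = default_cohort[:600]
    tree = random_tree(12, seed=2)
    bdf, pdf = generate_branch_table(genes, tree, vip_excess=2.0, seed=8)
    tips = [t.label for t in tree.taxon_namespace]
    clades = {"cladeA": clade_branches(tree, tips[:4])}
    tab = subset_excess(genes_to_frame(genes), bdf, pdf, grouping="clade",
                        groups=clades, busted_threshold=0.9, n_sets=20,
                        seed=9, min_valid=3)
    assert len(tab) == 1 and np.isfinite(tab["excess"].iloc[0])
    with pytest.raises(ParameterError):
        subset_excess(genes_to_frame(genes), bdf, pdf, grouping="clade",
                      groups={"bogus": ["zzz"]}, n_sets=5)


# --- interface enrichment ----------------------------------------------------

def test_interface_excess_uniform_signal_is_one():
    track = CodonSignalTrack("t", np.zeros(100), frozenset(range(40, 50)))
    res = interface_enrichment(track, [0.5], neighbor_k=[5], n_rand=2000, seed=0)
    assert res["excess"].iloc[0] == pytest.approx(1.0)


def test_interface_excess_closed_form():
    """10 significant codons all inside a 20-codon window of a 100-codon gene.

    Uniform relocation expects 10*(20/100)=2 in-window hits, excess 5.
    """
    p = np.ones(100)
    sig = list(range(40, 50))
    p[sig] = 0.001
    track = CodonSignalTrack("t", p, frozenset(range(40, 60)))
    res = interface_enrichment(track, [0.05], neighbor_k=[0], n_rand=100_000,
                               seed=1)
    row = res.iloc[0]
    assert row["window"] == 20
    assert row["expected"] == pytest.approx(2.0, rel=0.05)
    assert row["excess"] == pytest.approx(5.0, rel=0.05)
    assert row["p"] < 0.01


def test_interface_enrichment_deterministic():
    rng = np.random.default_rng(5)
    track = CodonSignalTrack("t", rng.uniform(0, 1, 200),
                             frozenset(range(10, 30)))
    a = interface_enrichment(track, [0.1, 0.05], n_rand=500, seed=9)
    b = interface_enrichment(track, [0.1, 0.05], n_rand=500, seed=9)
    pd.testing.assert_frame_equal(a, b)


def test_interface_zero_signal_reported_as_undefined():
    track = CodonSignalTrack("t", np.ones(50), frozenset({5}))
    res = interface_enrichment(track, [0.001], neighbor_k=[1], n_rand=100, seed=2)
    assert np.isnan(res["excess"].iloc[0]) and res["n_sig"].iloc[0] == 0


# --- sequons -----------------------------------------------------------------

@pytest.mark.parametrize("seq,expected", [
    ("NAS", [0]),
    ("NPS", []),
    ("NATNAT", [0, 3]),
    ("MNGSANCT", [1, 5]),
    ("", []),
    ("NA", []),
])
def test_scan_sequons(seq, expected):
    assert scan_sequons(seq) == expected


@settings(derandomize=True, max_examples=60)
@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", max_size=40))
def test_scan_sequons_matches_regex_oracle(seq):
    import re
    oracle = [m.start() for m in re.finditer(r"(?=N[^P][ST])", seq)]
    assert scan_sequons(seq) == oracle


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


def test_sequon_transitions_all_present():
    t = _tree("((A,B),C);")
    assert count_sequon_transitions(t, {"A": 1, "B": 1, "C": 1}) == (0, 0)


def test_sequon_single_tip_loss():
    # Fitch: root and internal resolve to 1; one loss on the edge to A
    t = _tree("((A,B),C);")
    assert count_sequon_transitions(t, {"A": 0, "B": 1, "C": 1}) == (1, 0)


def test_sequon_ancestral_loss_of_sister_pair():
    # two sister tips at 0: a single ancestral loss, no gains
    t = _tree("(((A,B),(C,D)),E);")
    states = {"A": 0, "B": 0, "C": 1, "D": 1, "E": 1}
    assert count_sequon_transitions(t, states) == (1, 0)


def test_sequon_gain_counted():
    t = _tree("(((A,B),(C,D)),E);")
    states = {"A": 1, "B": 0, "C": 0, "D": 0, "E": 0}
    losses, gains = count_sequon_transitions(t, states)
    assert (losses, gains) == (0, 1)


def test_sequon_internal_states_respected():
    t = _tree("((A,B)X,C)R;")
    for node in t.preorder_node_iter():
        label = node.taxon.label if node.taxon else node.label
        node.annotations.add_new("sequon", 1 if label in ("R", "X", "B", "C") else 0)
    assert count_sequon_transitions(t) == (1, 0)


def test_sequon_missing_tip_state_errors():
    t = _tree("((A,B),C);")
    with pytest.raises(ParameterError):
        count_sequon_transitions(t, {"A": 1, "B": 1})
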
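"""Phylogeny-wide adaptation aggregation and the interface case study.

Branch-site test output (per-branch proportions of positively selected
codons, per-gene overall-test p-values) is aggregated into per-gene means
over synteny-valid branches; the VIP-vs-control contrast is summarised as an
"excess of adaptation": (mean_VIP / mean_control - 1) x 100, optionally as a
curve over increasingly strict gene-level p-value thresholds. Also here:
codon-level interface-enrichment randomization, the N-glycosylation sequon
scan, and Fitch-parsimony counting of sequon gains and losses on a tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import EstimationError, ParameterError
from .matched_resampling import TargetAverageConfig, target_average_sample

logger = logging.getLogger(__name__)

#: default minimum synteny-valid branches for a gene to enter the analysis
MIN_VALID_BRANCHES = 39


@dataclass
class BranchSelection:
    gene_id: str
    branch_id: str
    prop_selected: float
    branch_p: float = 1.0
    synteny_ok: bool = True

    def __post_init__(self):
        if not 0.0 <= self.prop_selected <= 1.0:
            raise ParameterError("prop_selected must be in [0,1]")


@dataclass
class GeneTreeSummary:
    gene_id: str
    busted_p: float
    n_valid_branches: int
    mean_prop: float  # nan when excluded
    excluded: bool


@dataclass
class CodonSignalTrack:
    """Per-codon episodic-selection p-values plus an interface codon set."""

    gene_id: str
    site_p: np.ndarray
    interface: frozenset

    def __post_init__(self):
        self.site_p = np.asarray(self.site_p, dtype=float)
        self.interface = frozenset(int(i) for i in self.interface)
        if self.interface and (min(self.interface) < 0
                               or max(self.interface) >= len(self.site_p)):
            raise ParameterError("interface codons outside [0, length)")

    @property
    def length(self) -> int:
        return len(self.site_p)


def summarize_gene(
    branches: Sequence[BranchSelection],
    min_valid: int = MIN_VALID_BRANCHES,
    busted_p: float = float("nan"),
) -> GeneTreeSummary:
    """Mean proportion of selected codons over synteny-valid branches.

    Genes with fewer than ``min_valid`` valid branches are flagged excluded
    (mean undefined) rather than summarised from unreliable orthology.
    """
    branches = list(branches)
    if not branches:
        raise ParameterError("empty branch list")
    gid = branches[0].gene_id
    if any(b.gene_id != gid for b in branches):
        raise ParameterError("branches must share gene_id")
    valid = [b.prop_selected for b in branches if b.synteny_ok]
    excluded = len(valid) < min_valid
    return GeneTreeSummary(
        gene_id=gid,
        busted_p=busted_p,
        n_valid_branches=len(valid),
        mean_prop=float("nan") if excluded else float(np.mean(valid)),
        excluded=excluded,
    )


def summarize_table(
    branch_df: pd.DataFrame,
    busted_df: pd.DataFrame | None = None,
    min_valid: int = MIN_VALID_BRANCHES,
    branch_subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Vectorised :func:`summarize_gene` over a whole branch table.

    ``branch_subset`` restricts the average (and the validity count) to a
    named set of branches, e.g. one clade of the tree. Returns a frame with
    gene_id, n_valid_branches, mean_prop, excluded (and busted_p if given).
    """
    df = branch_df
    if branch_subset is not None:
        df = df[df["branch_id"].isin(set(branch_subset))]
    valid = df[df["synteny_ok"].astype(bool)]
    grp = valid.groupby("gene_id")["prop_selected"]
    out = pd.DataFrame({"n_valid_branches": grp.size(), "mean_prop": grp.mean()})
    out = out.reindex(branch_df["gene_id"].unique())
    out["n_valid_branches"] = out["n_valid_branches"].fillna(0).astype(int)
    out["excluded"] = out["n_valid_branches"] < min_valid
    out.loc[out["excluded"], "mean_prop"] = np.nan
    out = out.reset_index().rename(columns={"index": "gene_id"})
    if busted_df is not None:
        out = out.merge(busted_df[["gene_id", "busted_p"]], on="gene_id", how="left")
    return out


def adaptation_excess(
    vip_summaries: pd.DataFrame,
    control_summaries: pd.DataFrame,
    busted_threshold: float = 1.0,
) -> float:
    """Excess of adaptation in percent: (mean_VIP/mean_control - 1) x 100.

    Only genes passing the overall-test threshold (busted_p <= threshold) and
    not excluded contribute; a VIP mean 1.5x the control mean gives 50%.
    """
    def usable(df):
        d = df[~df["excluded"].astype(bool)]
        if "busted_p" in d.columns:
            d = d[d["busted_p"] <= busted_threshold]
        return d["mean_prop"].dropna()

    v = usable(vip_summaries)
    c = usable(control_summaries)
    if v.empty or c.empty:
        raise EstimationError("no usable genes after threshold filtering")
    cm = c.mean()
    if cm == 0:
        raise EstimationError("control mean proportion is zero; excess undefined")
    return float((v.mean() / cm - 1.0) * 100.0)


@dataclass
class ExcessPoint:
    threshold: float
    excess: float
    ci_low: float
    ci_high: float
    n_vip: int
    n_control: int
    flagged: bool


def _control_indices(pool, n, matching, ta_config, cov_values, target, rng):
    if matching == "target_average":
        return target_average_sample(cov_values, n, ta_config, target, rng=rng)
    return rng.choice(len(pool), size=n, replace=False)


def excess_curve(
    vip_summaries: pd.DataFrame,
    pool_summaries: pd.DataFrame,
    thresholds: Sequence[float],
    matching: str = "none",
    ta_config: TargetAverageConfig | None = None,
    pool_covariate: np.ndarray | None = None,
    vip_covariate_mean: float | None = None,
    n_sets: int = 100,
    seed: int = 0,
    min_genes: int = 10,
) -> list[ExcessPoint]:
    """Excess of adaptation against matched controls per p-value threshold.

    ``thresholds`` must be descending (weak to strict evidence). For each
    threshold, ``n_sets`` control sets are drawn from ``pool_summaries``
    (optionally via the target-average sampler on a supplied covariate, the
    power-equalising match) and the per-set excess distribution gives the
    point estimate and 95% interval. Points where either side has fewer than
    ``min_genes`` usable genes are flagged.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds, reverse=True):
        raise ParameterError("thresholds must be descending")
    if matching not in ("none", "target_average"):
        raise ParameterError(f"unknown matching mode {matching!r}")
    if matching == "target_average":
        if ta_config is None or pool_covariate is None or vip_covariate_mean is None:
            raise ParameterError(
                "target_average matching needs ta_config, pool_covariate and "
                "vip_covariate_mean")
    rng = np.random.default_rng(seed)
    n = len(vip_summaries)
    target = None
    if matching == "target_average":
        target = ta_config.match_fraction * vip_covariate_mean

    points = []
    for thr in thresholds:
        excesses = []
        n_ctrl_used = []
        for _ in range(n_sets):
            idx = _control_indices(pool_summaries, n, matching, ta_config,
                                   pool_covariate, target, rng)
            ctrl = pool_summaries.iloc[np.asarray(idx)]
            try:
                e = adaptation_excess(vip_summaries, ctrl, thr)
            except EstimationError:
                continue
            excesses.append(e)
            cu = ctrl[~ctrl["excluded"].astype(bool)]
            if "busted_p" in cu.columns:
                cu = cu[cu["busted_p"] <= thr]
            n_ctrl_used.append(len(cu))
        vu = vip_summaries[~vip_summaries["excluded"].astype(bool)]
        if "busted_p" in vu.columns:
            vu = vu[vu["busted_p"] <= thr]
        n_vip = len(vu)
        if not excesses:
            points.append(ExcessPoint(thr, float("nan"), float("nan"), float("nan"),
                                      n_vip, 0, True))
            continue
        ex = np.asarray(excesses)
        lo, hi = np.quantile(ex, [0.025, 0.975])
        n_ctrl = int(np.mean(n_ctrl_used))
        points.append(ExcessPoint(
            threshold=thr, excess=float(ex.mean()),
            ci_low=float(lo), ci_high=float(hi),
            n_vip=n_vip, n_control=n_ctrl,
            flagged=n_vip < min_genes or n_ctrl < min_genes,
        ))
    return points


def decompose_excess(
    vip_branches: pd.DataFrame,
    control_branches: pd.DataFrame,
    vip_busted: pd.DataFrame,
    control_busted: pd.DataFrame,
    busted_threshold: float = 0.5,
    branch_p_threshold: float = 0.05,
    min_valid: int = MIN_VALID_BRANCHES,
) -> dict[str, float]:
    """Split the excess into gene-count, branch-count and per-branch parts.

    Three excess percentages computed with the same (ratio-1)x100 form:
    ``genes`` uses the fraction of genes passing the overall-test threshold;
    ``branches_per_gene`` the mean number of significant
    (branch_p <= threshold) valid branches per passing gene; and
    ``prop_per_branch`` the mean proportion of selected codons over those
    significant branches.
    """
    def parts(branches, busted):
        summ = summarize_table(branches, busted, min_valid=min_valid)
        ok = summ[~summ["excluded"]]
        passing = ok[ok["busted_p"] <= busted_threshold]
        frac_genes = len(passing) / max(len(ok), 1)
        b = branches[branches["gene_id"].isin(set(passing["gene_id"]))]
        b = b[b["synteny_ok"].astype(bool)]
        sig = b[b["branch_p"] <= branch_p_threshold]
        branches_per = len(sig) / max(len(passing), 1)
        prop_per = sig["prop_selected"].mean() if len(sig) else float("nan")
        return frac_genes, branches_per, prop_per

    gv, bv, pv = parts(vip_branches, vip_busted)
    gc_, bc, pc = parts(control_branches, control_busted)
    for name, c in (("genes", gc_), ("branches_per_gene", bc), ("prop_per_branch", pc)):
        if not c or not np.isfinite(c):
            raise EstimationError(f"control component {name} degenerate")
    return {
        "genes": (gv / gc_ - 1.0) * 100.0,
        "branches_per_gene": (bv / bc - 1.0) * 100.0,
        "prop_per_branch": (pv / pc - 1.0) * 100.0,
    }


def subset_excess(
    genes: pd.DataFrame,
    branch_df: pd.DataFrame,
    busted_df: pd.DataFrame,
    grouping: str,
    groups: dict[str, Sequence[str]] | None = None,
    busted_threshold: float = 0.5,
    n_sets: int = 100,
    seed: int = 0,
    min_valid: int = MIN_VALID_BRANCHES,
    min_group: int = 10,
) -> pd.DataFrame:
    """Per-group excess of adaptation with control intervals.

    ``grouping``: "virus" (groups are virus labels; focal = VIPs annotated to
    that virus), "go" (groups are GO process ids) or "clade" (``groups`` maps
    clade names to branch-id subsets; the branch average is restricted to the
    clade before comparison). Focal sets are always VIP genes; controls are
    random same-size non-VIP sets. Groups with fewer focal genes than
    ``min_group`` are flagged.
    """
    if grouping not in ("virus", "go", "clade"):
        raise ParameterError(f"unknown grouping {grouping!r}")
    rng = np.random.default_rng(seed)
    rows = []

    def run_one(name, vip_ids, pool_ids, subset=None):
        summ = summarize_table(branch_df, busted_df, min_valid=min_valid,
                               branch_subset=subset)
        vip_s = summ[summ["gene_id"].isin(vip_ids)]
        pool_s = summ[summ["gene_id"].isin(pool_ids)]
        excesses = []
        for _ in range(n_sets):
            idx = rng.choice(len(pool_s), size=min(len(vip_s), len(pool_s)),
                             replace=False)
            try:
                excesses.append(adaptation_excess(vip_s, pool_s.iloc[idx],
                                                  busted_threshold))
            except EstimationError:
                continue
        if not excesses:
            rows.append(dict(group=name, excess=np.nan, ci_low=np.nan,
                             ci_high=np.nan, n_focal=len(vip_ids), flagged=True))
            return
        ex = np.asarray(excesses)
        lo, hi = np.quantile(ex, [0.025, 0.975])
        rows.append(dict(group=name, excess=float(ex.mean()), ci_low=float(lo),
                         ci_high=float(hi), n_focal=len(vip_ids),
                         flagged=len(vip_ids) < min_group))

    vips = genes[genes["is_vip"].astype(bool)]
    pool = genes[~genes["is_vip"].astype(bool)]
    if grouping == "virus":
        labels = sorted({v for s in vips["viruses"] for v in str(s).split(",") if v})
        for lab in labels:
            vid = set(vips[vips["viruses"].astype(str).str.contains(lab, regex=False)]
                      ["gene_id"])
            run_one(lab, vid, set(pool["gene_id"]))
    elif grouping == "go":
        labels = sorted({t for s in vips["go_terms"] for t in str(s).split(",") if t})
        for lab in labels:
            vid = set(vips[vips["go_terms"].astype(str).str.contains(lab, regex=False)]
                      ["gene_id"])
            run_one(lab, vid, set(pool["gene_id"]))
    else:
        if not groups:
            raise ParameterError("clade grouping requires a clade->branches map")
        known = set(branch_df["branch_id"])
        for name, subset in groups.items():
            if not set(subset) & known:
                raise ParameterError(
                    f"unknown clade {name!r}; branch ids in table: "
                    f"{sorted(known)[:8]}...")
            run_one(name, set(vips["gene_id"]), set(pool["gene_id"]), subset=subset)
    return pd.DataFrame(rows)


# --- interface enrichment and sequons ---------------------------------------

def interface_window(track: CodonSignalTrack, neighbor_k: int) -> np.ndarray:
    """Codon indices within ``neighbor_k`` (sequence distance) of the interface."""
    mask = np.zeros(track.length, dtype=bool)
    for i in track.interface:
        lo = max(0, i - neighbor_k)
        hi = min(track.length, i + neighbor_k + 1)
        mask[lo:hi] = True
    return np.flatnonzero(mask)


def interface_enrichment(
    track: CodonSignalTrack,
    p_thresholds: Sequence[float],
    neighbor_k: Sequence[int] = (1, 5, 10, 20),
    n_rand: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Excess of adaptation signals in and near the virus-contact interface.

    For each (p threshold, neighborhood width k): observed = significant
    codons (site p <= threshold) inside the interface window; expected = mean
    over ``n_rand`` uniform relocations of the significant-codon set (without
    replacement over all codons, preserving the count); excess =
    observed/expected; p = fraction of randomizations >= observed. Cells with
    zero significant codons are reported with NaN excess.
    """
    if track.length == 0:
        raise ParameterError("empty track")
    rng = np.random.default_rng(seed)
    rows = []
    total_sig_mask = None
    for k in neighbor_k:
        window = interface_window(track, int(k))
        w = len(window)
        if w >= track.length:
            logger.warning("window of k=%d covers the whole sequence", k)
        win_set = set(window.tolist())
        for thr in p_thresholds:
            sig = np.flatnonzero(track.site_p <= thr)
            n_sig = len(sig)
            if n_sig == 0:
                rows.append(dict(threshold=thr, k=int(k), observed=0,
                                 expected=np.nan, excess=np.nan, p=np.nan,
                                 n_sig=0, window=w))
                continue
            observed = int(sum(1 for i in sig if int(i) in win_set))
            draws = rng.hypergeometric(w, track.length - w, n_sig, size=n_rand)
            expected = float(draws.mean())
            rows.append(dict(
                threshold=thr, k=int(k), observed=observed,
                expected=expected,
                excess=observed / expected if expected > 0 else np.nan,
                p=float(np.mean(draws >= observed)),
                n_sig=n_sig, window=w,
            ))
    return pd.DataFrame(rows)


_HYDROXY = frozenset("ST")


def scan_sequons(protein: str) -> list[int]:
    """0-based positions of N-glycosylation sequons N-X-[S/T], X != P."""
    seq = protein.upper()
    return [
        i for i in range(len(seq) - 2)
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in _HYDROXY
    ]


def count_sequon_transitions(
    tree: dendropy.Tree,
    tip_states: dict[str, int] | None = None,
    state_attr: str = "sequon",
) -> tuple[int, int]:
    """Count losses (1->0) and gains (0->1) of a binary character on a tree.

    States may be supplied for every node via node annotations
    (``node.annotations[state_attr]``) or, more commonly, only for tips via
    ``tip_states`` (taxon label -> 0/1), in which case internal states are
    inferred by Fitch parsimony with ties broken toward the parent state
    (root ties toward the majority tip state, then presence).
    Requires a rooted tree. Returns (losses, gains).
    """
    root = tree.seed_node
    if root is None or len(root.child_nodes()) == 0:
        raise ParameterError("tree has no structure")
    if not tree.is_rooted and len(root.child_nodes()) > 2:
        raise ParameterError("tree must be rooted (or have a bifurcating root)")

    def node_state(n):
        v = n.annotations.get_value(state_attr)
        return None if v is None else int(v)

    have_all = all(node_state(n) is not None for n in tree.preorder_node_iter())
    assigned: dict = {}
    if have_all:
        for n in tree.preorder_node_iter():
            assigned[n] = node_state(n)
    else:
        if tip_states is None:
            raise ParameterError("tip_states required when internal states absent")
        downpass: dict = {}
        for n in tree.postorder_node_iter():
            if n.is_leaf():
                lab = n.taxon.label
                if lab not in tip_states:
                    raise ParameterError(f"no state for tip {lab!r}")
                downpass[n] = {int(tip_states[lab])}
            else:
                sets = [downpass[c] for c in n.child_nodes()]
                inter = set.intersection(*sets)
                downpass[n] = inter if inter else set.union(*sets)
        # uppass with parent-state tie-breaking
        rs = downpass[root]
        if len(rs) == 1:
            assigned[root] = next(iter(rs))
        else:
            tips = [int(tip_states[l.taxon.label]) for l in tree.leaf_node_iter()]
            assigned[root] = 1 if sum(tips) * 2 >= len(tips) else 0
        for n in tree.preorder_node_iter():
            if n is root:
                continue
            ps = assigned[n.parent_node]
            assigned[n] = ps if ps in downpass[n] else next(iter(downpass[n]))

    losses = gains = 0
    for n in tree.preorder_node_iter():
        if n.parent_node is None:
            continue
        a, b = assigned[n.parent_node], assigned[n]
        if a == 1 and b == 0:
            losses += 1
        elif a == 0 and b == 1:
            gains += 1
    return losses, gains
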
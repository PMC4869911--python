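"""Synthetic inputs with known ground truth for every analysis stage.

Three generators:

* a forward Wright-Fisher simulator of a multi-exon coding locus (the
  validation design: 400 codons, six exons, N=1000 diploids, 20,000
  generations, mu=2.5e-7, with one coding site in four synonymous), from
  which true alpha is known by counting fixed advantageous mutations;
* a gene-cohort generator producing :class:`GeneRecord` tables with
  configurable VIP effects (pN/pS reduction, alpha-inflated dN) and a modular
  GO label model that makes GO-matching feasible;
* a branch-selection table generator emulating branch-site test output
  (per-branch proportions of selected codons, synteny masks, gene-level
  test p-values) with a configurable VIP excess multiplier.

Every configured effect size is recoverable empirically at large n, so the
generators double as oracles for the estimators downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from ._wf import _wf_kernel
from .divergence_polymorphism import NONSYN, SYN, VariantSite
from .errors import ConfigurationError
from .matched_resampling import GeneRecord

NEUTRAL = "neutral"
ADVANTAGEOUS = "advantageous"
WEAK_DELETERIOUS = "weak_deleterious"
STRONG_DELETERIOUS = "strong_deleterious"

#: scaled selection coefficients (2Ns) of the named scenario presets
PRESET_GAMMA = {ADVANTAGEOUS: 20.0, WEAK_DELETERIOUS: -5.0, STRONG_DELETERIOUS: -100.0}


@dataclass(frozen=True)
class MutationClass:
    label: str
    probability: float
    s: float


@dataclass
class LocusConfig:
    """Configuration of one simulated coding locus.

    ``mutation_mix`` applies to non-synonymous sites only; synonymous sites
    (a ``syn_fraction`` of coding sites) receive neutral mutations only.
    ``size_schedule`` is an optional piecewise-constant demography, a list of
    (duration_generations, diploid_size) epochs covering burn_in +
    n_generations (the last epoch is extended if the durations fall short).
    ``n_exons``, ``intron_len`` and ``recomb_rate`` describe the locus
    layout; mutations are modelled as freely recombining, so they do not
    enter the dynamics. Fixations are recorded only after ``burn_in``
    generations; polymorphism is sampled at the end as ``sample_n``
    haplotypes.
    """

    n_codons: int = 400
    n_exons: int = 6
    intron_len: int = 4000
    pop_size: int = 1000
    n_generations: int = 20_000
    mu: float = 2.5e-7
    recomb_rate: float = 10.0
    syn_fraction: float = 0.25
    mutation_mix: tuple[MutationClass, ...] = (MutationClass(NEUTRAL, 1.0, 0.0),)
    seed: int = 0
    burn_in: int = 0
    sample_n: int = 216
    size_schedule: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self):
        if self.mu < 0:
            raise ConfigurationError("mu must be >= 0")
        if self.pop_size < 2:
            raise ConfigurationError("pop_size must be >= 2")
        if not 0.0 <= self.syn_fraction <= 1.0:
            raise ConfigurationError("syn_fraction must be in [0,1]")
        tot = sum(m.probability for m in self.mutation_mix)
        if abs(tot - 1.0) > 1e-9:
            raise ConfigurationError(
                f"mutation_mix probabilities sum to {tot}, expected 1"
            )
        if self.size_schedule is not None:
            for dur, n in self.size_schedule:
                if dur <= 0 or n < 2:
                    raise ConfigurationError("invalid size_schedule epoch")


@dataclass
class SimOutcome:
    """Result of a locus (or pooled cohort) simulation."""

    dn: int
    ds: int
    adaptive_fixations: int
    variants: list[VariantSite]
    sample_n: int

    @property
    def true_alpha(self) -> float:
        """Adaptive fraction of non-synonymous fixations (nan if dn=0)."""
        if self.dn == 0:
            return float("nan")
        return self.adaptive_fixations / self.dn


def scenario_mix(name: str, pop_size: int) -> tuple[MutationClass, ...]:
    """Named non-synonymous mutation mixes, s derived from preset 2Ns values.

    Proportions are implementation choices (the validation design names the
    four classes without proportions): "neutral" is fully neutral;
    "adaptive" adds 2% advantageous (2Ns=+20); "adaptive_weakdel" further
    adds slightly (2Ns=-5) and strongly (2Ns=-100) deleterious classes.
    """
    def s_of(label):
        return PRESET_GAMMA[label] / (2.0 * pop_size)

    if name == "neutral":
        return (MutationClass(NEUTRAL, 1.0, 0.0),)
    if name == "adaptive":
        return (
            MutationClass(NEUTRAL, 0.98, 0.0),
            MutationClass(ADVANTAGEOUS, 0.02, s_of(ADVANTAGEOUS)),
        )
    if name == "adaptive_weakdel":
        return (
            MutationClass(NEUTRAL, 0.55, 0.0),
            MutationClass(WEAK_DELETERIOUS, 0.35, s_of(WEAK_DELETERIOUS)),
            MutationClass(STRONG_DELETERIOUS, 0.08, s_of(STRONG_DELETERIOUS)),
            MutationClass(ADVANTAGEOUS, 0.02, s_of(ADVANTAGEOUS)),
        )
    if name == "purifying":
        # no advantageous class: true alpha is exactly 0
        return (
            MutationClass(NEUTRAL, 0.60, 0.0),
            MutationClass(WEAK_DELETERIOUS, 0.32, s_of(WEAK_DELETERIOUS)),
            MutationClass(STRONG_DELETERIOUS, 0.08, s_of(STRONG_DELETERIOUS)),
        )
    raise ConfigurationError(f"unknown scenario {name!r}")


def bottleneck_schedule(
    pop_size: int, burn_in: int, n_generations: int,
    crash_frac: float = 0.2, crash_duration: int = 500, crash_depth: int = 5,
) -> tuple[tuple[int, int], ...]:
    """A crash-and-recovery demography placed mid-window.

    The population spends the burn-in plus ``crash_frac`` of the observation
    window at ``pop_size``, drops to pop_size/crash_depth for
    ``crash_duration`` generations, then recovers.
    """
    pre = burn_in + int(crash_frac * n_generations)
    rest = burn_in + n_generations - pre - crash_duration
    return ((pre, pop_size), (crash_duration, max(pop_size // crash_depth, 2)),
            (max(rest, 1), pop_size))


def _epochs(config: LocusConfig) -> tuple[np.ndarray, np.ndarray]:
    total = config.burn_in + config.n_generations
    if config.size_schedule is None:
        return np.array([total], dtype=np.int64), np.array([config.pop_size], dtype=np.int64)
    durs = [int(d) for d, _ in config.size_schedule]
    sizes = [int(n) for _, n in config.size_schedule]
    if sum(durs) < total:
        durs[-1] += total - sum(durs)
    return np.array(durs, dtype=np.int64), np.array(sizes, dtype=np.int64)


def _kernel_seed(seed: int) -> int:
    return int(np.random.SeedSequence(seed).generate_state(1)[0] & 0x7FFFFFFF)


def simulate_locus(config: LocusConfig, gene_id: str = "locus") -> SimOutcome:
    """Forward-simulate one coding locus and summarize it for MK analysis.

    Returns fixed-difference counts by class (dn, ds, adaptive fixations
    recorded after burn-in) and the segregating variants observed in a
    final-generation sample of ``config.sample_n`` haplotypes.
    """
    l_coding = 3 * config.n_codons
    l_syn = int(round(l_coding * config.syn_fraction))
    l_nonsyn = l_coding - l_syn
    classes = [MutationClass(SYN, 1.0, 0.0)] + list(config.mutation_mix)
    rates = np.array(
        [config.mu * l_syn] + [config.mu * l_nonsyn * m.probability for m in config.mutation_mix]
    )
    s_arr = np.array([m.s for m in classes])
    epoch_len, epoch_n = _epochs(config)

    fixed, counts, klass, n_final, overflow = _wf_kernel(
        _kernel_seed(config.seed), config.burn_in, epoch_len, epoch_n, rates, s_arr
    )
    if overflow:
        raise RuntimeError(f"segregating-mutation capacity exceeded ({overflow} dropped)")

    ds = int(fixed[0])
    dn = int(fixed[1:].sum())
    adaptive = int(sum(
        fixed[i + 1] for i, m in enumerate(config.mutation_mix) if m.label == ADVANTAGEOUS
    ))

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    two_n = 2 * int(n_final)
    n_samp = min(config.sample_n, two_n)
    variants: list[VariantSite] = []
    for c, k in zip(counts, klass):
        drawn = int(rng.hypergeometric(int(c), two_n - int(c), n_samp))
        if 0 < drawn < n_samp:
            variants.append(VariantSite(
                gene_id=gene_id,
                daf=drawn / n_samp,
                klass=SYN if k == 0 else NONSYN,
                allele_count=drawn,
            ))
    return SimOutcome(dn=dn, ds=ds, adaptive_fixations=adaptive,
                      variants=variants, sample_n=n_samp)


def locus_seeds(seed: int, n_loci: int) -> list[int]:
    """Deterministic per-locus seeds derived from a cohort seed."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in ss.spawn(n_loci)]


def simulate_cohort(
    config: LocusConfig, n_loci: int, seed: int
) -> tuple[SimOutcome, list[SimOutcome]]:
    """Simulate ``n_loci`` loci and pool them into one aggregate outcome."""
    if n_loci < 1:
        raise ConfigurationError("n_loci must be >= 1")
    outcomes = []
    for i, s in enumerate(locus_seeds(seed, n_loci)):
        outcomes.append(simulate_locus(replace(config, seed=s), gene_id=f"locus_{i}"))
    agg = SimOutcome(
        dn=sum(o.dn for o in outcomes),
        ds=sum(o.ds for o in outcomes),
        adaptive_fixations=sum(o.adaptive_fixations for o in outcomes),
        variants=[v for o in outcomes for v in o.variants],
        sample_n=outcomes[0].sample_n,
    )
    return agg, outcomes


# --- gene cohorts -----------------------------------------------------------

#: the ten best-represented human viruses with VIP-count-derived weights
VIRUS_WEIGHTS = {
    "HIV-1": 240, "HPV": 150, "EBV": 130, "HBV": 120, "HSV": 110,
    "HCV": 109, "Influenza": 100, "ADV": 90, "HTLV": 70, "KSHV": 60,
}


@dataclass
class CohortConfig:
    """Gene-cohort generator settings.

    VIP effects: ``pnps_reduction`` multiplies the VIP non-synonymous
    polymorphism rate by (1 - reduction) relative to matched constraint;
    ``alpha_vip``/``alpha_nonvip`` inflate non-synonymous divergence by
    1/(1-alpha), so the classic MK statistic on pooled counts recovers them.
    Covariate means are (non-VIP, VIP) pairs with real-cohort-scale defaults.
    GO labels are drawn within ``n_go_modules`` modules partitioning
    ``n_go_terms`` processes, giving the term co-occurrence that makes
    GO-matching feasible.
    """

    n_genes: int = 2000
    vip_fraction: float = 0.13
    pnps_reduction: float = 0.25
    alpha_vip: float = 0.27
    alpha_nonvip: float = 0.09
    n_go_terms: int = 162
    go_per_gene: int = 5
    n_go_modules: int = 18
    theta_s: float = 8.0
    div_s: float = 6.0
    constraint_mean: float = 0.7
    constraint_shape: float = 4.0
    dnds_scale: float = 0.19
    gc_mean: tuple[float, float] = (0.523, 0.516)
    cds_len_mean: tuple[float, float] = (606.0, 668.0)
    recomb_mean: tuple[float, float] = (1.175, 1.145)
    rna_tissues_mean: tuple[float, float] = (11.9, 25.5)
    protein_tissues_mean: tuple[float, float] = (6.1, 15.1)
    ppi_degree_mean: tuple[float, float] = (3.2, 18.4)
    immune_frac: tuple[float, float] = (0.08, 0.19)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.vip_fraction <= 1.0:
            raise ConfigurationError("vip_fraction must be in [0,1]")
        if not 0.0 <= self.pnps_reduction < 1.0:
            raise ConfigurationError("pnps_reduction must be in [0,1)")
        if self.go_per_gene > self.n_go_terms:
            raise ConfigurationError("go_per_gene exceeds n_go_terms")
        if self.go_per_gene + 2 > self.n_go_terms // self.n_go_modules:
            raise ConfigurationError(
                "GO modules too small for go_per_gene (raise n_go_terms or "
                "lower n_go_modules/go_per_gene)"
            )

    @classmethod
    def null(cls, n_genes: int = 2000, seed: int = 0, **kw) -> "CohortConfig":
        """A cohort with no VIP effect on any quantity (for calibration)."""
        base = cls(n_genes=n_genes, seed=seed, pnps_reduction=0.0,
                   alpha_vip=0.09, alpha_nonvip=0.09, **kw)
        for name in ("gc_mean", "cds_len_mean", "recomb_mean", "rna_tissues_mean",
                     "protein_tissues_mean", "ppi_degree_mean", "immune_frac"):
            a, _ = getattr(base, name)
            setattr(base, name, (a, a))
        return base


def _negbin(rng, mean, n=2.0, size=None):
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def generate_gene_cohort(config: CohortConfig) -> list[GeneRecord]:
    """Draw a gene cohort with the configured VIP effect sizes.

    Polymorphism model per gene: pS ~ Poisson(theta_s * L/600),
    pN ~ Poisson(pS-rate * c * (1-reduction if VIP)) with a gamma-distributed
    constraint factor c, so the expected VIP/non-VIP mean pN/pS ratio equals
    exactly (1 - pnps_reduction). Non-synonymous divergence carries the same
    constraint and is inflated by 1/(1-alpha), so pooled classic MK recovers
    the configured alphas and the mammal-wide dN is adaptively inflated in
    VIPs (the structure the target-average calibration corrects for).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    is_vip = rng.random(n) < config.vip_fraction

    module_size = config.n_go_terms // config.n_go_modules
    terms = [f"GO{t:04d}" for t in range(config.n_go_terms)]
    modules = [terms[m * module_size:(m + 1) * module_size]
               for m in range(config.n_go_modules)]
    virus_names = list(VIRUS_WEIGHTS)
    virus_p = np.array(list(VIRUS_WEIGHTS.values()), dtype=float)
    virus_p /= virus_p.sum()

    def pick(pair, flag):
        return pair[1] if flag else pair[0]

    genes = []
    for i in range(n):
        vip = bool(is_vip[i])
        c = rng.gamma(config.constraint_shape,
                      config.constraint_mean / config.constraint_shape)
        sigma = 0.5
        cds_len = int(np.clip(rng.lognormal(
            np.log(pick(config.cds_len_mean, vip)) - sigma**2 / 2, sigma), 60, 5000))
        lfac = cds_len / 600.0
        lam_s = config.theta_s * lfac
        red = (1.0 - config.pnps_reduction) if vip else 1.0
        alpha = config.alpha_vip if vip else config.alpha_nonvip
        p_s = int(rng.poisson(lam_s))
        p_n = int(rng.poisson(lam_s * c * red))
        ds_count = int(rng.poisson(config.div_s * lfac))
        dn_count = int(rng.poisson(config.div_s * lfac * c * red / (1.0 - alpha)))
        d_s = rng.gamma(8.0, 1.0 / 8.0)
        d_n = d_s * config.dnds_scale * c * red / (1.0 - alpha) * rng.lognormal(0.0, 0.2)

        mod = int(rng.integers(config.n_go_modules))
        k = int(rng.integers(max(1, config.go_per_gene - 2), config.go_per_gene + 3))
        gterms = set(rng.choice(modules[mod], size=min(k, module_size), replace=False))
        if rng.random() < 0.2:
            gterms.add(terms[int(rng.integers(config.n_go_terms))])

        immune = rng.random() < pick(config.immune_frac, vip)
        antiviral = vip and immune and rng.random() < 0.25
        viruses = frozenset()
        if vip:
            nv = 1 + int(rng.poisson(0.5))
            viruses = frozenset(rng.choice(virus_names, size=min(nv, len(virus_names)),
                                           replace=False, p=virus_p))
        genes.append(GeneRecord(
            gene_id=f"g{i:05d}",
            is_vip=vip,
            viruses=viruses,
            go_terms=frozenset(gterms),
            immune=immune,
            antiviral=antiviral,
            pN=p_n, pS=p_s,
            dN=float(d_n), dS=float(d_s),
            dn_count=dn_count, ds_count=ds_count,
            gc=float(np.clip(rng.normal(pick(config.gc_mean, vip), 0.04), 0.25, 0.75)),
            cds_len=cds_len,
            recomb=float(rng.gamma(2.0, pick(config.recomb_mean, vip) / 2.0)),
            rna_tissues=int(_negbin(rng, pick(config.rna_tissues_mean, vip))),
            protein_tissues=int(_negbin(rng, pick(config.protein_tissues_mean, vip))),
            ppi_degree=int(_negbin(rng, pick(config.ppi_degree_mean, vip), n=1.2)),
        ))
    return genes


# --- trees and branch-selection tables --------------------------------------

def random_tree(n_tips: int = 24, seed: int = 0, prefix: str = "sp") -> dendropy.Tree:
    """A random rooted binary tree with exponential branch lengths."""
    rng = np.random.default_rng(seed)
    labels = [f"{prefix}{i:02d}" for i in range(n_tips)]
    nodes = [f"{lab}:{rng.exponential(0.1):.4f}" for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.exponential(0.1):.4f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    newick = nodes[0].rsplit(":", 1)[0] + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    return tree


def branch_ids(tree: dendropy.Tree) -> list[str]:
    """Stable identifiers for every branch (edge) of the tree except the root.

    Branches are labelled in preorder as b<k>_<tip|node> so tables remain
    readable; the mapping is deterministic for a given tree.
    """
    ids = []
    k = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        tag = node.taxon.label if node.taxon is not None else "node"
        ids.append(f"b{k:02d}_{tag}")
        k += 1
    return ids


def clade_branches(tree: dendropy.Tree, tip_labels: Sequence[str]) -> list[str]:
    """Branch ids inside (and including) the MRCA subtree of ``tip_labels``."""
    tree.is_rooted = True
    taxa = [t for t in tree.taxon_namespace if t.label in set(tip_labels)]
    mrca = tree.mrca(taxa=taxa)
    inside = set(mrca.preorder_iter())
    ids = []
    k = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        tag = node.taxon.label if node.taxon is not None else "node"
        if node in inside:
            ids.append(f"b{k:02d}_{tag}")
        k += 1
    return ids


def generate_branch_table(
    genes: Sequence[GeneRecord],
    tree: dendropy.Tree,
    vip_excess: float = 2.0,
    seed: int = 0,
    invalid_rate: float = 0.04,
    base_prop: float = 0.003,
    active_prob: float = 0.3,
    pnps_coupling: float = 0.0,
    busted_gain: float = 50.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emulate branch-site test output for a gene cohort on a species tree.

    Per gene, a latent mean proportion of selected codons m_g = base_prop *
    lognormal noise is multiplied by ``vip_excess`` for VIPs (so the
    downstream adaptation-excess statistic has expectation
    (vip_excess-1)*100%). Per branch the proportion is zero-inflated:
    Bernoulli(active_prob) x Exponential(m_g/active_prob), clipped to [0,1];
    active branches carry small branch p-values. Synteny masks are
    Bernoulli(1-invalid_rate). Gene-level (overall-test) p-values shrink with
    the gene's true signal: p = U**(1 + busted_gain*m_g).

    ``pnps_coupling`` > 0 couples m_g to the gene's pN/pS rank (the power
    confound: relaxed genes show more detected selection).

    Returns (branch table, gene-level p table) as DataFrames with columns
    (gene_id, branch_id, prop_selected, branch_p, synteny_ok) and
    (gene_id, busted_p).
    """
    if vip_excess < 0:
        raise ConfigurationError("vip_excess must be >= 0")
    bids = branch_ids(tree)
    if len(bids) < 2:
        raise ConfigurationError("tree must have >= 2 branches")
    rng = np.random.default_rng(seed)

    pnps = np.array([g.pnps for g in genes])
    z = (pnps - pnps.mean()) / max(pnps.std(), 1e-12)

    rows = []
    prows = []
    nb = len(bids)
    for gi, g in enumerate(genes):
        m = base_prop * rng.lognormal(0.0, 0.5)
        if g.is_vip:
            m *= vip_excess
        if pnps_coupling:
            m *= float(np.exp(pnps_coupling * z[gi]))
        active = rng.random(nb) < active_prob
        props = np.where(
            active,
            np.clip(rng.exponential(m / active_prob, size=nb), 0.0, 1.0),
            0.0,
        )
        branch_p = np.where(active, rng.beta(0.5, 10.0, size=nb), rng.random(nb))
        synteny = rng.random(nb) >= invalid_rate
        for b in range(nb):
            rows.append((g.gene_id, bids[b], float(props[b]),
                         float(branch_p[b]), bool(synteny[b])))
        prows.append((g.gene_id, float(rng.random() ** (1.0 + busted_gain * m))))

    branch_df = pd.DataFrame(
        rows, columns=["gene_id", "branch_id", "prop_selected", "branch_p", "synteny_ok"])
    busted_df = pd.DataFrame(prows, columns=["gene_id", "busted_p"])
    return branch_df, busted_df
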
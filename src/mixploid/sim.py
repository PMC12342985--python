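"""Synthetic mixed-ploidy datasets with known truth.

The generator emulates diploid and tetraploid populations sampled from a
lineage tree: per-site ancestral frequencies drift down each branch under a
Balding-Nichols Beta model, individuals draw genotype dosages binomially
(autotetraploids from one frequency, allotetraploids from two diverged
subgenome frequencies), read counts follow a Poisson/binomial sequencing
model, window genealogies carry planted introgression signal, and S-locus
coverage profiles follow the copy-number configuration of each individual.
Everything is deterministic under a fixed seed.

Two ancestral frequency spectra are available: ``"uniform"`` (frequencies
Uniform(0.05, 0.95) — a structured-panel stand-in) and ``"neutral"``
(density proportional to 1/x, the standard neutral spectrum, for which the
expected sample SFS is proportional to 1/i and Tajima's D centers on zero).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mixploid.io import MISSING, GenotypeMatrix, SampleSheet
from mixploid.ploidy import SAlleleProfile
from mixploid.topo import WindowTree, enumerate_topologies

logger = logging.getLogger("mixploid")

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class Lineage:
    """One branch of the lineage tree: drift F accumulates from the parent
    (parent None = the ancestral pool)."""

    name: str
    parent: str | None
    drift: float

    def __post_init__(self) -> None:
        if not 0.0 < self.drift < 1.0:
            raise ValueError(f"drift F must be in (0,1), got {self.drift} "
                             f"for lineage {self.name}")


@dataclass
class Population:
    name: str
    lineage: str
    n_samples: int
    ploidy: int
    mode: str = "auto"   # "auto" or "allo" (tetraploids only)

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 4):
            raise ValueError(f"ploidy must be 2 or 4, got {self.ploidy}")
        if self.mode not in ("auto", "allo"):
            raise ValueError(f"mode must be auto or allo, got {self.mode!r}")
        if self.mode == "allo" and self.ploidy != 4:
            raise ValueError(f"allopolyploid mode requires ploidy 4 "
                             f"(population {self.name})")


@dataclass
class Tract:
    """Planted introgression: recipient dosages redrawn from the donor
    lineage frequency with probability m per genotype inside [start, end] bp."""

    donor: str       # donor lineage name
    recipient: str   # recipient population name
    start: int
    end: int
    m: float

    def __post_init__(self) -> None:
        if not 0.0 < self.m <= 1.0:
            raise ValueError(f"admixture m must be in (0,1], got {self.m}")
        if self.end < self.start:
            raise ValueError("tract end before start")


@dataclass
class SimConfig:
    lineages: list[Lineage]
    populations: list[Population]
    n_sites: int = 1000
    chrom: str = "scaffold_1"
    chrom_length: int = 1_000_000
    allo_divergence: float = 0.3
    allo_eps: float = 0.01
    ancestral: str = "uniform"     # "uniform" or "neutral"
    neutral_xmin: float = 0.005
    tracts: list[Tract] = field(default_factory=list)
    depth: float = 30.0
    error: float = 0.01
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        names = [l.name for l in self.lineages]
        if len(set(names)) != len(names):
            raise ValueError("duplicate lineage names")
        known = set(names)
        for l in self.lineages:
            if l.parent is not None and l.parent not in known:
                raise ValueError(f"lineage {l.name} has unknown parent {l.parent}")
        for p in self.populations:
            if p.lineage not in known:
                raise ValueError(f"population {p.name} on unknown lineage")
        if not 0.0 <= self.allo_divergence <= 1.0:
            raise ValueError("allo_divergence must be in [0,1]")
        if not 0.0 <= self.error < 0.5:
            raise ValueError("sequencing error must be in [0, 0.5)")
        if self.ancestral not in ("uniform", "neutral"):
            raise ValueError("ancestral must be 'uniform' or 'neutral'")
        for t in self.tracts:
            if t.end > self.chrom_length:
                raise ValueError("tract outside chromosome")

    def population(self, name: str) -> Population:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)


@dataclass
class SimTruth:
    """Ground truth matched to the emitted matrix."""

    sample_pop: dict[str, str]
    ploidies: dict[str, int]
    modes: dict[str, str]
    frequencies: dict[str, np.ndarray]
    subgenomes: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    tracts: list[dict] = field(default_factory=list)
    s_copies: dict[str, dict[str, int]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def _ancestral_frequencies(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.ancestral == "uniform":
        return rng.uniform(0.05, 0.95, size=config.n_sites)
    # density ~ 1/x on (xmin, 1): inverse CDF of u -> xmin^(1-u)
    u = rng.uniform(0.0, 1.0, size=config.n_sites)
    return config.neutral_xmin ** (1.0 - u)


def _beta_drift(p: np.ndarray, F: float, rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols: child ~ Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    if not 0.0 < F < 1.0:
        raise ValueError(f"drift F must be in (0,1), got {F}")
    nu = (1.0 - F) / F
    q = rng.beta(np.maximum(nu * p, 1e-12), np.maximum(nu * (1.0 - p), 1e-12))
    return np.clip(q, 1e-9, 1.0 - 1e-9)


def simulate_frequencies(config: SimConfig,
                         rng: np.random.Generator | None = None) -> dict[str, np.ndarray]:
    """Per-lineage allele-frequency table (sites x lineages).

    Ancestral frequencies drift independently down each branch; a lineage's
    frequencies are conditioned on its parent's.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ancestral = _ancestral_frequencies(config, rng)
    freqs: dict[str, np.ndarray] = {}
    pending = list(config.lineages)
    # parents are simulated before children regardless of declaration order
    while pending:
        progressed = False
        for lin in list(pending):
            if lin.parent is None:
                parent_freq = ancestral
            elif lin.parent in freqs:
                parent_freq = freqs[lin.parent]
            else:
                continue
            freqs[lin.name] = _beta_drift(parent_freq, lin.drift, rng)
            pending.remove(lin)
            progressed = True
        if not progressed:
            raise ValueError("lineage tree has a cycle")
    freqs["__ancestral__"] = ancestral
    return freqs


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def sample_names(config: SimConfig) -> list[str]:
    return [f"{p.name}_{i:03d}" for p in config.populations
            for i in range(p.n_samples)]


def simulate_genotypes(freqs: dict[str, np.ndarray], config: SimConfig,
                       rng: np.random.Generator | None = None
                       ) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw dosages for every sample: Binomial(ploidy, p) in auto mode,
    Binomial(2, pA) + Binomial(2, pB) over diverged subgenomes in allo mode."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n_sites = config.n_sites
    positions = np.sort(rng.choice(config.chrom_length, size=n_sites,
                                   replace=False)) + 1
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    sites = pd.DataFrame({"chrom": config.chrom, "pos": positions,
                          "ref": _BASES[ref_idx], "alt": _BASES[alt_idx],
                          "qual": 100.0})
    names, ploidies, columns = [], [], []
    truth = SimTruth({}, {}, {}, dict(freqs))
    for pop in config.populations:
        p = freqs[pop.lineage]
        if pop.mode == "auto":
            dos = rng.binomial(pop.ploidy, p[:, None],
                               size=(n_sites, pop.n_samples))
        else:
            pa, pb = _subgenome_frequencies(p, config, rng)
            truth.subgenomes[pop.name] = (pa, pb)
            dos = (rng.binomial(2, pa[:, None], size=(n_sites, pop.n_samples))
                   + rng.binomial(2, pb[:, None], size=(n_sites, pop.n_samples)))
        columns.append(dos.astype(np.int16))
        for i in range(pop.n_samples):
            name = f"{pop.name}_{i:03d}"
            names.append(name)
            ploidies.append(pop.ploidy)
            truth.sample_pop[name] = pop.name
            truth.ploidies[name] = pop.ploidy
            truth.modes[name] = pop.mode
    dosages = np.hstack(columns)
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = MISSING
    gm = GenotypeMatrix(names, np.array(ploidies), sites, dosages)
    gm.validate()
    return gm, truth


def _subgenome_frequencies(p: np.ndarray, config: SimConfig,
                           rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two subgenome frequency vectors; a fraction d of sites is alternately
    near-fixed (one subgenome >= 1-eps, the other <= eps)."""
    pa, pb = p.copy(), p.copy()
    n = len(p)
    diverged = rng.random(n) < config.allo_divergence
    hi = rng.uniform(1.0 - config.allo_eps, 1.0, size=n)
    lo = rng.uniform(0.0, config.allo_eps, size=n)
    mirror = rng.random(n) < 0.5
    pa[diverged & ~mirror] = hi[diverged & ~mirror]
    pb[diverged & ~mirror] = lo[diverged & ~mirror]
    pa[diverged & mirror] = lo[diverged & mirror]
    pb[diverged & mirror] = hi[diverged & mirror]
    return pa, pb


def plant_introgression(gm: GenotypeMatrix, truth: SimTruth, config: SimConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[GenotypeMatrix, SimTruth]:
    """Redraw recipient dosages from the donor frequency inside each tract.

    Each recipient genotype inside a tract is replaced with probability m by
    a Binomial(ploidy, p_donor) draw.  Overlapping tracts for the same
    recipient are merged (warning).  Sites outside tracts are untouched.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if not config.tracts:
        return gm, truth
    merged: dict[tuple[str, str], list[list]] = {}
    for t in config.tracts:
        key = (t.donor, t.recipient)
        spans = merged.setdefault(key, [])
        placed = False
        for s in spans:
            if t.start <= s[1] and s[0] <= t.end:
                warnings.warn(f"overlapping tracts for recipient {t.recipient}; "
                              "merged", stacklevel=2)
                s[0], s[1] = min(s[0], t.start), max(s[1], t.end)
                s[2] = max(s[2], t.m)
                placed = True
                break
        if not placed:
            spans.append([t.start, t.end, t.m])
    dosages = gm.dosages.copy()
    pos = gm.sites["pos"].to_numpy()
    for (donor, recipient), spans in merged.items():
        pop = config.population(recipient)
        cols = gm.sample_index([s for s, p in truth.sample_pop.items()
                                if p == recipient])
        p_donor = truth.frequencies[donor]
        for start, end, m in spans:
            site_idx = np.where((pos >= start) & (pos <= end))[0]
            for j in site_idx:
                redraw = rng.random(len(cols)) < m
                if redraw.any():
                    new = rng.binomial(pop.ploidy, p_donor[j], size=int(redraw.sum()))
                    keep = dosages[j, cols[redraw]] != MISSING
                    vals = dosages[j, cols[redraw]]
                    vals[keep] = new[keep]
                    dosages[j, cols[redraw]] = vals
            truth.tracts.append({"donor": donor, "recipient": recipient,
                                 "start": start, "end": end, "m": m,
                                 "n_sites": len(site_idx)})
    out = GenotypeMatrix(gm.samples, gm.ploidies, gm.sites, dosages, gm.depths)
    return out, truth


# ---------------------------------------------------------------------------
# read counts
# ---------------------------------------------------------------------------

def simulate_read_counts(gm: GenotypeMatrix, depth: float = 30.0,
                         error: float = 0.01,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-genotype (ref, alt) read counts: depth ~ Poisson(lambda) and
    alt ~ Binomial(depth, q), q = (d/ploidy)(1-e) + (1-d/ploidy)e.
    Missing genotypes get zero depth."""
    if depth <= 0:
        raise ValueError("mean depth lambda must be > 0")
    if rng is None:
        rng = np.random.default_rng(0)
    dp = rng.poisson(depth, size=gm.dosages.shape)
    called = gm.dosages != MISSING
    dp[~called] = 0
    frac = np.where(called, gm.dosages, 0) / gm.ploidies[None, :]
    q = frac * (1.0 - error) + (1.0 - frac) * error
    alt = rng.binomial(dp, q)
    ad = np.stack([dp - alt, alt], axis=-1)
    return ad


# ---------------------------------------------------------------------------
# window genealogies
# ---------------------------------------------------------------------------

def _resolve_clade(tips: list[str], rng: np.random.Generator) -> str:
    """Random binary resolution of a tip list, unit branch lengths."""
    nodes = list(tips)
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        nodes.append(f"({a}:1,{b}:1)")
    return nodes[0]


def _topology_newick_with_tips(topology_newick: str, tips_by_group: dict[str, list[str]],
                               rng: np.random.Generator) -> str:
    """Replace each group label in a group-level newick by a random
    resolution of that group's tips (reciprocal monophyly by construction)."""
    import re

    out = topology_newick.rstrip(";")
    for group in sorted(tips_by_group):
        sub = _resolve_clade(tips_by_group[group], rng)
        out = re.sub(rf"(?<![\w]){re.escape(group)}(?![\w])", sub, out)
    # add unit lengths to group-level edges
    out = out.replace("),", "):1,").replace("))", "):1)")
    return out + ";"


def simulate_window_trees(tips_by_group: dict[str, list[str]],
                          class_probs: dict[str, float],
                          class_topologies: dict[str, str],
                          n_windows: int,
                          rng: np.random.Generator,
                          chrom: str = "scaffold_1",
                          span_bp: int = 5000) -> tuple[list[WindowTree], list[str]]:
    """Mixture-class window genealogies.

    Each window draws a class (e.g. species / introgression / random) from
    ``class_probs``; the emitted tree is reciprocally monophyletic for the
    class topology with random within-group resolution and unit branch
    lengths.  Class "random" (if not given a topology) picks uniformly from
    the full topology universe.
    """
    total = sum(class_probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class probabilities sum to {total}, expected 1")
    classes = sorted(class_probs)
    probs = np.array([class_probs[c] for c in classes])
    universe = enumerate_topologies(sorted(tips_by_group))
    trees, drawn = [], []
    for w in range(n_windows):
        cls = classes[rng.choice(len(classes), p=probs)]
        if cls in class_topologies:
            topo_newick = class_topologies[cls]
        else:
            topo_newick = universe[int(rng.integers(len(universe)))].newick
        newick = _topology_newick_with_tips(topo_newick, tips_by_group, rng)
        trees.append(WindowTree(chrom, w * span_bp, (w + 1) * span_bp, newick))
        drawn.append(cls)
    return trees, drawn


def simulate_tract_tree_series(tips_by_group: dict[str, list[str]],
                               roles: dict[str, str],
                               n_windows: int,
                               tracts: list[tuple[int, int]],
                               rng: np.random.Generator,
                               p_in: float = 0.8, p_out: float = 0.1,
                               chrom: str = "scaffold_1",
                               span_bp: int = 5000
                               ) -> tuple[list[WindowTree], pd.DataFrame]:
    """Window genealogies with planted introgression tracts.

    ``roles`` maps {"outgroup","donor","recipient","sister"} to group names.
    Per window, each recipient tip carries a donor-derived haplotype with
    probability ``p_in`` inside a tract (half-open window-index intervals)
    and ``p_out`` outside; migrant tips attach inside the donor clade, so the
    introgression-topology weight of the window approximates the migrant
    fraction.  Returns the trees plus a truth table
    (window, in_tract, n_migrant, n_recipient).
    """
    og, dn = roles["outgroup"], roles["donor"]
    rc, si = roles["recipient"], roles["sister"]
    rec_tips = tips_by_group[rc]
    rows, trees = [], []
    for w in range(n_windows):
        in_tract = any(a <= w < b for a, b in tracts)
        p = p_in if in_tract else p_out
        migrant = rng.random(len(rec_tips)) < p
        migrants = [t for t, m in zip(rec_tips, migrant) if m]
        residents = [t for t, m in zip(rec_tips, migrant) if not m]
        donor_clade = _resolve_clade(tips_by_group[dn] + migrants, rng)
        sister_clade = _resolve_clade(tips_by_group[si], rng)
        out_clade = _resolve_clade(tips_by_group[og], rng)
        if residents:
            res_clade = _resolve_clade(residents, rng)
            core = f"(({res_clade}:1,{sister_clade}:1):1,{donor_clade}:1)"
        else:
            core = f"({sister_clade}:1,{donor_clade}:1)"
        newick = f"({core}:1,{out_clade}:1);"
        trees.append(WindowTree(chrom, w * span_bp, (w + 1) * span_bp, newick))
        rows.append((w, in_tract, int(migrant.sum()), len(rec_tips)))
    truth = pd.DataFrame(rows, columns=["window", "in_tract", "n_migrant",
                                        "n_recipient"])
    return trees, truth


# ---------------------------------------------------------------------------
# S locus
# ---------------------------------------------------------------------------

def simulate_s_locus(ploidies: dict[str, int], rng: np.random.Generator,
                     pool_size: int = 20, lam: float = 25.0,
                     force_copies: tuple[int, ...] | None = None
                     ) -> tuple[dict[str, SAlleleProfile], dict[str, dict[str, int]]]:
    """S-allele copy configurations and Poisson coverage profiles.

    Each individual receives ploidy-many copies drawn with replacement from
    an allele pool; coverage per distinct allele ~ Poisson(copies * lam),
    control coverage ~ Poisson(ploidy * lam).  ``force_copies`` pins every
    individual to a given copy-number configuration over distinct alleles
    (the configuration must sum to the ploidy).
    """
    if lam <= 0:
        raise ValueError("per-copy coverage lambda must be > 0")
    profiles: dict[str, SAlleleProfile] = {}
    truth: dict[str, dict[str, int]] = {}
    for sample in ploidies:
        ploidy = ploidies[sample]
        if force_copies is not None:
            if sum(force_copies) != ploidy:
                raise ValueError("forced copies must sum to the ploidy")
            alleles = rng.choice(pool_size, size=len(force_copies), replace=False)
            counts = {f"S{a:02d}": c for a, c in zip(alleles, force_copies)}
        else:
            draws = rng.integers(0, pool_size, size=ploidy)
            counts = {}
            for a in draws:
                counts[f"S{a:02d}"] = counts.get(f"S{a:02d}", 0) + 1
        coverages = {a: float(rng.poisson(c * lam)) for a, c in sorted(counts.items())}
        control = float(max(rng.poisson(ploidy * lam), 1))
        profiles[sample] = SAlleleProfile(sample, coverages, control)
        truth[sample] = counts
    return profiles, truth


# ---------------------------------------------------------------------------
# gene-resolution dataset for the divergence scan
# ---------------------------------------------------------------------------

def simulate_gene_matrix(n_genes: int = 100, snps_per_gene: int = 25,
                         invariant_per_gene: int = 475, gene_span: int = 1500,
                         n_focal: int = 8, n_contrast: int = 8,
                         focal_ploidy: int = 4, contrast_ploidy: int = 2,
                         drift: float = 0.05, planted_gene: int | None = None,
                         dxy_factor: float = 5.0, missing_rate: float = 0.0,
                         seed: int = 0, chrom: str = "scaffold_1"):
    """Genotypes for a panel of genes plus a matching annotation.

    Two populations ("focal", "contrast") drift independently from shared
    ancestral frequencies.  Within each gene, ``snps_per_gene`` sites are
    variable and ``invariant_per_gene`` are monomorphic (they enter diversity
    denominators).  ``planted_gene`` (index) receives additional near-fixed
    differences sized analytically so its expected between-population dxy is
    ``dxy_factor`` times the neutral expectation — a positive-selection
    stand-in.  Returns (GenotypeMatrix, gene table, SampleSheet).
    """
    rng = np.random.default_rng(seed)
    # E[2p(1-p)] for p ~ U(a,b): the expected per-SNP dxy between two
    # independently drifted populations (drift leaves it unchanged)
    a, b = 0.05, 0.95
    e_site_dxy = 2 * (0.25 - (b - a) ** 2 / 12.0 - 0.0)
    n_extra = 0
    if planted_gene is not None:
        e_div = 2 * (0.02 * 0.02 + 0.98 * 0.98) / 2  # p=0.02 vs 0.98
        n_extra = int(np.ceil((dxy_factor - 1.0) * snps_per_gene
                              * e_site_dxy / e_div))
        if n_extra > invariant_per_gene:
            raise ValueError("not enough invariant sites to plant divergence")
    samples = ([f"focal_{i:03d}" for i in range(n_focal)]
               + [f"contrast_{i:03d}" for i in range(n_contrast)])
    ploidies = np.array([focal_ploidy] * n_focal + [contrast_ploidy] * n_contrast)
    sites_per_gene = snps_per_gene + invariant_per_gene
    rows, dosage_blocks, gene_rows = [], [], []
    for g in range(n_genes):
        start = g * (gene_span + 300) + 101
        # CDS length divisible by 3
        length = ((gene_span // 3) * 3)
        gene_rows.append((f"gene{g + 1:04d}", chrom, start, start + length - 1, "+"))
        offsets = np.sort(rng.choice(length, size=sites_per_gene, replace=False))
        positions = start + offsets
        variable = np.zeros(sites_per_gene, bool)
        variable[rng.choice(sites_per_gene, size=snps_per_gene, replace=False)] = True
        planted_here = planted_gene is not None and g == planted_gene
        divergent = np.zeros(sites_per_gene, bool)
        if planted_here:
            inv_idx = np.where(~variable)[0]
            divergent[rng.choice(inv_idx, size=n_extra, replace=False)] = True
        p_anc = rng.uniform(a, b, size=sites_per_gene)
        pf = _beta_drift(p_anc, drift, rng)
        pc = _beta_drift(p_anc, drift, rng)
        pf[~variable] = 0.0
        pc[~variable] = 0.0
        if planted_here:
            pf[divergent] = 0.02
            pc[divergent] = 0.98
        dos_f = rng.binomial(focal_ploidy, np.clip(pf, 0, 1)[:, None],
                             size=(sites_per_gene, n_focal))
        dos_c = rng.binomial(contrast_ploidy, np.clip(pc, 0, 1)[:, None],
                             size=(sites_per_gene, n_contrast))
        dos = np.hstack([dos_f, dos_c]).astype(np.int16)
        for k in range(sites_per_gene):
            alt = "A" if (variable[k] or divergent[k]) else "."
            rows.append((chrom, int(positions[k]), "G", alt, 100.0))
        dosage_blocks.append(dos)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "qual"])
    dosages = np.vstack(dosage_blocks)
    if missing_rate > 0:
        mask = rng.random(dosages.shape) < missing_rate
        dosages[mask] = MISSING
    gm = GenotypeMatrix(samples, ploidies, sites, dosages)
    gm.validate()
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start",
                                             "end", "strand"])
    sheet = SampleSheet(pd.DataFrame({
        "sample": samples,
        "population": ["focal"] * n_focal + ["contrast"] * n_contrast,
        "lineage": ["focal"] * n_focal + ["contrast"] * n_contrast,
        "ploidy": ploidies,
        "source": "synthetic"}))
    return gm, genes, sheet


def sample_sheet_from_truth(truth: SimTruth) -> SampleSheet:
    rows = []
    for sample, pop in truth.sample_pop.items():
        rows.append((sample, pop, pop, truth.ploidies[sample], "synthetic"))
    return SampleSheet(pd.DataFrame(rows, columns=["sample", "population",
                                                   "lineage", "ploidy",
                                                   "source"]))
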
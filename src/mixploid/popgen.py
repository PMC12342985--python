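"""Ploidy-aware diversity and differentiation statistics.

All estimators treat allele *copies* as the sampling unit, so diploid and
tetraploid individuals mix freely: at site j a population contributes
n_j = sum of ploidies over genotyped samples and a_j = sum of dosages.
Missing data is handled with pixy-style site weighting — numerators and
denominators accumulate per site over whatever copies were genotyped there,
and monomorphic genotyped sites enter denominators when the input carries
invariant sites.

pi   = sum_j a_j (n_j - a_j) / sum_j n_j (n_j - 1) / 2
dxy  = sum_j [a1 (n2 - a2) + a2 (n1 - a1)] / sum_j n1 n2

Tajima's D is restricted to complete-data sites (its variance constants
assume a fixed sample size).  Nei's standard genetic distance operates at
the individual level on dosage frequencies, as used for distance networks
and UPGMA clustering.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mixploid.io import MISSING, GenotypeMatrix

logger = logging.getLogger("mixploid")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def site_counts(gm: GenotypeMatrix, samples) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (n_j, a_j): genotyped copies and alt copies in a sample set."""
    cols = gm.sample_index(samples)
    dos = gm.dosages[:, cols]
    called = dos != MISSING
    pl = gm.ploidies[cols]
    n = (called * pl[None, :]).sum(axis=1).astype(np.int64)
    a = np.where(called, dos, 0).sum(axis=1).astype(np.int64)
    return n, a


def _window_iter(gm: GenotypeMatrix, windows: pd.DataFrame | None):
    """Yield (name, chrom, start, end, site index array); windows are 0-based
    half-open.  ``windows=None`` treats the whole matrix as one window."""
    pos0 = gm.sites["pos"].to_numpy() - 1
    chrom = gm.sites["chrom"].to_numpy()
    if windows is None:
        yield ("all", "*", 0, int(pos0.max()) + 1 if len(pos0) else 0,
               np.arange(gm.n_sites))
        return
    for k, row in enumerate(windows.itertuples(index=False)):
        name = getattr(row, "name", None) or getattr(row, "gene_id", None) \
            or f"win{k + 1}"
        idx = np.where((chrom == row.chrom) & (pos0 >= row.start)
                       & (pos0 < row.end))[0]
        yield (name, row.chrom, int(row.start), int(row.end), idx)


def subset_sites(gm: GenotypeMatrix, mask: np.ndarray) -> GenotypeMatrix:
    """Row-subset of a genotype matrix (boolean mask or index array)."""
    return GenotypeMatrix(gm.samples, gm.ploidies,
                          gm.sites.iloc[mask].reset_index(drop=True),
                          gm.dosages[mask],
                          None if gm.depths is None else gm.depths[mask])


# ---------------------------------------------------------------------------
# SNP filtering
# ---------------------------------------------------------------------------

def filter_snps(gm: GenotypeMatrix, min_qual: float = 20.0, min_depth: int = 5,
                max_missing: float = 0.2, max_het: float = 0.75,
                min_count: int = 5) -> GenotypeMatrix:
    """Variant-site filter for the introgression pipeline.

    Genotypes below ``min_depth`` are masked to missing first (skipped with a
    log line when the matrix carries no depths), then sites must satisfy
    QUAL >= min_qual, missing fraction <= max_missing, heterozygote fraction
    among called <= max_het and minor-allele copy count >= min_count.
    Invariant sites fail ``min_count`` by construction.
    """
    dosages = gm.dosages.copy()
    if gm.depths is not None:
        dosages[(gm.depths >= 0) & (gm.depths < min_depth)] = MISSING
    else:
        logger.info("filter_snps: no per-genotype depths; min_depth rule skipped")
    work = GenotypeMatrix(gm.samples, gm.ploidies, gm.sites, dosages, gm.depths)
    called = work.dosages != MISSING
    n, a = site_counts(work, work.samples)
    qual = work.sites["qual"].to_numpy(float)
    pass_qual = np.isnan(qual) | (qual >= min_qual)
    miss_frac = 1.0 - called.mean(axis=1)
    pl = np.broadcast_to(work.ploidies, work.dosages.shape)
    het = called & (work.dosages > 0) & (work.dosages < pl)
    with np.errstate(invalid="ignore"):
        het_frac = np.where(called.sum(axis=1) > 0,
                            het.sum(axis=1) / np.maximum(called.sum(axis=1), 1), 1.0)
    minor = np.minimum(a, n - a)
    keep = (pass_qual & (miss_frac <= max_missing) & (het_frac <= max_het)
            & (minor >= min_count))
    logger.info("filter_snps: %d/%d sites pass (qual %d, missing %d, het %d, "
                "count %d failed)", int(keep.sum()), gm.n_sites,
                int((~pass_qual).sum()), int((miss_frac > max_missing).sum()),
                int((het_frac > max_het).sum()), int((minor < min_count).sum()))
    if not keep.any():
        raise ValueError("no sites pass filters; review thresholds")
    return subset_sites(work, np.where(keep)[0])


# ---------------------------------------------------------------------------
# four-fold degenerate sites
# ---------------------------------------------------------------------------

def _fourfold_prefixes() -> set[str]:
    from Bio.Data.CodonTable import standard_dna_table

    table = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        table[stop] = "*"
    out = set()
    for b1 in "ACGT":
        for b2 in "ACGT":
            aas = {table[b1 + b2 + b3] for b3 in "ACGT"}
            if len(aas) == 1:
                out.add(b1 + b2)
    return out


_FOURFOLD_PREFIXES = None
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def fourfold_sites(annotation, reference) -> pd.DataFrame:
    """Genomic positions (1-based) whose codon third position is four-fold
    degenerate, honoring strand and CDS phase.

    ``reference`` is a pyfaidx.Fasta or a path to a FASTA.  Genes whose CDS
    length is not divisible by 3 are skipped (logged); positions claimed by
    overlapping CDS in conflicting frames are excluded.
    """
    global _FOURFOLD_PREFIXES
    if _FOURFOLD_PREFIXES is None:
        _FOURFOLD_PREFIXES = _fourfold_prefixes()
    import pyfaidx

    fasta = reference if isinstance(reference, pyfaidx.Fasta) \
        else pyfaidx.Fasta(str(reference))
    claims: dict[tuple[str, int], set] = {}
    verdicts: dict[tuple[str, int], bool] = {}
    n_skipped = 0
    for gene in annotation.genes.itertuples(index=False):
        if gene.chrom not in fasta:
            raise ValueError(f"chromosome {gene.chrom} not in reference")
        segs = annotation.cds[annotation.cds["gene_id"] == gene.gene_id]
        if segs.empty:
            continue
        if gene.gene_id in annotation.frame_warnings:
            n_skipped += 1
            continue
        order = segs.sort_values("start", ascending=(gene.strand == "+"))
        positions: list[int] = []
        for seg in order.itertuples(index=False):
            rng = range(seg.start, seg.end + 1)
            positions.extend(rng if gene.strand == "+" else reversed(rng))
        phase = int(order.iloc[0]["phase"])
        positions = positions[phase:]
        seq = {}
        for codon_start in range(0, len(positions) - 2, 3):
            codon_pos = positions[codon_start:codon_start + 3]
            bases = []
            for p in codon_pos:
                if p not in seq:
                    b = str(fasta[gene.chrom][p - 1:p]).upper()
                    seq[p] = b if gene.strand == "+" else b.translate(_COMPLEMENT)
                bases.append(seq[p])
            for offset, p in enumerate(codon_pos):
                claims.setdefault((gene.chrom, p), set()).add((gene.strand, offset))
            prefix = bases[0] + bases[1]
            third = (gene.chrom, codon_pos[2])
            verdicts[third] = prefix in _FOURFOLD_PREFIXES
    if n_skipped:
        logger.info("fourfold_sites: skipped %d genes with CDS length "
                    "not divisible by 3", n_skipped)
    rows = [key for key, ok in verdicts.items()
            if ok and len(claims[key]) == 1]
    out = pd.DataFrame(rows, columns=["chrom", "pos"])
    return out.sort_values(["chrom", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# diversity statistics
# ---------------------------------------------------------------------------

def pi(gm: GenotypeMatrix, samples, windows: pd.DataFrame | None = None) -> pd.DataFrame:
    """Nucleotide diversity per window with pixy-style site weighting.

    Sites with fewer than two genotyped copies are skipped; windows with a
    zero denominator report NA (never 0).
    """
    n, a = site_counts(gm, samples)
    num_j = a * (n - a)
    den_j = n * (n - 1) // 2
    usable = n >= 2
    rows = []
    for name, chrom, start, end, idx in _window_iter(gm, windows):
        sel = idx[usable[idx]]
        num, den = int(num_j[sel].sum()), int(den_j[sel].sum())
        value = num / den if den > 0 else np.nan
        rows.append((name, chrom, start, end, "pi", value, num, den, len(sel)))
    return pd.DataFrame(rows, columns=["window", "chrom", "start", "end",
                                       "statistic", "value", "numerator",
                                       "denominator", "n_sites_used"])


def dxy(gm: GenotypeMatrix, samples_a, samples_b,
        windows: pd.DataFrame | None = None) -> pd.DataFrame:
    """Between-population divergence per window (pixy-style weighting)."""
    n1, a1 = site_counts(gm, samples_a)
    n2, a2 = site_counts(gm, samples_b)
    num_j = a1 * (n2 - a2) + a2 * (n1 - a1)
    den_j = n1 * n2
    usable = (n1 >= 1) & (n2 >= 1)
    rows = []
    for name, chrom, start, end, idx in _window_iter(gm, windows):
        sel = idx[usable[idx]]
        num, den = int(num_j[sel].sum()), int(den_j[sel].sum())
        value = num / den if den > 0 else np.nan
        rows.append((name, chrom, start, end, "dxy", value, num, den, len(sel)))
    return pd.DataFrame(rows, columns=["window", "chrom", "start", "end",
                                       "statistic", "value", "numerator",
                                       "denominator", "n_sites_used"])


def _tajima_constants(n: int) -> tuple[float, float, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return a1, e1, e2


def tajimas_d(gm: GenotypeMatrix, samples,
              windows: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tajima's D per window on complete-data sites.

    Only sites where every sample of the population is genotyped are used,
    so the copy count n = sum of ploidies is constant and the standard
    variance constants apply.  Windows with no segregating site report NA;
    n < 4 is NA with a warning.
    """
    cols = gm.sample_index(samples)
    n = int(gm.ploidies[cols].sum())
    complete = (gm.dosages[:, cols] != MISSING).all(axis=1)
    a = np.where(complete, gm.dosages[:, cols].clip(min=0).sum(axis=1), 0)
    if n < 4:
        warnings.warn("Tajima's D undefined for fewer than 4 copies", stacklevel=2)
    rows = []
    a1, e1, e2 = _tajima_constants(n) if n >= 4 else (np.nan,) * 3
    pair_den = n * (n - 1) / 2.0
    for name, chrom, start, end, idx in _window_iter(gm, windows):
        sel = idx[complete[idx]]
        aj = a[sel]
        seg = (aj > 0) & (aj < n)
        S = int(seg.sum())
        if n < 4 or S == 0:
            rows.append((name, chrom, start, end, "tajimas_d", np.nan, S, len(sel)))
            continue
        khat = float((aj * (n - aj)).sum()) / pair_den
        var = e1 * S + e2 * S * (S - 1)
        D = (khat - S / a1) / math.sqrt(var)
        rows.append((name, chrom, start, end, "tajimas_d", D, S, len(sel)))
    return pd.DataFrame(rows, columns=["window", "chrom", "start", "end",
                                       "statistic", "value", "S", "n_sites_used"])


def watterson_theta(gm: GenotypeMatrix, samples,
                    windows: pd.DataFrame | None = None) -> pd.DataFrame:
    """Watterson's theta per site, on complete-data sites (constant n)."""
    cols = gm.sample_index(samples)
    n = int(gm.ploidies[cols].sum())
    a1 = sum(1.0 / i for i in range(1, n)) if n >= 2 else np.nan
    complete = (gm.dosages[:, cols] != MISSING).all(axis=1)
    a = np.where(complete, gm.dosages[:, cols].clip(min=0).sum(axis=1), 0)
    rows = []
    for name, chrom, start, end, idx in _window_iter(gm, windows):
        sel = idx[complete[idx]]
        aj = a[sel]
        S = int(((aj > 0) & (aj < n)).sum())
        value = S / a1 / len(sel) if len(sel) and n >= 2 else np.nan
        rows.append((name, chrom, start, end, "watterson", value, S, len(sel)))
    return pd.DataFrame(rows, columns=["window", "chrom", "start", "end",
                                       "statistic", "value", "S", "n_sites_used"])


# ---------------------------------------------------------------------------
# Nei's distance and UPGMA
# ---------------------------------------------------------------------------

def neis_distance(gm: GenotypeMatrix, samples=None) -> pd.DataFrame:
    """Nei's standard genetic distance between individuals.

    Per individual, allele frequency f = dosage/ploidy.  Over loci where
    both individuals are genotyped: J_xy = mean(f_x f_y + (1-f_x)(1-f_y)),
    I = J_xy / sqrt(J_x J_y), D = -ln I.  Identity I = 0 reports +inf; no
    shared loci reports NaN.
    """
    if samples is None:
        samples = gm.samples
    cols = gm.sample_index(samples)
    if len(cols) < 2:
        raise ValueError("need at least two individuals")
    dos = gm.dosages[:, cols].astype(float)
    dos[dos == MISSING] = np.nan
    f = dos / gm.ploidies[cols][None, :]
    n = len(cols)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~np.isnan(f[:, i]) & ~np.isnan(f[:, j])
            if not shared.any():
                D[i, j] = D[j, i] = np.nan
                continue
            fx, fy = f[shared, i], f[shared, j]
            jxy = float(np.mean(fx * fy + (1 - fx) * (1 - fy)))
            jx = float(np.mean(fx * fx + (1 - fx) * (1 - fx)))
            jy = float(np.mean(fy * fy + (1 - fy) * (1 - fy)))
            ident = jxy / math.sqrt(jx * jy)
            D[i, j] = D[j, i] = -math.log(ident) if ident > 0 else np.inf
    return pd.DataFrame(D, index=list(samples), columns=list(samples))


def upgma(distance: pd.DataFrame) -> str:
    """UPGMA clustering of a symmetric distance matrix to a newick string.

    Arithmetic-mean (proportional) cluster distances; ties broken by the
    lexicographically lowest pair of member labels, so the result is
    invariant to input order; ultrametric branch lengths.  NaN/inf entries
    are an error listing the offending pairs.
    """
    labels = list(distance.columns)
    D = distance.to_numpy(float).copy()
    bad = [(labels[i], labels[j]) for i in range(len(labels))
           for j in range(i + 1, len(labels))
           if not np.isfinite(D[i, j])]
    if bad:
        raise ValueError(f"non-finite distances for pairs: {bad}")
    active = {i: {"members": (labels[i],), "size": 1, "height": 0.0,
                  "newick": labels[i]}
              for i in range(len(labels))}
    dist = {frozenset((i, j)): D[i, j] for i in active for j in active if i < j}
    next_id = len(labels)
    while len(active) > 1:
        best = None
        for key, d in dist.items():
            i, j = sorted(key, key=lambda c: active[c]["members"][0])
            rank = (d, active[i]["members"][0], active[j]["members"][0])
            if best is None or rank < best[0]:
                best = (rank, i, j)
        _, i, j = best
        d = dist[frozenset((i, j))]
        ci, cj = active[i], active[j]
        height = d / 2.0
        newick = (f"({ci['newick']}:{format(height - ci['height'], '.12g')},"
                  f"{cj['newick']}:{format(height - cj['height'], '.12g')})")
        new = {"members": tuple(sorted(ci["members"] + cj["members"])),
               "size": ci["size"] + cj["size"], "height": height,
               "newick": newick}
        del active[i], active[j]
        for k in list(active):
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dist[frozenset((next_id, k))] = \
                (ci["size"] * dik + cj["size"] * djk) / (ci["size"] + cj["size"])
        del dist[frozenset((i, j))]
        active[next_id] = new
        next_id += 1
    return next(iter(active.values()))["newick"] + ";"


# ---------------------------------------------------------------------------
# site frequency spectra
# ---------------------------------------------------------------------------

@dataclass
class SFS:
    """Site frequency spectrum over derived-copy classes.

    ``counts[i]`` = number of sites with i derived copies; length
    n_chrom + 1 (unfolded) or n_chrom//2 + 1 (folded).
    """

    n_chrom: int
    counts: np.ndarray
    polarization: str
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("negative SFS counts")


def compute_sfs(gm: GenotypeMatrix, samples, polarization: str = "unfolded") -> SFS:
    """Tally the SFS over complete-data sites (constant copy number).

    Unfolded polarization takes the alt allele as derived; folded maps class
    i to min(i, n-i).  Sites with any missing genotype are skipped and
    counted.
    """
    if polarization not in ("unfolded", "folded"):
        raise ValueError("polarization must be 'unfolded' or 'folded'")
    cols = gm.sample_index(samples)
    n = int(gm.ploidies[cols].sum())
    complete = (gm.dosages[:, cols] != MISSING).all(axis=1)
    if not complete.any():
        raise ValueError("no complete-data sites to tally")
    a = gm.dosages[:, cols][complete].sum(axis=1).astype(np.int64)
    if polarization == "folded":
        a = np.minimum(a, n - a)
        counts = np.bincount(a, minlength=n // 2 + 1)
    else:
        counts = np.bincount(a, minlength=n + 1)
    return SFS(n, counts, polarization, n_skipped=int((~complete).sum()))


def allo_peak_statistic(sfs: SFS, delta: float = 0.05) -> float:
    """Mid-frequency excess E: observed fraction of segregating sites with
    frequency in [0.5-delta, 0.5+delta] over the neutral (1/i) expectation.

    Autopolyploids (no fixed subgenome divergence) give E near 1 or below;
    allopolyploids mapped to a single reference pile fixed heterozygous
    sites at frequency 1/2 and push E well above 1.
    """
    n = sfs.n_chrom
    if n < 4:
        raise ValueError("need at least 4 copies")
    lo, hi = 0.5 - delta, 0.5 + delta
    if sfs.polarization == "folded":
        classes = np.arange(1, n // 2 + 1)
        weights = np.where(classes < n - classes,
                           1.0 / classes + 1.0 / (n - classes),
                           1.0 / classes)
        seg_counts = sfs.counts[1:n // 2 + 1]
    else:
        classes = np.arange(1, n)
        weights = 1.0 / classes
        seg_counts = sfs.counts[1:n]
    freqs = classes / n
    band = (freqs >= lo) & (freqs <= hi)
    if not band.any():
        raise ValueError(f"no frequency class inside the band (n={n}, delta={delta})")
    total = seg_counts.sum()
    if total == 0:
        raise ValueError("no segregating sites in SFS")
    observed = seg_counts[band].sum() / total
    expected = weights[band].sum() / weights.sum()
    return float(observed / expected)


def block_bootstrap_sfs(gm: GenotypeMatrix, samples, block: int = 10_000,
                        target_sites: int | None = None, seed: int = 0,
                        polarization: str = "unfolded") -> SFS:
    """One block-bootstrap SFS replicate.

    The genome is partitioned into consecutive ``block``-bp segments; blocks
    are drawn with replacement until the cumulative segregating-site count
    reaches ``target_sites`` (default: the original total), and the SFS is
    tallied on the concatenated draw.
    """
    cols = gm.sample_index(samples)
    n = int(gm.ploidies[cols].sum())
    complete = (gm.dosages[:, cols] != MISSING).all(axis=1)
    a_all = gm.dosages[:, cols].clip(min=0).sum(axis=1).astype(np.int64)
    seg = complete & (a_all > 0) & (a_all < n)
    if not seg.any():
        raise ValueError("no segregating sites for bootstrap")
    chroms = gm.sites["chrom"].to_numpy()
    pos0 = gm.sites["pos"].to_numpy() - 1
    block_ids = []
    site_by_block: dict[tuple[str, int], np.ndarray] = {}
    for chrom in dict.fromkeys(chroms):
        on = np.where(chroms == chrom)[0]
        n_blocks = int(pos0[on].max() // block) + 1
        bidx = pos0[on] // block
        for b in range(n_blocks):
            key = (chrom, b)
            block_ids.append(key)
            site_by_block[key] = on[bidx == b]
    if target_sites is None:
        target_sites = int(seg.sum())
    rng = np.random.default_rng(seed)
    picked: list[np.ndarray] = []
    got = 0
    while got < target_sites:
        key = block_ids[int(rng.integers(len(block_ids)))]
        sites = site_by_block[key]
        picked.append(sites)
        got += int(seg[sites].sum())
    idx = np.concatenate(picked) if picked else np.array([], dtype=int)
    sub = subset_sites(gm, np.sort(idx))
    # re-sort not meaningful for a resample; tally directly instead
    comp = (sub.dosages[:, sub.sample_index(samples)] != MISSING).all(axis=1)
    a = sub.dosages[:, sub.sample_index(samples)][comp].sum(axis=1).astype(np.int64)
    if polarization == "folded":
        a = np.minimum(a, n - a)
        counts = np.bincount(a, minlength=n // 2 + 1)
    else:
        counts = np.bincount(a, minlength=n + 1)
    return SFS(n, counts, polarization, n_skipped=int((~comp).sum()))


def lineage_allele_freqs(gm: GenotypeMatrix, grouping: dict[str, list]) -> pd.DataFrame:
    """Per-site alternate-allele frequency a_j/n_j for each lineage; NaN
    where no copies are genotyped."""
    out = gm.sites[["chrom", "pos"]].copy()
    for lineage, samples in grouping.items():
        n, a = site_counts(gm, samples)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[lineage] = np.where(n > 0, a / np.maximum(n, 1), np.nan)
    return out


def write_sfs_dadi(sfs: SFS, path, label: str = "pop") -> None:
    """Single-population dadi-style SFS text: header then the count vector."""
    fold = "folded" if sfs.polarization == "folded" else "unfolded"
    with open(path, "w") as fh:
        fh.write(f"{len(sfs.counts)} {fold} \"{label}\"\n")
        fh.write(" ".join(str(int(c)) for c in sfs.counts) + "\n")
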
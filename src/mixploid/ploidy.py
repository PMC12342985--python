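"""Per-sample ploidy inference from three lines of sequencing evidence.

1.  Allele balance: at heterozygous biallelic sites the alt-read fraction
    concentrates near {1/2} in diploids and {1/4, 1/2, 3/4} in tetraploids.
    A Gaussian-mixture likelihood contest compares fixed-mean models against
    a free mixture.
2.  Heterozygosity: genotypes called as-if-diploid show a higher fraction of
    heterozygous sites in tetraploids.
3.  S-locus copy number: self-incompatibility alleles are hyper-diverse, so
    the number of distinct S-alleles per individual is bounded by ploidy;
    three or more distinct alleles, or a validated 3:1 coverage pattern over
    two alleles, require tetraploidy.

The three evidences combine into a final call of 2, 4 or "unsure".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("mixploid")

_LOG_2PI = math.log(2.0 * math.pi)

#: fixed component means of each ploidy model
FIXED_MEANS = {2: (0.5,), 3: (1.0 / 3.0, 2.0 / 3.0), 4: (0.25, 0.5, 0.75)}

#: default heterozygosity threshold separating 2x from 4x; midpoint between
#: the simulated diploid-outcrosser and tetraploid called-as-diploid means
HET_HI = 0.51


# ---------------------------------------------------------------------------
# allele balance
# ---------------------------------------------------------------------------

@dataclass
class AlleleBalanceSet:
    """Filtered per-sample alt-read fractions at biallelic sites."""

    fractions: dict[str, np.ndarray]
    min_depth: int
    bounds: tuple[float, float]
    kept: dict[str, int] = field(default_factory=dict)
    dropped: dict[str, int] = field(default_factory=dict)
    insufficient: set[str] = field(default_factory=set)


def extract_allele_balance(ad_table: pd.DataFrame, min_depth: int = 10,
                           bounds: tuple[float, float] = (0.1, 0.9),
                           min_sites: int = 20) -> AlleleBalanceSet:
    """Keep sites with depth >= min_depth and alt fraction strictly inside bounds.

    Samples retaining fewer than ``min_sites`` usable sites are flagged
    insufficient and excluded from mixture fitting.
    """
    if ad_table.empty:
        raise ValueError("empty allele-depth table")
    lo, hi = bounds
    out: dict[str, np.ndarray] = {}
    kept: dict[str, int] = {}
    dropped: dict[str, int] = {}
    insufficient: set[str] = set()
    for sample, grp in ad_table.groupby("sample", sort=True):
        depth = (grp["ref_reads"] + grp["alt_reads"]).to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = grp["alt_reads"].to_numpy(float) / depth
        ok = (depth >= min_depth) & (frac > lo) & (frac < hi)
        y = frac[ok]
        kept[sample] = int(ok.sum())
        dropped[sample] = int((~ok).sum())
        if len(y) < min_sites:
            insufficient.add(sample)
            logger.info("sample %s: only %d usable allele-balance sites, "
                        "flagged insufficient", sample, len(y))
        out[sample] = y
    return AlleleBalanceSet(out, min_depth, bounds, kept, dropped, insufficient)


# ---------------------------------------------------------------------------
# Gaussian mixture EM (shared sigma; fixed or free means)
# ---------------------------------------------------------------------------

def _log_normal(y: np.ndarray, means: np.ndarray, sigma: float) -> np.ndarray:
    z = (y[:, None] - means[None, :]) / sigma
    return -0.5 * z * z - math.log(sigma) - 0.5 * _LOG_2PI


def _em(y: np.ndarray, means: np.ndarray, weights: np.ndarray, *,
        free_means: bool, free_weights: bool, sigma: float | None = None,
        sigma_floor: float = 0.01, max_iter: int = 500,
        tol: float = 1e-8) -> dict:
    """EM for a 1-D Gaussian mixture with one shared standard deviation.

    The log-likelihood never decreases; convergence when the improvement
    drops below ``tol`` (or ``max_iter`` iterations, flagged).
    """
    y = np.asarray(y, float)
    n = len(y)
    means = np.array(means, float)
    weights = np.array(weights, float)
    weights /= weights.sum()
    if sigma is None:
        sigma = max(float(np.std(y)), sigma_floor)
    prev = -np.inf
    converged = False
    ll = prev
    for _ in range(max_iter):
        logp = _log_normal(y, means, sigma) + np.log(weights)[None, :]
        mx = logp.max(axis=1)
        lse = mx + np.log(np.exp(logp - mx[:, None]).sum(axis=1))
        ll = float(lse.sum())
        resp = np.exp(logp - lse[:, None])
        if ll - prev < tol and np.isfinite(prev):
            converged = True
            break
        prev = ll
        nk = resp.sum(axis=0)
        if free_weights:
            weights = nk / n
            weights = np.clip(weights, 1e-12, None)
            weights /= weights.sum()
        if free_means:
            means = (resp * y[:, None]).sum(axis=0) / np.clip(nk, 1e-12, None)
        var = (resp * (y[:, None] - means[None, :]) ** 2).sum() / n
        sigma = max(math.sqrt(max(var, 0.0)), sigma_floor)
    if not converged:
        logger.info("EM did not converge in %d iterations", max_iter)
    return {"logL": ll, "means": means, "weights": weights, "sigma": sigma,
            "converged": converged}


def fit_fixed_mixture(y: np.ndarray, model: int,
                      sigma_floor: float = 0.01) -> float:
    """Maximized log-likelihood of a fixed-mean ploidy model.

    Component means are fixed at the allele-balance expectations of the
    model (diploid {1/2}, triploid {1/3, 2/3}, tetraploid {1/4, 1/2, 3/4})
    with equal component weights; only the shared sigma is free.  Fixing the
    weights keeps the models non-nested, which is what makes the
    likelihood-ratio contest discriminative.
    """
    means = FIXED_MEANS[model]
    res = _em(np.asarray(y, float), means, np.full(len(means), 1.0 / len(means)),
              free_means=False, free_weights=False, sigma_floor=sigma_floor)
    return res["logL"]


def fit_free_mixture(y: np.ndarray, K: int = 3, seed: int | None = None,
                     n_restarts: int = 5, sigma_floor: float = 0.01) -> float:
    """Maximized log-likelihood of a free K-component mixture.

    Multi-start EM: the fixed-model means of every ploidy (padded/truncated
    to K components) plus random starts.  Because the fixed-model means are
    among the starting points, the free likelihood dominates every fixed
    model up to EM tolerance.
    """
    y = np.asarray(y, float)
    starts = []
    for model_means in FIXED_MEANS.values():
        m = list(model_means)
        while len(m) < K:
            m.append(0.5)
        starts.append(np.sort(np.array(m[:K])))
    rng = np.random.default_rng(seed)
    for _ in range(max(n_restarts - len(starts), 1)):
        starts.append(np.sort(rng.uniform(0.1, 0.9, size=K)))
    best = -np.inf
    for m0 in starts:
        res = _em(y, m0, np.full(K, 1.0 / K), free_means=True,
                  free_weights=True, sigma_floor=sigma_floor)
        best = max(best, res["logL"])
    return best


def classify_ploidy(y: np.ndarray, seed: int | None = None,
                    sigma_floor: float = 0.01) -> tuple[int, dict[int, float]]:
    """Likelihood-ratio contest: d_m = logL_free - logL_fixed(m).

    One free 3-component mixture is compared against each fixed model; the
    call is the model with the smallest delta, ties broken toward lower
    ploidy.  Deltas are >= -1e-6 by construction (EM monotonicity, free
    model multi-started from every fixed model's means).
    """
    y = np.asarray(y, float)
    free = fit_free_mixture(y, K=3, seed=seed, sigma_floor=sigma_floor)
    deltas = {m: free - fit_fixed_mixture(y, m, sigma_floor=sigma_floor)
              for m in (2, 3, 4)}
    call = min(sorted(deltas), key=lambda m: (deltas[m], m))
    return call, deltas


# ---------------------------------------------------------------------------
# heterozygosity (as-if-diploid calls)
# ---------------------------------------------------------------------------

def heterozygosity_proportion(gm_diploid) -> pd.Series:
    """Fraction of heterozygous (dosage 1) sites among called sites per sample.

    The input matrix must hold as-if-diploid calls (dosage in {0,1,2}).
    Samples with zero called sites get NaN.
    """
    dos = gm_diploid.dosages
    called = (dos >= 0).sum(axis=0)
    het = (dos == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(called > 0, het / np.maximum(called, 1), np.nan)
    return pd.Series(frac, index=gm_diploid.samples, name="het_proportion")


def diploid_calls_from_ad(ad_table: pd.DataFrame, min_depth: int = 8,
                          het_band: tuple[float, float] = (0.15, 0.85)):
    """Naive as-if-diploid genotypes from allele depths.

    Stand-in for a diploid-mode variant caller: alt fraction below the band
    -> 0, above -> 2, inside -> 1; depth < min_depth -> missing.  Returns a
    :class:`~mixploid.io.GenotypeMatrix` with all ploidies set to 2.
    """
    from mixploid.io import MISSING, GenotypeMatrix

    samples = sorted(ad_table["sample"].unique())
    sites = (ad_table[["chrom", "pos"]].drop_duplicates()
             .sort_values(["chrom", "pos"]).reset_index(drop=True))
    site_idx = {(c, p): j for j, (c, p) in enumerate(zip(sites["chrom"], sites["pos"]))}
    samp_idx = {s: i for i, s in enumerate(samples)}
    dos = np.full((len(sites), len(samples)), MISSING, dtype=np.int16)
    depth = (ad_table["ref_reads"] + ad_table["alt_reads"]).to_numpy()
    frac = np.where(depth > 0, ad_table["alt_reads"].to_numpy() / np.maximum(depth, 1), 0.0)
    lo, hi = het_band
    call = np.where(frac < lo, 0, np.where(frac > hi, 2, 1)).astype(np.int16)
    call[depth < min_depth] = MISSING
    rows = [site_idx[(c, p)] for c, p in zip(ad_table["chrom"], ad_table["pos"])]
    cols = [samp_idx[s] for s in ad_table["sample"]]
    dos[rows, cols] = call
    sites = sites.assign(ref="N", alt="N", qual=np.nan)
    return GenotypeMatrix(samples, np.full(len(samples), 2), sites, dos)


# ---------------------------------------------------------------------------
# S-locus copy counting
# ---------------------------------------------------------------------------

@dataclass
class SAlleleProfile:
    """Raw S-allele coverages for one individual plus control coverage.

    ``control`` is the coverage over unlinked single-copy-per-haplotype
    control regions, so control/ploidy estimates the per-copy coverage unit.
    """

    sample_id: str
    coverages: dict[str, float]
    control: float

    def normalized(self, ploidy_hypothesis: int) -> dict[str, float]:
        if self.control <= 0:
            raise ValueError(f"control coverage must be > 0 ({self.sample_id})")
        unit = self.control / ploidy_hypothesis
        return {a: c / unit for a, c in self.coverages.items()}


@dataclass
class SAlleleCall:
    n_distinct: int
    copies: list[int]          # final estimate, ordered as profile alleles
    raw_copies: list[int]      # plain rounding against the per-copy unit
    consistent: bool           # raw copies summed to the ploidy hypothesis
    ploidy_hypothesis: int


def count_s_alleles(profile: SAlleleProfile, ploidy_hypothesis: int,
                    detect_floor: float = 0.0) -> SAlleleCall:
    """Copy numbers per distinct S-allele under a ploidy hypothesis.

    Primary rule: copy_i = round(coverage_i / unit) with unit =
    control/ploidy, minimum 1 for any detected allele.  When the rounded
    copies do not sum to the hypothesis the call is flagged inconsistent and
    reconciled by largest-remainder proportional allocation of the ploidy
    across alleles (coverage proportions are insensitive to control noise).
    """
    if profile.control <= 0:
        raise ValueError(f"control coverage must be > 0 ({profile.sample_id})")
    alleles = [a for a, c in profile.coverages.items() if c > detect_floor]
    covs = np.array([profile.coverages[a] for a in alleles], float)
    unit = profile.control / ploidy_hypothesis
    raw = np.maximum(np.rint(covs / unit).astype(int), 1) if len(covs) else np.array([], int)
    consistent = int(raw.sum()) == ploidy_hypothesis
    if consistent or len(covs) == 0 or len(covs) > ploidy_hypothesis:
        copies = list(raw)
    else:
        exact = ploidy_hypothesis * covs / covs.sum()
        base = np.maximum(np.floor(exact).astype(int), 1)
        # largest remainders take the leftover copies (never below 1 each)
        leftover = ploidy_hypothesis - int(base.sum())
        order = np.argsort(-(exact - np.floor(exact)), kind="stable")
        k = 0
        while leftover > 0 and k < len(order):
            base[order[k]] += 1
            leftover -= 1
            k += 1
        while leftover < 0:  # floor+min-1 overshoot: trim largest copies
            j = int(np.argmax(base))
            if base[j] <= 1:
                break
            base[j] -= 1
            leftover += 1
        copies = list(base)
        logger.info("sample %s: raw S-allele copies %s sum to %d != %d, "
                    "reconciled to %s", profile.sample_id, list(raw),
                    int(raw.sum()), ploidy_hypothesis, copies)
    return SAlleleCall(len(alleles), copies, list(raw), consistent,
                       ploidy_hypothesis)


def _is_31_pattern(profile: SAlleleProfile) -> bool:
    """Two distinct alleles at 3:1 copies under the tetraploid hypothesis,
    with the diploid hypothesis inconsistent (rules out a noisy 1:1)."""
    call4 = count_s_alleles(profile, 4)
    if call4.n_distinct != 2 or sorted(call4.copies) != [1, 3]:
        return False
    call2 = count_s_alleles(profile, 2)
    return not call2.consistent


# ---------------------------------------------------------------------------
# evidence combination
# ---------------------------------------------------------------------------

def assign_ploidy(mixture_call: int | None, n_s_alleles: int | None,
                  het_proportion: float | None, pattern_31: bool = False,
                  het_hi: float = HET_HI) -> str:
    """Combine the three evidences into a final call of "2", "4" or "unsure".

    >= 3 distinct S-alleles (or a validated 3:1 pattern) is hard evidence
    for tetraploidy: it yields 4 unless another evidence votes diploid, in
    which case the conflict gives "unsure".  Otherwise the available
    mixture/heterozygosity votes must agree; <= 2 distinct S-alleles is weak
    support for 2 that cannot veto agreeing tetraploid evidence (low allele
    counts also occur in tetraploids).  Triploid mixture calls and NaN/None
    evidence are treated as unavailable.
    """
    m_vote = mixture_call if mixture_call in (2, 4) else None
    if het_proportion is None or (isinstance(het_proportion, float)
                                  and math.isnan(het_proportion)):
        h_vote = None
    else:
        h_vote = 4 if het_proportion > het_hi else 2
    hard4 = pattern_31 or (n_s_alleles is not None and n_s_alleles >= 3)
    if hard4:
        return "unsure" if 2 in (m_vote, h_vote) else "4"
    votes = [v for v in (m_vote, h_vote) if v is not None]
    if not votes:
        return "2" if n_s_alleles is not None and n_s_alleles <= 2 else "unsure"
    if all(v == 4 for v in votes):
        return "4"
    if all(v == 2 for v in votes):
        return "2"
    return "unsure"


@dataclass
class PloidyCall:
    sample_id: str
    mixture_call: int | None
    deltas: dict[int, float]
    het_proportion: float
    n_s_alleles: int | None
    s_copies: list[int] | None
    final_call: str


def infer_ploidy(ad_table: pd.DataFrame,
                 s_profiles: dict[str, SAlleleProfile] | None = None,
                 seed: int | None = None, het_hi: float = HET_HI,
                 min_depth: int = 10,
                 bounds: tuple[float, float] = (0.1, 0.9)) -> pd.DataFrame:
    """Full three-evidence ploidy inference for every sample in the AD table.

    Returns a tidy frame: sample, mixture_call, d2, d3, d4, het, n_s_alleles,
    copies, final_call.
    """
    balances = extract_allele_balance(ad_table, min_depth=min_depth, bounds=bounds)
    diploid_gm = diploid_calls_from_ad(ad_table)
    het = heterozygosity_proportion(diploid_gm)
    rows = []
    for sample in sorted(balances.fractions):
        if sample in balances.insufficient:
            mix, deltas = None, {2: np.nan, 3: np.nan, 4: np.nan}
        else:
            mix, deltas = classify_ploidy(balances.fractions[sample], seed=seed)
        n_s, copies, p31 = None, None, False
        if s_profiles and sample in s_profiles:
            prof = s_profiles[sample]
            call4 = count_s_alleles(prof, 4)
            n_s = call4.n_distinct
            p31 = _is_31_pattern(prof)
            # report copies under the hypothesis the final call supports
            copies = call4.copies
        h = float(het.get(sample, np.nan))
        final = assign_ploidy(mix, n_s, h, pattern_31=p31, het_hi=het_hi)
        if s_profiles and sample in s_profiles and final == "2":
            copies = count_s_alleles(s_profiles[sample], 2).copies
        rows.append({"sample": sample, "mixture_call": mix,
                     "d2": deltas[2], "d3": deltas[3], "d4": deltas[4],
                     "het": h, "n_s_alleles": n_s,
                     "copies": "" if copies is None else
                     ",".join(str(c) for c in copies),
                     "final_call": final})
    return pd.DataFrame(rows)


def read_s_coverage(path) -> dict[str, SAlleleProfile]:
    """Read a long-format S-locus coverage TSV.

    Columns: sample, allele, coverage, control (control repeated per row).
    """
    frame = pd.read_csv(path, sep="\t")
    out = {}
    for sample, grp in frame.groupby("sample", sort=True):
        out[sample] = SAlleleProfile(
            sample,
            dict(zip(grp["allele"].astype(str), grp["coverage"].astype(float))),
            float(grp["control"].iloc[0]))
    return out


def write_s_coverage(profiles: dict[str, SAlleleProfile], path) -> None:
    rows = []
    for sample in sorted(profiles):
        p = profiles[sample]
        for allele in sorted(p.coverages):
            rows.append((sample, allele, p.coverages[allele], p.control))
    pd.DataFrame(rows, columns=["sample", "allele", "coverage", "control"]) \
        .to_csv(path, sep="\t", index=False)
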
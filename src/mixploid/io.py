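"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions: VCF and GFF3 are 1-based closed, BED and all in-memory
window tables are 0-based half-open.  Conversion is centralized in
:func:`to_halfopen` / :func:`to_onebased`.

Genotypes are stored as integer alternate-allele dosages (0..ploidy) with
``MISSING = -1``; phasing separators ``/`` and ``|`` are treated identically.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger("mixploid")

#: sentinel for a missing dosage call
MISSING = -1

_VALID_SOURCES = {"herbarium", "live", "synthetic"}


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

def to_halfopen(start1: int, end1: int) -> tuple[int, int]:
    """1-based closed interval (VCF/GFF) -> 0-based half-open (BED)."""
    return start1 - 1, end1


def to_onebased(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open interval (BED) -> 1-based closed (VCF/GFF)."""
    return start0 + 1, end0


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

@dataclass
class SampleSheet:
    """Per-sample metadata: population, lineage, declared ploidy, source.

    ``declared_ploidy`` is 2 or 4, or 0 when unknown.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample", "population", "lineage", "ploidy", "source"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if self.frame["sample"].duplicated().any():
            dupes = self.frame.loc[self.frame["sample"].duplicated(), "sample"]
            raise ValueError(f"duplicate sample ids: {sorted(set(dupes))}")
        if (self.frame["population"].astype(str).str.len() == 0).any():
            raise ValueError("empty population labels in sample sheet")
        bad = set(self.frame["ploidy"]) - {0, 2, 4}
        if bad:
            raise ValueError(f"declared ploidy must be in {{0,2,4}}, got {sorted(bad)}")
        bad_src = set(self.frame["source"]) - _VALID_SOURCES
        if bad_src:
            raise ValueError(f"unknown sample sources: {sorted(bad_src)}")

    @property
    def samples(self) -> list[str]:
        return list(self.frame["sample"])

    def ploidy_of(self, sample: str) -> int:
        return int(self.frame.set_index("sample").loc[sample, "ploidy"])

    def population_of(self, sample: str) -> str:
        return str(self.frame.set_index("sample").loc[sample, "population"])

    def samples_in(self, population: str, column: str = "population") -> list[str]:
        return list(self.frame.loc[self.frame[column] == population, "sample"])


def read_sample_sheet(path) -> SampleSheet:
    frame = pd.read_csv(path, sep="\t", dtype={"sample": str, "population": str,
                                               "lineage": str, "source": str})
    frame["ploidy"] = frame["ploidy"].astype(int)
    return SampleSheet(frame)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Sites x samples dosage matrix with per-sample ploidy.

    ``sites`` has columns chrom, pos (1-based), ref, alt, qual; invariant
    sites carry alt ``"."``.  ``dosages`` holds alt-allele dosage in
    ``[0..ploidy]`` or ``MISSING``; ``depths`` (optional) per-genotype read
    depth.  Positions are strictly increasing within each chromosome and all
    records are biallelic.
    """

    samples: list[str]
    ploidies: np.ndarray
    sites: pd.DataFrame
    dosages: np.ndarray
    depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ploidies = np.asarray(self.ploidies, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        if self.dosages.shape != (len(self.sites), len(self.samples)):
            raise ValueError("dosage matrix shape does not match sites x samples")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.asarray([lookup[n] for n in names], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"sample {exc} not in matrix") from exc

    def validate(self) -> None:
        for _, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions not strictly increasing within chrom")
        called = self.dosages >= 0
        upper = np.broadcast_to(self.ploidies, self.dosages.shape)
        if np.any(self.dosages[called] > upper[called]):
            raise ValueError("dosage exceeds sample ploidy")
        if np.any(self.dosages < MISSING):
            raise ValueError("dosage below MISSING sentinel")

    def equals(self, other: "GenotypeMatrix") -> bool:
        if self.samples != other.samples:
            return False
        if not np.array_equal(self.ploidies, other.ploidies):
            return False
        if not np.array_equal(self.dosages, other.dosages):
            return False
        a, b = self.sites.reset_index(drop=True), other.sites.reset_index(drop=True)
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for col in a.columns:
            if col == "qual":
                if not np.allclose(a[col].astype(float), b[col].astype(float),
                                   equal_nan=True):
                    return False
            elif not (a[col] == b[col]).all():
                return False
        return True


def _dosage_from_gt(gt: tuple) -> int:
    if gt is None or len(gt) == 0 or any(a is None for a in gt):
        return MISSING
    return int(sum(1 for a in gt if a == 1))


def read_vcf(path, sample_sheet: SampleSheet) -> GenotypeMatrix:
    """Read a mixed-ploidy VCF into a :class:`GenotypeMatrix`.

    The GT arity of every called genotype must equal the sample's declared
    ploidy (``0/1/1/1`` for tetraploids); missing genotypes of any arity map
    to ``MISSING``.  Multi-allelic records are skipped and counted; invariant
    records (no ALT) are kept with alt ``"."``.
    """
    vcf = pysam.VariantFile(str(path))
    vcf_samples = list(vcf.header.samples)
    sheet_samples = sample_sheet.samples
    absent = [s for s in sheet_samples if s not in vcf_samples]
    if absent:
        raise ValueError(f"samples in sheet but not in VCF: {absent}")
    ploidies = np.array([sample_sheet.ploidy_of(s) for s in sheet_samples])

    rows, dosage_rows, depth_rows = [], [], []
    n_multi = 0
    any_depth = False
    for rec in vcf:
        alts = [a for a in (rec.alts or []) if a not in (None, ".")]
        if len(alts) > 1:
            n_multi += 1
            continue
        alt = alts[0] if alts else "."
        dos = np.empty(len(sheet_samples), dtype=np.int16)
        dep = np.full(len(sheet_samples), -1, dtype=np.int32)
        for i, s in enumerate(sheet_samples):
            call = rec.samples[s]
            gt = call.get("GT")
            d = _dosage_from_gt(gt)
            if d != MISSING and len(gt) != ploidies[i]:
                raise ValueError(
                    f"GT arity {len(gt)} conflicts with declared ploidy "
                    f"{ploidies[i]} for sample {s} at {rec.chrom}:{rec.pos}")
            dos[i] = d
            dp = call.get("DP")
            if dp is not None:
                dep[i] = int(dp)
                any_depth = True
        rows.append((rec.chrom, rec.pos, rec.ref, alt,
                     float(rec.qual) if rec.qual is not None else np.nan))
        dosage_rows.append(dos)
        depth_rows.append(dep)
    if n_multi:
        logger.info("read_vcf: skipped %d multi-allelic records", n_multi)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "qual"])
    dosages = (np.vstack(dosage_rows) if dosage_rows
               else np.empty((0, len(sheet_samples)), dtype=np.int16))
    depths = np.vstack(depth_rows) if (depth_rows and any_depth) else None
    gm = GenotypeMatrix(sheet_samples, ploidies, sites, dosages, depths)
    gm.validate()
    return gm


def read_allele_depths(path) -> pd.DataFrame:
    """Extract per-sample (ref_reads, alt_reads) from the AD field of a VCF.

    Returns a long DataFrame (sample, chrom, pos, ref_reads, alt_reads).
    Records without AD, or multi-allelic records, are skipped and counted.
    """
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    rows = []
    n_skipped = 0
    for rec in vcf:
        alts = [a for a in (rec.alts or []) if a not in (None, ".")]
        if len(alts) != 1:
            n_skipped += 1
            continue
        if "AD" not in rec.format:
            n_skipped += 1
            continue
        for s in samples:
            ad = rec.samples[s].get("AD")
            if ad is None or len(ad) < 2 or ad[0] is None or ad[1] is None:
                continue
            ref_n, alt_n = int(ad[0]), int(ad[1])
            if ref_n < 0 or alt_n < 0:
                raise ValueError(f"negative allele depth at {rec.chrom}:{rec.pos}")
            rows.append((s, rec.chrom, rec.pos, ref_n, alt_n))
    if n_skipped:
        logger.info("read_allele_depths: skipped %d records without usable AD",
                    n_skipped)
    if not rows:
        warnings.warn("no allele-depth records found", stacklevel=2)
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos",
                                       "ref_reads", "alt_reads"])


def _fmt_qual(q: float) -> str:
    if q is None or (isinstance(q, float) and np.isnan(q)):
        return "."
    return format(float(q), ".6g")


def write_vcf(gm: GenotypeMatrix, path, ad: np.ndarray | None = None,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a :class:`GenotypeMatrix` as a VCF 4.2 text file.

    ``ad``: optional (n_sites, n_samples, 2) ref/alt read counts; when given,
    AD and DP FORMAT fields are emitted.  Output is byte-deterministic.
    """
    chroms = list(dict.fromkeys(gm.sites["chrom"]))
    if contig_lengths is None:
        contig_lengths = {c: int(gm.sites.loc[gm.sites["chrom"] == c, "pos"].max())
                          for c in chroms}
    fmt_keys = "GT" if ad is None else "GT:AD:DP"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mixploid\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if ad is not None:
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                     'Description="Allelic depths">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,'
                     'Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        ploidies = gm.ploidies
        for j in range(gm.n_sites):
            chrom, pos, ref, alt, qual = gm.sites.iloc[j]
            cols = [str(chrom), str(int(pos)), ".", str(ref), str(alt),
                    _fmt_qual(qual), "PASS", ".", fmt_keys]
            for i in range(gm.n_samples):
                d, p = int(gm.dosages[j, i]), int(ploidies[i])
                if d == MISSING:
                    gt = "/".join(["."] * p)
                else:
                    gt = "/".join(["0"] * (p - d) + ["1"] * d)
                if ad is None:
                    cols.append(gt)
                else:
                    r, a = int(ad[j, i, 0]), int(ad[j, i, 1])
                    cols.append(f"{gt}:{r},{a}:{r + a}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# gene annotation (GFF3)
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """Gene models: per-gene interval plus CDS segments with phase.

    Both tables use GFF3 1-based closed coordinates.  ``genes`` columns:
    gene_id, chrom, start, end, strand.  ``cds`` columns: gene_id, start,
    end, phase.  Genes whose total CDS length is not divisible by 3 are
    listed in ``frame_warnings``.
    """

    genes: pd.DataFrame
    cds: pd.DataFrame
    frame_warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for gid, grp in self.cds.groupby("gene_id"):
            segs = sorted(zip(grp["start"], grp["end"]))
            for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping CDS segments in gene {gid}")
            total = sum(e - s + 1 for s, e in segs)
            if total % 3 != 0 and gid not in self.frame_warnings:
                self.frame_warnings.append(gid)

    def gene_intervals_halfopen(self) -> pd.DataFrame:
        """Genes as 0-based half-open intervals (gene_id, chrom, start, end)."""
        out = self.genes.copy()
        se = [to_halfopen(s, e) for s, e in zip(out["start"], out["end"])]
        out["start"] = [x[0] for x in se]
        out["end"] = [x[1] for x in se]
        return out[["gene_id", "chrom", "start", "end"]]

    def equals(self, other: "GeneAnnotation") -> bool:
        g1 = self.genes.sort_values("gene_id").reset_index(drop=True)
        g2 = other.genes.sort_values("gene_id").reset_index(drop=True)
        c1 = self.cds.sort_values(["gene_id", "start"]).reset_index(drop=True)
        c2 = other.cds.sort_values(["gene_id", "start"]).reset_index(drop=True)
        return g1.equals(g2) and c1.equals(c2)


def read_gff(path) -> GeneAnnotation:
    """Parse gene models (gene + CDS features) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    gene_rows, cds_rows = [], []
    for gene in db.features_of_type("gene"):
        gid = gene.id
        gene_rows.append((gid, gene.seqid, gene.start, gene.end, gene.strand))
        for cds in db.children(gene, featuretype="CDS", order_by="start"):
            phase = 0 if cds.frame in (None, ".") else int(cds.frame)
            cds_rows.append((gid, cds.start, cds.end, phase))
    genes = pd.DataFrame(gene_rows,
                         columns=["gene_id", "chrom", "start", "end", "strand"])
    cds = pd.DataFrame(cds_rows, columns=["gene_id", "start", "end", "phase"])
    return GeneAnnotation(genes, cds)


def write_gff(ann: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        cds_by_gene = dict(tuple(ann.cds.groupby("gene_id")))
        for row in ann.genes.itertuples(index=False):
            fh.write(f"{row.chrom}\tmixploid\tgene\t{row.start}\t{row.end}\t."
                     f"\t{row.strand}\t.\tID={row.gene_id}\n")
            fh.write(f"{row.chrom}\tmixploid\tmRNA\t{row.start}\t{row.end}\t."
                     f"\t{row.strand}\t.\tID={row.gene_id}.t1;"
                     f"Parent={row.gene_id}\n")
            for k, c in enumerate(cds_by_gene.get(row.gene_id,
                                                  pd.DataFrame()).itertuples(index=False)):
                fh.write(f"{row.chrom}\tmixploid\tCDS\t{c.start}\t{c.end}\t."
                         f"\t{row.strand}\t{c.phase}\tID={row.gene_id}.cds{k};"
                         f"Parent={row.gene_id}.t1\n")


# ---------------------------------------------------------------------------
# BED / newick / TSV
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read a BED file into (chrom, start, end[, name]); 0-based half-open."""
    rows = []
    n_cols = 3
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {ln}: {line!r}")
            try:
                rec = [parts[0], int(parts[1]), int(parts[2])]
            except ValueError as exc:
                raise ValueError(f"malformed BED line {ln}: {line!r}") from exc
            if len(parts) > 3:
                rec.append(parts[3])
                n_cols = 4
            rows.append(rec)
    cols = ["chrom", "start", "end", "name"][:n_cols]
    return pd.DataFrame([r[:n_cols] + [None] * (n_cols - len(r)) for r in rows],
                        columns=cols)


def write_bed(windows: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name"] if c in windows.columns]
    windows[cols].to_csv(path, sep="\t", index=False, header=False)


def read_newick(path) -> list[dendropy.Tree]:
    trees = dendropy.TreeList.get(path=str(path), schema="newick", preserve_underscores=True)
    return list(trees)


def write_newick(trees, path) -> None:
    """Write trees one-per-line; branch lengths kept only if any are present."""
    with open(path, "w") as fh:
        for t in trees:
            fh.write(newick_string(t) + "\n")


def newick_string(tree: dendropy.Tree) -> str:
    has_lengths = any(e.length is not None for e in tree.edges()
                      if e.head_node is not tree.seed_node)
    s = tree.as_string(schema="newick", suppress_rooting=True,
                       unquoted_underscores=True,
                       suppress_edge_lengths=not has_lengths)
    return s.strip()


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# flat key=value config
# ---------------------------------------------------------------------------

def parse_config(path) -> dict[str, str]:
    """Parse a flat ``key = value`` text config; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line {ln}: {line!r}")
            key, val = line.split("=", 1)
            out[key.strip()] = val.strip()
    return out
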
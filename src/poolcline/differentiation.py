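"""Per-SNP and per-gene differentiation: pi-based F_ST, exact
allele-frequency tests, empirical outlier tails, functional SNP
classification, cluster-fixed differences, and extraction of short
multi-SNP haplotype loci for coalescent migration analysis.

F_ST follows the heterozygosity decomposition used by Pool-seq sliding
scans: F_ST = (pi_total - pi_within) / pi_total with pi_within the
average of the two pools' unbiased per-site heterozygosities
h = (M/(M-1)) (1 - sum f^2) and pi_total the same quantity on the summed
counts.  Negative finite-sample values are clamped to 0; a fixed
difference gives exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneModels, SiteCountsTable, write_fasta


@dataclass(frozen=True)
class FstParams:
    min_minor_count: int = 4  # summed across pools
    snp_quantile: float = 0.995
    gene_quantile: float = 0.95
    family_alpha: float = 0.05
    promoter_length: int = 600
    gene_score: str = "max"  # max | mean over pairwise means

    def __post_init__(self) -> None:
        for q in (self.snp_quantile, self.gene_quantile):
            if not 0.0 < q < 1.0:
                raise ValueError("quantiles must lie in (0, 1)")
        if self.min_minor_count < 1:
            raise ValueError("min_minor_count must be >= 1")


def _het(counts: np.ndarray) -> np.ndarray:
    """Unbiased heterozygosity (M/(M-1))(1 - sum f^2) per row of base
    counts; 0 where coverage < 2."""
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    M = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f2 = (counts / M[:, None]) ** 2
        h = M / (M - 1.0) * (1.0 - f2.sum(axis=1))
    h[M < 2] = 0.0
    return h


def snp_fst(counts_pop1, counts_pop2) -> float:
    """Pairwise F_ST at a single site from two base-count vectors."""
    c1 = np.asarray(counts_pop1, dtype=np.int64)
    c2 = np.asarray(counts_pop2, dtype=np.int64)
    if c1.sum() == 0 or c2.sum() == 0:
        raise ValueError("all-zero counts: F_ST undefined")
    h1 = _het(c1)[0]
    h2 = _het(c2)[0]
    ht = _het(c1 + c2)[0]
    if ht <= 0:
        return 0.0
    return float(np.clip((ht - (h1 + h2) / 2.0) / ht, 0.0, 1.0))


def pairwise_fst_table(
    table: SiteCountsTable, params: FstParams | None = None
) -> pd.DataFrame:
    """All-pairs per-SNP F_ST.

    SNPs are sites with >= 2 alleles whose minor count summed across
    pools reaches ``min_minor_count``.  Returns one row per SNP with
    columns scaffold, position, major, minor and fst_{i}_{j} for every
    pool pair (0-based labels), values clamped to [0, 1].
    """
    params = params or FstParams()
    base = table.counts[:, :, :4]
    totals = base.sum(axis=1)  # (S, 4) summed across pools
    order = np.argsort(totals, axis=1)
    major = order[:, -1]
    minor = order[:, -2]
    minor_count = np.take_along_axis(totals, minor[:, None], axis=1)[:, 0]
    n_alleles = (totals > 0).sum(axis=1)
    is_snp = (n_alleles >= 2) & (minor_count >= params.min_minor_count)
    idx = np.where(is_snp)[0]
    P = table.n_pools
    data = {
        "scaffold": table.scaffold[idx],
        "position": table.position[idx],
        "major": np.array(["ATCG"[m] for m in major[idx]]),
        "minor": np.array(["ATCG"[m] for m in minor[idx]]),
    }
    sub = base[idx].astype(float)  # (S', P, 4)
    M = sub.sum(axis=2)  # (S', P)
    with np.errstate(divide="ignore", invalid="ignore"):
        f2 = (sub / M[:, :, None]) ** 2
        h = M / (M - 1.0) * (1.0 - f2.sum(axis=2))  # (S', P)
    h = np.where(M >= 2, h, 0.0)
    for i, j in combinations(range(P), 2):
        tot = sub[:, i, :] + sub[:, j, :]
        ht = _het(tot)
        hw = 0.5 * (h[:, i] + h[:, j])
        with np.errstate(divide="ignore", invalid="ignore"):
            fst = (ht - hw) / ht
        fst = np.where(ht > 0, fst, 0.0)
        data[f"fst_{i}_{j}"] = np.clip(fst, 0.0, 1.0)
    return pd.DataFrame(data)


def fst_columns(fst: pd.DataFrame) -> list[str]:
    return [c for c in fst.columns if c.startswith("fst_")]


def fisher_allele_test(count_table_2x2) -> float:
    """Two-sided Fisher exact p for a 2x2 allele-count table.

    Zero margins return p = 1 by convention with a warning.
    """
    t = np.asarray(count_table_2x2, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("zero margin: p = 1 by convention", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def bonferroni_threshold(family_alpha: float, n_tests: int) -> float:
    return family_alpha / n_tests


def empirical_outliers(values, q: float) -> tuple[float, np.ndarray]:
    """Type-7 empirical quantile threshold and indices of values >= it.

    Ties at the threshold are flagged inclusively, so a saturated
    distribution (many values at the maximum) can flag more than the
    nominal tail fraction.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if not finite.any():
        raise ValueError("need at least one finite value")
    thresh = float(np.quantile(values[finite], q, method="linear"))
    idx = np.where(finite & (values >= thresh))[0]
    return thresh, idx


def fisher_tests_for_snps(
    table: SiteCountsTable, fst: pd.DataFrame, rows: np.ndarray
) -> pd.DataFrame:
    """Fisher exact tests (major vs minor counts) for selected FstTable
    rows, all pool pairs.  Intended for inspection of outlier SNPs."""
    base = table.counts[:, :, :4]
    key = {(s, p): i for i, (s, p) in enumerate(zip(table.scaffold, table.position))}
    out = []
    allele_ix = {b: i for i, b in enumerate("ATCG")}
    P = table.n_pools
    for r in rows:
        rec = fst.iloc[int(r)]
        i0 = key[(rec.scaffold, rec.position)]
        mj, mn = allele_ix[rec.major], allele_ix[rec.minor]
        row = {"scaffold": rec.scaffold, "position": rec.position}
        for i, j in combinations(range(P), 2):
            tab = [
                [base[i0, i, mj], base[i0, i, mn]],
                [base[i0, j, mj], base[i0, j, mn]],
            ]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                row[f"p_{i}_{j}"] = fisher_allele_test(tab)
        out.append(row)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Gene-level summaries and SNP classification
# ---------------------------------------------------------------------------

def _snp_gene_map(
    scaffold: np.ndarray, position: np.ndarray, genes: GeneModels
) -> list[list[int]]:
    """For each gene (row order of genes.genes) the indices of SNPs inside
    its span."""
    out: list[list[int]] = []
    by_scaf: dict[str, np.ndarray] = {}
    for scaf in np.unique(scaffold):
        by_scaf[scaf] = np.where(scaffold == scaf)[0]
    for _, g in genes.genes.iterrows():
        idx = by_scaf.get(g.scaffold)
        if idx is None:
            out.append([])
            continue
        pos = position[idx]
        hit = idx[(pos >= g.start) & (pos <= g.end)]
        out.append(hit.tolist())
    return out


def gene_fst_summary(
    fst: pd.DataFrame, genes: GeneModels, params: FstParams | None = None
) -> tuple[pd.DataFrame, dict]:
    """Per-gene mean F_ST and top-tail flags.

    The per-gene score aggregates the per-pair means (``params.gene_score``:
    the maximum by default).  Returns (per-gene table, summary dict); the
    summary reports the percentage of gene-score outliers that are
    recovered by the gene list implied by SNP-level outliers.
    """
    params = params or FstParams()
    cols = fst_columns(fst)
    snp_map = _snp_gene_map(
        fst["scaffold"].to_numpy(), fst["position"].to_numpy(), genes
    )
    vals = fst[cols].to_numpy()
    rows = []
    for gi, (_, g) in enumerate(genes.genes.iterrows()):
        idx = snp_map[gi]
        if not idx:
            rows.append(dict(gene_id=g.gene_id, n_snps=0, score=np.nan))
            continue
        pair_means = vals[idx].mean(axis=0)
        score = pair_means.max() if params.gene_score == "max" else pair_means.mean()
        rows.append(dict(gene_id=g.gene_id, n_snps=len(idx), score=float(score)))
    per_gene = pd.DataFrame(rows)
    scored = per_gene.dropna(subset=["score"])
    summary: dict = {"n_genes_with_snps": int(len(scored))}
    if len(scored):
        thresh, out_idx = empirical_outliers(
            scored["score"].to_numpy(), params.gene_quantile
        )
        flagged = set(scored.iloc[out_idx].gene_id)
        per_gene["outlier"] = per_gene.gene_id.isin(flagged)
        summary["gene_threshold"] = thresh
        summary["n_gene_outliers"] = len(flagged)
        # gene list implied by SNP-level outliers (pooled across pairs)
        pooled = vals.ravel()
        snp_thresh, _ = empirical_outliers(pooled, params.snp_quantile)
        snp_out = (vals >= snp_thresh).any(axis=1)
        genes_by_snp = {
            genes.genes.iloc[gi].gene_id
            for gi, idx in enumerate(snp_map)
            if idx and snp_out[idx].any()
        }
        summary["snp_threshold"] = float(snp_thresh)
        summary["n_genes_by_snp_outliers"] = len(genes_by_snp)
        if flagged:
            summary["pct_gene_outliers_recovered"] = round(
                100.0 * len(flagged & genes_by_snp) / len(flagged), 1
            )
    else:
        per_gene["outlier"] = False
    return per_gene, summary


def classify_snps(
    scaffold: np.ndarray,
    position: np.ndarray,
    genes: GeneModels,
    promoter_length: int = 600,
) -> pd.DataFrame:
    """Assign each SNP one top-level class (genic/intergenic) and a
    subclass.

    Genic SNPs are exonic/coding/intronic (a SNP in any overlapping
    gene's exon is exonic; exonic-and-CDS is "coding"; genic beats
    promoter).  Intergenic SNPs within ``promoter_length`` bp upstream of
    a gene start, strand-aware, are flagged as promoter.
    """
    scaffold = np.asarray(scaffold)
    position = np.asarray(position)
    n = len(position)
    top = np.full(n, "intergenic", dtype=object)
    sub = np.full(n, "", dtype=object)
    promoter = np.zeros(n, dtype=bool)
    for scaf in np.unique(scaffold):
        sidx = np.where(scaffold == scaf)[0]
        pos = position[sidx]
        for _, g in genes.genes[genes.genes.scaffold == scaf].iterrows():
            inside = sidx[(pos >= g.start) & (pos <= g.end)]
            if len(inside):
                top[inside] = "genic"
                exons = genes.exons.get(g.gene_id, [])
                cds = genes.cds.get(g.gene_id, [])
                for i in inside:
                    p = position[i]
                    in_exon = any(s <= p <= e for s, e in exons)
                    in_cds = any(s <= p <= e for s, e in cds)
                    klass = "coding" if in_cds else ("exonic" if in_exon else "intronic")
                    # coding > exonic > intronic across overlapping genes
                    rank = {"coding": 2, "exonic": 1, "intronic": 0, "": -1}
                    if rank[klass] > rank[sub[i]]:
                        sub[i] = klass
            if g.strand == "+":
                up = sidx[(pos >= g.start - promoter_length) & (pos < g.start)]
            else:
                up = sidx[(pos > g.end) & (pos <= g.end + promoter_length)]
            promoter[up] = True
    promoter[top == "genic"] = False  # genic beats promoter
    return pd.DataFrame(
        {
            "scaffold": scaffold,
            "position": position,
            "top": top,
            "subclass": sub,
            "promoter": promoter,
        }
    )


def classification_summary(classes: pd.DataFrame) -> dict:
    """Count matrix mirroring a genic/intergenic feature table; checks
    genic + intergenic = total."""
    genic = int((classes.top == "genic").sum())
    inter = int((classes.top == "intergenic").sum())
    out = {
        "GENIC": genic,
        "exon": int(((classes.top == "genic")
                     & classes.subclass.isin(["exonic", "coding"])).sum()),
        "CDS": int((classes.subclass == "coding").sum()),
        "intron": int((classes.subclass == "intronic").sum()),
        "INTERGENIC": inter,
        "promoters": int(classes.promoter.sum()),
        "total": len(classes),
    }
    assert out["GENIC"] + out["INTERGENIC"] == out["total"]
    return out


def fixed_between_clusters(
    table: SiteCountsTable,
    cluster_a: tuple,
    cluster_b: tuple,
    min_count: int = 4,
) -> np.ndarray:
    """Indices of SNPs differentially fixed between two pool clusters.

    Alleles with per-pool count below ``min_count`` are treated as
    sub-threshold noise before testing fixation (filter-then-test), so a
    singleton sequencing error does not break fixation.  Returns row
    indices into ``table``.
    """
    a, b = set(cluster_a), set(cluster_b)
    if not a or not b or a & b:
        raise ValueError("clusters must be disjoint and non-empty")
    base = table.counts[:, :, :4]
    filt = np.where(base >= min_count, base, 0)
    fixed_allele = np.full((len(table), table.n_pools), -1, dtype=np.int64)
    pos = filt > 0
    one_allele = pos.sum(axis=2) == 1
    fixed_allele[one_allele] = np.argmax(pos, axis=2)[one_allele]
    ia, ib = sorted(a), sorted(b)
    fa = fixed_allele[:, ia]
    fb = fixed_allele[:, ib]
    ok_a = (fa >= 0).all(axis=1) & (fa == fa[:, :1]).all(axis=1)
    ok_b = (fb >= 0).all(axis=1) & (fb == fb[:, :1]).all(axis=1)
    diff = fa[:, 0] != fb[:, 0]
    return np.where(ok_a & ok_b & diff)[0]


# ---------------------------------------------------------------------------
# Haplotype locus extraction
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeLocusSet:
    """Short multi-SNP loci with per-population sampled haplotypes."""

    loci: list = field(default_factory=list)  # dicts per locus
    manifest: dict = field(default_factory=dict)

    def to_fasta(self, path) -> None:
        records = []
        for loc in self.loci:
            for pop, seqs in loc["haplotypes"].items():
                for r, s in enumerate(seqs, 1):
                    header = (
                        f"{loc['locus_id']}|{loc['scaffold']}|"
                        f"{loc['start']}-{loc['end']}|{pop}|{r}"
                    )
                    records.append((header, s))
        write_fasta(records, path)


def _candidate_region(positions: np.ndarray, max_span: int = 90,
                      min_snps: int = 3, min_len: int = 20):
    """Leftmost run of >= min_snps SNPs spanning < max_span and >= min_len
    bp on one scaffold; returns (start0, end0) half-open or None."""
    pos = np.sort(positions)
    n = len(pos)
    j = 0
    for i in range(n):
        if j < i:
            j = i
        while j + 1 < n and pos[j + 1] - pos[i] + 1 < max_span:
            j += 1
        if j - i + 1 >= min_snps:
            span = int(pos[j] - pos[i] + 1)
            if span >= min_len:
                return int(pos[i] - 1), int(pos[j])  # 0-based half-open
    return None


def extract_haplotype_loci(
    reads: pd.DataFrame,
    snps: pd.DataFrame,
    n_haplotypes: int = 20,
    min_coverage: int = 15,
    max_coverage: int = 100,
    max_span: int = 90,
    min_snps: int = 3,
    min_length: int = 20,
    seed: int = 0,
) -> HaplotypeLocusSet:
    """Extract per-population haplotype alignments at short SNP-dense loci.

    Candidate regions contain >= ``min_snps`` SNPs within < ``max_span``
    bp and span >= ``min_length`` bp; only the leftmost qualifying region
    per scaffold is retained.  Reads fully spanning the region are
    collected per population; a locus is dropped (with a logged reason)
    unless every population's spanning coverage lies within
    [min_coverage, max_coverage] and allows sampling ``n_haplotypes``
    sequences.  The manifest reports n_loci, total bp and the total
    sequence count (= n_haplotypes x n_populations x n_loci).
    """
    rng = np.random.default_rng(seed)
    pops = sorted(reads.population.unique())
    loci = []
    dropped: dict[str, str] = {}
    total_bp = 0
    for scaf, snp_grp in snps.groupby("scaffold", sort=True):
        region = _candidate_region(
            snp_grp.position.to_numpy(), max_span, min_snps, min_length
        )
        if region is None:
            continue
        start0, end0 = region
        scaf_reads = reads[reads.scaffold == scaf]
        per_pop: dict[str, list[str]] = {}
        reason = None
        for pop in pops:
            rr = scaf_reads[scaf_reads.population == pop]
            seq_len = rr.sequence.str.len()
            spanning = rr[(rr.start <= start0) & (rr.start + seq_len >= end0)]
            cov = len(spanning)
            if cov < max(min_coverage, n_haplotypes):
                reason = f"{pop}: {cov} spanning reads < required"
                break
            if cov > max_coverage:
                reason = f"{pop}: coverage {cov} > {max_coverage}"
                break
            take = rng.choice(len(spanning), size=n_haplotypes, replace=False)
            rows = spanning.iloc[take]
            per_pop[pop] = [
                r.sequence[start0 - r.start : end0 - r.start]
                for r in rows.itertuples()
            ]
        if reason is not None:
            dropped[scaf] = reason
            continue
        loci.append(
            dict(
                locus_id=f"locus{len(loci) + 1:03d}",
                scaffold=scaf,
                start=start0,
                end=end0,
                snp_positions=sorted(
                    int(p) for p in snp_grp.position
                    if start0 < p <= end0
                ),
                haplotypes=per_pop,
            )
        )
        total_bp += end0 - start0
    manifest = dict(
        n_loci=len(loci),
        total_bp=total_bp,
        n_populations=len(pops),
        n_sequences=n_haplotypes * len(pops) * len(loci),
        dropped=dropped,
    )
    return HaplotypeLocusSet(loci, manifest)
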
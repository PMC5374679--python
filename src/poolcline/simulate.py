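"""Synthetic Pool-seq datasets with the statistical structure of a
two-cluster altitudinal cline.

The generator emulates a study design of six population pools of 100
haploid individuals sequenced at ~90x each: two diverged genetic clusters
(pools 1-4 vs pool 6), one admixed pool (pool 5), and a minority of loci
whose allele frequencies track an altitude-like environmental gradient.

Allele frequencies follow a hierarchical Balding-Nichols model: an
ancestral frequency p0 ~ Uniform(0.05, 0.95), cluster frequencies drawn
Beta-distributed around p0 with drift parameter ``f_div``, pool
frequencies drawn around their cluster frequency with ``f_pop``, and the
admixed pool's base frequency a ``admix_lambda`` mixture of the two
cluster frequencies.  Selected loci add ``beta_env * env`` on the logit
scale.  Pooled read counts arise from two sampling stages: binomial
sampling of the pool's individuals, then binomial read sampling at
Poisson coverage with a per-base error rate.

A separate harness, :func:`simulate_neutral_windows`, draws genealogies
under the standard neutral coalescent (via msprime, no intra-window
recombination) to validate the window diversity estimators against a
known per-site theta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import msprime
import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import (
    GeneModels,
    OntologyGraph,
    SiteCountsTable,
    write_env_table,
    write_gene2go,
    write_gff3,
    write_obo,
    write_sync,
)

BASES = np.array(["A", "T", "C", "G"])

#: Station elevations (m a.s.l.) of the six default sampling sites.
DEFAULT_ALTITUDES = (176.0, 297.0, 588.0, 842.0, 1125.0, 1303.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the gradient experiment generator.

    Defaults reproduce the study design: 6 pools of 100 haploid
    individuals at mean coverage 90, clusters {1..4} vs {6} with pool 5
    admixed 50:50, 1% of loci under an altitude-linked selection with a
    logit-scale effect of 3 per standard deviation of altitude.
    """

    n_pools: int = 6
    pool_size: int = 100
    mean_coverage: float = 90.0
    error_rate: float = 0.002
    n_scaffolds: int = 200
    mean_scaffold_length: int = 10_000
    n_snps: int = 50_000
    cluster_a: tuple = (0, 1, 2, 3)
    cluster_c: tuple = (5,)
    admixed: tuple = (4,)
    f_div: float = 0.1
    f_pop: float = 0.02
    admix_lambda: float = 0.5
    selected_fraction: float = 0.01
    beta_env: float = 3.0
    altitudes: tuple = DEFAULT_ALTITUDES
    n_bioclim: int = 19
    env_noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        for name in ("f_div", "f_pop"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        for name in ("admix_lambda", "selected_fraction", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if len(self.altitudes) != self.n_pools:
            raise ValueError("need one altitude per pool")
        pools = set(self.cluster_a) | set(self.cluster_c) | set(self.admixed)
        if pools != set(range(self.n_pools)):
            raise ValueError("cluster assignment must partition the pools")
        if self.selected_fraction > 0 and (self.f_div == 0 and self.f_pop == 0):
            warnings.warn(
                "selected loci requested with zero drift; clines will be the "
                "only signal",
                stacklevel=2,
            )

    def env_scores(self) -> np.ndarray:
        """Standardized altitude scalar per pool (zero mean, unit sd)."""
        alt = np.asarray(self.altitudes, dtype=float)
        return (alt - alt.mean()) / alt.std()


@dataclass
class SyntheticDataset:
    """Bundle of everything the downstream pipeline consumes, plus truth."""

    table: SiteCountsTable
    truth: pd.DataFrame  # one row per emitted SNP
    truth_freqs: np.ndarray  # (n_snps, n_pools) post-selection pool frequencies
    gene_models: GeneModels | None
    ontology: OntologyGraph | None
    env: pd.DataFrame | None
    window_truth: pd.DataFrame | None
    config: SimulationConfig

    def write(self, outdir) -> None:
        """Emit sync/GFF3/OBO/gene2go/env/truth files under ``outdir``."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_sync(self.table, out / "counts.sync")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        if self.gene_models is not None:
            write_gff3(self.gene_models, out / "genes.gff3")
        if self.ontology is not None:
            write_obo(self.ontology.graph, out / "ontology.obo")
            write_gene2go(self.ontology.annotations, out / "gene2go.tsv")
        if self.env is not None:
            write_env_table(self.env, out / "env.tsv")
        if self.window_truth is not None:
            self.window_truth.to_csv(out / "window_truth.tsv", sep="\t", index=False)


def _stream(seed: int, stage: int) -> np.random.Generator:
    """Independent per-stage RNG stream derived from the master seed."""
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, stage))))


def _balding_nichols(
    rng: np.random.Generator, p: np.ndarray, f: float
) -> np.ndarray:
    """Beta draw with mean p and variance f*p*(1-p); identity for f = 0."""
    if f == 0.0:
        return np.array(p, copy=True)
    scale = (1.0 - f) / f
    a = np.clip(p * scale, 1e-9, None)
    b = np.clip((1.0 - p) * scale, 1e-9, None)
    return rng.beta(a, b)


def pool_reads_from_frequencies(
    freqs: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    ref_idx: np.ndarray,
    alt_idx: np.ndarray,
    pool_sampling: bool = True,
) -> np.ndarray:
    """Two-stage pooled sequencing noise model.

    ``freqs`` is (n_snps, n_pools) of focal (alt) allele frequencies.
    Stage 1 draws the alt-allele count among ``pool_size`` individuals;
    stage 2 draws reads at Poisson coverage from the realized pool
    frequency; sequencing errors substitute a uniformly chosen other base
    at rate ``error_rate``.  Returns counts with shape
    (n_snps, n_pools, 6) in sync column order.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim == 1:
        freqs = freqs[None, :]
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    S, P = freqs.shape
    n = config.pool_size
    if pool_sampling:
        pool_counts = rng.binomial(n, freqs)
        read_freq = pool_counts / n
    else:
        read_freq = freqs
    coverage = rng.poisson(config.mean_coverage, size=(S, P))
    alt_reads = rng.binomial(coverage, read_freq)
    ref_reads = coverage - alt_reads
    counts = np.zeros((S, P, 6), dtype=np.int64)
    e = config.error_rate
    if e > 0:
        err_alt = rng.binomial(alt_reads, e)
        err_ref = rng.binomial(ref_reads, e)
        alt_reads = alt_reads - err_alt
        ref_reads = ref_reads - err_ref
    s_ix = np.arange(S)[:, None]
    p_ix = np.arange(P)[None, :]
    np.add.at(counts, (s_ix, p_ix, ref_idx[:, None]), ref_reads)
    np.add.at(counts, (s_ix, p_ix, alt_idx[:, None]), alt_reads)
    if e > 0:
        third = np.full(3, 1.0 / 3.0)
        for reads_err, focal in ((err_ref, ref_idx), (err_alt, alt_idx)):
            if reads_err.sum() == 0:
                continue
            split = rng.multinomial(reads_err, third)  # (S, P, 3)
            others = np.array(
                [[b for b in range(4) if b != fi] for fi in focal]
            )  # (S, 3)
            for j in range(3):
                np.add.at(counts, (s_ix, p_ix, others[:, j][:, None]), split[:, :, j])
    return counts


def _scaffold_layout(config: SimulationConfig, rng: np.random.Generator):
    """Scaffold names and lengths (gamma-distributed, mean as configured)."""
    shape = 4.0
    lengths = rng.gamma(shape, config.mean_scaffold_length / shape, config.n_scaffolds)
    lengths = np.maximum(np.round(lengths).astype(np.int64), 2000)
    names = [f"sc{i + 1:04d}" for i in range(config.n_scaffolds)]
    return names, lengths


def _synthetic_gene_models(names, lengths) -> GeneModels:
    """Uniform gene models: one 3-kb gene per 5 kb, two exons, CDS = exons."""
    rows, exons, cds = [], {}, {}
    k = 0
    for scaf, L in zip(names, lengths):
        start = 1001
        strand_flip = 0
        while start + 2999 <= L:
            gid = f"g{k + 1:05d}"
            strand = "+" if strand_flip % 2 == 0 else "-"
            rows.append(
                dict(gene_id=gid, scaffold=scaf, strand=strand, start=start,
                     end=start + 2999)
            )
            exons[gid] = [(start, start + 1199), (start + 1800, start + 2999)]
            cds[gid] = list(exons[gid])
            k += 1
            strand_flip += 1
            start += 5000
    genes = pd.DataFrame(rows, columns=["gene_id", "scaffold", "strand", "start", "end"])
    return GeneModels(genes, exons, cds)


def _synthetic_ontology(gene_ids, rng: np.random.Generator) -> OntologyGraph:
    """Three-level is_a DAG (1 root, 5 mid terms, 20 leaves incl. a diamond)
    with genes annotated to leaves."""
    g = nx.DiGraph()
    root = "GO:0000001"
    g.add_node(root, name="root", namespace="biological_process")
    mids = [f"GO:00001{i:02d}" for i in range(5)]
    for m in mids:
        g.add_node(m, name=f"mid {m}", namespace="biological_process")
        g.add_edge(m, root)
    leaves = [f"GO:00002{i:02d}" for i in range(20)]
    for i, t in enumerate(leaves):
        g.add_node(t, name=f"leaf {t}", namespace="biological_process")
        g.add_edge(t, mids[i % 5])
        if i % 4 == 0:  # diamond: two parents
            g.add_edge(t, mids[(i + 1) % 5])
    ann: dict[str, set] = {}
    for gid in gene_ids:
        if rng.random() < 0.7:
            k = rng.integers(1, 4)
            ann[gid] = set(rng.choice(leaves, size=k, replace=False))
    return OntologyGraph(g, ann)


def _synthetic_env_table(config: SimulationConfig, rng: np.random.Generator):
    """Elevation plus 19 bioclim covariates, all near-linear in altitude."""
    alt_z = config.env_scores()
    cols = {"elevation_m": np.asarray(config.altitudes, dtype=float)}
    for j in range(config.n_bioclim):
        sign = -1.0 if j % 2 else 1.0
        coef = sign * rng.uniform(0.8, 1.2)
        cols[f"bio{j + 1}"] = coef * alt_z + rng.normal(0, config.env_noise_sd,
                                                        config.n_pools)
    idx = pd.Index([f"pop{i + 1}" for i in range(config.n_pools)], name="population")
    return pd.DataFrame(cols, index=idx)


def simulate_gradient_experiment(config: SimulationConfig) -> SyntheticDataset:
    """Draw a full synthetic cline dataset under ``config``.

    Deterministic for a fixed seed (integer-state PCG64 streams only).
    """
    rng_layout = _stream(config.seed, 0)
    rng_freq = _stream(config.seed, 1)
    rng_counts = _stream(config.seed, 2)
    rng_annot = _stream(config.seed, 3)
    rng_env = _stream(config.seed, 4)

    names, lengths = _scaffold_layout(config, rng_layout)
    cum = np.concatenate([[0], np.cumsum(lengths)])
    genome = int(cum[-1])
    n_snps = min(config.n_snps, genome)
    coords = np.sort(rng_layout.choice(genome, size=n_snps, replace=False))
    scaf_idx = np.searchsorted(cum, coords, side="right") - 1
    positions = coords - cum[scaf_idx] + 1  # 1-based within scaffold

    env = config.env_scores()
    S, P = n_snps, config.n_pools
    p0 = rng_freq.uniform(0.05, 0.95, S)
    p_a = _balding_nichols(rng_freq, p0, config.f_div)
    p_c = _balding_nichols(rng_freq, p0, config.f_div)
    freqs = np.empty((S, P))
    for k in range(P):
        if k in config.cluster_a:
            base = p_a
        elif k in config.cluster_c:
            base = p_c
        else:
            base = config.admix_lambda * p_a + (1 - config.admix_lambda) * p_c
        freqs[:, k] = _balding_nichols(rng_freq, base, config.f_pop)
    selected = rng_freq.random(S) < config.selected_fraction
    if selected.any() and config.beta_env != 0.0:
        shift = config.beta_env * env[None, :]
        sub = np.clip(freqs[selected], 1e-6, 1 - 1e-6)
        freqs[selected] = expit(logit(sub) + shift)

    ref_idx = rng_counts.integers(0, 4, S)
    alt_off = rng_counts.integers(1, 4, S)
    alt_idx = (ref_idx + alt_off) % 4
    counts = pool_reads_from_frequencies(freqs, config, rng_counts, ref_idx, alt_idx)

    scaffolds = np.asarray([names[i] for i in scaf_idx], dtype=object)
    table = SiteCountsTable(
        scaffolds, positions, np.asarray(BASES[ref_idx], dtype=object), counts
    )
    truth = pd.DataFrame(
        {
            "scaffold": scaffolds,
            "position": positions,
            "ref": BASES[ref_idx],
            "alt": BASES[alt_idx],
            "p0": p0,
            "selected": selected,
        }
    )
    models = _synthetic_gene_models(names, lengths)
    ontology = _synthetic_ontology(list(models.genes.gene_id), rng_annot)
    env_table = _synthetic_env_table(config, rng_env)
    return SyntheticDataset(
        table=table,
        truth=truth,
        truth_freqs=freqs,
        gene_models=models,
        ontology=ontology,
        env=env_table,
        window_truth=None,
        config=config,
    )


def simulate_neutral_windows(
    theta_per_site: float,
    n_windows: int,
    window_length: int,
    sample_size: int,
    config: SimulationConfig | None = None,
) -> SyntheticDataset:
    """Independent neutral coalescent windows pooled into read counts.

    Per window a genealogy for ``sample_size`` lineages is drawn under the
    standard coalescent (no recombination within the window), mutations
    are placed with rate ``theta_per_site / 2`` per unit coalescent-scaled
    branch length at continuous (infinite-sites-style) positions, and the
    sample haplotypes are pooled into read counts.  The sampled lineages
    themselves constitute the pool, so E[S] = theta * a_{n-1} * L exactly.
    Each window is emitted on its own scaffold; only segregating sites
    appear in the table (remaining sites are monomorphic).
    """
    if theta_per_site < 0:
        raise ValueError("theta_per_site must be non-negative")
    if config is None:
        config = SimulationConfig(
            n_pools=1, altitudes=(0.0,), cluster_a=(0,), cluster_c=(), admixed=(),
        )
    if sample_size > config.pool_size:
        raise ValueError("sample_size must not exceed the pool size")
    rng = _stream(config.seed, 7)
    scaffolds, positions, freq_rows = [], [], []
    names, thetas, s_true = [], [], []
    for w in range(n_windows):
        name = f"win{w + 1:05d}"
        names.append(name)
        thetas.append(theta_per_site)
        if theta_per_site == 0:
            s_true.append(0)
            continue
        seed_anc = int(rng.integers(1, 2**31 - 1))
        seed_mut = int(rng.integers(1, 2**31 - 1))
        ts = msprime.sim_ancestry(
            samples=sample_size,
            ploidy=1,
            population_size=1.0,
            sequence_length=window_length,
            random_seed=seed_anc,
        )
        mts = msprime.sim_mutations(
            ts,
            rate=theta_per_site / 2.0,
            random_seed=seed_mut,
            discrete_genome=False,
        )
        gm = mts.genotype_matrix()  # (S, n); alleles 0/1...
        if gm.size == 0:
            s_true.append(0)
            continue
        derived = (gm > 0).sum(axis=1)
        seg = (derived > 0) & (derived < sample_size)
        gm = gm[seg]
        pos = np.floor([s.position for s in mts.sites()]).astype(np.int64)[seg] + 1
        for i in range(1, len(pos)):  # resolve integer collisions
            if pos[i] <= pos[i - 1]:
                pos[i] = pos[i - 1] + 1
        freqs = (gm > 0).sum(axis=1) / sample_size
        s_true.append(len(freqs))
        scaffolds.extend([name] * len(freqs))
        positions.extend(pos.tolist())
        freq_rows.append(freqs)
    if freq_rows:
        f = np.concatenate(freq_rows)[:, None]
        S = len(f)
        ref_idx = np.zeros(S, dtype=np.int64)
        alt_idx = np.ones(S, dtype=np.int64)
        # the coalescent sample is the pool: read sampling only
        counts = pool_reads_from_frequencies(
            f, config, rng, ref_idx, alt_idx, pool_sampling=False
        )
        table = SiteCountsTable(
            np.asarray(scaffolds, dtype=object),
            np.asarray(positions, dtype=np.int64),
            np.asarray(BASES[ref_idx], dtype=object),
            counts,
        )
        truth = pd.DataFrame(
            {
                "scaffold": scaffolds,
                "position": positions,
                "p_sample": f[:, 0],
            }
        )
        truth_freqs = f
    else:
        table = SiteCountsTable.empty(config.n_pools)
        truth = pd.DataFrame(columns=["scaffold", "position", "p_sample"])
        truth_freqs = np.empty((0, config.n_pools))
    window_truth = pd.DataFrame(
        {
            "scaffold": names,
            "length": window_length,
            "theta_true": thetas,
            "n_segregating": s_true,
        }
    )
    return SyntheticDataset(
        table=table,
        truth=truth,
        truth_freqs=truth_freqs,
        gene_models=None,
        ontology=None,
        env=None,
        window_truth=window_truth,
        config=config,
    )


def simulate_haplotype_reads(
    n_loci: int,
    config: SimulationConfig,
    reads_per_pool: int = 30,
    n_snps_per_locus: int = 4,
    read_length: int = 80,
):
    """Synthetic read table with one short SNP-dense region per scaffold.

    Returns ``(reads_df, snp_df)`` shaped for
    :func:`poolcline.differentiation.extract_haplotype_loci`: each locus
    sits on its own scaffold, carries ``n_snps_per_locus`` SNPs spanning
    <90 bp, and every population contributes ``reads_per_pool`` fully
    spanning reads drawn from two locus haplotypes.
    """
    if not 15 <= reads_per_pool <= 100:
        raise ValueError("reads_per_pool must respect the 15-100x coverage window")
    rng = _stream(config.seed, 8)
    reads_rows, snp_rows = [], []
    pops = [f"pop{k + 1}" for k in range(config.n_pools)]
    for loc in range(n_loci):
        scaf = f"hap{loc + 1:04d}"
        region_start0 = 100  # 0-based
        snp_offsets = np.arange(n_snps_per_locus) * 20  # span 61 bp for 4 SNPs
        snp_pos0 = region_start0 + snp_offsets
        span = int(snp_pos0[-1] - snp_pos0[0] + 1)
        backbone = rng.choice(BASES, size=region_start0 + read_length + span + 60)
        hap_alleles = np.stack(
            [
                rng.choice(BASES, size=n_snps_per_locus),
                rng.choice(BASES, size=n_snps_per_locus),
            ]
        )
        while np.all(hap_alleles[0] == hap_alleles[1]):
            hap_alleles[1] = rng.choice(BASES, size=n_snps_per_locus)
        for p in snp_pos0:
            snp_rows.append(dict(scaffold=scaf, position=int(p) + 1))
        for k, pop in enumerate(pops):
            mix = rng.uniform(0.2, 0.8)
            for _ in range(reads_per_pool):
                start0 = region_start0 - int(rng.integers(0, 10))
                length = max(read_length, span + (region_start0 - start0) + 5)
                seq = backbone[start0 : start0 + length].copy()
                hap = 0 if rng.random() < mix else 1
                for j, p0_ in enumerate(snp_pos0):
                    seq[p0_ - start0] = hap_alleles[hap, j]
                reads_rows.append(
                    dict(
                        scaffold=scaf,
                        start=start0,
                        sequence="".join(seq),
                        population=pop,
                    )
                )
    reads_df = pd.DataFrame(reads_rows)
    snp_df = pd.DataFrame(snp_rows)
    return reads_df, snp_df
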
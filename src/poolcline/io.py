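"""Readers and writers for the external formats the pipeline touches.

The universal substrate is the PoPoolation2 "sync" table: one line per
genomic site carrying a scaffold, a 1-based position, a reference base and,
for each population pool, a colon-separated sextet of read counts in the
fixed order A:T:C:G:N:deletion.  Everything downstream (diversity, F_ST,
admixture and environmental-association statistics) consumes the in-memory
:class:`SiteCountsTable` built here.

Coordinate conventions: sync and GFF3 are 1-based inclusive, BED masks are
0-based half-open; all internal arithmetic converts to 0-based half-open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils
import networkx as nx
import numpy as np
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

#: Column order of a sync count sextet.
SYNC_ALLELES = ("A", "T", "C", "G", "N", "del")
#: Indices of the four true nucleotide columns within a sextet.
BASE_COLUMNS = np.array([0, 1, 2, 3])


class SyncParseError(ValueError):
    """A sync line could not be parsed; message names the offending line."""


class ConfigurationError(ValueError):
    """Inconsistent configuration (e.g. pool-count mismatch)."""


# ---------------------------------------------------------------------------
# SiteCountsTable
# ---------------------------------------------------------------------------

@dataclass
class SiteCountsTable:
    """Per-site, per-pool nucleotide read counts.

    Attributes
    ----------
    scaffold : np.ndarray of str, shape (n_sites,)
    position : np.ndarray of int, shape (n_sites,)
        1-based positions, strictly increasing within a scaffold.
    ref : np.ndarray of str, shape (n_sites,)
        Reference base (A/C/G/T/N); retained for reporting only.
    counts : np.ndarray of int, shape (n_sites, n_pools, 6)
        Read counts in sync order A,T,C,G,N,del.
    """

    scaffold: np.ndarray
    position: np.ndarray
    ref: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.scaffold = np.asarray(self.scaffold, dtype=object)
        self.position = np.asarray(self.position, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 3 or self.counts.shape[2] != 6:
            raise ValueError("counts must have shape (n_sites, n_pools, 6)")
        if len(self.scaffold) != len(self.counts):
            raise ValueError("scaffold/counts length mismatch")
        if len(self) and (self.position <= 0).any():
            raise ValueError("positions must be positive (1-based)")
        if (self.counts < 0).any():
            raise ValueError("negative read count")
        self._check_sorted()

    def _check_sorted(self) -> None:
        if len(self) < 2:
            return
        same = self.scaffold[1:] == self.scaffold[:-1]
        if np.any(same & (np.diff(self.position) <= 0)):
            raise ValueError("positions must be strictly increasing within a scaffold")

    def __len__(self) -> int:
        return len(self.position)

    @property
    def n_pools(self) -> int:
        return self.counts.shape[1]

    def select(self, mask: np.ndarray) -> "SiteCountsTable":
        """Row subset preserving order."""
        return SiteCountsTable(
            self.scaffold[mask], self.position[mask], self.ref[mask], self.counts[mask]
        )

    def scaffolds(self) -> list[str]:
        """Distinct scaffold names in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.scaffold:
            seen.setdefault(s, None)
        return list(seen)

    @classmethod
    def empty(cls, n_pools: int) -> "SiteCountsTable":
        return cls(
            np.empty(0, dtype=object),
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=object),
            np.empty((0, n_pools, 6), dtype=np.int64),
        )


def parse_sync(path, n_pools: int) -> SiteCountsTable:
    """Parse a PoPoolation2 sync file into a :class:`SiteCountsTable`.

    Parameters
    ----------
    path : str or Path
    n_pools : int
        Expected number of pool columns; a mismatch raises
        :class:`ConfigurationError` naming the line.
    """
    if n_pools < 1:
        raise ConfigurationError("n_pools must be positive")
    scaffolds: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    rows: list[list[int]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split()
            if len(fields) < 3:
                raise SyncParseError(f"line {lineno}: expected at least 3 fields")
            if len(fields) - 3 != n_pools:
                raise ConfigurationError(
                    f"line {lineno}: {len(fields) - 3} pool columns, expected {n_pools}"
                )
            try:
                pos = int(fields[1])
            except ValueError as exc:
                raise SyncParseError(f"line {lineno}: non-integer position") from exc
            if pos <= 0:
                raise SyncParseError(f"line {lineno}: non-positive position")
            sextets: list[int] = []
            for col in fields[3:]:
                parts = col.split(":")
                if len(parts) != 6:
                    raise SyncParseError(
                        f"line {lineno}: count column '{col}' is not a sextet"
                    )
                try:
                    vals = [int(p) for p in parts]
                except ValueError as exc:
                    raise SyncParseError(
                        f"line {lineno}: non-integer count in '{col}'"
                    ) from exc
                if any(v < 0 for v in vals):
                    raise SyncParseError(f"line {lineno}: negative count in '{col}'")
                sextets.extend(vals)
            scaffolds.append(fields[0])
            positions.append(pos)
            refs.append(fields[2])
            rows.append(sextets)
    if not rows:
        return SiteCountsTable.empty(n_pools)
    counts = np.asarray(rows, dtype=np.int64).reshape(len(rows), n_pools, 6)
    return SiteCountsTable(
        np.asarray(scaffolds, dtype=object),
        np.asarray(positions, dtype=np.int64),
        np.asarray(refs, dtype=object),
        counts,
    )


def write_sync(table: SiteCountsTable, path) -> None:
    """Write a sync file (tab-separated, counts colon-joined)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for i in range(len(table)):
            cols = [
                ":".join(str(c) for c in table.counts[i, k])
                for k in range(table.n_pools)
            ]
            fh.write(
                f"{table.scaffold[i]}\t{table.position[i]}\t{table.ref[i]}\t"
                + "\t".join(cols)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Region masks (BED, 0-based half-open)
# ---------------------------------------------------------------------------

@dataclass
class RegionMask:
    """Set of masked intervals per scaffold, 0-based half-open, merged."""

    intervals: dict = field(default_factory=dict)  # scaffold -> (starts, ends)

    @classmethod
    def from_intervals(cls, triples: Iterable[tuple]) -> "RegionMask":
        raw: dict[str, list[tuple[int, int]]] = {}
        for scaf, start, end in triples:
            if start >= end:
                raise ValueError(f"empty interval {scaf}:{start}-{end}")
            raw.setdefault(scaf, []).append((int(start), int(end)))
        merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for scaf, ivals in raw.items():
            ivals.sort()
            out: list[list[int]] = []
            for s, e in ivals:
                if out and s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            starts = np.array([s for s, _ in out], dtype=np.int64)
            ends = np.array([e for _, e in out], dtype=np.int64)
            merged[scaf] = (starts, ends)
        return cls(merged)

    def covers(self, scaffold: str, pos0: np.ndarray) -> np.ndarray:
        """Vectorized membership of 0-based positions in the mask."""
        pos0 = np.asarray(pos0, dtype=np.int64)
        if scaffold not in self.intervals:
            return np.zeros(pos0.shape, dtype=bool)
        starts, ends = self.intervals[scaffold]
        idx = np.searchsorted(starts, pos0, side="right") - 1
        hit = idx >= 0
        hit[hit] = pos0[hit] < ends[idx[hit]]
        return hit


def parse_bed(path) -> RegionMask:
    triples = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            triples.append((f[0], int(f[1]), int(f[2])))
    return RegionMask.from_intervals(triples)


def apply_region_mask(table: SiteCountsTable, mask: RegionMask) -> SiteCountsTable:
    """Drop records whose (scaffold, position-1) falls inside the mask."""
    if not mask.intervals or len(table) == 0:
        return table
    keep = np.ones(len(table), dtype=bool)
    for scaf in table.scaffolds():
        rows = table.scaffold == scaf
        keep[rows] = ~mask.covers(scaf, table.position[rows] - 1)
    return table.select(keep)


# ---------------------------------------------------------------------------
# Gene models (GFF3)
# ---------------------------------------------------------------------------

@dataclass
class GeneModels:
    """Gene/exon/CDS intervals, 1-based inclusive, as parsed from GFF3.

    ``genes`` is a DataFrame with columns gene_id, scaffold, strand,
    start, end; ``exons`` and ``cds`` map gene_id to lists of (start, end).
    """

    genes: pd.DataFrame
    exons: dict
    cds: dict

    def __post_init__(self) -> None:
        for _, g in self.genes.iterrows():
            if g.start > g.end:
                raise ValueError(f"gene {g.gene_id}: start > end")
            for s, e in self.exons.get(g.gene_id, []):
                if not (g.start <= s <= e <= g.end):
                    raise ValueError(f"gene {g.gene_id}: exon outside gene span")
        for gid, cds_ivals in self.cds.items():
            ex = self.exons.get(gid, [])
            for s, e in cds_ivals:
                if not any(xs <= s <= e <= xe for xs, xe in ex):
                    raise ValueError(f"gene {gid}: CDS outside exons")

    def __len__(self) -> int:
        return len(self.genes)


def parse_gff3(path) -> GeneModels:
    """Parse gene/exon/CDS features from a GFF3 file via gffutils."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    for gene in db.features_of_type("gene"):
        strand = gene.strand
        if strand == ".":
            warnings.warn(
                f"gene {gene.id}: '.' strand treated as '+'", stacklevel=2
            )
            strand = "+"
        rows.append(
            dict(
                gene_id=gene.id,
                scaffold=gene.seqid,
                strand=strand,
                start=gene.start,
                end=gene.end,
            )
        )
        exons[gene.id] = sorted(
            (f.start, f.end) for f in db.children(gene, featuretype="exon")
        )
        cds[gene.id] = sorted(
            (f.start, f.end) for f in db.children(gene, featuretype="CDS")
        )
    genes = pd.DataFrame(
        rows, columns=["gene_id", "scaffold", "strand", "start", "end"]
    )
    return GeneModels(genes, exons, cds)


def write_gff3(models: GeneModels, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for _, g in models.genes.iterrows():
            fh.write(
                f"{g.scaffold}\tpoolcline\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(models.exons.get(g.gene_id, []), 1):
                fh.write(
                    f"{g.scaffold}\tpoolcline\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )
            for i, (s, e) in enumerate(models.cds.get(g.gene_id, []), 1):
                fh.write(
                    f"{g.scaffold}\tpoolcline\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.cds{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Ontology (OBO + gene2go)
# ---------------------------------------------------------------------------

@dataclass
class OntologyGraph:
    """GO is_a DAG plus direct gene annotations.

    ``graph`` is a networkx DiGraph with edges child -> parent (is_a only).
    ``annotations`` maps gene id -> set of directly annotated term ids.
    """

    graph: nx.DiGraph
    annotations: dict

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("is_a graph is cyclic")

    def ancestors(self, term: str) -> set:
        """All terms reachable via is_a edges (excluding the term itself)."""
        return nx.descendants(self.graph, term)

    def terms(self) -> list:
        return list(self.graph.nodes)


def parse_obo(path) -> nx.DiGraph:
    """Read an OBO 1.2 file, keeping only is_a edges (child -> parent)."""
    multi = obonet.read_obo(str(path))
    g = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        g.add_node(node, **{k: data[k] for k in ("name", "namespace") if k in data})
    for u, v, key in multi.edges(keys=True):
        if key == "is_a":
            g.add_edge(u, v)
    return g


def write_obo(graph: nx.DiGraph, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n\n")
        for node in sorted(graph.nodes):
            data = graph.nodes[node]
            fh.write("[Term]\n")
            fh.write(f"id: {node}\n")
            fh.write(f"name: {data.get('name', node)}\n")
            if "namespace" in data:
                fh.write(f"namespace: {data['namespace']}\n")
            for parent in sorted(graph.successors(node)):
                fh.write(f"is_a: {parent}\n")
            fh.write("\n")


def read_gene2go(path) -> dict:
    """Two-column TSV gene<TAB>term -> dict gene -> set of terms."""
    ann: dict[str, set] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            ann.setdefault(gene, set()).add(term)
    return ann


def write_gene2go(annotations: dict, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\n")


def load_annotation(gff_path, obo_path, gene2go_path):
    """Load gene models and ontology, validating cross-references.

    Returns ``(GeneModels, OntologyGraph)``.  Annotations to terms absent
    from the ontology are dropped with a warning; genes absent from the GFF
    are retained in the mapping but logged.
    """
    models = parse_gff3(gff_path)
    graph = parse_obo(obo_path)
    raw = read_gene2go(gene2go_path)
    known_terms = set(graph.nodes)
    known_genes = set(models.genes.gene_id)
    ann: dict[str, set] = {}
    n_dropped = 0
    for gene, terms in raw.items():
        kept = terms & known_terms
        n_dropped += len(terms) - len(kept)
        if gene not in known_genes:
            logger.info("gene2go gene %s absent from GFF; retained in mapping", gene)
        if kept:
            ann[gene] = kept
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} annotations to unknown terms", stacklevel=2
        )
    return models, OntologyGraph(graph, ann)


# ---------------------------------------------------------------------------
# Environmental table, read tables, FASTA
# ---------------------------------------------------------------------------

def read_env_table(path) -> pd.DataFrame:
    """Populations x environmental-variables TSV; first column = population."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError("environmental table contains missing values")
    return df


def write_env_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_reads_table(path) -> pd.DataFrame:
    """Read table for haplotype extraction: scaffold, 0-based start,
    sequence, population label (TSV)."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=["scaffold", "start", "sequence", "population"],
        dtype={"scaffold": str, "start": np.int64, "sequence": str, "population": str},
        comment="#",
    )
    return df


def write_fasta(records: Sequence[tuple], path) -> None:
    """Write (header, sequence) pairs as FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    seqs = [SeqRecord(Seq(s), id=h, description="") for h, s in records]
    SeqIO.write(seqs, str(path), "fasta")
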
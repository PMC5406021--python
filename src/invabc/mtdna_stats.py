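"""Haplotype collapsing, diversity statistics, neutrality test, and a
minimum-spanning haplotype network for aligned mtDNA sequences.

Missing bases (N) are handled by pairwise deletion by default: sites with N in
either sequence of a pair are excluded from that comparison.  The open-reading-
frame check uses the invertebrate mitochondrial code with a configurable frame.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio import SeqIO
from scipy.sparse.csgraph import minimum_spanning_tree

ALPHABET = set(b"ACGTN-")
_N = ord("N")
_GAP = ord("-")


@dataclass
class SequenceAlignment:
    """Equal-length haploid sequences with (id, population, year) metadata.

    ``seqs`` is an (n, L) uint8 array of ASCII codes over {A,C,G,T,N,-}.
    """

    samples: pd.DataFrame
    seqs: np.ndarray

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.seqs = np.asarray(self.seqs, dtype=np.uint8)
        if self.seqs.ndim != 2 or self.seqs.shape[0] != len(self.samples):
            raise ValueError("seqs must be (n_records, L) with one row per record")
        if self.samples["id"].duplicated().any():
            raise ValueError("duplicate record ids")
        codes = set(np.unique(self.seqs).tobytes())
        if not codes <= ALPHABET:
            raise ValueError(f"invalid characters in alignment: {codes - ALPHABET}")

    @property
    def n_records(self) -> int:
        return self.seqs.shape[0]

    @property
    def length(self) -> int:
        return self.seqs.shape[1]

    def sequence(self, i: int) -> str:
        return self.seqs[i].tobytes().decode()

    def subset(self, rows) -> "SequenceAlignment":
        rows = np.asarray(rows)
        return SequenceAlignment(self.samples.iloc[rows], self.seqs[rows])

    def for_populations(self, pops) -> "SequenceAlignment":
        keep = self.samples["population"].isin(list(pops)).to_numpy()
        return self.subset(np.flatnonzero(keep))


def read_alignment(path) -> SequenceAlignment:
    """Read FASTA; headers ``id|population|year`` populate the metadata."""
    ids, pops, years, rows = [], [], [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        ids.append(parts[0])
        pops.append(parts[1] if len(parts) > 1 else "NA")
        years.append(int(parts[2]) if len(parts) > 2 else 0)
        rows.append(np.frombuffer(str(rec.seq).upper().encode(), dtype=np.uint8))
    if not rows:
        raise ValueError(f"no records in {path}")
    lengths = {r.size for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
    meta = pd.DataFrame({"id": ids, "population": pops, "year": years})
    return SequenceAlignment(meta, np.vstack(rows))


def write_alignment(aln: SequenceAlignment, path) -> None:
    with open(path, "w") as fh:
        for i, row in aln.samples.iterrows():
            fh.write(f">{row['id']}|{row['population']}|{row['year']}\n")
            fh.write(aln.sequence(i) + "\n")


# -- ORF check ----------------------------------------------------------------


def check_orf(aln: SequenceAlignment, frame: int = 0, table: int = 5) -> pd.DataFrame:
    """Internal stop codons per sequence under the given translation table
    (default 5: invertebrate mitochondrial)."""
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    rows = []
    for i in range(aln.n_records):
        seq = aln.sequence(i).replace("-", "")[frame:]
        seq = seq[: 3 * (len(seq) // 3)]
        aa = str(Seq(seq).translate(table=table))
        stops = [j for j, c in enumerate(aa[:-1]) if c == "*"]
        rows.append(
            {"id": aln.samples["id"].iloc[i], "n_internal_stops": len(stops),
             "stop_positions": stops, "pass": not stops}
        )
    return pd.DataFrame(rows)


# -- haplotypes ---------------------------------------------------------------


@dataclass
class HaplotypeSet:
    haplotypes: list[str]  # distinct sequences, index = integer label
    membership: dict[str, int]  # record id -> haplotype index
    counts: pd.DataFrame = field(repr=False)  # haplotype x population counts

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)


def _compatible(a: np.ndarray, b: np.ndarray) -> bool:
    ok = (a != _N) & (b != _N)
    return bool(np.all(a[ok] == b[ok]))


def collapse_haplotypes(aln: SequenceAlignment, ambiguous: str = "strict") -> HaplotypeSet:
    """Group records into haplotypes.

    ``strict``: exact string identity.  ``ignore-N``: a record joins the first
    existing haplotype (in order of anchor record id) whose anchor sequence it
    matches at all mutually non-N sites; records are processed in record-id
    order so the lowest id anchors each haplotype.
    """
    if ambiguous not in ("strict", "ignore-N"):
        raise ValueError(f"unknown ambiguous mode {ambiguous!r}")
    order = np.argsort(aln.samples["id"].to_numpy(), kind="stable")
    haplo_seqs: list[np.ndarray] = []
    membership: dict[str, int] = {}
    for i in order:
        seq = aln.seqs[i]
        rid = aln.samples["id"].iloc[i]
        assigned = None
        for h, anchor in enumerate(haplo_seqs):
            if ambiguous == "strict":
                if np.array_equal(seq, anchor):
                    assigned = h
                    break
            elif _compatible(seq, anchor):
                assigned = h
                break
        if assigned is None:
            haplo_seqs.append(seq)
            assigned = len(haplo_seqs) - 1
        membership[rid] = assigned
    pops = sorted(set(aln.samples["population"]))
    counts = pd.DataFrame(0, index=range(len(haplo_seqs)), columns=pops)
    for i in range(aln.n_records):
        h = membership[aln.samples["id"].iloc[i]]
        counts.loc[h, aln.samples["population"].iloc[i]] += 1
    return HaplotypeSet(
        haplotypes=[s.tobytes().decode() for s in haplo_seqs],
        membership=membership,
        counts=counts,
    )


def haplotype_diversity(h: HaplotypeSet, populations=None) -> float:
    """Hd = n/(n-1) (1 - sum p_i^2); NaN for n < 2."""
    counts = h.counts if populations is None else h.counts[list(populations)]
    c = counts.sum(axis=1).to_numpy(dtype=float)
    n = c.sum()
    if n < 2:
        return float("nan")
    p = c / n
    return float((n / (n - 1)) * (1.0 - np.sum(p**2)))


# -- diversity / neutrality ---------------------------------------------------


def _pairwise_diffs(seqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise (#differences, #compared sites) with pairwise N/gap deletion."""
    n = seqs.shape[0]
    valid = (seqs != _N) & (seqs != _GAP)
    diffs = np.zeros((n, n))
    comps = np.zeros((n, n))
    for i in range(n):
        ok = valid[i] & valid[i + 1 :]
        d = (seqs[i] != seqs[i + 1 :]) & ok
        diffs[i, i + 1 :] = d.sum(axis=1)
        comps[i, i + 1 :] = ok.sum(axis=1)
    diffs += diffs.T
    comps += comps.T
    return diffs, comps


def nucleotide_diversity(aln: SequenceAlignment, populations=None) -> float:
    """pi: mean pairwise proportion of differing sites over compared positions."""
    sub = aln if populations is None else aln.for_populations(populations)
    n = sub.n_records
    if n < 2:
        return float("nan")
    diffs, comps = _pairwise_diffs(sub.seqs)
    iu = np.triu_indices(n, 1)
    with np.errstate(invalid="ignore"):
        props = np.where(comps[iu] > 0, diffs[iu] / comps[iu], np.nan)
    return float(np.nanmean(props))


def segregating_sites(seqs: np.ndarray) -> int:
    valid = (seqs != _N) & (seqs != _GAP)
    s = 0
    for col in range(seqs.shape[1]):
        obs = np.unique(seqs[valid[:, col], col])
        if obs.size > 1:
            s += 1
    return s


def tajimas_d(aln: SequenceAlignment, populations=None) -> tuple[float, int, float]:
    """Tajima's D with the standard a1..e2 constants; returns (D, S, pi_per_site).

    D is NaN when S = 0 or n < 4.
    """
    sub = aln if populations is None else aln.for_populations(populations)
    n = sub.n_records
    S = segregating_sites(sub.seqs)
    pi_site = nucleotide_diversity(sub)
    if n < 4 or S == 0:
        return float("nan"), S, pi_site
    diffs, comps = _pairwise_diffs(sub.seqs)
    iu = np.triu_indices(n, 1)
    k_hat = float(np.mean(diffs[iu]))  # mean pairwise difference count
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    d = (k_hat - S / a1) / np.sqrt(var)
    return float(d), S, pi_site


def diversity_table(aln: SequenceAlignment, h: HaplotypeSet | None = None) -> pd.DataFrame:
    """Per-population n, n_H, Hd, pi plus a Total row."""
    if h is None:
        h = collapse_haplotypes(aln)
    rows = []
    pops = sorted(set(aln.samples["population"]))
    for pop in pops + ["Total"]:
        sel = None if pop == "Total" else [pop]
        sub = aln if sel is None else aln.for_populations(sel)
        counts = h.counts if sel is None else h.counts[sel]
        n_h = int((counts.sum(axis=1) > 0).sum())
        rows.append(
            {
                "population": pop,
                "n": sub.n_records,
                "n_H": n_h,
                "Hd": haplotype_diversity(h, sel),
                "pi": nucleotide_diversity(aln, sel),
            }
        )
    return pd.DataFrame(rows)


# -- haplotype network --------------------------------------------------------


def hamming_matrix(h: HaplotypeSet) -> np.ndarray:
    seqs = np.vstack([np.frombuffer(s.encode(), dtype=np.uint8) for s in h.haplotypes])
    diffs, _ = _pairwise_diffs(seqs)
    return diffs


def haplotype_network(h: HaplotypeSet, max_connection: int | None = None) -> nx.Graph:
    """Minimum-spanning network over pairwise Hamming distances.

    Edges carry ``weight`` (substitution count).  Edges longer than
    ``max_connection`` are dropped afterwards (disconnecting components, as a
    statistical-parsimony-style connection limit).  Edges of weight > 1 are
    decorated with unsampled intermediate nodes (``u<i>``).
    """
    if h.n_haplotypes < 2:
        raise ValueError("need >= 2 haplotypes for a network")
    d = hamming_matrix(h)
    mst = minimum_spanning_tree(d).toarray()
    g = nx.Graph()
    totals = h.counts.sum(axis=1)
    for i in range(h.n_haplotypes):
        g.add_node(f"H{i + 1}", count=int(totals.iloc[i]), sampled=True)
    for i, j in zip(*np.nonzero(mst)):
        w = int(round(mst[i, j]))
        if max_connection is not None and w > max_connection:
            continue
        g.add_edge(f"H{i + 1}", f"H{j + 1}", weight=w)
    # decorate multi-step edges with unsampled intermediates
    u_idx = itertools.count(1)
    for a, b, data in list(g.edges(data=True)):
        w = data["weight"]
        if w <= 1:
            continue
        g.remove_edge(a, b)
        prev = a
        for _ in range(w - 1):
            mid = f"u{next(u_idx)}"
            g.add_node(mid, count=0, sampled=False)
            g.add_edge(prev, mid, weight=1)
            prev = mid
        g.add_edge(prev, b, weight=1)
    return g


def write_network(g: nx.Graph, edge_tsv_path, graphml_path=None) -> None:
    with open(edge_tsv_path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for a, b, data in g.edges(data=True):
            fh.write(f"{a}\t{b}\t{data['weight']}\n")
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)
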
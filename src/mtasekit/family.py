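"""Sequence-similarity networks over a methyltransferase family.

Nodes are family sequences; an undirected edge connects two sequences when
their best local alignment scores an E-value strictly below a threshold
(default 1e-30, the level that separates the viral orthologs of the enzyme
from its eukaryotic homologs).  Nodes can be annotated, via a multiple
sequence alignment, with the residue each homolog carries at a reference
position of the reference enzyme (e.g. the position corresponding to K41).

Alignment uses BLOSUM62 with affine gaps (open 11, extend 1) and the
standard extreme-value (Karlin–Altschul) E-value with the gapped BLOSUM62
parameters, so the desk-scale internal route behaves like an all-versus-all
BLAST; externally computed 12-column tabular hits are accepted as the
faithful route.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

# Gapped Karlin–Altschul parameters for BLOSUM62 with gap open 11 / extend 1
# (the values protein BLAST uses for this scoring system).
_LAMBDA = 0.267
_K = 0.041


@dataclass(frozen=True)
class SequenceRecord:
    """One family member: accession and amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.id}")
        bad = sorted(set(self.sequence.upper()) - AA_ALPHABET)
        if bad:
            raise ValueError(
                f"non-amino-acid characters in {self.id}: {''.join(bad)}"
            )


@dataclass(frozen=True)
class PairwiseHit:
    """Best local-alignment hit between two sequences."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    e_value: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent_identity must be in [0, 100]")
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.query_id, self.subject_id))


def read_fasta(path) -> list[SequenceRecord]:
    return [
        SequenceRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_similarity(
    a: SequenceRecord, b: SequenceRecord, db_size: int | None = None
) -> PairwiseHit:
    """Local BLOSUM62 alignment of two sequences with a BLAST-style E-value.

    ``db_size`` is the effective database size in residues; by default the
    subject length is used (single-pair search space).
    """
    aligner = _make_aligner()
    aln = aligner.align(a.sequence, b.sequence)[0]
    score = aln.score
    n = db_size if db_size is not None else len(b.sequence)
    e_value = _K * len(a.sequence) * n * math.exp(-_LAMBDA * score)

    cols_a, cols_b = aln.indices  # -1 marks a gap in that row
    length = cols_a.shape[0]
    matches = sum(
        1
        for i in range(length)
        if cols_a[i] >= 0
        and cols_b[i] >= 0
        and a.sequence[cols_a[i]] == b.sequence[cols_b[i]]
    )
    pident = 100.0 * matches / length if length else 0.0
    return PairwiseHit(a.id, b.id, pident, max(length, 1), e_value)


def all_vs_all(records: Sequence[SequenceRecord]) -> list[PairwiseHit]:
    """Internal all-versus-all search: one best hit per unordered pair."""
    db_size = sum(len(r.sequence) for r in records)
    hits = []
    for i, ra in enumerate(records):
        for rb in records[i + 1 :]:
            hits.append(pairwise_similarity(ra, rb, db_size=db_size))
    return hits


def parse_blast_tabular(path) -> list[PairwiseHit]:
    """Parse standard 12-column BLAST tabular output (``-outfmt 6``).

    Reciprocal and repeated hits on the same unordered pair are deduplicated,
    keeping the lowest E-value.  Self-hits are dropped.
    """
    best: dict[frozenset, PairwiseHit] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            q, s = fields[0], fields[1]
            if q == s:
                continue
            hit = PairwiseHit(
                q, s, float(fields[2]), int(fields[3]), float(fields[10])
            )
            if hit.pair not in best or hit.e_value < best[hit.pair].e_value:
                best[hit.pair] = hit
    return list(best.values())


def dedupe_hits(hits: Iterable[PairwiseHit]) -> list[PairwiseHit]:
    """Keep the lowest-E-value hit per unordered pair."""
    best: dict[frozenset, PairwiseHit] = {}
    for hit in hits:
        if hit.query_id == hit.subject_id:
            continue
        if hit.pair not in best or hit.e_value < best[hit.pair].e_value:
            best[hit.pair] = hit
    return list(best.values())


def build_ssn(
    hits: Iterable[PairwiseHit],
    threshold: float = 1e-30,
    nodes: Iterable[str] | None = None,
) -> nx.Graph:
    """Build the sequence-similarity network at an E-value threshold.

    An edge is present iff the pair's best E-value is *strictly* below the
    threshold.  All sequences seen in any hit (and any ids passed via
    ``nodes``) are retained as nodes, so isolated sequences stay visible.
    Connected components are labelled on the nodes (attribute ``component``).
    """
    hits = dedupe_hits(hits)
    g = nx.Graph(threshold=threshold)
    if nodes is not None:
        g.add_nodes_from(nodes)
    for hit in hits:
        g.add_node(hit.query_id)
        g.add_node(hit.subject_id)
        if hit.e_value < threshold:
            g.add_edge(
                hit.query_id,
                hit.subject_id,
                e_value=hit.e_value,
                percent_identity=hit.percent_identity,
                alignment_length=hit.alignment_length,
            )
    for i, comp in enumerate(nx.connected_components(g)):
        for node in comp:
            g.nodes[node]["component"] = i
    return g


def extract_subnetwork(
    network: nx.Graph,
    node_set: Iterable[str] | None = None,
    component_seed: str | None = None,
    hits: Iterable[PairwiseHit] | None = None,
) -> nx.Graph:
    """Induced subgraph on a node set (or the component containing a seed).

    The graph attribute ``median_pairwise_identity`` reports the median
    percent identity over member-pair hits (edge attributes by default, the
    full hit list if ``hits`` is given).
    """
    if (node_set is None) == (component_seed is None):
        raise ValueError("give exactly one of node_set or component_seed")
    if component_seed is not None:
        if component_seed not in network:
            raise KeyError(f"unknown node {component_seed!r}")
        node_set = nx.node_connected_component(network, component_seed)
    node_set = set(node_set)
    unknown = node_set - set(network.nodes)
    if unknown:
        raise KeyError(f"unknown nodes: {sorted(unknown)}")
    sub = network.subgraph(node_set).copy()
    if hits is not None:
        idents = [
            h.percent_identity for h in dedupe_hits(hits) if h.pair <= node_set
        ]
    else:
        idents = [d["percent_identity"] for _, _, d in sub.edges(data=True)]
    sub.graph["median_pairwise_identity"] = median(idents) if idents else float("nan")
    return sub


def read_msa(path, fmt: str = "fasta"):
    """Read a multiple sequence alignment (FASTA or Stockholm)."""
    return AlignIO.read(str(path), fmt)


def _msa_row(msa, seq_id: str):
    for rec in msa:
        if rec.id == seq_id:
            return rec
    raise KeyError(f"sequence {seq_id!r} not in alignment")


def map_reference_position(msa, reference_id: str, reference_position: int) -> int:
    """MSA column (1-based) holding the reference sequence's residue
    ``reference_position`` (1-based, ungapped numbering)."""
    row = str(_msa_row(msa, reference_id).seq)
    count = 0
    for col, ch in enumerate(row, 1):
        if ch not in "-.":
            count += 1
            if count == reference_position:
                return col
    raise ValueError(
        f"position {reference_position} beyond ungapped length "
        f"({count}) of {reference_id!r}"
    )


@dataclass
class PositionAnnotation:
    """Residue carried by each network node at one reference position."""

    reference_id: str
    reference_position: int
    column_index: int
    per_node_residue: dict[str, str]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for res in self.per_node_residue.values():
            out[res] = out.get(res, 0) + 1
        return out


def annotate_nodes(
    network: nx.Graph,
    msa,
    reference_id: str,
    positions: Sequence[int],
) -> list[PositionAnnotation]:
    """Annotate network nodes with the residue at each reference position.

    Nodes missing from the MSA are annotated ``'?'`` with a warning.  The
    annotations are also written onto the graph nodes as attributes
    ``pos<position>``.
    """
    rows = {rec.id: str(rec.seq) for rec in msa}
    annotations = []
    for pos in positions:
        col = map_reference_position(msa, reference_id, pos)
        per_node = {}
        for node in network.nodes:
            if node in rows:
                ch = rows[node][col - 1]
                per_node[node] = "-" if ch in "-." else ch.upper()
            else:
                per_node[node] = "?"
        missing = [n for n, r in per_node.items() if r == "?"]
        if missing:
            warnings.warn(
                f"{len(missing)} network node(s) missing from MSA: "
                f"{sorted(missing)[:5]}..."
            )
        ref_res = per_node.get(reference_id)
        if ref_res is not None and ref_res not in "-?":
            ungapped = rows[reference_id].replace("-", "").replace(".", "")
            assert ref_res == ungapped[pos - 1].upper()
        ann = PositionAnnotation(reference_id, pos, col, per_node)
        annotations.append(ann)
        for node, res in per_node.items():
            network.nodes[node][f"pos{pos}"] = res
    return annotations


@dataclass
class PositionProbabilityMatrix:
    """Per-column residue probabilities (non-gap rows) and gap fractions."""

    columns: list[int]
    probabilities: list[dict[str, float]]
    gap_fraction: list[float]
    all_gap: list[bool]


def column_probabilities(msa, columns: Sequence[int]) -> PositionProbabilityMatrix:
    """Residue frequencies per MSA column (1-based), the logo-plot input.

    Probabilities are normalised over non-gap rows; the gap fraction is
    reported separately.  All-gap columns are flagged and get an empty
    probability map.
    """
    n_rows = len(msa)
    width = msa.get_alignment_length()
    probs, gaps, allgap = [], [], []
    for col in columns:
        if not 1 <= col <= width:
            raise ValueError(f"column {col} outside alignment width {width}")
        letters = [str(rec.seq)[col - 1].upper() for rec in msa]
        non_gap = [c for c in letters if c not in "-."]
        gaps.append(1 - len(non_gap) / n_rows)
        if not non_gap:
            allgap.append(True)
            probs.append({})
            continue
        allgap.append(False)
        freq: dict[str, float] = {}
        for c in non_gap:
            freq[c] = freq.get(c, 0) + 1
        probs.append({c: v / len(non_gap) for c, v in freq.items()})
    return PositionProbabilityMatrix(list(columns), probs, gaps, allgap)


def write_graphml(network: nx.Graph, path) -> None:
    nx.write_graphml(network, str(path))


def write_edge_csv(network: nx.Graph, path) -> None:
    import pandas as pd

    rows = [
        {"source": u, "target": v, **d} for u, v, d in network.edges(data=True)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
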
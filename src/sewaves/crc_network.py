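"""Core regulatory circuitry (CRC) from motif presence in TF-linked SEs.

A directed edge a -> b exists when the binding motif of TF a (a PWM
scanned in log-odds bits on both strands) is found inside an active SE of
TF b.  Nodes carry mRNA expression and are ranked by it; the graph is
serialized as a LEAF ("linked enhancer-activated factors") document plus
a DOT rendering.  The module also intersects GWAS SNPs with classified
SEs, carrying the SE wave label and the SNP statistics verbatim.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import (
    GenomicInterval,
    PWM,
    SnpRecord,
    fetch_sequence,
)

_BASE_TO_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class MotifHit:
    """One PWM match: location, strand and log-odds score in bits."""

    pwm_name: str
    interval: GenomicInterval
    strand: str
    score: float


def _encode(sequence: str) -> np.ndarray:
    """Map a DNA string to indices 0..3; N (or any other symbol) -> -1."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, -1, dtype=np.int64)
    for base, idx in _BASE_TO_IDX.items():
        out[arr == ord(base)] = idx
    return out


def _window_scores(codes: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Log-odds score at every offset; windows containing N score -inf."""
    L = lom.shape[0]
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for j in range(L):
        col = codes[j : j + n]
        ok = col >= 0
        valid &= ok
        scores[ok] += lom[j, col[ok]]
    scores[~valid] = -np.inf
    return scores


def pwm_scan(
    sequence: str,
    pwm: PWM,
    threshold: float,
    chrom: str = "",
    offset: int = 0,
) -> list[MotifHit]:
    """Scan both strands of ``sequence`` for matches scoring >= threshold.

    Scores are per-position log2(p/background) summed over the motif.
    A minus-strand hit is reported at the forward-strand coordinates it
    occupies.  ``chrom``/``offset`` place hits in genome coordinates.
    """
    L = len(pwm)
    if len(sequence) < L:
        return []
    codes = _encode(sequence)
    lom = pwm.log_odds()
    rc_lom = lom[::-1, ::-1]  # reverse-complement scan on the forward sequence
    hits = []
    for strand, matrix in (("+", lom), ("-", rc_lom)):
        scores = _window_scores(codes, matrix)
        for i in np.flatnonzero(scores >= threshold):
            hits.append(
                MotifHit(
                    pwm_name=pwm.name,
                    interval=GenomicInterval(chrom or "seq", offset + int(i), offset + int(i) + L),
                    strand=strand,
                    score=float(scores[i]),
                )
            )
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


@dataclass
class CRCGraph:
    """Directed TF-TF graph with expression-ranked nodes.

    ``graph`` node attrs: expression (float), rank (1 = highest
    expression); edge attrs: hits (int), offsets (list of genome starts).
    """

    graph: nx.DiGraph

    @property
    def tfs(self) -> list[str]:
        return sorted(self.graph.nodes)

    def rank_of(self, tf: str) -> int:
        return int(self.graph.nodes[tf]["rank"])


def _assign_ranks(graph: nx.DiGraph) -> None:
    ordered = sorted(
        graph.nodes, key=lambda t: (-graph.nodes[t]["expression"], t)
    )
    for rank, tf in enumerate(ordered, start=1):
        graph.nodes[tf]["rank"] = rank


def build_crc(
    tf_ses: dict[str, list[GenomicInterval]],
    genome,
    pwms: dict[str, PWM],
    expr: dict[str, float],
    threshold_bits: float | None = None,
    threshold_frac: float = 0.8,
) -> CRCGraph:
    """Build the CRC graph by scanning every TF's motif over every TF's
    active SE sequences.

    The scan threshold is ``threshold_bits`` when given, otherwise
    ``threshold_frac`` of each PWM's maximum achievable log-odds score.
    Self-edges (auto-regulation) are retained.
    """
    for tf in tf_ses:
        if tf not in pwms:
            raise KeyError(f"TF {tf} has no PWM")
        if tf not in expr:
            raise KeyError(f"TF {tf} has no expression value")
        if not tf_ses[tf]:
            raise ValueError(f"TF {tf} has no SE intervals")

    g = nx.DiGraph()
    for tf in tf_ses:
        g.add_node(tf, expression=float(expr[tf]))

    seqs = {
        tf: [(iv, fetch_sequence(genome, iv)) for iv in tf_ses[tf]]
        for tf in tf_ses
    }
    for source in tf_ses:
        pwm = pwms[source]
        thr = threshold_bits if threshold_bits is not None else threshold_frac * pwm.max_score
        for target in tf_ses:
            offsets = []
            for iv, seq in seqs[target]:
                for hit in pwm_scan(seq, pwm, thr, chrom=iv.chrom, offset=iv.start):
                    offsets.append(int(hit.interval.start))
            if offsets:
                g.add_edge(source, target, hits=len(offsets), offsets=sorted(offsets))
    _assign_ranks(g)
    return CRCGraph(graph=g)


def inward_outward(crc: CRCGraph, tf: str) -> tuple[int, int]:
    """(inward, outward) binding degree of a TF.

    inward = distinct TFs with a motif in ``tf``'s SEs; outward =
    distinct TFs whose SEs contain ``tf``'s motif.  Self-edges count in
    both directions.
    """
    if tf not in crc.graph:
        raise KeyError(f"unknown TF {tf}")
    return crc.graph.in_degree(tf), crc.graph.out_degree(tf)


def inward_outward_table(crc: CRCGraph) -> pd.DataFrame:
    rows = []
    for tf in crc.tfs:
        inward, outward = inward_outward(crc, tf)
        rows.append(
            {
                "tf": tf,
                "inward": inward,
                "outward": outward,
                "expression": float(crc.graph.nodes[tf]["expression"]),
                "rank": crc.rank_of(tf),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# LEAF serialization
# ---------------------------------------------------------------------------


def serialize_leaf(crc: CRCGraph) -> str:
    """LEAF document: nodes ordered by descending expression (ties broken
    by name) with rank and size proportional to expression, plus the
    directed motif-presence edges.  Deterministic byte-for-byte."""
    g = crc.graph
    max_expr = max((g.nodes[t]["expression"] for t in g.nodes), default=1.0) or 1.0
    nodes = [
        {
            "tf": tf,
            "expression": g.nodes[tf]["expression"],
            "rank": g.nodes[tf]["rank"],
            "size": g.nodes[tf]["expression"] / max_expr,
        }
        for tf in sorted(g.nodes, key=lambda t: (g.nodes[t]["rank"], t))
    ]
    edges = [
        {
            "source": u,
            "target": v,
            "hits": g.edges[u, v]["hits"],
            "offsets": list(g.edges[u, v]["offsets"]),
        }
        for u, v in sorted(g.edges)
    ]
    return json.dumps({"nodes": nodes, "edges": edges}, indent=2, sort_keys=True)


def parse_leaf(document: str) -> CRCGraph:
    """Rebuild a CRCGraph from a LEAF document (round-trip inverse)."""
    doc = json.loads(document)
    g = nx.DiGraph()
    for node in doc["nodes"]:
        g.add_node(node["tf"], expression=float(node["expression"]), rank=int(node["rank"]))
    for edge in doc["edges"]:
        g.add_edge(
            edge["source"], edge["target"],
            hits=int(edge["hits"]), offsets=[int(o) for o in edge["offsets"]],
        )
    return CRCGraph(graph=g)


def leaf_to_dot(crc: CRCGraph) -> str:
    """DOT rendering with node size scaled to expression."""
    g = crc.graph
    max_expr = max((g.nodes[t]["expression"] for t in g.nodes), default=1.0) or 1.0
    lines = ["digraph CRC {", "  rankdir=LR;"]
    for tf in sorted(g.nodes, key=lambda t: (g.nodes[t]["rank"], t)):
        size = 0.5 + 1.5 * g.nodes[tf]["expression"] / max_expr
        lines.append(
            f'  "{tf}" [shape=circle, width={size:.3f}, '
            f'label="{tf}\\n#{g.nodes[tf]["rank"]}"];'
        )
    for u, v in sorted(g.edges):
        lines.append(f'  "{u}" -> "{v}" [color=green, penwidth={min(4, g.edges[u, v]["hits"])}];')
    lines.append("}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# SNP intersection
# ---------------------------------------------------------------------------


def intersect_snps(
    snps: list[SnpRecord],
    ses: list[tuple[str, GenomicInterval, str]],
) -> pd.DataFrame:
    """Overlap GWAS SNPs with classified SEs (half-open intervals).

    ``ses`` rows are (se_id, interval, wave_label).  One output row per
    (SNP, SE) with the SNP strictly inside the interval; p-value and odds
    ratio are carried through verbatim.
    """
    rows = []
    for snp in snps:
        pos = snp.position.start
        for se_id, iv, wave in ses:
            if iv.chrom == snp.position.chrom and iv.start <= pos < iv.end:
                rows.append(
                    {
                        "rsid": snp.rsid,
                        "chrom": snp.position.chrom,
                        "pos": pos,
                        "se_id": se_id,
                        "se_start": iv.start,
                        "se_end": iv.end,
                        "wave_label": wave,
                        "p": snp.p_value,
                        "OR": snp.odds_ratio,
                        "alleles": snp.alleles,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "rsid", "chrom", "pos", "se_id", "se_start", "se_end",
            "wave_label", "p", "OR", "alleles",
        ],
    )
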
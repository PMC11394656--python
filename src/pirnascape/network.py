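"""piRNA-mRNA target prediction and the bipartite regulatory network.

Target sites are scored with a simplified antisense-complementarity scorer:
the piRNA is slid along the mRNA and, at each offset, Watson-Crick pairs,
G:U wobbles and mismatches are weighted and summed.  The "seed" is piRNA
positions 2-11, by analogy with the seed emphasis of the dedicated target
predictors this scorer approximates; those tools (thermodynamic duplex
folding, gap/bulge models) can be substituted by supplying an external edge
table.  Edges connect differentially expressed piRNAs to differentially
expressed mRNAs only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .sequences import normalize_dna, reverse_complement

#: piRNA positions (1-based) whose Watson-Crick matches count as seed matches.
SEED_POSITIONS = (2, 11)


@dataclass(frozen=True)
class DuplexScore:
    pirna_id: str | None
    mrna_id: str | None
    best_score: float
    site_start: int
    seed_matches: int


@dataclass(frozen=True)
class InteractionEdge:
    pirna_id: str
    mrna_id: str
    score: float
    pirna_status: str
    mrna_status: str


@dataclass
class RegulatoryNetwork:
    """Bipartite piRNA-mRNA graph with per-mRNA regulator degrees."""

    graph: nx.Graph

    @property
    def pirnas(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == "piRNA"}

    @property
    def mrnas(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == "mRNA"}

    @property
    def edges(self) -> list[InteractionEdge]:
        out = []
        for u, v, d in self.graph.edges(data=True):
            pid, mid = (u, v) if self.graph.nodes[u]["kind"] == "piRNA" else (v, u)
            out.append(
                InteractionEdge(
                    pid, mid, d["score"],
                    self.graph.nodes[pid]["status"], self.graph.nodes[mid]["status"],
                )
            )
        return out

    def degree_table(self) -> pd.DataFrame:
        """Distinct-regulator degree per mRNA, sorted descending."""
        rows = [(m, self.graph.degree[m]) for m in self.mrnas]
        return (
            pd.DataFrame(rows, columns=["mrna_id", "degree"])
            .sort_values(["degree", "mrna_id"], ascending=[False, True])
            .reset_index(drop=True)
        )


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(normalize_dna(seq).encode(), dtype=np.uint8)


def score_duplex(
    pirna_seq: str,
    mrna_seq: str,
    match_weight: float = 1.0,
    wobble_weight: float = 0.5,
    mismatch_weight: float = -1.0,
    pirna_id: str | None = None,
    mrna_id: str | None = None,
) -> DuplexScore:
    """Best antisense complementarity site of a piRNA on an mRNA.

    The piRNA binds antisense, so its reverse complement is compared against
    every mRNA window of equal length; at each offset the score sums
    ``match_weight`` per Watson-Crick pair, ``wobble_weight`` per G:U pair and
    ``mismatch_weight`` otherwise.  Ties break to the smallest site start.
    ``seed_matches`` counts Watson-Crick pairs at piRNA positions 2-11 of the
    winning site.
    """
    lp, lm = len(pirna_seq), len(mrna_seq)
    if lp < 11:
        raise ValueError(f"piRNA length must be >= 11, got {lp}")
    if lm < lp:
        raise ValueError(f"mRNA ({lm} nt) shorter than piRNA ({lp} nt)")

    rc = _encode(reverse_complement(pirna_seq))
    # piRNA base aligned with window position x is position lp - x (1-based)
    p_aligned = _encode(pirna_seq)[::-1]
    windows = np.lib.stride_tricks.sliding_window_view(_encode(mrna_seq), lp)

    match = windows == rc
    G, T = ord("G"), ord("T")
    wobble = ((p_aligned == G) & (windows == T)) | ((p_aligned == T) & (windows == G))
    wobble &= ~match
    n_match = match.sum(axis=1)
    n_wobble = wobble.sum(axis=1)
    scores = (
        match_weight * n_match
        + wobble_weight * n_wobble
        + mismatch_weight * (lp - n_match - n_wobble)
    )
    best = int(np.argmax(scores))  # first maximum = smallest site_start
    lo, hi = SEED_POSITIONS
    seed = int(match[best, lp - hi : lp - lo + 1].sum())
    return DuplexScore(pirna_id, mrna_id, float(scores[best]), best, seed)


def score_duplex_bruteforce(
    pirna_seq: str,
    mrna_seq: str,
    match_weight: float = 1.0,
    wobble_weight: float = 0.5,
    mismatch_weight: float = -1.0,
) -> DuplexScore:
    """All-offset, per-base oracle for :func:`score_duplex` (tests only)."""
    p = normalize_dna(pirna_seq)
    m = normalize_dna(mrna_seq)
    lp = len(p)
    wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    wob = {("G", "T"), ("T", "G")}
    best_score, best_start, best_seed = -np.inf, -1, 0
    for j in range(len(m) - lp + 1):
        score, seed = 0.0, 0
        for i in range(1, lp + 1):  # piRNA position, 1-based
            pair = (p[i - 1], m[j + lp - i])
            if pair in wc:
                score += match_weight
                if 2 <= i <= 11:
                    seed += 1
            elif pair in wob:
                score += wobble_weight
            else:
                score += mismatch_weight
        if score > best_score:
            best_score, best_start, best_seed = score, j, seed
    return DuplexScore(None, None, best_score, best_start, best_seed)


def predict_targets(
    de_pirnas: Mapping[str, str],
    mrna_seqs: Mapping[str, str],
    min_score: float,
    min_seed_matches: int = 9,
    **weights,
) -> list[tuple[str, str, DuplexScore]]:
    """Score every DE piRNA against every mRNA and keep qualifying pairs.

    Retains pairs with ``best_score >= min_score`` and ``seed_matches >=
    min_seed_matches``.  mRNAs shorter than a piRNA are skipped for that
    piRNA.  Raising either threshold never adds pairs.
    """
    hits = []
    for pid, pseq in de_pirnas.items():
        for mid, mseq in mrna_seqs.items():
            if len(mseq) < len(pseq):
                continue
            ds = score_duplex(pseq, mseq, pirna_id=pid, mrna_id=mid, **weights)
            if ds.best_score >= min_score and ds.seed_matches >= min_seed_matches:
                hits.append((pid, mid, ds))
    return hits


def build_network(
    edges: Iterable[tuple[str, str, float]],
    de_pirna_table: Mapping[str, str],
    de_mrna_table: Mapping[str, str],
) -> RegulatoryNetwork:
    """Assemble the bipartite network from (piRNA, mRNA, score) edges.

    Both endpoints must appear in their DE table with status ``up`` or
    ``down``.  Duplicate edges collapse (the last score wins), so mRNA degree
    counts distinct piRNA regulators.
    """
    g = nx.Graph()
    for pid, mid, score in edges:
        if pid not in de_pirna_table:
            raise KeyError(f"edge endpoint {pid!r} is not a DE piRNA")
        if mid not in de_mrna_table:
            raise KeyError(f"edge endpoint {mid!r} is not a DE mRNA")
        g.add_node(pid, kind="piRNA", bipartite=0, status=de_pirna_table[pid])
        g.add_node(mid, kind="mRNA", bipartite=1, status=de_mrna_table[mid])
        g.add_edge(pid, mid, score=float(score))
    return RegulatoryNetwork(g)


def export_network(network: RegulatoryNetwork, path: str, format: str) -> None:
    """Write the network as SIF, GraphML or TSV (``format`` case-insensitive)."""
    fmt = format.lower()
    if fmt == "sif":
        with open(path, "w") as fh:
            for e in network.edges:
                fh.write(f"{e.pirna_id}\tregulates\t{e.mrna_id}\n")
    elif fmt == "graphml":
        nx.write_graphml(network.graph, path)
    elif fmt == "tsv":
        rows = [
            (e.pirna_id, e.mrna_id, e.score, e.pirna_status, e.mrna_status)
            for e in network.edges
        ]
        pd.DataFrame(
            rows, columns=["pirna_id", "mrna_id", "score", "pirna_status", "mrna_status"]
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {format!r}")


def import_network_tsv(path: str) -> RegulatoryNetwork:
    """Re-read a TSV export; lossless round trip with :func:`export_network`."""
    df = pd.read_csv(path, sep="\t", dtype={"pirna_id": str, "mrna_id": str})
    pirna_status = dict(zip(df["pirna_id"], df["pirna_status"]))
    mrna_status = dict(zip(df["mrna_id"], df["mrna_status"]))
    edges = list(zip(df["pirna_id"], df["mrna_id"], df["score"]))
    return build_network(edges, pirna_status, mrna_status)
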
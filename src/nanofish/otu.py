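"""Greedy identity clustering, majority-rule consensus and OTU tables.

Two clustering rounds mirror common long-read amplicon practice: reads are
clustered per sample and each cluster reduced to a consensus; consensuses
from all samples of an experiment are then re-clustered at 97% so that one
OTU can be counted across samples. The greedy pass compares queries to
cluster *representatives* only, the incremental-clustering convention.

Identity here is the number of identical aligned positions in a global
alignment divided by the length of the shorter sequence (the default
convention of greedy incremental clusterers); among all minimum-edit
alignments the one maximizing matches is used, so the value is well defined.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import edlib
from Bio import Align

from .io import CountTable, SampleRecord

import pandas as pd

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

# Global aligner encoding "minimize edits, then maximize matches" in one
# score: with match +1 and mismatch/gap -1024, score = matches - 1024*edits,
# so matches = score mod 1024 (matches < 1024 always holds at amplicon scale).
_MATCH_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1024,
    open_gap_score=-1024,
    extend_gap_score=-1024,
)


@dataclass
class ClusterParams:
    identity_threshold: float = 0.97
    min_cluster_size: int = 5

    def __post_init__(self) -> None:
        if not 0.5 < self.identity_threshold <= 1:
            raise ValueError("identity_threshold must be in (0.5, 1]")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


@dataclass
class Cluster:
    representative: str
    member_ids: list[str]
    sample_id: str = ""

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class Consensus:
    sequence: str
    support: int
    sample_id: str = ""


@dataclass
class Otu:
    otu_id: str
    consensus: str
    per_sample_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.per_sample_counts.values())


def alignment_matches(a: str, b: str) -> int:
    """Maximum identical positions among minimum-edit global alignments."""
    score = _MATCH_ALIGNER.score(a, b)
    return int(score) % 1024


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identical positions / length of the shorter sequence."""
    if not a or not b:
        raise ValueError("empty sequence")
    return alignment_matches(a, b) / min(len(a), len(b))


def _identity_bounds(a: str, b: str) -> tuple[float, float]:
    """Cheap (lower, upper) bounds on pairwise_identity via edit distance."""
    d = edlib.align(a, b, mode="NW")["editDistance"]
    m, n = len(a), len(b)
    short = min(m, n)
    lower = max(0.0, ((m + n) / 2 - d) / short)
    upper = min(1.0, ((m + n - d) / 2) / short)
    return lower, upper


def _meets_threshold(a: str, b: str, threshold: float) -> bool:
    lower, upper = _identity_bounds(a, b)
    if upper < threshold:
        return False
    if lower >= threshold:
        return True
    return pairwise_identity(a, b) >= threshold


@dataclass
class ClusteringOutcome:
    clusters: list[Cluster]
    unclustered_ids: list[str]


def greedy_cluster(
    seqs: list[tuple[str, str]],
    params: ClusterParams | None = None,
    sample_id: str = "",
) -> ClusteringOutcome:
    """Greedy incremental clustering at a fixed identity threshold.

    Sequences are visited longest-first (ties: decreasing abundance of the
    identical sequence, then lexicographic id); each joins the first existing
    cluster whose representative it matches at or above the threshold, else
    founds a new cluster. Clusters below ``min_cluster_size`` are discarded
    and their members reported as unclustered.
    """
    params = params or ClusterParams()
    abundance = Counter(seq for _, seq in seqs)
    order = sorted(seqs, key=lambda t: (-len(t[1]), -abundance[t[1]], t[0]))
    clusters: list[Cluster] = []
    for seq_id, seq in order:
        for cl in clusters:
            if seq == cl.representative or _meets_threshold(
                seq, cl.representative, params.identity_threshold
            ):
                cl.member_ids.append(seq_id)
                break
        else:
            clusters.append(Cluster(seq, [seq_id], sample_id=sample_id))
    kept = [c for c in clusters if c.size >= params.min_cluster_size]
    dropped = [
        mid for c in clusters if c.size < params.min_cluster_size
        for mid in c.member_ids
    ]
    return ClusteringOutcome(kept, dropped)


def _aligned_columns(member: str, rep: str) -> tuple[list[str], dict[int, str]]:
    """Align a member to the representative; per-rep-column symbols and
    insertions keyed by the rep position they precede."""
    res = edlib.align(member, rep, mode="NW", task="path")
    cols = []
    insertions: dict[int, str] = {}
    qi = ri = 0
    for length, op in _CIGAR_RE.findall(res["cigar"]):
        length = int(length)
        if op in ("=", "X", "M"):
            cols.extend(member[qi : qi + length])
            qi += length
            ri += length
        elif op == "I":  # present in member, absent from rep
            insertions[ri] = insertions.get(ri, "") + member[qi : qi + length]
            qi += length
        elif op == "D":  # gap in member at rep columns
            cols.extend("-" * length)
            ri += length
    return cols, insertions


def majority_consensus(
    cluster: Cluster,
    member_seqs: dict[str, str],
    min_cluster_size: int = 1,
) -> Consensus:
    """Per-column majority vote over members aligned to the representative.

    Insertion columns kept only when observed in at least half the members;
    a majority gap deletes the column; symbol ties break toward the
    representative's base.
    """
    if cluster.size < min_cluster_size:
        raise ValueError(
            f"cluster of size {cluster.size} below minimum {min_cluster_size}"
        )
    rep = cluster.representative
    n = cluster.size
    col_votes: list[Counter] = [Counter() for _ in range(len(rep))]
    ins_votes: dict[int, Counter] = {}
    for mid in cluster.member_ids:
        cols, insertions = _aligned_columns(member_seqs[mid], rep)
        for j, sym in enumerate(cols):
            col_votes[j][sym] += 1
        for pos, ins_seq in insertions.items():
            ins_votes.setdefault(pos, Counter())[ins_seq] += 1

    def _ins_at(pos: int) -> str:
        votes = ins_votes.get(pos)
        if votes is None or sum(votes.values()) * 2 < n:
            return ""
        best = max(votes.items(), key=lambda kv: (kv[1], -len(kv[0]), kv[0]))
        return best[0]

    out: list[str] = []
    for j in range(len(rep)):
        out.append(_ins_at(j))
        votes = col_votes[j]
        top = max(votes.values())
        tied = sorted(sym for sym, c in votes.items() if c == top)
        sym = rep[j] if rep[j] in tied else tied[0]
        if sym != "-":
            out.append(sym)
    out.append(_ins_at(len(rep)))
    return Consensus("".join(out), support=n, sample_id=cluster.sample_id)


def cluster_sample(
    reads: list[tuple[str, str]],
    params: ClusterParams | None = None,
    sample_id: str = "",
) -> tuple[list[Consensus], ClusteringOutcome]:
    """First clustering round for one sample: cluster reads, call consensuses."""
    params = params or ClusterParams()
    outcome = greedy_cluster(reads, params, sample_id=sample_id)
    seqs = dict(reads)
    consensuses = [
        majority_consensus(c, seqs, params.min_cluster_size)
        for c in outcome.clusters
    ]
    return consensuses, outcome


def recluster_consensuses(
    consensuses: list[Consensus],
    params: ClusterParams | None = None,
) -> list[Otu]:
    """Secondary clustering of per-sample consensuses into experiment OTUs.

    Same greedy rules with no minimum size (a consensus already carries its
    read support); per-sample counts sum member supports, and OTU ids are
    assigned in decreasing total-count order.
    """
    params = params or ClusterParams()
    items = [(f"c{i:05d}", c.sequence) for i, c in enumerate(consensuses)]
    by_id = {f"c{i:05d}": c for i, c in enumerate(consensuses)}
    outcome = greedy_cluster(
        items, ClusterParams(params.identity_threshold, min_cluster_size=1)
    )
    otus = []
    for cl in outcome.clusters:
        counts: dict[str, int] = {}
        for mid in cl.member_ids:
            cons = by_id[mid]
            counts[cons.sample_id] = counts.get(cons.sample_id, 0) + cons.support
        otus.append(Otu("", cl.representative, counts))
    otus.sort(key=lambda o: (-o.total_count, o.consensus))
    for i, otu in enumerate(otus):
        otu.otu_id = f"OTU_{i + 1:04d}"
    return otus


def build_otu_table(otus: list[Otu], samples: list[SampleRecord]) -> CountTable:
    """OTU-by-sample count matrix; columns follow sample-sheet order."""
    sample_ids = [s.sample_id for s in samples]
    known = set(sample_ids)
    for otu in otus:
        orphan = set(otu.per_sample_counts) - known
        if orphan:
            raise ValueError(f"{otu.otu_id}: counts for unknown samples {sorted(orphan)}")
    counts = pd.DataFrame(
        [[otu.per_sample_counts.get(s, 0) for s in sample_ids] for otu in otus],
        index=[otu.otu_id for otu in otus],
        columns=sample_ids,
        dtype=int,
    )
    ann = pd.DataFrame(
        {"consensus": [otu.consensus for otu in otus]},
        index=counts.index,
    )
    return CountTable(counts, ann, {s.sample_id: s for s in samples})
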
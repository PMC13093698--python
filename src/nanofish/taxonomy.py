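"""Local-alignment taxonomic assignment with Karlin–Altschul bit scores.

OTU consensuses are assigned by exact affine-gap Smith–Waterman against the
reference panel. Raw scores S are normalized to bit scores

    S' = (lambda * S - ln K) / ln 2

with the standard gapped nucleotide parameters (match +2, mismatch -3, gap
open 5 / extend 2, lambda = 0.625, K = 0.41), under which a perfect ~170 bp
amplicon match scores about 308 bits — so the 250-bit species cutoff sits in
a meaningful range. Species whose read-weighted mean bit score falls below
the cutoff are pooled into a single "unknown" row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align

from .io import CountTable, ReferencePanel, ReferenceRecord


@dataclass
class AlignmentParams:
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    lambda_: float = 0.625
    k_const: float = 0.41

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be positive")
        if not 0 < self.k_const < 1:
            raise ValueError("k_const must be in (0, 1)")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties are non-negative magnitudes")


@dataclass
class AlignmentResult:
    raw_score: int
    bit_score: float
    identity: float
    query_span: tuple[int, int]
    ref_span: tuple[int, int]
    ref_accession: str = ""


@dataclass
class TaxonomyParams:
    min_species_bit_score: float = 250.0
    tie_identity_delta: float = 0.0

    def __post_init__(self) -> None:
        if self.min_species_bit_score <= 0:
            raise ValueError("min_species_bit_score must be positive")


_ALIGNER_CACHE: dict[tuple, Align.PairwiseAligner] = {}


def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    key = (params.match, params.mismatch, params.gap_open, params.gap_extend)
    if key not in _ALIGNER_CACHE:
        # affine gap of length k costs gap_open + k * gap_extend
        _ALIGNER_CACHE[key] = Align.PairwiseAligner(
            mode="local",
            match_score=params.match,
            mismatch_score=params.mismatch,
            open_gap_score=-(params.gap_open + params.gap_extend),
            extend_gap_score=-params.gap_extend,
        )
    return _ALIGNER_CACHE[key]


def bit_score(raw: float, params: AlignmentParams | None = None) -> float:
    """Karlin–Altschul normalization: (lambda*S - ln K) / ln 2."""
    params = params or AlignmentParams()
    return (params.lambda_ * raw - math.log(params.k_const)) / math.log(2)


def local_align(
    query: str, ref: str, params: AlignmentParams | None = None
) -> AlignmentResult:
    """Optimal affine-gap Smith–Waterman alignment of query against ref."""
    if not query or not ref:
        raise ValueError("empty sequence")
    params = params or AlignmentParams()
    aligner = _aligner(params)
    alignments = aligner.align(query, ref)
    aln = alignments[0]
    counts = aln.counts()
    columns = (
        counts.identities + counts.mismatches + counts.internal_gaps
    )
    q_blocks, r_blocks = aln.aligned
    query_span = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    ref_span = (int(r_blocks[0][0]), int(r_blocks[-1][1]))
    raw = int(round(alignments.score))
    return AlignmentResult(
        raw_score=raw,
        bit_score=bit_score(raw, params),
        identity=counts.identities / columns if columns else 0.0,
        query_span=query_span,
        ref_span=ref_span,
    )


def _split_binomial(species: str) -> tuple[str, str]:
    parts = species.split(" ", 1)
    return (parts[0], parts[1]) if len(parts) == 2 else (species, "")


def composite_label(species_names: list[str]) -> str:
    """Merge indistinguishable species into one label.

    Same genus: the genus once plus the epithets joined with "-", in
    alphabetical order ("Pomacentrus pavo-coelestis"); across genera the
    full binomials are joined with "-".
    """
    uniq = sorted(set(species_names))
    if len(uniq) == 1:
        return uniq[0]
    genera = {_split_binomial(sp)[0] for sp in uniq}
    if len(genera) == 1:
        genus = genera.pop()
        epithets = sorted(_split_binomial(sp)[1] for sp in uniq)
        return f"{genus} {'-'.join(epithets)}"
    return "-".join(uniq)


def _merged_lineage(records: list[ReferenceRecord]) -> dict[str, str]:
    """Keep the ranks on which all records agree; blank disagreement to the
    lowest common rank."""
    out = {}
    agree = True
    for rank in ("family", "order", "class_"):
        values = {getattr(r, rank) for r in records}
        if agree and len(values) == 1:
            out[rank] = values.pop()
        else:
            agree = False
            out[rank] = "Unknown"
    # class/order may still agree even if family does not
    if out["family"] == "Unknown":
        orders = {r.order for r in records}
        classes = {r.class_ for r in records}
        if len(orders) == 1:
            out["order"] = orders.pop()
        if len(classes) == 1:
            out["class_"] = classes.pop()
    return out


def collapse_indistinguishable(panel: ReferencePanel) -> ReferencePanel:
    """Merge references with byte-identical sequences into composite records."""
    groups: dict[str, list[ReferenceRecord]] = {}
    order: list[str] = []
    for rec in panel:
        if rec.sequence not in groups:
            order.append(rec.sequence)
        groups.setdefault(rec.sequence, []).append(rec)
    merged: list[ReferenceRecord] = []
    for seq in order:
        members = groups[seq]
        species = sorted({r.species for r in members})
        if len(species) == 1:
            if len(members) == 1:
                merged.append(members[0])
            else:
                merged.append(
                    ReferenceRecord(
                        accession="+".join(r.accession for r in members),
                        species=members[0].species,
                        family=members[0].family,
                        order=members[0].order,
                        class_=members[0].class_,
                        sequence=seq,
                    )
                )
            continue
        lineage = _merged_lineage(members)
        merged.append(
            ReferenceRecord(
                accession="+".join(sorted(r.accession for r in members)),
                species=composite_label(species),
                family=lineage["family"],
                order=lineage["order"],
                class_=lineage["class_"],
                sequence=seq,
            )
        )
    return ReferencePanel(merged)


def assign_sequence(
    sequence: str,
    panel: ReferencePanel,
    aln_params: AlignmentParams | None = None,
    tax_params: TaxonomyParams | None = None,
) -> tuple[dict[str, str], AlignmentResult]:
    """Best-bit-score assignment of one sequence against a collapsed panel.

    Exact ties across species yield an ad-hoc composite label with the
    lowest common lineage.
    """
    if len(panel) == 0:
        raise ValueError("empty reference panel")
    aln_params = aln_params or AlignmentParams()
    tax_params = tax_params or TaxonomyParams()
    results: list[tuple[ReferenceRecord, AlignmentResult]] = []
    for rec in panel:
        res = local_align(sequence, rec.sequence, aln_params)
        res.ref_accession = rec.accession
        results.append((rec, res))
    best_bits = max(r.bit_score for _, r in results)
    tied = [
        (rec, r)
        for rec, r in results
        if best_bits - r.bit_score <= tax_params.tie_identity_delta * best_bits + 1e-9
    ]
    tied.sort(key=lambda t: t[0].accession)
    records = [rec for rec, _ in tied]
    best = max(tied, key=lambda t: (t[1].bit_score, t[1].identity, t[0].accession))[1]
    if len({r.species for r in records}) == 1:
        rec = records[0]
        taxonomy = {
            "species": rec.species,
            "family": rec.family,
            "order": rec.order,
            "class_": rec.class_,
        }
    else:
        lineage = _merged_lineage(records)
        taxonomy = {
            "species": composite_label([r.species for r in records]),
            "family": lineage["family"],
            "order": lineage["order"],
            "class_": lineage["class_"],
        }
    return taxonomy, best


def assign_otu_table(
    table: CountTable,
    panel: ReferencePanel,
    aln_params: AlignmentParams | None = None,
    tax_params: TaxonomyParams | None = None,
) -> CountTable:
    """Annotate every OTU row (consensus sequences) with taxonomy and metrics."""
    ann = table.row_annotations.copy()
    cols = {"species": [], "family": [], "order": [], "class_": [],
            "identity": [], "bit_score": [], "ref_accession": []}
    for row_id in table.row_ids:
        taxonomy, best = assign_sequence(
            ann.at[row_id, "consensus"], panel, aln_params, tax_params
        )
        for rank in ("species", "family", "order", "class_"):
            cols[rank].append(taxonomy[rank])
        cols["identity"].append(best.identity)
        cols["bit_score"].append(best.bit_score)
        cols["ref_accession"].append(best.ref_accession)
    for name, values in cols.items():
        ann[name] = values
    return CountTable(table.counts.copy(), ann, dict(table.samples))


def aggregate_to_species(
    table: CountTable, tax_params: TaxonomyParams | None = None
) -> CountTable:
    """Sum OTU rows into species rows; apply the weighted bit-score cutoff.

    Each species' mean bit score weights every member OTU's bit score by that
    OTU's total read count; species under ``min_species_bit_score`` are
    pooled into one "unknown" row.
    """
    tax_params = tax_params or TaxonomyParams()
    ann = table.row_annotations
    if "species" not in ann.columns or "bit_score" not in ann.columns:
        raise ValueError("OTU table must be taxonomy-annotated first")

    species_rows: dict[str, list[str]] = {}
    for row_id in table.row_ids:
        species_rows.setdefault(ann.at[row_id, "species"], []).append(row_id)

    labels, counts_rows, ann_rows = [], [], []
    unknown_counts = None
    unknown_weight = unknown_bits = 0.0
    for species, row_ids in species_rows.items():
        sub_counts = table.counts.loc[row_ids].sum(axis=0)
        weights = table.counts.loc[row_ids].sum(axis=1).astype(float)
        bits = ann.loc[row_ids, "bit_score"].astype(float)
        total = float(weights.sum())
        mean_bits = float((weights * bits).sum() / total) if total else float(bits.mean())
        if mean_bits < tax_params.min_species_bit_score:
            if unknown_counts is None:
                unknown_counts = sub_counts.copy()
            else:
                unknown_counts = unknown_counts + sub_counts
            unknown_weight += total
            unknown_bits += float((weights * bits).sum())
            continue
        labels.append(species)
        counts_rows.append(sub_counts)
        first = row_ids[0]
        ann_rows.append(
            {
                "species": species,
                "family": ann.at[first, "family"],
                "order": ann.at[first, "order"],
                "class_": ann.at[first, "class_"],
                "mean_bit_score": mean_bits,
                "n_otus": len(row_ids),
            }
        )
    if unknown_counts is not None:
        labels.append("unknown")
        counts_rows.append(unknown_counts)
        ann_rows.append(
            {
                "species": "unknown",
                "family": "Unknown",
                "order": "Unknown",
                "class_": "Unknown",
                "mean_bit_score": unknown_bits / unknown_weight if unknown_weight else 0.0,
                "n_otus": 0,
            }
        )
    counts = pd.DataFrame(counts_rows, index=labels).astype(int)
    counts = counts[table.col_ids]
    annotations = pd.DataFrame(ann_rows, index=labels)
    return CountTable(counts, annotations, dict(table.samples))
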
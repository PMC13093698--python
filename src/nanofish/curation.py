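"""Control stripping, prevalence-based contaminant screening, rarefaction.

The contaminant screen follows the prevalence logic of negative-control
decontamination: a taxon over-represented in field/PCR blanks relative to
environmental samples is flagged. The score is a one-sided Fisher exact
p-value on the 2x2 presence table, exact at the tiny blank counts typical
of eDNA designs; a score below the threshold (default 0.5) flags the row.

Rarefaction normalizes every sample to the same depth — 90% of the smallest
environmental sample total by default — by seeded subsampling without
replacement; the closed-form hypergeometric expectation is available for
rarefaction curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .io import CountTable

logger = logging.getLogger(__name__)


@dataclass
class CurationParams:
    control_taxa: list[str] = field(default_factory=lambda: ["Homo sapiens"])
    contaminant_threshold: float = 0.5
    rarefy_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.contaminant_threshold < 1:
            raise ValueError("contaminant_threshold must be in (0, 1)")
        if not 0 < self.rarefy_fraction <= 1:
            raise ValueError("rarefy_fraction must be in (0, 1]")


@dataclass
class RemovalRecord:
    label: str
    reason: str
    reads_removed: int
    score: float | None = None


def strip_control_taxa(
    table: CountTable, params: CurationParams
) -> tuple[CountTable, list[RemovalRecord]]:
    """Drop rows whose species label is a declared control taxon."""
    ann = table.row_annotations
    strip = set(params.control_taxa)
    removed: list[RemovalRecord] = []
    keep_rows = []
    for row_id in table.row_ids:
        label = ann.at[row_id, "species"] if "species" in ann.columns else row_id
        if label in strip or row_id in strip:
            removed.append(
                RemovalRecord(
                    label=str(label),
                    reason="control_taxon",
                    reads_removed=int(table.counts.loc[row_id].sum()),
                )
            )
        else:
            keep_rows.append(row_id)
    out = CountTable(
        table.counts.loc[keep_rows].copy(),
        ann.loc[keep_rows].copy(),
        dict(table.samples),
    )
    return out, removed


def prevalence_contaminant_score(
    present_blanks: int, n_blanks: int, present_env: int, n_env: int
) -> float:
    """One-sided Fisher exact p for over-representation in blanks.

    Low scores mean the taxon is seen in blanks more often than its
    prevalence in environmental samples explains — evidence it entered via
    reagents or handling rather than the water sample.
    """
    if n_blanks < 1 or n_env < 1:
        raise ValueError("need at least one blank and one environmental sample")
    table = [
        [present_blanks, present_env],
        [n_blanks - present_blanks, n_env - present_env],
    ]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def screen_contaminants(
    table: CountTable, params: CurationParams
) -> tuple[CountTable, list[RemovalRecord]]:
    """Flag and remove prevalence contaminants; drop blank columns after.

    With no blanks in the design the screen is skipped with a warning and
    all rows are retained.
    """
    blanks = [s for s, rec in table.samples.items() if rec.is_blank]
    env = [
        s for s, rec in table.samples.items() if rec.sample_type == "environmental"
    ]
    removed: list[RemovalRecord] = []
    if not blanks:
        logger.warning("no blank samples in design; contaminant screen skipped")
        return table.copy(), removed
    if not env:
        raise ValueError("contaminant screen needs at least one environmental sample")

    presence = table.counts >= 1
    keep_rows = []
    for row_id in table.row_ids:
        score = prevalence_contaminant_score(
            int(presence.loc[row_id, blanks].sum()),
            len(blanks),
            int(presence.loc[row_id, env].sum()),
            len(env),
        )
        if score < params.contaminant_threshold:
            removed.append(
                RemovalRecord(
                    label=str(row_id),
                    reason="prevalence_contaminant",
                    reads_removed=int(table.counts.loc[row_id].sum()),
                    score=score,
                )
            )
        else:
            keep_rows.append(row_id)
    non_blank = [s for s in table.col_ids if s not in set(blanks)]
    out = CountTable(
        table.counts.loc[keep_rows, non_blank].copy(),
        table.row_annotations.loc[keep_rows].copy(),
        {s: table.samples[s] for s in non_blank},
    )
    return out, removed


def rarefy_counts(table: CountTable, params: CurationParams) -> CountTable:
    """Subsample every column to 90% of the smallest environmental total.

    Each column is drawn without replacement (multivariate hypergeometric)
    with the seeded generator, so identical seeds give identical tables.
    """
    env_totals = [
        int(table.counts[s].sum())
        for s, rec in table.samples.items()
        if rec.sample_type == "environmental" and s in table.counts.columns
    ]
    totals = env_totals or [int(table.counts[s].sum()) for s in table.col_ids]
    if min(totals) <= 0:
        raise ValueError("every sample must have at least one read")
    depth = int(np.floor(params.rarefy_fraction * min(totals)))
    if depth < 1:
        raise ValueError(f"rarefaction depth {depth} < 1")
    rng = np.random.default_rng(params.seed)
    out = {}
    for s in table.col_ids:
        col = table.counts[s].to_numpy()
        total = int(col.sum())
        if total < depth:
            raise ValueError(f"sample {s!r} has {total} reads < depth {depth}")
        out[s] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(out, index=table.counts.index, dtype=int)
    return CountTable(counts, table.row_annotations.copy(), dict(table.samples))


def expected_richness(counts: np.ndarray | pd.Series, depth: int) -> float:
    """Exact hypergeometric rarefaction: E[species seen in `depth` draws].

    E[S_d] = sum_i 1 - C(N - N_i, d) / C(N, d).
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    total = int(counts.sum())
    if not 1 <= depth <= total:
        raise ValueError(f"depth must be in [1, {total}]")

    def log_comb(n: np.ndarray, k: int) -> np.ndarray:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    rest = total - counts
    probs = np.zeros(len(counts))
    feasible = rest >= depth
    probs[feasible] = np.exp(
        log_comb(rest[feasible], depth) - log_comb(np.array(total), depth)
    )
    return float(np.sum(1.0 - probs))


def curate(
    table: CountTable, params: CurationParams
) -> tuple[CountTable, list[RemovalRecord]]:
    """Full curation: strip controls, screen contaminants, drop non-field
    samples, rarefy."""
    stripped, removed = strip_control_taxa(table, params)
    screened, flagged = screen_contaminants(stripped, params)
    removed.extend(flagged)
    env_and_mock = [
        s
        for s, rec in screened.samples.items()
        if rec.sample_type in ("environmental", "mock") and s in screened.counts.columns
    ]
    screened = screened.select_samples(env_and_mock)
    # drop rows emptied by control/column removal before rarefying
    nonzero = screened.counts.sum(axis=1) > 0
    screened = CountTable(
        screened.counts.loc[nonzero].copy(),
        screened.row_annotations.loc[nonzero].copy(),
        dict(screened.samples),
    )
    rarefied = rarefy_counts(screened, params)
    return rarefied, removed
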
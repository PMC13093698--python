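"""Synthetic reference panels, barcoded noisy amplicon reads and designs.

The simulator emulates the structure of a dual-barcoded MiFish-U amplicon:

    barcode + forward primer + insert + revcomp(reverse primer) + barcode

with independent per-base substitution/insertion/deletion errors, optional
two-parent chimeras, human contaminant reads, and a ground-truth table so
every downstream stage can be scored against what was actually emitted.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Read, ReferencePanel, ReferenceRecord, SampleRecord, revcomp

# MiFish-U universal fish primer pair (~170 bp 12S fragment).
MIFISH_U_F = "GCCGGTAAAACTCGTGCCAGC"
MIFISH_U_R = "CATAGTGGGGTATCTAATCCCAGTTTG"

HUMAN_SPECIES = "Homo sapiens"

MAX_BARCODES = 24
_BARCODE_LENGTH = 24
_BARCODE_MIN_DIST = 8
_BARCODE_SEED = 20211101  # fixed once; the barcode table is a package constant

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _edit_distance(a: str, b: str) -> int:
    import edlib

    return edlib.align(a, b, mode="NW")["editDistance"]


def _generate_barcodes() -> dict[str, str]:
    rng = random.Random(_BARCODE_SEED)
    barcodes: list[str] = []
    while len(barcodes) < MAX_BARCODES:
        cand = "".join(rng.choice("ACGT") for _ in range(_BARCODE_LENGTH))
        if all(_edit_distance(cand, b) >= _BARCODE_MIN_DIST for b in barcodes):
            barcodes.append(cand)
    return {f"BC{i + 1:02d}": seq for i, seq in enumerate(barcodes)}


_BARCODE_CACHE: dict[str, str] | None = None


def barcode_table() -> dict[str, str]:
    """The 24 synthetic barcodes (24-mers, pairwise edit distance >= 8)."""
    global _BARCODE_CACHE
    if _BARCODE_CACHE is None:
        _BARCODE_CACHE = _generate_barcodes()
    return dict(_BARCODE_CACHE)


@dataclass
class ErrorModel:
    """Independent per-base error rates and the constant simulated quality."""

    sub_rate: float = 0.03
    ins_rate: float = 0.02
    del_rate: float = 0.02
    base_quality: int = 12

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            rate = getattr(self, name)
            if not 0 <= rate <= 0.3:
                raise ValueError(f"{name} must be in [0, 0.3]")
        if self.sub_rate + self.ins_rate + self.del_rate >= 0.5:
            raise ValueError("total error rate must be < 0.5")


@dataclass
class CommunityProfile:
    """Relative species abundances, normalized to sum to one."""

    species_weights: dict[str, float]

    def __post_init__(self) -> None:
        if not self.species_weights:
            raise ValueError("empty community profile")
        if any(w <= 0 for w in self.species_weights.values()):
            raise ValueError("weights must be positive")
        total = float(sum(self.species_weights.values()))
        self.species_weights = {
            sp: w / total for sp, w in self.species_weights.items()
        }

    @classmethod
    def uniform(cls, species: list[str]) -> "CommunityProfile":
        return cls({sp: 1.0 for sp in species})


def synth_reference_panel(
    n_species: int,
    n_identical_pairs: int = 0,
    target_identity_range: tuple[float, float] = (0.80, 0.92),
    amplicon_length: int = 170,
    seed: int = 0,
    max_retries: int = 30,
) -> ReferencePanel:
    """Generate a fish reference panel plus one human control record.

    ``n_identical_pairs`` species pairs share byte-identical sequences
    (indistinguishable at this locus, as happens for congeners sharing a 12S
    fragment); all other inter-species identities fall inside
    ``target_identity_range``, verified with the package's own global-identity
    measure.
    """
    from .otu import pairwise_identity

    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if amplicon_length < 100:
        raise ValueError("amplicon_length must be >= 100")
    if n_identical_pairs > n_species // 2:
        raise ValueError("n_identical_pairs must be <= n_species / 2")

    lo, hi = target_identity_range
    n_distinct = n_species - n_identical_pairs
    # Divergence per lineage from a shared ancestor; two lineages at
    # substitution distance m each sit near identity 1 - 2m(1 - m·2/3).
    m_lo = (1 - hi) / 2 * 1.05
    m_hi = (1 - lo) / 2 * 0.95

    for attempt in range(max_retries):
        rng = np.random.default_rng((seed, attempt))
        ancestor = _BASES[rng.integers(0, 4, amplicon_length)]
        seqs: list[str] = []
        for _ in range(n_distinct):
            m = rng.uniform(m_lo, m_hi)
            n_mut = max(1, round(m * amplicon_length))
            pos = rng.choice(amplicon_length, size=n_mut, replace=False)
            derived = ancestor.copy()
            shift = rng.integers(1, 4, size=n_mut).astype(np.uint8)
            idx = np.searchsorted(_BASES, derived[pos])
            derived[pos] = _BASES[(idx + shift) % 4]
            seqs.append(derived.tobytes().decode())
        ok = all(
            lo <= pairwise_identity(seqs[i], seqs[j]) <= hi
            for i in range(n_distinct)
            for j in range(i + 1, n_distinct)
        )
        if ok:
            break
    else:
        raise RuntimeError(
            "could not satisfy identity constraints; widen target_identity_range"
        )

    records: list[ReferenceRecord] = []
    epithets = [f"taxon{i + 1:02d}" for i in range(n_species)]
    # duplicate partners reuse the first n_identical_pairs distinct sequences
    full_seqs = seqs + seqs[:n_identical_pairs]
    for i in range(n_species):
        records.append(
            ReferenceRecord(
                accession=f"SYN{i + 1:03d}",
                species=f"Synthichthys {epithets[i]}",
                family="Synthidae",
                order="Synthiformes",
                class_="Actinopteri",
                sequence=full_seqs[i],
            )
        )

    # human control: random sequence, re-drawn until clearly below `lo`
    hrng = np.random.default_rng((seed, 7))
    while True:
        human = _BASES[hrng.integers(0, 4, amplicon_length)].tobytes().decode()
        if all(pairwise_identity(human, s) < lo for s in seqs):
            break
    records.append(
        ReferenceRecord(
            accession="HSAP01",
            species=HUMAN_SPECIES,
            family="Hominidae",
            order="Primates",
            class_="Mammalia",
            sequence=human,
        )
    )
    return ReferencePanel(records)


def _mutate(seq: str, error: ErrorModel, rng: np.random.Generator) -> str:
    """Apply independent substitution/insertion/deletion errors to a sequence."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = arr.size
    draws = rng.random((3, n))
    sub = draws[0] < error.sub_rate
    if sub.any():
        idx = np.searchsorted(_BASES, arr[sub])
        shift = rng.integers(1, 4, size=int(sub.sum())).astype(np.uint8)
        arr[sub] = _BASES[(idx + shift) % 4]
    keep = draws[1] >= error.del_rate
    ins = draws[2] < error.ins_rate
    if not ins.any():
        return arr[keep].tobytes().decode()
    out = []
    ins_bases = _BASES[rng.integers(0, 4, int(ins.sum()))]
    k = 0
    for i in range(n):
        if keep[i]:
            out.append(arr[i])
        if ins[i]:
            out.append(ins_bases[k])
            k += 1
    return bytes(out).decode()


@dataclass
class SimulatedSample:
    reads: list[Read]
    truth: pd.DataFrame  # read_id, true_species, sample_id, is_chimera, is_contaminant


def simulate_sample(
    panel: ReferencePanel,
    profile: CommunityProfile,
    n_reads: int,
    error: ErrorModel,
    barcode_id: str,
    sample_id: str | None = None,
    chimera_rate: float = 0.0,
    contaminant_rate: float = 0.0,
    seed: int = 0,
) -> SimulatedSample:
    """Emit ``n_reads`` dual-barcoded amplicon reads plus their truth table."""
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    species_seqs = {rec.species: rec.sequence for rec in panel}
    missing = set(profile.species_weights) - set(species_seqs)
    if missing:
        raise ValueError(f"profile species not in panel: {sorted(missing)}")
    if HUMAN_SPECIES not in species_seqs and contaminant_rate > 0:
        raise ValueError("panel lacks a human record for contaminant reads")

    barcode = barcode_table()[barcode_id]
    sample_id = sample_id or barcode_id
    rng = np.random.default_rng((seed, 0xF15))
    names = list(profile.species_weights)
    weights = np.array([profile.species_weights[sp] for sp in names])
    picks = rng.choice(len(names), size=n_reads, p=weights)

    reads: list[Read] = []
    truth_rows = []
    rc_rev = revcomp(MIFISH_U_R)
    for i in range(n_reads):
        is_contaminant = bool(rng.random() < contaminant_rate)
        is_chimera = False
        if is_contaminant:
            species = HUMAN_SPECIES
            insert = species_seqs[HUMAN_SPECIES]
        else:
            species = names[picks[i]]
            insert = species_seqs[species]
            if len(names) >= 2 and rng.random() < chimera_rate:
                is_chimera = True
                other = names[int(rng.choice([j for j in range(len(names)) if j != picks[i]]))]
                partner = species_seqs[other]
                cut = int(rng.integers(1, min(len(insert), len(partner))))
                insert = insert[:cut] + partner[cut:]
        insert = _mutate(insert, error, rng)
        seq = barcode + MIFISH_U_F + insert + rc_rev + barcode
        if rng.random() < 0.5:
            seq = revcomp(seq)
        read_id = f"{sample_id}_r{i:06d}"
        reads.append(Read(read_id, seq, [error.base_quality] * len(seq)))
        truth_rows.append((read_id, species, sample_id, is_chimera, is_contaminant))

    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "true_species", "sample_id", "is_chimera", "is_contaminant"],
    )
    return SimulatedSample(reads, truth)


def build_design(
    n_replicates: int,
    include_blanks: bool = True,
    include_positive: bool = True,
    experiment_id: str = "EXP_A",
) -> list[SampleRecord]:
    """An experimental design: replicates plus optional blank/positive control."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    total = n_replicates + int(include_blanks) + int(include_positive)
    if total > MAX_BARCODES:
        raise ValueError(
            f"design needs {total} barcoded samples but only {MAX_BARCODES} "
            "unique ONT barcodes are available"
        )
    barcode_ids = list(barcode_table())
    samples = [
        SampleRecord(
            sample_id=f"ENV{i + 1:02d}",
            barcode_id=barcode_ids[i],
            sample_type="environmental",
            replicate=i + 1,
            experiment_id=experiment_id,
        )
        for i in range(n_replicates)
    ]
    nxt = n_replicates
    if include_blanks:
        samples.append(
            SampleRecord(
                sample_id="BLANK1",
                barcode_id=barcode_ids[nxt],
                sample_type="field_blank",
                experiment_id=experiment_id,
            )
        )
        nxt += 1
    if include_positive:
        samples.append(
            SampleRecord(
                sample_id="POS1",
                barcode_id=barcode_ids[nxt],
                sample_type="positive_control",
                experiment_id=experiment_id,
            )
        )
    return samples


# re-export the aquarium fixture here so the simulate surface is complete
from .aquarium import aquarium_fixture  # noqa: E402,F401
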
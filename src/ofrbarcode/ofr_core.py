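"""Oligonucleotide Frequency Range (OFR) species discrimination.

For each species the frequency of every k-mer is summarised by its minimum
and maximum over the species' accessions.  Two species are *resolved* when at
least one k-mer's ranges do not overlap and are separated by at least the
threshold t = 1/(a−k+1), where a is the dataset's average ungapped sequence
length (1/(a−1) for dinucleotides, 1/(a−2) for trinucleotides).  Pairwise
outcomes populate a symmetric 0/1 "binomial" matrix from which percent
species resolution is scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidLengthError, UndefinedScoreError
from .oligofreq import KmerProfile, all_kmers, kmer_frequencies
from .seqdata import BarcodeDataset

#: Absolute tolerance for comparisons against the threshold t.
T_TOL = 1e-12


@dataclass(frozen=True)
class ThresholdSpec:
    """Minimum inter-range gap for a k-mer to count as discriminating."""

    k: int
    average_length: float

    @property
    def t(self) -> float:
        return 1.0 / (self.average_length - (self.k - 1))


def threshold(average_length: float, k: int) -> ThresholdSpec:
    """Build the dataset-wide threshold t = 1/(a − k + 1)."""
    if average_length <= k - 1:
        raise InvalidLengthError(
            f"average length {average_length} too short for k={k}"
        )
    return ThresholdSpec(k=k, average_length=average_length)


@dataclass(frozen=True)
class FrequencyRange:
    oligo: str
    lo: float
    hi: float


@dataclass
class OFRProfile:
    """Per-species min–max frequency range for every k-mer."""

    species_id: str
    k: int
    lo: np.ndarray  # min frequency per oligo, lexicographic oligo order
    hi: np.ndarray
    n_accessions: int

    @property
    def ranges(self) -> dict[str, FrequencyRange]:
        return {
            w: FrequencyRange(w, float(l), float(h))
            for w, l, h in zip(all_kmers(self.k), self.lo, self.hi)
        }


def species_ofr(
    ds: BarcodeDataset, species_id: str, k: int, denominator: str = "length"
) -> OFRProfile:
    """Min/max k-mer frequencies over one species' accessions."""
    try:
        recs = ds.species_index[species_id]
    except KeyError:
        raise ConfigError(f"unknown species {species_id!r}") from None
    vecs = np.stack(
        [kmer_frequencies(r.residues, k, denominator).vector for r in recs]
    )
    return OFRProfile(
        species_id=species_id,
        k=k,
        lo=vecs.min(axis=0),
        hi=vecs.max(axis=0),
        n_accessions=len(recs),
    )


@dataclass
class PairResolution:
    """Outcome of one species-pair comparison.

    ``status`` is ``"not_evaluable"`` when either species has too few
    accessions to define a range — distinct from ``"unresolved"``.
    ``max_gap`` is the signed separation of the best oligo: positive for a
    gap, negative for an overlap (NaN when not evaluable).
    """

    species_a: str
    species_b: str
    status: str  # "resolved" | "unresolved" | "not_evaluable"
    discriminating_oligos: list[tuple[str, float]] = field(default_factory=list)
    max_gap: float = float("nan")

    @property
    def resolved(self) -> bool:
        return self.status == "resolved"


def resolve_pair(
    pa: OFRProfile,
    pb: OFRProfile,
    ts: ThresholdSpec,
    min_accessions: int = 2,
) -> PairResolution:
    """Compare two species' OFRs against the threshold.

    For each oligo the separation is ``max(lo_b − hi_a, lo_a − hi_b)``; the
    oligo discriminates when the separation is at least t ("at least" read
    inclusively). Symmetric in its two profiles.
    """
    if pa.k != pb.k or pa.k != ts.k:
        raise ConfigError(
            f"mismatched k: profiles {pa.k}/{pb.k}, threshold {ts.k}"
        )
    if pa.n_accessions < min_accessions or pb.n_accessions < min_accessions:
        return PairResolution(pa.species_id, pb.species_id, "not_evaluable")
    gaps = np.maximum(pb.lo - pa.hi, pa.lo - pb.hi)
    disc_mask = gaps >= ts.t - T_TOL
    oligos = all_kmers(ts.k)
    disc = [(oligos[i], float(gaps[i])) for i in np.nonzero(disc_mask)[0]]
    return PairResolution(
        species_a=pa.species_id,
        species_b=pb.species_id,
        status="resolved" if disc else "unresolved",
        discriminating_oligos=disc,
        max_gap=float(gaps.max()),
    )


@dataclass
class ResolutionMatrix:
    """Symmetric species-pair matrix: 1 resolved, 0 unresolved, NaN skipped."""

    species_ids: list[str]
    cells: np.ndarray
    evidence: dict[frozenset, PairResolution]
    threshold_spec: ThresholdSpec

    def pair(self, a: str, b: str) -> PairResolution:
        return self.evidence[frozenset((a, b))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.cells, index=self.species_ids, columns=self.species_ids
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", na_rep="NA")

    def evidence_report(self) -> dict:
        """JSON-serialisable per-pair evidence (discriminating oligos, gaps, t)."""
        pairs = []
        for pr in self.evidence.values():
            pairs.append(
                {
                    "species_a": pr.species_a,
                    "species_b": pr.species_b,
                    "status": pr.status,
                    "max_gap": None if np.isnan(pr.max_gap) else pr.max_gap,
                    "discriminating_oligos": [
                        {"oligo": o, "gap": g} for o, g in pr.discriminating_oligos
                    ],
                }
            )
        return {
            "k": self.threshold_spec.k,
            "average_length": self.threshold_spec.average_length,
            "t": self.threshold_spec.t,
            "pairs": pairs,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.evidence_report(), fh, indent=1)


def resolution_matrix(
    ds: BarcodeDataset,
    k: int,
    min_accessions: int = 2,
    denominator: str = "length",
) -> ResolutionMatrix:
    """Evaluate every unordered species pair with the dataset-wide threshold."""
    if ds.species_count < 2:
        raise ConfigError("resolution requires at least two species")
    ts = threshold(ds.average_length, k)
    profiles = {
        sp: species_ofr(ds, sp, k, denominator) for sp in ds.species_ids
    }
    ids = ds.species_ids
    m = len(ids)
    cells = np.full((m, m), np.nan)
    np.fill_diagonal(cells, np.nan)
    evidence: dict[frozenset, PairResolution] = {}
    for i, j in combinations(range(m), 2):
        pr = resolve_pair(profiles[ids[i]], profiles[ids[j]], ts, min_accessions)
        evidence[frozenset((ids[i], ids[j]))] = pr
        val = np.nan if pr.status == "not_evaluable" else float(pr.resolved)
        cells[i, j] = cells[j, i] = val
    return ResolutionMatrix(ids, cells, evidence, ts)


def percent_resolution(rm: ResolutionMatrix, mode: str = "species") -> float:
    """Score a resolution matrix as a percentage.

    ``"species"``: share of evaluable species resolved against *every* other
    evaluable species.  ``"pairs"``: share of evaluable pairs resolved.
    Not-evaluable pairs are excluded from both denominators.
    """
    cells = rm.cells
    m = len(rm.species_ids)
    if mode == "pairs":
        iu = np.triu_indices(m, 1)
        vals = cells[iu]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise UndefinedScoreError("no evaluable species pairs")
        return 100.0 * float(vals.sum()) / vals.size
    if mode == "species":
        evaluable = [
            i
            for i in range(m)
            if any(not np.isnan(cells[i, j]) for j in range(m) if j != i)
        ]
        if len(evaluable) < 2:
            raise UndefinedScoreError("fewer than two evaluable species")
        resolved = 0
        for i in evaluable:
            others = [cells[i, j] for j in evaluable if j != i]
            vals = [v for v in others if not np.isnan(v)]
            if vals and all(v == 1.0 for v in vals):
                resolved += 1
        return 100.0 * resolved / len(evaluable)
    raise ConfigError(f"unknown mode {mode!r}")
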